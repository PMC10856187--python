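"""Orchestration of the three analysis arms into a single revision report.

The arms are independent: a compound can be screened by fingerprint PCA
alone, ranked by DP4+ alone, or additionally checked against an experimental
ECD trace. Absent arms appear as explicit nulls in the report so downstream
consumers see a stable schema.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict

import numpy as np

from . import dft_nmr, ecd
from .dft_nmr import (DP4Parameters, DP4Result, ScalingFactors,
                      ShiftComparison, dp4_plus, error_stats,
                      candidate_shift_maps)
from .fingerprint import (FingerprintDataset, MisassignmentReport,
                          ShiftFingerprint, flag_misassignment)

logger = logging.getLogger("fpcrevise")

__version__ = "0.1.0"


class PipelineError(ValueError):
    """Contradictory pipeline configuration."""


@dataclass(frozen=True)
class RevisionReport:
    """Combined fingerprint / DP4+ / ECD evidence for one compound."""

    compound_id: str
    misassignment: MisassignmentReport | None
    comparisons: tuple          # of ShiftComparison, one per candidate
    dp4: DP4Result | None
    ecd_comparisons: dict | None   # candidate_id -> SpectrumComparison
    verdict: str | None            # candidate with the highest DP4+ probability
    concordant: bool | None


def run_revision(compound_id: str,
                 fingerprint_dataset: FingerprintDataset | None = None,
                 fingerprint: ShiftFingerprint | None = None,
                 ensembles=None,
                 exp_shifts: dict | None = None,
                 exp_nuclei: dict | None = None,
                 transition_sets: dict | None = None,
                 exp_spectrum: ecd.ECDSpectrum | None = None,
                 candidate_classes: dict | None = None,
                 factors: ScalingFactors | None = None,
                 dp4_params: DP4Parameters | None = None,
                 sigma_ref: dict | None = None,
                 window: float = dft_nmr.DEFAULT_ENERGY_WINDOW,
                 temperature: float = dft_nmr.DEFAULT_TEMPERATURE,
                 threshold: float = 1.0) -> RevisionReport:
    """Run every arm for which inputs were supplied and assemble the report.

    Requires at least the fingerprint arm (dataset + compound fingerprint) or
    the DP4+ arm (candidate ensembles + experimental shifts). The ECD arm
    (``transition_sets`` keyed by candidate id + ``exp_spectrum``) is
    optional. ``candidate_classes`` optionally maps candidate ids to
    fingerprint class labels so the concordance flag can include the
    fingerprint arm.
    """
    has_fp = fingerprint_dataset is not None and fingerprint is not None
    has_dp4 = bool(ensembles) and exp_shifts is not None
    if not (has_fp or has_dp4):
        raise PipelineError(
            "need fingerprint inputs or (ensembles + experimental shifts)"
        )
    if transition_sets is not None and ensembles:
        unknown = set(transition_sets) - {e.candidate_id for e in ensembles}
        if unknown:
            raise PipelineError(
                f"transition sets for unknown candidates: {sorted(unknown)}"
            )

    mis = None
    if has_fp:
        mis = flag_misassignment(fingerprint_dataset, fingerprint,
                                 threshold=threshold)
        logger.info("fingerprint arm: nearest class %s (flagged=%s)",
                    mis.pca_nearest_class, mis.flagged)
    else:
        logger.info("fingerprint arm skipped: no inputs")

    comparisons: list[ShiftComparison] = []
    dp4 = None
    verdict = None
    if has_dp4:
        factors = factors or dft_nmr.default_scaling_factors()
        dp4_params = dp4_params or dft_nmr.default_dp4_parameters()
        sigma_ref = sigma_ref or {el: f[1] for el, f in factors.factors.items()}
        nuclei = dict(exp_nuclei or {})
        cand_maps = []
        for ens in ensembles:
            maps = candidate_shift_maps(ens, exp_shifts, factors, sigma_ref,
                                        window=window, T=temperature)
            for nid, el in maps["elements"].items():
                nuclei.setdefault(nid, dft_nmr.NucleusRecord(
                    nid, el, ens.nuclei[nid].hybridization
                    if nid in ens.nuclei else "sp3"))
            comparisons.append(error_stats(maps["global_scaled"], exp_shifts,
                                           candidate_id=ens.candidate_id))
            cand_maps.append((ens.candidate_id, maps["regression_scaled"],
                              maps["unscaled"]))
        dp4 = dp4_plus(cand_maps, exp_shifts, dp4_params, nuclei)
        verdict = dp4.winner()
        top = sorted(dp4.total.values(), reverse=True)
        if len(top) > 1 and top[0] == top[1]:
            logger.warning("DP4+ tie; verdict %r chosen lexicographically",
                           verdict)
    else:
        logger.info("DP4+ arm skipped: no ensembles/experimental shifts")

    ecd_cmp = None
    if transition_sets is not None and exp_spectrum is not None:
        ecd_cmp = {}
        for cid, sets in transition_sets.items():
            calc = ecd.boltzmann_average_spectra(list(sets), T=temperature)
            ecd_cmp[cid] = ecd.similarity_with_shift(calc, exp_spectrum)
            logger.info("ECD arm: %s similarity %.4f at %+g nm", cid,
                        ecd_cmp[cid].similarity, ecd_cmp[cid].best_shift_nm)
    else:
        logger.info("ECD arm skipped: no transitions/experimental spectrum")

    concordant = None
    if verdict is not None:
        checks = []
        if ecd_cmp:
            best_ecd = max(ecd_cmp, key=lambda c: ecd_cmp[c].similarity)
            checks.append(best_ecd == verdict)
        if mis is not None and candidate_classes:
            checks.append(candidate_classes.get(verdict) == mis.pca_nearest_class)
        concordant = all(checks) if checks else True

    return RevisionReport(
        compound_id=compound_id,
        misassignment=mis,
        comparisons=tuple(comparisons),
        dp4=dp4,
        ecd_comparisons=ecd_cmp,
        verdict=verdict,
        concordant=concordant,
    )


# ---------------------------------------------------------------------------
# Serialization

def _jsonable(obj):
    if obj is None or isinstance(obj, (str, int, float, bool)):
        return obj
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    raise TypeError(f"cannot serialize {type(obj)}")


def report_to_dict(report: RevisionReport, config: dict | None = None) -> dict:
    doc = _jsonable(report)
    doc["version"] = __version__
    cfg = _jsonable(config or {})
    doc["config"] = cfg
    doc["config_hash"] = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]
    return doc


def write_report(report: RevisionReport, out_dir, config: dict | None = None):
    """Emit report.json plus a human-readable summary.md; returns the paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    doc = report_to_dict(report, config)
    json_path = out / f"{report.compound_id}_report.json"
    json_path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")

    lines = [f"# Revision report: {report.compound_id}", ""]
    if report.misassignment is not None:
        m = report.misassignment
        lines += [
            "## Fingerprint",
            f"- assigned class: {m.assigned_class}",
            f"- PCA nearest class: {m.pca_nearest_class}",
            f"- max range deviation: {m.max_deviation:.2f} ppm "
            f"(threshold {m.threshold:g})",
            f"- flagged: {m.flagged}", "",
        ]
    if report.comparisons:
        lines += ["## Shift errors (globally scaled)",
                  "| candidate | MAE / ppm | RMSD / ppm |", "|---|---|---|"]
        lines += [f"| {c.candidate_id} | {c.mae:.2f} | {c.rmsd:.2f} |"
                  for c in report.comparisons]
        lines.append("")
    if report.dp4 is not None:
        lines += ["## DP4+", "| candidate | probability |", "|---|---|"]
        lines += [f"| {cid} | {100 * p:.0f}% |"
                  for cid, p in sorted(report.dp4.total.items())]
        lines.append("")
    if report.ecd_comparisons:
        lines += ["## ECD", "| candidate | similarity | best shift / nm |",
                  "|---|---|---|"]
        lines += [f"| {cid} | {c.similarity:.4f} | {c.best_shift_nm:+g} |"
                  for cid, c in sorted(report.ecd_comparisons.items())]
        lines.append("")
    lines += [f"**Verdict:** {report.verdict}  ",
              f"**Concordant:** {report.concordant}", ""]
    md_path = out / f"{report.compound_id}_summary.md"
    md_path.write_text("\n".join(lines))
    return json_path, md_path
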