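"""Post-processing of GIAO DFT conformer ensembles into candidate-structure scores.

Input is everything downstream of the quantum chemistry: per-conformer
relative energies (kcal/mol) and isotropic shielding tensors (ppm) for each
candidate structure, plus the experimental shift assignments. The chain is

    energy filter (<= 3.0 kcal/mol) -> Boltzmann weights (298.15 K)
    -> weighted shieldings -> shifts (global linear scaling, or per-candidate
    regression for the DP4+ scaled branch, or reference-shielding subtraction
    for the unscaled branch) -> MAE/RMSD and DP4+ probabilities.

DP4+ models per-nucleus errors (calculated - experimental) as Student-t
variables: a mean-zero branch on regression-scaled shifts plus a branch on
unscaled shifts whose parameters are keyed by element and, for carbon,
hybridization. Candidate probabilities are the softmax of the summed
log-densities over candidates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

#: Gas constant in kcal/(mol K).
R_KCAL = 1.9872041e-3
DEFAULT_TEMPERATURE = 298.15
DEFAULT_ENERGY_WINDOW = 3.0  # kcal/mol, boundary inclusive
KJ_PER_KCAL = 4.184


class EnsembleError(ValueError):
    """Malformed conformer ensemble or inconsistent nucleus coverage."""


class DP4ParameterError(ValueError):
    """Missing or invalid Student-t parameter entry."""


@dataclass(frozen=True)
class NucleusRecord:
    """Identity of one NMR-active position matched to an experimental assignment."""

    nucleus_id: str
    element: str            # "C" or "H"
    hybridization: str = "sp3"   # sp2 | sp3; protons are sp3 by convention
    equivalence_group: str | None = None  # nuclei averaged into one assignment

    def __post_init__(self):
        if self.element not in ("C", "H"):
            raise EnsembleError(f"{self.nucleus_id}: element must be C or H")
        if self.hybridization not in ("sp2", "sp3"):
            raise EnsembleError(f"{self.nucleus_id}: bad hybridization")


@dataclass(frozen=True)
class Conformer:
    relative_energy: float              # kcal/mol above the ensemble minimum
    shieldings: dict                    # nucleus_id -> isotropic shielding, ppm


@dataclass(frozen=True)
class ConformerEnsemble:
    """All conformers of one candidate structure, energies re-based to min = 0."""

    candidate_id: str
    conformers: tuple                   # of Conformer
    nuclei: dict                        # nucleus_id -> NucleusRecord

    def __post_init__(self):
        if not self.conformers:
            raise EnsembleError(f"{self.candidate_id}: empty ensemble")
        keys = set(self.conformers[0].shieldings)
        for i, c in enumerate(self.conformers):
            if set(c.shieldings) != keys:
                missing = keys.symmetric_difference(c.shieldings)
                raise EnsembleError(
                    f"{self.candidate_id}: conformer {i} nucleus set differs "
                    f"from conformer 0 ({sorted(missing)})"
                )
        if set(self.nuclei) != keys:
            raise EnsembleError(
                f"{self.candidate_id}: nucleus metadata does not match shieldings"
            )
        e = np.array([c.relative_energy for c in self.conformers])
        if not np.isfinite(e).all():
            raise EnsembleError(f"{self.candidate_id}: non-finite energy")
        if abs(e.min()) > 1e-9:
            raise EnsembleError(
                f"{self.candidate_id}: energies not re-based (min = {e.min():g})"
            )

    @property
    def energies(self) -> np.ndarray:
        return np.array([c.relative_energy for c in self.conformers])


@dataclass(frozen=True)
class ShiftComparison:
    """Per-nucleus errors and summary statistics for one candidate."""

    candidate_id: str
    errors: dict        # nucleus_id -> calc - exp, ppm
    mae: float
    rmsd: float


@dataclass(frozen=True)
class DP4Result:
    """Normalized candidate probabilities with per-branch/per-element components."""

    candidate_ids: tuple
    total: dict         # candidate_id -> probability
    scaled_only: dict
    unscaled_only: dict
    carbon_only: dict
    proton_only: dict

    def winner(self) -> str:
        best = max(self.total.values())
        return min(c for c, p in self.total.items() if p == best)


# ---------------------------------------------------------------------------
# Parameter tables

@dataclass(frozen=True)
class ScalingFactors:
    """Per-element linear regression factors, delta = (intercept - sigma)/(-slope)."""

    factors: dict       # element -> (slope, intercept)
    provenance: str = ""

    def __post_init__(self):
        for el, (slope, _) in self.factors.items():
            if slope == 0:
                raise DP4ParameterError(f"zero slope for element {el}")

    @classmethod
    def from_json(cls, path) -> "ScalingFactors":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            factors={el: (v["slope"], v["intercept"])
                     for el, v in doc["factors"].items()},
            provenance=doc.get("provenance", ""),
        )


@dataclass(frozen=True)
class DP4Parameters:
    """Student-t (mu, sigma, nu) per branch/element (and hybridization, unscaled C)."""

    scaled: dict        # element -> (mu, sigma, nu)
    unscaled: dict      # element -> hybridization -> (mu, sigma, nu)
    provenance: str = ""

    def __post_init__(self):
        for mu, sigma, nu in list(self.scaled.values()) + [
            t for d in self.unscaled.values() for t in d.values()
        ]:
            if sigma <= 0 or nu <= 0:
                raise DP4ParameterError(
                    f"sigma and nu must be positive, got ({mu}, {sigma}, {nu})"
                )

    def lookup(self, element: str, branch: str, hybridization: str = "sp3"):
        if branch == "scaled":
            try:
                return self.scaled[element]
            except KeyError:
                raise DP4ParameterError(
                    f"no scaled parameters for element {element}"
                ) from None
        try:
            return self.unscaled[element][hybridization]
        except KeyError:
            raise DP4ParameterError(
                f"no unscaled parameters for ({element}, {hybridization})"
            ) from None

    @classmethod
    def from_json(cls, path) -> "DP4Parameters":
        with open(path) as fh:
            doc = json.load(fh)
        scaled = {el: (v["mu"], v["sigma"], v["nu"])
                  for el, v in doc["scaled"].items()}
        unscaled = {
            el: {hyb: (v["mu"], v["sigma"], v["nu"]) for hyb, v in d.items()}
            for el, d in doc["unscaled"].items()
        }
        return cls(scaled=scaled, unscaled=unscaled,
                   provenance=doc.get("provenance", ""))


def default_scaling_factors() -> ScalingFactors:
    from importlib.resources import files
    return ScalingFactors.from_json(files("fpcrevise.data") / "scaling_factors.json")


def default_dp4_parameters() -> DP4Parameters:
    from importlib.resources import files
    return DP4Parameters.from_json(files("fpcrevise.data") / "dp4_parameters.json")


# ---------------------------------------------------------------------------
# IO

_ENSEMBLE_COLUMNS = ("candidate_id", "conformer_id", "rel_energy_kcal",
                     "nucleus_id", "element", "hybridization", "shielding_ppm")


def read_ensemble_table(path, energies_in_kj: bool = False, sep: str | None = None):
    """Read a long-format ensemble CSV/TSV into one ensemble per candidate_id.

    Columns: candidate_id, conformer_id, rel_energy_kcal, nucleus_id, element,
    hybridization, shielding_ppm (optional equivalence_group). Energies are
    re-based so the minimum is 0; ``energies_in_kj`` converts at 4.184 kJ/kcal.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    missing = [c for c in _ENSEMBLE_COLUMNS if c not in df.columns]
    if missing:
        raise EnsembleError(f"{path}: missing columns {missing}")
    if df["shielding_ppm"].isna().any():
        bad = df[df["shielding_ppm"].isna()].iloc[0]
        raise EnsembleError(
            f"{path}: missing shielding for conformer "
            f"{bad['conformer_id']!r}, nucleus {bad['nucleus_id']!r}"
        )
    ensembles = []
    for cand, sub in df.groupby("candidate_id", sort=False):
        nuclei = {}
        for _, row in sub.drop_duplicates("nucleus_id").iterrows():
            eq = row.get("equivalence_group")
            nuclei[str(row["nucleus_id"])] = NucleusRecord(
                nucleus_id=str(row["nucleus_id"]),
                element=str(row["element"]),
                hybridization=str(row["hybridization"]),
                equivalence_group=None if pd.isna(eq) else str(eq),
            )
        conformers = []
        energies = []
        for conf_id, cs in sub.groupby("conformer_id", sort=False):
            sh = dict(zip(cs["nucleus_id"].astype(str), cs["shielding_ppm"]))
            if set(sh) != set(nuclei):
                missing_n = sorted(set(nuclei).symmetric_difference(sh))
                raise EnsembleError(
                    f"{path}: candidate {cand!r}, conformer {conf_id!r} nucleus "
                    f"set inconsistent with ensemble: {missing_n}"
                )
            e = float(cs["rel_energy_kcal"].iloc[0])
            if energies_in_kj:
                e /= KJ_PER_KCAL
            energies.append(e)
            conformers.append(sh)
        energies = np.asarray(energies) - min(energies)
        ensembles.append(ConformerEnsemble(
            candidate_id=str(cand),
            conformers=tuple(
                Conformer(relative_energy=float(e), shieldings=sh)
                for e, sh in zip(energies, conformers)
            ),
            nuclei=nuclei,
        ))
    return ensembles


def read_experimental_shifts(path, sep: str | None = None):
    """Read experimental assignments -> (shift map, nucleus records).

    Columns: nucleus_id, element, hybridization, shift_ppm, optional
    equivalence_group.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    required = ("nucleus_id", "element", "hybridization", "shift_ppm")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise EnsembleError(f"{path}: missing columns {missing}")
    shifts, nuclei = {}, {}
    for _, row in df.iterrows():
        nid = str(row["nucleus_id"])
        if nid in shifts:
            raise EnsembleError(f"{path}: duplicate nucleus_id {nid!r}")
        eq = row.get("equivalence_group")
        shifts[nid] = float(row["shift_ppm"])
        nuclei[nid] = NucleusRecord(
            nucleus_id=nid, element=str(row["element"]),
            hybridization=str(row["hybridization"]),
            equivalence_group=None if pd.isna(eq) else str(eq),
        )
    return shifts, nuclei


# ---------------------------------------------------------------------------
# Ensemble processing

def filter_energy_window(ensemble: ConformerEnsemble,
                         window: float = DEFAULT_ENERGY_WINDOW) -> ConformerEnsemble:
    """Drop conformers above ``window`` kcal/mol; the boundary is retained.

    The minimum-energy conformer (relative energy 0) always survives, so the
    result is never empty.
    """
    if window <= 0:
        raise EnsembleError(f"window must be positive, got {window}")
    kept = tuple(c for c in ensemble.conformers if c.relative_energy <= window)
    return replace(ensemble, conformers=kept)


def boltzmann_weights(energies, T: float = DEFAULT_TEMPERATURE) -> np.ndarray:
    """Normalized exp(-E/RT) populations; max-subtracted for stability."""
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise EnsembleError("empty energy list")
    if not np.isfinite(e).all():
        raise EnsembleError("non-finite energies")
    if T <= 0:
        raise EnsembleError(f"temperature must be positive, got {T}")
    x = -(e - e.min()) / (R_KCAL * T)
    w = np.exp(x)
    return w / w.sum()


def average_shieldings(ensemble: ConformerEnsemble, weights) -> dict:
    """Population-weighted shieldings, then equivalence groups collapsed.

    Equivalent nuclei (e.g. the three methyl protons) are replaced by a single
    entry named after their equivalence group, the unweighted mean of the
    member averages — one value per experimental assignment.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (len(ensemble.conformers),):
        raise EnsembleError(
            f"{len(w)} weights for {len(ensemble.conformers)} conformers"
        )
    if abs(w.sum() - 1.0) > 1e-9:
        raise EnsembleError("weights must sum to 1")
    ids = list(ensemble.conformers[0].shieldings)
    mat = np.array([[c.shieldings[n] for n in ids] for c in ensemble.conformers])
    avg = dict(zip(ids, w @ mat))
    groups: dict[str, list] = {}
    for nid, rec in ensemble.nuclei.items():
        if rec.equivalence_group is not None:
            groups.setdefault(rec.equivalence_group, []).append(nid)
    for gname, members in groups.items():
        avg[gname] = float(np.mean([avg.pop(m) for m in members]))
    return avg


# ---------------------------------------------------------------------------
# Shielding -> shift

def scale_shifts_global(shieldings: dict, factors: ScalingFactors,
                        elements: dict) -> dict:
    """delta = (intercept - sigma_iso)/(-slope), per element (repository convention)."""
    out = {}
    for nid, sigma in shieldings.items():
        el = elements[nid]
        if el not in factors.factors:
            raise DP4ParameterError(f"no scaling factors for element {el}")
        slope, intercept = factors.factors[el]
        out[nid] = (intercept - sigma) / (-slope)
    return out


def inverse_scale(shift: float, element: str, factors: ScalingFactors) -> float:
    """sigma_iso = intercept + slope * delta (exact inverse of scale_shifts_global)."""
    slope, intercept = factors.factors[element]
    return intercept + slope * shift


def unscaled_shifts(shieldings: dict, sigma_ref: dict, elements: dict) -> dict:
    """delta_u = sigma_ref(element) - sigma_iso (reference-standard subtraction)."""
    out = {}
    for nid, sigma in shieldings.items():
        el = elements[nid]
        if el not in sigma_ref:
            raise DP4ParameterError(f"no reference shielding for element {el}")
        out[nid] = sigma_ref[el] - sigma
    return out


def regression_scale(calc: dict, exp: dict, elements: dict):
    """Per-element least squares delta_calc = m*delta_exp + b; scaled = (calc-b)/m.

    This is the DP4+ scaled branch: each candidate's systematic error is
    removed by regressing its own calculated shifts on the experimental ones.
    Returns (scaled map, {element: (m, b)}).
    """
    shared = sorted(set(calc) & set(exp))
    fits = {}
    for el in sorted({elements[n] for n in shared}):
        nucs = [n for n in shared if elements[n] == el]
        if len(nucs) < 3:
            raise EnsembleError(
                f"need >= 3 paired nuclei for element {el}, got {len(nucs)}"
            )
        x = np.array([exp[n] for n in nucs])
        y = np.array([calc[n] for n in nucs])
        m, b = np.polyfit(x, y, 1)
        if m == 0:
            raise EnsembleError(f"degenerate regression (slope 0) for {el}")
        fits[el] = (float(m), float(b))
    scaled = {n: (calc[n] - fits[elements[n]][1]) / fits[elements[n]][0]
              for n in shared}
    return scaled, fits


# ---------------------------------------------------------------------------
# Error statistics

def error_stats(calc: dict, exp: dict, candidate_id: str = "",
                elements: dict | None = None,
                element: str = "all") -> ShiftComparison:
    """MAE and RMSD of calc - exp over shared nuclei, optionally one element."""
    shared = sorted(set(calc) & set(exp))
    if elements is not None and element != "all":
        shared = [n for n in shared if elements[n] == element]
    if not shared:
        missing = sorted(set(exp) - set(calc))
        raise EnsembleError(
            f"no shared {element} nuclei between calculated and experimental "
            f"maps (experimental-only: {missing})"
        )
    err = {n: calc[n] - exp[n] for n in shared}
    e = np.array(list(err.values()))
    return ShiftComparison(
        candidate_id=candidate_id,
        errors=err,
        mae=float(np.abs(e).mean()),
        rmsd=float(np.sqrt((e ** 2).mean())),
    )


def t_likelihood(error: float, params) -> float:
    """Student-t density of a shift error: t_nu((e - mu)/sigma) / sigma."""
    mu, sigma, nu = params
    if sigma <= 0 or nu <= 0:
        raise DP4ParameterError(f"invalid t parameters ({mu}, {sigma}, {nu})")
    return stats.t.pdf((error - mu) / sigma, df=nu) / sigma


def _log_t(errors: np.ndarray, params) -> np.ndarray:
    mu, sigma, nu = params
    if sigma <= 0 or nu <= 0:
        raise DP4ParameterError(f"invalid t parameters ({mu}, {sigma}, {nu})")
    return stats.t.logpdf((errors - mu) / sigma, df=nu) - math.log(sigma)


def _softmax(loglik: np.ndarray) -> np.ndarray:
    z = loglik - loglik.max()
    w = np.exp(z)
    return w / w.sum()


def dp4_plus(candidates, exp: dict, params: DP4Parameters, nuclei: dict) -> DP4Result:
    """DP4+ probabilities over candidate structures.

    ``candidates`` is a list of ``(candidate_id, scaled map, unscaled map)``.
    Per candidate the log-likelihood sums log Student-t densities of the
    scaled errors (mean-zero parameters per element) and of the unscaled
    errors (parameters per element and, for carbon, hybridization); the
    probability family is the softmax across candidates. Component
    probabilities use the corresponding partial sums. All accumulation is in
    log space.
    """
    if len(candidates) < 2:
        raise EnsembleError("DP4+ needs at least 2 candidates")
    ids = [c[0] for c in candidates]
    if len(set(ids)) != len(ids):
        raise EnsembleError(f"duplicate candidate ids: {ids}")
    cover = sorted(set(candidates[0][1]) & set(exp))
    if not cover:
        raise EnsembleError("no nuclei shared between candidates and experiment")
    for cid, scaled, unscaled in candidates:
        if sorted(set(scaled) & set(exp)) != cover or \
           sorted(set(unscaled) & set(exp)) != cover:
            raise EnsembleError(
                f"candidate {cid!r} nucleus coverage differs from "
                f"{candidates[0][0]!r}"
            )
    elements = np.array([nuclei[n].element for n in cover])
    parts = {"scaled": [], "unscaled": []}   # (n_candidates, n_nuclei)
    for _, scaled, unscaled in candidates:
        es = np.array([scaled[n] - exp[n] for n in cover])
        eu = np.array([unscaled[n] - exp[n] for n in cover])
        row_s = np.empty(len(cover))
        row_u = np.empty(len(cover))
        for j, n in enumerate(cover):
            rec = nuclei[n]
            row_s[j] = _log_t(es[j], params.lookup(rec.element, "scaled"))
            row_u[j] = _log_t(
                eu[j], params.lookup(rec.element, "unscaled", rec.hybridization)
            )
        parts["scaled"].append(row_s)
        parts["unscaled"].append(row_u)
    S = np.vstack(parts["scaled"])
    U = np.vstack(parts["unscaled"])
    is_c = elements == "C"

    def family(mask_scaled, mask_unscaled):
        ll = S[:, mask_scaled].sum(axis=1) + U[:, mask_unscaled].sum(axis=1)
        return dict(zip(ids, _softmax(ll)))

    all_n = np.ones(len(cover), dtype=bool)
    none = np.zeros(len(cover), dtype=bool)
    return DP4Result(
        candidate_ids=tuple(ids),
        total=family(all_n, all_n),
        scaled_only=family(all_n, none),
        unscaled_only=family(none, all_n),
        carbon_only=family(is_c, is_c),
        proton_only=family(~is_c, ~is_c),
    )


# ---------------------------------------------------------------------------
# Candidate pipeline helper

def candidate_shift_maps(ensemble: ConformerEnsemble, exp: dict,
                         factors: ScalingFactors, sigma_ref: dict,
                         window: float = DEFAULT_ENERGY_WINDOW,
                         T: float = DEFAULT_TEMPERATURE):
    """Full chain for one candidate: filter, weight, average, scale.

    Returns a dict with Boltzmann-averaged shieldings and three shift maps:
    ``global_scaled`` (repository factors, for MAE/RMSD reporting),
    ``regression_scaled`` and ``unscaled`` (the two DP4+ branches), plus the
    per-element regression fits.
    """
    filt = filter_energy_window(ensemble, window=window)
    w = boltzmann_weights(filt.energies, T=T)
    sigma = average_shieldings(filt, w)
    elements = {}
    for nid in sigma:
        rec = next((r for r in ensemble.nuclei.values()
                    if r.equivalence_group == nid), None)
        elements[nid] = (rec or ensemble.nuclei[nid]).element
    global_scaled = scale_shifts_global(sigma, factors, elements)
    unscaled = unscaled_shifts(sigma, sigma_ref, elements)
    reg_scaled, fits = regression_scale(global_scaled, exp, elements)
    return {
        "shieldings": sigma,
        "elements": elements,
        "global_scaled": global_scaled,
        "regression_scaled": reg_scaled,
        "unscaled": unscaled,
        "regression_fits": fits,
    }
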