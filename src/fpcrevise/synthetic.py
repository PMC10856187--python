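"""Seeded synthetic inputs with the statistical structure the analysis assumes.

Three generators mirror the study conditions of a phloroglucinol structure
revision:

* class-structured fingerprint datasets whose diagnostic slots are separated
  by a configurable number of ppm between classes (default 4 ppm or more, sd
  1 ppm within class);
* two-candidate DP4+ scenarios where the "correct" candidate's
  Boltzmann-averaged, scaled shifts deviate from the experimental values by
  N(0, 1.9 ppm) for 13C / N(0, 0.13 ppm) for 1H, while the "incorrect"
  candidate additionally carries six carbon positions offset by
  Uniform(5, 12) ppm with random sign — the error regimes separating revised
  from misassigned structures;
* ECD scenarios where the "experimental" trace is the Boltzmann-averaged
  broadened spectrum displaced by a known wavelength shift plus noise.

Shieldings are statistical stand-ins built by inverting the linear scaling
relation, not computed observables. Every generator is a pure function of
(config, seed); independent substreams per purpose are spawned from the
master seed so adding one generator call does not perturb another's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dft_nmr, ecd
from .dft_nmr import (Conformer, ConformerEnsemble, NucleusRecord,
                      ScalingFactors, default_scaling_factors)
from .fingerprint import SLOT_NAMES, FingerprintDataset, ShiftFingerprint

_STREAMS = {"fingerprint": 0, "dp4": 1, "ecd": 2}


def _rng(seed: int, purpose: str) -> np.random.Generator:
    """Per-purpose substream of the master seed."""
    ss = np.random.SeedSequence(entropy=int(seed),
                                spawn_key=(_STREAMS[purpose],))
    return np.random.default_rng(ss)


class ScenarioError(ValueError):
    """Invalid generator configuration."""


# ---------------------------------------------------------------------------
# Fingerprint generator

@dataclass(frozen=True)
class ClassTemplate:
    """Per-slot Normal(mean, sd) model of one substructure class.

    ``missing_prob`` gives the probability that a slot is absent in a drawn
    compound (proton slots are frequently unreported for some classes).
    """

    label: str
    means: dict          # slot -> ppm
    sds: dict            # slot -> ppm, > 0
    missing_prob: dict = field(default_factory=dict)  # slot -> [0, 1]

    def __post_init__(self):
        if not self.means:
            raise ScenarioError(f"{self.label}: template has no slots")
        unknown = set(self.means) - set(SLOT_NAMES)
        if unknown:
            raise ScenarioError(f"{self.label}: unknown slots {sorted(unknown)}")
        for s in self.means:
            if self.sds.get(s, 0.0) <= 0:
                raise ScenarioError(f"{self.label}: sd must be > 0 for {s}")
        if all(self.missing_prob.get(s, 0.0) >= 1.0 for s in SLOT_NAMES):
            raise ScenarioError(f"{self.label}: all slots missing")


#: Diagnostic carbon slots used for the separation guarantee.
DIAGNOSTIC_SLOTS = ("C2", "C4", "C6", "C7", "C9")


def default_class_templates(separation: float = 4.0, sd: float = 1.0):
    """Six FPC-like class templates with >= ``separation`` ppm diagnostic spacing.

    Base values echo phloroglucinol chemistry (oxygenated aromatic carbons
    90-170 ppm, carbonyls 185-200 ppm, aldehydic 1H 9.5-10.5, phenolic 1H
    11-14). Classes form a 3 x 2 factorial — ring-fusion skeleton (pyrano /
    oxepine / open euglobal-macrocarpal type) crossed with acylation pattern
    (diformyl / 3-acyl-1-formyl) — so class means span two independent
    directions in fingerprint space, as they do for real subclasses: the
    skeleton moves core carbons C-2/C-6 and carbonyl C-7, the acylation
    pattern moves C-4 and C-9. Every pair of classes differs by at least
    ``separation`` ppm on some diagnostic slot.
    """
    base = {
        "C1": 165.0, "C2": 104.0, "C3": 168.0, "C4": 105.0, "C5": 166.0,
        "C6": 104.0, "C7": 192.0, "C9": 191.0,
        "H_CHO_1": 10.1, "H_CHO_2": 10.0, "H_OH_1": 12.6, "H_OH_2": 13.2,
    }
    skeleton_slots = {"C2": -1.0, "C6": +1.0, "C7": +1.0}   # scaled by a
    acylation_slots = {"C4": +1.0, "C9": -1.0}              # scaled by b
    layout = (
        ("pyrano-diformyl", 0, 0),
        ("oxepine-diformyl", 1, 0),
        ("euglobal-type", 2, 0),
        ("pyrano-3-acyl-1-formyl", 0, 1),
        ("oxepine-1-formyl-3-acyl", 1, 1),
        ("macrocarpal-type", 2, 1),
    )
    missing = {"H_CHO_2": 0.3, "H_OH_2": 0.4}
    templates = []
    for label, a, b in layout:
        means = dict(base)
        for slot, sign in skeleton_slots.items():
            means[slot] += sign * separation * a
        for slot, sign in acylation_slots.items():
            means[slot] += sign * separation * b
        templates.append(ClassTemplate(
            label=label, means=means,
            sds={s: sd for s in means}, missing_prob=dict(missing),
        ))
    validate_separation(templates, separation)
    return templates


def validate_separation(templates, minimum: float) -> None:
    """Require >= minimum ppm between every class pair on some diagnostic slot."""
    for i, a in enumerate(templates):
        for b in templates[i + 1:]:
            gap = max(abs(a.means.get(s, 0.0) - b.means.get(s, 0.0))
                      for s in DIAGNOSTIC_SLOTS)
            if gap < minimum:
                raise ScenarioError(
                    f"classes {a.label!r}/{b.label!r} separated by only "
                    f"{gap:.2f} ppm on diagnostic slots (< {minimum})"
                )


def gen_fingerprint_dataset(templates, n_per_class: int, seed: int) -> FingerprintDataset:
    """Draw ``n_per_class`` compounds per template; deterministic in ``seed``."""
    if len(templates) < 2:
        raise ScenarioError("need at least 2 class templates")
    if n_per_class < 1:
        raise ScenarioError("n_per_class must be >= 1")
    rng = _rng(seed, "fingerprint")
    records = []
    for tpl in templates:
        for i in range(n_per_class):
            vals = []
            for slot in SLOT_NAMES:
                if slot not in tpl.means:
                    vals.append(np.nan)
                    continue
                x = rng.normal(tpl.means[slot], tpl.sds[slot])
                if rng.random() < tpl.missing_prob.get(slot, 0.0):
                    x = np.nan
                vals.append(x)
            records.append(ShiftFingerprint(
                compound_id=f"{tpl.label}-{i:03d}",
                assigned_class=tpl.label,
                shifts=tuple(vals),
            ))
    return FingerprintDataset(records=tuple(records))


# ---------------------------------------------------------------------------
# DP4+ scenario

@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs of the DP4+/ECD scenario generators (defaults = study conditions)."""

    seed: int = 0
    n_per_class: int = 30
    sd_correct_c: float = 1.9      # ppm, 13C error sd of the correct candidate
    sd_correct_h: float = 0.13     # ppm, 1H error sd
    n_offsets: int = 6             # carbon positions perturbed on the wrong candidate
    offset_range: tuple = (5.0, 12.0)   # ppm, localized deviations
    n_carbons: int = 25
    n_protons: int = 15
    n_conformers: int = 5
    energy_spread: float = 1.0     # kcal/mol, Exponential mean of conformer energies
    conformer_jitter: float = 0.5  # ppm, spread of per-conformer shieldings
    n_transitions: int = 8
    strength_scale: float = 20.0   # 1e-40 cgs
    ecd_shift_nm: float = 7.0
    ecd_noise: float = 0.05        # fraction of the spectrum's max |d_eps|

    def __post_init__(self):
        if min(self.n_offsets, self.n_carbons, self.n_protons,
               self.n_conformers, self.n_transitions, self.n_per_class) < 0:
            raise ScenarioError("counts must be non-negative")
        lo, hi = self.offset_range
        if not (0.0 <= lo <= hi <= 30.0):
            raise ScenarioError("offset_range must lie within [0, 30] ppm")
        if self.n_offsets > self.n_carbons:
            raise ScenarioError("more offsets than carbon nuclei")


@dataclass(frozen=True)
class DP4Scenario:
    """Planted-truth bundle: experimental map plus correct/incorrect ensembles."""

    exp_shifts: dict
    nuclei: dict
    correct: ConformerEnsemble
    incorrect: ConformerEnsemble
    factors: ScalingFactors
    sigma_ref: dict                # per-element reference shieldings


def _draw_true_shifts(rng, cfg: ScenarioConfig):
    """Chemically plausible 13C/1H shift assignments for an FPC-sized molecule."""
    nuclei, shifts = {}, {}
    n_ar = max(1, cfg.n_carbons * 7 // 25)       # phloroglucinol-like sp2
    n_co = max(1, cfg.n_carbons * 2 // 25)       # formyl/acyl carbonyls
    n_al = cfg.n_carbons - n_ar - n_co           # terpene sp3
    specs = ([("sp2", 90.0, 170.0)] * n_ar + [("sp2", 185.0, 200.0)] * n_co
             + [("sp3", 15.0, 85.0)] * n_al)
    for i, (hyb, lo, hi) in enumerate(specs):
        nid = f"C-{i + 1}"
        nuclei[nid] = NucleusRecord(nid, "C", hyb)
        shifts[nid] = float(rng.uniform(lo, hi))
    n_cho = min(2, cfg.n_protons)
    n_oh = min(2, max(0, cfg.n_protons - n_cho))
    n_hal = cfg.n_protons - n_cho - n_oh
    hspecs = ([(9.5, 10.5)] * n_cho + [(11.0, 14.0)] * n_oh
              + [(0.8, 5.5)] * n_hal)
    for i, (lo, hi) in enumerate(hspecs):
        nid = f"H-{i + 1}"
        nuclei[nid] = NucleusRecord(nid, "H", "sp3")
        shifts[nid] = float(rng.uniform(lo, hi))
    return shifts, nuclei


def _build_ensemble(rng, cfg: ScenarioConfig, candidate_id: str,
                    target_shifts: dict, nuclei: dict,
                    factors: ScalingFactors) -> ConformerEnsemble:
    """Ensemble whose Boltzmann-averaged shieldings invert exactly to the targets."""
    energies = rng.exponential(cfg.energy_spread, size=cfg.n_conformers)
    energies -= energies.min()
    ids = sorted(target_shifts)
    sigma_target = np.array([
        dft_nmr.inverse_scale(target_shifts[n], nuclei[n].element, factors)
        for n in ids
    ])
    jitter = rng.normal(0.0, cfg.conformer_jitter,
                        size=(cfg.n_conformers, len(ids)))
    # center the jitter over the conformers that survive the standard energy
    # window, with the weights renormalized to that subset — exactly what the
    # analysis chain averages over — so the planted targets are hit exactly
    mask = energies <= dft_nmr.DEFAULT_ENERGY_WINDOW
    w_win = dft_nmr.boltzmann_weights(energies[mask])
    jitter[mask] -= w_win @ jitter[mask]
    conformers = tuple(
        Conformer(relative_energy=float(e),
                  shieldings=dict(zip(ids, sigma_target + jitter[i])))
        for i, e in enumerate(energies)
    )
    return ConformerEnsemble(candidate_id=candidate_id, conformers=conformers,
                             nuclei=dict(nuclei))


def gen_dp4_scenario(cfg: ScenarioConfig,
                     factors: ScalingFactors | None = None) -> DP4Scenario:
    """Planted correct/incorrect candidate pair at the configured error regime."""
    rng = _rng(cfg.seed, "dp4")
    factors = factors or default_scaling_factors()
    exp, nuclei = _draw_true_shifts(rng, cfg)

    def perturbed(offsets: bool):
        tgt = {}
        for nid, true in exp.items():
            sd = cfg.sd_correct_c if nuclei[nid].element == "C" else cfg.sd_correct_h
            tgt[nid] = true + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        if offsets and cfg.n_offsets:
            carbons = sorted(n for n in exp if nuclei[n].element == "C")
            chosen = rng.choice(len(carbons), size=cfg.n_offsets, replace=False)
            lo, hi = cfg.offset_range
            for i in chosen:
                mag = rng.uniform(lo, hi)
                tgt[carbons[i]] += mag * rng.choice((-1.0, 1.0))
        return tgt

    correct = _build_ensemble(rng, cfg, "correct", perturbed(False),
                              nuclei, factors)
    incorrect = _build_ensemble(rng, cfg, "incorrect", perturbed(True),
                                nuclei, factors)
    # reference shieldings consistent with the scaling relation at delta = 0
    sigma_ref = {el: factors.factors[el][1] for el in factors.factors}
    return DP4Scenario(exp_shifts=exp, nuclei=nuclei, correct=correct,
                       incorrect=incorrect, factors=factors,
                       sigma_ref=sigma_ref)


# ---------------------------------------------------------------------------
# ECD scenario

@dataclass(frozen=True)
class ECDScenario:
    transition_sets: tuple
    exp_spectrum: ecd.ECDSpectrum
    true_shift_nm: float           # displacement planted in the "experimental" trace
    flipped: bool = False

    @property
    def expected_correction_nm(self) -> float:
        """Shift the scan should apply to the calculated spectrum: -planted."""
        return -self.true_shift_nm


def gen_ecd_scenario(cfg: ScenarioConfig, flip: bool = False) -> ECDScenario:
    """Transitions plus a noisy, wavelength-shifted 'experimental' trace.

    The experimental spectrum is the Boltzmann-averaged broadened spectrum of
    the generated conformers displaced by the planted ``cfg.ecd_shift_nm``,
    so matching it requires the compensating correction ``-ecd_shift_nm``
    applied to the calculated spectrum (``expected_correction_nm``); Normal
    noise of ``cfg.ecd_noise`` times the peak magnitude is added. ``flip``
    negates all rotatory strengths of the returned transition sets (the
    enantiomer scenario).
    """
    rng = _rng(cfg.seed, "ecd")
    sets = []
    energies = rng.exponential(cfg.energy_spread, size=cfg.n_conformers)
    energies -= energies.min()
    for i in range(cfg.n_conformers):
        lam = rng.uniform(200.0, 380.0, size=cfg.n_transitions)
        strengths = rng.normal(0.0, cfg.strength_scale, size=cfg.n_transitions)
        sets.append(ecd.TransitionSet(
            conformer_id=f"conf-{i + 1}",
            energies_ev=ecd.EV_NM / lam,
            strengths=strengths,
            relative_energy=float(energies[i]),
        ))
    avg = ecd.boltzmann_average_spectra(sets)
    exp = ecd.shift_spectrum(avg, -cfg.ecd_shift_nm) if cfg.ecd_shift_nm else avg
    vals = exp.values.copy()
    if cfg.ecd_noise > 0:
        scale = cfg.ecd_noise * np.nanmax(np.abs(vals))
        vals = vals + rng.normal(0.0, scale, size=vals.size)
    finite = np.isfinite(vals)
    exp_spectrum = ecd.ECDSpectrum(
        wavelengths=exp.wavelengths[finite], values=vals[finite],
        sigma_ev=exp.sigma_ev,
    )
    if flip:
        sets = [ecd.TransitionSet(ts.conformer_id, ts.energies_ev,
                                  -ts.strengths, ts.relative_energy)
                for ts in sets]
    return ECDScenario(transition_sets=tuple(sets), exp_spectrum=exp_spectrum,
                       true_shift_nm=cfg.ecd_shift_nm, flipped=flip)


# ---------------------------------------------------------------------------
# Table export (CSV schemas consumed by the analysis modules)

def ensemble_to_frame(ensemble: ConformerEnsemble):
    import pandas as pd

    rows = []
    for i, conf in enumerate(ensemble.conformers):
        for nid, sigma in conf.shieldings.items():
            rec = ensemble.nuclei[nid]
            rows.append((ensemble.candidate_id, f"conf-{i + 1}",
                         conf.relative_energy, nid, rec.element,
                         rec.hybridization, sigma,
                         rec.equivalence_group or ""))
    return pd.DataFrame(rows, columns=[
        "candidate_id", "conformer_id", "rel_energy_kcal", "nucleus_id",
        "element", "hybridization", "shielding_ppm", "equivalence_group",
    ])


def experimental_to_frame(shifts: dict, nuclei: dict):
    import pandas as pd

    rows = [(nid, nuclei[nid].element, nuclei[nid].hybridization, v,
             nuclei[nid].equivalence_group or "")
            for nid, v in sorted(shifts.items())]
    return pd.DataFrame(rows, columns=[
        "nucleus_id", "element", "hybridization", "shift_ppm",
        "equivalence_group",
    ])


def transitions_to_frame(sets):
    import pandas as pd

    rows = []
    for ts in sets:
        for e, r in zip(ts.energies_ev, ts.strengths):
            rows.append((ts.conformer_id, ts.relative_energy, e, r))
    return pd.DataFrame(rows, columns=[
        "conformer_id", "rel_energy_kcal", "energy_ev",
        "rotatory_strength_1e-40cgs",
    ])
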