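"""ECD spectrum synthesis from TDDFT rotatory strengths and spectral matching.

Each electronic transition (excitation energy E_i in eV, rotatory strength
R_i in 1e-40 cgs) is broadened with a Gaussian band on the energy axis,

    d_eps(E) = sum_i E_i * R_i / (22.97 * sigma * sqrt(pi))
               * exp(-((E - E_i)/sigma)^2),

with sigma the half-width at d_eps_max/e (SpecDis convention; default
0.23 eV). Per-conformer spectra are Boltzmann-weighted, optionally shifted
along the wavelength axis (the UV correction), and compared with an
experimental trace by normalized overlap (cosine similarity) over the common
wavelength window, scanning a range of shifts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .dft_nmr import DEFAULT_TEMPERATURE, boltzmann_weights

#: hc in eV nm: E[eV] = EV_NM / lambda[nm].
EV_NM = 1239.84193
#: cgs prefactor for R in 1e-40 esu^2 cm^2 and d_eps in M^-1 cm^-1.
DEFAULT_BROADENING_CONSTANT = 22.97
DEFAULT_SIGMA_EV = 0.23
DEFAULT_GRID = (180.0, 400.0, 1.0)  # nm start, stop (inclusive), step


class SpectrumError(ValueError):
    """Invalid transition table or spectrum operation."""


@dataclass(frozen=True)
class TransitionSet:
    """One conformer's electronic transitions plus its relative energy."""

    conformer_id: str
    energies_ev: np.ndarray      # excitation energies, eV, > 0
    strengths: np.ndarray        # rotatory strengths, 1e-40 cgs
    relative_energy: float = 0.0  # kcal/mol above the ensemble minimum

    def __post_init__(self):
        e = np.atleast_1d(np.asarray(self.energies_ev, dtype=float))
        r = np.atleast_1d(np.asarray(self.strengths, dtype=float))
        if e.shape != r.shape:
            raise SpectrumError(f"{self.conformer_id}: energy/strength mismatch")
        if e.size and (not np.isfinite(e).all() or (e <= 0).any()):
            raise SpectrumError(f"{self.conformer_id}: excitation energies must be > 0")
        if e.size and not np.isfinite(r).all():
            raise SpectrumError(f"{self.conformer_id}: non-finite rotatory strength")
        object.__setattr__(self, "energies_ev", e)
        object.__setattr__(self, "strengths", r)


@dataclass(frozen=True)
class ECDSpectrum:
    """Delta-epsilon curve on a uniform ascending wavelength grid (nm).

    NaN values mark points lost to a wavelength shift; comparisons skip them.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    sigma_ev: float = DEFAULT_SIGMA_EV
    shift_nm: float = 0.0

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or wl.shape != v.shape:
            raise SpectrumError("grid and values must be 1-D and equal length")
        if wl.size < 2:
            raise SpectrumError("grid needs at least 2 points")
        steps = np.diff(wl)
        if (steps <= 0).any() or not np.allclose(steps, steps[0], rtol=1e-9):
            raise SpectrumError("grid must be uniform and ascending")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", v)

    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])


@dataclass(frozen=True)
class SpectrumComparison:
    similarity: float        # in [-1, 1]
    best_shift_nm: float
    window_nm: tuple         # (lo, hi) wavelength overlap used

    def __post_init__(self):
        if abs(self.similarity) > 1 + 1e-9:
            raise SpectrumError("similarity outside [-1, 1]")


def default_grid() -> np.ndarray:
    lo, hi, step = DEFAULT_GRID
    return np.arange(lo, hi + step / 2, step)


# ---------------------------------------------------------------------------
# IO

def read_transitions(path, sep: str | None = None):
    """Read per-conformer transition tables -> list of TransitionSet.

    Columns: conformer_id, rel_energy_kcal, and energy_ev and/or
    wavelength_nm, rotatory_strength_1e-40cgs. When both energy columns are
    present they must agree through E = 1239.84193 / lambda to 1e-6 relative.
    """
    import pandas as pd

    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    need = {"conformer_id", "rel_energy_kcal", "rotatory_strength_1e-40cgs"}
    missing = sorted(need - set(df.columns))
    if missing:
        raise SpectrumError(f"{path}: missing columns {missing}")
    has_ev = "energy_ev" in df.columns
    has_nm = "wavelength_nm" in df.columns
    if not (has_ev or has_nm):
        raise SpectrumError(f"{path}: need energy_ev or wavelength_nm column")
    if has_ev and has_nm:
        e = df["energy_ev"].to_numpy(float)
        lam = df["wavelength_nm"].to_numpy(float)
        rel = np.abs(e - EV_NM / lam) / e
        if (rel > 1e-6).any():
            i = int(np.argmax(rel))
            raise SpectrumError(
                f"{path}: row {i}: energy_ev and wavelength_nm disagree "
                f"({e[i]} eV vs {lam[i]} nm)"
            )
    sets = []
    for conf_id, sub in df.groupby("conformer_id", sort=False):
        cid = str(conf_id)
        idx = sub.index.to_numpy()
        if idx.size > 1 and (np.diff(idx) != 1).any():
            # a conformer's transitions form one contiguous block; a second
            # block with the same id is a duplicated conformer
            raise SpectrumError(f"{path}: duplicate conformer_id {cid!r}")
        if has_ev:
            e = sub["energy_ev"].to_numpy(float)
        else:
            e = EV_NM / sub["wavelength_nm"].to_numpy(float)
        r = sub["rotatory_strength_1e-40cgs"].to_numpy(float)
        # rows with no transition (blank strength+energy) are not supported;
        # an empty conformer is expressed by zero strengths
        sets.append(TransitionSet(
            conformer_id=cid, energies_ev=e, strengths=r,
            relative_energy=float(sub["rel_energy_kcal"].iloc[0]),
        ))
    return sets


def read_experimental_spectrum(path, sigma_ev: float = DEFAULT_SIGMA_EV) -> ECDSpectrum:
    """Two-column (nm, d_eps) text trace, '#' comments; resampled to a 1 nm grid."""
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise SpectrumError(f"{path}: expected two columns (nm, d_eps)")
    wl, v = data[:, 0], data[:, 1]
    order = np.argsort(wl)
    wl, v = wl[order], v[order]
    grid = np.arange(math.ceil(wl[0]), math.floor(wl[-1]) + 0.5, 1.0)
    if grid.size < 2:
        raise SpectrumError(f"{path}: trace spans less than 2 nm")
    return ECDSpectrum(wavelengths=grid, values=np.interp(grid, wl, v),
                       sigma_ev=sigma_ev)


def write_spectrum(spectrum: ECDSpectrum, path) -> None:
    np.savetxt(path, np.column_stack([spectrum.wavelengths, spectrum.values]),
               fmt="%.6f", header="wavelength_nm  delta_epsilon")


# ---------------------------------------------------------------------------
# Synthesis

def broaden_spectrum(ts: TransitionSet, sigma_ev: float = DEFAULT_SIGMA_EV,
                     grid: np.ndarray | None = None,
                     constant: float = DEFAULT_BROADENING_CONSTANT) -> ECDSpectrum:
    """Gaussian band broadening of one conformer's transitions onto a nm grid."""
    if sigma_ev <= 0:
        raise SpectrumError(f"sigma_ev must be positive, got {sigma_ev}")
    wl = default_grid() if grid is None else np.asarray(grid, dtype=float)
    E = EV_NM / wl
    vals = np.zeros_like(wl)
    amp = 1.0 / (constant * sigma_ev * math.sqrt(math.pi))
    for Ei, Ri in zip(ts.energies_ev, ts.strengths):
        vals += Ei * Ri * amp * np.exp(-(((E - Ei) / sigma_ev) ** 2))
    return ECDSpectrum(wavelengths=wl, values=vals, sigma_ev=sigma_ev)


def boltzmann_average_spectra(sets, T: float = DEFAULT_TEMPERATURE,
                              sigma_ev: float = DEFAULT_SIGMA_EV,
                              grid: np.ndarray | None = None,
                              constant: float = DEFAULT_BROADENING_CONSTANT) -> ECDSpectrum:
    """Population-weighted pointwise sum of the per-conformer broadened spectra."""
    if not sets:
        raise SpectrumError("no transition sets")
    wl = default_grid() if grid is None else np.asarray(grid, dtype=float)
    spectra = [broaden_spectrum(ts, sigma_ev=sigma_ev, grid=wl, constant=constant)
               for ts in sets]
    w = boltzmann_weights([ts.relative_energy for ts in sets], T=T)
    vals = np.zeros_like(wl)
    for wi, sp in zip(w, spectra):
        vals += wi * sp.values
    return ECDSpectrum(wavelengths=wl, values=vals, sigma_ev=sigma_ev)


# ---------------------------------------------------------------------------
# Shifting and matching

def shift_spectrum(s: ECDSpectrum, delta_nm: float) -> ECDSpectrum:
    """Translate the curve by delta_nm and resample onto the original grid.

    Points shifted off the grid become NaN and are excluded from comparisons.
    """
    span = s.wavelengths[-1] - s.wavelengths[0]
    if abs(delta_nm) >= span:
        raise SpectrumError(
            f"shift {delta_nm} nm exceeds the grid span {span} nm"
        )
    shifted = np.interp(s.wavelengths, s.wavelengths + delta_nm, s.values,
                        left=np.nan, right=np.nan)
    return replace(s, values=shifted, shift_nm=s.shift_nm + delta_nm)


def _cosine_overlap(calc: ECDSpectrum, exp_wl: np.ndarray, exp_v: np.ndarray):
    """Trapezoidal cosine similarity over finite common support, or None."""
    lo = max(calc.wavelengths[0], exp_wl[0])
    hi = min(calc.wavelengths[-1], exp_wl[-1])
    if hi <= lo:
        return None
    m = (calc.wavelengths >= lo) & (calc.wavelengths <= hi)
    wl = calc.wavelengths[m]
    f = calc.values[m]
    g = np.interp(wl, exp_wl, exp_v)
    finite = np.isfinite(f) & np.isfinite(g)
    if finite.sum() < 2:
        return None
    wl, f, g = wl[finite], f[finite], g[finite]
    num = np.trapezoid(f * g, wl)
    den = math.sqrt(np.trapezoid(f * f, wl) * np.trapezoid(g * g, wl))
    if den == 0:
        return None
    return float(num / den), (float(wl[0]), float(wl[-1]))


def similarity_with_shift(calc: ECDSpectrum, exp: ECDSpectrum,
                          scan_nm: float = 15.0, step_nm: float = 1.0) -> SpectrumComparison:
    """Best cosine similarity of the shifted calculated spectrum vs experiment.

    Scans shifts in [-scan_nm, +scan_nm] at step_nm applied to the calculated
    spectrum. The maximizing shift is chosen by |similarity| so that an
    enantiomeric (sign-flipped) spectrum reports the same alignment with the
    sign of the similarity flipped; ties go to the smallest |shift|. The
    returned similarity keeps its sign.
    """
    if scan_nm < 0 or step_nm <= 0:
        raise SpectrumError("scan_nm must be >= 0 and step_nm > 0")
    shifts = np.arange(-scan_nm, scan_nm + step_nm / 2, step_nm)
    shifts = shifts[np.argsort(np.abs(shifts), kind="stable")]  # 0, ±step, ...
    best = None
    for d in shifts:
        shifted = shift_spectrum(calc, float(d)) if d != 0 else calc
        res = _cosine_overlap(shifted, exp.wavelengths, exp.values)
        if res is None:
            continue
        sim, window = res
        if best is None or abs(sim) > abs(best[0]) + 1e-15:
            best = (sim, float(d), window)
    if best is None:
        raise SpectrumError("no wavelength overlap between spectra")
    sim, d, window = best
    return SpectrumComparison(similarity=min(max(sim, -1.0), 1.0),
                              best_shift_nm=d, window_nm=window)


def plot_overlay(calc: ECDSpectrum, exp: ECDSpectrum, path,
                 label_calc: str = "calculated", label_exp: str = "experimental") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(exp.wavelengths, exp.values, "k-", label=label_exp)
    ax.plot(calc.wavelengths, calc.values, "b--", label=label_calc)
    ax.axhline(0, color="0.7", lw=0.5)
    ax.set_xlabel("wavelength / nm")
    ax.set_ylabel(r"$\Delta\varepsilon$ / M$^{-1}$ cm$^{-1}$")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
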