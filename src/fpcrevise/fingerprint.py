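"""Phloroglucinol NMR chemical-shift fingerprints: PCA, class ranges, misassignment flags.

A fingerprint is the 12-slot vector of diagnostic shifts for a formyl
phloroglucinol meroterpenoid (FPC): the six phloroglucinol core carbons
C-1..C-6, the formyl/acyl carbonyl carbons C-7 and C-9 (ppm, 13C), plus up to
two aldehydic and two phenolic proton shifts (ppm, 1H). Compounds of the same
substructure class (e.g. pyrano-diformyl vs. oxepine-diformyl) cluster in PCA
space, so a compound whose reported class disagrees with its position in that
space — or whose shifts fall outside the class's empirical ranges — is a
candidate for structure revision.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

#: Fixed feature order: 8 carbon slots then 4 proton slots.
SLOT_NAMES = (
    "C1", "C2", "C3", "C4", "C5", "C6", "C7", "C9",
    "H_CHO_1", "H_CHO_2", "H_OH_1", "H_OH_2",
)
CARBON_SLOTS = SLOT_NAMES[:8]
PROTON_SLOTS = SLOT_NAMES[8:]

N_SLOTS = len(SLOT_NAMES)
MIN_PRESENT_SLOTS = 6

_C_RANGE = (0.0, 230.0)
_H_RANGE = (0.0, 20.0)


class FingerprintError(ValueError):
    """Malformed fingerprint table or invalid fingerprint operation."""


@dataclass(frozen=True)
class ShiftFingerprint:
    """One compound's diagnostic shift vector plus its reported class label.

    Missing slots are NaN. At least 6 of the 12 slots must be present; carbon
    shifts must lie in [0, 230] ppm and proton shifts in [0, 20] ppm.
    """

    compound_id: str
    assigned_class: str
    shifts: tuple  # 12 floats, NaN = missing, order = SLOT_NAMES
    solvent: str = "CDCl3"

    def __post_init__(self):
        vals = np.asarray(self.shifts, dtype=float)
        if vals.shape != (N_SLOTS,):
            raise FingerprintError(
                f"{self.compound_id}: expected {N_SLOTS} slots, got {vals.shape}"
            )
        present = ~np.isnan(vals)
        if present.sum() < MIN_PRESENT_SLOTS:
            raise FingerprintError(
                f"{self.compound_id}: only {int(present.sum())} of {N_SLOTS} "
                f"slots present (need >= {MIN_PRESENT_SLOTS})"
            )
        c = vals[:8][present[:8]]
        h = vals[8:][present[8:]]
        if c.size and (c.min() < _C_RANGE[0] or c.max() > _C_RANGE[1]):
            raise FingerprintError(
                f"{self.compound_id}: 13C shift outside {_C_RANGE} ppm"
            )
        if h.size and (h.min() < _H_RANGE[0] or h.max() > _H_RANGE[1]):
            raise FingerprintError(
                f"{self.compound_id}: 1H shift outside {_H_RANGE} ppm"
            )
        object.__setattr__(self, "shifts", tuple(float(v) for v in vals))

    @property
    def values(self) -> np.ndarray:
        return np.asarray(self.shifts, dtype=float)

    @property
    def missing_slots(self) -> tuple:
        return tuple(s for s, v in zip(SLOT_NAMES, self.shifts) if np.isnan(v))


@dataclass(frozen=True)
class FingerprintDataset:
    """Ordered collection of fingerprints with unique compound ids."""

    records: tuple
    slot_names: tuple = SLOT_NAMES
    imputed_mask: np.ndarray | None = None  # True where a cell was imputed

    def __post_init__(self):
        ids = [r.compound_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise FingerprintError(f"duplicate compound_id: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def matrix(self) -> np.ndarray:
        """(n, 12) float matrix, NaN for missing."""
        return np.vstack([r.values for r in self.records])

    @property
    def classes(self) -> tuple:
        return tuple(r.assigned_class for r in self.records)

    @property
    def ids(self) -> tuple:
        return tuple(r.compound_id for r in self.records)

    def get(self, compound_id: str) -> ShiftFingerprint:
        for r in self.records:
            if r.compound_id == compound_id:
                return r
        raise KeyError(compound_id)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=list(self.slot_names))
        df.insert(0, "compound_id", list(self.ids))
        df.insert(1, "class", list(self.classes))
        df.insert(2, "solvent", [r.solvent for r in self.records])
        return df


@dataclass(frozen=True)
class PCAModel:
    """Centering/scaling parameters and top-k loadings of a fingerprint PCA."""

    column_means: np.ndarray        # (12,)
    column_scales: np.ndarray       # (12,), all ones when autoscale=False
    loadings: np.ndarray            # (12, k), columns orthonormal
    explained_variance: np.ndarray  # (k,), non-increasing
    k: int


@dataclass(frozen=True)
class MisassignmentReport:
    """Outcome of checking one compound against its reported class."""

    compound_id: str
    assigned_class: str
    pca_nearest_class: str
    class_distances: dict
    slot_deviations: dict   # slot -> ppm outside the assigned class's range
    unevaluated_slots: tuple
    max_deviation: float
    threshold: float
    flagged: bool


# ---------------------------------------------------------------------------
# IO

_META_COLUMNS = ("compound_id", "class", "solvent")


def read_fingerprint_table(path, sep: str | None = None) -> FingerprintDataset:
    """Read a fingerprint CSV/TSV (header: compound_id, class, solvent, 12 slots).

    Empty cells denote missing shifts. ``sep=None`` sniffs comma vs tab.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    missing_cols = [c for c in (*_META_COLUMNS, *SLOT_NAMES) if c not in df.columns]
    if missing_cols:
        raise FingerprintError(f"{path}: missing mandatory columns {missing_cols}")
    records = []
    for idx, row in df.iterrows():
        vals = []
        for slot in SLOT_NAMES:
            cell = row[slot]
            if pd.isna(cell) or (isinstance(cell, str) and not cell.strip()):
                vals.append(np.nan)
                continue
            try:
                vals.append(float(cell))
            except (TypeError, ValueError):
                raise FingerprintError(
                    f"{path}: non-numeric shift at row {idx}, column {slot!r}: {cell!r}"
                ) from None
        records.append(
            ShiftFingerprint(
                compound_id=str(row["compound_id"]),
                assigned_class=str(row["class"]),
                shifts=tuple(vals),
                solvent=str(row["solvent"]),
            )
        )
    return FingerprintDataset(records=tuple(records))


def write_fingerprint_table(dataset: FingerprintDataset, path, sep: str = ",") -> None:
    dataset.to_frame().to_csv(path, sep=sep, index=False)


def load_synthetic_example() -> FingerprintDataset:
    """Small bundled demonstration table (synthetic).

    24 compounds drawn from the six default class templates of
    :mod:`fpcrevise.synthetic` — a stand-in for a curated literature table,
    not literature data.
    """
    from importlib.resources import files
    return read_fingerprint_table(
        files("fpcrevise.data") / "synthetic_fpc_fingerprints.csv")


# ---------------------------------------------------------------------------
# Imputation

def impute_missing(dataset: FingerprintDataset) -> FingerprintDataset:
    """Replace each missing cell by its column mean over observed values.

    Observed cells are unchanged; the returned dataset carries an
    ``imputed_mask`` for reporting. A slot observed nowhere is an error.
    """
    X = dataset.matrix
    mask = np.isnan(X)
    n_obs = (~mask).sum(axis=0)
    empty = [s for s, n in zip(dataset.slot_names, n_obs) if n == 0]
    if empty:
        raise FingerprintError(f"slot(s) with zero observations: {empty}")
    if not mask.any():
        return replace(dataset, imputed_mask=mask)
    col_means = np.nanmean(X, axis=0)
    Xf = np.where(mask, col_means, X)
    records = tuple(
        replace(r, shifts=tuple(Xf[i])) for i, r in enumerate(dataset.records)
    )
    return FingerprintDataset(records=records, slot_names=dataset.slot_names,
                              imputed_mask=mask)


# ---------------------------------------------------------------------------
# PCA

def fit_pca(dataset: FingerprintDataset, k: int = 2, autoscale: bool = True) -> PCAModel:
    """Eigendecomposition PCA of the (imputed) fingerprint matrix.

    Columns are mean-centered and, with ``autoscale``, divided by the
    population standard deviation (ddof=0) so the 0-20 ppm proton scale is not
    swamped by the 0-230 ppm carbon scale. Loadings are the top-k eigenvectors
    of the sample covariance (ddof=1) of the processed matrix, eigenvalue
    order, each with its largest-magnitude element made positive.
    """
    X = dataset.matrix
    if np.isnan(X).any():
        raise FingerprintError("dataset contains missing values; impute first")
    n, p = X.shape
    if not (0 < k <= p):
        raise FingerprintError(f"k must be in 1..{p}, got {k}")
    if n <= k:
        raise FingerprintError(f"need more than k={k} records, got {n}")
    means = X.mean(axis=0)
    if autoscale:
        scales = X.std(axis=0, ddof=0)
        zero = [s for s, sd in zip(dataset.slot_names, scales) if sd == 0.0]
        if zero:
            raise FingerprintError(
                f"zero-variance slot(s) with autoscale=True: {zero}"
            )
    else:
        scales = np.ones(p)
    Z = (X - means) / scales
    cov = (Z.T @ Z) / (n - 1)
    evals, evecs = np.linalg.eigh(cov)       # ascending
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # reproducible sign: largest-|.| element of each loading positive
    for j in range(p):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    return PCAModel(
        column_means=means,
        column_scales=np.asarray(scales, dtype=float),
        loadings=evecs[:, :k].copy(),
        explained_variance=evals[:k].copy(),
        k=k,
    )


def project(model: PCAModel, fp: ShiftFingerprint | np.ndarray) -> np.ndarray:
    """Score vector loadings^T ((x - means) / scales); fp must have no missing slots."""
    x = fp.values if isinstance(fp, ShiftFingerprint) else np.asarray(fp, dtype=float)
    if np.isnan(x).any():
        raise FingerprintError(
            "fingerprint has missing slots; impute before projecting"
        )
    z = (x - model.column_means) / model.column_scales
    return model.loadings.T @ z


def project_dataset(model: PCAModel, dataset: FingerprintDataset) -> np.ndarray:
    """(n, k) score matrix for every record."""
    Z = (dataset.matrix - model.column_means) / model.column_scales
    return Z @ model.loadings


# ---------------------------------------------------------------------------
# Classification and ranges

def class_centroids(model: PCAModel, dataset: FingerprintDataset) -> pd.DataFrame:
    """Per-class centroid in score space; ``n_members`` column for diagnostics."""
    scores = project_dataset(model, dataset)
    df = pd.DataFrame(scores, columns=[f"PC{j + 1}" for j in range(model.k)])
    df["class"] = dataset.classes
    out = df.groupby("class").mean()
    out["n_members"] = df.groupby("class").size()
    return out


def assign_class(model: PCAModel, dataset: FingerprintDataset,
                 fp: ShiftFingerprint | np.ndarray):
    """Nearest class centroid in PC space (Euclidean); ties broken lexicographically.

    Returns ``(label, table)`` where the table lists every class's distance,
    member count and a small-class warning (n_members < 2).
    """
    cent = class_centroids(model, dataset)
    score = project(model, fp)
    pcs = [f"PC{j + 1}" for j in range(model.k)]
    dist = np.linalg.norm(cent[pcs].to_numpy() - score, axis=1)
    table = pd.DataFrame({
        "class": cent.index,
        "distance": dist,
        "n_members": cent["n_members"].to_numpy(),
    }).sort_values(["distance", "class"], kind="stable").reset_index(drop=True)
    table["warning"] = np.where(
        table["n_members"] < 2, "fewer than 2 members", ""
    )
    return str(table.loc[0, "class"]), table


def class_ranges(dataset: FingerprintDataset, min_obs: int = 3) -> pd.DataFrame:
    """Empirical (min, max, n) per (class, slot), kept only where n >= min_obs."""
    rows = []
    X = dataset.matrix
    labels = np.asarray(dataset.classes)
    for cls in sorted(set(labels)):
        sub = X[labels == cls]
        for j, slot in enumerate(dataset.slot_names):
            col = sub[:, j]
            col = col[~np.isnan(col)]
            if col.size >= min_obs:
                rows.append((cls, slot, col.min(), col.max(), col.size))
    return pd.DataFrame(rows, columns=["class", "slot", "min", "max", "n"])


def range_deviation(dataset: FingerprintDataset, fp: ShiftFingerprint,
                    class_label: str, min_obs: int = 3):
    """Per-slot ppm deviation of ``fp`` outside ``class_label``'s shift ranges.

    deviation = max(0, min - x, x - max); missing slots (in fp or without a
    range) contribute 0 and are returned as unevaluated.
    """
    ranges = class_ranges(dataset, min_obs=min_obs)
    available = sorted(ranges["class"].unique())
    if class_label not in available:
        raise FingerprintError(
            f"unknown class {class_label!r}; available: {available}"
        )
    ranges = ranges[ranges["class"] == class_label].set_index("slot")
    deviations, unevaluated = {}, []
    for slot, x in zip(dataset.slot_names, fp.values):
        if np.isnan(x) or slot not in ranges.index:
            unevaluated.append(slot)
            continue
        lo, hi = ranges.loc[slot, "min"], ranges.loc[slot, "max"]
        deviations[slot] = float(max(0.0, lo - x, x - hi))
    max_dev = max(deviations.values(), default=0.0)
    return deviations, tuple(unevaluated), max_dev


def flag_misassignment(dataset: FingerprintDataset, fp: ShiftFingerprint,
                       threshold: float = 1.0, k: int = 2,
                       autoscale: bool = True) -> MisassignmentReport:
    """Combine PCA nearest-class and range deviations into a misassignment flag.

    ``flagged`` is true iff the nearest PCA class differs from the reported
    class, or some slot lies more than ``threshold`` ppm outside the reported
    class's range. The 1.0 ppm default is the smallest deviation treated as
    diagnostic for these compound classes.
    """
    imputed = impute_missing(dataset)
    model = fit_pca(imputed, k=k, autoscale=autoscale)
    x = fp.values.copy()
    miss = np.isnan(x)
    if miss.any():
        x[miss] = np.nanmean(dataset.matrix, axis=0)[miss]
    nearest, table = assign_class(model, imputed, x)
    deviations, unevaluated, max_dev = range_deviation(
        dataset, fp, fp.assigned_class
    )
    flagged = (nearest != fp.assigned_class) or (max_dev > threshold)
    return MisassignmentReport(
        compound_id=fp.compound_id,
        assigned_class=fp.assigned_class,
        pca_nearest_class=nearest,
        class_distances=dict(zip(table["class"], table["distance"])),
        slot_deviations=deviations,
        unevaluated_slots=unevaluated,
        max_deviation=max_dev,
        threshold=threshold,
        flagged=bool(flagged),
    )


def leave_one_out_accuracy(dataset: FingerprintDataset, k: int = 2,
                           autoscale: bool = True) -> float:
    """Leave-one-out nearest-centroid classification accuracy over the dataset.

    For each held-out compound the PCA, the class centroids and the
    imputation means are refit on the remaining records only.
    """
    hits = 0
    for i, rec in enumerate(dataset.records):
        rest = impute_missing(FingerprintDataset(
            records=dataset.records[:i] + dataset.records[i + 1:],
            slot_names=dataset.slot_names,
        ))
        model = fit_pca(rest, k=k, autoscale=autoscale)
        x = rec.values.copy()
        miss = np.isnan(x)
        if miss.any():
            x[miss] = rest.matrix.mean(axis=0)[miss]
        label, _ = assign_class(model, rest, x)
        hits += label == rec.assigned_class
    return hits / len(dataset)


def plot_scores(model: PCAModel, dataset: FingerprintDataset, path,
                highlight: str | None = None) -> None:
    """PC1/PC2 scatter coloured by class; optional highlighted compound."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = project_dataset(model, dataset)
    fig, ax = plt.subplots(figsize=(6, 5))
    labels = np.asarray(dataset.classes)
    for cls in sorted(set(labels)):
        m = labels == cls
        ax.scatter(scores[m, 0], scores[m, 1], s=18, label=cls, alpha=0.8)
    if highlight is not None:
        i = dataset.ids.index(highlight)
        ax.scatter(scores[i, 0], scores[i, 1], s=120, facecolors="none",
                   edgecolors="k", linewidths=1.5, label=highlight)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
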