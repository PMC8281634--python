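"""Bayesian HER2-FISH signal classification and duct grouping.

Per-cell HER2 probe counts (signals/cell, clipped to 0-10) are classified
amplified / non-amplified by Bayes' rule against two reference probability
mass functions built from hand-picked non-amplified and amplified reference
ducts.  Each duct's signal distribution is summarized by a Gaussian KDE on a
fixed grid; ducts are grouped DCIS_noamp / DCIS_int / DCIS_amp by their
total-variation distances to the two references, with a PCA of the density
matrix retained as a QC view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

__all__ = [
    "ReferenceDensity",
    "CellPosterior",
    "DuctDensity",
    "DuctGroup",
    "build_reference_density",
    "classify_cell",
    "classify_cells",
    "duct_density",
    "group_ducts",
    "SIGNAL_MAX",
    "GRID",
]

SIGNAL_MAX = 10
GRID = np.round(np.arange(0, SIGNAL_MAX + 0.1, 0.1), 10)  # 101 points on [0, 10]


@dataclass(frozen=True)
class ReferenceDensity:
    """Smoothed pmf of signals/cell (support 0..10) for one reference group."""

    label: str  # "noamp" or "amp"
    pmf: np.ndarray
    n_cells: int
    alpha: float

    def __post_init__(self):
        if abs(self.pmf.sum() - 1.0) > 1e-12:
            raise ValueError("reference pmf must sum to 1")


@dataclass(frozen=True)
class CellPosterior:
    posterior_amp: float
    label: str  # argmax class; ties go to "noamp"
    prior: float = 0.5

    @property
    def posterior_noamp(self) -> float:
        return 1.0 - self.posterior_amp


@dataclass(frozen=True)
class DuctDensity:
    """KDE of one duct's signal distribution on the 101-point grid."""

    duct_id: str
    grid: np.ndarray
    density: np.ndarray
    n_cells: int


@dataclass(frozen=True)
class DuctGroup:
    duct_id: str
    group: str  # DCIS_noamp / DCIS_int / DCIS_amp
    d_noamp: float
    d_amp: float
    margin: float
    pc1: float = float("nan")
    pc2: float = float("nan")


def clip_signals(signals) -> np.ndarray:
    s = np.asarray(signals)
    if not np.issubdtype(s.dtype, np.integer):
        raise ValueError("signals must be integers")
    if (s < 0).any():
        raise ValueError("signals must be non-negative")
    return np.clip(s, 0, SIGNAL_MAX)


def build_reference_density(cells, label: str, alpha: float = 1.0) -> ReferenceDensity:
    """Pool per-cell signals into a Laplace-smoothed reference pmf.

    pmf(s) = (count(s) + alpha) / (n + 11 * alpha) over s = 0..10; cells from
    all reference ducts are pooled with equal weight (cell-weighted).
    """
    if isinstance(cells, pd.DataFrame):
        signals = cells["her2_signals"].to_numpy()
    else:
        signals = np.asarray(cells)
    if len(signals) == 0:
        raise ValueError("cannot build a reference from an empty cell table")
    s = clip_signals(signals)
    counts = np.bincount(s, minlength=SIGNAL_MAX + 1).astype(float)
    pmf = (counts + alpha) / (len(s) + (SIGNAL_MAX + 1) * alpha)
    return ReferenceDensity(label=label, pmf=pmf, n_cells=len(s), alpha=alpha)


def classify_cell(
    s: int,
    ref_noamp: ReferenceDensity,
    ref_amp: ReferenceDensity,
    prior: float = 0.5,
) -> CellPosterior:
    """Posterior probability that a cell with ``s`` signals is amplified.

    P(amp|s) = pi P(s|amp) / (pi P(s|amp) + (1 - pi) P(s|noamp)); the label
    is the class with the higher posterior, with ties called non-amplified.
    """
    if not 0.0 < prior < 1.0:
        raise ValueError("prior must lie strictly inside (0, 1)")
    s = int(clip_signals(np.asarray([s]))[0])
    num = prior * ref_amp.pmf[s]
    den = num + (1.0 - prior) * ref_noamp.pmf[s]
    post = num / den
    return CellPosterior(posterior_amp=post, label="amp" if post > 0.5 else "noamp", prior=prior)


def classify_cells(
    cells: pd.DataFrame,
    ref_noamp: ReferenceDensity,
    ref_amp: ReferenceDensity,
    prior: float = 0.5,
) -> pd.DataFrame:
    """Vectorized per-cell classification; returns the table plus posterior columns."""
    s = clip_signals(cells["her2_signals"].to_numpy())
    table = np.array(
        [classify_cell(v, ref_noamp, ref_amp, prior).posterior_amp for v in range(SIGNAL_MAX + 1)]
    )
    post = table[s]
    out = cells.copy()
    out["posterior_amp"] = post
    out["label"] = np.where(post > 0.5, "amp", "noamp")
    return out


def _silverman_bandwidth(x: np.ndarray, floor: float = 0.25) -> float:
    n = len(x)
    sd = x.std(ddof=1) if n > 1 else 0.0
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = 0.9 * spread * n ** (-0.2) if spread > 0 else 0.0
    return max(h, floor)


def _renormalize(grid: np.ndarray, dens: np.ndarray) -> np.ndarray:
    area = np.trapezoid(dens, grid)
    if area <= 0:
        raise ValueError("degenerate density")
    return dens / area


def pmf_to_grid_density(pmf: np.ndarray, grid: np.ndarray = GRID) -> np.ndarray:
    """Linear interpolation of a 0..10 pmf onto the grid, renormalized to
    integrate to 1 (trapezoid rule)."""
    dens = np.interp(grid, np.arange(len(pmf)), pmf)
    return _renormalize(grid, dens)


def duct_density(
    cells,
    duct_id: str = "",
    bandwidth_floor: float = 0.25,
    min_cells_kde: int = 5,
    alpha: float = 1.0,
) -> DuctDensity:
    """Gaussian-kernel KDE of one duct's signals on the 101-point grid.

    Silverman's rule sets the bandwidth with a floor of 0.25 (integer data
    can be degenerate); with fewer than ``min_cells_kde`` cells a smoothed
    pmf interpolated to the grid is used instead.  The returned density is
    renormalized so its trapezoidal integral is 1.
    """
    if isinstance(cells, pd.DataFrame):
        if not duct_id:
            ids = cells["duct_id"].unique()
            if len(ids) != 1:
                raise ValueError("pass cells of a single duct or give duct_id")
            duct_id = str(ids[0])
        signals = cells["her2_signals"].to_numpy()
    else:
        signals = np.asarray(cells)
    s = clip_signals(signals).astype(float)
    n = len(s)
    if n == 0:
        raise ValueError("duct has no cells")
    if n < min_cells_kde:
        ref = build_reference_density(s.astype(int), label="duct", alpha=alpha)
        dens = pmf_to_grid_density(ref.pmf)
        return DuctDensity(duct_id=duct_id, grid=GRID, density=dens, n_cells=n)
    h = _silverman_bandwidth(s, floor=bandwidth_floor)
    # evaluate the Gaussian mixture on the grid
    z = (GRID[:, None] - s[None, :]) / h
    dens = np.exp(-0.5 * z**2).sum(axis=1) / (n * h * np.sqrt(2 * np.pi))
    dens = _renormalize(GRID, dens)
    return DuctDensity(duct_id=duct_id, grid=GRID, density=dens, n_cells=n)


def tv_distance(grid: np.ndarray, p: np.ndarray, q: np.ndarray) -> float:
    """Total-variation distance between two grid densities (trapezoid rule)."""
    return 0.5 * float(np.trapezoid(np.abs(p - q), grid))


def group_ducts(
    densities: list[DuctDensity],
    ref_noamp: ReferenceDensity,
    ref_amp: ReferenceDensity,
    tau: float = 0.15,
) -> list[DuctGroup]:
    """Group ducts by distance to the two references.

    Each duct gets total-variation distances (d_no, d_amp) to the reference
    densities interpolated onto the KDE grid, and a margin
    m = |d_no - d_amp| / (d_no + d_amp).  Margins below ``tau`` are called
    ambiguous (DCIS_int); otherwise the duct takes the nearer reference's
    group.  PCA scores (centered, unscaled) of the density matrix are
    attached as a QC view, not a decision rule.
    """
    ref_no_d = pmf_to_grid_density(ref_noamp.pmf)
    ref_amp_d = pmf_to_grid_density(ref_amp.pmf)
    mat = np.vstack([d.density for d in densities])
    if len(densities) >= 2:
        k = min(2, len(densities), mat.shape[1])
        scores = PCA(n_components=k).fit_transform(mat)
        if scores.shape[1] < 2:
            scores = np.column_stack([scores, np.zeros(len(densities))])
    else:
        scores = np.zeros((len(densities), 2))
    out = []
    for i, d in enumerate(densities):
        d_no = tv_distance(d.grid, d.density, ref_no_d)
        d_amp = tv_distance(d.grid, d.density, ref_amp_d)
        tot = d_no + d_amp
        if tot == 0:
            m, group = 0.0, "DCIS_int"
        else:
            m = abs(d_no - d_amp) / tot
            if m < tau:
                group = "DCIS_int"
            else:
                group = "DCIS_noamp" if d_no < d_amp else "DCIS_amp"
        out.append(
            DuctGroup(
                duct_id=d.duct_id,
                group=group,
                d_noamp=d_no,
                d_amp=d_amp,
                margin=m,
                pc1=float(scores[i, 0]),
                pc2=float(scores[i, 1]),
            )
        )
    return out
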