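"""Efficacy classification and spatial overlap statistics.

Post-processes the steady oxygen (mmHg) and free-drug (nM) fields into:

* a four-way per-cell classification against the hypoxia threshold
  (default 8 mmHg) and the drug IC50 (default 2.9 nM, alternative 6.8 nM):
  1 drug>IC50 & O2>thr, 2 drug>IC50 & O2<thr, 3 drug<IC50 & O2>thr,
  4 drug<IC50 & O2<thr — class 1 is where the oxygen-dependent drug can act;
* core / periphery analysis masks: a central disk and an equal-area
  annulus (outer radius sqrt(2) x core radius); tissue beyond the annulus
  is excluded as boundary affected;
* the overlap index O = C * C_O2 / (max C * max C_O2), bounded in [0, 1]
  and invariant to rescaling either field;
* bivariate Moran's I: the cross-correlation of one z-scored field with
  the spatially lagged (neighbour-averaged) other, on row-standardised
  queen-contiguity raster weights;
* a two-sample Student's t test (pooled variance; Welch optional).

Inequalities are strict on both sides, so a cell exactly at a threshold
counts as insufficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import scipy.sparse as sp
from scipy import stats

from .transport import ScalarField, TissueGrid

__all__ = [
    "Thresholds",
    "RegionMasks",
    "EfficacyMap",
    "build_region_masks",
    "classify_efficacy",
    "class_fractions",
    "hypoxic_fraction",
    "overlap_index",
    "queen_weights",
    "bivariate_morans_I",
    "compare_distributions",
]


@dataclass(frozen=True)
class Thresholds:
    hypoxia_mmHg: float = 8.0
    ic50_nM: float = 2.9

    def __post_init__(self):
        if self.hypoxia_mmHg <= 0 or self.ic50_nM <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class RegionMasks:
    core: np.ndarray        # bool, (ny, nx)
    periphery: np.ndarray   # bool, disjoint from core
    core_radius: float
    outer_radius: float


@dataclass
class EfficacyMap:
    classes: np.ndarray     # int in {1, 2, 3, 4}, (ny, nx)
    thresholds: Thresholds


def build_region_masks(
    grid: TissueGrid,
    centre: Tuple[float, float],
    core_radius: float = 1000.0,
) -> RegionMasks:
    """Core disk and equal-area periphery annulus on the raster.

    The annulus outer radius is sqrt(2) x core_radius, which makes the two
    analysis regions equal in continuous area; cell counts agree to the
    raster discretisation error.
    """
    if core_radius <= 0:
        raise ValueError("core_radius must be positive")
    outer = math.sqrt(2.0) * core_radius
    cx, cy = centre
    x0, y0, x1, y1 = grid.extent
    if not (x0 <= cx - outer and cx + outer <= x1
            and y0 <= cy - outer and cy + outer <= y1):
        raise ValueError("periphery annulus exceeds the tissue domain")
    xs, ys = grid.cell_centres()
    r = np.hypot(xs - cx, ys - cy)
    core = r <= core_radius
    periphery = (r > core_radius) & (r <= outer)
    return RegionMasks(core=core, periphery=periphery,
                       core_radius=core_radius, outer_radius=outer)


def classify_efficacy(
    oxygen: ScalarField,
    drug: ScalarField,
    thresholds: Optional[Thresholds] = None,
) -> EfficacyMap:
    """Four-way sufficient/insufficient classification of every cell."""
    thresholds = thresholds or Thresholds()
    if oxygen.grid != drug.grid:
        raise ValueError("oxygen and drug fields must share a grid")
    if oxygen.units != "mmHg" or drug.units != "nM":
        raise ValueError(
            f"unit mismatch: expected oxygen in mmHg and drug in nM, "
            f"got {oxygen.units!r} / {drug.units!r}")
    drug_ok = drug.values > thresholds.ic50_nM
    o2_ok = oxygen.values > thresholds.hypoxia_mmHg
    classes = np.where(drug_ok, np.where(o2_ok, 1, 2), np.where(o2_ok, 3, 4))
    return EfficacyMap(classes=classes, thresholds=thresholds)


def class_fractions(emap: EfficacyMap, mask: np.ndarray) -> Dict[int, float]:
    """Fraction of mask cells in each class (sums to 1)."""
    if not mask.any():
        raise ValueError("empty analysis mask")
    sel = emap.classes[mask]
    n = sel.size
    return {c: float(np.count_nonzero(sel == c)) / n for c in (1, 2, 3, 4)}


def hypoxic_fraction(
    oxygen: ScalarField,
    mask: np.ndarray,
    thresholds: Optional[Thresholds] = None,
) -> float:
    """Fraction of mask cells with oxygen strictly below the threshold."""
    thresholds = thresholds or Thresholds()
    if not mask.any():
        raise ValueError("empty analysis mask")
    return float(np.mean(oxygen.values[mask] < thresholds.hypoxia_mmHg))


def overlap_index(
    drug: ScalarField,
    oxygen: ScalarField,
    mask: np.ndarray,
) -> Tuple[ScalarField, float, float]:
    """Per-cell overlap index and its (mean, sd) over the mask.

    O = C * C_O2 / (max C * max C_O2) with maxima over the analysis mask,
    so a boundary-affected cell outside the mask cannot set the
    normalisation.  0 where either species is absent; 1 where both attain
    their maxima.
    """
    if drug.grid != oxygen.grid:
        raise ValueError("fields must share a grid")
    if not mask.any():
        raise ValueError("empty analysis mask")
    cmax = drug.values[mask].max()
    omax = oxygen.values[mask].max()
    if cmax <= 0 or omax <= 0:
        raise ValueError("overlap index undefined for an all-zero field")
    vals = (drug.values * oxygen.values) / (cmax * omax)
    field = ScalarField(grid=drug.grid, values=vals, units="1")
    sel = vals[mask]
    return field, float(sel.mean()), float(sel.std())


# ---------------------------------------------------------------------------
# spatial statistics
# ---------------------------------------------------------------------------

def queen_weights(mask: np.ndarray) -> Tuple[sp.csr_matrix, np.ndarray]:
    """Row-standardised 8-neighbour contiguity weights on mask cells.

    Returns (W, flat_indices) where W is n x n over the masked cells in
    row-major order.  Rows of cells with no masked neighbour are zero.
    """
    ny, nx = mask.shape
    flat = np.flatnonzero(mask.ravel())
    inv = -np.ones(ny * nx, dtype=np.int64)
    inv[flat] = np.arange(flat.size)
    rows, cols = [], []
    iy, ix = np.divmod(flat, nx)
    for dy in (-1, 0, 1):
        for dx in (-1, 0, 1):
            if dy == 0 and dx == 0:
                continue
            jy, jx = iy + dy, ix + dx
            ok = (jy >= 0) & (jy < ny) & (jx >= 0) & (jx < nx)
            nb = inv[jy[ok] * nx + jx[ok]]
            src = np.arange(flat.size)[ok]
            good = nb >= 0
            rows.append(src[good])
            cols.append(nb[good])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    w = sp.csr_matrix((np.ones(rows.size), (rows, cols)),
                      shape=(flat.size, flat.size))
    rowsum = np.asarray(w.sum(axis=1)).ravel()
    inv_rowsum = np.divide(1.0, rowsum, out=np.zeros_like(rowsum),
                           where=rowsum > 0)
    return sp.diags(inv_rowsum) @ w, flat


def bivariate_morans_I(
    x: ScalarField,
    y: ScalarField,
    mask: np.ndarray,
    weights: Optional[Tuple[sp.csr_matrix, np.ndarray]] = None,
    symmetric: bool = False,
) -> float:
    """Bivariate Moran's I of x against the spatial lag of y.

    I = z_x . (W z_y) / n with z-scored fields and row-standardised W;
    the univariate special case (y = x) is the ordinary Moran's I.
    ``symmetric=True`` averages I_xy and I_yx.
    """
    if x.grid != y.grid:
        raise ValueError("fields must share a grid")
    if np.count_nonzero(mask) < 2:
        raise ValueError("need at least 2 cells for Moran's I")
    w, flat = weights if weights is not None else queen_weights(mask)
    zx = x.values.ravel()[flat]
    zy = y.values.ravel()[flat]
    sx, sy = zx.std(), zy.std()
    if sx == 0 or sy == 0:
        raise ValueError("Moran's I undefined for a constant field")
    zx = (zx - zx.mean()) / sx
    zy = (zy - zy.mean()) / sy
    n = zx.size
    i_xy = float(zx @ (w @ zy)) / n
    if not symmetric:
        return i_xy
    i_yx = float(zy @ (w @ zx)) / n
    return 0.5 * (i_xy + i_yx)


def compare_distributions(
    a,
    b,
    welch: bool = False,
    alpha: float = 0.05,
) -> Tuple[float, float, bool]:
    """Two-sample t test of equal means; returns (t, p, reject_at_alpha).

    Classical pooled-variance Student's t by default; ``welch=True`` drops
    the equal-variance assumption.  Note that per-cell field samples are
    spatially autocorrelated, which inflates the nominal significance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p), bool(p < alpha)
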