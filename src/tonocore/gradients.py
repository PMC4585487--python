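"""Automated tonotopic gradient-reversal detection on a 2-D analysis sheet.

For every orientation theta (default 0..179 deg in 1-deg steps) the sign of
the best-frequency change along theta is computed at each cell; locations
where strictly opposite signs meet mark a gradient reversal with respect to
that orientation.  Summing the per-orientation binary edge maps yields a
composite map whose value at a reversal equals the number of orientations
flagging it and hence, with 1-degree sampling, the angle (in degrees) between
the two tonotopic gradients adjoining the edge.  Stable reversals (large
composite values) inside the core mask are extracted as field borders and
classified as low- or high-frequency reversals; gradient directions are
summarised with axial (doubled-angle) circular statistics.

Sheet convention: arrays are indexed (row, col); the x axis of an orientation
is the column axis and the y axis the row axis, so theta = 0 points along
increasing columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from .exceptions import ParameterError

#: relative tolerance defining a "zero" directional difference
ZERO_TOL_REL = 1e-9


def _sample(arr: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(arr, [rows, cols], order=1, mode="constant",
                                   cval=0.0)


def directional_sign_map(bf_map: np.ndarray, theta_deg: float,
                         valid: np.ndarray | None = None,
                         tol: float | None = None):
    """Sign of the best-frequency change along orientation ``theta_deg``.

    The directional difference is the central finite difference between
    bilinear samples one cell ahead of and behind each cell along theta.
    Returns ``(sign, defined)``: sign in {-1, 0, +1} (0 where the magnitude is
    below ``tol``, default 1e-9 of the map's dynamic range) and a boolean
    lattice marking cells whose both samples fall entirely on valid cells.
    """
    bf = np.asarray(bf_map, dtype=float)
    if bf.ndim != 2:
        raise ParameterError("bf_map must be 2-D")
    if not (0.0 <= theta_deg < 180.0):
        raise ParameterError("theta must lie in [0, 180)")
    if valid is None:
        valid = np.isfinite(bf)
    vals = bf[valid]
    if vals.size < 2:
        raise ParameterError("need >= 2 valid cells")
    if tol is None:
        rng = float(vals.max() - vals.min())
        tol = ZERO_TOL_REL * (rng if rng > 0 else 1.0)
    th = math.radians(theta_deg)
    ur, uc = math.sin(th), math.cos(th)          # y = rows, x = cols
    rr, cc = np.meshgrid(np.arange(bf.shape[0], dtype=float),
                         np.arange(bf.shape[1], dtype=float), indexing="ij")
    f = np.where(valid, bf, 0.0)
    w = valid.astype(float)
    fp = _sample(f, rr + ur, cc + uc)
    fm = _sample(f, rr - ur, cc - uc)
    wp = _sample(w, rr + ur, cc + uc)
    wm = _sample(w, rr - ur, cc - uc)
    defined = valid & (wp > 1.0 - 1e-9) & (wm > 1.0 - 1e-9)
    d = fp - fm
    sign = np.zeros(bf.shape, dtype=np.int8)
    sign[d > tol] = 1
    sign[d < -tol] = -1
    sign[~defined] = 0
    return sign, defined


def nan_gaussian_smooth(bf_map: np.ndarray, sigma: float,
                        support_min: float = 0.3) -> np.ndarray:
    """Gaussian smoothing of a map with invalid (NaN) cells.

    Valid-cell values and the validity indicator are filtered separately and
    their ratio taken, so invalid cells neither leak values in nor shrink the
    map; cells whose smoothed support falls below ``support_min`` (or that
    were invalid) stay NaN.
    """
    a = np.asarray(bf_map, dtype=float)
    if sigma <= 0:
        return a.copy()
    valid = np.isfinite(a)
    num = ndimage.gaussian_filter(np.where(valid, a, 0.0), sigma)
    den = ndimage.gaussian_filter(valid.astype(float), sigma)
    out = np.where(den > support_min, num / np.maximum(den, 1e-12), np.nan)
    out[~valid] = np.nan
    return out


def edge_map(sign: np.ndarray, defined: np.ndarray | None = None) -> np.ndarray:
    """Binary reversal map: cells flanking a strict +1/-1 sign opposition.

    Opposition is tested between 4-adjacent cells (both lattice axes); a
    zero-sign cell never anchors an edge.  Each dual-lattice edge marks both
    flanking cells, so the composite map accumulates the full opposite-sign
    orientation measure at the reversal.
    """
    s = np.asarray(sign)
    if defined is None:
        defined = np.ones_like(s, dtype=bool)
    out = np.zeros(s.shape, dtype=bool)
    for ax in (0, 1):
        a = [slice(None)] * 2
        b = [slice(None)] * 2
        a[ax] = slice(None, -1)
        b[ax] = slice(1, None)
        a, b = tuple(a), tuple(b)
        opp = (s[a] * s[b] == -1) & defined[a] & defined[b]
        out[a] |= opp
        out[b] |= opp
    return out


@dataclass
class CompositeEdgeMap:
    """Sum of per-orientation reversal maps; values are degrees when the
    sweep samples every degree."""

    composite: np.ndarray        # (rows, cols) int
    orientations: np.ndarray     # degrees
    edge_stack: np.ndarray | None = None   # (n_theta, rows, cols) bool


def composite_edge_map(bf_map: np.ndarray, valid: np.ndarray | None = None,
                       orientations=None, keep_stack: bool = True,
                       tol: float | None = None) -> CompositeEdgeMap:
    """Sweep orientations (default 0..179 deg, 1-deg steps) and sum the
    per-orientation reversal maps."""
    if orientations is None:
        orientations = np.arange(180.0)
    orientations = np.asarray(orientations, dtype=float)
    comp = np.zeros(np.asarray(bf_map).shape, dtype=int)
    stack = np.zeros((orientations.size,) + comp.shape, dtype=bool) if keep_stack else None
    for i, th in enumerate(orientations):
        s, d = directional_sign_map(bf_map, th, valid=valid, tol=tol)
        e = edge_map(s, d)
        comp += e
        if keep_stack:
            stack[i] = e
    return CompositeEdgeMap(comp, orientations, stack)


# ---------------------------------------------------------------------------
# borders
# ---------------------------------------------------------------------------

@dataclass
class Border:
    """A detected gradient-reversal border."""

    cells: list                  # [(row, col), ...]
    stability: float             # mean composite value = mean inter-gradient angle (deg)
    frequency_class: str         # "low" | "high"
    representative_angle: float | None = None   # deg, relative to reference axis

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def extract_borders(composite: CompositeEdgeMap, bf_map: np.ndarray,
                    core_mask: np.ndarray, stability_min: float = 60.0,
                    f_range_hz=None, min_cells: int = 1) -> list:
    """Extract stable reversal paths inside the (1-cell-dilated) core mask.

    Cells with composite value >= ``stability_min`` are grouped into
    8-connected components (components smaller than ``min_cells`` are
    discarded as speckle); each component's frequency class is low/high
    according to whether the median best frequency along the path falls below
    or above the midpoint of the stimulus log-frequency range.  Components are
    returned ranked by mean composite value (stability).  An empty list is a
    valid outcome (no stable reversal in the region).
    """
    comp = composite.composite
    core = np.asarray(core_mask, dtype=bool)
    if comp.shape != core.shape:
        raise ParameterError("composite and core mask must share geometry")
    region = ndimage.binary_dilation(core, structure=np.ones((3, 3), bool))
    cand = (comp >= stability_min) & region
    lab, n = ndimage.label(cand, structure=np.ones((3, 3), bool))
    bf = np.asarray(bf_map, dtype=float)
    vals = bf[np.isfinite(bf)]
    if f_range_hz is not None:
        # bf_map is on the log2 axis; midpoint of the stimulus log2 range
        mid = 0.5 * (math.log2(f_range_hz[0]) + math.log2(f_range_hz[1]))
    else:
        mid = 0.5 * (float(vals.min()) + float(vals.max())) if vals.size else 0.0
    borders = []
    for k in range(1, n + 1):
        sel = lab == k
        if sel.sum() < min_cells:
            continue
        cells = [tuple(map(int, p)) for p in np.argwhere(sel)]
        med = float(np.nanmedian(bf[sel]))
        fclass = "low" if med < mid else "high"
        borders.append(Border(cells, float(comp[sel].mean()), fclass))
    borders.sort(key=lambda b: -b.stability)
    return borders


def border_angle(edge_stack: np.ndarray, composite: np.ndarray,
                 orientations=None, reference_axis_deg: float = 0.0,
                 region: np.ndarray | None = None) -> float:
    """Representative border angle from the orientation-resolved edge stack.

    The border angle is the complement to 90 deg of the orientation whose
    edge map correlates maximally (Pearson, on the binary lattices) with the
    composite map.  On idealised straight reversals many orientations flag
    exactly the same cells, so the maximiser can be a whole tied set; the
    representative orientation is then the axial (doubled-angle) circular
    mean of the tied orientations, which keeps the measure equivariant under
    rotations of the map.  The result is reported relative to
    ``reference_axis_deg`` and folded to [0, 90].
    """
    stack = np.asarray(edge_stack)
    if orientations is None:
        orientations = np.arange(stack.shape[0], dtype=float)
    comp = np.asarray(composite, dtype=float)
    if region is not None:
        sel = np.asarray(region, dtype=bool)
    else:
        sel = np.ones(comp.shape, dtype=bool)
    c = comp[sel]
    if c.std() == 0:
        raise ParameterError("composite map is constant; no reversals")
    rs = np.full(len(orientations), -np.inf)
    for i in range(len(orientations)):
        e = stack[i][sel].astype(float)
        if e.std() == 0:
            continue
        rs[i] = float(np.corrcoef(e, c)[0, 1])
    if not np.isfinite(rs).any():
        raise ParameterError("all edge maps empty; angle undefined")
    tied = np.asarray(orientations, float)[rs >= rs.max() - 1e-9]
    theta_max = _axial_mean(tied)
    return fold_axial(90.0 - theta_max - reference_axis_deg)


def fold_axial(angle_deg: float) -> float:
    """Fold an axial angle (mod 180) into [0, 90]."""
    a = angle_deg % 180.0
    return min(a, 180.0 - a)


# ---------------------------------------------------------------------------
# gradient direction statistics
# ---------------------------------------------------------------------------

@dataclass
class DirectionStats:
    """Axial summary of per-cell gradient directions relative to an axis."""

    directions: np.ndarray       # folded to [0, 90] deg
    mean_deg: float
    ci95: tuple
    hist_counts: np.ndarray
    bin_edges: np.ndarray
    n_zero_excluded: int

    @property
    def n(self) -> int:
        return int(self.directions.size)


def _axial_mean(rel_deg: np.ndarray) -> float:
    """Doubled-angle circular mean of directions defined modulo 180 deg."""
    z = np.exp(1j * np.deg2rad(2.0 * rel_deg))
    return float(np.rad2deg(np.angle(z.mean())) / 2.0) % 180.0


def gradient_directions(bf_map: np.ndarray, region: np.ndarray,
                        reference_axis_deg: float = 0.0,
                        n_boot: int = 2000, seed: int = 0,
                        tol: float | None = None) -> DirectionStats:
    """Per-cell tonotopic gradient directions relative to a reference axis.

    Gradients are central differences; direction is the (axial) angle of the
    gradient line to the reference axis, folded to [0, 90] deg.  The mean
    direction and its bootstrap 95% CI use doubled-angle circular statistics
    computed before folding; the histogram bins every 45 deg.  Zero-gradient
    cells are excluded and counted.
    """
    bf = np.asarray(bf_map, dtype=float)
    region = np.asarray(region, dtype=bool)
    gy, gx = np.gradient(np.where(np.isfinite(bf), bf, np.nan))
    ok = region & np.isfinite(gx) & np.isfinite(gy)
    if ok.sum() < 5:
        raise ParameterError("need >= 5 valid cells in region")
    vx, vy = gx[ok], gy[ok]
    mag = np.hypot(vx, vy)
    if tol is None:
        tol = ZERO_TOL_REL * (mag.max() if mag.max() > 0 else 1.0)
    nz = mag > tol
    n_zero = int((~nz).sum())
    if nz.sum() < 5:
        raise ParameterError("fewer than 5 non-zero gradients in region")
    rel = (np.rad2deg(np.arctan2(vy[nz], vx[nz])) - reference_axis_deg) % 180.0
    mean = fold_axial(_axial_mean(rel))
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, rel.size, rel.size)
        boots[b] = fold_axial(_axial_mean(rel[idx]))
    ci = (float(np.quantile(boots, 0.025)), float(np.quantile(boots, 0.975)))
    folded = np.minimum(rel, 180.0 - rel)
    edges = np.array([0.0, 45.0, 90.0])
    counts, _ = np.histogram(folded, bins=edges)
    return DirectionStats(folded, mean, ci, counts, edges, n_zero)


def proportion_bootstrap(n_total: int, n_below: int, angle_threshold: float,
                         angle_range=(0.0, 90.0), B: int = 100_000,
                         seed: int = 0) -> float:
    """Tail probability of >= ``n_below`` of ``n_total`` angles below the
    threshold under a uniform null on ``angle_range``, by bootstrap.

    Draws ``B`` samples of ``n_total`` uniform angles and reports the fraction
    of samples with at least ``n_below`` below ``angle_threshold``.
    """
    if not (0 <= n_below <= n_total):
        raise ParameterError("require 0 <= n_below <= n_total")
    if B < 1000:
        raise ParameterError("B must be >= 1000")
    rng = np.random.default_rng(seed)
    lo, hi = angle_range
    draws = rng.uniform(lo, hi, size=(B, n_total))
    counts = (draws < angle_threshold).sum(axis=1)
    return float(np.mean(counts >= n_below))


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class GradientReversalDetector(BaseEstimator):
    """Detect and classify tonotopic-gradient reversals on a sheet.

    Parameters
    ----------
    orientation_step_deg : float
        Sweep step; 1 deg makes composite values equal inter-gradient angles.
    stability_min : float
        Minimum mean inter-gradient angle (deg) for a border to count.
    reference_axis_deg : float
        Axis (e.g. the long axis of Heschl's gyrus) angles are reported
        against.
    bf_smooth_sigma : float
        Optional nan-aware Gaussian smoothing (in cells) of the
        best-frequency sheet before the orientation sweep; 0 disables.
    min_cells : int
        Discard supra-threshold components smaller than this as speckle.
    """

    def __init__(self, orientation_step_deg: float = 1.0,
                 stability_min: float = 60.0, reference_axis_deg: float = 0.0,
                 bf_smooth_sigma: float = 0.0, min_cells: int = 1,
                 n_boot: int = 2000, seed: int = 0):
        self.orientation_step_deg = orientation_step_deg
        self.stability_min = stability_min
        self.reference_axis_deg = reference_axis_deg
        self.bf_smooth_sigma = bf_smooth_sigma
        self.min_cells = min_cells
        self.n_boot = n_boot
        self.seed = seed

    def fit(self, bf_map: np.ndarray, core_mask: np.ndarray,
            f_range_hz=None):
        orientations = np.arange(0.0, 180.0, self.orientation_step_deg)
        bf_map = nan_gaussian_smooth(np.asarray(bf_map, dtype=float),
                                     self.bf_smooth_sigma)
        valid = np.isfinite(bf_map) & np.asarray(core_mask, dtype=bool)
        self.smoothed_bf_ = bf_map
        self.composite_ = composite_edge_map(bf_map, valid=valid,
                                             orientations=orientations)
        self.borders_ = extract_borders(self.composite_, bf_map, core_mask,
                                        self.stability_min, f_range_hz,
                                        self.min_cells)
        for b in self.borders_:
            sel = np.zeros(self.composite_.composite.shape, dtype=bool)
            sel[tuple(np.array(b.cells).T)] = True
            # include a margin: inside the path alone every informative edge
            # map is constant (all cells flagged) and would be skipped
            sel = ndimage.binary_dilation(sel, np.ones((3, 3), bool),
                                          iterations=3)
            try:
                b.representative_angle = border_angle(
                    self.composite_.edge_stack, self.composite_.composite,
                    orientations, self.reference_axis_deg, region=sel)
            except ParameterError:
                b.representative_angle = None
        try:
            self.direction_stats_ = gradient_directions(
                bf_map, valid, self.reference_axis_deg, self.n_boot, self.seed)
        except ParameterError:
            self.direction_stats_ = None
        return self
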