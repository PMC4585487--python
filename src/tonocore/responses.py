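"""Per-voxel condition responses versus silent baseline, and their reliability.

Under sparse sampling every trial yields one independent functional sample, so
the general linear model with one indicator regressor per condition plus a
baseline intercept reduces exactly to condition means versus the baseline mean.
Responses are expressed in percent signal change relative to the voxel's
baseline mean, which makes them invariant to rescaling the raw series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from sklearn.base import BaseEstimator

from .exceptions import ParameterError
from .phantom import GAUSS_FWHM_FACTOR, StimulusSchedule, VolumeSeries


@dataclass
class ResponseTable:
    """Per-voxel tuning curves (percent signal change per condition).

    Rows follow ``coords`` (voxel indices into the source volume).  Trial-level
    dispersion statistics are retained so that activation tests can be run on
    the table alone.
    """

    coords: np.ndarray           # (n_vox, 3) int
    volume_shape: tuple
    frequencies_hz: np.ndarray   # (n_cond,)
    values: np.ndarray           # (n_vox, n_cond) percent signal change
    cond_sd: np.ndarray          # (n_vox, n_cond) trial-level sd of percent change
    cond_n: np.ndarray           # (n_cond,) trials per condition
    base_sd: np.ndarray          # (n_vox,) trial-level sd of baseline percent change
    base_n: int
    valid: np.ndarray            # (n_vox,) False where baseline mean was <= 0

    @property
    def n_conditions(self) -> int:
        return int(self.values.shape[1])

    @property
    def n_voxels(self) -> int:
        return int(self.values.shape[0])

    @property
    def r_bar(self) -> np.ndarray:
        """Mean response across conditions (recomputed, never cached)."""
        return self.values.mean(axis=1)

    def as_volume(self, per_voxel: np.ndarray, fill=np.nan) -> np.ndarray:
        """Scatter a per-voxel vector back onto the 3-D lattice."""
        out = np.full(self.volume_shape, fill, dtype=float)
        out[tuple(self.coords.T)] = per_voxel
        return out

    def to_frame(self):
        import pandas as pd

        cols = {"x": self.coords[:, 0], "y": self.coords[:, 1], "z": self.coords[:, 2]}
        for i in range(self.n_conditions):
            cols[f"r_{i + 1}"] = self.values[:, i]
        cols["r_bar"] = self.r_bar
        cols["valid"] = self.valid
        return pd.DataFrame(cols)


def _smooth_volumes(data: np.ndarray, voxel_size_mm, fwhm_mm: float) -> np.ndarray:
    """Separable truncated-Gaussian spatial smoothing of each trial volume."""
    sigma_vox = [fwhm_mm / GAUSS_FWHM_FACTOR / s for s in voxel_size_mm]
    return ndimage.gaussian_filter(data, sigma=sigma_vox + [0.0], truncate=4.0)


def estimate_responses(series: VolumeSeries, schedule: StimulusSchedule | None = None,
                       smooth_fwhm_mm: float | None = None,
                       run: int | None = None) -> ResponseTable:
    """Estimate percent-signal-change tuning curves for every masked voxel.

    Dummy trials are always excluded.  ``run`` restricts estimation to one
    experimental run (baseline trials of that run included), which is how the
    per-run tables for split-run reliability are produced.  When
    ``smooth_fwhm_mm`` is given, each trial volume is spatially smoothed
    before estimation; the classification path never uses this option.
    """
    schedule = schedule or series.schedule
    if schedule.n_trials != series.data.shape[3]:
        raise ParameterError("schedule does not match series")
    keep = ~schedule.dummy_mask
    if run is not None:
        keep &= schedule.run == run
    data = series.data
    if smooth_fwhm_mm:
        data = _smooth_volumes(data, series.voxel_size_mm, smooth_fwhm_mm)

    coords = np.argwhere(series.brain_mask)
    vox = data[series.brain_mask]                   # (n_vox, n_trials)
    cond = schedule.condition
    base_idx = np.flatnonzero(keep & (cond == 0))
    if base_idx.size == 0:
        raise ParameterError("no baseline trials in selection")
    base_mean = vox[:, base_idx].mean(axis=1)
    valid = base_mean > 0
    safe = np.where(valid, base_mean, 1.0)
    pct = 100.0 * (vox - safe[:, None]) / safe[:, None]

    n_cond = schedule.n_conditions
    n_vox = coords.shape[0]
    values = np.zeros((n_vox, n_cond))
    cond_sd = np.zeros((n_vox, n_cond))
    cond_n = np.zeros(n_cond, dtype=int)
    for c in range(1, n_cond + 1):
        idx = np.flatnonzero(keep & (cond == c))
        cond_n[c - 1] = idx.size
        if idx.size:
            values[:, c - 1] = pct[:, idx].mean(axis=1)
            cond_sd[:, c - 1] = pct[:, idx].std(axis=1, ddof=1) if idx.size > 1 else 0.0
    base_sd = pct[:, base_idx].std(axis=1, ddof=1) if base_idx.size > 1 else np.zeros(n_vox)
    return ResponseTable(coords, series.data.shape[:3], schedule.nominal_frequencies,
                         values, cond_sd, cond_n, base_sd, base_idx.size, valid)


def voxelwise_activation_test(table: ResponseTable, alpha: float) -> np.ndarray:
    """Mask of voxels responding significantly to at least one condition.

    Per voxel and condition, a one-sided Welch t-test of the condition trials
    against the baseline trials (uncorrected, any-condition union).  Returns a
    3-D boolean lattice on the source volume's grid.
    """
    if np.any(table.cond_n < 2) or table.base_n < 2:
        raise ParameterError("need >= 2 trials per condition and baseline")
    nb = table.base_n
    vb = table.base_sd[:, None] ** 2
    nc = table.cond_n[None, :]
    vc = table.cond_sd ** 2
    se = np.sqrt(vc / nc + vb / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = table.values / se
        num = (vc / nc + vb / nb) ** 2
        den = (vc / nc) ** 2 / (nc - 1) + (vb / nb) ** 2 / (nb - 1)
        df = np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0)
        p = stats.t.sf(t, df)
    p = np.where(np.isfinite(p), p, 1.0)
    any_sig = (p <= alpha).any(axis=1) & table.valid
    return table.as_volume(any_sig.astype(float), fill=0.0).astype(bool)


@dataclass
class ReliabilityResult:
    """Split-run tuning-curve reliability versus a scrambled-voxel null."""

    correlations: np.ndarray     # observed per-voxel run1/run2 correlations
    null: np.ndarray             # scrambled-pair correlations
    median_r: float
    ranksum_stat: float
    p_value: float
    n_excluded: int              # constant tuning curves (correlation undefined)


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    num = (a * b).sum(axis=1)
    den = np.sqrt((a ** 2).sum(axis=1) * (b ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def split_run_reliability(run1: ResponseTable, run2: ResponseTable,
                          n_resamples: int = 10_000, seed: int = 0) -> ReliabilityResult:
    """Correlate each voxel's run-1 and run-2 tuning curves and test the
    observed distribution against a scrambled-voxel null.

    The null draws ``n_resamples`` voxel pairs (v, v') with v' != v uniformly
    with replacement and correlates run-1 voxel v with run-2 voxel v'; a
    two-sample Wilcoxon rank-sum test compares observed and null correlation
    distributions.  Voxels with constant tuning curves are excluded and
    counted.
    """
    if run1.values.shape != run2.values.shape:
        raise ParameterError("runs must share voxels and conditions")
    if run1.n_conditions < 3:
        raise ParameterError("need >= 3 conditions")
    rng = np.random.default_rng(seed)
    ok = run1.valid & run2.valid
    a, b = run1.values[ok], run2.values[ok]
    obs = _rowwise_pearson(a, b)
    n_excluded = int(np.isnan(obs).sum())
    obs = obs[~np.isnan(obs)]
    n = a.shape[0]
    if n < 2:
        raise ParameterError("need >= 2 voxels for the scrambled null")
    v = rng.integers(0, n, size=n_resamples)
    off = rng.integers(1, n, size=n_resamples)
    vp = (v + off) % n                   # guaranteed v' != v
    null = _rowwise_pearson(a[v], b[vp])
    null = null[~np.isnan(null)]
    stat, p = stats.ranksums(obs, null)
    return ReliabilityResult(obs, null, float(np.median(obs)), float(stat),
                             float(p), n_excluded)


class ResponseEstimator(BaseEstimator):
    """Estimator wrapper around :func:`estimate_responses`.

    Parameters
    ----------
    smooth_fwhm_mm : float or None
        Optional Gaussian spatial smoothing applied before estimation.
    alpha : float
        Significance level for the any-condition activation mask.
    """

    def __init__(self, smooth_fwhm_mm: float | None = None, alpha: float = 0.05):
        self.smooth_fwhm_mm = smooth_fwhm_mm
        self.alpha = alpha

    def fit(self, series: VolumeSeries, y=None):
        self.table_ = estimate_responses(series, smooth_fwhm_mm=self.smooth_fwhm_mm)
        self.run_tables_ = {
            r: estimate_responses(series, smooth_fwhm_mm=self.smooth_fwhm_mm, run=r)
            for r in range(1, series.schedule.n_runs + 1)}
        self.activation_mask_ = voxelwise_activation_test(self.table_, self.alpha)
        return self
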