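"""Voxel best frequencies and tuning widths: centroid method and roex fits.

The centroid of a voxel's tuning curve is the weighted mean of the stimulus
frequency values with weights ``w_i = r_i / (n * rbar)`` (equivalently
``r_i / sum(r)``), a non-parametric best-frequency estimate that uses the
responses to all frequencies.  Tuning width is the weighted spread about the
centroid, converted to a full-width-at-half-maximum with the Gaussian factor
``2 * sqrt(2 ln 2)``.  For comparison, tuning curves can also be fitted with a
rounded-exponential (roex) bell ``a (1 + p g) exp(-p g) + c`` whose peak is
constrained to the stimulated frequency range.

Both estimators default to the log2-frequency axis (stimuli are log-spaced and
tonotopy is logarithmic); a linear-Hz option is provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ParameterError
from .phantom import GAUSS_FWHM_FACTOR
from .responses import ResponseTable

#: x solving (1 + x) exp(-x) = 1/2, the roex half-maximum crossing
ROEX_HALF_X = float(optimize.brentq(lambda x: (1 + x) * math.exp(-x) - 0.5, 1e-9, 10.0))


def _weights(responses, clip_negative=True):
    r = np.asarray(responses, dtype=float)
    if clip_negative:
        r = np.clip(r, 0.0, None)
    s = r.sum()
    if not s > 0:
        return None
    return r / s


def centroid(responses, axis_values, clip_negative: bool = True) -> float:
    """Tuning-curve centroid: sum of normalised responses times axis values.

    Negative responses are clipped to zero before normalisation so the result
    stays a convex combination of the axis values.  Returns NaN (voxel
    flagged) when all responses are <= 0.
    """
    f = np.asarray(axis_values, dtype=float)
    if f.size < 2:
        raise ParameterError("need >= 2 frequencies")
    w = _weights(responses, clip_negative)
    if w is None:
        return float("nan")
    return float(w @ f)


def spread_fwhm(responses, axis_values, clip_negative: bool = True):
    """Weighted spread about the centroid and the derived FWHM.

    spread = sqrt(sum_i w_i (f_i - centroid)^2); FWHM = spread * 2 sqrt(2 ln 2).
    """
    f = np.asarray(axis_values, dtype=float)
    w = _weights(responses, clip_negative)
    if w is None:
        return float("nan"), float("nan")
    c = float(w @ f)
    spread = math.sqrt(float(w @ (f - c) ** 2))
    return spread, spread * GAUSS_FWHM_FACTOR


def roex_profile(g: np.ndarray, p: float) -> np.ndarray:
    """Rounded-exponential bell (peak 1 at g = 0): (1 + p g) exp(-p g)."""
    pg = p * np.abs(g)
    return (1.0 + pg) * np.exp(-pg)


def fit_roex(responses, frequencies_hz, f_range=None, axis: str = "log2"):
    """Least-squares roex fit of a tuning curve.

    Model: ``a * (1 + p g) exp(-p g) + c`` with ``g = |log2(f / f0)|`` on the
    default log2 axis (or ``|f - f0| / f0`` on the linear axis), the peak f0
    constrained to the stimulated range.  Initialisation grids f0 over the
    stimulus frequencies and p over {1, 4, 16}; the best start (smallest SSE,
    ties to the smallest p) is refined by bounded least squares.

    Returns ``(peak_hz, fwhm, p, ok)`` where ``fwhm`` is in octaves on the
    log2 axis and Hz on the linear axis, derived from the closed-form
    half-maximum crossing of the roex profile.
    """
    r = np.asarray(responses, dtype=float)
    f = np.asarray(frequencies_hz, dtype=float)
    if r.size < 4:
        raise ParameterError("need >= 4 points for a 4-parameter fit")
    if f_range is None:
        f_range = (f.min(), f.max())
    lo, hi = math.log2(f_range[0]), math.log2(f_range[1])
    l2f = np.log2(f)

    def g_of(l2f0):
        if axis == "log2":
            return np.abs(l2f - l2f0)
        return np.abs(f - 2.0 ** l2f0) / 2.0 ** l2f0

    def model(theta):
        l2f0, p, a, c = theta
        return a * roex_profile(g_of(l2f0), p) + c

    def resid(theta):
        return model(theta) - r

    best = None
    for l2f0 in np.clip(l2f, lo, hi):
        g = g_of(l2f0)
        for p in (1.0, 4.0, 16.0):
            basis = roex_profile(g, p)
            A = np.column_stack([basis, np.ones_like(basis)])
            (a, c), *_ = np.linalg.lstsq(A, r, rcond=None)
            a = max(a, 0.0)
            sse = float(((a * basis + c - r) ** 2).sum())
            if best is None or sse < best[0] - 1e-12 or (
                    abs(sse - best[0]) <= 1e-12 and p < best[1][1]):
                best = (sse, [l2f0, p, a, c])
    try:
        fit = optimize.least_squares(
            resid, best[1],
            bounds=([lo, 1e-2, 0.0, -np.inf], [hi, 1e3, np.inf, np.inf]))
        ok = bool(fit.success)
        l2f0, p, a, c = fit.x
    except Exception:
        ok = False
        l2f0, p, a, c = best[1]
    peak = 2.0 ** l2f0
    if axis == "log2":
        fwhm = 2.0 * ROEX_HALF_X / p                 # octaves
    else:
        fwhm = 2.0 * ROEX_HALF_X / p * peak          # Hz
    return float(peak), float(fwhm), float(p), ok


@dataclass
class TuningSummary:
    """Per-voxel best-frequency and tuning-width estimates."""

    coords: np.ndarray
    volume_shape: tuple
    axis: str                     # "log2" | "linear"
    centroid: np.ndarray          # axis units (log2 Hz or Hz)
    spread: np.ndarray
    fwhm_centroid: np.ndarray
    valid: np.ndarray
    roex_peak_hz: np.ndarray | None = None
    roex_fwhm: np.ndarray | None = None
    roex_p: np.ndarray | None = None
    roex_ok: np.ndarray | None = None
    #: provenance of the spread -> FWHM conversion
    fwhm_factor: float = GAUSS_FWHM_FACTOR

    def centroid_hz(self) -> np.ndarray:
        return 2.0 ** self.centroid if self.axis == "log2" else self.centroid

    def as_volume(self, per_voxel: np.ndarray) -> np.ndarray:
        out = np.full(self.volume_shape, np.nan)
        out[tuple(self.coords.T)] = per_voxel
        return out

    def to_frame(self):
        import pandas as pd

        d = {"x": self.coords[:, 0], "y": self.coords[:, 1], "z": self.coords[:, 2],
             "centroid": self.centroid, "spread": self.spread,
             "fwhm_centroid": self.fwhm_centroid, "valid": self.valid}
        if self.roex_peak_hz is not None:
            d.update(roex_peak_hz=self.roex_peak_hz, roex_fwhm=self.roex_fwhm,
                     roex_p=self.roex_p, roex_ok=self.roex_ok)
        return pd.DataFrame(d)


class TuningSummarizer(BaseEstimator, TransformerMixin):
    """Compute centroid (and optionally roex) tuning summaries from a
    :class:`~tonocore.responses.ResponseTable`.

    Parameters
    ----------
    axis : {"log2", "linear"}
        Frequency-axis convention for centroid and spread.
    clip_negative : bool
        Clip negative responses to zero before weight normalisation.
    fit_roex : bool
        Also fit the parametric roex bell per voxel (slower).
    """

    def __init__(self, axis: str = "log2", clip_negative: bool = True,
                 fit_roex: bool = False):
        self.axis = axis
        self.clip_negative = clip_negative
        self.fit_roex = fit_roex

    def fit(self, table: ResponseTable, y=None):
        if self.axis not in ("log2", "linear"):
            raise ParameterError("axis must be 'log2' or 'linear'")
        f = table.frequencies_hz
        fx = np.log2(f) if self.axis == "log2" else f
        n = table.n_voxels
        cen = np.full(n, np.nan)
        spr = np.full(n, np.nan)
        fwhm = np.full(n, np.nan)
        valid = np.zeros(n, dtype=bool)
        for i in range(n):
            if not table.valid[i]:
                continue
            c = centroid(table.values[i], fx, self.clip_negative)
            if math.isnan(c):
                continue
            s, w = spread_fwhm(table.values[i], fx, self.clip_negative)
            cen[i], spr[i], fwhm[i], valid[i] = c, s, w, True
        summary = TuningSummary(table.coords, table.volume_shape, self.axis,
                                cen, spr, fwhm, valid)
        if self.fit_roex:
            pk = np.full(n, np.nan)
            rw = np.full(n, np.nan)
            rp = np.full(n, np.nan)
            ok = np.zeros(n, dtype=bool)
            for i in range(n):
                if not valid[i]:
                    continue
                pk[i], rw[i], rp[i], ok[i] = fit_roex(
                    table.values[i], f, axis=self.axis)
            summary.roex_peak_hz, summary.roex_fwhm = pk, rw
            summary.roex_p, summary.roex_ok = rp, ok
        self.summary_ = summary
        return self

    def transform(self, table: ResponseTable) -> TuningSummary:
        self.fit(table)
        return self.summary_


def compare_best_frequency_maps(map_a: np.ndarray, map_b: np.ndarray):
    """Pearson correlation between two best-frequency maps over commonly
    valid (finite) voxels."""
    a = np.asarray(map_a, dtype=float).ravel()
    b = np.asarray(map_b, dtype=float).ravel()
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ParameterError("need >= 3 commonly valid voxels")
    r, p = stats.pearsonr(a[ok], b[ok])
    return float(r), float(p)


def accuracy_metric_correlations(accuracy_map: np.ndarray, summary: TuningSummary,
                                 table: ResponseTable) -> dict:
    """Correlate searchlight accuracy with tuning sharpness and amplitude.

    Returns Pearson (r, p) of accuracy against (a) centroid spread, (b) roex
    FWHM (if fitted), (c) maximum percent signal change across conditions and
    (d) RMS signal change; pairs with degenerate (constant) inputs are
    reported as None.
    """
    acc = np.asarray(accuracy_map, dtype=float)[tuple(summary.coords.T)]
    metrics = {
        "spread": summary.spread,
        "max_psc": table.values.max(axis=1),
        "rms_psc": np.sqrt((table.values ** 2).mean(axis=1)),
    }
    if summary.roex_fwhm is not None:
        metrics["roex_fwhm"] = summary.roex_fwhm
    out = {}
    for name, m in metrics.items():
        ok = np.isfinite(acc) & np.isfinite(m)
        if ok.sum() < 3 or np.std(m[ok]) == 0 or np.std(acc[ok]) == 0:
            out[name] = None
            continue
        r, p = stats.pearsonr(acc[ok], m[ok])
        out[name] = {"r": float(r), "p": float(p), "n": int(ok.sum())}
    return out
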