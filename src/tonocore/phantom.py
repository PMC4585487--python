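"""Synthetic sparse-sampling tonotopy experiments with known ground truth.

The generator emulates a passive pure-tone tonotopy protocol: ``n`` log-spaced
tone conditions plus silent baseline trials, presented in short stimulation
epochs under sparse sampling (one functional volume per trial, long TR, so no
haemodynamic convolution is modelled).  Voxels on a designated 2-D cortical
"sheet" carry bell-shaped frequency tuning arranged into mirror-symmetric
tonotopic fields that share a low-frequency border; an optional caudal field
adds a high-frequency border.  Everything downstream (response estimation,
searchlight classification, gradient-reversal border detection) can therefore
be validated against planted truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import LayoutError, ParameterError

# trial condition codes: 1..n are stimulus conditions
BASELINE = 0
DUMMY = -1

#: sd -> FWHM conversion for a Gaussian profile
GAUSS_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


# ---------------------------------------------------------------------------
# stimulus schedule
# ---------------------------------------------------------------------------

@dataclass
class StimulusSchedule:
    """Ordered trial sequence of a sparse-sampling tonotopy run set.

    ``condition`` holds one entry per trial: ``1..n_conditions`` for tone
    trials, ``0`` for silent baseline trials and ``-1`` for initial dummy
    trials (discarded from analysis).
    """

    condition: np.ndarray            # (n_trials,) int
    run: np.ndarray                  # (n_trials,) int, 1..n_runs
    n_conditions: int
    nominal_frequencies: np.ndarray  # (n_conditions,) Hz, strictly increasing
    epoch_len: int
    tr_s: float = 9.0
    n_dummy: int = 0

    def __post_init__(self) -> None:
        self.condition = np.asarray(self.condition, dtype=int)
        self.run = np.asarray(self.run, dtype=int)
        self.nominal_frequencies = np.asarray(self.nominal_frequencies, dtype=float)
        if self.condition.shape != self.run.shape:
            raise ParameterError("condition and run must have equal length")
        if self.nominal_frequencies.size != self.n_conditions:
            raise ParameterError("one nominal frequency per condition required")
        if self.n_conditions > 1 and not np.all(np.diff(self.nominal_frequencies) > 0):
            raise ParameterError("nominal frequencies must be strictly increasing")

    @property
    def n_trials(self) -> int:
        return int(self.condition.size)

    @property
    def n_runs(self) -> int:
        return int(self.run.max())

    @property
    def stimulus_mask(self) -> np.ndarray:
        return self.condition >= 1

    @property
    def baseline_mask(self) -> np.ndarray:
        return self.condition == BASELINE

    @property
    def dummy_mask(self) -> np.ndarray:
        return self.condition == DUMMY

    def condition_counts(self) -> np.ndarray:
        """Trial count per stimulus condition (index 0 = condition 1)."""
        return np.bincount(self.condition[self.stimulus_mask],
                           minlength=self.n_conditions + 1)[1:]

    def epoch_sequence(self) -> np.ndarray:
        """Condition of each stimulation epoch, in presentation order."""
        stim = self.condition[self.stimulus_mask]
        return stim[:: self.epoch_len]

    def to_frame(self):
        """Trial table with columns trial, run, condition, frequency_hz."""
        import pandas as pd

        labels = []
        freqs = []
        for c in self.condition:
            if c == BASELINE:
                labels.append("baseline")
                freqs.append(np.nan)
            elif c == DUMMY:
                labels.append("dummy")
                freqs.append(np.nan)
            else:
                labels.append(str(int(c)))
                freqs.append(self.nominal_frequencies[c - 1])
        return pd.DataFrame({
            "trial": np.arange(self.n_trials),
            "run": self.run,
            "condition": labels,
            "frequency_hz": freqs,
        })


def nominal_frequencies(n: int, f_min: float, f_max: float) -> np.ndarray:
    """``n`` geometrically spaced frequencies from ``f_min`` to ``f_max`` (Hz)."""
    if n < 2:
        raise ParameterError("need at least 2 frequencies")
    if not (0.0 < f_min < f_max):
        raise ParameterError("require 0 < f_min < f_max")
    return np.geomspace(f_min, f_max, n)


def _balanced_epoch_sequence(n: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """Sequence of ``m`` epochs of each of ``n`` conditions with near-uniform
    first-order transition counts.

    A randomised Eulerian path on a condition-transition multigraph whose cell
    multiplicities differ by at most one: every ordered pair (i, j) gets
    ``m // n`` transitions plus one extra along ``m % n`` circulant shifts,
    minus the single edge removed to open the circuit into a path.
    """
    if n == 1:
        return np.zeros(m, dtype=int)
    q, r = divmod(m, n)
    # circulant shifts; their gcd with n must be 1 so the graph is connected
    if q >= 1:
        shifts = rng.choice(n, size=r, replace=False) if r else np.empty(0, int)
    else:
        while True:
            shifts = rng.choice(n, size=r, replace=False)
            nz = [int(s) for s in shifts if s > 0]
            if nz and math.gcd(n, *nz) == 1:
                break
    mult = np.full((n, n), q, dtype=int)
    for s in shifts:
        mult[np.arange(n), (np.arange(n) + s) % n] += 1
    # remove one edge (u -> v): u becomes the path end, v the start
    u = int(rng.integers(n))
    if r:
        s = int(shifts[rng.integers(len(shifts))])
        v = (u + s) % n
    else:
        v = int(rng.integers(n))
    mult[u, v] -= 1
    # Hierholzer with randomised out-edge order
    adj = []
    for i in range(n):
        out = np.repeat(np.arange(n), mult[i])
        rng.shuffle(out)
        adj.append(list(out))
    stack, path = [v], []
    while stack:
        w = stack[-1]
        if adj[w]:
            stack.append(adj[w].pop())
        else:
            path.append(stack.pop())
    seq = np.array(path[::-1], dtype=int)
    if seq.size != m * n:                              # pragma: no cover
        raise RuntimeError("Eulerian path construction failed")
    return seq


def make_schedule(n_conditions: int, reps_per_condition: int, epoch_len: int,
                  n_dummy: int, n_runs: int, seed: int,
                  f_min: float = 200.0, f_max: float = 8000.0,
                  tr_s: float = 9.0) -> StimulusSchedule:
    """Build a pseudorandom sparse-sampling schedule.

    Tones are presented in epochs of ``epoch_len`` trials of one condition
    followed by ``epoch_len`` silent baseline trials; epoch order within each
    run has approximately balanced first-order transition probabilities.
    ``n_dummy`` dummy trials open the first run.  Total trial count is
    ``2 * reps_per_condition * n_conditions + n_dummy``.
    """
    if min(n_conditions, reps_per_condition, epoch_len, n_runs) < 1:
        raise ParameterError("counts must be >= 1")
    if n_dummy < 0:
        raise ParameterError("n_dummy must be >= 0")
    if reps_per_condition % epoch_len:
        raise ParameterError("reps_per_condition must be divisible by epoch_len")
    m = reps_per_condition // epoch_len          # epochs per condition
    if m % n_runs:
        raise ParameterError(
            "reps_per_condition must be divisible by epoch_len * n_runs")
    rng = np.random.default_rng(seed)
    if n_conditions >= 2:
        freqs = nominal_frequencies(n_conditions, f_min, f_max)
    else:
        freqs = np.array([math.sqrt(f_min * f_max)])

    condition, run = [], []
    for r_idx in range(n_runs):
        if r_idx == 0:
            condition += [DUMMY] * n_dummy
            run += [1] * n_dummy
        epochs = _balanced_epoch_sequence(n_conditions, m // n_runs, rng) + 1
        for c in epochs:
            condition += [int(c)] * epoch_len + [BASELINE] * epoch_len
            run += [r_idx + 1] * (2 * epoch_len)
    return StimulusSchedule(np.array(condition), np.array(run), n_conditions,
                            freqs, epoch_len, tr_s=tr_s, n_dummy=n_dummy)


# ---------------------------------------------------------------------------
# field layout (ground truth standing in for a manual parcellation)
# ---------------------------------------------------------------------------

@dataclass
class BorderTruth:
    """Planted border: cell path plus its low/high frequency class."""

    cells: list          # list of (row, col)
    frequency_class: str  # "low" | "high"


@dataclass
class FieldLayout:
    """Ground-truth tonotopic layout on a 2-D sheet.

    ``bf_truth`` holds each tuned cell's best frequency in Hz (NaN for the
    untuned surround); ``field_id`` labels cells 0 (surround) or 1..k.
    """

    sheet_shape: tuple
    bf_truth: np.ndarray
    field_id: np.ndarray
    fields: list                     # dicts: name, gradient_deg, rate_oct_per_cell, f_range
    border_segments: list            # list of BorderTruth
    f_lo: float
    f_hi: float

    @property
    def surround_cells(self) -> np.ndarray:
        return self.field_id == 0

    @property
    def tuned_mask(self) -> np.ndarray:
        return self.field_id > 0

    def to_json(self) -> str:
        return json.dumps({
            "sheet_shape": list(self.sheet_shape),
            "f_lo": self.f_lo, "f_hi": self.f_hi,
            "fields": self.fields,
            "border_segments": [
                {"cells": [list(map(int, c)) for c in b.cells],
                 "frequency_class": b.frequency_class}
                for b in self.border_segments],
        }, indent=2)


def make_field_layout(sheet_shape: Sequence[int], layout_spec: dict | None = None) -> FieldLayout:
    """Construct a mirror-gradient field layout on a rectangular sheet.

    The default ``layout_spec`` plants two rectangular fields ("A1", "R") with
    mirror-symmetric log-frequency gradients meeting at a straight shared
    low-frequency border; ``n_fields=3`` adds a caudal field behind A1's
    high-frequency end (shared high-frequency border), ``n_fields=1`` keeps a
    single gradient and hence no border.  ``gradient_axis_deg`` rotates the
    gradient axis (the border runs perpendicular to it).

    layout_spec keys (all optional):
      n_fields (2), gradient_axis_deg (0), field_extent (cells along the
      gradient axis per field), field_breadth (cells across), center
      (row, col), f_lo (200), f_hi (8000).
    """
    rows, cols = int(sheet_shape[0]), int(sheet_shape[1])
    spec = dict(layout_spec or {})
    n_fields = int(spec.pop("n_fields", 2))
    phi = math.radians(float(spec.pop("gradient_axis_deg", 0.0)))
    extent = spec.pop("field_extent", None)
    breadth = spec.pop("field_breadth", None)
    center = spec.pop("center", None)
    f_lo = float(spec.pop("f_lo", 200.0))
    f_hi = float(spec.pop("f_hi", 8000.0))
    if spec:
        raise LayoutError(f"unknown layout_spec keys: {sorted(spec)}")
    if n_fields not in (1, 2, 3):
        raise LayoutError("n_fields must be 1, 2 or 3")
    if not f_lo < f_hi:
        raise LayoutError("require f_lo < f_hi")
    if extent is None:
        extent = max(2, cols // (n_fields + 1))
    if breadth is None:
        breadth = max(2, int(0.7 * rows))
    extent = int(extent)
    breadth = int(breadth)
    if center is None:
        # integer column anchor: with the +0.5 shift below the low-frequency
        # crease always falls BETWEEN two cell columns for axis-aligned
        # layouts (a crease on a column has zero directional difference there
        # and would be invisible to the reversal detector)
        center = ((rows - 1) / 2.0, (cols - 1) // 2)

    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    x = cc - center[1]
    y = rr - center[0]
    # a tiny extra offset keeps oblique creases off exact cell centers
    eps = 1e-6 if phi % (math.pi / 2) else 0.0
    u = x * math.cos(phi) + y * math.sin(phi) + 0.5 + eps
    v = -x * math.sin(phi) + y * math.cos(phi)

    rate = math.log2(f_hi / f_lo) / extent        # octaves per cell
    in_breadth = np.abs(v) <= breadth / 2.0

    field_id = np.zeros((rows, cols), dtype=int)
    bf = np.full((rows, cols), np.nan)
    fields = []

    def add_field(fid, name, sel, dist, direction_deg):
        if not np.any(sel):
            raise LayoutError(f"sheet too small to host field {name}")
        if np.any(field_id[sel] != 0):
            raise LayoutError(f"field {name} overlaps an existing field")
        field_id[sel] = fid
        bf[sel] = f_lo * 2.0 ** (rate * dist[sel])
        fields.append({"name": name, "gradient_deg": direction_deg,
                       "rate_oct_per_cell": rate, "f_range": [f_lo, f_hi]})

    deg = math.degrees(phi)
    if n_fields == 1:
        add_field(1, "R", (u >= 0) & (u < extent) & in_breadth, u, deg)
    else:
        add_field(1, "A1", (u < 0) & (u >= -extent) & in_breadth, -u, deg + 180.0)
        add_field(2, "R", (u >= 0) & (u < extent) & in_breadth, u, deg)
        if n_fields == 3:
            add_field(3, "CM", (u < -extent) & (u >= -2 * extent) & in_breadth,
                      2 * extent + u, deg)

    borders = []
    if n_fields >= 2:
        low = (u > -0.5) & (u <= 0.5) & in_breadth
        borders.append(BorderTruth([tuple(p) for p in np.argwhere(low)], "low"))
    if n_fields == 3:
        high = (u > -extent - 0.5) & (u <= -extent + 0.5) & in_breadth
        borders.append(BorderTruth([tuple(p) for p in np.argwhere(high)], "high"))
    return FieldLayout((rows, cols), bf, field_id, fields, borders, f_lo, f_hi)


# ---------------------------------------------------------------------------
# volume simulation
# ---------------------------------------------------------------------------

@dataclass
class VoxelTuningParams:
    """Default tuning parameters applied to every tuned voxel.

    ``amplitude`` and ``baseline_level`` share the (arbitrary) raw signal
    units; with the default baseline of 100 the amplitude is numerically the
    peak percent signal change.  ``amplitude`` and ``tuning_fwhm_oct`` may be
    2-D arrays matching the sheet for spatially heterogeneous phantoms.
    """

    tuning_fwhm_oct: float | np.ndarray = 1.5
    amplitude: float | np.ndarray = 2.0
    baseline_level: float = 100.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.amplitude) < 0):
            raise ParameterError("amplitude must be >= 0")
        if np.any(np.asarray(self.tuning_fwhm_oct) <= 0):
            raise ParameterError("tuning_fwhm_oct must be > 0")


@dataclass
class VolumeSeries:
    """4-D trial-wise signal lattice plus acquisition geometry."""

    data: np.ndarray                 # (nx, ny, nz, n_trials)
    voxel_size_mm: tuple
    brain_mask: np.ndarray           # (nx, ny, nz) bool
    schedule: StimulusSchedule
    sheet_z: int | None = None       # z-slab hosting the tonotopic sheet

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ParameterError("data must be 4-D (x, y, z, trial)")
        if self.data.shape[3] != self.schedule.n_trials:
            raise ParameterError("trial axis length must equal schedule length")
        if any(s <= 0 for s in self.voxel_size_mm):
            raise ParameterError("voxel sizes must be > 0")
        if self.brain_mask.shape != self.data.shape[:3]:
            raise ParameterError("brain mask shape must match spatial dims")

    @property
    def shape(self) -> tuple:
        return self.data.shape


def gaussian_log2_response(f_hz: np.ndarray, bf_hz: np.ndarray,
                           fwhm_oct: np.ndarray | float) -> np.ndarray:
    """Bell-shaped tuning profile, Gaussian in log2 frequency, peak 1."""
    sigma = np.asarray(fwhm_oct, dtype=float) / GAUSS_FWHM_FACTOR
    d = np.log2(f_hz) - np.log2(bf_hz)
    return np.exp(-(d ** 2) / (2.0 * sigma ** 2))


def simulate_experiment(layout: FieldLayout, tuning: VoxelTuningParams | None,
                        schedule: StimulusSchedule, noise_sd: float,
                        jitter_semitones: float = 1.0, seed: int = 0,
                        n_z: int = 3, sheet_z: int | None = None,
                        voxel_size_mm: tuple = (1.5, 1.5, 2.5)) -> VolumeSeries:
    """Simulate a sparse-sampling tonotopy experiment on a phantom layout.

    Each trial contributes one independent functional sample (sparse sampling,
    no haemodynamic convolution).  Tone trials drive tuned voxels with
    ``baseline + amplitude * g(f_trial, bf)`` where ``g`` is Gaussian in log2
    frequency and the trial frequency jitters uniformly within
    ``jitter_semitones`` (total width) around the nominal value; baseline and
    dummy trials, untuned voxels and off-sheet slabs carry baseline only.
    Independent Gaussian noise of sd ``noise_sd`` is added everywhere.
    """
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    tuning = tuning or VoxelTuningParams()
    rows, cols = layout.sheet_shape
    if sheet_z is None:
        sheet_z = n_z // 2
    if not 0 <= sheet_z < n_z:
        raise ParameterError("sheet_z outside volume")
    rng = np.random.default_rng(seed)
    n_trials = schedule.n_trials

    # per-trial effective stimulus frequency (NaN on baseline/dummy trials)
    f_trial = np.full(n_trials, np.nan)
    stim = schedule.stimulus_mask
    f_nom = schedule.nominal_frequencies[schedule.condition[stim] - 1]
    jitter = rng.uniform(-0.5, 0.5, size=f_nom.size) * jitter_semitones / 12.0
    f_trial[stim] = f_nom * 2.0 ** jitter

    base = tuning.baseline_level
    data = np.full((rows, cols, n_z, n_trials), base, dtype=float)

    tuned = layout.tuned_mask
    bf = layout.bf_truth[tuned]                                  # (n_tuned,)
    amp = np.broadcast_to(np.asarray(tuning.amplitude, float),
                          layout.sheet_shape)[tuned]
    fwhm = np.broadcast_to(np.asarray(tuning.tuning_fwhm_oct, float),
                           layout.sheet_shape)[tuned]
    resp = amp[:, None] * gaussian_log2_response(
        f_trial[stim][None, :], bf[:, None], fwhm[:, None])      # (n_tuned, n_stim)
    sheet = data[:, :, sheet_z, :]
    stim_idx = np.flatnonzero(stim)
    flat = sheet[tuned]
    flat[:, stim_idx] += resp
    sheet[tuned] = flat

    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=data.shape)

    mask = np.ones((rows, cols, n_z), dtype=bool)
    return VolumeSeries(data, tuple(voxel_size_mm), mask, schedule, sheet_z=sheet_z)
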