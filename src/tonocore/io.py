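"""Reading and writing of pipeline artefacts.

Lattices travel as NIfTI-1 (via nibabel, affine = diag(voxel sizes)); trial
tables and voxel tables as TSV; configurations, reports and border lists as
JSON.  Round trips are exact at the level of array values and table cells.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import FormatError
from .phantom import BASELINE, DUMMY, StimulusSchedule, VolumeSeries
from .responses import ResponseTable

TRIAL_COLUMNS = ("trial", "run", "condition", "frequency_hz")


def _affine(voxel_size_mm) -> np.ndarray:
    return np.diag(list(voxel_size_mm) + [1.0])


def write_map(arr: np.ndarray, voxel_size_mm, path) -> None:
    """Write a 2-D/3-D/4-D lattice as NIfTI-1."""
    a = np.asarray(arr)
    if a.ndim == 2:
        a = a[:, :, None]
    vs = list(voxel_size_mm)[: max(a.ndim, 3)]
    while len(vs) < 3:
        vs.append(1.0)
    img = nib.Nifti1Image(a.astype(np.float64), _affine(vs))
    nib.save(img, str(path))


def read_map(path) -> tuple:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), tuple(img.header.get_zooms()[:3])


def write_volume_series(series: VolumeSeries, nifti_path, trial_table_path) -> None:
    write_map(series.data, series.voxel_size_mm, nifti_path)
    series.schedule.to_frame().to_csv(trial_table_path, sep="\t", index=False)


def _schedule_from_frame(df: pd.DataFrame) -> StimulusSchedule:
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trial table missing column(s): {missing}")
    cond = []
    for v in df["condition"]:
        s = str(v)
        if s == "baseline":
            cond.append(BASELINE)
        elif s == "dummy":
            cond.append(DUMMY)
        else:
            try:
                cond.append(int(float(s)))
            except ValueError as e:
                raise FormatError(f"unrecognised condition label {s!r}") from e
    cond = np.array(cond)
    stim = cond >= 1
    if not stim.any():
        raise FormatError("trial table contains no stimulus trials")
    pairs = sorted({(int(c), float(f)) for c, f in
                    zip(cond[stim], df.loc[stim, "frequency_hz"])})
    n_cond = max(p[0] for p in pairs)
    freqs = np.full(n_cond, np.nan)
    for c, f in pairs:
        freqs[c - 1] = f
    if np.isnan(freqs).any():
        raise FormatError("conditions without a nominal frequency")
    # epoch length = length of the first baseline block (baseline blocks are
    # always separated by stimulus trials, unlike stimulus blocks, which can
    # merge when consecutive epochs repeat a condition)
    base_idx = np.flatnonzero(cond == BASELINE)
    if base_idx.size:
        first = base_idx[0]
        epoch_len = 1
        while (first + epoch_len < cond.size
               and cond[first + epoch_len] == BASELINE):
            epoch_len += 1
    else:
        epoch_len = 1
    return StimulusSchedule(cond, df["run"].to_numpy(int), n_cond, freqs,
                            epoch_len, n_dummy=int((cond == DUMMY).sum()))


def read_experiment(nifti_path, trial_table_path,
                    brain_mask: np.ndarray | None = None) -> VolumeSeries:
    """Load a 4-D functional series plus its trial table.

    Validates dimensionality, positive voxel sizes and the trial-count match
    between the volume's 4th axis and the table; raises
    :class:`~tonocore.exceptions.FormatError` naming the offending axis.
    """
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise FormatError(f"expected 4-D NIfTI, got {data.ndim}-D")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise FormatError(f"non-positive voxel size in header: {zooms}")
    df = pd.read_csv(trial_table_path, sep="\t")
    schedule = _schedule_from_frame(df)
    if schedule.n_trials != data.shape[3]:
        raise FormatError(
            f"trial axis: volume has {data.shape[3]} trials, table has "
            f"{schedule.n_trials} rows")
    if brain_mask is None:
        brain_mask = np.ones(data.shape[:3], dtype=bool)
    return VolumeSeries(data, tuple(float(z) for z in zooms), brain_mask, schedule)


# ---------------------------------------------------------------------------
# voxel tables
# ---------------------------------------------------------------------------

def write_response_table(table: ResponseTable, tsv_path, meta_path=None) -> None:
    df = table.to_frame()
    for i in range(table.n_conditions):
        df[f"sd_{i + 1}"] = table.cond_sd[:, i]
    df["base_sd"] = table.base_sd
    df.to_csv(tsv_path, sep="\t", index=False)
    if meta_path:
        write_json({
            "volume_shape": list(table.volume_shape),
            "frequencies_hz": [float(f) for f in table.frequencies_hz],
            "cond_n": [int(n) for n in table.cond_n],
            "base_n": int(table.base_n),
        }, meta_path)


def read_response_table(tsv_path, meta_path) -> ResponseTable:
    df = pd.read_csv(tsv_path, sep="\t")
    meta = read_json(meta_path)
    n_cond = len(meta["frequencies_hz"])
    values = df[[f"r_{i + 1}" for i in range(n_cond)]].to_numpy(float)
    cond_sd = df[[f"sd_{i + 1}" for i in range(n_cond)]].to_numpy(float)
    return ResponseTable(
        df[["x", "y", "z"]].to_numpy(int), tuple(meta["volume_shape"]),
        np.asarray(meta["frequencies_hz"], float), values, cond_sd,
        np.asarray(meta["cond_n"], int), df["base_sd"].to_numpy(float),
        int(meta["base_n"]), df["valid"].to_numpy(bool))


# ---------------------------------------------------------------------------
# JSON
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_jsonable) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
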