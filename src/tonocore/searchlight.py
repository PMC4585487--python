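"""Searchlight frequency classification: delineating "core" as the region
whose local multi-voxel patterns predict stimulus frequency above chance.

Trial series are detrended per run with robust LOWESS, mean-corrected and
variance-normalised (no spatial smoothing on this path).  A sphere of
configurable radius (mm, centre-to-centre, inclusive) around every masked
voxel defines the local pattern; the multi-class problem is partitioned into
all pairwise binary problems solved by a linear max-margin classifier (or
k-NN), combined by majority voting, and evaluated with stratified
contiguous-block cross-validation.  Accuracies are converted to binomial
z scores and thresholded with a Monte-Carlo max-cluster-size correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats
from sklearn.base import BaseEstimator
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._mvpa import _center_accuracy
from .exceptions import ParameterError
from .phantom import StimulusSchedule, VolumeSeries

# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

@dataclass
class PreprocessedSeries:
    """Detrended, per-run standardised voxel-by-trial matrix."""

    data: np.ndarray             # (n_vox, n_kept_trials)
    coords: np.ndarray           # (n_vox, 3)
    volume_shape: tuple
    kept_trials: np.ndarray      # indices into the schedule (dummies dropped)
    valid: np.ndarray            # (n_vox,) False where variance vanished
    schedule: StimulusSchedule
    voxel_size_mm: tuple

    @property
    def stimulus_trials(self) -> np.ndarray:
        """Positions (into ``data`` columns) of the stimulus trials."""
        return np.flatnonzero(self.schedule.condition[self.kept_trials] >= 1)

    def labels(self) -> np.ndarray:
        """Zero-based condition labels of the stimulus trials."""
        return self.schedule.condition[self.kept_trials][self.stimulus_trials] - 1


def preprocess_timeseries(series: VolumeSeries, lowess_frac: float = 0.5,
                          lowess_it: int = 2) -> PreprocessedSeries:
    """Robust-LOWESS detrend + standardise each voxel's series, per run.

    The LOWESS window spans ``lowess_frac`` of a run (robustified with
    ``lowess_it`` reweighting iterations); after trend subtraction each run is
    mean-corrected and divided by its standard deviation.  Voxels whose
    residual variance vanishes in any run are flagged invalid and zeroed.
    """
    schedule = series.schedule
    keep = np.flatnonzero(~schedule.dummy_mask)
    runs = schedule.run[keep]
    for r in np.unique(runs):
        if (runs == r).sum() < 10:
            raise ParameterError("need >= 10 trials per run")
    coords = np.argwhere(series.brain_mask)
    raw = series.data[series.brain_mask][:, keep]
    out = np.zeros_like(raw)
    valid = np.ones(raw.shape[0], dtype=bool)
    for r in np.unique(runs):
        cols = np.flatnonzero(runs == r)
        t = cols.astype(float)
        for v in range(raw.shape[0]):
            y = raw[v, cols]
            trend = lowess(y, t, frac=lowess_frac, it=lowess_it,
                           return_sorted=False)
            res = y - trend
            res -= res.mean()
            sd = res.std()
            if sd <= 1e-12 * (abs(y).max() + 1.0):
                valid[v] = False
                out[v, cols] = 0.0
            else:
                out[v, cols] = res / sd
    return PreprocessedSeries(out, coords, series.data.shape[:3], keep, valid,
                              schedule, series.voxel_size_mm)


# ---------------------------------------------------------------------------
# neighbourhoods
# ---------------------------------------------------------------------------

def sphere_offsets(voxel_size_mm, radius_mm: float) -> np.ndarray:
    """Integer voxel offsets whose centre-to-centre distance is <= radius."""
    if radius_mm <= 0:
        raise ParameterError("radius must be > 0")
    sz = np.asarray(voxel_size_mm, dtype=float)
    lim = np.floor(radius_mm / sz).astype(int)
    axes = [np.arange(-l, l + 1) for l in lim]
    g = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    d2 = ((g * sz) ** 2).sum(axis=1)
    return g[d2 <= radius_mm ** 2 + 1e-9]


@dataclass
class NeighborhoodIndex:
    """Searchlight membership: for each centre voxel, its in-mask members."""

    centers: np.ndarray          # (n_centers, 3)
    members: list                # per centre, int array of voxel-row indices
    radius_mm: float
    voxel_size_mm: tuple
    volume_shape: tuple

    @property
    def n_centers(self) -> int:
        return len(self.members)


def sphere_neighborhoods(mask: np.ndarray, voxel_size_mm,
                         radius_mm: float) -> NeighborhoodIndex:
    """Build the searchlight index over all voxels of ``mask``.

    Member voxels are those in the mask whose centre lies within
    ``radius_mm`` (inclusive) of the centre voxel; the centre always belongs
    to its own neighbourhood.  Row indices refer to ``mask`` voxels in
    ``np.argwhere`` order.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ParameterError("empty mask")
    coords = np.argwhere(mask)
    idx_vol = np.full(mask.shape, -1, dtype=int)
    idx_vol[tuple(coords.T)] = np.arange(coords.shape[0])
    offs = sphere_offsets(voxel_size_mm, radius_mm)
    members = []
    shape = np.asarray(mask.shape)
    for c in coords:
        pts = c + offs
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        ids = idx_vol[tuple(pts[ok].T)]
        members.append(np.sort(ids[ids >= 0]))
    return NeighborhoodIndex(coords, members, radius_mm, tuple(voxel_size_mm),
                             mask.shape)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def stratified_contiguous_folds(labels: np.ndarray, n_folds: int) -> np.ndarray:
    """Assign each trial to one of ``n_folds`` test folds, stratified by
    class with contiguous-in-time blocks per class (limits leakage between
    temporally adjacent trials)."""
    labels = np.asarray(labels)
    if n_folds < 2:
        raise ParameterError("need >= 2 folds")
    fold = np.full(labels.size, -1, dtype=np.int64)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < n_folds:
            raise ParameterError(
                f"class {c} has {idx.size} trials; cannot stratify into "
                f"{n_folds} folds")
        for f, chunk in enumerate(np.array_split(idx, n_folds)):
            fold[chunk] = f
    return fold


@dataclass
class AccuracyMap:
    """Per-voxel searchlight proportion correct plus the test metadata."""

    accuracy: np.ndarray         # 3-D, NaN outside mask
    n_test: int                  # trials tested per centre
    p0: float                    # chance level
    classifier: str
    n_folds: int

    def z_map(self) -> np.ndarray:
        return accuracy_to_z(self.accuracy, self.n_test, self.p0)


def _classifier_params(classifier, C, n_neighbors):
    if classifier == "svm":
        return 0, float(C)
    if classifier == "knn":
        if n_neighbors < 1:
            raise ParameterError("n_neighbors must be >= 1")
        return int(n_neighbors), float(C)
    raise ParameterError("classifier must be 'svm' or 'knn'")


def searchlight_accuracy(pre: PreprocessedSeries, nbh: NeighborhoodIndex,
                         labels: np.ndarray | None = None,
                         classifier: str = "svm", C: float = 1.0,
                         n_neighbors: int = 1, n_folds: int = 5,
                         svm_tol: float = 1e-4, svm_max_epochs: int = 1000,
                         fold_id: np.ndarray | None = None) -> AccuracyMap:
    """Cross-validated classification accuracy for every searchlight centre.

    For each centre the member voxels' standardised responses on the stimulus
    trials form the pattern; all pairwise binary classifiers are trained per
    fold and combined by majority vote (ties: summed signed margins, then
    lowest class index); accuracy averages over the held-out parts.
    """
    if labels is None:
        labels = pre.labels()
    labels = np.asarray(labels, dtype=np.int64)
    classes = np.unique(labels)
    n_classes = classes.size
    if n_classes < 2:
        raise ParameterError("need >= 2 classes")
    lab = np.searchsorted(classes, labels)
    if fold_id is None:
        fold_id = stratified_contiguous_folds(lab, n_folds)
    knn_k, C = _classifier_params(classifier, C, n_neighbors)
    stim_cols = pre.stimulus_trials
    X_all = pre.data[:, stim_cols]                   # (n_vox, n_stim)
    acc_vol = np.full(pre.volume_shape, np.nan)
    for ci in range(nbh.n_centers):
        ids = nbh.members[ci]
        X = np.empty((stim_cols.size, ids.size + 1))
        X[:, :-1] = X_all[ids].T
        X[:, -1] = 1.0                               # bias column
        a = _center_accuracy(X, lab, fold_id, n_folds, n_classes, C,
                             svm_tol, svm_max_epochs, knn_k)
        acc_vol[tuple(nbh.centers[ci])] = a
    name = "svm" if knn_k == 0 else f"knn(k={knn_k})"
    return AccuracyMap(acc_vol, int(stim_cols.size), 1.0 / n_classes, name, n_folds)


def collapse_to_binary(labels: np.ndarray, frequencies_hz: np.ndarray,
                       split_hz: float | None = None) -> np.ndarray:
    """Collapse multi-frequency condition labels into low (0) vs high (1).

    ``labels`` are zero-based condition indices; conditions whose nominal
    frequency is at or below ``split_hz`` map to low.  The default split is
    the geometric midpoint of the frequency range, which halves an even,
    log-spaced ladder.
    """
    f = np.asarray(frequencies_hz, dtype=float)
    if f.size < 2:
        raise ParameterError("need >= 2 distinct frequencies")
    if split_hz is None:
        split_hz = float(np.sqrt(f.min() * f.max()))
    binary = (f[np.asarray(labels, dtype=int)] > split_hz).astype(np.int64)
    if binary.min() == binary.max():
        raise ParameterError("split leaves one class empty")
    return binary


def permuted_label_accuracy(pre: PreprocessedSeries, nbh: NeighborhoodIndex,
                            n_permutations: int = 20, labels: np.ndarray | None = None,
                            seed: int = 0, **kwargs) -> dict:
    """Mean searchlight accuracy under random label permutation.

    Permutes the trial labels uniformly at random before fold assignment and
    training, ``n_permutations`` times; returns per-permutation means over
    centres, their grand mean and the Monte-Carlo standard error (in percent
    correct).
    """
    if labels is None:
        labels = pre.labels()
    rng = np.random.default_rng(seed)
    means = []
    for _ in range(n_permutations):
        perm = rng.permutation(np.asarray(labels))
        amap = searchlight_accuracy(pre, nbh, labels=perm, **kwargs)
        means.append(float(np.nanmean(amap.accuracy)) * 100.0)
    means = np.asarray(means)
    se = means.std(ddof=1) / np.sqrt(len(means)) if len(means) > 1 else np.nan
    return {"mean_pct": float(means.mean()), "per_permutation_pct": means,
            "mc_se_pct": float(se), "n_permutations": n_permutations}


# ---------------------------------------------------------------------------
# inference on accuracy maps
# ---------------------------------------------------------------------------

def accuracy_to_z(accuracy, n_test: int, p0: float):
    """Binomial z transform: z = (k - N p0) / sqrt(N p0 (1 - p0))."""
    if n_test <= 0:
        raise ParameterError("n_test must be > 0")
    acc = np.asarray(accuracy, dtype=float)
    k = acc * n_test
    return (k - n_test * p0) / np.sqrt(n_test * p0 * (1.0 - p0))


def z_threshold(voxel_p: float) -> float:
    """One-sided standard-normal quantile for a voxel-level p threshold."""
    return float(stats.norm.ppf(1.0 - voxel_p))


@dataclass
class CoreMask:
    """Cluster-corrected supra-threshold mask."""

    mask: np.ndarray
    z_star: float
    cluster_size_threshold: int
    cluster_alpha: float
    achieved_alpha: float        # null P(max cluster size > threshold)
    n_perm: int


def _max_cluster_size(binary: np.ndarray, structure) -> int:
    lab, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(lab.ravel())[1:].max())


def cluster_threshold(z_lattice: np.ndarray, z_star: float,
                      cluster_alpha: float = 0.05, null_spec: dict | None = None,
                      seed: int = 0, mask: np.ndarray | None = None,
                      fixed_size_threshold: int | None = None) -> CoreMask:
    """Retain supra-threshold clusters larger than a Monte-Carlo null quantile.

    Supra-threshold voxels (z > z_star) are grouped by face connectivity.  The
    null distribution of the maximum cluster size is simulated from standard
    normal lattices (optionally smoothed with ``null_spec['smooth_fwhm_vox']``
    and re-standardised to unit variance); clusters larger than the
    (1 - cluster_alpha) quantile survive.  ``fixed_size_threshold`` bypasses
    the simulation and applies the given size cut directly.
    """
    spec = {"n_perm": 1000, "smooth_fwhm_vox": None}
    spec.update(null_spec or {})
    n_perm = int(spec["n_perm"])
    z = np.asarray(z_lattice, dtype=float)
    if mask is None:
        mask = np.isfinite(z)
    structure = ndimage.generate_binary_structure(z.ndim, 1)
    if fixed_size_threshold is None:
        if n_perm < 100:
            warnings.warn("fewer than 100 permutations: cluster-size quantile "
                          "is unstable", stacklevel=2)
        rng = np.random.default_rng(seed)
        fwhm = spec["smooth_fwhm_vox"]
        sizes = np.empty(n_perm, dtype=int)
        for i in range(n_perm):
            null = rng.standard_normal(z.shape)
            if fwhm:
                null = ndimage.gaussian_filter(null, sigma=fwhm / 2.3548)
                null /= null[mask].std()
            sizes[i] = _max_cluster_size((null > z_star) & mask, structure)
        k_star = int(np.quantile(sizes, 1.0 - cluster_alpha, method="higher"))
        achieved = float(np.mean(sizes > k_star))
    else:
        k_star = int(fixed_size_threshold)
        achieved = float("nan")
        n_perm = 0
    supra = np.where(mask, z, -np.inf) > z_star
    lab, n = ndimage.label(supra, structure=structure)
    keep = np.zeros_like(supra)
    for comp in range(1, n + 1):
        sel = lab == comp
        if sel.sum() > k_star:
            keep |= sel
    return CoreMask(keep, float(z_star), k_star, float(cluster_alpha),
                    achieved, n_perm)


# ---------------------------------------------------------------------------
# mask comparison utilities
# ---------------------------------------------------------------------------

def region_overlap(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap of two binary masks, in percent (0 when either is empty)."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ParameterError("masks must share lattice geometry")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(200.0 * np.logical_and(a, b).sum() / denom)


def centroid_distance(mask_a: np.ndarray, mask_b: np.ndarray,
                      voxel_size_mm) -> float:
    """Distance in mm between the binary masks' centres of mass."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ParameterError("masks must share lattice geometry")
    if not (a.any() and b.any()):
        raise ParameterError("centroid undefined for an empty mask")
    ca = np.array(ndimage.center_of_mass(a))
    cb = np.array(ndimage.center_of_mass(b))
    return float(np.linalg.norm((ca - cb) * np.asarray(voxel_size_mm)))


def probability_map(masks) -> np.ndarray:
    """Per-voxel count of masks containing the voxel."""
    masks = [np.asarray(m, dtype=bool) for m in masks]
    if not masks:
        raise ParameterError("need at least one mask")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ParameterError("masks must share lattice geometry")
    return np.sum(masks, axis=0).astype(int)


# ---------------------------------------------------------------------------
# estimator facade
# ---------------------------------------------------------------------------

class SearchlightClassifier(BaseEstimator):
    """Searchlight frequency classifier producing accuracy and z maps.

    Parameters mirror the pipeline stage: sphere ``radius_mm``
    (centre-to-centre, inclusive), ``classifier`` ("svm" regularised by ``C``
    or "knn" with ``n_neighbors``), ``n_folds`` cross-validation folds,
    ``voxel_p``/``cluster_p`` thresholds and the Monte-Carlo ``n_perm`` for
    cluster correction.  ``collapse_binary`` recodes the conditions into a
    low-versus-high problem before classification.
    """

    def __init__(self, radius_mm: float = 4.0, classifier: str = "svm",
                 C: float = 1.0, n_neighbors: int = 1, n_folds: int = 5,
                 voxel_p: float = 0.01, cluster_p: float = 0.05,
                 n_perm: int = 1000, collapse_binary: bool = False,
                 lowess_frac: float = 0.5, seed: int = 0):
        self.radius_mm = radius_mm
        self.classifier = classifier
        self.C = C
        self.n_neighbors = n_neighbors
        self.n_folds = n_folds
        self.voxel_p = voxel_p
        self.cluster_p = cluster_p
        self.n_perm = n_perm
        self.collapse_binary = collapse_binary
        self.lowess_frac = lowess_frac
        self.seed = seed

    def fit(self, series: VolumeSeries, y: np.ndarray | None = None):
        pre = preprocess_timeseries(series, lowess_frac=self.lowess_frac)
        nbh = sphere_neighborhoods(series.brain_mask, series.voxel_size_mm,
                                   self.radius_mm)
        labels = y if y is not None else pre.labels()
        if self.collapse_binary and y is None:
            labels = collapse_to_binary(labels, series.schedule.nominal_frequencies)
        self.preprocessed_ = pre
        self.neighborhoods_ = nbh
        self.accuracy_map_ = searchlight_accuracy(
            pre, nbh, labels=labels, classifier=self.classifier, C=self.C,
            n_neighbors=self.n_neighbors, n_folds=self.n_folds)
        self.z_map_ = self.accuracy_map_.z_map()
        self.core_mask_ = cluster_threshold(
            self.z_map_, z_threshold(self.voxel_p), self.cluster_p,
            {"n_perm": self.n_perm}, seed=self.seed)
        return self
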