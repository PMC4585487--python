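import numpy as np
import pytest

import tonocore as tc
from tonocore._mvpa import _center_accuracy, _dcd_svm, _knn_margin
from tonocore.exceptions import ParameterError
from tonocore.searchlight import (sphere_offsets,
                                  stratified_contiguous_folds)


class TestPreprocess:
    def test_linear_drift_removed(self, mirror_layout):
        sched = tc.make_schedule(4, 8, 2, 0, 1, seed=0)
        ser = tc.simulate_experiment(mirror_layout, None, sched, 0.0, 0.0,
                                     seed=0, n_z=1)
        drift = np.linspace(0.0, 5.0, sched.n_trials)
        flat = ser.data.copy()
        flat[:] = 100.0
        flat += drift                                 # pure linear trend
        ser2 = tc.VolumeSeries(flat, ser.voxel_size_mm, ser.brain_mask, sched)
        pre = tc.preprocess_timeseries(ser2)
        # residual variance vanishes -> voxels flagged, output zero
        assert not pre.valid.any()
        assert np.allclose(pre.data, 0.0, atol=1e-6)

    def test_white_noise_standardised(self, noisy_series):
        pre = tc.preprocess_timeseries(noisy_series)
        runs = noisy_series.schedule.run[pre.kept_trials]
        for r in (1, 2):
            cols = runs == r
            assert np.allclose(pre.data[:, cols].mean(axis=1), 0.0, atol=1e-12)
            assert np.allclose(pre.data[:, cols].std(axis=1), 1.0, atol=1e-9)

    def test_condition_effect_survives_detrending(self):
        """Drift plus condition effect: after detrending, the high condition
        still ranks above the low one in every tuned voxel."""
        sched = tc.make_schedule(2, 20, 2, 0, 1, seed=1, f_min=250, f_max=1000)
        bf = np.full((4, 4), 1000.0)
        lay = tc.FieldLayout((4, 4), bf, np.ones((4, 4), int), [], [],
                             250.0, 1000.0)
        ser = tc.simulate_experiment(lay, tc.VoxelTuningParams(1.0, 5.0, 100.0),
                                     sched, noise_sd=0.3, jitter_semitones=0.0,
                                     seed=2, n_z=1)
        ser.data += np.linspace(0, 10, sched.n_trials)   # slow drift
        pre = tc.preprocess_timeseries(ser)
        cond = sched.condition[pre.kept_trials]
        hi = pre.data[:, cond == 2].mean(axis=1)
        lo = pre.data[:, cond == 1].mean(axis=1)
        assert np.all(hi > lo)

    def test_too_few_trials_rejected(self, mirror_layout):
        sched = tc.make_schedule(2, 2, 1, 0, 1, seed=0)
        ser = tc.simulate_experiment(mirror_layout, None, sched, 0.0, seed=0,
                                     n_z=1)
        with pytest.raises(ParameterError):
            tc.preprocess_timeseries(ser)


class TestNeighborhoods:
    def brute_force_count(self, voxel_size, radius):
        """Independent oracle: enumerate integer offsets in a generous box."""
        count = 0
        for dx in range(-10, 11):
            for dy in range(-10, 11):
                for dz in range(-10, 11):
                    d2 = (dx * voxel_size[0]) ** 2 + (dy * voxel_size[1]) ** 2 \
                        + (dz * voxel_size[2]) ** 2
                    if d2 <= radius ** 2:
                        count += 1
        return count

    def test_tiny_radius_keeps_center_only(self):
        offs = sphere_offsets((1.0, 1.0, 1.0), 0.5)
        assert offs.shape == (1, 3)

    def test_unit_radius_face_neighbours(self):
        assert sphere_offsets((1.0, 1.0, 1.0), 1.0).shape[0] == 7

    def test_acquisition_geometry_sphere_size(self):
        """4-mm sphere at 1.5 x 1.5 x 2.5 mm voxels contains 47 voxels by
        centre-to-centre distance (brute-force oracle)."""
        vs = (1.5, 1.5, 2.5)
        offs = sphere_offsets(vs, 4.0)
        assert offs.shape[0] == self.brute_force_count(vs, 4.0) == 47

    def test_center_in_own_neighbourhood_and_mask_respected(self):
        mask = np.zeros((5, 5, 3), bool)
        mask[1:4, 1:4, 1] = True
        nbh = tc.sphere_neighborhoods(mask, (1.5, 1.5, 2.5), 4.0)
        assert nbh.n_centers == 9
        for i, c in enumerate(nbh.centers):
            row = np.flatnonzero((nbh.centers == c).all(axis=1))[0]
            assert row in nbh.members[i]

    def test_empty_mask_rejected(self):
        with pytest.raises(ParameterError):
            tc.sphere_neighborhoods(np.zeros((3, 3, 3), bool), (1, 1, 1), 2.0)


class TestClassifierKernels:
    """The compiled solvers must agree with reference library classifiers."""

    def _problem(self, seed, n=40, d=8, sep=1.5):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, d))
        y = np.repeat([-1.0, 1.0], n // 2)
        X[y > 0, 0] += sep
        return X, y

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_svm_matches_reference_predictions(self, seed):
        from sklearn.svm import SVC

        X, y = self._problem(seed)
        Xb = np.column_stack([X, np.ones(len(X))])
        w = _dcd_svm(Xb, y, 1.0, 1e-6, 10_000)
        rng = np.random.default_rng(seed + 100)
        Xt = rng.normal(size=(60, X.shape[1]))
        Xt[:30, 0] += 1.5
        ours = np.sign(np.column_stack([Xt, np.ones(60)]) @ w)
        ref = SVC(kernel="linear", C=1.0).fit(X, y).predict(Xt)
        # the reference leaves the bias unregularised, so boundary-zone
        # points may differ; bulk agreement must still be high
        assert (ours == ref).mean() > 0.9

    def test_knn_matches_reference(self):
        from sklearn.neighbors import KNeighborsClassifier

        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 5))
        y = np.where(rng.random(30) > 0.5, 1.0, -1.0)
        Xt = rng.normal(size=(50, 5))
        ref = KNeighborsClassifier(n_neighbors=1).fit(X, y).predict(Xt)
        ours = np.array([np.sign(_knn_margin(X, y, x, 1)) for x in Xt])
        assert np.array_equal(ours, ref)


class TestSearchlightAccuracy:
    def test_separable_patterns_classified_perfectly(self, mirror_layout):
        sched = tc.make_schedule(8, 20, 2, 0, 1, seed=3)
        ser = tc.simulate_experiment(mirror_layout, None, sched, 0.0, 0.0,
                                     seed=0, n_z=1)
        ser.data += np.random.default_rng(0).normal(
            scale=1e-6, size=ser.data.shape)        # break zero variance
        pre = tc.preprocess_timeseries(ser)
        # field-interior centers only: spheres spanning the mirror crease
        # contain duplicated best frequencies, which leaves one condition
        # pair genuinely non-separable there
        mask = np.zeros(ser.brain_mask.shape, bool)
        mask[8:12, 11:14, 0] = True
        nbh = tc.sphere_neighborhoods(ser.brain_mask, ser.voxel_size_mm, 4.0)
        sel = [i for i, c in enumerate(nbh.centers) if mask[tuple(c)]]
        nbh.centers = nbh.centers[sel]
        nbh.members = [nbh.members[i] for i in sel]
        amap = tc.searchlight_accuracy(pre, nbh)
        assert np.nanmin(amap.accuracy) == 1.0

    def test_binary_reduces_to_single_classifier(self):
        """With C = 2 the pairwise majority vote must equal the lone binary
        classifier's prediction for every trial."""
        rng = np.random.default_rng(11)
        n, d = 40, 6
        X = np.column_stack([rng.normal(size=(n, d)), np.ones(n)])
        y = rng.integers(0, 2, n).astype(np.int64)
        fold = stratified_contiguous_folds(y, 4)
        acc_vote = _center_accuracy(X, y, fold, 4, 2, 1.0, 1e-6, 10_000, 0)
        correct = 0
        for f in range(4):
            tr = fold != f
            yt = np.where(y[tr] == 1, 1.0, -1.0)
            w = _dcd_svm(X[tr], yt, 1.0, 1e-6, 10_000)
            pred = (X[fold == f] @ w >= 0).astype(int)
            correct += int((pred == y[fold == f]).sum())
        assert acc_vote == pytest.approx(correct / n)

    def test_collapse_to_binary(self):
        f6 = tc.nominal_frequencies(6, 500, 16000)
        lab = np.arange(6)
        b = tc.collapse_to_binary(lab, f6)
        assert list(b) == [0, 0, 0, 1, 1, 1]
        f8 = tc.nominal_frequencies(8, 200, 8000)
        b8 = tc.collapse_to_binary(np.arange(8), f8)
        assert list(b8) == [0] * 4 + [1] * 4
        assert list(tc.collapse_to_binary([0, 1], np.array([100.0, 400.0]))) \
            == [0, 1]
        with pytest.raises(ParameterError):
            tc.collapse_to_binary(np.zeros(4, int), f8)

    def test_missing_class_in_fold_rejected(self):
        labels = np.array([0] * 10 + [1] * 3)
        with pytest.raises(ParameterError):
            stratified_contiguous_folds(labels, 5)

    def test_deterministic_given_inputs(self, noisy_series):
        pre = tc.preprocess_timeseries(noisy_series)
        nbh = tc.sphere_neighborhoods(noisy_series.brain_mask,
                                      noisy_series.voxel_size_mm, 2.0)
        a = tc.searchlight_accuracy(pre, nbh)
        b = tc.searchlight_accuracy(pre, nbh)
        assert np.array_equal(a.accuracy, b.accuracy, equal_nan=True)


class TestAccuracyToZ:
    def test_chance_maps_to_zero(self):
        assert tc.accuracy_to_z(0.125, 160, 0.125) == pytest.approx(0.0)

    def test_closed_form_value(self):
        z = tc.accuracy_to_z(0.25, 160, 0.125)
        assert z == pytest.approx(20.0 / np.sqrt(17.5))
        assert z == pytest.approx(4.781, abs=1e-3)

    def test_threshold_quantile(self):
        from scipy import stats

        assert tc.z_threshold(0.01) == pytest.approx(stats.norm.ppf(0.99))
        assert tc.z_threshold(0.01) == pytest.approx(2.326, abs=1e-3)

    def test_zero_trials_rejected(self):
        with pytest.raises(ParameterError):
            tc.accuracy_to_z(0.5, 0, 0.125)


class TestClusterThreshold:
    def test_subthreshold_map_gives_empty_mask(self):
        z = np.zeros((10, 10, 3))
        cm = tc.cluster_threshold(z, 2.326, null_spec={"n_perm": 200}, seed=0)
        assert not cm.mask.any()

    def test_large_block_retained_intact(self):
        z = np.zeros((12, 12, 3))
        z[2:10, 2:10, 1] = 5.0
        cm = tc.cluster_threshold(z, 2.326, null_spec={"n_perm": 200}, seed=1)
        assert cm.mask.sum() == 64
        assert cm.mask[2:10, 2:10, 1].all()

    def test_monotone_in_z_star(self):
        """At a fixed cluster-size rule, raising z* never adds voxels."""
        rng = np.random.default_rng(2)
        z = rng.standard_normal((16, 16, 3)) * 2.0
        masks = []
        for zs in (1.5, 2.0, 2.5, 3.0):
            cm = tc.cluster_threshold(z, zs, fixed_size_threshold=2)
            masks.append(cm.mask)
        for lo, hi in zip(masks[1:], masks[:-1]):
            assert not np.any(lo & ~hi)

    def test_few_permutations_warn(self):
        with pytest.warns(UserWarning):
            tc.cluster_threshold(np.zeros((5, 5, 2)), 2.0,
                                 null_spec={"n_perm": 50}, seed=0)

    def test_family_wise_error_calibrated(self):
        """Smoothed Gaussian null fields: the fraction of 200 fresh null maps
        with any surviving cluster matches the procedure's achieved alpha and
        does not exceed the nominal 5% (plus binomial noise)."""
        shape = (24, 24, 3)
        spec = {"n_perm": 600, "smooth_fwhm_vox": 2.0}
        cm = tc.cluster_threshold(np.zeros(shape), 2.326, 0.05, spec, seed=10)
        from scipy import ndimage

        rng = np.random.default_rng(11)
        hits = 0
        n_sim = 200
        struct = ndimage.generate_binary_structure(3, 1)
        for _ in range(n_sim):
            null = ndimage.gaussian_filter(rng.standard_normal(shape),
                                           sigma=2.0 / 2.3548)
            null /= null.std()
            lab, n = ndimage.label(null > 2.326, structure=struct)
            if n and np.bincount(lab.ravel())[1:].max() > cm.cluster_size_threshold:
                hits += 1
        fwer = hits / n_sim
        se = np.sqrt(0.05 * 0.95 / n_sim)
        assert fwer <= 0.05 + 3 * se
        se_match = np.sqrt(max(cm.achieved_alpha, 1e-3) / n_sim) + \
            np.sqrt(max(cm.achieved_alpha, 1e-3) / cm.n_perm)
        assert abs(fwer - cm.achieved_alpha) <= 3 * se_match + 1e-9


class TestMaskUtilities:
    def test_identical_masks(self):
        m = np.zeros((6, 6, 2), bool)
        m[1:4, 1:4, 0] = True
        assert tc.region_overlap(m, m) == pytest.approx(100.0)
        assert tc.centroid_distance(m, m, (1.5, 1.5, 2.5)) == pytest.approx(0.0)

    def test_disjoint_masks(self):
        a = np.zeros((6, 6, 1), bool)
        b = np.zeros((6, 6, 1), bool)
        a[0, 0, 0] = True
        b[5, 5, 0] = True
        assert tc.region_overlap(a, b) == 0.0

    def test_half_shared_equal_masks_give_dice_50(self):
        a = np.zeros((8, 8, 1), bool)
        b = np.zeros((8, 8, 1), bool)
        a[0, 0:4, 0] = True
        b[0, 2:6, 0] = True
        assert tc.region_overlap(a, b) == pytest.approx(50.0)

    def test_centroid_distance_in_mm(self):
        a = np.zeros((10, 10, 3), bool)
        b = np.zeros((10, 10, 3), bool)
        a[2, 2, 1] = True
        b[2, 6, 1] = True
        d = tc.centroid_distance(a, b, (1.5, 1.5, 2.5))
        assert d == pytest.approx(4 * 1.5)

    def test_probability_map(self):
        m1 = np.zeros((4, 4, 1), bool)
        m1[0, 0, 0] = True
        m2 = m1.copy()
        m3 = np.zeros((4, 4, 1), bool)
        m3[1, 1, 0] = True
        pm = tc.probability_map([m1, m2, m3])
        assert pm.max() == 2
        assert pm[0, 0, 0] == 2 and pm[1, 1, 0] == 1
        assert tc.probability_map([m1]).max() == 1
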