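import math

import numpy as np
import pytest
from scipy import stats

import tonocore as tc
from tonocore.exceptions import ParameterError
from tonocore.gradients import nan_gaussian_smooth

from conftest import mirror_wedge, tilted_mirror


class TestSignMap:
    def test_uniform_map_all_zero(self):
        s, d = tc.directional_sign_map(np.full((10, 10), 3.0), 45.0)
        assert np.all(s == 0)

    def test_ramp_along_x(self):
        bf = np.tile(np.arange(10.0), (10, 1))
        s, d = tc.directional_sign_map(bf, 0.0)
        assert np.all(s[d] == 1)
        s2, d2 = tc.directional_sign_map(-bf, 0.0)
        assert np.all(s2[d2] == -1)

    def test_orthogonal_sampling_gives_zero(self):
        bf = np.tile(np.arange(10.0), (10, 1))
        s, d = tc.directional_sign_map(bf, 90.0)
        assert np.all(s[d] == 0)

    def test_invalid_cells_masked_out(self):
        bf = np.tile(np.arange(10.0), (10, 1))
        bf[4, 4] = np.nan
        s, d = tc.directional_sign_map(bf, 0.0)
        assert not d[4, 4] and not d[4, 3] and not d[4, 5]

    def test_bad_theta_rejected(self):
        with pytest.raises(ParameterError):
            tc.directional_sign_map(np.zeros((5, 5)), 180.0)


class TestEdgeMap:
    def test_all_positive_no_edges(self):
        assert not tc.edge_map(np.ones((6, 6), np.int8)).any()

    def test_half_plane_opposition_marks_flanking_columns(self):
        s = np.ones((6, 6), np.int8)
        s[:, 3:] = -1
        e = tc.edge_map(s)
        assert e[:, 2].all() and e[:, 3].all()
        assert not e[:, :2].any() and not e[:, 4:].any()

    def test_zero_stripe_blocks_edges(self):
        s = np.ones((6, 9), np.int8)
        s[:, 3:6] = 0
        s[:, 6:] = -1
        assert not tc.edge_map(s).any()


class TestComposite:
    def test_uniform_map_composite_zero(self):
        cm = tc.composite_edge_map(np.full((8, 8), 2.0), keep_stack=False)
        assert not cm.composite.any()

    def test_mirror_reversal_reaches_179(self):
        cm = tc.composite_edge_map(tilted_mirror(0.0), keep_stack=False)
        assert cm.composite.max() == 179
        # flagged only at the two crease-flanking columns
        cols = np.unique(np.argwhere(cm.composite > 170)[:, 1])
        assert set(cols) == {14, 15}

    @pytest.mark.parametrize("alpha", [30, 60, 90, 120, 150])
    def test_composite_equals_inter_gradient_angle(self, alpha):
        """Brute-force sweep on an analytic wedge: the composite value at the
        crease equals the planted angle between the two gradients within the
        1-degree sweep discretisation (+/- 2 deg)."""
        cm = tc.composite_edge_map(mirror_wedge(alpha), keep_stack=False)
        mid = cm.composite[5:-5, cm.composite.shape[1] // 2]
        assert abs(np.median(mid) - alpha) <= 2

    def test_mirror_is_180_case(self):
        cm = tc.composite_edge_map(tilted_mirror(0.0), keep_stack=False)
        ridge = cm.composite[5:-5, 14]
        assert abs(np.median(ridge) - 180) <= 2

    def test_composite_bounded_by_orientation_count(self):
        rng = np.random.default_rng(0)
        cm = tc.composite_edge_map(rng.normal(size=(12, 12)), keep_stack=False)
        assert cm.composite.min() >= 0 and cm.composite.max() <= 180


class TestBorders:
    def test_planted_mirror_border_recovered_within_one_cell(self):
        for phi in range(0, 91, 15):
            bf = tilted_mirror(float(phi))
            cm = tc.composite_edge_map(bf, keep_stack=False)
            borders = tc.extract_borders(cm, bf, np.ones(bf.shape, bool),
                                         stability_min=60)
            assert borders, f"no border found at phi={phi}"
            det = np.concatenate([np.array(b.cells) for b in borders])
            x = (np.arange(31) - 15)[None, :]
            y = (np.arange(31) - 15)[:, None]
            u = x * math.cos(math.radians(phi)) + \
                y * math.sin(math.radians(phi)) + 0.5001
            planted = np.argwhere(np.abs(u) <= 0.5)
            dists = [np.abs(det - p).max(axis=1).min() for p in planted]
            assert np.mean(np.asarray(dists) <= 1) >= 0.95

    def test_two_field_layout_gives_single_low_border(self):
        lay = tc.make_field_layout((21, 21))
        bf = np.log2(lay.bf_truth)
        cm = tc.composite_edge_map(bf)
        borders = tc.extract_borders(cm, bf, lay.tuned_mask, 60,
                                     f_range_hz=(lay.f_lo, lay.f_hi))
        assert len(borders) == 1
        assert borders[0].frequency_class == "low"

    def test_caudal_field_adds_high_border(self):
        lay = tc.make_field_layout((21, 29), {"n_fields": 3})
        bf = np.log2(lay.bf_truth)
        cm = tc.composite_edge_map(bf)
        borders = tc.extract_borders(cm, bf, lay.tuned_mask, 60,
                                     f_range_hz=(lay.f_lo, lay.f_hi))
        assert sorted(b.frequency_class for b in borders) == ["high", "low"]

    def test_single_gradient_yields_no_borders(self):
        lay = tc.make_field_layout((21, 21), {"n_fields": 1})
        bf = np.log2(lay.bf_truth)
        cm = tc.composite_edge_map(bf)
        assert tc.extract_borders(cm, bf, lay.tuned_mask, 60) == []

    def test_min_cells_filters_speckle(self):
        comp = np.zeros((10, 10), int)
        comp[2, 2] = 170                       # isolated speckle
        comp[5, 1:9] = 170                     # 8-cell path
        cm = tc.CompositeEdgeMap(comp, np.arange(180.0))
        bf = np.zeros((10, 10))
        out = tc.extract_borders(cm, bf, np.ones((10, 10), bool), 60,
                                 min_cells=5)
        assert len(out) == 1 and out[0].n_cells == 8


class TestBorderAngle:
    def test_border_perpendicular_to_reference_axis(self):
        bf = tilted_mirror(0.0)
        cm = tc.composite_edge_map(bf)
        interior = np.zeros(bf.shape, bool)
        interior[1:-1, 1:-1] = True
        ang = tc.border_angle(cm.edge_stack, cm.composite, region=interior)
        assert ang == pytest.approx(90.0, abs=1.0)

    def test_rotation_shifts_angle(self):
        bf = tilted_mirror(30.0)
        cm = tc.composite_edge_map(bf)
        interior = np.zeros(bf.shape, bool)
        interior[1:-1, 1:-1] = True
        ang = tc.border_angle(cm.edge_stack, cm.composite, region=interior)
        assert ang == pytest.approx(60.0, abs=1.0)

    def test_quarter_turn_equivariance(self):
        bf = tilted_mirror(0.0)
        cm = tc.composite_edge_map(bf)
        bf90 = np.rot90(bf)
        cm90 = tc.composite_edge_map(bf90)
        interior = np.zeros(bf.shape, bool)
        interior[1:-1, 1:-1] = True
        a0 = tc.border_angle(cm.edge_stack, cm.composite, region=interior)
        a90 = tc.border_angle(cm90.edge_stack, cm90.composite, region=interior)
        assert tc.fold_axial(a0 - a90) == pytest.approx(90.0, abs=1.0)

    def test_tied_orientations_use_axial_mean(self):
        """Documented tie rule: the representative orientation of an exactly
        tied set is its axial circular mean."""
        stack = np.zeros((180, 5, 5), dtype=bool)
        stack[40, :, 2] = True
        stack[60, :, 2] = True
        comp = stack.sum(axis=0)
        ang = tc.border_angle(stack, comp)
        assert ang == pytest.approx(tc.fold_axial(90.0 - 50.0))

    def test_empty_stack_rejected(self):
        stack = np.zeros((180, 4, 4), dtype=bool)
        with pytest.raises(ParameterError):
            tc.border_angle(stack, stack.sum(axis=0))


class TestDirectionStats:
    def test_uniform_ramp_at_30_degrees(self):
        x = np.arange(20.0)[None, :]
        y = np.arange(20.0)[:, None]
        bf = x * math.cos(math.radians(30)) + y * math.sin(math.radians(30))
        ds = tc.gradient_directions(bf, np.ones(bf.shape, bool), 0.0,
                                    n_boot=500, seed=0)
        assert ds.mean_deg == pytest.approx(30.0, abs=0.5)
        assert ds.ci95[1] - ds.ci95[0] < 1.0
        assert np.allclose(ds.directions, 30.0, atol=0.5)

    def test_axial_mean_of_10_and_170_is_zero(self):
        """{10 deg, 170 deg (= -10)} average to 0 under doubled angles."""
        from tonocore.gradients import _axial_mean

        assert tc.fold_axial(_axial_mean(np.array([10.0, 170.0]))) \
            == pytest.approx(0.0, abs=1e-9)

    def test_ramp_parallel_to_axis_gives_zero(self):
        bf = np.tile(np.arange(20.0), (20, 1))
        ds = tc.gradient_directions(bf, np.ones(bf.shape, bool), 0.0,
                                    n_boot=500, seed=1)
        assert ds.mean_deg == pytest.approx(0.0, abs=1e-6)

    def test_histogram_counts_sum_to_n(self):
        rng = np.random.default_rng(2)
        bf = rng.normal(size=(15, 15)).cumsum(axis=1)
        ds = tc.gradient_directions(bf, np.ones(bf.shape, bool), 0.0,
                                    n_boot=200, seed=3)
        assert ds.hist_counts.sum() == ds.n

    def test_too_small_region_rejected(self):
        with pytest.raises(ParameterError):
            tc.gradient_directions(np.zeros((3, 3)), np.ones((3, 3), bool))


class TestProportionBootstrap:
    def test_exact_binomial_anchor(self):
        """19 of 26 below the midpoint: exact tail P(X >= 19 | n=26, p=.5)
        = 971712 / 2^26 ~ 0.01448 (enumeration oracle); the bootstrap
        estimate must land within 3 SE."""
        exact = sum(math.comb(26, k) for k in range(19, 27)) / 2 ** 26
        assert exact == pytest.approx(971712 / 2 ** 26)
        est = tc.proportion_bootstrap(26, 19, 45.0, (0.0, 90.0), 100_000,
                                      seed=12)
        se = math.sqrt(exact * (1 - exact) / 100_000)
        assert abs(est - exact) <= 3 * se

    def test_zero_below_gives_certainty(self):
        assert tc.proportion_bootstrap(26, 0, 45.0, B=2000, seed=0) == 1.0

    def test_all_below_is_practically_never(self):
        assert tc.proportion_bootstrap(26, 26, 45.0, B=100_000, seed=1) == 0.0

    def test_preconditions(self):
        with pytest.raises(ParameterError):
            tc.proportion_bootstrap(10, 11, 45.0)
        with pytest.raises(ParameterError):
            tc.proportion_bootstrap(10, 5, 45.0, B=10)


class TestRobustness:
    def test_quarter_turn_pipeline_equivariance(self):
        """Rotating the best-frequency map by 90 deg rotates the detected
        border cells with it."""
        bf = tilted_mirror(20.0)
        core = np.ones(bf.shape, bool)
        det = tc.GradientReversalDetector(seed=0).fit(bf, core)
        det90 = tc.GradientReversalDetector(seed=0).fit(np.rot90(bf), core)
        cells = {(30 - c, r) for r, c in det.borders_[0].cells}  # rot90 map
        cells90 = {tuple(c) for c in det90.borders_[0].cells}
        overlap = len(cells & cells90) / len(cells | cells90)
        assert overlap > 0.9

    def test_recovery_distance_degrades_monotonically_with_noise(self):
        """Mean symmetric distance between planted and detected borders is
        non-decreasing in best-frequency noise (trend over 5 levels x 20
        seeds, Spearman on level means)."""
        bf0 = tilted_mirror(0.0, n=25)
        planted = np.argwhere(
            np.abs(((np.arange(25) - 12)[None, :] + 0.5001)
                   * np.ones((25, 1))) <= 0.5)
        levels = [0.0, 0.05, 0.1, 0.2, 0.4]
        means = []
        for sd in levels:
            dists = []
            for seed in range(20):
                rng = np.random.default_rng(1000 + seed)
                bf = bf0 + rng.normal(scale=sd * bf0.std(), size=bf0.shape)
                bf = nan_gaussian_smooth(bf, 1.0)
                cm = tc.composite_edge_map(bf, keep_stack=False)
                borders = tc.extract_borders(cm, bf, np.ones(bf.shape, bool),
                                             stability_min=60)
                if not borders:
                    dists.append(12.0)
                    continue
                det = np.concatenate([np.array(b.cells) for b in borders])
                d1 = np.mean([np.linalg.norm(det - p, axis=1).min()
                              for p in planted])
                d2 = np.mean([np.linalg.norm(planted - q, axis=1).min()
                              for q in det])
                dists.append(0.5 * (d1 + d2))
            means.append(np.mean(dists))
        rho, p = stats.spearmanr(levels, means)
        assert rho > 0
        assert means[-1] > means[0]
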