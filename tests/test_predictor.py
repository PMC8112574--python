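"""Discretization schemes, loss functions, polar composition, input
truncation/padding, and model-spec bookkeeping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from saccland.predictor import (DiscretizationScheme, LandingPointModel,
                                ModelSpec, PredictorEnsemble,
                                compose_from_polar, discretize_landing,
                                discretize_scalar, euclidean_error, loss_l1,
                                loss_l2, loss_l3, truncate_pad,
                                undiscretize_landing, undiscretize_scalar)
from saccland.trace import Saccade, ScreenGeometry

SCREEN = ScreenGeometry()
SCHEME = DiscretizationScheme()


class TestTruncatePad:
    def test_long_trajectory_truncated(self):
        traj = np.arange(24).reshape(12, 2).astype(float)
        out = truncate_pad(traj, 10)
        np.testing.assert_array_equal(out, traj[:10])

    def test_short_trajectory_zero_padded(self):
        traj = np.ones((8, 2))
        out = truncate_pad(traj, 10)
        np.testing.assert_array_equal(out[:8], traj)
        np.testing.assert_array_equal(out[8:], 0.0)

    def test_exact_length_identity(self):
        traj = np.random.default_rng(0).normal(size=(10, 2))
        np.testing.assert_array_equal(truncate_pad(traj, 10), traj)


class TestLandingGrid:
    def test_corner_cells(self):
        assert discretize_landing((-16.5, -9.5), SCREEN) == 0
        assert discretize_landing((16.5, 9.5), SCREEN) == 63

    def test_screen_centre_cell(self):
        # floor((0 + 16.5) / 4.125) = 4 on both axes -> row 4, col 4 -> 36
        assert discretize_landing((0.0, 0.0), SCREEN) == 36

    def test_off_screen_clamps_to_edge(self):
        assert discretize_landing((-100.0, -100.0), SCREEN) == 0
        assert discretize_landing((100.0, 0.1), SCREEN) == 4 * 8 + 7

    def test_matches_brute_force_nearest_centre(self):
        centres = np.array(
            [undiscretize_landing(i, SCREEN) for i in range(64)]
        )
        xs = np.linspace(-16.3, 16.3, 40)
        ys = np.linspace(-9.3, 9.3, 40)
        for x in xs:
            for y in ys:
                d2 = np.sum((centres - (x, y)) ** 2, axis=1)
                assert discretize_landing((x, y), SCREEN) == int(np.argmin(d2))

    def test_first_cell_centre_closed_form(self):
        cx, cy = undiscretize_landing(0, SCREEN)
        assert cx == pytest.approx(-16.5 + 4.125 / 2)
        assert cy == pytest.approx(-9.5 + 2.375 / 2)

    def test_round_trip_on_centres_is_identity(self):
        for i in range(64):
            assert discretize_landing(undiscretize_landing(i, SCREEN), SCREEN) == i

    def test_round_trip_error_bounded_by_half_diagonal(self):
        bound = math.hypot(33 / 8, 19 / 8) / 2
        rng = np.random.default_rng(1)
        for _ in range(500):
            p = (rng.uniform(-16.5, 16.5), rng.uniform(-9.5, 9.5))
            q = undiscretize_landing(discretize_landing(p, SCREEN), SCREEN)
            assert euclidean_error(p, q) <= bound + 1e-12

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ValueError):
            undiscretize_landing(64, SCREEN)


class TestScalarBins:
    def test_range_endpoints(self):
        assert discretize_scalar(0.1, 0.1, 40.0) == 0
        assert discretize_scalar(40.0, 0.1, 40.0) == 31

    def test_exact_midpoint_takes_lower_index(self):
        # (20.05 - 0.1) / ((40 - 0.1)/31) = 15.5 exactly
        assert discretize_scalar(20.05, 0.1, 40.0) == 15

    def test_clamping_outside_range(self):
        assert discretize_scalar(-5.0, 0.1, 40.0) == 0
        assert discretize_scalar(90.0, 0.1, 40.0) == 31

    def test_matches_brute_force_nearest_value(self):
        values = np.array([undiscretize_scalar(k, 0.1, 40.0) for k in range(32)])
        rng = np.random.default_rng(2)
        for _ in range(500):
            v = rng.uniform(-1.0, 42.0)
            dist = np.abs(values - v)
            # ties broken toward the lower index == first argmin
            assert discretize_scalar(v, 0.1, 40.0) == int(np.argmin(dist))

    def test_bin_spacing(self):
        assert SCHEME.disp_spacing == pytest.approx((40 - 0.1) / 31)
        assert SCHEME.angle_spacing == pytest.approx(math.pi / 31)


class TestLosses:
    def test_euclidean_error_cases(self):
        assert euclidean_error((0, 0), (3, 4)) == 5.0
        assert euclidean_error((1, 2), (1, 2)) == 0.0
        assert euclidean_error((0, 0), (3, 4)) == euclidean_error((3, 4), (0, 0))

    def test_cross_entropy_one_hot_is_zero(self):
        probs = np.zeros(64)
        probs[17] = 1.0
        assert loss_l2(probs, 17) == 0.0

    def test_cross_entropy_uniform_64(self):
        assert loss_l2(np.full(64, 1 / 64), 5) == pytest.approx(math.log(64))

    def test_cross_entropy_floor(self):
        probs = np.zeros(64)
        probs[0] = 1.0
        assert loss_l2(probs, 3) == pytest.approx(-math.log(1e-12))

    def test_cross_entropy_length_check(self):
        with pytest.raises(ValueError):
            loss_l2(np.full(32, 1 / 32), 3, n_classes=64)

    def test_combined_loss_arithmetic(self):
        # L1 = 5 (3-4-5), L2 = 2 -> L3 = 5 + 0.7 * 2 = 6.4
        probs = np.zeros(64)
        probs[9] = math.exp(-2.0)
        probs[10] = 1.0 - probs[9]
        assert loss_l3((0, 0), (3, 4), probs, 9) == pytest.approx(6.4)

    def test_beta_zero_reduces_to_l1(self):
        probs = np.full(64, 1 / 64)
        assert loss_l3((0, 0), (3, 4), probs, 0, beta=0.0) == 5.0

    @settings(derandomize=True, max_examples=200)
    @given(st.integers(0, 2**31 - 1))
    def test_combination_identity_random_components(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(-16, 16, 2)
        t = rng.uniform(-16, 16, 2)
        probs = rng.dirichlet(np.ones(64))
        k = int(rng.integers(64))
        expected = loss_l1(p, t) + 0.7 * loss_l2(probs, k)
        assert loss_l3(p, t, probs, k) == pytest.approx(expected, rel=1e-12)


class TestPolarComposition:
    @pytest.mark.parametrize("start,d,alpha,expected", [
        ((0, 0), 5, 0, (5, 0)),
        ((0, 0), 5, math.pi / 2, (0, 5)),
        ((1, 1), math.sqrt(2), math.pi / 4, (2, 2)),
    ])
    def test_closed_forms(self, start, d, alpha, expected):
        out = compose_from_polar(start[0], start[1], d, alpha)
        assert out == pytest.approx(expected)

    def test_negative_displacement_rejected(self):
        with pytest.raises(ValueError):
            compose_from_polar(0, 0, -1, 0)


def _toy_saccade(duration: int, pid: str = "p0") -> Saccade:
    t = np.linspace(0.0, 1.0, duration + 1)
    traj = np.column_stack([-3.0 + 6.0 * t, 1.0 + 2.0 * t])
    return Saccade(trajectory=traj, participant_id=pid)


@pytest.fixture(scope="module")
def mini_ensemble():
    """Six-horizon ensemble trained for a single epoch on toy data — only
    the dispatch logic matters here, not accuracy."""
    train = [_toy_saccade(d) for d in (20, 30, 40, 50)] * 8
    model = LandingPointModel(train, target="coordinates", loss="l1",
                              units=(32, 32))
    return model.fit(seed=0, epochs=1).ensemble


class TestHorizonDispatch:
    def test_exactly_ten_samples_uses_first_horizon(self, mini_ensemble):
        pred = mini_ensemble.predict(_toy_saccade(40).trajectory[:10])
        assert pred.horizon_used == 10 and pred.elapsed_ms == 10

    def test_largest_horizon_not_exceeding_data(self, mini_ensemble):
        pred = mini_ensemble.predict(_toy_saccade(40).trajectory[:23])
        assert pred.horizon_used == 20

    def test_long_input_capped_at_35(self, mini_ensemble):
        pred = mini_ensemble.predict(_toy_saccade(60).trajectory)
        assert pred.horizon_used == 35

    def test_under_ten_samples_no_prediction(self, mini_ensemble):
        assert mini_ensemble.predict(_toy_saccade(40).trajectory[:9]) is None

    def test_inflight_schedule_34ms(self, mini_ensemble):
        preds = mini_ensemble.inflight(_toy_saccade(34))
        assert [p.elapsed_ms for p in preds] == [10, 15, 20, 25, 30]

    def test_inflight_schedule_12ms(self, mini_ensemble):
        preds = mini_ensemble.inflight(_toy_saccade(12))
        assert [p.elapsed_ms for p in preds] == [10]

    def test_ensemble_requires_all_six_horizons(self, mini_ensemble):
        partial = {n: m for n, m in mini_ensemble.models.items() if n != 35}
        with pytest.raises(ValueError):
            PredictorEnsemble(partial)


class TestModelSpec:
    def test_head_widths_follow_target(self):
        assert ModelSpec(target="coordinates", horizon=10).g1 == 2
        assert ModelSpec(target="coordinates", horizon=10).g2 == 64
        assert ModelSpec(target="angle", horizon=10).g1 == 1
        assert ModelSpec(target="displacement", horizon=10).g2 == 32

    def test_invalid_horizon_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(horizon=12)

    def test_bidirectional_not_supported(self):
        with pytest.raises(NotImplementedError):
            ModelSpec(horizon=10, bidirectional=True)
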