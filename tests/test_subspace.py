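import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perchsense.exceptions import InvalidArgumentError, UndefinedVafError
from perchsense.subspace import (
    MOESP,
    _stabilize,
    block_hankel,
    estimate_foot_acc,
    markov_parameters,
    predict,
    select_order,
    vaf,
)
from tests.conftest import random_stable_system, simulate_lti


class TestBlockHankel:
    def test_scalar_hand_case(self):
        assert np.array_equal(
            block_hankel(np.array([1.0, 2, 3, 4]), 2), [[1, 2, 3], [2, 3, 4]]
        )

    def test_single_block_row_is_data_matrix(self):
        x = np.arange(12.0).reshape(6, 2)
        assert np.array_equal(block_hankel(x, 1), x.T)

    def test_two_channel_structure_matches_index_construction(self):
        x = np.arange(12.0).reshape(6, 2)
        h = block_hankel(x, 3)
        assert h.shape == (6, 4)
        for i in range(3):  # block row
            for c in range(2):  # channel within block
                for j in range(4):  # column (time shift)
                    assert h[i * 2 + c, j] == x[i + j, c]

    def test_too_short_series_rejected(self):
        with pytest.raises(InvalidArgumentError):
            block_hankel(np.zeros(3), 5)


class TestMoespFit:
    def test_siso_pole_recovery(self):
        rng = np.random.default_rng(0)
        u = rng.standard_normal((4000, 1))
        A, B, C, D = np.array([[0.9]]), np.array([[1.0]]), np.array([[1.0]]), np.array([[0.0]])
        y = simulate_lti(A, B, C, D, u)
        res = MOESP(u, y, order=1, s=10).fit()
        assert abs(res.eigenvalues[0] - 0.9) < 1e-6
        assert res.vaf() > 99.99

    @pytest.mark.parametrize("seed", range(5))
    def test_mimo_markov_parameter_recovery(self, seed):
        rng = np.random.default_rng(seed)
        A, B, C, D = random_stable_system(rng, 3, 3, 3)
        u = rng.standard_normal((4000, 3))
        y = simulate_lti(A, B, C, D, u)
        res = MOESP(u, y, order=3, s=10).fit()
        true = markov_parameters(A, B, C, D, 20)
        est = res.markov(20)
        scale = max(np.abs(M).max() for M in true)
        err = max(np.abs(a - b).max() for a, b in zip(true, est)) / scale
        assert err < 1e-6

    def test_zero_output_gives_zero_model(self):
        rng = np.random.default_rng(1)
        u = rng.standard_normal((2000, 2))
        y = np.zeros((2000, 2))
        res = MOESP(u, y, order=2, s=6).fit()
        assert np.abs(res.B).max() < 1e-8
        assert np.abs(res.fittedvalues).max() < 1e-8

    def test_preconditions(self):
        u = np.zeros((100, 1))
        with pytest.raises(InvalidArgumentError):
            MOESP(u, np.zeros((99, 1)))
        with pytest.raises(InvalidArgumentError):
            MOESP(u, np.zeros((100, 1)), order=3, s=3)  # s < order+1
        with pytest.raises(InvalidArgumentError):
            MOESP(np.zeros((30, 1)), np.zeros((30, 1)), order=1, s=10)  # too short

    def test_fit_is_deterministic(self):
        rng = np.random.default_rng(2)
        A, B, C, D = random_stable_system(rng, 3, 1, 1)
        u = rng.standard_normal((1000, 1))
        y = simulate_lti(A, B, C, D, u) + 0.01 * rng.standard_normal((1000, 1))
        m1 = MOESP(u, y, order=3, s=10).fit()
        m2 = MOESP(u, y, order=3, s=10).fit()
        assert all(np.array_equal(a, b) for a, b in zip(m1.markov(10), m2.markov(10)))

    def test_stabilize_leaves_stable_untouched_and_caps_unstable(self):
        rng = np.random.default_rng(3)
        A, *_ = random_stable_system(rng, 3, 1, 1, rho=0.7)
        assert np.array_equal(_stabilize(A), A)
        A_bad = A * (1.2 / 0.7)
        rho = np.max(np.abs(np.linalg.eigvals(_stabilize(A_bad))))
        assert rho < 1.0


class TestSelectOrder:
    def test_clear_gap(self):
        assert select_order(np.array([10, 5, 2, 1e-9, 1e-10])) == 3

    def test_noiseless_system_rank(self):
        rng = np.random.default_rng(4)
        A, B, C, D = random_stable_system(rng, 3, 3, 3)
        u = rng.standard_normal((4000, 3))
        y = simulate_lti(A, B, C, D, u)
        res = MOESP(u, y, order=3, s=10).fit()
        assert select_order(res.sv) == 3

    def test_fixed_criterion_ignores_spectrum(self):
        assert select_order(np.array([5.0, 4.9, 4.8]), criterion="fixed:3") == 3


class TestPredict:
    def test_feedthrough_only_is_identity(self):
        class M:
            A = np.zeros((1, 1))
            B = np.zeros((1, 2))
            C = np.zeros((2, 1))
            D = np.eye(2)

        u = np.random.default_rng(5).standard_normal((100, 2))
        assert np.allclose(predict(M, u), u)

    def test_zero_input_zero_state_is_silent(self):
        rng = np.random.default_rng(6)
        A, B, C, D = random_stable_system(rng, 3, 2, 2)

        class M:
            pass

        M.A, M.B, M.C, M.D = A, B, C, D
        assert np.all(predict(M, np.zeros((50, 2))) == 0)

    def test_impulse_response_equals_markov_parameters(self):
        rng = np.random.default_rng(7)
        A, B, C, D = random_stable_system(rng, 3, 1, 2)

        class M:
            pass

        M.A, M.B, M.C, M.D = A, B, C, D
        u = np.zeros((10, 1))
        u[0] = 1.0
        y = predict(M, u)
        mk = markov_parameters(A, B, C, D, 10)
        for k in range(10):
            assert np.allclose(y[k], mk[k][:, 0], atol=1e-10)

    def test_modal_path_matches_brute_force(self):
        rng = np.random.default_rng(8)
        A, B, C, D = random_stable_system(rng, 4, 2, 3, rho=0.95)

        class M:
            pass

        M.A, M.B, M.C, M.D = A, B, C, D
        u = rng.standard_normal((300, 2))
        x0 = rng.standard_normal(4)
        assert np.allclose(predict(M, u, x0), simulate_lti(A, B, C, D, u, x0), atol=1e-9)

    def test_channel_mismatch_rejected(self):
        class M:
            A = np.zeros((1, 1))
            B = np.zeros((1, 2))
            C = np.zeros((1, 1))
            D = np.zeros((1, 2))

        with pytest.raises(InvalidArgumentError):
            predict(M, np.zeros((10, 3)))


class TestVaf:
    def test_perfect_prediction_is_100(self):
        y = np.random.default_rng(9).standard_normal((50, 3))
        assert vaf(y, y) == 100.0

    def test_zero_prediction_is_0(self):
        y = np.random.default_rng(10).standard_normal(50)
        assert vaf(np.zeros(50), y) == pytest.approx(0.0, abs=1e-12)

    def test_hand_case_matches_brute_force(self):
        y = np.array([1.0, 2, 3, 4])
        y_hat = np.array([1.0, 2, 3, 5])
        err = y_hat - y
        expected = 100 * (1 - np.mean((err - err.mean()) ** 2) / np.mean((y - y.mean()) ** 2))
        assert vaf(y_hat, y) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(85.0)

    @settings(max_examples=25, derandomize=True)
    @given(st.floats(min_value=0.1, max_value=1e6), st.integers(0, 100))
    def test_scale_invariance(self, a, seed):
        rng = np.random.default_rng(seed)
        y = rng.standard_normal(40)
        y_hat = y + 0.3 * rng.standard_normal(40)
        assert vaf(a * y_hat, a * y) == pytest.approx(vaf(y_hat, y), rel=1e-9)
        assert vaf(a * y, a * y) == 100.0

    def test_constant_reference_rejected(self):
        with pytest.raises(UndefinedVafError):
            vaf(np.zeros(10), np.ones(10))


class TestEstimateFootAcc:
    def test_duplicated_fusion_channels_add_nothing(self, recording):
        dup = dataclasses.replace(recording, head=recording.hip.copy())
        hip = estimate_foot_acc(recording, "hip", window=(0, 20), train_samples=4000)
        fus = estimate_foot_acc(dup, "fusion", window=(0, 20), train_samples=4000)
        assert abs(fus.pooled_vaf - hip.pooled_vaf) < 0.1

    def test_noiseless_full_order_fit_is_near_perfect(self, noiseless_recording):
        # per axis the chain has 4 states; 3 axes -> order 12 captures it
        res = estimate_foot_acc(noiseless_recording, "hip", order=12, s=30, window=(0, 30))
        assert res.pooled_vaf > 99.0

    def test_hip_beats_head_on_synthetic_data(self, recording):
        hip = estimate_foot_acc(recording, "hip", window=(0, 40), train_samples=4000, held_out=True)
        head = estimate_foot_acc(recording, "head", window=(0, 40), train_samples=4000, held_out=True)
        assert hip.pooled_vaf > head.pooled_vaf

    def test_unknown_source_rejected(self, recording):
        with pytest.raises(InvalidArgumentError):
            estimate_foot_acc(recording, "knee")


def test_noise_degradation_is_monotone(cfg):
    """Median VAF must not increase as sensor noise grows (5-point grid,
    20 seeds per point)."""
    from perchsense.mechanics import add_sensor_noise, run_trial

    grid = [0.0, 0.05, 0.15, 0.4, 1.0]
    medians = []
    clean = {
        seed: run_trial(radius_m=0.01, neck_preset="low", n_moves=30, seed=seed, config=cfg)
        for seed in range(20)
    }
    import dataclasses as dc

    for sd in grid:
        vals = []
        for seed, rec in clean.items():
            nl = rec.meta["noiseless"]
            base = dc.replace(rec, foot=nl["foot"], hip=nl["hip"], head=nl["head"])
            noisy = add_sensor_noise(base, sd, seed=1000 + seed)
            vals.append(
                estimate_foot_acc(noisy, "hip", window=(0, 10), train_samples=4000).pooled_vaf
            )
        medians.append(np.median(vals))
    assert all(a >= b - 1e-9 for a, b in zip(medians, medians[1:]))
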