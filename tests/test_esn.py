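import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import sparse

from modular_esn import (
    ActivationParams,
    InputProjection,
    Readout,
    Reservoir,
    Trajectory,
    activation,
    build_input_weights,
    load_reservoir,
    readout_output,
    run_reservoir,
    save_reservoir,
    step_state,
    train_readout,
)

THRESHOLD = ActivationParams.threshold()


class TestActivation:
    def test_midpoint_value(self):
        """At z = c the sigmoid sits exactly halfway (a = b = 1, d = 0)."""
        assert activation(1.0, THRESHOLD) == pytest.approx(0.5, abs=1e-15)

    def test_zero_input_value(self):
        assert activation(0.0, THRESHOLD) == pytest.approx(1.0 / (1.0 + np.exp(10.0)), rel=1e-12)

    def test_saturation_limits(self):
        assert activation(1e3, THRESHOLD) == pytest.approx(1.0, abs=1e-12)
        assert activation(-1e3, THRESHOLD) == pytest.approx(0.0, abs=1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(
        z1=st.floats(-1e6, 1e6, allow_nan=False),
        dz=st.floats(0.0, 1e6, allow_nan=False),
    )
    def test_monotone_nondecreasing(self, z1, dz):
        assert activation(z1 + dz, THRESHOLD) >= activation(z1, THRESHOLD)

    def test_presets(self):
        z = np.linspace(-2, 2, 9)
        assert np.array_equal(activation(z, ActivationParams.linear()), z)
        assert np.allclose(activation(z, ActivationParams.tanh()), np.tanh(z))

    def test_bounded_range(self):
        z = np.linspace(-50, 50, 101)
        out = activation(z, THRESHOLD)
        lo, hi = THRESHOLD.range
        assert np.all(out >= lo) and np.all(out <= hi)

    def test_threshold_preset_parameters_fixed(self):
        with pytest.raises(ValueError):
            ActivationParams(name="threshold", gain=5.0)
        with pytest.raises(ValueError):
            ActivationParams(name="sigmoid", b=0.0)
        # arbitrary sigmoid shapes are allowed under the generic name
        f = ActivationParams(name="sigmoid", a=2.0, b=1.0, c=0.0, gain=1.0, d=1.0)
        assert activation(0.0, f) == pytest.approx(0.0)


class TestInputWeights:
    def test_full_fanin_constant(self):
        proj = InputProjection(r_sig=1.0, input_gain=2.0, iw_low=1.0, iw_high=1.0, seed=0)
        W_in = build_input_weights(10, 3, proj)
        assert np.all(W_in == 2.0)

    def test_nonzero_count_per_column(self):
        proj = InputProjection(r_sig=0.3, seed=1)
        W_in = build_input_weights(500, 4, proj)
        counts = np.count_nonzero(W_in, axis=0)
        assert np.all(counts == 150)

    def test_weight_bounds(self):
        proj = InputProjection(r_sig=0.3, seed=2)
        W_in = build_input_weights(500, 1, proj)
        nz = W_in[W_in != 0]
        assert nz.min() >= -0.2 and nz.max() <= 1.0

    def test_masks_independent_per_column(self):
        proj = InputProjection(r_sig=0.5, seed=3)
        W_in = build_input_weights(200, 2, proj)
        assert not np.array_equal(W_in[:, 0] != 0, W_in[:, 1] != 0)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            build_input_weights(10, 1, InputProjection(r_sig=0.01, seed=0))
        with pytest.raises(ValueError):
            InputProjection(r_sig=0.0)


class TestDynamics:
    def test_zero_state_zero_input(self, tiny_reservoir):
        x = step_state(np.zeros(5), np.zeros(2), tiny_reservoir)
        assert np.allclose(x, activation(0.0, THRESHOLD))

    def test_linear_no_recurrence_passes_input(self):
        W = sparse.csr_array((3, 3))
        W_in = np.array([[1.0], [2.0], [-1.0]])
        res = Reservoir(W=W, W_in=W_in, activation=ActivationParams.linear())
        x = step_state(np.ones(3), np.array([0.5]), res)
        assert np.allclose(x, W_in[:, 0] * 0.5)

    def test_matches_dense_oracle(self, tiny_reservoir):
        rng = np.random.default_rng(5)
        x = rng.random(5)
        u = rng.random(2)
        got = step_state(x, u, tiny_reservoir)
        z = tiny_reservoir.W.toarray() @ x + tiny_reservoir.W_in @ u
        expected = 1.0 / (1.0 + np.exp(-10.0 * (z - 1.0)))
        assert np.allclose(got, expected, atol=1e-12)

    def test_batch_columns_are_independent(self, tiny_reservoir):
        rng = np.random.default_rng(6)
        X = rng.random((5, 3))
        U = rng.random((2, 3))
        batch = step_state(X, U, tiny_reservoir)
        singles = np.column_stack([step_state(X[:, j], U[:, j], tiny_reservoir) for j in range(3)])
        # matrix-matrix and matrix-vector kernels may differ in the last bit
        assert np.allclose(batch, singles, atol=1e-12, rtol=0.0)

    def test_dimension_mismatch_rejected(self, tiny_reservoir):
        with pytest.raises(ValueError):
            step_state(np.zeros(4), np.zeros(2), tiny_reservoir)
        with pytest.raises(ValueError):
            step_state(np.zeros(5), np.zeros(3), tiny_reservoir)

    def test_empty_trajectory(self, tiny_reservoir):
        traj = run_reservoir(None, np.empty((2, 0)), tiny_reservoir)
        assert traj.n_steps == 0

    def test_run_is_deterministic(self, tiny_reservoir):
        rng = np.random.default_rng(7)
        U = rng.random((2, 20))
        t1 = run_reservoir(None, U, tiny_reservoir)
        t2 = run_reservoir(None, U, tiny_reservoir)
        assert np.array_equal(t1.X, t2.X)

    def test_threshold_states_stay_in_unit_interval(self, tiny_reservoir):
        rng = np.random.default_rng(8)
        U = rng.normal(scale=3.0, size=(2, 50))
        traj = run_reservoir(None, U, tiny_reservoir)
        assert traj.X.min() >= 0.0 and traj.X.max() <= 1.0


class TestReadout:
    def _random_traj(self, n=6, k=1, T=12, seed=0):
        rng = np.random.default_rng(seed)
        return Trajectory(X=rng.random((n, T)), U=rng.random((k, T)))

    def test_state_row_reconstructed_exactly(self):
        traj = self._random_traj()
        targets = traj.X[2:3, :]
        ro = train_readout(traj, targets)
        assert np.allclose(ro.W_out @ traj.design_matrix(), targets, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        traj = self._random_traj(seed=3)
        rng = np.random.default_rng(4)
        targets = rng.random((2, 12))
        ro = train_readout(traj, targets)
        D = traj.design_matrix()
        oracle = targets @ D.T @ np.linalg.inv(D @ D.T)  # full-row-rank normal equations
        assert np.allclose(ro.W_out, oracle, atol=1e-8)

    def test_rank_deficient_design_still_solvable(self):
        rng = np.random.default_rng(9)
        X = rng.random((5, 15))
        X[3] = X[1]  # duplicate state row
        traj = Trajectory(X=X, U=rng.random((1, 15)))
        targets = rng.random((1, 15))
        ro = train_readout(traj, targets)
        assert np.all(np.isfinite(ro.W_out))
        # training error matches the error of an explicit pseudoinverse fit
        D = traj.design_matrix()
        err = np.linalg.norm(ro.W_out @ D - targets)
        err_pinv = np.linalg.norm((targets @ np.linalg.pinv(D)) @ D - targets)
        assert err == pytest.approx(err_pinv, abs=1e-8)

    def test_least_squares_beats_random_alternatives(self):
        traj = self._random_traj(seed=5)
        rng = np.random.default_rng(6)
        targets = rng.random((2, 12))
        ro = train_readout(traj, targets)
        D = traj.design_matrix()
        best = np.linalg.norm(ro.W_out @ D - targets)
        for _ in range(5):
            alt = rng.normal(size=ro.W_out.shape)
            assert best <= np.linalg.norm(alt @ D - targets) + 1e-12

    def test_target_alignment_enforced(self):
        traj = self._random_traj()
        with pytest.raises(ValueError):
            train_readout(traj, np.zeros((1, 5)))

    def test_step_boundary(self):
        ro = Readout(W_out=np.array([[1.0, 0.0]]), mode="step")
        assert readout_output(np.array([0.5]), np.array([0.0]), ro)[0] == 0.0
        assert readout_output(np.array([0.51]), np.array([0.0]), ro)[0] == 1.0

    def test_identity_matches_dot_product(self):
        rng = np.random.default_rng(10)
        W_out = rng.normal(size=(3, 7))
        ro = Readout(W_out=W_out, mode="identity")
        x, u = rng.random(5), rng.random(2)
        assert np.allclose(readout_output(x, u, ro), W_out @ np.concatenate([x, u]), atol=1e-12)


class TestSerialization:
    def test_roundtrip_bit_exact(self, tiny_reservoir, tmp_path):
        save_reservoir(tmp_path / "res", tiny_reservoir)
        loaded = load_reservoir(tmp_path / "res")
        assert np.array_equal(loaded.W.toarray(), tiny_reservoir.W.toarray())
        assert np.array_equal(loaded.W_in, tiny_reservoir.W_in)
        assert loaded.activation == tiny_reservoir.activation
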