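"""Unit tests for the branching-style network model."""

import math

import numpy as np
import pytest

from neurotc import (
    ModelConfig,
    PerturbationConfig,
    WeightMatrix,
    apply_asm,
    build_network,
    order_parameter,
    phase_sweep,
    population_tc,
    simulate,
)
from neurotc.netmodel import ActivityTrace, _torus_distance_sq


def _trace_from_activity(x: np.ndarray) -> ActivityTrace:
    """Wrap a 1-D population-activity series for TC extraction."""
    x = np.asarray(x, dtype=float)
    return ActivityTrace(
        raster=np.zeros((1, x.size), dtype=np.uint8),
        population_activity=x,
        off_steps=np.zeros(x.size, dtype=bool),
        ied_steps=np.zeros(x.size, dtype=bool),
    )


class TestBuildNetwork:
    @pytest.mark.parametrize("lam", [0.5, 1.0, 1.3])
    def test_spectral_radius_matches_target(self, lam):
        cfg = ModelConfig.with_size(64, lambda_target=lam)
        w = build_network(cfg, seed=7)
        assert w.spectral_radius() == pytest.approx(lam, rel=1e-6)

    def test_sign_structure_and_zero_diagonal(self, small_network):
        W = small_network.weights
        assert np.all(np.diag(W) == 0.0)
        inhib = small_network.inhibitory_mask
        assert np.all(W[inhib, :] <= 0.0)
        assert np.all(W[~inhib, :] >= 0.0)
        # 20% of 64 = 12.8 -> rounds to 13 inhibitory neurons
        assert inhib.sum() == round(0.2 * 64)

    def test_torus_distances_on_2x2_grid(self):
        pos = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
        d2 = _torus_distance_sq(pos, side=2)
        assert d2[0, 1] == 1 and d2[0, 2] == 1
        assert d2[0, 3] == 2  # diagonal, sqrt(2)
        assert np.all(np.diag(d2) == 0)

    def test_huge_sigma_reduces_to_signed_uniform(self):
        cfg = ModelConfig.with_size(64, sigma=1e6)
        w = build_network(cfg, seed=3)
        # undo the global lambda rescale, then off-diagonal magnitudes ~ U[0,1)
        mags = np.abs(w.weights)
        mags = mags[~np.eye(64, dtype=bool)]
        mags /= mags.max()
        assert mags.mean() == pytest.approx(0.5, abs=0.05)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(n_neurons=10, grid_side=3)
        with pytest.raises(ValueError):
            ModelConfig.with_size(60)
        with pytest.raises(ValueError):
            ModelConfig.with_size(64, lambda_target=-1.0)


class TestApplyAsm:
    def test_identity_at_one(self, small_network):
        out = apply_asm(small_network, 1.0)
        np.testing.assert_array_equal(out.weights, small_network.weights)

    def test_zero_excitation_leaves_only_inhibition(self, small_network):
        out = apply_asm(small_network, 1e-12)
        exc = ~small_network.inhibitory_mask
        assert np.allclose(out.weights[exc, :], 0.0)
        np.testing.assert_array_equal(
            out.weights[~exc, :], small_network.weights[~exc, :]
        )

    def test_three_neuron_toy_row_halved(self):
        W = np.array([[0.0, 0.4, 0.2], [-0.1, 0.0, -0.3], [-0.2, -0.5, 0.0]])
        wm = WeightMatrix(
            weights=W.copy(),
            inhibitory_mask=np.array([False, True, True]),
            positions=np.zeros((3, 2), dtype=int),
            grid_side=2,
            lambda_target=1.0,
        )
        out = apply_asm(wm, 0.5)
        np.testing.assert_allclose(out.weights[0], [0.0, 0.2, 0.1])
        np.testing.assert_array_equal(out.weights[1:], W[1:])

    def test_reduces_spectral_radius(self, small_network):
        assert apply_asm(small_network, 0.7).spectral_radius() < (
            small_network.spectral_radius()
        )

    def test_out_of_range_rejected(self, small_network):
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                apply_asm(small_network, bad)


class TestSimulate:
    def _zero_net(self, cfg):
        w = build_network(cfg, seed=0)
        return WeightMatrix(
            weights=np.zeros_like(w.weights),
            inhibitory_mask=w.inhibitory_mask,
            positions=w.positions,
            grid_side=w.grid_side,
            lambda_target=cfg.lambda_target,
        )

    def test_drive_only_gives_one_active_neuron(self, small_config, unperturbed):
        w = self._zero_net(small_config)
        trace = simulate(small_config, unperturbed, w, seed=5)
        np.testing.assert_allclose(
            trace.population_activity, 1.0 / small_config.n_neurons
        )
        assert order_parameter(trace, 100) == pytest.approx(1.0 / 64)

    def test_p_off_one_silences_everything(self, small_config, small_network):
        trace = simulate(
            small_config, PerturbationConfig(p_off=1.0), small_network, seed=5
        )
        assert np.all(trace.population_activity == 0.0)

    def test_p_ied_one_forces_patch_active(self, small_config):
        w = self._zero_net(small_config)
        trace = simulate(
            small_config, PerturbationConfig(p_ied=1.0), w, seed=5
        )
        n_active = trace.raster.sum(axis=0)
        assert np.all(n_active >= math.ceil(0.2 * small_config.n_neurons))

    def test_bit_reproducible(self, small_config, small_network, unperturbed):
        t1 = simulate(small_config, unperturbed, small_network, seed=99)
        t2 = simulate(small_config, unperturbed, small_network, seed=99)
        np.testing.assert_array_equal(t1.raster, t2.raster)
        np.testing.assert_array_equal(
            t1.population_activity, t2.population_activity
        )

    def test_inconsistent_matrix_rejected(self, small_config, unperturbed):
        other = build_network(ModelConfig.with_size(16), seed=1)
        with pytest.raises(ValueError):
            simulate(small_config, unperturbed, other, seed=0)


class TestPopulationTc:
    def test_exponential_acf_matches_closed_form(self, rng):
        # AR(1) with correlation time tau steps: crossing at ceil(tau*ln2 + 1)
        tau = 20.0
        phi = math.exp(-1.0 / tau)
        n = 60000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.standard_normal(n) * math.sqrt(1 - phi ** 2)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + eps[t]
        tc, capped = population_tc(_trace_from_activity(x), transient=0)
        k_star = math.ceil(tau * math.log(2) + 1)
        assert not capped
        assert abs(tc - (k_star - 1)) <= 1

    def test_white_noise_hits_floor(self, rng):
        tc, _ = population_tc(_trace_from_activity(rng.standard_normal(5000)), 0)
        assert tc <= 2

    def test_constant_activity_rejected(self):
        with pytest.raises(ValueError):
            population_tc(_trace_from_activity(np.ones(2000)), transient=0)


class TestPhaseSweep:
    def test_deterministic_and_shaped(self, unperturbed):
        cfg = ModelConfig.with_size(64, n_steps=800, transient=200)
        a = phase_sweep([0.9, 1.0], unperturbed, reps=3, seed=11, config=cfg,
                        return_reps=True)
        b = phase_sweep([0.9, 1.0], unperturbed, reps=3, seed=11, config=cfg,
                        return_reps=True)
        assert a.equals(b)
        assert set(a.columns) == {
            "lambda", "f_exc", "p_off", "p_ied", "rep", "order_parameter",
            "tc_steps",
        }
        agg = phase_sweep([0.9, 1.0], unperturbed, reps=3, seed=11, config=cfg)
        assert len(agg) == 2

    def test_empty_grid_rejected(self, unperturbed):
        with pytest.raises(ValueError):
            phase_sweep([], unperturbed, reps=1, seed=0)
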