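"""Branching-style neuronal network model with tunable distance to criticality.

The model places N neurons on a periodic square grid, couples every pair with
a random-uniform weight shaped by a Gaussian distance kernel, and rescales the
weight matrix so its spectral radius (largest absolute eigenvalue) equals a
chosen control parameter ``lambda``.  Activity propagates by a clipped-linear
probabilistic update; a single background neuron is driven per step.  Three
perturbations move the network away from its operating point:

* antiseizure-medication effect — outgoing excitatory weights scaled by
  ``f_exc`` < 1 (reduced excitability);
* sleep-like off-periods — with probability ``p_off`` per step the whole
  network is silenced for that step;
* interictal-discharge events — with probability ``p_ied`` per step a random
  neuron and its nearest neighbors (20 % of the network) are forced active.

The summary statistic is the temporal correlation (TC): the half-width decay
time of the autocorrelation of the population activity, measured from the
lag-1 peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ModelConfig",
    "PerturbationConfig",
    "WeightMatrix",
    "ActivityTrace",
    "build_network",
    "apply_asm",
    "simulate",
    "order_parameter",
    "population_tc",
    "phase_sweep",
]


@dataclass(frozen=True)
class ModelConfig:
    """Structural and run-length parameters of the network model."""

    n_neurons: int = 1024
    grid_side: int = 32
    frac_inhibitory: float = 0.2
    sigma: float = 4.0
    lambda_target: float = 1.0
    n_steps: int = 5000
    transient: int = 500
    background_active_per_step: int = 1

    def __post_init__(self) -> None:
        if self.grid_side * self.grid_side != self.n_neurons:
            raise ValueError(
                f"n_neurons={self.n_neurons} must equal grid_side^2={self.grid_side ** 2}"
            )
        if not 0.0 < self.frac_inhibitory < 1.0:
            raise ValueError("frac_inhibitory must lie strictly in (0, 1)")
        if self.lambda_target <= 0:
            raise ValueError("lambda_target must be positive")
        if self.transient >= self.n_steps:
            raise ValueError("transient must be smaller than n_steps")

    @classmethod
    def with_size(cls, n_neurons: int, **kwargs) -> "ModelConfig":
        """Convenience constructor deriving grid_side from a square N."""
        side = math.isqrt(n_neurons)
        if side * side != n_neurons:
            raise ValueError(f"n_neurons={n_neurons} is not a perfect square")
        return cls(n_neurons=n_neurons, grid_side=side, **kwargs)


@dataclass(frozen=True)
class PerturbationConfig:
    """Strengths of the three perturbation mechanisms.

    ``f_exc=1, p_off=0, p_ied=0`` reproduces the unperturbed model.
    """

    f_exc: float = 1.0
    p_off: float = 0.0
    p_ied: float = 0.0
    ied_patch_frac: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 < self.f_exc <= 1.0:
            raise ValueError("f_exc must lie in (0, 1]")
        for name in ("p_off", "p_ied", "ied_patch_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class WeightMatrix:
    """Signed, distance-modulated connectivity with controlled spectral radius."""

    weights: np.ndarray  # (N, N), row i = outgoing weights of neuron i
    inhibitory_mask: np.ndarray  # (N,) bool
    positions: np.ndarray  # (N, 2) integer grid coordinates
    grid_side: int
    lambda_target: float

    @property
    def n_neurons(self) -> int:
        return self.weights.shape[0]

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.weights))))


@dataclass
class ActivityTrace:
    """Binary raster plus derived population activity and per-step event flags."""

    raster: np.ndarray  # (N, n_steps) uint8
    population_activity: np.ndarray  # (n_steps,) fraction of active neurons
    off_steps: np.ndarray  # (n_steps,) bool
    ied_steps: np.ndarray  # (n_steps,) bool

    @property
    def n_steps(self) -> int:
        return self.population_activity.shape[0]


def _torus_distance_sq(positions: np.ndarray, side: int) -> np.ndarray:
    """Pairwise squared Euclidean distance on the periodic grid."""
    diff = np.abs(positions[:, None, :] - positions[None, :, :])
    diff = np.minimum(diff, side - diff)
    return (diff ** 2).sum(axis=-1)


def build_network(config: ModelConfig, seed: int) -> WeightMatrix:
    """Construct the weight matrix.

    Weights are ``u_ij * exp(-r_ij^2 / (2 sigma^2))`` with ``u_ij`` uniform on
    [0, 1) and ``r_ij`` the torus grid distance; the diagonal is zeroed; a
    random ``frac_inhibitory`` of neurons have all outgoing weights negated;
    finally the whole matrix is rescaled by one scalar so its spectral radius
    equals ``lambda_target``.
    """
    rng = np.random.default_rng(seed)
    n, side = config.n_neurons, config.grid_side
    positions = np.stack(
        np.unravel_index(np.arange(n), (side, side)), axis=1
    ).astype(np.int64)
    r2 = _torus_distance_sq(positions, side)
    kernel = np.exp(-r2 / (2.0 * config.sigma ** 2))
    weights = rng.random((n, n)) * kernel
    np.fill_diagonal(weights, 0.0)

    n_inhib = round(config.frac_inhibitory * n)
    inhib_idx = rng.choice(n, size=n_inhib, replace=False)
    inhibitory = np.zeros(n, dtype=bool)
    inhibitory[inhib_idx] = True
    weights[inhibitory, :] *= -1.0

    radius = float(np.max(np.abs(np.linalg.eigvals(weights))))
    if radius == 0.0:
        raise ValueError("cannot rescale an all-zero weight matrix")
    weights *= config.lambda_target / radius
    return WeightMatrix(
        weights=weights,
        inhibitory_mask=inhibitory,
        positions=positions,
        grid_side=side,
        lambda_target=config.lambda_target,
    )


def apply_asm(w: WeightMatrix, f_exc: float) -> WeightMatrix:
    """Scale outgoing excitatory weights by ``f_exc`` (medication effect).

    The spectral radius is deliberately *not* re-normalized afterwards: the
    induced shift of the operating point is the perturbation mechanism.
    """
    if not 0.0 < f_exc <= 1.0:
        raise ValueError("f_exc must lie in (0, 1]")
    weights = w.weights.copy()
    weights[~w.inhibitory_mask, :] *= f_exc
    return WeightMatrix(
        weights=weights,
        inhibitory_mask=w.inhibitory_mask.copy(),
        positions=w.positions.copy(),
        grid_side=w.grid_side,
        lambda_target=w.lambda_target,
    )


def _ied_patch(w: WeightMatrix, center: int, patch_size: int) -> np.ndarray:
    """Indices of the center neuron plus its patch_size-1 nearest torus
    neighbors, ties broken by neuron index."""
    diff = np.abs(w.positions - w.positions[center])
    diff = np.minimum(diff, w.grid_side - diff)
    d2 = (diff ** 2).sum(axis=1)
    order = np.lexsort((np.arange(w.n_neurons), d2))
    return order[:patch_size]


def simulate(
    config: ModelConfig,
    perturb: PerturbationConfig,
    w: WeightMatrix,
    seed: int,
) -> ActivityTrace:
    """Run the probabilistic dynamics for ``config.n_steps`` steps.

    Per step: each neuron activates independently with probability equal to
    its weighted input sum clipped to [0, 1]; then one uniformly chosen neuron
    is forced active (background drive); then, if the step hosts an IED event,
    a random local patch is forced active; finally, if the step is an
    off-period, the entire network (drive included) is silenced.
    """
    if w.n_neurons != config.n_neurons:
        raise ValueError("weight matrix inconsistent with config")
    n, n_steps = config.n_neurons, config.n_steps
    rng = np.random.default_rng(seed)

    # All randomness drawn up-front for bit-reproducibility of the loop.
    uniforms = rng.random((n_steps, n))
    drive = rng.integers(0, n, size=n_steps)
    off_steps = rng.random(n_steps) < perturb.p_off
    ied_steps = rng.random(n_steps) < perturb.p_ied
    ied_centers = rng.integers(0, n, size=n_steps)

    patch_size = math.ceil(perturb.ied_patch_frac * n)
    patch_cache: dict[int, np.ndarray] = {}

    # Row i of `weights` holds the outgoing weights of neuron i, so the input
    # to neuron i is the i-th entry of W^T s.
    incoming = np.ascontiguousarray(w.weights.T)
    raster = np.zeros((n, n_steps), dtype=np.uint8)
    pop = np.empty(n_steps)
    state = np.zeros(n)
    for t in range(n_steps):
        p = np.clip(incoming @ state, 0.0, 1.0)
        state = (uniforms[t] < p).astype(np.float64)
        state[drive[t]] = 1.0
        if ied_steps[t] and patch_size > 0:
            c = int(ied_centers[t])
            patch = patch_cache.get(c)
            if patch is None:
                patch = _ied_patch(w, c, patch_size)
                patch_cache[c] = patch
            state[patch] = 1.0
        if off_steps[t]:
            state[:] = 0.0
        raster[:, t] = state
        pop[t] = state.mean()
    return ActivityTrace(
        raster=raster,
        population_activity=pop,
        off_steps=off_steps,
        ied_steps=ied_steps,
    )


def order_parameter(trace: ActivityTrace, transient: int) -> float:
    """Mean population activity after discarding the initial transient."""
    if transient >= trace.n_steps:
        raise ValueError("transient leaves no steps to average")
    return float(trace.population_activity[transient:].mean())


def _acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased (divide-by-n) sample autocorrelation at lags 1..max_lag."""
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    x = x - x.mean()
    c0 = float(np.dot(x, x)) / n
    if c0 == 0.0:
        raise ValueError("zero-variance series: autocorrelation undefined")
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[1 : max_lag + 1] / n
    return acov / c0


def population_tc(
    trace: ActivityTrace, transient: int, max_lag: int = 500
) -> tuple[int, bool]:
    """TC of the population activity, in timesteps.

    The autocorrelation is computed to ``max_lag``; the baseline is the median
    ACF over the last fifth of lags; the threshold sits halfway between the
    lag-1 value and the baseline; the TC is the width from the lag-1 peak to
    the first lag (>= 2) whose ACF falls below the threshold.  Returns
    ``(tc_steps, capped)`` where ``capped`` marks a no-crossing run.
    """
    x = trace.population_activity[transient:]
    if x.size <= max_lag:
        max_lag = x.size - 2
    if max_lag < 2:
        raise ValueError("post-transient activity too short for TC")
    acf = _acf(x, max_lag)  # acf[k-1] = ACF at lag k
    tail = acf[max_lag - max_lag // 5 :]
    baseline = float(np.median(tail))
    threshold = baseline + (acf[0] - baseline) / 2.0
    below = np.nonzero(acf[1:] < threshold)[0]
    if below.size:
        lag = int(below[0]) + 2  # first lag >= 2 below threshold
        return lag - 1, False
    return max_lag, True


def _run_once(
    config: ModelConfig, perturb: PerturbationConfig, seed_pair: tuple[int, int]
) -> tuple[float, int]:
    net_seed, sim_seed = seed_pair
    w = build_network(config, net_seed)
    if perturb.f_exc < 1.0:
        w = apply_asm(w, perturb.f_exc)
    trace = simulate(config, perturb, w, sim_seed)
    op = order_parameter(trace, config.transient)
    try:
        tc, _ = population_tc(trace, config.transient)
    except ValueError:
        # fully saturated (constant) activity has no defined TC
        tc = float("nan")
    return op, tc


def phase_sweep(
    lambdas,
    perturb: PerturbationConfig,
    reps: int,
    seed: int,
    config: ModelConfig | None = None,
    return_reps: bool = False,
) -> pd.DataFrame:
    """Sweep the control parameter, repeating independent builds and runs.

    Returns a table of ``(lambda, mean order parameter, mean TC, sd TC)``
    or, with ``return_reps=True``, one row per repetition with columns
    ``(lambda, f_exc, p_off, p_ied, rep, order_parameter, tc_steps)``.
    Deterministic given ``seed``.
    """
    lambdas = list(lambdas)
    if not lambdas:
        raise ValueError("empty lambda list")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    base = config or ModelConfig()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(lambdas) * reps * 2)
    rows = []
    k = 0
    for lam in lambdas:
        cfg = ModelConfig(
            n_neurons=base.n_neurons,
            grid_side=base.grid_side,
            frac_inhibitory=base.frac_inhibitory,
            sigma=base.sigma,
            lambda_target=float(lam),
            n_steps=base.n_steps,
            transient=base.transient,
        )
        for rep in range(reps):
            pair = (
                int(children[k].generate_state(1)[0] % (2 ** 31)),
                int(children[k + 1].generate_state(1)[0] % (2 ** 31)),
            )
            k += 2
            op, tc = _run_once(cfg, perturb, pair)
            rows.append(
                {
                    "lambda": float(lam),
                    "f_exc": perturb.f_exc,
                    "p_off": perturb.p_off,
                    "p_ied": perturb.p_ied,
                    "rep": rep,
                    "order_parameter": op,
                    "tc_steps": tc,
                }
            )
    per_rep = pd.DataFrame(rows)
    if return_reps:
        return per_rep
    agg = (
        per_rep.groupby("lambda")
        .agg(
            mean_order_parameter=("order_parameter", "mean"),
            mean_tc=("tc_steps", "mean"),
            sd_tc=("tc_steps", "std"),
        )
        .reset_index()
    )
    return agg
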