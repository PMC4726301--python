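"""Correlated white-noise generation and stochastic Heun integration.

Three Langevin variants of the depot model are integrated:

``full``
    the coupled ``(x, v, e)`` system — depot dynamics resolved explicitly,
    velocity driven by ``-gamma0*v + d2*e*v`` plus the two noises;
``reduced``
    the ``(x, v)`` system after adiabatic elimination of the depot,
    ``dv = f(v) dt - v o dW1 + dW2``;
``equivalent``
    the single-noise Langevin equation whose Fokker-Planck equation matches
    the reduced dynamics, ``dv = [F(v) - G'(v)/2] dt + sqrt(G(v)) o dW``.

All variants use the stochastic Heun (predictor-corrector) scheme — the
"stochastic second-order Runge-Kutta" — with the *same* Wiener increments in
predictor and corrector, which converges to the Stratonovich solution and is
therefore consistent with the Fokker-Planck layer.  Wiener increments carry
the ``<eta_i eta_j> = 2 M_ij delta`` convention, i.e. ``Var[dW_i] = 2 M_i dt``
and the unit-intensity increment of the equivalent variant has variance
``2 dt``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .fokker_planck import (
    NoiseParams,
    default_grid,
    diffusion_G,
    diffusion_G_prime,
    drift_F,
    stationary_distribution,
)
from .model_core import ModelParams, deterministic_force, quasistationary_depot

__all__ = [
    "SimulationConfig",
    "TrajectoryEnsemble",
    "IntegrationBlowupError",
    "correlated_increments",
    "step_full",
    "step_reduced",
    "step_equivalent",
    "run_ensemble",
]

Variant = Literal["full", "reduced", "equivalent"]

#: Ensemble size and step count of the reference numerical protocol
#: (dt = 0.01, 500 trajectories, 1e5 steps each, v and x initialised
#: uniformly on [-1, 1]).
PAPER_SCALE = {"dt": 0.01, "n_steps": 100_000, "n_traj": 500}
#: Reduced desk scale used by default in the experiments and tests.
TEST_SCALE = {"dt": 0.01, "n_steps": 20_000, "n_traj": 100}


class IntegrationBlowupError(FloatingPointError):
    """Raised when a trajectory becomes non-finite during integration."""

    def __init__(self, step: int, trajectories: np.ndarray):
        self.step = int(step)
        self.trajectories = np.asarray(trajectories)
        super().__init__(
            f"non-finite state at step {step} in trajectories "
            f"{self.trajectories.tolist()}"
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Integrator settings, ensemble size and initial-condition law.

    The initial-condition law draws ``v`` and ``x`` uniformly on the
    configured bounds (default ``[-1, 1]`` for both, the reference protocol);
    with ``v_init = "stationary"`` the initial velocities are instead drawn
    from the analytic stationary density by inverse-CDF sampling (useful for
    observables of the metastable reduced dynamics, whose wells are far too
    deep to equilibrate across within any feasible horizon).  The depot
    starts either at its quasi-stationary value for the drawn velocity
    (``"quasistationary"``) or at the noise-free reservoir level ``q/c``
    (``"reservoir"``).
    """

    dt: float = 0.01
    n_steps: int = 20_000
    n_traj: int = 100
    burn_in_steps: int = 4_000
    seed: int = 0
    variant: Variant = "reduced"
    v_init: Literal["uniform", "stationary"] = "uniform"
    v_bounds: tuple[float, float] = (-1.0, 1.0)
    x_bounds: tuple[float, float] = (-1.0, 1.0)
    e_init: Literal["quasistationary", "reservoir"] = "quasistationary"
    store_every: int = 1

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if not 0 <= self.burn_in_steps < self.n_steps:
            raise ValueError("need n_steps > burn_in_steps >= 0")
        if self.n_traj < 1:
            raise ValueError("n_traj must be >= 1")
        if self.variant not in ("full", "reduced", "equivalent"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.store_every < 1:
            raise ValueError("store_every must be >= 1")
        if self.v_init not in ("uniform", "stationary"):
            raise ValueError(f"unknown v_init {self.v_init!r}")

    def to_dict(self) -> dict:
        return {
            "dt": self.dt,
            "n_steps": self.n_steps,
            "n_traj": self.n_traj,
            "burn_in_steps": self.burn_in_steps,
            "seed": self.seed,
            "variant": self.variant,
            "v_init": self.v_init,
            "v_bounds": list(self.v_bounds),
            "x_bounds": list(self.x_bounds),
            "e_init": self.e_init,
            "store_every": self.store_every,
        }


@dataclass
class TrajectoryEnsemble:
    """Time grid plus per-trajectory state arrays with provenance.

    Arrays are shaped ``(n_traj, n_stored)`` with ``times`` strictly
    increasing; ``e`` is ``None`` for the reduced and equivalent variants.
    ``clamp_count`` counts depot clamping events (``e`` forced back to 0).
    """

    times: np.ndarray
    x: np.ndarray
    v: np.ndarray
    e: np.ndarray | None
    params: ModelParams
    noise: NoiseParams
    config: SimulationConfig
    clamp_count: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def n_traj(self) -> int:
        return self.v.shape[0]

    def retained_slice(self) -> slice:
        """Index slice of the stored grid past the configured burn-in."""
        first = self.config.burn_in_steps // self.config.store_every
        return slice(first + 1, None)


def correlated_increments(
    n_pairs: int, dt: float, n: NoiseParams, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n_pairs`` correlated Wiener-increment pairs ``(dW1, dW2)``.

    Zero-mean Gaussian with covariance
    ``[[2*M1*dt, 2*M12*dt], [2*M12*dt, 2*M2*dt]]``, realized through a
    lower-triangular square-root factor; at ``|mu| = 1`` the pair is rank-1
    (``dW2`` fully determined by ``dW1``).

    Raises
    ------
    ValueError
        If ``|mu| = 1`` with ``M1 = 0`` (correlation undefined against a
        null noise), or dt <= 0.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if abs(n.mu) == 1.0 and n.M1 == 0 and n.M2 > 0:
        raise ValueError("perfect correlation with M1 = 0 is undefined")
    resid = n.M2 * (1.0 - n.mu**2)
    if resid < 0:  # cannot occur for |mu| <= 1; guard against roundoff
        resid = 0.0
    ell = np.array(
        [
            [np.sqrt(2.0 * n.M1 * dt), 0.0],
            [n.mu * np.sqrt(2.0 * n.M2 * dt), np.sqrt(2.0 * resid * dt)],
        ]
    )
    z = rng.standard_normal((n_pairs, 2))
    return z @ ell.T


def step_full(state, dt, p: ModelParams, n: NoiseParams, increments):
    """One Heun step of the coupled ``(x, v, e)`` system.

    The corrector re-evaluates drift and diffusion coefficients at the
    predictor state but reuses the same increments (Stratonovich-consistent).
    The depot is clamped at zero after both stages; the return value carries
    the clamp count of this step.
    """
    x, v, e = state
    dw1, dw2 = increments[..., 0], increments[..., 1]
    clamps = 0

    def drift_v(v_, e_):
        return -p.gamma0 * v_ + p.d2 * e_ * v_

    def drift_e(v_, e_):
        return p.q - p.c * e_ - p.d2 * v_**2 * e_

    vp = v + drift_v(v, e) * dt - v * dw1 + dw2
    ep = e + drift_e(v, e) * dt
    neg = ep < 0
    clamps += int(np.count_nonzero(neg))
    ep = np.where(neg, 0.0, ep)
    xp = x + v * dt

    v_new = (
        v
        + 0.5 * (drift_v(v, e) + drift_v(vp, ep)) * dt
        - 0.5 * (v + vp) * dw1
        + dw2
    )
    e_new = e + 0.5 * (drift_e(v, e) + drift_e(vp, ep)) * dt
    neg = e_new < 0
    clamps += int(np.count_nonzero(neg))
    e_new = np.where(neg, 0.0, e_new)
    x_new = x + 0.5 * (v + vp) * dt
    return (x_new, v_new, e_new), clamps


def step_reduced(state, dt, p: ModelParams, n: NoiseParams, increments):
    """One Heun step of the reduced system
    ``dv = f(v) dt - v o dW1 + dW2``, ``dx = v dt``."""
    x, v = state
    dw1, dw2 = increments[..., 0], increments[..., 1]
    fv = deterministic_force(v, p)
    vp = v + fv * dt - v * dw1 + dw2
    v_new = v + 0.5 * (fv + deterministic_force(vp, p)) * dt \
        - 0.5 * (v + vp) * dw1 + dw2
    x_new = x + 0.5 * (v + vp) * dt
    return x_new, v_new


def step_equivalent(state, dt, p: ModelParams, n: NoiseParams,
                    single_increment):
    """One Heun step of the equivalent single-noise Langevin equation.

    The Stratonovich drift is ``F(v) - G'(v)/2`` so that the associated
    Fokker-Planck equation has drift ``F`` and diffusion ``G`` — the same as
    the reduced two-noise dynamics.  ``single_increment`` is a unit-intensity
    Wiener increment with variance ``2 dt``.
    """
    x, v = state
    dw = single_increment

    def a(v_):
        return drift_F(v_, p, n) - 0.5 * diffusion_G_prime(v_, n)

    def b(v_):
        g = diffusion_G(v_, n)
        return np.sqrt(np.maximum(g, 0.0))

    vp = v + a(v) * dt + b(v) * dw
    v_new = v + 0.5 * (a(v) + a(vp)) * dt + 0.5 * (b(v) + b(vp)) * dw
    x_new = x + 0.5 * (v + vp) * dt
    return x_new, v_new


def _stationary_sampler(p: ModelParams, n: NoiseParams):
    """Inverse-CDF sampler of the analytic stationary velocity density."""
    sol = stationary_distribution(default_grid(), p, n)
    cdf = np.concatenate(
        ([0.0], np.cumsum(0.5 * (sol.Q_st[1:] + sol.Q_st[:-1])
                          * np.diff(sol.grid)))
    )
    cdf /= cdf[-1]
    return lambda u: float(np.interp(u, cdf, sol.grid))


def _draw_increments(
    cfg: SimulationConfig, p: ModelParams, n: NoiseParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-trajectory increment streams plus initial conditions.

    Each trajectory owns a child stream spawned from the master seed, so the
    ensemble is reproducible and independent of trajectory execution order.
    """
    children = np.random.SeedSequence(cfg.seed).spawn(cfg.n_traj)
    if cfg.variant == "equivalent":
        dw = np.empty((cfg.n_traj, cfg.n_steps))
    else:
        dw = np.empty((cfg.n_traj, cfg.n_steps, 2))
    v0 = np.empty(cfg.n_traj)
    x0 = np.empty(cfg.n_traj)
    v_inv = _stationary_sampler(p, n) if cfg.v_init == "stationary" else None
    for i, child in enumerate(children):
        rng = np.random.Generator(np.random.PCG64(child))
        if v_inv is None:
            v0[i] = rng.uniform(*cfg.v_bounds)
        else:
            v0[i] = v_inv(rng.uniform())
        x0[i] = rng.uniform(*cfg.x_bounds)
        if cfg.variant == "equivalent":
            dw[i] = rng.standard_normal(cfg.n_steps) * np.sqrt(2.0 * cfg.dt)
        else:
            dw[i] = correlated_increments(cfg.n_steps, cfg.dt, n, rng)
    return dw, v0, x0


def run_ensemble(
    cfg: SimulationConfig, p: ModelParams, n: NoiseParams
) -> TrajectoryEnsemble:
    """Integrate an ensemble of trajectories and return it with provenance.

    Initial ``v`` and ``x`` are uniform on the configured bounds (default
    ``[-1, 1]``); the depot starts at its quasi-stationary value for the
    drawn velocity unless ``e_init = "reservoir"``.  The same seed yields a
    bit-identical ensemble.

    Raises
    ------
    IntegrationBlowupError
        If any trajectory becomes non-finite, reporting step and indices.
    """
    dw, v, x = _draw_increments(cfg, p, n)
    variant = cfg.variant
    keep = cfg.store_every
    n_stored = cfg.n_steps // keep + 1
    xs = np.empty((cfg.n_traj, n_stored))
    vs = np.empty((cfg.n_traj, n_stored))
    es = np.empty((cfg.n_traj, n_stored)) if variant == "full" else None
    clamp_count = 0

    if variant == "full":
        if cfg.e_init == "reservoir":
            e = np.full(cfg.n_traj, p.q / p.c)
        else:
            e = quasistationary_depot(v, p)
        es[:, 0] = e
    xs[:, 0], vs[:, 0] = x, v

    stored = 1
    # non-finite states are detected and reported; silence the transient
    # overflow warnings they would otherwise emit
    with np.errstate(over="ignore", invalid="ignore"):
        return _integrate_loop(cfg, p, n, dw, x, v,
                               e if variant == "full" else None,
                               xs, vs, es, stored, clamp_count)


def _integrate_loop(cfg, p, n, dw, x, v, e, xs, vs, es, stored, clamp_count):
    variant = cfg.variant
    keep = cfg.store_every
    for step in range(cfg.n_steps):
        if variant == "full":
            (x, v, e), clamps = step_full((x, v, e), cfg.dt, p, n, dw[:, step])
            clamp_count += clamps
        elif variant == "reduced":
            x, v = step_reduced((x, v), cfg.dt, p, n, dw[:, step])
        else:
            x, v = step_equivalent((x, v), cfg.dt, p, n, dw[:, step])
        if not np.all(np.isfinite(v)):
            raise IntegrationBlowupError(step + 1, np.nonzero(~np.isfinite(v))[0])
        if (step + 1) % keep == 0:
            xs[:, stored], vs[:, stored] = x, v
            if es is not None:
                es[:, stored] = e
            stored += 1

    times = np.arange(xs.shape[1]) * (cfg.dt * keep)
    return TrajectoryEnsemble(
        times=times,
        x=xs,
        v=vs,
        e=es,
        params=p,
        noise=n,
        config=cfg,
        clamp_count=clamp_count,
        meta={"variant": variant, "seed": cfg.seed},
    )
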