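"""Ensemble estimators: mean velocity and position, depot observables,
effective diffusion, and the zero crossing of a mean-velocity sweep.

Uncertainties are between-trajectory standard errors throughout: the
trajectories of an ensemble are independent replicates, so the standard
error of any time-averaged quantity is the standard deviation of the
per-trajectory means divided by ``sqrt(n_traj)``.  The effective diffusion
coefficient is defined from the spread *about* the mean motion,

    D_eff = (1/2) d/dt Var[x(t)],

estimated by a least-squares fit of the ensemble variance of position over a
late-time window, so a common drift does not contaminate the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .integrators import TrajectoryEnsemble

__all__ = [
    "Estimate",
    "ObservableSummary",
    "mean_velocity",
    "mean_position",
    "depot_observables",
    "effective_diffusion",
    "sign_change",
    "summarize",
]


@dataclass(frozen=True)
class Estimate:
    """A point estimate with its standard error."""

    value: float
    se: float

    def __iter__(self):
        return iter((self.value, self.se))


@dataclass(frozen=True)
class ObservableSummary:
    """All scalar observables of one ensemble, with provenance."""

    mean_v: Estimate
    mean_x_final: Estimate
    D_eff: Estimate
    depot_mean_e: Estimate | None
    depot_conversion_rate: Estimate | None
    n_traj: int
    retained_steps: int
    clamp_count: int


def _traj_mean_estimate(per_traj: np.ndarray) -> Estimate:
    per_traj = np.asarray(per_traj, dtype=float)
    n = per_traj.size
    se = float(np.std(per_traj, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return Estimate(float(per_traj.mean()), se)


def mean_velocity(ens: TrajectoryEnsemble, burn_in: int | None = None) -> Estimate:
    """Stationary mean velocity, averaged over retained steps and
    trajectories; SE from the between-trajectory spread of per-trajectory
    time averages."""
    sl = _retained(ens, burn_in)
    return _traj_mean_estimate(ens.v[:, sl].mean(axis=1))


def mean_position(ens: TrajectoryEnsemble, t_index: int = -1) -> Estimate:
    """Ensemble-mean position at a given stored time index (default final).

    With a nonzero drift this grows as ``mean_v * t``.
    """
    x_t = ens.x[:, t_index]
    return _traj_mean_estimate(x_t)


def depot_observables(
    ens: TrajectoryEnsemble, burn_in: int | None = None
) -> tuple[Estimate, Estimate]:
    """Stationary mean depot energy ``<e>`` and conversion rate
    ``d2 * <e * v**2>``.

    Both are reported: either is a sensible scalar summary of the rate at
    which the depot feeds the motion.  At stationarity they satisfy the
    energy balance ``q - c*<e> - d2*<e v^2> = 0``.

    Raises
    ------
    ValueError
        For reduced/equivalent ensembles, which carry no depot.
    """
    if ens.e is None:
        raise ValueError("ensemble has no depot variable (variant without e)")
    sl = _retained(ens, burn_in)
    e = ens.e[:, sl]
    v = ens.v[:, sl]
    d2 = ens.params.d2
    return (
        _traj_mean_estimate(e.mean(axis=1)),
        _traj_mean_estimate((d2 * e * v**2).mean(axis=1)),
    )


def effective_diffusion(
    ens: TrajectoryEnsemble, fit_window: tuple[int, int] | None = None
) -> Estimate:
    """Effective diffusion coefficient: half the least-squares slope of the
    ensemble variance of ``x(t)`` over the fit window (default: final half
    of the run).

    The SE is the regression standard error of the slope (a fit diagnostic;
    successive variance samples are correlated, so it understates the true
    Monte-Carlo error).  Negative point estimates are possible in fit noise
    and are returned as-is.

    Raises
    ------
    ValueError
        If the window has fewer than 10 samples.
    """
    n_stored = ens.x.shape[1]
    if fit_window is None:
        fit_window = (n_stored // 2, n_stored)
    lo, hi = fit_window
    if hi - lo < 10:
        raise ValueError("fit window must span at least 10 stored samples")
    t = ens.times[lo:hi]
    var_x = np.var(ens.x[:, lo:hi], axis=0, ddof=1)
    fit = stats.linregress(t, var_x)
    return Estimate(0.5 * float(fit.slope), 0.5 * float(fit.stderr))


def sign_change(
    mu_values,
    estimates,
    per_traj_means=None,
    *,
    n_boot: int = 200,
    rng: np.random.Generator | None = None,
) -> Estimate:
    """Zero crossing of a mean-velocity sweep by linear interpolation.

    Parameters
    ----------
    mu_values
        Swept cross-correlation intensities, increasing.
    estimates
        Mean-velocity point estimates at each value (floats or
        :class:`Estimate`).
    per_traj_means
        Optional list of per-trajectory mean arrays, one per sweep point;
        when given, the SE of the crossing is estimated by bootstrap over
        trajectories (``n_boot`` resamples).

    Raises
    ------
    ValueError
        If the sweep contains no sign change.
    """
    mu = np.asarray(mu_values, dtype=float)
    y = np.array([e.value if isinstance(e, Estimate) else float(e)
                  for e in estimates])
    crossing = _interp_crossing(mu, y)

    se = 0.0
    if per_traj_means is not None:
        rng = np.random.default_rng(0) if rng is None else rng
        boots = []
        for _ in range(n_boot):
            yb = np.empty_like(y)
            for j, tm in enumerate(per_traj_means):
                tm = np.asarray(tm, dtype=float)
                idx = rng.integers(0, tm.size, tm.size)
                yb[j] = tm[idx].mean()
            try:
                boots.append(_interp_crossing(mu, yb))
            except ValueError:
                continue
        if len(boots) > 1:
            se = float(np.std(boots, ddof=1))
    return Estimate(crossing, se)


def _interp_crossing(mu: np.ndarray, y: np.ndarray) -> float:
    sign = np.sign(y)
    flips = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    exact = np.nonzero(y == 0.0)[0]
    candidates = []
    for i in flips:
        candidates.append(mu[i] - y[i] * (mu[i + 1] - mu[i]) / (y[i + 1] - y[i]))
    candidates.extend(mu[exact])
    if not candidates:
        raise ValueError("no sign change of mean velocity in the swept range")
    # With multiple crossings (noise), report the one nearest the origin.
    return float(min(candidates, key=abs))


def _retained(ens: TrajectoryEnsemble, burn_in: int | None) -> slice:
    if burn_in is None:
        return ens.retained_slice()
    keep = ens.config.store_every
    first = burn_in // keep
    if first >= ens.v.shape[1] - 1:
        raise ValueError("burn-in leaves no retained samples")
    return slice(first + 1, None)


def summarize(ens: TrajectoryEnsemble, burn_in: int | None = None) -> ObservableSummary:
    """All scalar observables of one ensemble in a single record."""
    sl = _retained(ens, burn_in)
    retained = ens.v[:, sl].shape[1]
    if ens.e is not None:
        e_est, conv_est = depot_observables(ens, burn_in)
    else:
        e_est = conv_est = None
    return ObservableSummary(
        mean_v=mean_velocity(ens, burn_in),
        mean_x_final=mean_position(ens, -1),
        D_eff=effective_diffusion(ens),
        depot_mean_e=e_est,
        depot_conversion_rate=conv_est,
        n_traj=ens.n_traj,
        retained_steps=retained,
        clamp_count=ens.clamp_count,
    )
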