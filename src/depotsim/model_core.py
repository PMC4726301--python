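"""Deterministic skeleton of the energy-depot model of active Brownian motion.

A particle of unit mass carries an internal energy depot ``e(t)`` that gains
energy from the environment at a constant flux ``q``, leaks it by internal
dissipation at rate ``c`` and converts it into kinetic energy at rate
``d2 * v**2``.  Adiabatic elimination of the fast depot variable yields a
closed velocity equation with the nonlinear drag

    gamma(v) = gamma0 - d2 * q / (c + d2 * v**2),

which is negative at small speeds in the active regime (``d2*q > gamma0*c``):
slow particles are accelerated, fast ones are damped.  The associated
deterministic velocity potential is a double well with stable states at
``v = +/- sqrt(q/gamma0 - c/d2)`` separated by an unstable state at ``v = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelParams",
    "FixedPoints",
    "PAPER_PARAMS",
    "depot_rhs",
    "quasistationary_depot",
    "drag_coefficient",
    "deterministic_force",
    "deterministic_potential",
    "fixed_points",
]


@dataclass(frozen=True)
class ModelParams:
    """Physical constants of the depot model.

    Parameters
    ----------
    gamma0
        Stokes drag coefficient (per unit time), > 0.
    q
        Energy influx rate into the depot, >= 0.
    c
        Internal dissipation rate of the depot (per unit time), > 0.
    d2
        Depot-to-kinetic conversion rate coefficient, > 0.
    """

    gamma0: float = 20.0
    q: float = 2.0
    c: float = 0.01
    d2: float = 1.0

    def __post_init__(self) -> None:
        if not self.gamma0 > 0:
            raise ValueError(f"gamma0 must be > 0, got {self.gamma0}")
        if not self.q >= 0:
            raise ValueError(f"q must be >= 0, got {self.q}")
        if not self.c > 0:
            raise ValueError(f"c must be > 0, got {self.c}")
        if not self.d2 > 0:
            raise ValueError(f"d2 must be > 0, got {self.d2}")

    @property
    def active_regime(self) -> bool:
        """True when depot pumping beats drag, i.e. ``d2*q > gamma0*c``."""
        return self.d2 * self.q > self.gamma0 * self.c

    def to_dict(self) -> dict[str, float]:
        return {"gamma0": self.gamma0, "q": self.q, "c": self.c, "d2": self.d2}


#: Reference parameter set used throughout the accompanying experiments.
PAPER_PARAMS = ModelParams(gamma0=20.0, q=2.0, c=0.01, d2=1.0)


@dataclass(frozen=True)
class FixedPoints:
    """Equilibria of the reduced deterministic velocity dynamics.

    ``v_unstable`` is always 0.  In the active (bistable) regime the stable
    pair ``v_minus = -v_plus`` exists; otherwise both are ``None``.
    """

    v_unstable: float
    v_minus: float | None
    v_plus: float | None
    exists_bistable: bool


def depot_rhs(e, v, p: ModelParams):
    """Rate of change of the depot energy: ``q - c*e - d2*v**2*e``.

    Raises
    ------
    ValueError
        If any depot energy is negative (the depot is physically
        nonnegative).
    """
    e = np.asarray(e, dtype=float)
    if np.any(e < 0):
        raise ValueError("depot energy must be nonnegative")
    v = np.asarray(v, dtype=float)
    return p.q - p.c * e - p.d2 * v**2 * e


def quasistationary_depot(v, p: ModelParams):
    """Quasi-stationary depot energy ``q / (c + d2*v**2)``.

    This is the fast-variable equilibrium obtained by setting ``de/dt = 0``;
    it is even in ``v``, strictly positive for ``q > 0`` and decreasing in
    ``|v|``.
    """
    v = np.asarray(v, dtype=float)
    return p.q / (p.c + p.d2 * v**2)


def drag_coefficient(v, p: ModelParams):
    """Effective nonlinear drag ``gamma(v) = gamma0 - d2*q/(c + d2*v**2)``.

    Negative near ``v = 0`` in the active regime (energy pumping) and
    approaching ``gamma0`` as ``|v| -> inf``.
    """
    v = np.asarray(v, dtype=float)
    return p.gamma0 - p.d2 * p.q / (p.c + p.d2 * v**2)


def deterministic_force(v, p: ModelParams):
    """Deterministic drag force ``f(v) = -gamma(v) * v`` (odd in ``v``)."""
    v = np.asarray(v, dtype=float)
    return -drag_coefficient(v, p) * v


def deterministic_potential(v, p: ModelParams):
    """Deterministic velocity potential ``U(v)`` with ``U(0) = 0``.

    ``U(v) = gamma0*v**2/2 - (q/2) * log(1 + d2*v**2/c)``, which satisfies
    ``-dU/dv = f(v)``.  Only potential differences are physical; the additive
    constant is fixed by the ``U(0) = 0`` convention.
    """
    v = np.asarray(v, dtype=float)
    return 0.5 * p.gamma0 * v**2 - 0.5 * p.q * np.log1p(p.d2 * v**2 / p.c)


def fixed_points(p: ModelParams) -> FixedPoints:
    """Equilibria of ``dv/dt = f(v)`` and their stability.

    ``v = 0`` is always an equilibrium; it is unstable exactly when the
    active-regime condition ``d2*q > gamma0*c`` holds, in which case the
    stable pair ``+/- sqrt(q/gamma0 - c/d2)`` appears.  The non-bistable
    regime is a valid return (single fixed point), not an error, so parameter
    sweeps may cross the bifurcation.
    """
    if p.active_regime:
        v_star = float(np.sqrt(p.q / p.gamma0 - p.c / p.d2))
        return FixedPoints(v_unstable=0.0, v_minus=-v_star, v_plus=v_star,
                           exists_bistable=True)
    return FixedPoints(v_unstable=0.0, v_minus=None, v_plus=None,
                       exists_bistable=False)
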