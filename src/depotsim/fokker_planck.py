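"""Fokker-Planck layer for the reduced correlated-noise velocity dynamics.

The reduced Langevin equation

    dv/dt = f(v) - v * eta1(t) + eta2(t)

couples a multiplicative Gaussian white noise ``eta1`` (random variation of
the drag coefficient, coupling ``h1(v) = -v``, intensity ``M1``) and an
additive one ``eta2`` (internal agitation, ``h2(v) = 1``, intensity ``M2``)
with instantaneous cross-correlation intensity ``mu`` in [-1, 1], i.e.
``<eta_i(t) eta_j(t')> = 2 M_ij delta(t - t')`` with ``M12 = mu*sqrt(M1*M2)``.

Under the Stratonovich convention the associated Fokker-Planck equation has
drift and diffusion functions

    F(v) = f(v) + M1*v - mu*sqrt(M1*M2)
    G(v) = M1*v**2 - 2*mu*sqrt(M1*M2)*v + M2

and the stationary velocity density is ``Q_st(v) = N * exp(-U_FP(v))`` with
the effective potential

    U_FP(v) = log G(v) - int_0^v F(u)/G(u) du.

For ``mu != 0`` the cross term breaks the ``v -> -v`` symmetry of ``U_FP``,
tilting the double well and producing a nonzero net velocity; at ``|mu| = 1``
the diffusion ``G`` has a double root where the density formula is singular.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import ModelParams, deterministic_force

__all__ = [
    "NoiseParams",
    "StationarySolution",
    "DegenerateNoiseError",
    "TruncationError",
    "diffusion_G",
    "diffusion_G_prime",
    "drift_F",
    "effective_potential",
    "stationary_distribution",
    "stationary_moments",
    "stationarity_residual",
    "default_grid",
]


class DegenerateNoiseError(ValueError):
    """Raised when the diffusion function vanishes on the requested grid
    (perfect correlation ``|mu| = 1`` crossing the root of G)."""


class TruncationError(ValueError):
    """Raised when the velocity grid is too narrow to hold the stationary
    density (non-negligible boundary mass even after auto-widening)."""


@dataclass(frozen=True)
class NoiseParams:
    """Intensities of the two white noises and their cross-correlation.

    ``M1`` multiplicative (drag-fluctuation) intensity, ``M2`` additive
    intensity, both >= 0; ``mu`` in [-1, 1] is the normalized instantaneous
    cross-correlation (0 independent, +/-1 perfectly correlated).
    """

    M1: float
    M2: float
    mu: float = 0.0

    def __post_init__(self) -> None:
        if not self.M1 >= 0:
            raise ValueError(f"M1 must be >= 0, got {self.M1}")
        if not self.M2 >= 0:
            raise ValueError(f"M2 must be >= 0, got {self.M2}")
        if not -1.0 <= self.mu <= 1.0:
            raise ValueError(f"mu must lie in [-1, 1], got {self.mu}")

    @property
    def M12(self) -> float:
        """Cross intensity ``mu * sqrt(M1*M2)`` (satisfies M12^2 <= M1*M2)."""
        return self.mu * float(np.sqrt(self.M1 * self.M2))

    def mirrored(self) -> "NoiseParams":
        """The parameter set with the sign of the cross-correlation flipped."""
        return NoiseParams(M1=self.M1, M2=self.M2, mu=-self.mu)

    def to_dict(self) -> dict[str, float]:
        return {"M1": self.M1, "M2": self.M2, "mu": self.mu}


@dataclass(frozen=True)
class StationarySolution:
    """Stationary velocity density of the reduced dynamics on a grid."""

    grid: np.ndarray
    U_FP: np.ndarray
    Q_st: np.ndarray
    norm_constant: float
    mean_v: float
    mode_pair: tuple[float, ...] = field(default_factory=tuple)


def diffusion_G(v, n: NoiseParams):
    """Effective diffusion function ``G(v) = M1*v^2 - 2*M12*v + M2``.

    Strictly positive for ``|mu| < 1`` when both intensities are positive
    (the discriminant is ``4*M1*M2*(mu^2 - 1) < 0``); at ``|mu| = 1`` it is a
    perfect square with a double root at ``v = sign(mu)*sqrt(M2/M1)``.
    """
    v = np.asarray(v, dtype=float)
    return n.M1 * v**2 - 2.0 * n.M12 * v + n.M2


def diffusion_G_prime(v, n: NoiseParams):
    """Derivative ``G'(v) = 2*M1*v - 2*M12``."""
    v = np.asarray(v, dtype=float)
    return 2.0 * n.M1 * v - 2.0 * n.M12


def drift_F(v, p: ModelParams, n: NoiseParams):
    """Effective drift ``F(v) = f(v) + M1*v - M12``.

    ``M1*v`` is the Stratonovich noise-induced drift of the multiplicative
    coupling; at ``mu = 0`` the additive noise contributes no drift at all.
    """
    v = np.asarray(v, dtype=float)
    return deterministic_force(v, p) + n.M1 * v - n.M12


def _g_root(n: NoiseParams) -> float | None:
    """Location of the double root of G at perfect correlation, else None."""
    if abs(n.mu) == 1.0 and n.M1 > 0:
        return float(np.sign(n.mu) * np.sqrt(n.M2 / n.M1))
    return None


# Gauss-Legendre panel rule used for the cumulative integral of F/G.  Eight
# nodes per grid cell make the quadrature error negligible next to the
# trapezoidal normalization of the density.
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(8)


def _cumulative_from_zero(func, grid: np.ndarray) -> np.ndarray:
    """``int_0^{v_i} func(u) du`` for every point of a sorted grid.

    Panel-wise Gauss-Legendre over the grid cells plus one extra panel from
    the origin to its nearest grid neighbour; the origin need not be a grid
    point.
    """

    def panels(a: np.ndarray, b: np.ndarray) -> np.ndarray:
        half = 0.5 * (b - a)
        mid = 0.5 * (b + a)
        u = mid[:, None] + half[:, None] * _GL_NODES[None, :]
        return half * (func(u) @ _GL_WEIGHTS)

    seg = panels(grid[:-1], grid[1:])
    prefix = np.concatenate(([0.0], np.cumsum(seg)))  # int_{grid[0]}^{v_i}
    # int_{grid[0]}^{0}: bridge from the last grid point at or below zero.
    k = int(np.searchsorted(grid, 0.0, side="right") - 1)
    k = min(max(k, 0), len(grid) - 1)
    to_zero = prefix[k] + panels(np.array([grid[k]]), np.array([0.0]))[0]
    return prefix - to_zero


def effective_potential(grid, p: ModelParams, n: NoiseParams) -> np.ndarray:
    """Effective potential ``U_FP(v) = log G(v) - int_0^v F/G du`` on a grid,
    shifted so that ``U_FP(0) = 0``.

    ``exp(-U_FP)`` is proportional to the stationary velocity density.

    Raises
    ------
    DegenerateNoiseError
        If the grid range contains a zero of ``G`` (``|mu| = 1`` crossing the
        degenerate point), where the integrand ``F/G`` is non-integrable in
        the sense of this closed form.
    """
    grid = np.asarray(grid, dtype=float)
    g = diffusion_G(grid, n)
    if np.any(g <= 0):
        raise DegenerateNoiseError(
            "diffusion function G vanishes on the grid (|mu| = 1); "
            "use a grid on one side of the G-root"
        )
    root = _g_root(n)
    lo, hi = float(grid[0]), float(grid[-1])
    if root is not None and lo < root < hi:
        raise DegenerateNoiseError(
            f"grid straddles the G-root at v = {root:.6g} (|mu| = 1); "
            "restrict the grid to one side of the root"
        )

    def integrand(u):
        return drift_F(u, p, n) / diffusion_G(u, n)

    u_fp = np.log(g) - _cumulative_from_zero(integrand, grid)
    # Anchor U_FP(0) = 0 (the integral already vanishes at the origin).
    u_fp -= np.log(diffusion_G(0.0, n))
    return u_fp


def default_grid(half_width: float = 1.2, n_points: int = 2001) -> np.ndarray:
    """Symmetric uniform velocity grid, by default [-1.2, 1.2] with 2001
    points — wide margins around the deterministic wells at the reference
    parameters."""
    return np.linspace(-half_width, half_width, n_points)


def _boundary_mass(grid: np.ndarray, q: np.ndarray) -> float:
    h0 = grid[1] - grid[0]
    h1 = grid[-1] - grid[-2]
    return float(0.5 * (q[0] + q[1]) * h0 + 0.5 * (q[-2] + q[-1]) * h1)


def _one_sided_grid(grid: np.ndarray, n: NoiseParams) -> np.ndarray:
    """Restrict a grid straddling the |mu|=1 G-root to the side of the root
    that contains the origin (and the occupied well)."""
    root = _g_root(n)
    if root is None:
        return grid
    # Drop the root's side away from the origin, plus a safety margin where
    # G underflows.
    h = grid[1] - grid[0]
    if root > 0:
        kept = grid[grid < root - h]
    else:
        kept = grid[grid > root + h]
    if kept.size < 10 or not (kept[0] < 0.0 < kept[-1]):
        raise DegenerateNoiseError(
            "cannot build a one-sided grid containing the origin for |mu| = 1"
        )
    return kept


def stationary_distribution(
    grid,
    p: ModelParams,
    n: NoiseParams,
    *,
    auto_widen: bool = True,
    boundary_tol: float = 1e-8,
    max_widen: int = 6,
) -> StationarySolution:
    """Normalized stationary velocity density ``Q_st = exp(-U_FP)/N``.

    The normalization ``N`` is a trapezoidal quadrature over the grid.  If
    the density mass in the outermost grid cells exceeds ``boundary_tol`` the
    grid is widened geometrically (up to ``max_widen`` times) before a
    :class:`TruncationError` is raised.  At perfect correlation the grid is
    truncated to the side of the G-root containing the origin, where all the
    stationary mass lives.
    """
    grid = np.asarray(grid, dtype=float)
    if n.M1 == 0 and n.M2 == 0:
        raise ValueError("no stationary density without noise (M1 = M2 = 0)")
    degenerate = _g_root(n) is not None

    for _ in range(max_widen + 1):
        work = _one_sided_grid(grid, n) if degenerate else grid
        u_fp = effective_potential(work, p, n)
        # Work in shifted log-density for overflow safety.
        q_unnorm = np.exp(-(u_fp - u_fp.min()))
        norm = float(np.trapezoid(q_unnorm, work))
        q_st = q_unnorm / norm
        if degenerate or not auto_widen:
            break
        if _boundary_mass(work, q_st) <= boundary_tol:
            break
        half_width = 1.5 * max(abs(grid[0]), abs(grid[-1]))
        grid = default_grid(half_width, int(1.5 * (len(grid) - 1)) + 1)
    else:
        raise TruncationError(
            "stationary density has non-negligible boundary mass; "
            f"widen the grid beyond [{grid[0]:.3g}, {grid[-1]:.3g}]"
        )

    mean_v = float(np.trapezoid(work * q_st, work))
    modes = _local_maxima(work, q_st)
    return StationarySolution(
        grid=work,
        U_FP=u_fp,
        Q_st=q_st,
        norm_constant=norm * float(np.exp(u_fp.min())),
        mean_v=mean_v,
        mode_pair=modes,
    )


def _local_maxima(grid: np.ndarray, q: np.ndarray) -> tuple[float, ...]:
    interior = (q[1:-1] > q[:-2]) & (q[1:-1] >= q[2:])
    return tuple(float(v) for v in grid[1:-1][interior])


def stationary_moments(sol: StationarySolution, k: int) -> float:
    """k-th moment ``int v^k Q_st(v) dv`` by trapezoidal quadrature.

    ``k = 1`` is the analytic counterpart of the simulated mean velocity.
    """
    return float(np.trapezoid(sol.grid**k * sol.Q_st, sol.grid))


def stationarity_residual(
    sol: StationarySolution, p: ModelParams, n: NoiseParams
) -> float:
    """Max residual of the zero-flux identity ``d/dv [G*Q_st] - F*Q_st = 0``,
    relative to the flux scale ``max |F*Q_st|``.

    The derivative is a fourth-order central difference on the interior of
    the uniform grid, so for smooth parameter sets the residual reflects the
    quadrature accuracy of ``U_FP``, not the differencing.
    """
    v, q = sol.grid, sol.Q_st
    h = v[1] - v[0]
    gq = diffusion_G(v, n) * q
    # 5-point stencil: (-f2 + 8f1 - 8f_1 + f_2) / (12h)
    d = (-gq[4:] + 8.0 * gq[3:-1] - 8.0 * gq[1:-3] + gq[:-4]) / (12.0 * h)
    flux = drift_F(v[2:-2], p, n) * q[2:-2]
    scale = float(np.max(np.abs(flux)))
    if scale == 0.0:
        scale = 1.0
    return float(np.max(np.abs(d - flux)) / scale)
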