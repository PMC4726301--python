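"""Configuration, sweep orchestration and tabular outputs.

Regenerates the figure experiments of the depot model at a configurable
scale: mean-velocity / mean-position / depot sweeps over the noise
parameters (stochastic ensembles of the full system), effective-potential
and stationary-density tables (analytic layer), effective-diffusion sweeps,
and an SDE-versus-Fokker-Planck agreement report.

Every emitted row carries full provenance (all parameters, the seed, the
package version and the variant), so any row can be recomputed exactly from
its own metadata.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fokker_planck import (
    NoiseParams,
    default_grid,
    stationary_distribution,
)
from .integrators import (
    PAPER_SCALE,
    TEST_SCALE,
    SimulationConfig,
    run_ensemble,
)
from .model_core import ModelParams
from .observables import summarize

__all__ = [
    "SweepSpec",
    "load_config",
    "dump_config",
    "run_sweep",
    "run_fpe",
    "compare_sde_fpe",
    "preset",
    "PRESET_NAMES",
]

log = logging.getLogger("depotsim")

#: Caption-faithful defaults of the reference experiments.
DEFAULTS = {
    "model": {"gamma0": 20.0, "q": 2.0, "c": 0.01, "d2": 1.0},
    "noise": {"M1": 0.5, "M2": 0.05, "mu": 0.0},
    "simulation": dict(SimulationConfig(dt=0.01, n_traj=500,
                                        n_steps=100_000,
                                        burn_in_steps=20_000).to_dict()),
}

_SWEEPABLE = ("mu", "M1", "M2")


@dataclass(frozen=True)
class SweepSpec:
    """One sweep: a parameter, its values, and everything held fixed."""

    swept_parameter: str
    values: tuple[float, ...]
    model: ModelParams = field(default_factory=ModelParams)
    noise: NoiseParams = field(default_factory=lambda: NoiseParams(0.5, 0.05))
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    label: str = "sweep"

    def __post_init__(self) -> None:
        if self.swept_parameter not in _SWEEPABLE:
            raise ValueError(
                f"swept_parameter must be one of {_SWEEPABLE}, "
                f"got {self.swept_parameter!r}"
            )
        if len(self.values) == 0:
            raise ValueError("values must be nonempty")
        for val in self.values:
            _check_noise_value(self.swept_parameter, val)

    def noise_at(self, value: float) -> NoiseParams:
        return NoiseParams(**{**self.noise.to_dict(),
                              self.swept_parameter: float(value)})


def _check_noise_value(key: str, value: float) -> None:
    if key == "mu" and not -1.0 <= value <= 1.0:
        raise ValueError(f"mu must lie in [-1, 1], got {value}")
    if key in ("M1", "M2") and value < 0:
        raise ValueError(f"{key} must be >= 0, got {value}")


# ---------------------------------------------------------------------------
# configuration files


def _build_section(section: str, data: dict, cls):
    legal = {f.name for f in dataclasses.fields(cls)}
    for key in data:
        if key not in legal:
            raise ValueError(
                f"unknown key {key!r} in section {section!r}; "
                f"legal keys: {sorted(legal)}"
            )
    merged = {**DEFAULTS.get(section, {}), **data}
    if cls is SimulationConfig:
        for tup in ("v_bounds", "x_bounds"):
            if tup in merged:
                merged[tup] = tuple(merged[tup])
    return cls(**merged)


def load_config(path) -> tuple[ModelParams, NoiseParams, SimulationConfig,
                               SweepSpec | None]:
    """Read and validate a YAML config, filling reference defaults for
    omitted fields.

    Sections: ``model`` (gamma0, q, c, d2), ``noise`` (M1, M2, mu),
    ``simulation`` (integrator settings) and optionally ``sweep``
    (``swept_parameter``, ``values``, ``label``).  Unknown keys and
    out-of-range values raise :class:`ValueError` naming the key.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {"model", "noise", "simulation", "sweep"}
    for key in raw:
        if key not in known:
            raise ValueError(f"unknown config section {key!r}; "
                             f"legal sections: {sorted(known)}")
    model = _build_section("model", raw.get("model", {}), ModelParams)
    noise = _build_section("noise", raw.get("noise", {}), NoiseParams)
    sim = _build_section("simulation", raw.get("simulation", {}),
                         SimulationConfig)
    sweep = None
    if "sweep" in raw:
        sw = dict(raw["sweep"])
        legal = {"swept_parameter", "values", "label"}
        for key in sw:
            if key not in legal:
                raise ValueError(f"unknown key {key!r} in section 'sweep'; "
                                 f"legal keys: {sorted(legal)}")
        sweep = SweepSpec(
            swept_parameter=sw["swept_parameter"],
            values=tuple(float(v) for v in sw["values"]),
            model=model, noise=noise, sim=sim,
            label=sw.get("label", "sweep"),
        )
    return model, noise, sim, sweep


def dump_config(model: ModelParams, noise: NoiseParams,
                sim: SimulationConfig, sweep: SweepSpec | None = None) -> str:
    """Serialize a configuration back to YAML (round-trips with
    :func:`load_config`)."""
    doc: dict = {
        "model": model.to_dict(),
        "noise": noise.to_dict(),
        "simulation": sim.to_dict(),
    }
    if sweep is not None:
        doc["sweep"] = {
            "swept_parameter": sweep.swept_parameter,
            "values": list(sweep.values),
            "label": sweep.label,
        }
    return yaml.safe_dump(doc, sort_keys=True)


# ---------------------------------------------------------------------------
# sweep execution


def _point_seed(master: int, label: str, value: float) -> int:
    """Deterministic per-point seed derived from the master seed and the
    parameter point (stable across processes and sweep order)."""
    tag = zlib.crc32(f"{label}:{float(value):.12g}".encode())
    h = np.random.SeedSequence([int(master), int(tag)])
    return int(h.generate_state(1)[0] % (2**31))


def run_sweep(spec: SweepSpec, seed: int | None = None) -> pd.DataFrame:
    """Run one ensemble per swept value and return a tidy results table.

    Columns: all parameters, the swept value, every scalar observable with
    its standard error, and provenance (seed, variant, package version).
    Deterministic under a fixed master seed.
    """
    master = spec.sim.seed if seed is None else seed
    rows = []
    for value in spec.values:
        noise = spec.noise_at(value)
        cfg = replace(spec.sim, seed=_point_seed(master, spec.label, value))
        t0 = time.perf_counter()
        ens = run_ensemble(cfg, spec.model, noise)
        summ = summarize(ens)
        elapsed = time.perf_counter() - t0
        row = {
            "label": spec.label,
            "swept_parameter": spec.swept_parameter,
            "swept_value": float(value),
            **spec.model.to_dict(),
            **noise.to_dict(),
            "variant": cfg.variant,
            "seed": cfg.seed,
            "n_traj": cfg.n_traj,
            "n_steps": cfg.n_steps,
            "dt": cfg.dt,
            "mean_v": summ.mean_v.value,
            "mean_v_se": summ.mean_v.se,
            "mean_x_final": summ.mean_x_final.value,
            "mean_x_final_se": summ.mean_x_final.se,
            "D_eff": summ.D_eff.value,
            "D_eff_se": summ.D_eff.se,
            "clamp_count": summ.clamp_count,
            "package_version": __version__,
        }
        if summ.depot_mean_e is not None:
            row["depot_mean_e"] = summ.depot_mean_e.value
            row["depot_mean_e_se"] = summ.depot_mean_e.se
            row["depot_conversion_rate"] = summ.depot_conversion_rate.value
            row["depot_conversion_rate_se"] = summ.depot_conversion_rate.se
        rows.append(row)
        log.info(
            "%s %s=%g: mean_v=%.4f D_eff=%.4g clamps=%d (%.1fs)",
            spec.label, spec.swept_parameter, value,
            row["mean_v"], row["D_eff"], row["clamp_count"], elapsed,
        )
    return pd.DataFrame(rows)


def run_fpe(
    combos,
    model: ModelParams | None = None,
    grid=None,
) -> pd.DataFrame:
    """Analytic tables: one block of ``(v, U_FP, Q_st)`` per noise-parameter
    combination.

    ``combos`` is an iterable of :class:`NoiseParams`.  Degenerate-noise
    errors (a ``|mu| = 1`` grid crossing the zero of G) propagate to the
    caller.
    """
    model = model or ModelParams()
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    blocks = []
    for noise in combos:
        sol = stationary_distribution(grid, model, noise)
        blocks.append(pd.DataFrame({
            "M1": noise.M1, "M2": noise.M2, "mu": noise.mu,
            "v": sol.grid, "U_FP": sol.U_FP, "Q_st": sol.Q_st,
            "package_version": __version__,
        }))
    return pd.concat(blocks, ignore_index=True)


def compare_sde_fpe(
    model: ModelParams,
    noise: NoiseParams,
    sim: SimulationConfig | None = None,
    seed: int = 0,
) -> dict:
    """Agreement report between the reduced SDE and the stationary
    Fokker-Planck density.

    Runs a stationary-initialized reduced ensemble, pools the retained
    velocities and reports the one-sample Kolmogorov-Smirnov distance to
    ``Q_st`` together with the first-moment difference and its standard
    error.  Initializing from the stationary law makes the comparison a
    measure-preservation test of the integrator, which remains meaningful in
    the metastable regime where a uniform start cannot reach the stationary
    well weights within any feasible horizon.

    Raises
    ------
    ValueError
        For ``M1 = M2 = 0`` (no stationary density) or ``|mu| = 1`` (the
        density is degenerate at the zero of G).
    """
    if noise.M1 == 0 and noise.M2 == 0:
        raise ValueError("no stationary density without noise (M1 = M2 = 0)")
    if abs(noise.mu) >= 1.0:
        raise ValueError("compare_sde_fpe requires |mu| < 1")
    from scipy import stats

    sim = sim or SimulationConfig(
        dt=0.01, n_steps=12_500, n_traj=200, burn_in_steps=2_500,
        variant="reduced", v_init="stationary",
    )
    sim = replace(sim, variant="reduced", v_init="stationary", seed=seed)
    sol = stationary_distribution(default_grid(), model, noise)
    cdf = np.concatenate(
        ([0.0], np.cumsum(0.5 * (sol.Q_st[1:] + sol.Q_st[:-1])
                          * np.diff(sol.grid)))
    )
    cdf /= cdf[-1]
    ens = run_ensemble(sim, model, noise)
    samples = ens.v[:, ens.retained_slice()].ravel()
    ks = stats.ks_1samp(samples,
                        lambda x: np.interp(x, sol.grid, cdf))
    per_traj = ens.v[:, ens.retained_slice()].mean(axis=1)
    mean_diff = float(per_traj.mean() - sol.mean_v)
    se = float(per_traj.std(ddof=1) / np.sqrt(len(per_traj)))
    return {
        "ks_distance": float(ks.statistic),
        "mean_v_sim": float(per_traj.mean()),
        "mean_v_fpe": float(sol.mean_v),
        "mean_diff": mean_diff,
        "mean_diff_se": se,
        "n_samples": int(samples.size),
        "n_traj": ens.n_traj,
    }


# ---------------------------------------------------------------------------
# figure presets

_MU_GRID = (-0.9, -0.6, -0.3, 0.0, 0.3, 0.6, 0.9)
_M1_GRID = (0.01, 0.5, 1.0, 2.0, 3.0)
_M2_GRID = (0.05, 0.1, 0.2)

PRESET_NAMES = (
    "fig1", "fig2", "fig3", "fig4", "fig5", "fig6a", "fig6b",
    "fig7", "fig8", "fig9", "fig10a", "fig10b",
)


def _scale_cfg(scale: str, variant: str, **overrides) -> SimulationConfig:
    base = PAPER_SCALE if scale == "paper" else TEST_SCALE
    kw = dict(dt=base["dt"], n_steps=base["n_steps"], n_traj=base["n_traj"],
              burn_in_steps=base["n_steps"] // 5, variant=variant)
    kw.update(overrides)
    return SimulationConfig(**kw)


def preset(name: str, scale: str = "test"):
    """Caption-faithful experiment presets.

    Stochastic presets return a list of :class:`SweepSpec`; the analytic
    presets (fig5, fig6a, fig6b) return a list of :class:`NoiseParams`
    combinations for :func:`run_fpe`.  ``scale`` is ``"test"`` (reduced
    desk scale, the default) or ``"paper"`` (500 trajectories of 1e5 steps).

    The depot and transport figures (1-4, 7-9) simulate the full system;
    the effective-diffusion figures (10a, 10b) use the reduced dynamics
    started from the stationary law, whose late-time position variance
    defines the diffusive spread about the drift.
    """
    model = ModelParams()
    full = lambda: _scale_cfg(scale, "full")  # noqa: E731
    red_st = lambda: _scale_cfg(scale, "reduced", v_init="stationary")  # noqa: E731

    if name in ("fig1", "fig2"):
        return [
            SweepSpec("mu", _MU_GRID, model, NoiseParams(M1, 0.05, 0.0),
                      full(), label=f"{name}_M1={M1}")
            for M1 in (0.01, 2.0)
        ]
    if name == "fig3":
        return [
            SweepSpec("M1", _M1_GRID, model, NoiseParams(0.01, 0.05, mu),
                      full(), label=f"fig3_mu={mu}")
            for mu in (-0.9, -0.5, 0.0, 0.5, 0.9)
        ]
    if name == "fig4":
        return [
            SweepSpec("M2", _M2_GRID, model, NoiseParams(M1, 0.05, mu),
                      full(), label=f"fig4_M1={M1}_mu={mu}")
            for M1 in (0.01, 2.0)
            for mu in (-0.9, -0.5, 0.0, 0.5, 0.9)
        ]
    if name == "fig5":
        return [NoiseParams(0.5, 0.05, mu) for mu in (-0.5, 0.0, 0.5)]
    if name == "fig6a":
        return [NoiseParams(M1, 0.05, 0.5) for M1 in (0.01, 2.0, 3.0)]
    if name == "fig6b":
        return [NoiseParams(2.0, M2, 0.5) for M2 in (0.05, 0.1, 0.2)]
    if name == "fig7":
        return [
            SweepSpec("mu", _MU_GRID, model, NoiseParams(M1, 0.05, 0.0),
                      full(), label=f"fig7_M1={M1}")
            for M1 in (0.01, 1.0, 2.0)
        ]
    if name == "fig8":
        return [
            SweepSpec("M1", _M1_GRID, model, NoiseParams(0.01, 0.05, mu),
                      full(), label=f"fig8_mu={mu}")
            for mu in (0.5, 0.9)
        ]
    if name == "fig9":
        return [
            SweepSpec("M2", _M2_GRID, model, NoiseParams(0.01, 0.05, mu),
                      full(), label=f"fig9_mu={mu}")
            for mu in (0.5, 0.9)
        ]
    if name == "fig10a":
        return [
            SweepSpec("mu", (-1.0, -0.5, 0.0, 0.5, 1.0), model,
                      NoiseParams(M1, 0.05, 0.0), red_st(),
                      label=f"fig10a_M1={M1}")
            for M1 in (0.5, 2.0, 3.0)
        ]
    if name == "fig10b":
        return [
            SweepSpec("mu", (-1.0, -0.5, 0.0, 0.5, 1.0), model,
                      NoiseParams(0.5, M2, 0.0), red_st(),
                      label=f"fig10b_M2={M2}")
            for M2 in (0.05, 0.1, 0.2)
        ]
    raise ValueError(f"unknown preset {name!r}; known: {PRESET_NAMES}")


def run_preset(name: str, scale: str = "test",
               seed: int = 0) -> pd.DataFrame:
    """Run a preset end to end and return its results table."""
    specs = preset(name, scale)
    if specs and isinstance(specs[0], NoiseParams):
        return run_fpe(specs)
    return pd.concat([run_sweep(s, seed=seed) for s in specs],
                     ignore_index=True)


def write_results(df: pd.DataFrame, out_dir, stem: str,
                  provenance: dict | None = None) -> Path:
    """Write a results table as CSV plus a JSON provenance sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / f"{stem}.csv"
    df.to_csv(csv_path, index=False, lineterminator="\n")
    sidecar = {
        "package_version": __version__,
        "rows": int(len(df)),
        **(provenance or {}),
    }
    (out / f"{stem}.json").write_text(json.dumps(sidecar, indent=2) + "\n")
    return csv_path


def setup_logging(json_lines: bool = False) -> None:
    """One stderr line per parameter point; JSON-lines format on request."""
    handler = logging.StreamHandler(sys.stderr)
    if json_lines:
        handler.setFormatter(logging.Formatter(
            '{"logger": "%(name)s", "level": "%(levelname)s", '
            '"message": "%(message)s"}'
        ))
    else:
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(logging.INFO)
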