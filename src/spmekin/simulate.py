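"""Synthetic triplicate extraction-time profiles.

The generator emulates the data the fitting pipeline expects: triplicate
rise/overshoot/plateau profiles on a sparse minute-scale grid, with
per-replicate kinetic jitter and multiplicative lognormal measurement noise
(GC peak areas are positive and roughly constant-CV).

Replicate jitter is applied to the structural degrees of freedom of the
curve — the adsorption amplitude k1, the plateau C_inf = k1 - k2, the
adsorption time constant tau1 and the separation tau2 - tau1 — with
k2 = k1 - C_inf and tau2 = tau1 + dtau.  Jittering the members of either
nearly-equal pair independently would make their tiny difference (the
plateau, or the separation that scales the overshoot) swing by hundreds of
percent between replicates, which is nothing like the replicate
reproducibility of real extraction profiles.

``preset_scenarios`` exposes one scenario per row of the embedded reference
table of fitted beverage/chewing-gum compounds (scaled so C_inf = 1); those
parameter presets are simulation inputs and test fixtures, not fitting
targets.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .kinetics import MIN_TAU_SEPARATION, KineticParams, net_conc
from .profiles import ExtractionProfile, ReplicateSet

__all__ = [
    "BEVERAGE_GRID",
    "GUM_GRID",
    "REFERENCE_TABLE",
    "SimScenario",
    "generate_replicates",
    "preset_scenarios",
    "scenario_from_toml",
    "scenario_to_toml",
    "truncated",
]

#: Default sampling grids (minutes).  Beverage profiles run to the 300-min
#: validation point, chewing-gum profiles to the 20-min one.
BEVERAGE_GRID: tuple[float, ...] = (5, 10, 20, 30, 45, 60, 90, 120, 180, 240, 300)
GUM_GRID: tuple[float, ...] = (1, 2, 3, 5, 8, 12, 16, 20)

# Published two-loop fits for the beverage and chewing-gum model systems:
# optimized weighting factor W, summed parameter RSD F (%), raw-scale
# parameter averages with their RSDs (%), and total RMSE of the triplicate.
_REFERENCE_ROWS = [
    # system, compound, temperature_c, W, F_percent, k1, rsd_k1, k2, rsd_k2,
    # tau1, rsd_tau1, tau2, rsd_tau2, rmse
    ("beverage", "ethyl hexanoate", 30, 5.95, 13.48, 3.11e9, 2.41, 3.10e9, 2.36, 13.34, 4.33, 13.50, 4.37, 0.17),
    ("beverage", "hexyl acetate", 30, 326.38, 15.33, 1.77e9, 3.62, 1.75e9, 3.52, 21.93, 4.15, 22.44, 4.04, 0.10),
    ("beverage", "cis-3-hexenyl acetate", 30, 199.50, 7.16, 4.06e9, 3.54, 4.04e9, 3.56, 22.00, 0.00, 22.09, 0.05, 0.08),
    ("beverage", "allyl hexanoate", 30, 1.15, 3.61, 6.23e9, 1.09, 6.18e9, 1.03, 47.96, 0.77, 48.40, 0.72, 0.09),
    ("beverage", "ethyl octanoate", 30, 304.83, 8.89, 6.93e9, 2.36, 6.85e9, 2.26, 106.94, 2.39, 108.82, 1.87, 0.06),
    ("beverage", "isoamyl hexanoate", 30, 349.99, 7.52, 9.27e9, 3.58, 9.17e9, 3.65, 113.10, 0.29, 115.00, 0.00, 0.05),
    ("beverage", "ethyl hexanoate", 40, 3.53, 2.55, 2.58e9, 0.36, 2.57e9, 0.35, 13.63, 0.87, 13.80, 0.98, 0.19),
    ("beverage", "hexyl acetate", 40, 885.24, 12.72, 1.67e9, 0.81, 1.65e9, 0.92, 11.72, 5.49, 11.90, 5.51, 0.06),
    ("beverage", "cis-3-hexenyl acetate", 40, 28.86, 10.69, 8.30e8, 3.11, 8.18e8, 3.28, 14.17, 1.99, 14.37, 2.30, 0.12),
    ("beverage", "allyl hexanoate", 40, 30.88, 5.84, 3.01e9, 0.73, 2.98e9, 0.67, 35.79, 2.16, 36.53, 2.28, 0.12),
    ("beverage", "ethyl octanoate", 40, 227.48, 5.94, 8.71e9, 2.55, 8.66e9, 2.52, 58.30, 0.46, 59.08, 0.41, 0.11),
    ("beverage", "isoamyl hexanoate", 40, 34.02, 4.85, 8.01e9, 0.17, 7.94e9, 0.23, 61.86, 2.20, 63.09, 2.25, 0.10),
    ("beverage", "ethyl decanoate", 40, 863.01, 16.56, 2.25e10, 3.56, 2.23e10, 3.72, 322.53, 4.71, 326.39, 4.57, 0.04),
    ("beverage", "allyl hexanoate", 60, 748.05, 4.69, 1.38e9, 2.36, 1.36e9, 2.31, 9.10, 0.00, 9.26, 0.02, 0.07),
    ("beverage", "ethyl octanoate", 60, 2.00, 7.74, 2.67e9, 1.16, 2.64e9, 1.18, 19.82, 2.58, 20.26, 2.81, 0.09),
    ("beverage", "isoamyl hexanoate", 60, 2.81, 6.55, 3.51e9, 1.34, 3.47e9, 1.37, 20.27, 1.82, 20.77, 2.02, 0.08),
    ("beverage", "ethyl decanoate", 60, 241.21, 13.48, 8.10e9, 4.85, 8.02e9, 4.82, 73.81, 1.90, 75.34, 1.90, 0.04),
    ("beverage", "ethyl lauroate", 60, 642.31, 13.42, 6.10e10, 2.21, 6.08e10, 2.28, 358.69, 4.51, 360.80, 4.42, 0.06),
    ("gum", "sugar-free ethyl butanoate", 60, 37.94, 3.28, 1.34e10, 1.05, 1.33e10, 0.99, 6.17, 0.67, 6.23, 0.56, 0.09),
    ("gum", "sugar-base ethyl butanoate", 60, 1.01, 5.10, 3.68e9, 2.18, 3.63e9, 2.06, 2.49, 0.27, 2.51, 0.58, 0.04),
    ("gum", "sugar-free ethyl hexanoate", 60, 8.51, 2.88, 2.81e10, 0.26, 2.77e10, 0.34, 9.71, 1.11, 9.84, 1.17, 0.10),
    ("gum", "sugar-base ethyl hexanoate", 60, 11.38, 8.31, 2.18e10, 0.57, 2.16e10, 0.58, 4.29, 3.57, 4.32, 3.58, 0.07),
    ("gum", "sugar-free isopentyl acetate", 60, 13.00, 5.68, 3.40e9, 0.37, 3.36e9, 0.38, 6.11, 2.28, 6.28, 2.65, 0.13),
    ("gum", "sugar-base isopentyl acetate", 60, 81.08, 13.33, 1.86e9, 2.28, 1.85e9, 2.34, 2.05, 4.36, 2.10, 4.34, 0.08),
]

REFERENCE_TABLE = pd.DataFrame(
    _REFERENCE_ROWS,
    columns=[
        "system", "compound", "temperature_c", "W", "F_percent",
        "k1", "rsd_k1", "k2", "rsd_k2",
        "tau1", "rsd_tau1", "tau2", "rsd_tau2", "rmse",
    ],
)


@dataclass(frozen=True)
class SimScenario:
    """Everything needed to simulate one triplicate: truth, grid, noise, seed.

    Attributes
    ----------
    true_params : KineticParams
        Ground-truth kinetics, by convention on the normalized scale
        (k1 - k2 = 1).
    time_grid : tuple of float
        Ascending sampling times in minutes.
    obs_noise_cv : float
        Coefficient of variation of the multiplicative lognormal measurement
        noise (default 0.03).
    param_jitter_cv : float
        Relative per-replicate jitter of k1, C_inf, tau1, tau2 (default 0.01).
    raw_scale : float or None
        Optional multiplier to emit raw-like GC peak areas (~1e7-1e9).
    allow_truncation : bool
        Permit a grid ending before 3 * tau2 (deliberate non-equilibrium
        truncation scenarios).
    """

    name: str
    true_params: KineticParams
    time_grid: tuple[float, ...] = BEVERAGE_GRID
    obs_noise_cv: float = 0.03
    param_jitter_cv: float = 0.01
    raw_scale: float | None = None
    allow_truncation: bool = False
    seed: int = 0
    compound: str = "synthetic"
    condition: str = "simulated"

    def __post_init__(self) -> None:
        grid = tuple(float(t) for t in self.time_grid)
        object.__setattr__(self, "time_grid", grid)
        if len(grid) < 2 or not all(b > a for a, b in zip(grid, grid[1:])):
            raise ValueError("time_grid must be ascending with >= 2 points")
        if grid[0] <= 0:
            raise ValueError("time_grid must start after t = 0")
        if self.obs_noise_cv < 0 or self.param_jitter_cv < 0:
            raise ValueError("noise/jitter CVs must be nonnegative")
        if not self.allow_truncation and grid[-1] < 3.0 * self.true_params.tau2:
            raise ValueError(
                f"grid ends at {grid[-1]} min < 3*tau2 = "
                f"{3 * self.true_params.tau2:.1f} min; set allow_truncation=True "
                "for deliberate non-equilibrium scenarios"
            )


def _lognormal_mult(rng: np.random.Generator, cv: float, size=None) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def _jitter_params(
    p: KineticParams, cv: float, rng: np.random.Generator, max_tries: int = 200
) -> KineticParams:
    c_inf = p.k1 - p.k2
    dtau = p.tau2 - p.tau1
    for _ in range(max_tries):
        mk, mc, m1, md = (
            _lognormal_mult(rng, cv),
            _lognormal_mult(rng, cv),
            _lognormal_mult(rng, cv),
            _lognormal_mult(rng, cv),
        )
        k1 = p.k1 * mk
        k2 = k1 - c_inf * mc
        tau1 = p.tau1 * m1
        tau2 = tau1 + dtau * md
        if k2 > 0 and tau2 >= tau1 * (1.0 + MIN_TAU_SEPARATION):
            return KineticParams(k1=k1, k2=k2, tau1=tau1, tau2=tau2)
    raise RuntimeError("could not draw invariant-satisfying jittered parameters")


def generate_replicates(
    scenario: SimScenario, seed: int | None = None
) -> ReplicateSet:
    """Simulate one triplicate of extraction-time profiles.

    For each of the three replicates the true parameters are jittered, the
    net kinetic curve is evaluated on the grid, and multiplicative lognormal
    noise (and the optional raw scale) is applied.  Deterministic for a given
    seed; ``seed`` overrides ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    grid = np.asarray(scenario.time_grid)
    profiles = []
    for rid in (1, 2, 3):
        params = _jitter_params(scenario.true_params, scenario.param_jitter_cv, rng)
        y = net_conc(params, grid) * _lognormal_mult(
            rng, scenario.obs_noise_cv, size=len(grid)
        )
        if scenario.raw_scale is not None:
            y = y * scenario.raw_scale
        profiles.append(
            ExtractionProfile(
                compound=scenario.compound,
                condition=scenario.condition,
                replicate_id=rid,
                times=grid,
                areas=y,
            )
        )
    return ReplicateSet(tuple(profiles))


def _slug(text: str) -> str:
    return (
        text.lower().replace("-", "_").replace(" ", "_").replace("__", "_")
    )


def preset_scenarios() -> dict[str, SimScenario]:
    """One scenario per reference-table row, rescaled so C_inf = k1 - k2 = 1.

    Beverage rows use the default beverage grid (to 300 min), chewing-gum
    rows the gum grid (to 20 min).  Rows whose time constants outlast the
    grid (3 * tau2 beyond the last sample) are flagged as deliberate
    truncation scenarios — those are the compounds for which equilibrium was
    not reached within the sampled window.
    """
    out: dict[str, SimScenario] = {}
    for row in REFERENCE_TABLE.itertuples(index=False):
        c_inf = row.k1 - row.k2
        params = KineticParams(
            k1=row.k1 / c_inf, k2=row.k2 / c_inf, tau1=row.tau1, tau2=row.tau2
        )
        grid = BEVERAGE_GRID if row.system == "beverage" else GUM_GRID
        name = f"{_slug(row.compound)}_{row.temperature_c}C"
        out[name] = SimScenario(
            name=name,
            true_params=params,
            time_grid=grid,
            allow_truncation=grid[-1] < 3.0 * params.tau2,
            compound=row.compound,
            condition=f"{row.system} {row.temperature_c}C",
        )
    return out


def scenario_to_toml(scenario: SimScenario, path) -> Path:
    """Serialize a scenario to a plain-text key-value file."""
    p = scenario.true_params
    lines = [
        f"name = {scenario.name!r}",
        f"k1 = {p.k1!r}",
        f"k2 = {p.k2!r}",
        f"tau1 = {p.tau1!r}",
        f"tau2 = {p.tau2!r}",
        f"time_grid = [{', '.join(repr(t) for t in scenario.time_grid)}]",
        f"obs_noise_cv = {scenario.obs_noise_cv!r}",
        f"param_jitter_cv = {scenario.param_jitter_cv!r}",
        f"allow_truncation = {'true' if scenario.allow_truncation else 'false'}",
        f"seed = {scenario.seed}",
        f"compound = {scenario.compound!r}",
        f"condition = {scenario.condition!r}",
    ]
    if scenario.raw_scale is not None:
        lines.append(f"raw_scale = {scenario.raw_scale!r}")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


def scenario_from_toml(path) -> SimScenario:
    with open(path, "rb") as fh:
        d = tomllib.load(fh)
    params = KineticParams(
        k1=d.pop("k1"), k2=d.pop("k2"), tau1=d.pop("tau1"), tau2=d.pop("tau2")
    )
    d["time_grid"] = tuple(d.get("time_grid", BEVERAGE_GRID))
    return SimScenario(true_params=params, **d)


def truncated(scenario: SimScenario, last_time: float) -> SimScenario:
    """Variant of a scenario with the grid cut at ``last_time`` (inclusive)."""
    grid = tuple(t for t in scenario.time_grid if t <= last_time)
    return replace(
        scenario,
        name=f"{scenario.name}_truncated{int(last_time)}",
        time_grid=grid,
        allow_truncation=True,
    )
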