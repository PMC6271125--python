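import numpy as np
import pytest

from spmekin import FitConfig, KineticParams, net_conc
from spmekin.profiles import ExtractionProfile, ReplicateSet


@pytest.fixture
def toy_params() -> KineticParams:
    """Hand-checkable parameter set: t_max = 20*ln(4), C_max = 1.125, C_inf = 1."""
    return KineticParams(k1=2.0, k2=1.0, tau1=10.0, tau2=20.0)


@pytest.fixture
def octanoate_params() -> KineticParams:
    """Normalized ethyl-octanoate 40C preset (C_inf = 1)."""
    return KineticParams(k1=174.2, k2=173.2, tau1=58.30, tau2=59.08)


@pytest.fixture
def toy_grid() -> np.ndarray:
    return np.array([2.0, 5, 10, 15, 20, 27, 35, 50, 70, 90, 120])


@pytest.fixture
def identifiable_config() -> FitConfig:
    """Fit configuration admitting well-separated time constants (ratio up to 4)."""
    return FitConfig(seed=3, tau_ratio_max=4.0)


def make_profile(params, grid, replicate_id=1, compound="toy", condition="cond",
                 noise=None, rng=None):
    y = net_conc(params, grid)
    if noise:
        y = y * np.exp(rng.normal(0.0, noise, size=len(grid)))
    return ExtractionProfile(
        compound=compound, condition=condition, replicate_id=replicate_id,
        times=np.asarray(grid, dtype=float), areas=y,
    )


@pytest.fixture
def noise_free_profile(toy_params, toy_grid) -> ExtractionProfile:
    return make_profile(toy_params, toy_grid)


@pytest.fixture
def triplicate_csv(tmp_path):
    """Well-formed 3-replicate CSV for one compound/condition."""
    rng = np.random.default_rng(11)
    params = KineticParams(2.0, 1.0, 10.0, 20.0)
    grid = np.array([2.0, 5, 10, 15, 20, 27, 35, 50, 70, 90, 120])
    rows = ["compound,condition,replicate,time_min,peak_area"]
    for rid in (1, 2, 3):
        y = net_conc(params, grid) * np.exp(rng.normal(0, 0.02, len(grid)))
        for t, a in zip(grid, y):
            rows.append(f"ester A,beverage 30C,{rid},{t},{a}")
    path = tmp_path / "profiles.csv"
    path.write_text("\n".join(rows) + "\n")
    return path
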