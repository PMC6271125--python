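"""Closed-form bi-exponential SPME extraction kinetics.

The net amount of an analyte on an SPME fiber is modelled as the difference of
two parallel first-order processes, adsorption onto and release from the
coating::

    C_ads(t) = k1 * (1 - exp(-t / tau1))
    C_rel(t) = k2 * (1 - exp(-t / tau2))
    C(t)     = C_ads(t) - C_rel(t)

``k1`` and ``k2`` are the equilibrium constants (amplitudes, in the same units
as the peak areas being fitted) and ``tau1``, ``tau2`` the time constants in
minutes.  With ``k1 > k2`` and ``tau1 < tau2`` (adsorption faster than
release) the net curve rises, overshoots its plateau ``C_inf = k1 - k2`` and
relaxes back down — the rise/overshoot/plateau shape characteristic of
second-order flavour release.

Setting dC/dt = 0 gives the interior maximum in closed form::

    t_max = tau1 * tau2 / (tau2 - tau1) * ln(k1 * tau2 / (k2 * tau1))
    C_max = C(t_max)

which exists whenever the initial slope is positive (``k1/tau1 > k2/tau2``)
and ``tau1 < tau2``.
"""

from __future__ import annotations

from dataclasses import InitVar, dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MIN_TAU_SEPARATION",
    "KineticParams",
    "MonotoneProfileError",
    "adsorption_conc",
    "release_conc",
    "net_conc",
    "equilibrium_conc",
    "peak_time",
    "peak_conc",
    "has_overshoot",
    "decompose_curves",
]

#: Minimum relative separation of the two time constants: tau2 >= tau1 * (1 + delta).
#: Prevents the 0/0 indeterminacy of the peak-time formula as tau2 -> tau1.
MIN_TAU_SEPARATION = 1e-4


class MonotoneProfileError(ValueError):
    """The net curve has no interior maximum (monotone profile)."""


@dataclass(frozen=True)
class KineticParams:
    """The four parameters of one replicate's kinetic fit.

    Parameters
    ----------
    k1, k2 : float
        Adsorption / release equilibrium constants, in the units of the data
        being fitted (GC peak area, possibly normalized).  ``k1 > k2 > 0`` so
        the plateau ``k1 - k2`` is positive.
    tau1, tau2 : float
        Adsorption / release time constants in minutes, with
        ``tau2 >= tau1 * (1 + MIN_TAU_SEPARATION)``.
    validate : bool, keyword-only init argument
        Set False to skip invariant checks (used only to probe degenerate
        regimes such as monotone profiles).
    """

    k1: float
    k2: float
    tau1: float
    tau2: float
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool) -> None:
        if not validate:
            return
        for name in ("k1", "k2", "tau1", "tau2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        if not self.k1 > self.k2:
            raise ValueError(
                f"k1 must exceed k2 (positive plateau), got k1={self.k1}, k2={self.k2}"
            )
        if self.tau2 < self.tau1 * (1.0 + MIN_TAU_SEPARATION):
            raise ValueError(
                "tau2 must be at least tau1 * (1 + {:g}), got tau1={}, tau2={}".format(
                    MIN_TAU_SEPARATION, self.tau1, self.tau2
                )
            )

    def as_array(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.tau1, self.tau2], dtype=float)


def _check_time(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("extraction time must be nonnegative")
    return t


def adsorption_conc(params: KineticParams, t):
    """First-order adsorption curve ``k1 * (1 - exp(-t/tau1))``."""
    t = _check_time(t)
    return params.k1 * -np.expm1(-t / params.tau1)


def release_conc(params: KineticParams, t):
    """First-order release curve ``k2 * (1 - exp(-t/tau2))``."""
    t = _check_time(t)
    return params.k2 * -np.expm1(-t / params.tau2)


def net_conc(params: KineticParams, t):
    """Net amount on the fiber, adsorption minus release."""
    return adsorption_conc(params, t) - release_conc(params, t)


def equilibrium_conc(params: KineticParams) -> float:
    """Plateau of the net curve, ``C_inf = k1 - k2``."""
    return params.k1 - params.k2


def has_overshoot(params: KineticParams) -> bool:
    """True iff the net curve has a strict interior maximum.

    Requires a positive initial slope, ``k1/tau1 > k2/tau2``, together with
    ``tau1 < tau2``.  Under the default :class:`KineticParams` invariants both
    conditions hold automatically; the predicate matters for unvalidated
    parameter sets.
    """
    return (params.k1 / params.tau1 > params.k2 / params.tau2) and (
        params.tau1 < params.tau2
    )


def peak_time(params: KineticParams) -> float:
    """Time of the interior maximum of the net curve, in minutes.

    Raises
    ------
    MonotoneProfileError
        If the curve has no interior maximum (``k1/tau1 <= k2/tau2`` or
        ``tau1 >= tau2``).
    """
    if not has_overshoot(params):
        raise MonotoneProfileError(
            "net curve is monotone (k1/tau1 <= k2/tau2 or tau1 >= tau2): "
            "no interior maximum"
        )
    t1, t2 = params.tau1, params.tau2
    return t1 * t2 / (t2 - t1) * np.log(params.k1 * t2 / (params.k2 * t1))


def peak_conc(params: KineticParams) -> float:
    """Maximum of the net curve, ``C(t_max)``; at least ``k1 - k2``."""
    return float(net_conc(params, peak_time(params)))


def decompose_curves(params: KineticParams, t) -> pd.DataFrame:
    """Tabulate the adsorption, release and net curves on a time grid.

    Returns a DataFrame with columns ``t``, ``c_ads``, ``c_rel``, ``c_net``
    where ``c_net = c_ads - c_rel`` at every time.
    """
    t = _check_time(np.atleast_1d(t))
    ads = adsorption_conc(params, t)
    rel = release_conc(params, t)
    return pd.DataFrame({"t": t, "c_ads": ads, "c_rel": rel, "c_net": ads - rel})
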