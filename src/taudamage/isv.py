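"""Evaluation of the internal-state-variable damage laws.

Nucleation and growth rise exponentially with effective strain while the
nearest-neighbor distance (NND) between damaged regions decays; the
coalescence factor integrates a rate that blows up as regions approach
within a few characteristic diameters of one another (interaction becomes
significant inside roughly five diameters).  Total damage is the
multiplicative decomposition phi = eta * v * c, an area fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate

from .params import ISVParams, StrainSchedule

__all__ = [
    "nucleation",
    "growth",
    "nnd_law",
    "coalescence_rate",
    "coalescence",
    "total_damage",
    "evaluate_trajectory",
    "DamageTrajectory",
]

_DEFAULT_SCHEDULE = StrainSchedule("normalized_time")


def _schedule(schedule: StrainSchedule | None) -> StrainSchedule:
    return _DEFAULT_SCHEDULE if schedule is None else schedule


def nucleation(t, params: ISVParams, schedule: StrainSchedule | None = None):
    """Number density of damage nucleation sites, eta(t) = eta_coeff * exp(M*eps(t))."""
    s = _schedule(schedule)
    return params.eta_coeff * np.exp(params.M * s(t))


def growth(t, params: ISVParams, schedule: StrainSchedule | None = None):
    """Damaged area, v(t) = v_coeff * exp(Z*eps(t)), in cm^2."""
    s = _schedule(schedule)
    return params.v_coeff * np.exp(params.Z * s(t))


def nnd_law(t, params: ISVParams, schedule: StrainSchedule | None = None):
    """Mean nearest-neighbor distance, NND(t) = nnd_coeff * exp(Q*eps(t)), in cm."""
    s = _schedule(schedule)
    return params.nnd_coeff * np.exp(params.Q * s(t))


def coalescence_rate(nnd, params: ISVParams):
    """Instantaneous coalescence rate cdot = c_coeff * (4d / NND)**zeta.

    At NND equal to four characteristic diameters the base is one and the
    rate equals ``c_coeff`` exactly; the rate grows steeply as regions
    approach closer than that.
    """
    nnd = np.asarray(nnd, dtype=float)
    if np.any(nnd <= 0):
        raise ValueError("coalescence_rate requires nnd > 0")
    # (4d/nnd)^zeta in log space: robust when nnd is tiny and zeta large
    out = params.c_coeff * np.exp(params.zeta * (np.log(4.0 * params.d) - np.log(nnd)))
    return out if out.ndim else float(out)


def coalescence(t, params: ISVParams, schedule: StrainSchedule | None = None,
                method: str = "closed_form"):
    """Coalescence factor c(t) = c0 + integral_0^t cdot(NND(s)) ds.

    ``closed_form`` is available for schedules linear in time, eps(t) = K*t:
    the integrand is c_coeff*(4d/nnd_coeff)^zeta * exp(-Q*zeta*K*s), giving

        c(t) = c0 + B * (exp(-Q*zeta*K*t) - 1) / (-Q*zeta*K),   B = c_coeff*(4d/nnd_coeff)^zeta

    degenerating to c0 + B*t when Q*zeta*K = 0.  ``quadrature`` integrates
    the rate adaptively and works for any schedule.
    """
    s = _schedule(schedule)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if method == "closed_form":
        if not s.is_linear:
            raise ValueError("closed_form coalescence requires a schedule linear in time")
        K = s.rate
        B = params.c_coeff * (4.0 * params.d / params.nnd_coeff) ** params.zeta
        a = -params.Q * params.zeta * K
        if a == 0.0:
            out = params.c0 + B * t_arr
        else:
            out = params.c0 + B * np.expm1(a * t_arr) / a
    elif method == "quadrature":
        def rate(u: float) -> float:
            return coalescence_rate(nnd_law(u, params, s), params)

        out = np.array([params.c0 + integrate.quad(rate, 0.0, ti, epsabs=1e-13, epsrel=1e-11)[0]
                        for ti in t_arr])
    else:
        raise ValueError(f"unknown coalescence method {method!r}")
    return out if np.ndim(t) else float(out[0])


def total_damage(t, params: ISVParams, schedule: StrainSchedule | None = None,
                 coalescence_method: str = "closed_form"):
    """Total damage area fraction phi(t) = eta(t) * v(t) * c(t).

    eta carries count/cm^2 and v carries cm^2, so their product is a
    dimensionless area fraction scaled by the dimensionless c.
    """
    s = _schedule(schedule)
    return (nucleation(t, params, s) * growth(t, params, s)
            * coalescence(t, params, s, method=coalescence_method))


@dataclass
class DamageTrajectory:
    """Time series of all five damage quantities.

    Attributes are parallel 1-D arrays: ``times`` (years), ``eta``
    (regions/cm^2), ``v`` (cm^2), ``nnd`` (cm), ``c`` (dimensionless) and
    ``phi`` (area fraction).  The identity phi = eta*v*c holds pointwise by
    construction.
    """

    times: np.ndarray
    eta: np.ndarray
    v: np.ndarray
    nnd: np.ndarray
    c: np.ndarray
    phi: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "eta": self.eta, "v": self.v,
                             "nnd": self.nnd, "c": self.c, "phi": self.phi})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DamageTrajectory":
        df = pd.read_csv(path)
        return cls(df["time"].to_numpy(), df["eta"].to_numpy(), df["v"].to_numpy(),
                   df["nnd"].to_numpy(), df["c"].to_numpy(), df["phi"].to_numpy())


def evaluate_trajectory(times, params: ISVParams, schedule: StrainSchedule | None = None,
                        coalescence_method: str = "closed_form") -> DamageTrajectory:
    """Evaluate all five damage laws on an increasing time grid."""
    s = _schedule(schedule)
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a nonempty 1-D array")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    eta = nucleation(times, params, s)
    v = growth(times, params, s)
    nnd = nnd_law(times, params, s)
    c = np.atleast_1d(coalescence(times, params, s, method=coalescence_method))
    return DamageTrajectory(times=times, eta=eta, v=v, nnd=nnd, c=c, phi=eta * v * c)
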