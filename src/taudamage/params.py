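"""Damage-model parameter sets and the effective-strain schedule.

The damage state is decomposed multiplicatively into three internal state
variables (ISVs) — nucleation ``eta`` (number density of damaged regions),
growth ``v`` (damaged area), and coalescence ``c`` (a dimensionless
interaction factor driven by nearest-neighbor distance).  Each evolves
exponentially in an effective strain surrogate ``eps(t)``:

    eta(t) = eta_coeff * exp(M * eps(t))
    v(t)   = v_coeff  * exp(Z * eps(t))
    NND(t) = nnd_coeff * exp(Q * eps(t))
    cdot   = c_coeff * (4 d / NND)**zeta,   c(t) = c0 + integral(cdot)
    phi(t) = eta(t) * v(t) * c(t)

Two published constant sets ship as named presets; they differ in the
nucleation exponent and in the NND pair (the literature reports both, with
the fit-quality statements tied to the ``section31_text`` values, which are
therefore the default).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = [
    "ISVParams",
    "StrainSchedule",
    "SECTION31_TEXT",
    "TABLE1",
    "PRESETS",
    "get_preset",
]


@dataclass(frozen=True)
class ISVParams:
    """Constants of the nucleation/growth/coalescence damage laws.

    Parameters
    ----------
    eta_coeff : float
        Nucleation coefficient, regions per cm^2 at eps = 0.  Must be > 0.
    M : float
        Nucleation exponent (dimensionless lump of microstructure and
        stress-state dependence).
    v_coeff : float
        Growth coefficient, cm^2 at eps = 0.  Must be > 0.
    Z : float
        Growth exponent.
    nnd_coeff : float
        Nearest-neighbor-distance coefficient, cm at eps = 0.  Must be > 0.
    Q : float
        NND exponent; the fitted regime has Q < 0 (regions draw closer).
    c_coeff : float
        Coalescence rate coefficient (per unit time).  Must be > 0.
    d : float
        Characteristic damaged-region diameter, cm — the square root of the
        damaged area, fitted as a single constant.  Must be > 0.
    zeta : float
        Coalescence exponent; controls how sharply interaction intensifies
        as regions approach within a few diameters.  Must be > 0.
    c0 : float
        Coalescence initial condition c(0).  Defaults to 1 so that
        phi = eta * v before any interaction has accrued.
    """

    eta_coeff: float
    M: float
    v_coeff: float
    Z: float
    nnd_coeff: float
    Q: float
    c_coeff: float
    d: float
    zeta: float
    c0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("eta_coeff", "v_coeff", "nnd_coeff", "c_coeff", "d", "zeta"):
            if not getattr(self, name) > 0:
                raise ValueError(f"ISVParams.{name} must be > 0, got {getattr(self, name)!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ISVParams":
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ISVParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def replace(self, **kwargs) -> "ISVParams":
        return dataclasses.replace(self, **kwargs)


#: Constants reported in the narrative of the results (default preset).
SECTION31_TEXT = ISVParams(
    eta_coeff=0.01, M=5.338,
    v_coeff=0.016, Z=0.105,
    nnd_coeff=9.36, Q=-0.114,
    c_coeff=1.15, d=0.024, zeta=2.9,
)

#: Constants from the summary table (alternative preset; NND pair differs,
#: possibly reflecting a different normalization of the strain schedule).
TABLE1 = ISVParams(
    eta_coeff=0.01, M=5.065,
    v_coeff=0.016, Z=0.105,
    nnd_coeff=117.0, Q=-0.145,
    c_coeff=1.15, d=0.024, zeta=2.9,
)

PRESETS: dict[str, ISVParams] = {
    "section31_text": SECTION31_TEXT,
    "table1": TABLE1,
}


def get_preset(name: str) -> ISVParams:
    """Look up a named constant set; accepts a path to a YAML file instead."""
    if name in PRESETS:
        return PRESETS[name]
    p = Path(name)
    if p.is_file():
        return ISVParams.from_yaml(p)
    raise KeyError(f"unknown preset {name!r}; expected one of {sorted(PRESETS)} or a YAML path")


class StrainSchedule:
    """Effective strain surrogate eps(t).

    The damage laws are written in an effective strain, but observations are
    indexed by time (approximate age or years of play).  The default maps
    time to strain as eps(t) = t / t_ref with t_ref = 1, so fitted exponents
    are per unit normalized time and directly comparable to the published
    constants.  A ``linear`` form eps(t) = K*t and a monotone ``user_table``
    (interpolated) are also available.  Built-in forms satisfy eps(0) = 0.
    """

    def __init__(self, form: str = "normalized_time", *, t_ref: float = 1.0,
                 K: float | None = None, table: tuple | None = None):
        if form == "normalized_time":
            if not t_ref > 0:
                raise ValueError("t_ref must be > 0")
            self._rate = 1.0 / t_ref
        elif form == "linear":
            if K is None:
                raise ValueError("linear schedule requires K")
            self._rate = float(K)
        elif form == "user_table":
            import numpy as np

            if table is None:
                raise ValueError("user_table schedule requires table=(times, eps)")
            t, e = (np.asarray(a, dtype=float) for a in table)
            if t.ndim != 1 or t.shape != e.shape or len(t) < 2:
                raise ValueError("table must be two equal-length 1-D sequences")
            if not (np.all(np.diff(t) > 0) and np.all(np.diff(e) >= 0)):
                raise ValueError("table times must increase and eps be nondecreasing")
            self._table = (t, e)
            self._rate = None
        else:
            raise ValueError(f"unknown schedule form {form!r}")
        self.form = form

    @property
    def is_linear(self) -> bool:
        """True when eps(t) = K*t for a constant K (closed forms apply)."""
        return self._rate is not None

    @property
    def rate(self) -> float:
        if self._rate is None:
            raise ValueError("tabulated schedule has no constant rate")
        return self._rate

    def __call__(self, t):
        import numpy as np

        t = np.asarray(t, dtype=float)
        if self._rate is not None:
            out = self._rate * t
        else:
            tt, ee = self._table
            out = np.interp(t, tt, ee)
        return out if out.ndim else float(out)
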