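"""Data conditioning and calibration of the exponential damage laws.

The source histology dataset lacks per-slice ages, so the study's
conditioning step is reconstructed here: each measured series is sorted —
nucleation density, damaged area and damage fraction ascending, NND
descending (regions draw closer as damage progresses) — and paired
positionally with an approximate-age grid.  The exponential laws are then
fitted, by log-linear ordinary least squares by default (exact on noiseless
exponential data) or by nonlinear least squares.

The calibration surface follows the Model/Results idiom:
``DamageProgressionModel(data).fit()`` returns a
:class:`DamageProgressionResults` carrying the assembled
:class:`~taudamage.params.ISVParams`, the per-law fit diagnostics, a
``summary()`` table and ``predict``/``plot`` methods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .isv import DamageTrajectory, evaluate_trajectory
from .params import ISVParams, SECTION31_TEXT, StrainSchedule, get_preset

__all__ = [
    "FitResult",
    "sort_and_assign_ages",
    "condition_observations",
    "default_age_grid",
    "fit_exponential",
    "fit_all",
    "stage_statistics",
    "stage_years_of_play",
    "DamageProgressionModel",
    "DamageProgressionResults",
]

#: Years of football played assigned to damage stages 1-4.  The upstream
#: cohort study staged players on a two-level scale; its lowest level is
#: split into stages 1-2 and its highest into stages 3-4, yielding 7 and 13
#: years for the low stages and 15 and 20 years for the high ones.
STAGE_YEARS_OF_PLAY = {1: 7, 2: 13, 3: 15, 4: 20}

#: Series fitted against time and the sort direction each receives.
_SERIES_DIRECTION = {"eta": "ascending", "v": "ascending",
                     "phi": "ascending", "nnd": "descending"}


def stage_years_of_play(stage: int) -> int:
    """Years of football mapped to a damage stage (7, 13, 15, 20)."""
    try:
        return STAGE_YEARS_OF_PLAY[stage]
    except KeyError:
        raise ValueError("stage must be 1..4") from None


@dataclass(frozen=True)
class FitResult:
    """One exponential-law fit y = coeff * exp(exponent * t)."""

    coeff: float
    exponent: float
    r_squared: float
    n_points: int
    loss: str

    def __str__(self) -> str:  # compact row for summaries
        return (f"coeff={self.coeff:.6g} exponent={self.exponent:.6g} "
                f"R2={self.r_squared:.6f} n={self.n_points} ({self.loss})")


def default_age_grid(n: int, start: float = 28.3, stop: float = 77.4) -> np.ndarray:
    """Evenly spaced approximate ages spanning the stage-mean ages.

    A reconstruction of the study's unstated age-assignment rule, not the
    authors' exact grid; the endpoints default to the stage-1 and stage-4
    mean ages at death.
    """
    if n < 2:
        raise ValueError("need at least 2 ages")
    return np.linspace(start, stop, n)


def sort_and_assign_ages(values, direction: str, age_grid) -> pd.DataFrame:
    """Sort measurements and pair them positionally with an age grid.

    Returns a DataFrame with columns ``time`` and ``value``.  The sort is a
    permutation — the multiset of values is preserved.  NND uses descending
    order, all other series ascending.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(age_grid, dtype=float)
    if len(values) != len(ages):
        raise ValueError(f"{len(values)} values but {len(ages)} ages")
    if len(ages) > 1 and np.any(np.diff(ages) <= 0):
        raise ValueError("age_grid must be strictly increasing")
    if direction not in ("ascending", "descending"):
        raise ValueError("direction must be 'ascending' or 'descending'")
    v = np.sort(values, kind="stable")
    if direction == "descending":
        v = v[::-1]
    return pd.DataFrame({"time": ages, "value": v})


def condition_observations(data: pd.DataFrame, age_grid=None) -> pd.DataFrame:
    """Apply the sorting/age-assignment step to a full observation table.

    ``data`` needs columns among eta, v, nnd, phi (each sorted per its
    direction).  Returns a tidy frame indexed by the age grid with one
    column per available series.
    """
    series = [c for c in _SERIES_DIRECTION if c in data.columns]
    if not series:
        raise ValueError("no fittable series among columns "
                         f"{list(data.columns)}; expected some of {list(_SERIES_DIRECTION)}")
    n = len(data)
    ages = default_age_grid(n) if age_grid is None else np.asarray(age_grid, dtype=float)
    out = pd.DataFrame({"time": ages})
    for col in series:
        out[col] = sort_and_assign_ages(data[col], _SERIES_DIRECTION[col], ages)["value"].values
    return out


def _r_squared(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_exponential(times, values, loss: str = "log_linear_ols") -> FitResult:
    """Fit y = coeff * exp(exponent * t).

    ``log_linear_ols`` regresses log(y) on t (exact on noiseless exponential
    data; requires positive values — nonpositive entries are reported by
    index).  ``nonlinear_ls`` minimizes squared residuals on the natural
    scale, initialized from the log-linear solution.  R^2 is computed in the
    space the loss was minimized in.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times and values must be equal-length 1-D arrays")
    if len(t) < 2:
        raise ValueError("need at least 2 points")
    bad = np.nonzero(~(y > 0))[0]
    if bad.size:
        raise ValueError(f"nonpositive values at indices {bad.tolist()} "
                         "cannot be fit under an exponential law")
    slope, intercept = np.polyfit(t, np.log(y), 1)
    if loss == "log_linear_ols":
        coeff, exponent = math.exp(intercept), float(slope)
        r2 = _r_squared(np.log(y), intercept + slope * t)
    elif loss == "nonlinear_ls":
        popt, _ = curve_fit(lambda x, a, b: a * np.exp(b * x), t, y,
                            p0=(math.exp(intercept), slope), maxfev=20000)
        coeff, exponent = float(popt[0]), float(popt[1])
        r2 = _r_squared(y, coeff * np.exp(exponent * t))
    else:
        raise ValueError(f"unknown loss {loss!r}")
    return FitResult(coeff=coeff, exponent=exponent, r_squared=r2,
                     n_points=len(t), loss=loss)


def stage_statistics(data: pd.DataFrame, stage_boundaries) -> pd.DataFrame:
    """Per-stage means of every measured series.

    ``stage_boundaries`` are index cut points partitioning rows 0..n:
    [0, b1, ..., n].  Stage k covers rows [b_{k-1}, b_k).  An empty stage is
    an error.
    """
    b = list(stage_boundaries)
    n = len(data)
    if b[0] != 0 or b[-1] != n or any(x >= y for x, y in zip(b, b[1:])):
        raise ValueError(f"boundaries {b} must strictly increase from 0 to {n} "
                         "(no empty stages)")
    num = data.select_dtypes("number")
    rows = [num.iloc[lo:hi].mean() for lo, hi in zip(b, b[1:])]
    out = pd.DataFrame(rows)
    out.insert(0, "stage", range(1, len(rows) + 1))
    return out.reset_index(drop=True)


class DamageProgressionModel:
    """Calibrates the exponential ISV laws to a damage observation table.

    Parameters
    ----------
    data : DataFrame
        Columns ``time`` plus the measured series ``eta`` (regions/cm^2),
        ``v`` (cm^2) and ``nnd`` (cm); ``phi`` optional.  If ``time`` is
        absent the conditioning step (sorting + approximate-age assignment)
        is applied with ``age_grid``.
    schedule : StrainSchedule, optional
        Effective-strain schedule; defaults to normalized time.
    loss : str
        ``log_linear_ols`` (default) or ``nonlinear_ls``.
    coalescence_source : ISVParams or str
        The coalescence constants (c_coeff, d, zeta) are not identifiable
        from NND-vs-time data alone, so they are adopted from this preset
        unless a measured coalescence series ``c`` is present, in which case
        zeta and c_coeff are fitted on log(cdot) vs log(4d/NND).
    """

    REQUIRED = ("eta", "v", "nnd")

    def __init__(self, data: pd.DataFrame, schedule: StrainSchedule | None = None,
                 loss: str = "log_linear_ols",
                 coalescence_source: ISVParams | str = SECTION31_TEXT,
                 age_grid=None):
        missing = [c for c in self.REQUIRED if c not in data.columns]
        if missing:
            raise ValueError(f"observation table missing series: {missing}")
        if "time" not in data.columns:
            data = condition_observations(data, age_grid=age_grid)
        self.data = data.reset_index(drop=True)
        self.schedule = schedule or StrainSchedule("normalized_time")
        self.loss = loss
        if isinstance(coalescence_source, str):
            coalescence_source = get_preset(coalescence_source)
        self.coalescence_source = coalescence_source

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kw) -> "DamageProgressionModel":
        return cls(data, **kw)

    @classmethod
    def from_csv(cls, path, **kw) -> "DamageProgressionModel":
        """Load an observation CSV as written by the quantification stage."""
        df = pd.read_csv(path)
        rename = {"time_years": "time", "nucleation_per_cm2": "eta",
                  "damaged_area_cm2": "v", "mean_nnd_cm": "nnd", "damage_pct": "phi"}
        df = df.rename(columns={k: v for k, v in rename.items() if k in df.columns})
        if "damaged_area_mm2" in df.columns:
            df["v"] = df["damaged_area_mm2"] / 100.0  # mm^2 -> cm^2
        if "time" in df.columns and df["time"].isna().all():
            df = df.drop(columns="time")
        return cls(df[[c for c in ("time", "eta", "v", "nnd", "phi", "c") if c in df.columns]],
                   **kw)

    @classmethod
    def from_observations(cls, observations, **kw) -> "DamageProgressionModel":
        """Build from a list of DamageObservation (phi taken as fraction, not %)."""
        df = pd.DataFrame({
            "eta": [o.nucleation_density for o in observations],
            "v": [o.damaged_area for o in observations],
            "nnd": [o.nnd for o in observations],
            "phi": [o.damage_fraction / 100.0 for o in observations],
        })
        times = [o.time for o in observations]
        if not any(math.isnan(t) for t in times):
            df.insert(0, "time", times)
        return cls(df, **kw)

    def fit(self) -> "DamageProgressionResults":
        eps = np.asarray(self.schedule(self.data["time"].to_numpy()), dtype=float)
        fits = {
            "eta": fit_exponential(eps, self.data["eta"], self.loss),
            "v": fit_exponential(eps, self.data["v"], self.loss),
            "nnd": fit_exponential(eps, self.data["nnd"], self.loss),
        }
        src = self.coalescence_source
        c_coeff, d, zeta = src.c_coeff, src.d, src.zeta
        if "c" in self.data.columns:
            c_coeff, zeta, fits["c"] = self._fit_coalescence(d)
        params = ISVParams(
            eta_coeff=fits["eta"].coeff, M=fits["eta"].exponent,
            v_coeff=fits["v"].coeff, Z=fits["v"].exponent,
            nnd_coeff=fits["nnd"].coeff, Q=fits["nnd"].exponent,
            c_coeff=c_coeff, d=d, zeta=zeta, c0=src.c0,
        )
        return DamageProgressionResults(self, params, fits)

    def _fit_coalescence(self, d: float):
        """Fit zeta and c_coeff on log(cdot) vs log(4d/NND) from a measured c series."""
        t = self.data["time"].to_numpy(dtype=float)
        c = self.data["c"].to_numpy(dtype=float)
        nnd = self.data["nnd"].to_numpy(dtype=float)
        cdot = np.gradient(c, t)
        keep = cdot > 0
        if keep.sum() < 2:
            raise ValueError("measured coalescence series has no increasing stretch to fit")
        x = np.log(4.0 * d / nnd[keep])
        fr = fit_exponential(x, cdot[keep], "log_linear_ols")
        return fr.coeff, fr.exponent, fr


@dataclass
class DamageProgressionResults:
    """Fitted damage-law constants with per-law diagnostics."""

    model: DamageProgressionModel
    params: ISVParams
    fits: dict[str, FitResult]

    def predict(self, times=None) -> DamageTrajectory:
        """Evaluate the fitted laws (all five series) on a time grid."""
        if times is None:
            times = self.model.data["time"].to_numpy()
        return evaluate_trajectory(np.asarray(times, dtype=float), self.params,
                                   self.model.schedule)

    def summary(self) -> str:
        lines = ["Damage progression fit",
                 "=" * 62,
                 f"{'law':<12}{'coeff':>12}{'exponent':>12}{'R^2':>10}{'n':>6}"]
        names = {"eta": "nucleation", "v": "growth", "nnd": "NND", "c": "coalescence"}
        for key, fr in self.fits.items():
            lines.append(f"{names.get(key, key):<12}{fr.coeff:>12.5g}"
                         f"{fr.exponent:>12.5g}{fr.r_squared:>10.5f}{fr.n_points:>6d}")
        p = self.params
        lines += ["-" * 62,
                  f"coalescence constants: c_coeff={p.c_coeff} d={p.d} zeta={p.zeta} c0={p.c0}",
                  f"loss: {self.model.loss}; schedule: {self.model.schedule.form}"]
        return "\n".join(lines)

    def to_report(self) -> dict:
        """JSON-serializable fit report."""
        return {
            "params": self.params.to_dict(),
            "fits": {k: {"coeff": f.coeff, "exponent": f.exponent,
                         "r_squared": f.r_squared, "n": f.n_points, "loss": f.loss}
                     for k, f in self.fits.items()},
        }

    def plot(self, ax=None):
        """Observed series with fitted curves, one panel per law."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, axes = plt.subplots(1, 3, figsize=(12, 3.5))
        else:
            axes = ax
        t = self.model.data["time"].to_numpy()
        grid = np.linspace(t.min(), t.max(), 200)
        traj = self.predict(grid)
        panels = [("eta", traj.eta, "nucleation (1/cm$^2$)"),
                  ("v", traj.v, "damaged area (cm$^2$)"),
                  ("nnd", traj.nnd, "NND (cm)")]
        for axi, (col, curve, label) in zip(np.ravel(axes), panels):
            axi.plot(t, self.model.data[col], "+", label="data")
            axi.plot(grid, curve, "-", label="model")
            axi.set_xlabel("approximate age (years)")
            axi.set_ylabel(label)
            axi.legend(frameon=False)
        return axes


def fit_all(observations, schedule: StrainSchedule | None = None,
            loss: str = "log_linear_ols",
            coalescence_source: ISVParams | str = SECTION31_TEXT,
            age_grid=None) -> DamageProgressionResults:
    """One-call calibration: accepts a DataFrame or DamageObservation list."""
    if isinstance(observations, pd.DataFrame):
        model = DamageProgressionModel(observations, schedule, loss,
                                       coalescence_source, age_grid)
    else:
        model = DamageProgressionModel.from_observations(
            observations, schedule=schedule, loss=loss,
            coalescence_source=coalescence_source, age_grid=age_grid)
    return model.fit()
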