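"""Head-impact exposure histories and strain-life fatigue curves.

Football positions differ sharply in impact exposure: linemen take many
low-amplitude impacts (a high-cycle-fatigue, HCF, regime) while skill
positions such as quarterbacks take few high-amplitude impacts (low-cycle
fatigue, LCF).  This module builds per-position exposure tables — an annual
impact count apportioned over G-level bins and accumulated over the years
of play assigned to each damage stage (7, 13, 15, 20 years for stages
1-4) — and fits the two-term strain-life relationship

    amplitude(2N) = A_e * (2N)**b + A_p * (2N)**c,      b, c < 0, c < b,

whose elastic (Basquin) and plastic (Coffin-Manson) asymptotes intersect at
the LCF/HCF transition 2N_t = (A_p/A_e)**(1/(b-c)).  Internally the cycle
axis is reversals 2N; one head impact is one reversal, so reported impact
counts coincide with reversals.

The per-G-level impact proportions are an external measurement and must be
supplied by the user; :func:`taudamage.synthetic.example_g_level_proportions`
ships a clearly-labelled synthetic illustration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .fitting import STAGE_YEARS_OF_PLAY

__all__ = [
    "ExposureProfile",
    "StrainLifeModel",
    "StrainLifeResults",
    "qb_annual_impacts",
    "bin_impacts",
    "cumulative_cycles",
    "fit_strain_life",
    "lcf_hcf_transition",
    "stage_curve_points",
]

#: Annual head-impact count measured for an offensive lineman over all
#: practices and games, used as the exposure anchor.
LINEMAN_ANNUAL_IMPACTS = 10128


def qb_annual_impacts(qb_count: float, lineman_count: float,
                      lineman_total: float = LINEMAN_ANNUAL_IMPACTS) -> int:
    """Scale a quarterback's annual impacts onto the lineman exposure anchor.

    The studies that counted QB impacts (307/yr) used different
    instrumentation from the one behind the 10,128 lineman total (which saw
    798 lineman impacts/yr), so the QB total is rescaled by the ratio:
    round(lineman_total * qb_count / lineman_count) — e.g. 3896.
    """
    if not (qb_count > 0 and lineman_count > 0 and lineman_total > 0):
        raise ValueError("all impact counts must be > 0")
    return round(lineman_total * qb_count / lineman_count)


def bin_impacts(proportions, annual_total: int) -> list[tuple[float, int]]:
    """Apportion an annual impact total over G-level bins.

    ``proportions`` is a sequence of (g_level, fraction) with fractions >= 0
    summing to 1 within 1e-9.  Counts are integers by largest-remainder
    apportionment, ties broken toward higher G-levels (conservative for
    injury exposure); they sum to ``annual_total`` exactly.
    """
    props = [(float(g), float(f)) for g, f in proportions]
    fracs = np.array([f for _, f in props])
    if np.any(fracs < 0):
        raise ValueError("fractions must be >= 0")
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions sum to {fracs.sum():.12g}, not 1")
    if annual_total < 0:
        raise ValueError("annual_total must be >= 0")
    quota = fracs * annual_total
    counts = np.floor(quota).astype(int)
    short = int(annual_total - counts.sum())
    g_levels = np.array([g for g, _ in props])
    # stable sort on (-remainder, -g): biggest remainders first, high G wins ties
    order = np.lexsort((-g_levels, -(quota - counts)))
    counts[order[:short]] += 1
    return [(g, int(c)) for (g, _), c in zip(props, counts)]


@dataclass
class ExposureProfile:
    """Per-position annual impact exposure binned by G-level.

    ``bins`` is a list of (g_level, annual_count); counts sum exactly to
    ``annual_impacts``.  ``years_per_stage`` maps damage stages 1-4 to years
    of play (default 7, 13, 15, 20).
    """

    position: str
    annual_impacts: int
    bins: list[tuple[float, int]]
    years_per_stage: tuple[int, int, int, int] = (
        STAGE_YEARS_OF_PLAY[1], STAGE_YEARS_OF_PLAY[2],
        STAGE_YEARS_OF_PLAY[3], STAGE_YEARS_OF_PLAY[4])

    def __post_init__(self) -> None:
        if self.annual_impacts < 0:
            raise ValueError("annual_impacts must be >= 0")
        if sum(c for _, c in self.bins) != self.annual_impacts:
            raise ValueError("bin counts must sum exactly to annual_impacts")
        if any(c < 0 for _, c in self.bins):
            raise ValueError("bin counts must be >= 0")
        if len(self.years_per_stage) != 4 or any(y < 0 for y in self.years_per_stage):
            raise ValueError("years_per_stage must be 4 nonnegative integers")

    @classmethod
    def from_proportions(cls, position: str, annual_impacts: int, proportions,
                         years_per_stage=None) -> "ExposureProfile":
        bins = bin_impacts(proportions, annual_impacts)
        kw = {} if years_per_stage is None else {"years_per_stage": tuple(years_per_stage)}
        return cls(position=position, annual_impacts=annual_impacts, bins=bins, **kw)

    @classmethod
    def from_csv(cls, path, position: str | None = None,
                 years_per_stage=None) -> "ExposureProfile":
        """Read a (position, g_level, fraction, annual_impacts) table."""
        df = pd.read_csv(path)
        pos = position or str(df["position"].iloc[0])
        df = df[df["position"] == pos] if "position" in df.columns else df
        total = int(df["annual_impacts"].iloc[0])
        return cls.from_proportions(pos, total, list(zip(df["g_level"], df["fraction"])),
                                    years_per_stage)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"position": self.position,
                             "g_level": [g for g, _ in self.bins],
                             "annual_count": [c for _, c in self.bins]})


def cumulative_cycles(profile: ExposureProfile, stage: int) -> list[tuple[float, int]]:
    """Cumulative per-bin impact counts after the years of play of a stage.

    Stage k multiplies every annual bin count by years_per_stage[k]; e.g. a
    lineman's 10,128 impacts/yr over the 7 years of stage 1 accumulate to
    70,896 impacts.
    """
    if stage not in (1, 2, 3, 4):
        raise ValueError("stage must be 1..4")
    years = profile.years_per_stage[stage - 1]
    return [(g, c * years) for g, c in profile.bins]


def stage_curve_points(profile: ExposureProfile, damage_stage_fractions) -> pd.DataFrame:
    """Tag each stage's cumulative cycles with G-level and damage level.

    ``damage_stage_fractions`` gives the total damage (area fraction or %)
    reached at each of the four stages, from the ISV model or from data.
    Returns the fatigue-curve point set: one row per (stage, G-bin) with the
    cumulative impact count at that stage, the bin amplitude in G, and the
    stage damage level.
    """
    levels = list(damage_stage_fractions)
    if len(levels) != 4:
        raise ValueError("need one damage level per stage (4)")
    rows = []
    for stage, dmg in zip((1, 2, 3, 4), levels):
        for g, cyc in cumulative_cycles(profile, stage):
            rows.append((stage, g, cyc, dmg))
    return pd.DataFrame(rows, columns=["stage", "g_level", "cycles", "damage"])


@dataclass
class StrainLifeResults:
    """Fitted strain-life curve.

    ``elastic`` is (A_e, b) and ``plastic`` (A_p, c) on reversals 2N;
    ``plastic`` is None for pure-elastic data, in which case the LCF/HCF
    transition is undefined.
    """

    elastic: tuple[float, float]
    plastic: tuple[float, float] | None
    n_points: int
    max_log_residual: float

    @property
    def transition(self) -> tuple[float, float]:
        """LCF/HCF transition (reversals, amplitude) where the asymptotes cross."""
        return lcf_hcf_transition(self)

    def amplitude(self, reversals):
        """Evaluate the fitted curve at the given reversals."""
        x = np.asarray(reversals, dtype=float)
        A_e, b = self.elastic
        out = A_e * x**b
        if self.plastic is not None:
            A_p, c = self.plastic
            out = out + A_p * x**c
        return out

    def summary(self) -> str:
        A_e, b = self.elastic
        lines = ["Strain-life fit (amplitude vs reversals 2N)",
                 f"  elastic asymptote:  {A_e:.6g} * (2N)^{b:.6g}"]
        if self.plastic is None:
            lines.append("  plastic asymptote:  absent (pure-elastic data)")
            lines.append("  LCF/HCF transition: undefined")
        else:
            A_p, c = self.plastic
            nt, at = self.transition
            lines.append(f"  plastic asymptote:  {A_p:.6g} * (2N)^{c:.6g}")
            lines.append(f"  LCF/HCF transition: 2N = {nt:.6g} at amplitude {at:.6g}")
        lines.append(f"  n = {self.n_points}, max |log residual| = {self.max_log_residual:.3g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {"elastic": {"coeff": self.elastic[0], "slope": self.elastic[1]},
               "plastic": None, "transition": None,
               "n_points": self.n_points, "max_log_residual": self.max_log_residual}
        if self.plastic is not None:
            out["plastic"] = {"coeff": self.plastic[0], "slope": self.plastic[1]}
            nt, at = self.transition
            out["transition"] = {"reversals": nt, "amplitude": at}
        return out

    def plot(self, ax=None, points: pd.DataFrame | None = None):
        """Log-log strain-life plot with asymptotes and transition."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        A_e, b = self.elastic
        if self.plastic is not None:
            nt, _ = self.transition
            x = np.geomspace(nt * 1e-3, nt * 1e3, 200)
        else:
            x = np.geomspace(1.0, 1e7, 200)
        ax.loglog(x, self.amplitude(x), "k-", label="fatigue-life curve")
        ax.loglog(x, A_e * x**b, "b--", label="elastic asymptote")
        if self.plastic is not None:
            A_p, c = self.plastic
            ax.loglog(x, A_p * x**c, "r--", label="plastic asymptote")
            nt, at = self.transition
            ax.plot([nt], [at], "ko", label="LCF/HCF transition")
        if points is not None:
            ax.loglog(points["cycles"], points["g_level"], "+", label="exposure points")
        ax.set_xlabel("impacts (reversals 2N)")
        ax.set_ylabel("amplitude")
        ax.legend(frameon=False)
        return ax


class StrainLifeModel:
    """Fits the two-term strain-life curve to (reversals, amplitude) points.

    Fitting happens on log axes (amplitudes span decades).  If the data lie
    on a single power law — within ``elastic_tol`` in log space — the
    plastic term is reported absent rather than forced in.
    """

    def __init__(self, points, elastic_tol: float = 1e-9):
        pts = np.asarray(points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array of (reversals, amplitude)")
        if np.any(pts <= 0):
            raise ValueError("reversals and amplitudes must be > 0")
        if len(pts) < 4:
            raise ValueError("need at least 4 points spanning both regimes")
        self.points = pts[np.argsort(pts[:, 0])]
        self.elastic_tol = elastic_tol

    def fit(self) -> StrainLifeResults:
        x = self.points[:, 0]
        y = self.points[:, 1]
        lx, ly = np.log(x), np.log(y)

        # single power law first: if exact, the data carry no second term
        slope, intercept = np.polyfit(lx, ly, 1)
        resid = ly - (intercept + slope * lx)
        if np.max(np.abs(resid)) < self.elastic_tol:
            return StrainLifeResults(elastic=(math.exp(intercept), float(slope)),
                                     plastic=None, n_points=len(x),
                                     max_log_residual=float(np.max(np.abs(resid))))

        # two-term fit in log space; init elastic from the high-cycle half,
        # plastic from the low-cycle residual
        hi = lx >= np.median(lx)
        s_e, i_e = np.polyfit(lx[hi], ly[hi], 1)
        rem = y - math.exp(i_e) * x**s_e
        lo = (~hi) & (rem > 0)
        if lo.sum() >= 2:
            s_p, i_p = np.polyfit(lx[lo], np.log(rem[lo]), 1)
        else:
            s_p, i_p = s_e - 0.4, i_e + 1.0

        def residuals(p):
            la_e, b, la_p, c = p
            model = np.exp(la_e) * x**b + np.exp(la_p) * x**c
            return np.log(model) - ly

        sol = least_squares(residuals, x0=(i_e, s_e, i_p, s_p), method="lm",
                            xtol=1e-15, ftol=1e-15)
        la_e, b, la_p, c = sol.x
        elastic, plastic = (math.exp(la_e), float(b)), (math.exp(la_p), float(c))
        if plastic[1] < elastic[1]:
            pass  # plastic already the steeper term
        else:
            elastic, plastic = plastic, elastic
        return StrainLifeResults(elastic=elastic, plastic=plastic, n_points=len(x),
                                 max_log_residual=float(np.max(np.abs(sol.fun))))


def fit_strain_life(points) -> StrainLifeResults:
    """Convenience wrapper: ``StrainLifeModel(points).fit()``."""
    return StrainLifeModel(points).fit()


def lcf_hcf_transition(curve: StrainLifeResults) -> tuple[float, float]:
    """Intersection of the elastic and plastic asymptotes.

    2N_t = (A_p/A_e)**(1/(b-c)); amplitude_t = A_e * 2N_t**b.  Reversals
    below 2N_t are the LCF regime, above it HCF.  Parallel asymptotes
    (b == c) have no intersection, and a missing plastic term leaves the
    transition undefined; both raise ``ValueError``.
    """
    if curve.plastic is None:
        raise ValueError("transition undefined: no plastic asymptote")
    A_e, b = curve.elastic
    A_p, c = curve.plastic
    if b == c:
        raise ValueError("parallel asymptotes (b == c) never intersect")
    n_t = (A_p / A_e) ** (1.0 / (b - c))
    return float(n_t), float(A_e * n_t**b)
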