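"""Microclimate derivations and physiological-trait statistics.

Saturation vapor pressure (kPa) follows the exponential form

    SVP(T) = 0.61078 * exp(17.27 * T / (denom_const + T)),   T in degC,

with ``denom_const`` defaulting to 273.5 — the constant printed alongside
the source data for this pipeline — while the classical Tetens/Magnus
value is 237.3; pass ``denom_const=TETENS_DENOM`` (or use the CLI
``--tetens`` switch) to select it.  The discrepancy is deliberate and
surfaced rather than silently corrected.  Vapor pressure deficit is
VPD = SVP * (1 - RH/100).

Physiological traits (chlorophyll, POD activity, MDA) are analysed by
two-way fixed-effects ANOVA (tolerance class x sampling day; Type-II sums
of squares for unbalanced layouts) followed by Tukey's HSD over the
class-day cell means, via statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import time

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

PAPER_DENOM = 273.5
TETENS_DENOM = 237.3
SVP_COEF = 0.61078
SVP_EXP = 17.27


def svp(T, denom_const: float = PAPER_DENOM):
    """Saturation vapor pressure in kPa at air temperature T (degC)."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= -denom_const):
        raise ValueError(f"temperature must exceed -{denom_const} degC")
    out = SVP_COEF * np.exp(SVP_EXP * T / (denom_const + T))
    return float(out) if out.ndim == 0 else out


def vpd(T, RH, denom_const: float = PAPER_DENOM):
    """Vapor pressure deficit in kPa: SVP(T) * (1 - RH/100)."""
    RH = np.asarray(RH, dtype=float)
    if np.any((RH < 0) | (RH > 100)):
        raise ValueError("relative humidity must lie in [0, 100]")
    out = svp(T, denom_const=denom_const) * (1.0 - RH / 100.0)
    return float(out) if np.ndim(out) == 0 else out


@dataclass
class WindowSummary:
    """Per-treatment means of T, RH and VPD over the daily stress window."""

    table: pd.DataFrame  # index treatment; columns temperature_c, relative_humidity, vpd, n_records
    window: tuple


def window_summary(records: pd.DataFrame, window=(time(10, 0), time(16, 0)),
                   denom_const: float = PAPER_DENOM,
                   inclusive_end: bool = False) -> WindowSummary:
    """Mean T, RH, VPD within the daily stress window, per treatment.

    ``records`` needs columns timestamp, treatment, temperature_c,
    relative_humidity.  The window is half-open [start, end) by default
    (``inclusive_end`` closes it).  Means are taken per treatment per day
    and then averaged across days, so partially logged days are not
    over-weighted.
    """
    df = records.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    tod = df["timestamp"].dt.time
    start, end = window
    sel = (tod >= start) & ((tod <= end) if inclusive_end else (tod < end))
    df = df[sel]
    if df.empty:
        raise ValueError(f"no records inside the window {start}-{end}")
    df = df.assign(
        vpd=vpd(df["temperature_c"].to_numpy(), df["relative_humidity"].to_numpy(),
                denom_const=denom_const),
        date=df["timestamp"].dt.date,
    )
    daily = df.groupby(["treatment", "date"], observed=True)[
        ["temperature_c", "relative_humidity", "vpd"]].mean()
    out = daily.groupby("treatment", observed=True).mean()
    out["n_records"] = df.groupby("treatment", observed=True).size()
    return WindowSummary(table=out, window=(start, end))


@dataclass
class AnovaResult:
    """Two-way ANOVA decomposition with Tukey HSD pairwise comparisons."""

    trait: str
    anova_table: pd.DataFrame   # F and p per term (class, day, interaction, residual)
    tukey: pd.DataFrame | None
    degenerate: bool = False

    def p_value(self, term: str) -> float:
        return float(self.anova_table.loc[term, "PR(>F)"])

    def f_value(self, term: str) -> float:
        return float(self.anova_table.loc[term, "F"])


def anova_two_way(traits: pd.DataFrame, trait: str) -> AnovaResult:
    """Class x day fixed-effects ANOVA + Tukey HSD for one trait.

    ``traits`` is the tidy trait table (columns tolerance_class, day,
    replicate, trait, value).  Uses Type-II sums of squares, which are
    unambiguous for main effects in unbalanced layouts and coincide with
    the classical decomposition when balanced.  An all-constant response
    (zero residual variance) is reported as degenerate with a warning
    rather than an error.
    """
    df = traits[traits["trait"] == trait].copy()
    if df.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    counts = df.groupby(["tolerance_class", "day"], observed=True).size()
    if (counts < 2).any():
        raise ValueError("every class x day cell needs >= 2 replicates for ANOVA")
    for col in ("tolerance_class", "day"):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs >= 2 levels")
    df["day"] = df["day"].astype(str)
    if np.isclose(df["value"].var(ddof=1), 0.0):
        warnings.warn(f"trait {trait!r}: all observations identical; "
                      "F statistics are undefined", stacklevel=2)
        terms = ["C(tolerance_class)", "C(day)", "C(tolerance_class):C(day)", "Residual"]
        tab = pd.DataFrame({"sum_sq": 0.0, "df": np.nan, "F": np.nan, "PR(>F)": np.nan},
                           index=terms)
        return AnovaResult(trait=trait, anova_table=tab, tukey=None, degenerate=True)
    model = smf.ols("value ~ C(tolerance_class) * C(day)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=2)
    cell = df["tolerance_class"].astype(str) + ":" + df["day"]
    hsd = pairwise_tukeyhsd(df["value"].to_numpy(), cell.to_numpy())
    tukey = pd.DataFrame(hsd.summary().data[1:], columns=hsd.summary().data[0])
    return AnovaResult(trait=trait, anova_table=tab, tukey=tukey)
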