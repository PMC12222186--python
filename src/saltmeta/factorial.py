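"""Factorial analysis of the experimental arm: salt stress x setting.

The experiment grows plants under control and saline treatments in several
settings at once, so the question "does the setting change the stress
response?" is the interaction term of a two-factor model.  The primary
analysis is a two-way ANOVA (type-II sums of squares, so mildly unbalanced
designs from lost plants are handled); when its residuals fail a
Shapiro-Wilk normality check the ANOVA is discarded and replaced by the
nonparametric Scheirer-Ray-Hare rank test, a two-factor extension of
Kruskal-Wallis computed from an ANOVA on mid-ranks:

    H_effect = SS_effect(ranks) / MS_total(ranks),
    MS_total = SS_total(ranks) / (N - 1),

with H referred to a chi-square distribution on the effect's degrees of
freedom.  Computing ``MS_total`` from the observed mid-ranks applies the
standard tie correction automatically.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "FactorialMethod",
    "EffectResult",
    "FactorialResult",
    "two_way_anova",
    "scheirer_ray_hare",
    "gated_factorial",
    "factorial_table",
]


class FactorialMethod(str, enum.Enum):
    ANOVA2 = "anova2"
    SCHEIRER_RAY_HARE = "scheirer_ray_hare"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class EffectResult:
    statistic: float
    df: int
    p_value: float
    sum_sq: float = float("nan")


@dataclass(frozen=True)
class FactorialResult:
    response: str
    method: FactorialMethod
    stress: EffectResult
    setting: EffectResult
    interaction: EffectResult
    residual_normality_p: float
    ss_residual: float = float("nan")
    ss_total: float = float("nan")  # on ranks for the rank test
    degenerate: bool = False
    note: str = ""

    @property
    def effects(self) -> dict[str, EffectResult]:
        return {
            "stress": self.stress,
            "setting": self.setting,
            "interaction": self.interaction,
        }


def _check_design(
    values: np.ndarray, stress: np.ndarray, setting: np.ndarray
) -> tuple[int, int]:
    if not (len(values) == len(stress) == len(setting)):
        raise ValueError("values and factor vectors must have equal length")
    a = len(np.unique(stress))
    b = len(np.unique(setting))
    if a < 2 or b < 2:
        raise ValueError("both factors need at least two levels")
    for s in np.unique(stress):
        for t in np.unique(setting):
            if not np.any((stress == s) & (setting == t)):
                raise ValueError(
                    f"empty design cell (stress={s!r}, setting={t!r}); "
                    "the interaction model needs every cell occupied"
                )
    return a, b


def _frame(values, stress, setting) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "stress": np.asarray(stress, dtype=object),
            "setting": np.asarray(setting, dtype=object),
        }
    )


def _degenerate(response: str, method: FactorialMethod, a: int, b: int, note: str):
    nan_effect = lambda df: EffectResult(np.nan, df, np.nan)  # noqa: E731
    return FactorialResult(
        response,
        method,
        nan_effect(a - 1),
        nan_effect(b - 1),
        nan_effect((a - 1) * (b - 1)),
        residual_normality_p=np.nan,
        degenerate=True,
        note=note,
    )


def two_way_anova(
    values: Sequence[float],
    factor_stress: Sequence,
    factor_setting: Sequence,
    response: str = "value",
) -> FactorialResult:
    """Two-way ANOVA with interaction, type-II sums of squares.

    The residual Shapiro-Wilk p-value is recorded on the result so callers
    (see :func:`gated_factorial`) can decide whether to trust the F tests.
    """
    df = _frame(values, factor_stress, factor_setting)
    a, b = _check_design(
        df["value"].to_numpy(), df["stress"].to_numpy(), df["setting"].to_numpy()
    )
    if np.ptp(df["value"].to_numpy()) == 0:
        return _degenerate(
            response, FactorialMethod.ANOVA2, a, b, "constant response"
        )
    model = smf.ols("value ~ C(stress) * C(setting)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    resid = model.resid.to_numpy()
    if np.ptp(resid) == 0 or resid.size < 3:
        shapiro_p = np.nan
    else:
        shapiro_p = float(stats.shapiro(resid).pvalue)

    def _eff(term: str) -> EffectResult:
        row = table.loc[term]
        return EffectResult(
            float(row["F"]), int(row["df"]), float(row["PR(>F)"]),
            sum_sq=float(row["sum_sq"]),
        )

    y = df["value"].to_numpy()
    return FactorialResult(
        response,
        FactorialMethod.ANOVA2,
        _eff("C(stress)"),
        _eff("C(setting)"),
        _eff("C(stress):C(setting)"),
        residual_normality_p=shapiro_p,
        ss_residual=float(table.loc["Residual", "sum_sq"]),
        ss_total=float(np.sum((y - y.mean()) ** 2)),
    )


def scheirer_ray_hare(
    values: Sequence[float],
    factor_stress: Sequence,
    factor_setting: Sequence,
    response: str = "value",
) -> FactorialResult:
    """Scheirer-Ray-Hare rank test for a two-factor design.

    All values are replaced by mid-ranks; sums of squares come from a
    type-II two-way ANOVA on the ranks; each effect's H statistic is its SS
    divided by the total rank mean square and is compared to chi-square on
    the effect's df.  Because it only uses ranks, the result is invariant
    under strictly increasing transforms of the response.
    """
    df = _frame(values, factor_stress, factor_setting)
    a, b = _check_design(
        df["value"].to_numpy(), df["stress"].to_numpy(), df["setting"].to_numpy()
    )
    y = df["value"].to_numpy()
    if np.ptp(y) == 0:
        return _degenerate(
            response, FactorialMethod.SCHEIRER_RAY_HARE, a, b, "all values tied"
        )
    ranks = stats.rankdata(y)
    df["rank"] = ranks
    n = len(ranks)
    ms_total = float(np.sum((ranks - ranks.mean()) ** 2)) / (n - 1)
    if ms_total == 0:
        return _degenerate(
            response, FactorialMethod.SCHEIRER_RAY_HARE, a, b, "all values tied"
        )
    model = smf.ols("rank ~ C(stress) * C(setting)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)

    def _eff(term: str) -> EffectResult:
        row = table.loc[term]
        h = float(row["sum_sq"]) / ms_total
        dof = int(row["df"])
        return EffectResult(
            h, dof, float(stats.chi2.sf(h, dof)), sum_sq=float(row["sum_sq"])
        )

    return FactorialResult(
        response,
        FactorialMethod.SCHEIRER_RAY_HARE,
        _eff("C(stress)"),
        _eff("C(setting)"),
        _eff("C(stress):C(setting)"),
        residual_normality_p=np.nan,
        ss_residual=float(table.loc["Residual", "sum_sq"]),
        ss_total=ms_total * (n - 1),
    )


def gated_factorial(
    values: Sequence[float],
    factor_stress: Sequence,
    factor_setting: Sequence,
    alpha_gate: float = 0.05,
    response: str = "value",
) -> FactorialResult:
    """Run the two-way ANOVA; fall back to Scheirer-Ray-Hare when the ANOVA
    residuals are declared non-normal by Shapiro-Wilk at ``alpha_gate``."""
    if len(values) < 3:
        raise ValueError("need at least 3 observations for the normality gate")
    anova = two_way_anova(values, factor_stress, factor_setting, response=response)
    p = anova.residual_normality_p
    if not np.isnan(p) and p <= alpha_gate:
        srh = scheirer_ray_hare(
            values, factor_stress, factor_setting, response=response
        )
        return FactorialResult(
            srh.response,
            srh.method,
            srh.stress,
            srh.setting,
            srh.interaction,
            residual_normality_p=p,
            ss_residual=srh.ss_residual,
            ss_total=srh.ss_total,
            degenerate=srh.degenerate,
            note=srh.note or "anova residuals non-normal; rank test used",
        )
    return anova


def factorial_table(results: Sequence[FactorialResult]) -> pd.DataFrame:
    """Flat per-effect table mirroring the in-figure statistics tables."""
    rows = []
    for r in results:
        for effect, e in r.effects.items():
            rows.append(
                {
                    "response": r.response,
                    "method": r.method.value,
                    "effect": effect,
                    "statistic": e.statistic,
                    "df": e.df,
                    "p_value": e.p_value,
                    "residual_normality_p": r.residual_normality_p,
                    "degenerate": r.degenerate,
                }
            )
    return pd.DataFrame(rows)
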