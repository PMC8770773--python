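"""Repeated-measures behavioral statistics.

Ratings and SCR condition means are analyzed with a 2x2 fully
within-participant ANOVA (factors CS-Type: CS+/CS-, and Instruction:
view/imagine or view/regulate) reporting generalized eta-squared, plus
paired and one-sample t-tests with Cohen's d.

For a two-level within factor the F ratio is the classical
SS_effect / SS_effect-by-subject decomposition with df = (1, n-1).
Generalized eta-squared divides SS_effect by SS_effect plus *all*
subject-related sums of squares (subject main effect and every
factor-by-subject error term), which makes the measure comparable across
designs; it is systematically smaller than partial eta-squared.

Cohen's d for paired contrasts is mean(diff) / sd(diff) (the difference-
standard-deviation convention); a pooled-SD variant is available via
``d_convention="av"`` (mean difference over the average of the two
condition SDs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WithinSubjectTable",
    "AnovaResult",
    "TTestResult",
    "rm_anova_2x2",
    "paired_t",
    "one_sample_t",
]

_TINY_P = np.finfo(float).tiny


class StatsInputError(ValueError):
    pass


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    eta_G_sq: float


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    tail: str          # "one" or "two"
    cohen_d: float
    degenerate: bool = False   # zero variance with nonzero effect; p at machine bound


@dataclass
class WithinSubjectTable:
    """One value per participant per cell of a 2x2 within design.

    Built from a tidy frame with columns participant, the two factor
    columns, and a value column.  Participants with incomplete crossings
    are dropped listwise.
    """

    data: pd.DataFrame          # participants x 4 cells, MultiIndex columns
    factor_a: str
    factor_b: str

    @classmethod
    def from_tidy(
        cls,
        tidy: pd.DataFrame,
        factor_a: str,
        factor_b: str,
        value: str = "value",
        participant: str = "participant",
    ) -> "WithinSubjectTable":
        levels_a = sorted(tidy[factor_a].unique())
        levels_b = sorted(tidy[factor_b].unique())
        if len(levels_a) != 2 or len(levels_b) != 2:
            raise StatsInputError("both factors must have exactly 2 levels")
        wide = tidy.pivot_table(
            index=participant, columns=[factor_a, factor_b], values=value
        )
        wide = wide.dropna(axis=0, how="any")   # listwise deletion
        if wide.shape[1] != 4:
            raise StatsInputError("incomplete 2x2 crossing")
        return cls(data=wide, factor_a=factor_a, factor_b=factor_b)

    @property
    def n_participants(self) -> int:
        return len(self.data)

    def cells(self) -> np.ndarray:
        """(n, 2, 2) array ordered by sorted factor levels."""
        levels_a = sorted({a for a, _ in self.data.columns})
        levels_b = sorted({b for _, b in self.data.columns})
        out = np.empty((len(self.data), 2, 2))
        for i, a in enumerate(levels_a):
            for j, b in enumerate(levels_b):
                out[:, i, j] = self.data[(a, b)].to_numpy()
        return out


def rm_anova_2x2(table: WithinSubjectTable) -> list[AnovaResult]:
    """2x2 within-participant ANOVA: main effects, interaction, eta_G^2.

    Sums of squares use the participant as the blocking unit; each effect
    is tested against its own effect-by-subject error term with
    df = (1, n-1).
    """
    y = table.cells()                       # (n, 2, 2)
    n = y.shape[0]
    if n < 2:
        raise StatsInputError("need >= 2 complete participants")

    grand = y.mean()
    m_a = y.mean(axis=(0, 2))               # level means of factor A
    m_b = y.mean(axis=(0, 1))
    m_s = y.mean(axis=(1, 2))               # participant means
    m_ab = y.mean(axis=0)                   # (2, 2)
    m_as = y.mean(axis=2)                   # (n, 2)
    m_bs = y.mean(axis=1)                   # (n, 2)

    ss_a = 2 * n * np.sum((m_a - grand) ** 2)
    ss_b = 2 * n * np.sum((m_b - grand) ** 2)
    ss_s = 4 * np.sum((m_s - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = 2 * np.sum((m_as - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = 2 * np.sum((m_bs - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_abs = ss_total - (ss_a + ss_b + ss_s + ss_ab + ss_as + ss_bs)
    ss_abs = max(ss_abs, 0.0)               # guard tiny negative rounding

    ss_subject_related = ss_s + ss_as + ss_bs + ss_abs
    df_den = n - 1

    results = []
    for effect, ss_eff, ss_err in (
        (table.factor_a, ss_a, ss_as),
        (table.factor_b, ss_b, ss_bs),
        (f"{table.factor_a} x {table.factor_b}", ss_ab, ss_abs),
    ):
        if ss_err == 0:
            F = 0.0 if ss_eff == 0 else np.inf
        else:
            F = (ss_eff / 1) / (ss_err / df_den)
        p = float(stats.f.sf(F, 1, df_den)) if np.isfinite(F) else 0.0
        denom = ss_eff + ss_subject_related
        eta = float(ss_eff / denom) if denom > 0 else 0.0
        results.append(
            AnovaResult(effect=effect, F=float(F), df_num=1, df_den=df_den,
                        p=p, eta_G_sq=eta)
        )
    return results


def _t_result(t: float, df: int, tail: str, d: float,
              degenerate: bool = False) -> TTestResult:
    if degenerate:
        p = _TINY_P
    else:
        p_two = 2.0 * float(stats.t.sf(abs(t), df))
        # one-tailed: half the two-tailed p when the effect is in the
        # hypothesized (positive) direction
        p = p_two / 2.0 if (tail == "one" and t > 0) else (
            1.0 - p_two / 2.0 if tail == "one" else p_two
        )
    return TTestResult(t=float(t), df=df, p=float(p), tail=tail,
                       cohen_d=float(d), degenerate=degenerate)


def paired_t(
    x, y, tail: str = "two", d_convention: str = "diff"
) -> TTestResult:
    """Paired t-test on x - y with Cohen's d.

    ``d_convention="diff"`` (default): d = mean(diff)/sd(diff);
    ``"av"``: mean(diff) over the average of the SDs of x and y.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise StatsInputError("x and y must be equal-length 1-D, n >= 2")
    diff = x - y
    n = len(diff)
    sd = diff.std(ddof=1)
    if d_convention == "diff":
        d = diff.mean() / sd if sd > 0 else 0.0
    elif d_convention == "av":
        sd_av = (x.std(ddof=1) + y.std(ddof=1)) / 2
        d = diff.mean() / sd_av if sd_av > 0 else 0.0
    else:
        raise StatsInputError(f"unknown d convention {d_convention!r}")
    if sd == 0:
        if diff.mean() == 0:
            return _t_result(0.0, n - 1, tail, 0.0)
        return _t_result(np.inf if diff.mean() > 0 else -np.inf, n - 1, tail,
                         d, degenerate=True)
    t = diff.mean() / (sd / np.sqrt(n))
    return _t_result(t, n - 1, tail, d)


def one_sample_t(x, mu: float = 0.0, tail: str = "two") -> TTestResult:
    """One-sample t-test of mean(x) against ``mu`` (d = (mean - mu)/sd)."""
    x = np.asarray(x, float)
    if x.ndim != 1 or len(x) < 2:
        raise StatsInputError("x must be 1-D with n >= 2")
    n = len(x)
    sd = x.std(ddof=1)
    delta = x.mean() - mu
    if sd == 0:
        if delta == 0:
            return _t_result(0.0, n - 1, tail, 0.0)
        return _t_result(np.inf if delta > 0 else -np.inf, n - 1, tail,
                         np.inf if delta > 0 else -np.inf, degenerate=True)
    t = delta / (sd / np.sqrt(n))
    return _t_result(t, n - 1, tail, delta / sd)
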