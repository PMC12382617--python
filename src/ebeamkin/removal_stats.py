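"""Removal percentages with confidence intervals, two-way ANOVA and Tukey HSD.

Removal at dose D is computed per replicate against the mean unirradiated
peak area of the same analyte, ``100 * (1 - area(D) / mean area(0))``, and
summarized with a Student-t confidence interval over replicates.

The fixed-effects two-way ANOVA (factors: antibiotic and dose, with
interaction) is computed directly from its sums-of-squares decomposition on
a balanced design; pairwise antibiotic comparisons use Tukey's honestly
significant difference with the studentized-range distribution, or a
seed-controlled permutation fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, ValidationError
from .peak_tables import PeakTable

__all__ = [
    "RemovalRecord",
    "AnovaResult",
    "removal_table",
    "removal_frame",
    "removal_long_frame",
    "two_way_anova",
    "tukey_hsd",
]


@dataclass(frozen=True)
class RemovalRecord:
    """Replicate removal percentages at one (antibiotic, dose) cell."""

    antibiotic: str
    dose_kGy: float
    removals: tuple[float, ...]
    mean: float
    ci_halfwidth: float
    n: int
    confidence: float = 0.95


def removal_table(
    table: PeakTable, analyte: str, confidence: float = 0.95
) -> list[RemovalRecord]:
    """Per-dose removal percentages for one antibiotic.

    Censored ("not detected") observations count as complete removal (100%).
    The confidence-interval halfwidth is ``t_{1-(1-c)/2, n-1} * sd / sqrt(n)``;
    it is 0 when a dose has a single replicate.
    """
    d, y = table.arrays(analyte, include_censored=True)
    if d.size == 0:
        raise InsufficientDataError(f"no observations for analyte {analyte!r}")
    zero = (d == 0.0) & (y > 0)
    if not zero.any():
        raise InsufficientDataError(
            f"analyte {analyte!r}: dose-0 data required for removal"
        )
    baseline = float(np.mean(y[zero]))
    records: list[RemovalRecord] = []
    for dose in np.unique(d):
        vals = 100.0 * (1.0 - y[d == dose] / baseline)
        n = vals.size
        mean = float(np.mean(vals))
        if n > 1 and np.ptp(vals) > 0:
            half = float(
                stats.t.ppf(1 - (1 - confidence) / 2, n - 1)
                * np.std(vals, ddof=1)
                / math.sqrt(n)
            )
        else:
            half = 0.0
        records.append(
            RemovalRecord(
                antibiotic=analyte,
                dose_kGy=float(dose),
                removals=tuple(float(v) for v in vals),
                mean=mean,
                ci_halfwidth=half,
                n=int(n),
                confidence=confidence,
            )
        )
    return records


def removal_frame(records: Sequence[RemovalRecord]) -> pd.DataFrame:
    """Summary DataFrame (one row per antibiotic x dose cell)."""
    return pd.DataFrame(
        {
            "antibiotic": [r.antibiotic for r in records],
            "dose_kGy": [r.dose_kGy for r in records],
            "mean_removal_percent": [r.mean for r in records],
            "ci_halfwidth": [r.ci_halfwidth for r in records],
            "n": [r.n for r in records],
        }
    )


def removal_long_frame(
    table: PeakTable, analytes: Sequence[str], include_dose0: bool = False
) -> pd.DataFrame:
    """Long-format replicate removal data for several antibiotics.

    Dose-0 rows (removal identically 0, zero variance) are excluded by
    default, as they would degenerate the ANOVA error term.
    """
    rows = []
    for analyte in analytes:
        for rec in removal_table(table, analyte):
            if rec.dose_kGy == 0.0 and not include_dose0:
                continue
            for i, v in enumerate(rec.removals, start=1):
                rows.append(
                    {
                        "antibiotic": rec.antibiotic,
                        "dose_kGy": rec.dose_kGy,
                        "replicate": i,
                        "removal_percent": v,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Two-way fixed-effects ANOVA with interaction


@dataclass(frozen=True)
class AnovaResult:
    """Sums of squares, F statistics and p-values of the two-way layout."""

    ss_a: float
    ss_b: float
    ss_ab: float
    ss_error: float
    ss_total: float
    df_a: int
    df_b: int
    df_ab: int
    df_error: int
    f_a: float
    f_b: float
    f_ab: float
    p_a: float
    p_b: float
    p_ab: float
    factor_a: str
    factor_b: str
    cell_n: int
    a_levels: tuple
    b_levels: tuple

    @property
    def mse(self) -> float:
        return self.ss_error / self.df_error if self.df_error > 0 else math.nan

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": [self.factor_a, self.factor_b, "interaction", "error", "total"],
                "ss": [self.ss_a, self.ss_b, self.ss_ab, self.ss_error, self.ss_total],
                "df": [self.df_a, self.df_b, self.df_ab, self.df_error,
                       self.df_a + self.df_b + self.df_ab + self.df_error],
                "F": [self.f_a, self.f_b, self.f_ab, math.nan, math.nan],
                "p": [self.p_a, self.p_b, self.p_ab, math.nan, math.nan],
            }
        )

    def summary(self) -> str:
        return self.table().to_string(index=False, float_format=lambda x: f"{x:.6g}")


def _f_and_p(ss: float, df: int, mse: float, df_error: int) -> tuple[float, float]:
    if ss <= 0 or df == 0:
        return 0.0, 1.0
    if mse == 0:
        return math.inf, 0.0
    f = (ss / df) / mse
    return f, float(stats.f.sf(f, df, df_error))


def two_way_anova(
    data: pd.DataFrame,
    response: str = "removal_percent",
    factor_a: str = "antibiotic",
    factor_b: str = "dose_kGy",
) -> AnovaResult:
    """Classical balanced two-way fixed-effects ANOVA with interaction.

    Computed directly from the sums-of-squares decomposition

        SS_total = SS_A + SS_B + SS_AB + SS_error,

    with F statistics referred to the F distribution.  Requires a balanced
    design (the same number of replicates in every cell, >= 2 levels per
    factor, >= 2 replicates per cell).
    """
    for col in (response, factor_a, factor_b):
        if col not in data.columns:
            raise ValidationError(f"missing column {col!r}")
    y = data[response].to_numpy(dtype=float)
    a = data[factor_a].to_numpy()
    b = data[factor_b].to_numpy()
    a_levels = tuple(pd.unique(a))
    b_levels = tuple(pd.unique(b))
    na, nb = len(a_levels), len(b_levels)
    if na < 2 or nb < 2:
        raise InsufficientDataError("need >= 2 levels per factor")
    counts = data.groupby([factor_a, factor_b], sort=False).size()
    if counts.size != na * nb or counts.nunique() != 1:
        raise ValidationError("unbalanced design: equal replication per cell required")
    n = int(counts.iloc[0])
    if n < 2:
        raise ValidationError("need >= 2 replicates per cell for the error term")

    ai = pd.Categorical(a, categories=a_levels).codes
    bi = pd.Categorical(b, categories=b_levels).codes
    grand = y.mean()
    # cell / marginal means via bincount
    cell_sum = np.zeros((na, nb))
    np.add.at(cell_sum, (ai, bi), y)
    cell_mean = cell_sum / n
    mean_a = cell_mean.mean(axis=1)
    mean_b = cell_mean.mean(axis=0)

    ss_a = n * nb * float(np.sum((mean_a - grand) ** 2))
    ss_b = n * na * float(np.sum((mean_b - grand) ** 2))
    ss_ab = n * float(
        np.sum((cell_mean - mean_a[:, None] - mean_b[None, :] + grand) ** 2)
    )
    ss_error = float(np.sum((y - cell_mean[ai, bi]) ** 2))
    ss_total = float(np.sum((y - grand) ** 2))

    df_a, df_b = na - 1, nb - 1
    df_ab = df_a * df_b
    df_error = na * nb * (n - 1)
    mse = ss_error / df_error
    f_a, p_a = _f_and_p(ss_a, df_a, mse, df_error)
    f_b, p_b = _f_and_p(ss_b, df_b, mse, df_error)
    f_ab, p_ab = _f_and_p(ss_ab, df_ab, mse, df_error)
    return AnovaResult(
        ss_a=ss_a, ss_b=ss_b, ss_ab=ss_ab, ss_error=ss_error, ss_total=ss_total,
        df_a=df_a, df_b=df_b, df_ab=df_ab, df_error=df_error,
        f_a=f_a, f_b=f_b, f_ab=f_ab, p_a=p_a, p_b=p_b, p_ab=p_ab,
        factor_a=factor_a, factor_b=factor_b, cell_n=n,
        a_levels=a_levels, b_levels=b_levels,
    )


# ---------------------------------------------------------------------------
# Tukey's honestly significant difference over factor A


def tukey_hsd(
    data: pd.DataFrame,
    anova: AnovaResult | None = None,
    response: str = "removal_percent",
    factor_a: str = "antibiotic",
    factor_b: str = "dose_kGy",
    alpha: float = 0.05,
    method: str = "studentized-range",
    n_permutations: int = 10000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Pairwise comparison of factor-A level means.

    The q statistic per pair is ``|mean_i - mean_j| / sqrt(MSE / m)`` with m
    observations per level and the MSE/df taken from the two-way ANOVA.
    With ``method="studentized-range"`` p-values come from the
    studentized-range distribution; ``method="permutation"`` uses the null
    distribution of the maximum q over >= 10^4 label permutations (factor-A
    labels shuffled within each factor-B level; seed-controlled).
    """
    if anova is None:
        anova = two_way_anova(data, response, factor_a, factor_b)
    levels = anova.a_levels
    k = len(levels)
    if k < 2:
        raise InsufficientDataError("need >= 2 factor-A levels")
    m = anova.cell_n * len(anova.b_levels)  # observations per factor-A level
    means = data.groupby(factor_a, sort=False)[response].mean()
    mse, df_err = anova.mse, anova.df_error

    def q_stats(level_means) -> list[tuple]:
        out = []
        denom = math.sqrt(mse / m)
        for i in range(k):
            for j in range(i + 1, k):
                diff = float(level_means[levels[i]] - level_means[levels[j]])
                q = abs(diff) / denom if denom > 0 else (0.0 if diff == 0 else math.inf)
                out.append((levels[i], levels[j], diff, q))
        return out

    pairs = q_stats(means)
    if method == "studentized-range":
        rows = [
            {
                "level_1": p[0],
                "level_2": p[1],
                "mean_diff": p[2],
                "q": p[3],
                "p": float(stats.studentized_range.sf(p[3], k, df_err))
                if math.isfinite(p[3])
                else 0.0,
            }
            for p in pairs
        ]
        for r in rows:
            r["significant"] = r["p"] <= alpha
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        b_vals = data[factor_b].to_numpy()
        a_vals = data[factor_a].to_numpy().copy()
        y = data[response].to_numpy(dtype=float)
        qmax_null = np.empty(n_permutations)
        df_work = data[[factor_a, factor_b, response]].copy()
        for it in range(n_permutations):
            perm_a = a_vals.copy()
            for bl in anova.b_levels:
                idx = np.flatnonzero(b_vals == bl)
                perm_a[idx] = perm_a[rng.permutation(idx)]
            df_work[factor_a] = perm_a
            an_p = two_way_anova(df_work, response, factor_a, factor_b)
            pm = df_work.groupby(factor_a, sort=False)[response].mean()
            denom = math.sqrt(an_p.mse / m) if an_p.mse > 0 else math.nan
            qs = [
                abs(float(pm[levels[i]] - pm[levels[j]])) / denom
                for i in range(k)
                for j in range(i + 1, k)
            ]
            qmax_null[it] = max(qs)
        rows = []
        for p in pairs:
            pval = float((1 + np.sum(qmax_null >= p[3])) / (n_permutations + 1))
            rows.append(
                {
                    "level_1": p[0],
                    "level_2": p[1],
                    "mean_diff": p[2],
                    "q": p[3],
                    "p": pval,
                    "significant": pval <= alpha,
                }
            )
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(rows)
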