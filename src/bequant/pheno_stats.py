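"""Phenotype-side summaries: correlations, contrasts, fold changes.

The operations here are the downstream arithmetic applied to editing
outcomes joined with per-animal phenotype measurements: Pearson
correlation with a Fisher-z confidence interval, Welch's two-sample t
test, percent change and fold ratios of group means, delta-delta-Ct
relative qPCR quantification (fold = 2^(-ddCt)), and the composite
cerebellar ataxia score (four 0-3 items plus a 0/1 pelvic-tilt item,
summing to 0-13).

Reported values round half away from zero to one decimal (so 1.25
renders "1.3"); stored values are never rounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (1.25 -> 1.3), unlike banker's rounding."""
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    ci_low: float
    ci_high: float
    n: int

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("correlation needs n >= 3")
        if not (self.ci_low - 1e-12 <= self.r <= self.ci_high + 1e-12):
            raise ValueError("confidence interval must contain r")


def pearson(x: Sequence[float], y: Sequence[float],
            confidence: float = 0.95) -> CorrelationResult:
    """Product-moment correlation with t-test p and Fisher-z CI.

    p is two-sided from t = r sqrt((n-2)/(1-r^2)) on n-2 df; the CI uses
    the inverse hyperbolic tangent (Fisher z) transform with standard
    error 1/sqrt(n-3).  Degenerate |r| = 1 gives a point interval.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("correlation needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero variance input")
    r = float(stats.pearsonr(x, y).statistic)
    if abs(r) >= 1.0 - 1e-15:
        r = math.copysign(1.0, r)
        return CorrelationResult(r=r, p=0.0, ci_low=r, ci_high=r, n=n)
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    if n > 3:
        z = math.atanh(r)
        zcrit = stats.norm.ppf(0.5 + confidence / 2.0)
        se = 1.0 / math.sqrt(n - 3)
        lo, hi = math.tanh(z - zcrit * se), math.tanh(z + zcrit * se)
    else:
        lo, hi = -1.0, 1.0
    return CorrelationResult(r=r, p=float(p), ci_low=lo, ci_high=hi, n=n)


def percent_change(mean_treated: float, mean_control: float) -> float:
    """100 x (treated - control) / control; report with one decimal."""
    if mean_control <= 0:
        raise ValueError("control mean must be positive")
    return 100.0 * (mean_treated - mean_control) / mean_control


def fold_ratio(a: float, b: float) -> float:
    """a / b; report with one decimal (round_half_away)."""
    if b <= 0:
        raise ValueError("denominator must be positive")
    return a / b


def welch_t(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t test: (t, Satterthwaite df, two-sided p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def ddct_fold_change(
    ct: pd.DataFrame,
    gene: str,
    sample_group: str,
    calibrator_group: str,
    reference_gene: str = "Akt",
    group_col: str = "group",
    gene_col: str = "gene",
    ct_col: str = "ct",
    sample_col: str = "sample",
) -> float:
    """Relative expression by the delta-delta-Ct method.

    Per sample, dCt = Ct(gene) - Ct(reference gene); ddCt is the mean dCt
    of ``sample_group`` minus the mean dCt of ``calibrator_group``; the
    fold change is 2^(-ddCt).  The calibrator against itself is exactly 1.
    """
    wide = ct.pivot_table(
        index=[sample_col, group_col], columns=gene_col, values=ct_col
    )
    if reference_gene not in wide.columns:
        raise ValueError(f"reference gene {reference_gene!r} missing from table")
    if gene not in wide.columns:
        raise ValueError(f"gene {gene!r} missing from table")
    if wide[reference_gene].isna().any():
        missing = wide[wide[reference_gene].isna()].index.tolist()
        raise ValueError(f"reference gene missing for samples {missing}")
    dct = wide[gene] - wide[reference_gene]
    groups = dct.index.get_level_values(group_col)
    for g in (sample_group, calibrator_group):
        if g not in set(groups):
            raise ValueError(f"group {g!r} missing from table")
    ddct = dct[groups == sample_group].mean() - dct[groups == calibrator_group].mean()
    return float(2.0 ** (-ddct))


_ATAXIA_ITEMS = ("hindlimb", "gait", "kyphosis", "ledge")


def ataxia_composite(hindlimb: int, gait: int, kyphosis: int, ledge: int,
                     pelvic_tilt: int) -> int:
    """Composite cerebellar ataxia score in [0, 13].

    Four items scored 0-3 (hindlimb clasping, gait, kyphosis, ledge
    walking) plus pelvic tilt scored present (1) or absent (0); higher
    means worse neurological state.
    """
    items = dict(zip(_ATAXIA_ITEMS, (hindlimb, gait, kyphosis, ledge)))
    for name, value in items.items():
        if not isinstance(value, (int, np.integer)) or not (0 <= value <= 3):
            raise ValueError(f"{name} score {value!r} outside 0-3")
    if pelvic_tilt not in (0, 1):
        raise ValueError(f"pelvic_tilt {pelvic_tilt!r} must be 0 or 1")
    return int(hindlimb + gait + kyphosis + ledge + pelvic_tilt)


# ---------------------------------------------------------------------------
# joined editing/phenotype report
# ---------------------------------------------------------------------------

DEFAULT_PHENOTYPES = ("bodyweight_g", "grip_strength_n", "traverse_time_s")


def correlation_report(
    phenotypes: pd.DataFrame,
    editing_cols: Sequence[str],
    phenotype_cols: Sequence[str] = DEFAULT_PHENOTYPES,
    stratify_by: Optional[str] = "genotype",
    min_n: int = 3,
) -> pd.DataFrame:
    """One Pearson correlation per (editing outcome, phenotype) pair per
    stratum, on per-animal rows that have both values.

    Strata with fewer than ``min_n`` complete pairs are skipped with a
    warning row count of zero entries; duplicated animal ids are an error.
    """
    if phenotypes["animal_id"].duplicated().any():
        dupes = phenotypes.loc[
            phenotypes["animal_id"].duplicated(), "animal_id"
        ].tolist()
        raise ValueError(f"duplicated animal ids {dupes}")
    if stratify_by is None:
        strata = [("all", phenotypes)]
    else:
        strata = list(phenotypes.groupby(stratify_by, sort=True))
    rows = []
    for stratum, df in strata:
        for ecol in editing_cols:
            for pcol in phenotype_cols:
                pair = df[[ecol, pcol]].dropna()
                if len(pair) < min_n:
                    continue
                try:
                    res = pearson(pair[ecol].to_numpy(), pair[pcol].to_numpy())
                except ValueError:
                    continue
                rows.append(
                    {
                        "stratum": stratum,
                        "editing_outcome": ecol,
                        "phenotype": pcol,
                        "r": res.r,
                        "p": res.p,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "n": res.n,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["stratum", "editing_outcome", "phenotype",
                 "r", "p", "ci_low", "ci_high", "n"],
    )
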