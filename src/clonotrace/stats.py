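"""Group-comparison statistics used by the repertoire pipeline.

Thin, contract-carrying wrappers around scipy/statsmodels: unpaired
Student's t (pooled variance), Welch's t (Welch–Satterthwaite df), and
two-way ANOVA with Type II sums of squares for unbalanced layouts.  All
tests are two-sided; degenerate inputs (zero variance in both groups) get
explicit handling instead of NaNs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf


@dataclass(frozen=True)
class GroupComparison:
    test: str
    group_labels: tuple[str, str]
    n: tuple[int, ...]
    statistic: float
    p_value: float
    alpha: float = 0.05
    note: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _t_test(
    a, b, equal_var: bool, name: str, labels: tuple[str, str], alpha: float
) -> GroupComparison:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"{name} requires n >= 2 per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if a.mean() == b.mean():
            return GroupComparison(name, labels, (len(a), len(b)), 0.0, 1.0, alpha,
                                   note="zero variance, equal means")
        return GroupComparison(name, labels, (len(a), len(b)), float("inf"), 0.0, alpha,
                               note="zero variance, unequal means; statistic infinite")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return GroupComparison(name, labels, (len(a), len(b)), float(t), float(p), alpha)


def student_t(a, b, labels=("a", "b"), alpha: float = 0.05) -> GroupComparison:
    """Unpaired two-sample Student's t-test (pooled variance, two-sided)."""
    return _t_test(a, b, True, "student_t", tuple(labels), alpha)


def welch_t(a, b, labels=("a", "b"), alpha: float = 0.05) -> GroupComparison:
    """Welch's two-sample t-test (unequal variances, two-sided)."""
    return _t_test(a, b, False, "welch_t", tuple(labels), alpha)


def two_way_anova(
    values, factor1, factor2, alpha: float = 0.05
) -> dict[str, GroupComparison]:
    """Two-way ANOVA with Type II sums of squares.

    Returns comparisons keyed ``factor1``, ``factor2`` and (when estimable,
    i.e. replicated cells) ``interaction``.  Type II is appropriate for the
    unbalanced group sizes typical of animal studies.
    """
    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "f1": pd.Categorical(factor1),
        "f2": pd.Categorical(factor2),
    })
    for col in ("f1", "f2"):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col} has a single level")
    if df["value"].nunique() == 1:
        # constant response: every effect is exactly null
        cmp_ = GroupComparison("two_way_anova", ("f1", "f2"), (len(df),), 0.0, 1.0,
                               alpha, "zero variance")
        return {"factor1": cmp_, "factor2": cmp_, "interaction": cmp_}
    full = smf.ols("value ~ C(f1) * C(f2)", data=df).fit()
    keys = {"C(f1)": "factor1", "C(f2)": "factor2", "C(f1):C(f2)": "interaction"}
    if full.df_resid > 0:
        model, note = full, ""
    else:
        model, note = smf.ols("value ~ C(f1) + C(f2)", data=df).fit(), \
            "no replication; interaction not estimable"
    table = sm.stats.anova_lm(model, typ=2)
    out: dict[str, GroupComparison] = {}
    n = (len(df),)
    for row, key in keys.items():
        if row not in table.index:
            continue
        f = table.loc[row, "F"]
        p = table.loc[row, "PR(>F)"]
        row_note = note
        if np.isnan(f):  # all-equal responses: no variance anywhere
            f, p, row_note = 0.0, 1.0, (note + "; " if note else "") + "zero variance"
        out[key] = GroupComparison("two_way_anova", ("f1", "f2"), n, float(f),
                                   float(p), alpha, row_note)
    return out
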