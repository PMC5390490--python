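"""Factorial ANOVA, Duncan's multiple range test, and simple regressions.

The experimental design is a fixed-effects factorial: species x irrigation
x growth temperature with 4-5 replicates per cell. Treatment means are
compared post hoc with Duncan's new multiple range test at P < 0.05; the
relationships between traits (e.g. AN vs. Rubisco activation state,
activation state vs. J) are summarised by ordinary least squares.

Duncan's test compares the range of every pair of ordered means spanning
p ranks against the least significant range

    LSR_p = q(alpha_p, p, df) * sqrt(MS_res / n),
    alpha_p = 1 - (1 - alpha)^(p-1),

where q is the studentized-range quantile at Duncan's protection level
alpha_p. The step-down rule applies: a span declared non-significant
protects all spans nested inside it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

#: Classical Duncan 5% significant-range table (df -> [p=2..6]), the
#: historical definition of the test; used to cross-check the numerical
#: inversion of the studentized-range distribution. The p=2 column equals
#: sqrt(2) * t_{0.975, df}.
DUNCAN_TABLE_5PCT = {
    5: (3.635, 3.749, 3.796, 3.814, 3.814),
    10: (3.151, 3.293, 3.376, 3.430, 3.465),
    20: (2.950, 3.097, 3.190, 3.255, 3.303),
    30: (2.888, 3.035, 3.131, 3.199, 3.250),
}


@lru_cache(maxsize=4096)
def duncan_q(alpha: float, p: int, df: float) -> float:
    """Duncan's critical value: studentized-range quantile at the
    protection level alpha_p = 1 - (1-alpha)^(p-1).

    Cached: the studentized-range ppf is expensive and the test re-uses
    the same (p, df) pairs for every span.
    """
    if p < 2:
        raise ValidationError("span p must be >= 2")
    alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
    return float(sps.studentized_range.ppf(1.0 - alpha_p, p, df))


# ---------------------------------------------------------------------------
# Factorial ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaTable:
    """Fixed-effects ANOVA with all interactions."""

    table: pd.DataFrame      # index: effect names + Residual; SS, df, MS, F, p
    ms_residual: float
    df_residual: float
    balanced: bool

    def p_value(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])


def factorial_anova(
    data: pd.DataFrame,
    response: str,
    factors: list[str],
) -> AnovaTable:
    """Fixed-effects factorial ANOVA with all interactions.

    Balanced designs yield the exact orthogonal SS partition; unbalanced
    designs (replicate loss) fall back to Type II sums of squares with a
    warning. Empty cells raise, naming the cell.
    """
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    if response not in data.columns:
        raise ValidationError(f"response column {response!r} not in data")
    for f in factors:
        if f not in data.columns:
            raise ValidationError(f"factor column {f!r} not in data")
        if data[f].nunique() < 2:
            raise ValidationError(f"factor {f!r} has fewer than 2 levels")
    counts = data.groupby(factors, observed=True).size()
    full = np.prod([data[f].nunique() for f in factors])
    if len(counts) < full:
        present = set(counts.index)
        from itertools import product
        levels = [sorted(data[f].unique()) for f in factors]
        missing = [c for c in product(*levels)
                   if (c if len(c) > 1 else c[0]) not in present]
        raise ValidationError(f"empty design cell(s): {missing}")
    if counts.min() < 2:
        raise ValidationError("each design cell needs >= 2 replicates")
    balanced = counts.nunique() == 1
    if not balanced:
        warnings.warn(
            "unbalanced design: using Type II sums of squares", stacklevel=2
        )
    # subset so stray data columns (e.g. one named 'C') cannot shadow
    # patsy's categorical operator
    df = data[[response] + factors].rename(columns={response: "_y"})
    rhs = "*".join(f"C({f})" for f in factors)
    model = ols(f"_y ~ {rhs}", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(
        columns={"sum_sq": "SS", "F": "F", "PR(>F)": "p"}
    )
    table["MS"] = table["SS"] / table["df"]
    table = table[["SS", "df", "MS", "F", "p"]]
    # human-readable effect names: C(species):C(irrigation) -> species:irrigation
    table.index = [
        i.replace("C(", "").replace(")", "") for i in table.index
    ]
    resid = table.loc["Residual"]
    return AnovaTable(
        table=table,
        ms_residual=float(resid["MS"]),
        df_residual=float(resid["df"]),
        balanced=balanced,
    )


# ---------------------------------------------------------------------------
# Duncan's multiple range test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DuncanGrouping:
    """Means ranked ascending with letter codes; shared letter = not
    significantly different at alpha."""

    labels: tuple[str, ...]          # sorted by mean, ascending
    means: tuple[float, ...]
    letters: dict[str, str]          # label -> letter string, e.g. 'ab'
    significant: dict[tuple[str, str], bool]
    lsr: tuple[float, ...]           # LSR for span p = 2..k
    alpha: float


def duncan_test(
    groups: list[tuple[str, np.ndarray]],
    alpha: float = 0.05,
    ms_error: float | None = None,
    df_error: float | None = None,
) -> DuncanGrouping:
    """Duncan's new multiple range test.

    ``groups`` is a list of (label, replicate values). ``ms_error`` and
    ``df_error`` default to the one-way ANOVA residual of the groups
    themselves; pass the factorial ANOVA residual to match the original
    analysis. Unequal group sizes are handled with the harmonic mean n
    (with a warning).
    """
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    labels = [g[0] for g in groups]
    values = [np.asarray(g[1], dtype=float) for g in groups]
    ns = np.array([len(v) for v in values])
    if np.any(ns < 2):
        raise ValidationError("each group needs n >= 2")
    if ms_error is None or df_error is None:
        df_error = float(np.sum(ns - 1))
        ms_error = float(
            sum(np.sum((v - v.mean()) ** 2) for v in values) / df_error
        )
    if ns.min() != ns.max():
        warnings.warn(
            "unequal group sizes: using harmonic mean n", stacklevel=2
        )
        n_eff = len(ns) / np.sum(1.0 / ns)
    else:
        n_eff = float(ns[0])

    means = np.array([v.mean() for v in values])
    order = np.argsort(means, kind="stable")
    slabels = [labels[i] for i in order]
    smeans = means[order]
    k = len(groups)
    se = np.sqrt(ms_error / n_eff)
    lsr = {p: duncan_q(alpha, p, df_error) * se for p in range(2, k + 1)}

    # step-down: spans are significant iff range > LSR_p AND no enclosing
    # span was declared non-significant.
    nonsig_span = np.zeros((k, k), dtype=bool)  # [i, j], i < j
    sig = {}
    for span in range(k, 1, -1):  # widest first
        p = span
        for i in range(0, k - span + 1):
            j = i + span - 1
            rng_ij = smeans[j] - smeans[i]
            protected = any(
                nonsig_span[a, b]
                for a in range(0, i + 1)
                for b in range(j, k)
                if (a, b) != (i, j) and b - a > j - i
            )
            significant = (rng_ij > lsr[p]) and not protected
            if not significant:
                nonsig_span[i, j] = True
            sig[(slabels[i], slabels[j])] = significant
            sig[(slabels[j], slabels[i])] = significant

    # letters: one letter per maximal non-significant run of adjacent means
    spans = []
    for i in range(k):
        j = i
        while j + 1 < k and not sig[(slabels[i], slabels[j + 1])]:
            j += 1
        spans.append((i, j))
    maximal = [
        (i, j) for (i, j) in set(spans)
        if not any(a <= i and j <= b and (a, b) != (i, j) for (a, b) in spans)
    ]
    maximal.sort()
    letters = {lab: "" for lab in slabels}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for idx, (i, j) in enumerate(maximal):
        for m in range(i, j + 1):
            letters[slabels[m]] += alphabet[idx % len(alphabet)]
    return DuncanGrouping(
        labels=tuple(slabels),
        means=tuple(float(m) for m in smeans),
        letters=letters,
        significant=sig,
        lsr=tuple(lsr[p] for p in range(2, k + 1)),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Simple regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int


def simple_regression(x, y) -> RegressionResult:
    """OLS of y on x with R^2 and the slope t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in x")
    res = sps.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        p=float(res.pvalue),
        n=int(x.size),
    )
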