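"""Statistical kernel for the connectivity pipeline.

Every inferential procedure the pipeline relies on lives here, implemented
from its defining formula so each can be checked against closed forms and
independent references: Fisher's z transform, pooled- and Welch-variance
two-sample t, paired t, one-way ANOVA from raw data or from published
mean/SD/n summaries, Tukey's HSD (Tukey-Kramer for unbalanced groups), a
two-level mixed-design ANOVA, Pearson's chi-square test of independence,
the Pearson correlation test, and Benjamini-Hochberg FDR control.

Only distribution functions (t, F, chi-square, studentized range) are taken
from scipy; the statistics themselves are computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats as _dist

__all__ = [
    "TestResult",
    "GroupSummary",
    "ContingencyTable",
    "DegenerateDataError",
    "fisher_z",
    "inverse_fisher_z",
    "two_sample_t",
    "paired_t",
    "anova_oneway_raw",
    "anova_oneway_summary",
    "tukey_hsd",
    "mixed_anova_main_within",
    "chi_square_independence",
    "pearson_corr",
    "bh_fdr",
]

Tail = str  # "two-sided" | "less" | "greater"
_TAILS = ("two-sided", "less", "greater")


class DegenerateDataError(ValueError):
    """Raised when data carry no usable variance for the requested test."""


@dataclass(frozen=True)
class TestResult:
    """One test outcome: statistic, degrees of freedom, p-value, tail."""

    test: str
    statistic: float
    df: Union[float, tuple[float, float]]
    p: float
    tail: Tail = "two-sided"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or np.isnan(self.p)):
            raise ValueError(f"p-value out of [0, 1]: {self.p}")

    def to_dict(self) -> dict:
        df = list(self.df) if isinstance(self.df, tuple) else self.df
        return {
            "test": self.test,
            "statistic": float(self.statistic),
            "df": df,
            "p": float(self.p),
            "tail": self.tail,
            **self.extra,
        }


@dataclass(frozen=True)
class GroupSummary:
    """Per-group mean, SD and size — e.g. the 'mean ± SD' cells of a
    published demographics table."""

    means: tuple[float, ...]
    sds: tuple[float, ...]
    sizes: tuple[int, ...]
    labels: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        k = len(self.means)
        if k < 2:
            raise ValueError("need at least 2 groups")
        if len(self.sds) != k or len(self.sizes) != k:
            raise ValueError("means, sds and sizes must have equal length")
        if any(n < 2 for n in self.sizes):
            raise ValueError("every group size must be >= 2")
        if any(s < 0 for s in self.sds):
            raise ValueError("standard deviations must be >= 0")


class ContingencyTable:
    """R x C table of non-negative integer counts (R, C >= 2)."""

    def __init__(self, counts, row_labels=None, col_labels=None):
        counts = np.asarray(counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("contingency table must be at least 2 x 2")
        if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be non-negative integers")
        if counts.sum() <= 0:
            raise ValueError("grand total must be positive")
        self.counts = counts.astype(float)
        self.row_labels = row_labels
        self.col_labels = col_labels


def fisher_z(r, label: Optional[str] = None):
    """Fisher's variance-stabilizing transform z = atanh(r).

    ``label`` names the edge in the error message when |r| >= 1.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1.0):
        where = f" for edge {label}" if label else ""
        raise ValueError(f"|r| >= 1{where}: Fisher z is undefined")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def inverse_fisher_z(z):
    """Map Fisher z back to a correlation, r = tanh(z)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if np.isscalar(z) or out.ndim == 0 else out


def _check_tail(tail: Tail) -> None:
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {_TAILS}, got {tail!r}")


def _t_pvalue(t: float, df: float, tail: Tail) -> float:
    if tail == "two-sided":
        return 2.0 * _dist.t.sf(abs(t), df)
    if tail == "less":
        return _dist.t.cdf(t, df)
    return _dist.t.sf(t, df)


def two_sample_t(
    a: Sequence[float],
    b: Sequence[float],
    tail: Tail = "two-sided",
    equal_var: bool = True,
) -> TestResult:
    """Independent two-sample t test.

    Default is the Student pooled-variance form with df = n_a + n_b - 2;
    ``equal_var=False`` switches to Welch's unequal-variance form with
    Satterthwaite df.  ``tail="less"`` tests mean(a) < mean(b), the
    direction used for patient-vs-control reduction tests.
    """
    _check_tail(tail)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each sample needs at least 2 observations")
    diff = a.mean() - b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if equal_var:
        df = float(na + nb - 2)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:
        se = np.sqrt(va / na + vb / nb)
        if se > 0:
            df = (va / na + vb / nb) ** 2 / (
                (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
            )
        else:
            df = float(na + nb - 2)
    if se == 0.0:
        if diff == 0.0:
            # all values identical on both sides: no evidence either way
            return TestResult("two_sample_t", 0.0, df, _t_pvalue(0.0, df, tail), tail)
        raise DegenerateDataError(
            "zero pooled variance with unequal means: t is unbounded"
        )
    t = diff / se
    return TestResult("two_sample_t", float(t), float(df), _t_pvalue(t, df, tail), tail)


def paired_t(a: Sequence[float], b: Sequence[float], tail: Tail = "two-sided") -> TestResult:
    """Paired t test: one-sample t on the differences a - b, df = n - 1."""
    _check_tail(tail)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    df = float(n - 1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return TestResult("paired_t", 0.0, df, _t_pvalue(0.0, df, tail), tail)
        raise DegenerateDataError(
            "zero variance of differences with nonzero mean: t is unbounded"
        )
    t = d.mean() / (sd / np.sqrt(n))
    return TestResult("paired_t", float(t), df, _t_pvalue(t, df, tail), tail)


def _anova_from_ss(ssb: float, ssw: float, k: int, n_total: int, test: str) -> TestResult:
    df1, df2 = float(k - 1), float(n_total - k)
    if ssw <= 0.0:
        if ssb == 0.0:
            raise DegenerateDataError("no variance anywhere: F is undefined")
        raise DegenerateDataError(
            "zero within-group variance with unequal means: F is unbounded"
        )
    f = (ssb / df1) / (ssw / df2)
    return TestResult(test, float(f), (df1, df2), float(_dist.f.sf(f, df1, df2)), "greater")


def anova_oneway_raw(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way fixed-effects ANOVA from raw samples."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    ns = np.array([len(g) for g in groups], dtype=float)
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    return _anova_from_ss(ssb, ssw, len(groups), int(ns.sum()), "anova_oneway")


def anova_oneway_summary(summary: GroupSummary) -> TestResult:
    """One-way ANOVA recovered exactly from per-group mean, SD and n.

    SS_between = sum n_i (xbar_i - xbar)^2, SS_within = sum (n_i - 1) s_i^2;
    identical to the raw-data ANOVA whenever the summaries are exact.
    """
    ns = np.asarray(summary.sizes, dtype=float)
    means = np.asarray(summary.means, dtype=float)
    sds = np.asarray(summary.sds, dtype=float)
    grand = float((ns * means).sum() / ns.sum())
    ssb = float(np.sum(ns * (means - grand) ** 2))
    ssw = float(np.sum((ns - 1) * sds**2))
    return _anova_from_ss(ssb, ssw, len(ns), int(ns.sum()), "anova_oneway_summary")


def tukey_hsd(
    groups: Sequence[Sequence[float]],
    alpha: float = 0.05,
    labels: Optional[Sequence[str]] = None,
) -> list[TestResult]:
    """Tukey's honestly-significant-difference test for all group pairs.

    Uses the studentized-range distribution; unbalanced designs use the
    Tukey-Kramer standard error sqrt(MSW/2 * (1/n_i + 1/n_j)).  p-values
    rely on scipy's numerical studentized-range CDF and are accurate to
    roughly 4 decimals.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if labels is None:
        labels = [f"g{i}" for i in range(k)]
    ns = np.array([len(g) for g in groups], dtype=float)
    if np.any(ns < 2):
        raise ValueError("every group needs at least 2 observations")
    means = np.array([g.mean() for g in groups])
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    df_err = float(ns.sum() - k)
    if ssw <= 0.0:
        raise DegenerateDataError("zero within-group variance: Tukey q is unbounded")
    msw = ssw / df_err
    out: list[TestResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = means[i] - means[j]
            se = np.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(diff) / se
            p = float(np.clip(_dist.studentized_range.sf(q, k, df_err), 0.0, 1.0))
            out.append(
                TestResult(
                    "tukey_hsd",
                    float(q),
                    df_err,
                    p,
                    "two-sided",
                    extra={
                        "pair": (labels[i], labels[j]),
                        "mean_diff": float(diff),
                        "reject": bool(p < alpha),
                    },
                )
            )
    return out


def mixed_anova_main_within(
    level_a: Sequence[float],
    level_b: Sequence[float],
    group: Sequence,
) -> TestResult:
    """Main effect of a two-level within-subject factor in a mixed design.

    With exactly two within-subject levels the repeated-measures analysis
    reduces to an analysis of per-subject difference scores d = a - b
    adjusted for the between-subject factor: the main effect tests the
    unweighted grand mean of the per-group difference means, with error
    df = N - k.  This is exact for two levels (no sphericity assumption
    is needed) and matches the Type-III convention for unbalanced groups.
    """
    a = np.asarray(level_a, dtype=float)
    b = np.asarray(level_b, dtype=float)
    group = np.asarray(group)
    if not (a.shape == b.shape == group.shape):
        raise ValueError("level_a, level_b and group must have equal length")
    bad = np.flatnonzero(np.isnan(a) | np.isnan(b))
    if bad.size:
        raise ValueError(f"missing within-factor level for subject index {bad[0]}")
    d = a - b
    labels = np.unique(group)
    k = len(labels)
    if k < 1:
        raise ValueError("need at least one group")
    n_total = len(d)
    df_err = float(n_total - k)
    if df_err <= 0:
        raise ValueError("not enough subjects for the error term")
    group_means = np.array([d[group == g].mean() for g in labels])
    sse = float(sum(((d[group == g] - d[group == g].mean()) ** 2).sum() for g in labels))
    ns = np.array([(group == g).sum() for g in labels], dtype=float)
    mse = sse / df_err
    grand = group_means.mean()  # unweighted across groups
    if mse == 0.0:
        if grand == 0.0:
            return TestResult("mixed_anova_within", 0.0, (1.0, df_err), 1.0, "greater")
        raise DegenerateDataError("zero error variance with nonzero effect")
    f = grand**2 / (mse * np.sum(1.0 / ns) / k**2)
    p = float(_dist.f.sf(f, 1, df_err))
    return TestResult("mixed_anova_within", float(f), (1.0, df_err), p, "greater")


def chi_square_independence(table: ContingencyTable) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction.

    chi2 = sum (O - E)^2 / E with E from the row/column margins,
    df = (R - 1)(C - 1).
    """
    counts = table.counts
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero row or column margin: expected counts undefined")
    expected = np.outer(rows, cols) / counts.sum()
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    df = float((counts.shape[0] - 1) * (counts.shape[1] - 1))
    return TestResult(
        "chi_square_independence", chi2, df, float(_dist.chi2.sf(chi2, df)), "greater"
    )


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson correlation with the exact t-based two-sided p-value.

    t = r sqrt((n - 2) / (1 - r^2)) on n - 2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("samples must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0.0 or sy == 0.0:
        raise DegenerateDataError("zero variance: correlation undefined")
    r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    df = float(n - 2)
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = 2.0 * float(_dist.t.sf(abs(t), df))
    return TestResult("pearson_corr", r, df, p, "two-sided", extra={"n": n})


def bh_fdr(
    pvals: Sequence[float], alpha: float = 0.05, method: str = "bh"
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns (reject flags, adjusted p-values).  ``method="by"`` applies the
    Benjamini-Yekutieli correction factor for arbitrary dependence.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be one-dimensional")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if method not in ("bh", "by"):
        raise ValueError(f"unknown FDR method {method!r}")
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    scale = 1.0 if method == "bh" else float(np.sum(1.0 / np.arange(1, m + 1)))
    adj = ranked * m * scale / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj
    # step-up rule: reject every hypothesis with p(i) <= i*alpha/m at the
    # largest such i, equivalently adjusted p <= alpha
    reject = adjusted <= alpha
    return reject, adjusted
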