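"""Nonparametric group inference and reliability analysis.

Friedman repeated-measures test across conditions, pairwise Wilcoxon
signed-rank post-hocs with multiplicity correction, paired actual-vs-null
Wilcoxon, and two-way mixed consistency average-measures intraclass
correlation, ICC(3,k).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

CORRECTIONS = ("holm", "fdr_bh", "bonferroni", "none")


@dataclass(frozen=True)
class RepeatedMeasuresBlock:
    """Subjects x conditions matrix with no missing cells."""

    values: np.ndarray
    condition_names: tuple[str, ...]
    subject_ids: tuple[str, ...] = ()

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("values must be 2-D (subjects x conditions)")
        if np.isnan(v).any():
            raise ValueError("missing cells are not allowed (listwise complete)")
        if v.shape[1] != len(self.condition_names):
            raise ValueError("condition_names length mismatch")
        if v.shape[1] < 2:
            raise ValueError("need at least 2 conditions")
        object.__setattr__(self, "values", v)
        if not self.subject_ids:
            object.__setattr__(
                self,
                "subject_ids",
                tuple(f"s{i:03d}" for i in range(v.shape[0])),
            )


def _friedman_statistic(values: np.ndarray) -> float:
    """Tie-corrected Friedman chi-square from mid-ranked rows."""
    n, k = values.shape
    ranks = sps.rankdata(values, axis=1)
    rj = ranks.sum(axis=0)
    chisq = 12.0 / (n * k * (k + 1)) * float((rj**2).sum()) - 3.0 * n * (k + 1)
    # tie correction (Conover): 1 - sum(t^3 - t) / (n k (k^2 - 1))
    ties = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    c = 1.0 - ties / (n * k * (k * k - 1))
    if c <= 0:
        return 0.0
    return chisq / c


def friedman_test(
    block: RepeatedMeasuresBlock, method: str = "asymptotic"
) -> tuple[float, float]:
    """Friedman rank test across conditions within subjects.

    ``method='asymptotic'`` uses the chi-square reference distribution
    (k - 1 df); ``method='exact'`` enumerates the full within-subject
    permutation distribution (k!^n statistics, feasible only for tiny
    blocks).  Ties are mid-ranked in both paths.
    """
    v = block.values
    n, k = v.shape
    stat = _friedman_statistic(v)
    if method == "asymptotic":
        p = float(sps.chi2.sf(stat, k - 1))
    elif method == "exact":
        import math

        n_perm = math.factorial(k) ** n
        if n_perm > 2_000_000:
            raise ValueError(
                f"exact enumeration infeasible: {n_perm} permutations"
            )
        perms = list(itertools.permutations(range(k)))
        count = 0
        total = 0
        for assignment in itertools.product(perms, repeat=n):
            perm_vals = np.array(
                [v[i, list(assignment[i])] for i in range(n)]
            )
            if _friedman_statistic(perm_vals) >= stat - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(stat), float(p)


def _wilcoxon(
    d: np.ndarray, zero_method: str = "wilcox"
) -> tuple[float, float, bool]:
    """Wilcoxon signed-rank on a difference vector.

    Exact p when n <= 25 with no ties and no zeros, else normal
    approximation with continuity correction.  Returns
    (statistic, p, all_zero_flag); an all-zero vector is undefined and
    reported as p = 1 with the flag set.
    """
    d = np.asarray(d, dtype=float)
    if np.all(d == 0):
        return float("nan"), 1.0, True
    nonzero = d[d != 0]
    no_ties = len(np.unique(np.abs(nonzero))) == len(nonzero)
    no_zeros = len(nonzero) == len(d)
    if len(nonzero) <= 25 and no_ties and no_zeros:
        mode = "exact"
    else:
        mode = "approx"
    res = sps.wilcoxon(
        d, zero_method=zero_method, correction=(mode == "approx"), method=mode
    )
    return float(res.statistic), float(res.pvalue), False


def _adjust(p_raw: np.ndarray, method: str) -> np.ndarray:
    p = np.asarray(p_raw, dtype=float)
    m = len(p)
    if method == "none":
        return p.copy()
    order = np.argsort(p)
    adj = np.empty(m)
    if method == "holm":
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(1.0, running)
    elif method == "bonferroni":
        adj = np.minimum(1.0, p * m)
    elif method == "fdr_bh":
        ranked = p[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adj[order] = np.minimum(1.0, ranked)
    else:
        raise ValueError(f"unknown correction {method!r}; choose from {CORRECTIONS}")
    return adj


def pairwise_wilcoxon(
    block: RepeatedMeasuresBlock,
    method: str = "holm",
    zero_method: str = "wilcox",
) -> pd.DataFrame:
    """Wilcoxon signed-rank on every condition pair, with correction.

    Returns a frame with one row per unordered pair: condition_a,
    condition_b, statistic, p_raw, p_adjusted, direction, all_zero flag.
    Direction reports the sign of the median paired difference a - b.
    """
    v = block.values
    names = block.condition_names
    rows = []
    for ia, ib in itertools.combinations(range(len(names)), 2):
        d = v[:, ia] - v[:, ib]
        stat, p, flag = _wilcoxon(d, zero_method=zero_method)
        med = float(np.median(d))
        direction = "a>b" if med > 0 else ("a<b" if med < 0 else "equal")
        rows.append(
            {
                "condition_a": names[ia],
                "condition_b": names[ib],
                "statistic": stat,
                "p_raw": p,
                "direction": direction,
                "all_zero": flag,
            }
        )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = _adjust(df["p_raw"].to_numpy(), method)
    return df[
        [
            "condition_a",
            "condition_b",
            "statistic",
            "p_raw",
            "p_adjusted",
            "direction",
            "all_zero",
        ]
    ]


def actual_vs_null_test(actual, null) -> tuple[float, float, str]:
    """Paired Wilcoxon of actual energies against matched null energies.

    Returns (statistic, p, direction) where direction is
    'actual<null', 'actual>null' or 'equal' by the median difference.
    """
    a = np.asarray(actual, dtype=float)
    b = np.asarray(null, dtype=float)
    if a.shape != b.shape:
        raise ValueError(
            f"length mismatch: actual has {a.shape}, null has {b.shape}"
        )
    d = a - b
    stat, p, flag = _wilcoxon(d)
    med = float(np.median(d))
    if flag or med == 0:
        direction = "equal"
    else:
        direction = "actual<null" if med < 0 else "actual>null"
    return stat, p, direction


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str = "two-way mixed, consistency, average of k raters"
    n_subjects: int = 0
    n_raters: int = 2


def icc_consistency(ratings_a, ratings_b, confidence: float = 0.95) -> ICCResult:
    """ICC(3,k): two-way mixed effects, consistency, average measures, k=2.

    From the two-way ANOVA decomposition, ICC(3,k) = (MS_R - MS_E) / MS_R
    with MS_R the between-subjects and MS_E the residual mean square; the
    confidence interval follows from the F ratio MS_R / MS_E on
    (n-1, (n-1)(k-1)) degrees of freedom.  Invariant to affine rescaling
    of either rater.
    """
    a = np.asarray(ratings_a, dtype=float)
    b = np.asarray(ratings_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ratings must be equal-length 1-D sequences")
    n = len(a)
    if n < 5:
        raise ValueError(f"need at least 5 paired ratings, got {n}")
    y = np.column_stack([a, b])
    k = 2
    grand = y.mean()
    subj_means = y.mean(axis=1)
    rater_means = y.mean(axis=0)
    ss_total = float(((y - grand) ** 2).sum())
    ss_rows = k * float(((subj_means - grand) ** 2).sum())
    ss_cols = n * float(((rater_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    df_rows = n - 1
    df_err = (n - 1) * (k - 1)
    ms_rows = ss_rows / df_rows
    ms_err = ss_err / df_err
    if ms_rows <= 1e-300:
        raise ValueError("zero between-subject variance: ICC undefined")
    icc = (ms_rows - ms_err) / ms_rows
    if ms_err <= 0:
        return ICCResult(1.0, 1.0, 1.0, n_subjects=n)
    f_obs = ms_rows / ms_err
    alpha = 1.0 - confidence
    fl = f_obs / sps.f.ppf(1 - alpha / 2, df_rows, df_err)
    fu = f_obs * sps.f.ppf(1 - alpha / 2, df_err, df_rows)
    return ICCResult(
        icc=float(icc),
        ci_low=float(1 - 1 / fl),
        ci_high=float(1 - 1 / fu),
        n_subjects=n,
    )
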