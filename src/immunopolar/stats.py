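"""Contingency and correlation statistics for cohort comparisons.

Covers the descriptive statistics used around the polarization analysis:
odds ratios of a diagnosis within a cluster relative to the whole cohort,
Fisher exact tests of a group's categorical composition against the
population, unpaired two-sided t-tests, and one-sided Pearson correlation
tests.  No multiple-testing adjustment is applied by default; a
Benjamini-Hochberg utility is provided for callers who want one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyResult",
    "odds_ratio_vs_cohort",
    "odds_ratio_vs_reference",
    "categorical_vs_population_test",
    "ttest_unpaired",
    "pearson_correlation",
    "benjamini_hochberg",
]


@dataclass
class ContingencyResult:
    odds_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float | None
    counts: dict[str, int]
    method: str


def _woolf_ci(odds_ratio: float, counts: list[int]) -> tuple[float, float, float]:
    """Woolf log-OR interval and Wald p from the four cell counts."""
    se = float(np.sqrt(sum(1.0 / c for c in counts)))
    log_or = np.log(odds_ratio)
    z = sps.norm.ppf(0.975)
    p = float(2 * sps.norm.sf(abs(log_or) / se))
    return float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se)), p


def odds_ratio_vs_cohort(
    k_group: int, n_group: int, k_cohort: int, n_cohort: int
) -> ContingencyResult:
    """Odds of a diagnosis within a cluster relative to the full cohort.

    OR = [k_group/(n_group-k_group)] / [k_cohort/(n_cohort-k_cohort)], the
    group's odds against the whole cohort's odds (the group is part of the
    cohort).  Woolf CI on the log odds ratio; no continuity correction, so a
    zero cell is an error.
    """
    if not (0 <= k_group <= n_group and 0 <= k_cohort <= n_cohort):
        raise ValueError("counts must satisfy 0 <= k <= n")
    cells = [k_group, n_group - k_group, k_cohort, n_cohort - k_cohort]
    if 0 in cells:
        raise ValueError("zero cell count; odds ratio undefined without correction")
    odds_ratio = (k_group / (n_group - k_group)) / (k_cohort / (n_cohort - k_cohort))
    lo, hi, p = _woolf_ci(odds_ratio, cells)
    return ContingencyResult(
        odds_ratio=odds_ratio, ci_lower=lo, ci_upper=hi, p_value=p,
        counts={"k_group": k_group, "n_group": n_group,
                "k_cohort": k_cohort, "n_cohort": n_cohort},
        method="odds_ratio_vs_cohort",
    )


def odds_ratio_vs_reference(
    k_group: int, ref_group: int, k_cohort: int, ref_cohort: int
) -> ContingencyResult:
    """Odds of a diagnosis against a reference diagnosis, group vs cohort.

    OR = (k_group/ref_group) / (k_cohort/ref_cohort): e.g. triple-negative
    counts against hormone-receptor-positive counts within the cluster,
    relative to the same ratio in the full cohort.  An alternative reading of
    a cluster-enrichment odds ratio; both are exposed because published
    values can follow either convention.
    """
    cells = [k_group, ref_group, k_cohort, ref_cohort]
    if any(c <= 0 for c in cells):
        raise ValueError("all counts must be positive")
    odds_ratio = (k_group / ref_group) / (k_cohort / ref_cohort)
    lo, hi, p = _woolf_ci(odds_ratio, cells)
    return ContingencyResult(
        odds_ratio=odds_ratio, ci_lower=lo, ci_upper=hi, p_value=p,
        counts={"k_group": k_group, "ref_group": ref_group,
                "k_cohort": k_cohort, "ref_cohort": ref_cohort},
        method="odds_ratio_vs_reference",
    )


def categorical_vs_population_test(
    group_counts, population_counts, B: int = 10000, seed: int | None = None
) -> tuple[float, str]:
    """Exact test that a group's categorical composition differs from the
    population's.

    For two categories this is Fisher's exact test on the 2x2 table.  Larger
    tables use a seeded Monte-Carlo exact test: tables are sampled from the
    conditional (fixed-margin) distribution and the p-value is the fraction
    whose probability does not exceed the observed table's (add-one rule).
    Returns ``(p, method)`` with method flagged ``"fisher"`` or
    ``"monte_carlo"``.
    """
    g = np.asarray(group_counts, dtype=int)
    p_ = np.asarray(population_counts, dtype=int)
    if g.shape != p_.shape or g.ndim != 1 or len(g) < 2:
        raise ValueError("need matching count vectors over >= 2 categories")
    if (g < 0).any() or (p_ < 0).any():
        raise ValueError("counts must be nonnegative")
    table = np.vstack([g, p_])
    if len(g) == 2:
        _, p = sps.fisher_exact(table)
        return float(p), "fisher"
    rt = sps.random_table(table.sum(axis=1), table.sum(axis=0), seed=np.random.default_rng(seed))
    obs_logp = rt.logpmf(table)
    draws = rt.rvs(B)
    logp = rt.logpmf(draws)
    p = float((1 + np.count_nonzero(logp <= obs_logp + 1e-9)) / (B + 1))
    return p, "monte_carlo"


def ttest_unpaired(a, b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided unpaired Student's t-test (Welch via ``equal_var=False``)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 values")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def pearson_correlation(x, y, side: str = "two-sided") -> tuple[float, float]:
    """Pearson r with a t-distribution p-value (n-2 df).

    ``side`` is ``"two-sided"``, ``"positive"`` (H1: r > 0) or ``"negative"``
    (H1: r < 0), matching the one-sided tests used to call the sign of a
    gene-gene correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    alternative = {"two-sided": "two-sided", "positive": "greater",
                   "negative": "less"}.get(side)
    if alternative is None:
        raise ValueError(f"unknown side {side!r}")
    res = sps.pearsonr(x, y, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (off by default everywhere; a convenience only)."""
    return sps.false_discovery_control(np.asarray(p_values, dtype=float), method="bh")
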