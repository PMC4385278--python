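"""Two-group comparison of AUC(CV_T) scores and design ranking.

The Mann-Whitney U test (normal approximation, midranks with tie-corrected
variance, no continuity correction) compares the 40 diseased against the
40 healthy heterogeneity scores of a design.  Z is signed so that a
diseased group shifted to higher scores gives Z > 0; designs with Z <= 0
are excluded from the ranking, the rest are ordered by ascending two-sided
p value.  Bonferroni correction over the design family controls the
family-wise error of the optimisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import erfc, sqrt

import numpy as np
from scipy.stats import rankdata

from .errors import AnalysisError


@dataclass(frozen=True)
class TestResult:
    u_statistic: float
    z_statistic: float
    p_value: float
    n_a: int
    n_b: int

    def significant_after_bonferroni(self, m: int, alpha: float = 0.05) -> bool:
        return bonferroni(self.p_value, m, alpha)


def mann_whitney(group_a, group_b) -> TestResult:
    """Mann-Whitney U with normal approximation.

    ``group_a`` is the group expected to be shifted high (diseased); Z > 0
    when it tends to exceed ``group_b``.  Two-sided p = 2*Phi(-|Z|) with
    no continuity correction.  Midranks handle ties; a fully constant
    pooled sample yields Z = 0, p = 1.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    n1, n2 = len(a), len(b)
    if n1 < 2 or n2 < 2:
        raise AnalysisError("each group needs at least 2 values")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)

    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all values tied
        return TestResult(u_statistic=u, z_statistic=0.0, p_value=1.0, n_a=n1, n_b=n2)
    z = (u - n1 * n2 / 2.0) / sqrt(var)
    p = erfc(abs(z) / sqrt(2.0))  # 2 * Phi(-|z|)
    return TestResult(u_statistic=u, z_statistic=float(z), p_value=float(min(p, 1.0)),
                      n_a=n1, n_b=n2)


def mann_whitney_exact_p(group_a, group_b) -> float:
    """Exact two-sided p by enumeration of all group assignments.

    Brute-force reference for small samples only (n1 + n2 <= 12).
    """
    from itertools import combinations

    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    n1, n = len(a), len(a) + len(b)
    if n > 12:
        raise AnalysisError("exact enumeration limited to n1 + n2 <= 12")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)

    def u_of(idx):
        return ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0

    u_obs = u_of(range(n1))
    mu = n1 * (n - n1) / 2.0
    us = np.array([u_of(c) for c in combinations(range(n), n1)])
    return float(np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12))


def bonferroni(p: float, m: int, alpha: float = 0.05) -> bool:
    """Significance at family-wise level alpha over m comparisons."""
    if m < 1:
        raise AnalysisError("family size must be >= 1")
    return p < alpha / m


@dataclass
class DesignResult:
    """One row of the optimisation table."""

    design_id: str
    collimator: str
    activity_mbq: int
    n_iterations: int
    n_updates: int
    cutoff_cm: float | None
    kernel_cm: float
    lung_volume: str
    cv_t: float
    test: TestResult
    auc_healthy: np.ndarray = field(default_factory=lambda: np.array([]))
    auc_copd: np.ndarray = field(default_factory=lambda: np.array([]))
    rank: int | None = None
    failed: bool = False
    failure: str = ""


def rank_designs(results: list[DesignResult]) -> list[DesignResult]:
    """Order positive-Z designs by ascending p; negative-Z designs excluded.

    Ties break on the design identifier for determinism.  Rank numbers are
    written back onto the returned (ranked) results.
    """
    ranked = [r for r in results if not r.failed and r.test.z_statistic > 0]
    ranked.sort(key=lambda r: (r.test.p_value, r.design_id))
    for i, r in enumerate(ranked, start=1):
        r.rank = i
    return ranked
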