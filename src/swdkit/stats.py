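"""Nonparametric comparison layer for genotype and treatment contrasts.

Session and event samples are compared with the Wilcoxon rank-sum test
(independent groups), the Wilcoxon signed-rank test (paired designs) and
the Kruskal–Wallis omnibus test, with Dunn-type pairwise follow-up in the
Fisher's-LSD style (unadjusted pairwise p values, reported only alongside
the omnibus result).  All tests are rank-based: mid-ranks with tie-corrected
variances are used throughout, since event durations quantized by the
sampling grid tie often.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sstats

from .types import ValidationError

__all__ = [
    "TestResult",
    "LSDResult",
    "rank_sum_test",
    "signed_rank_test",
    "kruskal_wallis",
    "pairwise_lsd",
    "compare_conditions",
]

_EXACT_RANKSUM_N = 12  # exact enumeration up to this combined n (no ties)
_EXACT_SIGNRANK_N = 15


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    notes: str = ""
    medians: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise ValidationError(f"p_value out of [0, 1]: {self.p_value}")


def _has_ties(pooled: np.ndarray) -> bool:
    return len(np.unique(pooled)) < len(pooled)


def rank_sum_test(x: Sequence[float], y: Sequence[float], mode: str = "auto") -> TestResult:
    """Two-sided Mann–Whitney/Wilcoxon rank-sum test.

    Exact null by enumeration when ``n_x + n_y <= 12`` without ties (or when
    forced with ``mode='exact'``); otherwise the normal approximation with
    tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(
            "rank_sum",
            statistic=len(x) * len(y) / 2.0,
            p_value=1.0,
            group_sizes=(len(x), len(y)),
            notes="degenerate: all values identical",
            medians=(float(np.median(x)), float(np.median(y))),
        )
    if mode not in ("auto", "exact", "normal"):
        raise ValidationError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (
        mode == "auto" and len(pooled) <= _EXACT_RANKSUM_N and not _has_ties(pooled)
    )
    method = "exact" if use_exact else "asymptotic"
    res = sstats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return TestResult(
        "rank_sum",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        group_sizes=(len(x), len(y)),
        notes=f"{method}; tie correction applied" if method == "asymptotic" else "exact enumeration",
        medians=(float(np.median(x)), float(np.median(y))),
    )


def signed_rank_test(before: Sequence[float], after: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon convention); exact null for
    ``n <= 15`` nonzero differences without tied magnitudes, else normal
    approximation with tie and continuity corrections.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if len(before) != len(after):
        raise ValidationError("paired samples must have equal lengths")
    d = after - before
    d = d[d != 0]
    if len(d) == 0:
        raise ValidationError("all paired differences are zero; signed-rank test undefined")
    use_exact = len(d) <= _EXACT_SIGNRANK_N and not _has_ties(np.abs(d))
    method = "exact" if use_exact else "approx"
    res = sstats.wilcoxon(d, zero_method="wilcox", correction=not use_exact, method=method)
    return TestResult(
        "signed_rank",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        group_sizes=(len(before),),
        notes="exact enumeration" if use_exact else "normal approximation; tie correction applied",
        medians=(float(np.median(before)), float(np.median(after))),
    )


def _rank_data(groups: Sequence[np.ndarray]) -> tuple[np.ndarray, list[np.ndarray]]:
    pooled = np.concatenate(groups)
    ranks = sstats.rankdata(pooled)
    out = []
    i = 0
    for g in groups:
        out.append(ranks[i : i + len(g)])
        i += len(g)
    return ranks, out


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal–Wallis H test on joint ranks with tie correction.

    p from the chi-square distribution with k − 1 degrees of freedom.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValidationError("kruskal_wallis needs at least two groups")
    if any(len(g) == 0 for g in gs):
        raise ValidationError("every group must be non-empty")
    n_total = sum(len(g) for g in gs)
    if n_total < 3:
        raise ValidationError("need a total of at least 3 observations")
    pooled = np.concatenate(gs)
    if np.all(pooled == pooled[0]):
        return TestResult(
            "kruskal_wallis",
            statistic=0.0,
            p_value=1.0,
            group_sizes=tuple(len(g) for g in gs),
            notes="degenerate: all values identical; H = 0",
            medians=tuple(float(np.median(g)) for g in gs),
        )
    stat, p = sstats.kruskal(*gs)
    return TestResult(
        "kruskal_wallis",
        statistic=float(stat),
        p_value=float(p),
        group_sizes=tuple(len(g) for g in gs),
        notes=f"df={len(gs) - 1}; tie correction applied",
        medians=tuple(float(np.median(g)) for g in gs),
    )


@dataclass
class LSDResult:
    """Omnibus H test plus unadjusted Dunn-type pairwise follow-up."""

    omnibus: TestResult
    pairwise: list[TestResult] = field(default_factory=list)


def pairwise_lsd(groups: Sequence[Sequence[float]], labels: Optional[Sequence[str]] = None) -> LSDResult:
    """Dunn-type pairwise z tests on joint mean ranks, Fisher's-LSD style.

    Pairwise p values are left unadjusted (the LSD protection is the
    requirement that they be read only alongside the omnibus test, which is
    returned with them).  The z statistic for groups i, j is
    ``(R̄_i − R̄_j) / sqrt(S² (1/n_i + 1/n_j))`` with the tie-corrected
    pooled variance ``S² = N(N+1)/12 − ΣT/(12(N−1))``, ``ΣT = Σ(t³ − t)``.
    """
    omnibus = kruskal_wallis(groups)
    gs = [np.asarray(g, dtype=float) for g in groups]
    labs = list(labels) if labels is not None else [f"group{i}" for i in range(len(gs))]
    pooled, group_ranks = _rank_data(gs)
    n = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    s2 = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))
    results = []
    for i, j in combinations(range(len(gs)), 2):
        ri, rj = group_ranks[i].mean(), group_ranks[j].mean()
        if s2 <= 0:
            z = 0.0
        else:
            z = (ri - rj) / np.sqrt(s2 * (1.0 / len(gs[i]) + 1.0 / len(gs[j])))
        p = float(2 * sstats.norm.sf(abs(z)))
        results.append(
            TestResult(
                "pairwise_lsd",
                statistic=float(z),
                p_value=min(p, 1.0),
                group_sizes=(len(gs[i]), len(gs[j])),
                notes=f"{labs[i]} vs {labs[j]}; unadjusted, read with omnibus "
                f"H={omnibus.statistic:.3g} (p={omnibus.p_value:.3g})",
                medians=(float(np.median(gs[i])), float(np.median(gs[j]))),
            )
        )
    return LSDResult(omnibus=omnibus, pairwise=results)


def compare_conditions(
    stats_a: Sequence[float],
    stats_b: Sequence[float],
    design: str = "independent",
) -> TestResult:
    """Compare two samples of per-event or per-session values.

    ``independent`` dispatches to the rank-sum test, ``paired`` to the
    signed-rank test.  Group medians ride along on the result, since group
    medians are the headline numbers for SWD summaries.
    """
    if design == "independent":
        return rank_sum_test(stats_a, stats_b)
    if design == "paired":
        if len(stats_a) != len(stats_b):
            raise ValidationError("paired design requires equal-length samples")
        return signed_rank_test(stats_a, stats_b)
    raise ValidationError(f"unknown design {design!r}")
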