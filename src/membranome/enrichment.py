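"""Category-count enrichment statistics.

The core statistic is a Z-score for the count of sampled proteins falling in
a category, under hypergeometric sampling from a finite annotated universe:

    z = (a - n*A/N) / sqrt(n * (A/N) * (1 - A/N) * (N - n)/(N - 1))

where ``a`` = category count in the sample, ``n`` = sample size, ``A`` =
category count in the universe and ``N`` = universe size. ``|z| >= 2``
(roughly a 95% CI) marks significant enrichment/depletion. Exact
hypergeometric tail probabilities are provided alongside, computed in log
space via scipy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from scipy.stats import hypergeom

from membranome.ontology import AnnotationTable

Direction = Literal["enriched", "depleted", "neutral"]

DEFAULT_Z_THRESHOLD = 2.0


class CountError(ValueError):
    """Raised when category counts violate their invariants."""


@dataclass(frozen=True)
class CategoryCount:
    """Counts for one category: sample (a of n) vs universe (A of N)."""

    term_id: str
    a: int
    n: int
    A: int
    N: int

    def __post_init__(self) -> None:
        if not 0 < self.n <= self.N:
            raise CountError(f"need 0 < n <= N, got n={self.n}, N={self.N}")
        if not 0 <= self.A <= self.N:
            raise CountError(f"need 0 <= A <= N, got A={self.A}, N={self.N}")
        if not 0 <= self.a <= min(self.n, self.A):
            raise CountError(
                f"need 0 <= a <= min(n, A), got a={self.a}, n={self.n}, A={self.A}"
            )


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    counts: CategoryCount
    z: float
    p_hyper_right: float
    p_hyper_left: float
    direction: Direction


def zscore(
    counts: CategoryCount, variance: Literal["hypergeometric", "binomial"] = "hypergeometric"
) -> float:
    """Deviation of the observed category count from its sampling expectation.

    Positive means over-representation. ``variance="binomial"`` drops the
    finite-population correction factor (N-n)/(N-1), for comparison with
    tools that use the binomial approximation.

    Zero-variance inputs (A=0, A=N or n=N) return 0.0 when the count equals
    its expectation and signed infinity otherwise, with a warning.
    """
    a, n, A, N = counts.a, counts.n, counts.A, counts.N
    p = A / N
    mu = n * p
    var = n * p * (1.0 - p)
    if variance == "hypergeometric":
        if N < 2:
            var = 0.0
        else:
            var *= (N - n) / (N - 1)
    elif variance != "binomial":
        raise ValueError(f"unknown variance convention {variance!r}")
    if var <= 0.0:
        if a == mu:
            return 0.0
        warnings.warn(
            f"zero sampling variance for term {counts.term_id!r} "
            f"(a={a}, n={n}, A={A}, N={N}); returning signed infinity",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.inf if a > mu else -math.inf
    return (a - mu) / math.sqrt(var)


def hypergeom_tail(counts: CategoryCount, side: Literal["right", "left"]) -> float:
    """Exact tail probability for X ~ Hypergeometric(N, A, n).

    ``side="right"`` gives P(X >= a); ``side="left"`` gives P(X <= a). Both
    include the point mass at ``a``.
    """
    a, n, A, N = counts.a, counts.n, counts.A, counts.N
    rv = hypergeom(N, A, n)
    if side == "right":
        return float(min(1.0, rv.sf(a - 1)))
    if side == "left":
        return float(min(1.0, rv.cdf(a)))
    raise ValueError(f"side must be 'right' or 'left', got {side!r}")


def classify(z: float, z_threshold: float = DEFAULT_Z_THRESHOLD) -> Direction:
    """Threshold rule: z >= threshold is enriched, z <= -threshold depleted.

    Ties at exactly +/- threshold count as significant.
    """
    if z_threshold <= 0:
        raise ValueError("z_threshold must be positive")
    if z >= z_threshold:
        return "enriched"
    if z <= -z_threshold:
        return "depleted"
    return "neutral"


def bh_qvalues(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg adjusted p-values (supplementary, not a filter)."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top, i in enumerate(reversed(order)):
        rank = m - rank_from_top
        prev = min(prev, pvalues[i] * m / rank)
        q[i] = prev
    return q


def enrich_terms(
    membranome: Iterable[str],
    table: AnnotationTable,
    terms: Sequence[str],
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    variance: Literal["hypergeometric", "binomial"] = "hypergeometric",
) -> tuple[list[EnrichmentResult], dict[str, int]]:
    """Score every term in ``terms`` against a sampled protein set.

    Membranome proteins absent from the universe cannot contribute to any
    category count and are excluded from n; the exclusion is reported in the
    returned stats dict (``n_input, n_matched, n_unmatched``). Results come
    back in the order of ``terms``.
    """
    if not table.propagated:
        raise ValueError("annotation table must be propagated before enrichment")
    sample = set(membranome)
    matched = sample & table.proteins
    stats = {
        "n_input": len(sample),
        "n_matched": len(matched),
        "n_unmatched": len(sample) - len(matched),
    }
    if not matched:
        raise ValueError("no membranome protein found in universe")
    n = len(matched)
    N = table.universe_size
    universe_counts = table.term_counts()
    sample_counts: dict[str, int] = {}
    for protein in matched:
        for tid in table.assignments[protein]:
            sample_counts[tid] = sample_counts.get(tid, 0) + 1

    results: list[EnrichmentResult] = []
    for tid in terms:
        counts = CategoryCount(
            term_id=tid,
            a=sample_counts.get(tid, 0),
            n=n,
            A=universe_counts.get(tid, 0),
            N=N,
        )
        z = zscore(counts, variance=variance)
        results.append(
            EnrichmentResult(
                term_id=tid,
                counts=counts,
                z=z,
                p_hyper_right=hypergeom_tail(counts, "right"),
                p_hyper_left=hypergeom_tail(counts, "left"),
                direction=classify(z, z_threshold),
            )
        )
    return results, stats
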