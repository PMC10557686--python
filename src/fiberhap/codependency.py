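"""Single-molecule co-dependency between regulatory element pairs.

Because each fiber is one molecule, two elements spanned by the same fiber
reveal whether they open *together* on individual chromosomes.  The
co-dependency score of a peak pair is::

    score = observed co-accessibility - prop_a * prop_b

the observed fraction of doubly-spanning fibers accessible at both peaks
minus the fraction expected if the peaks actuated independently.
Significance comes from a two-sided Fisher exact test on the 2x2 of
(accessible at A) x (accessible at B) among spanning fibers.  Scanning an
anchor (e.g. a promoter) against neighboring peaks nominates
enhancer-promoter couplings.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core_io import Fiber, Peak
from .haplotype_tests import bh_fdr, fisher_exact_2x2

#: "FIRE precision <= 0.05" convention: patches with precision >= 0.95 count
DEFAULT_MIN_PRECISION = 0.95
DEFAULT_MIN_SPAN = 10


@dataclass(frozen=True, slots=True)
class CoDependencyResult:
    peak_a: str
    peak_b: str
    n_span: int
    prop_a: float
    prop_b: float
    observed: float
    expected: float
    score: float
    p_value: float | None
    q_value: float | None = None
    insufficient: bool = False


def _accessible(fiber: Fiber, peak: Peak, min_precision: float) -> bool:
    ps, pe = peak.interval.start, peak.interval.end
    return any(
        m.precision >= min_precision and m.interval.start < pe and ps < m.interval.end
        for m in fiber.msps
    )


def spanning_fibers(fibers: Sequence[Fiber], peak_a: Peak, peak_b: Peak) -> list[Fiber]:
    """Fibers fully containing both peak intervals."""
    if peak_a.interval.chrom != peak_b.interval.chrom:
        raise ValueError(
            f"peaks {peak_a.peak_id} and {peak_b.peak_id} are on different "
            "chromosomes; no single fiber can span both"
        )
    return [
        f
        for f in fibers
        if f.interval.contains(peak_a.interval) and f.interval.contains(peak_b.interval)
    ]


def codependency_score(
    fibers: Sequence[Fiber],
    peak_a: Peak,
    peak_b: Peak,
    min_precision: float = DEFAULT_MIN_PRECISION,
    min_span: int = DEFAULT_MIN_SPAN,
    marginals: str = "joint",
) -> CoDependencyResult:
    """Score and test the co-accessibility of one peak pair.

    ``marginals='joint'`` (default) computes both accessible proportions
    among the fibers spanning *both* peaks, which makes
    ``observed <= min(prop_a, prop_b)`` exact and the Fisher table
    self-consistent; ``'per-peak'`` uses each peak's own spanning fibers for
    its marginal.  Below ``min_span`` doubly-spanning fibers the result is
    flagged ``insufficient`` and carries no p-value.
    """
    if not (0.0 <= min_precision <= 1.0):
        raise ValueError("min_precision must be in [0, 1]")
    if marginals not in ("joint", "per-peak"):
        raise ValueError("marginals must be 'joint' or 'per-peak'")
    span = spanning_fibers(fibers, peak_a, peak_b)
    n = len(span)
    if n < min_span:
        return CoDependencyResult(
            peak_a.peak_id, peak_b.peak_id, n, float("nan"), float("nan"),
            float("nan"), float("nan"), float("nan"), None, None, True,
        )
    at_a = [_accessible(f, peak_a, min_precision) for f in span]
    at_b = [_accessible(f, peak_b, min_precision) for f in span]
    both = sum(a and b for a, b in zip(at_a, at_b))
    a_only = sum(a and not b for a, b in zip(at_a, at_b))
    b_only = sum(b and not a for a, b in zip(at_a, at_b))
    neither = n - both - a_only - b_only
    observed = both / n
    if marginals == "joint":
        prop_a = sum(at_a) / n
        prop_b = sum(at_b) / n
    else:
        own_a = [f for f in fibers if f.interval.contains(peak_a.interval)]
        own_b = [f for f in fibers if f.interval.contains(peak_b.interval)]
        prop_a = sum(_accessible(f, peak_a, min_precision) for f in own_a) / len(own_a)
        prop_b = sum(_accessible(f, peak_b, min_precision) for f in own_b) / len(own_b)
    expected = prop_a * prop_b
    p, _ = fisher_exact_2x2(both, a_only, b_only, neither)
    return CoDependencyResult(
        peak_a.peak_id, peak_b.peak_id, n, prop_a, prop_b,
        observed, expected, observed - expected, p,
    )


def codependency_scan(
    fibers: Sequence[Fiber],
    anchor_peak: Peak,
    candidate_peaks: Sequence[Peak],
    min_precision: float = DEFAULT_MIN_PRECISION,
    min_span: int = DEFAULT_MIN_SPAN,
    marginals: str = "joint",
) -> list[CoDependencyResult]:
    """Score the anchor against every candidate; BH q-values across the scan
    (computed over the candidates with enough spanning fibers)."""
    if any(c.peak_id == anchor_peak.peak_id for c in candidate_peaks):
        raise ValueError("anchor peak must not appear among the candidates")
    results = [
        codependency_score(fibers, anchor_peak, c, min_precision, min_span, marginals)
        for c in candidate_peaks
    ]
    tested = [r for r in results if not r.insufficient]
    if tested:
        qs = bh_fdr([r.p_value for r in tested])
        qmap = {id(r): float(q) for r, q in zip(tested, qs)}
        results = [
            CoDependencyResult(
                r.peak_a, r.peak_b, r.n_span, r.prop_a, r.prop_b, r.observed,
                r.expected, r.score, r.p_value, qmap.get(id(r)), r.insufficient,
            )
            for r in results
        ]
    return results
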