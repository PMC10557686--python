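"""Haplotype-specific chromatin accessibility testing.

For every peak, fibers that fully span the peak are classified as accessible
(some MSP with precision >= ``min_precision`` overlaps the peak) or
inaccessible; counts per haplotype feed a two-sided Fisher exact test, with
Benjamini-Hochberg FDR control across peaks.  This is the genome-wide
volcano analysis: |percent-accessible difference| against the Fisher p-value,
with a nominal p < 0.01 line and the BH significance line.

Fibers with an UNASSIGNED haplotype tag are excluded.  A fiber must fully
contain the peak to be counted, so "inaccessible" means closed chromatin was
actually observed rather than the fiber merely ending early.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import HAP1, HAP2, UNASSIGNED, Fiber, Peak, overlaps

logger = logging.getLogger(__name__)

ACCESSIBLE = "ACCESSIBLE"
INACCESSIBLE = "INACCESSIBLE"
NOT_SPANNING = "NOT_SPANNING"

#: default precision cutoff for calling a spanning fiber accessible at a peak
DEFAULT_MIN_PRECISION = 0.90


@dataclass(frozen=True, slots=True)
class HaplotypeCounts:
    """Accessible / total spanning-fiber counts per haplotype at one peak."""

    peak_id: str
    acc_h1: int
    total_h1: int
    acc_h2: int
    total_h2: int

    def __post_init__(self) -> None:
        if min(self.acc_h1, self.total_h1, self.acc_h2, self.total_h2) < 0:
            raise ValueError("counts must be >= 0")
        if self.acc_h1 > self.total_h1 or self.acc_h2 > self.total_h2:
            raise ValueError("accessible count exceeds total")


@dataclass(frozen=True, slots=True)
class HapTestResult:
    """Per-peak haplotype accessibility comparison (volcano row)."""

    peak_id: str
    pct_h1: float
    pct_h2: float
    abs_delta: float
    odds_ratio: float
    p_value: float
    q_value: float
    nominal_sig: bool
    fdr_sig: bool


def classify_fiber_at_peak(fiber: Fiber, peak: Peak, min_precision: float) -> str:
    """ACCESSIBLE / INACCESSIBLE / NOT_SPANNING classification of one fiber.

    NOT_SPANNING unless the fiber fully contains the peak interval;
    otherwise ACCESSIBLE iff some MSP with precision >= ``min_precision``
    overlaps the peak by at least 1 bp.
    """
    if not fiber.interval.contains(peak.interval):
        return NOT_SPANNING
    ps, pe = peak.interval.start, peak.interval.end
    for msp in fiber.msps:
        if msp.precision >= min_precision and overlaps(msp.interval.start, msp.interval.end, ps, pe):
            return ACCESSIBLE
    return INACCESSIBLE


def peak_haplotype_counts(
    fibers: Sequence[Fiber],
    peaks: Sequence[Peak],
    min_precision: float = DEFAULT_MIN_PRECISION,
) -> list[HaplotypeCounts]:
    """Accessible/total spanning-fiber counts per haplotype at every peak.

    UNASSIGNED fibers are excluded; totals count spanning fibers only.
    Peaks are processed independently, so overlapping peaks are allowed.
    """
    ids = [p.peak_id for p in peaks]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate peak_id in peak set")
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    index: dict[str, tuple[np.ndarray, list[Peak]]] = {}
    for chrom, plist in by_chrom.items():
        plist.sort(key=lambda p: (p.interval.start, p.interval.end))
        index[chrom] = (np.array([p.interval.start for p in plist], dtype=np.int64), plist)

    acc = {p.peak_id: [0, 0] for p in peaks}  # hap -> accessible
    tot = {p.peak_id: [0, 0] for p in peaks}
    for fiber in fibers:
        if fiber.haplotype == UNASSIGNED or fiber.chrom not in index:
            continue
        h = 0 if fiber.haplotype == HAP1 else 1
        starts, plist = index[fiber.chrom]
        lo = int(np.searchsorted(starts, fiber.interval.start, side="left"))
        hi = int(np.searchsorted(starts, fiber.interval.end, side="right"))
        for p in plist[lo:hi]:
            state = classify_fiber_at_peak(fiber, p, min_precision)
            if state == NOT_SPANNING:
                continue
            tot[p.peak_id][h] += 1
            if state == ACCESSIBLE:
                acc[p.peak_id][h] += 1
    return [
        HaplotypeCounts(p.peak_id, acc[p.peak_id][0], tot[p.peak_id][0], acc[p.peak_id][1], tot[p.peak_id][1])
        for p in peaks
    ]


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Two-sided Fisher exact test on ``[[a, b], [c, d]]``.

    Two-sidedness follows the minimum-likelihood convention (sum of the
    probabilities of all tables with the given margins whose point
    probability does not exceed the observed one).  The odds ratio is the
    sample ``(a*d)/(b*c)``, reported as ``inf`` when ``b*c == 0`` with
    ``a*d > 0`` and ``nan`` when both products vanish.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    if b * c == 0:
        odds = math.nan if a * d == 0 else math.inf
    else:
        odds = (a * d) / (b * c)
    return p, odds


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving,
    capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def haplotype_specific_accessibility(
    counts: Sequence[HaplotypeCounts],
    fdr_level: float = 0.05,
    nominal_p: float = 0.01,
) -> list[HapTestResult]:
    """Fisher-test every peak's 2x2 haplotype table and BH-adjust.

    Peaks with zero spanning fibers on either haplotype carry no information
    about imbalance and are dropped (a count of dropped peaks is logged).
    """
    usable = [c for c in counts if c.total_h1 > 0 and c.total_h2 > 0]
    dropped = len(counts) - len(usable)
    if dropped:
        logger.info("dropped %d peaks with a zero haplotype margin", dropped)
    if not usable:
        return []
    ps, ors = [], []
    for c in usable:
        p, o = fisher_exact_2x2(c.acc_h1, c.total_h1 - c.acc_h1, c.acc_h2, c.total_h2 - c.acc_h2)
        ps.append(p)
        ors.append(o)
    qs = bh_fdr(ps)
    results = []
    for c, p, o, q in zip(usable, ps, ors, qs):
        pct1 = 100.0 * c.acc_h1 / c.total_h1
        pct2 = 100.0 * c.acc_h2 / c.total_h2
        results.append(
            HapTestResult(
                peak_id=c.peak_id,
                pct_h1=pct1,
                pct_h2=pct2,
                abs_delta=abs(pct1 - pct2),
                odds_ratio=o,
                p_value=p,
                q_value=float(q),
                nominal_sig=p < nominal_p,
                fdr_sig=bool(q < fdr_level),
            )
        )
    return results
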