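"""Region-scale haplotype imbalance in chromatin accessibility.

Detects chromosome- or region-scale allelic imbalance — XCI skewing, and
XCI spreading into autosomal DNA on a derivative chromosome — and estimates
what fraction of cells silences the region.

Per peak the signed delta ``pct_h1 - pct_h2`` (percentage points of
accessible spanning fibers) is computed; low-coverage peaks (coverage below
``max(min_reads, median - 3*sd)``, statistics taken over the unfiltered set)
are excluded as mapping/phasing artifacts; each named region's delta
distribution is compared against the genomic background with a two-sided
Mann-Whitney U test.

If a haplotype of the region is fully silenced in a fraction ``f`` of cells,
its accessible-fiber proportion at every peak scales by ``(1 - f)``, so the
per-peak relative actuation loss ``(pct_active - pct_silenced)/pct_active``
estimates ``f``; the region estimate ``f_hat`` is the median across peaks
(robust to peak-level noise), clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core_io import Fiber, GenomicInterval, Peak
from .haplotype_tests import HAP1, HAP2, HaplotypeCounts, peak_haplotype_counts

#: "FIRE precision <= 0.10" convention for the imbalance analyses
DEFAULT_MIN_PRECISION = 0.90


@dataclass(frozen=True, slots=True)
class PeakDelta:
    """Signed accessibility difference and phased coverage at one peak."""

    peak_id: str
    delta: float  # pct_h1 - pct_h2, percentage points
    coverage: int  # total_h1 + total_h2


@dataclass(frozen=True, slots=True)
class RegionImbalanceResult:
    region_name: str
    region: GenomicInterval
    n_peaks_region: int
    n_peaks_background: int
    u_statistic: float | None
    p_value: float | None
    median_delta_region: float | None
    silenced_fraction_estimate: float | None


def peak_deltas(counts: Sequence[HaplotypeCounts]) -> list[PeakDelta]:
    """Per-peak signed deltas; peaks with a zero margin on either haplotype
    are dropped (delta undefined)."""
    out = []
    for c in counts:
        if c.total_h1 == 0 or c.total_h2 == 0:
            continue
        delta = 100.0 * c.acc_h1 / c.total_h1 - 100.0 * c.acc_h2 / c.total_h2
        out.append(PeakDelta(c.peak_id, delta, c.total_h1 + c.total_h2))
    return out


def coverage_filter(
    deltas: Sequence[PeakDelta],
    min_reads: int = 10,
    sd_mult: float = 3.0,
) -> list[PeakDelta]:
    """Drop peaks with coverage below ``max(min_reads, median - sd_mult*sd)``.

    The median and (sample) standard deviation are computed once, over the
    *input* set, so the filter is idempotent by construction.
    """
    if not deltas:
        return []
    cov = np.array([d.coverage for d in deltas], dtype=float)
    sd = float(np.std(cov, ddof=1)) if cov.size > 1 else 0.0
    cutoff = max(float(min_reads), float(np.median(cov)) - sd_mult * sd)
    return [d for d in deltas if d.coverage >= cutoff]


def region_imbalance_test(
    region_deltas: Sequence[float],
    background_deltas: Sequence[float],
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U on signed delta distributions.

    Exact null enumeration when both samples have n <= 20 and no ties;
    otherwise the normal approximation with tie and continuity correction.
    """
    x = np.asarray(region_deltas, dtype=float)
    y = np.asarray(background_deltas, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("region and background delta sets must be non-empty")
    no_ties = np.unique(np.concatenate([x, y])).size == x.size + y.size
    method = "exact" if (max(x.size, y.size) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def estimate_silenced_fraction(
    region_counts: Sequence[HaplotypeCounts],
    direction: str | None = None,
) -> float:
    """Estimate the fraction of cells silencing one haplotype of a region.

    ``direction`` names the putatively silenced haplotype (H1 or H2); when
    None it is inferred from the sign of the median per-peak delta (the
    less-accessible haplotype is taken as silenced).  Per peak with active
    accessibility > 0, the relative loss ``(pct_active - pct_silenced) /
    pct_active`` is computed; the estimate is the median across peaks,
    clipped to [0, 1].
    """
    deltas = peak_deltas(region_counts)
    if not deltas:
        raise ValueError("no informative peaks for silenced-fraction estimation")
    if direction is None:
        direction = HAP2 if float(np.median([d.delta for d in deltas])) >= 0 else HAP1
    if direction not in (HAP1, HAP2):
        raise ValueError("direction must be 'H1' or 'H2'")
    ratios = []
    for c in region_counts:
        if c.total_h1 == 0 or c.total_h2 == 0:
            continue
        pct1 = c.acc_h1 / c.total_h1
        pct2 = c.acc_h2 / c.total_h2
        active, silenced = (pct1, pct2) if direction == HAP2 else (pct2, pct1)
        if active > 0:
            ratios.append((active - silenced) / active)
    if not ratios:
        raise ValueError("silenced-fraction estimator undefined: no peak with active accessibility")
    return float(np.clip(np.median(ratios), 0.0, 1.0))


def genome_imbalance_report(
    fibers: Sequence[Fiber],
    peaks: Sequence[Peak],
    regions: Mapping[str, GenomicInterval],
    min_precision: float = DEFAULT_MIN_PRECISION,
    min_reads: int = 10,
    sd_mult: float = 3.0,
    exclude_chroms: Sequence[str] = (),
) -> tuple[list[RegionImbalanceResult], list[PeakDelta]]:
    """Per-region imbalance tests against the rest-of-genome background.

    The background is every coverage-filtered peak outside all named regions
    and not on an excluded chromosome.  Returns the per-region results and
    the full filtered per-peak delta table (swarm-plot ready).
    """
    counts = peak_haplotype_counts(fibers, peaks, min_precision)
    count_by_id = {c.peak_id: c for c in counts}
    peak_by_id = {p.peak_id: p for p in peaks}
    filtered = coverage_filter(peak_deltas(counts), min_reads, sd_mult)

    def region_of(peak_id: str) -> str | None:
        iv = peak_by_id[peak_id].interval
        for name, region in regions.items():
            if region.overlaps(iv):
                return name
        return None

    assignment = {d.peak_id: region_of(d.peak_id) for d in filtered}
    background = [
        d
        for d in filtered
        if assignment[d.peak_id] is None
        and peak_by_id[d.peak_id].interval.chrom not in exclude_chroms
    ]
    bg_values = [d.delta for d in background]

    results = []
    for name, region in regions.items():
        in_region = [d for d in filtered if assignment[d.peak_id] == name]
        if not in_region or not bg_values:
            results.append(
                RegionImbalanceResult(name, region, len(in_region), len(background),
                                      None, None, None, None)
            )
            continue
        u, p = region_imbalance_test([d.delta for d in in_region], bg_values)
        f_hat = estimate_silenced_fraction([count_by_id[d.peak_id] for d in in_region])
        results.append(
            RegionImbalanceResult(
                name, region, len(in_region), len(background), u, p,
                float(np.median([d.delta for d in in_region])), f_hat,
            )
        )
    return results, filtered
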