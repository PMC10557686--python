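"""Haplotype-resolved CpG methylation pileup and regional comparison.

The pileup summarizes per-fiber CpG calls into per-site, per-haplotype
percent methylation.  The regional test pools a region's calls per haplotype
and applies a two-sided Fisher exact test — the readthrough-silencing
readout: a promoter hypermethylated on one haplotype only.

Because several CpGs of a region often sit on the same fiber, per-call
pooling overstates the effective sample size; the default counting unit is
therefore the *fiber* (each fiber votes once with its majority methylation
state across the region's sites), with ``unit='call'`` available for raw
per-call pooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .core_io import HAP1, HAP2, UNASSIGNED, CpGCall, GenomicInterval
from .haplotype_tests import fisher_exact_2x2


@dataclass(frozen=True, slots=True)
class CpGSiteSummary:
    """Per-site haplotype methylation pileup."""

    chrom: str
    pos: int
    n_h1: int
    meth_h1: int
    n_h2: int
    meth_h2: int
    n_unassigned: int

    @property
    def pct_h1(self) -> float:
        return 100.0 * self.meth_h1 / self.n_h1 if self.n_h1 else float("nan")

    @property
    def pct_h2(self) -> float:
        return 100.0 * self.meth_h2 / self.n_h2 if self.n_h2 else float("nan")


def cpg_pileup(calls: Sequence[CpGCall]) -> list[CpGSiteSummary]:
    """Per-(chrom, pos) methylation summary, sorted by position.

    UNASSIGNED calls are tallied separately and excluded from the haplotype
    percentages.  Sites appear when they carry at least one haplotype-assigned
    call.
    """
    agg: dict[tuple[str, int], list[int]] = {}
    for c in calls:
        key = (c.chrom, c.pos)
        row = agg.setdefault(key, [0, 0, 0, 0, 0])  # n1, m1, n2, m2, n_un
        if c.haplotype == HAP1:
            row[0] += 1
            row[1] += int(c.methylated)
        elif c.haplotype == HAP2:
            row[2] += 1
            row[3] += int(c.methylated)
        else:
            row[4] += 1
    return [
        CpGSiteSummary(chrom, pos, *agg[(chrom, pos)])
        for chrom, pos in sorted(agg)
        if agg[(chrom, pos)][0] + agg[(chrom, pos)][2] > 0
    ]


def region_methylation_test(
    calls: Sequence[CpGCall],
    region: GenomicInterval,
    unit: str = "fiber",
    min_sites: int = 3,
) -> tuple[float, float]:
    """Haplotype methylation difference across a region.

    Pools the region's methylated/unmethylated counts per haplotype — per
    fiber (majority state across the region's CpGs; ties count methylated)
    or per call — and returns ``(delta_pct, p_value)`` with
    ``delta_pct = pct_h1 - pct_h2`` and a two-sided Fisher exact p.  Requires
    ``min_sites`` CpG sites with calls on both haplotypes inside the region.
    """
    if unit not in ("fiber", "call"):
        raise ValueError("unit must be 'fiber' or 'call'")
    in_region = [
        c
        for c in calls
        if c.chrom == region.chrom and region.start <= c.pos < region.end
    ]
    sites_both = {
        s.pos for s in cpg_pileup(in_region) if s.n_h1 > 0 and s.n_h2 > 0
    }
    if len(sites_both) < min_sites:
        raise ValueError(
            f"region {region.chrom}:{region.start}-{region.end} has only "
            f"{len(sites_both)} CpG sites with calls on both haplotypes "
            f"(need {min_sites})"
        )
    meth = {HAP1: 0, HAP2: 0}
    unmeth = {HAP1: 0, HAP2: 0}
    if unit == "call":
        for c in in_region:
            if c.haplotype == UNASSIGNED:
                continue
            (meth if c.methylated else unmeth)[c.haplotype] += 1
    else:
        per_fiber: dict[tuple[str, str], list[int]] = {}
        for c in in_region:
            if c.haplotype == UNASSIGNED:
                continue
            row = per_fiber.setdefault((c.fiber_id, c.haplotype), [0, 0])  # meth, total
            row[0] += int(c.methylated)
            row[1] += 1
        for (_fid, hap), (m, n) in per_fiber.items():
            if m * 2 >= n:
                meth[hap] += 1
            else:
                unmeth[hap] += 1
    n1 = meth[HAP1] + unmeth[HAP1]
    n2 = meth[HAP2] + unmeth[HAP2]
    if n1 == 0 or n2 == 0:
        raise ValueError("no haplotype-assigned counts on one haplotype in the region")
    delta_pct = 100.0 * meth[HAP1] / n1 - 100.0 * meth[HAP2] / n2
    p, _ = fisher_exact_2x2(meth[HAP1], unmeth[HAP1], meth[HAP2], unmeth[HAP2])
    return delta_pct, p
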