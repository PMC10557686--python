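"""Allele-specific expression from haplotype-assigned full-length transcripts.

Transcript reads arrive already assigned to a gene and, where a heterozygous
variant lies within the transcript, to a haplotype.  Per gene, the haplotype
counts are compared with a two-sided exact binomial test against a balanced
0.5 expectation (minimum-likelihood two-sidedness).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .core_io import HAP1, HAP2, TranscriptRead


@dataclass(frozen=True, slots=True)
class GeneAseResult:
    gene_id: str
    n_h1: int
    n_h2: int
    n_unassigned: int
    allelic_ratio: float  # n_h1 / (n_h1 + n_h2); nan when no assigned reads
    p_value: float | None  # None when no assigned reads


def gene_haplotype_counts(reads: Sequence[TranscriptRead]) -> dict[str, tuple[int, int, int]]:
    """Exact per-gene tallies ``gene_id -> (n_h1, n_h2, n_unassigned)``."""
    counts: dict[str, list[int]] = {}
    for r in reads:
        row = counts.setdefault(r.gene_id, [0, 0, 0])
        if r.haplotype == HAP1:
            row[0] += 1
        elif r.haplotype == HAP2:
            row[1] += 1
        else:
            row[2] += 1
    return {g: tuple(v) for g, v in counts.items()}


def allelic_expression_test(n_h1: int, n_h2: int) -> float:
    """Two-sided exact binomial p-value for haplotype counts against 0.5."""
    if n_h1 < 0 or n_h2 < 0:
        raise ValueError("counts must be >= 0")
    n = n_h1 + n_h2
    if n == 0:
        raise ValueError("allelic expression test needs at least one assigned read")
    return float(stats.binomtest(n_h1, n, 0.5).pvalue)


def allele_specific_expression(reads: Sequence[TranscriptRead]) -> list[GeneAseResult]:
    """Per-gene ASE results, sorted by gene id."""
    results = []
    counts = gene_haplotype_counts(reads)
    for gene_id in sorted(counts):
        n1, n2, nu = counts[gene_id]
        n = n1 + n2
        if n == 0:
            results.append(GeneAseResult(gene_id, n1, n2, nu, float("nan"), None))
        else:
            results.append(
                GeneAseResult(gene_id, n1, n2, nu, n1 / n, allelic_expression_test(n1, n2))
            )
    return results
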