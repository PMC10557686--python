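"""Canonical synthetic scenarios used by the analyses and tests.

Each builder returns a :class:`~fiberhap.synthetic_data.GenomeModel` encoding
one of the biological situations the pipeline is designed to detect:

* :func:`imprinted_locus_model` — one imprinted element (actuation 0.70 on
  H1 vs 0.05 on H2, the scale of a monoallelically regulated element)
  alongside balanced elements;
* :func:`balanced_peaks_model` — many elements with equal actuation on both
  haplotypes (the null for the volcano analysis);
* :func:`enhancer_codependency_model` — a promoter anchor with one coupled
  enhancer (correlation 0.8) among independent neighbors within fiber reach;
* :func:`readthrough_silencing_model` — a promoter silenced on one haplotype
  in every cell, with hypermethylated promoter CpGs and abolished transcription
  from that haplotype;
* :func:`xci_spreading_model` — a contiguous multi-peak region silenced on
  one haplotype in a fraction ``f`` of cells, with a balanced multi-chromosome
  background.
"""

from __future__ import annotations

from .core_io import HAP2, GenomicInterval
from .synthetic_data import (
    CpGSiteSpec,
    ElementSpec,
    GeneSpec,
    GenomeModel,
    SilencingSpec,
)

#: peak-to-peak spacing that keeps each element its own fiber locus
_SPACING = 40_000
_WIDTH = 200


def _element_grid(chrom: str, n: int, act_h1: float, act_h2: float, prefix: str,
                  offset: int = 20_000) -> list[ElementSpec]:
    return [
        ElementSpec(
            f"{prefix}{i}",
            GenomicInterval(chrom, offset + i * _SPACING, offset + i * _SPACING + _WIDTH),
            act_h1,
            act_h2,
        )
        for i in range(n)
    ]


def balanced_peaks_model(n_peaks: int = 1000, actuation: float = 0.3,
                         unassigned_rate: float = 0.0) -> GenomeModel:
    """Null scenario: every element actuates equally on both haplotypes."""
    chrom_size = 20_000 + n_peaks * _SPACING + 20_000
    return GenomeModel(
        chrom_sizes={"chr1": chrom_size},
        elements=_element_grid("chr1", n_peaks, actuation, actuation, "null"),
        background_msp_rate=0.2,
        unassigned_rate=unassigned_rate,
    )


def imprinted_locus_model(n_balanced: int = 20, actuation: float = 0.3,
                          unassigned_rate: float = 0.0) -> GenomeModel:
    """One imprinted element (0.70 vs 0.05) among balanced neighbors."""
    elements = _element_grid("chr1", n_balanced, actuation, actuation, "bal")
    pos = 20_000 + n_balanced * _SPACING
    elements.append(
        ElementSpec("imprinted", GenomicInterval("chr1", pos, pos + _WIDTH), 0.70, 0.05)
    )
    return GenomeModel(
        chrom_sizes={"chr1": pos + _SPACING},
        elements=elements,
        background_msp_rate=0.2,
        unassigned_rate=unassigned_rate,
    )


def enhancer_codependency_model(couple_corr: float = 0.8, n_independent: int = 8,
                                marginal: float = 0.5) -> GenomeModel:
    """Promoter anchor plus candidates within one fiber span; candidate 1 is
    coupled to the promoter, the rest actuate independently."""
    elements = [
        ElementSpec("promoter", GenomicInterval("chr13", 100_000, 100_200), marginal, marginal)
    ]
    elements.append(
        ElementSpec(
            "enhancer",
            GenomicInterval("chr13", 101_000, 101_200),
            marginal,
            marginal,
            couple_to="promoter",
            couple_corr=couple_corr,
        )
    )
    for i in range(n_independent):
        start = 102_000 + i * 1_000
        elements.append(
            ElementSpec(
                f"neighbor{i}", GenomicInterval("chr13", start, start + _WIDTH),
                marginal, marginal,
            )
        )
    return GenomeModel(
        chrom_sizes={"chr13": 250_000},
        elements=elements,
        background_msp_rate=0.2,
        unassigned_rate=0.0,
    )


def readthrough_silencing_model(
    baseline_meth: float = 0.1,
    silenced_meth: float = 0.9,
    n_cpg: int = 3,
    promoter_actuation: float = 0.8,
) -> GenomeModel:
    """Promoter silenced on H2 in all cells: closed chromatin, hyper-CpG
    methylation, and no transcription from the silenced haplotype."""
    promoter = GenomicInterval("chr13", 100_000, 100_400)
    cpgs = [
        CpGSiteSpec(100_050 + 100 * i, baseline_meth, baseline_meth) for i in range(n_cpg)
    ]
    return GenomeModel(
        chrom_sizes={"chr13": 300_000},
        elements=[
            ElementSpec("promoter", promoter, promoter_actuation, promoter_actuation)
        ],
        cpg_sites={"chr13": cpgs},
        silencing=[
            SilencingSpec(
                GenomicInterval("chr13", 95_000, 110_000), HAP2, 1.0,
                residual_actuation=0.0, silenced_methylation=silenced_meth,
            )
        ],
        genes=[
            GeneSpec("MAB21L1_like", "chr13", 100_500, 8.0, 8.0),
            GeneSpec("control_gene", "chr13", 200_000, 8.0, 8.0),
        ],
        background_msp_rate=0.2,
        unassigned_rate=0.0,
    )


def xci_spreading_model(
    fraction: float = 0.10,
    n_region_peaks: int = 200,
    n_background_peaks: int = 2000,
    actuation: float = 0.5,
    background_chroms: int = 4,
) -> GenomeModel:
    """A contiguous region of chr13 silenced on H2 in ``fraction`` of cells,
    against balanced peaks spread over several background chromosomes."""
    chrom_sizes = {"chr13": 20_000 + n_region_peaks * _SPACING + 20_000}
    elements = _element_grid("chr13", n_region_peaks, actuation, actuation, "region")
    per_bg = n_background_peaks // background_chroms
    rest = n_background_peaks - per_bg * background_chroms
    for b in range(background_chroms):
        n_b = per_bg + (rest if b == 0 else 0)
        chrom = f"chr{b + 1}"
        chrom_sizes[chrom] = 20_000 + n_b * _SPACING + 20_000
        elements += _element_grid(chrom, n_b, actuation, actuation, f"bg{b}_")
    return GenomeModel(
        chrom_sizes=chrom_sizes,
        elements=elements,
        silencing=[
            SilencingSpec(
                GenomicInterval("chr13", 0, chrom_sizes["chr13"]), HAP2, fraction,
            )
        ],
        background_msp_rate=0.1,
        unassigned_rate=0.0,
    )


def xci_region(model: GenomeModel) -> GenomicInterval:
    """The silenced region of an :func:`xci_spreading_model`."""
    return model.silencing[0].region
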