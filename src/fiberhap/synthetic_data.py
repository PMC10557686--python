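"""Synthetic chromatin-fiber, CpG, and transcript generator.

Emulates the statistical structure that the downstream haplotype analyses
assume, without simulating raw sequence:

* per-haplotype Bernoulli *actuation* of regulatory elements on individual
  fibers (an actuated element carries a high-precision MSP on that fiber);
* imprinted elements (strongly haplotype-skewed actuation probabilities);
* co-dependent element pairs — correlated actuation of two elements on the
  same fiber, drawn from the exact joint Bernoulli distribution determined by
  the two marginals and the target correlation (feasibility checked against
  the Frechet-Hoeffding bounds);
* promoter hypermethylation coupled to accessibility loss on one haplotype
  (transcriptional readthrough silencing);
* chromosome-scale silencing of one haplotype of a contiguous region in a
  fraction ``f`` of cells (XCI spreading).  Silencing is a *cell-persistent*
  state: it is drawn once per cell and jointly affects that cell's fibers,
  CpG calls, and transcripts in the region.

Cell states are re-derivable from ``(model, seed)`` alone, so
:func:`simulate_cpg` and :func:`simulate_transcripts` called with the same
seed as :func:`simulate_fibers` see the same silenced cells.  Fiber ids
encode ``locus.cell.true_haplotype.replicate`` (e.g. ``L3.c17.H2.0``) so the
CpG generator can apply the cell-level override even for fibers whose public
haplotype tag was masked to UNASSIGNED.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core_io import (
    HAP1,
    HAP2,
    UNASSIGNED,
    CpGCall,
    Fiber,
    GenomicInterval,
    MspCall,
    TranscriptRead,
)

_EPS = 1e-12


class InfeasibleCouplingError(ValueError):
    """Requested joint Bernoulli violates the Frechet-Hoeffding bounds."""


@dataclass(frozen=True, slots=True)
class ElementSpec:
    """A regulatory element with per-haplotype actuation probabilities."""

    element_id: str
    interval: GenomicInterval
    actuation_h1: float
    actuation_h2: float
    high_precision: float = 0.97
    couple_to: str | None = None
    couple_corr: float = 0.0

    def __post_init__(self) -> None:
        for p in (self.actuation_h1, self.actuation_h2, self.high_precision):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability out of [0,1] in element {self.element_id}")
        if abs(self.couple_corr) > 1.0:
            raise ValueError("couple_corr must be in [-1, 1]")

    def actuation(self, hap: str) -> float:
        return self.actuation_h1 if hap == HAP1 else self.actuation_h2


@dataclass(frozen=True, slots=True)
class CpGSiteSpec:
    """One CpG position with per-haplotype baseline methylation probability."""

    pos: int
    meth_h1: float
    meth_h2: float

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("pos must be >= 0")
        for p in (self.meth_h1, self.meth_h2):
            if not (0.0 <= p <= 1.0):
                raise ValueError("methylation probability out of [0,1]")

    def baseline(self, hap: str) -> float:
        return self.meth_h1 if hap == HAP1 else self.meth_h2


@dataclass(frozen=True, slots=True)
class SilencingSpec:
    """Cell-persistent epigenetic silencing of one haplotype of a region.

    In a fraction ``fraction`` of cells the named haplotype of ``region`` is
    silenced: element actuation drops to ``residual_actuation``, CpG
    methylation rises to ``silenced_methylation``, and transcription from
    genes in the region is abolished.
    """

    region: GenomicInterval
    haplotype: str
    fraction: float
    residual_actuation: float = 0.0
    silenced_methylation: float = 0.9

    def __post_init__(self) -> None:
        if self.haplotype not in (HAP1, HAP2):
            raise ValueError("silenced haplotype must be H1 or H2")
        for p in (self.fraction, self.residual_actuation, self.silenced_methylation):
            if not (0.0 <= p <= 1.0):
                raise ValueError("silencing probabilities must be in [0,1]")


@dataclass(frozen=True, slots=True)
class GeneSpec:
    """A gene with a genomic anchor position and per-haplotype expression."""

    gene_id: str
    chrom: str
    pos: int
    mean_h1: float
    mean_h2: float

    def __post_init__(self) -> None:
        if self.mean_h1 < 0 or self.mean_h2 < 0:
            raise ValueError(f"negative expected transcript count for {self.gene_id}")

    def mean(self, hap: str) -> float:
        return self.mean_h1 if hap == HAP1 else self.mean_h2


@dataclass(frozen=True)
class GenomeModel:
    """The full synthetic scenario: chromosomes, elements, CpGs, silencing,
    genes, and fiber sampling parameters.

    ``fiber_length_mean``/``sd`` default to the ~18 kb shearing target of the
    assay; ``background_msp_rate`` adds low-precision linker patches (per kb,
    precision ~ Uniform[0, 0.3]); ``unassigned_rate`` masks the haplotype tag
    of that fraction of fibers/transcripts (~10% of long reads cannot be
    phased).
    """

    chrom_sizes: Mapping[str, int]
    elements: Sequence[ElementSpec] = ()
    cpg_sites: Mapping[str, Sequence[CpGSiteSpec]] = field(default_factory=dict)
    silencing: Sequence[SilencingSpec] = ()
    genes: Sequence[GeneSpec] = ()
    fiber_length_mean: float = 18_000.0
    fiber_length_sd: float = 2_500.0
    background_msp_rate: float = 0.5  # MSPs per kb
    background_precision_max: float = 0.3
    unassigned_rate: float = 0.10
    locus_merge_gap: int = 5_000
    placement_jitter_sd: float = 1_000.0

    def __post_init__(self) -> None:
        ids = [e.element_id for e in self.elements]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate element ids")
        by_id = {e.element_id: e for e in self.elements}
        for e in self.elements:
            if e.interval.chrom not in self.chrom_sizes:
                raise ValueError(f"element {e.element_id} on unknown chromosome")
            if e.interval.end > self.chrom_sizes[e.interval.chrom]:
                raise ValueError(f"element {e.element_id} beyond chromosome end")
            if e.couple_to is not None:
                partner = by_id.get(e.couple_to)
                if partner is None:
                    raise ValueError(f"element {e.element_id} coupled to unknown id {e.couple_to}")
                if partner.couple_to is not None:
                    raise ValueError("coupling chains/cycles are not supported")
                for hap in (HAP1, HAP2):
                    _joint_prob(e.actuation(hap), partner.actuation(hap), e.couple_corr, strict=True)
        for chrom, sites in self.cpg_sites.items():
            if chrom not in self.chrom_sizes:
                raise ValueError(f"CpG sites on unknown chromosome {chrom}")
            for s in sites:
                if s.pos >= self.chrom_sizes[chrom]:
                    raise ValueError(f"CpG site {chrom}:{s.pos} beyond chromosome end")
        for s in self.silencing:
            if s.region.chrom not in self.chrom_sizes:
                raise ValueError("silencing region on unknown chromosome")
            if s.region.end > self.chrom_sizes[s.region.chrom]:
                raise ValueError("silencing region beyond chromosome end")
        for g in self.genes:
            if g.chrom not in self.chrom_sizes:
                raise ValueError(f"gene {g.gene_id} on unknown chromosome")
        if self.background_msp_rate < 0 or self.unassigned_rate < 0:
            raise ValueError("rates must be >= 0")


def _joint_prob(p: float, q: float, rho: float, strict: bool = False) -> float:
    """P(A=1, B=1) for correlated Bernoullis with marginals p, q and
    correlation rho.  With ``strict`` an infeasible request raises; otherwise
    the joint probability is clipped into the Frechet-Hoeffding bounds."""
    p11 = p * q + rho * math.sqrt(p * (1 - p) * q * (1 - q))
    lo, hi = max(0.0, p + q - 1.0), min(p, q)
    if strict and not (lo - _EPS <= p11 <= hi + _EPS):
        raise InfeasibleCouplingError(
            f"correlation {rho} with marginals ({p}, {q}) gives joint {p11:.4f} "
            f"outside the Frechet-Hoeffding bounds [{lo:.4f}, {hi:.4f}]"
        )
    return min(max(p11, lo), hi)


def _seed_children(seed: int) -> dict[str, np.random.SeedSequence]:
    kids = np.random.SeedSequence(seed).spawn(4)
    return {"cells": kids[0], "fibers": kids[1], "cpg": kids[2], "transcripts": kids[3]}


def draw_cell_states(model: GenomeModel, n_cells: int, seed: int) -> np.ndarray:
    """Boolean matrix ``(n_silencing_specs, n_cells)``: which cells silence
    each spec's haplotype-region.  Pure function of (model, n_cells, seed)."""
    rng = np.random.default_rng(_seed_children(seed)["cells"])
    states = np.zeros((len(model.silencing), n_cells), dtype=bool)
    for j, spec in enumerate(model.silencing):
        states[j] = rng.random(n_cells) < spec.fraction
    return states


def _derive_loci(model: GenomeModel) -> list[GenomicInterval]:
    """Cluster elements and CpG sites into fiber-placement loci (merge gap
    ``locus_merge_gap``); each locus attracts its own fiber coverage."""
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for e in model.elements:
        per_chrom.setdefault(e.interval.chrom, []).append((e.interval.start, e.interval.end))
    for chrom, sites in model.cpg_sites.items():
        for s in sites:
            per_chrom.setdefault(chrom, []).append((s.pos, s.pos + 1))
    loci: list[GenomicInterval] = []
    for chrom in sorted(per_chrom):
        spans = sorted(per_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s - cur_e <= model.locus_merge_gap:
                cur_e = max(cur_e, e)
            else:
                loci.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        loci.append(GenomicInterval(chrom, cur_s, cur_e))
    return loci


def _silencing_for(model: GenomeModel, interval: GenomicInterval) -> list[int]:
    """Indices of silencing specs whose region overlaps ``interval``."""
    return [j for j, s in enumerate(model.silencing) if s.region.overlaps(interval)]


def fiber_id_fields(fiber_id: str) -> tuple[int, int, str]:
    """Decode ``L{locus}.c{cell}.{hap}.{rep}`` -> (locus, cell, true haplotype)."""
    locus, cell, hap, _rep = fiber_id.split(".")
    return int(locus[1:]), int(cell[1:]), hap


def simulate_fibers(
    model: GenomeModel,
    n_cells: int,
    coverage_per_hap: int = 1,
    seed: int = 0,
) -> list[Fiber]:
    """Draw fibers for every locus and haplotype.

    Per locus and haplotype, ``coverage_per_hap`` fibers are drawn, each
    assigned to a cell sampled uniformly (with replacement) from the
    ``n_cells``-cell population — sequencing samples molecules from many
    cells, so distinct fibers at one locus usually come from distinct cells
    while all fibers of one cell share its persistent silencing state.
    Fiber length is Normal(mean, sd) truncated at 1 kb, the center jitters
    around the locus midpoint.  Elements
    overlapped by a fiber actuate (emit an MSP at ``high_precision``) with the
    haplotype-specific probability, overridden by ``residual_actuation`` when
    the fiber's cell silences that haplotype-region; coupled pairs are drawn
    from their exact joint Bernoulli.  Background low-precision MSPs fill
    nucleosome-free gaps at ``background_msp_rate`` per kb.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if n_cells == 0 or coverage_per_hap == 0:
        return []
    states = draw_cell_states(model, n_cells, seed)
    rng = np.random.default_rng(_seed_children(seed)["fibers"])

    elements_by_id = {e.element_id: e for e in model.elements}
    coupled_partner: dict[str, str] = {
        e.element_id: e.couple_to for e in model.elements if e.couple_to is not None
    }
    partner_ids = set(coupled_partner.values())

    fibers: list[Fiber] = []
    for li, locus in enumerate(_derive_loci(model)):
        chrom_size = model.chrom_sizes[locus.chrom]
        locus_elements = [e for e in model.elements if e.interval.overlaps(locus)]
        mid = (locus.start + locus.end) / 2.0
        for hap in (HAP1, HAP2):
            n_f = coverage_per_hap
            cells = rng.integers(0, n_cells, n_f)
            lengths = np.maximum(
                rng.normal(model.fiber_length_mean, model.fiber_length_sd, n_f), 1_000.0
            ).astype(np.int64)
            centers = mid + rng.normal(0.0, model.placement_jitter_sd, n_f)
            starts = np.clip((centers - lengths / 2).astype(np.int64), 0, None)
            ends = np.minimum(starts + lengths, chrom_size)
            starts = np.maximum(np.minimum(starts, ends - 1), 0)

            # element actuation, vectorized across the locus's fibers
            act: dict[str, np.ndarray] = {}
            probs: dict[str, np.ndarray] = {}
            for e in locus_elements:
                p = np.full(n_f, e.actuation(hap))
                for j in _silencing_for(model, e.interval):
                    s = model.silencing[j]
                    if s.haplotype == hap:
                        p = np.where(states[j, cells], s.residual_actuation, p)
                probs[e.element_id] = p
            handled: set[str] = set()
            for e in locus_elements:
                if e.element_id in handled:
                    continue
                partner_id = coupled_partner.get(e.element_id)
                if partner_id is not None and partner_id in probs:
                    pa, pb = probs[e.element_id], probs[partner_id]
                    p11 = np.array(
                        [_joint_prob(float(a), float(b), e.couple_corr) for a, b in zip(pa, pb)]
                    )
                    v = rng.random(n_f)
                    act[e.element_id] = v < pa
                    act[partner_id] = (v < p11) | ((v >= pa) & (v < pa + pb - p11))
                    handled.update((e.element_id, partner_id))
                elif e.element_id not in partner_ids or coupled_partner_missing(
                    e.element_id, coupled_partner, probs
                ):
                    act[e.element_id] = rng.random(n_f) < probs[e.element_id]
                    handled.add(e.element_id)
            for e in locus_elements:  # partners whose driver element missed the locus
                if e.element_id not in act:
                    act[e.element_id] = rng.random(n_f) < probs[e.element_id]

            unassigned = rng.random(n_f) < model.unassigned_rate
            n_bg = rng.poisson(model.background_msp_rate * (ends - starts) / 1_000.0)

            for i in range(n_f):
                fs, fe = int(starts[i]), int(ends[i])
                # element MSPs take priority; background linker patches fill
                # the remaining nucleosome-free gaps without shadowing them
                el_spans: list[tuple[int, int, float]] = []
                for e in locus_elements:
                    if act[e.element_id][i] and overlaps_ii(fs, fe, e.interval.start, e.interval.end):
                        el_spans.append(
                            (max(fs, e.interval.start), min(fe, e.interval.end), e.high_precision)
                        )
                el_spans.sort()
                bg_spans: list[tuple[int, int, float]] = []
                k = int(n_bg[i])
                if k:
                    bs = rng.integers(fs, fe, k)
                    bw = rng.integers(80, 221, k)
                    bp = rng.uniform(0.0, model.background_precision_max, k)
                    for s_, w_, p_ in zip(bs, bw, bp):
                        cand = (int(s_), min(int(s_ + w_), fe), float(p_))
                        if not any(overlaps_ii(cand[0], cand[1], a, b) for a, b, _ in el_spans):
                            bg_spans.append(cand)
                msp_spans = sorted(el_spans + bg_spans)
                msps: list[MspCall] = []
                prev_end = -1
                for s_, e_, p_ in msp_spans:
                    if s_ >= prev_end and e_ > s_:
                        msps.append(MspCall(GenomicInterval(locus.chrom, s_, e_), p_))
                        prev_end = e_
                tag = UNASSIGNED if unassigned[i] else hap
                fibers.append(
                    Fiber(
                        GenomicInterval(locus.chrom, fs, fe),
                        f"L{li}.c{cells[i]}.{hap}.{i}",
                        tag,
                        tuple(msps),
                    )
                )
    return fibers


def coupled_partner_missing(eid: str, coupled_partner: dict[str, str], probs: dict) -> bool:
    return eid in coupled_partner and coupled_partner[eid] not in probs


def overlaps_ii(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def simulate_cpg(model: GenomeModel, fibers: Sequence[Fiber], seed: int = 0) -> list[CpGCall]:
    """One CpG call per (fiber, overlapped CpG site).

    Methylation is Bernoulli at the site's haplotype baseline, overridden by
    ``silenced_methylation`` when the fiber's cell silences that
    haplotype-region.  ``seed`` must match the one given to
    :func:`simulate_fibers` for the cell states to agree.
    """
    if not fibers:
        return []
    n_cells = 1 + max(fiber_id_fields(f.fiber_id)[1] for f in fibers)
    states = draw_cell_states(model, n_cells, seed)
    rng = np.random.default_rng(_seed_children(seed)["cpg"])
    site_pos = {
        chrom: np.array([s.pos for s in sites], dtype=np.int64)
        for chrom, sites in model.cpg_sites.items()
    }
    calls: list[CpGCall] = []
    for f in fibers:
        if f.chrom not in model.chrom_sizes:
            raise ValueError(f"fiber {f.fiber_id} on unknown chromosome {f.chrom}")
        sites = model.cpg_sites.get(f.chrom)
        if not sites:
            continue
        pos = site_pos[f.chrom]
        lo, hi = np.searchsorted(pos, (f.interval.start, f.interval.end))
        if lo == hi:
            continue
        _, cell, true_hap = fiber_id_fields(f.fiber_id)
        for idx in range(int(lo), int(hi)):
            site = sites[idx]
            p = site.baseline(true_hap)
            for j, spec in enumerate(model.silencing):
                if (
                    spec.haplotype == true_hap
                    and spec.region.chrom == f.chrom
                    and spec.region.start <= site.pos < spec.region.end
                    and states[j, cell]
                ):
                    p = spec.silenced_methylation
            calls.append(
                CpGCall(f.chrom, site.pos, f.fiber_id, f.haplotype, bool(rng.random() < p))
            )
    return calls


def simulate_transcripts(model: GenomeModel, n_cells: int, seed: int = 0) -> list[TranscriptRead]:
    """Per-gene, per-haplotype transcript counts ~ Poisson(mean) per cell,
    zeroed for silenced haplotypes in silenced cells; the haplotype tag is
    masked to UNASSIGNED at ``unassigned_rate`` (reads lacking a heterozygous
    variant)."""
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if n_cells == 0:
        return []
    states = draw_cell_states(model, n_cells, seed)
    rng = np.random.default_rng(_seed_children(seed)["transcripts"])
    reads: list[TranscriptRead] = []
    for g in model.genes:
        anchor = GenomicInterval(g.chrom, g.pos, g.pos + 1)
        silencers = _silencing_for(model, anchor)
        for hap in (HAP1, HAP2):
            means = np.full(n_cells, g.mean(hap))
            for j in silencers:
                if model.silencing[j].haplotype == hap:
                    means = np.where(states[j], 0.0, means)
            counts = rng.poisson(means)
            for cell in range(n_cells):
                k = int(counts[cell])
                if k == 0:
                    continue
                masked = rng.random(k) < model.unassigned_rate
                for r in range(k):
                    tag = UNASSIGNED if masked[r] else hap
                    reads.append(TranscriptRead(f"{g.gene_id}.c{cell}.{hap}.{r}", g.gene_id, tag))
    return reads
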