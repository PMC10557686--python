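# fiberhap

Haplotype-resolved analysis of single-molecule chromatin fiber sequencing
(Fiber-seq style) multi-omes: chromatin accessibility, CpG methylation, and
full-length transcripts, all phased to parental haplotypes.

Fiber-seq stencils the chromatin architecture of individual DNA molecules
onto the molecule itself with a non-specific m6A methyltransferase before
long-read sequencing. Each sequenced fiber then carries
methyltransferase-sensitive patches (MSPs) — stretches between nucleosome
footprints that are a mixture of internucleosomal linkers and accessible
regulatory elements. An upstream classifier assigns each MSP a *precision*
`p`: the confidence that the patch is a regulatory element (a FIRE,
Fiber-seq Inferred Regulatory Element) rather than a linker. Because each
fiber is one molecule from one cell and can be phased to a parental
haplotype through heterozygous variants, the same data resolve questions
that bulk assays cannot: do two regulatory elements open *together* on the
same chromosome? Is an element accessible on only one haplotype? Is a whole
region epigenetically silenced on one haplotype in a small fraction of
cells?

`fiberhap` implements the analyses downstream of basecalling, phasing, and
MSP classification, which it consumes as plain TSV tables:

* **Aggregate FIRE signal and peak calling.** At genomic position *g* the
  phred-scaled signal over the `C_g` MSPs covering it is
  `S_g = -10 * Σ_{k=1..C_g} log10(1 - p_k)`.
  Reading `Π_k (1 - p_k)` as the per-base probability that no overlapping
  patch is a true regulatory element, a genome-wide Bonferroni correction at
  level α gives the peak threshold `S* = -10 * log10(α / G)` for `G` assayed
  bases; peaks are maximal runs with `S_g ≥ S*`.
* **Haplotype-specific accessibility.** Per peak, spanning fibers are
  classified accessible/inaccessible (MSP with `p ≥ 0.90` overlapping the
  peak), counted per haplotype, and tested with a two-sided Fisher exact
  test; Benjamini–Hochberg FDR across peaks (volcano-style output).
* **Single-molecule co-dependency.** For a peak pair, among fibers spanning
  both: `score = P̂(both accessible) - P̂(A)·P̂(B)`, with Fisher exact
  significance — nominating enhancer–promoter couplings on single
  chromosomes.
* **Region-scale allelic imbalance.** Per-peak signed deltas
  `%acc(H1) - %acc(H2)` with a coverage filter
  (`coverage ≥ max(10, median − 3·sd)`), Mann–Whitney U of a region's delta
  distribution against the rest of the genome, and an estimate of the
  silenced-cell fraction `f̂ = median_peaks[(pct_active − pct_silenced)/pct_active]`
  — the XCI-spreading readout for derivative chromosomes.
* **Haplotype CpG methylation.** Per-site pileups and pooled regional Fisher
  comparisons (per-fiber majority vote by default), detecting e.g.
  promoter hypermethylation confined to one haplotype.
* **Allele-specific expression.** Per-gene haplotype transcript counts with
  a two-sided exact binomial test against 0.5.

A synthetic-fiber generator (`fiberhap.synthetic_data` + ready-made
scenarios in `fiberhap.scenarios`) emulates the statistical structure these
analyses assume — per-haplotype Bernoulli actuation, imprinted elements,
correlated element pairs drawn from exact joint Bernoullis,
readthrough-silenced promoters, and cell-persistent partial region
silencing — so the whole pipeline is testable without sequencing data.

## Worked example

```bash
fiberhap run-all --config configs/demo.yaml     # or: python analysis/01_run_demo_pipeline.py
```

simulates a two-chromosome scenario (coupled promoter–enhancer pair,
imprinted element, readthrough-silenced promoter, partially silenced distal
region; 1,800 fibers) and writes `results/demo/`: the bedGraph signal track,
called peaks, volcano table, co-dependency scan, imbalance report, CpG
pileup, and ASE table, plus a manifest. Reruns with the same seed are
byte-identical.

The numbered drivers under `analysis/` run each analysis at scale and print
what they find, e.g.:

```text
$ python analysis/02_haplotype_volcano.py
21 peaks tested, 1 FDR-significant
top peak: imprinted (77% vs 8% accessible, |delta| = 69 points, p = 9.92e-25, q = 2.08e-23)

$ python analysis/03_enhancer_codependency.py
top-ranked candidate: enhancer (score +0.201 = observed 0.435 - expected 0.234, q = 3.13e-97, 600 doubly-spanning fibers)
independent candidates score between -0.016 and +0.015

$ python analysis/04_xci_spreading.py
f = 0.03: median delta +2.0 points, MWU p = 3.38e-03, f-hat = 0.040 (200 region peaks vs 2000 background)
f = 0.10: median delta +6.0 points, MWU p = 6.76e-12, f-hat = 0.104 (200 region peaks vs 2000 background)
f = 0.40: median delta +22.0 points, MWU p = 6.71e-92, f-hat = 0.431 (200 region peaks vs 2000 background)
```

Here the co-dependency score +0.201 of the coupled pair sits next to its
theoretical value 0.2 (marginals 0.5, correlation 0.8 ⇒ joint 0.45,
expected 0.25), and the silenced-cell fraction estimator tracks the
simulated fraction down to the few-percent regime.

## Layout

```
src/fiberhap/        library: core_io, synthetic_data, fire_signal,
                     haplotype_tests, codependency, imbalance, methylome,
                     transcripts, scenarios, cli
analysis/            numbered narrative drivers (write results/)
configs/demo.yaml    the shipped demo scenario
scripts/acceptance.py
docs/methods.md      models, assumptions, parameter defaults, limitations
tests/               pytest suite (unit, property, acceptance)
```
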