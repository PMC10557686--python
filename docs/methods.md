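# Methods

This note documents the statistical models implemented in `fiberhap`, the
assumptions behind them, the defaults that matter, what the synthetic-fiber
generator does and does not emulate, and the numerical choices a maintainer
should know about.

## Data model

All coordinates are 0-based, half-open (BED convention); browser-style
1-based closed coordinates must be converted at the boundary. One shared
overlap/containment predicate (`core_io.overlaps` / `contains`) backs every
module.

A *fiber* is one sequenced chromatin molecule: an interval, a haplotype tag
(`H1`, `H2`, or `UNASSIGNED` when no heterozygous variant allowed phasing),
and its ordered, non-overlapping MSP calls. Each MSP carries a precision
`p ∈ [0, 1]` — the upstream classifier's confidence that the patch is a
regulatory element rather than an internucleosomal linker. Precision values
are *inputs*: the classifier that produces them is out of scope here.
Haplotype labels are internal (`H1`/`H2`); mapping them to
maternal/paternal is a config concern (`haplotype_labels`), since trio
phasing happens upstream.

The on-disk contract is a set of bespoke TSVs (fiber, CpG, transcript
tables — headers documented in `core_io`) plus standard BED/bedGraph. The
bespoke tables exist so that everything is testable with small plain-text
fixtures; an alignment-file adapter could be layered on without touching
the analyses.

## Aggregate FIRE signal and peak calling

`S_g = -10 · Σ_{k=1..C_g} log10(1 − p_k)` over the MSPs covering base `g`.
Fibers covering `g` without an MSP contribute a `p = 0` term, i.e. nothing.
`1 − p` is clamped at `1e-10` before the log so `p = 1` stays finite (a
single such MSP contributes 100 phred units).

Interpretation: if `p_k` is the probability MSP `k` is a true regulatory
element, `Π_k (1 − p_k)` is the probability that *no* covering patch is
regulatory — a per-base combined null probability — and `S_g` is its phred
scaling. A base is significant when that probability falls below
`α / G` (Bonferroni over the `G` assayed bases), i.e. when
`S_g ≥ S* = -10·log10(α/G)`; default `α = 0.01`. `G` is a required
parameter (the demo uses the summed simulated chromosome lengths); whether
one counts the full assembly or only assayed bases changes `S*` by a few
phred units and is deliberately exposed rather than assumed.

All MSPs contribute with their precision, not only high-precision FIREs:
the high-precision cutoff defines *fiber-level* accessibility calls, while
the signal sum is a soft evidence aggregate in which low-`p` terms are
numerically negligible (`p = 0.3` adds 1.5 units vs 15.2 for `p = 0.97`).
A `min_precision` switch restores the truncated behavior if wanted.

Peaks are maximal runs of significant bases; runs separated by gaps of at
most `merge_gap` bases (default 0) are merged, and each peak records its
maximum signal.

## Fiber classification and haplotype testing

A fiber is counted at a peak only if it *fully contains* the peak interval:
partial overlaps cannot distinguish closed chromatin from a truncated
molecule, so "inaccessible" is only well defined for spanning fibers. A
spanning fiber is accessible iff some MSP with precision at or above the
threshold overlaps the peak by ≥ 1 bp.

Precision thresholds follow the convention that a stated FIRE precision
cutoff of `q` means patches with `1 − p ≤ q`: 0.90 for the
accessibility/imbalance analyses and 0.95 for co-dependency. Both are
configurable per analysis.

Per peak, the 2×2 of accessible/inaccessible × H1/H2 (UNASSIGNED excluded)
is tested with a two-sided Fisher exact test (minimum-likelihood
two-sidedness — the convention of the standard statistical libraries), with
BH step-up FDR across peaks (default level 0.05) and a nominal `p < 0.01`
flag. Peaks with zero spanning fibers on either haplotype carry no
information about imbalance and are dropped (logged count) rather than
assigned `p = 1`. The odds ratio is the sample `ad/bc` with `inf`/`nan`
sentinels for zero denominators.

## Single-molecule co-dependency

For peaks A and B, among the fibers spanning *both*:
`score = P̂(acc at A and B) − P̂(acc A)·P̂(acc B)`, with a Fisher exact test
on the (both / A-only / B-only / neither) table. Marginals are computed
among the doubly-spanning fibers by default (`marginals="joint"`), which
makes `observed ≤ min(prop_a, prop_b)` exact and the Fisher table
self-consistent; `"per-peak"` marginals (each peak's own spanning fibers)
are available since the definition is genuinely ambiguous. Pairs with fewer
than `min_span = 10` doubly-spanning fibers are flagged insufficient and get
no p-value — Fisher on tiny tables is uninformative. A scan of an anchor
against candidates carries BH q-values across the tested candidates.

## Region-scale imbalance and the silenced-fraction estimator

Per peak: `delta = %acc(H1) − %acc(H2)` (signed — silencing is directional)
and `coverage = total spanning phased fibers` (summed over haplotypes).
Low-coverage peaks are excluded by
`coverage < max(10, median − 3·sd)`, with median and *sample* sd (ddof = 1)
computed once over the unfiltered set — which makes the filter idempotent.
A named region's deltas are compared against the background (all filtered
peaks outside every named region, minus excluded chromosomes) with a
two-sided Mann–Whitney U: exact enumeration when both samples have n ≤ 20
and no ties, otherwise the normal approximation with tie and continuity
correction.

If one haplotype of a region is fully silenced in a fraction `f` of cells
and the silenced state has no residual actuation, that haplotype's
accessible proportion at every peak scales by `(1 − f)`. Hence the per-peak
relative loss `r_i = (pct_active − pct_silenced)/pct_active` estimates `f`,
and the region estimate is `f̂ = median_i r_i`, clipped to [0, 1], with the
silenced haplotype inferred from the sign of the median delta when not
given. The median is used for robustness to low-coverage peaks; because
`E[1/pct_active] > 1/E[pct_active]`, `f̂` carries a small positive bias at
finite coverage (~+0.5 percentage points at 100 fibers/haplotype and 50%
actuation) — visible but immaterial at the effect sizes of interest. Any
residual actuation in the silenced state deflates `f̂` proportionally; `f̂`
is therefore a model-based estimate, not an assay of cell states.

## Methylome and transcripts

CpG pileups tally per-site, per-haplotype methylated/total calls
(UNASSIGNED tallied separately). The regional comparison pools a region's
counts per haplotype and applies a two-sided Fisher exact test; because
several CpGs of a region often lie on the same fiber, per-call pooling
overstates the effective n, so the default counting unit is the fiber (one
majority-state vote per fiber across the region's sites; ties count
methylated), with `unit="call"` available. At least `min_sites = 3` sites
with calls on both haplotypes are required.

Per-gene haplotype transcript counts are tested with a two-sided exact
binomial against 0.5 (minimum-likelihood two-sidedness). Haplotype
assignment of reads is an input; reads without an informative variant
appear as UNASSIGNED and are reported but untested.

## The synthetic-fiber generator

The generator emulates exactly the structure the analyses assume:

* **Loci and placement.** Elements and CpG sites are clustered into loci
  (merge gap 5 kb); per locus and haplotype, `coverage_per_hap` fibers are
  drawn with length ~ Normal(18 kb, 2.5 kb) truncated at 1 kb (the assay's
  shearing target) and centers jittered (sd 1 kb) around the locus
  midpoint. Each fiber's cell is sampled uniformly with replacement from an
  `n_cells` population: sequencing draws molecules from many cells, so two
  fibers at one locus rarely share a cell, while all records of one cell
  share its silencing state.
* **Actuation.** Each element overlapped by a fiber emits an MSP (precision
  0.97) with the haplotype-specific probability. Coupled pairs are drawn
  from the exact joint Bernoulli fixed by the two marginals and the target
  correlation; requested couplings are validated against the
  Fréchet–Hoeffding bounds at model construction. Background linker MSPs
  arrive at 0.5/kb (width 80–220 bp, precision ~ U[0, 0.3] — the upstream
  classifier's linker regime is not published, so a conservative low-
  precision band is assumed); element patches take priority when they
  collide.
* **Cell-persistent silencing.** Each silencing spec (region, haplotype,
  fraction `f`) is drawn once per cell. In silenced cells the region's
  elements actuate at `residual_actuation` (default 0), CpG sites methylate
  at `silenced_methylation` (default 0.9), and the region's genes emit no
  transcripts from that haplotype — one coherent cell state across all
  three data types, which is what makes region-scale imbalance a ~`f`
  shift rather than per-fiber noise.
* **Phasing loss.** Haplotype tags are masked to UNASSIGNED at
  `unassigned_rate` (default 0.10, matching the ~90% phasing rate of
  long-read data); actuation still follows the true haplotype.
* **Transcripts.** Per gene, haplotype, and cell: Poisson counts at the
  specified mean, zeroed under silencing.

Determinism: all three generators derive independent RNG streams from one
seed via fixed `SeedSequence` children, with cell states re-derivable from
`(model, n_cells, seed)` alone, so fiber/CpG/transcript sets generated with
the same seed share the same silenced cells and identical inputs give
byte-identical output tables.

Not emulated: raw sequence and base-level m6A, mapping/alignment artifacts,
read errors, classifier miscalibration (precision values are taken at face
value), copy-number and breakpoint structure, linked actuation across
*different* fibers of the same cell, and distance-dependent background
co-accessibility. Passing recovery tests therefore demonstrates that the
estimators invert the generative model they assume — not that real data
meet those assumptions.

## Problem sizes and defaults in the shipped analyses

The scenario builders fix the study conditions used by the tests, the
analysis drivers, and the acceptance script: imprinted element at actuation
0.70 vs 0.05 with 100 fibers/haplotype among 20 balanced peaks (actuation
0.3); enhancer coupling 0.8 with marginals 0.5 and 300 fibers/haplotype at
the locus; partial silencing at `f ∈ {0.03 … 0.4}` over 200 region peaks vs
2,000 balanced background peaks at 50 fibers/haplotype/peak; readthrough
promoter with 3 CpGs × 10 fibers/haplotype at baseline methylation 0.1 vs
silenced 0.9. Null calibrations use 1,000 balanced peaks (accessibility)
and repeated balanced regions (methylation, ASE). Multi-seed recovery
checks run 20–100 seeds depending on the statistic.

## Numerical and degenerate-input choices

* `1 − p` clamped at `1e-10` in the signal; thresholds validated to
  `α ∈ (0,1)`, `G ≥ 1`.
* Fisher odds-ratio sentinels: `inf` when `bc = 0 < ad`, `nan` when both
  products vanish.
* Empty inputs: empty fiber/peak/delta/call/read sets yield empty outputs
  (not errors) everywhere except where a statistic is undefined — MWU with
  an empty side, the silenced-fraction estimator with no active peak, a
  methylation region with too few informative sites, a binomial test with
  zero assigned reads — which raise with the offending region/quantity
  named.
* Coverage-filter statistics are computed on the original set by
  definition; a single-peak input uses the `min_reads` floor only (sample
  sd undefined).
* Floats are serialized with `repr` (shortest round-trip form) so
  read∘write is identity and reruns are byte-comparable.

## Known limitations

* The silenced-fraction estimator assumes complete, cell-persistent
  silencing with zero residual actuation; partial silencing biases `f̂`
  downward.
* Pooled methylation testing treats fibers (or calls) as independent;
  fiber-level correlation between regions sharing fibers is not modeled.
* Co-dependency conditions on fibers spanning both peaks, so pairs beyond
  one fiber length are untestable by construction (flagged insufficient,
  never imputed).
* The Bonferroni peak caller tests each base marginally; it inherits the
  conservatism of Bonferroni and makes no attempt at signal deconvolution
  within a run of significant bases.
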