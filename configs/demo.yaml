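# Demo scenario for `fiberhap run-all --config configs/demo.yaml`.
#
# One chromosome carries a promoter-enhancer pair with coupled single-molecule
# actuation, an imprinted element, and a readthrough-silenced promoter
# (hypermethylated + transcriptionally silent on H2 in every cell); a second
# chromosome region is silenced on H2 in 20% of cells (XCI-spreading style)
# against a balanced background chromosome.
#
# Schema: see docs/methods.md ("Pipeline configuration").
seed: 7
out_dir: results/demo
n_cells: 2000            # cells in the simulated population
coverage_per_hap: 60     # fibers per haplotype per locus
genome_size: null        # Bonferroni denominator; null = sum of chrom sizes

thresholds:
  alpha: 0.01
  fdr_level: 0.05
  nominal_p: 0.01
  min_precision_haptest: 0.90
  min_precision_codep: 0.95
  min_precision_imbalance: 0.90
  min_reads: 10
  sd_mult: 3.0
  min_span: 10
  merge_gap: 0

codep_anchor: promoter
exclude_chroms: []

regions:
  silenced_region: {chrom: chr13, start: 1000000, end: 1500000}

methyl_regions:
  readthrough_promoter: {chrom: chr13, start: 100000, end: 100400}

model:
  chrom_sizes: {chr13: 2000000, chr1: 1000000}
  fiber_length_mean: 18000
  fiber_length_sd: 2500
  background_msp_rate: 0.2
  unassigned_rate: 0.05
  elements:
    # readthrough-silenced promoter (silenced on H2 in all cells, below)
    - {id: promoter, chrom: chr13, start: 100000, end: 100400,
       actuation_h1: 0.8, actuation_h2: 0.8}
    # enhancer coupled to the promoter on the same fibers
    - {id: enhancer, chrom: chr13, start: 103000, end: 103200,
       actuation_h1: 0.5, actuation_h2: 0.5, couple_to: promoter, couple_corr: 0.4}
    # independent neighbor
    - {id: neighbor, chrom: chr13, start: 105000, end: 105200,
       actuation_h1: 0.5, actuation_h2: 0.5}
    # imprinted element
    - {id: imprinted, chrom: chr13, start: 500000, end: 500200,
       actuation_h1: 0.7, actuation_h2: 0.05}
    # five peaks inside the partially silenced region
    - {id: xci1, chrom: chr13, start: 1100000, end: 1100200,
       actuation_h1: 0.5, actuation_h2: 0.5}
    - {id: xci2, chrom: chr13, start: 1160000, end: 1160200,
       actuation_h1: 0.5, actuation_h2: 0.5}
    - {id: xci3, chrom: chr13, start: 1220000, end: 1220200,
       actuation_h1: 0.5, actuation_h2: 0.5}
    - {id: xci4, chrom: chr13, start: 1280000, end: 1280200,
       actuation_h1: 0.5, actuation_h2: 0.5}
    - {id: xci5, chrom: chr13, start: 1340000, end: 1340200,
       actuation_h1: 0.5, actuation_h2: 0.5}
    # balanced background peaks on chr1
    - {id: bg1, chrom: chr1, start: 100000, end: 100200,
       actuation_h1: 0.4, actuation_h2: 0.4}
    - {id: bg2, chrom: chr1, start: 200000, end: 200200,
       actuation_h1: 0.4, actuation_h2: 0.4}
    - {id: bg3, chrom: chr1, start: 300000, end: 300200,
       actuation_h1: 0.4, actuation_h2: 0.4}
    - {id: bg4, chrom: chr1, start: 400000, end: 400200,
       actuation_h1: 0.4, actuation_h2: 0.4}
    - {id: bg5, chrom: chr1, start: 500000, end: 500200,
       actuation_h1: 0.4, actuation_h2: 0.4}
    - {id: bg6, chrom: chr1, start: 600000, end: 600200,
       actuation_h1: 0.4, actuation_h2: 0.4}
    - {id: bg7, chrom: chr1, start: 700000, end: 700200,
       actuation_h1: 0.4, actuation_h2: 0.4}
    - {id: bg8, chrom: chr1, start: 800000, end: 800200,
       actuation_h1: 0.4, actuation_h2: 0.4}
  cpg_sites:
    chr13:
      - {pos: 100050, meth_h1: 0.1, meth_h2: 0.1}
      - {pos: 100150, meth_h1: 0.1, meth_h2: 0.1}
      - {pos: 100250, meth_h1: 0.1, meth_h2: 0.1}
      - {pos: 100350, meth_h1: 0.1, meth_h2: 0.1}
  silencing:
    # transcriptional readthrough silencing of the promoter on H2, all cells
    - {chrom: chr13, start: 95000, end: 110000, haplotype: H2, fraction: 1.0,
       residual_actuation: 0.0, silenced_methylation: 0.9}
    # XCI-spreading-style partial silencing of a distal region on H2
    - {chrom: chr13, start: 1000000, end: 1500000, haplotype: H2, fraction: 0.2,
       residual_actuation: 0.0, silenced_methylation: 0.9}
  genes:
    - {id: silenced_gene, chrom: chr13, pos: 100500, mean_h1: 0.004, mean_h2: 0.004}
    - {id: balanced_gene, chrom: chr13, pos: 900000, mean_h1: 0.004, mean_h2: 0.004}
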