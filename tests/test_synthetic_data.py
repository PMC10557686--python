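"""Generator contracts: determinism, marginal and coupling calibration,
cell-persistent silencing, and feasibility checks."""

from __future__ import annotations

import numpy as np
import pytest

import fiberhap as fh
from fiberhap import scenarios
from fiberhap.synthetic_data import _joint_prob, draw_cell_states


def single_element_model(act_h1: float, act_h2: float, **kwargs) -> fh.GenomeModel:
    return fh.GenomeModel(
        chrom_sizes={"chr1": 100_000},
        elements=(
            fh.ElementSpec("e1", fh.GenomicInterval("chr1", 50_000, 50_200), act_h1, act_h2),
        ),
        unassigned_rate=0.0,
        **kwargs,
    )


def element_accessible(fiber: fh.Fiber, interval: fh.GenomicInterval, min_p=0.9) -> bool:
    return any(
        m.precision >= min_p and m.interval.overlaps(interval) for m in fiber.msps
    )


class TestSimulateFibers:
    def test_zero_cells_is_empty(self):
        assert fh.simulate_fibers(single_element_model(0.5, 0.5), 0, 10, seed=1) == []

    def test_degenerate_actuation_one(self):
        model = single_element_model(1.0, 1.0)
        fibers = fh.simulate_fibers(model, 100, 50, seed=1)
        iv = model.elements[0].interval
        spanning = [f for f in fibers if f.interval.contains(iv)]
        assert spanning and all(element_accessible(f, iv) for f in spanning)

    def test_same_seed_byte_identical_tables(self, tmp_path):
        model = scenarios.imprinted_locus_model(n_balanced=3)
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        fh.write_fiber_table(fh.simulate_fibers(model, 50, 20, seed=9), a)
        fh.write_fiber_table(fh.simulate_fibers(model, 50, 20, seed=9), b)
        assert a.read_bytes() == b.read_bytes()

    def test_different_seeds_differ(self):
        model = single_element_model(0.5, 0.5)
        fa = fh.simulate_fibers(model, 50, 20, seed=1)
        fb = fh.simulate_fibers(model, 50, 20, seed=2)
        assert fa != fb

    def test_marginal_calibration_within_binomial_bound(self):
        # 10,000 fibers per haplotype at actuation 0.5: observed within +-0.02
        model = single_element_model(0.5, 0.5, background_msp_rate=0.2)
        fibers = fh.simulate_fibers(model, 10_000, 10_000, seed=3)
        iv = model.elements[0].interval
        for hap in ("H1", "H2"):
            span = [f for f in fibers if f.haplotype == hap and f.interval.contains(iv)]
            rate = np.mean([element_accessible(f, iv) for f in span])
            assert abs(rate - 0.5) < 0.02

    def test_fiber_lengths_truncated_and_msps_valid(self):
        model = single_element_model(0.8, 0.2, fiber_length_sd=8_000.0)
        for f in fh.simulate_fibers(model, 200, 200, seed=4):
            assert len(f.interval) >= 1_000 or f.interval.start == 0
            prev_end = -1
            for m in f.msps:
                assert f.interval.contains(m.interval)
                assert m.interval.start >= prev_end
                prev_end = m.interval.end

    def test_unassigned_rate_masks_tags(self):
        model = single_element_model(0.5, 0.5)
        model = fh.GenomeModel(
            chrom_sizes=model.chrom_sizes, elements=model.elements, unassigned_rate=0.3
        )
        fibers = fh.simulate_fibers(model, 1000, 2000, seed=5)
        frac = np.mean([f.haplotype == "UNASSIGNED" for f in fibers])
        assert abs(frac - 0.3) < 0.03


class TestCoupling:
    def test_joint_prob_matches_closed_form(self):
        # rho=0.8, p=q=0.5: p11 = 0.25 + 0.8*0.25 = 0.45
        assert _joint_prob(0.5, 0.5, 0.8) == pytest.approx(0.45)

    def test_infeasible_coupling_names_frechet(self):
        with pytest.raises(fh.InfeasibleCouplingError, match="Frechet"):
            fh.GenomeModel(
                chrom_sizes={"chr1": 100_000},
                elements=(
                    fh.ElementSpec("a", fh.GenomicInterval("chr1", 1000, 1200), 0.9, 0.9),
                    fh.ElementSpec(
                        "b", fh.GenomicInterval("chr1", 2000, 2200), 0.1, 0.1,
                        couple_to="a", couple_corr=0.9,
                    ),
                ),
            )

    def test_coupling_calibration(self):
        # empirical per-fiber correlation within +-0.05 of target at n=10,000
        model = scenarios.enhancer_codependency_model(couple_corr=0.8, n_independent=0)
        fibers = fh.simulate_fibers(model, 10_000, 10_000, seed=6)
        prom, enh = model.elements[0].interval, model.elements[1].interval
        span = [f for f in fibers if f.interval.contains(prom) and f.interval.contains(enh)]
        a = np.array([element_accessible(f, prom, 0.95) for f in span])
        b = np.array([element_accessible(f, enh, 0.95) for f in span])
        assert len(span) > 10_000
        assert abs(np.corrcoef(a, b)[0, 1] - 0.8) < 0.05


class TestSilencingAndCpG:
    def test_cell_states_deterministic_and_fractional(self):
        model = scenarios.xci_spreading_model(0.25, 5, 0)
        s1 = draw_cell_states(model, 10_000, seed=7)
        s2 = draw_cell_states(model, 10_000, seed=7)
        np.testing.assert_array_equal(s1, s2)
        assert abs(s1.mean() - 0.25) < 0.02

    def test_silencing_is_cell_persistent_across_loci(self):
        # all fibers of a silenced cell-haplotype lack element MSPs at every peak
        model = scenarios.xci_spreading_model(0.5, 5, 0)
        fibers = fh.simulate_fibers(model, 200, 100, seed=8)
        states = draw_cell_states(model, 200, seed=8)[0]
        from fiberhap.synthetic_data import fiber_id_fields

        for f in fibers:
            _, cell, hap = fiber_id_fields(f.fiber_id)
            if hap == "H2" and states[cell]:
                for e in model.elements:
                    if f.interval.contains(e.interval):
                        assert not element_accessible(f, e.interval)

    def test_cpg_degenerate_baselines(self):
        model = scenarios.readthrough_silencing_model(baseline_meth=0.0)
        model = fh.GenomeModel(
            chrom_sizes=model.chrom_sizes,
            elements=model.elements,
            cpg_sites=model.cpg_sites,
            unassigned_rate=0.0,
        )  # no silencing, baseline 0 -> all unmethylated
        fibers = fh.simulate_fibers(model, 50, 50, seed=9)
        calls = fh.simulate_cpg(model, fibers, seed=9)
        assert calls and not any(c.methylated for c in calls)

    def test_cpg_silencing_override_calibration(self):
        # baseline 0.2 vs silenced_methylation 0.9 at fraction 1.0 on H2
        model = scenarios.readthrough_silencing_model(
            baseline_meth=0.2, silenced_meth=0.9, n_cpg=10
        )
        fibers = fh.simulate_fibers(model, 1000, 200, seed=10)
        calls = fh.simulate_cpg(model, fibers, seed=10)
        h1 = [c.methylated for c in calls if c.haplotype == "H1"]
        h2 = [c.methylated for c in calls if c.haplotype == "H2"]
        assert len(h1) >= 1000 and len(h2) >= 1000
        assert abs(np.mean(h1) - 0.2) < 0.05
        assert abs(np.mean(h2) - 0.9) < 0.05

    def test_cpg_unknown_chromosome_errors(self):
        model = scenarios.readthrough_silencing_model()
        alien = fh.Fiber(fh.GenomicInterval("chrZ", 0, 2000), "L0.c0.H1.0", "H1")
        with pytest.raises(ValueError, match="unknown chromosome"):
            fh.simulate_cpg(model, [alien], seed=1)


class TestTranscripts:
    def test_zero_cells_empty(self):
        model = scenarios.readthrough_silencing_model()
        assert fh.simulate_transcripts(model, 0, seed=1) == []

    def test_monoallelic_gene_all_h1(self):
        model = fh.GenomeModel(
            chrom_sizes={"chr1": 10_000},
            genes=(fh.GeneSpec("g", "chr1", 5_000, 10.0, 0.0),),
            unassigned_rate=0.0,
        )
        reads = fh.simulate_transcripts(model, 20, seed=2)
        assert reads and all(r.haplotype == "H1" for r in reads)

    def test_balanced_gene_ratio_near_half(self):
        model = fh.GenomeModel(
            chrom_sizes={"chr1": 10_000},
            genes=(fh.GeneSpec("g", "chr1", 5_000, 10.0, 10.0),),
            unassigned_rate=0.0,
        )
        reads = fh.simulate_transcripts(model, 500, seed=3)
        n1 = sum(r.haplotype == "H1" for r in reads)
        ratio = n1 / len(reads)
        assert abs(ratio - 0.5) < 0.02  # ~10,000 reads, 3-sigma Poisson-ratio bound

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            fh.GeneSpec("g", "chr1", 0, -1.0, 1.0)

    def test_silenced_gene_zeroed_in_silenced_cells(self):
        model = scenarios.readthrough_silencing_model()  # fraction 1.0 on H2
        reads = fh.simulate_transcripts(model, 100, seed=4)
        assert not any(
            r.haplotype == "H2" and r.gene_id == "MAB21L1_like" for r in reads
        )
        assert any(r.gene_id == "control_gene" and r.haplotype == "H2" for r in reads)
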