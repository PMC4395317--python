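import numpy as np
import pytest

from snpanchor.genotype_bayes import BaseCompositionModel
from snpanchor.simulator import (
    SimConfig,
    simulate_reads,
    simulate_truth,
)
from snpanchor.types import BASES


SMALL = SimConfig(
    seed=11, n_cells=6, genome_length=100_000, n_germline_snps=60,
    n_somatic_mutations=4, ado_rate=0.3, segment_length=10_000,
    depth_mean=25, lineage_depth=2,
)


class TestSimulateTruth:
    def test_no_dropout_preserves_genotype(self):
        cfg = SimConfig(seed=1, n_cells=4, genome_length=50_000,
                        n_germline_snps=40, n_somatic_mutations=2, ado_rate=0.0)
        truth = simulate_truth(cfg)
        assert truth.dropout == {}
        for cell in truth.cell_nodes:
            for snp in truth.germline_snps:
                assert truth.observable_alleles(cell, snp.site.key) == {
                    snp.site.ref, snp.alt
                }

    def test_fusion_cell_unites_parent_mutations(self):
        cfg = SimConfig(seed=2, n_cells=8, genome_length=200_000,
                        n_germline_snps=0, n_somatic_mutations=6,
                        lineage_depth=2, fusion=("00", "01"))
        truth = simulate_truth(cfg)
        assert truth.fusion_cell is not None
        m_a = {m.site.key for m in truth.somatic_mutations
               if "00".startswith(m.origin_node) or m.origin_node.startswith("00")}
        fused = truth.cell_mutations[truth.fusion_cell]
        # the two forced parent mutations are both present
        forced = [m for m in truth.somatic_mutations if m.origin_node in ("00", "01")]
        assert len(forced) >= 2
        for m in forced:
            assert m.site.key in fused

    def test_invalid_fusion_node_rejected(self):
        cfg = SimConfig(seed=3, lineage_depth=2, fusion=("00", "777"))
        with pytest.raises(ValueError, match="fusion"):
            simulate_truth(cfg)

    def test_lineage_containment(self):
        truth = simulate_truth(SMALL)
        for m in truth.somatic_mutations:
            for cell, node in truth.cell_nodes.items():
                if cell in truth.fusion_cells:
                    continue
                carried = m.site.key in truth.cell_mutations[cell]
                assert carried == node.startswith(m.origin_node)

    def test_dropout_rate_recovered(self):
        cfg = SimConfig(seed=4, n_cells=40, genome_length=2_000_000,
                        n_germline_snps=0, n_somatic_mutations=0,
                        ado_rate=0.25, segment_length=10_000)
        truth = simulate_truth(cfg)
        n_pairs = cfg.n_cells * cfg.n_segments
        frac = len(truth.dropout) / n_pairs
        se = np.sqrt(0.25 * 0.75 / n_pairs)
        assert abs(frac - 0.25) < 3 * se

    def test_anchors_share_segment_with_target(self):
        truth = simulate_truth(SMALL)
        cfg = SMALL
        for m in truth.somatic_mutations:
            assert m.anchor is not None
            assert cfg.segment_of(m.site.pos) == cfg.segment_of(m.anchor.pos)
            assert abs(m.site.pos - m.anchor.pos) < cfg.read_length

    def test_paired_snp_fraction(self):
        cfg = SimConfig(seed=5, n_germline_snps=200, paired_snp_fraction=1.0,
                        n_somatic_mutations=0, genome_length=1_000_000)
        truth = simulate_truth(cfg)
        pos = sorted(s.site.pos for s in truth.germline_snps)
        n_close = sum(1 for a, b in zip(pos, pos[1:]) if b - a < cfg.read_length)
        assert n_close >= 90  # 100 constructed pairs, minus rare adjacency


class TestSimulateReads:
    def test_noise_free_het_site_shows_both_alleles(self):
        cfg = SimConfig(seed=6, n_cells=3, genome_length=50_000,
                        n_germline_snps=20, n_somatic_mutations=0,
                        ado_rate=0.0, depth_mean=60, phred_q=93)
        truth = simulate_truth(cfg)
        reads = simulate_reads(truth)
        for cell, cols in reads.cells.items():
            for snp in truth.germline_snps:
                col = cols[snp.site.key]
                seen = {b for b, _, _ in col.observations}
                assert seen == {snp.site.ref, snp.alt}

    def test_dropped_segment_shows_one_allele(self):
        cfg = SimConfig(seed=7, n_cells=4, genome_length=50_000,
                        n_germline_snps=30, n_somatic_mutations=0,
                        ado_rate=0.5, segment_length=5_000,
                        depth_mean=40, phred_q=93)
        truth = simulate_truth(cfg)
        reads = simulate_reads(truth)
        n_checked = 0
        for cell in truth.cell_nodes:
            for snp in truth.germline_snps:
                seg = cfg.segment_of(snp.site.pos)
                lost = truth.dropout.get((cell, seg))
                if lost is None:
                    continue
                col = reads.cells[cell][snp.site.key]
                if not col.observations:
                    continue
                seen = {b for b, _, _ in col.observations}
                alleles = truth.haplotype_alleles(cell, snp.site.key)
                assert seen == {alleles[1 - lost]}
                n_checked += 1
        assert n_checked > 10

    def test_error_bases_follow_gc_weights(self):
        # at a hom-ref site every non-ref base is an error; their
        # identities follow w_b / (1 - w_ref)
        cfg = SimConfig(seed=8, n_cells=1, genome_length=400_000,
                        n_germline_snps=0, n_somatic_mutations=0,
                        ado_rate=0.0, gc_content=0.40)
        truth = simulate_truth(cfg)
        comp = BaseCompositionModel(0.40)
        rng = np.random.default_rng(99)
        from snpanchor.simulator import _pileup_from_alleles
        from snpanchor.types import GenomicSite

        counts = {b: 0 for b in BASES}
        site = GenomicSite("chr1", 10, "A")
        col = _pileup_from_alleles(rng, site, ["A"], 2_000_000, 0.1, comp)
        for b, _, _ in col.observations:
            counts[b] += 1
        n_err = sum(v for k, v in counts.items() if k != "A")
        for b in "CGT":
            expected = comp.weight(b) / (1 - comp.weight("A"))
            se = np.sqrt(expected * (1 - expected) / n_err)
            assert abs(counts[b] / n_err - expected) < 3 * se

    def test_bulks_have_no_dropout_and_tumor_carries_mutations(self):
        truth = simulate_truth(SMALL)
        reads = simulate_reads(truth)
        for m in truth.somatic_mutations:
            tumor = reads.tumor_bulk[m.site.key]
            normal = reads.normal_bulk[m.site.key]
            t_bases = {b for b, _, _ in tumor.observations}
            assert m.alt in t_bases
            n_bases = {b for b, _, _ in normal.observations if b == m.alt}
            # normal bulk is wild-type at somatic sites (errors aside)
            assert len(n_bases) == 0 or truth.config.phred_q < 93

    def test_low_normal_depth_scenario(self):
        cfg = SimConfig(seed=9, n_cells=2, genome_length=50_000,
                        n_germline_snps=10, n_somatic_mutations=0)
        truth = simulate_truth(cfg)
        key = truth.germline_snps[0].site.key
        cfg2 = SimConfig(seed=9, n_cells=2, genome_length=50_000,
                         n_germline_snps=10, n_somatic_mutations=0,
                         low_normal_depth_sites=(key,), low_normal_depth=6)
        truth2 = simulate_truth(cfg2)
        reads = simulate_reads(truth2)
        assert reads.normal_bulk[key].depth < 20

    def test_reproducibility(self):
        t1 = simulate_truth(SMALL)
        t2 = simulate_truth(SMALL)
        assert [s.site for s in t1.germline_snps] == [s.site for s in t2.germline_snps]
        assert t1.dropout == t2.dropout
        r1 = simulate_reads(t1)
        r2 = simulate_reads(t2)
        for cell in r1.cells:
            for key in r1.cells[cell]:
                assert r1.cells[cell][key].observations == r2.cells[cell][key].observations
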