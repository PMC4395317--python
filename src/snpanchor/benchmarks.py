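"""Seeded end-to-end simulation experiments.

Each experiment generates data with the simulator, runs the full analysis
through the library, and measures how well a known ground-truth quantity
is recovered.  They quantify the method's two headline properties on
synthetic data: the naive per-site false-negative rate equals the allele
dropout rate, while anchor-confirmed wild-type calls are essentially
error-free when target and anchor share an amplification segment.
"""

from __future__ import annotations

import math
from typing import Optional

from .clonal_check import find_incompatible_cases
from .evaluation import estimate_fnr
from .genotype_bayes import BaseCompositionModel
from .genotype_matrix import build_matrix
from .simulator import GroundTruth, SimConfig, SimReads, simulate_reads, simulate_truth
from .types import format_site_label
from .workflow import confirmed_genotype_entries, genotype_pileups

__all__ = [
    "fnr_recovery_experiment",
    "anchor_confirmation_experiment",
    "clonal_experiment",
]


def _call_all_cells(truth: GroundTruth, reads: SimReads):
    comp = BaseCompositionModel(truth.config.gc_content)
    return {
        cell: genotype_pileups(cols, comp) for cell, cols in reads.cells.items()
    }


def fnr_recovery_experiment(
    seed: int,
    ado_rate: float = 0.25,
    n_cells: int = 3,
    n_loci: int = 10_000,
    depth_mean: float = 40.0,
    phred_q: int = 30,
    genome_length: int = 2_000_000,
    segment_length: int = 20_000,
) -> dict:
    """Recover a configured regional dropout rate as the naive het FNR.

    Simulates ``n_loci`` germline heterozygous SNPs per cell at deep
    coverage and low base error, genotypes every site, and estimates the
    false-negative rate against the known het truth.  Because dropout is
    regional, the effective number of independent trials is cells x
    segments, and the Monte-Carlo standard error reported here accounts
    for that clustering.
    """
    cfg = SimConfig(
        seed=seed,
        n_cells=n_cells,
        genome_length=genome_length,
        n_germline_snps=n_loci,
        paired_snp_fraction=0.0,
        n_somatic_mutations=0,
        ado_rate=ado_rate,
        segment_length=segment_length,
        depth_mean=depth_mean,
        phred_q=phred_q,
    )
    truth = simulate_truth(cfg)
    reads = simulate_reads(truth)
    calls = _call_all_cells(truth, reads)
    snp_keys = [s.site.key for s in truth.germline_snps]
    report = estimate_fnr(snp_keys, calls)
    mc_se = math.sqrt(ado_rate * (1 - ado_rate) / (n_cells * cfg.n_segments))
    return {
        "configured_ado_rate": ado_rate,
        "average_fnr": report.average_fnr,
        "pooled_fnr": report.pooled_fnr,
        "mc_se": mc_se,
        "n_evaluable": sum(c.n_evaluable for c in report.per_cell.values()),
    }


def anchor_confirmation_experiment(
    seed: int,
    ado_rate: float = 0.2,
    n_cells: int = 16,
    n_mutations: int = 12,
    depth_mean: float = 40.0,
    phred_q: int = 30,
) -> dict:
    """Error rate of anchor-confirmed wild-type (-1) calls vs. truth.

    Every simulated somatic mutation carries an anchor SNP inside its own
    amplification segment, so target and anchor share their dropout fate.
    A confirmed wild-type call is an *error* when the cell truly carries
    the mutation; with truthful anchors this can only happen through a
    genotype miscall, so the expected error count is zero.
    """
    cfg = SimConfig(
        seed=seed,
        n_cells=n_cells,
        genome_length=1_000_000,
        n_germline_snps=0,
        n_somatic_mutations=n_mutations,
        linked_mutation_fraction=1.0,
        ado_rate=ado_rate,
        depth_mean=depth_mean,
        phred_q=phred_q,
    )
    truth = simulate_truth(cfg)
    reads = simulate_reads(truth)
    calls = _call_all_cells(truth, reads)
    targets = [(m.site, m.alt) for m in truth.somatic_mutations]
    snps = [s.site for s in truth.germline_snps]
    entries = confirmed_genotype_entries(calls, targets, snps)

    label_to_key = {
        format_site_label(m.site.chrom, m.site.pos, m.site.ref, m.alt): m.site.key
        for m in truth.somatic_mutations
    }
    n_confirmed = n_errors = n_evaluated = 0
    for cell, label, code in entries:
        key = label_to_key[label]
        n_evaluated += 1
        if code == -1:
            n_confirmed += 1
            if key in truth.cell_mutations[cell]:
                n_errors += 1
    return {
        "n_evaluated": n_evaluated,
        "n_confirmed_wildtype": n_confirmed,
        "n_errors": n_errors,
        "error_rate": (n_errors / n_confirmed) if n_confirmed else 0.0,
    }


def clonal_experiment(
    seed: int,
    fusion: Optional[tuple[str, str]] = None,
    n_cells: int = 16,
    n_fusion_cells: int = 3,
    n_mutations: int = 8,
    ado_rate: float = 0.1,
    depth_mean: float = 40.0,
) -> int:
    """One end-to-end clonal-consistency run; returns the case count.

    Simulates a clonal lineage (optionally with a fusion event joining
    two mutation-bearing branches), genotypes all cells, assembles the
    ternary matrix via anchor confirmation, and counts incompatible
    (site pair, cell triple) cases.  A pure clonal history should yield
    zero; a fusion should be detectable as soon as confirmations succeed
    in the right cells.
    """
    cfg = SimConfig(
        seed=seed,
        n_cells=n_cells,
        genome_length=1_000_000,
        n_germline_snps=0,
        n_somatic_mutations=n_mutations,
        linked_mutation_fraction=1.0,
        lineage_depth=2,
        fusion=fusion,
        n_fusion_cells=n_fusion_cells,
        ado_rate=ado_rate,
        depth_mean=depth_mean,
    )
    truth = simulate_truth(cfg)
    reads = simulate_reads(truth)
    calls = _call_all_cells(truth, reads)
    targets = [(m.site, m.alt) for m in truth.somatic_mutations]
    snps = [s.site for s in truth.germline_snps]
    entries = confirmed_genotype_entries(calls, targets, snps)
    cells = sorted(calls)
    sites = sorted({label for _, label, _ in entries})
    matrix = build_matrix(entries, cells, sites)
    return len(find_incompatible_cases(matrix))
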