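"""Convenience wiring of the per-cell analysis steps.

These helpers connect pileup genotyping, SNP anchoring and ternary-code
assignment the way the subcommands do, for callers working from Python.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

from .ado_linkage import classify_ado, confirm_wildtype, find_linked_pairs
from .genotype_bayes import (
    BaseCompositionModel,
    call_genotype,
    genotype_prior,
)
from .types import GenomicSite, GenotypeCall, PileupColumn, format_site_label

SiteKey = tuple[str, int]

__all__ = ["genotype_pileups", "confirmed_genotype_entries"]


def genotype_pileups(
    pileups: Mapping[SiteKey, PileupColumn],
    comp: Optional[BaseCompositionModel] = None,
    min_depth: int = 5,
    ratio_threshold: float = 1000.0,
) -> dict[SiteKey, GenotypeCall]:
    """Bayesian genotype calls for every column of one sample."""
    comp = comp or BaseCompositionModel()
    prior = genotype_prior(comp)
    return {
        key: call_genotype(col, prior, comp, min_depth=min_depth,
                           ratio_threshold=ratio_threshold)
        for key, col in pileups.items()
    }


def confirmed_genotype_entries(
    cell_calls: Mapping[str, Mapping[SiteKey, GenotypeCall]],
    targets: Sequence[tuple[GenomicSite, str]],
    germline_het_snps: Sequence[GenomicSite],
    read_length: int = 90,
) -> list[tuple[str, str, int]]:
    """Ternary codes (cell, site label, 1/-1/0) for every cell x target.

    Each target is anchored to every germline het SNP within one read
    length; a cell's code is 1 for a called ref/alt heterozygote, -1 for
    a called hom-ref with at least one anchor showing both alleles, and 0
    otherwise.
    """
    tsites = sorted((t for t, _ in targets), key=lambda s: (s.chrom, s.pos))
    snps = sorted(germline_het_snps, key=lambda s: (s.chrom, s.pos))
    pairs = find_linked_pairs(tsites, snps, read_length)
    anchors: dict[SiteKey, list] = {}
    for p in pairs:
        anchors.setdefault(p.target.key, []).append(p)

    entries: list[tuple[str, str, int]] = []
    for cell, calls in cell_calls.items():
        for t, alt in targets:
            tc = calls.get(t.key)
            if tc is None:
                continue
            verdicts = [
                classify_ado(p, calls[p.anchor_snp.key])
                for p in anchors.get(t.key, [])
                if p.anchor_snp.key in calls
            ]
            code = confirm_wildtype(tc, verdicts, t.ref, alt)
            entries.append(
                (cell, format_site_label(t.chrom, t.pos, t.ref, alt), code)
            )
    return entries
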