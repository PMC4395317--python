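"""Detecting allele dropout with linked heterozygous germline SNPs.

Allele dropout (ADO) during whole-genome amplification silently removes
one haplotype from a region of a single cell's genome, so "no mutant
allele observed" at a site can mean either true wild-type or a dropped
mutant allele.  The resolution implemented here: anchor each target site
to a germline SNP that is heterozygous in the individual and lies within
one sequencing-read length (< 90 bp by default).  Because the two sites
are tightly linked, they share their amplification fate — if both alleles
of the anchor SNP are seen in the cell, no dropout occurred in the region
and the absence of a mutant allele at the target is a *confirmed*
wild-type; if the anchor shows only one allele, dropout occurred and the
target's genotype stays undefined.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import defaultdict
from typing import Iterable, Mapping, Optional, Sequence

from .types import AdoVerdict, GenomicSite, GenotypeCall, LinkedPair

__all__ = [
    "find_linked_pairs",
    "classify_ado",
    "confirm_wildtype",
    "validate_pair_concordance",
    "PairConcordance",
]


def _check_sorted(sites: Sequence[GenomicSite], name: str) -> None:
    keys = [(s.chrom, s.pos) for s in sites]
    if keys != sorted(keys):
        raise ValueError(f"{name} must be sorted by (chrom, pos)")


def find_linked_pairs(
    targets: Sequence[GenomicSite],
    germline_het_snps: Sequence[GenomicSite],
    read_length: int = 90,
) -> list[LinkedPair]:
    """All (target, anchor SNP) pairs closer than one read length.

    Both inputs must be sorted by (chrom, pos).  The bound is strict:
    distance 89 is linked at the default read length of 90, distance 90 is
    not.  A target with several nearby SNPs yields one pair per SNP.
    """
    _check_sorted(targets, "targets")
    _check_sorted(germline_het_snps, "germline_het_snps")
    by_chrom: dict[str, list[int]] = defaultdict(list)
    for s in germline_het_snps:
        by_chrom[s.chrom].append(s.pos)
    snp_sites = {(s.chrom, s.pos): s for s in germline_het_snps}

    pairs: list[LinkedPair] = []
    for t in targets:
        positions = by_chrom.get(t.chrom)
        if not positions:
            continue
        lo = bisect_right(positions, t.pos - read_length)
        hi = bisect_left(positions, t.pos + read_length)
        for pos in positions[lo:hi]:
            if pos == t.pos:
                continue
            pairs.append(
                LinkedPair(t, snp_sites[(t.chrom, pos)], abs(pos - t.pos))
            )
    return pairs


def classify_ado(pair: LinkedPair, anchor_call: GenotypeCall) -> AdoVerdict:
    """Read the anchor SNP's genotype as a dropout verdict for the region.

    Two alleles at the anchor mean both haplotypes amplified
    (NO_DROPOUT); one allele means the other haplotype dropped (DROPOUT);
    an uncertain anchor genotype is UNINFORMATIVE.
    """
    if anchor_call.is_uncertain:
        return AdoVerdict.UNINFORMATIVE
    return AdoVerdict.NO_DROPOUT if anchor_call.is_het else AdoVerdict.DROPOUT


def confirm_wildtype(
    target_call: GenotypeCall,
    verdicts: Iterable[AdoVerdict],
    ref: str,
    alt: str,
) -> int:
    """Ternary genotype code for one (cell, target site).

    Returns 1 (confirmed mutant) when the target is called heterozygous
    ref/alt; -1 (confirmed wild-type) when the target is called
    homozygous-reference AND at least one anchor proves both haplotypes
    amplified; 0 (undefined) otherwise.  Disagreeing anchors do not veto a
    NO_DROPOUT verdict: dropout boundaries can fall between anchors, and
    one anchor showing both alleles suffices.
    """
    if target_call.is_het and target_call.call is not None:
        if set(target_call.call.alleles) == {ref, alt}:
            return 1
    if target_call.is_hom and target_call.call is not None:
        if target_call.call.alleles[0] == ref:
            if any(v is AdoVerdict.NO_DROPOUT for v in verdicts):
                return -1
    return 0


class PairConcordance:
    """Outcome of the SNP-pair self-validation.

    ``error_rate`` is ``None`` (reported NA) when no informative case was
    seen; it is never silently 0.
    """

    def __init__(self, n_informative: int, n_discordant: int) -> None:
        if n_discordant > n_informative:
            raise ValueError("discordant count cannot exceed informative count")
        self.n_informative = n_informative
        self.n_discordant = n_discordant

    @property
    def error_rate(self) -> Optional[float]:
        if self.n_informative == 0:
            return None
        return self.n_discordant / self.n_informative

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"PairConcordance(n_informative={self.n_informative}, "
            f"n_discordant={self.n_discordant}, error_rate={self.error_rate})"
        )


def validate_pair_concordance(
    snp_pairs: Sequence[LinkedPair],
    per_cell_calls: Mapping[str, Mapping[tuple[str, int], GenotypeCall]],
) -> PairConcordance:
    """Self-validation of the dropout test on germline het SNP pairs.

    Each pair links two germline SNPs, both heterozygous in normal and
    tumor bulk, closer than one read length.  For each cell and each
    orientation of each pair: the case is *informative* when the first
    SNP is called heterozygous (both haplotypes demonstrably present),
    and *discordant* when the second SNP is then called homozygous —
    which should be impossible without an error, since the two sites
    share their amplification fate.  Both orientations are counted, as
    either member can serve as the witness of amplification.
    """
    n_informative = 0
    n_discordant = 0
    for cell, calls in per_cell_calls.items():
        for pair in snp_pairs:
            k1 = (pair.target.chrom, pair.target.pos)
            k2 = (pair.anchor_snp.chrom, pair.anchor_snp.pos)
            for a, b in ((k1, k2), (k2, k1)):
                ca = calls.get(a)
                cb = calls.get(b)
                if ca is None or not ca.is_het or cb is None:
                    continue
                n_informative += 1
                if cb.is_hom:
                    n_discordant += 1
    return PairConcordance(n_informative, n_discordant)
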