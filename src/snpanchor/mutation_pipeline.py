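"""Somatic-mutation identification from per-cell and bulk variant records.

A site qualifies as a somatic mutation candidate when it is heterozygous
in enough tumor cells, homozygous-reference (at adequate depth) in the
normal bulk, also mutated in the tumor bulk, not a known polymorphism,
and outside blacklisted amplified regions.  All record-level thresholds
are strict inequalities (QUAL > 20, FS < 40, QD > 1.5, GQ > 20, depth
> 5 in cells / > 20 in bulk).

The normal bulk is mandatory: without a reliable normal genotype, a
germline SNP that loses an allele to shallow coverage in the normal
sample masquerades as a somatic mutation in every cell that shows the
second allele.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from scipy.stats import binom

from .types import CandidateMutation, GenomicSite, Region, VariantRecord

__all__ = [
    "FilterConfig",
    "filter_record",
    "exclude_known_sites",
    "min_support_cells",
    "call_mutations",
]


@dataclass
class FilterConfig:
    """Thresholds for record- and site-level filtering.

    All comparisons are strict: e.g. a record with QUAL exactly 20 or
    QD exactly 1.5 fails.  ``min_cell_depth``/``min_bulk_depth`` are the
    "more than N qualified reads" gates.
    """

    min_qual: float = 20.0
    max_fs: float = 40.0
    min_qd: float = 1.5
    min_gq: float = 20.0
    min_mq: float = 20.0
    min_cell_depth: int = 5
    min_bulk_depth: int = 20
    maf_cutoff: float = 0.01
    min_support_cells: int = 3
    flank_bp: int = 90

    def __post_init__(self) -> None:
        for name in (
            "min_qual", "max_fs", "min_qd", "min_gq", "min_mq",
            "min_cell_depth", "min_bulk_depth", "maf_cutoff",
            "min_support_cells", "flank_bp",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def filter_record(
    rec: VariantRecord, cfg: FilterConfig, role: str = "cell"
) -> tuple[bool, Optional[str]]:
    """Apply the record-level criteria; fail on the first violation.

    ``role`` selects the depth gate: 'cell' requires depth strictly above
    ``min_cell_depth``, 'bulk' above ``min_bulk_depth``.  A missing
    annotation fails the corresponding criterion (we cannot certify what
    we cannot see).  Returns (passed, reason); reason is one of
    'QUAL', 'FS', 'QD', 'GQ', 'DP' or None.
    """
    if role not in ("cell", "bulk"):
        raise ValueError(f"role must be 'cell' or 'bulk', got {role!r}")
    if rec.qual is None or not rec.qual > cfg.min_qual:
        return False, "QUAL"
    if rec.fs is None or not rec.fs < cfg.max_fs:
        return False, "FS"
    if rec.qd is None or not rec.qd > cfg.min_qd:
        return False, "QD"
    if rec.gq is None or not rec.gq > cfg.min_gq:
        return False, "GQ"
    min_depth = cfg.min_cell_depth if role == "cell" else cfg.min_bulk_depth
    if rec.dp is None or not rec.dp > min_depth:
        return False, "DP"
    return True, None


def exclude_known_sites(
    candidates: Sequence[CandidateMutation],
    exclusion_sets: Sequence[Iterable[GenomicSite] | Iterable[Region]] = (),
    maf_table: Optional[Mapping[tuple[str, int], float]] = None,
    maf_cutoff: float = 0.01,
) -> list[CandidateMutation]:
    """Drop candidates at known polymorphic or otherwise excluded sites.

    A candidate is removed when its site appears in any exclusion set
    (site lists or BED regions — e.g. normal-bulk SNVs, dbSNP, HapMap),
    or appears in the population allele-frequency table with minor allele
    frequency strictly greater than ``maf_cutoff`` (MAF exactly at the
    cutoff is retained).
    """
    excluded_keys: set[tuple[str, int]] = set()
    regions: list[Region] = []
    for ex in exclusion_sets:
        for item in ex:
            if isinstance(item, Region):
                regions.append(item)
            else:
                excluded_keys.add((item.chrom, item.pos))

    out: list[CandidateMutation] = []
    for c in candidates:
        key = (c.site.chrom, c.site.pos)
        if key in excluded_keys:
            continue
        if any(r.contains(c.site) for r in regions):
            continue
        if maf_table is not None and maf_table.get(key, 0.0) > maf_cutoff:
            continue
        out.append(c)
    return out


def min_support_cells(n_cells: int, fp_rate: float, alpha: float) -> int:
    """Smallest k such that P[Binomial(n_cells, fp_rate) >= k] < alpha.

    The binomial model asks how many cells must independently show a
    variant before chance false positives (per-cell rate ``fp_rate``)
    become an implausible explanation at level ``alpha``.  The pipeline
    default bypasses this computation and uses the fixed requirement of
    three supporting cells.
    """
    if not 0.0 < fp_rate < 1.0:
        raise ValueError("fp_rate must be in (0, 1)")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    for k in range(1, n_cells + 2):
        # exact upper tail P[X >= k]
        if binom.sf(k - 1, n_cells, fp_rate) < alpha:
            return k
    return n_cells + 1  # pragma: no cover - sf at k=n+1 is exactly 0


def _in_targets(site: GenomicSite, targets: Sequence[Region], flank: int) -> bool:
    return any(
        r.chrom == site.chrom and (r.start - flank) < site.pos <= (r.end + flank)
        for r in targets
    )


def call_mutations(
    cell_records: Mapping[str, Sequence[VariantRecord]],
    normal_bulk_records: Sequence[VariantRecord],
    tumor_bulk_records: Sequence[VariantRecord],
    cfg: Optional[FilterConfig] = None,
    exclusion_sets: Sequence[Iterable[GenomicSite] | Iterable[Region]] = (),
    maf_table: Optional[Mapping[tuple[str, int], float]] = None,
    amplified_blacklist: Sequence[Region] = (),
    target_regions: Optional[Sequence[Region]] = None,
) -> list[CandidateMutation]:
    """The full candidate-mutation pipeline.

    Survivors are heterozygous (after record filters) in at least
    ``cfg.min_support_cells`` cells, homozygous-reference in the normal
    bulk at more than ``min_bulk_depth`` reads, mutated in the tumor
    bulk, outside amplified-region blacklists and exclusion sets, and —
    when target regions are supplied — inside the targets or their 90 bp
    flanks.  Raises if the normal bulk is missing entirely.
    """
    if normal_bulk_records is None or len(normal_bulk_records) == 0:
        raise ValueError(
            "normal bulk records are required: somatic status cannot be "
            "established without a reliable normal genotype"
        )
    cfg = cfg or FilterConfig()

    # normal bulk: sites confirmed homozygous-reference at adequate depth
    normal_hom_ref: set[tuple[str, int]] = set()
    normal_variant: set[tuple[str, int]] = set()
    for rec in normal_bulk_records:
        key = (rec.site.chrom, rec.site.pos)
        if rec.is_het or rec.is_hom_alt:
            normal_variant.add(key)
        elif rec.is_hom_ref and rec.dp is not None and rec.dp > cfg.min_bulk_depth:
            normal_hom_ref.add(key)

    # tumor bulk: variant sites passing bulk filters
    tumor_mutated: set[tuple[str, int, str]] = set()
    for rec in tumor_bulk_records:
        if (rec.is_het or rec.is_hom_alt) and filter_record(rec, cfg, "bulk")[0]:
            tumor_mutated.add((rec.site.chrom, rec.site.pos, rec.alt))

    support: dict[tuple[GenomicSite, str], set[str]] = defaultdict(set)
    for cell_id, recs in cell_records.items():
        for rec in recs:
            if not rec.is_het:
                continue
            if not filter_record(rec, cfg, "cell")[0]:
                continue
            support[(rec.site, rec.alt)].add(cell_id)

    candidates: list[CandidateMutation] = []
    for (site, alt), cells in sorted(
        support.items(), key=lambda kv: (kv[0][0].chrom, kv[0][0].pos, kv[0][1])
    ):
        key = (site.chrom, site.pos)
        if len(cells) < cfg.min_support_cells:
            continue
        if key in normal_variant or key not in normal_hom_ref:
            continue  # germline, or normal genotype not reliably established
        if (site.chrom, site.pos, alt) not in tumor_mutated:
            continue
        if any(r.contains(site) for r in amplified_blacklist):
            continue
        if target_regions is not None and not _in_targets(
            site, target_regions, cfg.flank_bp
        ):
            continue
        candidates.append(CandidateMutation(site, alt, frozenset(cells)))

    return exclude_known_sites(
        candidates, exclusion_sets, maf_table, cfg.maf_cutoff
    )
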