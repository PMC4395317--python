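"""Synthetic single-cell sequencing data with WGA allele dropout.

The generator produces exactly the statistical structure the anchoring
strategy relies on, with known ground truth:

* germline heterozygous SNPs, a configurable fraction of them placed as
  close pairs (< one read length apart) so they can anchor each other;
* somatic mutations on a clonal lineage tree (complete binary tree), with
  an optional cell-fusion event whose cell carries the union of two
  lineages' mutations;
* *regional* allele dropout: whole-genome amplification fails per
  (cell, segment), removing one whole haplotype from a contiguous
  segment — so tightly linked sites share their amplification fate,
  which is the physical basis of the anchoring test;
* pileup reads with Phred-scaled base errors, misread bases drawn with
  GC-composition weights, depth Poisson per site; bulk samples without
  dropout.

Defaults follow the study conditions: 41% GC, dropout rate inside the
7-44% range reported across WGA platforms, 90 bp reads, ~0.4% SNP
density.  Identical seed and config give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .genotype_bayes import BaseCompositionModel
from .types import BASES, GenomicSite, GenotypeCall, PileupColumn, VariantRecord

__all__ = ["SimConfig", "GroundTruth", "SimReads", "simulate_truth", "simulate_reads",
           "records_from_calls"]

SiteKey = tuple[str, int]


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_cells: int = 16
    genome_length: int = 1_000_000
    chrom: str = "chr1"
    gc_content: float = 0.41
    #: polymorphic fraction of sites; ~0.4% as in exonic territory
    snp_density: float = 0.004
    #: explicit SNP count overriding snp_density when set
    n_germline_snps: Optional[int] = None
    #: fraction of germline SNPs placed as pairs < read_length apart
    paired_snp_fraction: float = 0.5
    n_somatic_mutations: int = 8
    #: fraction of somatic mutations given an anchor SNP < read_length away
    linked_mutation_fraction: float = 1.0
    lineage_depth: int = 3
    #: two lineage nodes whose mutation sets a fusion cell unites
    fusion: Optional[tuple[str, str]] = None
    #: cells sampled from the fused lineage (descendants of the fusion)
    n_fusion_cells: int = 1
    #: regional dropout probability per (cell, segment); platforms span 0.07-0.44
    ado_rate: float = 0.2
    #: amplification-segment length; MDA amplicons run tens of kilobases
    segment_length: int = 100_000
    depth_mean: float = 30.0
    phred_q: int = 30
    bulk_depth: int = 60
    read_length: int = 90
    #: sites whose normal-bulk depth is forced shallow (miscall scenario)
    low_normal_depth_sites: tuple[SiteKey, ...] = ()
    low_normal_depth: int = 8

    def __post_init__(self) -> None:
        if not 0.0 <= self.ado_rate <= 1.0:
            raise ValueError("ado_rate must be in [0, 1]")
        if self.segment_length < self.read_length:
            raise ValueError("segment_length must be >= read_length")
        if not 0.0 <= self.paired_snp_fraction <= 1.0:
            raise ValueError("paired_snp_fraction must be in [0, 1]")

    @property
    def n_segments(self) -> int:
        return -(-self.genome_length // self.segment_length)

    def segment_of(self, pos: int) -> int:
        return (pos - 1) // self.segment_length


@dataclass(frozen=True)
class GermlineSnp:
    site: GenomicSite
    alt: str
    alt_hap: int  # haplotype (0/1) carrying the alternate allele


@dataclass(frozen=True)
class SomaticMutation:
    site: GenomicSite
    alt: str
    hap: int           # haplotype carrying the mutation
    origin_node: str   # lineage-tree node where the mutation arose
    anchor: Optional[GenomicSite] = None  # linked germline SNP, if placed


@dataclass
class GroundTruth:
    config: SimConfig
    germline_snps: list[GermlineSnp]
    somatic_mutations: list[SomaticMutation]
    cell_nodes: dict[str, str]                 # cell id -> lineage leaf node
    cell_mutations: dict[str, set[SiteKey]]    # cell id -> carried somatic sites
    #: (cell, segment index) -> lost haplotype, for dropped segments only
    dropout: dict[tuple[str, int], int]
    fusion_cells: tuple[str, ...] = ()

    @property
    def fusion_cell(self) -> Optional[str]:
        return self.fusion_cells[0] if self.fusion_cells else None

    def haplotype_alleles(self, cell: str, site_key: SiteKey) -> tuple[str, str]:
        """True (hap0, hap1) alleles of a cell at a tracked site."""
        snp = self._snp_index().get(site_key)
        if snp is not None:
            alleles = [snp.site.ref, snp.site.ref]
            alleles[snp.alt_hap] = snp.alt
            return tuple(alleles)  # type: ignore[return-value]
        mut = self._mut_index().get(site_key)
        if mut is None:
            raise KeyError(f"untracked site {site_key}")
        alleles = [mut.site.ref, mut.site.ref]
        if site_key in self.cell_mutations[cell]:
            alleles[mut.hap] = mut.alt
        return tuple(alleles)  # type: ignore[return-value]

    def surviving_haps(self, cell: str, site_key: SiteKey) -> tuple[int, ...]:
        seg = self.config.segment_of(site_key[1])
        lost = self.dropout.get((cell, seg))
        if lost is None:
            return (0, 1)
        return (1 - lost,)

    def observable_alleles(self, cell: str, site_key: SiteKey) -> set[str]:
        alleles = self.haplotype_alleles(cell, site_key)
        return {alleles[h] for h in self.surviving_haps(cell, site_key)}

    # cached site indexes -------------------------------------------------
    def _snp_index(self) -> dict[SiteKey, GermlineSnp]:
        if not hasattr(self, "_snp_idx"):
            object.__setattr__(
                self, "_snp_idx", {s.site.key: s for s in self.germline_snps}
            )
        return self._snp_idx  # type: ignore[attr-defined]

    def _mut_index(self) -> dict[SiteKey, SomaticMutation]:
        if not hasattr(self, "_mut_idx"):
            object.__setattr__(
                self, "_mut_idx", {m.site.key: m for m in self.somatic_mutations}
            )
        return self._mut_idx  # type: ignore[attr-defined]

    @property
    def tracked_sites(self) -> list[GenomicSite]:
        sites = [s.site for s in self.germline_snps] + [
            m.site for m in self.somatic_mutations
        ]
        return sorted(sites, key=lambda s: (s.chrom, s.pos))


@dataclass
class SimReads:
    cells: dict[str, dict[SiteKey, PileupColumn]]
    normal_bulk: dict[SiteKey, PileupColumn]
    tumor_bulk: dict[SiteKey, PileupColumn]


# ---------------------------------------------------------------------------


def _draw_base(rng: np.random.Generator, weights: np.ndarray) -> str:
    return BASES[rng.choice(4, p=weights)]


def _lineage_nodes(depth: int) -> list[str]:
    """All non-root nodes of a complete binary tree, as binary strings."""
    nodes: list[str] = []
    frontier = [""]
    for _ in range(depth):
        frontier = [n + c for n in frontier for c in "01"]
        nodes.extend(frontier)
    return nodes


def simulate_truth(cfg: SimConfig) -> GroundTruth:
    """Sample ground truth: sites, lineage, mutations, dropout pattern."""
    rng = np.random.default_rng(cfg.seed)
    comp = BaseCompositionModel(cfg.gc_content)
    w = np.array([comp.weight(b) for b in BASES])

    used: set[int] = set()

    def fresh_pos(lo: int = 1, hi: Optional[int] = None) -> int:
        hi = hi or cfg.genome_length
        while True:
            p = int(rng.integers(lo, hi + 1))
            if p not in used:
                used.add(p)
                return p

    def random_snp_at(pos: int) -> GermlineSnp:
        ref = _draw_base(rng, w)
        others = [b for b in BASES if b != ref]
        ow = np.array([comp.weight(b) for b in others])
        alt = others[rng.choice(3, p=ow / ow.sum())]
        return GermlineSnp(
            GenomicSite(cfg.chrom, pos, ref), alt, int(rng.integers(2))
        )

    # germline SNPs: pairs first, then singletons
    n_snps = (
        cfg.n_germline_snps
        if cfg.n_germline_snps is not None
        else round(cfg.genome_length * cfg.snp_density)
    )
    snps: list[GermlineSnp] = []
    n_pairs = int(round(n_snps * cfg.paired_snp_fraction / 2))
    for _ in range(n_pairs):
        d = int(rng.integers(10, cfg.read_length))
        p1 = fresh_pos(1, cfg.genome_length - d)
        while p1 + d in used:
            p1 = fresh_pos(1, cfg.genome_length - d)
        used.add(p1 + d)
        snps.append(random_snp_at(p1))
        snps.append(random_snp_at(p1 + d))
    for _ in range(n_snps - 2 * n_pairs):
        snps.append(random_snp_at(fresh_pos()))

    # lineage: cells on the leaves of a complete binary tree
    nodes = _lineage_nodes(cfg.lineage_depth)
    leaves = [n for n in nodes if len(n) == cfg.lineage_depth]
    cell_ids = [f"cell{i:03d}" for i in range(cfg.n_cells)]
    cell_nodes = {c: leaves[i % len(leaves)] for i, c in enumerate(cell_ids)}
    fusion_cells: tuple[str, ...] = ()
    if cfg.fusion is not None:
        na, nb = cfg.fusion
        if na not in nodes or nb not in nodes:
            raise ValueError(f"fusion nodes {cfg.fusion} not in lineage tree")
        fusion_cells = tuple(cell_ids[-cfg.n_fusion_cells:])

    # somatic mutations on lineage edges; fusion parents get one each
    muts: list[SomaticMutation] = []
    for i in range(cfg.n_somatic_mutations):
        if cfg.fusion is not None and i < 2:
            origin = cfg.fusion[i]
        else:
            origin = nodes[int(rng.integers(len(nodes)))]
        linked = rng.random() < cfg.linked_mutation_fraction
        if linked:
            d = int(rng.integers(10, cfg.read_length))
            # keep the pair inside one amplification segment so target and
            # anchor share their dropout fate
            while True:
                p = fresh_pos(1, cfg.genome_length - d)
                if cfg.segment_of(p) == cfg.segment_of(p + d) and p + d not in used:
                    break
            used.add(p + d)
            anchor_snp = random_snp_at(p + d)
            snps.append(anchor_snp)
            anchor = anchor_snp.site
        else:
            p = fresh_pos()
            anchor = None
        ref = _draw_base(rng, w)
        others = [b for b in BASES if b != ref]
        ow = np.array([comp.weight(b) for b in others])
        alt = others[rng.choice(3, p=ow / ow.sum())]
        muts.append(
            SomaticMutation(
                GenomicSite(cfg.chrom, p, ref), alt, int(rng.integers(2)),
                origin, anchor,
            )
        )

    snps.sort(key=lambda s: s.site.pos)

    # which cells carry which mutations (fusion cell: union of two paths)
    cell_mutations: dict[str, set[SiteKey]] = {}
    for c in cell_ids:
        leaf = cell_nodes[c]
        carried = set()
        for m in muts:
            if c in fusion_cells and cfg.fusion is not None:
                na, nb = cfg.fusion
                if na.startswith(m.origin_node) or nb.startswith(m.origin_node):
                    carried.add(m.site.key)
            elif leaf.startswith(m.origin_node):
                carried.add(m.site.key)
        cell_mutations[c] = carried

    # regional dropout per (cell, segment)
    dropout: dict[tuple[str, int], int] = {}
    for c in cell_ids:
        dropped = rng.random(cfg.n_segments) < cfg.ado_rate
        lost = rng.integers(2, size=cfg.n_segments)
        for seg in np.nonzero(dropped)[0]:
            dropout[(c, int(seg))] = int(lost[seg])

    return GroundTruth(
        config=cfg,
        germline_snps=snps,
        somatic_mutations=muts,
        cell_nodes=cell_nodes,
        cell_mutations=cell_mutations,
        dropout=dropout,
        fusion_cells=fusion_cells,
    )


def _pileup_from_alleles(
    rng: np.random.Generator,
    site: GenomicSite,
    alleles: Sequence[str],
    depth: int,
    e: float,
    comp: BaseCompositionModel,
    mapq: int = 60,
) -> PileupColumn:
    """Sample one pileup column: reads pick a template allele uniformly,
    then misread with probability e into a GC-weighted wrong base."""
    obs: list[tuple[str, float, int]] = []
    if depth > 0 and alleles:
        picks = rng.integers(len(alleles), size=depth)
        errs = rng.random(depth) < e
        for k in range(depth):
            true_base = alleles[picks[k]]
            if errs[k]:
                others = [b for b in BASES if b != true_base]
                ow = np.array([comp.weight(b) for b in others])
                base = others[rng.choice(3, p=ow / ow.sum())]
            else:
                base = true_base
            obs.append((base, e, mapq))
    return PileupColumn(site, obs)


def simulate_reads(truth: GroundTruth, cfg: Optional[SimConfig] = None) -> SimReads:
    """Generate per-cell and bulk pileups at every tracked site.

    Per-cell columns reflect each cell's surviving haplotypes (regional
    dropout applied); bulk columns are dropout-free.  The normal bulk is
    wild-type at somatic sites; the tumor bulk is heterozygous at them.
    Sites listed in ``low_normal_depth_sites`` get shallow normal-bulk
    coverage, reproducing the germline-SNP miscall scenario.
    """
    cfg = cfg or truth.config
    rng = np.random.default_rng([cfg.seed, 1])
    comp = BaseCompositionModel(cfg.gc_content)
    e = 10.0 ** (-cfg.phred_q / 10.0)
    sites = truth.tracked_sites
    mut_keys = {m.site.key for m in truth.somatic_mutations}

    cells: dict[str, dict[SiteKey, PileupColumn]] = {}
    for c in truth.cell_nodes:
        cols: dict[SiteKey, PileupColumn] = {}
        for site in sites:
            key = site.key
            haps = truth.surviving_haps(c, key)
            alleles = truth.haplotype_alleles(c, key)
            templates = [alleles[h] for h in haps]
            depth = int(rng.poisson(cfg.depth_mean))
            cols[key] = _pileup_from_alleles(rng, site, templates, depth, e, comp)
        cells[c] = cols

    snp_idx = {s.site.key: s for s in truth.germline_snps}
    normal: dict[SiteKey, PileupColumn] = {}
    tumor: dict[SiteKey, PileupColumn] = {}
    low = set(cfg.low_normal_depth_sites)
    for site in sites:
        key = site.key
        if key in snp_idx:
            s = snp_idx[key]
            germ_alleles = [s.site.ref, s.alt]
        else:
            germ_alleles = [site.ref, site.ref]
        n_depth = cfg.low_normal_depth if key in low else cfg.bulk_depth
        normal[key] = _pileup_from_alleles(
            rng, site, germ_alleles, int(rng.poisson(n_depth)), e, comp
        )
        if key in mut_keys:
            m = next(x for x in truth.somatic_mutations if x.site.key == key)
            tumor_alleles = [site.ref, m.alt]
        else:
            tumor_alleles = germ_alleles
        tumor[key] = _pileup_from_alleles(
            rng, site, tumor_alleles, int(rng.poisson(cfg.bulk_depth)), e, comp
        )
    return SimReads(cells, normal, tumor)


def records_from_calls(
    calls: dict[SiteKey, GenotypeCall],
    ref_alt: dict[SiteKey, tuple[str, str]],
    chrom: str,
) -> list[VariantRecord]:
    """Turn genotype calls into minimal variant records for the pipeline.

    Annotation values are synthesised from the call: confident calls get
    passing QUAL/FS/QD/GQ; uncertain calls get sub-threshold quality so
    the record filters treat them as unusable.
    """
    recs: list[VariantRecord] = []
    for key, call in sorted(calls.items()):
        ref, alt = ref_alt[key]
        site = GenomicSite(chrom, key[1], ref)
        if call.is_uncertain or call.call is None:
            gt, qual, gq = "./.", 10.0, 10.0
        else:
            alleles = set(call.call.alleles)
            if alleles == {ref}:
                gt = "0/0"
            elif alleles == {ref, alt}:
                gt = "0/1"
            elif alleles == {alt}:
                gt = "1/1"
            else:  # genotype involves a base outside ref/alt
                gt = "./."
            qual = gq = 99.0
        qd = 25.0 if qual > 20.0 else 0.5
        recs.append(
            VariantRecord(
                site=site, alt=alt, qual=qual, fs=0.0,
                qd=qd, gq=gq, dp=call.depth, gt=gt,
            )
        )
    return recs
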