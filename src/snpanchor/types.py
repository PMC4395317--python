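"""Core domain types shared across the toolkit.

Conventions: pileup/VCF/matrix coordinates are 1-based; BED regions are
0-based half-open. Bases are upper-case single characters from {A,C,G,T}.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations_with_replacement
from typing import Optional

BASES = ("A", "C", "G", "T")


@dataclass(frozen=True, order=True)
class GenomicSite:
    """One genomic position with its reference base (1-based)."""

    chrom: str
    pos: int
    ref: str = "N"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if len(self.ref) != 1 or not self.ref.isupper():
            raise ValueError(f"ref must be a single upper-case base, got {self.ref!r}")

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass
class PileupColumn:
    """All base observations covering one site in one sample.

    Each observation is (base, error_prob, mapping_quality) where
    error_prob = 10**(-Q/10) for the Phred base quality Q.
    """

    site: GenomicSite
    observations: list[tuple[str, float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for b, e, _ in self.observations:
            if b not in BASES:
                raise ValueError(f"invalid base {b!r}")
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"error probability {e} outside [0, 1]")

    @property
    def depth(self) -> int:
        return len(self.observations)


@dataclass
class VariantRecord:
    """Minimal SNV record: the VCF annotations the filters act on.

    Missing annotations are ``None`` (never silently zero).
    """

    site: GenomicSite
    alt: str
    qual: Optional[float] = None
    fs: Optional[float] = None
    qd: Optional[float] = None
    gq: Optional[float] = None
    dp: Optional[int] = None
    gt: Optional[str] = None

    def __post_init__(self) -> None:
        if self.alt not in BASES:
            raise ValueError(f"alt must be a single base, got {self.alt!r}")
        for name in ("qual", "fs", "qd", "gq", "dp"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    @property
    def is_het(self) -> bool:
        return self.gt in ("0/1", "1/0")

    @property
    def is_hom_ref(self) -> bool:
        return self.gt == "0/0"

    @property
    def is_hom_alt(self) -> bool:
        return self.gt == "1/1"


@dataclass(frozen=True, order=True)
class Region:
    """BED-style region: 0-based start, exclusive end."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")

    def contains(self, site: GenomicSite) -> bool:
        # 1-based site pos p lies in [start, end) iff start < p <= end
        return site.chrom == self.chrom and self.start < site.pos <= self.end


@dataclass(frozen=True)
class Genotype:
    """Unordered diploid genotype: a pair of alleles from {A,C,G,T}."""

    alleles: tuple[str, str]

    def __post_init__(self) -> None:
        a1, a2 = self.alleles
        if a1 not in BASES or a2 not in BASES:
            raise ValueError(f"invalid alleles {self.alleles!r}")
        if (a1, a2) != tuple(sorted(self.alleles)):
            object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    @classmethod
    def of(cls, a1: str, a2: str) -> "Genotype":
        return cls(tuple(sorted((a1, a2))))  # type: ignore[arg-type]

    @property
    def is_hom(self) -> bool:
        return self.alleles[0] == self.alleles[1]

    @property
    def is_het(self) -> bool:
        return not self.is_hom

    def __contains__(self, base: str) -> bool:
        return base in self.alleles

    def __str__(self) -> str:
        return "".join(self.alleles)


#: The ten distinct diploid genotypes (4 homozygous + 6 heterozygous).
ALL_GENOTYPES: tuple[Genotype, ...] = tuple(
    Genotype.of(a, b) for a, b in combinations_with_replacement(BASES, 2)
)


@dataclass
class GenotypeCall:
    """Result of Bayesian genotype inference at one site in one sample.

    ``call`` is ``None`` when the evidence does not single out one genotype
    (too few reads, dominance ratio below threshold, or a tie).
    """

    call: Optional[Genotype]
    posterior: dict[Genotype, float]
    dominance_ratio: float
    depth: int = 0

    @property
    def is_uncertain(self) -> bool:
        return self.call is None

    @property
    def is_het(self) -> bool:
        return self.call is not None and self.call.is_het

    @property
    def is_hom(self) -> bool:
        return self.call is not None and self.call.is_hom


class AdoVerdict(Enum):
    """What an anchor SNP's genotype says about regional allele dropout."""

    NO_DROPOUT = "no_dropout"
    DROPOUT = "dropout"
    UNINFORMATIVE = "uninformative"


@dataclass(frozen=True)
class LinkedPair:
    """A target site anchored to a heterozygous germline SNP within one
    read length, so single reads can span both sites."""

    target: GenomicSite
    anchor_snp: GenomicSite
    distance: int

    def __post_init__(self) -> None:
        if self.target.chrom != self.anchor_snp.chrom:
            raise ValueError("target and anchor must share a chromosome")
        if self.distance != abs(self.target.pos - self.anchor_snp.pos):
            raise ValueError("distance inconsistent with site positions")
        if self.distance < 1:
            raise ValueError("target and anchor must be distinct positions")


@dataclass
class CandidateMutation:
    """A somatic SNV candidate surviving the filtering pipeline."""

    site: GenomicSite
    alt: str
    supporting_cells: frozenset[str]
    in_tumor_bulk: bool = True

    def __post_init__(self) -> None:
        if not self.supporting_cells:
            raise ValueError("supporting_cells must be non-empty")


@dataclass(frozen=True)
class IncompatibleCase:
    """A (site pair, cell triple) violating the clonal growth model:
    cell_x is mutant at site_a only, cell_y at site_b only, and cell_z —
    unexpectedly — at both."""

    site_a: str
    site_b: str
    cell_x: str
    cell_y: str
    cell_z: str


def normalize_chrom(chrom: str) -> str:
    """Canonical chromosome spelling used in site labels: 'Chr21'."""
    c = chrom
    if c.lower().startswith("chr"):
        c = c[3:]
    return f"Chr{c}"


def format_site_label(chrom: str, pos: int, ref: str, alt: str) -> str:
    """Site label in 'Chr21_37664570:G->T' form."""
    return f"{normalize_chrom(chrom)}_{pos}:{ref}->{alt}"


def parse_site_label(label: str) -> tuple[str, int, str, str]:
    """Inverse of :func:`format_site_label`."""
    locus, _, mut = label.partition(":")
    chrom, _, pos = locus.rpartition("_")
    ref, _, alt = mut.partition("->")
    if not (chrom and pos.isdigit() and len(ref) == 1 and len(alt) == 1):
        raise ValueError(f"malformed site label {label!r}")
    return chrom, int(pos), ref, alt
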