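"""Self-assessment statistics: false-negative rates and summary ratios.

The false-negative rate (FNR) of naive single-cell genotyping is
estimated from germline SNPs known to be heterozygous in both normal and
tumor bulk tissue: in each cell, the fraction of adequately covered such
SNPs that fail to be recovered as heterozygous.  Because those SNPs are
het by construction, any non-het outcome in a cell is a false negative —
mostly allele dropout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

__all__ = ["FnrReport", "CellFnr", "estimate_fnr", "comparison_summary", "snp_density"]


@dataclass
class CellFnr:
    n_evaluable: int
    n_recovered: int

    @property
    def fnr(self) -> Optional[float]:
        if self.n_evaluable == 0:
            return None
        return 1.0 - self.n_recovered / self.n_evaluable


@dataclass
class FnrReport:
    """Per-cell and aggregate false-negative rates.

    ``average_fnr`` is the unweighted mean over cells with at least one
    evaluable SNP; ``pooled_fnr`` pools all evaluable SNPs across cells
    first.  Both are reported because they answer slightly different
    questions (typical cell vs. typical observation).
    """

    per_cell: dict[str, CellFnr]

    @property
    def average_fnr(self) -> Optional[float]:
        rates = [c.fnr for c in self.per_cell.values() if c.fnr is not None]
        if not rates:
            return None
        return sum(rates) / len(rates)

    @property
    def pooled_fnr(self) -> Optional[float]:
        n_eval = sum(c.n_evaluable for c in self.per_cell.values())
        n_rec = sum(c.n_recovered for c in self.per_cell.values())
        if n_eval == 0:
            return None
        return 1.0 - n_rec / n_eval


def estimate_fnr(
    bulk_het_snps: Sequence[tuple[str, int]],
    cell_calls: Mapping[str, Mapping[tuple[str, int], "object"]],
    min_depth: int = 5,
) -> FnrReport:
    """FNR per cell over SNPs heterozygous in both bulks.

    A SNP is *evaluable* in a cell when the cell has a genotype call there
    with strictly more than ``min_depth`` qualified reads; it is
    *recovered* when that call is heterozygous.  fnr = 1 - recovered /
    evaluable.  Cells with no evaluable SNP report NA and are excluded
    from the average.
    """
    wanted = set(bulk_het_snps)
    report: dict[str, CellFnr] = {}
    for cell, calls in cell_calls.items():
        n_eval = 0
        n_rec = 0
        for key, call in calls.items():
            if key not in wanted:
                continue
            if getattr(call, "depth", 0) <= min_depth:
                continue
            n_eval += 1
            if getattr(call, "is_het", False):
                n_rec += 1
        report[cell] = CellFnr(n_eval, n_rec)
    return FnrReport(report)


def comparison_summary(
    ratios: Mapping[str, tuple[int, int]], decimals: int = 0
) -> dict[str, dict[str, float | int | str]]:
    """Report named numerator/denominator pairs as rounded percentages.

    Each entry maps a label to {'numerator', 'denominator', 'fraction',
    'percent'}; 'percent' is rounded to ``decimals`` places (the display
    precision of a results summary).
    """
    out: dict[str, dict[str, float | int | str]] = {}
    for name, (num, den) in ratios.items():
        if den <= 0:
            raise ValueError(f"{name}: denominator must be > 0")
        if num < 0:
            raise ValueError(f"{name}: numerator must be >= 0")
        frac = num / den
        pct = round(100.0 * frac, decimals)
        if decimals == 0:
            pct = int(pct)
        out[name] = {
            "numerator": num,
            "denominator": den,
            "fraction": frac,
            "percent": pct,
            "display": f"{num}/{den} = {pct}%",
        }
    return out


def snp_density(n_polymorphic: int, n_sites: float) -> float:
    """Fraction of examined sites that are polymorphic.

    The method's reach is bounded by this density: only targets within a
    read length of a heterozygous SNP can be anchored.  Report with
    ``round(100 * snp_density(...), 1)`` to display as a one-decimal
    percentage.
    """
    if n_sites <= 0:
        raise ValueError("n_sites must be > 0")
    if n_polymorphic < 0:
        raise ValueError("n_polymorphic must be >= 0")
    return n_polymorphic / n_sites
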