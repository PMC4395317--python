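"""Detecting mutation patterns incompatible with clonal tumor growth.

Under the clonal growth model a tumor descends by mitotic division from
one founder cell, so two mutations that arise in *different* lineages can
never co-occur in one cell (absent recurrent mutation or cell fusion).
With confirmed wild-types available, the violation is directly
observable: a cell mutant at site A but confirmed wild-type at B, a
second cell wild-type at A but mutant at B — proving the two mutations
arose in disjoint lineages — and a third cell carrying both.  Because
wild-type status is certified by linked SNP anchors, loss of
heterozygosity cannot mimic this pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .types import IncompatibleCase, parse_site_label

__all__ = ["find_incompatible_cases", "check_clonal_consistency", "ClonalReport"]


def find_incompatible_cases(matrix: pd.DataFrame) -> list[IncompatibleCase]:
    """Enumerate every clonal-model violation in a ternary matrix.

    For each unordered site pair {a, b} (orientation fixed by matrix
    column order: site_a precedes site_b) the output lists all cell
    triples (x, y, z) with x coded (a=1, b=-1), y coded (a=-1, b=1) and
    z coded (a=1, b=1).  The three cells are necessarily distinct.  The
    list is sorted by (site_a, site_b, cell_x, cell_y, cell_z) in matrix
    order and contains each case exactly once.
    """
    cases: list[IncompatibleCase] = []
    cols = list(matrix.columns)
    for i, a in enumerate(cols):
        ca = matrix[a]
        for b in cols[i + 1 :]:
            cb = matrix[b]
            xs = matrix.index[(ca == 1) & (cb == -1)]
            ys = matrix.index[(ca == -1) & (cb == 1)]
            zs = matrix.index[(ca == 1) & (cb == 1)]
            for x in xs:
                for y in ys:
                    for z in zs:
                        cases.append(IncompatibleCase(a, b, x, y, z))
    return cases


@dataclass
class ClonalReport:
    """Summary of a clonal-consistency scan."""

    cases: list[IncompatibleCase]
    n_site_pairs: int
    witnesses_per_pair: dict[tuple[str, str], int]
    linked_site_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def consistent(self) -> bool:
        return not self.cases

    @property
    def verdict(self) -> str:
        if self.consistent:
            return "consistent with clonal model"
        return (
            f"{self.n_site_pairs} site pair(s) incompatible with the "
            f"clonal model ({len(self.cases)} witness triple(s))"
        )


def check_clonal_consistency(
    matrix: pd.DataFrame, read_length: Optional[int] = 90
) -> ClonalReport:
    """Scan a matrix and summarise the clonal-model violations.

    Site pairs on the same chromosome within ``read_length`` bp of each
    other are additionally flagged (they could share a single amplicon
    and hence an artifact) but are not suppressed.
    """
    cases = find_incompatible_cases(matrix)
    per_pair: dict[tuple[str, str], int] = {}
    for c in cases:
        per_pair[(c.site_a, c.site_b)] = per_pair.get((c.site_a, c.site_b), 0) + 1

    linked: list[tuple[str, str]] = []
    if read_length is not None:
        for a, b in per_pair:
            try:
                ca, pa, _, _ = parse_site_label(a)
                cb, pb, _, _ = parse_site_label(b)
            except ValueError:
                continue
            if ca == cb and abs(pa - pb) < read_length:
                linked.append((a, b))
    return ClonalReport(cases, len(per_pair), per_pair, linked)
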