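"""The ternary cells x mutation-sites genotype matrix.

Entries follow the confirmed-genotype coding: 1 = confirmed mutant,
-1 = confirmed wild-type (an anchor SNP proved both haplotypes
amplified), 0 = undefined (no data, or absence that could be dropout),
NA = not applicable (the site belongs to a different dataset's panel).
The distinction between 0 and NA matters: 0 is a cell that *could* have
been genotyped at a site from its own panel, NA is a site that was never
part of that cell's experiment.
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .io_formats import read_matrix, write_matrix  # re-exported for convenience

__all__ = [
    "build_matrix",
    "count_codes",
    "load_confirmed_genotypes",
    "read_matrix",
    "write_matrix",
]


def build_matrix(
    entries: Iterable[tuple[str, str, int]],
    cells: Sequence[str],
    sites: Sequence[str],
    cell_panel: Optional[Mapping[str, str]] = None,
    site_panel: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Assemble the ternary matrix from (cell, site_label, code) triples.

    Unlisted (cell, site) pairs default to 0 when the site belongs to the
    cell's own panel (undefined genotype) and to NA when panels are given
    and differ (genotype not applicable).  Conflicting codes for one
    (cell, site) raise.
    """
    m = pd.DataFrame(index=list(cells), columns=list(sites), dtype="Int64")
    m.index.name = "cell"
    if cell_panel is not None and site_panel is not None:
        for cell in m.index:
            for site in m.columns:
                same = cell_panel.get(cell) == site_panel.get(site)
                m.loc[cell, site] = 0 if same else pd.NA
    else:
        m.loc[:, :] = 0

    seen: dict[tuple[str, str], int] = {}
    for cell, site, code in entries:
        if cell not in m.index:
            raise KeyError(f"unknown cell {cell!r}")
        if site not in m.columns:
            raise KeyError(f"unknown site {site!r}")
        if code not in (1, -1, 0):
            raise ValueError(f"invalid code {code!r} for ({cell}, {site})")
        key = (cell, site)
        if key in seen and seen[key] != code:
            raise ValueError(
                f"conflicting codes for ({cell}, {site}): {seen[key]} vs {code}"
            )
        seen[key] = code
        m.loc[cell, site] = code
    return m


def count_codes(
    matrix: pd.DataFrame, code: int, cell_subset: Optional[Iterable[str]] = None
) -> int:
    """Exact count of entries equal to ``code`` over a subset of cells."""
    if cell_subset is None:
        sub = matrix
    else:
        subset = list(cell_subset)
        unknown = [c for c in subset if c not in matrix.index]
        if unknown:
            raise KeyError(f"unknown cell ids: {unknown}")
        sub = matrix.loc[subset]
    return int((sub == code).sum().sum())


def load_confirmed_genotypes() -> pd.DataFrame:
    """The packaged confirmed-genotype matrix for the 80 MN ('LC-') and
    17 kidney-tumor ('RC-') cells over 18 mutation sites."""
    ref = resources.files("snpanchor.data") / "confirmed_genotypes.tsv"
    with resources.as_file(ref) as path:
        return read_matrix(path)
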