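"""Readers and writers for the external formats the toolkit touches.

Supported formats (all plain text):

* the 6-column samtools-mpileup dialect restricted to SNVs
  (chrom, pos, ref, depth, base string, quality string);
* a minimal VCF 4.x subset carrying QUAL, FS, QD, GQ, DP, GT for
  single-base REF/ALT records;
* BED3 region files (0-based half-open);
* the ternary genotype-matrix TSV (codes 1 / -1 / 0 / NA).

No science lives here: parsing errors are hard errors, and every reader
has a writer that round-trips.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .types import BASES, GenomicSite, PileupColumn, Region, VariantRecord

log = logging.getLogger(__name__)

_INDEL_RE = re.compile(r"[+-]\d")
_VALID_GT = {"0/0", "0/1", "1/0", "1/1", "./."}
MATRIX_CODES = {1, -1, 0}


class FormatError(ValueError):
    """A malformed input file."""


def _sample_id_from(path: str | Path) -> str:
    return Path(path).stem


# ---------------------------------------------------------------------------
# pileup


def _decode_base_string(bases: str, ref: str, line_no: int) -> list[str]:
    """Expand an mpileup base string into upper-case bases.

    '^X' (read start + mapping quality char) and '$' (read end) markers are
    stripped; '.'/',' resolve to the reference base.  Indel tokens are a
    hard error -- this dialect is SNVs only.
    """
    if _INDEL_RE.search(bases):
        raise FormatError(f"line {line_no}: indel token in base string {bases!r}")
    out: list[str] = []
    i = 0
    while i < len(bases):
        c = bases[i]
        if c == "^":
            i += 2  # skip the mapping-quality character that follows
            continue
        if c == "$":
            i += 1
            continue
        if c in ".,":
            out.append(ref)
        elif c.upper() in BASES:
            out.append(c.upper())
        else:
            raise FormatError(f"line {line_no}: unsupported pileup symbol {c!r}")
        i += 1
    return out


def phred_to_error(q: int) -> float:
    """e = 10**(-Q/10)."""
    return 10.0 ** (-q / 10.0)


def error_to_phred(e: float) -> int:
    """Nearest integer Phred score for an error probability."""
    if e <= 0.0:
        return 93  # highest encodable quality ('~')
    return round(-10.0 * math.log10(e))


def read_pileup(
    path: str | Path,
    sample_id: str | None = None,
    default_mapq: int = 255,
) -> Iterator[tuple[str, PileupColumn]]:
    """Stream (sample_id, PileupColumn) from a 6-column pileup file.

    The 6-column dialect carries no per-read mapping quality, so every
    observation gets ``default_mapq`` (255 = unavailable, as in SAM).
    """
    sid = sample_id or _sample_id_from(path)
    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated toy files
                fields = line.split()
            if len(fields) != 6:
                raise FormatError(
                    f"line {line_no}: expected 6 columns, got {len(fields)}"
                )
            chrom, pos_s, ref, depth_s, bases, quals = fields
            ref = ref.upper()
            site = GenomicSite(chrom, int(pos_s), ref)
            depth = int(depth_s)
            if depth == 0:
                # samtools prints '*' placeholders for empty columns
                yield sid, PileupColumn(site, [])
                continue
            decoded = _decode_base_string(bases, ref, line_no)
            if len(decoded) != depth or len(quals) != depth:
                raise FormatError(
                    f"line {line_no}: depth {depth} disagrees with "
                    f"{len(decoded)} bases / {len(quals)} qualities"
                )
            obs = [
                (b, phred_to_error(ord(q) - 33), default_mapq)
                for b, q in zip(decoded, quals)
            ]
            yield sid, PileupColumn(site, obs)


def write_pileup(columns: Iterable[PileupColumn], path: str | Path) -> None:
    """Write pileup columns in the 6-column dialect (inverse of
    :func:`read_pileup`; strand information is not represented)."""
    with open(path, "w") as fh:
        for col in columns:
            ref = col.site.ref
            if not col.observations:
                fh.write(f"{col.site.chrom}\t{col.site.pos}\t{ref}\t0\t*\t*\n")
                continue
            bases = "".join("." if b == ref else b for b, _, _ in col.observations)
            quals = "".join(chr(error_to_phred(e) + 33) for _, e, _ in col.observations)
            fh.write(
                f"{col.site.chrom}\t{col.site.pos}\t{ref}\t"
                f"{col.depth}\t{bases}\t{quals}\n"
            )


# ---------------------------------------------------------------------------
# VCF subset


@dataclass
class VcfReadResult:
    sample_id: str
    records: list[VariantRecord]
    n_skipped: int


def _parse_info(info: str) -> dict[str, str]:
    out: dict[str, str] = {}
    if info in (".", ""):
        return out
    for item in info.split(";"):
        if "=" in item:
            k, _, v = item.partition("=")
            out[k] = v
        else:
            out[item] = ""
    return out


def read_vcf_min(path: str | Path, sample_id: str | None = None) -> VcfReadResult:
    """Read the SNV subset of a VCF 4.x file.

    QUAL comes from column 6, FS and QD from INFO, and GQ/DP/GT from the
    first sample's FORMAT fields.  Multi-allelic and indel rows are
    skipped and counted.  GT codes outside {0/0, 0/1, 1/0, 1/1, ./.} are
    rejected.
    """
    records: list[VariantRecord] = []
    n_skipped = 0
    header_seen = False
    sid = sample_id or _sample_id_from(path)
    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                header_seen = True
                cols = line.split("\t")
                if sample_id is None and len(cols) >= 10:
                    sid = cols[9]
                continue
            if not header_seen:
                raise FormatError("missing #CHROM header line")
            fields = line.split("\t")
            if len(fields) < 8:
                raise FormatError(f"line {line_no}: expected >= 8 VCF columns")
            chrom, pos_s, _id, ref, alt = fields[:5]
            if len(ref) != 1 or len(alt) != 1 or "," in alt or alt == ".":
                n_skipped += 1
                continue
            qual = None if fields[5] == "." else float(fields[5])
            info = _parse_info(fields[7])
            fs = float(info["FS"]) if "FS" in info else None
            qd = float(info["QD"]) if "QD" in info else None
            gq = dp = gt = None
            if len(fields) >= 10:
                fmt_keys = fields[8].split(":")
                fmt_vals = fields[9].split(":")
                fmt = dict(zip(fmt_keys, fmt_vals))
                gt = fmt.get("GT")
                if gt is not None:
                    gt = gt.replace("|", "/")
                    if gt not in _VALID_GT:
                        raise FormatError(f"line {line_no}: unsupported GT {gt!r}")
                if fmt.get("GQ", ".") != ".":
                    gq = float(fmt["GQ"])
                if fmt.get("DP", ".") != ".":
                    dp = int(fmt["DP"])
            records.append(
                VariantRecord(
                    site=GenomicSite(chrom, int(pos_s), ref.upper()),
                    alt=alt.upper(),
                    qual=qual,
                    fs=fs,
                    qd=qd,
                    gq=gq,
                    dp=dp,
                    gt=gt,
                )
            )
    if n_skipped:
        log.info("read_vcf_min(%s): skipped %d non-SNV rows", path, n_skipped)
    return VcfReadResult(sid, records, n_skipped)


def write_vcf_min(
    records: Iterable[VariantRecord], path: str | Path, sample_id: str = "SAMPLE"
) -> None:
    """Write records in the minimal VCF subset read_vcf_min understands."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample_id}\n"
        )
        for r in records:
            info_parts = []
            if r.fs is not None:
                info_parts.append(f"FS={r.fs:g}")
            if r.qd is not None:
                info_parts.append(f"QD={r.qd:g}")
            info = ";".join(info_parts) or "."
            qual = "." if r.qual is None else f"{r.qual:g}"
            gt = r.gt or "./."
            gq = "." if r.gq is None else f"{r.gq:g}"
            dp = "." if r.dp is None else str(r.dp)
            fh.write(
                f"{r.site.chrom}\t{r.site.pos}\t.\t{r.site.ref}\t{r.alt}\t"
                f"{qual}\t.\t{info}\tGT:GQ:DP\t{gt}:{gq}:{dp}\n"
            )


# ---------------------------------------------------------------------------
# BED3 regions


def read_regions(path: str | Path) -> list[Region]:
    """Read a BED3 file into a region list (0-based half-open)."""
    regions: list[Region] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {line_no}: expected >= 3 BED columns")
            regions.append(Region(fields[0], int(fields[1]), int(fields[2])))
    return regions


def write_regions(regions: Iterable[Region], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")


# ---------------------------------------------------------------------------
# genotype matrix TSV


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a ternary genotype matrix TSV.

    Column 1 holds cell IDs; the header row holds site labels in
    'Chr21_37664570:G->T' style; entries are 1 / -1 / 0 / NA.  Returned as
    a cells x sites DataFrame with pandas nullable-integer dtype (NA kept
    as missing).
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False
    )
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate cell IDs: {dupes}")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype="Int64")
    for col in df.columns:
        vals = []
        for cell, v in df[col].items():
            if v == "NA":
                vals.append(pd.NA)
            else:
                try:
                    code = int(v)
                except ValueError:
                    raise FormatError(
                        f"unknown matrix code {v!r} at ({cell}, {col})"
                    ) from None
                if code not in MATRIX_CODES:
                    raise FormatError(f"unknown matrix code {v!r} at ({cell}, {col})")
                vals.append(code)
        out[col] = pd.array(vals, dtype="Int64")
    out.index.name = df.index.name or "cell"
    return out


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a ternary genotype matrix as TSV with literal 'NA' entries."""
    out = matrix.astype(object).where(matrix.notna(), "NA")
    out.to_csv(path, sep="\t", index_label=matrix.index.name or "cell")
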