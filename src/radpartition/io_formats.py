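"""Readers and writers for the external formats the toolkit touches:
FASTQ (with Phred-based quality masking), the pipe-delimited multi-locus
``.loci`` alignment dialect, relaxed Phylip supermatrices, Newick trees
and 12-column tabular homology-hit files.

Downstream modules consume only the in-memory types defined here and in
:mod:`radpartition.locus_matrix`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import pandas as pd
from Bio import SeqIO

from .locus_matrix import Locus

__all__ = [
    "ReadSet",
    "HitTable",
    "FormatError",
    "read_fastq",
    "mask_low_quality_reads",
    "parse_loci_file",
    "write_loci_file",
    "read_phylip",
    "write_phylip",
    "parse_hit_table",
]


class FormatError(ValueError):
    pass


@dataclass
class ReadSet:
    """Equal-length reads for one individual, with per-base Phred scores.

    Masked positions are 'N'.  ``qualities`` may be empty (e.g. after
    masking, when scores are no longer meaningful) or aligned 1:1 with
    ``reads``.
    """

    individual_id: str
    reads: List[str]
    qualities: List[List[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.reads}
        if len(lengths) > 1:
            raise FormatError(
                f"reads for {self.individual_id} have unequal lengths {sorted(lengths)}"
            )
        if self.qualities:
            for i, (r, q) in enumerate(zip(self.reads, self.qualities)):
                if len(r) != len(q):
                    raise FormatError(
                        f"read/quality length mismatch at record {i} of {self.individual_id}"
                    )

    def __len__(self) -> int:
        return len(self.reads)


def read_fastq(
    path,
    individual_id: str,
    phred_offset: int = 33,
    trim_prefix: int = 0,
) -> ReadSet:
    """Load a FASTQ file into a :class:`ReadSet`.

    ``trim_prefix`` removes a fixed-width prefix from every read (barcode
    plus retained restriction-recognition bases); ``phred_offset`` 33 is
    Sanger/Illumina 1.8+, 64 the Illumina 1.3+ variant.
    """
    reads: List[str] = []
    quals: List[List[int]] = []
    offset_shift = phred_offset - 33  # Biopython decodes at offset 33
    for rec in SeqIO.parse(str(path), "fastq"):
        seq = str(rec.seq).upper()[trim_prefix:]
        q = [s - offset_shift for s in rec.letter_annotations["phred_quality"]][trim_prefix:]
        reads.append(seq)
        quals.append(q)
    return ReadSet(individual_id=individual_id, reads=reads, qualities=quals)


def mask_low_quality_reads(
    reads: ReadSet, phred_min: int = 20, max_n_fraction: float = 0.05
) -> ReadSet:
    """Replace every base below ``phred_min`` with 'N' and drop reads
    whose post-masking N fraction strictly exceeds ``max_n_fraction``;
    survivor order is preserved.  Idempotent."""
    if reads.qualities and len(reads.qualities) != len(reads.reads):
        raise FormatError(f"quality rows do not match reads for {reads.individual_id}")
    out_reads: List[str] = []
    out_quals: List[List[int]] = []
    quals = reads.qualities or [[phred_min] * len(r) for r in reads.reads]
    for i, (r, q) in enumerate(zip(reads.reads, quals)):
        if len(r) != len(q):
            raise FormatError(
                f"read/quality length mismatch at record {i} of {reads.individual_id}"
            )
        masked = "".join("N" if s < phred_min else b for b, s in zip(r, q))
        if len(masked) and masked.count("N") / len(masked) > max_n_fraction:
            continue
        out_reads.append(masked)
        out_quals.append(list(q))
    return ReadSet(individual_id=reads.individual_id, reads=out_reads, qualities=out_quals)


# ---------------------------------------------------------------------
# .loci multi-locus alignments (pipe-delimited dialect)
# ---------------------------------------------------------------------

_LOCI_SEP = re.compile(r"^//.*\|(\d+)\|?\s*$")


def parse_loci_file(path) -> List[Locus]:
    """Parse a ``.loci``-style file: taxon-labelled sequence blocks
    separated by ``//...|index|`` delimiter lines."""
    loci: List[Locus] = []
    rows: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            m = _LOCI_SEP.match(line)
            if m:
                idx = m.group(1)
                if rows:
                    lengths = {len(s) for s in rows.values()}
                    if len(lengths) > 1:
                        raise FormatError(
                            f"locus {idx}: unequal sequence lengths {sorted(lengths)}"
                        )
                    loci.append(Locus(locus_id=f"locus_{int(idx):06d}", rows=dict(rows)))
                rows = {}
                continue
            parts = line.split()
            if len(parts) != 2:
                raise FormatError(f"line {lineno}: expected 'taxon sequence', got {line!r}")
            name = parts[0].lstrip(">")
            if name in rows:
                raise FormatError(f"line {lineno}: duplicate taxon {name!r} within a locus")
            rows[name] = parts[1].upper()
    if rows:
        raise FormatError("file ends inside a locus block (missing '//...|n|' delimiter)")
    return loci


def write_loci_file(path, loci: Sequence[Locus]) -> None:
    with open(path, "w") as fh:
        for i, locus in enumerate(loci, 1):
            width = max((len(n) for n in locus.rows), default=0) + 4
            for name, seq in locus.rows.items():
                fh.write(f">{name:<{width}}{seq}\n")
            fh.write("//" + " " * max(width - 2, 1) + f"|{i}|\n")


# ---------------------------------------------------------------------
# relaxed Phylip
# ---------------------------------------------------------------------

def read_phylip(path) -> Dict[str, str]:
    """Relaxed sequential Phylip: header 'ntaxa nchar', then one
    'name sequence' row per taxon (names up to 250 chars, whitespace
    delimited).  Returns an ordered taxon -> sequence mapping."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2 or not all(p.isdigit() for p in header):
            raise FormatError(f"bad phylip header: {header!r}")
        n_taxa, n_chars = int(header[0]), int(header[1])
        matrix: Dict[str, str] = {}
        for line in fh:
            if not line.strip():
                continue
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise FormatError(f"bad phylip row: {line!r}")
            name, seq = parts[0], parts[1].replace(" ", "").strip().upper()
            if name in matrix:
                raise FormatError(f"duplicate taxon {name!r}")
            if len(seq) != n_chars:
                raise FormatError(
                    f"taxon {name!r}: {len(seq)} characters, header says {n_chars}"
                )
            matrix[name] = seq
    if len(matrix) != n_taxa:
        raise FormatError(f"header claims {n_taxa} taxa, found {len(matrix)}")
    return matrix


def write_phylip(path, matrix: Dict[str, str]) -> None:
    if not matrix:
        raise FormatError("empty matrix")
    n_chars = {len(s) for s in matrix.values()}
    if len(n_chars) != 1:
        raise FormatError("unequal sequence lengths")
    with open(path, "w") as fh:
        fh.write(f"{len(matrix)} {n_chars.pop()}\n")
        for name, seq in matrix.items():
            fh.write(f"{name} {seq}\n")


# ---------------------------------------------------------------------
# homology hit tables (12-column BLAST-tabular dialect)
# ---------------------------------------------------------------------

@dataclass
class HitTable:
    """Locus -> expressed-sequence-target hits with E-values; a locus may
    carry any number of hits."""

    rows: pd.DataFrame  # columns: locus_id, target_id, evalue, database_tag

    def __len__(self) -> int:
        return len(self.rows)

    def hit_counts(self) -> pd.Series:
        return self.rows.groupby("locus_id").size()

    def loci_with_hits(self) -> set:
        return set(self.rows["locus_id"])


def parse_hit_table(path, max_evalue: float = float("inf"),
                    database_tag: str = "") -> HitTable:
    """Parse a 12-column tab-separated hit file (query, subject, pident,
    length, mismatch, gapopen, qstart, qend, sstart, send, evalue,
    bitscore); only rows with evalue strictly below ``max_evalue`` are
    retained."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 12:
                raise FormatError(f"line {lineno}: expected 12 columns, got {len(parts)}")
            try:
                evalue = float(parts[10])
            except ValueError:
                raise FormatError(f"line {lineno}: non-numeric E-value {parts[10]!r}")
            if evalue < 0:
                raise FormatError(f"line {lineno}: negative E-value {evalue}")
            if evalue < max_evalue:
                records.append((parts[0], parts[1], evalue, database_tag))
    df = pd.DataFrame(records, columns=["locus_id", "target_id", "evalue", "database_tag"])
    return HitTable(rows=df)
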