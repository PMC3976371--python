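"""Across-individual locus assembly: cluster per-individual consensus
sequences into loci, apply among-individual paralog/variability filters,
concatenate surviving loci into a supermatrix, and summarize locus
sharing (presence-absence, Jaccard distances, technical-replicate
overlap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "Locus",
    "SupermatrixBundle",
    "PresenceAbsence",
    "cluster_across_individuals",
    "apply_locus_filters",
    "concatenate",
    "split_by_spans",
    "jaccard_matrix",
    "replicate_overlap_report",
    "write_partition_file",
]

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-")

# IUPAC base sets for compatibility-aware identity
_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"}, "H": {"A", "C", "T"},
    "V": {"A", "C", "G"}, "N": set(), "-": set(), "?": set(),
}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Locus:
    """One across-individual locus: an ungapped short alignment whose rows
    are per-individual consensus sequences (IUPAC codes allowed)."""

    locus_id: str
    rows: Dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.locus_id}: unequal row lengths {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def n_individuals(self) -> int:
        return len(self.rows)

    @property
    def individuals(self) -> List[str]:
        return list(self.rows)

    def n_variable_sites(self) -> int:
        from .phylo_engine import classify_characters

        return classify_characters(self.rows).n_variable

    def n_pi_sites(self) -> int:
        from .phylo_engine import classify_characters

        return classify_characters(self.rows).n_parsimony_informative


def sequence_identity(a: str, b: str) -> float:
    """Un-gapped identity between two equal-length sequences: compatible
    positions (intersecting IUPAC base sets) over positions where both
    carry information.  Positions with 'N'/'-' on either side are
    excluded from numerator and denominator."""
    if len(a) != len(b):
        raise ValueError("sequences have unequal lengths")
    match = compared = 0
    for x, y in zip(a, b):
        sx, sy = _SETS.get(x, set()), _SETS.get(y, set())
        if not sx or not sy:
            continue
        compared += 1
        if sx & sy:
            match += 1
    return match / compared if compared else 0.0


def cluster_across_individuals(
    consensus: Mapping[str, Sequence[str]],
    similarity: float = 0.88,
    min_individuals: int = 4,
    check_revcomp: bool = True,
) -> List[Locus]:
    """Greedy centroid clustering of consensus sequences across
    individuals into loci.

    Sequences (all equal length) are sorted by multiplicity then
    lexicographically; each joins the first centroid with identity >=
    ``similarity`` (reverse complement also tested), else founds a new
    centroid.  Clusters receiving two sequences from the same individual
    are discarded as putative paralogs; clusters with fewer than
    ``min_individuals`` distinct individuals are discarded.  Locus ids
    are stable and deterministic.
    """
    entries: List[Tuple[str, str]] = []  # (individual, sequence)
    for ind, seqs in sorted(consensus.items()):
        for s in seqs:
            entries.append((ind, s.upper()))
    if not entries:
        return []
    counts: Dict[str, int] = {}
    for _, s in entries:
        counts[s] = counts.get(s, 0) + 1
    entries.sort(key=lambda e: (-counts[e[1]], e[1], e[0]))

    centroids: List[str] = []
    members: List[List[Tuple[str, str]]] = []
    for ind, seq in entries:
        placed = False
        for ci, cent in enumerate(centroids):
            if len(seq) != len(cent):
                continue
            if sequence_identity(seq, cent) >= similarity or (
                check_revcomp and sequence_identity(revcomp(seq), cent) >= similarity
            ):
                # store in centroid orientation
                if sequence_identity(seq, cent) < similarity:
                    seq = revcomp(seq)
                members[ci].append((ind, seq))
                placed = True
                break
        if not placed:
            centroids.append(seq)
            members.append([(ind, seq)])

    loci: List[Locus] = []
    idx = 0
    for cluster in members:
        inds = [ind for ind, _ in cluster]
        if len(inds) != len(set(inds)):
            continue  # >=2 sequences from one individual: paralog signal
        if len(set(inds)) < min_individuals:
            continue
        idx += 1
        loci.append(
            Locus(
                locus_id=f"locus_{idx:06d}",
                rows={ind: seq for ind, seq in sorted(cluster)},
            )
        )
    return loci


def apply_locus_filters(
    locus: Locus,
    max_shared_het_individuals: int = 2,
    max_variable_sites: int = 10,
) -> Tuple[bool, Optional[str]]:
    """Among-individual paralog filters: discard a locus if any column is
    heterozygous (a two-fold IUPAC call) in more than
    ``max_shared_het_individuals`` individuals, or if it has more than
    ``max_variable_sites`` variable columns.  Returns (keep, reason)."""
    het_codes = set("RYSWKM")
    seqs = list(locus.rows.values())
    for col in range(locus.length):
        n_het = sum(1 for s in seqs if s[col] in het_codes)
        if n_het > max_shared_het_individuals:
            return False, "shared_het"
    if locus.n_variable_sites() > max_variable_sites:
        return False, "too_variable"
    return True, None


@dataclass
class SupermatrixBundle:
    """Concatenated supermatrix with per-locus column spans.

    ``locus_spans`` are half-open 0-based (locus_id, start, end) column
    intervals tiling the matrix; absent (taxon, locus) cells are 'N'.
    """

    matrix: Dict[str, str]
    locus_spans: List[Tuple[str, int, int]]
    completeness: float
    mean_individuals_per_locus: float
    all_n_columns: List[int] = field(default_factory=list)

    @property
    def n_taxa(self) -> int:
        return len(self.matrix)

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.matrix.values()))) if self.matrix else 0


def concatenate(loci: Sequence[Locus], taxa: Sequence[str]) -> SupermatrixBundle:
    """Lay loci end-to-end in ascending locus_id order over ``taxa``,
    filling missing cells with 'N'; records completeness, the mean number
    of individuals per locus, and columns that are all-N across taxa."""
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon label")
    extra = {ind for l in loci for ind in l.rows} - set(taxa)
    if extra:
        raise ValueError(f"loci contain individuals not in taxa: {sorted(extra)}")
    ordered = sorted(loci, key=lambda l: l.locus_id)
    parts: Dict[str, List[str]] = {t: [] for t in taxa}
    spans: List[Tuple[str, int, int]] = []
    pos = 0
    present_cells = 0
    for locus in ordered:
        L = locus.length
        spans.append((locus.locus_id, pos, pos + L))
        pos += L
        for t in taxa:
            if t in locus.rows:
                parts[t].append(locus.rows[t])
                present_cells += 1
            else:
                parts[t].append("N" * L)
    matrix = {t: "".join(parts[t]) for t in taxa}
    if ordered:
        completeness = present_cells / (len(taxa) * len(ordered))
        mean_ind = float(np.mean([l.n_individuals for l in ordered]))
    else:
        warnings.warn("no loci: completeness reported as 1.0")
        completeness = 1.0
        mean_ind = 0.0
    all_n = []
    if ordered and taxa:
        arr = np.array([list(matrix[t]) for t in taxa])
        mask = np.isin(arr, ["N", "-"]).all(axis=0)
        all_n = list(np.nonzero(mask)[0])
    return SupermatrixBundle(
        matrix=matrix,
        locus_spans=spans,
        completeness=completeness,
        mean_individuals_per_locus=mean_ind,
        all_n_columns=all_n,
    )


def split_by_spans(bundle: SupermatrixBundle) -> List[Locus]:
    """Invert :func:`concatenate`: recover one Locus per span, dropping
    the taxa that are entirely 'N' within the span."""
    out = []
    for locus_id, start, end in bundle.locus_spans:
        rows = {}
        for taxon, seq in bundle.matrix.items():
            piece = seq[start:end]
            if set(piece) != {"N"}:
                rows[taxon] = piece
        out.append(Locus(locus_id=locus_id, rows=rows))
    return out


@dataclass
class PresenceAbsence:
    """Binary taxa x loci recovery matrix (1 = locus present)."""

    table: pd.DataFrame

    @classmethod
    def from_loci(cls, loci: Sequence[Locus], taxa: Sequence[str]) -> "PresenceAbsence":
        data = {
            l.locus_id: [1 if t in l.rows else 0 for t in taxa] for l in loci
        }
        return cls(table=pd.DataFrame(data, index=list(taxa), dtype=int))

    @property
    def taxa(self) -> List[str]:
        return list(self.table.index)


def jaccard_matrix(pa: PresenceAbsence) -> pd.DataFrame:
    """Pairwise Jaccard distances on locus presence profiles:
    d(i, j) = 1 - |shared| / |union|; pairs with an empty union get
    distance 1 with a warning."""
    taxa = pa.taxa
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    M = pa.table.values.astype(bool)
    n = len(taxa)
    d = np.zeros((n, n))
    empty_rows = [taxa[i] for i in range(n) if not M[i].any()]
    if empty_rows:
        warnings.warn(f"taxa with zero loci: {empty_rows}; their distances set to 1")
    for i in range(n):
        for j in range(i + 1, n):
            union = (M[i] | M[j]).sum()
            if union == 0:
                warnings.warn(f"{taxa[i]} and {taxa[j]} share no scored loci")
                d[i, j] = d[j, i] = 1.0
            else:
                shared = (M[i] & M[j]).sum()
                d[i, j] = d[j, i] = 1.0 - shared / union
    return pd.DataFrame(d, index=taxa, columns=taxa)


def replicate_overlap_report(
    pa: PresenceAbsence, pairs: Sequence[Tuple[str, str]]
) -> pd.DataFrame:
    """Technical-replicate locus-sharing report: per (A, B) pair the locus
    counts, the relative increase (B-A)/A, shared (intersection), total
    (union), and overlap = shared/total."""
    rows = []
    for a, b in pairs:
        for t in (a, b):
            if t not in pa.table.index:
                raise KeyError(f"unknown taxon {t!r}")
        va = pa.table.loc[a].values.astype(bool)
        vb = pa.table.loc[b].values.astype(bool)
        loci_a, loci_b = int(va.sum()), int(vb.sum())
        shared = int((va & vb).sum())
        total = int((va | vb).sum())
        rows.append({
            "taxon_a": a,
            "taxon_b": b,
            "loci_a": loci_a,
            "loci_b": loci_b,
            "increase": (loci_b - loci_a) / loci_a if loci_a else float("nan"),
            "shared": shared,
            "total": total,
            "overlap": shared / total if total else float("nan"),
        })
    return pd.DataFrame(rows)


def write_partition_file(path, bundle: SupermatrixBundle) -> None:
    """RAxML-style per-locus partition file ('DNA, name = start-end',
    1-based inclusive)."""
    with open(path, "w") as fh:
        for locus_id, start, end in bundle.locus_spans:
            fh.write(f"DNA, {locus_id} = {start + 1}-{end}\n")
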