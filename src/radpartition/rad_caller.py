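"""Within-individual RAD locus calling: greedy clustering of reads into
stacks, joint maximum-likelihood estimation of the per-base sequencing
error rate and per-site heterozygosity from stack base counts, binomial
posterior consensus calling, and paralog flagging.

The error/heterozygosity model treats every stack column as a mixture:
with probability 1-H the site is homozygous (reads match one true base,
errors uniform over the three other bases at rate eps), with probability
H it is an equal-dosage two-allele heterozygote (each read drawn from
either allele with probability 1/2, then subjected to the same error
process).  Both parameters are shared across all columns of all stacks
and maximized jointly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import List, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import minimize
from scipy.special import xlogy

from .io_formats import ReadSet
from .locus_matrix import Locus, revcomp, sequence_identity

__all__ = [
    "CallerConfig",
    "ReadStack",
    "ErrorHetEstimate",
    "ConsensusSequence",
    "cluster_within_individual",
    "estimate_error_het",
    "call_consensus",
    "consensus_of_alignment",
]

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}
_PAIR_CODE = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}
_HET_CODES = set(_PAIR_CODE.values())
_PAIRS = [frozenset(p) for p in ("AC", "AG", "AT", "CG", "CT", "GT")]


@dataclass
class CallerConfig:
    """Stack-calling parameters (defaults follow common RAD practice:
    0.88 clustering identity, stack depth >= 6, at most 3 heterozygous
    sites and 2 haplotypes per locus within an individual, 95% posterior
    to call a base)."""

    similarity: float = 0.88
    min_depth: int = 6
    max_het_sites: int = 3
    max_haplotypes: int = 2
    posterior_threshold: float = 0.95
    check_revcomp: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.similarity <= 1):
            raise ValueError("similarity must be in (0, 1]")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


@dataclass
class ReadStack:
    """Reads from one individual clustered at high identity, presumed to
    derive from a single locus; per-column A/C/G/T counts exclude N."""

    individual_id: str
    reads: List[str]

    def __post_init__(self) -> None:
        if not self.reads:
            raise ValueError("a stack needs at least one read")
        if len({len(r) for r in self.reads}) != 1:
            raise ValueError("stack reads have unequal lengths")

    @property
    def depth(self) -> int:
        return len(self.reads)

    @property
    def length(self) -> int:
        return len(self.reads[0])

    def base_counts(self) -> np.ndarray:
        """(length, 4) counts of A/C/G/T per column."""
        arr = np.frombuffer("".join(self.reads).encode(), dtype="S1").reshape(
            self.depth, self.length
        )
        out = np.zeros((self.length, 4), dtype=np.int64)
        for b, i in _BASE_IDX.items():
            out[:, i] = (arr == b.encode()).sum(axis=0)
        return out


def cluster_within_individual(reads: ReadSet, cfg: CallerConfig) -> List[ReadStack]:
    """Greedy centroid clustering of an individual's reads into stacks.

    Distinct read sequences are sorted by multiplicity then
    lexicographically; each joins the first centroid with un-gapped
    identity >= ``cfg.similarity`` (its reverse complement is also
    tested when ``cfg.check_revcomp``), else founds a new centroid.
    Stacks below ``cfg.min_depth`` are discarded.  Retained reads end up
    in exactly one stack.
    """
    if not reads.reads:
        return []
    if len({len(r) for r in reads.reads}) != 1:
        raise ValueError("reads have unequal lengths")
    mult = Counter(r.upper() for r in reads.reads)
    ordered = sorted(mult, key=lambda s: (-mult[s], s))
    centroids: List[str] = []
    members: List[List[str]] = []
    for seq in ordered:
        placed = False
        for ci, cent in enumerate(centroids):
            fwd = sequence_identity(seq, cent)
            if fwd >= cfg.similarity:
                members[ci].extend([seq] * mult[seq])
                placed = True
                break
            if cfg.check_revcomp:
                rc = revcomp(seq)
                if sequence_identity(rc, cent) >= cfg.similarity:
                    members[ci].extend([rc] * mult[seq])
                    placed = True
                    break
        if not placed:
            centroids.append(seq)
            members.append([seq] * mult[seq])
    return [
        ReadStack(individual_id=reads.individual_id, reads=m)
        for m in members
        if len(m) >= cfg.min_depth
    ]


@dataclass
class ErrorHetEstimate:
    """Joint MLEs of the sequencing error rate and heterozygosity."""

    epsilon: float
    het: float
    loglik: float
    unstable: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.epsilon < 0.5 and 0 <= self.het < 0.5):
            raise ValueError("estimates out of bounds")
        if not np.isfinite(self.loglik):
            raise ValueError("log-likelihood not finite")


def _column_triples(stacks: Sequence[ReadStack]) -> np.ndarray:
    """(m, 4) array of (n1, n2, n, multiplicity): per-column major count,
    second count and total depth, aggregated over identical triples."""
    triples: Counter = Counter()
    for stack in stacks:
        counts = stack.base_counts()
        for row in counts:
            n = int(row.sum())
            if n == 0:
                continue  # all-N column
            top2 = np.sort(row)[::-1][:2]
            triples[(int(top2[0]), int(top2[1]), n)] += 1
    return np.array([(a, b, c, m) for (a, b, c), m in sorted(triples.items())], dtype=float)


def _mixture_loglik(eps: float, het: float, tr: np.ndarray) -> float:
    n1, n2, n, mult = tr[:, 0], tr[:, 1], tr[:, 2], tr[:, 3]
    lp_homo = xlogy(n1, 1.0 - eps) + xlogy(n - n1, eps / 3.0)
    p_hetbase = (1.0 - 2.0 * eps / 3.0) / 2.0
    lp_het = xlogy(n1 + n2, p_hetbase) + xlogy(n - n1 - n2, eps / 3.0)
    col = np.logaddexp(np.log(1.0 - het) + lp_homo, np.log(het) + lp_het)
    return float(col @ mult)


def estimate_error_het(stacks: Sequence[ReadStack]) -> ErrorHetEstimate:
    """Maximize the shared (eps, H) mixture likelihood over all stack
    columns by bounded 2-D numerical search.

    All-N columns are skipped; with no usable columns this is an error,
    and with fewer than 10 columns the estimate is flagged unstable.
    Boundary estimates are clamped to 1e-9 so downstream posterior
    computations never take log(0).
    """
    tr = _column_triples(stacks)
    if tr.size == 0:
        raise ValueError("no usable (non-N) columns to estimate from")
    n_cols = int(tr[:, 3].sum())

    def neg(x: np.ndarray) -> float:
        return -_mixture_loglik(x[0], x[1], tr)

    best = None
    for start in ((0.01, 0.01), (0.001, 0.05), (0.05, 0.001)):
        res = minimize(
            neg, np.array(start), method="L-BFGS-B",
            bounds=[(1e-9, 0.4999), (1e-9, 0.4999)],
        )
        if best is None or res.fun < best.fun:
            best = res
    eps, het = (max(float(v), 1e-9) for v in best.x)
    return ErrorHetEstimate(
        epsilon=eps, het=het, loglik=-float(best.fun), unstable=n_cols < 10
    )


@dataclass
class ConsensusSequence:
    """Diploid consensus for one stack; heterozygous sites carry two-fold
    IUPAC codes, uncallable sites 'N'."""

    individual_id: str
    sequence: str
    n_het_sites: int
    n_haplotypes: int
    flags: Set[str] = field(default_factory=set)

    @property
    def usable(self) -> bool:
        return not self.flags


def _genotype_posteriors(counts: np.ndarray, eps: float, het: float) -> List[Tuple[str, float]]:
    """Unnormalized posteriors over the 4 homozygote and 6 unordered
    heterozygote genotypes for one column of base counts."""
    n = counts.sum()
    out: List[Tuple[str, float]] = []
    log_eps3 = np.log(eps / 3.0)
    for b in _BASES:
        i = _BASE_IDX[b]
        ll = xlogy(counts[i], 1.0 - eps) + (n - counts[i]) * log_eps3
        out.append((b, np.log((1.0 - het) / 4.0) + ll))
    p_hb = np.log((1.0 - 2.0 * eps / 3.0) / 2.0)
    for pair in _PAIRS:
        k = sum(counts[_BASE_IDX[b]] for b in pair)
        ll = k * p_hb + (n - k) * log_eps3
        out.append((_PAIR_CODE[pair], np.log(het / 6.0) + ll))
    logs = np.array([v for _, v in out])
    post = np.exp(logs - logs.max())
    post /= post.sum()
    return [(g, float(p)) for (g, _), p in zip(out, post)]


def call_consensus(
    stack: ReadStack, est: ErrorHetEstimate, cfg: CallerConfig
) -> ConsensusSequence:
    """Posterior genotype call per column: the argmax genotype is written
    iff its posterior reaches ``cfg.posterior_threshold``, otherwise 'N'.

    Heterozygous columns are phased by read co-occurrence: distinct
    combinations of het-site alleles observed in at least two reads count
    as haplotypes.  Flags mark stacks to exclude downstream:
    ``too_many_hets``, ``too_many_haplotypes``, ``low_depth``.
    """
    eps = max(est.epsilon, 1e-9)
    het = min(max(est.het, 1e-9), 0.4999)
    counts = stack.base_counts()
    seq_chars: List[str] = []
    het_positions: List[int] = []
    for col in range(stack.length):
        c = counts[col]
        if c.sum() == 0:
            seq_chars.append("N")
            continue
        genos = _genotype_posteriors(c, eps, het)
        g, p = max(genos, key=lambda gp: gp[1])
        if p >= cfg.posterior_threshold:
            seq_chars.append(g)
            if g in _HET_CODES:
                het_positions.append(col)
        else:
            seq_chars.append("N")
    sequence = "".join(seq_chars)

    if het_positions:
        combos: Counter = Counter()
        for read in stack.reads:
            alleles = tuple(read[p] for p in het_positions)
            if "N" in alleles:
                continue
            combos[alleles] += 1
        n_hap = sum(1 for v in combos.values() if v >= 2) or 1
    else:
        n_hap = 1

    flags: Set[str] = set()
    if len(het_positions) > cfg.max_het_sites:
        flags.add("too_many_hets")
    if n_hap > cfg.max_haplotypes:
        flags.add("too_many_haplotypes")
    if stack.depth < cfg.min_depth:
        flags.add("low_depth")
    return ConsensusSequence(
        individual_id=stack.individual_id,
        sequence=sequence,
        n_het_sites=len(het_positions),
        n_haplotypes=n_hap,
        flags=flags,
    )


def consensus_of_alignment(locus: Locus) -> str:
    """Across-individual strict consensus: per column the plurality base
    among literal A/C/G/T calls, ties broken alphabetically; columns with
    no resolved base are 'N'."""
    if not locus.rows:
        raise ValueError("empty locus")
    seqs = list(locus.rows.values())
    out = []
    for col in range(locus.length):
        counts = Counter(s[col] for s in seqs if s[col] in _BASE_IDX)
        if not counts:
            out.append("N")
            continue
        best = max(sorted(counts), key=lambda b: counts[b])
        out.append(best)
    return "".join(out)
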