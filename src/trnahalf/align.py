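"""Deterministic seed-based short-read aligner with explicit multiread policies.

Two alignment policies are implemented:

* ``maq_like`` -- candidate placements come from an exact (by default) match
  of the first ``seed_len`` bases of the read, i.e. its high-quality 5' end,
  and are extended end-to-end allowing at most ``max_total_mismatches``
  mismatches overall.
* ``kdiff`` -- the end-to-end k-difference policy: every placement with at
  most ``v`` mismatches anywhere in the read is valid.  Candidates are
  generated by pigeonhole seeding (one of v+1 disjoint chunks must match
  exactly), so the returned set is the complete valid set.

Two reporting policies control what multireads contribute downstream:
``best_one`` emits a single best placement per read (fewest mismatches,
deterministic lexicographic tie-break by default) while ``unique_only``
suppresses any read with more than one valid placement.  ``n_valid`` on
every emitted record is the exact size of the read's valid set, computed by
full enumeration.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

from .reference import revcomp

logger = logging.getLogger(__name__)


class AlignError(ValueError):
    pass


@dataclass(frozen=True)
class AlignPolicy:
    mode: str = "maq_like"  # or "kdiff"
    seed_len: int = 14
    seed_mismatches: int = 0
    max_total_mismatches: int = 2
    v: int = 0  # kdiff mismatch budget

    def __post_init__(self):
        if self.mode not in ("maq_like", "kdiff"):
            raise AlignError(f"unknown alignment mode {self.mode!r}")
        if min(self.seed_mismatches, self.max_total_mismatches, self.v) < 0:
            raise AlignError("mismatch budgets must be >= 0")


@dataclass(frozen=True)
class ReportMode:
    mode: str = "best_one"  # or "unique_only"

    def __post_init__(self):
        if self.mode not in ("best_one", "unique_only"):
            raise AlignError(f"unknown report mode {self.mode!r}")


@dataclass
class Alignment:
    read_id: str
    chrom: str
    start: int  # 0-based
    strand: str
    n_mismatch: int
    n_valid: int = 1
    reported: bool = False

    @property
    def key(self) -> tuple:
        return (self.chrom, self.start, self.strand)


class GenomeIndex:
    """Exact k-mer position index over the forward strand of a genome.

    ``lookup`` reports occurrences on both strands: a '-' strand hit at
    (chrom, start) means the reverse complement of the query k-mer occupies
    genome[start:start+k].  Auxiliary indexes at smaller k are built lazily
    for pigeonhole candidate generation.
    """

    def __init__(self, genome: dict[str, str], seed_len: int = 14):
        if seed_len < 4:
            raise AlignError("seed_len must be >= 4")
        self.genome = genome
        self.seed_len = seed_len
        self._tables: dict[int, dict[str, list[tuple[str, int]]]] = {}
        self.table_for(seed_len)

    def table_for(self, k: int) -> dict[str, list[tuple[str, int]]]:
        if k < 1:
            raise AlignError("k must be >= 1")
        if k not in self._tables:
            table: dict[str, list[tuple[str, int]]] = {}
            for chrom, seq in self.genome.items():
                for i in range(len(seq) - k + 1):
                    table.setdefault(seq[i : i + k], []).append((chrom, i))
            self._tables[k] = table
        return self._tables[k]

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        table = self.table_for(len(kmer))
        hits = [(c, p, "+") for c, p in table.get(kmer, [])]
        rc = revcomp(kmer)
        hits += [(c, p, "-") for c, p in table.get(rc, [])]
        return hits


def build_index(genome: dict[str, str], seed_len: int = 14) -> GenomeIndex:
    return GenomeIndex(genome, seed_len)


def _mismatch_counts(
    window: str, query: str, seed_lo: int, seed_hi: int, total_limit: int
) -> tuple[int, int]:
    """Mismatches of query vs window overall and within window[seed_lo:seed_hi].

    Aborts (returning total > total_limit) as soon as the budget is blown.
    """
    if window == query:
        return 0, 0
    total = seed = 0
    for j, (a, b) in enumerate(zip(window, query)):
        if a != b:
            total += 1
            if seed_lo <= j < seed_hi:
                seed += 1
            if total > total_limit:
                return total, seed
    return total, seed


def _hamming_ball(kmer: str, radius: int):
    """All k-mers within the given Hamming distance (radius 0 -> identity)."""
    yield kmer
    if radius <= 0:
        return
    for positions in itertools.combinations(range(len(kmer)), radius):
        for subs in itertools.product("ACGT", repeat=radius):
            if any(kmer[p] == s for p, s in zip(positions, subs)):
                continue
            s = list(kmer)
            for p, b in zip(positions, subs):
                s[p] = b
            yield "".join(s)


def align_read(
    read_id: str,
    seq: str,
    index: GenomeIndex,
    policy: AlignPolicy,
    genome: dict[str, str] | None = None,
) -> list[Alignment]:
    """Enumerate the complete valid placement set of one read.

    Returns one :class:`Alignment` per valid placement, each stamped with
    ``n_valid`` equal to the set size.  Placements on both strands of a
    palindromic site count separately.
    """
    genome = genome if genome is not None else index.genome
    L = len(seq)
    if policy.mode == "maq_like" and L < policy.seed_len:
        logger.debug("skipping %s: length %d < seed %d", read_id, L, policy.seed_len)
        return []
    rc = revcomp(seq)
    candidates: set[tuple[str, int, str]] = set()

    if policy.mode == "maq_like":
        k = policy.seed_len
        for radius in range(policy.seed_mismatches + 1):
            for kmer in _hamming_ball(seq[:k], radius):
                for chrom, p, strand in index.lookup(kmer):
                    start = p if strand == "+" else p - (L - k)
                    candidates.add((chrom, start, strand))
    else:
        v = policy.v
        c = max(1, min(index.seed_len, L // (v + 1))) if v else min(index.seed_len, L)
        table = index.table_for(c)
        n_chunks = (v + 1) if v else 1
        for which, oriented in (("+", seq), ("-", rc)):
            for ci in range(n_chunks):
                off = ci * c
                for chrom, p in table.get(oriented[off : off + c], []):
                    candidates.add((chrom, p - off, which))

    valid: list[Alignment] = []
    if policy.mode == "maq_like":
        k, seed_limit, total_limit = (
            policy.seed_len, policy.seed_mismatches, policy.max_total_mismatches,
        )
    else:
        k, seed_limit, total_limit = 0, policy.v, policy.v
    for chrom, start, strand in candidates:
        cseq = genome[chrom]
        if start < 0 or start + L > len(cseq):
            continue
        window = cseq[start : start + L]
        query = seq if strand == "+" else rc
        if policy.mode == "maq_like":
            # the read's 5' seed sits at the window start on '+' and at the
            # window end on '-'
            seed_lo, seed_hi = (0, k) if strand == "+" else (L - k, L)
        else:
            seed_lo, seed_hi = 0, L
        total, seed_mm = _mismatch_counts(window, query, seed_lo, seed_hi, total_limit)
        if total <= total_limit and seed_mm <= seed_limit:
            valid.append(Alignment(read_id, chrom, start, strand, total))
    for a in valid:
        a.n_valid = len(valid)
    return valid


def report(
    alignments: list[Alignment],
    mode: ReportMode,
    tie_break: str = "lexicographic",
    rng: np.random.Generator | None = None,
) -> list[Alignment]:
    """Apply the reporting policy to one read's valid alignment set."""
    if not alignments:
        return []
    if mode.mode == "unique_only":
        if len(alignments) != 1:
            return []
        chosen = alignments[0]
    else:
        best_mm = min(a.n_mismatch for a in alignments)
        ties = [a for a in alignments if a.n_mismatch == best_mm]
        if tie_break == "lexicographic" or len(ties) == 1:
            chosen = min(ties, key=lambda a: a.key)
        elif tie_break == "random":
            if rng is None:
                raise AlignError("random tie-break requires an rng")
            chosen = ties[int(rng.integers(len(ties)))]
        else:
            raise AlignError(f"unknown tie_break {tie_break!r}")
    chosen = replace_reported(chosen)
    return [chosen]


def replace_reported(a: Alignment) -> Alignment:
    out = Alignment(a.read_id, a.chrom, a.start, a.strand, a.n_mismatch, a.n_valid, True)
    return out


def align_and_report(
    reads: list[tuple[str, str, str]] | list[tuple[str, str]],
    index: GenomeIndex,
    policy: AlignPolicy,
    mode: ReportMode,
    tie_break: str = "lexicographic",
    rng: np.random.Generator | None = None,
) -> tuple[list[Alignment], dict[str, str]]:
    """Align a batch of reads and apply one reporting policy.

    Returns the reported alignments plus a read_id -> sequence map (needed
    for SAM emission and length accounting).
    """
    reported: list[Alignment] = []
    seqs: dict[str, str] = {}
    for rec in reads:
        rid, seq = rec[0], rec[1]
        seqs[rid] = seq
        valid = align_read(rid, seq, index, policy)
        reported.extend(report(valid, mode, tie_break, rng))
    return reported, seqs


def enumerate_valid(
    reads: list[tuple],
    index: GenomeIndex,
    policy: AlignPolicy,
) -> dict[str, list[Alignment]]:
    """Valid alignment sets for a batch, keyed by read id (no reporting)."""
    return {rec[0]: align_read(rec[0], rec[1], index, policy) for rec in reads}


# ---------------------------------------------------------------------------
# minimal SAM I/O (pysam)


def write_sam(
    path: str | Path,
    genome: dict[str, str],
    alignments: list[Alignment],
    seqs: dict[str, str],
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": len(s)} for c, s in genome.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for a in alignments:
            seq = seqs[a.read_id]
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = a.read_id
            seg.flag = 16 if a.strand == "-" else 0
            seg.reference_name = a.chrom
            seg.reference_start = a.start
            seg.mapping_quality = 255
            seg.cigartuples = [(0, len(seq))]
            seg.query_sequence = seq if a.strand == "+" else revcomp(seq)
            seg.set_tags([("NM", a.n_mismatch), ("NH", a.n_valid)])
            fh.write(seg)


def read_sam(path: str | Path) -> tuple[list[Alignment], dict[str, str]]:
    """Load reported alignments; returns records plus read sequences in
    original (read) orientation."""
    alignments: list[Alignment] = []
    seqs: dict[str, str] = {}
    with pysam.AlignmentFile(str(path), "r") as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            strand = "-" if seg.is_reverse else "+"
            a = Alignment(
                seg.query_name,
                seg.reference_name,
                seg.reference_start,
                strand,
                int(seg.get_tag("NM")) if seg.has_tag("NM") else 0,
                int(seg.get_tag("NH")) if seg.has_tag("NH") else 1,
                True,
            )
            alignments.append(a)
            seq = seg.query_sequence or ""
            seqs[a.read_id] = seq if strand == "+" else revcomp(seq)
    return alignments, seqs
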