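"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's candidate-generation machinery: the
alignment oracle scores every genomic window on both strands with a numpy
sliding-window comparison, and the adapter oracle scans every position with
a plain double loop and no early exits.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def mismatch_profiles(genome: dict[str, str], seq: str):
    """Per-position total and 5'-seed-region mismatch counts, both strands.

    Yields (chrom, strand, total_mm array, seed_mm_fn) where seed_mm_fn(k)
    gives the per-position mismatch count restricted to the read's first k
    bases.
    """
    L = len(seq)
    for chrom, cseq in genome.items():
        arr = np.frombuffer(cseq.encode(), dtype=np.uint8)
        if len(arr) < L:
            continue
        win = sliding_window_view(arr, L)
        for strand, q in (("+", seq), ("-", _rc(seq))):
            qa = np.frombuffer(q.encode(), dtype=np.uint8)
            neq = win != qa
            total = neq.sum(axis=1)
            if strand == "+":
                seed_fn = lambda k, neq=neq: neq[:, :k].sum(axis=1)
            else:
                # the read's 5' seed sits at the right edge of the window
                seed_fn = lambda k, neq=neq: neq[:, L - k :].sum(axis=1)
            yield chrom, strand, total, seed_fn


def brute_force_valid(
    genome: dict[str, str],
    seq: str,
    mode: str,
    seed_len: int = 14,
    seed_mismatches: int = 0,
    max_total_mismatches: int = 2,
    v: int = 0,
) -> set[tuple[str, int, str]]:
    """The exact valid placement set by exhaustive window scoring."""
    L = len(seq)
    if mode == "maq_like" and L < seed_len:
        return set()
    out: set[tuple[str, int, str]] = set()
    for chrom, strand, total, seed_fn in mismatch_profiles(genome, seq):
        if mode == "kdiff":
            ok = total <= v
        else:
            ok = (total <= max_total_mismatches) & (
                seed_fn(seed_len) <= seed_mismatches
            )
        for p in np.nonzero(ok)[0]:
            out.add((chrom, int(p), strand))
    return out


def brute_force_adapter_pos(
    seq: str, adapter: str, min_overlap: int, mismatch_rate: float
) -> int:
    """Leftmost tolerated adapter position by unoptimized exhaustive scan."""
    hits = []
    for i in range(len(seq)):
        ov = min(len(adapter), len(seq) - i)
        if ov < min_overlap:
            continue
        mm = sum(1 for a, b in zip(seq[i : i + ov], adapter[:ov]) if a != b)
        if mm <= int(mismatch_rate * ov):
            hits.append(i)
    return min(hits) if hits else -1
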