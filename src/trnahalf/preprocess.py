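"""Adapter trimming and quality filtering for raw small-RNA reads.

Trimming removes the leftmost occurrence of the 3' adapter -- either a full
internal match or a 3'-terminal prefix of at least ``min_overlap`` bases --
within a per-overlap mismatch tolerance, together with everything 3' of it.
Reads with no detectable adapter are kept whole.  Filtering then keeps reads
whose trimmed insert length falls in the allowed range and whose quality
string has a sufficient fraction of bases at or above the Phred threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO


class FastqFormatError(ValueError):
    pass


@dataclass
class PreprocessParams:
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    min_overlap: int = 5
    max_adapter_mismatch_rate: float = 0.1
    q_threshold: int = 20
    min_fraction_above_q: float = 0.8
    min_insert_len: int = 5
    max_insert_len: int = 48

    def __post_init__(self):
        if not (0 < self.min_overlap <= len(self.adapter)):
            raise ValueError("min_overlap must be in 1..len(adapter)")
        for r in (self.max_adapter_mismatch_rate, self.min_fraction_above_q):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must lie in [0, 1]")


def find_adapter(seq: str, params: PreprocessParams) -> int:
    """Return the start index of the leftmost tolerated adapter match, or -1.

    A match at position i covers overlap = min(len(adapter), len(seq)-i)
    bases and is tolerated when its mismatch count is at most
    floor(max_adapter_mismatch_rate * overlap).
    """
    adapter = params.adapter
    alen = len(adapter)
    L = len(seq)
    rate = params.max_adapter_mismatch_rate
    for i in range(0, L - params.min_overlap + 1):
        ov = min(alen, L - i)
        frag = adapter[:ov]
        if seq[i : i + ov] == frag:
            return i
        allowed = int(rate * ov)
        if allowed:
            mm = 0
            sub = seq[i : i + ov]
            for a, b in zip(sub, frag):
                if a != b:
                    mm += 1
                    if mm > allowed:
                        break
            if mm <= allowed:
                return i
    return -1


def trim_adapter(seq: str, params: PreprocessParams) -> str:
    """Remove the leftmost adapter occurrence and everything 3' of it."""
    if not seq:
        return seq
    i = find_adapter(seq, params)
    return seq if i < 0 else seq[:i]


def quality_filter(seq: str, qual: str, params: PreprocessParams) -> bool:
    """Keep iff length is in range and enough bases meet the Phred threshold.

    Both thresholds are inclusive.
    """
    if len(seq) != len(qual):
        raise FastqFormatError(
            f"sequence length {len(seq)} != quality length {len(qual)}"
        )
    if not (params.min_insert_len <= len(seq) <= params.max_insert_len):
        return False
    n_good = sum(1 for c in qual if ord(c) - 33 >= params.q_threshold)
    return n_good >= params.min_fraction_above_q * len(seq)


def preprocess_reads(
    reads: Iterable[tuple[str, str, str]], params: PreprocessParams
) -> tuple[list[tuple[str, str, str]], dict[str, int]]:
    """Trim and filter an iterable of (id, seq, qual); return survivors + stats."""
    kept: list[tuple[str, str, str]] = []
    stats = {"reads_in": 0, "trimmed": 0, "discarded_length": 0,
             "discarded_quality": 0, "reads_out": 0}
    for rid, seq, qual in reads:
        stats["reads_in"] += 1
        i = find_adapter(seq, params)
        if i >= 0:
            stats["trimmed"] += 1
            tseq, tqual = seq[:i], qual[:i]
        else:
            tseq, tqual = seq, qual
        if not (params.min_insert_len <= len(tseq) <= params.max_insert_len):
            stats["discarded_length"] += 1
            continue
        if not quality_filter(tseq, tqual, params):
            stats["discarded_quality"] += 1
            continue
        kept.append((rid, tseq, tqual))
        stats["reads_out"] += 1
    return kept, stats


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield rec.id, str(rec.seq).upper(), qual


def preprocess_fastq(
    in_path: str | Path, out_path: str | Path, params: PreprocessParams,
    log_path: str | Path | None = None,
) -> dict[str, int]:
    kept, stats = preprocess_reads(read_fastq(in_path), params)
    with open(out_path, "w", newline="\n") as fh:
        for rid, seq, qual in kept:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
    if log_path is not None:
        pd.DataFrame([stats]).to_csv(log_path, sep="\t", index=False,
                                     lineterminator="\n")
    return stats
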