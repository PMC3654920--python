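"""Feature-class assignment, tRNA 5'/3'-end classification, and profiling.

Reported alignments are intersected with the annotation track; each read is
assigned the highest-priority feature class among strand-compatible
overlaps (repeats are strandless).  Reads landing on tRNA loci are further
classified by which mature-tRNA terminus they carry: a read whose 5' end
maps within ``tol5`` nt of mature position 1 is a 5' half (``tRNA_5p``), a
read whose 3' end maps within ``tol3`` nt of the mature 3' terminus is a 3'
fragment, anything else is internal.  For 5' halves the mature position of
the 3'-terminal base is recorded as the cleavage position, reported
downstream as an offset upstream of the anticodon.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree

from .align import Alignment
from .reference import Feature, FeatureTrack, TrnaGene

READ_CLASSES = (
    "tRNA_5p", "tRNA_3p", "tRNA_internal",
    "miRNA", "rRNA", "other_smRNA", "repeat", "none",
)

#: track classes folded into the read-level "other_smRNA" bucket
_OTHER_SMRNA = {"scRNA", "snRNA", "srpRNA"}


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class ClassPriority:
    """Total order over coarse feature classes used to break overlap ties."""

    order: tuple[str, ...] = ("tRNA", "miRNA", "rRNA", "other_smRNA", "repeat")

    def rank(self, cls: str) -> int:
        try:
            return self.order.index(cls)
        except ValueError:
            raise AnnotationError(f"class {cls!r} missing from priority order")


@dataclass
class ReadAnnotation:
    read_id: str
    feature_class: str
    locus_id: str | None
    read_len: int
    cleavage_pos: int | None = None


def _coarse_class(feature_class: str) -> str:
    if feature_class in _OTHER_SMRNA:
        return "other_smRNA"
    return feature_class


def classify_trna_end(
    alignment: Alignment, read_len: int, gene: TrnaGene, tol5: int = 2, tol3: int = 2
) -> tuple[str, int | None]:
    """Classify a tRNA-overlapping read by mature-tRNA terminus.

    Returns (class, cleavage_pos); cleavage_pos is set only for tRNA_5p and
    is the 1-based mature position of the read's 3'-terminal base.
    """
    aln_end = alignment.start + read_len
    if aln_end <= gene.start or alignment.start >= gene.end:
        raise AnnotationError(
            f"{alignment.read_id} does not overlap {gene.gene_id}"
        )
    if gene.strand == "+":
        m5 = alignment.start - gene.start + 1
    else:
        m5 = gene.end - (aln_end - 1)
    m3 = m5 + read_len - 1
    if abs(m5 - 1) <= tol5:
        return "tRNA_5p", m3
    if abs(m3 - gene.length) <= tol3:
        return "tRNA_3p", None
    return "tRNA_internal", None


class Annotator:
    """Interval-tree-backed read annotator over a feature track."""

    def __init__(
        self,
        track: FeatureTrack,
        priority: ClassPriority = ClassPriority(),
        chrom_sizes: dict[str, int] | None = None,
        tol5: int = 2,
        tol3: int = 2,
        strand_required: bool = True,
    ):
        self.track = track
        self.priority = priority
        self.chrom_sizes = chrom_sizes
        self.tol5, self.tol3 = tol5, tol3
        self.strand_required = strand_required
        self._trees: dict[str, IntervalTree] = {}
        for f in track.features:
            self._trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)

    def annotate(self, alignment: Alignment, read_len: int) -> ReadAnnotation:
        if self.chrom_sizes is not None and alignment.chrom not in self.chrom_sizes:
            raise AnnotationError(f"unknown chromosome {alignment.chrom!r}")
        tree = self._trees.get(alignment.chrom)
        hits: list[Feature] = []
        if tree is not None:
            for iv in tree.overlap(alignment.start, alignment.start + read_len):
                f: Feature = iv.data
                if (
                    self.strand_required
                    and f.feature_class != "repeat"
                    and f.strand != alignment.strand
                ):
                    continue
                hits.append(f)
        if not hits:
            return ReadAnnotation(alignment.read_id, "none", None, read_len)
        best = min(
            hits,
            key=lambda f: (
                self.priority.rank(_coarse_class(f.feature_class)),
                f.chrom, f.start, f.strand,
            ),
        )
        if best.feature_class == "tRNA":
            cls, cleave = classify_trna_end(
                alignment, read_len, best.trna, self.tol5, self.tol3
            )
            return ReadAnnotation(alignment.read_id, cls, best.feature_id, read_len, cleave)
        return ReadAnnotation(
            alignment.read_id, _coarse_class(best.feature_class), best.feature_id, read_len
        )

    def annotate_batch(
        self, alignments: list[Alignment], seqs: dict[str, str]
    ) -> pd.DataFrame:
        anns = [self.annotate(a, len(seqs[a.read_id])) for a in alignments]
        return annotations_to_frame(anns)


def annotations_to_frame(anns: list[ReadAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [a.read_id for a in anns],
            "feature_class": pd.Categorical(
                [a.feature_class for a in anns], categories=READ_CLASSES
            ),
            "locus_id": [a.locus_id for a in anns],
            "read_len": [a.read_len for a in anns],
            "cleavage_pos": [a.cleavage_pos for a in anns],
        }
    )


def length_histogram(
    annotations: pd.DataFrame,
    lengths: range = range(5, 49),
    policy_combo_label: str | None = None,
) -> pd.DataFrame:
    """Read counts per (length, feature class); partitions the input reads."""
    df = annotations.copy()
    counts = (
        df.groupby(["read_len", "feature_class"], observed=False)
        .size()
        .unstack(fill_value=0)
        .reindex(list(lengths), fill_value=0)
    )
    counts.index.name = "length"
    counts["total"] = counts.sum(axis=1)
    if policy_combo_label is not None:
        counts.insert(0, "policy_combo", policy_combo_label)
    return counts.reset_index()


def cleavage_profile(
    annotations: pd.DataFrame, gene_lookup: dict[str, TrnaGene]
) -> pd.DataFrame:
    """Per-family cleavage-site table for 5' halves.

    One row per (family, mature cleavage position): read count, fraction of
    the family's 5'-half reads, and offset upstream of the anticodon
    (offset = anticodon_pos - cleavage_pos; >= 1 means the read stops short
    of the anticodon).
    """
    df = annotations[annotations["feature_class"] == "tRNA_5p"].copy()
    if df.empty:
        return pd.DataFrame(
            columns=["family_id", "cleavage_pos", "offset", "n_reads", "fraction"]
        )
    df["family_id"] = df["locus_id"].map(lambda g: gene_lookup[g].family_id)
    df["anticodon_pos"] = df["locus_id"].map(lambda g: gene_lookup[g].anticodon_pos)
    grouped = (
        df.groupby(["family_id", "anticodon_pos", "cleavage_pos"])
        .size()
        .rename("n_reads")
        .reset_index()
    )
    grouped["offset"] = grouped["anticodon_pos"] - grouped["cleavage_pos"].astype(int)
    grouped["fraction"] = grouped["n_reads"] / grouped.groupby("family_id")[
        "n_reads"
    ].transform("sum")
    return grouped[["family_id", "cleavage_pos", "offset", "n_reads", "fraction"]]


def isoacceptor_frequencies(
    annotations: pd.DataFrame,
    gene_lookup: dict[str, TrnaGene],
    half_classes: tuple[str, ...] = ("tRNA_5p", "tRNA_3p"),
) -> pd.DataFrame:
    """Fraction of tRNA-half reads per isotype, joined with gene copy number."""
    df = annotations[annotations["feature_class"].isin(half_classes)].copy()
    if df.empty:
        return pd.DataFrame(columns=["isotype", "n_reads", "fraction", "copy_number"])
    df["isotype"] = df["locus_id"].map(lambda g: gene_lookup[g].isotype)
    counts = df.groupby("isotype").size().rename("n_reads").reset_index()
    counts["fraction"] = counts["n_reads"] / counts["n_reads"].sum()
    copies = (
        pd.Series(
            {g.gene_id: g.isotype for g in gene_lookup.values()}, name="isotype"
        )
        .value_counts()
        .rename("copy_number")
        .reset_index()
        .rename(columns={"index": "isotype"})
    )
    out = counts.merge(copies, on="isotype", how="left")
    return out.sort_values("fraction", ascending=False).reset_index(drop=True)


def class_fractions(annotations: pd.DataFrame) -> pd.Series:
    """Coarse class shares (tRNA subclasses folded together); sums to 1."""
    coarse = annotations["feature_class"].astype(str).replace(
        {"tRNA_5p": "tRNA", "tRNA_3p": "tRNA", "tRNA_internal": "tRNA"}
    )
    return coarse.value_counts(normalize=True)
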