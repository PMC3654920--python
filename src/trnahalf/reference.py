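"""Synthetic genome + small-RNA feature annotation shared by all pipeline stages.

The central object is a genome (dict of chromosome name -> sequence string)
paired with a :class:`FeatureTrack` of annotated small-RNA loci.  tRNA loci
carry a :class:`TrnaGene` payload that fixes the coordinate frame used for
5'/3'-end classification and anticodon-relative cleavage profiling.

Multi-copy tRNA families are the scientifically load-bearing part: every
copy of a family carries an identical sequence, so short reads derived from
family members are genuine multireads.  Coordinates are 0-based half-open
genomically; positions inside the mature tRNA are 1-based with position 1 at
the mature 5' nucleotide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FEATURE_CLASSES = ("tRNA", "miRNA", "rRNA", "scRNA", "snRNA", "srpRNA", "repeat")

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def revcomp(seq: str) -> str:
    """Reverse complement via Biopython (accepts upper-case DNA)."""
    return str(Seq(seq).reverse_complement())


class ReferenceError(ValueError):
    """Raised for malformed or inconsistent reference inputs."""


class PlacementError(ReferenceError):
    """Raised when chromosome capacity cannot accommodate all features."""


@dataclass(frozen=True)
class TrnaGene:
    """One tRNA locus.

    ``anticodon_pos`` is the 1-based start of the anticodon within the
    mature tRNA; ``sequence`` is the mature (sense-strand) sequence, equal
    to the genome slice on '+' loci and its reverse complement on '-' loci.
    ``family_id`` groups identical-sequence copies.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    isotype: str
    anticodon: str
    anticodon_pos: int
    sequence: str
    family_id: str

    def __post_init__(self):
        if self.strand not in "+-":
            raise ReferenceError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.end - self.start != len(self.sequence):
            raise ReferenceError(
                f"{self.gene_id}: interval length {self.end - self.start} != "
                f"sequence length {len(self.sequence)}"
            )
        if not (1 <= self.anticodon_pos <= len(self.sequence) - 2):
            raise ReferenceError(
                f"{self.gene_id}: anticodon_pos {self.anticodon_pos} outside "
                f"1..{len(self.sequence) - 2}"
            )
        ac = self.sequence[self.anticodon_pos - 1 : self.anticodon_pos + 2]
        if ac != self.anticodon:
            raise ReferenceError(
                f"{self.gene_id}: sequence carries {ac} at anticodon_pos, "
                f"expected {self.anticodon}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Feature:
    """A genomic feature interval with a class label from the fixed vocabulary."""

    chrom: str
    start: int
    end: int
    strand: str
    feature_class: str
    feature_id: str
    trna: TrnaGene | None = None

    def __post_init__(self):
        if self.feature_class not in FEATURE_CLASSES:
            raise ReferenceError(f"unknown feature class {self.feature_class!r}")
        if self.feature_class == "tRNA" and self.trna is None:
            raise ReferenceError(f"tRNA feature {self.feature_id} lacks gene payload")


@dataclass
class FeatureTrack:
    features: list[Feature] = field(default_factory=list)

    def by_class(self, cls: str) -> list[Feature]:
        return [f for f in self.features if f.feature_class == cls]

    def trna_genes(self) -> list[TrnaGene]:
        return [f.trna for f in self.features if f.feature_class == "tRNA"]

    def gene_lookup(self) -> dict[str, TrnaGene]:
        return {g.gene_id: g for g in self.trna_genes()}

    def families(self) -> dict[str, list[TrnaGene]]:
        fams: dict[str, list[TrnaGene]] = {}
        for g in self.trna_genes():
            fams.setdefault(g.family_id, []).append(g)
        return fams


@dataclass(frozen=True)
class FamilySpec:
    """One identical-sequence tRNA gene family to synthesize."""

    isotype: str
    anticodon: str
    copy_number: int
    trna_length: int = 76
    anticodon_pos: int = 34
    # number of random substitutions applied independently to each copy
    # beyond the first (0 keeps copies exactly identical, the default that
    # makes family reads true multireads)
    copy_substitutions: int = 0


@dataclass
class ReferenceSpec:
    """Parameters of a synthetic reference build (deterministic given seed)."""

    families: list[FamilySpec]
    n_mirna: int = 20
    n_repeat_regions: int = 10
    n_rrna: int = 2
    n_other_smrna: int = 3
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 80_000, "chr2": 80_000, "chr3": 80_000}
    )
    mirna_length: int = 22
    seed: int = 0

    def validate(self) -> None:
        if not self.families:
            raise ReferenceError("spec needs at least one tRNA family")
        for fam in self.families:
            if fam.copy_number < 1:
                raise ReferenceError(f"copy_number < 1 for {fam.isotype}-{fam.anticodon}")
            if len(fam.anticodon) != 3:
                raise ReferenceError(f"anticodon must be a 3-mer, got {fam.anticodon!r}")
            if not (1 <= fam.anticodon_pos <= fam.trna_length - 2):
                raise ReferenceError("anticodon_pos outside mature tRNA")


def default_reference_spec(seed: int = 0) -> ReferenceSpec:
    """Reference emulating the copy-number structure of the mouse serum study.

    Family copy numbers follow the genomic tRNA database counts reported for
    the isoacceptors that dominate circulating 5' tRNA halves (Gly 29,
    Val 23, Glu 21, His 11) plus the minor families seen in the differential
    analysis.  Anticodon start defaults to mature position 34 so that
    cleavage 1-4 nt upstream of the anticodon yields 30-33 nt 5' halves.
    """
    fams = [
        FamilySpec("Gly", "GCC", 29),
        FamilySpec("Val", "AAC", 23),
        FamilySpec("Glu", "CTC", 21),
        FamilySpec("His", "GTG", 11),
        FamilySpec("Lys", "CTT", 8),
        FamilySpec("Cys", "GCA", 5),
        FamilySpec("Arg", "CCG", 4),
    ]
    return ReferenceSpec(families=fams, seed=seed)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _place(
    rng: np.random.Generator,
    occupied: dict[str, list[tuple[int, int]]],
    chrom_sizes: dict[str, int],
    length: int,
    max_tries: int = 2000,
) -> tuple[str, int]:
    """Rejection-sample a non-overlapping interval across chromosomes."""
    chroms = list(chrom_sizes)
    for _ in range(max_tries):
        chrom = chroms[rng.integers(len(chroms))]
        size = chrom_sizes[chrom]
        if size < length:
            continue
        start = int(rng.integers(0, size - length + 1))
        end = start + length
        if all(end <= s or start >= e for s, e in occupied[chrom]):
            occupied[chrom].append((start, end))
            return chrom, start
    raise PlacementError(
        f"could not place a {length} nt feature after {max_tries} tries; "
        "increase chrom_sizes or reduce feature load"
    )


def build_synthetic_reference(spec: ReferenceSpec) -> tuple[dict[str, str], FeatureTrack]:
    """Build a random genome with embedded multi-copy tRNA families.

    Every copy of a family is sequence-identical (unless the family requests
    per-copy substitutions), scattered over chromosomes and strands.  The
    build is byte-deterministic for a given spec and seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    chrom_arrays = {
        c: bytearray(_random_seq(rng, n), "ascii") for c, n in spec.chrom_sizes.items()
    }
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in spec.chrom_sizes}
    features: list[Feature] = []

    seen_prefixes: set[str] = set()
    for fam in spec.families:
        # resample until the family 5' end is unique among families, so each
        # family's halves multimap only within the family
        while True:
            seq = list(_random_seq(rng, fam.trna_length))
            seq[fam.anticodon_pos - 1 : fam.anticodon_pos + 2] = fam.anticodon
            mature = "".join(seq)
            if mature[:20] not in seen_prefixes:
                seen_prefixes.add(mature[:20])
                break
        family_id = f"{fam.isotype}-{fam.anticodon}"
        for i in range(fam.copy_number):
            copy_seq = mature
            if fam.copy_substitutions and i > 0:
                s = list(mature)
                for _ in range(fam.copy_substitutions):
                    p = int(rng.integers(fam.trna_length))
                    if fam.anticodon_pos - 1 <= p <= fam.anticodon_pos + 1:
                        continue  # keep the anticodon intact
                    s[p] = "ACGT"[int(rng.integers(4))]
                copy_seq = "".join(s)
            strand = "+" if rng.random() < 0.5 else "-"
            chrom, start = _place(rng, occupied, spec.chrom_sizes, fam.trna_length)
            genomic = copy_seq if strand == "+" else revcomp(copy_seq)
            chrom_arrays[chrom][start : start + fam.trna_length] = genomic.encode()
            gene = TrnaGene(
                gene_id=f"{chrom}.tRNA{len(features)}-{fam.isotype}{fam.anticodon}",
                chrom=chrom,
                start=start,
                end=start + fam.trna_length,
                strand=strand,
                isotype=fam.isotype,
                anticodon=fam.anticodon,
                anticodon_pos=fam.anticodon_pos,
                sequence=copy_seq,
                family_id=family_id,
            )
            features.append(
                Feature(chrom, start, gene.end, strand, "tRNA", gene.gene_id, gene)
            )

    def _simple(n: int, length_range: tuple[int, int], cls: str, prefix: str):
        for i in range(n):
            length = int(rng.integers(length_range[0], length_range[1] + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            chrom, start = _place(rng, occupied, spec.chrom_sizes, length)
            features.append(
                Feature(chrom, start, start + length, strand, cls, f"{prefix}{i}")
            )

    _simple(spec.n_mirna, (spec.mirna_length, spec.mirna_length), "miRNA", "mir-")
    _simple(spec.n_rrna, (120, 160), "rRNA", "rRNA-")
    _simple(spec.n_other_smrna, (80, 120), "scRNA", "scRNA-")
    _simple(spec.n_repeat_regions, (100, 300), "repeat", "rep-")

    genome = {c: arr.decode() for c, arr in chrom_arrays.items()}
    return genome, FeatureTrack(features)


# ---------------------------------------------------------------------------
# mature-tRNA coordinate frame


def trna_coordinate(gene: TrnaGene, genomic_pos: int) -> int:
    """Map a genomic position inside the gene to its 1-based mature position.

    Position 1 is the mature 5' nucleotide on either strand.
    """
    if not (gene.start <= genomic_pos < gene.end):
        raise ReferenceError(
            f"position {genomic_pos} outside {gene.gene_id} "
            f"[{gene.start},{gene.end})"
        )
    if gene.strand == "+":
        return genomic_pos - gene.start + 1
    return gene.end - genomic_pos


# ---------------------------------------------------------------------------
# on-disk formats: FASTA genome, BED6+5 annotation
#
# BED columns: chrom start end name score strand class isotype anticodon
# anticodon_pos family_id ('.' placeholders on non-tRNA rows).


def write_genome_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=c, description="") for c, s in genome.items()]
    with open(path, "w", newline="\n") as fh:
        SeqIO.write(records, fh, "fasta")


def load_genome_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_feature_bed(track: FeatureTrack, path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        for f in track.features:
            if f.feature_class == "tRNA":
                g = f.trna
                extra = [f.feature_class, g.isotype, g.anticodon, str(g.anticodon_pos), g.family_id]
            else:
                extra = [f.feature_class, ".", ".", ".", "."]
            fh.write(
                "\t".join(
                    [f.chrom, str(f.start), str(f.end), f.feature_id, "0", f.strand]
                    + extra
                )
                + "\n"
            )


def load_feature_bed(path: str | Path, genome: dict[str, str]) -> FeatureTrack:
    feats: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 11:
                raise ReferenceError(f"{path}:{lineno}: expected 11 BED columns")
            chrom, start, end, name, _score, strand, cls = parts[:7]
            try:
                start, end = int(start), int(end)
            except ValueError as exc:
                raise ReferenceError(f"{path}:{lineno}: bad coordinates") from exc
            if chrom not in genome:
                raise ReferenceError(f"{path}:{lineno}: unknown chromosome {chrom}")
            if not (0 <= start < end <= len(genome[chrom])):
                raise ReferenceError(
                    f"{path}:{lineno}: interval outside chromosome {chrom}"
                )
            trna = None
            if cls == "tRNA":
                isotype, anticodon, ac_pos, family_id = parts[7:11]
                gslice = genome[chrom][start:end]
                seq = gslice if strand == "+" else revcomp(gslice)
                try:
                    ac_pos = int(ac_pos)
                except ValueError as exc:
                    raise ReferenceError(f"{path}:{lineno}: bad anticodon_pos") from exc
                try:
                    trna = TrnaGene(
                        name, chrom, start, end, strand, isotype, anticodon,
                        ac_pos, seq, family_id,
                    )
                except ReferenceError as exc:
                    raise ReferenceError(f"{path}:{lineno}: {exc}") from exc
            feats.append(Feature(chrom, start, end, strand, cls, name, trna))
    return FeatureTrack(feats)


def load_reference(
    fasta_path: str | Path, annotation_path: str | Path
) -> tuple[dict[str, str], FeatureTrack]:
    genome = load_genome_fasta(fasta_path)
    track = load_feature_bed(annotation_path, genome)
    return genome, track


def write_reference(
    genome: dict[str, str],
    track: FeatureTrack,
    fasta_path: str | Path,
    annotation_path: str | Path,
) -> None:
    write_genome_fasta(genome, fasta_path)
    write_feature_bed(track, annotation_path)
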