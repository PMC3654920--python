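"""Summary tables and end-to-end pipeline orchestration.

Percentages are recomputed from counts at report time, at the precision the
summary tables use: overall mapping rate to one decimal, class and size
shares as integer percents, fold changes to one decimal.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import annotate as ann
from .align import AlignPolicy, ReportMode, align_and_report, build_index, write_sam
from .diff import (
    count_loci, estimate_dispersion, filter_low, fit_and_test,
    tmm_norm_factors, write_diff_table,
)
from .preprocess import PreprocessParams, preprocess_reads
from .reference import (
    ReferenceSpec, build_synthetic_reference, default_reference_spec,
    load_reference, write_reference,
)
from .simulate import MixtureSpec, default_design, simulate_experiment, write_fastq, write_truth

logger = logging.getLogger(__name__)

SMALL_RNA_CLASSES = ("tRNA", "miRNA", "rRNA", "other_smRNA")


class ReportError(ValueError):
    pass


@dataclass
class MappingSummary:
    n_preprocessed: int
    n_mapped: int
    class_counts: dict[str, int]
    n_small_rna: int
    mapped_pct: float
    small_rna_pct: int
    class_pct_of_small_rna: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("preprocessed_reads", self.n_preprocessed, ""),
            ("mapped_reads", self.n_mapped, f"{self.mapped_pct}%"),
            ("small_rna_reads", self.n_small_rna, f"{self.small_rna_pct}%"),
        ]
        for cls, n in self.class_counts.items():
            pct = self.class_pct_of_small_rna.get(cls)
            rows.append((f"class_{cls}", n, "" if pct is None else f"{pct}%"))
        return pd.DataFrame(rows, columns=["quantity", "count", "percent"])


def summarize_mapping(
    n_preprocessed: int,
    n_mapped: int,
    class_counts: dict[str, int] | None = None,
    n_small_rna: int | None = None,
) -> MappingSummary:
    """Read-accounting summary with percentages at printed precision.

    The overall mapping rate is a percent of preprocessed reads to one
    decimal; the small-RNA share is an integer percent of mapped reads; the
    per-class shares are integer percents of small-RNA-mapped reads.
    """
    class_counts = dict(class_counts or {})
    if n_mapped > n_preprocessed:
        raise ReportError("mapped reads exceed preprocessed reads")
    total_classes = sum(class_counts.values())
    if {"repeat", "none"} <= set(class_counts) and total_classes != n_mapped:
        raise ReportError(
            f"class counts sum to {total_classes}, expected n_mapped={n_mapped}"
        )
    if total_classes > n_mapped:
        raise ReportError("class counts exceed mapped reads")
    if n_small_rna is None:
        n_small_rna = sum(class_counts.get(c, 0) for c in SMALL_RNA_CLASSES)
    if n_small_rna > n_mapped:
        raise ReportError("small-RNA reads exceed mapped reads")
    mapped_pct = round(n_mapped / n_preprocessed * 100, 1)
    small_pct = int(round(n_small_rna / n_mapped * 100)) if n_mapped else 0
    class_pct = {
        c: int(round(class_counts[c] / n_small_rna * 100))
        for c in SMALL_RNA_CLASSES
        if c in class_counts and n_small_rna
    }
    return MappingSummary(
        n_preprocessed, n_mapped, class_counts, n_small_rna,
        mapped_pct, small_pct, class_pct,
    )


def size_share_table(counts_by_length: dict[int, int]) -> pd.DataFrame:
    """Integer-percent share of each read length among tRNA-mapping reads."""
    if not counts_by_length or all(v == 0 for v in counts_by_length.values()):
        raise ReportError("size table needs at least one nonzero count")
    if any(v < 0 for v in counts_by_length.values()):
        raise ReportError("negative count")
    total = sum(counts_by_length.values())
    rows = [
        (length, n, int(round(n / total * 100)))
        for length, n in sorted(counts_by_length.items())
    ]
    return pd.DataFrame(rows, columns=["length", "n_reads", "percent"])


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunConfig:
    out_dir: Path
    seed: int = 0
    # reference: either synthesize from spec or load from paths
    reference_spec: ReferenceSpec | None = None
    reference_fasta: Path | None = None
    reference_bed: Path | None = None
    design: dict[str, str] = field(default_factory=default_design)
    mix: MixtureSpec = field(default_factory=MixtureSpec)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    policy: AlignPolicy = field(default_factory=AlignPolicy)
    report_mode: ReportMode = field(default_factory=ReportMode)
    priority: ann.ClassPriority = field(default_factory=ann.ClassPriority)
    policy_grid: bool = True  # emit the 2x2 policy/reporting length histograms
    min_cpm: float = 500.0
    prior_df: float = 10.0
    use_tmm: bool = True
    write_sam_files: bool = True

    def validate(self) -> None:
        if self.reference_spec is None:
            if self.reference_fasta is None or self.reference_bed is None:
                raise ReportError(
                    "config needs either a reference_spec or both "
                    "reference_fasta and reference_bed paths"
                )
            for p in (self.reference_fasta, self.reference_bed):
                if not Path(p).exists():
                    raise ReportError(f"missing reference file: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Simulate -> preprocess -> align -> annotate -> quantify -> test -> report.

    Deterministic given the config seed; returns (and writes) a manifest of
    artifacts with checksums.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []
    t0 = time.time()

    def stage(name):
        logger.info("stage %-12s t=%.1fs", name, time.time() - t0)

    stage("reference")
    if config.reference_spec is not None:
        genome, track = build_synthetic_reference(config.reference_spec)
        write_reference(genome, track, out / "reference.fa", out / "features.bed")
        artifacts += [out / "reference.fa", out / "features.bed"]
    else:
        genome, track = load_reference(config.reference_fasta, config.reference_bed)
    gene_lookup = track.gene_lookup()
    chrom_sizes = {c: len(s) for c, s in genome.items()}

    stage("simulate")
    samples = simulate_experiment(genome, track, config.mix, config.design, config.seed)
    for sid, sim in samples.items():
        write_fastq(sim.reads, out / f"{sid}.fastq")
        write_truth(sim.truth, out / f"{sid}.truth.tsv")
        artifacts += [out / f"{sid}.fastq", out / f"{sid}.truth.tsv"]

    stage("preprocess")
    clean: dict[str, list] = {}
    pp_stats = {}
    for sid, sim in samples.items():
        clean[sid], pp_stats[sid] = preprocess_reads(sim.reads, config.preprocess)
    pp_log = pd.DataFrame(pp_stats).T.rename_axis("sample").reset_index()
    pp_log.to_csv(out / "preprocess_log.tsv", sep="\t", index=False, lineterminator="\n")
    artifacts.append(out / "preprocess_log.tsv")

    stage("align")
    index = build_index(genome, config.policy.seed_len)
    annotator = ann.Annotator(track, config.priority, chrom_sizes)
    annotations: dict[str, pd.DataFrame] = {}
    histograms = []
    for sid in samples:
        reported, seqs = align_and_report(
            clean[sid], index, config.policy, config.report_mode
        )
        if config.write_sam_files:
            write_sam(out / f"{sid}.sam", genome, reported, seqs)
            artifacts.append(out / f"{sid}.sam")
        annotations[sid] = annotator.annotate_batch(reported, seqs)

    if config.policy_grid:
        stage("policy_grid")
        combined = [r for sid in samples for r in clean[sid]]
        for pol_label, pol in (
            ("maq_like", AlignPolicy(mode="maq_like", seed_len=config.policy.seed_len)),
            ("kdiff", AlignPolicy(mode="kdiff", v=config.policy.v)),
        ):
            from .align import align_read, report as report_alns

            valid_sets = {}
            seqs = {}
            for rid, seq, _q in combined:
                seqs[rid] = seq
                valid_sets[rid] = align_read(rid, seq, index, pol)
            for rep_label, rep in (
                ("best_one", ReportMode("best_one")),
                ("unique_only", ReportMode("unique_only")),
            ):
                reported = [
                    a for v in valid_sets.values() for a in report_alns(v, rep)
                ]
                frame = annotator.annotate_batch(reported, seqs)
                histograms.append(
                    ann.length_histogram(frame, policy_combo_label=f"{pol_label}/{rep_label}")
                )
        hist = pd.concat(histograms, ignore_index=True)
        hist.to_csv(out / "length_histograms.tsv", sep="\t", index=False, lineterminator="\n")
        artifacts.append(out / "length_histograms.tsv")

    stage("report_tables")
    all_ann = pd.concat(annotations.values(), ignore_index=True)
    coarse = ann.class_fractions(all_ann)
    n_pre = int(sum(s["reads_out"] for s in pp_stats.values()))
    n_mapped = int(len(all_ann))
    class_counts = {
        c: int(round(coarse.get(c, 0.0) * n_mapped))
        for c in ("tRNA", "miRNA", "rRNA", "other_smRNA", "repeat", "none")
    }
    # rounding guard: force exact partition of n_mapped
    class_counts["none"] += n_mapped - sum(class_counts.values())
    summary = summarize_mapping(n_pre, n_mapped, class_counts)
    summary.to_frame().to_csv(out / "mapping_summary.tsv", sep="\t", index=False,
                              lineterminator="\n")
    artifacts.append(out / "mapping_summary.tsv")

    trna_lengths = (
        all_ann[all_ann["feature_class"].isin(["tRNA_5p", "tRNA_3p", "tRNA_internal"])]
        ["read_len"].value_counts().to_dict()
    )
    if trna_lengths:
        size_share_table(trna_lengths).to_csv(
            out / "trna_size_shares.tsv", sep="\t", index=False, lineterminator="\n"
        )
        artifacts.append(out / "trna_size_shares.tsv")

    ann.cleavage_profile(all_ann, gene_lookup).to_csv(
        out / "cleavage_profile.tsv", sep="\t", index=False, lineterminator="\n"
    )
    ann.isoacceptor_frequencies(all_ann, gene_lookup).to_csv(
        out / "isoacceptor_frequencies.tsv", sep="\t", index=False, lineterminator="\n"
    )
    artifacts += [out / "cleavage_profile.tsv", out / "isoacceptor_frequencies.tsv"]

    stage("quantify")
    cm = count_loci(annotations, config.design)
    if config.use_tmm:
        cm.norm_factors = tmm_norm_factors(cm)
    cm.counts.to_csv(out / "count_matrix.tsv", sep="\t", lineterminator="\n")
    artifacts.append(out / "count_matrix.tsv")

    stage("diff")
    filtered = filter_low(cm, config.min_cpm)
    diff_path = out / "diff_results.tsv"
    if len(filtered.counts):
        disp = estimate_dispersion(filtered, prior_df=config.prior_df)
        result = fit_and_test(filtered, disp)
        write_diff_table(result, diff_path)
    else:
        pd.DataFrame().to_csv(diff_path, sep="\t", lineterminator="\n")
    artifacts.append(diff_path)

    manifest = {
        "seed": config.seed,
        "n_samples": len(samples),
        "policy": asdict(config.policy),
        "report_mode": config.report_mode.mode,
        "artifacts": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
    }
    with open(out / "manifest.json", "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    stage("done")
    return manifest


def demo_config(out_dir: Path, seed: int = 0, n_reads: int = 4000) -> RunConfig:
    """A small, fast configuration exercising every stage."""
    mix = MixtureSpec(n_reads=n_reads)
    return RunConfig(
        out_dir=Path(out_dir),
        seed=seed,
        reference_spec=default_reference_spec(seed),
        mix=mix,
    )
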