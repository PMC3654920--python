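import numpy as np
import pytest

from trnahalf import (
    Alignment, ReadAnnotation, AlignPolicy, Annotator, ReportMode,
    classify_trna_end, cleavage_profile, isoacceptor_frequencies,
    length_histogram,
)
from trnahalf.align import align_read, report
from trnahalf.annotate import AnnotationError, annotations_to_frame, class_fractions
from trnahalf.reference import Feature, FeatureTrack, TrnaGene


def _toy_gene(strand="+", length=75, start=1000, ac_pos=34):
    seq = "A" * (ac_pos - 1) + "GCC" + "A" * (length - ac_pos - 2)
    return TrnaGene("toy", "chrT", start, start + length, strand,
                    "Gly", "GCC", ac_pos, seq, "Gly-GCC")


class TestClassifyEnd:
    def test_read_at_mature_start_is_5p_with_cleavage_pos(self):
        g = _toy_gene("+")
        aln = Alignment("r", "chrT", g.start, "+", 0)
        cls, cleave = classify_trna_end(aln, 32, g)
        assert cls == "tRNA_5p" and cleave == 32

    def test_read_ending_at_mature_3p_end(self):
        g = _toy_gene("+")
        aln = Alignment("r", "chrT", g.end - 30, "+", 0)
        cls, cleave = classify_trna_end(aln, 30, g)
        assert cls == "tRNA_3p" and cleave is None

    def test_midgene_read_is_internal(self):
        # 31-mer starting at mature position 20 of a 75 nt gene:
        # 5' terminus at 20 (|20-1|>2), 3' terminus at 50 (|50-75|>2)
        g = _toy_gene("+")
        aln = Alignment("r", "chrT", g.start + 19, "+", 0)
        cls, _ = classify_trna_end(aln, 31, g, tol5=2, tol3=2)
        assert cls == "tRNA_internal"

    def test_minus_strand_5p_half(self):
        g = _toy_gene("-")
        # mature 5' end of a '-' gene sits at the genomic end
        aln = Alignment("r", "chrT", g.end - 32, "-", 0)
        cls, cleave = classify_trna_end(aln, 32, g)
        assert cls == "tRNA_5p" and cleave == 32

    def test_tolerance_window(self):
        g = _toy_gene("+")
        aln = Alignment("r", "chrT", g.start + 2, "+", 0)  # mature pos 3
        assert classify_trna_end(aln, 30, g, tol5=2)[0] == "tRNA_5p"
        assert classify_trna_end(aln, 30, g, tol5=1)[0] == "tRNA_internal"

    def test_non_overlapping_read_raises(self):
        g = _toy_gene("+")
        with pytest.raises(AnnotationError):
            classify_trna_end(Alignment("r", "chrT", 10, "+", 0), 30, g)


class TestAnnotatorPriority:
    def _track(self):
        g = _toy_gene("+")
        feats = [
            Feature("chrT", g.start, g.end, "+", "tRNA", "toy", g),
            Feature("chrT", g.start + 20, g.end + 50, "+", "repeat", "rep1"),
            Feature("chrT", 3000, 3022, "+", "miRNA", "mir1"),
            Feature("chrT", 5000, 5100, "-", "rRNA", "rrna1"),
        ]
        return FeatureTrack(feats)

    def test_trna_beats_repeat(self):
        ann = Annotator(self._track())
        out = ann.annotate(Alignment("r", "chrT", 1030, "+", 0), 30)
        assert out.feature_class.startswith("tRNA")

    def test_mirna_only(self):
        ann = Annotator(self._track())
        out = ann.annotate(Alignment("r", "chrT", 3000, "+", 0), 22)
        assert out.feature_class == "miRNA" and out.locus_id == "mir1"

    def test_flank_is_none(self):
        ann = Annotator(self._track())
        assert ann.annotate(Alignment("r", "chrT", 9000, "+", 0), 30).feature_class == "none"

    def test_strand_requirement_for_genic_classes(self):
        ann = Annotator(self._track())
        # antisense to the rRNA locus -> no genic hit
        out = ann.annotate(Alignment("r", "chrT", 5010, "+", 0), 30)
        assert out.feature_class == "none"
        out = ann.annotate(Alignment("r", "chrT", 5010, "-", 0), 30)
        assert out.feature_class == "rRNA"

    def test_repeat_is_strandless(self):
        ann = Annotator(self._track())
        out = ann.annotate(Alignment("r", "chrT", 1100, "-", 0), 30)
        assert out.feature_class == "repeat"

    def test_unknown_chromosome_rejected(self):
        ann = Annotator(self._track(), chrom_sizes={"chrT": 10_000})
        with pytest.raises(AnnotationError):
            ann.annotate(Alignment("r", "chrX", 0, "+", 0), 30)


def _annotated_sample(default_ref, default_index, clean_sample):
    genome, track = default_ref
    _, clean, _ = clean_sample
    annot = Annotator(track, chrom_sizes={c: len(s) for c, s in genome.items()})
    reported = []
    seqs = {}
    for rid, seq, _q in clean:
        seqs[rid] = seq
        reported += report(align_read(rid, seq, default_index, AlignPolicy()),
                           ReportMode("best_one"))
    return annot.annotate_batch(reported, seqs)


@pytest.fixture(scope="module")
def annotated(default_ref, default_index, clean_sample):
    return _annotated_sample(default_ref, default_index, clean_sample)


def test_histogram_partitions_reads(annotated):
    hist = length_histogram(annotated)
    assert hist["total"].sum() == len(annotated)
    assert hist["total"].equals(hist.drop(columns=["length", "total"]).sum(axis=1))


def test_histogram_empty_input_all_zero():
    empty = annotations_to_frame([])
    hist = length_histogram(empty)
    assert (hist["total"] == 0).all()


def test_mixed_simulation_is_bimodal(annotated):
    """miRNA mode in 20-24 nt and a 5'-half mode in 30-33 nt."""
    hist = length_histogram(annotated).set_index("length")
    assert hist.loc[20:24, "total"].sum() > 5 * hist.loc[25:29, "total"].sum()
    assert hist.loc[30:33, "total"].sum() > 5 * hist.loc[25:29, "total"].sum()


def test_class_fractions_sum_to_one(annotated):
    assert class_fractions(annotated).sum() == pytest.approx(1.0)


def test_end_classification_recovers_truth(annotated, clean_sample):
    """>=99% of error-free reads get their true origin class back."""
    sim, _, _ = clean_sample
    truth = sim.truth.set_index("read_id")
    m = annotated.set_index("read_id").join(truth, rsuffix="_true")
    errfree = m[(m.n_errors == 0)
                & m.origin_class.isin(["trna_5p_half", "trna_3p_half", "mirna"])]
    expected = errfree.origin_class.map(
        {"trna_5p_half": "tRNA_5p", "trna_3p_half": "tRNA_3p", "mirna": "miRNA"}
    )
    assert (errfree.feature_class.astype(str) == expected).mean() >= 0.99


def test_reported_5p_share_exceeds_99_percent(annotated):
    trna = annotated[annotated.feature_class.isin(["tRNA_5p", "tRNA_3p", "tRNA_internal"])]
    assert (trna.feature_class == "tRNA_5p").mean() > 0.99


class TestCleavageProfile:
    def test_fractions_sum_to_one_per_family(self, annotated, default_ref):
        _, track = default_ref
        prof = cleavage_profile(annotated, track.gene_lookup())
        sums = prof.groupby("family_id").fraction.sum()
        assert np.allclose(sums, 1.0)

    def test_no_error_free_read_extends_into_anticodon(
        self, annotated, clean_sample, default_ref
    ):
        """Cleavage offsets are >=1: 5' halves stop upstream of the anticodon.

        Restricted to error-free reads whose adapter trim recovered the
        exact insert (a sequencing error inside the adapter can shift the
        trim point by a base or two)."""
        sim, _, _ = clean_sample
        _, track = default_ref
        truth = sim.truth.set_index("read_id")
        sel = annotated.join(truth, on="read_id", rsuffix="_true")
        sel = sel[(sel.origin_class == "trna_5p_half")
                  & (sel.n_errors == 0) & (sel.read_len == sel.insert_len)]
        prof = cleavage_profile(sel[annotated.columns], track.gene_lookup())
        assert len(prof) and (prof.offset >= 1).all()

    def test_site_fractions_recover_generator_probs(self, annotated, default_ref):
        from trnahalf import MixtureSpec
        _, track = default_ref
        prof = cleavage_profile(annotated, track.gene_lookup())
        by_off = prof.groupby("offset").n_reads.sum()
        frac = by_off / by_off.sum()
        n = by_off.sum()
        for off, p in MixtureSpec().cleavage_site_probs.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(frac[off] - p) < 4 * se + 0.005

    def test_single_site_profile(self):
        g = _toy_gene("+")
        anns = annotations_to_frame(
            [  # all reads cleaved at mature position 32
                *[ReadAnnotation(f"r{i}", "tRNA_5p", "toy", 32, 32)
                  for i in range(5)]
            ]
        )
        prof = cleavage_profile(anns, {"toy": g})
        assert len(prof) == 1 and prof.fraction.iloc[0] == 1.0
        assert prof.offset.iloc[0] == g.anticodon_pos - 32


class TestIsoacceptors:
    def test_only_gly_reads_give_full_share(self, default_ref):
        _, track = default_ref
        gly = track.families()["Gly-GCC"][0]
        anns = annotations_to_frame(
            [ReadAnnotation(f"r{i}", "tRNA_5p", gly.gene_id, 32, 32)
             for i in range(10)]
        )
        out = isoacceptor_frequencies(anns, track.gene_lookup())
        assert len(out) == 1
        assert out.iloc[0].isotype == "Gly" and out.iloc[0].fraction == 1.0
        assert out.iloc[0].copy_number == 29

    def test_fractions_sum_to_one_and_recover_weights(self, annotated, default_ref):
        from trnahalf import MixtureSpec
        _, track = default_ref
        out = isoacceptor_frequencies(annotated, track.gene_lookup())
        assert out.fraction.sum() == pytest.approx(1.0, abs=1e-9)
        weights = MixtureSpec().family_weights
        by_iso = {f.split("-")[0]: w for f, w in weights.items()}
        got = dict(zip(out.isotype, out.fraction))
        for iso, w in by_iso.items():
            assert got[iso] == pytest.approx(w, abs=0.02)
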