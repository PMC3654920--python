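import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trnahalf.diff import (
    CountError, CountMatrix, bh_adjust, count_loci, cpm, estimate_dispersion,
    filter_low, fit_and_test, signed_fold_change, tmm_norm_factors,
)

SAMPLES = [f"s{i}" for i in range(9)]
GROUPS9 = dict(zip(SAMPLES, ["young_control"] * 3 + ["old_control"] * 3 + ["old_CR"] * 3))


def _cm(y, lib=1e6):
    y = np.asarray(y)
    libs = pd.Series(lib, index=SAMPLES[: y.shape[1]], dtype=float)
    if np.ndim(lib) > 0:
        libs = pd.Series(np.asarray(lib, float), index=SAMPLES[: y.shape[1]])
    return CountMatrix(
        pd.DataFrame(y, columns=SAMPLES[: y.shape[1]],
                     index=[f"L{i}" for i in range(y.shape[0])]),
        pd.Series({s: GROUPS9[s] for s in SAMPLES[: y.shape[1]]}),
        libs,
    )


class TestCountLoci:
    def _ann(self, rows):
        return pd.DataFrame(rows, columns=["read_id", "feature_class", "locus_id",
                                           "read_len", "cleavage_pos"])

    def test_all_reads_at_one_locus(self):
        frames = {
            s: self._ann([(f"{s}:r{i}", "tRNA_5p", "locusA", 32, 32)
                          for i in range(100)])
            for s in SAMPLES
        }
        cm = count_loci(frames, GROUPS9)
        assert (cm.counts.loc["locusA"] == 100).all()
        assert cm.counts.values.sum() == 900

    def test_column_sums_conserve_trna_reads(self):
        rng = np.random.default_rng(0)
        frames = {}
        for s in SAMPLES[:3]:
            rows = []
            for i in range(50):
                cls = "tRNA_5p" if rng.random() < 0.7 else "miRNA"
                rows.append((f"{s}:r{i}", cls, f"loc{int(rng.integers(4))}", 32, 32))
            frames[s] = self._ann(rows)
        cm = count_loci(frames, GROUPS9)
        for s in SAMPLES[:3]:
            n_trna = (frames[s].feature_class == "tRNA_5p").sum()
            assert cm.counts[s].sum() == n_trna
            assert cm.lib_sizes[s] == 50  # default library = all mapped reads

    def test_duplicate_read_id_rejected(self):
        frames = {"s0": self._ann([("r1", "tRNA_5p", "a", 32, 32)] * 2)}
        with pytest.raises(CountError):
            count_loci(frames, {"s0": "young_control"})


class TestCpmAndFilter:
    def test_cpm_arithmetic(self):
        cm = _cm([[500, 0, 123]], lib=[1e6, 1e6, 2e6])
        x = cpm(cm)
        assert x.iloc[0, 0] == 500.0
        assert x.iloc[0, 1] == 0.0
        assert x.iloc[0, 2] == pytest.approx(61.5)

    def test_zero_library_rejected(self):
        with pytest.raises(CountError):
            _cm([[1, 2, 3]], lib=[1e6, 0, 1e6])

    def test_group_reaching_threshold_keeps_locus(self):
        # group mean cpm (600, 10, 10): kept; all groups at 499.x: dropped
        y = np.array([
            [600, 600, 600, 10, 10, 10, 10, 10, 10],
            [499, 499, 499, 499, 499, 499, 499, 499, 499],
        ])
        cm = _cm(y)
        kept = filter_low(cm, min_cpm=500)
        assert list(kept.counts.index) == ["L0"]

    def test_toy_matrix_exact_survivors(self):
        """Hand-built 5-locus matrix: exactly the 2 loci with a group mean
        >= 500 cpm survive."""
        y = np.array([
            [700, 600, 650, 5, 5, 5, 5, 5, 5],      # young group mean 650
            [5, 5, 5, 5, 5, 5, 480, 520, 515],      # old_CR mean 505
            [450, 450, 450, 450, 450, 450, 450, 450, 450],
            [0, 0, 0, 0, 0, 0, 0, 0, 0],
            [499, 501, 499, 10, 10, 10, 10, 10, 10],  # young mean 499.67
        ])
        kept = filter_low(_cm(y), min_cpm=500)
        assert list(kept.counts.index) == ["L0", "L1"]

    def test_sample_max_variant(self):
        y = np.array([[499, 501, 499, 10, 10, 10, 10, 10, 10]])
        assert len(filter_low(_cm(y), 500, stat="group_mean").counts) == 0
        assert len(filter_low(_cm(y), 500, stat="sample_max").counts) == 1


class TestSignedFoldChange:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            (16868, 3739, -4.5),   # Gly-GCC age contrast
            (4175, 1939, -2.2),    # Lys-CTT age contrast
            (1939, 3286, 1.7),     # Lys-CTT CR contrast
            (1247, 451, -2.8),     # Val-AAC age contrast
            (100, 100, 1.0),
        ],
    )
    def test_reported_convention(self, ref, alt, expected):
        assert round(signed_fold_change(ref, alt), 1) == expected

    def test_his_gtg_mean_ratio_differs_from_model_fc(self):
        # the mean-ratio convention gives 3.7 where the published table
        # prints a model-based 3.8 for this locus
        assert round(signed_fold_change(797, 2988), 1) == 3.7

    def test_zero_handling(self):
        assert np.isnan(signed_fold_change(0, 0))
        assert signed_fold_change(0, 5) == np.inf
        assert signed_fold_change(5, 0) == -np.inf

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(a=st.floats(0.1, 1e6), b=st.floats(0.1, 1e6))
    def test_antisymmetry(self, a, b):
        fa, fb = signed_fold_change(a, b), signed_fold_change(b, a)
        if abs(fa) > 1:
            assert fa == pytest.approx(-fb, rel=1e-9)


def test_bh_hand_computed_example():
    q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
    assert bh_adjust(np.array([0.2]))[0] == 0.2
    assert np.allclose(bh_adjust(np.array([0.3, 0.3, 0.3])), 0.3)


class TestTmm:
    def test_pure_scaling_gives_unit_factors(self):
        rng = np.random.default_rng(2)
        base = rng.poisson(200, size=(100, 1))
        y = np.hstack([base * c for c in (1, 2, 4, 1, 3, 1, 2, 1, 1)])
        libs = y.sum(axis=0).astype(float)
        f = tmm_norm_factors(_cm(y, lib=libs))
        assert np.allclose(f, 1.0, atol=0.02)

    def test_matches_edger_calcnormfactors(self, tmp_path):
        """Independent oracle: edgeR's TMM with the same trim settings and
        reference column."""
        rng = np.random.default_rng(0)
        y = rng.poisson(rng.gamma(10, 50, size=(80, 6)))
        y[:10, 3:] *= 5
        libs = y.sum(axis=0).astype(float)
        cm = _cm(y, lib=libs)
        ours = tmm_norm_factors(cm)
        ref_idx = int(np.argmin(np.abs(libs - np.median(libs)))) + 1
        counts_tsv = tmp_path / "cnt.tsv"
        pd.DataFrame(y).to_csv(counts_tsv, sep="\t", index=False)
        r = subprocess.run(
            ["Rscript", "-e",
             'suppressMessages(library(edgeR));'
             f'y <- as.matrix(read.delim("{counts_tsv}"));'
             f'f <- calcNormFactors(y, method="TMM", refColumn={ref_idx},'
             ' logratioTrim=0.3, sumTrim=0.05);'
             'cat(f, sep="\\n")'],
            capture_output=True, text=True, check=True,
        )
        edger = np.array([float(x) for x in r.stdout.split()])
        assert np.allclose(ours.values, edger, rtol=1e-4)


class TestDispersion:
    def test_poisson_counts_give_near_zero_common(self):
        rng = np.random.default_rng(3)
        cm = _cm(rng.poisson(500.0, size=(200, 9)))
        assert estimate_dispersion(cm).common <= 0.05

    def test_recovers_moderate_dispersion(self):
        rng = np.random.default_rng(4)
        y = rng.poisson(rng.gamma(1 / 0.2, 0.2 * 500.0, size=(500, 9)))
        est = estimate_dispersion(_cm(y))
        assert 0.1 <= est.common <= 0.3

    def test_single_sample_per_group_raises(self):
        y = [[10, 20, 30]]
        cm = CountMatrix(
            pd.DataFrame(y, columns=["a", "b", "c"]),
            pd.Series({"a": "young_control", "b": "old_control", "c": "old_CR"}),
            pd.Series({"a": 1e6, "b": 1e6, "c": 1e6}),
        )
        with pytest.raises(CountError, match="residual"):
            estimate_dispersion(cm)
        # a fixed dispersion still allows testing
        res = fit_and_test(cm, 0.1)
        assert len(res) == 1

    def test_tagwise_shrinks_toward_common(self):
        rng = np.random.default_rng(5)
        y = rng.poisson(rng.gamma(1 / 0.1, 0.1 * 300.0, size=(300, 9)))
        est = estimate_dispersion(_cm(y))
        spread = est.tagwise.quantile(0.9) - est.tagwise.quantile(0.1)
        est_loose = estimate_dispersion(_cm(y), prior_df=0.5)
        spread_loose = est_loose.tagwise.quantile(0.9) - est_loose.tagwise.quantile(0.1)
        assert spread < spread_loose


class TestFitAndTest:
    def test_identical_group_counts_give_p_near_one(self):
        y = np.tile([[100]], (3, 9))
        res = fit_and_test(_cm(y), 0.1)
        assert (res.age_lrt < 1e-8).all()
        assert (res.age_p > 0.999).all()

    def test_matches_statsmodels_nb_glm_loglik(self):
        """Independent per-locus check: statsmodels NB GLM with the same
        fixed dispersion and offsets reproduces our LRT."""
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        y = rng.poisson(rng.gamma(10, 40, size=(20, 9)))
        cm = _cm(y)
        phi = 0.15
        res = fit_and_test(cm, phi).loc[[f"L{i}" for i in range(y.shape[0])]]
        off = np.log(cm.lib_sizes.values)
        grp = np.array([GROUPS9[s] for s in SAMPLES])
        X_full = pd.get_dummies(pd.Series(grp)).values.astype(float)
        merged = np.where(grp == "young_control", "old_control", grp)
        X_red = pd.get_dummies(pd.Series(merged)).values.astype(float)
        for i in range(y.shape[0]):
            fam = sm.families.NegativeBinomial(alpha=phi)
            llf = sm.GLM(y[i], X_full, family=fam, offset=off).fit().llf
            llr = sm.GLM(y[i], X_red, family=fam, offset=off).fit().llf
            lrt = 2 * (llf - llr)
            assert res.age_lrt.iloc[i] == pytest.approx(lrt, abs=1e-5)

    def test_matches_edger_glmlrt_fixed_dispersion(self, tmp_path):
        """Independent oracle: edgeR glmFit/glmLRT at the same dispersion."""
        rng = np.random.default_rng(1)
        y = rng.poisson(rng.gamma(10, 60, size=(40, 9)))
        y[:5, 3:6] = (y[:5, 3:6] * 3.0).astype(int)
        res = fit_and_test(_cm(y), 0.1).loc[[f"L{i}" for i in range(y.shape[0])]]
        counts_tsv = tmp_path / "cnt.tsv"
        pd.DataFrame(y).to_csv(counts_tsv, sep="\t", index=False)
        r = subprocess.run(
            ["Rscript", "-e",
             'suppressMessages(library(edgeR));'
             f'y <- as.matrix(read.delim("{counts_tsv}"));'
             'grp <- factor(rep(c("young","old","oldCR"), each=3),'
             ' levels=c("young","old","oldCR"));'
             'design <- model.matrix(~grp);'
             'fit <- glmFit(y, design, dispersion=0.1,'
             ' offset=rep(log(1e6), 9), prior.count=0);'
             'cat(glmLRT(fit, coef=2)$table$PValue, sep="\\n")'],
            capture_output=True, text=True, check=True,
        )
        edger_p = np.array([float(x) for x in r.stdout.split()])
        assert np.allclose(res.age_p.values, edger_p, atol=1e-6)

    def test_power_monotone_in_fold_change(self):
        rates = []
        for fc in (1.5, 2.5, 4.0):
            rng = np.random.default_rng(42)
            mu = np.full((300, 9), 600.0)
            mu[:, 3:6] *= fc
            y = rng.poisson(rng.gamma(1 / 0.1, 0.1 * mu))
            res = fit_and_test(_cm(y), 0.1)
            rates.append((res.age_p < 0.05).mean())
        assert rates[0] <= rates[1] <= rates[2]

    def test_filtering_does_not_alter_survivor_statistics(self):
        rng = np.random.default_rng(8)
        y = rng.poisson(rng.gamma(10, 80, size=(50, 9)))
        y[25:] //= 50  # low-abundance loci to be filtered
        cm = _cm(y, lib=y.sum(axis=0).astype(float))
        phi = 0.12
        full = fit_and_test(cm, phi)
        survivors = filter_low(cm, min_cpm=500)
        filt = fit_and_test(survivors, phi)
        joined = filt.join(full, how="left", rsuffix="_full")
        assert np.allclose(joined.age_lrt, joined.age_lrt_full, atol=1e-8)
        assert np.allclose(joined.cr_lrt, joined.cr_lrt_full, atol=1e-8)

    def test_group_mean_columns_and_fc_signs(self):
        y = np.array([[100, 100, 100, 400, 400, 400, 200, 200, 200]])
        res = fit_and_test(_cm(y), 0.05)
        assert res.mean_young_control.iloc[0] == 100
        assert res.mean_old_control.iloc[0] == 400
        assert res.mean_old_CR.iloc[0] == 200
        assert res.age_fc.iloc[0] == pytest.approx(4.0)
        assert res.cr_fc.iloc[0] == pytest.approx(-2.0)
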