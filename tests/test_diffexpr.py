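import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from seedtx import diffexpr as de
from seedtx import synthetic_data as sd
from seedtx.io_formats import ExpressionMatrix, SampleDesign, ValidationError


def _em(arr, genes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples))


def brute_force_bh(p):
    """Independent step-up implementation straight from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestFitContrast:
    def test_noiseless_hand_example(self):
        m = _em([[4.0, 4.0, 2.0, 2.0]])
        fit = de.fit_contrast(m, None, ["s0", "s1"], ["s2", "s3"])
        assert fit["estimate"].iloc[0] == pytest.approx(2.0)
        assert fit["s2"].iloc[0] == pytest.approx(0.0)

    def test_pooled_variance_hand_example(self):
        m = _em([[1.0, 3.0, 2.0, 2.0]])
        fit = de.fit_contrast(m, None, ["s0", "s1"], ["s2", "s3"])
        assert fit["estimate"].iloc[0] == pytest.approx(0.0)
        assert fit["s2"].iloc[0] == pytest.approx(1.0)  # (2+0)/2
        assert fit["df"].iloc[0] == 2

    def test_shift_invariance(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=(10, 6))
        m1 = _em(x)
        m2 = _em(x + 5.0)
        a, b = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        pd.testing.assert_series_equal(
            de.fit_contrast(m1, None, a, b)["estimate"],
            de.fit_contrast(m2, None, a, b)["estimate"],
        )

    def test_overlapping_groups_rejected(self):
        m = _em(np.zeros((2, 4)))
        with pytest.raises(ValidationError, match="overlap"):
            de.fit_contrast(m, None, ["s0", "s1"], ["s1", "s2"])


class TestModerate:
    def _sim_fit(self, n=2000, d0=4.0, s0sq=0.05, dg=2, seed=17, effect=0.0):
        rng = np.random.default_rng(seed)
        sig2 = d0 * s0sq / rng.chisquare(d0, n)
        s2 = sig2 * rng.chisquare(dg, n) / dg
        est = rng.normal(effect, np.sqrt(sig2 * 1.0))
        return pd.DataFrame(
            {"estimate": est, "s2": s2, "df": float(dg), "v": 1.0},
            index=[f"g{i}" for i in range(n)],
        )

    def test_homoscedastic_limit_equals_ordinary_t(self):
        fit = self._sim_fit(n=500)
        fit["s2"] = 0.05
        res = de.moderate(fit)
        assert res.attrs["s0sq"] == pytest.approx(0.05, rel=1e-6)
        ordinary = fit["estimate"] / np.sqrt(fit["s2"] * fit["v"])
        np.testing.assert_allclose(res["t"], ordinary, rtol=1e-6)

    def test_hyperparameter_recovery(self):
        fit = self._sim_fit(n=2000, d0=4.0, s0sq=0.05, dg=2, seed=17)
        d0, s0sq = de.estimate_variance_prior(fit["s2"].to_numpy(), 2.0)
        assert 2.5 <= d0 <= 6.0
        assert abs(s0sq - 0.05) / 0.05 <= 0.30

    def test_forced_d0_limits(self):
        fit = self._sim_fit(n=200)
        res0 = de.moderate(fit, d0=0.0, s0sq=0.05)
        ordinary = fit["estimate"] / np.sqrt(np.maximum(fit["s2"], 1e-8) * fit["v"])
        np.testing.assert_allclose(res0["t"], ordinary, rtol=1e-9)
        res_inf = de.moderate(fit, d0=np.inf, s0sq=0.05)
        pooled_z = fit["estimate"] / np.sqrt(0.05 * fit["v"])
        np.testing.assert_allclose(res_inf["t"], pooled_z, rtol=1e-9)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(17)
        n = 10000
        sig2 = 4 * 0.05 / rng.chisquare(4, n)
        x = rng.standard_normal((n, 4)) * np.sqrt(sig2)[:, None] + 8.0
        m = _em(x)
        res = de.moderate(de.fit_contrast(m, None, ["s0", "s1"], ["s2", "s3"]))
        rate = float((res["p"] < 0.01).mean())
        assert 0.005 <= rate <= 0.015

    def test_all_zero_variance_falls_back_with_warning(self):
        fit = pd.DataFrame(
            {"estimate": [1.0, -1.0], "s2": [0.0, 0.0], "df": 2.0, "v": 1.0},
            index=["g1", "g2"],
        )
        with pytest.warns(UserWarning, match="floor"):
            res = de.moderate(fit)
        assert np.isfinite(res["t"]).all()

    def test_agrees_with_limma_reference(self, tmp_path):
        """Dual route: same fixture through Bioconductor limma lmFit+eBayes."""
        rng = np.random.default_rng(3)
        n = 300
        sig2 = 4 * 0.05 / rng.chisquare(4, n)
        eff = np.zeros(n)
        eff[:30] = 1.5
        x = np.hstack(
            [
                rng.standard_normal((n, 3)) * np.sqrt(sig2)[:, None] + 8 + eff[:, None],
                rng.standard_normal((n, 3)) * np.sqrt(sig2)[:, None] + 8,
            ]
        )
        m = _em(x)
        m.data.to_csv(tmp_path / "in.tsv", sep="\t")
        res = de.moderate(
            de.fit_contrast(m, None, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        )
        script = textwrap.dedent(
            f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.delim('{tmp_path / "in.tsv"}', row.names=1))
            design <- cbind(Intercept=1, Grp=c(1,1,1,0,0,0))
            fit <- eBayes(lmFit(x, design))
            out <- data.frame(t=fit$t[,'Grp'], p=fit$p.value[,'Grp'],
                              d0=fit$df.prior, s0sq=fit$s2.prior)
            write.table(out, '{tmp_path / "out.tsv"}', sep='\\t', quote=FALSE)
            """
        )
        (tmp_path / "check.R").write_text(script)
        subprocess.run(
            ["Rscript", str(tmp_path / "check.R")], check=True, capture_output=True
        )
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t", index_col=0)
        np.testing.assert_allclose(res["t"], ref["t"], rtol=1e-8)
        np.testing.assert_allclose(res["p"], ref["p"], rtol=1e-8)
        assert res.attrs["d0"] == pytest.approx(float(ref["d0"].iloc[0]), rel=1e-6)
        assert res.attrs["s0sq"] == pytest.approx(float(ref["s0sq"].iloc[0]), rel=1e-6)


class TestBHFDR:
    def test_hand_examples(self):
        np.testing.assert_allclose(de.bh_fdr([0.005]), [0.005])
        np.testing.assert_allclose(
            de.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            de.bh_fdr([0.0, 0.5])
        with pytest.raises(ValidationError):
            de.bh_fdr([1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-12, 1.0, exclude_min=False), min_size=1, max_size=60))
    def test_matches_brute_force_and_is_monotone(self, plist):
        p = np.asarray(plist)
        q = de.bh_fdr(p)
        np.testing.assert_allclose(q, brute_force_bh(p), rtol=1e-12)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()


class TestCallPredominant:
    def _res(self, q, lfc, genes=("g1",)):
        return pd.DataFrame({"q": q, "estimate": lfc}, index=list(genes))

    def test_single_tissue_and_both(self):
        em = self._res([1e-6], [2.0])
        en = self._res([0.5], [0.1])
        assert de.call_predominant(em, en)["g1"] == "embryo"
        both = de.call_predominant(self._res([1e-6], [2.0]), self._res([1e-6], [1.5]))
        assert both["g1"] == "both"

    def test_q_above_threshold_is_none_despite_large_fold(self):
        em = self._res([0.001], [3.0])
        en = self._res([0.9], [0.0])
        assert de.call_predominant(em, en)["g1"] == "none"

    def test_universe_mismatch_rejected(self):
        with pytest.raises(ValidationError, match="universe"):
            de.call_predominant(
                self._res([0.5], [0.0], genes=("g1",)),
                self._res([0.5], [0.0], genes=("g2",)),
            )


class TestAnovaTimecourse:
    def _design(self, stages, reps=2, tissue="embryo"):
        rows = []
        for s in stages:
            for r in range(1, reps + 1):
                rows.append((f"{tissue}_{s}_r{r}", tissue, s, r, "control"))
        return SampleDesign(
            pd.DataFrame(
                {
                    "tissue": [r[1] for r in rows],
                    "stage": [r[2] for r in rows],
                    "replicate": [r[3] for r in rows],
                    "treatment": [r[4] for r in rows],
                },
                index=pd.Index([r[0] for r in rows], name="sample_id"),
            )
        )

    def test_degenerate_flat_gene(self):
        design = self._design([3, 6, 9])
        m = _em(np.full((1, 6), 5.0), samples=design.sample_ids)
        res = de.anova_timecourse(m, design, "embryo")
        assert res["F"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0

    def test_matches_brute_force_f_on_random_toys(self):
        rng = np.random.default_rng(17)
        design = self._design([3, 6, 9, 12])
        for _ in range(200):
            x = rng.normal(size=(1, 8))
            m = _em(x, samples=design.sample_ids)
            res = de.anova_timecourse(m, design, "embryo")
            groups = [x[0, 2 * i : 2 * i + 2] for i in range(4)]
            f_ref, p_ref = stats.f_oneway(*groups)
            assert res["F"].iloc[0] == pytest.approx(f_ref, rel=1e-10)
            assert res["p"].iloc[0] == pytest.approx(p_ref, rel=1e-10)

    def test_planted_monotone_gene_detected_with_direction(self):
        rng = np.random.default_rng(17)
        design = self._design([3, 6, 9, 12])
        offsets = np.repeat([0.0, 1.0, 2.0, 3.0], 2)
        x = (offsets + rng.normal(0, 0.1, size=8))[None, :]
        m = _em(x, samples=design.sample_ids)
        res = de.anova_timecourse(m, design, "embryo")
        assert res["p"].iloc[0] < 0.001
        assert res["direction"].iloc[0] == "up"

    def test_too_few_stages_rejected(self):
        design = self._design([3, 6])
        m = _em(np.zeros((1, 4)), samples=design.sample_ids)
        with pytest.raises(ValidationError, match="stages"):
            de.anova_timecourse(m, design, "embryo")


class TestColdRegulation:
    def test_swapping_pair_swaps_up_and_down(self):
        rng = np.random.default_rng(17)
        x = rng.normal(8, 1, size=(300, 4)) + np.array([1.0, 1.0, 0.0, 0.0]) * \
            rng.choice([0, 2, -2], size=(300, 1), p=[0.8, 0.1, 0.1])
        m = _em(x)
        fwd = de.call_cold_regulated(m, None, [(["s0", "s1"], ["s2", "s3"])])
        rev = de.call_cold_regulated(m, None, [(["s2", "s3"], ["s0", "s1"])])
        assert fwd[0]["up"] == rev[0]["down"]
        assert fwd[0]["down"] == rev[0]["up"]

    def test_planted_down_sensitivity(self):
        cfg = sd.SimulationConfig(n_genes=2000, n_cold_down=200, n_cold_up=50)
        m, design, truth, pairs = sd.simulate_cold_experiment(cfg, seed=17)
        results = de.call_cold_regulated(m, design, pairs)
        planted_down_4 = {
            g for g, (s, d, _e) in truth.cold.items() if s == 4 and d == "down"
        }
        hit = len(planted_down_4 & results[0]["down"]) / len(planted_down_4)
        assert hit >= 0.9

    def test_null_counts_within_bounds(self):
        rng = np.random.default_rng(17)
        n = 3000
        sig2 = 4 * 0.05 / rng.chisquare(4, n)
        x = rng.standard_normal((n, 4)) * np.sqrt(sig2)[:, None] + 8
        m = _em(x)
        res = de.call_cold_regulated(m, None, [(["s0", "s1"], ["s2", "s3"])])
        # p<0.05 two-sided AND |log2FC|>1: far fewer than alpha*m expected
        assert len(res[0]["up"]) + len(res[0]["down"]) <= 0.05 * 2 * n


class TestTrendConcordance:
    def test_hand_count(self):
        a = {"g1": "up", "g2": "down", "g3": "up"}
        b = {"g2": "down", "g3": "down", "g4": "up"}
        common, n, frac = de.trend_concordance(a, b)
        assert common == ["g2", "g3"] and n == 2 and frac == 0.5

    def test_identity_and_empty(self):
        a = {"g1": "up"}
        assert de.trend_concordance(a, a)[2] == 1.0
        assert de.trend_concordance(a, {"g9": "down"}) == ([], 0, None)

    def test_invalid_direction_rejected(self):
        with pytest.raises(ValidationError):
            de.trend_concordance({"g1": "higher"}, {"g1": "up"})

    def test_independent_replicates_of_same_truth_agree(self):
        """Two noisy resamplings of one planted truth (the two-cultivar
        comparison setting) agree on >=80% of common regulated genes."""
        cfg = sd.SimulationConfig(n_genes=1500)
        m1, design, truth = sd.simulate_compendium(cfg, seed=17)
        m2, _, _ = sd.simulate_compendium(cfg, seed=18, truth=truth)
        dirs = []
        for m in (m1, m2):
            res = de.anova_timecourse(m, design, "embryo")
            dirs.append(de.timecourse_regulated(res))
        _, n_common, frac = de.trend_concordance(dirs[0], dirs[1])
        assert n_common >= 10
        assert frac >= 0.8
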