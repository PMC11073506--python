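"""TPM normalization identities, the moderated linear model, the NB GLM
route (against an independent statsmodels refit), and signature selection."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import sigrev as sr
from sigrev.diffexp import _nb_irls, _moment_dispersions, size_factors
from sigrev._stats import build_design, fit_moderated_lm, adjust_pvalues


def make_study(counts, lengths=None, condition=None, database=None):
    counts = np.asarray(counts)
    g, n = counts.shape
    genes = [f"g{i}" for i in range(g)]
    samples = [f"s{j}" for j in range(n)]
    return sr.ExpressionStudy(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        gene_lengths=pd.Series(
            lengths if lengths is not None else np.ones(g), index=genes
        ),
        condition=pd.Series(
            condition if condition is not None else [1] * (n // 2) + [0] * (n - n // 2),
            index=samples,
        ),
        database=pd.Series(
            database if database is not None else ["db0"] * n, index=samples
        ),
    )


class TestTpmLog:
    def test_equal_rates_give_equal_tpm(self):
        study = make_study([[10], [20]], lengths=[1.0, 2.0],
                           condition=[1], database=["db0"])
        tpm = 2 ** sr.tpm_log(study).to_numpy() - 1
        assert tpm[0, 0] == pytest.approx(5e5)
        assert tpm[1, 0] == pytest.approx(5e5)

    def test_zero_count_gives_zero_log(self):
        study = make_study([[0, 5], [3, 7]], condition=[1, 0])
        assert sr.tpm_log(study).iloc[0, 0] == 0.0

    def test_columns_sum_to_one_million(self, rng):
        counts = rng.integers(0, 500, size=(5, 3))
        counts[0] += 1        # keep every column nonzero
        study = make_study(counts, lengths=rng.uniform(0.5, 10, 5),
                           condition=[1, 1, 0], database=["a", "a", "a"])
        tpm = 2 ** sr.tpm_log(study).to_numpy() - 1
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(scale=st.integers(min_value=2, max_value=50))
    def test_invariant_to_scaling_one_sample(self, scale):
        counts = np.array([[5, 9], [11, 3], [2, 8]])
        scaled = counts.copy()
        scaled[:, 0] *= scale
        a = sr.tpm_log(make_study(counts, condition=[1, 0]))
        b = sr.tpm_log(make_study(scaled, condition=[1, 0]))
        assert np.allclose(a.to_numpy(), b.to_numpy())

    def test_all_zero_sample_names_the_column(self):
        study = make_study([[0, 5], [0, 7]], condition=[1, 0])
        with pytest.raises(ValueError, match="s0"):
            sr.tpm_log(study)


class TestModeratedLm:
    def test_identical_groups_give_null_result(self):
        Y = pd.DataFrame(np.tile([[3.0, 3.0, 3.0, 3.0]], (4, 1)))
        res = sr.moderated_lm_de(
            Y, pd.Series([1, 1, 0, 0]), pd.Series(["a"] * 4)
        )
        assert (res.table["log2fc"] == 0).all()
        assert (res.table["p"] == 1).all()

    def test_unmoderated_equals_ordinary_t(self, rng):
        Y = rng.normal(size=(30, 12))
        cond = np.array([1] * 6 + [0] * 6)
        X, _ = build_design(cond, np.array(["a"] * 12))
        fit = fit_moderated_lm(Y, X, moderate=False)
        t_ref = stats.ttest_ind(Y[:, :6], Y[:, 6:], axis=1).statistic
        assert np.allclose(fit.t, t_ref, rtol=1e-10)

    def test_constant_database_matches_one_covariate_model(self, rng):
        Y = rng.normal(size=(20, 10))
        cond = np.array([1] * 5 + [0] * 5)
        res = sr.moderated_lm_de(
            pd.DataFrame(Y), pd.Series(cond), pd.Series(["only"] * 10)
        )
        diff = Y[:, :5].mean(axis=1) - Y[:, 5:].mean(axis=1)
        assert np.allclose(res.table["log2fc"], diff, atol=1e-10)

    def test_confounded_design_rejected(self, rng):
        Y = pd.DataFrame(rng.normal(size=(5, 8)))
        cond = pd.Series([1] * 4 + [0] * 4)
        db = pd.Series(["t"] * 4 + ["n"] * 4)   # database == condition
        with pytest.raises(ValueError, match="confounded"):
            sr.moderated_lm_de(Y, cond, db)

    def test_null_simulation_calibrated(self):
        cfg = sr.SimConfig(seed=77, frac_de=0.0, n_genes=2000,
                           n_tumor=20, n_control=20)
        study, _ = sr.simulate_expression_study(cfg)
        res = sr.moderated_lm_de(
            sr.tpm_log(study), study.condition, study.database
        )
        frac = (res.table["p"] < 0.05).mean()
        band = 3 * np.sqrt(0.05 * 0.95 / 2000)
        assert abs(frac - 0.05) < band + 0.005

    def test_adjusted_never_below_raw(self, nb_de):
        tab = nb_de.table.dropna()
        assert (tab["p_adj"] >= tab["p"] - 1e-12).all()


class TestNbGlm:
    def test_size_factor_pure_depth(self):
        counts = np.array([[10, 20], [4, 8], [7, 14]])
        sf = size_factors(counts)
        assert sf[1] / sf[0] == pytest.approx(2.0)

    def test_size_factor_identical_samples(self):
        counts = np.tile([[8], [3], [11]], (1, 4))
        assert np.allclose(size_factors(counts), 1.0)

    def test_non_integer_counts_rejected(self):
        study = make_study(np.ones((3, 4)), condition=[1, 1, 0, 0])
        study.counts.iloc[0, 0] = 1.5
        with pytest.raises(ValueError, match="integer"):
            sr.nb_glm_de(study)

    def test_wald_agrees_with_statsmodels_refit(self, sim_study, rng):
        """Independent per-gene NB refit (statsmodels GLM, same dispersion)
        must reproduce the batched IRLS Wald statistic within 1%."""
        import statsmodels.api as sm

        study, _ = sim_study
        counts = study.counts.to_numpy().astype(float)
        cond = np.asarray(study.condition)
        db = np.asarray(study.database)
        X, _ = build_design(cond, db)
        sf = size_factors(counts)
        cells = np.array([f"{c}|{d}" for c, d in zip(cond, db)])
        alpha = _moment_dispersions(counts, sf, cells)
        pick = rng.choice(counts.shape[0], size=20, replace=False)
        beta, cov, conv = _nb_irls(counts[pick], X, np.log(sf), alpha[pick])
        for row, g in enumerate(pick):
            model = sm.GLM(
                counts[g], X,
                family=sm.families.NegativeBinomial(alpha=alpha[g]),
                offset=np.log(sf),
            ).fit()
            ours = beta[row, 1] / np.sqrt(cov[row, 1, 1])
            theirs = model.params[1] / model.bse[1]
            assert ours == pytest.approx(theirs, rel=0.01)

    def test_planted_genes_recovered(self, sim_study, nb_de):
        study, truth = sim_study
        hits = set(nb_de.table.index[nb_de.table["p_adj"] < 0.05])
        sens = len(hits & truth.de_genes) / len(truth.de_genes)
        fdr = len(hits - truth.de_genes) / max(len(hits), 1)
        assert sens >= 0.8
        assert fdr <= 0.1

    def test_shrunken_lfc_smaller_than_planted(self, sim_study, nb_de):
        """The ridge prior pulls fold changes toward zero, never past the
        planted magnitude on average."""
        study, truth = sim_study
        planted = nb_de.table.loc[sorted(truth.de_genes)]
        assert planted["log2fc"].abs().mean() < 2.0 + 0.2
        signs = pd.Series(truth.de_signs)
        agree = np.sign(planted["log2fc"]) == signs.loc[planted.index]
        assert agree.mean() > 0.95


class TestBuildSignature:
    def _de(self, lfc, padj=None, method="moderated_lm"):
        genes = list(lfc)
        tab = pd.DataFrame(
            {
                "log2fc": [lfc[g] for g in genes],
                "se": 1.0,
                "stat": 0.0,
                "p": 0.001,
                "p_adj": [0.001 if padj is None else padj[g] for g in genes],
            },
            index=genes,
        )
        return sr.DifferentialResult(table=tab, method=method, adjust="bh")

    def test_exhaustive_three_genes(self):
        de = self._de({"a": 5.0, "b": -4.0, "c": 1.0})
        sig = sr.build_de_signature(de, {"a", "b", "c"}, n_min=1, n_max=3,
                                    n_target=3)
        assert sig.up == ["a", "c"]
        assert sig.down == ["b"]

    def test_out_of_universe_gene_replaced_by_next(self):
        de = self._de({"a": 5.0, "b": -4.0, "c": 1.0, "d": 0.5})
        sig = sr.build_de_signature(de, {"b", "c", "d"}, n_min=1, n_max=3,
                                    n_target=3)
        assert "a" not in sig.up
        assert sig.up == ["c", "d"]
        assert sig.down == ["b"]

    def test_tie_broken_lexicographically(self):
        de = self._de({"zz": 2.0, "aa": -2.0, "mm": 2.0})
        sig = sr.build_de_signature(de, {"zz", "aa", "mm"}, n_min=1, n_max=3,
                                    n_target=2)
        assert sig.up == ["aa"] or sig.down == ["aa"]  # aa ranks first
        assert sig.size == 2
        assert sig.down == ["aa"]
        assert sig.up == ["mm"]

    def test_planted_signature_within_size_band(self, nb_de, sim_reference):
        ref, _, _ = sim_reference
        sig = sr.build_de_signature(nb_de, set(ref.gene_ids))
        assert 90 <= sig.size <= 120
        assert not set(sig.up) & set(sig.down)

    def test_too_few_significant_flags_warning(self):
        de = self._de({"a": 5.0, "b": -1.0})
        sig = sr.build_de_signature(de, {"a", "b"}, n_min=90, n_max=120,
                                    n_target=100)
        assert sig.warning is not None
        assert sig.size == 2

    def test_no_significant_gives_empty_signature(self):
        de = self._de({"a": 5.0}, padj={"a": 0.9})
        sig = sr.build_de_signature(de, {"a"}, n_min=1, n_max=3, n_target=1)
        assert sig.size == 0


def test_bh_adjustment_matches_scipy(rng):
    p = rng.uniform(size=40)
    ours = adjust_pvalues(p, "bh")
    theirs = stats.false_discovery_control(p, method="bh")
    assert np.allclose(ours, theirs)
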