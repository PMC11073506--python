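"""Latent projection algebra, the 3-SD effect rule, LV testing, signature
assembly, and the gene-label-switch validation experiment."""
import numpy as np
import pandas as pd
import pytest

import sigrev as sr
from sigrev.latent import standardize_rows


def _activity(B, cond, db=None):
    n = B.shape[1]
    return sr.LatentActivity(
        B=pd.DataFrame(B, index=[f"LV{i}" for i in range(B.shape[0])]),
        condition=pd.Series(cond),
        database=pd.Series(db if db is not None else ["a"] * n),
    )


class TestProjectLatent:
    def test_identity_loadings_return_standardized_expression(self, rng):
        Y = pd.DataFrame(rng.normal(size=(6, 8)),
                         index=[f"g{i}" for i in range(6)])
        Z = pd.DataFrame(np.eye(6), index=Y.index,
                         columns=[f"LV{i}" for i in range(6)])
        act = sr.project_latent(Y, Z, pd.Series([1] * 4 + [0] * 4),
                                pd.Series(["a"] * 8), ridge=0.0)
        assert np.allclose(act.B.to_numpy(), standardize_rows(Y.to_numpy()))

    def test_huge_ridge_shrinks_activity_to_zero(self, rng):
        Y = pd.DataFrame(rng.normal(size=(5, 6)),
                         index=[f"g{i}" for i in range(5)])
        Z = pd.DataFrame(rng.uniform(size=(5, 3)), index=Y.index)
        act = sr.project_latent(Y, Z, pd.Series([1, 1, 1, 0, 0, 0]),
                                pd.Series(["a"] * 6), ridge=1e12)
        assert np.abs(act.B.to_numpy()).max() < 1e-6

    def test_orthonormal_loadings_reduce_to_plain_projection(self, rng):
        Y = pd.DataFrame(rng.normal(size=(8, 10)),
                         index=[f"g{i}" for i in range(8)])
        Q, _ = np.linalg.qr(rng.normal(size=(8, 3)))
        Z = pd.DataFrame(Q, index=Y.index)
        act = sr.project_latent(Y, Z, pd.Series([1] * 5 + [0] * 5),
                                pd.Series(["a"] * 10), ridge=0.0)
        expected = Q.T @ standardize_rows(Y.to_numpy())
        assert np.allclose(act.B.to_numpy(), expected, atol=1e-8)

    def test_disjoint_gene_universes_rejected(self, rng):
        Y = pd.DataFrame(rng.normal(size=(3, 4)), index=["a", "b", "c"])
        Z = pd.DataFrame(rng.uniform(size=(2, 2)), index=["x", "y"])
        with pytest.raises(ValueError, match="shared genes"):
            sr.project_latent(Y, Z, pd.Series([1, 1, 0, 0]),
                              pd.Series(["a"] * 4))


class TestThreeSdCutoff:
    def test_reproduces_printed_bounds_example(self):
        # two effects whose mean +/- 3 SD bounds are exactly 0.27 and -0.23
        x = 0.25 / (3 * np.sqrt(2.0))
        effects = np.array([0.02 + x, 0.02 - x])
        assert np.mean(effects) + 3 * np.std(effects, ddof=1) == pytest.approx(0.27)
        assert np.mean(effects) - 3 * np.std(effects, ddof=1) == pytest.approx(-0.23)
        assert sr.three_sd_cutoff(effects) == 0.25

    def test_symmetric_effects_give_three_sd(self, rng):
        e = rng.normal(size=500)
        e = np.r_[e, -e]                       # exactly mean zero
        s = e.std(ddof=1)
        assert sr.three_sd_cutoff(e) == round(3 * s, 2)

    def test_degenerate_constant_effects(self):
        assert sr.three_sd_cutoff(np.array([0.1, 0.1, 0.1])) == 0.10

    def test_fewer_than_two_effects_rejected(self):
        with pytest.raises(ValueError):
            sr.three_sd_cutoff(np.array([0.5]))


class TestDifferentialLv:
    def test_constant_activity_row_is_null(self, rng):
        B = np.vstack([np.full(8, 2.0), rng.normal(size=8)])
        ld = sr.differential_lv(_activity(B, [1] * 4 + [0] * 4),
                                effect_cutoff=0.0)
        assert ld.table["effect"].iloc[0] == 0
        assert ld.table["p"].iloc[0] == 1

    def test_significance_requires_both_rules(self, rng):
        B = rng.normal(size=(10, 20)) * 0.01
        B[0, :10] += 5.0                        # strong condition effect
        ld = sr.differential_lv(_activity(B, [1] * 10 + [0] * 10))
        tab = ld.table
        assert bool(tab["significant"].iloc[0])
        expected = (tab["p_adj"] < 0.05) & (tab["effect"].abs() >= ld.cutoff)
        assert (tab["significant"] == expected).all()

    def test_planted_active_lvs_recovered(self, sim_study, sim_loadings):
        study, _ = sim_study
        Z, active = sim_loadings
        act = sr.project_latent(sr.tpm_log(study), Z,
                                study.condition, study.database)
        ld = sr.differential_lv(act)
        assert set(ld.significant_lvs) == active
        assert (ld.table.loc[sorted(active), "p_adj"] < 0.05).all()

    def test_null_activity_rarely_significant(self, rng):
        hits = 0
        for _ in range(20):
            B = rng.normal(size=(15, 16))
            ld = sr.differential_lv(_activity(B, [1] * 8 + [0] * 8),
                                    effect_cutoff=0.0)
            hits += (ld.table["p_adj"] < 0.05).any()
        assert hits <= 2


class TestTopWeightedGenes:
    def _Z(self):
        return pd.DataFrame(
            {"LV0": [3.0, 2.0, 1.0, 0.0], "LV1": [2.0, 2.0, 0.0, 1.0]},
            index=["a", "b", "c", "d"],
        )

    def test_orders_by_weight(self):
        assert sr.top_weighted_genes(self._Z(), "LV0", k=2) == ["a", "b"]

    def test_tie_broken_by_gene_id(self):
        assert sr.top_weighted_genes(self._Z(), "LV1", k=2) == ["a", "b"]

    def test_k_beyond_nonzero_returns_all_nonzero(self):
        got = sr.top_weighted_genes(self._Z(), "LV0", k=10)
        assert got == ["a", "b", "c"]

    def test_unknown_lv_rejected(self):
        with pytest.raises(KeyError):
            sr.top_weighted_genes(self._Z(), "LV9")


class TestBuildTlSignature:
    def _parts(self, effects, Z, lfc):
        tab = pd.DataFrame(
            {
                "effect": list(effects.values()),
                "se": 0.1,
                "p": 1e-9,
                "p_adj": 1e-8,
                "significant": True,
            },
            index=list(effects),
        )
        ld = sr.LatentDifferential(table=tab, cutoff=0.0)
        de = sr.DifferentialResult(
            table=pd.DataFrame(
                {"log2fc": pd.Series(lfc), "se": 1.0, "stat": 0.0,
                 "p": 0.01, "p_adj": 0.01}
            ),
            method="nb_glm", adjust="bh",
        )
        return ld, de

    def test_single_lv_takes_its_top_genes(self):
        Z = pd.DataFrame({"LV0": [5.0, 4.0, 3.0, 2.0, 1.0, 0.5]},
                         index=list("abcdef"))
        lfc = {g: 1.0 for g in "abcdef"}
        ld, de = self._parts({"LV0": 1.0}, Z, lfc)
        sig = sr.build_tl_signature(ld, Z, de, set("abcdef"), n_target=5)
        assert sorted(sig.up) == list("abcde")

    def test_shared_top_gene_appears_once(self):
        Z = pd.DataFrame({"LV0": [5.0, 1.0, 0.0], "LV1": [5.0, 0.0, 1.0]},
                         index=["shared", "b", "c"])
        lfc = {"shared": 1.0, "b": -1.0, "c": 1.0}
        ld, de = self._parts({"LV0": 2.0, "LV1": 1.0}, Z, lfc)
        sig = sr.build_tl_signature(ld, Z, de, {"shared", "b", "c"}, n_target=3)
        assert (sig.up + sig.down).count("shared") == 1
        assert sig.size == 3

    def test_zero_or_missing_fold_change_skipped(self):
        Z = pd.DataFrame({"LV0": [5.0, 4.0, 3.0]}, index=["a", "b", "c"])
        ld, de = self._parts({"LV0": 1.0}, Z, {"a": 0.0, "c": -2.0})
        sig = sr.build_tl_signature(ld, Z, de, {"a", "b", "c"}, n_target=2)
        assert sig.up == []
        assert sig.down == ["c"]

    def test_no_significant_lv_gives_empty_signature(self):
        Z = pd.DataFrame({"LV0": [1.0]}, index=["a"])
        ld, de = self._parts({"LV0": 1.0}, Z, {"a": 1.0})
        ld.table["significant"] = False
        sig = sr.build_tl_signature(ld, Z, de, {"a"})
        assert sig.size == 0
        assert sig.warning is not None

    def test_full_pipeline_reaches_exact_target(self, sim_study, sim_loadings,
                                                nb_de):
        study, _ = sim_study
        Z, _ = sim_loadings
        act = sr.project_latent(sr.tpm_log(study), Z,
                                study.condition, study.database)
        ld = sr.differential_lv(act)
        sig = sr.build_tl_signature(ld, Z, nb_de, set(study.gene_ids),
                                    n_target=100)
        assert sig.size == 100


class TestLabelSwitch:
    @pytest.fixture(scope="class")
    @staticmethod
    def small():
        cfg = sr.SimConfig(seed=13, n_genes=1200, frac_de=0.05, n_tumor=15,
                           n_control=15, n_lvs=30, lv_sparsity=0.02,
                           n_active_lvs=4)
        study, _ = sr.simulate_expression_study(cfg)
        Z, _ = sr.simulate_latent_loadings(cfg)
        return study, Z

    def test_seeded_runs_identical(self, small):
        study, Z = small
        kw = dict(fractions=np.array([0.5, 1.0]), reps=3, seed=42)
        a = sr.label_switch_validation(study, Z, **kw)
        b = sr.label_switch_validation(study, Z, **kw)
        pd.testing.assert_frame_equal(a, b)

    def test_baseline_matches_unpermuted_count(self, small):
        study, Z = small
        curve = sr.label_switch_validation(
            study, Z, fractions=np.array([1.0]), reps=2, seed=0
        )
        act = sr.project_latent(sr.tpm_log(study), Z,
                                study.condition, study.database)
        ld = sr.differential_lv(act, effect_cutoff=0.05)
        base = curve[curve["fraction"] == 0.0]["mean_significant"].iloc[0]
        assert base == len(ld.significant_lvs)

    def test_slope_negative_on_planted_data(self, small):
        study, Z = small
        curve = sr.label_switch_validation(
            study, Z, fractions=np.array([0.3, 0.6, 1.0]), reps=5, seed=1
        )
        assert curve.attrs["regression"]["slope"] < 0

    def test_too_few_reps_rejected(self, small):
        study, Z = small
        with pytest.raises(ValueError):
            sr.label_switch_validation(study, Z, reps=1)
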