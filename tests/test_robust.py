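import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgxmeta import (
    ModelSpec,
    cr2_vcov,
    fit_che,
    fit_interaction,
    holm_adjust,
    impute_sampling_covariance,
    phenotype_contrast_battery,
    wald_contrast,
)

from conftest import make_corpus


def _identity_working_fit(smds):
    """Singleton clusters, unit variances, all components pinned at zero:
    the working covariance is the identity and GLS collapses to OLS."""
    corpus = make_corpus(list(smds), variances=[1.0] * len(smds))
    vm = impute_sampling_covariance(corpus, 0.0)
    return fit_che(
        ModelSpec(response="signed_smd", moderators="intercept_only",
                  random_structure="nested_two_level"),
        corpus, vm, fix_components={"tau2": 0.0, "sigma2": 0.0},
    )


class TestCR2:
    def test_equals_hc2_on_singleton_clusters(self):
        """With one record per cluster and identity weights, CR2 reduces to
        the HC2 leverage-adjusted heteroskedasticity estimator."""
        rng = np.random.default_rng(11)
        y = rng.normal(0.3, 1.0, 10)
        fit = _identity_working_fit(y)
        rfit = cr2_vcov(fit)

        import statsmodels.api as sm

        ols = sm.OLS(y, np.ones((10, 1))).fit(cov_type="HC2")
        assert rfit.se[0] == pytest.approx(np.sqrt(ols.cov_params()[0][0]), rel=1e-10)

    def test_satterthwaite_df_on_balanced_singletons(self):
        # intercept-only, identical leverages: df should be close to J - 1
        y = np.linspace(-1, 1, 12)
        rfit = cr2_vcov(_identity_working_fit(y))
        assert rfit.df[0] == pytest.approx(11, abs=0.1)

    def test_fewer_than_two_clusters_rejected(self):
        corpus = make_corpus([0.1, 0.2], studies=["s", "s"])
        vm = impute_sampling_covariance(corpus, 0.0)
        fit = fit_che(
            ModelSpec(response="signed_smd", moderators="intercept_only",
                      random_structure="nested_two_level"),
            corpus, vm, fix_components={"tau2": 0.0, "sigma2": 0.0},
        )
        with pytest.raises(ValueError, match="clusters"):
            cr2_vcov(fit)

    def test_invariant_to_cluster_relabeling(self, sim_corpus_small):
        from pgxmeta import fit_primary_pair

        corpus = sim_corpus_small.corpus
        relabeled = corpus.select(np.ones(len(corpus), bool))
        relabeled.df["study_id"] = "x_" + relabeled.df["study_id"]
        a = cr2_vcov(fit_primary_pair(corpus, response="signed_smd")[0])
        b = cr2_vcov(fit_primary_pair(relabeled, response="signed_smd")[0])
        assert np.allclose(a.se, b.se, atol=1e-8)
        assert np.allclose(a.df, b.df, atol=1e-6)


@pytest.fixture(scope="module")
def interaction_rfit(sim_corpus_small):
    return cr2_vcov(fit_interaction(sim_corpus_small.corpus, response="signed_smd"))


class TestWaldContrast:
    def test_unit_contrast_reproduces_coefficient(self, interaction_rfit):
        rfit = interaction_rfit
        w = np.zeros(8)
        w[3] = 1.0
        res = wald_contrast(rfit, w)
        assert res.estimate == pytest.approx(rfit.base.beta[3])
        assert res.se == pytest.approx(rfit.se[3])
        assert res.df == pytest.approx(rfit.df[3])
        assert res.p == pytest.approx(rfit.p[3])

    def test_contrast_linear_in_beta(self, interaction_rfit):
        w1 = np.zeros(8); w1[0] = 1.0
        w2 = np.zeros(8); w2[4] = -1.0
        a = wald_contrast(interaction_rfit, w1)
        b = wald_contrast(interaction_rfit, w2)
        c = wald_contrast(interaction_rfit, w1 + w2)
        assert c.estimate == pytest.approx(a.estimate + b.estimate)

    def test_difference_contrast_equals_intercept_model(self, sim_corpus_small):
        from pgxmeta import fit_primary_pair

        no_int, with_int = fit_primary_pair(sim_corpus_small.corpus, response="signed_smd")
        r_no = cr2_vcov(no_int)
        res = wald_contrast(r_no, [-1.0, 1.0])
        assert res.estimate == pytest.approx(with_int.beta[1], abs=1e-5)

    def test_all_zero_weights_rejected(self, interaction_rfit):
        with pytest.raises(ValueError):
            wald_contrast(interaction_rfit, np.zeros(8))


class TestHolm:
    def test_hand_worked_example(self):
        assert holm_adjust([0.01, 0.03, 0.04]) == pytest.approx([0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones_capped(self):
        assert holm_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    @settings(deadline=None, max_examples=100)
    def test_matches_statsmodels_and_dominates_raw(self, ps):
        from statsmodels.stats.multitest import multipletests

        ours = holm_adjust(ps)
        _, theirs, _, _ = multipletests(ps, method="holm")
        assert np.allclose(ours, theirs, atol=1e-12)
        assert np.all(ours >= np.asarray(ps) - 1e-15)
        order = np.argsort(ps)
        assert np.all(np.diff(ours[order]) >= -1e-15)


class TestContrastBattery:
    def test_row_count_and_families(self, sim_corpus_small):
        rfit = cr2_vcov(fit_interaction(sim_corpus_small.corpus, response="signed_smd"))
        table = phenotype_contrast_battery(rfit)
        assert len(table) == 16
        counts = table.groupby("family").size().to_dict()
        assert counts == {"within_proximal": 6, "within_distal": 6,
                          "distal_vs_proximal": 4}
        assert (table["p_holm"] >= table["p"] - 1e-12).all()

    def test_exact_null_all_adjusted_to_one(self):
        # identical cell estimates, all components zero: contrasts vanish
        smds, outcomes, phenos, studies = [], [], [], []
        i = 0
        for out in ("proximal", "distal"):
            for phe in ("poor", "intermediate", "rapid", "ultrarapid"):
                for r in range(3):
                    smds.append(0.4)
                    outcomes.append(out)
                    phenos.append(phe)
                    studies.append(f"s{i}_{r}")
                i += 1
        corpus = make_corpus(smds, variances=[0.05] * len(smds), studies=studies,
                             outcomes=outcomes, phenotypes=phenos)
        vm = impute_sampling_covariance(corpus, 0.0)
        fit = fit_che(
            ModelSpec(response="signed_smd", moderators="outcome_phenotype_interaction",
                      random_structure="nested_two_level"),
            corpus, vm, fix_components={"tau2": 0.0, "sigma2": 0.0},
        )
        table = phenotype_contrast_battery(cr2_vcov(fit))
        assert np.allclose(table["estimate"], 0.0, atol=1e-10)
        assert np.allclose(table["p_holm"], 1.0)

    def test_planted_poor_proximal_signal_dominates(self):
        from pgxmeta import SimConfig, simulate_corpus

        sim = simulate_corpus(SimConfig(n_studies=80, seed=21))
        corpus = sim.corpus
        # inflate poor-phenotype proximal effects strongly
        mask = (corpus.df["phenotype"] == "poor") & (corpus.df["outcome_label"] == "proximal")
        corpus.df.loc[mask, "smd"] += 1.5
        rfit = cr2_vcov(fit_interaction(corpus, response="signed_smd"))
        table = phenotype_contrast_battery(rfit)
        best = table.loc[table["p_holm"].idxmin(), "test"]
        assert "poor" in best
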