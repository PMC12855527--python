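import numpy as np
import pytest

from pgxmeta import (
    ModelSpec,
    SimConfig,
    fit_che,
    fit_interaction,
    fit_primary_pair,
    impute_sampling_covariance,
    prediction_interval,
    profile_component,
    simulate_corpus,
)

from conftest import make_corpus


class TestSamplingCovariance:
    def test_singleton_block(self):
        corpus = make_corpus([0.3], variances=[0.04])
        vm = impute_sampling_covariance(corpus, 0.6)
        ids, block = vm.blocks["s0"]
        assert block.shape == (1, 1)
        assert block[0, 0] == pytest.approx(0.04)

    def test_off_diagonal_formula(self):
        corpus = make_corpus([0.3, 0.4], variances=[0.04, 0.09], studies=["s", "s"])
        vm = impute_sampling_covariance(corpus, 0.6)
        _, block = vm.blocks["s"]
        assert block[0, 1] == pytest.approx(0.6 * np.sqrt(0.04 * 0.09))  # 0.036
        assert np.allclose(np.diag(block), [0.04, 0.09])

    @pytest.mark.parametrize("rho", [0.0, 0.2, 0.4, 0.6, 0.8])
    def test_blocks_positive_definite(self, rho, sim_corpus_small):
        vm = impute_sampling_covariance(sim_corpus_small.corpus, rho)
        for _, block in vm.blocks.values():
            assert np.linalg.eigvalsh(block).min() > 0

    def test_rho_domain(self, sim_corpus_small):
        with pytest.raises(ValueError):
            impute_sampling_covariance(sim_corpus_small.corpus, 1.0)


def _reml_ll_dense(y, X, V, cluster, tau2, sigma2):
    """Independent dense-matrix restricted log-likelihood (oracle path)."""
    n, p = X.shape
    same = np.equal.outer(cluster, cluster).astype(float)
    Sigma = V + sigma2 * np.eye(n) + tau2 * same
    Si = np.linalg.inv(Sigma)
    XtSiX = X.T @ Si @ X
    beta = np.linalg.solve(XtSiX, X.T @ Si @ y)
    r = y - X @ beta
    _, ld_S = np.linalg.slogdet(Sigma)
    _, ld_X = np.linalg.slogdet(XtSiX)
    return -0.5 * ((n - p) * np.log(2 * np.pi) + ld_S + ld_X + r @ Si @ r)


class TestREMLOracle:
    def test_fixed_effect_reduction(self):
        """With every variance component pinned at zero and rho = 0 the CHE
        fit is the closed-form inverse-variance weighted mean."""
        corpus = make_corpus([0.0, 1.0, 2.0], variances=[1.0, 1.0, 1.0])
        vm = impute_sampling_covariance(corpus, 0.0)
        fit = fit_che(
            ModelSpec(response="signed_smd", moderators="intercept_only",
                      random_structure="nested_two_level"),
            corpus, vm, fix_components={"tau2": 0.0, "sigma2": 0.0},
        )
        assert fit.beta[0] == pytest.approx(1.0)
        assert fit.se[0] == pytest.approx(np.sqrt(1 / 3))

    def test_matches_grid_search_on_six_effect_toy(self):
        """REML optimum agrees with brute-force grid search of the dense
        restricted likelihood over (tau2, sigma2) to 3 decimals."""
        rng = np.random.default_rng(7)
        smds = [0.9, 0.4, 0.1, 0.55, 0.35, 0.72]
        variances = [0.05, 0.08, 0.04, 0.06, 0.09, 0.07]
        studies = ["a", "a", "b", "b", "c", "c"]
        corpus = make_corpus(smds, variances=variances, studies=studies)
        vm = impute_sampling_covariance(corpus, 0.6)
        spec = ModelSpec(response="signed_smd", moderators="intercept_only",
                         random_structure="nested_two_level")
        fit = fit_che(spec, corpus, vm)

        y = np.asarray(smds)
        X = np.ones((6, 1))
        V = np.zeros((6, 6))
        cl = np.asarray(studies)
        for i in range(6):
            for j in range(6):
                if cl[i] == cl[j]:
                    V[i, j] = (variances[i] if i == j
                               else 0.6 * np.sqrt(variances[i] * variances[j]))
        # coarse grid then two refinement passes around the incumbent
        t_grid = np.linspace(1e-6, 0.5, 41)
        s_grid = np.linspace(1e-6, 0.5, 41)
        for _ in range(3):
            lls = np.array([[_reml_ll_dense(y, X, V, cl, t, s) for s in s_grid]
                            for t in t_grid])
            it, is_ = np.unravel_index(np.argmax(lls), lls.shape)
            t_best, s_best = t_grid[it], s_grid[is_]
            half_t = (t_grid[1] - t_grid[0]) * 2
            half_s = (s_grid[1] - s_grid[0]) * 2
            t_grid = np.linspace(max(t_best - half_t, 1e-8), t_best + half_t, 41)
            s_grid = np.linspace(max(s_best - half_s, 1e-8), s_best + half_s, 41)

        assert fit.tau2 == pytest.approx(t_best, abs=1e-3)
        assert fit.sigma2 == pytest.approx(s_best, abs=1e-3)
        assert fit.reml_loglik == pytest.approx(
            _reml_ll_dense(y, X, V, cl, fit.tau2, fit.sigma2), abs=1e-8
        )

    def test_invariant_to_record_order(self, sim_corpus_small):
        from pgxmeta.corpus import Corpus

        corpus = sim_corpus_small.corpus
        perm = np.random.default_rng(0).permutation(len(corpus))
        shuffled = Corpus(corpus.df.iloc[perm].reset_index(drop=True))
        a, _ = fit_primary_pair(corpus, 0.6, response="signed_smd")
        b, _ = fit_primary_pair(shuffled, 0.6, response="signed_smd")
        assert np.allclose(a.beta, b.beta, atol=1e-6)
        assert a.sigma2 == pytest.approx(b.sigma2, abs=1e-6)


class TestPrimaryPair:
    def test_reparameterisation_identity(self, sim_corpus_small):
        no_int, with_int = fit_primary_pair(sim_corpus_small.corpus, response="signed_smd")
        assert with_int.reml_loglik == pytest.approx(no_int.reml_loglik, abs=1e-5)
        assert with_int.beta[1] == pytest.approx(
            no_int.beta[1] - no_int.beta[0], abs=1e-5
        )
        assert with_int.beta[0] == pytest.approx(no_int.beta[0], abs=1e-5)

    def test_balanced_toy_difference(self):
        corpus = make_corpus(
            [0.5, 0.5, 0.2, 0.2],
            variances=[0.1] * 4,
            studies=["s1", "s2", "s3", "s4"],
            outcomes=["proximal", "proximal", "distal", "distal"],
        )
        vm = impute_sampling_covariance(corpus, 0.0)
        no_int = fit_che(
            ModelSpec(response="signed_smd", moderators="outcome",
                      random_structure="nested_two_level"),
            corpus, vm, fix_components={"tau2": 0.0, "sigma2": 0.0},
        )
        with_int = fit_che(
            ModelSpec(response="signed_smd", moderators="outcome", intercept=True,
                      random_structure="nested_two_level"),
            corpus, vm, fix_components={"tau2": 0.0, "sigma2": 0.0},
        )
        assert no_int.beta == pytest.approx([0.5, 0.2])
        assert with_int.beta[1] == pytest.approx(-0.3)

    def test_single_outcome_level_errors(self):
        corpus = make_corpus([0.1, 0.2], outcomes=["proximal", "proximal"])
        with pytest.raises(ValueError, match="both"):
            fit_primary_pair(corpus)


class TestInteraction:
    def test_disjoint_cells_equal_weighted_means(self):
        smds, outcomes, phenos, studies = [], [], [], []
        truth = {}
        i = 0
        for out in ("proximal", "distal"):
            for phe in ("poor", "intermediate", "rapid", "ultrarapid"):
                truth[f"{out}:{phe}"] = 0.1 * (i + 1)
                for r in range(2):
                    smds.append(0.1 * (i + 1))
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
        for name, val in truth.items():
            assert fit.beta[fit.beta_names.index(name)] == pytest.approx(val)

    def test_coefficient_order_is_declared_cell_order(self, sim_corpus_small):
        fit = fit_interaction(sim_corpus_small.corpus, response="signed_smd")
        assert fit.beta_names == [
            "proximal:poor", "proximal:intermediate", "proximal:rapid",
            "proximal:ultrarapid", "distal:poor", "distal:intermediate",
            "distal:rapid", "distal:ultrarapid",
        ]

    def test_empty_cells_error_lists_cells(self):
        corpus = make_corpus([0.1, 0.2], outcomes=["proximal", "distal"],
                             phenotypes=["poor", "poor"])
        vm = impute_sampling_covariance(corpus, 0.0)
        with pytest.raises(ValueError, match="rapid"):
            fit_che(
                ModelSpec(response="signed_smd",
                          moderators="outcome_phenotype_interaction"),
                corpus, vm,
            )


class TestProfiles:
    def test_profile_peaks_at_reml_estimate(self):
        sim = simulate_corpus(SimConfig(n_studies=30, seed=9))
        corpus = sim.corpus
        vm = impute_sampling_covariance(corpus, 0.6)
        spec = ModelSpec(response="signed_smd", moderators="outcome",
                         random_structure="nested_two_level")
        fit = fit_che(spec, corpus, vm)
        grid = np.linspace(max(fit.sigma2 - 0.08, 1e-4), fit.sigma2 + 0.08, 9)
        trace = profile_component(spec, corpus, vm, "sigma2", grid)
        assert not trace.flat
        peak = trace.grid[np.argmax(trace.loglik)]
        assert peak == pytest.approx(fit.sigma2, abs=grid[1] - grid[0])
        assert trace.loglik[0] < trace.loglik.max()
        assert trace.loglik[-1] < trace.loglik.max()

    def test_singleton_studies_flat_ridge_flagged(self):
        # one effect per study: tau2 and sigma2 are aliased
        rng = np.random.default_rng(4)
        smds = rng.normal(0.4, 0.4, 12)
        corpus = make_corpus(smds, variances=[0.05] * 12)
        vm = impute_sampling_covariance(corpus, 0.6)
        spec = ModelSpec(response="signed_smd", moderators="intercept_only",
                         random_structure="nested_two_level")
        fit = fit_che(spec, corpus, vm)
        total = fit.tau2 + fit.sigma2
        grid = np.linspace(1e-4, total, 6)
        with np.errstate(all="ignore"):
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                trace = profile_component(spec, corpus, vm, "tau2", grid)
        assert trace.flat


class TestPredictionInterval:
    def test_degenerate_variance_equals_ci(self):
        corpus = make_corpus(
            [0.5, 0.3, 0.2, 0.25],
            outcomes=["proximal", "proximal", "distal", "distal"],
        )
        vm = impute_sampling_covariance(corpus, 0.0)
        fit = fit_che(
            ModelSpec(response="signed_smd", moderators="outcome",
                      random_structure="nested_two_level"),
            corpus, vm, fix_components={"tau2": 0.0, "sigma2": 0.0},
        )
        lo, hi = prediction_interval(fit, "proximal")
        from scipy import stats

        i = fit.beta_names.index("proximal")
        z = stats.norm.ppf(0.975)
        assert lo == pytest.approx(fit.beta[i] - z * fit.se[i])
        assert hi == pytest.approx(fit.beta[i] + z * fit.se[i])

    def test_pi_wider_than_ci_when_heterogeneous(self, sim_corpus_small):
        fit, _ = fit_primary_pair(sim_corpus_small.corpus, response="signed_smd")
        i = fit.beta_names.index("proximal")
        lo, hi = prediction_interval(fit, "proximal")
        from scipy import stats

        z = stats.norm.ppf(0.975)
        assert (hi - lo) > 2 * z * fit.se[i]

    def test_unknown_level_errors(self, sim_corpus_small):
        fit, _ = fit_primary_pair(sim_corpus_small.corpus, response="signed_smd")
        with pytest.raises(ValueError):
            prediction_interval(fit, "medial")
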