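import warnings

import numpy as np
import pytest

from fledgechoice.choice_data import Dataset, standardize_covariates
from fledgechoice.inference import (
    ConvergenceReport,
    MCMCSettings,
    PosteriorDraws,
    fit_nest,
    fit_postfledging,
    gelman_rubin,
    model_stage_names,
    split_rhat,
)
from fledgechoice.summaries import summarize_coefficients
from fledgechoice.synthetic_data import SimConfig, generate_dataset

from conftest import build_custom_dataset


def _quiet_fit(fn, *args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return fn(*args, **kwargs)


class TestSplitRhat:
    def test_stationary_chains_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(3, 1000))
        assert 1.0 <= split_rhat(x) <= 1.05

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(1)
        x = np.stack([rng.normal(0, 1, 500), rng.normal(10, 1, 500)])
        # closed-form: B/W ~ n*25, so Rhat ~ sqrt(1 + 25) >> 2
        assert split_rhat(x) > 2.0

    def test_drifting_chain_detected_by_split(self):
        # stationary-looking across chains but trending within each
        trend = np.linspace(-3, 3, 800)
        rng = np.random.default_rng(2)
        x = np.stack([trend + rng.normal(0, 0.3, 800) for _ in range(3)])
        assert split_rhat(x) > 1.5

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            split_rhat(np.zeros((1, 100)))

    def test_agrees_with_arviz_split_rhat(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        for loc2 in (0.0, 0.8):
            x = np.stack([rng.normal(0, 1, 400), rng.normal(loc2, 1.3, 400)])
            ours = split_rhat(x)
            theirs = az.rhat(az.convert_to_dataset(x[:, :, None]),
                             method="split")["x"].values.item()
            assert ours == pytest.approx(theirs, rel=1e-6)

    def test_threshold_is_inclusive(self):
        report = ConvergenceReport(rhat={"a": 1.1, "b": 1.02}, threshold=1.1)
        assert report.all_converged
        report2 = ConvergenceReport(rhat={"a": 1.100001}, threshold=1.1)
        assert not report2.all_converged


class TestNestModel:
    def test_seed_determinism(self):
        cfg = SimConfig(stages=("nest",), n_individuals_per_stage=30,
                        sets_per_individual=1,
                        population_sds={"nest": np.zeros(13)}, seed=1)
        std, _ = standardize_covariates(generate_dataset(cfg)[0])
        s = MCMCSettings(n_iterations=400, seed=77)
        a = _quiet_fit(fit_nest, std, settings=s)
        b = _quiet_fit(fit_nest, std, settings=s)
        np.testing.assert_array_equal(a.array, b.array)

    def test_chain_permutation_leaves_summaries_unchanged(self):
        cfg = SimConfig(stages=("nest",), n_individuals_per_stage=30,
                        sets_per_individual=1,
                        population_sds={"nest": np.zeros(13)}, seed=2)
        std, _ = standardize_covariates(generate_dataset(cfg)[0])
        draws = _quiet_fit(fit_nest, std, settings=MCMCSettings(n_iterations=600, seed=3))
        permuted = PosteriorDraws(array=draws.array[[2, 0, 1]], names=draws.names,
                                  kinds=draws.kinds, meta=dict(draws.meta))
        for s1, s2 in zip(summarize_coefficients(draws),
                          summarize_coefficients(permuted)):
            assert s1.mean == pytest.approx(s2.mean)
            assert s1.f == pytest.approx(s2.f)

    def test_empty_likelihood_recovers_prior(self):
        # zero choice sets: the posterior is the Normal(0, sd 10) prior
        empty = Dataset(sets=[], species="synthetic")
        draws = fit_nest(empty, settings=MCMCSettings(n_iterations=8000, seed=4))
        pooled = np.concatenate([draws.pooled(n) for n in draws.names[:3]])
        assert abs(pooled.std() - 10.0) / 10.0 < 0.10
        assert abs(pooled.mean()) < 1.0

    def test_rejects_juvenile_sets(self):
        cfg = SimConfig(n_individuals_per_stage=2, seed=5)
        std, _ = standardize_covariates(generate_dataset(cfg)[0])
        with pytest.raises(ValueError):
            fit_nest(std)


class TestHierarchicalModel:
    def test_stage_grouping_pooling_names(self):
        grouping = {"early_dependent": 0, "late_dependent": 1, "independent": 1}
        assert model_stage_names(grouping) == [
            "early_dependent", "late_dependent+independent"]

    def test_empty_model_stage_rejected(self):
        cfg = SimConfig(stages=("early_dependent",), n_individuals_per_stage=3, seed=6)
        std, _ = standardize_covariates(generate_dataset(cfg)[0])
        grouping = {"early_dependent": 0, "late_dependent": 1}
        with pytest.raises(ValueError, match="zero choice sets"):
            fit_postfledging(std, grouping,
                             settings=MCMCSettings(n_iterations=200, seed=0))

    def test_nest_sets_rejected(self):
        cfg = SimConfig(stages=("nest",), n_individuals_per_stage=3,
                        sets_per_individual=1,
                        population_sds={"nest": np.zeros(13)}, seed=7)
        std, _ = standardize_covariates(generate_dataset(cfg)[0])
        with pytest.raises(ValueError):
            fit_postfledging(std)

    def test_shrinkage_pulls_sparse_individuals_to_population_mean(self):
        # two focal individuals share the same true offset from mu=0 on the
        # understory coefficient; the one with a single choice set must end
        # closer to the population mean than the one with 20 sets
        offset = np.zeros(13)
        offset[1] = 1.2
        betas = {"sparse": offset, "rich": offset}
        sets_per = {"sparse": 1, "rich": 20}
        rng = np.random.default_rng(8)
        for i in range(10):
            betas[f"bg{i}"] = rng.normal(scale=0.3, size=13)
            sets_per[f"bg{i}"] = 10
        d = build_custom_dataset(betas, sets_per, seed=9)
        std, _ = standardize_covariates(d)
        draws = _quiet_fit(fit_postfledging, std,
                           settings=MCMCSettings(n_iterations=3000, seed=10))
        mu_hat = draws.pooled("mu[early_dependent].understory_density").mean()
        sparse_hat = draws.pooled(
            "beta[sparse|early_dependent].understory_density").mean()
        rich_hat = draws.pooled(
            "beta[rich|early_dependent].understory_density").mean()
        assert abs(sparse_hat - mu_hat) < abs(rich_hat - mu_hat)

    def test_degenerate_hierarchy_concentrates_sigma_near_zero(self):
        cfg = SimConfig(stages=("early_dependent", "late_dependent"),
                        n_individuals_per_stage=15, sets_per_individual=8,
                        population_sds={s: np.full(13, 0.01)
                                        for s in ("early_dependent", "late_dependent")},
                        seed=11)
        std, _ = standardize_covariates(generate_dataset(cfg)[0])
        draws = _quiet_fit(fit_postfledging, std,
                           settings=MCMCSettings(n_iterations=2000, seed=12))
        medians = [np.median(draws.pooled(n)) for n in draws.select(kind="sigma")]
        assert max(medians) < 0.15

    def test_seed_determinism(self):
        cfg = SimConfig(n_individuals_per_stage=4, sets_per_individual=3, seed=13)
        std, _ = standardize_covariates(generate_dataset(cfg)[0])
        s = MCMCSettings(n_iterations=300, seed=14)
        a = _quiet_fit(fit_postfledging, std, settings=s)
        b = _quiet_fit(fit_postfledging, std, settings=s)
        np.testing.assert_array_equal(a.array, b.array)


class TestPriorSamplingMode:
    def test_hierarchical_prior_moments(self):
        # likelihood off: mu must reproduce its Normal(0, sd 10) prior and
        # sigma its heavy-tailed prior (median 1/sqrt(ln 2 / rate))
        cfg = SimConfig(n_individuals_per_stage=4, sets_per_individual=2, seed=15)
        std, _ = standardize_covariates(generate_dataset(cfg)[0])
        draws = _quiet_fit(
            fit_postfledging, std,
            settings=MCMCSettings(n_iterations=12000, thin=3, seed=16,
                                  prior_only=True))
        mu_pooled = np.concatenate([draws.pooled(n)
                                    for n in draws.select(kind="mu")])
        assert abs(mu_pooled.std() - 10.0) / 10.0 < 0.15
        sig_median = np.median(np.concatenate(
            [draws.pooled(n) for n in draws.select(kind="sigma")]))
        expected = 1.0 / np.sqrt(np.log(2.0) / 1e-4)
        assert 0.5 * expected < sig_median < 2.0 * expected


class TestConvergenceReporting:
    def test_nonconvergence_is_a_warning_not_an_exception(self):
        cfg = SimConfig(n_individuals_per_stage=6, sets_per_individual=3, seed=17)
        std, _ = standardize_covariates(generate_dataset(cfg)[0])
        with pytest.warns(UserWarning, match="did not converge"):
            draws = fit_postfledging(
                std, settings=MCMCSettings(n_iterations=120, n_burnin=60, seed=18))
        assert draws.meta["all_converged"] is False
        assert max(draws.meta["rhat"].values()) > 1.1

    def test_gelman_rubin_covers_every_monitored_parameter(self):
        cfg = SimConfig(stages=("nest",), n_individuals_per_stage=10,
                        sets_per_individual=1,
                        population_sds={"nest": np.zeros(13)}, seed=19)
        std, _ = standardize_covariates(generate_dataset(cfg)[0])
        draws = _quiet_fit(fit_nest, std, settings=MCMCSettings(n_iterations=400, seed=20))
        report = gelman_rubin(draws)
        assert set(report.rhat) == set(draws.names)
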