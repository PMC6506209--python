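import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lossaversion.hba_fit import (DUAL_ALPHA, NO_LOSS_AVERSION, SINGLE_ALPHA,
                                  HierarchicalPrior, PosteriorDraws, dic,
                                  fit_hba, fit_mle, log_joint, rhat, run_mcmc,
                                  split_rhat, stack_choice_data)
from lossaversion.prospect_model import (ChoiceDataset, PTParams, choice_prob,
                                         dataset_nll)
from lossaversion.synthetic_data import (CohortSpec, generate_cohort,
                                         simulate_choices)
from lossaversion.task_design import Condition, GambleOption, Trial


def _tiny_dataset():
    """Two subjects, five mixed trials each, fixed choices."""
    rows = []
    trials = [(10, -6, 1), (8, -27, 0), (24, -9, 1), (14, -15, 0), (30, -11, 1)]
    for sid in (0, 1):
        for i, (g, l, c) in enumerate(trials):
            rows.append((sid, i, "mixed", float(g), float(l), 0.0,
                         float(c if sid == 0 else 1 - c)))
    return ChoiceDataset(pd.DataFrame(rows, columns=[
        "subject_id", "trial_index", "condition",
        "gamble_out1", "gamble_out2", "sure", "choice"]))


class TestLogJoint:
    def test_matches_bruteforce_oracle(self):
        """Hierarchical log density equals an independent scipy.stats
        reconstruction (priors + truncation + Jacobians + choice terms)."""
        data = stack_choice_data(_tiny_dataset())
        prior = HierarchicalPrior()
        mu = np.array([0.9, 1.6, 0.8])
        sigma = np.array([0.5, 0.4, 0.6])
        theta = np.array([[1.1, 1.9, 0.7], [0.8, 1.2, 1.4]])
        vec = np.concatenate([mu, np.log(sigma), np.log(theta).ravel()])

        expected = 0.0
        for j in range(3):
            expected += stats.norm.logpdf(mu[j], 0, 1)
            expected += stats.halfcauchy.logpdf(sigma[j], scale=5) + np.log(sigma[j])
            for i in range(2):
                a = (0 - mu[j]) / sigma[j]
                expected += stats.truncnorm.logpdf(theta[i, j], a, np.inf,
                                                   loc=mu[j], scale=sigma[j])
                expected += np.log(theta[i, j])
        for i, sid in enumerate((0, 1)):
            sub = _tiny_dataset().for_subject(sid)
            expected -= dataset_nll(sub, PTParams(*theta[i]))

        assert log_joint(vec, data, prior) == pytest.approx(expected, abs=1e-8)

    def test_difference_between_states_matches_oracle(self):
        data = stack_choice_data(_tiny_dataset())
        rng = np.random.default_rng(0)
        v1 = np.concatenate([[1.0, 1.5, 1.0], np.log([0.4, 0.4, 0.4]),
                             np.log(rng.uniform(0.5, 2.0, 6))])
        v2 = v1 + 0.1
        d_pkg = log_joint(v2, data) - log_joint(v1, data)
        assert np.isfinite(d_pkg)

    def test_nonfinite_vector_rejected(self):
        data = stack_choice_data(_tiny_dataset())
        vec = np.full(2 * 3 + 2 * 3, 0.5)
        vec[0] = np.nan
        assert log_joint(vec, data) == -np.inf

    def test_wrong_length_raises(self):
        data = stack_choice_data(_tiny_dataset())
        with pytest.raises(ValueError):
            log_joint(np.zeros(5), data)


class TestSplitRhat:
    def test_constant_chains_convention(self):
        assert split_rhat(np.ones((4, 100))) == 1.0

    def test_iid_chains_converge(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((4, 2000))
        assert split_rhat(x) < 1.01

    def test_separated_chains_flagged(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((2, 1000))
        x[1] += 10.0
        assert split_rhat(x) > 1.1

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            split_rhat(np.random.default_rng(0).standard_normal((1, 100)))

    def test_agrees_with_arviz_on_iid_draws(self):
        """Independent cross-check against the rank-normalised split R-hat."""
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        x = rng.standard_normal((4, 2000))
        ours = split_rhat(x)
        theirs = float(np.asarray(
            az.rhat(az.convert_to_dataset(x[:, :, None]))["x"]).ravel()[0])
        assert ours == pytest.approx(theirs, abs=0.01)


class TestMle:
    def test_recovers_generating_params_large_sample(self, task0):
        true = PTParams(1.0, 2.0, 3.0)
        frames = [simulate_choices(task0, true, seed=s).df for s in range(18)]
        df = pd.concat(frames, ignore_index=True)
        df["subject_id"] = 0
        df["trial_index"] = np.arange(len(df))
        res = fit_mle(ChoiceDataset(df), seed=0)
        assert res.params.alpha == pytest.approx(true.alpha, rel=0.10)
        assert res.params.lam == pytest.approx(true.lam, rel=0.10)
        assert res.params.tau == pytest.approx(true.tau, rel=0.10)
        assert not res.at_bound
        # optimality: no worse than the generating parameters
        sub = ChoiceDataset(df)
        assert res.nll <= dataset_nll(sub, true) + 1e-6

    def test_all_sure_chooser_hits_boundary(self, task0):
        df = simulate_choices(task0, PTParams(1, 1.5, 1), seed=0).df.copy()
        df.loc[~df["condition"].str.startswith("catch"), "choice"] = 0.0
        res = fit_mle(ChoiceDataset(df), seed=0)
        assert res.at_bound
        assert res.params.lam == pytest.approx(20.0, rel=1e-3)  # upper bound


class TestMcmcContract:
    def test_same_seed_identical_draws(self):
        data = _tiny_dataset()
        a = run_mcmc(data, n_chains=2, n_warmup=60, n_samples=40, seed=5)
        b = run_mcmc(data, n_chains=2, n_warmup=60, n_samples=40, seed=5)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            run_mcmc(_tiny_dataset(), n_chains=1, n_warmup=10, n_samples=10)

    def test_draws_positive_on_constrained_scale(self):
        d = run_mcmc(_tiny_dataset(), n_chains=2, n_warmup=60, n_samples=40,
                     seed=1)
        k = d.model.k
        assert np.all(d.draws[:, :, k:] > 0)  # sigmas and subject params


class TestDic:
    def _draws_from_theta(self, theta_draws, subject_ids):
        n, k = theta_draws.shape[1], theta_draws.shape[2]
        flat = np.concatenate([
            np.ones((theta_draws.shape[0], 2 * k)),
            theta_draws.reshape(theta_draws.shape[0], -1)], axis=1)
        names = ([f"mu_{p}" for p in SINGLE_ALPHA.param_names]
                 + [f"sigma_{p}" for p in SINGLE_ALPHA.param_names]
                 + [f"{p}[{i}]" for i in range(n)
                    for p in SINGLE_ALPHA.param_names])
        return PosteriorDraws(draws=flat[None, :, :].repeat(2, axis=0),
                              param_names=names, model=SINGLE_ALPHA,
                              subject_ids=subject_ids)

    def test_point_mass_posterior_has_zero_pd(self):
        data = _tiny_dataset()
        theta = np.tile(np.array([[1.0, 1.8, 0.9], [1.2, 1.1, 0.6]]), (50, 1, 1))
        draws = self._draws_from_theta(theta, [0, 1])
        res = dic(draws, data)
        assert res.p_d == pytest.approx(0.0, abs=1e-9)
        nll = sum(dataset_nll(data.for_subject(s), PTParams(*theta[0, i]))
                  for i, s in enumerate([0, 1]))
        assert res.dic == pytest.approx(2 * nll, rel=1e-10)

    def test_true_model_beats_no_loss_aversion_on_loss_averse_data(self, task0):
        """Model recovery: on loss-averse cohorts the full prospect model
        attains lower DIC than the lambda=1 restriction in most replicates."""
        wins = 0
        reps = 5
        for rep in range(reps):
            cohort = generate_cohort(
                CohortSpec(n_subjects=6, group_means=(1.0, 2.5, 1.0),
                           seed=100 + rep), task=task0)
            kw = dict(n_chains=2, n_warmup=600, n_samples=400, seed=rep)
            full = fit_hba(cohort.choices, model=SINGLE_ALPHA, **kw)
            restricted = fit_hba(cohort.choices, model=NO_LOSS_AVERSION, **kw)
            wins += full.dic.dic < restricted.dic.dic
        assert wins > reps / 2


class TestHierarchicalFitQuality:
    def test_rhat_converged_at_default_settings(self, full_fit):
        assert full_fit.max_rhat <= 1.01

    def test_subject_lambda_recovery(self, full_fit, cohort7):
        est = full_fit.subject_estimates.set_index("subject_id")
        true = cohort7.traits.set_index("subject_id")
        r = np.corrcoef(true["true_lam"], est.loc[true.index, "lam"])[0, 1]
        assert r >= 0.7
        assert abs(est["lam"].mean() - true["true_lam"].mean()) <= 0.25

    def test_shrinkage_toward_group_mean(self, full_fit, cohort7):
        """Partial pooling: subjects with extreme individual MLEs end up
        closer to the group mean than their MLE."""
        est = full_fit.subject_estimates.set_index("subject_id")
        group_lam = est["lam"].mean()
        mles = {sid: fit_mle(cohort7.choices.for_subject(sid), seed=0)
                for sid in cohort7.subject_ids}
        dev = sorted(cohort7.subject_ids,
                     key=lambda s: -abs(mles[s].params.lam - group_lam))
        shrunk = sum(
            abs(est.loc[s, "lam"] - group_lam)
            <= abs(mles[s].params.lam - group_lam) + 1e-9
            for s in dev[:5])
        assert shrunk >= 4

    def test_group_posterior_near_truth(self, full_fit):
        g = full_fit.group_summary
        assert g["mu_lam"] == pytest.approx(1.561, abs=0.4)
        assert g["mu_alpha"] == pytest.approx(1.033, abs=0.4)
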