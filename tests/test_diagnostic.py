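"""Diagnostic panels: filtering, screening, LASSO, cut point, validation."""

import copy

import numpy as np
import pytest
from scipy import stats

from bloodmark import diagnostic
from bloodmark.diagnostic import (EmptyPanelError, PanelModel,
                                  bayesian_lasso_screen,
                                  build_diagnostic_panel,
                                  heidi_matched_comparison, lasso_logistic,
                                  lasso_kkt_violation,
                                  spearman_concordance_filter, validate_panel,
                                  youden_cutpoint)
from bloodmark.synthetic import gen_case_control_matrix


class TestSpearmanFilter:
    def _cohort(self, shifts, seed=0, n=400):
        return gen_case_control_matrix(n // 2, n // 2, len(shifts), shifts,
                                       seed=seed)

    def test_direction_and_magnitude_rules(self):
        # strong positive, strong negative, and null marker
        c = self._cohort([0.8, -0.8, 0.0], seed=1)
        betas = {"m0": 0.5, "m1": 0.5, "m2": 0.5}
        res = spearman_concordance_filter(c.matrix, c.labels, betas,
                                          c.marker_ids)
        assert "m0" in res.retained           # rho > 0.05, same sign as beta
        assert "m1" not in res.retained       # rho < 0 but beta > 0: discordant
        assert not res.concordant["m1"]
        assert "m2" not in res.retained       # |rho| ~ 0 < 0.05

    def test_small_rho_dropped_even_if_concordant(self):
        rng = np.random.default_rng(3)
        n = 10_000  # large n so rho ~ 0.02 is estimated tightly
        labels = np.repeat([0, 1], n // 2)
        x = (0.04 * labels + rng.standard_normal(n)).reshape(-1, 1)
        rho = stats.spearmanr(x[:, 0], labels).statistic
        assert 0 < rho < 0.05
        res = spearman_concordance_filter(x, labels, {"m0": 1.0}, ["m0"])
        assert res.retained == []

    def test_constant_marker_dropped_with_warning(self, caplog):
        c = self._cohort([0.5, 0.5], seed=2)
        c.matrix[:, 1] = 7.0
        with caplog.at_level("WARNING"):
            res = spearman_concordance_filter(c.matrix, c.labels,
                                              {"m0": 1.0, "m1": 1.0},
                                              c.marker_ids)
        assert res.retained == ["m0"]
        assert np.isnan(res.rho["m1"])


class TestBayesianLassoScreen:
    def test_pure_noise_mostly_screened_out(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((200, 30))
        y = rng.integers(0, 2, 200)
        kept, diag = bayesian_lasso_screen(x, y, [f"m{j}" for j in range(30)],
                                           n_mcmc=1000, burn_in=300, seed=1)
        assert len(kept) <= 3  # >= 90% screened out

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_strong_marker_retained(self, seed):
        c = gen_case_control_matrix(100, 100, 10, [2.0] + [0.0] * 9, seed=seed)
        kept, _ = bayesian_lasso_screen(c.matrix, c.labels, c.marker_ids,
                                        n_mcmc=1000, burn_in=300, seed=seed)
        assert "m0" in kept

    def test_zero_markers_in_zero_out(self):
        kept, diag = bayesian_lasso_screen(np.empty((50, 0)),
                                           np.repeat([0, 1], 25), [],
                                           n_mcmc=1000, seed=0)
        assert kept == []

    def test_mcmc_floor_enforced(self):
        with pytest.raises(ValueError):
            bayesian_lasso_screen(np.zeros((10, 1)), np.repeat([0, 1], 5),
                                  ["m0"], n_mcmc=100, seed=0)


class TestLassoLogistic:
    def _toy(self, seed=0, n=400):
        c = gen_case_control_matrix(n // 2, n // 2, 3, [1.0, 0.6, 0.3],
                                    seed=seed)
        return c.matrix, c.labels, c.marker_ids

    def test_small_penalty_matches_newton_oracle(self):
        """penalty -> 0 limit agrees with the unpenalized MLE (statsmodels
        Newton solver) on a well-conditioned 3-marker set."""
        import statsmodels.api as sm
        x, y, ids = self._toy()
        model = lasso_logistic(x, y, ids, penalty=1e-7)
        mle = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        np.testing.assert_allclose(model.coef, mle.params[1:], atol=1e-4)
        assert model.intercept == pytest.approx(mle.params[0], abs=1e-4)

    def test_penalty_above_bound_zeroes_everything(self):
        x, y, ids = self._toy()
        lam_max = diagnostic._lambda_max(x, y)
        with pytest.raises(EmptyPanelError):
            lasso_logistic(x, y, ids, penalty=lam_max * 1.01)

    def test_kkt_conditions_hold_at_solution(self):
        x, y, ids = self._toy(seed=1)
        lam = diagnostic._lambda_max(x, y) * 0.3
        model = lasso_logistic(x, y, ids, penalty=lam)
        coef_full = np.zeros(3)
        for m, c in zip(model.marker_ids, model.coef):
            coef_full[ids.index(m)] = c
        viol = lasso_kkt_violation(x, y, coef_full, model.intercept, lam)
        assert viol < 1e-4

    def test_cross_validated_fit_is_sparse_and_deterministic(self):
        c = gen_case_control_matrix(150, 150, 20, [0.8] * 3 + [0.0] * 17,
                                    seed=4)
        m1 = lasso_logistic(c.matrix, c.labels, c.marker_ids, seed=11)
        m2 = lasso_logistic(c.matrix, c.labels, c.marker_ids, seed=11)
        assert m1.marker_ids == m2.marker_ids
        assert np.array_equal(m1.coef, m2.coef)
        assert len(m1.marker_ids) < 20


class TestYoudenCutpoint:
    def test_perfect_separation_midpoint(self):
        cut = youden_cutpoint([1, 2, 3, 4], [0, 0, 1, 1])
        assert cut == pytest.approx(2.5)

    def test_identical_scores_error(self):
        with pytest.raises(ValueError):
            youden_cutpoint([1.0, 1.0, 1.0], [0, 1, 0])

    def test_matches_enumeration_oracle(self):
        """Exhaustive threshold enumeration agrees on 100 random datasets."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(8, 40)
            scores = np.round(rng.normal(size=n), 1)  # induce ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max() or np.unique(scores).size < 2:
                continue
            uniq = np.unique(scores)
            mids = 0.5 * (uniq[:-1] + uniq[1:])
            n1, n0 = labels.sum(), n - labels.sum()
            js = np.array([((scores > t) & (labels == 1)).sum() / n1
                           + ((scores <= t) & (labels == 0)).sum() / n0 - 1
                           for t in mids])
            # smallest threshold among tied maxima (float-tolerant)
            best = mids[js >= js.max() - 1e-9][0]
            assert youden_cutpoint(scores, labels) == pytest.approx(best)


class TestValidatePanel:
    def _fitted(self, seed=0):
        c = gen_case_control_matrix(200, 200, 5, [1.0, 0.8, 0, 0, 0],
                                    seed=seed)
        model = lasso_logistic(c.matrix, c.labels, c.marker_ids, seed=seed)
        scores = model.score(c.matrix, c.marker_ids)
        model.cut_point = youden_cutpoint(scores, c.labels)
        model.metrics = diagnostic.panel_metrics(scores, c.labels,
                                                 model.cut_point)
        return model, c

    def test_validation_on_training_reproduces_training_metrics(self):
        model, c = self._fitted()
        val = validate_panel(model, c.matrix, c.labels, c.marker_ids)
        assert val["auc"] == pytest.approx(model.metrics["auc"])
        assert val["accuracy"] == pytest.approx(model.metrics["accuracy"])

    def test_permuted_labels_auc_chance(self):
        model, c = self._fitted(seed=1)
        rng = np.random.default_rng(0)
        val = validate_panel(model, c.matrix, rng.permutation(c.labels),
                             c.marker_ids)
        assert val["auc"] == pytest.approx(0.5, abs=0.06)

    def test_perfectly_ranked_scores(self):
        model = PanelModel(marker_ids=["m0"], coef=np.array([1.0]),
                           intercept=0.0, cut_point=2.5)
        val = validate_panel(model, np.array([[1.0], [2.0], [3.0], [4.0]]),
                             [0, 0, 1, 1], ["m0"])
        assert val["auc"] == 1.0
        assert val["accuracy"] == 1.0

    def test_missing_marker_column_is_explicit(self):
        model, c = self._fitted(seed=2)
        with pytest.raises(KeyError, match=model.marker_ids[0]):
            validate_panel(model, c.matrix[:, :1], c.labels, ["zzz"])

    def test_validation_leaves_model_untouched(self):
        model, c = self._fitted(seed=3)
        before = copy.deepcopy(model)
        validate_panel(model, c.matrix, c.labels, c.marker_ids)
        assert np.array_equal(before.coef, model.coef)
        assert before.cut_point == model.cut_point
        assert before.intercept == model.intercept


class TestHeidiMatchedComparison:
    def test_identical_sets_identical_metrics(self):
        c = gen_case_control_matrix(150, 150, 4, [0.5] * 4, seed=0)
        ids = c.marker_ids
        out = heidi_matched_comparison(ids[:2], ids[:2], [0.01, 0.02],
                                       c.matrix, c.labels, ids)
        assert out["plus"] == out["minus"]

    def test_matched_size_enforced(self):
        c = gen_case_control_matrix(150, 150, 6, [0.5] * 6, seed=1)
        ids = c.marker_ids
        out = heidi_matched_comparison(ids[:2], ids[2:], [0.04, 0.01, 0.03, 0.02],
                                       c.matrix, c.labels, ids)
        assert out["minus"]["n_markers"] == 2
        assert out["matched"]

    def test_minus_set_ranked_by_p(self):
        c = gen_case_control_matrix(150, 150, 4, [0.9, 0.9, 0.9, 0.0], seed=2)
        ids = c.marker_ids
        # smallest p belongs to the null marker m3 -> it must be chosen
        out = heidi_matched_comparison(ids[:1], ids[1:], [0.5, 0.5, 1e-9],
                                       c.matrix, c.labels, ids)
        assert out["minus"]["auc"] < out["plus"]["auc"]


class TestEndToEndPanel:
    def test_planted_signal_recovered(self):
        """11 planted markers among 200 nulls: the frozen three-set pipeline
        keeps most of them and validates above chance."""
        n_planted, n_null = 11, 200
        effect = np.array([0.4] * n_planted + [0.0] * n_null)
        parts = [gen_case_control_matrix(200, 200, effect.size, effect,
                                         seed=s) for s in (0, 1, 2)]
        feat, train, valid = parts
        betas = {m: (0.4 if i < n_planted else 0.01)
                 for i, m in enumerate(feat.marker_ids)}
        model = build_diagnostic_panel(feat.matrix, feat.labels, train.matrix,
                                       train.labels, feat.marker_ids, betas,
                                       n_mcmc=1000, burn_in=300, seed=5)
        recovered = set(model.marker_ids) & set(feat.marker_ids[:n_planted])
        assert len(recovered) >= 6
        val = validate_panel(model, valid.matrix, valid.labels,
                             valid.marker_ids)
        assert val["auc"] >= 0.65
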