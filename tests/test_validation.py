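"""Validation statistics: Pearson+CI, BH step-up, Welch t, logistic
treatment x score interaction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

import pharmsig as ps
from pharmsig.errors import SeparationError, ValidationError


def bh_brute_force(p):
    """Literal step-up definition: adj_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    for pos, idx in enumerate(order):
        tail = [p[order[j]] * m / (j + 1) for j in range(pos, m)]
        adj[idx] = min(1.0, min(tail))
    return adj


class TestPearson:
    def test_perfect_linearity(self):
        x = np.arange(10.0)
        r, ci, p = ps.pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _, _ = ps.pearson_with_p(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # brute force: sum((x-xbar)(y-ybar)) / sqrt(sum sq * sum sq) = 0.8
        r, ci, p = ps.pearson_with_p([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)
        assert ci[0] <= r <= ci[1]
        # two-sided p from t = r sqrt((n-2)/(1-r^2)) on n-2 df
        from scipy import stats

        t = 0.8 * np.sqrt(2 / (1 - 0.64))
        assert p == pytest.approx(2 * stats.t.sf(t, 2))

    def test_errors(self):
        with pytest.raises(ValidationError, match="constant"):
            ps.pearson_with_p([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValidationError, match="mismatch"):
            ps.pearson_with_p([1, 2, 3], [1, 2])
        with pytest.raises(ValidationError, match="n >= 3"):
            ps.pearson_with_p([1, 2], [1, 2])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance_and_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(12)
        y = rng.standard_normal(12)
        r0, _, p0 = ps.pearson_with_p(x, y)
        r1, _, p1 = ps.pearson_with_p(3.0 * x + 2.0, y)
        assert r1 == pytest.approx(r0, abs=1e-12)
        assert p1 == pytest.approx(p0, abs=1e-12)
        r2, _, _ = ps.pearson_with_p(-x, y)
        assert r2 == pytest.approx(-r0, abs=1e-12)


class TestBHAdjust:
    def test_single_p_is_identity(self):
        assert ps.bh_adjust([0.037])[0] == pytest.approx(0.037)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_definition(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, rng.integers(1, 40))
        np.testing.assert_allclose(ps.bh_adjust(p), bh_brute_force(p), atol=1e-12)

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 50)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ps.bh_adjust(p), expected, atol=1e-12)

    def test_monotone_and_never_below_raw(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0, 1, 30)
        adj = ps.bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            ps.bh_adjust([0.5, 1.2])
        with pytest.raises(ValidationError):
            ps.bh_adjust([-0.1])


class TestTwoSampleT:
    def test_identical_groups(self):
        scores = np.array([0.0, 1.0, 0.0, 1.0])
        marker = np.array([True, True, False, False])
        res = ps.two_sample_t(scores, marker)
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_welch(self):
        # A=(0,0,1,1), B=(1,1,2,2): mean diff -1; each sample variance
        # (ddof=1) is 1/3, so se = sqrt(1/12 + 1/12) = sqrt(1/6) and
        # t = -sqrt(6); equal variances make Welch df reduce to pooled df 6
        scores = np.array([0.0, 0.0, 1.0, 1.0, 1.0, 1.0, 2.0, 2.0])
        marker = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=bool)
        res = ps.two_sample_t(scores, marker)
        assert res.t == pytest.approx(-np.sqrt(6.0))
        assert res.df == pytest.approx(6.0)
        assert res.mean_difference == pytest.approx(-1.0)
        assert res.positive_more_sensitive

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        scores = rng.standard_normal(30)
        marker = rng.random(30) < 0.5
        a = ps.two_sample_t(scores, marker)
        b = ps.two_sample_t(scores * 7.3, marker)
        assert b.t == pytest.approx(a.t, abs=1e-12)
        assert b.p == pytest.approx(a.p, abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError, match=">=2"):
            ps.two_sample_t(np.arange(5.0), np.array([1, 0, 0, 0, 0], dtype=bool))

    def test_degenerate_equal_constants(self):
        res = ps.two_sample_t(np.ones(6), np.array([1, 1, 1, 0, 0, 0], dtype=bool))
        assert res.p == 1.0

    def test_degenerate_unequal_constants_rejected(self):
        with pytest.raises(ValidationError, match="zero variance"):
            ps.two_sample_t(
                np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0]),
                np.array([1, 1, 1, 0, 0, 0], dtype=bool),
            )


class TestValidateAgainstResponse:
    def _scores_and_auc(self, n_drugs=3, n=40, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        samples = [f"S{i}" for i in range(n)]
        scores = pd.DataFrame(
            rng.standard_normal((n_drugs, n)),
            index=[f"D{i}" for i in range(n_drugs)],
            columns=samples,
        )
        rows = []
        for d in scores.index:
            auc = -scores.loc[d] + noise * rng.standard_normal(n)
            rows += [(d, s, "auc", v) for s, v in auc.items()]
        return scores, pd.DataFrame(rows, columns=["drug", "sample", "measure", "value"])

    def test_score_equal_to_negative_auc_gives_r_one(self):
        scores, resp = self._scores_and_auc(n_drugs=1)
        (res,) = ps.validate_against_response(scores, resp)
        assert res.r == pytest.approx(1.0)

    def test_fdr_column_is_bh_of_the_tested_drugs(self):
        scores, resp = self._scores_and_auc(n_drugs=5, noise=0.8, seed=3)
        results = ps.validate_against_response(scores, resp)
        assert len(results) == 5
        expected = ps.bh_adjust([r.p for r in results])
        np.testing.assert_allclose([r.fdr for r in results], expected)
        for r in results:
            assert r.fdr >= r.p - 1e-15

    def test_all_significant_when_signal_strong(self):
        scores, resp = self._scores_and_auc(n_drugs=10, noise=0.1, seed=4)
        results = ps.validate_against_response(scores, resp)
        assert all(r.r > 0.9 and r.fdr < 1e-6 for r in results)

    def test_drug_with_two_pairs_skipped(self):
        scores, resp = self._scores_and_auc(n_drugs=2)
        resp = pd.concat(
            [
                resp,
                pd.DataFrame(
                    [("D9", "S0", "auc", 0.5), ("D9", "S1", "auc", 0.6)],
                    columns=resp.columns,
                ),
            ],
            ignore_index=True,
        )
        results = ps.validate_against_response(scores, resp)
        assert {r.drug_id for r in results} == {"D0", "D1"}

    def test_table_export_columns(self):
        scores, resp = self._scores_and_auc()
        tab = ps.correlation_table(ps.validate_against_response(scores, resp))
        assert list(tab.columns) == ["drug", "r", "ci_low", "ci_high", "p", "fdr", "n"]


class TestInteraction:
    def _cohort(self, b_interaction, n=400, seed=0):
        cfg = ps.ClinicalCohortConfig(
            n_patients=n, b_interaction=b_interaction, seed=seed
        )
        ann, score = ps.gen_clinical_cohort(cfg)
        treated = (ann.df["treatment"] == "drug_of_interest").to_numpy(float)
        return ann.df["response_binary"].to_numpy(float), treated, score.to_numpy()

    def test_strong_negative_interaction_detected(self):
        resp, treated, score = self._cohort(-2.0, n=400, seed=1)
        res = ps.interaction_test(resp, treated, score)
        assert res.interaction_coef < 0
        assert res.interaction_p < 0.05
        assert res.converged
        assert "treatment:score" in res.summary()

    def test_lr_test_option_agrees_in_order_of_magnitude(self):
        resp, treated, score = self._cohort(-2.0, n=400, seed=2)
        res = ps.interaction_test(resp, treated, score, lr_test=True)
        assert res.lr_interaction_p is not None
        assert (res.lr_interaction_p < 0.05) == (res.interaction_p < 0.05)

    def test_permuting_scores_destroys_planted_interaction(self):
        resp, treated, score = self._cohort(-2.0, n=400, seed=3)
        planted_p = ps.interaction_test(resp, treated, score).interaction_p
        rng = np.random.default_rng(0)
        perm_ps = [
            ps.interaction_test(resp, treated, rng.permutation(score)).interaction_p
            for _ in range(20)
        ]
        assert np.median(perm_ps) > 100 * planted_p

    def test_constant_response_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            ps.interaction_test(
                np.ones(40), np.tile([0.0, 1.0], 20), np.random.default_rng(0).standard_normal(40)
            )

    def test_single_arm_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValidationError, match="single treatment arm"):
            ps.interaction_test(
                rng.integers(0, 2, 40).astype(float), np.ones(40), rng.standard_normal(40)
            )

    def test_separation_reported_not_estimated(self):
        # response perfectly determined by score sign: complete separation
        n = 60
        rng = np.random.default_rng(1)
        score = rng.standard_normal(n)
        treated = np.tile([0.0, 1.0], n // 2)
        resp = (score > 0).astype(float)
        with pytest.raises(SeparationError):
            ps.interaction_test(resp, treated, score)

    def test_small_n_warns(self):
        resp = np.array([0, 1] * 8, dtype=float)
        treated = np.array([0, 0, 1, 1] * 4, dtype=float)
        score = np.random.default_rng(2).standard_normal(16)
        with pytest.warns(UserWarning, match="n < 20"):
            try:
                ps.interaction_test(resp, treated, score)
            except SeparationError:
                pass
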