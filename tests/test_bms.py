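"""Bayesian model selection and group-level parameter statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import digamma, softmax

from perceptdcm.bms import (BMSResult, exceedance_probabilities, ffx_bms,
                            group_parameter_test, hemodynamic_group_compare,
                            rfx_bms, subject_winning_counts)
from perceptdcm.inversion import Posterior

N_DRAWS = 200_000  # Monte-Carlo draws for the unit tests (tolerance ~0.01)


def evidence_frame(F, cohorts=None):
    N, M = F.shape
    rows = []
    for i in range(N):
        for j in range(M):
            rows.append({"subject": f"s{i}", "model": f"model{j + 1}",
                         "cohort": (cohorts[i] if cohorts else "young"),
                         "free_energy": F[i, j]})
    return pd.DataFrame(rows)


def make_posterior(values: dict, cohort: str, subject: str) -> Posterior:
    labels = tuple(values)
    return Posterior(means=np.array([values[l] for l in labels]),
                     cov=np.eye(len(labels)), free_energy=0.0,
                     r2=np.zeros(4), labels=labels, spec_name="model1",
                     converged=True, subject=subject, cohort=cohort)


class TestRFX:
    def test_identical_evidence_gives_symmetric_exceedance(self):
        F = np.tile([[3.0, 3.0]], (6, 1))
        res = rfx_bms(evidence_frame(F), seed=0, n_draws=N_DRAWS)
        assert np.allclose(res.exceedance, 0.5, atol=0.01)
        assert np.allclose(res.expected_frequency, 0.5, atol=1e-9)

    def test_forced_alpha_beta_closed_form(self):
        # alpha = (2, 1): P(Beta(2,1) > 0.5) = 1 - 0.5^2 = 0.75
        xp = exceedance_probabilities(np.array([2.0, 1.0]),
                                      n_draws=1_000_000, seed=1)
        assert xp[0] == pytest.approx(0.75, abs=0.01)

    def test_matches_naive_fixed_point_oracle(self):
        F = np.array([[1.0, 0.2], [0.5, 0.9], [2.0, 1.0]])
        ev = evidence_frame(F)
        res = rfx_bms(ev, seed=0, n_draws=10_000)
        alpha = np.ones(2)
        for _ in range(50_000):
            u = softmax(F + digamma(alpha) - digamma(alpha.sum()), axis=1)
            alpha_new = 1.0 + u.sum(axis=0)
            if np.abs(alpha_new - alpha).max() < 1e-13:
                break
            alpha = alpha_new
        assert np.allclose(res.alpha, alpha, atol=1e-6)
        assert np.allclose(res.responsibilities, u, atol=1e-6)

    def test_uninformative_evidence_near_uniform(self):
        F = np.zeros((8, 4))
        res = rfx_bms(evidence_frame(F), seed=2, n_draws=N_DRAWS)
        assert np.allclose(res.alpha, res.alpha[0])
        mc_err = 3.0 / np.sqrt(N_DRAWS)
        assert res.exceedance.max() <= 0.25 + 3 * 0.01 + mc_err

    def test_raising_one_model_weakly_raises_its_exceedance(self):
        base = np.zeros((5, 3))
        xs = []
        for bump in (0.0, 0.5, 1.0, 2.0):
            F = base.copy()
            F[:, 0] += bump
            res = rfx_bms(evidence_frame(F), seed=3, n_draws=N_DRAWS)
            xs.append(res.exceedance[0])
        assert all(b >= a - 0.02 for a, b in zip(xs, xs[1:]))
        assert xs[-1] > xs[0]

    def test_single_model_rejected(self):
        F = np.ones((3, 1))
        with pytest.raises(ValueError):
            rfx_bms(evidence_frame(F))

    def test_exceedance_sums_to_one(self):
        F = np.random.default_rng(0).standard_normal((6, 4))
        res = rfx_bms(evidence_frame(F), seed=4, n_draws=N_DRAWS)
        assert res.exceedance.sum() == pytest.approx(1.0, abs=1e-12)


class TestFFX:
    def test_single_subject_softmax(self):
        F = np.array([[1.0, 2.0, 0.5]])
        out = ffx_bms(evidence_frame(F))
        assert np.allclose(out["posterior"], softmax(F[0]))

    def test_constant_shift_invariance(self):
        F = np.random.default_rng(1).standard_normal((4, 3))
        a = ffx_bms(evidence_frame(F))["posterior"].to_numpy()
        F2 = F.copy()
        F2[2] += 55.0
        b = ffx_bms(evidence_frame(F2))["posterior"].to_numpy()
        assert np.allclose(a, b, atol=1e-12)

    def test_matches_high_precision_softmax_oracle(self):
        import sympy
        F = np.random.default_rng(2).standard_normal((3, 3)) * 5
        out = ffx_bms(evidence_frame(F))["posterior"].to_numpy()
        g = [sympy.exp(sympy.Float(x, 50)) for x in F.sum(axis=0)]
        Z = sum(g)
        oracle = np.array([float(x / Z) for x in g])
        assert np.allclose(out, oracle, atol=1e-12)


class TestWinningCounts:
    def _result(self, u, cohorts=None):
        N, M = u.shape
        return BMSResult(alpha=np.ones(M), expected_frequency=np.ones(M) / M,
                         exceedance=np.ones(M) / M, responsibilities=u,
                         subjects=tuple(f"s{i}" for i in range(N)),
                         models=tuple(f"model{j + 1}" for j in range(M)))

    def test_clear_winner_counted(self):
        u = np.array([[0.9, 0.05, 0.03, 0.02]])
        counts = subject_winning_counts(self._result(u))
        assert counts == {"model1": 1, "model2": 0, "model3": 0, "model4": 0}

    def test_tie_breaks_low_with_warning(self):
        u = np.array([[0.5, 0.5, 0.0, 0.0]])
        with pytest.warns(UserWarning, match="tie"):
            counts = subject_winning_counts(self._result(u))
        assert counts["model1"] == 1

    def test_counts_partition_cohort(self):
        rng = np.random.default_rng(3)
        u = rng.dirichlet(np.ones(4), size=9)
        cohort_of = {f"s{i}": ("young" if i < 4 else "older")
                     for i in range(9)}
        young = subject_winning_counts(self._result(u), cohort_of, "young")
        older = subject_winning_counts(self._result(u), cohort_of, "older")
        assert sum(young.values()) == 4 and sum(older.values()) == 5


class TestGroupTests:
    def test_symmetric_values_give_t_zero(self):
        posts = [make_posterior({"b": v}, "young", f"s{i}")
                 for i, v in enumerate([-2.0, -1.0, 1.0, 2.0])]
        res = group_parameter_test(posts, "b")
        assert res["t"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0)

    def test_matches_textbook_t_oracle(self, rng):
        from scipy import stats
        x = rng.standard_normal(10) + 0.4
        posts = [make_posterior({"b": v}, "young", f"s{i}")
                 for i, v in enumerate(x)]
        res = group_parameter_test(posts, "b")
        se = x.std(ddof=1) / np.sqrt(len(x))
        t = x.mean() / se
        p = 2 * stats.t.sf(abs(t), len(x) - 1)
        assert res["t"] == pytest.approx(t, abs=1e-10)
        assert res["p"] == pytest.approx(p, abs=1e-10)
        assert res["cohens_d"] == pytest.approx(x.mean() / x.std(ddof=1))

    def test_degenerate_zero_variance_flagged(self):
        posts = [make_posterior({"b": 0.7}, "young", f"s{i}") for i in range(4)]
        res = group_parameter_test(posts, "b")
        assert res["degenerate"] and res["p"] == 0.0

    def test_unknown_address_rejected(self):
        posts = [make_posterior({"b": 0.1}, "young", f"s{i}") for i in range(3)]
        with pytest.raises(KeyError):
            group_parameter_test(posts, "nonexistent")


class TestHemodynamicCompare:
    def _posts(self, shift=0.0):
        rng = np.random.default_rng(0)
        posts = []
        regions = ("LIN", "PRE", "MTG", "IOF")
        for i in range(8):
            cohort = "young" if i < 4 else "older"
            vals = {}
            for par in ("log_kappa", "log_tau"):
                for r in regions:
                    vals[f"{par}[{r}]"] = rng.standard_normal() * 0.1 \
                        + (shift if cohort == "older" else 0.0)
            posts.append(make_posterior(vals, cohort, f"s{i}"))
        return posts, regions

    def test_eight_tests_reported(self):
        posts, regions = self._posts()
        table = hemodynamic_group_compare(posts, regions)
        assert len(table) == 8
        assert set(table["parameter"]) == {"log_kappa", "log_tau"}

    def test_welch_statistic_matches_direct_formula(self):
        from scipy import stats
        posts, regions = self._posts(shift=0.3)
        table = hemodynamic_group_compare(posts, regions)
        row = table.iloc[0]
        # the comparison orders cohorts alphabetically (older, young)
        x = [p[f"{row.parameter}[{row.region}]"] for p in posts
             if p.cohort == "older"]
        y = [p[f"{row.parameter}[{row.region}]"] for p in posts
             if p.cohort == "young"]
        t, p = stats.ttest_ind(x, y, equal_var=False)
        assert row["t"] == pytest.approx(t, abs=1e-12)
        assert row["p_uncorrected"] == pytest.approx(p, abs=1e-12)

    def test_identical_cohorts_give_p_one(self):
        regions = ("LIN", "PRE", "MTG", "IOF")
        vals = {f"{par}[{r}]": 0.1 for par in ("log_kappa", "log_tau")
                for r in regions}
        posts = [make_posterior(vals, "young" if i < 3 else "older", f"s{i}")
                 for i in range(6)]
        table = hemodynamic_group_compare(posts, regions)
        assert np.allclose(table["p_uncorrected"], 1.0)
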