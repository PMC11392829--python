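import numpy as np
import pandas as pd
import pytest

from consig import survival_risk as sr
from consig.io_model import GeneSet, ValidationError
from consig.synthetic_data import SurvGenConfig, gen_survival_cohort

from conftest import make_survival


def breslow_loglik_oracle(beta: float, x, time, event) -> float:
    """Independent single-covariate partial log-likelihood (no ties assumed):
    plain double loop over risk sets."""
    ll = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            risk = [j for j in range(len(time)) if time[j] >= time[i]]
            ll += beta * x[i] - np.log(sum(np.exp(beta * x[j]) for j in risk))
    return ll


def grid_search_beta(x, time, event, lo=-4.0, hi=4.0) -> float:
    """1-D oracle: coarse grid then two refinement passes."""
    for _ in range(3):
        grid = np.linspace(lo, hi, 401)
        lls = [breslow_loglik_oracle(b, x, time, event) for b in grid]
        best = grid[int(np.argmax(lls))]
        span = (hi - lo) / 40
        lo, hi = best - span, best + span
    return best


class TestCoxFitter:
    def test_analytic_four_sample_toy(self):
        m = sr.fit_cox(np.array([[1.0], [0.0], [1.0], [0.0]]),
                       np.array([1.0, 2.0, 3.0, 4.0]), np.ones(4, dtype=int))
        assert m.beta[0] == pytest.approx(np.log((1 + np.sqrt(17)) / 2), abs=1e-8)
        assert m.converged and not m.separation

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_grid_search_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        x = rng.standard_normal(n)
        time = rng.exponential(10.0, n) * np.exp(-0.3 * x)
        event = rng.random(n) < 0.8
        if event.sum() < 2:
            pytest.skip("degenerate draw")
        m = sr.fit_cox(x[:, None], time, event.astype(int))
        assert m.beta[0] == pytest.approx(grid_search_beta(x, time, event), abs=1e-3)

    def test_matches_lifelines_multivariate(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(42)
        n, p = 120, 3
        X = rng.standard_normal((n, p))
        time = rng.exponential(50.0, n) * np.exp(-(0.5 * X[:, 0] - 0.3 * X[:, 1]))
        event = (rng.random(n) < 0.7).astype(int)
        m = sr.fit_cox(X, time, event)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["T"], df["E"] = time, event
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        np.testing.assert_allclose(m.beta, cph.params_.to_numpy(), atol=1e-5)
        np.testing.assert_allclose(m.se, cph.standard_errors_.to_numpy(), atol=1e-5)
        assert m.loglik == pytest.approx(cph.log_likelihood_, abs=1e-6)

    def test_efron_ties_match_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(3)
        n = 60
        x = rng.standard_normal(n)
        time = rng.integers(1, 8, n).astype(float)  # heavy ties
        event = (rng.random(n) < 0.7).astype(int)
        m = sr.fit_cox(x[:, None], time, event)
        df = pd.DataFrame({"x": x, "T": time, "E": event})
        cph = lifelines.CoxPHFitter().fit(df, "T", "E")
        assert m.beta[0] == pytest.approx(cph.params_.iloc[0], abs=1e-5)

    def test_planted_coefficient_recovery(self, planted_cohort):
        x = planted_cohort.expression.loc["G0001"].to_numpy()
        m = sr.fit_cox(x[:, None], planted_cohort.time, planted_cohort.event)
        assert 0.65 <= m.beta[0] <= 0.95

    def test_separation_flagged_not_silent(self):
        # risk perfectly ordered by x: monotone likelihood
        n = 30
        x = np.arange(n, dtype=float)
        time = np.linspace(100, 1, n)
        m = sr.fit_cox(x[:, None], time, np.ones(n, dtype=int))
        assert m.separation

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            sr.fit_cox(np.ones((10, 1)), np.arange(1.0, 11.0), np.ones(10, dtype=int))

    def test_no_events_rejected(self):
        with pytest.raises(ValidationError, match="events"):
            sr.fit_cox(np.random.default_rng(0).normal(size=(10, 1)),
                       np.arange(1.0, 11.0), np.zeros(10, dtype=int))

    def test_ridge_shrinks_toward_zero(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(80)
        time = rng.exponential(10.0, 80) * np.exp(-0.5 * x)
        event = np.ones(80, dtype=int)
        free = sr.fit_cox(x[:, None], time, event)
        pen = sr.fit_cox(x[:, None], time, event, ridge_lambda=50.0)
        assert abs(pen.beta[0]) < abs(free.beta[0])


class TestUnivariateScreen:
    def test_constant_gene_skipped_with_warning(self, caplog):
        rng = np.random.default_rng(0)
        ds = make_survival(rng.exponential(10, 50), np.ones(50, dtype=int),
                           x=np.vstack([np.ones(50), rng.standard_normal(50)]),
                           genes=["const", "noise"])
        with caplog.at_level("WARNING"):
            res = sr.univariate_screen(ds, ["const", "noise"], alpha=1.0)
        assert "const" in caplog.text
        assert [g for g, _, _ in res] == ["noise"]

    def test_planted_genes_retained(self):
        ds = gen_survival_cohort(SurvGenConfig(
            n_samples=500, n_genes=100,
            planted=(("G0001", 0.8), ("G0002", -0.8)), seed=21,
        ))
        kept = {g for g, _, _ in sr.univariate_screen(ds, ds.genes)}
        assert {"G0001", "G0002"} <= kept

    def test_sorted_by_p(self, planted_cohort):
        res = sr.univariate_screen(planted_cohort, planted_cohort.genes)
        ps = [p for _, _, p in res]
        assert ps == sorted(ps)


class TestStepwise:
    def test_single_informative_candidate_selected(self):
        ds = gen_survival_cohort(SurvGenConfig(
            n_samples=300, n_genes=5, planted=(("G0003", 1.0),), seed=13,
        ))
        model = sr.stepcox_forward(ds, ds.genes)
        assert "G0003" in model.genes
        # exhaustive 1-gene AIC oracle: the first accepted gene minimizes AIC
        aics = {g: sr.fit_cox(ds.expression.loc[g].to_numpy()[:, None],
                              ds.time, ds.event).aic for g in ds.genes}
        assert model.genes[0] == min(aics, key=aics.get)

    def test_null_candidates_give_empty_model(self):
        ds = gen_survival_cohort(SurvGenConfig(n_samples=60, n_genes=4, seed=17))
        model = sr.stepcox_forward(ds, ds.genes)
        if model.n_covariates == 0:  # expected for pure-noise candidates
            assert model.aic_trace == [model.aic]
        else:  # occasional spurious pick still must lower AIC
            assert model.aic < model.aic_trace[0]

    def test_aic_trace_strictly_decreasing(self, planted_cohort):
        model = sr.stepcox_forward(planted_cohort, planted_cohort.genes[:10])
        assert all(b < a for a, b in zip(model.aic_trace, model.aic_trace[1:]))

    def test_backward_agrees_on_easy_problem(self):
        ds = gen_survival_cohort(SurvGenConfig(
            n_samples=400, n_genes=6, planted=(("G0001", 1.0),), seed=19,
        ))
        fwd = sr.stepcox_forward(ds, ds.genes)
        bwd = sr.stepcox_backward(ds, ds.genes)
        assert "G0001" in fwd.genes and "G0001" in bwd.genes


class TestRiskScoreAndStratification:
    def test_hand_dot_product(self):
        ds = make_survival([5.0], [1], x=np.array([[2.0], [1.0]]), genes=["a", "b"])
        model = sr.CoxModel(genes=["a", "b"], beta=[0.5, -1.0], se=[0.1, 0.1],
                            wald_p=[0.5, 0.5], loglik=0.0, aic=0.0)
        assert sr.risk_score(model, ds)[0] == pytest.approx(0.0)

    def test_even_n_median_split(self):
        strat = sr.stratify_median(np.array([1.0, 2.0, 3.0, 4.0]))
        assert strat.cutoff == 2.5
        assert list(strat.groups) == ["low", "low", "high", "high"]

    def test_all_zero_scores_degenerate_all_high(self):
        strat = sr.stratify_median(np.zeros(5))
        assert strat.degenerate
        assert (strat.groups == "high").all()

    def test_training_cutoff_carries_to_validation(self):
        strat = sr.stratify_median(np.array([0.0, 1.0, 2.0, 5.0]), cutoff=1.5)
        assert list(strat.groups) == ["low", "low", "high", "high"]


class TestLogrank:
    def test_identical_groups_null(self):
        time = np.array([3.0, 5.0, 7.0, 3.0, 5.0, 7.0])
        event = np.array([1, 1, 0, 1, 1, 0])
        groups = np.array(["a"] * 3 + ["b"] * 3)
        chi2, p = sr.logrank_test(time, event, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_hand_enumerated_toy(self):
        # A: (1,2) both events; B: (3,4) both events.
        # risk sets: t=1: n=4,n_A=2,O=1,E=1/2,V=(2/4)(2/4)(3/3)=1/4
        #            t=2: n=3,n_A=1,O=1,E=1/3,V=(1/3)(2/3)(2/2)=2/9
        #            t=3: n=2,n_A=0; t=4: n=1,n_A=0
        # O-E = 2 - 5/6 = 7/6; V = 1/4 + 2/9 = 17/36; chi2 = (7/6)^2/(17/36)
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.ones(4, dtype=int)
        groups = np.array(["A", "A", "B", "B"])
        chi2, _ = sr.logrank_test(time, event, groups)
        assert chi2 == pytest.approx((7 / 6) ** 2 / (17 / 36), rel=1e-12)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(7)
        n = 80
        time = rng.exponential(10, n)
        event = (rng.random(n) < 0.7).astype(int)
        groups = np.where(rng.random(n) < 0.5, "a", "b")
        chi2, p = sr.logrank_test(time, event, groups)
        res = lifelines.statistics.logrank_test(
            time[groups == "a"], time[groups == "b"],
            event[groups == "a"], event[groups == "b"],
        )
        assert chi2 == pytest.approx(res.test_statistic, rel=1e-9)
        assert p == pytest.approx(res.p_value, rel=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            sr.logrank_test(np.array([1.0, 2.0]), np.array([1, 1]),
                            np.array(["a", "a"]))


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        km = sr.km_curve(np.array([1.0, 2.0, 3.0]), np.zeros(3, dtype=int))
        assert (km["survival"] == 1.0).all()

    def test_product_limit_hand_values(self):
        km = sr.km_curve(np.array([1.0, 2.0, 3.0]), np.ones(3, dtype=int))
        np.testing.assert_allclose(km["survival"], [1.0, 2 / 3, 1 / 3, 0.0])

    def test_early_censoring_leaves_curve_unchanged_at_value(self):
        km = sr.km_curve(np.array([0.5, 1.0, 2.0]), np.array([0, 1, 1]))
        # censored at 0.5 reduces the risk set but adds no step
        np.testing.assert_allclose(km["survival"], [1.0, 0.5, 0.0])
        assert list(km["time"]) == [0.0, 1.0, 2.0]


def cindex_bruteforce(scores, time, event):
    conc = disc = tied = 0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if time[i] < time[j] and event[i] == 1:
                if scores[i] > scores[j]:
                    conc += 1
                elif scores[i] < scores[j]:
                    disc += 1
                else:
                    tied += 1
    return conc, disc, tied


class TestConcordance:
    def test_perfect_concordance(self):
        time = np.array([5.0, 3.0, 9.0, 1.0])
        rep = sr.concordance_index(-time, time, np.ones(4, dtype=int))
        assert rep.cindex == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=60)
        time = rng.exponential(5, 60)
        event = (rng.random(60) < 0.7).astype(int)
        a = sr.concordance_index(scores, time, event).cindex
        b = sr.concordance_index(-scores, time, event).cindex
        assert a + b == pytest.approx(1.0)

    def test_matches_bruteforce_pair_counting(self):
        rng = np.random.default_rng(2)
        n = 50
        scores = np.round(rng.normal(size=n), 1)  # induce some score ties
        time = rng.exponential(5, n)
        event = (rng.random(n) < 0.6).astype(int)
        rep = sr.concordance_index(scores, time, event)
        conc, disc, tied = cindex_bruteforce(scores, time, event)
        assert (rep.concordant, rep.discordant, rep.tied) == (conc, disc, tied)
        assert rep.cindex == pytest.approx((conc + 0.5 * tied) / (conc + disc + tied))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=40)
        time = rng.exponential(5, 40)
        event = np.ones(40, dtype=int)
        a = sr.concordance_index(scores, time, event).cindex
        b = sr.concordance_index(np.exp(3 * scores), time, event).cindex
        assert a == b

    def test_no_usable_pairs_rejected(self):
        with pytest.raises(ValidationError):
            sr.concordance_index(np.array([1.0, 2.0]), np.array([5.0, 5.0]),
                                 np.array([1, 1]))
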