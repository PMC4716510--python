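import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from kindyad import (DemographyConfig, MaleResidenceRecord, cluster_bootstrap,
                     cox_fit, gen_demography, km_curve, records_to_frame,
                     stay_one_year_test, tenure_model)


def _rec(male, dur, censored=False, kin=False, **kw):
    return MaleResidenceRecord(male_id=male, group_id=kw.pop("group", "G"),
                               entry_month=kw.pop("entry", 0),
                               duration_months=dur, censored=censored,
                               kin_at_entry=kin, **kw)


class TestKaplanMeier:
    def test_four_distinct_events(self):
        recs = [_rec(f"m{i}", d) for i, d in enumerate([3, 7, 10, 15])]
        curve = km_curve(recs)["all"]
        assert list(curve["survival"]) == pytest.approx([1, 0.75, 0.5, 0.25, 0])

    def test_all_censored_flat(self):
        recs = [_rec(f"m{i}", 10, censored=True) for i in range(5)]
        curve = km_curve(recs)["all"]
        assert (curve["survival"] == 1).all()

    def test_hand_computed_mixed_fixture(self):
        # events at 2 (1 of 6) and 5 (2 of 4), censored at 3 and 5 and 8:
        # S(2) = 5/6; S(5) = 5/6 * (4-2)/4 = 5/12
        recs = [_rec("a", 2), _rec("b", 3, censored=True), _rec("c", 5),
                _rec("d", 5), _rec("e", 5, censored=True),
                _rec("f", 8, censored=True)]
        curve = km_curve(recs)["all"]
        assert list(curve["time"]) == [0, 2, 5]
        assert list(curve["survival"]) == pytest.approx([1, 5 / 6, 5 / 12])

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        recs = gen_demography(DemographyConfig(n_males=80, seed=21))
        curve = km_curve(recs)["all"]
        kmf = lifelines.KaplanMeierFitter()
        kmf.fit([r.duration_months for r in recs],
                [not r.censored for r in recs])
        for _, row in curve.iterrows():
            assert row["survival"] == pytest.approx(
                float(kmf.predict(row["time"])), abs=1e-9)

    def test_stratified_and_empty(self):
        recs = [_rec("a", 5, kin=True), _rec("b", 8)]
        strata = km_curve(recs, group_by="kin_at_entry")
        assert set(strata) == {True, False}
        with pytest.raises(ValueError):
            km_curve([])


def _breslow_loglik_oracle(beta, recs, covariate="kin_at_entry"):
    """Independent brute-force Breslow partial log-likelihood."""
    ll = 0.0
    for r in recs:
        if r.censored:
            continue
        x_i = float(getattr(r, covariate))
        risk = [o for o in recs if o.duration_months >= r.duration_months]
        denom = sum(math.exp(beta * float(getattr(o, covariate))) for o in risk)
        ll += beta * x_i - math.log(denom)
    return ll


class TestCox:
    def test_identical_strata_give_zero(self):
        recs = ([_rec(f"a{i}", d, kin=True) for i, d in enumerate([3, 6, 9])]
                + [_rec(f"b{i}", d) for i, d in enumerate([3, 6, 9])])
        fit = cox_fit(recs, ["kin_at_entry"])["kin_at_entry"]
        assert abs(fit.beta) < 1e-6
        assert fit.chi2_lr == pytest.approx(0.0, abs=1e-9)

    def test_matches_bruteforce_partial_likelihood(self):
        recs = [_rec("a", 2, kin=True), _rec("b", 4, kin=True),
                _rec("c", 3), _rec("d", 5), _rec("e", 6, censored=True, kin=True),
                _rec("f", 7)]
        fit = cox_fit(recs, ["kin_at_entry"])["kin_at_entry"]
        res = minimize_scalar(lambda b: -_breslow_loglik_oracle(b, recs),
                              bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-8})
        assert fit.beta == pytest.approx(float(res.x), abs=1e-4)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        recs = gen_demography(DemographyConfig(n_males=200, seed=22))
        # lifelines handles ties by the Efron method
        fit = cox_fit(recs, ["kin_at_entry"], ties="efron")["kin_at_entry"]
        df = records_to_frame(recs)
        df["event"] = ~df["censored"]
        df["kin"] = df["kin_at_entry"].astype(float)
        cph = lifelines.CoxPHFitter()
        cph.fit(df[["duration_months", "event", "kin"]],
                duration_col="duration_months", event_col="event")
        assert fit.beta == pytest.approx(cph.params_["kin"], abs=1e-5)
        assert fit.se == pytest.approx(cph.standard_errors_["kin"], rel=1e-4)

    def test_recovers_true_hazard_ratio(self):
        true_beta = -2.36
        recs = gen_demography(DemographyConfig(n_males=300, seed=23))
        fit = cox_fit(recs, ["kin_at_entry"])["kin_at_entry"]
        assert abs(fit.beta - true_beta) < 2 * fit.se

    def test_interaction_and_multiple_terms(self):
        recs = gen_demography(DemographyConfig(n_males=200, seed=24))
        fits = cox_fit(recs, ["kin_at_entry", "natal_disperser"],
                       interaction=("kin_at_entry", "natal_disperser"))
        assert set(fits) == {"kin_at_entry", "natal_disperser",
                             "kin_at_entry:natal_disperser"}
        for f in fits.values():
            assert f.z == pytest.approx(f.beta / f.se, abs=1e-6)
            assert f.chi2_lr >= -1e-9

    def test_separation_flagged_not_crashed(self):
        recs = ([_rec(f"k{i}", d, kin=True) for i, d in enumerate([1, 2, 3])]
                + [_rec(f"u{i}", d) for i, d in enumerate([20, 30, 40])])
        fit = cox_fit(recs, ["kin_at_entry"])["kin_at_entry"]
        assert not fit.converged
        assert "separation" in fit.note or "monotone" in fit.note

    def test_order_invariance(self):
        recs = gen_demography(DemographyConfig(n_males=100, seed=25))
        fit1 = cox_fit(recs, ["kin_at_entry"])["kin_at_entry"]
        rng = np.random.default_rng(0)
        shuffled = list(recs)
        rng.shuffle(shuffled)
        fit2 = cox_fit(shuffled, ["kin_at_entry"])["kin_at_entry"]
        assert fit1.beta == pytest.approx(fit2.beta, abs=1e-10)

    def test_efron_option_close_to_breslow(self):
        recs = gen_demography(DemographyConfig(n_males=150, seed=26))
        b = cox_fit(recs, ["kin_at_entry"], ties="breslow")["kin_at_entry"].beta
        e = cox_fit(recs, ["kin_at_entry"], ties="efron")["kin_at_entry"].beta
        assert abs(b - e) < 0.2


def _two_binomial_lr_oracle(k1, n1, k0, n0):
    """Textbook LR chi-square for two binomial proportions."""
    def ll(k, n, p):
        if p in (0, 1):
            return 0.0 if k in (0, n) else -math.inf
        return k * math.log(p) + (n - k) * math.log(1 - p)
    p_pool = (k1 + k0) / (n1 + n0)
    return 2 * (ll(k1, n1, k1 / n1) + ll(k0, n0, k0 / n0)
                - ll(k1, n1, p_pool) - ll(k0, n0, p_pool))


class TestStayOneYear:
    def _records_from_2x2(self, stay_kin, n_kin, stay_no, n_no):
        recs = []
        for i in range(n_kin):
            recs.append(_rec(f"k{i}", 20 if i < stay_kin else 5, kin=True))
        for i in range(n_no):
            recs.append(_rec(f"u{i}", 20 if i < stay_no else 5))
        return recs

    def test_balanced_table_is_null(self):
        recs = self._records_from_2x2(5, 10, 5, 10)
        fit = stay_one_year_test(recs, "kin_at_entry")
        assert fit.chi2_lr == pytest.approx(0.0, abs=1e-8)

    def test_matches_closed_form_lr(self):
        recs = self._records_from_2x2(10, 12, 5, 10)
        fit = stay_one_year_test(recs, "kin_at_entry")
        oracle = _two_binomial_lr_oracle(10, 12, 5, 10)
        assert fit.chi2_lr == pytest.approx(oracle, abs=1e-6)

    def test_censored_before_twelve_excluded(self):
        recs = self._records_from_2x2(6, 10, 4, 10)
        recs.append(_rec("cens", 5, censored=True))
        fit = stay_one_year_test(recs, "kin_at_entry")
        assert fit.n == 20
        assert "1 records censored" in fit.note

    def test_perfect_separation_reported(self):
        recs = self._records_from_2x2(10, 10, 3, 10)  # all kin males stay
        fit = stay_one_year_test(recs, "kin_at_entry")
        assert not fit.converged or fit.beta > 15
        assert np.isfinite(fit.chi2_lr)
        oracle = _two_binomial_lr_oracle(10, 10, 3, 10)
        assert fit.chi2_lr == pytest.approx(oracle, abs=1e-4)

    def test_constant_outcome_refused(self):
        recs = self._records_from_2x2(10, 10, 10, 10)
        with pytest.raises(ValueError):
            stay_one_year_test(recs, "kin_at_entry")


class TestTenure:
    def test_eligibility_filter(self):
        recs = [
            _rec("a", 30, kin=True, high_rank_tenure_months=20.0, max_rank=3,
                 group_n_nonnatal_males=4),   # rank 3 in a small group: out
            _rec("b", 30, kin=True, high_rank_tenure_months=25.0, max_rank=2,
                 group_n_nonnatal_males=4),
            _rec("c", 30, high_rank_tenure_months=10.0, max_rank=1,
                 group_n_nonnatal_males=8),
            _rec("d", 30, high_rank_tenure_months=12.0, max_rank=3,
                 group_n_nonnatal_males=8),
        ]
        fit = tenure_model(recs, "kin_at_entry")
        assert fit.n == 3
        no_rule = tenure_model(recs, "kin_at_entry", min_males_rule=False)
        assert no_rule.n == 4

    def test_equal_means_zero_slope(self):
        recs = [
            _rec("a", 30, kin=True, high_rank_tenure_months=10.0, max_rank=1),
            _rec("b", 30, kin=True, high_rank_tenure_months=20.0, max_rank=1),
            _rec("c", 30, high_rank_tenure_months=12.0, max_rank=2),
            _rec("d", 30, high_rank_tenure_months=18.0, max_rank=2),
        ]
        fit = tenure_model(recs, "kin_at_entry")
        assert fit.beta == pytest.approx(0.0, abs=1e-9)

    def test_recovers_kin_effect(self):
        recs = gen_demography(DemographyConfig(n_males=120, seed=27))
        fit = tenure_model(recs, "kin_at_entry")
        assert fit.n >= 40
        assert abs(fit.beta - 12.7) < 2 * fit.se

    def test_no_eligible_records(self):
        recs = [_rec("a", 30, max_rank=5)]
        with pytest.raises(ValueError, match="high-rank"):
            tenure_model(recs, "kin_at_entry")


class TestClusterBootstrap:
    @staticmethod
    def _mean_diff(recs):
        kin = [r.duration_months for r in recs if r.kin_at_entry]
        non = [r.duration_months for r in recs if not r.kin_at_entry]
        return float(np.mean(kin) - np.mean(non))

    def test_deterministic_given_seed(self):
        recs = gen_demography(DemographyConfig(n_males=60, seed=28))
        a = cluster_bootstrap(recs, self._mean_diff, n_boot=200, seed=5)
        b = cluster_bootstrap(recs, self._mean_diff, n_boot=200, seed=5)
        assert a == b

    def test_null_coverage(self):
        # under no kin effect the 95% CI should cover zero ~95% of the time
        covered = 0
        n_rep = 30
        for rep in range(n_rep):
            recs = gen_demography(DemographyConfig(
                n_males=120, kin_hazard_ratio=1.0, censor_month=100_000,
                seed=100 + rep))
            ci = cluster_bootstrap(recs, self._mean_diff, n_boot=200,
                                   seed=rep)["ci"]
            covered += ci[0] <= 0 <= ci[1]
        assert covered >= 0.85 * n_rep

    def test_minimum_boot_refused(self):
        recs = gen_demography(DemographyConfig(n_males=20, seed=29))
        with pytest.raises(ValueError):
            cluster_bootstrap(recs, self._mean_diff, n_boot=50, seed=1)
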