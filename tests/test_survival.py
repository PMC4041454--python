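import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank

from cistra.survival import (
    ConvergenceError,
    SurvivalRecord,
    compute_hscore,
    cox_ph,
    dichotomize_first_quartile,
    hf_quantile,
    km_estimate,
    logrank_test,
    optimal_cutpoint,
    read_clinical_tsv,
    write_km_tsv,
)
from cistra.synthetic import SyntheticSpec, gen_survival


def rec(i, t, e, **cov):
    return SurvivalRecord(f"s{i}", t, e, cov)


def random_records(rng, n, hazard=0.1, censor_rate=0.025, covariate=None):
    out = []
    for i in range(n):
        te = rng.exponential(1 / hazard)
        tc = rng.exponential(1 / censor_rate)
        cov = {"x": float(covariate[i])} if covariate is not None else {}
        out.append(rec(i, float(max(min(te, tc), 1e-9)), bool(te <= tc), **cov))
    return out


class TestHScore:
    def test_maximum(self):
        assert compute_hscore(3, 100).h == 300

    def test_zero_intensity(self):
        assert compute_hscore(0, 80).h == 0

    def test_first_quartile_cut_value(self):
        # the clinically reported low/high boundary value
        assert compute_hscore(2, 49).h == 98

    @pytest.mark.parametrize("i,p", [(4, 50), (-1, 50), (2, 101), (2, -1)])
    def test_out_of_range(self, i, p):
        with pytest.raises(ValueError):
            compute_hscore(i, p)


class TestHFQuantile:
    def test_formula_small_fixture(self):
        # h = (4 + 1/3) * 0.25 + 1/3 = 1.41667 -> x1 + 0.41667 * (x2 - x1)
        assert hf_quantile([1, 2, 3, 4], 0.25) == pytest.approx(1.4166666667)

    def test_constant_vector(self):
        for p in (0.0, 0.3, 1.0):
            assert hf_quantile([5, 5, 5], p) == 5

    def test_clamping(self):
        vals = [3, 1, 4, 1, 5]
        assert hf_quantile(vals, 0) == 1
        assert hf_quantile(vals, 1) == 5

    def test_matches_numpy_median_unbiased(self, rng):
        vals = rng.normal(size=25)
        for p in (0.1, 0.25, 0.5, 0.77):
            assert hf_quantile(vals, p) == pytest.approx(
                np.quantile(vals, p, method="median_unbiased")
            )

    def test_median_odd_n(self, rng):
        vals = rng.normal(size=11)
        assert hf_quantile(vals, 0.5) == pytest.approx(np.median(vals))

    def test_empty_error(self):
        with pytest.raises(ValueError):
            hf_quantile([], 0.5)


class TestKMEstimate:
    def test_hand_product_limit(self):
        records = [rec(0, 1, True), rec(1, 2, False), rec(2, 3, True)]
        km = km_estimate(records)
        assert km.times.tolist() == [1.0, 3.0]
        assert km.survival[0] == pytest.approx(2 / 3)
        assert km.survival[1] == pytest.approx(0.0)

    def test_all_censored(self):
        records = [rec(i, float(i + 1), False) for i in range(5)]
        km = km_estimate(records)
        assert km.times.size == 0
        assert km.survival_at(100.0) == 1.0

    def test_equals_one_minus_ecdf_no_censoring(self, rng):
        times = rng.exponential(10, 20)
        records = [rec(i, float(t), True) for i, t in enumerate(times)]
        km = km_estimate(records)
        for t, s in zip(km.times, km.survival):
            ecdf = np.mean(times <= t)
            assert s == pytest.approx(1 - ecdf)

    def test_non_increasing(self, rng):
        records = random_records(rng, 50)
        km = km_estimate(records)
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert np.all(km.ci_low <= km.survival + 1e-12)
        assert np.all(km.survival <= km.ci_high + 1e-12)

    def test_matches_lifelines(self, rng):
        records = random_records(rng, 80)
        km = km_estimate(records)
        t = [r.time for r in records]
        e = [r.event for r in records]
        kmf = KaplanMeierFitter().fit(t, e)
        ref = kmf.survival_function_["KM_estimate"]
        for tt, s in zip(km.times, km.survival):
            assert s == pytest.approx(ref.loc[tt], abs=1e-12)
        ci = kmf.confidence_interval_
        lo = ci.iloc[:, 0].loc[km.times].to_numpy()
        hi = ci.iloc[:, 1].loc[km.times].to_numpy()
        assert np.allclose(km.ci_low, lo, atol=1e-9)
        assert np.allclose(km.ci_high, hi, atol=1e-9)

    def test_nonpositive_time(self):
        with pytest.raises(ValueError):
            rec(0, 0.0, True)

    def test_roundtrip_tsv(self, tmp_path, rng):
        km = km_estimate(random_records(rng, 30))
        write_km_tsv(km, tmp_path / "km.tsv")
        df = pd.read_csv(tmp_path / "km.tsv", sep="\t")
        assert np.allclose(df["survival"], km.survival)


class TestLogrank:
    def test_identical_groups(self, rng):
        grp = random_records(rng, 30)
        chi2, p = logrank_test(grp, list(grp))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_lifelines(self, rng):
        a = random_records(rng, 40)
        b = random_records(rng, 35, hazard=0.2)
        chi2, p = logrank_test(a, b)
        res = ll_logrank(
            [r.time for r in a],
            [r.time for r in b],
            [r.event for r in a],
            [r.event for r in b],
        )
        assert chi2 == pytest.approx(res.test_statistic, rel=1e-9)
        assert p == pytest.approx(res.p_value, rel=1e-9)

    def test_power_with_planted_hazard_ratio(self):
        rng = np.random.default_rng(5150)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            a = random_records(rng, 100, hazard=0.05, censor_rate=0.0125)
            b = random_records(rng, 100, hazard=0.15, censor_rate=0.0375)
            chi2, p = logrank_test(a, b)
            hits += p < 0.01
        assert hits / n_rep >= 0.95

    def test_null_calibration(self):
        rng = np.random.default_rng(6021)
        rej = 0
        n_rep = 200
        for _ in range(n_rep):
            a = random_records(rng, 50)
            b = random_records(rng, 50)
            _, p = logrank_test(a, b)
            rej += p < 0.05
        assert 0.02 <= rej / n_rep <= 0.08

    def test_empty_group_error(self, rng):
        with pytest.raises(ValueError):
            logrank_test([], random_records(rng, 5))

    def test_no_events_error(self):
        a = [rec(0, 1.0, False)]
        b = [rec(1, 2.0, False)]
        with pytest.raises(ValueError):
            logrank_test(a, b)


class TestCoxPH:
    def test_symmetric_groups_beta_zero(self):
        # two groups with identical event patterns
        a = [rec(i, float(i + 1), True, x=0.0) for i in range(5)]
        b = [rec(i + 10, float(i + 1), True, x=1.0) for i in range(5)]
        res = cox_ph(a + b, ["x"])
        assert res.coef[0] == pytest.approx(0.0, abs=1e-8)

    def test_matches_lifelines(self, rng):
        x = rng.normal(0, 1, 120)
        haz = 0.05 * np.exp(0.5 * x)
        te = rng.exponential(1 / haz)
        tc = rng.exponential(60, 120)
        records = [
            rec(i, float(max(min(a, c), 1e-9)), bool(a <= c), x=float(xx))
            for i, (a, c, xx) in enumerate(zip(te, tc, x))
        ]
        mine = cox_ph(records, ["x"])
        df = pd.DataFrame(
            {
                "T": [r.time for r in records],
                "E": [int(r.event) for r in records],
                "x": x,
            }
        )
        ref = CoxPHFitter().fit(df, "T", "E")
        assert mine.coef[0] == pytest.approx(ref.params_["x"], abs=1e-5)
        assert mine.se[0] == pytest.approx(ref.standard_errors_["x"], abs=1e-5)

    def test_matches_lifelines_with_ties(self, rng):
        # integer (month-granularity) times force ties; lifelines uses Efron
        x = rng.normal(0, 1, 100)
        te = np.ceil(rng.exponential(10, 100))
        records = [
            rec(i, float(t), True, x=float(xx)) for i, (t, xx) in enumerate(zip(te, x))
        ]
        mine = cox_ph(records, ["x"])
        df = pd.DataFrame({"T": te, "E": 1, "x": x})
        ref = CoxPHFitter().fit(df, "T", "E")
        assert mine.coef[0] == pytest.approx(ref.params_["x"], abs=1e-5)

    def test_score_test_equals_logrank_no_ties(self, rng):
        for _ in range(50):
            n = int(rng.integers(20, 60))
            grp = rng.random(n) < 0.5
            if grp.all() or (~grp).all():
                continue
            records = random_records(rng, n, covariate=grp.astype(float))
            if not any(r.event for r in records):
                continue
            a = [r for r, g in zip(records, grp) if not g]
            b = [r for r, g in zip(records, grp) if g]
            if not a or not b:
                continue
            chi2, _ = logrank_test(a, b)
            res = cox_ph(records, ["x"])
            assert res.score_chi2 == pytest.approx(chi2, abs=1e-6)

    def test_parameter_recovery_hr2(self):
        rng = np.random.default_rng(314)
        cover = 0
        n_rep = 100
        for _ in range(n_rep):
            spec = SyntheticSpec(seed=int(rng.integers(2**31)), hr=2.0,
                                 censor_frac=0.2)
            _, recs = gen_survival(500, spec, "step", step_at=0.5)
            recs2 = [
                SurvivalRecord(
                    r.subject_id, r.time, r.event,
                    {"hi": 1.0 if r.covariates["score"] > 0.5 else 0.0},
                )
                for r in recs
            ]
            res = cox_ph(recs2, ["hi"])
            lo, hi = res.ci()[0]
            cover += lo <= np.log(2) <= hi
        assert cover / n_rep >= 0.90

    def test_constant_covariate_error(self, rng):
        records = random_records(rng, 20, covariate=np.ones(20))
        with pytest.raises(ValueError, match="constant"):
            cox_ph(records, ["x"])

    def test_no_events_error(self):
        records = [rec(i, 1.0 + i, False, x=float(i)) for i in range(5)]
        with pytest.raises(ValueError):
            cox_ph(records, ["x"])

    def test_separation_flagged(self):
        # perfect separation: all events in one group, before any censoring
        records = [rec(i, float(i + 1), True, x=1.0) for i in range(10)]
        records += [rec(i + 10, float(i + 100), False, x=0.0) for i in range(10)]
        res = cox_ph(records, ["x"])
        assert any("monotone" in w for w in res.warnings)

    def test_multivariate(self, rng):
        x1 = rng.normal(0, 1, 150)
        x2 = rng.normal(0, 1, 150)
        haz = 0.05 * np.exp(0.4 * x1 - 0.3 * x2)
        te = rng.exponential(1 / haz)
        records = [
            rec(i, float(t), True, a=float(u), b=float(v))
            for i, (t, u, v) in enumerate(zip(te, x1, x2))
        ]
        res = cox_ph(records, ["a", "b"])
        df = pd.DataFrame({"T": te, "E": 1, "a": x1, "b": x2})
        ref = CoxPHFitter().fit(df, "T", "E")
        assert np.allclose(res.coef, ref.params_.values, atol=1e-5)


class TestOptimalCutpoint:
    def test_two_distinct_values(self):
        recs = [rec(i, float(i + 1), True, s=0.0) for i in range(10)]
        recs += [rec(i + 10, float(i + 20), True, s=1.0) for i in range(10)]
        scores = {r.subject_id: r.covariates["s"] for r in recs}
        res = optimal_cutpoint(scores, recs, qrange=(0.05, 0.95))
        assert res.cut == 0.0  # split at 'score > 0'

    def test_planted_step_recovery(self):
        spec = SyntheticSpec(seed=3, hr=3.0, censor_frac=0.2)
        scores, recs = gen_survival(200, spec, "step", step_at=0.6)
        res = optimal_cutpoint(scores, recs)
        assert abs(res.cut - 0.6) <= 0.1

    def test_naive_not_above_adjusted(self, rng):
        spec = SyntheticSpec(seed=8, hr=2.0, censor_frac=0.2)
        scores, recs = gen_survival(120, spec, "step")
        res = optimal_cutpoint(scores, recs, n_perm=99, seed=11)
        assert res.p_naive <= res.p_adjusted + 1e-12

    def test_permutation_calibration(self):
        rng = np.random.default_rng(272)
        rej = 0
        n_rep = 200
        for i in range(n_rep):
            spec = SyntheticSpec(seed=int(rng.integers(2**31)), hr=1.0,
                                 censor_frac=0.2)
            scores, recs = gen_survival(80, spec, "none")
            res = optimal_cutpoint(
                scores, recs, n_perm=99, seed=int(rng.integers(2**31))
            )
            rej += res.p_adjusted <= 0.05
        assert 0.02 <= rej / n_rep <= 0.08

    def test_constant_scores_error(self, rng):
        recs = random_records(rng, 10)
        scores = {r.subject_id: 1.0 for r in recs}
        with pytest.raises(ValueError, match="constant"):
            optimal_cutpoint(scores, recs)

    def test_reproducible(self):
        spec = SyntheticSpec(seed=5, hr=2.0)
        scores, recs = gen_survival(100, spec, "step")
        r1 = optimal_cutpoint(scores, recs, n_perm=99, seed=4)
        r2 = optimal_cutpoint(scores, recs, n_perm=99, seed=4)
        assert (r1.cut, r1.p_adjusted) == (r2.cut, r2.p_adjusted)


class TestDichotomize:
    def test_boundary_is_low(self):
        cut, labels = dichotomize_first_quartile([0, 98, 150, 300])
        # Q1 of (0, 98, 150, 300) via the median-unbiased rule
        assert labels[0] == "low"
        boundary = [v for v in (0, 98, 150, 300) if v <= cut]
        assert all(
            lab == ("low" if v <= cut else "high")
            for v, lab in zip((0, 98, 150, 300), labels)
        )
        assert len(boundary) >= 1

    def test_all_equal_degenerate(self, caplog):
        with caplog.at_level("WARNING"):
            cut, labels = dichotomize_first_quartile([7.0] * 8)
        assert set(labels) == {"low"}

    def test_group_sizes_104(self, rng):
        scores = rng.normal(150, 60, 104)
        cut, labels = dichotomize_first_quartile(scores)
        n_low = labels.count("low")
        assert abs(n_low - 26) <= 1  # quartile arithmetic, no ties expected

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            dichotomize_first_quartile([1, 2, 3])


class TestClinicalIO:
    def test_roundtrip(self, tmp_path):
        df = pd.DataFrame(
            {
                "subject_id": ["a", "b"],
                "time_months": [12.5, 30.0],
                "event": [1, 0],
                "score": [0.3, 0.9],
                "age": [61.0, 55.0],
            }
        )
        p = tmp_path / "clin.tsv"
        df.to_csv(p, sep="\t", index=False)
        records = read_clinical_tsv(p)
        assert records[0].event and not records[1].event
        assert records[1].covariates == {"score": 0.9, "age": 55.0}

    def test_missing_columns(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("subject_id\ttime_months\na\t5\n")
        with pytest.raises(ValueError, match="event"):
            read_clinical_tsv(p)
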