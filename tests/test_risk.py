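"""Risk-model tests: Youden oracle, Cox properties, LR, KM, competing risks, PH checks."""
import shutil
import subprocess
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thoraxcomp.cohort import CohortSpec, simulate_cohort
from thoraxcomp.risk import (
    ModelSpec,
    competing_risk_mi,
    fit_cox,
    km_stratified,
    lr_chi2_increment,
    null_partial_loglik,
    schoenfeld_check,
    youden_thresholds,
)

warnings.filterwarnings("ignore", module="lifelines")


# ---------------------------------------------------------------------------
# Youden thresholds
# ---------------------------------------------------------------------------

def youden_bruteforce(values, outcome):
    """Independent exhaustive search with the documented tie-breaks."""
    best = None
    npos = int(np.count_nonzero(outcome == 1))
    nneg = int(np.count_nonzero(outcome == 0))
    for dircode, direction in ((0, "abnormal-above"), (1, "abnormal-below")):
        for c in np.unique(values):
            abn = values >= c if dircode == 0 else values <= c
            sens = np.count_nonzero(abn & (outcome == 1)) / npos
            spec = np.count_nonzero(~abn & (outcome == 0)) / nneg
            j = sens + spec - 1.0
            cand = (j, sens, c, direction, spec)
            if best is None:
                best = cand
            else:
                bj, bs, bc = best[0], best[1], best[2]
                if j > bj or (j == bj and sens > bs) or (j == bj and sens == bs and c < bc):
                    best = cand
    return best


class TestYouden:
    def test_separable_example(self):
        ts = youden_thresholds([1, 2, 3, 4], [0, 0, 1, 1], ["f"] * 4)
        t = ts.per_sex["f"]
        assert t.cutpoint == 3 and t.direction == "abnormal-above" and t.j == 1.0

    def test_uninformative_values_tie_at_zero(self):
        ts = youden_thresholds([1, 1, 2, 2], [0, 1, 0, 1], ["f"] * 4)
        t = ts.per_sex["f"]
        assert t.j == 0.0 and t.tied

    def test_single_class_stratum_named(self):
        with pytest.raises(ValueError, match="male"):
            youden_thresholds([1, 2, 3, 4], [0, 0, 1, 1], ["female", "female", "male", "male"])

    def test_sex_strata_independent(self, rng):
        v = rng.normal(size=200)
        y = (rng.uniform(size=200) < 0.4).astype(int)
        sex = np.where(rng.uniform(size=200) < 0.5, "female", "male")
        y[:2] = [0, 1]  # guarantee both classes overall
        ts = youden_thresholds(v, y, sex)
        for group in ("female", "male"):
            m = sex == group
            ref = youden_bruteforce(v[m], y[m])
            t = ts.per_sex[group]
            assert (t.j, t.sensitivity, t.cutpoint, t.direction) == ref[:4]

    @pytest.mark.parametrize("case", range(100))
    def test_matches_bruteforce_oracle(self, case):
        rng = np.random.default_rng(5000 + case)
        n = int(rng.integers(4, 200))
        ties = rng.uniform() < 0.5
        v = rng.integers(0, 12, size=n).astype(float) if ties else rng.normal(size=n)
        y = (rng.uniform(size=n) < rng.uniform(0.2, 0.8)).astype(int)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        ref = youden_bruteforce(v, y)
        t = youden_thresholds(v, y, ["x"] * n).per_sex["x"]
        assert (t.j, t.sensitivity, t.cutpoint, t.direction) == ref[:4]


# ---------------------------------------------------------------------------
# Cox models
# ---------------------------------------------------------------------------

def _one_covariate_cohort(n, beta, seed, shape=1.3, scale=8.0, censor=10.0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    t = scale * (-np.log(rng.uniform(size=n)) / np.exp(beta * x)) ** (1 / shape)
    c = rng.uniform(0, censor, size=n)
    return pd.DataFrame(
        {"x": x, "time_years": np.minimum(t, c), "death_or_mi": (t <= c).astype(int)}
    )


class TestFitCox:
    def test_null_effect_ci_spans_one(self):
        df = _one_covariate_cohort(800, beta=0.0, seed=1)
        res = fit_cox(df, ModelSpec(covariates=("x",)))
        row = res.summary.loc["x"]
        assert row["hr_lower"] < 1.0 < row["hr_upper"]

    def test_per_sd_hr_invariant_to_rescaling(self):
        df = _one_covariate_cohort(500, beta=np.log(2), seed=2)
        r1 = fit_cox(df, ModelSpec(covariates=("x",)))
        df2 = df.assign(x=df["x"] * 10.0)
        r2 = fit_cox(df2, ModelSpec(covariates=("x",)))
        assert r1.hr("x") == pytest.approx(r2.hr("x"), rel=1e-9)

    def test_known_effect_recovered(self):
        df = _one_covariate_cohort(4000, beta=np.log(2), seed=3)
        res = fit_cox(df, ModelSpec(covariates=("x",)))
        assert res.summary.loc["x", "coef"] == pytest.approx(np.log(2), abs=0.08)

    def test_log_transform_changes_design(self):
        df = _one_covariate_cohort(500, beta=0.3, seed=4)
        df["pos"] = np.exp(df["x"])
        r_log = fit_cox(df, ModelSpec(covariates=("pos",), log_transform=("pos",)))
        r_raw = fit_cox(df, ModelSpec(covariates=("pos",)))
        assert r_log.hr("pos") != pytest.approx(r_raw.hr("pos"), rel=1e-6)
        assert r_log.log_transformed == ("pos",)

    def test_log_transform_rejects_nonpositive(self):
        df = _one_covariate_cohort(200, beta=0.0, seed=5)
        with pytest.raises(ValueError, match="log-transform"):
            fit_cox(df, ModelSpec(covariates=("x",), log_transform=("x",)))

    def test_categorical_cac_reference_zero(self):
        df = simulate_cohort(CohortSpec(n=1500, seed=13)).table
        res = fit_cox(
            df,
            ModelSpec(covariates=("age", "cac_category"), categorical={"cac_category": "0"}),
        )
        assert "cac_category[1-99]" in res.terms
        assert "cac_category[0]" not in res.terms
        assert len(res.terms) == 4  # age + 3 non-reference CAC levels

    def test_too_few_events_rejected(self):
        df = _one_covariate_cohort(30, beta=0.0, seed=6, censor=0.1)
        with pytest.raises(ValueError, match="events"):
            fit_cox(df, ModelSpec(covariates=("x",)))

    def test_null_loglik_matches_lifelines_lr_machinery(self):
        df = _one_covariate_cohort(400, beta=0.4, seed=7)
        res = fit_cox(df, ModelSpec(covariates=("x",)))
        lifelines_chi2 = res.model.log_likelihood_ratio_test().test_statistic
        mine = 2 * (res.log_likelihood - res.ll_null)
        assert mine == pytest.approx(lifelines_chi2, rel=1e-8)

    def test_ties_efron_null_loglik(self):
        # all-distinct and heavily tied data both satisfy the closed form
        t = np.array([1.0, 1.0, 1.0, 2.0, 3.0])
        e = np.array([1, 1, 0, 1, 1])
        # events at t=1 (2 ties, 5 at risk), t=2 (2 at risk), t=3 (1 at risk)
        expected = -(np.log(5) + np.log(4)) - np.log(2) - np.log(1)
        assert null_partial_loglik(t, e) == pytest.approx(expected, rel=1e-12)


class TestLRIncrement:
    def test_collinear_addition_adds_nothing(self):
        # an exactly duplicated covariate is singular for the plain partial
        # likelihood: the failure must be loud, and under a vanishing ridge
        # the duplicated parameter adds (essentially) zero model fit
        from lifelines.exceptions import ConvergenceError

        df = _one_covariate_cohort(400, beta=0.4, seed=8)
        df["x2"] = df["x"]
        with pytest.raises(ConvergenceError):
            fit_cox(df, ModelSpec(covariates=("x", "x2")))
        base = fit_cox(df, ModelSpec(covariates=("x",), penalizer=1e-7))
        ext = fit_cox(df, ModelSpec(covariates=("x", "x2"), penalizer=1e-7))
        inc = lr_chi2_increment(base, ext)
        assert inc.chi2 == pytest.approx(0.0, abs=1e-2)

    def test_additivity_over_nested_chain(self):
        df = simulate_cohort(CohortSpec(n=1500, seed=14)).table
        a = fit_cox(df, ModelSpec(covariates=("age",)))
        b = fit_cox(df, ModelSpec(covariates=("age", "vat_density_hu")))
        c = fit_cox(df, ModelSpec(covariates=("age", "vat_density_hu", "sm_vol_idx")))
        ab, bc, ac = lr_chi2_increment(a, b), lr_chi2_increment(b, c), lr_chi2_increment(a, c)
        assert ac.chi2 == pytest.approx(ab.chi2 + bc.chi2, abs=1e-6)

    def test_true_effect_beats_noise(self):
        rng = np.random.default_rng(15)
        chis_true, chis_noise = [], []
        for rep in range(20):
            df = _one_covariate_cohort(400, beta=np.log(2), seed=100 + rep)
            df["noise"] = rng.standard_normal(len(df))
            base = fit_cox(df, ModelSpec(covariates=("noise",)))
            ext = fit_cox(df, ModelSpec(covariates=("noise", "x")))
            chis_true.append(lr_chi2_increment(base, ext).chi2)
            base2 = fit_cox(df, ModelSpec(covariates=("x",)))
            ext2 = fit_cox(df, ModelSpec(covariates=("x", "noise")))
            chis_noise.append(lr_chi2_increment(base2, ext2).chi2)
        assert np.median(chis_true) > np.median(chis_noise)

    def test_non_nested_rejected(self):
        df = _one_covariate_cohort(400, beta=0.4, seed=9)
        df["z"] = np.random.default_rng(0).standard_normal(len(df))
        a = fit_cox(df, ModelSpec(covariates=("x",)))
        b = fit_cox(df, ModelSpec(covariates=("z",)))
        with pytest.raises(ValueError, match="nested"):
            lr_chi2_increment(a, b)

    def test_different_samples_rejected(self):
        df = _one_covariate_cohort(400, beta=0.4, seed=10)
        a = fit_cox(df, ModelSpec(covariates=("x",)))
        b = fit_cox(df.iloc[:300], ModelSpec(covariates=("x",)))
        with pytest.raises(ValueError, match="different samples"):
            lr_chi2_increment(a, b)

    def test_significance_gate_at_adjusted_alpha(self):
        df = _one_covariate_cohort(4000, beta=np.log(2), seed=11)
        base = fit_cox(df, ModelSpec(covariates=()))
        ext = fit_cox(df, ModelSpec(covariates=("x",)))
        inc = lr_chi2_increment(base, ext)
        assert inc.significant and inc.alpha == 0.001


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

class TestKM:
    def test_product_limit_arithmetic(self):
        df = pd.DataFrame(
            {
                "time_years": [1, 2, 3, 4, 1, 2, 3, 4],
                "death_or_mi": [1] * 8,
                "grp": ["a"] * 4 + ["b"] * 4,
            }
        )
        km = km_stratified(df, "grp")
        curve = km.curves["a"].set_index("time")["survival"]
        assert curve.loc[2.0] == 0.5

    def test_all_censored_curve_is_one(self):
        df = pd.DataFrame(
            {
                "time_years": [1, 2, 3, 4, 1.0, 2.0],
                "death_or_mi": [0, 0, 0, 0, 1, 1],
                "grp": ["a"] * 4 + ["b"] * 2,
            }
        )
        km = km_stratified(df, "grp")
        assert (km.curves["a"]["survival"] == 1.0).all()

    def test_no_censoring_equals_one_minus_ecdf(self, rng):
        t = rng.exponential(scale=3.0, size=300)
        df = pd.DataFrame({"time_years": np.r_[t, t], "death_or_mi": 1, "grp": ["a"] * 300 + ["b"] * 300})
        km = km_stratified(df, "grp")
        curve = km.curves["a"]
        ecdf = np.searchsorted(np.sort(t), curve["time"], side="right") / len(t)
        assert np.max(np.abs(curve["survival"].to_numpy() - (1 - ecdf))) < 1e-12

    def test_two_group_hr_recovery(self):
        rng = np.random.default_rng(16)
        n = 2000
        grp = rng.uniform(size=n) < 0.5
        t = np.where(grp, rng.exponential(0.5, n), rng.exponential(1.0, n))
        df = pd.DataFrame(
            {"time_years": t, "death_or_mi": 1, "grp": np.where(grp, "high", "low")}
        )
        km = km_stratified(df, "grp")
        row = km.hazard_ratios.iloc[0]
        assert row["reference"] == "high" and row["group"] == "low"
        assert row["hr_lower"] < 0.5 < row["hr_upper"]

    def test_single_group_rejected(self):
        df = pd.DataFrame({"time_years": [1, 2], "death_or_mi": [1, 1], "grp": ["a", "a"]})
        with pytest.raises(ValueError, match="two groups"):
            km_stratified(df, "grp")


# ---------------------------------------------------------------------------
# Competing risks
# ---------------------------------------------------------------------------

def _competing_spec(**kw):
    defaults = dict(
        n=2000,
        seed=20,
        beta_death={"age": 0.3},
        beta_mi={"vat_density_hu": 0.35},
        mi_shape=1.0,
        mi_scale=8.0,
        death_shape=1.0,
        death_scale=10.0,
    )
    defaults.update(kw)
    return CohortSpec(**defaults)


class TestCompetingRisk:
    def test_null_covariate_ci_spans_one(self):
        df = simulate_cohort(_competing_spec(beta_mi={})).table
        res = competing_risk_mi(df, ModelSpec(covariates=("imat_vol_idx",)))
        row = res.summary.iloc[0]
        assert row["hr_lower"] < 1.0 < row["hr_upper"]

    def test_matches_r_cmprsk_oracle(self, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not on PATH")
        df = simulate_cohort(_competing_spec(n=400, seed=21)).table
        spec = ModelSpec(covariates=("vat_density_hu", "prior_mi"))
        mine = competing_risk_mi(df, spec)
        from thoraxcomp.risk import _build_design

        X, _ = _build_design(df, spec)
        X["time"] = df["time_years"].to_numpy()
        X["status"] = df["event"].to_numpy()
        X.to_csv(tmp_path / "fg.csv", index=False)
        rcode = (
            'suppressMessages(library(cmprsk));'
            f'd <- read.csv("{tmp_path / "fg.csv"}");'
            'f <- crr(d$time, d$status, cov1=as.matrix(d[,c("vat_density_hu","prior_mi")]),'
            ' failcode=1, cencode=0);'
            'cat(f$coef, sep="\\n")'
        )
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True, text=True, check=True)
        r_coefs = [float(v) for v in out.stdout.strip().splitlines()]
        np.testing.assert_allclose(mine.summary["coef"].to_numpy(), r_coefs, atol=1e-4)

    def test_higher_death_hazard_lowers_mi_incidence(self):
        # empirical CIF of MI at t=5 (no censoring) across 3 death-hazard levels
        cifs = []
        for scale in (None, 8.0, 3.0):
            df = simulate_cohort(
                _competing_spec(n=3000, seed=22, death_scale=scale, censor_high=None)
            ).table
            cifs.append(((df["time_years"] <= 5.0) & (df["event"] == 1)).mean())
        assert cifs[0] > cifs[1] > cifs[2]

    def test_cause_specific_flavour_recovers_truth(self):
        df = simulate_cohort(_competing_spec(n=5000, seed=23)).table
        res = competing_risk_mi(
            df, ModelSpec(covariates=("vat_density_hu",)), method="cause-specific"
        )
        assert res.summary.loc["vat_density_hu", "coef"] == pytest.approx(0.35, abs=0.08)

    def test_no_mi_events_rejected(self):
        df = simulate_cohort(_competing_spec(mi_scale=None, beta_mi={})).table
        with pytest.raises(ValueError, match="events of interest"):
            competing_risk_mi(df, ModelSpec(covariates=("age",)))


# ---------------------------------------------------------------------------
# Proportional-hazards diagnostics
# ---------------------------------------------------------------------------

def _flip_cohort(n, beta, seed):
    """Effect reverses sign at the flip time: a strong PH violation."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    h0, t_flip = 0.25, 1.8
    e = -np.log(rng.uniform(size=n))
    h1, h2 = h0 * np.exp(beta * x), h0 * np.exp(-beta * x)
    t = np.where(e < h1 * t_flip, e / h1, t_flip + (e - h1 * t_flip) / h2)
    return pd.DataFrame({"x": x, "time_years": t, "death_or_mi": 1})


class TestSchoenfeld:
    def test_size_near_alpha_under_ph(self):
        rejections = 0
        reps = 120
        for rep in range(reps):
            df = _one_covariate_cohort(300, beta=np.log(1.5), seed=3000 + rep)
            res = fit_cox(df, ModelSpec(covariates=("x",)))
            ph = schoenfeld_check(res)
            rejections += ph.per_covariate.loc["x", "p"] < 0.05
        assert 0.005 <= rejections / reps <= 0.12

    def test_power_against_sign_flip(self):
        rejections = 0
        reps = 40
        for rep in range(reps):
            df = _flip_cohort(2000, beta=0.7, seed=4000 + rep)
            res = fit_cox(df, ModelSpec(covariates=("x",)))
            ph = schoenfeld_check(res)
            rejections += ph.per_covariate.loc["x", "p"] < 0.05
        assert rejections / reps > 0.8

    def test_null_model_emits_no_tests(self):
        df = _one_covariate_cohort(300, beta=0.0, seed=17)
        res = fit_cox(df, ModelSpec(covariates=()))
        ph = schoenfeld_check(res)
        assert ph.per_covariate.empty and ph.global_p is None

    def test_global_statistic_aggregates_terms(self):
        df = simulate_cohort(CohortSpec(n=1500, seed=18)).table
        res = fit_cox(df, ModelSpec(covariates=("age", "vat_density_hu")))
        ph = schoenfeld_check(res)
        assert ph.global_df == 2
        assert ph.global_chi2 == pytest.approx(ph.per_covariate["test_statistic"].sum())
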