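"""Risk analysis: optimal cut-points, per-SD Cox models, competing risks.

Implements the downstream statistical stages applied to composition
metrics: sex-specific optimal cut-offs by Youden's J; Cox
proportional-hazards models whose continuous covariates are
standardised so hazard ratios are per SD (with designated covariates
natural-log transformed first, and coronary calcium entered
categorically with zero as reference); likelihood-ratio chi-square
increments between nested models with a multiplicity-adjusted
significance gate; Kaplan-Meier stratification with unadjusted
pairwise hazard ratios; a subdistribution-hazard (Fine-Gray) model for
MI with death as the competing event; and Schoenfeld-residual checks
of the proportional-hazards assumption.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, CoxTimeVaryingFitter, KaplanMeierFitter
from lifelines.statistics import proportional_hazard_test
from scipy import stats

__all__ = [
    "Threshold",
    "ThresholdSet",
    "ModelSpec",
    "CoxResult",
    "LRIncrement",
    "KMResult",
    "PHTestResult",
    "youden_thresholds",
    "fit_cox",
    "null_partial_loglik",
    "lr_chi2_increment",
    "km_stratified",
    "competing_risk_mi",
    "schoenfeld_check",
]

#: LR-increment significance gate, multiplicity-adjusted
LR_ALPHA = 0.001


# ---------------------------------------------------------------------------
# Youden thresholds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Threshold:
    """An optimal cut-point for one metric in one sex stratum."""

    cutpoint: float
    direction: str  # 'abnormal-above' | 'abnormal-below'
    j: float
    sensitivity: float
    specificity: float
    tied: bool  # True when several candidates achieve the maximal J


@dataclass
class ThresholdSet:
    per_sex: dict[str, Threshold]
    metric: str | None = None


def _youden_one(values: np.ndarray, outcome: np.ndarray) -> Threshold:
    cands = np.unique(values)
    pos = np.sort(values[outcome == 1])
    neg = np.sort(values[outcome == 0])
    npos, nneg = len(pos), len(neg)
    sens_above = (npos - np.searchsorted(pos, cands, side="left")) / npos
    spec_above = np.searchsorted(neg, cands, side="left") / nneg
    sens_below = np.searchsorted(pos, cands, side="right") / npos
    spec_below = (nneg - np.searchsorted(neg, cands, side="right")) / nneg

    sens = np.concatenate([sens_above, sens_below])
    spec = np.concatenate([spec_above, spec_below])
    j = sens + spec - 1.0
    cut = np.concatenate([cands, cands])
    dircode = np.concatenate([np.zeros(len(cands)), np.ones(len(cands))])

    # ties broken toward higher sensitivity, then the lower cutpoint,
    # then the abnormal-above orientation
    order = np.lexsort((dircode, cut, -sens, -j))
    best = order[0]
    tied = int(np.count_nonzero(j == j[best])) > 1
    return Threshold(
        cutpoint=float(cut[best]),
        direction="abnormal-above" if dircode[best] == 0 else "abnormal-below",
        j=float(j[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        tied=tied,
    )


def youden_thresholds(values, outcome, sex, metric: str | None = None) -> ThresholdSet:
    """Exhaustive sex-specific Youden cut-points over observed values.

    For every sex stratum, evaluates J = sensitivity + specificity - 1
    at every observed candidate cut-point in both orientations
    (abnormal at-or-above / at-or-below) and returns the maximiser.
    Strata with a single outcome class are rejected by name.
    """
    values = np.asarray(values, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    sex = np.asarray(sex)
    per_sex: dict[str, Threshold] = {}
    for group in np.unique(sex):
        m = sex == group
        y = outcome[m]
        if len(np.unique(y)) < 2:
            raise ValueError(
                f"sex stratum {group!r} has a single outcome class; no cut-point is identifiable"
            )
        per_sex[str(group)] = _youden_one(values[m], y)
    return ThresholdSet(per_sex=per_sex, metric=metric)


# ---------------------------------------------------------------------------
# Cox models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Covariate specification for a survival model.

    ``covariates`` are column names; those listed in ``log_transform``
    are natural-log transformed before standardisation (SDs are
    computed after the transform).  ``categorical`` maps a column to
    its reference level; its dummies are not standardised.
    """

    covariates: tuple[str, ...]
    duration_col: str = "time_years"
    event_col: str = "death_or_mi"
    log_transform: tuple[str, ...] = ()
    categorical: dict[str, str] = field(default_factory=dict)
    standardize: bool = True
    #: ridge penalty passed to the fitter; 0 gives the plain partial
    #: likelihood, a tiny value regularises degenerate (collinear) designs
    penalizer: float = 0.0


@dataclass
class CoxResult:
    """A fitted proportional-hazards model with per-SD hazard ratios."""

    summary: pd.DataFrame  # index: term; coef, se, hr, hr_lower, hr_upper, p
    log_likelihood: float
    ll_null: float | None
    n: int
    n_events: int
    terms: tuple[str, ...]
    spec: ModelSpec
    model: object | None = None
    design: pd.DataFrame | None = None
    log_transformed: tuple[str, ...] = ()

    def hr(self, term: str) -> float:
        return float(self.summary.loc[term, "hr"])


def _build_design(df: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, list[str]]:
    X = pd.DataFrame(index=df.index)
    terms: list[str] = []
    for col in spec.covariates:
        if col in spec.categorical:
            ref = spec.categorical[col]
            levels = sorted(df[col].astype(str).unique())
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent from column {col!r}")
            for level in levels:
                if level == ref:
                    continue
                term = f"{col}[{level}]"
                X[term] = (df[col].astype(str) == level).astype(float)
                terms.append(term)
            continue
        x = df[col].to_numpy(dtype=float)
        if col in spec.log_transform:
            if np.any(x <= 0):
                raise ValueError(f"column {col!r} has non-positive values; cannot log-transform")
            x = np.log(x)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"column {col!r} is not finite after transforms")
        nunique = len(np.unique(x))
        if spec.standardize and nunique > 2:
            sd = np.std(x, ddof=1)
            if sd <= 0:
                raise ValueError(f"column {col!r} is constant; cannot standardise")
            x = (x - np.mean(x)) / sd
        X[col] = x
        terms.append(col)
    return X, terms


def null_partial_loglik(durations, events) -> float:
    """Efron partial log-likelihood of the covariate-free Cox model."""
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events).astype(bool)
    ll = 0.0
    for t in np.unique(durations[events]):
        d = int(np.count_nonzero(events & (durations == t)))
        n_risk = int(np.count_nonzero(durations >= t))
        ll -= sum(np.log(n_risk - l) for l in range(d))
    return ll


def fit_cox(df: pd.DataFrame, spec: ModelSpec) -> CoxResult:
    """Fit a Cox model with per-SD hazard ratios (Efron tie handling).

    Requires at least 10 events.  An empty covariate list yields the
    null model (its partial log-likelihood only), which makes
    likelihood-ratio increments against the null expressible through
    :func:`lr_chi2_increment`.
    """
    durations = df[spec.duration_col].to_numpy(dtype=float)
    events = df[spec.event_col].to_numpy(dtype=float)
    n_events = int(np.count_nonzero(events))
    if n_events < 10:
        raise ValueError(f"need at least 10 events to fit, got {n_events}")
    ll0 = null_partial_loglik(durations, events)
    if not spec.covariates:
        return CoxResult(
            summary=pd.DataFrame(columns=["coef", "se", "hr", "hr_lower", "hr_upper", "p"]),
            log_likelihood=ll0,
            ll_null=ll0,
            n=len(df),
            n_events=n_events,
            terms=(),
            spec=spec,
        )
    X, terms = _build_design(df, spec)
    design = X.copy()
    design["__duration"] = durations
    design["__event"] = events
    cph = CoxPHFitter(penalizer=spec.penalizer)
    cph.fit(design, duration_col="__duration", event_col="__event")
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "se": s["se(coef)"],
            "hr": s["exp(coef)"],
            "hr_lower": s["exp(coef) lower 95%"],
            "hr_upper": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    return CoxResult(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        ll_null=ll0,
        n=len(df),
        n_events=n_events,
        terms=tuple(terms),
        spec=spec,
        model=cph,
        design=design,
        log_transformed=tuple(c for c in spec.covariates if c in spec.log_transform),
    )


@dataclass(frozen=True)
class LRIncrement:
    chi2: float
    df: int
    p: float
    significant: bool
    alpha: float


def lr_chi2_increment(base: CoxResult, extended: CoxResult, alpha: float = LR_ALPHA) -> LRIncrement:
    """Likelihood-ratio chi-square of ``extended`` over nested ``base``.

    chi2 = 2 (LL_extended - LL_base) on df = difference in parameters,
    flagged significant at the multiplicity-adjusted ``alpha``.
    """
    if base.n != extended.n or base.n_events != extended.n_events:
        raise ValueError("models were fitted on different samples; LR test is undefined")
    if not set(base.terms) <= set(extended.terms):
        raise ValueError("models are not nested: base terms are not a subset of extended terms")
    df_diff = len(extended.terms) - len(base.terms)
    if df_diff <= 0:
        raise ValueError("extended model adds no parameters over base")
    chi2 = 2.0 * (extended.log_likelihood - base.log_likelihood)
    if chi2 < -1e-6:
        raise ValueError(f"extended model fits worse than nested base (chi2={chi2:.3g})")
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df_diff))
    return LRIncrement(chi2=float(chi2), df=df_diff, p=p, significant=p < alpha, alpha=alpha)


# ---------------------------------------------------------------------------
# Kaplan-Meier stratification
# ---------------------------------------------------------------------------

@dataclass
class KMResult:
    curves: dict[str, pd.DataFrame]  # group -> (time, survival) step function
    hazard_ratios: pd.DataFrame  # reference, group, hr, hr_lower, hr_upper, p


def km_stratified(
    df: pd.DataFrame,
    group_col: str,
    duration_col: str = "time_years",
    event_col: str = "death_or_mi",
) -> KMResult:
    """Product-limit curves per group plus unadjusted pairwise hazard ratios.

    Hazard ratios come from single-covariate Cox fits (second group vs
    the first, in sorted group order).  Every group must be non-empty
    with at least one event.
    """
    groups = sorted(df[group_col].astype(str).unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups to stratify")
    curves: dict[str, pd.DataFrame] = {}
    for g in groups:
        sub = df[df[group_col].astype(str) == g]
        if len(sub) == 0:
            raise ValueError(f"group {g!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(sub[duration_col], event_observed=sub[event_col])
        sf = kmf.survival_function_
        curves[g] = pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})
    rows = []
    ref = groups[0]
    for g in groups[1:]:
        sub = df[df[group_col].astype(str).isin([ref, g])]
        if sub[event_col].sum() < 1:
            raise ValueError(f"groups {ref!r}/{g!r} have no events; hazard ratio undefined")
        design = pd.DataFrame(
            {
                "indicator": (sub[group_col].astype(str) == g).astype(float),
                "__duration": sub[duration_col].to_numpy(dtype=float),
                "__event": sub[event_col].to_numpy(dtype=float),
            }
        )
        cph = CoxPHFitter()
        cph.fit(design, duration_col="__duration", event_col="__event")
        s = cph.summary.loc["indicator"]
        rows.append(
            {
                "reference": ref,
                "group": g,
                "hr": float(s["exp(coef)"]),
                "hr_lower": float(s["exp(coef) lower 95%"]),
                "hr_upper": float(s["exp(coef) upper 95%"]),
                "p": float(s["p"]),
            }
        )
    return KMResult(curves=curves, hazard_ratios=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Competing risks (Fine-Gray subdistribution hazards)
# ---------------------------------------------------------------------------

def _censoring_km(durations: np.ndarray, status: np.ndarray):
    """Left-continuous censoring survivor G(t-) as a callable."""
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=(status == 0))
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)

    def g_minus(ts):
        ts = np.asarray(ts, dtype=float)
        idx = np.searchsorted(timeline, ts, side="left") - 1
        out = np.ones(ts.shape)
        valid = idx >= 0
        out[valid] = surv[idx[valid]]
        return out

    return g_minus


def _finegray_expand(durations, status, X: pd.DataFrame, interest: int, competing: int) -> pd.DataFrame:
    """Geskus risk-set expansion for the subdistribution hazard.

    Subjects failing from the competing cause stay in the risk set past
    their failure time, down-weighted by the censoring distribution:
    w_i(t) = G(t-)/G(T_i-).  The expansion reproduces the Fine-Gray
    partial likelihood when fitted as a weighted start-stop Cox model.
    """
    g_minus = _censoring_km(durations, status)
    event_times = np.unique(durations[status == interest])

    ids, starts, stops, evs, ws, xrows = [], [], [], [], [], []
    for i, (t_i, s_i) in enumerate(zip(durations, status)):
        ids.append(i)
        starts.append(0.0)
        stops.append(t_i)
        evs.append(1.0 if s_i == interest else 0.0)
        ws.append(1.0)
        xrows.append(i)
        if s_i == competing:
            g_ti = float(g_minus([t_i])[0])
            if g_ti <= 0:
                continue
            later = event_times[event_times > t_i]
            if len(later) == 0:
                continue
            weights = g_minus(later) / g_ti
            prev = t_i
            for e, w in zip(later, weights):
                ids.append(i)
                starts.append(prev)
                stops.append(float(e))
                evs.append(0.0)
                ws.append(float(w))
                xrows.append(i)
                prev = float(e)
    long = X.iloc[xrows].reset_index(drop=True)
    long["_id"] = ids
    long["_start"] = starts
    long["_stop"] = stops
    long["_ev"] = evs
    long["_w"] = ws
    return long


def competing_risk_mi(
    df: pd.DataFrame,
    spec: ModelSpec,
    event_col: str = "event",
    event_of_interest: int = 1,
    competing: int = 2,
    method: str = "fine-gray",
) -> CoxResult:
    """Model MI with death as the competing risk.

    ``method='fine-gray'`` (default) fits the subdistribution hazard via
    the IPCW risk-set expansion; ``method='cause-specific'`` censors
    competing events and fits an ordinary Cox model.  Covariate
    handling (log transforms, per-SD standardisation, categorical CAC)
    matches :func:`fit_cox`.
    """
    status = df[event_col].to_numpy(dtype=int)
    durations = df[spec.duration_col].to_numpy(dtype=float)
    n_interest = int(np.count_nonzero(status == event_of_interest))
    if n_interest == 0:
        raise ValueError("no events of interest; competing-risk model is undefined")
    if method == "cause-specific":
        work = df.copy()
        work["__interest"] = (status == event_of_interest).astype(int)
        cs_spec = ModelSpec(
            covariates=spec.covariates,
            duration_col=spec.duration_col,
            event_col="__interest",
            log_transform=spec.log_transform,
            categorical=spec.categorical,
            standardize=spec.standardize,
        )
        return fit_cox(work, cs_spec)
    if method != "fine-gray":
        raise ValueError(f"unknown competing-risk method {method!r}")

    X, terms = _build_design(df, spec)
    long = _finegray_expand(durations, status, X, event_of_interest, competing)
    ctv = CoxTimeVaryingFitter()
    ctv.fit(
        long,
        id_col="_id",
        event_col="_ev",
        start_col="_start",
        stop_col="_stop",
        weights_col="_w",
    )
    s = ctv.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "se": s["se(coef)"],
            "hr": s["exp(coef)"],
            "hr_lower": s["exp(coef) lower 95%"],
            "hr_upper": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    return CoxResult(
        summary=summary,
        log_likelihood=float(ctv.log_likelihood_),
        ll_null=None,
        n=len(df),
        n_events=n_interest,
        terms=tuple(terms),
        spec=spec,
        model=ctv,
        design=long,
        log_transformed=tuple(c for c in spec.covariates if c in spec.log_transform),
    )


# ---------------------------------------------------------------------------
# Proportional-hazards diagnostics
# ---------------------------------------------------------------------------

@dataclass
class PHTestResult:
    per_covariate: pd.DataFrame  # index term; test_statistic, p
    global_chi2: float | None
    global_df: int | None
    global_p: float | None


def schoenfeld_check(result: CoxResult, time_transform: str = "rank") -> PHTestResult:
    """Scaled-Schoenfeld-residual test of proportional hazards.

    Per-covariate correlation tests of the scaled residuals against
    transformed event time; the global statistic sums the per-covariate
    chi-squares (df = number of terms), an approximation to the joint
    test.  A model without covariates emits no tests.
    """
    if not result.terms:
        return PHTestResult(
            per_covariate=pd.DataFrame(columns=["test_statistic", "p"]),
            global_chi2=None,
            global_df=None,
            global_p=None,
        )
    if result.model is None or result.design is None:
        raise ValueError("result does not carry a fitted model; refit with fit_cox")
    if result.n_events < 10:
        raise ValueError("too few events for a proportional-hazards check")
    res = proportional_hazard_test(result.model, result.design, time_transform=time_transform)
    summ = res.summary
    if isinstance(summ.index, pd.MultiIndex):
        summ = summ.droplevel(-1)
    per = summ[["test_statistic", "p"]].copy()
    g_chi2 = float(per["test_statistic"].sum())
    g_df = len(per)
    return PHTestResult(
        per_covariate=per,
        global_chi2=g_chi2,
        global_df=g_df,
        global_p=float(stats.chi2.sf(g_chi2, g_df)),
    )
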