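"""Survival, categorical, rank and ordinal statistics for validating
phenotype clusters against clinical outcomes (MTX failure, DAS44
remission, Krenn synovitis grades).

Survival inputs are tidy DataFrames with ``time`` (days, > 0), ``event``
(0/1) and ``group`` columns plus optional covariates. Cox models are fitted
through lifelines (Efron ties by default); the proportional-odds ordinal
model through statsmodels; Kruskal-Wallis/chi-square through scipy. Dunn's
post-hoc test is implemented here (rank-based z statistics with tie
correction).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, \
    proportional_hazard_test
from scipy import stats
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .cohort import REMISSION_DAS44


#: DAS44 disease-activity bands: low < 2.4 <= moderate < 3.7 <= high.
DAS44_CATEGORY_CUTS = (2.4, 3.7)


def das_categories(das44_values, cuts=DAS44_CATEGORY_CUTS) -> np.ndarray:
    """Encode DAS44 values as ordered activity strata 0/1/2
    (low/moderate/high), for use as an ordinal adjustment covariate."""
    v = np.asarray(das44_values, dtype=float)
    return (v[:, None] >= np.asarray(cuts)[None, :]).sum(axis=1)


# ---------------------------------------------------------------- survival

@dataclass
class KMCurve:
    """Product-limit estimate with Greenwood standard errors."""

    times: np.ndarray          # distinct event times (plus t=0)
    survival: np.ndarray       # S(t) at those times, S(0)=1
    se: np.ndarray             # Greenwood SE of S(t)

    def at(self, t: float) -> float:
        """S(t): step-function value at time t."""
        i = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(i, 0)])


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier estimator; S(0) = 1, non-increasing."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("no observations")
    if (times <= 0).any():
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    surv = kmf.survival_function_["KM_estimate"]
    # Greenwood variance via lifelines' internal CI machinery is on the
    # log scale; recompute the classical form directly.
    t_grid = surv.index.to_numpy()
    s_vals = surv.to_numpy()
    order = np.argsort(times, kind="stable")
    ts, es = times[order], events[order]
    uniq = np.unique(ts[es == 1])
    at_risk = {t: (ts >= t).sum() for t in uniq}
    d = {t: int(((ts == t) & (es == 1)).sum()) for t in uniq}
    gw = 0.0
    cum = {}
    for t in uniq:
        n_t, d_t = at_risk[t], d[t]
        if n_t > d_t:
            gw += d_t / (n_t * (n_t - d_t))
            cum[t] = gw
        else:
            cum[t] = np.inf
    se = np.zeros_like(s_vals)
    for i, t in enumerate(t_grid):
        past = [v for u, v in cum.items() if u <= t]
        if past:
            g = past[-1]
            se[i] = s_vals[i] * np.sqrt(g) if np.isfinite(g) else 0.0
    return KMCurve(times=t_grid, survival=s_vals, se=se)


def logrank_test(times, events, groups) -> tuple[float, int, float]:
    """Multi-group log-rank test: (chi-square, df, p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("need >= 2 groups")
    if events.sum() == 0:
        raise ValueError("need >= 1 event")
    res = multivariate_logrank_test(times, groups, events)
    df = len(np.unique(groups)) - 1
    return float(res.test_statistic), df, float(res.p_value)


@dataclass
class CoxFit:
    """Cox proportional-hazards fit (Efron ties by default)."""

    coefficients: pd.Series
    standard_errors: pd.Series
    hazard_ratios: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    log_likelihood: float
    null_log_likelihood: float
    p_values: pd.Series
    ties: str
    covariates: list[str]
    _fitter: CoxPHFitter = field(repr=False, default=None)
    _data: pd.DataFrame = field(repr=False, default=None)


def cox_fit(data: pd.DataFrame, covariates: list[str],
            time_col: str = "time", event_col: str = "event",
            ties: str = "efron") -> CoxFit:
    """Fit a Cox model by partial-likelihood maximization.

    ``data`` is tidy (one row per patient); ``covariates`` are the model
    terms (binary/numeric columns). Raises on non-convergence (e.g.
    monotone likelihood from complete separation).
    """
    if data[event_col].sum() == 0:
        raise ValueError("need at least one event")
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    cols = [time_col, event_col] + list(covariates)
    if ties == "breslow":
        # Breslow tie handling (cross-check path) via statsmodels PHReg
        from statsmodels.duration.hazard_regression import PHReg
        mod = PHReg(data[time_col], data[list(covariates)],
                    status=data[event_col], ties="breslow")
        res = mod.fit()
        params = pd.Series(res.params, index=list(covariates))
        bse = pd.Series(res.bse, index=list(covariates))
        z = stats.norm.ppf(0.975)
        return CoxFit(
            coefficients=params, standard_errors=bse,
            hazard_ratios=np.exp(params),
            ci_lower=np.exp(params - z * bse),
            ci_upper=np.exp(params + z * bse),
            log_likelihood=float(res.llf),
            null_log_likelihood=float(mod.loglike(np.zeros(len(covariates)))),
            p_values=pd.Series(res.pvalues, index=list(covariates)),
            ties=ties, covariates=list(covariates),
            _fitter=None, _data=data[cols])
    cph = CoxPHFitter()
    try:
        cph.fit(data[cols], duration_col=time_col, event_col=event_col,
                robust=False)
    except Exception as exc:  # lifelines raises ConvergenceError
        raise RuntimeError(f"Cox fit failed to converge: {exc}") from exc
    ci = cph.confidence_intervals_
    lrt = cph.log_likelihood_ratio_test().test_statistic
    return CoxFit(
        coefficients=cph.params_,
        standard_errors=cph.standard_errors_,
        hazard_ratios=np.exp(cph.params_),
        ci_lower=np.exp(ci.iloc[:, 0]),
        ci_upper=np.exp(ci.iloc[:, 1]),
        log_likelihood=float(cph.log_likelihood_),
        null_log_likelihood=float(cph.log_likelihood_ - lrt / 2),
        p_values=cph.summary["p"],
        ties=ties, covariates=list(covariates),
        _fitter=cph, _data=data[cols])


def cox_lrt(nested: CoxFit, full: CoxFit) -> tuple[float, int, float]:
    """Likelihood-ratio ('ANOVA') comparison of nested Cox models."""
    if not set(nested.covariates) <= set(full.covariates):
        raise ValueError("models are not nested")
    df = len(full.covariates) - len(nested.covariates)
    if df == 0:
        return 0.0, 0, 1.0
    stat = 2.0 * (full.log_likelihood - nested.log_likelihood)
    stat = max(stat, 0.0)
    return float(stat), df, float(stats.chi2.sf(stat, df))


def schoenfeld_ph_test(fit: CoxFit) -> pd.DataFrame:
    """Grambsch-Therneau proportional-hazards check: correlation of scaled
    Schoenfeld residuals with (rank-transformed) event time, per covariate.
    Returns a DataFrame with ``stat`` and ``p`` rows indexed by covariate."""
    if fit._fitter is None:
        raise ValueError("fit does not carry its fitter/data")
    n_events = int(fit._data.iloc[:, 1].sum())
    if n_events < 3:
        raise ValueError("need >= 3 events")
    res = proportional_hazard_test(fit._fitter, fit._data,
                                   time_transform="rank")
    out = res.summary[["test_statistic", "p"]]
    out.columns = ["stat", "p"]
    return out.droplevel(1) if out.index.nlevels > 1 else out


# ------------------------------------------------------------- remission

def locf_remission(das_series, horizon: float = 365.0):
    """One-year remission by last-observation-carried-forward.

    Returns (remission_flag, first_remission_day). The flag is the LOCF
    status at the horizon: last observed DAS44 value on or before the
    horizon < 1.6. first_remission_day is the first visit day with a value
    below the cut (may exist even when the LOCF flag is False, if disease
    later flared). An empty series returns (None, None) — a missing
    outcome, not an error.
    """
    series = sorted(das_series, key=lambda p: p[0])
    if not series:
        return None, None
    in_horizon = [(d, v) for d, v in series if d <= horizon]
    if not in_horizon:
        return None, None
    flag = in_horizon[-1][1] < REMISSION_DAS44
    first = next((d for d, v in in_horizon if v < REMISSION_DAS44), None)
    return bool(flag), first


# ---------------------------------------------------------- categorical

def chi2_crosstab(table) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c count table (no continuity
    correction)."""
    table = np.asarray(table, dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("degenerate margins")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def kruskal_dunn(values_by_group: dict, adjust: str | None = None):
    """Kruskal-Wallis H (tie-corrected) plus Dunn's pairwise post-hoc z
    tests.

    Returns (H, p, DataFrame of pairwise rows: group1, group2, z, p[, p_adj
    when adjust='holm']). Dunn's variance uses the tie-corrected form
    (N(N+1)/12 - T)(1/n_i + 1/n_j) with T = sum(t^3 - t)/(12(N-1)).
    """
    names = list(values_by_group)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    samples = [np.asarray(values_by_group[g], dtype=float) for g in names]
    alldata = np.concatenate(samples)
    if np.ptp(alldata) == 0:
        pairs = pd.DataFrame([(a, b, 0.0, 1.0)
                              for a, b in itertools.combinations(names, 2)],
                             columns=["group1", "group2", "z", "p"])
        return 0.0, 1.0, pairs
    H, p = stats.kruskal(*samples)
    ranks = stats.rankdata(alldata)
    N = len(alldata)
    _, counts = np.unique(alldata, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / (12.0 * (N - 1))
    mean_ranks, sizes = {}, {}
    start = 0
    for g, s in zip(names, samples):
        mean_ranks[g] = ranks[start:start + len(s)].mean()
        sizes[g] = len(s)
        start += len(s)
    rows = []
    for a, b in itertools.combinations(names, 2):
        var = (N * (N + 1) / 12.0 - tie_term) * (1 / sizes[a] + 1 / sizes[b])
        z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(var)
        rows.append((a, b, float(z), float(2 * stats.norm.sf(abs(z)))))
    pairs = pd.DataFrame(rows, columns=["group1", "group2", "z", "p"])
    if adjust == "holm":
        order = np.argsort(pairs["p"].to_numpy())
        m = len(pairs)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * pairs["p"].iloc[i])
            adj[i] = min(running, 1.0)
        pairs["p_adj"] = adj
    return float(H), float(p), pairs


# --------------------------------------------------------------- ordinal

def merge_sparse_levels(y, threshold: int | None = None):
    """Merge ordinal grade 0 into grade 1 (the 'none' level is rare in
    treatment-naive active synovitis). With ``threshold`` set, merge only
    when the grade-0 count is below it. Returns (merged, mapping)."""
    y = np.asarray(y, dtype=int)
    if ((y < 0) | (y > 3)).any():
        raise ValueError("grades must lie in 0..3")
    n0 = int((y == 0).sum())
    if threshold is not None and n0 >= threshold:
        return y.copy(), {g: g for g in range(4)}
    merged = np.where(y == 0, 1, y)
    if (merged == merged[0]).all() and len(merged) > 0:
        import warnings
        warnings.warn("merge collapsed the outcome to a single category")
    return merged, {0: 1, 1: 1, 2: 2, 3: 3}


@dataclass
class OrdinalFit:
    """Proportional-odds fit: logit P(Y <= j) = theta_j - x beta."""

    thresholds: np.ndarray
    coefficients: pd.Series
    standard_errors: pd.Series
    covariance: pd.DataFrame
    wald_global: tuple[float, int, float]    # cluster-block Wald test
    pairwise: pd.DataFrame                   # cluster pairwise Wald z/p
    log_likelihood: float
    _result: object = field(repr=False, default=None)


def ordinal_fit(y, cluster_labels, covariate: pd.Series | None = None,
                reference: str | None = None) -> OrdinalFit:
    """Proportional-odds ordinal regression of grades on cluster indicators
    (plus an optional ordinal covariate, e.g. baseline DAS category).

    The cluster effect is summarized by a global Wald test on the cluster
    indicator block and by pairwise Wald contrasts between all cluster
    pairs (including the reference, whose coefficient is 0).
    """
    y = np.asarray(y)
    cluster_labels = np.asarray(cluster_labels)
    cats = np.unique(y)
    if len(cats) < 2:
        raise ValueError("need >= 2 observed outcome categories")
    groups = sorted(pd.unique(cluster_labels).tolist())
    if reference is None:
        reference = groups[0]
    others = [g for g in groups if g != reference]
    X = pd.DataFrame({f"cluster[{g}]": (cluster_labels == g).astype(float)
                      for g in others})
    if covariate is not None:
        X["covariate"] = np.asarray(covariate, dtype=float)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient")
    model = OrderedModel(pd.Categorical(y, ordered=True), X, distr="logit")
    try:
        res = model.fit(method="newton", maxiter=200, disp=False)
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError
    except Exception:
        res = model.fit(method="bfgs", maxiter=500, disp=False)
    k_beta = X.shape[1]
    params = np.asarray(res.params)
    beta = pd.Series(params[:k_beta], index=X.columns)
    se = pd.Series(np.asarray(res.bse)[:k_beta], index=X.columns)
    cov = pd.DataFrame(np.asarray(res.cov_params())[:k_beta, :k_beta],
                       index=X.columns, columns=X.columns)
    # statsmodels parameterizes cutpoints incrementally; recover thresholds
    # (its convention matches ours: P(Y<=j) = F(theta_j - x beta))
    thresholds = model.transform_threshold_params(params)[1:-1]
    cl_cols = [c for c in X.columns if c.startswith("cluster[")]
    b = beta[cl_cols].to_numpy()
    V = cov.loc[cl_cols, cl_cols].to_numpy()
    stat = float(b @ np.linalg.solve(V, b))
    dfree = len(cl_cols)
    wald_global = (stat, dfree, float(stats.chi2.sf(stat, dfree)))
    rows = []
    full = {reference: 0.0, **{g: beta[f"cluster[{g}]"] for g in others}}
    for a, bname in itertools.combinations(groups, 2):
        diff = full[a] - full[bname]
        var = 0.0
        for g, sgn in ((a, 1.0), (bname, -1.0)):
            if g == reference:
                continue
            var += cov.loc[f"cluster[{g}]", f"cluster[{g}]"]
        if a != reference and bname != reference:
            var -= 2 * cov.loc[f"cluster[{a}]", f"cluster[{bname}]"]
        z = diff / np.sqrt(var) if var > 0 else 0.0
        rows.append((a, bname, float(z),
                     float(2 * stats.norm.sf(abs(z)))))
    pairwise = pd.DataFrame(rows, columns=["group1", "group2", "z", "p"])
    return OrdinalFit(thresholds=thresholds, coefficients=beta,
                      standard_errors=se, covariance=cov,
                      wald_global=wald_global, pairwise=pairwise,
                      log_likelihood=float(res.llf), _result=res)
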