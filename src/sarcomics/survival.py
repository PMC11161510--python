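"""Survival and association statistics.

Metastasis-free survival (MFS, months from surgery to metastatic
relapse or censoring) is analyzed with the standard toolkit:
Kaplan-Meier curves with Greenwood variances, log-rank tests, uni- and
multivariable Cox proportional-hazards regression (Efron ties) with
backward selection minimizing the AIC, Harrell's concordance index with
5-fold cross-validation and bootstrap comparison of model c-indices.
Group associations use Pearson chi-square tests (Yates-corrected for
2x2 tables) and rank tests (Mann-Whitney / Kruskal-Wallis). Clinical
grouping rules are included: the SARCULATOR 10-year Pr-OS thresholds
(<=51% low, <=66% intermediate, >66% high), the 2-of-3 semantic
radiophenotype rule, and the combined radiomics x transcriptomics
group with its binarized worst-group indicator.

Records are pandas DataFrames with ``time`` (months) and ``event``
(0/1) columns plus named covariates; categorical covariates use the
first level (of a pandas Categorical, else lexicographic) as reference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "KMEstimate", "CoxFit", "CIndexResult",
    "km_estimate", "logrank_test", "cox_fit", "stepwise_backward_aic",
    "harrell_cindex", "cv_cindex", "bootstrap_cindex_diff",
    "chi_square_test", "rank_tests",
    "sarculator_grouping", "semantic_radiophenotype", "combine_groups",
]


# ------------------------------------------------------------ Kaplan-Meier

@dataclass
class KMEstimate:
    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    greenwood_var: np.ndarray

    def probability_at(self, t: float) -> float:
        """Right-continuous step lookup of S(t)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(records: pd.DataFrame) -> KMEstimate:
    """Product-limit survival estimate with Greenwood variances."""
    if len(records) == 0:
        raise ValueError("need at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], records["event"])
    table = kmf.event_table.iloc[1:] if kmf.event_table.index[0] == 0 else kmf.event_table
    times = table.index.to_numpy(float)
    d = table["observed"].to_numpy(float)
    n = table["at_risk"].to_numpy(float)
    surv = np.array([kmf.predict(t) for t in times], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > d, d / (n * (n - d)), 0.0)
    greenwood = surv ** 2 * np.cumsum(terms)
    return KMEstimate(times, surv, n, greenwood)


def logrank_test(records: pd.DataFrame, groups) -> tuple[float, int, float]:
    """Log-rank test across >= 2 groups; returns (chi2, df, p)."""
    groups = pd.Series(np.asarray(groups), index=records.index)
    if groups.nunique() < 2:
        raise ValueError("log-rank requires at least two groups")
    res = multivariate_logrank_test(records["time"], groups, records["event"])
    return float(res.test_statistic), int(groups.nunique() - 1), float(res.p_value)


# --------------------------------------------------------------------- Cox

@dataclass
class CoxFit:
    coefficients: pd.Series
    summary: pd.DataFrame          # coef, hr, ci_lower, ci_upper, p
    log_likelihood: float
    aic: float
    n_used: int
    n_dropped: int
    n_events: int
    converged: bool
    covariates: list
    _design_info: dict = field(default_factory=dict, repr=False)

    def predict_risk(self, records: pd.DataFrame) -> pd.Series:
        """Linear predictor x'beta for new records."""
        X = _design(records, self.covariates, self._design_info)[0]
        X = X.reindex(columns=self.coefficients.index, fill_value=0.0)
        return X @ self.coefficients


def _design(records: pd.DataFrame, covariates, info: dict | None = None):
    """Numeric design matrix with reference-level dummy coding.

    ``info`` (built at fit time) stores each categorical covariate's
    level order so prediction uses identical columns.
    """
    build = info is None
    info = {} if build else info
    cols = {}
    for cov in covariates:
        s = records[cov]
        if pd.api.types.is_numeric_dtype(s) and not isinstance(s.dtype, pd.CategoricalDtype):
            cols[cov] = s.astype(float)
        else:
            if build:
                levels = (list(s.cat.categories) if isinstance(s.dtype, pd.CategoricalDtype)
                          else sorted(s.dropna().unique()))
                info[cov] = levels
            levels = info[cov]
            for lev in levels[1:]:
                cols[f"{cov}[{lev}]"] = (s == lev).astype(float)
    X = pd.DataFrame(cols, index=records.index)
    return X, info


def cox_fit(records: pd.DataFrame, covariates, penalizer: float = 0.0) -> CoxFit:
    """Cox proportional-hazards fit (Efron tie handling, Wald 95% CI).

    Rows with missing time/event/covariate values are dropped and
    counted (complete-case analysis). A covariate constant across the
    analyzed subjects is a degenerate design and raises; a dummy column
    for an absent level is dropped silently.
    """
    covariates = list(covariates)
    cols = ["time", "event"] + covariates
    data = records[cols].dropna()
    n_dropped = len(records) - len(data)
    if data["event"].sum() < 1:
        raise ValueError("need at least one event")
    for cov in covariates:
        if data[cov].nunique() <= 1:
            raise ValueError(f"covariate {cov!r} is constant (degenerate design)")
    X, info = _design(data, covariates)
    keep = [c for c in X.columns if X[c].nunique() > 1]
    X = X[keep]
    df = pd.concat([X, data[["time", "event"]]], axis=1)
    cph = CoxPHFitter(penalizer=penalizer)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except ConvergenceError as err:
            raise ValueError(f"Cox fit did not converge: {err}") from err
    coefs = cph.params_
    summ = pd.DataFrame({
        "coef": cph.params_,
        "hr": np.exp(cph.params_),
        "ci_lower": np.exp(cph.confidence_intervals_.iloc[:, 0]),
        "ci_upper": np.exp(cph.confidence_intervals_.iloc[:, 1]),
        "p": cph.summary["p"],
    })
    ll = float(cph.log_likelihood_)
    aic = -2.0 * ll + 2.0 * len(coefs)
    return CoxFit(coefficients=coefs, summary=summ, log_likelihood=ll, aic=aic,
                  n_used=len(data), n_dropped=n_dropped,
                  n_events=int(data["event"].sum()), converged=converged,
                  covariates=covariates, _design_info=info)


def stepwise_backward_aic(records: pd.DataFrame, covariates,
                          penalizer: float = 0.0):
    """Backward elimination minimizing the AIC.

    Complete cases are fixed by the full model so all AICs are
    comparable. Returns (final CoxFit, trace of (covariates, AIC)).
    """
    covariates = list(covariates)
    data = records[["time", "event"] + covariates].dropna()
    current = covariates
    fit = cox_fit(data, current, penalizer=penalizer)
    trace = [(list(current), fit.aic)]
    while len(current) > 1:
        best_fit, best_drop = None, None
        for cov in current:
            reduced = [c for c in current if c != cov]
            try:
                cand = cox_fit(data, reduced, penalizer=penalizer)
            except ValueError:
                continue
            if best_fit is None or cand.aic < best_fit.aic:
                best_fit, best_drop = cand, cov
        if best_fit is None or best_fit.aic >= fit.aic:
            break
        fit, current = best_fit, [c for c in current if c != best_drop]
        trace.append((list(current), fit.aic))
    return fit, trace


# ----------------------------------------------------------------- c-index

@dataclass
class CIndexResult:
    cindex: float
    concordant: float = np.nan
    discordant: float = np.nan
    tied_risk: float = np.nan
    n_usable: int = 0
    per_fold: list = field(default_factory=list)
    ci: tuple = (np.nan, np.nan)


def harrell_cindex(risk_scores, records: pd.DataFrame) -> CIndexResult:
    """Harrell concordance index.

    Usable pairs are those orderable under censoring: t_i < t_j with
    subject i experiencing the event. A pair is concordant when the
    earlier failure carries the higher risk score; risk ties count 1/2.
    """
    r = np.asarray(risk_scores, float)
    t = records["time"].to_numpy(float)
    e = records["event"].to_numpy()
    if len(r) != len(t):
        raise ValueError("risk scores and records must align")
    earlier = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_usable = int(earlier.sum())
    if n_usable == 0:
        raise ValueError("no usable pair under censoring")
    higher = r[:, None] > r[None, :]
    tied = r[:, None] == r[None, :]
    conc = int((earlier & higher).sum())
    ties = int((earlier & tied).sum())
    disc = n_usable - conc - ties
    c = (conc + 0.5 * ties) / n_usable
    return CIndexResult(cindex=float(c), concordant=conc, discordant=disc,
                        tied_risk=ties, n_usable=n_usable)


def _stratified_folds(event: np.ndarray, folds: int, rng: np.random.Generator):
    """Fold assignment stratified by the event indicator."""
    assign = np.empty(len(event), dtype=int)
    for val in (0, 1):
        idx = np.where(event == val)[0]
        idx = rng.permutation(idx)
        assign[idx] = np.arange(len(idx)) % folds
    return assign


def cv_cindex(records: pd.DataFrame, covariates, folds: int = 5,
              seed: int = 0, penalizer: float = 0.0) -> CIndexResult:
    """Cross-validated Harrell c-index of a Cox model specification.

    Folds are stratified by the event indicator; per fold, the model is
    fit on the training folds and the held-out fold is scored. Reports
    the fold mean with a percentile 95% interval across folds.
    """
    records = records[["time", "event"] + list(covariates)].dropna()
    if records["event"].sum() < folds:
        raise ValueError("need at least one event per fold")
    rng = np.random.default_rng(seed)
    assign = _stratified_folds(records["event"].to_numpy(), folds, rng)
    per_fold = []
    for f in range(folds):
        train = records.iloc[assign != f]
        test = records.iloc[assign == f]
        if test["event"].sum() == 0 or train["event"].sum() == 0:
            warnings.warn(f"fold {f} skipped (no event)")
            continue
        try:
            fit = cox_fit(train, covariates, penalizer=penalizer)
        except ValueError:
            warnings.warn(f"fold {f} skipped (degenerate fit)")
            continue
        risk = fit.predict_risk(test)
        try:
            per_fold.append(harrell_cindex(risk, test).cindex)
        except ValueError:
            warnings.warn(f"fold {f} skipped (no usable pair)")
    if not per_fold:
        raise ValueError("no fold produced a c-index")
    arr = np.array(per_fold)
    ci = (float(np.percentile(arr, 2.5)), float(np.percentile(arr, 97.5)))
    return CIndexResult(cindex=float(arr.mean()), per_fold=per_fold, ci=ci)


def bootstrap_cindex_diff(records: pd.DataFrame, spec_a, spec_b,
                          B: int = 1000, folds: int = 5, seed: int = 0,
                          penalizer: float = 0.0):
    """Bootstrap comparison of two model specifications' CV c-indices.

    Per replicate, subjects are resampled with replacement and both
    cross-validated c-indices recomputed; the two-sided p-value is the
    percentile proportion of the bootstrap difference distribution
    beyond zero. Degenerate replicates (no events) are redrawn.
    Returns (mean difference, p, difference samples).
    """
    rng = np.random.default_rng(seed)
    n = len(records)
    diffs = []
    redrawn = 0
    while len(diffs) < B:
        idx = rng.integers(0, n, size=n)
        cv_seed = int(rng.integers(2 ** 31))  # shared folds: paired diff
        boot = records.iloc[idx].reset_index(drop=True)
        try:
            ca = cv_cindex(boot, spec_a, folds=folds,
                           seed=cv_seed, penalizer=penalizer)
            cb = cv_cindex(boot, spec_b, folds=folds,
                           seed=cv_seed, penalizer=penalizer)
        except ValueError:
            redrawn += 1
            if redrawn > 10 * B:
                raise RuntimeError("too many degenerate bootstrap replicates")
            continue
        diffs.append(ca.cindex - cb.cindex)
    diffs = np.array(diffs)
    frac_below = float(np.mean(diffs < 0))
    frac_above = float(np.mean(diffs > 0))
    p = min(1.0, 2.0 * min(frac_below + 0.5 * np.mean(diffs == 0),
                           frac_above + 0.5 * np.mean(diffs == 0)))
    return float(diffs.mean()), float(p), diffs


# ------------------------------------------------------------ associations

def chi_square_test(table, yates_2x2: bool = True) -> tuple[float, int, float]:
    """Pearson chi-square on an R x C contingency table.

    Yates continuity correction is applied iff the table is 2x2 and
    ``yates_2x2`` is set. Returns (statistic, df, p).
    """
    t = np.asarray(table, float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need an R x C table with R, C >= 2")
    if (t < 0).any() or t.sum() == 0:
        raise ValueError("counts must be non-negative with positive total")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero row/column margin")
    correction = yates_2x2 and t.shape == (2, 2)
    res = stats.chi2_contingency(t, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def rank_tests(values, groups) -> tuple[float, float]:
    """Mann-Whitney U for two groups, Kruskal-Wallis for three or more."""
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    samples = [values[groups == g] for g in pd.unique(groups)]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise ValueError("need >= 2 non-empty groups")
    if len(samples) == 2:
        res = stats.mannwhitneyu(samples[0], samples[1],
                                 alternative="two-sided", method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    res = stats.kruskal(*samples)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------- clinical rules

def sarculator_grouping(pr_os):
    """SARCULATOR 10-year Pr-OS category: low (<=0.51),
    intermediate ((0.51, 0.66]) or high (>0.66)."""
    arr = np.asarray(pr_os, float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("pr_os must lie in [0, 1]")
    out = np.where(arr <= 0.51, "low",
                   np.where(arr <= 0.66, "intermediate", "high"))
    return out.item() if np.isscalar(pr_os) else out


def semantic_radiophenotype(flags) -> str:
    """High-risk iff at least 2 of the 3 semantic flags are present
    (heterogeneous T2 signal, necrosis, peritumoral enhancement)."""
    flags = list(flags)
    if len(flags) != 3:
        raise ValueError("exactly 3 semantic flags expected")
    return "high risk" if sum(bool(f) for f in flags) >= 2 else "low risk"


def combine_groups(radiomics_labels: pd.Series, rna_labels: pd.Series,
                   worst=("A", "A")):
    """Hybrid radiomics x transcriptomics group and its binarized form.

    The hybrid label is the (radiomics, rna) pair; the binary variable
    pools every combination except the double-worst one (default both
    "A") into "Others". Subjects missing either label are excluded and
    counted. Returns (frame with ``hybrid``/``binary``, n_excluded).
    """
    df = pd.DataFrame({"radiomics": radiomics_labels, "rna": rna_labels})
    n_before = len(df)
    df = df.dropna()
    n_excluded = n_before - len(df)
    hybrid = df["radiomics"].astype(str) + "x" + df["rna"].astype(str)
    is_worst = (df["radiomics"] == worst[0]) & (df["rna"] == worst[1])
    binary = np.where(is_worst, f"{worst[0]}x{worst[1]}", "Others")
    return pd.DataFrame({"hybrid": hybrid, "binary": binary}, index=df.index), n_excluded
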