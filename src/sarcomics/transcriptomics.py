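"""Bulk transcriptomics: normalization, batch correction, differential
expression, geneset enrichment and the nearest-shrunken-centroid (PAM)
discriminant signature.

Counts are genes x samples non-negative integers. The analysis chain
mirrors the expression arm of the study: log2-CPM with voom-style
precision weights from the empirical mean-variance trend, ComBat
empirical-Bayes batch correction on the log scale, per-gene Welch
t-tests between two groups gated at fold-change 2 with
Benjamini-Hochberg control, hypergeometric over-representation of the
differential genes in geneset collections, and a PAM classifier whose
soft-thresholded centroids define a discriminant gene signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NormalizedExpression", "DGEResult", "PAMModel",
    "combat_correct", "voom_normalize", "dge_ttest", "bh_adjust",
    "geneset_enrichment", "pam_train", "pam_predict", "read_gmt",
]


@dataclass
class NormalizedExpression:
    log2_expr: pd.DataFrame     # genes x samples, log2-CPM
    weights: pd.DataFrame       # precision weights, same shape
    trend: pd.DataFrame         # mean log-count vs sqrt residual sd knots


@dataclass
class PAMModel:
    overall_centroid: pd.Series
    centroids: pd.DataFrame         # class x gene, shrunken
    delta: float
    s: pd.Series                    # pooled within-class sd per gene
    s0: float
    priors: pd.Series
    mk: pd.Series
    classes: list
    signature: list
    cv_error: pd.DataFrame | None = None
    flagged_empty: bool = False


# ------------------------------------------------------------------ ComBat

def combat_correct(matrix: pd.DataFrame, batches) -> pd.DataFrame:
    """Parametric empirical-Bayes batch correction (ComBat) on
    log-scale genes x samples data.

    Delegates to scanpy's ComBat implementation. A single batch is the
    identity; a batch with one sample cannot support a scale estimate
    and raises.
    """
    batches = pd.Series(np.asarray(batches, dtype=object),
                        index=matrix.columns, name="batch")
    counts = batches.value_counts()
    if len(counts) == 1:
        return matrix.copy()
    if (counts < 2).any():
        raise ValueError("every batch needs >= 2 samples")
    import anndata as ad
    import scanpy as sc
    adata = ad.AnnData(X=matrix.T.to_numpy(float),
                       obs=pd.DataFrame({"batch": batches.astype(str).to_numpy()},
                                        index=matrix.columns.astype(str)),
                       var=pd.DataFrame(index=matrix.index.astype(str)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.combat(adata, key="batch")
    return pd.DataFrame(adata.X.T, index=matrix.index, columns=matrix.columns)


# -------------------------------------------------------------------- voom

def voom_normalize(counts: pd.DataFrame, groups=None,
                   lowess_frac: float = 0.5) -> NormalizedExpression:
    """Log2-CPM with precision weights from the mean-variance trend.

    log2-CPM uses a 0.5 count offset. Residual standard deviations
    under the group-means model are square-rooted and regressed on mean
    log2 count by lowess; each observation's weight is the inverse
    fourth power of its interpolated sqrt-sd at its fitted log2-CPM.
    Single-pass (no second-round reweighting). All-zero genes get the
    weight floor and are flagged with a warning.
    """
    X = counts.to_numpy(float)
    lib = X.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("library sizes must be positive")
    logcpm = np.log2((X + 0.5) / (lib + 1.0)[None, :] * 1e6)
    if groups is None:
        groups = np.zeros(X.shape[1], dtype=int)
    groups = np.asarray(groups)
    fitted = np.zeros_like(logcpm)
    resvar = np.zeros(X.shape[0])
    dof = 0
    for g in pd.unique(groups):
        cols = groups == g
        mu = logcpm[:, cols].mean(axis=1, keepdims=True)
        fitted[:, cols] = mu
        resvar += ((logcpm[:, cols] - mu) ** 2).sum(axis=1)
        dof += cols.sum() - 1
    sd = np.sqrt(resvar / max(dof, 1))
    mean_logcount = np.log2(X.mean(axis=1) + 0.5)
    sqrt_sd = np.sqrt(sd)
    order = np.argsort(mean_logcount)
    fit = lowess(sqrt_sd[order], mean_logcount[order], frac=lowess_frac,
                 return_sorted=True)
    knots_x, knots_y = fit[:, 0], np.maximum(fit[:, 1], 1e-4)
    # interpolate each observation's fitted log-count on the trend
    fitted_count = fitted + np.log2(lib + 1.0)[None, :] - np.log2(1e6)
    interp = np.interp(fitted_count, knots_x, knots_y)
    weights = 1.0 / interp ** 4
    allzero = X.sum(axis=1) == 0
    if allzero.any():
        warnings.warn(f"{int(allzero.sum())} all-zero gene(s): weight floor applied")
        weights[allzero] = weights[weights > 0].min() if (weights > 0).any() else 1.0
    return NormalizedExpression(
        log2_expr=pd.DataFrame(logcpm, index=counts.index, columns=counts.columns),
        weights=pd.DataFrame(weights, index=counts.index, columns=counts.columns),
        trend=pd.DataFrame({"mean_log_count": knots_x, "sqrt_sd": knots_y}),
    )


# --------------------------------------------------------------------- DGE

@dataclass
class DGEResult:
    table: pd.DataFrame     # log2_fc, t, p, p_adj, call per gene

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["call"] != "ns"]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def dge_ttest(expr: pd.DataFrame, group_labels, fc_threshold: float = 2.0,
              alpha: float = 0.05, var_floor: float = 1e-8) -> DGEResult:
    """Per-gene Welch t-test between two groups on log2 expression.

    A gene is called up/down iff its BH-adjusted p is below ``alpha``
    AND |log2 fold change| >= log2(fc_threshold). log2FC is the mean
    difference (second group minus first, groups in sorted label
    order). Degenerate variances get a floor and a warning.
    """
    labels = pd.Series(np.asarray(group_labels), index=expr.columns)
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    a = expr.loc[:, labels == levels[0]].to_numpy(float)
    b = expr.loc[:, labels == levels[1]].to_numpy(float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("both groups need >= 2 samples")
    va = np.maximum(a.var(axis=1, ddof=1), var_floor)
    vb = np.maximum(b.var(axis=1, ddof=1), var_floor)
    na, nb = a.shape[1], b.shape[1]
    se2 = va / na + vb / nb
    t = (b.mean(axis=1) - a.mean(axis=1)) / np.sqrt(se2)
    dof = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    p_adj = bh_adjust(p)
    log2_fc = b.mean(axis=1) - a.mean(axis=1)
    sig = (p_adj < alpha) & (np.abs(log2_fc) >= np.log2(fc_threshold))
    call = np.where(~sig, "ns", np.where(log2_fc > 0, "up", "down"))
    table = pd.DataFrame({
        "log2_fc": log2_fc, "t": t, "p": p, "p_adj": p_adj, "call": call,
        "neg_log10_p_adj": -np.log10(np.maximum(p_adj, 1e-300)),
    }, index=expr.index)
    return DGEResult(table=table)


# -------------------------------------------------------------- enrichment

def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT geneset collection (name <tab> desc <tab> genes...)."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def geneset_enrichment(de_genes, universe, genesets: dict,
                       direction_calls: pd.Series | None = None) -> pd.DataFrame:
    """Hypergeometric over-representation of DE genes per geneset.

    For a universe of N genes with n differential, a set with K members
    in the universe and k differential members has
    p = P(X >= k), X ~ Hypergeom(N, K, n). p-values are BH-adjusted
    across sets. With ``direction_calls`` ("up"/"down" per DE gene) the
    activated proportion (fraction of the set's DE genes up-regulated)
    is reported. Sets with no universe overlap are skipped.
    """
    universe = set(universe)
    de = set(de_genes)
    if not de <= universe:
        raise ValueError("de_genes must be a subset of the universe")
    N, n = len(universe), len(de)
    rows = []
    for name, members in genesets.items():
        memb = set(members) & universe
        if not memb:
            continue
        K = len(memb)
        k = len(memb & de)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if n > 0 else 1.0
        row = {"geneset": name, "set_size": K, "n_de_in_set": k, "p": p}
        if direction_calls is not None and k > 0:
            calls = direction_calls.reindex(sorted(memb & de))
            row["prop_up"] = float((calls == "up").mean())
        rows.append(row)
    out = pd.DataFrame(rows).set_index("geneset")
    if len(out):
        out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out


# --------------------------------------------------------------------- PAM

def _pam_stats(X: np.ndarray, y: np.ndarray, classes):
    n, p = X.shape[1], X.shape[0]
    overall = X.mean(axis=1)
    cent = {}
    nk = {}
    sse = np.zeros(p)
    for c in classes:
        cols = y == c
        nk[c] = int(cols.sum())
        cent[c] = X[:, cols].mean(axis=1)
        sse += ((X[:, cols] - cent[c][:, None]) ** 2).sum(axis=1)
    s = np.sqrt(sse / (n - len(classes)))
    s0 = float(np.median(s))
    return overall, cent, nk, s, s0


def pam_train(expr: pd.DataFrame, labels, delta_grid=None, cv_folds: int = 5,
              seed: int = 0, delta: float | None = None) -> PAMModel:
    """Nearest-shrunken-centroid classifier (PAM).

    Standardized centroid differences d_kj = (xbar_kj - xbar_j) /
    (m_k (s_j + s0)) are soft-thresholded at delta; genes with any
    surviving difference form the discriminant signature. When
    ``delta`` is not fixed, it is chosen on a grid as the largest value
    within one standard error of the minimal cross-validated error.
    """
    labels = pd.Series(np.asarray(labels), index=expr.columns)
    classes = sorted(labels.unique())
    if len(classes) < 2 or any((labels == c).sum() < 2 for c in classes):
        raise ValueError("need >= 2 classes with >= 2 samples each")
    X = expr.to_numpy(float)
    y = labels.to_numpy()
    if delta is None:
        dmax = _max_abs_d(X, y, classes)
        grid = (np.asarray(delta_grid, float) if delta_grid is not None
                else np.linspace(0.0, dmax, 12))
        delta, cv_table = _pam_cv_delta(expr, labels, classes, grid, cv_folds, seed)
    else:
        cv_table = None
    model = _pam_build(expr, labels, classes, float(delta))
    model.cv_error = cv_table
    return model


def _max_abs_d(X, y, classes):
    overall, cent, nk, s, s0 = _pam_stats(X, y, classes)
    n = X.shape[1]
    dmax = 0.0
    for c in classes:
        mk = np.sqrt(1.0 / nk[c] - 1.0 / n) if nk[c] < n else 1e-6
        d = (cent[c] - overall) / (mk * (s + s0))
        dmax = max(dmax, float(np.abs(d).max()))
    return dmax


def _pam_build(expr: pd.DataFrame, labels: pd.Series, classes, delta: float) -> PAMModel:
    X = expr.to_numpy(float)
    y = labels.to_numpy()
    n = X.shape[1]
    overall, cent, nk, s, s0 = _pam_stats(X, y, classes)
    shrunk = {}
    mk = {}
    any_nonzero = np.zeros(X.shape[0], dtype=bool)
    for c in classes:
        mk[c] = np.sqrt(1.0 / nk[c] - 1.0 / n) if nk[c] < n else 1e-6
        d = (cent[c] - overall) / (mk[c] * (s + s0))
        dshr = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
        any_nonzero |= dshr != 0
        shrunk[c] = overall + mk[c] * (s + s0) * dshr
    signature = list(expr.index[any_nonzero])
    priors = pd.Series({c: (y == c).mean() for c in classes})
    return PAMModel(
        overall_centroid=pd.Series(overall, index=expr.index),
        centroids=pd.DataFrame(shrunk, index=expr.index).T[expr.index],
        delta=float(delta),
        s=pd.Series(s, index=expr.index), s0=s0, priors=priors,
        mk=pd.Series(mk), classes=list(classes), signature=signature,
        flagged_empty=not any_nonzero.any(),
    )


def _pam_cv_delta(expr, labels, classes, grid, folds, seed):
    rng = np.random.default_rng(seed)
    y = labels.to_numpy()
    assign = np.empty(len(y), dtype=int)
    for c in classes:
        idx = rng.permutation(np.where(y == c)[0])
        assign[idx] = np.arange(len(idx)) % folds
    errs = np.zeros((folds, len(grid)))
    for f in range(folds):
        tr, te = assign != f, assign == f
        if te.sum() == 0 or any((y[tr] == c).sum() < 2 for c in classes):
            errs[f, :] = np.nan
            continue
        for j, d in enumerate(grid):
            model = _pam_build(expr.loc[:, tr], labels[tr], classes, float(d))
            pred = pam_predict(model, expr.loc[:, te])
            errs[f, j] = float(np.mean(pred != y[te]))
    mean_err = np.nanmean(errs, axis=0)
    se = np.nanstd(errs, axis=0, ddof=1) / np.sqrt(np.sum(~np.isnan(errs[:, 0])))
    best = np.nanargmin(mean_err)
    thresh = mean_err[best] + se[best]
    # one-SE rule: the largest delta whose CV error is within one SE
    chosen = max((g for g, e in zip(grid, mean_err) if e <= thresh + 1e-12),
                 default=grid[best])
    table = pd.DataFrame({"delta": grid, "cv_error": mean_err, "se": se})
    return float(chosen), table


def pam_predict(model: PAMModel, samples: pd.DataFrame):
    """Classify samples by minimal discriminant score
    sum_j (x_j - centroid_kj)^2 / (s_j + s0)^2 - 2 log pi_k.

    With an empty (fully shrunken) signature the prediction falls back
    to the class priors.
    """
    X = samples.to_numpy(float) if isinstance(samples, pd.DataFrame) else \
        np.asarray(samples, float).reshape(len(model.overall_centroid), -1)
    denom = (model.s.to_numpy() + model.s0) ** 2
    if model.flagged_empty:
        best = model.priors.idxmax()
        return np.array([best] * X.shape[1], dtype=object)
    scores = np.zeros((len(model.classes), X.shape[1]))
    for i, c in enumerate(model.classes):
        diff = X - model.centroids.loc[c].to_numpy()[:, None]
        scores[i] = (diff ** 2 / denom[:, None]).sum(axis=0) \
            - 2.0 * np.log(model.priors[c])
    idx = np.argmin(scores, axis=0)
    return np.array([model.classes[i] for i in idx], dtype=object)
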