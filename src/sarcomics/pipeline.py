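"""End-to-end orchestration: simulate -> harmonize -> handcrafted
features -> deep features -> consensus clustering -> association and
survival statistics -> differential expression.

A single config dict (typically loaded from YAML) drives every stage;
per-stage seeds are derived from the master seed with
``numpy.random.SeedSequence`` spawning, so a full run is reproducible
and deterministic stages hash-stable. Each stage writes plain CSV/TSV
artifacts into the output directory and registers them, with SHA-256
hashes, in the run manifest.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import consensus as cc
from . import survival as sv
from . import transcriptomics as tx
from .autoencoder import CAEConfig, extract_latent, train
from .harmonize import discretize, extract_center_slice, harmonize_volume
from .radiomics import extract_features, filter_robust_features, icc
from .synthetic import generate_cohort

__all__ = ["DEFAULT_CONFIG", "RunManifest", "run_pipeline", "report"]


DEFAULT_CONFIG: dict = {
    "outdir": "sarcomics_run",
    "seed": 0,
    "simulate": {"n": 60, "n_genes": 1200, "n_de": 120},
    "radiomics": {"icc_subjects": 20, "icc_threshold": 0.90},
    "deep": {"input_size": [64, 64], "latent_dim": 64, "epochs": 12,
             "cv_repeats": 1, "lambda_prognostic": 0.05},
    "cluster": {"B": 200, "holdout": 0.40, "k_range": [2, 3, 4]},
    "survive": {"folds": 5},
    "dge": {"fc_threshold": 2.0, "alpha": 0.05},
    "stages": ["simulate", "radiomics", "deep", "cluster", "survive", "dge"],
}


@dataclass
class RunManifest:
    stages: list = field(default_factory=list)
    warnings_log: list = field(default_factory=list)

    def add(self, stage: str, outputs: dict, params: dict, seconds: float,
            warns=()):
        self.stages.append({
            "stage": stage,
            "outputs": {name: _sha256(path) for name, path in outputs.items()},
            "params": params,
            "wall_seconds": round(seconds, 2),
            "warnings": [str(w) for w in warns],
        })
        self.warnings_log.extend(str(w) for w in warns)

    def to_json(self) -> str:
        return json.dumps({"stages": self.stages}, indent=1)


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: (dict(v) if isinstance(v, dict) else v) for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def run_pipeline(config: dict | None = None) -> RunManifest:
    """Run the configured stages in order, writing artifacts and a
    manifest to ``config['outdir']``. Halts on the first stage failure
    (recorded in the manifest)."""
    cfg = _merge(DEFAULT_CONFIG, config)
    out = Path(cfg["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg["seed"])
    stage_seed = {name: int(c.generate_state(1)[0] % (2 ** 31))
                  for name, c in zip(
                      ["simulate", "radiomics", "deep", "cluster", "survive", "dge"],
                      ss.spawn(6))}
    manifest = RunManifest()
    state: dict = {}
    for stage in cfg["stages"]:
        fn = _STAGES[stage]
        t0 = time.time()
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                outputs = fn(cfg, state, out, stage_seed[stage])
            except Exception as err:  # halt downstream stages
                manifest.stages.append({"stage": stage, "failed": str(err)})
                break
        manifest.add(stage, outputs, cfg.get(stage, {}), time.time() - t0,
                     [w.message for w in caught])
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


# ------------------------------------------------------------------ stages

def _stage_simulate(cfg, state, out, seed):
    params = cfg["simulate"]
    cohort = generate_cohort(seed=seed, **params)
    state["cohort"] = cohort
    cohort.clinical.to_csv(out / "clinical.csv")
    cohort.survival.to_csv(out / "survival.csv")
    cohort.counts.to_csv(out / "counts.tsv", sep="\t")
    cohort.batches.to_csv(out / "batches.csv")
    cohort.truth.to_csv(out / "truth.csv")
    return {"clinical": out / "clinical.csv", "survival": out / "survival.csv",
            "counts": out / "counts.tsv", "truth": out / "truth.csv"}


def _stage_radiomics(cfg, state, out, seed):
    cohort = state["cohort"]
    params = cfg["radiomics"]
    rows, slices = [], []
    refs: dict = {}   # histogram reference = first cohort volume per channel
    for study in cohort.studies:
        disc = {}
        for name, vol in study.channels.items():
            h, m = harmonize_volume(vol, study.mask, reference=refs.get(name))
            refs.setdefault(name, h)
            disc[name] = discretize(h, m)
            if name == "CE":
                slices.append(extract_center_slice(h, m))
        rows.append(extract_features(disc, m, spacing=m.spacing))
    feats = pd.DataFrame(rows, index=cohort.clinical.index)
    state["slices"] = slices

    # repeat extraction with perturbed masks on a subject subset -> ICC
    rng = np.random.default_rng(seed)
    n_icc = min(params["icc_subjects"], len(cohort.studies))
    idx = rng.choice(len(cohort.studies), size=n_icc, replace=False)
    repeat_rows = []
    from scipy import ndimage as ndi

    from .images import SegmentationMask
    for i in idx:
        study = cohort.studies[i]
        mvals = study.mask.values
        op = ndi.binary_dilation if rng.uniform() < 0.5 else ndi.binary_erosion
        perturbed = op(mvals)
        if not perturbed.any():
            perturbed = mvals
        pmask = SegmentationMask(perturbed, study.mask.spacing)
        disc = {}
        for name, vol in study.channels.items():
            h, m = harmonize_volume(vol, pmask)
            disc[name] = discretize(h, m)
        repeat_rows.append(extract_features(disc, m, spacing=m.spacing))
    repeats = pd.DataFrame(repeat_rows, index=feats.index[idx])
    stacked = np.stack([feats.iloc[idx].to_numpy(), repeats.to_numpy()], axis=1)
    icc_vals = icc(stacked)
    icc_vals.index = feats.columns
    robust = filter_robust_features(feats, icc_vals,
                                    threshold=params["icc_threshold"])
    feats.to_csv(out / "features_all.csv")
    icc_vals.to_csv(out / "icc.csv")
    robust.to_csv(out / "features_robust.csv")
    state["features"] = robust
    return {"features_all": out / "features_all.csv", "icc": out / "icc.csv",
            "features_robust": out / "features_robust.csv"}


def _stage_deep(cfg, state, out, seed):
    from .autoencoder import preprocess_slices
    cohort = state["cohort"]
    params = dict(cfg["deep"])
    size = tuple(params.pop("input_size"))
    lam = params.pop("lambda_prognostic")
    imgs = preprocess_slices(state["slices"], size)
    survival = cohort.survival
    results = {}
    for name, lam_i in (("cae", 0.0), ("hscae", lam)):
        config = CAEConfig(input_size=size, lambda_prognostic=lam_i,
                           seed=seed, **params)
        model = train(imgs, survival if lam_i > 0 else None, config)
        lat = extract_latent(model, imgs)
        lat_df = pd.DataFrame(lat, index=cohort.clinical.index,
                              columns=[f"z{i:04d}" for i in range(lat.shape[1])])
        lat_df.to_csv(out / f"latent_{name}.csv")
        pd.DataFrame({"holdout_mse": model.history["holdout_mse"]}).to_csv(
            out / f"history_{name}.csv", index=False)
        state[f"latent_{name}"] = lat_df
        results[f"latent_{name}"] = out / f"latent_{name}.csv"
        results[f"history_{name}"] = out / f"history_{name}.csv"
    return results


def _stage_cluster(cfg, state, out, seed):
    cohort = state["cohort"]
    params = cfg["cluster"]
    labels = {}
    sources = {"hrf": state["features"],
               "cae": state["latent_cae"], "hscae": state["latent_hscae"]}
    norm = tx.voom_normalize(cohort.counts)
    expr = tx.combat_correct(norm.log2_expr, cohort.batches)
    state["expr"] = expr
    # cluster samples on the most variable genes
    top = expr.var(axis=1).nlargest(min(500, len(expr))).index
    sources["rna"] = expr.loc[top].T
    outputs = {}
    for name, matrix in sources.items():
        model = cc.consensus_cluster(matrix, k_range=tuple(params["k_range"]),
                                     B=params["B"], holdout=params["holdout"],
                                     seed=seed)
        labels[name] = model.labels
        (out / f"consensus_{name}.json").write_text(model.to_json())
        outputs[f"consensus_{name}"] = out / f"consensus_{name}.json"
    lab = pd.DataFrame(labels)
    lab.to_csv(out / "cluster_labels.csv")
    state["labels"] = lab
    outputs["cluster_labels"] = out / "cluster_labels.csv"
    return outputs


def _stage_survive(cfg, state, out, seed):
    cohort = state["cohort"]
    labels = state["labels"]
    folds = cfg["survive"]["folds"]
    records = cohort.survival.join(labels).join(
        cohort.clinical[["age", "size_mm", "grade", "pr_os"]])
    results = []
    for grouping in ("hrf", "cae", "hscae", "rna"):
        stat, df, p = sv.logrank_test(records, records[grouping])
        fit = sv.cox_fit(records, [grouping])
        cv = sv.cv_cindex(records, [grouping], folds=folds, seed=seed)
        results.append({"grouping": grouping, "logrank_chi2": stat,
                        "logrank_p": p, "cv_cindex": cv.cindex,
                        "ci_low": cv.ci[0], "ci_high": cv.ci[1]})
    combined = sv.cv_cindex(records, ["hscae", "rna"], folds=folds, seed=seed)
    results.append({"grouping": "hscae+rna", "cv_cindex": combined.cindex,
                    "ci_low": combined.ci[0], "ci_high": combined.ci[1]})
    res = pd.DataFrame(results).set_index("grouping")
    res.to_csv(out / "survival_models.csv")
    groups, n_excl = sv.combine_groups(labels["hscae"], labels["rna"])
    groups.to_csv(out / "combined_groups.csv")
    state["combined"] = groups
    return {"survival_models": out / "survival_models.csv",
            "combined_groups": out / "combined_groups.csv"}


def _stage_dge(cfg, state, out, seed):
    params = cfg["dge"]
    expr = state["expr"]
    combined = state["combined"]["binary"]
    res = tx.dge_ttest(expr, combined.loc[expr.columns],
                       fc_threshold=params["fc_threshold"],
                       alpha=params["alpha"])
    res.table.to_csv(out / "dge.csv")
    return {"dge": out / "dge.csv"}


_STAGES = {
    "simulate": _stage_simulate,
    "radiomics": _stage_radiomics,
    "deep": _stage_deep,
    "cluster": _stage_cluster,
    "survive": _stage_survive,
    "dge": _stage_dge,
}


def _report_figures(out: Path, lines: list) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .survival import km_estimate

    surv_path, lab_path = out / "survival.csv", out / "cluster_labels.csv"
    if surv_path.exists() and lab_path.exists():
        surv = pd.read_csv(surv_path, index_col=0)
        lab = pd.read_csv(lab_path, index_col=0)
        col = "hscae" if "hscae" in lab.columns else lab.columns[0]
        fig, ax = plt.subplots(figsize=(5, 4))
        for name, idx in lab.groupby(col).groups.items():
            km = km_estimate(surv.loc[idx])
            ax.step(np.concatenate([[0], km.event_times]),
                    np.concatenate([[1.0], km.survival]),
                    where="post", label=f"{col} {name} (n={len(idx)})")
        ax.set_xlabel("months")
        ax.set_ylabel("MFS probability")
        ax.legend()
        fig.savefig(out / "km_curves.png", dpi=100, bbox_inches="tight")
        plt.close(fig)
        lines.append("- figure: km_curves.png")
    dge_path = out / "dge.csv"
    if dge_path.exists():
        dge = pd.read_csv(dge_path, index_col=0)
        fig, ax = plt.subplots(figsize=(5, 4))
        sig = dge["call"] != "ns"
        ax.scatter(dge.loc[~sig, "log2_fc"], dge.loc[~sig, "neg_log10_p_adj"],
                   s=4, c="gray", alpha=0.5)
        ax.scatter(dge.loc[sig, "log2_fc"], dge.loc[sig, "neg_log10_p_adj"],
                   s=6, c="crimson")
        ax.set_xlabel("log2 fold change")
        ax.set_ylabel("-log10 adjusted p")
        fig.savefig(out / "volcano.png", dpi=100, bbox_inches="tight")
        plt.close(fig)
        lines.append("- figure: volcano.png")


def report(outdir) -> str:
    """Render a markdown summary (with KM and volcano figures) of a
    completed run."""
    out = Path(outdir)
    lines = ["# sarcomics run report", ""]
    manifest = json.loads((out / "manifest.json").read_text())
    for st in manifest["stages"]:
        if "failed" in st:
            lines.append(f"## {st['stage']}: FAILED — {st['failed']}")
            continue
        lines.append(f"## {st['stage']} ({st['wall_seconds']} s)")
        for name in st["outputs"]:
            lines.append(f"- {name}")
    lab_path = out / "cluster_labels.csv"
    if lab_path.exists():
        lab = pd.read_csv(lab_path, index_col=0)
        lines.append("")
        lines.append("## Cluster sizes")
        for col in lab.columns:
            sizes = lab[col].value_counts().sort_index()
            lines.append(f"- {col}: " + ", ".join(f"{k}={v}" for k, v in sizes.items()))
    surv_path = out / "survival_models.csv"
    if surv_path.exists():
        surv = pd.read_csv(surv_path, index_col=0)
        lines.append("")
        lines.append("## Cross-validated c-indices")
        lines.append(surv.round(4).to_string())
    lines.append("")
    _report_figures(out, lines)
    text = "\n".join(lines) + "\n"
    (out / "report.md").write_text(text)
    return text
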