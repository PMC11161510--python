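"""Synthetic sarcoma-cohort generator.

The real study population (locally advanced soft-tissue sarcoma with
baseline multi-sequence MRI, survival follow-up and RNA-seq on a
subcohort) is not publicly available, so this module plants the same
statistical structure synthetically:

* multi-channel tumor images (T1-like, T2-like, contrast-enhanced-like)
  whose phenotype — size, texture, necrotic core, peritumoral rim,
  heterogeneous signal — depends on a latent imaging group,
* exponential metastasis-free-survival times whose hazard depends
  log-linearly on the imaging and expression groups, with independent
  exponential censoring,
* negative-binomial expression counts with a planted set of fold-change
  differential genes between expression groups and multiplicative batch
  effects,
* clinical covariates (age, size, grade, histotype, 10-year predicted
  overall survival, treatment flags) with the group correlations the
  analyses probe.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import ImageVolume, SegmentationMask

__all__ = [
    "PhenotypeSpec",
    "TumorStudy",
    "SyntheticCohort",
    "generate_tumor_study",
    "generate_survival",
    "generate_expression",
    "generate_cohort",
    "default_imaging_specs",
    "default_expression_hazards",
]

CHANNELS = ("T1", "T2", "CE")


@dataclass
class PhenotypeSpec:
    """Parameters of one planted imaging phenotype group."""

    group_id: str
    proportion: float = 1.0
    size_mm_mean: float = 80.0
    size_mm_sd: float = 25.0
    texture_contrast: float = 1.0
    necrosis_prob: float = 0.3
    peritumoral_rim_prob: float = 0.3
    heterogeneity_prob: float = 0.3
    log_hazard: float = 0.0
    expr_group_id: str | None = None
    pr_os_mean: float = 0.6

    def __post_init__(self) -> None:
        for p in (self.necrosis_prob, self.peritumoral_rim_prob,
                  self.heterogeneity_prob, self.pr_os_mean):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.size_mm_mean <= 0:
            raise ValueError("size_mm_mean must be positive")
        if self.size_mm_sd < 0:
            raise ValueError("size_mm_sd must be non-negative")
        if self.texture_contrast < 0:
            raise ValueError("texture_contrast must be non-negative")


@dataclass
class TumorStudy:
    """One subject's three-channel image study plus mask and planted flags."""

    channels: dict
    mask: SegmentationMask
    flags: dict
    diameter_mm: float


@dataclass
class SyntheticCohort:
    studies: list
    clinical: pd.DataFrame
    survival: pd.DataFrame
    counts: pd.DataFrame
    batches: pd.Series
    truth: pd.DataFrame
    de_truth: pd.DataFrame


def default_imaging_specs() -> list[PhenotypeSpec]:
    """Two imaging phenotypes mirroring an aggressive (A) and an
    indolent (B) deep-radiomics group: larger, more textured, more
    necrotic tumors with worse predicted survival in group A."""
    return [
        PhenotypeSpec("A", proportion=0.60, size_mm_mean=120, size_mm_sd=50,
                      texture_contrast=2.0, necrosis_prob=0.70,
                      peritumoral_rim_prob=0.70, heterogeneity_prob=0.70,
                      log_hazard=float(np.log(3.3)), pr_os_mean=0.45),
        PhenotypeSpec("B", proportion=0.40, size_mm_mean=64, size_mm_sd=34,
                      texture_contrast=0.6, necrosis_prob=0.15,
                      peritumoral_rim_prob=0.20, heterogeneity_prob=0.25,
                      log_hazard=0.0, pr_os_mean=0.72),
    ]


def default_expression_hazards() -> dict[str, float]:
    """Log-hazards of the two expression groups (worse prognosis in A)."""
    return {"A_RNA": float(np.log(2.6)), "B_RNA": 0.0}


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_tumor_study(spec: PhenotypeSpec,
                         grid_shape=(64, 64, 16),
                         spacing=(2.0, 2.0, 4.0),
                         seed: int = 0) -> TumorStudy:
    """Generate one three-channel tumor study with an ellipsoidal mask.

    Channel intensities are a base tissue level modulated by a smooth
    multiplicative bias field plus Gaussian-filtered noise scaled by
    ``texture_contrast``. With the spec's probabilities a central
    low-enhancement "necrotic" core, a contrast-enhancing rim beyond the
    mask, and patchy T2 heterogeneity are added. Deterministic per seed.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    if any(g <= 0 for g in grid_shape):
        raise ValueError("grid shape must be positive")
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive (mm)")
    rng = np.random.default_rng(seed)

    extent = np.array(grid_shape) * np.array(spacing)
    diameter = float(max(8.0, rng.normal(spec.size_mm_mean, spec.size_mm_sd)))
    semi = diameter / 2.0 * rng.uniform(0.75, 1.25, size=3)
    # keep the ellipsoid strictly inside the grid
    semi = np.minimum(semi, extent / 2.0 - 2.0 * np.array(spacing))
    semi = np.maximum(semi, np.array(spacing))
    center = extent / 2.0 + rng.uniform(-0.05, 0.05, size=3) * extent

    coords = np.meshgrid(*[(np.arange(n) + 0.5) * s for n, s in zip(grid_shape, spacing)],
                         indexing="ij")
    r2 = sum(((c - c0) / a) ** 2 for c, c0, a in zip(coords, center, semi))
    mask = r2 <= 1.0
    if not mask.any():
        mask[tuple(np.array(grid_shape) // 2)] = True

    has_necrosis = bool(rng.uniform() < spec.necrosis_prob)
    has_rim = bool(rng.uniform() < spec.peritumoral_rim_prob)
    has_het = bool(rng.uniform() < spec.heterogeneity_prob)

    core = r2 <= 0.40 ** 2 if has_necrosis else np.zeros_like(mask)
    rim = np.zeros_like(mask)
    if has_rim:
        rim = ndimage.binary_dilation(mask, iterations=2) & ~mask
    het_field = np.zeros(grid_shape)
    if has_het:
        blobs = _smooth_field(rng, grid_shape, sigma=4.0)
        het_field = 0.25 * np.where(blobs > 0, 1.0, -1.0)

    base = {"T1": 0.35, "T2": 0.55, "CE": 0.70}
    background = 0.15
    channels = {}
    for name in CHANNELS:
        tex = _smooth_field(rng, grid_shape, sigma=1.2) * 0.05 * spec.texture_contrast
        img = np.full(grid_shape, background)
        img[mask] = base[name] + tex[mask]
        if name == "T2" and has_het:
            img[mask] += het_field[mask]
        if has_necrosis:
            if name == "CE":
                img[core & mask] = 0.25 * base["CE"] + tex[core & mask]
            elif name == "T2":
                img[core & mask] += 0.15
        if name == "CE" and has_rim:
            img[rim] = 0.9 + tex[rim]
        bias = np.exp(0.08 * _smooth_field(rng, grid_shape, sigma=12.0))
        img = np.clip(img * bias, 0.0, None)
        channels[name] = ImageVolume(img, spacing)

    return TumorStudy(
        channels=channels,
        mask=SegmentationMask(mask, spacing),
        flags={"heterogeneous_t2": has_het, "necrosis": has_necrosis,
               "peritumoral_enhancement": has_rim},
        diameter_mm=float(2.0 * semi.max()),
    )


def generate_survival(groups,
                      baseline_rate: float,
                      log_hazards: dict,
                      censor_rate: float,
                      seed: int = 0) -> pd.DataFrame:
    """Exponential event times with group log-hazards and censoring.

    Event time for a subject in group g is exponential with rate
    ``baseline_rate * exp(log_hazards[g])`` (months^-1); censoring is an
    independent exponential with rate ``censor_rate``. Returns a frame
    with columns ``time`` (months), ``event`` and ``group``.
    """
    if baseline_rate <= 0 or censor_rate <= 0:
        raise ValueError("rates must be positive")
    groups = list(groups)
    unknown = set(groups) - set(log_hazards)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    lh = np.array([log_hazards[g] for g in groups], dtype=float)
    rates = baseline_rate * np.exp(lh)
    t_event = rng.exponential(1.0 / rates)
    t_cens = rng.exponential(1.0 / censor_rate, size=len(groups))
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"time": time, "event": event, "group": groups})


def generate_expression(n_genes: int,
                        n_de: int,
                        log2_fc: float,
                        groups,
                        batches,
                        libsize_range=(2e5, 1e6),
                        dispersion: float = 0.15,
                        seed: int = 0):
    """Negative-binomial counts with planted differential genes.

    ``n_de`` genes are shifted by ``log2_fc`` between the two expression
    groups (half up-, half down-regulated in the second group).
    Batches act multiplicatively on gene means and on the gene-wise
    dispersions; library sizes are uniform over ``libsize_range``.
    Returns (counts genes x samples, truth frame with planted calls).
    """
    if n_de > n_genes:
        raise ValueError("n_de cannot exceed n_genes")
    if n_de < 0 or n_genes <= 0:
        raise ValueError("gene counts must be non-negative")
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if libsize_range[0] <= 0 or libsize_range[1] < libsize_range[0]:
        raise ValueError("invalid libsize_range")
    groups = np.asarray(list(groups))
    batches = np.asarray(list(batches))
    if len(groups) != len(batches):
        raise ValueError("groups and batches must align")
    n_samples = len(groups)
    rng = np.random.default_rng(seed)

    rel = np.exp(rng.normal(np.log(50.0), 1.2, size=n_genes))
    rel /= rel.sum()
    disp = dispersion * np.exp(rng.normal(0.0, 0.4, size=n_genes))

    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    direction = np.zeros(n_genes)
    direction[de_idx[: n_de // 2]] = 1.0
    direction[de_idx[n_de // 2:]] = -1.0

    group_levels = list(pd.unique(groups))
    in_second = np.isin(groups, group_levels[1:2]) if len(group_levels) > 1 else np.zeros(n_samples, bool)
    fc = np.where(in_second[None, :], 2.0 ** (log2_fc * direction[:, None]), 1.0)

    batch_levels = list(pd.unique(batches))
    loc_fac = np.ones((n_genes, n_samples))
    disp_fac = np.ones((n_genes, n_samples))
    if len(batch_levels) > 1:
        for b in batch_levels[1:]:
            cols = batches == b
            loc_fac[:, cols] = np.exp(rng.normal(0.0, 0.35, size=n_genes))[:, None]
            disp_fac[:, cols] = np.exp(rng.normal(0.0, 0.25, size=n_genes))[:, None]

    libsize = rng.uniform(libsize_range[0], libsize_range[1], size=n_samples)
    mu = rel[:, None] * fc * loc_fac * libsize[None, :]
    d = disp[:, None] * disp_fac
    # NB parametrized by size r = 1/d and p = r / (r + mu)
    r = 1.0 / d
    p = r / (r + np.maximum(mu, 1e-12))
    counts = rng.negative_binomial(r, p)

    genes = [f"gene{i:05d}" for i in range(n_genes)]
    samples = [f"s{j:04d}" for j in range(n_samples)]
    truth = pd.DataFrame({
        "gene": genes,
        "is_de": direction != 0,
        "direction": np.where(direction > 0, "up",
                              np.where(direction < 0, "down", "ns")),
    }).set_index("gene")
    return (pd.DataFrame(counts, index=genes, columns=samples), truth)


def _draw_categorical(rng, labels, probs, n):
    return rng.choice(np.asarray(labels, dtype=object), size=n, p=np.asarray(probs, float))


HISTOTYPES = ["UPS", "Leiomyosarcoma", "DD/Pleomorphic LPS", "M/RC LPS",
              "Myxofibrosarcoma", "Synovial sarcoma", "Other"]
HISTOTYPE_PROBS = [0.32, 0.11, 0.12, 0.09, 0.06, 0.07, 0.23]


def generate_cohort(n: int,
                    specs: list[PhenotypeSpec] | None = None,
                    mixing: dict | None = None,
                    seed: int = 0,
                    grid_shape=(64, 64, 16),
                    spacing=(2.0, 2.0, 4.0),
                    baseline_rate: float = 0.003,
                    censor_rate: float = 0.012,
                    expr_log_hazards: dict | None = None,
                    n_genes: int = 2000,
                    n_de: int = 200,
                    log2_fc: float = 1.0,
                    n_batches: int = 2,
                    dispersion: float = 0.15,
                    make_images: bool = True) -> SyntheticCohort:
    """Generate a full synthetic cohort.

    ``mixing`` maps each imaging group to a distribution over expression
    groups; the default is independent 50/50 mixing, reproducing the
    study's disconnection between radiomics and transcriptomics
    grouping. Survival hazard is log-additive in the imaging-group and
    expression-group effects. Semantic radiological flags come from the
    image generator and are therefore correlated with the imaging group.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    specs = specs if specs is not None else default_imaging_specs()
    props = np.array([s.proportion for s in specs], float)
    if abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("spec proportions must sum to 1")
    expr_log_hazards = expr_log_hazards or default_expression_hazards()
    expr_groups = sorted(expr_log_hazards)
    if mixing is None:
        mixing = {s.group_id: {e: 1.0 / len(expr_groups) for e in expr_groups}
                  for s in specs}
    for g, dist in mixing.items():
        tot = sum(dist.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"mixing distribution for {g!r} does not sum to 1")

    ss = np.random.SeedSequence(seed)
    s_assign, s_img, s_surv, s_expr, s_clin = [
        int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(5)]
    rng = np.random.default_rng(s_assign)
    spec_by_id = {s.group_id: s for s in specs}

    img_groups = _draw_categorical(rng, [s.group_id for s in specs], props, n)
    expr_assign = np.empty(n, dtype=object)
    for i, g in enumerate(img_groups):
        dist = mixing[g]
        labels = sorted(dist)
        expr_assign[i] = _draw_categorical(rng, labels, [dist[l] for l in labels], 1)[0]

    subjects = [f"subj{i:04d}" for i in range(n)]
    studies, rows = [], []
    crng = np.random.default_rng(s_clin)
    img_rng = np.random.default_rng(s_img)
    for i in range(n):
        spec = spec_by_id[img_groups[i]]
        study_seed = int(img_rng.integers(2 ** 31))
        if make_images:
            study = generate_tumor_study(spec, grid_shape, spacing, seed=study_seed)
            studies.append(study)
            flags = study.flags
            size = study.diameter_mm
        else:
            frng = np.random.default_rng(study_seed)
            flags = {"heterogeneous_t2": bool(frng.uniform() < spec.heterogeneity_prob),
                     "necrosis": bool(frng.uniform() < spec.necrosis_prob),
                     "peritumoral_enhancement": bool(frng.uniform() < spec.peritumoral_rim_prob)}
            size = float(max(8.0, frng.normal(spec.size_mm_mean, spec.size_mm_sd)))
        p3 = float(np.clip(1.2 - 1.4 * spec.pr_os_mean, 0.05, 0.9))
        grade = crng.choice(["I", "II", "III"],
                            p=[0.35 * (1 - p3), 0.65 * (1 - p3), p3])
        rows.append({
            "subject": subjects[i],
            "age": float(np.clip(crng.normal(62, 13), 18, 90)),
            "size_mm": size,
            "grade": grade,
            "histotype": _draw_categorical(crng, HISTOTYPES, HISTOTYPE_PROBS, 1)[0],
            "pr_os": float(np.clip(crng.normal(spec.pr_os_mean, 0.12), 0.01, 0.99)),
            "chemotherapy": int(crng.uniform() < 0.35),
            "radiotherapy": int(crng.uniform() < 0.55),
            "margins": crng.choice(["R0", "R1", "R2"], p=[0.70, 0.25, 0.05]),
            "heterogeneous_t2": int(flags["heterogeneous_t2"]),
            "necrosis": int(flags["necrosis"]),
            "peritumoral_enhancement": int(flags["peritumoral_enhancement"]),
        })
    clinical = pd.DataFrame(rows).set_index("subject") if rows else pd.DataFrame(
        columns=["age", "size_mm", "grade", "histotype", "pr_os", "chemotherapy",
                 "radiotherapy", "margins", "heterogeneous_t2", "necrosis",
                 "peritumoral_enhancement"])

    combined = [f"{g}|{e}" for g, e in zip(img_groups, expr_assign)]
    lh = {f"{s.group_id}|{e}": s.log_hazard + expr_log_hazards[e]
          for s in specs for e in expr_groups}
    if n > 0:
        survival = generate_survival(combined, baseline_rate, lh, censor_rate,
                                     seed=s_surv)
        survival.index = pd.Index(subjects, name="subject")
        survival = survival.drop(columns="group")
    else:
        survival = pd.DataFrame(columns=["time", "event"])

    erng = np.random.default_rng(s_expr)
    batches = pd.Series(erng.integers(0, n_batches, size=n).astype(str),
                        index=pd.Index(subjects, name="subject"), name="batch")
    if n > 0:
        counts, de_truth = generate_expression(
            n_genes, n_de, log2_fc, expr_assign, batches.to_numpy(),
            dispersion=dispersion, seed=s_expr)
        counts.columns = subjects
    else:
        counts = pd.DataFrame(index=[f"gene{i:05d}" for i in range(n_genes)])
        de_truth = pd.DataFrame(columns=["is_de", "direction"])

    truth = pd.DataFrame({"imaging_group": img_groups,
                          "expression_group": expr_assign},
                         index=pd.Index(subjects, name="subject"))
    return SyntheticCohort(studies=studies, clinical=clinical, survival=survival,
                           counts=counts, batches=batches, truth=truth,
                           de_truth=de_truth)
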