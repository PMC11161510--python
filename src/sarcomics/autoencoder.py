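"""Deep radiomics: convolutional autoencoder (CAE) and half-supervised
CAE (HSCAE).

A stack of stride-2 convolution blocks encodes the background-removed,
[0,1]-normalized tumor center slice into a dense latent vector (the
deep radiomics features, 1024 per image at full scale); a mirrored
upsample-convolution decoder reconstructs the slice through a sigmoid.
The CAE minimizes the reconstruction mean squared error; the HSCAE adds
``lambda_prognostic`` times a prognostic loss — the batch-wise negative
Cox partial log-likelihood (Breslow ties) of a linear risk head on the
latent vector — so the same code path with lambda = 0 is exactly the
CAE. Training runs a repeated leave-10%-out loop that records held-out
reconstruction error per repeat, then refits on all images. Grad-CAM
style class-activation maps localize the image regions driving the
risk head.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from ._nn import (Adam, Conv2d, Dense, Flatten, ReLU, Reshape, Sequential,
                  Sigmoid, Upsample2x)

__all__ = [
    "CAEConfig",
    "TrainedModel",
    "ReconstructionReport",
    "augment",
    "train",
    "reconstruction_mse",
    "extract_latent",
    "class_activation_map",
    "preprocess_slices",
    "save_model",
    "load_model",
]


@dataclass
class CAEConfig:
    input_size: tuple[int, int] = (64, 64)
    latent_dim: int = 1024
    enc_channels: tuple[int, ...] = (16, 32, 64, 64)
    lambda_prognostic: float = 0.0
    epochs: int = 40
    batch_size: int = 16
    learning_rate: float = 1.5e-3
    lr_schedule: str = "cosine"        # "cosine" or "constant"
    augmentation: bool | str = "flips"  # False, "flips", or True (full)
    cv_holdout_fraction: float = 0.10
    cv_repeats: int = 5
    refit_final: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if not 0.0 < self.cv_holdout_fraction < 1.0:
            raise ValueError("cv_holdout_fraction must be in (0, 1)")
        if self.lambda_prognostic < 0:
            raise ValueError("lambda_prognostic must be >= 0")
        h, w = self.input_size
        f = 2 ** len(self.enc_channels)
        if h % f or w % f:
            raise ValueError("input_size must be divisible by 2^n_blocks")


@dataclass
class TrainedModel:
    encoder: Sequential
    decoder: Sequential
    risk_head: Dense | None
    config: CAEConfig
    history: dict = field(default_factory=dict)
    trained: bool = False


@dataclass
class ReconstructionReport:
    mse: float
    per_subject: np.ndarray


# ------------------------------------------------------------- augmentation

def augment(image: np.ndarray, seed: int, flip: bool = True,
            max_rotate: float = 20.0, max_zoom: float = 0.10,
            elastic_alpha: float = 2.0, elastic_sigma: float = 8.0,
            jitter: float = 0.05, clip=(0.0, 1.0)) -> np.ndarray:
    """Random morphological/intensity augmentation of a 2-D slice.

    Composition of horizontal/vertical flips, rotation within
    ``max_rotate`` degrees, zoom within ``max_zoom``, a mild elastic
    deformation and multiplicative intensity jitter; shape preserved,
    output clipped to ``clip``. Deterministic per seed.
    """
    img = np.asarray(image, float)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("augment expects a square 2-D image")
    rng = np.random.default_rng(seed)
    out = img
    if flip:
        if rng.uniform() < 0.5:
            out = out[::-1, :]
        if rng.uniform() < 0.5:
            out = out[:, ::-1]
    if max_rotate > 0:
        angle = rng.uniform(-max_rotate, max_rotate)
        out = ndimage.rotate(out, angle, reshape=False, order=1, mode="constant")
    if max_zoom > 0:
        factor = 1.0 + rng.uniform(-max_zoom, max_zoom)
        zoomed = ndimage.zoom(out, factor, order=1)
        out = _fit_to_shape(zoomed, img.shape)
    if elastic_alpha > 0:
        disp = [ndimage.gaussian_filter(rng.standard_normal(img.shape),
                                        elastic_sigma) * elastic_alpha
                for _ in range(2)]
        ii, jj = np.meshgrid(np.arange(img.shape[0]), np.arange(img.shape[1]),
                             indexing="ij")
        out = ndimage.map_coordinates(out, [ii + disp[0], jj + disp[1]],
                                      order=1, mode="constant")
    if jitter > 0:
        out = out * (1.0 + rng.uniform(-jitter, jitter))
    return np.clip(np.ascontiguousarray(out), clip[0], clip[1])


def _fit_to_shape(img: np.ndarray, shape) -> np.ndarray:
    out = np.zeros(shape)
    src = [slice(max(0, (s - t) // 2), max(0, (s - t) // 2) + min(s, t))
           for s, t in zip(img.shape, shape)]
    dst = [slice(max(0, (t - s) // 2), max(0, (t - s) // 2) + min(s, t))
           for s, t in zip(img.shape, shape)]
    out[tuple(dst)] = img[tuple(src)]
    return out


def preprocess_slices(slices, size: tuple[int, int]) -> np.ndarray:
    """Resize 2-D slices to a common size and normalize each to [0, 1]."""
    out = np.zeros((len(slices),) + tuple(size))
    for i, sl in enumerate(slices):
        sl = np.asarray(sl, float)
        factors = (size[0] / sl.shape[0], size[1] / sl.shape[1])
        r = ndimage.zoom(sl, factors, order=1)
        r = _fit_to_shape(r, size)
        lo, hi = r.min(), r.max()
        out[i] = (r - lo) / (hi - lo) if hi > lo else 0.0
    return out


# ------------------------------------------------------------------ network

def _build(config: CAEConfig, rng: np.random.Generator):
    h, w = config.input_size
    enc_layers = []
    c_prev = 1
    for c in config.enc_channels:
        enc_layers += [Conv2d(c_prev, c, 3, stride=2, pad=1, rng=rng), ReLU()]
        c_prev = c
    n_blocks = len(config.enc_channels)
    hb, wb = h // 2 ** n_blocks, w // 2 ** n_blocks
    flat = c_prev * hb * wb
    enc_layers += [Flatten(), Dense(flat, config.latent_dim, rng=rng)]
    encoder = Sequential(enc_layers)

    dec_layers = [Dense(config.latent_dim, flat, rng=rng), ReLU(),
                  Reshape((c_prev, hb, wb))]
    chans = list(config.enc_channels[::-1][1:]) + [config.enc_channels[0]]
    c_cur = c_prev
    for i in range(n_blocks - 1):
        dec_layers += [Upsample2x(), Conv2d(c_cur, chans[i], 3, 1, 1, rng=rng), ReLU()]
        c_cur = chans[i]
    dec_layers += [Upsample2x(), Conv2d(c_cur, 1, 3, 1, 1, rng=rng), Sigmoid()]
    decoder = Sequential(dec_layers)

    risk = Dense(config.latent_dim, 1, rng=rng) if config.lambda_prognostic > 0 else None
    return encoder, decoder, risk


def _cox_loss_grad(risk: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Negative Cox partial log-likelihood (Breslow) and its gradient
    w.r.t. the risk scores, averaged over events."""
    n_events = int(event.sum())
    if n_events == 0:
        return 0.0, np.zeros_like(risk)
    order = np.argsort(-time, kind="stable")  # descending time
    r = risk[order]
    t = time[order]
    e = event[order]
    er = np.exp(r - r.max())
    cum = np.cumsum(er)  # risk-set sums for descending times
    # with Breslow ties, subjects tied on time share the full tied risk set
    risk_sum = np.empty_like(cum)
    i = 0
    while i < len(t):
        j = i
        while j + 1 < len(t) and t[j + 1] == t[i]:
            j += 1
        risk_sum[i:j + 1] = cum[j]
        i = j + 1
    # loss on the shifted scale (the max-shift cancels in r - log S)
    loss = -np.sum(e * ((r - r.max()) - np.log(risk_sum))) / n_events
    # gradient: -e_k + sum over events i with t_i <= t_k of exp(r_k)/S_i
    inv_s = e / risk_sum
    cum_inv = np.cumsum(inv_s[::-1])[::-1]
    # align ties: every member of a tied block is in the risk set of that block
    cum_inv_tied = np.empty_like(cum_inv)
    i = 0
    while i < len(t):
        j = i
        while j + 1 < len(t) and t[j + 1] == t[i]:
            j += 1
        cum_inv_tied[i:j + 1] = cum_inv[i]
        i = j + 1
    grad_sorted = (-e + er * cum_inv_tied) / n_events
    grad = np.empty_like(grad_sorted)
    grad[order] = grad_sorted
    return float(loss), grad


def _forward(encoder, decoder, risk_head, x):
    latent = encoder.forward(x[:, None, :, :])
    recon = decoder.forward(latent)[:, 0]
    risk = risk_head.forward(latent)[:, 0] if risk_head is not None else None
    return latent, recon, risk


def _train_one(images, surv, config: CAEConfig, rng: np.random.Generator):
    encoder, decoder, risk_head = _build(config, rng)
    modules = [encoder, decoder] + ([risk_head] if risk_head else [])
    opt = Adam(modules, lr=config.learning_rate)
    n = len(images)
    losses = []
    for epoch in range(config.epochs):
        if config.lr_schedule == "cosine":
            opt.lr = config.learning_rate * 0.5 * (
                1.0 + np.cos(np.pi * epoch / max(config.epochs - 1, 1)))
        order = rng.permutation(n)
        ep_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            if len(idx) < 2:
                continue
            xb = images[idx]
            if config.augmentation == "flips":
                flips = rng.integers(0, 2, size=(len(idx), 2)).astype(bool)
                xb = np.stack([im[::-1 if f0 else 1, ::-1 if f1 else 1]
                               for im, (f0, f1) in zip(xb, flips)])
            elif config.augmentation:
                xb = np.stack([augment(im, int(rng.integers(2 ** 31)))
                               for im in xb])
            latent, recon, risk = _forward(encoder, decoder, risk_head, xb)
            resid = recon - xb
            mse = float(np.mean(resid ** 2))
            loss = mse
            g_recon = 2.0 * resid / resid.size
            g_latent_extra = None
            if risk_head is not None:
                t = surv["time"].to_numpy()[idx]
                e = surv["event"].to_numpy()[idx]
                cox_l, g_risk = _cox_loss_grad(risk, t, e)
                loss += config.lambda_prognostic * cox_l
                g_latent_extra = risk_head.backward(
                    (config.lambda_prognostic * g_risk)[:, None])
            g_latent = decoder.backward(g_recon[:, None, :, :])
            if g_latent_extra is not None:
                g_latent = g_latent + g_latent_extra
            encoder.backward(g_latent)
            opt.step()
            opt.zero_grad()
            ep_loss += loss * len(idx)
        losses.append(ep_loss / n)
    return encoder, decoder, risk_head, losses


def train(images, survival=None, config: CAEConfig | None = None) -> TrainedModel:
    """Train the CAE (lambda = 0) or HSCAE (lambda > 0).

    ``images``: (N, H, W) array in [0, 1] at ``config.input_size``.
    ``survival``: frame with ``time``/``event`` columns, required iff
    ``lambda_prognostic > 0``. Runs ``cv_repeats`` random
    leave-``cv_holdout_fraction``-out splits, recording held-out
    reconstruction MSE per repeat, then refits on all images (unless
    ``refit_final`` is off, in which case the last repeat's model is
    kept). Deterministic per config.seed.
    """
    config = config or CAEConfig()
    images = np.asarray(images, float)
    if images.ndim != 3 or images.shape[1:] != tuple(config.input_size):
        raise ValueError("images must be (N, H, W) at config.input_size")
    if images.min() < -1e-9 or images.max() > 1 + 1e-9:
        raise ValueError("intensities must be normalized to [0, 1]")
    if config.lambda_prognostic > 0 and survival is None:
        raise ValueError("survival data required when lambda_prognostic > 0")
    n = len(images)
    ss = np.random.SeedSequence(config.seed)
    child = ss.spawn(config.cv_repeats + 1)
    holdout_mse, repeat_losses = [], []
    last = None
    n_hold = max(1, int(round(n * config.cv_holdout_fraction)))
    for rep in range(config.cv_repeats):
        rng = np.random.default_rng(child[rep])
        perm = rng.permutation(n)
        hold, tr = perm[:n_hold], perm[n_hold:]
        surv_tr = survival.iloc[tr] if survival is not None else None
        enc, dec, rk, losses = _train_one(images[tr], surv_tr, config, rng)
        model = TrainedModel(enc, dec, rk, config,
                             history={"train_loss": losses}, trained=True)
        rep_mse = reconstruction_mse(model, images[hold]).mse
        if not np.isfinite(losses[-1]):
            raise RuntimeError(f"non-finite training loss (history: {losses})")
        holdout_mse.append(rep_mse)
        repeat_losses.append(losses)
        last = model
    if config.refit_final or last is None:
        rng = np.random.default_rng(child[-1])
        enc, dec, rk, losses = _train_one(images, survival, config, rng)
        final = TrainedModel(enc, dec, rk, config, trained=True)
        final.history = {"train_loss": losses}
    else:
        final = last
    final.history["holdout_mse"] = holdout_mse
    final.history["repeat_train_loss"] = repeat_losses
    return final


def _batched_forward(model: TrainedModel, images, chunk: int = 64):
    latents, recons = [], []
    for start in range(0, len(images), chunk):
        xb = np.asarray(images[start:start + chunk], float)
        latent = model.encoder.forward(xb[:, None, :, :])
        recon = model.decoder.forward(latent)[:, 0]
        latents.append(latent)
        recons.append(recon)
    return np.concatenate(latents), np.concatenate(recons)


def reconstruction_mse(model: TrainedModel, images) -> ReconstructionReport:
    """Per-image and aggregate reconstruction MSE on the [0, 1] scale."""
    images = np.asarray(images, float)
    if images.shape[1:] != tuple(model.config.input_size):
        raise ValueError("image shape does not match the model input size")
    _, recon = _batched_forward(model, images)
    per = np.mean((recon - images) ** 2, axis=(1, 2))
    return ReconstructionReport(mse=float(per.mean()), per_subject=per)


def extract_latent(model: TrainedModel, images) -> np.ndarray:
    """Encoder forward pass: (N, latent_dim) deep radiomics features."""
    if not model.trained:
        raise RuntimeError("model is not trained")
    images = np.asarray(images, float)
    latent, _ = _batched_forward(model, images)
    return latent


def save_model(model: TrainedModel, path) -> None:
    """Serialize a trained model (parameters + config) to one .npz file."""
    import dataclasses
    import json
    arrays = {}
    for i, layer in enumerate(model.encoder.layers):
        for name, arr in layer.params.items():
            arrays[f"enc.{i}.{name}"] = arr
    for i, layer in enumerate(model.decoder.layers):
        for name, arr in layer.params.items():
            arrays[f"dec.{i}.{name}"] = arr
    if model.risk_head is not None:
        for name, arr in model.risk_head.params.items():
            arrays[f"risk.{name}"] = arr
    cfg = json.dumps(dataclasses.asdict(model.config))
    np.savez(path, __config__=np.frombuffer(cfg.encode(), dtype=np.uint8),
             **arrays)


def load_model(path) -> TrainedModel:
    """Rebuild a trained model from a checkpoint written by save_model."""
    import json
    data = np.load(path)
    cfg_dict = json.loads(bytes(data["__config__"]).decode())
    for key in ("input_size", "enc_channels"):
        cfg_dict[key] = tuple(cfg_dict[key])
    config = CAEConfig(**cfg_dict)
    encoder, decoder, risk = _build(config, np.random.default_rng(0))
    for i, layer in enumerate(encoder.layers):
        for name in layer.params:
            layer.params[name] = data[f"enc.{i}.{name}"]
    for i, layer in enumerate(decoder.layers):
        for name in layer.params:
            layer.params[name] = data[f"dec.{i}.{name}"]
    if risk is not None:
        for name in risk.params:
            risk.params[name] = data[f"risk.{name}"]
    return TrainedModel(encoder, decoder, risk, config, trained=True)


def class_activation_map(model: TrainedModel, image: np.ndarray) -> np.ndarray:
    """Grad-CAM of the risk head over the last encoder convolution.

    Channel weights are spatial means of the risk gradient; the weighted
    activation sum is rectified and bilinearly upsampled to the input
    size. Only defined for HSCAE models (lambda_prognostic > 0).
    """
    if model.risk_head is None:
        raise ValueError("class activation maps require a prognostic head")
    x = np.asarray(image, float)[None, None, :, :]
    acts = []
    out = x
    for layer in model.encoder.layers:
        out = layer.forward(out)
        acts.append(out)
    last_relu = max(i for i, l in enumerate(model.encoder.layers)
                    if isinstance(l, ReLU))
    latent = out
    model.risk_head.forward(latent)
    g_latent = model.risk_head.backward(np.ones((1, 1)))
    g = model.encoder.backward_from(g_latent, stop_after=last_relu)
    A = acts[last_relu][0]                     # C,h,w
    alpha = g[0].mean(axis=(1, 2))             # C
    cam = np.maximum((alpha[:, None, None] * A).sum(axis=0), 0.0)
    zoomf = (image.shape[0] / cam.shape[0], image.shape[1] / cam.shape[1])
    cam_up = ndimage.zoom(cam, zoomf, order=1)
    return np.maximum(_fit_to_shape(cam_up, image.shape), 0.0)
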