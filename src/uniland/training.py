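"""Loss, augmentation, mixed-domain batch sampling and the training loop.

Training follows the multi-domain recipe: batches are drawn from a mixture
of all registered datasets (each batch homogeneous in domain, domains drawn
proportionally to training-set size), the final fused heatmap is penalized
with soft-label binary cross entropy against the Gaussian target, and the
model with minimum pooled validation loss is kept.  Optimization is Adam
with a cyclic learning rate whose amplitude decays from lr_max to lr_min
over the run.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from ._nn import Adam
from .domains import LandmarkSample, zscore_normalize
from .heatmaps import default_gamma, encode_heatmaps
from .network import GU2Net, save_checkpoint

EPS_CLAMP = 1e-6


@dataclass(frozen=True)
class AugmentConfig:
    """On-the-fly rigid augmentation: with probability ``rotate_prob`` rotate
    by an angle uniform in [-rotate_deg, +rotate_deg]; with probability
    ``translate_prob`` translate by integer offsets uniform in
    [-translate_px, +translate_px] per axis (independent axes)."""

    rotate_deg: float = 2.0
    rotate_prob: float = 0.1
    translate_px: int = 10
    translate_prob: float = 0.1

    def __post_init__(self):
        if not (0 <= self.rotate_prob <= 1 and 0 <= self.translate_prob <= 1):
            raise ValueError("probabilities must be in [0, 1]")


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 4
    epochs: int = 100
    lr_max: float = 1e-2
    lr_min: float = 1e-4
    cycle_epochs: int = 10
    sigma: float = 3.0
    seed: int = 0
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    val_fraction: float = 0.1
    aux_supervision: bool = False  # additionally supervise local/global maps

    def __post_init__(self):
        if not self.lr_min < self.lr_max:
            raise ValueError("lr_min must be < lr_max")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class History:
    train_loss: list = field(default_factory=list)
    val_loss_per_domain: dict = field(default_factory=dict)  # d -> [per-epoch]
    val_loss_pooled: list = field(default_factory=list)
    lr_trace: list = field(default_factory=list)
    best_epoch: int = -1
    aborted: bool = False

    def to_json(self) -> str:
        d = asdict(self)
        d["val_loss_per_domain"] = {str(k): v for k, v in self.val_loss_per_domain.items()}
        return json.dumps(d, indent=1)


# ----------------------------------------------------------------------- loss


def heatmap_bce_loss(prediction, target, with_grad: bool = False):
    """Soft-label binary cross entropy summed over pixels and channels.

    ``prediction``/``target`` are (B, C, H, W) or (C, H, W); the per-image
    pixel sum is averaged over the batch.  Predictions are clamped to
    [eps, 1-eps] before the logs; the gradient is zero where the clamp is
    active.
    """
    p = np.asarray(prediction)
    y = np.asarray(target)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {y.shape}")
    if np.isnan(p).any() or np.isnan(y).any():
        raise ValueError("NaN inputs to the loss")
    if p.ndim == 3:
        p, y = p[None], y[None]
    b = p.shape[0]
    f = np.clip(p, EPS_CLAMP, 1.0 - EPS_CLAMP).astype(np.float64)
    loss = float(-(y * np.log(f) + (1.0 - y) * np.log1p(-f)).sum() / b)
    if not with_grad:
        return loss
    g = (f - y) / (f * (1.0 - f)) / b
    g[(p <= EPS_CLAMP) | (p >= 1.0 - EPS_CLAMP)] = 0.0
    g = g.astype(np.float32)
    if np.asarray(prediction).ndim == 3:
        g = g[0]
    return loss, g


# --------------------------------------------------------------- augmentation


def _rigid_params(rng, config: AugmentConfig):
    theta = 0.0
    if rng.random() < config.rotate_prob:
        theta = math.radians(rng.uniform(-config.rotate_deg, config.rotate_deg))
    tx = ty = 0
    if rng.random() < config.translate_prob:
        tx = int(rng.integers(-config.translate_px, config.translate_px + 1))
        ty = int(rng.integers(-config.translate_px, config.translate_px + 1))
    return theta, tx, ty


def _apply_rigid(sample: LandmarkSample, theta: float, tx: float, ty: float) -> LandmarkSample:
    h, w = sample.height, sample.width
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    cos, sin = math.cos(theta), math.sin(theta)
    # landmark map: p' = R (p - c) + c + t
    pts = sample.landmarks - [cx, cy]
    x = cos * pts[:, 0] - sin * pts[:, 1] + cx + tx
    y = sin * pts[:, 0] + cos * pts[:, 1] + cy + ty
    landmarks = np.stack([x, y], axis=1)
    # image: out(q) = in(R^-1 (q - c - t) + c), in (row, col) order
    m = np.array([[cos, sin], [-sin, cos]])  # R^-1 in (y, x) coordinates
    center = np.array([cy, cx])
    offset = center - m @ (center + [ty, tx])
    image = np.stack(
        [
            ndimage.affine_transform(ch, m, offset=offset, order=1, mode="nearest")
            for ch in sample.image
        ]
    ).astype(np.float32)
    return LandmarkSample(
        domain_id=sample.domain_id,
        image=image,
        landmarks=landmarks,
        spacing=sample.spacing,
        source_id=sample.source_id,
    )


def augment(sample: LandmarkSample, target_stack=None, rng=None, config: AugmentConfig | None = None, max_retries: int = 10):
    """Randomly rotate/translate a sample (and re-encode its target stack).

    Landmarks are transformed by the same rigid map as the image; targets are
    re-encoded from the transformed landmarks rather than warped.  If a draw
    pushes any landmark out of frame the transform is re-drawn (bounded
    retries), degenerating to the identity.
    """
    config = config or AugmentConfig()
    rng = rng if rng is not None else np.random.default_rng()
    out = sample
    for _ in range(max_retries):
        theta, tx, ty = _rigid_params(rng, config)
        if theta == 0.0 and tx == 0 and ty == 0:
            out = sample
            break
        cand = _apply_rigid(sample, theta, tx, ty)
        lm = cand.landmarks
        if (
            (lm[:, 0] >= 0).all()
            and (lm[:, 0] < cand.width).all()
            and (lm[:, 1] >= 0).all()
            and (lm[:, 1] < cand.height).all()
        ):
            out = cand
            break
    else:
        out = sample
    if target_stack is None:
        return out
    new_target = encode_heatmaps(
        out.landmarks,
        (out.height, out.width),
        sigma=target_stack.sigma,
        gamma=target_stack.gamma,
        role="target",
    )
    return out, new_target


# ------------------------------------------------------------ batch sampling


def sample_batches(datasets: dict, batch_size: int, rng):
    """Yield one epoch of homogeneous-domain batches from mixed datasets.

    ``datasets`` maps domain_id -> list of samples.  Each batch's domain is
    drawn with probability proportional to that domain's training-set size;
    within a domain, samples cycle through shuffled queues so every image is
    visited once per epoch in expectation.  Epoch length is
    total_images // batch_size batches (at least 1).
    """
    domains = sorted(d for d, s in datasets.items() if len(s) > 0)
    if not domains:
        raise ValueError("no non-empty datasets")
    sizes = np.array([len(datasets[d]) for d in domains], dtype=float)
    probs = sizes / sizes.sum()
    queues = {d: list(rng.permutation(len(datasets[d]))) for d in domains}
    n_batches = max(1, int(sizes.sum()) // batch_size)
    for _ in range(n_batches):
        d = domains[rng.choice(len(domains), p=probs)]
        q = queues[d]
        while len(q) < batch_size:
            q.extend(rng.permutation(len(datasets[d])))
        idx, queues[d] = q[:batch_size], q[batch_size:]
        yield d, [datasets[d][i] for i in idx]


def cyclic_lr(step: int, total_steps: int, steps_per_cycle: int, lr_min: float, lr_max: float) -> float:
    """Cosine-shaped cycles whose amplitude decays linearly from lr_max to
    lr_min across the run: starts at lr_max, ends at lr_min."""
    frac = step / max(1, total_steps - 1)
    amp = (lr_max - lr_min) * (1.0 - frac)
    c = (step % steps_per_cycle) / max(1, steps_per_cycle)
    return lr_min + amp * (1.0 + math.cos(2.0 * math.pi * c)) / 2.0


# ------------------------------------------------------------------ training


def split_validation(samples, fraction: float, seed: int):
    """Deterministic held-out split (by seed) of a training list."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(samples))
    n_val = max(1, int(round(fraction * len(samples)))) if len(samples) > 1 else 0
    val_idx = set(order[:n_val].tolist())
    train = [s for i, s in enumerate(samples) if i not in val_idx]
    val = [s for i, s in enumerate(samples) if i in val_idx]
    return train, val


def _prep(sample: LandmarkSample) -> LandmarkSample:
    """Z-score the image once, keeping landmarks/spacing untouched."""
    return LandmarkSample(
        domain_id=sample.domain_id,
        image=zscore_normalize(sample.image),
        landmarks=sample.landmarks,
        spacing=sample.spacing,
        source_id=sample.source_id,
    )


def _batch_arrays(samples, sigma):
    x = np.stack([s.image for s in samples]).astype(np.float32)
    gamma = default_gamma(sigma)
    y = np.stack(
        [
            encode_heatmaps(s.landmarks, (s.height, s.width), sigma=sigma, gamma=gamma).values
            for s in samples
        ]
    )
    return x, y


def _snapshot(model: GU2Net):
    params = {(p.tag, p.key): p.data.copy() for p in model.params()}
    bufs = {(bn.tag, bn._key): (bn.run_mean.copy(), bn.run_var.copy()) for bn in model.batchnorms()}
    return params, bufs


def _restore(model: GU2Net, snap):
    params, bufs = snap
    for p in model.params():
        p.data[...] = params[(p.tag, p.key)]
    for bn in model.batchnorms():
        m, v = bufs[(bn.tag, bn._key)]
        bn.set_buffers(m, v)


def validation_loss(model: GU2Net, val_sets: dict, sigma: float, batch_size: int = 4):
    """Per-domain mean per-image loss plus the pooled (sample-weighted) loss."""
    per_domain, pooled_sum, pooled_n = {}, 0.0, 0
    for d in sorted(val_sets):
        samples = val_sets[d]
        if not samples:
            continue
        tot = 0.0
        for i in range(0, len(samples), batch_size):
            chunk = samples[i : i + batch_size]
            x, y = _batch_arrays(chunk, sigma)
            _, _, final = model.forward_batch(x, d, train=False)
            tot += heatmap_bce_loss(final, y) * len(chunk)
        per_domain[d] = tot / len(samples)
        pooled_sum += tot
        pooled_n += len(samples)
    return per_domain, pooled_sum / max(1, pooled_n)


def train(
    model: GU2Net,
    train_sets: dict,
    val_sets: dict | None,
    config: TrainConfig,
    run_dir=None,
    verbose: bool = False,
):
    """Train a model on mixed-domain data; returns (model, History).

    ``train_sets``/``val_sets`` map domain_id -> list of LandmarkSample,
    already resized to the domain's target size (raw intensities; z-score is
    applied here).  If ``val_sets`` is None a fraction of each training list
    is held out deterministically.  The returned model carries the weights of
    the epoch with minimum pooled validation loss; the final checkpoint and
    history are written to ``run_dir`` when given.
    """
    rng = np.random.default_rng(config.seed)
    if val_sets is None:
        split = {d: split_validation(s, config.val_fraction, config.seed + 17 * d) for d, s in train_sets.items()}
        train_sets = {d: tv[0] for d, tv in split.items()}
        val_sets = {d: tv[1] for d, tv in split.items()}
    train_sets = {d: [_prep(s) for s in samples] for d, samples in train_sets.items()}
    val_sets = {d: [_prep(s) for s in samples] for d, samples in val_sets.items()}

    total = sum(len(s) for s in train_sets.values())
    steps_per_epoch = max(1, total // config.batch_size)
    total_steps = steps_per_epoch * config.epochs
    steps_per_cycle = max(1, steps_per_epoch * config.cycle_epochs)
    opt = Adam(model.params())
    hist = History(val_loss_per_domain={d: [] for d in sorted(train_sets)})
    best = (np.inf, -1)
    best_snap = _snapshot(model)
    step = 0
    for epoch in range(config.epochs):
        epoch_loss, nb = 0.0, 0
        for d, batch in sample_batches(train_sets, config.batch_size, rng):
            batch = [augment(s, None, rng, config.augment) for s in batch]
            x, y = _batch_arrays(batch, config.sigma)
            local, glob, final = model.forward_batch(x, d, train=True)
            loss, g = heatmap_bce_loss(final, y, with_grad=True)
            g_loc = g_glob = None
            if config.aux_supervision:
                l_loc, g_loc = heatmap_bce_loss(local, y, with_grad=True)
                l_glob, g_glob = heatmap_bce_loss(glob, y, with_grad=True)
                loss += l_loc + l_glob
            if not np.isfinite(loss):
                hist.aborted = True
                _restore(model, best_snap)
                if verbose:
                    print(f"[uniland] non-finite loss at epoch {epoch}, aborting")
                break
            lr = cyclic_lr(step, total_steps, steps_per_cycle, config.lr_min, config.lr_max)
            hist.lr_trace.append(lr)
            opt.zero_grad()
            model.backward_batch(g, g_local_extra=g_loc, g_global_extra=g_glob)
            opt.step(lr)
            epoch_loss += loss
            nb += 1
            step += 1
        if hist.aborted:
            break
        hist.train_loss.append(epoch_loss / max(1, nb))
        per_dom, pooled = validation_loss(model, val_sets, config.sigma, config.batch_size)
        for d, v in per_dom.items():
            hist.val_loss_per_domain[d].append(v)
        hist.val_loss_pooled.append(pooled)
        if pooled < best[0]:
            best = (pooled, epoch)
            best_snap = _snapshot(model)
        if verbose:
            print(
                f"[uniland] epoch {epoch + 1}/{config.epochs} "
                f"train={hist.train_loss[-1]:.2f} val={pooled:.2f} lr={hist.lr_trace[-1]:.2e}"
            )
    hist.best_epoch = best[1]
    _restore(model, best_snap)
    if run_dir is not None:
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        save_checkpoint(
            model,
            run_dir / "checkpoint.npz",
            epoch=int(hist.best_epoch),
            val_loss=float(best[0]) if np.isfinite(best[0]) else None,
        )
        (run_dir / "history.json").write_text(hist.to_json())
    return model, hist
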