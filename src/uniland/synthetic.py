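"""Seeded generator of visually distinct pseudo-anatomies with exact landmarks.

Each shape family is a parametric 2D figure (a skull-like elliptical ring, a
hand-like fan of digits, a chest-like pair of lobes, a pelvis-like pair of
arches) whose landmarks are *defined analytically* on the geometry before
rasterization, so ground truth is exact real-valued coordinates rather than
points detected in a rendered image.  Every sample applies a per-index random
similarity jitter (scale, rotation, translation) plus additive intensity
noise and a smooth illumination gradient; randomness is counter-based — the
stream is seeded by (config.seed, index) — so any sample is reproducible
independently of generation order.

The default three-domain benchmark (landmark counts 5/9/5, 64x64 images,
200/20/40 train/val/test per domain) is the stand-in for multi-anatomy X-ray
training used throughout the test-suite and experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .domains import (
    DomainRegistry,
    DomainSpec,
    LandmarkSample,
    Spacing,
    SpacingMode,
    load_sample,
    register_domains,
    registry_to_yaml,
    write_landmarks,
)

SHAPE_FAMILIES = ("ellipse_ring", "digit_fan", "twin_lobes", "arch_pair")

# landmark count is intrinsic to each family's geometry
FAMILY_LANDMARKS = {
    "ellipse_ring": 5,
    "digit_fan": 9,
    "twin_lobes": 5,
    "arch_pair": 6,
}


@dataclass(frozen=True)
class SynthDomainConfig:
    name: str
    shape_family: str
    num_landmarks: int
    image_size: tuple[int, int] = (64, 64)  # (W, H), divisible by 16
    scale_jitter: float = 0.10  # +- fraction
    rotation_jitter_deg: float = 10.0
    translation_jitter_px: float = 3.0
    texture_noise_sd: float = 0.05  # intensity units on a [0, 1] image
    n_train: int = 200
    n_val: int = 20
    n_test: int = 40
    seed: int = 0
    domain_id: int = 0
    margin_px: float = 6.0  # 2 * sigma with the default sigma of 3

    def __post_init__(self):
        if self.shape_family not in SHAPE_FAMILIES:
            raise ValueError(f"unknown shape_family {self.shape_family!r}")
        if self.num_landmarks != FAMILY_LANDMARKS[self.shape_family]:
            raise ValueError(
                f"{self.shape_family} defines {FAMILY_LANDMARKS[self.shape_family]} "
                f"landmarks, config says {self.num_landmarks}"
            )
        w, h = self.image_size
        if w % 16 or h % 16:
            raise ValueError("image_size must be divisible by 16")


# ------------------------------------------------------- canonical geometry


def _canonical_landmarks(family: str, w: int, h: int) -> np.ndarray:
    """Closed-form landmark loci of the un-jittered figure, as (x, y)."""
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    if family == "ellipse_ring":
        a, b = 0.30 * w, 0.24 * h
        pts = [(cx + a, cy), (cx - a, cy), (cx, cy - b), (cx, cy + b), (cx, cy)]
    elif family == "digit_fan":
        base = np.array([0.5 * (w - 1), 0.78 * h])
        angles = np.radians([-45.0, -15.0, 15.0, 45.0])
        lengths = np.array([0.30, 0.36, 0.38, 0.32]) * h
        tips = [base + L * np.array([math.sin(a), -math.cos(a)]) for a, L in zip(angles, lengths)]
        mids = [(base + t) / 2.0 for t in tips]
        pts = [tuple(base)] + [tuple(t) for t in tips] + [tuple(m) for m in mids]
    elif family == "twin_lobes":
        off, sx = 0.18 * w, 0.09 * w
        lc = (cx - off, cy)
        rc = (cx + off, cy)
        pts = [lc, rc, (cx - off - 1.5 * sx, cy), (cx + off + 1.5 * sx, cy), (cx, cy)]
    elif family == "arch_pair":
        off = 0.17 * w
        r = 0.13 * min(w, h)
        ay = cy + 0.05 * h
        pts = []
        for s in (-1, 1):
            ax = cx + s * off
            pts.extend([(ax - r, ay), (ax, ay - r), (ax + r, ay)])
    else:  # pragma: no cover
        raise ValueError(family)
    return np.asarray(pts, dtype=np.float64)


def _seg_dist(px, py, a, b):
    """Distance from grid points (px, py) to segment a-b."""
    ax, ay = a
    bx, by = b
    vx, vy = bx - ax, by - ay
    vv = vx * vx + vy * vy
    t = np.clip(((px - ax) * vx + (py - ay) * vy) / max(vv, 1e-12), 0.0, 1.0)
    return np.hypot(px - (ax + t * vx), py - (ay + t * vy))


def _canonical_intensity(family: str, px, py, w: int, h: int) -> np.ndarray:
    """Evaluate the figure's intensity at canonical coordinates (px, py)."""
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    img = np.zeros_like(px)
    if family == "ellipse_ring":
        a, b = 0.30 * w, 0.24 * h
        m = np.sqrt(((px - cx) / a) ** 2 + ((py - cy) / b) ** 2)
        img = 0.9 * np.exp(-(((m - 1.0) * b) ** 2) / (2 * 2.0**2))
        img += 0.35 * np.exp(-(((m - 0.55) * b) ** 2) / (2 * 2.0**2))
    elif family == "digit_fan":
        lms = _canonical_landmarks(family, w, h)
        base = lms[0]
        for tip in lms[1:5]:
            d = _seg_dist(px, py, base, tip)
            img = np.maximum(img, 0.85 * np.exp(-(d**2) / (2 * 1.8**2)))
    elif family == "twin_lobes":
        off, sx, sy = 0.18 * w, 0.09 * w, 0.14 * h
        for s in (-1, 1):
            img += 0.9 * np.exp(
                -(((px - (cx + s * off)) / sx) ** 2 + ((py - cy) / sy) ** 2) / 2.0
            )
        d = _seg_dist(px, py, (cx - off, cy), (cx + off, cy))
        img += 0.3 * np.exp(-(d**2) / (2 * 1.5**2))
    elif family == "arch_pair":
        off = 0.17 * w
        r = 0.13 * min(w, h)
        ay = cy + 0.05 * h
        for s in (-1, 1):
            ax = cx + s * off
            # distance to the upper semicircle: radial distance where the
            # point projects onto the arc, else distance to its endpoints
            dx, dy = px - ax, py - ay
            on_arc = dy <= 0
            d_rad = np.abs(np.hypot(dx, dy) - r)
            d_end = np.minimum(np.hypot(dx - r, dy), np.hypot(dx + r, dy))
            d = np.where(on_arc, d_rad, d_end)
            img = np.maximum(img, 0.85 * np.exp(-(d**2) / (2 * 1.6**2)))
    return img


# ------------------------------------------------------------------ samples


def _draw_jitter(rng, cfg: SynthDomainConfig):
    s = rng.uniform(1.0 - cfg.scale_jitter, 1.0 + cfg.scale_jitter)
    theta = math.radians(rng.uniform(-cfg.rotation_jitter_deg, cfg.rotation_jitter_deg))
    tx = rng.uniform(-cfg.translation_jitter_px, cfg.translation_jitter_px)
    ty = rng.uniform(-cfg.translation_jitter_px, cfg.translation_jitter_px)
    return s, theta, tx, ty


def _transform_points(pts, s, theta, tx, ty, w, h):
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    cos, sin = math.cos(theta), math.sin(theta)
    dx, dy = pts[:, 0] - cx, pts[:, 1] - cy
    x = cx + s * (cos * dx - sin * dy) + tx
    y = cy + s * (sin * dx + cos * dy) + ty
    return np.stack([x, y], axis=1)


def generate_sample(config: SynthDomainConfig, index: int) -> LandmarkSample:
    """Render sample ``index`` of a synthetic domain, bit-reproducibly.

    Jitter draws that would push a landmark within ``margin_px`` of the
    border are re-drawn (bounded retries, then identity jitter).
    """
    if index < 0:
        raise ValueError("index must be >= 0")
    w, h = config.image_size
    rng = np.random.default_rng([config.seed, index])
    canon = _canonical_landmarks(config.shape_family, w, h)
    m = config.margin_px
    jit = (1.0, 0.0, 0.0, 0.0)
    for _ in range(20):
        s, theta, tx, ty = _draw_jitter(rng, config)
        lm = _transform_points(canon, s, theta, tx, ty, w, h)
        if (
            (lm[:, 0] >= m).all()
            and (lm[:, 0] <= w - 1 - m).all()
            and (lm[:, 1] >= m).all()
            and (lm[:, 1] <= h - 1 - m).all()
        ):
            jit = (s, theta, tx, ty)
            break
    else:
        lm = canon.copy()
    s, theta, tx, ty = jit
    landmarks = _transform_points(canon, s, theta, tx, ty, w, h)

    # render by pulling the grid back into canonical coordinates
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    cos, sin = math.cos(-theta), math.sin(-theta)
    ux, uy = (xs - cx - tx) / s, (ys - cy - ty) / s
    px = cx + cos * ux - sin * uy
    py = cy + sin * ux + cos * uy
    img = _canonical_intensity(config.shape_family, px, py, w, h)
    img += 0.08  # background floor
    ga, gb = rng.uniform(-0.08, 0.08, size=2)
    img += ga * (xs / w - 0.5) + gb * (ys / h - 0.5)
    if config.texture_noise_sd > 0:
        img += rng.normal(0.0, config.texture_noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return LandmarkSample(
        domain_id=config.domain_id,
        image=img[None],
        landmarks=landmarks,
        spacing=Spacing.pixel(),
        source_id=f"{config.name}-{index:05d}",
    )


# ---------------------------------------------------------------- benchmark


@dataclass
class Benchmark:
    """A materialized multi-domain synthetic dataset."""

    registry: DomainRegistry
    train: dict
    val: dict
    test: dict
    configs: tuple


def default_benchmark_configs() -> tuple:
    """Three visually distinct pseudo-anatomies with landmark counts 5/9/5."""
    return (
        SynthDomainConfig("pseudo_skull", "ellipse_ring", 5),
        SynthDomainConfig("pseudo_hand", "digit_fan", 9),
        SynthDomainConfig("pseudo_chest", "twin_lobes", 5),
    )


def generate_benchmark(configs=None, seed: int = 0) -> Benchmark:
    """Build a registry plus train/val/test splits for every domain.

    Per-domain generator seeds are derived from ``seed`` with a spawning
    sequence, and sample indices are allocated contiguously
    (train, then val, then test), so the whole benchmark is a pure function
    of (configs, seed).
    """
    if configs is None:
        configs = default_benchmark_configs()
    names = [c.name for c in configs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate domain names: {names}")
    children = np.random.SeedSequence(seed).spawn(len(configs))
    configs = tuple(
        replace(c, domain_id=k, seed=int(children[k].generate_state(1)[0] % (2**31)))
        for k, c in enumerate(configs)
    )
    specs = [
        DomainSpec(
            domain_id=c.domain_id,
            name=c.name,
            num_landmarks=c.num_landmarks,
            target_size=c.image_size,
            spacing_mode=SpacingMode.pixel(),
            split=(c.n_train, c.n_test),
        )
        for c in configs
    ]
    registry = DomainRegistry(specs)
    train, val, test = {}, {}, {}
    for c in configs:
        d = c.domain_id
        train[d] = [generate_sample(c, i) for i in range(c.n_train)]
        val[d] = [generate_sample(c, c.n_train + i) for i in range(c.n_val)]
        test[d] = [generate_sample(c, c.n_train + c.n_val + i) for i in range(c.n_test)]
    return Benchmark(registry, train, val, test, configs)


def write_benchmark(benchmark: Benchmark, out_dir) -> None:
    """Write the benchmark as PNG + CSV files in the loader's layout."""
    from PIL import Image

    out = Path(out_dir)
    registry_to_yaml(benchmark.registry, _ensure_dir(out) / "registry.yaml")
    for split_name, split in (("train", benchmark.train), ("val", benchmark.val), ("test", benchmark.test)):
        for d, samples in split.items():
            spec = benchmark.registry[d]
            folder = _ensure_dir(out / spec.name / split_name)
            for i, s in enumerate(samples):
                arr = np.clip(s.image[0] * 255.0, 0, 255).astype(np.uint8)
                Image.fromarray(arr, mode="L").save(folder / f"img_{i:05d}.png")
                write_landmarks(folder / f"img_{i:05d}.csv", s.landmarks)


def _ensure_dir(p: Path) -> Path:
    p.mkdir(parents=True, exist_ok=True)
    return p


def load_benchmark_dir(data_root):
    """Load a written benchmark (or any dataset in the same layout).

    Layout: ``<root>/registry.yaml`` plus ``<root>/<domain>/<split>/*.png``
    with a same-stem ``.csv`` (or ``.json``) landmark file per image.
    Returns (registry, {split: {domain_id: [samples]}}); missing split
    folders are simply absent from the result.
    """
    root = Path(data_root)
    registry = register_domains(root / "registry.yaml")
    splits = {}
    for split_name in ("train", "val", "test"):
        per_domain = {}
        for spec in registry:
            folder = root / spec.name / split_name
            if not folder.is_dir():
                continue
            samples = []
            for img_path in sorted(folder.glob("*.png")) + sorted(folder.glob("*.jpg")):
                lm_path = img_path.with_suffix(".csv")
                if not lm_path.exists():
                    lm_path = img_path.with_suffix(".json")
                samples.append(load_sample(img_path, lm_path, spec))
            if samples:
                per_domain[spec.domain_id] = samples
        if per_domain:
            splits[split_name] = per_domain
    return registry, splits
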