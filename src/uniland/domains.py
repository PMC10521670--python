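"""Domain registry, sample I/O, resizing and spacing for landmark datasets.

A *domain* is one anatomy/dataset family (e.g. lateral-skull radiographs with
19 cephalometric landmarks).  Every image sample carries its landmark
coordinates in pixel units plus a physical pixel spacing so radial errors can
be reported in millimetres where the acquisition resolution is known.

Coordinate convention (used package-wide): 0-based, x = column, y = row,
pixel centers at integer coordinates.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from PIL import Image

from ._nn import resize_bilinear

PIXEL_UNITS = "px"
MM_UNITS = "mm"


@dataclass(frozen=True)
class Spacing:
    """Physical size of one pixel along x and y, in mm (or unit pixels)."""

    sx: float
    sy: float
    units: str = MM_UNITS

    def __post_init__(self):
        if not (self.sx > 0 and self.sy > 0):
            raise ValueError(f"spacing must be positive, got ({self.sx}, {self.sy})")

    @staticmethod
    def pixel() -> "Spacing":
        return Spacing(1.0, 1.0, PIXEL_UNITS)


@dataclass(frozen=True)
class SpacingMode:
    """How a domain obtains physical spacing.

    kind:
      * ``fixed_mm``   — constant mm-per-pixel from the acquisition protocol
      * ``pixel``      — no physical calibration; errors are reported in px
      * ``wrist_width_mm`` — isotropic spacing inferred per image from an
        assumed anatomical reference width between two landmark endpoints
        (the hand-radiograph convention: a 50 mm wrist between landmarks
        ``endpoints``)
    """

    kind: str
    mm: tuple[float, float] | None = None
    reference_mm: float | None = None
    endpoints: tuple[int, int] | None = None

    def __post_init__(self):
        if self.kind not in ("fixed_mm", "pixel", "wrist_width_mm"):
            raise ValueError(f"unknown spacing kind {self.kind!r}")
        if self.kind == "fixed_mm" and (self.mm is None or len(self.mm) != 2):
            raise ValueError("fixed_mm spacing needs mm=(sx, sy)")
        if self.kind == "wrist_width_mm" and (
            self.reference_mm is None or self.endpoints is None
        ):
            raise ValueError("wrist_width_mm spacing needs reference_mm and endpoints")

    @staticmethod
    def fixed(sx: float, sy: float) -> "SpacingMode":
        return SpacingMode("fixed_mm", mm=(float(sx), float(sy)))

    @staticmethod
    def pixel() -> "SpacingMode":
        return SpacingMode("pixel")

    @staticmethod
    def wrist(reference_mm: float, endpoints: tuple[int, int]) -> "SpacingMode":
        return SpacingMode(
            "wrist_width_mm", reference_mm=float(reference_mm), endpoints=tuple(endpoints)
        )


@dataclass(frozen=True)
class DomainSpec:
    """One registered anatomy/dataset."""

    domain_id: int
    name: str
    num_landmarks: int
    target_size: tuple[int, int]  # (width, height)
    spacing_mode: SpacingMode
    input_channels: int = 1
    split: tuple[int, int] = (0, 0)  # (n_train, n_test)

    def __post_init__(self):
        if self.num_landmarks < 1:
            raise ValueError("num_landmarks must be >= 1")
        w, h = self.target_size
        if w < 16 or h < 16 or w % 16 or h % 16:
            raise ValueError(
                f"target_size {self.target_size} must be >= 16 and divisible by 16 "
                "(the local branch halves resolution four times)"
            )
        if self.input_channels < 1:
            raise ValueError("input_channels must be >= 1")


class DomainRegistry:
    """Immutable ordered collection of :class:`DomainSpec`."""

    def __init__(self, specs: Sequence[DomainSpec]):
        specs = tuple(specs)
        if not specs:
            raise ValueError("registry needs at least one domain")
        ids = [s.domain_id for s in specs]
        if sorted(ids) != list(range(len(specs))):
            raise ValueError(f"domain_ids must be unique and contiguous from 0, got {ids}")
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate domain names in {names}")
        self._specs = tuple(sorted(specs, key=lambda s: s.domain_id))
        self._by_name = {s.name: s for s in self._specs}

    @property
    def t(self) -> int:
        return len(self._specs)

    def __len__(self):
        return len(self._specs)

    def __iter__(self):
        return iter(self._specs)

    def __getitem__(self, key) -> DomainSpec:
        if isinstance(key, str):
            return self._by_name[key]
        return self._specs[key]

    @property
    def total_landmarks(self) -> int:
        return sum(s.num_landmarks for s in self._specs)

    @property
    def total_images(self) -> int:
        return sum(s.split[0] + s.split[1] for s in self._specs)

    @property
    def total_test_images(self) -> int:
        return sum(s.split[1] for s in self._specs)


@dataclass
class LandmarkSample:
    """One image with its landmarks, spacing, and domain tag.

    ``image`` is float32 of shape (channels, height, width); ``landmarks`` is
    float64 of shape (num_landmarks, 2) holding (x, y) pixel coordinates.
    """

    domain_id: int
    image: np.ndarray
    landmarks: np.ndarray
    spacing: Spacing
    source_id: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float32)
        if self.image.ndim == 2:
            self.image = self.image[None]
        self.landmarks = np.asarray(self.landmarks, dtype=np.float64).reshape(-1, 2)
        if np.isnan(self.landmarks).any():
            raise ValueError("NaN landmark coordinates")

    @property
    def height(self) -> int:
        return self.image.shape[1]

    @property
    def width(self) -> int:
        return self.image.shape[2]


# -------------------------------------------------------------------- registry


def _spacing_mode_from_dict(d: Mapping) -> SpacingMode:
    kind = d["spacing_mode"]
    if kind == "fixed_mm":
        return SpacingMode.fixed(*d["spacing_mm"])
    if kind == "pixel":
        return SpacingMode.pixel()
    if kind == "wrist_width_mm":
        return SpacingMode.wrist(d["reference_mm"], tuple(d["endpoints"]))
    raise ValueError(f"unknown spacing_mode {kind!r}")


def register_domains(config) -> DomainRegistry:
    """Build a registry from a mapping, a YAML path, or DomainSpec objects.

    The mapping form is ``{name: {num_landmarks, target_size, spacing_mode,
    ...}}``; ``domain_id`` defaults to declaration order.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)["domains"]
    if isinstance(config, Sequence) and config and isinstance(config[0], DomainSpec):
        return DomainRegistry(config)
    specs = []
    for i, (name, d) in enumerate(config.items()):
        specs.append(
            DomainSpec(
                domain_id=int(d.get("domain_id", i)),
                name=name,
                num_landmarks=int(d["num_landmarks"]),
                target_size=tuple(d["target_size"]),
                spacing_mode=_spacing_mode_from_dict(d),
                input_channels=int(d.get("input_channels", 1)),
                split=tuple(d.get("split", (0, 0))),
            )
        )
    return DomainRegistry(specs)


def registry_to_yaml(registry: DomainRegistry, path) -> None:
    out = {}
    for s in registry:
        d = {
            "domain_id": s.domain_id,
            "num_landmarks": s.num_landmarks,
            "target_size": list(s.target_size),
            "spacing_mode": s.spacing_mode.kind,
            "input_channels": s.input_channels,
            "split": list(s.split),
        }
        if s.spacing_mode.kind == "fixed_mm":
            d["spacing_mm"] = list(s.spacing_mode.mm)
        elif s.spacing_mode.kind == "wrist_width_mm":
            d["reference_mm"] = s.spacing_mode.reference_mm
            d["endpoints"] = list(s.spacing_mode.endpoints)
        out[s.name] = d
    with open(path, "w") as fh:
        yaml.safe_dump({"domains": out}, fh, sort_keys=False)


def builtin_xray_registry() -> DomainRegistry:
    """The four-anatomy X-ray benchmark configuration (specs only, no data).

    head: 400 lateral cephalograms (150 train / 250 test), 19 landmarks,
    0.1 mm isotropic acquisition spacing, resized to 416x512.
    hand: 895 hand radiographs (595/300), 37 landmarks, spacing inferred from
    a 50 mm wrist width between landmarks 1 and 5, resized to 352x512.
    chest: 279 chest radiographs (204/75), 6 lung-contour landmarks, pixel
    units, 512x512.  pelvis: 136 radiographs (100/36), 10 landmarks, pixel
    units, 512x512.
    """
    return register_domains(
        {
            "head": {
                "num_landmarks": 19,
                "target_size": [416, 512],
                "spacing_mode": "fixed_mm",
                "spacing_mm": [0.1, 0.1],
                "split": [150, 250],
            },
            "hand": {
                "num_landmarks": 37,
                "target_size": [352, 512],
                "spacing_mode": "wrist_width_mm",
                "reference_mm": 50.0,
                "endpoints": [0, 4],
                "split": [595, 300],
            },
            "chest": {
                "num_landmarks": 6,
                "target_size": [512, 512],
                "spacing_mode": "pixel",
                "split": [204, 75],
            },
            "pelvis": {
                "num_landmarks": 10,
                "target_size": [512, 512],
                "spacing_mode": "pixel",
                "split": [100, 36],
            },
        }
    )


# ------------------------------------------------------------------ sample IO


def read_landmarks(path) -> np.ndarray:
    """Read landmarks from CSV (header ``x,y``) or JSON ``{"landmarks": ...}``."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            pts = json.load(fh)["landmarks"]
        arr = np.asarray(pts, dtype=np.float64)
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        arr = np.asarray([[r["x"], r["y"]] for r in rows], dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"{path}: expected (n, 2) landmark table, got {arr.shape}")
    return arr


def write_landmarks(path, landmarks) -> None:
    landmarks = np.asarray(landmarks, dtype=float).reshape(-1, 2)
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump({"landmarks": landmarks.tolist()}, fh)
        return
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x", "y"])
        w.writerows(landmarks.tolist())


def load_image(path) -> np.ndarray:
    """Decode an 8/16-bit grayscale PNG/JPEG into (1, H, W) float32."""
    img = Image.open(path)
    if img.mode not in ("L", "I", "I;16", "F"):
        img = img.convert("L")
    arr = np.asarray(img, dtype=np.float32)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel image")
    return arr[None]


def load_sample(image_path, landmark_path, spec: DomainSpec) -> LandmarkSample:
    """Load one image + landmark file against a domain spec.

    The sample is returned at its original resolution; for
    ``wrist_width_mm`` domains the spacing is computed from the image's own
    landmarks via :func:`hand_spacing`.
    """
    image = load_image(image_path)
    landmarks = read_landmarks(landmark_path)
    if len(landmarks) != spec.num_landmarks:
        raise ValueError(
            f"{landmark_path}: {len(landmarks)} landmarks, spec {spec.name!r} "
            f"requires {spec.num_landmarks}"
        )
    mode = spec.spacing_mode
    if mode.kind == "fixed_mm":
        spacing = Spacing(mode.mm[0], mode.mm[1], MM_UNITS)
    elif mode.kind == "wrist_width_mm":
        spacing = hand_spacing(landmarks, mode.reference_mm, mode.endpoints)
    else:
        spacing = Spacing.pixel()
    return LandmarkSample(
        domain_id=spec.domain_id,
        image=image,
        landmarks=landmarks,
        spacing=spacing,
        source_id=str(Path(image_path).stem),
    )


def resize_sample(sample: LandmarkSample, target_size) -> LandmarkSample:
    """Resample to ``target_size=(W, H)``, rescaling coordinates and spacing.

    Coordinates map as x -> x * W_new / W_old (same for y); spacing scales by
    the inverse factors, so physical distances between landmarks are
    preserved exactly.
    """
    w_new, h_new = int(target_size[0]), int(target_size[1])
    w_old, h_old = sample.width, sample.height
    fx, fy = w_new / w_old, h_new / h_old
    image = resize_bilinear(sample.image, (h_new, w_new)).astype(np.float32)
    landmarks = sample.landmarks * np.array([fx, fy])
    oob = (
        (landmarks[:, 0] < 0)
        | (landmarks[:, 0] >= w_new)
        | (landmarks[:, 1] < 0)
        | (landmarks[:, 1] >= h_new)
    )
    if oob.any():
        raise ValueError(f"landmarks {np.flatnonzero(oob).tolist()} fall outside the resized frame")
    spacing = Spacing(sample.spacing.sx / fx, sample.spacing.sy / fy, sample.spacing.units)
    return LandmarkSample(
        domain_id=sample.domain_id,
        image=image,
        landmarks=landmarks,
        spacing=spacing,
        source_id=sample.source_id,
    )


def hand_spacing(landmarks, wrist_width_mm: float, endpoint_indices) -> Spacing:
    """Isotropic mm-per-pixel from an assumed physical wrist width.

    s = wrist_width_mm / ||a - b||2, with a, b the two wrist endpoints taken
    from the landmark list.
    """
    landmarks = np.asarray(landmarks, dtype=float).reshape(-1, 2)
    i, j = endpoint_indices
    a, b = landmarks[i], landmarks[j]
    d = float(np.hypot(*(a - b)))
    if d == 0.0:
        raise ValueError("wrist endpoints coincide; cannot infer spacing")
    s = wrist_width_mm / d
    return Spacing(s, s, MM_UNITS)


def zscore_normalize(image: np.ndarray) -> np.ndarray:
    """Per-image z-score; constant images map to all zeros."""
    image = np.asarray(image, dtype=np.float32)
    mean = image.mean()
    std = image.std()
    if std == 0:
        return np.zeros_like(image)
    return (image - mean) / std
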