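"""Gaussian heatmap codec: landmark coordinates <-> per-landmark heatmaps.

A landmark at x_k is encoded as the map gamma/(2*pi*sigma) *
exp(-||p - x_k||^2 / (2 sigma^2)) over pixel centers p.  With the default
gamma = 2*pi*sigma the prefactor is 1, the peak value is exactly 1, and the
map lives in [0, 1].  Decoding is plain per-channel argmax (first occurrence
in row-major order); local and global predictions are fused by element-wise
multiplication.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_SIGMA = 3.0

ROLES = ("target", "local", "global", "final")


def default_gamma(sigma: float) -> float:
    return 2.0 * np.pi * sigma


@dataclass
class HeatmapStack:
    """num_landmarks x height x width probability maps in [0, 1]."""

    values: np.ndarray
    sigma: float
    gamma: float
    role: str = "target"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("heatmap stack must be (num_landmarks, H, W)")
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}")

    @property
    def num_landmarks(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self):
        return self.values.shape


def encode_heatmaps(
    landmarks,
    shape,
    sigma: float = DEFAULT_SIGMA,
    gamma: float | None = None,
    role: str = "target",
    center: str = "round",
) -> HeatmapStack:
    """Encode landmarks into a Gaussian heatmap stack of (H, W) ``shape``.

    ``center="round"`` (the default for training targets) centers each
    Gaussian on the nearest integer pixel so the channel maximum is exactly
    the peak value; ``center="exact"`` evaluates the Gaussian at the true
    sub-pixel landmark.  Out-of-bounds landmarks are an error — samples are
    validated upstream.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if gamma is None:
        gamma = default_gamma(sigma)
    h, w = int(shape[0]), int(shape[1])
    landmarks = np.asarray(landmarks, dtype=np.float64).reshape(-1, 2)
    if (
        (landmarks[:, 0] < 0).any()
        or (landmarks[:, 0] >= w).any()
        or (landmarks[:, 1] < 0).any()
        or (landmarks[:, 1] >= h).any()
    ):
        raise ValueError("landmark outside the frame; validate the sample first")
    centers = np.rint(landmarks) if center == "round" else landmarks
    xs = np.arange(w, dtype=np.float64)
    ys = np.arange(h, dtype=np.float64)
    amp = gamma / (2.0 * np.pi * sigma)
    maps = np.empty((len(centers), h, w), dtype=np.float32)
    for k, (cx, cy) in enumerate(centers):
        dx2 = (xs - cx) ** 2
        dy2 = (ys - cy) ** 2
        maps[k] = amp * np.exp(-(dy2[:, None] + dx2[None, :]) / (2.0 * sigma**2))
    return HeatmapStack(maps, sigma=sigma, gamma=gamma, role=role)


def decode_landmarks(stack) -> np.ndarray:
    """Per-channel argmax -> (num_landmarks, 2) array of (x, y).

    Ties break to the first occurrence in row-major scan order.
    """
    values = stack.values if isinstance(stack, HeatmapStack) else np.asarray(stack)
    if values.ndim != 3 or values.size == 0:
        raise ValueError("expected a non-empty (num_landmarks, H, W) stack")
    c, h, w = values.shape
    flat = values.reshape(c, -1).argmax(axis=1)
    return np.stack([flat % w, flat // w], axis=1).astype(np.float64)


def fuse(local_stack: HeatmapStack, global_stack: HeatmapStack) -> HeatmapStack:
    """Element-wise product of local and global heatmaps (the final map)."""
    if local_stack.shape != global_stack.shape:
        raise ValueError(
            f"shape mismatch: {local_stack.shape} vs {global_stack.shape}"
        )
    return HeatmapStack(
        local_stack.values * global_stack.values,
        sigma=local_stack.sigma,
        gamma=local_stack.gamma,
        role="final",
    )


def save_stack(stack: HeatmapStack, path) -> None:
    """Export a stack for inspection: .tif (multi-page float32) or .npz."""
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, stack.values, photometric="minisblack")
    else:
        np.savez_compressed(
            path, values=stack.values, sigma=stack.sigma, gamma=stack.gamma, role=stack.role
        )


def load_stack(path) -> HeatmapStack:
    path = str(path)
    if path.endswith((".tif", ".tiff")):
        import tifffile

        return HeatmapStack(tifffile.imread(path), sigma=DEFAULT_SIGMA, gamma=default_gamma(DEFAULT_SIGMA))
    with np.load(path) as z:
        return HeatmapStack(
            z["values"], sigma=float(z["sigma"]), gamma=float(z["gamma"]), role=str(z["role"])
        )
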