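"""GU2Net: a universal landmark detector shared across anatomies.

Two branches. The *local* branch is a U-shaped encoder/decoder in which
every convolution is depth-wise separable: a domain-specific channel-wise
3x3 convolution (one replica per registered anatomy, selected by domain id
at run time) followed by a domain-shared point-wise 1x1 convolution — the
mechanism that lets one network keep private appearance filters per anatomy
while learning cross-anatomy "common knowledge" in the shared 1x1 weights.
The *global* branch is a per-domain stack of five dilated 3x3 convolutions
(dilations 1, 2, 5, 2, 1) run at quarter resolution on the downsampled image
together with the local heatmap, capturing coarse structural context.  The
final prediction is the element-wise product of the two branches' heatmaps.

Parameter economy: a separable block with t domains, N input and M output
channels costs 9*t*N + N*M weights versus 9*t*N*M for t standard 3x3
convolutions.

Ablation variants: ``local_only`` (global map identically one),
``global_only`` (no local branch; its input heatmap is identically one) and
``unet_baseline`` (standard convolutions, one shared trunk, one output head
covering the union of all domains' landmark channels).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
import numpy as np

from ._nn import (
    SHARED,
    BatchNorm2d,
    Conv3x3,
    DepthwiseConv3x3,
    LeakyReLU,
    MaxPool2x2,
    PointwiseConv,
    ReLU,
    Sigmoid,
    UpsampleNearest2x,
    _bilinear_matrix,
)
from .heatmaps import DEFAULT_SIGMA, HeatmapStack, default_gamma

VARIANTS = ("gu2net", "local_only", "global_only", "unet_baseline")

DEFAULT_ENCODER_WIDTHS = (64, 128, 256, 512)
DEFAULT_GLOBAL_WIDTH = 160
DEFAULT_DILATIONS = (1, 2, 5, 2, 1)


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters.

    ``domains`` lists (domain_id, input_channels, num_landmarks) triples;
    ``fusion_input_mode`` selects how the global branch combines the
    downsampled image with the local heatmap ("cat" concatenates channels,
    "add" adds after a per-domain 1x1 projection).
    """

    domains: tuple
    encoder_widths: tuple = DEFAULT_ENCODER_WIDTHS
    downsample_steps: int = 4
    global_dilations: tuple = DEFAULT_DILATIONS
    global_width: int = DEFAULT_GLOBAL_WIDTH
    global_kernel: int = 3
    fusion_input_mode: str = "cat"
    variant: str = "gu2net"
    sigma: float = DEFAULT_SIGMA
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "domains", tuple(tuple(d) for d in self.domains))
        object.__setattr__(self, "encoder_widths", tuple(self.encoder_widths))
        object.__setattr__(self, "global_dilations", tuple(self.global_dilations))
        if not self.domains:
            raise ValueError("at least one domain required")
        if any(d < 1 for d in self.global_dilations):
            raise ValueError("dilations must be >= 1")
        w = self.encoder_widths
        if any(a >= b for a, b in zip(w, w[1:])):
            raise ValueError("encoder_widths must be strictly increasing")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.fusion_input_mode not in ("cat", "add"):
            raise ValueError("fusion_input_mode must be 'cat' or 'add'")

    @staticmethod
    def for_registry(registry, **kw) -> "NetworkConfig":
        doms = tuple((s.domain_id, s.input_channels, s.num_landmarks) for s in registry)
        return NetworkConfig(domains=doms, **kw)


def count_separable_params(t: int, n: int, m: int) -> int:
    """Weights of one depth-wise separable block replicated over t domains:
    9*t*n channel-wise + n*m point-wise (biases/normalization not included)."""
    if t < 1 or n < 1 or m < 1:
        raise ValueError("t, N, M must be >= 1")
    return 9 * t * n + n * m


def count_standard_params(t: int, n: int, m: int) -> int:
    """Weights of t parallel standard 3x3 convolutions: 9*t*n*m."""
    if t < 1 or n < 1 or m < 1:
        raise ValueError("t, N, M must be >= 1")
    return 9 * t * n * m


# ------------------------------------------------------------------- blocks


class SeparableBlock:
    """Per-domain DW 3x3 -> BN -> LReLU -> shared PW 1x1 -> BN -> LReLU."""

    def __init__(self, rng, domain_ids, c_in, c_out, key):
        self.c_in, self.c_out = c_in, c_out
        self.dw = {d: DepthwiseConv3x3(rng, c_in, f"{key}.dw", tag=d) for d in domain_ids}
        self.bnd = {d: BatchNorm2d(c_in, f"{key}.bnd", tag=d) for d in domain_ids}
        self.pw = PointwiseConv(rng, c_in, c_out, f"{key}.pw", tag=SHARED)
        self.bns = BatchNorm2d(c_out, f"{key}.bns", tag=SHARED)
        self.act1, self.act2 = LeakyReLU(), LeakyReLU()
        for d in domain_ids:
            self.bnd[d].tag = d
        self.bns.tag = SHARED

    def layers(self):
        return (
            list(self.dw.values()) + list(self.bnd.values()) + [self.pw, self.bns]
        )

    def forward(self, x, d, train=False):
        self._d = d
        h = self.dw[d].forward(x, train)
        h = self.bnd[d].forward(h, train)
        h = self.act1.forward(h, train)
        h = self.pw.forward(h, train)
        h = self.bns.forward(h, train)
        return self.act2.forward(h, train)

    def backward(self, gy):
        d = self._d
        g = self.act2.backward(gy)
        g = self.bns.backward(g)
        g = self.pw.backward(g)
        g = self.act1.backward(g)
        g = self.bnd[d].backward(g)
        return self.dw[d].backward(g)


class StandardBlock:
    """Standard 3x3 conv -> BN -> LReLU (U-Net baseline building block)."""

    def __init__(self, rng, c_in, c_out, key):
        self.c_in, self.c_out = c_in, c_out
        self.conv = Conv3x3(rng, c_in, c_out, f"{key}.conv", tag=SHARED)
        self.bn = BatchNorm2d(c_out, f"{key}.bn", tag=SHARED)
        self.bn.tag = SHARED
        self.act = LeakyReLU()

    def layers(self):
        return [self.conv, self.bn]

    def forward(self, x, d, train=False):
        return self.act.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, gy):
        return self.conv.backward(self.bn.backward(self.act.backward(gy)))


class LocalUNet:
    """U-shaped trunk: double-conv encoder levels, double-conv bottleneck
    capped at the deepest width, single-conv decoder levels, per-domain
    point-wise output heads squashed into (0, 1)."""

    def __init__(self, rng, config: NetworkConfig, separable: bool):
        widths = config.encoder_widths
        self.n_levels = len(widths)
        self.separable = separable
        dom = {d: (c, l) for d, c, l in config.domains}
        self.domain_ids = sorted(dom)
        c_in = config.domains[0][1]
        if any(c != c_in for _, c, _ in config.domains):
            raise ValueError("all domains must share input_channels in one trunk")

        def block(ci, co, key):
            if separable:
                return SeparableBlock(rng, self.domain_ids, ci, co, key)
            return StandardBlock(rng, ci, co, key)

        self.enc = []
        prev = c_in
        for l, w in enumerate(widths):
            self.enc.append([block(prev, w, f"local.enc{l}a"), block(w, w, f"local.enc{l}b")])
            prev = w
        self.pools = [MaxPool2x2() for _ in widths]
        wb = widths[-1]
        self.bott = [block(wb, wb, "local.botta"), block(wb, wb, "local.bottb")]
        self.ups = [UpsampleNearest2x() for _ in widths]
        self.dec = []
        for l, w in enumerate(widths):
            up_c = widths[l + 1] if l + 1 < len(widths) else wb
            self.dec.append(block(up_c + w, w, f"local.dec{l}"))
        if separable:
            self.heads = {
                d: PointwiseConv(rng, widths[0], dom[d][1], "local.head", tag=d)
                for d in self.domain_ids
            }
        else:
            total = sum(l for _, _, l in config.domains)
            self.union_head = PointwiseConv(rng, widths[0], total, "local.head", tag=SHARED)
            self._head_slices = {}
            off = 0
            for d, _, l in sorted(config.domains):
                self._head_slices[d] = slice(off, off + l)
                off += l
        self.out_act = Sigmoid()

    def blocks(self):
        out = []
        for lvl in self.enc:
            out.extend(lvl)
        out.extend(self.bott)
        out.extend(self.dec)
        return out

    def layers(self):
        out = []
        for b in self.blocks():
            out.extend(b.layers())
        if self.separable:
            out.extend(self.heads.values())
        else:
            out.append(self.union_head)
        return out

    def forward(self, x, d, train=False):
        self._d = d
        skips = []
        h = x
        for l in range(self.n_levels):
            h = self.enc[l][0].forward(h, d, train)
            h = self.enc[l][1].forward(h, d, train)
            skips.append(h)
            h = self.pools[l].forward(h, train)
        h = self.bott[0].forward(h, d, train)
        h = self.bott[1].forward(h, d, train)
        self._split = []
        for l in range(self.n_levels - 1, -1, -1):
            h = self.ups[l].forward(h, train)
            self._split.append(h.shape[1])
            h = np.concatenate([h, skips[l]], axis=1)
            h = self.dec[l].forward(h, d, train)
        if self.separable:
            z = self.heads[d].forward(h, train)
        else:
            z = self.union_head.forward(h, train)
            self._full_shape = z.shape
            z = z[:, self._head_slices[d]]
        return self.out_act.forward(z, train)

    def backward(self, gy):
        d = self._d
        g = self.out_act.backward(gy)
        if self.separable:
            g = self.heads[d].backward(g)
        else:
            gfull = np.zeros(self._full_shape, dtype=np.float32)
            gfull[:, self._head_slices[d]] = g
            g = self.union_head.backward(gfull)
        # forward decoder order was l = n-1 .. 0, so backward walks l = 0 .. n-1
        g_skip = {}
        for l in range(self.n_levels):
            g = self.dec[l].backward(g)
            n_up = self._split[self.n_levels - 1 - l]
            g_up, g_sk = g[:, :n_up], g[:, n_up:]
            g_skip[l] = g_sk
            g = self.ups[l].backward(g_up)
        g = self.bott[1].backward(g)
        g = self.bott[0].backward(g)
        for l in range(self.n_levels - 1, -1, -1):
            g = self.pools[l].backward(g)
            g = g + g_skip[l]
            g = self.enc[l][1].backward(g)
            g = self.enc[l][0].backward(g)
        return g


class GlobalBranch:
    """Per-domain dilated-convolution context network at 1/4 resolution."""

    def __init__(self, rng, config: NetworkConfig, domain_id, c_img, c_lm):
        d = domain_id
        g = config.global_width
        self.mode = config.fusion_input_mode
        self.c_img, self.c_lm = c_img, c_lm
        if self.mode == "add":
            self.proj = PointwiseConv(rng, c_lm, c_img, "global.proj", tag=d)
            c_in = c_img
        else:
            self.proj = None
            c_in = c_img + c_lm
        dil = config.global_dilations
        widths = [c_in] + [g] * (len(dil) - 1) + [c_lm]
        self.convs, self.bns, self.acts = [], [], []
        for k, dl in enumerate(dil):
            conv = Conv3x3(rng, widths[k], widths[k + 1], f"global.conv{k}", tag=d, dilation=dl)
            self.convs.append(conv)
            if k < len(dil) - 1:
                bn = BatchNorm2d(widths[k + 1], f"global.bn{k}", tag=d)
                bn.tag = d
                self.bns.append(bn)
                self.acts.append(ReLU())
        self.out_act = Sigmoid()

    def layers(self):
        out = list(self.convs) + list(self.bns)
        if self.proj is not None:
            out.append(self.proj)
        return out

    def forward(self, img, local_map, train=False):
        b, _, h, w = img.shape
        self._hw = (h, w)
        h4, w4 = h // 4, w // 4
        self._rh = _bilinear_matrix(h, h4)
        self._rw = _bilinear_matrix(w, w4)
        img4 = np.matmul(np.matmul(self._rh, img), self._rw.T)
        loc4 = np.matmul(np.matmul(self._rh, local_map), self._rw.T)
        if self.mode == "add":
            z = img4 + self.proj.forward(loc4, train)
        else:
            z = np.concatenate([img4, loc4], axis=1)
        hcur = z
        for k, conv in enumerate(self.convs):
            hcur = conv.forward(hcur, train)
            if k < len(self.bns):
                hcur = self.bns[k].forward(hcur, train)
                hcur = self.acts[k].forward(hcur, train)
        hcur = self.out_act.forward(hcur, train)
        rhu = _bilinear_matrix(h4, h)
        rwu = _bilinear_matrix(w4, w)
        self._rhu, self._rwu = rhu, rwu
        return np.matmul(np.matmul(rhu, hcur), rwu.T)

    def backward(self, gy):
        """Returns the gradient w.r.t. the full-resolution local heatmap."""
        g = np.matmul(np.matmul(self._rhu.T, gy), self._rwu)
        g = self.out_act.backward(g)
        for k in range(len(self.convs) - 1, -1, -1):
            if k < len(self.bns):
                g = self.acts[k].backward(g)
                g = self.bns[k].backward(g)
            g = self.convs[k].backward(g)
        if self.mode == "add":
            g_loc4 = self.proj.backward(g)
        else:
            g_loc4 = g[:, self.c_img :]
        return np.matmul(np.matmul(self._rh.T, g_loc4), self._rw)


# -------------------------------------------------------------------- model


class GU2Net:
    """The assembled model (or one of its ablation variants)."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.domain_ids = sorted(d for d, _, _ in config.domains)
        self._dom = {d: (c, l) for d, c, l in config.domains}
        v = config.variant
        self.local = None
        self.globals_ = {}
        if v in ("gu2net", "local_only"):
            self.local = LocalUNet(rng, config, separable=True)
        elif v == "unet_baseline":
            self.local = LocalUNet(rng, config, separable=False)
        if v in ("gu2net", "global_only"):
            for d in self.domain_ids:
                c_img, c_lm = self._dom[d]
                self.globals_[d] = GlobalBranch(rng, config, d, c_img, c_lm)
        self._params = self._collect_params()

    # -- parameters ------------------------------------------------------

    def _all_layers(self):
        out = []
        if self.local is not None:
            out.extend(self.local.layers())
        for d in sorted(self.globals_):
            out.extend(self.globals_[d].layers())
        return out

    def _collect_params(self):
        seen, out = set(), []
        for layer in self._all_layers():
            for p in layer.params():
                if id(p) not in seen:
                    seen.add(id(p))
                    out.append(p)
        return out

    def params(self):
        return list(self._params)

    def num_params(self) -> int:
        return sum(p.size for p in self._params)

    def batchnorms(self):
        from ._nn import BatchNorm2d as _BN

        return [l for l in self._all_layers() if isinstance(l, _BN)]

    def zero_grad(self):
        for p in self._params:
            p.grad[...] = 0

    # -- forward / backward ---------------------------------------------

    def _check(self, x, domain_id):
        if domain_id not in self._dom:
            raise KeyError(
                f"unknown domain_id {domain_id}: this model holds no domain-specific "
                f"parameters for it (known: {self.domain_ids})"
            )
        if x.shape[-2] % 16 or x.shape[-1] % 16:
            raise ValueError(f"spatial size {x.shape[-2:]} must be divisible by 16")

    def forward_batch(self, x, domain_id, train=False):
        """x: (B, C_in, H, W) -> (local, global, final) arrays (B, C'_d, H, W)."""
        self._check(x, domain_id)
        x = np.ascontiguousarray(x, dtype=np.float32)
        self._d = domain_id
        v = self.config.variant
        b, _, h, w = x.shape
        c_lm = self._dom[domain_id][1]
        ones = None
        if v in ("gu2net", "local_only", "unet_baseline"):
            local = self.local.forward(x, domain_id, train)
        else:
            local = np.ones((b, c_lm, h, w), dtype=np.float32)
        if v in ("gu2net", "global_only"):
            glob = self.globals_[domain_id].forward(x, local, train)
        else:
            glob = np.ones_like(local)
        final = local * glob
        self._local, self._glob = local, glob
        return local, glob, final

    def backward_batch(self, g_final, g_local_extra=None, g_global_extra=None):
        """Accumulate parameter gradients from d(loss)/d(final heatmap).

        ``g_local_extra``/``g_global_extra`` carry gradients of optional
        auxiliary losses applied directly to the branch heatmaps.
        """
        v = self.config.variant
        g_local = None
        if v in ("gu2net", "global_only"):
            g_glob = g_final * self._local
            if g_global_extra is not None:
                g_glob = g_glob + g_global_extra
            g_loc_from_glob = self.globals_[self._d].backward(g_glob)
            if v == "gu2net":
                g_local = g_final * self._glob + g_loc_from_glob
        else:
            g_local = g_final * self._glob
        if g_local is not None and g_local_extra is not None:
            g_local = g_local + g_local_extra
        if g_local is not None and self.local is not None:
            self.local.backward(np.ascontiguousarray(g_local, dtype=np.float32))

    def forward(self, image, domain_id):
        """Single-image inference -> (local, global, final) HeatmapStacks."""
        image = np.asarray(image, dtype=np.float32)
        if image.ndim == 2:
            image = image[None]
        local, glob, final = self.forward_batch(image[None], domain_id, train=False)
        sig, gam = self.config.sigma, default_gamma(self.config.sigma)
        return (
            HeatmapStack(local[0], sig, gam, role="local"),
            HeatmapStack(glob[0], sig, gam, role="global"),
            HeatmapStack(final[0], sig, gam, role="final"),
        )


def build_local_network(config: NetworkConfig) -> GU2Net:
    cfg = NetworkConfig(**{**asdict(config), "variant": "local_only"})
    return GU2Net(cfg)


def build_global_network(config: NetworkConfig) -> GU2Net:
    cfg = NetworkConfig(**{**asdict(config), "variant": "global_only"})
    return GU2Net(cfg)


def build_unet_baseline(config: NetworkConfig) -> GU2Net:
    cfg = NetworkConfig(**{**asdict(config), "variant": "unet_baseline"})
    return GU2Net(cfg)


# ------------------------------------------------------- partition and swap


@dataclass
class ParamPartition:
    """Disjoint, exhaustive split of parameters into shared vs per-domain."""

    shared: list
    per_domain: dict
    n_shared: int
    n_per_domain: dict
    total: int

    @property
    def total_millions(self) -> float:
        return self.total / 1e6


def partition_params(model: GU2Net) -> ParamPartition:
    shared, per_domain = [], {d: [] for d in model.domain_ids}
    seen = set()
    for p in model.params():
        if id(p) in seen:
            raise RuntimeError(f"parameter {p.key} reachable twice")
        seen.add(id(p))
        if p.tag == SHARED:
            shared.append(p)
        else:
            per_domain[p.tag].append(p)
    n_pd = {d: sum(p.size for p in ps) for d, ps in per_domain.items()}
    n_sh = sum(p.size for p in shared)
    total = n_sh + sum(n_pd.values())
    if total != model.num_params():
        raise RuntimeError("partition does not cover all trainable parameters")
    return ParamPartition(shared, per_domain, n_sh, n_pd, total)


def swap_domain_params(model: GU2Net, i: int, j: int, strict: bool = False):
    """Exchange the domain-specific parameters (and batch-norm statistics)
    of domains ``i`` and ``j`` in place.

    Sites whose shapes differ between the two domains (output heads and the
    global branch's first/last convolutions when landmark counts differ) are
    left untouched and reported; ``strict=True`` raises instead.  Returns
    ``(model, skipped_keys)``.  Swapping twice restores the model bit-exactly.
    """
    if i not in model._dom or j not in model._dom:
        raise KeyError(f"unknown domain in swap ({i}, {j})")
    skipped = []
    if i == j:
        return model, skipped
    part = partition_params(model)
    by_key_i = {p.key: p for p in part.per_domain[i]}
    by_key_j = {p.key: p for p in part.per_domain[j]}
    if set(by_key_i) != set(by_key_j):
        raise RuntimeError("per-domain parameter sites differ between domains")
    for key in sorted(by_key_i):
        pi, pj = by_key_i[key], by_key_j[key]
        if pi.data.shape != pj.data.shape:
            if strict:
                raise ValueError(f"shape mismatch at {key}: {pi.data.shape} vs {pj.data.shape}")
            skipped.append(key)
            continue
        pi.data, pj.data = pj.data, pi.data
    bns_i = {bn._key: bn for bn in model.batchnorms() if bn.tag == i}
    bns_j = {bn._key: bn for bn in model.batchnorms() if bn.tag == j}
    for key in sorted(bns_i):
        bi, bj = bns_i[key], bns_j.get(key)
        if bj is None or bi.run_mean.shape != bj.run_mean.shape:
            continue
        bi.run_mean, bj.run_mean = bj.run_mean, bi.run_mean
        bi.run_var, bj.run_var = bj.run_var, bi.run_var
    return model, skipped


# ---------------------------------------------------------------- checkpoint


def save_checkpoint(model: GU2Net, path, **manifest_extra) -> None:
    """Write a single-archive checkpoint: weights, batch-norm statistics and
    a JSON manifest (config + domain table) so the file is introspectable."""
    arrays = {}
    for p in model.params():
        arrays[f"param|{p.tag}|{p.key}"] = p.data
    for bn in model.batchnorms():
        arrays[f"buffer|{bn.tag}|{bn._key}.run_mean"] = bn.run_mean
        arrays[f"buffer|{bn.tag}|{bn._key}.run_var"] = bn.run_var
    manifest = {"config": asdict(model.config), **manifest_extra}
    arrays["manifest"] = np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path, model: GU2Net | None = None):
    """Rebuild (or repopulate) a model from a checkpoint archive.

    Returns ``(model, manifest)``.
    """
    with np.load(path) as z:
        manifest = json.loads(bytes(z["manifest"].tobytes()).decode())
        if model is None:
            cfg = manifest["config"]
            model = GU2Net(NetworkConfig(**cfg))
        for p in model.params():
            p.data[...] = z[f"param|{p.tag}|{p.key}"]
        for bn in model.batchnorms():
            bn.set_buffers(
                z[f"buffer|{bn.tag}|{bn._key}.run_mean"],
                z[f"buffer|{bn.tag}|{bn._key}.run_var"],
            )
    return model, manifest
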