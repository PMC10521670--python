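"""Radial-error metrics (MRE/SDR) and the cross-anatomy experiment harnesses.

MRE is the mean Euclidean distance between predicted and true landmarks
pooled over all (image, landmark) pairs; SDR(k) is the fraction of those
distances *strictly* below a threshold k, reported in percent.  Distances
are computed on spacing-scaled coordinate differences, so anisotropic
mm-per-pixel spacing is applied per axis before the norm; pixel-mode domains
use unit spacing.  The reported standard deviation is the population one
(divide by N).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .domains import Spacing, zscore_normalize
from .heatmaps import decode_landmarks
from .network import GU2Net, NetworkConfig, swap_domain_params

#: reporting grids used for the four X-ray anatomies (threshold units follow
#: each domain's spacing mode)
DEFAULT_THRESHOLDS = {
    "head": (2.0, 3.0, 4.0),  # mm
    "hand": (2.0, 4.0, 10.0),  # mm
    "chest": (3.0, 6.0, 9.0),  # px
    "pelvis": (3.0, 6.0, 9.0),  # px
}


@dataclass
class EvalResult:
    errors: np.ndarray  # per (image, landmark) radial error
    mre: float
    std: float
    sdr: dict  # threshold -> percent
    n: int
    units: str

    def summary(self) -> str:
        sdr = ", ".join(f"SDR<{k:g}: {v:.2f}%" for k, v in self.sdr.items())
        return f"MRE {self.mre:.3f} ± {self.std:.3f} {self.units} (n={self.n}); {sdr}"


def radial_errors(predicted, truth, spacing: Spacing) -> np.ndarray:
    """Per-landmark ||(dx * sx, dy * sy)||2 with dx, dy in pixels."""
    predicted = np.asarray(predicted, dtype=float).reshape(-1, 2)
    truth = np.asarray(truth, dtype=float).reshape(-1, 2)
    if predicted.shape != truth.shape:
        raise ValueError(f"landmark count mismatch: {predicted.shape} vs {truth.shape}")
    delta = (predicted - truth) * [spacing.sx, spacing.sy]
    return np.hypot(delta[:, 0], delta[:, 1])


def mre(errors) -> tuple[float, float]:
    """Arithmetic mean and population standard deviation of radial errors."""
    errors = np.asarray(errors, dtype=float).ravel()
    if errors.size == 0:
        raise ValueError("empty error list")
    return float(errors.mean()), float(errors.std())


def sdr(errors, thresholds) -> dict:
    """Fraction of errors strictly below each threshold, in percent."""
    errors = np.asarray(errors, dtype=float).ravel()
    out = {}
    for k in thresholds:
        out[float(k)] = float(100.0 * (errors < k).mean()) if errors.size else 0.0
    return out


def _eval_from_errors(errors: np.ndarray, thresholds, units: str) -> EvalResult:
    m, s = mre(errors)
    return EvalResult(errors=errors, mre=m, std=s, sdr=sdr(errors, thresholds), n=errors.size, units=units)


def evaluate(model: GU2Net, test_set, thresholds=(3.0, 6.0, 9.0), batch_size: int = 8) -> EvalResult:
    """Forward -> decode final heatmap -> radial errors for one domain's
    test set.  Deterministic given a checkpoint."""
    if not test_set:
        raise ValueError("empty test set")
    d = test_set[0].domain_id
    units = test_set[0].spacing.units
    all_err = []
    for i in range(0, len(test_set), batch_size):
        chunk = test_set[i : i + batch_size]
        x = np.stack([zscore_normalize(s.image) for s in chunk])
        _, _, final = model.forward_batch(x, d, train=False)
        for s, maps in zip(chunk, final):
            pred = decode_landmarks(maps)
            all_err.append(radial_errors(pred, s.landmarks, s.spacing))
    return _eval_from_errors(np.concatenate(all_err), thresholds, units)


def pooled(results) -> EvalResult:
    """Pool per-domain results over all (image, landmark) pairs.

    Equals the sample-weighted average of the per-domain metrics; units are
    'mixed' if the domains disagree."""
    results = list(results)
    if not results:
        raise ValueError("nothing to pool")
    units = {r.units for r in results}
    errors = np.concatenate([r.errors for r in results])
    thresholds = list(results[0].sdr)
    return _eval_from_errors(errors, thresholds, units.pop() if len(units) == 1 else "mixed")


def cross_anatomy_matrix(model: GU2Net, test_sets: dict, thresholds=(3.0, 6.0, 9.0)) -> np.ndarray:
    """t x t MRE matrix: entry (i, j) evaluates domain j's test set with
    domain i's domain-specific parameters installed in domain j's slot.

    The diagonal is the matched evaluation; each off-diagonal entry swaps
    the two domains' private parameters, evaluates, and swaps back (so the
    model is restored bit-exactly).  Sites with incompatible shapes between
    the two domains (heads for unequal landmark counts) stay unswapped.
    """
    ids = sorted(test_sets)
    t = len(ids)
    out = np.full((t, t), np.nan)
    for a, i in enumerate(ids):
        for b, j in enumerate(ids):
            if i == j:
                out[a, b] = evaluate(model, test_sets[j], thresholds).mre
                continue
            swap_domain_params(model, i, j)
            try:
                out[a, b] = evaluate(model, test_sets[j], thresholds).mre
            finally:
                swap_domain_params(model, i, j)
    return out


def domain_count_sweep(
    benchmark,
    subset_sizes,
    train_config,
    network_kwargs=None,
    thresholds=(3.0, 6.0, 9.0),
    max_combos: int | None = None,
):
    """Train on every s-sized domain subset containing each probe domain and
    report the probe's test metrics averaged over subsets.

    Mirrors the domain-count protocol: for subset size s and probe domain p,
    models are trained from scratch on each s-subset that includes p,
    evaluated on p's test set, and averaged.  ``max_combos`` caps the number
    of subsets per (probe, s) for budget control.  Returns a list of rows
    ``{probe, size, mre, std, sdr, n_runs}``.
    """
    from itertools import combinations

    from .training import train

    network_kwargs = dict(network_kwargs or {})
    all_ids = sorted(benchmark.train)
    spec_by_id = {s.domain_id: s for s in benchmark.registry}
    rows = []
    for s_size in subset_sizes:
        if s_size > len(all_ids):
            raise ValueError(f"subset size {s_size} exceeds domain count {len(all_ids)}")
        for probe in all_ids:
            combos = [c for c in combinations(all_ids, s_size) if probe in c]
            if max_combos is not None:
                combos = combos[:max_combos]
            mres, stds, sdrs = [], [], []
            for combo in combos:
                doms = tuple(
                    (d, spec_by_id[d].input_channels, spec_by_id[d].num_landmarks) for d in combo
                )
                model = GU2Net(NetworkConfig(domains=doms, **network_kwargs))
                model, _ = train(
                    model,
                    {d: benchmark.train[d] for d in combo},
                    {d: benchmark.val[d] for d in combo},
                    train_config,
                )
                res = evaluate(model, benchmark.test[probe], thresholds)
                mres.append(res.mre)
                stds.append(res.std)
                sdrs.append(res.sdr)
            rows.append(
                {
                    "probe": probe,
                    "size": s_size,
                    "mre": float(np.mean(mres)),
                    "std": float(np.mean(stds)),
                    "sdr": {k: float(np.mean([s[k] for s in sdrs])) for k in sdrs[0]},
                    "n_runs": len(combos),
                }
            )
    return rows
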