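import dataclasses

import numpy as np
import pytest

from uniland import (
    GU2Net,
    NetworkConfig,
    SynthDomainConfig,
    generate_benchmark,
)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Two-domain config small enough for per-test forward/backward passes."""
    return NetworkConfig(
        domains=((0, 1, 3), (1, 1, 5)),
        encoder_widths=(4, 6, 8, 12),
        global_width=6,
        seed=11,
    )


@pytest.fixture()
def tiny_model(tiny_cfg):
    return GU2Net(tiny_cfg)


def small_bench_configs(n_train=12, n_val=4, n_test=4):
    """Three 32x32 pseudo-anatomy domains with reduced sample counts."""
    kw = dict(
        image_size=(32, 32),
        margin_px=3.0,
        n_train=n_train,
        n_val=n_val,
        n_test=n_test,
    )
    return (
        SynthDomainConfig("pseudo_skull", "ellipse_ring", 5, **kw),
        SynthDomainConfig("pseudo_hand", "digit_fan", 9, **kw),
        SynthDomainConfig("pseudo_chest", "twin_lobes", 5, **kw),
    )


@pytest.fixture(scope="session")
def small_bench():
    return generate_benchmark(small_bench_configs(), seed=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def replace_cfg(cfg, **kw):
    return dataclasses.replace(cfg, **kw)
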