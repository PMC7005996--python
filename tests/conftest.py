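"""Shared fixtures: small reference models and the scaled-down sweep libraries."""

import numpy as np
import pytest
from scipy.stats import poisson

import coexland as cx


def truncated_poisson(mu: float, M: int) -> np.ndarray:
    """Stationary law of a birth-death chain with reflecting cap at M-1."""
    pmf = poisson.pmf(np.arange(M), mu)
    return pmf / pmf.sum()


@pytest.fixture
def fast_params():
    """Symmetric fast-regime kinetics within the catalogued ranges."""
    return cx.KineticParameters(g_hi_x=1.4, g_hi_y=1.4, h_a=100.0, f_a=1000.0,
                                h_r=100.0, f_r=100.0, regime="fast")


@pytest.fixture
def constitutive_model():
    """Always-on logic: both genes transcribe at g_hi in every promoter state."""
    p = cx.KineticParameters(g_hi_x=1.0, g_hi_y=1.0, k=0.2,
                             h_a=50.0, f_a=100.0, h_r=50.0, f_r=100.0)
    return cx.make_flex_model(0b1111, p, M=21)


@pytest.fixture
def small_ssa_model():
    """Small state space, moderate event rate: cheap Gillespie runs."""
    p = cx.KineticParameters(g_hi_x=2.0, g_hi_y=2.0, g_lo=0.01, k=1.0,
                             h_a=20.0, f_a=50.0, h_r=20.0, f_r=50.0)
    return cx.make_misa_model(p, M=6)


@pytest.fixture(scope="session")
def mini_misa_library():
    """Tiny fast-regime MISA quasipotential library (64 models, seconds)."""
    cfg = cx.default_misa_config(
        g_hi_values=(0.8, 1.4),
        h_a_values=(10.0, 500.0), h_r_values=(10.0, 500.0),
        f_a_values=(10.0, 1e5), f_r_values=(10.0, 1e5))
    return cx.compute_landscape_library(
        cx.generate_misa_grid(cfg), cfg.representation, floor=cfg.floor)


@pytest.fixture(scope="session")
def flex_library():
    """The default scaled-down Two-Gene Flex probability library (~2,300 models)."""
    cfg = cx.default_flex_config()
    models = cx.generate_flex_grid(cfg)
    return cx.compute_landscape_library(models, cfg.representation,
                                        floor=cfg.floor)


@pytest.fixture(scope="session")
def misa_library():
    """The default scaled-down fast-regime MISA quasipotential library (~1,300)."""
    cfg = cx.default_misa_config()
    models = cx.generate_misa_grid(cfg)
    return cx.compute_landscape_library(models, cfg.representation,
                                        floor=cfg.floor)
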