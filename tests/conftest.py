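"""Shared phantom fixtures (generated once per session to keep runtime low)."""

from __future__ import annotations

import numpy as np
import pytest

from mdxquant import synthdata


@pytest.fixture(scope="session")
def small_phantom():
    """A compact dystrophic-like phantom used by several recovery tests.

    448x448 px at 1 µm/px, ~150 fibres, moderate CNF/markers, SNR 10.
    """
    spec = synthdata.PhantomSpec(
        field_size_px=(448, 448),
        n_fibers_target=100,
        fiber_minferet_mean_um=28.0,
        fiber_minferet_cv=0.2,
        cnf_fraction=0.4,
        collagen_fraction=0.05,
        necrotic_fraction=0.04,
        igm_positive_fraction=0.10,
        emyhc_count_per_mm2=30.0,
        marker_snr=10.0,
        seed=42,
    )
    channels, brightfield, truth = synthdata.generate_phantom(spec)
    return spec, channels, brightfield, truth


@pytest.fixture(scope="session")
def clean_phantom():
    """Lesion- and collagen-free phantom for nucleus/cell-level tests."""
    spec = synthdata.PhantomSpec(
        field_size_px=(448, 448),
        n_fibers_target=100,
        cnf_fraction=0.0,
        marker_snr=20.0,
        seed=7,
    )
    channels, brightfield, truth = synthdata.generate_phantom(spec)
    return spec, channels, brightfield, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
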