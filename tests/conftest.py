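"""Shared fixtures: montage, mesh, eigenbasis, and a default synthetic
recording with its ICA decomposition (session-scoped, computed once)."""

import warnings

import numpy as np
import pytest

from dryclean import (
    GeneratorConfig,
    cap_montage,
    generate_recording,
    preprocess,
    decompose,
    classify_components,
)
from dryclean.sensor_mesh import assemble_fem, triangulate
from dryclean.sphara import compute_basis


@pytest.fixture(scope="session")
def montage64():
    return cap_montage(64)


@pytest.fixture(scope="session")
def mesh64(montage64):
    names, pos = montage64
    return assemble_fem(triangulate(pos, names))


@pytest.fixture(scope="session")
def basis64(mesh64):
    return compute_basis(mesh64)


@pytest.fixture(scope="session")
def default_recording():
    """60 s, 256 Hz, all artifact classes, fixed seed."""
    cfg = GeneratorConfig(srate=256.0, duration=60.0, seed=5)
    rec, gt = generate_recording(cfg)
    return cfg, rec, gt


@pytest.fixture(scope="session")
def preprocessed(default_recording):
    _, rec, _ = default_recording
    return preprocess(rec, high=70.0)


@pytest.fixture(scope="session")
def decomposition50(preprocessed):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dec = decompose(preprocessed, n_components=50, seed=1)
    classify_components(dec, preprocessed)
    return dec


def grid_positions(nx, ny, spacing=1.0):
    xx, yy = np.meshgrid(np.arange(nx) * spacing, np.arange(ny) * spacing)
    return np.column_stack([xx.ravel(), yy.ravel(), np.zeros(nx * ny)])
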