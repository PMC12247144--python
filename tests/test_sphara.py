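"""Spatial harmonic basis and filtering: eigenbasis contracts, transform
isometry, power-based subset selection, and Butterworth gain behavior."""

import numpy as np
import pytest
import scipy.linalg

from dryclean.sensor_mesh import SensorMesh, assemble_fem, triangulate
from dryclean.sphara import (
    SpatialFilterSpec,
    analyze,
    butterworth_gains,
    compute_basis,
    select_power_subset,
    spatial_filter,
    synthesize,
)
from dryclean import GeneratorConfig, generate_recording

from conftest import grid_positions


@pytest.fixture(scope="module")
def triangle_basis():
    mesh = SensorMesh(
        vertices=np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]),
        triangles=np.array([[0, 1, 2]]),
    )
    return compute_basis(assemble_fem(mesh))


class TestBasis:
    def test_single_triangle_constant_mode(self, triangle_basis):
        """λ₀ = 0 with constant BF₀ normalized so c²·area = 1 (c = √2 for
        area ½)."""
        b = triangle_basis
        assert b.eigenvalues[0] == pytest.approx(0.0, abs=1e-12)
        v0 = b.vectors[:, 0]
        assert np.ptp(v0) < 1e-10
        assert abs(v0[0]) == pytest.approx(np.sqrt(2.0), rel=1e-10)

    def test_mass_orthonormality(self, basis64):
        gram = basis64.vectors.T @ basis64.mass @ basis64.vectors
        assert np.abs(gram - np.eye(64)).max() < 1e-8

    def test_eigenvalues_ascending_nonnegative(self, basis64):
        w = basis64.eigenvalues
        assert (np.diff(w) >= -1e-12).all()
        assert (w >= 0).all()
        assert np.array_equal(basis64.natural_frequencies, np.sqrt(w))

    def test_dense_symmetrized_solver_equivalence(self):
        """For small meshes the generalized eigenpairs must match a brute
        force solve of M^{-1/2} S M^{-1/2} after back-transformation."""
        pos = grid_positions(3, 3)
        mesh = assemble_fem(triangulate(pos))
        basis = compute_basis(mesh)
        S, M = mesh.stiffness, mesh.mass
        Mh = scipy.linalg.sqrtm(M).real
        Mih = np.linalg.inv(Mh)
        w, y = np.linalg.eigh(Mih @ S @ Mih)
        w = np.clip(w, 0.0, None)
        assert np.abs(np.sort(w) - basis.eigenvalues).max() < 1e-8
        # eigenvectors: compare eigenspaces groupwise (degenerate
        # eigenvalues admit any orthonormal basis of their subspace)
        v = Mih @ y
        groups, start = [], 0
        for k in range(1, 10):
            if k == 9 or basis.eigenvalues[k] - basis.eigenvalues[k - 1] > 1e-6:
                groups.append(slice(start, k))
                start = k
        for g in groups:
            overlap = v[:, g].T @ M @ basis.vectors[:, g]
            sv = np.linalg.svd(overlap, compute_uv=False)
            assert np.abs(sv - 1.0).max() < 1e-6

    def test_first_nonconstant_mode_has_one_nodal_line(self):
        """On a 9×7 planar grid the second eigenvector is the first
        Neumann mode of the rectangle: exactly one sign change along the
        long axis in every row."""
        mesh = assemble_fem(triangulate(grid_positions(9, 7)))
        basis = compute_basis(mesh)
        v1 = basis.vectors[:, 1].reshape(7, 9)
        changes = (np.diff(np.sign(v1), axis=1) != 0).sum(axis=1)
        assert (changes == 1).all()

    def test_unassembled_mesh_rejected(self):
        mesh = triangulate(grid_positions(3, 3))
        with pytest.raises(ValueError, match="assemble"):
            compute_basis(mesh)


class TestTransform:
    def test_round_trip(self, basis64):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 20, (64, 256))
        back = synthesize(basis64, analyze(basis64, x))
        assert np.abs(back - x).max() < 1e-9 * np.abs(x).max()

    def test_basis_column_gives_unit_coefficient(self, basis64):
        k = 7
        x = np.tile(basis64.vectors[:, k : k + 1], (1, 5))
        c = analyze(basis64, x)
        expected = np.zeros((64, 5))
        expected[k] = 1.0
        assert np.abs(c - expected).max() < 1e-8

    def test_parseval(self, basis64):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 10, (64, 128))
        c = analyze(basis64, x)
        lhs = np.einsum("ct,ct->t", x, basis64.mass @ x)
        rhs = (c**2).sum(axis=0)
        assert np.abs(lhs - rhs).max() < 1e-9 * np.abs(lhs).max()

    def test_truncated_synthesis_stays_in_span(self, basis64):
        rng = np.random.default_rng(2)
        c = rng.normal(size=(10, 16))
        x = synthesize(basis64, c)
        c_back = analyze(basis64, x)
        assert np.abs(c_back[10:]).max() < 1e-9

    def test_channel_mismatch_rejected(self, basis64):
        with pytest.raises(ValueError):
            analyze(basis64, np.zeros((10, 4)))


class TestPowerSubset:
    def test_constructed_power_profile(self, basis64):
        """Power fractions 0.90/0.04/0.03/0.03 → K = 3 at the 95 % level."""
        fracs = np.array([0.90, 0.04, 0.03, 0.03])
        c = np.zeros((64, 4))
        c[np.arange(4), np.arange(4)] = np.sqrt(fracs)
        data = synthesize(basis64, c)
        assert select_power_subset(basis64, data, 0.95) == 3

    def test_exact_span(self, basis64):
        c = np.zeros((64, 8))
        c[:3, :] = np.random.default_rng(3).normal(size=(3, 8))
        data = synthesize(basis64, c)
        for rp in (0.5, 0.95, 1.0):
            assert select_power_subset(basis64, data, rp) <= 3
        assert select_power_subset(basis64, data, 1.0) == 3

    def test_full_rank_needs_all(self, basis64):
        rng = np.random.default_rng(4)
        data = synthesize(basis64, np.diag(rng.uniform(1, 2, 64)))
        assert select_power_subset(basis64, data, 1.0) == 64

    def test_zero_data_rejected(self, basis64):
        with pytest.raises(ValueError):
            select_power_subset(basis64, np.zeros((64, 4)))


class TestSpatialFilter:
    def test_butterworth_endpoints(self):
        f = np.array([0.0, 1.0, 2.0])
        g = butterworth_gains(f, cutoff=1.0, order=2)
        assert g[0] == 1.0
        assert g[1] == pytest.approx(1 / np.sqrt(2), rel=1e-12)
        assert (np.diff(g) < 0).all()

    def test_constant_pattern_unchanged(self, basis64):
        x = np.tile(basis64.vectors[:, :1], (1, 8))
        out = spatial_filter(basis64, x, SpatialFilterSpec(cutoff_frequency=0.5))
        assert np.abs(out - x).max() < 1e-9

    def test_half_power_at_cutoff(self, basis64):
        k = 5
        fc = float(basis64.natural_frequencies[k])
        x = np.tile(basis64.vectors[:, k : k + 1], (1, 8))
        out = spatial_filter(basis64, x, SpatialFilterSpec(cutoff_frequency=fc))
        assert np.abs(out - x / np.sqrt(2)).max() < 1e-9

    def test_temporal_phase_preserved(self, basis64):
        """A sinusoidal time course on a pure spatial pattern keeps its
        temporal phase at every channel (zero-phase spatial filtering)."""
        k, srate = 5, 256.0
        t = np.arange(2048) / srate
        x = np.outer(basis64.vectors[:, k], np.sin(2 * np.pi * 7.0 * t))
        fc = float(basis64.natural_frequencies[k])
        out = spatial_filter(basis64, x, SpatialFilterSpec(cutoff_frequency=fc))
        ch = int(np.argmax(np.abs(basis64.vectors[:, k])))
        fin, fout = np.fft.rfft(x[ch]), np.fft.rfft(out[ch])
        kk = int(np.argmax(np.abs(fin)))
        assert abs(np.angle(fout[kk]) - np.angle(fin[kk])) < 1e-9

    def test_linearity_and_shift_commutation(self, basis64):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(64, 64))
        spec = SpatialFilterSpec(cutoff_frequency=1.0)
        fx = spatial_filter(basis64, x, spec)
        # temporal shift commutes
        shifted = np.roll(x, 7, axis=1)
        assert np.abs(
            spatial_filter(basis64, shifted, spec) - np.roll(fx, 7, axis=1)
        ).max() < 1e-9
        # linearity
        y = rng.normal(size=(64, 64))
        fy = spatial_filter(basis64, y, spec)
        fxy = spatial_filter(basis64, 2 * x - 3 * y, spec)
        assert np.abs(fxy - (2 * fx - 3 * fy)).max() < 1e-9

    def test_truncation_mode_keeps_leading_subspace(self, basis64):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(64, 32))
        out = spatial_filter(
            basis64, x, SpatialFilterSpec(mode="truncation", retained_power=0.5)
        )
        c = analyze(basis64, out)
        k = select_power_subset(basis64, x, 0.5)
        assert np.abs(c[k:]).max() < 1e-9

    def test_invalid_cutoff_rejected(self):
        with pytest.raises(ValueError):
            SpatialFilterSpec(cutoff_frequency=-1.0)
        with pytest.raises(ValueError):
            butterworth_gains(np.array([1.0]), cutoff=0.0)


def test_denoising_smooth_background_plus_white_noise(basis64):
    """Spatial low-pass filtering must strictly reduce the RMS error to
    the ground-truth background when the corruption is spatially
    uncorrelated sensor noise (10 seeded repetitions, all must pass)."""
    for seed in range(10):
        cfg = GeneratorConfig(
            srate=256.0, duration=20.0, seed=300 + seed,
            blink_rate=0.0, eye_movement_rate=0.0, emg_burst_rate=0.0,
            heart_rate=0.0, jump_fraction=0.0, sensor_noise_sd=3.0,
        )
        rec, gt = generate_recording(cfg)
        filtered = spatial_filter(basis64, rec.data, SpatialFilterSpec())
        err_raw = np.sqrt(((rec.data - gt.clean) ** 2).mean())
        err_filt = np.sqrt(((filtered - gt.clean) ** 2).mean())
        assert err_filt < err_raw
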