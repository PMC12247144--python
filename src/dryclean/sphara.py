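"""Spatial harmonic analysis (SPHARA) on the sensor mesh.

The spatial basis functions (BFs) are the eigenvectors of the generalized
problem ``S v = λ M v`` with the FEM stiffness ``S`` and mass ``M`` from
:mod:`dryclean.sensor_mesh`.  λ plays the role of a squared spatial
frequency; the *natural frequency* of a BF is √λ.  The BFs are
M-orthonormal, so the analysis transform ``c = Vᵀ M x`` is an isometry with
respect to the mass inner product and ``x = V c`` inverts it exactly.

Spatial low-pass filtering multiplies each coefficient by an order-``p``
Butterworth gain ``g_k = (1 + (f_k/f_c)^{2p})^{-1/2}`` and resynthesizes.
The gain is applied identically at every time sample, so the temporal phase
of the data is untouched.  The cutoff ``f_c`` defaults to the natural
frequency of the smallest leading basis subset that retains 95 % of the
signal power.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .sensor_mesh import SensorMesh

__all__ = [
    "SpharaBasis",
    "SpatialFilterSpec",
    "compute_basis",
    "analyze",
    "synthesize",
    "select_power_subset",
    "butterworth_gains",
    "spatial_filter",
]


@dataclass
class SpharaBasis:
    """Mass-orthonormal eigenbasis of the discrete Laplace–Beltrami operator.

    ``vectors[:, k]`` is the k-th BF over channels; ``eigenvalues`` are
    ascending and ``natural_frequencies = sqrt(eigenvalues)``.
    """

    vectors: np.ndarray  # (n, n)
    eigenvalues: np.ndarray  # (n,), ascending, >= 0
    natural_frequencies: np.ndarray  # (n,)
    mass: np.ndarray  # (n, n), defines the inner product

    @property
    def n_channels(self) -> int:
        return self.vectors.shape[0]


@dataclass
class SpatialFilterSpec:
    """Configuration of the spatial low-pass filter.

    ``cutoff_frequency`` is in natural-frequency units (√λ); when ``None``
    it is derived from ``retained_power`` via :func:`select_power_subset`.
    ``mode="truncation"`` keeps the leading subset with unit gain instead of
    Butterworth weighting.
    """

    order: int = 2
    cutoff_frequency: float | None = None
    retained_power: float = 0.95
    mode: str = "butterworth"

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("order must be >= 1")
        if not 0 < self.retained_power <= 1:
            raise ValueError("retained_power must be in (0, 1]")
        if self.mode not in ("butterworth", "truncation"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.cutoff_frequency is not None and self.cutoff_frequency <= 0:
            raise ValueError("cutoff_frequency must be positive")


def compute_basis(mesh: SensorMesh) -> SpharaBasis:
    """Solve ``S v = λ M v`` and return the sorted, sign-fixed basis.

    Eigenvectors come out M-orthonormal from the dense symmetric
    generalized solver; signs are fixed so each column's max-|entry| is
    positive.  Small negative eigenvalues from round-off are clipped to 0.
    """
    if mesh.stiffness is None or mesh.mass is None:
        raise ValueError("mesh FEM matrices not assembled; call assemble_fem first")
    M = mesh.mass
    try:
        scipy.linalg.cholesky(M)
    except scipy.linalg.LinAlgError:
        raise ValueError("mass matrix is not positive definite") from None
    w, v = scipy.linalg.eigh(mesh.stiffness, M)
    order = np.argsort(w, kind="stable")
    w = w[order]
    v = v[:, order]
    w = np.where(w < 0, 0.0, w)
    signs = np.sign(v[np.argmax(np.abs(v), axis=0), np.arange(v.shape[1])])
    signs[signs == 0] = 1.0
    v = v * signs
    return SpharaBasis(
        vectors=v, eigenvalues=w, natural_frequencies=np.sqrt(w), mass=M
    )


def analyze(basis: SpharaBasis, data: np.ndarray) -> np.ndarray:
    """Forward transform: coefficients ``c = Vᵀ M x`` per time sample."""
    data = np.asarray(data, dtype=float)
    if data.shape[0] != basis.n_channels:
        raise ValueError(
            f"data has {data.shape[0]} channels, basis expects {basis.n_channels}"
        )
    return basis.vectors.T @ (basis.mass @ data)


def synthesize(basis: SpharaBasis, coefficients: np.ndarray) -> np.ndarray:
    """Inverse transform: ``x = V c``.

    ``coefficients`` may contain fewer rows than the full basis, in which
    case only the leading BFs are used.
    """
    coefficients = np.asarray(coefficients, dtype=float)
    k = coefficients.shape[0]
    if k > basis.n_channels:
        raise ValueError("more coefficient rows than basis functions")
    return basis.vectors[:, :k] @ coefficients


def select_power_subset(
    basis: SpharaBasis, data: np.ndarray, retained_power: float = 0.95
) -> int:
    """Smallest K such that the K lowest-frequency BFs hold ``retained_power``
    of the total signal power (power of BF k = Σ_t c_k(t)²)."""
    if not 0 < retained_power <= 1:
        raise ValueError("retained_power must be in (0, 1]")
    coeffs = analyze(basis, data)
    power = (coeffs**2).sum(axis=1)
    total = power.sum()
    if total <= 0:
        raise ValueError("data has zero power; cannot select a basis subset")
    cum = np.cumsum(power) / total
    # guard against round-off keeping cum[-1] microscopically below 1
    cum[-1] = max(cum[-1], 1.0)
    return int(np.searchsorted(cum, retained_power - 1e-12) + 1)


def butterworth_gains(
    natural_frequencies: np.ndarray, cutoff: float, order: int = 2
) -> np.ndarray:
    """Per-BF gain ``(1 + (f/f_c)^{2p})^{-1/2}``; unity at f = 0, 1/√2 at f_c."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    f = np.asarray(natural_frequencies, dtype=float)
    return 1.0 / np.sqrt(1.0 + (f / cutoff) ** (2 * order))


def resolve_cutoff(basis: SpharaBasis, data: np.ndarray, spec: SpatialFilterSpec) -> float:
    """Cutoff natural frequency implied by ``spec`` for ``data``.

    With an explicit ``cutoff_frequency`` that value is returned.  Otherwise
    K = :func:`select_power_subset` at ``spec.retained_power`` and the
    cutoff is the natural frequency of the K-th BF (or of the first BF with
    positive frequency if all retained power sits in the constant BF).
    """
    if spec.cutoff_frequency is not None:
        return float(spec.cutoff_frequency)
    k = select_power_subset(basis, data, spec.retained_power)
    fc = float(basis.natural_frequencies[k - 1])
    if fc <= 0:
        positive = basis.natural_frequencies[basis.natural_frequencies > 0]
        if positive.size == 0:
            raise ValueError("basis has no positive natural frequency")
        fc = float(positive[0])
    return fc


def spatial_filter(
    basis: SpharaBasis, data: np.ndarray, spec: SpatialFilterSpec | None = None
) -> np.ndarray:
    """Apply the spatial low-pass to ``data`` (channels × samples)."""
    if spec is None:
        spec = SpatialFilterSpec()
    coeffs = analyze(basis, data)
    if spec.mode == "truncation":
        k = (
            select_power_subset(basis, data, spec.retained_power)
            if spec.cutoff_frequency is None
            else int(np.searchsorted(basis.natural_frequencies, spec.cutoff_frequency, "right"))
        )
        coeffs[k:] = 0.0
        return synthesize(basis, coeffs)
    fc = resolve_cutoff(basis, data, spec)
    gains = butterworth_gains(basis.natural_frequencies, fc, spec.order)
    return synthesize(basis, gains[:, None] * coeffs)
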