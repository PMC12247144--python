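"""ICA-based physiological-artifact removal.

The stage mirrors the structure of automated IC-classification pipelines:
PCA pre-whitening to a fixed number of dimensions, extended-Infomax
unmixing (50 ICs by default, independent of the retained channel count, to
keep decompositions comparable across recordings), heuristic labeling of
artifactual components, and reprojection of the retained components back
to sensor space.

The component classifier is a documented heuristic built from standard
topographic and spectral features (it is *not* a trained classifier; all
thresholds are exposed on :class:`ClassifierConfig`):

* ``blink`` — frontal-dominant topography, mostly sub-5 Hz power, strongly
  skewed amplitude distribution;
* ``eye_movement`` — lateral-frontal dipolar topography with low-frequency,
  step-like time course;
* ``cardiac`` (covers pulse) — a regular peak train with inter-peak
  periodicity in the 0.6–1.67 s (36–100 bpm) range;
* ``myogenic`` — dominant power above 20 Hz with weak lag-1
  autocorrelation;
* ``neural`` — everything else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.signal
from mne.preprocessing import infomax

from .recording import Recording

__all__ = [
    "Decomposition",
    "ClassifierConfig",
    "ARTIFACT_LABELS",
    "decompose",
    "classify_components",
    "remove_and_reproject",
]

ARTIFACT_LABELS = ("blink", "eye_movement", "myogenic", "cardiac", "pulse")


@dataclass
class Decomposition:
    """PCA + extended-Infomax decomposition of a recording.

    ``mixing @ sources + mean[:, None]`` reconstructs the rank-``n_components``
    PCA approximation of the input.
    """

    mixing: np.ndarray  # (n_channels, n_components)
    sources: np.ndarray  # (n_components, n_samples), a.u.
    mean: np.ndarray  # (n_channels,) channel means, μV
    srate: float
    labels: list[str] | None = None

    @property
    def n_components(self) -> int:
        return self.mixing.shape[1]

    def reconstruct(self, keep: np.ndarray | None = None) -> np.ndarray:
        """Sensor-space back-projection of (a subset of) the components."""
        if keep is None:
            return self.mixing @ self.sources + self.mean[:, None]
        keep = np.asarray(keep)
        return self.mixing[:, keep] @ self.sources[keep] + self.mean[:, None]


def decompose(
    rec: Recording,
    n_components: int = 50,
    seed: int = 0,
    max_iter: int = 200,
    fit_max_samples: int | None = 4096,
) -> Decomposition:
    """PCA pre-whitening to ``n_components`` dimensions, then extended
    Infomax.

    The unmixing matrix is estimated on an evenly decimated subsample of at
    most ``fit_max_samples`` whitened samples (the mixing is
    time-invariant, so a subsample suffices and keeps the fit tractable);
    the source time courses are then computed for every sample.
    Deterministic for a given seed.
    """
    if rec.n_channels < n_components:
        raise ValueError(
            f"{rec.n_channels} channels < {n_components} requested components"
        )
    recommended = 20 * n_components**2
    if rec.n_samples < recommended:
        warnings.warn(
            f"{rec.n_samples} samples < recommended {recommended} for a stable "
            f"{n_components}-component unmixing",
            stacklevel=2,
        )
    mean = rec.data.mean(axis=1)
    X = rec.data - mean[:, None]
    # economy SVD: X = U S Vt; whitened rows have unit variance
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(s > 1e-6 * s[0]))
    k = n_components
    if rank < k:
        warnings.warn(
            f"data rank {rank} < {k} requested components; decomposing into "
            f"{rank} components",
            stacklevel=2,
        )
        k = rank
    scale = s[:k] / np.sqrt(X.shape[1])
    Z = (U[:, :k].T @ X) / scale[:, None]

    if fit_max_samples is not None and Z.shape[1] > fit_max_samples:
        step = int(np.ceil(Z.shape[1] / fit_max_samples))
        Zfit = Z[:, ::step]
    else:
        Zfit = Z
    W = infomax(
        Zfit.T,
        extended=True,
        max_iter=max_iter,
        rng=seed,
        verbose=False,
    )
    sources = W @ Z
    mixing = (U[:, :k] * scale[None, :]) @ np.linalg.inv(W)

    # sign convention: max-|mixing| entry of each column positive
    idx = np.argmax(np.abs(mixing), axis=0)
    signs = np.sign(mixing[idx, np.arange(k)])
    signs[signs == 0] = 1.0
    mixing = mixing * signs[None, :]
    sources = sources * signs[:, None]
    return Decomposition(mixing=mixing, sources=sources, mean=mean, srate=rec.srate)


@dataclass
class ClassifierConfig:
    """Thresholds of the heuristic component classifier (all documented
    defaults; tune per dataset if needed)."""

    frontal_y: float = 0.35  # channels with y > frontal_y count as frontal
    blink_frontal_frac: float = 0.45  # fraction of topography power on frontal chans
    blink_lowfreq_frac: float = 0.55  # source power below low_freq
    blink_skew: float = 1.0
    low_freq: float = 5.0
    eye_frontal_frac: float = 0.35
    eye_dipole_asym: float = 0.5  # |left - right| frontal weight asymmetry
    eye_lowfreq_frac: float = 0.60
    myo_high_freq: float = 20.0
    myo_highfreq_frac: float = 0.45
    myo_lag1_max: float = 0.90
    cardiac_min_peaks: int = 5
    cardiac_period_range: tuple[float, float] = (0.6, 1.67)  # s (36-100 bpm)
    cardiac_period_cv: float = 0.2
    cardiac_peak_z: float = 3.0


def _band_fraction(psd_f: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    total = psd.sum()
    if total <= 0:
        return 0.0
    band = psd[(psd_f >= lo) & (psd_f < hi)].sum()
    return float(band / total)


def classify_components(
    dec: Decomposition, rec: Recording, config: ClassifierConfig | None = None
) -> Decomposition:
    """Fill ``dec.labels`` in place (and return ``dec``).

    Checks are applied in the order blink → eye_movement → cardiac →
    myogenic; unmatched components are ``neural``.
    """
    if config is None:
        config = ClassifierConfig()
    pos = rec.positions
    frontal = pos[:, 1] > config.frontal_y
    left = frontal & (pos[:, 0] < 0)
    right = frontal & (pos[:, 0] >= 0)
    labels: list[str] = []
    nperseg = min(dec.sources.shape[1], int(4 * dec.srate))
    for kc in range(dec.n_components):
        topo = dec.mixing[:, kc]
        tp = topo**2
        tp_sum = tp.sum()
        frontal_frac = tp[frontal].sum() / tp_sum if tp_sum > 0 else 0.0
        asym = 0.0
        if tp_sum > 0 and left.any() and right.any():
            asym = abs(topo[left].mean() - topo[right].mean()) / np.sqrt(tp.mean())

        src = dec.sources[kc]
        f, psd = scipy.signal.welch(src, fs=dec.srate, nperseg=nperseg)
        low_frac = _band_fraction(f, psd, 0.0, config.low_freq)
        high_frac = _band_fraction(f, psd, config.myo_high_freq, dec.srate / 2)
        sd = src.std()
        skew = 0.0
        lag1 = 1.0
        if sd > 0:
            zs = (src - src.mean()) / sd
            skew = float((zs**3).mean())
            lag1 = float(np.corrcoef(src[:-1], src[1:])[0, 1])

        label = "neural"
        if (
            frontal_frac > config.blink_frontal_frac
            and low_frac > config.blink_lowfreq_frac
            and abs(skew) > config.blink_skew
        ):
            label = "blink"
        elif (
            frontal_frac > config.eye_frontal_frac
            and asym > config.eye_dipole_asym
            and low_frac > config.eye_lowfreq_frac
        ):
            label = "eye_movement"
        elif sd > 0 and _is_periodic_peak_train(src, dec.srate, config):
            label = "cardiac"
        elif high_frac > config.myo_highfreq_frac and lag1 < config.myo_lag1_max:
            label = "myogenic"
        labels.append(label)
    dec.labels = labels
    return dec


def _is_periodic_peak_train(src: np.ndarray, srate: float, config: ClassifierConfig) -> bool:
    z = np.abs(src - src.mean()) / src.std()
    min_dist = int(config.cardiac_period_range[0] * 0.8 * srate)
    peaks, _ = scipy.signal.find_peaks(
        z, height=config.cardiac_peak_z, distance=max(1, min_dist)
    )
    if len(peaks) < config.cardiac_min_peaks:
        return False
    intervals = np.diff(peaks) / srate
    med = np.median(intervals)
    lo, hi = config.cardiac_period_range
    if not lo <= med <= hi:
        return False
    return float(intervals.std() / med) < config.cardiac_period_cv


def remove_and_reproject(
    dec: Decomposition, rec: Recording, drop_labels=ARTIFACT_LABELS
) -> Recording:
    """Zero the components whose label is in ``drop_labels`` and mix the
    rest back to sensor space."""
    if dec.labels is None:
        raise ValueError("labels not filled; run classify_components first")
    drop_labels = set(drop_labels)
    keep = np.array([i for i, lb in enumerate(dec.labels) if lb not in drop_labels])
    if keep.size == 0:
        warnings.warn("all components dropped; returning a zero recording", stacklevel=2)
        return rec.copy(data=np.zeros_like(rec.data))
    return rec.copy(data=dec.reconstruct(keep))
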