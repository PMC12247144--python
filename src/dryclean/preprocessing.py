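"""Phase A preprocessing (temporal filtering, channel/trial hygiene) and
Phase C data preparation (re-referencing, channel interpolation, task
segmentation).

Filtering uses a windowed-sinc (Hamming) FIR band-pass (0.5–70 Hz by
default) combined with a 48–52 Hz FIR band-stop for line noise, applied
forward and backward (via FFT convolution with reflection padding) so the
net response is zero-phase.

Channel interpolation uses spherical splines (Perrin et al. 1989): scalp
potentials are modeled as ``z(r) = d + Σ_i c_i g(cos(r, r_i))`` with
``g(x) = 1/(4π) Σ_n (2n+1)/(n(n+1))^m P_n(x)``; the spline reproduces
spatially constant fields exactly.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.signal
from numpy.polynomial import legendre as npleg

from .recording import Epoch, Recording, TASK_LABELS

__all__ = [
    "bandpass_notch",
    "detect_bad_channels",
    "reject_bad_trials",
    "rereference_common_average",
    "interpolate_channels",
    "segment_by_task",
    "preprocess",
    "spherical_spline_matrix",
]


# ---------------------------------------------------------------------------
# Temporal filtering

def _fir_kernel(srate: float, low: float, high: float, notch: float | None) -> np.ndarray:
    """Combined band-pass + band-stop linear-phase kernel (odd length)."""
    def _odd(n: int) -> int:
        return n + 1 if n % 2 == 0 else n

    # transition width 0.5 Hz at the low edge sets the band-pass length
    ntaps = _odd(int(np.ceil(3.3 * srate / 0.5)))
    bp = scipy.signal.firwin(
        ntaps, [low, high], pass_zero=False, window="hamming", fs=srate
    )
    if notch is None:
        return bp
    ntaps_bs = _odd(int(np.ceil(3.3 * srate / 1.0)))
    bs = scipy.signal.firwin(
        ntaps_bs,
        [notch - 2.0, notch + 2.0],
        pass_zero="bandstop",
        window="hamming",
        fs=srate,
    )
    return np.convolve(bp, bs)


def _zero_phase_apply(data: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Forward-backward application of a FIR kernel along the last axis."""
    pad = len(kernel)
    padded = np.concatenate(
        [data[:, pad:0:-1], data, data[:, -2 : -pad - 2 : -1]], axis=1
    )
    for _ in range(2):  # forward, then backward pass of the same kernel
        padded = scipy.signal.fftconvolve(padded, kernel[None, :], mode="same", axes=1)
    return padded[:, pad:-pad]


def bandpass_notch(
    rec: Recording, low: float = 0.5, high: float = 70.0, notch: float | None = 50.0
) -> Recording:
    """Zero-phase FIR band-pass plus line-noise notch.

    Output length equals input length; group delay is zero by symmetric
    forward-backward application.
    """
    nyq = rec.srate / 2.0
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high edge {high} Hz not below Nyquist {nyq} Hz")
    if notch is not None and not low < notch < high:
        raise ValueError("notch frequency must lie inside the passband")
    kernel = _fir_kernel(rec.srate, low, high, notch)
    if len(kernel) >= rec.n_samples:
        raise ValueError("recording too short for the filter length")
    return rec.copy(data=_zero_phase_apply(rec.data, kernel))


# ---------------------------------------------------------------------------
# Channel / trial hygiene

def detect_bad_channels(
    rec: Recording,
    flat_tol: float = 0.5,
    amp_thresh: float = 100.0,
    frac: float = 0.70,
) -> set[str]:
    """Channels isoelectric (|x| < flat_tol) or high-amplitude
    (|x| > amp_thresh) for more than ``frac`` of the samples."""
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    absd = np.abs(rec.data)
    flat = (absd < flat_tol).mean(axis=1) > frac
    high = (absd > amp_thresh).mean(axis=1) > frac
    return {name for name, bad in zip(rec.channel_names, flat | high) if bad}


def reject_bad_trials(
    epochs: list[Epoch],
    disturb_thresh: float = 150.0,
    channel_frac: float = 0.40,
) -> list[Epoch]:
    """Drop trials in which more than ``channel_frac`` of the channels
    contain any sample above ``disturb_thresh`` (order preserved)."""
    if not epochs:
        raise ValueError("no epochs given")
    kept = []
    for ep in epochs:
        disturbed = (np.abs(ep.data) > disturb_thresh).any(axis=1).mean()
        if disturbed <= channel_frac:
            kept.append(ep)
    return kept


def rereference_common_average(rec: Recording) -> Recording:
    """Subtract the instantaneous mean over channels from every channel."""
    if rec.n_channels < 2:
        raise ValueError("common-average reference needs at least 2 channels")
    return rec.copy(data=rec.data - rec.data.mean(axis=0, keepdims=True))


# ---------------------------------------------------------------------------
# Spherical-spline interpolation

def _g_legendre(cosang: np.ndarray, stiffness: int = 4, n_terms: int = 50) -> np.ndarray:
    n = np.arange(1, n_terms + 1, dtype=float)
    coeffs = np.zeros(n_terms + 1)
    coeffs[1:] = (2 * n + 1) / (n * (n + 1)) ** stiffness
    return npleg.legval(np.clip(cosang, -1.0, 1.0), coeffs) / (4 * np.pi)


def spherical_spline_matrix(
    source_pos: np.ndarray,
    target_pos: np.ndarray,
    stiffness: int = 4,
    n_terms: int = 50,
    reg: float = 1e-5,
) -> np.ndarray:
    """Interpolation operator ``A`` with ``z_target = A @ z_source``.

    Positions are normalized to the unit sphere about the origin; the
    spline's constant term makes the operator exact for spatially constant
    fields regardless of geometry.
    """
    src = np.asarray(source_pos, float)
    tgt = np.atleast_2d(np.asarray(target_pos, float))
    src = src / np.linalg.norm(src, axis=1, keepdims=True)
    tgt = tgt / np.linalg.norm(tgt, axis=1, keepdims=True)
    ns = len(src)
    G = _g_legendre(src @ src.T, stiffness, n_terms)
    Gt = _g_legendre(tgt @ src.T, stiffness, n_terms)
    A = np.zeros((ns + 1, ns + 1))
    A[:ns, :ns] = G + reg * np.eye(ns)
    A[:ns, ns] = 1.0
    A[ns, :ns] = 1.0
    sol = np.linalg.solve(A, np.vstack([np.eye(ns), np.zeros(ns)]))
    return np.hstack([Gt, np.ones((len(tgt), 1))]) @ sol


def interpolate_channels(rec: Recording, targets) -> Recording:
    """Replace ``targets`` by spherical-spline estimates from the rest.

    Non-target channels are untouched; requires at least 4 source channels.
    """
    targets = [t for t in rec.channel_names if t in set(targets)]
    unknown = set(targets) - set(rec.channel_names)
    if unknown:
        raise KeyError(f"target channels not in recording: {sorted(unknown)}")
    if not targets:
        return rec.copy()
    tgt_idx = [rec.channel_index(t) for t in targets]
    src_idx = [i for i in range(rec.n_channels) if i not in set(tgt_idx)]
    if len(src_idx) < 4:
        raise ValueError("need at least 4 source channels for spline interpolation")
    A = spherical_spline_matrix(rec.positions[src_idx], rec.positions[tgt_idx])
    out = rec.copy()
    out.data[tgt_idx] = A @ rec.data[src_idx]
    return out


# ---------------------------------------------------------------------------
# Segmentation

def segment_by_task(rec: Recording, window: float = 7.0) -> list[Epoch]:
    """One epoch of ``window`` seconds per trial marker.

    Markers too close to the recording end are skipped with a warning.
    """
    n_win = int(round(window * rec.srate))
    epochs: list[Epoch] = []
    for trial_index, (label, onset) in enumerate(rec.events):
        if label not in TASK_LABELS:
            continue
        if onset + n_win > rec.n_samples:
            warnings.warn(
                f"trial {trial_index} ({label}) at sample {onset} extends past "
                "the recording end; skipped",
                stacklevel=2,
            )
            continue
        epochs.append(
            Epoch(
                task_label=label,
                data=rec.data[:, onset : onset + n_win].copy(),
                trial_index=trial_index,
                onset_sample=onset,
            )
        )
    return epochs


# ---------------------------------------------------------------------------
# Convenience: full Phase A

def preprocess(
    rec: Recording,
    low: float = 0.5,
    high: float = 70.0,
    notch: float | None = 50.0,
    flat_tol: float = 0.5,
    amp_thresh: float = 100.0,
    bad_frac: float = 0.70,
    drop_bad: bool = True,
) -> Recording:
    """Phase A: band-pass + notch, then flag (and optionally drop) bad
    channels.  The result serves as the reference (Ref) signal for the
    cleaning methods."""
    out = bandpass_notch(rec, low=low, high=high, notch=notch)
    bads = detect_bad_channels(out, flat_tol=flat_tol, amp_thresh=amp_thresh, frac=bad_frac)
    out.bad_channels = set(out.bad_channels) | bads
    if drop_bad and bads:
        dropped = out.drop_channels(bads)
        dropped.bad_channels = set(out.bad_channels)
        out = dropped
    return out
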