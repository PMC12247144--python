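"""Seeded synthetic dry-EEG generator with ground-truth annotations.

The generator emulates the statistical structure the cleaning pipeline
assumes, so every stage is testable without real recordings:

* spatially smooth background — a mixture of the lowest-order spatial
  harmonics of the montage mesh, driven by AR(2)-filtered noise (1/f-like)
  plus a posterior-weighted 10 Hz alpha rhythm;
* frontal-dominant eye blinks and lateral-frontal dipolar eye movements
  (low-frequency transients / step-like excursions);
* EMG bursts — band-limited (20–70 Hz) noise on peripheral channel groups;
* quasi-periodic cardiac spike-train interference;
* white sensor noise, spatially uncorrelated;
* transient single-channel high-amplitude jumps (step plus exponential
  return, time constant 0.3 s) occupying a configurable fraction of the
  channel-time (default 1.3 %), optionally co-occurring on a mesh
  neighbor.

The emitted recording is, bit-exactly, the sum of the ground-truth clean
background and the per-class artifact components.  All randomness descends
from one seed through named substreams, so identical configurations give
identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .ap0 import ArtifactPeriod
from .recording import Recording, TASK_LABELS
from .sensor_mesh import assemble_fem, triangulate
from .sphara import compute_basis

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "cap_montage",
    "generate_recording",
    "generate_task_events",
]

# order fixes the seed substream assignment; never reorder
_STREAMS = (
    "background",
    "alpha",
    "blink",
    "eye_movement",
    "emg",
    "cardiac",
    "sensor_noise",
    "jumps",
    "events",
)


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic recording.

    Rates are events per minute; amplitudes in μV.  ``jump_fraction`` is
    the target share of channel-time occupied by high-amplitude jump
    periods (the study's labeled share was 1.3 ± 0.9 %).
    """

    n_channels: int = 64
    srate: float = 1024.0
    duration: float = 60.0
    seed: int = 0
    blink_rate: float = 15.0
    eye_movement_rate: float = 6.0
    emg_burst_rate: float = 8.0
    heart_rate: float = 70.0
    jump_fraction: float = 0.013
    jump_amplitude_range: tuple[float, float] = (200.0, 800.0)
    jump_duration_range: tuple[float, float] = (0.4, 2.0)
    jump_neighbor_prob: float = 0.2
    jump_neighbor_atten: float = 0.5
    background_alpha_power: float = 9.0  # μV², per-channel alpha variance
    background_broadband_sd: float = 5.0  # μV, per-channel 1/f background
    sensor_noise_sd: float = 3.0  # μV per channel
    n_background_patterns: int = 8

    def __post_init__(self) -> None:
        if self.n_channels <= 0 or self.duration <= 0:
            raise ValueError("n_channels and duration must be positive")
        for name in ("blink_rate", "eye_movement_rate", "emg_burst_rate", "heart_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.jump_fraction < 0.5:
            raise ValueError("jump_fraction must be in [0, 0.5)")
        if self.srate <= 2 * 70.0:
            # 70 Hz is the highest generated frequency (EMG band top)
            raise ValueError("srate must exceed twice the highest generated frequency (70 Hz)")
        if self.sensor_noise_sd < 0 or self.background_alpha_power < 0:
            raise ValueError("noise/power parameters must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.srate))


@dataclass
class GroundTruth:
    """Exact decomposition of a generated recording.

    ``clean + Σ artifact_components.values()`` (summed in key order)
    reproduces the emitted data matrix exactly; ``jump_periods`` are the
    per-channel half-open jump intervals.
    """

    clean: np.ndarray
    artifact_components: dict[str, np.ndarray] = field(default_factory=dict)
    jump_periods: list[ArtifactPeriod] = field(default_factory=list)

    def total(self) -> np.ndarray:
        out = self.clean.astype(np.float64)
        for key in self.artifact_components:
            out = out + self.artifact_components[key]
        return out


def cap_montage(n_channels: int = 64) -> tuple[list[str], np.ndarray]:
    """Quasi-uniform electrode layout on a unit-sphere cap.

    A Fibonacci spiral from the apex (z = 1) down to slightly below the
    equator, matching the open-cap (disk) topology of an EEG montage.
    +y is the front of the head, +x the right side.
    """
    if n_channels < 4:
        raise ValueError("need at least 4 channels")
    i = np.arange(n_channels)
    z = 1.0 - (1.0 + 0.05) * i / (n_channels - 1)  # 1 .. -0.05
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = i * golden
    pos = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    names = [f"E{k + 1:02d}" for k in range(n_channels)]
    return names, pos


def _substreams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(_STREAMS, children)}


def _ar2_noise(rng: np.random.Generator, n: int, srate: float, f0: float = 2.0) -> np.ndarray:
    """AR(2) low-pass noise (double real pole at e^{-2π f0/srate})."""
    p = np.exp(-2 * np.pi * f0 / srate)
    x = scipy.signal.lfilter([1.0], [1.0, -2 * p, p * p], rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _gauss_weights(positions: np.ndarray, center: np.ndarray, width: float) -> np.ndarray:
    c = np.asarray(center, float)
    c = c / np.linalg.norm(c)
    d2 = ((positions - c) ** 2).sum(axis=1)
    w = np.exp(-d2 / (2 * width**2))
    return w / w.max()


def _poisson_times(rng: np.random.Generator, rate_per_min: float, duration: float) -> np.ndarray:
    if rate_per_min <= 0:
        return np.array([])
    n = rng.poisson(rate_per_min * duration / 60.0)
    return np.sort(rng.uniform(0.0, duration, size=n))


def generate_recording(config: GeneratorConfig) -> tuple[Recording, GroundTruth]:
    """Generate one synthetic dry-EEG recording with ground truth.

    Returns the recording (whose data matrix equals ``GroundTruth.total()``
    exactly) and the ground-truth decomposition.  Identical configurations
    produce bit-identical output.
    """
    names, pos = cap_montage(config.n_channels)
    n, ns = config.n_channels, config.n_samples
    srate = config.srate
    rngs = _substreams(config.seed)
    t = np.arange(ns) / srate

    mesh = assemble_fem(triangulate(pos, names))
    basis = compute_basis(mesh)
    npat = min(config.n_background_patterns, n - 1)
    low_bfs = basis.vectors[:, 1 : npat + 1]  # lowest non-constant harmonics

    # ---- clean background: smooth spatial patterns x AR(2) drivers -------
    rng = rngs["background"]
    drivers = np.vstack([_ar2_noise(rng, ns, srate) for _ in range(npat)])
    pattern_gain = 2.0 ** (-np.arange(npat) / 3.0)  # emphasize the smoothest
    bg = low_bfs @ (pattern_gain[:, None] * drivers)
    med = np.median(bg.std(axis=1))
    if med > 0 and config.background_broadband_sd > 0:
        bg *= config.background_broadband_sd / med
    else:
        bg[:] = 0.0

    # ---- alpha rhythm: posterior-weighted, narrowband around 10 Hz -------
    rng = rngs["alpha"]
    if config.background_alpha_power > 0:
        sos = scipy.signal.butter(2, [8.0, 12.0], btype="bandpass", fs=srate, output="sos")
        carrier = scipy.signal.sosfilt(sos, rng.standard_normal(ns))
        sd = carrier.std()
        if sd > 0:
            carrier /= sd
        post = _gauss_weights(pos, np.array([0.0, -0.85, 0.5]), 0.6)
        # project onto the low-order harmonics to keep the background smooth
        coeffs = low_bfs.T @ (basis.mass @ post[:, None])
        pattern = (low_bfs @ coeffs)[:, 0]
        pattern /= np.abs(pattern).max()
        alpha = np.sqrt(config.background_alpha_power) * pattern[:, None] * carrier[None, :]
        bg = bg + alpha

    clean = bg.astype(np.float32).astype(np.float64)

    components: dict[str, np.ndarray] = {}

    # ---- blinks: frontal-dominant low-frequency transients ---------------
    rng = rngs["blink"]
    blink = np.zeros((n, ns))
    w_front = _gauss_weights(pos, np.array([0.0, 0.95, 0.35]), 0.35)
    for onset in _poisson_times(rng, config.blink_rate, config.duration):
        dur = rng.uniform(0.25, 0.40)
        amp = max(80.0, rng.normal(150.0, 30.0))
        i0 = int(onset * srate)
        m = min(int(dur * srate), ns - i0)
        if m <= 2:
            continue
        shape = np.hanning(m) ** 2
        blink[:, i0 : i0 + m] += amp * w_front[:, None] * shape[None, :]
    components["blink"] = blink.astype(np.float32).astype(np.float64)

    # ---- eye movements: dipolar lateral-frontal step-like excursions -----
    rng = rngs["eye_movement"]
    eye = np.zeros((n, ns))
    dip = _gauss_weights(pos, np.array([-0.6, 0.75, 0.3]), 0.35) - _gauss_weights(
        pos, np.array([0.6, 0.75, 0.3]), 0.35
    )
    for onset in _poisson_times(rng, config.eye_movement_rate, config.duration):
        plateau = rng.uniform(0.5, 1.5)
        ramp = 0.15
        amp = rng.choice([-1.0, 1.0]) * rng.normal(60.0, 15.0)
        i0 = int(onset * srate)
        m = min(int((plateau + 2 * ramp) * srate), ns - i0)
        if m <= 4:
            continue
        nr = max(2, int(ramp * srate))
        shape = np.ones(m)
        shape[:nr] = 0.5 * (1 - np.cos(np.pi * np.arange(nr) / nr))
        shape[-nr:] = 0.5 * (1 + np.cos(np.pi * np.arange(nr) / nr))
        eye[:, i0 : i0 + m] += amp * dip[:, None] * shape[None, :]
    components["eye_movement"] = eye.astype(np.float32).astype(np.float64)

    # ---- EMG bursts: 20-70 Hz noise on peripheral channel groups ---------
    rng = rngs["emg"]
    emg = np.zeros((n, ns))
    peripheral = np.flatnonzero(pos[:, 2] < 0.35)
    if peripheral.size == 0:
        peripheral = np.arange(n)
    sos_emg = scipy.signal.butter(4, [20.0, 70.0], btype="bandpass", fs=srate, output="sos")
    for onset in _poisson_times(rng, config.emg_burst_rate, config.duration):
        dur = rng.uniform(0.5, 2.0)
        i0 = int(onset * srate)
        m = min(int(dur * srate), ns - i0)
        if m <= 8:
            continue
        center = pos[rng.choice(peripheral)]
        w = _gauss_weights(pos, center, 0.25)
        carrier = scipy.signal.sosfilt(sos_emg, rng.standard_normal(m))
        sd = carrier.std()
        if sd > 0:
            carrier /= sd
        rms = rng.uniform(15.0, 40.0)
        emg[:, i0 : i0 + m] += rms * w[:, None] * (np.hanning(m) * carrier)[None, :]
    components["emg"] = emg.astype(np.float32).astype(np.float64)

    # ---- cardiac: quasi-periodic biphasic spike train ---------------------
    rng = rngs["cardiac"]
    card = np.zeros((n, ns))
    if config.heart_rate > 0:
        period = 60.0 / config.heart_rate
        spike_m = max(8, int(0.04 * srate))
        ts = np.linspace(-2.5, 2.5, spike_m)
        spike = ts * np.exp(-(ts**2))  # biphasic, ~40 ms
        spike /= np.abs(spike).max()
        # pulse interference is strongest near the temporal/mastoid region
        ear = np.array([-0.95, 0.0, 0.2]) if rng.uniform() < 0.5 else np.array([0.95, 0.0, 0.2])
        pattern = _gauss_weights(pos, ear, 0.45)
        pattern = 15.0 * pattern / np.abs(pattern).max()
        beat = rng.uniform(0.0, period)
        while beat < config.duration:
            i0 = int(beat * srate)
            m = min(spike_m, ns - i0)
            if m > 0:
                card[:, i0 : i0 + m] += pattern[:, None] * spike[None, :m]
            beat += period * rng.uniform(0.95, 1.05)
    components["cardiac"] = card.astype(np.float32).astype(np.float64)

    # ---- sensor noise: spatially uncorrelated ----------------------------
    rng = rngs["sensor_noise"]
    noise = config.sensor_noise_sd * rng.standard_normal((n, ns))
    components["sensor_noise"] = noise.astype(np.float32).astype(np.float64)

    # ---- jumps: step + exponential return on single channels -------------
    rng = rngs["jumps"]
    jumps = np.zeros((n, ns))
    jump_periods: list[ArtifactPeriod] = []
    if config.jump_fraction > 0:
        d0, d1 = config.jump_duration_range
        mean_dur = 0.5 * (d0 + d1)
        rate = config.jump_fraction / (mean_dur * (1.0 + config.jump_neighbor_prob))
        occupied: dict[int, list[tuple[int, int]]] = {ci: [] for ci in range(n)}

        def _free(ci: int, s: int, e: int) -> bool:
            return all(e <= a or s >= b for a, b in occupied[ci])

        def _waveform(m: int, amp: float) -> np.ndarray:
            # step of height `amp` with exponential return (τ = 0.3 s); the
            # fast term shapes a small overshoot while keeping w(0) == amp
            tt = np.arange(m) / srate
            w = amp * (1.12 * np.exp(-tt / 0.3) - 0.12 * np.exp(-tt / 0.05))
            ramp = max(2, int(0.05 * srate))
            if m > ramp:
                w[-ramp:] *= 0.5 * (1 + np.cos(np.pi * np.arange(ramp) / ramp))
            else:
                w *= 0.5 * (1 + np.cos(np.pi * np.arange(m) / m))
            return w

        for ci in range(n):
            tcur = rng.exponential(1.0 / rate)
            while tcur < config.duration:
                dur = rng.uniform(d0, d1)
                s = int(tcur * srate)
                e = min(int((tcur + dur) * srate), ns)
                if e - s > 4 and _free(ci, s, e):
                    amp = rng.uniform(*config.jump_amplitude_range) * rng.choice([-1.0, 1.0])
                    w = _waveform(e - s, amp)
                    jumps[ci, s:e] += w
                    occupied[ci].append((s, e))
                    jump_periods.append(
                        ArtifactPeriod(names[ci], s, e, float(np.abs(w).max()), "manual")
                    )
                    if rng.uniform() < config.jump_neighbor_prob:
                        nb = rng.choice(mesh.vertex_neighbors(ci))
                        if _free(nb, s, e):
                            wn = w * config.jump_neighbor_atten
                            jumps[nb, s:e] += wn
                            occupied[nb].append((s, e))
                            jump_periods.append(
                                ArtifactPeriod(
                                    names[nb], s, e, float(np.abs(wn).max()), "manual"
                                )
                            )
                tcur += dur + rng.exponential(1.0 / rate)
    components["jumps"] = jumps.astype(np.float32).astype(np.float64)
    jump_periods.sort(key=lambda p: (p.channel, p.start))

    gt = GroundTruth(clean=clean, artifact_components=components, jump_periods=jump_periods)
    rec = Recording(
        data=gt.total(), srate=srate, channel_names=names, positions=pos
    )
    return rec, gt


def generate_task_events(
    config: GeneratorConfig, n_runs: int = 1, n_repetitions: int = 10, trial_dur: float = 7.0
) -> list[tuple[str, int]]:
    """Trial markers for the four-task motor paradigm.

    Each run holds ``n_repetitions`` of each task (L, R, T, F) in random
    order; trials last ``trial_dur`` seconds with uniform 0.5–2.5 s
    inter-trial gaps.  Raises ``ValueError`` if the configured duration
    cannot hold all trials.
    """
    rng = _substreams(config.seed)["events"]
    events: list[tuple[str, int]] = []
    tcur = 0.0
    for _ in range(n_runs):
        labels = np.repeat(TASK_LABELS, n_repetitions)
        rng.shuffle(labels)
        for label in labels:
            if tcur + trial_dur > config.duration:
                raise ValueError(
                    "recording duration too short for the requested trials"
                )
            events.append((str(label), int(tcur * config.srate)))
            tcur += trial_dur + rng.uniform(0.5, 2.5)
    return events
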