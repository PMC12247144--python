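"""Artifactual-period zeroing (AP0).

Dry-electrode recordings contain transient high-amplitude jumps (electrode
movement/settling) on single channels or small groups of nearby channels.
Any spatial filter mixes channels, so such a jump smears into its
neighbors with reduced amplitude.  AP0 prevents this: jump periods are set
to 0 V (with a 0.5 s Hann taper for smooth transitions) *before* spatial
filtering, and the affected channel spans are re-estimated from the other
channels by spherical-spline interpolation *afterwards*.

Detection follows explicit amplitude rules: a period is seeded where the
signal exceeds ``jump_thresh`` (150 μV), starts 200 ms before the first
threshold crossing (extended further back while the signal is already
outside ±``stable_band``), and ends at the first sample from which the
signal stays within ±80 μV for at least 200 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import spherical_spline_matrix
from .recording import Recording
from .sensor_mesh import SensorMesh

__all__ = [
    "ArtifactPeriod",
    "detect_ap0",
    "apply_zeroing",
    "interpolate_ap0_spans",
    "merge_periods",
    "read_periods_tsv",
    "write_periods_tsv",
]


@dataclass
class ArtifactPeriod:
    """Half-open high-amplitude-jump interval ``[start, end)`` on one channel."""

    channel: str
    start: int
    end: int
    peak_amplitude: float = 0.0
    source: str = "detected"  # or "manual"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid period [{self.start}, {self.end})")

    @property
    def n_samples(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "ArtifactPeriod", gap: int = 0) -> bool:
        return self.channel == other.channel and (
            self.start < other.end + gap and other.start < self.end + gap
        )


def merge_periods(periods: list[ArtifactPeriod], gap: int = 0) -> list[ArtifactPeriod]:
    """Merge per-channel periods closer than ``gap`` samples (or overlapping)."""
    out: list[ArtifactPeriod] = []
    by_channel: dict[str, list[ArtifactPeriod]] = {}
    for p in periods:
        by_channel.setdefault(p.channel, []).append(p)
    for ch in by_channel:
        ps = sorted(by_channel[ch], key=lambda p: p.start)
        cur = ps[0]
        for p in ps[1:]:
            if p.start < cur.end + gap:
                cur = ArtifactPeriod(
                    ch,
                    cur.start,
                    max(cur.end, p.end),
                    max(cur.peak_amplitude, p.peak_amplitude),
                    cur.source if cur.source == p.source else "detected",
                )
            else:
                out.append(cur)
                cur = p
        out.append(cur)
    out.sort(key=lambda p: (p.channel, p.start))
    return out


def detect_ap0(
    rec: Recording,
    jump_thresh: float = 150.0,
    stable_band: float = 80.0,
    pre_onset: float = 200.0,
    stable_dur: float = 200.0,
    merge_gap: float | None = 500.0,
) -> list[ArtifactPeriod]:
    """Detect high-amplitude jump periods channel by channel.

    Parameters
    ----------
    jump_thresh, stable_band : float
        Amplitude thresholds in μV (seed exceedance / return-to-normal band).
    pre_onset, stable_dur : float
        Times in ms: onset margin before the first crossing, and the
        duration the signal must stay within ±``stable_band`` to end a
        period.
    merge_gap : float or None
        Periods separated by less than this many ms are merged (so that
        taper zones of adjacent periods cannot overlap); ``None`` disables.
    """
    n = rec.n_samples
    pre_n = int(round(pre_onset * rec.srate / 1000.0))
    stab_n = max(1, int(round(stable_dur * rec.srate / 1000.0)))
    periods: list[ArtifactPeriod] = []
    for ci, name in enumerate(rec.channel_names):
        x = np.abs(rec.data[ci])
        exceed = np.flatnonzero(x > jump_thresh)
        if exceed.size == 0:
            continue
        within = x <= stable_band
        # stable[t] == True when samples [t, t + stab_n) are all within band;
        # a trailing window shorter than stab_n counts if fully within band
        cnt = np.convolve(within.astype(np.int64), np.ones(stab_n, np.int64))[
            stab_n - 1 : stab_n - 1 + n
        ]
        full = np.arange(n) <= n - stab_n
        need = np.where(full, stab_n, n - np.arange(n))
        stable_start = np.flatnonzero(cnt >= need)
        pos = 0
        while pos < exceed.size:
            i = exceed[pos]
            start = max(0, i - pre_n)
            while start > 0 and not within[start]:
                start -= 1
            j = np.searchsorted(stable_start, i + 1)
            end = int(stable_start[j]) if j < stable_start.size else n
            periods.append(
                ArtifactPeriod(
                    channel=name,
                    start=int(start),
                    end=end,
                    peak_amplitude=float(x[start:end].max()),
                    source="detected",
                )
            )
            pos = np.searchsorted(exceed, end)
    if merge_gap is not None:
        periods = merge_periods(periods, gap=int(round(merge_gap * rec.srate / 1000.0)))
    return periods


def apply_zeroing(
    rec: Recording, periods: list[ArtifactPeriod], taper: float = 0.5
) -> Recording:
    """Set period cores to exactly 0 μV with half-Hann fades on both sides.

    The 0.5 s Hann window is split into a ``taper/2`` fade-out ending at
    ``start`` and a ``taper/2`` fade-in beginning at ``end``; both are
    multiplicative on the original signal and truncated at the recording
    bounds.  Samples outside period ∪ taper zones are bit-identical to the
    input.  A period whose core is already identically zero is skipped, so
    re-applying the same periods is an exact no-op (idempotence).
    """
    out = rec.copy()
    half = int(round(taper / 2.0 * rec.srate))
    n = rec.n_samples
    for p in periods:
        try:
            ci = rec.channel_index(p.channel)
        except KeyError:
            raise KeyError(f"period channel {p.channel!r} not in recording") from None
        s, e = max(0, p.start), min(n, p.end)
        if s >= e:
            continue
        x = out.data[ci]
        if not np.any(x[s:e]):
            continue  # already zeroed: keep the operation idempotent
        if half > 0:
            lo = max(0, s - half)
            k = np.arange(lo, s)
            x[lo:s] *= 0.5 * (1.0 + np.cos(np.pi * (k - (s - half)) / half))
            hi = min(n, e + half)
            k = np.arange(e, hi)
            x[e:hi] *= 0.5 * (1.0 - np.cos(np.pi * (k - e + 1) / half))
        x[s:e] = 0.0
    return out


def interpolate_ap0_spans(
    rec_filtered: Recording,
    periods: list[ArtifactPeriod],
    mesh: SensorMesh | None = None,
    neighbors: str = "all",
) -> Recording:
    """Replace each period's span by spherical-spline estimates from the
    surrounding channels (applied to the spatially filtered signal).

    ``neighbors="mesh"`` restricts the interpolation sources to the mesh
    neighbors of the affected channel (requires ``mesh``); the default uses
    all other channels.
    """
    if neighbors not in ("all", "mesh"):
        raise ValueError("neighbors must be 'all' or 'mesh'")
    if neighbors == "mesh" and mesh is None:
        raise ValueError("mesh required for neighbors='mesh'")
    out = rec_filtered.copy()
    ops: dict[str, np.ndarray] = {}
    for p in periods:
        ci = rec_filtered.channel_index(p.channel)  # KeyError if absent
        if p.channel not in ops:
            if neighbors == "mesh":
                src = mesh.vertex_neighbors(ci).tolist()
            else:
                src = [i for i in range(rec_filtered.n_channels) if i != ci]
            if len(src) < 3:
                raise ValueError(
                    f"not enough source channels to interpolate {p.channel!r}"
                )
            A = spherical_spline_matrix(
                rec_filtered.positions[src], rec_filtered.positions[ci]
            )
            ops[p.channel] = (np.asarray(src), A)
        src, A = ops[p.channel]
        s, e = max(0, p.start), min(rec_filtered.n_samples, p.end)
        if s < e:
            out.data[ci, s:e] = (A @ rec_filtered.data[src, s:e])[0]
    return out


def read_periods_tsv(path) -> list[ArtifactPeriod]:
    """Read a tab-separated annotation file
    (``channel<TAB>start_sample<TAB>end_sample<TAB>source``, '#' comments)."""
    periods = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            ch, s, e = parts[0], int(parts[1]), int(parts[2])
            source = parts[3] if len(parts) > 3 else "manual"
            periods.append(ArtifactPeriod(ch, s, e, source=source))
    return periods


def write_periods_tsv(periods: list[ArtifactPeriod], path) -> None:
    with open(path, "w") as fh:
        fh.write("# channel\tstart_sample\tend_sample\tsource\n")
        for p in periods:
            fh.write(f"{p.channel}\t{p.start}\t{p.end}\t{p.source}\n")
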