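"""File I/O: EDF and BrainVision recordings, montage files, ground-truth
sidecars.

Readers go through :mod:`mne.io`; data are converted to the package's
internal convention (μV, channels × samples).  Writers produce BrainVision
(.vhdr/.vmrk/.eeg, IEEE float32 multiplexed) and plain EDF (16-bit) files
directly, plus whitespace-delimited montage files (``name x y z`` per
line) and JSON/NPZ ground-truth sidecars.
"""

from __future__ import annotations

import datetime as _dt
import json
import os

import numpy as np

from .ap0 import ArtifactPeriod
from .recording import Recording
from .synthetic_eeg import GroundTruth

__all__ = [
    "read_montage",
    "write_montage",
    "read_raw",
    "write_brainvision",
    "write_edf",
    "save_ground_truth",
    "load_ground_truth",
]


# ---------------------------------------------------------------------------
# Montage files

def read_montage(path) -> tuple[list[str], np.ndarray]:
    """Read ``name x y z`` per line ('#' comments allowed)."""
    names, rows = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            names.append(parts[0])
            rows.append([float(v) for v in parts[1:4]])
    return names, np.asarray(rows, float)


def write_montage(path, names: list[str], positions: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write("# name x y z\n")
        for name, p in zip(names, np.asarray(positions, float)):
            fh.write(f"{name} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


# ---------------------------------------------------------------------------
# Readers (via mne)

def read_raw(path, montage=None) -> Recording:
    """Read a BrainVision (.vhdr) or EDF (.edf) recording.

    ``montage`` is a montage file path or an ``(names, positions)`` pair;
    positions default to zeros when no montage is given (mesh-based stages
    then require one).  Event markers are taken from the annotations,
    stripping any BrainVision ``Stimulus/`` prefix.
    """
    import mne

    path = os.fspath(path)
    if path.lower().endswith(".vhdr"):
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose=False)
    elif path.lower().endswith((".edf", ".bdf")):
        raw = mne.io.read_raw_edf(path, preload=True, verbose=False)
    else:
        raise ValueError(f"unsupported recording format: {path}")
    data = raw.get_data() * 1e6  # V -> μV
    names = list(raw.ch_names)
    if montage is None:
        positions = np.zeros((len(names), 3))
    else:
        mnames, mpos = read_montage(montage) if isinstance(montage, (str, os.PathLike)) else montage
        lookup = {n: p for n, p in zip(mnames, mpos)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise ValueError(f"montage missing channels: {missing}")
        positions = np.array([lookup[n] for n in names])
    events = []
    for ann in raw.annotations:
        desc = ann["description"]
        if desc.startswith("Stimulus/"):
            desc = desc.split("/", 1)[1]
        if desc.startswith("New Segment"):
            continue
        onset = int(round(ann["onset"] * raw.info["sfreq"]))
        if 0 <= onset < data.shape[1]:
            events.append((desc.strip(), onset))
    return Recording(
        data=data,
        srate=float(raw.info["sfreq"]),
        channel_names=names,
        positions=positions,
        events=events,
    )


# ---------------------------------------------------------------------------
# BrainVision writer

def write_brainvision(rec: Recording, basename) -> None:
    """Write ``<basename>.vhdr/.vmrk/.eeg`` (IEEE float32, multiplexed, μV)."""
    basename = os.fspath(basename)
    base = os.path.basename(basename)
    with open(basename + ".vhdr", "w", encoding="utf-8") as fh:
        fh.write("Brain Vision Data Exchange Header File Version 1.0\n")
        fh.write("[Common Infos]\nCodepage=UTF-8\n")
        fh.write(f"DataFile={base}.eeg\nMarkerFile={base}.vmrk\n")
        fh.write("DataFormat=BINARY\nDataOrientation=MULTIPLEXED\n")
        fh.write(f"NumberOfChannels={rec.n_channels}\n")
        fh.write(f"SamplingInterval={1e6 / rec.srate:.10g}\n")
        fh.write("[Binary Infos]\nBinaryFormat=IEEE_FLOAT_32\n")
        fh.write("[Channel Infos]\n")
        for i, name in enumerate(rec.channel_names):
            fh.write(f"Ch{i + 1}={name},,1,µV\n")
    with open(basename + ".vmrk", "w", encoding="utf-8") as fh:
        fh.write("Brain Vision Data Exchange Marker File, Version 1.0\n")
        fh.write("[Common Infos]\nCodepage=UTF-8\n")
        fh.write(f"DataFile={base}.eeg\n[Marker Infos]\n")
        fh.write("Mk1=New Segment,,1,1,0,00000000000000000000\n")
        for k, (label, onset) in enumerate(rec.events):
            fh.write(f"Mk{k + 2}=Stimulus,{label},{onset + 1},1,0\n")
    rec.data.T.astype("<f4").tofile(basename + ".eeg")


# ---------------------------------------------------------------------------
# EDF writer

def _edf_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path) -> None:
    """Write a plain EDF file (16-bit, 1-second data records, μV).

    The last record is zero-padded when the length is not a whole number
    of seconds; event markers are not stored (use the BrainVision writer
    or a sidecar for those).
    """
    srate = int(round(rec.srate))
    if abs(srate - rec.srate) > 1e-6:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_ch = rec.n_channels
    spr = srate  # samples per 1 s record
    n_rec = int(np.ceil(rec.n_samples / spr))
    # round up to the 2-decimal precision stored in the header so the
    # reader's scaling matches the writer's exactly
    phys_max = np.ceil(np.maximum(np.abs(rec.data).max(axis=1), 1.0) * 100) / 100
    phys_min = -phys_max
    dig_max, dig_min = 32767, -32768

    now = _dt.datetime(2000, 1, 1)
    header = b""
    header += _edf_field("0", 8)
    header += _edf_field("X X X X", 80)
    header += _edf_field("Startdate X X X X", 80)
    header += _edf_field(now.strftime("%d.%m.%y"), 8)
    header += _edf_field(now.strftime("%H.%M.%S"), 8)
    header += _edf_field(256 * (1 + n_ch), 8)
    header += _edf_field("", 44)
    header += _edf_field(n_rec, 8)
    header += _edf_field(1, 8)
    header += _edf_field(n_ch, 4)
    for name in rec.channel_names:
        header += _edf_field(name, 16)
    header += b"".join(_edf_field("", 80) for _ in range(n_ch))
    header += b"".join(_edf_field("uV", 8) for _ in range(n_ch))
    header += b"".join(_edf_field(f"{v:.2f}", 8) for v in phys_min)
    header += b"".join(_edf_field(f"{v:.2f}", 8) for v in phys_max)
    header += b"".join(_edf_field(dig_min, 8) for _ in range(n_ch))
    header += b"".join(_edf_field(dig_max, 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 80) for _ in range(n_ch))
    header += b"".join(_edf_field(spr, 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 32) for _ in range(n_ch))

    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, : rec.n_samples] = rec.data
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.round((padded - phys_min[:, None]) * scale[:, None] + dig_min),
        dig_min,
        dig_max,
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


# ---------------------------------------------------------------------------
# Ground-truth sidecars

def save_ground_truth(gt: GroundTruth, basename) -> None:
    """``<basename>.json`` (annotations) + ``<basename>.npz`` (arrays)."""
    basename = os.fspath(basename)
    meta = {
        "components": list(gt.artifact_components),
        "jump_periods": [
            {
                "channel": p.channel,
                "start": p.start,
                "end": p.end,
                "peak_amplitude": p.peak_amplitude,
                "source": p.source,
            }
            for p in gt.jump_periods
        ],
    }
    with open(basename + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)
    arrays = {"clean": gt.clean}
    arrays.update({f"component_{k}": v for k, v in gt.artifact_components.items()})
    np.savez_compressed(basename + ".npz", **arrays)


def load_ground_truth(basename) -> GroundTruth:
    basename = os.fspath(basename)
    with open(basename + ".json") as fh:
        meta = json.load(fh)
    with np.load(basename + ".npz") as npz:
        clean = npz["clean"]
        comps = {k: npz[f"component_{k}"] for k in meta["components"]}
    periods = [
        ArtifactPeriod(
            d["channel"], d["start"], d["end"], d.get("peak_amplitude", 0.0), d.get("source", "manual")
        )
        for d in meta["jump_periods"]
    ]
    return GroundTruth(clean=clean, artifact_components=comps, jump_periods=periods)
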