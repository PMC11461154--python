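"""Domain containers for multichannel EEG analysis and their file formats.

The analysis operates on four kinds of objects: a :class:`Recording`
(channel-major voltage matrix with sampling rate and labels), an
:class:`EventStream` (timestamped stimulus/rest triggers), a
:class:`Montage` (2-D scalp coordinates plus the ordered region-of-interest
electrode list), and a :class:`CohortManifest` mapping participants to
groups and epochs to experimental conditions.

Interchange formats are deliberately boring: EDF for recordings (the one
format every EEG toolbox reads), a lossless ``.npz`` container for exact
round trips, CSV for events and montages, YAML for manifests.

Conventions: time is float seconds from recording start, sample indexing is
0-based, and all windows are half-open ``[start, stop)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DeltaSyncError",
    "MontageError",
    "FormatError",
    "BoundsError",
    "StateError",
    "DesignError",
    "Recording",
    "Event",
    "EventStream",
    "Montage",
    "ElectrodePair",
    "CohortManifest",
    "DEFAULT_ROI",
    "default_montage",
    "electrode_pairs",
    "read_recording",
    "write_recording",
    "slice_epoch",
    "read_events",
    "write_events",
    "read_montage",
    "write_montage",
    "read_manifest",
    "write_manifest",
    "CONDITIONS",
    "REST_STATES",
]


class DeltaSyncError(Exception):
    """Base class for all package errors."""


class MontageError(DeltaSyncError):
    """Montage/ROI is unusable (too few electrodes, unknown channel...)."""


class FormatError(DeltaSyncError):
    """A file does not parse under the named standard, or units mismatch."""


class BoundsError(DeltaSyncError):
    """A requested time span falls outside the recording."""


class StateError(DeltaSyncError):
    """Operation applied to data in the wrong processing state."""


class DesignError(DeltaSyncError):
    """Experimental design table is incomplete or inconsistent."""


#: The four stimulus condition cells of the 2 (posture) x 2 (style) design.
CONDITIONS = (
    "Symbolic-Sitting",
    "Geometric-Sitting",
    "Symbolic-Standing",
    "Geometric-Standing",
)

#: Baseline (rest) states: posture x eyes open/closed.
REST_STATES = ("sit-open", "sit-closed", "stand-open", "stand-closed")

#: The 12 fronto-parietal analysis electrodes, in canonical order.
DEFAULT_ROI = (
    "F3", "Fz", "F4", "FCz", "Cz", "CP3",
    "CP4", "P1", "Pz", "P2", "PPO1", "PPO2",
)

# Cap indices of the ROI electrodes in the 128-channel layout, and
# approximate 2-D scalp coordinates (unit head radius, x: left-, y: front+).
_DEFAULT_ENTRIES = {
    "F3": (5, (-0.40, 0.60)),
    "Fz": (6, (0.00, 0.60)),
    "F4": (7, (0.40, 0.60)),
    "FCz": (42, (0.00, 0.40)),
    "Cz": (16, (0.00, 0.00)),
    "CP3": (48, (-0.45, -0.20)),
    "CP4": (49, (0.45, -0.20)),
    "P1": (51, (-0.20, -0.55)),
    "Pz": (26, (0.00, -0.55)),
    "P2": (52, (0.20, -0.55)),
    "PPO1": (92, (-0.15, -0.72)),
    "PPO2": (93, (0.15, -0.72)),
}


@dataclass
class Recording:
    """Channel-major EEG voltage matrix.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    rate
        Sampling frequency in Hz, > 0.
    labels
        Ordered unique channel names, one per row of ``data``.
    reference
        ``"raw"`` or ``"common_average"``.
    band
        Optional band tag: ``"broadband"``, ``"delta"``, ``"theta"``,
        ``"alpha"`` or ``None`` for unfiltered data.
    """

    data: np.ndarray
    rate: float
    labels: tuple
    reference: str = "raw"
    band: str | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        self.labels = tuple(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not self.rate > 0:
            raise ValueError("sampling rate must be > 0")
        if self.reference not in ("raw", "common_average"):
            raise ValueError(f"unknown reference tag {self.reference!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def channel(self, name: str) -> np.ndarray:
        """Return one channel by exact (case-sensitive) name."""
        try:
            return self.data[self.labels.index(name)]
        except ValueError:
            raise KeyError(f"no channel named {name!r}") from None

    def copy_with(self, **kwargs) -> "Recording":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Event:
    time_s: float
    label: str
    duration_s: float = 0.0


@dataclass
class EventStream:
    """Ordered list of timestamped triggers (onsets in seconds)."""

    events: list

    def __post_init__(self):
        self.events = [
            e if isinstance(e, Event) else Event(*e) for e in self.events
        ]
        times = [e.time_s for e in self.events]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("event times must be non-decreasing")
        if any(e.time_s < 0 or e.duration_s < 0 for e in self.events):
            raise ValueError("event times and durations must be >= 0")

    def __iter__(self):
        return iter(self.events)

    def __len__(self):
        return len(self.events)

    def with_label_prefix(self, prefix: str) -> list:
        return [e for e in self.events if e.label.startswith(prefix)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": [e.time_s for e in self.events],
                "label": [e.label for e in self.events],
                "duration_s": [e.duration_s for e in self.events],
            }
        )


@dataclass
class Montage:
    """Channel positions plus the ordered analysis ROI.

    ``entries`` maps channel name to ``(cap_index, (x, y))``; ``roi`` is the
    ordered electrode list actually analysed and must be a subset of
    ``entries``.
    """

    entries: dict
    roi: tuple = DEFAULT_ROI

    def __post_init__(self):
        self.roi = tuple(self.roi)
        missing = [ch for ch in self.roi if ch not in self.entries]
        if missing:
            raise MontageError(f"ROI channels missing from montage: {missing}")

    def position(self, name: str) -> np.ndarray:
        return np.asarray(self.entries[name][1], dtype=float)


def default_montage() -> Montage:
    """The 12-electrode fronto-parietal montage used throughout."""
    return Montage(entries=dict(_DEFAULT_ENTRIES), roi=DEFAULT_ROI)


class ElectrodePair(tuple):
    """Unordered electrode pair stored in canonical (ROI) order."""

    __slots__ = ()

    def __new__(cls, a: str, b: str):
        if a == b:
            raise ValueError("electrode pair must join two distinct channels")
        return super().__new__(cls, (a, b))

    @property
    def a(self) -> str:
        return self[0]

    @property
    def b(self) -> str:
        return self[1]

    def __repr__(self):
        return f"{self[0]}-{self[1]}"


def electrode_pairs(montage: Montage) -> list:
    """All unordered ROI electrode pairs in canonical order.

    For the default 12-electrode ROI this yields the 66 pairs entering the
    synchrony comparison; in general ``C(n, 2)`` pairs for an ``n``-electrode
    ROI, each appearing exactly once with ``a`` preceding ``b`` in ROI order.
    """
    roi = montage.roi
    if len(roi) < 2:
        raise MontageError("ROI must contain at least 2 electrodes")
    return [
        ElectrodePair(roi[i], roi[j])
        for i in range(len(roi))
        for j in range(i + 1, len(roi))
    ]


# ---------------------------------------------------------------------------
# Epoching
# ---------------------------------------------------------------------------

def slice_epoch(rec: Recording, onset_s: float, duration_s: float) -> Recording:
    """Sample-accurate half-open slice ``[onset, onset + duration)``.

    The first sample is ``floor(onset * rate)``; adjacent epochs therefore
    never share samples.
    """
    if onset_s < 0 or duration_s < 0:
        raise BoundsError("onset and duration must be >= 0")
    # floor at both ends (with a float guard) so abutting epochs tile the
    # recording exactly, sharing no samples
    start = int(np.floor(onset_s * rec.rate + 1e-9))
    stop = int(np.floor((onset_s + duration_s) * rec.rate + 1e-9))
    if stop > rec.n_samples:
        raise BoundsError(
            f"epoch [{onset_s}, {onset_s + duration_s}) s exceeds recording "
            f"duration {rec.duration_s:.3f} s"
        )
    return rec.copy_with(data=rec.data[:, start:stop].copy())


# ---------------------------------------------------------------------------
# Recording I/O: lossless npz container and 16-bit EDF
# ---------------------------------------------------------------------------

_CONTAINER_KEYS = {"data", "rate", "labels", "reference", "band"}


def _write_container(rec: Recording, path: str) -> None:
    np.savez(
        path,
        data=rec.data,
        rate=np.float64(rec.rate),
        labels=np.array(rec.labels, dtype=object),
        reference=np.str_(rec.reference),
        band=np.str_(rec.band if rec.band is not None else ""),
    )


def _read_container(path: str) -> Recording:
    try:
        with np.load(path, allow_pickle=True) as z:
            if not _CONTAINER_KEYS.issubset(z.files):
                raise FormatError(
                    f"{path}: container missing keys "
                    f"{sorted(_CONTAINER_KEYS - set(z.files))}"
                )
            band = str(z["band"])
            return Recording(
                data=z["data"],
                rate=float(z["rate"]),
                labels=[str(x) for x in z["labels"]],
                reference=str(z["reference"]),
                band=band if band else None,
            )
    except (OSError, ValueError) as exc:
        raise FormatError(f"{path}: not a readable container file: {exc}")


def _edf_field(value, width: int) -> bytes:
    s = f"{value}"
    if len(s) > width:
        # keep numeric fields parseable when truncated
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _write_edf(rec: Recording, path: str) -> None:
    """Minimal EDF writer: 16-bit samples, 1-second data records.

    The physical range is taken from the data (symmetric, in µV); the last
    record is zero-padded when the recording length is not an integer number
    of seconds. EDF stores integer samples-per-record, so ``rate`` must be
    an integer.
    """
    if abs(rec.rate - round(rec.rate)) > 1e-9:
        raise FormatError("EDF writer requires an integer sampling rate")
    rate = int(round(rec.rate))
    n_ch = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / rate)) if rec.n_samples else 0

    pmax = float(np.max(np.abs(rec.data))) if rec.data.size else 1.0
    if pmax == 0:
        pmax = 1.0
    pmin = -pmax
    dmin, dmax = -32768, 32767

    header = b""
    header += _edf_field("0", 8)                      # version
    header += _edf_field("X X X X", 80)               # patient id
    header += _edf_field(f"Startdate X {rec.reference} {rec.band or 'none'}", 80)
    header += _edf_field("01.01.00", 8)               # start date
    header += _edf_field("00.00.00", 8)               # start time
    header += _edf_field(256 * (1 + n_ch), 8)         # header bytes
    header += _edf_field("", 44)                      # reserved
    header += _edf_field(n_rec, 8)                    # n data records
    header += _edf_field(1, 8)                        # record duration (s)
    header += _edf_field(n_ch, 4)                     # n signals
    for lab in rec.labels:
        header += _edf_field(lab, 16)
    header += b"".join(_edf_field("EEG", 80) for _ in range(n_ch))
    header += b"".join(_edf_field("uV", 8) for _ in range(n_ch))
    header += b"".join(_edf_field(f"{pmin:.8g}"[:8], 8) for _ in range(n_ch))
    header += b"".join(_edf_field(f"{pmax:.8g}"[:8], 8) for _ in range(n_ch))
    header += b"".join(_edf_field(dmin, 8) for _ in range(n_ch))
    header += b"".join(_edf_field(dmax, 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 80) for _ in range(n_ch))
    header += b"".join(_edf_field(rate, 8) for _ in range(n_ch))
    header += b"".join(_edf_field("", 32) for _ in range(n_ch))

    scale = (dmax - dmin) / (pmax - pmin)
    padded = np.zeros((n_ch, n_rec * rate))
    padded[:, : rec.n_samples] = rec.data
    digital = np.clip(
        np.round((padded - pmin) * scale + dmin), dmin, dmax
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            fh.write(digital[:, r * rate : (r + 1) * rate].tobytes())


def edf_quantization_step(rec: Recording) -> float:
    """Physical value of one digital unit for the EDF written from ``rec``."""
    pmax = float(np.max(np.abs(rec.data))) if rec.data.size else 1.0
    if pmax == 0:
        pmax = 1.0
    return 2 * pmax / (32767 - (-32768))


def _read_edf(path: str) -> Recording:
    import mne

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as exc:  # mne raises assorted types on malformed files
        raise FormatError(f"{path}: EDF parse failed: {exc}")
    units = set()
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        if len(hdr) < 256:
            raise FormatError(f"{path}: truncated EDF header at offset {len(hdr)}")
        n_ch = int(hdr[252:256].decode("ascii", "replace").strip() or 0)
        sig = fh.read(256 * n_ch)
        if len(sig) < 256 * n_ch:
            raise FormatError(
                f"{path}: truncated EDF signal headers at offset {256 + len(sig)}"
            )
        off = n_ch * (16 + 80)
        for c in range(n_ch):
            units.add(sig[off + 8 * c : off + 8 * (c + 1)].decode("ascii").strip())
        rdesc = hdr[88:168].decode("ascii", "replace").split()
    if units - {"uV", "mV", "V", ""}:
        raise FormatError(f"{path}: unsupported physical units {sorted(units)}")
    reference = "raw"
    band = None
    if len(rdesc) >= 3 and rdesc[2] in ("raw", "common_average"):
        reference = rdesc[2]
        if len(rdesc) >= 4 and rdesc[3] != "none":
            band = rdesc[3]
    data_uv = raw.get_data() * 1e6  # mne returns volts
    return Recording(
        data=data_uv,
        rate=float(raw.info["sfreq"]),
        labels=list(raw.ch_names),
        reference=reference,
        band=band,
    )


def write_recording(rec: Recording, path: str, format: str = "edf") -> str:
    """Write a recording as EDF (16-bit, portable) or npz container (exact)."""
    if format == "edf":
        _write_edf(rec, path)
    elif format == "container":
        _write_container(rec, path)
    else:
        raise ValueError(f"unknown recording format {format!r}")
    return path


def read_recording(path: str, format: str | None = None) -> Recording:
    """Read a recording; format inferred from the extension when omitted."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format is None:
        format = "container" if path.endswith(".npz") else "edf"
    if format == "edf":
        return _read_edf(path)
    if format == "container":
        return _read_container(path)
    raise ValueError(f"unknown recording format {format!r}")


# ---------------------------------------------------------------------------
# Event / montage / manifest I/O
# ---------------------------------------------------------------------------

def write_events(stream: EventStream, path: str) -> str:
    stream.to_frame().to_csv(path, index=False)
    return path


def read_events(path: str) -> EventStream:
    df = pd.read_csv(path)
    expected = ["time_s", "label", "duration_s"]
    if list(df.columns) != expected:
        raise FormatError(
            f"{path}: expected event columns {expected}, got {list(df.columns)}"
        )
    return EventStream(
        [Event(float(r.time_s), str(r.label), float(r.duration_s))
         for r in df.itertuples()]
    )


def write_montage(montage: Montage, path: str) -> str:
    rows = [
        {"name": name, "index": idx, "x": xy[0], "y": xy[1]}
        for name, (idx, xy) in montage.entries.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_montage(path: str, roi=DEFAULT_ROI) -> Montage:
    df = pd.read_csv(path)
    entries = {
        str(r.name): (int(r.index), (float(r.x), float(r.y)))
        for r in df.itertuples(index=False)
    }
    return Montage(entries=entries, roi=roi)


@dataclass
class CohortManifest:
    """Group assignment and the epoch -> condition map for every participant."""

    participants: list = field(default_factory=list)  # (id, group)
    epochs: dict = field(default_factory=dict)  # id -> [(event label, condition)]

    def __post_init__(self):
        for pid, group in self.participants:
            if group not in ("expert", "novice"):
                raise ValueError(f"unknown group {group!r} for {pid}")

    def group_of(self, pid: str) -> str:
        for p, g in self.participants:
            if p == pid:
                return g
        raise KeyError(pid)

    def condition_of(self, pid: str, label: str) -> str:
        for lab, cond in self.epochs.get(pid, []):
            if lab == label:
                return cond
        raise KeyError((pid, label))

    def validate_design(self, n_per_cell: int = 4) -> None:
        """Check each participant has ``n_per_cell`` epochs per condition."""
        for pid, _ in self.participants:
            conds = [c for _, c in self.epochs.get(pid, []) if c in CONDITIONS]
            for cond in CONDITIONS:
                n = conds.count(cond)
                if n != n_per_cell:
                    raise DesignError(
                        f"participant {pid}: {n} epochs in cell {cond}, "
                        f"expected {n_per_cell}"
                    )


def write_manifest(manifest: CohortManifest, path: str) -> str:
    doc = {
        "participants": [
            {"id": pid, "group": group} for pid, group in manifest.participants
        ],
        "epochs": {
            pid: [{"label": lab, "condition": cond} for lab, cond in items]
            for pid, items in manifest.epochs.items()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


def read_manifest(path: str) -> CohortManifest:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        return CohortManifest(
            participants=[(p["id"], p["group"]) for p in doc["participants"]],
            epochs={
                pid: [(e["label"], e["condition"]) for e in items]
                for pid, items in doc.get("epochs", {}).items()
            },
        )
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: malformed manifest: {exc}")
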