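"""Hilbert phase extraction and windowed phase-synchrony values (PSV).

The synchrony statistic is the classical 1:1 phase-locking value: for two
band-limited channels with instantaneous Hilbert phases phi_a(t), phi_b(t),

    PLV = | mean_t exp(i * (phi_a(t) - phi_b(t))) |

i.e. the mean resultant length of the phase difference over a window. A PSV
of 1 means rigid locking (any fixed lag), values near 1/sqrt(N) are chance.

Two stimulus segmentation schemes are supported: ``whole_stimuli`` (5-s
windows, 50% overlap, skipping the first 2 s and last 1 s of each epoch --
a 54-s epoch yields 19 windows over 2-53 s) and ``first_two_seconds``
(0.5-s windows, 50% overlap, over 250-2000 ms from onset: 6 windows).
Rest spans use 5-s windows with 50% overlap over the whole span.

Window PSVs are averaged per epoch, epoch PSVs per condition, so every
participant ends with one PSV per condition per electrode pair. Phase is
always computed once on the full epoch and windowed afterwards, keeping
analytic-signal edge artifacts out of the short windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig
from scipy.fft import next_fast_len

from .core_data import DeltaSyncError, Recording

__all__ = [
    "PhaseSeries",
    "SegmentScheme",
    "WHOLE_STIMULI",
    "FIRST_TWO_SECONDS",
    "REST",
    "SCHEMES",
    "EpochSkipped",
    "MissingCellError",
    "BandRequiredError",
    "instantaneous_phase",
    "phase_matrix",
    "plv",
    "segment_windows",
    "psv_epoch",
    "psv_epoch_matrix",
    "aggregate_condition",
    "psv_rest",
]


class BandRequiredError(DeltaSyncError):
    """Phase extraction demands band-limited input."""


class EpochSkipped(DeltaSyncError):
    """An epoch was too short for its segmentation scheme."""

    def __init__(self, epoch_id, message=""):
        self.epoch_id = epoch_id
        super().__init__(message or f"epoch {epoch_id!r} skipped: no windows fit")


class MissingCellError(DeltaSyncError):
    """A participant x condition cell has no usable epochs."""


@dataclass
class PhaseSeries:
    """Per-sample instantaneous phase in radians, wrapped to (-pi, pi]."""

    phases: np.ndarray
    rate: float
    band: str


@dataclass(frozen=True)
class SegmentScheme:
    """Windowing rule applied inside an epoch.

    The analysis span runs from ``start_offset_s`` after epoch onset to
    ``end_offset_s`` before epoch end (``end_offset_s <= 0``), unless
    ``fixed_end_s`` pins the span end at an absolute offset from onset.
    Windows of ``window_s`` seconds advance by ``window_s * (1 -
    overlap_frac)``; trailing partial windows are dropped.
    """

    name: str
    start_offset_s: float
    end_offset_s: float
    window_s: float
    overlap_frac: float
    fixed_end_s: float | None = None

    def __post_init__(self):
        if not self.window_s > 0:
            raise ValueError("window_s must be > 0")
        if not 0 <= self.overlap_frac < 1:
            raise ValueError("overlap_frac must be in [0, 1)")
        if self.end_offset_s > 0:
            raise ValueError("end_offset_s is measured from epoch end, <= 0")


WHOLE_STIMULI = SegmentScheme("whole_stimuli", 2.0, -1.0, 5.0, 0.5)
FIRST_TWO_SECONDS = SegmentScheme("first_two_seconds", 0.25, 0.0, 0.5, 0.5,
                                  fixed_end_s=2.0)
REST = SegmentScheme("rest", 0.0, 0.0, 5.0, 0.5)

SCHEMES = {s.name: s for s in (WHOLE_STIMULI, FIRST_TWO_SECONDS, REST)}

_EPS = 1e-9  # float guard so e.g. 1.5 + 0.5 <= 2.0 counts as inside


def segment_windows(epoch_duration_s: float, scheme: SegmentScheme):
    """Half-open analysis windows (seconds from epoch onset).

    Only windows lying fully inside the analysis span are returned. An
    empty list (with a warning) signals that the epoch is too short.
    """
    start = scheme.start_offset_s
    end = (scheme.fixed_end_s if scheme.fixed_end_s is not None
           else epoch_duration_s + scheme.end_offset_s)
    step = scheme.window_s * (1.0 - scheme.overlap_frac)
    windows = []
    k = 0
    while start + k * step + scheme.window_s <= end + _EPS:
        w0 = start + k * step
        windows.append((w0, w0 + scheme.window_s))
        k += 1
    if not windows:
        warnings.warn(
            f"epoch of {epoch_duration_s:.2f} s too short for scheme "
            f"{scheme.name!r}: no full window fits",
            stacklevel=2,
        )
    return windows


def _analytic_phase(x: np.ndarray) -> np.ndarray:
    n = x.shape[-1]
    analytic = _sig.hilbert(x, N=next_fast_len(n), axis=-1)[..., :n]
    return np.angle(analytic)


def instantaneous_phase(sig, rate: float | None = None,
                        band: str | None = None) -> PhaseSeries:
    """Instantaneous Hilbert phase of one band-limited channel.

    Accepts either a single-channel :class:`Recording` (its band tag is
    checked) or a 1-D array with explicit ``rate`` and ``band``. The phase
    is computed over the whole signal, before any windowing.
    """
    if isinstance(sig, Recording):
        if sig.n_channels != 1:
            raise ValueError("pass a single-channel recording")
        band = sig.band
        rate = sig.rate
        x = sig.data[0]
    else:
        x = np.asarray(sig, dtype=float)
    if band is None or band == "broadband":
        raise BandRequiredError(
            "instantaneous phase requires band-limited input "
            f"(got band={band!r})"
        )
    if rate is None or not rate > 0:
        raise ValueError("rate must be provided and > 0")
    if x.shape[-1] < 4:
        raise ValueError("signal too short for analytic phase")
    return PhaseSeries(phases=_analytic_phase(x), rate=float(rate), band=band)


def phase_matrix(rec: Recording) -> np.ndarray:
    """Hilbert phases of every channel of a band-limited recording."""
    if rec.band is None or rec.band == "broadband":
        raise BandRequiredError("recording must carry a narrow band tag")
    return _analytic_phase(rec.data)


def phase_matrix_batch(signal_blocks: list) -> list:
    """Hilbert phases of several channel x sample blocks, batching the FFTs.

    Each block gets the same transform length it would get on its own
    (``next_fast_len`` of its length), so the result is identical to
    calling :func:`phase_matrix` per block -- blocks that happen to share a
    transform length are just processed in one FFT pass.
    """
    out = [None] * len(signal_blocks)
    by_nfft = {}
    for i, b in enumerate(signal_blocks):
        by_nfft.setdefault(next_fast_len(b.shape[1]), []).append(i)
    for nfft, idxs in by_nfft.items():
        stacked = np.zeros((sum(signal_blocks[i].shape[0] for i in idxs),
                            nfft))
        row = 0
        for i in idxs:
            b = signal_blocks[i]
            stacked[row : row + b.shape[0], : b.shape[1]] = b
            row += b.shape[0]
        analytic = _sig.hilbert(stacked, N=nfft, axis=-1)
        row = 0
        for i in idxs:
            b = signal_blocks[i]
            out[i] = np.angle(analytic[row : row + b.shape[0], : b.shape[1]])
            row += b.shape[0]
    return out


def plv(pa, pb, window=None) -> float:
    """Phase-locking value of two phase series over a sample window.

    ``window`` is a half-open sample range ``(start, stop)``; ``None`` uses
    the full overlap. Returns the mean resultant length R in [0, 1].
    """
    a = pa.phases if isinstance(pa, PhaseSeries) else np.asarray(pa, float)
    b = pb.phases if isinstance(pb, PhaseSeries) else np.asarray(pb, float)
    if a.shape != b.shape:
        raise ValueError("phase series must have equal length")
    if isinstance(pa, PhaseSeries) and isinstance(pb, PhaseSeries):
        if pa.rate != pb.rate:
            raise ValueError("phase series must share a sampling rate")
    if window is not None:
        s0, s1 = window
        if s0 < 0 or s1 > a.shape[-1] or s1 <= s0:
            raise ValueError(f"empty or out-of-range window {window}")
        a = a[..., s0:s1]
        b = b[..., s0:s1]
    if a.size == 0:
        raise ValueError("empty window")
    return float(np.abs(np.mean(np.exp(1j * (a - b)))))


def _windows_to_samples(windows, rate: float):
    out = []
    for w0, w1 in windows:
        s0 = int(np.floor(w0 * rate + _EPS))
        s1 = s0 + int(round((w1 - w0) * rate))
        out.append((s0, s1))
    return out


def psv_epoch_matrix(phases: np.ndarray, rate: float, duration_s: float,
                     scheme: SegmentScheme, epoch_id=None) -> np.ndarray:
    """All-pairs PSV for one epoch from a channel x sample phase matrix.

    Returns the (n_ch, n_ch) symmetric matrix of window-averaged PSVs
    (diagonal = 1). Uses one rank-k Gram product per window, which makes
    cohort-scale runs cheap. Raises :class:`EpochSkipped` when no window
    fits.
    """
    windows = segment_windows(duration_s, scheme)
    if not windows:
        raise EpochSkipped(epoch_id)
    spans = [(s0, min(s1, phases.shape[1]))
             for s0, s1 in _windows_to_samples(windows, rate)]
    lo = min(s0 for s0, _ in spans)
    hi = max(s1 for _, s1 in spans)
    z = np.exp(1j * phases[:, lo:hi])  # only the samples the windows touch
    acc = np.zeros((phases.shape[0], phases.shape[0]))
    for s0, s1 in spans:
        zw = z[:, s0 - lo : s1 - lo]
        acc += np.abs(zw @ zw.conj().T) / zw.shape[1]
    return acc / len(windows)


def psv_epoch(phases: dict, scheme: SegmentScheme, pairs,
              duration_s: float | None = None, epoch_id=None) -> dict:
    """Per-pair PSV for one epoch: unweighted mean of per-window PLVs.

    ``phases`` maps ROI channel name to :class:`PhaseSeries` (all equal
    length and rate).
    """
    names = list(phases)
    missing = [ch for p in pairs for ch in p if ch not in phases]
    if missing:
        raise KeyError(f"ROI channels missing from epoch: {sorted(set(missing))}")
    first = phases[names[0]]
    rate = first.rate
    n = first.phases.shape[-1]
    if duration_s is None:
        duration_s = n / rate
    mat = np.stack([phases[ch].phases for ch in names])
    psv = psv_epoch_matrix(mat, rate, duration_s, scheme, epoch_id=epoch_id)
    idx = {ch: i for i, ch in enumerate(names)}
    return {p: float(psv[idx[p.a], idx[p.b]]) for p in pairs}


def aggregate_condition(epoch_psvs) -> dict:
    """Unweighted mean over a participant's epochs within one condition."""
    epoch_psvs = list(epoch_psvs)
    if not epoch_psvs:
        raise MissingCellError("no epochs available for this condition cell")
    pairs = epoch_psvs[0].keys()
    return {
        p: float(np.mean([e[p] for e in epoch_psvs])) for p in pairs
    }


def psv_rest(phases: dict, pairs, scheme: SegmentScheme = REST,
             duration_s: float | None = None, epoch_id=None) -> dict:
    """Per-pair PSV over one rest span (same mechanics as a stimulus epoch)."""
    return psv_epoch(phases, scheme, pairs, duration_s=duration_s,
                     epoch_id=epoch_id)
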