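"""Coupled-oscillator EEG cohort simulator.

Every ROI channel is a noisy phase oscillator pulled toward a latent
delta-band driver:

    d(phi_c) = 2*pi*f_c dt + G * kappa_c * sin(phi_d - phi_c) dt + sigma dW

with per-channel natural frequency ``f_c`` jittered around the driver
frequency, coupling strength ``kappa_c`` in [0, 1] (``G`` converts it to
rad/s), and phase-diffusion noise ``sigma`` (rad/sqrt(s)). The emitted
channel is ``A*cos(phi_c)`` plus 1/f background noise, so the delta-band
phase-locking value between two channels rises monotonically with their
coupling: kappa = 0 leaves independent phase diffusion (chance-level PSV
over long windows), strong coupling with small noise locks channels to the
driver (PSV -> 1).

Group and posture effects are injected regionally through "pair
communities" (left fronto-parietal, right fronto-parietal, midline): math
experts get stronger coupling than novices over the left and midline
communities in both postures, and additionally over the right community
when standing. Coupling during rest blocks is identical for both groups.
Between-participant spread is produced by participant- and channel-level
coupling jitter, sized so cohort PSV standard deviations land near 0.12-
0.13 while electrode pairs remain only partially correlated within a
participant.

The default coupling strengths were calibrated once (bisection via
:func:`calibrate_kappa`) so that the cohort-mean whole-stimuli delta PSV of
a midline parietal pair is ~0.42 for experts and ~0.35 for novices.

Everything is driven by `numpy.random.Generator`; per-participant streams
are derived by stable hashing of (cohort seed, participant id), so each
participant's data is independent of generation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
from scipy.fft import irfft, next_fast_len

from .core_data import (
    DEFAULT_ROI,
    REST_STATES,
    CohortManifest,
    Event,
    EventStream,
    Recording,
)

__all__ = [
    "COMMUNITIES",
    "CohortConfig",
    "ParticipantBundle",
    "default_coupling",
    "pink_noise",
    "simulate_channel",
    "simulate_participant",
    "simulate_cohort",
    "iter_cohort",
    "participant_seed",
    "calibrate_kappa",
    "KAPPA_NOVICE",
    "KAPPA_EXPERT",
    "KAPPA_EXPERT_STANDING_BOOST",
]

#: Electrode communities used to inject regional effects.
COMMUNITIES = {
    "left": ("F3", "CP3", "P1", "PPO1"),
    "right": ("F4", "CP4", "P2", "PPO2"),
    "midline": ("Fz", "FCz", "Cz", "Pz"),
}

_CHANNEL_COMMUNITY = {ch: c for c, chans in COMMUNITIES.items() for ch in chans}

# Calibrated coupling anchors (see module docstring and docs/methods.md).
KAPPA_NOVICE = 0.28
KAPPA_EXPERT = 0.39
KAPPA_EXPERT_STANDING_BOOST = 0.06


def default_coupling(kappa_novice: float = KAPPA_NOVICE,
                     kappa_expert: float = KAPPA_EXPERT,
                     standing_boost: float = KAPPA_EXPERT_STANDING_BOOST) -> dict:
    """Default (group, posture, community) -> kappa map.

    Novices couple at ``kappa_novice`` everywhere. Experts couple at
    ``kappa_expert`` over left and midline communities in both postures
    (the Group main effect) and extend the stronger coupling to the right
    community when standing (the Group x Posture interaction).
    """
    coupling = {}
    for posture in ("Sitting", "Standing"):
        for comm in COMMUNITIES:
            coupling[("novice", posture, comm)] = kappa_novice
    for comm in ("left", "midline"):
        coupling[("expert", "Sitting", comm)] = kappa_expert
        coupling[("expert", "Standing", comm)] = kappa_expert + standing_boost
    coupling[("expert", "Sitting", "right")] = kappa_novice
    coupling[("expert", "Standing", "right")] = kappa_expert + standing_boost
    return coupling


@dataclass
class CohortConfig:
    """Simulator parameters; defaults reproduce the study design.

    2 groups x ``n_per_group`` participants, 16 math-demonstration epochs
    per participant (8 demonstrations x symbolic/geometric, 4 per
    posture-style cell) with durations uniform in ``duration_range_s``,
    plus ``n_rest_blocks`` rest blocks of ``rest_block_s`` seconds.
    """

    n_per_group: int = 22
    n_demos: int = 8
    rate: float = 256.0
    duration_range_s: tuple = (13.0, 68.0)
    base_hz: float = 2.0              # delta-band driver frequency
    drift_hz: float = 0.25            # driver/channel frequency jitter (SD, Hz)
    sigma_phase: float = 1.2          # phase diffusion, rad/sqrt(s)
    coupling_gain: float = 6.0        # rad/s at kappa = 1
    noise_gain: float = 0.6           # 1/f background amplitude (x osc amp)
    osc_amp_uv: float = 10.0
    coupling: dict | None = None      # (group, posture, community) -> kappa
    rest_kappa: float = KAPPA_NOVICE  # group-independent rest coupling
    kappa_participant_sd: float = 0.03
    kappa_channel_sd: float = 0.12
    noise_participant_logsd: float = 0.15  # lognormal noise-amplitude jitter
    noise_channel_logsd: float = 0.50
    n_rest_blocks: int = 4
    rest_block_s: float = 120.0
    rest_analysis_offset_s: float = 15.0
    rest_analysis_span_s: float = 75.0
    gap_s: float = 2.0
    roi: tuple = DEFAULT_ROI
    n_background: int = 20  # uncoupled channels carried by the reference
    seed: int = 0

    def __post_init__(self):
        if self.coupling is None:
            self.coupling = default_coupling()
        for key, kappa in self.coupling.items():
            if not 0.0 <= kappa <= 1.0:
                raise ValueError(f"coupling kappa for {key} outside [0, 1]: {kappa}")
        if not 0.0 <= self.rest_kappa <= 1.0:
            raise ValueError(f"rest_kappa outside [0, 1]: {self.rest_kappa}")
        lo, hi = self.duration_range_s
        if not 0 < lo <= hi:
            raise ValueError("duration_range_s must satisfy 0 < lo <= hi")


@dataclass
class ParticipantBundle:
    participant_id: str
    group: str
    recording: Recording
    events: EventStream


# ---------------------------------------------------------------------------
# Primitive generators
# ---------------------------------------------------------------------------

def _pink_noise_multi(n_channels: int, n_samples: int, rate: float,
                      rng) -> np.ndarray:
    """Independent unit-variance 1/f channels, shaped in one batched FFT.

    Synthesis runs at the next fast FFT length and is truncated, which
    leaves the spectrum unchanged up to edge effects far below the band of
    interest.
    """
    nfft = next_fast_len(max(int(n_samples), 2), real=True)
    freqs = np.fft.rfftfreq(nfft, 1.0 / rate)
    amp = 1.0 / np.sqrt(np.maximum(freqs, 0.5))
    amp[0] = 0.0
    spec = amp * (rng.standard_normal((n_channels, len(freqs)))
                  + 1j * rng.standard_normal((n_channels, len(freqs))))
    x = irfft(spec, nfft, axis=-1)[:, :n_samples]
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def pink_noise(n_samples: int, rate: float, rng) -> np.ndarray:
    """Unit-variance noise with a ~1/f power spectrum over 0.5-40 Hz.

    Spectral shaping in the frequency domain: amplitude ~ f^(-1/2), flat
    below 0.5 Hz to keep the variance finite.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return _pink_noise_multi(1, n_samples, rate, rng)[0]


def _integrate_phases_py(phi0, f_hz, driver, kap_gain, dt, dw):
    n_ch = phi0.shape[0]
    n = dw.shape[1] + 1
    phi = np.empty((n_ch, n))
    phi[:, 0] = phi0
    for t in range(n - 1):
        phi[:, t + 1] = (
            phi[:, t]
            + 2.0 * np.pi * f_hz * dt
            + kap_gain * np.sin(driver[t] - phi[:, t]) * dt
            + dw[:, t]
        )
    return phi


try:  # numba gives a ~100x faster integrator; semantics are identical
    from numba import njit as _njit

    @_njit(cache=False)
    def _integrate_phases_nb(phi0, f_hz, driver, kap_gain, dt, dw):  # pragma: no cover
        n_ch = phi0.shape[0]
        n = dw.shape[1] + 1
        phi = np.empty((n_ch, n))
        for c in range(n_ch):
            phi[c, 0] = phi0[c]
        for t in range(n - 1):
            for c in range(n_ch):
                phi[c, t + 1] = (
                    phi[c, t]
                    + 2.0 * np.pi * f_hz[c] * dt
                    + kap_gain[c] * np.sin(driver[t] - phi[c, t]) * dt
                    + dw[c, t]
                )
        return phi

    _integrate_phases = _integrate_phases_nb
except ImportError:  # pragma: no cover
    _integrate_phases = _integrate_phases_py


def _oscillator_block(n: int, rate: float, kappa: np.ndarray, rng,
                      base_hz: float, drift_hz: float, sigma: float,
                      gain: float) -> np.ndarray:
    """Phases of ``len(kappa)`` channels coupled to one driver, n samples."""
    n_ch = len(kappa)
    dt = 1.0 / rate
    f_driver = base_hz + rng.normal(0.0, drift_hz)
    t = np.arange(n) * dt
    driver = rng.uniform(-np.pi, np.pi) + 2 * np.pi * f_driver * t
    f_chan = f_driver + rng.normal(0.0, drift_hz, n_ch)
    phi0 = rng.uniform(-np.pi, np.pi, n_ch)
    dw = rng.normal(0.0, sigma * np.sqrt(dt), (n_ch, n - 1))
    return _integrate_phases(
        phi0, f_chan, driver, np.asarray(gain * kappa, dtype=float), dt, dw
    )


def simulate_channel(driver_phase: np.ndarray, kappa: float, rate: float,
                     *, sigma: float = 1.2, gain: float = 6.0,
                     f_hz: float = 2.0, jitter_hz: float = 0.0,
                     seed=None) -> np.ndarray:
    """One band-limited channel phase-coupled to a given driver trace.

    Returns the emitted signal ``cos(phi_c)``; ``kappa`` in [0, 1] sets the
    pull toward the driver (0 = independent phase diffusion).
    """
    if not 0.0 <= kappa <= 1.0:
        raise ValueError(f"kappa outside [0, 1]: {kappa}")
    rng = np.random.default_rng(seed)
    n = len(driver_phase)
    dt = 1.0 / rate
    f_chan = np.array([f_hz + rng.normal(0.0, jitter_hz)])
    phi0 = rng.uniform(-np.pi, np.pi, 1)
    dw = rng.normal(0.0, sigma * np.sqrt(dt), (1, n - 1))
    phi = _integrate_phases(phi0, f_chan, np.asarray(driver_phase, float),
                            np.array([gain * kappa]), dt, dw)
    return np.cos(phi[0])


# ---------------------------------------------------------------------------
# Participant and cohort assembly
# ---------------------------------------------------------------------------

def _kappa_vector(cfg: CohortConfig, group: str, posture: str,
                  eta_p: float, eta_c: np.ndarray) -> np.ndarray:
    base = np.array(
        [cfg.coupling[(group, posture, _CHANNEL_COMMUNITY[ch])] for ch in cfg.roi]
    )
    return np.clip(base + eta_p + eta_c, 0.0, 1.0)


def participant_seed(cohort_seed: int, pid: str) -> np.random.SeedSequence:
    """Stable per-participant seed: independent of generation order."""
    return np.random.SeedSequence([int(cohort_seed), zlib.crc32(pid.encode())])


def simulate_participant(cfg: CohortConfig, pid: str, group: str,
                         seed=None):
    """One continuous recording with rest blocks and 16 demonstration epochs.

    Returns ``(Recording, EventStream, epoch_conditions)`` where
    ``epoch_conditions`` is the (event label, condition) list for the
    cohort manifest. Rest blocks come first (posture x eyes open/closed),
    then two posture blocks each holding both style sets of four
    demonstrations; posture and style orders are randomised per
    participant.
    """
    if seed is None:
        seed = participant_seed(cfg.seed, pid)
    rng = np.random.default_rng(seed)
    n_ch = len(cfg.roi)
    eta_p = rng.normal(0.0, cfg.kappa_participant_sd)
    eta_c = rng.normal(0.0, cfg.kappa_channel_sd, n_ch)
    # mean-one lognormal jitter, so noise_gain stays the average amplitude
    _s2 = cfg.noise_participant_logsd**2 + cfg.noise_channel_logsd**2
    noise_mult = np.exp(
        rng.normal(0.0, cfg.noise_participant_logsd)
        + rng.normal(0.0, cfg.noise_channel_logsd, n_ch)
        - _s2 / 2.0
    )

    segments = []  # (n_samples, kappa vector or None for gap)
    events = []
    manifest_entries = []
    cursor = 0

    def add_block(duration_s, kappa, label=None, condition=None):
        nonlocal cursor
        n = int(round(duration_s * cfg.rate))
        if label is not None:
            events.append(Event(cursor / cfg.rate, label, n / cfg.rate))
            manifest_entries.append((label, condition))
        segments.append((n, kappa))
        cursor += n

    # Rest blocks (group-independent coupling).
    kappa_rest = np.clip(cfg.rest_kappa + eta_p + eta_c, 0.0, 1.0)
    for state in REST_STATES[: cfg.n_rest_blocks]:
        add_block(cfg.rest_block_s, kappa_rest, f"rest:{state}", state)
        add_block(cfg.gap_s, None)

    # Demonstration epochs: 2 posture blocks x 2 style sets x 4 demos.
    n_per_cell = cfg.n_demos // 2
    postures = ["Sitting", "Standing"]
    rng.shuffle(postures)
    demo_idx = 0
    durations = rng.uniform(*cfg.duration_range_s, size=4 * n_per_cell * 2)
    for posture in postures:
        styles = ["Symbolic", "Geometric"]
        rng.shuffle(styles)
        kap = {s: _kappa_vector(cfg, group, posture, eta_p, eta_c)
               for s in styles}
        for style in styles:
            condition = f"{style}-{posture}"
            for _ in range(n_per_cell):
                add_block(durations[demo_idx], kap[style],
                          f"demo-{demo_idx:02d}", condition)
                add_block(cfg.gap_s, None)
                demo_idx += 1

    # Oscillator layer (zeros inside gaps), then one continuous 1/f layer:
    # batching the noise over the whole recording keeps the FFT count low.
    data = np.zeros((n_ch, cursor))
    pos = 0
    for n, kappa in segments:
        if n == 0:
            continue
        if kappa is not None:
            phases = _oscillator_block(
                n, cfg.rate, kappa, rng, cfg.base_hz, cfg.drift_hz,
                cfg.sigma_phase, cfg.coupling_gain,
            )
            data[:, pos : pos + n] = cfg.osc_amp_uv * np.cos(phases)
        pos += n
    if cfg.noise_gain > 0:
        amp = cfg.osc_amp_uv * cfg.noise_gain * noise_mult[:, None]
        data += amp * _pink_noise_multi(n_ch, cursor, cfg.rate, rng)

    # Background channels: uncoupled 1/f activity at ROI-like amplitude.
    # They emulate the rest of the cap, so the common-average reference is
    # not dominated by the coupled ROI oscillation (with only coupled
    # channels, re-referencing would subtract the shared signal itself).
    if cfg.n_background > 0:
        bg_amp = cfg.osc_amp_uv * np.sqrt(0.5 + cfg.noise_gain**2)
        bg = bg_amp * _pink_noise_multi(cfg.n_background, cursor, cfg.rate, rng)
        data = np.concatenate([data, bg], axis=0)
    labels = tuple(cfg.roi) + tuple(
        f"BG{i + 1:02d}" for i in range(cfg.n_background)
    )
    rec = Recording(data=data, rate=cfg.rate, labels=labels)
    return rec, EventStream(events), manifest_entries


def _participant_ids(cfg: CohortConfig):
    for group in ("expert", "novice"):
        for i in range(cfg.n_per_group):
            yield f"{group}{i + 1:02d}", group


def iter_cohort(cfg: CohortConfig):
    """Yield participant bundles one at a time (memory-friendly)."""
    for pid, group in _participant_ids(cfg):
        rec, events, entries = simulate_participant(cfg, pid, group)
        yield ParticipantBundle(pid, group, rec, events), entries


def simulate_cohort(cfg: CohortConfig):
    """Simulate the full cohort; returns (bundles, CohortManifest)."""
    bundles = []
    epochs = {}
    for bundle, entries in iter_cohort(cfg):
        bundles.append(bundle)
        epochs[bundle.participant_id] = entries
    manifest = CohortManifest(
        participants=[(b.participant_id, b.group) for b in bundles],
        epochs=epochs,
    )
    return bundles, manifest


def cohort_manifest(cfg: CohortConfig) -> CohortManifest:
    """Manifest only (epoch layout is deterministic per participant seed)."""
    epochs = {}
    participants = []
    # Epoch layout (labels, conditions) is fixed before any sample is drawn,
    # so a low-rate run yields the identical manifest cheaply.
    for pid, group in _participant_ids(cfg):
        _, _, entries = simulate_participant(replace(cfg, rate=16.0), pid, group)
        epochs[pid] = entries
        participants.append((pid, group))
    return CohortManifest(participants=participants, epochs=epochs)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def measure_cohort_psv(cfg: CohortConfig, pair=("Cz", "Pz"), group="expert",
                       n_participants: int = 12, seed: int = 0) -> float:
    """Cohort-mean whole-stimuli delta PSV of one pair for one group.

    Runs the actual analysis chain (reference, broadband + delta filtering,
    Hilbert phase, 5-s/50% windows, hierarchical averaging) on freshly
    simulated participants.
    """
    from .pipeline import participant_condition_psv  # lazy: avoids cycle

    cfg = replace(cfg, seed=seed)
    vals = []
    for i in range(n_participants):
        pid = f"cal-{group}{i:02d}"
        rec, events, entries = simulate_participant(cfg, pid, group)
        cond_map = dict(entries)
        table = participant_condition_psv(
            rec, events, cond_map, bands=("delta",), schemes=("whole_stimuli",),
            include_rest=False, roi=cfg.roi,
        )
        sub = table[(table.pair_a == pair[0]) & (table.pair_b == pair[1])]
        vals.append(sub.psv.mean())  # mean over the four conditions
    return float(np.mean(vals))


def calibrate_kappa(target_psv: float, cfg: CohortConfig | None = None,
                    pair=("Cz", "Pz"), n_participants: int = 12,
                    bracket=(0.0, 1.0), tol: float = 0.01,
                    max_iter: int = 12, seed: int = 0) -> float:
    """Bisection on uniform coupling so the cohort-mean PSV hits a target.

    All channels share the candidate kappa (no community structure, no
    kappa jitter) so the measured PSV is a clean monotone function of the
    coupling.
    """
    if cfg is None:
        cfg = CohortConfig()

    def mean_psv(kappa: float) -> float:
        coupling = {
            (g, p, c): kappa
            for g in ("expert", "novice")
            for p in ("Sitting", "Standing")
            for c in COMMUNITIES
        }
        trial = replace(
            cfg, coupling=coupling, kappa_participant_sd=0.0,
            kappa_channel_sd=0.0, n_rest_blocks=0,
        )
        return measure_cohort_psv(trial, pair=pair, group="expert",
                                  n_participants=n_participants, seed=seed)

    lo, hi = bracket
    f_lo, f_hi = mean_psv(lo), mean_psv(hi)
    if not f_lo <= target_psv <= f_hi:
        raise ValueError(
            f"target PSV {target_psv} outside achievable range "
            f"[{f_lo:.3f}, {f_hi:.3f}]"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = mean_psv(mid)
        if abs(f_mid - target_psv) < tol:
            return mid
        if f_mid < target_psv:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
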