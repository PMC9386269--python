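"""Seeded synthetic sessions with ground truth for every pipeline stage.

The generator emulates a structured tremor exam recorded by two wrist
accelerometers at 100 Hz: per posture a gravity component (1 g along a
posture-specific orientation), tremor as a narrowband oscillation on a fixed
axis (fundamental + optional second harmonic), broadband Gaussian sensor
noise, slow drift, a ~1 Hz voluntary component during the loaded-action task,
and photodiode pulses bracketing each marked epoch.  All randomness flows
through one seeded generator so identical seeds give bitwise-identical
channels.

The closed-form variance of the signal model (A²/2 per sinusoid, σ² for the
noise) provides exact oracles for the spectral metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import datetime

import numpy as np

from .device_io import DeviceMeta, RawRecording, STANDARD_GRAVITY
from .errors import ConfigurationError
from .segmentation import Position, ProtocolDef, default_protocol
from .spectral import DEFAULT_BAND

WRISTS = ("left", "right")


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ConfigurationError("axis vector must be nonzero")
    return v / n


@dataclass(frozen=True)
class PositionSignal:
    """Signal model parameters for one exam position."""

    tremor_frequency_hz: float = 5.0
    tremor_amplitude: float = 0.0  # m/s², fundamental acceleration amplitude
    harmonic2_ratio: float = 0.0  # second-harmonic amplitude / fundamental
    tremor_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    gravity_orientation: tuple[float, float, float] = (0.0, 0.0, 1.0)
    voluntary_amplitude: float = 0.0  # m/s² (loaded-action task only)


#: Default posture geometry: gravity reorients between postures and the
#: tremor axis is not gravity-aligned, exercising the PCA stage.
_DEFAULT_GEOMETRY: dict[Position, tuple[tuple, tuple]] = {
    # position: (tremor_axis, gravity_orientation)
    Position.REST: ((1.0, 0.2, 0.0), (0.0, 0.0, 1.0)),
    Position.POSTURE_UNIMANUAL_DOMINANT: ((1.0, 0.0, 1.0), (0.0, 1.0, 0.0)),
    Position.POSTURE_UNIMANUAL_NONDOMINANT: ((1.0, 0.0, 1.0), (0.0, 1.0, 0.0)),
    Position.POSTURE_BIMANUAL: ((1.0, 0.5, 0.5), (0.0, 1.0, 0.0)),
    Position.WING: ((0.0, 1.0, 1.0), (1.0, 0.0, 0.0)),
    Position.ACTION_LOADING: ((1.0, 1.0, 0.0), (0.3, 0.7, 0.6)),
}

#: Essential-tremor-like per-position fundamental amplitudes, m/s²:
#: rest ≪ extended-arm posture < loaded action ≤ wing.
ET_AMPLITUDES: dict[Position, float] = {
    Position.REST: 0.05,
    Position.POSTURE_UNIMANUAL_DOMINANT: 1.0,
    Position.POSTURE_UNIMANUAL_NONDOMINANT: 1.0,
    Position.POSTURE_BIMANUAL: 0.95,
    Position.WING: 2.0,
    Position.ACTION_LOADING: 1.5,
}

#: Voluntary drinking-motion component during loaded action, m/s² at
#: ``voluntary_frequency_hz`` (≈ once-per-second to-and-fro).
DEFAULT_VOLUNTARY_AMPLITUDE = 0.39


def position_signals(
    amplitudes: dict[Position, float],
    tremor_frequency_hz: float = 5.0,
    harmonic2_ratio: float = 0.0,
    voluntary_amplitude: float = DEFAULT_VOLUNTARY_AMPLITUDE,
) -> dict[Position, PositionSignal]:
    """Build per-position signal models from a position→amplitude map."""
    out = {}
    for pos, (axis, grav) in _DEFAULT_GEOMETRY.items():
        out[pos] = PositionSignal(
            tremor_frequency_hz=tremor_frequency_hz,
            tremor_amplitude=float(amplitudes.get(pos, 0.0)),
            harmonic2_ratio=harmonic2_ratio,
            tremor_axis=axis,
            gravity_orientation=grav,
            voluntary_amplitude=(
                voluntary_amplitude if pos is Position.ACTION_LOADING else 0.0
            ),
        )
    return out


@dataclass(frozen=True)
class SimConfig:
    """Full description of one simulated session."""

    seed: int
    positions: dict[Position, PositionSignal] = field(
        default_factory=lambda: position_signals(ET_AMPLITUDES)
    )
    protocol: ProtocolDef = field(default_factory=default_protocol)
    sample_rate: float = 100.0
    noise_sd: float = 0.1  # m/s², isotropic broadband
    drift_amplitude: float = 0.05  # m/s²
    drift_frequency_hz: float = 0.1
    voluntary_frequency_hz: float = 1.25
    light_baseline: float = 10.0
    light_pulse: float = 2000.0
    pulse_duration_s: float = 0.2
    buffer_s: float = 10.0  # within the protocol's 5–15 s prescription
    lead_in_s: float = 5.0
    subject_id: str = "sim subject"
    start_datetime: datetime = datetime(2018, 7, 13, 17, 27, 44)

    def validate(self) -> None:
        nyq = self.sample_rate / 2
        for pos, sig in self.positions.items():
            if sig.tremor_frequency_hz >= nyq:
                raise ConfigurationError(
                    f"{pos.value}: tremor frequency "
                    f"{sig.tremor_frequency_hz} Hz >= Nyquist {nyq} Hz"
                )
            if sig.tremor_amplitude < 0 or sig.harmonic2_ratio < 0:
                raise ConfigurationError("amplitudes must be nonnegative")


@dataclass(frozen=True)
class GroundTruthEpoch:
    """Configured truth for one marked epoch (untrimmed marker interval)."""

    position: Position
    repetition: int
    active_side: str
    start: int  # sample of the start pulse onset
    end: int  # sample of the end pulse onset (exclusive epoch bound)
    tremor_frequency_hz: dict[str, float]  # per wrist
    tremor_amplitude: dict[str, float]  # per wrist, m/s²
    expected_band_power: dict[str, float]  # per wrist, m²/s⁴ in DEFAULT_BAND


@dataclass(frozen=True)
class GroundTruth:
    markers: list[int]  # pulse-onset samples, shared by both wrists
    epochs: list[GroundTruthEpoch]
    n_samples: int


def _expected_band_power(
    sig: PositionSignal,
    noise_sd: float,
    sample_rate: float,
    voluntary_frequency_hz: float,
    band: tuple[float, float] = DEFAULT_BAND,
) -> float:
    """Closed-form in-band PC1 power of the configured signal model."""
    lo, hi = band
    p = 0.0
    a, f = sig.tremor_amplitude, sig.tremor_frequency_hz
    if a > 0 and lo <= f <= hi:
        p += a**2 / 2
    h = sig.harmonic2_ratio * a
    if h > 0 and lo <= 2 * f <= hi:
        p += h**2 / 2
    v = sig.voluntary_amplitude
    if v > 0 and lo <= voluntary_frequency_hz <= hi:
        p += v**2 / 2
    # Isotropic white noise contributes its in-band fraction along any axis.
    p += noise_sd**2 * (hi - lo) / (sample_rate / 2)
    return p


def _wrist_signal(
    sig: PositionSignal,
    active: bool,
    rest_sig: PositionSignal,
    t: np.ndarray,
    rng: np.random.Generator,
    cfg: SimConfig,
) -> np.ndarray:
    """Acceleration (n, 3) in m/s² (gravity included) for one wrist segment."""
    use = sig if active else rest_sig
    axis = _unit(use.tremor_axis)
    grav = _unit(use.gravity_orientation)
    n = t.size
    acc = np.outer(np.ones(n), grav) * STANDARD_GRAVITY
    a = use.tremor_amplitude
    f = use.tremor_frequency_hz
    if a > 0:
        phase = rng.uniform(0, 2 * math.pi)
        osc = a * np.sin(2 * math.pi * f * t + phase)
        if use.harmonic2_ratio > 0:
            osc = osc + use.harmonic2_ratio * a * np.sin(
                4 * math.pi * f * t + rng.uniform(0, 2 * math.pi)
            )
        acc += np.outer(osc, axis)
    if active and use.voluntary_amplitude > 0:
        vol = use.voluntary_amplitude * np.sin(
            2 * math.pi * cfg.voluntary_frequency_hz * t + rng.uniform(0, 2 * math.pi)
        )
        acc += np.outer(vol, axis)
    if cfg.drift_amplitude > 0:
        drift = cfg.drift_amplitude * np.sin(
            2 * math.pi * cfg.drift_frequency_hz * t + rng.uniform(0, 2 * math.pi)
        )
        acc += np.outer(drift, grav)
    if cfg.noise_sd > 0:
        acc += rng.normal(0.0, cfg.noise_sd, size=(n, 3))
    return acc


def simulate_session(
    config: SimConfig,
) -> tuple[dict[str, RawRecording], GroundTruth]:
    """Simulate one exam session: one recording per wrist plus ground truth.

    The timeline follows the protocol in repetition-major order: a 5 s lead-in,
    then each entry's hold window followed by a fixed buffer.  Marked entries
    are bracketed by light pulses at their first and one-past-last sample.
    """
    config.validate()
    cfg = config
    fs = cfg.sample_rate
    proto = cfg.protocol
    rng = np.random.default_rng(cfg.seed)
    rest_sig = cfg.positions.get(Position.REST, PositionSignal())

    # Build the sample-index timeline first:
    # (kind, position or None, active_side, repetition, start, end)
    cursor = int(round(cfg.lead_in_s * fs))
    buf = int(round(cfg.buffer_s * fs))
    timeline: list[tuple[str, Position | None, str, int, int, int]] = []
    timeline.append(("lead", None, "none", 0, 0, cursor))
    markers: list[int] = []
    gt_epochs: list[GroundTruthEpoch] = []
    for rep in range(1, proto.repetitions + 1):
        for entry in proto.sequence:
            dur = int(round(entry.duration_s * fs))
            start, end = cursor, cursor + dur
            timeline.append(
                ("hold", entry.position, entry.active_side, rep, start, end)
            )
            if entry.marked:
                markers.extend([start, end])
                sig = cfg.positions.get(entry.position, PositionSignal())
                per_wrist_p = {}
                per_wrist_f = {}
                per_wrist_a = {}
                for w in WRISTS:
                    active = entry.active_side in (w, "both")
                    use = sig if active else rest_sig
                    per_wrist_f[w] = use.tremor_frequency_hz
                    per_wrist_a[w] = use.tremor_amplitude
                    per_wrist_p[w] = _expected_band_power(
                        use if active else replace(use, voluntary_amplitude=0.0),
                        cfg.noise_sd,
                        fs,
                        cfg.voluntary_frequency_hz,
                    )
                gt_epochs.append(
                    GroundTruthEpoch(
                        position=entry.position,
                        repetition=rep,
                        active_side=entry.active_side,
                        start=start,
                        end=end,
                        tremor_frequency_hz=per_wrist_f,
                        tremor_amplitude=per_wrist_a,
                        expected_band_power=per_wrist_p,
                    )
                )
            cursor = end
            timeline.append(("buffer", None, "none", rep, cursor, cursor + buf))
            cursor += buf
    n_total = cursor

    recordings: dict[str, RawRecording] = {}
    light = np.full(n_total, cfg.light_baseline, dtype=float)
    pulse_len = max(1, int(round(cfg.pulse_duration_s * fs)))
    for m in markers:
        light[m : min(m + pulse_len, n_total)] = cfg.light_pulse
    # Bounded ambient flicker (quantized photodiode floor): keeps the MAD
    # finite while staying far below any plausible detection threshold.
    light = light + rng.uniform(0.0, 1.0, size=n_total)

    for w in WRISTS:
        acc = np.empty((n_total, 3), dtype=float)
        for kind, pos, side, _rep, s, e in timeline:
            if e <= s:
                continue
            t = np.arange(s, e) / fs
            if kind == "hold" and pos is not None:
                sig = cfg.positions.get(pos, PositionSignal())
                active = side in (w, "both")
            else:
                sig, active = rest_sig, False
            acc[s:e] = _wrist_signal(sig, active, rest_sig, t, rng, cfg)
        meta = DeviceMeta(
            subject_id=cfg.subject_id,
            wrist_side=w,
            watch_id=f"W{1 if w == 'left' else 2}",
            start_datetime=cfg.start_datetime,
        )
        recordings[w] = RawRecording(
            sample_rate=fs,
            acceleration=acc / STANDARD_GRAVITY,  # device emits g
            light=light.copy(),
            meta=meta,
            units="g",
        )
    return recordings, GroundTruth(markers=markers, epochs=gt_epochs, n_samples=n_total)


def _truncnorm_loc_for_mean(
    target_mean: float, sd: float, bounds: tuple[float, float]
) -> float:
    """Location of a truncated normal whose post-truncation mean is target_mean."""
    from scipy.optimize import brentq
    from scipy.stats import truncnorm

    def gap(loc: float) -> float:
        a, b = (bounds[0] - loc) / sd, (bounds[1] - loc) / sd
        return truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean

    lo, hi = bounds[0] - 5 * sd, bounds[1] + 5 * sd
    return float(brentq(gap, lo, hi, xtol=1e-10))


@dataclass(frozen=True)
class CohortSubject:
    """One simulated subject: session config plus generating parameters."""

    subject_id: str
    config: SimConfig
    true_frequency_hz: float
    true_amplitudes: dict[Position, float]
    severity: float


def make_cohort(
    n_subjects: int,
    profile: str = "et_like",
    seed: int = 0,
    tremor_frequency_mean: float = 4.6,
    tremor_frequency_sd: float = 1.0,
    frequency_bounds: tuple[float, float] = (3.0, 12.0),
    severity_sigma: float = 0.5,
    position_jitter_sigma: float = 0.1,
) -> list[CohortSubject]:
    """Draw a seeded cohort of simulated subjects.

    ``et_like``: per-subject peak frequency ~ Normal(4.6, 1.0) Hz truncated to
    [3, 12]; a subject-level lognormal severity multiplies the essential-
    tremor position amplitude profile (small per-position lognormal jitter on
    top), so the rest ≪ posture < wing ordering is coherent within subject.
    ``control_like``: all tremor amplitudes zero; only noise, drift and the
    voluntary action component remain.
    """
    if n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    if profile not in ("et_like", "control_like"):
        raise ConfigurationError(f"unknown cohort profile {profile!r}")
    # Calibrate the pre-truncation location so the truncated distribution's
    # mean equals the configured cohort mean (asymmetric bounds otherwise
    # bias the cohort upward).
    loc = _truncnorm_loc_for_mean(
        tremor_frequency_mean, tremor_frequency_sd, frequency_bounds
    )
    subjects: list[CohortSubject] = []
    for i in range(n_subjects):
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(i,))
        rng = np.random.default_rng(ss)
        freq = tremor_frequency_mean
        for _ in range(1000):
            freq = rng.normal(loc, tremor_frequency_sd)
            if frequency_bounds[0] <= freq <= frequency_bounds[1]:
                break
        severity = float(np.exp(rng.normal(0.0, severity_sigma)))
        if profile == "et_like":
            amps = {
                pos: base
                * severity
                * float(np.exp(rng.normal(0.0, position_jitter_sigma)))
                for pos, base in ET_AMPLITUDES.items()
            }
        else:
            amps = {pos: 0.0 for pos in ET_AMPLITUDES}
            severity = 0.0
        session_seed = int(rng.integers(0, 2**31 - 1))
        cfg = SimConfig(
            seed=session_seed,
            positions=position_signals(amps, tremor_frequency_hz=float(freq)),
            subject_id=f"subject {i + 1:02d}",
        )
        subjects.append(
            CohortSubject(
                subject_id=cfg.subject_id,
                config=cfg,
                true_frequency_hz=float(freq),
                true_amplitudes=amps,
                severity=severity,
            )
        )
    return subjects
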