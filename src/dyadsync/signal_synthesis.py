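"""Forward generator for two-participant multichannel optical recordings.

Builds true oxy-/deoxy-hemoglobin concentration series per channel
(physiological noise plus, on designated channels and segments, a shared
narrowband oscillation coupling the two participants), then converts them
through the modified Beer-Lambert relation to optical density and raw
intensity, so the preprocessing chain can invert the whole path.  Ground
truth (true concentrations, coupling waveform, artifact mask) is retained
on the recording for oracle-style testing.

Noise model per channel: 1/f ("pink") drift, cardiac / respiratory / Mayer
oscillations with random phases, and white noise.  The Mayer component
(~0.1 Hz) deliberately sits inside the analysis period band so the
task-minus-rest contrast is exercised against in-band nuisance power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import constants
from .errors import ConfigError, StageError, ValidationError
from .task_model import DyadSession, StrategyKind

__all__ = [
    "ProbeLayout",
    "AcquisitionConfig",
    "CouplingSpec",
    "NoiseSpec",
    "HyperscanRecording",
    "make_timeline",
    "synthesize_dyad_recording",
    "inject_motion_artifacts",
    "degrade_channel_snr",
]


@dataclass(frozen=True)
class ProbeLayout:
    n_channels: int = constants.N_CHANNELS
    grid: str = "3x5"
    roi_channels: frozenset[int] = frozenset(range(15, 23))
    target_channel: int = 19

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValidationError("n_channels must be positive")
        chans = set(self.roi_channels)
        if not chans or min(chans) < 1 or max(chans) > self.n_channels:
            raise ValidationError("roi_channels must be within 1..n_channels")
        if self.target_channel not in chans:
            raise ValidationError("target_channel must belong to roi_channels")


@dataclass(frozen=True)
class AcquisitionConfig:
    fs: float = constants.SAMPLING_RATE_HZ
    wavelengths: tuple[float, float] = constants.WAVELENGTHS_NM
    segment_labels: tuple[str, ...] = constants.SEGMENT_LABELS
    segment_durations: tuple[float, ...] = constants.SEGMENT_DURATIONS_S
    source_detector_distance: float = constants.SOURCE_DETECTOR_DISTANCE_CM

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        if len(self.segment_labels) != 5 or tuple(self.segment_labels) != constants.SEGMENT_LABELS:
            raise ValidationError("timeline must contain the 5 canonical segments in order")
        if len(self.segment_durations) != 5 or any(d <= 0 for d in self.segment_durations):
            raise ValidationError("segment durations must be positive")
        if len(self.wavelengths) != 2:
            raise ValidationError("exactly two wavelengths required")

    @property
    def total_duration(self) -> float:
        return float(sum(self.segment_durations))


@dataclass(frozen=True)
class CouplingSpec:
    coupled_channels: frozenset[int] = frozenset({19})
    period: float = 6.4
    strength_by_strategy: Mapping[str, float] = field(
        default_factory=lambda: {"delayed": 1.5, "immediate": 0.0, "none": 0.5}
    )
    lag: float = 0.0
    active_segments: frozenset[str] = frozenset(constants.TASK_SEGMENTS)
    bandwidth_octaves: float = 0.5

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValidationError("coupling period must be positive")
        if any(v < 0 for v in self.strength_by_strategy.values()):
            raise ValidationError("coupling strengths must be nonnegative")

    def strength_for(self, strategy: StrategyKind | str) -> float:
        key = StrategyKind.coerce(strategy).value
        return float(self.strength_by_strategy.get(key, 0.0))


@dataclass(frozen=True)
class NoiseSpec:
    """Amplitudes are concentration units (mM); typical hemodynamic noise
    is of order 1e-3 mM."""

    pink_exponent: float = 1.0
    pink_amplitude: float = 1.0e-3
    cardiac: tuple[float, float] = (1.0, 0.4e-3)
    respiration: tuple[float, float] = (0.25, 0.3e-3)
    mayer: tuple[float, float] = (0.1, 0.4e-3)
    white_sd: float = 0.3e-3
    artifact_rate: float = 1.0  # events per minute (used by inject_motion_artifacts)
    artifact_kinds: tuple[str, ...] = ("spike", "baseline_shift")

    def __post_init__(self) -> None:
        amps = [self.pink_amplitude, self.cardiac[1], self.respiration[1], self.mayer[1], self.white_sd]
        if any(a < 0 for a in amps):
            raise ValidationError("noise amplitudes must be nonnegative")
        if self.artifact_rate < 0:
            raise ValidationError("artifact_rate must be nonnegative")
        if any(k not in ("spike", "baseline_shift") for k in self.artifact_kinds):
            raise ValidationError("unknown artifact kind")


@dataclass
class HyperscanRecording:
    """Two-participant recording at one of three stages.

    ``data`` has shape (participant=2, channel, component=2, time); the
    component axis holds the two wavelengths at stages ``intensity``/``od``
    and (HbO, HbR) at stage ``hb``.
    """

    dyad_id: str
    stage: str
    data: np.ndarray
    fs: float
    timeline: pd.DataFrame
    wavelengths: tuple[float, float] = constants.WAVELENGTHS_NM
    source_detector_distance: float = constants.SOURCE_DETECTOR_DISTANCE_CM
    strategy: str | None = None
    bad_channels: np.ndarray | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in ("intensity", "od", "hb"):
            raise ValidationError(f"unknown stage {self.stage!r}")
        if self.data.ndim != 4 or self.data.shape[0] != 2 or self.data.shape[2] != 2:
            raise ValidationError("data must have shape (2, n_channels, 2, n_times)")
        if self.bad_channels is None:
            self.bad_channels = np.zeros(self.data.shape[:2], dtype=bool)
        if self.stage == "intensity" and not np.all(self.data > 0):
            raise ValidationError("intensity data must be strictly positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[-1]

    def copy_with(self, **kw) -> "HyperscanRecording":
        out = HyperscanRecording(
            dyad_id=kw.get("dyad_id", self.dyad_id),
            stage=kw.get("stage", self.stage),
            data=kw.get("data", self.data.copy()),
            fs=self.fs,
            timeline=self.timeline,
            wavelengths=self.wavelengths,
            source_detector_distance=self.source_detector_distance,
            strategy=self.strategy,
            bad_channels=kw.get("bad_channels", self.bad_channels.copy()),
            ground_truth=kw.get("ground_truth", dict(self.ground_truth)),
        )
        return out


def make_timeline(acq: AcquisitionConfig, session: DyadSession | None = None) -> pd.DataFrame:
    """Event table for the canonical block design.

    Returns segment rows (onset, duration, trial_type) plus, when a
    simulated session is given, per-trial go-signal markers placed by
    accumulating cue delay, the slower partner's RT, feedback time and the
    inter-trial interval inside each task block.  Raises
    :class:`ConfigError` when the simulated trials do not fit the block.
    """
    rows = []
    onset = 0.0
    seg_onsets: dict[str, float] = {}
    for label, dur in zip(acq.segment_labels, acq.segment_durations):
        rows.append({"onset": round(onset, 6), "duration": float(dur), "trial_type": label})
        seg_onsets[label] = onset
        onset += dur

    if session is not None:
        by_block: dict[int, list] = {}
        for t in session.trials:
            by_block.setdefault(t.block_index, []).append(t)
        task_labels = [s for s in acq.segment_labels if s.startswith("task")]
        if len(by_block) > len(task_labels):
            raise ConfigError("more trial blocks than task segments")
        for block_idx, trials in sorted(by_block.items()):
            label = task_labels[block_idx - 1]
            block_on = seg_onsets[label]
            block_dur = acq.segment_durations[acq.segment_labels.index(label)]
            t = block_on
            for trial in trials:
                go = t + trial.cue_delay
                rows.append(
                    {
                        "onset": round(go, 6),
                        "duration": 0.0,
                        "trial_type": f"trial_b{block_idx}",
                    }
                )
                t = go + max(trial.rt1, trial.rt2) + constants.FEEDBACK_DURATION_S + constants.INTER_TRIAL_INTERVAL_S
            if t > block_on + block_dur + 1e-9:
                raise ConfigError(
                    f"trials overflow segment {label}: end {t:.1f}s > {block_on + block_dur:.1f}s"
                )
    return pd.DataFrame(rows, columns=["onset", "duration", "trial_type"]).sort_values(
        "onset", kind="stable", ignore_index=True
    )


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD 1/f^exponent noise via spectral shaping."""
    white = rng.standard_normal(n)
    f = np.fft.rfftfreq(n, d=1.0)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(np.fft.rfft(white) * shape, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _narrowband_noise(
    n: int, fs: float, period: float, bandwidth_octaves: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-SD stochastic oscillation centered at 1/period with a Gaussian
    log-frequency envelope (SD = bandwidth/2 octaves)."""
    white = rng.standard_normal(n)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    f0 = 1.0 / period
    sigma_oct = max(bandwidth_octaves / 2.0, 1e-6)
    env = np.zeros_like(f)
    pos = f > 0
    env[pos] = np.exp(-0.5 * (np.log2(f[pos] / f0) / sigma_oct) ** 2)
    x = np.fft.irfft(np.fft.rfft(white) * env, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _segment_gate(times: np.ndarray, timeline: pd.DataFrame, segments: Iterable[str], ramp_s: float = 2.0) -> np.ndarray:
    """Indicator of the listed segments with raised-cosine on/off ramps."""
    gate = np.zeros_like(times)
    segs = set(segments)
    for _, row in timeline.iterrows():
        if row["trial_type"] in segs:
            on, off = float(row["onset"]), float(row["onset"]) + float(row["duration"])
            gate[(times >= on) & (times < off)] = 1.0
    if ramp_s > 0:
        w = max(int(ramp_s * (1.0 / (times[1] - times[0]))), 1)
        kernel = np.hanning(2 * w + 1)
        kernel /= kernel.sum()
        gate = np.convolve(gate, kernel, mode="same")
    return gate


def _channel_noise(n: int, fs: float, noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    """Physiological noise: 1/f drift plus quasi-periodic cardiac,
    respiratory and Mayer oscillations (narrowband noise, so that two
    independent channels genuinely decohere) plus white noise."""
    out = noise.pink_amplitude * _pink_noise(n, noise.pink_exponent, rng)
    for freq, amp in (noise.cardiac, noise.respiration, noise.mayer):
        if amp > 0 and freq < fs / 2:
            out += amp * _narrowband_noise(n, fs, 1.0 / freq, 0.4, rng)
    if noise.white_sd > 0:
        out += noise.white_sd * rng.standard_normal(n)
    return out


def hb_to_od(hbo: np.ndarray, hbr: np.ndarray, wavelengths, distance_cm: float, dpf: float) -> np.ndarray:
    """Forward modified Beer-Lambert: concentration (mM) -> optical density
    change per wavelength.  Returns array (..., 2, n_times)."""
    eps = constants.EXTINCTION_MM_CM
    od = np.stack(
        [
            (eps[w, 0] * hbo + eps[w, 1] * hbr) * distance_cm * dpf
            for w in range(2)
        ],
        axis=-2,
    )
    return od


def synthesize_dyad_recording(
    session: DyadSession,
    layout: ProbeLayout | None = None,
    acq: AcquisitionConfig | None = None,
    coupling: CouplingSpec | None = None,
    noise: NoiseSpec | None = None,
    seed: int | np.random.Generator = 0,
    dpf: float = constants.DIFFERENTIAL_PATHLENGTH_FACTOR,
) -> HyperscanRecording:
    """Generate a raw-intensity recording for one dyad.

    On ``coupling.coupled_channels`` and during ``coupling.active_segments``
    both participants share a narrowband oscillation at ``coupling.period``
    whose amplitude is ``strength * channel noise SD`` for the session's
    strategy; participant 2 receives it delayed by ``coupling.lag`` seconds.
    """
    layout = layout or ProbeLayout()
    acq = acq or AcquisitionConfig()
    coupling = coupling or CouplingSpec()
    noise = noise or NoiseSpec()
    if not (2.0 / acq.fs < coupling.period < min(acq.segment_durations)):
        raise ConfigError("coupling period outside the resolvable range")
    if any(c < 1 or c > layout.n_channels for c in coupling.coupled_channels):
        raise ConfigError("coupled channel index outside the probe layout")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    timeline = make_timeline(acq, session)
    n = int(round(acq.total_duration * acq.fs))
    times = np.arange(n) / acq.fs

    strength = coupling.strength_for(session.strategy)
    shared = _narrowband_noise(n, acq.fs, coupling.period, coupling.bandwidth_octaves, rng)
    lag_samples = int(round(coupling.lag * acq.fs))
    shared_lagged = np.roll(shared, lag_samples)
    gate = _segment_gate(times, timeline, coupling.active_segments)

    hbo = np.empty((2, layout.n_channels, n))
    hbr = np.empty_like(hbo)
    for p in range(2):
        src = shared if p == 0 else shared_lagged
        for c in range(layout.n_channels):
            base = _channel_noise(n, acq.fs, noise, rng)
            sd_ref = base.std()
            x = base.copy()
            if (c + 1) in coupling.coupled_channels and strength > 0:
                x = x + strength * sd_ref * src * gate
            hbo[p, c] = x
            hbr[p, c] = -x / 3.0 + 0.3 * sd_ref * _pink_noise(n, noise.pink_exponent, rng)

    od = hb_to_od(hbo, hbr, acq.wavelengths, acq.source_detector_distance, dpf)
    intensity = np.exp(-od)  # baseline intensity 1.0

    return HyperscanRecording(
        dyad_id=session.dyad_id,
        stage="intensity",
        data=intensity,
        fs=acq.fs,
        timeline=timeline,
        wavelengths=tuple(acq.wavelengths),
        source_detector_distance=acq.source_detector_distance,
        strategy=session.strategy.value,
        ground_truth={
            "hbo": hbo,
            "hbr": hbr,
            "coupling_signal": shared,
            "coupling_gate": gate,
            "coupled_channels": sorted(coupling.coupled_channels),
            "coupling_strength": strength,
            "dpf": dpf,
        },
    )


def inject_motion_artifacts(
    rec: HyperscanRecording,
    noise: NoiseSpec | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[HyperscanRecording, np.ndarray]:
    """Add spike and baseline-shift artifacts at Poisson-distributed times.

    Operates multiplicatively on intensity (equivalently additively in
    optical density).  Returns the corrupted recording and the ground-truth
    boolean mask with shape (2, n_channels, n_times).
    """
    noise = noise or NoiseSpec()
    if rec.stage not in ("intensity", "od"):
        raise StageError("artifacts are injected at the intensity or od stage")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = rec.n_times
    fs = rec.fs
    duration_min = n / fs / 60.0
    n_events = rng.poisson(noise.artifact_rate * duration_min)
    mask = np.zeros((2, rec.n_channels, n), dtype=bool)
    delta = np.zeros((2, rec.n_channels, 2, n))  # additive OD perturbation

    if rec.stage == "intensity":
        od_equiv = -np.log(rec.data / rec.data.mean(axis=-1, keepdims=True))
    else:
        od_equiv = rec.data
    sd = od_equiv.std(axis=-1)  # (2, n_ch, 2)

    for _ in range(n_events):
        p = int(rng.integers(2))
        c = int(rng.integers(rec.n_channels))
        kind = noise.artifact_kinds[int(rng.integers(len(noise.artifact_kinds)))]
        t0 = int(rng.integers(n))
        if kind == "spike":
            dur = rng.uniform(0.2, 0.8)
            half = max(int(dur * fs / 2), 1)
            amp = rng.uniform(10.0, 20.0) * (1 if rng.uniform() < 0.5 else -1)
            idx = np.arange(max(0, t0 - 3 * half), min(n, t0 + 3 * half + 1))
            bump = np.exp(-0.5 * ((idx - t0) / half) ** 2)
            for w in range(2):
                delta[p, c, w, idx] += amp * sd[p, c, w] * bump
            mask[p, c, idx[bump > 0.05]] = True
        else:
            amp = rng.uniform(5.0, 15.0) * (1 if rng.uniform() < 0.5 else -1)
            for w in range(2):
                delta[p, c, w, t0:] += amp * sd[p, c, w]
            half_w = int(0.5 * fs)
            mask[p, c, max(0, t0 - half_w) : min(n, t0 + half_w + 1)] = True

    if rec.stage == "intensity":
        data = rec.data * np.exp(-delta)
    else:
        data = rec.data + delta
    out = rec.copy_with(data=data)
    out.ground_truth["artifact_mask"] = mask
    return out, mask


def degrade_channel_snr(
    rec: HyperscanRecording,
    channels: Iterable[int],
    factor: float,
    seed: int | np.random.Generator = 0,
    participants: Iterable[int] = (0, 1),
) -> HyperscanRecording:
    """Inflate a channel's intensity noise SD by ``factor`` (1-based channel
    indices), pushing its mean/SD quality ratio down."""
    if rec.stage != "intensity":
        raise StageError("degrade_channel_snr operates on intensity data")
    channels = list(channels)
    if any(c < 1 or c > rec.n_channels for c in channels):
        raise ValidationError("unknown channel index")
    if factor < 0:
        raise ValidationError("factor must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    data = rec.data.copy()
    if factor > 1:
        extra = math.sqrt(factor**2 - 1.0)
        for p in participants:
            for c in channels:
                for w in range(2):
                    x = data[p, c - 1, w]
                    x = x + extra * x.std() * rng.standard_normal(x.size)
                    data[p, c - 1, w] = np.abs(x) + 1e-9
    return rec.copy_with(data=data)
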