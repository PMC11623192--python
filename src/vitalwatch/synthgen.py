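"""Synthetic multichannel vital-sign simulator with labelled anomalies.

Each channel is modelled as

    baseline_mean + circadian sinusoid + AR(1) noise

which captures the slowly varying set point, the diurnal rhythm, and the
short-range autocorrelation of sampled vitals (heart rate, pulse rate,
blood pressure, SpO2, respiration rate).  Anomalies are injected on top of
the clean stream with exact per-sample ground-truth labels, and streams can
be degraded with missing observations and irregular sampling so every
downstream stage is testable without external data.

Waveform-level morphology (ECG/PPG) is deliberately out of scope; the
simulator emulates sampled scalar vitals only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .frames import TIME_COLUMN, SensorFrame, ValidationError

__all__ = [
    "ChannelSpec",
    "AnomalySpec",
    "LabelledStream",
    "ScenarioConfig",
    "ANOMALY_KINDS",
    "DEFAULT_CHANNELS",
    "generate_baseline",
    "inject_anomalies",
    "degrade_stream",
    "make_dataset",
    "write_annotations",
    "write_anomaly_log",
]

ANOMALY_KINDS = ("spike", "level_shift", "drift", "dropout", "oscillation")

#: Broad physiologic plausibility ranges per canonical channel (channel units).
PHYSIOLOGIC_RANGES = {
    "heart_rate": (25.0, 250.0),
    "pulse_rate": (25.0, 250.0),
    "systolic_bp": (60.0, 260.0),
    "diastolic_bp": (30.0, 160.0),
    "spo2": (50.0, 100.0),
    "respiration_rate": (4.0, 70.0),
}

SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class ChannelSpec:
    """Statistical description of one vital-sign channel.

    ``ar_coefficient`` is the lag-1 autocorrelation of the noise component;
    stationarity requires |a| < 1, giving long-run noise variance
    ``noise_sd**2 / (1 - a**2)``.
    """

    name: str
    baseline_mean: float
    noise_sd: float
    circadian_amplitude: float = 0.0
    ar_coefficient: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        for attr in ("baseline_mean", "noise_sd", "circadian_amplitude", "ar_coefficient"):
            if not math.isfinite(float(getattr(self, attr))):
                raise ValidationError(f"channel {self.name!r}: {attr} must be finite")
        if self.noise_sd < 0:
            raise ValidationError(f"channel {self.name!r}: noise_sd must be >= 0")
        if abs(self.ar_coefficient) >= 1:
            raise ValidationError(
                f"channel {self.name!r}: |ar_coefficient| must be < 1 for stationarity"
            )
        rng = PHYSIOLOGIC_RANGES.get(self.name)
        if rng is not None and not (rng[0] <= self.baseline_mean <= rng[1]):
            raise ValidationError(
                f"channel {self.name!r}: baseline_mean {self.baseline_mean} outside "
                f"physiologic range {rng}"
            )


@dataclass(frozen=True)
class AnomalySpec:
    """One injected anomaly window with exact sample coverage."""

    kind: str
    channel: str
    start_index: int
    duration: int
    magnitude: float

    def __post_init__(self) -> None:
        if self.kind not in ANOMALY_KINDS:
            raise ValidationError(f"unknown anomaly kind {self.kind!r}; one of {ANOMALY_KINDS}")
        if self.start_index < 0:
            raise ValidationError("start_index must be >= 0")
        if self.duration < 1:
            raise ValidationError("duration must be >= 1")
        if not math.isfinite(float(self.magnitude)):
            raise ValidationError("magnitude must be finite")

    @property
    def end_index(self) -> int:
        """Exclusive end."""
        return self.start_index + self.duration


@dataclass
class LabelledStream:
    """A stream plus per-sample binary anomaly labels and the applied log."""

    frame: SensorFrame
    labels: np.ndarray
    anomaly_log: list[AnomalySpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.frame):
            raise ValidationError("labels length must equal frame length")


#: The six channels of the canonical bedside-monitor table, with defaults
#: matching typical resting adult vitals and modest sensor noise.
DEFAULT_CHANNELS = (
    ChannelSpec("heart_rate", 74.0, 1.5, circadian_amplitude=3.0, ar_coefficient=0.6, units="bpm"),
    ChannelSpec("pulse_rate", 73.0, 1.5, circadian_amplitude=3.0, ar_coefficient=0.6, units="bpm"),
    ChannelSpec("systolic_bp", 122.0, 2.0, circadian_amplitude=4.0, ar_coefficient=0.7, units="mmHg"),
    ChannelSpec("diastolic_bp", 80.0, 1.5, circadian_amplitude=3.0, ar_coefficient=0.7, units="mmHg"),
    ChannelSpec("spo2", 98.0, 0.4, circadian_amplitude=0.3, ar_coefficient=0.5, units="%"),
    ChannelSpec("respiration_rate", 18.0, 0.6, circadian_amplitude=1.0, ar_coefficient=0.5, units="breaths/min"),
)


def _channel_rng(seed: int, channel_index: int) -> np.random.Generator:
    # One generator per (seed, channel) so adding a channel leaves others unchanged.
    return np.random.default_rng([int(seed), int(channel_index)])


def generate_baseline(
    specs: list[ChannelSpec] | tuple[ChannelSpec, ...],
    n: int,
    dt: float = 1.0,
    seed: int = 0,
) -> SensorFrame:
    """Generate ``n`` samples of clean multichannel vitals.

    Each channel is ``mean + circadian_amplitude * sin(2*pi*t/day) + AR(1)``
    with the AR(1) component initialised from its stationary distribution.
    Deterministic given ``seed``.
    """
    specs = list(specs)
    if n < 1:
        raise ValidationError("n must be >= 1")
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    if not specs:
        raise ValidationError("at least one ChannelSpec is required")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate channel names in {names}")

    t = np.arange(n, dtype=float) * float(dt)
    data = {TIME_COLUMN: t}
    units = {}
    for idx, spec in enumerate(specs):
        rng = _channel_rng(seed, idx)
        a, s = spec.ar_coefficient, spec.noise_sd
        noise = np.zeros(n)
        if s > 0:
            eps = rng.normal(0.0, s, size=n)
            stat_sd = s / math.sqrt(1.0 - a * a)
            noise[0] = rng.normal(0.0, stat_sd)
            for k in range(1, n):
                noise[k] = a * noise[k - 1] + eps[k]
        circadian = spec.circadian_amplitude * np.sin(2.0 * np.pi * t / SECONDS_PER_DAY)
        data[spec.name] = spec.baseline_mean + circadian + noise
        units[spec.name] = spec.units
    return SensorFrame(pd.DataFrame(data), units)


def inject_anomalies(
    frame: SensorFrame,
    specs: list[AnomalySpec] | tuple[AnomalySpec, ...],
    seed: int = 0,
) -> LabelledStream:
    """Apply anomaly windows to a copy of ``frame`` with exact labels.

    Kinds: ``spike`` adds ``magnitude`` at every covered sample (duration is
    usually 1), ``level_shift`` adds a constant offset, ``drift`` adds a
    linear ramp from 0 up to ``magnitude``, ``dropout`` sets the samples
    missing, ``oscillation`` adds a full-cycle sinusoid of amplitude
    ``magnitude``.  Overlapping specs compose; labels are 1 exactly on the
    covered samples.
    """
    out = frame.copy()
    n = len(out)
    labels = np.zeros(n, dtype=int)
    for spec in specs:
        if spec.channel not in out.channels:
            raise ValidationError(f"anomaly channel {spec.channel!r} not in frame")
        if spec.end_index > n:
            raise ValidationError(
                f"anomaly [{spec.start_index}, {spec.end_index}) exceeds stream length {n}"
            )
        sl = slice(spec.start_index, spec.end_index)
        col = out.data[spec.channel].to_numpy(dtype=float)
        if spec.kind == "spike":
            col[sl] = col[sl] + spec.magnitude
        elif spec.kind == "level_shift":
            col[sl] = col[sl] + spec.magnitude
        elif spec.kind == "drift":
            ramp = np.linspace(0.0, spec.magnitude, spec.duration)
            col[sl] = col[sl] + ramp
        elif spec.kind == "dropout":
            col[sl] = np.nan
        elif spec.kind == "oscillation":
            phase = np.linspace(0.0, 2.0 * np.pi, spec.duration, endpoint=False)
            col[sl] = col[sl] + spec.magnitude * np.sin(phase)
        out.data[spec.channel] = col
        labels[sl] = 1
    return LabelledStream(out, labels, list(specs))


def degrade_stream(
    frame: SensorFrame,
    missing_rate: float,
    irregular: bool = False,
    seed: int = 0,
    keep_fraction: float = 0.7,
) -> SensorFrame:
    """Degrade a stream with independent missingness and/or irregular sampling.

    Every observation is masked missing independently with probability
    ``missing_rate``.  With ``irregular=True`` a random subset of rows
    (expected fraction ``keep_fraction``) is kept, preserving the original
    timestamps so gaps appear in the time column — emulating measurements
    made infrequently or at irregular intervals.
    """
    if not (0.0 <= missing_rate < 1.0):
        raise ValidationError("missing_rate must be in [0, 1)")
    if not (0.0 < keep_fraction <= 1.0):
        raise ValidationError("keep_fraction must be in (0, 1]")
    out = frame.copy()
    rng = np.random.default_rng([int(seed), 982_451_653])
    if missing_rate > 0:
        for ch in out.channels:
            mask = rng.random(len(out)) < missing_rate
            col = out.data[ch].to_numpy(dtype=float)
            col[mask] = np.nan
            out.data[ch] = col
    if irregular:
        keep = rng.random(len(out)) < keep_fraction
        keep[0] = True  # never drop the first sample: frames must be non-empty
        out = SensorFrame(out.data.loc[keep].reset_index(drop=True), dict(out.channel_units))
    return out


# --------------------------------------------------------------- scenarios


@dataclass(frozen=True)
class ScenarioConfig:
    """A full train/test generation scenario.

    ``anomaly_density`` is the target fraction of anomalous *samples* in the
    test stream; ``magnitude_sd`` scales event magnitudes in units of the
    affected channel's ``noise_sd``.  The training stream is always purely
    normal — the detector's contract is to be trained on typical data.
    """

    channels: tuple[ChannelSpec, ...] = DEFAULT_CHANNELS
    n_train: int = 8000
    n_test: int = 8004
    dt: float = 1.0
    anomaly_density: float = 0.05
    anomaly_kinds: tuple[str, ...] = ("spike", "level_shift")
    magnitude_sd: float = 6.0
    event_duration: int = 20
    missing_rate: float = 0.0
    irregular: bool = False

    def __post_init__(self) -> None:
        if self.n_train < 1 or self.n_test < 1:
            raise ValidationError("n_train and n_test must be >= 1")
        if not (0.0 <= self.anomaly_density < 1.0):
            raise ValidationError("anomaly_density must be in [0, 1)")
        for k in self.anomaly_kinds:
            if k not in ANOMALY_KINDS:
                raise ValidationError(f"unknown anomaly kind {k!r}")

    def with_magnitude(self, magnitude_sd: float) -> "ScenarioConfig":
        return replace(self, magnitude_sd=magnitude_sd)


def _sample_events(config: ScenarioConfig, rng: np.random.Generator) -> list[AnomalySpec]:
    """Draw non-overlapping anomaly events totalling ~density*n_test samples."""
    n = config.n_test
    budget = int(round(config.anomaly_density * n))
    events: list[AnomalySpec] = []
    occupied = np.zeros(n, dtype=bool)
    specs = list(config.channels)
    attempts = 0
    covered = 0
    while covered < budget and attempts < 50 * max(budget, 1):
        attempts += 1
        kind = str(rng.choice(list(config.anomaly_kinds)))
        duration = 1 if kind == "spike" else int(config.event_duration)
        duration = min(duration, budget - covered) if kind != "spike" else duration
        duration = max(duration, 1)
        if duration > n:
            continue
        start = int(rng.integers(0, n - duration + 1))
        # keep one clean sample of margin between events
        lo, hi = max(0, start - 1), min(n, start + duration + 1)
        if occupied[lo:hi].any():
            continue
        ch_idx = int(rng.integers(0, len(specs)))
        spec = specs[ch_idx]
        sign = -1.0 if rng.random() < 0.5 else 1.0
        if spec.name == "spo2" and sign > 0:
            sign = -1.0  # saturation cannot meaningfully exceed 100%
        magnitude = sign * config.magnitude_sd * max(spec.noise_sd, 1e-12)
        events.append(AnomalySpec(kind, spec.name, start, duration, magnitude))
        occupied[start : start + duration] = True
        covered += duration
    events.sort(key=lambda e: e.start_index)
    return events


def make_dataset(config: ScenarioConfig, seed: int = 0) -> tuple[LabelledStream, LabelledStream]:
    """Generate a normal-only training stream and a labelled test stream.

    Train and test use disjoint generator seeds derived from ``seed``;
    anomalies (and degradation, if configured) are applied to the test
    stream only.
    """
    train_frame = generate_baseline(config.channels, config.n_train, config.dt, seed=2 * seed + 1)
    test_frame = generate_baseline(config.channels, config.n_test, config.dt, seed=2 * seed + 2)
    rng = np.random.default_rng([int(seed), 15_485_863])
    events = _sample_events(config, rng)
    test = inject_anomalies(test_frame, events, seed=seed)
    if config.missing_rate > 0 or config.irregular:
        degraded = degrade_stream(
            test.frame, config.missing_rate, irregular=False, seed=seed
        )
        test = LabelledStream(degraded, test.labels, test.anomaly_log)
    train = LabelledStream(train_frame, np.zeros(config.n_train, dtype=int), [])
    return train, test


# ------------------------------------------------------------- annotations


def write_annotations(stream: LabelledStream, path) -> None:
    """Write applied anomaly windows as 3-column text: channel, start, end."""
    with open(path, "w") as fh:
        for spec in stream.anomaly_log:
            fh.write(f"{spec.channel}\t{spec.start_index}\t{spec.end_index}\n")


def write_anomaly_log(stream: LabelledStream, path) -> None:
    """Write the full anomaly log as JSON."""
    payload = [
        {
            "kind": s.kind,
            "channel": s.channel,
            "start_index": s.start_index,
            "duration": s.duration,
            "magnitude": s.magnitude,
        }
        for s in stream.anomaly_log
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
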