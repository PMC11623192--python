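"""Declarative pipeline configuration (YAML) with validation.

One file drives the whole chain: scenario generation, preprocessing,
feature extraction, discriminant projection, feature selection, detector
training and evaluation.  A single ``seed`` governs every source of
randomness.  Unknown keys and invalid values are collected into a
violation list rather than raised one at a time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .agrnn import DetectorConfig
from .synthgen import ANOMALY_KINDS, DEFAULT_CHANNELS, ScenarioConfig

__all__ = ["PipelineConfig", "ConfigError", "load_config", "default_config"]


class ConfigError(ValueError):
    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid configuration:\n" + "\n".join(f"- {v}" for v in violations))


@dataclass
class PipelineConfig:
    seed: int = 0
    scenario: dict = field(default_factory=dict)
    preprocessing: dict = field(default_factory=dict)
    feature: dict = field(default_factory=dict)
    dpca: dict = field(default_factory=dict)
    rfe: dict = field(default_factory=dict)
    agrnn: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)

    SECTION_DEFAULTS = {
        "scenario": {
            "n_train": 8000,
            "n_test": 8004,
            "dt": 1.0,
            "anomaly_density": 0.05,
            "anomaly_kinds": ["spike", "level_shift"],
            "magnitude_sd": 6.0,
            "event_duration": 20,
            "missing_rate": 0.0,
        },
        "preprocessing": {"smooth": False, "process_var": 1e-4, "band_multiple": 2.0},
        "feature": {
            "window": 8,
            "stride": 4,
            "xcorr_pairs": [["heart_rate", "pulse_rate"], ["systolic_bp", "diastolic_bp"]],
        },
        "dpca": {"K": 10, "gamma": 1.0, "rho": None},
        "rfe": {"enabled": True, "target": 20, "folds": 5},
        "agrnn": {
            "bottleneck": None,
            "ae_epochs": 500,
            "ae_learning_rate": 0.01,
            "ga_population": 10,
            "ga_generations": 8,
            "ga_rnn_epochs": 15,
            "rnn_hidden": 6,
            "rnn_epochs": 100,
            "rnn_learning_rate": 0.01,
            "val_fraction": 0.3,
            "val_anomaly_density": 0.08,
            "val_magnitude_sd": 6.0,
        },
        "evaluation": {"k": 6, "max_windows": 900, "kfold": True},
    }

    def __post_init__(self) -> None:
        for section, defaults in self.SECTION_DEFAULTS.items():
            merged = dict(defaults)
            merged.update(getattr(self, section) or {})
            setattr(self, section, merged)

    # -------------------------------------------------------- validation

    def n_raw_features(self) -> int:
        n_channels = len(DEFAULT_CHANNELS)
        return n_channels * 5 + len(self.feature["xcorr_pairs"])

    def validate(self) -> list[str]:
        v: list[str] = []
        for section, defaults in self.SECTION_DEFAULTS.items():
            for key in getattr(self, section):
                if key not in defaults:
                    v.append(f"{section}.{key}: unknown key")
        sc = self.scenario
        if sc["n_train"] < 1 or sc["n_test"] < 1:
            v.append("scenario.n_train and scenario.n_test must be >= 1")
        if not (0 <= sc["anomaly_density"] < 1):
            v.append("scenario.anomaly_density must be in [0, 1)")
        for kind in sc["anomaly_kinds"]:
            if kind not in ANOMALY_KINDS:
                v.append(f"scenario.anomaly_kinds: unknown kind {kind!r}")
        if self.feature["window"] < 4:
            v.append("feature.window must be >= 4")
        if self.feature["stride"] < 1:
            v.append("feature.stride must be >= 1")
        if not (0 <= self.dpca["gamma"] <= 1):
            v.append("dpca.gamma must be in [0, 1]")
        if self.dpca["rho"] is not None and not (0 <= self.dpca["rho"] <= 1):
            v.append("dpca.rho must be in [0, 1] or null")
        p = self.n_raw_features()
        if self.rfe["enabled"] and not (1 <= self.rfe["target"] <= p):
            v.append(f"rfe.target must be in [1, {p}] for this feature configuration")
        if self.rfe["folds"] < 2:
            v.append("rfe.folds must be >= 2")
        if self.agrnn["ga_population"] < 2:
            v.append("agrnn.ga_population must be >= 2")
        if self.evaluation["k"] < 2:
            v.append("evaluation.k must be >= 2")
        if not float(self.scenario["dt"]) > 0:
            v.append("scenario.dt must be > 0")
        for key in ("ae_epochs", "ga_generations", "rnn_epochs", "rnn_hidden"):
            if self.agrnn[key] < 1:
                v.append(f"agrnn.{key} must be >= 1")
        return v

    # ------------------------------------------------------- conversions

    def scenario_config(self) -> ScenarioConfig:
        sc = self.scenario
        return ScenarioConfig(
            channels=DEFAULT_CHANNELS,
            n_train=int(sc["n_train"]),
            n_test=int(sc["n_test"]),
            dt=float(sc["dt"]),
            anomaly_density=float(sc["anomaly_density"]),
            anomaly_kinds=tuple(sc["anomaly_kinds"]),
            magnitude_sd=float(sc["magnitude_sd"]),
            event_duration=int(sc["event_duration"]),
            missing_rate=float(sc["missing_rate"]),
        )

    def detector_config(self, feature_subset: tuple[str, ...] | None = None) -> DetectorConfig:
        f, a = self.feature, self.agrnn
        return DetectorConfig(
            window=int(f["window"]),
            stride=int(f["stride"]),
            xcorr_pairs=tuple(tuple(p) for p in f["xcorr_pairs"]),
            feature_subset=feature_subset,
            bottleneck=a["bottleneck"],
            ae_epochs=int(a["ae_epochs"]),
            ae_learning_rate=float(a["ae_learning_rate"]),
            ga_population=int(a["ga_population"]),
            ga_generations=int(a["ga_generations"]),
            ga_rnn_epochs=int(a["ga_rnn_epochs"]),
            rnn_hidden=int(a["rnn_hidden"]),
            rnn_epochs=int(a["rnn_epochs"]),
            rnn_learning_rate=float(a["rnn_learning_rate"]),
            val_fraction=float(a["val_fraction"]),
            val_anomaly_density=float(a["val_anomaly_density"]),
            val_magnitude_sd=float(a["val_magnitude_sd"]),
        )

    # --------------------------------------------------------------- I/O

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            **{s: dict(getattr(self, s)) for s in self.SECTION_DEFAULTS},
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Parse and validate a YAML config; raises ConfigError on violations."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(["configuration root must be a mapping"])
    known = {"seed", *PipelineConfig.SECTION_DEFAULTS}
    violations = [f"{k}: unknown top-level key" for k in raw if k not in known]
    cfg = PipelineConfig(
        seed=int(raw.get("seed", 0)),
        **{s: raw.get(s, {}) or {} for s in PipelineConfig.SECTION_DEFAULTS},
    )
    violations += cfg.validate()
    if violations:
        raise ConfigError(violations)
    return cfg


def default_config(seed: int = 0) -> PipelineConfig:
    return PipelineConfig(seed=seed)
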