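"""YAML study configuration for the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .phantom import PhantomSpec
from .simulate import SignalModel

__all__ = ["StudyConfig", "PatientConfig", "AnalysisConfig", "LongitudinalConfig",
           "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or incomplete study configuration."""


@dataclass(frozen=True)
class PatientConfig:
    id: str
    mode: str = "functional"
    gamma: float = 0.8
    network: int = 0  # functional mode
    n_blocks: int = 2
    centre: tuple | None = None  # spatial mode
    radius_mm: float = 4.5
    tau_mm: float = 6.0
    tumour_hemisphere: str = "L"


@dataclass(frozen=True)
class AnalysisConfig:
    fwhm_mm: float = 3.0
    smooth_rel_threshold: float = 0.05
    mad_consistency: bool = False
    use_fisher_z: bool = True
    restrict_attribution_to_anomalous: bool = True
    anomaly_threshold: float = -2.3
    anomaly_thresholds: tuple = (1.5, 2.0, 2.3, 2.6, 3.0)
    connectivity_threshold_r: float = 0.25
    vicinity_mm: float = 10.0
    min_new_cm3: float = 3.0
    n_perm: int = 2000


@dataclass(frozen=True)
class LongitudinalConfig:
    enabled: bool = False
    patient_id: str = "long01"
    pre_gamma: float = 0.8
    post_gamma: float = 0.3
    followup_gamma: float = 0.15
    recurrence_gamma: float = 0.8
    mode: str = "spatial"
    tau_mm: float = 6.0


@dataclass(frozen=True)
class StudyConfig:
    seed: int = 0
    output_dir: str = "canomap-out"
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    signal: SignalModel = field(default_factory=SignalModel)
    n_controls: int = 20
    patients: tuple = ()
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    longitudinal: LongitudinalConfig = field(default_factory=LongitudinalConfig)

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ConfigError("config must name at least 2 controls (n_controls >= 2)")
        ids = [p.id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate patient ids")


def _tuple(x):
    return tuple(x) if isinstance(x, (list, tuple)) else x


def load_config(path_or_dict) -> StudyConfig:
    """Load and validate a study configuration from YAML (or a dict)."""
    if isinstance(path_or_dict, (str, Path)):
        raw = yaml.safe_load(Path(path_or_dict).read_text())
    else:
        raw = dict(path_or_dict)
    if raw is None:
        raise ConfigError("empty configuration")
    if "controls" not in raw and "n_controls" not in raw:
        raise ConfigError("configuration missing the control list (controls.n)")
    try:
        n_controls = (
            int(raw["controls"]["n"]) if "controls" in raw else int(raw["n_controls"])
        )
        phantom = PhantomSpec(
            **{
                k: _tuple(v)
                for k, v in raw.get("phantom", {}).items()
            }
        )
        signal = SignalModel(**raw.get("signal", {}))
        patients = tuple(
            PatientConfig(**{k: _tuple(v) for k, v in p.items()})
            for p in raw.get("patients", [])
        )
        analysis = AnalysisConfig(
            **{k: _tuple(v) for k, v in raw.get("analysis", {}).items()}
        )
        longitudinal = LongitudinalConfig(**raw.get("longitudinal", {}))
        return StudyConfig(
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw.get("output_dir", "canomap-out")),
            phantom=phantom,
            signal=signal,
            n_controls=n_controls,
            patients=patients,
            analysis=analysis,
            longitudinal=longitudinal,
        )
    except (TypeError, KeyError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc
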