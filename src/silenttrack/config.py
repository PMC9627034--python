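"""Pipeline configuration: schema, YAML loading, provenance hashing.

Defaults mirror the analysis constants used throughout the package: delta
band 1–3 Hz, theta 4–7 Hz, coherence grid 1–25 Hz in 0.5-Hz steps with 3 Hz
multitaper smoothing, 2-s trials, 9-ms stimulus delay, 1000 permutations at
cluster alpha 0.05.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import InvalidParameterError

__all__ = ["PipelineConfig", "load_config", "save_config", "config_hash"]


@dataclass
class PipelineConfig:
    # frequency structure
    delta_band: tuple[float, float] = (1.0, 3.0)
    theta_band: tuple[float, float] = (4.0, 7.0)
    combined_band: tuple[float, float] = (1.0, 7.0)
    coherence_f_lo: float = 1.0
    coherence_f_hi: float = 25.0
    coherence_f_step: float = 0.5
    coherence_smoothing_hz: float = 3.0
    # timing
    trial_len_s: float = 2.0
    stimulus_delay_ms: float = 9.0
    analysis_rate_hz: float = 150.0
    # inference
    n_permutations: int = 1000
    cluster_alpha: float = 0.05
    connectivity: int = 18
    # simulated cohort
    n_subjects: int = 50
    age_low: float = 19.0
    age_high: float = 63.0
    n_trials_per_condition: int = 60
    grid_shape: tuple[int, int, int] = (6, 6, 6)
    grid_spacing_mm: float = 10.0
    coupling_preset: str = "headline"  # headline | zero
    sensor_space: bool = False
    n_sensors: int = 64
    sensor_noise_sd: float = 0.05
    lcmv_lambda: float = 0.05
    # bookkeeping
    seed: int = 0
    out_dir: str = "results"
    features: tuple[str, ...] = ("lip", "envelope", "formant", "pitch")

    def validate(self) -> "PipelineConfig":
        if self.n_permutations < 1:
            raise InvalidParameterError("n_permutations must be >= 1")
        if not 0 < self.cluster_alpha < 1:
            raise InvalidParameterError("cluster_alpha must lie in (0, 1)")
        for name in ("delta_band", "theta_band", "combined_band"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise InvalidParameterError(f"{name} must be (low, high) with low < high")
        if not self.coherence_f_lo < self.coherence_f_hi:
            raise InvalidParameterError("coherence_f_lo must be below coherence_f_hi")
        if self.coherence_f_step <= 0 or self.coherence_smoothing_hz <= 0:
            raise InvalidParameterError("frequency step and smoothing must be positive")
        if self.trial_len_s <= 0:
            raise InvalidParameterError("trial_len_s must be positive")
        if self.n_subjects < 3:
            raise InvalidParameterError("n_subjects must be >= 3")
        if not self.age_low < self.age_high:
            raise InvalidParameterError("age_low must be below age_high")
        if self.n_trials_per_condition < 1:
            raise InvalidParameterError("n_trials_per_condition must be >= 1")
        if self.coupling_preset not in ("headline", "zero"):
            raise InvalidParameterError("coupling_preset must be 'headline' or 'zero'")
        if self.connectivity not in (6, 18, 26):
            raise InvalidParameterError("connectivity must be 6, 18 or 26")
        unknown = set(self.features) - {"lip", "envelope", "formant", "pitch"}
        if unknown:
            raise InvalidParameterError(f"unknown features {sorted(unknown)}")
        return self


_TUPLE_FIELDS = {
    "delta_band",
    "theta_band",
    "combined_band",
    "grid_shape",
    "features",
}


def load_config(path: str | Path) -> PipelineConfig:
    """Parse and validate a YAML config; unknown keys are rejected, missing
    keys take the defaults.  An empty file yields the all-defaults config."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        loc = f" (line {mark.line + 1})" if mark is not None else ""
        raise InvalidParameterError(f"{path}: malformed YAML{loc}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise InvalidParameterError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise InvalidParameterError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in _TUPLE_FIELDS & set(raw):
        raw[key] = tuple(raw[key])
    try:
        cfg = PipelineConfig(**raw)
    except TypeError as exc:
        raise InvalidParameterError(f"{path}: invalid config value ({exc})") from exc
    return cfg.validate()


def save_config(path: str | Path, cfg: PipelineConfig) -> None:
    data = asdict(cfg)
    for key in _TUPLE_FIELDS:
        data[key] = list(data[key])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def config_hash(cfg: PipelineConfig) -> str:
    """Stable short hash of the canonical config JSON, used for provenance.

    The output directory is excluded: it names where results go, not what
    is computed, so the same analysis written to two places shares a hash.
    """
    data = asdict(cfg)
    data.pop("out_dir")
    for key in _TUPLE_FIELDS:
        data[key] = list(data[key])
    blob = json.dumps(data, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
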