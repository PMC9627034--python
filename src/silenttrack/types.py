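"""Core data containers shared across the pipeline.

All containers are thin dataclasses around numpy arrays; heavy computation
lives in the functional modules.  Sampling-rate conventions:

* stimulus audio: 48 kHz by default
* stimulus video: 50 frames/s by default
* sensor recordings: 1 kHz by default
* analysis timeline: 150 Hz, 2-s trials of 300 samples
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidParameterError

FEATURES = ("lip", "envelope", "formant", "pitch")
CONDITIONS = ("natural", "reversed")
REGIONS = ("occipital", "cingulate", "other")

ANALYSIS_RATE_HZ = 150.0
TRIAL_LEN_S = 2.0
TRIAL_LEN_SAMPLES = 300


@dataclass
class AudioWave:
    """Mono audio signal with its sampling rate (Hz)."""

    samples: np.ndarray
    rate_hz: float = 48000.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise InvalidParameterError("audio must be a non-empty 1-D array")
        if not self.rate_hz > 0:
            raise InvalidParameterError("rate_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidParameterError("audio samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate_hz

    def reversed(self) -> "AudioWave":
        return replace(self, samples=self.samples[::-1].copy())


@dataclass
class VideoFrames:
    """Stack of grayscale frames, intensities in [0, 1]."""

    frames: np.ndarray  # (n_frames, height, width)
    fps: float = 50.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise InvalidParameterError("frames must be (n_frames, height, width)")
        if not self.fps > 0:
            raise InvalidParameterError("fps must be positive")

    @property
    def frame_size(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    def reversed(self) -> "VideoFrames":
        return replace(self, frames=self.frames[::-1].copy())


@dataclass
class FeaturePlan:
    """Piecewise-linear plan for a time-varying scalar (Hz or px^2)."""

    times_s: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.size != self.values.size or self.times_s.size < 1:
            raise InvalidParameterError("times and values must have equal, nonzero length")
        if np.any(np.diff(self.times_s) <= 0):
            raise InvalidParameterError("breakpoint times must be strictly increasing")

    @classmethod
    def constant(cls, value: float, duration_s: float) -> "FeaturePlan":
        return cls(np.array([0.0, duration_s]), np.array([value, value]))

    def sample(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation, clamped to the first/last planned value."""
        return np.interp(t, self.times_s, self.values)


@dataclass
class FeatureTrack:
    """One stimulus feature as a uniformly sampled series."""

    name: str
    samples: np.ndarray
    rate_hz: float
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise InvalidParameterError("feature track must be 1-D")
        if not self.rate_hz > 0:
            raise InvalidParameterError("rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.samples.size


@dataclass
class FormantSet:
    """Per-frame formant candidates at a fixed analysis frame rate.

    ``freqs_hz``/``bands_hz`` are (n_frames, n_formants) arrays, NaN where a
    frame yielded fewer candidates than slots.
    """

    freqs_hz: np.ndarray
    bands_hz: np.ndarray
    rate_hz: float = 200.0

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.bands_hz = np.asarray(self.bands_hz, dtype=float)
        if self.freqs_hz.shape != self.bands_hz.shape or self.freqs_hz.ndim != 2:
            raise InvalidParameterError("freqs and bandwidths must share a 2-D shape")

    @property
    def n_frames(self) -> int:
        return self.freqs_hz.shape[0]


@dataclass
class SensorRecording:
    """Continuous multichannel sensor data (channels x samples)."""

    data: np.ndarray
    rate_hz: float = 1000.0
    channel_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidParameterError("sensor data must be channels x samples")
        if not self.rate_hz > 0:
            raise InvalidParameterError("rate_hz must be positive")
        if not np.all(np.isfinite(self.data)):
            raise InvalidParameterError("sensor data must be finite")
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i:03d}" for i in range(self.data.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class SourceGrid:
    """Regular 3-D voxel grid with anatomical region labels.

    Voxels are enumerated in C order over the grid shape; ``region_labels``
    assigns each voxel to occipital / cingulate / other, standing in for an
    anatomical atlas parcellation.
    """

    shape: tuple[int, int, int]
    spacing_mm: float
    coords_mm: np.ndarray  # (n_voxels, 3)
    region_labels: np.ndarray  # (n_voxels,) of str

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def region_mask(self, region: str) -> np.ndarray:
        if region not in REGIONS:
            raise InvalidParameterError(f"unknown region {region!r}; expected one of {REGIONS}")
        return self.region_labels == region


@dataclass
class ForwardModel:
    """Fixed-orientation toy forward model: lead field sensors x voxels."""

    leadfield: np.ndarray
    grid: SourceGrid

    def __post_init__(self) -> None:
        self.leadfield = np.asarray(self.leadfield, dtype=float)
        if self.leadfield.ndim != 2:
            raise InvalidParameterError("lead field must be sensors x voxels")
        if self.leadfield.shape[1] != self.grid.n_voxels:
            raise InvalidParameterError("lead-field voxel count must match the grid")
        norms = np.linalg.norm(self.leadfield, axis=0)
        if np.any(norms == 0):
            raise InvalidParameterError("lead field contains an all-zero column")

    @property
    def n_sensors(self) -> int:
        return self.leadfield.shape[0]


@dataclass
class SpatialFilter:
    """LCMV beamformer weights (voxels x sensors) with unit source gain."""

    weights: np.ndarray
    lambda_frac: float

    @property
    def n_voxels(self) -> int:
        return self.weights.shape[0]


@dataclass
class TrialSet:
    """Epoched data: trials x channels(or voxels) x samples at 150 Hz."""

    data: np.ndarray
    rate_hz: float = ANALYSIS_RATE_HZ
    condition: str = "natural"
    subject_id: str = ""
    space: str = "sensor"  # "sensor" | "source"

    def __post_init__(self) -> None:
        # float32 trial stacks are accepted as-is to keep large cohorts cheap
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.floating):
            self.data = self.data.astype(float)
        if self.data.ndim != 3:
            raise InvalidParameterError("trial data must be trials x channels x samples")
        if self.condition not in CONDITIONS:
            raise InvalidParameterError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class CrossSpectra:
    """Multitaper auto- and cross-spectra between voxels and one feature."""

    freqs_hz: np.ndarray  # (n_freqs,)
    s_xx: np.ndarray  # (n_voxels, n_freqs) real
    s_yy: np.ndarray  # (n_freqs,) real
    s_xy: np.ndarray  # (n_voxels, n_freqs) complex
    n_tapers: int = 0
    n_trials: int = 0


@dataclass
class CoherenceMap:
    """Coherence per voxel x frequency for one feature/condition/subject."""

    values: np.ndarray  # (n_voxels, n_freqs) in [0, 1]
    freqs_hz: np.ndarray
    feature: str
    condition: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)


@dataclass
class IndexMap:
    """Band-averaged intelligibility index (natural - reversed) per voxel."""

    values: np.ndarray  # (n_voxels,)
    band: tuple[float, float]
    feature: str
    subject_id: str = ""


@dataclass
class StatMap:
    """Voxel-wise Pearson r against age and the corresponding t statistic."""

    r: np.ndarray
    t: np.ndarray
    n_subjects: int


@dataclass
class Cluster:
    """One sign-homogeneous connected cluster of suprathreshold voxels."""

    voxels: np.ndarray  # sorted voxel indices
    sign: int  # +1 / -1
    mass: float  # sum of member t values
    p_value: float


@dataclass
class ClusterResult:
    """Outcome of the cluster-based permutation test."""

    clusters: list[Cluster]
    stat_map: StatMap
    n_permutations: int
    cluster_alpha: float
    seed: int
    null_max_mass: np.ndarray = field(default_factory=lambda: np.empty(0))

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_value <= alpha]

    @property
    def min_p(self) -> float:
        return min((c.p_value for c in self.clusters), default=1.0)


@dataclass
class RoiFit:
    """OLS fit of ROI-mean intelligibility index on age."""

    roi: str
    slope: float
    intercept: float
    f_stat: float
    p_value: float
    r_squared: float
    eta_squared: float
    df_den: int
    subject_means: np.ndarray = field(default_factory=lambda: np.empty(0))
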