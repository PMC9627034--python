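"""Synthetic audiovisual stimuli and neural cohorts with planted coupling.

This module generates every input the analysis pipeline consumes, with known
ground truth:

* vowel-like audio from a source--filter model (glottal impulse train through
  time-varying formant resonators) to exercise the acoustic extractors;
* mouth-aperture videos (a filled ellipse whose area follows a plan) for the
  lip-area extractor;
* a bank of band-limited feature tracks with a requested cross-correlation
  structure, standing in for the four speech features;
* an aging cohort whose source-space activity couples to the feature tracks
  with region-, condition- and age-dependent gains, plus 1/f background
  noise — the planted effect the statistics layer must recover.

Every generator is a pure function of its parameters and a seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .errors import InvalidParameterError
from .types import (
    CONDITIONS,
    FEATURES,
    REGIONS,
    TRIAL_LEN_SAMPLES,
    AudioWave,
    FeaturePlan,
    FeatureTrack,
    ForwardModel,
    SensorRecording,
    SourceGrid,
    TrialSet,
    VideoFrames,
)

__all__ = [
    "CouplingModel",
    "SyntheticCohort",
    "synthesize_vowel_audio",
    "synthesize_lip_video",
    "generate_feature_bank",
    "build_grid",
    "make_forward_model",
    "simulate_cohort",
    "project_to_sensors",
    "one_over_f_noise",
]


# ---------------------------------------------------------------------------
# audio synthesis
# ---------------------------------------------------------------------------

def synthesize_vowel_audio(
    formant_plans: list[FeaturePlan],
    pitch_plan: FeaturePlan,
    duration_s: float,
    rate_hz: float = 48000.0,
    bandwidths_hz: tuple[float, ...] | None = None,
) -> AudioWave:
    """Source--filter vowel synthesis with time-varying formants.

    A glottal-pulse excitation (impulse train at the instantaneous pitch) is
    passed through cascaded two-pole resonators centered at the planned
    formant frequencies.  The output is peak-normalized to 0.9.

    Parameters
    ----------
    formant_plans : at least three plans with centers in (0, rate_hz/2).
    pitch_plan : fundamental-frequency plan, values in [50, 400] Hz.
    bandwidths_hz : one -3 dB bandwidth per formant; defaults to
        (80, 120, 160, 200, 240)[: n_formants].
    """
    if duration_s <= 0:
        raise InvalidParameterError("duration_s must be positive")
    if len(formant_plans) < 3:
        raise InvalidParameterError("need at least three formant plans")
    nyq = rate_hz / 2.0
    for plan in formant_plans:
        if np.any(plan.values <= 0) or np.any(plan.values >= nyq):
            raise InvalidParameterError("formant centers must lie in (0, Nyquist)")
    if np.any(pitch_plan.values < 50) or np.any(pitch_plan.values > 400):
        raise InvalidParameterError("pitch values must lie in [50, 400] Hz")
    if bandwidths_hz is None:
        bandwidths_hz = (80.0, 120.0, 160.0, 200.0, 240.0)[: len(formant_plans)]
    if len(bandwidths_hz) != len(formant_plans):
        raise InvalidParameterError("one bandwidth per formant plan required")

    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz

    # impulse train by phase accumulation: a pulse whenever the running
    # integral of f0 crosses an integer
    f0 = pitch_plan.sample(t)
    phase = np.cumsum(f0) / rate_hz
    excitation = np.zeros(n)
    excitation[np.flatnonzero(np.diff(np.floor(phase), prepend=0.0) > 0)] = 1.0

    # cascade of time-varying 2-pole resonators, applied in short blocks with
    # carried filter state so slow parameter drift stays click-free
    block = max(1, int(round(0.005 * rate_hz)))
    out = excitation
    for plan, bw in zip(formant_plans, bandwidths_hz):
        centers = plan.sample(t)
        y = np.empty(n)
        zi = np.zeros(2)
        for start in range(0, n, block):
            stop = min(start + block, n)
            fc = centers[(start + stop) // 2]
            r = np.exp(-np.pi * bw / rate_hz)
            theta = 2 * np.pi * fc / rate_hz
            a = np.array([1.0, -2 * r * np.cos(theta), r * r])
            y[start:stop], zi = signal.lfilter([1.0], a, out[start:stop], zi=zi)
        out = y

    peak = np.max(np.abs(out))
    if peak > 0:
        out = 0.9 * out / peak
    return AudioWave(out, rate_hz=rate_hz)


# ---------------------------------------------------------------------------
# lip video synthesis
# ---------------------------------------------------------------------------

def synthesize_lip_video(
    aperture_plan: FeaturePlan,
    fps: float = 50.0,
    frame_size: tuple[int, int] = (96, 128),
    duration_s: float | None = None,
) -> VideoFrames:
    """Render a centered bright ellipse whose area follows the plan.

    The ellipse keeps a fixed 2:1 (width:height) axis ratio, so for a planned
    area A the semi-axes are a = sqrt(2A/pi) horizontally and a/2 vertically.
    Area 0 produces an all-dark (closed mouth) frame.
    """
    if fps <= 0:
        raise InvalidParameterError("fps must be positive")
    h, w = frame_size
    if duration_s is None:
        duration_s = float(aperture_plan.times_s[-1])
    n_frames = int(round(duration_s * fps))
    if n_frames < 1:
        raise InvalidParameterError("duration too short for a single frame")
    t = np.arange(n_frames) / fps
    areas = aperture_plan.sample(t)
    if np.any(areas < 0):
        raise InvalidParameterError("planned areas must be non-negative")
    max_a = np.sqrt(2 * np.max(areas) / np.pi)
    if 2 * max_a > w or max_a > h:
        raise InvalidParameterError("planned aperture does not fit inside the frame")

    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    frames = np.zeros((n_frames, h, w))
    for i, area in enumerate(areas):
        if area <= 0:
            continue
        a = np.sqrt(2 * area / np.pi)  # horizontal semi-axis
        b = a / 2.0
        mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
        frames[i][mask] = 1.0
    return VideoFrames(frames, fps=fps)


# ---------------------------------------------------------------------------
# feature bank
# ---------------------------------------------------------------------------

def generate_feature_bank(
    duration_s: float,
    rate_hz: float = 150.0,
    cross_corr: np.ndarray | None = None,
    band_hz: tuple[float, float] = (1.0, 7.0),
    seed: int = 0,
) -> dict[str, FeatureTrack]:
    """Band-limited Gaussian stand-ins for the four speech-feature tracks.

    Independent Gaussian processes band-limited to ``band_hz`` are mixed by
    the Cholesky factor of ``cross_corr`` so their pairwise correlations match
    the request; each track is then standardized to mean 0, SD 1 (scaling
    leaves correlations untouched).
    """
    if cross_corr is None:
        cross_corr = np.eye(len(FEATURES))
    cross_corr = np.asarray(cross_corr, dtype=float)
    k = len(FEATURES)
    if cross_corr.shape != (k, k) or not np.allclose(cross_corr, cross_corr.T):
        raise InvalidParameterError("cross_corr must be a symmetric 4x4 matrix")
    if not np.allclose(np.diag(cross_corr), 1.0):
        raise InvalidParameterError("cross_corr must have unit diagonal")
    eigvals = np.linalg.eigvalsh(cross_corr)
    if eigvals.min() < -1e-10:
        raise InvalidParameterError("cross_corr must be positive semi-definite")

    n = int(round(duration_s * rate_hz))
    if n < 8:
        raise InvalidParameterError("duration too short for a feature bank")
    rng = np.random.default_rng(seed)

    freqs = np.fft.rfftfreq(n, d=1.0 / rate_hz)
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    raw = np.empty((k, n))
    for i in range(k):
        spec = np.zeros(freqs.size, dtype=complex)
        m = int(in_band.sum())
        spec[in_band] = rng.standard_normal(m) + 1j * rng.standard_normal(m)
        raw[i] = np.fft.irfft(spec, n)

    # eigendecomposition-based square root tolerates PSD-but-singular requests
    w, v = np.linalg.eigh(cross_corr)
    mix = v @ np.diag(np.sqrt(np.clip(w, 0, None))) @ v.T
    std = raw.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    mixed = mix @ ((raw - raw.mean(axis=1, keepdims=True)) / std)
    mixed -= mixed.mean(axis=1, keepdims=True)
    s = mixed.std(axis=1, keepdims=True)
    s[s == 0] = 1.0
    mixed /= s

    units = {"lip": "px^2", "envelope": "a.u.", "formant": "Hz", "pitch": "Hz"}
    return {
        name: FeatureTrack(name, mixed[i], rate_hz=rate_hz, units=units[name])
        for i, name in enumerate(FEATURES)
    }


# ---------------------------------------------------------------------------
# grids and forward models
# ---------------------------------------------------------------------------

def build_grid(
    shape: tuple[int, int, int] = (6, 6, 6), spacing_mm: float = 10.0
) -> SourceGrid:
    """Regular grid with a posterior 'occipital' slab and a midline
    'cingulate' slab, standing in for an atlas parcellation.

    Axes follow (x = left-right, y = posterior-anterior, z = inferior-
    superior); voxel order is C order over (x, y, z) indices.
    """
    nx, ny, nz = shape
    if min(shape) < 3:
        raise InvalidParameterError("grid needs at least 3 voxels per axis")
    idx = np.indices(shape).reshape(3, -1).T  # (n_voxels, 3) of (i, j, k)
    coords = (idx - (np.array(shape) - 1) / 2.0) * spacing_mm

    labels = np.full(idx.shape[0], "other", dtype=object)
    posterior = idx[:, 1] < max(1, ny // 3)  # back third in y
    x_mid_lo, x_mid_hi = (nx - 1) / 2.0 - nx / 6.0, (nx - 1) / 2.0 + nx / 6.0
    midline = (idx[:, 0] >= x_mid_lo) & (idx[:, 0] <= x_mid_hi)
    labels[posterior] = "occipital"
    labels[~posterior & midline] = "cingulate"
    return SourceGrid(
        shape=tuple(shape),
        spacing_mm=spacing_mm,
        coords_mm=coords.astype(float),
        region_labels=np.asarray(labels, dtype=str),
    )


def make_forward_model(
    grid: SourceGrid, n_sensors: int = 64, seed: int = 0, falloff_mm: float | None = None
) -> ForwardModel:
    """Toy fixed-orientation lead field: sensors on a jittered shell above the
    grid, Gaussian distance falloff from each voxel."""
    if n_sensors < 2:
        raise InvalidParameterError("need at least two sensors")
    rng = np.random.default_rng(seed)
    extent = np.ptp(grid.coords_mm, axis=0).max() + grid.spacing_mm
    radius = 0.9 * extent
    # roughly uniform directions via Fibonacci sphere, with small jitter
    i = np.arange(n_sensors)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1 - 2 * (i + 0.5) / n_sensors
    r_xy = np.sqrt(np.clip(1 - z * z, 0, None))
    theta = golden * i
    dirs = np.stack([r_xy * np.cos(theta), r_xy * np.sin(theta), z], axis=1)
    sensors = radius * dirs + rng.normal(scale=0.02 * radius, size=(n_sensors, 3))

    if falloff_mm is None:
        falloff_mm = 2.0 * grid.spacing_mm
    d2 = ((sensors[:, None, :] - grid.coords_mm[None, :, :]) ** 2).sum(axis=2)
    lf = np.exp(-d2 / (2 * falloff_mm**2))
    lf /= np.linalg.norm(lf, axis=0, keepdims=True)  # unit-norm columns
    return ForwardModel(leadfield=lf, grid=grid)


# ---------------------------------------------------------------------------
# coupling model and cohort
# ---------------------------------------------------------------------------

@dataclass
class CouplingModel:
    """Age-dependent coupling gains g(age) = max(0, a0 + a1*age).

    ``gains`` maps (feature, region, condition) to (a0, a1); missing keys mean
    zero coupling.  Background noise is 1/f^beta Gaussian with SD ``noise_sd``
    per voxel.
    """

    gains: dict[tuple[str, str, str], tuple[float, float]] = field(default_factory=dict)
    noise_beta: float = 1.0
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.noise_beta < 0:
            raise InvalidParameterError("noise spectral exponent must be >= 0")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise SD must be >= 0")
        for key in self.gains:
            f, r, c = key
            if f not in FEATURES or r not in REGIONS or c not in CONDITIONS:
                raise InvalidParameterError(f"unknown coupling key {key!r}")

    def gain(self, feature: str, region: str, condition: str, age: float) -> float:
        a0, a1 = self.gains.get((feature, region, condition), (0.0, 0.0))
        return max(0.0, a0 + a1 * age)

    @classmethod
    def zero(cls) -> "CouplingModel":
        return cls()

    @classmethod
    def headline(
        cls,
        base_gain: float = 0.06,
        reversed_gain: float = 0.04,
        formant_gain_young: float = 0.12,
        formant_age_slope: float = -0.0016,
    ) -> "CouplingModel":
        """The planted pattern the analysis should recover: all four features
        couple in occipital cortex, natural more than reversed; only the
        natural-formant coupling declines with age (in occipital and
        cingulate regions), i.e. an age-declining intelligibility index for
        formants with lip tracking preserved.

        Gains are scaled so single-subject coherences land in the 0.05–0.2
        range typical of stimulus--brain coupling and the planted formant
        age effect has a per-voxel index-age correlation near -0.6.  The
        scale matters: features coupled into the same voxels share each
        voxel's total power, so an age-varying coupling perturbs the
        coherence denominators of the *other* features; at these gain
        levels that leakage is second-order (index-age r bias < 0.01),
        keeping the lip index genuinely age-flat.
        """
        gains: dict[tuple[str, str, str], tuple[float, float]] = {}
        for f in FEATURES:
            gains[(f, "occipital", "natural")] = (base_gain, 0.0)
            gains[(f, "occipital", "reversed")] = (reversed_gain, 0.0)
        for region in ("occipital", "cingulate"):
            gains[("formant", region, "natural")] = (formant_gain_young, formant_age_slope)
        gains[("formant", "cingulate", "reversed")] = (reversed_gain, 0.0)
        return cls(gains=gains)


@dataclass
class SyntheticCohort:
    """Participant table, per-subject trial sets, feature tracks and ground
    truth for one simulated study."""

    participants: pd.DataFrame  # columns: subject_id, age_years
    trials: dict[tuple[str, str], TrialSet]  # (subject_id, condition) -> TrialSet
    features: dict[tuple[str, str], dict[str, FeatureTrack]]  # (subject, condition) -> feature -> track
    coupling: CouplingModel
    grid: SourceGrid
    seed: int

    @property
    def subject_ids(self) -> list[str]:
        return list(self.participants["subject_id"])

    @property
    def ages(self) -> np.ndarray:
        return self.participants["age_years"].to_numpy(dtype=float)


def one_over_f_noise(
    n_samples: int, n_series: int, beta: float, rng: np.random.Generator, rate_hz: float = 150.0
) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to 1/f^beta,
    scaled to unit variance per series."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate_hz)
    amp = np.ones_like(freqs)
    amp[1:] = freqs[1:] ** (-beta / 2.0)
    amp[0] = 0.0
    spec = (
        rng.standard_normal((n_series, freqs.size))
        + 1j * rng.standard_normal((n_series, freqs.size))
    ) * amp
    x = np.fft.irfft(spec, n_samples, axis=1)
    std = x.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return x / std


def _band_limited_noise(
    n_samples: int,
    n_series: int,
    band_hz: tuple[float, float],
    rate_hz: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Unit-variance Gaussian noise confined to ``band_hz`` (same spectral
    support as the feature tracks)."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate_hz)
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    spec = np.zeros((n_series, freqs.size), dtype=complex)
    m = int(in_band.sum())
    spec[:, in_band] = rng.standard_normal((n_series, m)) + 1j * rng.standard_normal(
        (n_series, m)
    )
    x = np.fft.irfft(spec, n_samples, axis=1)
    std = x.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return x / std


def _subseed(master: int, *parts: object) -> int:
    """Stable per-stream seed below 2**31 derived from a master seed."""
    h = hashlib.sha256(("/".join(map(str, (master, *parts)))).encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def simulate_cohort(
    n_subjects: int,
    age_low: float = 19.0,
    age_high: float = 63.0,
    coupling: CouplingModel | None = None,
    grid: SourceGrid | None = None,
    n_trials_per_condition: int = 60,
    seed: int = 0,
    features: tuple[str, ...] = FEATURES,
    rate_hz: float = 150.0,
    dtype: type = np.float32,
    shared_stimuli: bool = False,
    equalize_band_power: bool = True,
) -> SyntheticCohort:
    """Simulate an aging cohort with planted feature--brain coupling.

    For each subject and condition, every voxel's source series is

        x_v(t) = sum_f g(age; f, region(v), cond) * feature_f(t)
                 + d_v * distractor_v(t) + sd * noise(t)

    with g = max(0, a0 + a1*age) from the coupling model and 1/f^beta noise.
    The continuous series is epoched into 2-s trials of 300 samples.

    Feature tracks are drawn independently per subject by default
    (``shared_stimuli=True`` reuses one draw per condition, as a real study
    with a fixed stimulus set would): independent draws keep the
    finite-sample cross-coherence between different feature tracks from
    entering every subject's maps as a common, age-correlated component.

    With ``equalize_band_power`` (default), an independent band-limited
    distractor process per voxel tops total stimulus-band drive up to its
    age-range maximum, so an age-varying coupling gain changes *which*
    signal a voxel follows but not its total band power.  Without it, a
    declining coupling thins the coherence denominator of every other
    feature coupled into the same voxel, giving nominally age-flat features
    a spurious age trend.
    """
    if n_subjects < 3:
        raise InvalidParameterError("need at least 3 subjects")
    if not age_low < age_high:
        raise InvalidParameterError("age_low must be < age_high")
    if n_trials_per_condition < 1:
        raise InvalidParameterError("need at least one trial per condition")
    for f in features:
        if f not in FEATURES:
            raise InvalidParameterError(f"unknown feature {f!r}")
    if coupling is None:
        coupling = CouplingModel.headline()
    if grid is None:
        grid = build_grid()
    present = set(grid.region_labels.tolist())
    if not set(REGIONS) <= present:
        raise InvalidParameterError(
            f"grid must contain all regions {REGIONS}, found {sorted(present)}"
        )

    rng_ages = np.random.default_rng(_subseed(seed, "ages"))
    ages = np.sort(rng_ages.uniform(age_low, age_high, size=n_subjects))
    subject_ids = [f"sub{i + 1:03d}" for i in range(n_subjects)]
    participants = pd.DataFrame({"subject_id": subject_ids, "age_years": ages})

    duration_s = n_trials_per_condition * (TRIAL_LEN_SAMPLES / rate_hz)
    n_samples = n_trials_per_condition * TRIAL_LEN_SAMPLES
    band_hz = (1.0, 7.0)

    region_of_voxel = grid.region_labels

    def gain_vector(f: str, cond: str, age: float) -> np.ndarray:
        return np.array([coupling.gain(f, r, cond, age) for r in region_of_voxel])

    # age-range maximum of total coupled power per voxel (each g^2 is convex
    # in age, so the maximum of the sum sits at an endpoint)
    p_max: dict[str, np.ndarray] = {}
    for cond in CONDITIONS:
        p_lo = sum(gain_vector(f, cond, age_low) ** 2 for f in features)
        p_hi = sum(gain_vector(f, cond, age_high) ** 2 for f in features)
        p_max[cond] = np.maximum(p_lo, p_hi)

    feature_banks: dict[tuple[str, str], dict[str, FeatureTrack]] = {}
    trials: dict[tuple[str, str], TrialSet] = {}
    for sid, age in zip(subject_ids, ages):
        for cond in CONDITIONS:
            bank_key = ("shared", cond) if shared_stimuli else (sid, cond)
            bank = generate_feature_bank(
                duration_s, rate_hz=rate_hz, band_hz=band_hz,
                seed=_subseed(seed, "features", *bank_key),
            )
            feature_banks[(sid, cond)] = {f: bank[f] for f in features}

            rng = np.random.default_rng(_subseed(seed, "noise", sid, cond))
            x = coupling.noise_sd * one_over_f_noise(
                n_samples, grid.n_voxels, coupling.noise_beta, rng, rate_hz
            )
            p_now = np.zeros(grid.n_voxels)
            for f in features:
                track = feature_banks[(sid, cond)][f].samples
                g = gain_vector(f, cond, age)
                p_now += g**2
                active = g != 0
                if active.any():
                    x[active] += g[active, None] * track[None, :]
            if equalize_band_power:
                deficit = np.sqrt(np.clip(p_max[cond] - p_now, 0.0, None))
                active = deficit > 0
                if active.any():
                    distractor = _band_limited_noise(
                        n_samples, int(active.sum()), band_hz, rate_hz,
                        np.random.default_rng(_subseed(seed, "distractor", sid, cond)),
                    )
                    x[active] += deficit[active, None] * distractor
            data = x.reshape(grid.n_voxels, n_trials_per_condition, TRIAL_LEN_SAMPLES)
            data = np.ascontiguousarray(np.swapaxes(data, 0, 1), dtype=dtype)
            trials[(sid, cond)] = TrialSet(
                data, rate_hz=rate_hz, condition=cond, subject_id=sid, space="source"
            )

    return SyntheticCohort(
        participants=participants,
        trials=trials,
        features=feature_banks,
        coupling=coupling,
        grid=grid,
        seed=seed,
    )


def project_to_sensors(
    forward: ForwardModel,
    source_series: np.ndarray,
    sensor_noise_sd: float = 0.0,
    seed: int = 0,
) -> SensorRecording:
    """Sensor data = lead field x sources + white Gaussian sensor noise."""
    source_series = np.asarray(source_series, dtype=float)
    if source_series.ndim != 2:
        raise InvalidParameterError("source series must be voxels x samples")
    if source_series.shape[0] != forward.leadfield.shape[1]:
        raise InvalidParameterError(
            f"source count {source_series.shape[0]} does not match "
            f"lead-field voxel count {forward.leadfield.shape[1]}"
        )
    data = forward.leadfield @ source_series
    if sensor_noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(scale=sensor_noise_sd, size=data.shape)
    return SensorRecording(data, rate_hz=150.0)
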