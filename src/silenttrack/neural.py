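"""Sensor-space preprocessing and LCMV beamforming.

The preprocessing chain mirrors a standard MEG pipeline: zero-phase FIR
high-pass at 1 Hz (Kaiser window, order 440 at 1 kHz, scaled with the
sampling rate), zero-phase FIR low-pass at 30 Hz, polyphase resampling to
150 Hz, stimulus-delay correction (9 ms) and segmentation into 2-s trials.

Source projection uses a linearly constrained minimum-variance (LCMV)
beamformer on a fixed-orientation lead field: with regularized covariance
C_r = C + lambda * mean(diag(C)) * I, the filter for voxel v is

    w_v = (l_v' C_r^-1 l_v)^-1 l_v' C_r^-1

which passes the voxel's own lead field with unit gain while minimizing
output variance from everything else.  The covariance is pooled over all
trials of both conditions so natural and reversed data share one filter.
"""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np
from scipy import signal

from .errors import InvalidParameterError, NumericalError, TooShortInputError
from .types import (
    ANALYSIS_RATE_HZ,
    ForwardModel,
    SensorRecording,
    SpatialFilter,
    TrialSet,
)

__all__ = [
    "preprocess_sensor",
    "resample_recording",
    "epoch",
    "compute_covariance",
    "lcmv_filters",
    "apply_filters",
]

_KAISER_BETA = 5.0
_HP_ORDER_AT_1KHZ = 440


def _highpass_taps(rate_hz: float, hp_hz: float) -> np.ndarray:
    # spectral inversion of a unity-DC low-pass: the high-pass then has an
    # exact zero at DC, which a direct window design of this length cannot
    # deliver at so low a cutoff
    order = int(round(_HP_ORDER_AT_1KHZ * rate_hz / 1000.0))
    order += order % 2  # Type-I (odd-length) FIR
    lp = signal.firwin(order + 1, hp_hz, fs=rate_hz, window=("kaiser", _KAISER_BETA))
    lp /= lp.sum()
    hp = -lp
    hp[order // 2] += 1.0
    return hp


def _lowpass_taps(rate_hz: float, lp_hz: float) -> np.ndarray:
    # passband edge at the cutoff, stopband edge two-thirds of an octave up
    # (30 -> 50 Hz), >= 50 dB single-pass stop attenuation
    width = 2 * lp_hz / 3.0
    numtaps, beta = signal.kaiserord(50.0, width / (rate_hz / 2.0))
    numtaps += 1 - numtaps % 2
    return signal.firwin(numtaps, lp_hz + width / 2.0, fs=rate_hz, window=("kaiser", beta))


def preprocess_sensor(
    rec: SensorRecording, hp_hz: float = 1.0, lp_hz: float = 30.0
) -> SensorRecording:
    """Zero-phase FIR high-pass then low-pass; length preserved."""
    if rec.rate_hz <= 2 * lp_hz:
        raise InvalidParameterError("sampling rate must exceed twice the low-pass cutoff")
    hp = _highpass_taps(rec.rate_hz, hp_hz)
    if rec.n_samples < 3 * hp.size:
        raise TooShortInputError(
            f"recording of {rec.n_samples} samples is shorter than 3x the "
            f"high-pass filter length ({hp.size})"
        )
    data = signal.filtfilt(hp, 1.0, rec.data, axis=1)
    lp = _lowpass_taps(rec.rate_hz, lp_hz)
    data = signal.filtfilt(lp, 1.0, data, axis=1)
    return SensorRecording(data, rate_hz=rec.rate_hz, channel_ids=list(rec.channel_ids))


def resample_recording(rec: SensorRecording, target_hz: float = ANALYSIS_RATE_HZ) -> SensorRecording:
    """Anti-alias polyphase resampling to ``target_hz``."""
    if target_hz >= rec.rate_hz:
        raise InvalidParameterError("target rate must be below the current rate")
    frac = Fraction(target_hz / rec.rate_hz).limit_denominator(1000)
    data = signal.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return SensorRecording(data, rate_hz=target_hz, channel_ids=list(rec.channel_ids))


def epoch(
    rec: SensorRecording,
    trial_len_s: float = 2.0,
    stimulus_delay_ms: float = 9.0,
    condition: str = "natural",
    subject_id: str = "",
    space: str = "sensor",
) -> TrialSet:
    """Delay-correct and cut into consecutive non-overlapping trials.

    The stimulus reached the participant ``stimulus_delay_ms`` after its
    nominal onset, so the neural timeline is shifted by that amount (rounded
    to the nearest sample — one sample at 150 Hz for 9 ms) before
    segmentation; an incomplete tail is dropped.
    """
    shift = int(round(stimulus_delay_ms / 1000.0 * rec.rate_hz))
    n_per = int(round(trial_len_s * rec.rate_hz))
    usable = rec.n_samples - shift
    n_trials = usable // n_per
    if n_trials < 1:
        raise TooShortInputError(
            f"recording of {rec.n_samples} samples yields no complete "
            f"{trial_len_s:g}-s trial after a {shift}-sample delay shift"
        )
    data = rec.data[:, shift : shift + n_trials * n_per]
    data = data.reshape(rec.n_channels, n_trials, n_per).swapaxes(0, 1)
    return TrialSet(
        np.ascontiguousarray(data),
        rate_hz=rec.rate_hz,
        condition=condition,
        subject_id=subject_id,
        space=space,
    )


def compute_covariance(trials: TrialSet, pooled_with: TrialSet | None = None) -> np.ndarray:
    """Channel covariance over all samples of all pooled trials.

    Pooling both conditions into one covariance gives a single common
    beamformer, so condition differences downstream cannot stem from
    different filters.
    """
    if trials.space != "sensor":
        raise InvalidParameterError("covariance is computed on sensor-space trials")
    stacks = [trials.data]
    if pooled_with is not None:
        if pooled_with.n_channels != trials.n_channels:
            raise InvalidParameterError("pooled trial sets must share the channel count")
        stacks.append(pooled_with.data)
    flat = np.concatenate(
        [s.transpose(1, 0, 2).reshape(trials.n_channels, -1) for s in stacks], axis=1
    )
    n_ch, n_samp = flat.shape
    if n_samp < n_ch:
        warnings.warn(
            "fewer samples than channels: covariance is rank deficient; "
            "beamforming will rely on regularization",
            stacklevel=2,
        )
    flat = flat - flat.mean(axis=1, keepdims=True)
    # population normalization (1/N) so pooling a set with itself is a no-op
    return (flat @ flat.T) / n_samp


def lcmv_filters(fwd: ForwardModel, cov: np.ndarray, lambda_frac: float = 0.05) -> SpatialFilter:
    """Unit-gain LCMV beamformer weights for every voxel."""
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (fwd.n_sensors, fwd.n_sensors):
        raise InvalidParameterError("covariance shape must match the sensor count")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise InvalidParameterError("covariance must be symmetric")
    c_r = cov + lambda_frac * np.mean(np.diag(cov)) * np.eye(cov.shape[0])
    try:
        ci_l = np.linalg.solve(c_r, fwd.leadfield)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            "regularized covariance is singular; raise lambda_frac"
        ) from exc
    denom = np.einsum("sv,sv->v", fwd.leadfield, ci_l)
    if np.any(denom <= 0) or not np.all(np.isfinite(denom)):
        raise NumericalError(
            "beamformer normalization failed (non-positive l' C^-1 l); raise lambda_frac"
        )
    weights = (ci_l / denom).T
    return SpatialFilter(weights=weights, lambda_frac=lambda_frac)


def apply_filters(filt: SpatialFilter, trials: TrialSet) -> TrialSet:
    """Project sensor trials to source space: per trial, weights x data."""
    if trials.n_channels != filt.weights.shape[1]:
        raise InvalidParameterError(
            f"trials have {trials.n_channels} channels but the filter expects "
            f"{filt.weights.shape[1]}"
        )
    src = np.einsum("vs,tsn->tvn", filt.weights, trials.data)
    return TrialSet(
        src,
        rate_hz=trials.rate_hz,
        condition=trials.condition,
        subject_id=trials.subject_id,
        space="source",
    )
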