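"""Stimulus feature extraction: envelope, formants, pitch, lip area.

Four feature tracks are derived per stimulus and aligned on a common 150-Hz
timeline:

* **envelope** — cochlear-spaced filterbank (nine Butterworth band-passes,
  100–10 000 Hz), per-band analytic-signal magnitude, averaged across bands;
* **formant** — Burg autoregressive formant tracking at 200 Hz; the mean of
  F2 and F3 is the downstream track (those two resonances are modulated near
  the lips and tend to merge around 2.5 kHz);
* **pitch** — normalized-autocorrelation f0 at 100 Hz, search range
  50–400 Hz, no voicing gate (downstream coherence needs a gap-free track);
* **lip** — bright-region area per video frame.

Resampling between non-integer rates uses linear interpolation on a shared
absolute time axis; an anti-alias low-pass precedes any downsampling.
"""

from __future__ import annotations

import numpy as np
from scipy import signal
from scipy import ndimage

from .errors import EmptyTrackError, InvalidParameterError, TooShortInputError
from .types import (
    ANALYSIS_RATE_HZ,
    TRIAL_LEN_SAMPLES,
    AudioWave,
    FeatureTrack,
    FormantSet,
    VideoFrames,
)

__all__ = [
    "cochlear_band_edges",
    "extract_envelope",
    "extract_formants",
    "merge_f2_f3",
    "extract_pitch",
    "extract_lip_area",
    "reverse_stimulus",
    "assemble_feature_trials",
    "resample_track",
    "zscore_track",
    "DEFAULT_BAND_EDGES",
]

# Cutoffs of the nine cochlear-spaced bands used for the envelope (Hz).
DEFAULT_BAND_EDGES = (101.0, 220.0, 402.0, 680.0, 1103.0, 1748.0, 2732.0, 4231.0, 6517.0, 10000.0)

# Greenwood cochlear position-frequency map, human parameters.
_GW_A, _GW_ALPHA, _GW_K = 165.4, 2.1, 0.88


def cochlear_band_edges(n_bands: int = 9, f_lo: float = 100.0, f_hi: float = 10000.0) -> np.ndarray:
    """Band cutoffs equidistant on the cochlear (Greenwood) frequency map.

    The default call returns the nine-band 100–10 000 Hz cutoffs used for the
    speech envelope verbatim.  Other arguments place ``n_bands + 1`` edges
    equidistant in Greenwood position x, where f(x) = A (10^(alpha x) - k)
    with human constants A = 165.4, alpha = 2.1, k = 0.88.
    """
    if n_bands < 1:
        raise InvalidParameterError("n_bands must be >= 1")
    if not 0 < f_lo < f_hi:
        raise InvalidParameterError("need 0 < f_lo < f_hi")
    if (n_bands, f_lo, f_hi) == (9, 100.0, 10000.0):
        return np.array(DEFAULT_BAND_EDGES)

    def pos(f: float) -> float:
        return np.log10(f / _GW_A + _GW_K) / _GW_ALPHA

    def freq(x: np.ndarray) -> np.ndarray:
        return _GW_A * (10.0 ** (_GW_ALPHA * x) - _GW_K)

    x = np.linspace(pos(f_lo), pos(f_hi), n_bands + 1)
    edges = freq(x)
    edges[0], edges[-1] = f_lo, f_hi  # pin endpoints against rounding
    return edges


def resample_track(samples: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    """Linear-interpolation resampling on a shared absolute time axis.

    Downsampling is preceded by a zero-phase Butterworth low-pass at 90% of
    the output Nyquist.  Output covers [0, t_last] at the new rate.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < 2:
        raise TooShortInputError("need at least two samples to resample")
    if rate_out < rate_in:
        cutoff = 0.9 * (rate_out / 2.0)
        sos = signal.butter(4, cutoff, fs=rate_in, output="sos")
        padlen = min(samples.size - 1, 3 * 6)
        samples = signal.sosfiltfilt(sos, samples, padlen=padlen)
    t_in = np.arange(samples.size) / rate_in
    n_out = int(np.floor(t_in[-1] * rate_out)) + 1
    t_out = np.arange(n_out) / rate_out
    return np.interp(t_out, t_in, samples)


# ---------------------------------------------------------------------------
# envelope
# ---------------------------------------------------------------------------

def extract_envelope(
    audio: AudioWave,
    edges: np.ndarray | None = None,
    out_rate_hz: float = ANALYSIS_RATE_HZ,
) -> FeatureTrack:
    """Cochlear-filterbank amplitude envelope at the analysis rate.

    Per band: fourth-order Butterworth band-pass applied forward-backward
    (zero phase), magnitude of the analytic signal; the per-band envelopes
    are averaged and the full-band envelope resampled to ``out_rate_hz``.
    """
    if edges is None:
        edges = cochlear_band_edges()
    edges = np.asarray(edges, dtype=float)
    if audio.rate_hz <= 2 * edges.max():
        raise InvalidParameterError("audio rate must exceed twice the highest band edge")
    x = audio.samples
    # transient of the lowest band dominates; require ~3 periods of its lower cutoff
    min_len = int(3 * audio.rate_hz / edges[0])
    if x.size < min_len:
        raise TooShortInputError(
            f"audio has {x.size} samples; need at least {min_len} for band filtering"
        )
    env = np.zeros_like(x)
    for lo, hi in zip(edges[:-1], edges[1:]):
        sos = signal.butter(4, [lo, hi], btype="bandpass", fs=audio.rate_hz, output="sos")
        band = signal.sosfiltfilt(sos, x)
        env += np.abs(signal.hilbert(band))
    env /= edges.size - 1
    out = resample_track(env, audio.rate_hz, out_rate_hz)
    return FeatureTrack("envelope", np.clip(out, 0.0, None), rate_hz=out_rate_hz, units="a.u.")


# ---------------------------------------------------------------------------
# formants
# ---------------------------------------------------------------------------

def _burg_coefficients(frame: np.ndarray, order: int) -> np.ndarray | None:
    from statsmodels.regression.linear_model import burg

    if np.allclose(frame, frame[0]):
        return None
    try:
        rho, _ = burg(frame, order=order, demean=True)
    except (ValueError, np.linalg.LinAlgError):
        return None
    return rho


def extract_formants(
    audio: AudioWave,
    n_formants: int = 5,
    rate_hz: float = 200.0,
    max_formant_hz: float = 5500.0,
    window_s: float = 0.025,
    pre_emphasis: float = 0.98,
    max_bandwidth_hz: float = 400.0,
) -> FormantSet:
    """Burg-method formant tracking at a fixed frame rate.

    The audio is resampled to 2x``max_formant_hz``, pre-emphasized
    (first-difference, coefficient ``pre_emphasis``), cut into Gaussian-
    tapered windows of ``window_s`` hopped at 1/``rate_hz``, and an
    autoregressive model of order 2*``n_formants`` is fitted per frame by
    Burg's method.  Polynomial roots give candidates with frequency
    f = angle * fs / (2 pi) and bandwidth b = -ln|root| * fs / pi; candidates
    with f in (50, max_formant_hz) and b < ``max_bandwidth_hz`` are kept,
    sorted ascending and labelled F1..Fn.  Frames with no valid candidate are
    left as NaN (interpolated downstream).
    """
    if n_formants < 1:
        raise InvalidParameterError("n_formants must be >= 1")
    if audio.samples.size < 2:
        raise TooShortInputError("audio too short for formant analysis")
    fs_a = 2.0 * max_formant_hz
    x = resample_track(audio.samples, audio.rate_hz, fs_a) if audio.rate_hz != fs_a else audio.samples
    x = np.append(x[0], x[1:] - pre_emphasis * x[:-1])

    frame_len = int(round(window_s * fs_a))
    hop = fs_a / rate_hz
    n_frames = int(round(x.size / hop))
    if n_frames < 1:
        raise TooShortInputError("audio shorter than one analysis frame")
    win = signal.windows.gaussian(frame_len, std=frame_len / 6.0)
    half = frame_len // 2
    xp = np.pad(x, half, mode="reflect")
    order = 2 * n_formants

    freqs = np.full((n_frames, n_formants), np.nan)
    bands = np.full((n_frames, n_formants), np.nan)
    for i in range(n_frames):
        start = int(round(i * hop))
        frame = xp[start : start + frame_len]
        if frame.size < frame_len:
            frame = np.pad(frame, (0, frame_len - frame.size))
        frame = (frame - frame.mean()) * win
        rho = _burg_coefficients(frame, order)
        if rho is None:
            continue
        roots = np.roots(np.concatenate(([1.0], -rho)))
        roots = roots[np.imag(roots) > 0]
        f = np.angle(roots) * fs_a / (2 * np.pi)
        with np.errstate(divide="ignore"):
            b = -np.log(np.abs(roots)) * fs_a / np.pi
        keep = (f > 50.0) & (f < max_formant_hz) & (b > 0) & (b < max_bandwidth_hz)
        cand = np.sort(f[keep])
        bw = b[keep][np.argsort(f[keep])]
        k = min(cand.size, n_formants)
        freqs[i, :k] = cand[:k]
        bands[i, :k] = bw[:k]
    return FormantSet(freqs_hz=freqs, bands_hz=bands, rate_hz=rate_hz)


def merge_f2_f3(fs: FormantSet, out_rate_hz: float = ANALYSIS_RATE_HZ) -> FeatureTrack:
    """Mean of F2 and F3 per frame, gap-filled and resampled to 150 Hz.

    Frames missing either formant are linearly interpolated from neighboring
    valid frames (edges held at the nearest valid value) so the track stays
    rectangular for trial segmentation.
    """
    if fs.freqs_hz.shape[1] < 3:
        raise InvalidParameterError("need at least three formant slots to merge F2 and F3")
    merged = np.nanmean(fs.freqs_hz[:, 1:3], axis=1)
    valid = np.isfinite(merged)
    if not valid.any():
        raise EmptyTrackError("no frame has a valid F2/F3 estimate")
    idx = np.arange(merged.size)
    merged = np.interp(idx, idx[valid], merged[valid])
    out = resample_track(merged, fs.rate_hz, out_rate_hz)
    return FeatureTrack("formant", out, rate_hz=out_rate_hz, units="Hz")


# ---------------------------------------------------------------------------
# pitch
# ---------------------------------------------------------------------------

def extract_pitch(
    audio: AudioWave,
    f_lo: float = 50.0,
    f_hi: float = 400.0,
    rate_hz: float = 100.0,
    window_s: float = 0.052,
    out_rate_hz: float = ANALYSIS_RATE_HZ,
) -> FeatureTrack:
    """Normalized-autocorrelation pitch track, upsampled to 150 Hz.

    Per 52-ms frame (hopped at 1/``rate_hz``), the normalized autocorrelation

        r(tau) = sum x[n] x[n+tau] / sqrt(sum_head x^2 * sum_tail x^2)

    is evaluated for lags in [fs/f_hi, fs/f_lo]; the estimate is the
    shortest locally maximal lag reaching 90% of the frame's best
    correlation (subharmonics at 2T, 3T, ... score as high as the true
    period T, so the earliest strong peak is the period), refined by
    parabolic interpolation and converted to Hz.  There is no voicing gate:
    every frame yields an estimate, and the final track is clipped to
    [f_lo, f_hi].
    """
    fs = audio.rate_hz
    if fs < 4 * f_hi:
        raise InvalidParameterError("audio rate must be at least 4x the upper pitch bound")
    if not 0 < f_lo < f_hi:
        raise InvalidParameterError("need 0 < f_lo < f_hi")
    frame_len = int(round(window_s * fs))
    lag_min = int(np.floor(fs / f_hi))
    lag_max = int(np.ceil(fs / f_lo))
    if frame_len <= lag_max:
        frame_len = lag_max + 1
    x = audio.samples
    if x.size < frame_len:
        raise TooShortInputError("audio shorter than one pitch analysis frame")

    hop = fs / rate_hz
    n_frames = int(round(x.size / hop))
    half = frame_len // 2
    xp = np.pad(x, half, mode="reflect")

    starts = np.round(np.arange(n_frames) * hop).astype(int)
    frames = np.stack([xp[s : s + frame_len] for s in starts])
    frames = frames - frames.mean(axis=1, keepdims=True)

    nfft = int(2 ** np.ceil(np.log2(2 * frame_len)))
    spec = np.fft.rfft(frames, nfft, axis=1)
    acorr = np.fft.irfft(spec * np.conj(spec), nfft, axis=1)[:, : lag_max + 1]
    # normalization: energy of the leading and trailing segments per lag
    csq = np.cumsum(frames**2, axis=1)
    total = csq[:, -1:]
    lags = np.arange(lag_max + 1)
    head = np.take_along_axis(
        np.pad(csq, ((0, 0), (1, 0))), (frame_len - lags)[None, :].repeat(n_frames, 0), axis=1
    )
    tail = total - np.take_along_axis(
        np.pad(csq, ((0, 0), (1, 0))), lags[None, :].repeat(n_frames, 0), axis=1
    )
    denom = np.sqrt(np.clip(head * tail, 1e-30, None))
    r = acorr / denom

    band = r[:, lag_min : lag_max + 1]
    # shortest strong peak: local maxima reaching 90% of the frame maximum
    inner = band[:, 1:-1]
    is_peak = (inner >= band[:, :-2]) & (inner >= band[:, 2:])
    strong = is_peak & (inner >= 0.9 * band.max(axis=1, keepdims=True))
    has_peak = strong.any(axis=1)
    first_peak = np.argmax(strong, axis=1) + 1  # first True along the lag axis
    best = np.where(has_peak, first_peak, np.argmax(band, axis=1)) + lag_min
    # parabolic refinement around the peak
    best_f = best.astype(float)
    interior = (best > lag_min) & (best < lag_max)
    if interior.any():
        i = np.flatnonzero(interior)
        y0 = r[i, best[i] - 1]
        y1 = r[i, best[i]]
        y2 = r[i, best[i] + 1]
        denom2 = y0 - 2 * y1 + y2
        delta = np.where(np.abs(denom2) > 1e-12, 0.5 * (y0 - y2) / denom2, 0.0)
        best_f[i] = best[i] + np.clip(delta, -0.5, 0.5)
    f0 = fs / best_f

    out = resample_track(f0, rate_hz, out_rate_hz)
    return FeatureTrack("pitch", np.clip(out, f_lo, f_hi), rate_hz=out_rate_hz, units="Hz")


# ---------------------------------------------------------------------------
# lip area
# ---------------------------------------------------------------------------

def extract_lip_area(
    video: VideoFrames, threshold: float = 0.5, out_rate_hz: float = ANALYSIS_RATE_HZ
) -> FeatureTrack:
    """Area (pixel count) of the largest bright component per frame,
    interpolated to the analysis rate.  Frames with no bright pixel get area
    0 (closed mouth)."""
    if not 0 < threshold < 1:
        raise InvalidParameterError("threshold must lie in (0, 1)")
    if video.frames.shape[0] < 1:
        raise InvalidParameterError("video has no frames")
    areas = np.zeros(video.frames.shape[0])
    for i, frame in enumerate(video.frames):
        mask = frame > threshold
        if not mask.any():
            continue
        labels, n = ndimage.label(mask)
        if n == 1:
            areas[i] = mask.sum()
        else:
            counts = np.bincount(labels.ravel())[1:]
            areas[i] = counts.max()
    if areas.size == 1:
        out = np.full(1, areas[0])
        return FeatureTrack("lip", out, rate_hz=out_rate_hz, units="px^2")
    out = resample_track(areas, video.fps, out_rate_hz)
    return FeatureTrack("lip", np.clip(out, 0.0, None), rate_hz=out_rate_hz, units="px^2")


# ---------------------------------------------------------------------------
# utilities
# ---------------------------------------------------------------------------

def reverse_stimulus(x: AudioWave | VideoFrames) -> AudioWave | VideoFrames:
    """Time-reverse a stimulus (sample or frame order); metadata unchanged."""
    if isinstance(x, (AudioWave, VideoFrames)):
        return x.reversed()
    raise InvalidParameterError(f"cannot reverse object of type {type(x).__name__}")


def assemble_feature_trials(
    track: FeatureTrack, trial_len_s: float = 2.0, detrend: bool = False
) -> np.ndarray:
    """Cut a 150-Hz track into consecutive non-overlapping trials
    (n_trials x samples); an incomplete tail is dropped."""
    if track.rate_hz != ANALYSIS_RATE_HZ:
        raise InvalidParameterError(
            f"track must be at {ANALYSIS_RATE_HZ:g} Hz, got {track.rate_hz:g}"
        )
    n_per = int(round(trial_len_s * track.rate_hz))
    n_trials = track.n_samples // n_per
    if n_trials < 1:
        raise TooShortInputError(
            f"track of {track.n_samples} samples is shorter than one "
            f"{trial_len_s:g}-s trial ({n_per} samples)"
        )
    trials = track.samples[: n_trials * n_per].reshape(n_trials, n_per)
    if detrend:
        trials = signal.detrend(trials, axis=1)
    return trials


def zscore_track(track: FeatureTrack) -> FeatureTrack:
    """Standardize a track to mean 0, SD 1 (coherence is scale-invariant;
    z-scoring just stabilizes the numerics)."""
    s = track.samples.std()
    if s == 0:
        return FeatureTrack(track.name, track.samples - track.samples.mean(), track.rate_hz, track.units)
    return FeatureTrack(
        track.name, (track.samples - track.samples.mean()) / s, track.rate_hz, track.units
    )
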