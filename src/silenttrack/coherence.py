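"""Multitaper cross-spectra, coherence maps, band averages and the
intelligibility index.

Spectra are estimated per 2-s trial with DPSS (Slepian) tapers at +-3 Hz
smoothing; the time-bandwidth product T*W = 6 yields K = 2*T*W - 1 = 11
tapers, of which any with spectral concentration below 0.9 are dropped (none
are, at the defaults).  Complex cross-spectra are averaged over tapers and
trials first (uniform weights), and coherence is the magnitude of the
normalized cross-spectrum

    c(v, f) = |S_xy(v, f)| / sqrt(S_xx(v, f) S_yy(f))

with the squared variant available behind a flag.  The intelligibility index
is the band-averaged natural-minus-reversed coherence per voxel: positive
where the brain tracks natural speech statistics better than time-reversed
ones.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np

from .errors import InvalidParameterError
from .types import CoherenceMap, CrossSpectra, IndexMap, TrialSet

__all__ = [
    "multitaper_spectra",
    "multitaper_spectra_multi",
    "coherence_map",
    "band_average",
    "intelligibility_index",
    "top_coherence_overlap",
    "DELTA_BAND",
    "THETA_BAND",
    "COMBINED_BAND",
]

DELTA_BAND = (1.0, 3.0)
THETA_BAND = (4.0, 7.0)
COMBINED_BAND = (1.0, 7.0)

_MIN_CONCENTRATION = 0.9


@lru_cache(maxsize=8)
def _dpss_tapers(n_samples: int, time_bandwidth: float, k_max: int) -> np.ndarray:
    from scipy.signal.windows import dpss

    tapers, ratios = dpss(n_samples, time_bandwidth, Kmax=k_max, return_ratios=True)
    keep = ratios >= _MIN_CONCENTRATION
    if not keep.any():
        raise InvalidParameterError("no taper reaches the required spectral concentration")
    return tapers[keep]


def multitaper_spectra_multi(
    neural: TrialSet,
    feature_trials: dict[str, np.ndarray],
    f_lo: float = 1.0,
    f_hi: float = 25.0,
    f_step: float = 0.5,
    smoothing_hz: float = 3.0,
) -> dict[str, CrossSpectra]:
    """Multitaper spectra of one neural trial set against several feature
    trial matrices at once, sharing the (dominant) neural FFT work."""
    if not feature_trials:
        raise InvalidParameterError("need at least one feature trial matrix")
    feats = {k: np.asarray(v, dtype=float) for k, v in feature_trials.items()}
    for name, y in feats.items():
        if y.ndim != 2 or y.shape != (neural.n_trials, neural.n_samples):
            raise InvalidParameterError(
                f"feature trials {name!r} {y.shape} do not pair with neural trials "
                f"({neural.n_trials}, {neural.n_samples})"
            )
    t_len = neural.n_samples / neural.rate_hz
    k = int(round(2 * t_len * smoothing_hz - 1))
    if k < 1:
        raise InvalidParameterError(
            f"smoothing of {smoothing_hz:g} Hz yields no taper for {t_len:g}-s trials"
        )
    freqs = np.round(np.arange(f_lo, f_hi + f_step / 2, f_step), 10)
    bins_f = freqs * t_len
    bins = np.round(bins_f).astype(int)
    if not np.allclose(bins_f, bins, atol=1e-6):
        raise InvalidParameterError(
            "requested frequencies must be multiples of the trial Rayleigh "
            f"resolution 1/T = {1 / t_len:g} Hz"
        )
    tapers = _dpss_tapers(neural.n_samples, t_len * smoothing_hz, k)

    x = neural.data - neural.data.mean(axis=2, keepdims=True)
    ys = {n: y - y.mean(axis=1, keepdims=True) for n, y in feats.items()}

    n_v = neural.n_channels
    s_xx = np.zeros((n_v, freqs.size))
    s_yy = {n: np.zeros(freqs.size) for n in feats}
    s_xy = {n: np.zeros((n_v, freqs.size), dtype=complex) for n in feats}
    for taper in tapers:
        xf = np.fft.rfft(x * taper, axis=2)[:, :, bins]
        s_xx += (xf.real**2 + xf.imag**2).sum(axis=0)
        for name, y in ys.items():
            yf = np.fft.rfft(y * taper, axis=1)[:, bins]
            s_yy[name] += (yf.real**2 + yf.imag**2).sum(axis=0)
            s_xy[name] += np.einsum("tvf,tf->vf", xf, np.conj(yf))
    norm = neural.n_trials * tapers.shape[0]
    return {
        name: CrossSpectra(
            freqs_hz=freqs,
            s_xx=s_xx / norm,
            s_yy=s_yy[name] / norm,
            s_xy=s_xy[name] / norm,
            n_tapers=tapers.shape[0],
            n_trials=neural.n_trials,
        )
        for name in feats
    }


def multitaper_spectra(
    neural: TrialSet,
    feature_trials: np.ndarray,
    f_lo: float = 1.0,
    f_hi: float = 25.0,
    f_step: float = 0.5,
    smoothing_hz: float = 3.0,
) -> CrossSpectra:
    """DPSS multitaper auto- and cross-spectra between every channel/voxel of
    ``neural`` and the paired feature trials.

    ``feature_trials`` must be (n_trials, n_samples) aligned 1:1 with the
    neural trials.  Target frequencies must sit on the trial's natural
    Rayleigh grid (multiples of 1/T); 2-s trials give exactly the 0.5-Hz
    steps of the default 1–25 Hz grid (49 bins).
    """
    feature_trials = np.asarray(feature_trials, dtype=float)
    if feature_trials.ndim != 2:
        raise InvalidParameterError("feature trials must be (n_trials, n_samples)")
    return multitaper_spectra_multi(
        neural, {"_": feature_trials}, f_lo=f_lo, f_hi=f_hi, f_step=f_step, smoothing_hz=smoothing_hz
    )["_"]


def coherence_map(
    cs: CrossSpectra,
    feature: str = "",
    condition: str = "natural",
    subject_id: str = "",
    squared: bool = False,
) -> CoherenceMap:
    """Magnitude (or squared) coherence from averaged cross-spectra."""
    if cs.n_tapers * cs.n_trials < 2:
        raise InvalidParameterError("coherence needs at least two taper x trial units")
    denom = cs.s_xx * cs.s_yy[None, :]
    bad = denom <= 0
    if bad.any():
        warnings.warn("zero auto-spectrum bin(s); coherence set to 0 there", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.abs(cs.s_xy) / np.sqrt(np.where(bad, 1.0, denom))
    c = np.where(bad, 0.0, np.clip(c, 0.0, 1.0))
    if squared:
        c = c**2
    return CoherenceMap(
        values=c, freqs_hz=cs.freqs_hz, feature=feature, condition=condition, subject_id=subject_id
    )


def _band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    mask = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    if not mask.any():
        raise InvalidParameterError(f"band {band} contains no frequency bin")
    return mask


def band_average(cm: CoherenceMap, band: tuple[float, float]) -> np.ndarray:
    """Arithmetic mean of coherence over the inclusive frequency band."""
    mask = _band_mask(cm.freqs_hz, band)
    return cm.values[:, mask].mean(axis=1)


def intelligibility_index(
    natural: CoherenceMap, reversed_: CoherenceMap, band: tuple[float, float] = COMBINED_BAND
) -> IndexMap:
    """Band-averaged natural minus reversed coherence per voxel."""
    if {natural.condition, reversed_.condition} != {"natural", "reversed"}:
        raise InvalidParameterError("need one 'natural' and one 'reversed' map")
    if natural.condition != "natural":
        natural, reversed_ = reversed_, natural
    if natural.feature != reversed_.feature or natural.values.shape != reversed_.values.shape:
        raise InvalidParameterError("maps must share feature and dimensions")
    values = band_average(natural, band) - band_average(reversed_, band)
    return IndexMap(
        values=values, band=band, feature=natural.feature, subject_id=natural.subject_id
    )


def top_coherence_overlap(
    maps: list[CoherenceMap], frac: float = 0.9, band: tuple[float, float] = COMBINED_BAND
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Per-feature masks of voxels reaching ``frac`` of the maximum
    band-averaged coherence, and the per-voxel count of features whose mask
    includes it."""
    if not maps:
        raise InvalidParameterError("need at least one coherence map")
    if not 0 <= frac <= 1:
        raise InvalidParameterError("frac must lie in [0, 1]")
    n_v = maps[0].values.shape[0]
    masks: dict[str, np.ndarray] = {}
    for cm in maps:
        if cm.values.shape[0] != n_v:
            raise InvalidParameterError("all maps must share the voxel grid")
        avg = band_average(cm, band)
        masks[cm.feature] = avg >= frac * avg.max()
    overlap = np.sum(np.stack(list(masks.values())), axis=0)
    return overlap, masks
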