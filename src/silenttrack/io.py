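"""Readers and writers: WAV audio, hierarchical HDF5 array store, TSV tables.

The array store keeps every dense artifact under a documented tree:

    /trials/<name>   epoched data with condition/subject/space attrs
    /maps/<name>     coherence or index maps with dimension metadata
    /grid            voxel coordinates, spacing, region labels
    /meta            provenance (config hash, seed, package version)

Tabular outputs (participant tables, contrast tables, ROI fits) are plain
TSV so they stay inspectable without any tooling.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import FormatError, SilentTrackError
from .types import AudioWave, SourceGrid, TrialSet

__all__ = [
    "read_wav",
    "write_wav",
    "array_store_write",
    "array_store_read",
    "save_trialset",
    "load_trialset",
    "save_grid",
    "load_grid",
    "write_table",
]


def read_wav(path: str | Path) -> AudioWave:
    """Read a WAV file as float samples in [-1, 1]; stereo is averaged to
    mono with a warning."""
    from scipy.io import wavfile

    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # scipy raises bare ValueError on bad headers
        raise FormatError(f"{path}: not a readable WAV file ({exc})") from exc
    data = np.asarray(data)
    if data.ndim == 2:
        warnings.warn(f"{path}: stereo input averaged to mono", stacklevel=2)
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        scale = float(max(abs(np.iinfo(data.dtype).min), np.iinfo(data.dtype).max))
        data = data.astype(float) / scale
    else:
        data = data.astype(float)
    return AudioWave(data, rate_hz=float(rate))


def write_wav(path: str | Path, audio: AudioWave) -> None:
    """Write float32 PCM WAV."""
    from scipy.io import wavfile

    wavfile.write(str(path), int(round(audio.rate_hz)), audio.samples.astype(np.float32))


# ---------------------------------------------------------------------------
# hierarchical array store
# ---------------------------------------------------------------------------

def array_store_write(
    path: str | Path,
    arrays: dict[str, np.ndarray],
    metadata: dict | None = None,
    attrs: dict[str, dict] | None = None,
) -> None:
    """Write named arrays to an HDF5 container.

    ``arrays`` maps slash-separated dataset paths (e.g. ``maps/formant``) to
    arrays; ``attrs`` optionally attaches per-dataset scalar attributes;
    ``metadata`` is stored JSON-encoded under ``/meta``.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        for name, arr in arrays.items():
            arr = np.asarray(arr)
            if np.issubdtype(arr.dtype, np.floating) and not np.all(np.isfinite(arr)):
                raise SilentTrackError(f"array {name!r} contains non-finite values")
            if arr.dtype.kind in ("U", "O"):
                arr = arr.astype(h5py.string_dtype())
            ds = f.create_dataset(name, data=arr)
            for k, v in (attrs or {}).get(name, {}).items():
                ds.attrs[k] = v
        if metadata is not None:
            f.create_dataset("meta", data=json.dumps(metadata, sort_keys=True))


def array_store_read(path: str | Path, names: list[str] | None = None):
    """Read datasets (all, or the named subset) plus decoded /meta.

    Returns ``(arrays, metadata)``.  A missing dataset raises ``KeyError``
    naming the absent path.
    """
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    metadata = None
    with h5py.File(path, "r") as f:
        if names is None:
            names = []
            f.visititems(
                lambda n, obj: names.append(n) if isinstance(obj, h5py.Dataset) else None
            )
            names = [n for n in names if n != "meta"]
        for name in names:
            if name not in f:
                raise KeyError(f"dataset {name!r} missing from {path}")
            arr = f[name][()]
            if isinstance(arr, np.ndarray) and arr.dtype.kind in ("S", "O"):
                arr = arr.astype(str)
            arrays[name] = arr
        if "meta" in f:
            raw = f["meta"][()]
            metadata = json.loads(raw.decode() if isinstance(raw, bytes) else raw)
    return arrays, metadata


def save_trialset(path: str | Path, ts: TrialSet, name: str = "trials/data") -> None:
    array_store_write(
        path,
        {name: ts.data},
        attrs={
            name: {
                "rate_hz": ts.rate_hz,
                "condition": ts.condition,
                "subject_id": ts.subject_id,
                "space": ts.space,
            }
        },
    )


def load_trialset(path: str | Path, name: str = "trials/data") -> TrialSet:
    with h5py.File(path, "r") as f:
        if name not in f:
            raise KeyError(f"dataset {name!r} missing from {path}")
        ds = f[name]
        return TrialSet(
            ds[()],
            rate_hz=float(ds.attrs["rate_hz"]),
            condition=str(ds.attrs["condition"]),
            subject_id=str(ds.attrs["subject_id"]),
            space=str(ds.attrs["space"]),
        )


def save_grid(path: str | Path, grid: SourceGrid) -> None:
    array_store_write(
        path,
        {
            "grid/coords_mm": grid.coords_mm,
            "grid/region_labels": grid.region_labels,
        },
        attrs={
            "grid/coords_mm": {"spacing_mm": grid.spacing_mm, "shape": list(grid.shape)}
        },
    )


def load_grid(path: str | Path) -> SourceGrid:
    with h5py.File(path, "r") as f:
        if "grid/coords_mm" not in f:
            raise KeyError(f"dataset 'grid/coords_mm' missing from {path}")
        coords = f["grid/coords_mm"][()]
        labels = f["grid/region_labels"][()].astype(str)
        shape = tuple(int(s) for s in f["grid/coords_mm"].attrs["shape"])
        spacing = float(f["grid/coords_mm"].attrs["spacing_mm"])
    expected = int(np.prod(shape))
    if coords.shape[0] != expected or labels.shape[0] != expected:
        raise SilentTrackError(
            f"{path}: grid datasets have {coords.shape[0]} voxels but the "
            f"recorded shape {shape} implies {expected}"
        )
    return SourceGrid(shape=shape, spacing_mm=spacing, coords_mm=coords, region_labels=labels)


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)
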