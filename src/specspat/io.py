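"""Readers and writers for cubes and label rasters.

Supported formats:

* ``envi`` — flat binary raster (BSQ/BIL/BIP interleave) with a text
  ``.hdr`` companion, the lingua franca of hyperspectral tooling;
* ``mat`` — MATLAB containers as distributed for the classic benchmark
  scenes (one cube or ground-truth array per file);
* ``archive`` — a portable NumPy ``.npz`` bundle used for fixtures and for
  serializing intermediate artifacts (projections, probability maps).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import scipy.io

from .core import HyperCube, LabelMap, ProbabilityMap

__all__ = [
    "read_cube",
    "write_cube",
    "read_labels",
    "write_labels",
    "read_envi_header",
    "write_probability_map",
    "read_probability_map",
]

# ENVI data type codes <-> numpy dtypes (subset in common use)
_ENVI_DTYPES = {
    1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
    5: np.float64, 12: np.uint16, 13: np.uint32, 14: np.int64,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def _infer_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in {".npz", ".npy"}:
        return "archive"
    if suffix == ".mat":
        return "mat"
    return "envi"


def read_envi_header(hdr_path: str | Path) -> dict:
    """Parse an ENVI ``.hdr`` file into a {key: str | list} dict."""
    text = Path(hdr_path).read_text()
    if not text.lstrip().lower().startswith("envi"):
        raise ValueError(f"{hdr_path} is not an ENVI header")
    fields: dict[str, object] = {}
    body = text.lstrip()[4:]
    i = 0
    while i < len(body):
        eq = body.find("=", i)
        if eq < 0:
            break
        key = body[i:eq].strip().lower()
        rest = body[eq + 1:].lstrip()
        offset = eq + 1 + (len(body[eq + 1:]) - len(rest))
        if rest.startswith("{"):
            close = body.find("}", offset)
            if close < 0:
                raise ValueError(f"unterminated list for header key '{key}'")
            raw = body[offset + 1: close]
            fields[key] = [item.strip() for item in raw.split(",") if item.strip()]
            i = close + 1
        else:
            nl = body.find("\n", offset)
            nl = len(body) if nl < 0 else nl
            fields[key] = body[offset:nl].strip()
            i = nl + 1
    return fields


def _envi_data_path(path: Path) -> Path:
    """Locate the binary companion of a header (or vice versa)."""
    if path.suffix.lower() == ".hdr":
        for cand in (path.with_suffix(""), path.with_suffix(".img"),
                     path.with_suffix(".dat"), path.with_suffix(".bsq")):
            if cand.exists() and cand != path:
                return cand
        raise FileNotFoundError(f"no data file found next to header {path}")
    return path


def _read_envi(path: Path) -> tuple[np.ndarray, dict]:
    data_path = _envi_data_path(path)
    hdr_path = Path(str(data_path) + ".hdr")
    if not hdr_path.exists():
        hdr_path = data_path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise FileNotFoundError(f"missing ENVI header for {data_path}")
    hdr = read_envi_header(hdr_path)
    lines = int(hdr["lines"])        # M
    samples = int(hdr["samples"])    # N
    bands = int(hdr.get("bands", 1))
    dtype_code = int(hdr["data type"])
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if int(hdr.get("byte order", 0)) == 1:
        dtype = dtype.newbyteorder(">")
    interleave = str(hdr.get("interleave", "bsq")).lower()
    offset = int(hdr.get("header offset", 0))
    raw = np.fromfile(data_path, dtype=dtype, offset=offset)
    expected = lines * samples * bands
    if raw.size != expected:
        raise ValueError(
            f"ENVI data size mismatch: header implies {expected} values, "
            f"file holds {raw.size}"
        )
    if interleave == "bsq":
        arr = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        arr = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        arr = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unsupported interleave '{interleave}'")
    return np.ascontiguousarray(arr), hdr


def _write_envi(arr: np.ndarray, path: Path, interleave: str = "bsq",
                dtype: np.dtype | type = np.float64,
                wavelengths: list[float] | None = None) -> None:
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    m, n, d = arr.shape
    dtype = np.dtype(dtype)
    if dtype not in _DTYPE_CODES:
        raise ValueError(f"dtype {dtype} has no ENVI type code")
    data = arr.astype(dtype)
    interleave = interleave.lower()
    if interleave == "bsq":
        flat = data.transpose(2, 0, 1)
    elif interleave == "bil":
        flat = data.transpose(0, 2, 1)
    elif interleave == "bip":
        flat = data
    else:
        raise ValueError(f"unsupported interleave '{interleave}'")
    path.parent.mkdir(parents=True, exist_ok=True)
    flat.tofile(path)
    lines = [
        "ENVI",
        f"samples = {n}",
        f"lines = {m}",
        f"bands = {d}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_DTYPE_CODES[dtype]}",
        f"interleave = {interleave}",
        "byte order = 0" if data.dtype.byteorder in ("=", "<", "|") else "byte order = 1",
    ]
    if wavelengths is not None:
        lines.append("wavelength = {" + ", ".join(f"{w:g}" for w in wavelengths) + "}")
    Path(str(path) + ".hdr").write_text("\n".join(lines) + "\n")


def _mat_arrays(path: Path) -> dict[str, np.ndarray]:
    data = scipy.io.loadmat(os.fspath(path))
    return {k: v for k, v in data.items()
            if not k.startswith("__") and isinstance(v, np.ndarray)}


def _pick_mat_array(path: Path, ndim: int, key: str | None) -> np.ndarray:
    arrays = _mat_arrays(path)
    if key is not None:
        if key not in arrays:
            raise KeyError(f"variable '{key}' not found in {path}")
        return arrays[key]
    cands = {k: v for k, v in arrays.items() if v.ndim == ndim}
    if len(cands) != 1:
        raise ValueError(
            f"{path} holds {len(cands)} {ndim}-D arrays; pass the variable name"
        )
    return next(iter(cands.values()))


def read_cube(path: str | Path, format: str | None = None,
              key: str | None = None) -> HyperCube:
    """Read a hyperspectral cube in (row, col, band) order.

    ``format`` is one of ``envi``/``mat``/``archive``; inferred from the
    file suffix when omitted.  ``key`` names the MAT variable if the file
    holds several arrays.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "envi":
        arr, hdr = _read_envi(path)
        wavelengths = None
        if "wavelength" in hdr:
            wavelengths = [float(w) for w in hdr["wavelength"]]  # type: ignore[union-attr]
        return HyperCube(values=arr.astype(np.float64), wavelengths=wavelengths)
    if fmt == "mat":
        arr = _pick_mat_array(path, ndim=3, key=key)
        return HyperCube(values=arr.astype(np.float64))
    if fmt == "archive":
        with np.load(path, allow_pickle=False) as npz:
            values = npz["values"]
            band_ids = npz["band_ids"].tolist() if "band_ids" in npz else []
            wavelengths = npz["wavelengths"].tolist() if "wavelengths" in npz else None
            mask = npz["nodata_mask"] if "nodata_mask" in npz else None
        return HyperCube(values=values, band_ids=band_ids,
                         wavelengths=wavelengths, nodata_mask=mask)
    raise ValueError(f"unsupported cube format '{fmt}'")


def write_cube(cube: HyperCube, path: str | Path, format: str | None = None,
               interleave: str = "bsq",
               dtype: np.dtype | type = np.float64) -> Path:
    """Write a cube; returns the path written."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "envi":
        _write_envi(cube.values, path, interleave=interleave, dtype=dtype,
                    wavelengths=cube.wavelengths)
    elif fmt == "mat":
        scipy.io.savemat(os.fspath(path), {"cube": cube.values})
    elif fmt == "archive":
        payload = {"values": cube.values, "band_ids": np.asarray(cube.band_ids)}
        if cube.wavelengths is not None:
            payload["wavelengths"] = np.asarray(cube.wavelengths)
        if cube.nodata_mask is not None:
            payload["nodata_mask"] = cube.nodata_mask
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(path, **payload)
    else:
        raise ValueError(f"unsupported cube format '{fmt}'")
    return path


def read_labels(path: str | Path, format: str | None = None,
                key: str | None = None) -> LabelMap:
    """Read an integer label raster (0 = background)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "envi":
        arr, _ = _read_envi(path)
        if arr.shape[2] != 1:
            raise ValueError("label raster must be single-band")
        return LabelMap(arr[:, :, 0].astype(np.int32))
    if fmt == "mat":
        arr = _pick_mat_array(path, ndim=2, key=key)
        return LabelMap(np.asarray(arr))
    if fmt == "archive":
        with np.load(path, allow_pickle=False) as npz:
            return LabelMap(npz["labels"])
    raise ValueError(f"unsupported label format '{fmt}'")


def write_labels(labels: LabelMap, path: str | Path,
                 format: str | None = None) -> Path:
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "envi":
        _write_envi(labels.labels, path, interleave="bsq", dtype=np.int32)
    elif fmt == "mat":
        scipy.io.savemat(os.fspath(path), {"labels": labels.labels})
    elif fmt == "archive":
        path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(path, labels=labels.labels)
    else:
        raise ValueError(f"unsupported label format '{fmt}'")
    return path


def write_probability_map(pm: ProbabilityMap, path: str | Path) -> Path:
    """Serialize a probability map to a portable archive."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(path, probs=pm.probs, class_ids=pm.class_ids,
                        pixel_coords=pm.pixel_coords)
    return path


def read_probability_map(path: str | Path) -> ProbabilityMap:
    with np.load(Path(path), allow_pickle=False) as npz:
        return ProbabilityMap(probs=npz["probs"], class_ids=npz["class_ids"],
                              pixel_coords=npz["pixel_coords"])
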