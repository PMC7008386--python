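"""Reading and writing hyperspectral cubes, masks, and distribution maps.

Supported cube dialects:

``envi``
    Minimal ENVI: a text ``.hdr`` next to a raw band-sequential binary
    file, float64, with the wavenumber axis in the ``wavelength`` field.
``hdf5``
    A single HDF5 file with datasets ``cube``, ``axis``, ``mask`` and
    metadata stored as root attributes.
``csv_long``
    Delimited text with one sample per line, fixed column order
    ``row, col, wavenumber, absorbance``; pixels that are entirely NaN
    are flagged invalid.

The in-memory axis convention is always ascending wavenumber; a cube
stored in descending order is reversed on load and the flip recorded in
``meta['axis_reversed']``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import NamedTuple

import h5py
import numpy as np

__all__ = [
    "SpectralImage",
    "PixelIndex",
    "load_image",
    "save_image",
    "save_maps",
    "load_map",
]


class PixelIndex(NamedTuple):
    """Provenance of one unfolded row: owning image and pixel position."""

    image_id: str
    row: int
    col: int


@dataclass
class SpectralImage:
    """One section's absorbance cube plus axis, validity mask, metadata.

    Parameters
    ----------
    cube : ndarray, shape (rows, cols, channels)
        Absorbance in arbitrary units.
    axis : ndarray, shape (channels,)
        Wavenumbers in cm^-1, strictly ascending.
    mask : ndarray of bool, shape (rows, cols), optional
        True for valid pixels. Defaults to all-valid.
    meta : dict, optional
        Free-form metadata; conventional keys are ``section_id``,
        ``direction`` ('cross' or 'tangential') and ``ring`` (1-9).
    """

    cube: np.ndarray
    axis: np.ndarray
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        if self.cube.ndim != 3:
            raise ValueError(f"cube must be 3-D (rows, cols, channels), got shape {self.cube.shape}")
        if self.axis.ndim != 1 or self.cube.shape[2] != self.axis.size:
            raise ValueError(
                f"axis length {self.axis.size} does not match cube channel count {self.cube.shape[2]}"
            )
        _check_axis(self.axis)
        if self.mask is None:
            self.mask = np.ones(self.cube.shape[:2], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.cube.shape[:2]:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match image shape {self.cube.shape[:2]}"
                )
        if not np.all(np.isfinite(self.cube[self.mask])):
            raise ValueError("non-finite absorbance on valid (unmasked) pixels")

    @property
    def shape(self) -> tuple[int, int]:
        return self.cube.shape[:2]

    @property
    def n_channels(self) -> int:
        return self.cube.shape[2]

    @property
    def image_id(self) -> str:
        sid = self.meta.get("section_id")
        if sid is not None:
            return str(sid)
        direction = self.meta.get("direction")
        ring = self.meta.get("ring")
        if direction is not None and ring is not None:
            return f"{'X' if direction == 'cross' else 'T'}{ring}"
        return "image"

    def copy(self) -> "SpectralImage":
        return SpectralImage(
            cube=self.cube.copy(),
            axis=self.axis.copy(),
            mask=self.mask.copy(),
            meta=dict(self.meta),
        )


def _check_axis(axis: np.ndarray) -> None:
    d = np.diff(axis)
    if axis.size > 1 and not np.all(d > 0):
        dup = axis[1:][d == 0]
        if dup.size:
            raise ValueError(f"axis not strictly monotonic: duplicated wavenumber {dup[0]:g}")
        raise ValueError("axis not strictly monotonic after orientation")


def _normalize_axis(cube: np.ndarray, axis: np.ndarray, meta: dict) -> tuple[np.ndarray, np.ndarray]:
    if axis.size > 1 and axis[0] > axis[-1]:
        axis = axis[::-1].copy()
        cube = cube[:, :, ::-1].copy()
        meta["axis_reversed"] = True
    _check_axis(axis)
    return cube, axis


# ---------------------------------------------------------------------------
# ENVI dialect

_ENVI_DTYPE = {4: np.float32, 5: np.float64}
_ENVI_DTYPE_INV = {np.dtype(np.float32): 4, np.dtype(np.float64): 5}


def _envi_paths(path: str) -> tuple[str, str]:
    base, ext = os.path.splitext(path)
    if ext == ".hdr":
        return path, base + ".dat"
    return path + ".hdr", path + ".dat"


def _parse_envi_header(text: str) -> dict:
    fields: dict[str, str] = {}
    key = None
    buf: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.upper() == "ENVI":
            continue
        if key is None:
            if "=" not in line:
                continue
            key, _, rest = line.partition("=")
            key = key.strip().lower()
            rest = rest.strip()
            if rest.startswith("{") and "}" not in rest:
                buf = [rest.lstrip("{")]
                continue
            fields[key] = rest.strip("{}").strip()
            key = None
        else:
            if "}" in line:
                buf.append(line.split("}")[0])
                fields[key] = " ".join(buf)
                key = None
                buf = []
            else:
                buf.append(line)
    return fields


def _load_envi(path: str) -> SpectralImage:
    hdr_path, dat_path = _envi_paths(path)
    with open(hdr_path) as fh:
        fields = _parse_envi_header(fh.read())
    lines = int(fields["lines"])
    samples = int(fields["samples"])
    bands = int(fields["bands"])
    dtype = _ENVI_DTYPE[int(fields.get("data type", 5))]
    interleave = fields.get("interleave", "bsq").lower()
    axis = np.array([float(v) for v in fields["wavelength"].replace(",", " ").split()])
    if axis.size != bands:
        raise ValueError(f"header wavelength count {axis.size} does not match bands {bands}")
    raw = np.fromfile(dat_path, dtype=dtype)
    if raw.size != lines * samples * bands:
        raise ValueError(
            f"channel-count mismatch: data has {raw.size} values, header implies {lines * samples * bands}"
        )
    if interleave == "bsq":
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bip":
        cube = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unsupported ENVI interleave {interleave!r}")
    cube = np.ascontiguousarray(cube, dtype=float)
    meta = {}
    for k, v in fields.items():
        if k.startswith("meta "):
            meta[k[5:]] = _from_str(v)
    return _finalize_load(cube, axis, meta)


def _from_str(v: str):
    for cast in (int, float):
        try:
            return cast(v)
        except ValueError:
            pass
    return v


def _save_envi(image: SpectralImage, path: str) -> None:
    hdr_path, dat_path = _envi_paths(path)
    cube = np.where(image.mask[:, :, None], image.cube, np.nan)
    rows, cols, bands = cube.shape
    wl = ", ".join(f"{v:.10g}" for v in image.axis)
    lines = [
        "ENVI",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_ENVI_DTYPE_INV[np.dtype(np.float64)]}",
        "interleave = bsq",
        "byte order = 0",
        "wavelength units = cm-1",
        "wavelength = { " + wl + " }",
    ]
    for k, v in image.meta.items():
        lines.append(f"meta {k} = {v}")
    with open(hdr_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    cube.transpose(2, 0, 1).astype(np.float64).tofile(dat_path)


# ---------------------------------------------------------------------------
# HDF5 dialect


def _load_hdf5(path: str) -> SpectralImage:
    with h5py.File(path, "r") as fh:
        cube = fh["cube"][()]
        axis = fh["axis"][()]
        mask = fh["mask"][()].astype(bool) if "mask" in fh else None
        meta = {k: _h5_attr(v) for k, v in fh.attrs.items()}
    if cube.shape[-1] != axis.size:
        raise ValueError(
            f"channel-count mismatch: cube has {cube.shape[-1]} channels, axis has {axis.size}"
        )
    return _finalize_load(cube, axis, meta, mask)


def _h5_attr(v):
    if isinstance(v, bytes):
        return v.decode()
    if isinstance(v, np.generic):
        return v.item()
    return v


def _save_hdf5(image: SpectralImage, path: str) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("cube", data=image.cube)
        fh.create_dataset("axis", data=image.axis)
        fh.create_dataset("mask", data=image.mask)
        for k, v in image.meta.items():
            fh.attrs[k] = v


# ---------------------------------------------------------------------------
# csv_long dialect: fixed column order (row, col, wavenumber, absorbance)


def _load_csv_long(path: str) -> SpectralImage:
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.shape[1] != 4:
        raise ValueError("csv_long requires exactly 4 columns: row, col, wavenumber, absorbance")
    rows = data[:, 0].astype(int)
    cols = data[:, 1].astype(int)
    wns = data[:, 2]
    axis = np.unique(wns)
    nr, nc, nch = rows.max() + 1, cols.max() + 1, axis.size
    counts = np.zeros((nr, nc), dtype=int)
    np.add.at(counts, (rows, cols), 1)
    if np.any(counts[counts > 0] != nch):
        for r, c in np.argwhere(counts > nch):
            w = wns[(rows == r) & (cols == c)]
            u, n = np.unique(w, return_counts=True)
            if np.any(n > 1):
                raise ValueError(f"duplicated wavenumber {u[n > 1][0]:g} at pixel ({r}, {c})")
        raise ValueError("channel-count mismatch between pixels")
    cube = np.full((nr, nc, nch), np.nan)
    ch = np.searchsorted(axis, wns)
    cube[rows, cols, ch] = data[:, 3]
    return _finalize_load(cube, axis, {})


def _save_csv_long(image: SpectralImage, path: str) -> None:
    rows, cols, nch = image.cube.shape
    cube = np.where(image.mask[:, :, None], image.cube, np.nan)
    with open(path, "w") as fh:
        fh.write("row,col,wavenumber,absorbance\n")
        for r in range(rows):
            for c in range(cols):
                for j in range(nch):
                    fh.write(f"{r},{c},{image.axis[j]:.10g},{cube[r, c, j]:.17g}\n")


def _finalize_load(
    cube: np.ndarray, axis: np.ndarray, meta: dict, mask: np.ndarray | None = None
) -> SpectralImage:
    cube = np.asarray(cube, dtype=float)
    axis = np.asarray(axis, dtype=float)
    cube, axis = _normalize_axis(cube, axis, meta)
    all_nan = np.all(np.isnan(cube), axis=2)
    mask = ~all_nan if mask is None else (mask & ~all_nan)
    # invalid pixels hold 0 in memory so the cube stays finite everywhere
    cube = np.where(mask[:, :, None], cube, 0.0)
    return SpectralImage(cube=cube, axis=axis, mask=mask, meta=meta)


_DIALECTS = {
    "envi": (_load_envi, _save_envi),
    "hdf5": (_load_hdf5, _save_hdf5),
    "csv_long": (_load_csv_long, _save_csv_long),
}


def load_image(path: str, dialect: str = "hdf5") -> SpectralImage:
    """Load a hyperspectral cube; see module docstring for dialects.

    The returned axis is always ascending; all-NaN pixels are masked
    invalid.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(_DIALECTS)}")
    return _DIALECTS[dialect][0](path)


def save_image(image: SpectralImage, path: str, dialect: str = "hdf5") -> None:
    """Write a cube in the given dialect. Invalid pixels are stored as NaN."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(_DIALECTS)}")
    _DIALECTS[dialect][1](image, path)


# ---------------------------------------------------------------------------
# Distribution maps


def save_maps(model_maps: dict[str, np.ndarray], out_dir: str) -> list[str]:
    """Write per-(image, component) distribution maps plus a manifest.

    Parameters
    ----------
    model_maps : dict
        Keys ``image_id`` mapping to arrays of shape
        (rows, cols, n_components); NaN marks invalid pixels.
    out_dir : str
        Target directory (created if missing).

    Returns
    -------
    list of str
        Paths written (maps first, manifest last).
    """
    stacks = list(model_maps.values())
    if not stacks:
        raise ValueError("no maps to save")
    k = stacks[0].shape[2]
    if any(s.shape[2] != k for s in stacks):
        raise ValueError("all images must share the same component count")
    os.makedirs(out_dir, exist_ok=True)
    written = []
    manifest = {"images": [], "n_components": k, "maps": []}
    for image_id, stack in model_maps.items():
        manifest["images"].append(image_id)
        for comp in range(k):
            m = np.asarray(stack[:, :, comp], dtype=float)
            fname = f"map_{image_id}_c{comp}.csv"
            fpath = os.path.join(out_dir, fname)
            np.savetxt(fpath, m, delimiter=",", fmt="%.10g")
            valid = m[np.isfinite(m)]
            lo, hi = (float(valid.min()), float(valid.max())) if valid.size else (0.0, 0.0)
            manifest["maps"].append(
                {"file": fname, "image_id": image_id, "component": comp, "range": [lo, hi]}
            )
            written.append(fpath)
    man_path = os.path.join(out_dir, "manifest.json")
    with open(man_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    written.append(man_path)
    return written


def load_map(path: str) -> np.ndarray:
    """Load a single 2-D map saved by :func:`save_maps`."""
    return np.loadtxt(path, delimiter=",", ndmin=2)
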