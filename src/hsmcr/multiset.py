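"""Unfolding images into pixel x channel matrices, row-wise multiset
augmentation, and refolding concentration columns back into maps.

Unfolded rows follow a row-major pixel scan: (0,0), (0,1), ..., (1,0).
Masked pixels never enter the augmented matrix; their provenance is
simply absent from the index, and refolded maps carry NaN there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from hsmcr.io_cube import PixelIndex, SpectralImage

__all__ = ["Multiset", "unfold", "augment", "refold", "save_multiset", "load_multiset"]

MISSING = np.nan


@dataclass
class Multiset:
    """Augmented multiset matrix with pixel provenance.

    ``blocks`` maps image_id -> (start, end) row range; block order
    partitions the rows in the order images were given.  ``shapes``
    retains each image's (rows, cols) and validity mask for refolding.
    """

    data: np.ndarray
    axis: np.ndarray
    index: list[PixelIndex]
    blocks: dict[str, tuple[int, int]]
    shapes: dict[str, tuple[int, int]] = field(default_factory=dict)
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    direction: str | None = None

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def image_ids(self) -> list[str]:
        return list(self.blocks)


def unfold(image: SpectralImage) -> tuple[np.ndarray, list[PixelIndex]]:
    """Unfold one image to (valid_pixels x channels) plus its row index."""
    mask = image.mask
    if not mask.any():
        raise ValueError(f"image {image.image_id} has zero valid pixels")
    rows, cols = image.shape
    data = image.cube[mask]  # row-major scan over valid pixels
    image_id = image.image_id
    rr, cc = np.nonzero(mask)
    index = [PixelIndex(image_id, int(r), int(c)) for r, c in zip(rr, cc)]
    return data, index


def augment(images: list[SpectralImage], direction: str | None = None) -> Multiset:
    """Stack unfolded images row-wise into one augmented matrix.

    Images with zero valid pixels are dropped with a warning, mirroring
    the exclusion of oversaturated sections from the real multisets.
    """
    if not images:
        raise ValueError("need at least one image")
    axis = images[0].axis
    for img in images[1:]:
        if img.axis.shape != axis.shape or not np.array_equal(img.axis, axis):
            raise ValueError(
                f"axis mismatch between images {images[0].image_id!r} and {img.image_id!r}"
            )
    parts, index = [], []
    blocks: dict[str, tuple[int, int]] = {}
    shapes: dict[str, tuple[int, int]] = {}
    masks: dict[str, np.ndarray] = {}
    start = 0
    for img in images:
        if not img.mask.any():
            warnings.warn(
                f"image {img.image_id!r} has zero valid pixels and is excluded from the multiset",
                stacklevel=2,
            )
            continue
        data, idx = unfold(img)
        parts.append(data)
        index.extend(idx)
        blocks[img.image_id] = (start, start + data.shape[0])
        shapes[img.image_id] = img.shape
        masks[img.image_id] = img.mask.copy()
        start += data.shape[0]
    if not parts:
        raise ValueError("all images were excluded (zero valid pixels)")
    return Multiset(
        data=np.vstack(parts),
        axis=axis.copy(),
        index=index,
        blocks=blocks,
        shapes=shapes,
        masks=masks,
        direction=direction,
    )


def refold(multiset: Multiset, values: np.ndarray, image_id: str) -> np.ndarray:
    """Refold one per-row vector into the named image's 2-D map.

    Masked pixels receive NaN.
    """
    values = np.asarray(values, dtype=float)
    if values.shape[0] != multiset.n_rows:
        raise ValueError(
            f"values length {values.shape[0]} != multiset row count {multiset.n_rows}"
        )
    if image_id not in multiset.blocks:
        raise KeyError(f"unknown image_id {image_id!r}; known: {multiset.image_ids}")
    start, end = multiset.blocks[image_id]
    out = np.full(multiset.shapes[image_id], MISSING)
    for i in range(start, end):
        pix = multiset.index[i]
        out[pix.row, pix.col] = values[i]
    return out


def refold_all(multiset: Multiset, matrix: np.ndarray) -> dict[str, np.ndarray]:
    """Refold every column of (rows x k) into per-image (r, c, k) stacks."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if matrix.shape[0] != multiset.n_rows:
        raise ValueError("matrix row count does not match multiset")
    out = {}
    for image_id in multiset.image_ids:
        stack = np.stack(
            [refold(multiset, matrix[:, k], image_id) for k in range(matrix.shape[1])], axis=-1
        )
        out[image_id] = stack
    return out


def save_multiset(multiset: Multiset, path: str) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=multiset.data)
        fh.create_dataset("axis", data=multiset.axis)
        ids = multiset.image_ids
        fh.create_dataset("image_ids", data=np.array(ids, dtype=h5py.string_dtype()))
        fh.create_dataset("blocks", data=np.array([multiset.blocks[i] for i in ids]))
        fh.create_dataset("shapes", data=np.array([multiset.shapes[i] for i in ids]))
        idx = np.array([(pi.row, pi.col) for pi in multiset.index])
        fh.create_dataset("index_rc", data=idx)
        grp = fh.create_group("masks")
        for i in ids:
            grp.create_dataset(i, data=multiset.masks[i])
        if multiset.direction is not None:
            fh.attrs["direction"] = multiset.direction


def load_multiset(path: str) -> Multiset:
    with h5py.File(path, "r") as fh:
        data = fh["data"][()]
        axis = fh["axis"][()]
        ids = [s.decode() if isinstance(s, bytes) else str(s) for s in fh["image_ids"][()]]
        blocks_arr = fh["blocks"][()]
        shapes_arr = fh["shapes"][()]
        idx_rc = fh["index_rc"][()]
        blocks = {i: (int(a), int(b)) for i, (a, b) in zip(ids, blocks_arr)}
        shapes = {i: (int(a), int(b)) for i, (a, b) in zip(ids, shapes_arr)}
        masks = {i: fh["masks"][i][()].astype(bool) for i in ids}
        direction = fh.attrs.get("direction")
    index = []
    for image_id in ids:
        start, end = blocks[image_id]
        for j in range(start, end):
            index.append(PixelIndex(image_id, int(idx_rc[j, 0]), int(idx_rc[j, 1])))
    return Multiset(
        data=data, axis=axis, index=index, blocks=blocks,
        shapes=shapes, masks=masks, direction=direction,
    )
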