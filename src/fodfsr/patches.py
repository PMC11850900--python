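"""Patch geometry linking low-resolution and high-resolution SH grids.

One low-resolution (LR) voxel ``(i, j, k)`` corresponds to the disjoint
high-resolution (HR) 2x2x2 block ``(2i..2i+1, 2j..2j+1, 2k..2k+1)`` (0-based);
its center sits at HR continuous coordinate ``(2i+0.5, 2j+0.5, 2k+0.5)``.
A training example pairs the flattened 3x3x3 LR neighborhood of a voxel
(27 voxels x 44 normalized SH coefficients = 1188 numbers, border
neighborhoods zero-padded) with the flattened HR block of the central
voxel (8 voxels x 44 = 352 numbers).

Flattening is C-order over ``(dx, dy, dz, coefficient)``: voxel-major with
z fastest among the spatial offsets and the coefficient index innermost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GridMapping", "PatchDataset", "extract_patches", "extract_inputs",
           "scatter_blocks", "blocks_to_volume", "assign_splits"]


@dataclass(frozen=True)
class GridMapping:
    """Bijection between LR voxels and HR 2x2x2 blocks (factor fixed at 2)."""

    factor: int = 2

    def hr_block(self, i: int, j: int, k: int) -> tuple[slice, slice, slice]:
        f = self.factor
        return slice(f * i, f * i + f), slice(f * j, f * j + f), slice(f * k, f * k + f)

    def lr_center_in_hr(self, idx: np.ndarray) -> np.ndarray:
        """HR continuous coordinate of an LR voxel center."""
        return self.factor * np.asarray(idx, dtype=float) + 0.5


@dataclass
class PatchDataset:
    """Paired (1188-vector, 352-vector) examples with voxel provenance.

    ``phantom_ids`` tag each example with its source phantom (subject) so
    that train/validation/test splits can be made at phantom granularity
    and leakage across splits is structurally impossible.
    """

    inputs: np.ndarray
    targets: np.ndarray
    provenance: np.ndarray  # (n, 3) LR voxel indices
    phantom_ids: np.ndarray  # (n,)

    def __post_init__(self) -> None:
        n = len(self.inputs)
        if not (len(self.targets) == len(self.provenance) == len(self.phantom_ids) == n):
            raise ValueError("inconsistent example counts")

    def __len__(self) -> int:
        return len(self.inputs)

    def subset(self, phantom_ids) -> "PatchDataset":
        keep = np.isin(self.phantom_ids, np.asarray(phantom_ids))
        return PatchDataset(
            self.inputs[keep], self.targets[keep],
            self.provenance[keep], self.phantom_ids[keep],
        )

    @classmethod
    def concatenate(cls, parts: list["PatchDataset"]) -> "PatchDataset":
        return cls(
            np.concatenate([p.inputs for p in parts]),
            np.concatenate([p.targets for p in parts]),
            np.concatenate([p.provenance for p in parts]),
            np.concatenate([p.phantom_ids for p in parts]),
        )


def _neighborhoods(lr_sh: np.ndarray) -> np.ndarray:
    """(X, Y, Z, 3, 3, 3, C) zero-padded 3x3x3 neighborhoods."""
    padded = np.pad(lr_sh, [(1, 1), (1, 1), (1, 1), (0, 0)])
    win = np.lib.stride_tricks.sliding_window_view(padded, (3, 3, 3), axis=(0, 1, 2))
    # sliding_window_view puts window axes last: (X, Y, Z, C, 3, 3, 3)
    return np.moveaxis(win, 3, -1)


def extract_inputs(lr_sh: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flattened 3x3x3xC input rows for every masked LR voxel."""
    if lr_sh.ndim != 4:
        raise ValueError("lr_sh must be 4D (x, y, z, coefficient)")
    if mask.shape != lr_sh.shape[:3]:
        raise ValueError("mask shape does not match LR grid")
    nbh = _neighborhoods(lr_sh)
    idx = np.argwhere(mask)
    rows = nbh[mask].reshape(len(idx), -1)
    return np.ascontiguousarray(rows), idx


def blocks_to_volume(blocks: np.ndarray, idx: np.ndarray, lr_shape, n_coef: int) -> np.ndarray:
    """Scatter (n, 352) HR block predictions into a (2X, 2Y, 2Z, C) volume."""
    X, Y, Z = lr_shape
    out = np.zeros((2 * X, 2 * Y, 2 * Z, n_coef))
    cubes = blocks.reshape(-1, 2, 2, 2, n_coef)
    for (i, j, k), cube in zip(idx, cubes):
        out[2 * i: 2 * i + 2, 2 * j: 2 * j + 2, 2 * k: 2 * k + 2] = cube
    return out


# alias matching the scatter direction of the mapping
scatter_blocks = blocks_to_volume


def extract_patches(
    lr_sh: np.ndarray,
    hr_sh: np.ndarray,
    mask: np.ndarray | None = None,
    phantom_id: int = 0,
) -> PatchDataset:
    """Build training examples from an aligned LR/HR pair of SH volumes.

    ``hr_sh`` must have exactly doubled spatial dimensions.  One example is
    produced per masked LR voxel; neighborhoods reaching outside the volume
    are zero-padded.
    """
    if hr_sh.ndim != 4 or lr_sh.ndim != 4:
        raise ValueError("SH volumes must be 4D")
    if hr_sh.shape[:3] != tuple(2 * s for s in lr_sh.shape[:3]):
        raise ValueError("HR dims must be exactly double the LR dims")
    if hr_sh.shape[3] != lr_sh.shape[3]:
        raise ValueError("LR and HR coefficient counts differ")
    if mask is None:
        mask = np.ones(lr_sh.shape[:3], dtype=bool)

    inputs, idx = extract_inputs(lr_sh, mask)
    X, Y, Z, C = lr_sh.shape
    blocks = hr_sh.reshape(X, 2, Y, 2, Z, 2, C).transpose(0, 2, 4, 1, 3, 5, 6)
    targets = blocks[mask].reshape(len(idx), -1)
    return PatchDataset(
        inputs,
        np.ascontiguousarray(targets),
        idx,
        np.full(len(idx), phantom_id, dtype=int),
    )


def assign_splits(
    phantom_ids, n_val: int = 0, n_test: int = 0, seed: int = 0
) -> dict[str, np.ndarray]:
    """Shuffle whole phantoms into train/val/test groups (no leakage)."""
    ids = np.unique(np.asarray(phantom_ids))
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    n_train = len(ids) - n_val - n_test
    if n_train <= 0:
        raise ValueError("no phantoms left for training")
    return {
        "train": np.sort(ids[:n_train]),
        "val": np.sort(ids[n_train:n_train + n_val]),
        "test": np.sort(ids[n_train + n_val:]),
    }
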