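"""Multiresolution hash encoding of coordinates.

Each level carries a virtual grid of resolution ``base · growth^level`` over
the unit cube; cell-corner feature vectors live in a learnable table indexed
either directly (when the grid fits the table — collision-free) or through
a spatial XOR-prime hash.  Query features are the d-linear interpolation of
the corner features, concatenated across levels, and are continuous and
piecewise-(multi)linear in the coordinates.

Because this package always queries a fixed coordinate set (the voxel grid
and the contrast indices), interpolation is precompiled into one sparse
matrix per level; a forward pass is then a sparse-dense product, and its
adjoint handles the backward scatter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .autodiff import Tensor, concat, custom_op
from .layers import Module, _PTensor

__all__ = ["HashEncodingConfig", "HashEncoding", "sparse_matmul"]

_PRIMES = np.array([1, 2654435761, 805459861], dtype=np.uint64)


@dataclass(frozen=True)
class HashEncodingConfig:
    n_levels: int = 16
    features_per_level: int = 2
    table_size_log2: int = 19
    base_resolution: int = 8
    growth_factor: float = 1.5
    dimensionality: int = 3

    def __post_init__(self):
        if self.dimensionality not in (1, 3):
            raise ValueError("dimensionality must be 1 or 3")
        if self.growth_factor <= 1.0 and self.n_levels > 1:
            raise ValueError("growth_factor must exceed 1")

    def level_resolution(self, level: int) -> int:
        return max(1, int(np.floor(self.base_resolution * self.growth_factor**level)))

    def level_table_size(self, level: int) -> int:
        """Direct (collision-free) size when the grid fits the table."""
        res = self.level_resolution(level)
        dense = (res + 1) ** self.dimensionality
        return min(dense, 2**self.table_size_log2)

    def level_is_direct(self, level: int) -> bool:
        res = self.level_resolution(level)
        return (res + 1) ** self.dimensionality <= 2**self.table_size_log2


def sparse_matmul(mat: sparse.csr_matrix, mat_t: sparse.csr_matrix, table: Tensor) -> Tensor:
    """``mat @ table`` with gradient scattered back through ``mat_t``."""
    out = mat @ table.data

    def backward(g):
        return ((mat_t @ g).astype(table.data.dtype),)

    return custom_op(out, (table,), backward)


class HashEncoding(Module):
    """Learnable multiresolution feature tables plus interpolation."""

    def __init__(self, config: HashEncodingConfig, rng: np.random.Generator):
        self.config = config
        self.tables = []
        for lvl in range(config.n_levels):
            size = config.level_table_size(lvl)
            t = _PTensor(
                rng.uniform(-1e-4, 1e-4, size=(size, config.features_per_level)).astype(
                    np.float32
                ),
                requires_grad=True,
            )
            t._is_param = True
            self.tables.append(_TableHolder(t))

    @property
    def n_features(self) -> int:
        return self.config.n_levels * self.config.features_per_level

    # -- index computation ------------------------------------------------
    def _corner_indices(self, corners: np.ndarray, level: int) -> np.ndarray:
        cfg = self.config
        res = cfg.level_resolution(level)
        size = cfg.level_table_size(level)
        corners = corners.astype(np.uint64)
        if cfg.level_is_direct(level):
            idx = corners[..., 0].copy()
            stride = np.uint64(res + 1)
            for d in range(1, cfg.dimensionality):
                idx = idx + corners[..., d] * stride**np.uint64(d)
            return idx.astype(np.int64)
        h = corners[..., 0] * _PRIMES[0]
        for d in range(1, cfg.dimensionality):
            h = h ^ (corners[..., d] * _PRIMES[d])
        return (h % np.uint64(size)).astype(np.int64)

    def build_interpolator(self, coords: np.ndarray, strict: bool = False):
        """Sparse interpolation matrices (and transposes) for fixed coords.

        ``coords``: (n, dim) in [0, 1]; values outside are clamped with a
        warning (or rejected when ``strict``).
        """
        cfg = self.config
        coords = np.atleast_2d(np.asarray(coords, dtype=np.float64))
        if coords.shape[1] != cfg.dimensionality:
            raise ValueError("coordinate dimensionality mismatch")
        if coords.min() < 0.0 or coords.max() > 1.0:
            if strict:
                raise ValueError("coordinates outside [0, 1]")
            warnings.warn("coordinates outside [0, 1]; clamping", stacklevel=2)
            coords = np.clip(coords, 0.0, 1.0)
        n = coords.shape[0]
        dim = cfg.dimensionality
        n_corners = 2**dim
        offsets = np.array(
            [[(c >> d) & 1 for d in range(dim)] for c in range(n_corners)]
        )
        mats = []
        for lvl in range(cfg.n_levels):
            res = cfg.level_resolution(lvl)
            size = cfg.level_table_size(lvl)
            pos = coords * res
            c0 = np.minimum(np.floor(pos), res - 1).astype(np.int64)
            frac = pos - c0
            rows = np.repeat(np.arange(n), n_corners)
            cols = np.empty(n * n_corners, dtype=np.int64)
            vals = np.empty(n * n_corners, dtype=np.float64)
            for ci, off in enumerate(offsets):
                corner = c0 + off[None, :]
                w = np.ones(n)
                for d in range(dim):
                    w = w * (frac[:, d] if off[d] else 1.0 - frac[:, d])
                cols[ci::n_corners] = self._corner_indices(corner, lvl)
                vals[ci::n_corners] = w
            mat = sparse.csr_matrix(
                (vals, (rows, cols)), shape=(n, size), dtype=np.float32
            )
            mat.sum_duplicates()
            mats.append((mat, mat.T.tocsr()))
        return mats

    def __call__(self, interp) -> Tensor:
        feats = [
            sparse_matmul(mat, mat_t, holder.table)
            for (mat, mat_t), holder in zip(interp, self.tables)
        ]
        return concat(feats, axis=1)


class _TableHolder(Module):
    def __init__(self, table: Tensor):
        self.table = table
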