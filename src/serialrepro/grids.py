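"""Discrete spatial domain shared by all other modules.

Coordinates are continuous in ``[0, 1]`` per axis ("fraction relative to an
image size of 1").  A :class:`Grid` partitions each axis into equal half-open
cells with centers at ``(i + 0.5) / n``; every probability object in the
package is a :class:`DensityField`, i.e. a probability *mass* per cell, so
that integrals over the domain become sums over cells.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

__all__ = [
    "Grid",
    "DensityField",
    "normalize",
    "kl_divergence",
    "DomainError",
    "ShapeMismatchError",
    "DegenerateDensityError",
]


class DomainError(ValueError):
    """A point or value lies outside the modeled domain."""


class ShapeMismatchError(ValueError):
    """Two objects that must share a grid do not."""


class DegenerateDensityError(ValueError):
    """A density is identically zero or otherwise unnormalizable."""


@dataclass(frozen=True)
class Grid:
    """Uniform grid over the unit interval (1D) or unit square (2D).

    Parameters
    ----------
    shape
        Number of cells per axis, e.g. ``(256,)`` or ``(64, 64)``.
    """

    shape: tuple[int, ...]

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) not in (1, 2):
            raise ValueError(f"only 1D/2D grids are supported, got shape {shape}")
        if any(n < 1 for n in shape):
            raise ValueError(f"grid shape must be positive, got {shape}")

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    @property
    def spacing(self) -> tuple[float, ...]:
        return tuple(1.0 / n for n in self.shape)

    @property
    def cell_volume(self) -> float:
        return float(np.prod(self.spacing))

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return (np.arange(n) + 0.5) / n

    @cached_property
    def centers(self) -> np.ndarray:
        """Cell centers as an ``(n_cells, ndim)`` array in C (row-major) order."""
        axes = [self.axis_centers(a) for a in range(self.ndim)]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)

    def point_to_cell(self, point) -> int:
        """Flat index of the cell whose center is nearest to ``point``.

        Ties (a point exactly midway between two centers) break toward the
        lower index; boundary points map to the nearest valid cell.
        """
        p = np.asarray(point, dtype=float).reshape(-1)
        if p.shape != (self.ndim,):
            raise DomainError(f"expected a point of dimension {self.ndim}, got {p}")
        if np.any(p < 0.0) or np.any(p > 1.0):
            raise DomainError(f"point {p} outside the unit domain")
        idx = []
        for a, n in enumerate(self.shape):
            # cell i covers [i/n, (i+1)/n); the midpoint between centers i and
            # i+1 is (i+1)/n, which floors to i+1 -- nudge down for lower-index
            # tie-breaking.
            i = int(np.floor(np.nextafter(p[a] * n, -np.inf)))
            idx.append(min(max(i, 0), n - 1))
        return int(np.ravel_multi_index(tuple(idx), self.shape))

    def points_to_cells(self, points: np.ndarray) -> np.ndarray:
        """Vectorized :meth:`point_to_cell` for an ``(m, ndim)`` array."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        if p.shape[1] != self.ndim:
            raise DomainError(f"expected points of dimension {self.ndim}")
        if np.any(p < 0.0) or np.any(p > 1.0):
            raise DomainError("point outside the unit domain")
        idx = []
        for a, n in enumerate(self.shape):
            i = np.floor(np.nextafter(p[:, a] * n, -np.inf)).astype(int)
            idx.append(np.clip(i, 0, n - 1))
        return np.ravel_multi_index(tuple(idx), self.shape)

    def cell_center(self, cell: int) -> np.ndarray:
        return self.centers[cell]

    def interior_mask(self, margin: int) -> np.ndarray:
        """Boolean mask (flat) of cells at least ``margin`` cells from a border."""
        masks = []
        for a, n in enumerate(self.shape):
            m = np.zeros(n, dtype=bool)
            if n > 2 * margin:
                m[margin : n - margin] = True
            masks.append(m)
        mesh = np.meshgrid(*masks, indexing="ij")
        out = np.ones(self.shape, dtype=bool)
        for m in mesh:
            out &= m
        return out.ravel()


@dataclass(frozen=True)
class DensityField:
    """Probability mass per grid cell; sums to 1."""

    grid: Grid
    mass: np.ndarray

    def __post_init__(self) -> None:
        mass = np.asarray(self.mass, dtype=float).reshape(-1)
        object.__setattr__(self, "mass", mass)
        if mass.shape != (self.grid.n_cells,):
            raise ShapeMismatchError(
                f"mass has {mass.shape[0]} entries for a {self.grid.n_cells}-cell grid"
            )
        if np.any(mass < 0):
            raise DomainError("negative probability mass")
        if not np.isclose(mass.sum(), 1.0, atol=1e-9):
            raise DegenerateDensityError(f"mass sums to {mass.sum()!r}, not 1")

    def as_array(self) -> np.ndarray:
        """Mass reshaped to the grid shape."""
        return self.mass.reshape(self.grid.shape)

    @property
    def density(self) -> np.ndarray:
        """Mass converted to density per unit volume (flat)."""
        return self.mass / self.grid.cell_volume

    def mean(self) -> np.ndarray:
        return self.mass @ self.grid.centers

    def floored(self, eps: float = 1e-12) -> "DensityField":
        """Add ``eps`` mass per cell and renormalize (strictly positive result)."""
        return normalize(self.mass + eps, self.grid)


def normalize(raw_values, grid: Grid) -> DensityField:
    """Normalize nonnegative per-cell values into a :class:`DensityField`."""
    raw = np.asarray(raw_values, dtype=float).reshape(-1)
    if raw.shape != (grid.n_cells,):
        raise ShapeMismatchError(
            f"{raw.shape[0]} values for a {grid.n_cells}-cell grid"
        )
    if np.any(raw < 0):
        raise DomainError("negative entries cannot be normalized into a density")
    total = raw.sum()
    if total <= 0 or not np.isfinite(total):
        raise DegenerateDensityError("all-zero (or non-finite) input")
    return DensityField(grid, raw / total)


def kl_divergence(p: DensityField, q: DensityField) -> float:
    """Kullback-Leibler divergence ``sum p log(p/q)`` between two fields.

    Used as the convergence diagnostic for chain iterates approaching the
    stationary distribution.  Requires ``q > 0`` wherever ``p > 0``.
    """
    if p.grid != q.grid:
        raise ShapeMismatchError("KL divergence requires a common grid")
    support = p.mass > 0
    if np.any(q.mass[support] <= 0):
        raise DomainError("q must be positive on the support of p")
    pm = p.mass[support]
    qm = q.mass[support]
    val = float(np.sum(pm * np.log(pm / qm)))
    # rounding can push an exactly-zero divergence a few ulp negative
    return 0.0 if -1e-12 < val < 0.0 else val
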