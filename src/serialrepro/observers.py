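"""Encoder models: likelihood matrices ``p(T = x_j | S = x_i)`` on a grid.

Three observers are implemented:

``FixedPrecisionObserver``
    Isotropic Gaussian sensory noise of constant SD ``sigma`` everywhere
    (the classical assumption behind the category-adjustment account).

``SymmetricVariablePrecisionObserver``
    Isotropic Gaussian noise whose local SD scales with the prior as
    ``sigma0 * density(x)**(-alpha)``: precise near landmarks, coarse far
    from them, but symmetric around the true location and hence unbiased
    on average.

``EfficientEncodingObserver``
    Constant Gaussian noise of SD ``sigma_w`` in a perceptually *warped*
    coordinate space in which the prior is uniform.  Regions of high prior
    probability are dilated in the warped space, so in Euclidean units the
    noise is small and skewed toward landmarks near the modes of the prior.

The warp is realized as the triangular (Knothe-Rosenblatt) rearrangement:
in 1D the prior's CDF, in 2D the first-axis marginal CDF followed by the
conditional CDF of the second axis given the first.  The pushforward of the
prior through this map is uniform on the unit interval/square.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .grids import (
    DensityField,
    DomainError,
    Grid,
    ShapeMismatchError,
)

__all__ = [
    "FixedPrecisionObserver",
    "SymmetricVariablePrecisionObserver",
    "EfficientEncodingObserver",
    "Observer",
    "LikelihoodMatrix",
    "warp_forward",
    "build_likelihood",
    "observer_is_bayesian",
    "NumericUnderflowError",
    "DegenerateConditionalError",
]

PRIOR_FLOOR = 1e-12  # mass added per cell before warping/conditioning


class NumericUnderflowError(FloatingPointError):
    """A likelihood row underflowed to all-zero; increase sigma or coarsen the grid."""


class DegenerateConditionalError(ValueError):
    """A conditional slice of the prior has no mass and cannot be warped."""


@dataclass(frozen=True)
class FixedPrecisionObserver:
    """Location-independent isotropic Gaussian encoder with SD ``sigma``."""

    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class SymmetricVariablePrecisionObserver:
    """Unbiased encoder whose noise SD shrinks where the prior is dense.

    Local SD is ``sigma0 * d(x)**(-alpha)`` with ``d`` the prior density per
    unit volume; ``alpha`` defaults to 1 in 1D and 1/2 in 2D so that the
    local precision matches the efficient encoder's, leaving bias structure
    as the only difference between the two variable-precision models.
    """

    prior: DensityField
    sigma0: float
    alpha: float | None = None

    def __post_init__(self) -> None:
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be > 0")
        alpha = self.alpha
        if alpha is None:
            alpha = 1.0 if self.prior.grid.ndim == 1 else 0.5
        if alpha < 0:
            raise ValueError("alpha must be >= 0")
        object.__setattr__(self, "alpha", float(alpha))


@dataclass(frozen=True)
class EfficientEncodingObserver:
    """Constant-precision encoder in prior-uniformized (warped) coordinates."""

    prior: DensityField
    sigma_w: float

    def __post_init__(self) -> None:
        if self.sigma_w <= 0:
            raise ValueError("sigma_w must be > 0")


Observer = Union[
    FixedPrecisionObserver,
    SymmetricVariablePrecisionObserver,
    EfficientEncodingObserver,
]


def observer_is_bayesian(observer: Observer) -> bool:
    """Whether reproduction goes through posterior inference.

    The fixed-precision and efficient-encoding models are Bayesian:
    responses are samples from the posterior ``p(S|T)``.  The symmetric
    variable-precision model responds with an independent symmetric noise
    sample around the true location (a draw from its likelihood row) and is
    unbiased by construction.
    """
    return not isinstance(observer, SymmetricVariablePrecisionObserver)


@dataclass(frozen=True)
class LikelihoodMatrix:
    """Row-stochastic matrix ``p(T = x_j | S = x_i)`` over grid cells."""

    grid: Grid
    matrix: np.ndarray

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", mat)
        n = self.grid.n_cells
        if mat.shape != (n, n):
            raise ShapeMismatchError(f"matrix shape {mat.shape} for {n} cells")
        if np.any(mat < 0):
            raise DomainError("negative likelihood entries")
        if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("likelihood rows must each sum to 1")


# ---------------------------------------------------------------------------
# Perceptual warp (triangular rearrangement)
# ---------------------------------------------------------------------------


def _edge_cdf(mass_1d: np.ndarray) -> np.ndarray:
    """Cumulative mass at the n+1 cell edges of a 1D mass vector."""
    c = np.concatenate([[0.0], np.cumsum(mass_1d)])
    c /= c[-1]
    return c


def _interp_cdf(mass_1d: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Piecewise-linear CDF of a per-cell mass vector, evaluated at ``x``.

    Linear within each cell, so a cell center maps to (mass below) + half
    the cell's own mass; a uniform prior warps to the identity.
    """
    n = mass_1d.shape[0]
    edges = np.arange(n + 1) / n
    return np.interp(x, edges, _edge_cdf(mass_1d))


def warp_forward(prior: DensityField, points) -> np.ndarray:
    """Map points to warped (prior-uniformized) coordinates.

    In 1D this is the prior's CDF.  In 2D it is the triangular transform:
    the first coordinate through the axis-0 marginal CDF, the second through
    the CDF of axis 1 conditional on the axis-0 cell containing the point.

    Accepts a single point or an ``(m, ndim)`` array; returns the same shape.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    grid = prior.grid
    if pts.shape[1] != grid.ndim:
        raise DomainError(f"expected points of dimension {grid.ndim}")
    if np.any(pts < 0) or np.any(pts > 1):
        raise DomainError("point outside the unit domain")
    mass = prior.floored(PRIOR_FLOOR).as_array()
    if grid.ndim == 1:
        out = _interp_cdf(mass, pts[:, 0])[:, None]
    else:
        marg0 = mass.sum(axis=1)
        if np.any(marg0 <= 0):
            raise DegenerateConditionalError("zero-mass marginal slice")
        u = _interp_cdf(marg0, pts[:, 0])
        # conditional CDF uses the axis-0 cell containing the point
        n0 = grid.shape[0]
        i0 = np.clip(np.floor(np.nextafter(pts[:, 0] * n0, -np.inf)).astype(int), 0, n0 - 1)
        cond = mass / marg0[:, None]
        edges1 = np.arange(grid.shape[1] + 1) / grid.shape[1]
        cond_edges = np.concatenate(
            [np.zeros((n0, 1)), np.cumsum(cond, axis=1)], axis=1
        )
        cond_edges /= cond_edges[:, -1:]
        v = np.empty(pts.shape[0])
        for row in np.unique(i0):
            sel = i0 == row
            v[sel] = np.interp(pts[sel, 1], edges1, cond_edges[row])
        out = np.stack([u, v], axis=1)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# Likelihood construction
# ---------------------------------------------------------------------------


def _gaussian_rows(centers: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """Row-normalized isotropic Gaussian weights between all center pairs.

    ``sigmas`` is a per-row SD vector; truncation at the domain boundary is
    handled by renormalizing each row over in-domain cells (no reflection).
    """
    sq = (centers**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (centers @ centers.T)
    np.maximum(d2, 0.0, out=d2)
    w = np.exp(-0.5 * d2 / sigmas[:, None] ** 2)
    row_sums = w.sum(axis=1)
    if np.any(row_sums <= 0) or not np.all(np.isfinite(row_sums)):
        raise NumericUnderflowError(
            "a likelihood row underflowed; increase sigma or use a finer grid"
        )
    return w / row_sums[:, None]


def build_likelihood(observer: Observer, grid: Grid) -> LikelihoodMatrix:
    """Build the likelihood matrix of ``observer`` on ``grid``.

    Fixed: row ``i`` is an isotropic Gaussian of SD ``sigma`` around the cell
    center, truncated to the domain and renormalized.  Symmetric-variable:
    same but with per-row SD ``sigma0 * density(x_i)**(-alpha)``.  Efficient:
    row ``i`` is the pullback of an isotropic Gaussian of SD ``sigma_w``
    centered on the warped cell center, evaluated at all warped cell centers
    and renormalized.
    """
    if isinstance(observer, FixedPrecisionObserver):
        sig = np.full(grid.n_cells, float(observer.sigma))
        return LikelihoodMatrix(grid, _gaussian_rows(grid.centers, sig))
    if isinstance(observer, SymmetricVariablePrecisionObserver):
        if observer.prior.grid != grid:
            raise ShapeMismatchError("observer prior grid differs from target grid")
        dens = observer.prior.floored(PRIOR_FLOOR).density
        sig = observer.sigma0 * dens ** (-observer.alpha)
        return LikelihoodMatrix(grid, _gaussian_rows(grid.centers, sig))
    if isinstance(observer, EfficientEncodingObserver):
        if observer.prior.grid != grid:
            raise ShapeMismatchError("observer prior grid differs from target grid")
        warped = np.atleast_2d(warp_forward(observer.prior, grid.centers))
        sig = np.full(grid.n_cells, float(observer.sigma_w))
        return LikelihoodMatrix(grid, _gaussian_rows(warped, sig))
    raise TypeError(f"unknown observer type: {type(observer).__name__}")
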