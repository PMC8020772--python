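"""Discrimination sensitivity (d') maps, predicted and empirical.

Predicted d' follows the signal-detection formula

    d(S1, S2) = (mu~(S1) - mu~(S2)) / sqrt((sig~(S1)^2 + sig~(S2)^2) / 2),

where ``mu~`` and ``sig~^2`` are the mean and variance of the reproduction
distribution ``p(R | S)`` (a row of the transition kernel).  In 2D the
reproduction distributions are projected onto the line through the two
points, avoiding full 2D signal detection theory.

Empirical d' comes from 2AFC same/shifted counts as ``z(hit rate) -
z(false-alarm rate)`` with the 1/(2N) correction for extreme rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from scipy.stats import norm

from .grids import DensityField, DomainError, Grid, ShapeMismatchError
from .observers import LikelihoodMatrix
from .chains import transition_kernel

__all__ = [
    "DPrimeMap",
    "TwoAFCDataset",
    "DiscriminationPredictor",
    "reproduction_moments",
    "predict_dprime",
    "dprime_map_predicted",
    "dprime_from_counts",
    "analyze_2afc",
    "smooth_dprime_map",
]


@dataclass
class DPrimeMap:
    """d' values on a regular probe grid; NaN marks dropped (edge) probes."""

    probe_grid: Grid
    values: np.ndarray
    radius: float | None = None
    kernel_sd: float = 0.0
    interpolated: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float).reshape(-1)
        if vals.shape != (self.probe_grid.n_cells,):
            raise ShapeMismatchError("values do not match the probe grid")
        self.values = vals

    def as_array(self) -> np.ndarray:
        return self.values.reshape(self.probe_grid.shape)

    @property
    def retained(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class TwoAFCDataset:
    """Same/shifted 2AFC records on a probe grid.

    ``frame`` columns: probe coordinates (``probe_x`` and, in 2D,
    ``probe_y``), ``condition`` in {"same", "shifted"} and ``response`` in
    {"same", "shifted"}.
    """

    frame: "object"  # pandas.DataFrame
    radius: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cols = set(self.frame.columns)
        required = {"probe_x", "condition", "response"}
        if not required <= cols:
            raise ValueError(f"2AFC frame missing columns {sorted(required - cols)}")
        conds = set(self.frame["condition"].unique())
        if not conds <= {"same", "shifted"}:
            raise ValueError(f"unknown conditions {conds - {'same', 'shifted'}}")


# ---------------------------------------------------------------------------
# Model predictions
# ---------------------------------------------------------------------------


class DiscriminationPredictor:
    """Precomputes reproduction moments for fast d' queries.

    Means and covariances of ``p(R | S = x_i)`` for every grid cell are
    computed once from the transition kernel; individual d' queries then
    snap their points to cells and read off the projected moments.
    """

    def __init__(self, prior: DensityField, likelihood: LikelihoodMatrix):
        if prior.grid != likelihood.grid:
            raise ShapeMismatchError("prior and likelihood grids differ")
        self.grid = prior.grid
        kernel = transition_kernel(prior, likelihood).matrix
        c = self.grid.centers  # (n, d)
        self.means = kernel @ c  # (n, d)
        d = self.grid.ndim
        self.covs = np.empty((self.grid.n_cells, d, d))
        for a in range(d):
            for b in range(a, d):
                exy = kernel @ (c[:, a] * c[:, b])
                cov = exy - self.means[:, a] * self.means[:, b]
                self.covs[:, a, b] = cov
                self.covs[:, b, a] = cov

    def moments(self, s_cell: int) -> tuple[np.ndarray, np.ndarray]:
        return self.means[s_cell], self.covs[s_cell]

    def dprime(self, s1, s2) -> float:
        """Projected d' between two points (antisymmetric in its arguments).

        The projection axis is the line through the points with a canonical
        orientation (positive leading component), so swapping the arguments
        flips the sign.
        """
        p1 = np.asarray(s1, dtype=float).reshape(-1)
        p2 = np.asarray(s2, dtype=float).reshape(-1)
        if np.allclose(p1, p2):
            return 0.0
        axis = p1 - p2
        # canonical orientation of the (unordered) line
        lead = axis[np.argmax(np.abs(axis) > 1e-15)]
        u = axis / np.linalg.norm(axis)
        i1 = self.grid.point_to_cell(p1)
        i2 = self.grid.point_to_cell(p2)
        m1 = float(u @ self.means[i1])
        m2 = float(u @ self.means[i2])
        v1 = float(u @ self.covs[i1] @ u)
        v2 = float(u @ self.covs[i2] @ u)
        pooled = 0.5 * (v1 + v2)
        if pooled <= 0:
            raise FloatingPointError("zero pooled reproduction variance")
        sign = 1.0 if lead > 0 else -1.0
        return sign * (m1 - m2) / np.sqrt(pooled)

    def dprime_map(
        self, probe_grid: Grid, radius: float, n_dir: int = 8
    ) -> DPrimeMap:
        """Mean |d'| over ``n_dir`` equally spaced offset directions per probe.

        Probes for which any offset endpoint leaves the domain are dropped
        (NaN): the fixed model's edge artifacts make border cells
        uninterpretable and they are excluded downstream anyway.
        """
        if radius <= max(self.grid.spacing):
            raise ValueError("offset radius must exceed one cell spacing")
        probes = probe_grid.centers
        if self.grid.ndim == 1:
            dirs = np.array([[1.0], [-1.0]])
        else:
            ang = np.arange(n_dir) * (2 * np.pi / n_dir)
            dirs = np.stack([np.cos(ang), np.sin(ang)], axis=1)
        values = np.full(probe_grid.n_cells, np.nan)
        for k, p in enumerate(probes):
            ends = p[None, :] + radius * dirs
            if np.any(ends < 0) or np.any(ends > 1):
                continue
            values[k] = float(
                np.mean([abs(self.dprime(p, e)) for e in ends])
            )
        if not np.any(np.isfinite(values)):
            raise ValueError("all probes dropped; radius too large for the grid")
        return DPrimeMap(probe_grid, values, radius=radius)


def reproduction_moments(
    prior: DensityField, likelihood: LikelihoodMatrix, s_cell: int
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of the reproduction distribution ``p(R | S = s)``."""
    return DiscriminationPredictor(prior, likelihood).moments(s_cell)


def predict_dprime(
    prior: DensityField, likelihood: LikelihoodMatrix, s1, s2
) -> float:
    """One-off projected d' between two points (see ``DiscriminationPredictor``)."""
    return DiscriminationPredictor(prior, likelihood).dprime(s1, s2)


def dprime_map_predicted(
    prior: DensityField,
    likelihood: LikelihoodMatrix,
    probe_grid: Grid,
    radius: float,
    n_dir: int = 8,
) -> DPrimeMap:
    """Predicted discrimination-accuracy map over a probe grid."""
    return DiscriminationPredictor(prior, likelihood).dprime_map(
        probe_grid, radius, n_dir=n_dir
    )


# ---------------------------------------------------------------------------
# Empirical d'
# ---------------------------------------------------------------------------


def _corrected_rate(k: int, n: int) -> float:
    """Hit/false-alarm rate with the 1/(2N) correction for 0 and 1."""
    if n <= 0:
        raise ValueError("condition total must be > 0")
    rate = k / n
    if rate <= 0.0:
        return 1.0 / (2 * n)
    if rate >= 1.0:
        return 1.0 - 1.0 / (2 * n)
    return rate


def dprime_from_counts(
    hits: int, misses: int, false_alarms: int, correct_rejections: int
) -> float:
    """d' = z(hit rate) - z(false-alarm rate) from 2AFC counts."""
    counts = (hits, misses, false_alarms, correct_rejections)
    if any(c < 0 for c in counts):
        raise DomainError("counts must be nonnegative")
    n_signal = hits + misses
    n_noise = false_alarms + correct_rejections
    h = _corrected_rate(hits, n_signal)
    f = _corrected_rate(false_alarms, n_noise)
    return float(norm.ppf(h) - norm.ppf(f))


def analyze_2afc(dataset: TwoAFCDataset, probe_grid: Grid) -> DPrimeMap:
    """Empirical d' per probe-grid cell from same/shifted responses.

    A "shifted" response in the shifted condition is a hit; in the same
    condition, a false alarm.  Probes with no data in either condition are
    NaN.
    """
    df = dataset.frame
    ndim = 2 if "probe_y" in df.columns else 1
    cols = ["probe_x", "probe_y"][:ndim]
    pts = df[cols].to_numpy(dtype=float)
    cells = probe_grid.points_to_cells(pts)
    values = np.full(probe_grid.n_cells, np.nan)
    shifted_resp = (df["response"] == "shifted").to_numpy()
    is_shifted = (df["condition"] == "shifted").to_numpy()
    for cell in np.unique(cells):
        sel = cells == cell
        sig = sel & is_shifted
        noi = sel & ~is_shifted
        if sig.sum() == 0 or noi.sum() == 0:
            continue
        hits = int(shifted_resp[sig].sum())
        fas = int(shifted_resp[noi].sum())
        values[cell] = dprime_from_counts(
            hits, int(sig.sum()) - hits, fas, int(noi.sum()) - fas
        )
    return DPrimeMap(probe_grid, values, radius=dataset.radius)


# ---------------------------------------------------------------------------
# Smoothing / interpolation
# ---------------------------------------------------------------------------


def smooth_dprime_map(
    dmap: DPrimeMap, kernel_sd: float, target_resolution: tuple[int, ...] | None = None
) -> DPrimeMap:
    """Gaussian smoothing plus cubic upsampling of a d' map.

    ``kernel_sd`` is in probe-grid steps; NaN (dropped) probes are handled
    by normalized convolution and stay NaN.  ``kernel_sd = 0`` with the same
    resolution is the identity.
    """
    if kernel_sd < 0:
        raise ValueError("kernel_sd must be >= 0")
    grid = dmap.probe_grid
    arr = dmap.as_array()
    if kernel_sd > 0:
        finite = np.isfinite(arr)
        filled = np.where(finite, arr, 0.0)
        num = ndimage.gaussian_filter(filled, sigma=kernel_sd, mode="nearest")
        den = ndimage.gaussian_filter(finite.astype(float), sigma=kernel_sd, mode="nearest")
        with np.errstate(invalid="ignore"):
            arr = np.where(finite, num / den, np.nan)
    if target_resolution is None or tuple(target_resolution) == grid.shape:
        return DPrimeMap(grid, arr.ravel(), radius=dmap.radius, kernel_sd=kernel_sd)
    target = tuple(int(n) for n in target_resolution)
    if any(t < s for t, s in zip(target, grid.shape)):
        raise ValueError("target resolution must be at least as fine as the probe grid")
    out_grid = Grid(target)
    axes = [grid.axis_centers(a) for a in range(grid.ndim)]
    interp = RegularGridInterpolator(
        axes, arr, method="cubic", bounds_error=False, fill_value=None
    )
    out_vals = interp(out_grid.centers)
    return DPrimeMap(
        out_grid, out_vals, radius=dmap.radius, kernel_sd=kernel_sd, interpolated=True
    )
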