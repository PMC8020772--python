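"""Single-trial bias vectors and the statistics built on them.

The signature of consistent perceptual bias is that nearby reproductions
move in similar directions: the distribution of angular differences between
averaged local bias vectors piles up near zero.  The band ratio quantifies
this as the probability mass of absolute angular differences within +/-12
degrees relative to the uniform expectation (24/360); a ratio of 1 is the
unbiased (symmetric-noise) prediction, ratios well above 1 the efficient
encoding prediction.  Uncertainty comes from a chain-level bootstrap.

Also here: map correlations with edge exclusion, disattenuation of
correlations for measurement unreliability, chi-square uniformity tests,
and the center-of-mass baseline prior built from segmentation masks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import chi2

from .chains import ChainDataset
from .grids import DensityField, DomainError, Grid, ShapeMismatchError, normalize

__all__ = [
    "BiasField",
    "bias_field",
    "angular_coherence",
    "coherence_band_ratio",
    "bootstrap_ci",
    "correlate_maps",
    "disattenuate",
    "uniformity_test",
    "center_of_mass_prior",
    "ANGULAR_BAND_DEG",
]

ANGULAR_BAND_DEG = 12.0  # +/- band for the coherence ratio


@dataclass
class BiasField:
    """Average bias vector (R - S) per spatial bin, with sample counts."""

    points: np.ndarray  # (m, ndim) bin centers (or raw sample points)
    vectors: np.ndarray  # (m, ndim) average bias per point
    counts: np.ndarray  # (m,) samples per point

    def __post_init__(self) -> None:
        if self.points.shape != self.vectors.shape:
            raise ShapeMismatchError("points and vectors must align")
        if np.any(self.counts < 1):
            raise ValueError("bins must contain at least one sample")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("non-finite bias vectors")


def bias_field(
    dataset: ChainDataset,
    iteration: int = 1,
    bin_size: float = 0.025,
    margin: float = 0.0,
) -> BiasField:
    """Bin single-trial biases ``R_t - S_{t-1}`` on a regular spatial grid.

    Biases are attributed to the stimulus location ``S_{t-1}``; empty bins
    are dropped.  ``margin`` excludes trials whose stimulus lies within that
    distance of the domain boundary: truncating response noise at the image
    border pulls responses inward everywhere along the edge, a coherent
    artifact unrelated to the encoder, so coherence analyses are run on the
    interior.
    """
    stim, resp = _bias_trials(dataset, iteration)
    if margin > 0:
        keep = np.all((stim >= margin) & (stim <= 1.0 - margin), axis=1)
        if not np.any(keep):
            raise ValueError("margin excludes every trial")
        stim, resp = stim[keep], resp[keep]
    bins = max(int(round(1.0 / bin_size)), 1)
    grid = Grid((bins,) * dataset.ndim)
    cells = grid.points_to_cells(stim)
    pts, vecs, counts = [], [], []
    for cell in np.unique(cells):
        sel = cells == cell
        pts.append(grid.cell_center(int(cell)))
        vecs.append((resp[sel] - stim[sel]).mean(axis=0))
        counts.append(int(sel.sum()))
    return BiasField(np.array(pts), np.array(vecs), np.array(counts))


def _bias_trials(dataset: ChainDataset, iteration: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-chain (stimulus, response) pairs for one iteration."""
    stim, resp = [], []
    for c in dataset.chains:
        if c.n_iterations < iteration:
            continue
        if c.is_dummy is not None and c.is_dummy[iteration]:
            continue
        stim.append(c.points[iteration - 1])
        resp.append(c.points[iteration])
    if not stim:
        raise ValueError(f"no trials at iteration {iteration}")
    return np.array(stim), np.array(resp)


def _band_ratio_and_hist(
    points: np.ndarray,
    vectors: np.ndarray,
    neighbor_radius: float,
    n_hist_bins: int = 30,
) -> tuple[float, np.ndarray, np.ndarray, int]:
    from scipy.spatial.distance import pdist, squareform

    m = points.shape[0]
    if m < 2:
        raise ValueError("need at least two bias samples")
    close = squareform(pdist(points)) <= neighbor_radius
    iu = np.triu_indices(m, k=1)
    pair_mask = close[iu]
    if not np.any(pair_mask):
        raise ValueError("no sample pairs within the neighbor radius")
    ang = np.degrees(np.arctan2(vectors[:, 1], vectors[:, 0]))
    diff = ang[iu[0][pair_mask]] - ang[iu[1][pair_mask]]
    diff = (diff + 180.0) % 360.0 - 180.0  # wrap to (-180, 180]
    absdiff = np.abs(diff)
    hist, edges = np.histogram(absdiff, bins=n_hist_bins, range=(0.0, 180.0))
    in_band = float(np.mean(absdiff <= ANGULAR_BAND_DEG))
    ratio = in_band / (2 * ANGULAR_BAND_DEG / 360.0)
    return ratio, hist, edges, int(pair_mask.sum())


def angular_coherence(
    field: BiasField, neighbor_radius: float = 0.05
) -> dict:
    """Pairwise angular-difference histogram and the +/-12 degree band ratio.

    Considers all pairs of bias-field sample points within
    ``neighbor_radius`` and the absolute angular differences of their
    average bias vectors.  Returns the histogram (30 bins over 0..180
    degrees), the number of pairs, and the ratio of observed probability in
    the +/-12 degree band to the uniform expectation (24/360).
    """
    if field.points.shape[1] != 2:
        raise ValueError("angular coherence is defined for 2D bias fields")
    ratio, hist, edges, n_pairs = _band_ratio_and_hist(
        field.points, field.vectors, neighbor_radius
    )
    return {
        "band_ratio": ratio,
        "histogram": hist,
        "bin_edges": edges,
        "n_pairs": n_pairs,
        "band_deg": ANGULAR_BAND_DEG,
        "neighbor_radius": neighbor_radius,
    }


def coherence_band_ratio(
    dataset: ChainDataset,
    iteration: int = 1,
    bin_size: float = 0.025,
    neighbor_radius: float = 0.05,
    margin: float = 0.1,
) -> float:
    """Band ratio recomputed from a dataset (bootstrap-friendly statistic).

    Defaults to interior trials only (``margin=0.1``); see ``bias_field``.
    """
    f = bias_field(dataset, iteration=iteration, bin_size=bin_size, margin=margin)
    return angular_coherence(f, neighbor_radius=neighbor_radius)["band_ratio"]


def bootstrap_ci(
    statistic_fn,
    dataset: ChainDataset,
    n_boot: int = 1000,
    rng_seed: int = 0,
    ci: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI for a chain-dataset statistic.

    Resamples whole chains with replacement (respecting within-chain
    dependence); deterministic given ``rng_seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if len(dataset) < 2:
        raise ValueError("need at least two chains to bootstrap")
    rng = np.random.default_rng(rng_seed)
    n = len(dataset)
    stats = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        resampled = ChainDataset(
            chains=[dataset.chains[i] for i in idx],
            stimulus_id=dataset.stimulus_id,
            provenance=dataset.provenance,
        )
        stats[b] = statistic_fn(resampled)
    lo = (1.0 - ci) / 2.0
    return (
        float(np.quantile(stats, lo)),
        float(np.quantile(stats, 1.0 - lo)),
    )


def correlate_maps(a, b, exclude_edge: int = 0) -> float:
    """Pearson correlation between two same-grid maps, edges excluded.

    Accepts :class:`DensityField` or d'-map objects (anything with a grid
    and flat values); cells within ``exclude_edge`` cells of the border and
    cells where either map is NaN are dropped.
    """
    grid_a, vals_a = _grid_values(a)
    grid_b, vals_b = _grid_values(b)
    if grid_a != grid_b:
        raise ShapeMismatchError("maps live on different grids")
    keep = np.isfinite(vals_a) & np.isfinite(vals_b)
    if exclude_edge > 0:
        keep &= grid_a.interior_mask(exclude_edge)
    x, y = vals_a[keep], vals_b[keep]
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        raise FloatingPointError("correlation undefined (constant or empty map)")
    return float(np.corrcoef(x, y)[0, 1])


def _grid_values(obj) -> tuple[Grid, np.ndarray]:
    if isinstance(obj, DensityField):
        return obj.grid, obj.mass
    if hasattr(obj, "probe_grid"):
        return obj.probe_grid, obj.values
    raise TypeError(f"cannot correlate object of type {type(obj).__name__}")


def disattenuate(r_obs: float, reliability_a: float, reliability_b: float) -> float:
    """Correct an observed correlation for measurement unreliability.

    ``r / sqrt(rel_a * rel_b)``, capped to [-1, 1]; reliabilities must lie
    in (0, 1].
    """
    for rel in (reliability_a, reliability_b):
        if not 0.0 < rel <= 1.0:
            raise DomainError("reliabilities must lie in (0, 1]")
    corrected = r_obs / np.sqrt(reliability_a * reliability_b)
    return float(np.clip(corrected, -1.0, 1.0))


def uniformity_test(points, grid_bins: int = 4) -> tuple[float, float]:
    """Chi-square goodness-of-fit of binned points against uniformity.

    Bins each axis into ``grid_bins`` equal intervals; if the expected count
    per bin falls below 5, the binning is coarsened by halving until it does
    not (minimum 2 bins per axis).  Returns (statistic, p-value).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n, d = pts.shape
    bins = int(grid_bins)
    while bins > 2 and n / bins**d < 5:
        bins //= 2
    if n / bins**d < 5:
        raise ValueError("too few points for a chi-square uniformity test")
    grid = Grid((bins,) * d)
    cells = grid.points_to_cells(pts)
    counts = np.bincount(cells, minlength=grid.n_cells)
    expected = n / grid.n_cells
    stat = float(((counts - expected) ** 2 / expected).sum())
    p = float(chi2.sf(stat, df=grid.n_cells - 1))
    return stat, p


def center_of_mass_prior(
    mask: np.ndarray, bump_width: float, grid: Grid
) -> DensityField:
    """Baseline prior: Gaussian bumps at the centroids of labeled regions.

    ``mask`` is a label-valued raster (0 = background) in image convention
    (row = y from top); centroids are converted to normalized (x, y)
    coordinates and each labeled region contributes one isotropic bump of SD
    ``bump_width``.
    """
    mask = np.asarray(mask)
    labels = np.unique(mask)
    labels = labels[labels != 0]
    if labels.size == 0:
        raise ValueError("mask contains no labeled regions")
    h, w = mask.shape
    total = np.zeros(grid.n_cells)
    centers = grid.centers
    for lab in labels:
        cy, cx = ndimage.center_of_mass(mask == lab)
        centroid = np.array([(cx + 0.5) / w, 1.0 - (cy + 0.5) / h])
        d2 = ((centers - centroid[None, :]) ** 2).sum(axis=1)
        total += np.exp(-0.5 * d2 / bump_width**2)
    return normalize(total, grid)
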