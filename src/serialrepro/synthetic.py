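"""Synthetic inputs: structured priors, shape images, simulated experiments.

Everything the analysis pipeline consumes can be generated here, emulating
the study conditions: multimodal spatial priors, grayscale shape stimuli,
transmission-chain datasets produced by posterior-sampling observers
(defaults 500 chains of 20 iterations with uniform seeds), and binomial
2AFC same/shifted datasets (default 20 responses per probe and condition).

Randomness flows from a single top-level seed: ``numpy.random.SeedSequence``
spawns one child per chain / probe, so any subset is independently
reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .chains import ChainDataset, ChainRecord, posterior_matrix
from .discrimination import DiscriminationPredictor, TwoAFCDataset
from .grids import DensityField, DomainError, Grid, normalize
from .observers import Observer, build_likelihood, observer_is_bayesian

__all__ = [
    "make_mixture_prior",
    "make_shape_prior",
    "make_shape_image",
    "simulate_experiment",
    "simulate_2afc",
    "SHAPES",
]

SHAPES = ("circle", "triangle", "square", "pentagon")

DEFAULT_N_CHAINS = 500
DEFAULT_N_ITER = 20
DEFAULT_N_PER_POINT = 20


def make_mixture_prior(modes, grid: Grid, background: float = 0.0) -> DensityField:
    """Gaussian-mixture prior from (center, covariance, weight) triples.

    Covariances may be scalars (isotropic), vectors (diagonal), or full
    matrices; weights must be positive.  ``background`` mixes in that
    fraction of uniform mass, mimicking the broad support of empirically
    estimated priors (landmarks sit on a nonzero floor rather than on
    vanishing Gaussian tails).
    """
    if not 0.0 <= background < 1.0:
        raise DomainError("background fraction must lie in [0, 1)")
    total = np.zeros(grid.n_cells)
    centers = grid.centers
    d = grid.ndim
    for center, cov, weight in modes:
        if weight <= 0:
            raise DomainError("mode weights must be positive")
        mu = np.asarray(center, dtype=float).reshape(d)
        cov = np.asarray(cov, dtype=float)
        if cov.ndim == 0:
            cov = float(cov) * np.eye(d)
        elif cov.ndim == 1:
            cov = np.diag(cov)
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise DomainError("mode covariance must be positive-definite") from exc
        diff = centers - mu[None, :]
        sol = np.linalg.solve(chol, diff.T)
        maha = (sol**2).sum(axis=0)
        det = np.prod(np.diag(chol)) ** 2
        total += weight * np.exp(-0.5 * maha) / np.sqrt((2 * np.pi) ** d * det)
    if background > 0:
        tot = total.sum()
        if tot <= 0:
            raise DomainError("mixture has no mass on the grid")
        total = (1.0 - background) * total / tot + background / grid.n_cells
    return normalize(total, grid)


def _shape_vertices(shape: str, center=(0.5, 0.5), circumradius: float = 0.35) -> np.ndarray:
    n = {"triangle": 3, "square": 4, "pentagon": 5}[shape]
    # vertex at the top; square rotated to sit axis-aligned
    phase = np.pi / 2 + (np.pi / n if shape == "square" else 0.0)
    ang = phase + 2 * np.pi * np.arange(n) / n
    return np.stack(
        [center[0] + circumradius * np.cos(ang), center[1] + circumradius * np.sin(ang)],
        axis=1,
    )


def _segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    t = np.clip(((points - a) @ ab) / (ab @ ab), 0.0, 1.0)
    proj = a[None, :] + t[:, None] * ab[None, :]
    return np.linalg.norm(points - proj, axis=1)


def make_shape_prior(
    shape: str,
    grid: Grid,
    edge_weight: float = 1.0,
    vertex_weight: float = 1.0,
    width: float = 0.02,
    center=(0.5, 0.5),
    circumradius: float = 0.35,
) -> DensityField:
    """Prior with Gaussian ridges along a shape's edges and bumps at vertices.

    Emulates the multimodal structure of shape-stimulus priors (mass pulled
    to edges and corners).  ``width`` is the ridge/bump SD in normalized
    units.
    """
    if shape not in SHAPES:
        raise ValueError(f"unknown shape {shape!r}; choose from {SHAPES}")
    if edge_weight < 0 or vertex_weight < 0 or edge_weight + vertex_weight == 0:
        raise DomainError("edge/vertex weights must be nonnegative, not both zero")
    centers = grid.centers
    total = np.zeros(grid.n_cells)
    if shape == "circle":
        r = np.linalg.norm(centers - np.asarray(center)[None, :], axis=1)
        total += edge_weight * np.exp(-0.5 * (r - circumradius) ** 2 / width**2)
    else:
        verts = _shape_vertices(shape, center, circumradius)
        n = len(verts)
        if edge_weight > 0:
            dmin = np.min(
                [
                    _segment_distance(centers, verts[i], verts[(i + 1) % n])
                    for i in range(n)
                ],
                axis=0,
            )
            total += edge_weight * np.exp(-0.5 * dmin**2 / width**2)
        if vertex_weight > 0:
            for v in verts:
                d2 = ((centers - v[None, :]) ** 2).sum(axis=1)
                total += vertex_weight * np.exp(-0.5 * d2 / width**2)
    return normalize(total, grid)


def make_shape_image(shape: str, size_px: int = 256) -> np.ndarray:
    """Binary-outline grayscale raster of a shape (1 = outline, 0 = ground).

    Image convention: row 0 is the top of the image; the shape is centered
    with circumradius 0.35 of the image size.
    """
    from skimage.draw import circle_perimeter, polygon_perimeter

    if shape not in SHAPES:
        raise ValueError(f"unknown shape {shape!r}; choose from {SHAPES}")
    if size_px < 32:
        raise ValueError("size_px must be >= 32")
    img = np.zeros((size_px, size_px), dtype=float)
    if shape == "circle":
        rr, cc = circle_perimeter(
            size_px // 2, size_px // 2, int(round(0.35 * size_px)), shape=img.shape
        )
    else:
        verts = _shape_vertices(shape)
        rows = (1.0 - verts[:, 1]) * size_px  # y up -> row down
        cols = verts[:, 0] * size_px
        rr, cc = polygon_perimeter(rows, cols, shape=img.shape)
    img[rr, cc] = 1.0
    return img


def _child_seeds(rng_seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(rng_seed).spawn(n)


def simulate_experiment(
    prior: DensityField,
    observer: Observer,
    n_chains: int = DEFAULT_N_CHAINS,
    n_iter: int = DEFAULT_N_ITER,
    rng_seed: int = 0,
    dummy_every: int | None = None,
    carryover: float = 0.0,
    stimulus_id: str = "synthetic",
) -> ChainDataset:
    """Simulate a full transmission-chain experiment.

    Seeds are drawn uniformly over the domain; each chain is advanced by
    posterior sampling for Bayesian observers (fixed, efficient) or by
    direct symmetric-noise sampling for the symmetric variable-precision
    observer.  ``dummy_every=k`` inserts a uniform dummy trial after every
    ``k`` real iterations (flagged, not fed back into the chain);
    ``carryover`` injects a synthetic Markov violation: each response is
    pulled toward the previous trial's stimulus by that fraction.
    """
    grid = prior.grid
    likelihood = build_likelihood(observer, grid)
    bayes = observer_is_bayesian(observer)
    cum_like = np.cumsum(likelihood.matrix, axis=1)
    cum_post = (
        np.cumsum(posterior_matrix(prior, likelihood), axis=1) if bayes else None
    )
    chains = []
    for cid, ss in enumerate(_child_seeds(rng_seed, n_chains)):
        rng = np.random.default_rng(ss)
        seed_pt = rng.random(grid.ndim)
        s = grid.point_to_cell(seed_pt)
        cells = [s]
        flags = [False]
        prev_stim_center = grid.centers[s]
        real_steps = 0
        while real_steps < n_iter:
            make_dummy = (
                dummy_every is not None
                and real_steps > 0
                and real_steps % dummy_every == 0
                and not flags[-1]
            )
            stim = (
                int(grid.points_to_cells(rng.random(grid.ndim)[None, :])[0])
                if make_dummy
                else cells[-1]
            )
            t = int(np.searchsorted(cum_like[stim], rng.random(), side="right"))
            r = (
                int(np.searchsorted(cum_post[t], rng.random(), side="right"))
                if bayes
                else t
            )
            if carryover > 0:
                pulled = (1 - carryover) * grid.centers[r] + carryover * prev_stim_center
                r = grid.point_to_cell(pulled)
            prev_stim_center = grid.centers[stim]
            cells.append(r)
            flags.append(make_dummy)
            if not make_dummy:
                real_steps += 1
        chains.append(
            ChainRecord(
                chain_id=cid,
                points=grid.centers[np.array(cells)],
                rng_seed=cid,  # spawn index under the dataset-level rng_seed
                is_dummy=np.array(flags),
            )
        )
    return ChainDataset(
        chains=chains,
        stimulus_id=stimulus_id,
        provenance="simulated",
        metadata={
            "rng_seed": int(rng_seed),
            "n_chains": n_chains,
            "n_iter": n_iter,
            "observer": type(observer).__name__,
            "dummy_every": dummy_every,
            "carryover": carryover,
        },
    )


def simulate_2afc(
    prior: DensityField,
    observer: Observer,
    probe_grid: Grid,
    radius: float,
    n_per_point: int = DEFAULT_N_PER_POINT,
    rng_seed: int = 0,
    n_dir: int = 8,
) -> TwoAFCDataset:
    """Simulate same/shifted 2AFC responses from an observer model.

    The generating d' at each probe is the model's predicted map value
    (mean |d'| over ``n_dir`` offset directions at ``radius``); responses
    follow the equal-variance signal-detection model with unbiased
    criterion: P("shifted" | shifted) = Phi(d'/2), P("shifted" | same) =
    Phi(-d'/2).  Edge probes dropped from the predicted map yield no trials.
    """
    likelihood = build_likelihood(observer, prior.grid)
    pred = DiscriminationPredictor(prior, likelihood)
    dmap = pred.dprime_map(probe_grid, radius, n_dir=n_dir)
    rows = []
    probes = probe_grid.centers
    keep = np.flatnonzero(dmap.retained)
    for k, ss in zip(keep, _child_seeds(rng_seed, len(keep))):
        rng = np.random.default_rng(ss)
        d = dmap.values[k]
        p_hit = norm.cdf(d / 2.0)
        p_fa = norm.cdf(-d / 2.0)
        for cond, p_shift_resp in (("shifted", p_hit), ("same", p_fa)):
            resp = rng.random(n_per_point) < p_shift_resp
            for r in resp:
                rows.append(
                    {
                        "probe_x": probes[k, 0],
                        **(
                            {"probe_y": probes[k, 1]}
                            if probe_grid.ndim == 2
                            else {}
                        ),
                        "condition": cond,
                        "response": "shifted" if r else "same",
                    }
                )
    frame = pd.DataFrame(rows)
    return TwoAFCDataset(
        frame=frame,
        radius=radius,
        metadata={
            "rng_seed": int(rng_seed),
            "n_per_point": n_per_point,
            "observer": type(observer).__name__,
            "generating_map": dmap,
        },
    )
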