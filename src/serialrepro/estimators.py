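"""Prior estimation from chain data, and the category adjustment model (CAM).

Two kernel density recipes estimate the prior from transmission chains:

* nonparametric: one Gaussian component per chain, centered on the chain's
  response mean with the chain's regularized covariance ``Sigma + lambda^2 I``
  (all response iterations used; defaults lambda = 0.015 for shape stimuli,
  0.020 for natural images);
* parametric: fixed-width isotropic kernels on the last-iteration points
  (defaults 0.025 for shapes, 0.040 for natural images).

The CAM is the classical descriptive baseline: a reproduction interpolates
between the stimulus and softmax-weighted prototypes,

    R = w S + (1 - w) sum_k v_k P_k,
    v_k = exp(-c ||S - P_k||) / sum_k' exp(-c ||S - P_k'||),

with memory weight ``w`` and sensitivity ``c``.  ``cam_fit`` estimates the
parameters from seed/response pairs by multi-start bound-constrained least
squares; ``cam_iterate`` exposes the fixed-point dynamics that make the
prototypes attractors of iterated reproduction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import multivariate_normal

from .chains import ChainDataset
from .grids import DensityField, DomainError, Grid, normalize

__all__ = [
    "KDEConfig",
    "CAMParams",
    "DEFAULT_LAMBDA",
    "DEFAULT_KERNEL_WIDTH",
    "kde_nonparametric",
    "kde_parametric",
    "cam_predict",
    "cam_fit",
    "cam_iterate",
]

# regularizer / kernel width defaults per stimulus class (normalized units)
DEFAULT_LAMBDA = {"shape": 0.015, "natural": 0.020}
DEFAULT_KERNEL_WIDTH = {"shape": 0.025, "natural": 0.040}


@dataclass(frozen=True)
class KDEConfig:
    """Configuration for the two KDE recipes.

    ``lambda_reg`` regularizes per-chain covariances (nonparametric mode);
    ``kernel_width`` is the isotropic SD of last-iteration kernels
    (parametric mode).  Both are in normalized image units.
    """

    mode: str = "parametric"
    lambda_reg: float = DEFAULT_LAMBDA["shape"]
    kernel_width: float = DEFAULT_KERNEL_WIDTH["shape"]
    grid: Grid = field(default_factory=lambda: Grid((64, 64)))

    def __post_init__(self) -> None:
        if self.mode not in ("parametric", "nonparametric"):
            raise ValueError(f"unknown KDE mode {self.mode!r}")
        if self.lambda_reg <= 0 or self.kernel_width <= 0:
            raise ValueError("lambda_reg and kernel_width must be > 0")

    @classmethod
    def for_stimulus(cls, stimulus_class: str, mode: str = "parametric", **kw) -> "KDEConfig":
        """Defaults keyed by stimulus class ('shape' or 'natural')."""
        return cls(
            mode=mode,
            lambda_reg=DEFAULT_LAMBDA[stimulus_class],
            kernel_width=DEFAULT_KERNEL_WIDTH[stimulus_class],
            **kw,
        )


def _clip_points(points: np.ndarray) -> np.ndarray:
    if np.any(points < 0) or np.any(points > 1):
        import warnings

        warnings.warn("points outside [0,1] clipped to the domain", stacklevel=3)
        return np.clip(points, 0.0, 1.0)
    return points


def _mixture_on_grid(
    grid: Grid, means: np.ndarray, covs: np.ndarray
) -> DensityField:
    """Equal-weight Gaussian mixture evaluated at cell centers, normalized."""
    total = np.zeros(grid.n_cells)
    centers = grid.centers
    for mu, cov in zip(means, covs):
        total += multivariate_normal.pdf(
            centers, mean=mu, cov=cov, allow_singular=False
        ).reshape(-1)
    return normalize(total, grid)


def kde_nonparametric(dataset: ChainDataset, config: KDEConfig) -> DensityField:
    """Per-chain regularized-covariance mixture estimate of the prior.

    Every chain contributes one Gaussian with its response mean ``mu_i`` and
    covariance ``Sigma_i + lambda^2 I`` over all iterations >= 1; a
    single-point chain degenerates gracefully to an isotropic kernel of SD
    lambda.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    d = dataset.ndim
    lam2 = config.lambda_reg**2
    means, covs = [], []
    for c in dataset.chains:
        pts = _clip_points(c.points[1:])
        if c.is_dummy is not None:
            pts = pts[~c.is_dummy[1:]]
        if pts.shape[0] == 0:
            raise ValueError(f"chain {c.chain_id} has no responses")
        mu = pts.mean(axis=0)
        if pts.shape[0] > 1:
            cov = np.cov(pts, rowvar=False).reshape(d, d)
        else:
            cov = np.zeros((d, d))
        means.append(mu)
        covs.append(cov + lam2 * np.eye(d))
    return _mixture_on_grid(config.grid, np.array(means), np.array(covs))


def kde_parametric(dataset: ChainDataset, config: KDEConfig) -> DensityField:
    """Fixed-width isotropic KDE on the last-iteration points of each chain."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    d = dataset.ndim
    pts = _clip_points(
        np.array([c.points[c.n_iterations] for c in dataset.chains])
    )
    cov = config.kernel_width**2 * np.eye(d)
    return _mixture_on_grid(config.grid, pts, np.broadcast_to(cov, (len(pts), d, d)))


# ---------------------------------------------------------------------------
# Category adjustment model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CAMParams:
    """CAM parameters: memory weight, sensitivity, prototypes, optional noise."""

    w: float
    c: float
    prototypes: np.ndarray
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        protos = np.atleast_2d(np.asarray(self.prototypes, dtype=float))
        object.__setattr__(self, "prototypes", protos)
        if not 0.0 <= self.w <= 1.0:
            raise DomainError("w must lie in [0, 1]")
        if self.c <= 0:
            raise DomainError("c must be > 0")
        if np.any(protos < 0) or np.any(protos > 1):
            raise DomainError("prototypes must lie in the unit domain")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")

    @property
    def n_prototypes(self) -> int:
        return self.prototypes.shape[0]


def _cam_pull(points: np.ndarray, params: CAMParams) -> np.ndarray:
    """Softmax-weighted prototype pull ``sum_k v_k P_k`` for each point."""
    dists = np.linalg.norm(
        points[:, None, :] - params.prototypes[None, :, :], axis=-1
    )
    logits = -params.c * dists
    logits -= logits.max(axis=1, keepdims=True)
    v = np.exp(logits)
    v /= v.sum(axis=1, keepdims=True)
    return v @ params.prototypes


def cam_predict(s, params: CAMParams):
    """Noise-free CAM reproduction ``w s + (1 - w) sum_k v_k P_k``."""
    pts = np.asarray(s, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    out = params.w * pts + (1.0 - params.w) * _cam_pull(pts, params)
    return out[0] if single else out


def cam_iterate(
    params: CAMParams, start, n_iter: int, rng_seed: int | None = None
) -> np.ndarray:
    """Trajectory of repeated CAM reproduction from ``start``.

    With a single prototype and no noise the distance to the prototype
    contracts by exactly ``w`` per step.  If ``params.noise_sd > 0`` and a
    seed is given, isotropic Gaussian noise is added each step (clipped to
    the domain).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(rng_seed) if rng_seed is not None else None
    p = np.asarray(start, dtype=float).reshape(1, -1)
    traj = [p[0].copy()]
    for _ in range(n_iter):
        p = params.w * p + (1.0 - params.w) * _cam_pull(p, params)
        if params.noise_sd > 0 and rng is not None:
            p = np.clip(p + rng.normal(0, params.noise_sd, size=p.shape), 0.0, 1.0)
        traj.append(p[0].copy())
    return np.array(traj)


def _cam_loss(theta: np.ndarray, seeds: np.ndarray, responses: np.ndarray, m: int, d: int) -> float:
    w, c = theta[0], theta[1]
    protos = theta[2:].reshape(m, d)
    params = CAMParams(w=w, c=max(c, 1e-9), prototypes=np.clip(protos, 0, 1))
    pred = params.w * seeds + (1.0 - params.w) * _cam_pull(seeds, params)
    return float(np.mean((pred - responses) ** 2))


def cam_fit(
    seeds,
    responses,
    m: int,
    n_restarts: int = 20,
    rng_seed: int = 0,
) -> tuple[CAMParams, float]:
    """Fit CAM parameters to seed/response pairs by multi-start optimization.

    Minimizes mean squared prediction error over ``(w, c, P_1..P_M)`` with
    box constraints (``0 <= w <= 1``, ``c > 0``, prototypes in the domain)
    using L-BFGS-B.  Restarts initialize prototypes from k-means on the
    responses plus seeded random jitter; deterministic given ``rng_seed``.
    Returns the best parameters and their loss.
    """
    from sklearn.cluster import KMeans

    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    responses = np.atleast_2d(np.asarray(responses, dtype=float))
    if seeds.shape != responses.shape:
        raise ValueError("seeds and responses must have matching shapes")
    n, d = seeds.shape
    if m < 1 or m > n:
        raise ValueError(f"M={m} prototypes not identifiable from {n} pairs")
    rng = np.random.default_rng(rng_seed)
    km = KMeans(n_clusters=m, n_init=5, random_state=int(rng.integers(2**31)))
    km_centers = km.fit(responses).cluster_centers_.clip(0, 1)

    bounds = [(0.0, 1.0), (1e-3, 1e3)] + [(0.0, 1.0)] * (m * d)
    best_theta, best_loss = None, np.inf
    for k in range(n_restarts):
        if k == 0:
            protos0 = km_centers
        else:
            protos0 = np.clip(
                km_centers + rng.normal(0, 0.1, size=km_centers.shape), 0, 1
            )
        w0 = rng.uniform(0.2, 0.8)
        c0 = np.exp(rng.uniform(np.log(1.0), np.log(50.0)))
        theta0 = np.concatenate([[w0, c0], protos0.ravel()])
        res = minimize(
            _cam_loss,
            theta0,
            args=(seeds, responses, m, d),
            method="L-BFGS-B",
            bounds=bounds,
        )
        if res.fun < best_loss:
            best_loss, best_theta = float(res.fun), res.x
    params = CAMParams(
        w=float(np.clip(best_theta[0], 0, 1)),
        c=float(best_theta[1]),
        prototypes=np.clip(best_theta[2:].reshape(m, d), 0, 1),
    )
    return params, best_loss
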