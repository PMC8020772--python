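"""Serial-reproduction dynamics on a grid.

A transmission chain is the Markov process ``... -> S_t -> T_t -> R_t =
S_{t+1} -> ...``: the current location ``S_t`` is noisily encoded as ``T_t``
(a draw from the likelihood row), the observer infers the posterior
``p(S | T = t)`` and reproduces a posterior sample ``R_t``, which becomes the
next stimulus.  Marginalizing the latent ``T`` gives the transition kernel

    K(r | s) = sum_t p(R = r | T = t) p(T = t | S = s),

whose stationary distribution is the prior itself: the kernel satisfies
detailed balance ``K(r|s) pi(s) = K(s|r) pi(r)``, so iterating the chain
reveals the observer's prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import (
    DensityField,
    DegenerateDensityError,
    DomainError,
    Grid,
    ShapeMismatchError,
    normalize,
)
from .observers import LikelihoodMatrix

__all__ = [
    "TransitionKernel",
    "ChainRecord",
    "ChainDataset",
    "posterior",
    "posterior_matrix",
    "transition_kernel",
    "propagate",
    "sample_chain",
    "markov_dummy_check",
]


@dataclass(frozen=True)
class TransitionKernel:
    """Row-stochastic matrix ``p(S_{n+1} = r | S_n = s)`` indexed (s, r)."""

    grid: Grid
    matrix: np.ndarray

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", mat)
        n = self.grid.n_cells
        if mat.shape != (n, n):
            raise ShapeMismatchError(f"kernel shape {mat.shape} for {n} cells")
        if np.any(mat < 0):
            raise DomainError("negative kernel entries")
        if not np.allclose(mat.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("kernel rows must each sum to 1")


@dataclass
class ChainRecord:
    """One transmission chain: seed point plus ordered reproductions.

    ``points`` has shape ``(n_iter + 1, ndim)``; row 0 is the seed ``S_0``
    and row ``t`` is the reproduction ``R_t``.  ``is_dummy[t]`` flags trials
    whose stimulus was a fresh uniform point rather than the previous
    response (used for Markov-assumption checks).
    """

    chain_id: int
    points: np.ndarray
    rng_seed: int | None = None
    is_dummy: np.ndarray | None = None
    latent_cells: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if np.any(self.points < 0) or np.any(self.points > 1):
            raise DomainError("chain points outside the unit domain")
        if self.is_dummy is not None:
            self.is_dummy = np.asarray(self.is_dummy, dtype=bool)
            if self.is_dummy.shape[0] != self.points.shape[0]:
                raise ShapeMismatchError("is_dummy length differs from points")

    @property
    def n_iterations(self) -> int:
        return self.points.shape[0] - 1

    @property
    def seed_point(self) -> np.ndarray:
        return self.points[0]

    def iteration(self, t: int) -> np.ndarray:
        if not 0 <= t <= self.n_iterations:
            raise IndexError(f"iteration {t} not in 0..{self.n_iterations}")
        return self.points[t]


@dataclass
class ChainDataset:
    """A collection of chains sharing one stimulus and coordinate convention."""

    chains: list[ChainRecord]
    stimulus_id: str = "synthetic"
    provenance: str = "simulated"
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.chains)

    @property
    def ndim(self) -> int:
        return self.chains[0].points.shape[1]

    def iteration_points(self, t: int, include_dummy: bool = False) -> np.ndarray:
        """Stack of iteration-``t`` points across chains that reach ``t``."""
        rows = []
        for c in self.chains:
            if c.n_iterations >= t:
                if not include_dummy and c.is_dummy is not None and c.is_dummy[t]:
                    continue
                rows.append(c.points[t])
        if not rows:
            raise ValueError(f"no chain reaches iteration {t}")
        return np.array(rows)

    def response_points(self, include_dummy: bool = False) -> np.ndarray:
        """All responses (iterations >= 1) across chains."""
        rows = []
        for c in self.chains:
            pts = c.points[1:]
            if not include_dummy and c.is_dummy is not None:
                pts = pts[~c.is_dummy[1:]]
            rows.append(pts)
        return np.concatenate(rows, axis=0)


# ---------------------------------------------------------------------------
# Inference and kernel
# ---------------------------------------------------------------------------


def posterior(
    prior: DensityField, likelihood: LikelihoodMatrix, t_cell: int
) -> DensityField:
    """Posterior ``p(S = r | T = t) ∝ p(T = t | S = r) p(S = r)``."""
    if prior.grid != likelihood.grid:
        raise ShapeMismatchError("prior and likelihood grids differ")
    evidence = likelihood.matrix[:, t_cell] * prior.mass
    total = evidence.sum()
    if total <= 0:
        raise DegenerateDensityError(
            f"zero evidence for observation cell {t_cell} (prior orthogonal "
            "to the likelihood column)"
        )
    return DensityField(prior.grid, evidence / total)


def posterior_matrix(prior: DensityField, likelihood: LikelihoodMatrix) -> np.ndarray:
    """All posteriors stacked: entry ``(t, r)`` is ``p(S = r | T = t)``."""
    if prior.grid != likelihood.grid:
        raise ShapeMismatchError("prior and likelihood grids differ")
    ev = likelihood.matrix.T * prior.mass[None, :]  # (t, r)
    z = ev.sum(axis=1)
    if np.any(z <= 0):
        bad = int(np.argmin(z))
        raise DegenerateDensityError(f"zero evidence for observation cell {bad}")
    return ev / z[:, None]


def transition_kernel(
    prior: DensityField, likelihood: LikelihoodMatrix
) -> TransitionKernel:
    """Chain transition kernel ``K(r|s) = sum_t p(S=r|T=t) p(T=t|S=s)``."""
    post = posterior_matrix(prior, likelihood)  # (t, r)
    return TransitionKernel(prior.grid, likelihood.matrix @ post)


def propagate(
    kernel: TransitionKernel, start: DensityField, n_iter: int
) -> list[DensityField]:
    """Analytic iterates ``p(S_1) ... p(S_n)`` from ``p(S_0) = start``."""
    if kernel.grid != start.grid:
        raise ShapeMismatchError("kernel and start grids differ")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    out: list[DensityField] = []
    p = start.mass
    for _ in range(n_iter):
        p = p @ kernel.matrix
        out.append(normalize(p, kernel.grid))
        p = out[-1].mass
    return out


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def _sample_rows(cum_rows: np.ndarray, row: int, rng: np.random.Generator) -> int:
    return int(np.searchsorted(cum_rows[row], rng.random(), side="right"))


def sample_chain(
    prior: DensityField,
    likelihood: LikelihoodMatrix,
    seed_point,
    n_iter: int,
    rng_seed: int,
    chain_id: int = 0,
    bayesian: bool = True,
    log_latent: bool = False,
) -> ChainRecord:
    """Simulate one chain of ``n_iter`` reproductions from ``seed_point``.

    Each step draws the latent observation ``T`` from the likelihood row of
    the current cell, then (``bayesian=True``, the posterior-sampling rule)
    draws the reproduction from the posterior given ``T``; with
    ``bayesian=False`` the reproduction is ``T`` itself, i.e. an independent
    symmetric noise sample around the stimulus, as in the symmetric
    variable-precision model.  Deterministic given ``rng_seed``; points are
    snapped to grid cells and reported as cell centers.
    """
    grid = prior.grid
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    cum_like = np.cumsum(likelihood.matrix, axis=1)
    cum_post = np.cumsum(posterior_matrix(prior, likelihood), axis=1) if bayesian else None
    rng = np.random.default_rng(rng_seed)
    s = grid.point_to_cell(seed_point)
    cells = [s]
    latents = []
    for _ in range(n_iter):
        t = _sample_rows(cum_like, cells[-1], rng)
        latents.append(t)
        r = _sample_rows(cum_post, t, rng) if bayesian else t
        cells.append(r)
    points = grid.centers[np.array(cells)]
    return ChainRecord(
        chain_id=chain_id,
        points=points,
        rng_seed=int(rng_seed),
        latent_cells=np.array(latents) if log_latent else None,
    )


# ---------------------------------------------------------------------------
# Markov-assumption diagnostic
# ---------------------------------------------------------------------------


def markov_dummy_check(
    dataset: ChainDataset,
    control: ChainDataset,
    kernel_width: float = 0.04,
    grid: Grid | None = None,
) -> dict:
    """Compare chains run with interleaved uniform dummy trials to controls.

    ``dataset`` must flag dummy trials; ``control`` is a matched simulation
    without dummies.  Returns the Pearson correlation between fixed-width
    KDEs of the two final-iteration response sets.  Under the Markov
    assumption dummy trials are inert and the correlation is ~1; an observer
    with trial-to-trial carry-over degrades it.
    """
    from .estimators import KDEConfig, kde_parametric

    has_flags = any(c.is_dummy is not None and c.is_dummy.any() for c in dataset.chains)
    if not has_flags:
        raise ValueError("dataset has no dummy-trial flags; nothing to compare")
    if grid is None:
        grid = Grid((64,) * dataset.ndim)
    cfg = KDEConfig(mode="parametric", kernel_width=kernel_width, grid=grid)
    kde_dummy = kde_parametric(dataset, cfg)
    kde_control = kde_parametric(control, cfg)
    a, b = kde_dummy.mass, kde_control.mass
    r = float(np.corrcoef(a, b)[0, 1])
    return {
        "kde_correlation": r,
        "n_chains_dummy": len(dataset),
        "n_chains_control": len(control),
        "kernel_width": kernel_width,
    }
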