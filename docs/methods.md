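# Methods

## The model

A remembered point location is modeled as a three-stage process on an image
whose coordinates are normalized to the unit interval/square ("fraction of
an image of size 1"): a true location `S` is noisily encoded as `T`
(likelihood `p(T|S)`), the observer infers `S` by Bayes' rule against a
shared spatial prior `π(s) = p(S = s)`, and the reproduction `R` is a sample
from the posterior `p(S|T)`.  In a serial-reproduction (transmission-chain)
experiment each reproduction becomes the next stimulus,

    ... -> S_t -> T_t -> R_t = S_{t+1} -> ...,

and marginalizing the latent `T` gives the transition kernel

    K(r|s) = ∫ p(R = r | T = t) p(T = t | S = s) dt.

Substituting the posterior for `p(R|T)` shows that `K(r|s) π(s)` is
symmetric in `(r, s)` — the chain is reversible with stationary distribution
`π` — so iterating the task reveals the observer's prior, whatever the
likelihood.  The package makes this executable: `transition_kernel` builds
`K` on a grid, and the stationarity / detailed-balance identities are
asserted numerically (L1 ≤ 1e-8, max flux asymmetry ≤ 1e-10) for all three
encoders on random priors.

All probability objects are discrete masses per grid cell (default 256
cells in 1D, 64×64 in 2D; 32×32 in the heavier 2D analyses to keep the
N²×N² likelihood matrices small).  Integrals become sums; continuous
points snap to the nearest cell center, ties breaking toward the lower
index.

## The three encoders

* **Fixed precision** — isotropic Gaussian rows of constant SD `sigma`,
  truncated to the domain and renormalized (no reflection).  The classical
  assumption behind the category-adjustment account; predicts *lower*
  discriminability near landmarks (perceptual magnet).
* **Symmetric variable precision** — isotropic Gaussian rows with local SD
  `sigma0 · d(x)^(−alpha)`, `d` the prior density.  `alpha` defaults to 1
  in 1D and 1/2 in 2D so the local precision matches the efficient
  encoder's and the two models differ only in bias structure.  When this
  observer is *simulated*, responses are draws from its likelihood row
  (symmetric noise around the stimulus, unbiased on average), not posterior
  samples — that is the defining feature of the model.
* **Efficient encoding** — constant Gaussian noise of SD `sigma_w` in a
  warped coordinate system in which the prior is uniform.  The warp is the
  triangular (Knothe–Rosenblatt) rearrangement: the 1D CDF of the prior,
  or marginal-CDF-then-conditional-CDF in 2D, evaluated as a piecewise
  linear function of the per-cell masses (cell centers map to "mass below
  plus half own mass", so a uniform prior warps to the identity).  Row `i`
  of the likelihood is the Gaussian evaluated at the warped cell centers,
  renormalized over cells.  Dense prior regions are dilated in warped
  space, so Euclidean noise is small near landmarks and skewed: the long
  Euclidean tail of a row near a landmark points *away* from it into the
  sparse (dilated) region, while the row's peak stays at the stimulus.
  Attraction toward landmarks is a chain-level phenomenon — iterates of
  `K` concentrate on the modes of `π` — not a property of a single row's
  mean.

The conditional-CDF step of the 2D warp uses the axis-0 cell containing
the point; a prior floor of 1e-12 mass per cell (renormalized) keeps
conditionals well defined.  The triangular construction is one concrete
choice of prior-uniformizing map; it reduces to the standard 1D CDF warp
and makes "constant precision in warped coordinates" fully computable, but
other area-preserving rearrangements exist and would differ in detail.

## Discrimination (d′) maps

Predicted sensitivity between two locations uses the signal-detection form

    d(S1, S2) = (μ̃(S1) − μ̃(S2)) / sqrt((σ̃²(S1) + σ̃²(S2)) / 2),

with `μ̃, σ̃²` the mean and variance of the reproduction distribution
`p(R|S)` (a row of `K`).  In 2D both distributions are projected onto the
line through the two points (avoiding full 2D signal detection theory);
the projection axis carries a canonical orientation so the statistic is
antisymmetric in its arguments.  A map averages `|d′|` over 8 equally
spaced offset directions at a configurable radius (default 0.05, i.e.
clearly above one cell spacing; the paper's task used a 6-pixel offset,
whose normalized size depends on unstated display dimensions).  Probes
whose offset would leave the image are dropped, and map–prior correlations
exclude a 2-cell border, because boundary truncation distorts the fixed
model's predictions at the edge.

Empirical d′ is `z(hit rate) − z(false-alarm rate)` from same/shifted 2AFC
counts, with the 1/(2N) correction for rates of 0 or 1.  Simulated 2AFC
responses use the equal-variance SDT model with unbiased criterion
(`P("shifted"|shifted) = Φ(d′/2)`, `P("shifted"|same) = Φ(−d′/2)`); the
paper specifies no response model and this is the standard companion to
its d′ analysis.  Smoothing of empirical maps is Gaussian (NaN-aware
normalized convolution, SD in probe-grid steps, default 1) followed by
cubic interpolation to a finer grid.

## Prior estimation and the CAM baseline

Two KDE recipes estimate `π` from chains.  The nonparametric recipe fits
one Gaussian per chain: mean and covariance of the chain's responses (all
iterations ≥ 1; the seed is a stimulus, not a response), covariance
regularized as `Σ + λ²I` with `λ = 0.015` for shape stimuli and `0.020`
for natural images; the estimate is the equal-weight mixture.  The
parametric recipe places fixed-width isotropic kernels (0.025 shapes,
0.040 natural) on the last-iteration points.  Both are evaluated on the
grid and normalized.

The category adjustment model is the descriptive baseline:
`R = wS + (1−w) Σ_k v_k P_k` with `v_k` a softmax over `−c‖S − P_k‖`.
`cam_fit` minimizes mean squared prediction error over `(w, c, P_1..P_M)`
with box constraints by L-BFGS-B, multi-started from k-means centers of
the responses plus seeded jitter (default 20 restarts).  Prototype
recovery is scored after optimal assignment (label permutations are
unidentifiable).  Noise-free single-prototype iteration contracts the
distance to the prototype by exactly `w` per step, which the tests assert
to machine precision.

## Bias statistics

Single-trial biases `R_t − S_{t−1}` are averaged in spatial bins of 0.025;
the angular-coherence statistic takes all pairs of occupied bins within
radius 0.05 and measures the probability that their average bias vectors
differ in direction by at most ±12°, relative to the uniform expectation
24/360.  Two analysis conditions matter and are defaults of the band-ratio
statistic:

* trials whose stimulus lies within 0.1 of the image boundary are
  excluded — truncating response noise at the border pulls responses
  inward along the whole edge, a coherent artifact produced by *every*
  encoder;
* coherence simulations run on a 64×64 grid — on coarser grids the
  snapping of responses to cell centers quantizes bias vectors into few
  discrete directions, and exact angular ties inflate the small-angle band
  even under the symmetric (null) observer.

Bootstrap confidence intervals resample whole chains with replacement
(1000 replicates, percentile CI), respecting within-chain dependence.
Uniformity of point sets is tested by chi-square on a regular bin grid
(bins coarsened until expected counts reach 5).  Disattenuation divides an
observed correlation by the square root of the product of the two
measures' reliabilities, capped to [−1, 1].  The center-of-mass baseline
converts a labeled segmentation raster into a mixture of Gaussian bumps at
region centroids.

## Synthetic study conditions

The generator reproduces the study's design parameters: 500 chains of 20
iterations with uniform random seeds, and 20 2AFC responses per probe and
condition.  One top-level seed expands to per-chain/per-probe children via
`numpy.random.SeedSequence.spawn`, so any subset is reproducible in
isolation.

The default 2D study prior is three isotropic Gaussian landmarks
(SD 0.063) on a 25% uniform background.  The background matters: priors
estimated from data have broad support, whereas a pure Gaussian mixture
has tails whose log-density gradient grows without bound, which under the
fixed encoder collapses the entire background onto the landmarks and
reverses the predicted negative d′–prior correlation.  Noise sweeps stay
in the regime where sensory noise is smaller than the landmark scale
(fixed: σ ∈ [0.02, 0.08]; efficient: σ_w ∈ [0.04, 0.16] warped units);
when noise exceeds the landmark scale both encoders merge all structure
and the model comparison is uninformative.

What the generator does *not* emulate: participant heterogeneity (one
shared prior generates every chain), lapses and response biases,
reproduction-stage motor noise (deliberately omitted, matching the
modeling assumption that biases arise at encoding), non-Markov carry-over
(available only as an explicit synthetic violation for the dummy-trial
diagnostic), and anything image-computable — priors are specified
directly rather than derived from pixels.  Passing tests therefore
establish internal consistency of the method and estimators under the
model's own assumptions, not that human data would satisfy them.

## Numerical choices and limitations

* Likelihood rows always contain their diagonal element (weight 1 before
  normalization), so rows cannot underflow to zero for any positive sigma.
* Density fields validate nonnegativity and unit mass at 1e-9; kernel and
  likelihood rows at 1e-9; KL values within 1e-12 below zero are clamped
  to zero (pure rounding).
* `point_to_cell` uses half-open cells with a downward nudge, making the
  midway tie break toward the lower index deterministically.
* Chains operate on cells; reported chain points are cell centers.  At
  32×32 this quantization is visible in direction-sensitive statistics
  (see the coherence grid choice above).
* The d′ map evaluates moments at the snapped cells of the two offset
  endpoints; radii must exceed one cell spacing or the two endpoints can
  share a cell.
* `cam_fit` with many prototypes inherits the usual multi-start caveats;
  the nested-model comparison (more prototypes fit better on data
  generated with more modes) holds on simulated data but fit quality at
  fixed `M` is not a substitute for the chain-based estimate, whose
  bootstrap mode variability is smaller in matched-budget comparisons.
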