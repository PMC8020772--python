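# serialrepro

Simulation and analysis of **serial-reproduction (transmission-chain)
experiments** on remembered point locations, for researchers studying
visuospatial memory and perceptual priors.

In a transmission chain, one person views a point on an image, reproduces
its location from memory, and the reproduction becomes the stimulus for the
next person.  If each reproduction is a posterior sample — the observer
noisily encodes the location `S` as `T` with likelihood `p(T|S)` and decodes
it against a shared spatial prior `π(s)` — the chain

    ... → S_t → T_t → R_t = S_{t+1} → ...

is a reversible Markov chain whose stationary distribution is the prior
itself: `K(r|s) = ∫ p(S=r|T=t) p(T=t|S=s) dt` satisfies detailed balance
`K(r|s)π(s) = K(s|r)π(r)`.  Iterating the task therefore *measures* the
prior, and the package builds everything around that fact:

* **Observer models** — three encoders as likelihood matrices on a grid:
  fixed precision (constant isotropic Gaussian noise), symmetric variable
  precision (noise SD shrinks where the prior is dense, unbiased), and
  efficient encoding (constant noise in prior-uniformized, "perceptually
  warped" coordinates, realized by a triangular CDF transform).
* **Chain dynamics** — transition kernels, analytic propagation, sampled
  chains, stationarity/detailed-balance/convergence diagnostics, and a
  dummy-trial check of the Markov assumption.
* **Discrimination maps** — predicted sensitivity
  `d′ = (μ̃₁ − μ̃₂)/√((σ̃₁² + σ̃₂²)/2)` from reproduction moments (2D
  distributions projected onto the line through the probe pair), and
  empirical `d′ = z(hit) − z(false alarm)` from same/shifted 2AFC data.
  The two encoders make opposite predictions: efficient encoding puts
  *high* d′ at the prior's modes, fixed precision puts *low* d′ there.
* **Prior estimators** — the two KDE recipes (per-chain regularized
  covariances on all iterations; fixed-width kernels on last-iteration
  points) and the category adjustment model baseline
  `R = wS + (1−w)Σ_k v_k P_k` with multi-start bound-constrained fitting.
* **Bias statistics** — binned bias fields, the ±12° angular-coherence
  band ratio with chain-level bootstrap CIs, map correlations with edge
  exclusion, disattenuation, chi-square uniformity tests, and a
  center-of-mass baseline prior from segmentation masks.
* **Synthetic experiments** — multimodal priors, shape stimuli, and fully
  seeded simulated chain/2AFC datasets (500 chains × 20 iterations and 20
  responses per probe/condition by default), so the entire pipeline runs
  with no external data.

## Worked example

```python
import serialrepro as sr

grid = sr.Grid((32, 32))
prior = sr.make_mixture_prior(
    [([0.3, 0.35], 0.004, 1.0), ([0.7, 0.4], 0.004, 1.0), ([0.5, 0.75], 0.004, 1.0)],
    grid, background=0.25,
)
observer = sr.EfficientEncodingObserver(prior, sigma_w=0.10)

# simulate the experiment and estimate the prior back from the chains
chains = sr.simulate_experiment(prior, observer, n_chains=500, n_iter=20, rng_seed=1)
kde = sr.kde_parametric(chains, sr.KDEConfig(mode="parametric", kernel_width=0.04, grid=grid))
print("KDE vs true prior r =", round(sr.correlate_maps(prior, kde, exclude_edge=2), 3))

# predicted discrimination maps for the two competing encoders
likelihood = sr.build_likelihood(observer, grid)
dmap = sr.dprime_map_predicted(prior, likelihood, grid, radius=0.05)
print("predicted d' vs prior r =", round(sr.correlate_maps(prior, dmap, exclude_edge=2), 3))

fixed = sr.build_likelihood(sr.FixedPrecisionObserver(0.05), grid)
dmap_fixed = sr.dprime_map_predicted(prior, fixed, grid, radius=0.05)
print("fixed-model d' vs prior r =", round(sr.correlate_maps(prior, dmap_fixed, exclude_edge=2), 3))
```

prints

```
KDE vs true prior r = 0.973
predicted d' vs prior r = 0.867
fixed-model d' vs prior r = -0.509
```

The chains recover the three-landmark prior almost exactly (r = 0.97); the
efficient encoder predicts a d′ map positively correlated with the prior
(high discriminability at the landmarks), while the fixed-precision encoder
predicts the opposite sign — the diagnostic contrast between the two
theories of spatial memory bias.

A command-line interface wraps the same workflows
(`serialrepro simulate-chains|estimate-prior|predict-dprime|analyze-2afc|
fit-cam|bias-stats|model-compare|fixtures`), each driven by a YAML config
plus a single `--seed`, writing its outputs and a `report.json` with the
full effective configuration.

See `docs/methods.md` for the model, its assumptions, all default
parameters, and known limitations.

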