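# Methods

## The problem

Disease-mapping data often exist at two nested administrative scales:
counts on a fine partition (counties) and the same counts aggregated to
a coarse partition (public-health districts), with coarse outcomes
obtained by summing the fine outcomes and coarse covariates by
averaging the fine ones. Aggregation smooths away fine-scale spatial
variation (the *scaling effect*), and a covariate that predicts risk at
one scale may appear not to at the other if the two levels are analysed
separately. `scalemap` fits two Bayesian models to such data — one that
ignores the linkage between scales and one that models it — and
compares them.

## Models

Level k ∈ {1 (fine), 2 (coarse)} has N_k units with outcome counts
y_ik, trial counts n_ik and a standardized covariate x_ik:

    y_ik ~ Binomial(n_ik, p_ik),   logit(p_ik) = η_ik.

**Independent multiscale convolution model** (`kind="independent"`):

    η_ik = β0k + β1k·x_ik + v_ik + ε_ik,   k = 1, 2,

two unlinked convolution (CH + UH) models. **Shared multiscale model**
(`kind="shared"`) adds the parent's coarse spatial effect to every
nested fine unit, with coefficient 1:

    η_i1 = β01 + β11·x_i1 + v_i1 + ε_i1 + v_{parent(i),2},

so the coarse field is common to all fine units it contains and carries
information across the scales.

*Correlated heterogeneity* (CH) v_k follows an intrinsic CAR (ICAR)
prior on the level-k adjacency graph: up to a constant,

    log p(v | σ_v) = −(1/2σ_v²) Σ_{i~j} (v_i − v_j)² − r·log σ_v,

with r the Laplacian rank N − (number of connected components). The
conditional of one unit is Normal(mean of its neighbours, σ_v²/degree).
Units with no neighbours (islands) are excluded from the pairwise sum
and given a proper Normal(0, σ_v²); each therefore contributes its own
quadratic term and one power of 1/σ_v. *Uncorrelated heterogeneity*
(UH) ε_k is iid Normal(0, σ_ε²).

Priors: flat on intercepts, Normal(0, 1000²) on slopes (vague but
proper, standard practice for logit-scale slopes of standardized
covariates), Uniform(0, 100) on all four standard deviations. Because
the flat intercept and the improper ICAR share a translation direction,
each CH vector is recentred to mean zero every sweep with the mean
folded into the intercept(s) — exactly posterior-invariant on a
connected map (and for the shared model the coarse CH mean folds into
*both* intercepts, since the coarse field enters both predictors). The
UH vectors are identified by their proper prior and are not recentred:
recentring them would change the posterior density and bias σ_ε
slightly, so the package deliberately centres only the CH fields.

## Inference

Metropolis-within-Gibbs, organised so every update is vectorised:

* **CH fields**: single-site Metropolis, colour class by colour class of
  a greedy colouring of the adjacency graph (units in one class are
  mutually non-adjacent, so their conditionals do not interact). The
  proposal is the ICAR full conditional itself; prior and proposal
  cancel and the acceptance probability is the binomial likelihood
  ratio. This independence proposal is *not* scale-adapted: an
  independence sampler's acceptance rate is not monotone in its scale,
  so Robbins–Monro tuning toward a fixed target is ill-posed for it
  (shrinking the proposal collapses the reverse-move probability).
* **UH fields**: simultaneous single-site random-walk Metropolis (each
  ε_i touches only unit i's likelihood).
* **Fixed effects**: joint (intercept, slope) random walk per level.
* **Standard deviations**: random walk on log σ with the Jacobian
  correction and rejection outside the Uniform(0, 100) support.

The likelihood pins each unit's η while the split of η between the
fixed effects and the two heterogeneity fields — and between a field
and its σ — is only weakly identified. Four families of auxiliary
posterior-invariant MH moves mix those ridge/funnel directions
directly; all leave the stationary distribution unchanged:

1. *Interweaved scale moves*: rescale a random-effect vector jointly
   with its σ (the non-centred parameterization); in whitened
   coordinates the prior ratio cancels the Jacobian, so the acceptance
   ratio is the likelihood ratio times the log-RW Jacobian.
2. *η-preserving shifts*: trade the intercept (or slope) against the UH
   vector (β += δ, ε −= δ·direction), accepted on the prior ratio.
3. *Slope-vs-CH shifts*: β1 += δ, v −= δ·x, accepted on the ICAR prior
   ratio (plus the slope prior).
4. *CH/UH trades*: per-site v_i += δ_i, ε_i −= δ_i by colour class,
   accepted on the two prior ratios.

In the shared model every move that changes the coarse CH field also
changes the fine-level predictor; all such moves carry the fine-level
likelihood correction.

All random-walk scales adapt by Robbins–Monro during burn-in only
(targets 0.44 single-site, 0.234 for blocks; step 4/(t+10)^0.6) and are
frozen afterwards, so retained draws come from a genuine Markov chain.
Chains initialize at β jittered Normal(0,1) per chain (over-dispersed
starts that make R-hat meaningful), random effects at 0, σ at 1.
Identical seeds reproduce every draw bit-for-bit (per-chain
`SeedSequence` spawning). The default protocol is 3 chains × 30,000
iterations with 15,000 burn-in and no thinning (45,000 retained draws);
desk-scale studies in the tests use 3 × 3,000 with 1,500 burn-in, which
the auxiliary moves make sufficient (all R-hat < 1.1 on the synthetic
designs).

Convergence is monitored by the classical Gelman–Rubin potential scale
reduction factor R̂ = sqrt((m−1)/m + B/(mW)) over retained draws, with
an optional split-chain variant; the CLI warns above 1.1.

## Assessment

Per level: Dbar is the posterior mean of −2·log-likelihood (including
the binomial constant — common to both models, harmless for
comparison); the plug-in deviance D̂ is evaluated at the posterior mean
of the linear predictor η (η is linear in all parameters, so this
equals the deviance at the posterior-mean parameters and avoids
nonlinearity artifacts of plugging into logit⁻¹); pD = Dbar − D̂ and
DIC = Dbar + pD. Negative pD, a known pathology of the plug-in
construction, is reported rather than clipped. MSPE draws one binomial
replicate dataset per retained draw and averages (y_rep − y)² over
draws and units, with a fixed seed for reproducibility. A DIC gap of at
least 3 is flagged as an improvement; lower DIC and lower MSPE are
preferred.

MSPE is computed against the data the model was fitted to. Such
in-sample predictive error tends to reward the model whose fitted means
track the observations most closely — typically the model with the
larger pD — and so can run against the parsimony ordering that DIC
encodes, particularly at the fine level where the independent model is
free to absorb district-scale structure into its own county effects.
The acceptance script reports the preference rates so this behaviour is
measured, not assumed.

## Synthetic data

The generator emulates the nested structure of aggregated surveillance
data. Fine units form a rook-adjacency lattice partitioned into
rectangular blocks (default 12×12 into nine 4×4 blocks: 144 units in 9,
near the 159-in-18 scale of the motivating Georgia analysis but exactly
divisible), or the deterministic irregular preset
`make_georgia_like_geography()` (159 units in 18 contiguous districts
of 8–9 units on a planar grid with corners removed). Fine covariates
are Normal(40, 8) in thousands of dollars — the scale of county median
household income — optionally with a column gradient; coarse covariates
are parent means. CH fields are exact draws from the ICAR prior
(eigendecomposition of each component Laplacian restricted to the
sum-to-zero subspace); UH is iid normal, uncentred (centering is an
inferential device, not part of the generative law). Fine outcomes are
Binomial(n, logit⁻¹(η)) with n = 500 trials per unit by default; coarse
outcomes and trials are parent *sums* of the fine ones — the coarse
level is deliberately an approximating model for sums, exactly the
situation aggregated data present, rather than an independent coarse
binomial draw.

Generating parameter defaults: intercepts −2.2 (baseline risk ≈ 10%,
the order of low-birth-weight incidence), fine slope −0.1 and coarse
slope −0.06 per SD of the covariate, σ_v = 0.1 / σ_ε = 0.1 (fine) and
σ_v = 0.3 / σ_ε = 0.05 (coarse) — the scale of published posterior
estimates for such convolution models. What the generator does *not*
emulate: real map geometry, heteroscedastic trial counts, covariate
measurement error, or non-nested (misaligned) multiscale structure;
passing tests therefore demonstrate correctness of the machinery and
recoverability under the model's own assumptions, not robustness to
real-data violations of them.

The replicated `recovery_experiment` simulates under the shared model,
fits both variants per replicate, and scores bias, 95%-interval
coverage, convergence, DIC/MSPE preference direction and fine-surface
roughness Σ_{i~j}(p̂_i − p̂_j)².

## Numerical and design choices

* Unit order is file order of first appearance and is the canonical
  vector index order everywhere.
* Coarse adjacency is read from its own file in real-data mode (treated
  as given, as district adjacency usually is); the lattice generator
  constructs it as block adjacency, which provably equals the
  cross-block-edge induction for full rectangular partitions, and the
  irregular preset induces it from cross-district county edges. Both
  conventions are supported; neither is asserted as canonical.
* Asymmetric adjacency input is refused with the offending pairs listed,
  never silently symmetrized; islands are preserved and flagged.
* The binomial log-likelihood uses the softplus form
  y·η − n·log(1+e^η), stable for |η| ≈ 40 and beyond.
* Posterior summaries are pooled across chains with equal-tailed
  empirical 95% intervals; displays round to 2 decimals, odds ratios to
  3, percent changes to 1.
* The odds ratio per raw covariate unit (per $1,000 of income) is
  reported two ways: exp(posterior-mean slope / sd_x) — the headline
  point arithmetic — and the posterior mean and interval of the
  draw-wise transform exp(β/sd_x), the Bayesian-coherent companion.
* Risk surfaces use the posterior mean of logit⁻¹(η) per unit (not the
  median), with equal-tailed intervals.
* `n_iter = burn_in` is allowed and yields an empty retained sample
  with valid provenance; the CLI treats it as a usage error (exit 2).

## Known limitations

* Exactly two nested levels; no Poisson likelihood; no proper-CAR
  (Leroux/BYM2) variants; no spatio-temporal extension.
* The improper ICAR leaves one free constant per connected component;
  recentring pins only the global constant against the intercept. On
  maps with several components the extra constants remain weakly
  identified (the study geographies are connected).
* DIC's plug-in pD can be negative under strong non-normality.
* In-sample MSPE limitations discussed under *Assessment*.
* The shared coarse field enters fine predictors with coefficient 1; no
  scaling parameter is estimated.
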