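# Methods

## Model

`wetlandbn` implements a non-parametric Bayesian network over wetland
traits: a directed acyclic graph whose nodes are random variables with
*empirical* (distribution-free) margins and whose dependence is a normal
copula.  The joint law of nodes X₁…Xₙ is
C_R(F₁(X₁), …, Fₙ(Xₙ)) with C_R the Gaussian copula; all dependence is
carried by the correlation matrix R of the normal scores
zᵢ = Φ⁻¹(Fᵢ(xᵢ)).  The model is *hierarchical* in the sense that the
DAG encodes which variables influence which: spatial context and
anthropic/hydrological pressures are parents of the target node, species
richness per wetland, whose conditional mean under a scenario is the
alpha diversity.

Assumptions worth stating explicitly:

- dependence is adequately captured by a Gaussian copula (tested, see
  below); tail dependence beyond the Gaussian family is not represented;
- margins are the empirical distributions of the calibration data, so
  simulated values never leave the observed range of each variable;
- ordinal traits (salinity 0–3, tourism 0–3, …) are treated through
  their midranks; the model sees their ordering, not their labels.

## Calibration

The z-space sample matrix is the Pearson correlation of per-column
normal scores zᵢ = Φ⁻¹(rᵢ/(n+1)) with midranks rᵢ.  Spearman's rank
correlation is computed as the product-moment correlation of midranks,
which coincides with the textbook 1 − 6Σdᵢ²/(n³−n) when all values are
distinct; the midrank form is the standard tie correction and the
ordinal traits are heavily tied at n = 22.

Two fit modes exist:

- **saturated** — R is the (PD-repaired) sample matrix itself; used for
  diagnostics and for the determinant-factorization identity.
- **bn_constrained** (default) — each arc (pₖ → v) is assigned
  ρ(v, pₖ | p₁…pₖ₋₁), the partial correlation of the node and that
  parent given the node's earlier-ordered parents (ordering: topological
  with declaration-order tie-breaks).  The implied joint matrix is
  rebuilt *from the arc partials alone*: correlations with parents by
  inverting the sequential (C-vine) partial-correlation recursion, and
  correlations with non-parent predecessors from the zero-partial
  constraint, i.e. the regression of the node's score on its parents'
  scores.  This parametrization makes the round trip exact (re-extracted
  arc partials equal the stored ones to machine precision) and
  guarantees positive definiteness whenever every |ρ| < 1.

Indefinite sample matrices (possible at small n) are repaired by
clipping eigenvalues at 1e−8 (with 2× headroom, since the subsequent
rescaling to unit diagonal can shrink the smallest eigenvalue) and
renormalizing; the repair is idempotent and leaves already-PD matrices
untouched.

## Validation

The determinant of a correlation matrix is 1 under independence and → 0
under multivariate linear dependence; over a network it factors as
D = Π(1 − ρ²) across arcs, and for a complete partial-correlation
ordering this product equals det R exactly (checked to 1e−10 in the
tests).  The copula test compares D_ER — by default the determinant of
the *Spearman* matrix of the observed table — with the simulated
sampling distribution of D_NR, the determinant of the *normal-scores*
matrix of same-size datasets drawn from the fitted copula (10⁴
simulations, equal-tailed 90% band).  The two rank conventions are one
flag apart (`d_er_mode`) because the literature uses both names without
fully fixing the convention; they differ only slightly and the
calibration test shows the default pairing keeps the nominal coverage
(pass rate 0.85–0.95 under the null at 200 replicates).  Simulated
replicates are drawn as continuous copula samples: ranks are invariant
under the monotone margin transforms, so pushing them through the
margins would only add ties without changing the statistic's meaning.

## Conditionalization

Scenario evidence is mapped to the copula scale with the midrank
convention u = midrank(value)/(n+1) against the calibration column;
values never observed interpolate linearly between neighbouring observed
levels, and values outside the observed support clamp to the nearest
level.  Given evidence z_e, the free nodes follow the exact conditional
multivariate normal (mean R_fe R_ee⁻¹ z_e, covariance the Schur
complement); samples are back-transformed through piecewise-linear
empirical quantile functions on the r/(n+1) plotting grid, clamped to
the observed minimum/maximum.  Conditioning is analytic — no iterative
assimilation — which is exact for the normal copula.

Results are summarized with the target histogram over the fixed range
[2, 32] species in 10 equal bins (width 3) shared by all scenarios, the
conditional mean µ (alpha diversity) and SD σ, and wetland counts by
largest-remainder rounding of the bin proportions times n (ties to the
earlier bin), so counts always sum to n.

Default per-scenario sample size is 10⁵, giving a Monte-Carlo standard
error on µ of roughly σ/√n ≈ 0.03 species.  All randomness derives from
one caller seed; multi-scenario runs spawn one independent
`SeedSequence` child per scenario.

## Scenario catalog

The shipped catalog holds 18 scenarios (codes a–r): the baseline (no
evidence); six worst cases fixing one driver at its damaging extreme
(tourism 3, salinity 3, discharges 2, anthropization 2, water level 11,
diversions 0) and their union (h, the worst possible scenario); six best
cases fixing each driver at its favourable value (tourism 0, salinity 0,
discharges 0, anthropization 0, water level 3, diversions 3) and their
union (o); and three mixed scenarios that equal h with exactly one
driver neutralized (tourism, salinity or discharges set to 0).  Water
level 3 (20–30 cm) is the favourable value because shallow but not dry
water maximizes foraging habitat for waders and dabbling birds.

## Synthetic data

The generator draws latent rows from a Gaussian copula with a recorded
ground-truth matrix and pushes each column through its margin:
continuous traits by a uniform or log-uniform stretch over the declared
range (log-uniform for size and isolation, which span two orders of
magnitude), ordinal traits by thresholding the copula uniform at
interior cut-points, counts by equal-mass rounding into the integer
range.  The default system has 22 wetlands and ten variables with
negative target correlations for salinity (−0.45), tourism (−0.38),
discharges (−0.32), water level (−0.30), anthropization (−0.25) and
isolation (−0.25), positive for diversions (+0.30) and size (+0.40),
plus one inter-driver entry (diversions–water level −0.30).  Magnitudes
are capped near 0.45 because nine drivers loading on one target require
Σρ² < 1 for a positive-definite matrix; the chosen values leave a
smallest eigenvalue of about 0.07.

What the generator does *not* emulate: spatial autocorrelation between
neighbouring wetlands, measurement error in the semi-quantitative
scores, year-to-year variation, and any nonlinear (non-monotone)
driver–richness response.  Passing tests therefore demonstrate the
correctness and calibration of the machinery under the model's own
assumptions, not the ecological validity of a particular fitted network.

Ordinal discretization attenuates rank correlations (by roughly 0.05–
0.08 for 3–4-level scores); recovery tolerances account for this rather
than inverting the attenuation, because the real pipeline also operates
on the discretized scale.

## Problem sizes and numerical choices

- Parameter-recovery experiments use 10⁴ generated rows (separating
  estimator bias from small-sample noise) and 100 replicates at the
  realistic n = 22 for sign-recovery rates.
- Validation calibration uses 200 outer replicates with 500 inner
  simulations; the full validation run uses 10⁴ simulations.
- Determinant simulation is vectorized: per column the normal scores are
  a permutation of a fixed grid, so each replicate reduces to a ranking,
  a gather and one batched determinant.
- Plotting positions are r/(n+1) (keeps Φ⁻¹ finite at the extremes); the
  convention is a documented choice, as the reference implementations in
  this model family do not publish theirs.
- Degenerate inputs fail loudly: constant columns, cyclic structures,
  evidence on the target, fewer than 5 rows, |ρ| ≥ 1 in a determinant
  product, and n_sims < 100 in validation all raise typed errors.

## Known limitations

- Exact reproduction of results obtained with proprietary engines for
  this model family can differ in the third decimal because their
  sampling settings and plotting-position conventions are not public.
- The default network structure is a documented reconstruction of the
  conceptual wetland model (all nine drivers → richness, one
  inter-driver arc); alternative arc sets among drivers are supported
  via structure files but their results are reported against the
  configured structure only.
- The bn_constrained implied matrix discards sample dependence between
  drivers not linked by an arc; with few inter-driver arcs, driver
  co-deterioration is represented only through the evidence itself.
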