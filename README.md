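# wetlandbn

Gaussian-copula Bayesian networks for scenario analysis of wetland bird
diversity.

## The problem

Coastal Mediterranean wetlands are stopover and breeding sites for many
waterbird species, and their quality is shaped by a handful of measurable
traits: spatial context (wetland size, isolation, distance to the
coastline), anthropic pressures (tourism, anthropization, water
discharges) and hydrology (water salinity, water diversions, mean water
level).  Managers need to know how *alpha avian diversity* — the mean
number of bird species per wetland — would respond to plausible futures:
what if salinity becomes widespread everywhere?  What if tourism is
banned?  `wetlandbn` answers such questions with a non-parametric
Bayesian network: a directed acyclic graph over the traits whose arcs
carry conditional rank correlations, realized through a normal (Gaussian)
copula with empirical margins.  It is aimed at quantitative ecologists
and conservation modellers who want a small, fully reproducible pipeline
for this class of models.

## The model

By Sklar's theorem a joint distribution F₁…ₙ(X₁, …, Xₙ) factors into its
margins Fᵢ and a copula C.  The normal copula is

C_R(u₁, …, uₙ) = Φ_R(Φ⁻¹(u₁), …, Φ⁻¹(uₙ)),

where Φ is the standard normal CDF and R a correlation matrix in the
space of normal scores zᵢ = Φ⁻¹(Fᵢ(xᵢ)).  Calibration estimates each
margin empirically and assigns to each arc (pₖ → v) the partial
correlation ρ(v, pₖ | p₁…pₖ₋₁) given the node's earlier-ordered parents;
the joint R is rebuilt from the arc partials with all non-arc partials
set to zero.  Rank correlations use Spearman's
ρ = 1 − 6Σdᵢ²/(n³ − n) (midrank form under ties).

The copula assumption is tested by comparing D_ER, the determinant of
the empirical rank correlation matrix, against the simulated sampling
distribution of D_NR, the determinant of the normal-scores correlation
matrix of same-size datasets drawn from the fitted copula; for a network
the determinant factors as D = Π(1 − ρᵢⱼ²) over the arcs.  Scenarios are
run by *conditionalization*: evidence values are mapped to z-space, the
remaining nodes follow the exact conditional multivariate normal (Schur
complement), and samples are mapped back through the empirical quantile
functions.

## Worked example

```python
import wetlandbn as w

table = w.generate(w.default_spec(n_wetlands=22, seed=11))  # synthetic survey
model = w.fit(table)                      # calibrate the default network
report = w.validate_model(model, table, n_sims=10_000, seed=1)
results = w.run_catalog(model, n_samples=100_000, seed=1)
```

Running `python examples/03_run_scenarios.py` prints (abridged):

```
code label           mu  sigma  delta
   a baseline     15.71   9.05  +0.00
   c worst-case   11.83   8.21  -3.87
   h worst-case    3.26   0.97 -12.45
   i best-case    19.66   8.52  +3.96
   o best-case    28.10   3.54 +12.39
```

`mu` is the expected alpha diversity under each scenario and `delta` its
change against the baseline: on this synthetic system, widespread
salinity (scenario c) costs about 3.9 species per wetland, the worst
possible scenario (h, all drivers deteriorate) collapses diversity to
~3 species, and the best possible one (o) raises it to ~28.  The
validation example prints `D_ER = 0.0165` inside the 90% band
(0.0037, 0.0369), so the normal-copula assumption is not rejected.

A thin CLI wraps the same pipeline:

```bash
wetlandbn synth --n 22 --seed 3 -o table.csv
wetlandbn fit      --data table.csv -o out/
wetlandbn validate --data table.csv -o out/      # exit 1 if test fails
wetlandbn simulate --data table.csv -o out/
```

## Layout

- `src/wetlandbn/` — `traits` (schema + table I/O), `copula` (rank
  transforms, copula sampling, margins), `network` (DAG + calibration),
  `scenarios` (conditionalization + catalog), `validation` (determinant
  test), `synthetic` (ground-truth generators), `cli`.
- `examples/` — one narrative script per capability.
- `docs/methods.md` — modelling assumptions, numerical choices,
  limitations.
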