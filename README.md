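# netgenstab

Valued exponential random graph models (ERGMs) and cross-generation
stability analysis for weighted animal interaction networks.

## The scientific problem

Whether social structure persists across generations is a prerequisite for
evolutionary processes that act through social networks, but it is hard to
test: it needs multi-generation network data and a way to compare networks
of different sizes. One tractable system is a wild population of the field
cricket *Gryllus campestris*, univoltine (one generation per year, no
shared individuals between years), living around burrows in a ~20 × 40 m
meadow, where every mating and fight between tagged adults can be recorded
on camera. Each year yields one weighted undirected network: an edge joins
two crickets that ever mated or fought, weighted by their number of
interactions.

This package implements the full analysis pipeline for that design:

1. **Model.** A valued ERGM over count networks *y* with Poisson reference
   measure *h(y) = ∏<sub>i<j</sub> 1/y<sub>ij</sub>!*:

   *P(y; θ) ∝ h(y) · exp(θ·g(y))*

   with six statistics *g*: Conway–Maxwell–Poisson dispersion
   (Σ log y<sub>ij</sub>!), sparsity (Σ 1[y<sub>ij</sub>>0]), valued
   transitive ties (Σ min(y<sub>ij</sub>, max<sub>k</sub>
   min(y<sub>ik</sub>, y<sub>kj</sub>))), a male main effect on strength,
   sex node-matching, and an inverse-distance dyadic covariate between
   emergence locations.
2. **Estimation.** Monte-Carlo maximum likelihood (importance-sampling
   Newton with partial stepping), standard errors from the inverse Fisher
   information, and the practical restart-until-stable convergence
   procedure.
3. **Comparison.** Simulate 100 networks for every ordered (model-year,
   target-year) pair — the target year's nodes, covariates and observed
   network condition the simulation; the model year's coefficients drive
   it — and score **predictive distances** |m(sim) − m(observed)| for mean
   path length, degree correlation and clustering coefficient.
4. **Inference.** Wilcoxon rank-sum tests (full vs reduced simulations;
   within-year vs between-year mean distances) and Mantel permutation
   tests of mean predictive distance against year-gap and
   population-size-gap matrices.

Because no field data are distributed, a first-class synthetic-data module
emulates the study system (annual populations of 79–239 crickets, sparse
over-dispersed interaction counts, mostly inter-sex edges, fight share
rising with density), both via exact ERGM draws and via a mechanistic
encounter simulator.

## Worked example

```python
import numpy as np
from netgenstab import (
    ERGMSpec, FitControl, SYNTH_THETA, closeness_matrix, fit_ergm,
    generate_population, simulate_from_ergm,
)

nodes = generate_population(100, rng=np.random.default_rng(42), year=2006)
clos = closeness_matrix(nodes)                # inverse distance, 1/m
net = simulate_from_ergm(nodes, SYNTH_THETA, seed=1)
print(net)
fit = fit_ergm(net, ERGMSpec(), control=FitControl(seed=2), closeness=clos)
for term, est, se in zip(fit.theta_hat.terms, fit.theta_hat.values, fit.se):
    print(f"{term:22s} {est:7.3f} ({se:.3f})")
```

Output (exact numbers vary with the seed):

```
ValuedNetwork(n=100, edges=200, total_weight=378)
cmp                      0.400 (0.086)
nonzero                 -3.797 (0.127)
transitive_ties          0.344 (0.067)
nodefactor_sex_male     -0.085 (0.071)
nodematch_sex           -0.471 (0.085)
edgecov_closeness        0.341 (0.055)
```

The network is sparse (200 of 4950 dyads tied) with over-dispersed
weights; every coefficient is recovered within about one standard error
of the generating values (0.50, −4.0, 0.40, −0.09, −0.45, 0.30): positive
dispersion and transitivity, negative sparsity and sex-matching, and a
positive effect of spatial closeness — the same sign pattern reported for
the wild population in every year.

A thin CLI mirrors the pipeline: `netgenstab fit`, `netgenstab simulate`,
`netgenstab efficacy` and `netgenstab stability --config config.yaml`.

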