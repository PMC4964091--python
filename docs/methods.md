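# Methods

## Model

Networks are symmetric count matrices *y* over a fixed node set with sex,
emergence coordinates (metres) and year. The model is an exponential
family over such matrices,

P(y; θ) = h(y) exp(θ·g(y)) / κ(θ),  h(y) = ∏_{i<j} 1/y_ij!,

so that with θ = 0 every dyad weight is iid Poisson(1). The six
statistics, over unordered dyads:

| term | statistic | interpretation |
|---|---|---|
| `cmp` | Σ log(y_ij!) | Conway–Maxwell–Poisson dispersion: with the Poisson reference the weight density carries (y!)^(θ−1), so θ > 0 is over-dispersion, θ = 1 a geometric tail |
| `nonzero` | Σ 1[y_ij > 0] | sparsity; negative values penalise ties |
| `transitive_ties` | Σ min(y_ij, max_k min(y_ik, y_kj)) | valued triadic closure (min–max–min two-path support); a `binary` variant applies the same formula to the 0/1 projection |
| `nodefactor_sex_male` | Σ y_ij (1[i male] + 1[j male]) | male main effect on total strength; females are the reference level |
| `nodematch_sex` | Σ y_ij 1[sex_i = sex_j] | sex homophily; negative when inter-sex interaction (mating) dominates |
| `edgecov_closeness` | Σ y_ij c_ij | spatial covariate c_ij = 1/max(d_ij, ε), ε = 0.1 m by default |

The closeness covariate is *not* rescaled by default (coefficients are on
the raw 1/m scale); a standardisation flag exists on the CLI because the
scale convention of historical analyses is not always recoverable.

### Degeneracy

Valued ERGMs with positive transitivity are bimodal: beyond a threshold
in (θ_cmp, θ_transitive) the sparse "realistic" mode coexists with — or
loses metastability to — a dense high-weight mode. Two-start equilibration
probes (sparse vs dense initialisation, compared on mean statistics) show
that coefficient magnitudes like those estimated from the wild population
(cmp ≈ 0.9, transitive ≈ 1.9) are inside the degenerate region at desk
scale: chains drift steadily denser and no stationary "ground-truth draw"
exists. Simulation *conditioned on an observed network with finite
chains* — the practice this package reproduces — samples the local mode
and is well defined; but parameter-recovery experiments need a truly
stationary truth. The synthetic ground truth is therefore

SYNTH_THETA = (cmp 0.50, nonzero −4.0, transitive 0.40, sex −0.09,
nodematch −0.45, closeness 0.30),

the field sign pattern at magnitudes verified stationary by the two-start
probe. The published per-year coefficient sets remain available as
fixtures (`FIELD_THETA`) for conditioned-simulation examples.

## Sampling

Metropolis–Hastings over single dyads: a dyad is chosen uniformly, a new
count proposed by a ±1 random walk reflected at zero (optionally a
mixture with a geometric independence jump, or a reflecting cap
`max_weight` used by exact-enumeration tests), and accepted using O(n)
change statistics, the Poisson reference ratio and the proposal
asymmetry correction. Chains are initialised at a template network, which
is how simulations are conditioned on a target population's size, sex
ratio, spatial layout and observed configuration; an optional
`sum_offset` coefficient on total weight can be bisection-calibrated so
mean simulated total weight matches the observed total within 2 %.

Defaults: burn-in 50 × n_dyads updates, thinning interval 10 × n_dyads,
chosen so retained networks have statistic autocorrelation well below the
chain scale for the synthetic benchmark; both are configurable and the
analysis entry points pass explicit, documented values (below). The
kernel exploits the symmetry of *y* so all inner loops stream along
matrix rows; one update costs ≈ 0.6 µs at n ≈ 120.

## Estimation

`fit_ergm` is importance-sampling Monte-Carlo MLE with three safeguards
that matter in the sparse, over-dispersed, near-degenerate regime:

- **Partial stepping.** Each iteration solves towards the pseudo-target
  γ·g_obs + (1−γ)·ḡ with γ chosen so the target lies within Mahalanobis
  distance 2 of the simulated statistic cloud; Newton steps are clamped
  to ‖Δθ‖∞ ≤ 0.5 and stopped when the importance-weight effective sample
  size falls below a third of the batch. Without this the optimiser can
  walk into the degenerate region, where short conditioned chains report
  a spurious moment match.
- **Drift guard.** Batches are sampled in four chunks; if a chunk's mean
  tie count exceeds three times the observed count the batch is aborted
  and θ pulled halfway back towards the last non-drifting value (or the
  density-matched initialiser).
- **Verification.** A converged fit is re-checked with a longer,
  better-thinned chain (burn-in 50 × n_dyads, interval 8 × n_dyads); the
  moment z-scores must stay below 4, and this decorrelated batch supplies
  the covariance for the standard errors (inverse Fisher information).

Convergence requires γ = 1 and every moment z-score below 2.8 — the
maximum of six correlated |N(0,1)| scores sits near 2, so a tolerance of
2 would fail about half the time *at the exact solution*. The initial θ
is zero except sparsity, set from observed density via its closed form
θ̂_nz = log(k/(m−k)) − log(e−1). A Robbins–Monro stochastic-approximation
fallback (`method="sa"`) exists for pathological cases.

`refit_until_stable` re-runs the fit seeded with the previous estimates
until max |Δθ| falls below a tolerance (default 0.05; the pipeline helper
`fit_years` uses the larger of 0.05 and twice the biggest standard error,
since stability cannot be resolved below Monte-Carlo precision). A stable
but z-unconverged fit is reported converged-by-stability only if its last
moment match was within twice the z tolerance — otherwise "stable" could
simply mean "stuck".

## Metrics and tests

Metrics are computed on the binary projection (an edge is any positive
weight): mean geodesic path length over reachable pairs (unreachable
pairs excluded), degree correlation (Pearson correlation of end-point
degrees over both orientations of each edge), and global transitivity
3 × closed triads / connected triples. Note the conventional transitivity
ratio is used (bounded in [0, 1]); an "open-to-closed ratio" phrasing
found in field descriptions is its monotone relabelling, and predictive
distances are unaffected because the same definition is applied to
observed and simulated networks. Degree correlation is computed in the
efficacy stage but excluded from the within/between and Mantel stages by
default, since randomisation-based models are recognised as poor at
reproducing it.

`permstats` is self-contained: rank-sum tests use exact enumeration up to
n = 12 without ties (two-sided p = 2·min(tails), R's W convention) and a
tie- and continuity-corrected normal approximation otherwise; the Mantel
test permutes rows and columns of one matrix simultaneously, uses
Spearman correlation of upper-triangle entries, enumerates the full
permutation group when it is no larger than `n_perm` (n ≤ 7 at the
default 999), and counts the observed configuration among random
permutations otherwise. The one-sided upper-tail alternative is the
default, matching the convention under which a negative rho is reported
with a large p.

Predictive distances are absolute differences between simulated and
observed metrics; simulated networks on which a metric is undefined
(e.g. an empty draw) are dropped with a logged count. The within/between
test compares the Y within-year mean distances with the Y(Y−1)
between-year mean distances; Mantel correlates use the unordered-pair
symmetrised mean-distance matrix (distance matrices must be symmetric;
the average of the two orientations is used).

## Synthetic data

Two engines share the node/event formats:

- **ERGM-exact** (`simulate_from_ergm`): one long-burn-in draw (default
  300 updates per dyad — the spatial-covariate statistic equilibrates
  slowly because weight accumulates on the few very close pairs), seeded
  with a Bernoulli edge set at the density implied by the sparsity
  coefficient. Used wherever an exact known truth is needed.
- **Mechanistic** (`simulate_mechanistic`): pairwise encounter counts are
  negative-binomial with mean proportional to closeness; inter-sex pairs
  (matings) interact at a higher base rate than intra-sex pairs (fights);
  the intra-sex rate scales with population size over a reference of 160,
  so larger populations fight relatively more; a triadic-closure pass
  adds interactions between pairs sharing a partner at the same
  intra/inter rate ratio. The default rates were tuned once to the
  documented property windows — tie density < 20 %, weight
  variance/mean > 1, inter-sex weight share > 60 %, fight percentage
  rising from ≈ 16 % at n = 79 to ≈ 38 % at n = 239 — and are fixed
  constants.

What the generators do *not* emulate: burrow turnover and movement
trajectories, survival, clustered burrow placement (uniform placement is
the default; emergence locations are iid), and any behavioural carryover
between years. Passing tests therefore demonstrate that the pipeline
recovers structure and stability *when the generating process matches
the model family or the documented mechanistic caricature*, not that the
model is correct for any particular field system.

Scenario presets define the study conditions used by the test-suite and
the acceptance script:

- `stationary_scenario`: four (by default) years of 150 crickets, all
  drawn from SYNTH_THETA — the stability null. The population size is the
  lever that makes the null hold at desk scale: each year's fitted
  coefficients carry estimation noise that favours within-year
  prediction, an overfitting artefact that shrinks with network size. Equal sizes make the
  size-gap Mantel degenerate by design; it is reported as such.
- `size_confounded_scenario`: six years with sizes (96, 120, 138, 76,
  156, 62) assigned so the size-gap matrix has exactly zero Spearman
  correlation with the year-gap matrix, and coefficients varying
  affinely with size (sparsity −4.6 → −3.9, transitivity 0.28 → 0.44,
  sex-matching −0.60 → −0.30): larger populations mix more densely, more
  transitively and less assortatively, emulating a size-dependent
  interaction mix. Predictive distance should correlate
  with size gap and not with year gap.
- `drifting_scenario`: transitivity decaying over years — the contrast
  case in which the year gap *does* matter.

## Problem sizes

Analyses are scaled to single-CPU desk runs, and these scales are part of
the package's stated conditions: fits inside the scenario pipelines use
192 simulated networks per iteration with burn-in 10 × n_dyads and
interval 1 × n_dyads (the verification phase uses the long defaults);
cross-year matrices use 50 simulations per cell with burn-in 30 × n_dyads
and interval 5 × n_dyads; parameter recovery uses one 100-node network
and the full default fit control. Exact-enumeration oracles run on 3-node
capped-weight models (64 states) and 4–6 element Mantel matrices.

## Known limitations

- Near the field coefficient magnitudes the model is degenerate at
  equilibrium; only conditioned finite-chain simulation is meaningful
  there, and the package makes no attempt at perfect sampling.
- Standard errors come from the simulated Fisher information and ignore
  Monte-Carlo error in θ̂ itself (small at the documented batch sizes,
  roughly SE/√ESS).
- The rank-sum normal approximation is used for the 6-vs-30
  within/between comparison (exact enumeration is implemented only to
  n = 12); at these sizes the continuity-corrected approximation is
  accurate to well under 0.02 in p.
- Mantel tests with six years have a minimum two-sided resolution of
  1/720 and little power; sign and magnitude of rho are the meaningful
  outputs, as in the motivating analyses.
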