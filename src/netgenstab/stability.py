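"""Cross-generation analysis: simulation efficacy, within- vs between-year
predictive distances, and their correlates.

A "predictive distance" is the absolute difference between a network
metric computed on a simulated network and the same metric on the observed
network.  Simulating a target year's network under the coefficients fitted
to a (possibly different) model year, and scoring the distances, measures
how well one generation's social structure predicts another's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ergm_estimate import FitControl, FitResult, refit_until_stable
from .ergm_model import ERGMSpec
from .ergm_sample import SamplerControl, derive_seed, simulate_networks
from .netdata import ClosenessMatrix, ValuedNetwork, closeness_matrix
from .netmetrics import METRIC_FUNCTIONS, UndefinedMetricError
from .permstats import MantelResult, RankSumResult, mantel_test, rank_sum_test

#: Metrics scored by default.  Degree correlation is computed by
#: ``efficacy_comparison`` but excluded from the within/between and Mantel
#: stages by default, because randomisation-based models are recognised as
#: poor at reproducing it; pass ``metrics`` explicitly to re-enable it.
DEFAULT_METRICS = ("path_length", "clustering")
EFFICACY_METRICS = ("path_length", "degree_correlation", "clustering")
REDUCED_TERMS = ("cmp", "nonzero")


@dataclass
class PredictiveDistanceSet:
    """Distances |m(sim) - m(observed)| for one (model-year, target-year,
    metric) combination.  Simulated networks on which the metric is
    undefined are dropped, with the count recorded."""

    model_year: int
    target_year: int
    metric: str
    distances: np.ndarray
    n_undefined: int = 0

    @property
    def mean_distance(self) -> float:
        return float(np.mean(self.distances))


@dataclass
class ComparisonMatrix:
    """Mean predictive distances for every ordered (model, target) pair."""

    years: list[int]
    sizes: dict[int, int]
    metrics: tuple[str, ...]
    cells: dict = field(default_factory=dict)  # (my, ty) -> {metric: PDS}

    @property
    def n_within(self) -> int:
        return sum(1 for (a, b) in self.cells if a == b)

    @property
    def n_between(self) -> int:
        return sum(1 for (a, b) in self.cells if a != b)

    def mean_distance(self, model_year: int, target_year: int,
                      metric: str) -> float:
        return self.cells[(model_year, target_year)][metric].mean_distance

    def within_means(self, metric: str) -> np.ndarray:
        return np.array([self.mean_distance(y, y, metric) for y in self.years])

    def between_means(self, metric: str) -> np.ndarray:
        return np.array([
            self.mean_distance(a, b, metric)
            for a in self.years for b in self.years if a != b
        ])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (my, ty), cell in sorted(self.cells.items()):
            for metric, pds in cell.items():
                rows.append((my, ty, self.sizes[my], self.sizes[ty], metric,
                             pds.mean_distance, pds.n_undefined))
        return pd.DataFrame(rows, columns=[
            "model_year", "target_year", "model_size", "target_size",
            "metric", "mean_distance", "n_undefined",
        ])


def predictive_distances(
    observed: ValuedNetwork,
    sims: list[ValuedNetwork],
    metric: str,
    model_year: int = 0,
    target_year: int = 0,
) -> PredictiveDistanceSet:
    """Score |metric(sim) - metric(observed)| over a simulation batch."""
    if not sims:
        raise ValueError("empty simulation batch")
    func = METRIC_FUNCTIONS[metric]
    m_obs = func(observed)
    dists, undefined = [], 0
    for s in sims:
        try:
            dists.append(abs(func(s) - m_obs))
        except UndefinedMetricError:
            undefined += 1
    if not dists:
        raise UndefinedMetricError(
            f"metric {metric!r} undefined on every simulated network"
        )
    return PredictiveDistanceSet(model_year, target_year, metric,
                                 np.array(dists), undefined)


def _closeness_for(net: ValuedNetwork, spec: ERGMSpec,
                   closeness: ClosenessMatrix | None,
                   epsilon: float) -> ClosenessMatrix | None:
    if "edgecov_closeness" not in spec.terms:
        return None
    return closeness if closeness is not None else closeness_matrix(
        net.nodes, epsilon)


def fit_years(
    networks: dict[int, ValuedNetwork],
    spec: ERGMSpec = ERGMSpec(),
    control: FitControl = FitControl(),
    max_restarts: int = 2,
    stability_tol: float | None = None,
    epsilon: float = 0.1,
    warm_start: bool = True,
) -> dict[int, FitResult]:
    """Fit every year with the restart-until-stable procedure.

    ``stability_tol=None`` uses an adaptive tolerance per year: the larger
    of 0.05 and twice the largest coefficient standard error — coefficient
    stability cannot be resolved below the Monte-Carlo precision of the
    estimates themselves.  With ``warm_start`` each year's optimisation is
    initialised at the previous year's estimates (an optimiser start only;
    the solution is each year's own moment match).
    """
    from .ergm_estimate import fit_ergm

    fits = {}
    init = None
    for yi, (year, net) in enumerate(sorted(networks.items())):
        clos = _closeness_for(net, spec, None, epsilon)
        for attempt in range(3):  # reseeded retries for unlucky chains
            ctl = replace(control,
                          seed=derive_seed(control.seed, 31, yi, attempt))
            first = fit_ergm(net, spec, init if attempt == 0 else None,
                             ctl, clos)
            if stability_tol is None:
                se = first.standard_errors
                tol = max(0.05, 2.0 * float(np.nanmax(se))) if np.isfinite(
                    se).any() else 0.05
            else:
                tol = stability_tol
            fits[year] = refit_until_stable(net, spec, ctl, max_restarts,
                                            tol, clos, first.theta_hat)
            if fits[year].converged:
                break
        if warm_start:
            init = fits[year].theta_hat
    return fits


# ---------------------------------------------------------------------------
# Full vs reduced simulation efficacy
# ---------------------------------------------------------------------------

def efficacy_comparison(
    net: ValuedNetwork,
    fit: FitResult,
    spec: ERGMSpec = ERGMSpec(),
    control: SamplerControl = SamplerControl(),
    n_sims: int = 100,
    metrics: tuple[str, ...] = EFFICACY_METRICS,
    closeness: ClosenessMatrix | None = None,
    epsilon: float = 0.1,
) -> dict:
    """Full-model vs reduced-model predictive distances, per metric.

    The reduced model keeps only the dispersion (cmp) and sparsity
    (nonzero) coefficients, zeroing the rest (no refit).  For each metric
    the two distance sets are compared with a two-sided rank-sum test; a
    significantly smaller full-model distance indicates the structural
    terms add real predictive content.
    """
    if not fit.converged:
        raise ValueError("efficacy comparison requires a converged fit")
    clos = _closeness_for(net, spec, closeness, epsilon)
    theta_full = fit.theta_hat
    theta_red = theta_full.restrict(REDUCED_TERMS)
    sims = {}
    for arm, (label, theta) in enumerate(
            (("full", theta_full), ("reduced", theta_red))):
        ctl = replace(control, seed=derive_seed(control.seed, 100 + arm))
        sims[label] = simulate_networks(net, theta, spec, n_sims, ctl, clos)
    out = {}
    for metric in metrics:
        try:
            d_full = predictive_distances(net, sims["full"], metric)
            d_red = predictive_distances(net, sims["reduced"], metric)
        except UndefinedMetricError as err:
            out[metric] = {"error": str(err)}
            continue
        test = rank_sum_test(d_full.distances, d_red.distances, "two-sided")
        out[metric] = {"full": d_full, "reduced": d_red, "test": test}
    return out


# ---------------------------------------------------------------------------
# Cross-year prediction
# ---------------------------------------------------------------------------

def cross_year_matrix(
    networks: dict[int, ValuedNetwork],
    fits: dict[int, FitResult],
    spec: ERGMSpec = ERGMSpec(),
    control: SamplerControl = SamplerControl(),
    n_sims: int = 100,
    metrics: tuple[str, ...] = DEFAULT_METRICS,
    epsilon: float = 0.1,
) -> ComparisonMatrix:
    """Simulate every ordered (model-year, target-year) pair.

    For each pair, ``n_sims`` networks are simulated on the target year's
    nodes, covariates and starting network using the model year's fitted
    coefficients, and predictive distances are recorded per metric.
    """
    years = sorted(networks)
    if len(years) < 2:
        raise ValueError("need at least 2 years for a cross-year comparison")
    if set(fits) != set(networks):
        raise ValueError("fits and networks must cover the same years")
    for y in years:
        if not fits[y].converged:
            raise ValueError(f"fit for year {y} is not converged")
    closc = {y: _closeness_for(networks[y], spec, None, epsilon)
             for y in years}
    matrix = ComparisonMatrix(
        years, {y: networks[y].n for y in years}, tuple(metrics))
    for mi, my in enumerate(years):
        theta = fits[my].theta_hat
        for ti, ty in enumerate(years):
            target = networks[ty]
            ctl = replace(control, seed=derive_seed(control.seed, mi, ti))
            sims = simulate_networks(target, theta, spec, n_sims, ctl,
                                     closc[ty])
            cell = {}
            for metric in metrics:
                cell[metric] = predictive_distances(target, sims, metric,
                                                    my, ty)
            matrix.cells[(my, ty)] = cell
    return matrix


def within_between_test(matrix: ComparisonMatrix, metric: str,
                        alternative: str = "two-sided") -> RankSumResult:
    """Rank-sum test of Y within-year vs Y(Y-1) between-year mean
    predictive distances.  A non-significant difference is the stability
    signature: other years predict a network as well as its own year."""
    if metric not in matrix.metrics:
        raise ValueError(f"metric {metric!r} not present in matrix")
    expected = len(matrix.years) ** 2
    if len(matrix.cells) != expected:
        raise ValueError("comparison matrix is incomplete")
    return rank_sum_test(matrix.within_means(metric),
                         matrix.between_means(metric), alternative)


def _symmetrised_distance(matrix: ComparisonMatrix, metric: str) -> np.ndarray:
    """Between-year mean distances averaged over the two orientations of
    each unordered pair (distance matrices must be symmetric)."""
    years = matrix.years
    k = len(years)
    d = np.zeros((k, k))
    for i, a in enumerate(years):
        for j, b in enumerate(years):
            if i == j:
                continue
            d[i, j] = 0.5 * (matrix.mean_distance(a, b, metric)
                             + matrix.mean_distance(b, a, metric))
    return d


def distance_correlates(
    matrix: ComparisonMatrix,
    metric: str,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> dict[str, MantelResult]:
    """Mantel tests of mean predictive distance against year-gap and
    population-size-gap matrices.

    A positive size-gap association with a null year-gap association is
    the signature that predictability tracks population size rather than
    elapsed time.
    """
    years = np.array(matrix.years, float)
    sizes = np.array([matrix.sizes[y] for y in matrix.years], float)
    if len(years) < 4:
        warnings.warn(
            "fewer than 4 years: Mantel permutation support is very small",
            stacklevel=2,
        )
    d_pred = _symmetrised_distance(matrix, metric)
    d_year = np.abs(years[:, None] - years[None, :])
    d_size = np.abs(sizes[:, None] - sizes[None, :])
    out = {}
    iu = np.triu_indices(len(years), 1)
    pred_constant = np.ptp(d_pred[iu]) == 0
    for name, gap, salt in (("year_gap", d_year, 11), ("size_gap", d_size, 13)):
        off = gap[iu]
        # no variation to correlate (e.g. equal-size design)
        if np.ptp(off) == 0 or pred_constant:
            out[name] = MantelResult(float("nan"), float("nan"), n_perm,
                                     seed, alternative, "degenerate")
            continue
        out[name] = mantel_test(d_pred, gap, n_perm, derive_seed(seed, salt),
                                alternative)
    return out
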