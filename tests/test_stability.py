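import numpy as np
import pytest

from netgenstab import (
    ComparisonMatrix,
    ERGMSpec,
    FitControl,
    SYNTH_THETA,
    SamplerControl,
    TERMS,
    ThetaVector,
    closeness_matrix,
    cross_year_matrix,
    distance_correlates,
    efficacy_comparison,
    predictive_distances,
    simulate_from_ergm,
    stationary_scenario,
    build_scenario,
    within_between_test,
)
from netgenstab.ergm_estimate import FitResult
from netgenstab.stability import PredictiveDistanceSet

from conftest import make_nodes
from netgenstab.synthdata import generate_population


def fake_fit(theta: ThetaVector) -> FitResult:
    """A converged FitResult wrapping known coefficients (no fitting)."""
    se = np.full(len(theta.terms), 0.1)
    return FitResult(theta, se, 0, True, theta.values[None, :])


def manual_matrix(years, sizes, mean_fn, metric="path_length"):
    """Build a ComparisonMatrix with prescribed cell means directly."""
    mat = ComparisonMatrix(list(years), dict(zip(years, sizes)), (metric,))
    for a in years:
        for b in years:
            mat.cells[(a, b)] = {
                metric: PredictiveDistanceSet(
                    a, b, metric, np.full(5, float(mean_fn(a, b))))
            }
    return mat


class TestPredictiveDistances:
    def test_absolute_distances(self):
        nodes = generate_population(30, rng=np.random.default_rng(0))
        net = simulate_from_ergm(nodes, SYNTH_THETA, seed=1)
        from netgenstab import simulate_networks

        sims = simulate_networks(net, SYNTH_THETA, ERGMSpec(), 10,
                                 SamplerControl(seed=2, burnin_mult=5,
                                                interval_mult=2),
                                 closeness_matrix(nodes))
        pds = predictive_distances(net, sims, "path_length")
        assert (pds.distances >= 0).all()
        assert pds.mean_distance == pytest.approx(pds.distances.mean())

    def test_empty_batch_rejected(self):
        nodes = generate_population(20, rng=np.random.default_rng(1))
        net = simulate_from_ergm(nodes, SYNTH_THETA, seed=3)
        with pytest.raises(ValueError):
            predictive_distances(net, [], "clustering")


class TestEfficacy:
    def test_identical_arms_are_indistinguishable(self):
        """When the 'full' coefficients already equal the reduced ones,
        both arms sample the same model and the rank-sum test is null."""
        nodes = generate_population(40, rng=np.random.default_rng(2))
        theta = ThetaVector(
            TERMS, [0.4, -3.5, 0.0, 0.0, 0.0, 0.0])
        net = simulate_from_ergm(nodes, theta, seed=4)
        res = efficacy_comparison(
            net, fake_fit(theta), ERGMSpec(),
            SamplerControl(seed=5, burnin_mult=20, interval_mult=4),
            n_sims=30, metrics=("path_length",))
        assert res["path_length"]["test"].p > 0.05

    def test_structural_terms_improve_clustering_prediction(self):
        """A transitive, spatially structured truth: the full model gives
        smaller clustering predictive distances than cmp+nonzero only."""
        nodes = generate_population(70, rng=np.random.default_rng(3))
        theta = ThetaVector(TERMS, [0.5, -4.0, 0.55, -0.05, -0.45, 0.40])
        net = simulate_from_ergm(nodes, theta, seed=6)
        res = efficacy_comparison(
            net, fake_fit(theta), ERGMSpec(),
            SamplerControl(seed=7, burnin_mult=20, interval_mult=4),
            n_sims=50, metrics=("clustering",))
        cell = res["clustering"]
        assert cell["full"].mean_distance < cell["reduced"].mean_distance
        assert cell["test"].p < 0.05

    def test_unconverged_fit_rejected(self):
        nodes = generate_population(20, rng=np.random.default_rng(4))
        net = simulate_from_ergm(nodes, SYNTH_THETA, seed=8)
        bad = fake_fit(SYNTH_THETA)
        bad.converged = False
        with pytest.raises(ValueError):
            efficacy_comparison(net, bad)


class TestCrossYearMatrix:
    def test_six_years_give_6_within_30_between(self):
        # a denser truth so every tiny network has defined metrics
        dense = ThetaVector(TERMS, [0.3, -2.2, 0.3, 0.0, -0.3, 0.2])
        cfg = stationary_scenario(sizes=(24,) * 6,
                                  years=(2006, 2007, 2008, 2011, 2012, 2013),
                                  theta_star=dense, seed=5)
        sc = build_scenario(cfg)
        years = [y for y, _ in cfg.years]
        nets = {y: sc[y]["network"] for y in years}
        fits = {y: fake_fit(SYNTH_THETA) for y in years}
        mat = cross_year_matrix(
            nets, fits, ERGMSpec(),
            SamplerControl(seed=6, burnin_mult=3, interval_mult=1),
            n_sims=4)
        assert len(mat.cells) == 36
        assert mat.n_within == 6
        assert mat.n_between == 30

    def test_single_year_rejected(self):
        cfg = stationary_scenario(sizes=(24, 24), years=(2006, 2007), seed=6)
        sc = build_scenario(cfg)
        nets = {2006: sc[2006]["network"]}
        with pytest.raises(ValueError):
            cross_year_matrix(nets, {2006: fake_fit(SYNTH_THETA)})

    def test_replicate_years_within_equals_between(self):
        """Two years that are replicate draws from the same coefficients:
        within and between distances are statistically indistinguishable."""
        cfg = stationary_scenario(sizes=(50, 50), years=(2006, 2007), seed=7)
        sc = build_scenario(cfg)
        nets = {y: sc[y]["network"] for y in (2006, 2007)}
        fits = {y: fake_fit(SYNTH_THETA) for y in (2006, 2007)}
        mat = cross_year_matrix(
            nets, fits, ERGMSpec(),
            SamplerControl(seed=8, burnin_mult=20, interval_mult=4),
            n_sims=30)
        from netgenstab import rank_sum_test

        for metric in ("path_length", "clustering"):
            within = np.concatenate([
                mat.cells[(y, y)][metric].distances for y in (2006, 2007)])
            between = np.concatenate([
                mat.cells[(a, b)][metric].distances
                for a in (2006, 2007) for b in (2006, 2007) if a != b])
            assert rank_sum_test(within, between).p > 0.01


class TestDriftingContrast:
    def test_decaying_transitivity_couples_distance_to_year_gap(self):
        """A truth whose transitivity decays over years: between-year
        predictive distance correlates positively with the year gap
        (the contrast case to the stability null)."""
        from netgenstab import drifting_scenario

        cfg = drifting_scenario(sizes=(90,) * 5,
                                years=(2006, 2008, 2010, 2012, 2014),
                                drift=0.11, seed=11)
        sc = build_scenario(cfg)
        years = [y for y, _ in cfg.years]
        nets = {y: sc[y]["network"] for y in years}
        # true coefficients stand in for fits: this isolates the
        # cross-simulation and Mantel machinery from estimation noise
        fits = {y: fake_fit(cfg.theta_for(y)) for y in years}
        mat = cross_year_matrix(
            nets, fits, ERGMSpec(),
            SamplerControl(seed=12, burnin_mult=30, interval_mult=5),
            n_sims=30)
        res = distance_correlates(mat, "clustering", seed=13)
        assert res["year_gap"].rho > 0.3

    def test_within_cell_consistent_with_refitting_noise(self):
        """A within-year cell's mean distance is no larger than the upper
        tail of distances generated under an independent refit of the
        same network (calibration of the within-cell scale)."""
        from netgenstab import FitControl, simulate_networks
        from netgenstab.stability import fit_years, predictive_distances

        nodes = generate_population(60, rng=np.random.default_rng(14))
        net = simulate_from_ergm(nodes, SYNTH_THETA, seed=15)
        clos = closeness_matrix(nodes)
        fits = [fit_years({2006: net}, ERGMSpec(),
                          FitControl(seed=s, n_sims=128, burnin_mult=10,
                                     interval_mult=1),
                          max_restarts=1)[2006] for s in (16, 17)]
        assert all(f.converged for f in fits)
        dists = {}
        for k, f in enumerate(fits):
            sims = simulate_networks(
                net, f.theta_hat, ERGMSpec(), 30,
                SamplerControl(seed=18 + k, burnin_mult=30,
                               interval_mult=5), clos)
            dists[k] = predictive_distances(net, sims, "clustering")
        assert dists[0].mean_distance <= np.percentile(
            dists[1].distances, 97.5)


class TestWithinBetween:
    def test_all_cells_equal_gives_p_one(self):
        mat = manual_matrix([1, 2, 3], [10, 20, 30], lambda a, b: 1.0)
        res = within_between_test(mat, "path_length")
        assert res.p > 0.9

    def test_shifted_between_cells_detected(self):
        mat = manual_matrix([1, 2, 3, 4, 5, 6], [10] * 6,
                            lambda a, b: 1.0 if a == b else 11.0)
        res = within_between_test(mat, "path_length")
        assert res.p < 0.01
        assert res.n_a == 6 and res.n_b == 30

    def test_incomplete_matrix_rejected(self):
        mat = manual_matrix([1, 2, 3], [10, 20, 30], lambda a, b: 1.0)
        del mat.cells[(1, 2)]
        with pytest.raises(ValueError):
            within_between_test(mat, "path_length")


class TestDistanceCorrelates:
    def test_distance_proportional_to_size_gap(self):
        years = [2006, 2007, 2008, 2011, 2012, 2013]
        sizes = [79, 110, 161, 198, 208, 239]
        size_of = dict(zip(years, sizes))
        mat = manual_matrix(years, sizes,
                            lambda a, b: abs(size_of[a] - size_of[b]))
        res = distance_correlates(mat, "path_length", seed=1)
        assert res["size_gap"].rho == pytest.approx(1.0)

    def test_orientation_symmetrisation(self):
        """Swapping the (model, target) orientation convention leaves the
        Mantel inputs, and hence the results, unchanged."""
        years = [1, 2, 3, 4, 5]
        rng = np.random.default_rng(3)
        vals = {}
        for a in years:
            for b in years:
                if a != b:
                    vals[(a, b)] = float(rng.random())
        mat1 = manual_matrix(years, [10, 30, 20, 50, 40],
                             lambda a, b: vals.get((a, b), 0.0))
        mat2 = manual_matrix(years, [10, 30, 20, 50, 40],
                             lambda a, b: vals.get((b, a), 0.0))
        r1 = distance_correlates(mat1, "path_length", seed=2)
        r2 = distance_correlates(mat2, "path_length", seed=2)
        assert r1["size_gap"].rho == pytest.approx(r2["size_gap"].rho)
        assert r1["year_gap"].p == pytest.approx(r2["year_gap"].p)

    def test_equal_sizes_yield_degenerate_result(self):
        mat = manual_matrix([1, 2, 3, 4], [10] * 4, lambda a, b: 1.0)
        res = distance_correlates(mat, "path_length", seed=3)
        assert res["size_gap"].method == "degenerate"
        assert np.isnan(res["size_gap"].rho)

    def test_few_years_warns(self):
        mat = manual_matrix([1, 2, 3], [10, 20, 30], lambda a, b: 1.0)
        with pytest.warns(UserWarning, match="fewer than 4"):
            distance_correlates(mat, "path_length", seed=4)
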