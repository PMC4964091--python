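import json
import math
from itertools import product

import numpy as np
import pytest

from netgenstab import (
    ERGMSpec,
    SamplerControl,
    TERMS,
    ThetaVector,
    ValuedNetwork,
    calibrate_sum_offset,
    closeness_matrix,
    mcmc_step,
    simulate_networks,
    sufficient_statistics,
    write_simulation_batch,
)

from conftest import make_nodes


def empty_net(n, seed=0):
    return ValuedNetwork(make_nodes(n, seed), np.zeros((n, n), np.int64))


def batch_se(per_net_values):
    v = np.asarray(per_net_values, float)
    return v.std(ddof=1) / math.sqrt(len(v))


class TestContracts:
    def test_batch_shape_and_validity(self):
        net = empty_net(10)
        theta = ThetaVector(TERMS, np.zeros(6))
        sims = simulate_networks(net, theta, ERGMSpec(), 20,
                                 SamplerControl(seed=1),
                                 closeness_matrix(net.nodes))
        assert len(sims) == 20
        for s in sims:
            assert np.array_equal(s.weights, s.weights.T)
            assert s.weights.dtype.kind == "i"
            assert (np.diagonal(s.weights) == 0).all()

    def test_same_seed_is_deterministic(self):
        net = empty_net(8)
        theta = ThetaVector(("nonzero",), [-1.0])
        spec = ERGMSpec(terms=("nonzero",))
        a = simulate_networks(net, theta, spec, 5, SamplerControl(seed=9))
        b = simulate_networks(net, theta, spec, 5, SamplerControl(seed=9))
        for x, y in zip(a, b):
            assert np.array_equal(x.weights, y.weights)
        c = simulate_networks(net, theta, spec, 5, SamplerControl(seed=10))
        assert any(not np.array_equal(x.weights, y.weights)
                   for x, y in zip(a, c))

    def test_mcmc_step_preserves_invariants(self):
        net = empty_net(5)
        theta = ThetaVector(TERMS, np.zeros(6))
        rng = np.random.default_rng(0)
        for _ in range(50):
            net = mcmc_step(net, theta, ERGMSpec(), SamplerControl(),
                            rng, closeness_matrix(net.nodes))
        assert np.array_equal(net.weights, net.weights.T)
        assert (net.weights >= 0).all()

    def test_nonfinite_theta_rejected(self):
        net = empty_net(5)
        with pytest.raises(ValueError):
            ThetaVector(("nonzero",), [np.nan])


class TestClosedForms:
    def test_zero_theta_gives_poisson_one_weights(self):
        """With no model terms the Poisson reference makes dyad weights
        iid Poisson(1); the sample mean must sit within 3 MC SE of 1."""
        net = empty_net(12, seed=3)
        theta = ThetaVector(TERMS, np.zeros(6))
        sims = simulate_networks(net, theta, ERGMSpec(), 150,
                                 SamplerControl(seed=5),
                                 closeness_matrix(net.nodes))
        iu = np.triu_indices(12, 1)
        means = [s.weights[iu].mean() for s in sims]
        se = batch_se(means)
        assert abs(np.mean(means) - 1.0) < 3 * se + 1e-9
        # variance is also ~1 for Poisson(1)
        allw = np.concatenate([s.weights[iu] for s in sims])
        assert abs(allw.var() - 1.0) < 0.05

    def test_nonzero_only_zero_probability(self):
        """P(y_ij = 0) = 1 / (1 + e^theta (e - 1)) for the sparsity-only
        model (analytic normalisation over counts)."""
        th = -2.0
        net = empty_net(12, seed=4)
        spec = ERGMSpec(terms=("nonzero",))
        sims = simulate_networks(net, ThetaVector(("nonzero",), [th]), spec,
                                 150, SamplerControl(seed=7))
        iu = np.triu_indices(12, 1)
        p0s = [(s.weights[iu] == 0).mean() for s in sims]
        theory = 1.0 / (1.0 + math.exp(th) * (math.e - 1.0))
        assert abs(np.mean(p0s) - theory) < 3 * batch_se(p0s) + 1e-9

    def test_geometric_proposal_same_stationary_distribution(self):
        net = empty_net(10, seed=5)
        theta = ThetaVector(TERMS, np.zeros(6))
        sims = simulate_networks(
            net, theta, ERGMSpec(), 100,
            SamplerControl(seed=6, proposal="geometric"),
            closeness_matrix(net.nodes))
        iu = np.triu_indices(10, 1)
        means = [s.weights[iu].mean() for s in sims]
        assert abs(np.mean(means) - 1.0) < 3 * batch_se(means) + 1e-9


class TestDetailedBalance:
    def test_empirical_matches_exact_enumeration(self, nodes3):
        """3 nodes, counts capped at 3: the long-run state frequencies
        match the exactly enumerated Gibbs distribution."""
        clos = closeness_matrix(nodes3)
        theta = ThetaVector(TERMS, [0.3, -0.5, 0.8, 0.2, -0.4, 0.1])
        spec = ERGMSpec()

        def log_prob(wvec):
            w = np.zeros((3, 3), np.int64)
            w[0, 1] = w[1, 0] = wvec[0]
            w[0, 2] = w[2, 0] = wvec[1]
            w[1, 2] = w[2, 1] = wvec[2]
            g = sufficient_statistics(ValuedNetwork(nodes3, w), spec, clos)
            h = -sum(math.lgamma(x + 1) for x in wvec)
            return h + float(theta.values @ g)

        states = list(product(range(4), repeat=3))
        lp = np.array([log_prob(s) for s in states])
        exact = np.exp(lp - lp.max())
        exact /= exact.sum()

        ctl = SamplerControl(burnin=2000, interval=3, seed=11, max_weight=3)
        sims = simulate_networks(ValuedNetwork(nodes3, np.zeros((3, 3), int)),
                                 theta, spec, 100_000, ctl, clos)
        counts = {}
        for s in sims:
            key = (s.weights[0, 1], s.weights[0, 2], s.weights[1, 2])
            counts[key] = counts.get(key, 0) + 1
        emp = np.array([counts.get(s, 0) / len(sims) for s in states])
        assert 0.5 * np.abs(emp - exact).sum() < 0.02  # total variation


class TestMonotoneProperties:
    def test_dispersion_increases_with_cmp(self):
        """Var/mean of dyad weights rises with the CMP coefficient."""
        net = empty_net(10, seed=8)
        iu = np.triu_indices(10, 1)
        vms = []
        for cmp_coef in (-0.5, 0.0, 0.5):
            theta = ThetaVector(("cmp", "nonzero"), [cmp_coef, -1.0])
            sims = simulate_networks(net, theta,
                                     ERGMSpec(terms=("cmp", "nonzero")),
                                     80, SamplerControl(seed=21))
            allw = np.concatenate([s.weights[iu] for s in sims])
            vms.append(allw.var() / allw.mean())
        assert vms[0] < vms[1] < vms[2]

    def test_sparsity_increases_as_nonzero_drops(self):
        net = empty_net(10, seed=9)
        iu = np.triu_indices(10, 1)
        dens = []
        for nz in (0.0, -1.0, -2.5):
            theta = ThetaVector(("nonzero",), [nz])
            sims = simulate_networks(net, theta,
                                     ERGMSpec(terms=("nonzero",)),
                                     60, SamplerControl(seed=22))
            dens.append(np.mean([(s.weights[iu] > 0).mean() for s in sims]))
        assert dens[0] > dens[1] > dens[2]


class TestFieldCoefficientSimulation:
    def test_chain_vs_chain_agreement_at_field_theta(self):
        """Conditioned simulation from the published 2006 coefficients on
        a 79-node synthetic template: two independent chains agree on mean
        sufficient statistics within Monte-Carlo error."""
        from netgenstab import FIELD_THETA, aggregate_events, \
            closeness_matrix, simulate_mechanistic
        from netgenstab.synthdata import ScenarioConfig, generate_population
        from netgenstab.ergm_estimate import _mcse

        cfg = ScenarioConfig(seed=6)
        rng = np.random.default_rng(60)
        nodes = generate_population(79, cfg, rng, year=2006)
        template = aggregate_events(simulate_mechanistic(nodes, cfg, rng),
                                    nodes)
        clos = closeness_matrix(nodes)
        theta = FIELD_THETA[2006]
        stats = {}
        for seed in (1, 2):
            stats[seed] = simulate_networks(
                template, theta, ERGMSpec(), 40,
                SamplerControl(seed=seed, burnin_mult=20, interval_mult=5),
                clos, return_stats=True)
        diff = stats[1].mean(axis=0) - stats[2].mean(axis=0)
        se = np.sqrt(_mcse(stats[1]) ** 2 + _mcse(stats[2]) ** 2)
        assert np.all(np.abs(diff) < 4 * se + 1e-9)


class TestCalibration:
    def test_sum_offset_matches_total_weight(self):
        rng = np.random.default_rng(1)
        n = 20
        w = (rng.random((n, n)) < 0.2).astype(np.int64)
        w = np.triu(w, 1)
        w = w + w.T
        net = ValuedNetwork(make_nodes(n, 1), w)
        theta = ThetaVector(("nonzero",), [-3.0])
        spec = ERGMSpec(terms=("nonzero",))
        ctl = SamplerControl(seed=3)
        offset = calibrate_sum_offset(net, theta, spec, ctl, n_probe=40)
        sims = simulate_networks(
            net, theta, spec, 60,
            SamplerControl(seed=99, burnin_mult=40, interval_mult=5,
                           sum_offset=offset))
        mean_total = np.mean([s.total_weight for s in sims])
        assert abs(mean_total - net.total_weight) < 0.15 * net.total_weight
        # and without the offset the plain model badly under-produces
        plain = simulate_networks(
            net, theta, spec, 30,
            SamplerControl(seed=98, burnin_mult=40, interval_mult=5))
        assert np.mean([s.total_weight for s in plain]) < 0.7 * net.total_weight


class TestBatchExport:
    def test_manifest_and_files(self, tmp_path):
        net = empty_net(6)
        theta = ThetaVector(("nonzero",), [-1.0])
        ctl = SamplerControl(seed=2)
        sims = simulate_networks(net, theta, ERGMSpec(terms=("nonzero",)),
                                 3, ctl)
        write_simulation_batch(tmp_path / "batch", sims, theta, ctl, net)
        manifest = json.loads((tmp_path / "batch" / "manifest.json").read_text())
        assert manifest["n_sims"] == 3
        assert manifest["theta"]["values"] == [-1.0]
        assert len(list((tmp_path / "batch").glob("sim_*.csv"))) == 3
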