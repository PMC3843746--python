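"""Ring-labeling Monte Carlo: geometry, counting rules, distributions."""

import itertools
import math

import numpy as np
import pytest

from fretcal import (
    DomainError,
    InvalidInputError,
    RingConfig,
    apply_maturation,
    assign_labels,
    bias_correction_factor,
    count_fret_pairs,
    enumerate_distribution,
    ring_distances,
    scan_donor_abundance,
    simulate_distribution,
)


def brute_pair_count(labels, fluor, adj):
    """Independent oracle: enumerate all position pairs."""
    n = len(labels)
    count = 0
    for i, j in itertools.combinations(range(n), 2):
        if not adj[i, j]:
            continue
        if fluor[i] and fluor[j] and labels[i] != labels[j]:
            count += 1
    return count


def brute_donor_count(labels, fluor, adj):
    count = 0
    for d in range(len(labels)):
        if not (labels[d] and fluor[d]):
            continue
        if any(adj[d, a] and (not labels[a]) and fluor[a] for a in range(len(labels))):
            count += 1
    return count


def nx_matching(labels, fluor, adj):
    """Independent maximum-matching oracle via networkx Hopcroft-Karp."""
    import networkx as nx

    g = nx.Graph()
    donors = [i for i in range(len(labels)) if labels[i] and fluor[i]]
    acceptors = [j for j in range(len(labels)) if (not labels[j]) and fluor[j]]
    g.add_nodes_from((f"d{i}" for i in donors), bipartite=0)
    g.add_nodes_from((f"a{j}" for j in acceptors), bipartite=1)
    for i in donors:
        for j in acceptors:
            if adj[i, j]:
                g.add_edge(f"d{i}", f"a{j}")
    if not donors or not acceptors:
        return 0
    match = nx.bipartite.maximum_matching(g, top_nodes=[f"d{i}" for i in donors])
    return sum(1 for k in match if k.startswith("d"))


class TestGeometry:
    def test_chord_distances_of_default_ring(self):
        d = ring_distances(13, 25.0)
        assert d[0, 1] == pytest.approx(25 * math.sin(math.pi / 13))
        assert d[0, 1] == pytest.approx(5.98, abs=5e-3)
        assert d[0, 2] == pytest.approx(11.62, abs=5e-3)
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)

    def test_spacing_mode_reproduces_lattice_spacing_exactly(self):
        d = ring_distances(13, adjacent_spacing_nm=6.15)
        assert d[0, 1] == pytest.approx(6.15, rel=1e-12)

    def test_two_position_ring(self):
        d = ring_distances(2, 10.0)
        assert d[0, 1] == pytest.approx(10.0)

    def test_single_position_rejected(self):
        with pytest.raises(InvalidInputError):
            ring_distances(1, 25.0)

    def test_second_neighbours_outside_default_fret_radius(self):
        adj = RingConfig().adjacency()
        assert adj[0, 1] and adj[0, 12]
        assert not adj[0, 2]
        assert adj.sum() == 2 * 13  # the 13-cycle


class TestLabelingAndMaturation:
    def test_all_donor_probability_one(self, rng):
        cfg = RingConfig(p_donor=1.0)
        assert assign_labels(cfg, rng).all()

    def test_fixed_counts_zero_gives_all_acceptors(self, rng):
        cfg = RingConfig(labeling="fixed_counts", n_donor=0)
        assert not assign_labels(cfg, rng).any()

    def test_fixed_counts_invariant(self, rng):
        cfg = RingConfig(labeling="fixed_counts", n_donor=6)
        for _ in range(50):
            assert assign_labels(cfg, rng).sum() == 6

    def test_n_donor_exceeding_positions_rejected(self):
        with pytest.raises(InvalidInputError):
            RingConfig(labeling="fixed_counts", n_donor=14)

    def test_full_maturation_keeps_everything_fluorescent(self, rng):
        cfg = RingConfig()
        labels = assign_labels(cfg, rng)
        assert apply_maturation(labels, cfg, rng).all()

    def test_zero_acceptor_maturation_darkens_all_acceptors(self, rng):
        cfg = RingConfig(maturation_acceptor=0.0)
        labels = np.zeros(13, dtype=bool)  # all acceptors
        assert not apply_maturation(labels, cfg, rng).any()

    def test_maturation_binomial_mean(self, rng):
        cfg = RingConfig(maturation_acceptor=0.25)
        labels = np.zeros((10_000, 10), dtype=bool)
        fluor = apply_maturation(labels, cfg, rng)
        counts = fluor.sum(axis=1)
        se = counts.std(ddof=1) / math.sqrt(counts.size)
        assert abs(counts.mean() - 2.5) <= 3 * se


class TestCounting:
    def test_all_donors_count_zero_in_every_mode(self):
        d = ring_distances(13, 25.0)
        labels = np.ones(13, dtype=bool)
        fluor = np.ones(13, dtype=bool)
        for mode in ("pair_count", "donor_count", "matching"):
            assert count_fret_pairs(labels, fluor, d, 10.0, mode) == 0

    def test_alternating_labels_against_brute_force(self):
        d = ring_distances(13, 25.0)
        adj = d <= 10.0
        np.fill_diagonal(adj, False)
        labels = np.array([i % 2 == 0 for i in range(13)])  # 7 donors
        fluor = np.ones(13, dtype=bool)
        assert count_fret_pairs(labels, fluor, d, 10.0, "pair_count") == \
            brute_pair_count(labels, fluor, adj)
        assert count_fret_pairs(labels, fluor, d, 10.0, "donor_count") == \
            brute_donor_count(labels, fluor, adj)
        assert count_fret_pairs(labels, fluor, d, 10.0, "matching") == \
            nx_matching(labels, fluor, adj)

    def test_random_configurations_against_oracles(self, rng):
        d = ring_distances(13, 25.0)
        adj = d <= 10.0
        np.fill_diagonal(adj, False)
        for _ in range(60):
            labels = rng.random(13) < rng.uniform(0.2, 0.8)
            fluor = rng.random(13) < rng.uniform(0.3, 1.0)
            pc = count_fret_pairs(labels, fluor, d, 10.0, "pair_count")
            dc = count_fret_pairs(labels, fluor, d, 10.0, "donor_count")
            mt = count_fret_pairs(labels, fluor, d, 10.0, "matching")
            assert pc == brute_pair_count(labels, fluor, adj)
            assert dc == brute_donor_count(labels, fluor, adj)
            assert mt == nx_matching(labels, fluor, adj)
            # structural inequality for saturating vs permissive rules
            assert mt <= dc <= pc

    def test_unknown_mode_rejected(self):
        d = ring_distances(13, 25.0)
        with pytest.raises(InvalidInputError):
            count_fret_pairs(np.ones(13, bool), np.ones(13, bool), d, 10.0, "bogus")


class TestDistributions:
    def test_unbiased_bernoulli_mean_matches_analytic(self):
        # 13 cycle edges, each mixed with probability 1/2 -> mean 13/2
        res = simulate_distribution(RingConfig(seed=11))
        assert abs(res.mean - 6.5) <= 3 * res.se
        assert res.histogram.sum() == pytest.approx(1.0, abs=1e-12)

    def test_seeded_reproducibility(self):
        cfg = RingConfig(seed=123, replicates=500)
        r1 = simulate_distribution(cfg)
        r2 = simulate_distribution(cfg)
        assert r1.mean == r2.mean
        assert np.array_equal(r1.histogram, r2.histogram)

    def test_single_replicate_deterministic(self):
        cfg = RingConfig(seed=7, replicates=1)
        assert simulate_distribution(cfg).mean == simulate_distribution(cfg).mean

    def test_fixed_counts_match_exhaustive_enumeration(self):
        for g in (2, 6, 10):
            cfg = RingConfig(labeling="fixed_counts", n_donor=g, seed=5,
                             replicates=4000)
            sim = simulate_distribution(cfg)
            exact = enumerate_distribution(cfg)
            assert exact.mean == pytest.approx(g * (13 - g) / 6, rel=1e-12)
            assert abs(sim.mean - exact.mean) <= 3 * sim.se

    def test_enumeration_requires_full_maturation(self):
        with pytest.raises(InvalidInputError):
            enumerate_distribution(RingConfig(maturation_acceptor=0.5))

    def test_donor_acceptor_exchange_symmetry(self):
        # swapping donor/acceptor counts leaves pair statistics unchanged
        for g in (3, 5):
            a = enumerate_distribution(
                RingConfig(labeling="fixed_counts", n_donor=g))
            b = enumerate_distribution(
                RingConfig(labeling="fixed_counts", n_donor=13 - g))
            assert a.mean == pytest.approx(b.mean, rel=1e-12)
            assert np.allclose(a.histogram, b.histogram)

    def test_counts_bounded(self):
        res = simulate_distribution(RingConfig(seed=2, replicates=2000))
        assert len(res.histogram) - 1 <= 13**2 / 4
        resm = simulate_distribution(
            RingConfig(seed=2, replicates=2000, counting_mode="matching"))
        assert len(resm.histogram) - 1 <= 6  # min(#donors, #acceptors) <= 6


class TestScansAndBias:
    def test_scan_endpoints_are_zero(self):
        scan = scan_donor_abundance(
            RingConfig(labeling="fixed_counts", n_donor=0, seed=9,
                       replicates=2000))
        t = scan.table.set_index("n_donor")
        assert t.loc[0, "mean_pairs"] == 0.0
        assert t.loc[13, "mean_pairs"] == 0.0

    def test_full_maturation_optimum_near_balanced(self):
        scan = scan_donor_abundance(
            RingConfig(labeling="fixed_counts", n_donor=0, seed=9,
                       replicates=4000))
        assert set(scan.maximizing_set) <= {6, 7}
        assert 6.0 <= scan.midpoint <= 7.0

    def test_balanced_abundance_needs_no_correction(self):
        cfg = RingConfig(seed=21, replicates=4000)
        assert bias_correction_factor(cfg, 6) == pytest.approx(1.0, abs=0.05)

    def test_bias_factor_matches_analytic_expectation_ratio(self):
        # E[pairs | g] = g(13-g)/6, so factor(3) = 7 / 5 = 1.4
        cfg = RingConfig(seed=22, replicates=20_000)
        assert bias_correction_factor(cfg, 3) == pytest.approx(1.4, rel=0.03)

    def test_bias_factor_grows_with_imbalance(self):
        cfg = RingConfig(seed=23, replicates=10_000)
        factors = [bias_correction_factor(cfg, g) for g in (6, 4, 2, 1)]
        assert all(np.diff(factors) > 0)
        assert all(f >= 0.99 for f in factors)

    def test_zero_mean_bias_factor_diverges(self):
        with pytest.raises(DomainError):
            bias_correction_factor(RingConfig(seed=1, replicates=100), 0)
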