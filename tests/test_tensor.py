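import numpy as np
import pytest
from scipy import sparse

from oracles import (
    comodule_similarity_oracle,
    domain_similarity_oracle,
    module_density_oracle,
    topology_similarity_oracle,
)
from rwrt.io import ComplexCatalog, DomainAnnotation, PPINetwork, ProteinIndex
from rwrt.synth import SyntheticConfig, generate
from rwrt.tensor import (
    DomainContext,
    build_tensor,
    comodule_layer,
    costructure_layer,
    domain_context,
    domain_similarity,
    module_density,
    read_tensor,
    topology_layer,
    write_tensor,
)


def make_net(n, edges):
    index = ProteinIndex.from_ids(f"P{i:02d}" for i in range(n))
    return PPINetwork(index=index, edges=frozenset(tuple(sorted(e)) for e in edges))


def random_net(rng, n, p=0.3):
    edges = {
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p
    }
    return make_net(n, edges)


class TestTopologyLayer:
    def test_identical_closed_neighborhoods_score_one(self):
        net = make_net(2, [(0, 1)])  # N_0 = N_1 = {0, 1}
        layer = topology_layer(net)
        assert layer[0, 1] == pytest.approx(1.0)
        assert layer.nnz == 2  # the single pair, mirrored

    def test_partial_overlap_hand_value(self):
        # N_0 = {0, a}, N_1 = {1, a} with a = 2: 4*1 / ((2+1)(2+1)) = 4/9
        net = make_net(3, [(0, 2), (1, 2)])
        layer = topology_layer(net)
        assert layer[0, 1] == pytest.approx(4.0 / 9.0)

    def test_disjoint_neighborhoods_absent(self):
        net = make_net(4, [(0, 1), (2, 3)])
        layer = topology_layer(net)
        assert layer[0, 2] == 0.0
        assert layer[1, 3] == 0.0

    def test_matches_set_arithmetic_oracle_on_random_graphs(self):
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(30):
            net = random_net(rng, int(rng.integers(3, 10)))
            layer = topology_layer(net).toarray()
            closed = net.closed_neighborhoods()
            for i in range(net.n):
                for j in range(i + 1, net.n):
                    expected = topology_similarity_oracle(set(closed[i]), set(closed[j]))
                    assert layer[i, j] == pytest.approx(expected, rel=1e-9, abs=1e-15)
                    checked += 1
        assert checked >= 200

    def test_values_bounded_by_one_and_symmetric(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            layer = topology_layer(random_net(rng, 12, p=0.4))
            assert layer.data.max() <= 1.0 + 1e-12
            assert (abs(layer - layer.T)).nnz == 0
            assert np.all(layer.diagonal() == 0.0)


class TestDomainSimilarity:
    def test_worked_example_sets(self):
        # the canonical illustration: D_A = {1..5}, D_B = {5,6,7}, DC = {5}
        d_a = frozenset({1, 2, 3, 4, 5})
        d_b = frozenset({5, 6, 7})
        for dt in (8, 10, 20):
            expected = domain_similarity_oracle(set(d_a), set(d_b), dt)
            assert domain_similarity(d_a, d_b, dt) == pytest.approx(expected, rel=1e-9)

    def test_matches_exact_binomial_oracle_randomized(self):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 250:
            dt = int(rng.integers(2, 41))
            universe = list(range(dt))
            d_i = set(rng.choice(universe, size=rng.integers(1, dt + 1), replace=False))
            d_j = set(rng.choice(universe, size=rng.integers(1, dt + 1), replace=False))
            got = domain_similarity(frozenset(d_i), frozenset(d_j), dt)
            want = domain_similarity_oracle(d_i, d_j, dt)
            assert got == pytest.approx(want, rel=1e-9, abs=1e-9)
            checked += 1

    def test_all_domains_shared(self):
        universe = frozenset(range(12))
        got = domain_similarity(universe, universe, 12)
        assert got == pytest.approx(domain_similarity_oracle(set(universe), set(universe), 12), rel=1e-9)

    def test_undefined_binomial_raises(self):
        with pytest.raises(ValueError, match="undefined binomial"):
            domain_similarity(frozenset(range(5)), frozenset(range(3)), 4)

    def test_nonnegative(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            dt = int(rng.integers(2, 30))
            d_i = set(rng.choice(dt, size=rng.integers(1, dt + 1), replace=False))
            d_j = set(rng.choice(dt, size=rng.integers(1, dt + 1), replace=False))
            assert domain_similarity(frozenset(d_i), frozenset(d_j), dt) >= -1e-12


class TestCostructureLayer:
    def test_minmax_endpoints(self):
        ctx = DomainContext(
            context_of=(
                frozenset({"a", "b", "c"}),
                frozenset({"a", "b", "c"}),
                frozenset({"a", "z"}),
                frozenset({"q"}),
            ),
            universe=frozenset("abczq"),
        )
        layer = costructure_layer(ctx)
        vals = layer[layer.nonzero()]
        assert layer.toarray().max() == pytest.approx(1.0)
        # the minimum-DS pair is mapped to 0 and therefore absent
        assert layer[0, 3] == 0.0

    def test_single_computed_pair_degenerate_rule(self):
        ctx = DomainContext(
            context_of=(frozenset({"a"}), frozenset({"a"}), frozenset()),
            universe=frozenset({"a", "b"}),
        )
        layer = costructure_layer(ctx)
        assert layer[0, 1] == 1.0
        assert layer.nnz == 2

    def test_monotone_in_raw_similarity(self):
        rng = np.random.default_rng(17)
        universe = [f"d{k}" for k in range(12)]
        sets = [
            frozenset(rng.choice(universe, size=rng.integers(1, 8), replace=False))
            for _ in range(10)
        ]
        ctx = DomainContext(context_of=tuple(sets), universe=frozenset(universe))
        layer = costructure_layer(ctx).toarray()
        pairs = [
            (i, j, domain_similarity(sets[i], sets[j], len(universe)))
            for i in range(10)
            for j in range(i + 1, 10)
            if sets[i] & sets[j]
        ]
        for (i1, j1, ds1) in pairs:
            for (i2, j2, ds2) in pairs:
                if ds1 > ds2:
                    assert layer[i1, j1] >= layer[i2, j2] - 1e-12

    def test_no_shared_domains_empty_layer(self):
        ctx = DomainContext(
            context_of=(frozenset({"a"}), frozenset({"b"})), universe=frozenset({"a", "b"})
        )
        assert costructure_layer(ctx).nnz == 0

    def test_context_includes_neighbors_domains(self):
        net = make_net(3, [(0, 1)])
        domains = DomainAnnotation.from_map({1: {"d1"}}, 3)
        ctx = domain_context(net, domains)
        assert ctx.context_of[0] == {"d1"}  # inherited from neighbor
        assert ctx.context_of[2] == frozenset()


class TestComoduleLayer:
    def test_density_hand_values(self):
        net = make_net(3, [(0, 1), (1, 2), (0, 2)])
        assert module_density(frozenset({0, 1, 2}), net) == pytest.approx(1.0)
        net2 = make_net(3, [(0, 1), (1, 2)])
        assert module_density(frozenset({0, 1, 2}), net2) == pytest.approx(2.0 / 3.0)
        net3 = make_net(4, [(0, 1)])
        assert module_density(frozenset({2, 3}), net3) == 0.0

    def test_density_requires_two_members(self):
        net = make_net(2, [(0, 1)])
        with pytest.raises(ValueError):
            module_density(frozenset({0}), net)

    def test_single_shared_module_scores_one(self):
        net = make_net(3, [(0, 1)])
        cat = ComplexCatalog(modules=[frozenset({0, 1})])
        layer = comodule_layer(cat, net)
        assert layer[0, 1] == pytest.approx(1.0)

    def test_hand_value_two_modules(self):
        # i in modules A(0.5), B(1.0); j in A(0.5): (0.5)^2/((1.5)(0.5)) = 1/3
        net = make_net(5, [(0, 1), (0, 2), (2, 3), (3, 0), (2, 0)])
        cat = ComplexCatalog(modules=[frozenset({0, 1, 4}), frozenset({0, 2, 3})])
        layer = comodule_layer(cat, net)
        scores = cat.scores
        expected = comodule_similarity_oracle(0, 1, cat.modules, scores)
        assert layer[0, 1] == pytest.approx(expected, rel=1e-12)

    def test_matches_oracle_on_random_catalogs(self):
        rng = np.random.default_rng(23)
        checked = 0
        while checked < 200:
            n = int(rng.integers(4, 10))
            net = random_net(rng, n, p=0.5)
            modules = []
            for _ in range(rng.integers(1, 5)):
                size = int(rng.integers(2, n + 1))
                modules.append(frozenset(rng.choice(n, size=size, replace=False).tolist()))
            cat = ComplexCatalog(modules=modules)
            layer = comodule_layer(cat, net).toarray()
            scores = [module_density_oracle(set(m), net.edges) for m in modules]
            assert scores == pytest.approx(cat.scores, rel=1e-12)
            for i in range(n):
                for j in range(i + 1, n):
                    want = comodule_similarity_oracle(i, j, modules, scores)
                    assert layer[i, j] == pytest.approx(want, rel=1e-9, abs=1e-12)
                    assert layer[i, j] <= 1.0 + 1e-12
                    checked += 1

    def test_no_shared_module_absent(self):
        net = make_net(4, [(0, 1), (2, 3)])
        cat = ComplexCatalog(modules=[frozenset({0, 1}), frozenset({2, 3})])
        layer = comodule_layer(cat, net)
        assert layer[0, 2] == 0.0


class TestBuildTensor:
    def test_empty_domain_and_complex_data(self):
        net = make_net(3, [(0, 1), (1, 2)])
        tensor = build_tensor(
            net, DomainAnnotation.from_map({}, 3), ComplexCatalog(modules=[])
        )
        assert tensor.layers[0].nnz > 0
        assert tensor.layers[1].nnz == 0
        assert tensor.layers[2].nnz == 0

    def test_symmetry_and_no_diagonal_everywhere(self, planted_tensor):
        for layer in planted_tensor.layers:
            assert (abs(layer - layer.T)).nnz == 0
            assert np.all(layer.diagonal() == 0.0)
            assert np.all(layer.data > 0.0)
            assert np.all(np.isfinite(layer.data))

    def test_permutation_equivariance(self):
        truth = generate(SyntheticConfig(seed=3, n_proteins=24, n_modules=3))
        ds = truth.dataset
        tensor = build_tensor(ds.net, ds.domains, ds.catalog)

        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.net.n)
        inv = np.argsort(perm)
        pnet = PPINetwork(
            index=ds.net.index,
            edges=frozenset(
                tuple(sorted((int(perm[i]), int(perm[j])))) for i, j in ds.net.edges
            ),
        )
        pdom = DomainAnnotation.from_map(
            {int(perm[i]): ds.domains.domains_of[i] for i in range(ds.net.n)}, ds.net.n
        )
        pcat = ComplexCatalog(
            modules=[frozenset(int(perm[i]) for i in mod) for mod in ds.catalog.modules]
        )
        ptensor = build_tensor(pnet, pdom, pcat)
        for orig, permuted in zip(tensor.layers, ptensor.layers):
            back = permuted.toarray()[np.ix_(perm, perm)]
            np.testing.assert_allclose(back, orig.toarray(), atol=1e-12)

    def test_tsv_round_trip(self, tmp_path, planted_truth, planted_tensor):
        path = tmp_path / "tensor.tsv"
        write_tensor(planted_tensor, planted_truth.dataset.index, path)
        again = read_tensor(path, planted_truth.dataset.index)
        for a, b in zip(planted_tensor.layers, again.layers):
            assert (abs(a - b)).nnz == 0

    def test_five_node_multigraph_entry_count(self, fixtures):
        tensor = fixtures["five_node_multigraph"]
        assert tensor.n == 5 and tensor.m == 3
        # 8 typed undirected connections, stored mirrored
        assert tensor.nnz() == 16
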