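"""Distance metrics: hand-computed values, oracles, and invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gsclust.distances import (
    DistanceMatrix,
    MetricParams,
    distance_matrix,
    go_semantic_distance,
    pmm_distance,
    read_distance_matrix,
    set_distance,
    write_distance_matrix,
)
from gsclust.exceptions import ParameterError, ResourceError
from gsclust.genesets import GeneSet, GeneSetCollection
from gsclust.ontology import GODag
from gsclust.ppi import PPINetwork
from gsclust.synthetic import generate_toy_dag


def gs(set_id, *genes):
    return GeneSet(id=set_id, genes=tuple(genes))


ALPHABET = [f"g{i}" for i in range(12)]

gene_subsets = st.sets(st.sampled_from(ALPHABET), min_size=1, max_size=10)


class TestSetDistances:
    A = gs("A", "a", "b", "c")
    B = gs("B", "b", "c", "d")

    @pytest.mark.parametrize(
        "metric,expected",
        [("jaccard", 0.5), ("dice", 1 / 3), ("meetmin", 1 / 3)],
    )
    def test_worked_example(self, metric, expected):
        d = set_distance(self.A, self.B, MetricParams(metric=metric))
        assert d == pytest.approx(expected)

    def test_kappa_contingency_example(self):
        a = gs("A", *[f"g{i}" for i in range(1, 5)])
        b = gs("B", *[f"g{i}" for i in range(3, 7)])
        universe = frozenset(f"g{i}" for i in range(1, 11))
        d = set_distance(a, b, MetricParams(metric="kappa", universe=universe))
        assert d == pytest.approx(5 / 6)

    @pytest.mark.parametrize("metric", ["jaccard", "dice", "kappa", "meetmin"])
    def test_identical_sets_distance_zero(self, metric):
        assert set_distance(self.A, self.A, MetricParams(metric=metric)) == 0.0

    @pytest.mark.parametrize("metric", ["jaccard", "dice", "kappa", "meetmin"])
    def test_disjoint_sets_distance_one(self, metric):
        c = gs("C", "x", "y", "z")
        assert set_distance(self.A, c, MetricParams(metric=metric)) == 1.0

    def test_kappa_universe_must_cover_sets(self):
        params = MetricParams(metric="kappa", universe=frozenset({"a"}))
        with pytest.raises(ParameterError):
            set_distance(self.A, self.B, params)

    def test_unknown_metric_rejected(self):
        with pytest.raises(ParameterError, match="unknown metric"):
            MetricParams(metric="cosine")

    @given(sa=gene_subsets, sb=gene_subsets)
    @settings(max_examples=200, derandomize=True)
    def test_metric_ordering_property(self, sa, sb):
        """d_meetmin <= d_dice <= d_jaccard for any pair of sets."""
        a, b = gs("A", *sorted(sa)), gs("B", *sorted(sb))
        d = {
            m: set_distance(a, b, MetricParams(metric=m))
            for m in ("meetmin", "dice", "jaccard")
        }
        assert d["meetmin"] <= d["dice"] + 1e-12
        assert d["dice"] <= d["jaccard"] + 1e-12

    @given(sa=gene_subsets, sb=gene_subsets)
    @settings(max_examples=200, derandomize=True)
    def test_symmetry_property(self, sa, sb):
        a, b = gs("A", *sorted(sa)), gs("B", *sorted(sb))
        for m in ("jaccard", "dice", "meetmin", "kappa"):
            params = MetricParams(metric=m, universe=frozenset(ALPHABET))
            assert set_distance(a, b, params) == pytest.approx(
                set_distance(b, a, params)
            )


class TestPmm:
    A = gs("A", "a", "b", "c", "d")
    B = gs("B", "c", "d", "e", "f")

    @pytest.fixture
    def single_edge_net(self):
        net = PPINetwork()
        net.add_edge("a", "e", 0.8)
        return net

    def test_worked_example(self, single_edge_net):
        d1 = pmm_distance(self.A, self.B, single_edge_net, MetricParams(metric="pmm"))
        assert d1 == pytest.approx(0.3)
        d05 = pmm_distance(
            self.A, self.B, single_edge_net, MetricParams(metric="pmm", alpha=0.5)
        )
        assert d05 == pytest.approx(0.4)

    def test_identity_is_zero(self, single_edge_net):
        assert pmm_distance(self.A, self.A, single_edge_net, MetricParams()) == 0.0

    def test_null_network_reduces_to_meetmin(self):
        empty = PPINetwork()
        d_pmm = pmm_distance(self.A, self.B, empty, MetricParams(metric="pmm"))
        d_mm = set_distance(self.A, self.B, MetricParams(metric="meetmin"))
        assert d_pmm == d_mm

    def test_symmetric_under_swap(self, single_edge_net):
        params = MetricParams(metric="pmm")
        small = gs("S", "a", "b")
        assert pmm_distance(small, self.B, single_edge_net, params) == pytest.approx(
            pmm_distance(self.B, small, single_edge_net, params)
        )

    def test_increasing_a_weight_never_increases_distance(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(10)]
        a = gs("A", *genes[:6])
        b = gs("B", *genes[4:])
        net = PPINetwork()
        for x, y in itertools.combinations(genes, 2):
            if rng.random() < 0.3:
                net.add_edge(x, y, float(rng.uniform(0, 0.5)))
        base = pmm_distance(a, b, net, MetricParams(metric="pmm"))
        for x, y, w in list(net.edges()):
            net._weights[frozenset((x, y))] = min(1.0, w + 0.3)
            bumped = pmm_distance(a, b, net, MetricParams(metric="pmm"))
            assert bumped <= base + 1e-12
            net._weights[frozenset((x, y))] = w

    @given(sa=gene_subsets, sb=gene_subsets, seed=st.integers(0, 100))
    @settings(max_examples=100, derandomize=True)
    def test_pmm_bounded_by_meetmin(self, sa, sb, seed):
        rng = np.random.default_rng(seed)
        net = PPINetwork()
        for x, y in itertools.combinations(ALPHABET, 2):
            if rng.random() < 0.4:
                net.add_edge(x, y, float(rng.uniform(0, 1)))
        a, b = gs("A", *sorted(sa)), gs("B", *sorted(sb))
        d_pmm = pmm_distance(a, b, net, MetricParams(metric="pmm"))
        d_mm = set_distance(a, b, MetricParams(metric="meetmin"))
        assert d_pmm <= d_mm + 1e-12


# --- Wang semantic distance ---------------------------------------------------


def wang_oracle(term_a, term_b, dag, params):
    """Exhaustive path-enumeration oracle for the Wang measure (tiny DAGs).

    S-value of an ancestor = max over all child->parent paths of the product
    of edge factors, enumerated explicitly instead of via relaxation.
    """
    weights = {"is_a": params.w_isa, "part_of": params.w_partof}

    def all_paths(term):
        sv = {term: 1.0}

        def walk(node, product):
            for parent, rel in dag.parents(node):
                p = product * weights[rel]
                if p > sv.get(parent, 0.0):
                    sv[parent] = p
                walk(parent, p)

        walk(term, 1.0)
        return sv

    sa, sb = all_paths(term_a), all_paths(term_b)
    shared = set(sa) & set(sb)
    if not shared:
        return 1.0
    sim = sum(sa[u] + sb[u] for u in shared) / (sum(sa.values()) + sum(sb.values()))
    return 1.0 - sim


class TestWang:
    def test_identity(self):
        dag = generate_toy_dag(depth=2, branching=2)
        assert go_semantic_distance("T.0", "T.0", dag, MetricParams(metric="go")) == 0.0

    def test_sibling_leaves_toy_value(self):
        dag = generate_toy_dag(depth=2, branching=2)
        d = go_semantic_distance("T.0.0", "T.0.1", dag, MetricParams(metric="go"))
        # S = {self: 1, parent: 0.8, root: 0.64}, SV = 2.44 each,
        # shared {parent, root} -> sim = 2.88 / 4.88
        assert d == pytest.approx(1 - 2.88 / 4.88, abs=1e-9)
        assert d == pytest.approx(0.4098, abs=1e-4)

    def test_separate_roots_are_maximally_distant(self, caplog):
        dag = GODag()
        dag.add_edge("A", "R1")
        dag.add_edge("B", "R2")
        with caplog.at_level("WARNING"):
            d = go_semantic_distance("A", "B", dag, MetricParams(metric="go"))
        assert d == 1.0

    def test_absent_term_named_in_error(self):
        dag = generate_toy_dag(depth=1, branching=2)
        with pytest.raises(ParameterError, match="T.9"):
            go_semantic_distance("T.0", "T.9", dag, MetricParams(metric="go"))

    def test_part_of_edges_use_their_own_factor(self):
        dag = GODag()
        dag.add_edge("A", "R", relation="part_of")
        dag.add_edge("B", "R", relation="part_of")
        d = go_semantic_distance("A", "B", dag, MetricParams(metric="go"))
        # S = {self: 1, root: 0.6}; sim = 1.2 / 3.2
        assert d == pytest.approx(1 - 1.2 / 3.2)

    def test_matches_exhaustive_oracle_on_random_dags(self):
        """Relaxation agrees with path enumeration on DAGs of <= 20 terms."""
        params = MetricParams(metric="go")
        rng = np.random.default_rng(7)
        for trial in range(20):
            dag = GODag()
            n_terms = int(rng.integers(5, 20))
            terms = [f"N{i}" for i in range(n_terms)]
            # parents only among earlier terms keeps the graph acyclic
            for i, term in enumerate(terms[1:], start=1):
                n_parents = int(rng.integers(1, min(i, 3) + 1))
                for p in rng.choice(i, size=n_parents, replace=False):
                    rel = "is_a" if rng.random() < 0.5 else "part_of"
                    dag.add_edge(term, terms[p], relation=rel)
            i, j = rng.choice(n_terms, size=2, replace=False)
            expected = wang_oracle(terms[i], terms[j], dag, params)
            got = go_semantic_distance(terms[i], terms[j], dag, params)
            assert got == pytest.approx(expected, abs=1e-9), f"trial {trial}"


class TestDistanceMatrix:
    def test_identical_sets_give_zero_matrix(self):
        coll = GeneSetCollection(
            sets=tuple(gs(f"S{i}", "a", "b") for i in range(3))
        )
        dm = distance_matrix(coll, MetricParams(metric="jaccard"))
        assert np.all(dm.values == 0)

    @pytest.mark.parametrize("metric", ["jaccard", "dice", "kappa", "meetmin"])
    def test_entries_match_pairwise_calls(self, small_collection, metric):
        params = MetricParams(metric=metric, universe=small_collection.universe)
        dm = distance_matrix(small_collection, params)
        for i, a in enumerate(small_collection.sets):
            for j, b in enumerate(small_collection.sets):
                expected = 0.0 if i == j else set_distance(a, b, params)
                assert dm.values[i, j] == pytest.approx(expected)

    def test_invariants_enforced(self):
        with pytest.raises(ParameterError, match="symmetric"):
            DistanceMatrix(labels=("a", "b"), values=np.array([[0, 0.1], [0.7, 0]]))
        with pytest.raises(ParameterError, match="diagonal"):
            DistanceMatrix(labels=("a", "b"), values=np.array([[0.2, 0.5], [0.5, 0.2]]))
        with pytest.raises(ParameterError, match="0, 1"):
            DistanceMatrix(labels=("a", "b"), values=np.array([[0.0, 1.5], [1.5, 0.0]]))

    def test_float_fuzz_snapped_to_bounds(self):
        eps = 1e-13
        dm = DistanceMatrix(
            labels=("a", "b"), values=np.array([[0.0, 1 + eps], [1 + eps, 0.0]])
        )
        assert dm.values.max() == 1.0

    def test_missing_resource_errors(self, small_collection):
        with pytest.raises(ResourceError, match="PPI"):
            distance_matrix(small_collection, MetricParams(metric="pmm"))
        with pytest.raises(ResourceError, match="ontology"):
            distance_matrix(small_collection, MetricParams(metric="go"))

    def test_serialization_round_trip(self, small_collection, tmp_path):
        dm = distance_matrix(small_collection, MetricParams(metric="dice"))
        path = tmp_path / "d.tsv"
        write_distance_matrix(dm, path)
        back = read_distance_matrix(path)
        assert back.labels == dm.labels
        assert back.params.metric == "dice"
        np.testing.assert_allclose(back.values, dm.values, atol=1e-10)
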