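"""Signal distances, neighbor-joining, Robinson-Foulds, bootstrap."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio import DistanceMatrix, TreeNode

from codonmap import (
    SignalError,
    TreeError,
    bootstrap_support,
    encode_amino_acids,
    generate_cds,
    generate_family,
    neighbor_joining,
    normalized_rf_distance,
    pairwise_distance_matrix,
    proportional_deviation,
)

signal_strategy = st.lists(st.integers(0, 20), min_size=1, max_size=40)


def newick(text):
    return TreeNode.read(io.StringIO(text))


class TestProportionalDeviation:
    @pytest.mark.parametrize(
        "a1, a2, expected",
        [
            ([3, 7, 7], [3, 7, 7], 0.0),
            ([0], [20], 1.0),
            ([20, 10], [10, 10], 0.25),
        ],
    )
    def test_hand_cases(self, a1, a2, expected):
        assert proportional_deviation(a1, a2) == pytest.approx(expected)

    def test_length_mismatch_instructs_prealignment(self):
        with pytest.raises(SignalError, match="pre-align"):
            proportional_deviation([1, 2], [1, 2, 3])

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(1, 30).flatmap(
        lambda n: st.tuples(*[st.lists(st.integers(0, 20), min_size=n, max_size=n)] * 3)
    ))
    def test_is_a_metric(self, triple):
        x, y, z = (np.array(v) for v in triple)
        assert proportional_deviation(x, x) == 0.0
        assert proportional_deviation(x, y) == pytest.approx(proportional_deviation(y, x))
        assert proportional_deviation(x, z) <= (
            proportional_deviation(x, y) + proportional_deviation(y, z) + 1e-12
        )
        if not np.array_equal(x, y):
            assert proportional_deviation(x, y) > 0


class TestDistanceMatrix:
    def test_identical_signals_give_zero_matrix(self):
        s = np.array([1, 2, 3])
        dm = pairwise_distance_matrix({"a": s, "b": s, "c": s})
        assert np.allclose(dm.data, 0)

    def test_entries_match_direct_pairwise_recomputation(self):
        rng = np.random.default_rng(13)
        signals = {f"t{i}": rng.integers(0, 21, 25) for i in range(5)}
        dm = pairwise_distance_matrix(signals)
        for i in signals:
            for j in signals:
                assert dm[i, j] == pytest.approx(
                    proportional_deviation(signals[i], signals[j])
                )

    def test_unequal_lengths_error_names_lengths(self):
        with pytest.raises(SignalError, match="unequal"):
            pairwise_distance_matrix({"a": [1, 2], "b": [1], "c": [2, 3]})

    def test_fewer_than_three_signals_rejected(self):
        with pytest.raises(SignalError):
            pairwise_distance_matrix({"a": [1], "b": [2]})


class TestNeighborJoining:
    def test_three_taxa_forced_topology_and_branch_lengths(self):
        # three-point formulas: xA=(dAB+dAC-dBC)/2 etc.
        dm = DistanceMatrix([[0, 4, 6], [4, 0, 8], [6, 8, 0]], ids=list("ABC"))
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == pytest.approx({"A": 1.0, "B": 3.0, "C": 5.0})

    def test_additive_four_taxon_matrix_recovers_split_and_lengths(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) => dAB=3 dAC=5 dAD=6 dBC=6 dBD=7 dCD=7
        dm = DistanceMatrix(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            ids=list("ABCD"),
        )
        tree = neighbor_joining(dm)
        from codonmap.phylo import unrooted_bipartitions

        assert unrooted_bipartitions(tree) == {
            frozenset({frozenset("AB"), frozenset("CD")})
        }
        # path lengths reproduce the additive distances exactly
        for i in "ABCD":
            for j in "ABCD":
                if i < j:
                    ti = tree.find(i)
                    assert ti.distance(tree.find(j)) == pytest.approx(dm[i, j])

    def test_all_zero_matrix_yields_star_tree_with_warning(self):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("ABCD"))
        with pytest.warns(UserWarning, match="star"):
            tree = neighbor_joining(dm)
        assert {t.name for t in tree.tips()} == set("ABCD")

    def test_outgroup_rooting_produces_bifurcating_root(self):
        dm = DistanceMatrix(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            ids=list("ABCD"),
        )
        tree = neighbor_joining(dm, outgroup="D")
        assert len(tree.children) == 2
        with pytest.raises(TreeError, match="outgroup"):
            neighbor_joining(dm, outgroup="Z")

    def test_simulated_eight_taxon_family_topology_recovered(self, code1, global_map):
        topo = newick("(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);")
        root = generate_cds(code1, 148, seed=42)
        family = generate_family(topo, root, 8.0, seed=43, code=code1)
        signals = {
            k: encode_amino_acids(global_map, code1, v) for k, v in family.items()
        }
        tree = neighbor_joining(pairwise_distance_matrix(signals))
        assert normalized_rf_distance(tree, topo, rooted=False) == 0.0


class TestRobinsonFoulds:
    def test_identical_trees_distance_zero(self):
        t = newick("((((A,B),C),D),((E,F),(G,H)));")
        assert normalized_rf_distance(t, newick(str(t))) == 0.0

    def test_one_clade_difference_on_eight_leaves_is_one_sixth(self):
        t1 = newick("((((A,B),C),D),((E,F),(G,H)));")
        t2 = newick("((((A,C),B),D),((E,F),(G,H)));")
        assert normalized_rf_distance(t1, t2) == pytest.approx(2 / 12)

    def test_maximally_different_rooted_caterpillars(self):
        t1 = newick("(((((((A,B),C),D),E),F),G),H);")
        t2 = newick("(((((((H,G),F),E),D),C),B),A);")
        assert normalized_rf_distance(t1, t2) == 1.0

    def test_unrooted_mode_uses_bipartitions(self):
        t1 = newick("((A,B),C,(D,(E,(F,(G,H)))));")
        t2 = newick("((A,C),B,(D,(E,(F,(G,H)))));")
        d = normalized_rf_distance(t1, t2, rooted=False)
        assert d == pytest.approx(2 / 10)

    def test_symmetry_and_leaf_set_mismatch(self):
        t1 = newick("((((A,B),C),D),((E,F),(G,H)));")
        t2 = newick("((((A,C),B),D),((E,F),(G,H)));")
        assert normalized_rf_distance(t1, t2) == normalized_rf_distance(t2, t1)
        t3 = newick("(((A,B),C),(D,E));")
        with pytest.raises(TreeError, match="leaf sets"):
            normalized_rf_distance(t1, t3)

    def test_rooted_mode_requires_bifurcating_roots(self):
        unrooted = newick("((A,B),C,(D,E));")
        with pytest.raises(TreeError, match="root"):
            normalized_rf_distance(unrooted, unrooted)


@pytest.fixture(scope="module")
def family_signals(code1, global_map):
    topo = newick("(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1);")
    root = generate_cds(code1, 148, seed=9)
    family = generate_family(topo, root, 6.0, seed=10, code=code1)
    return {k: encode_amino_acids(global_map, code1, v) for k, v in family.items()}


class TestBootstrap:
    def test_single_replicate_supports_are_zero_or_hundred(self, family_signals):
        tree = bootstrap_support(family_signals, replicates=1, seed=1)
        supports = [int(n.name) for n in tree.non_tips() if n.name is not None]
        assert supports and set(supports) <= {0, 100}

    def test_same_seed_reproduces_identical_supports(self, family_signals):
        t1 = bootstrap_support(family_signals, replicates=25, seed=77)
        t2 = bootstrap_support(family_signals, replicates=25, seed=77)
        assert str(t1) == str(t2)

    def test_well_separated_clades_get_high_support(self, code1, global_map):
        """Two low-noise clades: the deepest split should be supported in
        at least 95% of 1000 replicates."""
        topo = newick("((A:0.2,B:0.2):5,(C:0.2,D:0.2):5,(E:0.2,F:0.2):0.2);")
        root = generate_cds(code1, 148, seed=21)
        family = generate_family(topo, root, 10.0, seed=22, code=code1)
        signals = {
            k: encode_amino_acids(global_map, code1, v) for k, v in family.items()
        }
        tree = bootstrap_support(signals, replicates=1000, seed=23)
        supports = {
            frozenset(t.name for t in n.tips()): int(n.name)
            for n in tree.non_tips()
            if n.name is not None
        }
        assert supports[frozenset("AB")] >= 95
        assert supports[frozenset("CD")] >= 95

    def test_too_few_signals_rejected(self):
        with pytest.raises(SignalError):
            bootstrap_support({"a": [1, 2], "b": [1, 2], "c": [2, 3]}, replicates=5)
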