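"""Variant comparison: identities, substitutions, p-distances, NJ tree."""

import random

import numpy as np
import pytest
import skbio
from hypothesis import given, settings, strategies as st

from lanthimine.variants import (
    DistanceMatrix,
    VariantPanel,
    nj_tree,
    p_distance_matrix,
    panel_from_records,
    percent_identity,
    reference_panel,
    substitution_list,
    unique_residues,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def path_lengths(tree):
    """Leaf-to-leaf path lengths as a dict keyed by frozenset of names."""
    dm = tree.tip_tip_distances()
    return {
        frozenset((a, b)): dm[a, b]
        for a in dm.ids
        for b in dm.ids
        if a != b
    }


class TestPercentIdentity:
    def test_candidate_vs_named_variants(self, nisin_s, nisin_a, nisin_f):
        assert percent_identity(nisin_s, nisin_a) == 79.41
        assert percent_identity(nisin_s, nisin_f) == 82.35

    def test_self_identity(self, nisin_s):
        assert percent_identity(nisin_s, nisin_s) == 100.00

    def test_symmetry_and_length_check(self, nisin_s, nisin_a):
        assert percent_identity(nisin_s, nisin_a) == percent_identity(
            nisin_a, nisin_s
        )
        with pytest.raises(ValueError):
            percent_identity("AAA", "AAAA")


class TestSubstitutionList:
    def test_seven_differences_from_template(self, nisin_a, nisin_s):
        subs = substitution_list(nisin_a, nisin_s)
        assert subs == ["I4Y", "N20T", "T25S", "H27G", "S29H", "I30V", "V32I"]

    def test_identical_sequences(self, nisin_s):
        assert substitution_list(nisin_s, nisin_s) == []

    @settings(derandomize=True, max_examples=100)
    @given(
        st.text(alphabet=AA, min_size=1, max_size=40),
        st.randoms(use_true_random=False),
    )
    def test_count_equals_hamming_distance(self, seq, rnd):
        other = "".join(
            rnd.choice(AA) if rnd.random() < 0.3 else c for c in seq
        )
        hamming = sum(a != b for a, b in zip(seq, other))
        assert len(substitution_list(seq, other)) == hamming

    def test_count_consistent_with_identity(self, nisin_a, nisin_s):
        subs = substitution_list(nisin_a, nisin_s)
        ident = percent_identity(nisin_a, nisin_s)
        assert len(subs) == round((1 - ident / 100) * len(nisin_a))


class TestUniqueResidues:
    def test_candidate_unique_positions_in_reduced_panel(self, panel):
        uniq = unique_residues("nisin_S", panel)
        # the two residues reported as unique among natural variants must be
        # unique even in the reduced three-member panel
        assert "T20" in uniq and "S25" in uniq

    def test_duplicate_entry_has_no_unique_positions(self, nisin_s):
        p = VariantPanel((("a", nisin_s), ("b", nisin_s)))
        assert unique_residues("a", p) == []

    def test_anti_monotone_in_panel_size(self, nisin_s, nisin_a, nisin_f):
        small = VariantPanel((("S", nisin_s), ("A", nisin_a)))
        big = VariantPanel((("S", nisin_s), ("A", nisin_a), ("F", nisin_f)))
        assert set(unique_residues("S", big)) <= set(unique_residues("S", small))


class TestPDistance:
    def test_distance_from_identity(self, panel):
        dm = p_distance_matrix(panel)
        i, j = dm.labels.index("nisin_S"), dm.labels.index("nisin_F")
        assert dm.distances[i, j] == pytest.approx(6 / 34)

    def test_matrix_invariants(self, nisin_s):
        rng = random.Random(2)
        entries = [("ref", nisin_s)]
        for k in range(4):
            entries.append(
                (f"v{k}", "".join(rng.choice(AA) for _ in nisin_s))
            )
        dm = p_distance_matrix(VariantPanel(tuple(entries)))
        assert np.allclose(dm.distances, dm.distances.T)
        assert np.allclose(np.diag(dm.distances), 0)
        assert ((dm.distances >= 0) & (dm.distances <= 1)).all()


class TestNeighborJoining:
    def _additive_matrix(self):
        # Four taxa on a known tree: ((a:0.1,b:0.2):0.3,(c:0.1,d:0.2));
        labels = ("a", "b", "c", "d")
        d = np.array(
            [
                [0.0, 0.3, 0.5, 0.6],
                [0.3, 0.0, 0.6, 0.7],
                [0.5, 0.6, 0.0, 0.3],
                [0.6, 0.7, 0.3, 0.0],
            ]
        )
        return DistanceMatrix(labels, d)

    def test_additive_metric_recovered_exactly(self):
        dm = self._additive_matrix()
        tree = nj_tree(dm)
        pl = path_lengths(tree)
        for i, a in enumerate(dm.labels):
            for j, b in enumerate(dm.labels):
                if i < j:
                    assert pl[frozenset((a, b))] == pytest.approx(
                        dm.distances[i, j], abs=1e-9
                    )

    @staticmethod
    def _random_additive(rng, n):
        """Distance matrix of a random binary tree with random edge lengths."""
        # grow the tree by repeatedly joining two clusters
        dists = {(i, i): 0.0 for i in range(n)}
        clusters = [[i] for i in range(n)]
        heights = {i: 0.0 for i in range(n)}  # tip-to-cluster-root distance
        while len(clusters) > 1:
            a = clusters.pop(rng.integers(len(clusters)))
            b = clusters.pop(rng.integers(len(clusters)))
            la, lb = rng.uniform(0.05, 0.4, size=2)
            for i in a:
                for j in b:
                    d = heights[i] + la + heights[j] + lb
                    dists[(i, j)] = dists[(j, i)] = d
            for i in a:
                heights[i] += la
            for j in b:
                heights[j] += lb
            clusters.append(a + b)
        m = np.zeros((n, n))
        for (i, j), d in dists.items():
            m[i, j] = d
        return m

    def test_agrees_with_independent_nj_on_additive_matrices(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            n = 6
            labels = tuple(f"t{i}" for i in range(n))
            d = self._random_additive(rng, n)
            ours = nj_tree(DistanceMatrix(labels, d))
            ref = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
            pl_ours, pl_ref = path_lengths(ours), path_lengths(ref)
            for key in pl_ref:
                assert pl_ours[key] == pytest.approx(pl_ref[key], abs=1e-6)

    def test_closest_variant_is_nearest_leaf(self, panel):
        # add a distant outgroup so the 3-taxon panel becomes a 4-taxon tree
        entries = panel.entries + (("outgroup", "W" * 34),)
        dm = p_distance_matrix(VariantPanel(entries))
        tree = nj_tree(dm)
        pl = path_lengths(tree)
        dists = {
            name: pl[frozenset(("nisin_S", name))]
            for name in ("nisin_A", "nisin_F", "outgroup")
        }
        assert min(dists, key=dists.get) == "nisin_F"

    def test_ultrametric_three_taxa(self):
        dm = DistanceMatrix(
            ("a", "b", "c"),
            np.array([[0, 0.2, 0.4], [0.2, 0, 0.4], [0.4, 0.4, 0]]),
        )
        tree = nj_tree(dm)
        pl = path_lengths(tree)
        assert pl[frozenset(("a", "b"))] == pytest.approx(0.2)
        assert pl[frozenset(("a", "c"))] == pytest.approx(0.4)

    def test_too_few_taxa(self):
        dm = DistanceMatrix(("a", "b"), np.array([[0.0, 0.1], [0.1, 0.0]]))
        with pytest.raises(ValueError):
            nj_tree(dm)


def test_reference_panel_contents(panel):
    assert set(panel.names) == {"nisin_A", "nisin_F", "nisin_S"}
    assert all(31 <= len(seq) <= 35 for _, seq in panel.entries)
    # the variant differs from the template at exactly seven positions
    subs = substitution_list(panel.sequence("nisin_A"), panel.sequence("nisin_S"))
    assert len(subs) == 7
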