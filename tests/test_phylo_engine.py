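"""Jukes-Cantor distances, neighbour joining, bootstrap, clade calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from palcolin import synthetic_data as sd
from palcolin.errors import PhyloError, SaturationError
from palcolin.phylo_engine import (
    Alignment, DistanceMatrix, bootstrap_support, classify_clade,
    distance_matrix, jc_distance, nj_tree, p_distance, tree_bipartitions,
)


class TestJukesCantor:
    def test_zero_difference_gives_zero_distance(self):
        assert jc_distance(0.0) == 0.0

    def test_closed_form_value(self):
        assert jc_distance(0.3) == pytest.approx(-0.75 * math.log(0.6),
                                                 rel=1e-12)
        assert jc_distance(0.3) == pytest.approx(0.38312, abs=5e-6)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            jc_distance(0.75)

    def test_protein_alphabet_form(self):
        expected = -(19 / 20) * math.log(1 - (20 / 19) * 0.3)
        assert jc_distance(0.3, alphabet_size=20) == pytest.approx(expected)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=0.74))
    def test_correction_dominates_p_and_is_increasing(self, p):
        d = jc_distance(p)
        assert d >= p
        if p + 1e-4 < 0.75:
            assert jc_distance(p + 1e-4) > d

    def test_pairwise_deletion_of_gap_columns(self):
        p, n = p_distance("AC-GT", "ACA-T")
        assert (p, n) == (0.0, 3)
        with pytest.raises(PhyloError):
            p_distance("--", "AA")


class TestNeighbourJoining:
    def test_three_taxa_three_point_formulas(self):
        D = DistanceMatrix(("a", "b", "c"),
                           np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]]))
        res = nj_tree(D)
        lengths = {t.name: t.length for t in res.tree.tips()}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(PhyloError):
            nj_tree(DistanceMatrix(("a", "b"), np.zeros((2, 2))))

    def test_additive_four_taxon_matrix_recovers_topology_and_lengths(self):
        # tree: ((a:1,b:2):1,(c:3,d:4)) — additive path distances
        D = DistanceMatrix(("a", "b", "c", "d"), np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0.0]]))
        res = nj_tree(D)
        assert tree_bipartitions(res.tree) == {frozenset({"c", "d"})}
        dist = {}
        for i, x in enumerate(("a", "b", "c", "d")):
            for y in ("a", "b", "c", "d")[i + 1:]:
                tip = next(t for t in res.tree.tips() if t.name == x)
                dist[(x, y)] = tip.distance(
                    next(t for t in res.tree.tips() if t.name == y))
        assert dist[("a", "b")] == pytest.approx(3)
        assert dist[("c", "d")] == pytest.approx(7)
        assert dist[("a", "c")] == pytest.approx(5)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_additive_matrices_recover_the_generating_tree(self, seed):
        tree = sd.random_tree(6, seed=seed, branch_range=(0.1, 1.0))
        taxa = sorted(t.name for t in tree.tips())
        tips = {t.name: t for t in tree.tips()}
        m = np.zeros((6, 6))
        for i, x in enumerate(taxa):
            for j, y in enumerate(taxa):
                if i < j:
                    m[i, j] = m[j, i] = tips[x].distance(tips[y])
        res = nj_tree(DistanceMatrix(tuple(taxa), m))
        assert tree_bipartitions(res.tree) == tree_bipartitions(tree)

    def test_deterministic_output(self):
        rng = np.random.default_rng(5)
        m = rng.uniform(0.1, 1.0, size=(5, 5))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        D = DistanceMatrix(tuple("abcde"), m)
        t1, t2 = nj_tree(D), nj_tree(D)
        assert t1.newick() == t2.newick()


class TestAlignment:
    def test_rows_must_align(self):
        with pytest.raises(PhyloError):
            Alignment(("a", "b"), ("ACGT", "ACG"))
        with pytest.raises(PhyloError):
            Alignment(("a", "a"), ("ACGT", "ACGT"))

    def test_alphabet_detection(self):
        assert Alignment(("a",), ("ACGT-",)).is_nucleotide()
        assert not Alignment(("a",), ("MKLV",)).is_nucleotide()


class TestBootstrap:
    def _informative_alignment(self):
        # 100 copies of one perfectly informative column (split {a,b} vs
        # {c,d,e}) diluted with 300 constant columns so no pair saturates
        rows = {"a": "A", "b": "A", "c": "C", "d": "C", "e": "C"}
        return Alignment(tuple(rows), tuple(
            rows[t] * 100 + "G" * 300 for t in rows))

    def test_perfectly_informative_split_gets_full_support(self):
        res = bootstrap_support(self._informative_alignment(), reps=100, seed=1)
        key = frozenset({"c", "d", "e"})  # canonical side (anchor 'a' excluded)
        assert res.supports[key] == 100.0

    def test_same_seed_identical_supports_different_seed_may_differ(self):
        tree = sd.random_tree(6, seed=3)
        aln = sd.simulate_alignment(tree, 120, seed=9)
        r1 = bootstrap_support(aln, reps=50, seed=11)
        r2 = bootstrap_support(aln, reps=50, seed=11)
        r3 = bootstrap_support(aln, reps=50, seed=12)
        assert r1.supports == r2.supports
        assert r1.supports != r3.supports or not r1.supports
        assert all(0 <= v <= 100 for v in r1.supports.values())

    def test_too_few_columns_rejected(self):
        aln = Alignment(("a", "b", "c"), ("A", "C", "G"))
        with pytest.raises(PhyloError):
            bootstrap_support(aln, reps=10, seed=0)


class TestCladeClassification:
    def _references(self, length=300, seed=7):
        # two clades ~25% divergent, ~8% within-clade divergence spread over
        # many sites so bootstrap resampling cannot collapse references
        rng = np.random.default_rng(seed)
        letters = np.array(list("ACGT"))
        base_acp = rng.integers(0, 4, size=length)
        base_pcp = base_acp.copy()
        flip = rng.random(length) < 0.25
        base_pcp[flip] = (base_pcp[flip] + rng.integers(1, 4, int(flip.sum()))) % 4

        def variants(base, n=3):
            out = []
            for _ in range(n):
                v = base.copy()
                hit = rng.random(length) < 0.08
                v[hit] = (v[hit] + rng.integers(1, 4, int(hit.sum()))) % 4
                out.append("".join(letters[v]))
            return out

        acp = variants(base_acp)
        pcp = variants(base_pcp)
        labels = {}
        rows, names = [], []
        for i, s in enumerate(acp):
            names.append(f"acp{i}")
            rows.append(s)
            labels[f"acp{i}"] = "ACP"
        for i, s in enumerate(pcp):
            names.append(f"pcp{i}")
            rows.append(s)
            labels[f"pcp{i}"] = "PCP"
        return Alignment(tuple(names), tuple(rows)), labels

    def test_query_identical_to_reference_joins_its_clade_with_full_support(self):
        refs, labels = self._references()
        call = classify_clade("q", refs.row("acp0"), refs, labels,
                              reps=50, seed=2)
        assert call.label == "ACP"
        assert call.support == 100.0

    def test_query_simulated_from_the_pcp_subtree_classified_pcp(self):
        refs, labels = self._references()
        # mutate a PCP reference lightly
        q = list(refs.row("pcp1"))
        q[0], q[5] = "A", "T"
        call = classify_clade("q", "".join(q), refs, labels, reps=50, seed=4)
        assert call.label == "PCP"

    def test_unlabeled_reference_rejected(self):
        refs, labels = self._references()
        labels.pop("acp2")
        with pytest.raises(PhyloError, match="acp2"):
            classify_clade("q", refs.row("acp0"), refs, labels)

    def test_mixed_smallest_group_is_unclassified(self):
        # one ACP and one PCP reference are identical to each other and to
        # the query: the smallest enclosing group mixes labels
        core = "A" * 15 + "C" * 15
        rows = (core,
                core,
                core[:-3] + "GGG",
                "TTT" + core[3:],
                core[:-5] + "GGGGG")
        names = ("acp0", "pcp0", "acp1", "pcp1", "acp2")
        labels = {"acp0": "ACP", "pcp0": "PCP", "acp1": "ACP",
                  "pcp1": "PCP", "acp2": "ACP"}
        refs = Alignment(names, rows)
        call = classify_clade("q", core, refs, labels, reps=20, seed=1)
        assert call.label == "unclassified"
        assert "mixes labels" in call.diagnostics


class TestCrossCheckAgainstSkbio:
    @pytest.mark.parametrize("seed", range(10))
    def test_nj_topology_agrees_with_reference_implementation(self, seed):
        """Independent library cross-check on random additive matrices."""
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        tree = sd.random_tree(7, seed=100 + seed, branch_range=(0.2, 1.0))
        taxa = sorted(t.name for t in tree.tips())
        tips = {t.name: t for t in tree.tips()}
        m = np.zeros((7, 7))
        for i, x in enumerate(taxa):
            for j, y in enumerate(taxa):
                if i < j:
                    m[i, j] = m[j, i] = tips[x].distance(tips[y])
        ours = nj_tree(DistanceMatrix(tuple(taxa), m))
        theirs = skbio_nj(SkbioDM(m, ids=taxa))
        assert tree_bipartitions(ours.tree) == tree_bipartitions(theirs)
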