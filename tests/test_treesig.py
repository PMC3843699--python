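import math

import numpy as np
import pytest

from parapop.popdata import HaplotypeAlignment
from parapop.treesig import (SATURATION_SENTINEL, DistanceMatrix,
                             bootscan_signal, bootstrap_support,
                             jc_distance_matrix, nj_tree, random_rf_baseline,
                             random_topology, robinson_foulds_normalized,
                             tree_from_newick)
from parapop.windows import WindowSpec


def _aln(named_seqs):
    ids = list(named_seqs)
    return HaplotypeAlignment(ids, [named_seqs[i] for i in ids], [1] * len(ids))


class TestJCDistance:
    def test_identical_sequences(self):
        dm = jc_distance_matrix(_aln({"a": "ACGTACGTAC", "b": "ACGTACGTAC"}))
        assert dm.d[0, 1] == 0.0

    def test_closed_form_p_ten_percent(self):
        seqs = {"a": "A" * 10, "b": "C" + "A" * 9}
        dm = jc_distance_matrix(_aln(seqs))
        assert dm.d[0, 1] == pytest.approx(-0.75 * math.log(1 - 0.4 / 3), rel=1e-9)
        assert dm.d[0, 1] == pytest.approx(0.10732, abs=1e-5)

    def test_saturation_sentinel(self):
        seqs = {"a": "AAAA", "b": "CCCC"}
        dm = jc_distance_matrix(_aln(seqs))
        assert dm.d[0, 1] == SATURATION_SENTINEL and dm.saturated

    def test_complete_deletion_of_gap_columns(self):
        seqs = {"a": "AC-T", "b": "ACGT", "c": "TC-T"}
        dm = jc_distance_matrix(_aln(seqs))
        # column 3 dropped for everyone: a vs b over ACT/ACT
        assert dm.d[0, 1] == 0.0


class TestNJ:
    def test_additive_four_taxon_exact(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        labels = ["A", "B", "C", "D"]
        d = np.array([
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(labels, d))
        assert frozenset({"A", "B"}) in tree.bipartitions() or \
               frozenset({"C", "D"}) in tree.bipartitions()
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert tree.path_length(a, b) == pytest.approx(d[i, j], abs=1e-9)

    def test_consistency_on_random_additive_matrices(self, rng):
        """NJ reconstructs path lengths of random additive matrices exactly."""
        for _ in range(5):
            ref = random_topology([f"t{i}" for i in range(7)], rng)
            # assign random branch lengths by rebuilding adjacency weights
            for v in list(ref.adj):
                ref.adj[v] = [(u, None) for u, _ in ref.adj[v]]
            lengths = {}
            for v in ref.adj:
                for u, _ in ref.adj[v]:
                    key = frozenset({str(v), str(u)})
                    if key not in lengths:
                        lengths[key] = float(rng.uniform(0.05, 2.0))
            for v in ref.adj:
                ref.adj[v] = [(u, lengths[frozenset({str(v), str(u)})])
                              for u, _ in ref.adj[v]]
            labels = ref.tips
            m = len(labels)
            d = np.zeros((m, m))
            for i in range(m):
                for j in range(i + 1, m):
                    d[i, j] = d[j, i] = ref.path_length(labels[i], labels[j])
            out = nj_tree(DistanceMatrix(labels, d))
            assert out.bipartitions() == ref.bipartitions()
            for i in range(m):
                for j in range(i + 1, m):
                    assert out.path_length(labels[i], labels[j]) == pytest.approx(
                        d[i, j], abs=1e-8)

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))


class TestRobinsonFoulds:
    def test_identical_topologies(self, rng):
        t = random_topology(list("ABCDEF"), rng)
        assert robinson_foulds_normalized(t, t) == 0.0

    def test_disjoint_quartets(self):
        t1 = tree_from_newick("((A,B),(C,D));")
        t2 = tree_from_newick("((A,C),(B,D));")
        assert robinson_foulds_normalized(t1, t2) == 1.0
        assert robinson_foulds_normalized(t2, t1) == 1.0

    def test_symmetry_random_trees(self, rng):
        a = random_topology(list("ABCDEFG"), rng)
        b = random_topology(list("ABCDEFG"), rng)
        assert robinson_foulds_normalized(a, b) == robinson_foulds_normalized(b, a)

    def test_tip_mismatch_rejected(self, rng):
        a = random_topology(list("ABCD"), rng)
        b = random_topology(list("ABCE"), rng)
        with pytest.raises(ValueError):
            robinson_foulds_normalized(a, b)

    def test_quartet_baseline_mean(self, rng):
        """Against a fixed quartet, a uniform random quartet matches it with
        probability 1/3: mean RF = 2/3."""
        ref = tree_from_newick("((A,B),(C,D));")
        mean, half = random_rf_baseline(ref, R=600, rng=rng)
        assert mean == pytest.approx(2 / 3, abs=0.06)

    def test_many_tips_baseline_near_one(self, rng):
        ref = random_topology([f"t{i}" for i in range(12)], rng)
        mean, half = random_rf_baseline(ref, R=60, rng=rng)
        assert mean > 0.85
        assert half < 0.1

    def test_baseline_seed_reproducible(self):
        ref = tree_from_newick("((A,B),(C,(D,E)));")
        m1 = random_rf_baseline(ref, R=50, rng=np.random.default_rng(4))
        m2 = random_rf_baseline(ref, R=50, rng=np.random.default_rng(4))
        assert m1 == m2


class TestBootstrap:
    def _two_clade_alignment(self):
        left = "A" * 30 + "C" * 30
        right = "T" * 30 + "C" * 30
        return _aln({
            "a1": left, "a2": left[:-1] + "G",
            "b1": right, "b2": right[:-1] + "A",
        })

    def test_clear_split_gets_full_support(self):
        aln = self._two_clade_alignment()
        tree = bootstrap_support(aln, B=50, rng=np.random.default_rng(1))
        split = frozenset({"b1", "b2"})
        assert tree.supports.get(split, tree.supports.get(frozenset({"a1", "a2"}))) \
            == pytest.approx(100.0, abs=2.0)

    def test_seed_determinism(self):
        aln = self._two_clade_alignment()
        t1 = bootstrap_support(aln, B=30, rng=np.random.default_rng(7))
        t2 = bootstrap_support(aln, B=30, rng=np.random.default_rng(7))
        assert t1.supports == t2.supports

    def test_supports_bounded(self):
        aln = self._two_clade_alignment()
        tree = bootstrap_support(aln, B=20, rng=np.random.default_rng(2))
        assert all(0 <= v <= 100 for v in tree.supports.values())


class TestBootscan:
    def _mosaic(self, rng):
        """Recombinant r: left half identical to p, right half from q.

        q and o form a well-separated sister clade (shared + private
        changes) so pair monophyly of (p, r) is resolvable in every window.
        """
        L = 600
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        base = "".join(rng.choice(list("ACGT"), size=L))
        p = list(base)
        q = list(base)
        o = list(base)
        for i in range(0, L, 9):       # shared branch of the (q, o) clade
            q[i] = o[i] = flip[q[i]]
        for i in range(4, L, 18):      # q-private changes
            q[i] = flip[q[i]]
        for i in range(7, L, 18):      # o-private changes
            o[i] = flip[o[i]]
        r = p[:300] + q[300:]
        return _aln({"p": "".join(p), "q": "".join(q),
                     "r": "".join(r), "o": "".join(o)})

    def test_signal_crosses_breakpoint(self, rng):
        aln = self._mosaic(rng)
        spec = WindowSpec(150, 150)
        track_pr = bootscan_signal(aln, ("p", "r"), spec, B=40,
                                   rng=np.random.default_rng(3))
        # left windows: r identical to p -> near 100%; right: r sides with q
        assert track_pr.pct_trees.iloc[0] > 90
        assert track_pr.pct_trees.iloc[-1] < 10

    def test_homogeneous_pairs_flat_signal(self, rng):
        L = 400
        base = "".join(rng.choice(list("ACGT"), size=L))
        seqs = {}
        for i, name in enumerate(["w", "x", "y", "z"]):
            s = list(base)
            for j in range(i, L, 9):
                s[j] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[j]]
            seqs[name] = "".join(s)
        track = bootscan_signal(_aln(seqs), ("w", "x"), WindowSpec(200, 200),
                                B=30, rng=np.random.default_rng(5))
        assert track.pct_trees.between(0, 100).all()

    def test_too_few_taxa_rejected(self):
        aln = _aln({"a": "ACGT" * 30, "b": "ACGT" * 30, "c": "ACGA" * 30})
        with pytest.raises(ValueError):
            bootscan_signal(aln, ("a", "b"), WindowSpec(60, 60), B=5)


class TestNewick:
    def test_round_trip_preserves_topology(self, rng):
        t = random_topology(list("ABCDEF"), rng)
        back = tree_from_newick(t.to_newick())
        assert back.bipartitions() == t.bipartitions()

    def test_dendropy_agrees_on_rf(self):
        """Cross-check normalized RF against dendropy's symmetric difference."""
        import dendropy
        n1 = "((A,B),((C,D),(E,F)));"
        n2 = "((A,C),((B,D),(E,F)));"
        t1, t2 = tree_from_newick(n1), tree_from_newick(n2)
        mine = robinson_foulds_normalized(t1, t2)
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=n1, schema="newick", taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=n2, schema="newick", taxon_namespace=tns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        sym = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert mine == pytest.approx(sym / (2 * (6 - 3)))
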