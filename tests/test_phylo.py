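"""Distance matrices, NJ exactness on additive inputs, bootstrap."""

import numpy as np
import pytest
import skbio
from skbio import DistanceMatrix

from ervkit.phylo import (
    bootstrap_support,
    distance_matrix_from_alignment,
    nj_tree,
)


def random_additive_matrix(rng, n_taxa):
    """Random binary tree with random branch lengths -> path-length matrix.

    The tree-path oracle: NJ must reconstruct these distances exactly.
    """
    nodes = [({i}, {i: 0.0}) for i in range(n_taxa)]  # (tips, dist-to-tips)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        (ta, da), (tb, db) = nodes[i], nodes[j]
        la, lb = rng.uniform(0.05, 1.0, size=2)
        merged = {t: d + la for t, d in da.items()}
        merged.update({t: d + lb for t, d in db.items()})
        for idx in sorted((i, j), reverse=True):
            nodes.pop(idx)
        nodes.append((ta | tb, merged))
        # record pairwise distances once both sides are in one component
        for x in da:
            for y in db:
                DIST[(min(x, y), max(x, y))] = da[x] + la + lb + db[y]
    M = np.zeros((n_taxa, n_taxa))
    for (x, y), d in DIST.items():
        M[x, y] = M[y, x] = d
    return DistanceMatrix(M, ids=[f"t{i}" for i in range(n_taxa)])


class TestDistanceMatrix:
    def test_identical_sequences_zero_matrix(self):
        dm = distance_matrix_from_alignment(
            {"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        assert np.allclose(dm.data, 0)

    def test_hand_counted_triplet(self):
        dm = distance_matrix_from_alignment(
            {"x": "ACGT", "y": "ACGA", "z": "TCGA"})
        assert dm["x", "y"] == pytest.approx(0.25)
        assert dm["x", "z"] == pytest.approx(0.5)
        assert dm["y", "z"] == pytest.approx(0.25)

    def test_masking_is_noop_without_cpg(self):
        seqs = {"a": "ATATTA", "b": "ATTTTA", "c": "AAATTA"}
        d1 = distance_matrix_from_alignment(seqs, mask_cpg=False)
        d2 = distance_matrix_from_alignment(seqs, mask_cpg=True)
        assert np.allclose(d1.data, d2.data)

    def test_disjoint_pair_raises_naming_both(self):
        with pytest.raises(ValueError, match="a.*b|b.*a"):
            distance_matrix_from_alignment(
                {"a": "AC--", "b": "--GT", "c": "ACGT"})


class TestNeighborJoining:
    def test_four_taxon_split_and_lengths(self):
        dm = DistanceMatrix(np.array([
            [0, .2, .4, .4], [.2, 0, .4, .4],
            [.4, .4, 0, .2], [.4, .4, .2, 0]]), ids=list("ABCD"))
        t = nj_tree(dm)
        # split AB|CD with leaf branches 0.1 and internal branch 0.2
        ab = t.lca([t.find("A"), t.find("B")])
        assert {x.name for x in ab.tips()} in ({"A", "B"}, {"C", "D"})
        assert t.find("A").length == pytest.approx(0.1)
        assert t.find("A").distance(t.find("B")) == pytest.approx(0.2)
        assert t.find("A").distance(t.find("C")) == pytest.approx(0.4)

    @pytest.mark.parametrize("trial", range(10))
    def test_exact_recovery_on_additive_matrices(self, trial):
        global DIST
        DIST = {}
        rng = np.random.default_rng(trial)
        n = int(rng.integers(6, 11))
        dm = random_additive_matrix(rng, n)
        t = nj_tree(dm)
        tips = {x.name: x for x in t.tips()}
        for i, a in enumerate(dm.ids):
            for b in dm.ids[i + 1:]:
                assert tips[a].distance(tips[b]) == \
                    pytest.approx(dm[a, b], abs=1e-9)

    def test_matches_reference_nj_topology(self):
        # independent cross-check against scikit-bio's NJ
        from skbio.tree import nj as skbio_nj
        rng = np.random.default_rng(3)
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), 200))
                for i in range(7)}
        dm = distance_matrix_from_alignment(seqs)

        def splits(t):
            tips = frozenset(x.name for x in t.tips())
            out = set()
            for n_ in t.non_tips(include_self=False):
                s = frozenset(x.name for x in n_.tips())
                if 1 < len(s) < len(tips) - 1:
                    out.add(min(s, tips - s,
                                key=lambda z: (len(z), sorted(z))))
            return out

        assert splits(nj_tree(dm)) == splits(skbio_nj(dm))

    def test_label_permutation_invariant(self):
        # generic (tie-free) additive distances: the same tree must come
        # back whatever the input label order
        global DIST
        DIST = {}
        rng = np.random.default_rng(4)
        dm1 = random_additive_matrix(rng, 7)
        order = list(reversed(dm1.ids))
        dm2 = dm1.filter(order)
        t1, t2 = nj_tree(dm1), nj_tree(dm2)
        d1 = {frozenset((a.name, b.name)): t1.find(a.name).distance(
            t1.find(b.name)) for a in t1.tips() for b in t1.tips()
            if a.name < b.name}
        d2 = {k: t2.find(min(k)).distance(t2.find(max(k))) for k in d1}
        for k in d1:
            assert d1[k] == pytest.approx(d2[k], abs=1e-9)

    def test_too_few_taxa_rejected(self):
        dm = DistanceMatrix(np.array([[0, .1], [.1, 0]]), ids=["a", "b"])
        with pytest.raises(ValueError):
            nj_tree(dm)


def _two_clade_seqs(rng, n_per=4, L=400, within=4, between=80):
    base = "".join(rng.choice(list("ACGT"), L))
    other = list(base)
    for p in rng.choice(L, between, replace=False):
        other[p] = rng.choice([c for c in "ACGT" if c != other[p]])
    other = "".join(other)

    def mut(s, n):
        s = list(s)
        for p in rng.choice(L, n, replace=False):
            s[p] = rng.choice([c for c in "ACGT" if c != s[p]])
        return "".join(s)

    seqs = {f"x{i}": mut(base, within) for i in range(n_per)}
    seqs |= {f"y{i}": mut(other, within) for i in range(n_per)}
    return seqs


class TestBootstrap:
    def test_clade_split_strongly_supported(self):
        rng = np.random.default_rng(11)
        seqs = _two_clade_seqs(rng)
        tree = bootstrap_support(seqs, n_reps=200, seed=5)
        clade = frozenset(f"x{i}" for i in range(4))
        supports = {frozenset(t.name for t in n.tips()): n.support
                    for n in tree.non_tips(include_self=False)
                    if hasattr(n, "support")}
        matching = [s for side, s in supports.items()
                    if side in (clade, frozenset(seqs) - clade)]
        assert matching and max(matching) >= 95

    def test_single_replicate_supports_are_binary(self):
        rng = np.random.default_rng(12)
        seqs = _two_clade_seqs(rng, n_per=3, L=200)
        tree = bootstrap_support(seqs, n_reps=1, seed=1)
        for n in tree.non_tips(include_self=False):
            if hasattr(n, "support"):
                assert n.support in (0.0, 100.0)

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(13)
        seqs = _two_clade_seqs(rng, n_per=3, L=200)
        t1 = bootstrap_support(seqs, n_reps=30, seed=9)
        t2 = bootstrap_support(seqs, n_reps=30, seed=9)
        s1 = sorted(n.support for n in t1.non_tips(include_self=False)
                    if hasattr(n, "support"))
        s2 = sorted(n.support for n in t2.non_tips(include_self=False)
                    if hasattr(n, "support"))
        assert s1 == s2


class TestCategorySeparation:
    def test_young_category_clusters_apart_from_old(self, small_cohort):
        """Age structure separates the young species-specific insertions
        from the old human-shared ones, echoing the category clustering
        seen in provirus trees: the young loci sit much closer to each
        other than to any old locus."""
        from ervkit.dating import p_distance
        old, young = [], []
        for pl in small_cohort.loci:
            if pl.solo_ltr or pl.species != "macfas":
                continue
            if pl.category == "human_shared":
                old.append(pl.ltr5)
            elif pl.category == "species_specific":
                young.append(pl.ltr5)
        within_young = [p_distance(a, b)[0]
                        for i, a in enumerate(young) for b in young[i + 1:]]
        between = [p_distance(a, b)[0] for a in old for b in young]
        assert max(within_young) < min(between)
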