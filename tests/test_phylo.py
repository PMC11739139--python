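import itertools

import dendropy
import numpy as np
import pytest

from retrohtt import phylo, simulate
from retrohtt.divergence import SaturatedDistanceError
from retrohtt.evaluation import random_additive_tree
from retrohtt.phylo import (
    DistanceMatrix,
    UndefinedSisterError,
    bipartitions,
    bootstrap_support,
    distance_matrix,
    htt_flag,
    is_monophyletic,
    midpoint_root,
    nj_tree,
    patristic_distances,
    rf_distance,
    sister_group,
    tip_labels,
)

# ---------------------------------------------------------------------------
# independent oracle: exhaustive minimum-evolution search
#
# Enumerate every unrooted binary topology (by sequential taxon addition to
# each edge), fit branch lengths by ordinary least squares on the path
# matrix, and keep the topology with the smallest residual.  For an additive
# matrix the generating topology fits with zero residual and unique branch
# lengths, so this search is an oracle for NJ correctness.


def _splits_from_adjacency(adj, taxa):
    """Non-trivial splits of an unrooted tree given as an adjacency map."""
    labels = frozenset(taxa)
    ref = min(labels)
    splits = set()
    for u in adj:
        for v in adj[u]:
            # taxa reachable from v without crossing u
            stack, seen = [v], {u, v}
            side = set()
            while stack:
                cur = stack.pop()
                if isinstance(cur, str):
                    side.add(cur)
                for nxt in adj[cur]:
                    if nxt not in seen:
                        seen.add(nxt)
                        stack.append(nxt)
            side = frozenset(side)
            if ref in side:
                side = labels - side
            if 2 <= len(side) <= len(labels) - 2:
                splits.add(frozenset(side))
    return frozenset(splits)


def _enumerate_topologies(taxa):
    """Yield the split set of every unrooted binary topology over ``taxa``
    (sequential taxon insertion onto each edge; 6 taxa -> 105 trees)."""
    counter = itertools.count()

    def edges_of(adj):
        out = []
        for u in adj:
            for v in adj[u]:
                if (v, u) not in out:
                    out.append((u, v))
        return out

    def grow(adj, remaining):
        if not remaining:
            yield _splits_from_adjacency(adj, taxa)
            return
        t = remaining[0]
        for u, v in edges_of(adj):
            w = ("internal", next(counter))
            new = {k: set(vs) for k, vs in adj.items()}
            new[u].discard(v)
            new[v].discard(u)
            new[w] = {u, v, t}
            new[u].add(w)
            new[v].add(w)
            new[t] = {w}
            yield from grow(new, remaining[1:])

    root = ("internal", next(counter))
    adj = {root: set(taxa[:3])}
    for t in taxa[:3]:
        adj[t] = {root}
    yield from grow(adj, list(taxa[3:]))


def _ols_fit(splits, taxa, matrix):
    """OLS branch lengths for the topology given by ``splits``; returns
    (residual, fitted path matrix)."""
    n = len(taxa)
    idx = {t: i for i, t in enumerate(taxa)}
    all_edges = [frozenset([t]) for t in taxa] + sorted(splits, key=sorted)
    pairs = list(itertools.combinations(taxa, 2))
    A = np.zeros((len(pairs), len(all_edges)))
    y = np.zeros(len(pairs))
    for r, (a, b) in enumerate(pairs):
        y[r] = matrix[idx[a], idx[b]]
        for c, edge in enumerate(all_edges):
            # edge separates a from b iff exactly one of them is inside
            if (a in edge) != (b in edge):
                A[r, c] = 1.0
    coef, residuals, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = float(np.sum((A @ coef - y) ** 2))
    return resid, coef


def exhaustive_best_topology(taxa, matrix):
    best = None
    count = 0
    for splits in _enumerate_topologies(list(taxa)):
        count += 1
        resid, _ = _ols_fit(splits, list(taxa), matrix)
        if best is None or resid < best[0]:
            best = (resid, splits)
    return best[1], best[0], count


def _tree_splits(tree):
    return bipartitions(tree)


class TestNJ:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(ids=["a", "b", "c"],
                            matrix=np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0.0]]))
        tree = nj_tree(dm)
        pd = patristic_distances(tree)
        assert np.allclose(pd.matrix, dm.matrix)

    def test_four_taxon_additive_recovery(self):
        # ((A:2,B:1):4,(C:1,D:2)) -> classic additive matrix
        m = np.array([[0, 3, 7, 8], [3, 0, 6, 7], [7, 6, 0, 3], [8, 7, 3, 0]],
                     dtype=float)
        dm = DistanceMatrix(ids=list("ABCD"), matrix=m)
        for variant in ("classic", "bionj"):
            tree = nj_tree(dm, variant=variant)
            assert frozenset(["A", "B"]) in _tree_splits(tree) or \
                frozenset(["C", "D"]) in _tree_splits(tree)
            assert np.allclose(patristic_distances(tree).matrix, m, atol=1e-12)

    @pytest.mark.parametrize("variant", ["classic", "bionj"])
    def test_six_taxon_additive_matches_exhaustive_search(self, variant, rng):
        for _ in range(5):
            true_tree, ids, matrix = random_additive_tree(6, rng)
            est = nj_tree(DistanceMatrix(ids=ids, matrix=matrix), variant=variant)
            best_splits, resid, count = exhaustive_best_topology(ids, matrix)
            assert count == 105  # all unrooted 6-taxon topologies visited
            assert resid < 1e-18
            assert _tree_splits(est) == set(best_splits)
            assert np.allclose(patristic_distances(est).matrix, matrix, atol=1e-9)

    def test_saturated_pair_refused_with_actionable_message(self):
        m = np.array([[0, 0.1, np.nan], [0.1, 0, 0.2], [np.nan, 0.2, 0.0]])
        dm = DistanceMatrix(ids=["a", "b", "c"], matrix=m)
        with pytest.raises(SaturatedDistanceError, match="saturated"):
            nj_tree(dm)

    def test_distance_matrix_equals_elementwise_k2p(self, rng):
        from retrohtt.divergence import k2p

        msa = {}
        anc = simulate.random_sequence(400, rng)
        for i in range(5):
            msa[f"t{i}"] = simulate.evolve_sequence(anc, 0.05, 2.0, rng)
        dm = distance_matrix(msa)
        for i, j in itertools.combinations(range(5), 2):
            expected = k2p(msa[dm.ids[i]], msa[dm.ids[j]]).d
            assert dm.matrix[i, j] == pytest.approx(expected, abs=1e-12)
        assert np.allclose(dm.matrix, dm.matrix.T)


class TestMidpointRoot:
    def test_two_tip_midpoint(self):
        tree = dendropy.Tree.get(data="(a:1,b:3);", schema="newick")
        rooted = midpoint_root(tree)
        depths = {leaf.taxon.label: leaf.distance_from_root()
                  for leaf in rooted.leaf_node_iter()}
        assert depths["a"] == pytest.approx(2.0)
        assert depths["b"] == pytest.approx(2.0)

    def test_max_depth_is_half_diameter(self, rng):
        _, ids, matrix = random_additive_tree(10, rng)
        tree = nj_tree(DistanceMatrix(ids=ids, matrix=matrix))
        rooted = midpoint_root(tree)
        diameter = matrix.max()
        max_depth = max(leaf.distance_from_root()
                        for leaf in rooted.leaf_node_iter())
        assert max_depth == pytest.approx(diameter / 2, abs=1e-9)

    def test_idempotent_on_topology(self, rng):
        _, ids, matrix = random_additive_tree(8, rng)
        tree = nj_tree(DistanceMatrix(ids=ids, matrix=matrix))
        once = midpoint_root(tree)
        twice = midpoint_root(once)
        assert bipartitions(once) == bipartitions(twice)

    def test_zero_length_tree_is_ambiguous(self):
        tree = dendropy.Tree.get(data="(a:0,b:0);", schema="newick")
        with pytest.raises(ValueError):
            midpoint_root(tree)


class TestCladeQueries:
    @staticmethod
    def _tree(newick):
        return dendropy.Tree.get(data=newick, schema="newick")

    def test_full_tip_set_is_monophyletic_with_undefined_sister(self):
        t = self._tree("((a:1,b:1):1,(c:1,d:1):1);")
        assert is_monophyletic(t, ["a", "b", "c", "d"])
        with pytest.raises(UndefinedSisterError):
            sister_group(t, ["a", "b", "c", "d"])

    def test_sister_group_of_cherry(self):
        t = self._tree("((a:1,b:1):1,(c:1,d:1):1);")
        assert sister_group(t, ["a", "b"]) == frozenset(["c", "d"])

    def test_unknown_tip_rejected(self):
        t = self._tree("((a:1,b:1):1,c:1);")
        with pytest.raises(ValueError):
            is_monophyletic(t, ["a", "zzz"])

    def test_rf_distance_self_is_zero(self):
        t = self._tree("((a:1,b:1):1,(c:1,(d:1,e:1):1):1);")
        assert rf_distance(t, t) == 0

    def test_rf_of_single_nni_is_two(self):
        t1 = self._tree("(((a:1,b:1):1,c:1):1,(d:1,e:1):1);")
        t2 = self._tree("(((a:1,c:1):1,b:1):1,(d:1,e:1):1);")
        assert rf_distance(t1, t2) == 2

    def test_monophyly_matches_brute_force_on_random_tree(self, rng):
        _, ids, matrix = random_additive_tree(8, rng)
        tree = nj_tree(DistanceMatrix(ids=ids, matrix=matrix))
        splits = bipartitions(tree)
        labels = set(ids)
        ref = min(labels)
        for size in (2, 3, 4):
            for subset in itertools.combinations(sorted(ids), size):
                side = frozenset(subset)
                canonical = side if ref not in side else frozenset(labels - side)
                expected = (len(canonical) < 2 or len(canonical) > len(ids) - 2
                            or canonical in splits)
                assert is_monophyletic(tree, subset) == expected


class TestBootstrap:
    @staticmethod
    def _perfect_alignment():
        # caterpillar (((a,b),c),((d,e),f)): 40 unique synapomorphy columns
        # per internal edge plus constant background -> zero homoplasy and
        # every internal edge has positive length
        taxa = list("abcdef")
        edge_groups = [("a", "b"), ("d", "e"), ("a", "b", "c")]
        cols = []
        for g in edge_groups:
            for _ in range(20):
                cols.append(["G" if t in g else "A" for t in taxa])
        for _ in range(200):
            cols.append(["C"] * 6)
        arr = np.array(cols).T
        return {t: "".join(arr[i]) for i, t in enumerate(taxa)}

    def test_strong_signal_gives_full_support(self):
        msa = self._perfect_alignment()
        tree = bootstrap_support(msa, n=50, seed=0)
        sups = [int(n.label) for n in tree.preorder_internal_node_iter()
                if n.label is not None]
        assert sups and all(s == 100 for s in sups)

    def test_single_replicate_supports_are_binary(self):
        msa = self._perfect_alignment()
        tree = bootstrap_support(msa, n=1, seed=3)
        sups = [int(n.label) for n in tree.preorder_internal_node_iter()
                if n.label is not None]
        assert set(sups) <= {0, 100}

    def test_same_seed_reproduces_supports(self):
        msa = self._perfect_alignment()
        t1 = bootstrap_support(msa, n=20, seed=7)
        t2 = bootstrap_support(msa, n=20, seed=7)
        s1 = sorted(n.label for n in t1.preorder_internal_node_iter() if n.label)
        s2 = sorted(n.label for n in t2.preorder_internal_node_iter() if n.label)
        assert s1 == s2

    def test_supports_invariant_to_taxon_input_order(self):
        msa = self._perfect_alignment()
        rev = dict(reversed(list(msa.items())))
        sup = {}
        for key, m in (("fwd", msa), ("rev", rev)):
            tree = bootstrap_support(m, n=25, seed=11)
            labels = set(tip_labels(tree))
            ref = min(labels)
            for node in tree.preorder_internal_node_iter():
                if node.label is None:
                    continue
                side = frozenset(l.taxon.label for l in node.leaf_iter())
                if ref in side:
                    side = frozenset(labels - side)
                sup.setdefault(side, {})[key] = node.label
        for side, vals in sup.items():
            if len(vals) == 2:
                assert vals["fwd"] == vals["rev"]


class TestHTTFlag:
    @staticmethod
    def _host():
        # lineage tree ((X,Y),Z) with one strain per lineage
        return dendropy.Tree.get(data="((X:1,Y:1):1,Z:2);", schema="newick")

    def test_vertical_pattern_produces_no_flags(self):
        te = dendropy.Tree.get(
            data="(((x1:0.01,x2:0.01)100:0.5,(y1:0.01,y2:0.01)100:0.5)100:1,"
                 "(z1:0.01,z2:0.01)100:1.5);", schema="newick")
        species = {t: t[0].upper() for t in
                   ("x1", "x2", "y1", "y2", "z1", "z2")}
        flags = htt_flag(te, self._host(), species)
        assert flags == []

    def test_transferred_clade_is_flagged_incongruent(self):
        # x3 nests within the Z clade: X's TE sister is Z, host sister is Y
        te = dendropy.Tree.get(
            data="(((x1:0.01,x2:0.01)100:0.5,(y1:0.01,y2:0.01)100:0.5)100:1,"
                 "((z1:0.02,x3:0.02)100:0.2,z2:0.2)100:1.5);", schema="newick")
        species = {t: t[0].upper() for t in
                   ("x1", "x2", "x3", "y1", "y2", "z1", "z2")}
        flags = htt_flag(te, self._host(), species)
        evidence = {f.evidence for f in flags}
        assert "incongruence" in evidence
        inc = next(f for f in flags if f.evidence == "incongruence")
        assert inc.clade == frozenset(["x3"])
        assert "excess_similarity" in evidence  # x3-z1 distance << host X-Z

    def test_patchy_presence_is_flagged(self):
        te = dendropy.Tree.get(
            data="(((x1:0.01,x2:0.01)100:0.5,(y1:0.01,y2:0.01)100:0.5)100:1,"
                 "(z1:0.01,z2:0.01)100:1.5);", schema="newick")
        species = {t: t[0].upper() for t in
                   ("x1", "x2", "y1", "y2", "z1", "z2")}
        presence = {"X": {"Tsu4": True}, "Y": {"Tsu4": False}, "Z": {"Tsu4": True}}
        flags = htt_flag(te, self._host(), species, presence_table=presence,
                         patchy_min_absent=1)
        assert any(f.evidence == "patchy_distribution" for f in flags)
        # by default, a single absent tip is attributed to one loss event
        flags = htt_flag(te, self._host(), species, presence_table=presence)
        assert not any(f.evidence == "patchy_distribution" for f in flags)

    def test_unmapped_tip_rejected(self):
        te = dendropy.Tree.get(data="((x1:1,y1:1):1,z1:2);", schema="newick")
        with pytest.raises(ValueError, match="without species"):
            htt_flag(te, self._host(), {"x1": "X"})
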