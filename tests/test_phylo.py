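"""Tree container, Newick round-trips, birth-death simulation, transforms."""

import math

import numpy as np
import pytest

from treesink.phylo import (
    NewickError,
    Phylogeny,
    cophenetic_distances,
    delta_rescale,
    eb_rescale,
    read_newick,
    simulate_birth_death,
    tree_depth,
    write_newick,
)


# ----------------------------------------------------------------------
# independent oracles
# ----------------------------------------------------------------------

def brute_force_distances(tree: Phylogeny) -> np.ndarray:
    """Per-pair path walk: edges to root per tip, symmetric difference."""
    paths = []
    for tip in range(tree.n_tips):
        edges = {}
        v = tip
        while v != tree.root:
            edges[v] = tree.edge_length[v]
            v = tree.parent[v]
        paths.append(edges)
    n = tree.n_tips
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            keys = set(paths[i]) ^ set(paths[j])
            d = sum(paths[i].get(k, 0.0) + paths[j].get(k, 0.0) for k in keys)
            D[i, j] = D[j, i] = d
    return D


def gillespie_crown_depth(n_tips, birth, death, rng):
    """Event-record forward simulation; returns crown depth of survivors.

    Independent re-implementation used as an oracle: explicit per-lineage
    event records, ancestry walks for the MRCA, no tree structure shared
    with the package.
    """
    while True:
        # records: (parent_record, start_time); alive set of record ids
        parent = {0: (-1, 0.0), 1: (0, 0.0), 2: (0, 0.0)}
        alive = {1, 2}
        t = 0.0
        nxt = 3
        while alive and len(alive) < n_tips:
            t += rng.exponential(1.0 / ((birth + death) * len(alive)))
            lin = list(alive)[rng.integers(len(alive))]
            if rng.random() < birth / (birth + death):
                alive.remove(lin)
                parent[nxt] = (lin, t)
                parent[nxt + 1] = (lin, t)
                alive.update((nxt, nxt + 1))
                nxt += 2
            else:
                alive.remove(lin)
        if len(alive) == n_tips:
            break
    # MRCA of survivors by ancestry intersection
    def ancestry(v):
        out = []
        while v != -1:
            out.append(v)
            v = parent[v][0]
        return out

    common = set(ancestry(next(iter(alive))))
    for v in alive:
        common &= set(ancestry(v))
    # MRCA = the common ancestor whose (only) relevant split is deepest:
    # the one with the latest start time among common ancestors whose two
    # child-lineages both lead to survivors.  Equivalently: of all common
    # ancestors, the one with maximal birth time of its children on the
    # surviving paths.  Walk from a survivor until reaching the first node
    # shared by all ancestries.
    path0 = ancestry(next(iter(alive)))
    mrca = next(v for v in path0 if v in common)
    # depth = stop time - time the MRCA's children were born
    children_start = [st for v, (p, st) in parent.items() if p == mrca]
    return t - min(children_start) if children_start else 0.0


# ----------------------------------------------------------------------
# Newick I/O
# ----------------------------------------------------------------------

class TestNewick:
    def test_basic_parse(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        assert t.n_tips == 3
        assert tree_depth(t) == pytest.approx(2.0)
        # ladderized order: singleton clade C first, then {A, B}
        assert t.tip_labels == ["C", "A", "B"]

    def test_round_trip_idempotent(self, tree48):
        text1 = write_newick(tree48)
        text2 = write_newick(read_newick(text1))
        assert text1 == text2

    def test_round_trip_preserves_lengths(self, tree48):
        back = read_newick(write_newick(tree48))
        assert back.tip_labels == tree48.tip_labels
        np.testing.assert_allclose(
            cophenetic_distances(back), cophenetic_distances(tree48), rtol=1e-10
        )

    @pytest.mark.parametrize("bad", ["((A:1,B:1):1,C)", "((A:1,B:1:1,C:2);", "(A,B);"])
    def test_malformed_or_missing_length_raises(self, bad):
        with pytest.raises(NewickError):
            read_newick(bad)

    def test_rotation_invariant_tip_order(self):
        a = read_newick("((A:1,B:1):1,C:2);")
        b = read_newick("(C:2,(B:1,A:1):1);")
        assert a.tip_labels == b.tip_labels


# ----------------------------------------------------------------------
# birth-death simulation
# ----------------------------------------------------------------------

class TestBirthDeath:
    def test_tip_count_and_ultrametric(self, tree48):
        assert tree48.n_tips == 48
        assert tree48.is_ultrametric()

    def test_pure_birth_small(self):
        t = simulate_birth_death(3, 1.0, 0.0, seed=7)
        assert t.n_tips == 3
        assert t.is_ultrametric()

    def test_seeded_reproducibility(self):
        a = simulate_birth_death(20, 0.8, 0.2, seed=11)
        b = simulate_birth_death(20, 0.8, 0.2, seed=11)
        assert write_newick(a) == write_newick(b)

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            simulate_birth_death(10, 0.2, 0.8, seed=1)
        with pytest.raises(ValueError):
            simulate_birth_death(2, 1.0, 0.0, seed=1)

    def test_mean_depth_matches_event_queue_oracle(self):
        """Crown depth distribution agrees with an independent Gillespie
        implementation (Welch comparison of means over 200 replicates)."""
        n_rep = 200
        rng = np.random.default_rng(99)
        ours = np.array(
            [tree_depth(simulate_birth_death(48, 0.8, 0.2, seed=rng)) for _ in range(n_rep)]
        )
        rng2 = np.random.default_rng(199)
        oracle = np.array(
            [gillespie_crown_depth(48, 0.8, 0.2, rng2) for _ in range(n_rep)]
        )
        se = math.sqrt(ours.var(ddof=1) / n_rep + oracle.var(ddof=1) / n_rep)
        assert abs(ours.mean() - oracle.mean()) < 4 * se


# ----------------------------------------------------------------------
# transforms
# ----------------------------------------------------------------------

class TestEBRescale:
    def test_identity_at_zero(self, tree48):
        out = eb_rescale(tree48, 0.0)
        np.testing.assert_array_equal(out.edge_length, tree48.edge_length)

    def test_single_branch_closed_form(self):
        t = read_newick("(A:1,B:1);")  # two branches spanning [0, 1]
        out = eb_rescale(t, 1.0)
        np.testing.assert_allclose(
            out.edge_length[:2], math.e - 1.0, rtol=1e-12
        )

    def test_chain_closed_form_and_additivity(self):
        # chain 0 -> 0.5 -> 1.0 realized as a cherry hanging at height 0.5
        t = read_newick("((A:0.5,B:0.5):0.5,C:1);")
        out = eb_rescale(t, 2.0)
        internal = t.n_tips  # first internal node after tips is the root; cherry node follows
        # tip branches of the cherry span [0.5, 1.0]
        lab = {l: i for i, l in enumerate(t.tip_labels)}
        assert out.edge_length[lab["A"]] == pytest.approx((math.e**2 - math.e) / 2, abs=1e-9)
        # C spans [0, 1]
        assert out.edge_length[lab["C"]] == pytest.approx((math.e**2 - 1) / 2, abs=1e-9)
        # cherry stem spans [0, 0.5]
        stem = [v for v in range(t.n_nodes) if v not in (t.root, lab["A"], lab["B"], lab["C"])][0]
        assert out.edge_length[stem] == pytest.approx((math.e - 1) / 2, abs=1e-9)
        # additivity: stem + tip = full span
        assert out.edge_length[stem] + out.edge_length[lab["A"]] == pytest.approx(
            out.edge_length[lab["C"]], rel=1e-12
        )

    def test_limit_a_to_zero(self, tree48):
        out = eb_rescale(tree48, 1e-10)
        assert np.abs(out.edge_length - tree48.edge_length).max() < 1e-8

    def test_root_to_tip_additivity(self, tree48):
        a = 0.7
        out = eb_rescale(tree48, a)
        expected = (np.exp(a * tree48.node_depths[:48]) - 1.0) / a
        np.testing.assert_allclose(out.node_depths[:48], expected, rtol=1e-10)


class TestDeltaRescale:
    def test_identity_at_one(self, tree48):
        out = delta_rescale(tree48, 1.0)
        np.testing.assert_allclose(out.edge_length, tree48.edge_length, atol=1e-12)

    def test_chain_delta_two(self):
        t = read_newick("((A:0.5,B:0.5):0.5,C:1);")
        out = delta_rescale(t, 2.0)
        lab = {l: i for i, l in enumerate(t.tip_labels)}
        stem = [v for v in range(t.n_nodes) if v not in (t.root, lab["A"], lab["B"], lab["C"])][0]
        assert out.edge_length[stem] == pytest.approx(0.25, abs=1e-9)
        assert out.edge_length[lab["A"]] == pytest.approx(0.75, abs=1e-9)

    def test_cherry_delta_half(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        out = delta_rescale(t, 0.5)
        lab = {l: i for i, l in enumerate(t.tip_labels)}
        assert out.edge_length[lab["A"]] == pytest.approx(2 - math.sqrt(2), abs=1e-9)

    def test_depth_preserved(self, tree48):
        for d in (0.3, 2.5):
            assert tree_depth(delta_rescale(tree48, d)) == pytest.approx(
                tree_depth(tree48), rel=1e-10
            )

    def test_no_rescale_flag(self, tree48):
        out = delta_rescale(tree48, 2.0, preserve_depth=False)
        assert tree_depth(out) == pytest.approx(tree_depth(tree48) ** 2, rel=1e-10)

    def test_nonpositive_delta(self, tree48):
        with pytest.raises(ValueError):
            delta_rescale(tree48, 0.0)


class TestDepthAndDistances:
    def test_cherry_depth(self, cherry_tree):
        assert tree_depth(cherry_tree) == pytest.approx(2.0)

    def test_caterpillar_depth(self):
        t = read_newick("((A:1,(B:0.5,C:0.5):0.5):1);")
        assert tree_depth(t) == pytest.approx(2.0)

    def test_depth_matches_path_walk(self, tree48):
        depths = []
        for tip in range(tree48.n_tips):
            v, d = tip, 0.0
            while v != tree48.root:
                d += tree48.edge_length[v]
                v = tree48.parent[v]
            depths.append(d)
        assert tree_depth(tree48) == pytest.approx(max(depths), rel=1e-12)

    def test_hand_cophenetic(self, cherry_tree):
        D = cophenetic_distances(cherry_tree)
        lab = {l: i for i, l in enumerate(cherry_tree.tip_labels)}
        assert D[lab["A"], lab["B"]] == pytest.approx(2.0)
        assert D[lab["A"], lab["C"]] == pytest.approx(4.0)
        assert D[lab["B"], lab["C"]] == pytest.approx(4.0)
        assert np.all(np.diag(D) == 0)

    def test_star_tree(self):
        t = read_newick("(A:1,B:1,C:1,D:1);")
        D = cophenetic_distances(t)
        off = D[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, 2.0)

    def test_matches_brute_force(self, tree48):
        np.testing.assert_allclose(
            cophenetic_distances(tree48), brute_force_distances(tree48), rtol=1e-10
        )

    def test_matches_dendropy(self, tree48):
        """Cross-check patristic distances against dendropy's own matrix."""
        import dendropy

        dt = dendropy.Tree.get(data=write_newick(tree48), schema="newick")
        pdm = dt.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in dt.taxon_namespace}
        D = cophenetic_distances(tree48)
        for i in range(0, 48, 7):
            for j in range(i + 1, 48, 11):
                expect = pdm.patristic_distance(
                    taxa[tree48.tip_labels[i]], taxa[tree48.tip_labels[j]]
                )
                assert D[i, j] == pytest.approx(expect, rel=1e-9)

    def test_root_lca_pairs_at_twice_depth(self, tree48):
        D = cophenetic_distances(tree48)
        assert D.max() == pytest.approx(2 * tree_depth(tree48), rel=1e-9)
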