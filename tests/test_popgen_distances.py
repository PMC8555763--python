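"""Nei D_A, R_st AMOVA and neighbor-joining against independent oracles."""

import io
import math

import numpy as np
import pytest

from forenpop.haploid_forensics import HaplotypeSet
from forenpop.io_formats import DistanceMatrix, ValidationError
from forenpop.popgen_distances import (
    Tree,
    TreeNode,
    da_matrix,
    nei_da,
    neighbor_joining,
    pairwise_rst,
    to_newick,
    two_group_amova,
)


def _hapset(mat, label):
    """Rows of single-copy repeat vectors → HaplotypeSet."""
    mat = np.asarray(mat, dtype=float)
    return HaplotypeSet(
        individuals=[f"{label}{i}" for i in range(len(mat))],
        loci=[f"L{j}" for j in range(mat.shape[1])],
        rows=[tuple((float(x),) for x in row) for row in mat],
        label=label,
    )


class TestNeiDA:
    def test_identical_is_zero(self):
        f = {"L1": {"a": 0.3, "b": 0.7}, "L2": {"x": 1.0}}
        assert nei_da(f, f) == 0.0

    def test_fixed_different_is_one(self):
        f1 = {"L1": {"a": 1.0}, "L2": {"x": 1.0}}
        f2 = {"L1": {"b": 1.0}, "L2": {"y": 1.0}}
        assert nei_da(f1, f2) == 1.0

    def test_no_shared_loci_rejected(self):
        with pytest.raises(ValidationError):
            nei_da({"L1": {"a": 1.0}}, {"L2": {"a": 1.0}})

    @pytest.mark.parametrize("seed", range(5))
    def test_bhattacharyya_oracle(self, seed):
        rng = np.random.default_rng(seed)
        f1, f2 = {}, {}
        for locus in ["L1", "L2", "L3"]:
            k = int(rng.integers(2, 5))
            alleles = [f"a{i}" for i in range(k)]
            f1[locus] = dict(zip(alleles, rng.dirichlet([1] * k)))
            f2[locus] = dict(zip(alleles, rng.dirichlet([1] * k)))
        # independent per-locus Bhattacharyya coefficients
        bc = [
            sum(
                math.sqrt(f1[l][a] * f2[l][a])
                for a in f1[l]
            )
            for l in ["L1", "L2", "L3"]
        ]
        assert nei_da(f1, f2) == pytest.approx(1 - np.mean(bc), abs=1e-12)

    def test_symmetry_and_range(self, cohort):
        dm = da_matrix(cohort.snp_frequencies)
        assert np.allclose(dm.values, dm.values.T)
        assert (dm.values >= 0).all() and (dm.values <= 1).all()
        assert np.allclose(np.diag(dm.values), 0.0)


def brute_force_rst(x1, x2):
    """Independent AMOVA from the explicit full pairwise d² matrix."""
    pooled = np.vstack([x1, x2])
    N = len(pooled)
    d2 = np.zeros((N, N))
    for i in range(N):
        for j in range(N):
            d2[i, j] = ((pooled[i] - pooled[j]) ** 2).sum()
    ssd_total = d2[np.triu_indices(N, 1)].sum() / N
    n1 = len(x1)
    within = 0.0
    for lo, hi in ((0, n1), (n1, N)):
        sub = d2[lo:hi, lo:hi]
        within += sub[np.triu_indices(hi - lo, 1)].sum() / (hi - lo)
    among = ssd_total - within
    s2w = within / (N - 2)
    nc = N - (n1**2 + (N - n1) ** 2) / N
    s2a = (among - s2w) / nc
    return s2a / (s2a + s2w)


class TestRst:
    def test_identical_groups_near_zero(self):
        x = np.array([[10, 20], [11, 21], [12, 20], [10, 22]], dtype=float)
        res = two_group_amova(x, x.copy())
        assert res.rst <= 1e-12

    def test_fixed_difference_is_one(self):
        a = np.full((5, 2), 10.0)
        b = np.full((6, 2), 14.0)
        res = two_group_amova(a, b)
        assert res.rst == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x1 = rng.integers(8, 20, size=(rng.integers(4, 12), 5)).astype(float)
        x2 = (
            rng.integers(8, 20, size=(rng.integers(4, 12), 5)).astype(float)
            + rng.integers(0, 3)
        )
        res = two_group_amova(x1, x2)
        assert res.rst == pytest.approx(brute_force_rst(x1, x2), abs=1e-10)
        assert res.ssd_total == pytest.approx(
            res.ssd_within + res.ssd_among, abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_affine_recoding_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x1 = rng.integers(8, 20, size=(8, 4)).astype(float)
        x2 = rng.integers(10, 22, size=(9, 4)).astype(float)
        shift = rng.integers(-5, 6, size=4).astype(float)
        r0 = two_group_amova(x1, x2).rst
        r1 = two_group_amova(x1 + shift, x2 + shift).rst
        assert r0 == pytest.approx(r1, abs=1e-12)

    def test_pairwise_matrix_and_microvariant_exclusion(self):
        g1 = _hapset([[10, 20], [11, 21], [12, 20]], "A")
        g2 = _hapset([[14, 20], [15, 21], [14, 22]], "B")
        # add a microvariant column to g1/g2 via direct row surgery
        g1m = HaplotypeSet(
            individuals=g1.individuals,
            loci=g1.loci + ["Lmv"],
            rows=[r + ((9.3,),) for r in g1.rows],
            label="A",
        )
        g2m = HaplotypeSet(
            individuals=g2.individuals,
            loci=g2.loci + ["Lmv"],
            rows=[r + ((10.0,),) for r in g2.rows],
            label="B",
        )
        with pytest.warns(UserWarning, match="Lmv"):
            dm_m, _ = pairwise_rst([g1m, g2m])
        dm, _ = pairwise_rst([g1, g2])
        assert dm_m.values == pytest.approx(dm.values)

    def test_permutation_p_identical_groups_large(self):
        rng = np.random.default_rng(0)
        x = rng.integers(10, 16, size=(12, 3)).astype(float)
        g1 = _hapset(x, "A")
        g2 = _hapset(rng.permutation(x), "B")
        _, pvals = pairwise_rst([g1, g2], n_perm=200, seed=4)
        assert pvals["p_value"].iloc[0] > 0.1

    def test_divergence_increases_rst(self):
        """Mean pairwise R_st grows with shared population drift time."""
        from forenpop.synthetic_data import (
            drift_founders,
            random_founders,
            simulate_str_haplotypes,
        )
        from forenpop.io_formats import LocusSpec

        specs = [LocusSpec(f"DYSx{i}", "Y-STR") for i in range(10)]
        founders = random_founders(specs, seed=2)
        means = []
        for gens in (0, 600, 2400):
            vals = []
            for rep in range(6):
                groups = []
                for side, s0 in (("A", 100), ("B", 500)):
                    drifted = drift_founders(
                        founders, mu=0.002, generations=gens,
                        seed=s0 + rep, label=f"{side}{gens}{rep}",
                    )
                    groups.append(
                        simulate_str_haplotypes(
                            drifted, mu=0.002, generations=200, n=40,
                            seed=s0 + rep, label=f"{side}{gens}{rep}",
                        )
                    )
                dm, _ = pairwise_rst(groups)
                vals.append(dm.values[0, 1])
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


def _biparts_from_newick(newick, labels):
    from skbio import TreeNode as SkNode

    t = SkNode.read(io.StringIO(newick))
    full = frozenset(labels)
    out = set()
    for node in t.non_tips(include_self=False):
        s = frozenset(x.name for x in node.tips())
        if 1 < len(s) < len(labels) - 1:
            out.add(min(s, full - s, key=sorted))
    return out


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        # three-point formulas: la = (dab + dac - dbc)/2, etc.
        m = DistanceMatrix(
            labels=["A", "B", "C"],
            values=[[0, 4, 6], [4, 0, 8], [6, 8, 0]],
        )
        t = neighbor_joining(m)
        pd_ = t.leaf_distances()
        assert pd_.loc["A", "B"] == pytest.approx(4)
        assert pd_.loc["A", "C"] == pytest.approx(6)
        assert pd_.loc["B", "C"] == pytest.approx(8)

    def test_four_taxon_additive_recovery(self):
        # tree ((A:2,B:3):1,C:4,D:5): additive path metric
        m = DistanceMatrix(
            labels=list("ABCD"),
            values=[[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]],
        )
        t = neighbor_joining(m)
        pd_ = t.leaf_distances()
        np.testing.assert_allclose(pd_.loc[list("ABCD"), list("ABCD")], m.values)
        assert _biparts_from_newick(to_newick(t), list("ABCD")) == {
            frozenset({"A", "B"})
        }

    @pytest.mark.parametrize("seed", range(6))
    def test_random_additive_matrices_recovered(self, seed):
        """NJ reconstructs the generating topology and path lengths of a
        random additive (tree-metric) matrix."""
        rng = np.random.default_rng(seed)
        n = 8
        labels = [f"T{i}" for i in range(n)]
        # random binary tree by sequential attachment, then path metric
        import itertools

        parent = {}
        lengths = {}
        nodes = [0, 1]
        lengths[(0, 1)] = rng.uniform(0.5, 2.0)
        edges = [(0, 1)]
        nxt = 2
        internal = n
        for leaf in range(2, n):
            u, v = edges[rng.integers(len(edges))]
            w = internal
            internal += 1
            edges.remove((u, v))
            half = lengths.pop((u, v)) / 2
            for pair, ln in (
                ((u, w), half),
                ((w, v), half),
                ((w, leaf), rng.uniform(0.5, 2.0)),
            ):
                edges.append(pair)
                lengths[pair] = ln
        adj = {}
        for (u, v), ln in lengths.items():
            adj.setdefault(u, []).append((v, ln))
            adj.setdefault(v, []).append((u, ln))

        def path(u, v):
            stack = [(u, None, 0.0)]
            while stack:
                node, prev, dist = stack.pop()
                if node == v:
                    return dist
                for nbr, ln in adj[node]:
                    if nbr != prev:
                        stack.append((nbr, node, dist + ln))

        mat = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            mat[i, j] = mat[j, i] = path(i, j)
        t = neighbor_joining(DistanceMatrix(labels=labels, values=mat))
        rec = t.leaf_distances().loc[labels, labels].to_numpy()
        np.testing.assert_allclose(rec, mat, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_topology_matches_skbio_on_random_matrices(self, seed):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj

        rng = np.random.default_rng(seed)
        n = 8
        x = rng.uniform(1, 10, size=(n, n))
        x = (x + x.T) / 2
        np.fill_diagonal(x, 0)
        labels = [f"P{i}" for i in range(n)]
        mine = to_newick(
            neighbor_joining(DistanceMatrix(labels=labels, values=x))
        )
        theirs = str(nj(SkDM(x, ids=labels)))
        assert _biparts_from_newick(mine, labels) == _biparts_from_newick(
            theirs, labels
        )

    def test_too_few_taxa_rejected(self):
        m = DistanceMatrix(labels=["A", "B"], values=[[0, 1], [1, 0]])
        with pytest.raises(ValidationError):
            neighbor_joining(m)

    def test_branch_lengths_non_negative(self, cohort):
        dm = da_matrix(cohort.snp_frequencies)
        t = neighbor_joining(dm)

        def walk(node):
            for child, bl in node.children:
                assert bl >= 0
                walk(child)

        walk(t.root)


class TestNewick:
    def test_two_leaf_star(self):
        t = Tree(
            root=TreeNode(
                children=[
                    (TreeNode(name="A"), 1.5),
                    (TreeNode(name="B"), 2.25),
                ]
            )
        )
        assert to_newick(t) == "(A:1.5,B:2.25);"

    def test_labels_with_spaces_quoted(self):
        t = Tree(
            root=TreeNode(
                children=[
                    (TreeNode(name="pop one"), 1.0),
                    (TreeNode(name="B"), 1.0),
                ]
            )
        )
        assert to_newick(t) == "('pop one':1,B:1);"

    def test_round_trip_through_skbio_parser(self, cohort):
        """Parsing our Newick with an independent parser preserves the
        native tree's leaf set and bipartitions."""
        from skbio import TreeNode as SkNode

        dm = da_matrix(cohort.snp_frequencies)
        t = neighbor_joining(dm)
        leaves = t.leaves()
        parsed = SkNode.read(io.StringIO(to_newick(t)))
        assert sorted(x.name for x in parsed.tips()) == sorted(leaves)

        # bipartitions computed natively from the Tree object
        full = frozenset(leaves)
        native = set()

        def walk(node):
            clade = frozenset(node.leaves())
            if 1 < len(clade) < len(full) - 1:
                native.add(min(clade, full - clade, key=sorted))
            for child, _ in node.children:
                walk(child)

        for child, _ in t.root.children:
            walk(child)
        assert native == _biparts_from_newick(to_newick(t), leaves)
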