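"""Population differentiation: Nei's D_A, pairwise R_st AMOVA, NJ trees.

D_A (Nei, Tajima & Tateno 1983) is one minus the locus-averaged
Bhattacharyya coefficient between two populations' allele-frequency
vectors. R_st is the stepwise-mutation-model analogue of F_st, obtained
from AMOVA variance components on squared repeat-count distances between
Y-STR haplotypes. Neighbor-joining follows Saitou & Nei with the
Studier–Keppler Q-criterion, with deterministic lexicographic
tie-breaking and midpoint rooting for the rooted presentation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .haploid_forensics import HaplotypeSet
from .io_formats import DistanceMatrix, ValidationError


# ---------------------------------------------------------------------------
# Nei's D_A
# ---------------------------------------------------------------------------


def nei_da(f1: dict, f2: dict) -> float:
    """Nei's D_A between two per-locus allele-frequency maps.

    ``f1``/``f2``: locus → {allele: frequency}. Only shared loci are
    used; within each locus the allele union is taken with absent
    alleles at frequency 0. D_A = 1 − (1/L) Σ_l Σ_i √(x_li · y_li).
    """
    shared = [l for l in f1 if l in f2]
    if not shared:
        raise ValidationError("no shared loci between populations")
    total = 0.0
    for locus in shared:
        x, y = f1[locus], f2[locus]
        total += sum(math.sqrt(x[a] * y[a]) for a in set(x) & set(y))
    d = 1.0 - total / len(shared)
    return min(max(d, 0.0), 1.0)


def da_matrix(freqs, populations=None) -> DistanceMatrix:
    """Pairwise D_A matrix from an AlleleFrequencyTable."""
    pops = populations or freqs.populations
    per_pop = {
        p: {l: freqs.freqs(p, l) for l in freqs.loci if freqs.freqs(p, l)}
        for p in pops
    }
    n = len(pops)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = nei_da(per_pop[pops[i]], per_pop[pops[j]])
    return DistanceMatrix(labels=list(pops), values=m, metric="DA")


# ---------------------------------------------------------------------------
# pairwise R_st (AMOVA on repeat counts)
# ---------------------------------------------------------------------------


def _haplotype_matrix(groups: list[HaplotypeSet]) -> tuple[list[str], list[np.ndarray]]:
    """Flatten shared integer-repeat loci of each group into arrays.

    Returns the retained locus column labels and one (n_g × m) array per
    group. A locus is excluded with a warning when any observed repeat
    number is non-integer (microvariants break the stepwise model);
    individuals missing any retained locus are dropped.
    """
    shared = [l for l in groups[0].loci if all(l in g.loci for g in groups)]
    if not shared:
        raise ValidationError("no shared loci across groups")
    copy_counts = {}
    bad = set()
    for locus in shared:
        arities = set()
        for g in groups:
            j = g.loci.index(locus)
            for row in g.rows:
                v = row[j]
                if v is None:
                    continue
                arities.add(len(v))
                if any(not float(x).is_integer() for x in v):
                    bad.add(locus)
        copy_counts[locus] = max(arities) if arities else 1
        if len(arities) > 1:
            bad.add(locus)
    for locus in sorted(bad):
        warnings.warn(
            f"locus {locus!r} excluded from R_st (microvariant or unequal "
            "copy number)",
            stacklevel=3,
        )
    kept = [l for l in shared if l not in bad]
    if not kept:
        raise ValidationError("no usable integer-repeat loci for R_st")
    columns = []
    for locus in kept:
        columns += [f"{locus}#{k}" for k in range(copy_counts[locus])]
    arrays = []
    for g in groups:
        idx = [g.loci.index(l) for l in kept]
        vecs = []
        for row in g.rows:
            if any(row[j] is None for j in idx):
                continue
            flat = []
            for j in idx:
                flat.extend(row[j])  # already sorted tuples
            vecs.append(flat)
        if len(vecs) < 2:
            raise ValidationError(
                f"group {g.label or '?'} has < 2 complete haplotypes"
            )
        arrays.append(np.asarray(vecs, dtype=float))
    return columns, arrays


@dataclass
class AmovaResult:
    """Two-group AMOVA on squared repeat-count distances."""

    ssd_total: float
    ssd_within: float
    ssd_among: float
    sigma2_within: float
    sigma2_among: float
    n_coefficient: float
    rst: float
    p_value: "float | None" = None

    def __post_init__(self):
        if abs(self.ssd_total - self.ssd_within - self.ssd_among) > 1e-9 * max(
            1.0, abs(self.ssd_total)
        ):
            raise ValidationError("SSD decomposition does not add up")


def _sum_within_pairs(x: np.ndarray) -> float:
    """Σ_{i<j} ‖x_i − x_j‖², via n Σ‖x_i‖² − ‖Σ x_i‖²."""
    n = len(x)
    sq = float((x * x).sum())
    s = x.sum(axis=0)
    return n * sq - float(s @ s)


def two_group_amova(
    x1: np.ndarray,
    x2: np.ndarray,
    n_perm: int = 0,
    seed: "int | None" = None,
) -> AmovaResult:
    """AMOVA variance components for two groups of repeat-count vectors.

    With d² the squared Euclidean distance on repeat numbers and N the
    pooled size: SSD_total = (1/N) Σ_{i<j} d²; SSD_within =
    Σ_g (1/n_g) Σ_{i<j∈g} d²; σ²_within = SSD_within/(N−2);
    n_c = N − (n₁²+n₂²)/N; σ²_among = (SSD_among − σ²_within)/n_c;
    R_st = σ²_among/(σ²_among + σ²_within). The optional permutation
    p-value is the fraction of label shuffles with R_st ≥ observed.
    """
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs >= 2 haplotypes")
    pooled = np.vstack([x1, x2])
    N = n1 + n2

    def components(a: np.ndarray, b: np.ndarray) -> tuple:
        na, nb = len(a), len(b)
        within = _sum_within_pairs(a) / na + _sum_within_pairs(b) / nb
        total = _sum_within_pairs(np.vstack([a, b])) / (na + nb)
        among = total - within
        s2_w = within / (na + nb - 2)
        n_c = (na + nb) - (na * na + nb * nb) / (na + nb)
        s2_a = (among - s2_w) / n_c
        denom = s2_a + s2_w
        rst = s2_a / denom if denom != 0 else 0.0
        return total, within, among, s2_w, s2_a, n_c, rst

    total, within, among, s2_w, s2_a, n_c, rst = components(x1, x2)

    p_value = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        idx = np.arange(N)
        hits = 0
        for _ in range(n_perm):
            rng.shuffle(idx)
            a = pooled[idx[:n1]]
            b = pooled[idx[n1:]]
            if components(a, b)[-1] >= rst - 1e-12:
                hits += 1
        p_value = hits / n_perm

    return AmovaResult(
        ssd_total=total,
        ssd_within=within,
        ssd_among=among,
        sigma2_within=s2_w,
        sigma2_among=s2_a,
        n_coefficient=n_c,
        rst=rst,
        p_value=p_value,
    )


def pairwise_rst(
    groups: list[HaplotypeSet],
    n_perm: int = 0,
    seed: "int | None" = None,
) -> tuple[DistanceMatrix, "pd.DataFrame | None"]:
    """Pairwise R_st matrix between populations of Y-STR haplotypes.

    Negative values are reported as computed (small negatives are
    sampling noise around zero differentiation), never truncated here.
    """
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    labels = [g.label or f"group{i + 1}" for i, g in enumerate(groups)]
    if len(set(labels)) != len(labels):
        raise ValidationError("group labels must be unique")
    _, arrays = _haplotype_matrix(groups)
    n = len(groups)
    m = np.zeros((n, n))
    prows = []
    for i in range(n):
        for j in range(i + 1, n):
            sub_seed = None if seed is None else (seed + 104729 * (i * n + j)) % (2**31)
            res = two_group_amova(arrays[i], arrays[j], n_perm=n_perm, seed=sub_seed)
            m[i, j] = m[j, i] = res.rst
            if n_perm > 0:
                prows.append(
                    {"pop1": labels[i], "pop2": labels[j], "p_value": res.p_value}
                )
    dm = DistanceMatrix(labels=labels, values=m, metric="RST")
    return dm, (pd.DataFrame(prows) if n_perm > 0 else None)


# ---------------------------------------------------------------------------
# neighbor-joining
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Rooted tree node; ``children`` holds (child, branch length) pairs."""

    name: "str | None" = None
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class Tree:
    """A rooted phylogenetic tree of population labels."""

    root: TreeNode

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def leaf_distances(self) -> pd.DataFrame:
        """Pairwise path-length matrix between leaves."""
        dists: dict = {}

        def walk(node: TreeNode) -> dict:
            if node.is_leaf:
                return {node.name: 0.0}
            below: list[dict] = []
            for child, bl in node.children:
                sub = walk(child)
                below.append({leaf: d + bl for leaf, d in sub.items()})
            for a in range(len(below)):
                for b in range(a + 1, len(below)):
                    for la, da in below[a].items():
                        for lb, db in below[b].items():
                            dists[tuple(sorted((la, lb)))] = da + db
            merged: dict = {}
            for sub in below:
                merged.update(sub)
            return merged

        walk(self.root)
        labels = sorted(self.leaves())
        m = pd.DataFrame(0.0, index=labels, columns=labels)
        for (a, b), d in dists.items():
            m.loc[a, b] = m.loc[b, a] = d
        return m


def neighbor_joining(m: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor-joining with midpoint rooting.

    Q-criterion ties are broken by the lexicographically first label
    pair (internal nodes inherit their smallest leaf label), so output
    is deterministic. Negative branch lengths are clamped to 0 with the
    deficit transferred to the sister branch.
    """
    if len(m.labels) < 3:
        raise ValidationError("neighbor-joining needs >= 3 taxa")

    # adjacency of the growing unrooted tree
    adjacency: dict = {}

    def connect(a, b, length):
        adjacency.setdefault(a, []).append((b, length))
        adjacency.setdefault(b, []).append((a, length))

    nodes = {lab: TreeNode(name=lab) for lab in m.labels}
    canon = {lab: lab for lab in m.labels}  # deterministic sort key per node
    d = {
        (a, b): float(m.get(a, b))
        for a in m.labels
        for b in m.labels
        if a != b
    }
    active = list(m.labels)
    next_id = 0

    while len(active) > 2:
        k = len(active)
        r = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best = None
        for ai in range(k):
            for bi in range(ai + 1, k):
                a, b = active[ai], active[bi]
                q = (k - 2) * d[(a, b)] - r[a] - r[b]
                key = tuple(sorted((canon[a], canon[b])))
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and key < best[1]
                ):
                    best = (q, key, a, b)
        _, _, a, b = best
        limb_a = d[(a, b)] / 2.0 + (r[a] - r[b]) / (2.0 * (k - 2))
        limb_b = d[(a, b)] - limb_a
        # clamp negative limbs, moving the deficit to the sister branch
        if limb_a < 0:
            limb_b += limb_a
            limb_a = 0.0
        if limb_b < 0:
            limb_a += limb_b
            limb_b = 0.0
        limb_b = max(limb_b, 0.0)
        new = f"__nj{next_id}"
        next_id += 1
        nodes[new] = TreeNode(name=None)
        canon[new] = min(canon[a], canon[b])
        connect(a, new, limb_a)
        connect(b, new, limb_b)
        for c in active:
            if c in (a, b):
                continue
            d[(new, c)] = d[(c, new)] = max(
                (d[(a, c)] + d[(b, c)] - d[(a, b)]) / 2.0, 0.0
            )
        active = [c for c in active if c not in (a, b)] + [new]

    a, b = active
    connect(a, b, max(d[(a, b)], 0.0))

    return _midpoint_root(nodes, adjacency)


def _midpoint_root(nodes: dict, adjacency: dict) -> Tree:
    """Root an unrooted adjacency at the midpoint of its longest path."""

    def farthest(start):
        # the graph is a tree, so DFS with path tracking suffices
        best = (start, 0.0, [start])
        stack = [(start, None, 0.0, [start])]
        while stack:
            node, prev, dist, path = stack.pop()
            if dist > best[1] and not node.startswith("__nj"):
                best = (node, dist, path)
            for nbr, bl in adjacency[node]:
                if nbr != prev:
                    stack.append((nbr, node, dist + bl, path + [nbr]))
        return best

    leaves = sorted(n for n in adjacency if not n.startswith("__nj"))
    end1, _, _ = farthest(leaves[0])
    end2, diameter, path = farthest(end1)

    # locate midpoint along `path`
    edge_lengths = []
    for u, v in zip(path, path[1:]):
        bl = next(l for nbr, l in adjacency[u] if nbr == v)
        edge_lengths.append(bl)
    half = diameter / 2.0
    acc = 0.0
    for i, bl in enumerate(edge_lengths):
        if acc + bl >= half - 1e-15:
            u, v = path[i], path[i + 1]
            offset = half - acc  # distance from u along (u, v)
            break
        acc += bl
    else:  # zero-diameter tree: root at an internal node
        u = v = path[-1]
        offset = 0.0

    def build(node, parent) -> TreeNode:
        t = TreeNode(name=node if not node.startswith("__nj") else None)
        for nbr, bl in sorted(
            adjacency[node], key=lambda e: e[0]
        ):
            if nbr == parent:
                continue
            child = build(nbr, node)
            t.children.append((child, bl))
        return t

    root = TreeNode(name=None)
    if u == v:
        return Tree(root=build(u, None))
    edge_uv = next(l for nbr, l in adjacency[u] if nbr == v)
    left = build(u, v)
    right = build(v, u)
    root.children = [(left, offset), (right, max(edge_uv - offset, 0.0))]
    return Tree(root=root)


# ---------------------------------------------------------------------------
# Newick serialization
# ---------------------------------------------------------------------------


def _quote(label: str) -> str:
    # underscores must be quoted too: Newick readers turn bare "_" into " "
    if any(ch in label for ch in " _\t()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(t: Tree) -> str:
    """Serialize a tree to Newick with branch lengths (6 sig digits)."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            return _quote(node.name)
        parts = [
            f"{render(child)}:{bl:.6g}" for child, bl in node.children
        ]
        label = _quote(node.name) if node.name else ""
        return "(" + ",".join(parts) + ")" + label

    return render(t.root) + ";"
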