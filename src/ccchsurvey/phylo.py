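"""Neighbor-joining phylogeny with bootstrap support and clade grouping.

Distances are uncorrected p-distances with pairwise deletion: each pair is
compared only over the alignment columns where both rows are ungapped (a
Poisson-corrected variant is available behind a flag).  Trees are built
with the classical neighbor-joining algorithm; negative branch-length
estimates are clamped to zero with the deficit moved to the sibling edge,
and ties in the Q criterion break on the lexicographically smallest
taxon-pair representative so the construction is fully deterministic.

Bootstrap support on an internal edge is the percentage of
column-resampled replicate trees containing the same leaf bipartition;
per-replicate RNG streams derive from one master seed by counter, so runs
are reproducible and order-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

GAP = "-"


# ---------------------------------------------------------------------------
# alignment and distances


class Alignment:
    """Equal-length aligned residue rows keyed by taxon identifier."""

    def __init__(self, rows: dict[str, str]):
        if not rows:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"unequal row lengths: {sorted(lengths)}")
        self.ids: list[str] = list(rows)
        self.matrix = np.array(
            [list(rows[t]) for t in self.ids], dtype="U1"
        )

    @property
    def n_taxa(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        cols = rng.integers(0, self.n_columns, size=self.n_columns)
        aln = Alignment.__new__(Alignment)
        aln.ids = list(self.ids)
        aln.matrix = self.matrix[:, cols]
        return aln

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        from Bio import SeqIO

        return cls({r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")})


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal
    compared_sites: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        self.values = v


def p_distance(alignment: Alignment, correction: str | None = None) -> DistanceMatrix:
    """Pairwise-deletion p-distance matrix.

    distance = mismatches / sites where both rows are ungapped.  With
    ``correction="poisson"`` distances become -ln(1 - p).  Pairs with zero
    comparable sites are undefined and reported in one error.
    """
    if alignment.n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    m = alignment.matrix
    ungapped = m != GAP
    n = alignment.n_taxa
    values = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)
    undefined = []
    for i in range(n):
        for j in range(i + 1, n):
            both = ungapped[i] & ungapped[j]
            sites = int(both.sum())
            counts[i, j] = counts[j, i] = sites
            if sites == 0:
                undefined.append((alignment.ids[i], alignment.ids[j]))
                continue
            p = float((m[i][both] != m[j][both]).sum()) / sites
            if correction == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"saturated pair {alignment.ids[i]}/{alignment.ids[j]}"
                    )
                p = -math.log1p(-p)
            elif correction is not None:
                raise ValueError(f"unknown correction {correction!r}")
            values[i, j] = values[j, i] = p
    if undefined:
        raise ValueError(
            f"no comparable sites for pairs: {undefined}; tree cannot be built"
        )
    return DistanceMatrix(list(alignment.ids), values, counts)


# ---------------------------------------------------------------------------
# tree structure


@dataclass
class TreeNode:
    name: str | None = None  # taxon id for leaves
    children: list["TreeNode"] = field(default_factory=list)
    length: float = 0.0  # branch length to parent
    support: float | None = None  # bootstrap %, internal edges only

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())


class PhyloTree:
    """Rooted representation of an unrooted NJ tree.

    The root is the trifurcation left by the final agglomeration step;
    bootstrap supports live on internal (non-root, non-leaf) edges.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self.taxa = sorted(root.leaf_names())

    # -- traversal helpers

    def internal_nodes(self) -> list[TreeNode]:
        out = []

        def walk(node):
            if not node.is_leaf:
                if node is not self.root:
                    out.append(node)
                for ch in node.children:
                    walk(ch)

        walk(self.root)
        return out

    def bipartitions(self) -> dict[frozenset[str], TreeNode]:
        """Internal-edge bipartitions, keyed by the child-side leaf set."""
        return {n.leaf_names(): n for n in self.internal_nodes()}

    def canonical_splits(self) -> set[frozenset[str]]:
        """Unrooted splits, each keyed by the side NOT containing the first
        taxon (alphabetically) so representations are comparable."""
        anchor = self.taxa[0]
        full = frozenset(self.taxa)
        splits = set()
        for side in self.bipartitions():
            side = full - side if anchor in side else side
            if 1 < len(side) < len(self.taxa) - 1:
                splits.add(side)
        return splits

    # -- metric

    def path_lengths(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf path-length metric of the tree."""
        taxa = self.taxa
        index = {t: i for i, t in enumerate(taxa)}
        n = len(taxa)
        dist = np.zeros((n, n))

        def walk(node) -> dict[int, float]:
            if node.is_leaf:
                return {index[node.name]: 0.0}
            below: dict[int, float] = {}
            child_maps = []
            for ch in node.children:
                cm = {k: v + ch.length for k, v in walk(ch).items()}
                child_maps.append(cm)
            for a in range(len(child_maps)):
                for b in range(a + 1, len(child_maps)):
                    for i, di in child_maps[a].items():
                        for j, dj in child_maps[b].items():
                            dist[i, j] = dist[j, i] = di + dj
            for cm in child_maps:
                below.update(cm)
            return below

        walk(self.root)
        return taxa, dist

    # -- newick

    def to_newick(self) -> str:
        def fmt(node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(ch) for ch in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            return f"({inner}){label}:{node.length:.6g}"

        inner = ",".join(fmt(ch) for ch in self.root.children)
        return f"({inner});"


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Classical NJ with deterministic tie-breaking and length clamping.

    On an additive distance matrix the returned tree's path-length metric
    reproduces the input exactly (up to float error).
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.ids]
    reps: list[str] = list(dm.ids)  # lexicographic representative per cluster
    D = dm.values.astype(float).copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(D[i, j] for j in active if j != i) for i in active}
        best = None
        scale = max(1.0, float(np.max(np.abs(D[np.ix_(active, active)]))) * r)
        tol = 1e-9 * scale  # float-noise band: ties break lexicographically
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (r - 2) * D[i, j] - sums[i] - sums[j]
                key = tuple(sorted((reps[i], reps[j])))
                if (
                    best is None
                    or q < best[0] - tol
                    or (abs(q - best[0]) <= tol and key < best[1])
                ):
                    best = (q, key, i, j)
        _, _, i, j = best
        li = 0.5 * D[i, j] + (sums[i] - sums[j]) / (2.0 * (r - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        # distances from the new node
        new_row = {}
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        D = np.pad(D, ((0, 1), (0, 1)))
        m = len(nodes) - 1
        for k, v in new_row.items():
            D[m, k] = D[k, m] = v
        active = [k for k in active if k not in (i, j)] + [m]

    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    nodes[i].length = max(li, 0.0)
    nodes[j].length = max(lj, 0.0)
    nodes[k].length = max(lk, 0.0)
    order = sorted((i, j, k), key=lambda x: reps[x])
    root = TreeNode(children=[nodes[x] for x in order])
    return PhyloTree(root)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    # negative NJ estimates: clamp to 0, move the deficit to the sibling
    if li < 0:
        lj = max(lj + li, 0.0)
        li = 0.0
    elif lj < 0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


def build_tree(
    alignment: Alignment, correction: str | None = None
) -> PhyloTree:
    """p-distance + NJ in one call."""
    return neighbor_joining(p_distance(alignment, correction=correction))


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap(
    alignment: Alignment,
    n_reps: int = 1000,
    seed: int = 0,
    correction: str | None = None,
) -> PhyloTree:
    """NJ tree with bootstrap supports from column resampling.

    Support on an internal edge = 100 x fraction of replicate trees (full
    pipeline re-run on columns resampled with replacement) containing the
    same leaf bipartition.  ``n_reps=0`` returns the tree with supports
    undefined.
    """
    tree = build_tree(alignment, correction=correction)
    if n_reps == 0:
        return tree
    counts: dict[frozenset[str], int] = {}
    anchor = sorted(alignment.ids)[0]
    full = frozenset(alignment.ids)
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])  # counter-derived stream
        rep_aln = alignment.resample_columns(rng)
        rep_tree = build_tree(rep_aln, correction=correction)
        for split in rep_tree.canonical_splits():
            counts[split] = counts.get(split, 0) + 1
    for side, node in tree.bipartitions().items():
        canon = full - side if anchor in side else side
        if 1 < len(canon) < len(tree.taxa) - 1:
            node.support = 100.0 * counts.get(canon, 0) / n_reps
    return tree


# ---------------------------------------------------------------------------
# grouping and sister pairs


def assign_groups(
    tree: PhyloTree, threshold: float = 50.0, inclusive: bool = False
) -> dict[str, str | None]:
    """Family groups from supported clades.

    Groups are the maximal clades (preorder from the NJ root) whose
    subtending edge support passes the threshold (strict ``>`` by default,
    ``>=`` with ``inclusive``), with two refinements applied recursively:
    a supported clade whose immediate children are all themselves supported
    internal clades is decomposed into them (a deep well-supported split
    inside an arbitrary rooting must not swallow distinct subfamilies), and
    a supported clade strictly weaker than its strongest supported internal
    child defers to that nested structure (a borderline wrapper edge must
    not absorb a strongly supported subfamily).  If the taxa
    left ungrouped afterwards are exactly one side of a supported
    bipartition — the complement of a supported clade at the root — they
    form one further group, so both clades flanking a supported deepest
    split are recovered.  Remaining taxa map to None.
    """

    def passes(s: float | None) -> bool:
        if s is None:
            return False
        return s >= threshold if inclusive else s > threshold

    groups: list[frozenset[str]] = []

    def emit(node) -> None:
        # node subtends a supported edge; split if cleanly decomposable or
        # if a strictly stronger supported clade is nested directly below
        internal_supported = [
            ch for ch in node.children if not ch.is_leaf and passes(ch.support)
        ]
        cleanly = len(node.children) >= 2 and len(internal_supported) == len(
            node.children
        )
        outranked = internal_supported and node.support is not None and (
            node.support < max(ch.support for ch in internal_supported)
        )
        if cleanly or outranked:
            for ch in node.children:
                if ch.is_leaf:
                    continue
                if passes(ch.support):
                    emit(ch)
                else:
                    walk(ch)
        else:
            groups.append(node.leaf_names())

    def walk(node) -> None:
        for ch in node.children:
            if ch.is_leaf:
                continue
            if passes(ch.support):
                emit(ch)
            else:
                walk(ch)

    walk(tree.root)
    grouped = set().union(*groups) if groups else set()
    leftover = frozenset(tree.taxa) - grouped
    if leftover and leftover != frozenset(tree.taxa):
        full = frozenset(tree.taxa)
        for side, node in tree.bipartitions().items():
            if passes(node.support) and (side == leftover or full - side == leftover):
                groups.append(leftover)
                break
    groups.sort(key=lambda g: min(g))
    out: dict[str, str | None] = {t: None for t in tree.taxa}
    for gi, g in enumerate(groups, start=1):
        for t in g:
            out[t] = f"G{gi}"
    return out


def sister_pairs(tree: PhyloTree) -> list[tuple[str, str, float | None]]:
    """All cherries of the rooted representation: nodes with exactly two
    leaf children, with the subtending edge's support."""
    pairs = []

    def walk(node) -> None:
        if node.is_leaf:
            return
        if len(node.children) == 2 and all(ch.is_leaf for ch in node.children):
            a, b = sorted(ch.name for ch in node.children)
            pairs.append((a, b, node.support))
        for ch in node.children:
            walk(ch)

    walk(tree.root)
    pairs.sort()
    return pairs
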