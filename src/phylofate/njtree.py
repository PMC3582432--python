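"""Distance-based phylogenies per cluster: NJ, bootstrap, support filter.

Distances are p-distances or Jukes-Cantor corrected distances computed with
pairwise deletion of gap columns.  Trees are built by Saitou-Nei
neighbor-joining with the standard Q criterion, deterministic tie-breaking by
the smallest (i, j) index pair, and negative branch-length estimates clamped
to zero.  Bootstrap supports come from column resampling; trees containing
any internal node under the support cutoff (default 60%) are discarded.
Rooting places the root at the midpoint of the outgroup's branch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np

__all__ = [
    "Node",
    "DistanceError",
    "collapse_zero_branches",
    "distance_matrix",
    "nj_tree",
    "bootstrap_support",
    "filter_by_support",
    "root_at_outgroup",
    "parse_newick",
]


class DistanceError(ValueError):
    """Raised when a distance is undefined (e.g. p >= 0.75 under JC69)."""


@dataclass
class Node:
    """Tree node; an unrooted tree is held as a top node with 3+ children."""

    name: str | None = None
    species: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def copy(self) -> "Node":
        return Node(
            name=self.name,
            species=self.species,
            length=self.length,
            support=self.support,
            children=[c.copy() for c in self.children],
        )

    def postorder(self):
        for c in self.children:
            yield from c.postorder()
        yield self

    def to_newick(self, with_support: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = (
                f"{node.support:g}"
                if (with_support and node.support is not None)
                else ""
            )
            return f"({inner}){label}:{node.length:.6f}"

        inner = ",".join(fmt(c) for c in self.children)
        return f"({inner});"


def parse_newick(text: str, species_map: dict | None = None) -> Node:
    """Read a Newick string (internal labels interpreted as supports)."""
    from skbio import TreeNode as _SkbioTree

    tree = _SkbioTree.read(StringIO(text))

    def conv(n) -> Node:
        if n.is_tip():
            return Node(
                name=n.name,
                length=n.length or 0.0,
                species=(species_map or {}).get(n.name),
            )
        support = None
        if n.name:
            try:
                support = float(n.name)
            except ValueError:
                pass
        return Node(
            support=support,
            length=n.length or 0.0,
            children=[conv(c) for c in n.children],
        )

    return conv(tree)


# ---------------------------------------------------------------------------
# distances


def distance_matrix(alignment, model: str = "JC69"):
    """Pairwise distance matrix from a ClusterAlignment.

    p-distance is mismatches over pairwise-covered columns (gap columns
    excluded per pair); JC69 applies -(3/4) ln(1 - 4p/3) and raises
    :class:`DistanceError` when p >= 0.75 for any pair.
    Returns ``(ids, D)``.
    """
    rows = alignment.rows
    if len(rows) < 3:
        raise ValueError("need at least 3 sequences for a tree")
    arr = np.array([np.frombuffer(r.encode(), dtype=np.uint8) for r in rows])
    gap = ord("-")
    n = len(rows)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (arr[i] != gap) & (arr[j] != gap)
            covered = int(both.sum())
            if covered == 0:
                raise DistanceError(
                    f"no shared columns between rows {i} and {j}"
                )
            p = float((arr[i][both] != arr[j][both]).sum()) / covered
            if model == "p":
                d = p
            elif model == "JC69":
                if p >= 0.75:
                    raise DistanceError(
                        f"p-distance {p:.3f} >= 0.75: JC69 undefined "
                        f"for rows {i},{j}"
                    )
                d = -0.75 * np.log(1 - 4.0 * p / 3.0)
            else:
                raise ValueError(f"unknown model {model!r}")
            D[i, j] = D[j, i] = d
    return list(alignment.ids), D


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(D, labels, species=None) -> Node:
    """Saitou-Nei neighbor joining; returns an unrooted tree.

    The top node has three children (for n >= 3).  Ties in the Q criterion
    break on the smallest (i, j) pair; negative branch lengths are clamped
    to zero.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be square and symmetric")
    if n < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    if species is None:
        species = [None] * n
    nodes = [
        Node(name=labels[i], species=species[i]) for i in range(n)
    ]
    mat = D.copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = mat.sum(axis=1)
        Q = (m - 2) * mat - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        ties = [(int(a), int(b)) for a, b in ties if a < b]
        i, j = min(ties)
        li = 0.5 * mat[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = mat[i, j] - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = max(li, 0.0) + 0.0
        child_j.length = max(lj, 0.0) + 0.0
        new = Node(children=[child_i, child_j])
        dist_new = 0.5 * (mat[i, :] + mat[j, :] - mat[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        new_mat = np.zeros((len(keep) + 1, len(keep) + 1))
        new_mat[:-1, :-1] = mat[np.ix_(keep, keep)]
        new_mat[-1, :-1] = dist_new[keep]
        new_mat[:-1, -1] = dist_new[keep]
        nodes = [nodes[k] for k in keep] + [new]
        mat = new_mat
    # resolve the final three nodes with the three-point formulas
    a, b, c = nodes
    d_ab, d_ac, d_bc = mat[0, 1], mat[0, 2], mat[1, 2]
    a.length = max(0.5 * (d_ab + d_ac - d_bc), 0.0) + 0.0
    b.length = max(0.5 * (d_ab + d_bc - d_ac), 0.0) + 0.0
    c.length = max(0.5 * (d_ac + d_bc - d_ab), 0.0) + 0.0
    return Node(children=[a, b, c])


def collapse_zero_branches(tree: Node, eps: float = 1e-12) -> Node:
    """Contract internal branches of (numerically) zero length.

    Zero-length internal edges carry no signal, so a tree built from
    identical sequences reduces to a star with no internal branches.
    """
    out = tree.copy()

    def walk(node: Node) -> None:
        changed = True
        while changed:
            changed = False
            new_children = []
            for c in node.children:
                if not c.is_leaf and abs(c.length) <= eps:
                    new_children.extend(c.children)
                    changed = True
                else:
                    new_children.append(c)
            node.children = new_children
        for c in node.children:
            walk(c)

    walk(out)
    return out


def tree_distances(tree: Node) -> dict:
    """Patristic (path-length) distances between all leaf pairs."""
    dists: dict[tuple, float] = {}

    def walk(node: Node) -> dict:
        if node.is_leaf:
            return {node.name: 0.0}
        maps = []
        for c in node.children:
            sub = walk(c)
            maps.append({k: v + c.length for k, v in sub.items()})
        for x in range(len(maps)):
            for y in range(x + 1, len(maps)):
                for la, da in maps[x].items():
                    for lb, db in maps[y].items():
                        key = (la, lb) if la < lb else (lb, la)
                        dists[key] = da + db
        merged = {}
        for mp in maps:
            merged.update(mp)
        return merged

    walk(tree)
    return dists


def bipartitions(tree: Node) -> list:
    """Internal-edge bipartitions as (node, canonical leaf-name frozenset).

    The canonical side is the one not containing the lexicographically
    smallest leaf; trivial (leaf or full-set) splits are omitted.
    """
    all_leaves = frozenset(l.name for l in tree.leaves())
    ref = min(all_leaves)
    out = []
    seen = set()

    def walk(node: Node, is_top: bool):
        below = frozenset(l.name for l in node.leaves())
        if not is_top and not node.is_leaf:
            side = below if ref not in below else all_leaves - below
            if 1 < len(side) < len(all_leaves) - 1 and side not in seen:
                seen.add(side)
                out.append((node, side))
        for c in node.children:
            walk(c, False)

    walk(tree, True)
    return out


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_support(
    alignment, replicates: int = 1000, seed: int = 0, model: str = "JC69"
):
    """Column-resampling bootstrap supports mapped onto the NJ tree.

    Returns ``(tree, supports)`` where supports maps each internal-edge
    bipartition (canonical frozenset of leaf ids) to the percentage of
    replicates containing it.  Replicate p-distances >= 0.75 are clamped
    just below the JC69 singularity so every replicate yields a tree.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    ids, D = distance_matrix(alignment, model=model)
    tree = collapse_zero_branches(
        nj_tree(D, ids, species=list(alignment.species))
    )
    edges = bipartitions(tree)
    if not edges:
        return tree, {}
    rows = alignment.rows
    arr = np.array([np.frombuffer(r.encode(), dtype=np.uint8) for r in rows])
    gap = ord("-")
    n = len(rows)
    L = arr.shape[1]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    cov = np.array([(arr[i] != gap) & (arr[j] != gap) for i, j in pairs])
    dif = np.array(
        [((arr[i] != arr[j]) & cov[k]) for k, (i, j) in enumerate(pairs)]
    )
    rng = np.random.default_rng(seed)
    counts = {side: 0 for _, side in edges}
    for _ in range(replicates):
        idx = rng.integers(0, L, size=L)
        c = cov[:, idx].sum(axis=1).astype(float)
        d = dif[:, idx].sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(c > 0, d / np.maximum(c, 1), 0.75)
        if model == "JC69":
            p = np.minimum(p, 0.7499999)
            dist = -0.75 * np.log(1 - 4.0 * p / 3.0)
        else:
            dist = p
        D_rep = np.zeros((n, n))
        for k, (i, j) in enumerate(pairs):
            D_rep[i, j] = D_rep[j, i] = dist[k]
        rep_tree = nj_tree(D_rep, ids)
        rep_sides = {side for _, side in bipartitions(rep_tree)}
        for side in counts:
            if side in rep_sides:
                counts[side] += 1
    supports = {side: 100.0 * c / replicates for side, c in counts.items()}
    for node, side in edges:
        node.support = supports[side]
    return tree, supports


def filter_by_support(tree: Node, cutoff: float = 60.0) -> tuple[bool, float | None]:
    """Fail when any internal node support is under the cutoff.

    Returns ``(passed, min_support)``; a tree without internal supports
    (star topology) passes trivially.
    """
    sups = [
        n.support
        for n in tree.postorder()
        if not n.is_leaf and n.support is not None
    ]
    if not sups:
        return True, None
    return all(s >= cutoff for s in sups), min(sups)


# ---------------------------------------------------------------------------
# rooting


def root_at_outgroup(tree: Node, outgroup_species: str = "outgroup") -> Node:
    """Root on the outgroup's branch, at its midpoint.

    Requires exactly one leaf whose species (or name) equals
    ``outgroup_species``.
    """
    t = tree.copy()
    parent: dict[int, Node] = {}

    def index(n: Node):
        for c in n.children:
            parent[id(c)] = n
            index(c)

    index(t)
    out_leaves = [
        l
        for l in t.leaves()
        if l.species == outgroup_species or l.name == outgroup_species
    ]
    if len(out_leaves) != 1:
        raise ValueError(
            f"need exactly one outgroup leaf, found {len(out_leaves)}"
        )
    leaf = out_leaves[0]
    p = parent.get(id(leaf))
    if p is None:
        raise ValueError("outgroup leaf cannot be the tree top")
    p.children.remove(leaf)

    def hang_from(node: Node) -> Node:
        pa = parent.get(id(node))
        if pa is not None:
            pa.children.remove(node)
            hang_from(pa)
            edge_len, edge_sup = node.length, node.support
            pa.length = edge_len
            pa.support = edge_sup
            node.children.append(pa)
        return node

    sub = hang_from(p)
    half = leaf.length / 2.0
    leaf.length = half
    sub.length = half
    root = Node(children=[leaf, sub])
    _suppress_unary(root)
    return root


def _suppress_unary(node: Node) -> None:
    for c in list(node.children):
        _suppress_unary(c)
    new_children = []
    for c in node.children:
        if len(c.children) == 1:
            only = c.children[0]
            only.length += c.length
            new_children.append(only)
        else:
            new_children.append(c)
    node.children = new_children
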