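"""Species-topology canonicalization and category classification.

Each rooted cluster tree is reduced to a canonical species-labeled shape:
internal branches shorter than an equivalence cutoff (default 0.01
substitutions/site) are contracted to polytomies, leaves are relabeled
A (polyploid), B (S-genome parent), C (T-genome parent), the outgroup (used
for rooting only) is dropped, and subtrees are recursively sorted.  The
canonical string is looked up in a registry of named categories:

    ((A,B),(A,C)) -> AB_AC   both homeologs retained and expressed
    ((A,B),C)     -> AB_C    single copy grouping with the S parent
    ((A,C),B)     -> AC_B    single copy grouping with the T parent
    ((B,C),A)     -> BC_A    parents grouping together, excluding the polyploid

Polytomies are "unresolved"; any other shape is reported systematically as
``other:<canonical form>`` so an arbitrary partition of shapes can be
recovered from the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .njtree import Node

__all__ = [
    "TopologyCategory",
    "collapse_short_branches",
    "species_topology",
    "classify_topology",
    "tally_topologies",
    "SPECIES_LETTERS",
]

SPECIES_LETTERS = {
    "polyploid": "A",
    "parent_s": "B",
    "parent_t": "C",
    "outgroup": "O",
}

REGISTRY = {
    "((A,B),(A,C))": "AB_AC",
    "((A,B),C)": "AB_C",
    "((A,C),B)": "AC_B",
    "((B,C),A)": "BC_A",
}


@dataclass
class TopologyCategory:
    label: str
    canonical_form: str
    n_polyploid_leaves: int


def collapse_short_branches(tree: Node, length_cutoff: float = 0.01) -> Node:
    """Contract internal branches shorter than the cutoff into polytomies."""
    out = tree.copy()

    def walk(node: Node) -> None:
        changed = True
        while changed:
            changed = False
            new_children = []
            for c in node.children:
                if not c.is_leaf and c.length < length_cutoff:
                    new_children.extend(c.children)
                    changed = True
                else:
                    new_children.append(c)
            node.children = new_children
        for c in node.children:
            walk(c)

    walk(out)
    return out


def species_topology(tree: Node, letters: dict | None = None) -> str:
    """Canonical nested-parenthesis species string of a rooted tree.

    Leaves are replaced by species letters, the outgroup leaf and all branch
    lengths are dropped, and children are sorted lexically at every level, so
    the result is invariant under child rotation and leaf renaming.
    """
    letters = letters or SPECIES_LETTERS
    t = tree.copy()
    for leaf in t.leaves():
        if leaf.species is None:
            raise ValueError(f"leaf {leaf.name!r} has no species label")
    out_leaves = [l for l in t.leaves() if letters.get(l.species) == "O"]
    if len(out_leaves) != 1:
        raise ValueError("rooted tree must contain exactly one outgroup leaf")

    def drop(node: Node) -> None:
        node.children = [c for c in node.children if c is not out_leaves[0]]
        for c in node.children:
            drop(c)

    drop(t)
    while len(t.children) == 1:
        t = t.children[0]

    def prune_unary(node: Node) -> Node:
        node.children = [prune_unary(c) for c in node.children]
        if len(node.children) == 1:
            return node.children[0]
        return node

    t = prune_unary(t)

    def canon(node: Node) -> str:
        if node.is_leaf:
            return letters[node.species]
        return "(" + ",".join(sorted(canon(c) for c in node.children)) + ")"

    return canon(t)


def _has_polytomy(form: str) -> bool:
    depth = 0
    commas: dict[int, int] = {}
    stack: list[int] = []
    for ch in form:
        if ch == "(":
            depth += 1
            stack.append(0)
        elif ch == ")":
            if not stack:
                raise ValueError(f"malformed canonical form {form!r}")
            if stack.pop() >= 2:
                return True
            depth -= 1
        elif ch == ",":
            if not stack:
                raise ValueError(f"malformed canonical form {form!r}")
            stack[-1] += 1
    if stack:
        raise ValueError(f"malformed canonical form {form!r}")
    return False


def classify_topology(canonical_form: str) -> TopologyCategory:
    """Map a canonical species string onto the category registry."""
    if not canonical_form or any(
        ch not in "(),ABC" for ch in canonical_form
    ):
        raise ValueError(f"malformed canonical form {canonical_form!r}")
    n_poly = canonical_form.count("A")
    if canonical_form in REGISTRY:
        label = REGISTRY[canonical_form]
    elif "(" not in canonical_form:
        raise ValueError(f"malformed canonical form {canonical_form!r}")
    elif _has_polytomy(canonical_form):
        label = "unresolved"
    else:
        label = f"other:{canonical_form}"
    return TopologyCategory(
        label=label, canonical_form=canonical_form, n_polyploid_leaves=n_poly
    )


def tally_topologies(categories) -> pd.DataFrame:
    """Counts and proportions per category label (observed labels only)."""
    labels = [
        c.label if isinstance(c, TopologyCategory) else str(c)
        for c in categories
    ]
    if not labels:
        raise ValueError("no categories to tally")
    counts = pd.Series(labels).value_counts()
    table = pd.DataFrame(
        {
            "label": counts.index,
            "count": counts.values,
            "proportion": counts.values / counts.values.sum(),
        }
    )
    named = [l for l in ("AB_AC", "AB_C", "AC_B", "BC_A") if l in set(labels)]
    rest = sorted(set(labels) - set(named))
    order = {l: i for i, l in enumerate(named + rest)}
    return (
        table.sort_values("label", key=lambda s: s.map(order))
        .reset_index(drop=True)
    )
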