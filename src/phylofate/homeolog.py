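"""Subgenome-origin assignment for polyploid sequences in a classified tree.

Each polyploid leaf is assigned S or T origin from its nearest parental leaf
by patristic (path-length) distance on the support-filtered rooted tree; the
call is confirmed only when a pairwise alignment to that parent reaches the
identity/overlap cutoffs (defaults 90% over 60 bp).  Distance ties and
failed confirmations yield "unassigned" with a reason.
"""

from __future__ import annotations

from dataclasses import dataclass

from .cluster import pairwise_overlap
from .njtree import Node, tree_distances

__all__ = ["HomeologCall", "assign_origin"]

_ORIGIN = {"parent_s": "S", "parent_t": "T"}


@dataclass
class HomeologCall:
    sequence_id: str
    origin: str  # "S", "T", or "unassigned"
    sister_species: str | None
    identity: float
    overlap: int
    tree_distance: float
    reason: str = ""


def assign_origin(
    tree: Node,
    sequences: dict,
    min_identity: float = 90.0,
    min_overlap: int = 60,
) -> list[HomeologCall]:
    """Call S/T origin for every polyploid leaf of a rooted cluster tree.

    ``sequences`` maps leaf names to ungapped sequences (used for the
    confirmation alignment).  Raises when the tree has no parental leaves.
    """
    leaves = tree.leaves()
    poly = [l for l in leaves if l.species == "polyploid"]
    parents = [l for l in leaves if l.species in _ORIGIN]
    if not parents:
        raise ValueError("tree contains no parental leaves")
    dists = tree_distances(tree)
    calls = []
    for leaf in sorted(poly, key=lambda l: l.name):
        ranked = sorted(
            parents,
            key=lambda p: (
                dists[tuple(sorted((leaf.name, p.name)))],
                p.name,
            ),
        )
        best = ranked[0]
        best_d = dists[tuple(sorted((leaf.name, best.name)))]
        tie = any(
            abs(dists[tuple(sorted((leaf.name, p.name)))] - best_d) < 1e-12
            and p.species != best.species
            for p in ranked[1:]
        )
        if tie:
            calls.append(
                HomeologCall(
                    leaf.name, "unassigned", None, 0.0, 0, best_d, "tie"
                )
            )
            continue
        overlap, identity = pairwise_overlap(
            sequences[leaf.name], sequences[best.name], min_overlap=1
        )
        if overlap < min_overlap:
            calls.append(
                HomeologCall(
                    leaf.name, "unassigned", best.species, identity,
                    overlap, best_d, f"overlap {overlap} < {min_overlap}",
                )
            )
        elif identity < min_identity:
            calls.append(
                HomeologCall(
                    leaf.name, "unassigned", best.species, identity,
                    overlap, best_d, f"identity {identity:.1f} < {min_identity}",
                )
            )
        else:
            calls.append(
                HomeologCall(
                    leaf.name, _ORIGIN[best.species], best.species,
                    identity, overlap, best_d,
                )
            )
    return calls
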