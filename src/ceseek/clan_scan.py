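"""Detection of same-species paralog clans on unrooted gene trees.

A species' paralogs form a *clan* when the full set of that species' leaves
is exactly one side of some edge's bipartition — the unrooted analogue of
monophyly, which makes the test independent of where the gene tree happens
to be rooted.  The initial screen keeps a gene family when clans are found
in at least five distinct species; support values are ignored at that stage
and only enforced later by the concerted-evolution caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .tree_infer import SupportTree

__all__ = ["ParalogClanEvent", "find_species_clans", "initial_selection"]


@dataclass(frozen=True)
class ParalogClanEvent:
    """One species whose full paralog set is monophyletic in one gene tree."""

    family_id: str
    species_id: str
    leaves: frozenset[str]
    support: int | None  # percentage on the defining edge, if the tree has supports

    @property
    def n_paralogs(self) -> int:
        return len(self.leaves)


def _edge_sides(stree: SupportTree):
    """Yield (side, support_label_node) for every edge of the unrooted tree.

    ``side`` is the leaf set below the edge's child node; pendant edges are
    included (their side is a single leaf) because the complementary side of
    a pendant edge can itself be a species' full paralog set.
    """
    tree = stree.tree
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        yield side, node


def find_species_clans(stree: SupportTree,
                       family_id: str = "") -> list[ParalogClanEvent]:
    """Find every species whose complete leaf set forms a clan.

    Only the full set of a species' paralogs is tested: a species with three
    copies of which only two are sisters emits nothing.  The attached
    support is the defining edge's value when the tree carries supports; a
    clan defined by the complement of a pendant edge is trivially supported
    (100) since pendant bipartitions occur in every tree on the same leaves.
    """
    all_labels = frozenset(lf.taxon.label for lf in stree.tree.leaf_node_iter())
    if len(all_labels) < 4:
        raise ValueError("clan scan requires a tree with at least 4 leaves")
    by_species = stree.leaves_by_species()
    targets = {sp: leaves for sp, leaves in by_species.items()
               if len(leaves) >= 2 and leaves != all_labels}

    events: list[ParalogClanEvent] = []
    found: set[str] = set()
    for side, node in _edge_sides(stree):
        complement = all_labels - side
        for sp, leaves in targets.items():
            if sp in found:
                continue
            if side == leaves:
                support = _node_support(node)
                events.append(ParalogClanEvent(family_id, sp, frozenset(leaves), support))
                found.add(sp)
            elif complement == leaves:
                # defining edge seen from the far side; for a pendant edge the
                # bipartition is trivial and always present
                support = 100 if node.is_leaf() else _node_support(node)
                events.append(ParalogClanEvent(family_id, sp, frozenset(leaves), support))
                found.add(sp)
    events.sort(key=lambda e: e.species_id)
    return events


def _node_support(node) -> int | None:
    if node.is_leaf() or node.label is None:
        return None
    try:
        return int(round(float(node.label)))
    except ValueError:
        return None


def initial_selection(events_by_family: Mapping[str, Sequence[ParalogClanEvent]],
                      min_species: int = 5) -> list[str]:
    """Initial screen: keep families with clan events in >= min_species
    distinct species.  Support values are deliberately ignored here."""
    kept = [
        family_id
        for family_id, events in events_by_family.items()
        if len({e.species_id for e in events}) >= min_species
    ]
    return sorted(kept)
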