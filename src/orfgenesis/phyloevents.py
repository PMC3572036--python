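"""Placing ORF events on a species phylogeny.

Given per-species ORF reports, shared disruptions are matched by identity
(kind, reference position, indel length) and assigned to the stem branch of
the maximal clade all of whose informative tips carry the event — the
Dollo-style single-gain placement appropriate for events, like identical
frameshifting indels, that are vanishingly unlikely to recur.  Carrier sets
that are not monophyletic are flagged ambiguous and decomposed into maximal
carrier clades.  Ancestral state sets for arbitrary discrete characters are
available through two-pass Fitch parsimony, and per-clade lower bounds on
ancestral sequence content come from the maximum of tip alignable fractions.

Trees are rooted newick (dendropy underneath); named clades (Boreoeutheria,
Hominidae, ...) are supplied as a mapping from clade name to tip list, since
genome-browser trees carry no internal labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from .orftrace import OrfDisruption, SpeciesOrfReport


class PhyloTree:
    """A rooted species tree with optional named clades.

    Parameters
    ----------
    newick : str
        Rooted newick text; tip labels must match species names in reports.
    clades : dict, optional
        Mapping clade name -> list of tip names (the MRCA of those tips is
        the clade's root node).
    """

    def __init__(self, newick: str, clades: dict[str, list[str]] | None = None):
        self.tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        self.tree.is_rooted = True
        self._label_nodes()
        self.clades = dict(clades or {})

    def _label_nodes(self) -> None:
        k = 0
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                node.node_id = node.taxon.label
            elif node.label:
                node.node_id = node.label
            else:
                node.node_id = f"node{k}"
                k += 1

    @property
    def tips(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def node(self, node_id: str):
        for n in self.tree.preorder_node_iter():
            if n.node_id == node_id:
                return n
        raise KeyError(f"no node {node_id!r} in tree")

    def clade_node(self, name: str):
        """MRCA node of a named clade."""
        if name in self.clades:
            return self.mrca(self.clades[name])
        return self.node(name)

    def mrca(self, tip_names: list[str]):
        if len(tip_names) == 1:
            return self.node(tip_names[0])
        node = self.tree.mrca(taxon_labels=list(tip_names))
        if node is None:
            raise ValueError(f"no MRCA for {tip_names}")
        return node

    def tips_below(self, node) -> set[str]:
        return {leaf.taxon.label for leaf in node.leaf_iter()}


@dataclass
class EventPlacement:
    event: OrfDisruption
    branch: str  # child-node id of the branch the event maps to
    supporting_tips: set[str] = field(default_factory=set)
    ambiguous: bool = False


def fitch_ancestral(
    tree: PhyloTree, tip_states: dict[str, str]
) -> tuple[dict[str, frozenset], int]:
    """Two-pass Fitch parsimony for one discrete character.

    Returns (node_id -> state set, minimum number of changes).  On binary
    trees the returned sets are the states each node takes in at least one
    most-parsimonious reconstruction; ties surface as multi-state sets.
    """
    missing = [t for t in tree.tips if t not in tip_states]
    if missing:
        raise ValueError(f"missing tip state for {missing[0]!r}")

    up: dict = {}
    was_union: dict = {}
    changes = 0
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            up[node] = frozenset([tip_states[node.taxon.label]])
            was_union[node] = False
        else:
            sets = [up[c] for c in node.child_nodes()]
            inter = frozenset.intersection(*sets)
            if inter:
                up[node] = inter
                was_union[node] = False
            else:
                # Multifurcations: keep states present in the most children
                # (reduces to plain union for binary nodes).
                counts: dict[str, int] = {}
                for s in sets:
                    for st in s:
                        counts[st] = counts.get(st, 0) + 1
                best = max(counts.values())
                up[node] = frozenset(st for st, c in counts.items() if c == best)
                was_union[node] = True
                changes += len(sets) - best

    final: dict = {}
    root = tree.tree.seed_node
    final[root] = up[root]
    for node in tree.tree.preorder_node_iter():
        if node is root:
            continue
        parent_final = final[node.parent_node]
        if parent_final <= up[node]:
            final[node] = parent_final
        elif was_union[node]:
            final[node] = up[node] | parent_final
        else:
            child_union = frozenset.union(
                *[up[c] for c in node.child_nodes()]
            ) if not node.is_leaf() else up[node]
            final[node] = up[node] | (parent_final & child_union)

    return {n.node_id: s for n, s in final.items()}, changes


def clade_lower_bound(
    tree: PhyloTree, node_id: str, tip_fractions: dict[str, float]
) -> float:
    """Lower bound on an ancestor's alignable CDS content.

    The ancestor of a clade carried at least as much of the reference
    sequence as its best-preserved descendant, so the bound is the maximum
    tip fraction within the clade.
    """
    node = tree.clade_node(node_id)
    vals = [
        tip_fractions[t] for t in tree.tips_below(node) if t in tip_fractions
    ]
    if not vals:
        raise ValueError(f"no annotated tips below {node_id!r}")
    return max(vals)


def _maximal_carrier_clades(tree: PhyloTree, carriers: set[str],
                            informative: set[str]) -> list:
    """Maximal nodes whose informative tips all carry the event."""
    out = []

    def visit(node) -> None:
        below = tree.tips_below(node) & informative
        if below and below <= carriers:
            out.append(node)
        else:
            for c in node.child_nodes():
                visit(c)

    visit(tree.tree.seed_node)
    return out


def place_events(
    tree: PhyloTree,
    reports: list[SpeciesOrfReport],
    *,
    min_alignable: float = 0.10,
) -> list[EventPlacement]:
    """Assign shared ORF disruptions to tree branches (Dollo single gain).

    Tips with alignable fraction below ``min_alignable`` are uninformative
    (their ORF calls rest on too little sequence) and are excluded from event
    matching.  An event whose informative carriers form a clade maps to that
    clade's stem branch; a private event maps to the tip's terminal branch;
    non-monophyletic carrier sets yield one flagged placement per maximal
    carrier clade.
    """
    informative = {
        r.species for r in reports
        if r.alignable_fraction >= min_alignable and not r.absent
    }
    by_event: dict[tuple, set[str]] = {}
    for rep in reports:
        if rep.species not in informative:
            continue
        for d in rep.disruptions:
            by_event.setdefault(d.key(), set()).add(rep.species)

    event_of: dict[tuple, OrfDisruption] = {}
    for rep in reports:
        for d in rep.disruptions:
            event_of.setdefault(d.key(), d)

    placements: list[EventPlacement] = []
    for key, carriers in sorted(by_event.items(), key=lambda kv: (kv[0][1], kv[0][0])):
        event = event_of[key]
        nodes = _maximal_carrier_clades(tree, carriers, informative)
        if len(nodes) == 1 and (tree.tips_below(nodes[0]) & informative) == carriers:
            placements.append(EventPlacement(
                event=event, branch=nodes[0].node_id,
                supporting_tips=set(carriers), ambiguous=False,
            ))
        else:
            for node in nodes:
                placements.append(EventPlacement(
                    event=event, branch=node.node_id,
                    supporting_tips=tree.tips_below(node) & carriers,
                    ambiguous=True,
                ))
    return placements
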