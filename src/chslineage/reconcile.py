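"""Gene-tree/species-tree reconciliation and ancestral lineage inference.

The model: each gene-tree node v is mapped to the species-tree node M(v)
that is the most recent common ancestor of the species carried by the genes
below v (LCA mapping). An internal node is a *duplication* when its mapping
equals the mapping of at least one child — the descendant copies coexisted
in the same ancestral genome — and a *speciation* otherwise.

Ancestral gene lineages at the species root are read off the set

    D = { internal v : event(v) = duplication and M(v) = species root }.

D is a connected crown at the gene-tree root (if v is in D, every ancestor
of v maps to the root and is itself a duplication). Lineage roots are the
gene root if it is not in D, plus every node outside D whose parent is in D;
each lineage root's subtree is one ancestral lineage, so the leaves
partition exactly. Per-lineage losses are inferred under Dollo parsimony
with presence forced at the species root (single origin): a species-tree
node is present iff it is the root or lies on a root-to-leaf path of a
species that retains the lineage, and each edge from a present node to an
absent child is one loss. That count is the minimum number of losses
compatible with root presence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

from .trees import TreeError, assert_binary

__all__ = [
    "ReconciliationResult",
    "AncestralLineage",
    "RetentionSummary",
    "SpeciesIndex",
    "lca_map",
    "label_events",
    "reconcile",
    "decompose_lineages",
    "dollo_losses",
    "retention_summary",
    "split_at_duplication",
    "node_signature",
]

SPECIATION = "speciation"
DUPLICATION = "duplication"


def node_signature(node: dendropy.Node) -> str:
    """Stable human-readable identifier for a tree node: its label if any,
    else the sorted leaf labels below it joined by '|'."""
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    if node.label:
        return node.label
    return "|".join(sorted(l.taxon.label for l in node.leaf_iter()))


class SpeciesIndex:
    """Constant-factor helpers on a rooted species tree: leaf lookup, depth,
    parent, and pairwise LCA by depth-walking."""

    def __init__(self, species_tree: dendropy.Tree):
        self.tree = species_tree
        self.root = species_tree.seed_node
        self.parent: dict[dendropy.Node, dendropy.Node | None] = {}
        self.depth: dict[dendropy.Node, int] = {}
        self.leaf_by_species: dict[str, dendropy.Node] = {}
        for node in species_tree.preorder_node_iter():
            p = node.parent_node
            self.parent[node] = p
            self.depth[node] = 0 if p is None else self.depth[p] + 1
            if node.is_leaf():
                self.leaf_by_species[node.taxon.label] = node

    def species_node(self, species: str) -> dendropy.Node:
        try:
            return self.leaf_by_species[species]
        except KeyError:
            raise TreeError(f"species {species!r} not in the species tree") from None

    def lca(self, a: dendropy.Node, b: dendropy.Node) -> dendropy.Node:
        while self.depth[a] > self.depth[b]:
            a = self.parent[a]
        while self.depth[b] > self.depth[a]:
            b = self.parent[b]
        while a is not b:
            a = self.parent[a]
            b = self.parent[b]
        return a

    def mrca_of_species(self, species: Iterable[str]) -> dendropy.Node:
        nodes = [self.species_node(s) for s in set(species)]
        if not nodes:
            raise TreeError("empty species set has no MRCA")
        acc = nodes[0]
        for n in nodes[1:]:
            acc = self.lca(acc, n)
        return acc


@dataclass
class ReconciliationResult:
    """LCA mapping M and per-internal-node event labels for one gene tree."""

    gene_tree: dendropy.Tree
    species_tree: dendropy.Tree
    species_index: SpeciesIndex
    mapping: dict[dendropy.Node, dendropy.Node]
    events: dict[dendropy.Node, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for node in self.gene_tree.preorder_node_iter():
            rows.append(
                {
                    "node": node_signature(node),
                    "is_leaf": node.is_leaf(),
                    "mapping": node_signature(self.mapping[node]),
                    "event": self.events.get(node, "leaf" if node.is_leaf() else ""),
                }
            )
        return pd.DataFrame(rows)


@dataclass
class AncestralLineage:
    """One maximal gene-tree clade traced to the species-tree root."""

    lineage_id: str
    root_node: dendropy.Node
    members: frozenset[str]
    species_counts: Counter
    losses: frozenset[dendropy.Node]  # child ends of lost species-tree edges
    n_losses_unconstrained: int

    @property
    def n_copies(self) -> int:
        return len(self.members)

    @property
    def n_species(self) -> int:
        return sum(1 for c in self.species_counts.values() if c > 0)

    @property
    def n_losses(self) -> int:
        return len(self.losses)


@dataclass
class RetentionSummary:
    """Species x lineage copy-count matrix plus retention tallies."""

    matrix: pd.DataFrame  # index: species, columns: lineage ids
    lineages_per_species: pd.Series
    n_multi: int  # species retaining >= 2 lineages
    n_single: int  # species retaining exactly 1


def lca_map(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    species_of: Mapping[str, str],
    *,
    index: SpeciesIndex | None = None,
) -> ReconciliationResult:
    """Compute the LCA mapping bottom-up.

    Every gene leaf must appear in ``species_of`` and map to a species-tree
    leaf; both trees must be rooted and binary.
    """
    assert_binary(gene_tree, "gene tree")
    assert_binary(species_tree, "species tree")
    idx = index or SpeciesIndex(species_tree)
    mapping: dict[dendropy.Node, dendropy.Node] = {}
    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in species_of:
                raise TreeError(f"gene leaf {label!r} has no species mapping")
            mapping[node] = idx.species_node(species_of[label])
        else:
            kids = node.child_nodes()
            acc = mapping[kids[0]]
            for child in kids[1:]:
                acc = idx.lca(acc, mapping[child])
            mapping[node] = acc
    return ReconciliationResult(gene_tree, species_tree, idx, mapping)


def label_events(result: ReconciliationResult) -> ReconciliationResult:
    """Label each internal node duplication/speciation from the mapping.

    Duplication iff M(v) equals M(c) for at least one child c.
    """
    for node in result.gene_tree.preorder_internal_node_iter():
        m = result.mapping[node]
        dup = any(result.mapping[c] is m for c in node.child_nodes())
        result.events[node] = DUPLICATION if dup else SPECIATION
    return result


def reconcile(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    species_of: Mapping[str, str],
) -> ReconciliationResult:
    """LCA mapping plus event labels in one call."""
    return label_events(lca_map(gene_tree, species_tree, species_of))


def dollo_losses(
    species_present: Iterable[str],
    species_tree: dendropy.Tree,
    *,
    index: SpeciesIndex | None = None,
    force_root: bool = True,
) -> set[dendropy.Node]:
    """Minimal loss set under Dollo parsimony (single origin).

    With ``force_root`` the gene is assumed present at the species root; the
    present set is then the union of the root paths of retaining species,
    and each edge from a present node to an absent child is one loss. With
    ``force_root=False`` the origin is placed at the MRCA of the retaining
    species instead (the unconstrained minimum).

    Returns the set of species-tree nodes that are the child ends of lost
    edges.
    """
    present_species = set(species_present)
    if not present_species:
        raise TreeError("lineage with empty species set")
    idx = index or SpeciesIndex(species_tree)
    present: set[dendropy.Node] = set()
    for sp in present_species:
        node = idx.species_node(sp)  # raises if absent from the tree
        while node is not None and node not in present:
            present.add(node)
            node = idx.parent[node]
    origin = idx.root if force_root else idx.mrca_of_species(present_species)
    losses: set[dendropy.Node] = set()
    stack = [origin]
    while stack:
        node = stack.pop()
        for child in node.child_nodes():
            if child in present:
                stack.append(child)
            else:
                losses.add(child)
    return losses


def decompose_lineages(
    result: ReconciliationResult,
) -> list[AncestralLineage]:
    """Cut the gene tree into ancestral lineages at root-mapped duplications.

    Lineage ids are assigned by pre-order of the lineage roots
    (``lineage_1``, ``lineage_2``, ...). Losses are attached per lineage
    under root-forced Dollo parsimony; the unconstrained minimum is kept
    alongside for comparison.
    """
    if not result.events and any(
        not n.is_leaf() for n in result.gene_tree.preorder_node_iter()
    ):
        raise TreeError("events not labelled; run label_events/reconcile first")
    idx = result.species_index
    root = result.gene_tree.seed_node
    in_crown = (
        lambda v: not v.is_leaf()
        and result.events.get(v) == DUPLICATION
        and result.mapping[v] is idx.root
    )
    lineage_roots: list[dendropy.Node] = []
    stack = [root]
    while stack:  # pre-order over the crown only
        node = stack.pop()
        if in_crown(node):
            stack.extend(reversed(node.child_nodes()))
        else:
            lineage_roots.append(node)
    lineages: list[AncestralLineage] = []
    species_of = {
        leaf.taxon.label: result.mapping[leaf].taxon.label
        for leaf in result.gene_tree.leaf_node_iter()
    }
    for i, lroot in enumerate(lineage_roots, start=1):
        members = frozenset(l.taxon.label for l in lroot.leaf_iter())
        counts = Counter(species_of[m] for m in members)
        losses = dollo_losses(counts, result.species_tree, index=idx, force_root=True)
        free = dollo_losses(counts, result.species_tree, index=idx, force_root=False)
        lineages.append(
            AncestralLineage(
                lineage_id=f"lineage_{i}",
                root_node=lroot,
                members=members,
                species_counts=counts,
                losses=frozenset(losses),
                n_losses_unconstrained=len(free),
            )
        )
    return lineages


def retention_summary(
    lineages: Sequence[AncestralLineage],
    species: Sequence[str],
) -> RetentionSummary:
    """Species-by-lineage copy counts and multi/single retention tallies."""
    matrix = pd.DataFrame(
        0, index=list(species), columns=[l.lineage_id for l in lineages], dtype=int
    )
    for lin in lineages:
        for sp, n in lin.species_counts.items():
            matrix.loc[sp, lin.lineage_id] = n
    per_species = (matrix > 0).sum(axis=1)
    return RetentionSummary(
        matrix=matrix,
        lineages_per_species=per_species,
        n_multi=int((per_species >= 2).sum()),
        n_single=int((per_species == 1).sum()),
    )


def split_at_duplication(
    lineage: AncestralLineage,
    result: ReconciliationResult,
    species_node: dendropy.Node,
) -> tuple[Counter, Counter]:
    """Split a lineage's members at the duplication node mapping to a given
    species-tree ancestor and return the two sub-clades' species counts.

    Used for paralog sub-clade bookkeeping, e.g. the two Fabales paralog
    clades delimited by the duplication in the Fabales ancestor. The highest
    such duplication within the lineage (closest to the lineage root, ties
    broken by pre-order) is the split point.
    """
    target = None
    stack = [lineage.root_node]
    while stack:
        node = stack.pop()
        if node.is_leaf():
            continue
        if (
            result.events.get(node) == DUPLICATION
            and result.mapping[node] is species_node
        ):
            target = node
            break
        stack.extend(reversed(node.child_nodes()))
    if target is None:
        raise TreeError(
            f"no duplication mapping to {node_signature(species_node)!r} "
            f"inside {lineage.lineage_id}"
        )
    left, right = target.child_nodes()
    species_of = {
        leaf.taxon.label: result.mapping[leaf].taxon.label
        for leaf in result.gene_tree.leaf_node_iter()
    }
    def counts(sub):
        return Counter(species_of[l.taxon.label] for l in sub.leaf_iter())
    return counts(left), counts(right)
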