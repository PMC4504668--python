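"""Tree input/output, rooting, and gene-to-species label mapping.

All trees are :class:`dendropy.Tree` objects parsed with leaf labels kept as
plain node labels (no shared taxon namespace magic), so the same label may
appear in different trees without conflict. Gene trees and species trees are
rooted; the reconciliation stage additionally requires them to be binary.
"""

from __future__ import annotations

import io
from typing import Iterable, Mapping

import dendropy

__all__ = [
    "parse_newick",
    "write_newick",
    "load_tree",
    "leaf_labels",
    "is_binary",
    "assert_binary",
    "resolve_polytomies",
    "root_with_outgroup",
    "species_of_leaf",
    "build_species_map",
    "read_species_map",
    "write_species_map",
]


class TreeError(ValueError):
    """Raised for malformed or inconsistent tree input."""


def parse_newick(text: str, *, rooted: bool = True) -> dendropy.Tree:
    """Parse a newick string into a rooted dendropy tree.

    Duplicate leaf labels and unbalanced parentheses raise :class:`TreeError`
    with the parser's position information preserved.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted" if rooted else "default-unrooted",
            preserve_underscores=True,
        )
    except (dendropy.utility.error.DataParseError, ValueError) as exc:
        raise TreeError(f"newick parse error: {exc}") from exc
    labels = leaf_labels(tree)
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise TreeError(f"duplicate leaf labels: {dupes}")
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to newick, preserving branch lengths if present."""
    out = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return out.strip() + "\n"


def load_tree(path: str, *, rooted: bool = True) -> dendropy.Tree:
    with open(path) as fh:
        return parse_newick(fh.read(), rooted=rooted)


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


def is_binary(tree: dendropy.Tree) -> bool:
    for node in tree.preorder_node_iter():
        n = len(node.child_nodes())
        if n not in (0, 2):
            return False
    return True


def assert_binary(tree: dendropy.Tree, what: str = "tree") -> None:
    if not is_binary(tree):
        bad = [
            (node.taxon.label if node.taxon else "<internal>")
            for node in tree.preorder_node_iter()
            if len(node.child_nodes()) not in (0, 2)
        ]
        raise TreeError(
            f"{what} is not strictly binary ({len(bad)} polytomy/unary node(s)); "
            "resolve polytomies first or pass resolve=True where supported"
        )


def resolve_polytomies(tree: dendropy.Tree) -> dendropy.Tree:
    """Deterministically resolve polytomies by ladderizing sorted leaf labels.

    Children of each polytomy are ordered by their smallest descendant leaf
    label and folded into a caterpillar, so the output is a pure function of
    the input topology.
    """
    for node in list(tree.preorder_internal_node_iter()):
        kids = node.child_nodes()
        if len(kids) <= 2:
            continue
        def key(child):
            return min(l.taxon.label for l in child.leaf_iter())
        ordered = sorted(kids, key=key)
        for child in kids:
            node.remove_child(child)
        # fold into a caterpillar: ((a,b),c),d ...
        current = ordered[0]
        for nxt in ordered[1:-1]:
            join = dendropy.Node()
            join.add_child(current)
            join.add_child(nxt)
            current = join
        node.add_child(current)
        node.add_child(ordered[-1])
    return tree


def root_with_outgroup(
    tree: dendropy.Tree, outgroup_labels: Iterable[str]
) -> dendropy.Tree:
    """Root the ingroup on the edge separating it from the outgroup, then
    drop the outgroup leaves and suppress the resulting unary nodes.

    The outgroup must be a single leaf or form a clade in the unrooted
    topology; otherwise a :class:`TreeError` lists the conflicting leaves.
    """
    outgroup = set(outgroup_labels)
    all_leaves = set(leaf_labels(tree))
    missing = outgroup - all_leaves
    if missing:
        raise TreeError(f"outgroup leaves not in tree: {sorted(missing)}")
    if outgroup == all_leaves:
        raise TreeError("outgroup contains every leaf; no ingroup remains")
    if not outgroup:
        raise TreeError("empty outgroup")

    tree = tree.clone(depth=1)
    # Find a node whose below-leafset equals the outgroup (clade in current
    # rooting) or whose complement equals it (outgroup wraps the root).
    target = None
    for node in tree.postorder_node_iter():
        below = {l.taxon.label for l in node.leaf_iter()}
        if below == outgroup or (all_leaves - below) == outgroup:
            target = node
            below_is_outgroup = below == outgroup
            break
    if target is None:
        # diagnose: leaves that break monophyly = ingroup leaves inside the
        # minimal clade spanning the outgroup
        mrca = tree.mrca(taxon_labels=sorted(outgroup))
        inside = {l.taxon.label for l in mrca.leaf_iter()}
        conflict = sorted(inside - outgroup)
        raise TreeError(
            f"outgroup {sorted(outgroup)} is not monophyletic in the unrooted "
            f"tree; conflicting ingroup leaves: {conflict}"
        )
    if below_is_outgroup and target.parent_node is not None:
        tree.reroot_at_edge(target.edge, update_bipartitions=False)
    # else: the ingroup already forms a clade under the current root.
    tree.prune_taxa_with_labels(sorted(outgroup), suppress_unifurcations=True)
    # pruning can leave a unary root; suppress it
    while len(tree.seed_node.child_nodes()) == 1:
        only = tree.seed_node.child_nodes()[0]
        tree.seed_node = only
        only.parent_node = None
    tree.seed_node.edge.length = None
    return tree


def species_of_leaf(
    label: str,
    *,
    table: Mapping[str, str] | None = None,
    delimiter: str = "_",
    field: int = 0,
) -> str:
    """Map one gene leaf label to its species.

    An explicit lookup ``table`` wins over the delimiter convention; with the
    default rule ``"Gmax_chr9_T1" -> "Gmax"``.
    """
    if table is not None and label in table:
        return table[label]
    parts = label.split(delimiter)
    if table is not None and not parts:
        raise TreeError(f"leaf {label!r} not present in the species map")
    if len(parts) <= field or not parts[field]:
        raise TreeError(
            f"cannot extract species from leaf label {label!r} "
            f"(delimiter {delimiter!r}, field {field})"
        )
    return parts[field]


def build_species_map(
    labels: Iterable[str],
    *,
    table: Mapping[str, str] | None = None,
    delimiter: str = "_",
    field: int = 0,
    valid_species: Iterable[str] | None = None,
) -> dict[str, str]:
    """Resolve every gene leaf label to a species, validating against the
    species tree's leaf set when given."""
    valid = set(valid_species) if valid_species is not None else None
    out: dict[str, str] = {}
    for label in labels:
        sp = species_of_leaf(label, table=table, delimiter=delimiter, field=field)
        if valid is not None and sp not in valid:
            raise TreeError(
                f"leaf {label!r} maps to species {sp!r} absent from the species tree"
            )
        out[label] = sp
    return out


def read_species_map(path: str) -> dict[str, str]:
    """Read a two-column TSV (leaf_label, species)."""
    table: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            leaf, sp = line.split("\t")[:2]
            table[leaf] = sp
    return table


def write_species_map(table: Mapping[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for leaf in sorted(table):
            fh.write(f"{leaf}\t{table[leaf]}\n")
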