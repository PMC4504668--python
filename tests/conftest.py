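"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's own algorithms: the LCA oracle
picks the smallest species-tree clade containing a gene node's species set
by scanning every species-tree node, and the Dollo oracle enumerates every
presence/absence labelling of the species-tree internal nodes. They are
only usable on small trees, which is the point.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import pytest
from hypothesis import HealthCheck, settings

from chslineage.fixtures import canonical_fixture
from chslineage.trees import parse_newick

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


SPECIES4 = ("A", "B", "C", "D")
SPECIES4_NEWICK = "((A:1,B:1):1,(C:1,D:1):1);"


@pytest.fixture(scope="session")
def fixture_bundle():
    return canonical_fixture()


@pytest.fixture()
def species4_tree():
    return parse_newick(SPECIES4_NEWICK)


# ---------------------------------------------------------------- oracles


def leafset(node):
    return frozenset(l.taxon.label for l in node.leaf_iter())


def oracle_lca_map(gene_tree, species_tree, species_of):
    """Brute-force mapping: smallest species-tree clade covering the gene
    node's species set (scan of every species-tree node)."""
    clades = [(node, leafset(node)) for node in species_tree.preorder_node_iter()]
    mapping = {}
    for gnode in gene_tree.preorder_node_iter():
        species = {species_of[l.taxon.label] for l in gnode.leaf_iter()}
        best = None
        for snode, cl in clades:
            if species <= cl and (best is None or len(cl) < len(best[1])):
                best = (snode, cl)
        mapping[gnode] = best[0]
    return mapping


def oracle_events(gene_tree, oracle_mapping):
    """Event labels recomputed from the brute-force mapping."""
    events = {}
    for node in gene_tree.preorder_internal_node_iter():
        events[node] = (
            "duplication"
            if any(oracle_mapping[c] is oracle_mapping[node] for c in node.child_nodes())
            else "speciation"
        )
    return events


def oracle_dollo_count(present_species, species_tree, force_root=True):
    """Minimum loss count by exhaustive search over presence labellings.

    Leaves are fixed (present iff the species retains the gene), the root is
    forced present when ``force_root``; internal nodes range over all 0/1
    assignments subject to no-regain (present child => present parent).
    Losses are edges from a present parent to an absent child.
    """
    present_species = set(present_species)
    nodes = list(species_tree.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    best = None
    for bits in itertools.product((0, 1), repeat=len(internal)):
        state = dict(zip(internal, bits))
        for n in nodes:
            if n.is_leaf():
                state[n] = 1 if n.taxon.label in present_species else 0
        root = species_tree.seed_node
        if force_root and not state[root]:
            continue
        if not force_root:
            # single origin still required: exactly one maximal present node
            tops = [
                n
                for n in nodes
                if state[n] and (n.parent_node is None or not state[n.parent_node])
            ]
            if len(tops) != 1:
                continue
        ok = all(
            state[n.parent_node] >= state[n]
            for n in nodes
            if n.parent_node is not None
        )
        if not ok:
            continue
        if not all(
            state[n] for n in nodes if n.is_leaf() and n.taxon.label in present_species
        ):
            continue
        losses = sum(
            1
            for n in nodes
            if n.parent_node is not None and state[n.parent_node] and not state[n]
        )
        if best is None or losses < best:
            best = losses
    return best


# ------------------------------------------------- gene-tree enumeration


@lru_cache(maxsize=None)
def species_labelled_shapes(n: int) -> tuple[str, ...]:
    """All rooted binary shapes on n leaves labelled from SPECIES4, as
    canonical newick fragments (unordered children deduplicated)."""
    if n == 1:
        return SPECIES4
    out = set()
    for i in range(1, n // 2 + 1):
        for left in species_labelled_shapes(i):
            for right in species_labelled_shapes(n - i):
                if i == n - i and left > right:
                    continue
                out.add(f"({left},{right})")
    return tuple(sorted(out))


def shape_to_gene_tree(shape: str):
    """Instantiate a shape as a gene tree with unique leaf labels; returns
    (tree, species_of)."""
    counter = itertools.count(1)
    species_of = {}
    parts = []
    for ch in shape:
        if ch in SPECIES4:
            label = f"{ch}.{next(counter)}"
            species_of[label] = ch
            parts.append(label)
        else:
            parts.append(ch)
    return parse_newick("".join(parts) + ";"), species_of


def random_gene_tree(rng, n_leaves, species=SPECIES4):
    """Random rooted binary gene tree by sequential random joins."""
    labels = [f"{rng.choice(species)}.{i}" for i in range(1, n_leaves + 1)]
    species_of = {l: l.split(".")[0] for l in labels}
    frags = list(labels)
    while len(frags) > 1:
        i, j = sorted(rng.choice(len(frags), size=2, replace=False))
        b = frags.pop(j)
        a = frags.pop(i)
        frags.append(f"({a},{b})")
    return parse_newick(frags[0] + ";"), species_of


def canon(tree) -> str:
    """Canonical topology string (children sorted by smallest leaf)."""

    def go(node):
        if node.is_leaf():
            return node.taxon.label
        return "(" + ",".join(sorted(go(c) for c in node.child_nodes())) + ")"

    return go(tree.seed_node)
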