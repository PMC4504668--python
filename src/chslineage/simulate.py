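"""Birth-death gene-family simulation along a dated species tree.

Each of k root gene copies evolves independently down the species tree. On
a branch of length t (time units, typically my) every extant copy
duplicates at rate lam and is lost at rate mu, with exponential waiting
times; at each speciation node every surviving copy is transmitted to both
descendant branches. Extinct subtrees are pruned and unary nodes
suppressed, so the returned gene tree contains only lineages with extant
descendants. Surviving root copies are joined at the species-root age, so
the joins reconcile as root-mapped duplications — exactly the structure the
lineage decomposition cuts at — which makes the simulator a direct oracle
for the reconciliation stage.

Replicates with total extinction are reported as empty results, never
silently resampled, so downstream estimators stay unbiased.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .trees import TreeError, parse_newick

__all__ = [
    "SimulationParams",
    "SimulationResult",
    "simulate",
    "simulate_replicates",
    "recovery_experiment",
]


@dataclass
class SimulationParams:
    """Rates are per gene copy per unit branch length."""

    lam: float  # duplication rate
    mu: float  # loss rate
    k: int = 1  # root copy number
    seed: int = 0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.lam < 0 or self.mu < 0:
            raise ValueError("rates must be non-negative")
        if self.k < 1:
            raise ValueError("root copy number k must be >= 1")


class _GNode:
    __slots__ = ("children", "length", "species", "label")

    def __init__(self, length: float = 0.0):
        self.children: list["_GNode"] = []
        self.length = length
        self.species: str | None = None
        self.label: str | None = None


@dataclass
class SimulationResult:
    gene_tree: dendropy.Tree | None  # None when every copy went extinct
    true_root_copies: int  # root copies with >= 1 extant descendant
    true_lineage_of: dict[str, int]  # leaf label -> 1-based root copy index
    per_species_counts: Counter

    @property
    def n_leaves(self) -> int:
        return sum(self.per_species_counts.values())


def _check_branch_lengths(species_tree: dendropy.Tree) -> None:
    for node in species_tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None or node.edge.length <= 0:
            raise TreeError(
                "species tree for simulation needs positive branch lengths "
                f"(offending node above {node.taxon.label if node.taxon else 'internal'})"
            )


def _evolve_branch(
    t: float,
    sp_child: dendropy.Node,
    lam: float,
    mu: float,
    rng: np.random.Generator,
) -> _GNode | None:
    """One gene copy entering a species branch with t time remaining.

    Returns the (possibly pruned-to-None) gene subtree it leaves behind.
    """
    elapsed = 0.0
    total = lam + mu
    while True:
        wait = rng.exponential(1.0 / total) if total > 0 else np.inf
        if elapsed + wait >= t:
            # reached the bottom of the branch
            sub = _evolve_at(sp_child, lam, mu, rng)
            if sub is not None:
                sub.length += t - elapsed
            return sub
        elapsed += wait
        if rng.random() < (lam / total):
            # duplication: two independent continuations of the remainder
            left = _evolve_branch(t - elapsed, sp_child, lam, mu, rng)
            right = _evolve_branch(t - elapsed, sp_child, lam, mu, rng)
            kids = [c for c in (left, right) if c is not None]
            if not kids:
                return None
            if len(kids) == 1:  # one side extinct: suppress the unary node
                kids[0].length += elapsed
                return kids[0]
            node = _GNode(length=elapsed)
            node.children = kids
            return node
        return None  # loss


def _evolve_at(
    sp_node: dendropy.Node, lam: float, mu: float, rng: np.random.Generator
) -> _GNode | None:
    """One gene copy sitting at a species-tree node (speciation or tip)."""
    if sp_node.is_leaf():
        leaf = _GNode()
        leaf.species = sp_node.taxon.label
        return leaf
    kids = []
    for child in sp_node.child_nodes():
        sub = _evolve_branch(child.edge.length, child, lam, mu, rng)
        if sub is not None:
            kids.append(sub)
    if not kids:
        return None
    if len(kids) == 1:
        return kids[0]
    node = _GNode()
    node.children = kids
    return node


def _to_dendropy(root: _GNode) -> dendropy.Tree:
    newick = _as_newick(root) + ";"
    return parse_newick(newick)


def _as_newick(node: _GNode) -> str:
    if not node.children:
        return f"{node.label}:{node.length:g}"
    inner = ",".join(_as_newick(c) for c in node.children)
    return f"({inner}):{node.length:g}"


def simulate(
    species_tree: dendropy.Tree,
    params: SimulationParams,
    rng: np.random.Generator | None = None,
) -> SimulationResult:
    """Simulate one replicate of the gene family down the species tree."""
    _check_branch_lengths(species_tree)
    if rng is None:
        rng = np.random.default_rng(params.seed)
    surviving: list[tuple[int, _GNode]] = []
    for copy_index in range(1, params.k + 1):
        sub = _evolve_at(species_tree.seed_node, params.lam, params.mu, rng)
        if sub is not None:
            surviving.append((copy_index, sub))
    # label leaves species_c1, species_c2, ... and record truth
    counter: Counter = Counter()
    true_lineage: dict[str, int] = {}

    def label(node: _GNode, copy_index: int) -> None:
        if not node.children:
            counter[node.species] += 1
            node.label = f"{node.species}_c{counter[node.species]}"
            true_lineage[node.label] = copy_index
        else:
            for c in node.children:
                label(c, copy_index)

    for copy_index, sub in surviving:
        label(sub, copy_index)
    if not surviving:
        tree = None
    elif len(surviving) == 1:
        tree = _to_dendropy(surviving[0][1])
    else:
        # join surviving root copies at the species-root age (ladder of
        # zero-length internal branches above the root)
        root = _GNode()
        current = root
        copies = [sub for _, sub in surviving]
        current.children = [copies[0]]
        for sub in copies[1:-1]:
            join = _GNode(length=0.0)
            current.children.append(join)
            join.children = [sub]
            current = join
        current.children.append(copies[-1])
        tree = _to_dendropy(root)
    return SimulationResult(
        gene_tree=tree,
        true_root_copies=len(surviving),
        true_lineage_of=true_lineage,
        per_species_counts=counter,
    )


def simulate_replicates(
    species_tree: dendropy.Tree, params: SimulationParams
) -> list[SimulationResult]:
    """n_replicates independent replicates with per-replicate RNG streams
    derived deterministically from the root seed."""
    streams = np.random.SeedSequence(params.seed).spawn(params.n_replicates)
    return [
        simulate(species_tree, params, rng=np.random.default_rng(s))
        for s in streams
    ]


def _root_bipartition(species_tree: dendropy.Tree) -> tuple[set[str], set[str]]:
    kids = species_tree.seed_node.child_nodes()
    left = {l.taxon.label for l in kids[0].leaf_iter()}
    right = {
        l.taxon.label
        for c in kids[1:]
        for l in c.leaf_iter()
    }
    return left, right


def recovery_experiment(
    species_tree: dendropy.Tree, params: SimulationParams
) -> pd.DataFrame:
    """Simulate replicates and run the lineage decomposition on each.

    Returns one row per replicate with the true number of surviving root
    copies, the number of lineages the reconciliation recovers, and whether
    every surviving copy had extant members on both sides of the
    species-root bipartition (the regime where recovery is provably exact).
    """
    from .reconcile import decompose_lineages, reconcile

    left, right = _root_bipartition(species_tree)
    rows = []
    for rep, sim in enumerate(simulate_replicates(species_tree, params)):
        if sim.gene_tree is None:
            rows.append(
                {
                    "replicate": rep,
                    "true_surviving_copies": 0,
                    "recovered_lineages": 0,
                    "all_copies_span_root": False,
                    "n_leaves": 0,
                }
            )
            continue
        species_of = {
            leaf: leaf.rsplit("_c", 1)[0] for leaf in sim.true_lineage_of
        }
        result = reconcile(sim.gene_tree, species_tree, species_of)
        lineages = decompose_lineages(result)
        by_copy: dict[int, set[str]] = {}
        for leaf, copy_index in sim.true_lineage_of.items():
            by_copy.setdefault(copy_index, set()).add(species_of[leaf])
        spans = all(
            (sps & left) and (sps & right) for sps in by_copy.values()
        )
        rows.append(
            {
                "replicate": rep,
                "true_surviving_copies": sim.true_root_copies,
                "recovered_lineages": len(lineages),
                "all_copies_span_root": spans,
                "n_leaves": sim.n_leaves,
            }
        )
    return pd.DataFrame(rows)
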