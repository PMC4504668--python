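"""Reconciliation core: LCA mapping, event labels, lineage decomposition,
Dollo losses, retention summaries — each checked against independent
brute-force oracles on small trees."""

import numpy as np
import pytest

from chslineage.fixtures import canonical_fixture, lineage_color
from chslineage.reconcile import (
    DUPLICATION,
    SPECIATION,
    SpeciesIndex,
    decompose_lineages,
    dollo_losses,
    lca_map,
    reconcile,
    retention_summary,
)
from chslineage.trees import TreeError, parse_newick
from conftest import (
    SPECIES4_NEWICK,
    oracle_dollo_count,
    oracle_events,
    oracle_lca_map,
    random_gene_tree,
    species_labelled_shapes,
    shape_to_gene_tree,
)


@pytest.fixture(scope="module")
def fx():
    return canonical_fixture()


@pytest.fixture(scope="module")
def fx_recon(fx):
    return reconcile(fx.gene_tree, fx.species_tree, fx.species_map)


@pytest.fixture(scope="module")
def fx_lineages(fx_recon):
    return decompose_lineages(fx_recon)


def _by_color(lineages):
    return {lineage_color(l.members): l for l in lineages}


class TestLcaMapAndEvents:
    def test_leaf_maps_to_its_species(self):
        st = parse_newick(SPECIES4_NEWICK)
        gt = parse_newick("(A.1,(B.1,B.2));")
        res = lca_map(gt, st, {"A.1": "A", "B.1": "B", "B.2": "B"})
        for leaf in gt.leaf_node_iter():
            assert res.mapping[leaf].taxon.label == leaf.taxon.label.split(".")[0]

    def test_same_species_cherry_is_duplication(self):
        st = parse_newick(SPECIES4_NEWICK)
        gt = parse_newick("(A.1,(B.1,B.2));")
        res = reconcile(gt, st, {"A.1": "A", "B.1": "B", "B.2": "B"})
        cherry = [
            n
            for n in gt.preorder_internal_node_iter()
            if {l.taxon.label for l in n.leaf_iter()} == {"B.1", "B.2"}
        ][0]
        assert res.events[cherry] == DUPLICATION
        assert res.events[gt.seed_node] == SPECIATION

    def test_unmapped_leaf_errors(self):
        st = parse_newick(SPECIES4_NEWICK)
        gt = parse_newick("(A.1,B.1);")
        with pytest.raises(TreeError):
            lca_map(gt, st, {"A.1": "A"})

    def test_random_trees_match_bruteforce(self):
        st = parse_newick(SPECIES4_NEWICK)
        rng = np.random.default_rng(7)
        for _ in range(500):
            gt, species_of = random_gene_tree(rng, int(rng.integers(2, 16)))
            res = reconcile(gt, st, species_of)
            omap = oracle_lca_map(gt, st, species_of)
            for node in gt.preorder_node_iter():
                assert res.mapping[node] is omap[node]
            oev = oracle_events(gt, omap)
            assert res.events == oev


class TestFixtureMapping:
    """Spot checks pinned to the canonical fixture's published structure."""

    def test_pink_root_maps_to_fabales_ancestor(self, fx, fx_recon, fx_lineages):
        pink = _by_color(fx_lineages)["pink"]
        idx = fx_recon.species_index
        fabales = idx.mrca_of_species(["Gmax", "Mtruncatula", "Ljaponicus"])
        assert fx_recon.mapping[pink.root_node] is fabales
        assert fx_recon.events[pink.root_node] == DUPLICATION

    def test_green_root_is_a_speciation_at_the_species_root(
        self, fx_recon, fx_lineages
    ):
        green = _by_color(fx_lineages)["green"]
        assert fx_recon.mapping[green.root_node] is fx_recon.species_index.root
        assert fx_recon.events[green.root_node] == SPECIATION

    def test_backbone_nodes_are_root_mapped_duplications(self, fx_recon):
        root = fx_recon.gene_tree.seed_node
        idx = fx_recon.species_index
        node, backbone = root, []
        while node is not None:
            if (
                not node.is_leaf()
                and fx_recon.mapping[node] is idx.root
                and fx_recon.events[node] == DUPLICATION
            ):
                backbone.append(node)
                node = node.child_nodes()[1]
            else:
                node = None
        assert len(backbone) == 5


class TestDecomposition:
    def test_no_root_duplication_gives_single_lineage(self):
        st = parse_newick(SPECIES4_NEWICK)
        gt = parse_newick("((A.1,B.1),(C.1,D.1));")
        res = reconcile(gt, st, {l: l.split(".")[0] for l in "A.1 B.1 C.1 D.1".split()})
        lineages = decompose_lineages(res)
        assert len(lineages) == 1
        assert lineages[0].n_copies == 4

    def test_fixture_decomposes_into_six_coloured_lineages(self, fx_lineages):
        assert len(fx_lineages) == 6
        assert set(_by_color(fx_lineages)) == {
            "yellow",
            "blue",
            "red",
            "green",
            "brown",
            "pink",
        }

    def test_leaves_partition_exactly(self, fx, fx_lineages):
        union = set()
        total = 0
        for lin in fx_lineages:
            union |= lin.members
            total += lin.n_copies
        assert total == len(union) == len(fx.species_map)

    def test_lineage_ids_follow_preorder(self, fx_lineages):
        assert [l.lineage_id for l in fx_lineages] == [
            f"lineage_{i}" for i in range(1, 7)
        ]


class TestDolloLosses:
    def test_lineage_in_all_species_has_no_losses(self, fx):
        assert dollo_losses(fx.species, fx.species_tree) == set()

    def test_blue_lineage_four_losses(self, fx):
        """Cassava-only lineage: root-forced Dollo needs exactly 4 losses
        (malvids; Rosales+Fabales; poplar; castor bean), matching the
        brute-force minimum."""
        losses = dollo_losses(["Mesculenta"], fx.species_tree)
        assert len(losses) == 4
        assert len(losses) == oracle_dollo_count(["Mesculenta"], fx.species_tree)

    def test_green_lineage_three_losses(self, fx):
        present = ["Athaliana", "Alyrata", "Brapa", "Gmax", "Mtruncatula", "Ljaponicus"]
        losses = dollo_losses(present, fx.species_tree)
        assert len(losses) == 3
        assert len(losses) == oracle_dollo_count(present, fx.species_tree)

    def test_unknown_species_errors(self, fx):
        with pytest.raises(TreeError):
            dollo_losses(["Zmays"], fx.species_tree)

    def test_losses_are_maximal_absent_subtrees(self, fx):
        """Each loss edge is the top of one maximal absent subtree, so the
        lost subtrees are disjoint and cover every absent species."""
        idx = SpeciesIndex(fx.species_tree)
        rng = np.random.default_rng(3)
        species = np.array(fx.species)
        for _ in range(50):
            k = int(rng.integers(1, len(species) + 1))
            present = set(rng.choice(species, size=k, replace=False).tolist())
            losses = dollo_losses(present, fx.species_tree, index=idx)
            lost_leaves = [
                {l.taxon.label for l in n.leaf_iter()} for n in losses
            ]
            for i, a in enumerate(lost_leaves):
                assert not (a & present)
                for b in lost_leaves[i + 1 :]:
                    assert not (a & b)
            covered = set().union(*lost_leaves) if lost_leaves else set()
            assert covered == set(fx.species) - present

    def test_adding_a_species_changes_losses_by_bounded_amount(self, fx):
        """Adding one retaining species to a lineage changes the Dollo loss
        count by at most the number of edges newly marked present (each new
        present node exposes at most one extra absent sibling subtree, and
        at most one former loss edge is absorbed)."""
        idx = SpeciesIndex(fx.species_tree)
        rng = np.random.default_rng(8)
        species = np.array(fx.species)
        for _ in range(50):
            k = int(rng.integers(1, len(species)))
            present = set(rng.choice(species, size=k, replace=False).tolist())
            extra = rng.choice([s for s in fx.species if s not in present])
            before = dollo_losses(present, fx.species_tree, index=idx)
            after = dollo_losses(present | {extra}, fx.species_tree, index=idx)
            new_nodes = 0  # nodes on extra's root path not already present
            node = idx.species_node(extra)
            covered = set()
            for sp in present:
                n = idx.species_node(sp)
                while n is not None:
                    covered.add(n)
                    n = idx.parent[n]
            while node is not None and node not in covered:
                new_nodes += 1
                node = idx.parent[node]
            assert len(after) - len(before) <= new_nodes
            assert len(before) - len(after) <= 1

    def test_unconstrained_count_never_exceeds_root_forced(self, fx):
        rng = np.random.default_rng(4)
        species = np.array(fx.species)
        for _ in range(30):
            k = int(rng.integers(1, len(species) + 1))
            present = rng.choice(species, size=k, replace=False).tolist()
            forced = dollo_losses(present, fx.species_tree)
            free = dollo_losses(present, fx.species_tree, force_root=False)
            assert len(free) <= len(forced)


class TestRetentionSummary:
    def test_fixture_retention(self, fx, fx_lineages):
        ret = retention_summary(fx_lineages, fx.species)
        assert ret.n_multi == 7
        assert ret.n_single == 5
        # conservation: matrix totals equal lineage sizes and leaf census
        assert ret.matrix.to_numpy().sum() == len(fx.species_map)
        for lin in fx_lineages:
            assert ret.matrix[lin.lineage_id].sum() == lin.n_copies

    def test_single_lineage_everywhere(self):
        st = parse_newick(SPECIES4_NEWICK)
        gt = parse_newick("((A.1,B.1),(C.1,D.1));")
        res = reconcile(gt, st, {l: l.split(".")[0] for l in "A.1 B.1 C.1 D.1".split()})
        ret = retention_summary(decompose_lineages(res), ["A", "B", "C", "D"])
        assert ret.n_multi == 0
        assert ret.n_single == 4


class TestExhaustiveOracleEquivalence:
    def test_all_small_gene_trees_agree_with_bruteforce(self):
        """Every species-labelled gene-tree shape with <= 6 leaves over the
        4-species tree: mapping, events, and per-lineage root-forced Dollo
        losses all equal the brute-force computations."""
        st = parse_newick(SPECIES4_NEWICK)
        checked = 0
        for n in range(1, 7):
            for shape in species_labelled_shapes(n):
                gt, species_of = shape_to_gene_tree(shape)
                res = reconcile(gt, st, species_of)
                omap = oracle_lca_map(gt, st, species_of)
                for node in gt.preorder_node_iter():
                    assert res.mapping[node] is omap[node], shape
                assert res.events == oracle_events(gt, omap), shape
                for lin in decompose_lineages(res):
                    assert lin.n_losses == oracle_dollo_count(
                        lin.species_counts, st
                    ), shape
                checked += 1
        assert checked == 4 + 10 + 40 + 215 + 1260 + 8010
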