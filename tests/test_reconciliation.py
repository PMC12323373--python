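import math

import numpy as np
import pytest

from dtl_oracle import (
    brute_force_min_cost,
    dl_cost_closed_form,
    enumerate_topologies,
    random_topology,
    species_arrays,
)
from pulrecon.reconciliation import (
    EventCosts,
    PhyloTree,
    classify_family_history,
    reconcile,
    root_search,
)

DEFAULT = EventCosts()


class TestBasics:
    def test_congruent_tree_costs_zero(self, species5):
        gene = PhyloTree.from_newick("(((a,b),(c,d)),e);")
        lm = dict(zip("abcde", "ABCDE"))
        res = reconcile(gene, species5, lm)
        assert res.total_cost == 0.0
        assert res.counts() == {"speciation": 4, "duplication": 0, "transfer": 0, "loss": 0}

    def test_duplication_example(self):
        species = PhyloTree.from_newick("(A,B);")
        gene = PhyloTree.from_newick("((a1,a2),b);")
        res = reconcile(gene, species, {"a1": "A", "a2": "A", "b": "B"})
        assert res.total_cost == 2.0
        assert res.counts()["duplication"] == 1
        dup = next(e for e in res.events if e.type == "duplication")
        assert dup.species_branch == "A"

    def test_transfer_example_matches_oracle(self):
        species = PhyloTree.from_newick("((A,B),C);")
        gene = PhyloTree.from_newick("((a,c),b);")
        lm = {"a": "A", "b": "B", "c": "C"}
        res = reconcile(gene, species, lm)
        assert res.total_cost == brute_force_min_cost(gene, species, lm, DEFAULT)
        assert res.counts()["transfer"] == 1

    def test_loss_example(self, species5):
        # ((a,b),c): the c lineage passes through the (C,D) ancestor, so D
        # must be lost; no loss is charged above the inferred gene origin
        gene = PhyloTree.from_newick("((a,b),c);")
        lm = dict(zip("abc", "ABC"))
        res = reconcile(gene, species5, lm)
        assert res.total_cost == 1.0
        assert res.counts()["loss"] == 1
        assert res.total_cost == brute_force_min_cost(gene, species5, lm, DEFAULT)
        loss = next(e for e in res.events if e.type == "loss")
        assert loss.species_branch == "D"

    def test_unmapped_leaf_rejected(self, species5):
        gene = PhyloTree.from_newick("(a,z);")
        with pytest.raises(ValueError, match="leaf map"):
            reconcile(gene, species5, {"a": "A"})

    def test_cost_identity_invariant(self, species8):
        rng = np.random.default_rng(11)
        for _ in range(20):
            gene, lm = _random_instance(species8, rng, n_leaves=6)
            res = reconcile(gene, species8, lm)
            c = res.counts()
            assert res.total_cost == pytest.approx(
                c["loss"] * 1.0 + c["duplication"] * 2.0 + c["transfer"] * 3.0
            )

    def test_leaf_mapping_respected(self, species5):
        gene = PhyloTree.from_newick("((a,b),e);")
        res = reconcile(gene, species5, {"a": "A", "b": "B", "e": "E"})
        assert res.mapping["a"] == "A"
        assert res.mapping["e"] == "E"


def _random_instance(species, rng, n_leaves=5, multi_copy=True):
    sp_labels = [species.labels[i] for i in species.leaves]
    leaf_species = [sp_labels[int(rng.integers(0, len(sp_labels)))] for _ in range(n_leaves)]
    if not multi_copy:
        leaf_species = list(rng.permutation(sp_labels))[:n_leaves]
    names = [f"x{i}" for i in range(len(leaf_species))]
    gene = random_topology(names, rng)
    return gene, dict(zip(names, leaf_species))


class TestOracleEquivalence:
    def test_exhaustive_3_leaves(self):
        labels = ["A", "B", "C"]
        species_trees = enumerate_topologies(labels)
        gene_trees = enumerate_topologies([l.lower() for l in labels])
        lm = {l.lower(): l for l in labels}
        for sp in species_trees:
            pre = species_arrays(sp)
            for g in gene_trees:
                assert reconcile(g, sp, lm).total_cost == pytest.approx(
                    brute_force_min_cost(g, sp, lm, DEFAULT, pre)
                )

    def test_exhaustive_4_leaves(self):
        labels = ["A", "B", "C", "D"]
        species_trees = enumerate_topologies(labels)
        gene_trees = enumerate_topologies([l.lower() for l in labels])
        lm = {l.lower(): l for l in labels}
        for sp in species_trees:
            pre = species_arrays(sp)
            for g in gene_trees:
                assert reconcile(g, sp, lm).total_cost == pytest.approx(
                    brute_force_min_cost(g, sp, lm, DEFAULT, pre)
                )

    def test_random_multi_copy_instances(self, species5):
        rng = np.random.default_rng(42)
        pre = species_arrays(species5)
        for _ in range(50):
            gene, lm = _random_instance(species5, rng, n_leaves=5)
            dp = reconcile(gene, species5, lm).total_cost
            bf = brute_force_min_cost(gene, species5, lm, DEFAULT, pre)
            assert dp == pytest.approx(bf)

    def test_random_cost_vectors(self, species5):
        rng = np.random.default_rng(7)
        pre = species_arrays(species5)
        for _ in range(20):
            costs = EventCosts(
                loss=float(rng.uniform(0.1, 3)),
                duplication=float(rng.uniform(0.1, 4)),
                transfer=float(rng.uniform(0.1, 5)),
            )
            gene, lm = _random_instance(species5, rng, n_leaves=4)
            dp = reconcile(gene, species5, lm, costs).total_cost
            bf = brute_force_min_cost(gene, species5, lm, costs, pre)
            assert dp == pytest.approx(bf)


class TestProperties:
    def test_cost_monotonicity(self, species5):
        rng = np.random.default_rng(13)
        for _ in range(10):
            gene, lm = _random_instance(species5, rng, n_leaves=5)
            base = reconcile(gene, species5, lm, EventCosts(1.0, 2.0, 3.0)).total_cost
            for bumped in (EventCosts(1.5, 2.0, 3.0), EventCosts(1.0, 2.5, 3.0),
                           EventCosts(1.0, 2.0, 3.5)):
                assert reconcile(gene, species5, lm, bumped).total_cost >= base - 1e-9

    def test_degenerate_dl_matches_closed_form(self, species5):
        rng = np.random.default_rng(17)
        no_transfer = EventCosts(loss=1.0, duplication=2.0, transfer=1e9)
        for _ in range(50):
            gene, lm = _random_instance(species5, rng, n_leaves=5)
            dp = reconcile(gene, species5, lm, no_transfer)
            assert dp.counts()["transfer"] == 0
            assert dp.total_cost == pytest.approx(
                dl_cost_closed_form(gene, species5, lm, 2.0, 1.0)
            )

    def test_zero_loss_sanity_any_costs(self, species8):
        gene = PhyloTree.from_newick("((((a,b),(c,d)),((e,f),g)),h);")
        lm = {l: l.upper() for l in "abcdefgh"}
        rng = np.random.default_rng(3)
        for _ in range(5):
            costs = EventCosts(
                loss=float(rng.uniform(0, 5)),
                duplication=float(rng.uniform(0, 5)),
                transfer=float(rng.uniform(0, 5)),
            )
            assert reconcile(gene, species8, lm, costs).total_cost == 0.0

    def test_count_optima_at_least_one(self, species5):
        rng = np.random.default_rng(23)
        for _ in range(10):
            gene, lm = _random_instance(species5, rng, n_leaves=4)
            res = reconcile(gene, species5, lm, count_optima=True)
            assert res.n_optima is not None and res.n_optima >= 1


class TestRootSearch:
    def test_congruent_unrooted_achieves_zero(self, species5):
        rooted, res = root_search(
            "((a,b),(c,d),e);", species5, dict(zip("abcde", "ABCDE"))
        )
        assert res.total_cost == 0.0

    def test_all_rootings_evaluated(self, species5):
        # 5-leaf unrooted binary tree has 2n-3 = 7 edges; best rooting must
        # be at least as cheap as every explicit rooting we can build
        lm = dict(zip("abcde", "ABCDE"))
        _, res = root_search("((a,c),(b,d),e);", species5, lm)
        explicit = reconcile(
            PhyloTree.from_newick("(((a,c),(b,d)),e);"), species5, lm
        )
        assert res.total_cost <= explicit.total_cost

    def test_too_few_leaves_rejected(self, species5):
        with pytest.raises(ValueError):
            root_search("(a,b);", species5, {"a": "A", "b": "B"})


class TestClassify:
    def test_vertical(self, species5):
        gene = PhyloTree.from_newick("((a,b),(c,d));")
        res = reconcile(gene, species5, dict(zip("abcd", "ABCD")))
        assert classify_family_history(res)["verdict"] == "vertical"

    def test_hgt_dominated(self):
        species = PhyloTree.from_newick("((A,B),C);")
        gene = PhyloTree.from_newick("((a,c),b);")
        res = reconcile(gene, species, {"a": "A", "b": "B", "c": "C"})
        out = classify_family_history(res)
        assert out["verdict"] == "HGT-dominated"  # 3.0 of 3.0 total
        assert out["transfers"] == [("A", "C")]

    def test_mixed(self):
        # synthetic result: 1 transfer (3.0) + 4 losses (4.0) -> 3/7 <= 0.5
        from pulrecon.reconciliation import Event, ReconciliationResult

        res = ReconciliationResult(
            total_cost=7.0,
            events=[Event("transfer", "n", "X", donor="X", recipient="Y")]
            + [Event("loss", "n", "Z")] * 4,
            mapping={},
        )
        assert classify_family_history(res)["verdict"] == "mixed"
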