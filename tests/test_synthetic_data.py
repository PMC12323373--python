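import numpy as np
import pytest

from pulrecon.annotation import (
    call_susCD,
    consensus_cazymes,
    merge_roles,
)
from pulrecon.pul_detection import predict_puls
from pulrecon.reconciliation import EventCosts, PhyloTree, reconcile
from pulrecon.synthetic_data import (
    DECOY_TYPES,
    FamilySimConfig,
    GenomeSimConfig,
    PlantedLocus,
    mutate_genome,
    simulate_family,
    simulate_genome,
)


def run_pipeline(sim):
    roles = merge_roles(
        consensus_cazymes(sim.hits["CAZy"]),
        call_susCD(sim.hits["Pfam"] + sim.hits["TIGRFAM"]),
    )
    return predict_puls(sim.genes, roles)


class TestSimulateGenome:
    def test_single_category1_locus_recovered(self):
        sim = simulate_genome(GenomeSimConfig(
            planted_loci=(PlantedLocus(rule_category=1, substrate="alginate"),),
            seed=1,
        ))
        puls = run_pipeline(sim)
        assert len(puls) == 1
        assert puls[0].rule_category == 1
        assert puls[0].rank_span == tuple(sim.truth[0]["span"])
        assert puls[0].is_AUL

    def test_category2_locus_recovered(self):
        sim = simulate_genome(GenomeSimConfig(
            planted_loci=(PlantedLocus(rule_category=2),), seed=2,
        ))
        puls = run_pipeline(sim)
        assert len(puls) == 1 and puls[0].rule_category == 2

    @pytest.mark.parametrize("decoy", DECOY_TYPES)
    def test_each_decoy_alone_yields_no_pul(self, decoy):
        sim = simulate_genome(GenomeSimConfig(decoy_spec=(decoy,), seed=3))
        assert run_pipeline(sim) == []

    def test_determinism(self):
        cfg = GenomeSimConfig(
            n_genes=250, planted_loci=(PlantedLocus(),), decoy_spec=DECOY_TYPES, seed=9,
        )
        a, b = simulate_genome(cfg), simulate_genome(cfg)
        assert a.genes == b.genes
        assert a.hits == b.hits
        assert [s.sequence for s in a.sequences] == [s.sequence for s in b.sequences]
        assert a.truth == b.truth

    def test_loci_that_do_not_fit_rejected(self):
        with pytest.raises(ValueError, match="fit|slots"):
            simulate_genome(GenomeSimConfig(
                n_genes=30, planted_loci=tuple(PlantedLocus() for _ in range(4)),
            ))

    def test_multi_replicon_layout(self):
        sim = simulate_genome(GenomeSimConfig(
            n_genes=300, n_replicons=2,
            planted_loci=(PlantedLocus(), PlantedLocus(substrate="fucoidan")),
            seed=4,
        ))
        reps = {g.replicon_id for g in sim.genes}
        assert len(reps) == 2
        for rep in reps:
            ranks = [g.rank for g in sim.genes if g.replicon_id == rep]
            assert sorted(ranks) == list(range(len(ranks)))


class TestMutate:
    def test_rate_zero_identity(self):
        assert mutate_genome("ACGT" * 50, 0.0, seed=1) == "ACGT" * 50

    def test_substitution_fraction_within_3sd(self):
        n, r = 1_000_000, 0.05
        rng = np.random.default_rng(0)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
        mut = mutate_genome(seq, r, seed=2)
        observed = sum(1 for a, b in zip(seq, mut) if a != b) / n
        sd = (r * (1 - r) / n) ** 0.5
        assert abs(observed - r) < 3 * sd

    def test_rate_bounds(self):
        with pytest.raises(ValueError):
            mutate_genome("ACGT", 0.5, seed=0)

    def test_non_acgt_untouched(self):
        assert mutate_genome("NNNN", 0.2, seed=0) == "NNNN"


class TestSimulateFamily:
    def test_null_model_congruent(self, species8):
        fam = simulate_family(FamilySimConfig(species_tree=species8, seed=1))
        assert fam.events == []
        assert len(fam.gene_tree.leaves) == 8
        res = reconcile(fam.gene_tree, species8, fam.leaf_map)
        assert res.total_cost == 0.0

    def test_parsimony_bound(self, species8):
        costs = EventCosts()
        checked = 0
        for seed in range(30):
            fam = simulate_family(FamilySimConfig(
                species_tree=species8, p_dup=0.05, p_transfer=0.05,
                p_loss=0.05, seed=seed,
            ))
            truth_cost = sum(
                {"loss": 1.0, "duplication": 2.0, "transfer": 3.0}[e["type"]]
                for e in fam.events
            )
            res = reconcile(fam.gene_tree, species8, fam.leaf_map, costs)
            assert res.total_cost <= truth_cost + 1e-9
            checked += 1
        assert checked == 30

    def test_determinism(self, species8):
        cfg = FamilySimConfig(species_tree=species8, p_dup=0.1, p_loss=0.05, seed=5)
        a, b = simulate_family(cfg), simulate_family(cfg)
        assert a.gene_tree.newick_string() == b.gene_tree.newick_string()
        assert a.events == b.events
        assert a.leaf_map == b.leaf_map

    def test_extinction_raises(self):
        tiny = PhyloTree.from_newick("(A,B);")
        with pytest.raises(RuntimeError, match="p_loss"):
            simulate_family(FamilySimConfig(
                species_tree=tiny, p_loss=0.99, seed=0, max_attempts=5,
            ))

    def test_loss_rate_expectation(self, species8):
        # loss-only model: expected losses per surviving family computed by
        # independent recursion over the species tree
        p = 0.1
        S = species8

        def survive_prob(x):
            # probability a copy entering branch x leaves >=1 descendant leaf
            if not S.children[x]:
                return 1 - p
            c1, c2 = S.children[x]
            both_dead = (1 - survive_prob(c1)) * (1 - survive_prob(c2))
            return (1 - p) * (1 - both_dead)

        def expected_losses(x):
            # expected loss events in the subtree below-and-including branch x
            if not S.children[x]:
                return p
            c1, c2 = S.children[x]
            return p + (1 - p) * (expected_losses(c1) + expected_losses(c2))

        n = 1000
        totals = []
        for seed in range(n):
            try:
                fam = simulate_family(FamilySimConfig(
                    species_tree=S, p_loss=p, seed=seed, max_attempts=1,
                ))
            except RuntimeError:
                continue  # extinct or too small: excluded from the estimate
            totals.append(len(fam.events))
        # families conditioned on >=2 surviving leaves: compare against the
        # unconditional expectation loosely (3 s.d. of the sample mean, plus
        # the conditioning bias bounded by the extinction mass)
        expected = expected_losses(S.root)
        sample_mean = np.mean(totals)
        sd = np.std(totals) / len(totals) ** 0.5
        assert abs(sample_mean - expected) < 3 * sd + expected * (1 - survive_prob(S.root)) * 2


class TestLowRateRecovery:
    def test_single_event_type_recovered(self, species8):
        """In the <=1-event regime the inferred event multiset matches truth."""
        matched = total = 0
        seed = 0
        while total < 60:
            seed += 1
            fam = simulate_family(FamilySimConfig(
                species_tree=species8, p_dup=0.01, p_transfer=0.01,
                p_loss=0.01, seed=seed,
            ))
            if len(fam.events) > 1:
                continue
            total += 1
            res = reconcile(fam.gene_tree, species8, fam.leaf_map)
            counts = res.counts()
            inferred = (
                ["duplication"] * counts["duplication"]
                + ["transfer"] * counts["transfer"]
                + ["loss"] * counts["loss"]
            )
            truth = [e["type"] for e in fam.events]
            if sorted(inferred) == sorted(truth):
                matched += 1
        assert matched / total >= 0.95
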