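"""Simulator: history validation, gene-tree structure, clock calibration."""

import numpy as np
import pytest

from ohnolog.ks import pairwise_ks
from ohnolog.simulate import (
    ScenarioError,
    SimScenario,
    WGDEvent,
    canonical_scenarios,
    emit_mito_times,
    simulate_codon_sequences,
    simulate_dataset,
    simulate_gene_trees,
    simulate_history,
)
from ohnolog.topology import classify_pair_tree, classify_triplet_tree
from ohnolog.trees import read_newick


def scenario(topology, events, **kw):
    defaults = dict(name="test", outgroup=None, n_families=10,
                    n_codons=100, q=0.0, loss_prob=0.0)
    defaults.update(kw)
    return SimScenario(topology=topology, events=tuple(events), **defaults)


class TestHistoryValidation:
    def test_independent_tip_events_annotate_tip_edges(self):
        sc = scenario(
            ("A", "B", 9.02),
            [WGDEvent(("A",), 0.93), WGDEvent(("B",), 1.45)],
        )
        hist = simulate_history(sc)
        assert hist.split_time("A", "B") == 9.02
        assert hist.expected_ohnolog_divergence() == {"A": 0.93, "B": 1.45}

    def test_shared_event_on_stem(self):
        sc = scenario(
            (("A", "B", 0.16), "D", 5.0),
            [WGDEvent(("A", "B"), 2.0)],
        )
        hist = simulate_history(sc)
        assert hist.expected_ohnolog_divergence() == {"A": 2.0, "B": 2.0}

    def test_event_outside_edge_interval_errors(self):
        # A WGD at 10 Mya cannot sit on a tip edge that ends at 9 Mya.
        sc = scenario(("A", "B", 9.0), [WGDEvent(("A",), 10.0)])
        with pytest.raises(ScenarioError):
            simulate_history(sc)

    def test_shared_event_younger_than_crown_errors(self):
        sc = scenario((("A", "B", 2.0), "D", 5.0), [WGDEvent(("A", "B"), 1.0)])
        with pytest.raises(ScenarioError):
            simulate_history(sc)

    def test_non_clade_event_errors(self):
        sc = scenario((("A", "B", 1.0), "C", 5.0), [WGDEvent(("A", "C"), 2.0)])
        with pytest.raises(ScenarioError):
            simulate_history(sc)

    def test_allo_donor_constraints(self):
        with pytest.raises(ScenarioError):
            WGDEvent(("A",), 1.0, mode="allo")  # no donor
        sc = scenario(
            ("A", "B", 3.0),
            [WGDEvent(("A",), 4.0, mode="allo", donor="B")],
        )
        with pytest.raises(ScenarioError):
            simulate_history(sc)  # hybridization older than lineage split

    def test_species_in_two_events_rejected(self):
        with pytest.raises(ScenarioError):
            scenario(
                (("A", "B", 0.5), "C", 5.0),
                [WGDEvent(("A",), 0.3), WGDEvent(("A", "B"), 2.0)],
            )


class TestGeneTrees:
    def test_noise_free_independent_auto_shape(self):
        sc = scenario(
            ("A", "B", 9.0), [WGDEvent(("A",), 1.0), WGDEvent(("B",), 1.5)]
        )
        trees = simulate_gene_trees(simulate_history(sc), n=5, seed=0)
        for t in trees:
            assert classify_pair_tree(t).label == "T1"

    def test_noise_free_shared_shape(self):
        sc = scenario(
            (("A", "B", 0.16), "D", 5.0), [WGDEvent(("A", "B"), 2.0)]
        )
        trees = simulate_gene_trees(simulate_history(sc), n=5, seed=0)
        for t in trees:
            sub = t.restrict_to_species(["A", "B"])
            assert classify_pair_tree(sub).mode == "SP"

    def test_shared_triplet_shape(self):
        sc = scenario(
            ((("A", "B", 0.1), "C", 0.2), "D", 5.0),
            [WGDEvent(("A", "B", "C"), 2.0)],
        )
        trees = simulate_gene_trees(simulate_history(sc), n=3, seed=0)
        for t in trees:
            assert classify_triplet_tree(t.restrict_to_species("ABC")) == "SP"

    def test_same_seed_identical_trees(self):
        sc = scenario(
            ("A", "B", 9.0), [WGDEvent(("A",), 1.0)], q=0.3, loss_prob=0.2
        )
        hist = simulate_history(sc)
        t1 = [t.to_newick() for t in simulate_gene_trees(hist, n=20, seed=4)]
        t2 = [t.to_newick() for t in simulate_gene_trees(hist, n=20, seed=4)]
        assert t1 == t2

    def test_nni_noise_bounds_minority_fraction(self):
        q = 0.3
        sc = scenario(("A", "B", 9.0),
                      [WGDEvent(("A",), 1.0), WGDEvent(("B",), 1.5)], q=q)
        trees = simulate_gene_trees(simulate_history(sc), n=200, seed=1)
        ip = sum(classify_pair_tree(t).mode == "IP" for t in trees)
        assert ip / len(trees) >= 1 - q

    def test_loss_prunes_copies(self):
        sc = scenario(("A", "B", 9.0),
                      [WGDEvent(("A",), 1.0), WGDEvent(("B",), 1.5)],
                      loss_prob=0.5)
        trees = simulate_gene_trees(simulate_history(sc), n=100, seed=2)
        n_leaves = [t.n_leaves for t in trees]
        assert min(n_leaves) < 4 and max(n_leaves) == 4

    def test_allo_copy_groups_with_donor(self):
        sc = scenario(
            (("A", "DA", 3.0), "B", 9.0),
            [WGDEvent(("A",), 1.0, mode="allo", donor="DA")],
        )
        trees = simulate_gene_trees(simulate_history(sc), n=3, seed=0)
        for t in trees:
            # One A copy is sister to the donor; ohnologs coalesce at 3 Mya.
            sub = t.restrict_to_species(["A", "DA"])
            assert sorted(sub.leaf_labels()) == ["A_1", "A_2", "DA"]
            assert sub.shape() == (
                "I",
                (("I", (("L", "A"), ("L", "DA"))), ("L", "A")),
            )


class TestCodonSequences:
    def test_mean_ks_matches_clock(self):
        # Two tips separated by total time T: E[Ks] = 2 r T under the
        # estimator's own site accounting.
        b = 0.005  # r * T per lineage, in Ks units
        tree = read_newick(f"(A:{b},B:{b});")
        vals = []
        for seed in range(300):
            aln = simulate_codon_sequences(tree, 500, seed=seed)
            rec = pairwise_ks(aln["A"], aln["B"])
            vals.append(rec.ks)
        mean = float(np.mean(vals))
        assert mean == pytest.approx(2 * b, rel=0.10)

    def test_doubling_branch_doubles_ks(self):
        short = read_newick("(A:0.004,B:0.004);")
        long_ = read_newick("(A:0.008,B:0.008);")
        m = []
        for tree in (short, long_):
            vals = [
                pairwise_ks(*simulate_codon_sequences(tree, 400, seed=s).values()).ks
                for s in range(150)
            ]
            m.append(np.mean(vals))
        assert m[1] / m[0] == pytest.approx(2.0, rel=0.15)

    def test_zero_time_identical_sequences(self):
        tree = read_newick("(A:0.0,B:0.0);")
        aln = simulate_codon_sequences(tree, 50, seed=3)
        assert aln["A"] == aln["B"]
        assert pairwise_ks(aln["A"], aln["B"]).ks == 0.0

    def test_zero_length_errors(self):
        tree = read_newick("(A:0.01,B:0.01);")
        with pytest.raises(ValueError):
            simulate_codon_sequences(tree, 0)

    def test_deterministic_given_seed(self):
        tree = read_newick("(A:0.01,(B:0.005,C:0.005):0.005);")
        a1 = simulate_codon_sequences(tree, 100, seed=11)
        a2 = simulate_codon_sequences(tree, 100, seed=11)
        assert a1 == a2


class TestMitoTimes:
    def test_half_width_interval(self):
        sc = scenario(("A", "B", 9.02), [WGDEvent(("A",), 1.0)])
        hist = simulate_history(sc)
        rows = emit_mito_times(hist, ci_half_width=2.0)
        row = next(m for m in rows if m.key == frozenset(("A", "B")))
        assert (row.low, row.high) == (7.02, 11.02)

    def test_zero_half_width_degenerate(self):
        sc = scenario(("A", "B", 9.02), [WGDEvent(("A",), 1.0)])
        rows = emit_mito_times(simulate_history(sc), ci_half_width=0.0)
        assert rows[0].low == rows[0].high == rows[0].T_mt

    def test_three_species_three_rows(self):
        sc = scenario((("A", "B", 1.0), "C", 5.0), [WGDEvent(("A",), 0.5)])
        rows = emit_mito_times(simulate_history(sc), 1.0)
        assert len(rows) == 3

    def test_negative_half_width_errors(self):
        sc = scenario(("A", "B", 9.0), [WGDEvent(("A",), 1.0)])
        with pytest.raises(ValueError):
            emit_mito_times(simulate_history(sc), -1.0)


class TestDatasetBundle:
    def test_reproducible_from_seed(self):
        sc = canonical_scenarios(n_families=5)["independent-auto"]
        d1 = simulate_dataset(sc, seed=9)
        d2 = simulate_dataset(sc, seed=9)
        assert [t.to_newick() for t in d1.gene_trees] == [
            t.to_newick() for t in d2.gene_trees
        ]
        assert d1.alignments == d2.alignments

    def test_truth_records_expected_divergence(self):
        sc = canonical_scenarios(n_families=5)["shared-allo"]
        truth = simulate_dataset(sc, seed=0).truth
        # allo ohnologs coalesce at the parental-lineage divergence (5 Mya),
        # not at the hybridization time (2 Mya)
        assert truth["expected_ohnolog_divergence_mya"] == {"PA": 5.0, "PB": 5.0}
        assert truth["events"][0]["time_mya"] == 2.0
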