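"""MUL-tree hypothesis enumeration and duplication-loss reconciliation."""

import numpy as np
import pytest

from ohnolog import canonical_scenarios
from ohnolog.reconcile import enumerate_hypotheses, rank_hypotheses, reconcile
from ohnolog.simulate import simulate_gene_trees, simulate_history
from ohnolog.trees import TreeError, read_newick

from oracles import oracle_reconcile


class TestEnumerateHypotheses:
    def test_two_taxon_tree_single_polyploid(self):
        st = read_newick("(A,B);", kind="species")
        hyps = enumerate_hypotheses(st, {"A"})
        ids = {h.hypothesis_id for h in hyps}
        assert ids == {"baseline", "auto", "allo-B", "allo-root"}
        modes = {h.hypothesis_id: h.mode for h in hyps}
        assert modes["auto"] == "auto"
        assert modes["allo-B"] == "allo"
        assert modes["baseline"] == "no-wgd"

    def test_empty_polyploid_set_gives_baseline_only(self):
        st = read_newick("(A,B);", kind="species")
        hyps = enumerate_hypotheses(st, set())
        assert [h.hypothesis_id for h in hyps] == ["baseline"]

    def test_unknown_taxon_errors(self):
        st = read_newick("(A,B);", kind="species")
        with pytest.raises(TreeError):
            enumerate_hypotheses(st, {"Z"})

    def test_polyploid_clade_hypotheses(self):
        st = read_newick("((A,B),C);", kind="species")
        hyps = enumerate_hypotheses(st, {"A", "B"})
        # no H2 attachment inside the polyploid clade itself
        for h in hyps:
            if h.h2 not in (None, "root"):
                assert not (h.h2 < {"A", "B"})
        assert any(h.mode == "auto" for h in hyps)

    def test_bound_enforced(self):
        st = read_newick("((A,B),C);", kind="species")
        with pytest.raises(ValueError):
            enumerate_hypotheses(st, {"A"}, max_groups=2)


class TestReconcileExamples:
    def setup_method(self):
        self.st = read_newick("(A,B);", kind="species")
        self.hyps = {
            h.hypothesis_id: h for h in enumerate_hypotheses(self.st, {"A"})
        }

    def test_duplication_against_baseline(self):
        gt = read_newick("((A_1,A_2),B);")
        r = reconcile(gt, self.hyps["baseline"])
        assert (r.duplications, r.losses, r.score) == (1, 0, 1)

    def test_zero_score_on_auto_multree(self):
        gt = read_newick("((A_1,A_2),B);")
        r = reconcile(gt, self.hyps["auto"])
        assert r.score == 0

    def test_congruent_single_copy_tree_scores_zero(self):
        gt = read_newick("(A,B);")
        r = reconcile(gt, self.hyps["baseline"])
        assert r.score == 0

    def test_missing_species_errors(self):
        gt = read_newick("((A_1,A_2),C);")
        with pytest.raises(TreeError):
            reconcile(gt, self.hyps["baseline"])

    def test_score_invariant_under_leaf_reordering(self):
        a = read_newick("((A_1,A_2),B);")
        b = read_newick("(B,(A_2,A_1));")
        for hyp in self.hyps.values():
            assert reconcile(a, hyp).score == reconcile(b, hyp).score

    def test_adding_congruent_species_never_increases_score(self):
        st2 = read_newick("((A,B),C);", kind="species")
        hyps2 = {h.hypothesis_id: h for h in enumerate_hypotheses(st2, {"A"})}
        gt = read_newick("((A_1,A_2),B);")
        gt2 = read_newick("(((A_1,A_2),B),C);")
        for name in ("baseline", "auto"):
            assert reconcile(gt2, hyps2[name]).score <= reconcile(
                gt, self.hyps[name]
            ).score + 0  # congruent extension adds no events


def _random_topology(rng, labels):
    shapes = [l for l in labels]
    while len(shapes) > 1:
        i, j = rng.choice(len(shapes), size=2, replace=False)
        a, b = shapes[i], shapes[j]
        shapes = [s for k, s in enumerate(shapes) if k not in (i, j)] + [(a, b)]
    return shapes[0]


def _newick(shape):
    def rec(n):
        if isinstance(n, str):
            return n
        return "(" + ",".join(rec(k) for k in n) + ")"

    return rec(shape) + ";"


class TestAgainstBruteForce:
    def test_random_instances_match_oracle(self):
        """Exhaustive-assignment reconciliation equals an independent
        brute-force on random gene trees and MUL hypotheses."""
        rng = np.random.default_rng(2024)
        species = ["A", "B", "C", "D"]
        st = read_newick("(((A,B),C),D);", kind="species")
        for rep in range(25):
            poly = ["A"] if rep % 2 == 0 else ["A", "B"]
            hyps = enumerate_hypotheses(st, set(poly))
            # random gene tree: polyploids carry 2 copies, others 1
            leaves = []
            for sp in species:
                if sp in poly:
                    leaves += [f"{sp}_1", f"{sp}_2"]
                else:
                    leaves.append(sp)
            shape = _random_topology(rng, leaves)
            gt = read_newick(_newick(shape))
            hyp = hyps[rng.integers(len(hyps))]
            mine = reconcile(gt, hyp)
            # oracle: hypothesis nested tuple with unique leaf ids
            counter = {}

            def uniquify(n):
                if isinstance(n, tuple):
                    return tuple(uniquify(k) for k in n)
                counter[n] = counter.get(n, 0) + 1
                return f"{n}#{counter[n]}"

            from ohnolog.reconcile import _nested

            if hyp.is_baseline:
                hyp_nested = uniquify(_nested(hyp.tree.tree))
            else:
                def nested_mul(node):
                    if node.is_leaf():
                        from ohnolog.trees import leaf_label

                        return leaf_label(node)
                    return tuple(nested_mul(c) for c in node.child_nodes())

                hyp_nested = uniquify(nested_mul(hyp.tree.tree.seed_node))

            def hyp_leaf_ids(nested, acc):
                if isinstance(nested, tuple):
                    for k in nested:
                        hyp_leaf_ids(k, acc)
                else:
                    acc.append(nested)
                return acc

            ids = hyp_leaf_ids(hyp_nested, [])
            options = {}
            for leaf in leaves:
                sp = leaf.split("_")[0]
                options[leaf] = [i for i in ids if i.split("#")[0] == sp]
            od, ol, oscore = oracle_reconcile(shape, hyp_nested, options)
            assert mine.score == oscore, (rep, hyp.hypothesis_id)

    def test_oracle_agreement_with_many_polyploid_leaves(self):
        """A 12-polyploid-leaf instance still minimised exactly."""
        rng = np.random.default_rng(7)
        st = read_newick("((A,B),C);", kind="species")
        hyps = enumerate_hypotheses(st, {"A", "B"})
        # three families' worth of copies merged into one big tree is not
        # biological, but exercises the assignment search: 6 copies per
        # species is 12 polyploid leaves.
        leaves = [f"A_{i}" for i in range(1, 7)] + [f"B_{i}" for i in range(1, 7)] + ["C"]
        shape = _random_topology(rng, leaves)
        gt = read_newick(_newick(shape))
        hyp = hyps[2]
        r = reconcile(gt, hyp)
        assert not r.non_optimal
        greedy = reconcile(gt, hyp, max_exhaustive=4)
        assert greedy.non_optimal
        assert greedy.score >= r.score


class TestRanking:
    def test_auto_ranks_first_on_auto_simulation(self, noise_free_scenarios):
        sc = noise_free_scenarios["independent-auto"]
        hist = simulate_history(sc)
        trees = simulate_gene_trees(hist, n=50, q=0.0, loss_prob=0.0, seed=9)
        focal = [t.restrict_to_species(["PA", "DIP"]) for t in trees]
        st = hist.species_tree.restrict({"PA", "DIP"})
        ranked = rank_hypotheses(focal, enumerate_hypotheses(st, {"PA"}))
        assert ranked[0].hypothesis.mode == "auto"
        assert ranked[0].score < ranked[1].score

    def test_allo_attachment_recovered(self, noise_free_scenarios):
        sc = noise_free_scenarios["independent-allo"]
        hist = simulate_history(sc)
        trees = simulate_gene_trees(hist, n=50, q=0.0, loss_prob=0.0, seed=9)
        focal = [t.restrict_to_species(["PA", "DA", "DB"]) for t in trees]
        st = hist.species_tree.restrict({"PA", "DA", "DB"})
        ranked = rank_hypotheses(focal, enumerate_hypotheses(st, {"PA"}))
        assert ranked[0].hypothesis.mode == "allo"
        assert ranked[0].hypothesis.h2 == frozenset({"DA"})

    def test_single_copy_trees_prefer_baseline(self):
        st = read_newick("(A,B);", kind="species")
        hyps = enumerate_hypotheses(st, {"A"})
        trees = [read_newick("(A,B);") for _ in range(5)]
        ranked = rank_hypotheses(trees, hyps)
        assert ranked[0].hypothesis_id == "baseline"

    def test_empty_gene_trees_error(self):
        st = read_newick("(A,B);", kind="species")
        with pytest.raises(ValueError):
            rank_hypotheses([], enumerate_hypotheses(st, {"A"}))
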