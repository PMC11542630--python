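"""Simplified MUL-tree duplication–loss reconciliation.

To distinguish auto- from allopolyploidy, gene trees carrying both ohnolog
copies are reconciled against a set of hypotheses: the singly-labelled
species tree (baseline, no WGD) and every multi-labelled (MUL) tree obtained
by attaching a second copy of the polyploid subtree (H2) to an edge of the
species tree while the first copy (H1) keeps its original position.  H2 on
the same edge as H1 is the autopolyploid hypothesis; H2 elsewhere is an
allopolyploid hypothesis naming the donor lineage.  Each hypothesis is
scored by the parsimony duplication + loss cost (unit costs by default)
under LCA mapping, minimised exactly over all assignments of each polyploid
gene copy to one of that species' two MUL leaves; the hypothesis with the
lowest total over gene trees wins.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .trees import (
    GeneTree,
    MULTree,
    SpeciesTree,
    TreeError,
    leaf_label,
    parse_leaf_label,
    read_newick,
)

__all__ = [
    "Hypothesis",
    "ReconciliationResult",
    "enumerate_hypotheses",
    "reconcile",
    "rank_hypotheses",
]

MAX_EXHAUSTIVE_POLYPLOID_LEAVES = 12


# ---------------------------------------------------------------------------
# Hypothesis enumeration


def _nested(tree) -> object:
    """Dendropy tree -> nested tuple of leaf labels (topology only)."""

    def rec(node):
        if node.is_leaf():
            return node.taxon.label
        return tuple(rec(c) for c in node.child_nodes())

    return rec(tree.seed_node)


def _leafset(nested) -> frozenset:
    if isinstance(nested, str):
        return frozenset([nested])
    return frozenset().union(*(_leafset(k) for k in nested))


def _edges(nested) -> list[frozenset]:
    """Edge keys: clade of every non-root node, plus the root edge ("root")."""
    out: list = []

    def rec(node, is_root):
        if not is_root:
            out.append(_leafset(node))
        if not isinstance(node, str):
            for k in node:
                rec(k, False)

    rec(nested, True)
    out.append("root")
    return out


def _attach(nested, edge_key, subtree):
    """Attach ``subtree`` on the edge identified by ``edge_key``."""
    if edge_key == "root":
        return (nested, subtree)

    def rec(node):
        if _leafset(node) == edge_key:
            return (node, subtree)
        if isinstance(node, str):
            return node
        return tuple(rec(k) for k in node)

    return rec(nested)


def _subtree(nested, clade: frozenset):
    if _leafset(nested) == clade:
        return nested
    if isinstance(nested, str):
        return None
    for k in nested:
        found = _subtree(k, clade)
        if found is not None:
            return found
    return None


def _to_newick(nested) -> str:
    def rec(node):
        if isinstance(node, str):
            return node
        return "(" + ",".join(rec(k) for k in node) + ")"

    return rec(nested) + ";"


@dataclass
class Hypothesis:
    """One reconciliation hypothesis: a MUL tree or the singly-labelled baseline."""

    hypothesis_id: str
    tree: MULTree | SpeciesTree
    h1: frozenset | None = None
    h2: frozenset | str | None = None

    @property
    def is_baseline(self) -> bool:
        return self.h1 is None

    @property
    def mode(self) -> str:
        if self.is_baseline:
            return "no-wgd"
        return "auto" if self.h1 == self.h2 else "allo"

    def describe(self) -> str:
        if self.is_baseline:
            return "baseline (no WGD)"
        h2 = "root" if self.h2 == "root" else "+".join(sorted(self.h2))
        return f"{self.mode}: H1={'+'.join(sorted(self.h1))}, H2={h2}"


def enumerate_hypotheses(
    species_tree: SpeciesTree,
    polyploid_taxa: Iterable[str],
    max_groups: int = 15,
) -> list[Hypothesis]:
    """All single-WGD MUL-tree hypotheses for one polyploid clade + baseline.

    The polyploid taxa must form a clade (or a single species) of the
    species tree; its subtree keeps its position (H1) while a second copy is
    attached to every edge outside the clade, to the clade's own edge
    (autopolyploidy) and to the root edge.  Raises when the number of MUL
    hypotheses would exceed ``max_groups``.
    """
    poly = frozenset(polyploid_taxa)
    missing = poly - species_tree.species()
    if missing:
        raise TreeError(f"polyploid taxa not in species tree: {sorted(missing)}")
    nested = _nested(species_tree.tree)
    hyps: list[Hypothesis] = [
        Hypothesis(hypothesis_id="baseline", tree=species_tree)
    ]
    if not poly:
        return hyps
    sub = _subtree(nested, poly)
    if sub is None:
        raise TreeError(
            f"polyploid taxa {sorted(poly)} do not form a clade of the species tree"
        )
    candidate_edges = [
        e
        for e in _edges(nested)
        if e == "root" or not (e < poly or (e <= poly and e != poly))
    ]
    # Exclude edges strictly inside the polyploid clade; keep the clade edge
    # itself (auto) and every outside edge (allo) including the root edge.
    candidate_edges = [
        e for e in candidate_edges if e == "root" or e == poly or not e <= poly
    ]
    muls = []
    for e in candidate_edges:
        mul_nested = _attach(nested, e, sub)
        name = "auto" if e == poly else (
            "allo-root" if e == "root" else "allo-" + "+".join(sorted(e))
        )
        tree = read_newick(_to_newick(mul_nested), kind="mul")
        muls.append(Hypothesis(hypothesis_id=name, tree=tree, h1=poly, h2=e))
    if len(muls) > max_groups:
        raise ValueError(
            f"{len(muls)} MUL hypotheses exceed the allowed maximum {max_groups}"
        )
    return hyps + muls


# ---------------------------------------------------------------------------
# Reconciliation


class _HypIndex:
    """Parent/depth index of a hypothesis tree for LCA queries."""

    def __init__(self, tree):
        self.parent: dict = {}
        self.depth: dict = {}
        self.leaves_by_species: dict[str, list] = {}
        root = tree.seed_node
        for node in tree.preorder_node_iter():
            self.depth[id(node)] = (
                0 if node is root else self.depth[id(node.parent_node)] + 1
            )
            self.parent[id(node)] = node.parent_node
            if node.is_leaf():
                self.leaves_by_species.setdefault(leaf_label(node), []).append(node)

    def lca(self, a, b):
        da, db = self.depth[id(a)], self.depth[id(b)]
        while da > db:
            a = self.parent[id(a)]
            da -= 1
        while db > da:
            b = self.parent[id(b)]
            db -= 1
        while a is not b:
            a = self.parent[id(a)]
            b = self.parent[id(b)]
        return a


@dataclass
class ReconciliationResult:
    hypothesis_id: str
    hypothesis: Hypothesis | None
    duplications: int
    losses: int
    score: float
    per_tree: list = field(default_factory=list)  # (dup, loss) per gene tree
    non_optimal: bool = False
    tied_with: list = field(default_factory=list)


def _score_assignment(gene_root, mapping, index, dup_cost, loss_cost):
    """Duplication+loss cost of one fixed leaf assignment under LCA mapping."""
    M: dict = {}
    dups = 0
    losses = 0
    post = []

    def collect(node):
        for c in node.child_nodes():
            collect(c)
        post.append(node)

    collect(gene_root)
    for node in post:
        if node.is_leaf():
            M[id(node)] = mapping[id(node)]
            continue
        kids = node.child_nodes()
        m = M[id(kids[0])]
        for k in kids[1:]:
            m = index.lca(m, M[id(k)])
        M[id(node)] = m
        if any(M[id(k)] is m for k in kids):
            dups += 1
            is_dup = 1
        else:
            is_dup = 0
        for k in kids:
            d = index.depth[id(M[id(k)])] - index.depth[id(m)]
            losses += max(0, d - 1 + is_dup)
    return dups, losses, dups * dup_cost + losses * loss_cost


def reconcile(
    gene_tree: GeneTree,
    hypothesis: Hypothesis | MULTree | SpeciesTree,
    dup_cost: float = 1.0,
    loss_cost: float = 1.0,
    max_exhaustive: int = MAX_EXHAUSTIVE_POLYPLOID_LEAVES,
) -> ReconciliationResult:
    """Minimum duplication+loss reconciliation of one gene tree.

    Every gene-tree leaf of a doubled (polyploid) hypothesis species may map
    to either of that species' two hypothesis leaves; the score is minimised
    exhaustively over all assignments when the number of such leaves is at
    most ``max_exhaustive``, otherwise by a greedy per-leaf pass flagged
    ``non_optimal``.
    """
    if isinstance(hypothesis, Hypothesis):
        hyp = hypothesis
    else:
        hyp = Hypothesis(hypothesis_id="adhoc", tree=hypothesis)
        if isinstance(hypothesis, MULTree):
            hyp.h1 = frozenset(hypothesis.polyploid_species) or None
            hyp.h2 = hypothesis.h2
    index = _HypIndex(hyp.tree.tree)
    fixed: dict = {}
    choices: list[tuple] = []  # (gene leaf, [hyp leaf options])
    for leaf in gene_tree.tree.leaf_node_iter():
        sp = parse_leaf_label(leaf.taxon.label, gene_tree.sep).species
        options = index.leaves_by_species.get(sp)
        if not options:
            raise TreeError(f"species {sp!r} missing from hypothesis tree")
        if len(options) == 1:
            fixed[id(leaf)] = options[0]
        else:
            choices.append((leaf, options))
    root = gene_tree.tree.seed_node
    non_optimal = False
    if len(choices) <= max_exhaustive:
        best = None
        for combo in itertools.product(*(opts for _, opts in choices)):
            mapping = dict(fixed)
            for (leaf, _), target in zip(choices, combo):
                mapping[id(leaf)] = target
            res = _score_assignment(root, mapping, index, dup_cost, loss_cost)
            if best is None or res[2] < best[2]:
                best = res
    else:
        non_optimal = True
        mapping = dict(fixed)
        for leaf, opts in choices:
            mapping[id(leaf)] = opts[0]
        for leaf, opts in choices:
            scored = []
            for opt in opts:
                mapping[id(leaf)] = opt
                scored.append(
                    (_score_assignment(root, mapping, index, dup_cost, loss_cost), opt)
                )
            best_local = min(scored, key=lambda t: t[0][2])
            mapping[id(leaf)] = best_local[1]
        best = _score_assignment(root, mapping, index, dup_cost, loss_cost)
    dups, losses, score = best
    return ReconciliationResult(
        hypothesis_id=hyp.hypothesis_id,
        hypothesis=hyp,
        duplications=dups,
        losses=losses,
        score=score,
        per_tree=[(dups, losses)],
        non_optimal=non_optimal,
    )


def rank_hypotheses(
    gene_trees: Sequence[GeneTree],
    hypotheses: Sequence[Hypothesis],
    dup_cost: float = 1.0,
    loss_cost: float = 1.0,
) -> list[ReconciliationResult]:
    """Score every hypothesis over all gene trees; ascending by total score.

    Ties for the best score are reported on the winner (``tied_with``), not
    broken silently.  The winner's H1/H2 placement gives the mode call:
    same edge → autopolyploid, different edges → allopolyploid, baseline →
    no duplication signal.
    """
    if not gene_trees:
        raise ValueError("need at least one gene tree")
    results = []
    for hyp in hypotheses:
        total_d = total_l = 0
        per_tree = []
        non_opt = False
        for gt in gene_trees:
            r = reconcile(gt, hyp, dup_cost=dup_cost, loss_cost=loss_cost)
            total_d += r.duplications
            total_l += r.losses
            non_opt = non_opt or r.non_optimal
            per_tree.append((r.duplications, r.losses))
        results.append(
            ReconciliationResult(
                hypothesis_id=hyp.hypothesis_id,
                hypothesis=hyp,
                duplications=total_d,
                losses=total_l,
                score=total_d * dup_cost + total_l * loss_cost,
                per_tree=per_tree,
                non_optimal=non_opt,
            )
        )
    # On ties prefer the hypothesis assuming fewer WGDs (baseline first);
    # remaining ties are reported on the winner, not broken silently.
    results.sort(
        key=lambda r: (r.score, 0 if r.hypothesis.is_baseline else 1, r.hypothesis_id)
    )
    best = results[0]
    best.tied_with = [
        r.hypothesis_id for r in results[1:] if r.score == best.score
    ]
    return results
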