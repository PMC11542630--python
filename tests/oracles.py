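"""Independent brute-force oracles used to check the package's algorithms.

Everything here is deliberately written from first principles (explicit
enumeration, nested-tuple trees, Biopython translation) and shares no code
with the implementation under test.
"""

from __future__ import annotations

import itertools
import math

from Bio.Seq import Seq

BASES = "ACGT"
ALL_CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]


def aa(codon: str) -> str:
    return str(Seq(codon).translate())


SENSE = [c for c in ALL_CODONS if aa(c) != "*"]


# ---------------------------------------------------------------------------
# NG86 per-codon oracle


def oracle_sites(codon: str) -> float:
    """Synonymous sites of one codon: per position, the fraction of the three
    alternative bases whose change keeps the amino acid (stops count as
    nonsynonymous)."""
    syn = 0.0
    for pos in range(3):
        for base in BASES:
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1:]
            if aa(mut) != "*" and aa(mut) == aa(codon):
                syn += 1.0 / 3.0
    return syn


def oracle_differences(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (syn, nonsyn) differences between two sense codons.

    Enumerates every ordering of the differing positions; orderings whose
    intermediate codons include a stop are discarded.  If all orderings are
    blocked, every ordering is used with steps touching a stop counted as
    nonsynonymous.
    """
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return (0.0, 0.0)

    def steps_of(order):
        cur = c1
        steps = []
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            steps.append((cur, nxt))
            cur = nxt
        return steps

    all_orders = list(itertools.permutations(positions))
    valid = []
    for order in all_orders:
        steps = steps_of(order)
        intermediates = [b for (_, b) in steps[:-1]]
        if all(aa(x) != "*" for x in intermediates):
            valid.append(steps)
    fallback = not valid
    if fallback:
        valid = [steps_of(o) for o in all_orders]
    totals = []
    for steps in valid:
        sd = nd = 0.0
        for x, y in steps:
            if aa(x) != "*" and aa(y) != "*" and aa(x) == aa(y):
                sd += 1
            else:
                nd += 1
        totals.append((sd, nd))
    sd = sum(t[0] for t in totals) / len(totals)
    nd = sum(t[1] for t in totals) / len(totals)
    return (sd, nd)


def oracle_ng86(seq1: str, seq2: str) -> dict:
    """Full NG86 on an aligned codon pair (sense codons only)."""
    assert len(seq1) == len(seq2) and len(seq1) % 3 == 0
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq1), 3):
        ca, cb = seq1[i:i + 3], seq2[i:i + 3]
        S += (oracle_sites(ca) + oracle_sites(cb)) / 2
        N += (3 - oracle_sites(ca) + 3 - oracle_sites(cb)) / 2
        sd, nd = oracle_differences(ca, cb)
        Sd += sd
        Nd += nd
    ps = Sd / S
    ks = -0.75 * math.log(1 - 4 * ps / 3) if ps < 0.75 else float("nan")
    return {"S": S, "N": N, "Sd": Sd, "Nd": Nd, "ps": ps, "ks": ks}


# ---------------------------------------------------------------------------
# Counting rooted binary labelled topologies


def double_factorial_count(n_leaves: int) -> int:
    """(2n-3)!! rooted binary labelled topologies on n leaves."""
    out = 1
    for k in range(2 * n_leaves - 3, 0, -2):
        out *= k
    return out


# ---------------------------------------------------------------------------
# Duplication-loss reconciliation oracle (nested-tuple trees)
#
# Hypothesis trees use *distinct leaf ids* (species, instance) so MUL trees
# are ordinary trees; gene-tree leaves carry a species plus the list of
# hypothesis leaf ids they may map to.


def _index_tree(nested):
    """Flatten a nested-tuple tree into integer-indexed nodes.

    Returns (parent list, depth list, children list, leaf_index: leaf id ->
    node index, postorder).  Leaf ids must be unique.
    """
    parent: list = []
    depth: list = []
    children: list = []
    leaf_index: dict = {}
    post: list = []

    def rec(node, par):
        idx = len(parent)
        parent.append(par)
        depth.append(0 if par is None else depth[par] + 1)
        children.append([])
        if par is not None:
            children[par].append(idx)
        if isinstance(node, tuple):
            for c in node:
                rec(c, idx)
        else:
            assert node not in leaf_index, f"duplicate leaf id {node!r}"
            leaf_index[node] = idx
        post.append(idx)
        return idx

    rec(nested, None)
    return parent, depth, children, leaf_index, post


def oracle_reconcile(gene_tree, hyp_tree, leaf_options) -> tuple[int, int, int]:
    """Minimum (dups, losses, score) over all leaf assignments.

    ``gene_tree``: nested tuple whose leaves are gene-leaf names (unique).
    ``hyp_tree``: nested tuple whose leaves are unique hypothesis leaf ids.
    ``leaf_options``: gene leaf name -> list of hypothesis leaf ids.
    """
    h_parent, h_depth, _, h_leaf, _ = _index_tree(hyp_tree)

    def lca(a, b):
        while h_depth[a] > h_depth[b]:
            a = h_parent[a]
        while h_depth[b] > h_depth[a]:
            b = h_parent[b]
        while a != b:
            a, b = h_parent[a], h_parent[b]
        return a

    g_parent, _, g_children, g_leaf, g_post = _index_tree(gene_tree)
    gene_leaves = sorted(g_leaf)
    option_lists = [leaf_options[g] for g in gene_leaves]
    best = None
    for combo in itertools.product(*option_lists):
        assigned = {g_leaf[g]: h_leaf[h] for g, h in zip(gene_leaves, combo)}
        M: dict = dict(assigned)
        dups = losses = 0
        for idx in g_post:
            kids = g_children[idx]
            if not kids:
                continue
            m = M[kids[0]]
            for k in kids[1:]:
                m = lca(m, M[k])
            M[idx] = m
            is_dup = any(M[k] == m for k in kids)
            if is_dup:
                dups += 1
            for k in kids:
                d = h_depth[M[k]] - h_depth[m]
                losses += max(0, d - 1 + (1 if is_dup else 0))
        score = dups + losses
        if best is None or score < best[2]:
            best = (dups, losses, score)
    return best


# ---------------------------------------------------------------------------
# Exact Wilcoxon signed-rank (sign-pattern enumeration, small n, no ties)


def oracle_wilcoxon_exact_p(diffs) -> float:
    """Two-sided exact p-value by enumerating all 2^n sign patterns."""
    import numpy as np

    d = [x for x in diffs if x != 0]
    n = len(d)
    ranks = {}
    order = sorted(range(n), key=lambda i: abs(d[i]))
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    w_obs = sum(ranks[i] for i in range(n) if d[i] > 0)
    mean = n * (n + 1) / 4
    stat_obs = abs(w_obs - mean)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(ranks[i] for i in range(n) if signs[i])
        if abs(w - mean) >= stat_obs - 1e-12:
            count += 1
    return count / 2**n
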