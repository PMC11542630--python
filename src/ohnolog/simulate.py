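"""Ground-truth simulator for polyploidization scenarios.

Generates time-calibrated species histories carrying whole-genome
duplication (WGD) events, per-family gene trees that follow the history
deterministically (plus configurable topological noise), and codon
alignments whose synonymous divergence is calibrated to the molecular clock
E[Ks] = 2·r·T under the same NG86 site accounting the estimator uses.

Scenario semantics
------------------
* An *auto* event on a lineage duplicates every gene lineage passing through
  that edge at the event time; both subgenome copies stay on the lineage.
* An *allo* event grafts the second copy of the recipient clade's subtree
  onto the donor lineage at the event time (hybrid origin of subgenome 2);
  the ohnolog coalescence is then the divergence of the two parental
  lineages, which predates the hybridization itself — the reason Ks-based
  dating of allopolyploids reflects parental divergence, not WGD age.
* A *shared* event sits on the stem edge of a multi-species clade (the WGD
  precedes the splits inside the clade); an *independent* event sits on a
  terminal branch.

Topological noise is one random NNI per family with probability ``q`` plus
independent loss of each ohnolog copy with probability ``loss_prob`` —
direct dials for the rate of minority/AMBIGUOUS topologies downstream.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Iterable

import numpy as np

from .inference import MitoDivergence
from .ks import DEFAULT_RATE, SENSE_CODONS, STOP_CODONS, _AA, _site_table
from .trees import GeneTree, SpeciesTree, read_newick

__all__ = [
    "WGDEvent",
    "SimScenario",
    "SimHistory",
    "SimulatedDataset",
    "simulate_history",
    "simulate_gene_trees",
    "simulate_codon_sequences",
    "emit_mito_times",
    "simulate_dataset",
    "canonical_scenarios",
]


class ScenarioError(ValueError):
    """Inconsistent simulation scenario."""


# ---------------------------------------------------------------------------
# Scenario description


@dataclass(frozen=True)
class WGDEvent:
    """One polyploidization event.

    ``species`` is the affected clade (one species = independent event,
    several = shared event on their stem); ``time`` is the event age in Mya;
    ``mode`` is ``"auto"`` or ``"allo"``; allo events name the sampled
    ``donor`` species whose lineage contributed the second subgenome.
    """

    species: tuple[str, ...]
    time: float
    mode: str = "auto"
    donor: str | None = None

    def __post_init__(self):
        if self.mode not in {"auto", "allo"}:
            raise ScenarioError(f"mode must be auto/allo, got {self.mode!r}")
        if self.mode == "allo" and self.donor is None:
            raise ScenarioError("allo events need a donor lineage")
        if self.donor is not None and self.donor in self.species:
            raise ScenarioError("donor cannot belong to the recipient clade")
        if self.time <= 0:
            raise ScenarioError(f"WGD time must be positive, got {self.time}")

    @property
    def sharing(self) -> str:
        return "shared" if len(self.species) > 1 else "independent"


# topology node: either a species name (str) or (left, right, age_in_mya)
Topology = tuple


@dataclass
class SimScenario:
    """Full description of one simulated study condition."""

    name: str
    topology: Topology
    events: tuple[WGDEvent, ...]
    outgroup: str | None = "OUT"
    r: float = DEFAULT_RATE
    n_families: int = 500
    n_codons: int = 2000
    q: float = 0.05  # per-family probability of one random NNI
    loss_prob: float = 0.05  # per-ohnolog-copy loss probability
    nonsyn_ratio: float = 0.2
    mito_ci_half_width: float = 2.0

    def __post_init__(self):
        self.events = tuple(self.events)
        if not 0 <= self.q < 1 or not 0 <= self.loss_prob < 1:
            raise ScenarioError("q and loss_prob must lie in [0, 1)")
        seen: set[str] = set()
        for ev in self.events:
            overlap = seen & set(ev.species)
            if overlap:
                raise ScenarioError(f"species in multiple WGD events: {sorted(overlap)}")
            seen.update(ev.species)

    @property
    def polyploid_species(self) -> set[str]:
        return {s for ev in self.events for s in ev.species}

    def truth(self) -> dict:
        """Ground-truth record for test harnesses (JSON-serialisable)."""
        hist = simulate_history(self)
        return {
            "name": self.name,
            "events": [
                {
                    "species": list(ev.species),
                    "time_mya": ev.time,
                    "sharing": ev.sharing,
                    "mode": ev.mode,
                    "donor": ev.donor,
                }
                for ev in self.events
            ],
            "n_events": len(self.events),
            "expected_ohnolog_divergence_mya": hist.expected_ohnolog_divergence(),
            "r": self.r,
        }


# ---------------------------------------------------------------------------
# Species history


class _Node:
    """Mutable aged tree node used during simulation."""

    __slots__ = ("age", "children", "parent", "species", "copy_tag", "label")

    def __init__(self, age=0.0, species=None):
        self.age = age
        self.children: list["_Node"] = []
        self.parent: "_Node" | None = None
        self.species = species
        self.copy_tag = False  # True on leaves of a duplicated subtree
        self.label: str | None = None

    def add(self, child: "_Node") -> "_Node":
        child.parent = self
        self.children.append(child)
        return child

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["_Node"]:
        if self.is_leaf():
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


def _build_nodes(topology: Topology) -> _Node:
    if isinstance(topology, str):
        return _Node(age=0.0, species=topology)
    if len(topology) != 3:
        raise ScenarioError(
            f"topology nodes must be (left, right, age) or a species name: {topology!r}"
        )
    left, right, age = topology
    node = _Node(age=float(age))
    node.add(_build_nodes(left))
    node.add(_build_nodes(right))
    for c in node.children:
        if c.age >= node.age:
            raise ScenarioError(
                f"node age {node.age} must exceed child age {c.age}"
            )
    return node


def _mrca(root: _Node, species: Iterable[str]) -> _Node:
    wanted = set(species)
    best = None
    for node in root.walk():
        leaves = {l.species for l in node.leaves()}
        if wanted <= leaves and (best is None or node.age < best.age):
            best = node
    if best is None:
        missing = wanted - {l.species for l in root.leaves()}
        raise ScenarioError(f"species not in topology: {sorted(missing)}")
    return best


@dataclass
class SimHistory:
    """Validated, time-calibrated species history with WGD annotations."""

    scenario: SimScenario
    root: _Node  # species topology with ages
    species_tree: SpeciesTree

    def species(self) -> list[str]:
        return sorted(l.species for l in self.root.leaves())

    def split_time(self, a: str, b: str) -> float:
        return _mrca(self.root, (a, b)).age

    def expected_ohnolog_divergence(self) -> dict[str, float]:
        """Expected ohnolog coalescence per polyploid species (Mya).

        Equals the WGD time for autopolyploids and the divergence of the two
        parental lineages for allopolyploids.
        """
        out: dict[str, float] = {}
        for ev in self.scenario.events:
            if ev.mode == "auto":
                t = ev.time
            else:
                anchor = ev.species[0]
                t = self.split_time(anchor, ev.donor)
            for sp in ev.species:
                out[sp] = t
        return out


def simulate_history(scenario: SimScenario) -> SimHistory:
    """Build and validate the time-calibrated species tree with its events.

    Each event must sit on the stem edge of the MRCA of its species set:
    crown age < event time < stem-parent age.  Allo events additionally need
    the donor lineage to be distinct from the recipient lineage at the event
    time (event time < recipient–donor divergence).
    """
    root = _build_nodes(scenario.topology)
    all_species = [l.species for l in root.leaves()]
    if len(set(all_species)) != len(all_species):
        raise ScenarioError("duplicate species in topology")
    for ev in scenario.events:
        node = _mrca(root, ev.species)
        if {l.species for l in node.leaves()} != set(ev.species):
            raise ScenarioError(
                f"event species {sorted(ev.species)} do not form a clade"
            )
        crown = node.age
        parent_age = node.parent.age if node.parent else float("inf")
        if not crown < ev.time < parent_age:
            raise ScenarioError(
                f"event time {ev.time} Mya outside the stem edge of "
                f"{sorted(ev.species)} (crown {crown}, stem parent {parent_age})"
            )
        if ev.mode == "allo":
            div = _mrca(root, (*ev.species, ev.donor)).age
            if ev.time >= div:
                raise ScenarioError(
                    f"allo event at {ev.time} Mya is not younger than the "
                    f"recipient–donor divergence at {div} Mya"
                )
    newick = _nodes_to_newick(root) + ";"
    stree = read_newick(newick, kind="species")
    ages = {
        frozenset(l.species for l in node.leaves()): node.age
        for node in root.walk()
        if not node.is_leaf()
    }
    stree.set_ages(ages)
    return SimHistory(scenario=scenario, root=root, species_tree=stree)


def _nodes_to_newick(node: _Node, parent_age: float | None = None) -> str:
    if node.is_leaf():
        body = node.label or node.species
    else:
        body = "(" + ",".join(_nodes_to_newick(c, node.age) for c in node.children) + ")"
    if parent_age is None:
        return body
    return f"{body}:{parent_age - node.age:.8g}"


# ---------------------------------------------------------------------------
# Gene trees


def _base_gene_tree(history: SimHistory) -> _Node:
    """Noise-free family tree: the species history with WGD copies grafted."""
    root = copy.deepcopy(history.root)

    def ancestral_edge_node(species: str, t: float) -> _Node:
        """The node whose parent edge spans age t on the (primary) lineage of
        ``species``."""
        node = next(
            l for l in root.leaves() if l.species == species and not l.copy_tag
        )
        while node.parent is not None and node.parent.age <= t:
            node = node.parent
        if node.age > t:
            raise ScenarioError(
                f"no edge spans {t} Mya on the lineage of {species}"
            )
        return node

    for ev in sorted(history.scenario.events, key=lambda e: e.time):
        # Subtree to duplicate: the recipient clade's gene lineage at ev.time.
        sub_top = ancestral_edge_node(ev.species[0], ev.time)
        dup = copy.deepcopy(sub_top)
        for leaf in dup.leaves():
            leaf.copy_tag = True
        if ev.mode == "auto":
            parent = sub_top.parent
            wgd = _Node(age=ev.time)
            if parent is None:
                wgd.add(sub_top)
                wgd.add(dup)
                root = wgd
            else:
                parent.children[parent.children.index(sub_top)] = wgd
                wgd.parent = parent
                wgd.add(sub_top)
                wgd.add(dup)
        else:
            target = ancestral_edge_node(ev.donor, ev.time)
            parent = target.parent
            hyb = _Node(age=ev.time)
            if parent is None:
                hyb.add(target)
                hyb.add(dup)
                root = hyb
            else:
                parent.children[parent.children.index(target)] = hyb
                hyb.parent = parent
                hyb.add(target)
                hyb.add(dup)

    # Label leaves: polyploid species carry copy indices 1 (primary) / 2.
    per_species: dict[str, list[_Node]] = {}
    for leaf in root.leaves():
        per_species.setdefault(leaf.species, []).append(leaf)
    for sp, leaves in per_species.items():
        if len(leaves) == 1:
            leaves[0].label = sp
        else:
            leaves.sort(key=lambda l: l.copy_tag)
            for i, leaf in enumerate(leaves, start=1):
                leaf.label = f"{sp}_{i}"
    return root


def _apply_nni(root: _Node, rng: np.random.Generator) -> None:
    """One random nearest-neighbour interchange on an internal edge."""
    candidates = [
        n for n in root.walk() if n.parent is not None and not n.is_leaf()
    ]
    if not candidates:
        return
    v = candidates[rng.integers(len(candidates))]
    u = v.parent
    sibs = [c for c in u.children if c is not v]
    if not sibs:
        return
    s = sibs[rng.integers(len(sibs))]
    c = v.children[rng.integers(len(v.children))]
    # Swap s and c across the (u, v) edge.
    u.children[u.children.index(s)] = c
    v.children[v.children.index(c)] = s
    c.parent, s.parent = u, v
    top = max(k.age for k in v.children)
    if v.age <= top:
        v.age = (u.age + top) / 2.0


def _apply_loss(root: _Node, loss_prob: float, rng: np.random.Generator) -> _Node:
    copies = [l for l in root.leaves() if l.label and "_" in l.label]
    doomed = [l for l in copies if rng.random() < loss_prob]
    if len(root.leaves()) - len(doomed) < 2:
        return root
    for leaf in doomed:
        parent = leaf.parent
        parent.children.remove(leaf)
        node = parent
        # Splice out unary nodes created by the removal.
        while node is not None and len(node.children) == 1:
            only = node.children[0]
            if node.parent is None:
                only.parent = None
                root = only
                node = None
            else:
                gp = node.parent
                gp.children[gp.children.index(node)] = only
                only.parent = gp
                node = gp if len(gp.children) == 1 else None
    return root


def _to_gene_tree(root: _Node, r: float) -> GeneTree:
    """Render an aged family tree as a GeneTree with Ks-unit branch lengths."""

    def rec(node: _Node, parent_age: float | None) -> str:
        if node.is_leaf():
            body = node.label or node.species
        else:
            body = "(" + ",".join(rec(c, node.age) for c in node.children) + ")"
        if parent_age is None:
            return body
        return f"{body}:{r * (parent_age - node.age) * 1e6:.10g}"

    return read_newick(rec(root, None) + ";", kind="gene", allow_multifurcations=True)


def simulate_gene_trees(
    history: SimHistory,
    n: int | None = None,
    q: float | None = None,
    loss_prob: float | None = None,
    seed: int = 0,
) -> list[GeneTree]:
    """Per-family gene trees following the history, with NNI/loss noise.

    Branch lengths are expected synonymous substitutions per synonymous site
    (r × branch duration).  Reproducible from (scenario, seed).
    """
    sc = history.scenario
    n = sc.n_families if n is None else n
    q = sc.q if q is None else q
    loss_prob = sc.loss_prob if loss_prob is None else loss_prob
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    base = _base_gene_tree(history)
    trees: list[GeneTree] = []
    for _ in range(n):
        fam = copy.deepcopy(base)
        if q and rng.random() < q:
            _apply_nni(fam, rng)
        if loss_prob:
            fam = _apply_loss(fam, loss_prob, rng)
        trees.append(_to_gene_tree(fam, sc.r))
    return trees


# ---------------------------------------------------------------------------
# Codon sequences


@lru_cache(maxsize=1)
def _sim_tables():
    codon_index = {c: i for i, c in enumerate(SENSE_CODONS)}
    sites = _site_table()
    s_arr = np.array([sites[c][0] for c in SENSE_CODONS])
    n_arr = np.array([sites[c][1] for c in SENSE_CODONS])
    syn_nb: list[list[int]] = []
    non_nb: list[list[int]] = []
    for c in SENSE_CODONS:
        syn, non = [], []
        for pos in range(3):
            for base in "ACGT":
                if base == c[pos]:
                    continue
                alt = c[:pos] + base + c[pos + 1:]
                if alt in STOP_CODONS:
                    continue
                (syn if _AA[alt] == _AA[c] else non).append(codon_index[alt])
        syn_nb.append(syn)
        non_nb.append(non)
    return codon_index, s_arr, n_arr, syn_nb, non_nb


def simulate_codon_sequences(
    tree: GeneTree,
    length: int,
    r: float = DEFAULT_RATE,
    seed: int = 0,
    nonsyn_ratio: float = 0.2,
) -> dict[str, str]:
    """Evolve an in-frame codon alignment along a gene tree.

    Branch lengths of ``tree`` are read as expected synonymous substitutions
    per synonymous site (i.e. r × years).  Along each branch, synonymous
    events arrive per codon as a Poisson count with mean = branch length ×
    that codon's NG86 synonymous site count, and nonsynonymous events at
    ``nonsyn_ratio`` times the equivalent nonsynonymous rate; each event
    substitutes a random single-nucleotide neighbour of the matching class
    (never a stop codon).  No indels — the output is aligned by construction.
    """
    if length <= 0:
        raise ValueError(f"length must be positive, got {length}")
    _, s_arr, n_arr, syn_nb, non_nb = _sim_tables()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 211]))
    root_seq = rng.integers(0, len(SENSE_CODONS), size=length)
    out: dict[str, str] = {}

    def evolve(seq: np.ndarray, branch: float) -> np.ndarray:
        seq = seq.copy()
        if branch > 0:
            k_syn = rng.poisson(branch * s_arr[seq])
            k_non = rng.poisson(nonsyn_ratio * branch * n_arr[seq])
            hits = np.nonzero(k_syn + k_non)[0]
            for i in hits:
                cur = int(seq[i])
                for _ in range(int(k_syn[i])):
                    nb = syn_nb[cur]
                    if nb:
                        cur = nb[rng.integers(len(nb))]
                for _ in range(int(k_non[i])):
                    nb = non_nb[cur]
                    if nb:
                        cur = nb[rng.integers(len(nb))]
                seq[i] = cur
        return seq

    def rec(node, seq):
        for child in node.child_nodes():
            b = child.edge.length or 0.0
            cseq = evolve(seq, b)
            if child.is_leaf():
                out[child.taxon.label] = "".join(SENSE_CODONS[i] for i in cseq)
            else:
                rec(child, cseq)

    rec(tree.tree.seed_node, root_seq)
    return out


# ---------------------------------------------------------------------------
# Mito table and bundled dataset


def emit_mito_times(
    history: SimHistory, ci_half_width: float | None = None
) -> list[MitoDivergence]:
    """True pairwise split times with symmetric 95% intervals."""
    h = (
        history.scenario.mito_ci_half_width
        if ci_half_width is None
        else ci_half_width
    )
    if h < 0:
        raise ValueError(f"CI half-width must be non-negative, got {h}")
    rows = []
    for a, b in combinations(history.species(), 2):
        t = history.split_time(a, b)
        rows.append(
            MitoDivergence(pair=(a, b), T_mt=t, low=max(0.0, t - h), high=t + h)
        )
    return rows


@dataclass
class SimulatedDataset:
    """Everything one simulated study condition produces."""

    scenario: SimScenario
    history: SimHistory
    gene_trees: list[GeneTree]
    alignments: list[dict[str, str]]  # per family: leaf label -> CDS
    mito: list[MitoDivergence]
    truth: dict
    seed: int


def simulate_dataset(scenario: SimScenario, seed: int = 0) -> SimulatedDataset:
    """Simulate gene trees + alignments + mito table for a scenario."""
    history = simulate_history(scenario)
    trees = simulate_gene_trees(history, seed=seed)
    seq_seeds = np.random.SeedSequence([seed, 307]).generate_state(len(trees))
    alignments = [
        simulate_codon_sequences(
            t,
            scenario.n_codons,
            r=scenario.r,
            seed=int(s) % 2**31,
            nonsyn_ratio=scenario.nonsyn_ratio,
        )
        for t, s in zip(trees, seq_seeds)
    ]
    return SimulatedDataset(
        scenario=scenario,
        history=history,
        gene_trees=trees,
        alignments=alignments,
        mito=emit_mito_times(history),
        truth=scenario.truth(),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Canonical study conditions


def canonical_scenarios(
    n_families: int = 500, q: float = 0.05, loss_prob: float = 0.05
) -> dict[str, SimScenario]:
    """The four canonical WGD scenarios used throughout validation.

    Split times and WGD ages follow the magnitudes reported for Pleistocene
    polyploid lineages: deep matrilineal splits near 9 Mya with tip WGDs near
    1 Mya for the independent cases, and a shared WGD at 2 Mya predating a
    0.16-Mya split for the shared cases.  Allo scenarios sample each donor
    lineage explicitly (with an unsampled or shared donor the independent
    case is unidentifiable).
    """
    mk = lambda **kw: SimScenario(
        n_families=n_families, q=q, loss_prob=loss_prob, **kw
    )
    return {
        "independent-auto": mk(
            name="independent-auto",
            topology=((("PA", "PB", 9.02), "DIP", 12.0), "OUT", 25.0),
            events=(
                WGDEvent(species=("PA",), time=0.93, mode="auto"),
                WGDEvent(species=("PB",), time=1.45, mode="auto"),
            ),
            mito_ci_half_width=2.0,
        ),
        "shared-auto": mk(
            name="shared-auto",
            topology=((("PA", "PB", 0.16), "DIP", 5.0), "OUT", 25.0),
            events=(WGDEvent(species=("PA", "PB"), time=2.0, mode="auto"),),
            mito_ci_half_width=0.05,
        ),
        "independent-allo": mk(
            name="independent-allo",
            topology=(
                (("PA", "DA", 3.0), ("PB", "DB", 4.0), 9.02),
                "OUT",
                25.0,
            ),
            events=(
                WGDEvent(species=("PA",), time=1.0, mode="allo", donor="DA"),
                WGDEvent(species=("PB",), time=1.4, mode="allo", donor="DB"),
            ),
            mito_ci_half_width=2.0,
        ),
        "shared-allo": mk(
            name="shared-allo",
            topology=((("PA", "PB", 0.16), "DIP", 5.0), "OUT", 25.0),
            events=(
                WGDEvent(species=("PA", "PB"), time=2.0, mode="allo", donor="DIP"),
            ),
            mito_ci_half_width=0.05,
        ),
    }
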