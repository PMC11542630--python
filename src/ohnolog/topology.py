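"""Ohnolog genealogy topology classification (T1–T6, IP/SP) and tallying.

For two tetraploid species A and B, an orthologous family carries four gene
copies A1, A2, B1, B2.  There are (2·4−3)!! = 15 rooted binary labelled
topologies on those four leaves; ignoring copy identity and keeping only the
species labels collapses them into six classes, T1–T6.  Classes in which some
species' two copies form a cherry support independent polyploidization (IP:
each genome doubled after the species split); classes in which copies pair
across species support shared polyploidization (SP: one doubling in the
common ancestor).

For three tetraploids (six leaves) the same logic gives the triplet
predicates: IP when every species' copy pair is a cherry, SP when the root
splits the tree into two clades each holding exactly one copy of every
species, AMBIGUOUS otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .trees import GeneTree, TreeError, parse_leaf_label

__all__ = [
    "TopologyClass",
    "TopologyTally",
    "enumerate_rooted_topologies",
    "collapse_to_species_classes",
    "classify_pair_tree",
    "classify_triplet_tree",
    "tally_and_decide",
    "PAIR_CLASSES",
    "AMBIGUOUS",
]

AMBIGUOUS = "AMBIGUOUS"

# ---------------------------------------------------------------------------
# Topology enumeration


def enumerate_rooted_topologies(labels: int | Sequence[str]) -> list[tuple]:
    """All distinct rooted binary labelled topologies on the given leaves.

    ``labels`` may be a leaf count (labels are then ``L1..Ln``) or an explicit
    label sequence.  Topologies are returned as canonical nested tuples
    (leaves as strings, internal nodes as sorted 2-tuples); their number is
    (2n−3)!!.  Bounded at 2 ≤ n ≤ 8 — the enumeration is exhaustive.
    """
    if isinstance(labels, int):
        labels = [f"L{i + 1}" for i in range(labels)]
    labels = list(labels)
    n = len(labels)
    if not 2 <= n <= 8:
        raise ValueError(f"leaf count must be in [2, 8], got {n}")

    def insert_everywhere(shape, leaf):
        """Yield every topology obtained by attaching ``leaf`` on an edge of
        ``shape``, including the root edge."""
        yield _norm((shape, leaf))
        if isinstance(shape, tuple):
            a, b = shape
            for sub in insert_everywhere(a, leaf):
                yield _norm((sub, b))
            for sub in insert_everywhere(b, leaf):
                yield _norm((a, sub))

    shapes = [labels[0]]
    for leaf in labels[1:]:
        nxt = set()
        for s in shapes:
            nxt.update(insert_everywhere(s, leaf))
        shapes = sorted(nxt, key=repr)
    return [s if isinstance(s, tuple) else (s,) for s in shapes]


def _norm(shape):
    """Canonicalise a nested-tuple topology (sort children recursively)."""
    if isinstance(shape, str):
        return shape
    kids = tuple(sorted((_norm(k) for k in shape), key=repr))
    return kids


def species_shape(shape, species_of_leaf: Mapping[str, str]):
    """Collapse a labelled topology to its species-labelled canonical form."""
    if isinstance(shape, str):
        return ("L", species_of_leaf[shape])
    return ("I", tuple(sorted((species_shape(k, species_of_leaf) for k in shape), key=repr)))


# ---------------------------------------------------------------------------
# The six AABB classes

def _pair_shape(nested):
    """Build the canonical species shape of a nested (A/B) description."""
    if isinstance(nested, str):
        return ("L", nested)
    return ("I", tuple(sorted((_pair_shape(k) for k in nested), key=repr)))


# Canonical ordering follows the convention that within-species grouping
# (IP evidence) comes first: T1 balanced IP, T2/T3 the IP caterpillars,
# T4 balanced SP, T5/T6 the SP caterpillars.
_PAIR_DEFS = [
    ("T1", (("A", "A"), ("B", "B")), "IP"),
    ("T2", ((("A", "A"), "B"), "B"), "IP"),
    ("T3", ((("B", "B"), "A"), "A"), "IP"),
    ("T4", (("A", "B"), ("A", "B")), "SP"),
    ("T5", ((("A", "B"), "A"), "B"), "SP"),
    ("T6", ((("A", "B"), "B"), "A"), "SP"),
]


@dataclass(frozen=True)
class TopologyClass:
    """One of the six species-labelled quartet classes (or AMBIGUOUS)."""

    label: str
    mode: str  # "IP" | "SP" | "AMBIGUOUS"
    shape: tuple | None = None

    def __str__(self) -> str:
        return self.label


PAIR_CLASSES: dict[tuple, TopologyClass] = {
    _pair_shape(nested): TopologyClass(label, mode, _pair_shape(nested))
    for label, nested, mode in _PAIR_DEFS
}
AMBIGUOUS_CLASS = TopologyClass(AMBIGUOUS, AMBIGUOUS, None)


def collapse_to_species_classes(
    topologies: Iterable[tuple],
    species_of_leaf: Mapping[str, str],
) -> list[TopologyClass]:
    """Group labelled topologies into species-labelled classes.

    For the two-tetraploid labelling (two leaves per species, two species)
    the 15 labelled topologies collapse to exactly the six classes T1–T6;
    each class carries its IP/SP mode.  The generic species-shape grouping is
    performed first and then matched against the canonical class table.
    """
    species = sorted(set(species_of_leaf.values()))
    counts: dict[str, int] = {s: 0 for s in species}
    for sp in species_of_leaf.values():
        counts[sp] += 1
    if len(species) != 2 or any(c != 2 for c in counts.values()):
        raise TreeError(
            "species-class collapse is defined for two species with two copies "
            f"each; got {counts}"
        )
    rename = {species[0]: "A", species[1]: "B"}
    seen: dict[tuple, TopologyClass] = {}
    for topo in topologies:
        key = species_shape(
            topo if len(topo) != 1 else topo[0],
            {leaf: rename[sp] for leaf, sp in species_of_leaf.items()},
        )
        if key not in PAIR_CLASSES:
            raise TreeError(f"non-binary or unexpected species shape: {key}")
        seen[key] = PAIR_CLASSES[key]
    return sorted(seen.values(), key=lambda c: c.label)


# ---------------------------------------------------------------------------
# Classification of individual gene trees


def _tree_species_shape(tree: GeneTree, rename: Mapping[str, str]):
    def rec(node):
        if node.is_leaf():
            sp = parse_leaf_label(node.taxon.label, tree.sep).species
            return ("L", rename[sp])
        return ("I", tuple(sorted((rec(c) for c in node.child_nodes()), key=repr)))

    return rec(tree.tree.seed_node)


def classify_pair_tree(
    tree: GeneTree,
    species_pair: Sequence[str] | None = None,
) -> TopologyClass:
    """Classify a 4-leaf ohnolog quartet tree into T1–T6 (or AMBIGUOUS).

    The tree must carry exactly two copies for each of exactly two species
    (outgroup already pruned).  ``species_pair`` fixes which species plays
    the role of A (first) and B (second); by default species are taken in
    sorted order.  Multifurcating trees are routed to AMBIGUOUS.
    """
    counts = tree.copies_per_species()
    if species_pair is None:
        species_pair = sorted(counts)
    species_pair = list(species_pair)
    if sorted(counts) != sorted(species_pair) or len(species_pair) != 2:
        raise TreeError(
            f"expected the two species {species_pair}, got leaves for {sorted(counts)}"
        )
    if any(counts[s] != 2 for s in species_pair):
        raise TreeError(f"expected exactly two copies per species, got {counts}")
    if not tree.is_binary:
        return AMBIGUOUS_CLASS
    rename = {species_pair[0]: "A", species_pair[1]: "B"}
    key = _tree_species_shape(tree, rename)
    try:
        return PAIR_CLASSES[key]
    except KeyError:  # pragma: no cover - unreachable for valid binary input
        raise TreeError(f"unclassifiable species shape {key}")


def classify_triplet_tree(tree: GeneTree) -> str:
    """Classify a 6-leaf three-tetraploid tree as ``"IP"``/``"SP"``/AMBIGUOUS.

    IP requires all three within-species copy pairs to be cherries; SP
    requires the root to split the leaves into two clades each containing
    exactly one copy of every species.
    """
    counts = tree.copies_per_species()
    if len(counts) != 3 or any(c != 2 for c in counts.values()):
        raise TreeError(
            f"triplet classification needs three species with two copies each, got {counts}"
        )
    if not tree.is_binary:
        return AMBIGUOUS

    species = set(counts)

    def leaf_species(node):
        return [
            parse_leaf_label(lf.taxon.label, tree.sep).species
            for lf in node.leaf_iter()
        ]

    # IP: every species' two copies form a cherry.
    cherries = set()
    for node in tree.tree.preorder_internal_node_iter():
        kids = node.child_nodes()
        if len(kids) == 2 and all(k.is_leaf() for k in kids):
            sps = {parse_leaf_label(k.taxon.label, tree.sep).species for k in kids}
            if len(sps) == 1:
                cherries.add(sps.pop())
    if cherries == species:
        return "IP"

    # SP: root children are two one-copy-per-species clades.
    root_kids = tree.tree.seed_node.child_nodes()
    if len(root_kids) == 2:
        sides = [leaf_species(k) for k in root_kids]
        if all(sorted(side) == sorted(species) for side in sides):
            return "SP"

    return AMBIGUOUS


# ---------------------------------------------------------------------------
# Tallying


@dataclass
class TopologyTally:
    """Per-unit (pair or triplet) classification counts and IP/SP decision."""

    unit: str
    counts: dict = field(default_factory=dict)
    n_classified: int = 0
    n_ambiguous: int = 0
    n_excluded: int = 0
    ip_fraction: float = float("nan")
    sp_fraction: float = float("nan")
    decision: str = "ambiguous"
    margin: float = float("nan")

    @property
    def ip_count(self) -> int:
        return sum(
            c for lbl, c in self.counts.items()
            if lbl in {"T1", "T2", "T3", "IP"}
        )

    @property
    def sp_count(self) -> int:
        return sum(
            c for lbl, c in self.counts.items()
            if lbl in {"T4", "T5", "T6", "SP"}
        )


def tally_and_decide(
    classifications: Iterable[TopologyClass | str],
    min_margin: float = 0.10,
    unit: str = "",
    n_excluded: int = 0,
) -> TopologyTally:
    """Count topology classes and decide independent vs shared polyploidy.

    ``classifications`` holds :class:`TopologyClass` objects (pair scheme) or
    plain mode strings (triplet scheme).  AMBIGUOUS entries are counted apart
    and excluded from the fractions.  The decision is ``independent`` when
    IP fraction − SP fraction ≥ ``min_margin``, ``shared`` for the reverse,
    otherwise ``ambiguous``; fractions are over classified families only.
    """
    tally = TopologyTally(unit=unit, n_excluded=n_excluded)
    for cls in classifications:
        label = cls.label if isinstance(cls, TopologyClass) else str(cls)
        mode = cls.mode if isinstance(cls, TopologyClass) else str(cls)
        if mode == AMBIGUOUS:
            tally.n_ambiguous += 1
            continue
        tally.counts[label] = tally.counts.get(label, 0) + 1
        tally.n_classified += 1
    if tally.n_classified == 0:
        raise ValueError("no classified families to tally")
    ip, sp = tally.ip_count, tally.sp_count
    tally.ip_fraction = ip / tally.n_classified
    tally.sp_fraction = sp / tally.n_classified
    tally.margin = tally.ip_fraction - tally.sp_fraction
    if tally.margin >= min_margin:
        tally.decision = "independent"
    elif -tally.margin >= min_margin:
        tally.decision = "shared"
    else:
        tally.decision = "ambiguous"
    return tally
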