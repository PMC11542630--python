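"""Rooted-tree data model, Newick I/O, and basic tree algebra.

Three tree kinds are distinguished:

* :class:`GeneTree` — a rooted gene-family tree whose leaves are gene copies
  labelled ``SPECIES`` or ``SPECIES<sep>copyN`` (e.g. ``PPI_1``, ``PPI_2``),
  optionally carrying an outgroup leaf, branch supports and branch lengths.
* :class:`SpeciesTree` — a rooted binary tree with singly-labelled species
  leaves and optional node ages in Mya.
* :class:`MULTree` — a multi-labelled species tree in which each polyploid
  species appears exactly twice (once per subgenome), used as a reconciliation
  hypothesis.

dendropy does the Newick parsing/serialisation; the classes here add the
label dialect, invariant checks, and the small tree algebra every downstream
stage relies on (outgroup rooting, low-support collapsing, restriction to a
subset of species).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy

__all__ = [
    "TreeError",
    "NewickParseError",
    "LeafInfo",
    "parse_leaf_label",
    "format_leaf_label",
    "GeneTree",
    "SpeciesTree",
    "MULTree",
    "read_newick",
    "write_newick",
    "read_label_map",
    "root_and_prune_outgroup",
    "collapse_low_support",
]

DEFAULT_SEPARATOR = "_"


class TreeError(ValueError):
    """Invalid tree structure or labelling."""


class NewickParseError(TreeError):
    """Malformed Newick input (wraps the parser's position report)."""


@dataclass(frozen=True)
class LeafInfo:
    """Parsed leaf label: species code plus optional 1-based copy index."""

    species: str
    copy: int | None
    raw: str

    @property
    def is_copy(self) -> bool:
        return self.copy is not None


def parse_leaf_label(label: str, sep: str = DEFAULT_SEPARATOR) -> LeafInfo:
    """Split ``SPECIES<sep>copyN`` into its parts; plain labels have no copy.

    The species code is everything before the *last* separator whose suffix is
    an integer, so species codes may themselves contain the separator.
    """
    label = label.strip()
    if not label:
        raise TreeError("empty leaf label")
    if sep in label:
        head, _, tail = label.rpartition(sep)
        if tail.isdigit():
            copy = int(tail)
            if copy < 1:
                raise TreeError(f"copy index must be >= 1 in label {label!r}")
            return LeafInfo(species=head, copy=copy, raw=label)
    return LeafInfo(species=label, copy=None, raw=label)


def format_leaf_label(species: str, copy: int | None, sep: str = DEFAULT_SEPARATOR) -> str:
    return species if copy is None else f"{species}{sep}{copy}"


def _parse_newick(text: str, allow_duplicate_leaves: bool = False) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=allow_duplicate_leaves,
        )
    except Exception as exc:  # dendropy raises several error types with positions
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return tree


def leaf_label(node: dendropy.Node) -> str:
    """Leaf label whether or not the leaf carries a taxon (MUL trees do not)."""
    return node.taxon.label if node.taxon is not None else node.label


def _leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf_label(lf) for lf in tree.leaf_node_iter()]


def _supports(tree: dendropy.Tree) -> None:
    """Interpret numeric internal-node labels as branch supports in [0, 100]."""
    for node in tree.preorder_internal_node_iter():
        node.support = None
        if node.label is not None:
            try:
                node.support = float(node.label)
            except ValueError:
                pass


class _TreeBase:
    """Shared behaviour: Newick serialisation and basic structure queries."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree

    # -- structure ---------------------------------------------------------
    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    @property
    def is_binary(self) -> bool:
        return all(
            len(node.child_nodes()) == 2
            for node in self.tree.preorder_internal_node_iter()
        )

    def leaf_labels(self) -> list[str]:
        return _leaf_labels(self.tree)

    # -- I/O ---------------------------------------------------------------
    def to_newick(self, include_branch_lengths: bool = True) -> str:
        out = self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            suppress_edge_lengths=not include_branch_lengths,
        ).strip()
        return out

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<{type(self).__name__} {self.n_leaves} leaves>"


class GeneTree(_TreeBase):
    """Rooted gene-family tree with ``SPECIES_copyN`` leaves.

    Invariants enforced at construction: unique leaf labels and unique copy
    indices within each species.  Binarity is *queried*, not enforced: trees
    with multifurcations (e.g. produced by :func:`collapse_low_support`) are
    legal objects that classifiers route to the AMBIGUOUS bin, but
    multifurcating *input* is rejected by :func:`read_newick` unless
    explicitly allowed.
    """

    def __init__(self, tree: dendropy.Tree, sep: str = DEFAULT_SEPARATOR):
        super().__init__(tree)
        self.sep = sep
        _supports(tree)
        labels = self.leaf_labels()
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate leaf labels in gene tree: {dupes}")
        seen: dict[tuple[str, int], str] = {}
        for label in labels:
            info = parse_leaf_label(label, sep)
            if info.copy is not None:
                key = (info.species, info.copy)
                if key in seen:
                    raise TreeError(
                        f"duplicate copy index {info.copy} for species {info.species}"
                    )
                seen[key] = label

    # -- label queries -----------------------------------------------------
    def leaf_info(self) -> list[LeafInfo]:
        return [parse_leaf_label(l, self.sep) for l in self.leaf_labels()]

    def species(self) -> set[str]:
        return {i.species for i in self.leaf_info()}

    def copies_per_species(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for info in self.leaf_info():
            counts[info.species] = counts.get(info.species, 0) + 1
        return counts

    # -- algebra -----------------------------------------------------------
    def restrict_to_species(self, species: Iterable[str]) -> "GeneTree":
        """Prune to the leaves whose species code is in ``species``."""
        wanted = set(species)
        keep = [
            lf.taxon.label
            for lf in self.tree.leaf_node_iter()
            if parse_leaf_label(lf.taxon.label, self.sep).species in wanted
        ]
        if not keep:
            raise TreeError(f"no leaves belong to species {sorted(wanted)}")
        sub = self.tree.extract_tree_with_taxa_labels(
            keep, suppress_unifurcations=True
        )
        sub.purge_taxon_namespace()
        return GeneTree(_reparse(sub), sep=self.sep)

    def shape(self) -> tuple:
        """Canonical species-labelled shape (order-invariant nested tuples)."""
        def rec(node):
            if node.is_leaf():
                return ("L", parse_leaf_label(node.taxon.label, self.sep).species)
            return ("I", tuple(sorted(rec(c) for c in node.child_nodes())))

        return rec(self.tree.seed_node)

    def labeled_shape(self) -> tuple:
        """Canonical full-label shape (used for round-trip identities)."""
        def rec(node):
            if node.is_leaf():
                return ("L", node.taxon.label)
            return ("I", tuple(sorted(rec(c) for c in node.child_nodes())))

        return rec(self.tree.seed_node)


def _reparse(tree: dendropy.Tree) -> dendropy.Tree:
    """Round-trip a dendropy tree through Newick to detach shared namespaces."""
    text = tree.as_string(
        schema="newick", suppress_rooting=True, unquoted_underscores=True
    )
    return _parse_newick(text)


class SpeciesTree(_TreeBase):
    """Rooted binary species tree; each species appears exactly once.

    Node ages in Mya may be attached via :meth:`set_ages`; they must decrease
    root -> tip.
    """

    def __init__(self, tree: dendropy.Tree):
        super().__init__(tree)
        labels = self.leaf_labels()
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate species in species tree: {dupes}")
        if not self.is_binary:
            raise TreeError("species tree must be binary")
        for lf in self.tree.leaf_node_iter():
            lf.age_mya = getattr(lf, "age_mya", 0.0)

    def species(self) -> set[str]:
        return set(self.leaf_labels())

    def set_ages(self, ages: Mapping[tuple, float] | None = None) -> None:
        """Attach node ages (Mya) keyed by the frozenset of descendant leaves."""
        if ages is None:
            return
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                node.age_mya = 0.0
                continue
            key = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if key not in ages:
                raise TreeError(f"no age given for clade {sorted(key)}")
            node.age_mya = float(ages[key])
            kid_ages = [getattr(c, "age_mya", 0.0) for c in node.child_nodes()]
            if any(node.age_mya <= a for a in kid_ages if a):
                raise TreeError(
                    f"ages must decrease root->tip (clade {sorted(key)})"
                )

    def restrict(self, species: Iterable[str]) -> "SpeciesTree":
        wanted = set(species)
        missing = wanted - self.species()
        if missing:
            raise TreeError(f"species not in tree: {sorted(missing)}")
        sub = self.tree.extract_tree_with_taxa_labels(
            wanted, suppress_unifurcations=True
        )
        sub.purge_taxon_namespace()
        return SpeciesTree(_reparse(sub))


class MULTree(_TreeBase):
    """Multi-labelled species tree: each polyploid species appears twice.

    ``h1`` and ``h2`` record the two attachment edges of the duplicated
    subtree on the underlying singly-labelled tree, each identified by the
    frozenset of species subtended by the edge's child node ("root" denotes
    the root edge).
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        polyploid_species: Iterable[str] | None = None,
        h1: frozenset | str | None = None,
        h2: frozenset | str | None = None,
        hypothesis_id: str | None = None,
    ):
        super().__init__(tree)
        labels = self.leaf_labels()
        counts = {l: labels.count(l) for l in set(labels)}
        inferred_poly = {l for l, c in counts.items() if c == 2}
        bad = {l: c for l, c in counts.items() if c > 2}
        if bad:
            raise TreeError(f"species appearing more than twice: {bad}")
        if polyploid_species is None:
            self.polyploid_species = inferred_poly
        else:
            self.polyploid_species = set(polyploid_species)
            if self.polyploid_species != inferred_poly:
                raise TreeError(
                    "polyploid species must appear exactly twice; "
                    f"declared {sorted(self.polyploid_species)}, "
                    f"doubled in tree {sorted(inferred_poly)}"
                )
        self.h1 = h1
        self.h2 = h2
        self.hypothesis_id = hypothesis_id

    def to_newick(self, include_branch_lengths: bool = False) -> str:
        # dendropy's writer drops taxon-less leaf labels; write directly.
        def rec(node):
            if node.is_leaf():
                return leaf_label(node)
            return "(" + ",".join(rec(c) for c in node.child_nodes()) + ")"

        return rec(self.tree.seed_node) + ";"

    @property
    def is_auto(self) -> bool | None:
        if self.h1 is None or self.h2 is None:
            return None
        return self.h1 == self.h2


_KINDS = {"gene": GeneTree, "species": SpeciesTree, "mul": MULTree}


def read_newick(
    text: str,
    kind: str = "gene",
    sep: str = DEFAULT_SEPARATOR,
    allow_multifurcations: bool = False,
):
    """Parse a Newick string into the requested tree kind.

    Parameters
    ----------
    text:
        A single Newick tree.
    kind:
        ``"gene"``, ``"species"`` or ``"mul"``.
    sep:
        Separator of the ``SPECIES<sep>copyN`` leaf-label dialect (gene trees).
    allow_multifurcations:
        Gene trees with multifurcations are rejected by default so that
        unresolved input cannot silently manufacture topology signal; when
        allowed, classifiers route such trees to the AMBIGUOUS bin.
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown tree kind {kind!r}; expected one of {sorted(_KINDS)}")
    tree = _parse_newick(text, allow_duplicate_leaves=(kind == "mul"))
    if kind == "gene":
        gt = GeneTree(tree, sep=sep)
        if not allow_multifurcations and not gt.is_binary:
            raise TreeError(
                "multifurcating gene tree rejected (pass allow_multifurcations=True "
                "to route it to the AMBIGUOUS bin instead)"
            )
        return gt
    if kind == "species":
        return SpeciesTree(tree)
    return MULTree(tree)


def write_newick(tree: _TreeBase, include_branch_lengths: bool = True) -> str:
    return tree.to_newick(include_branch_lengths=include_branch_lengths)


def read_label_map(text: str) -> dict[str, str]:
    """Parse a two-column TSV mapping internal species codes to display names."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"label map line {lineno}: expected 2 columns, got {len(parts)}")
        code, name = (p.strip() for p in parts)
        if code in out:
            raise ValueError(f"label map line {lineno}: duplicate code {code!r}")
        out[code] = name
    return out


def root_and_prune_outgroup(
    gtree: GeneTree,
    outgroup_label: str,
    allow_prerooted: bool = False,
) -> GeneTree:
    """Root on the edge leading to the outgroup leaf, then remove that leaf.

    The outgroup may be given either as a full leaf label or as a species
    code; it must correspond to exactly one leaf.  With ``allow_prerooted``,
    a tree lacking the outgroup is returned unchanged (already rooted).
    """
    matches = [
        lf
        for lf in gtree.tree.leaf_node_iter()
        if lf.taxon.label == outgroup_label
        or parse_leaf_label(lf.taxon.label, gtree.sep).species == outgroup_label
    ]
    if not matches:
        if allow_prerooted:
            return gtree
        raise TreeError(f"outgroup {outgroup_label!r} not found in tree")
    if len(matches) > 1:
        raise TreeError(
            f"outgroup {outgroup_label!r} matches {len(matches)} leaves; "
            "must be a single leaf"
        )
    # Work on a copy so the input tree is untouched.
    work = _reparse(gtree.tree)
    out_leaf = next(
        lf
        for lf in work.leaf_node_iter()
        if lf.taxon.label == matches[0].taxon.label
    )
    work.reroot_at_edge(out_leaf.edge, update_bipartitions=False)
    keep = [lf.taxon.label for lf in work.leaf_node_iter() if lf is not out_leaf]
    pruned = work.extract_tree_with_taxa_labels(keep, suppress_unifurcations=True)
    pruned.purge_taxon_namespace()
    return GeneTree(_reparse(pruned), sep=gtree.sep)


def collapse_low_support(gtree: GeneTree, threshold: float) -> GeneTree:
    """Contract internal edges whose support is below ``threshold``.

    Edges without a support value are kept.  The result may be
    multifurcating; classifiers then treat it as AMBIGUOUS.  The leaf set and
    root are never altered, and ``threshold`` must lie in [0, 100].
    """
    if not 0 <= threshold <= 100:
        raise ValueError(f"support threshold must be in [0, 100], got {threshold}")
    work = _reparse(gtree.tree)
    _supports(work)
    if threshold == 0:
        return GeneTree(work, sep=gtree.sep)
    to_collapse = [
        node
        for node in work.preorder_internal_node_iter()
        if node is not work.seed_node
        and node.support is not None
        and node.support < threshold
    ]
    for node in to_collapse:
        node.edge.collapse()
    return GeneTree(work, sep=gtree.sep)
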