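"""Model/Results facade tying the whole inference together.

:class:`PolyploidyHistory` is built from data — per-family gene trees, codon
alignments, a species tree with the polyploid taxa named, and matrilineal
divergence times — and :meth:`PolyploidyHistory.fit` runs the full pipeline:

1. root each family tree on the outgroup and prune it (optionally collapsing
   low-support edges),
2. classify every usable family's ohnolog quartet per polyploid species pair
   into the T1–T6 scheme and tally independent vs shared polyploidization,
3. estimate per-family ohnolog Ks (NG86), locate the Ks density peak per
   species and date it via T = Ks/(2r),
4. rank MUL-tree reconciliation hypotheses (auto vs allo vs no-WGD),
5. order ohnolog divergence against matrilineal divergence per pair, and
6. synthesize everything into a per-lineage WGD event table.

The returned :class:`PolyploidyHistoryResults` carries every intermediate
(tallies, densities, timings, reconciliation rankings, ordering decisions)
plus the final calls, and renders a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import ks as ksmod
from .inference import (
    MitoDivergence,
    OrderingDecision,
    WGDCall,
    order_events,
    synthesize_calls,
)
from .reconcile import Hypothesis, ReconciliationResult, enumerate_hypotheses, rank_hypotheses
from .simulate import SimScenario, SimulatedDataset, simulate_dataset
from .topology import TopologyTally, classify_pair_tree, classify_triplet_tree, tally_and_decide
from .trees import (
    GeneTree,
    SpeciesTree,
    TreeError,
    collapse_low_support,
    parse_leaf_label,
    root_and_prune_outgroup,
)

__all__ = ["PipelineConfig", "PolyploidyHistory", "PolyploidyHistoryResults"]


@dataclass
class PipelineConfig:
    """Tunable thresholds of the inference pipeline."""

    outgroup: str | None = "OUT"
    support_threshold: float = 0.0
    min_margin: float = 0.10
    r: float = ksmod.DEFAULT_RATE
    rel_tol: float = 0.0
    bandwidth: float | str = "auto"
    lattice_bandwidth_mult: float = 1.5
    min_families_for_density: int = 10
    dup_cost: float = 1.0
    loss_cost: float = 1.0
    max_mul_hypotheses: int = 15
    classify_triplets: bool = False


class PolyploidyHistory:
    """Polyploidization-history model over a set of orthologous gene families.

    Parameters
    ----------
    gene_trees:
        Mapping family id -> :class:`GeneTree` (rooted, outgroup included or
        already pruned).
    species_tree:
        Singly-labelled rooted species tree covering every species that
        appears in the gene trees (outgroup optional).
    polyploid_species:
        Species expected to carry two ohnolog copies.
    alignments:
        Mapping family id -> {leaf label -> in-frame CDS}; needed for Ks
        dating and the ortholog-asymmetry test.
    mito:
        Pairwise matrilineal divergence times with 95% intervals.
    conversion_mask:
        Family ids flagged by an external gene-conversion screen; excluded
        from tallies and Ks (counted in the results).
    """

    def __init__(
        self,
        gene_trees: Mapping[str, GeneTree],
        species_tree: SpeciesTree,
        polyploid_species: Iterable[str],
        alignments: Mapping[str, Mapping[str, str]] | None = None,
        mito: Iterable[MitoDivergence] = (),
        conversion_mask: Iterable[str] = (),
        config: PipelineConfig | None = None,
    ):
        self.gene_trees = dict(gene_trees)
        self.species_tree = species_tree
        self.polyploid_species = sorted(polyploid_species)
        self.alignments = dict(alignments or {})
        self.mito = {m.key: m for m in mito}
        self.conversion_mask = set(conversion_mask)
        self.config = config or PipelineConfig()
        unknown = set(self.polyploid_species) - species_tree.species()
        if unknown:
            raise TreeError(f"polyploid species not in species tree: {sorted(unknown)}")

    # ------------------------------------------------------------------
    @classmethod
    def from_simulation(
        cls,
        scenario: SimScenario,
        seed: int = 0,
        config: PipelineConfig | None = None,
    ) -> "PolyploidyHistory":
        """Build the model directly from a simulated dataset."""
        data = simulate_dataset(scenario, seed=seed)
        return cls.from_dataset(data, config=config)

    @classmethod
    def from_dataset(
        cls, data: SimulatedDataset, config: PipelineConfig | None = None
    ) -> "PolyploidyHistory":
        cfg = config or PipelineConfig(outgroup=data.scenario.outgroup)
        ids = [f"fam{i:04d}" for i in range(len(data.gene_trees))]
        model = cls(
            gene_trees=dict(zip(ids, data.gene_trees)),
            species_tree=data.history.species_tree,
            polyploid_species=data.scenario.polyploid_species,
            alignments=dict(zip(ids, data.alignments)),
            mito=data.mito,
            config=cfg,
        )
        model.truth = data.truth
        return model

    # ------------------------------------------------------------------
    def _preprocessed_trees(self) -> dict[str, GeneTree]:
        cfg = self.config
        out: dict[str, GeneTree] = {}
        for fam, tree in self.gene_trees.items():
            if cfg.outgroup and cfg.outgroup in {
                i.species for i in tree.leaf_info()
            }:
                tree = root_and_prune_outgroup(tree, cfg.outgroup)
            if cfg.support_threshold > 0:
                tree = collapse_low_support(tree, cfg.support_threshold)
            out[fam] = tree
        return out

    def _diploid_species(self) -> list[str]:
        cfg = self.config
        return sorted(
            self.species_tree.species()
            - set(self.polyploid_species)
            - ({cfg.outgroup} if cfg.outgroup else set())
        )

    def _analysis_species_tree(self) -> SpeciesTree:
        keep = self.species_tree.species()
        if self.config.outgroup:
            keep = keep - {self.config.outgroup}
        return self.species_tree.restrict(keep)

    # ------------------------------------------------------------------
    def fit(self) -> "PolyploidyHistoryResults":
        cfg = self.config
        trees = self._preprocessed_trees()
        usable = {
            fam: t for fam, t in trees.items() if fam not in self.conversion_mask
        }
        n_masked = len(trees) - len(usable)

        # --- topology tallies per polyploid pair -----------------------
        tallies: dict[frozenset, TopologyTally] = {}
        for a, b in combinations(self.polyploid_species, 2):
            classes = []
            excluded = 0
            for fam, tree in usable.items():
                counts = tree.copies_per_species()
                if counts.get(a) != 2 or counts.get(b) != 2:
                    excluded += 1
                    continue
                classes.append(classify_pair_tree(
                    tree.restrict_to_species([a, b]), species_pair=(a, b)
                ))
            if classes:
                tallies[frozenset((a, b))] = tally_and_decide(
                    classes,
                    min_margin=cfg.min_margin,
                    unit=f"{a}-{b}",
                    n_excluded=excluded + n_masked,
                )

        triplet_tallies: dict[frozenset, TopologyTally] = {}
        if cfg.classify_triplets and len(self.polyploid_species) >= 3:
            for trio in combinations(self.polyploid_species, 3):
                modes = []
                excluded = 0
                for fam, tree in usable.items():
                    counts = tree.copies_per_species()
                    if any(counts.get(s) != 2 for s in trio):
                        excluded += 1
                        continue
                    modes.append(classify_triplet_tree(
                        tree.restrict_to_species(trio)
                    ))
                if any(m != "AMBIGUOUS" for m in modes):
                    triplet_tallies[frozenset(trio)] = tally_and_decide(
                        modes,
                        min_margin=cfg.min_margin,
                        unit="-".join(trio),
                        n_excluded=excluded + n_masked,
                    )

        # --- Ks, density peaks, dating ---------------------------------
        densities: dict[str, ksmod.KsDensity] = {}
        timings: dict[str, ksmod.TimeEstimate] = {}
        ks_records: dict[str, list[ksmod.KsRecord]] = {}
        for sp in self.polyploid_species:
            records = []
            for fam, aln in self.alignments.items():
                if fam in self.conversion_mask:
                    continue
                k1, k2 = f"{sp}_1", f"{sp}_2"
                if k1 in aln and k2 in aln:
                    try:
                        rec = ksmod.pairwise_ks(aln[k1], aln[k2], pair=(k1, k2), family=fam)
                    except ksmod.KsError:
                        continue
                    if rec.valid:
                        records.append(rec)
            ks_records[sp] = records
            if len(records) >= cfg.min_families_for_density:
                floor = ksmod.lattice_bandwidth(
                    [r.S for r in records], mult=cfg.lattice_bandwidth_mult
                )
                dens = ksmod.ks_density(
                    [r.ks for r in records],
                    bandwidth=cfg.bandwidth,
                    min_bandwidth=floor,
                )
                densities[sp] = dens
                timings[sp] = ksmod.ks_to_time(dens.peak, r=cfg.r)

        # --- ortholog asymmetry (diploid reference) ---------------------
        asymmetry: dict[str, ksmod.AsymmetryReport] = {}
        diploids = self._diploid_species()
        for sp in self.polyploid_species:
            ref = self._nearest_diploid(sp, diploids)
            if ref is None:
                continue
            recs = []
            for fam, aln in self.alignments.items():
                k1, k2 = f"{sp}_1", f"{sp}_2"
                if k1 in aln and k2 in aln and ref in aln:
                    try:
                        r1 = ksmod.pairwise_ks(aln[k1], aln[ref])
                        r2 = ksmod.pairwise_ks(aln[k2], aln[ref])
                    except ksmod.KsError:
                        continue
                    if r1.valid and r2.valid:
                        recs.append(
                            ksmod.AsymmetryRecord(family=fam, ks_copy1=r1.ks, ks_copy2=r2.ks)
                        )
            if len(recs) >= 6:
                asymmetry[sp] = ksmod.ortholog_asymmetry_test(recs, "larger-smaller")

        # --- reconciliation ---------------------------------------------
        analysis_tree = self._analysis_species_tree()
        reconciliations: dict[frozenset, list[ReconciliationResult]] = {}
        recon_modes: dict[frozenset, str] = {}
        for sp in self.polyploid_species:
            unit = frozenset((sp,))
            ranked = self._reconcile_unit(usable, analysis_tree, (sp,), diploids)
            if ranked:
                reconciliations[unit] = ranked
                recon_modes[unit] = ranked[0].hypothesis.mode

        # --- ordering ----------------------------------------------------
        orderings: dict[frozenset, OrderingDecision] = {}
        for pair in tallies:
            a, b = sorted(pair)
            if a in timings and b in timings and pair in self.mito:
                orderings[pair] = order_events(
                    timings[a], timings[b], self.mito[pair], rel_tol=cfg.rel_tol
                )

        # --- joint reconciliation for prospective shared groups ----------
        shared_groups = self._shared_groups(tallies, orderings)
        for group in shared_groups:
            unit = frozenset(group)
            ranked = self._reconcile_unit(usable, analysis_tree, group, diploids)
            if ranked:
                reconciliations[unit] = ranked
                recon_modes[unit] = ranked[0].hypothesis.mode

        # --- synthesis ----------------------------------------------------
        calls = synthesize_calls(tallies, orderings, recon_modes, timings, self.mito)

        return PolyploidyHistoryResults(
            model=self,
            tallies=tallies,
            triplet_tallies=triplet_tallies,
            densities=densities,
            timings=timings,
            ks_records=ks_records,
            asymmetry=asymmetry,
            reconciliations=reconciliations,
            reconciliation_modes=recon_modes,
            orderings=orderings,
            calls=calls,
            n_families=len(self.gene_trees),
            n_masked=n_masked,
        )

    # ------------------------------------------------------------------
    def _nearest_diploid(self, sp: str, diploids: Sequence[str]) -> str | None:
        """Diploid sharing the smallest clade with ``sp`` in the species tree."""
        if not diploids:
            return None
        def clade_size(other):
            best = None
            for node in self.species_tree.tree.preorder_node_iter():
                leaves = {l.taxon.label for l in node.leaf_iter()}
                if {sp, other} <= leaves and (best is None or len(leaves) < best):
                    best = len(leaves)
            return best
        return min(diploids, key=lambda d: (clade_size(d), d))

    def _shared_groups(self, tallies, orderings) -> list[tuple[str, ...]]:
        parent = {s: s for s in self.polyploid_species}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for pair, tally in tallies.items():
            ordering = orderings.get(pair)
            sharing = tally.decision
            if ordering is not None and ordering.sharing != sharing:
                continue
            if sharing == "shared":
                a, b = sorted(pair)
                parent[find(a)] = find(b)
        groups: dict[str, list[str]] = {}
        for s in self.polyploid_species:
            groups.setdefault(find(s), []).append(s)
        return [tuple(sorted(g)) for g in groups.values() if len(g) > 1]

    def _reconcile_unit(
        self,
        usable: Mapping[str, GeneTree],
        analysis_tree: SpeciesTree,
        focal: tuple[str, ...],
        diploids: Sequence[str],
    ) -> list[ReconciliationResult] | None:
        cfg = self.config
        keep = set(focal) | set(diploids)
        try:
            stree = analysis_tree.restrict(keep)
            hypotheses = enumerate_hypotheses(
                stree, focal, max_groups=cfg.max_mul_hypotheses
            )
        except (TreeError, ValueError):
            return None
        gene_trees = []
        for fam, tree in usable.items():
            counts = tree.copies_per_species()
            if any(counts.get(s) != 2 for s in focal):
                continue
            present = keep & set(counts)
            if not (present - set(focal)):
                continue  # need at least one diploid leaf to anchor the tree
            try:
                gene_trees.append(tree.restrict_to_species(present))
            except TreeError:
                continue
        if not gene_trees:
            return None
        return rank_hypotheses(
            gene_trees, hypotheses, dup_cost=cfg.dup_cost, loss_cost=cfg.loss_cost
        )


# ---------------------------------------------------------------------------


@dataclass
class PolyploidyHistoryResults:
    """Fitted polyploidization history: evidence tables and final calls."""

    model: PolyploidyHistory
    tallies: dict
    triplet_tallies: dict
    densities: dict
    timings: dict
    ks_records: dict
    asymmetry: dict
    reconciliations: dict
    reconciliation_modes: dict
    orderings: dict
    calls: list
    n_families: int
    n_masked: int

    # -- derived -----------------------------------------------------------
    @property
    def n_events(self) -> int:
        return len(self.calls)

    def events_frame(self) -> pd.DataFrame:
        rows = []
        for call in self.calls:
            rows.append(
                {
                    "species": "+".join(call.species),
                    "sharing": call.sharing,
                    "mode": call.mode,
                    "T_ks_mya": ";".join(
                        f"{call.T_ks[s]:.2f}" for s in call.species if s in call.T_ks
                    ),
                    "T_mt_mya": None if call.T_mt is None else round(call.T_mt, 2),
                    "tally": call.tally_decision,
                    "ordering": call.ordering_decision,
                    "reconciliation": call.reconciliation_mode,
                    "agreement": call.agreement,
                }
            )
        return pd.DataFrame(rows)

    def tally_frame(self) -> pd.DataFrame:
        rows = []
        for pair, t in sorted(self.tallies.items(), key=lambda kv: kv[1].unit):
            row = {"unit": t.unit, "n": t.n_classified}
            for lbl in ("T1", "T2", "T3", "T4", "T5", "T6"):
                row[lbl] = t.counts.get(lbl, 0)
            row.update(
                ip_fraction=round(t.ip_fraction, 4),
                sp_fraction=round(t.sp_fraction, 4),
                ambiguous=t.n_ambiguous,
                excluded=t.n_excluded,
                decision=t.decision,
            )
            rows.append(row)
        return pd.DataFrame(rows)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        lines = []
        w = 78
        lines.append("=" * w)
        lines.append("Polyploidization history inference".center(w))
        lines.append("=" * w)
        lines.append(
            f"families: {self.n_families}   masked (gene conversion): {self.n_masked}   "
            f"polyploid species: {len(self.model.polyploid_species)}"
        )
        lines.append("-" * w)
        lines.append("Ohnolog genealogy tallies (per species pair)")
        hdr = f"{'pair':<14}{'n':>6}{'IP%':>8}{'SP%':>8}{'ambig':>7}  decision"
        lines.append(hdr)
        for pair, t in sorted(self.tallies.items(), key=lambda kv: kv[1].unit):
            lines.append(
                f"{t.unit:<14}{t.n_classified:>6}{100*t.ip_fraction:>8.2f}"
                f"{100*t.sp_fraction:>8.2f}{t.n_ambiguous:>7}  {t.decision}"
            )
        for trio, t in sorted(self.triplet_tallies.items(), key=lambda kv: kv[1].unit):
            lines.append(
                f"{t.unit:<14}{t.n_classified:>6}{100*t.ip_fraction:>8.2f}"
                f"{100*t.sp_fraction:>8.2f}{t.n_ambiguous:>7}  {t.decision} (triplet)"
            )
        lines.append("-" * w)
        lines.append("Ohnolog Ks peaks and divergence dating (T = Ks/2r)")
        lines.append(f"{'species':<12}{'n':>6}{'Ks peak':>12}{'T_Ks (Mya)':>12}")
        for sp in sorted(self.timings):
            d = self.densities[sp]
            t = self.timings[sp]
            lines.append(f"{sp:<12}{d.n:>6}{d.peak:>12.4f}{t.T:>12.2f}")
        if self.asymmetry:
            lines.append("-" * w)
            lines.append("Ortholog-Ks asymmetry (larger vs smaller copy, Wilcoxon)")
            for sp in sorted(self.asymmetry):
                a = self.asymmetry[sp]
                lines.append(
                    f"  {sp:<12} n={a.n_used:<5} medians {a.median_group1:.4f}/"
                    f"{a.median_group2:.4f}  p={a.pvalue:.3g}"
                )
        lines.append("-" * w)
        lines.append("MUL-tree reconciliation (winner per unit)")
        for unit, ranked in sorted(
            self.reconciliations.items(), key=lambda kv: sorted(kv[0])
        ):
            best, runner = ranked[0], (ranked[1] if len(ranked) > 1 else None)
            margin = "" if runner is None else f" (margin {runner.score - best.score:g})"
            lines.append(
                f"  {'+'.join(sorted(unit)):<18} {best.hypothesis.describe():<40}"
                f" score {best.score:g}{margin}"
            )
        lines.append("-" * w)
        lines.append(f"Inferred polyploidization events: {self.n_events}")
        for call in self.calls:
            lines.append(f"  {call}")
        lines.append("=" * w)
        return "\n".join(lines)

    def __str__(self) -> str:  # pragma: no cover
        return self.summary()
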