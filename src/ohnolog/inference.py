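"""Synthesis of per-lineage polyploidization calls.

Combines three evidence streams into one event table:

* topology tallies (independent vs shared polyploidization per species pair),
* the ordering of ohnolog divergence (T_Ks, a point estimate from the Ks
  density peak) against matrilineal divergence (T_mt, with its 95% interval):
  T_Ks < T_mt means the genome doubled after the species split (independent),
  T_Ks > T_mt means doubling preceded the split (shared),
* MUL-tree reconciliation ranking (auto vs allo placement of the second
  subgenome).

Species connected by a "shared" pair decision are merged transitively into a
single event; conflicting evidence is surfaced (agreement flag, or an error
for non-transitive sharing), never silently arbitrated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .ks import TimeEstimate
from .topology import TopologyTally

__all__ = [
    "MitoDivergence",
    "OrderingDecision",
    "WGDCall",
    "order_events",
    "synthesize_calls",
]


@dataclass(frozen=True)
class MitoDivergence:
    """Matrilineal (mitochondrial) divergence time for a species pair, Mya."""

    pair: tuple[str, str]
    T_mt: float
    low: float | None = None
    high: float | None = None

    def __post_init__(self):
        if self.low is not None and self.high is not None:
            if not (self.low <= self.T_mt <= self.high):
                raise ValueError(
                    f"interval [{self.low}, {self.high}] must bracket T_mt={self.T_mt}"
                )

    @property
    def key(self) -> frozenset:
        return frozenset(self.pair)


@dataclass(frozen=True)
class OrderingDecision:
    """Outcome of comparing ohnolog divergence to matrilineal divergence."""

    pair: tuple[str, str]
    sharing: str  # "independent" | "shared" | "ambiguous"
    max_T_ks: float
    min_T_ks: float
    T_mt: float
    band: tuple[float, float]


def order_events(
    T_ks_a: TimeEstimate | float,
    T_ks_b: TimeEstimate | float,
    mito: MitoDivergence,
    rel_tol: float = 0.0,
) -> OrderingDecision:
    """Order polyploidization against speciation for one species pair.

    ``independent`` when both ohnolog divergence times fall below the lower
    95% bound of the matrilineal divergence; ``shared`` when both exceed the
    upper bound; ``ambiguous`` otherwise.  ``rel_tol`` widens the exclusion
    band by that relative fraction on each side.  Without an interval the
    point T_mt is used on both sides (with a warning).
    """
    ta = T_ks_a.T if isinstance(T_ks_a, TimeEstimate) else float(T_ks_a)
    tb = T_ks_b.T if isinstance(T_ks_b, TimeEstimate) else float(T_ks_b)
    low, high = mito.low, mito.high
    if low is None or high is None:
        warnings.warn(
            f"no 95% interval for pair {mito.pair}; falling back to point comparison"
        )
        low = high = mito.T_mt
    band = (low * (1.0 - rel_tol), high * (1.0 + rel_tol))
    if max(ta, tb) < band[0]:
        sharing = "independent"
    elif min(ta, tb) > band[1]:
        sharing = "shared"
    else:
        sharing = "ambiguous"
    return OrderingDecision(
        pair=tuple(mito.pair),
        sharing=sharing,
        max_T_ks=max(ta, tb),
        min_T_ks=min(ta, tb),
        T_mt=mito.T_mt,
        band=band,
    )


@dataclass
class WGDCall:
    """One inferred polyploidization event (possibly spanning several species)."""

    species: tuple[str, ...]
    sharing: str  # "independent" | "shared" | "ambiguous"
    mode: str  # "auto" | "allo" | "ambiguous"
    T_ks: dict = field(default_factory=dict)  # species -> Mya
    T_mt: float | None = None
    tally_decision: str | None = None
    ordering_decision: str | None = None
    reconciliation_mode: str | None = None
    agreement: bool = True

    def __str__(self) -> str:
        sp = "+".join(self.species)
        times = ", ".join(f"{s}: {t:.2f}" for s, t in sorted(self.T_ks.items()))
        return f"WGD[{sp}] {self.sharing}/{self.mode} (T_Ks {times} Mya)"


class _DSU:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def synthesize_calls(
    tallies: Mapping[frozenset, TopologyTally],
    orderings: Mapping[frozenset, OrderingDecision],
    reconciliation_modes: Mapping[frozenset, str],
    timings: Mapping[str, TimeEstimate],
    mito: Mapping[frozenset, MitoDivergence] | None = None,
) -> list[WGDCall]:
    """Merge pairwise evidence into the per-lineage event table.

    Pair-level sharing is the tally decision when it agrees with the
    T_Ks/T_mt ordering, otherwise ``ambiguous`` with both decisions recorded.
    Species pairs called ``shared`` are merged transitively into one event;
    an ``independent`` pair inside a merged group is a contradiction and
    raises.  The event's mode comes from the reconciliation winner (the joint
    group's winner when available, else the consensus of its members).
    """
    species = sorted({s for pair in tallies for s in pair} | set(timings))
    if not species:
        raise ValueError("no units to synthesize")
    mito = mito or {}

    pair_sharing: dict[frozenset, tuple[str, bool]] = {}
    for pair, tally in tallies.items():
        ordering = orderings.get(pair)
        if ordering is None:
            pair_sharing[pair] = (tally.decision, True)
            continue
        if tally.decision == ordering.sharing:
            pair_sharing[pair] = (tally.decision, True)
        else:
            pair_sharing[pair] = ("ambiguous", False)

    dsu = _DSU(species)
    for pair, (sharing, _) in pair_sharing.items():
        if sharing == "shared":
            a, b = sorted(pair)
            dsu.union(a, b)
    groups: dict[str, list[str]] = {}
    for s in species:
        groups.setdefault(dsu.find(s), []).append(s)

    # Non-transitive sharing: an "independent" pair within a merged group.
    offending = [
        tuple(sorted(pair))
        for pair, (sharing, _) in pair_sharing.items()
        if sharing == "independent"
        and len({dsu.find(s) for s in pair}) == 1
        and len(groups[dsu.find(next(iter(pair)))]) > 1
    ]
    if offending:
        raise ValueError(
            f"non-transitive sharing: pairs {offending} are called independent "
            "but belong to a transitively shared group"
        )

    calls: list[WGDCall] = []
    for members in groups.values():
        members = tuple(sorted(members))
        if len(members) == 1:
            sp = members[0]
            related = [
                (pair, pair_sharing[pair]) for pair in pair_sharing if sp in pair
            ]
            sharings = {s for _, (s, _) in related}
            agreement = all(ok for _, (_, ok) in related)
            if sharings == {"independent"}:
                sharing = "independent"
            elif not sharings:
                sharing = "ambiguous"
            else:
                sharing = "independent" if "independent" in sharings else "ambiguous"
                agreement = agreement and sharings == {"independent"}
            mode = reconciliation_modes.get(frozenset(members), "ambiguous")
            tal = next((tallies[p].decision for p, _ in related), None)
            orddec = next(
                (orderings[p].sharing for p, _ in related if p in orderings), None
            )
            tmt = next(
                (mito[p].T_mt for p, _ in related if p in mito), None
            )
        else:
            sharing = "shared"
            agreement = all(
                pair_sharing.get(frozenset((a, b)), ("shared", True))[1]
                for i, a in enumerate(members)
                for b in members[i + 1:]
            )
            mode = reconciliation_modes.get(frozenset(members), None)
            if mode is None:
                member_modes = {
                    reconciliation_modes.get(frozenset((s,)), "ambiguous")
                    for s in members
                }
                mode = member_modes.pop() if len(member_modes) == 1 else "ambiguous"
            tal = orddec = None
            for i, a in enumerate(members):
                for b in members[i + 1:]:
                    p = frozenset((a, b))
                    if p in tallies and tal is None:
                        tal = tallies[p].decision
                    if p in orderings and orddec is None:
                        orddec = orderings[p].sharing
            tmt = min(
                (mito[frozenset((a, b))].T_mt
                 for i, a in enumerate(members)
                 for b in members[i + 1:]
                 if frozenset((a, b)) in mito),
                default=None,
            )
        calls.append(
            WGDCall(
                species=members,
                sharing=sharing,
                mode=mode if mode is not None else "ambiguous",
                T_ks={s: timings[s].T for s in members if s in timings},
                T_mt=tmt,
                tally_decision=tal,
                ordering_decision=orddec,
                reconciliation_mode=mode,
                agreement=agreement,
            )
        )
    calls.sort(key=lambda c: c.species)
    return calls
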