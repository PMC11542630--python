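"""Orthologous gene-family circumscription from similarity-hit tables.

Consumes tabular similarity output (the standard 12-column layout: query,
subject, %identity, alignment length, mismatches, gap opens, q.start, q.end,
s.start, s.end, E-value, bit score) plus per-sequence lengths, and applies
the filtering and redundancy rules used for orthogroup circumscription:

1. keep hits with E-value ≤ 1e−3, coverage ≥ 50% and identity ≥ 50%;
2. group transcripts into the family of each anchor (reference) gene they hit
   reciprocally, best bit score winning for multi-anchor transcripts;
3. within a species, collapse transcripts that are 100% identical over their
   aligned span, retaining the longest;
4. where a species still carries two transcripts, a pairwise Ks above the
   cutoff (default 1.0) marks them as old paralogs — only the best match to
   the anchor is kept as the ortholog — while Ks ≤ cutoff retains both as
   candidate ohnologs;
5. families flagged by an external gene-conversion screen are excluded from
   downstream tallies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "HIT_COLUMNS",
    "HitRecord",
    "FamilyMember",
    "GeneFamily",
    "read_hit_table",
    "filter_hits",
    "build_families",
    "dedupe_identical",
    "resolve_by_ks",
    "apply_conversion_mask",
    "membership_table",
]

logger = logging.getLogger(__name__)

HIT_COLUMNS = [
    "query",
    "subject",
    "pct_identity",
    "aln_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bit_score",
]


@dataclass(frozen=True)
class HitRecord:
    """One similarity hit with derived coverage."""

    query: str
    subject: str
    pct_identity: float
    aln_length: int
    evalue: float
    bit_score: float
    query_length: int | None = None
    subject_length: int | None = None

    def coverage(self, on: str = "query") -> float:
        """Alignment coverage in percent of the query (default) or subject."""
        length = self.query_length if on == "query" else self.subject_length
        if length is None or length <= 0:
            raise ValueError(
                f"no {on} length available for hit {self.query}->{self.subject}"
            )
        return 100.0 * self.aln_length / length


def read_hit_table(
    path_or_buffer,
    lengths: Mapping[str, int] | None = None,
) -> list[HitRecord]:
    """Read a 12-column tab-separated hit table into HitRecords.

    ``lengths`` maps sequence ids to lengths (used for coverage); ids missing
    from the map simply lack a coverage denominator.
    """
    df = pd.read_csv(path_or_buffer, sep="\t", names=HIT_COLUMNS, header=None)
    lengths = lengths or {}
    return [
        HitRecord(
            query=str(row.query),
            subject=str(row.subject),
            pct_identity=float(row.pct_identity),
            aln_length=int(row.aln_length),
            evalue=float(row.evalue),
            bit_score=float(row.bit_score),
            query_length=lengths.get(str(row.query)),
            subject_length=lengths.get(str(row.subject)),
        )
        for row in df.itertuples()
    ]


def filter_hits(
    hits: Iterable[HitRecord],
    e_max: float = 1e-3,
    cov_min: float = 50.0,
    id_min: float = 50.0,
    coverage_on: str = "query",
) -> list[HitRecord]:
    """Keep exactly the hits with E ≤ e_max, coverage ≥ cov_min, identity ≥ id_min.

    Idempotent and order-preserving.  Coverage is alignment length over the
    query length by default (``coverage_on="subject"`` switches denominator).
    """
    if e_max < 0 or cov_min < 0 or id_min < 0:
        raise ValueError("thresholds must be non-negative")
    return [
        h
        for h in hits
        if h.evalue <= e_max
        and h.coverage(coverage_on) >= cov_min
        and h.pct_identity >= id_min
    ]


@dataclass
class FamilyMember:
    transcript_id: str
    species: str
    bit_score: float
    sequence: str | None = None
    role: str = "member"  # member | ohnolog1 | ohnolog2 | ortholog | dropped:<reason>


@dataclass
class GeneFamily:
    """One orthologous family anchored on a reference gene."""

    family_id: str
    members: dict = field(default_factory=dict)  # species -> list[FamilyMember]
    excluded: bool = False
    flags: set = field(default_factory=set)

    def n_members(self) -> int:
        return sum(len(v) for v in self.members.values())

    def active_members(self, species: str) -> list[FamilyMember]:
        return [
            m for m in self.members.get(species, []) if not m.role.startswith("dropped")
        ]

    def copies_per_species(self) -> dict[str, int]:
        return {
            sp: len(self.active_members(sp))
            for sp in self.members
            if self.active_members(sp)
        }


def build_families(
    hits: Iterable[HitRecord],
    anchor_ids: Sequence[str],
    species_of: Mapping[str, str],
    sequences: Mapping[str, str] | None = None,
) -> list[GeneFamily]:
    """Group transcripts into one family per anchor gene.

    A transcript joins an anchor's family when hits exist in *both*
    directions (anchor→transcript and transcript→anchor) among the provided
    (already filtered) hits.  Transcripts qualifying for several anchors are
    assigned to the one with the best bit score, ties broken by lexicographic
    anchor id.  Anchors with no qualifying transcript yield an empty family
    flagged ``"empty"``.
    """
    anchor_ids = list(anchor_ids)
    if not anchor_ids:
        raise ValueError("anchor id list is empty")
    anchors = set(anchor_ids)
    fwd: dict[tuple[str, str], float] = {}
    rev: dict[tuple[str, str], float] = {}
    for h in hits:
        if h.query in anchors and h.subject not in anchors:
            key = (h.query, h.subject)
            fwd[key] = max(fwd.get(key, 0.0), h.bit_score)
        elif h.subject in anchors and h.query not in anchors:
            key = (h.subject, h.query)
            rev[key] = max(rev.get(key, 0.0), h.bit_score)
    best: dict[str, tuple[float, str]] = {}  # transcript -> (bit, anchor)
    for (anchor, transcript), bit in fwd.items():
        if (anchor, transcript) not in rev:
            continue
        bit = max(bit, rev[(anchor, transcript)])
        cur = best.get(transcript)
        # Higher bit score wins; on a tie the lexicographically smaller anchor.
        cand = (bit, anchor)
        if cur is None or (cand[0], _neg_str(cand[1])) > (cur[0], _neg_str(cur[1])):
            best[transcript] = cand
    families = {a: GeneFamily(family_id=a) for a in anchor_ids}
    for transcript, (bit, anchor) in best.items():
        sp = species_of.get(transcript)
        if sp is None:
            raise KeyError(f"no species known for transcript {transcript!r}")
        member = FamilyMember(
            transcript_id=transcript,
            species=sp,
            bit_score=bit,
            sequence=(sequences or {}).get(transcript),
        )
        families[anchor].members.setdefault(sp, []).append(member)
    out = []
    for a in anchor_ids:
        fam = families[a]
        if fam.n_members() == 0:
            fam.flags.add("empty")
        for members in fam.members.values():
            members.sort(key=lambda m: (-m.bit_score, m.transcript_id))
        out.append(fam)
    return out


class _NegStr(str):
    """Reverses comparison order so max() prefers the smaller string."""

    def __lt__(self, other):
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def _neg_str(s: str) -> _NegStr:
    return _NegStr(s)


def _identical_over_aligned_span(a: str, b: str) -> bool:
    """100% identity over the shorter sequence's aligned span.

    Without re-aligning, this is containment of the shorter sequence in the
    longer — the redundancy case of UTR-trimmed or truncated isoforms.
    """
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)
    return short in long_


def dedupe_identical(family: GeneFamily) -> GeneFamily:
    """Within each species, collapse 100%-identical transcripts to the longest.

    Sequences must be attached to the members; members without a sequence are
    left untouched.  Transcripts that are merely similar (<100%) are kept.
    """
    for sp, members in family.members.items():
        active = [m for m in members if not m.role.startswith("dropped")]
        withseq = [m for m in active if m.sequence]
        # Greedy clustering by containment; keep the longest of each cluster.
        withseq.sort(key=lambda m: (-len(m.sequence), m.transcript_id))
        kept: list[FamilyMember] = []
        for m in withseq:
            rep = next(
                (k for k in kept if _identical_over_aligned_span(m.sequence, k.sequence)),
                None,
            )
            if rep is None:
                kept.append(m)
            else:
                m.role = "dropped:redundant"
    return family


def resolve_by_ks(
    family: GeneFamily,
    ks_fn: Callable[[str, str], float],
    ks_cut: float = 1.0,
) -> GeneFamily:
    """Separate ohnolog candidates from old paralogs by pairwise Ks.

    For each species with exactly two retained transcripts: Ks > ``ks_cut``
    means the pair predates the duplication of interest — only the best
    match to the anchor (highest bit score) is kept as the ortholog; Ks ≤
    ``ks_cut`` (boundary inclusive) retains both as candidate ohnologs.
    Species with more than two retained copies are flagged
    ``copy-count-violation`` and left untouched (excluded downstream).  A
    failing ``ks_fn`` flags the family ``ks-error`` instead of dropping it.
    """
    for sp in family.members:
        active = family.active_members(sp)
        if len(active) == 1:
            active[0].role = "ortholog"
            continue
        if len(active) > 2:
            family.flags.add("copy-count-violation")
            continue
        if len(active) != 2:
            continue
        a, b = active
        if a.sequence is None or b.sequence is None:
            family.flags.add("ks-error")
            continue
        try:
            ks = ks_fn(a.sequence, b.sequence)
        except Exception as exc:
            logger.warning("Ks failed for family %s species %s: %s", family.family_id, sp, exc)
            family.flags.add("ks-error")
            continue
        if ks > ks_cut:
            keep, drop = (a, b) if a.bit_score >= b.bit_score else (b, a)
            keep.role = "ortholog"
            drop.role = "dropped:paralog"
        else:
            a.role = "ohnolog1"
            b.role = "ohnolog2"
    return family


def apply_conversion_mask(
    families: Iterable[GeneFamily], masked_ids: Iterable[str]
) -> list[GeneFamily]:
    """Flag families identified by an external gene-conversion screen.

    Masked families are marked excluded (downstream tallies skip them and
    report the count); mask ids not matching any family only warn.
    """
    families = list(families)
    known = {f.family_id for f in families}
    mask = set(masked_ids)
    for unknown in sorted(mask - known):
        warnings.warn(f"conversion mask id {unknown!r} matches no family")
    for fam in families:
        if fam.family_id in mask:
            fam.excluded = True
            fam.flags.add("gene-conversion")
    return families


def membership_table(families: Iterable[GeneFamily]) -> pd.DataFrame:
    """Long-format membership table (family, species, transcript, role)."""
    rows = []
    for fam in families:
        for sp, members in sorted(fam.members.items()):
            for m in members:
                rows.append(
                    {
                        "family": fam.family_id,
                        "species": sp,
                        "transcript": m.transcript_id,
                        "role": m.role,
                        "excluded": fam.excluded,
                        "flags": ",".join(sorted(fam.flags)),
                    }
                )
    return pd.DataFrame(
        rows, columns=["family", "species", "transcript", "role", "excluded", "flags"]
    )
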