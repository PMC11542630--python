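"""Hit filtering, family circumscription, redundancy and paralog resolution."""

import io

import pytest

from ohnolog.families import (
    GeneFamily,
    HitRecord,
    apply_conversion_mask,
    build_families,
    dedupe_identical,
    filter_hits,
    membership_table,
    read_hit_table,
    resolve_by_ks,
)


def hit(q, s, ident=80.0, alen=300, e=1e-10, bit=500.0, qlen=400, slen=400):
    return HitRecord(
        query=q, subject=s, pct_identity=ident, aln_length=alen,
        evalue=e, bit_score=bit, query_length=qlen, subject_length=slen,
    )


class TestFilterHits:
    def test_all_thresholds_met(self):
        kept = filter_hits([hit("a", "t", ident=55, alen=240, e=1e-5, qlen=400)])
        assert len(kept) == 1  # coverage 60%, identity 55%, E 1e-5

    def test_evalue_fails(self):
        kept = filter_hits([hit("a", "t", ident=90, alen=360, e=1e-2)])
        assert kept == []

    def test_toy_table_counts(self):
        rows = [
            hit("a", "t1", ident=55, alen=240, e=1e-5),    # keep
            hit("a", "t2", ident=90, alen=360, e=1e-2),    # E fails
            hit("a", "t3", ident=49, alen=360, e=1e-9),    # identity fails
            hit("a", "t4", ident=75, alen=150, e=1e-9),    # coverage 37.5% fails
            hit("a", "t5", ident=50, alen=200, e=1e-3),    # boundary: keep
            hit("a", "t6", ident=64, alen=320, e=1e-20),   # keep
        ]
        kept = filter_hits(rows)
        assert [h.subject for h in kept] == ["t1", "t5", "t6"]

    def test_idempotent_and_order_independent(self):
        rows = [
            hit("a", "t1", ident=55), hit("a", "t2", ident=45),
            hit("a", "t3", e=1), hit("a", "t4"),
        ]
        once = filter_hits(rows)
        assert filter_hits(once) == once
        rev = filter_hits(rows[::-1])
        assert sorted(h.subject for h in rev) == sorted(h.subject for h in once)

    def test_negative_threshold_errors(self):
        with pytest.raises(ValueError):
            filter_hits([], e_max=-1)

    def test_subject_coverage_switch(self):
        h = hit("a", "t", alen=240, qlen=400, slen=240)
        assert filter_hits([h], coverage_on="subject")  # 100% of subject
        assert filter_hits([h], cov_min=61) == []  # 60% of query


class TestReadHitTable:
    def test_twelve_column_layout(self):
        text = "a\tt1\t85.0\t300\t40\t2\t1\t300\t1\t300\t1e-50\t420\n"
        recs = read_hit_table(io.StringIO(text), {"a": 400, "t1": 350})
        assert recs[0].query == "a"
        assert recs[0].coverage() == pytest.approx(75.0)
        assert recs[0].coverage("subject") == pytest.approx(300 / 350 * 100)


def reciprocal(anchor, transcript, bit=500.0, **kw):
    return [
        hit(anchor, transcript, bit=bit, **kw),
        hit(transcript, anchor, bit=bit, **kw),
    ]


class TestBuildFamilies:
    SPECIES = {"t1": "A", "t2": "A", "t3": "B", "t4": "B", "t5": "B"}

    def test_one_family_two_species(self):
        hits = sum(
            (reciprocal("anc1", t) for t in ["t1", "t2", "t3", "t4"]), []
        )
        fams = build_families(hits, ["anc1"], self.SPECIES)
        assert len(fams) == 1
        assert {sp: len(m) for sp, m in fams[0].members.items()} == {"A": 2, "B": 2}

    def test_best_bit_score_wins(self):
        hits = reciprocal("ancX", "t1", bit=900) + reciprocal("ancY", "t1", bit=300)
        fams = build_families(hits, ["ancX", "ancY"], self.SPECIES)
        by_id = {f.family_id: f for f in fams}
        assert by_id["ancX"].n_members() == 1
        assert by_id["ancY"].n_members() == 0
        assert "empty" in by_id["ancY"].flags

    def test_tie_broken_lexicographically(self):
        hits = reciprocal("ancB", "t1", bit=500) + reciprocal("ancA", "t1", bit=500)
        fams = build_families(hits, ["ancB", "ancA"], self.SPECIES)
        assert {f.family_id: f.n_members() for f in fams} == {"ancA": 1, "ancB": 0}

    def test_one_directional_hit_not_enough(self):
        hits = [hit("anc1", "t1")]
        fams = build_families(hits, ["anc1"], self.SPECIES)
        assert fams[0].n_members() == 0

    def test_empty_anchor_list_errors(self):
        with pytest.raises(ValueError):
            build_families([], [], self.SPECIES)


class TestDedupe:
    @staticmethod
    def family(seqs):
        fam = GeneFamily(family_id="f")
        hits = []
        for i, s in enumerate(seqs):
            hits += reciprocal("f", f"t{i}")
        fams = build_families(
            hits, ["f"], {f"t{i}": "A" for i in range(len(seqs))},
            sequences={f"t{i}": s for i, s in enumerate(seqs)},
        )
        return fams[0]

    def test_contained_transcript_dropped_longest_kept(self):
        short = "ATGGCTAAATTT" * 25           # 300 nt
        long_ = "GGG" * 25 + short + "CCC" * 25  # 450 nt containing it
        fam = dedupe_identical(self.family([short, long_]))
        roles = {m.transcript_id: m.role for m in fam.members["A"]}
        kept = [t for t, r in roles.items() if not r.startswith("dropped")]
        assert len(kept) == 1
        assert len(dict(zip(["t0", "t1"], [short, long_]))[kept[0]]) == 450

    def test_similar_but_not_identical_kept(self):
        a = "ATGGCTAAATTT" * 25
        b = a[:-3] + "GGA"  # one codon differs
        fam = dedupe_identical(self.family([a, b]))
        assert all(
            not m.role.startswith("dropped") for m in fam.members["A"]
        )

    def test_single_transcript_unchanged(self):
        fam = self.family(["ATGGCTAAATTT"])
        dedupe_identical(fam)
        assert fam.members["A"][0].role == "member"


class TestResolveByKs:
    @staticmethod
    def two_member_family(bits=(900, 300)):
        hits = reciprocal("f", "t0", bit=bits[0]) + reciprocal("f", "t1", bit=bits[1])
        fams = build_families(
            hits, ["f"], {"t0": "A", "t1": "A"},
            sequences={"t0": "ATG" * 100, "t1": "ATG" * 100},
        )
        return fams[0]

    def test_high_ks_keeps_best_match_only(self):
        fam = self.two_member_family()
        resolve_by_ks(fam, lambda a, b: 1.2)
        roles = sorted(m.role for m in fam.members["A"])
        assert roles == ["dropped:paralog", "ortholog"]
        kept = fam.active_members("A")[0]
        assert kept.bit_score == 900

    @pytest.mark.parametrize("ks", [0.8, 1.0])
    def test_low_or_boundary_ks_keeps_both(self, ks):
        fam = self.two_member_family()
        resolve_by_ks(fam, lambda a, b: ks)
        assert sorted(m.role for m in fam.members["A"]) == ["ohnolog1", "ohnolog2"]

    def test_ks_failure_flags_family(self):
        fam = self.two_member_family()

        def bad(a, b):
            raise RuntimeError("frame mismatch")

        resolve_by_ks(fam, bad)
        assert "ks-error" in fam.flags
        assert fam.n_members() == 2  # not silently dropped

    def test_three_copies_flagged_copy_count(self):
        hits = sum((reciprocal("f", f"t{i}") for i in range(3)), [])
        fam = build_families(
            hits, ["f"], {f"t{i}": "A" for i in range(3)},
            sequences={f"t{i}": "ATG" * 10 for i in range(3)},
        )[0]
        resolve_by_ks(fam, lambda a, b: 0.5)
        assert "copy-count-violation" in fam.flags


class TestConversionMask:
    @staticmethod
    def families(n):
        return [GeneFamily(family_id=f"f{i}") for i in range(n)]

    def test_empty_mask_no_change(self):
        fams = apply_conversion_mask(self.families(5), [])
        assert not any(f.excluded for f in fams)

    def test_masked_families_excluded(self):
        fams = apply_conversion_mask(self.families(10), ["f1", "f7"])
        assert sum(f.excluded for f in fams) == 2
        assert sum(not f.excluded for f in fams) == 8

    def test_unknown_id_warns(self):
        with pytest.warns(UserWarning):
            apply_conversion_mask(self.families(2), ["nope"])


def test_membership_table_roles():
    hits = reciprocal("f", "t0") + reciprocal("f", "t1")
    fams = build_families(
        hits, ["f"], {"t0": "A", "t1": "A"},
        sequences={"t0": "ATGGCT" * 50, "t1": "ATGGCT" * 50 },
    )
    dedupe_identical(fams[0])
    df = membership_table(fams)
    assert set(df.columns) >= {"family", "species", "transcript", "role"}
    assert len(df) == 2
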