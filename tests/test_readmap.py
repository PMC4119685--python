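"""Mapping, classification, expression, isomiR and opp-miRNA reports."""

import math
import random

import pytest

from mirseq.readmap import (HAIRPIN_OTHER, MATURE, OPP_ARM, align_tag,
                            assign_hit_to_mature, au_rich_share, build_profile,
                            classify_tags, detect_opp_mirnas,
                            detection_summary, display_suffix,
                            enumerate_isomirs, filter_frequent,
                            mod_pattern_frequencies, parse_isomir_alignment,
                            render_isomir_alignment, run_readmap)
from mirseq.readpro import UniqueTag
from mirseq.reference import (Hairpin, MatureAnnotation, ReferenceSet,
                              build_substring_index, locate_matures)

from conftest import random_seq


@pytest.fixture(scope="module")
def hairpin():
    rng = random.Random(10)
    seq = random_seq(rng, 60)
    hp = Hairpin("syn-mir-x", seq)
    hp.matures = locate_matures(hp, [("syn-miR-x-5p", seq[7:29])])
    assert hp.matures[0].start == 8 and hp.matures[0].end == 29
    return hp


@pytest.fixture(scope="module")
def hairpin_index(hairpin):
    return build_substring_index({hairpin.name: hairpin.seq})


def exhaustive_clip_and_scan(seq, hairpins, max_mod=3, min_match=15):
    """Oracle: smallest clip whose clipped core occurs somewhere."""
    for c in range(max_mod + 1):
        core = seq[:len(seq) - c] if c else seq
        if len(core) < min_match:
            return []
        hits = []
        for name, ref in hairpins:
            for i in range(len(ref) - len(core) + 1):
                if ref[i:i + len(core)] == core:
                    hits.append((name, i + 1, i + len(core), display_suffix(seq[len(core):])))
        if hits:
            return hits
    return []


class TestAlignTag:
    def test_exact_mature_read(self, hairpin, hairpin_index):
        tag = UniqueTag(hairpin.seq[7:29], 3)
        [hit] = align_tag(tag, hairpin_index)
        assert (hit.start, hit.end, hit.mod_suffix) == (8, 29, "")

    def test_single_base_tail_clipped_and_displayed_as_u(self, hairpin, hairpin_index):
        core = hairpin.seq[7:29]
        suffix_base = "T" if hairpin.seq[29] != "T" else "A"
        tag = UniqueTag(core + suffix_base, 1)
        [hit] = align_tag(tag, hairpin_index)
        assert (hit.start, hit.end) == (8, 29)
        assert hit.mod_suffix == display_suffix(suffix_base)

    def test_smallest_clip_preferred(self, hairpin, hairpin_index):
        # a templated extension must be reported unclipped, not as a mod
        tag = UniqueTag(hairpin.seq[7:30], 1)
        [hit] = align_tag(tag, hairpin_index)
        assert (hit.start, hit.end, hit.mod_suffix) == (8, 30, "")

    def test_min_match_floor(self, hairpin_index):
        assert align_tag(UniqueTag("ACGTACGTACGTACG", 1), hairpin_index,
                         max_mod=3, min_match=16) == []

    def test_planted_clips_recovered_and_match_oracle(self):
        rng = random.Random(11)
        refs = [(f"h{i}", random_seq(rng, 80)) for i in range(5)]
        index = build_substring_index(refs)
        for _ in range(200):
            name, ref = refs[rng.randrange(5)]
            start = rng.randint(0, 50)
            core = ref[start:start + rng.randint(18, 24)]
            clip = rng.randint(0, 3)
            seq = core + random_seq(rng, clip)
            hits = align_tag(UniqueTag(seq, 1), index)
            oracle = exhaustive_clip_and_scan(seq, refs)
            assert sorted((h.hairpin, h.start, h.end, h.mod_suffix) for h in hits) \
                == sorted(oracle)


class TestAssignHit:
    def test_identity_placement(self, hairpin, hairpin_index):
        [hit] = align_tag(UniqueTag(hairpin.seq[7:29], 2), hairpin_index)
        a = assign_hit_to_mature(hit, hairpin)
        assert (a.target, a.mature, a.shift5, a.shift3) == \
            (MATURE, "syn-miR-x-5p", 0, 0)

    def test_five_prime_shift_convention(self, hairpin, hairpin_index):
        [hit] = align_tag(UniqueTag(hairpin.seq[8:29], 2), hairpin_index)
        a = assign_hit_to_mature(hit, hairpin)
        assert (a.shift5, a.shift3) == (1, 0)

    def test_read_on_unannotated_arm_is_opp(self, hairpin, hairpin_index):
        [hit] = align_tag(UniqueTag(hairpin.seq[38:58], 2), hairpin_index)
        a = assign_hit_to_mature(hit, hairpin)
        assert a.target == OPP_ARM and a.mature is None

    def test_low_overlap_read_on_annotated_arm_is_other(self, hairpin, hairpin_index):
        # spans positions 1..20: overlaps mature 8..29 by 13/20 < 50%? 13/20 = 65%
        # use positions 1..16 -> overlap 9/16 = 56%; need < 50%: 1..15 -> 8/15
        [hit] = align_tag(UniqueTag(hairpin.seq[0:15], 2), hairpin_index,
                          min_match=15)
        a = assign_hit_to_mature(hit, hairpin, min_overlap_frac=0.6)
        assert a.target == HAIRPIN_OTHER


class TestClassifyTags:
    @pytest.fixture()
    def refs(self, toy_refs):
        return toy_refs

    def test_order_mirna_beats_rrna(self):
        rng = random.Random(12)
        hp_seq = random_seq(rng, 60)
        shared = hp_seq[10:32]
        hp = Hairpin("syn-mir-1", hp_seq)
        hp.matures = locate_matures(hp, [("syn-miR-1-5p", shared)])
        refs = ReferenceSet(hairpins=[hp],
                            categories=[("rRNA", {"r1": "AAAA" + shared + "TTTT"})])
        res = classify_tags([UniqueTag(shared, 4)], refs)
        assert res.counts["miRNA"] == 4 and res.counts["rRNA"] == 0

    def test_unmatched_tag_is_unknown(self, refs):
        rng = random.Random(13)
        tag = UniqueTag(random_seq(rng, 24), 2)
        while classify_tags([tag], refs).counts["unknown"] != 2:  # pragma: no cover
            tag = UniqueTag(random_seq(rng, 24), 2)
        res = classify_tags([tag], refs)
        assert res.per_category["unknown"] == [tag]

    def test_genome_category_searched_on_both_strands(self):
        rng = random.Random(14)
        hp = Hairpin("syn-mir-1", random_seq(rng, 60))
        genome = random_seq(rng, 200)
        from mirseq.reference import revcomp
        tag_seq = revcomp(genome[50:72])
        refs = ReferenceSet(hairpins=[hp], categories=[("genome", {"chr1": genome})])
        res = classify_tags([UniqueTag(tag_seq, 3)], refs)
        assert res.counts["genome"] == 3

    def test_shares_sum_to_100_and_exclusive(self, refs, sim_library):
        _, truth, _ = sim_library
        res = classify_tags(truth.qualified_tags, refs)
        assert sum(res.shares.values()) == pytest.approx(100.0)
        assert sum(res.counts.values()) == sum(t.count for t in truth.qualified_tags)
        assigned = [t for tags in res.per_category.values() for t in tags]
        assert len(assigned) == len(truth.qualified_tags)


class TestProfile:
    def _assignments(self, spec):
        """spec: list of (tag_count, [mature names]) built on one toy hairpin."""
        rng = random.Random(15)
        assignments = []
        for i, (count, matures) in enumerate(spec):
            seq = random_seq(rng, 22)
            tag = UniqueTag(seq, count)
            hp = Hairpin(f"hp{i}", seq)
            from mirseq.readmap import HairpinHit, MatureAssignment
            for m in matures:
                hit = HairpinHit(tag=tag, hairpin=f"hp{i}", start=1, end=22)
                assignments.append(MatureAssignment(hit=hit, target=MATURE,
                                                    mature=m, shift5=0, shift3=0))
        return assignments

    def test_tpm_two_matures(self):
        profile = build_profile(self._assignments([(3, ["A"]), (1, ["B"])]))
        assert profile.tpm["A"] == pytest.approx(750_000)
        assert profile.tpm["B"] == pytest.approx(250_000)

    def test_single_mature_gets_the_million(self):
        profile = build_profile(self._assignments([(7, ["A"])]))
        assert profile.tpm == {"A": pytest.approx(1_000_000)}

    def test_multimap_split_conserves_counts(self):
        profile = build_profile(
            self._assignments([(4, ["m1", "m2"]), (2, ["m2"])]))
        assert profile.raw_counts == {"m2": 4.0, "m1": 2.0}
        assert sum(profile.tpm.values()) == pytest.approx(1e6)

    def test_empty_profile(self):
        profile = build_profile([])
        assert profile.raw_counts == {} and profile.tpm == {}
        assert profile.top_share() == 0.0


class TestModPatterns:
    def _assign(self, spec):
        from mirseq.readmap import HairpinHit, MatureAssignment
        rng = random.Random(16)
        out = []
        for count, suffix in spec:
            tag = UniqueTag(random_seq(rng, 22), count)
            hit = HairpinHit(tag=tag, hairpin="h", start=1, end=22, mod_suffix=suffix)
            out.append(MatureAssignment(hit=hit, target=MATURE, mature="m",
                                        shift5=0, shift3=0))
        return out

    def test_all_unmodified(self):
        freqs = mod_pattern_frequencies(self._assign([(10, "")]))
        assert freqs == {"": 100.0}

    def test_au_rich_share(self):
        freqs = mod_pattern_frequencies(
            self._assign([(70, "u"), (20, "a"), (10, "g")]))
        assert au_rich_share(freqs) == pytest.approx(90.0)

    def test_filter_view_keeps_only_frequent(self):
        freqs = mod_pattern_frequencies(
            self._assign([(990, ""), (7, "u"), (3, "g")]))
        view = filter_frequent(freqs, min_pct=1.0)
        assert set(view) == {""}  # 0.7% and 0.3% fall below the 1% rule


class TestIsomirs:
    def test_merge_and_conservation(self, hairpin, hairpin_index, toy_refs):
        core = hairpin.seq[7:29]
        tags = [UniqueTag(core, 5), UniqueTag(hairpin.seq[8:29], 2)]
        refs = ReferenceSet(hairpins=[hairpin], categories=[])
        result = run_readmap(tags, refs)
        records = result.isomirs["syn-miR-x-5p"]
        keys = {(r.shift5, r.shift3, r.mod_suffix): r.count for r in records}
        assert keys == {(0, 0, ""): 5.0, (1, 0, ""): 2.0}
        assert sum(r.count for r in records) == \
            pytest.approx(result.profile.raw_counts["syn-miR-x-5p"])

    def test_identical_keys_merge(self):
        from mirseq.readmap import HairpinHit, MatureAssignment
        rng = random.Random(17)
        assigns = []
        for count in (3, 4):
            tag = UniqueTag(random_seq(rng, 22), count)
            hit = HairpinHit(tag=tag, hairpin="h", start=8, end=29, mod_suffix="u")
            assigns.append(MatureAssignment(hit=hit, target=MATURE, mature="m",
                                            shift5=0, shift3=0))
        [record] = enumerate_isomirs(assigns)["m"]
        assert record.count == 7


class TestOppMiRNA:
    def _opp_assignments(self, hairpin, spans_counts):
        from mirseq.readmap import HairpinHit, MatureAssignment
        out = []
        for (start, end), count in spans_counts:
            seq = hairpin.seq[start - 1:end]
            hit = HairpinHit(tag=UniqueTag(seq, count), hairpin=hairpin.name,
                             start=start, end=end)
            out.append(MatureAssignment(hit=hit, target=OPP_ARM))
        return out

    def test_defining_span_and_total(self, hairpin):
        assigns = self._opp_assignments(
            hairpin, [((39, 58), 5), ((40, 58), 2), ((39, 58), 1)])
        [opp] = detect_opp_mirnas(assigns)
        assert (opp.start, opp.end, opp.total_count) == (39, 58, 8)
        keys = {(r.shift5, r.shift3): r.count for r in opp.isomirs}
        assert keys == {(0, 0): 6, (1, 0): 2}

    def test_below_threshold_not_reported(self, hairpin):
        assigns = self._opp_assignments(hairpin, [((39, 58), 1)])
        assert detect_opp_mirnas(assigns, opp_min_count=2) == []

    def test_fully_annotated_hairpin_never_opp(self):
        rng = random.Random(18)
        seq = random_seq(rng, 70)
        hp = Hairpin("h", seq)
        hp.matures = locate_matures(
            hp, [("m-5p", seq[4:26]), ("m-3p", seq[44:66])])
        assert hp.annotated_arms() == {"5p", "3p"}
        index = build_substring_index({"h": seq})
        for start in range(1, 45):
            tag = UniqueTag(seq[start - 1:start + 19], 5)
            for hit in align_tag(tag, index):
                assert assign_hit_to_mature(hit, hp).target != OPP_ARM


class TestDetection:
    def test_empty(self, toy_refs):
        from mirseq.readmap import ExpressionProfile
        d = detection_summary(ExpressionProfile({}, {}), toy_refs)
        assert (d.detected_matures, d.detected_premirnas, d.detected_opp) == (0, 0, 0)

    def test_counts(self, toy_refs):
        from mirseq.readmap import ExpressionProfile, OppMiRNA
        hp = toy_refs.hairpins
        profile = ExpressionProfile.from_raw({
            hp[0].matures[0].name: 5, hp[1].matures[0].name: 3})
        opp = [OppMiRNA(hairpin=hp[2].name, start=40, end=60, total_count=4)]
        d = detection_summary(profile, toy_refs, opp)
        assert (d.detected_matures, d.detected_premirnas, d.detected_opp) == (2, 3, 1)
        assert d.detected_matures <= d.annotated_matures
        assert d.detected_premirnas <= d.annotated_premirnas


class TestRenderIsomirAlignment:
    def _records(self, counts_keys):
        from mirseq.readmap import IsomiRRecord
        return [IsomiRRecord(mature="syn-miR-x-5p", shift5=s5, shift3=s3,
                             mod_suffix=suf, count=c)
                for (s5, s3, suf), c in counts_keys]

    def test_layout(self, hairpin):
        text = render_isomir_alignment(
            hairpin, self._records([((0, 0, ""), 455)]))
        lines = text.splitlines()
        assert lines[0][7:29] == hairpin.seq[7:29]          # mature upper case
        assert lines[0][:7] == hairpin.seq[:7].lower()
        assert lines[1].startswith(" " * 7 + hairpin.seq[7:29])
        assert lines[1].endswith("  455 0,0")

    def test_shifted_record_with_suffix(self, hairpin):
        text = render_isomir_alignment(
            hairpin, self._records([((1, 0, "u"), 12)]))
        line = text.splitlines()[1]
        assert line.startswith(" " * 8 + hairpin.seq[8:29] + "u")
        assert line.endswith("  12 1,0")

    def test_round_trip(self, hairpin):
        records = self._records(
            [((0, 0, ""), 455), ((1, 0, "u"), 12), ((0, -1, "au"), 3),
             ((-2, 1, ""), 9)])
        text = render_isomir_alignment(hairpin, records)
        assert parse_isomir_alignment(text, hairpin) == records

    def test_out_of_bounds_record_rejected(self, hairpin):
        with pytest.raises(ValueError):
            render_isomir_alignment(hairpin, self._records([((40, 40, ""), 1)]))


def test_run_readmap_consistency(toy_refs, sim_library):
    _, truth, _ = sim_library
    result = run_readmap(truth.qualified_tags, toy_refs)
    assert sum(result.profile.tpm.values()) == pytest.approx(1e6, rel=1e-6)
    for mature, records in result.isomirs.items():
        assert sum(r.count for r in records) == \
            pytest.approx(result.profile.raw_counts[mature])
    assert math.isclose(sum(result.classification.shares.values()), 100.0)
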