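from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsrnakit.classify import (AlignmentStats, FragmentAlignment, TsRNAName,
                               TsRNAType, classify, collapse_and_name,
                               map_reads, parse_name)
from tsrnakit.pipeline import run_pipeline
from tsrnakit.simulate import SimConfig

from ._oracles import classify_case


def _aln(rec, start, end, region="mature"):
    if region == "mature":
        seq = rec.mature_seq[start - 1:end]
    else:
        seq = rec.precursor.trailer_seq[start - 1:end]
    return FragmentAlignment(read_seq=seq, trna_id=rec.id, region=region,
                             start=start, end=end)


class TestClassify:
    def test_rule_examples(self, fixture_record):
        rec = fixture_record
        ac = rec.loops.anticodon_loop
        # 5' half: starts at 1, ends inside the anticodon loop
        assert classify(_aln(rec, 1, ac.start + 2), rec) is TsRNAType.TIRNA5
        # 5' tRF: starts at 1, ends within the D-arm region
        assert classify(_aln(rec, 1, 18), rec) is TsRNAType.TRF5
        # 3' tRF: starts in the T-loop, runs to the CCA end
        assert classify(_aln(rec, 55, 76), rec) is TsRNAType.TRF3
        # internal: anchored at neither end
        assert classify(_aln(rec, 10, 34), rec) is TsRNAType.ITRF
        # precursor trailer
        assert classify(_aln(rec, 1, 16, region="trailer"), rec) \
            is TsRNAType.TRF1

    def test_full_length_molecule_is_excluded(self, fixture_record):
        assert classify(_aln(fixture_record, 1, 76), fixture_record) is None

    def test_trailer_hit_far_from_boundary_is_not_trf1(self, fixture_record):
        rec = fixture_record
        assert classify(_aln(rec, 4, len(rec.precursor.trailer_seq),
                             region="trailer"), rec) is None

    def test_out_of_bounds_alignment_is_error(self, fixture_record):
        rec = fixture_record
        bad = FragmentAlignment(read_seq="A" * 80, trna_id=rec.id,
                                region="mature", start=1, end=80)
        with pytest.raises(ValueError):
            classify(bad, rec)

    def test_agrees_with_exhaustive_case_oracle(self, fixture_record):
        """Every (start, end) pair on the 76-nt fixture matches the
        six-way case enumeration."""
        rec = fixture_record
        ac = rec.loops.anticodon_loop
        for start in range(1, 77):
            for end in range(start, 77):
                expected = classify_case(start, end, 76, ac.start, ac.end)
                got = classify(_aln(rec, start, end), rec)
                got = got.value if got is not None else None
                assert got == expected, (start, end)


class TestMapping:
    def test_prefix_read_maps_once(self, fixture_record):
        rec = fixture_record
        read = rec.mature_seq[:30]
        hits = map_reads([read], [rec])
        assert len(hits) == 1
        assert (hits[0].region, hits[0].start, hits[0].end) == ("mature", 1, 30)

    def test_read_shared_by_two_isodecoders_maps_twice(self, fixture_record):
        import dataclasses
        rec = fixture_record
        twin = dataclasses.replace(rec, id="fix-tRNA-Gly-2")
        hits = map_reads([rec.mature_seq[:30]], [rec, twin])
        assert {h.trna_id for h in hits} == {rec.id, twin.id}

    def test_unmapped_read_counts_as_unaligned(self, fixture_record):
        stats = AlignmentStats()
        hits = map_reads(["ACGU" * 5], [fixture_record], stats=stats)
        assert hits == [] and stats.n_unaligned == 1

    def test_mismatch_tolerance(self, fixture_record):
        rec = fixture_record
        read = "A" + rec.mature_seq[1:30] if rec.mature_seq[0] != "A" \
            else "C" + rec.mature_seq[1:30]
        assert map_reads([read], [rec], max_mismatch=0) == []
        hits = map_reads([read], [rec], max_mismatch=1)
        assert len(hits) == 1 and hits[0].mismatches == 1

    def test_empty_reference_set_is_error(self):
        with pytest.raises(ValueError):
            map_reads(["ACGU"], [])


class TestNaming:
    def test_variant_letters_follow_abundance(self, fixture_record):
        rec = fixture_record
        a1 = _aln(rec, 10, 29)          # 20-nt internal fragment
        a2 = _aln(rec, 11, 30)          # distinct 20-nt internal fragment
        frags = collapse_and_name(
            [(a1, rec, TsRNAType.ITRF), (a2, rec, TsRNAType.ITRF)],
            "rno", {a1.read_seq: 10, a2.read_seq: 50})
        by_seq = {f.sequence: f for f in frags}
        assert by_seq[a2.read_seq].name == "rno-tRFi-Gly-20a"
        assert by_seq[a1.read_seq].name == "rno-tRFi-Gly-20b"

    def test_name_carries_type_code_family_and_length(self, fixture_record):
        rec = fixture_record
        ac = rec.loops.anticodon_loop
        aln = _aln(rec, 1, ac.start + 3)
        frags = collapse_and_name([(aln, rec, TsRNAType.TIRNA5)], "rno",
                                  {aln.read_seq: 5})
        assert frags[0].name == f"rno-tiR5-Gly-{ac.start + 3}a"
        parsed = parse_name(frags[0].name)
        assert parsed.length == len(frags[0].sequence)

    def test_too_many_variants_is_error(self, fixture_record):
        rec = fixture_record
        entries, abundance = [], {}
        for k in range(27):
            seq = f"{'A' * (20 - len(str(k)))}{k}"      # 27 distinct "seqs"
            aln = FragmentAlignment(read_seq=seq, trna_id=rec.id,
                                    region="mature", start=10,
                                    end=9 + len(seq))
            entries.append((aln, rec, TsRNAType.ITRF))
            abundance[seq] = 1
        with pytest.raises(ValueError, match="26"):
            collapse_and_name(entries, "rno", abundance)

    @pytest.mark.parametrize("name, parts", [
        ("rno-tRFi-Gln-16a", ("rno", "tRFi", "Gln", 16, "a")),
        ("rno-tiR3-Met-42c", ("rno", "tiR3", "Met", 42, "c")),
        ("rno-tiR5-Lys-35b", ("rno", "tiR5", "Lys", 35, "b")),
        ("rno-tRFi-Ser-25a", ("rno", "tRFi", "Ser", 25, "a")),
    ])
    def test_published_names_parse(self, name, parts):
        p = parse_name(name)
        assert (p.organism, p.type_code, p.amino_acid, p.length, p.variant) \
            == parts
        assert p.render() == name

    @pytest.mark.parametrize("bad", ["rno-tRFx-Gly-20a", "rno-tRFi-Gly-a20",
                                     "tRFi-Gly-20a", "rno-tRFi-Gly-20"])
    def test_malformed_names_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_name(bad)

    @settings(max_examples=200, deadline=None)
    @given(org=st.sampled_from(["rno", "hsa", "mmu"]),
           code=st.sampled_from(["tiR5", "tiR3", "tRF5", "tRF3", "tRFi",
                                 "tRF1"]),
           aa=st.sampled_from(["Ala", "Gly", "Ser", "Met", "Lys"]),
           length=st.integers(min_value=14, max_value=50),
           var=st.sampled_from("abcdefg"))
    def test_name_round_trip(self, org, code, aa, length, var):
        name = TsRNAName(org, code, aa, length, var)
        assert parse_name(name.render()) == name


def test_planted_types_recovered_exactly(small_cfg):
    """With zero sequencing error, every planted fragment classifies to
    its generating type (diagonal confusion matrix)."""
    result = run_pipeline(small_cfg)
    truth = result.fragment_catalog.set_index("sequence")["type"]
    assert len(result.fragments) == len(truth)
    for frag in result.fragments:
        assert frag.type.value == truth[frag.sequence]
        assert parse_name(frag.name).length == len(frag.sequence)
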