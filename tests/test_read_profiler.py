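import itertools

import numpy as np
import pysam
import pytest

from ighrecomb.config import Config
from ighrecomb.locus_model import ReferenceSet
from ighrecomb.read_profiler import (
    AlignedSegment,
    EventClass,
    build_read_evidence,
    choose_reference,
    classify_read,
    detect_cigar_deletions,
    extract_segments,
    junctions_from_segments,
    load_evidence_tsv,
    profile_sample,
    write_evidence_tsv,
)
from ighrecomb.synthetic import (
    CloneMixSpec,
    CloneSpec,
    SimEventSpec,
    simulate_reads,
)

from conftest import profile_simulated, simulate_all_classes


def _header(name="toyIGH", length=100000):
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": name, "LN": length}]}
    )


def _record(header, name, pos, cigar, flag=0, seq_len=None, sa=None):
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.reference_name = header.references[0]
    a.reference_start = pos
    a.flag = flag
    a.cigarstring = cigar
    a.mapping_quality = 60
    if seq_len:
        a.query_sequence = "A" * seq_len
    if sa:
        a.set_tag("SA", sa)
    return a


class TestExtractSegments:
    def test_single_unclipped_record_spans_whole_read(self):
        h = _header()
        segs = extract_segments([_record(h, "r", 1000, "500M", seq_len=500)])
        assert len(segs) == 1
        s = segs[0]
        assert (s.read_start, s.read_end) == (0, 500)
        assert (s.ref_start, s.ref_end) == (1000, 1500)

    def test_complementary_soft_clips_order_by_read_offset(self):
        h = _header()
        recs = [
            _record(h, "r", 5000, "300S200M", seq_len=500),
            _record(h, "r", 1000, "300M200S", flag=2048, seq_len=500),
        ]
        segs = extract_segments(recs)
        assert [(s.read_start, s.read_end) for s in segs] == [(0, 300), (300, 500)]
        assert segs[0].ref_start == 1000 and segs[1].ref_start == 5000

    def test_hard_clips_reconciled_with_soft_clips(self):
        h = _header()
        recs = [
            _record(h, "r", 1000, "300M200S", seq_len=500),
            _record(h, "r", 5000, "300H200M", flag=2048, seq_len=200),
        ]
        segs = extract_segments(recs)
        assert [(s.read_start, s.read_end) for s in segs] == [(0, 300), (300, 500)]

    def test_reverse_strand_offsets_in_original_orientation(self):
        # reverse alignment: leading cigar clip corresponds to read tail
        h = _header()
        segs = extract_segments(
            [_record(h, "r", 1000, "100S400M", flag=16, seq_len=500)]
        )
        assert (segs[0].read_start, segs[0].read_end) == (0, 400)
        assert segs[0].is_reverse

    def test_sa_tag_dialect_matches_records(self, toy_locus, tmp_path):
        sample = simulate_all_classes(toy_locus, depth=25, seed=3)
        sam_r = tmp_path / "r.sam"
        sam_s = tmp_path / "s.sam"
        sample.write_truth_sam(sam_r, style="records")
        sample.write_truth_sam(sam_s, style="sa_only")

        def segs(path):
            out = {}
            with pysam.AlignmentFile(str(path), check_sq=False) as fh:
                grouped = {}
                for rec in fh:
                    grouped.setdefault(rec.query_name, []).append(rec)
            for name, recs in grouped.items():
                out[name] = [
                    (s.read_start, s.read_end, s.ref_start, s.ref_end, s.is_reverse)
                    for s in extract_segments(recs)
                ]
            return out

        assert segs(sam_r) == segs(sam_s)

    def test_inconsistent_read_lengths_rejected(self):
        h = _header()
        recs = [
            _record(h, "r", 1000, "500M", seq_len=500),
            _record(h, "r", 5000, "100M", flag=2048, seq_len=100),
        ]
        with pytest.raises(ValueError, match="inconsistent read lengths"):
            extract_segments(recs)


class TestJunctions:
    def test_breakends_at_anchors_confident(self, toy_locus):
        lm = toy_locus.locus_map
        j_anchor = toy_locus.anchor("IGHJ1", "downstream").position
        v_anchor = toy_locus.anchor("IGHV2", "upstream").position
        segs = [
            AlignedSegment("r", 0, 500, lm.reference, j_anchor - 500, j_anchor, False),
            AlignedSegment("r", 500, 1000, lm.reference, v_anchor, v_anchor + 500, False),
        ]
        (j,) = junctions_from_segments(segs, lm)
        assert j.confident and not j.orientation_flip
        assert j.rss_left[0].gene == "IGHJ1" and j.rss_right[0].gene == "IGHV2"

    def test_far_from_anchor_marked_non_meaningful(self, toy_locus):
        lm = toy_locus.locus_map
        inter = lm.jd_intergenic
        mid = (inter[0] + inter[1]) // 2  # deep intergenic, no anchor nearby
        segs = [
            AlignedSegment("r", 0, 500, lm.reference, mid - 500, mid, False),
            AlignedSegment("r", 500, 1000, lm.reference, mid + 600, mid + 1100, False),
        ]
        (j,) = junctions_from_segments(segs, lm)
        assert not j.meaningful and not j.confident

    def test_inversion_read_has_two_flipped_junctions(self, toy_locus, tmp_path):
        mix = CloneMixSpec(
            clones=[
                CloneSpec(
                    "inv", 1.0, SimEventSpec(EventClass.inversion_DD, ("IGHD2", "IGHD3"))
                )
            ],
            depth=40,
            error_rate=0.0,
            seed=5,
        )
        sample = simulate_reads(toy_locus, mix)
        evs = profile_simulated(toy_locus, sample, tmp_path)
        flipped = [
            e for e in evs if any(j.orientation_flip for j in e.junctions)
        ]
        assert flipped, "no read spanned an inversion breakend"
        both = [e for e in flipped if len(e.junctions) == 2]
        assert all(
            all(j.orientation_flip for j in e.junctions) for e in both
        )


class TestCigarDeletions:
    def _segment_with_deletion(self, toy_locus, del_len, start_shift=0):
        da = toy_locus.locus_map.gene("IGHD2")
        seg_start = da.end - 200 + start_shift
        return AlignedSegment(
            "r",
            0,
            400,
            toy_locus.name,
            seg_start,
            seg_start + 400 + del_len,
            False,
            cigar=[("M", 200), ("D", del_len), ("M", 200)],
        )

    def test_deletion_matching_anchor_distance_confident(self, toy_locus):
        lm = toy_locus.locus_map
        d = lm.gene("IGHD3").start - lm.gene("IGHD2").end
        (j,) = detect_cigar_deletions(self._segment_with_deletion(toy_locus, d), lm)
        assert j.confident and j.origin == "cigar_deletion"
        assert {j.rss_left[0].gene, j.rss_right[0].gene} == {"IGHD2", "IGHD3"}

    def test_short_deletion_ignored(self, toy_locus):
        seg = self._segment_with_deletion(toy_locus, 10)
        assert detect_cigar_deletions(seg, toy_locus.locus_map) == []

    @pytest.mark.parametrize("delta,expected", [(50, 1), (51, 0), (-50, 1), (-51, 0)])
    def test_length_rule_boundary(self, toy_locus, delta, expected):
        lm = toy_locus.locus_map
        d = lm.gene("IGHD3").start - lm.gene("IGHD2").end
        seg = self._segment_with_deletion(toy_locus, d + delta)
        assert len(detect_cigar_deletions(seg, lm)) == expected


class TestClassifyRead:
    def _junction(self, toy_locus, left, right, flip=False):
        lm = toy_locus.locus_map
        la = toy_locus.anchor(*left)
        ra = toy_locus.anchor(*right)
        if flip:
            # reversed right segment: its read-start boundary maps to ref_end
            right_iv = (ra.position - 500, ra.position)
        else:
            right_iv = (ra.position, ra.position + 500)
        segs = [
            AlignedSegment("r", 0, 500, lm.reference, la.position - 500, la.position, False),
            AlignedSegment("r", 500, 1000, lm.reference, right_iv[0], right_iv[1], flip),
        ]
        (j,) = junctions_from_segments(segs, lm)
        return j

    def test_j_to_v_is_complete_vdj(self, toy_locus):
        j = self._junction(toy_locus, ("IGHJ1", "downstream"), ("IGHV3", "upstream"))
        cls, genes = classify_read([j], toy_locus.locus_map)
        assert cls is EventClass.complete_VDJ
        assert genes == [("IGHJ1", "downstream"), ("IGHV3", "upstream")]

    def test_two_junctions_distinct_d_genes_multiple_d(self, toy_locus):
        # RSS skipping: J joined to one D, a different D joined to V
        j1 = self._junction(toy_locus, ("IGHJ2", "downstream"), ("IGHD2", "upstream"))
        j2 = self._junction(toy_locus, ("IGHD4", "downstream"), ("IGHV3", "upstream"))
        cls, genes = classify_read([j1, j2], toy_locus.locus_map)
        assert cls is EventClass.multiple_D
        assert [g for g, _ in genes] == ["IGHJ2", "IGHD2", "IGHD4", "IGHV3"]

    def test_no_junctions_is_unrecombined(self, toy_locus):
        cls, genes = classify_read([], toy_locus.locus_map)
        assert cls is EventClass.unrecombined and genes == []

    def test_flipped_j_d_junction_is_inversion_dj(self, toy_locus):
        j = self._junction(
            toy_locus, ("IGHJ3", "downstream"), ("IGHD2", "downstream"), flip=True
        )
        cls, _ = classify_read([j], toy_locus.locus_map)
        assert cls is EventClass.inversion_DJ

    def test_permutation_invariant(self, toy_locus):
        j1 = self._junction(toy_locus, ("IGHJ2", "downstream"), ("IGHD2", "upstream"))
        j2 = self._junction(toy_locus, ("IGHD4", "downstream"), ("IGHV3", "upstream"))
        assert classify_read([j1, j2], toy_locus.locus_map) == classify_read(
            [j2, j1], toy_locus.locus_map
        )


class TestChooseReference:
    def _evidence(self, toy_locus, reference, confident):
        lm = toy_locus.locus_map
        ja = toy_locus.anchor("IGHJ1", "downstream").position
        va = toy_locus.anchor("IGHV2", "upstream").position
        shift = 0 if confident else 200  # push one breakend off its anchor
        segs = [
            AlignedSegment("r", 0, 500, reference, ja - 500, ja, False),
            AlignedSegment("r", 500, 1000, reference, va + shift, va + shift + 500, False),
        ]
        junctions = junctions_from_segments(segs, lm)
        cls, genes = classify_read(junctions, lm)
        from ighrecomb.read_profiler import ReadEvidence

        return ReadEvidence("r", reference, segs, junctions, cls, genes, confident)

    def test_single_reference_returned(self, toy_locus):
        refset = ReferenceSet([("A", None, toy_locus.locus_map)])
        ev = self._evidence(toy_locus, "A", True)
        assert choose_reference({"A": ev}, refset) is ev

    def test_fully_confident_reference_preferred(self, toy_locus):
        refset = ReferenceSet(
            [("A", None, toy_locus.locus_map), ("B", None, toy_locus.locus_map)]
        )
        good = self._evidence(toy_locus, "A", True)
        partial = self._evidence(toy_locus, "B", False)
        assert choose_reference({"B": partial, "A": good}, refset) is good
        # and the preference is by support, not input order or priority
        refset2 = ReferenceSet(
            [("B", None, toy_locus.locus_map), ("A", None, toy_locus.locus_map)]
        )
        assert choose_reference({"B": partial, "A": good}, refset2) is good

    def test_full_tie_breaks_by_priority_deterministically(self, toy_locus):
        refset = ReferenceSet(
            [("A", None, toy_locus.locus_map), ("B", None, toy_locus.locus_map)],
            priority=["B", "A"],
        )
        ev_a = self._evidence(toy_locus, "A", True)
        ev_b = self._evidence(toy_locus, "B", True)
        first = choose_reference({"A": ev_a, "B": ev_b}, refset)
        second = choose_reference({"A": ev_a, "B": ev_b}, refset)
        assert first is ev_b and second is ev_b


class TestProfileSample:
    def test_monoclonal_error_free_recall(self, toy_locus, tmp_path):
        mix = CloneMixSpec(
            clones=[
                CloneSpec(
                    "p", 0.5, SimEventSpec(EventClass.complete_VDJ, ("IGHJ2", "IGHD3", "IGHV4"))
                ),
                CloneSpec("m", 0.5, SimEventSpec(EventClass.DJ_only, ("IGHJ1", "IGHD2"))),
            ],
            depth=60,
            error_rate=0.0,
            seed=9,
        )
        sample = simulate_reads(toy_locus, mix)
        evs = {e.read_id: e for e in profile_simulated(toy_locus, sample, tmp_path)}
        for r in sample.reads:
            if str(r.expected_class) == "unrecombined":
                continue
            ev = evs[r.read_id]
            assert str(ev.event_class) == str(r.expected_class)
            assert tuple(ev.genes_used) == r.expected_genes

    def test_germline_only_sample_all_unrecombined(self, toy_locus, tmp_path):
        mix = CloneMixSpec(
            clones=[CloneSpec("g", 1.0, None)], depth=25, error_rate=0.0, seed=2
        )
        sample = simulate_reads(toy_locus, mix)
        evs = profile_simulated(toy_locus, sample, tmp_path)
        assert evs and all(e.event_class is EventClass.unrecombined for e in evs)

    def test_multi_d_clone_recovers_true_gene_set(self, toy_locus, tmp_path):
        mix = CloneMixSpec(
            clones=[
                CloneSpec(
                    "md",
                    0.5,
                    SimEventSpec(EventClass.multiple_D, ("IGHJ2", "IGHD2", "IGHD4", "IGHV3")),
                ),
                CloneSpec("g", 0.5, None),
            ],
            depth=60,
            error_rate=0.0,
            seed=13,
        )
        sample = simulate_reads(toy_locus, mix)
        evs = profile_simulated(toy_locus, sample, tmp_path)
        md = [e for e in evs if e.event_class is EventClass.multiple_D]
        assert md
        full = [
            e
            for e in md
            if [g for g, _ in e.genes_used] == ["IGHJ2", "IGHD2", "IGHD4", "IGHV3"]
        ]
        assert full, "no read recovered the full multi-D gene set"


class TestSegmentInvariants:
    def test_segment_coverage_within_read_length(self, toy_locus, tmp_path):
        sample = simulate_all_classes(toy_locus, depth=40, seed=21)
        evs = profile_simulated(toy_locus, sample, tmp_path)
        reads = {r.read_id: r for r in sample.reads}
        for ev in evs:
            total = sum(s.read_end - s.read_start for s in ev.segments)
            assert total <= len(reads[ev.read_id].sequence)
            for a, b in zip(ev.segments, ev.segments[1:]):
                assert b.read_start - a.read_end >= -30  # overlap within slack


# --- brute-force oracle: anchor-assignment enumeration for <= 3 segments ---

def _naive_classify(junction_anchor_pairs):
    """Literal rule table over (left anchor, right anchor, flip) triples."""
    if not junction_anchor_pairs:
        return "unrecombined"
    flips = [t for t in junction_anchor_pairs if t[2]]
    if flips:
        pairs = {frozenset((l.segment_class, r.segment_class)) for l, r, _ in flips}
        if pairs == {frozenset("JD")}:
            return "inversion_DJ"
        if pairs == {frozenset("D")}:
            return "inversion_DD"
        if pairs == {frozenset("DV")}:
            return "inversion_VD"
        return "complex"
    if len(junction_anchor_pairs) == 1:
        l, r, _ = junction_anchor_pairs[0]
        pair = frozenset((l.segment_class, r.segment_class))
        if pair == frozenset("JV"):
            return "complete_VDJ"
        if pair == frozenset("JD"):
            return "DJ_only"
        if pair == frozenset("DV"):
            return "VD_only_or_multiple_D"
        if pair == frozenset("D") and l.gene != r.gene:
            return "multiple_D"
        return "complex"
    d_genes = {a.gene for l, r, _ in junction_anchor_pairs for a in (l, r) if a.segment_class == "D"}
    all_anchors = [a for l, r, _ in junction_anchor_pairs for a in (l, r)]
    if len(d_genes) >= 2:
        return "multiple_D"
    if len(d_genes) == 1:
        d = next(iter(d_genes))
        sides = {a.side for a in all_anchors if a.gene == d}
        if sides == {"upstream", "downstream"} and {"J", "V"} <= {
            a.segment_class for a in all_anchors
        }:
            return "complete_VDJ"
    return "complex"


def test_classification_agrees_with_anchor_enumeration(toy_locus, tmp_path):
    """For reads with <= 3 segments, the classifier matches a brute-force
    enumeration over all anchor assignments within the RSS window (taking
    the minimal-total-distance assignment)."""
    lm = toy_locus.locus_map
    anchors = lm.anchors
    sample = simulate_all_classes(toy_locus, depth=50, seed=17)
    evs = profile_simulated(toy_locus, sample, tmp_path)
    checked = 0
    for ev in evs:
        if len(ev.segments) > 3:
            continue
        conf = [j for j in ev.junctions if j.confident]
        assignments = []
        for j in conf:
            lcands = [
                (a, abs(a.position - j.left.ref_position))
                for a in anchors
                if abs(a.position - j.left.ref_position) <= 50
            ] or ([(j.rss_left[0], 0)] if j.dd_rule else [])
            rcands = [
                (a, abs(a.position - j.right.ref_position))
                for a in anchors
                if abs(a.position - j.right.ref_position) <= 50
            ] or ([(j.rss_right[0], 0)] if j.dd_rule else [])
            assignments.append([(l, r, j.orientation_flip, dl + dr) for (l, dl), (r, dr) in itertools.product(lcands, rcands)])
        if not all(assignments) and conf:
            continue
        best = []
        for options in assignments:
            l, r, flip, _ = min(options, key=lambda t: t[3])
            best.append((l, r, flip))
        naive = _naive_classify(best)
        got = str(ev.event_class)
        if naive == "VD_only_or_multiple_D":
            assert got in ("VD_only", "multiple_D")
        else:
            assert got == naive, ev.read_id
        checked += 1
    assert checked >= 20


def test_evidence_tsv_round_trip(toy_locus, tmp_path):
    sample = simulate_all_classes(toy_locus, depth=25, seed=31)
    evs = profile_simulated(toy_locus, sample, tmp_path)
    path = tmp_path / "ev.tsv"
    write_evidence_tsv(evs, path)
    loaded = load_evidence_tsv(path)
    assert [e.read_id for e in loaded] == [e.read_id for e in evs]
    for a, b in zip(evs, loaded):
        assert str(a.event_class) == str(b.event_class)
        assert a.genes_used == b.genes_used
        assert a.confident == b.confident
        assert [j.confident for j in a.junctions] == [j.confident for j in b.junctions]
        assert [j.meaningful for j in a.junctions] == [j.meaningful for j in b.junctions]
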