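"""Read-level V(D)J recombination evidence from long-read alignments.

A read spanning a somatic recombination junction aligns as two or more
*segments* (split alignment), or — for a deletion between two nearby D
genes — as a single alignment with a long in-CIGAR deletion. This module
normalises alignment records into read-oriented segments, derives
junctions between adjacent segments, matches breakends to RSS anchors,
classifies the read's event, and picks the best-supported reference when
the read was aligned to several.

Classification vocabulary (see :class:`EventClass`):

* ``complete_VDJ`` — one junction joining a J anchor to a V anchor (the
  intervening D is too short for the aligner to split on), or two
  junctions using both sides of a single D gene between a J and a V.
* ``DJ_only`` / ``VD_only`` — partial recombinations.
* ``multiple_D`` — RSS skipping: junctions using two distinct D genes.
* ``inversion_DJ`` / ``inversion_DD`` / ``inversion_VD`` — a junction whose
  flanking segments have opposite orientations, at the stated anchors.
* ``complex`` — meaningful evidence that fits none of the above.
"""

from __future__ import annotations

import enum
import json
import re
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pysam

from .config import Config, DEFAULT_CONFIG
from .locus_model import LocusMap, ReferenceSet, RssAnchor, nearest_rss


class EventClass(str, enum.Enum):
    unrecombined = "unrecombined"
    complete_VDJ = "complete_VDJ"
    DJ_only = "DJ_only"
    VD_only = "VD_only"
    multiple_D = "multiple_D"
    inversion_DJ = "inversion_DJ"
    inversion_DD = "inversion_DD"
    inversion_VD = "inversion_VD"
    complex = "complex"

    def __str__(self) -> str:  # TSV-friendly
        return self.value


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# cigar ops consuming query / reference
_Q_OPS = set("MIS=X")
_R_OPS = set("MDN=X")


@dataclass
class AlignedSegment:
    """One aligned portion of a read, in original read orientation."""

    read_id: str
    read_start: int
    read_end: int
    reference: str
    ref_start: int
    ref_end: int
    is_reverse: bool
    cigar: list[tuple[str, int]] = field(default_factory=list)
    nm: int = 0

    @property
    def read_length_aligned(self) -> int:
        return self.read_end - self.read_start


@dataclass
class Breakend:
    read_offset: int
    ref_position: int
    direction: str  # 'left' or 'right' flank of the junction
    origin: str  # 'split_alignment' or 'cigar_deletion'


@dataclass
class Junction:
    left: Breakend
    right: Breakend
    rss_left: Optional[tuple[RssAnchor, int]]
    rss_right: Optional[tuple[RssAnchor, int]]
    orientation_flip: bool
    origin: str
    adjacent: bool = True
    #: set True by the D-D deletion-length rule even when anchor distances
    #: exceed the RSS window.
    dd_rule: bool = False
    left_segment: Optional[AlignedSegment] = None
    right_segment: Optional[AlignedSegment] = None

    @property
    def meaningful(self) -> bool:
        return self.adjacent and (self.rss_left is not None or self.rss_right is not None)

    @property
    def confident(self) -> bool:
        if self.dd_rule:
            return True
        return self.adjacent and self.rss_left is not None and self.rss_right is not None

    @property
    def n_confident_breakends(self) -> int:
        return int(self.rss_left is not None) + int(self.rss_right is not None)


@dataclass
class ReadEvidence:
    read_id: str
    reference: str
    segments: list[AlignedSegment]
    junctions: list[Junction]
    event_class: EventClass
    genes_used: list[tuple[str, str]]
    confident: bool

    @property
    def has_meaningful(self) -> bool:
        return any(j.meaningful for j in self.junctions)


# ---------------------------------------------------------------------------
# segment extraction
# ---------------------------------------------------------------------------

def _parse_cigar(cig: str) -> list[tuple[str, int]]:
    return [(op, int(n)) for n, op in _CIGAR_RE.findall(cig)]


def _cigar_lengths(cigar: Sequence[tuple[str, int]]) -> tuple[int, int, int, int]:
    """(read length incl. clips, left clip, right clip, ref span)."""
    total = left = right = ref = 0
    seen_aligned = False
    for op, n in cigar:
        if op in "SH":
            total += n
            if seen_aligned:
                right += n
            else:
                left += n
            continue
        if op in _Q_OPS:
            total += n
            seen_aligned = True
        if op in _R_OPS:
            ref += n
            seen_aligned = True
    return total, left, right, ref


def _segment_from_cigar(
    read_id: str,
    reference: str,
    pos0: int,
    is_reverse: bool,
    cigar: Sequence[tuple[str, int]],
    nm: int,
) -> tuple[AlignedSegment, int]:
    total, left, right, ref_span = _cigar_lengths(cigar)
    if is_reverse:
        read_start, read_end = right, total - left
    else:
        read_start, read_end = left, total - right
    seg = AlignedSegment(
        read_id=read_id,
        read_start=read_start,
        read_end=read_end,
        reference=reference,
        ref_start=pos0,
        ref_end=pos0 + ref_span,
        is_reverse=is_reverse,
        cigar=list(cigar),
        nm=nm,
    )
    return seg, total


def extract_segments(records: Sequence[pysam.AlignedSegment]) -> list[AlignedSegment]:
    """Normalise primary + supplementary records of one read into segments.

    Falls back to the SA-tag dialect when supplementary records are absent.
    Hard- and soft-clipped coordinates are reconciled; segments come back
    sorted by read offset in the original read orientation.
    """
    mapped = [r for r in records if not r.is_unmapped and not r.is_secondary]
    if not mapped:
        return []
    read_ids = {r.query_name for r in mapped}
    if len(read_ids) != 1:
        raise ValueError(f"records from multiple reads: {sorted(read_ids)}")
    read_id = read_ids.pop()

    segments: list[AlignedSegment] = []
    lengths: set[int] = set()
    have_supplementary = any(r.is_supplementary for r in mapped)
    for r in mapped:
        cig = [( "MIDNSHP=X"[op], n) for op, n in r.cigartuples]
        nm = r.get_tag("NM") if r.has_tag("NM") else 0
        seg, total = _segment_from_cigar(
            read_id, r.reference_name, r.reference_start, r.is_reverse, cig, nm
        )
        segments.append(seg)
        lengths.add(total)
    if not have_supplementary and len(mapped) == 1 and mapped[0].has_tag("SA"):
        for entry in mapped[0].get_tag("SA").rstrip(";").split(";"):
            rname, pos, strand, cig, _mapq, nm = entry.split(",")
            seg, total = _segment_from_cigar(
                read_id, rname, int(pos) - 1, strand == "-", _parse_cigar(cig), int(nm)
            )
            segments.append(seg)
            lengths.add(total)
    if len(lengths) != 1:
        raise ValueError(f"{read_id}: inconsistent read lengths across records: {lengths}")
    segments.sort(key=lambda s: (s.read_start, s.read_end, s.ref_start))
    return segments


# ---------------------------------------------------------------------------
# junction building
# ---------------------------------------------------------------------------

def _boundary_ref(seg: AlignedSegment, at_read_end: bool, shift: int = 0) -> int:
    """Reference coordinate at a segment's read-interval boundary.

    ``shift`` moves the boundary into the segment interior by that many read
    bases (used when adjacent segments overlap on the read); assumes a
    match-dominated CIGAR near the junction.
    """
    if at_read_end:
        return seg.ref_end - shift if not seg.is_reverse else seg.ref_start + shift
    return seg.ref_start + shift if not seg.is_reverse else seg.ref_end - shift


def junctions_from_segments(
    segments: Sequence[AlignedSegment],
    locus_map: LocusMap,
    config: Config = DEFAULT_CONFIG,
) -> list[Junction]:
    """One junction per adjacent segment pair, with RSS matches filled in.

    When the two segments overlap on the read (aligners sometimes
    double-count a few junction bases) the junction point is the midpoint
    of the overlap. Gaps larger than ``config.adjacency_slack`` leave the
    junction recorded but flagged non-adjacent.
    """
    out: list[Junction] = []
    for a, b in zip(segments, segments[1:]):
        gap = b.read_start - a.read_end
        if gap < 0:
            mid = (a.read_end + b.read_start) // 2
            l_off = r_off = mid
            l_ref = _boundary_ref(a, True, shift=a.read_end - mid)
            r_ref = _boundary_ref(b, False, shift=mid - b.read_start)
            adjacent = True
        else:
            l_off, r_off = a.read_end, b.read_start
            l_ref = _boundary_ref(a, True)
            r_ref = _boundary_ref(b, False)
            adjacent = gap <= config.adjacency_slack
        out.append(
            Junction(
                left=Breakend(l_off, l_ref, "left", "split_alignment"),
                right=Breakend(r_off, r_ref, "right", "split_alignment"),
                rss_left=nearest_rss(locus_map, l_ref, config.rss_window),
                rss_right=nearest_rss(locus_map, r_ref, config.rss_window),
                orientation_flip=a.is_reverse != b.is_reverse,
                origin="split_alignment",
                adjacent=adjacent,
                left_segment=a,
                right_segment=b,
            )
        )
    return out


def detect_cigar_deletions(
    segment: AlignedSegment,
    locus_map: LocusMap,
    config: Config = DEFAULT_CONFIG,
) -> list[Junction]:
    """D-D recombination evidence hidden as long in-CIGAR deletions.

    A deletion of length L counts when the nearest D-gene anchors flanking
    it (downstream-side on the left, upstream-side on the right, two
    distinct genes) lie a distance d apart with ``|L - d| <=
    config.dd_del_tolerance``. The aligner may slide the deletion away from
    the RSSs, so anchor proximity itself is not required.
    """
    d_down = [a for a in locus_map.anchors if a.segment_class == "D" and a.side == "downstream"]
    d_up = [a for a in locus_map.anchors if a.segment_class == "D" and a.side == "upstream"]
    if not d_down or not d_up:
        return []
    out: list[Junction] = []
    ref = segment.ref_start
    # read offset bookkeeping in original orientation
    read = segment.read_start if not segment.is_reverse else segment.read_end
    step = 1 if not segment.is_reverse else -1
    for op, n in segment.cigar:
        if op in "SH":
            continue
        if op in ("M", "=", "X"):
            ref += n
            read += step * n
        elif op == "I":
            read += step * n
        elif op in ("D", "N"):
            p, q = ref, ref + n
            ref += n
            if n < config.cigar_del_min_len:
                continue
            left_anchor = min(d_down, key=lambda a: (abs(a.position - p), locus_map.locus_rank(a.gene)))
            right_anchor = min(d_up, key=lambda a: (abs(a.position - q), locus_map.locus_rank(a.gene)))
            if left_anchor.gene == right_anchor.gene:
                continue
            d = abs(right_anchor.position - left_anchor.position)
            if abs(n - d) > config.dd_del_tolerance:
                continue
            off = read if not segment.is_reverse else read
            out.append(
                Junction(
                    left=Breakend(off, p, "left", "cigar_deletion"),
                    right=Breakend(off, q, "right", "cigar_deletion"),
                    rss_left=(left_anchor, abs(left_anchor.position - p)),
                    rss_right=(right_anchor, abs(right_anchor.position - q)),
                    orientation_flip=False,
                    origin="cigar_deletion",
                    adjacent=True,
                    dd_rule=True,
                    left_segment=segment,
                    right_segment=segment,
                )
            )
    return out


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _anchor_pair(j: Junction) -> list[RssAnchor]:
    out = []
    if j.rss_left:
        out.append(j.rss_left[0])
    if j.rss_right:
        out.append(j.rss_right[0])
    return out


def _d_side_germline_flank(j: Junction, locus_map: LocusMap) -> int:
    """Overlap (bp) between the D-side segment and the J-D intergenic gap."""
    inter = locus_map.jd_intergenic
    if inter is None:
        return 0
    seg = None
    if j.rss_left and j.rss_left[0].segment_class == "D":
        seg = j.left_segment
    elif j.rss_right and j.rss_right[0].segment_class == "D":
        seg = j.right_segment
    if seg is None:
        return 0
    lo, hi = max(seg.ref_start, inter[0]), min(seg.ref_end, inter[1])
    return max(0, hi - lo)


def _genes_sorted(anchors: Iterable[RssAnchor], locus_map: LocusMap) -> list[tuple[str, str]]:
    seen = []
    for a in anchors:
        key = (a.gene, a.side)
        if key not in seen:
            seen.append(key)
    seen.sort(key=lambda g: (locus_map.locus_rank(g[0]), g[1] != "upstream"))
    return seen


def classify_read(
    junctions: Sequence[Junction],
    locus_map: LocusMap,
    config: Config = DEFAULT_CONFIG,
) -> tuple[EventClass, list[tuple[str, str]]]:
    """Apply the event grammar to one read's junctions (any input order)."""
    if not junctions:
        return EventClass.unrecombined, []
    conf = [j for j in junctions if j.confident]
    conf.sort(key=lambda j: j.left.read_offset)
    if not conf:
        return EventClass.complex, []

    flips = [j for j in conf if j.orientation_flip]
    anchors = [a for j in conf for a in _anchor_pair(j)]
    genes = _genes_sorted(anchors, locus_map)

    if flips:
        pairs = {frozenset(a.segment_class for a in _anchor_pair(j)) for j in flips}
        if len(pairs) == 1:
            pair = next(iter(pairs))
            if pair == {"J", "D"}:
                return EventClass.inversion_DJ, genes
            if pair == {"D"}:
                return EventClass.inversion_DD, genes
            if pair == {"D", "V"}:
                return EventClass.inversion_VD, genes
        return EventClass.complex, genes

    d_genes = {a.gene for a in anchors if a.segment_class == "D"}
    if len(conf) == 1:
        j = conf[0]
        pair = _anchor_pair(j)
        classes = frozenset(a.segment_class for a in pair)
        if classes == {"J", "V"}:
            return EventClass.complete_VDJ, genes
        if classes == {"J", "D"}:
            return EventClass.DJ_only, genes
        if classes == {"D", "V"}:
            if _d_side_germline_flank(j, locus_map) >= config.vd_flank_min:
                return EventClass.VD_only, genes
            return EventClass.multiple_D, genes
        if classes == {"D"} and len({a.gene for a in pair}) == 2:
            return EventClass.multiple_D, genes
        return EventClass.complex, genes

    if len(d_genes) >= 2:
        return EventClass.multiple_D, genes
    seg_classes = {a.segment_class for a in anchors}
    if len(d_genes) == 1:
        d = next(iter(d_genes))
        sides = {a.side for a in anchors if a.gene == d}
        if sides == {"upstream", "downstream"} and {"J", "V"} <= seg_classes:
            non_d = [g for g in genes if g[0] != d]
            return EventClass.complete_VDJ, non_d
    return EventClass.complex, genes


# ---------------------------------------------------------------------------
# per-read evidence, reference choice, sample profiling
# ---------------------------------------------------------------------------

def build_read_evidence(
    records: Sequence[pysam.AlignedSegment],
    reference: str,
    locus_map: LocusMap,
    config: Config = DEFAULT_CONFIG,
) -> ReadEvidence:
    segments = extract_segments(records)
    junctions = junctions_from_segments(segments, locus_map, config)
    for seg in segments:
        junctions.extend(detect_cigar_deletions(seg, locus_map, config))
    event, genes = classify_read(junctions, locus_map, config)
    meaningful = [j for j in junctions if j.meaningful]
    confident = bool(meaningful) and all(j.confident for j in meaningful)
    return ReadEvidence(
        read_id=segments[0].read_id if segments else "",
        reference=reference,
        segments=segments,
        junctions=junctions,
        event_class=event,
        genes_used=genes,
        confident=confident and event is not EventClass.unrecombined,
    )


def _evidence_rank(ev: ReadEvidence, reference_set: ReferenceSet) -> tuple:
    all_conf = bool(ev.junctions) and all(j.confident for j in ev.junctions)
    n_conf_breakends = sum(j.n_confident_breakends for j in ev.junctions)
    n_bad = sum(1 for j in ev.junctions if not j.meaningful) + (
        1 if ev.event_class is EventClass.complex else 0
    )
    return (
        int(all_conf),
        n_conf_breakends,
        -n_bad,
        -reference_set.priority_rank(ev.reference),
    )


def choose_reference(
    per_reference_evidence: Mapping[str, ReadEvidence],
    reference_set: ReferenceSet,
) -> ReadEvidence:
    """Pick the best-supported evidence across references.

    Rank: (1) all breakends RSS-confident, (2) count of RSS-confident
    breakends, (3) fewer complex/non-meaningful junctions, (4) fixed
    priority order. Deterministic for identical input.
    """
    if not per_reference_evidence:
        raise ValueError("no reference produced evidence for this read")
    return max(
        per_reference_evidence.values(),
        key=lambda ev: _evidence_rank(ev, reference_set),
    )


def _overlaps_jd(segments: Sequence[AlignedSegment], locus_map: LocusMap) -> bool:
    jd = locus_map.jd_interval
    if jd is None:
        return False
    return any(s.ref_start < jd[1] and s.ref_end > jd[0] for s in segments)


def _only_vv_junctions(ev: ReadEvidence) -> bool:
    """True when every junction joins two V anchors (germline SV evidence)."""
    if not ev.junctions:
        return False
    for j in ev.junctions:
        pair = _anchor_pair(j)
        if len(pair) < 2 or any(a.segment_class != "V" for a in pair):
            return False
    return True


def profile_sample(
    alignments: Mapping[str, str],
    reference_set: ReferenceSet,
    config: Config = DEFAULT_CONFIG,
) -> list[ReadEvidence]:
    """Profile every read overlapping the J-D interval on some reference.

    ``alignments`` maps reference name to a SAM/BAM path aligned against
    that reference. Reads whose only junctions join two V genes are
    treated as potential germline SV evidence and dropped. Output is in
    lexicographic read-id order.
    """
    if not reference_set.members:
        raise ValueError("empty reference set")
    per_read: dict[str, dict[str, ReadEvidence]] = defaultdict(dict)
    for ref_name, path in alignments.items():
        locus_map = reference_set.locus_map(ref_name)
        grouped: dict[str, list] = defaultdict(list)
        with pysam.AlignmentFile(str(path), check_sq=False) as fh:
            for rec in fh:
                if rec.is_unmapped or rec.is_secondary:
                    continue
                grouped[rec.query_name].append(rec)
        for read_id in grouped:
            ev = build_read_evidence(grouped[read_id], ref_name, locus_map, config)
            if not _overlaps_jd(ev.segments, locus_map):
                continue
            if _only_vv_junctions(ev):
                continue
            per_read[read_id][ref_name] = ev
    out = []
    for read_id in sorted(per_read):
        out.append(choose_reference(per_read[read_id], reference_set))
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_EVIDENCE_COLUMNS = (
    "read_id",
    "reference",
    "event_class",
    "confident",
    "genes_used",
    "junctions",
)


def _junction_str(j: Junction) -> str:
    return "|".join(
        [
            str(j.left.read_offset),
            str(j.right.read_offset),
            str(j.left.ref_position),
            str(j.right.ref_position),
            "F" if j.orientation_flip else ".",
            j.origin,
            "M" if j.meaningful else ".",
            "C" if j.confident else ".",
        ]
    )


def write_evidence_tsv(evidences: Sequence[ReadEvidence], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_EVIDENCE_COLUMNS) + "\n")
        for ev in evidences:
            genes = ",".join(f"{g}:{s}" for g, s in ev.genes_used)
            juncs = ";".join(_junction_str(j) for j in ev.junctions)
            fh.write(
                "\t".join(
                    [
                        ev.read_id,
                        ev.reference,
                        str(ev.event_class),
                        "1" if ev.confident else "0",
                        genes or ".",
                        juncs or ".",
                    ]
                )
                + "\n"
            )


def load_evidence_tsv(path) -> list[ReadEvidence]:
    """Rehydrate evidence written by :func:`write_evidence_tsv`.

    Segments are not serialised; junction breakend offsets (enough for
    read surgery and clonality) are restored.
    """
    out: list[ReadEvidence] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: header.index(c) for c in _EVIDENCE_COLUMNS}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            genes = []
            if parts[idx["genes_used"]] != ".":
                for tok in parts[idx["genes_used"]].split(","):
                    g, s = tok.rsplit(":", 1)
                    genes.append((g, s))
            restored = []
            if parts[idx["junctions"]] != ".":
                for tok in parts[idx["junctions"]].split(";"):
                    lo, ro, lr, rr, flip, origin, mean, confd = tok.split("|")
                    j = Junction(
                        left=Breakend(int(lo), int(lr), "left", origin),
                        right=Breakend(int(ro), int(rr), "right", origin),
                        rss_left=None,
                        rss_right=None,
                        orientation_flip=flip == "F",
                        origin=origin,
                        adjacent=mean == "M" or confd == "C",
                        # confident junctions round-trip via the dd_rule flag
                        dd_rule=confd == "C",
                    )
                    if mean == "M":
                        # sentinel anchor so meaningful() survives the trip
                        j.rss_left = (
                            RssAnchor("?", "V", "upstream", j.left.ref_position),
                            0,
                        )
                    restored.append(j)
            out.append(
                ReadEvidence(
                    read_id=parts[idx["read_id"]],
                    reference=parts[idx["reference"]],
                    segments=[],
                    junctions=restored,
                    event_class=EventClass(parts[idx["event_class"]]),
                    genes_used=genes,
                    confident=parts[idx["confident"]] == "1",
                )
            )
    return out


def event_summary(evidences: Sequence[ReadEvidence]) -> dict:
    counts: dict[str, int] = defaultdict(int)
    for ev in evidences:
        counts[str(ev.event_class)] += 1
    return {"n_reads": len(evidences), "event_counts": dict(sorted(counts.items()))}


def write_event_summary(evidences: Sequence[ReadEvidence], path) -> None:
    with open(path, "w") as fh:
        json.dump(event_summary(evidences), fh, indent=2)
        fh.write("\n")
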