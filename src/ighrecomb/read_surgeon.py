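"""Read preprocessing for germline reassembly.

Two steps: (1) *surgery* — reads carrying somatic V(D)J junction evidence
are cut at the junction positions, breaking the somatic haplotype while
leaving germline reads intact; (2) *enrichment* — reads or fragments whose
alignments touch the J-D region are duplicated to counter the read
depletion that recombination causes there. Enriched output is meant only
for de novo assembly; downstream polishing uses the split, unenriched
reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pysam

from .config import DEFAULT_CONFIG
from .locus_model import LocusMap
from .read_profiler import EventClass, ReadEvidence


@dataclass
class ReadRecord:
    name: str
    sequence: str
    quality: Optional[str] = None
    is_duplicate: bool = False

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"{self.name}: quality/sequence length mismatch")

    @property
    def header(self) -> str:
        return f"{self.name} dup" if self.is_duplicate else self.name


@dataclass
class SurgeryPlan:
    cuts: dict[str, list[int]] = field(default_factory=dict)

    def add(self, read_id: str, offset: int) -> None:
        offsets = self.cuts.setdefault(read_id, [])
        if offset not in offsets:
            offsets.append(offset)
            offsets.sort()


@dataclass
class EnrichmentRegion:
    """Per-reference interval that triggers duplication (J-D span + flank)."""

    intervals: dict[str, tuple[int, int]]

    @classmethod
    def from_locus_maps(
        cls, locus_maps: Iterable[LocusMap], flank: int = 0
    ) -> "EnrichmentRegion":
        intervals = {}
        for lm in locus_maps:
            jd = lm.jd_interval
            if jd is not None:
                intervals[lm.reference] = (max(0, jd[0] - flank), jd[1] + flank)
        return cls(intervals)

    def overlaps(self, reference: str, start: int, end: int) -> bool:
        iv = self.intervals.get(reference)
        return iv is not None and start < iv[1] and end > iv[0]


def plan_surgery(evidences: Sequence[ReadEvidence]) -> SurgeryPlan:
    """One cut per somatic junction, at the junction midpoint on the read.

    Junctions between two V anchors are germline-SV candidates and yield
    no cut; unrecombined reads are absent from the plan.
    """
    plan = SurgeryPlan()
    for ev in evidences:
        if ev.event_class is EventClass.unrecombined:
            continue
        for j in ev.junctions:
            if not j.meaningful:
                continue
            anchors = [x[0] for x in (j.rss_left, j.rss_right) if x is not None]
            if len(anchors) == 2 and all(a.segment_class == "V" for a in anchors):
                continue
            plan.add(ev.read_id, (j.left.read_offset + j.right.read_offset) // 2)
    return plan


def apply_surgery(
    reads: Iterable[ReadRecord],
    plan: SurgeryPlan,
    min_fragment: int = DEFAULT_CONFIG.min_fragment,
) -> tuple[list[ReadRecord], list[tuple[str, int]]]:
    """Cut reads per plan; fragments named ``read_id/1``, ``read_id/2``...

    The concatenation of a read's fragments equals the original sequence;
    fragments shorter than ``min_fragment`` are dropped and logged as
    (fragment name, length). Reads absent from the plan pass through
    unchanged.
    """
    out: list[ReadRecord] = []
    dropped: list[tuple[str, int]] = []
    for rec in reads:
        offsets = plan.cuts.get(rec.name)
        if not offsets:
            out.append(rec)
            continue
        if any(not 0 < o < len(rec.sequence) for o in offsets):
            raise ValueError(f"{rec.name}: cut offset out of range")
        bounds = [0, *sorted(offsets), len(rec.sequence)]
        for k, (a, b) in enumerate(zip(bounds, bounds[1:]), start=1):
            frag = ReadRecord(
                f"{rec.name}/{k}",
                rec.sequence[a:b],
                rec.quality[a:b] if rec.quality else None,
            )
            if b - a < min_fragment:
                dropped.append((frag.name, b - a))
            else:
                out.append(frag)
    return out, dropped


def enrich_reads(
    reads: Sequence[ReadRecord],
    alignments: Mapping[str, list[tuple[str, int, int]]],
    region: EnrichmentRegion,
    factor: int = DEFAULT_CONFIG.enrich_factor,
) -> list[ReadRecord]:
    """Duplicate reads whose alignment overlaps the J-D region.

    ``alignments`` maps read name to (reference, start, end) placements on
    any member reference. Overlapping reads are emitted ``factor`` times
    (copies flagged as duplicates), all others once.
    """
    out: list[ReadRecord] = []
    for rec in reads:
        out.append(rec)
        hit = any(
            region.overlaps(ref, s, e) for ref, s, e in alignments.get(rec.name, [])
        )
        if hit:
            for _ in range(factor - 1):
                out.append(
                    ReadRecord(rec.name, rec.sequence, rec.quality, is_duplicate=True)
                )
    return out


def alignments_from_sam(path) -> dict[str, list[tuple[str, int, int]]]:
    """Collect (reference, start, end) placements per read from a SAM/BAM."""
    out: dict[str, list[tuple[str, int, int]]] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            out.setdefault(rec.query_name, []).append(
                (rec.reference_name, rec.reference_start, rec.reference_end)
            )
    return out


# ---------------------------------------------------------------------------
# FASTA/FASTQ I/O (fragment dialect ``readid/k``, duplicates ``readid dup``)
# ---------------------------------------------------------------------------

def read_fastx(path) -> list[ReadRecord]:
    from Bio import SeqIO

    fmt = "fastq" if str(path).endswith(("fastq", "fq")) else "fasta"
    out = []
    for rec in SeqIO.parse(str(path), fmt):
        qual = None
        if fmt == "fastq":
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(ReadRecord(rec.id, str(rec.seq).upper(), qual))
    return out


def write_fastx(records: Sequence[ReadRecord], path) -> None:
    fastq = str(path).endswith(("fastq", "fq"))
    with open(path, "w") as fh:
        for r in records:
            if fastq:
                q = r.quality or "I" * len(r.sequence)
                fh.write(f"@{r.header}\n{r.sequence}\n+\n{q}\n")
            else:
                fh.write(f">{r.header}\n{r.sequence}\n")
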