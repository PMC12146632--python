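"""SV typing, haplotype reconciliation, personalized reference, masking.

The population carries a small catalogue of common IGH structural
variants (six large deletions plus one complex two-haplotype variant).
Contig gene content types each SV per contig: a contig carrying the genes
flanking a deletion but none of the genes inside it supports the deletion
allele; carrying an inside gene supports the default; otherwise the call
is unknown. Per-parental-group calls are consolidated, conflicts are
reconciled by moving single contigs between groups, and a personalized
guide reference is stitched from a segment registry onto a backbone, one
alternative segment per non-default SV call. Finally, guided-assembly
output can be masked: positions with neither read nor contig support are
replaced by N so no guide-reference sequence survives unsupported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pysam

from .config import Config, DEFAULT_CONFIG
from .locus_model import LocusMap

DEFAULT_CALL = "default"
ALT_CALL = "alternative"
UNKNOWN_CALL = "unknown"


@dataclass(frozen=True)
class SvDefinition:
    sv_id: int
    kind: str  # 'deletion' or 'complex'
    inside_genes: tuple[str, ...]
    flank_genes: tuple[str, str]
    hapA_genes: tuple[str, ...] = ()
    hapB_genes: tuple[str, ...] = ()
    source_default: str = "backbone"
    source_alternative: str = "alternative"

    def __post_init__(self) -> None:
        if self.kind == "deletion" and not self.inside_genes:
            raise ValueError(f"SV{self.sv_id}: deletion needs inside genes")
        if self.kind == "complex":
            if set(self.hapA_genes) & set(self.hapB_genes):
                raise ValueError(f"SV{self.sv_id}: hapA/hapB gene sets must be disjoint")
        if self.kind not in ("deletion", "complex"):
            raise ValueError(self.kind)


@dataclass
class AlleleCall:
    contig: str
    sv_id: int
    call: str

    def __post_init__(self) -> None:
        if self.call not in (DEFAULT_CALL, ALT_CALL, UNKNOWN_CALL):
            raise ValueError(self.call)


@dataclass
class HaplotypeGroup:
    label: str
    contigs: list[str]
    consolidated: dict[int, str] = field(default_factory=dict)
    conflicts: list[int] = field(default_factory=list)

    @property
    def conflict(self) -> bool:
        return bool(self.conflicts)


@dataclass
class PersonalReference:
    name: str
    sequence: str
    provenance: list[tuple[int, int, str]]


@dataclass
class MaskedAssembly:
    sequences: dict[str, str]
    mask_log: list[tuple[str, int, int, str]]
    dropped_contigs: list[str]


def human_sv_catalog() -> list[SvDefinition]:
    """The seven catalogued common IGH SVs (real gene names).

    Shipped for reference/CLI use against real annotations; the test
    fixtures exercise the same logic on a toy catalogue.
    """
    return [
        SvDefinition(1, "deletion", ("IGHD2-8", "IGHD1-7", "IGHD6-6", "IGHD5-5",
                                     "IGHD4-4", "IGHD3-3"),
                     ("IGHD3-9", "IGHD2-2"), source_default="CHM13",
                     source_alternative="HG02148"),
        SvDefinition(2, "deletion", ("IGHV7-4-1",), ("IGHV4-4", "IGHV1-3"),
                     source_default="CHM13", source_alternative="GRCh37"),
        SvDefinition(3, "complex", (), ("IGHV3-7", "IGHV3-11"),
                     hapA_genes=("IGHV1-8", "IGHV3-9"),
                     hapB_genes=("IGHV3-64D", "IGHV5-10-1"),
                     source_default="CHM13", source_alternative="GRCh38"),
        SvDefinition(4, "deletion", ("IGHV3-23D",), ("IGHV3-23", "IGHV3-25"),
                     source_default="Custom", source_alternative="CHM13"),
        SvDefinition(5, "deletion", ("IGHV4-30-2", "IGHV3-30-3", "IGHV4-30-4",
                                     "IGHV3-30-5", "IGHV4-31", "IGHV3-33"),
                     ("IGHV3-30", "IGHV3-33-2"), source_default="CHM13",
                     source_alternative="GRCh38"),
        SvDefinition(6, "deletion", ("IGHV4-38-2", "IGHV3-43D", "IGHV3-38-3",
                                     "IGHV1-38-4"),
                     ("IGHV3-38", "IGHV4-39"), source_default="Custom",
                     source_alternative="CHM13"),
        SvDefinition(7, "deletion", ("IGHV2-70D", "IGHV1-69-2", "IGHV1-69D"),
                     ("IGHV1-69", "IGHV2-70"), source_default="CHM13",
                     source_alternative="GRCh38"),
    ]


# ---------------------------------------------------------------------------
# SV typing
# ---------------------------------------------------------------------------

def type_sv_alleles(profile, catalog: Sequence[SvDefinition]) -> list[AlleleCall]:
    """Call each catalogued SV from one contig's gene content.

    ``profile`` needs only ``contig`` and ``gene_names`` attributes
    (an :class:`ighrecomb.asm_assessor.ContigProfile` after duplicate-name
    assignment). Invariant under hit order and contig orientation, since
    only the gene *set* matters.
    """
    genes = set(profile.gene_names)
    out = []
    for sv in catalog:
        if sv.kind == "deletion":
            if genes & set(sv.inside_genes):
                call = DEFAULT_CALL
            elif all(g in genes for g in sv.flank_genes):
                call = ALT_CALL
            else:
                call = UNKNOWN_CALL
        else:
            a = bool(genes & set(sv.hapA_genes))
            b = bool(genes & set(sv.hapB_genes))
            call = DEFAULT_CALL if a and not b else ALT_CALL if b and not a else UNKNOWN_CALL
        out.append(AlleleCall(profile.contig, sv.sv_id, call))
    return out


def genotype_from_genes(genes: Iterable[str], catalog: Sequence[SvDefinition]) -> dict[int, str]:
    """SV genotype implied by a gene presence set (e.g. a re-annotated
    stitched haplotype)."""

    class _P:
        contig = "_"
        gene_names = list(genes)

    return {c.sv_id: c.call for c in type_sv_alleles(_P(), catalog)}


def consolidate_group(
    label: str,
    contigs: Sequence[str],
    contig_calls: Mapping[str, Mapping[int, str]],
) -> HaplotypeGroup:
    """Merge per-contig calls; unknowns are compatible with anything,
    default vs alternative on one SV is a conflict."""
    merged: dict[int, str] = {}
    conflicts: list[int] = []
    for contig in contigs:
        for sv_id, call in contig_calls.get(contig, {}).items():
            if call == UNKNOWN_CALL:
                merged.setdefault(sv_id, UNKNOWN_CALL)
                continue
            prev = merged.get(sv_id, UNKNOWN_CALL)
            if prev == UNKNOWN_CALL:
                merged[sv_id] = call
            elif prev != call:
                if sv_id not in conflicts:
                    conflicts.append(sv_id)
    return HaplotypeGroup(label, sorted(contigs), merged, sorted(conflicts))


def reconcile_haplotypes(
    paternal: Sequence[str],
    maternal: Sequence[str],
    contig_calls: Mapping[str, Mapping[int, str]],
) -> tuple[dict[str, HaplotypeGroup], str]:
    """Resolve within-group SV conflicts by moving single contigs.

    Tries the current assignment first, then every single-contig move
    between groups in lexicographic contig order, accepting the first
    conflict-free assignment. Returns the groups and a status of ``ok``,
    ``reconciled`` or ``manual_required``.
    """

    def groups_for(pat, mat):
        return {
            "paternal": consolidate_group("paternal", pat, contig_calls),
            "maternal": consolidate_group("maternal", mat, contig_calls),
        }

    current = groups_for(paternal, maternal)
    if not any(g.conflict for g in current.values()):
        return current, "ok"
    for contig in sorted([*paternal, *maternal]):
        if contig in paternal:
            pat = [c for c in paternal if c != contig]
            mat = [*maternal, contig]
        else:
            pat = [*paternal, contig]
            mat = [c for c in maternal if c != contig]
        attempt = groups_for(pat, mat)
        if not any(g.conflict for g in attempt.values()):
            return attempt, "reconciled"
    return current, "manual_required"


# ---------------------------------------------------------------------------
# segment registry and stitching
# ---------------------------------------------------------------------------

@dataclass
class SegmentRegistry:
    """Named sequence segments standing in for the SV source references.

    Abstracts the five source representations the guide reference is
    stitched from; ``segments`` maps (sv_id, allele) to the replacement
    sequence, ``backbone`` is the default full-locus sequence.
    """

    backbone: str
    segments: dict[tuple[int, str], str] = field(default_factory=dict)

    def segment(self, sv_id: int, allele: str) -> str:
        try:
            return self.segments[(sv_id, allele)]
        except KeyError:
            raise KeyError(f"registry lacks segment for SV{sv_id}/{allele}") from None

    @classmethod
    def from_files(cls, registry_json, fasta_path) -> "SegmentRegistry":
        from .synthetic import read_fasta

        with open(registry_json) as fh:
            spec = json.load(fh)
        records = read_fasta(fasta_path)
        segments = {}
        for sv_id, alleles in spec.get("segments", {}).items():
            for allele, rec in alleles.items():
                segments[(int(sv_id), allele)] = records[rec]
        return cls(records[spec["backbone"]], segments)


def _sv_span(sv: SvDefinition, locus_map: LocusMap) -> tuple[int, int]:
    """Backbone span replaced for an SV: flank genes included, junctions at
    the midpoint between each flank gene and its nearest outside
    neighbour (deterministic placement)."""
    gl = locus_map.gene(sv.flank_genes[0])
    gr = locus_map.gene(sv.flank_genes[1])
    if gl.start > gr.start:
        gl, gr = gr, gl
    before = [g for g in locus_map.genes if g.end <= gl.start]
    after = [g for g in locus_map.genes if g.start >= gr.end]
    left = (before[-1].end + gl.start) // 2 if before else max(0, gl.start - 100)
    right = (gr.end + after[0].start) // 2 if after else gr.end + 100
    return left, right


def build_personal_reference(
    calls: Mapping[int, str],
    catalog: Sequence[SvDefinition],
    registry: SegmentRegistry,
    locus_map: LocusMap,
    name: str = "personal",
) -> PersonalReference:
    """Stitch a per-haplotype guide reference from the backbone.

    SVs with an ``alternative`` consolidated call have their span swapped
    for the registered alternative segment; ``default`` and ``unknown``
    keep the backbone. Provenance intervals tile the output exactly.
    """
    spans = []
    for sv in sorted(catalog, key=lambda s: _sv_span(s, locus_map)[0]):
        span = _sv_span(sv, locus_map)
        if spans and span[0] < spans[-1][1][1]:
            raise ValueError(f"SV{sv.sv_id} span overlaps the previous SV span")
        spans.append((sv, span))
    pieces: list[tuple[str, str]] = []
    cursor = 0
    backbone = registry.backbone
    for sv, (lo, hi) in spans:
        if cursor < lo:
            pieces.append((backbone[cursor:lo], "backbone"))
        if calls.get(sv.sv_id, UNKNOWN_CALL) == ALT_CALL:
            pieces.append((registry.segment(sv.sv_id, ALT_CALL), sv.source_alternative))
        else:
            pieces.append((backbone[lo:hi], sv.source_default))
        cursor = hi
    if cursor < len(backbone):
        pieces.append((backbone[cursor:], "backbone"))
    seq_parts = []
    provenance = []
    pos = 0
    for seq, source in pieces:
        seq_parts.append(seq)
        provenance.append((pos, pos + len(seq), source))
        pos += len(seq)
    return PersonalReference(name, "".join(seq_parts), provenance)


# ---------------------------------------------------------------------------
# masking
# ---------------------------------------------------------------------------

def _read_coverage(assembly: Mapping[str, str], alignment_path) -> dict[str, np.ndarray]:
    """Per-base read coverage, counting secondary/supplementary records
    and bases spanned by deletions (mirrors ``depth -a -g 0x100 -J``)."""
    cov = {name: np.zeros(len(seq), dtype=np.int32) for name, seq in assembly.items()}
    if alignment_path is None:
        return cov
    with pysam.AlignmentFile(str(alignment_path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            if rec.reference_name not in cov:
                raise ValueError(f"alignment target {rec.reference_name!r} not in assembly")
            cov[rec.reference_name][rec.reference_start : rec.reference_end] += 1
    return cov


def contig_support_from_sam(
    assembly: Mapping[str, str],
    alignment_path,
    config: Config = DEFAULT_CONFIG,
) -> dict[str, list[tuple[int, int]]]:
    """Support intervals from de novo contigs aligned to the assembly.

    An alignment counts when it is long and accurate enough
    (``contig_support_min_len``, ``contig_support_min_identity``;
    identity inferred from the NM tag when present).
    """
    out: dict[str, list[tuple[int, int]]] = {name: [] for name in assembly}
    with pysam.AlignmentFile(str(alignment_path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary:
                continue
            span = rec.reference_end - rec.reference_start
            if span < config.contig_support_min_len:
                continue
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            if 1 - nm / span < config.contig_support_min_identity:
                continue
            out[rec.reference_name].append((rec.reference_start, rec.reference_end))
    return out


def mask_unsupported(
    assembly: Mapping[str, str],
    read_alignments=None,
    contig_support: Optional[Mapping[str, Sequence[tuple[int, int]]]] = None,
) -> MaskedAssembly:
    """Mask guide-reference carry-over: N out positions with neither read
    coverage nor contig support; drop scaffolds with no contig support at
    all (when contig support information is supplied). Lengths of retained
    sequences are preserved and the operation is idempotent.
    """
    read_cov = _read_coverage(assembly, read_alignments)
    out: dict[str, str] = {}
    log: list[tuple[str, int, int, str]] = []
    dropped: list[str] = []
    for name, seq in assembly.items():
        intervals = list(contig_support.get(name, [])) if contig_support is not None else None
        if intervals is not None and not intervals:
            dropped.append(name)
            log.append((name, 0, len(seq), "no_contig_support"))
            continue
        ccov = np.zeros(len(seq), dtype=bool)
        for s, e in intervals or []:
            ccov[s:e] = True
        unsupported = (read_cov[name] == 0) & ~ccov
        if unsupported.any():
            chars = np.frombuffer(seq.upper().encode(), dtype="S1").copy()
            chars[unsupported] = b"N"
            out[name] = chars.tobytes().decode()
            # contiguous runs for the log
            idx = np.flatnonzero(unsupported)
            run_start = idx[0]
            prev = idx[0]
            for i in idx[1:]:
                if i != prev + 1:
                    log.append((name, int(run_start), int(prev + 1), "no_support"))
                    run_start = i
                prev = i
            log.append((name, int(run_start), int(prev + 1), "no_support"))
        else:
            out[name] = seq
    return MaskedAssembly(out, log, dropped)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_calls_tsv(calls: Sequence[AlleleCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tsv_id\tcall\n")
        for c in calls:
            fh.write(f"{c.contig}\t{c.sv_id}\t{c.call}\n")


def load_calls_tsv(path) -> list[AlleleCall]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            contig, sv_id, call = line.rstrip("\n").split("\t")
            out.append(AlleleCall(contig, int(sv_id), call))
    return out
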