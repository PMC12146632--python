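"""Synthetic IGH fixtures: toy loci, recombined haplotypes, reads, truth.

The generator emulates the study system at desk scale: a miniature IGH
locus laid out in J -> D -> V order with point RSS anchors at recombining
gene boundaries, germline haplotypes (optionally carrying catalogued SV
alleles), clone mixtures whose haplotypes carry canonical and
non-canonical V(D)J recombination events, and HiFi-like reads with
substitution-only errors plus *truth alignments* written directly as SAM
(with supplementary records and SA tags), so the whole event-calling
stack is testable without running an aligner.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pysam

from .config import Config, DEFAULT_CONFIG
from .locus_model import GeneAnnotation, LocusMap, RssAnchor, write_locus_map
from .read_profiler import EventClass

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")
HEPTAMER = "CACAGTG"  # conserved RSS heptamer, decorative flavour in spacers


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


# ---------------------------------------------------------------------------
# toy locus
# ---------------------------------------------------------------------------

@dataclass
class ToyLocusSpec:
    """Layout parameters of the miniature locus.

    Gene lengths follow the real locus scale: J ~60 bp, D ~20 bp (human D
    genes never exceed 40 bp), V ~300 bp. Spacings are compressed ~20x so
    a few-kilobase read plays the role of a HiFi read over the ~1 Mb
    locus. ``pad`` emulates the flanking non-IGH chromosome sequence and
    defaults to a full read length, so junction-spanning probabilities are
    not biased by the sequence ends.
    """

    n_j: int = 3
    n_d: int = 5
    n_v: int = 8
    j_len: int = 60
    d_len: int = 20
    v_len: int = 300
    j_spacer: int = 400
    d_spacer: int = 400
    v_spacer: int = 800
    jd_gap: int = 2000
    dv_gap: int = 1500
    pad: int = 4000
    n_pseudo_v: int = 1
    seed: int = 0
    reference_name: str = "toyIGH"

    def __post_init__(self) -> None:
        if min(self.n_j, self.n_d, self.n_v) < 1:
            raise ValueError("gene counts must be >= 1")


@dataclass
class ToyLocus:
    spec: ToyLocusSpec
    name: str
    seq: str
    locus_map: LocusMap
    allele_db: dict[str, str]  # "GENE*01" -> sequence

    def write_reference(self, path) -> None:
        _write_fasta({self.name: self.seq}, path)

    def write_annotation(self, path) -> None:
        write_locus_map(self.locus_map, path)

    def write_allele_db(self, path) -> None:
        _write_fasta(self.allele_db, path)

    def anchor(self, gene: str, side: str) -> RssAnchor:
        for a in self.locus_map.anchors:
            if a.gene == gene and a.side == side:
                return a
        raise KeyError((gene, side))


def _write_fasta(records: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def make_toy_locus(spec: ToyLocusSpec = ToyLocusSpec()) -> ToyLocus:
    """Build the toy locus: sequence, annotation, IMGT-style allele DB."""
    rng = np.random.default_rng(spec.seed)
    parts: list[str] = []
    pos = 0
    genes: list[GeneAnnotation] = []
    alleles: dict[str, str] = {}

    def emit(s: str) -> None:
        nonlocal pos
        parts.append(s)
        pos += len(s)

    def add_gene(name, cls, length, rss_sides, functionality="functional"):
        gseq = _rand_seq(rng, length)
        genes.append(
            GeneAnnotation(
                name=name,
                segment_class=cls,
                functionality=functionality,
                reference=spec.reference_name,
                start=pos,
                end=pos + length,
                strand="+",
                rss_sides=frozenset(rss_sides),
            )
        )
        alleles[f"{name}*01"] = gseq
        mut = list(gseq)
        i = int(rng.integers(0, length))
        mut[i] = "ACGT"[("ACGT".index(mut[i]) + 1) % 4]
        alleles[f"{name}*02"] = "".join(mut)
        emit(gseq)

    def spacer(n, head_rss=False, tail_rss=False):
        body = _rand_seq(rng, max(0, n - head_rss * len(HEPTAMER) - tail_rss * len(HEPTAMER)))
        emit((HEPTAMER if head_rss else "") + body + (revcomp(HEPTAMER) if tail_rss else ""))

    spacer(spec.pad)
    for i in range(spec.n_j):
        add_gene(f"IGHJ{i + 1}", "J", spec.j_len, ("downstream",))
        # recombining RSS sits just downstream (V-ward) of each J gene
        spacer(spec.j_spacer if i < spec.n_j - 1 else spec.jd_gap, head_rss=True)
    for i in range(spec.n_d):
        add_gene(f"IGHD{i + 1}", "D", spec.d_len, ("upstream", "downstream"))
        spacer(spec.d_spacer if i < spec.n_d - 1 else spec.dv_gap, head_rss=True, tail_rss=True)
    for i in range(spec.n_v):
        func = "pseudogene" if i >= spec.n_v - spec.n_pseudo_v else "functional"
        add_gene(f"IGHV{i + 1}", "V", spec.v_len, ("upstream",), functionality=func)
        if i < spec.n_v - 1:
            spacer(spec.v_spacer, tail_rss=True)
    spacer(spec.pad)

    seq = "".join(parts)
    lm = LocusMap(spec.reference_name, genes, "+")
    return ToyLocus(spec, spec.reference_name, seq, lm, alleles)


# ---------------------------------------------------------------------------
# haplotypes and recombination events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RefBlock:
    start: int
    end: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class InsBlock:
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class SimEventSpec:
    """One somatic event: class, participating genes, junction insertions.

    ``genes`` are ordered J-proximal first; class-specific arities:
    complete_VDJ (J, D, V); DJ_only (J, D); VD_only (D, V);
    multiple_D (J, Da, Db, V) or, with ``dd_as_deletion``, (Da, Db);
    inversion_DJ (J, D); inversion_DD (Da, Db); inversion_VD (D, V).
    Non-templated junction insertions are drawn uniformly from
    ``ins_range`` (bp); the default stays well inside the read-profiler
    adjacency slack even when an aligner-collapsed D gene adds ~20 bp.
    """

    event_class: EventClass
    genes: tuple[str, ...]
    ins_range: tuple[int, int] = (0, 5)
    dd_as_deletion: bool = False


@dataclass
class Haplotype:
    name: str
    reference: str
    blocks: list
    event: Optional[SimEventSpec] = None

    @property
    def length(self) -> int:
        return sum(b.length for b in self.blocks)

    def sequence(self, ref_seq: str) -> str:
        out = []
        for b in self.blocks:
            if isinstance(b, InsBlock):
                out.append(b.seq)
            elif b.strand == "+":
                out.append(ref_seq[b.start : b.end])
            else:
                out.append(revcomp(ref_seq[b.start : b.end]))
        return "".join(out)


def _gene(locus: ToyLocus, name: str, cls: str) -> GeneAnnotation:
    g = locus.locus_map.gene(name)
    if g.segment_class != cls:
        raise ValueError(f"{name} is a {g.segment_class} gene, expected {cls}")
    return g


def simulate_recombination(
    locus: ToyLocus,
    event: SimEventSpec,
    rng: np.random.Generator,
    name: str = "hap",
) -> Haplotype:
    """Apply one V(D)J recombination event to the germline toy locus.

    Deletion-type events excise the sequence between the relevant RSS
    anchors (D-J first, then V-D, mirroring the biological order);
    inversions reverse-complement the span between the stated anchors and
    conserve length. Random non-templated nucleotides are inserted at the
    deletion junctions.
    """
    L = len(locus.seq)
    lo, hi = event.ins_range

    def ins() -> list:
        n = int(rng.integers(lo, hi + 1))
        return [InsBlock(_rand_seq(rng, n))] if n else []

    ec = event.event_class
    g = event.genes
    if ec is EventClass.unrecombined:
        blocks: list = [RefBlock(0, L)]
    elif ec is EventClass.complete_VDJ:
        j, d, v = (_gene(locus, g[0], "J"), _gene(locus, g[1], "D"), _gene(locus, g[2], "V"))
        blocks = [RefBlock(0, j.end), *ins(), RefBlock(d.start, d.end), *ins(), RefBlock(v.start, L)]
    elif ec is EventClass.DJ_only:
        j, d = _gene(locus, g[0], "J"), _gene(locus, g[1], "D")
        blocks = [RefBlock(0, j.end), *ins(), RefBlock(d.start, L)]
    elif ec is EventClass.VD_only:
        d, v = _gene(locus, g[0], "D"), _gene(locus, g[1], "V")
        blocks = [RefBlock(0, d.end), *ins(), RefBlock(v.start, L)]
    elif ec is EventClass.multiple_D and event.dd_as_deletion:
        da, db = _gene(locus, g[0], "D"), _gene(locus, g[1], "D")
        if not da.start < db.start:
            raise ValueError("D genes must be ordered J-proximal first")
        blocks = [RefBlock(0, da.end), *ins(), RefBlock(db.start, L)]
    elif ec is EventClass.multiple_D:
        j, da, db, v = (
            _gene(locus, g[0], "J"),
            _gene(locus, g[1], "D"),
            _gene(locus, g[2], "D"),
            _gene(locus, g[3], "V"),
        )
        if not da.start < db.start:
            raise ValueError("D genes must be ordered J-proximal first")
        blocks = [RefBlock(0, j.end), *ins(), RefBlock(da.start, db.end), *ins(), RefBlock(v.start, L)]
    elif ec is EventClass.inversion_DJ:
        j, d = _gene(locus, g[0], "J"), _gene(locus, g[1], "D")
        blocks = [RefBlock(0, j.end), *ins(), RefBlock(j.end, d.end, "-"), *ins(), RefBlock(d.end, L)]
    elif ec is EventClass.inversion_DD:
        da, db = _gene(locus, g[0], "D"), _gene(locus, g[1], "D")
        if not da.start < db.start:
            raise ValueError("D genes must be ordered J-proximal first")
        blocks = [RefBlock(0, da.start), *ins(), RefBlock(da.start, db.start, "-"), *ins(), RefBlock(db.start, L)]
    elif ec is EventClass.inversion_VD:
        d, v = _gene(locus, g[0], "D"), _gene(locus, g[1], "V")
        blocks = [RefBlock(0, d.start), *ins(), RefBlock(d.start, v.start, "-"), *ins(), RefBlock(v.start, L)]
    else:
        raise ValueError(f"cannot simulate event class {ec}")
    return Haplotype(name, locus.name, blocks, event)


# ---------------------------------------------------------------------------
# junction zones: truth geometry shared by read simulation and the oracle
# ---------------------------------------------------------------------------

@dataclass
class Zone:
    """Unalignable material between two alignable haplotype blocks."""

    start: int  # haplotype coordinate
    end: int
    left_block: RefBlock
    right_block: RefBlock
    left_ref: int
    right_ref: int
    flip: bool
    colinear_gap: int  # >0: would merge into one record with a deletion op


def junction_zones(hap: Haplotype, min_seg: int) -> list[Zone]:
    """Zones between blocks an aligner could anchor (length >= min_seg)."""
    offsets = []
    pos = 0
    for b in hap.blocks:
        offsets.append((pos, pos + b.length, b))
        pos += b.length
    alignable = [
        (s, e, b)
        for s, e, b in offsets
        if isinstance(b, RefBlock) and b.length >= min_seg
    ]
    zones = []
    for (s1, e1, b1), (s2, e2, b2) in zip(alignable, alignable[1:]):
        left_ref = b1.end if b1.strand == "+" else b1.start
        right_ref = b2.start if b2.strand == "+" else b2.end
        flip = b1.strand != b2.strand
        gap = 0
        if not flip:
            gap = (b2.start - b1.end) if b1.strand == "+" else (b1.start - b2.end)
        zones.append(Zone(e1, s2, b1, b2, left_ref, right_ref, flip, max(gap, 0)))
    return zones


def _anchor_at(locus_map: LocusMap, position: int) -> Optional[RssAnchor]:
    from .locus_model import nearest_rss

    hit = nearest_rss(locus_map, position, 0)
    return hit[0] if hit else None


# ---------------------------------------------------------------------------
# clone mixtures and read simulation
# ---------------------------------------------------------------------------

@dataclass
class CloneSpec:
    label: str
    fraction: float
    event: Optional[SimEventSpec] = None  # None = germline haplotype


@dataclass
class CloneMixSpec:
    """Sampling model for a clone mixture.

    Defaults emulate the study conditions at toy scale: ~38x coverage (the
    observed IGH-locus depth of the WGS HiFi datasets), reads of 4 kb over
    a ~16 kb locus (scaled HiFi), substitution-only errors at HiFi-like
    0.2%. ``min_seg`` is the shortest truth segment an aligner would
    anchor; shorter segments are soft-clipped in the truth alignments.
    """

    clones: list[CloneSpec] = field(default_factory=list)
    depth: float = 38.0
    read_len: int = 4000
    error_rate: float = 0.002
    min_seg: int = 50
    merge_max: int = 1000  # colinear ref gap merged into a deletion op
    seed: int = 0

    def __post_init__(self) -> None:
        if self.clones:
            total = sum(c.fraction for c in self.clones)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"clone fractions must sum to 1, got {total}")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")


@dataclass
class Piece:
    """One aligned portion of a simulated read (truth segment)."""

    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    strand: str
    ops: list[tuple[str, int]]  # read-order M/I/D ops


@dataclass
class SimRead:
    read_id: str
    clone: str
    sequence: str
    hap_start: int
    orientation: str  # read sampled forward/reverse from the haplotype
    pieces: list[Piece]
    expected_class: EventClass
    expected_genes: tuple[tuple[str, str], ...]
    informative: bool
    error_positions: tuple[int, ...] = ()

    @property
    def expected_key(self) -> tuple[str, tuple[tuple[str, str], ...]]:
        return (str(self.expected_class), self.expected_genes)


@dataclass
class SimSample:
    locus: ToyLocus
    mix: CloneMixSpec
    haplotypes: dict[str, Haplotype]
    reads: list[SimRead]

    def write_truth_sam(self, path, style: str = "records") -> None:
        write_truth_sam(self, path, style)

    def write_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")

    def write_truth_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\tclone\texpected_class\texpected_genes\tinformative\n")
            for r in self.reads:
                genes = ",".join(f"{g}:{s}" for g, s in r.expected_genes) or "."
                fh.write(
                    f"{r.read_id}\t{r.clone}\t{r.expected_class}\t{genes}\t"
                    f"{int(r.informative)}\n"
                )


def _pieces_for_window(
    hap: Haplotype, s: int, e: int, min_seg: int, merge_max: int
) -> list[Piece]:
    """Truth segments of the read covering haplotype window [s, e)."""
    raw: list = []  # (read_start, read_end, ref_start, ref_end, strand) or int gap
    pos = 0
    for b in hap.blocks:
        b_lo, b_hi = pos, pos + b.length
        pos = b_hi
        lo, hi = max(b_lo, s), min(b_hi, e)
        if lo >= hi:
            continue
        if isinstance(b, InsBlock):
            raw.append(hi - lo)
            continue
        k0, k1 = lo - b_lo, hi - b_lo
        if b.strand == "+":
            r0, r1 = b.start + k0, b.start + k1
        else:
            r0, r1 = b.end - k1, b.end - k0
        if hi - lo < min_seg:
            raw.append(hi - lo)  # aligner would not anchor this piece
        else:
            raw.append((lo - s, hi - s, r0, r1, b.strand))

    pieces: list[Piece] = []
    pending_gap = 0
    for item in raw:
        if isinstance(item, int):
            pending_gap += item
            continue
        rs, re_, r0, r1, strand = item
        merged = False
        if pieces:
            prev = pieces[-1]
            if prev.strand == strand and pending_gap <= 50:
                refgap = (r0 - prev.ref_end) if strand == "+" else (prev.ref_start - r1)
                if 0 <= refgap <= merge_max and (refgap > 0 or pending_gap > 0):
                    if pending_gap:
                        prev.ops.append(("I", pending_gap))
                    if refgap:
                        prev.ops.append(("D", refgap))
                    prev.ops.append(("M", re_ - rs))
                    prev.read_end = re_
                    if strand == "+":
                        prev.ref_end = r1
                    else:
                        prev.ref_start = r0
                    merged = True
        if not merged:
            pieces.append(Piece(rs, re_, r0, r1, strand, [("M", re_ - rs)]))
        pending_gap = 0
    return pieces


def _mirror_pieces(pieces: list[Piece], read_len: int) -> list[Piece]:
    out = []
    for p in pieces:
        out.append(
            Piece(
                read_start=read_len - p.read_end,
                read_end=read_len - p.read_start,
                ref_start=p.ref_start,
                ref_end=p.ref_end,
                strand="-" if p.strand == "+" else "+",
                ops=list(reversed(p.ops)),
            )
        )
    out.sort(key=lambda p: p.read_start)
    return out


# --- geometric expectation (forward model of what the evidence supports) ---

def _expected_for_window(
    hap: Haplotype,
    locus_map: LocusMap,
    s: int,
    e: int,
    mix: CloneMixSpec,
    config: Config,
) -> tuple[EventClass, tuple[tuple[str, str], ...], bool]:
    """Event evidence a read over [s, e) genuinely carries.

    Derived purely from the haplotype construction geometry: a junction is
    visible when the read covers its zone plus ``min_seg`` anchorable bases
    on both sides; colinear zones surface as CIGAR deletions and obey the
    deletion-length rule instead. Returns (class, genes, informative);
    ``informative`` is False only for configurations the event grammar
    cannot express (for example a junction zone wider than the adjacency
    slack), which the default generator settings never produce.
    """
    zones = junction_zones(hap, mix.min_seg)
    visible = []
    informative = True
    for z in zones:
        if not (s <= z.start - mix.min_seg and z.end + mix.min_seg <= e):
            continue
        if z.colinear_gap:
            if z.colinear_gap < config.cigar_del_min_len:
                continue  # too short to surface as a deletion call
        elif (z.end - z.start) > config.adjacency_slack:
            informative = False
            continue
        la = _anchor_at(locus_map, z.left_ref)
        ra = _anchor_at(locus_map, z.right_ref)
        if la is None or ra is None:
            informative = False
            continue
        visible.append((z, la, ra))
    if not visible:
        return EventClass.unrecombined, (), informative

    def genes_of(items):
        seen = []
        for _, la, ra in items:
            for a in (la, ra):
                if (a.gene, a.side) not in seen:
                    seen.append((a.gene, a.side))
        seen.sort(key=lambda t: (locus_map.locus_rank(t[0]), t[1] != "upstream"))
        return tuple(seen)

    genes = genes_of(visible)
    flips = [v for v in visible if v[0].flip]
    if flips:
        pairs = {frozenset((la.segment_class, ra.segment_class)) for _, la, ra in flips}
        if len(pairs) == 1:
            pair = next(iter(pairs))
            table = {
                frozenset("JD"): EventClass.inversion_DJ,
                frozenset("D"): EventClass.inversion_DD,
                frozenset("DV"): EventClass.inversion_VD,
            }
            if pair in table:
                return table[pair], genes, informative
        return EventClass.complex, genes, informative

    anchors = [a for _, la, ra in visible for a in (la, ra)]
    d_genes = {a.gene for a in anchors if a.segment_class == "D"}
    if len(visible) == 1:
        z, la, ra = visible[0]
        classes = frozenset((la.segment_class, ra.segment_class))
        if classes == {"J", "V"}:
            return EventClass.complete_VDJ, genes, informative
        if classes == {"J", "D"}:
            return EventClass.DJ_only, genes, informative
        if classes == {"D", "V"}:
            d_block = z.left_block if la.segment_class == "D" else z.right_block
            # germline reach of the read within the D-side flank block
            blk_lo = 0
            pos = 0
            for b in hap.blocks:
                if b is d_block:
                    blk_lo = pos
                    break
                pos += b.length
            covered0 = d_block.start + max(0, s - blk_lo)
            covered1 = d_block.start + min(d_block.length, e - blk_lo)
            inter = locus_map.jd_intergenic
            reach = 0
            if inter:
                reach = max(0, min(covered1, inter[1]) - max(covered0, inter[0]))
            if reach >= config.vd_flank_min:
                return EventClass.VD_only, genes, informative
            return EventClass.multiple_D, genes, informative
        if classes == {"D"} and la.gene != ra.gene:
            return EventClass.multiple_D, genes, informative
        return EventClass.complex, genes, informative
    if len(d_genes) >= 2:
        return EventClass.multiple_D, genes, informative
    if len(d_genes) == 1:
        d = next(iter(d_genes))
        sides = {a.side for a in anchors if a.gene == d}
        cls = {a.segment_class for a in anchors}
        if sides == {"upstream", "downstream"} and {"J", "V"} <= cls:
            return (
                EventClass.complete_VDJ,
                tuple(t for t in genes if t[0] != d),
                informative,
            )
    return EventClass.complex, genes, informative


def simulate_reads(
    locus: ToyLocus,
    mix: CloneMixSpec,
    rng: Optional[np.random.Generator] = None,
    config: Config = DEFAULT_CONFIG,
) -> SimSample:
    """Draw reads uniformly along each clone haplotype.

    Per-clone read counts are Poisson around depth x fraction x
    haplotype-length / read-length; substitution errors are injected at
    ``mix.error_rate``; about half the reads are sampled from the reverse
    strand. Truth segments, expected event evidence, and informativeness
    are recorded per read.
    """
    rng = rng if rng is not None else np.random.default_rng(mix.seed)
    haplotypes: dict[str, Haplotype] = {}
    reads: list[SimRead] = []
    for clone in mix.clones:
        if clone.event is None:
            hap = Haplotype(clone.label, locus.name, [RefBlock(0, len(locus.seq))])
        else:
            hap = simulate_recombination(locus, clone.event, rng, name=clone.label)
        haplotypes[clone.label] = hap
        hap_seq = hap.sequence(locus.seq)
        hl = len(hap_seq)
        rl = min(mix.read_len, hl)
        n_reads = int(rng.poisson(mix.depth * clone.fraction * hl / rl))
        for i in range(n_reads):
            s = int(rng.integers(0, hl - rl + 1))
            e = s + rl
            seq = hap_seq[s:e]
            pieces = _pieces_for_window(hap, s, e, mix.min_seg, mix.merge_max)
            exp_class, exp_genes, informative = _expected_for_window(
                hap, locus.locus_map, s, e, mix, config
            )
            orientation = "+" if rng.random() < 0.5 else "-"
            if orientation == "-":
                seq = revcomp(seq)
                pieces = _mirror_pieces(pieces, rl)
            n_err = int(rng.binomial(rl, mix.error_rate))
            err_pos = tuple(sorted(rng.choice(rl, size=n_err, replace=False))) if n_err else ()
            if err_pos:
                sl = list(seq)
                for p in err_pos:
                    sl[p] = "ACGT"[("ACGT".index(sl[p]) + 1) % 4]
                seq = "".join(sl)
            reads.append(
                SimRead(
                    read_id=f"{clone.label}_{i:05d}",
                    clone=clone.label,
                    sequence=seq,
                    hap_start=s,
                    orientation=orientation,
                    pieces=pieces,
                    expected_class=exp_class,
                    expected_genes=exp_genes,
                    informative=informative,
                    error_positions=err_pos,
                )
            )
    reads.sort(key=lambda r: r.read_id)
    return SimSample(locus, mix, haplotypes, reads)


# ---------------------------------------------------------------------------
# truth SAM emission
# ---------------------------------------------------------------------------

def _cigar_string(p: Piece, read_len: int, clip_op: str) -> str:
    lead = p.read_start if p.strand == "+" else read_len - p.read_end
    trail = read_len - p.read_end if p.strand == "+" else p.read_start
    ops = p.ops if p.strand == "+" else list(reversed(p.ops))
    out = []
    if lead:
        out.append(f"{lead}{clip_op}")
    out.extend(f"{n}{op}" for op, n in ops)
    if trail:
        out.append(f"{trail}{clip_op}")
    return "".join(out)


def _piece_nm(p: Piece, err_pos: Sequence[int]) -> int:
    subs = sum(1 for x in err_pos if p.read_start <= x < p.read_end)
    dels = sum(n for op, n in p.ops if op == "D")
    inss = sum(n for op, n in p.ops if op == "I")
    return subs + dels + inss


def write_truth_sam(sample: SimSample, path, style: str = "records") -> None:
    """Emit truth alignments as SAM.

    ``style='records'``: one primary (soft-clipped, full SEQ) plus
    hard-clipped supplementary records, all carrying SA tags.
    ``style='sa_only'``: only the primary record, split evidence encoded
    in its SA tag — exercises the SA-dialect path of the profiler.
    """
    if style not in ("records", "sa_only"):
        raise ValueError(style)
    locus = sample.locus
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": locus.name, "LN": len(locus.seq)}],
        }
    )
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in sample.reads:
            if not r.pieces:
                continue
            rl = len(r.sequence)
            primary_idx = max(
                range(len(r.pieces)),
                key=lambda i: sum(n for op, n in r.pieces[i].ops if op == "M"),
            )
            sa_strings = [
                f"{locus.name},{p.ref_start + 1},{p.strand},"
                f"{_cigar_string(p, rl, 'S')},60,{_piece_nm(p, r.error_positions)}"
                for p in r.pieces
            ]
            for i, p in enumerate(r.pieces):
                is_primary = i == primary_idx
                if style == "sa_only" and not is_primary:
                    continue
                a = pysam.AlignedSegment(header)
                a.query_name = r.read_id
                a.reference_name = locus.name
                a.reference_start = p.ref_start
                a.mapping_quality = 60
                flag = 0
                if p.strand == "-":
                    flag |= 16
                if not is_primary:
                    flag |= 2048
                a.flag = flag
                oriented = r.sequence if p.strand == "+" else revcomp(r.sequence)
                if is_primary:
                    a.cigarstring = _cigar_string(p, rl, "S")
                    a.query_sequence = oriented
                else:
                    a.cigarstring = _cigar_string(p, rl, "H")
                    lead = p.read_start if p.strand == "+" else rl - p.read_end
                    trail = rl - p.read_end if p.strand == "+" else p.read_start
                    a.query_sequence = oriented[lead : rl - trail]
                a.set_tag("NM", _piece_nm(p, r.error_positions))
                others = [sa for k, sa in enumerate(sa_strings) if k != i]
                if others and (style == "sa_only" or len(r.pieces) > 1):
                    a.set_tag("SA", ";".join(others) + ";")
                out.write(a)


# ---------------------------------------------------------------------------
# short reads (assembly validation fixtures)
# ---------------------------------------------------------------------------

def tile_short_reads(
    seq: str,
    read_len: int = 150,
    stride: int = 75,
    skip_interval: Optional[tuple[int, int]] = None,
    variants: Optional[dict[int, str]] = None,
) -> list[tuple[str, int, str]]:
    """Deterministic tiling reads over a sequence.

    ``skip_interval`` omits reads overlapping it (engineering a coverage
    hole); ``variants`` substitutes bases at reference positions in every
    read that covers them (emulating consistent sample-vs-assembly
    differences).
    """
    reads = []
    starts = list(range(0, max(len(seq) - read_len, 0) + 1, stride))
    if starts and starts[-1] != len(seq) - read_len:
        starts.append(len(seq) - read_len)
    for i, s in enumerate(starts):
        if skip_interval and s < skip_interval[1] and s + read_len > skip_interval[0]:
            continue
        sub = list(seq[s : s + read_len])
        if variants:
            for pos, base in variants.items():
                if s <= pos < s + read_len:
                    sub[pos - s] = base
        reads.append((f"sr_{i:05d}", s, "".join(sub)))
    return reads


def write_short_read_sam(
    target_name: str,
    target_len: int,
    reads: Sequence[tuple[str, int, str]],
    path,
    mapq: int = 60,
) -> None:
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": target_name, "LN": target_len}]}
    )
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for name, start, seq in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = name
            a.reference_name = target_name
            a.reference_start = start
            a.mapping_quality = mapq
            a.flag = 0
            a.cigarstring = f"{len(seq)}M"
            a.query_sequence = seq
            out.write(a)


# ---------------------------------------------------------------------------
# SV catalogue fixture (toy genotyping / stitching round-trips)
# ---------------------------------------------------------------------------

@dataclass
class SvToyFixture:
    """Toy locus plus a 7-SV catalogue mirroring the real topology:
    six simple deletions (each one V gene between two flanking V genes)
    and one complex SV whose alternative haplotype carries two genes
    absent from the backbone."""

    locus: ToyLocus
    catalog: list
    registry: object
    allele_db: dict[str, str]

    @property
    def sv_ids(self) -> list[int]:
        return sorted(sv.sv_id for sv in self.catalog)


def make_toy_sv_fixture(seed: int = 0) -> SvToyFixture:
    from .ref_builder import SegmentRegistry, SvDefinition, _sv_span

    spec = ToyLocusSpec(n_v=22, seed=seed)
    locus = make_toy_locus(spec)
    lm = locus.locus_map
    rng = np.random.default_rng(seed + 1)
    backbone = locus.seq

    catalog: list[SvDefinition] = []
    registry_segments: dict[tuple[int, str], str] = {}
    deletion_ids = [1, 2, 4, 5, 6, 7]
    for j, sv_id in enumerate(deletion_ids):
        gl = lm.gene(f"IGHV{3 * j + 1}")
        gin = lm.gene(f"IGHV{3 * j + 2}")
        gr = lm.gene(f"IGHV{3 * j + 3}")
        sv = SvDefinition(
            sv_id,
            "deletion",
            (gin.name,),
            (gl.name, gr.name),
            source_default="toy-default",
            source_alternative="toy-alt",
        )
        catalog.append(sv)
        lo, hi = _sv_span(sv, lm)
        cut1 = (gl.end + gin.start) // 2
        cut2 = (gin.end + gr.start) // 2
        registry_segments[(sv_id, "alternative")] = backbone[lo:cut1] + backbone[cut2:hi]

    gl, gr = lm.gene("IGHV19"), lm.gene("IGHV22")
    hap_a = (lm.gene("IGHV20").name, lm.gene("IGHV21").name)
    vb1, vb2 = _rand_seq(rng, spec.v_len), _rand_seq(rng, spec.v_len)
    sv3 = SvDefinition(
        3,
        "complex",
        (),
        (gl.name, gr.name),
        hapA_genes=hap_a,
        hapB_genes=("IGHVB1", "IGHVB2"),
        source_default="toy-hapA",
        source_alternative="toy-hapB",
    )
    catalog.append(sv3)
    lo, hi = _sv_span(sv3, lm)
    cut1 = (gl.end + lm.gene("IGHV20").start) // 2
    cut2 = (lm.gene("IGHV21").end + gr.start) // 2
    registry_segments[(3, "alternative")] = (
        backbone[lo:cut1] + vb1 + _rand_seq(rng, spec.v_spacer) + vb2 + backbone[cut2:hi]
    )

    allele_db = dict(locus.allele_db)
    allele_db["IGHVB1*01"] = vb1
    allele_db["IGHVB2*01"] = vb2
    registry = SegmentRegistry(backbone, registry_segments)
    catalog.sort(key=lambda sv: sv.sv_id)
    return SvToyFixture(locus, catalog, registry, allele_db)


def slice_contigs(seq: str, n: int = 3, overlap: int = 4000, prefix: str = "ctg") -> dict[str, str]:
    """Cut a haplotype into ``n`` overlapping contig slices.

    The overlap should exceed the widest catalogued SV span so that every
    SV region is fully contained in at least one slice (otherwise its
    allele is legitimately unknown on every contig).
    """
    L = len(seq)
    step = max(1, L // n)
    out = {}
    for i in range(n):
        lo = max(0, i * step - overlap // 2)
        hi = min(L, (i + 1) * step + overlap // 2) if i < n - 1 else L
        out[f"{prefix}{i}"] = seq[lo:hi]
    return out
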