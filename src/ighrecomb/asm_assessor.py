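"""Assembly QC for the IGH locus: annotation, artifacts, validation.

Contigs are annotated against an IMGT-style allele database with an
internal seed-free annotator (best infix edit-distance placement per
allele, both strands, iteratively masking found copies). Orphon-like hits
(edit distance above a threshold) are filtered, duplicated-gene names are
resolved positionally, and two artifact classes are called:

* **V(D)J junctions** — gene segments of different classes within 10 kbp
  on one contig: the contig records a somatic recombination, not the
  germline locus.
* **breakpoints** — adjacent contigs that are disjoint / overlapping /
  duplicated in locus coordinates; only disjoint breakpoints lose genes.

Newly assembled genes can be validated with an independent short-read
alignment: a gene is *confident* when every base is covered and at most
one covered base lacks a supporting read.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import edlib
import numpy as np
import pysam

from .config import Config, DEFAULT_CONFIG
from .locus_model import LocusMap

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class GeneHit:
    contig: str
    gene: str
    allele: str
    start: int
    end: int
    strand: str
    mismatches: int
    kept: bool = True
    extra_copy: bool = False

    @property
    def segment_class(self) -> str:
        base = self.gene.upper()
        for cls in ("V", "D", "J"):
            if base.startswith(f"IGH{cls}"):
                return cls
        return "C"


@dataclass
class ContigProfile:
    contig: str
    hits: list[GeneHit]
    orientation: str = "+"

    def __post_init__(self) -> None:
        self.hits = sorted(self.hits, key=lambda h: (h.start, h.end))
        if self.hits:
            rev = sum(1 for h in self.hits if h.strand == "-")
            self.orientation = "-" if rev * 2 > len(self.hits) else "+"

    @property
    def gene_names(self) -> list[str]:
        return [h.gene for h in self.hits]


@dataclass
class JunctionCallAsm:
    contig: str
    left: GeneHit
    right: GeneHit
    gap: int
    type: str  # VJ / DJ / VD


@dataclass
class BreakpointCall:
    contig_a: str
    contig_b: str
    relation: str  # disjoint / overlap / duplication
    boundary_genes: tuple[str, str]
    missing_genes: list[str] = field(default_factory=list)


@dataclass
class ValidationResult:
    hit: GeneHit
    fully_covered: bool
    edit_distance: int

    @property
    def confident(self) -> bool:
        return self.fully_covered and self.edit_distance <= 1


@dataclass
class AssemblyReport:
    haplotypes: dict[str, dict]

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, (GeneHit, JunctionCallAsm, BreakpointCall)):
                return o.__dict__
            return str(o)

        return json.dumps(self.haplotypes, default=enc, indent=2)


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def _allele_gene(allele_name: str) -> str:
    return allele_name.split("*")[0].split("|")[0]


def annotate_contigs(
    contigs: Mapping[str, str],
    allele_db: Mapping[str, str],
    config: Config = DEFAULT_CONFIG,
) -> list[GeneHit]:
    """Locate every database allele on every contig, best allele per spot.

    Each allele is matched on both strands with infix (semi-global) edit
    distance, capped at ``annotate_max_edit_frac`` of the allele length so
    short D genes cannot pick up random matches; found copies are masked
    and the search repeated, so tandem duplications yield one hit per
    copy. Overlapping placements of the same gene collapse to the
    best-scoring allele.
    """
    if not allele_db:
        raise ValueError("empty allele database")
    hits: list[GeneHit] = []
    for contig_name, contig_seq in contigs.items():
        contig_seq = contig_seq.upper()
        candidates: dict[str, list[GeneHit]] = defaultdict(list)
        for allele_name, allele_seq in allele_db.items():
            cap = int(len(allele_seq) * config.annotate_max_edit_frac)
            if len(allele_seq) <= config.annotate_short_allele_len:
                cap = min(cap, config.annotate_short_max_edit)
            gene = _allele_gene(allele_name)
            for strand in "+-":
                query = allele_seq if strand == "+" else _revcomp(allele_seq)
                masked = contig_seq
                while True:
                    res = edlib.align(query, masked, mode="HW", task="locations")
                    if res["editDistance"] < 0 or res["editDistance"] > cap:
                        break
                    spans = []
                    for s, e in res["locations"]:
                        span = (s, e + 1)
                        if not any(a < span[1] and span[0] < b for a, b in spans):
                            spans.append(span)
                    for s, e in spans:
                        candidates[gene].append(
                            GeneHit(
                                contig_name,
                                gene,
                                allele_name,
                                s,
                                e,
                                strand,
                                res["editDistance"],
                            )
                        )
                    masked_l = list(masked)
                    for s, e in spans:
                        masked_l[s:e] = "N" * (e - s)
                    masked = "".join(masked_l)
        # collapse overlapping placements of one gene to the best allele
        for gene, cands in candidates.items():
            cands.sort(key=lambda h: (h.start, h.mismatches, h.allele))
            clusters: list[list[GeneHit]] = []
            for h in cands:
                if clusters and h.start < max(x.end for x in clusters[-1]):
                    clusters[-1].append(h)
                else:
                    clusters.append([h])
            for cluster in clusters:
                best = min(
                    cluster, key=lambda h: (h.mismatches, h.strand == "-", h.allele)
                )
                hits.append(best)
    hits.sort(key=lambda h: (h.contig, h.start, h.gene))
    return hits


def filter_orphons(
    hits: Sequence[GeneHit], max_mismatch: int = DEFAULT_CONFIG.orphon_max_mismatch
) -> tuple[list[GeneHit], list[str]]:
    """Drop hits with more than ``max_mismatch`` edits; drop contigs whose
    hits are all gone (likely orphon-only contigs)."""
    kept = [replace(h, kept=True) for h in hits if h.mismatches <= max_mismatch]
    retained = sorted({h.contig for h in kept})
    return kept, retained


def build_profiles(hits: Sequence[GeneHit]) -> list[ContigProfile]:
    by_contig: dict[str, list[GeneHit]] = defaultdict(list)
    for h in hits:
        if h.kept:
            by_contig[h.contig].append(h)
    return [ContigProfile(c, hs) for c, hs in sorted(by_contig.items())]


# ---------------------------------------------------------------------------
# duplicate gene naming
# ---------------------------------------------------------------------------

def assign_duplicate_names(
    profile: ContigProfile,
    locus_map: Optional[LocusMap] = None,
    config: Config = DEFAULT_CONFIG,
) -> ContigProfile:
    """Resolve sequence-identical duplicate pairs (e.g. IGHV3-23/-23D).

    When two or more instances of a duplicate-pair base gene occur on one
    contig, the instance matching the reference layout position is renamed
    with the "D" suffix (layout order taken from the locus map when it
    contains both names, else base-then-D along the locus axis); further
    copies keep the base name but are flagged as extra copies. Single
    instances are left untouched.
    """
    hits = [replace(h) for h in profile.hits]
    for base in config.duplicate_gene_bases:
        idx = [i for i, h in enumerate(hits) if h.gene == base]
        if len(idx) < 2:
            continue
        ordered = sorted(idx, key=lambda i: hits[i].start)
        if profile.orientation == "-":
            ordered = ordered[::-1]
        names = [base, base + "D"]
        if locus_map is not None:
            try:
                if locus_map.locus_rank(base + "D") < locus_map.locus_rank(base):
                    names = [base + "D", base]
            except KeyError:
                pass
        for k, i in enumerate(ordered):
            if k < 2:
                hits[i] = replace(hits[i], gene=names[k])
            else:
                hits[i] = replace(hits[i], extra_copy=True)
    return ContigProfile(profile.contig, hits)


# ---------------------------------------------------------------------------
# artifact calls
# ---------------------------------------------------------------------------

def detect_vdj_junctions(
    profile: ContigProfile, config: Config = DEFAULT_CONFIG
) -> list[JunctionCallAsm]:
    """Adjacent hits of differing V/D/J classes within the window.

    The D gene that sits within the window of the J genes in the germline
    locus (IGHD7-27 in the real annotation) is exempted from D/J calls.
    """
    out = []
    hits = [h for h in profile.hits if h.segment_class in "VDJ"]
    for a, b in zip(hits, hits[1:]):
        if a.segment_class == b.segment_class:
            continue
        gap = max(0, b.start - a.end)
        if gap > config.junction_window:
            continue
        classes = {a.segment_class, b.segment_class}
        if classes == {"D", "J"}:
            d_gene = a.gene if a.segment_class == "D" else b.gene
            if d_gene == config.junction_exempt_d:
                continue
            jtype = "DJ"
        elif classes == {"V", "J"}:
            jtype = "VJ"
        else:
            jtype = "VD"
        out.append(JunctionCallAsm(profile.contig, a, b, gap, jtype))
    return out


def _hit_rank(hit: GeneHit, locus_map: LocusMap) -> Optional[int]:
    for name in (hit.gene, hit.gene.rstrip("D")):
        try:
            return locus_map.locus_rank(name)
        except KeyError:
            continue
    return None


def _ranks(profile: ContigProfile, locus_map: LocusMap) -> list[int]:
    return [r for h in profile.hits if (r := _hit_rank(h, locus_map)) is not None]


def locus_position(profile: ContigProfile, locus_map: LocusMap) -> float:
    """Median locus rank of a contig's hits (robust projection)."""
    ranks = _ranks(profile, locus_map)
    return float(np.median(ranks)) if ranks else float("nan")


def classify_breakpoints(
    profiles: Sequence[ContigProfile], locus_map: LocusMap
) -> list[BreakpointCall]:
    """Relations between coordinate-adjacent contigs of one haplotype."""
    ordered = sorted(profiles, key=lambda p: locus_position(p, locus_map))
    out = []
    for a, b in zip(ordered, ordered[1:]):
        ra, rb = _ranks(a, locus_map), _ranks(b, locus_map)
        sa, sb = set(a.gene_names), set(b.gene_names)
        lo_a, hi_a = min(ra), max(ra)
        lo_b, hi_b = min(rb), max(rb)
        if sb <= sa or sa <= sb:
            relation = "duplication"
            missing: list[str] = []
        elif lo_b > hi_a or lo_a > hi_b:
            relation = "disjoint"
            lo, hi = (hi_a, lo_b) if lo_b > hi_a else (hi_b, lo_a)
            missing = [
                g.name
                for g in locus_map.genes
                if lo < locus_map.locus_rank(g.name) < hi
            ]
        else:
            relation = "overlap"
            missing = []
        boundary_a = max(a.hits, key=lambda h: _hit_rank(h, locus_map) or -1)
        boundary_b = min(b.hits, key=lambda h: _hit_rank(h, locus_map) or 10**9)
        out.append(
            BreakpointCall(a.contig, b.contig, relation, (boundary_a.gene, boundary_b.gene), missing)
        )
    return out


def summarize_assembly(
    profiles_by_haplotype: Mapping[str, Sequence[ContigProfile]],
    locus_map: LocusMap,
    config: Config = DEFAULT_CONFIG,
) -> AssemblyReport:
    """Per-haplotype contig counts, deduplicated gene presence, artifacts.

    Genes on duplicated sequences count once per haplotype; the headline V
    count excludes pseudogenes (looked up in the locus map; genes absent
    from the map count as functional).
    """
    haps = {}
    for hap, profiles in profiles_by_haplotype.items():
        presence: set[str] = set()
        junctions: list[JunctionCallAsm] = []
        for p in profiles:
            presence |= set(p.gene_names)
            junctions.extend(detect_vdj_junctions(p, config))
        breakpoints = (
            classify_breakpoints(profiles, locus_map) if len(profiles) > 1 else []
        )

        def functional(name: str) -> bool:
            for n in (name, name.rstrip("D")):
                try:
                    return locus_map.gene(n).functionality != "pseudogene"
                except KeyError:
                    continue
            return True

        counts = {
            "V": sum(
                1 for g in presence if g.upper().startswith("IGHV") and functional(g)
            ),
            "D": sum(1 for g in presence if g.upper().startswith("IGHD")),
            "J": sum(1 for g in presence if g.upper().startswith("IGHJ")),
        }
        haps[hap] = {
            "n_contigs": len(profiles),
            "genes_present": sorted(presence),
            "gene_counts": counts,
            "vdj_junctions": junctions,
            "breakpoints": breakpoints,
        }
    return AssemblyReport(haps)


# ---------------------------------------------------------------------------
# short-read validation
# ---------------------------------------------------------------------------

def validate_genes_with_short_reads(
    assembly: Mapping[str, str],
    alignment_path,
    hits: Sequence[GeneHit],
    config: Config = DEFAULT_CONFIG,
) -> list[ValidationResult]:
    """Check each gene hit against an independent short-read alignment.

    A base is *covered* when at least one passing (MAPQ >= threshold)
    read aligns across it, and *supported* when at least one such read
    agrees with the assembly base there. Per gene: fully covered iff all
    bases covered; edit distance = covered-but-unsupported bases
    (mismatches, deletions and insertion-adjacent disagreements all
    surface this way); confident iff fully covered and edit <= threshold.
    """
    covered: dict[str, np.ndarray] = {}
    supported: dict[str, np.ndarray] = {}
    for name, seq in assembly.items():
        covered[name] = np.zeros(len(seq), dtype=bool)
        supported[name] = np.zeros(len(seq), dtype=bool)
    with pysam.AlignmentFile(str(alignment_path), check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.mapping_quality < config.validate_mapq_min:
                continue
            if rec.reference_name not in covered:
                raise ValueError(
                    f"alignment target {rec.reference_name!r} not in assembly"
                )
            cov = covered[rec.reference_name]
            sup = supported[rec.reference_name]
            ref_seq = assembly[rec.reference_name]
            qseq = rec.query_sequence
            cov[rec.reference_start : rec.reference_end] = True
            if qseq is None:
                continue
            for qpos, rpos in rec.get_aligned_pairs():
                if rpos is None:
                    continue
                if qpos is not None and qseq[qpos].upper() == ref_seq[rpos].upper():
                    sup[rpos] = True
    out = []
    for h in hits:
        cov = covered[h.contig][h.start : h.end]
        sup = supported[h.contig][h.start : h.end]
        fully = bool(cov.all())
        edit = int((cov & ~sup).sum())
        out.append(ValidationResult(h, fully, edit))
    return out


def write_hits_tsv(hits: Sequence[GeneHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tgene\tallele\tstart\tend\tstrand\tmismatches\tkept\n")
        for h in hits:
            fh.write(
                f"{h.contig}\t{h.gene}\t{h.allele}\t{h.start}\t{h.end}\t"
                f"{h.strand}\t{h.mismatches}\t{int(h.kept)}\n"
            )


def load_hits_tsv(path) -> list[GeneHit]:
    out = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            c, g, a, s, e, st, m, k = line.rstrip("\n").split("\t")
            out.append(GeneHit(c, g, a, int(s), int(e), st, int(m), kept=k == "1"))
    return out
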