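"""IGH locus coordinate model: genes, RSS anchors, reference registry.

All coordinates are 0-based, half-open. Vocabulary is in *locus
orientation*: the axis running J -> D -> V. "Upstream" means toward the J
end of the locus, "downstream" toward the V end, regardless of which
reference strand the locus sits on. A ``LocusMap`` with
``locus_orientation == '+'`` has J genes at low reference coordinates (the
toy loci built by :mod:`ighrecomb.synthetic`); the real IGH locus on the
minus strand of chr14 would use ``'-'``.

Recombination breakends fall at RSSs, which are modelled as single anchor
coordinates at gene boundaries: J genes carry one anchor on their
downstream (D-facing) side, V genes one on their upstream (D-facing) side,
and D genes carry both.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Optional

SEGMENT_CLASSES = ("V", "D", "J", "C")
FUNCTIONALITIES = ("functional", "ORF", "pseudogene")
RSS_SIDES = ("upstream", "downstream")

#: maximum length of a human D gene (bp); used as an annotation invariant.
MAX_D_GENE_LEN = 40

ANNOTATION_COLUMNS = (
    "reference",
    "start",
    "end",
    "gene",
    "class",
    "functionality",
    "strand",
    "rss_sides",
)


class AnnotationError(ValueError):
    """Malformed or inconsistent locus annotation."""


@dataclass(frozen=True)
class GeneAnnotation:
    """One IGH gene segment on a named reference."""

    name: str
    segment_class: str
    functionality: str
    reference: str
    start: int
    end: int
    strand: str
    rss_sides: frozenset[str]

    def __post_init__(self) -> None:
        if self.segment_class not in SEGMENT_CLASSES:
            raise AnnotationError(f"bad segment class {self.segment_class!r}")
        if self.functionality not in FUNCTIONALITIES:
            raise AnnotationError(f"bad functionality {self.functionality!r}")
        if not self.start < self.end:
            raise AnnotationError(f"{self.name}: start must be < end")
        if not self.rss_sides <= set(RSS_SIDES):
            raise AnnotationError(f"{self.name}: bad rss_sides {self.rss_sides}")
        if self.segment_class == "D":
            if self.rss_sides != {"upstream", "downstream"}:
                raise AnnotationError(f"{self.name}: D genes need both RSS sides")
            if self.end - self.start > MAX_D_GENE_LEN:
                raise AnnotationError(
                    f"{self.name}: D gene longer than {MAX_D_GENE_LEN} bp"
                )
        elif self.segment_class in ("J", "V") and len(self.rss_sides) != 1:
            raise AnnotationError(f"{self.name}: J/V genes need exactly one RSS side")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class RssAnchor:
    """Single junction coordinate of an RSS at a gene boundary."""

    gene: str
    segment_class: str
    side: str
    position: int


@dataclass
class LocusMap:
    """Ordered IGH gene annotation on one reference."""

    reference: str
    genes: list[GeneAnnotation]
    locus_orientation: str = "+"
    _anchors: list[RssAnchor] = field(default_factory=list, repr=False)
    _rank: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.locus_orientation not in "+-":
            raise AnnotationError("locus_orientation must be '+' or '-'")
        self.genes = sorted(self.genes, key=lambda g: g.start)
        names = [g.name for g in self.genes]
        if len(names) != len(set(names)):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise AnnotationError(f"duplicate gene names on {self.reference}: {dup}")
        jd = self.jd_interval
        if jd is not None:
            for g in self.genes:
                if g.segment_class == "V" and g.start < jd[1] and g.end > jd[0]:
                    raise AnnotationError(
                        f"V gene {g.name} overlaps the J-D interval {jd}"
                    )
        ordered = self.genes if self.locus_orientation == "+" else self.genes[::-1]
        self._rank = {g.name: i for i, g in enumerate(ordered)}
        self._anchors = self._build_anchors()

    # -- anchors -----------------------------------------------------------
    def _anchor_position(self, gene: GeneAnnotation, side: str) -> int:
        # upstream = J-ward boundary of the gene along the locus axis
        if self.locus_orientation == "+":
            return gene.start if side == "upstream" else gene.end
        return gene.end if side == "upstream" else gene.start

    def _build_anchors(self) -> list[RssAnchor]:
        anchors = []
        for g in self.genes:
            for side in sorted(g.rss_sides):
                anchors.append(
                    RssAnchor(g.name, g.segment_class, side, self._anchor_position(g, side))
                )
        # stable locus order: gene rank, then upstream side first
        anchors.sort(key=lambda a: (self._rank[a.gene], a.side != "upstream"))
        return anchors

    @property
    def anchors(self) -> list[RssAnchor]:
        return list(self._anchors)

    def locus_rank(self, gene: str) -> int:
        """Index of the gene along the J -> D -> V axis."""
        return self._rank[gene]

    def gene(self, name: str) -> GeneAnnotation:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    # -- derived intervals -------------------------------------------------
    @property
    def jd_interval(self) -> Optional[tuple[int, int]]:
        """Closed span from the outermost J gene to the outermost D gene."""
        jd = [g for g in self.genes if g.segment_class in ("J", "D")]
        if not jd:
            return None
        return (min(g.start for g in jd), max(g.end for g in jd))

    @property
    def jd_intergenic(self) -> Optional[tuple[int, int]]:
        """Gap between the D-proximal J gene and the J-proximal D gene."""
        js = [g for g in self.genes if g.segment_class == "J"]
        ds = [g for g in self.genes if g.segment_class == "D"]
        if not js or not ds:
            return None
        if self.locus_orientation == "+":
            lo = max(g.end for g in js)
            hi = min(g.start for g in ds)
        else:
            lo = max(g.end for g in ds)
            hi = min(g.start for g in js)
        return (lo, hi) if lo < hi else None

    @property
    def span(self) -> tuple[int, int]:
        return (min(g.start for g in self.genes), max(g.end for g in self.genes))


@dataclass
class ReferenceSet:
    """Named references with locus maps and a fixed tie-break priority."""

    members: list[tuple[str, object, LocusMap]]
    priority: Optional[list[str]] = None

    def __post_init__(self) -> None:
        names = [m[0] for m in self.members]
        if len(names) != len(set(names)):
            raise ValueError("reference names must be unique")
        if self.priority is None:
            self.priority = list(names)
        if sorted(self.priority) != sorted(names):
            raise ValueError("priority must be a permutation of reference names")

    def locus_map(self, name: str) -> LocusMap:
        for n, _, lm in self.members:
            if n == name:
                return lm
        raise KeyError(name)

    def priority_rank(self, name: str) -> int:
        return self.priority.index(name)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def load_locus_map(
    annotation_path, reference_name: str, locus_orientation: str = "+"
) -> LocusMap:
    """Read a BED-like TSV annotation into a :class:`LocusMap`.

    The file must carry a header with columns
    ``reference start end gene class functionality strand rss_sides``;
    ``rss_sides`` is a comma-joined subset of upstream/downstream. ``#``
    comment lines are allowed. Malformed rows raise
    :class:`AnnotationError` with the offending row number.
    """
    genes: list[GeneAnnotation] = []
    with open(annotation_path, newline="") as fh:
        rows = [
            (i + 1, line)
            for i, line in enumerate(fh)
            if line.strip() and not line.startswith("#")
        ]
    if not rows:
        raise AnnotationError("empty annotation file")
    header = rows[0][1].rstrip("\n").split("\t")
    missing = [c for c in ANNOTATION_COLUMNS if c not in header]
    if missing:
        raise AnnotationError(f"missing required column(s): {missing}")
    idx = {c: header.index(c) for c in ANNOTATION_COLUMNS}
    for rowno, line in rows[1:]:
        parts = line.rstrip("\n").split("\t")
        if len(parts) < len(header):
            raise AnnotationError(f"row {rowno}: expected {len(header)} columns")
        if parts[idx["reference"]] != reference_name:
            continue
        try:
            sides = frozenset(
                s for s in parts[idx["rss_sides"]].split(",") if s
            )
            genes.append(
                GeneAnnotation(
                    name=parts[idx["gene"]],
                    segment_class=parts[idx["class"]],
                    functionality=parts[idx["functionality"]],
                    reference=parts[idx["reference"]],
                    start=int(parts[idx["start"]]),
                    end=int(parts[idx["end"]]),
                    strand=parts[idx["strand"]],
                    rss_sides=sides,
                )
            )
        except (ValueError, AnnotationError) as exc:
            raise AnnotationError(f"row {rowno}: {exc}") from exc
    if not genes:
        raise AnnotationError(f"no rows for reference {reference_name!r}")
    return LocusMap(reference_name, genes, locus_orientation)


def write_locus_map(locus_map: LocusMap, path) -> None:
    """Serialize a LocusMap back to the annotation TSV dialect."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(ANNOTATION_COLUMNS)
        for g in locus_map.genes:
            w.writerow(
                [
                    g.reference,
                    g.start,
                    g.end,
                    g.name,
                    g.segment_class,
                    g.functionality,
                    g.strand,
                    ",".join(sorted(g.rss_sides)),
                ]
            )


def nearest_rss(
    locus_map: LocusMap, position: int, max_dist: int
) -> Optional[tuple[RssAnchor, int]]:
    """Closest RSS anchor within ``max_dist`` bp of ``position`` (inclusive).

    Ties are broken by locus order, J-proximal anchor first.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    best: Optional[tuple[RssAnchor, int]] = None
    for a in locus_map._anchors:  # already in locus order
        d = abs(a.position - position)
        if d <= max_dist and (best is None or d < best[1]):
            best = (a, d)
    return best


def genes_in_interval(
    locus_map: LocusMap, interval: tuple[int, int]
) -> list[GeneAnnotation]:
    """Genes whose interval overlaps the half-open query, in locus order."""
    lo, hi = interval
    hit = [g for g in locus_map.genes if g.start < hi and g.end > lo]
    hit.sort(key=lambda g: locus_map.locus_rank(g.name))
    return hit
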