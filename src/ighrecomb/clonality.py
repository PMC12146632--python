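"""Clonality of an LCL sample from its read-level recombination evidence.

Reads supporting the same recombination event (same event class, same
gene/side set) are pooled into *distinct events*; Simpson's index

    SI = sum_i n_i^2 / N^2,

with ``n_i`` the reads supporting distinct event i and ``N`` the total
number of recombination-bearing reads, is the probability that two reads
drawn at random (with replacement) support the same event. One dominant
event per haplotype gives SI near 0.5; at ~38x coverage the measurable
floor is about 1/38 ~ 0.03. Samples are labelled monoclonal above 0.25,
polyclonal below 0.125, intermediate in between.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .config import Config, DEFAULT_CONFIG
from .read_profiler import EventClass, ReadEvidence

EventKey = tuple[str, tuple[tuple[str, str], ...]]


@dataclass
class DistinctEvent:
    key: EventKey
    read_ids: list[str]

    @property
    def n(self) -> int:
        return len(self.read_ids)


@dataclass
class ClonalityReport:
    si: Optional[float]
    n_total: int
    n_distinct: int
    label: Optional[str]
    thresholds: tuple[float, float]
    #: informational: fraction of reads in the dominant event
    dominant_fraction: Optional[float] = None

    def to_dict(self) -> dict:
        return {
            "si": self.si,
            "n_total": self.n_total,
            "n_distinct": self.n_distinct,
            "label": self.label,
            "thresholds": {"monoclonal": self.thresholds[0], "polyclonal": self.thresholds[1]},
            "dominant_fraction": self.dominant_fraction,
        }


@dataclass
class GeneUsageTable:
    vj_counts: dict[tuple[str, str], int]
    dj_counts: dict[tuple[str, str], int]
    scope: str


def canonical_key(event_class: EventClass, genes_used: Iterable[tuple[str, str]]) -> EventKey:
    """Injective key on (class, gene set, sides), order-independent."""
    return (str(event_class), tuple(sorted(genes_used)))


def aggregate_events(
    evidences: Sequence[ReadEvidence], confident_only: bool = False
) -> list[DistinctEvent]:
    """Group one sample's recombination-bearing reads into distinct events.

    Unrecombined reads and reads without a meaningful junction never enter
    (they do not bear a recombination event, so they are outside N); with
    ``confident_only`` only reads whose junctions all sit within the RSS
    window count.
    """
    groups: dict[EventKey, list[str]] = defaultdict(list)
    for ev in evidences:
        if ev.event_class is EventClass.unrecombined or not ev.has_meaningful:
            continue
        if confident_only and not ev.confident:
            continue
        groups[canonical_key(ev.event_class, ev.genes_used)].append(ev.read_id)
    out = [DistinctEvent(key, sorted(ids)) for key, ids in groups.items()]
    out.sort(key=lambda e: (-e.n, e.key))
    return out


def simpson_index(events: Sequence[DistinctEvent]) -> Optional[float]:
    """SI = sum(n^2) / N^2 over distinct events; None for an empty sample."""
    n_total = sum(e.n for e in events)
    if n_total == 0:
        return None
    return sum(e.n ** 2 for e in events) / n_total ** 2


def classify_clonality(
    si: Optional[float], config: Config = DEFAULT_CONFIG
) -> Optional[str]:
    if si is None:
        return None
    if not 0 < si <= 1:
        raise ValueError(f"Simpson's index out of range: {si}")
    if si > config.monoclonal_threshold:
        return "monoclonal"
    if si < config.polyclonal_threshold:
        return "polyclonal"
    return "intermediate"


def clonality_report(
    events: Sequence[DistinctEvent], config: Config = DEFAULT_CONFIG
) -> ClonalityReport:
    si = simpson_index(events)
    n_total = sum(e.n for e in events)
    dominant = max((e.n for e in events), default=0)
    return ClonalityReport(
        si=si,
        n_total=n_total,
        n_distinct=len(events),
        label=classify_clonality(si, config),
        thresholds=(config.monoclonal_threshold, config.polyclonal_threshold),
        dominant_fraction=dominant / n_total if n_total else None,
    )


def gene_usage(
    items: Sequence[DistinctEvent] | Sequence[ReadEvidence],
    scope: str = "reads",
) -> GeneUsageTable:
    """Tabulate V-J pairs of complete V(D)J events and D-J pairs of
    D-J-only events; only the canonical classes feed the tables.

    ``scope``: 'reads' counts supporting reads, 'distinct_events' counts
    each event once. (Per-individual tallies are obtained by summing
    distinct-event tables across samples, counting each pair once each.)
    """
    if scope not in ("reads", "distinct_events"):
        raise ValueError(scope)
    vj: dict[tuple[str, str], int] = defaultdict(int)
    dj: dict[tuple[str, str], int] = defaultdict(int)

    def add(event_class: str, genes: Sequence[tuple[str, str]], weight: int) -> None:
        j = [g for g, _ in genes if g.upper().startswith("IGHJ")]
        v = [g for g, _ in genes if g.upper().startswith("IGHV")]
        d = [g for g, _ in genes if g.upper().startswith("IGHD")]
        if event_class == str(EventClass.complete_VDJ) and j and v:
            vj[(v[0], j[0])] += weight
        elif event_class == str(EventClass.DJ_only) and j and d:
            dj[(d[0], j[0])] += weight

    for item in items:
        if isinstance(item, DistinctEvent):
            cls, genes = item.key
            add(cls, genes, item.n if scope == "reads" else 1)
        else:
            if not item.confident:
                continue
            add(str(item.event_class), item.genes_used, 1)
    return GeneUsageTable(dict(vj), dict(dj), scope)


def merge_usage_by_individual(tables: Sequence[GeneUsageTable]) -> GeneUsageTable:
    """Count each gene pair once per sample across many samples."""
    vj: dict[tuple[str, str], int] = defaultdict(int)
    dj: dict[tuple[str, str], int] = defaultdict(int)
    for t in tables:
        for pair in t.vj_counts:
            vj[pair] += 1
        for pair in t.dj_counts:
            dj[pair] += 1
    return GeneUsageTable(dict(vj), dict(dj), "individuals")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_events_tsv(events: Sequence[DistinctEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write("event_class\tgenes\tn\tread_ids\n")
        for e in events:
            cls, genes = e.key
            gene_str = ",".join(f"{g}:{s}" for g, s in genes) or "."
            fh.write(f"{cls}\t{gene_str}\t{e.n}\t{','.join(e.read_ids)}\n")


def write_clonality_json(report: ClonalityReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")


def write_usage_tsv(table: GeneUsageTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("table\tgene_a\tgene_j\tcount\n")
        for (a, j), c in sorted(table.vj_counts.items()):
            fh.write(f"VJ\t{a}\t{j}\t{c}\n")
        for (a, j), c in sorted(table.dj_counts.items()):
            fh.write(f"DJ\t{a}\t{j}\t{c}\n")
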