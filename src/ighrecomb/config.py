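"""Shared tunable parameters.

All distance/length values are base pairs on the reference or read unless
noted. Defaults mirror the published IGH analysis protocol; everything is a
plain dataclass field so callers (and the CLI) can override per run.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class Config:
    # --- read-level event calling ---
    #: maximum distance between a split site and the nearest RSS anchor for
    #: the breakend to count as RSS-confident (inclusive).
    rss_window: int = 50
    #: unaligned gap tolerated between adjacent read segments (non-templated
    #: junction nucleotides plus an aligner-collapsed short D gene).
    adjacency_slack: int = 30
    #: in-CIGAR deletions shorter than this are ignored when scanning for
    #: D-D recombination evidence.
    cigar_del_min_len: int = 100
    #: |deletion length - inter-anchor distance| tolerance for the D-D
    #: deletion rule (inclusive).
    dd_del_tolerance: int = 50
    #: minimum germline-consistent flank reaching into the J-D intergenic
    #: region required to resolve a D<->V junction as V-D-only rather than
    #: multiple-D.
    vd_flank_min: int = 200

    # --- clonality ---
    #: Simpson's index above this -> monoclonal.
    monoclonal_threshold: float = 0.25
    #: Simpson's index below this -> polyclonal.
    polyclonal_threshold: float = 0.125

    # --- assembly assessment ---
    #: gene hits with edit distance above this are treated as orphons.
    orphon_max_mismatch: int = 15
    #: two gene hits of different segment classes closer than this on a
    #: contig constitute a V(D)J junction call (inclusive).
    junction_window: int = 10_000
    #: D gene exempted from the junction rule (it sits within the window of
    #: the J genes in the germline locus).
    junction_exempt_d: str = "IGHD7-27"
    #: short-read alignments below this MAPQ are ignored in validation.
    validate_mapq_min: int = 10
    #: confident gene rule: fully covered and edit distance <= this.
    validate_max_edit: int = 1
    #: fraction of an allele's length allowed as edit distance when locating
    #: it on a contig (annotator search cap).
    annotate_max_edit_frac: float = 0.25
    #: alleles at or below this length (the D genes) get a near-exact cap
    #: instead, since a 25% cap on a 20-mer admits chance matches.
    annotate_short_allele_len: int = 40
    annotate_short_max_edit: int = 2
    #: gene pairs that share sequence with a "D"-suffixed duplicate and are
    #: renamed positionally when two instances occur on one contig.
    duplicate_gene_bases: tuple[str, ...] = ("IGHV3-23", "IGHV1-69", "IGHV2-70")

    # --- read surgery / enrichment ---
    #: post-cut fragments shorter than this are dropped (logged).
    min_fragment: int = 500
    #: copies emitted for reads overlapping the J-D enrichment region.
    enrich_factor: int = 2
    #: flank added to the J-D interval when building the enrichment region.
    enrich_flank: int = 0

    # --- reference building / masking ---
    #: minimum identity for a guided-assembly contig to count as supported
    #: by a de novo contig.
    contig_support_min_identity: float = 0.95
    #: minimum aligned length for contig support.
    contig_support_min_len: int = 5_000
    #: documented locus-cropping constants of the evaluation protocol
    #: (telomere-end and centromere-end extensions); provided for reference
    #: only, not used by this package.
    crop_telomere_ext: int = 100_000
    crop_centromere_ext: int = 376_000


DEFAULT_CONFIG = Config()
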