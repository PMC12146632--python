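# Methods

This note documents the models, rules and numerical choices behind
`ighrecomb`, the assumptions they rest on, and what the synthetic test
system does and does not show about real data.

## Coordinate model and RSS anchors

All coordinates are 0-based, half-open. The locus vocabulary is expressed
along the J→D→V axis ("upstream" = toward the J end), independent of
reference strand, so one code path serves toy loci and either orientation
of the real locus. Recombination signal sequences are modelled as single
*anchor* coordinates at gene boundaries: each J gene carries one anchor
on its D-facing (downstream) side, each V gene one on its D-facing
(upstream) side, and each D gene both. This is deliberate: the read-level
test is "split site within 50 bp of the RSS", and a point anchor plus a
distance threshold reproduces that test without modelling
heptamer/nonamer structure. The 50 bp window is inclusive at exactly 50
(the protocol's phrasing "within 50 bp" is read as ≤ 50) and is a
configuration value, not a constant.

Annotation invariants enforced at load time: D genes are ≤ 40 bp (human D
genes never exceed this) and carry both anchor sides; J and V genes carry
exactly one; no V gene may overlap the J–D interval.

## Read-level event calling

Alignment records (primary + supplementary, or an SA tag when
supplementary records are absent) are normalised into read-oriented
segments, reconciling hard- and soft-clip conventions. Junctions form
between adjacent segments; when segments overlap on the read (aligners
double-count a few junction bases) the junction point is the overlap
midpoint — symmetric and deterministic. Unaligned gaps of up to 30 bp
between adjacent segments are tolerated without breaking adjacency: they
absorb non-templated N/P junction nucleotides and an aligner-collapsed
short D gene (≤ 40 bp). The 30 bp default is a configuration value; the
simulator's junction-insertion cap is tied to it.

D–D recombination between nearby D genes can surface as a long in-CIGAR
deletion rather than a split. A deletion of length L (≥ 100 bp, below
which indel noise dominates; the shortest inter-D RSS distances in the
real locus exceed 100 bp) is accepted as a junction when |L − d| ≤ 50,
where d is the distance between the D-facing anchors of the two flanking
D genes. Anchor proximity itself is *not* required here because aligners
slide deletions within repetitive D-locus sequence; such junctions count
as confident by this rule alone.

Classification applies to confident junctions (both breakends anchored,
or the D–D rule): a single J↔V junction is a complete V(D)J (the D
segment is too short to split on); J↔D is D–J-only; D↔V is V–D-only when
the D-side segment runs ≥ 200 bp into the J–D intergenic region in
germline form, else multiple-D — the published rule describes this signal
qualitatively, and 200 bp is our quantitative default; a junction joining
two distinct D genes is multiple-D; two junctions using two distinct D
genes are multiple-D (RSS skipping); two junctions using both sides of
one D gene between a J and a V are a complete V(D)J whose D survived as a
separate segment (the event key then omits the D, matching the collapsed
single-junction form, since the read-level call cannot always resolve the
D); any flipped junction is an inversion typed by its anchor classes;
anything else with a meaningful junction is complex. Reads whose only
junctions join two V genes are excluded before classification: such
connections are treated as potential germline structural variation, not
somatic recombination.

With alignments to several references, evidence is ranked by (1) all
breakends RSS-confident, (2) number of RSS-confident breakends, (3) fewer
complex/non-meaningful junctions, (4) fixed reference priority. A read
aligned on only one reference is ranked by the same key (evidence beats
absence). Reads are processed in lexicographic id order so outputs are
byte-stable. Only reads touching the J–D interval are analysed; any
recombination involving a V gene also involves a J or D gene, so this
restriction keeps V-locus germline SVs out without losing events.

## Clonality

Distinct events are keyed by (event class, sorted gene/side set); the key
is injective on that tuple. Simpson's index SI = Σn²/N² uses all
recombination-bearing reads (meaningful junctions) by default, with a
confident-only switch; the published analysis computes gene usage on
confident events but states no confidence qualifier for SI, and we follow
that reading. Unrecombined reads never enter N. An empty sample yields an
absent SI, not zero. Labels: monoclonal strictly above 0.25, polyclonal
strictly below 0.125, intermediate otherwise (the thresholds themselves
are intermediate). Gene-usage tables are fed only by the canonical
classes: complete V(D)J increments the V–J table, D–J-only the D–J table.
The alternative "dominant-event fraction" clonality is reported as an
informational field only.

## Assembly assessment

The annotator locates every database allele on every contig by infix
(semi-global) edit distance on both strands, iteratively masking found
copies so tandem duplications yield one hit per copy, then keeps the
best-scoring allele per gene per locus position. The search cap is 25% of
allele length, tightened to 2 edits for alleles ≤ 40 bp (the D genes),
where a 25% cap would admit chance matches. Limitations: a second copy
diverged from the first by more than the cap is found only through the
iterative masking of better copies; alleles absent from the database are
invisible.

Orphon handling mirrors the published rule: hits with more than 15
(unit-cost) edits are dropped, and contigs left without hits are removed.
Duplicate pairs (IGHV3-23/-23D, IGHV1-69/-69D, IGHV2-70/-70D) cannot be
separated by sequence; when two instances occur on one contig the
instance matching the reference layout position takes the "D" name and
further copies are flagged rather than invented names.

V(D)J junction calls require two hits of different segment classes within
10 kbp (inclusive) on one contig; the D gene that germline-adjacent to
the J genes (IGHD7-27 in the real annotation) is exempted from D/J calls.
Breakpoints between coordinate-adjacent contigs (ordered by the median
locus rank of their hits — robust to single mis-annotations) are disjoint
when their rank intervals do not meet (only these lose genes), a
duplication when one gene set contains the other, and an overlap
otherwise; the containment rule is our concrete reading of an otherwise
qualitative distinction. Gene presence is counted once per haplotype, and
the headline V count excludes pseudogenes.

Short-read validation: a base is covered when ≥ 1 read with MAPQ ≥ 10
spans it and supported when ≥ 1 such read agrees with the assembly base;
per gene, edit distance = covered-but-unsupported bases, and a gene is
confident iff fully covered with edit ≤ 1. Defining support per base
(rather than per read pair) is deterministic and testable, and both
readings are consistent with the published phrasing.

## Read surgery and enrichment

Reads with somatic junction evidence are cut at the junction midpoint on
the read — including CIGAR-deletion junctions, which are equally somatic —
while V–V junctions and unrecombined reads are never cut. Fragments are
named `readid/k`; the concatenation of a read's fragments equals the
original read, and fragments under 500 bp (an assembler-friendly floor;
configurable) are dropped and logged. Quality strings are sliced
alongside. Enrichment duplicates every read or fragment whose alignment
touches the J–D region exactly once (factor 2, configurable), doubling
depth there exactly; enriched output is intended only for de novo
assembly.

## SV typing, stitching, masking

Deletion SVs are typed per contig from gene content: both flank genes
present with no inside gene supports the deletion allele; any inside gene
supports the default; anything else — including a single flank — is
unknown. The complex SV is typed by haplotype-unique genes, unknown when
neither or both sets appear. Within a parental group, unknown is
compatible with anything and default-vs-alternative on one SV is a
conflict; reconciliation tries every single-contig move between groups in
lexicographic order and accepts the first conflict-free assignment,
otherwise reports that manual reconciliation is required.

The personalized reference copies the backbone and swaps the span of each
alternative-called SV for a registered segment. Spans include the flank
genes, with junctions at the midpoint between each flank gene and its
nearest outside neighbour — deterministic and safely inside intergenic
sequence. Unknown calls keep the default source. The segment registry
abstracts the five source references of the published protocol as named
sequences; the shipped fixtures use toy segments with the same topology,
because the logic, not the sequences, is what this package contributes.
Masking replaces positions with neither read coverage (counting
secondary/supplementary records and deletion-spanned bases) nor de novo
contig support (≥ 95% identity over ≥ 5 kb, configurable — the support
criterion is otherwise unspecified) with N, drops scaffolds with no
contig support at all, preserves lengths, and is idempotent.

## Synthetic system and what passing tests mean

The toy locus compresses the ~1 Mb IGH locus ~20×: 3 J (60 bp), 5 D
(20 bp), 8 V (300 bp) genes in J→D→V order with RSS anchors at the
recombining boundaries, 4 kb of flanking pad on each side (≥ one read
length, so junction-spanning probabilities are not biased by sequence
ends), and 4 kb reads standing in for HiFi reads. Default sampling depth
is 38× — the IGH-locus coverage of the emulated datasets — with
substitution-only errors at 0.2% (HiFi-like; indel errors and somatic
hypermutation are not modelled). Reads are drawn uniformly per clone
haplotype at clone-proportional rates (Poisson counts), roughly half on
the reverse strand, and truth alignments are emitted directly as SAM —
with supplementary records and SA tags, or SA-only to exercise that
dialect — so no aligner runs in the test loop. Event haplotypes delete
between the same anchors the biology uses (D–J excision, then V–D) or
reverse-complement the span between the stated anchors for inversions;
truth segments shorter than 50 bp are soft-clipped the way an aligner
would treat an unanchorable fragment, and colinear segments separated by
≤ 1 kb are merged into a single record with a deletion CIGAR (this is how
D–D deletion events surface).

Each simulated read carries a geometrically derived *expected* evidence
record: the junctions it covers with ≥ 50 bp anchorable flank on both
sides, classified by the same published rules applied to truth geometry.
A read from a V–D-only clone whose flank does not reach 200 bp into the
J–D intergenic region genuinely supports only a multiple-D-compatible
junction, and its expectation says so; recall statistics are therefore
measured against what each read's evidence supports, which is the honest
per-read ground truth. Passing the error-free recovery tests shows the
detection and classification machinery is exact on clean split
alignments; it does not show robustness to real aligner behaviour —
breakend wobble beyond the insertion model, SHM-dense junctions,
reference bias between genuinely different references — nor does the toy
SV catalogue capture the repeat structure that makes the real V locus
hard. The multi-reference selection logic is exercised with synthetic
rank fixtures, not with three genuinely divergent references.

The SV fixture mirrors the real catalogue's topology (six simple
deletions plus one complex variant whose alternative haplotype carries
two genes absent from the backbone) on a 22-V-gene toy locus; the 2⁷
round-trip shows typing, consolidation and stitching are mutually
consistent, not that the real source sequences are correct.

## Numerical and determinism choices

Everything that draws randomness takes a seed; outputs are byte-stable
for a fixed seed. Ties in nearest-RSS lookup break J-proximal first;
reference ties break by fixed priority; contig moves during
reconciliation try lexicographic order; junction midpoints round down.
Simpson's index statistics in the parameter-recovery test use the
multinomial sampling model: conditional on N recombination-bearing reads,
the estimator's mean is Σf² + (1 − Σf²)/N and its first-order variance
4(Σf³ − (Σf²)²)/N; recovery is asserted within three such standard
errors per seed. Problem sizes used by the test suite (depths 20–120×,
4 kb reads, ≤ 23 kb loci, 128 SV genotypes) were chosen as the smallest
scales at which every rule boundary and sampling property is still
exercised with comfortable margins.
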