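# Methods

## Ancestry classification model

A single-gene tree is treated as an unrooted topology; the unit of
evaluation is the bipartition (clan pair) induced by each internal edge,
never a rooted clade, because the rooting of maximum-likelihood output is
arbitrary. For every bipartition with bootstrap support at or above
`support_min` (default 75, on a 0–100 scale), each side containing at
least one focal-taxon leaf is tested for the composition rule: focal
leaves plus one or more leaves of exactly one defined taxonomic group,
no second group, no unmapped taxon. The set of qualifying groups across
all edges forms the tree's bins:

- 1 or 2 bins → `classified` (two bins is the dual assignment: two
  disjoint well-supported sister clans pointing at different donors);
- 0 bins → `unclassified`;
- more than 2 bins → `flagged`: reported in full but kept out of the
  classified tally, since no downstream convention exists for such trees.

Interpretation choices worth stating explicitly:

- A clan of focal leaves only does not qualify — sister-group evidence
  requires at least one donor-group member.
- Multiple focal paralogs in the qualifying clan are allowed; the rule
  constrains composition, not copy number.
- Nested qualifying edges for the same group count once (bins are a set).
- Any qualifying edge is accepted; the rule is not restricted to the
  smallest qualifying clan.
- Unresolvable leaf taxa (not in the taxonomy map) disqualify the clan
  they sit in and are logged, rather than being silently ignored.
- Leaf labels resolve to taxa by their first underscore-delimited field.
- Polytomies contribute no internal edges across the polytomy; supports
  on terminal edges are ignored.

Support-scale handling: supports are declared to be percentages in
[0, 100]. If every support in a tree is ≤ 1.0 *and* at least one is
strictly between 0 and 1, the tree is taken to use fractional supports
and rescaled ×100 with a warning; all-integer supports that happen to be
0/1 are left untouched, since rescaling them on the strength of two
values would silently promote support-0/1 edges to 0/100. With
`autoscale=False` fractional-looking trees are an error instead.

Prefilter comparisons are strict, matching the published funnel: a
protein needs at least 3 homologs with E-value < 10⁻² (not ≤), and a
trimmed alignment longer than 74 positions (≥ 75) with all sequences
determined.

## Organelle inclusion rules

Mitochondrial: include iff score > 0.9 (strict), or reference-ortholog
without non-mitochondrial function, or annotation-based except MTERF, or
manual. Attribution is by fixed priority (score → ortholog → annotation →
manual): the published per-category counts (607/343/62/81) sum exactly to
the published total (1093), which implies disjoint attribution, and
priority order makes it deterministic. Adding lower-priority evidence to
an included protein therefore never changes its category.

Plastid: stage one gates on (signal-peptide positive by either tool) AND
transit-peptide positive; the category records which signal tool(s)
fired. The mature-sequence window for transit-peptide prediction cuts
after the 1-based cleavage residue and truncates to 200 aa; when both
signal tools are positive the first tool's cleavage site is used
(configurable). Stage two is a union with reference-chloroplast orthologs
and then manual additions; already-included proteins keep their stage-one
category, so finalisation is idempotent and categories partition the
final set. A transit-peptide flag without any signal-tool positive is
logged as an inconsistency and ignored (the predictor only ran
downstream of a signal call). A protein satisfying both compartments'
rules is reported in both outputs with a warning; the source analyses do
not address overlap.

## Expression filters and concordance

The replicate layout is fixed at 3 light + 3 dark. Retention requires
detection in all three replicates of at least one condition, applied
identically to protein groups and transcript classes. "Observed in only
one state" means zero detections in the other condition, so a feature
fully detected in light and partially in dark counts as `both`
(quantifiable in both, not single-state).

Per-condition summary for ratios is the arithmetic mean of replicate
intensities with undetected replicates contributing zero (the exact
published summarisation is unstated; the mean of label-free
quantification intensities is the simplest defensible choice).
log₁₀(L/D) is finite when both means are positive; one zero mean yields
an infinite-flagged ratio (the single-state cohort); two zero means drop
the feature with a warning. Swapping condition labels negates every
finite ratio by construction.

Concordance pairs finite ratios through a many-to-one
transcript→protein-group map, averaging multiple transcripts per group,
and reports a Spearman rank correlation — chosen because the underlying
claim is about monotone agreement, not linearity, and no coefficient is
published to match. The plastid-encoded subset is reported separately.

## Genome architecture

Coordinates are 0-based half-open internally, converted losslessly from
1-based closed GFF3 (exon features grouped by `Parent`). Contig selection
is strict (> 10 kbp). Introns are the gaps between consecutive exons;
donor/acceptor dinucleotides are read from the contig sequence,
reverse-complemented on the minus strand, and classified as conventional
(GT..AG), intermediate (exactly one canonical boundary) or
nonconventional (neither). GC..AG is not conventional by default but the
rule is exposed as a flag, since the boundary taxonomy for euglenid
nonconventional introns is a convention rather than a measurement.
Boundaries containing N are `ambiguous` and excluded from percentage
denominators. Means are reported to 2 decimals, percentages to 1.

## Synthetic data: what it emulates and what it does not

The generators produce inputs with the *count structure* the analyses
consume, not biologically realistic sequences:

- **Gene trees** are small fixed-shape topologies (focal + two planted
  donor-group leaves as a clan at the configured support, four background
  leaves spanning at least two other groups). The two-group background
  guarantee is what makes planted recovery exact: no clan containing the
  focal leaf other than the planted one can be taxonomically homogeneous.
  Noise modes plant sub-threshold support or a mixed-group sister clan.
  Real trees have variable size, rogue taxa and correlated support
  errors; passing the planted-recovery tests shows the rule is
  implemented correctly, not that 75% bootstrap is a good threshold.
- **Tool-score tables** assign each protein at most one mitochondrial and
  one plastid evidence pattern with exact category counts, plus decoys
  exercising every exclusion clause (MTERF, non-mitochondrial ortholog,
  score exactly at threshold, signal-positive without transit peptide).
  The ChloroP-negative pattern counts are free parameters set so the
  marginal signal-tool totals match the published ones.
- **Replicate tables** realise exact detection-pattern counts; intensities
  are a log-normal baseline shifted by half the true effect per condition
  with log-normal replicate noise (σ = 0.05 in log₁₀ by default, effect
  σ = 0.5). Protein and RNA effects are independent except a
  plastid-encoded subset sharing one effect — the structure, not the
  mechanism, of translational decoupling.
- **Toy genomes** meet configured intron counts, total lengths and
  splice-class mixes exactly; sequence is materialised only for
  gene-bearing contigs (lengths suffice elsewhere). The calibrated
  configuration honours the published intron-side numbers (135 models,
  271 introns, 278,354 bp, 218/30/23 classes, 53 of 1459 contigs with
  CDS); the published exon count is arithmetically inconsistent with
  those (271 introns over 135 single-transcript models imply 406 exons)
  and is not reproduced.

Exact-count mode is the default for the calibrated configurations;
multinomial sampling would only add noise around the same frequencies.
All randomness flows from a single integer seed through
`numpy.random.default_rng`; a fixed seed gives byte-identical outputs.

## Problem sizes and numerical choices

The calibrated runs use the published table sizes directly (4087 trees of
8 leaves, 36,526-protein score table, 8661 + 66,542 replicate features,
1459 contigs) — all complete in seconds. Property suites use 200–1000
random trees of ≤ 8 leaves and n = 2000 features for correlation
recovery. Integer percentages use round-half-even; they are reported per
bin and for user-defined rollups (e.g. all excavate bins), computed from
summed counts, never by summing rounded percentages. A dual-bin tree
counts once in the classified denominator and once per bin in the
numerators, so bin counts sum to classified + dual.

## Known limitations

- The classifier consumes one tree per protein and does not model
  alignment or tree-inference error beyond the support values it is
  given; the direction of transfer is not inferred.
- Peptide-to-protein-group assembly, differential-expression testing and
  the external predictors themselves are out of scope; their outputs are
  inputs here.
- The consolidated report is JSON-only.
- Behaviour for trees qualifying for three or more groups is a flag, not
  a classification; no published convention covers them.
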