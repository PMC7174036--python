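# Methods

This note documents the models and procedures magtk implements, the
parameters that matter, the synthetic-data generator's assumptions, and the
numerical and design choices made where the underlying method leaves room.

## Taxonomy-guided decontamination

A bin is a set of contigs, each with a 6-rank lineage (phylum, class,
order, family, genus, species) from a contig classifier. Classifiers emit
the token `NA` at unresolved ranks; because contamination can occur at any
rank, magtk first converts every lineage into concrete labels at all ranks:

- a non-`NA` entry is kept verbatim;
- `NA` at phylum becomes `P_NA`;
- `NA` at a lower rank becomes `<label one rank up, after propagation>` +
  `_NA_` + the rank letter (C, O, F, G, S).

Propagation is deterministic, is the identity on NA-free lineages, and
never leaves the bare token `NA` in its output. The species value
`Unknown species` is an ordinary observed label, not an `NA`. Lineages
shorter than six ranks are padded with `NA` at the tail by the reader;
longer lineages are assumed to carry leading super-rank fields (the
classifier's domain level), which are dropped.

Per rank, the composition of a bin is the fraction of its contigs carrying
each label. Fractions are **per contig count** by default; an optional
length-weighted mode divides by total base pairs instead. The per-contig
reading is the simplest interpretation of a label "percentage" and makes
subset fractions exact ratios of integers. A label is emitted as a
candidate subset when its fraction is **strictly greater** than the
threshold (default `min_fraction = 0.5`); strictness makes a 50/50 bin
yield no subset rather than two. With threshold 0 the subsets at a rank
partition the bin, and raising the threshold can only remove or leave
subsets unchanged (monotonicity) — both are tested properties.

Completeness and contamination of candidate subsets come from an external
assessor (e.g. CheckM); magtk only ranks them, by
`completeness − weight × contamination` with `weight = 5` by default
(a subset trading 5 completeness points for 1 contamination point is
considered neutral). Ties break toward higher completeness, then
lexicographic name.

## Coverage normalization

Coverage of a contig in a sample is defined as mapped reads divided by
contig length (reads per base). Normalization divides each sample column
by that sample's scaling factor, `total_mapped_reads / 1e6`. The per-base
definition is implemented literally; a `per_kb` switch rescales by 1000
for users whose tables are reads per kilobase. Since the grouping
threshold is data-derived (a median) and module abundance is linear in the
weights, the choice of per-base vs per-kilobase units cancels when applied
consistently.

`total_mapped_reads` is metadata supplied per sample, never recomputed
from the coverage table — whether the denominator counts reads mapped to
the MAG set or to the whole co-assembly is the user's choice and is simply
recorded.

The coverage container carries an explicit `raw`/`normalized` state and
rejects double normalization. Relative abundance of a MAG in a sample is
the sum of its member contigs' mapping ratios; a MAG summing above 1
(beyond 1e-9) is rejected as inconsistent input.

## Coverage-pattern groups

The global threshold TH is the median over **all** contig × sample
normalized entries (not per sample): a single global cut is what makes
groups comparable across samples. Binarization is *present iff value ≥ TH*.
The underlying rule table writes both `≥ TH` for presence and `≤ TH` for
absence, which overlap exactly at TH; resolving the boundary to "present"
makes the classification a total partition, verified exhaustively for
2–6 PL samples. The group of a contig follows from its presence pattern
over (AL, PL₁…PLₙ) as described in the README; `UN` is the remainder class
(AL present with a strict non-empty subset of PL present), and `PL_SUB`
generalizes to 2..n−1 PL samples present (the 4-PL study design gives
"2 or 3").

Depth trends: for PL_ALL and PL_SUB contigs only, Pearson correlation is
computed between the contig's PL coverages and the PL sample depths
(ordered by increasing depth; PL_Pi indices follow the same order). All PL
values enter the correlation, including sub-threshold ones — the trend
criterion is stated on PL coverage without restriction. r ≥ 0.9 tags KI,
r ≤ −0.9 tags KD; a zero-variance profile has undefined r and is never
tagged. Group assignment is invariant to rescaling the whole matrix
(TH scales along), and raising TH can never move a contig from LO into a
presence-requiring group.

## KEGG-Module abundance

A module is treated as a plain set of KOs (boolean definition grammars are
out of scope). Within a MAG, each annotated gene hit contributes its
contig's scalar weight; a KO's weight is the mean over its hits. Multiple
hits of one KO on the *same* contig each count separately by default
(`per_hit=True`); a per-distinct-contig mode is available. Module
abundance is the sum of present-KO weights divided by module size, so it
is bounded by the largest KO weight and equals w when every KO occurs
exactly once on weight-w contigs.

Because a contig's normalized coverage is a per-sample vector, group-level
aggregation needs a scalar per contig. The **weight policy** makes this
choice explicit (it is recorded in output headers):

- `group-mean` (default): mean over the samples whose presence defines the
  group — AL → the AL sample; BO → all samples; PL_ALL, KI, KD → all PL;
  PL_Pi → that sample; PL_SUB → the contig's supra-threshold PL samples;
  LO and UN → all samples.
- `max`: maximum over all samples.
- `per-sample`: no reduction; one output column per (group, sample).

A MAG is *present* in a group when at least one of its contigs is assigned
to it; the group value is the sum over present MAGs. By default KO weights
are computed **group-scoped** (only the group's contigs contribute), the
reading under which a group's matrix reflects the genetic material that
actually shows that coverage pattern; `group_scoped=False` (CLI
`--whole-mag`) instead evaluates each present MAG over all its contigs,
each weighted by its own group's scope. Both modes are tested against an
independent brute-force enumeration to 1e-9. KI/KD columns are overlays:
their contigs are selected by trend tag and also appear in their primary
group's column.

## Synthetic communities

The generator plants, per contig: a group label (optionally a KI/KD
trend), a bin of origin, a lineage (bin-cohesive majority lineage, or a
foreign lineage with NA at genus/species for planted contaminants), 2
genes with KOs drawn from the module pool (80% annotation rate), and a
per-sample normalized coverage profile. Defaults describe a community of
52 contigs in 3 bins over 1 AL + 4 PL samples at depths 110/122/135/170 cm
beneath the surface (AL at 7 cm), 20% planted contamination per bin, 6
modules of 4 KOs, and coverage strata at 5.0 (supra-threshold) and 0.05
(sub-threshold) with ±15% multiplicative jitter.

Profiles are planted on the normalized scale and multiplied by each
sample's per-million factor (drawn from 5–20 M mapped reads) to emit the
raw table, so normalization recovers them to machine precision. Three
constructions guarantee that truth tables match pipeline output exactly:

- **Median placement.** The counts of sub- and supra-threshold entries are
  balanced, so the global median falls in the gap between the strata and
  every planted presence pattern binarizes correctly. The default design
  is balanced as given; unbalanced designs get filler BO/LO/UN/PL_SUB
  contigs, recorded in the truth table (`auto_balance=False` turns this
  into an error).
- **Trend margins.** KI/KD contigs get exactly affine-in-depth PL profiles
  (r = ±1); trend-free PL_ALL/PL_SUB contigs are re-jittered (and for
  PL_SUB the presence subset re-drawn, since a depth-monotone subset is
  inherently depth-correlated) until |r| ≤ 0.8, a margin below the 0.9
  tag threshold.
- **Contamination bounds.** Contaminants per bin are capped strictly below
  half the bin, so the majority lineage always exceeds the default 0.5
  refinement threshold at every rank.

What the generator does **not** emulate: boundary-straddling coverage
(every value sits clearly in one stratum), shared KOs between modules,
strain-level taxonomic ambiguity, chimeric contigs, and any relationship
between sequence content and coverage (sequences are uniform random
nucleotides of 500–2000 bp). Passing recovery tests therefore shows the
classification and aggregation logic is correct under its stated
definitions, not that those definitions are robust to borderline real
data — on real data, contigs near the median or near |r| = 0.9 will be
sensitive to noise by construction of the method itself.

## Numerical choices and degenerate inputs

- Medians over an even count are the mean of the central pair (numpy).
- Pearson r is computed by numpy; an independent textbook-formula
  implementation in the test suite agrees to 1e-12.
- A PL_SUB contig with no supra-threshold PL sample cannot occur by
  definition; the group-mean policy still guards that case by falling back
  to all PL samples.
- Coverage readers treat blank cells as 0, reject negatives, and parse
  floats in round-trip precision so written tables read back bit-exact.
- Empty bins, empty matrices, zero-KO modules, non-positive read totals
  and wrong-arity lineages are rejected with named errors rather than
  propagated as NaN.
- Filename sanitization for subset FASTA maps runs of non-alphanumerics to
  `_`; collisions get numeric suffixes.

## Problem sizes

The test suite and the reproduction script run on communities of 52–150
contigs, 3–5 bins, up to 20 modules, and 5 samples; the exhaustive
partition check covers all presence patterns for 2–6 PL samples plus
10,000 random profiles. These sizes exercise every code path (all groups,
both trends, fillers, contamination at every rank) while keeping a full
run under a minute; all algorithms are linear or near-linear in contigs ×
samples and have no scale-dependent constants, the single data-derived
quantity (the median threshold) being recomputed per dataset.

## Known limitations

- The boolean structure of real KEGG MODULE definitions (alternative
  blocks, complexes) is deliberately ignored; module abundance here is a
  set-average statistic.
- The grouping scheme assumes exactly one AL sample, as in the depth-profile
  design it was built for; multiple AL samples would need an AL presence
  convention the method does not define.
- Completeness/contamination are consumed, never computed; the refinement
  score is a convenience ranking, not a quality model.
- With a single classifier as taxonomic ground truth, "decontamination"
  inherits the classifier's errors; the per-rank subsets exist precisely so
  users can pick the rank where they trust the labels.
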