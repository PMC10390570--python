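# Methods

## Input model and QC

The unit of observation is a *contig*: one assembled receptor-chain
transcript for one cell barcode. Both supported dialects (10x
`filtered_contig_annotations.csv`, AIRR Rearrangement TSV) are mapped to a
common record with the raw dialect values preserved verbatim; nothing is
coerced at read time so the QC stage sees exactly what the caller's
pipeline wrote.

QC applies four screens in a fixed order — `is_cell` FALSE,
`high_confidence` FALSE, chain outside {TRA, TRB}, `productive` None — and
attributes a multiply-failing record to the first failing criterion, so
drop tallies are deterministic and partition the input. Flag literals are
compared case-insensitively against `true`/`false` (`none` for
productive); unrecognized values fail the corresponding criterion and are
logged rather than silently kept, since an unparseable flag cannot attest
to the property the screen requires. TRD/TRG and `Multi` calls count as
wrong-chain: the analysis concerns αβ T cells only.

## Chains and cells

A chain is functional (F) only if its contig is productive **and** its V
segment is IMGT-functional. ORF-class V genes are treated as
non-functional: an ORF cannot be assumed to yield a working receptor, and
the conservative call only moves borderline chains from F to N.
Pseudogene V segments can appear in annotated, even "productive", contigs
and are always N. Chains whose V call is empty are retained as N with a
warning — they still occupy a slot in the cell's chain pattern.

Per-barcode contigs collapse to the cell's multiset of *distinct* chains,
where identity is the full (locus, V, D, J, C, CDR3-aa) tuple. Including
the junction prevents conflating independent rearrangements that happen
to reuse the same segments; duplicates keep the higher-UMI contig, with a
deterministic tie-break so collapse is order-independent.

## The 23-category scheme and TCR status

A cell's pattern is a pure function of its (locus, F/N) counts:
categories 1–4 are the single-chain cells, 5–14 the two-chain
combinations, 15–22 the same-locus three-chain combinations, and 23
("others") everything else. Mixed three-chain combinations (e.g.
β(F)+α(F)+α(N)) and all cells with ≥4 chains fall to "others"; only the
same-locus triples have their own categories. This matters when reading
pattern tables: "others" is not rare (it absorbs the common
one-pair-plus-extras cells).

TCR status depends only on functional-pair arithmetic: *abnormal* means no
β(F)+α(F) pair can be formed (including cells with three β(F) and no
α(F)); *single* means exactly one β(F) and one α(F), regardless of extra N
chains; *multiple* means both loci have ≥1 F chain and ≥3 F chains in
total. "Functional cell" ≡ status ∈ {single, multiple}. Cells whose
chains were all removed at QC never reach classification and are excluded
from denominators.

## Cohort summaries and tests

Per-sample: the functional proportion is over all classified cells; the
single/multiple split is over functional cells only and is reported as
undefined (not 0) when a sample has no functional cells.
`n_unique_sequences` is the count of distinct chain identity keys among
the sample's kept contigs — an explicit operational choice, since
"unique sequences" has no single standard meaning across upstream tools.

Group averages are **unweighted arithmetic means of per-sample
percentages**, not pooled-cell ratios; a two-hundred-cell sample counts as
much as a ten-thousand-cell one. Percentages are formatted at 3 decimals
with half-up rounding (spreadsheet convention, not banker's rounding).

Between-group comparisons dispatch on screens the test family requires:
Shapiro–Wilk normality per group at α=0.05 and, for ≥3 groups, Levene
homogeneity at α=0.05. Two normal groups get a two-tailed t test; ≥3
normal homoscedastic groups one-way ANOVA; otherwise Mann–Whitney or
Kruskal–Wallis. Identical samples short-circuit to statistic 0, p = 1.
Labels: \* for p<0.05, \*\* for p<0.01. The tests run on per-sample
percentages, not pooled counts.

## Locus topology

Mechanism inference needs only relative gene order, orientation, D–J–C
cluster membership and RSS spacer class, so loci are modelled as ordinal
tables, one row per gene, validated on load (strictly increasing
ordinals; exactly one reverse V per TRB locus, downstream of C2; RSS
classes fixed by segment class: V 23-spacer 3', D 12-spacer 5' +
23-spacer 3', J 12-spacer 5'). Using ordinals instead of coordinates
avoids assembly-version coupling. The packaged human/mouse TRA/TRB tables
are curated to the IMGT reference gene order; segment-level topology (V
array order, the two TRB D–J–C clusters, reverse TRBV30/TRBV31, the
inverted numbering of the TRAJ genes with TRAJ61 most 5') is faithful,
while allele-level detail and a handful of rare ORF/pseudogene
assignments are simplified. TRA tables list TRAV/DV dual-name genes under
their TRAV alias and omit the embedded TRD cluster. Gene-call
normalization strips allele suffixes and maps ambiguous multi-gene calls
(e.g. `TRBV12-3/12-4`) to the 5'-most member with a logged warning.

A reduced 12-segment toy locus (three forward V, one reverse V, two
two-J clusters) ships alongside for exhaustive oracle testing.

## Traceability

For a pair of same-locus rearrangements on one chromosome, feasibility is
decided by three rule predicates:

* **TREC-circle β**: circle-resident event uses cluster DJC1, the
  chromosome-resident event uses DJC2 with a strictly more 5' forward V —
  then the second V→D2 excision interval contains the first complete
  V-D1-J1 join, which persists on the excised circle and can be
  transcribed.
* **TREC-circle α**: the chromosome-resident V–J excision interval must
  strictly contain the circle-resident join (more 5' V *and* more 3' J).
* **Inversion**: exactly one event uses the reverse V; it must use DJC2
  and its partner DJC1. The cluster constraint is forced by physics, not
  convention: a forward V joining D2 first deletes cluster 1 entirely,
  and an inversional join onto D1 first leaves cluster 2 in inverted
  orientation where no canonical join geometry remains.

Every predicate also requires 12/23-legal joins. Role assignment (which
transcript is circle-resident) is inferred purely from positional
feasibility — transcripts carry no timestamps — and all feasible role
assignments are reported. N-status chains participate identically to F
chains. TRB contigs lacking a D call get the cluster's D inferred from
the J (with the C call as a consistency check); circle-resident
transcripts are not required to carry a C call.

The independent correctness reference is a brute-force excision oracle: a
chromosome is the ordinal list of segments; a deletional join excises the
open interval between the joined segments onto a circle (D–J first, then
V onto the fused block), an inversional join reverses the intervening
interval in place and flips its orientations; completed joins are atomic
blocks; a scheme (assignment of events to ≤2 chromosomes with a temporal
order) is feasible iff every join forms legally and each physical segment
is used at most once. Joins are only attempted in the two canonical
geometries (forward-V deletional upstream, reverse-V inversional
downstream); segments left in inverted orientation by a prior inversion
are not re-usable targets. Rule/oracle equivalence is checked
exhaustively on the toy locus (all 240 ordered event pairs) and on 500
random packaged-locus pairs per species and locus.

Cell-level calls enumerate partitions of a locus's events into ≤2
chromosomes: singleton parts are ordinary alleles, pairs need a feasible
mechanism, and ≥3 events on one chromosome are admitted only as strictly
nested TRA TREC chains (TRB is capped at two events per chromosome by its
two D clusters). `two_chromosomes` is reported whenever an all-singleton
partition covers the events (hence always for ≤2 same-locus events);
`unexplained` iff no partition works — e.g. three same-cluster β events.

## Synthetic data

The generator draws each cell's pattern from a 23-entry weight vector,
realizes it with locus-consistent uniform gene draws (cluster-consistent
D/J/C for TRB; N chains are 70% non-productive contigs with functional V,
30% productive contigs with pseudogene V), random 8–20-aa CDR3 junctions
(to keep identity keys distinct, with no biological junction model), and
appends QC-noise rows per criterion, reusing real barcodes to exercise
per-barcode filtering. The category-23 realization is drawn from seven
fixed mixed multisets (three single-pair-plus-extras, three multiple-TCR,
one abnormal), so configured weights imply a known status mix: P(single)
= w₁₁ + 3/7·w₂₃, P(multiple) = 3/7·w₂₃.

Default weights approximate a thymus-like mix (β(F)+α(F) dominant at 35%,
"others" 28%, ~15% single-chain cells led by β(F)); real repertoires have
skewed gene usage and depth-dependent dropout that the generator does not
model, so passing recovery tests demonstrates pipeline correctness, not
robustness to real-data artefacts. A usage-table hook exists but no
usage estimates ship.

Planted mechanism cells draw their gene pair from the feasible set by
construction and are re-verified against the excision oracle at
generation time; each planted cell carries the same-locus pair plus one
functional partner chain on the other locus, giving ≥3 chains. All
randomness flows from one `numpy` `default_rng(seed)`; identical configs
produce byte-identical output files.

The rearrangement-process simulator models at most one attempt per allele
over two alleles with a per-attempt success probability p; with p = 1/3,
first- and second-attempt success fractions converge to 1/3 and 2/9.

## Problem sizes and numerical choices

Recovery tests use 5000-cell samples (status-mix checks within binomial
95% intervals) and 2000-cell samples with 10%/5%/2% planted
TREC-β/TREC-α/inversion cells (≥99% recovery required); the
rearrangement simulator runs at n = 100 000 with a 3-standard-error
band. The whole suite runs in a few seconds on one CPU. Statistical
screens use scipy's Shapiro–Wilk, Levene, t, ANOVA, Mann–Whitney and
Kruskal–Wallis implementations; constant groups are treated as normal
(Shapiro is undefined there) and NaN p-values (fully degenerate inputs)
fall back to p = 1.

## Known limitations

* The locus tables are ordinal curations, not coordinate-exact IMGT
  exports; analyses needing base-pair positions or allele-level
  resolution are out of scope.
* Mechanism calls state *positional feasibility*, not proof: a feasible
  TREC-circle geometry does not demonstrate that the transcript came
  from a circle, and population-level mechanism frequencies are not
  estimated.
* The inversional-join simulation is a simplified geometry (the reverse V
  is relocated adjacent to the fused D–J block and the intervening
  interval inverted); it preserves exactly the retain-vs-excise and
  segment-reuse facts the mechanism logic depends on.
* No protein-level pairing, clonotype expansion, CDR3 analytics, UMI
  deduplication beyond the provided counts, or transcriptome integration.
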