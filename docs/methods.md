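# Methods

## Coordinate model

All genomic intervals are 0-based half-open with explicit strand; GTF input
(1-based inclusive) is converted on read, BED12 is taken as-is. Transcript
coordinates are cumulative exonic offsets in splicing (5′→3′) order, so all
breakpoint, CDS and kinase-domain arithmetic is strand-free after loading.
Exon indices are 0-based internally and 1-based in every user-facing table.
One transcript per gene (a MANE-style selection) is the expected input, but
multiple isoforms per gene are supported: junction matching tries each
isoform of the assigned gene and reports the transcript id alongside exon
numbers, since "exon N" is meaningless without the isoform. Kinase-domain
intervals are supplied as a table of transcript-coordinate ranges rather
than computed — domain prediction is out of scope, and the packaged toy
domain tables are synthetic.

## Read screening

A chimeric read is accepted when (c1) its two segments map to transcripts
of two different genes, (c2) each segment maps to exactly one gene and the
upstream aligner reported a single genomic hit, (c3) the 5′ segment's 3′
terminus falls on an annotated exon 3′ boundary and the 3′ segment's 5′
terminus on an exon 5′ boundary, and (c4) both segments align sense to
their transcripts. Read order defines the 5′/3′ moieties: criterion c4
forces sense orientation, so read order is transcript order.

Parameters:

* `tolerance_nt` (default 0 nt) — boundary-match slack for c3. Exact
  matching is the defining property of a spliced junction; the parameter
  exists because 50-nt FFPE reads can carry soft-clipped terminal bases.
* `min_overhang` (default 10 nt) — minimum segment length before a moiety
  is considered assignable at all; shorter overhangs fail c2. The value is
  a judgment call (a 50-nt read with a <10 nt overhang cannot anchor a
  gene), and is exposed because curation practice varies.

Ambiguity is judged from the aligner's reported multiplicity rather than by
re-searching the genome: re-implementing a BLAT-style search is out of
scope and every chimeric-output format carries a hit count.

Passing reads are grouped per distinct junction (donor transcript/exon ×
acceptor transcript/exon); distinct junctions of one gene pair remain
separate calls (breakpoint variants). Unique-read counts collapse exact
sequence duplicates only — reads sharing a start but differing in sequence
are independent evidence.

## Frame and domain annotation

A fusion is in-frame when both breakpoints lie inside their partners' CDS
and their codon phases agree. Breakpoints in UTRs are out-of-frame by
definition here, even though a native downstream start codon could in
principle rescue translation: the test is deliberately a purely structural
phase test. The tyrosine-kinase domain counts as retained only when its
interval is entirely inside the retained moiety ([bp₃, L) for a 3′ RTK,
[0, bp₅) for a 5′ RTK) — a truncated kinase domain is not the druggable
entity the criteria target, so partial retention is "no". When both
partners are RTKs the 3′ partner is the evaluated moiety, matching the
downstream-coverage criterion's definition.

## Coverage normalization

Per-exon read counts use the bedtools-multicov overlap rule (a read counts
for every exon it overlaps by ≥1 base; junction-spanning reads increment
both exons). Counts are double-normalized in one of two modes:

* **depth** — `cᵢ / (Lᵢ/10³) / (D/10⁶)` (reads per kilobase per million
  mapped), used within one sample; any per-sample constant cancels in the
  within-sample test.
* **gene** — `cᵢ / Lᵢ / Σⱼcⱼ`, used for cross-sample cohort comparison,
  where it removes between-sample differences in overall gene expression.
  An unexpressed gene maps to all zeros rather than 0/0.

Keeping both modes reconciles the two normalizations the method calls for:
depth-scaled values for the asymmetry test, gene-scaled values for
comparing a patient against a control cohort.

## Downstream-coverage criterion

Two tests, combined with OR ("and/or"), assessed only for fusions whose
RTK moiety is the 3′ partner (others report ND):

1. **Within-sample asymmetry** — one-sided Welch t-test on per-exon
   normalized values, downstream > upstream, α = 0.05 (default). The
   directional alternative matches the hypothesis (a promoter swap can
   only elevate downstream coverage); the unequal-variance form is the
   safer default since downstream exons have both higher mean and higher
   variance. Both choices are configurable. Exons are treated as
   independent observations — a statistical simplification (neighboring
   exons share fragments), so the nominal p-value is approximate; simulated
   null profiles put the empirical type-I error near 4% at α = 0.05.
   Fewer than two exons on a side yields "no" from this test (the cohort
   pattern may still fire); a junction at exon 1 leaves no upstream exons
   and the result is ND.
2. **Cohort pattern** — against ≥5 control samples of the same cancer type
   without the fusion: every downstream exon above the controls' per-exon
   empirical 95th percentile (linear interpolation) while every upstream
   exon lies within the t-based 95% CI of the control mean
   (mean ± t₀.₉₇₅,ₙ₋₁·sd/√n). Whether the upstream condition applies per
   exon or to the mean is not prescribed anywhere; per-exon with a strict
   all-exons aggregation is the default, with a `fraction` parameter to
   relax either side to "at least f of the exons". Note two consequences
   of the strict default: the mean-CI band is narrow (width ∝ sd/√n), so a
   noisy upstream profile often exits it and the pattern is conservative;
   and under gene-mode normalization a strongly expressed fusion deflates
   its own upstream share below the control band. Both situations are
   covered by the t-test arm of the OR. The pattern's strength is the
   opposite regime — a 3′ partner silent in controls (p95 = 0) with
   downstream-only expression in the fusion sample.

## Classifier and evaluation

The five criteria (ORF, TK, catalog membership, downstream coverage,
multiread) are scored as yes/no with ND counting as not-met; positive means
score ≥ k. Catalog membership is on the ordered (5′, 3′) pair — fusion
catalogs index directional events. The 5′/3′ moiety-expression concordance
is computed and reported per fusion but never enters the score: it proved
unreliable as a criterion. For the in-frame + domain-retained subgroup the
rule is ≥2 of {catalog, downstream, multiread}.

Evaluation against confirmed/non-confirmed labels reports per-criterion and
per-threshold sensitivity and specificity, raw fractions plus 2-decimal
rounding. ND rows are excluded from the downstream criterion's own Sn/Sp
denominators but retained (as not-met) in threshold scoring — the two
conventions are forced by consistency of the reported reference metrics
(downstream Sn 7/9 with the ND row dropped, yet threshold Sn 1.0 at k = 2
with the same fusion passing on other criteria). The subgroup threshold
sensitivity is reported under two catalog conventions — strict catalog
membership (5/7) and counting a literature-reported but uncatalogued
fusion as positive (6/7) — because the reference analysis is ambiguous on
this point and the package does not guess.

## Synthetic data

The generators emulate the study conditions the tool targets: 50-nt
single-end reads (FFPE fragment lengths), a 20-exon RTK transcript with
the junction at exon 12 (the prototypical RET configuration), 30 million
mapped reads per sample, a 20-sample same-type control cohort, and roughly
tenfold downstream over-expression in fusion-bearing samples. Per-exon
count noise is lognormal around the exon mean (mean-preserving, CV-
parameterized, default CV 0.2) rounded to integers — simple, heavy-tailed
like RNA-seq counts; no reference noise model exists for this setting.
Exon length (150 nt) is divisible by 3 and the CDS pads are multiples of 3,
so default toy junctions are in-frame by construction; the straddling-domain
flag produces domain-losing fusions. Reads are built from seeded random
reference sequence, with a configurable junction offset (for
boundary-tolerance sweeps) and duplicate-injection rate (for unique-read
counting).

What the simulations do **not** model: positional degradation bias along
transcripts, GC bias, paired-end reads, isoform mixtures, alignment errors,
or correlated exon noise. Passing the statistical property tests therefore
shows correctness of the statistics under idealized i.i.d. noise, not
performance on real FFPE libraries — the packaged 36-fusion feature matrix
of real validated calls is the bridge to real data.

## Problem sizes and numerical choices

Statistical properties are measured at: 500 null replicates for the
asymmetry type-I error, 200 replicates at fold-change 10 / CV 0.1 for
detection rate, 300 null cohorts (20 controls each) for the cohort
false-positive rate — sizes at which the binomial simulation error is well
below the margins being checked, while the whole suite runs in seconds.
Empirical quantiles use linear interpolation; t-quantities come from
scipy. Degenerate inputs are explicit: zero-variance t-tests report "no"
with a reason rather than NaN verdicts, all-zero genes normalize to zeros,
and a whole-gene-retained junction (exon 1) is ND.

## Known limitations

* Criterion c2 trusts the upstream aligner's multiplicity; a caller that
  reports multiplicity differently shifts the screen's stringency.
* The exon-independence assumption in the t-test overstates degrees of
  freedom for transcripts with few, long exons.
* The cohort pattern requires the 3′ partner to be quiet in controls;
  amplified genes (the ERBB2 situation) defeat it, as they elevate all
  exons regardless of the fusion.
* Catalog lookups are offline set-membership on gene symbols; no live
  database queries, no breakpoint-level matching.
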