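# Methods

This note documents the models, rules and numerical choices implemented in
stemsplice, what the synthetic-data generator does and does not emulate, and
the design decisions taken where more than one reasonable convention exists.

## Inclusion quantification

Inclusion levels are derived from junction reads only. For exon and intron
events, PSI/PIR = 100·Ī/(Ī+Ē) with Ī the arithmetic mean of
mappability-corrected counts over the event's inclusion junctions and Ē the
mean over its exclusion junctions. The averaging form is chosen because a
single included transcript molecule supports each inclusion junction of the
event exactly once, so the two (or more) inclusion junctions are replicate
measurements of the same inclusion rate; they enter the coverage rule
symmetrically for the same reason. Whether inclusion junctions should
instead be weighted by their mappable positions is an open choice; simple
averaging is used. Multi-exon cassette groups pool all C1→C2
forward-combination junctions into a single inclusion mean. Alternative
3'/5' events report percent splice-site usage: 100·(focal junction)/(sum
over all junctions of the event).

Coverage gating uses raw counts, before mappability correction, because the
minima are read-evidence thresholds, not rate estimates. Standard regime:
exon events pass with ≥ 10 summed exclusion reads OR an inclusion pair at
(≥ 10, ≥ 5); microexons replace the pairwise rule with a summed-inclusion
rule; retained introns mirror the exon rule on their exon–intron junction
pair; Alt3/Alt5 need ≥ 10 reads over all junctions. The strict regime (15,
15/10) exists for single-replicate knockdown comparisons and is defined only
for exon events; requesting it for IR or Alt3/5 is an error rather than a
silent fallback. Coverage is monotone in reads by construction.

PSI values are kept at full precision internally; serialization rounds to
two decimals, below the precision achievable at realistic junction depths.
PSI is clamped to [0, 100] against floating-point overshoot at the
boundaries.

## Differential calling

"Alternatively spliced": inclusion in [10, 90] in at least 10% of covered
samples, or a range ≥ 25 across them.

The X1-vs-differentiated caller pools Xins and neoblast-depleted whole-worm
samples as the "diff" group (unweighted) and requires coverage in ≥ 3
samples per group — the generalization of "3 of 6 X1 and 3 of 8 diff" to
arbitrary designs. Q3's ≥ 4-samples gate is kept as an absolute count. With
Δ = Mean_X1 − Mean_diff the criteria are Q1 (|Δ| ≥ 25 with a tight group),
Q2 (|Mean_X1 − Mean80_diff| ≥ 20 with a small SD), and Q3 (qualitative
presence/absence at the 98/90 and 2/10 bounds). The ≥ form of the Q1/Q2
thresholds is deliberate: these criteria describe events with *large*
inclusion differences, so a ≤ reading would contradict their purpose; a
`ge_thresholds` flag exposes the ≤ variant for audit. Mean80 drops
k = ceil(0.2·n) values most distant from the X1 mean, breaking distance ties
by dropping the later sample in manifest order so results are deterministic.
The SD of a single value is defined as 0, which keeps Q1/Q2 evaluable at
n = 1 while Q3's own n ≥ 4 gate still applies.

The moderated test shrinks each event's pooled two-group variance s²_g (d_g
residual df) toward a prior estimated across all events passing the
coverage gate (not only AS events): on e_g = log s²_g − ψ(d_g/2) +
log(d_g/2), the prior df d₀ solves ψ′(d₀/2) = Var(e) − mean ψ′(d_g/2) via a
Newton inversion of the trigamma function, and s₀² follows from the mean of
e. The posterior variance is s̃²_g = (d₀s₀² + d_gs²_g)/(d₀ + d_g), the
statistic t = Δ/(s̃_g·√(1/n_a + 1/n_b)) is referred to a t distribution
with d_g + d₀ df (capped at the summed residual df), and the B statistic —
the log posterior odds of differential inclusion at prior proportion 0.01 —
is reported but never used as a gate. The test operates on PSI values
directly (no logit transform), mirroring the use of inclusion levels as the
response; a unit test verifies exact agreement (t, p, prior fit, B) with the
standard R implementation of the moderated linear model. Setting the prior
df to 0 recovers the ordinary pooled t test; an infinite prior collapses all
posterior variances onto s₀².

The non-regulated background ("AS_nonX1") is the set of alternatively
spliced events with the same coverage gate, |Δ| < 10 and moderated p ≥ 0.05.
Knockdown response: among differential events covered (strict regime) in
both the treated and control sample, an event responds when ΔPSI =
PSI_treated − PSI_control reaches 15 in the direction of the X1 pattern
(the sign of Δ). Direction concordance between two knockdowns is an exact
one-sided binomial tail, P(X ≥ k) for X ~ Binomial(n, ½), over events
shifting by ≥ 15 in both.

No multiplicity correction is applied across events: the caller gates on the
per-event p < 0.05 by design, with the pattern criteria carrying most of the
specificity.

## ORF and NMD prediction

Events are first located on a transcript model: alternative spans that
coincide with annotated exons are compared against the CDS interval in
transcript coordinates (MIXED when straddling a boundary, then classified by
the CDS-overlapping portion); unannotated spans and retained introns are
projected from the 3' end of their upstream exon. Events on transcripts
without a CDS, or in UTRs, are non-coding at the protein level.

For coding events the inclusion isoform is built explicitly (cassette exon
inserted, or intron retained and read in the upstream exon's frame) and
translated from the annotated start codon. Rules, in order: an annotated
start codon inside the alternative sequence means the isoform lacking it
loses the start (disruption on exclusion). A frame-shifting length (mod 3
≠ 0) disrupts the isoform carrying the shift — inclusion for unannotated
cassettes and retained introns, exclusion when removing an annotated
constitutive-frame segment. For frame-preserving events, a premature stop
can only come from the alternative segment: none → ORF-preserving; a stop
more than 50 nt upstream of the final exon–exon junction of the inclusion
isoform → NMD (the canonical last-junction rule; stops within 50 nt of, or
downstream of, that junction do not trigger NMD); a non-NMD stop disrupts
the ORF only when the protein is more than 100 aa shorter than the annotated
isoform (strictly greater), otherwise it is an alternative C-terminus.
Truncation is measured in amino acids against the annotated isoform. When a
gene carries several annotated ORFs, the longest ORF's model is used.

Multi-exon groups are assessed per cell class: the net frame shift is the
sum of included members' lengths mod 3, and a class isoform preserves the
ORF iff that net shift is 0 and no included member contributes a qualifying
(NMD-positioned or > 100 aa-truncating) stop. A one-member group reduces
exactly to the single-exon classification.

The classifier is exercised against a constructed factorial — frame shift
(0/+1/+2) × stop position (none / NMD-positioned / junction-proximal) ×
truncation (≤ 100 / > 100 aa) × strand — whose labels are derived from the
construction arithmetic, independently of the classifier; reverse-strand
constructions must match their forward equivalents exactly. One known
simplification: for frame-preserving removal of an annotated exon, a stop
codon formed de novo at the new exon–exon junction is not scanned for; such
junction-spanning stops are rare and not covered by the stated rules.

## Positional motif maps

Bins: four 20-nt bins from the first 80 nt and four from the last 80 nt of
each flanking intron (labels BIN_U1..U8 and BIN_D1..D8, 5'→3' on the
transcribed strand; at exactly 160 nt the two halves abut), plus the whole
exon as a single bin. Introns shorter than 160 nt contribute no bins on
their side; an 80-nt-flank variant without the short-intron filter is
available through the bin extractor's inputs. All overlapping 7-mer windows
are counted (no collapsing); windows containing N are skipped.

High-affinity 7-mers are the top ceil(0.10·N) by affinity Z-score, ties at
the cutoff broken lexicographically so the set is deterministic. Each bin
forms a 2×2 table of high-affinity versus other windows in signal versus
background events; the Fisher test is one-sided and computed only when the
signal rate exceeds the background rate ("if enrichment was observed"),
otherwise p = 1. The Bonferroni factor is the number of bins actually tested
for that comparison (bins emptied by the short-intron exclusion do not
count), and the exon bin is included in that denominator. The library scan
reports each RBP's minimum raw p over bins, keeping RBPs below 10⁻⁴.

## Knockdown expression statistics

Only control columns are quantile-normalized (a flag-free choice: callers
pass the columns to normalize); treated columns stay on their original
scale, and fold changes are taken against the corresponding control. Within
a column, tied values receive the mean of the reference order statistics at
their tied ranks. A numerical detail: when the selected columns already
share identical sorted vectors, the reference is taken as that common vector
rather than re-averaged, making normalization an exact fixed point
(idempotence holds bitwise).

Detection requires log2(TPM+1) > 1.5 in every control column (the strictest
reading of "reliably detected"). Downregulation is log2FC < −0.7, strictly;
the reported set is the union over timepoints. Cluster enrichment is the
hypergeometric upper tail P(X ≥ k) with all expressed transcripts as
background, Bonferroni-corrected over the clusters that overlap the
background; clusters with no background overlap are skipped rather than
treated as errors.

## Synthetic data

The generator emulates the study design, not any particular dataset:
6 X1 / 4 X2 / 6 Xins + 2 depleted-WW samples by default; an event census
dominated by intron retention (50% IR, 20% single cassette exons, 10%
microexons, 5% multi-exon groups, 15% Alt3/Alt5) with microexons at 3–27 nt
and IR lengths from a bimodal mixture (55% lognormal around 57 nt, else
uniform 1–10 kb); 2,000 events with 200 planted differential events at
|ΔPSI| = 40 and within-group noise of 5 PSI; X2 true levels at the midpoint
of X1 and the differentiated pool. Junction depth is depth_min + negative
binomial (default minimum 50, mean 150, dispersion 2), and each junction is
sampled binomially — inclusion junctions at the sample-level ψ, exclusion
junctions at 1 − ψ. This per-junction sampling (rather than splitting one
inclusion draw across junctions) is the model under which the averaging PSI
estimator is consistent, which the estimator-recovery checks rely on.

Motif sequences are i.i.d. uniform over ACGU with Poisson-planted motif
copies: every 20-nt bin of every event receives the base rate (0.25 expected
copies), and signal events receive the configured multiplier (default 3×) in
the target bin, so the null is exactly exchangeable between the sets. The
uniform background (no dinucleotide structure, no compositional bias between
introns and exons) is adequate for calibration and recovery tests but does
not reproduce the k-mer covariance of real genomes — a significant bin on
real data still needs the usual scrutiny of background choice. Likewise the
count model has no mappability structure (corrected = raw), no GC effects
and no between-sample library-size variation, so passing tests demonstrate
correctness of the statistical machinery, not robustness to those real-data
artefacts.

Problem sizes in the test suite (500 events at depth 1000 for estimator
recovery; 2,000 events × 3 seeds for caller recovery; 100 planted and 200
null replicates of 150 + 500 events for the motif map) were chosen as the
smallest sizes at which the targeted properties are statistically sharp.

All randomness flows from a single integer seed through named
`numpy.random.default_rng` streams, making every emitted table and sequence
bit-for-bit reproducible; no output depends on dict or file-system
ordering.

## Known limitations

- The PSI model ignores junction-specific mappability weighting; corrected
  counts are taken as given.
- The moderated test assumes approximately normal within-group PSI noise;
  near the 0/100 boundaries the truncation makes it conservative.
- The ORF classifier evaluates one transcript model per event and does not
  enumerate junction-spanning stop codons created by exon removal.
- The motif map treats events as independent; shared promoters or paralogy
  among signal events would inflate significance on real data.
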