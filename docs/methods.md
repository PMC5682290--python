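# Methods

## Data model

All statistics operate on per-base *read-start* vectors: one vector per
transcript per (condition, enzyme, replicate) library, where the entry at
base j counts reads whose 5'-most aligned base is j. RNase V1 cuts
double-stranded (DS) RNA and S1 nuclease cuts single-stranded (SS) RNA, so a
read start is a cut at a base in the corresponding state. Counting applies
three rules: the alignment must be unique (MAPQ ≥ 10 by default, never
secondary/supplementary), its orientation must match the transcript strand
(the protocol is strand-specific), and the read's 5' end must match the
reference for at least five bases without gaps (a leading clip or indel
disqualifies it — local aligners otherwise place spurious 5' ends).
Libraries are then scaled by one factor each so all read-start totals equal
the mean raw total; any common target is equivalent for every downstream
ratio, the mean keeps counts on their original scale.

Internal coordinates are 0-based half-open throughout; BED output is
0-based; the pileup interface (chrom, pos, strand, A/C/G/T counts) is
1-based, converted at the boundary.

## PARS score

`PARS(j) = log2((V1_j + c) / (S1_j + c))` on normalized counts with
pseudocount c = 1.0 by default. The pseudocount keeps the score defined at
zero-count bases and shrinks low-coverage scores toward 0; with c = 0
requested, any zero count is an error rather than ±inf. Replicate-averaged
scores are the mean of per-replicate scores (not the score of summed
counts) — the two differ at low coverage and the averaged form is what the
constraint-derivation procedure uses. Folding constraints force bases with
averaged score > 2.5 paired and < −2.5 unpaired ('|' / 'x' / '.' in the
constraint dialect folding tools accept); differential editing sites with
more than 100 reads and mean control level above 0.1 are substituted A→G in
the emitted sequence so the fold reflects the inosine-bearing molecule.

## Per-base DS/SS classification and stability classes

Base j of a transcript is tested with a two-sided Fisher exact test on
[[V1_j, S1_j], [V1_total − V1_j, S1_total − S1_j]] — the base against the
rest of its transcript. Normalized (fractional) counts are rounded
half-to-even first. A base is DS when p ≤ 0.05 with the V1 share exceeding
the S1 share, SS in the reverse case, otherwise undetermined; no multiple-
testing correction is applied at this step by default (an optional BH flag
exists), matching how structure-preference profiles are conventionally
computed. The base-versus-transcript-total table is our reading of the
published per-position construction; a windowed variant is left to
configuration. Transcripts enter this analysis when longer than 100 bases
with more than 256 read starts summed over samples.

Per transcript and condition the summary is the ratio DS/(DS+SS) over
confident calls. Replicates are classified independently and averaged at
the ratio level; a transcript is DSWE (destabilized while edited) when the
mean ratio is higher in knockdown than control — removing editing left it
more paired — and SWE in the reverse case, with exact ties or undefined
ratios unclassified. Conditions are compared with the paired two-sided
Wilcoxon signed-rank test over matched transcripts.

## CorDiff and SSC calling

For four same-length count vectors (two control replicates c1, c2 and two
knockdown replicates kd1, kd2):

    CorDiff = Cor(c1,c2)² + Cor(kd1,kd2)² − Cor(c1,kd1)² − Cor(c2,kd2)²

with Pearson correlations. CorDiff ∈ [−2, 2], is invariant to per-vector
scaling and shifts, and is large positive when replicates agree within
conditions but profiles differ across them. Vectors with zero variance make
the correlation undefined; such regions are excluded (not assigned r = 0).
Since a permutation of a non-constant vector is never constant, exclusion
before testing also settles what would otherwise be a degenerate-shuffle
case inside the trial loop.

The null is built by shuffling positions within each sample's vector
independently (a coupled shuffle — one permutation shared by all four
samples per trial — is available by flag); 100 trials by default. The
reported p is the raw fraction of trials with shuffled CorDiff ≥ observed,
ties counting against significance, with an add-one-corrected p alongside;
a region is significant when the observed score beats 95% of trials
(p < 0.05). A region is SSC when CorDiff > 0 **and** p < 0.05 in both the
V1 and S1 libraries; we require the shuffle test per enzyme since the score
is computed per enzyme. Regions can be genes, exons, or any interval; the
synthetic analysis uses the 3'UTR region (where the inverted-repeat duplex
lives) as its exon-grain unit.

The same machinery compares reads partitioned by the base they carry at an
editing site (G = edited, A = not) in a ±50-base window, the edited
partition playing the role of one condition; each partition needs strictly
more than 50 read starts per replicate in the window, and the relative-PARS
contrast is restricted to bases upstream of the site because the read start
and the interrogated base must lie on the same read.

Calibration note: the position-shuffle null destroys all profile structure,
so for regions with strong structured signal shared by all samples the
shuffle test alone is anti-conservative; the CorDiff > 0 sign filter in two
independent enzyme libraries is what holds the joint false-positive rate
down. On exchangeable noise the test is exact (rejection ≈ 5/101 at the
default trial count).

## Editing

Editing level is G/(A+G) on the annotated strand, pooled over replicates
within condition (pooling matches how levels are averaged over samples and
maximizes power at low coverage). Differential editing sites (DES) are
called by a one-sided Fisher exact test on [[G_ctrl, A_ctrl], [G_kd, A_kd]]
against level(kd) < level(control) at p < 0.05 — the test itself is a
package choice, with a two-proportion z test by flag — plus BH q-values
(q < 0.1 subset reported). Sites significantly *higher* in knockdown are
flagged separately as candidate ADAR2 targets, since ADAR2 rises when ADAR1
is silenced. The hyper-edited-read filter passes a read when its count of
Phred ≥ 30 A-to-G mismatches is at least 5% of the read length and A-to-G
mismatches exceed 90% of all mismatches; de-novo hyper-editing discovery
(transform-and-realign) is out of scope — the filter applies to given
alignments.

Pairing context classes each edited adenosine by the base opposite it in
the duplex: A:C (editing creates a stabilizing I:C pair), A:U (editing
creates a destabilizing I:U mismatch), other/unpaired. The "expected by
chance" A:C fraction is the fraction of *all* duplex adenosines opposite C
among those opposite C or U; a dinucleotide-matched expectation would be an
alternative but the composition-based one is the direct operationalization
and is what the Fisher contrast uses. Level-by-context keeps sites with
A+G coverage strictly above 5 and compares A:C vs A:U levels with a
two-sided rank-sum test.

## Enrichment and translation arithmetic

Feature enrichment between region sets is the density ratio
fold = (n1/size1)/(n2/size2) over merged interval sizes, with a two-sided
Fisher exact p on the feature-versus-base 2×2 table. The folds are fully
determined by the counts; the p-value construction behind the published
tables is not stated there, so p is reported but only the folds are treated
as exactly reproducible. Fold changes are library-normalized KD/control
ratios (total-count or median-of-ratios scaling). Translation efficiency is
TE = normalized Ribo-seq / normalized RNA-seq per gene for genes with more
than 100 reads in both assays, and TER = TE_kd/TE_control, which equals
FC_ribo/FC_rna identically under any per-library scaling — asserted to
1e-12 in the tests. Ranked-overlap enrichment takes the top 1000 genes by
descending TER by default (ranking by |TER − 1| is a flag, since "highest
ratio" is ambiguous for a ratio below 1).

## The synthetic generator

Each simulated transcript has a 5'UTR (50 nt), CDS (150 nt), and a 3'UTR
carrying an inverted-repeat duplex: two 60-nt arms separated by a 20-nt
spacer, arm2 the reverse complement of arm1 with Bernoulli(0.15) mismatches
— imperfect Alu-like duplexes typically carry >15% mismatches. Total length
is uniform on 350–500 nt: the analysis grain is the 3'UTR exon / duplex
region, a few hundred bases, not a full-length mRNA. By default 50% of
transcripts carry stabilizing A:C editing sites (SWE-like), 30% carry
destabilizing A:U sites (DSWE-like), 20% carry none (stabilization
predominates in the real transcriptome by roughly 5:1 among classified
genes). Eight sites per duplex (hyper-edited IR Alus carry tens), control
levels uniform on [0.3, 0.8] (differential-grade, strongly edited sites),
knockdown retaining 30% of the control level (editing in 3'UTR IR Alus
drops ~70% under knockdown). For SWE-type duplexes the required number of
A:C mismatches is planted among the realized mismatches (composition, not
count, is adjusted) so the stabilizing effect is not availability-limited —
this is the calibration that gives the structure-change caller its stated
sensitivity at the default depth; otherwise a 0.4 fraction of mismatches is
A:C.

Editing acts through a binary per-molecule rule: each site is edited
independently Bernoulli(level); A:U and I:C positions (and their partners)
are paired, A:C and I:U unpaired; everything else follows the unedited pair
map. No thermodynamic rescoring is attempted — the binary rule keeps truth
exactly computable and mirrors the qualitative I:C-stabilizes /
I:U-destabilizes trade-off. Digestion draws a fixed depth (10⁴ read starts
per transcript per library) multinomially with per-base weight ds_rate ×
P(paired) + ss_rate × (1 − P(paired)), the pairing probability averaged over
a 400-molecule ensemble. Default rates are 1.0 (preferred state) vs 0.1:
on a half-paired molecule this yields ~91% read agreement with the known
structure, the level observed on real probing controls. Read start equals
cleavage position; fragment-length, ligation, and sequencing-error biases
are not modeled because the analysis consumes read starts only.

What passing recovery tests shows, and what it does not: the simulator
plants exactly the signal class the statistics target (condition-dependent
pairing at editing sites inside one duplex) with independent sites,
homogeneous cleavage rates, and no alternative splicing, expression change,
coverage bias, or mapping artifacts. Recovery on it validates the
estimators' logic and calibration, not their robustness to those real-data
confounders; the alternative-splicing cross-check of real SSC calls, in
particular, is accepted as an external exclusion list.

## Numerical choices and degenerate inputs

* Fisher tests come from scipy; the per-base classifier memoizes p-values
  (count pairs repeat heavily within a transcript) and is cross-checked in
  the tests against a brute-force hypergeometric enumeration.
* Normalized counts are rounded half-to-even before exact tests.
* Identical paired samples short-circuit the Wilcoxon test to p = 1.
* Zero-total tracks, zero-variance regions, empty annotation/region/class
  inputs raise named errors rather than propagating NaN.
* The shuffle p with n < 20 trials warns about resolution; the seed fixes
  every simulation, shuffle, and pipeline output bit-for-bit.

## Problem sizes

The shipped analyses and checks run at desk scale, chosen to exercise the
estimators at realistic per-base coverage: 60–200 transcripts, depth 10⁴
read starts per transcript-library, 100 shuffle trials, 1000 null regions
for calibration, 1000 simulated sites at coverage 100 for estimator bias.
Transcriptome-scale counts (10⁵ editing sites, thousands of SSC
transcripts) require the deposited sequencing data and are out of scope.

## Known limitations

* The base-classification contingency uses transcript totals, not a local
  window; low-complexity coverage landscapes can shift calls relative to a
  windowed variant (config hook present).
* The shuffle null is anti-conservative for structured profiles when used
  without the two-enzyme sign filter (see above); single-enzyme p-values
  should not be interpreted alone.
* Whether the original PARS pipeline used a pseudocount is unknowable from
  the text; agreement percentages depend mildly on it, so it is config, and
  exact agreement values should be compared only at matched settings.
* DESeq-style dispersion modeling is deliberately not reimplemented; fold
  changes are plain normalized ratios, and externally computed fold-change
  tables can be supplied wherever FCs are consumed.
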