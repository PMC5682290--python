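# parsedit

Analysis of ADAR1-dependent RNA secondary-structure change from PARS-seq
nuclease-probing data.

## The problem

A-to-I RNA editing by ADAR1 rewrites Watson–Crick interfaces: an edited
adenosine (inosine, read as G by sequencing) pairs with C but mismatches U.
In human mRNAs most editing falls inside imperfect duplexes formed by
inverted Alu repeats in untranslated regions, so editing can either
*destabilize* a duplex (A:U → I:U mismatch) or *stabilize* it (A:C mismatch
→ I:C pair). PARS-seq probes structure directly: RNase V1 cleaves
double-stranded RNA, S1 nuclease cleaves single-stranded RNA, and the
5'-most aligned base of each sequencing read (its *read start*) marks a cut
site. Comparing V1/S1 read-start profiles between control and
ADAR1-knockdown cells localizes the structural consequences of editing
transcriptome-wide.

This package implements that analysis end to end for people working with
nuclease-probing or editing data:

* **`parsedit.counts`** — read-start extraction from SAM alignments
  (unique, strand-matching reads whose 5' end matches ≥ 5 bases without
  gaps), library normalization to equal read-start totals, RPKM, coverage
  tiers;
* **`parsedit.pars`** — the PARS score
  `PARS(j) = log2(V1_j / S1_j)` per base (positive ⇒ paired), relative
  profiles, agreement with known structures, hard folding constraints
  (score > 2.5 forced paired, < −2.5 forced unpaired, DES substituted A→G),
  metagene and codon-periodicity profiles, buried bases;
* **`parsedit.strclass`** — per-base DS/SS calls by Fisher exact test of a
  base's V1/S1 counts against its transcript totals, the per-transcript
  DS/(DS+SS) ratio, control-vs-knockdown comparison, and the
  stabilized/destabilized-while-edited (SWE/DSWE) classes;
* **`parsedit.sschange`** — the correlation-difference statistic

  `CorDiff = Cor(c1,c2)² + Cor(kd1,kd2)² − Cor(c1,kd1)² − Cor(c2,kd2)²`

  over replicate read-start vectors, its within-region shuffle null
  (significant when the observed score beats 95% of 100 trials), SSC calls
  (CorDiff > 0 and p < 0.05 in both enzymes), and the edited-vs-non-edited
  read-partition comparison around single sites;
* **`parsedit.editing`** — editing levels G/(A+G) from pileups,
  differential editing sites (one-sided Fisher, level lower in knockdown,
  BH-FDR), the hyper-edited-read filter (≥ 5% of read length high-quality
  A-to-G, > 90% purity), A:C / A:U pairing context, level-by-context;
* **`parsedit.downstream`** — density-ratio enrichment folds with Fisher
  p, feature-in-region counting, normalized fold changes, translation
  efficiency TE = Ribo/RNA and its ratio TER = TE_kd/TE_control =
  FC_ribo/FC_rna, rank-overlap enrichment, up/down contrasts;
* **`parsedit.synthio`** — a simulator generating transcripts with
  imperfect 3'UTR inverted-repeat duplexes, condition-dependent editing,
  and multinomial V1/S1 digestion with exact ground truth;
* **`parsedit.pipeline` / `parsedit` CLI** — one-command orchestration.

## Worked example

```
$ parsedit run --seed 7 --out demo_out
```

runs simulate → count → normalize → score → classify → structure-change →
editing on a synthetic experiment and prints (abridged):

```
"n_eligible_transcripts": 60,
"ds_ratio_wilcoxon_p": 0.000147,
"ds_ratio_frac_control_higher": 0.65,
"n_ssc": 41,
"ssc_sensitivity": 0.854,
"ssc_fpr": 0.0,
"n_des": 360,
"ac_observed_fraction": 0.6,
"ac_expected_fraction": 0.188,
```

Reading: of 60 transcripts deep enough for structure calling, the fraction
of confidently paired bases is higher in control than knockdown (editing is
net-stabilizing under the default A:C-dominated site mix; paired Wilcoxon
p ≈ 1.5 × 10⁻⁴), 41 3'UTR regions are called structure-changed — recovering
85% of the planted changes with no false positives — all 360 simulated
sites are differentially edited, and edited adenosines sit opposite C in
60% of cases although only 19% of duplex adenosines have a C opposite: the
pairing-context excess that marks preferential stabilizing editing.

The numbered drivers under `analysis/` run the same steps as a narrative
(simulation, per-base structure calls, SSC calls, editing and pairing
context, published enrichment folds, translation efficiency), each writing
its tables under `results/`.

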