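# Methods

`ampbench` reimplements, at desk scale and on synthetic data, a
cross-benchmark experiment probing how the construction of the *negative*
(non-AMP) class biases benchmarks of antimicrobial-peptide (AMP)
predictors.  This note documents the models, the synthetic data, the
numerical conventions and the deliberate design choices, in the order the
pipeline runs them.

## The experiment

Published AMP predictors share their positive data (curated AMPs) but build
their negative sets from an annotated protein database with idiosyncratic
rule sets — keyword exclusions, length policies, redundancy reduction,
localization restrictions, similarity screens.  The package expresses 11
published rule sets as declarative `SamplingSpec`s and runs the full
cross-design: every architecture × every training sampling method (TSM) ×
replicates, with every trained model evaluated (ROC AUC) against the shared
positive benchmark sample paired with every benchmark sampling method's
(BSM) negatives.  The *diagonal* of the TSM × BSM grid corresponds to the
conventional benchmark design (same method for training and benchmark
negatives); the bias of interest is a diagonal advantage.

## Synthetic data generator

The generator (`ampbench.synthetic`) emulates the statistical structure the
analysis needs, not real biology:

* **Positives** — i.i.d. sequences over a composition enriched in K/R
  (cationic) and L/I/F/W (hydrophobic); lengths from a shifted negative
  binomial, median 18 residues, truncated to [5, 190].
* **Background** — a UniProt-like database (default 60 000 records) with
  database-average residue frequencies and discretized log-normal lengths
  (median ≈ 280, range [5, 2000]).  Each record carries independent
  function keywords and localization terms at configurable prevalences,
  with three deliberate dependencies:
  * the `secreted` keyword is positively associated with `antimicrobial`
    (odds ratio 4) and with the `secreted` localization;
  * annotation-linked composition shifts: `transmembrane` records are
    aliphatic-rich, `secreted`/`toxin` records cysteine-rich — so keyword
    and localization screens change the *composition* of the surviving
    pool, as they do on real data;
  * a configurable fraction (default 0.5) of `antimicrobial`-keyword
    records is planted with positive-style composition (mislabel-like true
    AMPs), flagged via `SequenceRecord.amp_like` as a held-out oracle.

The background size (60 000) is the smallest round count at which every
sampling method retains enough sequences after its filters and redundancy
reduction to meet its sizing target; the real study drew from a 564 k-record
database.  What passing tests show: the *mechanism* (methods produce
statistically different negative samples, and models transfer poorly across
them).  What they do not show: real-data AUC levels, motif- or
domain-driven signal (sequences are i.i.d. per composition; there is no
protein grammar), or signal-peptide structure.

## Negative sampling engine

Stage order: keyword filter → localization filter → potential-AMP screen →
length policy → cysteine-free rule → clustering → AMP-similarity screen →
positive-overlap removal → sizing → train/bench partition.  Two families:

* **Whole-record methods** (length ranges such as 16–90): filters apply to
  whole records; sizing draws without replacement; train/bench negatives
  are split 80/20 to mirror the positive split.  Redundancy reduction
  operates on a seeded subsample grown adaptively (starting at 3× the
  sizing target) until the survivors suffice — clustering the entire
  filtered pool would dominate runtime without changing the survivors'
  distribution.
* **Fragment methods** (length distribution equal/similar to the positive
  sample): for each positive length L (times the imbalance ratio), a
  database record of length ≥ L is chosen uniformly and a uniform
  contiguous window of exactly L extracted, with rejection rules applied
  per fragment (cysteine-free window, no shared 10-mer with any positive,
  not identical to a positive, unused coordinates).  Provenance (parent id,
  0-based half-open coordinates) is recorded for every negative.

**Identity and clustering.** The CD-HIT stand-in defines pairwise identity
as (shorter length − d) / shorter length, where d is the edit distance of
the shorter sequence against the best-matching region of the longer
(edlib infix alignment — the analogue of CD-HIT's banded alignment; a
contained substring scores 1.0).  Clustering is greedy longest-first: a
sequence joins the first representative with identity ≥ the threshold, else
founds a cluster.  A fully global (free end-gap) alignment was rejected:
for short-versus-long pairs it inflates identity so much that 0.4-threshold
clustering collapses realistic pools almost entirely.

**Equal-length methods with clustering** (the cysteine-free method):
clustering strictly after sampling would break the exact length-multiset
property that equal-length methods guarantee.  The engine clusters the
sampled fragments and refills removed slots with fresh fragments of the
same length (checked against surviving representatives, up to 30 draws;
for very short lengths, where identity is quantized at 1/length and
non-redundancy can be unsatisfiable, the slot is refilled without the
freshness requirement).

**Imbalance ratios** for the unbalanced methods (the sources describe them
only qualitatively): Wang 2:1, iAMP-2L 2:1, Gabere&Noble 5:1 ("highly
imbalanced"), AMAP 1.2:1, dbAMP 1.2:1 ("slightly imbalanced"),
ampir-mature 0.8:1 (negatives in the minority).  All configurable.  For the
fragment methods with redundancy reduction (Wang, AMAP) the post-clustering
sample is smaller than ratio × positives — that shrinkage *is* the
"similar" (rather than "equal") length distribution those methods describe.

## Feature extraction

All extractors are pure functions; dimension contracts: AAC 20,
PseAAC 20+λ, CTD distribution 105, reduced CTD subset 23, structural
panel 9, MACREL-style 22, ampir-style 27, grey-model PseAAC 30.

Conventions worth stating:

* **PseAAC** (Chou type 1): scales = Eisenberg hydrophobicity, Hopp–Woods
  hydrophilicity, side-chain mass (standardized over the 20 residues);
  weight w = 0.05.  Peptides must be longer than λ; the fuzzy-k-NN
  architecture uses λ = 20 with `clip_lam=True` (θ_j = 0 beyond the
  available span) because AMP-scale peptides are frequently shorter than
  21 residues.
* **CTD distribution**: 7 attributes × 3 classes × 5 descriptors (first,
  25/50/75/100 % occurrence positions as proportions of length); an absent
  class contributes zeros (keeps the dimension fixed).  The reduced
  23-descriptor subset is a fixed, documented package constant (all 15
  hydrophobicity descriptors, the 5 positive-charge descriptors, and 3
  helix-class positions) — the originally published subset is only
  described by size in the sources available here, so this stand-in subset
  is the package's own choice.
* **Physicochemical panel**: net charge by Henderson–Hasselbalch with
  EMBOSS pKa values; pI by bisection on that charge; Eisenberg hydrophobic
  moment at 100°/residue, normalized per residue; amphipathicity = moment
  relative to its maximum attainable value (mean |H|); instability and
  molecular weight from the standard ProtParam tables; Boman index = minus
  the mean transfer free energy; aliphatic index per its standard formula;
  propensities/flexibility are mean per-residue scale values.  The
  solubility flag is a documented heuristic: charged (|q| ≥ 1) or net-polar
  (mean Eisenberg < 0) peptides are flagged soluble.
* **MACREL-style 22-slot layout** (package layout; sources give the
  descriptor families, not the order): first-occurrence and fraction
  descriptors for the free-energy-of-transition and solvent-accessibility
  3-letter alphabets (12), then charge, pI, solubility, instability,
  aliphatic index, Boman, hydrophobic moment, mean hydrophobicity,
  amphipathicity, molecular weight.
* **Grey-model PseAAC**: AAC + GM(1,1) coefficients (a, b) of five
  per-residue property series (hydrophobicity, hydrophilicity, mass, pK1,
  pK2), each scale min-max mapped to [1, 2] so the accumulated series is
  positive; a constant series yields a = 0 exactly.  Needs length ≥ 4.
* **n-grams**: binary presence of all contiguous 1-/2-/3-grams plus
  single-gap 2- and 3-grams observed in the training set.
* **QuiPT**: exact permutation p-value of the information gain (natural
  log) of a binary feature against the binary label, computed by
  hypergeometric enumeration of the 2×2 tables with the observed margins;
  ties enter the rejection region (≥ with 1e-12 tolerance).  Note the
  rejection region is two-sided in association: the perfectly
  anti-correlated table has the same information gain as the perfectly
  correlated one, so a perfect feature at n=10 with 5 positives has
  p = 2/C(10,5), not 1/C(10,5).  Constant columns score p = 1 by
  convention.
* **LZ76 similarity**: phrase-count complexity C per the exhaustive-history
  parsing; similarity s(x, r) = 1 − (C(xr) − min(Cx, Cr)) / max(Cx, Cr).
  The reference panel is drawn at training time, half from each class; the
  panel size is 100 at desk scale (the original used 1000; configurable).

## Architectures

Feature schemes bind to classifiers per the published table: SVMs (linear
kernel for the pure-AAC architecture, RBF with C = 1, γ = 1/n_features
otherwise, standardized inputs, sigmoid score calibration fitted on
training decision values), random forests (200 trees — AUC at these sample
sizes is insensitive to more; seeds fixed per model), and a fuzzy k-NN
(k = 5, m = 2, Euclidean, exact-match short-circuit).  Selectors are fitted
on training data only: PCA keeps the components explaining 95 % of training
variance; QuiPT keeps n-grams significant after Benjamini–Hochberg at 0.05,
capped at the 5000 smallest p-values.  The two deep-learning rows of the
published roster are registered for grid planning (the 660-model count) but
are not trainable here — no neural-network stack is part of the package's
dependency set, and the headline analysis does not require them.

## Grid and statistics

* AUC = Mann–Whitney U / (n_pos × n_neg), half-credit for ties.
* Pairing rule: training replicate r is evaluated against benchmark
  replicate r (`paired_replicate`, default); `full_cross` is available.
* Bias summary: per-architecture mean AUC on the diagonal vs off the
  diagonal; improvement = 100 × (same − different) / different.
* MAD ratio: between-group MAD of group medians over the median of
  per-group MADs, MADs unscaled; a zero within-group MAD is flagged
  (inf/nan) rather than silently dropped.
* Distances: computed between *negative* samples (TSM training negatives
  vs BSM benchmark negatives).  The positive sample is shared by every
  cell, so pooling it into both sets would only attenuate the regressor;
  the benchmark negative-vs-positive median-length gap is reported
  separately.
* Correlations: Spearman, AUC averaged over architectures at
  (TSM, BSM, replicate) granularity; p-values from the t-approximation for
  n > 30 and a (seeded, exact up to n = 8) permutation test below that.
* Tests: per-architecture Kruskal–Wallis (same vs different method),
  Bonferroni across architectures; pairwise paired Wilcoxon within each
  grouping family (architectures, TSMs, BSMs), pairing cells by the
  complementary keys, Bonferroni within family.

## Scale and determinism

The default study — 1200 positives (≈1199 after 90 % redundancy reduction,
split 959/240), 60 000 background records, all 11 sampling methods, the 10
classical architectures, 2 replicates — runs in roughly a quarter hour on
one CPU and is the configuration the acceptance script recomputes.  The
published experiment used 5 replicates and half a million database records;
the package keeps those as configuration, not as defaults.  Every stage
seeds its randomness from a stable hash of (master seed, stage name,
replicate), so any run is reproducible byte-for-byte, and the grid is
resumable by cell fingerprint.

## Known limitations

* Synthetic sequences are i.i.d. given a composition vector; architectures
  that exploit order (n-grams, CTD, grey models) see only composition-level
  and length-level signal, so their relative ranking here does not predict
  their real-data ranking.
* The infix-alignment identity is a stand-in, not CD-HIT; absolute cluster
  counts differ from real CD-HIT output even though the contract (greedy
  threshold clustering, identity relative to the shorter sequence) matches.
* The 23-descriptor reduced subset and the 22-slot layout are package
  conventions standing in for the original tools' exact published choices.
* Improvement percentages, correlation magnitudes and MAD ratios are
  qualitative mirrors of the real study (same signs and ordering), not
  quantitative reproductions — the underlying data are synthetic.
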