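# Methods

## Problem and model

A bacterial protein's subcellular localization is encoded as a binary
vector over a fixed, ordered universe of location codes: Gram-negative
proteins over (C, I, O, P, S, V) = cytoplasm, inner membrane, outer
membrane, periplasm, extracellular, vacuole; Gram-positive proteins over
(C, I, S, W, V), replacing outer membrane/periplasm with the cell wall.
Multi-site proteins set several bits; in curated benchmarks they are
rare (<1%) and limited to location pairs.

Learning uses the **Label Powerset** transformation: the distinct label
subsets observed in training become the classes of a single multi-class
problem. This captures label co-occurrence directly — the dual-site
subset {C, I} is its own class — at the cost that unseen subsets can
never be predicted by a single model. The base classifier is a Random
Forest (500 trees, fixed seed) by default; an RBF-SVM with probability
estimates behind a feature standardizer is the alternative. The hard
prediction is the subset of the maximum-posterior class; per-label
marginal scores are the posterior mass of all classes containing the
label, which is what ranking-based metrics (rank loss, ROC) consume.

The **consensus model** ORs the hard decisions of member models
(PSSM-based and GO-based; optionally also PseAAC). The OR is a union, so
for every protein the consensus label set is a superset of each
member's: per-instance recall can only rise, precision can only fall,
and previously unreachable dual-site calls appear whenever two members
disagree with single-site calls. Consensus scores are the element-wise
maximum of member scores — a ranking convenience only; the decision is
purely the OR of hard calls.

## Feature views

**PseAAC (Type I).** Components 1–20 are residue frequencies; components
21–20+λ are sequence-order correlation factors θ_k, the mean over
positions of the mean squared difference of three standardized
physicochemical properties (hydrophobicity, hydrophilicity, side-chain
mass) between residues k apart. All components are divided by
1 + w·Σθ so the vector sums to 1. Defaults λ = 30 (capped at the
shortest batch sequence length minus one, keeping the view rectangular)
and w = 0.05, the conventional settings for this encoding; both are
configurable, as is the property set. λ = 0 reproduces the plain
amino-acid composition exactly.

**PSSM auto-cross covariance.** Profiles are consumed as PSI-BLAST ASCII
files; the log-odds block is the default input (the percentage block is
selectable by configuration — which block upstream profile generators
feed into ACC is not standardized, and log-odds is the conventional
"profile"). The ACC transform maps an L×20 profile to a fixed vector:
the AC block holds, for each column and each lag 1…lg, the lagged
autocovariance centred on the column's own mean; the CC block holds the
lagged cross-covariance for each *ordered* column pair (CC is
asymmetric). Vector length is 20·lg + 380·lg = 400·lg; ordering is AC by
(residue, lag) then CC by (i, j, lag). lg defaults to 1, keeping the
view at 400 features. Both AC and CC are invariant to adding a constant
to any column.

**GO terms.** Annotations are consumed as (protein, sub-ontology, GO id,
PPV) rows, where PPV ∈ [0, 1] is the upstream GO predictor's confidence.
Duplicate (protein, term) rows keep the maximum PPV. The feature space
is the sorted union of the MF/BP/CC terms seen on *training* proteins;
terms first seen at prediction time are ignored, and unannotated
proteins legally encode to the zero vector. Two modes: 0/1 presence, or
the PPV value itself. Inside cross-validation the vocabulary is rebuilt
from each fold's training part so that held-out terms cannot leak into
the encoding (a global-vocabulary option exists for single-split use).

## Evaluation

Example-based metrics average per-instance quantities: Jaccard accuracy
|Y∩Ỹ|/|Y∪Ỹ|, precision |Y∩Ỹ|/|Ỹ|, recall |Y∩Ỹ|/|Y|, F1
2|Y∩Ỹ|/(|Y|+|Ỹ|), the exact-match indicator, and the fraction of
disagreeing label positions (Hamming loss). Rank loss is the mean
proportion of (relevant, irrelevant) label pairs whose scores are
inverted, with half credit for ties; instances with no relevant or no
irrelevant label carry no ranking information and are excluded but
counted.

Label-based metrics come from per-location TP/FP/FN/TN counts: macro
averages of per-label ratios and pooled micro ratios. Two macro-F1
conventions circulate; both are reported: `macro_f1` is the harmonic
mean of macro-precision and macro-recall, and `macro_f1_per_label` is
the unweighted mean of per-label F1 scores. Degenerate cases are
defined explicitly because the consensus evaluator accepts arbitrary
matrices even though an LP model cannot emit an empty set: an empty
prediction contributes 0 to precision, and a zero-denominator label
contributes 0 to a macro average with a warning. AUC is micro-averaged
over the flattened (instance, label) pairs by default (macro by flag),
with the trapezoid rule on the ROC points; it is undefined (error) when
the flattened truth is single-class.

The Hamming loss satisfies the pooled identity
(ΣFP + ΣFN)/(N·Q) with the confusion counts; the per-location confusion
table reports TP/FP/FN/TN, Correct = TP+TN, Wrong = FP+FN and the
fractions of N rounded to 2 d.p. for display (full precision in JSON).
Reported tables round to 3 d.p.

Cross-validation shuffles with a seeded generator and assigns proteins
round-robin to k = 5 folds (sizes within one). Per fold, every view
model is fitted on the training part (GO vocabulary rebuilt fold-locally)
and the held-out part predicted; consensus variants OR the member
predictions of the same fold, so members always share the split.
Held-out predictions are pooled over folds — every protein is evaluated
exactly once — and all metrics and confusion counts are computed on the
pooled matrix. The eight reported variants are PseAAC, PSSM, GO-0/1,
GO-PPV, the PseAAC+PSSM+GO and PSSM+GO feature fusions, and the two
consensus models; fusion and consensus use the PPV-mode GO view, the
stronger of the two GO representations.

## Synthetic data generator

The generator emulates the statistical structure of curated bacterial
SCL benchmarks; its defaults are the regime the pipeline is tested in.

* **Labels** are drawn i.i.d. from a subset distribution whose default
  probabilities are the empirical subset frequencies of the curated
  benchmarks (Gram-negative: 6,578 proteins, 39 dual-site; Gram-positive:
  2,448 proteins, 8 dual-site), i.e. ~63% cytoplasm-only for
  Gram-negative, a 0.15% vacuole class and ~0.6% dual-site mass.
* **Sequences** are i.i.d. residues with lengths uniform on [50, 300];
  no homology or compositional signal is injected, so the PseAAC view is
  essentially uninformative on synthetic data — by design, it acts as
  the weak-member control.
* **PSSMs**: background entries are N(−1, 2²) rounded and clipped to the
  PSI-BLAST log-odds range [−10, 12]. Each location owns three
  designated columns which receive `pssm_signal · (1 + z)` where z is an
  AR(1) latent (ρ = 0.7, unit stationary variance) along the sequence.
  The mean-shift term keeps raw profiles visibly location-biased, but it
  is the autocorrelated term that makes the signal learnable: AC/CC
  features are shift-invariant, and an AR(1) component raises the lag-1
  auto- and cross-covariances of exactly the designated columns
  (≈ signal²·ρ against a ≈0 background). Default signal 2.0.
* **GO annotations**: each location has two indicative terms per
  sub-ontology, each emitted with probability `go_emission` (default
  0.9) and PPV ~ Beta(5, 2) clipped to (0, 1] — right-skewed, like
  confident predictor output. Uninformative noise terms are added per
  protein at a Poisson rate (mean 2.0) with PPV ~ Beta(2, 2). Vocabulary
  sizes default to 60/80/30 (MF/BP/CC).

With a fixed seed the four written artifacts (FASTA, per-protein ASCII
PSSMs, GO TSV, labels TSV) are byte-identical across runs.

What passing synthetic tests does and does not show: recovery of the
injected signal demonstrates that the encoders, the LP learner, the
fold-local vocabulary and the consensus plumbing are correct and
leak-free, and that the metric layer measures what it claims. It does
not show that real benchmark accuracies are attainable — real PSSMs
carry evolutionary correlations and real GO terms a DAG structure that
the generator deliberately omits.

**Zero-signal control.** The chance-level control removes *all*
annotation signal (indicative emission 0, noise rate 0, PSSM signal 0):
the GO vocabulary is then empty and the view degenerates to zero-width
features, under which the LP model reduces to the training class prior
and subset accuracy must sit within 3 binomial σ of the majority-subset
frequency. Random *noise* annotations are deliberately excluded from
this control: a fully grown forest memorizes them at the leaves and
spreads its predictions toward the class distribution, which
systematically lowers subset accuracy below the majority prior (towards
Σp²) without any label information being present — an estimator-variance
effect, not a signal. The informative comparison for leak detection is
the annotation-free run.

## Numerical and design choices

* Canonical amino-acid order is the PSI-BLAST column order
  ARNDCQEGHILKMFPSTWYV; PSSM files with a different header alphabet are
  reordered on read.
* Canonical label order is the universe's code order (alphabetical
  within each preset). The OR-combination is order-independent.
* Argmax ties in LP prediction break deterministically: higher training
  class frequency first, then lexicographic subset order.
* Zero-width feature views (empty GO vocabulary) are substituted by a
  constant column so the base classifier degenerates cleanly to the
  class prior.
* In the cross-covariance the lagged index pairs position k with
  position k + lag in the second column; pairing both columns at k would
  make the lag parameter vanish from the summand.
* Floating-point tolerances: transform and metric implementations are
  required to match naive reference implementations to 1e-12 absolute.
* Problem sizes: the test-suite and acceptance runs use N = 150–500
  synthetic proteins with 5-fold CV and the default 500-tree forest
  (200 trees in the CLI smoke run at N = 240); these sizes give stable
  estimates of the recovery behaviour while keeping a full run on one
  CPU in the tens of seconds.

## Known limitations

* PSSM generation (PSI-BLAST against UniRef50) and GO-term prediction
  (PANNZER2-style homology transfer) are out of scope; profiles and
  annotations are consumed, not produced.
* The LP transformation cannot predict label subsets unseen in training;
  only the consensus can leave the observed-subset family.
* Binary Relevance, classifier chains and hierarchical label structures
  are not implemented.
* The synthetic generator draws i.i.d. proteins: no homology between
  sequences, no GO DAG semantics, no correlation between views beyond
  the shared true label.
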