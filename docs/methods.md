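# Methods

## Model

`bitterpep` treats bitter-peptide recognition as binary classification of
short amino-acid sequences (bitter = 1, non-bitter = 0). Each peptide is
mapped to a fixed-length vector by concatenating ten descriptor families —
AAC, TPAAC, APAAC, ASDC, DPC, DDE, GAAC, GDPC, SOCNumber and QSOrder, in
that fixed order — giving 1,337 named columns at the default lags. A
zero-column filter then removes columns that are identically zero in the
training matrix, and a random forest (or one of four baseline families) is
fitted to the retained columns. Nothing in the pipeline uses positional
motifs or alignments: every descriptor is a closed-form function of residue
identities and their pairwise order statistics, which is the appropriate
regime for peptides too short and too heterogeneous to align.

Assumptions worth making explicit:

- sequences contain only the 20 standard residues (others are rejected, not
  coerced; an explicit `drop_invalid` opt-in discards offending records);
- every peptide has length ≥ 2, and length must exceed the lag parameters
  λ and nlag for the lag-based descriptors to exist;
- classes are roughly balanced (stratified splitting and stratified k-fold
  are used throughout; metrics are also reported per class via Sn/Sp).

## Parameters

| parameter | default | meaning |
|---|---|---|
| λ (`lambda_`) | 1 | correlation depth of TPAAC/APAAC (dimensionless lag) |
| ω (`omega_tpaac`) | 0.05 | weight of the θ factors in TPAAC |
| w (`w_apaac`) | 0.5 | weight of the τ factors in APAAC |
| w (`w_qsorder`) | 0.1 | weight of the coupling numbers in QSOrder |
| nlag | 1 | maximum lag of SOCNumber/QSOrder |
| threshold | 0.5 | probability cut-off for binary calls |
| trees | 500 | random-forest size (√p features per split, unlimited depth) |

λ = nlag = 1 is deliberate: it is the largest value valid for dipeptides,
which genuinely occur in bitter-peptide data, and it fixes the descriptor
dimensions at 20/21/22/400/400/400/5/25/2/42 (total 1,337). Larger lags are
fully supported and tested but change the dimensionality. The APAAC weight
of 0.5 is unusually large compared with the 0.05 more often seen for
pseudo-composition weights; both are exposed, 0.5 is the default here.
Because Σf_r = 1 when f is the count frequency (the convention adopted for
TPAAC, APAAC and QSOrder denominators), every composition-style descriptor
sums to exactly 1 — a property the test suite checks on random peptides.

Random-forest hyperparameters are deliberately plain, strong defaults; no
tuning or feature selection beyond zero-column removal is performed
anywhere, and the classification threshold is never tuned.

## Property tables

The three per-residue scales (hydrophobicity, hydrophilicity, side-chain
mass) ship as TSV files in a documented alphabetical residue order and are
normalized to zero mean and unit root-mean-square deviation over the 20
residues ("standard normal" convention, population denominator 20).
Normalization is idempotent and invariant under positive affine transforms
of the raw scale; a constant scale is rejected (zero denominator). Users
can substitute any published variant of these scales via
`properties.load_scale`; descriptor values shift accordingly.

Two 20×20 residue distance matrices feed SOCNumber and QSOrder. The
Grantham chemical distance matrix is shipped as published (unscaled; an
optional normalization is unnecessary since QSOrder's shared denominator
makes each block scale-free in the coupling terms' relative weight only).
The classical Schneider–Wrede physicochemical distance table was not
available for redistribution here; in its place ships a **synthetic**
stand-in, `schneider_wrede_synthetic.tsv`: the Euclidean distance between
residues in the space of the three normalized scales, max-normalized to
[0, 1]. It has the same mathematical structure (symmetric, zero diagonal,
bounded, physicochemically ordered) and the loader accepts any replacement
TSV, but numeric descriptor values for SOCNumber/QSOrder differ from ones
computed against the published table.

## Evaluation protocol

Data are split per class — shuffle with a seeded generator, take the first
round(f·n) of each class — so 320+320 at f = 0.8 gives exactly 256+256
training and 64+64 independent peptides. Cross-validation is stratified
k-fold (k = 10 by default), shuffled with the given seed; the zero-column
filter is refitted inside every training fold, so no information about
validation columns leaks into fitting. Because per-fold metrics at n ≈ 51
are noisy, the primary aggregate is computed on the pooled out-of-fold
scores and calls; per-fold reports and their means are retained alongside.

Sn, Sp, ACC and MCC come from the confusion matrix at the 0.5 threshold;
MCC with a degenerate denominator (an empty confusion row/column) is
defined as 0 and flagged. AUROC is the probability that a random positive
outscores a random negative with ties counted ½. The test suite verifies
all five against brute-force confusion-count and O(n²) pair-counting
oracles, including tied scores.

## Synthetic data: what it does and does not show

The generator draws negative peptides with uniform residue probabilities
and positive peptides with probability mass δ moved onto the hydrophobic
set {A,V,L,I,M,F,W,G} (renormalized), lengths uniform on 2–15. This
emulates the single best-established property of bitter peptides —
hydrophobic enrichment — and deliberately includes dipeptides to stress
the λ/nlag < N edge cases. It does **not** emulate positional motifs,
length–class dependence, realistic residue usage, or homology structure;
passing pipeline tests on it demonstrates that the descriptors, fusion,
filtering, training and evaluation machinery are correct and sensitive to
compositional signal, not that real-data accuracies will be matched.

Because residues are i.i.d. given the class, the generator admits an exact
optimum: the count log-likelihood-ratio is the Bayes classifier, and
`synthetic.bayes_optimal_auroc` estimates its AUROC by Monte Carlo. Short
lengths cap attainable separation well below 1 — at the default δ = 0.3
the ceiling is about 0.89 (recomputed by `scripts/acceptance.py`) — so
classifier AUROCs on this generator should be read against that ceiling,
not against 1.0.

## Numerical and design choices

- **Index conventions.** The pseudo-composition component ranges are
  treated inclusively (residue components 1..20, pseudo-components
  21..20+λ resp. 21..20+2λ); ASDC's denominator is the total ordered-pair
  count N(N−1)/2. DDE uses the standard genetic code's 61 sense codons.
- **Labels.** Primary labeled input is two FASTA files
  (positives/negatives), the form such benchmarks are distributed in; a
  TSV id→label table is the alternative.
- **Zero filter.** Fitted on the training partition by default to avoid
  leakage; a fit-on-everything mode exists (`bitterpep benchmark` reports
  its retained-column count) because published reductions are sometimes
  computed on the pooled data. Constant-but-nonzero columns are kept.
- **Determinism.** Every stochastic step (generation, splitting, fold
  assignment, forest construction) takes an explicit seed; identical seeds
  give byte-identical outputs.
- **Problem sizes.** Repeated-simulation tests (10 seeds × 3 shift levels)
  use 200 peptides per class and 150-tree forests — enough for stable
  pooled-CV AUROC estimates at modest cost; single benchmark-scale runs
  use 320 per class and the full 500-tree default.
- **Generalized correlation functions.** The single-property and
  property-set variants of the TPAAC correlation are available by passing
  custom scale tuples; the default is the classic three-property form.

## Known limitations

- The shipped Schneider–Wrede-style matrix is a constructed stand-in (see
  above); SOCNumber/QSOrder values are internally consistent and fully
  tested against oracles, but not numerically comparable to values
  computed with the published table.
- No feature selection, hyperparameter search or threshold tuning; the
  toolkit evaluates the plain fused-descriptor pipeline only.
- The CKSAAGP descriptor family and deep-learning-based embeddings are out
  of scope.
- Synthetic validation covers compositional signal only; claims about real
  bitter-peptide benchmarks require supplying that data to the same CLI.
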