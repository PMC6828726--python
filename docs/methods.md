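# Methods

This note documents the model, the numerical conventions and the open design
choices made in `glysite`, and what the synthetic benchmark does and does not
demonstrate.

## Problem setting and model

Only asparagines inside N-X-S/T sequons (X ≠ proline) are candidate
N-glycosylation sites; everything the package scores is a sequon. Evaluating
at sequons — rather than at every asparagine — is deliberate: asparagines
outside the motif are trivially non-glycosylated and counting them as true
negatives inflates every metric.

The predictor has two stages with different granularity:

* **Protein stage.** Whether a protein is a glycoprotein at all is strongly
  predictable from remote homology. Each protein's similar-protein set S(P)
  is the hit list of a profile-HMM search, filtered at reported probability
  ≥ 0.5 (percent probabilities are normalized to fractions; self-hits are
  removed). A training protein with |S(Q) ∩ S(P)| ≥ k (default k = 5)
  becomes a template and votes with the *square* of the overlap, so a few
  strong homologs dominate many marginal ones. The score
  V_G/(V_G + V_NG) ∈ [0, 1] estimates the probability that Q is a
  glycoprotein.
* **Sequon stage.** A support-vector classifier with an RBF kernel over
  156-dimensional feature vectors (23 GDR + 79 SA + 54 SS with the reference
  vocabularies; the SA/SS block sizes are data-dependent). Training uses
  glycoprotein sequons only: experimentally validated sites are positives,
  unvalidated sequons of glycoproteins negatives. Sequons whose evidence is
  "Probable"/"Potential"/"By sequence similarity" are excluded from training
  and evaluation entirely, because their true status is unknown.
* **Integration.** Multiplicative adjustment of sequon scores by protein
  score: ×0.8 below 0.4, ×1.1 above 0.8 (capped at 1.0), unchanged in
  between; glycosite call at final score > 0.6. The percent changes are read
  as multiplicative factors (the natural reading of "percent" on a score);
  an additive variant (−0.2/+0.1) is available behind a flag. Boundary
  scores of exactly 0.4 / 0.8 fall in the unchanged band (strict
  inequalities, as specified). A protein with no templates has an
  *undefined* score and its sequons pass through unadjusted — absence of
  homology evidence should not penalize sequon-level calls.

## Feature conventions

**Gapped dipeptides.** A 25-mer window centred on the sequon N yields 23
gapped dipeptides: flank residue at gap k = 0…11 upstream (AkN) and
k = 0, 2…11 downstream (NkA). Downstream gap 1 is the sequon's own S/T and
is excluded as uninformative, giving a 460-type space (12·20 + 11·20).
String keys follow the printed AkN/NkA convention; the eleven downstream
types whose flank residue is itself N collide with their upstream
counterparts as plain strings and carry a `_c` suffix internally.

* GDR = (positive occurrence share) / (negative occurrence share). The
  denominator uses total dipeptide occurrences per class; per-class window
  counts differ only by a constant factor that cancels in min-max
  normalization (asserted by test).
* Zero negative count → GDR undefined rather than smoothed, so fitted
  ratios are exact odds ratios; a pseudocount ε (default 0) is exposed.
* Min-max normalization is per (gap, side) class; a degenerate class maps
  to 0.5. At encoding time undefined, unseen and X-containing dipeptides
  take the neutral value 0.5, so chain-end padding cannot push a prediction
  either way. Ambiguity letters (B, Z, U, O) are treated like X.
* Feature order is fixed (upstream gaps 11→0, then downstream 0, 2→11) so
  serialized models are stable.

**SA/SS patterns.** Window-level class strings (E/B exposure; H/E/C
structure; '-' at padded positions) are sliced into three regions anchored
at the sequon: N-terminal (ends at window position 12), sequon (positions
13–15, length fixed at 3), C-terminal (starts at position 16). For terminal
regions the pattern length w is swept over 3…11 and w\* maximizes APD_w
(ties to smaller w). Conventions:

* The 1%-of-windows frequency floor is ceil(0.01·N) compared with ≥, so a
  count exactly at the floor is retained.
* Patterns below the floor, patterns containing the pad character, and
  patterns never seen in negatives (whose ratio e/n would be infinite) are
  pooled into a single rare-pattern bucket; the bucket enters the APD sum
  as one pattern, and is skipped there only in the degenerate case where
  its own negative count is zero. Merging happens *before* APD computation.
* Encoding is one-hot per region block — the matched retained pattern or
  the bucket — giving exactly six ones across the six blocks. The bucket
  slot is always present for terminal regions (padded query patterns can
  appear at prediction time even if training saw none); the sequon region,
  which is never padded, drops it only when the retained patterns already
  exhaust the class alphabet.

## Training protocol

Grid search over C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵} × γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³}
(110 cells) by 10-fold cross-validated accuracy; the featurizers (GDR table
and pattern vocabularies) live inside the cross-validated pipeline, so each
fold's statistics come from its training windows only. With the winning
(C, γ), each fold model is refit with Platt-style probability estimation,
its decision threshold is picked from 0.25…0.75 (step 0.01; only the range
is prescribed) by maximum training-fold MCC, and the fold model with the
highest test-fold MCC is kept for prediction. Folds are grouped by protein
id by default, so sequons of one protein never straddle a split — the
grouping granularity is not prescribed and within-protein leakage seemed
the greater risk; `fold_mode="sequon"` restores plain stratified folds.
With a fixed `random_state` the whole procedure is bit-reproducible.

MCC is defined as 0 when any factor of its denominator vanishes. The ROC
curve is traced at 1000 evenly spaced cutoffs on [0, 1] (score ≥ cutoff
called positive) with trapezoidal AUC over the curve plus its (0,0)/(1,1)
end points; on continuous scores this grid AUC tracks the exact rank-based
AUC to well under 0.01.

## Synthetic data: what it emulates and what it does not

The generator produces, deterministically per seed and with one independent
random stream per operation: proteins with lognormal lengths (mean 400,
σ = 0.35) and well-separated planted sequons (about 4 per protein, two
thirds of glycoprotein sequons validated positives — mirroring the
≈ 2:1 positive:negative ratio of curated glycoprotein sequon sets);
class-conditional flank composition (a planted dipeptide with factor f
appears at rate f/20 in glycosite flanks versus the uniform 1/20
background); class-conditional SA/SS emission shifted at the
sequon-adjacent residues of glycosites; and homolog sets drawn from a
two-halves universe (300 members, mean set size 40) where an overlap boost
b sets the own-half draw probability to 0.5 + b/2. All outputs are written
in the exact file formats the real pipeline consumes.

It does **not** emulate real amino-acid composition, sequence evolution,
structural context, or profile-HMM alignment statistics. Passing the
planted-signal tests therefore demonstrates that the mechanics recover a
known signal under the stated conditions — not that the trained models
transfer to real proteomes, which requires the real training corpus plus
external homology-search and structure-predictor runs.

Test problem sizes were chosen to exercise the statistics at meaningful
scale while staying light: the end-to-end benchmark trains on ~60+60
proteins (~350 glycoprotein sequons) with a reduced 5×4 (C, γ) grid and
5 folds, and evaluates on ~100 held-out proteins (~600 sequons); the
strong-signal condition (six dipeptides at factor 8, SA effect 0.4, SS
effect 0.35, boost 0.9) must reach held-out MCC ≥ 0.6 and the matched null
must stay within |MCC| ≤ 0.15.

## Known limitations

* The quality of the SA/SS and homology inputs bounds the predictor; the
  package ships adapters and contracts, not the predictors themselves.
* Vocabulary sizes (and hence feature counts) are data-dependent; 79/54 are
  properties of the reference training corpus and are not asserted.
* The GDR neutral value 0.5 for never-observed dipeptides is a convention;
  prediction-time behaviour for such dipeptides is otherwise unspecified.
* Interval calibration of the protein score (the five-bin summary) is
  descriptive, not a fitted calibration.
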