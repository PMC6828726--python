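# glysite

Two-stage prediction of N-linked glycosylation sites in protein sequences.

N-linked glycosylation attaches a glycan to the amide nitrogen of an
asparagine, almost exclusively within the sequon **N-X-S/T** (X any residue
except proline). The sequon is necessary but not sufficient — roughly a third
of sequon asparagines are never glycosylated — so the practical question for
glycobiologists and protein engineers is: *which* sequons of a protein carry
a glycan? `glysite` answers this from sequence alone, in two stages:

1. **Protein stage — similarity voting.** An external profile-HMM homology
   search gives each protein P a similar-protein set S(P) (hits retained at
   probability ≥ 0.5). Training proteins whose sets share at least k = 5
   members with the query's set become *templates* and vote with weight
   |S(Q) ∩ S(P)|²:

   score(Q) = V_G / (V_G + V_NG),  V_G = Σᵢ |S(Q) ∩ S(Pᵢ)|² over
   glycoprotein templates, V_NG likewise over non-glycoprotein templates.

2. **Sequon stage — RBF-SVM over window features.** Each sequon is a 25-mer
   window centred on its asparagine (X-padded at chain ends), encoded as
   - 23 **gapped dipeptide ratios** (GDR): for dipeptide AkN / NkA (flank
     residue A at gap k from the sequon N), GDR = share of its occurrences
     among glycosite windows ÷ share among non-glycosite windows, min-max
     normalized within each (gap, side) class; 460 realizable types.
   - one-hot **pattern encodings** of predicted surface accessibility (E/B)
     and secondary structure (H/E/C) over three window regions, with the
     region pattern length w\* chosen to maximize the average pattern
     deviation APD_w = Σᵢ |eᵢ/nᵢ − z|(eᵢ+nᵢ) / Σᵢ (eᵢ+nᵢ), where z is the
     background glycosite:non-glycosite ratio.

   The SVM is tuned by 10-fold cross-validated grid search
   (C ∈ 2⁻⁵…2¹⁵, γ ∈ 2⁻¹⁵…2³, accuracy criterion) and its decision
   threshold is chosen from [0.25, 0.75] by maximum MCC.

**Integration.** The protein score adjusts every sequon score in that
protein: below 0.4 → ×0.8; above 0.8 → ×1.1 (capped at 1); otherwise
unchanged. A sequon with final score > 0.6 is called a glycosite.

The library is organised as scikit-learn-style estimators
(`SequonClassifier`, `SimilarityVotingClassifier`, `GlycositeFeaturizer`,
`GappedDipeptideEncoder`) with a thin CLI on top, plus a deterministic
synthetic-data generator that emits every input format the pipeline reads.

## Worked example

Simulate a labelled universe with planted signal, train, predict on fresh
proteins from the same conditions, and evaluate:

```bash
glysite simulate --seed 42 --out-dir demo/data \
    --n-glycoproteins 30 --n-non-glycoproteins 30 \
    --planted "W5N:8,Y0N:8,N0Y:8,L2N:8" \
    --sa-effect 0.4 --ss-effect 0.35 --overlap-boost 0.9
glysite train --fasta demo/data/proteins.fasta \
    --annotations demo/data/annotations.tsv \
    --labels demo/data/protein_labels.tsv \
    --sa-ss-dir demo/data/sa_ss --hits-dir demo/data/hits \
    --bundle demo/model --folds 5 --seed 1
# -> trained on 165 sequons: C=2^5, gamma=2^-11, threshold=0.68

glysite simulate --seed 43 --out-dir demo/query \
    --n-glycoproteins 10 --n-non-glycoproteins 10 \
    --planted "W5N:8,Y0N:8,N0Y:8,L2N:8" \
    --sa-effect 0.4 --ss-effect 0.35 --overlap-boost 0.9
glysite predict --bundle demo/model --fasta demo/query/proteins.fasta \
    --sa-ss-dir demo/query/sa_ss --hits-dir demo/query/hits \
    --out demo/predictions.tsv
glysite evaluate --predictions demo/predictions.tsv \
    --truth demo/query/annotations.tsv \
    --fasta demo/query/proteins.fasta --out-dir demo/eval
# -> accuracy=0.975  precision=1.000  sensitivity=0.933  specificity=1.000
#    mcc=0.948  auc=0.997
```

The predictions table carries both stage scores and the adjusted final call
per sequon:

```
protein_id  position  stage2_score  stage1_score  final_score  call
G0000       293       0.311242      1.000000      0.342366     False
G0000       321       0.983375      1.000000      1.000000     True
G0001       43        0.007934      1.000000      0.008727     False
```

The first row shows the stage-1 lift (×1.1) leaving a weak sequon below the
0.6 call threshold; the second a confident glycosite capped at 1.0. Here the
training universe is small, so the fitted vocabularies give 136 features
rather than the 156 of the reference training set; the layout is recorded in
the bundle manifest.

For real proteins, supply per-residue E/B and H/E/C class tables from any
surface-accessibility/secondary-structure predictor (`--sa-ss-dir`, one
whitespace-delimited table per protein) and per-protein homology hit lists
(`--hits-dir`, `hit_id probability` rows or ranked search summaries).
Without hit lists the protein stage is skipped and sequon scores pass
through unadjusted; without class tables the model trains on gapped
dipeptides alone.

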