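# circpred

Sequence-based prediction of proteins encoded by circadian genes.

Circadian genes (CRGs) drive the ~24-hour rhythms that organize plant
physiology, and almost all computational screens for them rely on time-course
gene-expression data. `circpred` takes the complementary route: it decides
from the **protein sequence alone** whether a gene product looks circadian,
so that whole proteomes can be scanned without any expression experiment.
It is aimed at plant molecular biologists shortlisting candidate clock
components, and at bioinformaticians who want to retrain the classifier on
their own positive/negative sequence sets.

## Method

Each protein sequence (canonical 20 residues, 39–1000 amino acids) is encoded
into a fixed 62-dimensional descriptor vector:

| block | k | description |
|---|---|---|
| AAC | 20 | amino-acid composition (residue frequencies) |
| scale means | 8 + 6 + 3 | per-residue physico-chemical descriptor scales averaged over the sequence |
| transitions | 21 | CTD class-transition frequencies: 9 ordered hydrophobicity pairs, 9 ordered secondary-structure pairs, 3 unordered solvent-accessibility pairs, each normalized by L−1 |
| physico-chemical | 4 | GRAVY, instability index, molecular weight, isoelectric point |

Classification is a binary C-SVM, `f(x) = sgn{Σᵢ yᵢ αᵢ K(xᵢ, x) + b}` with
`0 ≤ αᵢ ≤ C` and `Σᵢ αᵢ yᵢ = 0`, where `y = +1` for CRG and `−1` otherwise.
Seven kernels are implemented (linear, polynomial, rbf, sigmoid, hyperbolic,
Bessel and **Laplace**, `K(x,y) = exp(−γ‖x−y‖)`); the Laplace kernel is the
default. Because sequence length dominates several descriptors, training is
stratified into four length-homogeneous sub-datasets Q1–Q4 (quartile bins of
sequence length, separate bins per class), each with its own model; at
prediction time a sequence is routed to its bin's model by length. Class
imbalance is handled by repeated balanced undersampling: every replicate
keeps all positives and draws an equal-size negative subset, and metrics are
averaged over replicates of stratified fivefold cross-validation. Competing
kernels can be ranked over TPR/TNR/balanced accuracy/PPV/auROC/auPR with
TOPSIS closeness scores, and an iterative scheme that appends the out-of-fold
predicted label as an extra feature is available for kernels that profit
from it.

The 8/6/3-component residue scales shipped with the package are synthetic
stand-ins (PCA of RDKit descriptors of the 20 amino acids, see
`scripts/derive_scales.py`); users holding the published ProtFP/FASGAI/
Cruciani tables can substitute them through `DescriptorTables`. See
`docs/methods.md` for the full model description and design choices.

## Worked example

Simulate a labelled dataset with a strong compositional class signal, train
the 4-bin Laplace-kernel ensemble, and scan the positives:

```sh
$ circpred simulate --n-pos 60 --n-neg 300 --delta 0.2 \
      --min-length 39 --max-length 1000 --seed 7 --outdir data
wrote 60 positive and 300 negative sequences to data

$ circpred train --positive data/positive.fasta --negative data/negative.fasta \
      --kernel laplace --out model.joblib
trained laplace-kernel bundle on 60+300 sequences -> model.joblib

$ circpred predict --fasta data/positive.fasta --model model.joblib \
      --threshold 0.8 --out predictions.tsv
60 sequence(s): 60 predicted CRG (probability > 0.8), 0 rejected -> predictions.tsv

$ head -4 predictions.tsv
id      length  bin     probability     label   note
pos_1   947     Q4      0.9999529444300322      CRG
pos_2   640     Q4      0.9999477813278844      CRG
pos_3   255     Q2      0.9999976202290207      CRG
```

Each row gives the sequence id, its length, the length stratum whose model
scored it, the calibrated probability of being circadian, and the label
(`CRG` when the probability exceeds the threshold; sequences outside 39–1000
residues are kept in the table as `rejected` with the reason in `note`).
At this large class separation the trained ensemble recovers every held-in
positive with probability ≈ 1. Other subcommands: `encode` (FASTA → 62-column
feature TSV), `evaluate` (repeated balanced CV, JSON report) and
`select-kernel` (TOPSIS ranking of evaluation reports).

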