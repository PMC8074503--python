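# Methods

This note documents the model implemented by `circpred`, the choices made
where the design was genuinely open, and what the synthetic-data experiments
do and do not demonstrate.

## Problem and model

The task is binary discrimination of proteins encoded by circadian genes
(CRG, label +1) from other proteins (non-CRG, −1) using sequence information
only. The classifier is a C-SVM with the decision function
`f(x) = sgn{Σᵢ yᵢ αᵢ K(xᵢ, x) + b}`, dual box constraint `0 ≤ αᵢ ≤ C` and
equality constraint `Σᵢ αᵢ yᵢ = 0`. The quadratic program is solved by
scikit-learn's C-SVC on a **precomputed** Gram matrix; the kernels
themselves, and everything around them, are this package's code. One
contradictory label convention appears in the method's lineage (−1 for CRG
in the iterative-feature step); this package uses CRG = +1 throughout, which
only affects orientation, never accuracy.

## Feature encoding (62 dimensions)

* **AAC (20)** — residue frequencies, alphabetical by one-letter code.
* **Residue-scale means (8 + 6 + 3)** — each residue is mapped to a
  multi-component numeric descriptor and the components are averaged over
  the sequence. Arithmetic mean is the aggregation used by the descriptor
  literature's reference implementations. The shipped tables are *synthetic
  stand-ins*: deterministic standardized-PCA scores of RDKit 2D descriptors
  of the 20 free amino acids (`scripts/derive_scales.py`), with the same
  dimensionality and role as the published ProtFP (8), FASGAI (6) and
  Cruciani (3) scales. They are not the published values; `DescriptorTables`
  accepts user-supplied tables for anyone holding them. Every downstream
  property (feature counts, simplex structure, kernel behaviour, parameter
  recovery) is independent of the specific values.
* **CTD transitions (21)** — residues are mapped to property classes under
  three partitions: hydrophobicity {polar RKEDQN, neutral GASTPHY,
  hydrophobic CLVIMFW}, secondary-structure propensity {helix EALMQKRH,
  strand VIYCWFT, coil GNPSD}, and solvent accessibility {buried (incl.
  intermediate) ALFCGIVWMPSTHY, exposed RKQEND}. Adjacent-pair class
  transitions are counted over the L−1 dipeptides and normalized by L−1.
  The 21-feature layout is 9 ordered hydrophobicity pairs (self-pairs
  included) + 9 ordered secondary-structure pairs + 3 unordered
  solvent-accessibility pairs. With class cardinalities (3, 3, 2) this is
  the unique simple enumeration reaching 21; fully ordered counting would
  give 22 and unordered-distinct 7. Each sub-block sums to 1.
* **Physico-chemical (4)** — GRAVY (mean Kyte–Doolittle hydropathy),
  Guruprasad instability index `(10/L)·Σ DIWV[xᵢ][xᵢ₊₁]`, average molecular
  weight (Σ residue masses + one water, Biopython's curated mass table),
  and isoelectric point: the zero of the Henderson–Hasselbalch net-charge
  function over the termini and ionizable side chains (C, D, E, H, K, R, Y)
  with the EMBOSS pKa set, found by bisection on [0, 14] to 1e-3 pH. Which
  hydropathy scale and pKa set the original tool used is not documented;
  Kyte–Doolittle and EMBOSS are the field defaults and are versioned here.

Input handling: sequences are uppercased, one trailing `*` is stripped,
records containing B/J/O/U/X/Z are rejected (or skipped, by policy), and
lengths outside 39–1000 residues are excluded — long outliers produce
length-dominated, noisy descriptor vectors. Homology reduction (e.g. CD-HIT
at 40% identity) is recommended preprocessing for real training sets but is
an external step.

## Length stratification

Both classes are partitioned into four length-quartile strata; defaults are
the reference bins positive [39,221), [221,363), [363,538), [538,1000] and
negative [43,407), [407,485), [485,607), [607,1000], half-open with the last
bin closed at the 1000-residue cap. (The reference material prints both 538
and 539 for the positive third quartile; the inequality form 538 is used.)
`compute_quartile_bins` recomputes bins (linear-interpolation quantiles) for
retraining on new data. Unlabelled test sequences are routed by the
*positive* bins — the entity being detected — with the first bin extended
down to the minimum trainable length; lengths 39–42 fall below the negative
minimum (43) and are still routed, with correspondingly thinner negative
support.

## Balanced repeated evaluation

Negatives outnumber positives in every stratum, so each evaluation replicate
keeps all positives and draws an equal number of negatives without
replacement (replicate seed = master seed + replicate index). Stratified
fivefold CV is run per replicate and metrics are averaged across replicates
(default 10; an `outer_repeats` factor is available since the heavier
100-repeat reading of the protocol is also plausible). Reported metrics:
TPR, TNR, balanced accuracy `(TPR+TNR)/2`, PPV, and trapezoid-rule auROC /
auPR from out-of-fold decision values. Undefined metrics (zero denominator)
are NaN, excluded from means, and logged; an all-positive evaluation set
therefore reports accuracy = sensitivity.

## Training details

* **Standardization** — features are z-scored with statistics fitted on the
  training rows of each fit (never test rows). The original description is
  silent on scaling; distance kernels are meaningless when molecular weight
  (~10⁴ Da) shares a metric with frequencies (~10⁻²), so scaling is on by
  construction.
* **Kernel defaults** — γ = 1/62 (1/n_features) for distance kernels,
  d = 3, r = 0; C = 1. A 13×13 power-of-two grid search (2⁻⁶…2⁶ for γ and C,
  C only for linear) over CV balanced accuracy is provided; ties break
  toward smaller C, then smaller γ.
* **Probabilities** — Platt-style sigmoid on training decision values
  (logistic regression on the 1-D decision value); monotone by construction.
  The 0.8 probability threshold for proteome scans trades sensitivity for a
  low false-positive count.
* **Iterative label feature** — per iteration, the out-of-fold predicted
  labels (±1) are appended as one numeric feature and the model is refit;
  the CV-accuracy trace is recorded and the model of the best iteration is
  returned (early stop on a patience of non-improving iterations).
  Out-of-fold rather than resubstitution predictions are used so the
  appended column carries no target leakage.
* **Kernel quirks** — the method's nomenclature swaps "sigmoid" (here an
  inhomogeneous polynomial `(<x,y>+r)^d`) and "hyperbolic" (the tanh
  kernel); both are implemented as named. The printed Bessel form is not a
  usable formula; the kernlab-style normalized Bessel kernel is implemented
  instead. Sigmoid/hyperbolic/Bessel are indefinite kernels kept as
  baselines; final models use Laplace/linear/rbf.

## TOPSIS kernel selection

Competing kernels are ranked by TOPSIS: vector-normalize each criterion
column, weight (equal weights by default; the original weighting is
undocumented), form ideal/anti-ideal points, and score
`100·d⁻/(d⁺+d⁻)`. All six metrics are treated as benefit criteria; the
"overall" ranking concatenates the four per-stratum metric blocks into 24
criteria. Constant criterion columns are dropped with a warning. Published
overall scores for the reference datasets are not reproducible from printed
information alone (the full input matrix is unpublished), so no numeric
TOPSIS targets are asserted.

## Synthetic data: what it shows

The generator draws residues i.i.d. from a class-specific composition: a
base simplex (uniform by default) shifted by ±δ spread over the hydrophobic
residue class and renormalized (the renormalization shrinks the nominal 2δ
between-class mass difference to ≈ 0.2 at δ = 0.15). Lengths are uniform on
[60, 400] by default — inside the trainable range and wide enough to
exercise length-dependent features. An optional two-state Markov self-bias
injects adjacency structure for the transition features. Study conditions
used by the tests and the acceptance script: 400 sequences per class,
δ ∈ {0, 0.15}, fixed seeds; fivefold CV balanced accuracy is ≈ 0.5 at δ = 0
and ≥ 0.95 at δ = 0.15.

These experiments validate the machinery (encoding, balancing, kernels,
CV, calibration) under a controlled, purely compositional signal. They do
not emulate real circadian proteins: no positional motifs, domains,
phylogenetic correlation, or homology structure, and the real CRG/non-CRG
separation is far weaker (~60–65% balanced accuracy on curated plant data).
Passing the recovery test therefore demonstrates correctness of the
pipeline, not expected field accuracy.

## Numerical choices and degenerate inputs

* Bisection tolerance 1e-3 pH for pI; charge endpoints clamp to 0 or 14.
* Gram symmetry asserted to 1e-10; PSD checks tolerate eigenvalues ≥ −1e-8.
* Decision ties (f(x) = 0) predict +1.
* Constant features in training get unit scale (stay centred at zero).
* Balanced undersampling refuses strata where negatives < positives
  (oversampling is out of scope); degenerate all-equal length distributions
  are rejected when recomputing quartile bins.
* Model bundles serialize with a format-version field and refuse mismatches.

## Problem sizes

Default test and acceptance runs use 25–400 sequences per class, 30×62
Gram oracles, and ≤ 5 augmentation iterations at reduced scale; these sizes
were chosen to exercise every code path at comfortably interactive runtimes.
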