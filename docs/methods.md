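# Methods

## Problem and labels

Conformational B-cell epitopes are antigen surface patches bound by
antibodies; their residues are distant in sequence but adjacent in the fold.
`episeq` predicts the per-residue epitope state from sequence-derived
information only. Ground-truth labels are assumed to come from solvent
accessibility computed on antigen structures with and without the antibody:
a residue is an epitope when its accessibility drops by at least 5
percentage points upon binding (inclusive at the threshold), and exposed
when its unbound accessibility strictly exceeds 5% (equality counts as
buried — the asymmetry tracks the wording of the two rules). The low
exposure cut-off is deliberate: it makes essentially every epitope residue
"exposed", so the exposed non-epitope residues are a proper background
population for the composition features. Accessibility values are consumed
as opaque percentages; no max-ASA normalization is applied or assumed.
Positions are 1-based in files and 0-based in memory.

## Features

| Feature | Source | Meaning |
|---|---|---|
| F1 | computed | per-type frequency ratio, epitopes / exposed non-epitope residues |
| F2 | computed | per-type frequency ratio, epitopes / all non-epitope residues |
| F3 | computed | Hopp–Woods hydrophilicity scale |
| F9 | computed | energy-like epitope/non-epitope window potential ΔW(E), I = 7 |
| F11 | computed | energy-like exposed/buried window potential ΔW(E), I = 7 |
| F4–F8, F10, F12, F13 | external | per-residue columns from outside predictors (secondary structure, flexibility, disorder, predicted accessibility, solubility, conservation) |

External predictors are never reimplemented or invoked: their outputs enter
as named numeric columns of the annotation TSV, declared in the feature
registry (a multi-column feature, e.g. three secondary-structure
propensities, occupies several declared columns). Missing external cells
are imputed with the training-set column mean, which is neutral for both
classifier members. Composition ratios are smoothed with one pseudo-count
per type in each population, so they are finite and strictly positive even
for types unseen in epitopes. An entirely absent declared column is a
configuration error rather than silent imputation.

## Energy-like potentials

For a binary state u of the central residue, the singlet and pair
potentials are inverse-Boltzmann log-ratios of observed to independence
frequencies (see README for the formulas), counted over sequence intervals
I = 2w + 1 centred on each labeled residue. Conventions that were fixed
here, where more than one literal reading exists:

* the singlet sum includes the central position j = i (the window
  constraint admits it, and the self-term carries the composition signal);
* pair tables are keyed by unordered amino-acid type pair, aggregated over
  all offsets in the interval — offset-resolved tables would be hopelessly
  sparse under the σ = 10 shrinkage — and each unordered position pair
  {j, k}, j < k, counts once (an ordered convention would only scale ΔW₂
  by 2);
* frequencies are computed over *incidences* (one event per central
  residue × window position, or per central residue × position pair), so
  numerator and denominator marginals of each table share one total and
  stay consistent;
* windows truncate at chain termini — missing positions contribute
  nothing — and neighbours of non-standard type ('X') are skipped;
* the sparse-count correction r → (σ + n·r)/(σ + n) uses the incidence
  count n of the type (or type pair); unseen types give exactly r = 1 and
  a potential of exactly 0;
* RT = 0.593 kcal/mol (room temperature, natural log). Any positive
  constant would rescale all potentials linearly; ranking metrics and the
  tree ensemble are scale-invariant, the choice only fixes units.
* the per-residue feature is ΔW for the state u = E (epitope, resp.
  exposed); the score of the complementary state carries the mirrored
  information, so only one is used as a feature column.

Trained models serialize to a TSV of counts and derived potentials and
round-trip exactly (counts are integers; potentials are recomputed).

## Windowing and classification

Per-residue feature vectors are concatenated over a W-residue window
(offsets −(W−1)/2 … +(W−1)/2; W = 9 by default, W = 0 meaning the central
residue only). Concatenation rather than averaging preserves positional
information for the forest. Off-chain positions are filled with training
column means, computed after assembly and before standardization.

Training standardizes columns, then oversamples the minority class with
SVM-SMOTE: an RBF-kernel SVC (C = 1, γ = 0.01) is fitted on the z-scored
matrix, its minority-class support vectors — the borderline minority points
— seed the synthesis, and each synthetic row interpolates x + λ(x_nn − x)
with λ ~ U(0,1) toward one of the seed's k = 5 nearest minority neighbours
(k and the interpolation rule follow the toolbox convention the algorithm
is known by; the variant's optional extrapolation step away from safe
seeds is not used, keeping every synthetic row on a segment between two
real minority rows and the synthesis fully auditable). Neighbour searches
run in z-scored space, but the interpolation itself is done in the original
feature space, so original rows pass through bit-identically and the
segment geometry is exact. The parent pair and λ of every synthetic row
are recorded. The target ratio is 1:1, reached up to rounding; a balanced
input is returned unchanged.

The classifier is a soft vote: the arithmetic mean of the class
probabilities of a Gaussian naive Bayes and a 100-tree random forest
(library defaults otherwise: unlimited depth, √p features per split,
bootstrap on; all pinned by the seed and recorded in the model file). The
vote is therefore always bracketed by the two member outputs. The decision
threshold is 0.5, inclusive, for the per-residue E/N call; ranking metrics
use the probability directly.

## Evaluation

* Feature screening: two-sample Kolmogorov–Smirnov D between epitope and
  non-epitope feature values, with the asymptotic p-value.
* AUC: trapezoidal ROC integration, tie-consistent with the pairwise
  Mann–Whitney statistic (ties count ½).
* Cross-validation is grouped **by antigen record**: all residues of a
  protein share a fold, so window context never spans the split. Within
  each fold, everything that learns from data — composition ratios, both
  potential models, imputation means, the standardizer, SMOTE and the
  ensemble — is fitted on the training records only. The pooled AUC over
  all held-out residues is the headline number; per-fold AUCs are also
  reported. SMOTE provenance can be kept per fold to audit that no
  synthetic row has a held-out parent.
* Ablations: single-feature registries across window sizes, and sequential
  feature addition. No monotonicity is asserted for the latter; plateaus
  are expected.

## Synthetic corpora

Real training data require curated antigen–antibody structures, so all
calibration and testing run on generated corpora: background residues drawn
from a uniform (optionally Swiss-Prot-like) composition; exposure as
alternating exposed/buried runs (geometric lengths, mean 10, half exposed);
epitopes planted as contiguous 3–8-residue runs inside exposed segments at
a 1:11 epitope fraction, matching the ~1:10 epitope:non-epitope imbalance
of structure-derived corpora; epitope residues re-drawn from an
exponentially tilted composition; and "external predictor" columns as
class-conditional Gaussians (value = SNR·is_epitope + N(0,1)).
Accessibility columns are generated consistently with the labels, so the
labeling rules re-derive the generated states exactly and generated files
exercise the real readers.

The planted study condition (`planted_config`) uses a +0.65 log-enrichment
of D/E/K/R in epitopes and three independent external columns at SNR 0.30.
It was calibrated once so that individual features are weakly informative —
cross-validated single-feature AUCs near 0.6 — while their combination
stays measurably better, the regime sequence-only epitope predictors occupy
on real data. Contiguous sequence runs only approximate conformational
patches; no 3D geometry, antigen redundancy, or label noise from
complex-specific epitopes is simulated, so passing these simulations shows
the machinery is correct and calibrated, not that real-data accuracy will
match.

## Problem sizes and numerical choices

Simulation-based checks use sizes chosen to keep the whole suite fast on a
single CPU while leaving the statistics meaningful: null-calibration
potentials are measured on a ~500k-residue corpus (the per-residue window
score is an O(n) computation); the chance-level cross-validation check uses
a ~12k-residue null corpus (pooled-AUC standard error ≈ 0.01); the
signal-recovery comparison averages 10 generated corpora of 28 antigens
(~3,300 residues) with 5-fold grouped CV. The RBF-SVM inside SMOTE is the
superlinear step and dominates beyond a few tens of thousands of rows.

Under a zero-signal corpus the potentials converge to 0 as 1/√n of the
training size (each ΔW at I = 7 sums 28 estimated log-ratios); the signed
mean — the convexity bias of −ln — decays faster, as 1/n. At 500k residues
the mean |ΔW| is ≈ 0.23·RT and the signed mean ≈ 0.01·RT; per-type singlet
potentials stay below 0.05·RT. Tests pin the decay rate and bias rather
than an absolute noise floor.

Other conventions: ties at the decision threshold are positive; AUC is
undefined (an error) on single-class labels; KS requires non-empty samples;
fold assignment is a pure function of the record ids and the seed; all
CLI outputs embed the tool version, seed and a configuration hash, and
contain no timestamps, so equal invocations are byte-identical.

## Known limitations

* Sequence-only: residues adjacent in space but not in sequence are
  invisible to both the potentials and the window features.
* The non-epitope class is noisy by construction in real data (residues can
  be epitopes in complexes not observed); the generator does not emulate
  this, so real-data AUCs will be lower than simulation AUCs at equal
  signal.
* External features are taken at face value; their errors and mutual
  correlations propagate into the model untracked.
* The composition-ratio features are corpus-level lookups per amino-acid
  type; on small training corpora they are dominated by the pseudo-count
  smoothing.
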