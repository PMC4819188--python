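# Methods

## Problem and model

`bitterx` predicts, for a small organic molecule, (1) whether it is a
bitterant and (2) a ranking of the 25 human bitter taste receptors
(TAS2Rs) by probability of interaction. Both stages are binary RBF-kernel
SVMs whose raw decision values g(x) are mapped to probabilities with
Platt's sigmoid P(+1|g) = 1/(1 + exp(A·g + B)). The probability from
stage 1 is interpreted as bitterness confidence (call threshold 0.5); in
stage 2 it is the priority of a bitterant binding a given TAS2R, reported
on a 0–100% scale.

Assumptions worth stating explicitly:

- Bitterness and receptor binding are treated as properties of the 2D
  molecular graph (no conformers, no stereo-dependent descriptors) and of
  the receptor's primary sequence (no structure, no alignment).
- Decoy negatives (cluster representatives of a large compound pool) are
  *presumed* non-bitter; pseudo-negative pairs are *presumed*
  non-interacting. Label noise in the negative class is therefore part of
  the model's operating assumptions, which is one reason probabilities
  rather than hard labels are the primary output.
- Calibration assumes decision values independent of their labels, which
  is enforced by fitting the sigmoid only to out-of-fold CV decision
  values.

## Featurization

**Molecules.** Inputs (SMILES or MDL MOL) are standardized: salts and
solvents stripped to the largest organic fragment, charges neutralized
where chemically sensible, canonical SMILES emitted. Standardization is a
fixed point of itself. Queries with more than 200 heavy atoms are refused
(configurable; heavy atoms, hydrogens implicit). Descriptors come from an
open registry of ~58 2D physicochemical/topological descriptors (MW,
logP, TPSA, H-bond counts, rotatable bonds, ring counts, chi and kappa
indices, Balaban J, Bertz complexity, VSA bins, atom-class counts, …).
The registry is deliberately a *pool*: the active subset of a deployed
model is whatever feature selection chose, carried in the model bundle.

**Receptors.** Classic pseudo amino acid composition. With residue
frequencies f_u and correlation factors

    θ_k = (1/(L−k)) Σ_i Θ(R_i, R_{i+k}),
    Θ(a,b) = (1/5) Σ_t (T_t(a) − T_t(b))²,

the feature vector is x_u = f_u/(1 + wΣθ) for u ≤ 20 and
x_{20+k} = wθ_k/(1 + wΣθ), so all 20+λ values are non-negative and sum
to one. T_t are the five T-scale components (principal components of
topological descriptors over 67 amino acids), bundled as a 20×5 text
table and standardized to zero mean / unit variance per column over the
20 standard residues before use. Defaults λ = 20, w = 0.05 (the
conventional choices for this encoding); both are config keys, as is the
scale table itself. Sequences must use the 20 standard letters; a config
flag maps unknown letters to the column mean (zero after
standardization) instead of failing.

**Fingerprints** (used only for clustering/similarity, not as model
features) hash linear bond paths of 1–7 bonds into 1024 bits. This is a
dialect in the FP2 family, deterministic and graph-determined, not
bit-compatible with any external tool. A bond-less molecule (single heavy
atom) receives one atom-derived hashed bit so no valid molecule has an
empty fingerprint. Tanimoto similarity |a∧b|/|a∨b| is defined as 0 for
two empty sets.

## Dataset construction

The bitterant task balances positives against scarce true negatives plus
decoys: pool compounds duplicating a known molecule are excluded, the
remainder are clustered by 1 − Tanimoto into exactly the number of
missing negatives, and each cluster contributes its most central member
(maximal mean within-cluster similarity, ties by lexicographic id).
Clustering is seeded k-medoids by default; Butina-style leader clustering
is available behind a switch. k-medoids was chosen because it is
deterministic under a seed, fingerprint-native, and dependency-light.

The recognition task uses experimentally negative pairs first (for
receptors present in the positive set), then tops up with mismatched
(molecule, receptor) pseudo-negatives drawn uniformly from the product of
positive-set molecules × positive-set receptors (optionally plus extra
molecules), excluding positives and duplicates, always filling the
receptor with the fewest negatives so per-receptor counts differ by at
most one where feasible.

Splits are stratified per class with floor(train_fraction × class size)
training members; explicit per-class counts can override the floor rule
when a fixed published partition must be matched.

## Feature selection

A generational GA over chromosomes = (descriptor bit mask, C index,
γ index) with C ∈ 2^{−5..15}, γ ∈ 2^{−15..3}. Fitness is
q² − W·N_desp with W = 0.007; q² is the squared Pearson correlation
between ±1 labels and stratified 5-fold CV decision values (a config
switch substitutes CV accuracy). Operators: tournament selection (size
3), uniform crossover (rate 0.9), per-bit mutation at 1/|mask|,
single-step ± moves on the grid indices (rate 0.2 each), elitism 1.
Population 40, 30 generations, early stop after 10 stagnant generations.
These are desk-scale defaults — small enough to run in tens of seconds on
one core at n = 400 × 50 features, large enough to recover planted
signal reliably. Fitness evaluations are cached by chromosome, and the
best-ever fitness is non-decreasing by elitism. Selection error is not
nested-CV-unbiased; the q² used to pick features is optimistically
biased, a known limitation of single-loop wrapper selection.

## SVM and calibration

SVMs are trained with scikit-learn's SVC; the fitted machine is then
carried as explicit support-vector data (α, SVs, b) so model bundles are
plain text and reload reproduces probabilities to 1e-12. Features are
min-max scaled to [0, 1] on training data (constant features pass
through); scaling parameters ship with the model.

The Platt fit minimizes the negative log-likelihood against smoothed
targets t₊ = (N₊+1)/(N₊+2), t₋ = 1/(N₋+2) by Newton iteration with
backtracking line search, with all sigmoid/log terms evaluated in branch
form so no exponential overflows. Convergence is declared at per-sample
gradient norm < 1e-8; the objective is a sum over samples, so an
absolute gradient threshold would be unattainable in double precision at
large n (the line search also terminates cleanly if float precision
stalls it within 1e-6 per-sample gradient of the optimum). Two properties
of the smoothed targets worth knowing: probabilities never reach 0 or 1,
and on data whose true probabilities are extreme the fitted |A| is biased
slightly low — visible when decision values have large spread.

## Evaluation

SE, SP, PRE, ACC from exact integer confusion counts; a zero denominator
yields an explicit undefined (None) with a warning rather than a silent
zero. ROC is a threshold sweep over unique scores (ties cross together)
anchored at (0,0) and (1,1); AUC is the trapezoid area and equals the
tie-adjusted Mann–Whitney statistic, which the tests verify on random
instances to 1e-12.

## Synthetic data and what passing tests show

The generators produce: molecules from a fragment grammar
(prefix/scaffold/chain/terminal concatenation, deduplicated on canonical
SMILES, all under the atom limit); uniform-composition random sequences
of TAS2R-like length (300); and Gaussian feature matrices with a planted
standardized mean shift (default 5 informative of 50 features, effect
1.5, n = 400, balanced classes, optional label flips). The demonstration
bundle plants a simple chemical rule (aromatic + heteroatom ⇒ bitter;
N-containing molecules pair with alanine-rich receptors) purely to give
the SVMs learnable structure.

Synthetic data emulates the *pipeline conditions* — balanced classes,
planted low-dimensional signal, descriptor-scale features — but not real
bitterant chemistry: no realistic descriptor covariance, no activity
cliffs, no class imbalance, no assay noise structure. Passing tests
therefore demonstrate that the machinery is correct (arithmetic, fold
bookkeeping, calibration, recovery of recoverable signal), not that the
models would reach any particular accuracy on curated bitterant data.

## Numerical choices and degenerate inputs

- Platt per-sample gradient tolerance 1e-8; PseAAC sum-to-one within
  1e-9; model round-trip within 1e-12 (text serialization at %.17g).
- Tanimoto of two empty fingerprints is 0; receptor ranking ties break by
  receptor name; cluster-medoid ties break by molecule id; stratified
  split uses per-class floor.
- Degenerate inputs fail loudly: single-class datasets, CV folds with one
  class, k > n clustering, λ ≥ sequence length, empty masks, unknown
  descriptor names.
- Problem sizes used in the self-checks: 1159 molecules for the
  1078-entry dataset build, n = 5000 for calibration recovery, 400 × 50
  for GA recovery, 10-molecule batches for pipeline timing.

## Known limitations

- Descriptor identities of any historically deployed model are not
  reproduced; the registry is an open re-expression, so trained models
  here are *methodologically* comparable, not numerically identical, to
  prior results on curated data.
- The GA fitness uses q² for a classification task — a pragmatic choice
  that rewards margin-consistent ranking; it is not a proper scoring rule.
- Pseudo-negative pairs may contain unknown true interactions; reported
  recognition specificity is accordingly optimistic by construction.
- Fingerprints and clustering are 2D-topological only; stereoisomers
  collapse to one representative.
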