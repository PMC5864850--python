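# Methods

`pvpsvm` implements a sequence-based binary protein classifier of the kind
used to distinguish phage virion proteins (PVPs, the structural proteins of
a bacteriophage particle) from non-virion proteins. The method has four
stages: hybrid feature encoding, randomized-forest feature selection,
RBF-kernel SVM training with exhaustive hyperparameter search, and
leave-one-out cross-validated model selection by the Matthews correlation
coefficient (MCC). This note records the model, its assumptions, the
defaults and why, and the numerical conventions that a re-implementation
would need to match our outputs exactly.

## Feature encoding

Each sequence over the 20 standard residues maps to a fixed-order
583-component vector, blocks AAC(20) | ATC(5) | CTD(147) | DPC(400) |
PCP(11). All components are in [0, 1] so no dataset-level scaling is
needed and encoding is strictly local to the sequence.

* **AAC** — residue frequencies, alphabetical order (A…Y).
* **DPC** — overlapping dipeptide counts divided by `L − 1`; 400 pairs in
  alphabetical (first, second) order. Requires `L ≥ 2`.
* **ATC** — fractions of C, H, N, O, S atoms. We use peptide-bonded residue
  formulas (free amino acid minus one water) and add one terminal water per
  chain, so a free glycine gives (0.2, 0.5, 0.1, 0.2, 0) over its 10 atoms.
  The alternative convention (free-residue formulas throughout) differs only
  by a length-dependent water term; the shipped table
  (`pvpsvm/data/atom_counts.tsv`) pins our choice and can be overridden.
* **CTD** — for each of seven physicochemical properties the 20 residues are
  partitioned into three groups (tables in `pvpsvm/data/ctd_groups.tsv`,
  the standard three-group partitions from the protein-fold-class
  literature: hydrophobicity, normalized van der Waals volume, polarity,
  polarizability, charge, secondary-structure propensity, solvent
  accessibility). Per property: 3 composition values (group fractions),
  3 transition values (adjacent pairs crossing each unordered group pair,
  divided by `L − 1`; defined 0 for `L = 1`), and 15 distribution values.
  The distribution convention: positions are 1-based; for each group the
  reported values are `pos(1st occurrence)/L` and `pos(⌈p·n_g⌉-th
  occurrence)/L` for p = 25, 50, 75, 100%, where `n_g` is the group's count;
  an absent group contributes five zeros. Seven properties are required for
  the 7 × 21 = 147 layout; charge (positive KR / neutral / negative DE) is
  the seventh alongside the six named above.
* **PCP** — fractions of residues in ten classes (polar, hydrophobic,
  charged, aliphatic, aromatic, positively/negatively charged, small, tiny,
  large; Taylor-style memberships in `pvpsvm/data/pcp_classes.tsv`, with
  "large" the complement of "small") plus a mass term: the mean average
  residue mass, min–max rescaled over the residue-mass range
  [57.05 (Gly), 186.21 (Trp)] so that it is in [0, 1] without reference to
  any dataset.

All fractions are computed in double precision and stored unrounded.
Non-standard residues (B, J, O, U, X, Z, gaps) are outside the encoders'
domain: records containing them are rejected with a warning by default, or
stripped when sanitizing is requested explicitly.

## Feature selection

The importance score (FIS) of a feature is its mean Gini (impurity-decrease)
importance over forests grown on the training split of each round of a
stratified k-fold cross-validation (default 10 folds, 5,000 trees per
forest). The number of candidate variables per split (`mtry`) is drawn
uniformly from [1, 100] once per forest, so averaging over rounds also
averages over `mtry`; standard forest implementations fix `mtry` per forest,
which is why we randomize at that granularity rather than per node. The
held-out split of each round is unused — cross-validation here only serves
to average importances over data perturbations. FIS values are nonnegative
and, within one forest, sum to 1 across features.

Candidate subsets are formed by thresholding: a subset contains every
feature with FIS ≥ cutoff, ordered by descending FIS (ties by feature
index), so subsets from an increasing cutoff schedule are nested. The
default schedule is 25 evenly spaced cutoffs over [0.001, 0.004]
(step 0.000125), a choice we fixed because an arithmetic schedule with step
0.0011 over that range yields only ~3 subsets; the schedule is a config
parameter.

## Classifier and hyperparameter search

The classifier is an SVM with Gaussian RBF kernel
`K(x, y) = exp(−γ‖x−y‖²)`. The search evaluates every point of the integer
log₂ lattice C ∈ 2⁻¹⁵…2¹⁰, γ ∈ 2⁻¹⁰…2¹⁰ (26 × 21 = 546 points), scoring
each by pooled cross-validated MCC; ties break toward higher accuracy, then
smaller C, then smaller γ (the smoother model). An optional second stage
re-evaluates a 0.25-step lattice spanning ±1 around the coarse optimum —
off-lattice optima only arise through this refinement, which is on by
default. The inner CV scheme is LOOCV by default and k-fold as an option;
k-fold is substantially cheaper and is what the scaled-down acceptance
protocol uses.

Random-forest (RF) and extremely-randomized-trees (ERT) comparators run the
identical subset protocol; their `mtry` is tuned over {√p, p/4, p/2} on the
same CV scheme, 500 trees, and their decision score is the fraction of trees
voting positive (threshold 0.5; the SVM uses the raw decision function,
threshold 0).

## Evaluation and model selection

Per-subset performance is the LOOCV MCC: each sample is predicted by a model
trained on the remaining n − 1. By default hyperparameters are fixed once by
the grid search on the full training set and only the SVM weights are refit
per fold (non-nested); a `nested` option re-runs the grid search inside
every fold, the leakage-free but far costlier alternative. Metrics follow
the standard confusion-count formulas; MCC with a zero denominator (any
empty margin) is defined as 0 so model selection is total. AUC comes from
the ROC threshold sweep over distinct scores (equal scores grouped, curve
anchored at (0,0) and (1,1)) and equals the normalized Mann–Whitney U
statistic; constant scores yield AUC 0.5 with a warning. The final model is
the subset with the highest LOOCV MCC; ties break by higher accuracy, then
smaller subset, then lower cutoff index.

## Synthetic data

Real PVP training corpora are distributed through the original authors' web
services, so the package ships a generator instead of data. Sequences are
drawn i.i.d. per position from class-specific residue distributions —
uniform background by default (cleanest null; a natural-frequency table is
available) — with positives enriched multiplicatively on a signal-residue
set and optionally emitting a signal dipeptide at a fixed per-step rate.
Lengths are uniform over a range, identical for both classes, so no
length/mass signal leaks the label. The pinned acceptance scenario uses
30 positives / 60 negatives (the ~1:2 class imbalance typical of curated
PVP datasets), lengths 100–300, K/R enrichment 2.5 and a KR dipeptide at
rate 0.05. With enrichment 1 and no dipeptide the classes are exchangeable.

What the generator does *not* emulate: real protein families, domain
architecture, homology between sequences, or positional composition bias.
Passing the recovery tests therefore shows the machinery finds a planted
compositional signal at realistic sizes; it does not certify accuracy on
real phage data, which depends on biological signal strength the generator
cannot represent.

## Problem sizes and numerical choices

The recovery checks and the acceptance script run a scaled-down protocol we
consider adequate for a 90-sample dataset: 500 trees per importance forest
(instead of 5,000), 5-fold inner grid search (instead of LOOCV), refinement
off. On this protocol the pinned scenario attains LOOCV MCC ≥ 0.97 across
seeds, comfortably above the 0.8 recovery threshold.

The null-scenario leakage guard deserves a note. The *selection* pipeline is
optimistically biased on null data by construction — the reported MCC is a
maximum over 546 grid points × 25 subsets of correlated CV estimates, worth
roughly +0.4 at n = 40 — so chance-level output cannot be expected from it
and would not indicate a bug. Conversely, a heavily regularized smooth-kernel
SVM at null degenerates to training-majority voting, whose LOOCV MCC is −1
(each held-out sample leaves its own class in the minority): equally
uninformative about leakage. The guard therefore LOOCVs a single
fixed-configuration SVM in its discriminating regime — median-heuristic
γ (1 / median squared pairwise distance) and C = 8 — whose null MCC is
centered at 0; leakage of the held-out sample into any fitted quantity pushes
it toward +1. Measured mean over 20 seeds: ≈ 0.0.

Other conventions: a single run seed fans out to stage seeds through
`numpy.random.SeedSequence` spawn keys (stages: FIS, grid, final refit,
synthesis), so stages are independently reproducible; LOOCV folds whose
training degenerates to one class are recorded as failed with NaN
predictions rather than aborting the run; model archives embed the property
-table version and refuse to predict under a mismatched installation.

## Known limitations

* Non-nested LOOCV (the default) reports optimistic estimates whenever the
  candidate pool is large relative to n; the `nested` mode exists but is
  quadratically more expensive.
* LOOCV with near-balanced classes is anti-biased for majority-voting
  classifiers; comparisons across configs in very-low-signal regimes should
  use the holdout path instead.
* The CTD group tables, PCP memberships and ATC atom-count conventions are
  choices among published variants; they ship as data files precisely so
  they can be swapped, but archived models are only valid under the table
  version they were trained with.
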