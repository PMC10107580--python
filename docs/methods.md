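# Methods

## Problem

Activity cliffs (ACs) are pairs of structurally similar compounds whose
measured activities against one target differ by a large factor. They break
the similarity principle that underlies QSAR modelling, and any QSAR
regression f can be repurposed as an AC classifier by thresholding the
absolute difference of its predictions for the two compounds of a pair.
`acqsar` implements that evaluation end to end: curation of raw SMILES +
activity tables, matched-molecular-pair (MMP) detection and AC labelling, a
pair-aware compound split, a 3 x 3 grid of representation x regressor QSAR
models, and pair-level AC and potency-direction (PD) metrics — exercisable
without any external download through a bundled synthetic-landscape
generator.

## Curation

Structures are desalted by keeping the fragment with most heavy atoms (ties
broken by lexicographically smallest canonical SMILES), stripped of isotope
labels, and canonicalised with RDKit; unparseable rows are dropped and
counted. Duplicate structures (keyed on the standardised SMILES) are unified
at the geometric mean of their activities when max/min <= 10 — boundary
inclusive, matching the factor-10 language of the non-AC class — and removed
as unreliable otherwise. Geometric averaging of activities is exactly
arithmetic averaging of the log-labels; the tests assert this. The activity
label is a(s) = -log10(activity in its original unit) (nM for K_i, uM for
IC_50): a pK_i/pIC_50 shifted towards zero, with no molar conversion.
Cross-unit duplicate sets are flagged as an error rather than merged.

## MMP detection and labels

A decomposition cuts one acyclic single bond between heavy atoms (ring
bonds are never cut), each cut giving both (core, variable) orientations;
additionally every H-bearing heavy atom yields a hydrogen decomposition
(variable part = H, zero heavy atoms) so that H <-> OH style transformations
are representable. Two compounds form an MMP when they share a canonical
core fragment with differing variable parts subject to n_core >= 2 *
max(n_var1, n_var2), n_var <= 13 and |n_var1 - n_var2| <= 8 (heavy atoms).
Among multiple valid shared cores the record keeps the one with most heavy
atoms, ties broken by smallest canonical core SMILES; one record per
unordered pair. A consequence worth noting: for homologue pairs such as
toluene/ethylbenzene the canonical core is the benzyl fragment (H <-> CH3
exchange), not the phenyl fragment, because it is larger.

Detection is fragment-and-index (decompositions grouped by canonical core);
a brute-force all-pairs comparator over the same decomposition primitive is
kept as an independent oracle, and exact set equality of the two detectors
is asserted on random subsets in every test run.

Pairs are labelled by delta = |a(s) - a(s~)|: AC when delta >= 2 (factor
>= 100), non-AC when delta <= 1 (factor <= 10), half-AC in between;
half-ACs are removed before classification. Thresholds are compared with
exact IEEE semantics — no epsilon. The PD label is the compound with the
larger activity label; exact ties raise an error.

## Splitting

Compounds are split into k near-equal random folds (uniform permutation,
contiguous chunks, remainder to the earliest folds), repeated with m seeds;
the default plan is (m, k) = (3, 2). Each MMP then lands in M_train (both
compounds in training), M_inter (exactly one) or M_test (neither); M_cores
is the subset of M_test whose core does not occur among the cores of
M_train u M_inter. Under k = 2 the expected size ratio
|M_train| : |M_inter| : |M_test| is 1:2:1, which the acceptance script
re-estimates by simulation.

## Representations and regressors

* **ECFP** — binary Morgan fingerprints, radius 2, 2048 bits, chirality
  flags on (RDKit).
* **PDV** — a 200-dimensional physicochemical-descriptor vector; the
  descriptor names are frozen in `acqsar.descriptors` (RDKit 2D descriptors
  covering druglikeness, logP, refractivity, E-state, graph structure,
  fragment counts, charge and TPSA; the numerically unstable Ipc family is
  excluded). This manifest approximates the published general descriptor
  lists; the exact historical list is not reproducible from the sources at
  hand. Descriptors are standardised with training-set statistics only;
  non-finite values are imputed as 0 with a warning. Fingerprints and graph
  embeddings are not scaled.
* **GIN** — a graph-isomorphism-style encoder written in NumPy: per layer
  h' = MLP(h + sum of neighbour features) with two internal hidden layers
  (ReLU + batch normalisation) per layer, max-pool readout over atom
  vectors (permutation invariant). Atom features: one-hot element, degree,
  formal charge, aromaticity, attached-H count. For RF/kNN the encoder is
  pretrained with a single linear head on the training labels, then frozen
  and used as a static feature extractor; with the MLP it is trained end to
  end with the MLP as projection head.

Regressors: random forests and k-nearest neighbours (scikit-learn; kNN uses
the Jaccard distance on binary fingerprints and Euclidean distance
otherwise) and a NumPy multilayer perceptron (ReLU + batch normalisation at
every hidden layer, dropout, MSE loss, AdamW with decoupled weight decay
and per-epoch learning-rate decay). The neural nets are seeded and
deterministic; gradient correctness of every layer, including the graph
aggregation and the max-pool readout, is verified against numerical
differentiation in the tests.

## Hyperparameter optimisation

Every model is tuned on a single seeded 80/20 split of the training
compounds; test compounds never reach the objective (asserted by
instrumentation). RF/kNN sample uniformly from a declared grid; the MLP and
the end-to-end graph model use a lightweight categorical tree-structured
Parzen estimator (good/bad trial split at the 25% quantile, add-one
smoothed per-parameter densities, candidates drawn from the good density
and ranked by likelihood ratio). Grids and trial budgets are experiment
configuration, declared and versioned in `acqsar.hpo`; the printed neural
epoch budget is 500, while desk-scale runs and tests use much smaller
budgets (set explicitly wherever used). Training length interacts with
batch size, which is searchable while the epoch count stays fixed.

## Pair-level evaluation

With one activity known (M_inter) a pair is called AC iff
|a(s) - f(s~)| > d_crit; with both unknown (M_test, M_cores) iff
|f(s) - f(s~)| > d_crit; d_crit = 1.5 is the midpoint between the non-AC
and AC delta intervals, and a difference exactly equal to d_crit is non-AC.
PD is classified by comparing the two predictions; the literal rule uses
predictions for both compounds even on M_inter (a configuration switch
substitutes the known label, off by default, since the source procedure
states the prediction-only rule). Predicted ties score as incorrect —
conservative, and measure-zero for real-valued regressors.

Per trial: MAE over all test-set compounds (not only those in MMPs); MCC,
sensitivity and precision for AC classification (AC = positive class); PD
accuracy on the full pair set and on the pairs the same model predicted to
be ACs. Edge rules for the imbalanced AC task: with no positive predictions
MCC is recorded as 0 and the ill-defined precision as missing; missing
values are excluded from aggregate means but their counts are reported, so
exclusions stay auditable. Aggregates are means and sample standard
deviations (ddof = 1) over the m*k trials; plots draw error bars of total
length twice the standard deviation.

## Synthetic landscape

The generator assembles congeneric series: 25 ring-system scaffolds (10-14
heavy atoms, one substitution point) x 40 substituents (<= 5 heavy atoms,
including hydrogen), 1000 unique compounds by default. The noise-free label
is base(scaffold) + effect(substituent, scaffold) + context(scaffold,
substituent): base potencies uniform in [-3, -0.5] (0.3 nM - 1 uM in
label units), ordinary effects uniform in [-0.35, +0.35], context terms
N(0, 0.1^2). One designated cliff substituent carries +3 log units on a
seeded half of the scaffolds and nothing on the rest. The context-dependent
cliff is deliberate and is what real activity cliffs look like — the same
substituent is only a cliff where the binding site can exploit it; a
globally additive cliff fragment would be learnable to saturation from
fingerprint bits, collapsing the distinction between the pair sets that the
evaluation is designed to expose. Measured labels add N(0, sigma^2) noise
in log10 space (default sigma = 0.3, a typical inter-assay spread);
activities are reported as 10^(-label) nM. Five percent of rows are
duplicated with a +-2% value jitter and five percent are salt-decorated, to
exercise curation. Everything derives from one seed.

Ground truth records the noise-free label of every compound and, for every
same-scaffold pair, its noise-free delta, implied class and whether the
size-constraint arithmetic (scaffold as core) admits it as an MMP. With the
default geometry all same-scaffold pairs are admissible; an optional
14-ring-atom macrocyclic substituent exists whose pairs violate the 13-atom
bound and must be absent from detection. At sigma = 0 detection recovers
100% of admissible pairs with exactly matching classes; at sigma = 0.3
about 94% of detected classes match the noise-free classes (noise moves
pairs across the class boundaries), and the planted AC:non-AC imbalance
lands near 1:38 with roughly 6% half-ACs — all inside the regimes reported
for real assay extracts.

What the generator does not emulate: realistic medicinal-chemistry property
distributions, multi-site substitution, scaffold hopping, correlated
assay artefacts. Passing tests therefore demonstrate correctness of the
pipeline's bookkeeping and the qualitative pair-set phenomenology, not
performance on real assay data.

## Problem sizes and numerical choices

Tests and the acceptance script run the full default landscape (1000
compounds, ~18000 MMPs) for detection, splitting and recovery checks, and
train fingerprint RF/kNN models with reduced trial budgets (2-4 trials) for
the directional check; neural tests use tiny epoch budgets. These sizes are
the package's desk-scale defaults and complete in a few minutes on one CPU.
Batch normalisation falls back to running statistics for batches of one;
degenerate descriptor columns (zero variance) divide by 1 instead of 0;
empty pair sets report missing metrics rather than NaN.

## Known limitations

* Fragment canonical SMILES inherit chiral tags from the parent atom order;
  stereocentre parity adjacent to a cut may not be strictly canonical.
  Both detectors share the primitive, so their equivalence is unaffected.
* Only single cuts are implemented; multi-cut MMPs, ring cutting and
  MCS-based similarity are out of scope.
* A compound pair sharing several distinct valid cores yields exactly one
  record (the canonical core); alternative conventions would multiply
  records per pair.
* The TPE sampler treats every hyperparameter independently and
  categorically; it does not model interactions or continuous ranges.
* kNN distance on fingerprints is fixed to Jaccard by default rather than
  searched; the choice is configurable.
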