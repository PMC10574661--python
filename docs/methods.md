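# Methods

`qsarscreen` implements a cascade ligand-based virtual-screening analysis:
curate a compound library, build QSAR models of enzyme inhibition under a
fixed featurization/splitting/tuning protocol, combine them into stacked
ensembles, derive a self-organizing-map (SOM) activity landscape, and push
an unlabeled library through a multi-stage filter. This note records the
models, the protocol decisions, and what the synthetic benchmark does and
does not demonstrate.

## Curation

Raw SMILES are standardized before anything else: alkali/alkaline-earth
counter-ions of simple salts are disconnected and discarded, only the
organic fragment with the most heavy atoms is retained (ties broken by
longer canonical SMILES, then lexicographically), and the canonical
isomeric SMILES is emitted. Charged acids are kept as drawn — no
neutralization — and no tautomer canonicalization or protonation-state
enumeration is attempted. Deduplication keys on the canonical isomeric
SMILES, so E/Z and R/S isomers are distinct library members.

## Featurization protocol

*Classification* uses three binary fingerprints: MACCS structural keys
(166 bits; RDKit's unused bit 0 is dropped), Avalon topological
fingerprints (1024 bits) and ECFP4 circular fingerprints (Morgan radius 2,
1024 bits). Before modeling, the lowest-variance quartile of columns —
exactly ⌊d/4⌋ of them, computed on the training partition only — is
removed; ties go to the lower column index so the filter is deterministic.
A count-based reading of "bottom quartile" was chosen over a
percentile-of-variance reading precisely because the latter is ambiguous
under ties (fingerprint matrices are full of identical variances).

*Regression* uses numeric descriptor sets behind a pluggable provider
registry. Two open 2D sets ship as defaults: `physchem_2d` (RDKit's 2D
descriptor list minus the 85 fragment counters and minus `Ipc`, which
overflows on large molecules; 124 descriptors) and `fragment_counts` (the
85 RDKit `fr_*` substructure counters). A 3D provider can be registered
without touching the pipeline. A descriptor that fails or returns a
non-finite value is imputed by the training-set median; fingerprints are
never imputed. Descriptors then pass a pairwise Pearson-correlation
filter: pairs with |r| > 0.95 (configurable; the threshold is a package
default, chosen once) lose the member less correlated with the response,
greedily in descending |r|. Remaining descriptors are ranked by recursive
feature elimination under a random forest (one feature eliminated per
step, the least important by impurity importance; 500 trees by default,
config-exposed) and auto-scaled linearly so the training minimum maps to
0.1 and the training maximum to 0.9. A constant training feature maps to
the midpoint 0.5, and out-of-range values at apply time are deliberately
not clipped — the map stays affine so that distances remain meaningful.

## Datasets, labeling and splitting

Activity labels come from explicit IC50 threshold schemes, each a "high"
rule (an upper bound) and a "weak" rule (a lower bound) with exact
comparator semantics; four presets cover the two inhibition targets:

| scheme | high | weak | gap |
|---|---|---|---|
| `cox2_gap` | IC50 < 0.1 μM | IC50 > 10 μM | yes |
| `cox2_cut1` | IC50 ≤ 1 μM | IC50 > 1 μM | no |
| `mpges1_gap` | IC50 < 0.6 μM | IC50 > 10 μM | no label between |
| `mpges1_cut10` | IC50 < 10 μM | IC50 ≥ 10 μM | no |

Gapped schemes exclude mid-range molecules before splitting. Potency is
pIC50 = 6 − log10(IC50 μM).

Train/test splits are stratified with a test-set size of
round-half-up(n · fraction) and largest-remainder allocation across
strata, so every class's test count deviates from exact proportionality
by less than one molecule. Round-half-up is the unique rounding rule
consistent with all the published partition sizes this package reproduces
(e.g. 3455 · 0.25 = 863.75 → 864). Regression splits stratify on five
response-quantile bins. Repeated splitting uses consecutive seeds
(base_seed … base_seed + 9 by default), making every repeat independently
reproducible.

## Models and tuning

Four families, classification and regression: RBF-kernel SVM (C, γ, plus ε
for regression), random forest (n_estimators, max_leaf_nodes),
gradient-boosted trees via XGBoost (n_estimators, max_depth, subsample,
colsample_bytree) and a feed-forward net with four hidden layers. Grid
search runs under repeated stratified 5-fold cross-validation; regression
selects by smallest mean CV MSE, classification by largest mean CV MCC
(MCC being the headline classification metric throughout). For regression
the number of retained top-ranked descriptors is itself a grid dimension.
The tuning never sees the test partition. Default grids (all
config-exposed): C ∈ {0.1, 1, 10, 100}, γ ∈ {10⁻³…1}, ε ∈ {0.01, 0.1,
0.2}, n_estimators ∈ {100, 300, 500}, max_leaf_nodes ∈ {32, 128, 512, ∞},
max_depth ∈ {3, 6, 9}, subsample/colsample ∈ {0.6, 0.8, 1.0}, descriptor
counts ∈ {10, 20, 40, 80, all}.

The SVM classifier is wrapped in `CalibratedClassifierCV(ensemble=False)`
to provide class probabilities for stacking.

The DNN uses ReLU activations and Adam at learning rate 10⁻⁴ (default).
Its epoch count is not a grid dimension: inside repeated 5-fold CV each
fold trains with early stopping — patience 50 epochs on validation
accuracy (classification) or validation MSE (regression) — and the final
net is retrained on the full training partition for the median stopped
epoch. The epoch-selection loop defaults to 5 CV repeats at desk scale
(a flag restores more). Hidden widths default to (256, 128, 64, 32); no
dropout or weight decay is applied by default. Note that narrow ReLU
stacks at high learning rates can collapse to the majority class (dead
units); the defaults avoid this regime.

## Stacked generalization

For one algorithm, the three fingerprint-specific classifiers' positive
-class probabilities feed a logistic-regression meta-learner
(unregularized beyond numerical stability). Meta-features are out-of-fold
probabilities from a 5-fold split of the training partition — the
leakage-free choice; an `in_sample=True` flag reproduces the literal
"stack on training probabilities" reading. Each fold refits the base
model at its already-chosen hyperparameters rather than re-tuning.

## SOM activity landscape and HP

A rectangular SOM (default 10 × 11 ≈ the √(5√n) heuristic at the dataset
sizes involved; config-exposed) is trained by online competitive learning
on the same fingerprint features the classification stage uses (ECFP4 by
default): best-matching unit by Euclidean distance, Gaussian neighborhood,
learning rate and radius decaying linearly over epochs, everything
seeded. The map is trained on the full labeled dataset — both classes are
required, since the per-cell statistic

HP = (highly active molecules in cell) / (all molecules in cell)

needs a denominator that mixes classes. HP is undefined (NaN) for empty
cells; a candidate mapping to an empty cell is reported as "unmapped" and
dropped, never silently given HP 0. The screening rule keeps candidates
with HP ≥ 0.8 — inclusive, because screens of this design report kept
candidates at exactly 0.82 under rounding; a strict-inequality flag
exists. Ties in the BMU search go to the lower row-major cell index.

## The cascade

Stages run in order with per-molecule short-circuiting: (1) consensus of
the selected classifiers (default unanimity; the fraction is
configurable, since unanimity across tens of heterogeneous models is an
aggressive default); (2) mean predicted pIC50 across the selected
regressors — averaging happens in pIC50 space, where the models live, and
the implied IC50 = 10^(6−mean pIC50) must fall strictly below 10 μM;
(3) the HP rule; (4) the known-aggregator filter, which flags a candidate
only on exact structural identity or MACCS Tanimoto ≥ 1.0 by default (the
strictest reading; a lower advisory threshold is configurable). Model
selection for stages 1–2 is by external-validation MCC/RMSE (top-k or
threshold, ties by model id). Scaffold analysis and literature review are
inherently manual; the package renders them as a report (scaffold
frequency table plus nearest labeled neighbor per survivor), never as an
automatic filter. Every input molecule appears exactly once in the
output, survivors ranked by ascending implied IC50.

## Synthetic benchmark

The generator assembles molecules by attaching substituents to eight
aromatic scaffolds and assigns pIC50 = β₀ + Σ βₖ·1[substructure k] + ε,
ε ~ N(0, σ²), IC50 = 10^(6−pIC50) μM. Defaults — the study conditions the
tests run under — are β₀ = 4 (IC50 100 μM), σ = 0.2, and strong effects
on four substituents that both fingerprints and fragment counters can
see: sulfonamide +2.0, nitrile +1.8, trifluoromethyl +1.7, nitro +1.6
(all ≥ 1.5); chloro +0.3 and phenol −0.4 give the regression surface some
texture. Active-type molecules (40% of a training library) carry 2–3
strong groups (noiseless pIC50 ≥ 7.3), decoy-type molecules none
(≈ 4), and a 10% mid tier carries exactly one strong group and lands in
the exclusion gap of the gapped labeling scheme. Noiseless potency spans
roughly 3.6–9.8, comparable to a curated inhibitor set. Noise is Gaussian
in pIC50 (log-normal in IC50), which is how assay noise behaves.

The benchmark study (`run_study`) uses one stratified 4:1 split of a
2,000-molecule library (≈ 1,460 after deduplication and gap exclusion),
a 300-molecule external set and a ~440-molecule screening library with
15% planted actives, with reduced tuning grids and a single CV repeat —
problem sizes chosen so a complete study runs in about ten minutes on one
CPU. The DNN family is exercised by its own tests but excluded from the
default study algorithms for the same reason.

What passing shows: the pipeline's plumbing is sound end to end — the
features can represent the planted signal, tuning finds it, stacking does
not destroy it, the SOM landscape concentrates actives, and the cascade's
bookkeeping (consensus, unit conversion, thresholds, audit) is correct.
What it does not show: performance on real inhibitor data. The synthetic
activity model is linear in a handful of indicators with homoscedastic
noise and near-perfectly separable classes; real structure–activity
landscapes have activity cliffs, assay heterogeneity, scaffold bias and
class overlap, and real MCC/RMSE values will be far from the near-perfect
numbers the benchmark produces.

## Numerical choices and edge cases

- Tanimoto of two all-zero fingerprints is defined as 0 (RDKit returns 1).
- MCC with any zero denominator factor is defined as 0.
- A constant feature correlates 0 with everything in the correlation
  filter: removable, never the trigger.
- Exact pairwise diversity on very large libraries is quadratic; the
  sampled mode (10⁶ seeded pairs by default) is the desk-scale default,
  and sampling every pair reproduces the exact statistics.
- Scaffold clustering runs K-means on the 2-D t-SNE embedding of scaffold
  ECFP4 fingerprints (the reading that matches "reduce, then cluster");
  `cluster_in_fingerprint_space=True` clusters in the raw 1024-bit space
  instead. LogP is the Crippen atom-contribution estimate.
- All stochastic components (splits, forests, boosting, SOM, t-SNE,
  K-means, the generator) take explicit seeds; two runs with the same
  seeds are identical.

## Known limitations

No 3D, conformer-dependent or learned featurization; no scaffold-based or
temporal splitting; no probability calibration beyond what the base
learners provide; no docking stage (structure-based validation is outside
the package's scope); aggregator matching is whole-structure, not
SMARTS-alert-based, by design.
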