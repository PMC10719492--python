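# Methods

## The packing angle

The VH/VL packing angle summarises the relative orientation of the two
variable domains as one signed torsion. Eight structurally conserved
framework positions per domain define it: Chothia L35–L38 and L85–L88 in
the light chain, H36–H39 and H89–H92 in the heavy chain.

The computation, in order:

1. collect the sixteen Cα coordinates (an error naming *every* absent
   position is raised if any is missing, so incomplete structures can be
   excluded wholesale, matching the missing-residue filter);
2. fit a total-least-squares line through each octet — the principal
   axis of the centred 8×3 coordinate matrix via SVD, which minimises
   the sum of squared perpendicular distances over all lines;
3. orient each axis deterministically from the centroid of the first
   four residues (L35–L38 / H36–H39) toward the centroid of the last
   four (L85–L88 / H89–H92) — the ± ambiguity of a principal axis must
   be resolved by a numbering-based rule or the torsion sign would be
   arbitrary;
4. take the right-handed dihedral of the four points
   (light_pivot + light_axis, light_pivot, heavy_pivot,
   heavy_pivot + heavy_axis), where each pivot is the projection of that
   residue set's centroid onto its fitted line. For a total-least-squares
   line the projection *is* the centroid, so the pivots are the two
   octet centroids; the torsion axis is the line joining them.

The dihedral sign convention is the standard right-handed one; it was
cross-checked numerically against two independent implementations
(Biopython's `calc_dihedral` and mdtraj's `compute_dihedrals`). Under
this convention and the orientation rule above, natural antibodies score
near −46°; no global sign flip is applied. Angles are reported in
degrees in (−180, 180], to two decimals in file outputs (the same
precision the redundancy rule uses).

Rigid-motion invariance (< 1e−9°) and chirality (reflection negates the
angle) are enforced by tests, as is exactness of the inverse
construction used by the fixture generator.

## Residue encoding

Each amino acid is encoded by four physical parameters:

| channel | meaning | examples |
|---|---|---|
| sidechain_atoms | side-chain non-hydrogen atoms | Gly 0, Trp 10 |
| compactness | atoms on the shortest bond path from Cβ to the most distal side-chain atom | Val 2, Arg 6 |
| charge | formal charge, His = +0.5 | Asp/Glu −1, Lys/Arg +1 |
| hydrophobicity | Eisenberg consensus scale | Ile 1.38, Arg −2.53 |

The table ships as `src/abypap/data/encoding.tsv` rather than being
hard-coded, so it is auditable and swappable. Side-chain atom counts and
compactness were derived from the canonical side-chain bond topologies
(e.g. His: Cβ–Cγ–Nδ1–Cε1 is the shortest path to the most distal ring
atom, four atoms, so compactness 4; the aromatic rings of Phe/Tyr/Trp
count along the shorter branch). Hydrophobicities are the published
Eisenberg consensus values. No rescaling or standardisation is applied
to any channel: trees are scale-invariant, and the MLP baseline uses the
same raw features for comparability.

Positions absent from a structure — short CDR-H3 loops legitimately
leave H100A–H100G unoccupied — encode as the all-zero gap vector. Zeros
are distinguishable from every real residue only jointly (Gly has 0
side-chain atoms but hydrophobicity 0.48); the convention is fixed and
identical at training and prediction time.

## Feature schemas

* 13-position set: L38, L40, L41, L44, L46, L87, H33, H42, H45, H60,
  H62, H91, H105 (the historically selected most-informative subset).
* 37-position set: the full interface-position list, including the
  CDR-H3 insertion positions H100A–H100G.
* Loop lengths: occupied-position counts of CDR-L1 (L24–L34), CDR-H2
  (H50–H58) and CDR-H3 (H95–H102), insertion codes included — H100A
  counts toward H95–H102, otherwise the feature could never vary.
  (Some summaries of this feature set name CDR-L2 instead of CDR-H2;
  the ranges above are the operative definition and are what this
  package implements.)

Schema lengths follow as 4×13 = 52, 55 with loop lengths, 4×37 = 148,
and 151 with loop lengths. The schemas are named `gbr1`–`gbr4` after the
model variants that use them.

## Dataset rules

Structure filters (first failing reason recorded per rejection): both
chains present; solved by X-ray crystallography; resolution ≤ 3.0 Å; no
missing residues. "No missing residues" is implemented as: no internal
gap in either chain's numbering, and all sixteen geometry positions have
a Cα. Whole-chain completeness is not checkable without reference
sequences, so this numbering-based policy is the package's default and
is stated here deliberately.

Non-redundantization keys on (feature-residue string under the active
schema, angle rounded to two decimals, round-half-even). The first
occurrence survives; order is preserved; records with identical residues
but genuinely different angles all survive, keeping flexible antibodies
whose angle depends on binding status or crystal form. Loop lengths are
deliberately not part of the key. Rounding mode matters at boundary
cases and is therefore fixed here.

Splitting selects a seeded uniform 10% test set (size = round(n/10),
clamped to [1, n−1]); the default seed 100 echoes the models'
random_state. The temporal holdout takes records of a newer snapshot
whose dedup key is absent from the older one, giving an independent
validation set.

## Models

All predictors are scikit-learn-style estimators and compose with
pipelines, `clone` and model selection.

Gradient boosted regression (`PackingAngleGBR`), shipped defaults:
alpha 0.01, learning_rate 0.1, max_depth 2, min_samples_leaf 10,
n_estimators 50 000, random_state 100, loss "squared_error". In
scikit-learn's estimator, `alpha` only affects huber/quantile losses;
with the default squared-error loss it is recorded but inert. Because
the source of these tuned values does not state the loss, both readings
are runnable: set `loss="huber"` or `loss="quantile"` to make alpha
active. Training is bit-reproducible for fixed data and config.

Gated variant (`GatedPackingAngleRegressor`): angles are bucketed into
`normal` (−50° to −40°, inclusive on both ends — the boundary belongs to
the band, so no tie can fall in two classes), `max_outlier` (above) and
`min_outlier` (below). A gradient boosted classifier (same
hyperparameters plus warm_start) routes each query to one of three
regressors trained only on that class's examples with the regression
hyperparameters unchanged. Each class must have at least
2×min_samples_leaf training examples, otherwise fitting aborts with
advice to widen the data or use the plain regressor.
`last_dispatch_counts_` exposes per-class serving counts after each
predict call.

MLP baseline (`PackingAngleMLP`): one hidden layer of 15 rectified
linear units, L2 penalty 1e−4, up to 1200 iterations, otherwise
scikit-learn defaults; non-convergence logs a warning but returns the
fitted model.

Cross-validation uses scikit-learn's `RepeatedKFold` (default 10 folds,
1 repeat — the repeat count is not fixed by the protocol, so the
cheapest faithful setting is the default); every record is predicted
exactly once per repeat by a model not trained on it, and metrics are
computed on the pooled out-of-fold predictions as well as per fold.

Model bundles serialise the fitted estimator with its feature schema,
config and a dataset hash; loading refuses a bundle whose schema
disagrees with the requested one.

## Evaluation metrics

* Pearson's R between actual and predicted;
* mean error = mean *absolute* error (for a well-centred predictor a
  signed mean would sit near zero; MAE is also always ≤ RMSE, matching
  the observed orderings);
* RMSE;
* RELRMSE = RMSE / RMS(actual). With angles near −46° the denominator
  is ≈ 45–46, so RMSE/RELRMSE ≈ 45–46 is a built-in consistency check.
  The denominator is a documented choice: RMS of the actuals reproduces
  published (RMSE, RELRMSE) pairs to rounding, and alternatives (e.g.
  mean absolute actual) differ by < 2% in this angle regime;
* slope and intercept of ordinary least squares with *predicted* as
  response and *actual* as covariate, matching predicted-vs-actual
  plots where the optimum is slope 1, intercept 0. The regression
  direction is a recorded decision;
* classification: 3×3 confusion matrix in class order (min_outlier,
  normal, max_outlier), accuracy = trace/sum, and the multiclass
  (Gorodkin) Matthews correlation. Degenerate marginals (a single
  observed class) give MCC 0 with a warning so tiny fixtures keep
  running.

Constant predictors are reported with Pearson's R = 0 (correlation is
undefined at zero variance; 0 is the conventional, pipeline-safe value).

## Synthetic data: what it emulates, and what it does not

`make_fv_fixture` inverts the angle definition: the light octet lies on
the x-axis through the origin, the heavy octet on a line through
(0, 0, d) (d = 16 Å by default, a typical inter-centroid distance)
rotated by the target angle about the z-axis with the sign matching the
dihedral convention, first-four/last-four order matching the
orientation rule. With zero jitter the round trip is exact to machine
precision — that identity is the geometry module's strongest oracle.
Remaining framework positions (full Chothia numbering L1–L107,
H1–H113, configurable insertions) are filled with spaced filler
coordinates and a fixed pseudo-consensus sequence; EXPDTA and REMARK 2
headers are written so the quality filter is exercisable end to end.
Isotropic Gaussian jitter (default 0) emulates coordinate noise.

`make_planted_dataset` generates sequence→angle records in two modes.

*Regression mode*: angle = −46° + Σ w·(hydrophobicity of the residue at
each signal position, centred) + N(0, noise_sd), noise 1° by default.
Signal positions (default: all schema positions) draw from a designed
two-letter alphabet, R/I — the extremes of the hydrophobicity scale —
and weights are auto-scaled to a 5° signal SD. The alphabet is the
deliberate design point: with two levels per position the planted
additive function is exactly representable by depth-2 trees, each level
has ~n/2 sample support, and boosted test error converges to the noise
floor and stays there instead of drifting upward by chasing noise
through high-cardinality features. The cost is realism: real feature
columns have up to 20 levels and the real sequence–angle relationship
is not additive, which is precisely why real-data performance
(R ≈ 0.8 at best) is far from these clean-recovery ceilings. Passing
recovery tests therefore demonstrates the correctness of the
featurization/training/evaluation plumbing and the learners' ability to
reach a known noise floor — not field performance.

*Class-mix mode*: class labels are drawn from requested proportions
(e.g. 3% / 94% / 3%, the natural split); a marker position carries a
class-specific alphabet (D/E for minimum outliers, K/R for maximum
outliers, neutral residues for normal) and angles come from truncated
normals inside each class band. Classes are thus separable by
construction — a gatekeeper recovery test checks the classifier and
dispatch machinery, not real-world outlier detectability (the
real-data analogue is far harder: published gatekeeper MCC is ≈ 0.62).
Noise above 2° is rejected as incompatible with a requested mix, since
it would blur the bands the mix is defined over.

`realistic_angles` samples N(−46°, 2.5°), which puts ~94% of mass in
the −50° to −40° band and covers the observed −61° to −31° range.

The generators are pure functions of their seed. The fixtures do not
attempt physically realistic all-atom geometry, side-chain placement,
chain topology or inter-domain contacts.

## Problem sizes and numerical choices

Recovery and cross-validation checks run at n = 2000 with a 90/10
split (and the shipped 50 000-estimator configuration alongside a
500-estimator scaled configuration — both must meet the same recovery
assertions, and with the two-level signal design they do, with
indistinguishable error). Gatekeeper checks use n = 1500 with a
10/80/10 mix so each outlier class comfortably exceeds the
2×min_samples_leaf training minimum. Invariance checks use 1000 random
rigid placements at 1e−9° tolerance; inverse-construction identity is
asserted at 1e−6°. Tiny-fixture tests scale min_samples_leaf and tree
counts down; the shipped defaults are never changed by tests.

Parsing keeps altloc ' ' or 'A' only (single-conformer convention),
maps common modified residues to their parents (MSE→M etc., otherwise
skipped with a warning), takes Chothia numbers and insertion codes
verbatim, and never renumbers. Insertion codes order '' < 'A' < 'B'
within a number. Coordinates are used as-is in Å.

## Known limitations

* Renumbering raw PDB entries into Chothia numbering and splitting
  multi-antibody files are out of scope; inputs are assumed AbDb-style.
* The missing-residue filter is numbering-based (see above), so a
  structure missing its chain termini without an internal gap passes.
* λ/κ light-chain label conventions vary between sources; the reader
  exposes explicit `--light/--heavy` chain selection rather than
  guessing.
* The exact projection construction inside the original packing-angle
  tool is published only in outline; this implementation's reading
  (centroid pivots on total-least-squares axes) is stated above so any
  systematic offset against that tool on real data can be diagnosed
  rather than silently absorbed.
* mmCIF input is not supported.
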