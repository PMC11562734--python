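# Methods

## The model and its assumptions

An ionic liquid is modeled as an ordered pair of component molecules — a
cation and an anion given as SMILES — plus measurement conditions
(temperature in K, pressure in kPa). Properties are regressed on four
independent numeric representations of the pair; the working assumption is
that each representation captures different facets of the chemistry, so
models built on them agree where they interpolate and diverge where they
extrapolate. That divergence, the representation uncertainty
RU(x) = sd(ŷ_C-MF, ŷ_MD, ŷ_MI, ŷ_MG), is used as an applicability-domain
signal; the conventional model uncertainty MU(x) is the same statistic over
four hyperparameter variants of a single-representation model.

Canonical target units: viscosity is log₁₀(mPa·s) — viscosity spans orders
of magnitude, so the log scale makes additive errors meaningful; CO₂
absorption capacity is a mole fraction in [0, 1]; toxicity is log EC₅₀
(higher = less toxic); refractive index is dimensionless (> 1). Viscosity
models receive temperature, CO₂-capacity models temperature and pressure;
refractive index and log EC₅₀ are treated as condition-free and evaluated at
the ambient reference (298.15 K, 101.325 kPa). Condition coordinates are
centred on the reference and scaled by typical lab ranges (30 K, 100 kPa) so
they are O(1) next to the molecular features.

## Representations

- **C-MF / B-MF**: circular (Morgan) substructure fingerprints, radius 2,
  1024 slots per ion, cation and anion hashed separately and concatenated
  (2048 total) so ion identity is preserved. C-MF stores occurrence counts,
  B-MF presence bits; elementwise min(count, 1) reproduces B-MF exactly, a
  pinned test invariant.
- **MD**: a fixed, versioned list of 40 2D descriptors per ion (size,
  composition, topology, flexibility, electronic character), concatenated.
  A descriptor undefined for a molecule is imputed to 0. The list is recorded
  in the scheme tag; no conformers or quantum descriptors, which would defeat
  the speed advantage screening needs.
- **MI**: a deterministic 64×64 grayscale depiction of both ions on one
  canvas, pixels as ink intensity in [0, 1]; optional 4-fold rotation
  augmentation exists for training only, and is off by default.
- **MG**: heavy atoms as nodes (element one-hot over {C,N,O,S,F,Cl,Br,I,P}
  + other, degree, formal charge, aromaticity, ring flag, H count), bonds as
  undirected edges with bond-order one-hots, and a cation/anion component
  tag. No edge crosses the component boundary.

Every featurizer is a pure function of (pair, config); a `scheme_tag`
identifying featurizer + configuration is stored in each trained model and
checked at prediction time (an explicit override flag is required to bypass
it).

## Regressors

Vector representations (B-MF, C-MF, MD) use gradient-boosted trees
(LightGBM, deterministic single-thread mode). The image model is a
convolutional random-features regressor: a seeded bank of random k×k filters
+ ReLU + non-overlapping average pooling, feeding a standardized ridge head.
The graph model is a message-passing regressor: node states are iteratively
augmented with the mean of their neighbors' states, pooled (sum/mean/max)
per component after every round, and the concatenated rounds feed a
gradient-boosted head. Both deep-learning-shaped models therefore have fixed
(seeded) feature layers and trainable heads — small enough to train a full
suite on one CPU in about half a minute, while still being genuinely
convolutional / message-passing in structure. Conditions enter the image and
graph models as scalar side-inputs concatenated to the pooled features, not
painted into pixels or graphs, keeping the featurizers condition-free.

Each representation has a default 4-variant hyperparameter grid (trees:
leaves/learning-rate/rounds; image: filter count/size, pooling, ridge
strength; graph: message rounds plus head settings). `train_suite` compares
the variants on an internal 80/20 validation split of the training set
(seeded with the suite seed), selects the lowest-validation-RMSE variant,
then retrains all four variants on the full training set; the best model is
the selected member of that retrained set, so the MU variant set and the RU
best model share their training data. Ties in validation RMSE break toward
the lexicographically first variant name.

## Uncertainty and thresholds

Both MU and RU use the sample standard deviation (divisor n−1) over the four
member predictions; the convention is recorded in every profile, and a
population mode exists — the choice rescales all uncertainties by one
constant and the flagging rule is scale-equivariant, so it is
threshold-neutral. Thresholds are calibrated on training-set uncertainties:
kind I is the maximum (all training predictions deemed reliable — guaranteed
by the strict ">" flagging rule, under which ties stay reliable); kind II,
the default, is the Tukey fence Q3 + 1.5·IQR with quartiles by linear
interpolation between order statistics (the common scientific-software
default; pinned by a brute-force oracle test). MU is supported for all four
representations, but the default benchmark report covers the fingerprint,
descriptor and graph MUs alongside RU.

## Ensemble, metrics, interpretation

The ensemble is the unweighted arithmetic mean of the four best-model
predictions; a weight vector is configurable but defaults to (¼,¼,¼,¼).
Metrics are RMSE, MAE and R² = 1 − SS_res/SS_tot, with R² reported as
undefined (None) when the truth has zero variance; range-stratified RMSE
uses half-open bins on the true value (last bin closed), with default CO₂
edges (0, 0.2, 0.4, 0.6, 0.8, 1.0). Global interpretation of vector models
is seeded permutation importance (mean RMSE increase over shuffles of one
design-matrix column; constant columns are exactly 0), reported top-8 by
default; the direction of effect is a separate, documented heuristic — the
sign of the correlation between feature value and prediction.

## OOD benchmark and screening

Benchmark groups are full cross products of sub-samples from "non-cation" /
"non-anion" pools: by default 5 groups of 100 × 100 = 10 000 candidate
pairs, sampled without replacement within a group and independently across
groups (groups may overlap), evaluated uniformly at 298.15 K / 101.325 kPa.
Charge validation is relaxed for these candidates — the probes are arbitrary
molecules by design. Pools come from a user file or the synthetic OOD
generator; no external database client ships with the package.

The sequential screen applies property stages in order (default: viscosity
low → toxicity low, i.e. log EC₅₀ high → CO₂ capacity high), each stage
consuming the previous stage's survivors: candidates with RU above the
stage threshold are dropped as extrapolations (not deferred), then the
reliable ones are filtered by an absolute or percentile cutoff (default:
keep the best 50 %). Per stage, inputs = unreliable + cutoff-failures +
survivors exactly; with absolute cutoffs the final survivor set is
order-independent. Both facts are asserted in tests.

## Synthetic study conditions

The generator stands in for measured property datasets and makes ground
truth knowable. In-domain chemistry is tetraalkylammonium cations (four
alkyl chains, lengths 1–8, optional methyl branch) paired 1:1 with simple
organic anions (halides, carboxylates, sulfonates, alkylsulfates) — the
quaternary-ammonium salt family that dominates practical CO₂-absorbing ILs.
The OOD family is neutral fused aromatics (naphthalene/quinoline/anthracene
and indole/benzofuran/benzothiophene scaffolds with halogen, CF₃, methoxy,
nitro, cyano substituents) — structurally disjoint from the purely aliphatic
in-domain grammar by construction, which a test verifies as zero shared
canonical SMILES.

Targets are linear in substructure counts plus condition terms plus Gaussian
noise: value = baseline + Σ w_s·count(s) + w_T·(T−298.15) + w_P·(P−101.325)
+ ε. Coefficient signs follow physical intuition (longer chains raise
viscosity and toxicity, anionic oxygen raises CO₂ affinity, temperature
thins liquids and lowers uptake, pressure raises uptake). CO₂-capacity
targets squash the linear predictor (noise included) through a logistic map,
so values stay in (0, 1) and the noiseless value remains recomputable by an
independent count-and-sum oracle. Conditions are drawn from T ∈ [283, 343] K
and P ∈ [50, 500] kPa — plausible lab ranges, documented and arbitrary.
Noise defaults are ≈ one third of the noiseless signal spread under the
default coefficients (viscosity 0.12 log units, log EC₅₀ 0.30, pre-squash
CO₂ 0.25, refractive index 0.01), i.e. a best-achievable R² near 0.9, the
accuracy level typical of published IL QSPR models.

A substructure-count-linear ground truth is learnable by all four
representations (each reaches test R² > 0.5 at n_train = 400, a tested
floor), while the disjoint OOD alphabet drives the representations apart —
exactly the mechanism RU exploits. What the generator does **not** emulate:
real IL property distributions, inter-laboratory noise structure,
condition–structure interactions, measurement censoring, or chemistry
outside the two grammars. Passing synthetic experiments therefore
demonstrates that the pipeline's machinery behaves as designed, not that any
particular accuracy will transfer to measured data.

## Problem sizes and runtime

The self-validation experiment uses 400 training pairs, 100 in-domain test
pairs and 200 OOD probes per seed, three seeds, with the default small model
budgets; a full suite trains in roughly half a minute on one CPU, the whole
test suite in a few minutes, and `scripts/acceptance.py` in about two
minutes. These sizes were chosen as the smallest at which the uncertainty
statistics are stable across seeds.

## Numerical choices and degenerate inputs

- CSV round-trips write reals with 17 significant digits and parse with
  round-trip float precision, so datasets reproduce bit-for-bit.
- Dataset splits are uniform random with a recorded seed; |test| =
  round(fraction·n), clamped to keep both sides non-empty.
- Duplicate records (same pair and conditions) are kept and flagged;
  deduplication is an explicit call.
- A pair that fails featurization at prediction time yields NaN for that
  item rather than failing the batch.
- Empty candidate lists propagate as empty results; an empty bin in
  stratified RMSE reports n = 0 and an undefined RMSE; R² on zero-variance
  truth is reported as undefined rather than a number.
- Multivalent ions are rejected by default (the datasets are 1:1 salts);
  a permissive mode accepts any charge-balanced (+, −) pair, and benchmark
  candidates skip charge validation entirely.

## Known limitations

- The image and graph models use fixed random/structural feature maps with
  trainable heads; fully trained deep networks (and transfer learning from
  pretrained image models) would likely be stronger but are out of scope.
- RU is a spread statistic, not a calibrated probability; thresholds are
  outlier fences on training uncertainty, not coverage guarantees.
- Permutation importance on hashed fingerprints attributes signal to hash
  slots; collisions can smear importance across unrelated substructures.
- The in-domain flag rate under threshold II is substantial (tens of
  percent) because test-set uncertainties are systematically larger than
  the training uncertainties the fence is calibrated on; threshold I is the
  permissive alternative.
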