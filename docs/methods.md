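# Methods

## Property and data model

The modeled property is the decimal-log selectivity at infinite
dilution, log10 S_inf = log10(gamma_inf_raffinate / gamma_inf_solute),
for an ionic-liquid (IL) solvent, a solute/raffinate pair and a
temperature. One data point is the tuple (cation, anion, solute,
raffinate, T); atmospheric pressure is implied. The companion binary
property is the big-IDAC flag: a record is unreliable when both
underlying activity coefficients exceed a threshold (default 20,
configurable), because a ratio of two large IDACs signals a solvent
that dissolves neither component. When raw IDAC pairs are supplied the
package derives both the property and the flag; when only selectivities
are supplied the flag column is read as-is.

Duplicate records — identical in all five key fields — are merged by
the arithmetic mean of log10 S_inf; a conflicting flag on merged rows
is kept raised (conservative). Temperatures are stored in kelvin; a
read-time switch converts Celsius inputs.

SMILES standardization: RDKit canonicalization; ions keep their
explicit charges (they are the modeling subject and their charge is a
descriptor); neutral roles are reduced to the largest neutral covalent
fragment, dropping counter-ions and solvent fragments. A cation whose
net charge is not >= +1 (or anion not <= -1) is rejected rather than
neutralized.

## Features

Each component contributes the same 17-descriptor vector:
logP, topological polar surface area, molar refractivity, H-bond donor
and acceptor counts, rotatable-bond count, aromatic-atom count, ring
count, heavy-atom count, molecular weight, formal charge, fraction of
sp3 carbons, heteroatom count, N count, O count, topological diameter
(longest shortest path in bonds) and the Balaban J index. The roster
mixes physico-chemical character with structural features and is
configurable by name; 4 x 17 plus temperature gives the 69-variable
row in fixed block order cation | anion | solute | raffinate | T.
Descriptors are computed once per unique SMILES and cached, since large
tables reuse a few hundred components. A component whose descriptor
computation fails has its dependent data points dropped and counted,
never silently.

Single-atom ions are assigned topological diameter 0 and Balaban index
0 (the graph invariants are undefined on a vertex without edges; 0 is
the natural degenerate value and is constant across all such ions).

## Splits

Hyperparameter selection uses an optimization set held out IL-out:
every data point of a selected IL leaves together, though its cation or
anion may reappear on the training side in other pairings. Selection is
distance-based: Euclidean distances between unscaled 34-dimensional IL
vectors (cation block + anion block), per-IL median distance to the
*other* ILs, and the median of those medians as the threshold Thr.
Self-distances (always 0) are excluded from the per-IL medians — with
them, small rosters would bias every median low and degenerate the
threshold. Even-count medians use the midpoint convention. The first
10% of ILs above Thr and the first 10% below are taken; "first" is
ordered by descending |median − Thr| (most extreme first), which is
deterministic and maximizes the spread of familiar and unfamiliar
patterns; input order is available by option. If a side has fewer
eligible ILs than requested, all available are taken with a warning.

Cross-validation is five-fold and random at the data-point level within
the training side, with validation fraction 0.2, 0.5 or 0.8. At 0.2 the
five validation sets are a disjoint partition; at 0.5/0.8 they are
independent draws of round(fraction * n) points, followed by a minimal
repair: any point never drawn is swapped into the last fold in place of
a point covered elsewhere, so every point is validated at least once.
All draws flow from the plan seed.

## Scaling and applicability domain

Descriptors (temperature included — it is one of the 69 variables and
the procedure draws no distinction) are range-scaled on the training
side: x' = (x − min)/(max − min), then rounded to one decimal with
round-half-to-even (bit-reproducible; tie behavior is otherwise
arbitrary), collapsing training values onto the 11-point grid
{0.0, ..., 1.0}. The fitted coefficients are applied unchanged to
optimization/test/screening rows, which may leave [0, 1] and are not
clipped. Constant training columns scale to 0.0 and are excluded from
applicability-domain checks (their box edge is a single point and any
measurement noise would spuriously flag every query).

The applicability domain is a bounding box on the *unscaled*
descriptors: per-variable training [min, max], bounds inclusive; a row
is inside iff every (non-constant) variable is in range. Out-of-domain
predictions are reported with a flag, never suppressed.

## Networks and training

Both tasks use the same architecture: 69 inputs, a first hidden layer
with a parametric rectified-linear activation (one learned slope per
layer, initialized at 0.25), a second rectified-linear hidden layer,
and a single sigmoid output unit. Regression targets are min-max scaled
to [0, 1] on the training side so the sigmoid head is well-posed, and
predictions are inverse-transformed; the loss is mean absolute error.
The classifier trains the same head under binary cross-entropy and the
ensemble score is thresholded at 0.5. A constant regression target is
centered at sigmoid output 0.5 to avoid a degenerate scale.

Fixed training parameters: 2 hidden layers, batch size 2000, 500
epochs (reducible in configuration). Tunable parameters form the
exhaustive 72-point grid: initializer in {glorot, lecun, he} (uniform
variants), first hidden width in {100, 200}, second in {10, 20, 40},
optimizer in {rmsprop, adamax, adadelta, sgd}. The optimizers use
their conventional default rates (sgd 0.01; rmsprop 0.001, rho 0.9;
adamax 0.002, betas 0.9/0.999; adadelta rho 0.95 with unit step — the
original formulation, since a small global rate makes adadelta inert).
The implementation is plain numpy backpropagation; weight draws and
per-epoch batch shuffles derive from the run seed, and per-fold seeds
are spawned from it through a seed sequence, so runs are exactly
repeatable.

For each grid point five networks are trained, one per fold on the
fold's fit partition; the ensemble prediction is their arithmetic mean
(inverse-transformed for regression). Configurations are scored on the
optimization set by the decision functions (lowest wins for regression,
highest for classification); ties break toward the smaller first then
second hidden width. The per-configuration report with every metric
component is written out so the argmin/argmax is externally auditable.

Repeatability of a headline error across retrained models is
summarized by a normal-theory interval mean ± z·sd/√n (z = 1.96, sample
standard deviation), endpoints rounded to three decimals.

## Metrics

Regression: pooled MAE; per-IL MAE averaged with equal weight per IL
(so abundant extractants cannot mask poorly predicted rare ones); the
absolute difference between observed and predicted population (1/n)
covariances of the property with temperature; and the absolute
difference of the observed and predicted value ranges. The decision
function is the geometric mean (fourth root of the product) of the
four, so each metric contributes equally on the log scale.

Classification: sensitivity, specificity, balanced accuracy — their
mean — pooled accuracy and per-IL accuracy (equal IL weight); decision
function sqrt(BA × Acc_IL). A one-class evaluation leaves the
undefined rate as NaN rather than raising inside a pipeline run.

The regression output can also be read categorically ("is this a good
extractant?") by binarizing observed and predicted values at a
threshold (default log10 S_inf > 1, i.e. ten-fold selectivity) and
reporting accuracy, sensitivity, specificity, BA, PPV and NPV.

## Virtual screening

All cation × anion combinations are enumerated row-major; the
plain-text matrix (rows cations, columns anions, X explored / O
unexplored) marks combinations already studied, which are excluded from
candidates. Each candidate is featurized for the query solute,
raffinate and temperature, scaled with the training scaler, predicted
by the regression ensemble, flagged by the classifier and checked
against the applicability domain. Output is sorted by predicted
log10 S_inf descending with a lexicographic IL-code tie-break, so
reports are deterministic; one screen call covers one temperature.

## Synthetic studies

The generator emulates the structure of a selectivity compilation, not
its statistics. Cations are enumerated from three cores (quaternary
ammonium, N-methylmorpholinium, pyridinium) crossed with eight side
chains (C1–C5 alkyl, hydroxyethyl, hydroxypropyl, methoxyethyl); anions
come from a fixed list of ten common IL anions; solutes and raffinates
from a list of fourteen common neutral molecules. The dataset is the
full factorial grid over ILs × mixtures × temperatures.

The planted map is Z w + c·Z_p Z_q over the column-standardized
features — linear plus a single pairwise product, recoverable by a
small network yet not trivially linear — affinely rescaled to a
realistic span of log10 S_inf in [−0.5, 3.5] (selectivities from ~0.3
to ~3000). Observed values add N(0, σ) noise, default σ = 0.1, a
typical inter-laboratory spread of about 25% in S_inf. Planted IDAC
magnitudes are log-normal around a base level calibrated by the normal
quantile so that roughly `big_idac_rate` (default 10%) of records
raise the flag, with a second planted descriptor direction (sd 0.4)
plus record noise (sd 0.3) making the flag partially learnable. A
hidden truth table retains the noiseless values for recovery tests.

Default study size: 10 cations × 6 anions × 3 solutes × 3 raffinates ×
9 temperatures (288.15–368.15 K) = 4860 points — large enough for the
networks to recover the planted map, small enough that the full
pipeline (4-configuration grid, 100 epochs, both tasks, screening) runs
in about a minute on a single CPU core.

What passing synthetic tests shows: the plumbing is correct end to end,
the learner recovers a smooth planted map well below twice the noise
level, and the screen ranks the planted optimum first. What it does not
show: performance on real selectivity data, whose noise is
heteroscedastic, whose design is extremely unbalanced across ILs and
temperatures, and whose structure–property relation is not a
linear-plus-interaction map. Headline accuracies on external
compilations are therefore out of scope here.

## Numerical choices and limitations

* Rounding everywhere is round-half-to-even (numpy default).
* Euclidean distances via scipy `pdist`; exact, no approximation.
* The optimization-set size rounding uses floor(0.10 · N) per side.
* The big-IDAC criterion (both IDACs strictly above the threshold) and
  the duplicate-merge rule are configurable, as different compilations
  document them differently.
* The 17-descriptor roster reproduces the descriptor *categories* of
  commercial calculators with open RDKit implementations; numeric
  values differ from any specific commercial tool, so coefficients are
  not transferable to tables produced by one.
* The full 72-configuration × 5-fold search at 500 epochs on millions
  of rows is a cluster-scale computation; the configuration exposes the
  reduced grid, epoch count and synthetic study size used for
  desk-scale runs.
* No early stopping, dropout or regularization: model capacity is
  controlled only through the enumerated grid.
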