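# Methods

`dualniche` implements a dual-niche habitat modelling workflow for a
desert host shrub and its obligate root parasite: separate climate and
soil suitability models are fitted with a tree ensemble, combined by a
minimum rule, constrained by host availability for the parasite,
attributed with exact Shapley values, compared with Schoener's D, and
projected under climate-shift scenarios. This note records the model,
the numerical choices, and what the synthetic benchmark does and does
not demonstrate.

## Suitability model

Occurrence records are thinned to one per grid cell (seeded random
retention within multiply occupied cells) to blunt sampling bias.
Continuous predictors with pairwise Pearson |r| >= 0.8 are greedily
pruned, dropping the lower-importance member of the worst pair first;
ties keep the lexicographically smaller name so the filter is
deterministic and order-insensitive.

Because true absences are unavailable, pseudo-absences are sampled from
cells that fail a dual eligibility filter:

* **Environmental profile** — a cell is too presence-like (ineligible)
  if, on every continuous layer, its value lies within the presence
  [q05, q95] envelope.
* **K-means vote** — valid cells are clustered in z-scored continuous
  environmental space (k = 8, 5 seeded runs); per run, clusters in the
  lowest quartile of presence density are flagged, and a cell is
  eligible when flagged in a majority of runs. Majority voting is used
  because averaging raw cluster labels across runs is ill-defined under
  label switching; the vote preserves the intent (stability across
  initialisations) with a well-defined operator. k, the run count and
  the density quantile are config parameters; the defaults above are
  declared, not estimated.

Model evaluation uses spatial block cross-validation: the grid is tiled
into square blocks (default side = landscape side / 5), and in each of
10 iterations a seeded permutation assigns 70% of blocks (round half
up) to training and 30% to validation. Pseudo-absences are drawn fresh
each iteration, equal in number to the presences of the training and of
the validation block set, and sampled only inside that block set so the
partitions stay spatially separated. When a partition's blocks contain
too few dual-eligible cells — common at desk scale, where the
K-means-flagged region is spatially clumped — the draw tops up from the
envelope-only mask within the partition rather than discarding the
iteration.

Each iteration fits four probabilistic classifiers on the same points:
random forests and gradient-boosted trees at two complexities
(RF_simple: 100 trees, depth 6, min leaf 10; RF_interm: 300 trees,
unlimited depth, min leaf 2; GBDT_simple: 100 trees, depth 2, learning
rate 0.1; GBDT_interm: 400 trees, depth 4, learning rate 0.05). The
habitat suitability index (HSI) of a cell is the mean presence
probability of the four members, and the final surface is the mean over
iterations. Categorical soil codes enter as plain integer features;
tree models split on them directly without one-hot encoding. The
climate model and the soil model are fitted on their respective feature
subsets of the same presence/pseudo-absence tables, so both see the
same contrast while attributing it to different environmental axes.

Metrics per iteration: AUC-ROC, sensitivity, specificity, TSS
(= sensitivity + specificity − 1), precision, and the continuous Boyce
index on the validation presences (10 overlapping windows of width 0.2
on the [0, 1] HSI range; Spearman correlation of predicted-to-expected
ratios against window midpoints; windows with zero expected frequency
dropped). The binarization threshold is the score maximising
sensitivity + specificity, ties resolved toward the lower threshold;
final maps use the mean of the per-iteration optima. Binarization uses
the >= convention at the boundary throughout.

## Integration, overlap, areas

Following the minimum-suitability ("barrel") principle, the dual
surface is the cellwise minimum of the climate and soil surfaces; the
parasite is additionally capped by the host's dual surface, so parasite
suitability can never exceed host suitability. Binary co-suitable maps
are the logical AND of the per-surface binary maps, each at its own
threshold. Threshold robustness is probed by recomputing suitable area
at t × (1 ± 0.05). Whether the parasite's own soil surface or the
host's is used in the parasite minimum is a config choice
(`host_dual_surface` capping covers the host-soil reading); neither
reading is asserted as canonical.

Schoener's D between two suitability surfaces is
D = 1 − ½ Σ_i |p_X,i − p_Y,i| over cells valid in both. By default each
surface is first normalised to unit sum: raw [0, 1] HSI surfaces can
push D outside [0, 1], contradicting its definition as a bounded
overlap index, and normalisation reconciles the formula with its range.
A raw mode is retained and flagged in the report. Overlap bands:
very low [0, 0.2), low [0.2, 0.4), moderate [0.4, 0.6), high
[0.6, 0.8), very high [0.8, 1.0].

Cell areas assume a spherical Earth (R = 6371.0088 km): a cell of
angular size c degrees centred at latitude φ covers
(πR/180)² c² cos φ km²; suitable areas are reported in 10³ km².
Percent change is (current − future) / current × 100.

## Scenario projection

Future scenarios are additive shifts on the standardized climate
layers; soil layers are held static (soils change on much slower
timescales than decadal climate). The already-fitted per-iteration
ensembles re-predict on the shifted stack — no re-training, since
occurrence data for a future period cannot exist — and future maps are
binarized at the current-period thresholds.

## Synthetic landscape

The generator emulates the structure of the real inputs rather than any
particular geography. Climate layers are Gaussian random fields
(seeded white noise smoothed with σ = 6 cells, then standardised);
with a 100×100 domain this yields enough independent environmental
patches that marginal responses are identifiable. The soil-class layer
is a Voronoi tessellation of 12 seed points per class, giving
contiguous soil units at finer spatial grain than the climatic
gradients, as in harmonized soil maps — every class then intersects a
range of climates. AWC (available water capacity) is a smoothed field
mapped through the normal CDF to a uniform [0, 1] marginal.

Truth surfaces: climate suitability is logistic(β₀ + Σ βⱼ xⱼ) with a
dominant first coefficient and intercept β₀ = −2, chosen so that
roughly 5% of the landscape is finally suitable — the prevalence
regime of a range-restricted desert specialist (the modelled system's
suitable area is a few percent of its study window). Soil suitability
is a per-class base value times a Gaussian response in AWC (optimum
0.6, width 0.25). Final truths are cellwise minima, with the parasite
additionally capped by the host's final truth; the parasite's climate
coefficients are a blend of the host's vector with a rotation of it, so
the two niches overlap strongly without being identical. Presences are
drawn cell-by-cell with acceptance probability equal to the truth HSI
and jittered within the cell.

The benchmark experiment (100×100 cells, 400 host and 200 parasite
presences, 10 iterations) runs in roughly two minutes on one CPU.
Of the validation metrics, the Boyce index is by far the noisiest: it
is estimated from roughly a hundred validation presences per iteration
over ten overlapping windows, and the tree ensembles' probability
surfaces concentrate near 0 and 1, leaving mid-range windows sparsely
populated. Its per-landscape mean typically falls between 0.4 and 0.75,
whereas AUC, TSS and the truth-recovery correlation are stable across
landscape seeds.
Truth recovery is measured as the Spearman correlation between the
truth surface and the mean surface of an ensemble trained on
host-truth samples with the full feature set; the min-combined dual
surface is reported alongside but carries an extra penalty from
combining two independently calibrated probability scales, which
affects ranks without affecting the binary maps.

**What passing does not show.** The synthetic landscape has no
observation bias, no spatially correlated sampling effort, no
label noise, stationary responses, and truly static soil; real
occurrence data violate all of these. Benchmarks here validate the
machinery (filters, CV, integration, attribution, accounting), not
field-level predictive skill.

## Degenerate inputs and numerical details

Constant predictor columns have undefined correlations and are dropped
with a warning. Single-class training or validation partitions skip the
iteration with a warning; a run with zero completed iterations is an
error. Precision is reported missing when nothing is predicted
positive; Boyce is missing when fewer than three windows are
informative. Points on nodata cells are dropped and counted. Exact
Shapley enumeration is refused above 15 features; the value function is
the interventional expectation over an explicit background sample, so
attributions obey efficiency (base + Σφ = prediction) to float
precision, and explanations of the four members are averaged pointwise.
All randomness flows from explicit integer seeds; identical seeds give
bit-identical outputs.
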