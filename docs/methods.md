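# Methods

## The analysis problem

A two-factor endpoint study: heterozygous CAG knock-in mice and wild-type
littermates are randomized at weaning to one of two high-fat diets (45% vs.
60% kcal fat) and profiled at ~8 months by LC-MS across six tissues, giving
one wide peak-area table per tissue (samples × metabolites, roughly 170–255
metabolites of known identity per tissue). Peak areas are non-negative;
zero encodes a non-detection, not a true zero. A companion cell-culture
experiment profiles immortalized striatal progenitor cells (three independent
cultures per genotype) and their spent growth media.

The questions the pipeline answers, per tissue: which metabolites respond to
genotype, to diet, or to their interaction; how those responses are
distributed and shared across tissues; whether metabolite profiles carry a
genotype-predictive signature; and whether lipid species accumulate
coordinately in mutant samples, both in tissue and in cells.

## Per-metabolite factorial inference

**Detection filter.** A metabolite enters the model only if it has at least
3 non-zero values in every arm (genotype × diet cell) of the design within
that tissue. The filter is idempotent and applied per tissue, so tested
denominators differ across tissues.

**Model.** For each retained metabolite, a linear model with genotype, diet
and genotype×diet terms is fitted to the detected (non-zero) values.
Sums of squares are sequential (Type I) in the order genotype → diet →
interaction by default; a marginal (Type II) option exists because the
convention is not dictated by the design. With the near-balanced 2×2 used
here the two differ only marginally (the option sweep in the test suite
bounds the drift in significance counts). Each term's F uses the full
model's residual mean square. Zero residual variance with a non-zero term
sum of squares reports F = +∞, p = 0 with a warning; an exactly constant
input is degenerate (NaN) rather than 0/0.

**Scale.** The default fit is on raw peak areas; a log-scale option is
recorded in the run manifest when used. Under multiplicative noise the
log scale is where the model is exactly specified: in simulation the
raw-scale F-test is mildly conservative (type-I error ≈ 0.047–0.048 at
α = 0.05 for log-SD 0.4–0.5) while the log-scale test is exact. The null
calibration checks therefore run on the log scale and additionally assert
that the raw default is never anti-conservative.

**Effect summaries.** Arm means are arithmetic means of detected values on
the raw scale. The genotype fold change is the mutant over wild-type ratio
of group means (marginal over diet), reported as a percent change; its sign
defines the direction. Diet uses the 60%-fat minus 45%-fat contrast. Under
the generator's log-normal model a planted mean multiplier m is recovered
consistently on this mean-ratio scale.

**FDR + fold-change gate.** For a single contrast (e.g. the cell-pellet
genotype comparison) metabolites pass at Benjamini–Hochberg q ≤ 0.10 AND a
symmetric 30% fold change (ratio ≥ 1.3 or ≤ 1/1.3). BH q-values come from
statsmodels; the test suite checks them against a brute-force step-up
enumeration.

**Enrichment ranks.** Between two tissues, metabolites are ranked by the
ratio of mean peak areas (means over all samples of the tissue, zeros
included as below-detection); species absent from the denominator tissue
rank ahead of all finite ratios, ordered by numerator mean, ties broken by
name.

## Cross-tissue landscape

"Nominally significant" is raw p < 0.05 with no multiplicity correction —
the landscape counts are descriptive, not inferential. Heterogeneity of the
significant proportion across tissues is the Pearson chi-square on the
2 × k contingency table (significant / not-significant × tissue) without
continuity correction, df = k − 1. The construction, not any particular
printed value, is the contract: the test suite verifies it against the
Σ(O−E)²/E formula on randomized tables. Pairwise overlap between tissues
counts metabolites significant in both; concordance compares effect
directions (genotype or diet); interaction overlaps carry no natural sign
and are counted undirected.

## Classifier signatures

**Tissue discriminant.** Multi-class LDA on all samples with tissue labels;
metabolites with pooled within-class variance below a relative tolerance
(default 1e-8) are dropped first, since they destabilize the within-class
scatter. Separation of the top-3 projections is summarized as the mean
silhouette under the true labels — a scalar stand-in for the visual
assessment the scatter-plot matrix invites. The control refits the LDA on
uniformly shuffled labels (the unshuffled labelling is never part of the
null); the empirical p is (1 + #{permuted ≥ observed}) / (n_perm + 1).
LDA fitted at p ≈ n overfits even under the null, which is exactly why the
permutation control, not an absolute score, is the reference.

**Genotype forest.** Bootstrap-aggregated classification trees with √p
candidate features per split — the classical random-forest construction,
implemented as bagged `DecisionTreeClassifier(max_features="sqrt")` so the
per-tree bootstrap indices are available through a public API. Defaults:
500 trees, unlimited depth. Each tree's out-of-bag samples provide the
error estimate; combining trees cumulatively gives the OOB error trajectory
(error among samples with at least one OOB vote), whose last entry is the
final OOB error. Missing values are left as zeros (non-detections carry
signal).

**Permutation importance.** For each metabolite in turn, its values are
shuffled across samples (one seeded permutation) and the final OOB error is
recomputed without refitting; the importance is the increase in error in
percentage points, ranked descending with name tie-breaks. The alternative
reading — permuting the class labels themselves — cannot produce
per-metabolite ranks, since it destroys all metabolites' signal at once.

## Lipid-accumulation statistics

**Descriptors.** A lipid species is identified by class (TAG, DAG, PC, LPC,
PE, LPE, SM, CE, FFA), total acyl carbons and total double bonds. Both the
compact `CX.Y.CLASS` form and the display form `CLASS X:Y` parse to the
same canonical descriptor, and cross-compartment matching (tissue vs. cell
tables) joins on the descriptor rather than the raw string. Parsing is
total: anything else is simply not a lipid.

**Ratio distribution.** Per species, the observed ratio is the mutant over
wild-type mean of detected values; species with a zero group mean are
excluded (logged). The center is the arithmetic mean of ratios (a
geometric-mean option exists, since ratios are asymmetric about 1). The
null reshuffles genotype labels preserving group sizes, recomputing the
center each time; p is the two-sided (1 + #{|permuted − 1| ≥
|observed − 1|}) / (n_perm + 1). With 3+3 replicates only C(6,3) = 20
balanced labelings exist, so sampled permutations revisit the identity
partition about once in 20 draws and the attainable p floor is ≈ 0.05; an
exhaustive-enumeration mode provides the exact null at such small n. The
16-vs-16 tissue design has an astronomically larger labeling space and
supports p ≤ 0.001 at 1000 permutations.

**Heatmap ordering.** Lipid rows are sorted ascending by genotype p-value
in a chosen tissue (ties by name); cells are per-tissue mutant/wild-type
ratios with nominal-significance flags. Sorting by the striatal p-value
concentrates elevated ratios at the top of the striatum column when a
striatal signature exists; re-sorting by another tissue's p-values destroys
that gradient — the property the tests assert.

**Quadrant concordance.** Species quantified in both tissue and cells are
placed in four quadrants by (tissue ratio vs. 1, cell ratio vs. 1) and the
counts tested against an even n/4 expectation (goodness-of-fit chi-square,
df 3; equal to 3n when all species fall in one quadrant). A ratio of
exactly 1 — measure-zero for continuous data — is assigned to the
"increased" side (logged); an exclusion mode exists.

## The synthetic-data generator

The generator emulates the study design so that every statistic above can
be exercised against known truth:

* **Cohort**: 16 mutant + 14 wild-type animals by default, diets assigned
  in balanced halves within genotype, six tissues, 250 metabolites of which
  40% are lipid species with realistic class/chain-length descriptors.
* **Values**: log-normal around per-(tissue, metabolite) baselines. The
  shared metabolite baseline is uniform on log-scale [10, 16] (peak areas
  ~2×10⁴–9×10⁶, the magnitude range of integrated LC-MS areas); each tissue
  adds an independent N(0, 1) offset per metabolite, so inter-tissue
  variation dominates intra-tissue variation (what the tissue discriminant
  measures). Multiplicative noise has log-SD 0.5 by default (~50% CV, a
  realistic untargeted-LC-MS scale); several tests use 0.3 for planted-
  effect conditions.
* **Non-detection**: independent thinning — each value is zeroed with
  probability 1 − detect_prob (default 0.95 detection). This is the
  simplest mechanism that exercises the ≥3-non-zero filter; real dropout is
  concentration-dependent, so detection-filter behaviour on real data is
  harsher for low-abundance species than these tests show.
* **Effects**: a multiplier m on a target set shifts the affected arm's
  log-location by log m — genotype effects act on the mutant arm, diet on
  the 60%-fat arm, interaction on the mutant×60%-fat cell only — making the
  planted mean ratio exactly m.
* **Cells**: n replicates per genotype (default 3), each with a paired
  pellet and media sample; genotype effects can target either compartment.
  Passing an explicit metabolite list shares species names with a tissue
  cohort for cross-compartment matching.
* **Reproducibility**: one RNG stream per table, seeded explicitly; the
  pipeline spawns per-stage seeds from a single root seed via
  `SeedSequence`, so adding a stage never perturbs earlier streams.

What passing tests on this generator do *not* show: behaviour under
chromatographic artefacts (retention drift, adducts, isotopes), correlated
metabolite panels (the generator draws species independently, so forest
importance on real, correlated lipid families will spread credit across
co-varying species), concentration-dependent dropout, or batch effects.

## Problem sizes used in the test suite

Simulation-based checks are scaled to keep the suite quick while retaining
the stated study conditions (arm sizes, noise scales, planted multipliers):
null calibration uses 200 seeds × 6 tissues × 250 metabolites; planted-
effect recovery uses 100 seeds of a 16+16 striatal cohort with 80
metabolites and 4+4 designated PC/CE species planted at 1.49×/1.54×;
forests in sweeps use 150–300 trees (500, the default, where a single
fit is examined). The acceptance script uses the same designs at 40–50
seeds per block.

## Known limitations

* Raw-scale F-tests are mildly conservative under multiplicative noise
  (measured above); use `log_transform=True` when calibrated type-I error
  matters more than mean-scale effect sizes.
* The OOB trajectory's early entries average over few voted samples and are
  noisy; only the plateau is interpretable. At small n the null OOB error of
  a majority-vote ensemble sits slightly above 0.5 on average (per-tree
  bootstrap class imbalance anti-correlates votes with the held-out label),
  so chance-level checks average several seeds rather than reading one run.
* Permutation importance shares one permutation per metabolite; for
  near-tied importances, rank order between adjacent metabolites is within
  permutation noise.
* The heterogeneity chi-square assumes independent metabolites within a
  tissue; correlated panels inflate its statistic on real data.
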