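# Methods

## Scope and data model

The package analyses aligned LC-MS feature tables (feature × sample
intensities with m/z and retention time) from a four-group rodent design:
healthy controls, a disease model group, and two treated groups. All
downstream statistics are computed from this matrix plus file-based
compound libraries, pathway definitions and interaction edge lists; no
stage queries an external service.

## Preprocessing

Missing intensities are imputed (default: half the feature's observed
minimum, the conventional "half-min" rule for values below the detection
limit; `zero` and `drop_feature` are alternatives). When at least two QC
injections are present, features whose relative standard deviation across
QC samples exceeds 30% are removed — a common instrument-stability screen;
without a QC series the filter is a no-op.

Pareto scaling is mean-centering followed by division by the square root
of the sample standard deviation (ddof = 1). It sits between plain
centering and unit-variance scaling: intense features keep more weight,
but not quadratically more. Constant features scale to zero columns and
are flagged rather than raising, so small hand-made tables survive.
Scaling excludes QC samples by default so pooled injections cannot shift
group means.

## PCA and OPLS-DA

PCA is the singular value decomposition of the centered matrix; per-
component R²X is the singular value's share of total sum of squares. The
`auto` component rule keeps components whose variance exceeds the mean
component variance — a deterministic, data-driven analogue of the
eigenvalue-above-average rule, chosen over row-wise cross-validation for
reproducibility and cost.

OPLS-DA follows the orthogonal projections to latent structures scheme:
repeatedly extract from X the component orthogonal to the (centered 0/1)
class vector yet capturing X-variance, deflate it, and finish with a
single predictive component on the filtered matrix. With zero orthogonal
components the model reduces exactly to one-component PLS1 — the test
suite verifies this against an independent NIPALS implementation.

* R²Y = 1 − RSS/TSS on the centered class vector.
* Q² = 1 − PRESS/TSS under k-fold cross-validation (default 7 folds,
  SIMCA's habit): folds are assigned round-robin per class after a seeded
  shuffle, the full orthogonal-plus-predictive fit is repeated on each
  training set, and held-out samples are predicted with the training-set
  class mean as offset.
* The number of orthogonal components under `auto` grows while
  cross-validated Q² improves by more than 0.01.

**VIP** is computed on the predictive component only: with the predictive
weights w unit-norm and all explained Y-variance on that one component,
VIPⱼ = √p·|wⱼ|, which makes the mean of VIP² exactly 1. Orthogonal
components explain no Y by construction and contribute nothing; users
comparing against software that reports a "total" VIP across all
components should expect small differences.

**S-plot** coordinates per feature: p(cov) = cov(xⱼ, t) and
p(corr) = p(cov)/(sd(xⱼ)·sd(t)) against the predictive score t.
Zero-variance features get p(corr) = 0 with a flag.

**Permutation validation** refits the whole model on label permutations
(default n = 200) with the observed model's component count and reports
the add-one estimate p = (#{Q²_perm ≥ Q²_obs} + 1)/(n + 1), bounded below
by 1/(n+1). Model validity rests on this test, not on the sign of Q²: on
structureless data the null Q² distribution centres slightly below zero
but lands above it in a sizeable minority of replicates (stratified folds
make cross-validation less punishing), so "Q² ≤ 0" is not a reliable null
signature, while the permutation p-value is calibrated by construction.

## Marker screening

A feature is a marker when VIP > 1.5 **and** the two-sided Welch t-test
between control and model gives p < 0.05, both strict, matching how
candidate metabolites are conventionally short-listed from an OPLS-DA
model. The t-test runs on log intensities: LC-MS intensities are
approximately log-normal, and at n = 6 per group the raw-scale test is
measurably conservative (null rejection ≈ 3.5% at α = 0.05) while the
log-scale test is calibrated; if non-positive values are present (e.g.
zero-imputed), the raw scale is used for that feature. No multiple-testing
correction enters selection — the screen mirrors the raw-p convention —
but Benjamini–Hochberg adjusted p-values are emitted alongside.

Fold change is mean(model)/mean(control) on raw intensities; the trend is
"up" iff FC > 1, with FC = 1 labelled "down" purely for determinism.
Recovery flags come from Welch tests of each treated group against the
model group: `ns`, `p05`, `p01`. The heatmap matrix z-scores each marker
across samples and orders both axes by average-linkage Euclidean
clustering with scipy's optimal leaf ordering for a deterministic layout.

Because VIP and the t-test p are functions of the same group contrast,
they are strongly positively dependent under the null: on data with no
planted effects the joint rule selects close to the t-test's own
false-positive count (≈ α per feature), not the product of the two rates.
The suite asserts this true behaviour rather than an independence-based
bound.

## Annotation

Monoisotopic masses are summed from CHNOPS atomic masses (C exactly 12,
H 1.0078250319, N 14.0030740052, O 15.9949146221, P 30.97376151,
S 31.97207069 Da). The charge carrier is the proton (1.00727646 Da), so
electron mass is implicit. Built-in adducts: [M+H]⁺, [M−H]⁻ and the
formate adduct [M+FA−H]⁻ (FA = CH₂O₂, 46.0054793 Da); the table is
user-extensible. A query matches a library compound when the signed ppm
error to the theoretical adduct m/z is within tolerance (default 10 ppm,
inclusive); candidates are ordered by |ppm|, isomeric entries are
returned as co-equal alternatives and never collapsed.

## Pathways

Over-representation is the hypergeometric upper tail P(X ≥ k) with the
universe defaulting to all library-annotated compounds (configurable) —
not all of KEGG, since no KEGG snapshot is bundled. The topology *impact*
of a hit set is the sum of relative betweenness centralities of matched
nodes over the pathway graph's total; pathways whose graph carries no
betweenness mass (edgeless, complete or tiny) fall back to uniform
centrality 1/|members| so the statistic remains defined and reduces to
hit coverage. Raw p-values drive ordering; BH-adjusted values are
reported.

## Network pharmacology

ADME screening keeps compounds with oral bioavailability ≥ 30% and
drug-likeness ≥ 0.18, unioned with an explicit literature whitelist; the
report separates rule-passers, whitelist-only entries and their overlap
(one bundled compound, GE26, both passes the rule and is whitelisted, so
the deduplicated union over the bundled table is 20).

The tripartite network merges three layers on upper-cased gene symbols:
a bipartite compound–target graph, a PPI layer built by one-hop expansion
around seed proteins, and a bipartite gene–metabolite graph. Candidate
targets are the intersection of compound targets with the protein side of
the other layers. Centralities are computed per connected component:
average shortest path length (hops, reachable nodes only) and betweenness
normalized by the component's (n−1)(n−2)/2 pair count — the convention of
common network-analysis tools. Isolated nodes are excluded with a
warning.

The R score min-max-normalises ASPL and the *reciprocal* of betweenness
over the candidate set and averages the two with equal weight; the
reciprocal reading is the one consistent with the bundled candidate table,
where the node holding both minimum ASPL and maximum betweenness scores
exactly 0. Candidates with zero betweenness are excluded (undefined
reciprocal). R is invariant to affine rescaling of all ASPLs and scalar
rescaling of all betweenness values, and always lies in [0, 1]. Ranking
is ascending by R with lexicographic tie-breaks. Note that the bundled
table's printed score column is consistent with the recomputed scores as
a sorted set (within the rounding of its 2-decimal ASPL and 5-decimal
betweenness inputs) but not row-by-row in the middle ranks, so per-gene
assertions are limited to the extremes.

## Synthetic data

`generate_feature_study` emulates the four-group design: per feature a
baseline log-mean is drawn (default N(10, 0.3²)), planted markers are
shifted by ±1.1 natural-log units in the model group (≈ 3× the log-scale
noise SD of 0.4 — a strong metabolic perturbation at n = 6), and treated
groups sit at model + recovery·(control − model) with recovery 0.8 by
default (substantial but incomplete normalisation; both treated groups
share the parameter, reflecting the near-equivalence of the two
preparations). Intensities are exp(Normal), one explicit seed drives all
randomness, and identical parameters give identical tables.

The baseline spread is kept moderate (0.3 log units) so planted markers
are comparably weighted by the scale-sensitive Pareto + VIP screen. Real
LC-MS data span orders of magnitude in baseline abundance, which makes
low-abundance markers systematically harder for this screen — a
limitation the generator deliberately does not emulate, so passing
recovery tests bound the method's behaviour under comparable-abundance
conditions only. Also not simulated: chromatographic peak shape, RT
drift, isotope patterns, correlated features, or batch effects; features
arrive "aligned" by construction.

`generate_interactome` builds two connected random communities (random
spanning tree plus extra edges up to the requested mean degree) joined
solely through one planted bridge node, with compound-target seeds in one
community and metabolite-gene seeds in the other. The bridge is therefore
a cut vertex with dominant betweenness — a known-answer instance for the
R-score ranking.

## Numerical choices and degenerate inputs

* All seeds are explicit; the pipeline derives per-stage seeds from one
  top-level seed via SHA-256 (kept below 2³¹).
* PCA/OPLS sign convention: each loading's largest-magnitude entry is
  positive (PCA); OPLS oracle comparisons allow a global sign flip.
* Strictness: marker thresholds are strict inequalities; the ppm gate is
  inclusive at the tolerance.
* Degenerate inputs: constant features are flagged and zeroed by scaling
  and by z-scoring; a feature entirely missing under half-min imputation
  is dropped with a warning; candidates with zero betweenness are excluded
  from ranking; equal ASPLs zero the first R term for all candidates.
* Problem sizes in the test suite (300-feature studies, 60-node
  interactomes, 20-seed repetitions, 99–200 permutations) were chosen to
  estimate each rate with adequate precision while keeping the suite
  quick to run.

## Known limitations

* Two-class OPLS-DA only; the four-group overview is handled by PCA.
* VIP covers the predictive component only (documented above).
* Annotation is exact-mass only: no MS/MS fragments, no retention-time
  prediction, so isobaric compounds within tolerance are inherently
  ambiguous and returned as alternatives.
* Pathway impact depends on the user-supplied pathway graphs; without
  edges it degrades to uniform centrality.
* The disease-gene layer is ingested from a user-provided list; no
  disease database ships with the package.
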