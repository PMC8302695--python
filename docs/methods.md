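# Methods

## Model

All modeling happens on a samples × variables matrix whose columns are
taxon activities/abundances, gene expression values and
environment/performance variables, each min-max rescaled to [0, 1]
(`(v − min)/(max − min)` per column). Rescaling is applied to the
*assembled* matrix, after core-taxon selection and column concatenation,
so one set of per-variable minima/maxima covers the whole model and can
invert predictions. A constant column is undefined under the transform;
it is mapped to 0 (matching the knockout convention that a silenced gene
has expression 0), a warning is logged, and `drop_zero_variance` removes
it before learning.

The joint model is a linear-Gaussian Bayesian network: a DAG in which
each node equals an intercept plus a weighted sum of its parents plus
Gaussian noise. The implied joint distribution is multivariate normal
with covariance `(I − B)⁻¹ Ω (I − B)⁻ᵀ` (B the coefficient matrix, Ω the
diagonal of residual variances); that closed form is used both for joint
conditional prediction and as the oracle the simulator is tested against.

### Structure search

Structures are scored with the Gaussian BIC, decomposable per node:
maximized log-likelihood of the node given its parents minus
`(k/2)·ln n` with `k = |parents| + 2` (intercept, coefficients,
variance). Families whose parameter count exceeds the sample count, or
whose parent covariance is numerically singular, score −∞ and are
thereby excluded. Scores are computed from the fold's mean vector and
MLE covariance via the normal equations and cached per
(child, parent-set), so an evaluation costs O(k³) independent of n.

The search is greedy hill climbing from the whitelist-only graph with
add/delete/reverse operators; a move must keep the graph acyclic, avoid
blacklisted edges and keep whitelisted ones. Ties are broken
lexicographically on (operator kind: add < delete < reverse, parent
name, child name), making the search fully deterministic. Because the
two orientations of a single new edge always tie exactly in score, plain
greedy ascent can enter a plateau oriented away from a collider and
stall; the search therefore ends with a short deterministic tabu phase —
when no operator improves the score, the best operator whose resulting
graph is not among the last 10 visited is applied anyway, for at most 5
non-improving steps, and the best graph seen overall is returned.
`tabu_off` reduces the search to plain greedy ascent; `restarts` adds
seeded random starting graphs (default 0: determinism first). For ≤5
nodes `exhaustive_search` enumerates every constraint-honoring DAG and
is the exact reference the greedy search is validated against
(label-DAG counts 1, 3, 25, 543, 29281 for n = 1…5).

### Constraints

`build_blacklist` encodes the biological inference direction as tier
ranks {fermenter, geobacter} < methanogen < output: every edge from a
strictly later to a strictly earlier rank is forbidden, as is every edge
leaving the output node. Fermenters and *Geobacter* form one class and
may point at each other; environment variables are unranked and connect
freely except that nothing leaves the output. `allow_within_tier=False`
additionally forbids edges inside one tier class.

### Parameters and prediction

Maximum-likelihood parameters are per-family OLS with residual variance
RSS/n (not n−k), floored at ε = 10⁻¹² so interpolating fits keep finite
likelihoods. Collinear parent sets raise an error naming the family.

Two prediction regimes exist because the forecasting step of a fitted
network can be read two ways: `parents` (default) evaluates each
target's node equation on the observed parent values; `joint` conditions
the implied multivariate normal on all non-target evidence. Reports
record which was used.

## Validation

Leave-one-out cross-validation relearns structure and parameters on each
n−1 subset and predicts the held-out sample. A column that is constant
within a training fold is dropped for that fold (logged) and predicted
as its constant. The null model predicts every target as its
training-fold mean — the same LOO discipline, no structure.

Metrics: Bray–Curtis similarity `1 − Σ|u−v|/Σ(u+v)` per held-out sample
between predicted and observed community on the normalized scale
(negative predictions are clipped to 0 first, logged; two all-zero
vectors compare as 1), averaged over samples; squared Pearson
correlation as R² (the regression coefficient of determination is
available as `kind="determination"`); and relative RMSE
`sqrt(mean squared error)/max(observed)`. Because "average R²" can pool
over variables or over all cells, the report exposes both aggregations.

## In-silico knockout

A scenario silences a named gene set (expression set to 0 in every
sample). The default experiment contrasts `complete`, `delta_IHT`
(hydrogen-metabolism genes) and `delta_DIET` (extracellular-electron-
transfer genes) and reports R²/relative RMSE of the output variable and
the R² drop versus `complete`. Default mode `retrain` silences the
columns, drops the resulting constants and reruns learning + LOO-CV —
silencing the measured expression levels naturally re-trains everything
downstream; `evidence_only` keeps the complete fold models and zeroes
only the silenced evidence at prediction time, for the reading in which
the network is fixed and only inputs change. Both are reported with
their mode; they agree on which mechanism matters more even where
magnitudes differ. "Significance" of a knockout effect is
operationalized as a sign test across seeded simulation replicates — an
artifact convention, not a claim about any particular dataset.

## Synthetic data generator

The generator defines the study conditions the package is exercised
under; its defaults are fixed and documented here.

**Template gene SEM.** Fifteen nodes: 4 fermenter genes (adhE-, dhaT-like
alcohol metabolism; hndC-, hyaB-like H₂ evolution), 4 *Geobacter* genes
(hox-, ech-like hydrogenases = IHT; omcF-, pilA-like EET machinery =
DIET), 3 methanogen genes (mvhA-like H₂ uptake = IHT; mvhB-like
polyferredoxin = DIET; hdrB-like core methanogenesis), one CH₄ output,
and 3 disconnected distractor genes. Substrate-driven background edges
carry weight 0.7; every edge on the hydrogen route carries `iht_effect`
(default 0.8) and every edge on the direct-transfer route carries
`diet_effect` (default 0.2); the hdrB→CH₄ edge carries 0.3. Exogenous
nodes are standard Gaussians; endogenous noise is `noise_sd` (default
0.2). With these defaults the population R² of CH₄ on its parents is
≈0.96, and the IHT route carries an order of magnitude more total path
weight (sum over directed paths of coefficient products) than the DIET
route — the contrast the knockout experiment is designed to detect.
Expression tables are sampled in topological order and each column is
*shifted* (never truncated) to non-negativity, so the linear-Gaussian
covariance structure stays exact and the closed-form SEM covariance
remains a valid oracle.

**Community generator.** 22 designated core taxa (named after the genera
that dominate such reactors: *Ethanoligenens*, *Clostridium*,
*Rhodocyclaceae*, *Desulfovibrio*, three *Geobacter*, three
*Methanobacterium*, plus generic OTUs) carry latent log-abundances with
baselines ln(0.008)–ln(0.04). Taxon–taxon dependencies are a seeded
chain: ~70% of core taxa track one earlier taxon with coefficient 0.9
and own noise 0.25 (latent correlation ≈0.85 — strong syntrophic partner
coupling), the rest are exogenous with sd 0.5; `independent_taxa=True`
removes all dependencies for no-self-deception checks. Activity (RNA)
equals the abundance latent plus a per-taxon activity offset (sd 0.3)
and sample noise (sd 0.2) — activity tracks the same community
realization, it is not an independent community. Compositional closure
exponentiates the latents and renormalizes against a remainder bucket
(mean 0.6, sd 0.05: the bucket aggregates the long tail of rare taxa and
is therefore statistically stable), so every row is non-negative and
sums to < 1. Distractor taxa have ~0.05% abundance and 20% occurrence,
failing both core rules with wide margin, so the designated core is
selected exactly. Nine environment variables (CH₄ production plus eight
reactor chemistry/performance variables) are linear in designated taxon
activities with noise scaled to `noise_sd` × signal sd.

**Counts.** Read counts for RPKM testing are multinomial per sample with
probabilities ∝ expression × gene length, reserving 10% of each library
(0.8–1.2 M reads) for unassigned reads, so totals never exceed the
library size.

All randomness flows from one integer seed through a spawned
`SeedSequence` hierarchy (separate streams for DNA, RNA, environment and
structure), so regenerating one table never perturbs another.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequencing count noise and overdispersion
(closure is the only compositional effect), taxonomic mis-assignment,
temporal reactor dynamics, nonlinear dose–response between gene
expression and methane, and unmeasured confounders. Results on this
generator demonstrate that the pipeline recovers the structures and
contrasts it assumes; they do not certify performance on data violating
linearity or Gaussianity.

## Problem sizes and replication

The shipped studies use: 100 seeded 3-node problems (n = 200) for
search-vs-enumeration agreement; 20 seeds at n = 1000 for parameter
recovery; 50 seeds at n = 200 for the knockout contrast (iht 0.8 / diet
0.2 / noise 0.2) with a distractor-silencing null scenario; 20 seeds at
n = 36 (a three-batch triplicate reactor design) for the community
null-model comparison, in dependent and independent variants. These
sizes give stable medians and sign tests while keeping a full run in the
minutes range on one CPU.

## Known limitations

Continuous variables only (no discretization, no discrete/multinomial
networks); no constraint-based (PC-style) learning or bootstrap model
averaging; fitted coefficients are predictive weights under the assumed
direction, not identified causal effects; the greedy search is exact
only where the exhaustive oracle can verify it (small graphs) and is
otherwise a well-tested heuristic; leave-one-out is the only
cross-validation scheme.
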