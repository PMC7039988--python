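# Methods

## The model

The unit of analysis is an undirected protein interaction observed through
the co-expression of its two coding genes. After discretizing each gene
into three levels, a pair of genes occupies one of nine ordered joint
states per sample. For a state observed N₀ times among N_C control samples
and N₁ times among N_T case samples, its case prevalence is

    q = (N₁/N_T) / (N₀/N_C + N₁/N_T)

q is the probability that a normalized observation of this state comes from
the case group: 0 when the state is control-exclusive, 1 when
case-exclusive, and exactly 0.5 when the normalized frequencies coincide.
It is invariant to proportional scaling of both groups' counts and obeys
group-swap antisymmetry (swapping the phenotype labels maps q to 1 − q);
both properties are enforced as tests. A state with neither group observing
it has no q (undefined, never passes).

An interaction is called differential when some state passes both criteria:

* **significance**: q < 0.10 (repressed in the case phenotype) or q > 0.90
  (activated) — strict inequalities;
* **frequency**: the state's normalized frequency exceeds 0.20 in at least
  one group, so that calls rest on a state actually prevalent somewhere
  rather than on a rare-state ratio.

Nine states yield up to nine q values per edge. The per-edge label comes
from the passing state with maximal |q − 0.5| (ties broken by larger
maximal frequency, then lowest state index); the full nine-state table is
retained in the output, and edges whose passing states disagree in
direction carry a `conflict` flag. No multiplicity correction is applied
across edges: the fixed cutoffs are the decision rule, and the null
behavior of the whole rule is characterized empirically instead (see
Calibration).

An optional detectability filter keeps only calls whose endpoint proteins
are pathologically detectable (high/medium/low) in the cohort under a
`both` (default) or `either` endpoint policy. Proteins absent from the
table are `unknown` and pass by default, so an incomplete annotation
shrinks nothing silently.

## Discretization

Levels are defined per gene from the pooled cohort (control + case
together): z = (x − mean)/SD, level 1 if z > t, −1 if z < −t, else 0, with
t = 1.0. Pooling keeps both groups' state counts on a common scale, which
the q statistic implicitly assumes; standardizing per gene removes
between-gene scale differences in FPKM-type data. A quantile rule
(cutoffs 0.25/0.75, linear-interpolation quantiles, ties to the middle
level) is provided as an alternative; the rule and its parameters are
recorded in the output's `method_tag`. Zero-variance genes map to
all-average with a warning. The reference population (per gene across
samples, rather than per sample across genes) is the single most
result-sensitive free choice in the pipeline and is deliberately explicit
in the API.

## Network, hubs, modules

The differential network spans exactly the proteins incident to at least
one dPPI. Topology metrics follow network-analyzer conventions: mean local
clustering; diameter and characteristic path length on the largest
connected component (the component policy is recorded in the report);
degree centralization Σ(k_max − kᵢ)/((n−1)(n−2)); average degree; and
heterogeneity defined as the coefficient of variation SD/mean of the degree
distribution. An empirical null is available from either G(n, m) draws or
degree-preserving edge swaps (10·|E| attempted swaps), with two-sided
plug-in p-values (1 + #extreme)/(n_reps + 1).

"Hub" has no canonical quantification, so both a rank rule (default: top
10% of nodes by degree, ties at the cutoff included, minimum degree 2) and
an absolute rule (degree ≥ 5) are exposed. Hubs are the differentially
interacting proteins (DIPs): Class I when every incident differential edge
is repressed, Class II when every one is activated, and `mixed` otherwise —
mixed is reported as its own class rather than forced into I/II, since the
pure definitions do not cover it.

A DIP-centered module is the star around its center: the center, its
neighbors, and the center-incident edges only (partner–partner edges are
excluded; modules of adjacent DIPs overlap). Module coherence is a
Kruskal–Wallis test comparing, across the module's edges, the deciding
state's case frequencies against its control frequencies. With two groups
this reduces to a Mann–Whitney-equivalent rank test — stated explicitly,
and verified against `scipy.stats.kruskal` in the tests. Modules with
fewer than two edges are untestable and flagged, not given a p-value.

## Diagnostic evaluation

Each repetition draws 30 samples per class, z-scores the module genes
within the draw, fits a PCA, and keeps the smallest number of components
(capped at 2) whose cumulative explained variance reaches 80% — when even
two components fall short, two are used and the result is flagged. Samples
are classified by leave-one-out nearest class centroid in the retained
component space; this is the minimal parameter-free decision rule
consistent with separating classes in a PC plot. Confusion counts are
pooled over repetitions *before* forming sensitivity, specificity and the
DOR (pooling avoids averaging ratios); a Haldane correction of 0.5 per cell
is applied when any pooled cell is zero, and flagged. Repetitions stop once
the running means of sensitivity and specificity both move less than 0.005
(configurable) between successive blocks of ten, or at the cap of 200.

## Prognostic evaluation

A multivariate Cox proportional-hazards model (lifelines) is fitted on the
module genes, z-scored across subjects with clinical records; zero-variance
genes are dropped with a warning, and a non-converging fit (e.g. complete
separation) is retried with an L2 penalty of 0.1 and flagged. The
prognostic index PI = Σᵢ βᵢxᵢ is the fitted linear predictor. Subjects are
split at the median PI (a configurable quantile; ties go low), compared by
Kaplan–Meier curves and the two-group log-rank test, and summarized by the
hazard ratio of a univariate Cox fit on the high-vs-low indicator — the
hazard ratio is reported as high-vs-low without reciprocal flipping.
Screening thresholds elsewhere in the pipeline use log-rank p < 0.05 with
HR > 1.3, and sensitivity = specificity ≥ 0.90 (DOR ≥ 81) on the
diagnostic side.

## Pan-cohort comparison

dPPI sets are compared order- and label-insensitively by default (an edge
activated in one cohort and repressed in another still marks the same
rewired interaction); a label-sensitive mode exists behind a flag. Reports:
pairwise Jaccard matrix, prevalence histogram (edges present in exactly k
cohorts; its total equals the union size), and per-cohort specificity
(count and fraction of private edges). Specificity denominators count
edges, not proteins.

## Synthetic data

The generator provides the conditions under which the pipeline is
validated:

* **Interactome**: preferential attachment (Barabási–Albert, topped up or
  trimmed to an exact edge count with degree-proportional additions) for a
  scale-free degree distribution, or uniform G(n, m). Default 150 proteins,
  200 edges.
* **Expression**: background genes i.i.d. log-normal
  (exp(μ_g + 0.5·N(0,1)), μ_g ~ N(log 10, 0.5)) identically in both groups
  — FPKM distributions are right-skewed. For each planted activated edge, a
  fixed subset of round(effect · n_case) case samples is pushed so both
  endpoint genes discretize to level 1 there; repressed edges mirror this
  in the control group. Planting operates in discretized-state space and
  maps back to values: pushed values are raised iteratively until they
  z-score above t in the pooled distribution *including the push itself*,
  so the planted [1 1] frequency survives default discretization by
  construction. This couples generator and discretizer deliberately. A
  planted level cannot hold ≥ ~half of all pooled samples (a point mass at
  pooled fraction p has z = √((1−p)/p) ≤ t at p ≥ 0.5 for t = 1), so the
  generator rejects requests where the pushed subset would reach 45% of
  the pooled cohort. Defaults: 20 activated + 20 repressed edges, effect
  0.6, 100 control / 100 case samples.
* **Ground truth**: planted edges are chosen gene-disjoint, low-degree
  edges first (optionally one activated star of up to 5 edges around a
  common center, recorded as a planted DIP). `planted_null` contains only
  edges fully disjoint from every planted gene: an edge merely sharing an
  endpoint with a planted edge inherits a genuine marginal state shift and
  is neither planted signal nor clean null, so it belongs to no truth set.
* **Survival**: exponential times with hazard baseline · exp(Σ βᵢzᵢ)
  (baseline 1/1000 per day), independent exponential censoring whose rate
  is solved by bisection so the expected censored fraction matches the
  requested rate (default 0.2).
* **Pathology**: not-detected with probability 0.1, otherwise uniform over
  high/medium/low.

What the generator does *not* emulate: batch effects, tumor purity,
subtype structure, gene–gene background correlation, or realistic
library-size artifacts. Passing the recovery tests therefore shows the
inference machinery is correct under the model's own assumptions, not that
the defaults are optimal for any particular real cohort.

## Calibration and validation (computed by the test suite)

* Null calibration: with both groups drawn from one distribution (200
  independent edges, 20 replicates), the fraction of states passing the q
  thresholds plus frequency gate is below 2% at n = 20 per group and
  decreases with n over {20, 50, 100}.
* Parameter recovery: at the default planted conditions, median recall of
  planted edges ≥ 0.9 with label accuracy ≥ 0.95 and false calls among
  clean-null edges ≤ 0.05 across 10 seeds.
* Topology metrics agree with an independent Floyd–Warshall/triangle-count
  oracle on the full non-isomorphic graph atlas up to 7 nodes plus sampled
  8-node graphs.
* Survival stack: Kaplan–Meier equals the empirical survivor function
  without censoring; a planted two-fold hazard ratio at n = 300 is
  recovered within [1.5, 2.6] with log-rank p < 0.05 in ≥ 90% of 50 seeded
  replicates.

Problem sizes in the suite (hundreds of genes/edges, ≤ 200 samples,
tens of replicates) are chosen as the smallest scales at which these
statistical checks are stable.

## Numerical and degenerate-input policy

* Undefined q (state never observed): skipped, never passes.
* Zero-variance genes: all-average levels (discretize), dropped (Cox),
  rejected when nothing remains (diagnostics).
* Empty pathology table: filter is the identity, with a warning.
* Jaccard of two empty sets: 0, with a warning.
* Graphs: single-node path metrics are null; centralization needs n ≥ 3;
  path metrics on disconnected graphs use the largest component and say so.
* Missing expression values: the gene is dropped at ingestion (not the
  sample) because state-count conservation requires every retained gene
  observed in every sample.
* Gene identifiers are uppercased and matched exactly; alias resolution is
  a data-preparation concern, out of scope.

## Known limitations

* The three-level cutoffs are a modeling choice; results are sensitive to
  the reference population (per-gene vs per-sample) and to t.
* DIP classes depend on the hub rule; absolute-degree and rank rules can
  disagree on sparse networks.
* The q cutoffs control the per-state false-call rate only empirically;
  there is no closed-form error guarantee across correlated edges sharing
  a gene.
* Diagnostic repetitions subsample with replacement across repetitions
  (draws overlap), so the stopping rule measures stability of the running
  mean, not independent-replicate variance.
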