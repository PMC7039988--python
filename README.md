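# diffinteractome

Differential interactome analysis for two-phenotype expression cohorts.

Protein–protein interactions (PPIs) are not constant across conditions: an
interaction that is active in healthy tissue can be lost in a tumor, and new
co-expression patterns can appear. `diffinteractome` estimates this rewiring
from bulk RNA-seq. Given a genes × samples expression matrix (FPKM-like),
a control/case label per sample and an undirected PPI edge list, it:

1. discretizes each gene into three levels (−1 low, 0 average, 1 high);
2. for every interaction, counts the nine ordered joint states
   [0 0], [0 1], [0 −1], [1 0], [1 1], [1 −1], [−1 0], [−1 1], [−1 −1]
   separately in the control group (N₀ of N_C samples) and case group
   (N₁ of N_T samples);
3. scores each state's case prevalence with

       q = (N₁/N_T) / (N₀/N_C + N₁/N_T)

   and calls an interaction **repressed** in the case phenotype when some
   state has q < 0.10, or **activated** when q > 0.90, provided the state's
   normalized frequency exceeds 20% in at least one group — these are the
   differential PPIs (dPPIs), optionally filtered by per-protein pathology
   detectability (high/medium/low vs not detected);
4. builds the differential network, reports its topology (clustering
   coefficient, diameter, centralization, characteristic path length,
   average neighbors, degree heterogeneity), identifies hub proteins
   (differentially interacting proteins, DIPs; Class I = all incident edges
   repressed, Class II = all activated) and extracts DIP-centered modules
   tested by a two-group Kruskal–Wallis comparison of edge frequencies;
5. evaluates each module as a biomarker: diagnostically via repeated
   subsampled PCA with leave-one-out nearest-centroid classification
   (sensitivity, specificity, diagnostic odds ratio
   DOR = (sens/(1−sens))·(spec/(1−spec))), and prognostically via a Cox
   prognostic index PI = Σᵢ βᵢxᵢ, median-split risk groups, Kaplan–Meier
   curves, log-rank test and hazard ratio;
6. compares dPPI sets across cohorts (Jaccard index, prevalence histogram,
   per-cohort specificity rates).

A synthetic-data module generates complete ground-truthed inputs — a
scale-free interactome, a two-group expression matrix with planted
differential co-expression states, pathology and survival tables — so the
whole pipeline is testable end to end without external downloads.

Intended users: computational/systems biologists studying condition-specific
network rewiring (typically tumor vs matched normal) who have their own
expression and interaction data.

## Worked example

```python
from diffinteractome import synthetic_data as synth
from diffinteractome.discretize import discretize_expression
from diffinteractome.diffcore import (
    count_states, call_differential, apply_pathology_filter)
from diffinteractome.netanalysis import (
    build_network, topology, identify_dips, extract_modules, score_modules)
from diffinteractome.evaluation import (
    pca_diagnostics, fit_cox_pi, stratify_and_test)

inter, study, pathology, clinical, truth = synth.generate_cohort(seed=1)
disc = discretize_expression(study)                 # 3-level codes, |z| > 1
counts = count_states(disc, study.phenotype, inter)  # 9-state tallies
calls = call_differential(counts)                   # q < 0.10 / q > 0.90
dppis = apply_pathology_filter(calls, pathology, "SYN")
net = build_network(dppis)
rep = topology(net)
dips = identify_dips(net)                           # top-decile hubs
modules = score_modules(extract_modules(net, dips))
mod = next(m for m in modules if m.center.protein in truth.planted_dips)
diag = pca_diagnostics(study, mod.proteins, seed=1)
prog = stratify_and_test(fit_cox_pi(study, clinical, mod.proteins), clinical)
```

Output:

```
dPPIs: 119 (51 activated, 68 repressed)
network: 101 proteins, 119 interactions, heterogeneity 0.82
DIPs: 18; planted hub recovered: True
module G0008: kw_p=0.0126, sens=0.63, spec=0.96, DOR=37
prognosis: log-rank p=8.58e-05, HR=2.50
```

Reading the numbers: of the 200 simulated interactions, 119 pass the q and
frequency criteria plus the detectability filter — more than the 40 planted
ones, because a planted gene's marginal shift genuinely changes the joint
states of *all* its interactions, not just the planted one. The network is
hub-dominated (heterogeneity, SD/mean of degree, 0.82), the planted hub is
among the 18 DIPs, and its module separates the phenotypes (Kruskal–Wallis
p = 0.013), classifies case samples with specificity 0.96 at sensitivity
0.63 (DOR 37), and splits subjects into risk groups with a 2.5-fold hazard
difference (log-rank p < 10⁻⁴) — the survival signal was planted on the
hub-adjacent genes by the generator.

The same pipeline is available from a shell:

```
diffint simulate --seed 1 --out sim/
diffint run --expression sim/expression.tsv --phenotype sim/phenotype.tsv \
    --interactions sim/interactions.tsv --pathology sim/pathology.tsv \
    --clinical sim/clinical.tsv --out run/
diffint compare runA/dppi.tsv runB/dppi.tsv --out compare.json
```

## Layout

| module | contents |
| --- | --- |
| `io_formats` | TSV/SIF readers and writers, identifier hygiene |
| `discretize` | three-level discretization, 9-state joint alphabet |
| `diffcore` | state counting, q statistic, dPPI calling, pathology filter |
| `netanalysis` | differential network, topology, DIPs, modules, random nulls |
| `pancancer` | cross-cohort Jaccard/prevalence/specificity |
| `evaluation` | PCA diagnostics, Cox/KM/log-rank prognostics, ORA |
| `synthetic_data` | ground-truthed generators for every input |
| `cli` | `diffint` subcommands: simulate, run, compare, evaluate |

See `docs/methods.md` for the modeling choices and their rationale.
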