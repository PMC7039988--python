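"""Ground-truthed synthetic inputs for the full pipeline.

The generator emulates the statistical structure the analysis assumes:

* a scale-free (preferential-attachment) or uniform-random interactome;
* a two-group FPKM-like expression matrix — background genes i.i.d.
  log-normal in both groups, with a chosen set of "planted" interactions
  whose [1 1] joint co-expression state is driven to a target frequency
  (the effect size) in one phenotype group only: in the case group for
  activated edges, in the control group for repressed edges;
* a per-protein pathology detectability table;
* right-censored survival times whose hazard follows a Cox model on
  chosen risk genes.

Planting operates in discretized-state space and maps back to continuous
values: the pushed samples' values are raised iteratively until they are
guaranteed to discretize to the high level under the default pooled
z-score rule, whatever shift the planting itself induces in the pooled
mean and SD. This couples generator and discretizer deliberately.

Edges that merely share an endpoint with a planted edge inherit a genuine
(if weaker) state shift from that gene's marginal change; they are
therefore excluded from ``planted_null``, which contains only edges fully
disjoint from every planted gene.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import numpy as np

from .datatypes import (
    CASE,
    CONTROL,
    ClinicalTable,
    ExpressionStudy,
    GroundTruth,
    InteractionSet,
    PathologyTable,
    canonical_edge,
)

logger = logging.getLogger(__name__)


def _gene_name(i: int) -> str:
    return f"G{i:04d}"


def generate_interactome(
    n_proteins: int,
    n_edges: int,
    model: str = "scale_free",
    seed: int | None = None,
) -> InteractionSet:
    """Simple undirected interactome with exactly ``n_edges`` edges.

    ``scale_free`` grows a preferential-attachment graph and then adds or
    removes edges (preferentially for additions) to hit the exact edge
    count; ``gnm`` draws a uniform G(n, m) graph.
    """
    max_edges = n_proteins * (n_proteins - 1) // 2
    if not (0 <= n_edges <= max_edges):
        raise ValueError(f"n_edges={n_edges} infeasible for {n_proteins} proteins")
    rng = np.random.default_rng(seed)

    if model == "gnm":
        g = nx.gnm_random_graph(n_proteins, n_edges, seed=int(rng.integers(2**31)))
    elif model == "scale_free":
        m_attach = max(1, round(n_edges / max(1, n_proteins)))
        m_attach = min(m_attach, n_proteins - 1)
        g = nx.barabasi_albert_graph(
            n_proteins, m_attach, seed=int(rng.integers(2**31))
        )
        # trim or preferentially top up to the exact edge count
        while g.number_of_edges() > n_edges:
            edges = sorted(g.edges)
            u, v = edges[rng.integers(len(edges))]
            g.remove_edge(u, v)
        nodes = sorted(g.nodes)
        while g.number_of_edges() < n_edges:
            deg = np.array([g.degree(v) + 1 for v in nodes], dtype=float)
            p = deg / deg.sum()
            u, v = rng.choice(nodes, size=2, replace=False, p=p)
            if not g.has_edge(u, v):
                g.add_edge(u, v)
    else:
        raise ValueError(f"unknown interactome model: {model!r}")

    return InteractionSet(
        (_gene_name(a), _gene_name(b)) for a, b in g.edges
    )


def _plant_high(
    values: np.ndarray,
    pushed: np.ndarray,
    t: float,
    rng: np.random.Generator,
    max_iter: int = 300,
) -> np.ndarray:
    """Raise ``values[pushed]`` until they z-score above ``t`` in the pooled
    (self-including) distribution; the push is multiplicative so values stay
    positive and log-normal-shaped."""
    v = values.copy()
    m, s = v.mean(), v.std()
    v[pushed] = m + (t + 1.2 + 0.4 * np.abs(rng.standard_normal(pushed.sum()))) * max(
        s, 1e-9
    )
    for _ in range(max_iter):
        m, s = v.mean(), v.std()
        z = (v - m) / s
        bad = pushed & (z <= t)
        if not bad.any():
            return v
        v[bad] *= 1.2
    raise RuntimeError("state planting failed to converge")  # pragma: no cover


def generate_expression(
    interactome: InteractionSet,
    n_activated: int = 20,
    n_repressed: int = 20,
    effect: float = 0.6,
    n_control: int = 100,
    n_case: int = 100,
    noise_sd: float = 0.5,
    mean_log_fpkm: float = math.log(10.0),
    hub_degree: int | None = None,
    t: float = 1.0,
    cohort_id: str = "SYN",
    seed: int | None = None,
) -> tuple[ExpressionStudy, GroundTruth]:
    """Two-group expression matrix with planted differential interactions.

    Background values for gene g are i.i.d. log-normal,
    ``exp(mu_g + noise_sd * N(0,1))`` with ``mu_g ~ N(mean_log_fpkm, 0.5)``,
    identical in both groups. For each planted activated edge, a fixed
    subset of ``round(effect * n_case)`` case samples is pushed so both
    endpoint genes discretize to level 1 there, making the [1 1] state
    attain frequency ~``effect`` in cases while controls stay at background;
    repressed edges are the mirror image (pushed in controls). With
    ``hub_degree`` set, up to that many activated edges share a common
    center pushed on one common sample subset, planting a known hub
    (recorded in ``planted_dips``).
    """
    if not (0 < effect <= 1):
        raise ValueError(f"effect must be in (0, 1], got {effect}")
    edges = sorted(interactome.edges)
    if n_activated + n_repressed > len(edges):
        raise ValueError(
            f"cannot plant {n_activated + n_repressed} edges among {len(edges)}"
        )
    # a z>t level cannot hold a majority of the pooled samples: a point mass
    # at pooled fraction p has z = sqrt((1-p)/p), which drops below t=1 as p
    # approaches 0.5, so planting saturates; refuse clearly infeasible asks
    n_total = n_control + n_case
    for n_grp, n_edges_grp in ((n_case, n_activated), (n_control, n_repressed)):
        if n_edges_grp and round(effect * n_grp) / n_total >= 0.45:
            raise ValueError(
                "planted level would cover >=45% of all pooled samples; "
                "reduce effect or rebalance the group sizes"
            )
    rng = np.random.default_rng(seed)

    genes = sorted(interactome.proteins())
    gidx = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    n_samples = n_control + n_case
    samples = [f"C{i:04d}" for i in range(n_control)] + [
        f"T{i:04d}" for i in range(n_case)
    ]
    phenotype = {s: (CONTROL if s.startswith("C") else CASE) for s in samples}
    control_cols = np.arange(n_control)
    case_cols = np.arange(n_control, n_samples)

    mu = mean_log_fpkm + 0.5 * rng.standard_normal(n_genes)
    values = np.exp(mu[:, None] + noise_sd * rng.standard_normal((n_genes, n_samples)))

    # -- choose planted edges ---------------------------------------------
    def draw_pushed(cols: np.ndarray) -> np.ndarray:
        k = int(round(effect * len(cols)))
        mask = np.zeros(n_samples, dtype=bool)
        mask[rng.choice(cols, size=max(k, 1), replace=False)] = True
        return mask

    # gene -> (pushed mask) once constrained; a gene may join several planted
    # edges only with the identical pushed subset (hub planting)
    constraint: dict[str, np.ndarray] = {}
    activated: list[tuple[str, str]] = []
    repressed: list[tuple[str, str]] = []
    planted_dips: set[str] = set()

    degree: dict[str, int] = {}
    for a, b in edges:
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
    # plant on peripheral (low-degree) edges first: keeps the bulk of the
    # interactome fully disjoint from planted genes, so planted_null stays large
    shuffled = [edges[i] for i in rng.permutation(len(edges))]
    order = sorted(shuffled, key=lambda e: degree[e[0]] + degree[e[1]])

    if hub_degree and n_activated >= 2:
        # smallest node that can host the hub, so it does not monopolize edges
        candidates = [g for g in sorted(degree) if degree[g] >= hub_degree]
        center = min(candidates, key=lambda g: degree[g]) if candidates else max(
            sorted(degree), key=lambda g: degree[g]
        )
        want = min(hub_degree, degree[center], n_activated)
        if want >= 2:
            hub_mask = draw_pushed(case_cols)
            constraint[center] = hub_mask
            planted_dips.add(center)
            for e in order:
                if len(activated) >= want:
                    break
                if center in e:
                    partner = e[0] if e[1] == center else e[1]
                    if partner not in constraint:
                        constraint[partner] = hub_mask
                        activated.append(e)

    for e in order:
        a, b = e
        if e in activated or a in constraint or b in constraint:
            continue
        if len(activated) < n_activated:
            mask = draw_pushed(case_cols)
            constraint[a] = mask
            constraint[b] = mask
            activated.append(e)
        elif len(repressed) < n_repressed:
            mask = draw_pushed(control_cols)
            constraint[a] = mask
            constraint[b] = mask
            repressed.append(e)
        if len(activated) >= n_activated and len(repressed) >= n_repressed:
            break
    if len(activated) < n_activated or len(repressed) < n_repressed:
        raise ValueError(
            "interactome too entangled to plant the requested number of "
            "gene-disjoint edges"
        )

    for gene, mask in constraint.items():
        values[gidx[gene]] = _plant_high(values[gidx[gene]], mask, t, rng)

    planted_genes = set(constraint)
    planted_edges = set(activated) | set(repressed)
    planted_null = {
        e
        for e in edges
        if e not in planted_edges and not (set(e) & planted_genes)
    }

    study = ExpressionStudy(
        cohort_id=cohort_id,
        genes=genes,
        samples=samples,
        values=values,
        phenotype=phenotype,
    )
    truth = GroundTruth(
        planted_activated={canonical_edge(*e) for e in activated},
        planted_repressed={canonical_edge(*e) for e in repressed},
        planted_null=planted_null,
        planted_dips=planted_dips,
        survival_beta={},
        generator_params={
            "n_activated": n_activated,
            "n_repressed": n_repressed,
            "effect": effect,
            "n_control": n_control,
            "n_case": n_case,
            "noise_sd": noise_sd,
            "hub_degree": hub_degree,
            "t": t,
            "seed": seed,
        },
    )
    return study, truth


def generate_clinical(
    study: ExpressionStudy,
    risk_genes: list[str],
    betas: list[float] | np.ndarray,
    baseline_hazard: float = 1.0 / 1000.0,
    censor_rate: float = 0.2,
    group: str = CASE,
    seed: int | None = None,
) -> ClinicalTable:
    """Exponential survival times with a Cox-model hazard on risk genes.

    Subject hazards are ``baseline_hazard * exp(sum_i beta_i * z_i)`` with
    z the gene's expression standardized across the chosen subjects
    (``group`` = "case" by default, or "all"). Censoring is independent
    exponential, its rate solved numerically so the expected censored
    fraction matches ``censor_rate``.
    """
    if not (0 <= censor_rate < 1):
        raise ValueError(f"censor_rate must be in [0, 1), got {censor_rate}")
    missing = [g for g in risk_genes if g.upper() not in set(study.genes)]
    if missing:
        raise KeyError(f"risk genes not in study: {missing}")
    betas = np.asarray(betas, dtype=float)
    if len(betas) != len(risk_genes):
        raise ValueError("betas must align with risk_genes")
    rng = np.random.default_rng(seed)

    if group == "all":
        subjects = list(study.samples)
    else:
        subjects = [s for s in study.samples if study.phenotype[s] == group]
    cols = [study.samples.index(s) for s in subjects]
    gi = study.gene_index()
    rows = [gi[g.upper()] for g in risk_genes]
    x = study.values[np.ix_(rows, cols)]
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=1, keepdims=True)) / sd

    hazards = baseline_hazard * np.exp(betas @ z)
    times = rng.exponential(1.0 / hazards)

    if censor_rate == 0:
        events = np.ones(len(subjects), dtype=int)
        observed = times
    else:
        # expected censored fraction for exponential censoring at rate c:
        # mean_i c / (c + hazard_i); solve for c by bisection
        def frac(c: float) -> float:
            return float(np.mean(c / (c + hazards)))

        lo, hi = 1e-12, 1e6 * baseline_hazard
        while frac(hi) < censor_rate:
            hi *= 10
        for _ in range(200):
            mid = math.sqrt(lo * hi)
            if frac(mid) < censor_rate:
                lo = mid
            else:
                hi = mid
        c = math.sqrt(lo * hi)
        censor_times = rng.exponential(1.0 / c, size=len(subjects))
        events = (times <= censor_times).astype(int)
        observed = np.minimum(times, censor_times)

    observed = np.maximum(observed, 1e-6)  # strictly positive days
    return ClinicalTable(
        records={s: (float(t), int(e)) for s, t, e in zip(subjects, observed, events)}
    )


def generate_pathology(
    proteins: list[str],
    cohort_id: str,
    p_not_detected: float = 0.1,
    seed: int | None = None,
) -> PathologyTable:
    """Random per-protein detectability levels for one cohort."""
    if not (0 <= p_not_detected <= 1):
        raise ValueError(f"p_not_detected must be in [0, 1], got {p_not_detected}")
    rng = np.random.default_rng(seed)
    records = {}
    detectable = ["high", "medium", "low"]
    for p in proteins:
        if rng.random() < p_not_detected:
            level = "not_detected"
        else:
            level = detectable[rng.integers(3)]
        records[(p, cohort_id)] = level
    return PathologyTable(records)


def generate_cohort(
    n_proteins: int = 150,
    n_edges: int = 200,
    n_activated: int = 20,
    n_repressed: int = 20,
    effect: float = 0.6,
    n_control: int = 100,
    n_case: int = 100,
    noise_sd: float = 0.5,
    hub_degree: int | None = 5,
    p_not_detected: float = 0.1,
    survival_beta: float = 0.7,
    censor_rate: float = 0.2,
    cohort_id: str = "SYN",
    seed: int | None = None,
):
    """One full synthetic cohort: interactome, expression, pathology, clinical.

    Survival hazards depend on the genes of the first planted activated
    edges (coefficient ``survival_beta`` each, up to 3 genes), so the
    planted modules genuinely carry prognostic signal.

    Returns ``(interactome, study, pathology, clinical, truth)``.
    """
    rng = np.random.default_rng(seed)
    seeds = rng.integers(2**31, size=4)
    interactome = generate_interactome(
        n_proteins, n_edges, model="scale_free", seed=int(seeds[0])
    )
    study, truth = generate_expression(
        interactome,
        n_activated=n_activated,
        n_repressed=n_repressed,
        effect=effect,
        n_control=n_control,
        n_case=n_case,
        noise_sd=noise_sd,
        hub_degree=hub_degree,
        cohort_id=cohort_id,
        seed=int(seeds[1]),
    )
    pathology = generate_pathology(
        sorted(interactome.proteins()), cohort_id, p_not_detected, seed=int(seeds[2])
    )
    risk_genes = sorted({g for e in sorted(truth.planted_activated) for g in e})[:3]
    betas = [survival_beta] * len(risk_genes)
    clinical = generate_clinical(
        study, risk_genes, betas, censor_rate=censor_rate, seed=int(seeds[3])
    )
    truth.survival_beta = {g: survival_beta for g in risk_genes}
    truth.generator_params.update(
        {
            "n_proteins": n_proteins,
            "n_edges": n_edges,
            "p_not_detected": p_not_detected,
            "censor_rate": censor_rate,
            "master_seed": seed,
        }
    )
    return interactome, study, pathology, clinical, truth
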