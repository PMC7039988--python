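"""Differential-network construction, topology, hubs (DIPs) and modules.

The differential network is the undirected simple graph spanned by the
dPPIs, each edge carrying its label (activated/repressed) and deciding-state
q. Topology metrics follow the usual network-analyzer conventions:

* degree centralization  sum_i (k_max - k_i) / ((n-1)(n-2)), 1 for a star
* heterogeneity          SD(degree) / mean(degree) (population SD)
* path-based metrics     computed on the largest connected component,
                         recorded in the report

Hubs of the differential network are the differentially interacting
proteins (DIPs): Class I if all their incident differential edges are
repressed in the case phenotype, Class II if all activated, "mixed"
otherwise. Each DIP with its interacting partners and incident dPPIs forms
a DIP-centered module, whose coherence is tested by a two-group
Kruskal-Wallis comparison of the edges' case vs control deciding-state
frequencies (with two groups this is equivalent to a Mann-Whitney test).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .diffcore import DifferentialCall

logger = logging.getLogger(__name__)


def build_network(dppis: list[DifferentialCall]) -> nx.Graph:
    """Graph over exactly the proteins incident to at least one dPPI."""
    g = nx.Graph()
    for call in dppis:
        if call.label == "none":
            raise ValueError("build_network expects labeled calls only")
        a, b = call.interaction
        g.add_edge(
            a,
            b,
            label=call.label,
            q=call.deciding_q(),
            state=call.deciding_state,
            call=call,
        )
    return g


@dataclass
class TopologyReport:
    """The eight standard differential-network topology metrics."""

    n_nodes: int
    n_edges: int
    clustering_coefficient: float
    diameter: float | None
    centralization: float | None
    characteristic_path_length: float | None
    avg_neighbors: float
    heterogeneity: float | None
    component_policy: str = "largest_connected_component"

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def topology(network: nx.Graph) -> TopologyReport:
    """Compute the topology report; path metrics use the largest component."""
    n = network.number_of_nodes()
    if n == 0:
        raise ValueError("topology of an empty graph is undefined")
    m = network.number_of_edges()
    degrees = np.array([d for _, d in network.degree()], dtype=float)
    mean_deg = degrees.mean()

    clustering = float(np.mean(list(nx.clustering(network).values())))
    heterogeneity = float(degrees.std() / mean_deg) if mean_deg > 0 else None

    if n >= 3:
        centralization = float(
            (degrees.max() - degrees).sum() / ((n - 1) * (n - 2))
        )
    else:
        centralization = None

    if n >= 2:
        lcc_nodes = max(nx.connected_components(network), key=len)
        lcc = network.subgraph(lcc_nodes)
        if lcc.number_of_nodes() >= 2:
            diameter = float(nx.diameter(lcc))
            cpl = float(nx.average_shortest_path_length(lcc))
        else:
            diameter = cpl = None
    else:
        diameter = cpl = None

    return TopologyReport(
        n_nodes=n,
        n_edges=m,
        clustering_coefficient=clustering,
        diameter=diameter,
        centralization=centralization,
        characteristic_path_length=cpl,
        avg_neighbors=float(mean_deg),
        heterogeneity=heterogeneity,
    )


@dataclass
class DIPRecord:
    """A hub of the differential network with its edge-label breakdown."""

    protein: str
    degree: int
    repressed_degree: int
    activated_degree: int

    @property
    def dip_class(self) -> str:
        if self.activated_degree == 0 and self.repressed_degree > 0:
            return "I"
        if self.repressed_degree == 0 and self.activated_degree > 0:
            return "II"
        return "mixed"


def _dip_record(network: nx.Graph, node: str) -> DIPRecord:
    rep = act = 0
    for _, _, data in network.edges(node, data=True):
        if data["label"] == "repressed":
            rep += 1
        else:
            act += 1
    return DIPRecord(
        protein=node, degree=rep + act, repressed_degree=rep, activated_degree=act
    )


def identify_dips(
    network: nx.Graph,
    rule: str = "top_fraction",
    param: float | int | None = None,
    min_degree: int = 2,
) -> list[DIPRecord]:
    """Select hub proteins of the differential network.

    ``rule="degree_min"``: nodes with degree >= param (default 5).
    ``rule="top_fraction"``: the ceil(param * n) highest-degree nodes
    (default fraction 0.10), with all ties at the cutoff degree included,
    subject to a floor of ``min_degree``.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("cannot identify hubs in an empty network")
    degrees = dict(network.degree())
    if rule == "degree_min":
        k = 5 if param is None else int(param)
        if k < 1:
            raise ValueError(f"degree_min parameter must be >= 1, got {k}")
        hubs = [v for v, d in degrees.items() if d >= k]
    elif rule == "top_fraction":
        frac = 0.10 if param is None else float(param)
        if not (0 < frac <= 1):
            raise ValueError(f"top_fraction parameter must be in (0, 1], got {frac}")
        n = len(degrees)
        k = math.ceil(frac * n)
        ranked = sorted(degrees.items(), key=lambda kv: (-kv[1], kv[0]))
        cutoff = ranked[k - 1][1]
        hubs = [v for v, d in degrees.items() if d >= max(cutoff, min_degree)]
    else:
        raise ValueError(f"unknown hub rule: {rule!r}")
    records = [_dip_record(network, v) for v in hubs]
    records.sort(key=lambda r: (-r.degree, r.protein))
    return records


@dataclass
class DIPModule:
    """A DIP with its partners and incident dPPIs; the systems-biomarker unit."""

    center: DIPRecord
    partners: list[str]
    edges: list[DifferentialCall]
    kw_p: float | None = None
    diagnostic: object = None
    prognostic: object = None

    @property
    def proteins(self) -> list[str]:
        return [self.center.protein] + self.partners


def extract_modules(network: nx.Graph, dips: list[DIPRecord]) -> list[DIPModule]:
    """One module per DIP: the center plus its incident differential edges.

    Partner-partner edges are deliberately excluded — a module is the star
    around its center; modules of adjacent DIPs overlap.
    """
    nodes = set(network.nodes)
    modules = []
    for dip in dips:
        if dip.protein not in nodes:
            raise KeyError(f"DIP {dip.protein} not in network")
        partners = sorted(network.neighbors(dip.protein))
        edges = [network.edges[dip.protein, p]["call"] for p in partners]
        modules.append(DIPModule(center=dip, partners=partners, edges=edges))
    return modules


def module_significance_kw(module: DIPModule) -> float | None:
    """Kruskal-Wallis p for case vs control deciding-state frequencies.

    Across the module's dPPIs, compares the vector of deciding-state case
    frequencies with the vector of control frequencies (two groups, tie
    corrected). Modules with fewer than 2 edges are untestable (None).
    """
    if len(module.edges) < 2:
        return None
    f_case = [float(c.freq_case[c.deciding_state - 1]) for c in module.edges]
    f_ctrl = [float(c.freq_control[c.deciding_state - 1]) for c in module.edges]
    if np.ptp(f_case + f_ctrl) == 0:  # all values identical: H = 0, p = 1
        return 1.0
    stat, p = stats.kruskal(f_case, f_ctrl)
    return float(p)


def score_modules(modules: list[DIPModule]) -> list[DIPModule]:
    """Fill each module's ``kw_p`` in place and return the list."""
    for mod in modules:
        mod.kw_p = module_significance_kw(mod)
    return modules


# -- random-network null ---------------------------------------------------

_NULL_METRICS = (
    "clustering_coefficient",
    "diameter",
    "centralization",
    "characteristic_path_length",
    "avg_neighbors",
    "heterogeneity",
)


def random_network_null(
    network: nx.Graph,
    n_reps: int = 99,
    model: str = "gnm",
    seed: int | None = None,
) -> dict:
    """Compare the observed topology against a random-graph null.

    ``model="gnm"`` draws Erdos-Renyi G(n, m) graphs with the same node and
    edge counts; ``model="degree_preserving"`` rewires by double edge swaps
    (10 * |E| attempted swaps), preserving the degree sequence. Per metric,
    the empirical two-sided p is (1 + #{null at least as extreme}) /
    (n_reps + 1), extremeness measured as |value - null mean|.
    """
    if n_reps < 19:
        raise ValueError("need n_reps >= 19 for a meaningful empirical p")
    rng = np.random.default_rng(seed)
    observed = topology(network).to_dict()
    n, m = network.number_of_nodes(), network.number_of_edges()

    null_values: dict[str, list[float]] = {k: [] for k in _NULL_METRICS}
    for _ in range(n_reps):
        if model == "gnm":
            g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
        elif model == "degree_preserving":
            g = network.copy()
            if m >= 2:
                try:
                    nx.double_edge_swap(
                        g,
                        nswap=10 * m,
                        max_tries=200 * m,
                        seed=int(rng.integers(2**31)),
                    )
                except nx.NetworkXError:
                    logger.warning(
                        "degree sequence admits no swaps; null has zero variance"
                    )
        else:
            raise ValueError(f"unknown null model: {model!r}")
        rep = topology(g).to_dict()
        for k in _NULL_METRICS:
            null_values[k].append(rep[k] if rep[k] is not None else np.nan)

    result = {}
    for k in _NULL_METRICS:
        nulls = np.array(null_values[k], dtype=float)
        obs = observed[k]
        if obs is None or np.isnan(nulls).all():
            result[k] = {"observed": obs, "null_mean": None, "p": None}
            continue
        center = np.nanmean(nulls)
        extreme = np.sum(np.abs(nulls - center) >= abs(obs - center) - 1e-12)
        p = (1 + int(extreme)) / (n_reps + 1)
        result[k] = {
            "observed": obs,
            "null_mean": float(center),
            "null_sd": float(np.nanstd(nulls)),
            "p": float(p),
        }
    result["model"] = model
    result["n_reps"] = n_reps
    return result
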