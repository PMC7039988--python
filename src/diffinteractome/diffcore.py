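"""Differential-interaction calling from joint co-expression states.

For every interaction and each of the 9 joint states, the state's
occurrences are counted separately in the control group (N0, out of NC
samples) and the case group (N1, out of NT samples). The prevalence of a
state in the case phenotype is summarized by

    q = (N1/NT) / (N0/NC + N1/NT)

which is 0 when the state is control-exclusive, 1 when case-exclusive and
0.5 when the normalized frequencies coincide. An interaction is called
differential when some state has q below ``q_low`` (repressed in the case
phenotype) or above ``q_high`` (activated), and that state's normalized
frequency exceeds ``min_freq`` in at least one group. An optional
protein-detectability filter then yields the final dPPI set.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datatypes import (
    DETECTABLE_LEVELS,
    InteractionSet,
    PathologyTable,
    canonical_edge,
)
from .discretize import N_STATES, DiscretizedMatrix, joint_state_matrix

logger = logging.getLogger(__name__)


@dataclass
class StateCountTable:
    """Per-interaction 9-state occurrence counts for both groups.

    Invariant: each sample contributes exactly one state per interaction,
    so each row of ``N0`` sums to ``NC`` and each row of ``N1`` to ``NT``.
    """

    edges: list[tuple[str, str]]
    N0: np.ndarray  # n_edges x 9 control counts
    N1: np.ndarray  # n_edges x 9 case counts
    NC: int
    NT: int

    def __post_init__(self) -> None:
        self.N0 = np.asarray(self.N0, dtype=np.int64)
        self.N1 = np.asarray(self.N1, dtype=np.int64)
        n = len(self.edges)
        if self.N0.shape != (n, N_STATES) or self.N1.shape != (n, N_STATES):
            raise ValueError("count matrices must be n_edges x 9")
        if (self.N0 < 0).any() or (self.N1 < 0).any():
            raise ValueError("counts must be non-negative")
        if n and (not (self.N0.sum(axis=1) == self.NC).all()
                  or not (self.N1.sum(axis=1) == self.NT).all()):
            raise ValueError("state counts must sum to the group size for every edge")


@dataclass
class DifferentialCall:
    """Per-interaction calling result with the full 9-state table retained.

    ``q`` holds NaN for states never observed in either group (undefined).
    ``label`` is decided by the passing state with maximal |q - 0.5|
    (ties: larger max frequency, then lowest state index); ``conflict``
    flags edges where passing states disagree in direction.
    """

    interaction: tuple[str, str]
    q: np.ndarray                # length 9, NaN where undefined
    freq_control: np.ndarray     # length 9, N0/NC
    freq_case: np.ndarray        # length 9, N1/NT
    passes: np.ndarray           # length 9 bool
    label: str                   # activated | repressed | none
    deciding_state: int | None   # 1-based state index
    conflict: bool = False

    def deciding_q(self) -> float | None:
        if self.deciding_state is None:
            return None
        return float(self.q[self.deciding_state - 1])


def count_states(
    discretized: DiscretizedMatrix,
    phenotype: dict[str, str],
    interactions: InteractionSet,
) -> StateCountTable:
    """Tally the 9 joint states per interaction, separately per group."""
    idx = discretized.gene_index()
    edges = sorted(interactions.edges)
    for a, b in edges:
        if a not in idx or b not in idx:
            raise KeyError(f"interaction endpoint missing from matrix: ({a}, {b})")

    control_mask = np.array(
        [phenotype[s] == "control" for s in discretized.samples]
    )
    NC = int(control_mask.sum())
    NT = int((~control_mask).sum())

    n = len(edges)
    N0 = np.zeros((n, N_STATES), dtype=np.int64)
    N1 = np.zeros((n, N_STATES), dtype=np.int64)
    if n:
        rows_a = np.array([idx[a] for a, _ in edges])
        rows_b = np.array([idx[b] for _, b in edges])
        states = joint_state_matrix(
            discretized.levels[rows_a, :], discretized.levels[rows_b, :]
        )  # n_edges x n_samples, values 1..9
        for e in range(n):
            N0[e] = np.bincount(states[e, control_mask] - 1, minlength=N_STATES)
            N1[e] = np.bincount(states[e, ~control_mask] - 1, minlength=N_STATES)
    return StateCountTable(edges=edges, N0=N0, N1=N1, NC=NC, NT=NT)


def q_value(N0: int, N1: int, NC: int, NT: int) -> float:
    """Relative case-observation frequency of one state.

    Returns NaN (undefined) when the state was observed in neither group.
    """
    if NC <= 0 or NT <= 0:
        raise ValueError("group sizes must be positive")
    if N0 < 0 or N1 < 0:
        raise ValueError("counts must be non-negative")
    if N0 > NC or N1 > NT:
        raise ValueError("count exceeds its group size")
    if N0 == 0 and N1 == 0:
        return float("nan")
    f0 = N0 / NC
    f1 = N1 / NT
    return f1 / (f0 + f1)


def q_matrix(counts: StateCountTable) -> np.ndarray:
    """Vectorized q over all edges and states (NaN where undefined)."""
    f0 = counts.N0 / counts.NC
    f1 = counts.N1 / counts.NT
    denom = f0 + f1
    with np.errstate(invalid="ignore", divide="ignore"):
        q = np.where(denom > 0, f1 / np.where(denom == 0, 1.0, denom), np.nan)
    return q


def call_differential(
    counts: StateCountTable,
    q_low: float = 0.10,
    q_high: float = 0.90,
    min_freq: float = 0.20,
) -> list[DifferentialCall]:
    """Label every interaction as activated / repressed / none.

    A state passes iff (q < q_low or q > q_high) and
    max(N0/NC, N1/NT) > min_freq — all comparisons strict. The edge label
    comes from the passing state maximizing |q - 0.5|, breaking ties by
    larger max frequency, then lowest state index.
    """
    if not (0 < q_low < q_high < 1):
        raise ValueError(f"need 0 < q_low < q_high < 1, got {q_low}, {q_high}")
    if not (0 <= min_freq < 1):
        raise ValueError(f"min_freq must be in [0, 1), got {min_freq}")

    q = q_matrix(counts)
    f0 = counts.N0 / counts.NC
    f1 = counts.N1 / counts.NT
    fmax = np.maximum(f0, f1)
    with np.errstate(invalid="ignore"):
        sig = (q < q_low) | (q > q_high)  # NaN -> False on both sides
    passes = sig & (fmax > min_freq)

    calls: list[DifferentialCall] = []
    for e, edge in enumerate(counts.edges):
        pass_idx = np.flatnonzero(passes[e])
        if pass_idx.size == 0:
            label, deciding, conflict = "none", None, False
        else:
            # deciding state: max |q-0.5|, ties -> larger fmax, then lowest index
            key = sorted(
                pass_idx,
                key=lambda s: (-abs(q[e, s] - 0.5), -fmax[e, s], s),
            )
            deciding = int(key[0]) + 1
            label = "activated" if q[e, deciding - 1] > q_high else "repressed"
            directions = {"activated" if q[e, s] > q_high else "repressed"
                          for s in pass_idx}
            conflict = len(directions) > 1
        calls.append(
            DifferentialCall(
                interaction=edge,
                q=q[e].copy(),
                freq_control=f0[e].copy(),
                freq_case=f1[e].copy(),
                passes=passes[e].copy(),
                label=label,
                deciding_state=deciding,
                conflict=conflict,
            )
        )
    return calls


def apply_pathology_filter(
    calls: list[DifferentialCall],
    pathology: PathologyTable,
    cohort_id: str,
    policy: str = "both",
    unknown_detectable: bool = True,
) -> list[DifferentialCall]:
    """Keep labeled calls whose endpoints are detectable in this cohort.

    ``policy="both"`` requires both endpoints detectable (high/medium/low);
    ``policy="either"`` requires at least one. Proteins absent from the
    table have level "unknown" and pass by default
    (``unknown_detectable=True``). An empty table makes the filter the
    identity, with a warning.
    """
    if policy not in ("both", "either"):
        raise ValueError(f"policy must be 'both' or 'either', got {policy!r}")
    labeled = [c for c in calls if c.label != "none"]
    if len(pathology) == 0:
        logger.warning("empty pathology table: detectability filter is the identity")
        return labeled
    if cohort_id not in pathology.cohorts():
        logger.warning(
            "cohort %r absent from pathology table: all proteins treated as unknown",
            cohort_id,
        )

    def detectable(protein: str) -> bool:
        level = pathology.level(protein, cohort_id)
        if level == "unknown":
            return unknown_detectable
        return level in DETECTABLE_LEVELS

    kept = []
    for call in labeled:
        a, b = call.interaction
        ok = (detectable(a) and detectable(b)) if policy == "both" else (
            detectable(a) or detectable(b)
        )
        if ok:
            kept.append(call)
    logger.info("pathology filter (%s): %d -> %d dPPIs", policy, len(labeled), len(kept))
    return kept


# -- dPPI table I/O --------------------------------------------------------

DPPI_COLUMNS = [
    "proteinA", "proteinB", "deciding_state", "q",
    "freq_control", "freq_case", "label", "conflict",
]


def write_dppi_table(calls: list[DifferentialCall], path: str | Path) -> None:
    """Write labeled calls as the canonical dPPI TSV."""
    with open(path, "w") as fh:
        fh.write("\t".join(DPPI_COLUMNS) + "\n")
        for c in sorted(calls, key=lambda c: c.interaction):
            if c.label == "none":
                continue
            s = c.deciding_state
            fh.write(
                f"{c.interaction[0]}\t{c.interaction[1]}\t{s}\t"
                f"{c.q[s - 1]:.10g}\t{c.freq_control[s - 1]:.10g}\t"
                f"{c.freq_case[s - 1]:.10g}\t{c.label}\t{int(c.conflict)}\n"
            )


def read_dppi_table(path: str | Path) -> list[dict]:
    """Read a dPPI TSV back as a list of plain records."""
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != DPPI_COLUMNS:
            raise ValueError(f"unexpected dPPI table header: {reader.fieldnames!r}")
        for row in reader:
            a, b = canonical_edge(row["proteinA"], row["proteinB"])
            out.append(
                {
                    "interaction": (a, b),
                    "deciding_state": int(row["deciding_state"]),
                    "q": float(row["q"]),
                    "freq_control": float(row["freq_control"]),
                    "freq_case": float(row["freq_case"]),
                    "label": row["label"],
                    "conflict": bool(int(row["conflict"])),
                }
            )
    return out


def dppi_edge_set(calls_or_records) -> set[tuple[str, str]]:
    """Label-agnostic edge set from calls or dPPI-table records."""
    edges = set()
    for item in calls_or_records:
        if isinstance(item, DifferentialCall):
            if item.label != "none":
                edges.add(item.interaction)
        else:
            edges.add(item["interaction"])
    return edges
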