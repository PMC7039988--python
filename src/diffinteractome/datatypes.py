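"""Core in-memory containers shared by every pipeline stage.

All containers validate their invariants at construction time so that
downstream code can assume clean data: unique uppercase gene symbols,
complete phenotype labels, finite non-negative expression values,
self-loop-free undirected edges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

CONTROL = "control"
CASE = "case"

#: accepted synonyms for the two phenotype labels
PHENOTYPE_SYNONYMS = {
    "control": CONTROL,
    "normal": CONTROL,
    "case": CASE,
    "tumor": CASE,
    "tumour": CASE,
}

PATHOLOGY_LEVELS = frozenset({"high", "medium", "low", "not_detected", "unknown"})
DETECTABLE_LEVELS = frozenset({"high", "medium", "low"})


def normalize_phenotype(label: str) -> str:
    """Map a phenotype label (or synonym) to the canonical control/case pair."""
    key = label.strip().lower()
    if key not in PHENOTYPE_SYNONYMS:
        raise ValueError(
            f"unknown phenotype label {label!r}; expected one of "
            f"{sorted(PHENOTYPE_SYNONYMS)}"
        )
    return PHENOTYPE_SYNONYMS[key]


def canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Order-insensitive, uppercased representation of an undirected edge."""
    a, b = a.strip().upper(), b.strip().upper()
    return (a, b) if a <= b else (b, a)


@dataclass
class ExpressionStudy:
    """Expression matrix with phenotype labels for one cohort.

    Parameters
    ----------
    cohort_id : short cohort label (e.g. ``"LIHC"``).
    genes : ordered gene symbols (rows of ``values``).
    samples : ordered sample ids (columns of ``values``).
    values : genes x samples matrix of non-negative FPKM-like reals.
    phenotype : sample id -> ``"control"`` or ``"case"``.
    """

    cohort_id: str
    genes: list[str]
    samples: list[str]
    values: np.ndarray
    phenotype: dict[str, str]

    def __post_init__(self) -> None:
        self.genes = [g.strip().upper() for g in self.genes]
        self.samples = list(self.samples)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            dup = _first_duplicate(self.genes)
            raise ValueError(f"duplicate gene symbol: {dup}")
        if len(set(self.samples)) != len(self.samples):
            dup = _first_duplicate(self.samples)
            raise ValueError(f"duplicate sample id: {dup}")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        self.phenotype = {s: normalize_phenotype(p) for s, p in self.phenotype.items()}
        missing = [s for s in self.samples if s not in self.phenotype]
        if missing:
            raise ValueError(f"samples without phenotype label: {missing[:5]}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite (no NA/inf)")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        groups = {self.phenotype[s] for s in self.samples}
        if groups != {CONTROL, CASE}:
            raise ValueError(
                f"both phenotype groups must be non-empty; found only {sorted(groups)}"
            )

    # -- convenience views -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def group_mask(self, group: str) -> np.ndarray:
        """Boolean mask over samples for one phenotype group."""
        return np.array([self.phenotype[s] == group for s in self.samples])

    def control_samples(self) -> list[str]:
        return [s for s in self.samples if self.phenotype[s] == CONTROL]

    def case_samples(self) -> list[str]:
        return [s for s in self.samples if self.phenotype[s] == CASE]

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionStudy":
        idx = self.gene_index()
        keep = [g.strip().upper() for g in genes]
        missing = [g for g in keep if g not in idx]
        if missing:
            raise KeyError(f"genes not in study: {missing[:5]}")
        rows = [idx[g] for g in keep]
        return ExpressionStudy(
            cohort_id=self.cohort_id,
            genes=keep,
            samples=list(self.samples),
            values=self.values[rows, :].copy(),
            phenotype=dict(self.phenotype),
        )


class InteractionSet:
    """Deduplicated, undirected, self-loop-free protein-pair edge list."""

    def __init__(self, edges: Iterable[tuple[str, str]] = ()):
        self._edges: set[tuple[str, str]] = set()
        for a, b in edges:
            e = canonical_edge(a, b)
            if e[0] == e[1]:
                continue  # self-loop
            self._edges.add(e)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self._edges)

    def proteins(self) -> set[str]:
        return {p for e in self._edges for p in e}

    def __len__(self) -> int:
        return len(self._edges)

    def __iter__(self):
        return iter(sorted(self._edges))

    def __contains__(self, pair) -> bool:
        return canonical_edge(*pair) in self._edges

    def __eq__(self, other) -> bool:
        return isinstance(other, InteractionSet) and self._edges == other._edges

    def __repr__(self) -> str:
        return f"InteractionSet({len(self._edges)} edges, {len(self.proteins())} proteins)"


@dataclass
class PathologyTable:
    """Per-protein detectability level by cohort.

    ``records`` maps ``(protein, cohort_id)`` to a level in
    {high, medium, low, not_detected, unknown}.
    """

    records: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {}
        for (protein, cohort), level in self.records.items():
            level = level.strip().lower().replace(" ", "_")
            if level not in PATHOLOGY_LEVELS:
                raise ValueError(
                    f"invalid pathology level {level!r} for {protein}; "
                    f"allowed: {sorted(PATHOLOGY_LEVELS)}"
                )
            clean[(protein.strip().upper(), cohort)] = level
        self.records = clean

    def level(self, protein: str, cohort_id: str) -> str:
        return self.records.get((protein.strip().upper(), cohort_id), "unknown")

    def cohorts(self) -> set[str]:
        return {c for (_, c) in self.records}

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ClinicalTable:
    """Right-censored survival records: sample -> (time in days, event flag)."""

    records: dict[str, tuple[float, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sample, (time, event) in self.records.items():
            if not (time > 0):
                raise ValueError(f"non-positive survival time for {sample}: {time}")
            if event not in (0, 1):
                raise ValueError(f"event indicator for {sample} must be 0 or 1, got {event}")

    def __len__(self) -> int:
        return len(self.records)

    def samples(self) -> list[str]:
        return list(self.records)

    def times_events(self, samples: Iterable[str]) -> tuple[np.ndarray, np.ndarray]:
        t, e = [], []
        for s in samples:
            time, event = self.records[s]
            t.append(time)
            e.append(event)
        return np.asarray(t, dtype=float), np.asarray(e, dtype=int)


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort, for parameter-recovery checks."""

    planted_activated: set[tuple[str, str]]
    planted_repressed: set[tuple[str, str]]
    planted_null: set[tuple[str, str]]
    planted_dips: set[str]
    survival_beta: dict[str, float]
    generator_params: dict

    def __post_init__(self) -> None:
        self.planted_activated = {canonical_edge(*e) for e in self.planted_activated}
        self.planted_repressed = {canonical_edge(*e) for e in self.planted_repressed}
        self.planted_null = {canonical_edge(*e) for e in self.planted_null}
        overlap = (
            (self.planted_activated & self.planted_repressed)
            | (self.planted_activated & self.planted_null)
            | (self.planted_repressed & self.planted_null)
        )
        if overlap:
            raise ValueError(f"planted edge sets must be disjoint; overlap: {sorted(overlap)[:3]}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_activated": sorted(map(list, self.planted_activated)),
                "planted_repressed": sorted(map(list, self.planted_repressed)),
                "planted_null": sorted(map(list, self.planted_null)),
                "planted_dips": sorted(self.planted_dips),
                "survival_beta": self.survival_beta,
                "generator_params": self.generator_params,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            planted_activated={tuple(e) for e in d["planted_activated"]},
            planted_repressed={tuple(e) for e in d["planted_repressed"]},
            planted_null={tuple(e) for e in d["planted_null"]},
            planted_dips=set(d["planted_dips"]),
            survival_beta=dict(d["survival_beta"]),
            generator_params=dict(d["generator_params"]),
        )


def _first_duplicate(items: list) -> object:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None
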