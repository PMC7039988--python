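"""Cross-cohort comparison of dPPI sets.

Cohorts are compared as plain edge sets, order-insensitively and (by
default) label-insensitively: an interaction activated in one cohort and
repressed in another still counts as shared rewiring. Three summaries:

* pairwise Jaccard index |A n B| / |A u B|
* prevalence distribution: for k = 1..n_cohorts, how many distinct edges
  occur in exactly k cohorts
* per-cohort specificity: edges private to the cohort, as a count and as a
  fraction of the cohort's dPPI set
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .datatypes import canonical_edge

logger = logging.getLogger(__name__)

Edge = tuple[str, str]


def jaccard(set_a: set, set_b: set) -> float:
    """Intersection over union; 0 (with a warning) when both sets are empty."""
    union = set_a | set_b
    if not union:
        logger.warning("Jaccard of two empty sets defined as 0")
        return 0.0
    return len(set_a & set_b) / len(union)


def prevalence_distribution(dppi_sets: dict[str, set[Edge]]) -> dict[int, int]:
    """Histogram: number of distinct edges present in exactly k cohorts."""
    if not dppi_sets:
        raise ValueError("need at least one cohort")
    counts = Counter()
    for edges in dppi_sets.values():
        for e in edges:
            counts[e] += 1
    hist: dict[int, int] = {}
    for k in counts.values():
        hist[k] = hist.get(k, 0) + 1
    return dict(sorted(hist.items()))


def specificity_summary(
    dppi_sets: dict[str, set[Edge]]
) -> dict[str, tuple[int, float | None]]:
    """Per cohort: number of private edges and the private fraction."""
    if len(dppi_sets) < 2:
        raise ValueError("specificity needs at least 2 cohorts")
    counts = Counter()
    for edges in dppi_sets.values():
        for e in edges:
            counts[e] += 1
    out = {}
    for cohort, edges in dppi_sets.items():
        n_specific = sum(1 for e in edges if counts[e] == 1)
        rate = n_specific / len(edges) if edges else None
        out[cohort] = (n_specific, rate)
    return out


@dataclass
class CohortComparison:
    """Full pan-cohort comparison report."""

    cohorts: list[str]
    dppi_sets: dict[str, set[Edge]]
    jaccard_matrix: np.ndarray
    prevalence: dict[int, int]
    specificity: dict[str, tuple[int, float | None]]

    def to_dict(self) -> dict:
        return {
            "cohorts": self.cohorts,
            "jaccard": {
                a: {b: float(self.jaccard_matrix[i, j])
                    for j, b in enumerate(self.cohorts)}
                for i, a in enumerate(self.cohorts)
            },
            "prevalence_histogram": {str(k): v for k, v in self.prevalence.items()},
            "specificity": {
                c: {"n_specific": n, "rate": r}
                for c, (n, r) in self.specificity.items()
            },
            "set_sizes": {c: len(s) for c, s in self.dppi_sets.items()},
        }


def compare_cohorts(
    dppi_sets: dict[str, set[Edge] | list],
    label_sensitive: bool = False,
) -> CohortComparison:
    """Build the full comparison from cohort -> dPPI edge collections.

    Input edges may be plain pairs or (a, b, label) triples; unless
    ``label_sensitive`` the label is discarded before set comparison.
    """
    if len(dppi_sets) < 2:
        raise ValueError("pan-cohort comparison needs at least 2 cohorts")
    clean: dict[str, set] = {}
    for cohort, edges in dppi_sets.items():
        s = set()
        for e in edges:
            if len(e) == 2:
                s.add(canonical_edge(*e))
            else:
                a, b = canonical_edge(e[0], e[1])
                s.add((a, b, e[2]) if label_sensitive else (a, b))
        clean[cohort] = s

    cohorts = sorted(clean)
    k = len(cohorts)
    jmat = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            ji = jaccard(clean[cohorts[i]], clean[cohorts[j]])
            jmat[i, j] = jmat[j, i] = ji
    return CohortComparison(
        cohorts=cohorts,
        dppi_sets=clean,
        jaccard_matrix=jmat,
        prevalence=prevalence_distribution(clean),
        specificity=specificity_summary(clean),
    )
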