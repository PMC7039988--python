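"""Three-level discretization of expression and the 9-state joint alphabet.

Each gene's continuous values are mapped to levels -1 (low), 0 (average),
1 (high). Two rules are provided:

* ``zscore`` (default): per-gene z across ALL cohort samples (control and
  case pooled, so the two groups' state counts stay on a common scale);
  level 1 if z > t, -1 if z < -t, else 0, with t = 1.0 by default.
* ``quantile``: per-gene linear-interpolation quantile cutoffs q_lo/q_hi
  (defaults 0.25/0.75); values tied with a cutoff get the middle level.

An interacting pair's levels form one of 9 ordered joint states:

    1:[0 0]  2:[0 1]  3:[0 -1]  4:[1 0]  5:[1 1]
    6:[1 -1] 7:[-1 0] 8:[-1 1]  9:[-1 -1]
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import ExpressionStudy

logger = logging.getLogger(__name__)

N_STATES = 9

#: level order used by the canonical state enumeration
LEVEL_ORDER = (0, 1, -1)
_LEVEL_POS = {0: 0, 1: 1, -1: 2}

#: state index (1-based) -> (level_A, level_B)
STATE_PAIRS = {
    3 * i + j + 1: (a, b)
    for i, a in enumerate(LEVEL_ORDER)
    for j, b in enumerate(LEVEL_ORDER)
}

STATE_LABELS = {s: f"[{a} {b}]" for s, (a, b) in STATE_PAIRS.items()}


def joint_state(level_a: int, level_b: int) -> int:
    """Map an ordered pair of levels to its 1-based joint-state index.

    The map is bijective and order-sensitive: (0,1) and (1,0) are distinct
    states (2 and 4).
    """
    try:
        return 3 * _LEVEL_POS[level_a] + _LEVEL_POS[level_b] + 1
    except KeyError:
        raise ValueError(
            f"levels must be in {{-1, 0, 1}}, got ({level_a}, {level_b})"
        ) from None


def joint_state_matrix(levels_a: np.ndarray, levels_b: np.ndarray) -> np.ndarray:
    """Vectorized :func:`joint_state` over arrays of levels."""
    la = np.asarray(levels_a)
    lb = np.asarray(levels_b)
    for arr in (la, lb):
        if not np.isin(arr, (-1, 0, 1)).all():
            raise ValueError("levels must be in {-1, 0, 1}")
    # position in LEVEL_ORDER: 0 -> 0, 1 -> 1, -1 -> 2
    pa = np.where(la == 0, 0, np.where(la == 1, 1, 2))
    pb = np.where(lb == 0, 0, np.where(lb == 1, 1, 2))
    return 3 * pa + pb + 1


@dataclass
class DiscretizedMatrix:
    """Per-gene three-level codes with the discretization rule recorded."""

    genes: list[str]
    samples: list[str]
    levels: np.ndarray  # genes x samples, entries in {-1, 0, 1}
    method_tag: dict

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int8)
        if self.levels.shape != (len(self.genes), len(self.samples)):
            raise ValueError("levels shape does not match genes x samples")
        if not np.isin(self.levels, (-1, 0, 1)).all():
            raise ValueError("levels must be in {-1, 0, 1}")

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


def discretize_expression(
    study: ExpressionStudy,
    method: str = "zscore",
    t: float = 1.0,
    q_lo: float = 0.25,
    q_hi: float = 0.75,
) -> DiscretizedMatrix:
    """Discretize a study's expression matrix into levels {-1, 0, 1}.

    The per-gene reference statistics (mean/SD or quantiles) are computed
    across all samples of the cohort, both groups pooled. Genes with zero
    variance map to all-zero levels with a warning.
    """
    values = study.values
    if values.shape[1] < 2:
        raise ValueError("discretization needs at least 2 samples per gene")

    if method == "zscore":
        if t <= 0:
            raise ValueError(f"z threshold t must be > 0, got {t}")
        mean = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, keepdims=True)
        flat = (sd.ravel() == 0)
        sd_safe = np.where(sd == 0, 1.0, sd)
        z = (values - mean) / sd_safe
        levels = np.zeros_like(values, dtype=np.int8)
        levels[z > t] = 1
        levels[z < -t] = -1
        levels[flat, :] = 0
        tag = {"method": "zscore", "t": t}
    elif method == "quantile":
        if not (0 <= q_lo < q_hi <= 1):
            raise ValueError(f"need 0 <= q_lo < q_hi <= 1, got {q_lo}, {q_hi}")
        lo = np.quantile(values, q_lo, axis=1, keepdims=True)
        hi = np.quantile(values, q_hi, axis=1, keepdims=True)
        flat = (values.std(axis=1) == 0)
        levels = np.zeros_like(values, dtype=np.int8)
        # ties with a cutoff stay at the middle level
        levels[values > hi] = 1
        levels[values < lo] = -1
        levels[flat, :] = 0
        tag = {"method": "quantile", "q_lo": q_lo, "q_hi": q_hi}
    else:
        raise ValueError(f"unknown discretization method: {method!r}")

    if flat.any():
        logger.warning(
            "%d zero-variance gene(s) mapped to all-average levels", int(flat.sum())
        )
    return DiscretizedMatrix(
        genes=list(study.genes),
        samples=list(study.samples),
        levels=levels,
        method_tag=tag,
    )
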