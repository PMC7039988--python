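import numpy as np
import pytest

from diffinteractome.datatypes import ExpressionStudy, InteractionSet


def make_study(
    gene_values: dict[str, list[float]],
    n_control: int,
    n_case: int,
    cohort_id: str = "TOY",
) -> ExpressionStudy:
    """Study from per-gene value lists; first n_control columns are controls."""
    genes = list(gene_values)
    n = n_control + n_case
    samples = [f"C{i}" for i in range(n_control)] + [f"T{i}" for i in range(n_case)]
    values = np.array([gene_values[g] for g in genes], dtype=float)
    assert values.shape[1] == n
    phenotype = {s: ("control" if s.startswith("C") else "case") for s in samples}
    return ExpressionStudy(cohort_id, genes, samples, values, phenotype)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_interactions():
    return InteractionSet([("A", "B"), ("B", "C"), ("C", "D")])
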