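"""Readers and writers for every external file format.

Formats (all plain text, tab-separated):

* expression matrix — genes as rows, header row of sample ids, cells FPKM
* phenotype map — two columns (sample_id, label), labels control/case with
  normal/tumor accepted as synonyms
* interactions — two symbol columns, or a BioGRID tab-format subset
  (detected by the "Official Symbol Interactor A/B" header columns)
* pathology — three columns (protein, cohort, level)
* clinical — three columns (sample_id, time_days, event)
* networks out — SIF ("A activated B") or labeled TSV that round-trips
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalTable,
    ExpressionStudy,
    InteractionSet,
    PathologyTable,
    canonical_edge,
    normalize_phenotype,
)

logger = logging.getLogger(__name__)

BIOGRID_COL_A = "Official Symbol Interactor A"
BIOGRID_COL_B = "Official Symbol Interactor B"


def read_phenotype_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample, label) TSV into a sample -> control/case map."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValueError(f"phenotype map line needs 2 columns: {row!r}")
            sample, label = row[0].strip(), row[1]
            if sample.lower() in ("sample", "sample_id") and len(mapping) == 0:
                continue  # header
            if sample in mapping:
                raise ValueError(f"duplicate sample in phenotype map: {sample}")
            mapping[sample] = normalize_phenotype(label)
    return mapping


def read_expression(
    path: str | Path,
    phenotype_map_path: str | Path,
    cohort_id: str = "cohort",
) -> ExpressionStudy:
    """Read an expression TSV plus phenotype map into a validated study.

    Genes containing any missing or non-numeric value are dropped with a
    logged warning (the state-count bookkeeping requires every retained gene
    to be observed in every sample). Duplicate genes or samples, and samples
    absent from the phenotype map, are errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    genes = [str(g).strip().upper() for g in df.index]
    samples = [str(s).strip() for s in df.columns]
    if len(set(genes)) != len(genes):
        dup = next(g for g in genes if genes.count(g) > 1)
        raise ValueError(f"duplicate gene symbol in expression matrix: {dup}")
    if len(set(samples)) != len(samples):
        dup = next(s for s in samples if samples.count(s) > 1)
        raise ValueError(f"duplicate sample id in expression matrix: {dup}")

    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = ~np.all(np.isfinite(values), axis=1)
    if bad.any():
        dropped = [g for g, b in zip(genes, bad) if b]
        logger.warning(
            "dropping %d gene(s) with missing/non-numeric values: %s%s",
            len(dropped),
            dropped[:5],
            "..." if len(dropped) > 5 else "",
        )
        values = values[~bad]
        genes = [g for g, b in zip(genes, bad) if not b]

    phenotype = read_phenotype_map(phenotype_map_path)
    missing = [s for s in samples if s not in phenotype]
    if missing:
        raise ValueError(f"samples absent from phenotype map: {missing[:5]}")

    return ExpressionStudy(
        cohort_id=cohort_id,
        genes=genes,
        samples=samples,
        values=values,
        phenotype={s: phenotype[s] for s in samples},
    )


def read_interactions(path: str | Path, dialect: str = "two_column") -> InteractionSet:
    """Read an edge list as an undirected, deduplicated, self-loop-free set.

    ``dialect="two_column"``: first two tab-separated columns are symbols.
    ``dialect="biogrid_tab"``: header must carry the official-symbol columns;
    only those two columns are consulted.
    """
    if dialect == "two_column":
        pairs = []
        with open(path) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                if len(row) < 2:
                    raise ValueError(f"interaction line needs 2 columns: {row!r}")
                pairs.append((row[0], row[1]))
        return InteractionSet(pairs)
    if dialect == "biogrid_tab":
        df = pd.read_csv(path, sep="\t", dtype=str)
        for col in (BIOGRID_COL_A, BIOGRID_COL_B):
            if col not in df.columns:
                raise ValueError(f"biogrid_tab file missing required column {col!r}")
        return InteractionSet(zip(df[BIOGRID_COL_A], df[BIOGRID_COL_B]))
    raise ValueError(f"unknown interaction dialect: {dialect!r}")


def filter_interactome_to_expression(
    interactions: InteractionSet, study: ExpressionStudy
) -> InteractionSet:
    """Keep edges whose BOTH endpoints have expression rows in the study."""
    genes = set(study.genes)
    kept = InteractionSet(e for e in interactions if e[0] in genes and e[1] in genes)
    logger.info(
        "interactome filter: %d -> %d edges (%d gene symbols in expression)",
        len(interactions),
        len(kept),
        len(genes),
    )
    return kept


def read_pathology(path: str | Path) -> PathologyTable:
    """Read a (protein, cohort, level) TSV."""
    records: dict[tuple[str, str], str] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if row[0].strip().lower() == "protein" and not records:
                continue
            if len(row) < 3:
                raise ValueError(f"pathology line needs 3 columns: {row!r}")
            records[(row[0], row[1].strip())] = row[2]
    return PathologyTable(records)


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a (sample_id, time_days, event) TSV."""
    records: dict[str, tuple[float, int]] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if row[0].strip().lower() in ("sample", "sample_id") and not records:
                continue
            if len(row) < 3:
                raise ValueError(f"clinical line needs 3 columns: {row!r}")
            records[row[0].strip()] = (float(row[1]), int(row[2]))
    return ClinicalTable(records)


# -- labeled-network output ------------------------------------------------

NETWORK_TSV_COLUMNS = ["proteinA", "proteinB", "label", "q", "state"]


def write_network(
    network: Iterable[tuple[str, str, str, float, int]],
    path: str | Path,
    format: str = "tsv",
) -> None:
    """Write labeled edges (proteinA, proteinB, label, q, state).

    ``format="sif"`` emits Cytoscape SIF lines with relation tokens
    "activated"/"repressed"; ``format="tsv"`` emits a header plus one row
    per edge and round-trips losslessly through :func:`read_network`.
    """
    rows = list(network)
    for a, b, label, _q, _s in rows:
        if label not in ("activated", "repressed"):
            raise ValueError(f"edge label must be activated/repressed, got {label!r}")
    with open(path, "w") as fh:
        if format == "sif":
            for a, b, label, _q, _s in rows:
                fh.write(f"{a}\t{label}\t{b}\n")
        elif format == "tsv":
            fh.write("\t".join(NETWORK_TSV_COLUMNS) + "\n")
            for a, b, label, q, s in rows:
                fh.write(f"{a}\t{b}\t{label}\t{q:.17g}\t{s}\n")
        else:
            raise ValueError(f"unknown network format: {format!r}")


def read_network(path: str | Path) -> list[tuple[str, str, str, float, int]]:
    """Read back the labeled-network TSV written by :func:`write_network`."""
    out = []
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is not None and header != NETWORK_TSV_COLUMNS:
            raise ValueError(f"unexpected network TSV header: {header!r}")
        for row in reader:
            if not row:
                continue
            a, b = canonical_edge(row[0], row[1])
            out.append((a, b, row[2], float(row[3]), int(row[4])))
    return out


def write_expression(study: ExpressionStudy, path: str | Path) -> None:
    """Write the expression matrix in the TSV layout read_expression expects."""
    df = pd.DataFrame(study.values, index=study.genes, columns=study.samples)
    df.to_csv(path, sep="\t", index_label="gene", float_format="%.6g")


def write_phenotype_map(phenotype: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tlabel\n")
        for sample, label in phenotype.items():
            fh.write(f"{sample}\t{label}\n")


def write_interactions(interactions: InteractionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in interactions:
            fh.write(f"{a}\t{b}\n")


def write_pathology(table: PathologyTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein\tcohort\tlevel\n")
        for (protein, cohort), level in sorted(table.records.items()):
            fh.write(f"{protein}\t{cohort}\t{level}\n")


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\ttime_days\tevent\n")
        for sample, (time, event) in clinical.records.items():
            fh.write(f"{sample}\t{time:.6g}\t{event}\n")
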