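"""Diagnostic and prognostic scoring of DIP-centered modules.

Diagnostic: repeated balanced subsampling, PCA on the module's genes, and
leave-one-out nearest-centroid classification in the retained component
space give a pooled confusion matrix, from which sensitivity, specificity
and the diagnostic odds ratio

    DOR = (sens / (1 - sens)) * (spec / (1 - spec))

are computed (case/tumor is the positive class; DOR(0.9, 0.9) = 81).

Prognostic: a multivariate Cox proportional-hazards fit over the module's
genes yields per-subject prognostic indices PI = sum_i beta_i x_i; subjects
are split at the median PI into low/high-risk groups, compared by
Kaplan-Meier curves, the log-rank test and a univariate Cox hazard ratio.

Also provided: generic Fisher-exact over-representation with
Benjamini-Hochberg correction, and simple list-overlap annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .datatypes import CASE, CONTROL, ClinicalTable, ExpressionStudy

logger = logging.getLogger(__name__)


def dor(sensitivity: float, specificity: float) -> float:
    """Diagnostic odds ratio; infinite at a perfect sensitivity or specificity."""
    if not (0 <= sensitivity <= 1 and 0 <= specificity <= 1):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    if sensitivity == 1 or specificity == 1:
        return float("inf")
    return (sensitivity / (1 - sensitivity)) * (specificity / (1 - specificity))


@dataclass
class DiagnosticResult:
    sensitivity: float
    specificity: float
    dor: float
    n_components: int
    variance_explained: float
    n_reps: int
    below_variance_target: bool = False
    dor_corrected: bool = False  # Haldane 0.5 applied to a zero cell

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _loo_nearest_centroid(pcs: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Leave-one-out nearest-class-centroid prediction in PC space."""
    preds = np.empty_like(labels)
    classes = np.unique(labels)
    sums = {c: pcs[labels == c].sum(axis=0) for c in classes}
    counts = {c: int((labels == c).sum()) for c in classes}
    for i in range(len(labels)):
        best, best_d = None, np.inf
        for c in classes:
            s, n = sums[c], counts[c]
            if labels[i] == c:
                if n == 1:
                    continue  # no centroid without the held-out point
                centroid = (s - pcs[i]) / (n - 1)
            else:
                centroid = s / n
            d = float(np.linalg.norm(pcs[i] - centroid))
            if d < best_d:
                best, best_d = c, d
        preds[i] = best
    return preds


def pca_diagnostics(
    study: ExpressionStudy,
    genes: list[str],
    n_per_class: int = 30,
    var_target: float = 0.80,
    max_components: int = 2,
    max_reps: int = 200,
    tol: float = 0.005,
    seed: int | None = None,
) -> DiagnosticResult:
    """Estimate module sensitivity/specificity/DOR by repeated subsampling.

    Each repetition draws ``n_per_class`` samples per phenotype class,
    z-scores the module genes within the draw, runs PCA, keeps the smallest
    number of components (capped at ``max_components``) whose cumulative
    explained variance reaches ``var_target`` (flagged when unreachable),
    and classifies every drawn sample by leave-one-out nearest centroid.
    Repetitions stop once the running means of sensitivity and specificity
    move less than ``tol`` across successive blocks of 10, or at
    ``max_reps``. Confusion counts are pooled over repetitions before the
    DOR is formed (Haldane 0.5 correction when any pooled cell is zero).
    """
    rng = np.random.default_rng(seed)
    sub = study.subset_genes(genes)
    variances = sub.values.var(axis=1)
    keep = variances > 0
    if keep.sum() < 2:
        raise ValueError("need >= 2 module genes with nonzero variance")
    values = sub.values[keep]
    control_idx = np.flatnonzero(sub.group_mask(CONTROL))
    case_idx = np.flatnonzero(sub.group_mask(CASE))
    if len(control_idx) < n_per_class or len(case_idx) < n_per_class:
        raise ValueError(
            f"both classes need >= {n_per_class} samples "
            f"(control={len(control_idx)}, case={len(case_idx)})"
        )

    tp = fn = tn = fp = 0
    ncomp_used, var_used, below = [], [], []
    prev_sens = prev_spec = None
    reps = 0
    while reps < max_reps:
        for _ in range(10):
            if reps >= max_reps:
                break
            ctrl = rng.choice(control_idx, n_per_class, replace=False)
            case = rng.choice(case_idx, n_per_class, replace=False)
            cols = np.concatenate([ctrl, case])
            y = np.concatenate([np.zeros(n_per_class, int), np.ones(n_per_class, int)])
            x = values[:, cols].T  # samples x genes
            sd = x.std(axis=0)
            sd[sd == 0] = 1.0
            x = (x - x.mean(axis=0)) / sd
            pca = PCA(n_components=min(max_components, x.shape[0], x.shape[1]))
            pcs_full = pca.fit_transform(x)
            cum = np.cumsum(pca.explained_variance_ratio_)
            reach = np.flatnonzero(cum >= var_target)
            if reach.size:
                k = int(reach[0]) + 1
                below.append(False)
            else:
                k = len(cum)
                below.append(True)
            ncomp_used.append(k)
            var_used.append(float(cum[k - 1]))
            preds = _loo_nearest_centroid(pcs_full[:, :k], y)
            tp += int(((preds == 1) & (y == 1)).sum())
            fn += int(((preds == 0) & (y == 1)).sum())
            tn += int(((preds == 0) & (y == 0)).sum())
            fp += int(((preds == 1) & (y == 0)).sum())
            reps += 1
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
        if prev_sens is not None and abs(sens - prev_sens) < tol and abs(
            spec - prev_spec
        ) < tol:
            break
        prev_sens, prev_spec = sens, spec

    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    corrected = 0 in (tp, fn, tn, fp)
    if corrected:
        tp_, fn_, tn_, fp_ = (c + 0.5 for c in (tp, fn, tn, fp))
    else:
        tp_, fn_, tn_, fp_ = tp, fn, tn, fp
    dor_value = (tp_ / fn_) * (tn_ / fp_)
    return DiagnosticResult(
        sensitivity=sens,
        specificity=spec,
        dor=float(dor_value),
        n_components=int(round(np.mean(ncomp_used))),
        variance_explained=float(np.mean(var_used)),
        n_reps=reps,
        below_variance_target=bool(np.mean(below) > 0.5),
        dor_corrected=corrected,
    )


# -- prognostic ------------------------------------------------------------

@dataclass
class PrognosticResult:
    betas: dict[str, float]
    pi: dict[str, float]  # subject -> prognostic index
    groups: dict[str, str] = field(default_factory=dict)  # subject -> low/high
    logrank_p: float | None = None
    hazard_ratio: float | None = None
    km_curves: pd.DataFrame | None = None
    ridge_stabilized: bool = False

    def to_dict(self) -> dict:
        return {
            "betas": self.betas,
            "logrank_p": self.logrank_p,
            "hazard_ratio": self.hazard_ratio,
            "n_low": sum(1 for g in self.groups.values() if g == "low"),
            "n_high": sum(1 for g in self.groups.values() if g == "high"),
            "ridge_stabilized": self.ridge_stabilized,
        }


def fit_cox_pi(
    study: ExpressionStudy,
    clinical: ClinicalTable,
    genes: list[str],
) -> PrognosticResult:
    """Fit a multivariate Cox model over module genes; compute the PI.

    Gene expression is z-scored across the subjects that have clinical
    records; zero-variance genes are dropped with a warning. The prognostic
    index of subject j is PI_j = sum_i beta_i x_ij over the retained genes.
    On partial-likelihood non-convergence (e.g. complete separation) the fit
    is retried with an L2 penalty and flagged ``ridge_stabilized``.
    """
    sub = study.subset_genes(genes)
    subjects = [s for s in sub.samples if s in clinical.records]
    if len(subjects) < 10:
        raise ValueError(f"need >= 10 subjects with clinical records, got {len(subjects)}")
    times, events = clinical.times_events(subjects)
    if events.sum() < 1:
        raise ValueError("need at least one observed event")

    cols = [sub.samples.index(s) for s in subjects]
    x = sub.values[:, cols]  # genes x subjects
    sd = x.std(axis=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all module genes have zero variance among subjects")
    if (~keep).any():
        logger.warning("dropping %d zero-variance gene(s) from Cox fit", int((~keep).sum()))
    z = (x[keep] - x[keep].mean(axis=1, keepdims=True)) / sd[keep, None]
    kept_genes = [g for g, k in zip(sub.genes, keep) if k]

    df = pd.DataFrame(z.T, columns=kept_genes)
    df["time"] = times
    df["event"] = events

    ridge = False
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, Exception) as exc:  # noqa: BLE001 - lifelines raises mixed types
        logger.warning("Cox fit failed (%s); retrying with L2 penalty", type(exc).__name__)
        cph = CoxPHFitter(penalizer=0.1)
        cph.fit(df, duration_col="time", event_col="event")
        ridge = True

    betas = {g: float(cph.params_[g]) for g in kept_genes}
    beta_vec = np.array([betas[g] for g in kept_genes])
    pi_values = beta_vec @ z
    return PrognosticResult(
        betas=betas,
        pi={s: float(v) for s, v in zip(subjects, pi_values)},
        ridge_stabilized=ridge,
    )


def stratify_and_test(
    pr: PrognosticResult,
    clinical: ClinicalTable,
    quantile: float = 0.5,
) -> PrognosticResult:
    """Split subjects at a PI quantile (ties to low) and compare survival.

    Fills ``groups``, the two Kaplan-Meier step tables, the two-group
    log-rank p and the hazard ratio (high vs low) from a univariate Cox
    fit on the group indicator.
    """
    subjects = list(pr.pi)
    pis = np.array([pr.pi[s] for s in subjects])
    cut = float(np.quantile(pis, quantile))
    groups = {s: ("high" if p > cut else "low") for s, p in zip(subjects, pis)}
    n_low = sum(1 for g in groups.values() if g == "low")
    n_high = len(groups) - n_low
    if n_low == 0 or n_high == 0:
        raise ValueError("risk-group split left one group empty")

    times, events = clinical.times_events(subjects)
    high = np.array([groups[s] == "high" for s in subjects])

    lr = logrank_test(times[high], times[~high], events[high], events[~high])

    cox_df = pd.DataFrame({"time": times, "event": events, "high": high.astype(int)})
    cph = CoxPHFitter()
    cph.fit(cox_df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["high"]))

    curves = []
    for name, mask in (("low", ~high), ("high", high)):
        km = KaplanMeierFitter()
        km.fit(times[mask], events[mask], label=name)
        tbl = km.event_table
        surv = km.survival_function_.iloc[:, 0]
        curves.append(
            pd.DataFrame(
                {
                    "time": surv.index.to_numpy(dtype=float),
                    "at_risk": tbl["at_risk"].to_numpy(dtype=int),
                    "survival": surv.to_numpy(dtype=float),
                    "group": name,
                }
            )
        )
    pr.groups = groups
    pr.logrank_p = float(lr.p_value)
    pr.hazard_ratio = hr
    pr.km_curves = pd.concat(curves, ignore_index=True)
    return pr


# -- over-representation & list overlap ------------------------------------

def ora_fisher(
    query: set[str],
    annotations: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher-exact enrichment per annotation with BH correction.

    The query must lie within the universe; each annotation is intersected
    with the universe before forming the 2x2 table.
    """
    universe = {g.upper() for g in universe}
    if not universe:
        raise ValueError("empty universe")
    query = {g.upper() for g in query}
    if not query <= universe:
        raise ValueError("query genes must be a subset of the universe")

    rows = []
    for name, ann in annotations.items():
        ann = {g.upper() for g in ann} & universe
        a = len(query & ann)
        b = len(query) - a
        c = len(ann) - a
        d = len(universe) - len(query) - c
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"annotation": name, "overlap": a, "set_size": len(ann), "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
        df["significant"] = df["p_adj"] < alpha
    return df


def list_overlap(
    dips: list[str], reference_lists: dict[str, set[str]]
) -> pd.DataFrame:
    """Per reference list: overlap size, fraction of DIPs covered, members."""
    dip_set = {d.upper() for d in dips}
    rows = []
    for name, ref in reference_lists.items():
        hit = sorted(dip_set & {g.upper() for g in ref})
        rows.append(
            {
                "list": name,
                "overlap": len(hit),
                "fraction": len(hit) / len(dip_set) if dip_set else 0.0,
                "members": ",".join(hit),
            }
        )
    return pd.DataFrame(rows)
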