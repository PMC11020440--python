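"""Benchmark filters and performance metrics for fitness predictors.

Evaluation of a predictor against deep-mutational-scanning fitness data
follows a fixed recipe: filter the experimental set (drop
hyper-complementing variants whose assay fitness exceeds a cutoff;
floor negative fitness at zero and drop high-noise measurements), then
report rank and linear correlations (Kendall tau-b, Spearman, Pearson)
plus the root-mean-square deviation.  Against clinical labels the
binary metrics are sensitivity, specificity, balanced accuracy and
AUC-ROC, with the orientation fixed by the fitness convention: a LOW
predicted score calls a variant pathogenic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BenchmarkSet",
    "MetricsReport",
    "HYPERCOMPLEMENTING_CUTOFF",
    "SE_MAX",
    "filter_hypercomplementing",
    "filter_floor_and_se",
    "correlation_metrics",
    "classification_metrics",
    "auc_roc",
]

#: Default assay-fitness cutoff above which variants are discarded.
HYPERCOMPLEMENTING_CUTOFF = 1.36

#: Default maximum tolerated standard error of an experimental fitness value.
SE_MAX = 0.3

PATHOGENIC = "pathogenic"
BENIGN = "benign"


@dataclass(frozen=True)
class BenchmarkSet:
    """Per-variant predictions paired with experimental ground truth.

    ``table`` columns: ``pred`` (predicted score), ``exp``
    (experimental fitness); optional ``se`` (standard error of the
    experiment) and ``label`` (clinical annotation, 'pathogenic' or
    'benign').  ``filter_log`` records what each filter removed.
    """

    table: pd.DataFrame
    filter_log: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if "pred" not in self.table.columns or "exp" not in self.table.columns:
            raise ValueError("benchmark table needs 'pred' and 'exp' columns")
        if "label" in self.table.columns:
            labels = set(self.table["label"].dropna())
            bad = labels - {PATHOGENIC, BENIGN}
            if bad:
                raise ValueError(f"unknown clinical labels: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class MetricsReport:
    """All metrics of one predictor on one benchmark."""

    kendall: float | None = None
    spearman: float | None = None
    pearson: float | None = None
    rmsd: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    bacc: float | None = None
    auc_roc: float | None = None
    n: int = 0
    filter_log: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in ("kendall", "spearman", "pearson", "rmsd",
                      "sensitivity", "specificity", "bacc", "auc_roc", "n")
        }


# ---------------------------------------------------------------------------
# Dataset filters
# ---------------------------------------------------------------------------


def filter_hypercomplementing(
    bench: BenchmarkSet,
    cutoff: float = HYPERCOMPLEMENTING_CUTOFF,
) -> BenchmarkSet:
    """Drop variants whose experimental fitness is strictly above ``cutoff``.

    Variants with strongly increased fitness in complementation assays
    tend to behave differently in the native organism, so they are
    excluded from correlation benchmarks.  The boundary is strict: a
    value exactly at the cutoff is kept.
    """
    if not np.isfinite(cutoff):
        kept = bench.table.copy()
        removed = 0
    else:
        keep = bench.table["exp"] <= cutoff
        removed = int((~keep).sum())
        kept = bench.table[keep].copy()
    if kept.empty:
        warnings.warn("all variants removed by the hyper-complementing filter", stacklevel=2)
    log = bench.filter_log + (
        f"hypercomplementing(cutoff={cutoff}): removed {removed} of {len(bench)}",
    )
    return BenchmarkSet(table=kept, filter_log=log)


def filter_floor_and_se(bench: BenchmarkSet, se_max: float = SE_MAX) -> BenchmarkSet:
    """Floor negative experimental fitness at zero; drop noisy rows.

    Rows whose experimental standard error strictly exceeds ``se_max``
    are removed (a value exactly at the threshold is kept).  Without an
    ``se`` column only the flooring applies, with a warning.
    """
    table = bench.table.copy()
    n_floored = int((table["exp"] < 0).sum())
    table.loc[table["exp"] < 0, "exp"] = 0.0
    if "se" in table.columns:
        keep = table["se"] <= se_max
        removed = int((~keep).sum())
        table = table[keep].copy()
        log_entry = (
            f"floor_and_se(se_max={se_max}): floored {n_floored}, removed {removed}"
        )
    else:
        warnings.warn(
            "no standard-error column; SE exclusion skipped, flooring applied",
            stacklevel=2,
        )
        log_entry = f"floor_and_se: floored {n_floored}, no SE column"
    return BenchmarkSet(table=table, filter_log=bench.filter_log + (log_entry,))


# ---------------------------------------------------------------------------
# Correlation metrics
# ---------------------------------------------------------------------------


def correlation_metrics(pred, exp) -> MetricsReport:
    """Kendall tau-b, Spearman, Pearson and RMSD of predictions vs data.

    Kendall uses the tie-corrected tau-b variant (deep-mutagenesis data
    is heavy in ties); Spearman uses mid-ranks.  RMSD is the root mean
    squared difference on the native score scales.
    """
    pred = np.asarray(pred, dtype=float)
    exp = np.asarray(exp, dtype=float)
    if pred.shape != exp.shape or pred.ndim != 1:
        raise ValueError("pred and exp must be 1-D arrays of equal length")
    if pred.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(pred) == 0 or np.ptp(exp) == 0:
        raise ValueError("constant input: rank correlations are undefined")
    kendall = stats.kendalltau(pred, exp, variant="b").statistic
    spearman = stats.spearmanr(pred, exp).statistic
    pearson = stats.pearsonr(pred, exp).statistic
    rmsd = float(np.sqrt(np.mean((pred - exp) ** 2)))
    return MetricsReport(
        kendall=float(kendall), spearman=float(spearman),
        pearson=float(pearson), rmsd=rmsd, n=pred.size,
    )


# ---------------------------------------------------------------------------
# Classification metrics
# ---------------------------------------------------------------------------


def _split_by_label(pred, labels) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    labels = np.asarray(labels)
    bad = set(labels) - {PATHOGENIC, BENIGN}
    if bad:
        raise ValueError(f"unknown labels: {sorted(bad)}")
    patho = pred[labels == PATHOGENIC]
    benign = pred[labels == BENIGN]
    if patho.size == 0 or benign.size == 0:
        raise ValueError("both classes must be nonempty")
    return patho, benign


def classification_metrics(pred, labels, threshold: float) -> MetricsReport:
    """Sensitivity, specificity and balanced accuracy at a threshold.

    Orientation follows the fitness convention: a score BELOW the
    threshold calls the variant pathogenic (low fitness = deleterious).
    Sensitivity is recall on the pathogenic class, specificity recall
    on the benign class, BACC their mean.
    """
    patho, benign = _split_by_label(pred, labels)
    sensitivity = float((patho < threshold).mean())
    specificity = float((benign >= threshold).mean())
    bacc = 0.5 * (sensitivity + specificity)
    return MetricsReport(
        sensitivity=sensitivity, specificity=specificity, bacc=bacc,
        n=patho.size + benign.size,
    )


def auc_roc(pred, labels) -> float:
    """Area under the ROC curve, pathogenic-is-positive, low-score-positive.

    Computed by the rank (Mann-Whitney) formulation, which handles tied
    scores by mid-ranks: the AUC is the probability that a random
    pathogenic variant scores below a random benign one (ties count
    one half).
    """
    patho, benign = _split_by_label(pred, labels)
    ranks = stats.rankdata(np.concatenate([patho, benign]))
    n1, n0 = patho.size, benign.size
    # U statistic for "pathogenic scores lower than benign"
    r1 = ranks[:n1].sum()
    u_greater = r1 - n1 * (n1 + 1) / 2.0      # pairs where pathogenic > benign
    u_lower = n1 * n0 - u_greater
    return float(u_lower / (n1 * n0))
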