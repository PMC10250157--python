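"""Classification metrics, Friedman rank comparison, cross-organism matrix.

Metric conventions: the positive class is ``true_site``; recall =
TP/(TP+FN), precision = TP/(TP+FP), accuracy = (TP+TN)/total, F1 = harmonic
mean of precision and recall.  Ratios with a zero denominator are reported
as ``None`` (undefined), never silently as 0.

The Friedman test compares m algorithms over k independent tests: within
each test the accuracies are converted to ranks (rank 1 = best, ties
averaged); the chi-square statistic with m-1 degrees of freedom uses the
standard rank-sum form with tie correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EvaluationError
from .models import ArchitectureSpec, ModelWeights, predict
from .seqdata import SpliceDataset


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricSet:
    """Metrics in [0, 1]; ``None`` marks an undefined (0/0) ratio."""

    recall: float | None
    precision: float | None
    accuracy: float | None
    f1: float | None

    def as_percent(self, decimals: int = 2) -> dict[str, float | None]:
        return {
            k: None if v is None else round(100.0 * v, decimals)
            for k, v in vars(self).items()
        }


def confusion_counts(
    true_labels: Sequence[int] | np.ndarray, predicted_labels: Sequence[int] | np.ndarray
) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with 1 = true_site as the positive class.

    Accepts integer labels (0/1) or the string labels used by datasets.
    """
    t = _as_binary(true_labels)
    p = _as_binary(predicted_labels)
    if t.shape != p.shape:
        raise EvaluationError(
            f"label vectors differ in length: {t.shape[0]} vs {p.shape[0]}"
        )
    return ConfusionCounts(
        TP=int(((t == 1) & (p == 1)).sum()),
        TN=int(((t == 0) & (p == 0)).sum()),
        FP=int(((t == 0) & (p == 1)).sum()),
        FN=int(((t == 1) & (p == 0)).sum()),
    )


def _as_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UO":
        mapping = {"true_site": 1, "false_site": 0, "true": 1, "false": 0}
        try:
            arr = np.array([mapping[str(v)] for v in arr], dtype=np.int64)
        except KeyError as exc:
            raise EvaluationError(f"unknown label {exc.args[0]!r}") from exc
    arr = arr.astype(np.int64).ravel()
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise EvaluationError("labels must be binary (0 = false_site, 1 = true_site)")
    return arr


def metrics(c: ConfusionCounts) -> MetricSet:
    recall = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else None
    precision = c.TP / (c.TP + c.FP) if (c.TP + c.FP) else None
    accuracy = (c.TP + c.TN) / c.total if c.total else None
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None if (precision is None or recall is None) else 0.0
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricSet(recall=recall, precision=precision, accuracy=accuracy, f1=f1)


# ---------------------------------------------------------------------------
# Friedman rank comparison


@dataclass
class RankTable:
    """m algorithms x k tests of accuracies with per-test ranks."""

    accuracies: np.ndarray  # (m, k)
    algorithms: list[str]
    ranks: np.ndarray  # (m, k), rank 1 = highest accuracy, ties averaged

    @property
    def mean_ranks(self) -> np.ndarray:
        return self.ranks.mean(axis=1)


def rank_table(
    accuracies: np.ndarray | pd.DataFrame, algorithms: Sequence[str] | None = None
) -> RankTable:
    if isinstance(accuracies, pd.DataFrame):
        algorithms = list(accuracies.index)
        acc = accuracies.to_numpy(dtype=float)
    else:
        acc = np.asarray(accuracies, dtype=float)
        if algorithms is None:
            algorithms = [f"alg{i + 1}" for i in range(acc.shape[0])]
    if acc.ndim != 2:
        raise EvaluationError("accuracy table must be 2-D (algorithms x tests)")
    # rank within each test (column); highest accuracy -> rank 1
    ranks = np.apply_along_axis(lambda col: stats.rankdata(-col), 0, acc)
    return RankTable(accuracies=acc, algorithms=list(algorithms), ranks=ranks)


@dataclass
class FriedmanResult:
    statistic: float
    p_value: float
    m: int  # number of algorithms
    k: int  # number of independent tests
    mean_ranks: dict[str, float]


def friedman_test(table: RankTable | np.ndarray | pd.DataFrame) -> FriedmanResult:
    """Standard Friedman chi-square test over an m x k accuracy table.

    Uses the rank-sum statistic with tie correction and the chi-square
    approximation with m - 1 degrees of freedom; an all-tied table yields
    statistic 0 and p-value 1.
    """
    if not isinstance(table, RankTable):
        table = rank_table(table)
    m, k = table.accuracies.shape
    if m < 2 or k < 2:
        raise EvaluationError(
            f"need at least 2 algorithms and 2 tests, got m={m}, k={k}"
        )
    rank_sums = table.ranks.sum(axis=1)  # R_i over tests
    chi = (12.0 / (k * m * (m + 1))) * float((rank_sums**2).sum()) - 3.0 * k * (m + 1)
    # tie correction: within each test, sum of (t^3 - t) over tie groups
    ties = 0.0
    for j in range(k):
        _, counts = np.unique(table.accuracies[:, j], return_counts=True)
        ties += float((counts**3 - counts).sum())
    correction = 1.0 - ties / (k * (m**3 - m))
    if correction <= 0:  # every test fully tied
        statistic = 0.0
        p_value = 1.0
    else:
        statistic = chi / correction
        if statistic <= 0:
            statistic = 0.0
            p_value = 1.0
        else:
            p_value = float(stats.chi2.sf(statistic, df=m - 1))
    return FriedmanResult(
        statistic=float(statistic),
        p_value=float(p_value),
        m=m,
        k=k,
        mean_ranks={a: float(r) for a, r in zip(table.algorithms, table.mean_ranks)},
    )


def friedman_report(result: FriedmanResult) -> pd.DataFrame:
    """Algorithm/rank/mean-rank table, best (lowest mean rank) first."""
    rows = sorted(result.mean_ranks.items(), key=lambda kv: (kv[1], kv[0]))
    return pd.DataFrame(
        {
            "Algorithm": [a for a, _ in rows],
            "Rank": np.arange(1, len(rows) + 1),
            "Mean rank": [round(r, 2) for _, r in rows],
        }
    )


# ---------------------------------------------------------------------------
# cross-organism generalizability


def cross_organism_matrix(
    model_map: Mapping[str, tuple[ArchitectureSpec, ModelWeights]],
    dataset_map: Mapping[str, SpliceDataset],
) -> tuple[pd.DataFrame, dict[tuple[str, str], MetricSet]]:
    """Evaluate every organism's model on every organism's dataset.

    Returns an accuracy DataFrame (rows = training organism of the model,
    columns = test organism of the dataset; the diagonal is the self-test)
    plus the full MetricSet per cell.
    """
    if not model_map or not dataset_map:
        raise EvaluationError("need at least one model and one dataset")
    encoded = {
        org: (ds.encode(), ds.labels()) for org, ds in dataset_map.items()
    }
    acc = pd.DataFrame(
        index=list(model_map), columns=list(dataset_map), dtype=float
    )
    cells: dict[tuple[str, str], MetricSet] = {}
    for train_org, (spec, weights) in model_map.items():
        for test_org, (x, y) in encoded.items():
            if x.shape[1] != spec.input_len:
                raise EvaluationError(
                    f"model {train_org!r} expects length {spec.input_len}, "
                    f"dataset {test_org!r} has length {x.shape[1]}"
                )
            batch = predict(spec, weights, x)
            mset = metrics(confusion_counts(y, batch.predicted_labels))
            cells[(train_org, test_org)] = mset
            acc.loc[train_org, test_org] = mset.accuracy
    return acc, cells
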