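"""Evaluation statistics for screening runs.

Confusion-matrix metrics (accuracy, TPR, precision, MCC), rank-based ROC
AUC, the prediction-versus-random enrichment ratio in its two equivalent
algebraic forms, per-case summary-table aggregation, and reconstruction of
integer confusion counts from printed summary metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigError, UndefinedMetricError

CASE_TABLE_COLUMNS = ["name", "auc", "accuracy", "tpr", "precision", "mcc", "pos_num", "neg_num"]


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (matches printed-table formatting)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ConfigError(f"negative confusion count: {self}")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    accuracy: float
    tpr: float
    precision: float
    mcc: float


def confusion(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Count TP/FP/TN/FN with predicted-positive = score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ConfigError("scores and labels must have the same length")
    if not set(np.unique(labels)).issubset({0, 1}):
        raise ConfigError("labels must be binary 0/1")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def metrics_from_counts(c: ConfusionCounts) -> Metrics:
    """Standard definitions; zero-denominator metrics come back as NaN
    (a flagged undefined sentinel, never silently 0)."""
    accuracy = (c.tp + c.tn) / c.total if c.total else math.nan
    tpr = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else math.nan
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else math.nan
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom) if denom else math.nan
    return Metrics(accuracy=accuracy, tpr=tpr, precision=precision, mcc=mcc)


def roc_auc(scores, labels) -> float:
    """Rank (Mann-Whitney) AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not set(np.unique(labels)).issubset({0, 1}):
        raise ConfigError("labels must be binary 0/1")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC undefined with a single class")
    ranks = rankdata(scores)  # average ranks handle ties
    rank_sum_pos = float(np.sum(ranks[labels == 1]))
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


@dataclass(frozen=True)
class RatioReport:
    """Enrichment bookkeeping: selected actives vs selected overall."""

    n_sel_active: int
    n_total_active: int
    nn_sel: int
    n_all: int
    cutoff: float | None = None

    def __post_init__(self):
        if not (0 <= self.n_sel_active <= self.n_total_active <= self.n_all):
            raise ConfigError("require 0 <= N_sel_active <= N_total_active <= N_all")
        if not (self.n_sel_active <= self.nn_sel <= self.n_all):
            raise ConfigError("require N_sel_active <= NN_sel <= N_all")
        if self.nn_sel == 0:
            raise UndefinedMetricError("ratio undefined: no compounds selected")

    @property
    def p_tpr(self) -> float:
        return self.n_sel_active / self.n_total_active

    @property
    def random_rate(self) -> float:
        return self.nn_sel / self.n_all

    @property
    def ratio(self) -> float:
        """(N_sel/N_total) / (NN_sel/N_all); equal to the
        (N_sel/NN_sel) / (N_total/N_all) form, asserted at construction-time
        via ratio_alt."""
        return self.p_tpr / self.random_rate

    @property
    def ratio_alt(self) -> float:
        return (self.n_sel_active / self.nn_sel) / (self.n_total_active / self.n_all)


def prediction_random_ratio(
    n_sel_active: int, n_total_active: int, nn_sel: int, n_all: int,
    cutoff: float | None = None,
) -> RatioReport:
    """Build a RatioReport and assert both algebraic forms agree."""
    report = RatioReport(
        n_sel_active=n_sel_active, n_total_active=n_total_active,
        nn_sel=nn_sel, n_all=n_all, cutoff=cutoff,
    )
    if not math.isclose(report.ratio, report.ratio_alt, rel_tol=1e-9):
        raise AssertionError("the two ratio forms disagree beyond float error")
    return report


def ratio_from_screening(result, active_ids: set[str], cutoff: float) -> RatioReport:
    """Compute the enrichment ratio directly from a ranked screening result."""
    n_total_active = len(active_ids)
    if n_total_active == 0:
        raise UndefinedMetricError("no active compounds")
    selected = [cid for cid, s in result.rows if s >= cutoff]
    return prediction_random_ratio(
        n_sel_active=sum(1 for cid in selected if cid in active_ids),
        n_total_active=n_total_active,
        nn_sel=len(selected),
        n_all=len(result.rows),
        cutoff=cutoff,
    )


# ---------------------------------------------------------------------------
# per-case summary tables
# ---------------------------------------------------------------------------


def read_case_table(path) -> pd.DataFrame:
    """Read a per-case metric table (TSV, header row, Table-1 column order)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.strip().lower().replace(" ", "_") for c in df.columns]
    missing = set(CASE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"case table missing columns {sorted(missing)}")
    return df[CASE_TABLE_COLUMNS]


def summarize_cases(rows: pd.DataFrame, ndigits: int | None = None) -> dict[str, float]:
    """Arithmetic column means of the numeric columns; optional half-up
    rounding to ndigits for comparison against printed tables."""
    if len(rows) == 0:
        raise ConfigError("no case rows to summarize")
    out = {}
    for col in rows.columns:
        if col == "name":
            continue
        mean = float(np.mean(rows[col].to_numpy(dtype=float)))
        out[col] = round_half_up(mean, ndigits) if ndigits is not None else mean
    return out


def reconstruct_counts(
    tpr: float, precision: float, pos_num: int, neg_num: int
) -> ConfusionCounts:
    """Rebuild integer confusion counts from printed summary metrics.

    TP = round(TPR x Pos); predicted positives = round(TP / precision);
    FP, FN, TN by subtraction.  Raises if any count comes out negative.
    """
    if not (0 <= tpr <= 1) or not (0 < precision <= 1):
        raise ConfigError("tpr must be in [0,1] and precision in (0,1]")
    tp = int(round(tpr * pos_num))
    predicted_pos = int(round(tp / precision))
    fp = predicted_pos - tp
    fn = pos_num - tp
    tn = neg_num - fp
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
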