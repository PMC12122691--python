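"""Sliding-window evaluation, score aggregation, and paired-model statistics.

A model trained on 3-s windows is applied to longer excerpts by scoring
overlapping 3-s windows at a 1-s stride and combining the per-window
softmax score vectors with one of three rules:

* mean — column-wise average of the score vectors, then argmax;
* max — column-wise maximum, then argmax (a single confident window can
  decide the outcome);
* majority — per-window argmax first, then the modal class, ties broken
  by the earliest window's prediction among the tied classes.

Two models evaluated on the same items are compared with McNemar's test
on their binary correct/incorrect outcome arrays (exact binomial on the
discordant pairs by default; chi-square with continuity correction as
the large-sample alternative).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar


@dataclass
class WindowPredictions:
    """Per-window class-score vectors for one evaluation excerpt.

    scores: [n_windows, n_classes], each row a softmax distribution in
    temporal order.
    """

    scores: np.ndarray
    true_label: int

    def __post_init__(self):
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        sums = self.scores.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=0.02):
            raise ValueError(f"score rows must sum to ~1, got sums {sums}")

    @property
    def n_windows(self) -> int:
        return self.scores.shape[0]

    @property
    def n_classes(self) -> int:
        return self.scores.shape[1]


@dataclass
class AggregationResult:
    method: str
    predicted_class: int
    per_class_evidence: np.ndarray


@dataclass
class McNemarResult:
    n_01: int          # A wrong, B right
    n_10: int          # A right, B wrong
    statistic: float
    p_value: float
    method: str


@dataclass
class AccuracyBreakdown:
    overall: float
    by_song: dict = field(default_factory=dict)
    by_subject: dict = field(default_factory=dict)
    by_length: dict = field(default_factory=dict)


def sliding_window_scores(
    predict_fn,
    eeg_excerpt: np.ndarray,
    fs: float,
    true_label: int,
    window_seconds: float = 3.0,
    stride_seconds: float = 1.0,
) -> WindowPredictions:
    """Score overlapping windows of a long excerpt in temporal order.

    ``predict_fn`` maps a [n, channels, window] stack to [n, K] softmax
    rows.  A T-second excerpt at a 1-s stride yields T - window + 1
    windows.
    """
    W = int(round(window_seconds * fs))
    stride = int(round(stride_seconds * fs))
    S = eeg_excerpt.shape[1]
    if S < W:
        raise ValueError(f"excerpt of {S} samples shorter than window {W}")
    starts = np.arange(0, S - W + 1, stride)
    windows = np.stack([eeg_excerpt[:, s : s + W] for s in starts])
    return WindowPredictions(scores=predict_fn(windows), true_label=true_label)


def aggregate_mean(wp: WindowPredictions) -> AggregationResult:
    """Column-wise average of score vectors; lowest index wins exact ties."""
    ev = wp.scores.mean(axis=0)
    return AggregationResult("mean", int(np.argmax(ev)), ev)


def aggregate_max(wp: WindowPredictions) -> AggregationResult:
    """Column-wise maximum over windows; the globally most confident class wins."""
    ev = wp.scores.max(axis=0)
    return AggregationResult("max", int(np.argmax(ev)), ev)


def aggregate_majority(wp: WindowPredictions) -> AggregationResult:
    """Modal per-window prediction; ties go to the earliest window's class."""
    preds = np.argmax(wp.scores, axis=1)
    counts = np.bincount(preds, minlength=wp.n_classes).astype(float)
    top = counts.max()
    tied = set(np.flatnonzero(counts == top))
    winner = next(int(p) for p in preds if int(p) in tied)
    return AggregationResult("majority", winner, counts)


AGGREGATORS = {"mean": aggregate_mean, "max": aggregate_max, "majority": aggregate_majority}


def mcnemar_test(correct_a, correct_b, method: str = "exact") -> McNemarResult:
    """Paired comparison of two classifiers' binary outcome arrays.

    exact: two-sided binomial on the discordant pairs,
    p = 2 * P(X <= min(n01, n10) | n01 + n10, 1/2), capped at 1.
    chi2: continuity-corrected chi-square statistic on the same counts.
    """
    a = np.asarray(correct_a).astype(int)
    b = np.asarray(correct_b).astype(int)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("outcome arrays must be equal-length 1-D vectors")
    n01 = int(np.sum((1 - a) * b))   # A wrong, B right
    n10 = int(np.sum(a * (1 - b)))   # A right, B wrong
    if n01 + n10 == 0:
        return McNemarResult(n01, n10, 0.0, 1.0, method)
    n11 = int(np.sum(a * b))
    n00 = int(np.sum((1 - a) * (1 - b)))
    table = [[n11, n10], [n01, n00]]
    if method == "exact":
        res = _sm_mcnemar(table, exact=True)
    elif method == "chi2":
        res = _sm_mcnemar(table, exact=False, correction=True)
    else:
        raise ValueError(f"unknown method {method!r}")
    return McNemarResult(n01, n10, float(res.statistic), min(float(res.pvalue), 1.0), method)


def chance_level(n_classes: int) -> float:
    """Expected accuracy of uniform random guessing."""
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    return 1.0 / n_classes


def accuracy_report(records) -> AccuracyBreakdown:
    """Overall and per-song / per-subject / per-length accuracy tables.

    ``records``: iterable of dicts with keys ``predicted``, ``true``,
    ``song``, ``subject`` and optionally ``length_seconds``.  Partition
    accuracies are count-weighted, so each partition's weighted mean
    equals the overall accuracy.
    """
    df = pd.DataFrame(list(records))
    required = {"predicted", "true", "song", "subject"}
    if not required.issubset(df.columns) or df.isna().any().any():
        raise ValueError(f"records need complete metadata columns {sorted(required)}")
    df["correct"] = (df["predicted"] == df["true"]).astype(float)
    out = AccuracyBreakdown(overall=float(df["correct"].mean()))
    out.by_song = df.groupby("song")["correct"].mean().to_dict()
    out.by_subject = df.groupby("subject")["correct"].mean().to_dict()
    if "length_seconds" in df.columns:
        out.by_length = df.groupby("length_seconds")["correct"].mean().to_dict()
    return out


def evaluate_lengths(
    predict_fn,
    excerpts,
    lengths=(3, 4, 5, 6, 7),
    methods=("mean", "max", "majority"),
    window_seconds: float = 3.0,
    stride_seconds: float = 1.0,
    delay_ms: float = 0.0,
):
    """Length-by-method accuracy table over tiled evaluation units.

    Each excerpt (an object with ``eeg``, ``song_id``, ``subject_id`` and
    ``fs``) is tiled into non-overlapping length-L units, offset by the
    stimulus-to-response delay; each unit is scored by sliding windows
    and aggregated with each method.  Returns (table, records) where
    ``table`` is a DataFrame indexed by length with one column per
    method, and ``records`` feed :func:`accuracy_report`.
    """
    records = []
    for L in lengths:
        for exc in excerpts:
            fs = exc.fs
            d = int(round(delay_ms * fs / 1000.0))
            unit = int(round(L * fs))
            n_units = (exc.eeg.shape[1] - d) // unit
            for u in range(n_units):
                seg = exc.eeg[:, d + u * unit : d + (u + 1) * unit]
                wp = sliding_window_scores(
                    predict_fn, seg, fs, exc.song_id, window_seconds, stride_seconds
                )
                for m in methods:
                    res = AGGREGATORS[m](wp)
                    records.append(
                        {
                            "length_seconds": L,
                            "method": m,
                            "predicted": res.predicted_class,
                            "true": exc.song_id,
                            "song": exc.song_id,
                            "subject": exc.subject_id,
                        }
                    )
    df = pd.DataFrame(records)
    df["correct"] = (df["predicted"] == df["true"]).astype(float)
    table = df.pivot_table(index="length_seconds", columns="method", values="correct")
    return table, records
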