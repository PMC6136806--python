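"""Unsupervised syllable typing from a fitted song model.

Each syllable is assigned the mixture component with maximum posterior
probability,

    z_n = argmax_k  pi_k N(x_n | mu_k, Sigma_k) / sum_j pi_j N(x_n | mu_j, Sigma_j),

treating each Gaussian as one syllable "type".  Against known labels,
agreement is scored after an optimal one-to-one matching of predicted to
true labels (Hungarian assignment on the confusion matrix), the standard
way to score unsupervised clusterings.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .similarity import SimilarityMatrix
from .song_model import SongModel

LOW_CONFIDENCE = 0.5


@dataclass(frozen=True)
class LabeledSyllable:
    segment_id: str
    label: int
    posterior: float

    @property
    def low_confidence(self) -> bool:
        return self.posterior < LOW_CONFIDENCE


def classify(model: SongModel, rows: SimilarityMatrix | np.ndarray,
             ids: list[str] | None = None) -> list[LabeledSyllable]:
    """Maximum-posterior component label for each row.

    Ties break to the lowest component index (argmax convention).
    """
    if isinstance(rows, SimilarityMatrix):
        ids = ids or rows.row_ids
        x = rows.values
    else:
        x = np.atleast_2d(np.asarray(rows, dtype=np.float64))
    if ids is None:
        ids = [str(i) for i in range(x.shape[0])]
    resp = model.responsibilities(x)
    labels = np.argmax(resp, axis=1)
    return [LabeledSyllable(segment_id=i, label=int(z), posterior=float(r[z]))
            for i, z, r in zip(ids, labels, resp)]


@dataclass(frozen=True)
class LabelReport:
    counts: dict[int, int]
    percent_correct: float | None = None
    mapping: dict[int, int] | None = None  # predicted label -> true label


def label_report(labels: list[LabeledSyllable],
                 truth: dict[str, int] | None = None) -> LabelReport:
    """Per-label counts and, given ground truth, percent correct after
    optimal one-to-one label matching."""
    counts: dict[int, int] = {}
    for s in labels:
        counts[s.label] = counts.get(s.label, 0) + 1
    if truth is None:
        return LabelReport(counts=counts)
    missing = [s.segment_id for s in labels if s.segment_id not in truth]
    if missing:
        raise ValueError(f"truth labels missing for ids: {missing[:5]}...")
    pred = np.array([s.label for s in labels])
    true = np.array([truth[s.segment_id] for s in labels])
    pred_vals, pred_inv = np.unique(pred, return_inverse=True)
    true_vals, true_inv = np.unique(true, return_inverse=True)
    confusion = np.zeros((pred_vals.size, true_vals.size), dtype=int)
    np.add.at(confusion, (pred_inv, true_inv), 1)
    rows, cols = linear_sum_assignment(-confusion)
    correct = int(confusion[rows, cols].sum())
    mapping = {int(pred_vals[r]): int(true_vals[c]) for r, c in zip(rows, cols)}
    return LabelReport(counts=counts,
                       percent_correct=100.0 * correct / len(labels),
                       mapping=mapping)


def write_label_table(path: str | Path, labels: list[LabeledSyllable],
                      segments: pd.DataFrame | None = None) -> None:
    """CSV of segment_id, onset_s, offset_s (when known), label, posterior."""
    df = pd.DataFrame({"segment_id": [s.segment_id for s in labels],
                       "label": [s.label for s in labels],
                       "posterior": [round(s.posterior, 6) for s in labels]})
    if segments is not None and {"onset_s", "offset_s"} <= set(segments.columns):
        seg = segments.reset_index(drop=True).copy()
        seg_id = seg["segment_id"] if "segment_id" in seg.columns \
            else seg.index.astype(str)
        lookup = dict(zip(seg_id.astype(str),
                          zip(seg["onset_s"], seg["offset_s"])))
        df["onset_s"] = [lookup.get(i, (np.nan, np.nan))[0]
                         for i in df["segment_id"]]
        df["offset_s"] = [lookup.get(i, (np.nan, np.nan))[1]
                          for i in df["segment_id"]]
        df = df[["segment_id", "onset_s", "offset_s", "label", "posterior"]]
    df.to_csv(path, index=False)


def read_label_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
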