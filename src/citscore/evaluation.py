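"""Cohort-level operating characteristics for CIT judgments and scores.

Rates follow field conventions: the inconclusive rate is taken over all
cases, while hit and correct-rejection rates condition on *conclusive* cases
of the corresponding truth class.  Rates are reported on the 0-100 percent
scale; empty denominators yield ``None`` (undefined), never 0 or 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .exceptions import InsufficientDataError
from .judgment import INCONCLUSIVE, RECOGNIZED, UNRECOGNIZED, Judgment
from .simulate import SessionTruth

#: Integrated-d histogram bin edges (left-closed, right-open, open extremes).
D_BIN_EDGES = [-np.inf, -0.2, 0.0, 0.2, 0.4, 0.6, np.inf]
#: Integrated-p histogram bin edges.
P_BIN_EDGES = [0.0, 0.025, 0.05, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0]


@dataclass
class CohortRates:
    """Inconclusive / hit / correct-rejection summary (percent)."""

    inconclusive_rate: float
    hit_rate: Optional[float]
    correct_rejection_rate: Optional[float]
    n_total: int
    n_conclusive_recognizing: int
    n_conclusive_unrecognizing: int


def _truth_flags(truth: Sequence) -> np.ndarray:
    return np.array(
        [t.recognizing if isinstance(t, SessionTruth) else bool(t) for t in truth]
    )


def cohort_rates(judgments: Sequence[Judgment], truth: Sequence) -> CohortRates:
    """Three-rate summary of a judged cohort.

    ``truth`` holds :class:`SessionTruth` records or booleans (True =
    recognizing).
    """
    if len(judgments) != len(truth):
        raise ValueError("judgments and truth must have equal length")
    labels = np.array([j.label for j in judgments])
    flags = _truth_flags(truth)
    n = len(labels)
    inconclusive = labels == INCONCLUSIVE
    conc_rec = (~inconclusive) & flags
    conc_unr = (~inconclusive) & ~flags
    hit = (
        100.0 * np.mean(labels[conc_rec] == RECOGNIZED) if conc_rec.any() else None
    )
    cr = (
        100.0 * np.mean(labels[conc_unr] == UNRECOGNIZED) if conc_unr.any() else None
    )
    return CohortRates(
        inconclusive_rate=100.0 * inconclusive.mean() if n else 0.0,
        hit_rate=hit,
        correct_rejection_rate=cr,
        n_total=n,
        n_conclusive_recognizing=int(conc_rec.sum()),
        n_conclusive_unrecognizing=int(conc_unr.sum()),
    )


def roc_auc(
    scores: Sequence[float], truth: Sequence, higher_means_recognizing: bool = True
) -> float:
    """Trapezoidal area under the ROC curve, tie-averaged.

    For p-type scores pass ``higher_means_recognizing=False`` (they are
    negated internally so larger always means more recognizing).
    """
    flags = _truth_flags(truth)
    if flags.all() or not flags.any():
        raise InsufficientDataError("ROC needs both truth classes present")
    s = np.asarray(scores, dtype=float)
    if not higher_means_recognizing:
        s = -s
    return float(roc_auc_score(flags.astype(int), s))


def binned_recognition_ratios(
    scores: Sequence[float],
    truth: Sequence,
    bin_edges: Sequence[float] = D_BIN_EDGES,
) -> pd.DataFrame:
    """Per-bin shares: of all examinees, and of recognizing / unrecognizing
    examinees among those whose score falls in the bin (percent).

    Bins are left-closed right-open; the last finite edge is included in the
    final bin so a p of exactly 1 is counted.  Conditional shares of empty
    bins are NaN (undefined).
    """
    s = np.asarray(scores, dtype=float)
    flags = _truth_flags(truth)
    edges = np.asarray(bin_edges, dtype=float)
    idx = np.digitize(s, edges[1:-1], right=False)
    if np.isfinite(edges[-1]):
        idx[s == edges[-1]] = len(edges) - 2  # close the top bin
    rows = []
    n_total = len(s)
    for b in range(len(edges) - 1):
        in_bin = idx == b
        n_bin = int(in_bin.sum())
        n_rec = int((in_bin & flags).sum())
        rows.append(
            {
                "bin_low": edges[b],
                "bin_high": edges[b + 1],
                "n": n_bin,
                "share_of_all": 100.0 * n_bin / n_total if n_total else np.nan,
                "share_recognizing": 100.0 * n_rec / n_bin if n_bin else np.nan,
                "share_unrecognizing": (
                    100.0 * (n_bin - n_rec) / n_bin if n_bin else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SearchingDecomposition:
    """Searching-CIT outcome counts, separating the two false-positive types:
    recognizing examinees judged as recognizing the wrong item (type 1) and
    unrecognizing examinees judged as recognizing any item (type 2)."""

    n_total: int
    hits: int
    type1_false_positives: int
    type2_false_positives: int
    misses: int
    correct_rejections: int
    inconclusives: int

    @property
    def rates(self) -> dict[str, float]:
        """Each count as a percentage of the cohort."""
        n = self.n_total or 1
        return {
            "hit": 100.0 * self.hits / n,
            "type1_false_positive": 100.0 * self.type1_false_positives / n,
            "type2_false_positive": 100.0 * self.type2_false_positives / n,
            "miss": 100.0 * self.misses / n,
            "correct_rejection": 100.0 * self.correct_rejections / n,
            "inconclusive": 100.0 * self.inconclusives / n,
        }


def searching_error_decomposition(
    judgments: Sequence[Judgment], truth: Sequence[SessionTruth]
) -> SearchingDecomposition:
    """Classify searching-CIT judgments against hidden truth.

    A recognizing case judged recognized counts as a hit only when the
    identified item matches the true relevant item.
    """
    if len(judgments) != len(truth):
        raise ValueError("judgments and truth must have equal length")
    hits = t1 = t2 = miss = cr = inc = 0
    for j, t in zip(judgments, truth):
        if j.label == INCONCLUSIVE:
            inc += 1
        elif t.recognizing:
            if j.label == RECOGNIZED:
                if j.identified_item == t.relevant_index:
                    hits += 1
                else:
                    t1 += 1
            else:
                miss += 1
        else:
            if j.label == RECOGNIZED:
                t2 += 1
            else:
                cr += 1
    return SearchingDecomposition(
        n_total=len(judgments),
        hits=hits,
        type1_false_positives=t1,
        type2_false_positives=t2,
        misses=miss,
        correct_rejections=cr,
        inconclusives=inc,
    )
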