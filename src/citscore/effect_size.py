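"""Pooled-SD effect size *d* for CIT sessions.

For one measure, with n1 responses to the relevant item and n2 responses to
the irrelevant items,

    s_p = sqrt( ((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2) )
    d   = direction * (mean_relevant - mean_irrelevant) / s_p

where s1^2, s2^2 are unbiased (n-1 denominator) variances and ``direction``
is the measure's expected response direction, so a positive d always means a
response in the expected direction to the relevant item (HR, RLL and NPV
effects are sign-flipped).  Measures are integrated by simple averaging;
missing measures are averaged over the remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .data import CITSession, ResponseMatrix
from .exceptions import DegenerateDataError, InsufficientDataError


@dataclass
class EffectSizeResult:
    """Per-measure d values, their ingredients, and the averaged d."""

    per_measure_d: dict[str, float]
    ingredients: dict[str, dict[str, float]]
    integrated_d: float


def pooled_sd(relevant_responses, irrelevant_responses) -> float:
    """Pooled standard deviation from unbiased group variances.

    Both groups need at least two observations.
    """
    x1 = np.asarray(relevant_responses, dtype=float)
    x2 = np.asarray(irrelevant_responses, dtype=float)
    n1, n2 = x1.size, x2.size
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError(
            f"pooled SD needs >=2 observations per group (got n1={n1}, n2={n2})"
        )
    s1_sq = x1.var(ddof=1)
    s2_sq = x2.var(ddof=1)
    return float(np.sqrt(((n1 - 1) * s1_sq + (n2 - 1) * s2_sq) / (n1 + n2 - 2)))


def effect_size_d(
    session_or_matrix, measure: Optional[str] = None, relevant_index: Optional[int] = None
) -> float:
    """Direction-corrected standardized mean difference for one measure.

    Accepts either a :class:`CITSession` plus a measure name, or a bare
    :class:`ResponseMatrix`.  ``relevant_index`` defaults to the session's
    designated relevant item.
    """
    if isinstance(session_or_matrix, ResponseMatrix):
        matrix = session_or_matrix
    else:
        session: CITSession = session_or_matrix
        if measure is None:
            raise ValueError("measure name required with a session argument")
        matrix = session.matrices[measure]
        if relevant_index is None:
            relevant_index = session.relevant_index
    if relevant_index is None:
        raise ValueError("relevant_index required (session has none designated)")

    rel = matrix.values[relevant_index]
    irr = np.delete(matrix.values, relevant_index, axis=0).ravel()
    s_p = pooled_sd(rel, irr)
    if s_p == 0.0:
        raise DegenerateDataError(
            f"{matrix.measure.name}: zero pooled SD, d undefined"
        )
    return float(matrix.measure.direction * (rel.mean() - irr.mean()) / s_p)


def integrate_d(per_measure_d: Mapping[str, float]) -> float:
    """Average d across present measures (missing measures simply skipped)."""
    if not per_measure_d:
        raise InsufficientDataError("no measures to integrate")
    return float(np.mean(list(per_measure_d.values())))


def session_effect_size(
    session: CITSession, relevant_index: Optional[int] = None
) -> EffectSizeResult:
    """Per-measure and integrated d for every measure present in a session."""
    if relevant_index is None:
        relevant_index = session.relevant_index
    if relevant_index is None:
        raise ValueError("relevant_index required (session has none designated)")
    per_measure: dict[str, float] = {}
    ingredients: dict[str, dict[str, float]] = {}
    for name, matrix in session.matrices.items():
        rel = matrix.values[relevant_index]
        irr = np.delete(matrix.values, relevant_index, axis=0).ravel()
        s_p = pooled_sd(rel, irr)
        ingredients[name] = {
            "n1": float(rel.size),
            "n2": float(irr.size),
            "s1_sq": float(rel.var(ddof=1)),
            "s2_sq": float(irr.var(ddof=1)),
            "s_p": s_p,
        }
        if s_p == 0.0:
            raise DegenerateDataError(f"{name}: zero pooled SD, d undefined")
        per_measure[name] = float(
            matrix.measure.direction * (rel.mean() - irr.mean()) / s_p
        )
    return EffectSizeResult(
        per_measure_d=per_measure,
        ingredients=ingredients,
        integrated_d=integrate_d(per_measure),
    )
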