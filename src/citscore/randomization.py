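"""Randomization (permutation) test for CIT response differences.

Per measure, the observed statistic is the mean response to the relevant item
minus the mean response to the irrelevant items.  B random relabelings each
pick n_reps of the n_items*n_reps cells as pseudo-relevant and yield a
generated difference the same way.  The real difference is ranked among the
generated ones in the measure's expected direction (largest-first for SCR,
smallest-first for HR/RLL/NPV) and p = x/B.

Measures are integrated by multiplying their p-values and calibrating the
product against its own permutation null: each relabeling b is assigned a
pseudo-p per measure (the self-inclusive rank of its generated difference
among all B), the per-measure pseudo-p's are multiplied, and the original
multiplied p is ranked among the B generated multiplied p's.  The same B
relabelings are applied to every measure, which preserves cross-measure
dependence in the null and is what makes the product calibration valid.

Tie and edge rules (Monte-Carlo mode): x = 1 + #{generated differences more
extreme than or tied with the real one}, so a real difference beyond every
generated one gives p = 1/B (never 0) and fully tied data give p = 1.  In
exhaustive mode the true labeling is itself one of the enumerated labelings,
so the self-inclusive count is used without the +1 (the exact permutation p).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Optional

import numpy as np

from .data import CITSession, ResponseMatrix
from .exceptions import InsufficientDataError

DEFAULT_B = 1000
#: Exhaustive enumeration is auto-selected when C(n_cells, n_reps) is at most
#: this many labelings.
DEFAULT_EXHAUSTIVE_CAP = 10_000


@dataclass
class RandomizationResult:
    """Per-measure and integrated randomization-test p-values."""

    per_measure_p: dict[str, float]
    per_measure_rank_x: dict[str, int]
    integrated_p: float
    integrated_rank_x: int
    B: int
    seed: Optional[int]
    exhaustive: bool


def n_labelings(n_items: int, n_reps: int) -> int:
    """Number of distinct relevant/irrelevant cell partitions."""
    return comb(n_items * n_reps, n_reps)


def generate_relabelings(
    n_items: int,
    n_reps: int,
    B: int = DEFAULT_B,
    seed: Optional[int] = None,
    exhaustive: bool = False,
) -> np.ndarray:
    """B subsets of n_reps cells (flat indices into the item x rep grid).

    With ``exhaustive=True`` every C(n_cells, n_reps) subset is returned
    exactly once and B is ignored.  Only the relevant/irrelevant partition
    matters for a mean difference, so subsets rather than full permutations
    are sampled.
    """
    n_cells = n_items * n_reps
    if exhaustive:
        return np.array(
            list(itertools.combinations(range(n_cells), n_reps)), dtype=np.intp
        )
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    # row-wise uniform subsets via partial argsort of random keys
    keys = rng.random((B, n_cells))
    return np.argpartition(keys, n_reps - 1, axis=1)[:, :n_reps].astype(np.intp)


def _differences(values: np.ndarray, relabelings: np.ndarray) -> np.ndarray:
    """Mean(pseudo-relevant) - mean(rest) for each relabeling row."""
    flat = values.ravel()
    total = flat.sum()
    k = relabelings.shape[1]
    n = flat.size
    sums = flat[relabelings].sum(axis=1)
    return sums / k - (total - sums) / (n - k)


def _real_difference(values: np.ndarray, relevant_index: int) -> float:
    # same arithmetic path as _differences so the true labeling ties exactly
    # with its own subset under exhaustive enumeration
    flat = values.ravel()
    total = flat.sum()
    n_reps = values.shape[1]
    n = flat.size
    s = flat[relevant_index * n_reps : (relevant_index + 1) * n_reps].sum()
    return float(s / n_reps - (total - s) / (n - n_reps))


def rank_to_p(
    real: float, generated: np.ndarray, direction: int, exhaustive: bool
) -> tuple[float, int]:
    """Rank the real difference among generated ones, in the expected direction."""
    if direction == +1:
        count = int(np.count_nonzero(generated >= real))
    else:
        count = int(np.count_nonzero(generated <= real))
    x = count if exhaustive else count + 1
    B = generated.size
    return min(x / B, 1.0), x


def randomization_p(
    matrix: ResponseMatrix,
    relevant_index: int,
    relabelings: np.ndarray,
    exhaustive: bool = False,
) -> tuple[float, int, np.ndarray]:
    """Single-measure randomization p.

    Returns ``(p, rank x, generated differences)``.
    """
    generated = _differences(matrix.values, relabelings)
    real = _real_difference(matrix.values, relevant_index)
    p, x = rank_to_p(real, generated, matrix.measure.direction, exhaustive)
    return p, x, generated


def _pseudo_ranks(generated: np.ndarray, direction: int) -> np.ndarray:
    """Self-inclusive directional rank of each generated difference among all B.

    The most extreme generated difference gets rank 1; ranks lie in [1, B].
    """
    srt = np.sort(generated)
    B = generated.size
    if direction == +1:
        # count of generated >= g_b
        return B - np.searchsorted(srt, generated, side="left")
    return np.searchsorted(srt, generated, side="right")


def integrated_randomization_p(
    session: CITSession,
    relevant_index: Optional[int] = None,
    B: int = DEFAULT_B,
    seed: Optional[int] = None,
    exhaustive: Optional[bool] = None,
    exhaustive_cap: int = DEFAULT_EXHAUSTIVE_CAP,
) -> RandomizationResult:
    """Per-measure p-values and the permutation-calibrated multiplied p.

    ``exhaustive=None`` auto-selects full enumeration when the labeling space
    has at most ``exhaustive_cap`` subsets.  The same relabelings are shared
    by all measures.  Missing measures are simply skipped.
    """
    if not session.matrices:
        raise InsufficientDataError("session has no measures")
    if relevant_index is None:
        relevant_index = session.relevant_index
    if relevant_index is None:
        raise ValueError("relevant_index required (session has none designated)")

    n_items, n_reps = session.n_items, session.n_reps
    if exhaustive is None:
        exhaustive = n_labelings(n_items, n_reps) <= exhaustive_cap
    relabelings = generate_relabelings(
        n_items, n_reps, B=B, seed=seed, exhaustive=exhaustive
    )
    B_eff = relabelings.shape[0]

    per_p: dict[str, float] = {}
    per_x: dict[str, int] = {}
    rank_rows = []
    for name, matrix in session.matrices.items():
        p, x, generated = randomization_p(
            matrix, relevant_index, relabelings, exhaustive=exhaustive
        )
        per_p[name] = p
        per_x[name] = x
        rank_rows.append((x, _pseudo_ranks(generated, matrix.measure.direction)))

    m = len(rank_rows)
    # products of integer ranks order identically to products of p = rank/B;
    # integers keep tie comparisons exact
    if (B_eff + 1) ** m < 2**62:
        orig_prod = 1
        gen_prod = np.ones(B_eff, dtype=np.int64)
        for x, ranks in rank_rows:
            orig_prod *= x
            gen_prod *= ranks.astype(np.int64)
    else:  # overflow guard for many measures / huge B
        orig_prod = float(np.prod([float(x) for x, _ in rank_rows]))
        gen_prod = np.ones(B_eff, dtype=float)
        for _, ranks in rank_rows:
            gen_prod *= ranks
    count = int(np.count_nonzero(gen_prod <= orig_prod))
    x_int = count if exhaustive else count + 1
    return RandomizationResult(
        per_measure_p=per_p,
        per_measure_rank_x=per_x,
        integrated_p=min(x_int / B_eff, 1.0),
        integrated_rank_x=x_int,
        B=B_eff,
        seed=seed,
        exhaustive=exhaustive,
    )
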