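"""Traditional Lykken scoring, the rank-based comparator method.

Within each repetition block the relevant item scores 2 if it shows the
largest direction-adjusted response among the items, 1 if the second largest,
0 otherwise; block scores are summed, so a session score lies in
[0, 2 * n_reps].  Per-measure scores are integrated by averaging.

Lykken scoring always awards points somewhere in every block, even when no
response stands out — which is why it lacks an inconclusive band and serves
here only as a comparator, with no decision thresholds attached.
"""

from __future__ import annotations

from typing import Mapping, Optional

import numpy as np

from .data import ResponseMatrix
from .exceptions import InsufficientDataError


def lykken_score(
    matrix: ResponseMatrix, relevant_index: int, seed: Optional[int] = 0
) -> int:
    """Sum of per-block 2/1/0 scores for the relevant item.

    Responses are multiplied by the measure direction first, so "largest"
    means most in the expected direction.  Ties are resolved by placing the
    relevant item uniformly at random within its tie block (seeded); exact
    ties are rare for real-valued data.
    """
    if matrix.n_items < 3:
        raise InsufficientDataError("Lykken scoring needs >= 3 items")
    adjusted = matrix.values * matrix.measure.direction
    rng = np.random.default_rng(seed)
    total = 0
    for r in range(matrix.n_reps):
        block = adjusted[:, r]
        rel = block[relevant_index]
        others = np.delete(block, relevant_index)
        greater = int(np.count_nonzero(others > rel))
        ties = int(np.count_nonzero(others == rel))
        rank = 1 + greater + (int(rng.integers(0, ties + 1)) if ties else 0)
        if rank == 1:
            total += 2
        elif rank == 2:
            total += 1
    return total


def integrate_lykken(per_measure_scores: Mapping[str, float]) -> float:
    """Average Lykken score across present measures."""
    if not per_measure_scores:
        raise InsufficientDataError("no measures to integrate")
    return float(np.mean(list(per_measure_scores.values())))
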