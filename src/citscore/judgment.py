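"""Three-way judgments for known-solution and searching CITs.

Integrated statistics are mapped to one of three labels — recognized,
inconclusive, unrecognized — using published threshold presets.  For the
effect size d, recognized lies above the upper cutoff and unrecognized below
the lower; for the randomization p the orientation is reversed (small p means
recognition).  Values exactly at a cutoff are judged inconclusive, the
conservative reading of strict inequalities on both sides.

In searching mode every item is scored as if it were the relevant one; the
decision statistic is the maximum integrated d (or minimum integrated p)
across items, and a recognized judgment also identifies the item.  Per-item
p-values are not multiplicity-corrected: family-wise error is controlled by
the stricter searching thresholds instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .data import CITSession
from .effect_size import session_effect_size
from .randomization import DEFAULT_B, integrated_randomization_p

logger = logging.getLogger(__name__)

RECOGNIZED = "recognized"
INCONCLUSIVE = "inconclusive"
UNRECOGNIZED = "unrecognized"


@dataclass(frozen=True)
class JudgmentConfig:
    """Threshold pair defining the three decision bands for one statistic.

    For ``statistic="d"``: recognized iff stat > ``recognized_cutoff``,
    unrecognized iff stat < ``unrecognized_cutoff``.  For ``statistic="p"``:
    recognized iff stat < ``recognized_cutoff``, unrecognized iff
    stat > ``unrecognized_cutoff``.
    """

    mode: str  # "known_solution" | "searching"
    statistic: str  # "d" | "p"
    recognized_cutoff: float
    unrecognized_cutoff: float
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.mode not in ("known_solution", "searching"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.statistic not in ("d", "p"):
            raise ValueError(f"unknown statistic {self.statistic!r}")


#: Published threshold presets, keyed by (mode, statistic, variant).
PRESETS: dict[tuple[str, str, str], JudgmentConfig] = {
    ("known_solution", "d", "strict"): JudgmentConfig(
        "known_solution", "d", 0.4, 0.0, "known_solution/d/strict"
    ),
    ("known_solution", "d", "lenient"): JudgmentConfig(
        "known_solution", "d", 0.3, 0.1, "known_solution/d/lenient"
    ),
    ("known_solution", "p", "strict"): JudgmentConfig(
        "known_solution", "p", 0.025, 0.6, "known_solution/p/strict"
    ),
    ("known_solution", "p", "lenient"): JudgmentConfig(
        "known_solution", "p", 0.05, 0.4, "known_solution/p/lenient"
    ),
    ("searching", "d", "strict"): JudgmentConfig(
        "searching", "d", 0.6, 0.2, "searching/d/strict"
    ),
    ("searching", "p", "strict"): JudgmentConfig(
        "searching", "p", 0.01, 0.2, "searching/p/strict"
    ),
}


def get_preset(mode: str, statistic: str, variant: str = "strict") -> JudgmentConfig:
    try:
        return PRESETS[(mode, statistic, variant)]
    except KeyError:
        raise KeyError(
            f"no preset for mode={mode!r}, statistic={statistic!r}, "
            f"variant={variant!r}"
        ) from None


@dataclass
class Judgment:
    """Three-way decision, the statistic that drove it, and (searching mode)
    the identified item."""

    label: str
    basis: str
    identified_item: Optional[int] = None
    thresholds_used: Optional[JudgmentConfig] = None


def _band(stat: float, config: JudgmentConfig) -> str:
    if config.statistic == "d":
        if stat > config.recognized_cutoff:
            return RECOGNIZED
        if stat < config.unrecognized_cutoff:
            return UNRECOGNIZED
        return INCONCLUSIVE
    if stat < config.recognized_cutoff:
        return RECOGNIZED
    if stat > config.unrecognized_cutoff:
        return UNRECOGNIZED
    return INCONCLUSIVE


def judge_known(integrated_stat: float, config: JudgmentConfig) -> Judgment:
    """Three-way judgment of an integrated statistic for a known-solution CIT."""
    if config.mode != "known_solution":
        raise ValueError("config.mode must be 'known_solution'")
    return Judgment(
        label=_band(integrated_stat, config),
        basis=config.statistic,
        thresholds_used=config,
    )


@dataclass
class SearchingScores:
    """Integrated d and p for every item scored as if it were relevant."""

    integrated_d: list[float]
    integrated_p: list[float]


def searching_scores(
    session: CITSession, B: int = DEFAULT_B, seed: Optional[int] = 0
) -> SearchingScores:
    """Score each item as the hypothetical relevant item.

    All items share the same relabelings (same B, seed), so the generated
    null differences are identical across items and only the real difference
    changes.
    """
    ds, ps = [], []
    for i in range(session.n_items):
        ds.append(session_effect_size(session, relevant_index=i).integrated_d)
        ps.append(
            integrated_randomization_p(
                session, relevant_index=i, B=B, seed=seed
            ).integrated_p
        )
    return SearchingScores(integrated_d=ds, integrated_p=ps)


def judge_searching(scores: SearchingScores, config: JudgmentConfig) -> Judgment:
    """Max-d / min-p decision across items, identifying the item if recognized.

    Ties on the decision statistic are broken toward the lowest item index,
    with a logged warning.
    """
    if config.mode != "searching":
        raise ValueError("config.mode must be 'searching'")
    if config.statistic == "d":
        values = np.asarray(scores.integrated_d)
        best = int(np.argmax(values))
        stat = float(values[best])
        n_tied = int(np.count_nonzero(values == stat))
    else:
        values = np.asarray(scores.integrated_p)
        best = int(np.argmin(values))
        stat = float(values[best])
        n_tied = int(np.count_nonzero(values == stat))
    if n_tied > 1:
        logger.warning(
            "searching decision statistic tied across %d items; "
            "choosing lowest index %d",
            n_tied,
            best,
        )
    label = _band(stat, config)
    return Judgment(
        label=label,
        basis=config.statistic,
        identified_item=best if label == RECOGNIZED else None,
        thresholds_used=config,
    )


def judge_both(
    d_stat: float,
    p_stat: float,
    d_config: JudgmentConfig,
    p_config: JudgmentConfig,
) -> Judgment:
    """Conjunctive d+p judgment: recognized (or unrecognized) only when both
    statistics agree on that label; otherwise inconclusive."""
    a = _band(d_stat, d_config)
    b = _band(p_stat, p_config)
    label = a if a == b and a in (RECOGNIZED, UNRECOGNIZED) else INCONCLUSIVE
    return Judgment(label=label, basis="both", thresholds_used=d_config)
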