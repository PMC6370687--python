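"""Statsmodels-style facade: a model object per CIT session.

``CITModel(session).fit()`` computes the effect size d, the randomization-test
p and the Lykken score for every present measure, plus their integrated
values; the returned :class:`CITResults` carries the numbers, a ``summary()``
table and judgment helpers.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .data import CITSession
from .effect_size import EffectSizeResult, session_effect_size
from .judgment import (
    Judgment,
    JudgmentConfig,
    get_preset,
    judge_both,
    judge_known,
    judge_searching,
    searching_scores,
)
from .lykken import integrate_lykken, lykken_score
from .randomization import DEFAULT_B, RandomizationResult, integrated_randomization_p


class CITResults:
    """Fitted per-session CIT statistics."""

    def __init__(
        self,
        model: "CITModel",
        effect_size: EffectSizeResult,
        randomization: RandomizationResult,
        lykken_per_measure: dict[str, int],
        lykken_integrated: float,
    ) -> None:
        self.model = model
        self.effect_size = effect_size
        self.randomization = randomization
        self.lykken_per_measure = lykken_per_measure
        self.lykken_integrated = lykken_integrated

    @property
    def integrated_d(self) -> float:
        return self.effect_size.integrated_d

    @property
    def integrated_p(self) -> float:
        return self.randomization.integrated_p

    def judge(
        self, statistic: str = "d", variant: str = "strict",
        config: Optional[JudgmentConfig] = None,
    ) -> Judgment:
        """Known-solution judgment of the integrated statistic.

        ``statistic="both"`` applies the conjunctive d+p rule.
        """
        if statistic == "both":
            return judge_both(
                self.integrated_d,
                self.integrated_p,
                get_preset("known_solution", "d", variant),
                get_preset("known_solution", "p", variant),
            )
        cfg = config or get_preset("known_solution", statistic, variant)
        stat = self.integrated_d if cfg.statistic == "d" else self.integrated_p
        return judge_known(stat, cfg)

    def to_frame(self) -> pd.DataFrame:
        """Per-measure statistics as a tidy DataFrame."""
        rows = []
        for name in self.model.session.measures:
            rows.append(
                {
                    "measure": name,
                    "d": self.effect_size.per_measure_d[name],
                    "p": self.randomization.per_measure_p[name],
                    "lykken": self.lykken_per_measure[name],
                }
            )
        rows.append(
            {
                "measure": "integrated",
                "d": self.integrated_d,
                "p": self.integrated_p,
                "lykken": self.lykken_integrated,
            }
        )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        session = self.model.session
        rel = (
            session.items[session.relevant_index]
            if session.relevant_index is not None
            else "unknown"
        )
        lines = [
            "Concealed Information Test — session statistics",
            "=" * 55,
            f"session:   {session.session_id}",
            f"items:     {len(session.items)} x {session.n_reps} repetitions",
            f"relevant:  {rel}",
            f"B:         {self.randomization.B}"
            + (" (exhaustive)" if self.randomization.exhaustive else ""),
            "-" * 55,
            f"{'measure':<12}{'d':>10}{'p':>10}{'Lykken':>10}",
        ]
        for _, row in self.to_frame().iterrows():
            lines.append(
                f"{row['measure']:<12}{row['d']:>10.3f}{row['p']:>10.3f}"
                f"{row['lykken']:>10.1f}"
            )
        lines.append("=" * 55)
        return "\n".join(lines)


class CITModel:
    """Per-session scoring model for a known-solution CIT.

    Parameters
    ----------
    session
        The CIT session to score; must designate a relevant item unless one
        is passed to :meth:`fit`.
    """

    def __init__(self, session: CITSession) -> None:
        self.session = session

    def fit(
        self,
        relevant_index: Optional[int] = None,
        B: int = DEFAULT_B,
        seed: Optional[int] = 0,
    ) -> CITResults:
        rel = relevant_index if relevant_index is not None else self.session.relevant_index
        if rel is None:
            raise ValueError(
                "session designates no relevant item; pass relevant_index "
                "or use fit_searching()"
            )
        es = session_effect_size(self.session, relevant_index=rel)
        rand = integrated_randomization_p(
            self.session, relevant_index=rel, B=B, seed=seed
        )
        lyk = {
            name: lykken_score(m, rel, seed=seed)
            for name, m in self.session.matrices.items()
        }
        return CITResults(self, es, rand, lyk, integrate_lykken(lyk))

    def fit_searching(
        self, B: int = DEFAULT_B, seed: Optional[int] = 0
    ):
        """Score every item as hypothetically relevant (searching CIT)."""
        return searching_scores(self.session, B=B, seed=seed)
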