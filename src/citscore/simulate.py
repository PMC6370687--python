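"""Synthetic CIT cohorts with the structure of a mock-crime study dataset.

The generator emulates a laboratory cohort of 152 examinees (80 who committed
a mock theft and recognize the relevant item, 72 who did not), each tested
with 5 items x 5 presentations on four autonomic measures.  Per presentation
a cell draws correlated Gaussian noise across measures; for recognizing
examinees the relevant item's cell means are shifted by the per-measure
effect size in the measure's expected direction (positive for SCR, negative
for HR/RLL/NPV), optionally decaying geometrically across repetitions
(habituation).  A configurable fraction of examinees are electrodermal
non-responders whose SCR channel is dropped (or replaced by effect-free
noise).

Effect sizes are free parameters in units of the noise SD.  The default
"paper-like" values are calibrated so the integrated-d ROC area on a default
cohort lands near 0.92; see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .data import CITSession, MeasureSpec, ResponseMatrix

#: Per-measure effect sizes (noise-SD units) of the default paper-like preset.
PAPER_LIKE_EFFECTS: dict[str, float] = {
    "SCR": 1.10,
    "HR": 0.50,
    "RLL": 0.50,
    "NPV": 0.40,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Cohort design and response-model parameters.

    Defaults mirror the emulated study: 80 recognizing + 72 unrecognizing
    examinees, 5 items x 5 repetitions, four measures, ~25% electrodermal
    non-responders.
    """

    n_recognizing: int = 80
    n_unrecognizing: int = 72
    n_items: int = 5
    n_reps: int = 5
    effect_sizes: dict = field(default_factory=lambda: dict(PAPER_LIKE_EFFECTS))
    habituation: float = 0.0  # fractional decay of the shift per repetition
    rho: float = 0.3  # pairwise cross-measure noise correlation
    nonresponder_prob: float = 0.25
    nonresponder_mode: str = "drop"  # "drop" | "noise"
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if not (0.0 <= self.habituation < 1.0):
            raise ValueError("habituation must lie in [0, 1)")
        if self.nonresponder_mode not in ("drop", "noise"):
            raise ValueError("nonresponder_mode must be 'drop' or 'noise'")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class SessionTruth:
    """Ground truth for a simulated session."""

    session_id: str
    recognizing: bool
    relevant_index: Optional[int]  # hidden truth; None for unrecognizing


def _item_labels(n_items: int) -> list[str]:
    return [f"item{i + 1}" for i in range(n_items)]


def simulate_session(
    config: SyntheticConfig,
    recognizing: bool,
    seed: Optional[int] = None,
    relevant_index: Optional[int] = None,
    session_id: str = "sim",
) -> tuple[CITSession, SessionTruth]:
    """Draw one session; returns the session and its ground truth.

    The session carries the designated relevant item (known-solution form);
    strip it for searching-CIT experiments.  ``relevant_index=None`` picks a
    uniformly random item.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_i, n_r = config.n_items, config.n_reps
    if relevant_index is None:
        relevant_index = int(rng.integers(0, n_i))

    measures = list(config.effect_sizes)
    n_m = len(measures)
    # equicorrelated noise: common factor + idiosyncratic
    z_common = rng.standard_normal((n_i, n_r))
    z_own = rng.standard_normal((n_m, n_i, n_r))
    noise = config.noise_sd * (
        np.sqrt(config.rho) * z_common[None, :, :]
        + np.sqrt(1.0 - config.rho) * z_own
    )

    nonresponder = (
        "SCR" in measures and rng.random() < config.nonresponder_prob
    )
    decay = (1.0 - config.habituation) ** np.arange(n_r)

    matrices: dict[str, ResponseMatrix] = {}
    for j, name in enumerate(measures):
        spec = (
            MeasureSpec.standard(name)
            if name in ("SCR", "HR", "RLL", "NPV")
            else MeasureSpec(name, +1)
        )
        grid = noise[j].copy()
        apply_effect = recognizing and not (nonresponder and name == "SCR")
        if apply_effect:
            shift = (
                config.effect_sizes[name] * config.noise_sd * spec.direction
            )
            grid[relevant_index] += shift * decay
        if nonresponder and name == "SCR" and config.nonresponder_mode == "drop":
            continue
        matrices[name] = ResponseMatrix(spec, grid)

    session = CITSession(
        items=_item_labels(n_i),
        matrices=matrices,
        relevant_index=relevant_index,
        session_id=session_id,
    )
    truth = SessionTruth(
        session_id=session_id,
        recognizing=recognizing,
        relevant_index=relevant_index if recognizing else None,
    )
    return session, truth


def simulate_cohort(
    config: SyntheticConfig, searching: bool = False
) -> list[tuple[CITSession, SessionTruth]]:
    """Draw a full cohort of recognizing + unrecognizing sessions.

    With ``searching=True`` the designated relevant item is stripped from the
    sessions (it stays in the truth records), emulating a searching CIT where
    the examiner does not know the relevant item.
    """
    rng = np.random.default_rng(config.seed)
    n_total = config.n_recognizing + config.n_unrecognizing
    child_seeds = rng.integers(0, 2**31 - 1, size=n_total)
    out = []
    flags = [True] * config.n_recognizing + [False] * config.n_unrecognizing
    for k, (flag, s) in enumerate(zip(flags, child_seeds)):
        session, truth = simulate_session(
            config, recognizing=flag, seed=int(s), session_id=f"sim{k + 1:04d}"
        )
        if searching:
            session.relevant_index = None
        out.append((session, truth))
    return out


def null_config(base: Optional[SyntheticConfig] = None, **overrides) -> SyntheticConfig:
    """A copy of ``base`` with all effect sizes set to zero (pure noise)."""
    base = base or SyntheticConfig()
    zeroed = {m: 0.0 for m in base.effect_sizes}
    return replace(base, effect_sizes=zeroed, **overrides)
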