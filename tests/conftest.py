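import numpy as np
import pytest

from citscore import CITSession, MeasureSpec, ResponseMatrix


def make_matrix(values, measure="SCR", direction=None):
    values = np.asarray(values, dtype=float)
    spec = (
        MeasureSpec.standard(measure)
        if direction is None
        else MeasureSpec(measure, direction)
    )
    return ResponseMatrix(spec, values)


def make_session(per_measure_values, relevant_index=0, session_id="t"):
    """Build a session from {measure: 2-D array} with auto item labels."""
    matrices = {
        name: make_matrix(vals, measure=name) for name, vals in per_measure_values.items()
    }
    n_items = next(iter(matrices.values())).n_items
    return CITSession(
        items=[f"item{i + 1}" for i in range(n_items)],
        matrices=matrices,
        relevant_index=relevant_index,
        session_id=session_id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240921)


@pytest.fixture
def random_session(rng):
    """A 4-measure 5x5 session of pure noise with item 0 designated relevant."""
    return make_session(
        {m: rng.normal(size=(5, 5)) for m in ("SCR", "HR", "RLL", "NPV")},
        relevant_index=0,
    )
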