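"""Domain types and tabular I/O for Concealed Information Test (CIT) sessions.

A CIT session presents ``n_items`` question items, each repeated ``n_reps``
times, while recording one scalar response per presentation for up to four
autonomic measures: skin conductance response (SCR), heart rate (HR),
respiration line length (RLL) and normalized pulse volume (NPV).  A recognized
item typically elicits a *larger* SCR but a *smaller* HR/RLL/NPV response, so
every measure carries an expected response direction.

Sessions are stored as long-format CSV with a small ``#``-prefixed metadata
header (item order, designated relevant item or ``unknown``, measure
directions).  Values round-trip bit-identically.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import SessionFormatError

#: Expected response direction for the four standard autonomic measures:
#: +1 means the response to a recognized item is expected to be larger than to
#: irrelevant items, -1 smaller.
DEFAULT_DIRECTIONS: dict[str, int] = {"SCR": +1, "HR": -1, "RLL": -1, "NPV": -1}

FORMAT_TAG = "cit-session v1"


@dataclass(frozen=True)
class MeasureSpec:
    """An autonomic measure and its expected response direction."""

    name: str
    direction: int

    def __post_init__(self) -> None:
        if self.direction not in (+1, -1):
            raise SessionFormatError(
                f"direction for measure {self.name!r} must be +1 or -1, "
                f"got {self.direction!r}"
            )

    @classmethod
    def standard(cls, name: str) -> "MeasureSpec":
        """Build one of the four conventional measures (SCR, HR, RLL, NPV)."""
        try:
            return cls(name, DEFAULT_DIRECTIONS[name])
        except KeyError:
            raise SessionFormatError(
                f"unknown measure {name!r}: no default direction; declare one"
            ) from None


class ResponseMatrix:
    """A complete item x repetition grid of scalar responses for one measure.

    A measure is either entirely present (a full grid) or absent from the
    session; partially missing cells are rejected rather than imputed.
    """

    def __init__(self, measure: MeasureSpec, values: np.ndarray) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise SessionFormatError(
                f"{measure.name}: response grid must be 2-D (items x reps)"
            )
        if values.shape[0] < 2:
            raise SessionFormatError(f"{measure.name}: need at least 2 items")
        if values.shape[1] < 1:
            raise SessionFormatError(f"{measure.name}: need at least 1 repetition")
        if not np.isfinite(values).all():
            raise SessionFormatError(f"{measure.name}: non-finite response value")
        self.measure = measure
        self.values = values

    @property
    def n_items(self) -> int:
        return self.values.shape[0]

    @property
    def n_reps(self) -> int:
        return self.values.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResponseMatrix):
            return NotImplemented
        return self.measure == other.measure and np.array_equal(
            self.values, other.values
        )

    def __repr__(self) -> str:
        return (
            f"ResponseMatrix({self.measure.name}, "
            f"{self.n_items} items x {self.n_reps} reps)"
        )


@dataclass
class CITSession:
    """One CIT question: item labels, per-measure response grids, metadata.

    ``relevant_index`` is the 0-based position of the designated crime-relevant
    item; it is ``None`` for searching CITs, where the relevant item (if any)
    is unknown to the examiner.
    """

    items: Sequence[str]
    matrices: Mapping[str, ResponseMatrix]
    relevant_index: Optional[int] = None
    session_id: str = "session"

    def __post_init__(self) -> None:
        self.items = list(self.items)
        self.matrices = dict(self.matrices)
        if len(self.items) < 2:
            raise SessionFormatError("a session needs at least 2 items")
        if len(set(self.items)) != len(self.items):
            raise SessionFormatError("item labels must be unique")
        if not self.matrices:
            raise SessionFormatError("a session needs at least one measure")
        reps = {m.n_reps for m in self.matrices.values()}
        if len(reps) != 1:
            raise SessionFormatError(
                f"measures disagree on repetition count: {sorted(reps)}"
            )
        for name, m in self.matrices.items():
            if name != m.measure.name:
                raise SessionFormatError(
                    f"matrix keyed {name!r} holds measure {m.measure.name!r}"
                )
            if m.n_items != len(self.items):
                raise SessionFormatError(
                    f"{name}: grid has {m.n_items} items, session has "
                    f"{len(self.items)}"
                )
        if self.relevant_index is not None and not (
            0 <= self.relevant_index < len(self.items)
        ):
            raise SessionFormatError(
                f"relevant_index {self.relevant_index} out of range"
            )

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def n_reps(self) -> int:
        return next(iter(self.matrices.values())).n_reps

    @property
    def measures(self) -> list[str]:
        return list(self.matrices)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CITSession):
            return NotImplemented
        return (
            self.items == other.items
            and self.relevant_index == other.relevant_index
            and self.session_id == other.session_id
            and self.matrices == other.matrices
        )


def _parse_header(lines: list[str]) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in lines:
        body = line.lstrip("#").strip()
        if ":" not in body:
            continue
        key, _, value = body.partition(":")
        meta[key.strip()] = value.strip()
    return meta


def read_session(path) -> CITSession:
    """Read a session from long-format CSV with a ``#`` metadata header.

    Raises :class:`SessionFormatError` on duplicate (measure, item,
    repetition) cells, ragged grids, or measures lacking a direction.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    header_lines, body_lines = [], []
    for line in text.splitlines():
        (header_lines if line.startswith("#") else body_lines).append(line)
    meta = _parse_header(header_lines)
    if "items" not in meta:
        raise SessionFormatError(f"{path}: missing 'items' metadata line")
    items = [s.strip() for s in meta["items"].split("|")]
    relevant = meta.get("relevant", "unknown")
    if relevant == "unknown":
        relevant_index: Optional[int] = None
    else:
        if relevant not in items:
            raise SessionFormatError(
                f"{path}: relevant item {relevant!r} not among items"
            )
        relevant_index = items.index(relevant)
    directions = dict(DEFAULT_DIRECTIONS)
    if meta.get("directions"):
        for part in meta["directions"].split(";"):
            name, _, sign = part.strip().partition("=")
            try:
                directions[name.strip()] = int(sign)
            except ValueError:
                raise SessionFormatError(
                    f"{path}: bad direction declaration {part!r}"
                ) from None

    df = pd.read_csv(
        io.StringIO("\n".join(body_lines)), float_precision="round_trip"
    )
    expected = {"measure", "item", "repetition", "value"}
    if set(df.columns) != expected:
        raise SessionFormatError(
            f"{path}: columns must be {sorted(expected)}, got {list(df.columns)}"
        )
    if df.duplicated(["measure", "item", "repetition"]).any():
        raise SessionFormatError(f"{path}: duplicate (measure,item,repetition) cell")
    unknown_items = set(df["item"]) - set(items)
    if unknown_items:
        raise SessionFormatError(f"{path}: items not in header: {unknown_items}")

    matrices: dict[str, ResponseMatrix] = {}
    for name, sub in df.groupby("measure", sort=False):
        name = str(name)
        if name not in directions:
            raise SessionFormatError(
                f"{path}: measure {name!r} has no declared direction"
            )
        reps = sorted(sub["repetition"].unique())
        n_reps = len(reps)
        if reps != list(range(1, n_reps + 1)):
            raise SessionFormatError(
                f"{path}: {name}: repetitions must be 1..n, got {reps}"
            )
        if len(sub) != len(items) * n_reps:
            raise SessionFormatError(
                f"{path}: {name}: ragged grid "
                f"({len(sub)} cells for {len(items)} items x {n_reps} reps)"
            )
        grid = np.empty((len(items), n_reps))
        pos = {label: i for i, label in enumerate(items)}
        grid[
            sub["item"].map(pos).to_numpy(), sub["repetition"].to_numpy() - 1
        ] = sub["value"].to_numpy()
        matrices[name] = ResponseMatrix(MeasureSpec(name, directions[name]), grid)

    return CITSession(
        items=items,
        matrices=matrices,
        relevant_index=relevant_index,
        session_id=meta.get("session_id", "session"),
    )


def write_session(session: CITSession, path) -> None:
    """Write a session to CSV; ``read_session`` reproduces it exactly."""
    relevant = (
        "unknown"
        if session.relevant_index is None
        else session.items[session.relevant_index]
    )
    directions = ";".join(
        f"{m.measure.name}={m.measure.direction:+d}"
        for m in session.matrices.values()
    )
    rows = []
    for name, matrix in session.matrices.items():
        for i, item in enumerate(session.items):
            for r in range(matrix.n_reps):
                rows.append((name, item, r + 1, matrix.values[i, r]))
    df = pd.DataFrame(rows, columns=["measure", "item", "repetition", "value"])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {FORMAT_TAG}\n")
        fh.write(f"# session_id: {session.session_id}\n")
        fh.write(f"# items: {'|'.join(session.items)}\n")
        fh.write(f"# relevant: {relevant}\n")
        fh.write(f"# directions: {directions}\n")
        # str(float) round-trips exactly in Python 3
        df.to_csv(fh, index=False, lineterminator="\n")
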