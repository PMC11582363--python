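"""Information-system container: the universe of objects × attributes.

An information system is the rough-set formalism's quadruple (U, A, Val, f):
a finite universe of objects, a finite attribute set, the attribute value
domains, and the information function mapping (object, attribute) pairs to
values. One attribute may be designated the decision (here: the four-level
Dukes stage of colorectal cancer), one the follow-up time (months), and one
the event indicator (1 = event observed, 0 = right-censored).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AttributeSpec",
    "InformationSystem",
    "SchemaError",
    "ValidationError",
    "load_information_system",
    "save_information_system",
]

ATTRIBUTE_KINDS = ("numeric", "categorical", "decision", "time", "event")


class SchemaError(ValueError):
    """The file or role mapping does not describe a readable information system."""


class ValidationError(ValueError):
    """The table violates an information-system invariant."""


@dataclass(frozen=True)
class AttributeSpec:
    """One column of the information system.

    Parameters
    ----------
    name : str
        Column label.
    kind : str
        One of ``numeric``, ``categorical``, ``decision``, ``time``, ``event``.
    value_range : tuple of (float, float), optional
        Plausible (min, max) of the attribute, e.g. the printed probe ranges
        of a microarray panel. Informational; not enforced on the data.
    """

    name: str
    kind: str = "numeric"
    value_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ATTRIBUTE_KINDS:
            raise ValidationError(f"unknown attribute kind {self.kind!r}")
        if self.value_range is not None:
            lo, hi = self.value_range
            if lo > hi:
                raise ValidationError(
                    f"attribute {self.name!r}: value_range min {lo} > max {hi}"
                )


@dataclass
class InformationSystem:
    """Objects × attributes table with designated decision/time/event columns.

    ``values`` is a dense float matrix with one row per object id and one
    column per :class:`AttributeSpec`. Categorical codes (e.g. gender 1/2)
    are stored as floats like everything else; ``kind`` records how a column
    is to be treated downstream.
    """

    object_ids: list[str]
    attributes: list[AttributeSpec]
    values: np.ndarray
    decision_attribute: str | None = None
    time_attribute: str | None = None
    event_attribute: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        n, m = self.values.shape
        if n != len(self.object_ids):
            raise ValidationError(
                f"{len(self.object_ids)} object ids but {n} value rows"
            )
        if m != len(self.attributes):
            raise ValidationError(
                f"{len(self.attributes)} attributes but {m} value columns"
            )
        if len(set(self.object_ids)) != len(self.object_ids):
            dupes = sorted(
                {x for x in self.object_ids if self.object_ids.count(x) > 1}
            )
            raise ValidationError(f"duplicate object ids: {dupes}")
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate attribute names")
        special = [
            self.decision_attribute,
            self.time_attribute,
            self.event_attribute,
        ]
        set_special = [s for s in special if s is not None]
        if len(set(set_special)) != len(set_special):
            raise ValidationError(
                "decision/time/event attributes must be distinct"
            )
        for s in set_special:
            if s not in names:
                raise ValidationError(f"designated attribute {s!r} not in table")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_objects(self) -> int:
        return len(self.object_ids)

    @property
    def attribute_names(self) -> list[str]:
        return [a.name for a in self.attributes]

    def column(self, name: str) -> np.ndarray:
        """Return a copy of one attribute column."""
        return self.values[:, self._index(name)].copy()

    def spec(self, name: str) -> AttributeSpec:
        return self.attributes[self._index(name)]

    def _index(self, name: str) -> int:
        try:
            return self.attribute_names.index(name)
        except ValueError:
            raise KeyError(f"no attribute named {name!r}") from None

    def conditional_attributes(self, numeric_only: bool = False) -> list[str]:
        """Names of the conditional (non-decision/time/event) attributes."""
        out = []
        for a in self.attributes:
            if a.name in (
                self.decision_attribute,
                self.time_attribute,
                self.event_attribute,
            ):
                continue
            if numeric_only and a.kind != "numeric":
                continue
            out.append(a.name)
        return out

    def drop_attributes(self, names: Sequence[str]) -> "InformationSystem":
        """Return a copy without the named attributes (never the designated ones)."""
        names = set(names)
        protected = {
            self.decision_attribute,
            self.time_attribute,
            self.event_attribute,
        } - {None}
        clash = names & protected
        if clash:
            raise ValidationError(
                f"cannot drop designated attribute(s): {sorted(clash)}"
            )
        keep = [i for i, a in enumerate(self.attributes) if a.name not in names]
        return InformationSystem(
            object_ids=list(self.object_ids),
            attributes=[self.attributes[i] for i in keep],
            values=self.values[:, keep].copy(),
            decision_attribute=self.decision_attribute,
            time_attribute=self.time_attribute,
            event_attribute=self.event_attribute,
        )

    def with_column(
        self, spec: AttributeSpec, column: np.ndarray, role: str | None = None
    ) -> "InformationSystem":
        """Return a copy with a column added (or replaced, matching by name)."""
        column = np.asarray(column, dtype=float).reshape(-1)
        if column.shape[0] != self.n_objects:
            raise ValidationError("column length does not match object count")
        names = self.attribute_names
        if spec.name in names:
            j = names.index(spec.name)
            attrs = list(self.attributes)
            attrs[j] = spec
            vals = self.values.copy()
            vals[:, j] = column
        else:
            attrs = list(self.attributes) + [spec]
            vals = np.column_stack([self.values, column])
        kwargs = dict(
            decision_attribute=self.decision_attribute,
            time_attribute=self.time_attribute,
            event_attribute=self.event_attribute,
        )
        if role is not None:
            kwargs[f"{role}_attribute"] = spec.name
        return InformationSystem(
            object_ids=list(self.object_ids),
            attributes=attrs,
            values=vals,
            **kwargs,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=self.object_ids, columns=self.attribute_names
        )
        df.index.name = "object"
        return df


def _infer_kind(name: str, schema: Mapping[str, str]) -> str:
    if name == schema.get("decision"):
        return "decision"
    if name == schema.get("time"):
        return "time"
    if name == schema.get("event"):
        return "event"
    if name in schema.get("categorical", ()):
        return "categorical"
    return "numeric"


def load_information_system(
    path: str | Path, schema: Mapping[str, object] | None = None
) -> InformationSystem:
    """Read an information system from CSV.

    The CSV must have a header row; the first column holds object ids.
    ``schema`` maps column roles onto column names::

        {"decision": "d", "time": "DFS", "event": "event",
         "categorical": ["Gender", "LOC"]}

    Raises
    ------
    SchemaError
        Empty file, missing header, or a role naming a non-existent column.
    ValidationError
        Duplicate object ids or non-numeric cells in numeric columns.
    """
    schema = dict(schema or {})
    path = Path(path)
    try:
        df = pd.read_csv(path, header=0, index_col=0)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise SchemaError(f"cannot parse {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise SchemaError(f"{path} has no attribute columns")
    for role in ("decision", "time", "event"):
        name = schema.get(role)
        if name is not None and name not in df.columns:
            raise SchemaError(f"{role} column {name!r} not found in {path}")
    for name in schema.get("categorical", ()):
        if name not in df.columns:
            raise SchemaError(f"categorical column {name!r} not found in {path}")
    attrs = [AttributeSpec(str(c), _infer_kind(str(c), schema)) for c in df.columns]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        col = bad.any(axis=0).idxmax()
        raise ValidationError(f"non-numeric cell(s) in column {col!r}")
    if numeric.isna().any().any():
        col = numeric.isna().any(axis=0).idxmax()
        raise ValidationError(f"missing value(s) in column {col!r}")
    return InformationSystem(
        object_ids=[str(i) for i in df.index],
        attributes=attrs,
        values=numeric.to_numpy(dtype=float),
        decision_attribute=schema.get("decision"),
        time_attribute=schema.get("time"),
        event_attribute=schema.get("event"),
    )


def save_information_system(is_: InformationSystem, path: str | Path) -> None:
    """Write the system to CSV (comma, UTF-8, '.' decimal, header row).

    Round-trips with :func:`load_information_system` to full printed precision:
    values are written with :func:`repr`-faithful float formatting.
    """
    df = is_.to_frame()
    # shortest round-trippable decimal representation per cell
    df.to_csv(Path(path), float_format=None)
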