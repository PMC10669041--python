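"""Wetland trait tables: schema definition, loading, validation.

The data model is a site-by-variable table: each row is one coastal wetland,
each column one of nine habitat traits (spatial, anthropic, hydrological)
plus the target variable, the number of waterbird species recorded at the
site.  Traits are either continuous (e.g. wetland size in hectares) or
semi-quantitative ordinal scores (e.g. water salinity coded 0 = absent to
3 = widespread).  Validation is strict: every cell must fall inside its
declared range, ordinal cells must be integers, identifiers must be unique
and no cell may be missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

ID_COLUMN = "wetland_id"

#: canonical column name of the target variable (species richness)
TARGET = "number of species"

_KINDS = ("continuous", "ordinal", "count")


@dataclass(frozen=True)
class TraitSchema:
    """Declared type and admissible range of one table column.

    Parameters
    ----------
    name:
        Canonical lower-case variable name.
    kind:
        ``"continuous"`` (real-valued), ``"ordinal"`` (small integer score
        with labelled levels) or ``"count"`` (integer-valued magnitude).
    unit:
        Unit of measure; ``"score"`` for dimensionless ordinal codes.
    allowed_range:
        Closed interval ``(low, high)`` every cell must fall in.
    level_labels:
        For ordinal variables, meaning of each level code.
    """

    name: str
    kind: str
    unit: str
    allowed_range: tuple[float, float]
    level_labels: dict[int, str] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise SchemaError(f"unknown kind {self.kind!r} for {self.name!r}")
        low, high = self.allowed_range
        if not low <= high:
            raise SchemaError(
                f"invalid range for {self.name!r}: lower {low} > upper {high}"
            )
        if self.kind in ("ordinal", "count"):
            if low != int(low) or high != int(high):
                raise SchemaError(
                    f"{self.kind} variable {self.name!r} needs integer bounds"
                )

    @property
    def is_integer(self) -> bool:
        return self.kind in ("ordinal", "count")

    def check_values(self, values: np.ndarray) -> np.ndarray:
        """Return a boolean mask of cells violating this schema."""
        v = np.asarray(values, dtype=float)
        low, high = self.allowed_range
        bad = np.isnan(v) | (v < low) | (v > high)
        if self.is_integer:
            bad |= ~np.isnan(v) & (np.round(v) != v)
        return bad


_SPREAD = {0: "absent", 1: "localized", 2: "scattered", 3: "widespread"}


def default_schema() -> list[TraitSchema]:
    """The ten-variable schema of the Sardinian coastal-wetland survey.

    Nine traits plus species richness, with the printed survey ranges.
    Mean water level is a 1-11 ordinal class (class k = (k-1)*10 to k*10 cm).
    """
    return [
        TraitSchema("wetland size", "continuous", "hectares", (13.3, 2048.0)),
        TraitSchema("isolation", "continuous", "meters", (296.0, 54472.0)),
        TraitSchema("distance to coastline", "continuous", "meters", (0.0, 2050.0)),
        TraitSchema(
            "mean water level", "ordinal", "score", (1, 11),
            {k: f"{(k - 1) * 10} to {k * 10} cm" for k in range(1, 12)},
        ),
        TraitSchema("water salinity", "ordinal", "score", (0, 3), dict(_SPREAD)),
        TraitSchema("water diversions", "ordinal", "score", (0, 3), dict(_SPREAD)),
        TraitSchema(
            "water discharges", "ordinal", "score", (0, 2),
            {k: _SPREAD[k] for k in range(3)},
        ),
        TraitSchema("tourism pressure", "ordinal", "score", (0, 3), dict(_SPREAD)),
        TraitSchema(
            "anthropization", "ordinal", "score", (0, 2),
            {k: _SPREAD[k] for k in range(3)},
        ),
        TraitSchema("number of species", "count", "species", (2, 32)),
    ]


@dataclass
class WetlandTable:
    """A validated wetland-by-trait table.

    ``data`` is indexed by wetland id with one column per schema entry, in
    schema order.  Construction validates ranges, uniqueness and
    completeness; use :meth:`from_frame` for arbitrary frames.
    """

    data: pd.DataFrame
    schema: list[TraitSchema]

    def __post_init__(self) -> None:
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, schema: list[TraitSchema] | None = None
    ) -> "WetlandTable":
        """Build a table from a DataFrame with an id column or index.

        Column names are matched to schema names case-insensitively; the
        canonical (schema) spelling is used in the result.
        """
        schema = schema if schema is not None else default_schema()
        frame = frame.copy()
        if frame.index.name != ID_COLUMN:
            id_col = _find_column(frame.columns, ID_COLUMN)
            if id_col is None:
                raise SchemaError(f"missing required column {ID_COLUMN!r}")
            frame = frame.set_index(id_col)
            frame.index.name = ID_COLUMN
        cols = {}
        for spec in schema:
            col = _find_column(frame.columns, spec.name)
            if col is None:
                raise SchemaError(f"missing column {spec.name!r}")
            if col != spec.name:
                logger.info("matched column %r to schema name %r", col, spec.name)
            cols[spec.name] = frame[col]
        data = pd.DataFrame(cols, index=frame.index)
        data.index = data.index.astype(str)
        return cls(data, schema)

    # -- properties --------------------------------------------------------

    @property
    def n(self) -> int:
        """Number of wetlands (rows)."""
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def column(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy(dtype=float)

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def schema_for(self, name: str) -> TraitSchema:
        for spec in self.schema:
            if spec.name == name:
                return spec
        raise KeyError(name)

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        if self.data.empty:
            raise SchemaError("table has no rows")
        ids = self.data.index
        if ids.duplicated().any():
            dupes = sorted(set(ids[ids.duplicated()]))
            raise ValidationError(f"duplicate wetland_id values: {dupes}")
        for spec in self.schema:
            if spec.name not in self.data.columns:
                raise SchemaError(f"missing column {spec.name!r}")
            col = self.data[spec.name]
            try:
                vals = col.to_numpy(dtype=float)
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    f"non-numeric cell in column {spec.name!r}"
                ) from exc
            bad = spec.check_values(vals)
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"value {col.iloc[i]!r} for trait {spec.name!r} at wetland "
                    f"{self.data.index[i]!r} outside allowed range "
                    f"{spec.allowed_range} ({bad.sum()} offending cell(s))"
                )

    # -- i/o ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        """Write the normalized table (canonical names, dot decimal, UTF-8)."""
        self.data.to_csv(path, index=True, encoding="utf-8")


def _find_column(columns, name: str) -> str | None:
    lowered = {str(c).strip().lower(): c for c in columns}
    return lowered.get(name.strip().lower())


def load_trait_table(path, schema: list[TraitSchema] | None = None) -> WetlandTable:
    """Load and validate a comma-separated trait table.

    The file must have one header row naming the id column and every schema
    variable (case-insensitive), dot decimal separator, UTF-8 encoding.

    Raises
    ------
    SchemaError
        Empty file or missing column.
    ValidationError
        Out-of-range cell, duplicate id, or non-numeric cell.
    """
    try:
        frame = pd.read_csv(path, encoding="utf-8", comment="#")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"empty trait table file: {path}") from exc
    if frame.empty:
        raise SchemaError(f"trait table has no data rows: {path}")
    return WetlandTable.from_frame(frame, schema)
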