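"""Schema-typed tabular containers for mixed numeric/binary/categorical
clinical records, with explicit missingness masks.

A :class:`DataTable` is the pipeline's currency: a validated grid of cell
values plus a boolean mask marking missing cells ("" or "NA" in CSV form).
:func:`encode_table` maps it to the numeric geometry every model consumes —
numeric columns min-max scaled to [0, 1], binary columns 0/1 in declared
level order, categorical columns one-hot — and :func:`decode_matrix` inverts
that map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit

MISSING_TOKENS = {"", "na"}

__all__ = [
    "ColumnSpec", "FeatureSchema", "DataTable", "EncodedMatrix",
    "SchemaError", "ValidationError",
    "load_table", "write_table", "encode_table", "decode_matrix",
    "stratified_split",
]


class SchemaError(ValueError):
    """Structural mismatch between a file/matrix and the declared schema."""


class ValidationError(ValueError):
    """A cell value violates the schema contract."""


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    kind: str  # "numeric" | "binary" | "categorical"
    levels: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in {"numeric", "binary", "categorical"}:
            raise SchemaError(f"unknown column kind {self.kind!r} for {self.name!r}")
        if self.kind == "binary" and len(self.levels) != 2:
            raise SchemaError(f"binary column {self.name!r} needs exactly 2 levels")
        if self.kind == "categorical" and len(self.levels) < 2:
            raise SchemaError(f"categorical column {self.name!r} needs >=2 levels")


@dataclass(frozen=True)
class FeatureSchema:
    columns: tuple[ColumnSpec, ...]
    label_column: str
    id_column: str | None = None

    def __post_init__(self):
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate column names in schema")
        lbl = self.column(self.label_column)
        if lbl.kind != "binary":
            raise SchemaError("label column must be binary")

    def column(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise SchemaError(f"column {name!r} not in schema")

    @property
    def feature_columns(self) -> tuple[ColumnSpec, ...]:
        """Columns that participate in encoding (not label, not id)."""
        skip = {self.label_column, self.id_column}
        return tuple(c for c in self.columns if c.name not in skip)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.columns]


@dataclass
class DataTable:
    schema: FeatureSchema
    values: pd.DataFrame          # object dtype; cells are str for cat/bin, float for numeric
    missing_mask: np.ndarray      # n_rows x n_cols bool, True = missing

    def __post_init__(self):
        if self.values.shape != self.missing_mask.shape:
            raise ValidationError("values and mask shapes differ")
        if list(self.values.columns) != self.schema.names:
            raise SchemaError("value columns do not match schema order")
        self._validate_cells()

    def _validate_cells(self):
        for j, col in enumerate(self.schema.columns):
            mask = self.missing_mask[:, j]
            if col.name == self.schema.label_column and mask.any():
                raise ValidationError("label cells may not be missing")
            vals = self.values[col.name].to_numpy()
            if col.kind == "numeric":
                continue
            observed = vals[~mask]
            bad = [v for v in observed if str(v) not in col.levels]
            if bad:
                i = int(np.flatnonzero(~mask)[[str(v) in col.levels for v in observed].index(False)])
                raise ValidationError(
                    f"value {bad[0]!r} in column {col.name!r} (row {i}) not in levels {col.levels}")

    @property
    def n_rows(self) -> int:
        return len(self.values)

    def labels(self) -> np.ndarray:
        col = self.schema.column(self.schema.label_column)
        vals = self.values[self.schema.label_column].astype(str).to_numpy()
        return np.asarray([col.levels.index(v) for v in vals], dtype=int)

    def copy(self) -> "DataTable":
        return DataTable(self.schema, self.values.copy(), self.missing_mask.copy())

    def subset(self, rows: np.ndarray) -> "DataTable":
        return DataTable(self.schema,
                         self.values.iloc[rows].reset_index(drop=True),
                         self.missing_mask[rows])


@dataclass
class EncodedMatrix:
    matrix: np.ndarray            # n_rows x d float
    mask: np.ndarray              # n_rows x d bool, True = missing
    encoding_map: dict            # per source column: kind, out indices, min/max or levels
    label_vector: np.ndarray      # n_rows int {0,1}
    column_kinds: np.ndarray = field(default=None)  # "continuous"/"discrete" per encoded column

    def __post_init__(self):
        if self.column_kinds is None:
            kinds = np.empty(self.matrix.shape[1], dtype=object)
            for rec in self.encoding_map.values():
                k = "continuous" if rec["kind"] == "numeric" else "discrete"
                for idx in rec["indices"]:
                    kinds[idx] = k
            self.column_kinds = kinds

    @property
    def continuous_idx(self) -> np.ndarray:
        return np.flatnonzero(self.column_kinds == "continuous")

    @property
    def discrete_idx(self) -> np.ndarray:
        return np.flatnonzero(self.column_kinds == "discrete")


def _is_missing_token(cell: str) -> bool:
    return str(cell).strip().lower() in MISSING_TOKENS


def load_table(path, schema: FeatureSchema) -> DataTable:
    """Read a header-row CSV into a validated :class:`DataTable`.

    Cells equal to "" or "NA" (case-insensitive) are flagged missing; all
    other cells are validated against the schema.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(raw.columns) != schema.names:
        raise SchemaError(
            f"CSV header {list(raw.columns)} does not match schema columns {schema.names}")
    n = len(raw)
    mask = np.zeros((n, len(schema.columns)), dtype=bool)
    out = {}
    for j, col in enumerate(schema.columns):
        cells = raw[col.name].to_numpy()
        miss = np.array([_is_missing_token(c) for c in cells])
        mask[:, j] = miss
        if col.kind == "numeric":
            vals = np.full(n, np.nan)
            for i, c in enumerate(cells):
                if not miss[i]:
                    try:
                        vals[i] = float(c)
                    except ValueError as exc:
                        raise ValidationError(
                            f"non-numeric value {c!r} in column {col.name!r}, row {i}") from exc
            out[col.name] = vals
        else:
            vals = np.array([("" if m else str(c).strip()) for c, m in zip(cells, miss)],
                            dtype=object)
            out[col.name] = vals
    return DataTable(schema, pd.DataFrame(out, columns=schema.names), mask)


def write_table(table: DataTable, path) -> None:
    """Write a DataTable back to CSV, emitting "" for missing cells."""
    df = table.values.copy()
    for j, col in enumerate(table.schema.columns):
        cells = df[col.name].astype(object).to_numpy()
        miss = table.missing_mask[:, j]
        rendered = np.empty(len(cells), dtype=object)
        for i, c in enumerate(cells):
            if miss[i]:
                rendered[i] = ""
            elif col.kind == "numeric":
                f = float(c)
                rendered[i] = repr(int(f)) if f == int(f) else repr(f)
            else:
                rendered[i] = str(c)
        df[col.name] = rendered
    df.to_csv(path, index=False)


def encode_table(table: DataTable) -> EncodedMatrix:
    """Encode a table into the [0, 1] numeric geometry.

    Numeric columns are min-max scaled using observed cells only (a constant
    observed column maps to 0.5); binary columns map declared levels to 0/1;
    categorical columns expand one-hot.  Missing source cells carry
    placeholder 0 in every derived column and propagate the mask.
    """
    import warnings

    schema = table.schema
    cols = schema.feature_columns
    blocks, mask_blocks = [], []
    enc_map: dict = {}
    pos = 0
    for col in cols:
        j = schema.names.index(col.name)
        miss = table.missing_mask[:, j]
        vals = table.values[col.name].to_numpy()
        if col.kind == "numeric":
            v = np.asarray(vals, dtype=float)
            obs = v[~miss]
            lo, hi = (float(np.min(obs)), float(np.max(obs))) if obs.size else (0.0, 1.0)
            if hi > lo:
                scaled = (v - lo) / (hi - lo)
            else:
                warnings.warn(f"column {col.name!r} has zero observed range; encoding as 0.5")
                scaled = np.full_like(v, 0.5)
            scaled = np.where(miss, 0.0, np.clip(scaled, 0.0, 1.0))
            blocks.append(scaled[:, None])
            mask_blocks.append(miss[:, None])
            enc_map[col.name] = {"kind": "numeric", "indices": [pos], "min": lo, "max": hi}
            pos += 1
        elif col.kind == "binary":
            code = np.zeros(len(vals))
            for i, c in enumerate(vals):
                if not miss[i]:
                    code[i] = float(col.levels.index(str(c)))
            blocks.append(code[:, None])
            mask_blocks.append(miss[:, None])
            enc_map[col.name] = {"kind": "binary", "indices": [pos], "levels": list(col.levels)}
            pos += 1
        else:
            k = len(col.levels)
            onehot = np.zeros((len(vals), k))
            for i, c in enumerate(vals):
                if not miss[i]:
                    onehot[i, col.levels.index(str(c))] = 1.0
            blocks.append(onehot)
            mask_blocks.append(np.repeat(miss[:, None], k, axis=1))
            enc_map[col.name] = {"kind": "categorical",
                                 "indices": list(range(pos, pos + k)),
                                 "levels": list(col.levels)}
            pos += k
    matrix = np.hstack(blocks) if blocks else np.zeros((table.n_rows, 0))
    mask = np.hstack(mask_blocks) if mask_blocks else np.zeros((table.n_rows, 0), dtype=bool)
    return EncodedMatrix(matrix, mask, enc_map, table.labels())


def decode_matrix(enc: EncodedMatrix, schema: FeatureSchema,
                  id_values=None) -> DataTable:
    """Invert :func:`encode_table`: inverse min-max for numerics, declared
    level order for binaries (threshold 0.5), arg-max for one-hot groups.

    The returned table has an all-false mask (decoding realises every cell).
    """
    width = 1 + max((max(rec["indices"]) for rec in enc.encoding_map.values()), default=-1)
    if enc.matrix.shape[1] != width:
        raise SchemaError(f"matrix width {enc.matrix.shape[1]} != encoding map width {width}")
    n = enc.matrix.shape[0]
    out = {}
    for col in schema.columns:
        if col.name == schema.label_column:
            out[col.name] = np.array([col.levels[y] for y in enc.label_vector], dtype=object)
            continue
        if schema.id_column is not None and col.name == schema.id_column:
            if id_values is None:
                id_values = np.arange(n)
            if col.kind == "numeric":
                out[col.name] = np.asarray(id_values, dtype=float)
            else:
                out[col.name] = np.asarray(id_values, dtype=object)
            continue
        rec = enc.encoding_map[col.name]
        idx = rec["indices"]
        if rec["kind"] == "numeric":
            lo, hi = rec["min"], rec["max"]
            v = enc.matrix[:, idx[0]]
            out[col.name] = v * (hi - lo) + lo if hi > lo else np.full(n, lo)
        elif rec["kind"] == "binary":
            v = enc.matrix[:, idx[0]]
            out[col.name] = np.array([rec["levels"][int(x > 0.5)] for x in v], dtype=object)
        else:
            block = enc.matrix[:, idx]
            best = block.argmax(axis=1)
            out[col.name] = np.array([rec["levels"][b] for b in best], dtype=object)
    df = pd.DataFrame(out, columns=schema.names)
    return DataTable(schema, df, np.zeros((n, len(schema.columns)), dtype=bool))


def stratified_split(table: DataTable, test_fraction: float, seed: int):
    """Deterministic stratified train/test split on the label column."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    y = table.labels()
    counts = np.bincount(y, minlength=2)
    if (counts < 2).any():
        raise ValueError("each class needs at least 2 members to stratify")
    splitter = StratifiedShuffleSplit(n_splits=1, test_size=test_fraction, random_state=seed)
    train_idx, test_idx = next(splitter.split(np.zeros(len(y)), y))
    return np.sort(train_idx), np.sort(test_idx)
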