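"""Domain types, feature-table I/O, labeling and complex-level splitting.

A :class:`ResidueRecord` holds one mutation site at a protein-DNA
interface: identifiers, the four raw per-residue signal blocks
(bound/unbound/delta solvent accessibility, secondary structure), the
depth/protrusion descriptors, the hydrogen-bond count, and either the
measured binding free-energy change on alanine mutation (ddG, kcal/mol)
or a binary hot-spot label.

Tables are plain CSV/TSV with a header, "." as the decimal separator and
UTF-8 encoding. Two table shapes exist:

* the *residue table* — raw blocks as named columns, one row per
  mutation site (the package's input format);
* the *feature table* — an assembled numeric matrix whose columns follow
  a :class:`~ecpdh.schema.FeatureSchema`.

Train/test splitting is by complex, never by row: all mutation sites of
one complex land on the same side, preventing leakage between homologous
rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, ParseError, SchemaError
from .schema import FeatureSchema, conventional_names

#: hot-spot ddG threshold (kcal/mol), inclusive
DDG_HOT_THRESHOLD = 1.0

_BLOCK_FIELDS = {
    "asa_complex": 8,
    "asa_unbound": 8,
    "asa_delta": 8,
    "dssp": 6,
    "dpx_cx": 12,
}

_BLOCK_COLUMN_PREFIX = {
    "asa_complex": "asa_c",
    "asa_unbound": "asa_u",
    "asa_delta": "asa_d",
    "dssp": "dssp",
    "dpx_cx": "dpxcx",
}


def label_from_ddg(ddg: float, threshold: float = DDG_HOT_THRESHOLD) -> int:
    """Binary hot-spot label from a ddG value (kcal/mol).

    A mutation site is a hot spot (1) iff ddG >= threshold; the boundary
    is included.
    """
    ddg = float(ddg)
    if not math.isfinite(ddg):
        raise InvalidInputError(f"ddg must be finite, got {ddg!r}")
    return 1 if ddg >= threshold else 0


@dataclass
class ResidueRecord:
    """One mutation site with its raw descriptor blocks."""

    complex_id: str
    chain: str
    position: int
    wild_aa: str
    asa_complex: np.ndarray
    asa_unbound: np.ndarray
    asa_delta: np.ndarray
    dssp: np.ndarray
    dpx_cx: np.ndarray
    hbond_count: int
    ddg: float | None = None
    label: int | None = None

    def __post_init__(self) -> None:
        for name, length in _BLOCK_FIELDS.items():
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (length,):
                raise SchemaError(
                    f"block {name!r} must have length {length}, got shape {arr.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise SchemaError(f"block {name!r} contains non-finite values")
            setattr(self, name, arr)
        if self.hbond_count < 0:
            raise SchemaError("hbond_count must be non-negative")
        if self.ddg is None and self.label is None:
            raise SchemaError("at least one of ddg/label must be present")
        if self.ddg is not None and not math.isfinite(float(self.ddg)):
            raise SchemaError("ddg must be finite")
        if self.label is not None and self.label not in (0, 1):
            raise SchemaError(f"label must be 0/1, got {self.label!r}")

    @property
    def effective_label(self) -> int:
        """Stored label if present, else the label implied by ddG."""
        if self.label is not None:
            return int(self.label)
        return label_from_ddg(self.ddg)

    def signal(self, group: str) -> np.ndarray:
        """Raw signal for one of the four signal groups
        (``ASA``/``u_ASA``/``d_ASA``/``dssp``)."""
        mapping = {
            "ASA": self.asa_complex,
            "u_ASA": self.asa_unbound,
            "d_ASA": self.asa_delta,
            "dssp": self.dssp,
        }
        try:
            return mapping[group]
        except KeyError:
            raise InvalidInputError(f"unknown signal group {group!r}") from None

    def conventional_vector(self) -> np.ndarray:
        """The 43 conventional descriptors in schema order."""
        return np.concatenate(
            [
                self.asa_complex,
                self.asa_unbound,
                self.asa_delta,
                self.dssp,
                self.dpx_cx,
                [float(self.hbond_count)],
            ]
        )


@dataclass(frozen=True)
class DatasetSplit:
    """Row-index sets for a complex-level train/test split."""

    train_indices: np.ndarray
    test_indices: np.ndarray

    def __post_init__(self) -> None:
        tr = np.asarray(self.train_indices, dtype=int)
        te = np.asarray(self.test_indices, dtype=int)
        if np.intersect1d(tr, te).size:
            raise InvalidInputError("train and test indices overlap")
        object.__setattr__(self, "train_indices", tr)
        object.__setattr__(self, "test_indices", te)


@dataclass
class FeatureTable:
    """Assembled numeric feature matrix with labels and complex grouping."""

    schema: FeatureSchema
    rows: np.ndarray
    labels: np.ndarray
    groups: np.ndarray  # complex_id per row

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.groups = np.asarray(self.groups, dtype=object)
        if self.rows.ndim != 2 or self.rows.shape[1] != len(self.schema):
            raise SchemaError(
                f"row width {self.rows.shape} does not match schema length {len(self.schema)}"
            )
        n = self.rows.shape[0]
        if self.labels.shape != (n,) or self.groups.shape != (n,):
            raise SchemaError("labels/groups length must equal row count")
        if not np.isin(self.labels, (0, 1)).all():
            raise SchemaError("labels must be binary 0/1")

    def __len__(self) -> int:
        return self.rows.shape[0]

    @property
    def feature_names(self) -> list[str]:
        return self.schema.names

    def subset_rows(self, indices: Sequence[int]) -> "FeatureTable":
        idx = np.asarray(indices, dtype=int)
        return FeatureTable(self.schema, self.rows[idx], self.labels[idx], self.groups[idx])

    def subset_columns(self, names: Iterable[str]) -> "FeatureTable":
        sub = self.schema.subset(names)  # keeps original schema order
        cols = [self.schema.index(n) for n in sub.names]
        return FeatureTable(sub, self.rows[:, cols], self.labels, self.groups)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows, columns=self.schema.names)
        df.insert(0, "complex_id", self.groups)
        df.insert(1, "label", self.labels)
        return df


def write_feature_table(table: FeatureTable, path: str | Path, dialect: str = "csv") -> None:
    """Write an assembled feature table; full float precision, header row."""
    sep = _sep(dialect)
    df = table.to_dataframe()
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_feature_table(
    path: str | Path, dialect: str = "csv", schema: FeatureSchema | None = None
) -> FeatureTable:
    """Read an assembled feature table written by :func:`write_feature_table`.

    Column order in the file defines the schema when none is given; block
    provenance is recovered from the default registry where names match,
    defaulting to ``conventional`` otherwise.
    """
    sep = _sep(dialect)
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except ValueError as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    for col in ("complex_id", "label"):
        if col not in df.columns:
            raise SchemaError(f"feature table {path} lacks mandatory column {col!r}")
    feat_cols = [c for c in df.columns if c not in ("complex_id", "label", "ddg")]
    if schema is None:
        from .schema import build_default_schema

        default = build_default_schema()
        known = {e.name: e.block for e in default.entries}
        from .schema import SchemaEntry

        schema = FeatureSchema(
            tuple(SchemaEntry(c, known.get(c, "conventional")) for c in feat_cols)
        )
    else:
        if list(schema.names) != feat_cols:
            raise SchemaError("file columns do not match the supplied schema")
    mat = _numeric_block(df, feat_cols, path)
    labels = df["label"].to_numpy()
    return FeatureTable(schema, mat, labels, df["complex_id"].to_numpy(dtype=object))


def residue_table_columns() -> list[str]:
    cols = ["complex_id", "chain", "position", "wild_aa", "ddg", "label"]
    for fieldname, length in _BLOCK_FIELDS.items():
        prefix = _BLOCK_COLUMN_PREFIX[fieldname]
        cols += [f"{prefix}_{i}" for i in range(1, length + 1)]
    cols.append("hbond_count")
    return cols


def write_residue_table(
    records: Sequence[ResidueRecord], path: str | Path, dialect: str = "csv"
) -> None:
    """Write raw residue records as a flat CSV/TSV table."""
    rows = []
    for r in records:
        row: dict = {
            "complex_id": r.complex_id,
            "chain": r.chain,
            "position": r.position,
            "wild_aa": r.wild_aa,
            "ddg": "" if r.ddg is None else r.ddg,
            "label": "" if r.label is None else r.label,
            "hbond_count": r.hbond_count,
        }
        for fieldname in _BLOCK_FIELDS:
            prefix = _BLOCK_COLUMN_PREFIX[fieldname]
            for i, v in enumerate(getattr(r, fieldname), start=1):
                row[f"{prefix}_{i}"] = v
        rows.append(row)
    df = pd.DataFrame(rows, columns=residue_table_columns())
    df.to_csv(path, sep=_sep(dialect), index=False, float_format="%.17g")


def read_residue_table(path: str | Path, dialect: str = "csv") -> list[ResidueRecord]:
    """Read a raw residue table.

    Every signal block must be complete: a missing block column is a
    schema error. ``ddg`` and ``label`` are optional per row but at least
    one must be present.
    """
    try:
        df = pd.read_csv(path, sep=_sep(dialect), float_precision="round_trip")
    except ValueError as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    required = [c for c in residue_table_columns() if c not in ("ddg", "label")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"residue table {path} missing mandatory columns: {missing}")
    records: list[ResidueRecord] = []
    for idx, row in df.iterrows():
        blocks = {}
        for fieldname, length in _BLOCK_FIELDS.items():
            prefix = _BLOCK_COLUMN_PREFIX[fieldname]
            cols = [f"{prefix}_{i}" for i in range(1, length + 1)]
            vals = _numeric_block(df.loc[[idx]], cols, path)[0]
            blocks[fieldname] = vals
        ddg = row.get("ddg")
        label = row.get("label")
        ddg = None if pd.isna(ddg) else float(ddg)
        label = None if pd.isna(label) else int(label)
        try:
            records.append(
                ResidueRecord(
                    complex_id=str(row["complex_id"]),
                    chain=str(row["chain"]),
                    position=int(row["position"]),
                    wild_aa=str(row["wild_aa"]),
                    hbond_count=int(row["hbond_count"]),
                    ddg=ddg,
                    label=label,
                    **blocks,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"row {idx} of {path}: {exc}") from exc
    return records


def split_by_complex(
    records: Sequence[ResidueRecord] | FeatureTable,
    n_test_complexes: int,
    seed: int,
) -> DatasetSplit:
    """Complex-level train/test split: whole complexes are assigned to one
    side, deterministically for a fixed seed."""
    if isinstance(records, FeatureTable):
        groups = np.asarray(records.groups, dtype=object)
    else:
        groups = np.asarray([r.complex_id for r in records], dtype=object)
    distinct = sorted(set(groups.tolist()))
    if n_test_complexes >= len(distinct):
        raise InvalidInputError(
            f"n_test_complexes={n_test_complexes} must be < number of complexes ({len(distinct)})"
        )
    if n_test_complexes < 1:
        raise InvalidInputError("n_test_complexes must be >= 1")
    rng = np.random.default_rng(seed)
    test_ids = set(rng.choice(distinct, size=n_test_complexes, replace=False).tolist())
    mask = np.array([g in test_ids for g in groups])
    return DatasetSplit(np.flatnonzero(~mask), np.flatnonzero(mask))


def assemble_features(
    record: ResidueRecord,
    wavelet_block: np.ndarray,
    emd_block: np.ndarray,
    schema: FeatureSchema,
) -> np.ndarray:
    """Concatenate the conventional, wavelet and EMD blocks in schema
    order into one feature row."""
    conv = record.conventional_vector()
    parts = {
        "conventional": np.asarray(conv, dtype=float),
        "wavelet": np.asarray(wavelet_block, dtype=float),
        "emd": np.asarray(emd_block, dtype=float),
    }
    for block, vec in parts.items():
        expected = schema.block_count(block)
        if vec.ndim != 1 or vec.shape[0] != expected:
            raise SchemaError(
                f"{block} block has length {vec.shape}, schema expects {expected}"
            )
    out = np.concatenate([parts[b] for b in ("conventional", "wavelet", "emd")
                          if schema.block_count(b)])
    if out.shape[0] != len(schema):
        raise SchemaError("assembled width does not match schema length")
    return out


def records_to_table(
    records: Sequence[ResidueRecord],
    schema: FeatureSchema,
    feature_rows: np.ndarray,
) -> FeatureTable:
    """Bundle precomputed rows with labels/groups taken from the records."""
    labels = np.array([r.effective_label for r in records], dtype=int)
    groups = np.array([r.complex_id for r in records], dtype=object)
    return FeatureTable(schema, np.asarray(feature_rows, dtype=float), labels, groups)


def _sep(dialect: str) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    raise InvalidInputError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")


def _numeric_block(df: pd.DataFrame, cols: list[str], path) -> np.ndarray:
    try:
        mat = df[cols].apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    except (ValueError, TypeError) as exc:
        for col in cols:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ParseError(
                    f"{path}: malformed numeric cell at row {row}, column {col!r}"
                ) from exc
        raise ParseError(f"{path}: malformed numeric data in {cols}") from exc
    if not np.all(np.isfinite(mat)):
        raise ParseError(f"{path}: non-finite value in columns {cols}")
    return mat
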