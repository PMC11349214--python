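"""Mixed-type subject-by-variable tables.

:class:`MixedDataset` is the currency every pipeline stage consumes and
produces: a pandas table of continuous and categorical columns, a per-variable
metadata table (kind, ordered level list, role), an explicit missingness mask,
and the name of the binary outcome column.  Categorical cells are stored as
strings, missing cells as NaN; the mask mirrors the NaN pattern and survives
round-trips through the CSV + sidecar format.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"

#: variable roles understood by the pipeline
ROLES = (
    "baseline",
    "outcome",
    "spirometry",
    "spirometry-derived",
    "snp",
    "future-info",
)


@dataclasses.dataclass
class MixedDataset:
    """Subject-by-variable table with per-variable type metadata.

    Parameters
    ----------
    values
        Table of shape (n_subjects, n_variables).  Continuous columns are
        float, categorical columns hold string levels; NaN marks missing.
    meta
        Indexed by variable name with columns ``kind`` (``continuous`` or
        ``categorical``), ``levels`` (tuple of level names, None for
        continuous) and ``role``.
    outcome_name
        Name of the binary outcome column, or None for outcome-free tables.
    synthetic
        Boolean flag per row marking SMOTE-generated records.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    outcome_name: str | None = None
    synthetic: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.synthetic is None:
            self.synthetic = np.zeros(len(self.values), dtype=bool)
        else:
            self.synthetic = np.asarray(self.synthetic, dtype=bool)
        self.validate()

    # ------------------------------------------------------------------ #
    # basic accessors

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness table (True = missing)."""
        return self.values.isna()

    def kind(self, name: str) -> str:
        return str(self.meta.loc[name, "kind"])

    def levels(self, name: str) -> tuple[str, ...] | None:
        lv = self.meta.loc[name, "levels"]
        return None if lv is None else tuple(lv)

    def role(self, name: str) -> str:
        return str(self.meta.loc[name, "role"])

    @property
    def continuous_vars(self) -> list[str]:
        return [v for v in self.variables if self.kind(v) == CONTINUOUS]

    @property
    def categorical_vars(self) -> list[str]:
        return [v for v in self.variables if self.kind(v) == CATEGORICAL]

    def is_complete(self) -> bool:
        return not self.values.isna().any().any()

    # ------------------------------------------------------------------ #
    # manipulation

    def copy(self) -> "MixedDataset":
        return MixedDataset(
            self.values.copy(),
            self.meta.copy(),
            self.outcome_name,
            None if self.synthetic is None else self.synthetic.copy(),
        )

    def select(self, columns: Sequence[str]) -> "MixedDataset":
        """Column projection, keeping metadata and the outcome if retained."""
        columns = list(columns)
        outcome = self.outcome_name if self.outcome_name in columns else None
        return MixedDataset(
            self.values[columns].copy(),
            self.meta.loc[columns].copy(),
            outcome,
            self.synthetic.copy(),
        )

    def subset_rows(self, idx) -> "MixedDataset":
        """Row selection by positional index (used for CV fold splits)."""
        idx = np.asarray(idx)
        return MixedDataset(
            self.values.iloc[idx].reset_index(drop=True),
            self.meta.copy(),
            self.outcome_name,
            self.synthetic[idx],
        )

    def drop(self, columns: Iterable[str]) -> "MixedDataset":
        drop = set(columns)
        keep = [c for c in self.variables if c not in drop]
        return self.select(keep)

    def outcome_values(self) -> np.ndarray:
        """Outcome column as a 0/1 integer array (second declared level = 1)."""
        if self.outcome_name is None:
            raise ValueError("dataset has no outcome column")
        levels = self.levels(self.outcome_name)
        y = self.values[self.outcome_name].to_numpy()
        return (y == levels[1]).astype(int)

    # ------------------------------------------------------------------ #
    # validation

    def validate(self) -> None:
        cols = list(self.values.columns)
        if len(set(cols)) != len(cols):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise ValueError(f"duplicated column names: {dupes}")
        missing_meta = [c for c in cols if c not in self.meta.index]
        if missing_meta:
            raise ValueError(f"variables without metadata: {missing_meta}")
        for name in cols:
            kind = self.kind(name)
            if kind == CATEGORICAL:
                levels = self.levels(name)
                if levels is None or len(levels) < 1:
                    raise ValueError(f"categorical {name!r} lacks a level list")
                col = self.values[name]
                observed = col[col.notna()]
                bad = set(observed.unique()) - set(levels)
                if bad:
                    row = int(col[col.isin(bad)].index[0])
                    raise ValueError(
                        f"column {name!r} row {row}: value outside declared "
                        f"levels {levels}: {sorted(bad)}"
                    )
            elif kind != CONTINUOUS:
                raise ValueError(f"unknown kind {kind!r} for {name!r}")
        if self.outcome_name is not None:
            if self.outcome_name not in cols:
                raise ValueError(f"outcome {self.outcome_name!r} not in table")
            if self.kind(self.outcome_name) != CATEGORICAL:
                raise ValueError("outcome must be categorical")
            if len(self.levels(self.outcome_name)) != 2:
                raise ValueError("outcome must be binary")
            if self.values[self.outcome_name].isna().any():
                raise ValueError("outcome column must be complete")
        if len(self.synthetic) != len(self.values):
            raise ValueError("synthetic flag length mismatch")

    # ------------------------------------------------------------------ #
    # IO: CSV with a variable-metadata sidecar

    def write(self, table_path: str | Path, meta_path: str | Path) -> None:
        """Write values as CSV (missing cells empty) and the metadata sidecar."""
        self.values.to_csv(table_path, index=False, na_rep="")
        rows = []
        for name in self.variables:
            levels = self.levels(name) if self.kind(name) == CATEGORICAL else None
            rows.append(
                {
                    "name": name,
                    "kind": self.kind(name),
                    "levels": "" if levels is None else "|".join(levels),
                    "role": self.role(name),
                    "outcome": name == self.outcome_name,
                }
            )
        pd.DataFrame(rows).to_csv(meta_path, index=False)

    @classmethod
    def read(cls, table_path: str | Path, meta_path: str | Path) -> "MixedDataset":
        """Load a dataset written by :meth:`write`, validating levels."""
        meta_raw = pd.read_csv(meta_path, dtype={"name": str})
        required = {"name", "kind", "levels", "role"}
        if not required.issubset(meta_raw.columns):
            raise ValueError(f"metadata sidecar must have columns {sorted(required)}")
        values = pd.read_csv(table_path, dtype=str, keep_default_na=False)
        meta_cols = list(meta_raw["name"])
        extra = [c for c in values.columns if c not in meta_cols]
        if extra:
            raise ValueError(f"columns absent from metadata: {extra}")
        absent = [c for c in meta_cols if c not in values.columns]
        if absent:
            raise ValueError(f"metadata rows without table columns: {absent}")
        values = values.replace("", np.nan)

        meta_rows = {}
        outcome = None
        for _, row in meta_raw.iterrows():
            name = row["name"]
            kind = row["kind"]
            levels_field = row["levels"]
            if kind == CATEGORICAL:
                if not isinstance(levels_field, str) or levels_field == "":
                    raise ValueError(f"categorical {name!r} lacks levels in sidecar")
                levels = tuple(levels_field.split("|"))
            else:
                levels = None
                values[name] = pd.to_numeric(values[name])
            meta_rows[name] = {"kind": kind, "levels": levels, "role": row["role"]}
            if "outcome" in meta_raw.columns and bool(row["outcome"]):
                outcome = name
        meta = pd.DataFrame.from_dict(meta_rows, orient="index")
        return cls(values, meta, outcome)


def build_meta(
    kinds: dict[str, str],
    levels: dict[str, Sequence[str]] | None = None,
    roles: dict[str, str] | None = None,
    default_role: str = "baseline",
) -> pd.DataFrame:
    """Assemble a metadata table from per-variable dicts."""
    levels = levels or {}
    roles = roles or {}
    rows = {}
    for name, kind in kinds.items():
        rows[name] = {
            "kind": kind,
            "levels": tuple(levels[name]) if name in levels else None,
            "role": roles.get(name, default_role),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
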