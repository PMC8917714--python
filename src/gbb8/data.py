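"""Respondent-level data container and delimited-text I/O.

An :class:`ItemDataset` wraps a pandas DataFrame holding integer item
responses (missing cells as NaN), categorical grouping columns (e.g. sex and
age band) and optional numeric validity covariates, together with the item
list and subscale map that give the columns their meaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import instrument


class SchemaError(ValueError):
    """Raised when an input table does not match the declared schema."""


@dataclass
class ItemDataset:
    """Item responses plus grouping labels and covariates.

    Parameters
    ----------
    df : DataFrame
        One row per respondent. Item columns are numeric with NaN for
        missing; grouping columns are categorical/string; covariate columns
        numeric.
    item_names : sequence of str
        Names of the item columns, in instrument order.
    subscales : dict
        Subscale name -> tuple of item names (pairs for the GBB-8).
    group_cols : list of str
        Names of grouping columns present in ``df``.
    covariate_cols : list of str
        Names of covariate columns present in ``df``.
    """

    df: pd.DataFrame
    item_names: tuple[str, ...] = instrument.ITEM_NAMES
    subscales: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(instrument.SUBSCALES)
    )
    group_cols: list[str] = field(default_factory=list)
    covariate_cols: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in self.item_names if c not in self.df.columns]
        if missing:
            raise SchemaError(f"item columns missing from table: {missing}")
        flat = [i for pair in self.subscales.values() for i in pair]
        if sorted(flat) != sorted(self.item_names):
            raise SchemaError("subscale map does not partition the item list")
        vals = self.responses.to_numpy()
        ok = np.isnan(vals) | (
            (vals >= instrument.MIN_RESPONSE)
            & (vals <= instrument.MAX_RESPONSE)
            & (vals == np.round(vals))
        )
        if not ok.all():
            r, c = np.argwhere(~ok)[0]
            raise SchemaError(
                f"item value {vals[r, c]!r} out of range 0..4 at row {r}, "
                f"column {self.item_names[c]!r}"
            )

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def n_items(self) -> int:
        return len(self.item_names)

    @property
    def responses(self) -> pd.DataFrame:
        """Item columns as float (NaN = missing)."""
        return self.df[list(self.item_names)].astype(float)

    @property
    def covariates(self) -> pd.DataFrame:
        return self.df[self.covariate_cols].astype(float)

    def groups(self, col: str) -> list[str]:
        """Sorted distinct labels of a grouping column (NaN excluded)."""
        if col not in self.group_cols:
            raise SchemaError(f"unknown grouping column {col!r}")
        return sorted(x for x in self.df[col].dropna().unique())

    def split_by(self, col: str) -> dict[str, "ItemDataset"]:
        """Partition into per-group datasets, dropping rows with a missing label."""
        out = {}
        for label in self.groups(col):
            sub = self.df[self.df[col] == label].reset_index(drop=True)
            out[label] = ItemDataset(
                sub, self.item_names, dict(self.subscales),
                list(self.group_cols), list(self.covariate_cols),
            )
        return out

    def complete_cases(self) -> np.ndarray:
        """Boolean mask of respondents with no missing item."""
        return ~self.responses.isna().any(axis=1).to_numpy()

    def missing_fraction(self) -> float:
        return float(self.responses.isna().to_numpy().mean())

    # ------------------------------------------------------------------
    def to_csv(self, path) -> None:
        """Write as comma-separated text; missing cells become empty fields."""
        self.df.to_csv(path, index=False, na_rep="")


def read_dataset(
    path,
    item_names: tuple[str, ...] = instrument.ITEM_NAMES,
    subscales: dict[str, tuple[str, str]] | None = None,
    group_cols: list[str] | None = None,
    covariate_cols: list[str] | None = None,
) -> ItemDataset:
    """Read a delimited-text respondent table into an :class:`ItemDataset`.

    Item values must be integers in 0..4 or empty (missing). Rows whose
    eight items are all missing are dropped; the count is recorded in
    ``meta['n_dropped_all_missing']`` (mirroring the handling of fully
    empty questionnaires in survey data).

    Raises
    ------
    SchemaError
        On unknown columns, non-integer item values, or out-of-range values
        (the offending row and column are named).
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in item_names if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"input file lacks item columns {missing_cols}")
    group_cols = group_cols or [c for c in ("sex", "age_band") if c in df.columns]
    covariate_cols = covariate_cols or []
    for c in group_cols + covariate_cols:
        if c not in df.columns:
            raise SchemaError(f"declared column {c!r} not in input file")

    for c in item_names:
        col = pd.to_numeric(df[c], errors="coerce")
        bad_parse = col.isna() & df[c].notna() & (df[c].astype(str).str.strip() != "")
        if bad_parse.any():
            row = int(np.flatnonzero(bad_parse.to_numpy())[0])
            raise SchemaError(f"non-numeric item value at row {row}, column {c!r}")
        non_int = col.notna() & (col != np.round(col))
        if non_int.any():
            row = int(np.flatnonzero(non_int.to_numpy())[0])
            raise SchemaError(f"non-integer item value at row {row}, column {c!r}")
        out_of_range = col.notna() & (
            (col < instrument.MIN_RESPONSE) | (col > instrument.MAX_RESPONSE)
        )
        if out_of_range.any():
            row = int(np.flatnonzero(out_of_range.to_numpy())[0])
            raise SchemaError(
                f"item value {col.iloc[row]} out of range 0..4 at row {row}, column {c!r}"
            )
        df[c] = col

    all_missing = df[list(item_names)].isna().all(axis=1)
    n_dropped = int(all_missing.sum())
    if n_dropped:
        df = df[~all_missing].reset_index(drop=True)

    return ItemDataset(
        df,
        item_names=tuple(item_names),
        subscales=dict(subscales) if subscales else dict(instrument.SUBSCALES),
        group_cols=list(group_cols),
        covariate_cols=list(covariate_cols),
        meta={"n_dropped_all_missing": n_dropped},
    )
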