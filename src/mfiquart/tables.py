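"""Long-format MFI% measurement tables.

The interchange format is a CSV with the exact header::

    subject_id,level,side,quartile,rater_id,session_id,mfi_percent

with ``quartile`` drawn from the closed enum {Q1, Q2, Q3, Q4, Qmean} and one
row per (subject, level, side, quartile, rater, session) key.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DuplicateKeyError, TableFormatError
from .io import LEVELS, QUARTILE_LABELS, SIDES

CSV_COLUMNS = [
    "subject_id", "level", "side", "quartile", "rater_id", "session_id", "mfi_percent",
]
KEY_COLUMNS = CSV_COLUMNS[:-1]


@dataclass(frozen=True)
class MfiMeasurement:
    """One normalized MFI% observation."""

    subject_id: str
    level: str
    side: str
    quartile: str
    rater_id: str
    session_id: str
    mfi_percent: float

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"level must be one of {LEVELS}, got {self.level!r}")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.quartile not in QUARTILE_LABELS:
            raise ValueError(
                f"quartile must be one of {QUARTILE_LABELS}, got {self.quartile!r}"
            )
        if not np.isfinite(self.mfi_percent) or self.mfi_percent < 0:
            raise ValueError("mfi_percent must be finite and non-negative")


class MeasurementTable:
    """Collection of :class:`MfiMeasurement` rows, unique on the 6-part key.

    Thin wrapper over a pandas DataFrame; ``df`` exposes the validated frame.
    ``metadata`` carries simulation ground truth (e.g. a theoretical ICC) when
    the table was generated rather than measured.
    """

    def __init__(self, df: pd.DataFrame, metadata: dict | None = None):
        df = df.copy()
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise TableFormatError(f"missing column(s): {missing}")
        df = df[CSV_COLUMNS]
        for col in KEY_COLUMNS:
            df[col] = df[col].astype(str)
        try:
            df["mfi_percent"] = pd.to_numeric(df["mfi_percent"], errors="raise")
        except (ValueError, TypeError) as exc:
            raise TableFormatError(f"non-numeric mfi_percent value: {exc}") from exc
        if len(df) == 0:
            raise TableFormatError("measurement table is empty")

        bad_level = set(df["level"]) - set(LEVELS)
        bad_side = set(df["side"]) - set(SIDES)
        bad_q = set(df["quartile"]) - set(QUARTILE_LABELS)
        if bad_level or bad_side or bad_q:
            raise TableFormatError(
                f"invalid enum values: level={bad_level} side={bad_side} quartile={bad_q}"
            )
        if not np.isfinite(df["mfi_percent"]).all() or (df["mfi_percent"] < 0).any():
            raise TableFormatError("mfi_percent must be finite and non-negative")

        dup = df.duplicated(subset=KEY_COLUMNS)
        if dup.any():
            first = df.loc[dup.idxmax(), KEY_COLUMNS].tolist()
            raise DuplicateKeyError(f"duplicated measurement key: {first}")

        self._df = df.reset_index(drop=True)
        self.metadata = dict(metadata or {})

    @classmethod
    def from_measurements(cls, rows: list[MfiMeasurement], metadata: dict | None = None):
        if not rows:
            raise TableFormatError("no measurements provided")
        return cls(pd.DataFrame([vars(r) for r in rows]), metadata=metadata)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MeasurementTable):
            return NotImplemented
        a = self._df.sort_values(KEY_COLUMNS).reset_index(drop=True)
        b = other._df.sort_values(KEY_COLUMNS).reset_index(drop=True)
        return a.equals(b)

    def filter(self, **criteria) -> pd.DataFrame:
        """Subset the frame by column equality, e.g. ``filter(level="L3", side="left")``.

        Values may be scalars or collections; unknown column names raise.
        """
        df = self._df
        for col, val in criteria.items():
            if col not in df.columns:
                raise KeyError(f"unknown column {col!r}")
            if isinstance(val, (list, tuple, set, frozenset)):
                df = df[df[col].isin(val)]
            else:
                df = df[df[col] == val]
        return df

    def raters(self) -> list[str]:
        return sorted(self._df["rater_id"].unique())

    def sessions(self) -> list[str]:
        return sorted(self._df["session_id"].unique())


def write_measurement_table(table: MeasurementTable, path) -> None:
    """Write the table as CSV with the canonical header, full float precision."""
    table.df.to_csv(path, index=False, columns=CSV_COLUMNS)


def read_measurement_table(path) -> MeasurementTable:
    """Read a measurement CSV, validating header, enums and key uniqueness."""
    path = Path(path)
    if not path.exists():
        raise TableFormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, dtype={c: str for c in KEY_COLUMNS})
    except pd.errors.EmptyDataError as exc:
        raise TableFormatError(f"{path}: empty CSV") from exc
    if list(df.columns) != CSV_COLUMNS:
        raise TableFormatError(
            f"{path}: expected header {','.join(CSV_COLUMNS)}, got {','.join(df.columns)}"
        )
    return MeasurementTable(df)
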