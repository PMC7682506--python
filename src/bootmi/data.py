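"""Rectangular datasets with explicit missingness.

A :class:`Dataset` is a thin wrapper around a :class:`pandas.DataFrame` of
numeric columns. The package-wide missing-data marker is ``NaN``; on disk a
declared text token (default ``"NA"``) is used instead, so CSV round trips are
lossless for any choice of token.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError

DEFAULT_MISSING_TOKEN = "NA"


@dataclass
class Dataset:
    """Numeric rectangular data with NaN marking missing cells.

    Parameters
    ----------
    frame
        Data table. All columns must be numeric; the frame is copied and cast
        to float64 so callers cannot mutate observed cells from outside.
    """

    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not isinstance(self.frame, pd.DataFrame):
            self.frame = pd.DataFrame(self.frame)
        bad = [c for c in self.frame.columns if not pd.api.types.is_numeric_dtype(self.frame[c])]
        if bad:
            raise DataError(f"non-numeric columns: {bad}")
        self.frame = self.frame.astype(float).reset_index(drop=True)

    # -- basic accessors ---------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def columns(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        """Per-cell boolean mask, True where the value is missing."""
        return self.frame.isna()

    def column(self, name: str) -> np.ndarray:
        if name not in self.frame.columns:
            raise DataError(f"no such column: {name!r}")
        return self.frame[name].to_numpy(dtype=float)

    def with_column(self, name: str, values) -> "Dataset":
        """Return a new Dataset with column ``name`` replaced."""
        frame = self.frame.copy()
        frame[name] = np.asarray(values, dtype=float)
        return Dataset(frame)

    # -- validation helpers ------------------------------------------------
    def require_complete(self, names) -> None:
        for name in names:
            if np.isnan(self.column(name)).any():
                raise DataError(f"column {name!r} contains missing values")

    def require_binary(self, name: str) -> None:
        vals = self.column(name)
        vals = vals[~np.isnan(vals)]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise DataError(f"column {name!r} is not binary (values outside {{0,1}})")


def read_csv(path, missing_token: str = DEFAULT_MISSING_TOKEN) -> Dataset:
    """Read a delimited text table, treating only ``missing_token`` as missing."""
    frame = pd.read_csv(path, na_values=[missing_token], keep_default_na=False)
    return Dataset(frame)


def write_csv(data: Dataset, path, missing_token: str = DEFAULT_MISSING_TOKEN) -> None:
    data.frame.to_csv(path, index=False, na_rep=missing_token)
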