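"""Person-level dataset container.

A :class:`Dataset` holds one record per subject: a binary outcome ``y``, a
main error-prone exposure measurement ``w1``, an optional repeat ``w2``
(missing for subjects without a second measurement, encoded as NaN), a block
of error-free covariates ``z1..zk``, and — for simulated data only — the
true exposure ``x``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Dataset"]


@dataclass
class Dataset:
    """Tabular study data with canonical column names.

    Parameters
    ----------
    df : pandas.DataFrame
        Must contain columns ``id``, ``y``, ``w1``; optionally ``w2``
        (NaN = no repeat), covariates ``z1..zk`` and true exposure ``x``.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"id", "y", "w1"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"dataset missing required columns: {sorted(missing)}")
        y = self.df["y"].to_numpy()
        if not np.isin(y, [0, 1]).all():
            bad = sorted(set(y) - {0, 1})
            raise ValueError(f"outcome y must be coded 0/1; found values {bad}")
        if self.df["id"].duplicated().any():
            raise ValueError("duplicate subject ids")
        if self.df["w1"].isna().any():
            n_bad = int(self.df["w1"].isna().sum())
            raise ValueError(f"{n_bad} subjects have missing w1; drop them upstream")
        for c in self.z_columns:
            if self.df[c].isna().any():
                raise ValueError(f"covariate {c} has missing values (complete-case required)")

    # -- accessors ---------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def y(self) -> np.ndarray:
        return self.df["y"].to_numpy(dtype=int)

    @property
    def w1(self) -> np.ndarray:
        return self.df["w1"].to_numpy(dtype=float)

    @property
    def w2(self) -> np.ndarray:
        """Repeat measurement; NaN where absent."""
        if "w2" not in self.df.columns:
            return np.full(self.n, np.nan)
        return self.df["w2"].to_numpy(dtype=float)

    @property
    def x(self) -> np.ndarray | None:
        if "x" not in self.df.columns:
            return None
        return self.df["x"].to_numpy(dtype=float)

    @property
    def z_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("z") and c[1:].isdigit()]

    @property
    def z(self) -> np.ndarray:
        """Covariate matrix, shape (n, k); k may be 0."""
        cols = self.z_columns
        if not cols:
            return np.empty((self.n, 0))
        return self.df[cols].to_numpy(dtype=float)

    @property
    def has_repeat(self) -> np.ndarray:
        return ~np.isnan(self.w2)

    @property
    def n_repeat(self) -> int:
        return int(self.has_repeat.sum())

    @property
    def n_cases(self) -> int:
        return int(self.y.sum())

    def repeat_subset(self) -> "Dataset":
        return Dataset(self.df.loc[self.has_repeat].reset_index(drop=True))

    def with_log_exposure(self) -> "Dataset":
        """Log-transform w1/w2 (and x if present); requires positive values."""
        df = self.df.copy()
        if (df["w1"] <= 0).any():
            raise ValueError("log transform requires strictly positive w1")
        df["w1"] = np.log(df["w1"])
        if "w2" in df.columns:
            if (df["w2"].dropna() <= 0).any():
                raise ValueError("log transform requires strictly positive w2")
            df["w2"] = np.log(df["w2"])
        if "x" in df.columns:
            df["x"] = np.log(df["x"])
        return Dataset(df)

    def resample(self, idx: np.ndarray) -> "Dataset":
        """Row-resampled copy with fresh unique ids (for the bootstrap)."""
        df = self.df.iloc[idx].reset_index(drop=True)
        df = df.assign(id=np.arange(len(df)))
        return Dataset(df)
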