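"""Reading and writing person-level datasets as delimited text.

The canonical on-disk form is comma-separated with a header row
``id,y,w1,w2,z1..zk,x``; a missing repeat measurement W2 is an empty
field, never a sentinel number. Floats are written with repr precision so
a write/read round trip is bit-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import Dataset

__all__ = ["write_dataset", "read_dataset"]

log = logging.getLogger("errkit")

CANONICAL = ("id", "y", "w1", "w2", "x")


def write_dataset(dataset: Dataset, path) -> None:
    df = dataset.df
    ordered = [c for c in ("id", "y", "w1", "w2") if c in df.columns]
    ordered += dataset.z_columns
    if "x" in df.columns:
        ordered.append("x")
    # %.17g guarantees a bit-identical float round trip through text
    df[ordered].to_csv(path, index=False, float_format="%.17g")


def read_dataset(path, columns: dict | None = None,
                 na_values=("", "NA")) -> Dataset:
    """Read a delimited file into a Dataset.

    ``columns`` optionally maps canonical names to file column names, e.g.
    ``{"y": "case", "w1": "diary1", "w2": "diary2", "z": ["age", "sex"]}``.
    Unmapped canonical z columns are any file columns named z1..zk.
    """
    raw = pd.read_csv(path, na_values=list(na_values), keep_default_na=True,
                      float_precision="round_trip")
    columns = columns or {}
    rename = {}
    for canon in ("id", "y", "w1", "w2", "x"):
        src = columns.get(canon, canon)
        if src in raw.columns:
            rename[src] = canon
        elif canon in ("y", "w1"):
            raise ValueError(f"required column {canon!r} (file column {src!r}) "
                             "not found")
    z_list = columns.get("z")
    if z_list is not None:
        for j, src in enumerate(z_list, start=1):
            if src not in raw.columns:
                raise ValueError(f"covariate column {src!r} not found")
            rename[src] = f"z{j}"
    df = raw.rename(columns=rename)
    keep = [c for c in df.columns
            if c in CANONICAL or (c.startswith("z") and c[1:].isdigit())]
    df = df[keep]
    if "id" not in df.columns:
        df.insert(0, "id", np.arange(len(df)))

    y_vals = set(pd.unique(df["y"].dropna()))
    if not y_vals <= {0, 1}:
        raise ValueError(f"outcome must be coded 0/1; found {sorted(y_vals)}; "
                         "recode it explicitly before analysis")
    if not np.issubdtype(df["w1"].dtype, np.number):
        raise ValueError("exposure w1 is not numeric")
    ds = Dataset(df)
    log.info("read %d subjects (%d cases); %d (%.0f%%) with a repeat measurement",
             ds.n, ds.n_cases, ds.n_repeat, 100.0 * ds.n_repeat / max(ds.n, 1))
    return ds
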