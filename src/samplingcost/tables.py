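"""Tabular I/O: the single TSV dialect used across the package.

All tables are tab-delimited UTF-8 with a header row and '.' decimals.
Reading-time tables require columns subject_id, item_id, surprisal, rt;
prev_surprisal is optional and derived from item order within subject when
absent.
"""

from __future__ import annotations

import pandas as pd

from .synthetic import RTDataset, REQUIRED_COLUMNS

__all__ = ["read_rt_table", "write_rt_table"]

RT_COLUMNS = ("subject_id", "item_id", "surprisal", "prev_surprisal", "rt")


def read_rt_table(path) -> RTDataset:
    """Read and validate an RT table from TSV.

    Missing required columns, non-positive reading times, and duplicate
    (subject, item) pairs raise errors naming the offending columns/rows.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return RTDataset(df, provenance="external")


def write_rt_table(data: RTDataset, path) -> None:
    """Write an RT table as TSV with the canonical column order."""
    data.frame.loc[:, list(RT_COLUMNS)].to_csv(path, sep="\t", index=False)
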