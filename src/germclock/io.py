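"""Readers/writers for the pipeline's plain-text formats.

Beta and M matrices travel as TSV (first column probe id, remaining
columns sample ids, one row per CpG); the region map as a BED-like TSV
(region_id, comma-joined probe ids, flags); cohort/phenotype tables as
CSV; fitted clocks as JSON.
"""

from __future__ import annotations

import pandas as pd

from .cohort import RegionMap

__all__ = [
    "read_beta_tsv",
    "write_beta_tsv",
    "read_region_map",
    "write_region_map",
    "read_cohort_csv",
]


def write_beta_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="probe_id")


def read_beta_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicate probe ids in matrix")
    if df.columns.duplicated().any():
        raise ValueError("duplicate sample ids in matrix")
    return df


def write_region_map(region_map: RegionMap, path) -> None:
    region_map.to_frame().to_csv(path, sep="\t", index=False)


def read_region_map(path) -> RegionMap:
    return RegionMap.from_frame(pd.read_csv(path, sep="\t"))


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df["id"].duplicated().any():
        raise ValueError("duplicate participant ids in cohort table")
    return df
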