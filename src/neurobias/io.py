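"""CSV readers/writers for the package's tabular interchange formats.

All files are UTF-8 with '.' decimal separators.  Concentration-response
tables are long format (``agonist, pathway, conc_M, replicate, response``);
GIRK traces are two-column (``time_s, current``).
"""

from __future__ import annotations

import pandas as pd

from .girk_kinetics import GIRKTrace

__all__ = [
    "DATASET_COLUMNS",
    "read_dataset",
    "write_dataset",
    "read_girk_trace",
    "write_girk_trace",
]

DATASET_COLUMNS = ["agonist", "pathway", "conc_M", "replicate", "response"]


def write_dataset(path, dataset: pd.DataFrame) -> None:
    missing = [c for c in DATASET_COLUMNS if c not in dataset.columns]
    if missing:
        raise ValueError(f"dataset missing columns: {missing}")
    dataset.to_csv(path, index=False, float_format="%.17g")


def read_dataset(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def write_girk_trace(path, trace: GIRKTrace) -> None:
    pd.DataFrame({"time_s": trace.time, "current": trace.current}).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_girk_trace(path) -> GIRKTrace:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_s", "current"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return GIRKTrace(time=df["time_s"].to_numpy(float), current=df["current"].to_numpy(float))
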