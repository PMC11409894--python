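"""CSV readers and writers for the pipeline's tables.

All tables are UTF-8 CSV with a header row.  Genotype matrices travel as
two-character call codes (``AA`` homozygous reference, ``AB`` heterozygous,
``BB`` homozygous alternate, ``--`` missing) and are held in memory as
0/1/2 integer calls with −1 for missing.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from orcadiet.calibration import MockDesign

CALL_CODES = {0: "AA", 1: "AB", 2: "BB", -1: "--"}
CODE_CALLS = {v: k for k, v in CALL_CODES.items()}


def read_counts(path: str | Path) -> pd.DataFrame:
    """Sample × species read counts; first column is the sample ID."""
    df = pd.read_csv(path, index_col=0)
    return df.astype(int)


def write_counts(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index_label="sample_id")


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0, dtype={"replicate_group": str})
    if "replicate_group" in df:
        df["replicate_group"] = df["replicate_group"].fillna("")
    return df


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, index_label="sample_id")


def read_mock_design(proportions_path: str | Path, replicates_path: str | Path) -> MockDesign:
    """Mock design from a control × species proportion CSV and a
    sample → control replicate map CSV (columns: sample_id, control)."""
    props = pd.read_csv(proportions_path, index_col=0)
    reps = pd.read_csv(replicates_path, index_col=0)["control"]
    return MockDesign(props, reps)


def write_mock_design(design: MockDesign, proportions_path: str | Path, replicates_path: str | Path) -> None:
    design.proportions.to_csv(proportions_path, index_label="control")
    design.replicates.rename("control").to_csv(replicates_path, index_label="sample_id")


def read_genotypes(path: str | Path) -> pd.DataFrame:
    """Genotype matrix from two-character call codes."""
    raw = pd.read_csv(path, index_col=0, dtype=str)
    bad = set(np.unique(raw.fillna("--").values)) - set(CODE_CALLS)
    if bad:
        raise ValueError(f"unknown genotype codes: {sorted(bad)}")
    return raw.fillna("--").apply(lambda col: col.map(CODE_CALLS)).astype(np.int8)


def write_genotypes(matrix: pd.DataFrame, path: str | Path, index_label: str = "sample_id") -> None:
    coded = matrix.apply(lambda col: col.map(CALL_CODES))
    coded.to_csv(path, index_label=index_label)


def read_proportions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0).astype(float)


def write_proportions(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index_label="sample_id", float_format="%.10g")
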