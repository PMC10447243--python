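"""Readers and writers for the tabular dialects the pipeline consumes.

The proteomics stage reads the MaxQuant ``proteinGroups.txt`` dialect: a
tab-separated table with one identifier column (``Majority protein IDs``)
and one ``LFQ intensity <sample>`` column per sample.  Zero intensities are
treated as missing (the MaxQuant convention for proteins not quantified in a
sample), and rows flagged ``+`` in ``Reverse`` or ``Potential contaminant``
columns are dropped when those columns are present.
"""

from __future__ import annotations

import pathlib
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

LFQ_PREFIX = "LFQ intensity "
ID_COLUMN = "Majority protein IDs"
_FLAG_COLUMNS = ("Reverse", "Potential contaminant", "Only identified by site")


def read_protein_groups(
    path: str | pathlib.Path,
    *,
    zero_is_missing: bool = True,
    apply_row_filters: bool = True,
) -> pd.DataFrame:
    """Read a proteinGroups-style TSV into a protein x sample intensity frame.

    Returns a DataFrame indexed by protein id with one column per sample
    (the ``LFQ intensity `` prefix stripped); missing values are NaN.
    """
    raw = pd.read_csv(path, sep="\t", dtype={ID_COLUMN: str})
    if ID_COLUMN not in raw.columns:
        raise ValueError(f"column {ID_COLUMN!r} not found in {path}")
    lfq_cols = [c for c in raw.columns if c.startswith(LFQ_PREFIX)]
    if not lfq_cols:
        raise ValueError(f"no '{LFQ_PREFIX}<sample>' columns found in {path}")
    if apply_row_filters:
        for col in _FLAG_COLUMNS:
            if col in raw.columns:
                raw = raw[raw[col].fillna("") != "+"]
    mat = raw.set_index(ID_COLUMN)[lfq_cols].astype(float)
    mat.columns = [c[len(LFQ_PREFIX):] for c in lfq_cols]
    if zero_is_missing:
        mat = mat.where(mat != 0.0, np.nan)
    mat.index.name = "protein_id"
    return mat


def write_protein_groups(
    intensities: pd.DataFrame,
    path: str | pathlib.Path,
    *,
    missing_as_zero: bool = True,
) -> None:
    """Write a protein x sample frame in the proteinGroups TSV dialect."""
    out = intensities.copy()
    out.columns = [LFQ_PREFIX + str(c) for c in out.columns]
    if missing_as_zero:
        out = out.fillna(0.0)
    out.index.name = ID_COLUMN
    out.to_csv(path, sep="\t")


def read_design(path: str | pathlib.Path) -> pd.DataFrame:
    """Read a sample design table (sample, group, biosample columns)."""
    design = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "group"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table missing columns: {sorted(missing)}")
    if "biosample" not in design.columns:
        design["biosample"] = design["sample"]
    return design.set_index("sample")


def write_design(design: pd.DataFrame, path: str | pathlib.Path) -> None:
    design.to_csv(path, sep="\t", index_label="sample")


def read_gmt(path: str | pathlib.Path) -> dict[str, set[str]]:
    """Read gene sets from GMT (name <tab> description <tab> members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | pathlib.Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, name] + sorted(members)) + "\n")
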