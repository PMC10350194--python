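"""Plain-TSV readers and writers for every stage artifact.

All floats are written with a fixed general format so that identical inputs
reproduce byte-identical files.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

from trap_rescue.design import validate_design
from trap_rescue.errors import DataError

FLOAT_FORMAT = "%.10g"


def write_table(frame: pd.DataFrame, path, index_label: str | None = "gene_id") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT,
                 index=index_label is not None, index_label=index_label)


def read_counts(path) -> pd.DataFrame:
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if counts.index.duplicated().any():
        raise DataError("duplicate gene_ids in count matrix")
    if (counts.to_numpy() < 0).any():
        raise DataError("negative entries in count matrix")
    return counts


def write_counts(counts: pd.DataFrame, path) -> None:
    write_table(counts, path)


def read_design(path) -> pd.DataFrame:
    return validate_design(pd.read_csv(path, sep="\t"))


def write_design(design: pd.DataFrame, path) -> None:
    write_table(design, path, index_label=None)


def read_de_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
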