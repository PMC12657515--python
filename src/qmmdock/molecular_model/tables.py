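"""Benchmark metadata tables as TSV with a header row."""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Sequence, Union

from qmmdock.errors import FormatError
from qmmdock.molecular_model.types import BenchmarkRecord

PathLike = Union[str, Path]

_COLUMNS = [
    "complex_id",
    "resolution",
    "dpi",
    "ligand_b_factor_avg",
    "ediam",
    "mw",
    "n_rotatable_bonds",
    "ghose_pass_count",
    "lipinski_pass_count",
    "has_missing_atoms",
    "has_altlocs",
    "min_crystal_contact",
]

_FLOATS = {"resolution", "dpi", "ligand_b_factor_avg", "ediam", "mw",
           "min_crystal_contact"}
_INTS = {"n_rotatable_bonds", "ghose_pass_count", "lipinski_pass_count"}
_BOOLS = {"has_missing_atoms", "has_altlocs"}


def write_benchmark_tsv(records: Sequence[BenchmarkRecord], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    getattr(r, c) if c not in _BOOLS else int(getattr(r, c))
                    for c in _COLUMNS
                ]
            )


def read_benchmark_tsv(path: PathLike) -> list[BenchmarkRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or set(reader.fieldnames) != set(_COLUMNS):
            raise FormatError(f"{path}: expected header columns {_COLUMNS}")
        for lineno, row in enumerate(reader, start=2):
            kwargs = {}
            for col in _COLUMNS:
                raw = row[col]
                try:
                    if col in _FLOATS:
                        kwargs[col] = float(raw)
                    elif col in _INTS:
                        kwargs[col] = int(raw)
                    elif col in _BOOLS:
                        kwargs[col] = bool(int(raw))
                    else:
                        kwargs[col] = raw
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: bad value for {col}") from exc
            records.append(BenchmarkRecord(**kwargs))
    return records
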