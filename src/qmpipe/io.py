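"""Readers and writers for the plain-text file dialects of the pipeline.

All tables are UTF-8 text with a mandatory header row: tab-separated for
taxon-indexed matrices (``counts.tsv``, ``taxonomy.tsv``,
``copy_numbers.tsv``) and comma-separated for per-sample values and
participant metadata.  Readers validate identifiers and value types and
report offending lines or columns.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import ParticipantRecord

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_taxonomy",
    "write_taxonomy",
    "read_sample_values",
    "write_sample_values",
    "read_copy_numbers",
    "write_copy_numbers",
    "read_metadata",
    "write_metadata",
]

TAXONOMY_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")

METADATA_COLUMNS = (
    ["sample_id", "age", "sex", "bmi", "se_copies",
     "acpa_titre", "acpa_uln", "rf_titre", "rf_uln", "ra33_titre", "ra33_uln"]
    + [f"csa_item_{i}" for i in range(1, 8)]
    + ["ra_diagnosis"]
)


def _check_unique(names, what: str, path) -> None:
    seen: dict[str, int] = {}
    for name in names:
        seen[name] = seen.get(name, 0) + 1
    dups = [n for n, c in seen.items() if c > 1]
    if dups:
        raise ValueError(f"{path}: duplicated {what}: {dups[:5]}")


def read_count_matrix(path) -> pd.DataFrame:
    """Read a taxa x samples integer count matrix (``counts.tsv`` dialect).

    Rejects duplicated identifiers, ragged rows, negative and
    non-integer cells, naming the offending location.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if not header or header[0] != "taxon_id":
            raise ValueError(f"{path}: first header column must be 'taxon_id'")
        samples = header[1:]
        _check_unique(samples, "sample columns", path)
        taxa: list[str] = []
        rows: list[list[int]] = []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            taxa.append(row[0])
            values: list[int] = []
            for col, cell in zip(samples, row[1:]):
                try:
                    v = int(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}:{lineno}: non-integer count {cell!r} "
                        f"in column {col!r}"
                    ) from None
                if v < 0:
                    raise ValueError(
                        f"{path}:{lineno}: negative count in column {col!r}"
                    )
                values.append(v)
            rows.append(values)
    _check_unique(taxa, "taxon ids", path)
    return pd.DataFrame(
        np.asarray(rows, dtype=np.int64), index=pd.Index(taxa, name="taxon_id"),
        columns=samples,
    )


def write_count_matrix(counts: pd.DataFrame, path) -> None:
    out = counts.copy()
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def read_taxonomy(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    expected = ["taxon_id", *TAXONOMY_RANKS]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    _check_unique(df["taxon_id"], "taxon ids", path)
    return df.set_index("taxon_id")


def write_taxonomy(taxonomy: pd.DataFrame, path) -> None:
    out = taxonomy.copy()
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t")


def read_sample_values(path) -> pd.Series:
    """Read a ``sample_id,value`` CSV into a float series."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"sample_id": str})
    if list(df.columns) != ["sample_id", "value"]:
        raise ValueError(f"{path}: expected columns sample_id,value")
    _check_unique(df["sample_id"], "sample ids", path)
    return pd.Series(
        df["value"].astype(float).values, index=df["sample_id"].values,
        name="value",
    )


def write_sample_values(values: pd.Series, path) -> None:
    df = pd.DataFrame({"sample_id": values.index, "value": values.values})
    df.to_csv(path, index=False)


def read_copy_numbers(path) -> pd.Series:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"taxon_id": str})
    if list(df.columns) != ["taxon_id", "copy_number"]:
        raise ValueError(f"{path}: expected columns taxon_id,copy_number")
    _check_unique(df["taxon_id"], "taxon ids", path)
    return pd.Series(
        df["copy_number"].astype(float).values, index=df["taxon_id"].values,
        name="copy_number",
    )


def write_copy_numbers(copy_numbers: pd.Series, path) -> None:
    df = pd.DataFrame(
        {"taxon_id": copy_numbers.index, "copy_number": copy_numbers.values}
    )
    df.to_csv(path, sep="\t", index=False)


def _opt_float(cell: str):
    return None if cell == "" else float(cell)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def read_metadata(path) -> list[ParticipantRecord]:
    """Read participant metadata into validated records.

    Missing values are empty strings; CSA items are 1 (positive),
    0 (negative) or empty (missing).
    """
    path = Path(path)
    records: list[ParticipantRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != METADATA_COLUMNS:
            raise ValueError(
                f"{path}: expected columns {METADATA_COLUMNS}, "
                f"got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                items = []
                for i in range(1, 8):
                    cell = row[f"csa_item_{i}"]
                    items.append(None if cell == "" else bool(int(cell)))
                se = row["se_copies"]
                records.append(
                    ParticipantRecord(
                        participant_id=row["sample_id"],
                        age=float(row["age"]),
                        sex=row["sex"],
                        bmi=_opt_float(row["bmi"]),
                        se_copies=None if se == "" else int(se),
                        acpa_titre=_opt_float(row["acpa_titre"]),
                        acpa_uln=_opt_float(row["acpa_uln"]),
                        rf_titre=_opt_float(row["rf_titre"]),
                        rf_uln=_opt_float(row["rf_uln"]),
                        ra33_titre=_opt_float(row["ra33_titre"]),
                        ra33_uln=_opt_float(row["ra33_uln"]),
                        csa_items=tuple(items),
                        ra_diagnosis=bool(int(row["ra_diagnosis"])),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    _check_unique([r.participant_id for r in records], "participant ids", path)
    return records


def write_metadata(records, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(METADATA_COLUMNS)
        for r in records:
            row = [
                r.participant_id, _fmt(float(r.age)), r.sex, _fmt(r.bmi),
                _fmt(r.se_copies),
                _fmt(r.acpa_titre), _fmt(r.acpa_uln),
                _fmt(r.rf_titre), _fmt(r.rf_uln),
                _fmt(r.ra33_titre), _fmt(r.ra33_uln),
            ]
            row += [_fmt(it) for it in r.csa_items]
            row.append(_fmt(r.ra_diagnosis))
            writer.writerow(row)
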