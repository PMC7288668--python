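"""Readers and writers for the plain-text formats the pipeline touches:
FASTA (protein / DNA), gene × sample TSV tables, and TSV/JSON result
tables."""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .records import DnaRecord, ExpressionTable, ProteinRecord

logger = logging.getLogger(__name__)


class FastaParseError(ValueError):
    pass


class TableParseError(ValueError):
    pass


def read_fasta(path: str | Path, alphabet: str = "protein"):
    """Read a FASTA file into ProteinRecord or DnaRecord objects.

    Order is preserved; duplicate ids are rejected; lowercase sequence is
    uppercased with a warning.  ``alphabet`` is ``"protein"`` or ``"dna"``.
    """
    if alphabet not in ("protein", "dna"):
        raise ValueError(f"unknown alphabet {alphabet!r}")
    cls = ProteinRecord if alphabet == "protein" else DnaRecord
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not rec.id:
            raise FastaParseError(f"{path}: record with empty id")
        if not seq:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        if seq != seq.upper():
            logger.warning("record %s: lowercase sequence uppercased on read", rec.id)
            seq = seq.upper()
        records.append(cls(id=rec.id, sequence=seq, description=rec.description))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ProteinRecord | DnaRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), 60):
                fh.write(rec.sequence[i : i + 60] + "\n")


def read_expression_table(
    path: str | Path, kind: str = "relative", missing_token: str = "NA"
) -> ExpressionTable:
    """Read a TSV with gene ids in the first column and sample ids in the
    header row.  Cells equal to ``missing_token`` (or empty) become NaN;
    any other non-numeric cell raises with its coordinates."""
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise TableParseError(f"{path}: empty table")
    n_fields = len(lines[0].split("\t"))
    for lineno, line in enumerate(lines[1:], start=2):
        if len(line.split("\t")) != n_fields:
            raise TableParseError(
                f"{path}: line {lineno} has {len(line.split(chr(9)))} fields, "
                f"header has {n_fields}"
            )
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise TableParseError(f"{path}: duplicate gene id {dup!r}")
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for j, sample in enumerate(raw.columns):
        for i, gene in enumerate(raw.index):
            cell = raw.iat[i, j].strip()
            if cell == "" or cell == missing_token:
                values.iat[i, j] = float("nan")
                continue
            try:
                values.iat[i, j] = float(cell)
            except ValueError:
                raise TableParseError(
                    f"{path}: non-numeric cell {cell!r} at gene {gene!r}, "
                    f"sample {sample!r} (row {i + 2}, column {j + 2})"
                ) from None
    return ExpressionTable(values=values, kind=kind)


def write_expression_table(table: ExpressionTable, path: str | Path,
                           missing_token: str = "NA") -> None:
    table.values.to_csv(path, sep="\t", na_rep=missing_token, index_label="gene")


def _rows_to_frame(rows) -> pd.DataFrame:
    if isinstance(rows, pd.DataFrame):
        return rows
    return pd.DataFrame(list(rows))


def write_table(rows: pd.DataFrame | Sequence[dict], path: str | Path,
                format: str = "tsv") -> None:
    """Write a homogeneous result table as TSV (tab separator, '.' decimal
    point, repr-round-trip floats) or JSON (list of objects keyed by
    column name)."""
    frame = _rows_to_frame(rows)
    path = Path(path)
    if format == "tsv":
        frame.to_csv(path, sep="\t", index=False, na_rep="NA")
    elif format == "json":
        payload = frame.to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=str)
            fh.write("\n")
    else:
        raise ValueError(f"unknown table format {format!r}")


def read_table(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    if format == "tsv":
        return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    if format == "json":
        with open(path) as fh:
            return pd.DataFrame(json.load(fh))
    raise ValueError(f"unknown table format {format!r}")
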