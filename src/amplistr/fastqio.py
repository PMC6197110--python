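"""FASTQ streaming and tabular output helpers.

FASTQ reading goes through Biopython's fast general iterator and is
transparently gzip-aware; tables are written as UTF-8 tab-separated text
with a header row and '.' for missing values.
"""

from __future__ import annotations

import gzip

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = ["read_fastq", "collapse_reads", "write_table", "read_table"]

MISSING = "."


def _open_in(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fastq(path):
    """Stream (title, sequence, quality) tuples from a FASTQ(.gz) file.

    Malformed records raise a ValueError naming the offending record
    index.
    """
    with _open_in(path) as fh:
        idx = 0
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                idx += 1
                if len(seq) != len(qual):
                    raise ValueError(
                        f"{path}: record {idx}: sequence/quality length mismatch")
                yield title, seq, qual
        except ValueError as e:
            raise ValueError(f"{path}: record {idx + 1}: {e}") from e


def collapse_reads(records) -> list[tuple[str, int]]:
    """Collapse a FASTQ stream to unique (sequence, count) pairs."""
    counts: dict[str, int] = {}
    for _title, seq, _qual in records:
        counts[seq] = counts.get(seq, 0) + 1
    return list(counts.items())


def write_table(rows: list[dict], path, columns: list[str] | None = None) -> None:
    """Write dict rows as a TSV with a header; None becomes '.'."""
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(
                MISSING if row.get(c) is None else str(row.get(c, MISSING))
                for c in columns) + "\n")


def read_table(path) -> list[dict]:
    """Read a TSV written by :func:`write_table`; '.' maps back to None."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        rows = []
        for line in fh:
            values = line.rstrip("\n").split("\t")
            rows.append({c: (None if v == MISSING else v)
                         for c, v in zip(header, values)})
    return rows
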