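"""Embedded relational store for filtered reads and per-pool coverage.

Filtered reads are persisted in a single-file sqlite database, one table
per (element type x library) — with N element types (the 5' and 3' ends of
the element) and L pooled libraries the store holds N*L tables, each with
the same three fields (index_seq, trimmed_seq, read_id). Query logic is
generated internally; users never write SQL.

Coverage of an index sequence in a library is the number of reads sharing
that index, normalized by the library's total read count to damp
per-library preparation and sequencing depth bias. Indices are ranked 1..K
in descending normalized coverage; these ranks are what the deconvolution
stage thresholds.
"""

from __future__ import annotations

import re
import sqlite3
from pathlib import Path
from typing import Iterable

import pandas as pd

from .preprocess import FilteredRead, read_filtered_tsv

COVERAGE_COLUMNS = ["index_seq", "raw_count", "norm_cov", "rank", "representative_read"]

_NAME_RE = re.compile(r"[^A-Za-z0-9_]")


def _safe(name: str) -> str:
    return _NAME_RE.sub("_", name)


class ReadStore:
    """Single-writer embedded store (path or ``":memory:"``)."""

    def __init__(self, path: str | Path = ":memory:") -> None:
        self.path = str(path)
        self._conn = sqlite3.connect(self.path)

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "ReadStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- schema --------------------------------------------------------------

    @staticmethod
    def table_name(element_type: str, library_id: str) -> str:
        return f"{_safe(element_type)}__{_safe(library_id)}"

    def tables(self) -> list[str]:
        rows = self._conn.execute(
            "SELECT name FROM sqlite_master WHERE type='table' ORDER BY name"
        ).fetchall()
        return [r[0] for r in rows]

    def _create(self, table: str) -> None:
        self._conn.execute(
            f'CREATE TABLE IF NOT EXISTS "{table}" '
            "(index_seq TEXT NOT NULL, trimmed_seq TEXT NOT NULL, read_id TEXT NOT NULL)"
        )

    # -- loading -------------------------------------------------------------

    def load_library(
        self,
        records: Iterable[FilteredRead],
        element_type: str,
        library_id: str,
        overwrite: bool = False,
    ) -> int:
        """Insert filtered reads 1:1 into the (element_type, library) table.

        Refuses to load into a non-empty table unless `overwrite` is given,
        in which case the table is replaced (idempotent re-runs).
        """
        table = self.table_name(element_type, library_id)
        self._create(table)
        (existing,) = self._conn.execute(f'SELECT COUNT(*) FROM "{table}"').fetchone()
        if existing:
            if not overwrite:
                raise ValueError(
                    f"table {table} already holds {existing} rows; pass overwrite=True"
                )
            self._conn.execute(f'DELETE FROM "{table}"')
        cur = self._conn.executemany(
            f'INSERT INTO "{table}" VALUES (?, ?, ?)',
            ((r.index_seq, r.trimmed_seq, r.read_id) for r in records),
        )
        self._conn.commit()
        return cur.rowcount

    def load_tsv(
        self,
        path: str | Path,
        element_type: str,
        library_id: str,
        overwrite: bool = False,
    ) -> int:
        """Import one tab-separated filtered-reads file."""
        return self.load_library(
            read_filtered_tsv(path, library_id), element_type, library_id, overwrite
        )

    def count(self, element_type: str, library_id: str) -> int:
        table = self.table_name(element_type, library_id)
        self._create(table)
        (n,) = self._conn.execute(f'SELECT COUNT(*) FROM "{table}"').fetchone()
        return n

    # -- coverage ------------------------------------------------------------

    def compute_coverage(self, element_type: str, library_id: str) -> pd.DataFrame:
        """Group the library's reads by index sequence into a coverage table.

        Returns a DataFrame with columns ``index_seq, raw_count, norm_cov,
        rank, representative_read``: raw_count reads share the index,
        norm_cov = raw_count / library total, ranks run 1..K in descending
        coverage (ties broken by ascending index_seq, deterministically),
        and representative_read is the modal full-length trimmed sequence
        among the index's reads (ties broken by ascending sequence).
        """
        table = self.table_name(element_type, library_id)
        self._create(table)
        counts = pd.read_sql_query(
            f'SELECT index_seq, COUNT(*) AS raw_count FROM "{table}" GROUP BY index_seq',
            self._conn,
        )
        if counts.empty:
            return pd.DataFrame(columns=COVERAGE_COLUMNS)
        total = int(counts["raw_count"].sum())
        counts["norm_cov"] = counts["raw_count"] / total
        counts = counts.sort_values(
            ["raw_count", "index_seq"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        counts["rank"] = counts.index + 1
        reps = pd.read_sql_query(
            f'SELECT index_seq, trimmed_seq, COUNT(*) AS c FROM "{table}" '
            "GROUP BY index_seq, trimmed_seq",
            self._conn,
        )
        reps = (
            reps.sort_values(["c", "trimmed_seq"], ascending=[False, True], kind="mergesort")
            .drop_duplicates("index_seq", keep="first")
            .rename(columns={"trimmed_seq": "representative_read"})
        )
        out = counts.merge(reps[["index_seq", "representative_read"]], on="index_seq")
        return out[COVERAGE_COLUMNS]

    def export_coverage(
        self, element_type: str, library_id: str, out_path: str | Path
    ) -> pd.DataFrame:
        cov = self.compute_coverage(element_type, library_id)
        cov.to_csv(out_path, sep="\t", index=False)
        return cov
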