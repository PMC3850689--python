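"""Geometry of a multidimensional pooled sample design.

Samples sit in a plate x row x column "cube" of wells. One sequencing
library is prepared per plate, per row and per column, so a design with
P plates, R rows and C columns holds P*R*C wells but only P+R+C pooled
libraries; each well is identified by the unique intersection of the three
pools that contain it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Iterator, Mapping

import yaml

#: Dimension names, in canonical order.
DIMENSIONS = ("plate", "row", "column")


@dataclass(frozen=True)
class Pool:
    """One pooled sequencing library: a whole plate, row or column."""

    dimension: str
    label: str
    library_id: str

    @property
    def key(self) -> tuple[str, str]:
        return (self.dimension, self.label)


class PoolDesign:
    """A 3-D pooling layout and its pool -> library correspondence.

    Parameters
    ----------
    plates, rows, columns:
        Ordered labels for each dimension (e.g. ``["01", ..., "10"]``,
        ``["A", ..., "H"]``, ``["01", ..., "12"]``).
    libraries:
        Optional mapping ``(dimension, label) -> library_id``. Defaults to
        ``"{dimension}_{label}"`` for every pool. Each library id must be
        unique (one library per pool).
    """

    def __init__(
        self,
        plates: list[str],
        rows: list[str],
        columns: list[str],
        libraries: Mapping[tuple[str, str], str] | None = None,
    ) -> None:
        self.plates = tuple(str(p) for p in plates)
        self.rows = tuple(str(r) for r in rows)
        self.columns = tuple(str(c) for c in columns)
        for name, labels in zip(DIMENSIONS, (self.plates, self.rows, self.columns)):
            if not labels:
                raise ValueError(f"design has no {name} labels")
            if len(set(labels)) != len(labels):
                raise ValueError(f"duplicate {name} labels: {labels}")
        lib_map: dict[tuple[str, str], str] = {}
        for dim, labels in zip(DIMENSIONS, (self.plates, self.rows, self.columns)):
            for label in labels:
                key = (dim, label)
                if libraries and key in libraries:
                    lib_map[key] = str(libraries[key])
                else:
                    lib_map[key] = f"{dim}_{label}"
        if len(set(lib_map.values())) != len(lib_map):
            raise ValueError("every pool must map to a distinct library_id")
        self._libraries = lib_map
        self._by_library = {v: k for k, v in lib_map.items()}

    # -- construction helpers ------------------------------------------------

    @classmethod
    def grid(cls, n_plates: int, n_rows: int, n_columns: int) -> "PoolDesign":
        """Standard microtiter-style labels: numeric plates, lettered rows,
        zero-padded numeric columns (well ``22E04`` = plate 22, row E, col 04).
        """
        if n_rows > 26:
            raise ValueError("row labels are single letters; at most 26 rows")
        plates = [f"{i + 1:02d}" for i in range(n_plates)]
        rows = [chr(ord("A") + i) for i in range(n_rows)]
        columns = [f"{i + 1:02d}" for i in range(n_columns)]
        return cls(plates, rows, columns)

    # -- geometry ------------------------------------------------------------

    def labels(self, dimension: str) -> tuple[str, ...]:
        try:
            return {
                "plate": self.plates,
                "row": self.rows,
                "column": self.columns,
            }[dimension]
        except KeyError:
            raise ValueError(f"unknown dimension {dimension!r}") from None

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.plates), len(self.rows), len(self.columns))

    @property
    def n_wells(self) -> int:
        p, r, c = self.shape
        return p * r * c

    @property
    def wells_per_plate(self) -> int:
        _, r, c = self.shape
        return r * c

    @property
    def n_pools(self) -> int:
        return sum(self.shape)

    def pools(self) -> tuple[Pool, ...]:
        return tuple(
            Pool(dim, label, self._libraries[(dim, label)])
            for dim in DIMENSIONS
            for label in self.labels(dim)
        )

    def library_for(self, dimension: str, label: str) -> str:
        return self._libraries[(dimension, str(label))]

    def pool_for_library(self, library_id: str) -> tuple[str, str]:
        return self._by_library[library_id]

    def expected_per_pool(self, dimension: str) -> int:
        """Number of wells (hence genuine elements) in one pool of `dimension`:
        R*C for a plate pool, P*C for a row pool, P*R for a column pool."""
        p, r, c = self.shape
        return {"plate": r * c, "row": p * c, "column": p * r}[dimension]

    def candidate_bound(self, dimension: str, threshold: float) -> int:
        """Coverage-rank cutoff ``floor(threshold * expected_per_pool)`` used
        to pick candidate elements in one pool of `dimension`."""
        if threshold <= 0:
            raise ValueError("threshold must be positive")
        return math.floor(threshold * self.expected_per_pool(dimension))

    # -- wells ---------------------------------------------------------------

    def iter_wells(self) -> Iterator[tuple[str, str, str]]:
        yield from product(self.plates, self.rows, self.columns)

    def well_label(self, plate: str, row: str, column: str) -> str:
        if (
            plate not in self.plates
            or row not in self.rows
            or column not in self.columns
        ):
            raise ValueError(f"well ({plate},{row},{column}) outside design")
        return f"{plate}{row}{column}"

    def pools_of_well(self, plate: str, row: str, column: str) -> tuple[Pool, ...]:
        return (
            Pool("plate", plate, self.library_for("plate", plate)),
            Pool("row", row, self.library_for("row", row)),
            Pool("column", column, self.library_for("column", column)),
        )

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "plates": list(self.plates),
            "rows": list(self.rows),
            "columns": list(self.columns),
            "libraries": {
                f"{dim}:{label}": lib for (dim, label), lib in self._libraries.items()
            },
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "PoolDesign":
        libraries = None
        if "libraries" in data and data["libraries"]:
            libraries = {}
            for key, lib in data["libraries"].items():
                dim, _, label = str(key).partition(":")
                libraries[(dim, label)] = lib
        return cls(data["plates"], data["rows"], data["columns"], libraries)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PoolDesign":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def __repr__(self) -> str:  # pragma: no cover
        p, r, c = self.shape
        return f"PoolDesign({p} plates x {r} rows x {c} columns, {self.n_wells} wells)"
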