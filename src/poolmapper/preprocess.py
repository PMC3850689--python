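"""Read conversion, filtering and trimming for target-enriched pooled reads.

Each retained read is expected to start with a technical prefix
``barcode + primer + identifier`` laid down by the enrichment PCR: the
barcode identifies the pooled library, the primer sits on the element
terminus, and a short identifier sequence immediately downstream of the
primer excludes misprimed products. The prefix is trimmed off and the first
``index_length`` bases of the remainder — the target site duplication (TSD)
left by the element insertion — are sliced out as the read's index sequence,
the grouping key for all downstream coverage and deconvolution work.

Matching is substitution-only (Hamming): the barcode must match exactly,
the primer and identifier each tolerate a configurable number of
substitutions, and ``N`` never matches any base.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_VALID = set("ACGTN")

__all__ = [
    "FilterSpec",
    "RawRead",
    "FilteredRead",
    "FilterStats",
    "PrefixMatcher",
    "build_filter_pattern",
    "convert_fastq_to_fasta",
    "read_sequences",
    "filter_reads",
    "filter_library",
    "write_filtered_tsv",
    "read_filtered_tsv",
]


def _check_nucleotides(name: str, seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"{name} contains non-nucleotide characters {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class FilterSpec:
    """Filtering criteria for one element end in one (or all) libraries.

    Attributes
    ----------
    barcode:
        In-read library barcode, matched exactly at the read start. Empty
        when pools arrive pre-demultiplexed (one file per library).
    primer:
        Enrichment primer sequence expected right after the barcode.
    identifier:
        Short element-terminus sequence expected right after the primer;
        extends the match to exclude misprimed reads. May be empty.
    max_mismatches_primer, max_mismatches_identifier:
        Substitution allowances for the respective segments (no indels).
    index_length:
        Length of the TSD sliced as the index sequence (8 for Ds-family
        elements, whose insertions duplicate 8 bp of host sequence).
    known_endogenous:
        Index sequences of known endogenous elements; reads carrying them
        are dropped.
    end_label:
        Which element end this spec enriches: ``five_prime`` or
        ``three_prime``.
    """

    primer: str
    barcode: str = ""
    identifier: str = ""
    max_mismatches_primer: int = 0
    max_mismatches_identifier: int = 0
    index_length: int = 8
    known_endogenous: frozenset[str] = field(default_factory=frozenset)
    end_label: str = "three_prime"

    def __post_init__(self) -> None:
        object.__setattr__(self, "barcode", _check_nucleotides("barcode", self.barcode))
        object.__setattr__(self, "primer", _check_nucleotides("primer", self.primer))
        object.__setattr__(
            self, "identifier", _check_nucleotides("identifier", self.identifier)
        )
        object.__setattr__(
            self,
            "known_endogenous",
            frozenset(s.upper() for s in self.known_endogenous),
        )
        if self.end_label not in ("five_prime", "three_prime"):
            raise ValueError(f"end_label must be five_prime/three_prime, got {self.end_label!r}")
        if self.index_length < 1:
            raise ValueError("index_length must be >= 1")
        if self.max_mismatches_primer < 0 or self.max_mismatches_identifier < 0:
            raise ValueError("mismatch allowances must be non-negative")
        if not self.primer and self.max_mismatches_primer > 0:
            raise ValueError("empty primer cannot carry a mismatch allowance")
        if not self.identifier and self.max_mismatches_identifier > 0:
            raise ValueError("empty identifier cannot carry a mismatch allowance")
        if self.primer and self.max_mismatches_primer >= len(self.primer):
            raise ValueError("max_mismatches_primer must be < primer length")
        if self.identifier and self.max_mismatches_identifier >= len(self.identifier):
            raise ValueError("max_mismatches_identifier must be < identifier length")

    @property
    def prefix_length(self) -> int:
        """Total technical-prefix length trimmed from a matching read."""
        return len(self.barcode) + len(self.primer) + len(self.identifier)

    def with_endogenous(self, indices: Iterable[str]) -> "FilterSpec":
        """A copy with extra known-endogenous index sequences."""
        return replace(
            self, known_endogenous=self.known_endogenous | {s.upper() for s in indices}
        )


@dataclass(frozen=True)
class RawRead:
    read_id: str
    sequence: str
    quality: str | None = None


@dataclass(frozen=True)
class FilteredRead:
    """A retained read: TSD index, trimmed sequence, provenance."""

    index_seq: str
    trimmed_seq: str
    read_id: str
    library_id: str
    end_label: str


@dataclass
class FilterStats:
    total: int = 0
    matched: int = 0
    dropped_no_match: int = 0
    dropped_endogenous: int = 0
    dropped_short: int = 0
    retained: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "total": self.total,
            "matched": self.matched,
            "dropped_no_match": self.dropped_no_match,
            "dropped_endogenous": self.dropped_endogenous,
            "dropped_short": self.dropped_short,
            "retained": self.retained,
        }


def _mismatches_over(segment: str, target: str, allowance: int) -> bool:
    """True once substitutions exceed `allowance`. 'N' on either side is
    always a mismatch (conservative)."""
    mismatches = 0
    for a, b in zip(segment, target):
        if a != b or a == "N":
            mismatches += 1
            if mismatches > allowance:
                return True
    return False


class PrefixMatcher:
    """Predicate over read sequences for one :class:`FilterSpec`.

    A read matches iff it begins with the exact barcode, followed by the
    primer within its substitution allowance, followed by the identifier
    within its allowance. Reports the prefix length to trim on match.
    """

    def __init__(self, spec: FilterSpec) -> None:
        self.spec = spec
        self.prefix_length = spec.prefix_length

    def matches(self, sequence: str) -> bool:
        seq = sequence.upper()
        if len(seq) < self.prefix_length:
            return False
        s = self.spec
        pos = 0
        if s.barcode:
            segment = seq[: len(s.barcode)]
            if _mismatches_over(segment, s.barcode, 0):
                return False
            pos = len(s.barcode)
        if s.primer:
            segment = seq[pos : pos + len(s.primer)]
            if _mismatches_over(segment, s.primer, s.max_mismatches_primer):
                return False
            pos += len(s.primer)
        if s.identifier:
            segment = seq[pos : pos + len(s.identifier)]
            if _mismatches_over(segment, s.identifier, s.max_mismatches_identifier):
                return False
        return True

    def __call__(self, sequence: str) -> bool:
        return self.matches(sequence)


def build_filter_pattern(spec: FilterSpec) -> PrefixMatcher:
    """Build the match predicate for `spec` (see :class:`PrefixMatcher`)."""
    return PrefixMatcher(spec)


# ---------------------------------------------------------------------------
# File handling
# ---------------------------------------------------------------------------


def _open_text(path: str | Path | IO[str]) -> tuple[IO[str], bool]:
    if isinstance(path, (str, Path)):
        return open(path, "rt"), True
    return path, False


def sniff_format(path: str | Path) -> str:
    """Guess FASTQ vs FASTA from the first non-blank character."""
    with open(path, "rt") as fh:
        for line in fh:
            if line.strip():
                if line.startswith("@"):
                    return "fastq"
                if line.startswith(">"):
                    return "fasta"
                break
    raise ValueError(f"{path}: neither FASTQ nor FASTA (no '@'/'>' header found)")


def convert_fastq_to_fasta(
    in_path: str | Path | IO[str], out_path: str | Path | IO[str]
) -> int:
    """Transliterate FASTQ to FASTA, discarding qualities.

    Returns the number of records written. A malformed record raises
    ``ValueError`` naming the offending record number.
    """
    fh, close_in = _open_text(in_path)
    if isinstance(out_path, (str, Path)):
        out: IO[str] = open(out_path, "wt")
        close_out = True
    else:
        out, close_out = out_path, False
    n = 0
    try:
        for title, seq, _qual in FastqGeneralIterator(fh):
            out.write(f">{title}\n{seq}\n")
            n += 1
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ at record {n + 1}: {exc}") from exc
    finally:
        if close_in:
            fh.close()
        if close_out:
            out.close()
    return n


def read_sequences(path: str | Path, fmt: str | None = None) -> Iterator[RawRead]:
    """Stream reads from a FASTQ or FASTA file (format sniffed by default)."""
    fmt = fmt or sniff_format(path)
    with open(path, "rt") as fh:
        if fmt == "fastq":
            for title, seq, qual in FastqGeneralIterator(fh):
                yield RawRead(title.split()[0], seq, qual)
        elif fmt == "fasta":
            for title, seq in SimpleFastaParser(fh):
                yield RawRead(title.split()[0], seq)
        else:
            raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


def filter_reads(
    reads: Iterable[RawRead],
    spec: FilterSpec,
    library_id: str,
    stats: FilterStats | None = None,
) -> Iterator[FilteredRead]:
    """Stream-filter reads against `spec`, trimming the technical prefix and
    slicing the TSD index from each retained read.

    Bad reads are counted in `stats` (if given), never fatal. Order
    preserving and deterministic; constant memory.
    """
    matcher = PrefixMatcher(spec)
    trim = matcher.prefix_length
    k = spec.index_length
    for read in reads:
        if stats is not None:
            stats.total += 1
        seq = read.sequence.upper()
        if not matcher.matches(seq):
            if stats is not None:
                stats.dropped_no_match += 1
            continue
        if stats is not None:
            stats.matched += 1
        trimmed = seq[trim:]
        if len(trimmed) < k:
            if stats is not None:
                stats.dropped_short += 1
            continue
        index = trimmed[:k]
        if index in spec.known_endogenous:
            if stats is not None:
                stats.dropped_endogenous += 1
            continue
        if stats is not None:
            stats.retained += 1
        yield FilteredRead(index, trimmed, read.read_id, library_id, spec.end_label)


def write_filtered_tsv(records: Iterable[FilteredRead], out_path: str | Path) -> int:
    """Write retained reads as the tab-separated exchange format
    (columns: index_seq, trimmed_seq, read_id)."""
    n = 0
    with open(out_path, "wt") as out:
        for rec in records:
            out.write(f"{rec.index_seq}\t{rec.trimmed_seq}\t{rec.read_id}\n")
            n += 1
    return n


def read_filtered_tsv(
    path: str | Path, library_id: str, end_label: str = "three_prime"
) -> Iterator[FilteredRead]:
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            yield FilteredRead(parts[0], parts[1], parts[2], library_id, end_label)


def filter_library(
    in_path: str | Path,
    spec: FilterSpec,
    library_id: str,
    out_path: str | Path | None = None,
    fmt: str | None = None,
) -> tuple[FilterStats, list[FilteredRead] | None]:
    """Filter one library file end to end.

    With `out_path`, retained reads stream straight to the TSV file and the
    in-memory list is ``None``; without it they are collected and returned.
    """
    stats = FilterStats()
    stream = filter_reads(read_sequences(in_path, fmt), spec, library_id, stats)
    if out_path is not None:
        write_filtered_tsv(stream, out_path)
        return stats, None
    return stats, list(stream)
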