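"""Alignments and partition schemes.

The character matrix is a plain aligned FASTA; the partition scheme labels
column ranges as named regions, each belonging to the ``plastid`` or
``nuclear`` class.  Externally, partition files use the community
convention of 1-based inclusive column spans; internally everything is
0-based half-open.  ``'?'`` and ``'-'`` are both treated as missing by the
likelihood machinery, but ``'-'`` is preserved on write; a taxon lacking a
whole region is encoded as an all-``'?'`` span.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_CHARS = frozenset("ACGTURYSWKMBDHVN-?")
PLASTID = "plastid"
NUCLEAR = "nuclear"
CLASSES = (PLASTID, NUCLEAR)


class AlignmentError(ValueError):
    pass


class PartitionError(ValueError):
    pass


@dataclass
class Alignment:
    """Aligned character matrix keyed by unique specimen labels."""

    taxa: list[str]
    matrix: dict[str, str]
    n_columns: int

    @classmethod
    def from_records(cls, records: Sequence[tuple[str, str]]) -> "Alignment":
        taxa: list[str] = []
        matrix: dict[str, str] = {}
        n_columns = None
        for i, (label, seq) in enumerate(records, start=1):
            if not label:
                raise AlignmentError(f"record {i} has an empty label")
            if label in matrix:
                raise AlignmentError(f"duplicate label {label!r}")
            seq = seq.upper().replace("U", "T")
            if n_columns is None:
                n_columns = len(seq)
            elif len(seq) != n_columns:
                raise AlignmentError(
                    f"record {i} ({label!r}) has length {len(seq)}, "
                    f"expected {n_columns}"
                )
            bad = set(seq) - VALID_CHARS
            if bad:
                raise AlignmentError(
                    f"record {i} ({label!r}) has invalid characters {sorted(bad)}"
                )
            taxa.append(label)
            matrix[label] = seq
        if n_columns is None:
            raise AlignmentError("no records")
        return cls(taxa=taxa, matrix=matrix, n_columns=n_columns)

    def sequence(self, label: str) -> str:
        try:
            return self.matrix[label]
        except KeyError:
            raise KeyError(f"taxon {label!r} not in alignment") from None

    def subset_taxa(self, taxa: Iterable[str]) -> "Alignment":
        taxa = list(taxa)
        for t in taxa:
            if t not in self.matrix:
                raise KeyError(f"taxon {t!r} not in alignment")
        return Alignment(
            taxa=taxa,
            matrix={t: self.matrix[t] for t in taxa},
            n_columns=self.n_columns,
        )

    def take_columns(self, columns: np.ndarray) -> "Alignment":
        cols = np.asarray(columns, dtype=int)
        matrix = {}
        for t in self.taxa:
            arr = np.frombuffer(self.matrix[t].encode("ascii"), dtype="S1")
            matrix[t] = b"".join(arr[cols]).decode("ascii")
        return Alignment(taxa=list(self.taxa), matrix=matrix, n_columns=len(cols))

    def with_rows(self, extra: dict[str, str]) -> "Alignment":
        """New alignment with additional rows appended."""
        records = [(t, self.matrix[t]) for t in self.taxa]
        records += list(extra.items())
        return Alignment.from_records(records)


@dataclass(frozen=True)
class Region:
    name: str
    ranges: tuple[tuple[int, int], ...]  # 0-based half-open
    klass: str

    @property
    def n_columns(self) -> int:
        return sum(b - a for a, b in self.ranges)

    def columns(self) -> np.ndarray:
        return np.concatenate(
            [np.arange(a, b) for a, b in self.ranges]
        ) if self.ranges else np.empty(0, dtype=int)


@dataclass
class PartitionScheme:
    regions: list[Region]

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(names) != len(set(names)):
            raise PartitionError("duplicate region names")
        seen: set[int] = set()
        for r in self.regions:
            if r.klass not in CLASSES:
                raise PartitionError(
                    f"region {r.name!r}: class must be one of {CLASSES}"
                )
            for a, b in r.ranges:
                if not (0 <= a < b):
                    raise PartitionError(f"region {r.name!r}: bad interval {(a, b)}")
                cols = set(range(a, b))
                if cols & seen:
                    raise PartitionError(
                        f"region {r.name!r}: interval {(a, b)} overlaps another region"
                    )
                seen |= cols

    def validate_against(self, aln: Alignment) -> None:
        for r in self.regions:
            for a, b in r.ranges:
                if b > aln.n_columns:
                    raise PartitionError(
                        f"region {r.name!r}: interval {(a, b)} exceeds "
                        f"alignment width {aln.n_columns}"
                    )

    def class_regions(self, klass: str) -> list[Region]:
        if klass not in CLASSES:
            raise PartitionError(f"unknown class {klass!r}")
        return [r for r in self.regions if r.klass == klass]

    def columns(self, klass: str) -> np.ndarray:
        regions = self.class_regions(klass)
        if not regions:
            return np.empty(0, dtype=int)
        return np.concatenate([r.columns() for r in regions])

    def region(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(f"region {name!r} not in scheme")

    @property
    def n_columns(self) -> int:
        return sum(r.n_columns for r in self.regions)


# ---------------------------------------------------------------- file I/O


def read_alignment(path, format: str = "fasta") -> Alignment:
    if format != "fasta":
        raise ValueError(f"unsupported alignment format {format!r}")
    records = [
        (rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    return Alignment.from_records(records)


def write_alignment(aln: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(aln.matrix[t]), id=t, description="") for t in aln.taxa
    ]
    with open(path, "w", encoding="utf-8") as fh:
        SeqIO.write(records, fh, "fasta")


def read_partitions(path) -> PartitionScheme:
    """Parse a plain-text partition file.

    One region per line: ``name, class, start-end[, start-end ...]`` with
    1-based inclusive spans.  ``#`` starts a comment.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    return parse_partitions(text)


def parse_partitions(text: str) -> PartitionScheme:
    regions = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) < 3:
            raise PartitionError(
                f"line {lineno}: expected 'name, class, start-end[, ...]'"
            )
        name, klass = parts[0], parts[1].lower()
        ranges = []
        for span in parts[2:]:
            m = span.split("-")
            if len(m) != 2:
                raise PartitionError(f"line {lineno}: bad span {span!r}")
            try:
                start, end = int(m[0]), int(m[1])
            except ValueError:
                raise PartitionError(f"line {lineno}: bad span {span!r}") from None
            if start < 1 or end < start:
                raise PartitionError(
                    f"line {lineno}: span {span!r} must be 1-based inclusive"
                )
            ranges.append((start - 1, end))  # to 0-based half-open
        regions.append(Region(name=name, ranges=tuple(ranges), klass=klass))
    if not regions:
        raise PartitionError("no regions in partition file")
    return PartitionScheme(regions=regions)


def write_partitions(scheme: PartitionScheme, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# name, class, 1-based inclusive spans\n")
        for r in scheme.regions:
            spans = ", ".join(f"{a + 1}-{b}" for a, b in r.ranges)
            fh.write(f"{r.name}, {r.klass}, {spans}\n")


def subset(
    aln: Alignment,
    scheme: PartitionScheme,
    klass: str,
    taxa: Optional[Iterable[str]] = None,
) -> Alignment:
    """Restrict the alignment to one class's columns (and optionally taxa)."""
    scheme.validate_against(aln)
    cols = scheme.columns(klass)
    if not len(cols):
        raise PartitionError(f"no regions of class {klass!r} in scheme")
    out = aln if taxa is None else aln.subset_taxa(taxa)
    return out.take_columns(cols)


def taxa_with_data(aln: Alignment, columns: np.ndarray) -> list[str]:
    """Taxa having at least one non-missing character in the given columns."""
    out = []
    for t in aln.taxa:
        seq = aln.matrix[t]
        if any(seq[c] not in "-?N" for c in columns):
            out.append(t)
    return out
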