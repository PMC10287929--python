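"""Readers and writers for the interval, track and table formats the pipeline consumes.

Coordinate conventions
----------------------
BED and bedGraph are 0-based half-open.  RepeatMasker ``.out`` files are
1-based inclusive and are converted on read; the conversion happens here and
nowhere else.  Tables are TSV with a header row and ``.`` as the null token.
Gzip-compressed inputs are accepted transparently (by ``.gz`` suffix).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeSpec",
    "Interval",
    "SignalTrack",
    "BedParseError",
    "BedGraphDialectError",
    "SchemaError",
    "read_bed",
    "write_bed",
    "read_repeatmasker_out",
    "read_bedgraph",
    "write_bedgraph",
    "read_table",
    "write_table",
]

VALID_STRANDS = ("+", "-", ".")


class BedParseError(ValueError):
    """Malformed interval line; message carries the 1-based line number."""


class BedGraphDialectError(ValueError):
    """bedGraph input violates the non-overlapping-runs dialect."""


class SchemaError(ValueError):
    """A table is missing a mandatory column."""


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosome names and lengths (bp) of the working genome."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(set(self.chrom_names)):
            raise ValueError("chromosome names must be unique")
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise ValueError("names and lengths differ in count")
        if any(l < 1 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be >= 1")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    @property
    def size(self) -> int:
        return int(sum(self.chrom_lengths))

    def check_interval(self, iv: "Interval") -> None:
        try:
            length = self.lengths[iv.chrom]
        except KeyError:
            raise BedParseError(f"unknown chromosome {iv.chrom!r}") from None
        if not (0 <= iv.start < iv.end <= length):
            raise BedParseError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} outside chromosome bounds [0, {length})"
            )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeSpec":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "length": np.int64})
        if not {"chrom", "length"}.issubset(df.columns):
            raise SchemaError("genome TSV needs columns: chrom, length")
        return cls(tuple(df["chrom"]), tuple(int(x) for x in df["length"]))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"chrom": self.chrom_names, "length": self.chrom_lengths}).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True, order=True)
class Interval:
    """Genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


@dataclass
class SignalTrack:
    """Stepwise-constant coverage with bedGraph semantics.

    Per chromosome the track is three parallel arrays (starts, ends, values)
    of sorted, non-overlapping runs; base pairs not covered by a run have
    value 0.  Construction canonicalizes: zero-value runs are dropped and
    adjacent runs with equal value are merged, so equal tracks have equal
    run lists.
    """

    genome: GenomeSpec
    runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_runs(
        cls,
        genome: GenomeSpec,
        runs: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
    ) -> "SignalTrack":
        canon: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (s, e, v) in runs.items():
            s = np.asarray(s, dtype=np.int64)
            e = np.asarray(e, dtype=np.int64)
            v = np.asarray(v, dtype=np.float64)
            if chrom not in genome.lengths:
                raise BedParseError(f"unknown chromosome {chrom!r}")
            if s.size == 0:
                continue
            order = np.argsort(s, kind="stable")
            s, e, v = s[order], e[order], v[order]
            if np.any(e[:-1] > s[1:]):
                i = int(np.argmax(e[:-1] > s[1:]))
                raise BedGraphDialectError(
                    f"overlapping runs on {chrom} near {int(s[i + 1])}"
                )
            if np.any(v < 0) or not np.all(np.isfinite(v)):
                raise ValueError("track values must be finite and >= 0")
            if s[0] < 0 or e[-1] > genome.lengths[chrom]:
                raise BedParseError(f"run outside {chrom} bounds")
            keep = v != 0
            s, e, v = s[keep], e[keep], v[keep]
            if s.size == 0:
                continue
            # merge adjacent equal-value runs -> unique canonical form
            brk = np.flatnonzero((s[1:] != e[:-1]) | (v[1:] != v[:-1])) + 1
            starts = s[np.concatenate(([0], brk))]
            ends = e[np.concatenate((brk - 1, [s.size - 1]))]
            vals = v[np.concatenate(([0], brk))]
            canon[chrom] = (starts, ends, vals)
        return cls(genome, canon)

    def total_signal(self) -> float:
        """Sum over the genome of value x run length (bp·coverage mass)."""
        tot = 0.0
        for s, e, v in self.runs.values():
            tot += float(np.sum((e - s) * v))
        return tot

    def mean_coverage(self) -> float:
        return self.total_signal() / self.genome.size

    def scaled(self, factor: float) -> "SignalTrack":
        return SignalTrack.from_runs(
            self.genome,
            {c: (s.copy(), e.copy(), v * factor) for c, (s, e, v) in self.runs.items()},
        )

    def interval_sum(self, iv: Interval) -> float:
        """Sum of per-bp values over the interval (coverage mass)."""
        if iv.chrom not in self.runs:
            return 0.0
        s, e, v = self.runs[iv.chrom]
        lo = int(np.searchsorted(e, iv.start, side="right"))
        hi = int(np.searchsorted(s, iv.end, side="left"))
        if lo >= hi:
            return 0.0
        ov = np.minimum(e[lo:hi], iv.end) - np.maximum(s[lo:hi], iv.start)
        return float(np.sum(ov * v[lo:hi]))

    def values_array(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-bp expansion of [start, end) on one chromosome."""
        out = np.zeros(end - start, dtype=np.float64)
        if chrom not in self.runs:
            return out
        s, e, v = self.runs[chrom]
        lo = int(np.searchsorted(e, start, side="right"))
        hi = int(np.searchsorted(s, end, side="left"))
        for i in range(lo, hi):
            a = max(int(s[i]), start) - start
            b = min(int(e[i]), end) - start
            out[a:b] = v[i]
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        if self.genome != other.genome or set(self.runs) != set(other.runs):
            return False
        return all(
            np.array_equal(self.runs[c][0], other.runs[c][0])
            and np.array_equal(self.runs[c][1], other.runs[c][1])
            and np.array_equal(self.runs[c][2], other.runs[c][2])
            for c in self.runs
        )


# ---------------------------------------------------------------------------
# BED


def read_bed(
    path: str | Path, genome: GenomeSpec | None = None
) -> list[tuple[Interval, str | None, float | None]]:
    """Read a BED3/BED6 file.

    Returns one ``(interval, name, score)`` triple per data line, in file
    order.  ``name`` and ``score`` are None when the file is BED3; strand is
    ``"."`` when absent.  With a :class:`GenomeSpec`, every interval is
    bounds-checked.
    """
    out: list[tuple[Interval, str | None, float | None]] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"line {lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(f"line {lineno}: non-integer coordinates") from None
            if start >= end:
                raise BedParseError(f"line {lineno}: start >= end ({start} >= {end})")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 else "."
            try:
                iv = Interval(chrom, start, end, strand)
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from None
            if genome is not None:
                genome.check_interval(iv)
            out.append((iv, name, score))
    return out


def write_bed(
    records: Iterable[tuple[Interval, str | None, float | None]], path: str | Path
) -> None:
    with open(path, "wt") as fh:
        for iv, name, score in records:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name if name is not None else '.'}\t"
                f"{score if score is not None else '.'}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# RepeatMasker .out


def read_repeatmasker_out(path: str | Path, genome: GenomeSpec | None = None):
    """Parse a RepeatMasker ``.out`` annotation into TE instances.

    The standard layout has 3 header lines and whitespace-separated fields;
    coordinates are 1-based inclusive (converted to 0-based half-open) and
    strand ``C`` means the reverse strand.  The repeat name column becomes
    the family label and repClass/repFamily is mapped onto the closed class
    vocabulary {ERV1, ERVK, ERVL, LINE, SINE, other}.
    """
    from .te_annotation import TEInstance, normalize_te_class

    out: list[TEInstance] = []
    with _open_text(path) as fh:
        lines = fh.readlines()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if lineno <= 3 and (line.startswith(("SW", "score")) or not line[0].isdigit()):
            continue  # header block
        fields = line.split()
        if len(fields) < 11:
            raise BedParseError(f"line {lineno}: truncated RepeatMasker record")
        chrom = fields[4]
        try:
            begin, end = int(fields[5]), int(fields[6])
        except ValueError:
            raise BedParseError(f"line {lineno}: non-integer coordinates") from None
        if end < begin:
            raise BedParseError(f"line {lineno}: end < begin")
        strand = "-" if fields[8] in ("C", "-") else "+"
        family = fields[9]
        te_class = normalize_te_class(fields[10])
        iv = Interval(chrom, begin - 1, end, strand)
        if genome is not None:
            genome.check_interval(iv)
        out.append(
            TEInstance(
                interval=iv,
                family=family,
                te_class=te_class,
                instance_id=f"{family}|{chrom}:{begin - 1}-{end}",
            )
        )
    return out


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path: str | Path, genome: GenomeSpec) -> SignalTrack:
    """Read a 4-column bedGraph into a canonical :class:`SignalTrack`.

    Runs may appear in any order in the file but must not overlap (the value
    of an overlapped base would be ambiguous); uncovered bases are 0.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise BedParseError(f"line {lineno}: expected 4 bedGraph columns")
            chrom = fields[0]
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError:
                raise BedParseError(f"line {lineno}: malformed bedGraph fields") from None
            if start >= end:
                raise BedParseError(f"line {lineno}: start >= end")
            if value < 0:
                raise ValueError(f"line {lineno}: negative bedGraph value {value}")
            per_chrom.setdefault(chrom, []).append((start, end, value))
    runs = {
        chrom: (
            np.array([r[0] for r in rs], dtype=np.int64),
            np.array([r[1] for r in rs], dtype=np.int64),
            np.array([r[2] for r in rs], dtype=np.float64),
        )
        for chrom, rs in per_chrom.items()
    }
    return SignalTrack.from_runs(genome, runs)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "wt") as fh:
        for chrom in track.genome.chrom_names:
            if chrom not in track.runs:
                continue
            s, e, v = track.runs[chrom]
            for i in range(s.size):
                fh.write(f"{chrom}\t{int(s[i])}\t{int(e[i])}\t{v[i]:.17g}\n")


# ---------------------------------------------------------------------------
# TSV tables

#: mandatory columns per record kind, used by read_table for schema checks
TABLE_SCHEMAS: dict[str, Sequence[str]] = {
    "de": ("feature_id", "feature_type", "log2fc", "pvalue", "padj", "significant"),
    "enrichment": ("element_id", "mark", "log2_fe"),
    "nfr": ("anchor_id", "central_count", "rank", "depleted"),
    "cells": ("cell_id", "n_genes_detected", "pct_mito", "condition"),
}


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a records table as TSV; floats at 17 significant digits so the
    write/read round trip is bit-exact; None/NaN rendered as ``.``."""
    df.to_csv(path, sep="\t", index=False, na_rep=".", float_format="%.17g")


def read_table(path: str | Path, schema: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", na_values=["."], keep_default_na=True,
        float_precision="round_trip",
    )
    if schema is not None:
        required = TABLE_SCHEMAS[schema]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"table {path} missing mandatory column(s): {missing}")
    return df
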