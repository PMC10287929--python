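"""Curation and stitching of transposable-element annotations.

TE instances (RepeatMasker copies) are curated with an instance-length
filter followed by a family copy-number filter, matching the common
practice of discarding elements <300 bp and families with <50 genomic
copies before enrichment scoring.  Fragmented internal elements (e.g.
IAPEz-int copies interrupted by LTR insertions) can be stitched into
full-length elements by merging same-family, same-strand fragments whose
gaps do not exceed ``max_gap``.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import Interval

logger = logging.getLogger(__name__)

__all__ = [
    "TEInstance",
    "StitchedElement",
    "TEFamilySummary",
    "normalize_te_class",
    "curate_te_instances",
    "stitch_fragments",
    "select_full_length",
    "summarize_families",
]

TE_CLASSES = ("ERV1", "ERVK", "ERVL", "LINE", "SINE", "other")

DEFAULT_MIN_LENGTH = 300
DEFAULT_MIN_COPIES = 50
DEFAULT_MAX_GAP = 500


def normalize_te_class(raw: str) -> str:
    """Map a RepeatMasker repClass/repFamily string onto the closed class
    vocabulary.  ``LTR/ERVK`` -> ERVK, ``LINE/L1`` -> LINE, anything not
    recognized -> ``other``."""
    token = raw.split("/")[-1].split("?")[0]
    upper = token.upper()
    for cls in ("ERVK", "ERVL", "ERV1"):
        if upper.startswith(cls) or upper.replace("-MALR", "").startswith(cls):
            return cls
    head = raw.split("/")[0].upper()
    if head == "LINE" or upper in ("L1", "L2", "CR1", "RTE"):
        return "LINE"
    if head == "SINE" or upper in ("ALU", "B2", "B4", "MIR", "ID"):
        return "SINE"
    if upper == "ERV1":
        return "ERV1"
    return "other"


@dataclass(frozen=True)
class TEInstance:
    """One genomic copy of a repeat family."""

    interval: Interval
    family: str
    te_class: str
    instance_id: str

    def __post_init__(self) -> None:
        if self.te_class not in TE_CLASSES:
            raise ValueError(f"te_class {self.te_class!r} not in {TE_CLASSES}")

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class StitchedElement:
    """A run of same-family fragments merged into one element span."""

    interval: Interval
    family: str
    member_ids: tuple[str, ...]

    @property
    def n_fragments(self) -> int:
        return len(self.member_ids)

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class TEFamilySummary:
    family: str
    te_class: str
    copy_number: int
    median_length: float


def curate_te_instances(
    instances: list[TEInstance],
    min_length: int = DEFAULT_MIN_LENGTH,
    min_copies: int = DEFAULT_MIN_COPIES,
) -> list[TEInstance]:
    """Two-pass curation: drop instances shorter than ``min_length``, then
    drop whole families whose copy number *after* the length filter is below
    ``min_copies``.  Input order is preserved; empty input yields empty
    output."""
    if min_length < 1 or min_copies < 1:
        raise ValueError("min_length and min_copies must be >= 1")
    long_enough = [t for t in instances if t.length >= min_length]
    copies = Counter(t.family for t in long_enough)
    return [t for t in long_enough if copies[t.family] >= min_copies]


def stitch_fragments(
    instances: list[TEInstance], family: str, max_gap: int = DEFAULT_MAX_GAP
) -> list[StitchedElement]:
    """Merge adjacent fragments of one family into stitched elements.

    Fragments on the same chromosome and strand whose successive gaps are
    <= ``max_gap`` bp form one element; a fragment with no neighbour within
    range becomes a singleton element.  Output is sorted by coordinate.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    members = [t for t in instances if t.family == family]
    by_group: dict[tuple[str, str], list[TEInstance]] = defaultdict(list)
    for t in members:
        by_group[(t.interval.chrom, t.interval.strand)].append(t)
    out: list[StitchedElement] = []
    for (chrom, strand), frags in by_group.items():
        frags.sort(key=lambda t: (t.interval.start, t.interval.end))
        run: list[TEInstance] = [frags[0]]
        run_end = frags[0].interval.end
        for t in frags[1:]:
            if t.interval.start - run_end <= max_gap:
                run.append(t)
                run_end = max(run_end, t.interval.end)
            else:
                out.append(_make_element(chrom, strand, family, run))
                run = [t]
                run_end = t.interval.end
        out.append(_make_element(chrom, strand, family, run))
    out.sort(key=lambda e: (e.interval.chrom, e.interval.start, e.interval.end))
    return out


def _make_element(
    chrom: str, strand: str, family: str, run: list[TEInstance]
) -> StitchedElement:
    start = min(t.interval.start for t in run)
    end = max(t.interval.end for t in run)
    return StitchedElement(
        interval=Interval(chrom, start, end, strand),
        family=family,
        member_ids=tuple(t.instance_id for t in run),
    )


def select_full_length(
    instances: list[TEInstance], family: str, min_length: int
) -> list[TEInstance]:
    """Instances of ``family`` with length >= ``min_length`` (the
    full-length subset used for per-element correlation)."""
    if min_length <= 0:
        raise ValueError("min_length must be > 0")
    of_family = [t for t in instances if t.family == family]
    if not of_family:
        logger.warning("select_full_length: no instances of family %r", family)
        return []
    return [t for t in of_family if t.length >= min_length]


def summarize_families(instances: list[TEInstance]) -> pd.DataFrame:
    """One row per family with its class, copy number and median length."""
    if not instances:
        return pd.DataFrame(columns=["family", "te_class", "copy_number", "median_length"])
    rows = pd.DataFrame(
        {
            "family": [t.family for t in instances],
            "te_class": [t.te_class for t in instances],
            "length": [t.length for t in instances],
        }
    )
    grouped = (
        rows.groupby("family", sort=True)
        .agg(
            te_class=("te_class", "first"),
            copy_number=("length", "size"),
            median_length=("length", lambda x: float(np.median(x))),
        )
        .reset_index()
    )
    return grouped
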