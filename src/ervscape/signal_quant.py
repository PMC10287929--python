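"""Track normalization, per-element enrichment over input, and peak curation.

Coverage tracks are scaled to 1x genome coverage (RPGC-style: mean per-bp
coverage over the genome equals 1).  Per-element enrichment is the log2
ratio of mean observed coverage to mean input coverage over the element,
with a pseudocount guarding uncovered elements.  Factor-vs-mark agreement
across elements is a two-sided Pearson correlation test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import Interval, SignalTrack

__all__ = [
    "Peak",
    "EnrichmentRecord",
    "CorrelationResult",
    "NormalizationError",
    "normalize_1x",
    "element_mean_signal",
    "log2_enrichment",
    "enrichment_table",
    "curate_peaks",
    "per_element_correlation",
]

DEFAULT_PSEUDOCOUNT = 0.1
DEFAULT_MIN_FE = 2.0


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class Peak:
    """Factor-binding interval with its caller's fold enrichment."""

    interval: Interval
    fold_enrichment: float
    peak_id: str
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.fold_enrichment) or self.fold_enrichment < 0:
            raise ValueError("fold_enrichment must be finite and >= 0")

    @property
    def center(self) -> int:
        """Floor midpoint (anchor for occupancy profiles)."""
        return (self.interval.start + self.interval.end) // 2


@dataclass(frozen=True)
class EnrichmentRecord:
    element_id: str
    mark: str
    log2_fe: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_two_sided: float
    n: int


def normalize_1x(track: SignalTrack) -> SignalTrack:
    """Scale so mean per-bp coverage over the whole genome is exactly 1."""
    total = track.total_signal()
    if total <= 0:
        raise NormalizationError("cannot 1x-normalize an all-zero track")
    return track.scaled(track.genome.size / total)


def element_mean_signal(track: SignalTrack, interval: Interval) -> float:
    """Per-bp mean coverage of the track over the interval."""
    return track.interval_sum(interval) / interval.length


def log2_enrichment(
    observed: SignalTrack,
    input_track: SignalTrack,
    element_id: str,
    interval: Interval,
    mark: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> EnrichmentRecord:
    """log2((mean observed + pc) / (mean input + pc)) over one element."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    mean_obs = element_mean_signal(observed, interval)
    mean_inp = element_mean_signal(input_track, interval)
    log2_fe = float(np.log2((mean_obs + pseudocount) / (mean_inp + pseudocount)))
    return EnrichmentRecord(element_id=element_id, mark=mark, log2_fe=log2_fe)


def enrichment_table(
    observed: SignalTrack,
    input_track: SignalTrack,
    elements: list[tuple[str, Interval]],
    mark: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-element enrichment for a list of ``(element_id, interval)``."""
    recs = [
        log2_enrichment(observed, input_track, eid, iv, mark, pseudocount)
        for eid, iv in elements
    ]
    return pd.DataFrame(
        {
            "element_id": [r.element_id for r in recs],
            "mark": [r.mark for r in recs],
            "log2_fe": [r.log2_fe for r in recs],
        }
    )


def curate_peaks(peaks: list[Peak], min_fe: float = DEFAULT_MIN_FE) -> list[Peak]:
    """Retain peaks with fold enrichment strictly above ``min_fe``."""
    return [p for p in peaks if p.fold_enrichment > min_fe]


def per_element_correlation(
    records_a: pd.DataFrame, records_b: pd.DataFrame
) -> CorrelationResult:
    """Pearson correlation of two enrichment tables joined on element_id.

    p comes from the t-distribution with n-2 degrees of freedom, two-sided.
    Raises on fewer than 3 shared elements or on zero variance.
    """
    merged = records_a.merge(records_b, on="element_id", suffixes=("_a", "_b"))
    x = merged["log2_fe_a"].to_numpy(dtype=float)
    y = merged["log2_fe_b"].to_numpy(dtype=float)
    n = x.size
    if n < 3:
        raise ValueError(f"need >= 3 paired elements, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation: zero variance in one vector")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_two_sided=float(res.pvalue), n=n)
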