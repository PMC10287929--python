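"""Single-cell QC filters and totipotent-like fraction statistics.

QC rules follow the assay: Smart-seq2 cells are kept with >500 expressed
genes and a between-cell Pearson correlation >0.60 (both strict); droplet
cells are removed with <200 expressed genes or >10% mitochondrial reads
(boundary values retained).  A marker-score classifier (2C markers such
as Zscan4/Usp17l vs pluripotency markers such as Pou5f1/Nanog) stands in
for graph clustering; externally produced cluster labels are accepted
the same way.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FractionResult",
    "qc_filter_smartseq",
    "qc_filter_droplet",
    "marker_score_classify",
    "cluster_fraction",
    "fraction_fold_change",
]

TOTIPOTENT_LABEL = "totipotent-like"


@dataclass(frozen=True)
class FractionResult:
    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if not (0 <= self.numerator <= self.denominator) or self.denominator <= 0:
            raise ValueError("need 0 <= numerator <= denominator, denominator > 0")

    @property
    def percentage(self) -> float:
        return 100.0 * self.numerator / self.denominator

    @property
    def percentage_rounded(self) -> float:
        return round(self.percentage, 2)


def qc_filter_smartseq(
    cells: pd.DataFrame, min_genes: int = 500, min_corr: float = 0.60
) -> pd.DataFrame:
    """Retain cells with n_genes_detected > min_genes and pairwise_corr >
    min_corr, both strict.  ``pairwise_corr`` is each cell's maximum Pearson
    correlation to any other cell (configurable upstream to the mean)."""
    keep = (cells["n_genes_detected"] > min_genes) & (cells["pairwise_corr"] > min_corr)
    return cells[keep].reset_index(drop=True)


def qc_filter_droplet(
    cells: pd.DataFrame, min_genes: int = 200, max_mito: float = 0.10
) -> pd.DataFrame:
    """Remove cells with n_genes_detected < min_genes OR pct_mito > max_mito;
    cells sitting exactly on either boundary are retained."""
    remove = (cells["n_genes_detected"] < min_genes) | (cells["pct_mito"] > max_mito)
    return cells[~remove].reset_index(drop=True)


def marker_score_classify(
    expression: pd.DataFrame,
    markers_2c: list[str],
    markers_pluri: list[str],
    margin: float = 0.0,
) -> pd.Series:
    """Label each cell by its 2C-vs-pluripotency marker score.

    score = mean log1p expression over 2C markers minus the same over
    pluripotency markers; a cell is "totipotent-like" iff score > margin
    (strict), otherwise "pluripotent-like".  ``expression`` is cells x genes.
    """
    missing = [m for m in markers_2c + markers_pluri if m not in expression.columns]
    if missing:
        raise KeyError(f"marker gene(s) absent from expression matrix: {missing}")
    log = np.log1p(expression[markers_2c + markers_pluri])
    score = log[markers_2c].mean(axis=1) - log[markers_pluri].mean(axis=1)
    labels = np.where(score > margin, TOTIPOTENT_LABEL, "pluripotent-like")
    return pd.Series(labels, index=expression.index, name="cluster_label")


def cluster_fraction(cells: pd.DataFrame, label: str, condition: str) -> FractionResult:
    """Fraction of cells of one condition carrying a cluster label."""
    of_condition = cells[cells["condition"] == condition]
    if of_condition.empty:
        raise ValueError(f"no cells with condition {condition!r}")
    num = int((of_condition["cluster_label"] == label).sum())
    return FractionResult(numerator=num, denominator=len(of_condition))


def fraction_fold_change(
    f_depleted: FractionResult, f_control: FractionResult
) -> tuple[float, int]:
    """Ratio of two percentages (unrounded) plus a rounded-to-integer
    convenience value."""
    if f_control.percentage <= 0:
        raise ValueError("control fraction must be > 0")
    ratio = f_depleted.percentage / f_control.percentage
    return ratio, round(ratio)
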