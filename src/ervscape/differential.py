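"""Differential calling for genes, TE families and binding sites.

The external DE engine is not re-implemented; a lightweight
negative-binomial Wald test keeps the pipeline self-contained, and every
downstream step equally accepts an externally produced table
(feature_id, log2fc, pvalue, padj).  The thresholds are the study's:
genes significant at BH padj < 0.01 and |FC| > 2, TE families at padj <
0.01 and |FC| > 1.5, differential binding sites at raw p < 0.05 and
|FC| > 1.5.

The stand-in test: library sizes by median-of-ratios, per-feature
fold change of size-factor-normalized means with a 0.5 pseudocount,
method-of-moments dispersion pooled across conditions and then shared
across features (the experiment-wide mean of the per-feature estimates),
and a Wald statistic on the log difference with a delta-method standard
error (two-sided normal p).  Sharing dispersion across features is what
keeps the test calibrated at 2-3 replicates: a per-feature plug-in
dispersion at that depth is so noisy that the Wald statistic becomes
strongly anti-conservative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "size_factors",
    "nb_de_test",
    "bh_adjust",
    "call_de",
    "call_differential_peaks",
    "select_strong_early2c",
]

FC_PSEUDOCOUNT = 0.5
DISPERSION_FLOOR = 1e-8
P_FLOOR = 1e-300

#: fold-change significance thresholds on the linear scale, per feature type
FC_THRESHOLDS = {"gene": 2.0, "te_family": 1.5, "peak": 1.5}
DEFAULT_MAX_PADJ = 0.01


class CountMatrix:
    """Integer counts, features x samples, with condition and replicate labels.

    ``conditions`` maps each sample id to "control" or "depleted".
    """

    def __init__(self, counts: pd.DataFrame, conditions: dict[str, str]):
        if counts.index.duplicated().any():
            raise ValueError("feature ids must be unique")
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        unknown = set(counts.columns) - set(conditions)
        if unknown:
            raise ValueError(f"samples without condition label: {sorted(unknown)}")
        self.counts = counts
        self.conditions = dict(conditions)

    def samples(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]

    def to_tsv(self, path) -> None:
        df = self.counts.copy()
        df.columns = [
            f"{s}:{self.conditions[s]}:{i}" for i, s in enumerate(self.counts.columns)
        ]
        df.index.name = "feature_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        conditions = {}
        names = []
        for col in df.columns:
            sample, condition, _rep = col.split(":")
            conditions[sample] = condition
            names.append(sample)
        df.columns = names
        return cls(df, conditions)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors.

    Ratios are taken against the geometric mean over samples, using features
    with all-positive counts; if none exist, total-count ratios are used.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if positive.any():
        logmat = np.log(mat[positive])
        logref = logmat.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logmat - logref, axis=0))
    else:
        totals = mat.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(np.maximum(totals, 1.0))))
    return pd.Series(sf, index=counts.columns)


def nb_de_test(cm: CountMatrix, feature_type: str = "gene") -> pd.DataFrame:
    """Per-feature negative-binomial Wald test, depleted versus control.

    Returns a table with feature_id, feature_type, log2fc, pvalue.
    Features with all-zero counts are skipped.  With a single replicate in
    either condition the fold change is still reported but pvalue is NaN.
    """
    ctrl = cm.samples("control")
    dep = cm.samples("depleted")
    if not ctrl or not dep:
        raise ValueError("need samples in both conditions")
    sf = size_factors(cm.counts)
    norm = cm.counts / sf

    nz = cm.counts.sum(axis=1) > 0
    norm = norm.loc[nz]

    a = norm[ctrl].to_numpy(dtype=float)
    b = norm[dep].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    m1, m2 = a.mean(axis=1), b.mean(axis=1)
    log2fc = np.log2((m2 + FC_PSEUDOCOUNT) / (m1 + FC_PSEUDOCOUNT))

    if n1 < 2 or n2 < 2:
        pvalue = np.full(m1.size, np.nan)
    else:
        # method-of-moments dispersion per condition, pooled by residual df,
        # then shared across features (mean of per-feature estimates)
        v1, v2 = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a1 = np.where(m1 > 0, (v1 - m1) / np.square(m1), 0.0)
            a2 = np.where(m2 > 0, (v2 - m2) / np.square(m2), 0.0)
        alpha_feature = ((n1 - 1) * a1 + (n2 - 1) * a2) / (n1 + n2 - 2)
        alpha = max(float(np.mean(alpha_feature)), DISPERSION_FLOOR)
        # delta-method variance of log(mean + pc) under NB var = mu + alpha mu^2
        var1 = (m1 + alpha * np.square(m1)) / (n1 * np.square(m1 + FC_PSEUDOCOUNT))
        var2 = (m2 + alpha * np.square(m2)) / (n2 * np.square(m2 + FC_PSEUDOCOUNT))
        se = np.sqrt(var1 + var2)
        z = np.where(se > 0, (np.log(m2 + FC_PSEUDOCOUNT) - np.log(m1 + FC_PSEUDOCOUNT)) / np.where(se > 0, se, 1.0), 0.0)
        pvalue = np.maximum(2.0 * stats.norm.sf(np.abs(z)), P_FLOOR)

    return pd.DataFrame(
        {
            "feature_id": norm.index.to_numpy(),
            "feature_type": feature_type,
            "log2fc": log2fc,
            "pvalue": pvalue,
        }
    )


def joint_de_test(
    gene_counts: pd.DataFrame,
    te_counts: pd.DataFrame,
    conditions: dict[str, str],
    max_padj: float = DEFAULT_MAX_PADJ,
) -> pd.DataFrame:
    """Test genes and TE families in one run, the way TE-aware counting
    pipelines feed a single combined matrix to the DE engine: size factors
    and the BH correction are shared, and the per-type fold-change
    thresholds are applied afterwards."""
    combined = CountMatrix(pd.concat([gene_counts, te_counts]), conditions)
    table = nb_de_test(combined)
    table["feature_type"] = np.where(
        table["feature_id"].isin(te_counts.index), "te_family", "gene"
    )
    return call_de(table, max_padj=max_padj)


def bh_adjust(pvalues: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    table: pd.DataFrame,
    feature_type: str | None = None,
    max_padj: float = DEFAULT_MAX_PADJ,
) -> pd.DataFrame:
    """Flag significant features: padj < 0.01 and |FC| strictly above the
    type's threshold (2 for genes, 1.5 for TE families).  Adds padj when the
    table has only raw p."""
    out = table.copy()
    if feature_type is not None:
        out["feature_type"] = feature_type
    if "padj" not in out.columns:
        out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    thr = out["feature_type"].map(FC_THRESHOLDS)
    if thr.isna().any():
        bad = sorted(out.loc[thr.isna(), "feature_type"].unique())
        raise ValueError(f"unknown feature_type(s): {bad}")
    out["significant"] = (out["padj"] < max_padj) & (
        np.abs(out["log2fc"]) > np.log2(thr.to_numpy(dtype=float))
    )
    return out


def call_differential_peaks(
    cm: CountMatrix, max_p: float = 0.05, min_fc: float = 1.5
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gained/lost binding sites from per-peak counts.

    Calls use raw p < 0.05 and linear |FC| > 1.5 (gained: FC > 1.5;
    lost: FC < 1/1.5), the confidence thresholds of differential-binding
    pipelines.  Returns (gained, lost) tables.
    """
    table = nb_de_test(cm, feature_type="peak")
    log_thr = np.log2(min_fc)
    ok = table["pvalue"] < max_p
    gained = table[ok & (table["log2fc"] > log_thr)].reset_index(drop=True)
    lost = table[ok & (table["log2fc"] < -log_thr)].reset_index(drop=True)
    return gained, lost


def select_strong_early2c(
    table: pd.DataFrame, min_log2fc: float = 5.0, max_fdr: float = 0.01
) -> pd.DataFrame:
    """Strongly up-regulated features: log2FC strictly > 5 at FDR < 0.01."""
    out = table.copy()
    if "padj" not in out.columns:
        out["padj"] = bh_adjust(out["pvalue"].to_numpy())
    return out[(out["log2fc"] > min_log2fc) & (out["padj"] < max_fdr)].reset_index(
        drop=True
    )
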