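"""Genotype/stage comparisons: fold changes, differential-expression
flagging and significance ranking.

Differential-expression testing itself is intentionally lightweight: the
adjusted p values used for flagging and ranking come from a plain Welch
(unequal-variance) two-sample t test on log2-transformed replicate TPMs with
Benjamini-Hochberg adjustment. This is a declared stand-in that exercises
the flagging/ranking logic; it is not a negative-binomial DE model.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import SampleQuant

_METRICS = ("total_tpm", "proximal_tpm", "distal_tpm", "proximal_rpm", "distal_rpm", "log2_ratio")


def fold_change(mean_a: float, mean_b: float) -> float:
    """Simple ratio of group means, B over A. NaN when the reference mean is
    zero (flagged downstream as missing)."""
    if mean_a == 0:
        return math.nan
    return mean_b / mean_a


def flag_de(
    fc: float,
    adjusted_p: float | None,
    fc_threshold: float = 2.0,
    p_threshold: float = 1e-3,
) -> str:
    """'up' / 'down' / 'none' by the strictly-more-than-twofold rule.

    up: fc > fc_threshold and p < p_threshold; down: fc < 1/fc_threshold and
    p < p_threshold; 'none' otherwise or when p is missing.
    """
    if adjusted_p is None or (isinstance(adjusted_p, float) and math.isnan(adjusted_p)):
        return "none"
    if not 0.0 <= adjusted_p <= 1.0:
        raise ValueError("adjusted_p must lie in [0, 1]")
    if math.isnan(fc):
        return "none"
    if fc > fc_threshold and adjusted_p < p_threshold:
        return "up"
    if fc < 1.0 / fc_threshold and adjusted_p < p_threshold:
        return "down"
    return "none"


def rank_by_significance(table: pd.DataFrame) -> pd.DataFrame:
    """Order genes by ascending adjusted p, ties by descending |log2 fold
    change|, then lexically by gene id. Missing p values rank last (as 1)."""
    if table.empty:
        raise ValueError("cannot rank an empty table")
    df = table.copy()
    df["_p"] = df["padj"].fillna(1.0)
    df["_a"] = -df["log2_fc"].fillna(0.0).abs()
    out = df.sort_values(["_p", "_a", "gene_id"], kind="stable").drop(columns=["_p", "_a"])
    return out.reset_index(drop=True)


def _metric_values(q: SampleQuant) -> pd.DataFrame:
    """Per-gene metric values for one sample, in the comparison layout."""
    apa = q.gene_apa.set_index("gene_id")
    rows = []
    for gid in q.gene_table.gene_id:
        gtpm = float(q.gene_table.set_index("gene_id").tpm[gid])
        rows.append(
            {
                "gene_id": gid,
                "total_tpm": gtpm,
                "proximal_tpm": float(apa.proximal_tpm[gid]),
                "distal_tpm": float(apa.distal_tpm[gid]),
                "proximal_rpm": float(apa.proximal_rpm[gid]),
                "distal_rpm": float(apa.distal_rpm[gid]),
                "log2_ratio": float(apa.log2_ratio[gid]),
            }
        )
    return pd.DataFrame(rows)


def compare_groups(
    quants_a: Sequence[SampleQuant],
    quants_b: Sequence[SampleQuant],
    fc_threshold: float = 2.0,
    p_threshold: float = 1e-3,
) -> pd.DataFrame:
    """Compare two replicate groups (B relative to A) per gene and metric.

    Returns one row per (gene, metric) with group means, fold change,
    log2 fold change, an adjusted p value (total_tpm metric only, Welch t on
    log2 TPM + BH across genes, requires >= 2 replicates per group) and the
    DE flag for total_tpm rows.
    """
    va = [_metric_values(q) for q in quants_a]
    vb = [_metric_values(q) for q in quants_b]
    genes = sorted(set().union(*[set(v.gene_id) for v in va + vb]))

    def stack(vs, metric):
        return {
            g: np.array(
                [float(v.set_index("gene_id")[metric].get(g, math.nan)) for v in vs]
            )
            for g in genes
        }

    # Stand-in significance on log TPM replicates.
    padj: dict[str, float] = {g: math.nan for g in genes}
    if len(va) >= 2 and len(vb) >= 2:
        ta, tb = stack(va, "total_tpm"), stack(vb, "total_tpm")
        pvals = []
        for g in genes:
            a, b = np.log2(ta[g] + 0.5), np.log2(tb[g] + 0.5)
            with np.errstate(invalid="ignore", divide="ignore"):
                p = stats.ttest_ind(a, b, equal_var=False).pvalue
            pvals.append(1.0 if math.isnan(p) else float(p))
        adj = multipletests(pvals, method="fdr_bh")[1]
        padj = dict(zip(genes, adj))

    rows = []
    for metric in _METRICS:
        sa, sb = stack(va, metric), stack(vb, metric)
        for g in genes:
            mean_a = float(np.nanmean(sa[g])) if not np.all(np.isnan(sa[g])) else math.nan
            mean_b = float(np.nanmean(sb[g])) if not np.all(np.isnan(sb[g])) else math.nan
            fc = fold_change(mean_a, mean_b) if not math.isnan(mean_a) else math.nan
            p = padj[g] if metric == "total_tpm" else math.nan
            rows.append(
                {
                    "gene_id": g,
                    "metric": metric,
                    "mean_a": mean_a,
                    "mean_b": mean_b,
                    "fold_change": fc,
                    "log2_fc": math.log2(fc) if fc and fc > 0 else math.nan,
                    "padj": p,
                    "flag": flag_de(fc, p, fc_threshold, p_threshold)
                    if metric == "total_tpm"
                    else "none",
                    "reference_mean_zero": mean_a == 0,
                }
            )
    return pd.DataFrame(rows)
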