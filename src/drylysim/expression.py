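"""Microarray differential-expression filtering and family profiling.

The pipeline enters at a gene-level intensity matrix (probe summarization is
upstream).  Processing follows the standard two-color-free array workflow:
quantile normalization across samples, replicate-correlation QC, per-contrast
Welch t-tests on log2 intensities with Benjamini-Hochberg FDR control, DEG
calling at fold change >= 2 (|log2 FC| >= 1) and FDR <= 0.01, Venn-style
bookkeeping of shared/unique DEGs between two genotypes, and per-family
(e.g. aquaporin) drought-response profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the common distribution of row-mean
    order statistics.

    After normalization each column's sorted values are identical: the mean
    across samples of the per-rank sorted values.  Ties within a column
    receive the average of the values their ranks span.
    """
    x = matrix.to_numpy(dtype=float)
    if np.isnan(x).all(axis=0).any():
        raise ValueError("a sample column is entirely missing")
    if (x < 0).any():
        raise ValueError("intensities must be nonnegative")
    n, m = x.shape
    sorted_means = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(m):
        ranks = stats.rankdata(x[:, j], method="average")  # 1-based, .5 on ties
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = (sorted_means[lo] + sorted_means[hi]) / 2.0
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def replicate_qc(
    matrix: pd.DataFrame,
    annotations: pd.DataFrame,
    log2: bool = True,
    flag_below: float = 0.9,
) -> pd.DataFrame:
    """Pearson correlation for every within-condition replicate pair.

    Conditions are (genotype, tissue, treatment) cells; each must hold at
    least two replicates.  Correlations are computed on log2 intensities by
    default.  Pairs below ``flag_below`` are flagged for inspection.
    """
    x = matrix
    if log2:
        x = np.log2(matrix + 1.0)
    rows = []
    for (geno, tissue, trt), grp in annotations.groupby(
        ["genotype", "tissue", "treatment"], sort=True
    ):
        samples = list(grp["sample"])
        if len(samples) < 2:
            raise ValueError(f"condition {(geno, tissue, trt)} has < 2 replicates")
        for a, b in combinations(samples, 2):
            r = float(np.corrcoef(x[a], x[b])[0, 1])
            rows.append(
                {
                    "genotype": geno, "tissue": tissue, "treatment": trt,
                    "sample_a": a, "sample_b": b, "r": r, "flagged": r < flag_below,
                }
            )
    return pd.DataFrame(rows)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(i) = min_{j >= i} ( p_(j) * m / j ), clipped at 1, mapped back to
    the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.clip(adj_sorted, 0.0, 1.0)
    return adj


def de_test(
    matrix: pd.DataFrame,
    annotations: pd.DataFrame,
    genotype: str,
    tissue: str,
    treatment_pair: tuple[str, str] = ("drought", "control"),
    already_log2: bool = False,
) -> pd.DataFrame:
    """Per-gene drought-vs-control test within one genotype x tissue cell.

    Welch two-sample t-tests on log2 intensities; log2 FC is the stressed
    minus control mean.  FDR is Benjamini-Hochberg within this contrast.
    Genes with zero variance in both arms fall back to a pooled-variance
    test and are flagged.
    """
    stressed, control = treatment_pair
    sel = annotations[(annotations["genotype"] == genotype) & (annotations["tissue"] == tissue)]
    s_cols = list(sel.loc[sel["treatment"] == stressed, "sample"])
    c_cols = list(sel.loc[sel["treatment"] == control, "sample"])
    if len(s_cols) < 2 or len(c_cols) < 2:
        raise ValueError(
            f"{genotype}/{tissue}: need >= 2 replicates per arm, "
            f"got {len(s_cols)} vs {len(c_cols)}"
        )
    x = matrix[s_cols + c_cols].to_numpy(dtype=float)
    if not already_log2:
        x = np.log2(x + 1.0)
    a = x[:, : len(s_cols)]
    b = x[:, len(s_cols) :]
    lfc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", "Precision loss occurred")
        t_res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(t_res.pvalue, dtype=float)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    if degenerate.any():
        pooled = stats.ttest_ind(a[degenerate], b[degenerate], axis=1, equal_var=True)
        p[degenerate] = np.where(
            np.isfinite(pooled.pvalue),
            pooled.pvalue,
            np.where(lfc[degenerate] == 0, 1.0, 0.0),
        )
    return pd.DataFrame(
        {
            "unigene_id": matrix.index,
            "genotype": genotype,
            "tissue": tissue,
            "log2_fc": lfc,
            "p": p,
            "fdr": bh_adjust(p),
            "degenerate_variance": degenerate,
        }
    ).set_index("unigene_id")


@dataclass(frozen=True)
class VennCounts:
    """Per-direction shared/unique DEG counts between two genotypes."""

    direction: str
    genotype_a: str
    genotype_b: str
    unique_a: int
    shared: int
    unique_b: int

    @property
    def total_a(self) -> int:
        return self.unique_a + self.shared

    @property
    def total_b(self) -> int:
        return self.unique_b + self.shared


def call_degs(
    results: pd.DataFrame,
    fc_min: float = 2.0,
    fdr_max: float = 0.01,
) -> pd.DataFrame:
    """Differentially expressed genes at the fold-change and FDR thresholds.

    Both thresholds are inclusive: |log2 FC| >= log2(fc_min) and
    fdr <= fdr_max.  Input is one or more concatenated ``de_test`` outputs;
    the result carries a direction column (up/down under stress).
    """
    lfc_min = np.log2(fc_min)
    res = results.reset_index()
    passing = res[(res["log2_fc"].abs() >= lfc_min) & (res["fdr"] <= fdr_max)].copy()
    passing["direction"] = np.where(passing["log2_fc"] > 0, "up", "down")
    return passing[
        ["unigene_id", "genotype", "tissue", "log2_fc", "fdr", "direction"]
    ].reset_index(drop=True)


def venn_counts(
    degs: pd.DataFrame, genotype_a: str, genotype_b: str
) -> list[VennCounts]:
    """Shared and genotype-unique DEG counts, split by direction.

    A gene counts for a genotype if it is a DEG in that direction in any
    tissue of that genotype (union over tissues).
    """
    out = []
    for direction in ("up", "down"):
        sub = degs[degs["direction"] == direction]
        set_a = set(sub.loc[sub["genotype"] == genotype_a, "unigene_id"])
        set_b = set(sub.loc[sub["genotype"] == genotype_b, "unigene_id"])
        out.append(
            VennCounts(
                direction=direction, genotype_a=genotype_a, genotype_b=genotype_b,
                unique_a=len(set_a - set_b), shared=len(set_a & set_b),
                unique_b=len(set_b - set_a),
            )
        )
    return out


def family_profile(
    degs: pd.DataFrame,
    family_ids: list[str],
    assayed_ids: list[str] | None = None,
    tissues: tuple[str, ...] = ("leaf", "root"),
    genotypes: tuple[str, ...] = ("B47", "B128"),
) -> tuple[pd.DataFrame, dict]:
    """Drought-response profile of a gene family (e.g. the 52 aquaporins).

    Returns a per-member table of the genotype x tissue cells where the
    member is a DEG (with direction), and a summary dict: number of
    regulated members, members regulated in exactly one tissue
    (tissue-specific) or exactly one genotype (genotype-specific), the
    up/down split, and ids not assayed on the array.
    """
    fam = set(family_ids)
    not_assayed = sorted(fam - set(assayed_ids)) if assayed_ids is not None else []
    sub = degs[degs["unigene_id"].isin(fam)]
    rows = []
    for gid in sorted(fam - set(not_assayed)):
        cells = sub[sub["unigene_id"] == gid]
        row = {"unigene_id": gid}
        for geno in genotypes:
            for tissue in tissues:
                cell = cells[(cells["genotype"] == geno) & (cells["tissue"] == tissue)]
                row[f"{geno}_{tissue}"] = cell["direction"].iloc[0] if len(cell) else ""
        row["regulated"] = bool(len(cells))
        row["tissues_hit"] = sorted(set(cells["tissue"]))
        row["genotypes_hit"] = sorted(set(cells["genotype"]))
        rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        regulated = table[table["regulated"]]
        tissue_specific = {
            t: int((regulated["tissues_hit"].apply(lambda x, t=t: x == [t])).sum())
            for t in tissues
        }
        genotype_specific = {
            g: int((regulated["genotypes_hit"].apply(lambda x, g=g: x == [g])).sum())
            for g in genotypes
        }
        directions = set(
            zip(sub["unigene_id"], sub["direction"])
        )
        up_ids = {g for g, d in directions if d == "up"}
        down_ids = {g for g, d in directions if d == "down"}
        summary = {
            "n_regulated": int(regulated.shape[0]),
            "tissue_specific": tissue_specific,
            "genotype_specific": genotype_specific,
            "n_up": len(up_ids),
            "n_down": len(down_ids),
            "not_assayed": not_assayed,
        }
    else:
        summary = {
            "n_regulated": 0,
            "tissue_specific": {t: 0 for t in tissues},
            "genotype_specific": {g: 0 for g in genotypes},
            "n_up": 0,
            "n_down": 0,
            "not_assayed": not_assayed,
        }
    return table, summary


def export_ranked_list(results: pd.DataFrame, path, by: str = "p") -> None:
    """Write a ranked unigene list (ascending p) for external GO tools."""
    ranked = results.reset_index().sort_values(by)["unigene_id"]
    ranked.to_csv(path, index=False, header=False)
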