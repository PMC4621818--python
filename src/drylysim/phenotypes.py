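"""Visual drought scores, leaf relative water content, and cross-year trait correlations.

Three ordinal 0-5 scales are used for seedling-stage drought resistance in
cowpea panels: whole-plant wilting (Wt), senescence of unifoliates (Scu) and
stem greenness (Stg).  Wt and Stg are anchored only at their endpoints (0 =
no symptom, 5 = complete wilt / completely yellow) and enter the pipeline as
validated integers; Scu has printed leaf-area bins and is computed here from
the senesced fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TRAITS = ("Wt", "Scu", "Stg")

#: Upper edges of the Scu leaf-area bins for scores 1..4.  A fraction of 0
#: maps to 0; anything above 0.80 (or a dead/fallen plant) maps to 5.
SCU_BIN_EDGES = (0.20, 0.40, 0.60, 0.80)


def scu_score(senesced_fraction: float, dead_or_fallen: bool = False) -> int:
    """Map a senesced leaf-area fraction to the 0-5 unifoliate-senescence index.

    The bins are inclusive at their upper edge: score 1 covers
    0 < f <= 0.20, score 2 covers 0.20 < f <= 0.40, and so on.  A score of 5
    means more than 80% senesced area or a dead/fallen plant.

    Parameters
    ----------
    senesced_fraction
        Fraction of unifoliate leaf area senesced, in [0, 1].
    dead_or_fallen
        True if the plant is dead or the unifoliates have fallen; forces 5.
    """
    f = float(senesced_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"senesced fraction must be in [0, 1], got {f}")
    if dead_or_fallen:
        return 5
    if f == 0.0:
        return 0
    for score, edge in enumerate(SCU_BIN_EDGES, start=1):
        if f <= edge:
            return score
    return 5


@dataclass(frozen=True)
class RwcInput:
    """Fresh, dry and turgid weights (g) of a leaf sample."""

    fw: float
    dw: float
    tw: float

    def validate(self) -> None:
        if not (self.tw >= self.fw >= self.dw > 0):
            raise ValueError(
                f"expected tw >= fw >= dw > 0, got fw={self.fw}, dw={self.dw}, tw={self.tw}"
            )


def rwc(inp: RwcInput) -> float:
    """Leaf relative water content, RWC = (FW - DW) / (TW - DW) x 100%."""
    inp.validate()
    if inp.tw == inp.dw:
        raise ZeroDivisionError("turgid weight equals dry weight; RWC undefined")
    return (inp.fw - inp.dw) / (inp.tw - inp.dw) * 100.0


def validate_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-form score table (accession, trait, year, replicate, score).

    Scores must be integers in 0..5; (accession, trait, year, replicate) must
    be unique.  Returns the table unchanged on success.
    """
    required = {"accession", "trait", "year", "replicate", "score"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"score table missing columns: {sorted(missing)}")
    bad_trait = set(scores["trait"]) - set(TRAITS)
    if bad_trait:
        raise ValueError(f"unknown traits: {sorted(bad_trait)}")
    s = scores["score"]
    if not ((s >= 0) & (s <= 5) & (s == s.round())).all():
        raise ValueError("scores must be integers in 0..5")
    if scores.duplicated(["accession", "trait", "year", "replicate"]).any():
        raise ValueError("duplicate (accession, trait, year, replicate) rows")
    return scores


def accession_means(scores: pd.DataFrame) -> pd.DataFrame:
    """Replicate-mean score per accession for each (trait, year).

    Returns a wide table indexed by accession with one ``<trait><year>``
    column per trait-year combination (e.g. ``Scu2011``).
    """
    validate_scores(scores)
    means = (
        scores.groupby(["accession", "trait", "year"])["score"].mean().reset_index()
    )
    means["col"] = means["trait"] + means["year"].astype(str)
    wide = means.pivot(index="accession", columns="col", values="score")
    wide.columns.name = None
    return wide


def trait_correlations(
    scores: pd.DataFrame,
    alpha: float = 0.05,
    method: str = "pearson",
    min_shared: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise correlations between trait-year score vectors across accessions.

    Replicates are averaged per accession first; every (trait, year) pair is
    then correlated across the accessions shared by the two vectors.  Cells
    with p > ``alpha`` are masked (NaN), mirroring how such tables are
    conventionally reported with "-" for non-significant pairs.

    Returns
    -------
    (r, p) : two square DataFrames over the trait-year columns; ``r`` has
        non-significant cells masked, ``p`` holds the raw p-values.
        Pairs with fewer than ``min_shared`` shared accessions are left NaN
        in both.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    wide = accession_means(scores)
    cols = list(wide.columns)
    k = len(cols)
    r_mat = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    p_mat = r_mat.copy()
    corr = stats.pearsonr if method == "pearson" else stats.spearmanr
    for i, a in enumerate(cols):
        r_mat.loc[a, a] = 1.0
        p_mat.loc[a, a] = 0.0
        for b in cols[i + 1 :]:
            pair = wide[[a, b]].dropna()
            if len(pair) < min_shared:
                continue
            if pair[a].std() == 0 or pair[b].std() == 0:
                continue
            res = corr(pair[a], pair[b])
            r_val, p_val = float(res.statistic), float(res.pvalue)
            p_mat.loc[a, b] = p_mat.loc[b, a] = p_val
            if p_val <= alpha:
                r_mat.loc[a, b] = r_mat.loc[b, a] = r_val
    return r_mat, p_mat
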