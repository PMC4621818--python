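"""DEG-SNP co-localization and candidate-gene selection.

Two evidence routes link a differentially expressed gene to a significant
SNP:

* genetic map — both mapped on the consensus linkage map; a pair qualifies
  when it sits on the same linkage group and is coincident or strictly
  closer than the LD window (default 2 cM, the panel's average LD decay
  distance).
* ortholog physical — both anchored on a reference genome through their
  best filtered ortholog hit (aligned length >= 80 bp, e-value <= 1e-10,
  best = lowest e-value); a pair qualifies when the hits share a chromosome
  and their interval edge gap is at most 1.8 Mb (the physical equivalent of
  ~2 cM), inclusive.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

MAP_COLUMNS = ["entity_id", "linkage_group", "position_cm"]


def read_blast6(path) -> pd.DataFrame:
    """Read a 12-column tabular alignment file (outfmt 6 dialect)."""
    return pd.read_csv(path, sep="\t", names=BLAST6_COLUMNS, comment="#")


def genetic_colocalize(
    deg_positions: pd.DataFrame,
    snp_positions: pd.DataFrame,
    max_cm: float = 2.0,
    snp_traits: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """All (DEG, SNP) pairs on the same linkage group within the LD window.

    A pair is a candidate iff it is coincident (distance 0) or strictly
    closer than ``max_cm``.  Long-form output retains every qualifying pair
    and marks, per DEG, the nearest qualifying SNP.  Entities missing a map
    position are skipped with a warning.
    """
    out_cols = ["unigene_id", "snp", "evidence", "linkage_group", "distance", "nearest"]
    frames = []
    for name, tab in (("DEG", deg_positions), ("SNP", snp_positions)):
        missing = set(MAP_COLUMNS) - set(tab.columns)
        if missing:
            raise ValueError(f"{name} map table missing columns: {sorted(missing)}")
        bad = tab[MAP_COLUMNS[1:]].isna().any(axis=1)
        if bad.any():
            warnings.warn(
                f"{int(bad.sum())} {name} entries lack map positions; skipped",
                stacklevel=2,
            )
        frames.append(tab[~bad])
    degs, snps = frames
    rows = []
    for lg, dsub in degs.groupby("linkage_group"):
        ssub = snps[snps["linkage_group"] == lg]
        if ssub.empty:
            continue
        dpos = dsub["position_cm"].to_numpy(dtype=float)
        spos = ssub["position_cm"].to_numpy(dtype=float)
        dist = np.abs(dpos[:, None] - spos[None, :])
        hit = (dist == 0) | (dist < max_cm)
        di, si = np.where(hit)
        for a, b in zip(di, si):
            rows.append(
                {
                    "unigene_id": dsub["entity_id"].iloc[a],
                    "snp": ssub["entity_id"].iloc[b],
                    "evidence": "genetic_map",
                    "linkage_group": lg,
                    "distance": float(dist[a, b]),
                }
            )
    cand = pd.DataFrame(rows, columns=out_cols[:-1])
    if len(cand):
        cand["nearest"] = (
            cand.groupby("unigene_id")["distance"].transform("min") == cand["distance"]
        )
        cand = cand.sort_values(["unigene_id", "distance"]).reset_index(drop=True)
    else:
        cand = pd.DataFrame(columns=out_cols)
    if snp_traits is not None:
        cand = annotate_traits(cand, snp_traits)
    return cand


def best_ortholog(
    hits: pd.DataFrame, min_len: int = 80, max_evalue: float = 1e-10
) -> pd.DataFrame:
    """Filter alignment hits and keep at most one best hit per query.

    Hits with aligned length below ``min_len`` or e-value above
    ``max_evalue`` are discarded; among survivors the best hit has the
    lowest e-value, ties broken by highest bitscore then longest alignment.
    Subject coordinates are normalized so start <= end.
    """
    missing = set(BLAST6_COLUMNS) - set(hits.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    ok = hits[(hits["length"] >= min_len) & (hits["evalue"] <= max_evalue)].copy()
    if ok.empty:
        return ok
    ok = ok.sort_values(
        ["qseqid", "evalue", "bitscore", "length"],
        ascending=[True, True, False, False],
        kind="mergesort",
    )
    best = ok.groupby("qseqid", sort=True).head(1).copy()
    lo = best[["sstart", "send"]].min(axis=1)
    hi = best[["sstart", "send"]].max(axis=1)
    best["sstart"], best["send"] = lo, hi
    return best.reset_index(drop=True)


def _edge_gap(a_start, a_end, b_start, b_end):
    """Distance between the closest ends of two intervals; 0 when they overlap."""
    return np.maximum(0, np.maximum(b_start - a_end, a_start - b_end))


def physical_colocalize(
    deg_orthologs: pd.DataFrame,
    snp_orthologs: pd.DataFrame,
    max_bp: int = 1_800_000,
    snp_traits: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """All (DEG, SNP) ortholog pairs within the physical LD window.

    Both sides must carry best-hit intervals on the same reference assembly
    (chromosome in ``sseqid``, coordinates in ``sstart``/``send``).  A pair
    qualifies when the hits share a chromosome and their edge gap is at most
    ``max_bp`` (overlap counts as gap 0).  The midpoint distance is reported
    alongside the edge gap.
    """
    out_cols = [
        "unigene_id", "snp", "evidence", "chromosome",
        "distance", "midpoint_distance", "nearest",
    ]
    rows = []
    for chrom, dsub in deg_orthologs.groupby("sseqid"):
        ssub = snp_orthologs[snp_orthologs["sseqid"] == chrom]
        if ssub.empty:
            continue
        ds, de = dsub["sstart"].to_numpy(), dsub["send"].to_numpy()
        ss, se = ssub["sstart"].to_numpy(), ssub["send"].to_numpy()
        gap = _edge_gap(ds[:, None], de[:, None], ss[None, :], se[None, :])
        mid = np.abs((ds + de)[:, None] / 2.0 - (ss + se)[None, :] / 2.0)
        di, si = np.where(gap <= max_bp)
        for a, b in zip(di, si):
            rows.append(
                {
                    "unigene_id": dsub["qseqid"].iloc[a],
                    "snp": ssub["qseqid"].iloc[b],
                    "evidence": "ortholog_physical",
                    "chromosome": chrom,
                    "distance": int(gap[a, b]),
                    "midpoint_distance": float(mid[a, b]),
                }
            )
    cand = pd.DataFrame(rows, columns=out_cols[:-1])
    if len(cand):
        cand["nearest"] = (
            cand.groupby("unigene_id")["distance"].transform("min") == cand["distance"]
        )
        cand = cand.sort_values(["unigene_id", "distance"]).reset_index(drop=True)
    else:
        cand = pd.DataFrame(columns=out_cols)
    if snp_traits is not None:
        cand = annotate_traits(cand, snp_traits)
    return cand


def annotate_traits(candidates: pd.DataFrame, snp_traits: pd.DataFrame) -> pd.DataFrame:
    """Attach the traits of each linked SNP (table with columns snp, trait)."""
    trait_map = (
        snp_traits.groupby("snp")["trait"].apply(lambda s: ", ".join(sorted(set(s))))
    )
    out = candidates.copy()
    out["traits"] = out["snp"].map(trait_map).fillna("")
    return out


def combine_candidates(
    genetic: pd.DataFrame, physical: pd.DataFrame
) -> pd.DataFrame:
    """Union of the two evidence routes, deduplicated by (unigene, SNP).

    When a pair is supported by both routes the genetic-map record is kept
    and the evidence column reads ``genetic_map+ortholog_physical``.
    """
    both = pd.concat([genetic, physical], ignore_index=True, sort=False)
    if both.empty:
        return both
    keys = both.groupby(["unigene_id", "snp"])["evidence"].transform(
        lambda s: "+".join(sorted(set(s)))
    )
    both = both.assign(evidence=keys)
    return (
        both.drop_duplicates(["unigene_id", "snp"], keep="first")
        .sort_values(["unigene_id", "snp"])
        .reset_index(drop=True)
    )
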