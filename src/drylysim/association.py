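"""Marker-trait association scans with population structure and kinship.

Two models are provided, mirroring standard diversity-panel practice:

* GLM — fixed-effects least squares, trait ~ intercept + Q (minus one
  column, since memberships sum to one) + marker dosage, with a partial
  F-test (1 df) for the marker term.
* MLM — the kinship mixed model y = Xb + u + e with u ~ N(0, sg^2 K),
  e ~ N(0, se^2 I).  The variance ratio d = se^2/sg^2 is estimated once by
  REML on the null (no-marker) model through the spectral decomposition of K
  (the P3D/EMMAX approximation), then every marker is tested by GLS in the
  rotated, whitened basis.  With K = I the weights are constant and the MLM
  collapses exactly to the GLM.

Scans are vectorized across markers: trait and dosages are residualized
against the covariates and the per-marker F statistic follows from the
residual cross-products.  Declared significance follows a fixed -log10 P
threshold (default 3) with a consistency rule over (model, year) detections.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: Reporting cap for perfect fits: p-values below 1e-16 are reported at the cap.
P_CAP = 1e-16
NEG_LOG10_P_CAP = 16.0


@dataclass(frozen=True)
class QcReport:
    n_input: int
    n_kept: int
    removed_maf: tuple[str, ...]
    removed_missing: tuple[str, ...]


def qc_filter(
    genotypes: pd.DataFrame, maf_min: float = 0.05, missing_max: float = 0.2
) -> tuple[pd.DataFrame, QcReport]:
    """Drop markers failing minor-allele-frequency or missingness thresholds.

    Genotypes are accession x marker dosages in {0, 2, NaN}.  MAF is computed
    from non-missing calls.  Raises if no marker survives.
    """
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must lie in [0, 0.5]")
    if not 0 <= missing_max <= 1:
        raise ValueError("missing_max must lie in [0, 1]")
    g = genotypes.to_numpy(dtype=float)
    miss_rate = np.isnan(g).mean(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(g, axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    bad_missing = miss_rate > missing_max
    bad_maf = ~bad_missing & (np.isnan(maf) | (maf < maf_min))
    keep = ~(bad_missing | bad_maf)
    if not keep.any():
        raise ValueError("QC removed every marker")
    cols = genotypes.columns
    report = QcReport(
        n_input=len(cols),
        n_kept=int(keep.sum()),
        removed_maf=tuple(cols[bad_maf]),
        removed_missing=tuple(cols[bad_missing]),
    )
    return genotypes.loc[:, keep], report


def _impute_dosages(genotypes: pd.DataFrame) -> np.ndarray:
    g = genotypes.to_numpy(dtype=float).copy()
    means = np.nanmean(g, axis=0)
    nan_r, nan_c = np.where(np.isnan(g))
    g[nan_r, nan_c] = means[nan_c]
    return g


def _covariates(n: int, q: pd.DataFrame | None) -> np.ndarray:
    cols = [np.ones(n)]
    if q is not None:
        # Membership proportions sum to 1; drop the last column to keep the
        # design full rank alongside the intercept.
        cols.append(q.to_numpy(dtype=float)[:, :-1])
    return np.column_stack(cols)


def _marker_ftests(y: np.ndarray, G: np.ndarray, C: np.ndarray) -> pd.DataFrame:
    """Vectorized 1-df partial F-tests of each marker given covariates C.

    Equivalent to fitting trait ~ C + marker per marker by OLS and testing
    the marker coefficient; computed by residualizing y and every marker
    column on C and forming the F statistic from residual cross-products.
    """
    n, p = C.shape
    Cq, _ = np.linalg.qr(C)
    y_res = y - Cq @ (Cq.T @ y)
    G_res = G - Cq @ (Cq.T @ G)
    gg = np.einsum("ij,ij->j", G_res, G_res)
    gy = G_res.T @ y_res
    yy = float(y_res @ y_res)
    df_resid = n - p - 1
    if df_resid <= 0:
        raise ValueError("not enough accessions for the covariate design")
    ok = gg > 1e-12 * max(yy, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ss_marker = np.where(ok, gy**2 / gg, 0.0)
        rss = yy - ss_marker
        f = np.where(ok & (rss > 0), ss_marker / (rss / df_resid), np.inf)
        partial_r2 = np.where(ok & (yy > 0), ss_marker / yy, 0.0)
    pvals = stats.f.sf(f, 1, df_resid)
    capped = pvals < P_CAP
    pvals = np.clip(pvals, P_CAP, 1.0)
    out = pd.DataFrame(
        {
            "p": pvals,
            "neg_log10_p": -np.log10(pvals),
            "var_explained": partial_r2,
            "tested": ok,
            "p_capped": capped,
        }
    )
    out.loc[~ok, ["p", "neg_log10_p", "var_explained"]] = np.nan
    return out


def glm_scan(
    trait: pd.Series,
    genotypes: pd.DataFrame,
    q: pd.DataFrame | None = None,
    trait_name: str = "trait",
    year: int | str | None = None,
) -> pd.DataFrame:
    """Fixed-effects structured association scan (GLM with Q covariates)."""
    acc = genotypes.index
    y = trait.reindex(acc).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("trait values missing for some accessions")
    G = _impute_dosages(genotypes)
    C = _covariates(len(acc), q.reindex(acc) if q is not None else None)
    res = _marker_ftests(y, G, C)
    res.insert(0, "marker", genotypes.columns)
    res.insert(1, "trait", trait_name)
    res.insert(2, "year", year)
    res.insert(3, "model", "GLM")
    return res


@dataclass(frozen=True)
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    delta: float  # se^2 / sg^2
    reml_loglik: float


def _reml_delta(y: np.ndarray, X: np.ndarray, lam: np.ndarray, U: np.ndarray):
    """REML estimate of delta = se^2/sg^2 for V = sg^2 (K + delta I)."""
    n, p = X.shape
    yr = U.T @ y
    Xr = U.T @ X

    def neg_reml(log_delta: float) -> float:
        d = np.exp(log_delta)
        w = lam + d
        Xw = Xr / w[:, None]
        XtWX = Xr.T @ Xw
        beta = np.linalg.solve(XtWX, Xw.T @ yr)
        resid = yr - Xr @ beta
        rss = float(resid @ (resid / w))
        sg2 = rss / (n - p)
        _, ld_xtwx = np.linalg.slogdet(XtWX)
        _, ld_xtx = np.linalg.slogdet(X.T @ X)
        ll = -0.5 * (
            (n - p) * np.log(2 * np.pi * sg2)
            + np.sum(np.log(w))
            + ld_xtwx
            - ld_xtx
            + (n - p)
        )
        return -ll

    grid = np.linspace(-8, 8, 33)
    vals = [neg_reml(g) for g in grid]
    i = int(np.argmin(vals))
    lo, hi = grid[max(0, i - 1)], grid[min(len(grid) - 1, i + 1)]
    res = optimize.minimize_scalar(neg_reml, bounds=(lo, hi), method="bounded")
    log_delta = float(res.x)
    d = float(np.exp(log_delta))
    w = lam + d
    Xw = Xr / w[:, None]
    beta = np.linalg.solve(Xr.T @ Xw, Xw.T @ yr)
    resid = yr - Xr @ beta
    sg2 = float(resid @ (resid / w)) / (n - p)
    return VarianceComponents(
        sigma_g2=sg2, sigma_e2=sg2 * d, delta=d, reml_loglik=float(-res.fun)
    )


def mlm_scan(
    trait: pd.Series,
    genotypes: pd.DataFrame,
    q: pd.DataFrame | None = None,
    k: pd.DataFrame | None = None,
    trait_name: str = "trait",
    year: int | str | None = None,
    return_vc: bool = False,
):
    """Kinship mixed-model association scan (Q + K).

    Variance components are estimated once on the null model by REML over
    the spectral decomposition of K; each marker is then tested by a 1-df
    GLS F-test in the whitened basis.  K must be symmetric positive
    semidefinite over the scanned accessions.
    """
    if k is None:
        raise ValueError("MLM scan requires a kinship matrix K")
    acc = genotypes.index
    y = trait.reindex(acc).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("trait values missing for some accessions")
    K = k.reindex(index=acc, columns=acc).to_numpy(dtype=float)
    if np.isnan(K).any():
        raise ValueError("kinship matrix missing accessions")
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kinship matrix must be symmetric")
    lam, U = np.linalg.eigh(K)
    if lam.min() < -1e-8 * max(1.0, lam.max()):
        raise ValueError("kinship matrix must be positive semidefinite")
    lam = np.clip(lam, 0.0, None)

    G = _impute_dosages(genotypes)
    C = _covariates(len(acc), q.reindex(acc) if q is not None else None)
    vc = _reml_delta(y, C, lam, U)

    w = np.sqrt(lam + vc.delta)
    y_t = (U.T @ y) / w
    C_t = (U.T @ C) / w[:, None]
    G_t = (U.T @ G) / w[:, None]
    res = _marker_ftests(y_t, G_t, C_t)
    res.insert(0, "marker", genotypes.columns)
    res.insert(1, "trait", trait_name)
    res.insert(2, "year", year)
    res.insert(3, "model", "MLM")
    if return_vc:
        return res, vc
    return res


def genomic_inflation(neg_log10_p: np.ndarray) -> float:
    """Genomic inflation factor: median chi2(1df) of the scan over its
    null expectation (0.4549)."""
    p = 10.0 ** (-np.asarray(neg_log10_p, dtype=float))
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))


def call_significant(
    results: pd.DataFrame,
    threshold_neg_log10_p: float = 3.0,
    consistency_min: int = 2,
) -> pd.DataFrame:
    """Declare marker-trait associations from scans across models and years.

    A marker is significant for a trait when its -log10 P exceeds the
    threshold in at least ``consistency_min`` distinct (model, year)
    combinations.  Support labels follow the G<year>/M<year> convention
    (G = GLM, M = MLM).
    """
    needed = {"marker", "trait", "year", "model", "neg_log10_p"}
    missing = needed - set(results.columns)
    if missing:
        raise ValueError(f"results table missing columns: {sorted(missing)}")
    hits = results[results["neg_log10_p"] > threshold_neg_log10_p]
    rows = []
    for (marker, trait), grp in hits.groupby(["marker", "trait"], sort=True):
        combos = sorted(
            {(m, y) for m, y in zip(grp["model"], grp["year"])},
            key=lambda c: (str(c[1]), c[0]),
        )
        if len(combos) < consistency_min:
            continue
        support = ", ".join(f"{'G' if m == 'GLM' else 'M'}{y}" for m, y in combos)
        rows.append(
            {
                "marker": marker, "trait": trait, "n_support": len(combos),
                "support": support,
                "max_neg_log10_p": float(grp["neg_log10_p"].max()),
            }
        )
    return pd.DataFrame(rows, columns=["marker", "trait", "n_support", "support",
                                       "max_neg_log10_p"])


def load_reported_associations() -> pd.DataFrame:
    """The published marker-trait association table bundled as a fixture.

    Columns: snp, trait, support, linkage_group, position_cm plus the
    reported African-cowpea trait and QTL annotations.  One row per
    trait-locus association; loci associated with two traits appear twice.
    """
    path = resources.files("drylysim.data").joinpath("reported_marker_associations.tsv")
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", dtype={"snp": str})
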