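"""Segmented midday transpiration vs. soil water content.

During progressive soil drying, midday whole-plant transpiration (normalized
to plant weight and VPD; ETW) stays on a plateau E_max while soil water is
non-limiting, then declines once the relative soil water content drops below
a critical value theta_cr.  The response is modeled as a continuous hinge:

    etw(s) = E_max                              for s >= theta_cr
    etw(s) = E_max - slope * (theta_cr - s)     for s <  theta_cr

E_max, theta_cr and the decline slope are estimated per plant by least
squares with a grid search over the breakpoint, and genotypes are compared by
pairwise Welch t-tests summarized in a compact letter display.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass(frozen=True)
class MiddayPoint:
    """One drought-day observation: midday SWC (relative, 0-1) and ETW."""

    day: int
    swc: float
    etw: float


@dataclass(frozen=True)
class WaterResponseFit:
    e_max: float
    theta_cr: float | None  # None when no breakpoint is identifiable
    slope: float
    rss: float
    n_points: int

    @property
    def has_breakpoint(self) -> bool:
        return self.theta_cr is not None


def extract_midday_points(
    etw: pd.Series,
    swc: pd.Series,
    midday_window: tuple[str, str] = ("11:00", "14:00"),
    days: pd.DatetimeIndex | None = None,
) -> list[MiddayPoint]:
    """One (SWC, ETW) point per drought day.

    For each day, ETW is summarized by the median over the midday window
    (robust to residual spikes around probe events) and SWC by the mean.
    Days whose window holds no finite ETW sample are omitted.
    """
    frame = pd.DataFrame({"etw": etw, "swc": swc.reindex(etw.index)})
    points: list[MiddayPoint] = []
    for day_i, (day, sub) in enumerate(frame.groupby(frame.index.normalize())):
        if days is not None and day not in days:
            continue
        win = sub.between_time(*midday_window).dropna()
        if win.empty:
            continue
        points.append(
            MiddayPoint(day=day_i, swc=float(win["swc"].mean()), etw=float(win["etw"].median()))
        )
    return points


def _hinge_rss(s: np.ndarray, y: np.ndarray, theta: float) -> tuple[float, float, float]:
    """Least-squares (e_max, slope, rss) for a fixed breakpoint theta.

    Linear in the basis [1, max(theta - s, 0)]; the slope is constrained to
    be nonnegative (a negative fitted slope collapses to the flat model).
    """
    h = np.maximum(theta - s, 0.0)
    ones = np.ones_like(s)
    X = np.column_stack([ones, -h])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    e_max, slope = float(beta[0]), float(beta[1])
    if slope < 0:
        e_max, slope = float(y.mean()), 0.0
    resid = y - (e_max - slope * h)
    return e_max, slope, float(resid @ resid)


def fit_segmented(
    points: list[MiddayPoint],
    grid_step: float = 0.005,
    min_side: int = 2,
) -> WaterResponseFit:
    """Fit the continuous two-segment plateau/decline model.

    The breakpoint is located by a grid search over the observed SWC range
    (candidates must leave at least ``min_side`` points on each side),
    minimizing RSS, followed by bounded local refinement.  RSS ties are
    broken toward the smallest theta_cr (the most conservative, earliest
    stomatal-response interpretation).  When no candidate breakpoint is
    admissible, or the best segmented fit degenerates to slope 0, a flat
    model is returned with ``theta_cr=None``.
    """
    if len(points) < 5:
        raise ValueError(f"segmented fit requires >= 5 points, got {len(points)}")
    s = np.array([p.swc for p in points], dtype=float)
    y = np.array([p.etw for p in points], dtype=float)
    order = np.argsort(s)
    s_sorted = s[order]
    lo = s_sorted[min_side - 1] if min_side > 0 else s_sorted[0]
    hi = s_sorted[-min_side] if min_side > 0 else s_sorted[-1]
    flat = WaterResponseFit(
        e_max=float(y.mean()), theta_cr=None, slope=0.0,
        rss=float(((y - y.mean()) ** 2).sum()), n_points=len(points),
    )
    if not lo < hi:
        return flat
    candidates = np.arange(lo + grid_step, hi, grid_step)
    if candidates.size == 0:
        return flat
    rss_grid = np.array([_hinge_rss(s, y, th)[2] for th in candidates])
    # Tie tolerance scales with the data; among RSS ties take the smallest
    # theta (earliest stomatal response).
    tol = 1e-9 * float(y @ y)
    best_i = int(np.flatnonzero(rss_grid <= rss_grid.min() + tol).min())
    theta0 = float(candidates[best_i])
    # Local refinement within one grid step either side.
    res = optimize.minimize_scalar(
        lambda th: _hinge_rss(s, y, th)[2],
        bounds=(max(lo, theta0 - grid_step), min(hi, theta0 + grid_step)),
        method="bounded",
    )
    theta = float(res.x) if res.fun <= rss_grid[best_i] else theta0
    e_max, slope, rss = _hinge_rss(s, y, theta)
    if slope == 0.0 or rss >= flat.rss:
        return flat
    return WaterResponseFit(
        e_max=e_max, theta_cr=theta, slope=slope, rss=rss, n_points=len(points)
    )


def fits_to_frame(fits: dict[str, dict[str, WaterResponseFit]]) -> pd.DataFrame:
    """Long-form table of per-plant fits: genotype, plant_id, parameters."""
    rows = []
    for genotype, plants in fits.items():
        for plant_id, fit in plants.items():
            rows.append(
                {
                    "genotype": genotype, "plant_id": plant_id,
                    "e_max": fit.e_max, "theta_cr": fit.theta_cr,
                    "slope": fit.slope, "rss": fit.rss, "n_points": fit.n_points,
                }
            )
    return pd.DataFrame(rows)


def compact_letters(
    groups: list[str], significant: set[tuple[str, str]]
) -> dict[str, str]:
    """Compact letter display from a pairwise-significance relation.

    Greedy insert-absorb: groups sharing a letter are not significantly
    different.  ``significant`` holds unordered pairs that differ.
    """
    sig = {frozenset(p) for p in significant}

    def compatible(g: str, members: set[str]) -> bool:
        return all(frozenset((g, m)) not in sig for m in members)

    letter_sets: list[set[str]] = []
    for g in groups:
        placed = False
        for ls in letter_sets:
            if compatible(g, ls):
                ls.add(g)
                placed = True
        if not placed:
            # Seed a new set with g and absorb every compatible group.
            new = {g}
            for h in groups:
                if h != g and compatible(h, new):
                    new.add(h)
            letter_sets.append(new)
    # Drop sets contained in (or duplicating) another.
    letter_sets = [
        ls for i, ls in enumerate(letter_sets)
        if not any(
            ls < other or (ls == other and j < i)
            for j, other in enumerate(letter_sets) if i != j
        )
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, ls in zip(alphabet, letter_sets):
        for g in groups:
            if g in ls:
                out[g] += letter
    return out


def compare_genotypes(
    fit_table: pd.DataFrame,
    params: tuple[str, ...] = ("e_max", "theta_cr", "slope"),
    alpha: float = 0.05,
    min_plants: int = 3,
) -> pd.DataFrame:
    """Per-parameter genotype comparison with significance letters.

    For each parameter, pairwise Welch t-tests between genotypes (per-plant
    fits as replicates); genotypes sharing a letter are not significantly
    different at ``alpha``.  Returns mean, SE, n and letters per genotype and
    parameter.
    """
    genotypes = sorted(fit_table["genotype"].unique())
    if len(genotypes) < 2:
        raise ValueError("genotype comparison requires >= 2 genotypes")
    rows = []
    for param in params:
        samples = {
            g: fit_table.loc[fit_table["genotype"] == g, param].dropna().to_numpy()
            for g in genotypes
        }
        for g, v in samples.items():
            if len(v) < min_plants:
                raise ValueError(
                    f"genotype {g}: {len(v)} plants with {param}; need >= {min_plants}"
                )
        sig: set[tuple[str, str]] = set()
        for a, b in combinations(genotypes, 2):
            t = stats.ttest_ind(samples[a], samples[b], equal_var=False)
            if t.pvalue < alpha:
                sig.add((a, b))
        letters = compact_letters(genotypes, sig)
        for g in genotypes:
            v = samples[g]
            rows.append(
                {
                    "parameter": param, "genotype": g, "mean": float(v.mean()),
                    "se": float(v.std(ddof=1) / np.sqrt(len(v))), "n": len(v),
                    "letters": letters[g],
                }
            )
    return pd.DataFrame(rows)
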