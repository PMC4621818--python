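"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the study designs this pipeline targets: diurnal
pot-weight traces from a gravimetric lysimeter array with nightly
irrigation/drainage cycles, a 95-accession x ~1,100-SNP inbred diversity
panel with two subpopulations, a 2 genotypes x 2 tissues x 2 treatments x 3
replicates expression-array design, and genetic-map / ortholog-hit tables
with planted DEG-SNP co-localization pairs.  Every generator takes a seed
and is byte-deterministic given it.

The lysimeter model: during daylight a plant transpires at
rate = ETW(s) * W_plant * VPD(t) g/min, where ETW(s) is the piecewise
plateau/decline function of relative soil water content s (plateau E_max
above the critical content theta_cr, linear decline with the given slope
below it, floored at zero).  Nighttime transpiration is zero (stomata
closed).  Biomass accumulates as wue_true x transpired water.  Nightly
irrigation overfills the container and free drainage returns it to a fixed
water level, so each morning's weight is the base weight plus accumulated
biomass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lysimetry import SoilProbeTrace, WeighTrace, compute_vpd
from .water_response import MiddayPoint

START_DATE = "2010-08-01"  # anchors all simulated timestamps

BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


# ---------------------------------------------------------------------------
# Climate
# ---------------------------------------------------------------------------

def simulate_climate(
    days: int,
    step_min: int = 10,
    seed: int = 0,
    t_max: float = 34.0,
    t_min: float = 15.0,
    rh_min: float = 30.0,
    rh_max: float = 85.0,
    peak_hour: float = 14.0,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Sinusoidal diurnal greenhouse climate (temperature, RH) on a minute grid.

    Temperature peaks at ``peak_hour`` with the configured max:min range;
    relative humidity runs in anti-phase (driest at the temperature peak).
    Gaussian noise of ``noise_sd`` (deg C; scaled x2 for RH) is added when
    requested.  Returns a DataFrame indexed by timestamp with columns
    ``air_temp_c`` and ``rel_humidity_pct``.
    """
    if days < 1 or step_min < 1:
        raise ValueError("days and step_min must be positive")
    if 1440 % step_min != 0:
        raise ValueError("step_min must divide 1440")
    rng = np.random.default_rng(seed)
    idx = pd.date_range(START_DATE, periods=days * 1440 // step_min, freq=f"{step_min}min")
    hours = idx.hour + idx.minute / 60.0
    phase = np.cos(2 * np.pi * (hours - peak_hour) / 24.0)
    temp = (t_max + t_min) / 2.0 + (t_max - t_min) / 2.0 * phase
    rh = (rh_max + rh_min) / 2.0 - (rh_max - rh_min) / 2.0 * phase
    if noise_sd > 0:
        temp = temp + rng.normal(0, noise_sd, len(idx))
        rh = rh + rng.normal(0, 2 * noise_sd, len(idx))
    rh = np.clip(rh, 0.0, 100.0)
    return pd.DataFrame({"air_temp_c": temp, "rel_humidity_pct": rh}, index=idx)


# ---------------------------------------------------------------------------
# Lysimeter runs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LysimeterTruth:
    """Ground-truth physiology for one simulated plant/genotype.

    Units: e_max in g water per g plant per kPa per min; theta_cr and slope
    on the relative soil-water-content scale; wue in g biomass per g water.
    """

    genotype_id: str
    e_max_true: float = 1.0e-3
    theta_cr_true: float = 0.35
    slope_true: float = 4.0e-3
    wue_true: float = 0.05
    growth_rate_true: float = 4.5  # nominal g/day under well-watered demand
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.theta_cr_true < 1:
            raise ValueError("theta_cr_true must lie strictly inside (0, 1)")
        if self.slope_true <= 0 or self.wue_true <= 0 or self.e_max_true < 0:
            raise ValueError("slope_true and wue_true must be positive, e_max_true >= 0")

    def etw_at(self, swc: float) -> float:
        """Piecewise plateau/decline transpiration response at relative SWC."""
        if swc >= self.theta_cr_true:
            return self.e_max_true
        return max(0.0, self.e_max_true - self.slope_true * (self.theta_cr_true - swc))


@dataclass(frozen=True)
class IrrigationSchedule:
    """Nightly irrigation/drainage clock times and the overfill fraction."""

    irrigation_time: str = "22:00"
    drainage_time: str = "23:00"
    overfill_fraction: float = 0.2  # extra water beyond refill, drained away


@dataclass
class LysimeterRun:
    trace: WeighTrace
    probe: SoilProbeTrace
    ledger: pd.DataFrame  # per-day: transpiration_g, biomass_gain_g, irrigation_g, drainage_g
    truth: LysimeterTruth


def simulate_lysimeter_run(
    truth: LysimeterTruth,
    climate: pd.DataFrame,
    phases: tuple[int, int, int] = (7, 10, 0),
    schedule: IrrigationSchedule | None = None,
    pot_capacity_g: float = 1000.0,
    tare_g: float = 2000.0,
    initial_plant_weight_g: float = 20.0,
    daylight: tuple[float, float] = (6.0, 19.5),
    noise_g: float = 0.0,
    seed: int | None = None,
) -> LysimeterRun:
    """Simulate one pot through pretreatment, drought and recovery phases.

    Container weight = tare + pot water + plant biomass (+ measurement
    noise).  Irrigation happens nightly during pretreatment and recovery;
    withholding irrigation defines the drought phase.  The per-day water
    ledger (transpiration, biomass gain, irrigation, drainage) is returned
    alongside the weight and soil-probe traces.
    """
    schedule = schedule or IrrigationSchedule()
    pre, drt, rec = phases
    if pre < 0 or drt < 0 or rec < 0 or (pre + drt + rec) < 1:
        raise ValueError("phase lengths must be nonnegative with a positive total")
    n_days_needed = pre + drt + rec
    idx = climate.index
    step_min = (idx[1] - idx[0]).total_seconds() / 60.0
    n_days_avail = len(idx) * step_min / 1440.0
    if n_days_avail + 1e-9 < n_days_needed:
        raise ValueError(
            f"climate trace covers {n_days_avail:.1f} days; run needs {n_days_needed}"
        )
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    vpd = compute_vpd(climate["air_temp_c"].to_numpy(), climate["rel_humidity_pct"].to_numpy())

    irr_h, irr_m = (int(x) for x in schedule.irrigation_time.split(":"))
    drn_h, drn_m = (int(x) for x in schedule.drainage_time.split(":"))
    day0 = idx[0].normalize()

    n = pre + drt + rec
    n_steps = int(n * 1440 / step_min)
    water = pot_capacity_g
    biomass = initial_plant_weight_g
    weight = np.empty(n_steps)
    swc = np.empty(n_steps)
    irrigation = np.zeros(n_steps, dtype=bool)
    drainage = np.zeros(n_steps, dtype=bool)
    day_transp = np.zeros(n)
    day_irr = np.zeros(n)
    day_drain = np.zeros(n)
    biomass_morning = np.full(n + 1, np.nan)
    biomass_morning[0] = biomass
    overfill = schedule.overfill_fraction * pot_capacity_g

    # Daytime container weight loss is pure vapor loss; the day's assimilate
    # (wue x transpired water, i.e. carbon fixed) is booked into biomass
    # overnight, so predawn-to-evening differences measure transpiration and
    # morning-to-morning post-drainage differences measure biomass gain.
    assimilate = 0.0
    for i in range(n_steps):
        ts = idx[i]
        day_k = int((ts - day0).days)
        in_drought = pre <= day_k < pre + drt
        hour = ts.hour + ts.minute / 60.0
        if ts.hour == 0 and ts.minute == 0:
            biomass += assimilate
            assimilate = 0.0
            if day_k < n:
                biomass_morning[day_k] = biomass
        if daylight[0] <= hour < daylight[1] and biomass > 0:
            s = water / pot_capacity_g
            rate = truth.etw_at(s) * biomass * vpd[i]  # g/min
            transp = min(rate * step_min, water)
            water -= transp
            assimilate += truth.wue_true * transp
            day_transp[day_k] += transp
        if not in_drought:
            if ts.hour == irr_h and ts.minute == irr_m:
                added = (pot_capacity_g - water) + overfill
                water += added
                day_irr[day_k] += added
                irrigation[i] = True
            elif ts.hour == drn_h and ts.minute == drn_m:
                drained = max(0.0, water - pot_capacity_g)
                water -= drained
                day_drain[day_k] += drained
                drainage[i] = True
        weight[i] = tare_g + water + biomass
        swc[i] = water / pot_capacity_g
    biomass_morning[n] = biomass + assimilate

    readings = weight + (rng.normal(0, noise_g, n_steps) if noise_g > 0 else 0.0)
    run_idx = idx[:n_steps]
    trace = WeighTrace(
        plant_id=truth.genotype_id,
        data=pd.DataFrame(
            {"weight_g": readings, "irrigation": irrigation, "drainage": drainage},
            index=run_idx,
        ),
    )
    probe = SoilProbeTrace(
        plant_id=truth.genotype_id,
        data=pd.DataFrame(
            {
                "swc": swc,
                "ec": np.full(n_steps, 1.2),
                "soil_temp": climate["air_temp_c"].to_numpy()[:n_steps] * 0.8,
            },
            index=run_idx,
        ),
    )
    ledger = pd.DataFrame(
        {
            "day": np.arange(n),
            "phase": ["pretreatment"] * pre + ["drought"] * drt + ["recovery"] * rec,
            "transpiration_g": day_transp,
            "biomass_gain_g": np.diff(biomass_morning),
            "irrigation_g": day_irr,
            "drainage_g": day_drain,
        }
    ).set_index("day")
    return LysimeterRun(trace=trace, probe=probe, ledger=ledger, truth=truth)


def simulate_midday_points(
    truth: LysimeterTruth,
    n_days: int = 10,
    noise_frac: float = 0.05,
    seed: int = 0,
    pot_capacity_g: float = 1000.0,
    initial_plant_weight_g: float = 45.0,
    vpd_daylight_integral: float = 2070.0,  # kPa*min of daytime demand per day
    swc_start: float = 1.0,
) -> list[MiddayPoint]:
    """Daily midday (SWC, ETW) observations from a drying-down water balance.

    Runs the same piecewise transpiration model as the trace simulator at
    day resolution: each drought day the plant transpires
    ETW(s) x W x (daylight VPD integral) grams, depleting the pot, while
    biomass grows by wue x transpiration.  The observed midday ETW carries
    Gaussian noise with standard deviation ``noise_frac x E_max``; SWC is
    read at midday (half the day's depletion).
    """
    rng = np.random.default_rng(seed)
    water = swc_start * pot_capacity_g
    w_plant = initial_plant_weight_g
    points: list[MiddayPoint] = []
    sd = noise_frac * truth.e_max_true
    for day in range(n_days):
        s_morning = water / pot_capacity_g
        etw_true = truth.etw_at(s_morning)
        transp = min(etw_true * w_plant * vpd_daylight_integral, water)
        s_midday = (water - transp / 2.0) / pot_capacity_g
        etw_obs = max(0.0, truth.etw_at(s_midday) + (rng.normal(0, sd) if sd > 0 else 0.0))
        points.append(MiddayPoint(day=day, swc=float(s_midday), etw=float(etw_obs)))
        water -= transp
        w_plant += truth.wue_true * transp
    return points


# ---------------------------------------------------------------------------
# Association panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelTruth:
    """Causal architecture of the simulated diversity panel.

    ``causal_snps`` maps trait -> list of (marker index, effect size on the
    liability scale); ``h2`` maps trait -> fraction of liability variance
    from the causal markers.  ``structure_sd`` sets the standard deviation of
    the subpopulation shift on the liability.
    """

    causal_snps: dict[str, list[tuple[int, float]]] = field(default_factory=dict)
    h2: dict[str, float] = field(default_factory=dict)
    structure_sd: float = 0.0

    def __post_init__(self) -> None:
        for t, v in self.h2.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"h2 for {t} must lie in [0, 1], got {v}")


@dataclass
class SimulatedPanel:
    genotypes: pd.DataFrame       # accessions x markers, codes {0, 2}
    marker_map: pd.DataFrame      # marker, linkage_group, position_cm
    q: pd.DataFrame               # accessions x subpopulations, rows sum to 1
    k: pd.DataFrame               # accessions x accessions kinship
    scores: pd.DataFrame          # long-form ordinal score table
    liabilities: pd.DataFrame     # accessions x traits, pre-discretization
    truth: PanelTruth


def _kinship_vanraden(geno01: np.ndarray) -> np.ndarray:
    """VanRaden genomic relationship matrix from 0/1 allele dosages."""
    p = geno01.mean(axis=0)
    keep = (p > 0) & (p < 1)
    z = geno01[:, keep] - p[keep]
    denom = np.sum(p[keep] * (1 - p[keep]))
    k = z @ z.T / denom
    return k


def _discretize_scores(liability: np.ndarray) -> np.ndarray:
    """Map standardized liabilities to 0-5 by equal-probability normal bins."""
    from scipy.stats import norm

    z = (liability - liability.mean()) / (liability.std() or 1.0)
    edges = norm.ppf(np.arange(1, 6) / 6.0)
    return np.digitize(z, edges).astype(int)


def simulate_panel(
    n_acc: int = 95,
    n_snp: int = 1127,
    truth: PanelTruth | None = None,
    seed: int = 0,
    n_subpop: int = 2,
    fst: float = 0.15,
    years: tuple[int, ...] = (2011, 2012, 2014),
    traits: tuple[str, ...] = ("Wt", "Scu", "Stg"),
    n_reps: int = 3,
    n_lg: int = 11,
) -> SimulatedPanel:
    """Inbred diversity panel with subpopulation structure and ordinal traits.

    Genotypes are biallelic 0/2 codes (selfing crop, no heterozygotes) with
    Balding-Nichols subpopulation-differentiated allele frequencies at the
    given Fst.  Q holds soft subpopulation memberships; K is computed from
    the genotypes (VanRaden).  Per trait and year, a liability
    sum(effects) + structure shift + noise at the stated h2 is built, and
    each replicate's liability (with replicate-level noise) is discretized
    to 0-5 scores by equal-probability bins under the null.
    """
    if n_acc < 10:
        raise ValueError("panel needs at least 10 accessions")
    truth = truth or PanelTruth()
    for trait, pairs in truth.causal_snps.items():
        for j, _ in pairs:
            if not 0 <= j < n_snp:
                raise ValueError(f"causal marker index {j} outside panel for {trait}")
    rng = np.random.default_rng(seed)

    subpop = rng.integers(0, n_subpop, n_acc)
    p_anc = rng.uniform(0.1, 0.9, n_snp)
    a = p_anc * (1 - fst) / fst
    b = (1 - p_anc) * (1 - fst) / fst
    p_sub = rng.beta(a, b, size=(n_subpop, n_snp))
    geno01 = (rng.random((n_acc, n_snp)) < p_sub[subpop]).astype(float)

    accessions = pd.Index([f"ACC{i:03d}" for i in range(n_acc)], name="accession")
    markers = [f"1_{i:04d}" for i in range(n_snp)]
    genotypes = pd.DataFrame(2.0 * geno01, index=accessions, columns=markers)

    lg = rng.integers(1, n_lg + 1, n_snp)
    cm = np.round(rng.uniform(0, 100, n_snp), 2)
    marker_map = pd.DataFrame(
        {"marker": markers, "linkage_group": lg, "position_cm": cm}
    ).set_index("marker")

    own = rng.uniform(0.75, 0.95, n_acc)
    q = np.full((n_acc, n_subpop), 0.0)
    for i in range(n_acc):
        q[i] = (1 - own[i]) / (n_subpop - 1)
        q[i, subpop[i]] = own[i]
    q = pd.DataFrame(q, index=accessions, columns=[f"Q{s+1}" for s in range(n_subpop)])

    k = pd.DataFrame(_kinship_vanraden(geno01), index=accessions, columns=accessions)

    rows = []
    liab_cols = {}
    for trait in traits:
        pairs = truth.causal_snps.get(trait, [])
        h2 = truth.h2.get(trait, 0.0)
        genetic = np.zeros(n_acc)
        for j, beta in pairs:
            genetic += beta * geno01[:, j]
        var_g = genetic.var()
        if h2 > 0 and var_g > 0:
            var_e = var_g * (1 - h2) / h2
        else:
            genetic = np.zeros(n_acc)
            var_e = 1.0
        structure = (
            truth.structure_sd * (subpop - subpop.mean()) if truth.structure_sd else 0.0
        )
        sd_e = np.sqrt(var_e)
        for year in years:
            acc_noise = rng.normal(0, sd_e, n_acc)
            liability = genetic + structure + acc_noise
            liab_cols[f"{trait}{year}"] = liability
            for rep in range(1, n_reps + 1):
                rep_liab = liability + rng.normal(0, 0.3 * sd_e, n_acc)
                scores = _discretize_scores(rep_liab)
                rows.extend(
                    {
                        "accession": accessions[i], "trait": trait, "year": year,
                        "replicate": rep, "score": int(scores[i]),
                    }
                    for i in range(n_acc)
                )
    scores = pd.DataFrame(rows)
    liabilities = pd.DataFrame(liab_cols, index=accessions)
    return SimulatedPanel(
        genotypes=genotypes, marker_map=marker_map, q=q, k=k,
        scores=scores, liabilities=liabilities, truth=truth,
    )


# ---------------------------------------------------------------------------
# Expression arrays
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionTruth:
    """Planted differential expression: (genotype, tissue) -> {gene: log2 FC}."""

    true_degs: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cond, genes in self.true_degs.items():
            for g, lfc in genes.items():
                if abs(lfc) < 1.0:
                    raise ValueError(
                        f"planted DEG {g} in {cond} has |log2FC| {abs(lfc)} < 1"
                    )


@dataclass
class SimulatedExpression:
    matrix: pd.DataFrame       # genes x samples, linear-scale intensities
    annotations: pd.DataFrame  # sample, genotype, tissue, treatment, replicate
    truth: ExpressionTruth


def simulate_expression(
    n_genes: int = 2000,
    truth: ExpressionTruth | None = None,
    seed: int = 0,
    genotypes: tuple[str, ...] = ("B47", "B128"),
    tissues: tuple[str, ...] = ("leaf", "root"),
    treatments: tuple[str, ...] = ("control", "drought"),
    n_reps: int = 3,
    rep_sd: float = 0.13,
    base_mean: float = 8.0,
    base_sd: float = 1.5,
) -> SimulatedExpression:
    """Factorial expression-array intensities with planted DEGs.

    Per-gene baselines are drawn on the log2 scale (so intensities are
    log-normal); planted DEGs are shifted by their log2 fold change in the
    stressed samples of their (genotype, tissue) condition; replicate noise
    is Gaussian on the log2 scale.  Sample count is
    genotypes x tissues x treatments x replicates.
    """
    truth = truth or ExpressionTruth()
    if n_reps < 2:
        raise ValueError("differential expression needs at least 2 replicates")
    planted = {g for genes in truth.true_degs.values() for g in genes}
    if n_genes < len(planted):
        raise ValueError("n_genes smaller than the number of planted DEGs")
    rng = np.random.default_rng(seed)
    gene_ids = [f"UG{i:05d}" for i in range(n_genes)]
    id_index = {g: i for i, g in enumerate(gene_ids)}
    for g in planted:
        if g not in id_index:
            raise ValueError(f"planted DEG id {g} outside the gene id space")
    base = rng.normal(base_mean, base_sd, n_genes)

    cols, annot = [], []
    data = np.empty((n_genes, 0))
    blocks = []
    for geno in genotypes:
        for tissue in tissues:
            shifts = np.zeros(n_genes)
            for g, lfc in truth.true_degs.get((geno, tissue), {}).items():
                shifts[id_index[g]] = lfc
            for trt in treatments:
                for rep in range(1, n_reps + 1):
                    mu = base + (shifts if trt == "drought" else 0.0)
                    log2_vals = mu + rng.normal(0, rep_sd, n_genes)
                    blocks.append(2.0 ** log2_vals)
                    name = f"{geno}_{tissue}_{trt}_r{rep}"
                    cols.append(name)
                    annot.append(
                        {"sample": name, "genotype": geno, "tissue": tissue,
                         "treatment": trt, "replicate": rep}
                    )
    data = np.column_stack(blocks)
    matrix = pd.DataFrame(data, index=gene_ids, columns=cols)
    annotations = pd.DataFrame(annot)
    return SimulatedExpression(matrix=matrix, annotations=annotations, truth=truth)


# ---------------------------------------------------------------------------
# Maps and ortholog hits for co-localization
# ---------------------------------------------------------------------------

@dataclass
class SimulatedMaps:
    deg_map: pd.DataFrame          # genetic-map positions of DEG unigenes
    snp_map: pd.DataFrame          # genetic-map positions of significant SNPs
    deg_hits: pd.DataFrame         # outfmt-6 ortholog hits for DEGs
    snp_hits: pd.DataFrame         # outfmt-6 ortholog hits for SNP source unigenes
    genetic_pairs: set[tuple[str, str]]   # planted (unigene, snp) within < 2 cM
    physical_pairs: set[tuple[str, str]]  # planted (unigene, snp) within <= 1.8 Mb


def _place_apart(rng, n, n_groups, span, anchors, min_gap, max_tries=2000):
    """Place n points on (group, position) charts keeping >= min_gap from all
    anchors sharing the group.  anchors: dict group -> array of positions."""
    out = []
    for _ in range(n):
        for attempt in range(max_tries):
            g = int(rng.integers(1, n_groups + 1))
            pos = float(rng.uniform(0, span))
            near = anchors.get(g, np.empty(0))
            if near.size == 0 or np.abs(near - pos).min() > min_gap:
                out.append((g, pos))
                break
        else:
            raise RuntimeError("placement failure: anchor density leaves no room")
    return out


def simulate_maps(
    n_deg: int = 100,
    n_snp: int = 39,
    planted_pairs: int = 7,
    seed: int = 0,
    n_lg: int = 11,
    lg_span_cm: float = 100.0,
    max_cm: float = 2.0,
    n_chrom: int = 20,
    chrom_span_bp: int = 50_000_000,
    max_bp: int = 1_800_000,
) -> SimulatedMaps:
    """Genetic-map and ortholog-hit fixtures with planted co-localizations.

    Exactly ``planted_pairs`` DEG-SNP pairs fall inside the genetic window
    (< ``max_cm`` on the same linkage group) and, independently, exactly
    ``planted_pairs`` pairs fall inside the physical window (edge gap <=
    ``max_bp`` on the same pseudo-chromosome); all remaining placements are
    guaranteed outside both windows.  Ortholog hits are emitted in the
    12-column BLAST tabular dialect and pass the downstream best-hit filter.
    """
    if planted_pairs > min(n_deg, n_snp):
        raise ValueError("planted_pairs cannot exceed min(n_deg, n_snp)")
    rng = np.random.default_rng(seed)
    snp_ids = [f"1_{i:04d}" for i in range(n_snp)]
    deg_ids = [f"UG{i:05d}" for i in range(n_deg)]

    # --- genetic map ---
    snp_lg = rng.integers(1, n_lg + 1, n_snp)
    snp_cm = rng.uniform(5, lg_span_cm - 5, n_snp)
    snp_map = pd.DataFrame(
        {"entity_id": snp_ids, "linkage_group": snp_lg, "position_cm": np.round(snp_cm, 2)}
    )
    anchors = {
        g: snp_map.loc[snp_map["linkage_group"] == g, "position_cm"].to_numpy()
        for g in range(1, n_lg + 1)
    }
    genetic_pairs: set[tuple[str, str]] = set()
    deg_rows = []
    for i in range(planted_pairs):
        j = int(rng.integers(0, n_snp))
        offset = float(rng.uniform(0, 0.9 * max_cm)) * rng.choice([-1, 1])
        pos = max(0.0, snp_cm[j] + offset)
        deg_rows.append((deg_ids[i], int(snp_lg[j]), round(pos, 3)))
        genetic_pairs.add((deg_ids[i], snp_ids[j]))
    spare = _place_apart(
        rng, n_deg - planted_pairs, n_lg, lg_span_cm, anchors, min_gap=1.5 * max_cm
    )
    for i, (g, pos) in enumerate(spare, start=planted_pairs):
        deg_rows.append((deg_ids[i], g, round(pos, 3)))
    deg_map = pd.DataFrame(deg_rows, columns=["entity_id", "linkage_group", "position_cm"])
    # Planted DEGs may incidentally sit near a second SNP on the same LG;
    # count every in-window pair as planted truth.
    for _, d in deg_map.iloc[:planted_pairs].iterrows():
        for sid, slg, scm in zip(snp_ids, snp_lg, snp_cm):
            if int(slg) == int(d["linkage_group"]) and abs(scm - d["position_cm"]) < max_cm:
                genetic_pairs.add((d["entity_id"], sid))

    # --- physical (ortholog) coordinates ---
    hit_len = 300
    snp_chrom = rng.integers(1, n_chrom + 1, n_snp)
    snp_start = rng.integers(5 * max_bp, chrom_span_bp - 5 * max_bp, n_snp)
    phys_anchors = {
        c: snp_start[snp_chrom == c].astype(float) for c in range(1, n_chrom + 1)
    }
    physical_pairs: set[tuple[str, str]] = set()
    deg_phys = []
    for i in range(planted_pairs):
        j = int(rng.integers(0, n_snp))
        gap = int(rng.uniform(0, 0.9 * max_bp))
        start = snp_start[j] + hit_len + gap
        deg_phys.append((deg_ids[i], int(snp_chrom[j]), int(start)))
        physical_pairs.add((deg_ids[i], snp_ids[j]))
    spare_phys = _place_apart(
        rng, n_deg - planted_pairs, n_chrom, chrom_span_bp - hit_len,
        phys_anchors, min_gap=2.0 * max_bp,
    )
    for i, (c, pos) in enumerate(spare_phys, start=planted_pairs):
        deg_phys.append((deg_ids[i], c, int(pos)))
    for qid, chrom, start in deg_phys[:planted_pairs]:
        for sid, schrom, sstart in zip(snp_ids, snp_chrom, snp_start):
            gap = max(0, max(start - (sstart + hit_len), sstart - (start + hit_len)))
            if int(schrom) == chrom and gap <= max_bp:
                physical_pairs.add((qid, sid))

    def _hits(entries):
        rows = []
        for qid, chrom, start in entries:
            rows.append(
                {
                    "qseqid": qid, "sseqid": f"Gm{chrom:02d}", "pident": 92.0,
                    "length": hit_len, "mismatch": 20, "gapopen": 1,
                    "qstart": 1, "qend": hit_len, "sstart": int(start),
                    "send": int(start + hit_len - 1),
                    "evalue": 1e-50, "bitscore": 400.0,
                }
            )
        return pd.DataFrame(rows, columns=BLAST6_COLUMNS)

    deg_hits = _hits(deg_phys)
    snp_hits = _hits(
        [(sid, int(c), int(s)) for sid, c, s in zip(snp_ids, snp_chrom, snp_start)]
    )
    return SimulatedMaps(
        deg_map=deg_map, snp_map=snp_map, deg_hits=deg_hits, snp_hits=snp_hits,
        genetic_pairs=genetic_pairs, physical_pairs=physical_pairs,
    )
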