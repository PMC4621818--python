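"""End-to-end orchestration: synthetic demo or file-driven runs.

``run_all`` executes the stages in dependency order — synthetic generation
(optional), lysimetry -> water response, phenotypes -> association ->
expression -> co-localization — writes every intermediate as TSV under the
output directory, and emits a run manifest (package version, seeds, config
echo, per-stage row counts).  Stage results are also returned in-memory as a
plain dict so library users can skip the filesystem entirely.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, association, coloc, expression, io, lysimetry, phenotypes
from . import synth, water_response
from .config import PipelineConfig

#: The four accessions profiled on the lysimeter array, with genotype-specific
#: ground truths spanning the plateau/threshold/slope space: B47 is the
#: conservative water-saver (high theta_cr, steep decline), B128 the fast
#: grower with low sensitivity to drying soil.
DEFAULT_LYSIMETER_TRUTHS = {
    "B47": dict(e_max_true=0.8e-3, theta_cr_true=0.45, slope_true=6.0e-3, wue_true=0.04),
    "B118": dict(e_max_true=1.1e-3, theta_cr_true=0.35, slope_true=4.5e-3, wue_true=0.05),
    "B128": dict(e_max_true=1.2e-3, theta_cr_true=0.28, slope_true=5.0e-3, wue_true=0.06),
    "B253": dict(e_max_true=1.0e-3, theta_cr_true=0.36, slope_true=4.8e-3, wue_true=0.05),
}


def _subseed(seed: int, label: str) -> int:
    """Stable per-stage seed below 2^31 derived from the run seed."""
    h = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_lysimetry_stage(cfg: PipelineConfig, out: Path | None) -> dict:
    """Simulate lysimeter runs for the four genotypes and fit physiology."""
    climate = synth.simulate_climate(
        days=cfg.pretreatment_days + cfg.drought_days + cfg.recovery_days,
        step_min=10, seed=_subseed(cfg.seed, "climate"),
    )
    vpd = pd.Series(
        lysimetry.compute_vpd(
            climate["air_temp_c"].to_numpy(), climate["rel_humidity_pct"].to_numpy()
        ),
        index=climate.index,
    )
    fits: dict[str, dict[str, water_response.WaterResponseFit]] = {}
    wue_rows, daily_frames = [], []
    phases = (cfg.pretreatment_days, cfg.drought_days, cfg.recovery_days)
    for genotype, params in DEFAULT_LYSIMETER_TRUTHS.items():
        fits[genotype] = {}
        for p in range(cfg.n_plants_per_genotype):
            plant_id = f"{genotype}_p{p}"
            truth = synth.LysimeterTruth(
                genotype_id=plant_id, seed=_subseed(cfg.seed, plant_id), **params
            )
            run = synth.simulate_lysimeter_run(
                truth, climate, phases=phases, noise_g=0.5,
            )
            with warnings.catch_warnings():
                # drought mornings have no drainage by design
                warnings.filterwarnings("ignore", ".*no drainage-complete marker")
                daily = lysimetry.build_daily(run.trace, cfg.lysimetry)
            daily_frames.append(daily)
            wfit = lysimetry.fit_wue(daily, phase=(0, cfg.pretreatment_days))
            wue_rows.append(
                {"genotype": genotype, "plant_id": plant_id, "wue": wfit.wue,
                 "r2": wfit.r2, "n_days": wfit.n_days}
            )
            rate = lysimetry.smooth_and_rate(run.trace, cfg.lysimetry.smooth_window_min)
            weight_by_day = lysimetry.plant_weight_series(
                daily, initial_weight_g=20.0, wue=wfit.wue
            )
            etw = lysimetry.normalize_etw(
                rate, weight_by_day, vpd, cfg.lysimetry.vpd_floor_kpa
            )
            drought_days = climate.index.normalize().unique()[
                cfg.pretreatment_days : cfg.pretreatment_days + cfg.drought_days
            ]
            points = water_response.extract_midday_points(
                etw, run.probe.data["swc"], days=drought_days
            )
            try:
                fits[genotype][plant_id] = water_response.fit_segmented(points)
            except ValueError:
                continue
    fit_table = water_response.fits_to_frame(fits)
    comparison = water_response.compare_genotypes(fit_table, alpha=cfg.compare_alpha)
    wue_table = pd.DataFrame(wue_rows)
    daily_all = pd.concat(daily_frames)
    if out:
        daily_all.to_csv(out / "daily_physiology.tsv", sep="\t")
        wue_table.to_csv(out / "wue.tsv", sep="\t", index=False)
        fit_table.to_csv(out / "water_response_fits.tsv", sep="\t", index=False)
        comparison.to_csv(out / "genotype_comparison.tsv", sep="\t", index=False)
    return {
        "daily": daily_all, "wue": wue_table, "fits": fit_table,
        "comparison": comparison,
    }


def run_panel_stages(cfg: PipelineConfig, out: Path | None) -> dict:
    """Simulate the diversity panel, correlate scores, run the GWAS."""
    n = cfg.n_snps
    truth = synth.PanelTruth(
        causal_snps={
            "Scu": [(n // 10, 1.0), (n // 4, 0.8)],
            "Wt": [(n // 2, 1.0)],
            "Stg": [(3 * n // 4, 1.0)],
        },
        h2={"Scu": 0.5, "Wt": 0.4, "Stg": 0.5},
        structure_sd=0.5,
    )
    panel = synth.simulate_panel(
        n_acc=cfg.n_accessions, n_snp=cfg.n_snps, truth=truth,
        seed=_subseed(cfg.seed, "panel"),
    )
    r_mat, p_mat = phenotypes.trait_correlations(
        panel.scores, alpha=cfg.correlation_alpha, method=cfg.correlation_method
    )
    geno_qc, qc_report = association.qc_filter(
        panel.genotypes, cfg.maf_min, cfg.missing_max
    )
    means = phenotypes.accession_means(panel.scores)
    scans = []
    for trait in ("Wt", "Scu", "Stg"):
        for year in sorted(panel.scores["year"].unique()):
            y = means[f"{trait}{year}"]
            scans.append(
                association.glm_scan(y, geno_qc, panel.q, trait_name=trait, year=year)
            )
            scans.append(
                association.mlm_scan(
                    y, geno_qc, panel.q, panel.k, trait_name=trait, year=year
                )
            )
    results = pd.concat(scans, ignore_index=True)
    significant = association.call_significant(
        results, cfg.assoc_threshold_neg_log10_p, cfg.assoc_consistency_min
    )
    if out:
        io.write_genotypes_tsv(out / "genotypes.tsv", panel.genotypes)
        io.write_matrix_tsv(out / "Q.tsv", panel.q, "accession")
        io.write_matrix_tsv(out / "K.tsv", panel.k, "accession")
        io.write_scores_tsv(out / "scores.tsv", panel.scores)
        r_mat.rename_axis("pair").to_csv(out / "trait_correlations.tsv", sep="\t")
        results.to_csv(out / "assoc_results.tsv", sep="\t", index=False)
        significant.to_csv(out / "assoc_significant.tsv", sep="\t", index=False)
    return {
        "panel": panel, "correlations": (r_mat, p_mat), "qc_report": qc_report,
        "assoc_results": results, "significant": significant,
    }


def run_expression_stage(cfg: PipelineConfig, out: Path | None) -> dict:
    """Simulate the factorial array design and call DEGs."""
    rng = np.random.default_rng(_subseed(cfg.seed, "expr-truth"))
    gene_ids = [f"UG{i:05d}" for i in range(cfg.n_genes)]
    # Per tissue: a set of DEGs shared by both genotypes (same sign) plus
    # genotype-unique sets, so the Venn bookkeeping has all three cells.
    true_degs = {("B47", ts): {} for ts in ("leaf", "root")}
    true_degs.update({("B128", ts): {} for ts in ("leaf", "root")})
    for tissue in ("leaf", "root"):
        picks = rng.choice(cfg.n_genes, size=60, replace=False)
        shared, uniq_a, uniq_b = picks[:20], picks[20:40], picks[40:]
        for i in shared:
            lfc = float(rng.choice([-3.0, -2.5, 2.5, 3.0]))
            true_degs[("B47", tissue)][gene_ids[i]] = lfc
            true_degs[("B128", tissue)][gene_ids[i]] = lfc
        for i in uniq_a:
            true_degs[("B47", tissue)][gene_ids[i]] = float(rng.choice([-2.5, 2.5]))
        for i in uniq_b:
            true_degs[("B128", tissue)][gene_ids[i]] = float(rng.choice([-2.5, 2.5]))
    truth = synth.ExpressionTruth(true_degs=true_degs)
    sim = synth.simulate_expression(
        n_genes=cfg.n_genes, truth=truth, seed=_subseed(cfg.seed, "expr")
    )
    norm = expression.quantile_normalize(sim.matrix)
    qc = expression.replicate_qc(norm, sim.annotations, flag_below=cfg.replicate_r_flag)
    de_frames = []
    for geno in ("B47", "B128"):
        for tissue in ("leaf", "root"):
            de_frames.append(
                expression.de_test(norm, sim.annotations, geno, tissue)
            )
    de_results = pd.concat(de_frames)
    degs = expression.call_degs(de_results, cfg.fc_min, cfg.fdr_max)
    venn = expression.venn_counts(degs, "B47", "B128")
    # Family fixture: 16 planted DEGs plus 36 unregulated members, mirroring
    # a water-channel family where a minority responds to drought.
    planted_ids = sorted({g for d in true_degs.values() for g in d})
    non_planted = sorted(set(gene_ids) - set(planted_ids))
    family = sorted(
        list(rng.choice(planted_ids, size=16, replace=False))
        + list(rng.choice(non_planted, size=36, replace=False))
    )
    fam_table, fam_summary = expression.family_profile(degs, family, gene_ids)
    if out:
        io.write_expression_tsv(
            out / "expression_matrix.tsv", out / "expression_samples.tsv",
            sim.matrix, sim.annotations,
        )
        qc.to_csv(out / "replicate_qc.tsv", sep="\t", index=False)
        degs.to_csv(out / "degs.tsv", sep="\t", index=False)
        fam_table.to_csv(out / "family_profile.tsv", sep="\t", index=False)
    return {
        "sim": sim, "normalized": norm, "qc": qc, "de_results": de_results,
        "degs": degs, "venn": venn, "family": (fam_table, fam_summary),
    }


def run_coloc_stage(cfg: PipelineConfig, out: Path | None,
                    snp_traits: pd.DataFrame | None = None) -> dict:
    """Simulate map/ortholog fixtures and select candidate genes."""
    maps = synth.simulate_maps(
        n_deg=100, n_snp=39, planted_pairs=7, seed=_subseed(cfg.seed, "maps"),
        max_cm=cfg.max_cm, max_bp=cfg.max_bp,
    )
    genetic = coloc.genetic_colocalize(
        maps.deg_map, maps.snp_map, cfg.max_cm, snp_traits=snp_traits
    )
    deg_best = coloc.best_ortholog(maps.deg_hits, cfg.blast_min_len, cfg.blast_max_evalue)
    snp_best = coloc.best_ortholog(maps.snp_hits, cfg.blast_min_len, cfg.blast_max_evalue)
    physical = coloc.physical_colocalize(deg_best, snp_best, cfg.max_bp,
                                         snp_traits=snp_traits)
    combined = coloc.combine_candidates(genetic, physical)
    if out:
        io.write_map_tsv(out / "deg_map.tsv", maps.deg_map)
        io.write_map_tsv(out / "snp_map.tsv", maps.snp_map)
        combined.to_csv(out / "candidate_genes.tsv", sep="\t", index=False)
    return {"maps": maps, "genetic": genetic, "physical": physical, "combined": combined}


def run_all(cfg: PipelineConfig, out_dir=None, write: bool = True) -> dict:
    """Run every enabled stage on synthetic inputs; return the result bundle."""
    out = Path(out_dir if out_dir is not None else cfg.out_dir) if write else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}
    if cfg.run_lysimetry:
        bundle["lysimetry"] = run_lysimetry_stage(cfg, out)
    if cfg.run_phenotypes or cfg.run_association:
        bundle["panel"] = run_panel_stages(cfg, out)
    if cfg.run_expression:
        bundle["expression"] = run_expression_stage(cfg, out)
    if cfg.run_coloc:
        snp_traits = None
        if "panel" in bundle and len(bundle["panel"]["significant"]):
            snp_traits = bundle["panel"]["significant"][["marker", "trait"]].rename(
                columns={"marker": "snp"}
            )
        bundle["coloc"] = run_coloc_stage(cfg, out, snp_traits=snp_traits)
    manifest = {
        "package": "drylysim",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "stages": {
            name: {k: int(len(v)) for k, v in res.items()
                   if isinstance(v, pd.DataFrame)}
            for name, res in bundle.items()
        },
    }
    bundle["manifest"] = manifest
    if out:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
    return bundle
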