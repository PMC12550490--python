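"""End-to-end orchestration on synthetic or user-supplied data.

`run_demo` builds a small synthetic world (per-species genomes with known
Ne, shared climate grids across paleo periods, a species tree with traits),
runs heterozygosity -> coalescent HMM -> niche models -> trend coding ->
PGLS -> chromosome assignment, and writes a combined report.  A single
global seed fans out to per-stage seeds by stable hashing so stages stay
reproducible independently.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import chromassign, demography, niche, smc, synthdata, trends
from .discretize import TimeDiscretization
from .pgls import ComparativeDataset, pgls_fit, tukey_from_fit


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


# study-protocol settings shared by the config defaults below
_DEFAULTS = dict(
    pattern="2+2+25*2+4+6",
    t_max=15.0,
    thin_km=4.5,
    buffer_deg=10.0,
    kfold=4,
    auc_min=0.7,
    area_threshold=0.36,
    p_max=0.01,
)


@dataclass
class PipelineConfig:
    """Stage parameters; defaults follow the study protocol settings."""

    seed: int = 0
    out_dir: str = "scratch/demo"
    n_species: int = 6
    genome_mb: float = 1.0
    n_em_iters: int = 5
    n_bootstrap: int = 0
    grid_shape: tuple[int, int] = (50, 50)
    n_occurrences: int = 150
    n_background: int = 1000
    feature_grid: tuple[str, ...] = ("L", "LQ")
    multipliers: tuple[float, ...] = (1.0, 2.0)
    pattern: str = _DEFAULTS["pattern"]
    t_max: float = _DEFAULTS["t_max"]
    thin_km: float = _DEFAULTS["thin_km"]
    buffer_deg: float = _DEFAULTS["buffer_deg"]
    kfold: int = _DEFAULTS["kfold"]
    auc_min: float = _DEFAULTS["auc_min"]
    area_threshold: float = _DEFAULTS["area_threshold"]
    p_max: float = _DEFAULTS["p_max"]
    generation_time: float = 27.0
    mu_per_gen: float = 1e-8
    # sharp, fairly rare suitability surface: niche models separate well
    niche_coefficients: dict = field(
        default_factory=lambda: {"L1": 3.0, "L2": -2.0, "const": -2.0}
    )

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**mapping)
        return cfg

    def provenance(self) -> dict:
        payload = {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self).items()}
        digest = hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()
        return {"config": payload, "config_sha256": digest}


def run_demo(seed: int = 0, config: PipelineConfig | None = None) -> dict:
    """Full synthetic end-to-end run; returns the report dictionary."""
    cfg = config or PipelineConfig(seed=seed)
    cfg.seed = seed
    os.makedirs(cfg.out_dir, exist_ok=True)
    report: dict = {"provenance": cfg.provenance()}
    report["provenance"]["seed"] = seed

    # --- demography per species -------------------------------------------
    # Each species carries a true two-epoch Ne history whose change point
    # (14k generations, ~0.7 coalescent units at the demo scale) separates
    # the MIS19 and LIG period ages, so the MIS19->LIG Ne trend code has a
    # known truth; alternating species decline or expand toward the present.
    disc = TimeDiscretization(pattern=cfg.pattern, t_max=cfg.t_max)
    species = [f"sp{i + 1}" for i in range(cfg.n_species)]
    true_ne_direction = {}
    trajectories: dict[str, demography.DemographicTrajectory] = {}
    het_rows = []
    for i, sp in enumerate(species):
        declining = i % 2 == 0  # Ne smaller toward the present
        ne_recent, ne_ancient = (6000.0, 20000.0) if declining else (20000.0, 6000.0)
        true_ne_direction[sp] = "decreasing" if declining else "increasing"
        scen = synthdata.DemographyScenario(
            epochs=[(0.0, ne_recent), (14_000.0, ne_ancient)],
            mutation_rate_per_site_per_gen=cfg.mu_per_gen,
            sequence_length_bp=int(cfg.genome_mb * 1e6),
            seed=stage_seed(seed, f"genome:{sp}"),
        )
        sim = synthdata.simulate_het_track(scen)
        fit = smc.fit_smc(sim.het_track, disc, n_em_iters=cfg.n_em_iters)
        calib = demography.calibrate(
            d=2 * cfg.mu_per_gen / cfg.generation_time * 3e7, T=3e7, alpha=12.0, L=30.0
        )
        traj = demography.scale_to_years(fit.trajectory, calib)
        traj.species = sp
        if cfg.n_bootstrap:
            boots = smc.bootstrap(
                sim.het_track, disc, n_reps=cfg.n_bootstrap,
                segment_size_bp=min(5e6, cfg.genome_mb * 1e6 / 4),
                seed=stage_seed(seed, f"boot:{sp}"), n_em_iters=max(2, cfg.n_em_iters // 2),
            )
            traj.bootstrap = [demography.scale_to_years(b, calib) for b in boots]
        trajectories[sp] = traj
        het_rows.append(
            {"species": sp, "true_ne_recent": ne_recent, "true_ne_ancient": ne_ancient,
             "true_direction": true_ne_direction[sp],
             "het_bin_fraction": sim.het_track.het_fraction(),
             "theta_hat": fit.model.theta, "loglik": fit.loglik}
        )
    het_df = pd.DataFrame(het_rows)
    het_df.to_csv(os.path.join(cfg.out_dir, "demography_summary.tsv"), sep="\t", index=False)
    report["demography"] = het_df.to_dict("records")

    # --- niche models per species -----------------------------------------
    area_rows = {}
    for i_sp, sp in enumerate(species):
        # alternate per-species climate-shift directions so trend codes vary
        sign = 1.0 if i_sp % 2 else -1.0
        period_shifts = {
            "LIG": {"L1": 0.4 * sign},
            "LGM": {"L1": -1.2},
            "MIS19": {"L1": 0.15 * sign},
        }
        nscen = synthdata.NicheScenario(
            grid_shape=cfg.grid_shape,
            n_occurrences=cfg.n_occurrences,
            true_coefficients=dict(cfg.niche_coefficients),
            per_period_climate_shift=period_shifts,
            seed=stage_seed(seed, f"niche:{sp}"),
        )
        stacks, occ, truth = synthdata.simulate_rasters_and_occurrences(nscen)
        occ_thin = niche.thin_occurrences(occ, min_distance_km=cfg.thin_km, seed=stage_seed(seed, f"thin:{sp}"))
        present = niche.crop_with_buffer(stacks["present"], occ_thin, buffer_deg=cfg.buffer_deg)
        pca, pc_present = niche.raster_pca(present)
        occ_X = np.column_stack([pc_present.layers[n][pc_present.index_of(occ_thin.lon, occ_thin.lat)] for n in pc_present.layer_names])
        bg_X = niche.sample_background(pc_present, cfg.n_background, seed=stage_seed(seed, f"bg:{sp}"))
        evals, best = niche.evaluate_and_select(
            occ_X, bg_X, feature_grid=list(cfg.feature_grid), multipliers=cfg.multipliers,
            k=cfg.kfold, seed=stage_seed(seed, f"folds:{sp}"), auc_min=cfg.auc_min,
        )
        if best is None:
            continue
        pc_periods = {"present": pc_present}
        for period in period_shifts:
            cropped = niche.crop_with_buffer(stacks[period], occ_thin, buffer_deg=cfg.buffer_deg)
            pc_periods[period] = pca.transform(cropped)
        areas = niche.project_and_area(best, pc_periods, threshold=cfg.area_threshold)
        area_rows[sp] = areas.set_index("period")["area_km2"]
    area_df = pd.DataFrame(area_rows).T
    area_df.to_csv(os.path.join(cfg.out_dir, "area_series.tsv"), sep="\t")
    report["area_series"] = area_df.to_dict()

    # --- trend coding and associations ------------------------------------
    temperature = {"MIS19": 14.5, "LIG": 15.0, "LGM": 9.0}
    ne_values = pd.DataFrame(
        {
            period: {
                sp: float(trajectories[sp].value_at(trends.PERIOD_AGES_YEARS[period]))
                for sp in area_df.index
            }
            for period in ("MIS19", "LIG", "LGM")
        }
    )
    meta = pd.DataFrame(
        {
            "habitat": ["aquatic" if i % 2 else "terrestrial" for i in range(len(area_df.index))],
            "climate": ["tropical" if i % 3 else "temperate" for i in range(len(area_df.index))],
        },
        index=area_df.index,
    )
    trend_table = trends.build_trend_table(ne_values, area_df, temperature, species_meta=meta)
    mis_lig = trend_table[trend_table["pair"] == "MIS19->LIG"].set_index("species")
    report["ne_code_accuracy_mis19_lig"] = float(
        np.mean([mis_lig.loc[sp, "ne_code"] == true_ne_direction[sp] for sp in mis_lig.index])
    )
    trend_table.to_csv(os.path.join(cfg.out_dir, "trend_table.tsv"), sep="\t", index=False)
    assoc_area = trends.association_report(trend_table, rows="ne_code", cols="area_code")
    assoc_temp = trends.association_report(trend_table, rows="ne_code", cols="temp_code", per_pair=False)
    assoc = pd.concat([assoc_area, assoc_temp], ignore_index=True)
    assoc.to_csv(os.path.join(cfg.out_dir, "associations.tsv"), sep="\t", index=False)
    report["associations"] = assoc.to_dict("records")

    # --- comparative PGLS --------------------------------------------------
    cscen = synthdata.ComparativeScenario(
        n_species=max(8, cfg.n_species), status_effect=1.0, seed=stage_seed(seed, "tree")
    )
    tree, table = synthdata.simulate_comparative(cscen)
    ds = ComparativeDataset(tree, table)
    fit_h = pgls_fit(ds, "H", ["status", "current_area_km2"])
    fit_ne = pgls_fit(ds, "mean_Ne", ["status", "mean_past_area_km2"])
    hsd = tukey_from_fit(ds, "H", "status")
    pgls_out = pd.DataFrame(
        {
            "model": ["H~status+current_area"] * len(fit_h.params) + ["meanNe~status+past_area"] * len(fit_ne.params),
            "term": list(fit_h.params.index) + list(fit_ne.params.index),
            "estimate": list(fit_h.params) + list(fit_ne.params),
            "p": list(fit_h.pvalues) + list(fit_ne.pvalues),
        }
    )
    pgls_out.to_csv(os.path.join(cfg.out_dir, "pgls_summary.tsv"), sep="\t", index=False)
    hsd.to_csv(os.path.join(cfg.out_dir, "tukey_hsd.tsv"), sep="\t", index=False)
    report["pgls"] = pgls_out.to_dict("records")
    report["tukey"] = hsd.to_dict("records")

    # --- chromosome assignment ---------------------------------------------
    scaf_lengths = {f"scaf{i + 1}": 2_000_000 for i in range(6)}
    enr = {f"chr{i + 1}": f"scaf{i + 1}" for i in range(6)}
    reads = synthdata.simulate_chromosome_reads(
        6, scaf_lengths, enr, seed=stage_seed(seed, "chromseq"), enrichment_factor=10.0
    )
    calls = chromassign.assign(reads, scaf_lengths, p_max=cfg.p_max)
    calls.to_csv(os.path.join(cfg.out_dir, "chrom_assignments.tsv"), sep="\t", index=False)
    amap = chromassign.assignment_map(calls)
    report["chromosome_assignment"] = {k: v for k, v in amap.items()}
    report["chromosome_assignment_correct"] = sum(
        1 for c, s in enr.items() if amap.get(c) == [s]
    )

    with open(os.path.join(cfg.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report


def plot_report(report: dict, trajectories=None, out_path: str | None = None):
    """Combined panel: normalized Ne trajectories, area series, summaries."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    if trajectories:
        for sp, traj in trajectories.items():
            axes[0].step(traj.times, traj.ne, where="post", label=sp)
            for rep in traj.bootstrap:
                axes[0].step(rep.times, rep.ne, where="post", alpha=0.2, color="grey")
        axes[0].set_xscale("log")
        axes[0].set_xlabel("years before present")
        axes[0].set_ylabel("Ne")
        axes[0].legend(fontsize=6)
    areas = report.get("area_series", {})
    if areas:
        df = pd.DataFrame(areas)
        for sp in df.index:
            axes[1].plot(df.columns, df.loc[sp], marker="o", label=sp)
        axes[1].set_ylabel("suitable area (km^2)")
        axes[1].legend(fontsize=6)
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=100)
    return fig
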