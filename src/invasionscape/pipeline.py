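"""End-to-end orchestration: occurrences -> geoprofile + occupancy;
genotypes -> diversity -> clustering -> connectivity -> surfaces.

Every stage is driven by a single :class:`PipelineConfig` (loadable from
JSON), runs with explicit seeds, and contributes to one JSON report. A
manifest records input hashes, parameters and the seed so a rerun with an
identical config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from . import core_io, geoprofile, occupancy, popgen_stats, geneflow_kinship
from . import resistance_surface as rs

logger = logging.getLogger("invasionscape")


@dataclass
class PipelineConfig:
    occurrences_csv: str
    genotypes_path: str | None = None
    locality_map_csv: str | None = None
    localities_csv: str | None = None
    out_dir: str = "invasionscape_out"
    seed: int | None = None
    # thinning + geoprofile
    cutoff_year: int = 2009
    dedup_radius_m: float = 200.0
    sigma_mean_km: float = 5.0
    sigma_var_km2: float = 10.0
    sigma_shape: float = 1.5
    n_burn: int = 1000
    n_sample: int = 10_000
    n_chains: int = 5
    cell_m: float = 250.0
    # occupancy
    buffer_m: float = 1000.0
    # connectivity
    kinship_fullsib_threshold: float = 0.5
    kinship_edge_threshold: float = 0.35
    d_max_m: list[float] = field(default_factory=lambda: [2000.0, 5000.0, 10_000.0])
    n_resample: int = 1000
    # diversity surface
    window_cells: int = 10
    rarefaction_n: int = 5

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("config must set an explicit seed (no wall-clock seeding)")
        for p in (self.occurrences_csv, self.genotypes_path,
                  self.locality_map_csv, self.localities_csv):
            if p is not None and not os.path.exists(p):
                raise FileNotFoundError(p)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute every configured stage in dependency order.

    Returns the report dict (also written to out_dir/report.json alongside a
    manifest). A stage failure leaves a partial manifest naming the failed
    stage.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "input_hashes": {
            p: _sha256(p)
            for p in (config.occurrences_csv, config.genotypes_path,
                      config.locality_map_csv, config.localities_csv)
            if p is not None
        },
        "stages_completed": [],
    }
    report: dict = {}
    stage = "read_occurrences"
    try:
        records = core_io.read_occurrences(config.occurrences_csv)
        manifest["stages_completed"].append(stage)

        stage = "geoprofile"
        thin = geoprofile.thin_records(
            records,
            geoprofile.ThinningConfig(config.cutoff_year, config.dedup_radius_m),
        )
        prior = geoprofile.SigmaPrior(config.sigma_mean_km, config.sigma_var_km2,
                                      config.sigma_shape)
        gp = geoprofile.run_dpm(
            thin, prior, n_burn=config.n_burn, n_sample=config.n_sample,
            n_chains=config.n_chains, cell_m=config.cell_m, seed=config.seed,
        )
        core_io.write_raster(gp.surface, os.path.join(config.out_dir, "surface.asc"))
        core_io.write_raster(gp.hit_score_grid,
                             os.path.join(config.out_dir, "hitscores.asc"))
        ci = gp.sigma_ci()
        report["geoprofile"] = {
            "n_records_thinned": len(thin),
            "k_posterior": gp.k_posterior,
            "k_mode": gp.k_mode,
            "sigma_mean_km": gp.sigma_mean(),
            "sigma_ci_km": [float(ci[0]), float(ci[1])],
            "gelman_rubin": gp.gelman_rubin_stat,
            "source_estimates": gp.source_estimates,
        }
        manifest["stages_completed"].append(stage)

        stage = "occupancy"
        series = occupancy.eoo_by_year(records, buffer_m=config.buffer_m)
        series.to_frame().to_csv(os.path.join(config.out_dir, "eoo.csv"), index=False)
        report["occupancy"] = {
            "final_eoo_km2": series.eoo_km2[-1],
            "mean_speed_radius_diff_m": float(np.nanmean(series.speed_radius_diff_m)),
            "mean_speed_increment_m": float(np.nanmean(series.speed_increment_m)),
            "default_mode": series.default_mode,
        }
        manifest["stages_completed"].append(stage)

        if config.genotypes_path is not None:
            stage = "diversity"
            G = core_io.read_genotypes(config.genotypes_path, config.locality_map_csv)
            div = popgen_stats.heterozygosity(G)
            div.to_csv(os.path.join(config.out_dir, "diversity.csv"))
            report["diversity"] = {
                "mean_ho": float(div.ho.mean()),
                "mean_he": float(div.he.mean()),
                "mean_fis": float(div.fis.mean()),
            }
            manifest["stages_completed"].append(stage)

            stage = "kinship"
            kin = geneflow_kinship.wang_relatedness(G)
            retained, removal_log = geneflow_kinship.filter_fullsibs(
                kin, G.locality_of, threshold=config.kinship_fullsib_threshold,
                seed=config.seed,
            )
            with open(os.path.join(config.out_dir, "retained.txt"), "w") as fh:
                fh.write("\n".join(retained) + "\n")
            report["kinship"] = {
                "n_individuals": G.n_individuals,
                "n_retained": len(retained),
                "n_removed": len(removal_log),
            }
            G = G.subset_individuals(retained)
            manifest["stages_completed"].append(stage)

            stage = "migration"
            M = geneflow_kinship.directional_migration(G)
            summ = geneflow_kinship.migration_summary(M)
            summ.to_csv(os.path.join(config.out_dir, "migration_summary.csv"))
            report["migration"] = {
                "mean_rate": float(np.nanmean(M.m)),
                "max_rate": float(np.nanmax(M.m)),
                "mean_R_IE": float(np.nanmean(summ.R_IE)),
            }
            manifest["stages_completed"].append(stage)

            if config.localities_csv is not None:
                stage = "ibd"
                locs = core_io.read_localities(config.localities_csv)
                present = set(G.locality_ids())
                locs = [l for l in locs if l.locality_id in present]
                freqs = popgen_stats.allele_frequencies(G)
                chord = popgen_stats.chord_distance(
                    {l.locality_id: freqs[l.locality_id] for l in locs})
                geo = core_io.euclidean_distance(locs)
                mres = popgen_stats.mantel(geo, chord, seed=config.seed)
                report["ibd"] = {"mantel_r": mres.r, "mantel_p": mres.p}
                manifest["stages_completed"].append(stage)

        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_outputs(config.out_dir, manifest, report)
        raise

    _write_outputs(config.out_dir, manifest, report)
    return report


def _write_outputs(out_dir: str, manifest: dict, report: dict) -> None:
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
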