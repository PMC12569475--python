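"""End-to-end orchestration: samples + sets + layers -> niches -> metrics
-> driver models -> diets.

The pipeline is a pure function of (input files, configuration, seed): a
rerun with the same config produces bit-identical output tables.  Each
stage logs a JSON line with its record counts, and a failing stage halts
the run with an error naming the stage.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import competition, cpue as cpue_mod, drivers as drivers_mod, mixing
from .io import DriverLayer, GridSpec, assign_to_grid, read_isotope_table
from .niche import LowSampleSizeError, estimate_kud, kud_overlap
from .synthetic import DTDF, SourceGroup

__all__ = ["RunConfig", "validate_config", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """Stage failure; carries the stage name for machine-readable handling."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage={stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    samples: str
    out_dir: str
    grid: str = "-21,24,1,30,19"          # lon0,lat0,size,nlon,nlat
    sets: str | None = None
    layers: dict = field(default_factory=dict)     # name -> csv raster path
    sources: str | None = None                     # prey source table csv
    dtdf: dict = field(default_factory=dict)       # coef_c, coef_n, sd_c, sd_n
    min_n: int = 10
    level: float = 0.95
    bandwidth: str = "plugin"
    itp_log_base: float = math.e
    grid_size_kde: int = 128
    mcmc: dict = field(default_factory=lambda: {"chains": 3, "draws": 6000, "burnin": 3000})
    candidate_models: dict = field(default_factory=dict)  # name -> term_spec list
    spearman_threshold: float = 0.8
    # when two drivers are collinear the later name here is dropped
    driver_priority: list = field(default_factory=lambda: ["OPFish", "MLD", "effort", "Chl"])
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def gridspec(self) -> GridSpec:
        return GridSpec.parse(self.grid)


def validate_config(cfg: RunConfig) -> list[str]:
    """Check every config invariant before any compute; aggregated report."""
    errors: list[str] = []
    if not Path(cfg.samples).exists():
        errors.append(f"samples path does not exist: {cfg.samples}")
    for name, p in [("sets", cfg.sets), ("sources", cfg.sources)]:
        if p is not None and not Path(p).exists():
            errors.append(f"{name} path does not exist: {p}")
    for lname, p in cfg.layers.items():
        if not Path(p).exists():
            errors.append(f"layer {lname!r} path does not exist: {p}")
    if not 0 < cfg.level < 1:
        errors.append(f"level must be in (0, 1), got {cfg.level}")
    if cfg.min_n < 3:
        errors.append("min_n must be >= 3")
    if cfg.bandwidth not in ("plugin", "ref"):
        errors.append(f"bandwidth must be plugin|ref, got {cfg.bandwidth!r}")
    if cfg.itp_log_base <= 1:
        errors.append("itp_log_base must be > 1")
    try:
        cfg.gridspec()
    except (ValueError, TypeError) as exc:
        errors.append(f"bad grid spec: {exc}")
    return errors


class _Log:
    def __init__(self, path: Path):
        self.fh = open(path, "w")

    def stage(self, name: str, **counts):
        rec = {"stage": name, "t": round(time.time(), 2), **counts}
        self.fh.write(json.dumps(rec) + "\n")
        self.fh.flush()


def _float_fmt(df: pd.DataFrame) -> pd.DataFrame:
    return df


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage and persist outputs under ``cfg.out_dir``.

    Stages: read -> grid -> KUD (region and cell) -> overlap -> CCD/ITP ->
    group tests -> CPUE surfaces -> driver models -> diet mixing models ->
    report.  Stages whose inputs are not configured (no longline sets, no
    driver layers, no prey sources) are skipped and logged as such.
    """
    problems = validate_config(cfg)
    if problems:
        raise PipelineError("validate", "; ".join(problems))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log(out / "log.jsonl")
    grid = cfg.gridspec()
    rng_seed = cfg.seed

    # ---- read + grid ----------------------------------------------------
    try:
        samples, rejects = read_isotope_table(cfg.samples)
        samples = assign_to_grid(samples, grid)
    except Exception as exc:
        raise PipelineError("read", str(exc)) from exc
    log.stage("read", n_samples=len(samples), n_rejected=len(rejects))

    # ---- region-level niches + overlap ---------------------------------
    try:
        region_rows, overlap_rows = [], []
        ests: dict[tuple[str, str], object] = {}
        for (sp, reg), grp in samples.groupby(["species", "region"], observed=True):
            pts = grp[["d13c", "d15n"]].to_numpy()
            try:
                est = estimate_kud(pts, level=cfg.level, bandwidth=cfg.bandwidth,
                                   min_n=cfg.min_n, grid_size=cfg.grid_size_kde,
                                   species=sp, group_key=reg)
            except LowSampleSizeError:
                region_rows.append({"species": sp, "region": reg, "n": len(grp),
                                    "kud_area": np.nan, "c_d13c": np.nan,
                                    "c_d15n": np.nan, "note": "low_n"})
                continue
            ests[(sp, reg)] = est
            region_rows.append({"species": sp, "region": reg, "n": est.n,
                                "kud_area": est.area, "c_d13c": est.centroid[0],
                                "c_d15n": est.centroid[1], "note": ""})
        regions = sorted({r for (_, r) in ests})
        for reg in regions:
            sps = sorted(sp for (sp, r) in ests if r == reg)
            for i, a in enumerate(sps):
                for b in sps[i + 1:]:
                    ov = kud_overlap(ests[(a, reg)], ests[(b, reg)],
                                     grid_size=cfg.grid_size_kde)
                    overlap_rows.append({"region": reg, "species_a": a, "species_b": b,
                                         "pct_a_in_b": ov.pct_a_in_b,
                                         "pct_b_in_a": ov.pct_b_in_a})
        pd.DataFrame(region_rows).to_csv(out / "niche_regions.csv", index=False)
        pd.DataFrame(overlap_rows).to_csv(out / "niche_overlap.csv", index=False)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("kud_region", str(exc)) from exc
    log.stage("kud_region", n_niches=len(ests), n_overlaps=len(overlap_rows))

    # ---- cell-level niches ----------------------------------------------
    try:
        cell_rows = []
        for (sp, cid), grp in samples.groupby(["species", "cell_id"], observed=True):
            pts = grp[["d13c", "d15n"]].to_numpy()
            row = {"species": sp, "cell_id": cid, "n": len(grp),
                   "lon": grp["lon"].mean(), "lat": grp["lat"].mean(),
                   "region": grp["region"].mode().iat[0],
                   "c_d13c": pts[:, 0].mean(), "c_d15n": pts[:, 1].mean()}
            try:
                est = estimate_kud(pts, level=cfg.level, bandwidth=cfg.bandwidth,
                                   min_n=cfg.min_n, grid_size=cfg.grid_size_kde)
                row["kud_area"] = est.area
            except (LowSampleSizeError, ValueError):
                row["kud_area"] = np.nan
            cell_rows.append(row)
        cells = pd.DataFrame(cell_rows)
        cells.to_csv(out / "niche_cells.csv", index=False)
    except Exception as exc:
        raise PipelineError("kud_cell", str(exc)) from exc
    log.stage("kud_cell", n_cells=len(cells))

    # ---- CCD -------------------------------------------------------------
    try:
        cents = cells.rename(columns={"cell_id": "key"})[
            ["key", "species", "c_d13c", "c_d15n"]]
        ccd = competition.compute_ccd(cents)
        ccd = ccd.merge(cells.rename(columns={"cell_id": "key"})[
            ["key", "species", "region", "lon", "lat", "kud_area", "n"]],
            on=["key", "species"], how="left")
        ccd.to_csv(out / "ccd_cells.csv", index=False)
        ccd_summary = competition.summarize_metric(ccd, "ccd", by="species")
        ccd_summary.to_csv(out / "ccd_summary.csv", index=False)
        tests = {}
        if ccd["species"].nunique() >= 2 and len(ccd) >= 6:
            cmp_res = competition.compare_groups(ccd["ccd"], ccd["species"])
            tests["ccd_by_species"] = {
                "test": cmp_res.omnibus_test, "statistic": cmp_res.statistic,
                "p_value": cmp_res.p_value}
    except Exception as exc:
        raise PipelineError("ccd", str(exc)) from exc
    log.stage("ccd", n_records=len(ccd))

    # ---- PERMANOVA on raw isotope values --------------------------------
    try:
        perma = None
        if samples["species"].nunique() >= 2 and samples["region"].nunique() >= 2:
            res = competition.permanova2(
                samples[["d13c", "d15n"]].to_numpy(),
                samples["species"].to_numpy(), samples["region"].to_numpy(),
                n_perm=499, seed=rng_seed)
            perma = {"pseudo_f": list(res.pseudo_f), "p_value": list(res.p_value)}
            tests["permanova_species_region"] = perma
    except Exception as exc:
        raise PipelineError("permanova", str(exc)) from exc
    log.stage("permanova", done=int(perma is not None))

    # ---- CPUE standardization -------------------------------------------
    surfaces: dict[str, DriverLayer] = {}
    if cfg.sets:
        try:
            sets = pd.read_csv(cfg.sets)
            sp_cols = [c for c in sets.columns if c.startswith("catch_")]
            for col in sp_cols:
                sp = col[len("catch_"):]
                try:
                    fit = cpue_mod.fit_nb_additive(sets, sp)
                except (cpue_mod.ZeroCatchError, ValueError):
                    continue
                layer = cpue_mod.predict_abundance(fit, grid, species=sp)
                layer.write_csv(out / f"ncpue_{sp}.csv")
                surfaces[sp] = layer
        except Exception as exc:
            raise PipelineError("cpue", str(exc)) from exc
        log.stage("cpue", n_models=len(surfaces))

    # ---- ITP -------------------------------------------------------------
    try:
        itp = cells.dropna(subset=["kud_area"]).copy()
        if surfaces:
            ncp = []
            for _, row in itp.iterrows():
                lay = surfaces.get(row["species"])
                if lay is None:
                    ncp.append(np.nan)
                    continue
                ix, iy = grid.cell_index(row["lon"], row["lat"])
                ncp.append(lay.values[iy, ix] if ix >= 0 else np.nan)
            itp["ncpue"] = ncp
            itp = itp.dropna(subset=["ncpue"])
            itp["itp"] = competition.compute_itp(itp["ncpue"], itp["kud_area"],
                                                 log_base=cfg.itp_log_base)
            itp.to_csv(out / "itp_cells.csv", index=False)
            competition.summarize_metric(itp, "itp", by="species").to_csv(
                out / "itp_summary.csv", index=False)
            if itp["species"].nunique() >= 2 and len(itp) >= 6:
                cmp_res = competition.compare_groups(itp["itp"], itp["species"])
                tests["itp_by_species"] = {
                    "test": cmp_res.omnibus_test, "statistic": cmp_res.statistic,
                    "p_value": cmp_res.p_value}
    except Exception as exc:
        raise PipelineError("itp", str(exc)) from exc
    log.stage("itp", n_records=0 if not surfaces else len(itp))

    with open(out / "group_tests.json", "w") as fh:
        json.dump(tests, fh, indent=2)

    # ---- driver models ---------------------------------------------------
    if cfg.layers:
        try:
            layers = {name: DriverLayer.read_csv(p, grid, name=name)
                      for name, p in cfg.layers.items()}
            retained, corr, dropped = drivers_mod.spearman_screen(
                layers, threshold=cfg.spearman_threshold,
                priority=cfg.driver_priority)
            corr.to_csv(out / "driver_correlations.csv")
            records = ccd.dropna(subset=["ccd"]).copy()
            ix, iy = grid.cell_index(records["lon"].to_numpy(),
                                     records["lat"].to_numpy())
            for name, lay in retained.items():
                records[name] = lay.values[iy, ix]
            for sp, lay in surfaces.items():
                records[f"ncpue_{sp}"] = lay.values[iy, ix]
            if surfaces:
                own = [surfaces[r["species"]].values[iy[i], ix[i]]
                       if r["species"] in surfaces else np.nan
                       for i, (_, r) in enumerate(records.iterrows())]
                records["ncpue"] = own
            records = records.dropna()
            if cfg.candidate_models and len(records) >= 30:
                fits, names = [], []
                for name, term_spec in cfg.candidate_models.items():
                    spec = [tuple(t) for t in term_spec]
                    fits.append(drivers_mod.fit_gamma_additive(records, "ccd", spec))
                    names.append(name)
                if len(fits) >= 2:
                    best, ranking = drivers_mod.select_model(fits, names)
                    ranking.table.to_csv(out / "ccd_model_ranking.csv", index=False)
                    for t in best.terms:
                        drivers_mod.partial_effects(best, t.label).to_csv(
                            out / f"ccd_effect_{t.label.replace('(', '_').replace(')', '').replace(',', '_')}.csv",
                            index=False)
        except Exception as exc:
            raise PipelineError("drivers", str(exc)) from exc
        log.stage("drivers", n_layers=len(cfg.layers), n_dropped=len(dropped))

    # ---- diet mixing models ---------------------------------------------
    if cfg.sources:
        try:
            src_df = pd.read_csv(cfg.sources)
            diet_rows = []
            mc = cfg.mcmc
            for (sp, reg), grp in samples.groupby(["species", "region"], observed=True):
                if len(grp) < cfg.min_n:
                    continue
                sub = src_df[src_df["region"] == reg] if "region" in src_df.columns else src_df
                if len(sub) < 2:
                    continue
                sources = [SourceGroup(r["name"], r["mu_c"], r["mu_n"],
                                       r["sd_c"], r["sd_n"]) for _, r in sub.iterrows()]
                if cfg.dtdf.get("coef_c") is not None:
                    dtdf = mixing.estimate_dtdf(
                        sources, tuple(cfg.dtdf["coef_c"]), tuple(cfg.dtdf["coef_n"]),
                        sd_c=cfg.dtdf.get("sd_c", 0.3), sd_n=cfg.dtdf.get("sd_n", 0.5))
                else:
                    dtdf = DTDF.constant(len(sources))
                res = mixing.bsimm_fit(grp, sources, dtdf,
                                       chains=mc.get("chains", 3),
                                       draws=mc.get("draws", 6000),
                                       burnin=mc.get("burnin", 3000),
                                       seed=rng_seed)
                s = res.summary()
                s.insert(0, "region", reg)
                s.insert(0, "species", sp)
                s["converged"] = res.converged
                diet_rows.append(s)
            if diet_rows:
                pd.concat(diet_rows, ignore_index=True).to_csv(
                    out / "diet_posteriors.csv", index=False)
        except Exception as exc:
            raise PipelineError("mixing", str(exc)) from exc
        log.stage("mixing", n_models=len(diet_rows))

    log.stage("done")
    log.fh.close()
    return out
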