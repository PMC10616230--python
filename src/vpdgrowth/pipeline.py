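"""End-to-end orchestration: synthetic generation (optional), climate
derivation, ring processing, per-site growth models, driver forest,
species detrending and trend statistics — with a manifest recording
seeds, stage timings and attrition counts at every filter."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import climate as clim
from . import drivers as drv
from . import rings as rg
from . import synthgen as sg
from . import trends as tr
from .growth_model import GrowthModelSpec, classify_response, fit_growth_gamm

__all__ = ["PipelineConfig", "run_pipeline", "summarize_run", "load_config"]


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    seed: int = 0
    synthetic: bool = True
    weather_csv: str | None = None
    rings_path: str | None = None
    sites_csv: str | None = None
    alpha_level: float = 0.05
    juvenile_exclude: int = 10
    min_retained_years: int = 25
    min_trees_per_site: int = 2
    basis_dim: int = 8
    smoothness_selection: str = "REML"
    rf_n_trees: int = 500
    n_boot: int = 1000
    summer_months: tuple = (6, 7, 8)
    smi_critical_mm: float = 300.0
    smi_capacity_mm: float = 400.0
    sim: dict = field(default_factory=dict)

    def child_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage in order, persisting intermediates and a manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "counts": {},
                      "config_hash": hashlib.sha256(
                          json.dumps(asdict(config), sort_keys=True, default=str).encode()
                      ).hexdigest()}

    def stage(name):
        manifest["stages"][name] = {"t0": time.time()}

    def done(name, **counts):
        st = manifest["stages"][name]
        st["seconds"] = round(time.time() - st.pop("t0"), 3)
        st.update(counts)

    try:
        # --- inputs -------------------------------------------------------
        stage("inputs")
        if config.synthetic:
            sim_cfg = sg.SimulationConfig(**{"seed": config.child_seed("sim"), **config.sim})
            weather = {}
            yrs = np.arange(sim_cfg.year_start - sim_cfg.max_age_offset - 2,
                            sim_cfg.year_end + 1)
            for s in range(sim_cfg.n_sites):
                sp = sim_cfg.site_params(s)
                weather[f"S{s:03d}"] = sg.simulate_daily_weather(
                    sp, yrs, seed=config.child_seed(f"weather{s}"))
            site_meta = pd.DataFrame([
                {"site_id": f"S{s:03d}", "lat": sim_cfg.site_params(s).lat,
                 "lon": sim_cfg.site_params(s).lon, "elev": sim_cfg.site_params(s).elev}
                for s in range(sim_cfg.n_sites)
            ])
            # derive climate first; ring growth is driven by derived summer VPD
            clim_tables = {}
            for sid, w in weather.items():
                lat = float(site_meta.set_index("site_id").loc[sid, "lat"])
                daily = clim.derive_daily_climate(w, lat)
                clim_tables[sid] = clim.summarize_site_climate(
                    daily, sid, lat,
                    float(site_meta.set_index("site_id").loc[sid, "lon"]))
            series, truth = sg.simulate_ring_series(
                sim_cfg,
                {sid: t.rename(columns={}) for sid, t in clim_tables.items()},
                seed=config.child_seed("rings"))
            paths = sg.write_fixture_bundle(series, weather, truth, out / "fixtures")
            series = rg.read_rwl(paths["rwl"])  # round-trip through the reader
            meta_by_tree = {t["tree_id"]: t for t in truth["trees"]}
            for rs in series:
                m = meta_by_tree[rs.tree_id]
                rs.site_id, rs.species = m["site_id"], m["species"]
        else:
            if not (config.weather_csv and config.rings_path and config.sites_csv):
                raise FileNotFoundError("non-synthetic mode needs weather_csv, rings_path, sites_csv")
            site_meta = pd.read_csv(config.sites_csv)
            wdf = pd.read_csv(config.weather_csv)
            weather = {sid: g.drop(columns="site_id") for sid, g in wdf.groupby("site_id")}
            p = Path(config.rings_path)
            series = rg.read_long_csv(p) if p.suffix == ".csv" else rg.read_rwl(p)
            meta_idx = site_meta.set_index("site_id")
            clim_tables = {}
            for sid, w in weather.items():
                lat = float(meta_idx.loc[sid, "lat"])
                daily = clim.derive_daily_climate(w, lat)
                clim_tables[sid] = clim.summarize_site_climate(
                    daily, sid, lat, float(meta_idx.loc[sid, "lon"]))
            truth = None
        done("inputs", n_series=len(series), n_sites=len(weather))

        # --- climate table -----------------------------------------------
        stage("climate")
        climate_df = pd.concat(clim_tables.values(), ignore_index=True)
        climate_df.to_csv(out / "site_climate.csv", index=False)
        done("climate", n_site_years=len(climate_df))

        # --- rings -> BAI with filters -----------------------------------
        stage("rings")
        bai_all = [rg.widths_to_bai(rs) for rs in series]
        filtered = [rg.apply_juvenile_filter(b, config.juvenile_exclude,
                                             config.min_retained_years) for b in bai_all]
        kept = [b for b in filtered if not b.excluded]
        site_sum = rg.site_summary(kept)
        site_sum.to_csv(out / "site_summary.csv", index=False)
        pd.concat([b.to_frame() for b in kept], ignore_index=True).to_csv(
            out / "bai.csv", index=False)
        done("rings", n_trees_in=len(bai_all), n_trees_kept=len(kept),
             n_excluded=len(bai_all) - len(kept))

        # --- growth models ------------------------------------------------
        stage("fit")
        table = _model_table(kept, climate_df)
        spec = GrowthModelSpec(basis_dim=config.basis_dim,
                               smoothness_selection=config.smoothness_selection,
                               alpha_level=config.alpha_level)
        fits, fit_rows = [], []
        for (sid, spp), grp in table.groupby(["site_id", "species"]):
            if grp["tree_id"].nunique() < config.min_trees_per_site:
                continue
            fit = fit_growth_gamm(grp, spec, site_id=sid, species=spp)
            fits.append(fit)
            resp = classify_response(fit, config.alpha_level)
            fit_rows.append({
                "site_id": sid, "species": spp, "converged": fit.converged,
                "reason": fit.reason,
                "alpha_hat": fit.alpha_hat, "beta1_hat": fit.beta1_hat,
                "beta2_hat": fit.beta2_hat, "phi_hat": fit.phi_hat,
                "sigma_tree_hat": fit.sigma_tree_hat, "sigma_eps_hat": fit.sigma_eps_hat,
                "lambda_hat": fit.lambda_hat,
                "t_beta1": fit.t_beta1, "p_beta1": fit.p_beta1,
                "t_beta2": fit.t_beta2, "p_beta2": fit.p_beta2,
                "r2_fluctuations": fit.r2_fluctuations,
                "class_vpd_t": resp.class_vpd_t, "class_vpd_t1": resp.class_vpd_t1,
            })
        fits_df = pd.DataFrame(fit_rows)
        fits_df.to_csv(out / "fits.csv", index=False)
        n_conv = int(fits_df["converged"].sum()) if len(fits_df) else 0
        sig_t = int((fits_df.get("class_vpd_t", pd.Series(dtype=str))
                     .isin(["negative", "positive"])).sum()) if len(fits_df) else 0
        sig_t1 = int((fits_df.get("class_vpd_t1", pd.Series(dtype=str))
                      .isin(["negative", "positive"])).sum()) if len(fits_df) else 0
        done("fit", attempted=len(fits), convergent=n_conv,
             significant_vpd_t=sig_t, significant_vpd_t1=sig_t1)
        manifest["counts"] = {
            "attempted": len(fits), "convergent": n_conv,
            "significant_vpd_t": sig_t, "significant_vpd_t1": sig_t1,
            "sign_breakdown": {
                c: fits_df[c].value_counts().to_dict() if len(fits_df) else {}
                for c in ("class_vpd_t", "class_vpd_t1")
            },
        }

        # --- drivers ------------------------------------------------------
        stage("drivers")
        climatol = (climate_df.groupby("site_id")
                    .agg(mat=("mat", "first"), map=("map", "first"),
                         summer_smi=("mean_summer_smi", "first")).reset_index())
        climatol = climatol.merge(site_meta[["site_id", "elev"]].rename(
            columns={"elev": "elevation"}), on="site_id", how="left")
        sens = drv.assemble_sensitivity_table(fits, site_sum, climatol,
                                              alpha_level=config.alpha_level)
        sens.to_csv(out / "sensitivity_table.csv", index=False)
        if len(sens) >= 5 and sens["t_value"].nunique() > 1:
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                forest = drv.fit_forest(sens, n_trees=config.rf_n_trees,
                                        seed=config.child_seed("rf"))
                report = drv.importance_report(forest, seed=config.child_seed("perm"))
            report.to_csv(out / "driver_importance.csv", index=False)
            done("drivers", n_rows=len(sens), forest="fitted")
        else:
            done("drivers", n_rows=len(sens), forest="skipped (too few significant rows)")

        # --- trends -------------------------------------------------------
        stage("trends")
        gc_frames, trend_rows = [], []
        for spp, grp in table.groupby("species"):
            dfit = tr.fit_species_detrend(grp, spec, species=spp)
            if not dfit.converged:
                trend_rows.append({"species": spp, "status": "detrend nonconvergent"})
                continue
            gc = tr.growth_change(dfit, grp, alpha=config.alpha_level)
            gc_frames.append(gc)
            vpd_sp = (table[table["species"] == spp]
                      .groupby("year")["vpd_t1"].mean().reset_index())
            merged = gc.merge(vpd_sp, on="year")
            row = {"species": spp, "status": "ok"}
            if len(merged) >= 15:
                corr = tr.boot_correlation(merged["vpd_t1"].to_numpy(),
                                           merged["gc_mean"].to_numpy(),
                                           n_boot=config.n_boot,
                                           seed=config.child_seed(f"boot{spp}"))
                row.update(r=corr.r, r_ci_low=corr.ci_low, r_ci_high=corr.ci_high,
                           trend_slope=corr.ols_slope)
            if len(gc) >= 10:
                tt = tr.trend_test(gc["gc_mean"].to_numpy(), gc["year"].to_numpy())
                row.update(gc_trend_slope=tt.slope, gc_trend_p=tt.p_adjusted,
                           gc_trend_n_eff=tt.n_eff)
                vt = tr.trend_test(vpd_sp["vpd_t1"].to_numpy(), vpd_sp["year"].to_numpy())
                row.update(vpd_trend_slope=vt.slope, vpd_trend_p=vt.p_adjusted)
            trend_rows.append(row)
        if gc_frames:
            pd.concat(gc_frames, ignore_index=True).to_csv(out / "growth_change.csv",
                                                           index=False)
        with open(out / "trends.json", "w") as fh:
            json.dump(trend_rows, fh, indent=1, default=float)
        done("trends", n_species=len(trend_rows))
    except Exception as exc:
        manifest["failed_stage"] = next(
            (k for k, v in manifest["stages"].items() if "t0" in v), "unknown")
        manifest["error"] = repr(exc)
        _write_manifest(manifest, out)
        raise

    manifest["complete"] = True
    _write_manifest(manifest, out)
    return out


def _write_manifest(manifest: dict, out: Path) -> None:
    body = json.dumps(manifest, indent=1, sort_keys=True, default=str)
    manifest_hash = hashlib.sha256(body.encode()).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        fh.write(body)
    with open(out / "manifest.hash", "w") as fh:
        fh.write(manifest_hash + "\n")


def _model_table(bai_list, climate_df: pd.DataFrame) -> pd.DataFrame:
    """Merge filtered BAI series with site-year climate into the fitting table."""
    clim_idx = climate_df.set_index(["site_id", "year"])
    rows = []
    for bs in bai_list:
        for yr, bai, ba_prev, age in zip(bs.years, bs.bai, bs.ba_prev, bs.age):
            try:
                v_t = clim_idx.loc[(bs.site_id, yr), "vpd_summer"]
                v_t1 = clim_idx.loc[(bs.site_id, yr - 1), "vpd_summer"]
                smi_t = clim_idx.loc[(bs.site_id, yr), "smi_summer"]
            except KeyError:
                continue
            if ba_prev <= 0:
                continue
            rows.append({
                "tree_id": bs.tree_id, "site_id": bs.site_id, "species": bs.species,
                "year": int(yr), "log_bai": float(np.log(bai)),
                "log_ba_prev": float(np.log(ba_prev)), "age": int(age),
                "vpd_t": float(v_t), "vpd_t1": float(v_t1), "smi_t": float(smi_t),
            })
    return pd.DataFrame(rows)


def summarize_run(run_dir) -> dict:
    """Machine-readable report of a completed (or partial) run."""
    run = Path(run_dir)
    report: dict = {"run_dir": str(run)}
    mpath = run / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"no manifest in {run}")
    manifest = json.loads(mpath.read_text())
    report["complete"] = bool(manifest.get("complete", False))
    if not report["complete"]:
        report["failed_stage"] = manifest.get("failed_stage")
    report["counts"] = manifest.get("counts", {})
    fits_path = run / "fits.csv"
    if fits_path.exists():
        fits = pd.read_csv(fits_path)
        n = len(fits)
        report["n_models"] = n
        report["convergence_rate"] = float(fits["converged"].mean()) if n else 0.0
        conv = fits[fits["converged"] == True]  # noqa: E712
        for c in ("class_vpd_t", "class_vpd_t1"):
            if len(conv):
                props = conv[c].value_counts(normalize=True).to_dict()
            else:
                props = {}
            report[f"proportions_{c}"] = props
    else:
        report["n_models"] = 0
    for name in ("driver_importance", "growth_change"):
        p = run / f"{name}.csv"
        if p.exists():
            report[name] = pd.read_csv(p).to_dict(orient="records")
    tpath = run / "trends.json"
    if tpath.exists():
        report["trends"] = json.loads(tpath.read_text())
    text = [f"run: {run}", f"complete: {report['complete']}"]
    if report.get("counts"):
        text.append(f"counts: {report['counts']}")
    if "convergence_rate" in report:
        text.append(f"convergence rate: {report['convergence_rate']:.2f}")
    report["text"] = "\n".join(text)
    return report
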