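"""End-to-end pipeline: simulate → SDM → CMR → transects → structure → associate.

A single declarative config drives every stage; each stage draws from its
own seeded random stream (derived from the master seed by stage name) so a
stage can be rerun in isolation, and every artifact lands in the run
directory with a checksummed manifest. Rerunning an identical config
reproduces every deterministic output byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import associations, cmr, io, landscape, sdm, structure, transects
from .errors import OncaError

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Declarative settings for a full pipeline run."""

    seed: int = 0
    # synthetic landscape
    rows: int = 64
    cols: int = 64
    cell_km: float = 0.5
    n_sightings: int = 302
    bias: bool = True
    # SDM (convergence threshold 1e-5, 5000-iteration cap, 99 null reps,
    # 75/25 split are the classical settings)
    reg_multiplier: float = 1.0
    tol: float = 1e-5
    max_iter: int = 5000
    null_reps: int = 99
    train_frac: float = 0.75
    bootstrap_reps: int = 10
    # CMR
    cmr_sites: int = 2
    stations_side: int = 4
    occasions: int = 10
    buffers: tuple[str, ...] = ("half-mmdm", "mmdm")
    # transects
    transect_sites: int = 30
    km_per_site: float = 97.0
    effort_threshold: float = 0.9
    traits_path: str | None = None
    # association / overlay
    rf_trees: int = 500
    hfi_cut: float = 15.0
    rough_cut: float = 12.0

    def stage_seed(self, stage: str) -> int:
        """Independent stream per stage: crc32(stage) xor master seed, < 2^31."""
        return (zlib.crc32(stage.encode()) ^ (self.seed & 0x7FFFFFFF)) & 0x7FFFFFFF

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "buffers" in data:
            data["buffers"] = tuple(data["buffers"])
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineAbort(OncaError):
    """A stage failed; carries the stage name and partial-run manifest."""

    def __init__(self, stage: str, cause: Exception, manifest: dict):
        self.stage, self.cause, self.manifest = stage, cause, manifest
        super().__init__(f"pipeline aborted in stage {stage!r}: {cause}")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every stage, writing artifacts, metrics and a manifest.

    Returns the metrics dict; raises :class:`PipelineAbort` naming the
    failed stage, after writing the partial-run manifest.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s [%(name)s] %(message)s"))
    root = logging.getLogger("onca")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    metrics: dict = {"config_hash": config.config_hash(), "seed": config.seed}
    artifacts: list[Path] = []
    state: dict = {}
    stages = [
        ("simulate", _stage_simulate),
        ("sdm", _stage_sdm),
        ("cmr", _stage_cmr),
        ("transects", _stage_transects),
        ("structure", _stage_structure),
        ("associate", _stage_associate),
    ]
    try:
        for name, fn in stages:
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                fn(config, out, state, metrics, artifacts)
            except Exception as exc:
                _write_manifest(config, out, artifacts, complete=False,
                                failed_stage=name)
                raise PipelineAbort(name, exc, {"failed_stage": name}) from exc
            log.info("stage %s: done in %.1fs", name, time.time() - t0)
        with open(out / "metrics.json", "w") as fh:
            json.dump(metrics, fh, indent=2, sort_keys=True, default=float)
        artifacts.append(out / "metrics.json")
        _write_manifest(config, out, artifacts, complete=True)
    finally:
        root.removeHandler(handler)
        handler.close()
    return metrics


def _write_manifest(config, out: Path, artifacts: list[Path], complete: bool,
                    failed_stage: str | None = None) -> None:
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "complete": complete,
        "failed_stage": failed_stage,
        "outputs": {p.name: _sha256(p) for p in artifacts if p.exists()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def _stage_simulate(cfg, out, state, metrics, artifacts):
    stack = landscape.generate_layers(cfg.stage_seed("simulate"),
                                      cfg.rows, cfg.cols, cfg.cell_km)
    truth = landscape.default_truth(stack)
    sightings = landscape.generate_sightings(
        stack, truth, cfg.n_sightings, bias=cfg.bias,
        seed=cfg.stage_seed("sightings"))
    state.update(stack=stack, truth=truth, sightings=sightings)
    stack_dir = io.save_stack(stack, out / "layers")
    sightings.to_csv(out / "sightings.csv", index=False)
    with open(out / "truth.yml", "w") as fh:
        yaml.safe_dump({"weights": truth.weights,
                        "n_population": truth.n_population,
                        "sigma_km": truth.sigma_km, "g0": truth.g0,
                        "het_sd": truth.het_sd}, fh)
    artifacts += [out / "sightings.csv", out / "truth.yml",
                  *sorted(stack_dir.iterdir())]


def _stage_sdm(cfg, out, state, metrics, artifacts):
    stack, truth = state["stack"], state["truth"]
    feats = sdm.build_features(stack)
    flat = state["sightings"]["row"] * stack.cols + state["sightings"]["col"]
    row_of = {c: i for i, c in enumerate(feats.cell_index)}
    pres = np.array([row_of[c] for c in flat])
    bg = feats.sampling_rows
    model, auc = sdm.fit_and_score(
        feats, pres, bg, seed=cfg.stage_seed("sdm"),
        train_frac=cfg.train_frac, reg_multiplier=cfg.reg_multiplier,
        max_iter=cfg.max_iter, tol=cfg.tol)
    null = sdm.null_model_test(
        feats, auc, pres.size, bg, seed=cfg.stage_seed("null"),
        n_reps=cfg.null_reps, reg_multiplier=cfg.reg_multiplier,
        max_iter=cfg.max_iter, tol=cfg.tol)
    suit = sdm.project(model, stack, features=feats)
    state.update(features=feats, model=model, suitability=suit)
    io.write_ascii_grid(out / "suitability.asc", suit, cfg.cell_km)
    pd.DataFrame({"replicate": np.arange(1, null.null_aucs.size + 1),
                  "auc": null.null_aucs}).to_csv(out / "null_aucs.csv",
                                                 index=False)
    metrics["sdm"] = {
        "auc": auc, "null_threshold": null.threshold,
        "significant": null.significant, "p_value": null.p_value,
        "converged": model.converged, "n_iter": model.n_iter,
        "entropy": model.entropy,
        "truth_spearman": float(associations.correlate(
            suit[stack.validity], truth.suitability[stack.validity],
            method="spearman").r),
    }
    artifacts += [out / "suitability.asc", out / "null_aucs.csv"]


def _stage_cmr(cfg, out, state, metrics, artifacts):
    truth = state["truth"]
    rows_table = []
    site_densities = {}
    for k in range(cfg.cmr_sites):
        stations = landscape.station_grid(cfg.stations_side, spacing_km=2.5,
                                          seed=cfg.stage_seed(f"stations{k}"))
        det = landscape.simulate_cmr(truth, stations, cfg.occasions,
                                     seed=cfg.stage_seed(f"cmr{k}"))
        det.to_csv(out / f"detections_site{k}.csv", index=False)
        artifacts.append(out / f"detections_site{k}.csv")
        hist = cmr.build_encounter_history(det, 1, stations)
        est_m0 = cmr.estimate_m0(hist)
        est_mh = cmr.estimate_mh_jackknife(hist)
        best = (est_mh if not np.isfinite(est_m0.n_hat)
                or est_mh.n_hat >= est_m0.n_hat else est_m0)
        dens = cmr.density_from_detections(det, best, stations,
                                           buffers=tuple(cfg.buffers))
        site_densities[f"site{k}"] = {d.buffer_kind: d.density_1dp
                                      for d in dens}
        for d in dens:
            rows_table.append({
                "site": f"site{k}", "n_identified": hist.m_t1,
                "estimator": best.estimator, "n_hat": best.n_hat,
                "se": best.se, "mmdm_km": d.mmdm_km, "buffer": d.buffer_kind,
                "area_km2": d.area_km2, "density_per_100km2": d.density_1dp,
                "interval_low": d.interval[0], "interval_high": d.interval[1],
            })
        curve = cmr.accumulation_curve(det)
        curve.to_csv(out / f"accumulation_site{k}.csv", index=False)
        artifacts.append(out / f"accumulation_site{k}.csv")
    table = pd.DataFrame(rows_table)
    table.to_csv(out / "density_table.csv", index=False)
    artifacts.append(out / "density_table.csv")
    metrics["cmr"] = site_densities
    state["density_table"] = table


def _stage_transects(cfg, out, state, metrics, artifacts):
    stack, truth = state["stack"], state["truth"]
    if cfg.traits_path is not None:
        traits = pd.read_csv(cfg.traits_path)   # may raise -> abort names stage
    else:
        traits = truth.species[["species", "group", "gregarious", "mass_kg"]]
    contacts, site_table = landscape.simulate_transects(
        stack, truth, sites=cfg.transect_sites, km_per_site=cfg.km_per_site,
        seed=cfg.stage_seed("transects"))
    contacts.to_csv(out / "transect_contacts.csv", index=False)
    site_table.to_csv(out / "transect_sites.csv", index=False)
    surveys = transects.surveys_from_tables(contacts, site_table)
    table = transects.ki_table(surveys, traits)
    table.to_csv(out / "ki_biomass.csv", index=False)
    grid = np.arange(10.0, cfg.km_per_site + 1e-9, 10.0)
    curves = []
    for sp in ("Dasyprocta_leporina", "Crax_alector"):
        if sp not in set(traits["species"]):
            continue
        ec = transects.effort_sufficiency(surveys, sp, traits, grid,
                                          threshold=cfg.effort_threshold)
        c = ec.curve.copy()
        c["species"] = sp
        curves.append(c)
        metrics.setdefault("effort", {})[sp] = ec.sufficient_km
    if curves:
        pd.concat(curves, ignore_index=True).to_csv(out / "effort_curve.csv",
                                                    index=False)
        artifacts.append(out / "effort_curve.csv")
    state.update(ki_table=table, traits=traits, surveys=surveys)
    artifacts += [out / "transect_contacts.csv", out / "transect_sites.csv",
                  out / "ki_biomass.csv"]


def _stage_structure(cfg, out, state, metrics, artifacts):
    stack = state["stack"]
    rough = structure.focal_roughness(stack.continuous["dem"])
    io.write_ascii_grid(out / "roughness.asc", rough, cfg.cell_km)
    artifacts.append(out / "roughness.asc")
    table = state["ki_table"]
    sites = {}
    half = 1.0  # 1-km half-side summary window per transect site
    site_table = pd.read_csv(out / "transect_sites.csv")
    for _, r in site_table.iterrows():
        x, y = stack.cell_xy(np.array([r["row"]]), np.array([r["col"]]))
        sites[r["site"]] = structure.square_site_polygon(x[0], y[0], half)
    struct = structure.site_structure_table(
        sites, stack, rasters={"roughness": rough,
                               "suitability": state["suitability"]})
    merged = table.merge(struct, on="site")
    merged.to_csv(out / "site_structure.csv", index=False)
    artifacts.append(out / "site_structure.csv")
    state["merged"] = merged


def _stage_associate(cfg, out, state, metrics, artifacts):
    merged = state["merged"]
    results = [
        associations.correlate(merged["ki_mammal_total"], merged["hfi"],
                               label="ki_mammal_total~hfi"),
        associations.correlate(merged["ki_bird_total"], merged["hfi"],
                               label="ki_bird_total~hfi"),
        associations.correlate(merged["biomass_bird_total"], merged["hfi"],
                               label="biomass_bird_total~hfi"),
        associations.correlate(merged["mean_roughness"], merged["hfi"],
                               label="roughness~hfi"),
    ]
    predictors = associations.encode_predictors(
        merged[["mean_roughness", "mean_agb", "mean_hfi", "modal_geology"]])
    results.append(associations.rf_association(
        merged["suitability_y"] if "suitability_y" in merged else
        merged["suitability"], predictors,
        seed=cfg.stage_seed("rf"), trees=cfg.rf_trees,
        label="suitability~structure"))
    table = associations.association_table(results)
    table.to_csv(out / "associations.csv", index=False)
    artifacts.append(out / "associations.csv")
    stack = state["stack"]
    rough = structure.focal_roughness(stack.continuous["dem"])
    mask, frac = associations.threshold_overlay(
        state["suitability"], stack.continuous["footprint"], rough,
        hfi_cut=cfg.hfi_cut, rough_cut=cfg.rough_cut, validity=stack.validity)
    io.write_ascii_grid(out / "priority_mask.asc", mask.astype(float),
                        cfg.cell_km)
    artifacts.append(out / "priority_mask.asc")
    metrics["associations"] = {r.variables: {"r": r.r, "p": r.p_uncorrected}
                               for r in results}
    metrics["priority_fraction"] = frac


def write_report(outdir) -> Path:
    """Condense a run directory's metrics into a small markdown report."""
    out = Path(outdir)
    with open(out / "metrics.json") as fh:
        metrics = json.load(fh)
    lines = ["# Pipeline report", "",
             f"config hash: `{metrics.get('config_hash')}`",
             f"seed: {metrics.get('seed')}", ""]
    sdm_m = metrics.get("sdm", {})
    if sdm_m:
        lines += ["## SDM",
                  f"- test AUC: {sdm_m['auc']:.3f} "
                  f"(null 95th: {sdm_m['null_threshold']:.3f}, "
                  f"significant: {sdm_m['significant']}, p = {sdm_m['p_value']:.3f})",
                  ""]
    if "cmr" in metrics:
        lines.append("## Jaguar density (animals / 100 km²)")
        for site, dens in metrics["cmr"].items():
            parts = ", ".join(f"{k}: {v}" for k, v in dens.items())
            lines.append(f"- {site}: {parts}")
        lines.append("")
    if "associations" in metrics:
        lines.append("## Associations")
        for k, v in metrics["associations"].items():
            lines.append(f"- {k}: r = {v['r']:.2f} (p = {v['p']:.3g})")
    path = out / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
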