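"""Pipeline orchestration: simulate -> describe -> prep -> fit -> predict ->
compare, driven by one YAML config, with a JSON run manifest recording
seeds, per-stage outputs and file hashes for reproducibility audits."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from geoprev import core_io, covariate_prep, descriptives, prediction, synthetic
from geoprev import spatial_model as sm

log = logging.getLogger("geoprev")

STAGES = ["simulate", "describe", "prep", "fit", "predict", "compare"]

POOLED_LABEL = "pooled"


@dataclass
class RunConfig:
    """Validated pipeline settings (see ``from_yaml`` for the file layout)."""

    out_dir: Path
    seed: int = 0
    counts_per_wave: list[int] = dc_field(
        default_factory=lambda: list(synthetic.DEFAULT_COUNTS_PER_WAVE)
    )
    grid: synthetic.GridSpec = dc_field(default_factory=synthetic.GridSpec)
    alpha_true: float = -0.55
    beta_true: list[float] = dc_field(default_factory=lambda: [-0.39, 0.09])
    field_sigma: float = 0.5
    field_range_km: float | None = None
    smoothness_range: float = 1.0
    children_per_cluster: tuple[int, int] = (5, 25)
    covariates: list[str] | None = None
    collinearity_threshold: float = 0.8
    priors: sm.PriorSpec = dc_field(default_factory=sm.PriorSpec)
    chains: sm.ChainConfig = dc_field(default_factory=sm.ChainConfig)
    include_field: bool = True
    waves_to_fit: list[str] = dc_field(default_factory=lambda: [POOLED_LABEL])
    predict_draws: int = 200

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.seed < 0:
            raise ValueError("seed must be a non-negative integer")

    @classmethod
    def from_yaml(cls, path, overrides: dict | None = None) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if overrides:
            doc.update(overrides)
        kwargs: dict = {}
        sim = doc.pop("simulate", {})
        if "grid" in sim:
            kwargs["grid"] = synthetic.GridSpec(**sim["grid"])
        for key in (
            "counts_per_wave", "alpha_true", "beta_true", "field_sigma",
            "field_range_km", "smoothness_range",
        ):
            if key in sim:
                kwargs[key] = sim[key]
        if "children_per_cluster" in sim:
            kwargs["children_per_cluster"] = tuple(sim["children_per_cluster"])
        if "priors" in doc:
            kwargs["priors"] = sm.PriorSpec(**doc.pop("priors"))
        if "chains" in doc:
            kwargs["chains"] = sm.ChainConfig(**doc.pop("chains"))
        for key in (
            "out_dir", "seed", "covariates", "collinearity_threshold",
            "include_field", "waves_to_fit", "predict_draws",
        ):
            if key in doc:
                kwargs[key] = doc.pop(key)
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _setup_logging(out_dir: Path) -> None:
    if log.handlers:
        return
    fmt = logging.Formatter(
        "%(asctime)s %(name)s %(levelname)s %(message)s"
    )
    for handler in (
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(out_dir / "run.log"),
    ):
        handler.setFormatter(fmt)
        log.addHandler(handler)
    log.setLevel(logging.INFO)


# ---------------------------------------------------------------------------
# stages — each reads its inputs from out_dir so stages can be re-run solo
# ---------------------------------------------------------------------------

def stage_simulate(cfg: RunConfig) -> list[Path]:
    if cfg.field_range_km is None:
        box = cfg.grid.bounding_box()
        diam_km = float(np.hypot(box[2] - box[0], box[3] - box[1])) * 111.0
        range_km = 0.25 * diam_km
    else:
        range_km = cfg.field_range_km
    matern = sm.MaternParams(range_km, cfg.field_sigma)
    ds = synthetic.simulate_dataset(
        seed=cfg.seed,
        counts_per_wave=cfg.counts_per_wave,
        grid_spec=cfg.grid,
        alpha_true=cfg.alpha_true,
        beta_true=cfg.beta_true,
        matern_true=matern,
        smoothness_range=cfg.smoothness_range,
        children_per_cluster=cfg.children_per_cluster,
    )
    # two-rectangle region partition of the bounding box, for regional tables
    lon_min, lat_min, lon_max, lat_max = cfg.grid.bounding_box()
    lon_mid = (lon_min + lon_max) / 2.0
    regions = [
        core_io.RegionPolygon(
            "WEST",
            [[(lon_min, lat_min), (lon_mid, lat_min), (lon_mid, lat_max),
              (lon_min, lat_max), (lon_min, lat_min)]],
        ),
        core_io.RegionPolygon(
            "EAST",
            [[(lon_mid, lat_min), (lon_max, lat_min), (lon_max, lat_max),
              (lon_mid, lat_max), (lon_mid, lat_min)]],
        ),
    ]
    points = [(r.lon, r.lat) for r in ds.records]
    labels = core_io.assign_regions(points, regions)
    records = [
        core_io.ClusterRecord(
            r.cluster_id, r.wave, r.lon, r.lat, r.n_children,
            r.n_underweight, lab,
        )
        for r, lab in zip(ds.records, labels)
    ]
    out = cfg.out_dir
    paths = []
    core_io.write_clusters(records, out / "clusters.csv")
    paths.append(out / "clusters.csv")
    for g in ds.grids:
        p = out / f"{g.name}.asc"
        core_io.write_grid(g, p)
        paths.append(p)
    core_io.write_regions(regions, out / "regions.geojson")
    paths.append(out / "regions.geojson")
    ds.truth.to_json(out / "truth.json")
    paths.append(out / "truth.json")
    return paths


def stage_describe(cfg: RunConfig) -> list[Path]:
    records = core_io.read_clusters(cfg.out_dir / "clusters.csv")
    table = descriptives.prevalence_table(records)
    wide = table.to_wide()
    csv_path = cfg.out_dir / "prevalence_table.csv"
    wide.to_csv(csv_path)
    txt_path = cfg.out_dir / "prevalence_table.txt"
    txt_path.write_text(wide.to_string() + "\n")
    return [csv_path, txt_path]


def _load_grids(cfg: RunConfig) -> list[core_io.CovariateGrid]:
    names = cfg.covariates or [
        f"cov{k}" for k in range(len(cfg.beta_true))
    ]
    return [
        core_io.read_grid(cfg.out_dir / f"{n}.asc", name=n) for n in names
    ]


def stage_prep(cfg: RunConfig) -> list[Path]:
    records = core_io.read_clusters(cfg.out_dir / "clusters.csv")
    grids = _load_grids(cfg)
    raw = core_io.extract_covariates(
        grids, [(r.lon, r.lat) for r in records]
    )
    design = covariate_prep.standardize(raw, [g.name for g in grids])
    if len(design.columns) >= 2:
        retained, dropped = covariate_prep.correlation_screen(
            design, cfg.collinearity_threshold
        )
    else:
        retained, dropped = list(design.columns), []
    doc = {
        "columns": design.columns,
        "means": design.means.tolist(),
        "sds": design.sds.tolist(),
        "values": design.values.tolist(),
        "retained": retained,
        "dropped": [
            {"kept": k, "dropped": d, "r": r} for k, d, r in dropped
        ],
    }
    path = cfg.out_dir / "design.json"
    with open(path, "w") as fh:
        json.dump(doc, fh)
    return [path]


def _load_design(cfg: RunConfig) -> covariate_prep.DesignMatrix:
    with open(cfg.out_dir / "design.json") as fh:
        doc = json.load(fh)
    design = covariate_prep.DesignMatrix(
        columns=doc["columns"],
        values=np.asarray(doc["values"]),
        means=np.asarray(doc["means"]),
        sds=np.asarray(doc["sds"]),
    )
    return design.select(doc["retained"])


def _wave_subsets(cfg, records):
    for wave in cfg.waves_to_fit:
        if wave == POOLED_LABEL:
            yield wave, list(range(len(records)))
        else:
            yield wave, [
                i for i, r in enumerate(records) if r.wave == str(wave)
            ]


def stage_fit(cfg: RunConfig) -> list[Path]:
    records = core_io.read_clusters(cfg.out_dir / "clusters.csv")
    design = _load_design(cfg)
    paths = []
    for wave, idx in _wave_subsets(cfg, records):
        sub_records = [records[i] for i in idx]
        sub_design = design.values[idx]
        points_km = core_io.project_points(
            np.array([[r.lon, r.lat] for r in sub_records])
        )
        post = sm.fit_mcmc(
            sub_records,
            sub_design,
            beta_names=design.columns,
            points_km=points_km,
            priors=cfg.priors,
            config=sm.ChainConfig(
                n_chains=cfg.chains.n_chains,
                n_iter=cfg.chains.n_iter,
                burn_in=cfg.chains.burn_in,
                thin=cfg.chains.thin,
                store_budget=cfg.chains.store_budget,
                seed=cfg.seed + hash_wave(wave),
            ),
            include_field=cfg.include_field,
        )
        log.info(
            "fit[%s]: %d draws, acceptance %s", wave, post.n_stored,
            post.acceptance,
        )
        draws_path = cfg.out_dir / f"posterior_{wave}.csv"
        post.to_frame().to_csv(draws_path, index=False)
        summary_path = cfg.out_dir / f"posterior_{wave}_summary.json"
        with open(summary_path, "w") as fh:
            json.dump(
                {
                    "wave": wave,
                    "n_clusters": len(sub_records),
                    "acceptance": post.acceptance,
                    "summary": post.summary().to_dict(orient="records"),
                    "waic": sm.waic(post, sub_records),
                },
                fh,
                indent=1,
            )
        paths.extend([draws_path, summary_path])
    return paths


def hash_wave(wave: str) -> int:
    import zlib

    return zlib.crc32(str(wave).encode()) % 100_000


def _load_posterior(cfg: RunConfig, wave: str, design, idx) -> sm.Posterior:
    df = None
    import pandas as pd

    df = pd.read_csv(cfg.out_dir / f"posterior_{wave}.csv")
    beta_cols = [c for c in df.columns if c.startswith("beta:")]
    zeta_cols = [c for c in df.columns if c.startswith("zeta:")]
    return sm.Posterior(
        alpha=df["alpha"].to_numpy(),
        beta=df[beta_cols].to_numpy(),
        zeta=df[zeta_cols].to_numpy()
        if zeta_cols
        else np.empty((len(df), 0)),
        log_rho=df["log_rho"].to_numpy() if "log_rho" in df else np.empty(0),
        log_sigma=df["log_sigma"].to_numpy()
        if "log_sigma" in df
        else np.empty(0),
        beta_names=[c.split(":", 1)[1] for c in beta_cols],
        design=design.values[idx],
    )


def stage_predict(cfg: RunConfig) -> list[Path]:
    records = core_io.read_clusters(cfg.out_dir / "clusters.csv")
    design = _load_design(cfg)
    grids = [
        core_io.read_grid(cfg.out_dir / f"{n}.asc", name=n)
        for n in design.columns
    ]
    paths = []
    for wave, idx in _wave_subsets(cfg, records):
        post = _load_posterior(cfg, wave, design, idx)
        obs = np.array([[records[i].lon, records[i].lat] for i in idx])
        surface = prediction.predict_surface(
            post,
            grids,
            design,
            obs,
            n_draws=cfg.predict_draws,
            seed=cfg.seed + hash_wave(wave) + 1,
        )
        for g in surface.as_grids():
            p = cfg.out_dir / f"surface_{wave}_{g.name}.asc"
            core_io.write_grid(g, p)
            paths.append(p)
        p = cfg.out_dir / f"surface_{wave}_summary.json"
        with open(p, "w") as fh:
            json.dump(surface.summary(), fh, indent=1)
        paths.append(p)
    return paths


def stage_compare(cfg: RunConfig) -> list[Path]:
    fits = []
    for wave in cfg.waves_to_fit:
        with open(cfg.out_dir / f"posterior_{wave}_summary.json") as fh:
            doc = json.load(fh)
        fits.append((str(wave), doc["waic"]))
    table = sm.compare_models(fits)
    path = cfg.out_dir / "waic_comparison.csv"
    table.to_csv(path, index=False)
    return [path]


_STAGE_FN = {
    "simulate": stage_simulate,
    "describe": stage_describe,
    "prep": stage_prep,
    "fit": stage_fit,
    "predict": stage_predict,
    "compare": stage_compare,
}


def run_pipeline(cfg: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in order and write ``manifest.json``.

    The manifest lists every stage's outputs, the seed, and a sha256 per
    output file; re-running with the same config and seed reproduces the
    same file hashes.
    """
    stages = stages or STAGES
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ValueError(f"unknown stage(s): {bad}")
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(cfg.out_dir)
    manifest: dict = {
        "seed": cfg.seed,
        "stages": [],
        "files": {},
        "status": "incomplete",
    }
    # merge with a previous partial run so stages can be re-run one at a time
    prior_path = cfg.out_dir / "manifest.json"
    if prior_path.exists():
        with open(prior_path) as fh:
            prior = json.load(fh)
        if prior.get("seed") == cfg.seed:
            manifest["files"] = prior.get("files", {})
            manifest["stages"] = [
                s for s in prior.get("stages", []) if s["name"] not in stages
            ]
    t0 = time.time()
    try:
        for name in STAGES:
            if name not in stages:
                continue
            log.info("stage %s: start", name)
            t_stage = time.time()
            outputs = _STAGE_FN[name](cfg)
            entry = {
                "name": name,
                "outputs": [str(p.relative_to(cfg.out_dir)) for p in outputs],
                "wall_clock_s": round(time.time() - t_stage, 3),
            }
            manifest["stages"].append(entry)
            for p in outputs:
                manifest["files"][str(p.relative_to(cfg.out_dir))] = _sha256(p)
            log.info("stage %s: done (%.2fs)", name, entry["wall_clock_s"])
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_manifest(cfg, manifest, t0)
        raise RuntimeError(f"stage failed: {exc}") from exc
    manifest["status"] = "complete"
    _write_manifest(cfg, manifest, t0)
    return manifest


def _write_manifest(cfg: RunConfig, manifest: dict, t0: float) -> None:
    manifest["wall_clock_s"] = round(time.time() - t0, 3)
    with open(cfg.out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
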