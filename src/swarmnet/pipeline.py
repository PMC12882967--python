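"""Stage orchestration: simulate/load → build → metrics → betadiv → models.

All stages exchange data through declared files under one output
directory and a manifest records a content hash for every artifact, so
a rerun with the same inputs and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import betadiv, netbuild, netmetrics, obs_io
from .errors import ConvergenceError, ValidationError
from .gradient_models import (
    FAMILY_FOR_RESPONSE,
    GammSpec,
    GlmmSpec,
    aicc_select,
    fit_gamm,
    gamm_report,
    glmm_report,
    render_text_table,
)
from .synthetic_data import SimConfig, simulate_dataset, write_dataset

logger = logging.getLogger(__name__)

GLMM_RESPONSES = list(FAMILY_FOR_RESPONSE)
GAMM_RESPONSES = ["beta_wn", "beta_st", "beta_os"]


@dataclass
class RunConfig:
    """Pipeline configuration; defaults are the analysis defaults.

    Either ``windows_path``/``sites_path`` point at observation data, or
    ``simulate`` is set and a synthetic dataset is generated first.
    """

    out_dir: str = "swarmnet_out"
    windows_path: str | None = None
    sites_path: str | None = None
    simulate: bool = False
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0
    quadratic_candidate: bool = True
    n_knots: int = 3
    p_threshold: float = 0.05
    dissimilarity_scale: str = "raw"  # "raw" components or "proportions" of beta_wn
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("sim", None)
        cfg = cls(**d)
        if sim:
            cfg.sim = SimConfig(**sim)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage in dependency order; return the artifact manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    # -- input stage --------------------------------------------------------
    if cfg.simulate:
        sim_cfg = dataclasses.replace(cfg.sim, seed=cfg.seed)
        sites_list, windows, truth = simulate_dataset(sim_cfg)
        paths = write_dataset(out, sites_list, windows, truth)
        artifacts.update(paths)
        sites = {s.site_id: s for s in sites_list}
        logger.info("simulated %d windows at %d sites (seed %d)",
                    len(windows), len(sites), cfg.seed)
    else:
        if not cfg.windows_path or not cfg.sites_path:
            raise ValidationError("windows_path and sites_path required unless simulating")
        windows = obs_io.read_windows(cfg.windows_path)
        sites = obs_io.read_site_env(cfg.sites_path)
        logger.info("read %d windows, %d sites", len(windows), len(sites))

    # -- build --------------------------------------------------------------
    groups = obs_io.group_by_swarm(windows)
    nets = netbuild.build_all(groups)
    logger.info("built %d networks", len(nets))
    edges = []
    for net in nets:
        el = netbuild.edge_list(net)
        el.insert(0, "site_id", net.key.site_id)
        el.insert(1, "swarm_id", net.key.swarm_id)
        el.insert(2, "date", net.key.date.isoformat())
        edges.append(el)
    edge_path = out / "edge_lists.csv"
    pd.concat(edges, ignore_index=True).to_csv(edge_path, index=False) if edges \
        else edge_path.write_text("site_id,swarm_id,date,species_1,species_2,weight\n")
    artifacts["edge_lists"] = edge_path

    # -- metrics ------------------------------------------------------------
    metrics = netmetrics.metrics_table(nets)
    metrics_path = out / "metrics.csv"
    metrics.to_csv(metrics_path, index=False)
    artifacts["metrics"] = metrics_path
    logger.info("metrics for %d networks", len(metrics))

    # -- betadiv ------------------------------------------------------------
    pairs = betadiv.all_pairs(nets)
    logger.info("%d pairwise comparisons", len(pairs))
    pairs_df = betadiv.pairs_table(pairs, sites)
    pairs_path = out / "pairwise.csv"
    pairs_df.to_csv(pairs_path, index=False)
    artifacts["pairwise"] = pairs_path
    summary = betadiv.site_summary_table(betadiv.site_pair_summary(pairs))
    summary_path = out / "site_pair_summary.csv"
    summary.to_csv(summary_path, index=False)
    artifacts["site_pair_summary"] = summary_path
    n_between = int((~summary["same_site"]).sum())
    logger.info("%d between-site summaries", n_between)

    # -- GLMMs --------------------------------------------------------------
    env = pd.DataFrame(
        [
            {"site_id": s.site_id, "rainfall": s.rainfall, "suitability": s.suitability}
            for s in sites.values()
        ]
    )
    model_data = metrics.merge(env, on="site_id", how="left")
    glmm_fits = {}
    aicc_rows = []
    for response in GLMM_RESPONSES:
        spec = GlmmSpec(response=response, family=FAMILY_FOR_RESPONSE[response])
        try:
            if cfg.quadratic_candidate:
                fit, table = aicc_select(spec, model_data)
                table.insert(0, "response", response)
                aicc_rows.append(table)
            else:
                from .gradient_models import fit_glmm
                fit = fit_glmm(spec, model_data)
            glmm_fits[response] = fit
        except (ValidationError, ConvergenceError) as exc:
            logger.warning("GLMM for %s skipped: %s", response, exc)
    if glmm_fits:
        rep = glmm_report(glmm_fits)
        glmm_path = out / "glmm_results.csv"
        rep.to_csv(glmm_path, index=False)
        artifacts["glmm_results"] = glmm_path
        if aicc_rows:
            aicc_path = out / "glmm_aicc.csv"
            pd.concat(aicc_rows, ignore_index=True).to_csv(aicc_path, index=False)
            artifacts["glmm_aicc"] = aicc_path

    # -- GAMMs --------------------------------------------------------------
    gamm_data = pairs_df.copy()
    if cfg.dissimilarity_scale == "proportions":
        pos = gamm_data["beta_wn"] > 0
        gamm_data = gamm_data[pos].copy()
        gamm_data["beta_st"] = gamm_data["beta_st"] / gamm_data["beta_wn"]
        gamm_data["beta_os"] = gamm_data["beta_os"] / gamm_data["beta_wn"]
    gamm_fits = {}
    for response in GAMM_RESPONSES:
        try:
            fit = fit_gamm(GammSpec(response=response, n_knots=cfg.n_knots), gamm_data)
            gamm_fits[response] = fit
        except (ValidationError, ConvergenceError) as exc:
            logger.warning("GAMM for %s skipped: %s", response, exc)
    if gamm_fits:
        rep = gamm_report(gamm_fits)
        gamm_path = out / "gamm_results.csv"
        rep.to_csv(gamm_path, index=False)
        artifacts["gamm_results"] = gamm_path

    # -- rendered tables ----------------------------------------------------
    text = []
    if glmm_fits:
        text.append(render_text_table(glmm_report(glmm_fits), title="Network metric GLMMs"))
    if gamm_fits:
        text.append(render_text_table(gamm_report(gamm_fits), title="Dissimilarity GAMMs"))
    tables_path = out / "tables.txt"
    tables_path.write_text("\n".join(text), encoding="utf-8")
    artifacts["tables"] = tables_path

    manifest = {
        "seed": cfg.seed,
        "counts": {
            "windows": len(windows),
            "networks": len(nets),
            "pairwise_comparisons": len(pairs),
            "between_site_summaries": n_between,
            "glmm_responses_fit": len(glmm_fits),
            "gamm_responses_fit": len(gamm_fits),
        },
        "files": {
            name: {"path": str(p.relative_to(out)), "sha256": _sha256(p)}
            for name, p in sorted(artifacts.items())
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
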