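"""Sequential pipeline orchestration with reproducible run manifests.

A run is described by a config (YAML or JSON): a list of stages, their
parameters and per-stage seeds.  Stages execute in dependency order and
write their outputs under the run directory; a manifest records the
package version, the config hash, the seeds used and a SHA-256 digest of
every output file, so a rerun with an identical config produces
identical digests.

Available stages
----------------
``variants``          FASTA + properties table of the four isoforms
``synth_tht``         synthetic ThT plate (long CSV) with truth
``fit_tht``           empirical λ/κ/θ fits of a plate file
``synth_kappa``       synthetic κ(I) series with truth
``fit_salt``          FEB/BB fits with AICc model comparison
``frag_test``         synthetic seeded pair → fragmentation verdict
``simulate``          CG trajectory for one variant (XYZ + sidecar)
``analyze_ensemble``  Rg/ν/Δ/S, contact map and cluster report
``synth_observation`` planted observation table + per-pair distances
``correlate``         pooled/per-variant heatmaps and per-pair ρ map
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (cg_sim, correlate, ensemble_analysis, fida, frag_test,
               salt_models, sequences, synthetic_data, tht_kinetics)

STAGE_ORDER = ["variants", "synth_tht", "fit_tht", "synth_kappa", "fit_salt",
               "frag_test", "simulate", "analyze_ensemble",
               "synth_observation", "correlate"]


@dataclass
class RunConfig:
    stages: list[str]
    outdir: str
    seed: int = 0
    params: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the run seed."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps({"stages": config.stages, "seed": config.seed,
                       "params": config.params}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


# ------------------------------------------------------------ stages


def _stage_variants(cfg, out: Path, ctx):
    variants = sequences.splice_isoforms()
    sequences.write_fasta(variants.values(), out / "variants.fasta")
    sequences.properties_table(variants.values()).to_csv(
        out / "sequence_properties.tsv", sep="\t")
    mask = sequences.common_pair_mask(variants.values())
    sequences.write_pair_mask_json(mask, out / "common_pairs.json")
    ctx["variants"], ctx["mask"] = variants, mask
    return ["variants.fasta", "sequence_properties.tsv", "common_pairs.json"]


def _stage_synth_tht(cfg, out: Path, ctx):
    p = cfg.params.get("synth_tht", {})
    seed = cfg.stage_seed("synth_tht")
    t = np.arange(0.0, p.get("t_max_h", 45.0), p.get("dt_h", 0.25))
    rows, truths = [], {}
    for rep in range(p.get("n_replicates", 3)):
        trace, truth = synthetic_data.gen_tht(
            p.get("lam", 0.05), p.get("kap", 0.8), p.get("theta", 1.0), t,
            noise_sigma=p.get("noise_sigma", 0.02), seed=seed + rep,
            well_id=f"W{rep}")
        truths[trace.well_id] = truth
        for ti, yi in zip(trace.time, trace.signal):
            rows.append({"time_h": ti, "signal": yi, "well": trace.well_id,
                         "variant": p.get("variant", "FL"),
                         "conc_uM": p.get("conc_uM", 100.0),
                         "nacl_mM": p.get("nacl_mM", 0.0), "seeded": False})
    pd.DataFrame(rows).to_csv(out / "tht_plate.csv", index=False)
    (out / "tht_truth.json").write_text(json.dumps(truths, indent=1))
    ctx["tht_plate"] = out / "tht_plate.csv"
    return ["tht_plate.csv", "tht_truth.json"]


def _stage_fit_tht(cfg, out: Path, ctx):
    src = cfg.params.get("fit_tht", {}).get("plate",
                                            ctx.get("tht_plate"))
    if src is None:
        raise RuntimeError("fit_tht needs a plate file: run synth_tht first "
                           "or set params.fit_tht.plate")
    traces = tht_kinetics.read_plate_csv(src)
    traces = [tht_kinetics.normalize_trace(tr) for tr in traces]
    fits = tht_kinetics.fit_empirical(traces, shared_theta=True)
    tht_kinetics.fits_table(fits).to_csv(out / "kinetic_fits.tsv", sep="\t",
                                         index=False)
    ctx["kinetic_fits"] = fits
    return ["kinetic_fits.tsv"]


def _stage_synth_kappa(cfg, out: Path, ctx):
    p = cfg.params.get("synth_kappa", {})
    pts, truth = synthetic_data.gen_kappa_vs_I(
        p.get("model", "feb"),
        p.get("params", {"kappa0": 0.3, "kappa_sat": 1.5, "I_mid": 120.0}),
        noise_frac=p.get("noise_frac", 0.05), seed=cfg.stage_seed("synth_kappa"))
    pd.DataFrame(pts, columns=["I_mM", "kappa_per_h"]).to_csv(
        out / "kappa_vs_I.tsv", sep="\t", index=False)
    (out / "kappa_truth.json").write_text(json.dumps(truth, indent=1))
    ctx["kappa_points"] = pts
    return ["kappa_vs_I.tsv", "kappa_truth.json"]


def _stage_fit_salt(cfg, out: Path, ctx):
    p = cfg.params.get("fit_salt", {})
    if "table" in p:
        df = pd.read_csv(p["table"], sep="\t")
        pts = df[["I_mM", "kappa_per_h"]].to_numpy()
    elif "kappa_points" in ctx:
        pts = ctx["kappa_points"]
    else:
        raise RuntimeError("fit_salt needs κ(I) data: run synth_kappa first "
                           "or set params.fit_salt.table")
    cmp = salt_models.compare_models(pts)
    rep = {m: {k: v for k, v in vars(cmp[m]).items() if not k.startswith("_")}
           for m in ("feb", "bb")}
    rep["delta_aicc_feb_minus_bb"] = cmp["delta_aicc_feb_minus_bb"]
    rep["preferred"] = cmp["preferred"]
    (out / "salt_fits.json").write_text(json.dumps(rep, indent=1, default=str))
    return ["salt_fits.json"]


def _stage_frag_test(cfg, out: Path, ctx):
    p = cfg.params.get("frag_test", {})
    first, second, truth = synthetic_data.gen_seeded_pair(
        p.get("k", 0.036), p.get("kappa", 0.4), p.get("r", 0.1),
        p.get("dt", 15.0), fragmentation=p.get("fragmentation", False),
        seed=cfg.stage_seed("frag_test"))
    k = frag_test.fit_seeded(first).k
    k_obs = frag_test.fit_seeded(second).k
    pred = frag_test.frag_test(k, k_obs, p.get("kappa", 0.4),
                               p.get("r", 0.1), p.get("dt", 15.0))
    rep = frag_test.report_json(pred, out / "frag_report.json")
    (out / "frag_truth.json").write_text(json.dumps(truth, indent=1))
    return ["frag_report.json", "frag_truth.json"]


def _stage_simulate(cfg, out: Path, ctx):
    p = cfg.params.get("simulate", {})
    variant = sequences.splice_isoforms()[p.get("variant", "FL")]
    proto = cg_sim.SimProtocol(
        ionic_strength_mM=p.get("ionic_strength_mM", 49.0),
        production_ns=p.get("production_ns", 3.5),
        frame_interval_ps=p.get("frame_interval_ps", 70.0))
    traj = cg_sim.run_simulation(variant, proto,
                                 seed=cfg.stage_seed("simulate"))
    traj.to_xyz(out / f"{variant.name}.xyz")
    ctx["trajectory"] = traj
    return [f"{variant.name}.xyz", f"{variant.name}.xyz.json"]


def _stage_analyze_ensemble(cfg, out: Path, ctx):
    p = cfg.params.get("analyze_ensemble", {})
    traj = ctx.get("trajectory")
    if traj is None:
        src = p.get("trajectory")
        if src is None:
            raise RuntimeError("analyze_ensemble needs a trajectory: run "
                               "simulate first or set params.analyze_ensemble."
                               "trajectory")
        traj = cg_sim.Trajectory.from_xyz(src)
    frames = traj.frames
    ensemble_analysis.metrics_table(frames).to_csv(
        out / "frame_metrics.tsv", sep="\t", index=False)
    nu, nu_err, _ = ensemble_analysis.flory_exponent(frames)
    cmap = ensemble_analysis.contact_map(frames)
    cmap.to_long().to_csv(out / "contact_map.tsv", sep="\t", index=False)
    aff = ensemble_analysis.affinity_matrix(frames)
    res = ensemble_analysis.cluster_conformers(
        aff, frames, k=p.get("k", 4), seed=cfg.stage_seed("analyze_ensemble"))
    rep = ensemble_analysis.cluster_report(res)
    rep["flory_nu"] = nu
    rep["flory_nu_err"] = nu_err
    (out / "ensemble_report.json").write_text(json.dumps(rep, indent=1))
    return ["frame_metrics.tsv", "contact_map.tsv", "ensemble_report.json"]


def _stage_synth_observation(cfg, out: Path, ctx):
    p = cfg.params.get("synth_observation", {})
    mask = ctx.get("mask")
    if mask is None:
        mask = sequences.common_pair_mask(sequences.splice_isoforms().values())
    # a small pair universe keeps the table light unless overridden
    pairs = sorted(mask)[: p.get("n_pairs", 60)]
    planted = [tuple(q) for q in p.get("planted_pairs", [list(pairs[0])])]
    effects = p.get("effect_sizes", [0.4] * len(planted))
    submask = set(pairs) | set(planted)
    table, dists, truth = synthetic_data.gen_observation_table(
        planted, effects, submask, seed=cfg.stage_seed("synth_observation"))
    table.to_csv(out / "observation_table.tsv", sep="\t", index=False)
    dists.to_csv(out / "pair_distances.tsv", sep="\t", index=False)
    (out / "observation_truth.json").write_text(json.dumps(truth, indent=1))
    ctx["observation"] = (table, dists, submask)
    return ["observation_table.tsv", "pair_distances.tsv",
            "observation_truth.json"]


def _stage_correlate(cfg, out: Path, ctx):
    if "observation" in ctx:
        table, dists, submask = ctx["observation"]
    else:
        p = cfg.params.get("correlate", {})
        if "table" not in p or "distances" not in p:
            raise RuntimeError("correlate needs an observation table: run "
                               "synth_observation first or set params."
                               "correlate.table/.distances")
        table = pd.read_csv(p["table"], sep="\t")
        dists = pd.read_csv(p["distances"], sep="\t")
        submask = set(map(tuple, dists[["i", "j"]].drop_duplicates()
                          .itertuples(index=False)))
    heat = correlate.metric_kinetics_heatmap(table)
    heat.pooled.to_csv(out / "heatmap_pooled.tsv", sep="\t")
    per_pair = correlate.per_pair_correlation(table, dists, submask)
    per_pair.to_csv(out / "per_pair_rho.tsv", sep="\t", index=False)
    (out / "top_pairs.json").write_text(
        json.dumps(correlate.top_pairs(per_pair), indent=1))
    return ["heatmap_pooled.tsv", "per_pair_rho.tsv", "top_pairs.json"]


_STAGES = {
    "variants": _stage_variants,
    "synth_tht": _stage_synth_tht,
    "fit_tht": _stage_fit_tht,
    "synth_kappa": _stage_synth_kappa,
    "fit_salt": _stage_fit_salt,
    "frag_test": _stage_frag_test,
    "simulate": _stage_simulate,
    "analyze_ensemble": _stage_analyze_ensemble,
    "synth_observation": _stage_synth_observation,
    "correlate": _stage_correlate,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; return the manifest."""
    unknown = set(config.stages) - set(_STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ordered = [s for s in STAGE_ORDER if s in config.stages]
    ctx: dict = {}
    manifest = {
        "package_version": _pkg_version("synsplice"),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": [],
        "outputs": {},
    }
    for stage in ordered:
        files = _STAGES[stage](config, out, ctx)
        manifest["stages"].append(
            {"name": stage, "seed": config.stage_seed(stage), "outputs": files})
        for f in files:
            manifest["outputs"][f] = _digest(out / f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
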