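"""File formats, provenance headers, reports and the pipeline driver.

CSV for frame/feature tables and population curves (inspectable), JSON for
reports and manifests, flat YAML for configuration.  Every artifact carries
a provenance header (tool version, config hash, seed) as '#' comment lines;
unknown columns in user tables are preserved verbatim.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import ModelError

REQUIRED_FEATURE_COLUMNS = ["time_us"]


def config_hash(obj) -> str:
    """Stable short hash of a JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def provenance_header(seed, cfg_hash) -> str:
    return (f"# phytohop {__version__}\n"
            f"# config_hash: {cfg_hash}\n"
            f"# seed: {seed}\n")


def write_feature_table(frames: pd.DataFrame, path, seed=0, cfg_hash="-") -> None:
    """Write a pocket feature table as CSV with a provenance header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, cfg_hash))
        frames.to_csv(fh, index=False, lineterminator="\n")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature-table CSV (header comments ignored, unknown columns
    preserved)."""
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise ModelError(f"malformed feature table {path}: {exc}") from exc
    missing = [c for c in REQUIRED_FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ModelError(
            f"feature table {path} lacks required column(s) {missing}; "
            f"expected at least {REQUIRED_FEATURE_COLUMNS} plus named "
            "distance/indicator columns")
    return df


def write_trajectory_csv(traj, path, seed=0, cfg_hash="-") -> None:
    """Write one surface-hopping trajectory (strided records) as CSV."""
    df = pd.DataFrame({
        "time_fs": traj.times_fs,
        "theta6_deg": traj.theta6_deg,
        "theta5_deg": traj.theta5_deg,
        "r_hb_A": traj.r_hb_A,
        "active_state": traj.active_state,
        "pop_S1": traj.pop_s1,
        "gap_eV": traj.gap_ev,
        "energy_kcal": traj.energy_kcal,
    })
    with open(path, "w") as fh:
        fh.write(provenance_header(seed, cfg_hash))
        df.to_csv(fh, index=False, lineterminator="\n")


def hop_events_json(trajectories) -> list:
    out = []
    for i, t in enumerate(trajectories):
        for h in t.hop_events:
            out.append({
                "trajectory": i, "time_fs": h.time_fs,
                "from_state": h.from_state, "to_state": h.to_state,
                "gap_ev": h.gap_ev, "theta6_deg": h.coordinates.theta6,
                "theta5_deg": h.coordinates.theta5,
                "r_hb_A": h.coordinates.r_hb,
                "accepted": h.accepted, "frustrated": h.frustrated,
            })
    return out


def write_report(obj: dict, path) -> None:
    """Deterministic JSON report (sorted keys, no volatile fields)."""
    def convert(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=convert)
        fh.write("\n")


def append_log(outdir: Path, stage: str, seed, cfg_hash, t_start: float) -> None:
    entry = {"stage": stage, "seed": seed, "config_hash": cfg_hash,
             "wall_s": round(time.time() - t_start, 3),
             "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S")}
    with open(Path(outdir) / "pipeline.log.jsonl", "a") as fh:
        fh.write(json.dumps(entry) + "\n")


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    chain: str = "photo"            # photo | pocket | both
    outdir: str = "phytohop_out"
    seed: int = 1
    variant: str = "set-A"
    params_file: str | None = None
    n_trajectories: int = 500
    t_max_ps: float = 15.0
    pocket_n_frames: int = 20000
    pocket_n_replicas: int = 50
    overrides: dict = field(default_factory=dict)
    verbosity: int = 1

    def to_dict(self):
        return asdict(self)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _stage_cached(outdir: Path, name: str, cfg_hash: str) -> bool:
    manifest = outdir / f"{name}.manifest.json"
    if not manifest.exists():
        return False
    try:
        return json.loads(manifest.read_text()).get("config_hash") == cfg_hash
    except Exception:
        return False


def _mark_stage(outdir: Path, name: str, cfg_hash: str, seed, outputs) -> None:
    write_report({"stage": name, "config_hash": cfg_hash, "seed": seed,
                  "outputs": outputs}, outdir / f"{name}.manifest.json")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stage chain with caching; returns the combined
    report (also written to <outdir>/report.json)."""
    from . import model, photoanalysis, pocketanalysis, pocketsynth, irspectra
    from .sampling import sample_initial_conditions
    from .shdynamics import SHSettings, counter_seeds, run_ensemble

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_hash = config_hash(config.to_dict())
    report_path = outdir / "report.json"
    report: dict = {"config_hash": cfg_hash, "seed": config.seed,
                    "version": __version__, "stages": []}

    if config.chain not in ("photo", "pocket", "both"):
        raise ModelError(f"unknown chain {config.chain!r}")

    if _stage_cached(outdir, "report", cfg_hash) and report_path.exists():
        return json.loads(report_path.read_text())

    if config.chain in ("photo", "both"):
        t0 = time.time()
        params = (model.load_parameters(config.params_file)
                  if config.params_file else model.load_parameters(config.variant))
        if config.overrides:
            params = model.ModelParameters.from_dict(
                dict(params.to_dict(), **config.overrides))
        ics = sample_initial_conditions(params, config.n_trajectories,
                                        config.seed)
        settings = SHSettings(t_max_ps=config.t_max_ps)
        trajs = run_ensemble(params, ics, settings,
                             counter_seeds(config.seed + 7,
                                           config.n_trajectories))
        fit = photoanalysis.fit_ensemble_lifetime(trajs, n_boot=100,
                                                  seed=config.seed)
        summ = photoanalysis.summarize_ensemble(trajs)
        curve = photoanalysis.state_populations(trajs, seed=config.seed)
        pd.DataFrame({
            "time_fs": curve.times_fs, "p_s1": curve.p_s1,
            "ci_lo": curve.ci_lo, "ci_hi": curve.ci_hi,
        }).to_csv(outdir / "populations.csv", index=False)
        write_report({"hops": hop_events_json(trajs)},
                     outdir / "hop_events.json")
        report["photo"] = {
            "tau_ps": fit.tau_ps, "t0_ps": fit.t0_ps,
            "tau_ci_ps": list(fit.ci_tau_ps),
            **summ.to_dict(),
        }
        report["stages"].append("photo")
        append_log(outdir, "photo", config.seed, cfg_hash, t0)

    if config.chain in ("pocket", "both"):
        t0 = time.time()
        gen = pocketsynth.GeneratorConfig()
        early = pocketsynth.generate_early_ensemble(
            gen, config.pocket_n_frames, config.seed)
        pr = pocketsynth.generate_pr_reference(
            gen, max(2000, config.pocket_n_frames // 10), config.seed + 1)
        replicas = pocketsynth.generate_relaxation_replicas(
            gen, config.seed + 2, n_replicas=config.pocket_n_replicas)
        write_feature_table(early, outdir / "early_frames.csv",
                            config.seed, cfg_hash)
        clust = pocketanalysis.pca_cluster(early)
        late = pd.concat([r[r.hidden_state == "late"] for r in replicas],
                         ignore_index=True)
        contacts_early = pocketanalysis.contact_count_probabilities(early)
        contacts_late = pocketanalysis.contact_count_probabilities(late)
        hb_early = pocketanalysis.hbond_probability_table(early)
        hb_late = pocketanalysis.hbond_probability_table(late)
        relax = pocketanalysis.estimate_relaxation_lifetime(replicas)
        fmap = irspectra.FrequencyMap()
        spec_by_cluster = [
            irspectra.ensemble_spectrum(early[clust.labels == k], fmap)
            for k in range(3)]
        avg = irspectra.weighted_average(spec_by_cluster, clust.weights)
        spec_pr = irspectra.ensemble_spectrum(pr, fmap, isomerized=False)
        diff = irspectra.difference_spectrum(avg, spec_pr, shift_cm1=8.0)
        pd.DataFrame({"wavenumber_cm1": diff.wavenumber,
                      "intensity": diff.intensity}).to_csv(
            outdir / "difference_spectrum.csv", index=False)
        report["pocket"] = {
            "cluster_weights": clust.weights.tolist(),
            "n_pca_components": clust.n_components,
            "contacts_early": contacts_early.as_dict(),
            "contacts_late": contacts_late.as_dict(),
            "hbond_early": hb_early.probability.round(6).to_dict(),
            "hbond_late": hb_late.probability.round(6).to_dict(),
            "tau_late_us": relax.tau_us,
            "tau_late_ci_us": [relax.ci_us[0], relax.ci_us[1]],
            "n_switch_events": relax.n_events,
        }
        report["stages"].append("pocket")
        append_log(outdir, "pocket", config.seed, cfg_hash, t0)

    write_report(report, report_path)
    _mark_stage(outdir, "report", cfg_hash, config.seed, ["report.json"])
    return report
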