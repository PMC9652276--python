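"""Synthetic binding-pocket feature trajectories.

Emulates the statistical structure of chromophore-pocket dynamics through
the Lumi-R photocycle stages, so the intermediate-characterization analyses
run without any atomistic data:

* a Pr reference ensemble (no Tyr263...N_D hydrogen bond, carbonyl mostly
  water-coordinated, tight Asp207-Arg466 salt bridge);
* an early-Lumi-R ensemble drawn from a three-cluster mixture (Cl0: water
  H-bond to CO_D present; Cl1: water H-bond lost; Cl2: Tyr263...Asp207
  broken), all sharing the short N_D...Tyr263 hallmark;
* mu-s-scale relaxation replicas that switch irreversibly from the early to
  the late intermediate at an exponentially distributed time, after which
  Arg466 becomes dynamic (bimodal O_D...Arg466), the salt bridge weakens and
  the pyrrole water replaces Tyr263 at the D-ring.

All emission parameters are generator conventions chosen to reproduce the
qualitative contrasts of the modelled system (shorter/longer, unimodal/
bimodal, cluster weights); they are collected in one annotated config.
Ground-truth state and cluster labels are included only when requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .model import ModelError

DISTANCE_COLUMNS = [
    "OD_His290", "OD_water", "Tyr263_Asp207", "ND_Tyr263", "OD_Arg466",
    "OB_Ser257", "OB_Tyr216", "Asp207_Arg466_c1", "Asp207_Arg466_c2",
]
FLAG_COLUMNS = ["water_bridge_OD", "pyrrole_water_D"]
GROUND_TRUTH_COLUMNS = ["hidden_state", "hidden_cluster"]


def _g(mean, sd):
    return {"kind": "gauss", "mean": mean, "sd": sd}


def _g2(m1, s1, m2, s2, w1):
    return {"kind": "mix2", "mean1": m1, "sd1": s1, "mean2": m2, "sd2": s2,
            "w1": w1}


# Emission distributions (angstrom) and indicator probabilities per state.
# Cluster-specific overrides apply on top of the shared early-state block.
DEFAULT_EMISSIONS = {
    "pr": {
        "OD_His290": _g(3.1, 0.40), "OD_water": _g(2.9, 0.30),
        "Tyr263_Asp207": _g(2.7, 0.20), "ND_Tyr263": _g(5.6, 0.70),
        "OD_Arg466": _g(5.0, 0.45), "OB_Ser257": _g(2.8, 0.25),
        "OB_Tyr216": _g(4.5, 0.55), "Asp207_Arg466_c1": _g(2.75, 0.28),
        "Asp207_Arg466_c2": _g(2.85, 0.30),
        "water_bridge_OD": 0.70, "pyrrole_water_D": 0.10,
    },
    "early": {
        "OD_His290": _g(4.6, 0.70), "OD_water": _g(2.85, 0.22),
        "Tyr263_Asp207": _g(2.75, 0.22), "ND_Tyr263": _g(3.0, 0.25),
        "OD_Arg466": _g(5.2, 0.35), "OB_Ser257": _g(2.8, 0.25),
        "OB_Tyr216": _g(4.2, 0.50), "Asp207_Arg466_c1": _g(2.7, 0.25),
        "Asp207_Arg466_c2": _g(2.8, 0.28),
        "water_bridge_OD": 0.92, "pyrrole_water_D": 0.15,
    },
    # Cluster signatures are correlated across several features, as pocket
    # rearrangements are in real trajectories: the lost water H-bond (Cl1)
    # coherently loosens the carbonyl environment, and the broken
    # Tyr263...Asp207 contact (Cl2) also slackens the Tyr263...D-ring bond
    # (still short on the early-state scale).
    "early_cluster_overrides": {
        0: {},
        1: {"OD_water": _g(5.2, 0.50), "water_bridge_OD": 0.05,
            "OD_His290": _g(5.8, 0.70), "OB_Ser257": _g(3.25, 0.28),
            "OB_Tyr216": _g(5.1, 0.50)},
        2: {"Tyr263_Asp207": _g(5.6, 0.55), "ND_Tyr263": _g(3.6, 0.35)},
    },
    "late": {
        "OD_His290": _g(5.0, 0.90), "OD_water": _g(3.6, 0.80),
        "Tyr263_Asp207": _g(5.0, 0.95), "ND_Tyr263": _g(4.8, 0.85),
        "OD_Arg466": _g2(3.2, 0.35, 5.8, 0.55, 0.45),
        "OB_Ser257": _g(4.2, 0.75), "OB_Tyr216": _g(2.9, 0.30),
        "Asp207_Arg466_c1": _g(3.3, 0.60), "Asp207_Arg466_c2": _g(3.6, 0.65),
        "water_bridge_OD": 0.30, "pyrrole_water_D": 0.75,
    },
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the synthetic pocket-trajectory generator.

    ``cluster_weights`` are the early-Lumi-R mixture weights (Cl0, Cl1, Cl2);
    ``tau_late_us`` is the mean of the exponential early->late switching
    time; ``frame_interval_us`` and ``replica_length_us`` define the sampling
    of relaxation replicas.
    """

    cluster_weights: tuple = (0.18, 0.81, 0.01)
    tau_late_us: float = 0.4
    frame_interval_us: float = 1e-4      # 100 ps
    replica_length_us: float = 2.0
    n_replicas: int = 10
    emissions: dict = field(default_factory=lambda: DEFAULT_EMISSIONS)

    def __post_init__(self):
        w = np.asarray(self.cluster_weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ModelError("cluster weights must be non-negative and sum to 1")
        for state in ("pr", "early", "late"):
            for name, spec in self.emissions[state].items():
                if isinstance(spec, dict):
                    for key in ("sd", "sd1", "sd2"):
                        if key in spec and spec[key] <= 0:
                            raise ModelError(f"SD of {state}/{name} must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        """Load a generator configuration; schema: the top-level keys of this
        dataclass, with ``cluster_weights`` as a 3-list, ``emissions`` as
        nested mappings of {kind: gauss|mix2, mean(s), sd(s), w1} per feature
        (indicator features are bare probabilities)."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cluster_weights" in raw:
            raw["cluster_weights"] = tuple(raw["cluster_weights"])
        if "emissions" in raw:
            emis = raw["emissions"]
            if "early_cluster_overrides" in emis:
                emis["early_cluster_overrides"] = {
                    int(k): v for k, v in emis["early_cluster_overrides"].items()}
        return cls(**raw)


def _draw(spec, n, rng):
    if not isinstance(spec, dict):  # indicator probability
        return (rng.random(n) < float(spec)).astype(int)
    if spec["kind"] == "gauss":
        x = rng.normal(spec["mean"], spec["sd"], size=n)
    else:
        pick = rng.random(n) < spec["w1"]
        x = np.where(pick, rng.normal(spec["mean1"], spec["sd1"], size=n),
                     rng.normal(spec["mean2"], spec["sd2"], size=n))
    return np.clip(x, 0.05, None)  # distances strictly positive


def _emit(emissions: dict, n: int, rng) -> dict:
    cols = {}
    for name in DISTANCE_COLUMNS + FLAG_COLUMNS:
        cols[name] = _draw(emissions[name], n, rng)
    return cols


def generate_early_ensemble(config: GeneratorConfig, n_frames: int, seed: int,
                            ground_truth: bool = True) -> pd.DataFrame:
    """Draw early-Lumi-R frames from the three-cluster mixture."""
    rng = np.random.default_rng(seed)
    labels = rng.choice(3, size=n_frames, p=np.asarray(config.cluster_weights))
    base = config.emissions["early"]
    overrides = config.emissions["early_cluster_overrides"]
    frames = {}
    cols = None
    for cl in range(3):
        idx = np.nonzero(labels == cl)[0]
        emis = dict(base, **overrides.get(cl, {}))
        drawn = _emit(emis, len(idx), rng)
        if cols is None:
            cols = {k: np.empty(n_frames, dtype=np.asarray(v).dtype)
                    for k, v in drawn.items()}
        for k, v in drawn.items():
            cols[k][idx] = v
    df = pd.DataFrame(cols)
    df.insert(0, "time_us", np.arange(n_frames) * config.frame_interval_us)
    if ground_truth:
        df["hidden_state"] = "early"
        df["hidden_cluster"] = labels
    return df


def generate_pr_reference(config: GeneratorConfig, n_frames: int, seed: int,
                          ground_truth: bool = True) -> pd.DataFrame:
    """Draw frames of the resting Pr ensemble (difference-spectrum reference)."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(_emit(config.emissions["pr"], n_frames, rng))
    df.insert(0, "time_us", np.arange(n_frames) * config.frame_interval_us)
    if ground_truth:
        df["hidden_state"] = "pr"
        df["hidden_cluster"] = -1
    return df


def generate_relaxation_replicas(config: GeneratorConfig, seed: int,
                                 n_replicas: int | None = None,
                                 ground_truth: bool = True) -> list:
    """Simulate independent early->late relaxation replicas.

    Each replica starts in the early state and switches irreversibly to the
    late state at an exponential time with mean ``tau_late_us`` (a rate of
    zero never switches); frames are emitted on a fixed time grid.
    """
    n_replicas = config.n_replicas if n_replicas is None else n_replicas
    rng = np.random.default_rng(seed)
    n_frames = int(round(config.replica_length_us / config.frame_interval_us))
    t_grid = np.arange(n_frames) * config.frame_interval_us
    base_early = config.emissions["early"]
    overrides = config.emissions["early_cluster_overrides"]
    weights = np.asarray(config.cluster_weights)
    out = []
    for _ in range(n_replicas):
        if config.tau_late_us > 0 and np.isfinite(config.tau_late_us):
            t_switch = rng.exponential(config.tau_late_us)
        else:
            t_switch = np.inf
        is_late = t_grid >= t_switch
        n_early = int(np.sum(~is_late))
        n_late = n_frames - n_early
        labels = rng.choice(3, size=n_early, p=weights)
        cols = {k: np.empty(n_frames) for k in DISTANCE_COLUMNS}
        for k in FLAG_COLUMNS:
            cols[k] = np.empty(n_frames, dtype=int)
        for cl in range(3):
            idx = np.nonzero(labels == cl)[0]
            emis = dict(base_early, **overrides.get(cl, {}))
            for k, v in _emit(emis, len(idx), rng).items():
                cols[k][idx] = v
        late_cols = _emit(config.emissions["late"], n_late, rng)
        for k, v in late_cols.items():
            cols[k][n_early:] = v
        df = pd.DataFrame(cols)
        df.insert(0, "time_us", t_grid)
        if ground_truth:
            state = np.where(is_late, "late", "early")
            cluster = np.full(n_frames, -1)
            cluster[:n_early] = labels
            df["hidden_state"] = state
            df["hidden_cluster"] = cluster
            df.attrs["t_switch_us"] = float(t_switch)
        out.append(df)
    return out
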