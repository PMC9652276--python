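"""Statistics characterizing the Lumi-R intermediates from pocket feature
tables: distance distributions (with bimodality tests), hydrogen-bond and
salt-bridge contact probabilities, PCA + hierarchical clustering, and the
early->late relaxation kinetics.  Runs identically on synthetic and
user-supplied tables with the same column schema.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import gaussian_kde
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA
from sklearn.neighbors import kneighbors_graph
from sklearn.preprocessing import StandardScaler

from ._diptest import dip_statistic, dip_test
from .model import ModelError
from .pocketsynth import DISTANCE_COLUMNS

# hydrogen-bond donor-acceptor distance criterion (O/N pairs); the
# Asp207-Arg466 salt-bridge contact rule uses the stricter 3 A cutoff
HBOND_CUTOFF = 3.5
CONTACT_CUTOFF = 3.0

DEFAULT_HBOND_DEFINITIONS = {
    "OD_His290": ("distance", "OD_His290", HBOND_CUTOFF),
    "OD_water": ("distance", "OD_water", HBOND_CUTOFF),
    "Tyr263_Asp207": ("distance", "Tyr263_Asp207", HBOND_CUTOFF),
    "ND_Tyr263": ("distance", "ND_Tyr263", HBOND_CUTOFF),
    "OB_Ser257": ("distance", "OB_Ser257", HBOND_CUTOFF),
    "OB_Tyr216": ("distance", "OB_Tyr216", HBOND_CUTOFF),
    "water_bridge_OD": ("indicator", "water_bridge_OD", None),
    "pyrrole_water_D": ("indicator", "pyrrole_water_D", None),
}


def distance_distributions(frames: pd.DataFrame, pairs=None,
                           bandwidth=None, alpha: float = 0.05,
                           seed: int = 0) -> dict:
    """Histogram, kernel density and a dip-test bimodality flag per pair."""
    if len(frames) < 100:
        raise ModelError("need at least 100 frames for distributions")
    pairs = list(pairs) if pairs is not None else [
        c for c in DISTANCE_COLUMNS if c in frames.columns]
    unknown = [p for p in pairs if p not in frames.columns]
    if unknown:
        raise ModelError(f"unknown pair name(s) {unknown}; valid names: "
                         f"{[c for c in frames.columns if c in DISTANCE_COLUMNS]}")
    out = {}
    for p in pairs:
        x = frames[p].to_numpy(float)
        hist, edges = np.histogram(x, bins="auto", density=True)
        if np.ptp(x) > 0:
            kde = gaussian_kde(x, bw_method=bandwidth)
            grid = np.linspace(x.min(), x.max(), 256)
            dens = kde(grid)
            dip, pval = dip_test(x, seed=seed)
        else:  # degenerate single-point data
            grid = np.array([x[0]])
            dens = np.array([np.inf])
            dip, pval = 0.0, 1.0
        out[p] = {
            "hist": hist, "bin_edges": edges, "grid": grid, "density": dens,
            "dip": dip, "dip_pvalue": pval, "bimodal": bool(pval < alpha),
        }
    return out


@dataclass
class ContactTable:
    """P(0), P(1), P(2) Asp207-Arg466 contacts with standard errors."""

    probabilities: np.ndarray
    standard_errors: np.ndarray
    n_frames: int

    def as_dict(self):
        return {f"P{k}": float(self.probabilities[k]) for k in range(3)}


def contact_count_probabilities(frames: pd.DataFrame,
                                cutoff: float = CONTACT_CUTOFF) -> ContactTable:
    """Per-frame contact count (how many of the two Asp207-Arg466 atom-pair
    distances are below ``cutoff``) and its probability table."""
    cols = ("Asp207_Arg466_c1", "Asp207_Arg466_c2")
    missing = [c for c in cols if c not in frames.columns]
    if missing:
        raise ModelError(f"missing contact-distance columns: {missing}")
    counts = ((frames[cols[0]].to_numpy(float) < cutoff).astype(int)
              + (frames[cols[1]].to_numpy(float) < cutoff).astype(int))
    n = len(counts)
    probs = np.array([(counts == k).mean() for k in range(3)])
    se = np.sqrt(probs * (1 - probs) / n)
    return ContactTable(probabilities=probs, standard_errors=se, n_frames=n)


def hbond_probability_table(frames: pd.DataFrame,
                            definitions: dict = None) -> pd.DataFrame:
    """Fraction of frames satisfying each named interaction definition.

    Definitions map a name to ("distance", column, cutoff) or
    ("indicator", column, None).
    """
    definitions = definitions or {
        k: v for k, v in DEFAULT_HBOND_DEFINITIONS.items()
        if v[1] in frames.columns}
    rows = []
    n = len(frames)
    for name, (kind, col, cutoff) in definitions.items():
        if kind == "distance":
            sat = frames[col].to_numpy(float) < cutoff
        else:
            sat = frames[col].to_numpy() > 0.5
        p = float(sat.mean()) if n else float("nan")
        rows.append((name, p, math.sqrt(p * (1 - p) / n) if n else float("nan")))
    return pd.DataFrame(rows, columns=["interaction", "probability",
                                       "standard_error"]).set_index("interaction")


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusteringResult:
    labels: np.ndarray
    weights: np.ndarray
    pca_components: np.ndarray
    explained_variance_ratio: np.ndarray
    n_components: int
    feature_columns: list
    silhouette: float
    linkage: str = "ward"


def pca_cluster(frames: pd.DataFrame, feature_columns=None, K: int = 3,
                n_components="kaiser", explained_variance: float = 0.90,
                connectivity_above: int = 4000, seed: int = 0) -> ClusteringResult:
    """Standardize features, project on the leading principal components and
    cut a Ward-linkage hierarchical clustering at K clusters.

    Component selection defaults to the noise-edge rule ("kaiser"): after
    standardization, feature directions without cluster structure have
    eigenvalues below the Marchenko-Pastur edge (1 + sqrt(p/n))^2, so only
    components above it are informative; at least K - 1 components (the
    maximal number of discriminant directions K clusters can span) are
    always retained.  Discarding the isotropic remainder matters because it
    would otherwise dominate the Euclidean Ward distances.  Pass
    ``n_components="variance"`` to retain components explaining
    ``explained_variance`` of the total instead, or an integer for a fixed
    count.

    For large frame counts a k-nearest-neighbour connectivity graph keeps the
    Ward linkage tractable; labels are relabelled in order of first
    appearance so the result is deterministic for a given input order.
    """
    feature_columns = list(feature_columns) if feature_columns is not None \
        else [c for c in DISTANCE_COLUMNS if c in frames.columns]
    X = frames[feature_columns].to_numpy(float)
    n = len(X)
    if K > n:
        raise ModelError(f"K={K} exceeds the number of frames ({n})")
    if K < 1:
        raise ModelError("K must be >= 1")
    Xs = StandardScaler().fit_transform(X)
    pca = PCA()
    Z = pca.fit_transform(Xs)
    evr = pca.explained_variance_ratio_
    if n_components == "kaiser":
        p = Z.shape[1]
        if p <= 4:
            # with this few features, discarding components loses more
            # discriminant structure than the noise it removes
            n_comp = p
        else:
            edge = (1.0 + math.sqrt(p / max(n, 2))) ** 2 * 1.005
            mean_ev = float(np.mean(pca.explained_variance_))
            n_comp = int(np.sum(pca.explained_variance_ > edge * mean_ev))
            n_comp = max(n_comp, K - 1, 1)
    elif n_components == "variance":
        n_comp = int(np.searchsorted(np.cumsum(evr), explained_variance) + 1)
    else:
        n_comp = int(n_components)
    n_comp = min(max(n_comp, 1), Z.shape[1])
    Zp = Z[:, :n_comp]
    if K == 1:
        labels = np.zeros(n, dtype=int)
    else:
        conn = None
        if n > connectivity_above:
            conn = kneighbors_graph(Zp, n_neighbors=15, include_self=False)
        model = AgglomerativeClustering(n_clusters=K, linkage="ward",
                                        connectivity=conn)
        raw = model.fit_predict(Zp)
        # stable relabelling: clusters numbered by first appearance
        order = {}
        labels = np.empty(n, dtype=int)
        for i, lab in enumerate(raw):
            if lab not in order:
                order[lab] = len(order)
            labels[i] = order[lab]
    weights = np.bincount(labels, minlength=K) / n
    if K > 1 and n >= 50:
        from sklearn.metrics import silhouette_score
        rng = np.random.default_rng(seed)
        sub = rng.choice(n, size=min(n, 4000), replace=False)
        sil = float(silhouette_score(Zp[sub], labels[sub]))
    else:
        sil = float("nan")
    return ClusteringResult(labels=labels, weights=weights,
                            pca_components=pca.components_[:n_comp],
                            explained_variance_ratio=evr,
                            n_components=n_comp,
                            feature_columns=feature_columns, silhouette=sil)


def select_k_by_silhouette(frames: pd.DataFrame, feature_columns=None,
                           k_range=(2, 3, 4, 5), seed: int = 0) -> int:
    """Optional cluster-count selection: the K (from ``k_range``) whose Ward
    clustering maximizes the silhouette score.  Not the default (K = 3)."""
    best_k, best_s = None, -np.inf
    for k in k_range:
        res = pca_cluster(frames, feature_columns=feature_columns, K=int(k),
                          seed=seed)
        if np.isfinite(res.silhouette) and res.silhouette > best_s:
            best_k, best_s = int(k), res.silhouette
    if best_k is None:
        raise ModelError("silhouette selection needs at least 50 frames")
    return best_k


# ---------------------------------------------------------------------------
# relaxation kinetics
# ---------------------------------------------------------------------------

@dataclass
class RelaxationFit:
    tau_us: float
    ci_us: tuple
    n_events: int
    n_censored: int
    first_passage_us: np.ndarray
    censored: np.ndarray


def first_passage_times(replicas, column: str = "Tyr263_Asp207",
                        threshold: float = 4.0, window: int = 10):
    """Per-replica first-passage time into the late state.

    The late state is declared at the first frame opening a run of at least
    ``window`` consecutive frames with ``column`` above ``threshold``; the
    recorded time subtracts half a frame interval to unbias the onset
    (the true switch falls uniformly within the preceding interval).
    Replicas that never qualify are right-censored at their last frame.
    """
    times, censored = [], []
    for rep in replicas:
        x = rep[column].to_numpy(float) > threshold
        t = rep["time_us"].to_numpy(float)
        dt = t[1] - t[0] if len(t) > 1 else 0.0
        onset = None
        run = 0
        for i, flag in enumerate(x):
            run = run + 1 if flag else 0
            if run >= window:
                onset = t[i - window + 1]
                break
        if onset is None:
            times.append(t[-1])
            censored.append(True)
        else:
            times.append(max(onset - 0.5 * dt, 0.0))
            censored.append(False)
    return np.asarray(times), np.asarray(censored)


def estimate_relaxation_lifetime(replicas, column: str = "Tyr263_Asp207",
                                 threshold: float = 4.0, window: int = 10,
                                 conf: float = 0.95) -> RelaxationFit:
    """Censored exponential maximum-likelihood estimate of the early->late
    relaxation lifetime with a profile-likelihood confidence interval.

    tau_hat = (sum of all observation times, censored included) / n_events.
    """
    if len(replicas) < 5:
        raise ModelError("need at least 5 replicas")
    times, censored = first_passage_times(replicas, column, threshold, window)
    k = int(np.sum(~censored))
    if k == 0:
        raise ModelError("no early->late switching events observed; "
                         "censoring-only data cannot identify the lifetime")
    total = float(np.sum(times))
    tau = total / k

    def loglik(t):
        return -k * math.log(t) - total / t

    from scipy.stats import chi2

    lmax = loglik(tau)
    target = lmax - 0.5 * float(chi2.ppf(conf, 1))

    def f(t):
        return loglik(t) - target

    lo_bracket = tau / 50.0
    hi_bracket = tau * 50.0
    lo = brentq(f, lo_bracket, tau) if f(lo_bracket) < 0 else lo_bracket
    hi = brentq(f, tau, hi_bracket) if f(hi_bracket) < 0 else float("inf")
    return RelaxationFit(tau_us=tau, ci_us=(float(lo), float(hi)),
                         n_events=k, n_censored=int(np.sum(censored)),
                         first_passage_us=times, censored=censored)
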