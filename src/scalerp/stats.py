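"""Inference machinery for scaled-time waveforms.

* spatiotemporal cluster-based permutation test with a participant-level
  sign-flip null
* paired t with Cohen's d
* PCA latency analysis (PC2 as a latency index)
* one-way repeated-measures ANOVA with partial and generalized eta squared
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.stats

__all__ = [
    "TMap",
    "NeighborGraph",
    "Cluster",
    "ClusterResult",
    "EffectSizes",
    "PcaLatencyResult",
    "AnovaResult",
    "one_sample_tmap",
    "cluster_permutation_test",
    "paired_t_cohens_d",
    "pca_latency",
    "rm_anova",
    "load_neighbors",
    "default_neighbors",
]

_DATA_DIR = Path(__file__).parent / "data"


# ---------------------------------------------------------------------------
# t maps
# ---------------------------------------------------------------------------


@dataclass
class TMap:
    t: np.ndarray  # electrodes x points
    df: int
    critical_t: float
    zero_variance: np.ndarray  # bool, electrodes x points


def _tmap_arrays(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """t statistics against zero along axis 0; zero-variance cells -> +/-inf."""
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    zero_var = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        t = np.where(zero_var, np.sign(mean) * np.inf, t)
        t = np.where(zero_var & (mean == 0), 0.0, t)
    return t, zero_var


def one_sample_tmap(waveforms: np.ndarray, alpha: float = 0.05) -> TMap:
    """Single-sample t at each electrode x point cell.

    ``waveforms`` is participants x electrodes x points (participants first).
    """
    data = np.asarray(waveforms, dtype=float)
    if data.ndim != 3:
        raise ValueError("waveforms must be participants x electrodes x points")
    n = data.shape[0]
    if n < 3:
        raise ValueError("need at least 3 participants")
    t, zero_var = _tmap_arrays(data)
    crit = float(scipy.stats.t.ppf(1 - alpha / 2, df=n - 1))
    return TMap(t=t, df=n - 1, critical_t=crit, zero_variance=zero_var)


# ---------------------------------------------------------------------------
# neighbor graphs
# ---------------------------------------------------------------------------


@dataclass
class NeighborGraph:
    adjacency: dict[str, set[str]]

    def __post_init__(self):
        # symmetrize
        adj = {k: set(v) for k, v in self.adjacency.items()}
        for k, vs in list(adj.items()):
            for v in vs:
                adj.setdefault(v, set()).add(k)
        self.adjacency = adj

    def neighbors(self, electrode: str) -> set[str]:
        return self.adjacency.get(electrode, set())

    def covers(self, electrodes) -> bool:
        return all(e in self.adjacency for e in electrodes)


def load_neighbors(path: str | Path) -> NeighborGraph:
    """Adjacency-list text format: ``NAME: nbr1 nbr2 ...`` per line, ``#`` comments."""
    adj: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        name, _, rest = line.partition(":")
        adj[name.strip()] = set(rest.split())
    return NeighborGraph(adj)


def default_neighbors() -> NeighborGraph:
    """Bundled 10-20 montage neighbor template."""
    return load_neighbors(_DATA_DIR / "neighbors_1020.txt")


# ---------------------------------------------------------------------------
# cluster-based permutation test
# ---------------------------------------------------------------------------


@dataclass
class Cluster:
    seed_electrode: str
    electrodes: tuple[str, ...]
    start_fraction: float  # temporal extent as fraction of the interval
    end_fraction: float
    mass: float
    p_value: float | None
    significant: bool


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    null_max_mass: np.ndarray  # per-permutation max mass (scope per config)
    critical_t: float
    n_perm: int
    alpha_cluster: float
    seed: int | None

    @property
    def any_significant(self) -> bool:
        return any(c.significant for c in self.clusters)


def _max_run_mass(active: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Per-row maximum run-sum of ``weights`` over maximal True runs of ``active``.

    ``active``/``weights`` are (rows x points); weights are nonnegative where
    active.  Vectorized via a cumulative-sum reset trick.
    """
    z = np.where(active, weights, 0.0)
    c = np.cumsum(z, axis=1)
    # c is nondecreasing, so the cummax of c at the most recent inactive point
    # equals c there; subtracting gives the running within-run sum
    base = np.maximum.accumulate(np.where(~active, c, 0.0), axis=1)
    run = np.where(active, c - base, 0.0)
    return run.max(axis=1)


def _observed_runs(active: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs [start, stop) of a 1-D boolean array."""
    runs = []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], active.view(np.int8), [0]))))
    for s, e in zip(idx[::2], idx[1::2]):
        runs.append((int(s), int(e)))
    return runs


def cluster_permutation_test(
    waveforms: np.ndarray,
    graph: NeighborGraph,
    electrodes: list[str],
    alpha_cell: float = 0.05,
    n_perm: int = 1000,
    alpha_cluster: float = 0.05,
    seed: int | None = None,
    null_scope: str = "global",
) -> ClusterResult:
    """Sign-flip permutation test on participant x electrode x point waveforms.

    A spatial cluster is each electrode together with its template neighbors
    (restricted to the analysis set).  A temporal cluster is a maximal run of
    points where ALL electrodes of the spatial cluster exceed the critical
    |t|.  Cluster mass is the spatial mean of the per-electrode sum of |t|
    within the run.  The null records, per permutation (each participant's
    whole waveform flipped by a fair coin), the maximum mass — over all
    spatial clusters when ``null_scope='global'`` (family-wise calibrated
    default) or per spatial cluster when ``null_scope='per_cluster'``.
    p-values use the add-one convention.
    """
    data = np.asarray(waveforms, dtype=float)
    if data.ndim != 3:
        raise ValueError("waveforms must be participants x electrodes x points")
    n, n_elec, n_pts = data.shape
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if len(electrodes) != n_elec:
        raise ValueError("electrode list length mismatch")
    if not graph.covers(electrodes):
        missing = [e for e in electrodes if e not in graph.adjacency]
        raise ValueError(f"neighbor graph missing electrodes: {missing}")
    if null_scope not in ("global", "per_cluster"):
        raise ValueError("null_scope must be 'global' or 'per_cluster'")

    eset = set(electrodes)
    e_index = {e: i for i, e in enumerate(electrodes)}
    spatial: list[tuple[str, tuple[int, ...]]] = []
    for e in electrodes:
        members = sorted({e} | (graph.neighbors(e) & eset), key=e_index.get)
        spatial.append((e, tuple(e_index[m] for m in members)))

    tmap = one_sample_tmap(data, alpha=alpha_cell)
    crit = tmap.critical_t
    abs_t = np.abs(tmap.t)

    # --- permutation null -------------------------------------------------
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    flat = data.reshape(n, -1)
    sumsq = np.sum(flat**2, axis=0)  # invariant under sign flips
    perm_mean = (signs @ flat) / n  # n_perm x (elec*pts)
    with np.errstate(divide="ignore", invalid="ignore"):
        perm_var = (sumsq[None, :] - n * perm_mean**2) / (n - 1)
        perm_var = np.clip(perm_var, 0.0, None)
        perm_t = perm_mean / np.sqrt(perm_var / n)
    perm_t = np.nan_to_num(perm_t, nan=0.0, posinf=np.inf, neginf=-np.inf)
    perm_abs = np.abs(perm_t).reshape(n_perm, n_elec, n_pts)

    null_per_cluster = np.zeros((len(spatial), n_perm))
    for ci, (_, members) in enumerate(spatial):
        sub = perm_abs[:, members, :]  # n_perm x m x pts
        active = (sub > crit).all(axis=1)
        weights = sub.mean(axis=1)  # spatial mean of |t|
        null_per_cluster[ci] = _max_run_mass(active, weights)
    null_global = null_per_cluster.max(axis=0)

    # --- observed clusters ------------------------------------------------
    clusters: list[Cluster] = []
    for ci, (seed_e, members) in enumerate(spatial):
        sub = abs_t[list(members), :]
        active = (sub > crit).all(axis=0)
        weights = sub.mean(axis=0)
        null = null_global if null_scope == "global" else null_per_cluster[ci]
        for s, e in _observed_runs(active):
            mass = float(weights[s:e].sum())
            p = float((np.sum(null >= mass) + 1) / (n_perm + 1))
            clusters.append(
                Cluster(
                    seed_electrode=seed_e,
                    electrodes=tuple(electrodes[m] for m in members),
                    start_fraction=s / n_pts,
                    end_fraction=e / n_pts,
                    mass=mass,
                    p_value=p,
                    significant=p <= alpha_cluster,
                )
            )
    null_out = null_global if null_scope == "global" else null_per_cluster
    return ClusterResult(
        clusters=clusters,
        null_max_mass=null_out,
        critical_t=crit,
        n_perm=n_perm,
        alpha_cluster=alpha_cluster,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# paired t / Cohen's d
# ---------------------------------------------------------------------------


@dataclass
class EffectSizes:
    t_statistic: float
    df: int
    p: float
    cohens_d: float
    mean_diff: float
    sd_diff: float


def paired_t_cohens_d(a: np.ndarray, b: np.ndarray) -> EffectSizes:
    """Paired t test with Cohen's d = mean(a-b) / sd(a-b) (n-1 denominator)."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size or a.size < 2:
        raise ValueError("a and b must have equal length >= 2")
    d = a - b
    n = d.size
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    if sd_diff == 0:
        return EffectSizes(np.nan, n - 1, np.nan, np.nan, mean_diff, 0.0)
    t = mean_diff / (sd_diff / np.sqrt(n))
    p = float(2 * scipy.stats.t.sf(abs(t), df=n - 1))
    return EffectSizes(
        t_statistic=float(t), df=n - 1, p=p,
        cohens_d=mean_diff / sd_diff, mean_diff=mean_diff, sd_diff=sd_diff,
    )


# ---------------------------------------------------------------------------
# PCA latency analysis
# ---------------------------------------------------------------------------


@dataclass
class PcaLatencyResult:
    pc1: np.ndarray
    pc2: np.ndarray
    variance_explained: np.ndarray  # singular values squared (all components)
    pc2_scores: np.ndarray  # per response-time bin
    scores: np.ndarray  # (bins*electrodes) x components projection matrix
    components: np.ndarray  # components x time


def pca_latency(bin_waveforms: np.ndarray) -> PcaLatencyResult:
    """PCA over (bin x electrode) mean waveforms; PC2 indexes latency shifts.

    Rows of the observation matrix are the per-bin, per-electrode mean
    waveforms (columns = time), each row mean-centered.  Sign conventions:
    PC1 has positive inner product with the grand-mean waveform; PC2
    correlates positively with the forward-difference derivative of PC1.
    ``pc2_scores`` is the per-bin mean (over electrodes) projection onto PC2.
    """
    W = np.asarray(bin_waveforms, dtype=float)
    if W.ndim == 2:
        W = W[:, None, :]
    if W.ndim != 3:
        raise ValueError("bin_waveforms must be bins x electrodes x time")
    n_bins, n_elec, n_time = W.shape
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    M = W.reshape(n_bins * n_elec, n_time)
    M = M - M.mean(axis=1, keepdims=True)  # row centering
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    if np.sum(S > 1e-12 * S[0]) < 2:
        raise ValueError("observation matrix has rank < 2: PC2 undefined")
    comps = Vt
    scores = U * S  # rows x components

    grand = M.mean(axis=0)
    if comps[0] @ grand < 0:
        comps[0] = -comps[0]
        scores[:, 0] = -scores[:, 0]
    d_pc1 = np.diff(comps[0])
    if comps[1][:-1] @ d_pc1 < 0:
        comps[1] = -comps[1]
        scores[:, 1] = -scores[:, 1]

    pc2_scores = scores[:, 1].reshape(n_bins, n_elec).mean(axis=1)
    return PcaLatencyResult(
        pc1=comps[0],
        pc2=comps[1],
        variance_explained=S**2,
        pc2_scores=pc2_scores,
        scores=scores,
        components=comps,
    )


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------


@dataclass
class AnovaResult:
    F: float
    df_effect: int
    df_error: int
    p: float
    ss_effect: float
    ss_error: float
    ss_subjects: float
    eta_p_sq: float
    eta_g_sq: float


def rm_anova(scores: np.ndarray) -> AnovaResult:
    """One-way repeated-measures ANOVA on a complete participants x bins table.

    Decomposes SS_total = SS_effect + SS_subjects + SS_error;
    eta_p^2 = SS_effect / (SS_effect + SS_error);
    eta_g^2 = SS_effect / (SS_effect + SS_subjects + SS_error).
    """
    Y = np.asarray(scores, dtype=float)
    if Y.ndim != 2:
        raise ValueError("scores must be participants x bins")
    n, b = Y.shape
    if b < 2 or n < 3:
        raise ValueError("need >= 2 bins and >= 3 participants")
    if not np.all(np.isfinite(Y)):
        raise ValueError("missing cells are not allowed")
    grand = Y.mean()
    ss_effect = n * float(np.sum((Y.mean(axis=0) - grand) ** 2))
    ss_subjects = b * float(np.sum((Y.mean(axis=1) - grand) ** 2))
    ss_total = float(np.sum((Y - grand) ** 2))
    ss_error = ss_total - ss_effect - ss_subjects
    df_effect = b - 1
    df_error = (b - 1) * (n - 1)
    ms_effect = ss_effect / df_effect
    ms_error = ss_error / df_error
    if ms_error > 0:
        F = ms_effect / ms_error
    else:
        F = 0.0 if ms_effect == 0 else np.inf
    p = float(scipy.stats.f.sf(F, df_effect, df_error)) if np.isfinite(F) else 0.0
    denom_p = ss_effect + ss_error
    denom_g = ss_effect + ss_subjects + ss_error
    return AnovaResult(
        F=float(F),
        df_effect=df_effect,
        df_error=df_error,
        p=p,
        ss_effect=ss_effect,
        ss_error=ss_error,
        ss_subjects=ss_subjects,
        eta_p_sq=ss_effect / denom_p if denom_p > 0 else 0.0,
        eta_g_sq=ss_effect / denom_g if denom_g > 0 else 0.0,
    )
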