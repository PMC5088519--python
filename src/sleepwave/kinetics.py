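"""Trajectory clustering and exponential decay time constants.

Significant genes' log2 fold changes are assembled across the recovery
time course (t = 0 h at the end of sleep deprivation, then 1, 2, 3, 6 h of
recovery sleep, each contrast taken against its time-matched control),
clustered hierarchically, and classified as fast responders (back to
baseline within 1-3 h), slow responders (recovered by 6 h) or
late-induced (unaffected by deprivation, induced by the sixth hour).

For each cluster's mean trajectory the decay time constant tau_d of

    logFC_t = LA + (logFC_0 - LA) * exp(-t / tau_d)

is estimated by nonlinear least squares with logFC_0 fixed to the t = 0
mean and the lower asymptote LA approximated as the minimum of the mean
trajectory (a coarse grid over tau_d seeds a bounded local refinement).
Trajectories that recover upward (genes downregulated by deprivation) are
negated before fitting so the decreasing form applies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist

from .de import DEResult
from .simulate import RECOVERY_HOURS

__all__ = [
    "TrajectoryMatrix",
    "ClusterAssignment",
    "DecayFit",
    "build_trajectories",
    "cluster_trajectories",
    "classify_clusters",
    "fit_decay",
    "summarize_kinetics",
]


@dataclass
class TrajectoryMatrix:
    """Per-gene logFC time courses over the recovery time points.

    Restricted to genes significant (FDR below the cutoff) in at least one
    contrast; carries per-time-point significance flags and the
    time-of-day (circadian) flag from the control comparisons.
    """

    logfc: pd.DataFrame  # genes x time points (columns = hours, ordered)
    significant: pd.DataFrame  # same shape, bool
    times: np.ndarray
    circadian: pd.Series
    fdr: float


def build_trajectories(
    de_results: dict,
    circadian_flags: pd.Series = None,
    fdr: float = 0.01,
) -> TrajectoryMatrix:
    """Assemble the trajectory matrix from per-contrast DE results.

    ``de_results`` maps the treated group label (SD, RS1, RS2, RS3, RS6)
    to its :class:`DEResult`; all five must be present.
    """
    missing = [g for g in RECOVERY_HOURS if g not in de_results]
    if missing:
        raise ValueError(f"missing contrasts for groups: {missing}")
    order = sorted(RECOVERY_HOURS, key=RECOVERY_HOURS.get)
    times = np.array([RECOVERY_HOURS[g] for g in order])
    genes = de_results[order[0]].table.index
    sig_any = pd.Series(False, index=genes)
    logfc = {}
    sig = {}
    for g in order:
        table = de_results[g].table
        logfc[RECOVERY_HOURS[g]] = table["logFC"]
        s = table["fdr"] < fdr
        sig[RECOVERY_HOURS[g]] = s
        sig_any |= s
    keep = genes[sig_any].sort_values()
    if len(keep) == 0:
        warnings.warn("no genes significant in any contrast", stacklevel=2)
    logfc_df = pd.DataFrame(logfc).loc[keep]
    sig_df = pd.DataFrame(sig).loc[keep]
    if circadian_flags is None:
        circ = pd.Series(False, index=keep, name="time_of_day")
    else:
        circ = circadian_flags.reindex(keep).fillna(False).rename("time_of_day")
    return TrajectoryMatrix(
        logfc=logfc_df, significant=sig_df, times=times, circadian=circ, fdr=fdr
    )


@dataclass
class ClusterAssignment:
    """Hierarchical clustering of trajectories cut at ``n_clusters``."""

    labels: pd.Series  # gene -> cluster id (1..n_clusters)
    means: pd.DataFrame  # cluster x time
    sds: pd.DataFrame
    classes: dict = None  # cluster id -> responder class (set by classify)

    @property
    def cluster_ids(self):
        return list(self.means.index)


def cluster_trajectories(
    tm: TrajectoryMatrix,
    n_clusters: int = 7,
    standardize: bool = True,
    sd_floor: float = 0.2,
) -> ClusterAssignment:
    """Agglomerative clustering (Euclidean, complete linkage) of logFC
    trajectories, deterministic through gene-id ordering.

    With ``standardize`` (default) each gene's trajectory is centered and
    scaled by sqrt(sd^2 + sd_floor^2) before computing distances, so genes
    group by the pattern of their response rather than its magnitude. The
    floor (log2 units, of the order of the logFC estimation noise) keeps
    noise-level trajectories from being amplified into arbitrary patterns:
    they shrink toward the origin and share one cluster instead of
    scattering. Cluster means and standard deviations are always reported
    on the raw logFC scale. ``standardize=False`` clusters raw logFC.
    """
    if n_clusters < 2:
        raise ValueError("n_clusters must be >= 2")
    if len(tm.logfc) < n_clusters:
        raise ValueError(
            f"cannot form {n_clusters} clusters from {len(tm.logfc)} genes"
        )
    data = tm.logfc.sort_index()
    X = data.to_numpy(float)
    if standardize:
        sd = X.std(axis=1, keepdims=True)
        scale = np.sqrt(sd**2 + sd_floor**2)
        scale[scale == 0] = 1.0
        X = (X - X.mean(axis=1, keepdims=True)) / scale
    Z = hierarchy.linkage(pdist(X), method="complete")
    labels = pd.Series(
        hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust"),
        index=data.index,
        name="cluster",
    ).reindex(tm.logfc.index)
    means = tm.logfc.groupby(labels).mean()
    sds = tm.logfc.groupby(labels).std(ddof=0)
    return ClusterAssignment(labels=labels, means=means, sds=sds)


def classify_clusters(
    ca: ClusterAssignment,
    tm: TrajectoryMatrix,
    recovery_fraction: float = 0.25,
) -> dict:
    """Assign a responder class to every cluster.

    late_induced: the majority of member genes are non-significant at the
    end of deprivation (t = 0) but significant at t = 6. fast: the mean
    |logFC| at t = 3 has dropped below ``recovery_fraction`` of its t = 0
    value and the majority of genes are non-significant by t = 3.
    Everything else is slow.
    """
    t0, t3, t6 = 0.0, 3.0, 6.0
    classes = {}
    for cid in ca.cluster_ids:
        members = ca.labels.index[ca.labels == cid]
        sig = tm.significant.loc[members]
        m = ca.means.loc[cid]
        sd_majority_sig = sig[t0].mean() > 0.5
        t6_majority_sig = sig[t6].mean() > 0.5
        if not sd_majority_sig and t6_majority_sig:
            classes[cid] = "late_induced"
            continue
        recovered = abs(m[t3]) < recovery_fraction * abs(m[t0]) if m[t0] != 0 else False
        if recovered and sig[t3].mean() < 0.5:
            classes[cid] = "fast"
        else:
            classes[cid] = "slow"
    ca.classes = classes
    return classes


@dataclass
class DecayFit:
    """Single-cluster exponential decay fit.

    ``logfc0`` and ``la`` are reported on the original (signed) logFC
    scale; ``orientation`` is -1 when the trajectory was negated so the
    decreasing form of the model applied.
    """

    logfc0: float
    la: float
    tau: float
    rss: float
    converged: bool
    degenerate: bool = False
    orientation: int = 1


def _decay_rss(tau: float, y: np.ndarray, t: np.ndarray, la: float, y0: float) -> float:
    pred = la + (y0 - la) * np.exp(-t / tau)
    return float(((y - pred) ** 2).sum())


def fit_decay(
    trajectory,
    times,
    la: float = None,
    tau_bounds=(0.1, 12.0),
    grid_size: int = 240,
) -> DecayFit:
    """Fit tau_d to a cluster mean trajectory.

    The trajectory is oriented by the sign of its t = 0 value (negated when
    negative), logFC_0 is fixed to the t = 0 mean and LA to the minimum of
    the oriented trajectory unless ``la`` is given (on the oriented scale).
    tau_d is the single free parameter: a coarse grid over ``tau_bounds``
    seeds a bounded scalar minimization of the residual sum of squares.
    A flat trajectory (logFC_0 equal to LA) is flagged degenerate.
    """
    y = np.asarray(trajectory, float)
    t = np.asarray(times, float)
    if y.size != t.size:
        raise ValueError("trajectory and times differ in length")
    if y.size < 3:
        raise ValueError("need at least 3 time points to fit a decay")
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    orientation = -1 if y[0] < 0 else 1
    yo = orientation * y
    la_o = float(np.min(yo)) if la is None else float(la)
    y0 = float(yo[0])
    if np.isclose(y0, la_o):
        return DecayFit(
            logfc0=float(y[0]),
            la=orientation * la_o,
            tau=float("nan"),
            rss=float("nan"),
            converged=False,
            degenerate=True,
            orientation=orientation,
        )
    taus = np.geomspace(tau_bounds[0], tau_bounds[1], grid_size)
    rss = np.array([_decay_rss(tau, yo, t, la_o, y0) for tau in taus])
    best = int(np.argmin(rss))
    lo = taus[max(best - 1, 0)]
    hi = taus[min(best + 1, len(taus) - 1)]
    if lo == hi:
        tau_hat, final_rss, converged = float(taus[best]), float(rss[best]), True
    else:
        res = minimize_scalar(
            _decay_rss,
            bounds=(lo, hi),
            args=(yo, t, la_o, y0),
            method="bounded",
            options={"xatol": 1e-10},
        )
        if res.success and res.fun <= rss[best] + 1e-12:
            tau_hat, final_rss, converged = float(res.x), float(res.fun), True
        else:
            tau_hat, final_rss, converged = float(taus[best]), float(rss[best]), False
    return DecayFit(
        logfc0=float(y[0]),
        la=orientation * la_o,
        tau=tau_hat,
        rss=final_rss,
        converged=converged,
        orientation=orientation,
    )


def summarize_kinetics(fits: dict, classes: dict, sizes: dict = None, min_size: int = 0) -> dict:
    """Unweighted mean tau_d of converged fits within each responder class.

    ``sizes``/``min_size`` optionally drop clusters with fewer member genes
    than ``min_size`` from the averages: complete linkage assigns every
    gene somewhere, and the small leftover clusters are heterogeneous
    grab-bags whose mean trajectory does not follow a single kinetic law.
    """
    by_class: dict = {}
    for cid, fit in fits.items():
        if not fit.converged or fit.degenerate:
            continue
        if sizes is not None and sizes.get(cid, 0) < min_size:
            continue
        by_class.setdefault(classes[cid], []).append(fit.tau)
    if not by_class:
        warnings.warn("no converged decay fits to summarize", stacklevel=2)
    return {cls: float(np.mean(taus)) for cls, taus in by_class.items()}
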