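"""Clustering of developmental expression profiles into waves.

Within-gene z-normalization puts every gene's time course on a common scale
so that temporal shape, not absolute expression level, drives clustering —
this is what exposes the successive "waves" of expression where different
gene sets peak at different developmental stages.

Two clustering routes are provided: hierarchical-initialized K-means
(average-linkage hierarchical clustering on correlation distance supplies
deterministic starting centroids for standard K-means), and the cluster
affinity search technique (CAST), a greedy graph method that grows and
prunes one cluster at a time against a fixed affinity threshold.  Pairwise
affinity is the Pearson correlation mapped onto the unit interval,
``(r + 1) / 2``.  An affinity search against a reference profile (by default
a monotonically decreasing "maternal" ramp peaking at the first timepoint)
screens for genes that track a given temporal pattern, and a simple modality
classifier labels each z-profile as peaking at the start, unimodal, bimodal
(elevated at both the first and last timepoints), or flat.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

DEFAULT_AFFINITY = 0.7
DEFAULT_K = 10


@dataclass
class ProfileMatrix:
    """Gene/probe x timepoint mean-expression profiles.

    ``degenerate`` flags constant rows (undefined z-scores, stored as zeros).
    """

    data: pd.DataFrame
    z_normalized: bool = False
    degenerate: pd.Series | None = None

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    @property
    def timepoints(self) -> np.ndarray:
        return np.asarray(self.data.columns, dtype=float)


@dataclass
class ClusterResult:
    """A partition of genes with the method, parameters and mean profiles."""

    assignment: pd.Series  # gene -> integer cluster id
    method: str
    parameters: dict = field(default_factory=dict)
    cluster_profiles: pd.DataFrame | None = None

    @property
    def n_clusters(self) -> int:
        return self.assignment.nunique()

    def members(self, cluster_id: int) -> list:
        return self.assignment.index[self.assignment == cluster_id].tolist()


def timepoint_means(values: pd.DataFrame, log2: bool = True) -> ProfileMatrix:
    """Collapse a probe x array matrix to mean expression per timepoint.

    Columns must be array ids of the form ``<time>hpf_<replicate>``; the mean
    is over the biological replicates at each timepoint.  By default signals
    are log2-transformed first, so that profile shape reflects fold change
    rather than absolute intensity.
    """
    from .temporal_de import _parse_columns

    x = values.to_numpy(dtype=float)
    if log2:
        if (x <= 0).any():
            raise ValueError("non-positive signal; floor the data before log transform")
        x = np.log2(x)
    cols = _parse_columns(values.columns)
    frame = pd.DataFrame(x, index=values.index, columns=cols)
    means = frame.T.groupby(level=0).mean().T
    means.columns = [float(c) for c in means.columns]
    return ProfileMatrix(data=means.sort_index(axis=1))


def z_normalize(profiles: ProfileMatrix) -> ProfileMatrix:
    """Within-gene z-scores: subtract row mean, divide by population SD.

    Constant rows become all zeros and are flagged degenerate.  Idempotent on
    non-degenerate rows.
    """
    if profiles.data.shape[1] < 2:
        raise ValueError("z-normalization needs at least 2 timepoints")
    x = profiles.data.to_numpy(dtype=float)
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=0, keepdims=True)
    degenerate = sd[:, 0] == 0
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (x - mean) / sd_safe
    z[degenerate] = 0.0
    return ProfileMatrix(
        data=pd.DataFrame(z, index=profiles.data.index, columns=profiles.data.columns),
        z_normalized=True,
        degenerate=pd.Series(degenerate, index=profiles.data.index),
    )


def _correlation_distances(x: np.ndarray) -> np.ndarray:
    """Condensed pairwise correlation distances; constant rows -> distance 1."""
    with np.errstate(divide="ignore", invalid="ignore"):
        d = pdist(x, metric="correlation")
    return np.nan_to_num(d, nan=1.0)


def kmeans_clusters(
    profiles: ProfileMatrix, k: int = DEFAULT_K, seed: int = 0
) -> ClusterResult:
    """Hierarchical-initialized K-means over expression profiles.

    Average-linkage hierarchical clustering on correlation distance, cut at
    ``k`` groups, supplies the starting centroids; standard K-means then
    iterates to convergence (tolerance 1e-8, at most 300 iterations).  The
    result is deterministic given the input and seed.
    """
    x = profiles.data.to_numpy(dtype=float)
    n = len(x)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds number of rows ({n})")
    if k == 1:
        labels = np.zeros(n, dtype=int)
    else:
        z = linkage(_correlation_distances(x), method="average")
        init_labels = fcluster(z, t=k, criterion="maxclust")
        centroids = np.vstack([x[init_labels == c].mean(axis=0) for c in np.unique(init_labels)])
        km = KMeans(
            n_clusters=len(centroids),
            init=centroids,
            n_init=1,
            max_iter=300,
            tol=1e-8,
            random_state=seed,
        )
        labels = km.fit_predict(x)
    assignment = pd.Series(labels, index=profiles.data.index, name="cluster")
    return ClusterResult(
        assignment=assignment,
        method="kmeans",
        parameters={"k": k, "seed": seed},
        cluster_profiles=_cluster_profiles(profiles, assignment),
    )


def _cluster_profiles(profiles: ProfileMatrix, assignment: pd.Series) -> pd.DataFrame:
    return profiles.data.groupby(assignment).mean()


def affinity_matrix(profiles: ProfileMatrix) -> np.ndarray:
    """Pairwise affinities ``(pearson r + 1) / 2`` in [0, 1].

    Undefined correlations (constant profiles) map to affinity 0.5; the
    diagonal (self-affinity) is 1.
    """
    x = profiles.data.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(x)
    r = np.nan_to_num(r, nan=0.0)
    aff = (r + 1.0) / 2.0
    np.fill_diagonal(aff, 1.0)
    return aff


def cast_clusters(
    profiles: ProfileMatrix,
    affinity_threshold: float = DEFAULT_AFFINITY,
    raw_correlation: bool = False,
) -> ClusterResult:
    """Greedy cluster affinity search over the pairwise affinity graph.

    Repeatedly opens a cluster seeded by the unassigned gene with the highest
    total affinity to the other unassigned genes, then alternates adding
    unassigned genes whose mean affinity to the cluster meets the threshold
    and removing members whose mean affinity (self included) falls below it,
    until the cluster is stable; ties break by input gene order.

    With ``raw_correlation`` the threshold applies to Pearson r directly
    instead of the [0, 1]-mapped affinity.
    """
    if profiles.data.shape[1] < 2:
        raise ValueError("affinity requires at least 2 timepoints")
    n = len(profiles.data)
    aff = affinity_matrix(profiles)
    if raw_correlation:
        aff = 2.0 * aff - 1.0
        self_aff = 1.0
    else:
        self_aff = 1.0
    t = affinity_threshold

    labels = np.full(n, -1, dtype=int)
    unassigned = list(range(n))
    cluster_id = 0
    while unassigned:
        if len(unassigned) == 1:
            seedling = unassigned[0]
        else:
            sub = aff[np.ix_(unassigned, unassigned)].copy()
            np.fill_diagonal(sub, 0.0)
            conn = sub.sum(axis=1)
            seedling = unassigned[int(np.argmax(conn))]  # argmax is first on ties
        cluster = [seedling]
        pool = [g for g in unassigned if g != seedling]
        for _ in range(10 * n + 10):
            changed = False
            # addition passes
            while pool:
                means = aff[np.ix_(pool, cluster)].mean(axis=1)
                ok = means >= t
                if not ok.any():
                    break
                # ties break by gene order: argmax returns the first maximum
                ok_idx = np.flatnonzero(ok)
                best = int(ok_idx[int(np.argmax(means[ok_idx]))])
                gene = pool.pop(best)
                cluster.append(gene)
                changed = True
            # removal passes (mean affinity over members incl. self)
            while len(cluster) > 1:
                means = aff[np.ix_(cluster, cluster)].copy()
                np.fill_diagonal(means, self_aff)
                mvals = means.mean(axis=1)
                low = mvals < t
                if not low.any():
                    break
                worst = int(np.flatnonzero(low)[int(np.argmin(mvals[low]))])
                gene = cluster.pop(worst)
                pool.append(gene)
                pool.sort()
                changed = True
            if not changed:
                break
        for g in cluster:
            labels[g] = cluster_id
        unassigned = [g for g in unassigned if labels[g] == -1]
        cluster_id += 1
    assignment = pd.Series(labels, index=profiles.data.index, name="cluster")
    return ClusterResult(
        assignment=assignment,
        method="cast",
        parameters={"affinity_threshold": affinity_threshold, "raw_correlation": raw_correlation},
        cluster_profiles=_cluster_profiles(profiles, assignment),
    )


def maternal_seed_profile(timepoints: Sequence[float]) -> np.ndarray:
    """Default maternal reference: strictly decreasing ramp, z-normalized."""
    ramp = -np.arange(len(timepoints), dtype=float)
    return (ramp - ramp.mean()) / ramp.std(ddof=0)


def affinity_search(
    profiles: ProfileMatrix,
    seed_profile: Sequence[float] | None = None,
    affinity_threshold: float = DEFAULT_AFFINITY,
) -> list:
    """Genes whose affinity to a reference profile meets the threshold.

    The default reference is the maternal-decay ramp (peak at the first
    timepoint, monotone decline), mirroring a screen for maternally
    deposited transcript.  Flat genes have undefined correlation, which maps
    to affinity 0.5 and is excluded at the default threshold.
    """
    tps = profiles.data.columns
    seed = (
        maternal_seed_profile(tps)
        if seed_profile is None
        else np.asarray(seed_profile, dtype=float)
    )
    if len(seed) != len(tps):
        raise ValueError("seed profile length must equal number of timepoints")
    x = profiles.data.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    sc = seed - seed.mean()
    denom = np.sqrt((xc**2).sum(axis=1) * (sc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ sc) / denom
    r = np.nan_to_num(r, nan=0.0)
    aff = (r + 1.0) / 2.0
    hits = aff >= affinity_threshold
    return profiles.data.index[hits].tolist()


@dataclass(frozen=True)
class ModalityCall:
    kind: str  # peak_at_start | unimodal | bimodal | flat
    peak_time: float | None = None


def classify_modality(
    profile: Sequence[float],
    timepoints: Sequence[float] | None = None,
    z_threshold: float = 0.5,
    degenerate: bool = False,
) -> ModalityCall:
    """Classify one z-normalized profile by its above-threshold local maxima.

    Two qualifying maxima at the first and last timepoints give ``bimodal``;
    otherwise the dominant peak at the first timepoint gives
    ``peak_at_start`` and anywhere else ``unimodal`` with its time;
    degenerate (constant) profiles are ``flat``.
    """
    z = np.asarray(profile, dtype=float)
    tps = np.asarray(timepoints if timepoints is not None else range(len(z)), dtype=float)
    if degenerate or np.allclose(z, z[0]):
        return ModalityCall("flat")
    n = len(z)
    is_max = np.zeros(n, dtype=bool)
    for i in range(n):
        left = z[i - 1] if i > 0 else -np.inf
        right = z[i + 1] if i < n - 1 else -np.inf
        is_max[i] = z[i] > left and z[i] > right
    qual = np.flatnonzero(is_max & (z > z_threshold))
    if len(qual) >= 2 and 0 in qual and (n - 1) in qual:
        return ModalityCall("bimodal")
    peak = int(qual[np.argmax(z[qual])]) if len(qual) else int(np.argmax(z))
    if peak == 0:
        return ModalityCall("peak_at_start", peak_time=float(tps[0]))
    return ModalityCall("unimodal", peak_time=float(tps[peak]))
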