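"""Unsupervised discovery of oligonucleosome patterns.

Single-molecule autocorrelograms are assembled into a fixed-width matrix
(molecules shorter than 500 bp are excluded; autocorrelograms are computed
on at most the 5' 1000 bp of each molecule and truncated to the 250 lags
every eligible molecule shares), a k-nearest-neighbour graph is built on the
rows, and Leiden community detection with the modularity objective assigns
every fibre to a cluster.  Cluster summaries report size fractions,
single-molecule NRL medians and MADs, the fraction of molecules without a
detectable periodicity peak, and mean modification / autocorrelation
profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import igraph
import leidenalg
import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation
from sklearn.neighbors import NearestNeighbors

from .footprint import Autocorrelogram, NrlCall, autocorrelogram, rolling_mean_nan
from .io import ModificationTrack

logger = logging.getLogger(__name__)

MIN_MOLECULES = 50  # below this a kNN graph partition is not meaningful
SMALL_CLUSTER = 100  # clusters smaller than this are reported but flagged


@dataclass
class FibreMatrix:
    molecule_ids: list[str]
    matrix: np.ndarray  # n_molecules x n_lags, fully finite after imputation
    n_excluded: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.molecule_ids):
            raise ValueError("matrix shape does not match molecule_ids")


@dataclass
class ClusterAssignment:
    molecule_ids: list[str]
    labels: np.ndarray  # contiguous ints, 0 = largest cluster
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size != len(self.molecule_ids):
            raise ValueError("labels length does not match molecule_ids")

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"molecule_id": self.molecule_ids, "cluster": self.labels}
        )


@dataclass
class ClusterSummary:
    table: pd.DataFrame  # one row per cluster
    mod_profiles: np.ndarray  # n_clusters x profile_len mean modification
    mean_acg: np.ndarray | None  # n_clusters x n_lags mean autocorrelogram


def autocorrelogram_matrix(
    tracks: Sequence[ModificationTrack],
    smooth_window: int = 33,
    min_len: int = 500,
    max_len_used: int = 1000,
) -> tuple[list[Autocorrelogram], int]:
    """Smooth tracks, truncate to the 5' ``max_len_used`` bp, autocorrelate.

    Molecules shorter than ``min_len`` or with constant smoothed signal are
    skipped and counted.  Feeds :func:`build_matrix`.
    """
    acgs: list[Autocorrelogram] = []
    skipped = 0
    for t in tracks:
        if len(t) < min_len:
            skipped += 1
            continue
        sm = rolling_mean_nan(t.prob, smooth_window)[:max_len_used]
        try:
            acgs.append(autocorrelogram(sm, molecule_id=t.molecule_id))
        except ValueError:
            skipped += 1
    if skipped:
        logger.info("%d molecules skipped before autocorrelation", skipped)
    return acgs, skipped


def build_matrix(
    autocorrelograms: Sequence[Autocorrelogram],
    min_len: int = 500,
    max_len_used: int = 1000,
    min_molecules: int = MIN_MOLECULES,
) -> FibreMatrix:
    """Fixed-width fibre matrix: ``min_len // 2`` lags per row.

    Rows shorter than the common lag range (molecules under ``min_len`` bp)
    are excluded and counted; residual missing lags are imputed with the
    row's observed mean so the matrix is dense for graph construction.
    """
    n_lags = min_len // 2
    ids: list[str] = []
    rows: list[np.ndarray] = []
    excluded = 0
    for acg in autocorrelograms:
        if acg.values.size < n_lags:
            excluded += 1
            continue
        row = acg.values[:n_lags].astype(float).copy()
        miss = ~np.isfinite(row)
        if miss.all():
            excluded += 1
            continue
        if miss.any():
            row[miss] = row[~miss].mean()
        ids.append(acg.molecule_id)
        rows.append(row)
    if excluded:
        logger.info("%d autocorrelograms excluded from the fibre matrix", excluded)
    if len(rows) < min_molecules:
        raise ValueError(
            f"only {len(rows)} eligible molecules (< {min_molecules}): "
            "too few for graph clustering"
        )
    return FibreMatrix(ids, np.vstack(rows), n_excluded=excluded)


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Contiguous labels ordered by descending cluster size (stable ties)."""
    uniq, counts = np.unique(labels, return_counts=True)
    order = uniq[np.lexsort((uniq, -counts))]
    mapping = {old: new for new, old in enumerate(order)}
    return np.array([mapping[v] for v in labels], dtype=int)


def knn_graph(matrix: np.ndarray, k_neighbors: int) -> igraph.Graph:
    """Undirected, unweighted Euclidean kNN graph over matrix rows."""
    n = matrix.shape[0]
    if k_neighbors >= n:
        raise ValueError(f"k_neighbors ({k_neighbors}) must be < n ({n})")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(matrix)
    _, idx = nn.kneighbors(matrix)
    edges = set()
    for i in range(n):
        for j in idx[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    return igraph.Graph(n=n, edges=sorted(edges))


def leiden_cluster(
    matrix: FibreMatrix | np.ndarray,
    k_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
    molecule_ids: Sequence[str] | None = None,
) -> ClusterAssignment:
    """Leiden community detection (modularity objective) on the kNN graph.

    Deterministic under ``seed``; clusters are relabelled by descending
    size.  Resolution and ``k_neighbors`` are the knobs to adjust when the
    partition fragments into many small clusters.
    """
    if isinstance(matrix, FibreMatrix):
        ids = list(matrix.molecule_ids)
        mat = matrix.matrix
    else:
        mat = np.asarray(matrix, dtype=float)
        ids = list(molecule_ids) if molecule_ids is not None else [
            str(i) for i in range(mat.shape[0])
        ]
    if not np.isfinite(mat).all():
        raise ValueError("fibre matrix must be finite (impute first)")
    g = knn_graph(mat, k_neighbors)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    labels = _relabel_by_size(np.asarray(part.membership))
    params = {"k_neighbors": k_neighbors, "resolution": resolution, "seed": seed}
    return ClusterAssignment(ids, labels, params)


def summarize_clusters(
    assignment: ClusterAssignment,
    nrl_calls: Sequence[NrlCall] | None = None,
    tracks: Sequence[ModificationTrack] | None = None,
    fibre_matrix: FibreMatrix | None = None,
    profile_len: int = 1000,
) -> ClusterSummary:
    """Per-cluster sizes, NRL statistics and mean profiles.

    Size fractions sum to 1 and every summary is invariant to permuting the
    cluster labels (up to row order).  Clusters smaller than
    ``SMALL_CLUSTER`` molecules are flagged, not merged.
    """
    labels = assignment.labels
    ncl = assignment.n_clusters
    total = labels.size
    by_id = {mid: lab for mid, lab in zip(assignment.molecule_ids, labels)}

    nrl_by_cluster: dict[int, list[float]] = {c: [] for c in range(ncl)}
    miss_by_cluster = {c: 0 for c in range(ncl)}
    n_called = {c: 0 for c in range(ncl)}
    if nrl_calls is not None:
        for call in nrl_calls:
            c = by_id.get(call.molecule_id)
            if c is None:
                continue
            n_called[c] += 1
            if call.peak_found:
                nrl_by_cluster[c].append(call.nrl_lag)
            else:
                miss_by_cluster[c] += 1

    rows = []
    for c in range(ncl):
        size = int((labels == c).sum())
        vals = np.asarray(nrl_by_cluster[c], dtype=float)
        rows.append(
            {
                "cluster": c,
                "n": size,
                "size_fraction": size / total,
                "median_nrl": float(np.median(vals)) if vals.size else np.nan,
                "nrl_mad": float(median_abs_deviation(vals)) if vals.size else np.nan,
                "frac_no_peak": (
                    miss_by_cluster[c] / n_called[c] if n_called[c] else np.nan
                ),
                "small_cluster": size < SMALL_CLUSTER,
            }
        )
    table = pd.DataFrame(rows)

    mod_profiles = np.full((ncl, profile_len), np.nan)
    if tracks is not None:
        sums = np.zeros((ncl, profile_len))
        cnts = np.zeros((ncl, profile_len))
        for t in tracks:
            c = by_id.get(t.molecule_id)
            if c is None:
                continue
            v = t.prob[:profile_len]
            fin = np.isfinite(v)
            sums[c, : v.size][fin] += v[fin]
            cnts[c, : v.size][fin] += 1
        with np.errstate(invalid="ignore"):
            mod_profiles = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)

    mean_acg = None
    if fibre_matrix is not None:
        fm_lab = np.array(
            [by_id[mid] for mid in fibre_matrix.molecule_ids], dtype=int
        )
        mean_acg = np.vstack(
            [
                fibre_matrix.matrix[fm_lab == c].mean(axis=0)
                if (fm_lab == c).any()
                else np.full(fibre_matrix.matrix.shape[1], np.nan)
                for c in range(ncl)
            ]
        )
    return ClusterSummary(table, mod_profiles, mean_acg)
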