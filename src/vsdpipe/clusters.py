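"""Activity clustering and dorsoventral integration.

Cells are clustered per behavior on the correlation distance of their
dF/F traces (d = 1 - Pearson r), by average-linkage hierarchical
clustering with a fixed-distance tree cut.  Each cell's dorsoventrality
index (DVI) is the fraction of dorsally located cells in that cell's
cluster; cells in clusters with fewer than three members are excluded.
The integration coefficient

    CI = < 1 - 2 |DVI - 1/2| >

(averaged over included cells) is 0 when every cluster lies wholly on
one surface and 1 when every cluster is spread equally over both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "ClusterAssignment",
    "correlation_distance",
    "cut_dendrogram",
    "dorsoventrality",
    "integration_coefficient",
    "behavior_summary",
    "ActivityClusterer",
]

MIN_CLUSTER_SIZE = 3


@dataclass
class ClusterAssignment:
    """Cluster labels per cell, with small clusters flagged excluded."""

    labels: pd.Series                 # cluster id per cell
    included: pd.Series               # False for cells in clusters < min size
    distance: pd.DataFrame
    linkage: np.ndarray
    min_cluster_size: int = MIN_CLUSTER_SIZE


def correlation_distance(traces: pd.DataFrame) -> pd.DataFrame:
    """Correlation-distance matrix d_ij = 1 - Pearson r_ij of cell traces.

    ``traces`` has one column per cell.  Zero-variance cells are excluded
    with a warning (their correlation is undefined).
    """
    if traces.shape[1] < 2:
        raise ValueError("need at least 2 cells")
    sd = traces.std(axis=0, ddof=0)
    bad = sd[sd == 0].index.tolist()
    if bad:
        warnings.warn(f"excluding zero-variance cells: {bad}", stacklevel=2)
        traces = traces.drop(columns=bad)
    if traces.shape[1] < 2:
        raise ValueError("fewer than 2 cells with nonzero variance")
    r = np.corrcoef(traces.to_numpy().T)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(d, index=traces.columns, columns=traces.columns)


def cut_dendrogram(distance: pd.DataFrame, linkage_method: str = "average",
                   cut_distance: float = 0.7,
                   min_cluster_size: int = MIN_CLUSTER_SIZE
                   ) -> ClusterAssignment:
    """Hierarchical clustering with a fixed-distance tree cut.

    Deterministic for fixed inputs.  Cells landing in clusters smaller
    than ``min_cluster_size`` are flagged excluded (not dropped).
    """
    if distance.shape[0] < 2:
        raise ValueError("need at least 2 cells to cluster")
    condensed = squareform(distance.to_numpy(), checks=False)
    z = hierarchy.linkage(condensed, method=linkage_method)
    labels = hierarchy.fcluster(z, t=cut_distance, criterion="distance")
    labels = pd.Series(labels, index=distance.index, name="cluster")
    sizes = labels.value_counts()
    included = labels.map(sizes) >= min_cluster_size
    included.name = "included"
    return ClusterAssignment(labels=labels, included=included,
                             distance=distance, linkage=z,
                             min_cluster_size=min_cluster_size)


def dorsoventrality(assignment: ClusterAssignment,
                    surfaces: pd.Series) -> pd.Series:
    """Per-cell DVI: fraction of dorsal cells in that cell's cluster.

    Identical for all members of one cluster; excluded cells carry no DVI.
    ``surfaces`` maps cell id to "ventral"/"dorsal".
    """
    missing = [c for c in assignment.labels.index if c not in surfaces.index]
    if missing:
        raise ValueError(f"missing surface label for cells {missing[:5]}")
    surf = surfaces.loc[assignment.labels.index]
    if not surf.isin(["ventral", "dorsal"]).all():
        raise ValueError("surface labels must be 'ventral' or 'dorsal'")
    is_dorsal = (surf == "dorsal").astype(float)
    frac = is_dorsal.groupby(assignment.labels).mean()
    dvi = assignment.labels.map(frac)
    dvi.name = "DVI"
    return dvi[assignment.included]


def integration_coefficient(dvis: pd.Series | np.ndarray) -> float:
    """CI = mean over included cells of 1 - 2 |DVI - 1/2|, in [0, 1]."""
    dvis = np.asarray(dvis, dtype=float)
    if dvis.size == 0:
        raise ValueError("no included cells: CI undefined")
    return float(np.mean(1.0 - 2.0 * np.abs(dvis - 0.5)))


def behavior_summary(traces: pd.DataFrame, surfaces: pd.Series,
                     linkage_method: str = "average",
                     cut_distance: float = 0.7,
                     min_cluster_size: int = MIN_CLUSTER_SIZE
                     ) -> tuple[pd.DataFrame, float]:
    """Cluster one behavior's traces and reduce to per-cell DVI and CI.

    Returns a per-cell table (cluster, surface, DVI, included) and the CI.
    """
    d = correlation_distance(traces)
    asg = cut_dendrogram(d, linkage_method, cut_distance, min_cluster_size)
    dvi = dorsoventrality(asg, surfaces)
    table = pd.DataFrame({
        "cluster": asg.labels,
        "surface": surfaces.loc[asg.labels.index],
        "included": asg.included,
    })
    table["DVI"] = dvi.reindex(table.index)
    ci = integration_coefficient(dvi.to_numpy())
    return table, ci


class ActivityClusterer(BaseEstimator, ClusterMixin):
    """Estimator interface: correlation-distance clustering of cell traces.

    ``fit(X)`` expects rows = cells, columns = time points (the transpose
    of the trace table).  Small clusters are flagged in ``included_``.
    """

    def __init__(self, linkage_method: str = "average",
                 cut_distance: float = 0.7,
                 min_cluster_size: int = MIN_CLUSTER_SIZE):
        self.linkage_method = linkage_method
        self.cut_distance = cut_distance
        self.min_cluster_size = min_cluster_size

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        df = pd.DataFrame(X.T)  # columns = cells
        d = correlation_distance(df)
        asg = cut_dendrogram(d, self.linkage_method, self.cut_distance,
                             self.min_cluster_size)
        self.labels_ = asg.labels.to_numpy()
        self.included_ = asg.included.to_numpy()
        self.distance_ = d
        self.linkage_ = asg.linkage
        return self
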