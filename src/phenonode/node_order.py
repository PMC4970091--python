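"""Node-order estimation: cluster detections by height, fit node lines.

Detections pooled over the whole image sequence are clustered on their
y coordinate alone with affinity propagation (damping 0.5, similarity =
negative squared difference, preference = median similarity), which
chooses the number of clusters — i.e. the number of nodes — on its own.
Clusters are ranked into node orders by decreasing mean y (order 1 is
lowest on the plant, largest y in image coordinates), and each order
gets a "node line": an ordinary least-squares fit of y on capture time
(UNIX seconds) that interpolates missed detections and averages out
spurious ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning


@dataclass
class APConfig:
    damping: float = 0.5
    preference: float | None = None  # None -> median of similarities
    max_iterations: int = 1000
    convergence_window: int = 100

    def __post_init__(self):
        if not (0.5 <= self.damping < 1.0):
            raise ValueError("damping must be in [0.5, 1)")


@dataclass
class NodeClustering:
    n: int
    assignments: np.ndarray  # detection index -> cluster id (0..n-1)
    exemplars: np.ndarray  # cluster id -> exemplar detection index
    mean_y: np.ndarray  # cluster id -> mean y of members


@dataclass
class NodeLine:
    """y(t) = intercept + slope * t for one node order."""

    order: int
    slope: float  # px per second
    intercept: float  # px
    appearance_time: float  # earliest member timestamp (UNIX s)
    n_members: int = 0

    def y_at(self, t) -> float:
        return self.intercept + self.slope * np.asarray(t, dtype=float)


def cluster_by_y(y_values: np.ndarray, config: APConfig | None = None) -> NodeClustering:
    """Affinity propagation on 1-D y values.

    The similarity between two detections is the negative squared
    difference of their y coordinates; the number of clusters is
    determined by the message passing, not supplied.
    """
    config = config or APConfig()
    y = np.asarray(y_values, dtype=np.float64).ravel()
    if y.size == 0:
        raise ValueError("no detections to cluster")
    if y.size == 1:
        return NodeClustering(
            n=1,
            assignments=np.zeros(1, dtype=int),
            exemplars=np.zeros(1, dtype=int),
            mean_y=y.copy(),
        )
    # AP messages can oscillate at low damping (1-D data has many tied
    # similarities); damping only stabilizes the iteration and does not
    # change the fixed point, so escalate it until the run converges.
    labels = None
    for damping in sorted({config.damping, 0.7, 0.9}):
        if damping < config.damping:
            continue
        ap = AffinityPropagation(
            damping=damping,
            max_iter=config.max_iterations,
            convergence_iter=config.convergence_window,
            preference=config.preference,
            affinity="euclidean",  # sklearn uses -||.||^2 internally
            random_state=0,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fit_labels = ap.fit_predict(y[:, None])
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
        if converged and ap.cluster_centers_indices_ is not None \
                and len(ap.cluster_centers_indices_) > 0:
            labels = fit_labels
            break
        warnings.warn(
            f"affinity propagation did not converge at damping {damping}",
            stacklevel=2,
        )
    if labels is None:
        warnings.warn("affinity propagation never converged; using one cluster", stacklevel=2)
        return NodeClustering(
            n=1,
            assignments=np.zeros(y.size, dtype=int),
            exemplars=np.array([int(np.argmin(np.abs(y - np.median(y))))]),
            mean_y=np.array([y.mean()]),
        )
    n = len(ap.cluster_centers_indices_)
    mean_y = np.array([y[labels == c].mean() for c in range(n)])
    return NodeClustering(
        n=n,
        assignments=labels.astype(int),
        exemplars=np.asarray(ap.cluster_centers_indices_, dtype=int),
        mean_y=mean_y,
    )


def assign_orders(clustering: NodeClustering, timestamps: np.ndarray | None = None) -> list[int]:
    """Cluster ids in node order: order 1 = largest mean y, descending.

    Exact ties on mean y break toward the cluster with the smaller
    minimum timestamp (the older cluster sits lower on the plant).
    Returns ``ordered[i]`` = cluster id of order ``i+1``.
    """
    n = clustering.n
    if timestamps is not None:
        timestamps = np.asarray(timestamps, dtype=float)
        min_t = np.array([
            timestamps[clustering.assignments == c].min() for c in range(n)
        ])
    else:
        min_t = np.zeros(n)
    return sorted(range(n), key=lambda c: (-clustering.mean_y[c], min_t[c]))


def fit_node_lines(
    timestamps: np.ndarray,
    y_values: np.ndarray,
    clustering: NodeClustering,
) -> list[NodeLine]:
    """Per-order OLS of y on UNIX time; singletons get a constant line.

    Times are centered before the solve so intercepts stay numerically
    exact despite UNIX-scale abscissae; coefficients are reported in the
    original y = intercept + slope*t parameterization.
    """
    t = np.asarray(timestamps, dtype=np.float64)
    y = np.asarray(y_values, dtype=np.float64)
    ordered = assign_orders(clustering, timestamps=t)
    lines = []
    for order, cluster_id in enumerate(ordered, start=1):
        member = clustering.assignments == cluster_id
        tm, ym = t[member], y[member]
        appearance = float(tm.min())
        if tm.size == 1 or np.unique(tm).size == 1:
            slope, intercept = 0.0, float(ym.mean())
        else:
            t0 = tm.mean()
            slope = float(np.sum((tm - t0) * (ym - ym.mean())) / np.sum((tm - t0) ** 2))
            intercept = float(ym.mean() - slope * t0)
        lines.append(NodeLine(
            order=order,
            slope=slope,
            intercept=intercept,
            appearance_time=appearance,
            n_members=int(member.sum()),
        ))
    return lines


def node_y_at(line: NodeLine, t) -> float:
    """Node line evaluated at any time (interpolation or extrapolation)."""
    return float(line.y_at(t))
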