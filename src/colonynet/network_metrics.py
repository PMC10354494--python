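"""Seven colony-level network metrics with a disconnected-graph correction.

Per daily network the metrics span three social scales:

* local -- mean weighted degree, mean binary degree, mean edge weight;
* intermediate -- CV of edge weights (social differentiation), edge density;
* global -- mean path length and diameter on the weighted network.

Shortest paths treat edge weights as traversal costs (the default of common
graph libraries when a ``weight`` attribute is supplied); the alternative
1/weight cost convention is available via ``weight_mode="inverse"``.

Global metrics are undefined on disconnected networks, so they are corrected
by a randomized augmentation: compute the metric on the largest connected
component (value 2), then repeatedly join all clusters -- isolated detected
birds count as clusters of size one -- through edges carrying the smallest
strictly-positive edge weight observed anywhere in the study for that
network type, recompute on the joined network (value 1), and add the mean
of (value 1 - value 2) over ``n_reps`` repetitions (default 100) to value 2.
Clusters are joined in a random chain, one sampled representative per
cluster per link; a star topology is available via ``join="star"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_array
from scipy.sparse.csgraph import connected_components, shortest_path

from colonynet.network_construction import DailyNetwork

logger = logging.getLogger(__name__)

METRIC_NAMES = [
    "mean_weighted_degree", "mean_binary_degree", "mean_edge_weight",
    "cv_edge_weight", "edge_density", "mean_path_length", "diameter",
]


@dataclass
class CorrectionContext:
    """Study-level context for correcting global metrics of one network type.

    ``smallest_edge_weight`` is the minimum strictly-positive edge weight over
    all daily networks of that type in the study.
    """

    smallest_edge_weight: float
    n_reps: int = 100
    seed: int = 0
    join: str = "chain"

    def __post_init__(self):
        if self.smallest_edge_weight <= 0:
            raise ValueError("smallest_edge_weight must be > 0")
        if self.join not in ("chain", "star"):
            raise ValueError("join must be 'chain' or 'star'")


def local_metrics(net: DailyNetwork) -> tuple[float, float, float]:
    """(mean weighted degree, mean binary degree, mean edge weight).

    Weighted degree is the row sum of W; binary degree counts nonzero edges
    per bird; mean edge weight averages over all n(n-1)/2 unordered pairs,
    zeros included.  Undefined (NaN) for networks with fewer than two birds.
    """
    n = net.n_nodes
    if n < 2:
        logger.warning("local_metrics undefined for n_nodes=%d", n)
        return (float("nan"),) * 3
    W = net.W
    mwd = float(W.sum(axis=1).mean())
    mbd = float((W > 0).sum(axis=1).mean())
    iu = np.triu_indices(n, k=1)
    mew = float(W[iu].mean())
    return mwd, mbd, mew


def intermediate_metrics(net: DailyNetwork, cv_mode: str = "per_individual",
                         ) -> tuple[float, float]:
    """(CV edge weight, edge density).

    CV edge weight is computed per individual -- the sd/mean (n-1 denominator)
    of its n-1 edge weights, zeros included -- then averaged over individuals;
    birds whose weights are all zero have an undefined CV and are excluded
    from the average.  ``cv_mode="global"`` instead takes sd/mean over all
    dyadic weights at once.  Edge density is nonzero pairs / (n(n-1)/2).
    """
    n = net.n_nodes
    if n < 2:
        logger.warning("intermediate_metrics undefined for n_nodes=%d", n)
        return float("nan"), float("nan")
    W = net.W
    iu = np.triu_indices(n, k=1)
    density = float((W[iu] > 0).mean())
    if cv_mode == "global":
        vals = W[iu]
        mean = vals.mean()
        cv = float(vals.std(ddof=1) / mean) if mean > 0 else float("nan")
        return cv, density
    if cv_mode != "per_individual":
        raise ValueError(f"unknown cv_mode {cv_mode!r}")
    cvs = []
    off = ~np.eye(n, dtype=bool)
    for i in range(n):
        w = W[i][off[i]]
        m = w.mean()
        if m == 0 or len(w) < 2:  # all-zero or single-edge birds: undefined
            logger.debug("bird %s has no defined CV; excluded",
                         net.nodes[i])
            continue
        cvs.append(w.std(ddof=1) / m)
    cv = float(np.mean(cvs)) if cvs else float("nan")
    return cv, density


def _cost_matrix(W: np.ndarray, weight_mode: str) -> np.ndarray:
    if weight_mode == "cost":
        return W
    if weight_mode == "inverse":
        C = np.zeros_like(W)
        nz = W > 0
        C[nz] = 1.0 / W[nz]
        return C
    raise ValueError(f"unknown weight_mode {weight_mode!r}")


def _components(W: np.ndarray) -> tuple[int, np.ndarray]:
    return connected_components(csr_array(W != 0), directed=False)


def _path_metrics_on_nodes(W: np.ndarray, idx: np.ndarray, weight_mode: str,
                           ) -> tuple[float, float]:
    """Mean path length and diameter among the (connected) nodes ``idx``."""
    sub = W[np.ix_(idx, idx)]
    D = shortest_path(csr_array(_cost_matrix(sub, weight_mode)),
                      method="D", directed=False)
    iu = np.triu_indices(len(idx), k=1)
    dists = D[iu]
    return float(dists.mean()), float(dists.max())


def weighted_global_metrics(net: DailyNetwork, weight_mode: str = "cost",
                            ) -> tuple[float, float]:
    """Raw (uncorrected) mean path length and diameter.

    Computed on the largest connected component only, averaging shortest-path
    distances over all unordered pairs within it.  NaN when the network has
    no edges.
    """
    if net.n_nodes < 2 or not np.any(net.W):
        logger.warning("global metrics undefined without edges (%s %s %s)",
                       net.colony_id, net.date, net.net_type)
        return float("nan"), float("nan")
    n_comp, labels = _components(net.W)
    sizes = np.bincount(labels, minlength=n_comp)
    idx = np.flatnonzero(labels == sizes.argmax())
    return _path_metrics_on_nodes(net.W, idx, weight_mode)


def study_smallest_edge_weight(networks: list[DailyNetwork], net_type: str,
                               ) -> float:
    """Minimum strictly-positive edge weight across all networks of a type."""
    best = np.inf
    for net in networks:
        if net.net_type != net_type:
            continue
        pos = net.W[net.W > 0]
        if pos.size:
            best = min(best, float(pos.min()))
    if not np.isfinite(best):
        raise ValueError(f"no positive edge weight in any {net_type} network")
    return best


def _augmented(W: np.ndarray, labels: np.ndarray, n_comp: int, s: float,
               rng: np.random.Generator, join: str) -> np.ndarray:
    """Join all components with edges of weight ``s`` between random members."""
    reps = np.empty(n_comp, dtype=int)
    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        reps[c] = members[rng.integers(len(members))]
    order = rng.permutation(n_comp)
    A = W.copy()
    if join == "star":
        hub = reps[order[0]]
        for c in order[1:]:
            A[hub, reps[c]] = A[reps[c], hub] = s
    else:  # chain
        for k in range(n_comp - 1):
            a, b = reps[order[k]], reps[order[k + 1]]
            A[a, b] = A[b, a] = s
    return A


def correct_global_metric(net: DailyNetwork, ctx: CorrectionContext,
                          metric_fn, rng: np.random.Generator | None = None,
                          weight_mode: str = "cost") -> float:
    """Correct one global metric for disconnected components.

    ``metric_fn(W, weight_mode)`` must evaluate the metric on the largest
    connected component of an adjacency matrix.  On a single-component
    network the corrected value equals the raw value exactly.
    """
    if rng is None:
        rng = np.random.default_rng(ctx.seed)
    n_comp, labels = _components(net.W)
    value2 = metric_fn(net.W, weight_mode)
    if n_comp <= 1:
        return value2
    diffs = np.empty(ctx.n_reps)
    for r in range(ctx.n_reps):
        A = _augmented(net.W, labels, n_comp, ctx.smallest_edge_weight, rng,
                       ctx.join)
        diffs[r] = metric_fn(A, weight_mode) - value2
    return float(value2 + diffs.mean())


def mean_path_length_of(W: np.ndarray, weight_mode: str = "cost") -> float:
    """Mean shortest-path length on the largest component of ``W``."""
    return _largest_component_paths(W, weight_mode)[0]


def diameter_of(W: np.ndarray, weight_mode: str = "cost") -> float:
    """Diameter (maximum shortest-path length) on the largest component."""
    return _largest_component_paths(W, weight_mode)[1]


def _largest_component_paths(W: np.ndarray, weight_mode: str,
                             ) -> tuple[float, float]:
    if W.shape[0] < 2 or not np.any(W):
        return float("nan"), float("nan")
    n_comp, labels = _components(W)
    sizes = np.bincount(labels, minlength=n_comp)
    idx = np.flatnonzero(labels == sizes.argmax())
    return _path_metrics_on_nodes(W, idx, weight_mode)


def corrected_global_metrics(net: DailyNetwork, ctx: CorrectionContext,
                             rng: np.random.Generator | None = None,
                             weight_mode: str = "cost",
                             ) -> tuple[float, float]:
    """Corrected (mean path length, diameter), sharing one set of join draws."""
    if rng is None:
        rng = np.random.default_rng(ctx.seed)
    raw = _largest_component_paths(net.W, weight_mode)
    if not np.isfinite(raw[0]):
        return raw
    n_comp, labels = _components(net.W)
    if n_comp <= 1:
        return raw
    diffs = np.zeros((ctx.n_reps, 2))
    for r in range(ctx.n_reps):
        A = _augmented(net.W, labels, n_comp, ctx.smallest_edge_weight, rng,
                       ctx.join)
        value1 = _path_metrics_on_nodes(A, np.arange(A.shape[0]), weight_mode)
        diffs[r] = (value1[0] - raw[0], value1[1] - raw[1])
    mean_diff = diffs.mean(axis=0)
    return float(raw[0] + mean_diff[0]), float(raw[1] + mean_diff[1])


def metrics_table(networks: list[DailyNetwork], n_reps: int = 100,
                  seed: int = 0, weight_mode: str = "cost",
                  cv_mode: str = "per_individual", join: str = "chain",
                  ) -> pd.DataFrame:
    """Compute the full metric table of a study.

    One row per daily network with the seven metrics (global ones corrected)
    plus the raw mean path length and diameter.  The smallest positive edge
    weight entering the correction is determined per network type across the
    whole study; per-network RNG streams are derived deterministically from
    ``seed``.
    """
    ordered = sorted(networks, key=lambda n: (n.net_type, n.colony_id, n.date))
    smallest: dict[str, float | None] = {}
    for net_type in {n.net_type for n in ordered}:
        try:
            smallest[net_type] = study_smallest_edge_weight(ordered, net_type)
        except ValueError:
            smallest[net_type] = None
    streams = np.random.SeedSequence(seed).spawn(len(ordered))
    rows = []
    for net, stream in zip(ordered, streams):
        mwd, mbd, mew = local_metrics(net)
        cv, density = (intermediate_metrics(net, cv_mode) if net.n_nodes >= 2
                       else (float("nan"), float("nan")))
        raw_mpl, raw_diam = _largest_component_paths(net.W, weight_mode)
        s = smallest[net.net_type]
        if s is not None and np.isfinite(raw_mpl):
            ctx = CorrectionContext(smallest_edge_weight=s, n_reps=n_reps,
                                    join=join)
            mpl, diam = corrected_global_metrics(
                net, ctx, rng=np.random.default_rng(stream),
                weight_mode=weight_mode)
        else:
            mpl, diam = raw_mpl, raw_diam
        rows.append({
            "colony_id": net.colony_id, "date": net.date,
            "net_type": net.net_type, "n_nodes": net.n_nodes,
            "mean_weighted_degree": mwd, "mean_binary_degree": mbd,
            "mean_edge_weight": mew, "cv_edge_weight": cv,
            "edge_density": density, "mean_path_length": mpl,
            "diameter": diam, "mean_path_length_raw": raw_mpl,
            "diameter_raw": raw_diam,
        })
    return pd.DataFrame(rows)
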