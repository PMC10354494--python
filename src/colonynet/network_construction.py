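"""Build daily interaction and association networks from detection records.

Two network types are constructed per colony-day:

* **interaction** -- affiliative "clumping" on perches.  Two birds clump in a
  frame when their barcodes sit less than ``threshold_px`` (default 80, one
  body-width) apart on the same perch camera.  Edge weights use a *strict*
  simple ratio index: frames clumped divided by frames both birds were
  detected on the same perch, isolating the choice to interact from mere
  co-presence.

* **association** -- foraging co-occurrence at feeding tables
  (gambit-of-the-group).  Edge weights use the simple ratio index: frames
  both birds were on the same feeder divided by frames at least one of the
  two was detected at any feeder.

Dyads with an empty denominator get weight 0 (no data = no edge), keeping
every adjacency matrix total and defined.  Nodes are the birds detected that
day at the relevant location class, so the two network types of the same
colony-day may have different node sets.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from colonynet.detections_io import PERCH_LOCATIONS

logger = logging.getLogger(__name__)

NET_TYPES = ("interaction", "association")
DEFAULT_CLUMP_THRESHOLD_PX = 80

EDGE_COLUMNS = ["colony_id", "date", "net_type", "bird_a", "bird_b", "weight", "x", "d"]
NODE_COLUMNS = ["colony_id", "date", "net_type", "bird_id"]


@dataclass
class DailyNetwork:
    """Symmetric weighted network of one colony-day in one social context.

    ``W`` is an ``n x n`` symmetric matrix of edge weights in [0, 1] with a
    zero diagonal, indexed by ``nodes`` (the birds detected that day at the
    relevant location class).  ``counts`` holds the underlying dyadic
    numerators/denominators (columns bird_a, bird_b, x, d).
    """

    colony_id: str
    date: str
    net_type: str
    nodes: list[str]
    W: np.ndarray
    counts: pd.DataFrame = field(repr=False, default=None)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def __post_init__(self):
        if self.net_type not in NET_TYPES:
            raise ValueError(f"unknown net_type {self.net_type!r}")
        W = np.asarray(self.W, dtype=float)
        if W.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("W shape does not match node list")
        if not np.allclose(W, W.T):
            raise ValueError("W must be symmetric")
        if np.any(np.diag(W) != 0):
            raise ValueError("W must have a zero diagonal")
        if W.size and (W.min() < 0 or W.max() > 1):
            raise ValueError("edge weights must lie in [0, 1]")
        self.W = W


def detect_clumps(frame_records: pd.DataFrame,
                  threshold_px: int = DEFAULT_CLUMP_THRESHOLD_PX) -> set[frozenset]:
    """Clumped pairs within one frame of one perch camera.

    A pair is clumped iff the absolute pixel distance between the two
    detections is strictly less than ``threshold_px``.  All records must share
    colony, date, frame and camera; ``x_px`` must be present.
    """
    for key in ("colony_id", "date", "frame_id", "camera_id"):
        if frame_records[key].nunique() > 1:
            raise ValueError(f"detect_clumps expects records of a single {key}")
    if frame_records["x_px"].isna().any():
        raise ValueError("x_px missing in perch frame records")
    birds = frame_records["bird_id"].to_numpy()
    x = frame_records["x_px"].to_numpy(dtype=float)
    out = set()
    for i, j in itertools.combinations(range(len(birds)), 2):
        if abs(x[i] - x[j]) < threshold_px:
            out.add(frozenset((birds[i], birds[j])))
    return out


def _require_single_day(records: pd.DataFrame) -> tuple[str, str]:
    colonies = records["colony_id"].unique()
    dates = records["date"].unique()
    if len(colonies) > 1 or len(dates) > 1:
        raise ValueError("records must belong to a single colony-day")
    return (colonies[0] if len(colonies) else "", dates[0] if len(dates) else "")


def _all_pairs(nodes: list[str]) -> pd.DataFrame:
    pairs = list(itertools.combinations(nodes, 2))
    return pd.DataFrame(pairs, columns=["bird_a", "bird_b"])


def accumulate_interaction_counts(day_records: pd.DataFrame,
                                  threshold_px: int = DEFAULT_CLUMP_THRESHOLD_PX,
                                  ) -> pd.DataFrame:
    """Strict-SRI dyad counts for one colony-day of perch records.

    For each unordered dyad of birds detected on a perch that day:
    ``x`` = frames clumped (< ``threshold_px`` apart on the same camera) and
    ``d`` = frames both were detected on the same perch camera.  Dyads never
    co-present get (0, 0).
    """
    _require_single_day(day_records)
    perch = day_records[day_records["location_type"].isin(PERCH_LOCATIONS)]
    nodes = sorted(perch["bird_id"].unique())
    base = _all_pairs(nodes)
    if perch.empty or len(nodes) < 2:
        base["x"] = 0
        base["d"] = 0
        return base
    if perch["x_px"].isna().any():
        raise ValueError("perch records with missing x_px")
    m = perch[["camera_id", "frame_id", "bird_id", "x_px"]]
    joined = m.merge(m, on=["camera_id", "frame_id"], suffixes=("_a", "_b"))
    joined = joined[joined["bird_id_a"] < joined["bird_id_b"]]
    if joined.empty:
        base["x"] = 0
        base["d"] = 0
        return base
    clumped = (
        (joined["x_px_a"] - joined["x_px_b"]).abs() < threshold_px
    ).astype(int)
    agg = (
        pd.DataFrame({
            "bird_a": joined["bird_id_a"].to_numpy(),
            "bird_b": joined["bird_id_b"].to_numpy(),
            "clumped": clumped.to_numpy(),
        })
        .groupby(["bird_a", "bird_b"], sort=True)
        .agg(x=("clumped", "sum"), d=("clumped", "size"))
        .reset_index()
    )
    out = base.merge(agg, on=["bird_a", "bird_b"], how="left")
    out[["x", "d"]] = out[["x", "d"]].fillna(0).astype(int)
    return out


def accumulate_association_counts(day_records: pd.DataFrame) -> pd.DataFrame:
    """Simple-ratio-index dyad counts for one colony-day of feeder records.

    For each unordered dyad of birds detected at a feeder that day:
    ``x`` = frames both were on the same feeding table and ``d`` = frames at
    least one of the two was detected at any feeding table.
    """
    _require_single_day(day_records)
    feed = day_records[day_records["location_type"] == "feeder"]
    nodes = sorted(feed["bird_id"].unique())
    base = _all_pairs(nodes)
    if feed.empty or len(nodes) < 2:
        base["x"] = 0
        base["d"] = 0
        return base
    # one row per bird-frame (a bird cannot be at two feeders at once, but
    # deduplicate defensively for the any-feeder margin)
    per_frame = feed[["frame_id", "bird_id"]].drop_duplicates()
    n_frames = per_frame.groupby("bird_id").size()

    same = feed[["camera_id", "frame_id", "bird_id"]]
    both_same = same.merge(same, on=["camera_id", "frame_id"], suffixes=("_a", "_b"))
    both_same = both_same[both_same["bird_id_a"] < both_same["bird_id_b"]]
    x = (
        both_same.drop_duplicates(["frame_id", "bird_id_a", "bird_id_b"])
        .groupby(["bird_id_a", "bird_id_b"]).size()
    )

    both_any = per_frame.merge(per_frame, on="frame_id", suffixes=("_a", "_b"))
    both_any = both_any[both_any["bird_id_a"] < both_any["bird_id_b"]]
    overlap = both_any.groupby(["bird_id_a", "bird_id_b"]).size()

    key = pd.MultiIndex.from_frame(base[["bird_a", "bird_b"]])
    na = n_frames.reindex(base["bird_a"]).to_numpy()
    nb = n_frames.reindex(base["bird_b"]).to_numpy()
    both = overlap.reindex(key, fill_value=0).to_numpy()
    base["x"] = x.reindex(key, fill_value=0).to_numpy().astype(int)
    base["d"] = (na + nb - both).astype(int)
    return base


def ratio_index(x: int, d: int) -> float:
    """Simple ratio index x/d, with the 0/0 convention mapping to 0."""
    if x < 0 or d < 0:
        raise ValueError("counts must be non-negative")
    if x > d:
        raise ValueError(f"numerator x={x} exceeds denominator d={d}")
    return x / d if d > 0 else 0.0


def build_daily_network(day_records: pd.DataFrame, net_type: str,
                        threshold_px: int = DEFAULT_CLUMP_THRESHOLD_PX,
                        ) -> DailyNetwork:
    """Assemble the DailyNetwork of one colony-day in one social context."""
    if net_type not in NET_TYPES:
        raise ValueError(f"unknown net_type {net_type!r}")
    colony_id, date = _require_single_day(day_records)
    if net_type == "interaction":
        relevant = day_records[day_records["location_type"].isin(PERCH_LOCATIONS)]
        counts = accumulate_interaction_counts(day_records, threshold_px)
    else:
        relevant = day_records[day_records["location_type"] == "feeder"]
        counts = accumulate_association_counts(day_records)
    nodes = sorted(relevant["bird_id"].unique())
    n = len(nodes)
    W = np.zeros((n, n), dtype=float)
    if n < 2:
        logger.warning("colony %s %s %s: fewer than 2 detected birds, empty edge set",
                       colony_id, date, net_type)
    else:
        pos = {b: i for i, b in enumerate(nodes)}
        xs = counts["x"].to_numpy()
        ds = counts["d"].to_numpy()
        w = np.divide(xs, ds, out=np.zeros(len(counts), dtype=float), where=ds > 0)
        ia = counts["bird_a"].map(pos).to_numpy()
        ib = counts["bird_b"].map(pos).to_numpy()
        W[ia, ib] = w
        W[ib, ia] = w
    return DailyNetwork(colony_id=colony_id, date=date, net_type=net_type,
                        nodes=nodes, W=W, counts=counts)


def build_networks(records: pd.DataFrame,
                   net_types: tuple[str, ...] = NET_TYPES,
                   threshold_px: int = DEFAULT_CLUMP_THRESHOLD_PX,
                   ) -> list[DailyNetwork]:
    """Build all daily networks of a study, ordered by (net_type, colony, date)."""
    networks: list[DailyNetwork] = []
    for net_type in net_types:
        for (_, _), day in records.groupby(["colony_id", "date"], sort=True):
            networks.append(build_daily_network(day, net_type, threshold_px))
    return networks


def networks_to_edge_table(networks: list[DailyNetwork]) -> pd.DataFrame:
    """Long-format edge list (rows with d > 0 only; zeros are implicit)."""
    frames = []
    for net in networks:
        c = net.counts
        observed = c[c["d"] > 0].copy() if c is not None and len(c) else c
        if observed is None or not len(observed):
            continue
        observed.insert(0, "colony_id", net.colony_id)
        observed.insert(1, "date", net.date)
        observed.insert(2, "net_type", net.net_type)
        observed["weight"] = observed["x"] / observed["d"]
        frames.append(observed[EDGE_COLUMNS])
    if not frames:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def networks_to_node_table(networks: list[DailyNetwork]) -> pd.DataFrame:
    rows = [
        (net.colony_id, net.date, net.net_type, bird)
        for net in networks for bird in net.nodes
    ]
    return pd.DataFrame(rows, columns=NODE_COLUMNS)


def write_networks(networks: list[DailyNetwork], edges_path, nodes_path) -> None:
    networks_to_edge_table(networks).to_csv(edges_path, index=False)
    networks_to_node_table(networks).to_csv(nodes_path, index=False)


def read_networks(edges_path, nodes_path) -> list[DailyNetwork]:
    """Reconstruct DailyNetwork objects from the edge and node CSVs."""
    edges = pd.read_csv(edges_path, dtype={"colony_id": str, "date": str,
                                           "bird_a": str, "bird_b": str})
    nodes = pd.read_csv(nodes_path, dtype={"colony_id": str, "date": str,
                                           "bird_id": str})
    networks = []
    edge_groups = dict(iter(edges.groupby(["net_type", "colony_id", "date"])))
    for (net_type, colony_id, date), grp in nodes.groupby(
            ["net_type", "colony_id", "date"], sort=True):
        node_list = sorted(grp["bird_id"].unique())
        pos = {b: i for i, b in enumerate(node_list)}
        n = len(node_list)
        W = np.zeros((n, n), dtype=float)
        counts = _all_pairs(node_list)
        counts["x"] = 0
        counts["d"] = 0
        e = edge_groups.get((net_type, colony_id, date))
        if e is not None and len(e):
            counts = counts.merge(
                e[["bird_a", "bird_b", "x", "d"]], on=["bird_a", "bird_b"],
                how="left", suffixes=("_zero", ""))
            counts["x"] = counts["x"].fillna(0).astype(int)
            counts["d"] = counts["d"].fillna(0).astype(int)
            counts = counts[["bird_a", "bird_b", "x", "d"]]
            ia = e["bird_a"].map(pos).to_numpy()
            ib = e["bird_b"].map(pos).to_numpy()
            w = (e["x"] / e["d"]).to_numpy()
            W[ia, ib] = w
            W[ib, ia] = w
        networks.append(DailyNetwork(colony_id=colony_id, date=date,
                                     net_type=net_type, nodes=node_list,
                                     W=W, counts=counts))
    return networks
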