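"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (dict/loop-based, frame-by-frame or
element-by-element) and shares no code with the package implementation.
"""

from __future__ import annotations

import itertools
from collections import Counter, defaultdict

import numpy as np
import pandas as pd

DETECTION_COLUMNS = ["colony_id", "date", "frame_id", "camera_id",
                     "location_type", "bird_id", "x_px"]


def rec(colony="C1", date="2020-01-01", frame=0, camera="social_perch_1",
        loc="social_perch", bird="B1", x=0):
    return {"colony_id": colony, "date": date, "frame_id": frame,
            "camera_id": camera, "location_type": loc, "bird_id": bird,
            "x_px": x}


def det_df(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=DETECTION_COLUMNS)
    df["x_px"] = pd.array(df["x_px"], dtype="Int64")
    return df


def oracle_interaction_counts(rows: list[dict], threshold: int = 80):
    """Frame-by-frame strict-SRI counts: {pair: x}, {pair: d}."""
    perch = [r for r in rows
             if r["location_type"] in ("social_perch", "copulation_perch")]
    frames = defaultdict(list)
    for r in perch:
        frames[(r["camera_id"], r["frame_id"])].append(r)
    x, d = Counter(), Counter()
    for members in frames.values():
        for r1, r2 in itertools.combinations(members, 2):
            pair = tuple(sorted((r1["bird_id"], r2["bird_id"])))
            d[pair] += 1
            if abs(r1["x_px"] - r2["x_px"]) < threshold:
                x[pair] += 1
    birds = sorted({r["bird_id"] for r in perch})
    return birds, x, d


def oracle_association_counts(rows: list[dict]):
    """Frame-by-frame SRI counts: {pair: x}, {pair: d}."""
    feed = [r for r in rows if r["location_type"] == "feeder"]
    frames_of = defaultdict(set)
    at_feeder = defaultdict(set)
    for r in feed:
        frames_of[r["bird_id"]].add(r["frame_id"])
        at_feeder[(r["camera_id"], r["frame_id"])].add(r["bird_id"])
    x = Counter()
    for members in at_feeder.values():
        for a, b in itertools.combinations(sorted(members), 2):
            x[(a, b)] += 1
    birds = sorted(frames_of)
    d = Counter()
    for a, b in itertools.combinations(birds, 2):
        d[(a, b)] = len(frames_of[a] | frames_of[b])
    return birds, x, d


def oracle_local_metrics(W: np.ndarray):
    n = W.shape[0]
    wdeg = [sum(W[i][j] for j in range(n) if j != i) for i in range(n)]
    bdeg = [sum(1 for j in range(n) if j != i and W[i][j] > 0)
            for i in range(n)]
    weights = [W[i][j] for i in range(n) for j in range(i + 1, n)]
    return (sum(wdeg) / n, sum(bdeg) / n, sum(weights) / len(weights))


def oracle_cv_edge_weight(W: np.ndarray):
    n = W.shape[0]
    cvs = []
    for i in range(n):
        w = [W[i][j] for j in range(n) if j != i]
        m = sum(w) / len(w)
        if m == 0 or len(w) < 2:
            continue
        var = sum((v - m) ** 2 for v in w) / (len(w) - 1)
        cvs.append(var ** 0.5 / m)
    return sum(cvs) / len(cvs) if cvs else float("nan")


def oracle_edge_density(W: np.ndarray):
    n = W.shape[0]
    present = sum(1 for i in range(n) for j in range(i + 1, n) if W[i][j] > 0)
    return present / (n * (n - 1) / 2)


def _oracle_components(W: np.ndarray):
    n = W.shape[0]
    seen, comps = set(), []
    for start in range(n):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            i = stack.pop()
            if i in comp:
                continue
            comp.add(i)
            stack.extend(j for j in range(n) if W[i][j] > 0 and j not in comp)
        seen |= comp
        comps.append(sorted(comp))
    return comps


def oracle_path_metrics(W: np.ndarray):
    """Floyd-Warshall (weights as costs) on the largest component."""
    comps = _oracle_components(W)
    comp = max(comps, key=len)
    if len(comp) < 2:
        return float("nan"), float("nan")
    idx = {node: k for k, node in enumerate(comp)}
    m = len(comp)
    INF = float("inf")
    dist = [[0.0 if a == b else INF for b in range(m)] for a in range(m)]
    for i in comp:
        for j in comp:
            if i != j and W[i][j] > 0:
                dist[idx[i]][idx[j]] = W[i][j]
    for k in range(m):
        for a in range(m):
            for b in range(m):
                alt = dist[a][k] + dist[k][b]
                if alt < dist[a][b]:
                    dist[a][b] = alt
    pair_dists = [dist[a][b] for a in range(m) for b in range(a + 1, m)]
    return sum(pair_dists) / len(pair_dists), max(pair_dists)


def random_day_records(rng: np.random.Generator, max_birds=6, max_frames=100):
    """A random colony-day of raw detections, including crowded frames."""
    n_birds = int(rng.integers(2, max_birds + 1))
    n_frames = int(rng.integers(5, max_frames + 1))
    birds = [f"B{i}" for i in range(n_birds)]
    cameras = [("social_perch_1", "social_perch"),
               ("copulation_perch", "copulation_perch"),
               ("feeder_1", "feeder"), ("feeder_2", "feeder")]
    rows = []
    for f in range(n_frames):
        for b in birds:
            u = rng.random()
            if u < 0.45:
                continue  # bird not detected this frame
            cam, loc = cameras[int(rng.integers(len(cameras)))]
            x = int(rng.integers(0, 300)) if loc != "feeder" else 0
            rows.append(rec(frame=f, camera=cam, loc=loc, bird=b, x=x))
    return rows


def random_symmetric_weights(rng: np.random.Generator, max_nodes=8,
                             p_edge=0.5) -> np.ndarray:
    n = int(rng.integers(2, max_nodes + 1))
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                W[i, j] = W[j, i] = float(np.round(rng.uniform(0.05, 1.0), 3))
    return W
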