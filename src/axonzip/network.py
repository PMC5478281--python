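"""Planar graphs of segmented axon networks and coarsening statistics.

Frames come from polyline segmentation exports (CSV or JSON).  Polyline
endpoints within a snap tolerance merge into junction nodes; crossings are
kept as annotations only (they neither merge connectivity nor count as
vertices).  Statistics follow the conventions of the time-lapse analysis:
total drawn length, junction counts, bounded faces ("chordless loops") of
the planar embedding with shoelace areas, and per-junction zipper angles
taken as the sharpest of the three inter-edge angles.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "NetworkFrame",
    "NetworkStats",
    "load_segmentation",
    "total_length",
    "count_junctions",
    "chordless_loops",
    "zipper_angles",
    "timeseries_stats",
    "vertex_type_fractions",
]


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


@dataclass
class NetworkFrame:
    """One time point of a segmented network.

    nodes : id -> {"pos": (x, y), "kind": "junction" | "endpoint"}
    edges : list of (node_a, node_b, polyline) with polyline endpoints at
            the node positions
    crossings : list of (x, y) overlap annotations (not graph nodes)
    """

    timestamp: float = 0.0
    nodes: dict = field(default_factory=dict)
    edges: list = field(default_factory=list)
    crossings: list = field(default_factory=list)
    bounds: tuple | None = None

    @classmethod
    def from_polylines(cls, polylines, crossings=(), snap_tol: float = 1.0,
                       timestamp: float = 0.0) -> "NetworkFrame":
        """Build a frame by snapping polyline endpoints into shared nodes."""
        chains = [np.asarray(p, dtype=float) for p in polylines]
        for i, c in enumerate(chains):
            if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 2:
                raise ValueError(f"polyline {i} must be an (n>=2, 2) array")

        # greedy clustering of endpoints within the snap tolerance
        positions: list[np.ndarray] = []

        def node_for(pt: np.ndarray) -> int:
            for k, q in enumerate(positions):
                if np.linalg.norm(pt - q) <= snap_tol:
                    return k
            positions.append(pt.copy())
            return len(positions) - 1

        edges = []
        for c in chains:
            a = node_for(c[0])
            b = node_for(c[-1])
            geom = c.copy()
            geom[0] = positions[a]
            geom[-1] = positions[b]
            edges.append((a, b, geom))

        degree = np.zeros(len(positions), dtype=int)
        for a, b, _ in edges:
            degree[a] += 1
            degree[b] += 1
        nodes = {
            k: {"pos": tuple(positions[k]),
                "kind": "junction" if degree[k] >= 3 else "endpoint"}
            for k in range(len(positions))
        }
        return cls(timestamp=timestamp, nodes=nodes, edges=edges,
                   crossings=[tuple(map(float, c)) for c in crossings])

    def degree(self, node: int) -> int:
        return sum((a == node) + (b == node) for a, b, _ in self.edges)


def load_segmentation(path, snap_tol: float = 1.0,
                      pixel_size: float = 1.0) -> NetworkFrame:
    """Read one frame from a segmentation export.

    CSV schema: columns frame, polyline_id, point_index, x, y and optional
    kind (rows marked 'crossing' annotate overlap points).  A JSON file
    mirrors this: {"timestamp": .., "polylines": [{"id": .., "points":
    [[x, y], ..]}], "crossings": [[x, y], ..]}.  Coordinates are multiplied
    by pixel_size to convert to um.
    """
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            doc = json.load(fh)
        polylines = [np.asarray(p["points"], dtype=float) * pixel_size
                     for p in doc.get("polylines", [])]
        crossings = [np.asarray(c, dtype=float) * pixel_size
                     for c in doc.get("crossings", [])]
        return NetworkFrame.from_polylines(
            polylines, crossings, snap_tol=snap_tol,
            timestamp=float(doc.get("timestamp", 0.0)))

    df = pd.read_csv(path)
    required = {"polyline_id", "point_index", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("x", "y", "point_index"):
        bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(
                f"{path}: malformed value in column {col!r} at line "
                f"{int(bad.index[0]) + 2}")
    timestamp = float(df["frame"].iloc[0]) if "frame" in df.columns else 0.0
    crossings = []
    if "kind" in df.columns:
        cross_rows = df[df["kind"].astype(str).str.lower() == "crossing"]
        crossings = [(r.x * pixel_size, r.y * pixel_size)
                     for r in cross_rows.itertuples()]
        df = df.drop(cross_rows.index)
    polylines = []
    for _, grp in df.groupby("polyline_id"):
        grp = grp.sort_values("point_index")
        polylines.append(grp[["x", "y"]].to_numpy(dtype=float) * pixel_size)
    return NetworkFrame.from_polylines(polylines, crossings,
                                       snap_tol=snap_tol, timestamp=timestamp)


def total_length(frame: NetworkFrame) -> float:
    """Sum of drawn polyline lengths (um); shared zippered segments count
    once, exactly as segmented."""
    return sum(_polyline_length(g) for _, _, g in frame.edges)


def count_junctions(frame: NetworkFrame) -> int:
    """Number of graph nodes of degree >= 3; crossings are excluded by
    construction (they are annotations, not nodes)."""
    return sum(1 for k in frame.nodes if frame.degree(k) >= 3)


def _outgoing_halfedges(frame: NetworkFrame):
    """Map node -> list of (angle, halfedge) where halfedge = (edge_idx,
    forward_flag) oriented away from the node."""
    out: dict[int, list] = {k: [] for k in frame.nodes}
    for idx, (a, b, geom) in enumerate(frame.edges):
        da = geom[1] - geom[0]
        db = geom[-2] - geom[-1]
        out[a].append((float(np.arctan2(da[1], da[0])), (idx, True)))
        out[b].append((float(np.arctan2(db[1], db[0])), (idx, False)))
    for k in out:
        out[k].sort()
    return out


def chordless_loops(frame: NetworkFrame) -> list:
    """Bounded faces of the planar embedding with shoelace areas.

    Faces are traced with the leftmost-turn rule on half-edges ordered by
    departure angle at each node; the unbounded outer face (negative
    orientation) is discarded.  Returns a list of dicts with keys
    'nodes', 'polygon' (closed (n, 2) array) and 'area' (um^2).
    """
    out = _outgoing_halfedges(frame)
    # position in the rotation for each half-edge
    order = {}
    for node, lst in out.items():
        for pos, (_, he) in enumerate(lst):
            order[he] = (node, pos)

    def twin(he):
        return (he[0], not he[1])

    def next_face_halfedge(he):
        # arriving over `he` at its head; leave by the rotational successor
        # of the twin (clockwise), which traces faces counterclockwise
        t = twin(he)
        node, pos = order[t]
        lst = out[node]
        return lst[(pos - 1) % len(lst)][1]

    visited = set()
    faces = []
    for he0 in order:
        if he0 in visited:
            continue
        cycle = []
        he = he0
        while he not in visited:
            visited.add(he)
            cycle.append(he)
            he = next_face_halfedge(he)
        faces.append(cycle)

    loops = []
    for cycle in faces:
        pts = []
        node_ids = []
        for idx, forward in cycle:
            a, b, geom = frame.edges[idx]
            g = geom if forward else geom[::-1]
            node_ids.append(a if forward else b)
            pts.append(g[:-1])
        poly = np.vstack(pts + [pts[0][:1]])
        x, y = poly[:-1, 0], poly[:-1, 1]
        area = 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        if area > 1e-9:
            loops.append({"nodes": node_ids, "polygon": poly, "area": area})
    return loops


def _tangent(geom: np.ndarray, from_start: bool, arm_length: float):
    """Unit direction of an edge within arm_length of one of its ends."""
    g = geom if from_start else geom[::-1]
    seg = np.linalg.norm(np.diff(g, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    s = min(arm_length, arc[-1])
    x = np.interp(s, arc, g[:, 0])
    y = np.interp(s, arc, g[:, 1])
    d = np.array([x, y]) - g[0]
    n = np.linalg.norm(d)
    if n == 0:
        d = g[-1] - g[0]
        n = np.linalg.norm(d)
    return d / n


def zipper_angles(frame: NetworkFrame, arm_length: float = 5.0,
                  overrides: dict | None = None) -> list:
    """Zipper angle (deg) at each degree-3 junction.

    Edge directions are tangents estimated over arm_length um of polyline;
    the reported angle is the sharpest of the three pairwise inter-edge
    angles unless an override maps the node id to a specific edge pair.
    Nodes of other degrees are skipped.
    """
    overrides = overrides or {}
    incident: dict[int, list] = {k: [] for k in frame.nodes}
    for idx, (a, b, geom) in enumerate(frame.edges):
        incident[a].append(_tangent(geom, True, arm_length))
        incident[b].append(_tangent(geom, False, arm_length))

    angles = []
    for node, dirs in incident.items():
        if len(dirs) != 3:
            continue
        pair_angles = {}
        for i in range(3):
            for j in range(i + 1, 3):
                c = float(np.clip(np.dot(dirs[i], dirs[j]), -1.0, 1.0))
                pair_angles[(i, j)] = np.degrees(np.arccos(c))
        if node in overrides:
            angles.append(pair_angles[tuple(sorted(overrides[node]))])
        else:
            angles.append(min(pair_angles.values()))
    return angles


@dataclass(frozen=True)
class NetworkStats:
    timestamp: float
    total_length: float
    n_junctions: int
    n_loops: int
    mean_loop_area: float
    median_angle: float
    n_angles: int


def frame_stats(frame: NetworkFrame, arm_length: float = 5.0) -> NetworkStats:
    loops = chordless_loops(frame)
    angles = zipper_angles(frame, arm_length=arm_length)
    return NetworkStats(
        timestamp=frame.timestamp,
        total_length=total_length(frame),
        n_junctions=count_junctions(frame),
        n_loops=len(loops),
        mean_loop_area=float(np.mean([l["area"] for l in loops]))
        if loops else float("nan"),
        median_angle=float(np.median(angles)) if angles else float("nan"),
        n_angles=len(angles))


def timeseries_stats(frames, arm_length: float = 5.0,
                     normalize_index: int | None = None):
    """Per-frame statistics plus the Pearson correlation of the median
    zipper angle with the total network length.

    With normalize_index set, length/junction/loop columns are divided by
    the values at that frame (e.g. the last pre-drug time point).  Returns
    (DataFrame, r); r is NaN with a warning when either series is constant.
    """
    frames = list(frames)
    if len(frames) < 3:
        raise ValueError("need at least 3 frames")
    rows = [frame_stats(f, arm_length=arm_length) for f in frames]
    df = pd.DataFrame([r.__dict__ for r in rows])
    if normalize_index is not None:
        ref = df.iloc[normalize_index]
        for col in ("total_length", "n_junctions", "n_loops",
                    "mean_loop_area"):
            df[col + "_norm"] = df[col] / ref[col]

    L = df["total_length"].to_numpy()
    bM = df["median_angle"].to_numpy()
    ok = np.isfinite(L) & np.isfinite(bM)
    if ok.sum() < 3 or np.ptp(L[ok]) < 1e-12 or np.ptp(bM[ok]) < 1e-12:
        warnings.warn("correlation undefined: constant series")
        r = float("nan")
    else:
        r = float(sstats.pearsonr(bM[ok], L[ok]).statistic)
    return df, r


def vertex_type_fractions(counts: dict) -> dict:
    """Integer-rounded percentages of vertex classes from raw counts,
    e.g. {'simple': 134, 'entangled': 69, 'crossing': 44}."""
    if any(v < 0 for v in counts.values()):
        raise ValueError("counts must be non-negative")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("zero total count")
    return {k: int(round(100.0 * v / total)) for k, v in counts.items()}
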