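"""Seeded generators emulating the study's measurement structure.

Three generators cover the pipeline inputs:

* tension / equilibrium-angle samples with a planted adhesion strength,
* BFP force recordings with plateau staircases and the stated noise model,
* time-lapse sequences of planar axon networks that coarsen (or de-coarsen)
  through vertex motion, edge contraction and triangular-loop collapse.

All randomness flows from one ``numpy`` Generator seeded by the spec, so a
given spec reproduces its outputs bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Voronoi

from . import statics
from .bfp import BFPRecording
from .network import NetworkFrame
from .statics import FULL_ZIPPERING

__all__ = [
    "GeneratorSpec",
    "gen_tension_and_angle_samples",
    "gen_bfp_recording",
    "gen_network_sequence",
    "collapse_triangle",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Seed, scenario name and parameter overrides for a generator run."""

    seed: int
    scenario: str = "coarsening"
    overrides: dict = field(default_factory=dict)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def get(self, key: str, default):
        return self.overrides.get(key, default)


# ---------------------------------------------------------------------------
# tension and angle samples
# ---------------------------------------------------------------------------

def gen_tension_and_angle_samples(spec: GeneratorSpec):
    """Draw lognormal tensions and the matching equilibrium angles.

    Returns (tensions_nN, angles_deg, S_nN).  Angles follow the static
    balance for independently drawn tensions, plus Gaussian measurement
    noise; the defaults mirror the study's sample sizes (7 tensions, 34
    angle measurements).
    """
    rng = spec.rng()
    mean_T = spec.get("mean_T", 0.68)
    sd_T = spec.get("sd_T", 0.25)
    S = spec.get("S", 0.13)
    n_T = int(spec.get("n_tension", 7))
    n_A = int(spec.get("n_angle", 34))
    noise = spec.get("angle_noise_deg", 3.0)

    sigma2 = math.log1p((sd_T / mean_T) ** 2)
    mu = math.log(mean_T) - sigma2 / 2.0
    sigma = math.sqrt(sigma2)

    tensions = rng.lognormal(mu, sigma, size=n_T)
    t_for_angles = rng.lognormal(mu, sigma, size=n_A)
    t_for_angles = np.maximum(t_for_angles, S / 2 + 1e-9)
    angles = np.degrees(2 * np.arccos(1 - S / (2 * t_for_angles)))
    angles = angles + rng.normal(0.0, noise, size=n_A)
    angles = np.clip(angles, 0.5, 179.5)
    return tensions, angles, S


# ---------------------------------------------------------------------------
# BFP recordings
# ---------------------------------------------------------------------------

def gen_bfp_recording(spec: GeneratorSpec, T_true_pN: float = 680.0,
                      k: float = 150.0) -> BFPRecording:
    """Synthetic probe recording with a staircase of pulling plateaux.

    Plateau deflections step up from about 1 to 8 degrees; within each
    plateau the measured deflection carries 0.5 degree per-frame noise and
    the force carries k times the bead-tracking noise (default 20 nm).
    Planted ground truth is stored in the recording metadata.
    """
    rng = spec.rng()
    n_plateaux = int(spec.get("n_plateaux", 5))
    if n_plateaux < 1:
        raise ValueError("need at least one plateau")
    plateau_s = spec.get("plateau_duration", 12.0)
    ramp_s = spec.get("ramp_duration", 1.5)
    fps = spec.get("fps", 65.0)
    angle_noise = spec.get("angle_noise_deg", 0.5)
    tracking_um = spec.get("tracking_noise_nm", 20.0) * 1e-3
    offset = spec.get("force_offset_pN", rng.normal(0.0, 10.0))
    phi_deg = spec.get("phi_deg", 90.0)
    if T_true_pN <= 0 or k <= 0:
        raise ValueError("T_true and k must be positive")

    deltas = np.linspace(1.0, 8.0, n_plateaux)
    # piecewise-linear true deflection schedule
    t_knots = [0.0]
    d_knots = [deltas[0]]
    for i, d in enumerate(deltas):
        t_knots.append(t_knots[-1] + plateau_s)
        d_knots.append(d)
        if i + 1 < n_plateaux:
            t_knots.append(t_knots[-1] + ramp_s)
            d_knots.append(deltas[i + 1])
    total = t_knots[-1]
    t = np.arange(0.0, total, 1.0 / fps)
    delta_true = np.interp(t, t_knots, d_knots)

    sin_phi = math.sin(math.radians(phi_deg))
    f_perp_true = 2.0 * T_true_pN * np.sin(np.radians(delta_true))
    force_true = f_perp_true / sin_phi + offset
    force = force_true + k * rng.normal(0.0, tracking_um, size=t.size)
    delta = delta_true + rng.normal(0.0, angle_noise, size=t.size)

    plateau_spans = []
    tk = 0.0
    for i in range(n_plateaux):
        plateau_spans.append((tk, tk + plateau_s))
        tk += plateau_s + ramp_s

    return BFPRecording(
        t=t, force_pN=force, delta_deg=delta,
        phi_deg=np.full(t.size, phi_deg), fps=fps,
        meta={"T_true_pN": T_true_pN, "k": k, "offset_pN": offset,
              "plateau_spans": plateau_spans})


# ---------------------------------------------------------------------------
# network sequences
# ---------------------------------------------------------------------------

class _Net:
    """Mutable planar network used during generation."""

    def __init__(self):
        self.pos: dict[int, np.ndarray] = {}
        self.adj: dict[int, set] = {}
        self.anchored: set = set()
        self.entangled: set = set()
        self.next_id = 0

    def add_node(self, p, anchored=False) -> int:
        k = self.next_id
        self.next_id += 1
        self.pos[k] = np.asarray(p, dtype=float)
        self.adj[k] = set()
        if anchored:
            self.anchored.add(k)
        return k

    def add_edge(self, a, b):
        if a != b:
            self.adj[a].add(b)
            self.adj[b].add(a)

    def remove_edge(self, a, b):
        self.adj[a].discard(b)
        self.adj[b].discard(a)

    def merge(self, keep, gone):
        """Redirect gone's edges to keep and drop gone."""
        for nb in list(self.adj[gone]):
            self.remove_edge(gone, nb)
            if nb != keep:
                self.add_edge(keep, nb)
        del self.adj[gone]
        del self.pos[gone]
        self.anchored.discard(gone)
        self.entangled.discard(gone)

    def degree(self, k) -> int:
        return len(self.adj[k])

    def junctions(self):
        return [k for k in self.adj
                if self.degree(k) >= 3 and k not in self.anchored]

    def edges(self):
        return [(a, b) for a in self.adj for b in self.adj[a] if a < b]

    def total_length(self) -> float:
        return sum(float(np.linalg.norm(self.pos[a] - self.pos[b]))
                   for a, b in self.edges())

    def to_frame(self, timestamp: float, crossings=()) -> NetworkFrame:
        nodes = {k: {"pos": tuple(self.pos[k]),
                     "kind": "junction" if self.degree(k) >= 3
                     else "endpoint"}
                 for k in self.adj}
        edges = [(a, b, np.vstack([self.pos[a], self.pos[b]]))
                 for a, b in self.edges()]
        return NetworkFrame(timestamp=timestamp, nodes=nodes, edges=edges,
                            crossings=list(crossings))

    def triangles(self):
        tris = []
        for a, b in self.edges():
            for c in self.adj[a] & self.adj[b]:
                if c > b:
                    tris.append((a, b, c))
        return tris


def collapse_triangle(net: _Net, tri) -> int:
    """Merge the three vertices of a triangular loop into one (the network
    analogue of a foam T2 event); exactly two junctions disappear."""
    a, b, c = tri
    centroid = (net.pos[a] + net.pos[b] + net.pos[c]) / 3.0
    for u, v in ((a, b), (b, c), (a, c)):
        net.remove_edge(u, v)
    net.merge(a, b)
    net.merge(a, c)
    net.pos[a] = centroid
    return a


def _voronoi_net(rng, n_seeds: int, field: float, squash: float) -> _Net:
    """Clipped Voronoi diagram of random seeds: interior vertices become
    degree-3 zipper junctions, ridges leaving the field are cut at the
    border into anchored degree-1 tips (axons exiting the field).  The
    y-coordinates are squashed toward the field midline, which sharpens
    the vertex angles into the observed range."""
    pts = rng.uniform(-0.2 * field, 1.2 * field, size=(int(n_seeds * 2), 2))
    vor = Voronoi(pts)

    def transform(p):
        q = np.array([p[0], field / 2.0 + (p[1] - field / 2.0) * squash])
        return q

    def inside(p):
        return 0.0 <= p[0] <= field and 0.0 <= p[1] <= field

    def clip_to_box(p_in, p_out):
        """Intersection of the segment with the box border, seen from the
        inside point."""
        d = p_out - p_in
        t_best = 1.0
        for dim in (0, 1):
            for edge in (0.0, field):
                if abs(d[dim]) < 1e-12:
                    continue
                t = (edge - p_in[dim]) / d[dim]
                if 1e-9 < t < t_best:
                    q = p_in + t * d
                    lo = -1e-9
                    if lo <= q[0] <= field + 1e-9 \
                            and lo <= q[1] <= field + 1e-9:
                        t_best = t
        return p_in + t_best * d

    net = _Net()
    index: dict[int, int] = {}

    def node_of(vi):
        if vi not in index:
            index[vi] = net.add_node(transform(vor.vertices[vi]))
        return index[vi]

    for (v1, v2) in vor.ridge_vertices:
        if v1 < 0 or v2 < 0:
            continue
        p1, p2 = vor.vertices[v1], vor.vertices[v2]
        if inside(p1) and inside(p2):
            net.add_edge(node_of(v1), node_of(v2))
        elif inside(p1) != inside(p2):
            pin, vin = (p1, v1) if inside(p1) else (p2, v2)
            pout = p2 if inside(p1) else p1
            tip = clip_to_box(pin, pout)
            if np.linalg.norm(tip - pin) < 1.0:
                continue
            t_node = net.add_node(transform(tip), anchored=True)
            net.add_edge(node_of(vin), t_node)
    # drop isolated nodes
    for k in [k for k in net.adj if net.degree(k) == 0]:
        del net.adj[k]
        del net.pos[k]
        net.anchored.discard(k)
    return net


def _sharpest(net: _Net, v: int):
    """Sharpest-pair decomposition at a degree-3 vertex.

    Returns (beta_deg, free_nbrs, anchor_nbr) where beta is the sharpest of
    the three pairwise inter-edge angles, the sharpest pair are the free
    segments and the remaining neighbor anchors the zippered segment.
    """
    nbrs = list(net.adj[v])
    if len(nbrs) != 3:
        return None
    dirs = [net.pos[n] - net.pos[v] for n in nbrs]
    norms = [float(np.linalg.norm(d)) for d in dirs]
    if min(norms) < 1e-6:
        return None
    units = [d / n for d, n in zip(dirs, norms)]
    best, pair = None, (0, 1)
    for i in range(3):
        for j in range(i + 1, 3):
            c = float(np.dot(units[i], units[j]))
            if best is None or c > best:
                best, pair = c, (i, j)
    beta = math.degrees(math.acos(max(-1.0, min(1.0, best))))
    k_c = ({0, 1, 2} - set(pair)).pop()
    return beta, (nbrs[pair[0]], nbrs[pair[1]]), nbrs[k_c]


def _recede(net: _Net, v: int, target_deg: float, cap_um: float) -> float:
    """Unzipper: slide the vertex toward its zippered anchor until the
    zipper angle drops to the target or the travel cap is spent.  Returns
    the distance moved.  Entangled vertices do not recede."""
    if v in net.entangled:
        return 0.0
    moved = 0.0
    step = 0.2
    while moved < cap_um:
        sharp = _sharpest(net, v)
        if sharp is None:
            break
        beta, _, anchor = sharp
        if beta <= target_deg:
            break
        d = net.pos[anchor] - net.pos[v]
        dist = float(np.linalg.norm(d))
        if dist < 1.5 + step:
            break
        net.pos[v] = net.pos[v] + (step / dist) * d
        moved += step
    return moved


def gen_network_sequence(spec: GeneratorSpec):
    """Generate a time-lapse of planar network frames.

    The initial geometry is a clipped, anisotropically squashed Voronoi
    diagram whose interior vertices are degree-3 zipper junctions; the
    planted equilibrium-angle law is the set of constructed vertex angles
    (each vertex's adhesion is planted to balance its tension at exactly
    that angle).  Scenarios:

    * "coarsening": scheduled edge contractions and triangle collapses
      remove about 20% of the length over 3 h while per-vertex target
      angles shrink with the growing mean fascicle size n(t) = L0/L(t)
      (tension scales with n, adhesion with sqrt(n));
    * "stable": planted equilibria, nothing moves;
    * "decoarsen": after the ramp onset a tension rise lowers the target
      angles sharply and the network expands by unzippering.

    Returns (frames, manifest); the manifest holds the planted truth.
    """
    rng = spec.rng()
    scenario = spec.scenario
    field_um = spec.get("field", 150.0)
    n_seeds = int(spec.get("n_seeds", 18))
    duration = spec.get("duration_min", 180.0)
    cadence = spec.get("cadence_min", 5.0)
    mean_T = spec.get("mean_T", 0.68)
    sd_T = spec.get("sd_T", 0.25)
    length_loss = spec.get("length_loss", 0.20)
    squash = spec.get("squash", 0.6)
    entangled_frac = spec.get("entangled_fraction", 0.28)
    crossing_frac = spec.get("crossing_fraction", 0.18)

    net = _voronoi_net(rng, n_seeds, field_um, squash)

    # per-vertex tension draws; adhesion planted to balance the as-built
    # vertex angle, defining the planted equilibrium-angle law
    sigma2 = math.log1p((sd_T / mean_T) ** 2)
    mu = math.log(mean_T) - sigma2 / 2.0
    T_v, beta0, S_v = {}, {}, {}
    for v in list(net.adj):
        if net.degree(v) != 3:
            continue
        sharp = _sharpest(net, v)
        if sharp is None:
            continue
        T_v[v] = float(rng.lognormal(mu, math.sqrt(sigma2)))
        beta0[v] = sharp[0]
        S_v[v] = statics.adhesion_from_angle(T_v[v], beta0[v])
    for v in list(T_v):
        if rng.uniform() < entangled_frac:
            net.entangled.add(v)

    def angle_shrink(n_fasc: float, ramp: float = 1.0) -> dict:
        """Target angle per vertex when tension scales by n*ramp and
        adhesion by sqrt(n) (full zippering clipped at 179 deg)."""
        out = {}
        for v, b in beta0.items():
            if v not in net.adj:
                continue
            beta = statics.equilibrium_angle_symmetric(
                T_v[v] * n_fasc * ramp, S_v[v] * math.sqrt(n_fasc))
            out[v] = 179.0 if beta is FULL_ZIPPERING else beta
        return out

    L0 = net.total_length()
    n_frames = int(duration / cadence)
    crossings = [tuple(rng.uniform(0.1 * field_um, 0.9 * field_um, 2))
                 for _ in range(int(crossing_frac * len(T_v)))]
    frames = [net.to_frame(0.0, crossings)]
    manifest = {"scenario": scenario, "seed": spec.seed,
                "tensions": dict(T_v), "adhesions": dict(S_v),
                "planted_beta_eq": dict(beta0), "L0": L0, "events": []}

    if scenario == "stable":
        frames += [net.to_frame(i * cadence, crossings)
                   for i in range(1, n_frames + 1)]
        return frames, manifest

    events = []          # active contractions: [a, b, endpoint_speed]
    retractions = []     # active boundary retractions: [node, speed, speed]
    event_log = manifest["events"]
    ramp_onset = spec.get("ramp_onset_min", 60.0)
    ramp_gain = spec.get("ramp_gain", 3.0)

    def spawn_event(t_min):
        in_event = {n for e in events for n in e[:2]}
        cands = [(a, b) for a, b in net.edges()
                 if net.degree(a) >= 3 and net.degree(b) >= 3
                 and a not in net.anchored and b not in net.anchored
                 and a not in in_event and b not in in_event]
        if not cands:
            return False
        lengths = [float(np.linalg.norm(net.pos[a] - net.pos[b]))
                   for a, b in cands]
        # prefer the shortest edge that still offers real length to remove
        viable = [i for i, ln in enumerate(lengths) if ln >= 5.0]
        idx = (min(viable, key=lambda i: lengths[i]) if viable
               else int(np.argmax(lengths)))
        a, b = cands[idx]
        speed = float(rng.uniform(0.5, 1.8))
        events.append([a, b, speed])
        event_log.append({"t_min": t_min, "kind": "contraction",
                          "nodes": (a, b), "speed_um_min": speed})
        return True

    def advance_events(scale: float = 1.0):
        done = []
        for ev in events:
            a, b, speed = ev
            if (a not in net.adj or b not in net.adj
                    or b not in net.adj[a]):
                done.append(ev)
                continue
            d = net.pos[b] - net.pos[a]
            dist = float(np.linalg.norm(d))
            move = speed * cadence * scale
            if dist <= 1.0:
                mid = 0.5 * (net.pos[a] + net.pos[b])
                net.remove_edge(a, b)
                net.merge(a, b)
                net.pos[a] = mid
                done.append(ev)
                continue
            # approach without overshooting so the eventual merge moves
            # the surviving node's edges only marginally
            closure = min(2 * move, max(dist - 0.8, 0.0))
            step = (closure / 2 / dist) * d
            net.pos[a] = net.pos[a] + step
            net.pos[b] = net.pos[b] - step
        for ev in done:
            events.remove(ev)

    for i in range(1, n_frames + 1):
        t_min = i * cadence
        L = net.total_length()

        if scenario == "decoarsen":
            ramp = 1.0
            if t_min > ramp_onset:
                ramp = 1.0 + (ramp_gain - 1.0) * min(
                    1.0, (t_min - ramp_onset) / 60.0)
            targets = angle_shrink(1.0, ramp=ramp)
            for v in net.junctions():
                if v in targets:
                    _recede(net, v, targets[v], cap_um=0.8 * cadence)
            frames.append(net.to_frame(t_min, crossings))
            continue

        # --- coarsening ---
        n_fasc = max(1.0, L0 / max(L, 1e-9))
        targets = angle_shrink(n_fasc)

        # one scheduled zipper contraction at a time (merges junctions)
        if not events and rng.uniform() < 0.5:
            spawn_event(t_min)
        advance_events()

        # T2-analogue: collapse any sufficiently small triangular loop
        for tri in net.triangles():
            pts = [net.pos[k] for k in tri]
            per = sum(float(np.linalg.norm(pts[i] - pts[(i + 1) % 3]))
                      for i in range(3))
            if per < spec.get("collapse_perimeter", 6.0):
                keep = collapse_triangle(net, tri)
                event_log.append({"t_min": t_min, "kind": "collapse",
                                  "nodes": tri, "kept": keep})
                break

        # unzipper toward the shrunken target angles (adds a little
        # length, so only within the headroom the events created)
        headroom = (L - 0.2) - net.total_length()
        budget = min(0.5 * cadence, max(0.0, headroom))
        excess = []
        for v in net.junctions():
            sharp = _sharpest(net, v)
            if sharp is None or v not in targets:
                continue
            if sharp[0] > targets[v]:
                excess.append((sharp[0] - targets[v], v))
        for _, v in sorted(excess, reverse=True):
            if budget <= 0:
                break
            budget -= _recede(net, v, targets[v],
                              cap_um=min(budget, 0.1 * cadence))

        # boundary retraction: the guaranteed length sink.  Anchored tips
        # (degree 1) slide along their only edge, so each um of travel
        # removes exactly one um of network length.
        target_next = L0 * (1.0 - length_loss * t_min / duration)
        need = max(net.total_length() - target_next,
                   net.total_length() - (L - 0.1))
        while need > 0:
            # top up capacity with new retraction events
            cap = sum(e[2] * cadence for e in retractions)
            if cap < need:
                cands = [k for k in net.anchored
                         if k in net.adj and net.degree(k) == 1
                         and k not in {e[0] for e in retractions}
                         and float(np.linalg.norm(
                             net.pos[k]
                             - net.pos[next(iter(net.adj[k]))])) > 3.0]
                if not cands:
                    break
                k = cands[int(rng.integers(len(cands)))]
                speed = float(rng.uniform(0.5, 1.8))
                retractions.append([k, speed, speed])
                event_log.append({"t_min": t_min, "kind": "retraction",
                                  "nodes": (k,), "speed_um_min": speed})
                continue
            break
        done = []
        for ev in retractions:
            k, speed, _ = ev
            if k not in net.adj or net.degree(k) != 1:
                done.append(ev)
                continue
            nb = next(iter(net.adj[k]))
            d = net.pos[nb] - net.pos[k]
            dist = float(np.linalg.norm(d))
            travel = min(speed * cadence, max(dist - 1.0, 0.0), max(need, 0.0))
            if travel <= 0:
                done.append(ev)
                continue
            net.pos[k] = net.pos[k] + (travel / dist) * d
            need -= travel
            if dist - travel <= 1.5:
                done.append(ev)
        for ev in done:
            retractions.remove(ev)

        # retraction capacity exhausted: fall back to extra contractions
        tries = 0
        while net.total_length() >= L - 0.05 and tries < 8:
            before = net.total_length()
            if len(events) < 3:
                spawn_event(t_min)
            if not events:
                break
            advance_events(scale=0.2)
            if net.total_length() >= before - 1e-6:
                tries += 1

        # last resort: a uniform similarity shrink about the centroid
        # (exact on every edge length, leaves all angles untouched)
        L_now = net.total_length()
        if L_now >= L - 0.05 and L_now > 0:
            f = (L - 0.1) / L_now
            centroid = np.mean(list(net.pos.values()), axis=0)
            for k in net.pos:
                net.pos[k] = centroid + f * (net.pos[k] - centroid)

        frames.append(net.to_frame(t_min, crossings))

    manifest["final_beta_eq"] = {v: b for v, b in
                                 angle_shrink(max(1.0, L0 / max(
                                     net.total_length(), 1e-9))).items()}
    return frames, manifest


def gen_triangle_loop_frame(seed: int) -> NetworkFrame:
    """Random triangular loop of zipper vertices with outward spokes.

    Each corner carries a third edge along the exterior bisector, so the
    sharpest of the three inter-edge angles at every corner is the
    triangle's interior angle.  Corners are resampled until all interior
    angles stay below 110 degrees (at 120 the bisector pair would become
    the sharpest).
    """
    rng = np.random.default_rng(seed)
    while True:
        pts = rng.uniform(-10.0, 10.0, (3, 2))
        angles = []
        for i in range(3):
            v1 = pts[(i + 1) % 3] - pts[i]
            v2 = pts[(i + 2) % 3] - pts[i]
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if min(n1, n2) < 2.0:
                angles = None
                break
            angles.append(math.degrees(math.acos(float(np.clip(
                np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)))))
        if angles and max(angles) < 110.0:
            break
    polys = [[tuple(pts[i]), tuple(pts[(i + 1) % 3])] for i in range(3)]
    for i in range(3):
        v1 = pts[(i + 1) % 3] - pts[i]
        v2 = pts[(i + 2) % 3] - pts[i]
        bis = v1 / np.linalg.norm(v1) + v2 / np.linalg.norm(v2)
        spoke = -bis / np.linalg.norm(bis)
        polys.append([tuple(pts[i]), tuple(pts[i] + 8.0 * spoke)])
    return NetworkFrame.from_polylines(polys, snap_tol=1e-6)
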