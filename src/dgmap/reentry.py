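"""Reentry detection: cycle enumeration, filtering, grouping, tracking.

A directed cycle in a merged activation graph is a candidate reentry.
Because many overlapping cycles describe the same rotating wave, cycles
found in one analysis frame are condensed into *distinct reentries* by
density-based clustering (DBSCAN) of their spatial centroids, and the
per-frame distinct reentries are linked over time into tracks.  Loops are
classified by their winding number around the ventricular cavity axes:

``holo_LV`` / ``holo_RV``
    the loop encircles exactly one cavity (macro-reentry around that
    ventricle);
``biventricular``
    the loop encircles both cavities in a single rotation, i.e. it closes
    around the outside of the heart instead of through the septum;
``localized``
    everything else (functional or small anatomical reentry within the
    wall).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.cluster import DBSCAN

from .geometry import ElectrodeGrid

__all__ = [
    "Cycle",
    "ClusterParams",
    "ReentryCluster",
    "ReentryTrack",
    "SimultaneousProfile",
    "find_cycles",
    "filter_cycles",
    "classify_loop",
    "group_loops",
    "track_reentries",
    "simultaneous_profile",
]

HOLO_CLASSES = frozenset({"holo_LV", "holo_RV", "biventricular"})
_CLASS_SEVERITY = {"localized": 0, "holo_LV": 1, "holo_RV": 1, "biventricular": 2}


@dataclass
class Cycle:
    """One closed directed cycle of electrodes at one analysis frame."""

    electrodes: list[int]  # closed: first == last
    frame_time: float
    center: np.ndarray  # centroid of member positions, mm
    classification: str = "localized"

    @property
    def n_distinct(self) -> int:
        return len(self.electrodes) - 1


@dataclass(frozen=True)
class ClusterParams:
    """DBSCAN parameters for condensing cycles into distinct reentries.

    ``strict_core`` selects the literal "more than min_pts neighbors"
    core rule instead of the classical "at least min_pts (self
    included)"; the classical rule is the default because with
    min_pts = 2 the strict rule would demote a pair of coincident loop
    detections to noise.
    """

    d_eps: float = 10.0  # mm
    min_pts: int = 2
    strict_core: bool = False

    def __post_init__(self) -> None:
        if self.d_eps <= 0:
            raise ValueError("d_eps must be positive")
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")


@dataclass
class ReentryCluster:
    """One distinct reentry at one frame: a condensed group of cycles."""

    frame_time: float
    center: np.ndarray
    members: list[Cycle]
    classification: str

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class ReentryTrack:
    """One distinct reentry followed over consecutive frames."""

    track_id: int
    frames: list[tuple[float, np.ndarray, str]]  # (time, center, class)
    frame_step: float

    @property
    def start(self) -> float:
        return self.frames[0][0]

    @property
    def end(self) -> float:
        """End of the last frame's interval (exclusive)."""
        return self.frames[-1][0] + self.frame_step

    @property
    def duration(self) -> float:
        return self.end - self.start

    @property
    def mean_center(self) -> np.ndarray:
        return np.mean([c for _, c, _ in self.frames], axis=0)

    @property
    def classification(self) -> str:
        """Modal class over the lifetime, severity breaking ties."""
        classes = [cl for _, _, cl in self.frames]
        return max(
            set(classes), key=lambda c: (classes.count(c), _CLASS_SEVERITY[c])
        )

    def class_at(self, t: float) -> str:
        for ft, _, cl in reversed(self.frames):
            if ft <= t:
                return cl
        return self.frames[0][2]

    def class_fractions(self) -> dict[str, float]:
        classes = [cl for _, _, cl in self.frames]
        return {c: classes.count(c) / len(classes) for c in set(classes)}

    @classmethod
    def from_interval(
        cls, track_id: int, start: float, end: float,
        classification: str = "localized", center=(0.0, 0.0, 0.0),
        frame_step: float = 50.0,
    ) -> "ReentryTrack":
        """Build a track from a plain [start, end) interval."""
        times = np.arange(start, end, frame_step)
        if len(times) == 0:
            times = np.array([start])
        step = end - times[-1]
        frames = [(float(t), np.asarray(center, float), classification) for t in times]
        return cls(track_id, frames, frame_step=float(step if len(times) == 1 else frame_step))


def find_cycles(
    merged: nx.DiGraph, max_len: int = 12, max_cycles: int | None = 2000
) -> list[Cycle]:
    """Elementary directed cycles with 3..max_len distinct electrodes.

    Each cycle is annotated with the centroid of its member electrode
    positions and the frame time of the merged graph it came from.  On
    dense merged graphs the number of elementary cycles grows
    combinatorially with redundant chords; enumeration stops after
    ``max_cycles`` (the surplus cycles are homotopic variants of ones
    already found, which the downstream clustering would condense
    anyway).  ``max_cycles=None`` enumerates exhaustively.
    """
    t0 = merged.graph.get("build_times", (0.0,))[0]
    out = []
    for nodes in nx.simple_cycles(merged, length_bound=max_len):
        if len(nodes) < 3:
            continue
        pos = np.array([merged.nodes[n]["pos"] for n in nodes])
        out.append(Cycle(list(nodes) + [nodes[0]], t0, pos.mean(axis=0)))
        if max_cycles is not None and len(out) >= max_cycles:
            break
    return out


def _best_fit_plane(points: np.ndarray) -> np.ndarray:
    """Project 3D points onto their best-fit plane; returns (n, 2)."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return centered @ vt[:2].T


def _cross2(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def _point_segment_dist(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distance from points p to segments a-b, elementwise over leading axes."""
    ab = b - a
    denom = np.einsum("...i,...i", ab, ab)
    t = np.einsum("...i,...i", p - a, ab) / np.where(denom == 0, 1.0, denom)
    t = np.clip(np.where(denom == 0, 0.0, t), 0.0, 1.0)
    closest = a + t[..., None] * ab
    return np.linalg.norm(p - closest, axis=-1)


def _min_pair_segment_distances(
    p1: np.ndarray, p2: np.ndarray, q1: np.ndarray, q2: np.ndarray
) -> np.ndarray:
    """Min distance between segment pairs (p1-p2 vs q1-q2), vectorized."""
    d1, d2 = p2 - p1, q2 - q1
    denom = _cross2(d1, d2)
    r = q1 - p1
    with np.errstate(divide="ignore", invalid="ignore"):
        s = _cross2(r, d2) / denom
        u = _cross2(r, d1) / denom
    crossing = (
        (np.abs(denom) > 1e-12)
        & (s >= 0) & (s <= 1) & (u >= 0) & (u <= 1)
    )
    endpoint = np.min(
        np.stack(
            [
                _point_segment_dist(q1, p1, p2),
                _point_segment_dist(q2, p1, p2),
                _point_segment_dist(p1, q1, q2),
                _point_segment_dist(p2, q1, q2),
            ]
        ),
        axis=0,
    )
    return np.where(crossing, 0.0, endpoint)


def filter_cycles(
    cycles: list[Cycle],
    grid: ElectrodeGrid,
    cos_max: float = 0.75,
    crossing_tol: float = 0.5,
) -> list[Cycle]:
    """Drop geometrically impossible loops.

    A cycle is removed if (a) any two non-adjacent segments pass within
    ``crossing_tol`` of each other after projection onto the cycle's
    best-fit plane (self-crossing, e.g. a figure-eight), or (b) at any
    vertex the cosine of the angle between the two incident segments
    (vectors from the vertex to its two cycle neighbors) exceeds
    ``cos_max`` — a sharp doubling-back that no smooth wavefront can
    follow.
    """
    kept = []
    for cyc in cycles:
        nodes = cyc.electrodes[:-1]
        pts = np.array([grid.position(e) for e in nodes])
        n = len(nodes)

        v1 = np.roll(pts, 1, axis=0) - pts
        v2 = np.roll(pts, -1, axis=0) - pts
        denom = np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        if np.any(denom == 0) or np.any(
            np.einsum("ij,ij->i", v1, v2) / denom > cos_max
        ):
            continue

        flat = _best_fit_plane(pts)
        nxt = np.roll(np.arange(n), -1)
        ii, jj = zip(
            *(
                (i, j)
                for i, j in itertools.combinations(range(n), 2)
                # skip segments sharing a vertex (cyclically adjacent)
                if not (j == i + 1 or (i == 0 and j == n - 1))
            )
        ) if n > 3 else ((), ())
        if len(ii) == 0 or np.all(
            _min_pair_segment_distances(
                flat[list(ii)], flat[nxt[list(ii)]],
                flat[list(jj)], flat[nxt[list(jj)]],
            )
            >= crossing_tol
        ):
            kept.append(cyc)
    return kept


def _winding_number(points_2d: np.ndarray, about: np.ndarray) -> int:
    """Signed winding of a closed polygon (first != last) about a point."""
    rel = points_2d - about[None, :]
    ang = np.arctan2(rel[:, 1], rel[:, 0])
    d = np.diff(np.append(ang, ang[0]))
    d = np.mod(d + np.pi, 2 * np.pi) - np.pi
    return int(round(d.sum() / (2 * np.pi)))


def classify_loop(cycle: Cycle, grid: ElectrodeGrid) -> str:
    """Classify a loop by winding numbers around the cavity axes.

    Encircling both cavity axes means the loop closes around the outside
    of both ventricles (biventricular); exactly one, a holo-ventricular
    loop of that cavity; neither, a localized reentry.
    """
    if not grid.cavity_axes:
        raise ValueError("grid has no cavity axes")
    pts = np.array([grid.position(e) for e in cycle.electrodes[:-1]])
    winds = {}
    for name in ("LV", "RV"):
        axis = grid.cavity_axes[name]
        w = np.asarray(axis.direction, float)
        w = w / np.linalg.norm(w)
        seed = np.array([1.0, 0.0, 0.0])
        if abs(seed @ w) > 0.9:
            seed = np.array([0.0, 1.0, 0.0])
        u = seed - (seed @ w) * w
        u /= np.linalg.norm(u)
        v = np.cross(w, u)
        rel = pts - np.asarray(axis.point, float)
        flat = np.c_[rel @ u, rel @ v]
        winds[name] = abs(_winding_number(flat, np.zeros(2)))
    if winds["LV"] >= 1 and winds["RV"] >= 1:
        return "biventricular"
    if winds["LV"] >= 1:
        return "holo_LV"
    if winds["RV"] >= 1:
        return "holo_RV"
    return "localized"


def group_loops(
    cycles: list[Cycle], params: ClusterParams | None = None
) -> list[ReentryCluster]:
    """Condense one frame's cycles into distinct reentries via DBSCAN.

    Clustering runs on the Euclidean distances between cycle centroids.
    Noise points are kept as singleton reentries: a lone clean loop is
    still a reentry.  Each cluster's class is the modal class of its
    member cycles (ties broken toward the more extensive class).
    """
    if not cycles:
        return []
    params = params or ClusterParams()
    centers = np.array([c.center for c in cycles])
    min_samples = params.min_pts + 1 if params.strict_core else params.min_pts
    labels = DBSCAN(eps=params.d_eps, min_samples=min_samples).fit_predict(centers)

    clusters = []
    next_noise = labels.max() + 1 if (labels >= 0).any() else 0
    groups: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        if lab == -1:
            groups[next_noise] = [i]
            next_noise += 1
        else:
            groups.setdefault(int(lab), []).append(i)
    for idxs in groups.values():
        members = [cycles[i] for i in idxs]
        classes = [m.classification for m in members]
        cls = max(set(classes), key=lambda c: (classes.count(c), _CLASS_SEVERITY[c]))
        clusters.append(
            ReentryCluster(
                frame_time=members[0].frame_time,
                center=centers[idxs].mean(axis=0),
                members=members,
                classification=cls,
            )
        )
    return clusters


def track_reentries(
    frame_clusters: list[tuple[float, list[ReentryCluster]]],
    linking_radius: float = 10.0,
    frame_step: float | None = None,
) -> list[ReentryTrack]:
    """Link per-frame distinct reentries into tracks over time.

    Greedy nearest-center matching between consecutive frames: the
    closest (track, cluster) pairs within ``linking_radius`` are linked
    first; unmatched clusters open new tracks and unmatched tracks end.
    """
    if frame_step is None:
        times = [t for t, _ in frame_clusters]
        frame_step = float(np.median(np.diff(times))) if len(times) > 1 else 50.0

    tracks: list[ReentryTrack] = []
    active: list[ReentryTrack] = []
    next_id = 0
    for t, clusters in frame_clusters:
        if active and clusters:
            pairs = sorted(
                (
                    (np.linalg.norm(tr.frames[-1][1] - cl.center), i, j)
                    for i, tr in enumerate(active)
                    for j, cl in enumerate(clusters)
                ),
            )
            used_tr: set[int] = set()
            used_cl: set[int] = set()
            matches = {}
            for d, i, j in pairs:
                if d > linking_radius or i in used_tr or j in used_cl:
                    continue
                matches[j] = i
                used_tr.add(i)
                used_cl.add(j)
        else:
            matches, used_tr = {}, set()

        still_active = []
        for j, cl in enumerate(clusters):
            if j in matches:
                tr = active[matches[j]]
                tr.frames.append((t, cl.center, cl.classification))
            else:
                tr = ReentryTrack(next_id, [(t, cl.center, cl.classification)], frame_step)
                next_id += 1
                tracks.append(tr)
            still_active.append(tr)
        active = still_active
    return tracks


@dataclass
class SimultaneousProfile:
    """Time composition of an episode by number of concurrent reentries."""

    total_reentry_ms: float
    time_by_count: dict[int, float]  # k -> ms with exactly k loops (k >= 1)
    fractions_pct: dict[int, float]  # k -> % of reentry-present time
    mean_loops: float  # time-weighted mean count over reentry time
    max_loops: int
    n_tracks: int
    holo_fraction_pct: float | None  # % of reentry time with a holo/bi loop


def simultaneous_profile(
    tracks: list[ReentryTrack],
    episode_span: tuple[float, float] | None = None,
) -> SimultaneousProfile:
    """Distinct-loop count profile over the reentry-present time.

    Fractions are percentages of the total time during which at least one
    reentry is present (they sum to 100% whenever that time is positive).
    The holo fraction is the share of reentry-present time during which
    at least one track is holo- or bi-ventricular.
    """
    if not tracks:
        return SimultaneousProfile(0.0, {}, {}, 0.0, 0, 0, None)

    edges = sorted(
        {tr.start for tr in tracks}
        | {tr.end for tr in tracks}
        | {ft for tr in tracks for ft, _, _ in tr.frames}
    )
    if episode_span is not None:
        lo, hi = episode_span
        edges = sorted({max(lo, min(hi, e)) for e in edges} | {lo, hi})

    time_by_count: dict[int, float] = {}
    holo_ms = 0.0
    weighted = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        mid = (a + b) / 2.0
        covering = [tr for tr in tracks if tr.start <= mid < tr.end]
        k = len(covering)
        if k == 0:
            continue
        dt = b - a
        time_by_count[k] = time_by_count.get(k, 0.0) + dt
        weighted += k * dt
        if any(tr.class_at(mid) in HOLO_CLASSES for tr in covering):
            holo_ms += dt

    total = sum(time_by_count.values())
    fractions = {k: 100.0 * v / total for k, v in time_by_count.items()}
    return SimultaneousProfile(
        total_reentry_ms=total,
        time_by_count=time_by_count,
        fractions_pct=fractions,
        mean_loops=weighted / total if total else 0.0,
        max_loops=max(time_by_count) if time_by_count else 0,
        n_tracks=len(tracks),
        holo_fraction_pct=100.0 * holo_ms / total if total else None,
    )
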