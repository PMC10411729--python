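"""Directed activation networks from local activation times.

At a build time ``t``, every usable electrode contributes its activation
time nearest to ``t`` (within a window).  For each neighboring electrode
pair, the apparent conduction velocity Δd/|ΔLAT| is computed from the
inter-electrode distance and the LAT difference; if it falls strictly
inside the permissible band (cv_min, cv_max), a directed edge is drawn
from the earlier-activated electrode to the later one.  Such a graph is
necessarily acyclic: activation time strictly increases along every edge,
so a reentrant loop cannot close — somewhere along the loop a late LAT
sits next to an early one, their difference being the loop's cycle
length, which fails the velocity gate.  Building a second graph half a
cycle later and taking the union moves that discontinuity to a different
part of the loop, and reentry becomes visible as a directed cycle in the
merged graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .geometry import ElectrodeGrid, NeighborParams

__all__ = [
    "GraphParams",
    "build_graph",
    "merge_graphs",
    "build_frames",
    "estimate_cycle_length",
]


@dataclass(frozen=True)
class GraphParams:
    """Velocity gate and timing parameters for graph construction.

    cv_min / cv_max bound the physiological ventricular conduction
    velocity (mm/ms); delta_t is the offset between the two graphs that
    are merged per analysis frame; lat_window limits how far an
    electrode's chosen LAT may sit from the build time; step is the frame
    stride for sliding analysis.  delta_t and lat_window default to half
    and one estimated activation cycle length respectively when left None.
    """

    cv_min: float = 0.2
    cv_max: float = 2.0
    delta_t: float | None = None
    lat_window: float | None = None
    step: float = 50.0
    neighbor: NeighborParams = field(default_factory=NeighborParams)

    def __post_init__(self) -> None:
        if not 0 < self.cv_min < self.cv_max:
            raise ValueError("need 0 < cv_min < cv_max")
        if self.delta_t is not None and self.delta_t <= 0:
            raise ValueError("delta_t must be positive")
        if self.lat_window is not None and self.lat_window <= 0:
            raise ValueError("lat_window must be positive")

    def resolve(self, events: pd.DataFrame) -> "GraphParams":
        """Fill delta_t / lat_window from the events' median cycle length."""
        if self.delta_t is not None and self.lat_window is not None:
            return self
        cl = estimate_cycle_length(events)
        return GraphParams(
            cv_min=self.cv_min,
            cv_max=self.cv_max,
            delta_t=self.delta_t if self.delta_t is not None else cl / 2.0,
            lat_window=self.lat_window if self.lat_window is not None else cl,
            step=self.step,
            neighbor=self.neighbor,
        )


def estimate_cycle_length(events: pd.DataFrame, default: float = 200.0) -> float:
    """Median interval between successive activations of one electrode.

    Electrodes with a single activation contribute nothing; if none has a
    repeat activation the default is returned.
    """
    diffs = []
    for _, grp in events.groupby("electrode_id"):
        t = np.sort(grp["time_ms"].to_numpy())
        if len(t) > 1:
            diffs.append(np.diff(t))
    if not diffs:
        return default
    return float(np.median(np.concatenate(diffs)))


def _nearest_lats(events: pd.DataFrame, t: float, window: float) -> dict[int, float]:
    """Per electrode, the LAT nearest to t within +-window."""
    ids = events["electrode_id"].to_numpy()
    times = events["time_ms"].to_numpy(float)
    off = np.abs(times - t)
    mask = off <= window
    ids, times, off = ids[mask], times[mask], off[mask]
    order = np.argsort(off, kind="stable")
    uniq, first = np.unique(ids[order], return_index=True)
    chosen = times[order][first]
    return {int(e): float(lat) for e, lat in zip(uniq, chosen)}


def build_graph(
    events: pd.DataFrame,
    grid: ElectrodeGrid,
    t: float,
    params: GraphParams,
) -> nx.DiGraph:
    """Directed activation graph at build time ``t``.

    Nodes are electrode ids with a ``lat`` attribute; edges carry
    ``dlat`` (ms), ``dist`` (mm) and ``cv`` (mm/ms) and run from the
    earlier-activated electrode to the later one.  ΔLAT = 0 draws no
    edge: the direction would be undefined and the apparent velocity
    infinite, outside the open velocity interval.
    """
    if len(events) == 0:
        raise ValueError("events table is empty")
    params = params.resolve(events)
    lats = _nearest_lats(events, t, params.lat_window)

    g = nx.DiGraph(build_time=t)
    pos = {int(e): grid.position(int(e)) for e in lats}
    for eid, lat in lats.items():
        g.add_node(eid, lat=lat, pos=pos[eid])

    nbrs = grid.neighbor_map(params.neighbor)
    for a, lat_a in lats.items():
        for b in nbrs.get(a, ()):
            if b <= a or b not in lats:
                continue
            lat_b = lats[b]
            dlat = lat_b - lat_a
            if dlat == 0:
                continue
            dist = float(np.linalg.norm(pos[a] - pos[b]))
            cv = dist / abs(dlat)
            if not params.cv_min < cv < params.cv_max:
                continue
            src, dst = (a, b) if dlat > 0 else (b, a)
            g.add_edge(src, dst, dlat=abs(dlat), dist=dist, cv=cv)
    return g


def merge_graphs(g1: nx.DiGraph, g2: nx.DiGraph) -> nx.DiGraph:
    """Union of two activation graphs built at t and t + Δt.

    Nodes are electrodes, so the union can contain directed cycles even
    though each source graph is acyclic.  Node ``lats`` collects the LATs
    the electrode carried in each source graph.
    """
    merged = nx.DiGraph(
        build_times=(g1.graph.get("build_time"), g2.graph.get("build_time"))
    )
    for g in (g1, g2):
        for n, d in g.nodes(data=True):
            if merged.has_node(n):
                merged.nodes[n]["lats"] = sorted(
                    set(merged.nodes[n]["lats"]) | {d["lat"]}
                )
            else:
                merged.add_node(n, lats=[d["lat"]], pos=d["pos"])
        for u, v, d in g.edges(data=True):
            if not merged.has_edge(u, v):
                merged.add_edge(u, v, **d)
    return merged


def build_frames(
    events: pd.DataFrame,
    grid: ElectrodeGrid,
    params: GraphParams | None = None,
    t_start: float | None = None,
    t_end: float | None = None,
) -> list[tuple[float, nx.DiGraph]]:
    """Sliding merged-graph analysis across an episode.

    Returns ``(frame_time, merged_graph)`` pairs, one per ``step`` ms from
    t_start to t_end (defaults: the events' time span).
    """
    params = (params or GraphParams()).resolve(events)
    if t_start is None:
        t_start = float(events["time_ms"].min())
    if t_end is None:
        t_end = float(events["time_ms"].max())
    frames = []
    for t in np.arange(t_start, t_end + 1e-9, params.step):
        g1 = build_graph(events, grid, float(t), params)
        g2 = build_graph(events, grid, float(t) + params.delta_t, params)
        frames.append((float(t), merge_graphs(g1, g2)))
    return frames
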