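"""End-to-end episode analysis: events in, summary and artifacts out.

The stages are: build merged activation graphs on a sliding time grid;
enumerate, filter and classify directed cycles per frame; condense cycles
into distinct reentries (DBSCAN) and link them into tracks; detect and
verify focal sources; summarize the episode.  Every run is a pure
function of (inputs, configuration, seed); when an output directory is
given, all intermediate artifacts plus the resolved configuration are
written as CSV/JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import AnnotationParams
from .focal import FocalSource, detect_candidates, heatmap, verify_all
from .geometry import ElectrodeGrid, NeighborParams
from .graph import GraphParams, build_frames
from .reentry import (
    ClusterParams,
    ReentryTrack,
    classify_loop,
    filter_cycles,
    find_cycles,
    group_loops,
    track_reentries,
)
from .stats import EpisodeSummary, summarize
from .synthetic import ElectrogramSet

__all__ = ["RunConfig", "EpisodeResult", "run_episode"]


@dataclass
class RunConfig:
    """All tunable parameters of one episode analysis."""

    neighbor: NeighborParams = field(default_factory=NeighborParams)
    graph: GraphParams = field(default_factory=GraphParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    annotation: AnnotationParams = field(default_factory=AnnotationParams)
    max_cycle_len: int = 12
    max_cycles_per_frame: int = 2000
    cos_max: float = 0.75
    crossing_tol: float = 0.5
    linking_radius: float = 10.0
    upstroke_fraction: float = 0.10
    seed: int = 0
    episode_id: str = "episode"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["version"] = __version__
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d.pop("version", None)
        for key, typ in (
            ("neighbor", NeighborParams),
            ("graph", GraphParams),
            ("cluster", ClusterParams),
            ("annotation", AnnotationParams),
        ):
            if key in d and isinstance(d[key], dict):
                if key == "graph" and isinstance(d[key].get("neighbor"), dict):
                    d[key]["neighbor"] = NeighborParams(**d[key]["neighbor"])
                d[key] = typ(**d[key])
        return cls(**d)


@dataclass
class EpisodeResult:
    """Everything one pipeline run produced."""

    summary: EpisodeSummary
    tracks: list[ReentryTrack]
    focal_sources: list[FocalSource]  # verified (confirmed or rejected)
    frames: list  # (time, merged graph)
    frame_cycles: list  # (time, filtered classified cycles)
    config: RunConfig

    @property
    def confirmed_sources(self) -> list[FocalSource]:
        return [s for s in self.focal_sources if s.status.endswith("confirmed")]


def run_episode(
    events: pd.DataFrame,
    grid: ElectrodeGrid,
    config: RunConfig | None = None,
    electrograms: ElectrogramSet | None = None,
    out_dir: str | Path | None = None,
) -> EpisodeResult:
    """Analyse one episode of activation events.

    If ``electrograms`` are given, focal candidates are verified on the
    unipolar traces (upstroke criterion); otherwise the pre-LAT silence
    fallback is used.  See :class:`RunConfig` for the knobs.
    """
    config = config or RunConfig()
    gp = GraphParams(
        cv_min=config.graph.cv_min,
        cv_max=config.graph.cv_max,
        delta_t=config.graph.delta_t,
        lat_window=config.graph.lat_window,
        step=config.graph.step,
        neighbor=config.neighbor,
    ).resolve(events)

    frames = build_frames(events, grid, gp)

    frame_clusters = []
    frame_cycles = []
    for t, merged in frames:
        cycles = find_cycles(
            merged, max_len=config.max_cycle_len, max_cycles=config.max_cycles_per_frame
        )
        cycles = filter_cycles(cycles, grid, config.cos_max, config.crossing_tol)
        for c in cycles:
            c.classification = classify_loop(c, grid)
        frame_cycles.append((t, cycles))
        frame_clusters.append((t, group_loops(cycles, config.cluster)))

    tracks = track_reentries(
        frame_clusters, linking_radius=config.linking_radius, frame_step=gp.step
    )

    candidates = detect_candidates(frames)
    sources = verify_all(
        candidates,
        electrograms,
        grid=grid,
        events=events,
        upstroke_fraction=config.upstroke_fraction,
    )
    confirmed = [s for s in sources if s.status.endswith("confirmed")]

    span = (float(events["time_ms"].min()), float(events["time_ms"].max()))
    summary = summarize(
        tracks,
        confirmed,
        episode_id=config.episode_id,
        duration_s=(span[1] - span[0]) / 1000.0,
        episode_span=span,
    )

    result = EpisodeResult(summary, tracks, sources, frames, frame_cycles, config)
    if out_dir is not None:
        _write_artifacts(result, events, grid, Path(out_dir))
    return result


def _write_artifacts(
    result: EpisodeResult, events: pd.DataFrame, grid: ElectrodeGrid, out: Path
) -> None:
    out.mkdir(parents=True, exist_ok=True)
    events.to_csv(out / "events.csv", index=False)

    pd.DataFrame(
        [
            {
                "track_id": tr.track_id,
                "start_ms": tr.start,
                "end_ms": tr.end,
                "class": tr.classification,
                "mean_x": tr.mean_center[0],
                "mean_y": tr.mean_center[1],
                "mean_z": tr.mean_center[2],
            }
            for tr in result.tracks
        ],
        columns=["track_id", "start_ms", "end_ms", "class", "mean_x", "mean_y", "mean_z"],
    ).to_csv(out / "tracks.csv", index=False)

    pd.DataFrame(
        [
            {
                "frame_ms": t,
                "n_loops": len(cl),
                "classes": ";".join(sorted({c.classification for c in cl})),
            }
            for (t, _), (_, cl) in zip(result.frames, result.frame_cycles)
        ],
        columns=["frame_ms", "n_loops", "classes"],
    ).to_csv(out / "frames.csv", index=False)

    pd.DataFrame(
        [
            {"electrode_id": s.electrode, "time_ms": s.time, "status": s.status}
            for s in result.focal_sources
        ],
        columns=["electrode_id", "time_ms", "status"],
    ).to_csv(out / "sources.csv", index=False)

    heatmap(result.confirmed_sources, grid).to_csv(out / "heatmap.csv", index=False)

    s = result.summary
    with open(out / "summary.json", "w") as fh:
        json.dump(
            {
                "episode_id": s.episode_id,
                "label": s.label,
                "duration_s": s.duration_s,
                "mean_loops": s.mean_loops,
                "max_loops": s.max_loops,
                "n_tracks": s.n_tracks,
                "holo_fraction_pct": s.holo_fraction_pct,
                "n_focal_beats": s.n_focal_beats,
            },
            fh,
            indent=1,
        )
    with open(out / "config.json", "w") as fh:
        json.dump(result.config.to_dict(), fh, indent=1, default=str)
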