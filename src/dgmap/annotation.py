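"""Local activation time annotation of unipolar electrograms.

The wavefront passage under a unipolar electrode produces the steepest
negative deflection of the trace, so each LAT is marked at the sample
where the first difference of the trace is most negative within a
sliding window (default 200 ms).  Low-amplitude markings — deflections
whose peak absolute amplitude within ±10 ms falls below 10% of the
electrode's average peak amplitude — are discarded as noise, unless a
neighboring electrode holds an accepted LAT close enough in time, in
which case the marking is rescued (a genuine low-amplitude activation in
a region the wave demonstrably reached).

Manual curation is supported as a programmatic edit overlay: a table of
add/remove edits applied on top of the automatic annotations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .geometry import ElectrodeGrid, NeighborParams
from .synthetic import ElectrogramSet

__all__ = ["AnnotationParams", "annotate", "apply_edits"]


@dataclass(frozen=True)
class AnnotationParams:
    """Marking-rule parameters (all in ms except the fraction)."""

    window: float = 200.0  # sliding window for the most-negative derivative
    amp_fraction: float = 0.10  # acceptance threshold vs average peak amplitude
    amp_window: float = 10.0  # +- ms around the marking for the peak search
    rescue_tolerance: float = 10.0  # neighbor-LAT closeness for rescue

    def __post_init__(self) -> None:
        for name in ("window", "amp_fraction", "amp_window", "rescue_tolerance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def annotate(
    electrograms: ElectrogramSet,
    grid: ElectrodeGrid,
    params: AnnotationParams | None = None,
    neighbor_params: NeighborParams | None = None,
) -> pd.DataFrame:
    """Annotate LATs on every usable electrode's trace.

    Returns an events table ``electrode_id, time_ms, quality`` with
    quality ``auto`` (passed the amplitude check) or ``rescued``
    (accepted only through neighbor support).
    """
    params = params or AnnotationParams()
    fs = electrograms.sampling_rate
    if fs < 500:
        raise ValueError("sampling_rate must be >= 500 Hz for derivative fidelity")
    if electrograms.n_samples < 2:
        raise ValueError("traces are empty or too short")
    dt_ms = 1000.0 / fs
    win_samples = max(1, int(round(params.window / dt_ms)))
    amp_samples = max(1, int(round(params.amp_window / dt_ms)))

    accepted: list[tuple[int, float]] = []
    rejected: list[tuple[int, float]] = []
    for eid in electrograms.traces.columns:
        tr = electrograms.trace(eid)
        d = np.diff(tr)
        if not np.any(d < 0):
            continue
        # candidate markings: minima of the first difference, each the most
        # negative within the sliding window
        peaks, _ = find_peaks(-d, distance=win_samples)
        if len(peaks) == 0:
            continue
        amps = np.array(
            [
                np.abs(tr[max(0, p - amp_samples): p + amp_samples + 1]).max()
                for p in peaks
            ]
        )
        avg_peak = amps.mean()
        for p, amp in zip(peaks, amps):
            t = p * dt_ms
            if amp >= params.amp_fraction * avg_peak:
                accepted.append((int(eid), t))
            else:
                rejected.append((int(eid), t))

    # rescue pass: a rejected marking survives if any neighbor electrode
    # holds an accepted LAT within the tolerance
    nbrs = grid.neighbor_map(neighbor_params)
    acc_by_electrode: dict[int, np.ndarray] = {}
    for eid, t in accepted:
        acc_by_electrode.setdefault(eid, [])
    for eid, t in accepted:
        acc_by_electrode[eid].append(t)
    acc_by_electrode = {k: np.asarray(v) for k, v in acc_by_electrode.items()}

    rescued = []
    for eid, t in rejected:
        for nb in nbrs.get(eid, ()):
            ts = acc_by_electrode.get(nb)
            if ts is not None and np.any(np.abs(ts - t) <= params.rescue_tolerance):
                rescued.append((eid, t))
                break

    rows = [
        {"electrode_id": e, "time_ms": t, "quality": "auto"} for e, t in accepted
    ] + [
        {"electrode_id": e, "time_ms": t, "quality": "rescued"} for e, t in rescued
    ]
    events = pd.DataFrame(rows, columns=["electrode_id", "time_ms", "quality"])
    return events.sort_values(["time_ms", "electrode_id"], ignore_index=True)


def apply_edits(events: pd.DataFrame, edits: pd.DataFrame, tol: float = 1.0) -> pd.DataFrame:
    """Apply a manual-curation overlay to an events table.

    ``edits`` has columns ``action`` ("add" or "remove"),
    ``electrode_id`` and ``time_ms``; removals match any event of that
    electrode within ``tol`` ms.  Added events get quality ``manual``.
    """
    out = events.copy()
    if "quality" not in out.columns:
        out["quality"] = "auto"
    for row in edits.itertuples():
        if row.action == "add":
            out = pd.concat(
                [out, pd.DataFrame([
                    {"electrode_id": int(row.electrode_id),
                     "time_ms": float(row.time_ms), "quality": "manual"}
                ])],
                ignore_index=True,
            )
        elif row.action == "remove":
            keep = ~(
                (out["electrode_id"] == row.electrode_id)
                & (np.abs(out["time_ms"] - row.time_ms) <= tol)
            )
            out = out[keep]
        else:
            raise ValueError(f"unknown edit action {row.action!r}")
    return out.sort_values(["time_ms", "electrode_id"], ignore_index=True)
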