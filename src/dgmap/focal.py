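"""Focal-source detection, heatmaps and the binomial spatial-randomness null.

A focal (ectopic) beat appears in a directed activation graph as a node
with outgoing arrows only: the wave starts there, nothing arrives.  Graph
topology alone over-calls focal sources — the entry edge of any passing
wavefront also has no upstream electrode — so candidates are verified on
the unipolar electrogram: a true focal origin shows no positive upstroke
before its intrinsic negative deflection (QS morphology), because no wave
approaches the electrode.  Verified sources are aggregated into
per-electrode heatmaps and compared against the null hypothesis that n
sources land independently and uniformly on e electrodes, under which the
per-electrode source count follows a binomial distribution with
p = 1/e (Eq. of the occupancy model):

    p_x = C(n, x) p^x (1 - p)^(n - x),   x = 0..n
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .geometry import ElectrodeGrid, NeighborParams
from .synthetic import ElectrogramSet

__all__ = [
    "FocalSource",
    "BinomialNull",
    "detect_candidates",
    "verify",
    "verify_all",
    "heatmap",
    "binomial_null",
    "randomness_table",
]


@dataclass
class FocalSource:
    """A candidate or verified ectopic origin."""

    electrode: int
    time: float  # ms (the LAT of the only-outgoing node)
    status: str = "auto"  # auto | electrogram_confirmed | silence_confirmed | rejected


def detect_candidates(
    frames: list[tuple[float, nx.DiGraph]],
    dedup_tol: float = 1.0,
) -> list[FocalSource]:
    """Nodes with only outgoing arrows across all analysis frames.

    A node qualifies if it has at least one outgoing and no incoming edge
    in a merged frame graph.  The same physical beat appears in several
    overlapping frames; duplicates are collapsed by (electrode, LAT)
    within ``dedup_tol`` ms.
    """
    seen: dict[int, list[float]] = {}
    out: list[FocalSource] = []
    for _, g in frames:
        for n in g.nodes:
            if g.out_degree(n) >= 1 and g.in_degree(n) == 0:
                lat = min(g.nodes[n]["lats"])
                times = seen.setdefault(n, [])
                if any(abs(lat - t) <= dedup_tol for t in times):
                    continue
                times.append(lat)
                out.append(FocalSource(int(n), float(lat)))
    out.sort(key=lambda s: (s.time, s.electrode))
    return out


def verify(
    candidate: FocalSource,
    electrograms: ElectrogramSet | None,
    grid: ElectrodeGrid | None = None,
    events: pd.DataFrame | None = None,
    upstroke_fraction: float = 0.10,
    pre_window: float = 15.0,
    silent_window: float = 50.0,
    neighbor_params: NeighborParams | None = None,
) -> FocalSource:
    """Confirm or reject a candidate focal origin.

    With electrograms: confirmed iff the positive excursion of the trace
    in the ``pre_window`` ms before the LAT stays below
    ``upstroke_fraction`` of the trace's mean peak amplitude (a QS
    complex — no incoming wave).  Without electrograms, a pre-LAT silence
    criterion is used instead: confirmed iff no neighboring electrode
    activated within ``silent_window`` ms before the candidate's LAT.
    """
    if electrograms is not None:
        if candidate.electrode not in electrograms.traces.columns:
            raise KeyError(f"no trace for electrode {candidate.electrode}")
        tr = electrograms.trace(candidate.electrode)
        times = electrograms.times_ms
        mean_peak = _mean_peak_amplitude(tr, electrograms.sampling_rate)
        sel = (times >= candidate.time - pre_window) & (times < candidate.time - 1.0)
        upstroke = float(np.max(tr[sel], initial=0.0))
        # absence of an upstroke can only be asserted when the pre-LAT
        # baseline is actually recorded
        baseline_ok = candidate.time - pre_window >= times[0]
        ok = baseline_ok and mean_peak > 0 and upstroke <= upstroke_fraction * mean_peak
        status = "electrogram_confirmed" if ok else "rejected"
    else:
        if grid is None or events is None:
            raise ValueError("silence fallback needs grid and events")
        nbrs = grid.neighbor_map(neighbor_params)
        sel = events["electrode_id"].isin(nbrs.get(candidate.electrode, set()))
        t = events.loc[sel, "time_ms"].to_numpy()
        quiet = not np.any((t < candidate.time) & (t >= candidate.time - silent_window))
        status = "silence_confirmed" if quiet else "rejected"
    return FocalSource(candidate.electrode, candidate.time, status)


def _mean_peak_amplitude(trace: np.ndarray, fs_hz: float) -> float:
    """Mean absolute peak over the trace's deflections.

    Deflections are located as prominent extrema of |trace|, separated by
    at least 50 ms; their mean absolute amplitude is the per-electrode
    normalization used by the upstroke criterion.
    """
    from scipy.signal import find_peaks

    dist = max(1, int(0.05 * fs_hz))
    mag = np.abs(trace)
    peaks, _ = find_peaks(mag, distance=dist, height=0.2 * mag.max() if mag.max() > 0 else None)
    if len(peaks) == 0:
        return float(mag.max())
    return float(mag[peaks].mean())


def verify_all(
    candidates: list[FocalSource],
    electrograms: ElectrogramSet | None,
    grid: ElectrodeGrid | None = None,
    events: pd.DataFrame | None = None,
    **kwargs,
) -> list[FocalSource]:
    """Verify every candidate; see :func:`verify`."""
    return [
        verify(c, electrograms, grid=grid, events=events, **kwargs)
        for c in candidates
    ]


def heatmap(sources: list[FocalSource], grid: ElectrodeGrid) -> pd.DataFrame:
    """Per-electrode focal-source counts over the usable grid.

    The count column sums to the number of sources passed in; electrodes
    with no source are present with count 0.
    """
    counts = pd.Series(0, index=pd.Index(grid.usable_ids, name="electrode_id"))
    for s in sources:
        if s.electrode in counts.index:
            counts[s.electrode] += 1
        else:
            raise ValueError(f"source at unknown/unusable electrode {s.electrode}")
    out = grid.electrodes.loc[counts.index, ["x", "y", "z"]].copy()
    out.insert(0, "electrode_id", counts.index)
    out["count"] = counts.to_numpy()
    return out.reset_index(drop=True)


@dataclass
class BinomialNull:
    """Uniform-placement null for n sources over e electrodes."""

    n: int
    e: int
    p: float  # 1/e
    pmf: np.ndarray  # p_x for x = 0..n

    def expected_electrodes(self, x: int) -> float:
        return self.e * self.pmf[x]


def binomial_null(n: int, e: int) -> BinomialNull:
    """Binomial occupancy null: p_x = C(n,x) (1/e)^x (1-1/e)^(n-x)."""
    if e < 1:
        raise ValueError("need at least one electrode")
    if n < 0:
        raise ValueError("n must be non-negative")
    p = 1.0 / e
    pmf = stats.binom.pmf(np.arange(n + 1), n, p)
    return BinomialNull(n=n, e=e, p=p, pmf=pmf)


def randomness_table(
    heat: pd.DataFrame,
    null: BinomialNull,
    flag_threshold: float = 0.05,
) -> pd.DataFrame:
    """Observed vs expected electrode counts per per-electrode source count.

    One row per source count x from 0 to the maximum observed; rows where
    sources were observed but the null expects fewer than
    ``flag_threshold`` electrodes are flagged as hotspots ("almost
    certainly impossible" under uniform placement).
    """
    counts = heat["count"].to_numpy(int)
    if counts.sum() != null.n or len(counts) != null.e:
        raise ValueError(
            f"heatmap totals ({counts.sum()} sources, {len(counts)} electrodes) "
            f"do not match the null (n={null.n}, e={null.e})"
        )
    x_max = int(counts.max(initial=0))
    rows = []
    for x in range(x_max + 1):
        obs = int((counts == x).sum())
        exp = null.expected_electrodes(x)
        rows.append(
            {
                "x": x,
                "observed_electrodes": obs,
                "expected_electrodes": exp,
                "observed_pct": 100.0 * obs / null.e,
                "expected_pct": 100.0 * null.pmf[x],
                "flag": bool(obs > 0 and exp < flag_threshold),
            }
        )
    return pd.DataFrame(rows)
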