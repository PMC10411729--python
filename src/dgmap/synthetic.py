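"""Synthetic activation patterns and unipolar electrograms with ground truth.

Four kinematic activation mechanisms are generated on an
:class:`~dgmap.geometry.ElectrodeGrid`:

``focal``
    Radial spread from a point origin at constant speed, one wave per beat.
``planar``
    A plane wave crossing the grid in a fixed direction.
``rotor``
    A scroll wave rotating about an arbitrary (typically intramural,
    horizontal) core axis; local activation time is proportional to the
    azimuth of each electrode around the axis.
``macro_reentry``
    As ``rotor`` but rotating about a ventricular cavity axis (LV, RV, or
    the combined axis), with events restricted to the wall electrodes that
    encircle that axis.

These are phase maps, not reaction--diffusion simulations: wavefront
curvature, meander and restitution are deliberately absent, which makes
every generated pattern exactly recoverable and gives the detection
pipeline an unambiguous ground truth.  Electrograms are rendered as
derivative-of-Gaussian biphasic wavelets whose steepest negative slope
falls exactly at the activation time, so the annotator's marking rule is
exactly invertible on noise-free traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay

from .geometry import CavityAxis, ElectrodeGrid

__all__ = [
    "GroundTruth",
    "ElectrogramSet",
    "gen_focal",
    "gen_planar",
    "gen_rotor",
    "gen_macro_reentry",
    "gen_electrograms",
    "perturb",
]

EVENT_COLUMNS = ["electrode_id", "time_ms"]

#: Gaussian width of the rendered wavelet (ms); the biphasic deflection
#: spans roughly +-2 sigma, i.e. about 20 ms.
WAVELET_SIGMA_MS = 5.0


@dataclass
class GroundTruth:
    """What a generator actually produced, for recovery checks."""

    mechanism: str  # focal | planar | rotor | macro_reentry
    conduction_velocity: float | None = None  # mm/ms, where defined
    cycle_length: float | None = None  # ms, periodic mechanisms
    beat_times: list[float] = field(default_factory=list)
    origin: np.ndarray | None = None  # focal origin, mm
    core_axis: CavityAxis | None = None  # rotor / macro-reentry axis
    cavity: str | None = None  # macro-reentry: LV | RV | both
    direction: np.ndarray | None = None  # planar front normal
    qs_electrodes: frozenset[int] = frozenset()  # no-upstroke morphology


@dataclass
class ElectrogramSet:
    """Equal-length unipolar traces, one per electrode."""

    sampling_rate: float  # Hz
    traces: pd.DataFrame  # columns = electrode ids, rows = samples
    morphology: dict[int, str]  # electrode -> "QS" | "RS"

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.traces)

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * 1000.0 / self.sampling_rate

    def trace(self, electrode_id: int) -> np.ndarray:
        return self.traces[electrode_id].to_numpy(float)


def _events_frame(ids, times) -> pd.DataFrame:
    df = pd.DataFrame({"electrode_id": ids, "time_ms": times})
    return df.sort_values(["time_ms", "electrode_id"], ignore_index=True)


def _check_in_hull(grid: ElectrodeGrid, point: np.ndarray, what: str) -> None:
    pts = grid.positions(grid.usable_ids)
    hull = Delaunay(pts)
    if hull.find_simplex(np.asarray(point, float)) < 0:
        raise ValueError(f"{what} {point!r} lies outside the electrode hull")


def gen_focal(
    grid: ElectrodeGrid,
    origin,
    cv: float = 0.8,
    beat_times=(0.0,),
) -> tuple[pd.DataFrame, GroundTruth]:
    """Radial activation from a point source, one wave per beat.

    LAT(e) = t0 + dist(e, origin) / cv for each beat time t0.
    """
    if not 0.1 < cv <= 2.0:
        raise ValueError(f"cv {cv} outside plausible range (0.1, 2.0] mm/ms")
    origin = np.asarray(origin, float)
    _check_in_hull(grid, origin, "focal origin")

    ids = grid.usable_ids
    dist = np.linalg.norm(grid.positions(ids) - origin, axis=1)
    all_ids, all_t = [], []
    for t0 in beat_times:
        all_ids.append(ids)
        all_t.append(t0 + dist / cv)
    events = _events_frame(np.concatenate(all_ids), np.concatenate(all_t))

    nearest = int(ids[np.argmin(dist)])
    truth = GroundTruth(
        mechanism="focal",
        conduction_velocity=cv,
        beat_times=list(beat_times),
        origin=origin,
        qs_electrodes=frozenset({nearest}),
    )
    return events, truth


def gen_planar(
    grid: ElectrodeGrid,
    direction,
    cv: float = 0.8,
    t0: float = 0.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Plane wave: LAT(e) = t0 + <position(e), direction> / cv."""
    direction = np.asarray(direction, float)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("direction must be a non-zero vector")
    direction = direction / norm
    ids = grid.usable_ids
    proj = grid.positions(ids) @ direction
    lats = t0 + (proj - proj.min()) / cv
    events = _events_frame(ids, lats)
    truth = GroundTruth(
        mechanism="planar",
        conduction_velocity=cv,
        beat_times=[t0],
        direction=direction,
    )
    return events, truth


def _axis_frame(axis: CavityAxis) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal (u, v, w) with w along the axis direction."""
    w = np.asarray(axis.direction, float)
    w = w / np.linalg.norm(w)
    seed = np.array([1.0, 0.0, 0.0])
    if abs(seed @ w) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = seed - (seed @ w) * w
    u /= np.linalg.norm(u)
    v = np.cross(w, u)
    return u, v, w


def _azimuth_about(axis: CavityAxis, points: np.ndarray) -> np.ndarray:
    """Azimuth of each point around the axis, in [0, 2*pi)."""
    u, v, _ = _axis_frame(axis)
    rel = points - np.asarray(axis.point, float)
    theta = np.arctan2(rel @ v, rel @ u)
    return np.mod(theta, 2 * np.pi)


def _rotational_events(
    ids, theta, cycle_length: float, n_rotations: int, t0: float
) -> pd.DataFrame:
    all_ids, all_t = [], []
    for k in range(n_rotations):
        all_ids.append(ids)
        all_t.append(t0 + cycle_length * (theta / (2 * np.pi) + k))
    return _events_frame(np.concatenate(all_ids), np.concatenate(all_t))


def gen_rotor(
    grid: ElectrodeGrid,
    core_axis: CavityAxis,
    cycle_length: float = 200.0,
    n_rotations: int = 5,
    t0: float = 0.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Scroll wave about an arbitrary core axis.

    LAT(e, k) = t0 + cycle_length * (theta(e)/2pi + k), theta being the
    azimuth of electrode e around the core axis.  Successive rotations
    share the phase map (no meander).
    """
    if cycle_length <= 0:
        raise ValueError("cycle_length must be positive")
    _check_in_hull(grid, np.asarray(core_axis.point, float), "rotor core")
    ids = grid.usable_ids
    theta = _azimuth_about(core_axis, grid.positions(ids))
    events = _rotational_events(ids, theta, cycle_length, n_rotations, t0)
    truth = GroundTruth(
        mechanism="rotor",
        cycle_length=cycle_length,
        beat_times=[t0 + k * cycle_length for k in range(n_rotations)],
        core_axis=core_axis,
    )
    return events, truth


def gen_macro_reentry(
    grid: ElectrodeGrid,
    cavity: str = "LV",
    cycle_length: float = 200.0,
    n_rotations: int = 5,
    t0: float = 0.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Macro-reentrant rotation about a cavity axis.

    Events are restricted to the wall electrodes that encircle the chosen
    axis (the grid's per-cavity encircling sets), so the rotating wave
    travels along the wall rather than through the cavity.
    """
    if cavity not in grid.cavity_axes:
        raise ValueError(f"unknown cavity {cavity!r}")
    if cycle_length <= 0:
        raise ValueError("cycle_length must be positive")
    axis = grid.cavity_axes[cavity]
    wall = grid.encircling_electrodes(cavity)
    ids = np.asarray(sorted(wall & set(grid.usable_ids)))
    if len(ids) == 0:
        raise ValueError(f"no usable wall electrodes encircle cavity {cavity!r}")
    theta = _azimuth_about(axis, grid.positions(ids))
    events = _rotational_events(ids, theta, cycle_length, n_rotations, t0)
    truth = GroundTruth(
        mechanism="macro_reentry",
        cycle_length=cycle_length,
        beat_times=[t0 + k * cycle_length for k in range(n_rotations)],
        core_axis=axis,
        cavity=cavity,
    )
    return events, truth


def _wavelet(u_ms: np.ndarray, sigma: float = WAVELET_SIGMA_MS) -> np.ndarray:
    """Derivative-of-Gaussian biphasic deflection, unit peak amplitude.

    Positive lobe before u=0, negative after; the steepest negative slope
    is exactly at u=0.
    """
    raw = -(u_ms / sigma) * np.exp(-(u_ms**2) / (2 * sigma**2))
    return raw * np.e**0.5  # peak |raw| is exp(-1/2) at u = +-sigma


def gen_electrograms(
    events: pd.DataFrame,
    grid: ElectrodeGrid,
    truth: GroundTruth,
    sampling_rate: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    pad_ms: float = 100.0,
) -> ElectrogramSet:
    """Render events as unipolar traces.

    Electrodes in ``truth.qs_electrodes`` (focal origins) get a QS
    morphology: the positive lobe is clipped, leaving a monophasic
    negative deflection with no upstroke.  All other electrodes get the
    full biphasic RS shape.  Gaussian noise is added with standard
    deviation ``noise_sd`` relative to the unit deflection peak.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    rng = np.random.default_rng(seed)
    t_end = (events["time_ms"].max() + pad_ms) if len(events) else pad_ms
    n = int(np.ceil(t_end * sampling_rate / 1000.0)) + 1
    times = np.arange(n) * 1000.0 / sampling_rate

    morphology: dict[int, str] = {}
    cols: dict[int, np.ndarray] = {}
    by_electrode = events.groupby("electrode_id")["time_ms"] if len(events) else {}
    for eid in grid.usable_ids:
        eid = int(eid)
        qs = eid in truth.qs_electrodes
        morphology[eid] = "QS" if qs else "RS"
        tr = np.zeros(n)
        if len(events) and eid in events["electrode_id"].values:
            for lat in by_electrode.get_group(eid).to_numpy():
                w = _wavelet(times - lat)
                if qs:
                    w = np.minimum(w, 0.0)
                tr += w
        if noise_sd > 0:
            tr = tr + rng.normal(0.0, noise_sd, size=n)
        cols[eid] = tr
    return ElectrogramSet(sampling_rate, pd.DataFrame(cols), morphology)


def perturb(
    events: pd.DataFrame,
    jitter_sd: float = 0.0,
    dropout_frac: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Jitter LATs and drop whole electrodes, deterministically per seed."""
    if not 0.0 <= dropout_frac <= 1.0:
        raise ValueError("dropout_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out = events.copy()
    electrodes = np.asarray(sorted(out["electrode_id"].unique()))
    n_drop = int(round(dropout_frac * len(electrodes)))
    if n_drop:
        dropped = set(rng.choice(electrodes, size=n_drop, replace=False).tolist())
        out = out[~out["electrode_id"].isin(dropped)]
    if jitter_sd > 0:
        out = out.copy()
        out["time_ms"] = out["time_ms"] + rng.normal(0.0, jitter_sd, size=len(out))
    return out.sort_values(["time_ms", "electrode_id"], ignore_index=True)
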