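"""Multi-needle electrode lattices for intramural ventricular mapping.

The recording hardware this package models is a stack of parallel tissue
layers, each instrumented with plunge needles carrying four terminals at
fixed spacing along the needle shaft.  Two canonical needle layouts are
provided, both stylized cross-sections of a two-cavity ventricular slice:
six needles inserted radially through the left-ventricular (LV) wall and
four through the right-ventricular (RV) free wall.  Absolute electrode
coordinates in experiments of this kind are typically estimated visually,
so the layouts here are idealized but keep the length scales of the real
preparation: 4 mm between terminals on one needle, 12 mm between layers,
10--15 mm between adjacent needles.

Cavity axes (one per cavity plus a combined axis between them) are vertical
lines perpendicular to the layer planes; they anchor the winding-number
classification of macro-reentrant loops.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "CavityAxis",
    "ElectrodeGrid",
    "NeighborParams",
    "build_grid",
    "neighbors",
    "load_grid",
    "save_grid",
]

#: Polar needle layouts, per config: (cavity, azimuth deg).  Each needle is
#: radial from its cavity centre; its four terminals sit at the radii below,
#: terminal 0 innermost (endocardial), terminal 3 epicardial.  Azimuths are
#: chosen so that closed electrode rings exist around the LV cavity, around
#: the RV cavity (via the two septal LV needles at +-33 deg / +-35 deg), and
#: around both cavities jointly, all with inter-electrode hops inside the
#: default 15 mm neighbor radius.
_LV_CENTER = np.array([0.0, 0.0])
_RV_CENTER = np.array([22.0, 0.0])

_CONFIGS: dict[int, list[tuple[str, float]]] = {
    # config 1: two septal LV needles flanking the septum at +-33 deg,
    # RV needles at +-37/+-110 deg over free wall and junctions
    1: [("LV", a) for a in (33, 90, 150, 210, 270, 327)]
    + [("RV", a) for a in (-110, -37, 37, 110)],
    # config 2: slightly rotated variant of the same scheme
    2: [("LV", a) for a in (35, 95, 155, 205, 265, 325)]
    + [("RV", a) for a in (-112, -40, 40, 112)],
}

_LV_RADII = (13.0, 17.0, 21.0, 25.0)
_RV_RADII = (9.0, 13.0, 17.0, 21.0)

#: LV needles with azimuth in (-45, 45) deg face the septum; they complete
#: the ring around the RV cavity, and their innermost terminal is the only
#: electrode lying between the two cavity axes.
_SEPTAL_HALF_ANGLE = 45.0


@dataclass(frozen=True)
class CavityAxis:
    """A vertical line (point + direction) through a ventricular cavity."""

    point: np.ndarray  # (3,) mm, on the axis
    direction: np.ndarray  # (3,) unit vector, perpendicular to layers

    def to_dict(self) -> dict:
        return {
            "axis_point": [float(v) for v in self.point],
            "axis_dir": [float(v) for v in self.direction],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CavityAxis":
        return cls(np.asarray(d["axis_point"], float), np.asarray(d["axis_dir"], float))


@dataclass(frozen=True)
class NeighborParams:
    """Neighborhood rule: k nearest usable electrodes within a hard radius.

    The relation is symmetrized by union so that conduction edges can be
    drawn in either direction between any neighboring pair.
    """

    max_distance: float = 15.0  # mm
    max_neighbors: int = 14

    def __post_init__(self) -> None:
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")
        if self.max_neighbors < 1:
            raise ValueError("max_neighbors must be >= 1")


@dataclass
class ElectrodeGrid:
    """3D electrode lattice with needle/layer/terminal indexing.

    Parameters
    ----------
    electrodes
        One row per electrode: columns ``id, needle, layer, terminal,
        x, y, z, usable``.
    cavity_axes
        Keys ``"LV"``, ``"RV"`` and ``"both"`` mapping to :class:`CavityAxis`.
    """

    electrodes: pd.DataFrame
    cavity_axes: dict[str, CavityAxis]
    config_id: int = 1
    layer_spacing: float = 12.0
    terminal_spacing: float = 4.0
    _tree_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        ids = self.electrodes["id"]
        if ids.duplicated().any():
            raise ValueError("electrode ids must be unique")
        self.electrodes = self.electrodes.set_index("id", drop=False)

    # -- basic queries ---------------------------------------------------
    @property
    def ids(self) -> np.ndarray:
        return self.electrodes["id"].to_numpy()

    @property
    def usable_ids(self) -> np.ndarray:
        e = self.electrodes
        return e.loc[e["usable"], "id"].to_numpy()

    @property
    def n_usable(self) -> int:
        return int(self.electrodes["usable"].sum())

    def position(self, electrode_id: int) -> np.ndarray:
        pos_map = self._tree_cache.get("pos_map")
        if pos_map is None:
            xyz = self.electrodes[["x", "y", "z"]].to_numpy(float)
            pos_map = {
                int(i): xyz[k] for k, i in enumerate(self.electrodes["id"])
            }
            self._tree_cache["pos_map"] = pos_map
        return pos_map[electrode_id]

    def positions(self, electrode_ids=None) -> np.ndarray:
        e = self.electrodes
        if electrode_ids is not None:
            e = e.loc[list(electrode_ids)]
        return e[["x", "y", "z"]].to_numpy(float)

    def is_usable(self, electrode_id: int) -> bool:
        return bool(self.electrodes.loc[electrode_id, "usable"])

    def encircling_electrodes(self, cavity: str) -> set[int]:
        """Electrode ids on the wall encircling the given cavity axis.

        ``"LV"``: all LV-wall needles.  ``"RV"``: RV-wall needles plus the
        septal LV needles, which close the ring on the septal side.
        ``"both"``: every electrode except the innermost septal terminals,
        which lie between the two cavity axes and would let a loop cut
        through the septum instead of encircling both cavities.
        """
        e = self.electrodes
        if cavity == "LV":
            sel = e["cavity_wall"] == "LV"
        elif cavity == "RV":
            sel = (e["cavity_wall"] == "RV") | e["septal"]
        elif cavity == "both":
            sel = ~(e["septal"] & (e["terminal"] == 0))
        else:
            raise ValueError(f"unknown cavity {cavity!r}")
        return set(int(i) for i in e.loc[sel, "id"])

    def with_mask(self, usable_ids) -> "ElectrodeGrid":
        """Return a copy restricted to the given usable electrode ids."""
        e = self.electrodes.copy().reset_index(drop=True)
        e["usable"] = e["id"].isin(set(usable_ids))
        return ElectrodeGrid(
            e, dict(self.cavity_axes), self.config_id,
            self.layer_spacing, self.terminal_spacing,
        )

    # -- neighbor relation ----------------------------------------------
    def _usable_tree(self) -> tuple[cKDTree, np.ndarray]:
        key = ("tree", tuple(self.usable_ids))
        if key not in self._tree_cache:
            ids = np.asarray(self.usable_ids)
            self._tree_cache[key] = (cKDTree(self.positions(ids)), ids)
        return self._tree_cache[key]

    def neighbor_map(self, params: NeighborParams | None = None) -> dict[int, set[int]]:
        """Symmetric neighbor sets for every usable electrode (cached)."""
        params = params or NeighborParams()
        cache_key = ("nbrs", tuple(self.usable_ids), params)
        if cache_key in self._tree_cache:
            return self._tree_cache[cache_key]
        tree, ids = self._usable_tree()
        pos = self.positions(ids)
        # query k+1 because the query point is its own nearest neighbor
        k = min(params.max_neighbors + 1, len(ids))
        dist, idx = tree.query(pos, k=k, distance_upper_bound=params.max_distance)
        nbrs: dict[int, set[int]] = {int(i): set() for i in ids}
        dist = np.atleast_2d(dist)
        idx = np.atleast_2d(idx)
        for row, eid in enumerate(ids):
            for d, j in zip(dist[row], idx[row]):
                if not np.isfinite(d) or j == row or j >= len(ids):
                    continue
                nbrs[int(eid)].add(int(ids[j]))
        # symmetrize by union
        for a in list(nbrs):
            for b in nbrs[a]:
                nbrs[b].add(a)
        self._tree_cache[cache_key] = nbrs
        return nbrs


def neighbors(grid: ElectrodeGrid, electrode: int, params: NeighborParams | None = None) -> set[int]:
    """Usable neighbors of one electrode under the k-nearest-in-radius rule."""
    if electrode not in grid.electrodes.index:
        raise KeyError(f"unknown electrode id {electrode}")
    if not grid.is_usable(electrode):
        raise ValueError(f"electrode {electrode} is masked out")
    return grid.neighbor_map(params)[electrode]


def _needle_positions(cavity: str, azimuth_deg: float) -> np.ndarray:
    center = _LV_CENTER if cavity == "LV" else _RV_CENTER
    radii = _LV_RADII if cavity == "LV" else _RV_RADII
    th = np.deg2rad(azimuth_deg)
    u = np.array([np.cos(th), np.sin(th)])
    return center[None, :] + np.outer(radii, u)


def build_grid(
    config_id: int = 1,
    layers: int = 6,
    layer_spacing: float = 12.0,
    terminal_spacing: float = 4.0,
) -> ElectrodeGrid:
    """Build a canonical needle grid.

    Parameters
    ----------
    config_id
        1 or 2, selecting one of the two canonical per-layer needle layouts.
    layers
        Number of stacked layers (layer 0 basal, stacked along +z).
    layer_spacing, terminal_spacing
        Vertical spacing between layers and radial spacing between the four
        terminals on one needle, both in mm.
    """
    if config_id not in _CONFIGS:
        raise ValueError(f"unknown config_id {config_id!r}; expected 1 or 2")
    if layers < 1:
        raise ValueError("layers must be >= 1")

    scale = terminal_spacing / 4.0  # radii tables assume 4 mm spacing
    rows = []
    eid = 0
    for layer in range(layers):
        z = layer * layer_spacing
        for needle, (cavity, az) in enumerate(_CONFIGS[config_id]):
            xy = _needle_positions(cavity, az)
            center = _LV_CENTER if cavity == "LV" else _RV_CENTER
            xy = center[None, :] + (xy - center[None, :]) * scale
            septal = cavity == "LV" and abs(((az + 180) % 360) - 180) < _SEPTAL_HALF_ANGLE
            for terminal in range(4):
                rows.append(
                    {
                        "id": eid,
                        "needle": needle,
                        "layer": layer,
                        "terminal": terminal,
                        "cavity_wall": cavity,
                        "septal": septal,
                        "x": xy[terminal, 0],
                        "y": xy[terminal, 1],
                        "z": float(z),
                        "usable": True,
                    }
                )
                eid += 1

    z_dir = np.array([0.0, 0.0, 1.0])
    mid = np.append((_LV_CENTER + _RV_CENTER) / 2.0, 0.0)
    axes = {
        "LV": CavityAxis(np.append(_LV_CENTER, 0.0), z_dir),
        "RV": CavityAxis(np.append(_RV_CENTER, 0.0), z_dir),
        "both": CavityAxis(mid, z_dir),
    }
    return ElectrodeGrid(
        pd.DataFrame(rows), axes, config_id, layer_spacing, terminal_spacing
    )


# -- serialization -------------------------------------------------------

def save_grid(grid: ElectrodeGrid, path) -> None:
    """Write a grid to the JSON geometry format."""
    doc = {
        "config_id": grid.config_id,
        "layer_spacing_mm": grid.layer_spacing,
        "terminal_spacing_mm": grid.terminal_spacing,
        "electrodes": [
            {
                "id": int(r.id),
                "needle": int(r.needle),
                "layer": int(r.layer),
                "terminal": int(r.terminal),
                "cavity_wall": str(r.cavity_wall),
                "septal": bool(r.septal),
                "x": float(r.x),
                "y": float(r.y),
                "z": float(r.z),
                "usable": bool(r.usable),
            }
            for r in grid.electrodes.itertuples()
        ],
        "cavities": {name: ax.to_dict() for name, ax in grid.cavity_axes.items()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def load_grid(path) -> ElectrodeGrid:
    with open(path) as fh:
        doc = json.load(fh)
    df = pd.DataFrame(doc["electrodes"])
    axes = {name: CavityAxis.from_dict(d) for name, d in doc["cavities"].items()}
    return ElectrodeGrid(
        df,
        axes,
        config_id=doc["config_id"],
        layer_spacing=doc["layer_spacing_mm"],
        terminal_spacing=doc["terminal_spacing_mm"],
    )
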