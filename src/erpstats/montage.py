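"""Electrode layout, scalp regions, and the spatial adjacency used for clustering.

The analyses in this package are driven by electrode *identities* (integer
labels 1..61) grouped into six scalp regions.  True cap coordinates for the
61-channel equidistant montage are not published, so a deterministic
quasi-equidistant stand-in layout is generated on the upper hemisphere and
IDs are assigned so that each region's electrodes sit over the matching part
of the scalp (anterior = +y, left = -x).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = [
    "ElectrodeLayout",
    "RegionMap",
    "AdjacencyGraph",
    "RegionOverlapWarning",
    "build_default_layout",
    "build_region_map",
    "build_adjacency",
]


class RegionOverlapWarning(UserWarning):
    """Emitted when region definitions assign an electrode to two regions."""


# Region membership, frozen.  Electrodes 17 and 42 appear in both the
# left-anterior and left-posterior lists; this is preserved verbatim (see
# build_region_map, which warns about it).
_LEFT_ANTERIOR = frozenset({5, 6, 17, 18, 19, 20, 21, 42, 43, 44, 45})
_ANTERIOR_MIDLINE = frozenset({1, 7, 33, 34})
_RIGHT_ANTERIOR = frozenset({2, 3, 8, 9, 10, 11, 35, 36, 37})
_LEFT_POSTERIOR = frozenset({15, 16, 17, 28, 41, 42, 56, 55})
_POSTERIOR_MIDLINE = frozenset({4, 40, 27, 54})
_RIGHT_POSTERIOR = frozenset({12, 13, 14, 26, 38, 39, 52, 53})


@dataclass(frozen=True)
class ElectrodeLayout:
    """Electrode identities and their positions on a unit sphere.

    Parameters
    ----------
    ids
        Integer electrode labels; unique.
    positions
        ``(n, 3)`` array of Cartesian coordinates.  All rows must share a
        common radius (relative tolerance 1e-9); they are stored normalized
        to the unit sphere.
    """

    ids: tuple[int, ...]
    positions: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(int(i) for i in self.ids)
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if len(ids) != pos.shape[0]:
            raise ValueError("ids and positions length mismatch")
        if len(set(ids)) != len(ids):
            raise ValueError("electrode ids must be unique")
        radii = np.linalg.norm(pos, axis=1)
        if np.any(radii == 0):
            raise ValueError("electrode at the origin")
        if np.ptp(radii) > 1e-9 * radii.mean():
            raise ValueError("positions do not lie on a common sphere")
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "positions", pos / radii[:, None])

    @property
    def n_electrodes(self) -> int:
        return len(self.ids)

    def index_of(self, electrode_id: int) -> int:
        try:
            return self.ids.index(int(electrode_id))
        except ValueError:
            raise KeyError(f"electrode id {electrode_id} not in layout") from None

    def indices_of(self, electrode_ids) -> np.ndarray:
        return np.array([self.index_of(i) for i in electrode_ids], dtype=int)

    def position_of(self, electrode_id: int) -> np.ndarray:
        return self.positions[self.index_of(electrode_id)]

    def subset(self, electrode_ids) -> "ElectrodeLayout":
        """Layout restricted to the given ids (order preserved as given)."""
        idx = self.indices_of(electrode_ids)
        return ElectrodeLayout(tuple(int(i) for i in electrode_ids), self.positions[idx])

    def chord_distances(self) -> np.ndarray:
        """Pairwise Euclidean (chord) distance matrix."""
        return cdist(self.positions, self.positions)

    def nearest_neighbor_distances(self) -> np.ndarray:
        d = self.chord_distances()
        np.fill_diagonal(d, np.inf)
        return d.min(axis=1)

    def median_nn_distance(self) -> float:
        return float(np.median(self.nearest_neighbor_distances()))

    # -- text round-trip ----------------------------------------------------
    def to_tsv(self, path, region_map: "RegionMap | None" = None) -> None:
        """Write ``id\tx\ty\tz\tregion`` rows.  Overlapping regions joined by '+'."""
        with open(path, "w") as fh:
            fh.write("id\tx\ty\tz\tregion\n")
            for i, eid in enumerate(self.ids):
                x, y, z = self.positions[i]
                if region_map is not None:
                    names = region_map.regions_of(eid)
                    region = "+".join(names) if names else "other"
                else:
                    region = "other"
                fh.write(f"{eid}\t{x:.12g}\t{y:.12g}\t{z:.12g}\t{region}\n")

    @classmethod
    def from_tsv(cls, path) -> "ElectrodeLayout":
        ids, pos = [], []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:4] != ["id", "x", "y", "z"]:
                raise ValueError(f"unexpected layout header: {header}")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if not parts or parts == [""]:
                    continue
                ids.append(int(parts[0]))
                pos.append([float(parts[1]), float(parts[2]), float(parts[3])])
        return cls(tuple(ids), np.array(pos))


@dataclass(frozen=True)
class RegionMap:
    """The six scalp regions plus derived anterior/posterior unions."""

    left_anterior: frozenset[int] = _LEFT_ANTERIOR
    anterior_midline: frozenset[int] = _ANTERIOR_MIDLINE
    right_anterior: frozenset[int] = _RIGHT_ANTERIOR
    left_posterior: frozenset[int] = _LEFT_POSTERIOR
    posterior_midline: frozenset[int] = _POSTERIOR_MIDLINE
    right_posterior: frozenset[int] = _RIGHT_POSTERIOR

    _NAMES = (
        "left_anterior",
        "anterior_midline",
        "right_anterior",
        "left_posterior",
        "posterior_midline",
        "right_posterior",
    )

    @property
    def anterior(self) -> frozenset[int]:
        """Union of the three anterior regions (24 electrodes)."""
        return self.left_anterior | self.anterior_midline | self.right_anterior

    @property
    def posterior(self) -> frozenset[int]:
        """Union of the three posterior regions (20 electrodes)."""
        return self.left_posterior | self.posterior_midline | self.right_posterior

    def region(self, name: str) -> frozenset[int]:
        if name in ("anterior", "posterior"):
            return getattr(self, name)
        if name not in self._NAMES:
            raise KeyError(f"unknown region {name!r}")
        return getattr(self, name)

    def regions_of(self, electrode_id: int) -> list[str]:
        return [n for n in self._NAMES if electrode_id in getattr(self, n)]

    def items(self):
        return [(n, getattr(self, n)) for n in self._NAMES]


def build_region_map() -> RegionMap:
    """Return the six-region electrode grouping.

    Electrodes 17 and 42 are listed under both left-anterior and
    left-posterior in the source region definition; they are kept in both
    sets as printed and a :class:`RegionOverlapWarning` is emitted.
    """
    rm = RegionMap()
    overlap = sorted(rm.anterior & rm.posterior)
    if overlap:
        warnings.warn(
            f"electrodes {overlap} belong to both an anterior and a posterior "
            "region as printed in the region definition; kept in both",
            RegionOverlapWarning,
            stacklevel=2,
        )
    return rm


def _ring_points(n_rings: int) -> np.ndarray:
    """Apex plus n_rings rings of 4*i points on the upper hemisphere.

    Ring ``i`` sits at colatitude ``i * 90deg / n_rings``; azimuth 0 points
    to the front (+y), increasing clockwise when seen from above.
    """
    pts = [np.array([0.0, 0.0, 1.0])]
    for i in range(1, n_rings + 1):
        theta = i * (np.pi / 2) / n_rings
        m = 4 * i
        az = 2 * np.pi * np.arange(m) / m
        x = np.sin(theta) * np.sin(az)
        y = np.sin(theta) * np.cos(az)
        z = np.full(m, np.cos(theta))
        pts.append(np.column_stack([x, y, z]))
    return np.vstack([p.reshape(-1, 3) for p in pts])


# Target directions used to place each region's ids over the matching scalp
# area; ids outside every region go to the central/temporal band.
_REGION_TARGETS = {
    "left_anterior": (-0.60, 0.65, 0.45),
    "anterior_midline": (0.0, 0.70, 0.70),
    "right_anterior": (0.60, 0.65, 0.45),
    "left_posterior": (-0.60, -0.65, 0.45),
    "posterior_midline": (0.0, -0.70, 0.70),
    "right_posterior": (0.60, -0.65, 0.45),
}
_OVERLAP_TARGET = (-0.85, 0.0, 0.50)  # ids printed in both left regions
_OTHER_TARGET = (0.0, 0.0, 1.0)


def build_default_layout(n_rings: int = 5) -> ElectrodeLayout:
    """Deterministic 61-electrode stand-in layout on the unit upper hemisphere.

    ``n_rings`` controls the geodesic grid (apex + rings of 4i points,
    ``1 + 2*n_rings*(n_rings+1)`` candidates); it must generate at least 61
    points, of which exactly 61 are retained.  Ids are assigned to positions
    by solving a linear assignment problem against per-region target
    directions, so that e.g. electrode 1 lands on an anterior-midline site.
    """
    total = 1 + 2 * n_rings * (n_rings + 1)
    if total < 61:
        raise ValueError(f"n_rings={n_rings} yields only {total} < 61 candidate positions")
    pts = _ring_points(n_rings)[:61]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RegionOverlapWarning)
        rm = build_region_map()
    overlap = rm.anterior & rm.posterior
    targets = np.empty((61, 3))
    for row, eid in enumerate(range(1, 62)):
        if eid in overlap:
            t = _OVERLAP_TARGET
        else:
            names = rm.regions_of(eid)
            t = _REGION_TARGETS[names[0]] if names else _OTHER_TARGET
        targets[row] = t
    # pin electrode 1 to the front-most midline site so the sigma-source
    # default ("an anterior electrode") is unambiguous
    targets[0] = (0.0, 0.85, 0.53)
    targets /= np.linalg.norm(targets, axis=1, keepdims=True)

    cost = -targets @ pts.T  # maximize alignment
    _, col = linear_sum_assignment(cost)
    return ElectrodeLayout(tuple(range(1, 62)), pts[col])


@dataclass(frozen=True)
class AdjacencyGraph:
    """Symmetric, irreflexive spatial neighbor relation over electrode ids."""

    ids: tuple[int, ...]
    matrix: np.ndarray  # boolean (n, n)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=bool)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("adjacency matrix shape mismatch")
        if not np.array_equal(m, m.T):
            raise ValueError("adjacency must be symmetric")
        if m.diagonal().any():
            raise ValueError("adjacency must have no self-edges")
        object.__setattr__(self, "ids", tuple(int(i) for i in self.ids))
        object.__setattr__(self, "matrix", m)

    def neighbors(self, electrode_id: int) -> frozenset[int]:
        i = self.ids.index(int(electrode_id))
        return frozenset(self.ids[j] for j in np.flatnonzero(self.matrix[i]))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.ids)
        rows, cols = np.nonzero(np.triu(self.matrix, 1))
        g.add_edges_from((self.ids[r], self.ids[c]) for r, c in zip(rows, cols))
        return g

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_networkx())

    @property
    def mean_degree(self) -> float:
        return float(self.matrix.sum(axis=1).mean())

    def reorder(self, electrode_ids) -> "AdjacencyGraph":
        idx = np.array([self.ids.index(int(i)) for i in electrode_ids])
        return AdjacencyGraph(tuple(int(i) for i in electrode_ids), self.matrix[np.ix_(idx, idx)])


def build_adjacency(layout: ElectrodeLayout, scale: float = 1.5) -> AdjacencyGraph:
    """Neighbor graph: edge iff chord distance < scale * median NN distance.

    ``scale`` must exceed 1 (otherwise no electrode would reliably have a
    neighbor).  Raises on degenerate layouts where all positions coincide.
    """
    if scale <= 1:
        raise ValueError("scale must be > 1")
    d = layout.chord_distances()
    med = layout.median_nn_distance()
    if not np.isfinite(med) or med == 0:
        raise ValueError("degenerate layout: zero median nearest-neighbor distance")
    m = d < scale * med
    np.fill_diagonal(m, False)
    return AdjacencyGraph(layout.ids, m)
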