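"""Parcel geometries: coordinates, hemispheres and pairwise distances.

Two flavours are used throughout: unit-sphere geometries standing in for
surface-projected cortical parcels (great-circle distances, two hemispheres
mirrored across the x = 0 plane) and volumetric geometries in mm standing in
for subcortical voxels (Euclidean distances).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Geometry", "make_sphere_geometry", "make_volumetric_geometry"]


@dataclass
class Geometry:
    """Node coordinates plus the pairwise distance matrix.

    Attributes
    ----------
    coords : (n, 3) float array
        Unit-sphere positions for surface-like geometries, mm otherwise.
    dist : (n, n) float array
        Symmetric nonnegative distances with zero diagonal.
    hemisphere : (n,) array of "L"/"R"
    medial_mask : (n,) bool array
        True marks nodes standing in for the medial wall (excluded from
        spin reassignment).
    kind : {"sphere", "volume"}
    """

    coords: np.ndarray
    dist: np.ndarray
    hemisphere: np.ndarray
    medial_mask: np.ndarray
    kind: str = "sphere"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.dist = np.asarray(self.dist, dtype=float)
        n = self.coords.shape[0]
        if self.dist.shape != (n, n):
            raise ValueError("dist shape does not match coords")
        if not np.allclose(self.dist, self.dist.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.dist) != 0):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(self.dist < 0):
            raise ValueError("distances must be nonnegative")

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]


def _fibonacci_sphere(n: int) -> np.ndarray:
    # Fibonacci lattice: near-uniform coverage without clustering at poles.
    golden = (1 + np.sqrt(5)) / 2
    i = np.arange(n)
    z = 1 - (2 * i + 1) / n
    theta = 2 * np.pi * i / golden
    r = np.sqrt(np.maximum(0.0, 1 - z**2))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def great_circle_distances(coords: np.ndarray) -> np.ndarray:
    """Pairwise great-circle (arc) distances between unit vectors."""
    g = np.clip(coords @ coords.T, -1.0, 1.0)
    d = np.arccos(g)
    np.fill_diagonal(d, 0.0)
    return 0.5 * (d + d.T)


def make_sphere_geometry(
    n_nodes: int, seed: int = 0, medial_fraction: float = 0.0
) -> Geometry:
    """Near-uniform parcel centres on the unit sphere.

    Hemispheres are split by the sign of x; an optional fraction of nodes
    per hemisphere (those nearest the x = 0 midline) is flagged as medial
    wall. ``seed`` applies a random rotation so distinct seeds give distinct
    but statistically identical geometries.
    """
    if n_nodes < 4:
        raise ValueError("n_nodes must be >= 4")
    if not 0 <= medial_fraction < 1:
        raise ValueError("medial_fraction must be in [0, 1)")
    coords = _fibonacci_sphere(n_nodes)
    rng = np.random.default_rng(seed)
    # random rotation about z keeps hemisphere balance while varying layout
    ang = rng.uniform(0, 2 * np.pi)
    rot = np.array(
        [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
    )
    coords = coords @ rot.T
    coords /= np.linalg.norm(coords, axis=1, keepdims=True)
    hemi = np.where(coords[:, 0] < 0, "L", "R")
    medial = np.zeros(n_nodes, dtype=bool)
    if medial_fraction > 0:
        k = int(round(medial_fraction * n_nodes))
        if k > 0:
            medial[np.argsort(np.abs(coords[:, 0]))[:k]] = True
    return Geometry(
        coords=coords,
        dist=great_circle_distances(coords),
        hemisphere=hemi,
        medial_mask=medial,
        kind="sphere",
    )


def make_volumetric_geometry(n_nodes: int, seed: int = 0, extent: float = 40.0) -> Geometry:
    """Random voxel-like positions in a box (mm), Euclidean distances."""
    if n_nodes < 4:
        raise ValueError("n_nodes must be >= 4")
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-extent / 2, extent / 2, size=(n_nodes, 3))
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(dist, 0.0)
    hemi = np.where(coords[:, 0] < 0, "L", "R")
    return Geometry(
        coords=coords,
        dist=0.5 * (dist + dist.T),
        hemisphere=hemi,
        medial_mask=np.zeros(n_nodes, dtype=bool),
        kind="volume",
    )
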