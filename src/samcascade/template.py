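"""Synthetic 3D shoot-apical-meristem templates built from overlapping spheres.

The shoot apical meristem (SAM) of *Arabidopsis* is a dome of small,
tightly packed cells organised in clonally distinct layers: the epidermis
(L1, the outermost single cell layer), the sub-epidermis (L2) and the
interior corpus.  This module generates an idealised stand-in for such a
tissue: cells are spheres placed on concentric spherical-cap shells under
a dome, two cells are neighbours when their spheres overlap, and layers
are read off the shell structure (outermost shell -> L1, next -> L2,
remainder -> CORPUS).

Boundary handling is implicit: cells on the tissue surface simply have
fewer neighbours, which realises a no-flux boundary condition for any
graph-Laplacian transport defined on the neighbour graph.

The module also builds the per-cell input fields of functional
ATML1/PDF2 protein ([ML1p], arbitrary units) that drive the signalling
cascade: the wild-type field (1 a.u. in L1, 0 elsewhere), ectopic
activation fields, and the 75-member family of perturbed input patterns
used to probe robustness of HAM mRNA suppression.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.spatial import cKDTree

L1 = "L1"
L2 = "L2"
CORPUS = "CORPUS"
LAYERS = (L1, L2, CORPUS)

GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


class TemplateError(ValueError):
    """Raised for geometrically impossible or inconsistent template requests."""


@dataclass(frozen=True)
class DomeGeometry:
    """Dome dimensions for the layered-shell construction.

    The dome is a spherical cap of curvature radius ``radius_of_curvature``
    and height ``height`` (both in length a.u.).  Cells sit on
    ``n_shells`` concentric cap shells spaced ``shell_spacing`` apart,
    all sharing the cap's opening angle.  ``sphere_radius`` fixes the
    cell-sphere radius; when ``None`` it is derived from the realised
    packing so that the overlap graph is connected (see
    :func:`build_dome_template`).  ``radius_jitter`` is the relative
    half-width of the deterministic per-cell radius perturbation.
    """

    radius_of_curvature: float = 16.0
    height: float = 8.0
    n_shells: int = 6
    shell_spacing: float = 2.0
    sphere_radius: float | None = None
    radius_jitter: float = 0.04

    def validate(self) -> None:
        if self.height <= 0 or self.radius_of_curvature <= 0:
            raise TemplateError("dome height and curvature radius must be positive")
        if self.height > self.radius_of_curvature:
            raise TemplateError("dome height cannot exceed the radius of curvature")
        if self.n_shells < 1:
            raise TemplateError("need at least one shell")
        if self.shell_spacing <= 0:
            raise TemplateError("shell spacing must be positive")
        if self.shell_spacing > self.height:
            raise TemplateError("shell spacing exceeds dome height")
        innermost = self.radius_of_curvature - (self.n_shells - 1) * self.shell_spacing
        if innermost <= 0:
            raise TemplateError(
                f"{self.n_shells} shells at spacing {self.shell_spacing} do not fit "
                f"inside curvature radius {self.radius_of_curvature}"
            )

    @property
    def opening_angle(self) -> float:
        """Polar half-angle of the cap, arccos(1 - height / curvature radius)."""
        return math.acos(1.0 - self.height / self.radius_of_curvature)


#: Two-shell miniature dome used for hand-checkable examples.
MICRO_DOME = DomeGeometry(radius_of_curvature=4.0, height=2.0, n_shells=2, shell_spacing=1.5)


@dataclass(frozen=True)
class Cell:
    id: int
    center: tuple[float, float, float]
    radius: float
    volume: float
    layer: str
    shell: int


@dataclass(frozen=True)
class MLpField:
    """Per-cell [ML1p] input concentration (a.u.) with a scenario label."""

    values: np.ndarray
    label: str

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("MLpField values must be one-dimensional")
        if np.any(values < 0):
            raise ValueError("[ML1p] values must be non-negative")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class CellTemplate:
    """Immutable multicellular geometry: sphere packing plus neighbour graph.

    ``centers`` is (n, 3), ``radii``/``volumes``/``shells``/``layers`` are
    length n, and ``edges`` is an (m, 2) array of unordered neighbour pairs
    with i < j.  Layers may be empty strings before :func:`assign_layers`.
    """

    centers: np.ndarray
    radii: np.ndarray
    volumes: np.ndarray
    shells: np.ndarray
    layers: np.ndarray
    edges: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        n = centers.shape[0]
        radii = np.asarray(self.radii, dtype=float)
        volumes = np.asarray(self.volumes, dtype=float)
        shells = np.asarray(self.shells, dtype=int)
        layers = np.asarray(self.layers, dtype=object)
        edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if not (len(radii) == len(volumes) == len(shells) == len(layers) == n):
            raise ValueError("inconsistent per-cell array lengths")
        if np.any(radii <= 0) or np.any(volumes <= 0):
            raise ValueError("cell radii and volumes must be positive")
        if edges.size:
            if np.any(edges[:, 0] == edges[:, 1]):
                raise ValueError("self-neighbours are not allowed")
            lo = np.minimum(edges[:, 0], edges[:, 1])
            hi = np.maximum(edges[:, 0], edges[:, 1])
            edges = np.unique(np.column_stack([lo, hi]), axis=0)
        for name, arr in [
            ("centers", centers), ("radii", radii), ("volumes", volumes),
            ("shells", shells), ("layers", layers), ("edges", edges),
        ]:
            object.__setattr__(self, name, arr)

    # -- basic accessors -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.centers.shape[0]

    @property
    def cells(self) -> list[Cell]:
        return [
            Cell(
                id=i,
                center=tuple(self.centers[i]),
                radius=float(self.radii[i]),
                volume=float(self.volumes[i]),
                layer=str(self.layers[i]),
                shell=int(self.shells[i]),
            )
            for i in range(self.n_cells)
        ]

    @property
    def neighbor_pairs(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.edges}

    def layer_mask(self, layer: str) -> np.ndarray:
        return self.layers == layer

    def layer_counts(self) -> dict[str, int]:
        return {layer: int(np.sum(self.layers == layer)) for layer in LAYERS}

    def adjacency(self) -> csr_matrix:
        """Symmetric unweighted adjacency matrix of the neighbour graph."""
        n = self.n_cells
        if not self.edges.size:
            return csr_matrix((n, n))
        i, j = self.edges[:, 0], self.edges[:, 1]
        rows = np.concatenate([i, j])
        cols = np.concatenate([j, i])
        data = np.ones(rows.size)
        return csr_matrix((data, (rows, cols)), shape=(n, n))

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency().sum(axis=1)).ravel()

    def is_connected(self) -> bool:
        if self.n_cells == 1:
            return True
        n_comp, _ = connected_components(self.adjacency(), directed=False)
        return n_comp == 1

    def checksum(self) -> str:
        """SHA-256 digest of the geometry, for provenance records."""
        h = hashlib.sha256()
        for arr in (self.centers, self.radii, self.volumes, self.shells, self.edges):
            h.update(np.ascontiguousarray(arr).tobytes())
        h.update(",".join(map(str, self.layers)).encode())
        return h.hexdigest()

    # -- serialisation ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(self.n_cells),
                "x": self.centers[:, 0],
                "y": self.centers[:, 1],
                "z": self.centers[:, 2],
                "radius": self.radii,
                "volume": self.volumes,
                "layer": self.layers,
                "shell": self.shells,
            }
        )

    def to_csv(self, cells_path: str | Path, edges_path: str | Path) -> None:
        # %.17g keeps the roundtrip bit-exact for float64 coordinates
        self.to_frame().to_csv(cells_path, index=False, float_format="%.17g")
        pd.DataFrame(self.edges, columns=["i", "j"]).to_csv(edges_path, index=False)

    @classmethod
    def from_csv(cls, cells_path: str | Path, edges_path: str | Path) -> "CellTemplate":
        cells = pd.read_csv(cells_path, float_precision="round_trip").sort_values("id")
        edges = pd.read_csv(edges_path)
        return cls(
            centers=cells[["x", "y", "z"]].to_numpy(),
            radii=cells["radius"].to_numpy(),
            volumes=cells["volume"].to_numpy(),
            shells=cells["shell"].to_numpy() if "shell" in cells else np.zeros(len(cells), int),
            layers=cells["layer"].to_numpy(dtype=object),
            edges=edges[["i", "j"]].to_numpy(),
        )

    def to_json(self, path: str | Path) -> None:
        doc = {
            "metadata": _jsonable(self.metadata),
            "cells": self.to_frame().to_dict(orient="records"),
            "edges": self.edges.tolist(),
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "CellTemplate":
        doc = json.loads(Path(path).read_text())
        cells = pd.DataFrame(doc["cells"]).sort_values("id")
        return cls(
            centers=cells[["x", "y", "z"]].to_numpy(),
            radii=cells["radius"].to_numpy(),
            volumes=cells["volume"].to_numpy(),
            shells=cells["shell"].to_numpy(),
            layers=cells["layer"].to_numpy(dtype=object),
            edges=np.asarray(doc["edges"], dtype=int).reshape(-1, 2),
            metadata=doc.get("metadata", {}),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# neighbour detection
# ---------------------------------------------------------------------------

def find_neighbors(
    centers: np.ndarray,
    radii: np.ndarray,
    overlap_factor: float = 1.0,
) -> np.ndarray:
    """Detect neighbouring cells by sphere overlap.

    Cells i and j are neighbours iff
    ``distance(center_i, center_j) < overlap_factor * (radius_i + radius_j)``.

    Returns an (m, 2) integer array of unordered pairs with i < j.
    Raises :class:`TemplateError` if two centres coincide (degenerate
    packing) or any radius is non-positive.
    """
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    radii = np.asarray(radii, dtype=float)
    if overlap_factor <= 0:
        raise TemplateError("overlap_factor must be positive")
    if np.any(radii <= 0):
        raise TemplateError("all sphere radii must be positive")
    tree = cKDTree(centers)
    cutoff = overlap_factor * 2.0 * float(radii.max())
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    if pairs.size == 0:
        return np.empty((0, 2), dtype=int)
    d = np.linalg.norm(centers[pairs[:, 0]] - centers[pairs[:, 1]], axis=1)
    if np.any(d < 1e-12):
        raise TemplateError("two cell centers coincide")
    keep = d < overlap_factor * (radii[pairs[:, 0]] + radii[pairs[:, 1]])
    out = pairs[keep]
    order = np.lexsort((out[:, 1], out[:, 0]))
    return out[order]


# ---------------------------------------------------------------------------
# dome construction
# ---------------------------------------------------------------------------

def _apportion(total: int, weights: np.ndarray, minimum: int = 1) -> np.ndarray:
    """Split ``total`` into integer parts proportional to ``weights``.

    Largest-remainder rounding; every part receives at least ``minimum``.
    """
    weights = np.asarray(weights, dtype=float)
    k = len(weights)
    if total < minimum * k:
        raise TemplateError(f"cannot place {total} cells across {k} bins (minimum {minimum})")
    free = total - minimum * k
    quota = free * weights / weights.sum()
    parts = np.floor(quota).astype(int)
    remainder = free - parts.sum()
    # deterministic tie-break: largest fractional part, then lowest index
    frac = quota - np.floor(quota)
    order = np.lexsort((np.arange(k), -frac))
    parts[order[:remainder]] += 1
    return parts + minimum


def _cap_points(shell_radius: float, theta_max: float, n: int, ring_offsets: np.ndarray) -> np.ndarray:
    """Near-uniform points on a spherical cap of radius ``shell_radius``.

    One apex point plus latitude rings; per-ring counts follow sin(theta)
    (area weighting) via largest-remainder rounding, so the total is
    exactly ``n``.  ``ring_offsets`` gives the azimuthal phase of each
    ring (stagger + jitter), indexed from ring 1.
    """
    if n == 1:
        return np.array([[0.0, 0.0, shell_radius]])
    # choose ring count so polar spacing ~ azimuthal spacing
    m = max(1, round(theta_max * math.sqrt(n / (2.0 * math.pi * (1.0 - math.cos(theta_max))))))
    m = min(m, n - 1)
    thetas = theta_max * np.arange(1, m + 1) / m
    counts = _apportion(n - 1, np.sin(thetas), minimum=1)
    pts = [np.array([0.0, 0.0, shell_radius])]
    for j, (theta, cnt) in enumerate(zip(thetas, counts)):
        phi0 = ring_offsets[j % len(ring_offsets)]
        phi = phi0 + 2.0 * math.pi * np.arange(cnt) / cnt
        pts.append(
            shell_radius
            * np.column_stack([
                math.sin(theta) * np.cos(phi),
                math.sin(theta) * np.sin(phi),
                np.full(cnt, math.cos(theta)),
            ])
        )
    return np.vstack(pts)


def _auto_sphere_radius(centers: np.ndarray, jitter: float) -> float:
    """Uniform base sphere radius guaranteeing a connected overlap graph.

    Uses the longest edge L of a Euclidean minimum spanning tree built on
    a k-nearest-neighbour candidate graph: any overlap threshold above L
    connects the packing, so the base radius is set to 0.58 L, leaving
    headroom for a +/- ``jitter`` relative radius perturbation
    (2 * 0.58 * (1 - jitter) > 1 for jitter <= 0.13).
    """
    n = centers.shape[0]
    if n == 1:
        return 1.0
    tree = cKDTree(centers)
    k = min(n, 13)
    dist, idx = tree.query(centers, k=k)
    rows = np.repeat(np.arange(n), k - 1)
    cols = idx[:, 1:].ravel()
    vals = dist[:, 1:].ravel()
    graph = csr_matrix((vals, (rows, cols)), shape=(n, n))
    n_comp, _ = connected_components(graph, directed=False)
    if n_comp != 1:  # sparse candidate graph too local; fall back to full graph
        from scipy.spatial.distance import pdist, squareform

        graph = csr_matrix(squareform(pdist(centers)))
    mst = minimum_spanning_tree(graph)
    longest = float(mst.data.max())
    return 0.58 * longest


def build_dome_template(
    n_target: int = 1216,
    geometry: DomeGeometry | None = None,
    seed: int = 0,
    overlap_factor: float = 1.0,
) -> CellTemplate:
    """Build a dome-shaped template of exactly ``n_target`` overlapping spheres.

    Cells are apportioned across concentric cap shells in proportion to
    shell surface area and laid out on latitude rings within each shell.
    The neighbour graph comes from :func:`find_neighbors`; layers are
    assigned from the shell structure by :func:`assign_layers`.  The
    construction is fully deterministic for a given ``seed``, which only
    perturbs ring phases and sphere radii.

    Raises :class:`TemplateError` for impossible geometry or if the
    resulting overlap graph is disconnected.
    """
    geometry = geometry or DomeGeometry()
    geometry.validate()
    if n_target < 10:
        raise TemplateError("n_target must be at least 10")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5A3]))
    theta_max = geometry.opening_angle
    shell_radii = geometry.radius_of_curvature - geometry.shell_spacing * np.arange(geometry.n_shells)
    counts = _apportion(n_target, shell_radii**2, minimum=1)

    centers, shells = [], []
    for s, (R_s, n_s) in enumerate(zip(shell_radii, counts)):
        # deterministic stagger between rings plus a small seeded phase
        offsets = GOLDEN_ANGLE * np.arange(1, 64) + rng.uniform(0, 2 * math.pi, 63)
        pts = _cap_points(float(R_s), theta_max, int(n_s), offsets)
        centers.append(pts)
        shells.append(np.full(len(pts), s, dtype=int))
    centers = np.vstack(centers)
    shells = np.concatenate(shells)

    base_r = geometry.sphere_radius or _auto_sphere_radius(centers, geometry.radius_jitter)
    radii = base_r * (1.0 + geometry.radius_jitter * rng.uniform(-1.0, 1.0, len(centers)))
    volumes = (4.0 / 3.0) * math.pi * radii**3

    edges = find_neighbors(centers, radii, overlap_factor=overlap_factor)
    template = CellTemplate(
        centers=centers,
        radii=radii,
        volumes=volumes,
        shells=shells,
        layers=np.full(len(centers), "", dtype=object),
        edges=edges,
        metadata={
            "n_target": int(n_target),
            "seed": int(seed),
            "overlap_factor": float(overlap_factor),
            "geometry": {
                "radius_of_curvature": geometry.radius_of_curvature,
                "height": geometry.height,
                "n_shells": geometry.n_shells,
                "shell_spacing": geometry.shell_spacing,
                "sphere_radius": base_r,
                "radius_jitter": geometry.radius_jitter,
            },
        },
    )
    template = assign_layers(template)
    if not template.is_connected():
        raise TemplateError("generated neighbour graph is disconnected; widen sphere radius")
    return template


def assign_layers(template: CellTemplate) -> CellTemplate:
    """Label cells by shell index: outermost -> L1, next -> L2, rest -> CORPUS.

    Requires at least two geometric shells.
    """
    shells = template.shells
    distinct = np.unique(shells)
    if len(distinct) < 2:
        raise TemplateError("layer assignment requires at least two shells")
    layers = np.empty(template.n_cells, dtype=object)
    layers[shells == distinct[0]] = L1
    layers[shells == distinct[1]] = L2
    layers[shells > distinct[1]] = CORPUS
    return replace(template, layers=layers)


# ---------------------------------------------------------------------------
# [ML1p] input fields
# ---------------------------------------------------------------------------

def _require_layers(template: CellTemplate) -> None:
    if not np.all(np.isin(template.layers, LAYERS)):
        raise TemplateError("template layers must be assigned first")


def make_ml1p_wildtype(template: CellTemplate) -> MLpField:
    """Wild-type input: [ML1p] = 1 a.u. in every L1 cell, 0 a.u. elsewhere."""
    _require_layers(template)
    values = np.where(template.layer_mask(L1), 1.0, 0.0)
    return MLpField(values=values, label="wild_type")


def make_ml1p_ectopic(template: CellTemplate, l1_value: float, deep_value: float) -> MLpField:
    """Ectopic-activation input: ``l1_value`` in L1, ``deep_value`` in L2 and corpus.

    The reference ectopic scenario (ATML1 over-expression) uses
    (1.1, 0.4) a.u.; (1.0, 0.0) degenerates to the wild-type field.
    """
    _require_layers(template)
    if l1_value < 0 or deep_value < 0:
        raise ValueError("[ML1p] values must be non-negative")
    values = np.where(template.layer_mask(L1), float(l1_value), float(deep_value))
    return MLpField(values=values, label=f"ectopic({l1_value:g},{deep_value:g})")


#: (family, L1 range, deep range, fixed (l1, deep) member); family C is uniform.
PERTURBATION_FAMILIES = (
    ("A", (1.05, 1.5), (0.3, 0.6), (1.3, 0.5)),
    ("B", (1.05, 1.5), (0.6, 2.0), (1.1, 0.7)),
    ("C", (1.05, 1.5), None, (1.1, 1.1)),
)

N_RANDOM_PER_FAMILY = 24


def sample_ml1p_patterns(template: CellTemplate, seed: int = 0) -> list[MLpField]:
    """Draw the 75 perturbed [ML1p] patterns probing suppression robustness.

    Three families of 25 (24 uniform-random draws plus one fixed member):

    * A — ectopic ranges suggested by in-situ data: L1 in [1.05, 1.5],
      deep layers (L2 + corpus) in [0.3, 0.6]; fixed member (1.3, 0.5).
    * B — elevated deep layers: L1 in [1.05, 1.5], deep in [0.6, 2.0];
      fixed member (1.1, 0.7).
    * C — a single level in [1.05, 1.5] applied to every layer;
      fixed member 1.1 everywhere.

    Family order is A, B, C with the 24 random draws first and the fixed
    member last; each family consumes an independent sub-stream of
    ``seed``, so the collection is reproducible.
    """
    _require_layers(template)
    fields: list[MLpField] = []
    for fam_idx, (name, l1_range, deep_range, fixed) in enumerate(PERTURBATION_FAMILIES):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB17, fam_idx]))
        for k in range(N_RANDOM_PER_FAMILY):
            l1_val = rng.uniform(*l1_range)
            deep_val = l1_val if deep_range is None else rng.uniform(*deep_range)
            fields.append(
                MLpField(
                    values=np.where(template.layer_mask(L1), l1_val, deep_val),
                    label=f"perturb_{name}_rand{k + 1:02d}",
                )
            )
        l1_fix, deep_fix = fixed
        fields.append(
            MLpField(
                values=np.where(template.layer_mask(L1), l1_fix, deep_fix),
                label=f"perturb_{name}_fixed",
            )
        )
    return fields


def write_ml1p_csv(field: MLpField, path: str | Path) -> None:
    pd.DataFrame(
        {"id": np.arange(len(field.values)), "ml1p": field.values, "label": field.label}
    ).to_csv(path, index=False)


def read_ml1p_csv(path: str | Path) -> MLpField:
    df = pd.read_csv(path).sort_values("id")
    label = str(df["label"].iloc[0]) if "label" in df and len(df) else "custom"
    return MLpField(values=df["ml1p"].to_numpy(), label=label)
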