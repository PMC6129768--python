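"""Cortical source-space geometry.

Triangle meshes serve as the solution space of the distributed inverse
problem: each vertex carries a current-dipole triple.  This module loads
meshes (ASCII OFF, FreeSurfer binary surfaces), derives the edge graph used
for neighborhood queries and shortest paths, converts Talairach coordinates
to MNI space, and constructs the anatomical reference region against which
reconstructed activity is scored.

All coordinates are millimeters in an MNI-aligned, RAS-oriented frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import trimesh.creation

__all__ = [
    "SourceSpace",
    "MeshGraph",
    "ReferenceRegion",
    "MeshParseError",
    "load_mesh",
    "load_freesurfer_pair",
    "build_graph",
    "adjacency_quantiles",
    "talairach_to_mni",
    "map_to_vertices",
    "shortest_path",
    "build_reference_region",
    "make_sphere_source_space",
    "save_region",
    "load_region",
]

LEFT = "left"
RIGHT = "right"


class MeshParseError(ValueError):
    """Raised when a mesh file cannot be parsed; carries line context."""


@dataclass
class SourceSpace:
    """A triangulated cortical surface with per-vertex hemisphere labels.

    Attributes
    ----------
    vertices : (N_s, 3) float array, positions in mm.
    faces : (M, 3) int array of vertex-index triples.
    hemisphere : (N_s,) array of {"left", "right"} labels.
    """

    vertices: np.ndarray
    faces: np.ndarray
    hemisphere: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        self.hemisphere = np.asarray(self.hemisphere)
        n = len(self.vertices)
        if n < 4:
            raise ValueError(f"source space needs at least 4 vertices, got {n}")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be an (M, 3) index array")
        if self.faces.min() < 0 or self.faces.max() >= n:
            raise ValueError("face indices out of range")
        used = np.zeros(n, dtype=bool)
        used[self.faces.ravel()] = True
        if not used.all():
            orphans = np.flatnonzero(~used)
            raise ValueError(f"vertices without incident faces: {orphans[:10].tolist()}")
        if len(self.hemisphere) != n:
            raise ValueError("hemisphere labels must match vertex count")
        bad = set(np.unique(self.hemisphere)) - {LEFT, RIGHT}
        if bad:
            raise ValueError(f"unknown hemisphere labels: {sorted(bad)}")

    @property
    def n_sources(self) -> int:
        return len(self.vertices)


@dataclass
class MeshGraph:
    """Edge graph of a source space: adjacency sets and Euclidean edge lengths."""

    adjacency: dict[int, set[int]]
    edge_lengths: dict[tuple[int, int], float]

    def __post_init__(self) -> None:
        for (u, v), length in self.edge_lengths.items():
            if length <= 0:
                raise ValueError(f"non-positive edge length on edge ({u}, {v})")

    @property
    def n_vertices(self) -> int:
        return len(self.adjacency)

    def degrees(self) -> np.ndarray:
        return np.array([len(self.adjacency[v]) for v in sorted(self.adjacency)])

    def lengths(self) -> np.ndarray:
        return np.fromiter(self.edge_lengths.values(), dtype=float)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.adjacency)
        for (u, v), length in self.edge_lengths.items():
            g.add_edge(u, v, weight=length)
        return g


@dataclass
class ReferenceRegion:
    """A set of source-space vertices representing the expected generator."""

    vertex_ids: np.ndarray
    seed_coords: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    def __post_init__(self) -> None:
        self.vertex_ids = np.unique(np.asarray(self.vertex_ids, dtype=int))
        self.seed_coords = np.atleast_2d(np.asarray(self.seed_coords, dtype=float))
        if len(self.vertex_ids) == 0:
            raise ValueError("reference region is empty")

    def __len__(self) -> int:
        return len(self.vertex_ids)


# ---------------------------------------------------------------------------
# mesh I/O


def _parse_off(path: Path, text: str) -> tuple[np.ndarray, np.ndarray]:
    lines = text.splitlines()
    # strip comments/blank lines but remember original numbering for errors
    content: list[tuple[int, str]] = [
        (i + 1, ln.strip()) for i, ln in enumerate(lines)
        if ln.strip() and not ln.strip().startswith("#")
    ]
    if not content or content[0][1].upper() != "OFF":
        raise MeshParseError(f"{path}: line 1: missing OFF header")
    try:
        counts = content[1][1].split()
        n_v, n_f = int(counts[0]), int(counts[1])
    except (IndexError, ValueError) as exc:
        raise MeshParseError(f"{path}: line {content[1][0]}: bad count line") from exc
    rows = content[2:]
    if len(rows) < n_v + n_f:
        raise MeshParseError(f"{path}: truncated file, expected {n_v + n_f} rows")
    verts = np.empty((n_v, 3))
    for k in range(n_v):
        lineno, ln = rows[k]
        parts = ln.split()
        if len(parts) < 3:
            raise MeshParseError(f"{path}: line {lineno}: expected 3 coordinates")
        try:
            verts[k] = [float(p) for p in parts[:3]]
        except ValueError as exc:
            raise MeshParseError(f"{path}: line {lineno}: non-numeric coordinate") from exc
    faces = np.empty((n_f, 3), dtype=int)
    for k in range(n_f):
        lineno, ln = rows[n_v + k]
        parts = ln.split()
        try:
            arity = int(parts[0])
        except (IndexError, ValueError) as exc:
            raise MeshParseError(f"{path}: line {lineno}: bad face row") from exc
        if arity != 3:
            raise MeshParseError(
                f"{path}: line {lineno}: only triangular faces supported, got {arity}-gon"
            )
        try:
            faces[k] = [int(p) for p in parts[1:4]]
        except ValueError as exc:
            raise MeshParseError(f"{path}: line {lineno}: non-integer vertex index") from exc
    return verts, faces


def _hemisphere_by_x(vertices: np.ndarray) -> np.ndarray:
    return np.where(vertices[:, 0] < 0, LEFT, RIGHT)


def load_mesh(path: str | Path, hemisphere_rule: str | np.ndarray = "x-sign") -> SourceSpace:
    """Load a triangle mesh as a SourceSpace.

    ASCII OFF files are detected by their header; anything else is handed to
    the FreeSurfer binary surface reader.  ``hemisphere_rule`` is either
    ``"x-sign"`` (x < 0 is the left hemisphere), ``"left"``/``"right"``
    (whole file is one hemisphere), or an explicit per-vertex label array.
    """
    path = Path(path)
    head = path.open("rb").read(4)
    if head[:3].upper() == b"OFF":
        verts, faces = _parse_off(path, path.read_text())
    else:
        from nibabel.freesurfer.io import read_geometry

        try:
            verts, faces = read_geometry(str(path))
        except Exception as exc:  # noqa: BLE001 - re-raise with file context
            raise MeshParseError(f"{path}: not a parsable OFF or FreeSurfer surface: {exc}") from exc
        verts = np.asarray(verts, dtype=float)
        faces = np.asarray(faces, dtype=int)
    if isinstance(hemisphere_rule, str):
        if hemisphere_rule == "x-sign":
            hemi = _hemisphere_by_x(verts)
        elif hemisphere_rule in (LEFT, RIGHT):
            hemi = np.full(len(verts), hemisphere_rule)
        else:
            raise ValueError(f"unknown hemisphere rule {hemisphere_rule!r}")
    else:
        hemi = np.asarray(hemisphere_rule)
    return SourceSpace(verts, faces, hemi)


def load_freesurfer_pair(left_path: str | Path, right_path: str | Path) -> SourceSpace:
    """Load left/right surface files and concatenate with an index offset."""
    lh = load_mesh(left_path, hemisphere_rule=LEFT)
    rh = load_mesh(right_path, hemisphere_rule=RIGHT)
    verts = np.vstack([lh.vertices, rh.vertices])
    faces = np.vstack([lh.faces, rh.faces + len(lh.vertices)])
    hemi = np.concatenate([lh.hemisphere, rh.hemisphere])
    return SourceSpace(verts, faces, hemi)


def make_sphere_source_space(n_subdiv: int, radius: float) -> SourceSpace:
    """Subdivided icosahedron scaled to ``radius`` (mm); x < 0 is 'left'.

    Handy desk-scale stand-in for a cortical surface: n_subdiv=0 gives 12
    vertices, each subdivision roughly quadruples the count (2 -> 162,
    3 -> 642).
    """
    if n_subdiv < 0:
        raise ValueError("n_subdiv must be >= 0")
    if radius <= 0:
        raise ValueError("radius must be positive")
    mesh = trimesh.creation.icosphere(subdivisions=n_subdiv, radius=radius)
    verts = np.asarray(mesh.vertices, dtype=float)
    faces = np.asarray(mesh.faces, dtype=int)
    return SourceSpace(verts, faces, _hemisphere_by_x(verts))


# ---------------------------------------------------------------------------
# graph operations


def build_graph(space: SourceSpace) -> MeshGraph:
    """Derive the undirected edge graph (all face edges) with mm edge lengths."""
    adjacency: dict[int, set[int]] = {v: set() for v in range(space.n_sources)}
    edge_lengths: dict[tuple[int, int], float] = {}
    for a, b, c in space.faces:
        for u, v in ((a, b), (b, c), (a, c)):
            u, v = (int(u), int(v)) if u < v else (int(v), int(u))
            if (u, v) not in edge_lengths:
                edge_lengths[(u, v)] = float(
                    np.linalg.norm(space.vertices[u] - space.vertices[v])
                )
            adjacency[u].add(v)
            adjacency[v].add(u)
    return MeshGraph(adjacency, edge_lengths)


def adjacency_quantiles(graph: MeshGraph, q: float = 0.95) -> tuple[float, int]:
    """q-quantiles of edge lengths and vertex degrees.

    Returns ``(eps, min_points)`` — the DBSCAN neighborhood radius and the
    core-point threshold derived from the mesh tessellation (the idea being
    that adjacent vertices should land in the same cluster).  Quantiles use
    linear interpolation; ``min_points`` is rounded half-up.
    """
    if graph.n_vertices == 0 or not graph.edge_lengths:
        raise ValueError("empty graph")
    eps = float(np.quantile(graph.lengths(), q))
    min_points = int(np.floor(np.quantile(graph.degrees(), q) + 0.5))
    return eps, min_points


def shortest_path(graph: MeshGraph, u: int, v: int) -> list[int]:
    """Minimal-total-edge-length path between two vertices (Dijkstra)."""
    if u == v:
        return [u]
    g = graph.to_networkx()
    try:
        return [int(n) for n in nx.dijkstra_path(g, u, v, weight="weight")]
    except nx.NetworkXNoPath as exc:
        raise ValueError(f"vertices {u} and {v} are not connected") from exc


# ---------------------------------------------------------------------------
# coordinates

# Lancaster et al. affines mapping ICBM/MNI coordinates to Talairach space
# ("icbm2tal"); Talairach->MNI applies the inverse.  "pooled" is the
# software-pooled matrix, "spm" and "fsl" the software-specific variants.
_ICBM2TAL = {
    "pooled": np.array(
        [
            [0.9357, 0.0029, -0.0072, -1.0423],
            [-0.0065, 0.9396, -0.0726, -1.3940],
            [0.0103, 0.0752, 0.8967, 3.6475],
            [0.0, 0.0, 0.0, 1.0],
        ]
    ),
    "spm": np.array(
        [
            [0.9254, 0.0024, -0.0118, -1.0207],
            [-0.0048, 0.9316, -0.0871, -1.7667],
            [0.0152, 0.0883, 0.8924, 4.0926],
            [0.0, 0.0, 0.0, 1.0],
        ]
    ),
    "fsl": np.array(
        [
            [0.9464, 0.0034, -0.0026, -1.0680],
            [-0.0083, 0.9479, -0.0580, -1.0239],
            [0.0053, 0.0617, 0.9010, 3.1883],
            [0.0, 0.0, 0.0, 1.0],
        ]
    ),
}


def talairach_to_mni(coord: np.ndarray, variant: str = "pooled") -> np.ndarray:
    """Affine Talairach -> MNI (mm), Lancaster-style.

    Accepts a single (3,) triple or an (n, 3) array; returns raw float
    coordinates (round with ``np.rint`` for integer reporting).
    """
    if variant not in _ICBM2TAL:
        raise ValueError(f"unknown transform variant {variant!r}")
    m = np.linalg.inv(_ICBM2TAL[variant])
    coord = np.asarray(coord, dtype=float)
    if not np.all(np.isfinite(coord)):
        raise ValueError("coordinates must be finite")
    single = coord.ndim == 1
    pts = np.atleast_2d(coord)
    out = pts @ m[:3, :3].T + m[:3, 3]
    return out[0] if single else out


def map_to_vertices(space: SourceSpace, coords: np.ndarray) -> np.ndarray:
    """Index of the Euclidean-nearest vertex per coordinate (ties: lowest index)."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.size == 0:
        raise ValueError("no coordinates given")
    d2 = ((coords[:, None, :] - space.vertices[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)


def build_reference_region(
    space: SourceSpace, graph: MeshGraph, seed_coords: np.ndarray
) -> ReferenceRegion:
    """Region = shortest paths between all seed-vertex pairs, grown by one ring.

    Seeds are mapped to their nearest vertices; the union of Dijkstra paths
    between every unordered pair of seed vertices is taken, then every graph
    neighbor of every path vertex is added.
    """
    seed_coords = np.atleast_2d(np.asarray(seed_coords, dtype=float))
    seeds = map_to_vertices(space, seed_coords)
    members: set[int] = set(int(s) for s in seeds)
    uniq = sorted(set(int(s) for s in seeds))
    for i, u in enumerate(uniq):
        for v in uniq[i + 1 :]:
            members.update(shortest_path(graph, u, v))
    ring = set()
    for v in members:
        ring |= graph.adjacency[v]
    members |= ring
    return ReferenceRegion(np.array(sorted(members)), seed_coords)


# ---------------------------------------------------------------------------
# region I/O: plain-text ids + JSON sidecar


def save_region(region: ReferenceRegion, path: str | Path, **params) -> None:
    path = Path(path)
    path.write_text("\n".join(str(i) for i in region.vertex_ids) + "\n")
    sidecar = {
        "seed_coords": region.seed_coords.tolist(),
        "n_vertices": int(len(region)),
        **params,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_region(path: str | Path) -> ReferenceRegion:
    path = Path(path)
    ids = np.array([int(ln) for ln in path.read_text().split()])
    sidecar = path.with_suffix(path.suffix + ".json")
    seeds = np.empty((0, 3))
    if sidecar.exists():
        seeds = np.asarray(json.loads(sidecar.read_text()).get("seed_coords", []), dtype=float)
    return ReferenceRegion(ids, seeds if seeds.size else np.empty((0, 3)))
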