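"""Triangulated surfaces and nested conductivity compartments.

Surfaces are flat-facet triangle meshes in SI units (meters).  A head model
is an ordered list of closed interfaces, outermost first, each separating an
inner tissue (conductivity ``sigma_in``, the side the facet normals point
away from) from an outer one (``sigma_out``, the side the normals point
toward).  For nested compartments this means outward-pointing normals with
``sigma_in`` the enclosed tissue.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "TriangleSurface",
    "Interface",
    "HeadModel",
    "MeshFormatError",
    "MeshTopologyError",
    "read_stl",
    "write_stl",
    "make_icosahedron",
    "make_icosphere",
    "subdivide_1to4",
    "validate_model",
    "read_model_json",
    "write_model_json",
]

# Welding and degeneracy thresholds -- far below any physical mesh scale.
WELD_TOL = 1e-9          # m, duplicate-vertex merge distance
DEGENERATE_AREA = 1e-16  # m^2
MAX_ASPECT = 1e6         # longest edge / shortest height
CLOSURE_TOL = 1e-10      # |sum(A_m n_m)| <= CLOSURE_TOL * sum(A_m)


class MeshFormatError(ValueError):
    """Malformed surface file or degenerate geometry."""


class MeshTopologyError(ValueError):
    """Non-manifold or non-closed surface where a closed one is required."""


@dataclass
class TriangleSurface:
    """Closed or open triangle mesh with cached per-facet geometry.

    Attributes
    ----------
    vertices : (V, 3) float array, meters
    triangles : (F, 3) int array of vertex indices (counter-clockwise seen
        from the side the normal points toward)
    areas : (F,) float array, m^2
    normals : (F, 3) unit vectors
    centroids : (F, 3) float array, meters
    """

    vertices: np.ndarray
    triangles: np.ndarray
    areas: np.ndarray = field(init=False, repr=False)
    normals: np.ndarray = field(init=False, repr=False)
    centroids: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError("vertices must be (V, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshFormatError("triangles must be (F, 3)")
        if len(self.triangles) == 0:
            raise MeshFormatError("surface has zero facets")
        if self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices):
            raise MeshFormatError("triangle index out of range")
        if np.any(
            (self.triangles[:, 0] == self.triangles[:, 1])
            | (self.triangles[:, 1] == self.triangles[:, 2])
            | (self.triangles[:, 0] == self.triangles[:, 2])
        ):
            bad = np.where(
                (self.triangles[:, 0] == self.triangles[:, 1])
                | (self.triangles[:, 1] == self.triangles[:, 2])
                | (self.triangles[:, 0] == self.triangles[:, 2])
            )[0]
            raise MeshFormatError(f"facets with repeated vertices: {bad.tolist()}")
        v = self.vertices[self.triangles]                    # (F, 3, 3)
        cross = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        double_area = np.linalg.norm(cross, axis=1)
        bad = np.where(double_area / 2.0 < DEGENERATE_AREA)[0]
        if bad.size:
            raise MeshFormatError(f"degenerate (zero-area) facets: {bad.tolist()}")
        self.areas = double_area / 2.0
        self.normals = cross / double_area[:, None]
        self.centroids = v.mean(axis=1)
        edge_len = np.stack(
            [
                np.linalg.norm(v[:, 1] - v[:, 0], axis=1),
                np.linalg.norm(v[:, 2] - v[:, 1], axis=1),
                np.linalg.norm(v[:, 0] - v[:, 2], axis=1),
            ],
            axis=1,
        ).max(axis=1)
        # height of the triangle relative to its longest edge
        height = double_area / edge_len
        bad = np.where(edge_len / height > MAX_ASPECT)[0]
        if bad.size:
            raise MeshFormatError(f"sliver facets (aspect > {MAX_ASPECT:g}): {bad.tolist()}")

    @property
    def n_facets(self) -> int:
        return len(self.triangles)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def closure_defect(self) -> float:
        """Norm of the area-weighted normal sum, zero for a closed surface."""
        return float(np.linalg.norm((self.areas[:, None] * self.normals).sum(axis=0)))

    def is_closed(self, tol: float = CLOSURE_TOL) -> bool:
        return self.closure_defect() <= tol * self.total_area

    def signed_volume(self) -> float:
        """Divergence-theorem volume; positive for outward-oriented closed surfaces."""
        v = self.vertices[self.triangles]
        return float(np.einsum("ij,ij->", np.cross(v[:, 0], v[:, 1]), v[:, 2]) / 6.0)

    def facet_size(self) -> np.ndarray:
        """Characteristic per-facet length scale sqrt(area)."""
        return np.sqrt(self.areas)

    def edge_manifold_check(self) -> None:
        """Raise unless every edge is shared by exactly two facets."""
        edges = np.sort(
            self.triangles[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1
        )
        _, counts = np.unique(edges, axis=0, return_counts=True)
        if np.any(counts != 2):
            n_bad = int(np.sum(counts != 2))
            raise MeshTopologyError(
                f"{n_bad} edges are not shared by exactly 2 facets; "
                "surface is not a closed manifold"
            )

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Inside test for a closed oriented surface via the winding number.

        Sums the signed solid angle of every facet at each point: 4 pi for
        interior points, 0 for exterior (on-surface points are ill-defined
        and classified by rounding).
        """
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        tri = self.vertices[self.triangles]
        inside = np.empty(len(points), dtype=bool)
        for i, p in enumerate(points):
            r = tri - p                                   # (F, 3, 3)
            R = np.linalg.norm(r, axis=2)
            num = np.einsum("ij,ij->i", r[:, 0], np.cross(r[:, 1], r[:, 2]))
            den = (
                R[:, 0] * R[:, 1] * R[:, 2]
                + np.einsum("ij,ij->i", r[:, 0], r[:, 1]) * R[:, 2]
                + np.einsum("ij,ij->i", r[:, 1], r[:, 2]) * R[:, 0]
                + np.einsum("ij,ij->i", r[:, 2], r[:, 0]) * R[:, 1]
            )
            omega = 2.0 * np.arctan2(num, den).sum()
            inside[i] = omega > 2.0 * np.pi
        return inside

    def flipped(self) -> "TriangleSurface":
        """Same mesh with all facet windings (hence normals) reversed."""
        return TriangleSurface(self.vertices.copy(), self.triangles[:, ::-1].copy())

    def geometry_digest(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.vertices).tobytes())
        h.update(np.ascontiguousarray(self.triangles).tobytes())
        return h.hexdigest()


@dataclass
class Interface:
    """One conductivity interface: a closed surface with inner/outer conductivity.

    ``contrast`` is K = (sigma_in - sigma_out) / (sigma_in + sigma_out),
    the quantity that scales the induced surface charge.
    """

    surface: TriangleSurface
    sigma_in: float
    sigma_out: float
    name: str = ""
    #: optional (center, radius) when the interface discretizes a sphere;
    #: lets refinement re-project new vertices onto the exact geometry
    projection: tuple | None = None

    def __post_init__(self) -> None:
        if self.sigma_in < 0 or self.sigma_out < 0:
            raise ValueError("conductivities must be non-negative")
        if self.sigma_in + self.sigma_out == 0:
            raise ValueError(f"interface {self.name!r}: sigma_in and sigma_out both zero")

    @property
    def contrast(self) -> float:
        return (self.sigma_in - self.sigma_out) / (self.sigma_in + self.sigma_out)


@dataclass
class HeadModel:
    """Ordered nested interfaces (outermost first) with global facet indexing."""

    interfaces: list[Interface]

    def __post_init__(self) -> None:
        if not self.interfaces:
            raise ValueError("model has no interfaces")
        counts = [itf.surface.n_facets for itf in self.interfaces]
        self.facet_offsets = np.concatenate([[0], np.cumsum(counts)])
        self.total_facets = int(self.facet_offsets[-1])

    # ---- concatenated per-facet arrays (global facet indexing) ----

    def _concat(self, attr: str) -> np.ndarray:
        return np.concatenate([getattr(i.surface, attr) for i in self.interfaces])

    @property
    def centroids(self) -> np.ndarray:
        return self._concat("centroids")

    @property
    def normals(self) -> np.ndarray:
        return self._concat("normals")

    @property
    def areas(self) -> np.ndarray:
        return self._concat("areas")

    @property
    def contrasts(self) -> np.ndarray:
        """Per-facet conductivity contrast K_m."""
        return np.concatenate(
            [np.full(i.surface.n_facets, i.contrast) for i in self.interfaces]
        )

    def all_triangles(self) -> np.ndarray:
        """(N, 3, 3) vertex coordinates of every facet in global order."""
        return np.concatenate(
            [i.surface.vertices[i.surface.triangles] for i in self.interfaces]
        )

    def local_index(self, global_idx: int) -> tuple[int, int]:
        k = int(np.searchsorted(self.facet_offsets, global_idx, side="right") - 1)
        return k, int(global_idx - self.facet_offsets[k])

    def interface_slices(self) -> list[slice]:
        return [
            slice(int(self.facet_offsets[k]), int(self.facet_offsets[k + 1]))
            for k in range(len(self.interfaces))
        ]

    def fingerprint(self) -> str:
        """Digest of geometry plus conductivities; binds factorizations to models."""
        h = hashlib.sha256()
        for itf in self.interfaces:
            h.update(itf.surface.geometry_digest().encode())
            h.update(np.array([itf.sigma_in, itf.sigma_out]).tobytes())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# STL I/O
# ---------------------------------------------------------------------------

def _weld(vertices: np.ndarray, triangles: np.ndarray, tol: float = WELD_TOL):
    """Merge vertices closer than ``tol`` via snapping to a tol-spaced grid."""
    key = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    return vertices[first], inverse[triangles]


def read_stl(path, units: str = "m") -> TriangleSurface:
    """Read a binary or ASCII STL file and weld duplicate vertices.

    ``units`` may be ``"m"`` (default) or ``"mm"``; millimeter files are
    converted to meters on read.  Facet winding is preserved from the file.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    try:
        mesh = trimesh.load_mesh(str(path), file_type="stl", process=False)
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise MeshFormatError(f"cannot parse STL {path}: {exc}") from exc
    faces = np.asarray(mesh.faces)
    if faces.size == 0:
        raise MeshFormatError(f"{path}: STL contains no facets")
    scale = {"m": 1.0, "mm": 1e-3}[units]
    verts, tris = _weld(np.asarray(mesh.vertices, dtype=np.float64) * scale, faces)
    return TriangleSurface(verts, tris)


def write_stl(surface: TriangleSurface, path) -> None:
    """Write a surface as binary STL (meters)."""
    mesh = trimesh.Trimesh(
        vertices=surface.vertices, faces=surface.triangles, process=False
    )
    mesh.export(str(path), file_type="stl")


# ---------------------------------------------------------------------------
# Synthetic sphere meshes
# ---------------------------------------------------------------------------

# Icosahedron: 12 vertices from three orthogonal golden rectangles.
_PHI = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array(
    [
        [-1, _PHI, 0], [1, _PHI, 0], [-1, -_PHI, 0], [1, -_PHI, 0],
        [0, -1, _PHI], [0, 1, _PHI], [0, -1, -_PHI], [0, 1, -_PHI],
        [_PHI, 0, -1], [_PHI, 0, 1], [-_PHI, 0, -1], [-_PHI, 0, 1],
    ],
    dtype=np.float64,
)
_ICO_FACES = np.array(
    [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ],
    dtype=np.int64,
)


def make_icosahedron(radius: float = 1.0, center=(0.0, 0.0, 0.0)) -> TriangleSurface:
    if radius <= 0:
        raise ValueError("radius must be positive")
    verts = _ICO_VERTS / np.linalg.norm(_ICO_VERTS[0]) * radius + np.asarray(center)
    surf = TriangleSurface(verts, _ICO_FACES.copy())
    if surf.signed_volume() < 0:  # pragma: no cover - table is outward already
        surf = surf.flipped()
    return surf


def subdivide_1to4(
    surface: TriangleSurface,
    project_to_sphere: tuple | None = None,
) -> TriangleSurface:
    """Split every facet at its edge midpoints into four facets.

    Shared edges are split consistently so watertightness is preserved.
    Without projection the total area is conserved exactly (flat split).
    ``project_to_sphere=(center, radius)`` additionally pushes all vertices
    of the refined mesh onto the given sphere, used for icosphere refinement.
    """
    surface.edge_manifold_check()
    tris = surface.triangles
    edges = np.sort(tris[:, [0, 1, 1, 2, 2, 0]].reshape(-1, 2), axis=1)
    uniq, inverse = np.unique(edges, axis=0, return_inverse=True)
    midpoints = surface.vertices[uniq].mean(axis=1)
    mid_idx = inverse.reshape(-1, 3) + surface.n_vertices   # (F, 3): m01, m12, m20
    new_verts = np.vstack([surface.vertices, midpoints])
    a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
    m01, m12, m20 = mid_idx[:, 0], mid_idx[:, 1], mid_idx[:, 2]
    new_tris = np.concatenate(
        [
            np.stack([a, m01, m20], axis=1),
            np.stack([m01, b, m12], axis=1),
            np.stack([m20, m12, c], axis=1),
            np.stack([m01, m12, m20], axis=1),
        ]
    )
    # interleave children of each parent so child k of parent f sits at 4f+k
    order = np.arange(4 * surface.n_facets).reshape(4, -1).T.ravel()
    new_tris = new_tris[order]
    if project_to_sphere is not None:
        center, radius = project_to_sphere
        center = np.asarray(center, dtype=np.float64)
        d = new_verts - center
        new_verts = center + d * (radius / np.linalg.norm(d, axis=1))[:, None]
    return TriangleSurface(new_verts, new_tris)


def make_icosphere(radius: float, subdivisions: int = 0, center=(0.0, 0.0, 0.0)) -> TriangleSurface:
    """Geodesic sphere with 20 * 4**subdivisions facets, vertices on the sphere."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    surf = make_icosahedron(radius, center)
    for _ in range(subdivisions):
        surf = subdivide_1to4(surf, project_to_sphere=(center, radius))
    return surf


# ---------------------------------------------------------------------------
# Model validation and model files
# ---------------------------------------------------------------------------

def validate_model(model: HeadModel, auto_flip: bool = False) -> dict:
    """Check closure, orientation and conductivity consistency of a model.

    Returns a report dict; raises :class:`MeshTopologyError` or
    :class:`ValueError` on fatal defects.  With ``auto_flip`` an
    inward-oriented interface is reversed in place instead of raising.
    """
    report: dict = {"interfaces": []}
    for k, itf in enumerate(model.interfaces):
        surf = itf.surface
        entry = {
            "name": itf.name or f"interface{k}",
            "n_facets": surf.n_facets,
            "closure_defect": surf.closure_defect() / surf.total_area,
            "signed_volume": surf.signed_volume(),
        }
        if not surf.is_closed():
            raise MeshTopologyError(
                f"interface {entry['name']}: not closed "
                f"(relative closure defect {entry['closure_defect']:.3e})"
            )
        if entry["signed_volume"] < 0:
            if auto_flip:
                model.interfaces[k] = Interface(
                    surf.flipped(), itf.sigma_in, itf.sigma_out, itf.name
                )
                entry["flipped"] = True
            else:
                raise MeshTopologyError(
                    f"interface {entry['name']}: normals point inward "
                    "(negative signed volume); pass auto_flip=True to fix"
                )
        report["interfaces"].append(entry)
    # nesting consistency: the outside of interface k+1 is the inside of k
    for k in range(len(model.interfaces) - 1):
        outer, inner = model.interfaces[k], model.interfaces[k + 1]
        if not np.isclose(inner.sigma_out, outer.sigma_in, rtol=1e-12, atol=0.0):
            raise ValueError(
                f"conductivity mismatch: sigma_out of {inner.name or k + 1} "
                f"({inner.sigma_out}) != sigma_in of enclosing {outer.name or k} "
                f"({outer.sigma_in})"
            )
    report["total_facets"] = model.total_facets
    report["fingerprint"] = model.fingerprint()
    return report


def read_model_json(path) -> HeadModel:
    """Load a model description file.

    The file is JSON with ``units`` ("m" or "mm") and an ordered
    ``interfaces`` list (outermost first) of
    ``{"stl_path": ..., "sigma_in": S/m, "sigma_out": S/m, "name": ...}``;
    STL paths are resolved relative to the JSON file.
    """
    path = Path(path)
    spec = json.loads(path.read_text())
    units = spec.get("units", "m")
    if units not in ("m", "mm"):
        raise ValueError(f"unknown units {units!r} (expected 'm' or 'mm')")
    interfaces = []
    for entry in spec["interfaces"]:
        stl = Path(entry["stl_path"])
        if not stl.is_absolute():
            stl = path.parent / stl
        interfaces.append(
            Interface(
                read_stl(stl, units=units),
                float(entry["sigma_in"]),
                float(entry["sigma_out"]),
                entry.get("name", stl.stem),
            )
        )
    return HeadModel(interfaces)


def write_model_json(model: HeadModel, path, stl_dir=None) -> None:
    """Write a model as JSON plus one STL per interface (meters)."""
    path = Path(path)
    stl_dir = Path(stl_dir) if stl_dir is not None else path.parent
    stl_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for k, itf in enumerate(model.interfaces):
        name = itf.name or f"interface{k}"
        stl_path = stl_dir / f"{name}.stl"
        write_stl(itf.surface, stl_path)
        entries.append(
            {
                "stl_path": str(stl_path.relative_to(path.parent))
                if stl_path.is_relative_to(path.parent)
                else str(stl_path),
                "sigma_in": itf.sigma_in,
                "sigma_out": itf.sigma_out,
                "name": name,
            }
        )
    path.write_text(json.dumps({"units": "m", "interfaces": entries}, indent=2))
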