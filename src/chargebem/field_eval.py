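"""Total electric field evaluation from a solved surface-charge density.

Off the interfaces the total field is the coil's primary field plus the
Coulomb field of the induced charges,

    E(r) = E_p(r) + sum_n F_n(r) rho*_n,

with F_n the unit-density facet field (analytic for facets near r, centroid
monopole beyond).  On an interface the field is discontinuous: the local
facet is a planar charge sheet contributing -+ n rho*/2 on the side the
normal points away from / toward, on top of the principal-value field of
all charges.  The normal-current continuity condition
sigma_in n.E_in = sigma_out n.E_out is what the charge solve enforces, so
its pointwise violation is a useful discretization residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .bem_operator import (
    ChargeSolution,
    near_pairs,
    triangle_fields,
    weighted_monopole_field,
    INV_4PI,
)
from .mesh_model import HeadModel

__all__ = [
    "ObservationSet",
    "FieldResult",
    "NearSurfaceError",
    "secondary_field",
    "field_off_surface",
    "field_one_sided",
    "bc_residual",
    "BCResidual",
    "read_points",
    "write_field_tsv",
    "read_field_tsv",
    "write_field_vtk",
]

#: points closer to a facet than this multiple of its size must use
#: one-sided (on-surface) evaluation
GUARD_FACTOR = 0.1

#: facets within this multiple of their size from an observation point are
#: summed with the analytic triangle field instead of the centroid
#: monopole.  Evaluation is per-point and cheap, so this is deliberately
#: wider than the assembly near radius: it keeps the evaluation quadrature
#: error well below the discretization error of the charge solve.
EVAL_NEAR_THRESHOLD = 20.0


class NearSurfaceError(ValueError):
    """Off-surface evaluation requested too close to an interface."""


@dataclass
class ObservationSet:
    """Evaluation points: free-space points or facet-attached one-sided points."""

    points: np.ndarray
    kind: str = "off_surface"             # "off_surface" | "on_surface"
    facet_indices: np.ndarray | None = None
    side: str = "out"                     # for on_surface: "in" | "out"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))
        if self.kind not in ("off_surface", "on_surface"):
            raise ValueError(f"unknown observation kind {self.kind!r}")
        if self.kind == "on_surface":
            if self.facet_indices is None:
                raise ValueError("on_surface observations need facet indices")
            if self.side not in ("in", "out"):
                raise ValueError("side must be 'in' or 'out'")


@dataclass
class FieldResult:
    """Per-point total and primary fields with provenance tags."""

    e_total: np.ndarray
    e_primary: np.ndarray
    provenance: dict = field(default_factory=dict)

    @property
    def e_secondary(self) -> np.ndarray:
        return self.e_total - self.e_primary

    def magnitudes(self) -> np.ndarray:
        return np.linalg.norm(self.e_total, axis=1)


def secondary_field(
    model: HeadModel,
    rho_star: np.ndarray,
    points: np.ndarray,
    near_threshold: float = EVAL_NEAR_THRESHOLD,
) -> np.ndarray:
    """Coulomb field of the facet charges at arbitrary points.

    Monopole sum over all facets, then near facets replaced by the analytic
    triangle field.  A point exactly in a near facet's plane receives that
    facet's principal-value (tangential) field, which is the correct
    on-surface limit for collocation points.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    cent, areas = model.centroids, model.areas
    E = weighted_monopole_field(cent, areas * rho_star, points)
    ti, sj = near_pairs(points, cent, areas, near_threshold)
    if ti.size:
        d = points[ti] - cent[sj]
        r2 = np.einsum("ij,ij->i", d, d)
        safe = r2 > 0.0
        mono = np.zeros_like(d)
        mono[safe] = (
            INV_4PI * (areas[sj][safe] / (r2[safe] * np.sqrt(r2[safe])))[:, None]
            * d[safe]
        )
        tris = model.all_triangles()
        delta = np.zeros_like(points)
        chunk = 200_000
        for s in range(0, len(ti), chunk):
            tc, sc = ti[s : s + chunk], sj[s : s + chunk]
            ana = triangle_fields(tris[sc], points[tc])
            np.add.at(
                delta, tc, (ana - mono[s : s + chunk]) * rho_star[sc][:, None]
            )
        E += delta
    return E


def _min_facet_distance(model: HeadModel, points: np.ndarray) -> np.ndarray:
    """Approximate distance to the surfaces, relative to local facet size.

    Distance to the nearest facet centroid divided by that facet's size;
    a cheap guard against evaluating the discontinuous kernel on top of an
    interface (exact point-to-triangle distance is not needed for a guard).
    """
    tree = cKDTree(model.centroids)
    d, idx = tree.query(points)
    return d / np.sqrt(model.areas[idx])


def field_off_surface(
    model: HeadModel,
    solution: ChargeSolution,
    coil,
    points: np.ndarray,
    near_threshold: float = EVAL_NEAR_THRESHOLD,
    allow_near: bool = False,
) -> FieldResult:
    """Total field at points away from all interfaces.

    Points within ``GUARD_FACTOR`` facet sizes of a surface are rejected
    (use :func:`field_one_sided` there), unless ``allow_near`` is set for
    controlled limit studies.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if not allow_near:
        rel = _min_facet_distance(model, points)
        if np.any(rel < GUARD_FACTOR):
            k = int(np.argmin(rel))
            raise NearSurfaceError(
                f"point {points[k]} is within {GUARD_FACTOR} facet sizes of an "
                "interface; use field_one_sided for on-surface values"
            )
    ep = coil.primary_field(points)
    es = secondary_field(model, solution.rho_star, points, near_threshold)
    return FieldResult(
        ep + es,
        ep,
        {"solution": solution.solver_tag, "coil": solution.coil_tag, "kind": "off_surface"},
    )


def field_one_sided(
    model: HeadModel,
    solution: ChargeSolution,
    coil,
    facet_indices: np.ndarray | None = None,
    side: str = "out",
    near_threshold: float = EVAL_NEAR_THRESHOLD,
) -> FieldResult:
    """One-sided limit of the total field at facet centroids.

    ``side="in"`` is the limit from the tissue the normal points away from
    (jump term -n rho*/2), ``side="out"`` from the tissue the normal points
    toward (+n rho*/2); the two differ by exactly n rho*.
    """
    if side not in ("in", "out"):
        raise ValueError("side must be 'in' or 'out'")
    idx = (
        np.arange(model.total_facets)
        if facet_indices is None
        else np.asarray(facet_indices, dtype=np.int64)
    )
    pts = model.centroids[idx]
    ep = coil.primary_field(pts)
    # principal-value field: own facet enters through its analytic in-plane
    # (tangential) term; its monopole contribution is zero at zero distance
    es = secondary_field(model, solution.rho_star, pts, near_threshold)
    jump = 0.5 * model.normals[idx] * solution.rho_star[idx][:, None]
    e_total = ep + es + (jump if side == "out" else -jump)
    return FieldResult(
        e_total,
        ep,
        {
            "solution": solution.solver_tag,
            "coil": solution.coil_tag,
            "kind": f"on_surface_{side}",
        },
    )


@dataclass
class BCResidual:
    per_facet: np.ndarray
    area_weighted_mean: float


def bc_residual(
    model: HeadModel,
    solution: ChargeSolution,
    coil,
    near_threshold: float = EVAL_NEAR_THRESHOLD,
) -> BCResidual:
    """Pointwise violation of normal-current continuity across interfaces.

    Per facet the current mismatch |s_in n.E_in - s_out n.E_out| is
    normalized by the local conductivity-weighted field magnitude
    (s_in + s_out) (|E_in| + |E_out|) / 2 plus a tiny floor.  Normalizing
    by the normal currents themselves would be degenerate on an insulating
    exterior (s_out = 0 forces J_out = 0, making that ratio identically
    one however accurate the solution).  The area-weighted mean summarizes
    discretization quality and decreases under mesh refinement.
    """
    e_in = field_one_sided(model, solution, coil, None, "in", near_threshold)
    e_out = field_one_sided(model, solution, coil, None, "out", near_threshold)
    n = model.normals
    sig_in = np.concatenate(
        [np.full(i.surface.n_facets, i.sigma_in) for i in model.interfaces]
    )
    sig_out = np.concatenate(
        [np.full(i.surface.n_facets, i.sigma_out) for i in model.interfaces]
    )
    jin = sig_in * np.einsum("ij,ij->i", n, e_in.e_total)
    jout = sig_out * np.einsum("ij,ij->i", n, e_out.e_total)
    mag = np.linalg.norm(e_in.e_total, axis=1) + np.linalg.norm(e_out.e_total, axis=1)
    scale = (sig_in + sig_out) * mag / 2.0
    floor = 1e-12 * (scale.max() if scale.max() > 0 else 1.0)
    per_facet = np.abs(jin - jout) / (scale + floor)
    w = model.areas
    return BCResidual(per_facet, float(np.sum(w * per_facet) / np.sum(w)))


# ---------------------------------------------------------------------------
# Point lists and field files
# ---------------------------------------------------------------------------

def read_points(path) -> np.ndarray:
    """Whitespace-delimited ``x y z`` per line (meters); '#' comments allowed."""
    pts = np.loadtxt(path, comments="#", ndmin=2)
    if pts.shape[1] != 3:
        raise ValueError(f"{path}: expected 3 columns, got {pts.shape[1]}")
    return pts


def write_field_tsv(points: np.ndarray, result: FieldResult, path) -> None:
    """TSV with columns x y z Ex Ey Ez |E| (meters, V/m)."""
    mag = result.magnitudes()
    data = np.column_stack([points, result.e_total, mag])
    header = "x\ty\tz\tEx\tEy\tEz\tEmag"
    np.savetxt(path, data, delimiter="\t", header=header, comments="", fmt="%.17g")


def read_field_tsv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a field TSV; returns (points (P,3), E (P,3))."""
    data = np.loadtxt(path, skiprows=1, ndmin=2)
    if data.shape[1] < 6:
        raise ValueError(f"{path}: expected at least 6 columns")
    return data[:, :3], data[:, 3:6]


def write_field_vtk(points: np.ndarray, result: FieldResult, path) -> None:
    """Legacy-VTK point cloud with the E-field as point vector data."""
    lines = [
        "# vtk DataFile Version 3.0",
        "chargebem field",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {len(points)} double",
    ]
    lines += [f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}" for p in points]
    lines += [f"POINT_DATA {len(points)}", "VECTORS E double"]
    lines += [f"{e[0]:.9g} {e[1]:.9g} {e[2]:.9g}" for e in result.e_total]
    Path(path).write_text("\n".join(lines) + "\n")
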