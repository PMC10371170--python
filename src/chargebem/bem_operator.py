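"""Discretized surface-charge integral operator and right-hand side.

The quasistatic surface-charge formulation leads to a Fredholm equation of
the second kind for the scaled charge density rho* = rho / eps0 on the
conductivity interfaces:

    rho*(r)/2 - K(r) n(r) . integral_S (r - r')/(4 pi |r - r'|^3) rho*(r') dS'
        = K(r) n(r) . E_p(r),

with K the conductivity contrast of the interface through r.  With
piecewise-constant charges per facet and centroid collocation this becomes
the N x N system A x = b,

    A_mn = delta_mn / 2 - K_m n_m . F_n(c_m),      b_m = K_m n_m . E_p(c_m),

where F_n is the electric field of facet n carrying unit scaled charge
density.  The outer average (1/A_m) integral_{t_m} n_m . F_n dA of the
double integral is evaluated with a 7-point degree-5 triangle rule for
near facet pairs -- plain centroid collocation there loses an order of
accuracy on curved surfaces -- while far pairs collapse to the centroid
monopole, for which the one-point outer rule is as accurate as the kernel
approximation itself.  The self term vanishes identically for a flat
facet (the principal-value field of a planar charge sheet is purely
tangential anywhere in its plane), so the diagonal is exactly 1/2.

F_n is computed in closed form (edge log terms plus a signed solid angle)
for near facet pairs.  Everything is stored in the rho* = rho/eps0
convention, so no factor of eps0 appears anywhere in assembled quantities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import LinearOperator
from scipy.spatial import cKDTree

from .mesh_model import HeadModel

__all__ = [
    "SystemOperator",
    "RightHandSide",
    "ChargeSolution",
    "CapacityError",
    "conductivity_contrast",
    "triangle_field_integral",
    "triangle_fields",
    "assemble_rhs",
    "assemble_dense",
    "assemble_matrix_free",
    "apply_operator",
    "charge_imbalance",
]

INV_4PI = 1.0 / (4.0 * np.pi)

#: facet pairs closer than this multiple of the local facet size
#: (sqrt of the larger of the two areas) use the analytic integral
DEFAULT_NEAR_THRESHOLD = 5.0

#: refuse dense assembly beyond this many facets
DENSE_CAP_DEFAULT = 60_000

_CHUNK = 2_000_000  # max pairwise entries per temporary block

# degree-5 symmetric triangle quadrature (7 points) in barycentric
# coordinates, used for the outer facet average of near interactions
_Q_A1, _Q_B1 = 0.059715871789770, 0.470142064105115
_Q_A2, _Q_B2 = 0.797426985353087, 0.101286507323456
TRI_QUAD_BARY = np.array(
    [
        [1 / 3, 1 / 3, 1 / 3],
        [_Q_A1, _Q_B1, _Q_B1], [_Q_B1, _Q_A1, _Q_B1], [_Q_B1, _Q_B1, _Q_A1],
        [_Q_A2, _Q_B2, _Q_B2], [_Q_B2, _Q_A2, _Q_B2], [_Q_B2, _Q_B2, _Q_A2],
    ]
)
TRI_QUAD_W = np.array(
    [0.225]
    + [0.132394152788506] * 3
    + [0.125939180544827] * 3
)


class CapacityError(RuntimeError):
    """Dense assembly would exceed the configured facet cap."""


def conductivity_contrast(sigma_in: float, sigma_out: float) -> float:
    """K = (sigma_in - sigma_out) / (sigma_in + sigma_out); |K| <= 1."""
    if sigma_in < 0 or sigma_out < 0:
        raise ValueError("conductivities must be non-negative")
    total = sigma_in + sigma_out
    if total == 0:
        raise ValueError("sigma_in and sigma_out cannot both be zero")
    return (sigma_in - sigma_out) / total


# ---------------------------------------------------------------------------
# Analytic field of a uniformly charged triangle
# ---------------------------------------------------------------------------

def triangle_fields(tri: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Closed-form E-field of unit-density charged triangles, pairwise.

    ``tri`` is (M, 3, 3) triangle vertices, ``points`` is (M, 3); entry i of
    the (M, 3) result is the field of triangle i at point i,

        F_i = (1/4pi) integral_{tri_i} (p_i - r') / |p_i - r'|^3 dA'.

    The closed form is the in-plane edge-log gradient plus the signed solid
    angle for the normal part.  When the point lies in the triangle's plane
    the solid angle vanishes and the result is the principal-value field
    (purely tangential), which is the on-surface limit used by collocation.

    Raises for points coinciding with a triangle vertex (non-integrable).
    """
    tri = np.asarray(tri, dtype=np.float64).reshape(-1, 3, 3)
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    n = np.cross(b - a, c - a)
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    acc = np.zeros_like(points)
    with np.errstate(divide="ignore", invalid="ignore"):
        for p, q in ((a, b), (b, c), (c, a)):
            t = q - p
            t = t / np.linalg.norm(t, axis=1, keepdims=True)
            sm = np.einsum("ij,ij->i", t, p - points)
            sp = np.einsum("ij,ij->i", t, q - points)
            Rm = np.linalg.norm(p - points, axis=1)
            Rp = np.linalg.norm(q - points, axis=1)
            if np.any(Rm == 0.0) or np.any(Rp == 0.0):
                raise ValueError("observation point coincides with a triangle vertex")
            # two algebraically equal forms; pick the numerically safe one
            edge_log = np.where(
                sp + Rp > Rm - sm,
                np.log((Rp + sp) / (Rm + sm)),
                np.log((Rm - sm) / (Rp - sp)),
            )
            acc += np.cross(t, n) * edge_log[:, None]
        # signed solid angle (van Oosterom & Strackee); the sign is such
        # that the normal field is +1/2 just off the +n side of the facet
        r1, r2, r3 = a - points, b - points, c - points
        R1 = np.linalg.norm(r1, axis=1)
        R2 = np.linalg.norm(r2, axis=1)
        R3 = np.linalg.norm(r3, axis=1)
        num = np.einsum("ij,ij->i", r1, np.cross(r2, r3))
        den = (
            R1 * R2 * R3
            + np.einsum("ij,ij->i", r1, r2) * R3
            + np.einsum("ij,ij->i", r2, r3) * R1
            + np.einsum("ij,ij->i", r3, r1) * R2
        )
        # principal value: an exactly in-plane point must see zero solid
        # angle even inside the triangle footprint (where den < 0 and
        # atan2 would jump to +-2 pi on float noise in the triple product)
        omega = 2.0 * np.arctan2(num, den)
        omega[np.abs(num) <= 1e-12 * R1 * R2 * R3] = 0.0
        acc -= n * omega[:, None]
    if not np.isfinite(acc).all():
        raise ValueError("singular triangle integral (point on a triangle edge?)")
    return acc * INV_4PI


def triangle_field_integral(triangle: np.ndarray, point: np.ndarray) -> np.ndarray:
    """Single-pair convenience wrapper around :func:`triangle_fields`."""
    return triangle_fields(
        np.asarray(triangle)[None, :, :], np.asarray(point)[None, :]
    )[0]


def weighted_monopole_field(
    src_centroids: np.ndarray, weights: np.ndarray, points: np.ndarray
) -> np.ndarray:
    """Field sum_n w_n (p - c_n)/(4 pi |p - c_n|^3) at each point, chunked."""
    points = np.atleast_2d(points)
    out = np.zeros_like(points)
    S = len(src_centroids)
    chunk = max(1, _CHUNK // max(S, 1))
    for s in range(0, len(points), chunk):
        p = points[s : s + chunk]
        d = p[:, None, :] - src_centroids[None, :, :]      # (T, S, 3)
        r2 = np.einsum("tsj,tsj->ts", d, d)
        r2[r2 == 0.0] = np.inf  # coincident source contributes nothing
        w = weights / (r2 * np.sqrt(r2))
        out[s : s + chunk] = INV_4PI * np.einsum("tsj,ts->tj", d, w)
    return out


# ---------------------------------------------------------------------------
# Near-pair search
# ---------------------------------------------------------------------------

def near_pairs(
    tgt_points: np.ndarray,
    src_centroids: np.ndarray,
    src_areas: np.ndarray,
    near_threshold: float,
    tgt_areas: np.ndarray | None = None,
):
    """(i, j) index pairs with |tgt_i - c_j| <= threshold * local facet size.

    The local size is sqrt(max(A_i, A_j)) when target areas are given,
    sqrt(A_j) otherwise.  Self pairs (zero distance) are included; callers
    exclude them as needed.
    """
    if not np.isfinite(near_threshold):
        ti, sj = np.meshgrid(
            np.arange(len(tgt_points)), np.arange(len(src_centroids)), indexing="ij"
        )
        return ti.ravel(), sj.ravel()
    hmax = near_threshold * np.sqrt(src_areas.max())
    if tgt_areas is not None:
        hmax = max(hmax, near_threshold * np.sqrt(tgt_areas.max()))
    tree = cKDTree(src_centroids)
    neighbors = tree.query_ball_point(tgt_points, r=hmax)
    ti = np.concatenate(
        [np.full(len(js), i, dtype=np.int64) for i, js in enumerate(neighbors)]
        or [np.empty(0, dtype=np.int64)]
    )
    sj = np.concatenate(
        [np.asarray(js, dtype=np.int64) for js in neighbors]
        or [np.empty(0, dtype=np.int64)]
    )
    if ti.size == 0:
        return ti, sj
    size2 = src_areas[sj]
    if tgt_areas is not None:
        size2 = np.maximum(size2, tgt_areas[ti])
    d = np.linalg.norm(tgt_points[ti] - src_centroids[sj], axis=1)
    keep = d <= near_threshold * np.sqrt(size2)
    return ti[keep], sj[keep]


# ---------------------------------------------------------------------------
# System operator, right-hand side, solution containers
# ---------------------------------------------------------------------------

@dataclass
class RightHandSide:
    """Collocation right-hand side b_m = K_m n_m . E_p(c_m), units V/m."""

    values: np.ndarray
    coil_tag: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite right-hand side")


@dataclass
class ChargeSolution:
    """Per-facet scaled surface charge density rho* = rho/eps0 (V/m)."""

    rho_star: np.ndarray
    residual: float
    solver_tag: str
    coil_tag: str = ""

    def __post_init__(self) -> None:
        self.rho_star = np.asarray(self.rho_star, dtype=np.float64).ravel()


@dataclass
class SystemOperator:
    """The discretized second-kind operator A, dense or matrix-free.

    In dense mode ``dense_matrix`` holds the full N x N coefficients.  In
    matrix-free mode the monopole far field is summed directly by a
    compiled kernel and a sparse correction replaces near-pair monopole
    entries with the analytic triangle integrals; the matrix is never
    stored.  Both modes implement the same linear map.
    """

    model: HeadModel
    near_threshold: float
    mode: str                                 # "dense" | "matrix-free"
    dense_matrix: np.ndarray | None = None
    _mf_data: dict = field(default_factory=dict, repr=False)

    @property
    def n(self) -> int:
        return self.model.total_facets

    @property
    def shape(self):
        return (self.n, self.n)

    def apply(self, x: np.ndarray) -> np.ndarray:
        return apply_operator(self, x)

    def as_linear_operator(self) -> LinearOperator:
        return LinearOperator(self.shape, matvec=self.apply, dtype=np.float64)


def assemble_rhs(
    model: HeadModel, coil, check_coil_placement: bool = True
) -> RightHandSide:
    """Project the coil's primary field onto the collocation points.

    Any object with a ``primary_field(points) -> (N, 3)`` method serves as
    the excitation.  A coil element found inside the outermost surface
    triggers a warning (physically dubious) but not an error.
    """
    if check_coil_placement and hasattr(coil, "elements"):
        _warn_if_inside(model, coil.elements)
    ep = coil.primary_field(model.centroids)
    b = model.contrasts * np.einsum("ij,ij->i", model.normals, ep)
    return RightHandSide(b, coil_tag=getattr(coil, "tag", ""))


def _warn_if_inside(model: HeadModel, points: np.ndarray) -> None:
    if bool(np.any(model.interfaces[0].surface.contains(points))):
        warnings.warn(
            "coil elements lie inside the outermost surface "
            "(physically dubious placement)",
            stacklevel=3,
        )


def _near_entries(model, ti, sj):
    """Outer-averaged analytic interaction (1/A_i) int_{t_i} n_i . F_j dA.

    The source-facet field F_j is the closed-form triangle integral; the
    outer average over the target facet uses the 7-point degree-5 rule.
    Quadrature points are strictly interior to the target facet, so they
    never touch a source-facet edge even for edge-adjacent pairs.
    """
    tris = model.all_triangles()
    nrm = model.normals[ti]
    vals = np.zeros(len(ti))
    chunk = 100_000
    for s in range(0, len(ti), chunk):
        tc, sc = ti[s : s + chunk], sj[s : s + chunk]
        src = tris[sc]
        acc = np.zeros(len(tc))
        for q, wq in zip(TRI_QUAD_BARY, TRI_QUAD_W):
            pts = np.einsum("k,nkj->nj", q, tris[tc])
            acc += wq * np.einsum(
                "ij,ij->i", nrm[s : s + chunk], triangle_fields(src, pts)
            )
        vals[s : s + chunk] = acc
    return vals


def assemble_dense(
    model: HeadModel,
    near_threshold: float = DEFAULT_NEAR_THRESHOLD,
    cap: int = DENSE_CAP_DEFAULT,
) -> SystemOperator:
    """Assemble the full N x N collocation matrix.

    Off-diagonal entries use the analytic triangle integral for near pairs
    and the centroid monopole for far pairs; with ``near_threshold=inf``
    every entry is analytic.  The diagonal is exactly 1/2.
    """
    N = model.total_facets
    if N > cap:
        raise CapacityError(
            f"{N} facets exceeds the dense cap ({cap}); use assemble_matrix_free"
        )
    cent, nrm, areas, K = model.centroids, model.normals, model.areas, model.contrasts
    G = np.zeros((N, N))
    chunk = max(1, _CHUNK // N)
    for s in range(0, N, chunk):
        p = cent[s : s + chunk]
        d = p[:, None, :] - cent[None, :, :]
        r2 = np.einsum("tsj,tsj->ts", d, d)
        np.fill_diagonal(r2[:, s : s + chunk], np.inf)
        G[s : s + chunk] = (
            INV_4PI
            * areas
            * np.einsum("tsj,tj->ts", d, nrm[s : s + chunk])
            / (r2 * np.sqrt(r2))
        )
    ti, sj = near_pairs(cent, cent, areas, near_threshold, tgt_areas=areas)
    off = ti != sj
    ti, sj = ti[off], sj[off]
    if ti.size:
        G[ti, sj] = _near_entries(model, ti, sj)
    A = -K[:, None] * G
    np.fill_diagonal(A, 0.5)
    return SystemOperator(model, near_threshold, "dense", dense_matrix=A)


def assemble_matrix_free(
    model: HeadModel, near_threshold: float = DEFAULT_NEAR_THRESHOLD
) -> SystemOperator:
    """Build the matrix-free operator: compiled monopole sum + near correction.

    The sparse correction holds, for each near pair (m, n), the difference
    between the analytic entry and the monopole entry already included in
    the direct sum, scaled by -K_m.  Applying the operator is then one
    direct N^2 monopole pass plus one sparse matvec.
    """
    cent, nrm, areas, K = model.centroids, model.normals, model.areas, model.contrasts
    ti, sj = near_pairs(cent, cent, areas, near_threshold, tgt_areas=areas)
    off = ti != sj
    ti, sj = ti[off], sj[off]
    d = cent[ti] - cent[sj]
    r2 = np.einsum("ij,ij->i", d, d)
    mono = INV_4PI * areas[sj] * np.einsum("ij,ij->i", d, nrm[ti]) / (r2 * np.sqrt(r2))
    ana = _near_entries(model, ti, sj)
    corr = sparse.csr_matrix(
        (-K[ti] * (ana - mono), (ti, sj)), shape=(model.total_facets,) * 2
    )
    mf = {
        "cx": np.ascontiguousarray(cent[:, 0]),
        "cy": np.ascontiguousarray(cent[:, 1]),
        "cz": np.ascontiguousarray(cent[:, 2]),
        "nx": np.ascontiguousarray(nrm[:, 0]),
        "ny": np.ascontiguousarray(nrm[:, 1]),
        "nz": np.ascontiguousarray(nrm[:, 2]),
        "area": areas,
        "K": K,
        "correction": corr,
    }
    return SystemOperator(model, near_threshold, "matrix-free", _mf_data=mf)


def apply_operator(op: SystemOperator, x: np.ndarray) -> np.ndarray:
    """Matrix-vector product A @ x in either mode."""
    x = np.asarray(x, dtype=np.float64).ravel()
    if x.shape[0] != op.n:
        raise ValueError(f"vector length {x.shape[0]} != system size {op.n}")
    if op.mode == "dense":
        return op.dense_matrix @ x
    mf = op._mf_data
    y = np.empty_like(x)
    _monopole_normal_matvec(
        mf["cx"], mf["cy"], mf["cz"], mf["nx"], mf["ny"], mf["nz"],
        mf["area"], mf["K"], x, y,
    )
    return y + mf["correction"] @ x


def charge_imbalance(model: HeadModel, solution: ChargeSolution) -> np.ndarray:
    """Relative net charge per interface, |sum A rho*| / sum A |rho*|.

    For a solenoidal (closed-loop coil) excitation each closed interface
    carries zero net induced charge; this diagnostic should be tiny.
    """
    out = []
    for sl, itf in zip(model.interface_slices(), model.interfaces):
        a = itf.surface.areas
        r = solution.rho_star[sl]
        denom = float(np.sum(a * np.abs(r)))
        out.append(abs(float(np.sum(a * r))) / denom if denom > 0 else 0.0)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Compiled direct-summation kernel (the desk-scale stand-in for an
# accelerated far-field backend; the contract is a plain matvec)
# ---------------------------------------------------------------------------

try:
    import numba

    @numba.njit(cache=True, fastmath=True)
    def _monopole_normal_matvec(cx, cy, cz, nxa, nya, nza, area, K, x, y):
        N = cx.shape[0]
        inv4pi = 1.0 / (4.0 * np.pi)
        for m in range(N):
            px, py, pz = cx[m], cy[m], cz[m]
            nx, ny, nz = nxa[m], nya[m], nza[m]
            acc = 0.0
            for n in range(N):
                dx = px - cx[n]
                dy = py - cy[n]
                dz = pz - cz[n]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 > 0.0:
                    acc += (
                        area[n] * x[n] * (dx * nx + dy * ny + dz * nz)
                        / (r2 * np.sqrt(r2))
                    )
            y[m] = 0.5 * x[m] - K[m] * inv4pi * acc

except ImportError:  # pragma: no cover - numba is a hard dependency

    def _monopole_normal_matvec(cx, cy, cz, nxa, nya, nza, area, K, x, y):
        cent = np.stack([cx, cy, cz], axis=1)
        nrm = np.stack([nxa, nya, nza], axis=1)
        f = weighted_monopole_field(cent, area * x, cent)
        y[:] = 0.5 * x - K * np.einsum("ij,ij->i", nrm, f)
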