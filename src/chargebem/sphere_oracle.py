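"""Multilayer concentric-sphere models with analytic and self-consistency oracles.

Spherically symmetric volume conductors admit several exact statements that
make them ideal verification targets for the charge-based solver without
any external head data:

* A single conducting sphere in air under a *uniform conservative* applied
  field E0 z develops the surface charge rho* = 3 E0 cos(theta) and a
  vanishing total interior field (the insulating boundary forces all
  current to stop).
* Under a genuinely *inductive* excitation (any closed-loop coil), the
  total interior E-field of a spherically symmetric conductor is
  independent of the radial conductivity profile, and its radial component
  vanishes.  Solvers that confuse conservative with inductive excitation
  fail one of the two regimes.
* A uniformly refined (1:4 per step, sphere-projected) model solved at
  tight tolerance serves as the self-convergence ground truth for
  default-resolution accuracy studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bem_operator import (
    assemble_dense,
    assemble_matrix_free,
    assemble_rhs,
    ChargeSolution,
)
from .field_eval import FieldResult, field_off_surface
from .mesh_model import HeadModel, Interface, make_icosphere, subdivide_1to4
from .metrics import ErrorReport, error_report
from .solver import solve_iterative

__all__ = [
    "default_three_layer_case",
    "SphereSpec",
    "UniformFieldCoil",
    "AnalyticUniformSphere",
    "fibonacci_sphere",
    "make_sphere_model",
    "analytic_uniform_field_case",
    "profile_independence_check",
    "refined_ground_truth",
    "solve_model",
]

#: default mesh level: 3 icosahedron subdivisions = 1280 facets per surface
DEFAULT_SUBDIVISIONS = 3

#: probe shell radius as a fraction of the innermost sphere radius, far
#: enough inside that near-surface evaluation error cannot contaminate
#: oracle comparisons
PROBE_SHELL_FRACTION = 0.8

DEFAULT_N_PROBES = 1000

#: dense assembly + factorization are preferred up to this many facets
DENSE_PREFERRED_MAX = 8000


def default_three_layer_case(
    subdivisions: int = DEFAULT_SUBDIVISIONS,
    n_probes: int = DEFAULT_N_PROBES,
    coil_standoff: float = 0.005,
):
    """Reference synthetic study: three-layer sphere head plus figure-8 coil.

    Radii 90/85/80 mm with conductivities 0.33/0.01/0.33 S/m (scalp-like /
    skull-like / brain-like shells), a 70 mm figure-8 coil with 64 segments
    per loop placed ``coil_standoff`` above the top of the outer sphere,
    tangential coil plane, dI/dt = 9.4e7 A/s.  Returns
    ``(model, probes, coil)`` with the probe shell inside the innermost
    sphere.
    """
    from .coil import make_figure8, transform_coil

    spec = SphereSpec([0.09, 0.085, 0.08], [0.33, 0.01, 0.33], subdivisions)
    model, probes = make_sphere_model(spec, n_probes=n_probes)
    coil = transform_coil(
        make_figure8(), np.eye(3), [0.0, 0.0, spec.radii[0] + coil_standoff]
    )
    return model, probes, coil


@dataclass
class SphereSpec:
    """Concentric spheres: strictly decreasing radii (m) and per-shell
    conductivities (S/m), outermost shell first / innermost ball last.
    Outside the outermost sphere is air (conductivity 0)."""

    radii: list
    conductivities: list
    subdivisions: int = DEFAULT_SUBDIVISIONS
    center: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.radii = [float(r) for r in self.radii]
        self.conductivities = [float(s) for s in self.conductivities]
        if len(self.radii) != len(self.conductivities):
            raise ValueError("need one conductivity per sphere")
        if any(r <= 0 for r in self.radii):
            raise ValueError("radii must be positive")
        if any(b >= a for a, b in zip(self.radii, self.radii[1:])):
            raise ValueError("radii must be strictly decreasing (outermost first)")
        if any(s < 0 for s in self.conductivities):
            raise ValueError("conductivities must be non-negative")


class UniformFieldCoil:
    """Synthetic excitation whose 'primary field' is a constant vector.

    Nonphysical (a uniform conservative field is not inducible by any real
    coil) but exact, which makes it the right driver for the closed-form
    uniform-field sphere oracle.
    """

    def __init__(self, e0):
        self.e0 = np.asarray(e0, dtype=np.float64)
        if self.e0.shape != (3,):
            raise ValueError("e0 must be a 3-vector")
        self.tag = "uniform-field"

    def primary_field(self, points) -> np.ndarray:
        points = np.atleast_2d(points)
        return np.broadcast_to(self.e0, (len(points), 3)).copy()


def fibonacci_sphere(n: int, radius: float, center=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Nearly uniform deterministic point distribution on a sphere."""
    i = np.arange(n, dtype=np.float64)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = 2.0 * np.pi * i / golden
    s = np.sqrt(1.0 - z * z)
    pts = np.stack([s * np.cos(phi), s * np.sin(phi), z], axis=1)
    return pts * radius + np.asarray(center, dtype=np.float64)


def make_sphere_model(
    spec: SphereSpec, n_probes: int = DEFAULT_N_PROBES
) -> tuple[HeadModel, np.ndarray]:
    """Concentric icosphere model plus an interior probe shell.

    Interface k carries sigma_in = conductivity of the shell it encloses
    and sigma_out = conductivity of the enclosing shell (air outside the
    outermost).  Probe points sit on a sphere at
    ``PROBE_SHELL_FRACTION`` x innermost radius.
    """
    interfaces = []
    for k, (r, sig) in enumerate(zip(spec.radii, spec.conductivities)):
        sigma_out = 0.0 if k == 0 else spec.conductivities[k - 1]
        interfaces.append(
            Interface(
                make_icosphere(r, spec.subdivisions, spec.center),
                sig,
                sigma_out,
                name=f"sphere_r{r:g}",
                projection=(spec.center, r),
            )
        )
    model = HeadModel(interfaces)
    probes = fibonacci_sphere(
        n_probes, PROBE_SHELL_FRACTION * spec.radii[-1], spec.center
    )
    return model, probes


@dataclass
class AnalyticUniformSphere:
    """Closed-form solution for a conducting sphere in air under a uniform
    conservative applied field: rho* = 3 (E0 . r_hat), interior E = 0."""

    radius: float
    e0: np.ndarray
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def rho_star(self, points: np.ndarray) -> np.ndarray:
        """Scaled charge density at (near-)surface points: 3 E0 cos(theta)."""
        d = np.atleast_2d(points) - self.center
        rhat = d / np.linalg.norm(d, axis=1, keepdims=True)
        return 3.0 * rhat @ self.e0

    def interior_field(self, points: np.ndarray) -> np.ndarray:
        """Total field inside the sphere vanishes identically."""
        return np.zeros((len(np.atleast_2d(points)), 3))


def analytic_uniform_field_case(radius: float, e0) -> AnalyticUniformSphere:
    e0 = np.asarray(e0, dtype=np.float64)
    if e0.ndim == 0:  # magnitude given: take the field along z
        e0 = np.array([0.0, 0.0, float(e0)])
    return AnalyticUniformSphere(float(radius), e0)


def solve_model(
    model: HeadModel,
    coil,
    tol: float = 1e-8,
    x0: np.ndarray | None = None,
    max_iter: int = 300,
):
    """Assemble and GMRES-solve a model, dense below the preferred cap."""
    if model.total_facets <= DENSE_PREFERRED_MAX:
        op = assemble_dense(model)
    else:
        op = assemble_matrix_free(model)
    b = assemble_rhs(model, coil)
    return solve_iterative(op, b, tol=tol, max_iter=max_iter, x0=x0)


def profile_independence_check(
    spec_single: SphereSpec,
    spec_multi: SphereSpec,
    coil,
    tol: float = 1e-8,
    n_probes: int = DEFAULT_N_PROBES,
) -> ErrorReport:
    """Interior-field agreement between two radial conductivity profiles.

    Both models share the outer radius; under an inductive (closed-loop
    coil) excitation their interior total fields must agree up to
    discretization error, because the induced field in a spherically
    symmetric conductor does not depend on the radial profile.
    """
    if not np.isclose(spec_single.radii[0], spec_multi.radii[0]):
        raise ValueError("profiles must share the outer radius")
    r_probe = PROBE_SHELL_FRACTION * min(spec_single.radii[-1], spec_multi.radii[-1])
    probes = fibonacci_sphere(n_probes, r_probe, spec_single.center)
    fields = []
    for spec in (spec_single, spec_multi):
        model, _ = make_sphere_model(spec, n_probes=1)
        sol, _ = solve_model(model, coil, tol=tol)
        fields.append(field_off_surface(model, sol, coil, probes).e_total)
    return error_report(fields[0], fields[1], roi_tag="profile-independence")


def refine_model(model: HeadModel, levels: int = 1) -> HeadModel:
    """Uniform 1:4 refinement of every interface, re-projected onto the
    exact sphere wherever an interface carries projection metadata."""
    interfaces = []
    for itf in model.interfaces:
        surf = itf.surface
        for _ in range(levels):
            surf = subdivide_1to4(surf, project_to_sphere=itf.projection)
        interfaces.append(
            Interface(surf, itf.sigma_in, itf.sigma_out, itf.name, itf.projection)
        )
    return HeadModel(interfaces)


def prolong(model_coarse: HeadModel, rho: np.ndarray) -> np.ndarray:
    """Carry a per-facet charge density to the 1:4-refined mesh.

    Children of parent facet f occupy slots 4f..4f+3 within each interface,
    so the piecewise-constant density simply repeats.
    """
    parts = []
    for sl in model_coarse.interface_slices():
        parts.append(np.repeat(rho[sl], 4))
    return np.concatenate(parts)


def refined_ground_truth(
    model: HeadModel,
    coil,
    levels: int,
    points: np.ndarray,
    tol: float = 1e-8,
    intermediate_fields: bool = False,
):
    """Self-convergence ground truth: refine all interfaces, solve tightly.

    Refinement proceeds one 1:4 step at a time; each level's solve starts
    from the previous level's solution prolonged onto the finer mesh
    (nested iteration), which shortens the Krylov sweep without changing
    the converged answer (the stopping test is on the true relative
    residual).  Returns the total field at ``points`` tagged as ground
    truth; with ``intermediate_fields`` additionally returns the fields of
    every coarser level (index 0 = the unrefined model), the inputs of a
    refinement-convergence study.
    """
    if levels not in (1, 2):
        raise ValueError("levels must be 1 or 2")
    current = model
    sol, rep = solve_model(current, coil, tol=tol)
    coarse: list[FieldResult] = []
    for level in range(levels):
        if intermediate_fields:
            partial = field_off_surface(current, sol, coil, points)
            partial.provenance.update(
                {"levels": level, "n_facets": current.total_facets}
            )
            coarse.append(partial)
        finer = refine_model(current, 1)
        x0 = prolong(current, sol.rho_star)
        sol, rep = solve_model(finer, coil, tol=tol, x0=x0)
        current = finer
    result = field_off_surface(current, sol, coil, points)
    result.provenance.update(
        {
            "ground_truth": True,
            "levels": levels,
            "n_facets": current.total_facets,
            "iterations": rep.iterations,
            "residual": rep.residual,
        }
    )
    if intermediate_fields:
        return result, coarse
    return result
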