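"""TMS coil models as elementary current elements.

A coil is a cloud of straight current elements: positions r_j and moments
m_j (direction x segment length x winding weight, in meters).  Under the
quasistatic approximation the coil's primary electric field is the time
derivative of its magnetostatic vector potential,

    E_p(r) = -(mu0 / 4 pi) * dI/dt * sum_j m_j / |r - r_j|,

so the field scales linearly with the current ramp rate dI/dt (A/s).
Any physical winding (circular loops, figure-8 pairs, multi-turn spirals,
skin-effect-resolved distributions) is encoded purely through the element
list; generators for canonical synthetic coils are provided below.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Coil",
    "primary_field",
    "make_loop",
    "make_figure8",
    "transform_coil",
    "read_coil_file",
    "write_coil_file",
]

MU0_OVER_4PI = 1e-7  # exactly, in SI (H/m / (4 pi))

#: default current ramp rate, A/s, a typical TMS pulse drive
DEFAULT_DIDT = 9.4e7

_POINT_CLEARANCE = 1e-9  # m, minimum element-to-observation distance


@dataclass
class Coil:
    """Current-element coil with a drive rate.

    ``elements`` is (J, 3) positions in meters, ``moments`` is (J, 3)
    direction-times-length vectors (winding weight folded in).
    """

    elements: np.ndarray
    moments: np.ndarray
    didt: float = DEFAULT_DIDT

    def __post_init__(self) -> None:
        self.elements = np.atleast_2d(np.asarray(self.elements, dtype=np.float64))
        self.moments = np.atleast_2d(np.asarray(self.moments, dtype=np.float64))
        if self.elements.shape != self.moments.shape or self.elements.shape[1] != 3:
            raise ValueError("elements and moments must both be (J, 3)")
        if not np.isfinite(self.elements).all() or not np.isfinite(self.moments).all():
            raise ValueError("non-finite coil element data")
        if not np.isfinite(self.didt):
            raise ValueError("didt must be finite")
        zero = np.linalg.norm(self.moments, axis=1) == 0.0
        if zero.any():
            raise ValueError(
                f"zero-moment elements at indices {np.where(zero)[0].tolist()}"
            )

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def moment_sum(self) -> np.ndarray:
        """Vector sum of moments; zero for closed current loops (Kirchhoff)."""
        return self.moments.sum(axis=0)

    def primary_field(self, points: np.ndarray) -> np.ndarray:
        return primary_field(self, points)


def primary_field(coil: Coil, points: np.ndarray) -> np.ndarray:
    """Primary electric field E_p (V/m) of the coil at the given points.

    Direct summation over elements; chunked over observation points so the
    pairwise distance block stays small.  Raises if an observation point
    coincides with an element position.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    out = np.zeros_like(points)
    scale = -MU0_OVER_4PI * coil.didt
    chunk = max(1, int(4e6 // max(coil.n_elements, 1)))
    for s in range(0, len(points), chunk):
        p = points[s : s + chunk]
        d = np.linalg.norm(p[:, None, :] - coil.elements[None, :, :], axis=2)
        if np.any(d < _POINT_CLEARANCE):
            i, j = np.argwhere(d < _POINT_CLEARANCE)[0]
            raise ValueError(
                f"observation point {p[i]} coincides with coil element {j}"
            )
        out[s : s + chunk] = scale * ((1.0 / d) @ coil.moments)
    return out


# ---------------------------------------------------------------------------
# Synthetic coil generators
# ---------------------------------------------------------------------------

def make_loop(
    radius: float,
    center=(0.0, 0.0, 0.0),
    turns: int = 1,
    segments: int = 64,
    sense: int = +1,
    didt: float = DEFAULT_DIDT,
) -> Coil:
    """Planar circular loop in the xy-plane discretized into straight elements.

    ``sense`` +1 winds counter-clockwise seen from +z.  The number of turns
    multiplies the element moments (the winding weight).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if segments < 8:
        raise ValueError("need at least 8 segments per loop")
    ang = np.linspace(0.0, 2.0 * np.pi, segments + 1)[:-1]
    if sense < 0:
        ang = ang[::-1]
    pts = np.stack(
        [radius * np.cos(ang), radius * np.sin(ang), np.zeros_like(ang)], axis=1
    ) + np.asarray(center, dtype=np.float64)
    nxt = np.roll(pts, -1, axis=0)
    positions = 0.5 * (pts + nxt)
    moments = (nxt - pts) * float(turns)
    return Coil(positions, moments, didt)


def make_figure8(
    radius: float = 0.035,
    turns: int = 1,
    segments_per_turn: int = 64,
    separation: float = 0.07,
    didt: float = DEFAULT_DIDT,
) -> Coil:
    """Figure-8 coil: two coplanar loops of opposite winding sense.

    Loop centers sit at (+-separation/2, 0, 0) in the coil's canonical frame
    (coil plane = xy, coil axis = z).  Defaults approximate a 70 mm
    figure-8 stimulation coil.  The currents of the two wings reinforce at
    the midpoint, the usual TMS focality argument.
    """
    left = make_loop(
        radius, (-separation / 2.0, 0.0, 0.0), turns, segments_per_turn, +1, didt
    )
    right = make_loop(
        radius, (+separation / 2.0, 0.0, 0.0), turns, segments_per_turn, -1, didt
    )
    return Coil(
        np.vstack([left.elements, right.elements]),
        np.vstack([left.moments, right.moments]),
        didt,
    )


def transform_coil(coil: Coil, rotation, translation=(0.0, 0.0, 0.0)) -> Coil:
    """Rigidly move a coil: positions rotated then translated, moments rotated."""
    R = np.asarray(rotation, dtype=np.float64)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-12):
        raise ValueError("rotation must be a 3x3 orthonormal matrix")
    t = np.asarray(translation, dtype=np.float64)
    return Coil(coil.elements @ R.T + t, coil.moments @ R.T, coil.didt)


# ---------------------------------------------------------------------------
# Coil files: whitespace-delimited text, one element per line
# ---------------------------------------------------------------------------

_HEADER_PREFIX = "# chargebem coil"


def write_coil_file(coil: Coil, path) -> None:
    """Write ``x y z mx my mz`` per line (meters), with a header line."""
    lines = [f"{_HEADER_PREFIX} units=m elements={coil.n_elements} didt={coil.didt!r}"]
    for p, m in zip(coil.elements, coil.moments):
        lines.append(
            f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g} {m[0]:.17g} {m[1]:.17g} {m[2]:.17g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_coil_file(path, didt: float | None = None) -> Coil:
    """Read the text coil format written by :func:`write_coil_file`.

    ``didt`` overrides the header drive rate when given.
    """
    path = Path(path)
    text = path.read_text().strip().splitlines()
    if not text:
        raise ValueError(f"{path}: empty coil file")
    header_didt = DEFAULT_DIDT
    rows = []
    for lineno, line in enumerate(text, start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tok in line.split():
                if tok.startswith("didt="):
                    header_didt = float(tok[5:])
            continue
        parts = line.split()
        if len(parts) != 6:
            raise ValueError(
                f"{path}:{lineno}: expected 6 columns (x y z mx my mz), "
                f"got {len(parts)}"
            )
        try:
            rows.append([float(v) for v in parts])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric field") from exc
    if not rows:
        raise ValueError(f"{path}: no coil elements")
    arr = np.asarray(rows, dtype=np.float64)
    return Coil(arr[:, :3], arr[:, 3:], didt if didt is not None else header_didt)
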