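"""Relative field-error metrics and region-of-interest selection.

Two scalar errors compare a test field against a reference over a set of
observation points:

    Error_total = || E - E_ref ||_2 / || E_ref ||_2        (vector error)
    Error_mag   = || |E| - |E_ref| ||_2 / || |E_ref| ||_2  (magnitude error)

where the 2-norm stacks all points (and, for the vector error, all
components).  By the reverse triangle inequality applied per point,
Error_mag <= Error_total always.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ErrorReport", "error_total", "error_mag", "error_report", "roi_select"]


@dataclass
class ErrorReport:
    error_total: float
    error_mag: float
    n_points: int
    roi_tag: str = ""

    def as_dict(self) -> dict:
        return {
            "error_total": self.error_total,
            "error_mag": self.error_mag,
            "n_points": self.n_points,
            "roi": self.roi_tag,
        }


def _check(E_test: np.ndarray, E_ref: np.ndarray):
    E_test = np.atleast_2d(np.asarray(E_test, dtype=np.float64))
    E_ref = np.atleast_2d(np.asarray(E_ref, dtype=np.float64))
    if E_test.shape != E_ref.shape or len(E_test) == 0:
        raise ValueError("field arrays must be equal nonempty shapes")
    return E_test, E_ref


def error_total(E_test: np.ndarray, E_ref: np.ndarray) -> float:
    """Relative 2-norm error of the vector field (reference in denominator)."""
    E_test, E_ref = _check(E_test, E_ref)
    denom = np.linalg.norm(E_ref)
    if denom == 0.0:
        raise ValueError("reference field has zero norm")
    return float(np.linalg.norm(E_test - E_ref) / denom)


def error_mag(E_test: np.ndarray, E_ref: np.ndarray) -> float:
    """Relative 2-norm error of the field magnitudes."""
    E_test, E_ref = _check(E_test, E_ref)
    mt = np.linalg.norm(E_test, axis=1)
    mr = np.linalg.norm(E_ref, axis=1)
    denom = np.linalg.norm(mr)
    if denom == 0.0:
        raise ValueError("reference field has zero norm")
    return float(np.linalg.norm(mt - mr) / denom)


def error_report(E_test, E_ref, roi_tag: str = "") -> ErrorReport:
    E_test, E_ref = _check(E_test, E_ref)
    return ErrorReport(
        error_total(E_test, E_ref), error_mag(E_test, E_ref), len(E_test), roi_tag
    )


def roi_select(points: np.ndarray, center, diameter: float) -> np.ndarray:
    """Indices of points inside (boundary-inclusive) a sphere of given diameter."""
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    d = np.linalg.norm(points - np.asarray(center, dtype=np.float64), axis=1)
    return np.where(d <= diameter / 2.0)[0]
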