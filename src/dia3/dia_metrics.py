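"""Diffusion Anisotropy (DiA), average diffusivity, and orientation color code.

DiA measures the distance from a diffusivity profile D(u) on the sphere to
its isotropic equivalent:

    DiA = 1 - [∫ D(u) du]² / (4π ∫ D²(u) du)          (definition)
        = 1 - C00²{D} / (sqrt(4π) · C00{D²})          (SH implementation)

Three estimators are provided:

* ``dia_simplified`` — the closed form for 3 orthogonal samples,
  DiA = 1 - (Dx+Dy+Dz)² / (3(Dx²+Dy²+Dz²)); it is also what the SH
  estimator reduces to at order 0.
* ``dia_sh`` — fits D and D² separately in the real even SH basis (same
  order and Laplace–Beltrami λ) and applies the C0,0 formula.
* ``dia_quadrature`` — dense spherical quadrature of the defining
  integrals, the ground-truth oracle.

DiA is scale invariant, lies in [0, 1), and the order-0 / N-sample
estimator is bounded by 1 - 1/N (2/3 for the 3-direction acquisition).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .spherical_harmonics import (
    DEFAULT_LAMBDA_LB,
    SQRT4PI,
    fit_matrix,
    order_for_samples,
)

__all__ = [
    "average_diffusivity",
    "dia_simplified",
    "dia_sh",
    "dia_quadrature",
    "dia_closed_form",
    "color_code",
    "sphere_quadrature",
    "DiAResult",
]


@dataclass
class DiAResult:
    """A DiA map/value with provenance of the estimator used."""

    dia: np.ndarray | float
    estimator: str
    n_directions: int


def average_diffusivity(Dx, Dy, Dz):
    """Average diffusivity DAV = (Dx + Dy + Dz)/3 (an MD surrogate)."""
    return (np.asarray(Dx, float) + np.asarray(Dy, float) + np.asarray(Dz, float)) / 3.0


def _check_nonnegative(*arrays) -> None:
    for a in arrays:
        if np.any(np.asarray(a) < 0):
            raise ValueError("diffusivity samples must be nonnegative")


def dia_simplified(Dx, Dy, Dz):
    """3-orthogonal-direction DiA: 1 - (ΣD)² / (3 ΣD²).

    Background voxels (all three samples zero) are defined as 0, so they
    render black.  Inputs must be nonnegative (upstream clamping
    guarantees this for real data).
    """
    Dx, Dy, Dz = (np.asarray(a, dtype=float) for a in (Dx, Dy, Dz))
    _check_nonnegative(Dx, Dy, Dz)
    # algebraically identical to 1 - (ΣD)²/(3ΣD²) but exactly 0 for equal
    # samples and nonnegative by construction
    num = (Dx - Dy) ** 2 + (Dy - Dz) ** 2 + (Dx - Dz) ** 2
    den = 3.0 * (Dx**2 + Dy**2 + Dz**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        dia = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    dia = np.clip(dia, 0.0, 2.0 / 3.0)
    return float(dia) if dia.ndim == 0 else dia


def dia_sh(
    samples: np.ndarray,
    directions: np.ndarray,
    lambda_lb: float = DEFAULT_LAMBDA_LB,
    order: int | None = None,
) -> np.ndarray | float:
    """SH-based DiA from N ≥ 3 diffusivity samples.

    Fits D and D² separately (same order and λ) and returns
    1 - C00²{D} / (sqrt(4π) · C00{D²}).  ``samples`` may be (..., N) for
    whole volumes; ``order=None`` applies the N-samples rule, so with 3
    orthogonal axis samples this reproduces :func:`dia_simplified` to
    float precision.
    """
    samples = np.asarray(samples, dtype=float)
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    if len(directions) < 3:
        raise ValueError(
            f"DiA needs at least 3 directions, got {len(directions)}"
        )
    if samples.shape[-1] != len(directions):
        raise ValueError(
            f"{samples.shape[-1]} samples vs {len(directions)} directions"
        )
    _check_nonnegative(samples)
    if order is None:
        order = order_for_samples(len(directions))
    # c00 of a linear fit is a fixed linear functional of the samples
    row = fit_matrix(directions, order, lambda_lb)[0]
    c00_D = samples @ row
    c00_D2 = (samples**2) @ row
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            c00_D2 > 0, c00_D**2 / (SQRT4PI * np.where(c00_D2 > 0, c00_D2, 1.0)), 1.0
        )
    dia = np.clip(1.0 - ratio, 0.0, 1.0)
    return float(dia) if dia.ndim == 0 else dia


def sphere_quadrature(n_points: int = 2562) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic quadrature rule on the unit sphere.

    Gauss–Legendre nodes in the polar cosine crossed with a uniform
    azimuthal grid: exact for spherical polynomials up to high degree and
    rotation-robust.  Returns (points (M,3), weights (M,)) with
    Σ weights = 4π and M ≥ n_points.
    """
    if n_points < 500:
        raise ValueError("use at least 500 quadrature points")
    n_theta = int(np.ceil(np.sqrt(n_points / 2.0)))
    n_phi = 2 * n_theta
    mu, w_mu = np.polynomial.legendre.leggauss(n_theta)  # mu = cos(theta)
    phi = 2.0 * np.pi * np.arange(n_phi) / n_phi
    sin_theta = np.sqrt(1.0 - mu**2)
    x = np.outer(sin_theta, np.cos(phi)).ravel()
    y = np.outer(sin_theta, np.sin(phi)).ravel()
    z = np.repeat(mu, n_phi)
    points = np.column_stack([x, y, z])
    weights = np.repeat(w_mu, n_phi) * (2.0 * np.pi / n_phi)
    return points, weights


def dia_quadrature(
    adc_fn: Callable[[np.ndarray], np.ndarray], n_points: int = 2562
) -> float:
    """Ground-truth DiA by dense quadrature of the defining integrals.

    ``adc_fn`` maps an (M, 3) array of unit directions to M nonnegative
    diffusivities.
    """
    points, weights = sphere_quadrature(n_points)
    D = np.asarray(adc_fn(points), dtype=float)
    int_D = float(weights @ D)
    int_D2 = float(weights @ D**2)
    if int_D2 <= 0:
        return 0.0
    return float(1.0 - int_D**2 / (4.0 * np.pi * int_D2))


def dia_closed_form(tensor: np.ndarray) -> float:
    """Exact DiA of a diffusion-tensor profile D(u) = uᵀTu.

    From ∫uᵀTu du = (4π/3) tr T and ∫(uᵀTu)² du = (4π/15)[(tr T)² +
    2 tr(T²)]:  DiA = 1 - 5 (tr T)² / (3 [(tr T)² + 2 tr(T²)]).
    """
    T = np.asarray(tensor, dtype=float)
    tr = np.trace(T)
    tr2 = np.trace(T @ T)
    den = 3.0 * (tr**2 + 2.0 * tr2)
    if den == 0:
        return 0.0
    return float(1.0 - 5.0 * tr**2 / den)


def color_code(Dx, Dy, Dz, dia):
    """Orientation RGB code: channel_i = DiA · D_i / DAV, clipped to [0, 1].

    Red/green/blue map to the x/y/z image axes, luminance-weighted by DiA
    (isotropic voxels are black).  Voxels with DAV = 0 map to (0,0,0).
    Meaningful only when the three acquired gradients are orthogonal and
    axis-aligned; otherwise the hue must be read as orientation *relative
    to the acquired directions*.
    """
    Dx, Dy, Dz = (np.asarray(a, dtype=float) for a in (Dx, Dy, Dz))
    dia = np.asarray(dia, dtype=float)
    dav = average_diffusivity(Dx, Dy, Dz)
    with np.errstate(divide="ignore", invalid="ignore"):
        safe = np.where(dav > 0, dav, 1.0)
        rgb = np.stack(
            [dia * Dx / safe, dia * Dy / safe, dia * Dz / safe], axis=-1
        )
    rgb = np.where(dav[..., None] > 0, rgb, 0.0)
    return np.clip(rgb, 0.0, 1.0)
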