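"""Real even-order spherical harmonics: basis, penalized fit, C0,0.

Basis convention
----------------
Real, antipodally symmetric basis (even degrees l only), built from the
complex orthonormal harmonics Y_l^m:

    R_l^m = sqrt(2) * (-1)^m * Im(Y_l^|m|)   for m < 0
    R_l^0 = Y_l^0
    R_l^m = sqrt(2) * (-1)^m * Re(Y_l^m)     for m > 0

ordered (l, m) = (0,0), (2,-2) ... (2,2), (4,-4) ...  The basis is
orthonormal on the unit sphere, so R_0^0 = 1/sqrt(4π) and the coefficient
of a function H satisfies

    C0,0{H} = (1 / sqrt(4π)) ∫_S H(u) du,

i.e. the spherical mean of H is C0,0 / sqrt(4π).

Fitting minimizes ||B c - d||² + λ Σ l²(l+1)² c_lm²  (Laplace–Beltrami
penalty; the l = 0 term is unpenalized, so the spherical mean is never
shrunk).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import sph_harm_y

SQRT4PI = float(np.sqrt(4.0 * np.pi))

#: default Laplace–Beltrami penalty weight for signal fits.
DEFAULT_LAMBDA_LB = 0.006

#: default cap on the automatic order rule.
MAX_AUTO_ORDER = 8


def n_coefficients(order: int) -> int:
    """Number of real even-degree SH coefficients up to ``order``."""
    if order < 0 or order % 2:
        raise ValueError(f"SH order must be a nonnegative even integer, got {order}")
    return (order + 1) * (order + 2) // 2


def sh_degrees(order: int) -> np.ndarray:
    """Degree l of each coefficient in storage order."""
    ls = []
    for l in range(0, order + 1, 2):
        ls.extend([l] * (2 * l + 1))
    return np.asarray(ls, dtype=int)


def order_for_samples(n_samples: int, max_order: int = MAX_AUTO_ORDER) -> int:
    """Largest even order L with (L+1)(L+2)/2 ≤ n_samples (capped).

    N = 3..5 → 0, N = 6..14 → 2, N = 15..27 → 4, ...  With N = 3 the fit
    reduces to the arithmetic-mean (simplified) estimator; with N = 6 a
    diffusion tensor profile is captured exactly.
    """
    if n_samples < 1:
        raise ValueError("need at least one sample")
    L = 0
    while L + 2 <= max_order and n_coefficients(L + 2) <= n_samples:
        L += 2
    return L


@dataclass
class SHCoefficients:
    """Real even-order SH coefficient vector of a spherical function."""

    coeffs: np.ndarray
    order: int
    convention: str = "real-symmetric"

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape[-1] != n_coefficients(self.order):
            raise ValueError(
                f"expected {n_coefficients(self.order)} coefficients for "
                f"order {self.order}, got {self.coeffs.shape[-1]}"
            )

    @property
    def c00(self) -> np.ndarray | float:
        c = self.coeffs[..., 0]
        return float(c) if np.ndim(c) == 0 else c

    @property
    def spherical_mean(self) -> np.ndarray | float:
        return self.c00 / SQRT4PI


def _check_unit(directions: np.ndarray) -> np.ndarray:
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    if directions.shape[-1] != 3:
        raise ValueError(f"directions must be (N, 3), got {directions.shape}")
    norms = np.linalg.norm(directions, axis=-1)
    if np.any(np.abs(norms - 1.0) > 1e-4):
        raise ValueError("directions must be unit vectors (|norm - 1| ≤ 1e-4)")
    return directions


def sh_design_matrix(directions: np.ndarray, order: int) -> np.ndarray:
    """Evaluate the real even-degree SH basis at unit directions.

    Returns an (N, n_coefficients(order)) matrix whose row i is the basis
    at direction i.
    """
    directions = _check_unit(directions)
    n_coefficients(order)  # validates order
    x, y, z = directions.T
    theta = np.arccos(np.clip(z, -1.0, 1.0))  # polar angle
    phi = np.arctan2(y, x)
    cols = []
    for l in range(0, order + 1, 2):
        for m in range(-l, l + 1):
            if m < 0:
                Y = sph_harm_y(l, -m, theta, phi)
                cols.append(np.sqrt(2.0) * (-1.0) ** m * Y.imag)
            elif m == 0:
                cols.append(sph_harm_y(l, 0, theta, phi).real)
            else:
                Y = sph_harm_y(l, m, theta, phi)
                cols.append(np.sqrt(2.0) * (-1.0) ** m * Y.real)
    return np.stack(cols, axis=-1)


def laplace_beltrami_penalty(order: int) -> np.ndarray:
    """Diagonal penalty weights l²(l+1)² per coefficient."""
    l = sh_degrees(order)
    return (l * (l + 1)) ** 2


def fit_matrix(
    directions: np.ndarray, order: int, lambda_lb: float = DEFAULT_LAMBDA_LB
) -> np.ndarray:
    """Pseudo-inverse of the penalized normal equations.

    Returns M of shape (n_coeffs, N) with c = M @ d; precomputing it lets
    whole volumes be fitted with one matrix product.
    """
    B = sh_design_matrix(directions, order)
    P = np.diag(laplace_beltrami_penalty(order).astype(float))
    A = B.T @ B + lambda_lb * P
    if lambda_lb == 0:
        rank = np.linalg.matrix_rank(A)
        if rank < A.shape[0]:
            raise np.linalg.LinAlgError(
                f"unpenalized SH system is rank-deficient (rank {rank} < "
                f"{A.shape[0]}); use lambda_lb > 0 or a lower order"
            )
    return np.linalg.solve(A, B.T)


def fit_sh(
    values: np.ndarray,
    directions: np.ndarray,
    order: int | None = None,
    lambda_lb: float = DEFAULT_LAMBDA_LB,
) -> SHCoefficients:
    """Penalized least-squares SH fit of samples of a spherical function.

    ``values`` may be a vector (N,) or an array (..., N) of stacked
    problems sharing the directions.  ``order=None`` applies the
    N-samples rule of :func:`order_for_samples`.
    """
    values = np.asarray(values, dtype=float)
    directions = _check_unit(directions)
    if values.shape[-1] != len(directions):
        raise ValueError(
            f"{values.shape[-1]} values vs {len(directions)} directions"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if order is None:
        order = order_for_samples(len(directions))
    M = fit_matrix(directions, order, lambda_lb)
    coeffs = values @ M.T
    return SHCoefficients(coeffs=coeffs, order=order)


def resample(coeffs: SHCoefficients, directions: np.ndarray) -> np.ndarray:
    """Evaluate the fitted spherical function at new directions."""
    B = sh_design_matrix(directions, coeffs.order)
    return coeffs.coeffs @ B.T


def c00(coeffs: SHCoefficients) -> np.ndarray | float:
    """The 0-th order coefficient; spherical mean × sqrt(4π)."""
    return coeffs.c00
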