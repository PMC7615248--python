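"""Ground-truth diffusion tensors, rotations, direction sets and phantoms.

The simulator provides the controlled inputs for the numerical studies:
single diffusion tensors with prescribed eigenvalues (the reference tensor
has eigenvalues [1, 0.3, 0.3]×10⁻³ mm²/s, FA = 0.6444), two rotation
families (in-plane about the y axis, and a spatial rotation about the
(1,1,1)/√3 diagonal so no eigenvector stays aligned with any axis),
deterministic gradient-direction sets, and synthetic DWI phantoms with
optional Rician noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .io_grad import DWIVolume, GradientTable

__all__ = [
    "DiffusionTensor",
    "make_tensor",
    "rotation_matrix",
    "rotate_tensor",
    "tensor_adc",
    "tensor_fa",
    "SamplingScheme",
    "axes_scheme",
    "scheme_directions",
    "named_scheme",
    "fibonacci_directions",
    "repulsion_directions",
    "synthesize_phantom",
    "REFERENCE_EIGENVALUES",
]

#: eigenvalues of the reference simulation tensor (mm²/s).
REFERENCE_EIGENVALUES = (1.0e-3, 0.3e-3, 0.3e-3)

#: spatial-rotation axis (the corner diagonal), unit length.
SPATIAL_AXIS = np.array([1.0, 1.0, 1.0]) / np.sqrt(3.0)


@dataclass
class DiffusionTensor:
    """3×3 symmetric PSD tensor with its eigen-decomposition.

    ``eigenvalues`` are sorted descending λ1 ≥ λ2 ≥ λ3 with matching
    orthonormal ``eigenvectors`` columns.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if M.shape != (3, 3):
            raise ValueError(f"tensor must be 3x3, got {M.shape}")
        if not np.allclose(M, M.T, atol=1e-10):
            raise ValueError("tensor must be symmetric")
        self.matrix = 0.5 * (M + M.T)
        w, V = np.linalg.eigh(self.matrix)
        if w[0] < -1e-12 * max(1.0, abs(w[-1])):
            raise ValueError(f"tensor has negative eigenvalue {w[0]}")
        order = np.argsort(w)[::-1]
        self.eigenvalues = np.clip(w[order], 0.0, None)
        self.eigenvectors = V[:, order]

    def adc(self, u: np.ndarray) -> np.ndarray | float:
        return tensor_adc(self.matrix, u)


def make_tensor(
    eigenvalues, eigenvectors: np.ndarray | None = None
) -> DiffusionTensor:
    """Assemble VΛVᵀ from eigenvalues and (optional) orthonormal axes."""
    lam = np.asarray(eigenvalues, dtype=float).ravel()
    if lam.shape != (3,):
        raise ValueError("exactly 3 eigenvalues required")
    if np.any(lam < 0):
        raise ValueError("eigenvalues must be nonnegative")
    if eigenvectors is None:
        V = np.eye(3)
    else:
        V = np.asarray(eigenvectors, dtype=float)
        if V.shape != (3, 3) or not np.allclose(V.T @ V, np.eye(3), atol=1e-8):
            raise ValueError("eigenvectors must form an orthonormal 3x3 matrix")
    return DiffusionTensor(matrix=V @ np.diag(lam) @ V.T)


def rotation_matrix(scheme: str, theta: float) -> np.ndarray:
    """Rotation matrix of one of the two simulation schemes.

    ``plane``:   rotation about the y axis, so one tensor eigenvector stays
    in-plane aligned with an axis:
    [[cosθ, 0, sinθ], [0, 1, 0], [-sinθ, 0, cosθ]].

    ``spatial``: Rodrigues rotation about (1,1,1)/√3, so for generic θ no
    eigenvector is aligned with any axis; its diagonal is
    1/3 + (2/3)cosθ, and θ = 2π/3 is the cyclic coordinate permutation.
    """
    c, s = np.cos(theta), np.sin(theta)
    if scheme == "plane":
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    if scheme == "spatial":
        a = SPATIAL_AXIS
        K = np.array(
            [[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]]
        )
        return np.eye(3) * c + s * K + (1.0 - c) * np.outer(a, a)
    raise ValueError(f"unknown rotation scheme {scheme!r} (plane|spatial)")


def rotate_tensor(
    tensor: DiffusionTensor | np.ndarray, R: np.ndarray
) -> DiffusionTensor:
    """Conjugate the tensor: R T Rᵀ (eigenvalues preserved)."""
    T = tensor.matrix if isinstance(tensor, DiffusionTensor) else np.asarray(tensor)
    R = np.asarray(R, dtype=float)
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
        raise ValueError("R must be a proper rotation matrix")
    return DiffusionTensor(matrix=R @ T @ R.T)


def tensor_adc(tensor: np.ndarray, u: np.ndarray) -> np.ndarray | float:
    """Diffusivity along u under the tensor model: uᵀTu."""
    T = tensor.matrix if isinstance(tensor, DiffusionTensor) else np.asarray(tensor)
    u = np.asarray(u, dtype=float)
    single = u.ndim == 1
    u2 = np.atleast_2d(u)
    if np.any(np.abs(np.linalg.norm(u2, axis=-1) - 1.0) > 1e-4):
        raise ValueError("directions must be unit vectors")
    d = np.einsum("ni,ij,nj->n", u2, T, u2)
    return float(d[0]) if single else d


def tensor_fa(tensor: DiffusionTensor | np.ndarray) -> float:
    """Fractional anisotropy: sqrt(3/2)·‖λ − mean(λ)‖ / ‖λ‖."""
    if isinstance(tensor, DiffusionTensor):
        lam = tensor.eigenvalues
    else:
        lam = np.linalg.eigvalsh(np.asarray(tensor, dtype=float))
    norm = np.linalg.norm(lam)
    if norm == 0:
        raise ValueError("FA is undefined for the zero tensor")
    return float(np.sqrt(1.5) * np.linalg.norm(lam - lam.mean()) / norm)


# --------------------------------------------------------------------------
# Gradient-direction sets
# --------------------------------------------------------------------------

@dataclass
class SamplingScheme:
    """A named set of unit gradient directions."""

    name: str
    directions: np.ndarray

    def __post_init__(self) -> None:
        d = np.atleast_2d(np.asarray(self.directions, dtype=float))
        norms = np.linalg.norm(d, axis=1)
        if np.any(norms < 1e-12):
            raise ValueError("zero direction in sampling scheme")
        d = d / norms[:, None]
        dots = np.abs(d @ d.T)
        np.fill_diagonal(dots, 0.0)
        if np.any(dots > 1.0 - 1e-9):
            raise ValueError("duplicate or antipodal directions in scheme")
        self.directions = d

    @property
    def n(self) -> int:
        return len(self.directions)


def axes_scheme() -> SamplingScheme:
    """The Cartesian-axes triple used by fast clinical acquisitions."""
    return SamplingScheme(name="axes", directions=np.eye(3))


def fibonacci_directions(n: int) -> np.ndarray:
    """Near-uniform deterministic point set (spherical Fibonacci lattice)."""
    if n < 1:
        raise ValueError("n must be positive")
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(1.0 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def _antipodal_energy_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
    """Coulomb energy Σ_{i<j} 1/‖xi−xj‖ + 1/‖xi+xj‖ and its gradient."""
    diff = x[:, None, :] - x[None, :, :]
    summ = x[:, None, :] + x[None, :, :]
    dd = np.linalg.norm(diff, axis=-1)
    ds = np.linalg.norm(summ, axis=-1)
    np.fill_diagonal(dd, np.inf)
    np.fill_diagonal(ds, np.inf)
    energy = 0.5 * np.sum(1.0 / dd) + 0.5 * np.sum(1.0 / ds)
    grad = -(diff / dd[..., None] ** 3).sum(axis=1) - (
        summ / ds[..., None] ** 3
    ).sum(axis=1)
    return float(energy), grad


def repulsion_directions(n: int, n_iter: int = 2000) -> np.ndarray:
    """Electrostatic-repulsion optimized direction set (antipodally aware).

    Minimizes the antipodal Coulomb energy Σ_{i<j} 1/‖xi−xj‖ + 1/‖xi+xj‖
    by projected gradient descent with backtracking, starting from a
    deterministic Fibonacci initialization, so repeated calls give
    identical sets.
    """
    if n < 2:
        raise ValueError("need at least 2 directions")
    x = fibonacci_directions(n)
    step = 0.1 / n
    e, g = _antipodal_energy_grad(x)
    for _ in range(n_iter):
        # project the gradient onto the tangent planes of the sphere
        g_t = g - (np.sum(g * x, axis=1, keepdims=True)) * x
        x_new = x - step * g_t
        x_new /= np.linalg.norm(x_new, axis=1, keepdims=True)
        e_new, g_new = _antipodal_energy_grad(x_new)
        if e_new < e:
            x, e, g = x_new, e_new, g_new
            step *= 1.2
        else:
            step *= 0.5
            if step < 1e-14:
                break
    return x


_PHI = (1.0 + np.sqrt(5.0)) / 2.0

#: tetrahedral 4-direction set (optimal antipodal repulsion for n=4).
_DIRS4 = np.array(
    [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
) / np.sqrt(3.0)

#: icosahedral 6-direction set, the classic minimal DTI scheme.
_DIRS6 = np.array(
    [
        [1, _PHI, 0],
        [-1, _PHI, 0],
        [0, 1, _PHI],
        [0, -1, _PHI],
        [_PHI, 0, 1],
        [_PHI, 0, -1],
    ]
) / np.sqrt(1.0 + _PHI**2)


@lru_cache(maxsize=None)
def _cached_repulsion(n: int) -> tuple[tuple[float, float, float], ...]:
    return tuple(map(tuple, repulsion_directions(n)))


def scheme_directions(n: int) -> SamplingScheme:
    """Deterministic n-direction fixture.

    n = 3 → Cartesian axes; n = 4 → tetrahedral vertices; n = 6 →
    icosahedral vertices; n = 5 and n > 6 → electrostatic-repulsion
    optimized sets (deterministic, cached per n).
    """
    if n < 3:
        raise ValueError("schemes start at 3 directions")
    if n == 3:
        return axes_scheme()
    if n == 4:
        return SamplingScheme(name="tetrahedral4", directions=_DIRS4)
    if n == 5:
        return SamplingScheme(
            name="repulsion5", directions=np.asarray(_cached_repulsion(5))
        )
    if n == 6:
        return SamplingScheme(name="icosahedral6", directions=_DIRS6)
    return SamplingScheme(
        name=f"repulsion{n}", directions=np.asarray(_cached_repulsion(n))
    )


def named_scheme(spec: str) -> SamplingScheme:
    """Resolve a CLI scheme spec: ``axes`` or ``fixture:<n>``."""
    if spec == "axes":
        return axes_scheme()
    if spec.startswith("fixture:"):
        return scheme_directions(int(spec.split(":", 1)[1]))
    raise ValueError(f"unknown scheme spec {spec!r} (axes | fixture:<n>)")


# --------------------------------------------------------------------------
# Phantom synthesis
# --------------------------------------------------------------------------

def synthesize_phantom(
    tensors: np.ndarray | DiffusionTensor,
    scheme: SamplingScheme,
    b: float = 1000.0,
    S0: float = 1000.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    n_b0: int = 1,
    shape: tuple[int, int, int] | None = None,
    affine: np.ndarray | None = None,
) -> DWIVolume:
    """Simulate a single-shell DWI series from ground-truth tensors.

    ``tensors`` is either one :class:`DiffusionTensor` (replicated over
    ``shape``, default 1×1×1) or an array of per-voxel tensors with shape
    (X, Y, Z, 3, 3).  The noiseless signal is S0·exp(−b·uᵀTu) per voxel
    and direction, with ``n_b0`` baseline volumes prepended.  If
    ``noise_sigma > 0``, Rician noise is applied: the magnitude of the
    signal perturbed by two independent Gaussian channels of that standard
    deviation (seeded, so identical seeds give identical phantoms).
    """
    if b <= 0:
        raise ValueError("b must be positive")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be nonnegative")
    if isinstance(tensors, DiffusionTensor):
        grid = np.broadcast_to(
            tensors.matrix, tuple(shape or (1, 1, 1)) + (3, 3)
        )
    else:
        grid = np.asarray(tensors, dtype=float)
        if grid.ndim != 5 or grid.shape[-2:] != (3, 3):
            raise ValueError("tensor grid must have shape (X, Y, Z, 3, 3)")

    u = scheme.directions
    adc = np.einsum("xyzij,ni,nj->xyzn", grid, u, u)
    signal = S0 * np.exp(-b * adc)
    b0 = np.full(grid.shape[:3] + (n_b0,), float(S0))
    data = np.concatenate([b0, signal], axis=-1)

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        g1 = rng.normal(0.0, noise_sigma, size=data.shape)
        g2 = rng.normal(0.0, noise_sigma, size=data.shape)
        data = np.sqrt((data + g1) ** 2 + g2**2)

    table = GradientTable(
        bvals=np.concatenate([np.zeros(n_b0), np.full(scheme.n, float(b))]),
        bvecs=np.vstack([np.zeros((n_b0, 3)), u]),
    )
    if affine is None:
        affine = np.diag([2.0, 2.0, 2.0, 1.0])  # 2 mm isotropic voxels
    return DWIVolume(data=data, affine=affine, table=table)
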