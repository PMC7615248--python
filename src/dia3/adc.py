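"""Raw DWI → normalized signal → per-direction apparent diffusion coefficient.

The mono-exponential model ties the normalized signal to the diffusivity
along the applied gradient direction u:

    E(u) = S(u) / S0 = exp(-b · D(u)),   so   D(u) = -ln(E(u)) / b.

Noise can push S above S0; such voxels are clamped to E = 1 (D = 0), and
vanishing signals are clamped to a small positive floor so the log stays
finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .io_grad import DWIVolume

logger = logging.getLogger("dia3")

#: floor applied to the normalized signal before taking logs.
EPSILON_E = 1e-8

B0_POLICIES = ("mean", "median", "first")


@dataclass
class NormalizedSignal:
    """S/S0 per diffusion-weighted volume, with a foreground mask.

    ``E`` is 4-D with one entry per *non-b0* direction, clamped into
    (EPSILON_E, 1].  ``directions`` and ``b`` are carried along so the ADC
    step needs no second look at the gradient table.
    """

    E: np.ndarray
    mask: np.ndarray
    directions: np.ndarray
    b: float

    def __post_init__(self) -> None:
        if self.E.ndim != 4:
            raise ValueError("E must be 4-D")
        if self.E.shape[3] != len(self.directions):
            raise ValueError(
                f"{self.E.shape[3]} signal volumes vs "
                f"{len(self.directions)} directions"
            )


@dataclass
class ADCMap:
    """One diffusivity volume per gradient direction (mm²/s, ≥ 0)."""

    D: np.ndarray
    directions: np.ndarray
    b: float
    mask: np.ndarray


def normalize(
    dwi: DWIVolume,
    b0_policy: str = "mean",
    mask: np.ndarray | None = None,
    epsilon_E: float = EPSILON_E,
) -> NormalizedSignal:
    """Divide the DWIs by the baseline and clamp into (epsilon_E, 1].

    S0 is the mean / median / first of the b0 volumes depending on
    ``b0_policy``.  The foreground mask defaults to Otsu thresholding of
    S0; a user-supplied boolean mask overrides it.  Voxels with S0 = 0
    inside the requested mask are excluded (with a logged count).
    """
    table = dwi.table
    table.validate_for_dia()
    if b0_policy not in B0_POLICIES:
        raise ValueError(f"b0_policy must be one of {B0_POLICIES}")

    data = np.asarray(dwi.data, dtype=float)
    b0s = data[..., table.b0_mask]
    if b0_policy == "mean":
        S0 = b0s.mean(axis=-1)
    elif b0_policy == "median":
        S0 = np.median(b0s, axis=-1)
    else:
        S0 = b0s[..., 0]

    if mask is None:
        finite = S0[np.isfinite(S0)]
        if finite.size and finite.max() > finite.min():
            mask = S0 > threshold_otsu(finite)
        else:
            mask = np.ones(S0.shape, dtype=bool)
    else:
        mask = np.asarray(mask).astype(bool)
        if mask.shape != S0.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match volume {S0.shape}"
            )

    dead = mask & (S0 <= 0)
    if dead.any():
        logger.warning(
            "excluding %d voxel(s) with S0 = 0 from the mask", int(dead.sum())
        )
        mask = mask & ~dead

    S = data[..., table.dwi_mask]
    with np.errstate(divide="ignore", invalid="ignore"):
        E = S / S0[..., None]
    E = np.clip(E, epsilon_E, 1.0)
    E[~mask] = 1.0  # background renders as D = 0

    return NormalizedSignal(
        E=E, mask=mask, directions=table.directions, b=table.shell_bvalue
    )


def compute_adc(signal: NormalizedSignal, b: float | None = None) -> ADCMap:
    """Invert the mono-exponential model: D = -ln(E)/b, per direction."""
    if b is None:
        b = signal.b
    if b <= 0:
        raise ValueError(f"b-value must be positive, got {b}")
    D = -np.log(signal.E) / b
    return ADCMap(D=D, directions=signal.directions, b=float(b), mask=signal.mask)
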