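"""NIfTI and FSL gradient-table I/O.

Conventions
-----------
* Gradient directions (bvecs) are interpreted in the **image coordinate
  frame** (FSL convention), not the scanner/world frame.  The orientation
  color code produced downstream therefore refers to the image axes; it is
  only meaningful when the acquisition used gradients aligned with those
  axes.
* Scalar maps are written as 3-D float32 NIfTI; RGB maps as 4-D float32
  NIfTI with a trailing dimension of 3 and values in [0, 1].
* All outputs carry the input affine unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

logger = logging.getLogger("dia3")

#: b-value (s/mm²) at or below which a volume counts as a b=0 baseline.
DEFAULT_B0_TOLERANCE = 50.0

#: tolerance on the unit norm of non-b0 directions after renormalization.
UNIT_NORM_TOL = 1e-4


@dataclass
class GradientTable:
    """Per-volume b-values and unit gradient directions.

    Parameters
    ----------
    bvals : (N,) array
        b-value of each volume in s/mm².
    bvecs : (N, 3) array
        Gradient direction of each volume.  Non-b0 entries are renormalized
        to unit length on construction; the zero vector is only legal for
        b0 entries.
    b0_tolerance : float
        b-value below which a volume is treated as a baseline (b0).
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    b0_tolerance: float = DEFAULT_B0_TOLERANCE

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise ValueError(
                f"bvecs must be (N, 3), got shape {self.bvecs.shape}"
            )
        if len(self.bvals) != len(self.bvecs):
            raise ValueError(
                f"gradient table length mismatch: {len(self.bvals)} b-values "
                f"vs {len(self.bvecs)} directions"
            )
        norms = np.linalg.norm(self.bvecs, axis=1)
        dwi = ~self.b0_mask
        if np.any(norms[dwi] < 1e-12):
            bad = np.flatnonzero(dwi & (norms < 1e-12))
            raise ValueError(
                f"zero gradient direction for non-b0 entries {bad.tolist()}"
            )
        # renormalize in place; b0 rows may stay zero
        nz = norms > 1e-12
        self.bvecs = self.bvecs.copy()
        self.bvecs[nz] /= norms[nz, None]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= self.b0_tolerance

    @property
    def dwi_mask(self) -> np.ndarray:
        return ~self.b0_mask

    @property
    def n_b0(self) -> int:
        return int(np.count_nonzero(self.b0_mask))

    @property
    def directions(self) -> np.ndarray:
        """Unit directions of the diffusion-weighted volumes, (Nd, 3)."""
        return self.bvecs[self.dwi_mask]

    @property
    def shell_bvalue(self) -> float:
        """Common b-value of the (single) diffusion shell."""
        b = self.bvals[self.dwi_mask]
        if len(b) == 0:
            raise ValueError("gradient table has no diffusion-weighted entries")
        return float(np.mean(b))

    def __len__(self) -> int:
        return len(self.bvals)

    def validate_for_dia(self) -> None:
        """Check minimum requirements for any anisotropy computation."""
        if self.n_b0 < 1:
            raise ValueError(
                "at least one b=0 baseline volume is required "
                f"(b0_tolerance={self.b0_tolerance} s/mm²)"
            )
        nd = int(np.count_nonzero(self.dwi_mask))
        if nd < 3:
            raise ValueError(
                f"DiA needs at least 3 diffusion-weighted directions, got {nd}"
            )


@dataclass
class DWIVolume:
    """A 4-D diffusion-weighted series with its gradient table."""

    data: np.ndarray
    affine: np.ndarray
    table: GradientTable = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"DWI data must be 4-D, got {self.data.ndim}-D")
        if min(self.data.shape[:3]) < 1:
            raise ValueError(f"empty spatial dimension in shape {self.data.shape}")
        if self.data.shape[3] != len(self.table):
            raise ValueError(
                f"4th dimension ({self.data.shape[3]}) does not match "
                f"gradient table length ({len(self.table)})"
            )
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")


def _parse_numeric_table(path: str | Path) -> np.ndarray:
    """Parse a whitespace-separated numeric text file into a 2-D array."""
    rows = []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            try:
                row = [float(t) for t in tokens]
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric token on line {lineno}: {exc}"
                ) from None
            if ncols is not None and len(row) != ncols:
                raise ValueError(
                    f"{path}: ragged row on line {lineno} "
                    f"({len(row)} values, expected {ncols})"
                )
            ncols = len(row)
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: file contains no numeric data")
    return np.asarray(rows, dtype=float)


def read_gradient_table(
    bval_path: str | Path,
    bvec_path: str | Path,
    b0_tolerance: float = DEFAULT_B0_TOLERANCE,
) -> GradientTable:
    """Read FSL-style ``.bval`` / ``.bvec`` text files.

    The bvec layout is auto-detected between 3×N (FSL, one row per
    coordinate) and N×3 (one row per volume); when both dimensions are 3
    the FSL convention (3 rows) is assumed.
    """
    bvals = _parse_numeric_table(bval_path).ravel()
    vecs = _parse_numeric_table(bvec_path)
    if vecs.shape[0] == 3:
        bvecs = vecs.T  # FSL rows-are-coordinates, incl. the ambiguous 3x3
    elif vecs.shape[1] == 3:
        bvecs = vecs
    else:
        raise ValueError(
            f"{bvec_path}: expected a 3xN or Nx3 table, got {vecs.shape}"
        )
    if len(bvals) != len(bvecs):
        raise ValueError(
            f"gradient table length mismatch: {len(bvals)} b-values in "
            f"{bval_path} vs {len(bvecs)} directions in {bvec_path}"
        )
    return GradientTable(bvals=bvals, bvecs=bvecs, b0_tolerance=b0_tolerance)


def write_gradient_table(
    table: GradientTable, bval_path: str | Path, bvec_path: str | Path
) -> None:
    """Write FSL-style bval/bvec files (bvec in 3×N layout)."""
    with open(bval_path, "w") as fh:
        fh.write(" ".join(f"{b:g}" for b in table.bvals) + "\n")
    with open(bvec_path, "w") as fh:
        for row in table.bvecs.T:
            fh.write(" ".join(f"{v:.8f}" for v in row) + "\n")


def read_dwi(nifti_path: str | Path, table: GradientTable) -> DWIVolume:
    """Load a 4-D NIfTI series and attach its gradient table."""
    img = nib.load(str(nifti_path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 3:
        raise ValueError(
            f"{nifti_path} is a 3-D volume; a 4-D diffusion series is "
            "required (pass each single volume through write_map/nibabel "
            "directly if that is what you need)"
        )
    if data.ndim != 4:
        raise ValueError(f"{nifti_path}: expected 4-D data, got {data.ndim}-D")
    return DWIVolume(data=data, affine=img.affine, table=table)


def write_dwi(dwi: DWIVolume, nifti_path: str | Path) -> None:
    nib.save(nib.Nifti1Image(dwi.data, dwi.affine), str(nifti_path))


def write_map(
    volume: np.ndarray,
    affine: np.ndarray,
    out_path: str | Path,
    allow_nan: bool = False,
) -> None:
    """Write a scalar (3-D) or RGB (4-D, trailing dim 3) map as NIfTI.

    Scalar maps are stored float32.  RGB maps are stored as 4-D float32 in
    [0, 1] (values clipped), which round-trips losslessly and displays in
    standard viewers.  Non-finite voxels raise unless ``allow_nan``, in
    which case they are mapped to 0 and counted in the log.
    """
    volume = np.asarray(volume, dtype=np.float32)
    is_rgb = volume.ndim == 4 and volume.shape[-1] == 3
    if not is_rgb and volume.ndim != 3:
        raise ValueError(
            f"expected a 3-D scalar or (...,3) RGB map, got shape {volume.shape}"
        )
    bad = ~np.isfinite(volume)
    if bad.any():
        n_bad = int(bad.sum())
        if not allow_nan:
            raise ValueError(
                f"map contains {n_bad} non-finite value(s); "
                "pass allow_nan=True (CLI: --allow-nan) to zero them"
            )
        logger.warning("zeroing %d non-finite voxel value(s)", n_bad)
        volume = np.where(bad, np.float32(0), volume)
    if is_rgb:
        volume = np.clip(volume, 0.0, 1.0)
    nib.save(nib.Nifti1Image(volume, np.asarray(affine, float)), str(out_path))
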