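"""Registration-derived functional variables: J, ADI, SRI and ΔV_air^f.

All metrics live on the expiration reference grid.  The displacement field u
maps expiration to inspiration (``x_insp = x_exp + u(x_exp)``), so the local
deformation gradient is ``F = I + ∇u`` and its determinant ``J = det F`` is
the expansion ratio from expiration toward inspiration — J > 1 means local
inflation.

Directional preference is read off the principal stretches λ1 ≥ λ2 ≥ λ3 > 0
(square roots of the eigenvalues of FᵀF, i.e. the singular values of F):

* ADI = sqrt( ((λ1−λ2)/λ2)² + ((λ2−λ3)/λ3)² )  — magnitude of anisotropy,
  0 for isotropic expansion;
* SRI = (2/π)·arctan2( λ2·(λ1−λ2), λ3·(λ2−λ3) ) ∈ [0, 1] — shape of the
  anisotropy, 0 for slab-like (λ1 = λ2 > λ3 gives an angle of 0 only when
  λ1 = λ2; rod-like λ1 > λ2 = λ3 gives 1).

Air content uses the linear HU mixing model with pure-air at −1000 HU and
soft tissue at +55 HU: β(HU) = clamp((55 − HU)/1055, 0, 1).  The air-volume
change per expiration voxel is ΔV_air^f = J·β_IN(x + u(x)) − β_EX(x), i.e.
the inspiration air content of the corresponding (volume-scaled) region
minus the expiration air content.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .io import CTVolume, DisplacementField, LungMask, logger
from .prm import HU_AIR, HU_TISSUE, PairedScan


def deformation_gradient(field: DisplacementField) -> np.ndarray:
    """Per-voxel F = I + ∇u, shape (nx, ny, nz, 3, 3).

    Gradients are central differences in physical mm (second-order one-sided
    at the grid boundary), so affine fields are reproduced exactly in the
    interior.
    """
    if any(s <= 0 for s in field.spacing):
        raise ValueError(f"degenerate spacing {field.spacing}")
    if min(field.shape) < 3:
        raise ValueError("field must span at least 3 voxels per axis")
    u = field.vectors.astype(np.float64)
    F = np.empty(field.shape + (3, 3), dtype=np.float64)
    for i in range(3):
        grads = np.gradient(u[..., i], *field.spacing, edge_order=2)
        for j in range(3):
            F[..., i, j] = grads[j]
    F[..., 0, 0] += 1.0
    F[..., 1, 1] += 1.0
    F[..., 2, 2] += 1.0
    return F


def jacobian(F_grid: np.ndarray) -> np.ndarray:
    """det F per voxel (closed-form 3×3 determinant)."""
    a = F_grid
    return (
        a[..., 0, 0] * (a[..., 1, 1] * a[..., 2, 2] - a[..., 1, 2] * a[..., 2, 1])
        - a[..., 0, 1] * (a[..., 1, 0] * a[..., 2, 2] - a[..., 1, 2] * a[..., 2, 0])
        + a[..., 0, 2] * (a[..., 1, 0] * a[..., 2, 1] - a[..., 1, 1] * a[..., 2, 0])
    )


def principal_stretches(F_grid: np.ndarray) -> np.ndarray:
    """Sorted principal stretches (λ1 ≥ λ2 ≥ λ3), shape (..., 3).

    Computed as square roots of the eigenvalues of the right Cauchy–Green
    tensor C = FᵀF; negative eigenvalues from round-off are clipped at zero
    and flagged.
    """
    C = np.einsum("...ki,...kj->...ij", F_grid, F_grid)
    w = np.linalg.eigvalsh(C)  # ascending
    bad = w[..., 0] < -1e-10
    if np.any(bad):
        logger.warning("principal_stretches: %d voxels with non-PSD FᵀF", int(bad.sum()))
    lam = np.sqrt(np.clip(w, 0.0, None))
    return lam[..., ::-1]


def adi(lam: np.ndarray) -> np.ndarray:
    """Anisotropic deformation index from sorted stretches (λ1 ≥ λ2 ≥ λ3 > 0)."""
    lam = np.asarray(lam, dtype=np.float64)
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    if np.any(l3 <= 0):
        raise ValueError("all principal stretches must be positive")
    return np.sqrt(((l1 - l2) / l2) ** 2 + ((l2 - l3) / l3) ** 2)


def sri(lam: np.ndarray) -> np.ndarray:
    """Slab–rod index in [0, 1] from sorted stretches."""
    lam = np.asarray(lam, dtype=np.float64)
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    if np.any(l3 <= 0):
        raise ValueError("all principal stretches must be positive")
    val = (2.0 / np.pi) * np.arctan2(l2 * (l1 - l2), l3 * (l2 - l3))
    return np.clip(val, 0.0, 1.0)


def air_fraction(hu: np.ndarray | float) -> np.ndarray | float:
    """Air volume fraction β of a voxel from its attenuation.

    Linear interpolation between pure air (−1000 HU, β = 1) and soft tissue
    (+55 HU, β = 0), clamped to [0, 1].
    """
    hu = np.asarray(hu, dtype=np.float64)
    beta = (HU_TISSUE - hu) / (HU_TISSUE - HU_AIR)
    return np.clip(beta, 0.0, 1.0)


def delta_vair_f(pair: PairedScan, field: DisplacementField,
                 F_grid: np.ndarray | None = None) -> np.ndarray:
    """Per-voxel air-volume change ΔV_air^f on the expiration grid.

    For each expiration voxel x, the corresponding inspiration location
    x + u(x) is sampled trilinearly from the inspiration β map (out-of-grid
    positions clamp to the nearest edge) and weighted by the local volume
    expansion J.
    """
    if F_grid is None:
        F_grid = deformation_gradient(field)
    J = jacobian(F_grid)
    beta_in = air_fraction(pair.insp.voxels)
    beta_ex = air_fraction(pair.exp_reg.voxels)

    idx = np.indices(field.shape, dtype=np.float64)
    spacing = np.asarray(field.spacing, dtype=np.float64)
    # voxel index of the corresponding inspiration location (shared origin)
    coords = [idx[a] + field.vectors[..., a] / spacing[a] for a in range(3)]
    n_out = sum(
        int(np.sum((c < 0) | (c > s - 1)))
        for c, s in zip(coords, field.shape)
    )
    if n_out:
        logger.debug("delta_vair_f: %d out-of-grid correspondences clamped", n_out)
    beta_in_warp = map_coordinates(beta_in, np.stack(coords), order=1, mode="nearest")
    return J * beta_in_warp - beta_ex


@dataclass
class FunctionalMaps:
    """Voxel maps of the four functional variables plus per-subject medians."""

    j_map: np.ndarray
    adi_map: np.ndarray
    sri_map: np.ndarray
    dvair_map: np.ndarray
    j_median: float
    adi_median: float
    sri_median: float
    dvair_median: float


def functional_maps(pair: PairedScan, field: DisplacementField,
                    mask: LungMask | None = None) -> FunctionalMaps:
    """Compute J/ADI/SRI/ΔV_air^f maps and their voxel-medians over the mask."""
    if mask is None:
        mask = pair.mask
    F = deformation_gradient(field)
    j_map = jacobian(F)
    lam = principal_stretches(F)
    adi_map = adi(lam)
    sri_map = sri(lam)
    dvair_map = delta_vair_f(pair, field, F_grid=F)
    m = mask.voxels
    return FunctionalMaps(
        j_map=j_map,
        adi_map=adi_map,
        sri_map=sri_map,
        dvair_map=dvair_map,
        j_median=float(np.median(j_map[m])),
        adi_median=float(np.median(adi_map[m])),
        sri_median=float(np.median(sri_map[m])),
        dvair_median=float(np.median(dvair_map[m])),
    )


def median_jacobian(field: DisplacementField, mask: LungMask) -> float:
    """Voxel-median of det(I + ∇u) over the lung mask."""
    return float(np.median(jacobian(deformation_gradient(field))[mask.voxels]))
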