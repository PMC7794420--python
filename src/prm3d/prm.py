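"""Voxel-wise parametric response mapping (PRM) of paired inspiration/expiration CT.

A registered voxel carries two attenuations: HU at inspiration (total lung
capacity) and HU at expiration (functional residual capacity).  Two fixed
cuts — −950 HU on the inspiratory scan, −856 HU on the expiratory scan —
split the joint density plane into three classes:

==========  ===========================  ====
class       rule (inclusive cuts)        code
==========  ===========================  ====
emphysema   IN ≤ −950 and EX ≤ −856       64
fSAD        IN > −950 and EX ≤ −856       32
normal      EX > −856 (either IN side)     8
==========  ===========================  ====

The fourth quadrant (IN ≤ −950, EX > −856) is physiologically implausible
and conventionally folded into "normal"; a diagnostic count of such voxels
is logged.  Voxels outside the lung mask are coded 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CTVolume, GeometryError, LungMask, logger

CODE_BACKGROUND = 0
CODE_NORMAL = 8
CODE_FSAD = 32
CODE_EMPH = 64

#: attenuation of pure air / water / soft tissue, HU
HU_AIR = -1000.0
HU_WATER = 0.0
HU_TISSUE = 55.0


@dataclass
class PRMThresholds:
    """The two attenuation cuts (HU)."""

    insp_cut: float = -950.0
    exp_cut: float = -856.0

    def __post_init__(self) -> None:
        if not self.insp_cut < self.exp_cut:
            raise ValueError(
                f"insp_cut ({self.insp_cut}) must be below exp_cut ({self.exp_cut})"
            )


@dataclass
class PairedScan:
    """Inspiration volume, expiration volume resampled onto it, shared mask."""

    insp: CTVolume
    exp_reg: CTVolume
    mask: LungMask

    def __post_init__(self) -> None:
        if not (
            self.insp.shape == self.exp_reg.shape == self.mask.shape
            and np.allclose(self.insp.spacing, self.exp_reg.spacing)
        ):
            raise GeometryError("insp, exp_reg and mask must share geometry")


@dataclass
class PRMVolume:
    """Integer class-code grid {0, 8, 32, 64} plus provenance."""

    codes: np.ndarray
    thresholds: PRMThresholds
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass
class QCTSummary:
    """Per-subject quantitative CT summary.

    Percentages are over lung-mask voxel counts and sum to 100; TLC/FRC are
    air volumes in litres obtained by integrating the linear air-fraction
    map over the mask.
    """

    emph_pct: float
    fsad_pct: float
    normal_pct: float
    tlc_l: float
    frc_l: float


def classify_voxel(hu_in: float, hu_ex: float, th: PRMThresholds | None = None) -> int:
    """PRM class code of a single lung voxel (inclusive ≤ on both cuts)."""
    if th is None:
        th = PRMThresholds()
    if not (np.isfinite(hu_in) and np.isfinite(hu_ex)):
        raise ValueError("HU values must be finite")
    if hu_ex <= th.exp_cut:
        return CODE_EMPH if hu_in <= th.insp_cut else CODE_FSAD
    return CODE_NORMAL


def classify_volume(pair: PairedScan, th: PRMThresholds | None = None) -> PRMVolume:
    """Apply the PRM rule voxel-wise inside the lung mask."""
    if th is None:
        th = PRMThresholds()
    mask = pair.mask.voxels
    if not mask.any():
        raise GeometryError("lung mask is empty")
    hu_in = pair.insp.voxels
    hu_ex = pair.exp_reg.voxels
    low_in = hu_in <= th.insp_cut
    low_ex = hu_ex <= th.exp_cut
    codes = np.full(hu_in.shape, CODE_NORMAL, dtype=np.uint8)
    codes[low_ex & low_in] = CODE_EMPH
    codes[low_ex & ~low_in] = CODE_FSAD
    codes[~mask] = CODE_BACKGROUND
    n_uncl = int((low_in & ~low_ex & mask).sum())
    if n_uncl:
        logger.debug("PRM: %d unclassified-quadrant voxels folded into normal", n_uncl)
    return PRMVolume(codes, th, pair.insp.spacing, pair.insp.origin)


def summarize(prm: PRMVolume, pair: PairedScan) -> QCTSummary:
    """Class fractions (percent of mask voxels) and TLC/FRC air volumes (litres)."""
    from .deformation import air_fraction

    mask = pair.mask.voxels
    n = int(mask.sum())
    n_e = int((prm.codes == CODE_EMPH).sum())
    n_f = int((prm.codes == CODE_FSAD).sum())
    n_n = int((prm.codes == CODE_NORMAL).sum())
    if n_e + n_f + n_n != n:
        raise GeometryError("PRM volume does not match the pair's mask")
    vv = pair.insp.voxel_volume_mm3
    tlc = float(air_fraction(pair.insp.voxels[mask]).sum()) * vv / 1e6
    frc = float(air_fraction(pair.exp_reg.voxels[mask]).sum()) * vv / 1e6
    return QCTSummary(
        emph_pct=100.0 * n_e / n,
        fsad_pct=100.0 * n_f / n,
        normal_pct=100.0 * n_n / n,
        tlc_l=tlc,
        frc_l=frc,
    )
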