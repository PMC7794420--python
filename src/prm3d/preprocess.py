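"""Conversion of any supported map kind into the fixed-size network input.

Every input modality — PRM code map, raw IN/EX attenuation, ΔV_air^f, J,
ADI, SRI, or the two-channel IN+EX concatenation — goes through the same
two steps: trilinear resampling to 32×32×32 on the voxel-centred lattice,
then an affine normalization into [0, 1] with a *fixed* window per kind
(per-volume min–max scaling would erase the between-group density signal
the classifier must learn):

=========  =======================  ==========================
kind       window                   note
=========  =======================  ==========================
in, ex     [−1024, 0] HU            clamp then affine
prm        codes / 64               0, 0.125, 0.5, 1.0
j          [0.5, 3]                 clamp then affine
adi        [0, 2]                   clamp then affine
sri        identity                 already in [0, 1]
dvair      [−0.5, 1.5]              clamp then affine
=========  =======================  ==========================

PRM code maps are linearly interpolated like every other volume, so class
borders blend into intermediate values; the code/64 intensity convention
keeps severity monotone (normal < fSAD < emphysema).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

TARGET_SHAPE = (32, 32, 32)

INPUT_KINDS = ("prm", "in", "ex", "dvair", "j", "adi", "sri", "inex")

#: (low, high) clamp window per kind; None means identity
_WINDOWS: dict[str, tuple[float, float] | None] = {
    "in": (-1024.0, 0.0),
    "ex": (-1024.0, 0.0),
    "prm": (0.0, 64.0),
    "j": (0.5, 3.0),
    "adi": (0.0, 2.0),
    "sri": None,
    "dvair": (-0.5, 1.5),
}


class DependencyError(KeyError):
    """A map required by the requested input kind is missing."""


@dataclass
class NetworkInput:
    """Fixed-size normalized classifier input.

    ``values`` has shape (C, 32, 32, 32) with every entry in [0, 1];
    C = 2 for the IN+EX concatenation, 1 otherwise.
    """

    values: np.ndarray
    input_kind: str
    subject_id: str = ""
    label: int | None = None  # 1 = COPD, 0 = non-COPD

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float32)
        if v.ndim != 4 or v.shape[1:] != TARGET_SHAPE:
            raise ValueError(f"expected (C, 32, 32, 32), got {v.shape}")
        self.values = v


def resample(grid: np.ndarray, target: tuple[int, int, int] = TARGET_SHAPE
             ) -> np.ndarray:
    """Trilinear resampling onto a voxel-centred target lattice.

    Target index t along an axis of T voxels samples source coordinate
    ``(t + 0.5)·S/T − 0.5``; edge samples clamp.  A same-shape call returns
    the input unchanged.
    """
    grid = np.asarray(grid)
    if grid.ndim != 3:
        raise ValueError(f"expected a 3-D grid, got {grid.ndim}-D")
    if any(t < 1 for t in target):
        raise ValueError(f"invalid target shape {target}")
    if min(grid.shape) < 2:
        raise ValueError("source must have at least 2 voxels per axis")
    if tuple(grid.shape) == tuple(target):
        return grid.copy()
    coords = np.meshgrid(
        *(
            (np.arange(t) + 0.5) * (s / t) - 0.5
            for s, t in zip(grid.shape, target)
        ),
        indexing="ij",
    )
    return map_coordinates(
        grid.astype(np.float64), np.stack(coords), order=1, mode="nearest"
    )


def normalize(grid: np.ndarray, input_kind: str) -> np.ndarray:
    """Map a grid into [0, 1] with the fixed window of its kind."""
    kind = "in" if input_kind == "inex" else input_kind
    if kind not in _WINDOWS:
        raise ValueError(f"unknown input kind {input_kind!r}")
    grid = np.asarray(grid, dtype=np.float64)
    if not np.all(np.isfinite(grid)):
        raise ValueError("grid contains non-finite values")
    window = _WINDOWS[kind]
    if window is None:
        return np.clip(grid, 0.0, 1.0)
    lo, hi = window
    return (np.clip(grid, lo, hi) - lo) / (hi - lo)


def assemble(maps: dict[str, np.ndarray], input_kind: str,
             subject_id: str = "", label: int | None = None) -> NetworkInput:
    """Resample → normalize → stack channels for the requested input kind.

    ``maps`` holds whichever source grids exist for the subject, keyed by
    kind (``"in"``, ``"ex"``, ``"prm"``, ``"j"``, ``"adi"``, ``"sri"``,
    ``"dvair"``).
    """
    if input_kind not in INPUT_KINDS:
        raise ValueError(f"unknown input kind {input_kind!r}")
    needed = ("in", "ex") if input_kind == "inex" else (input_kind,)
    channels = []
    for k in needed:
        if k not in maps or maps[k] is None:
            raise DependencyError(
                f"input kind {input_kind!r} requires map {k!r}, which is missing"
            )
        channels.append(normalize(resample(np.asarray(maps[k], dtype=np.float64)), k))
    return NetworkInput(
        values=np.stack(channels).astype(np.float32),
        input_kind=input_kind,
        subject_id=subject_id,
        label=label,
    )


def subject_maps(subject, kinds=("prm",)) -> dict[str, np.ndarray]:
    """Collect the source grids a phantom ``Subject`` can provide.

    Deformation-derived kinds are computed on demand; PRM is classified with
    the default thresholds.
    """
    from .deformation import functional_maps
    from .prm import classify_volume

    out: dict[str, np.ndarray] = {}
    wanted = set()
    for k in kinds:
        wanted.update(("in", "ex") if k == "inex" else (k,))
    if "in" in wanted:
        out["in"] = subject.pair.insp.voxels
    if "ex" in wanted:
        out["ex"] = subject.pair.exp_reg.voxels
    if "prm" in wanted:
        out["prm"] = classify_volume(subject.pair).codes
    if wanted & {"j", "adi", "sri", "dvair"}:
        fm = functional_maps(subject.pair, subject.field)
        out.update(j=fm.j_map, adi=fm.adi_map, sri=fm.sri_map, dvair=fm.dvair_map)
    return out
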