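"""Synthetic paired inspiration/expiration CT phantoms with known ground truth.

Each phantom is an ellipsoidal "lung" embedded in soft tissue, carrying

* planted emphysema blobs (low attenuation at both breath holds),
* planted functional small-airway-disease (fSAD) blobs (normal at
  inspiration, air-trapped at expiration),
* a smooth expiration→inspiration displacement field whose voxel-median
  Jacobian over the lung equals the subject's target value, with local
  expansion suppressed inside disease blobs (air trapping), and
* per-voxel HU noise that leaves a small, realistic misclassification tail
  at the −950/−856 HU cuts.

Group-level burden distributions (percent emphysema, percent fSAD, mean
Jacobian for COPD and non-COPD) default to the cohort statistics of the
study population this package models.  Draws are truncated to their valid
ranges; because plain truncation would inflate the group mean (the non-COPD
burden SDs exceed their means), the pre-truncation location is calibrated by
root-finding so the *post*-truncation mean equals the nominal group mean.
The truncated SD is then necessarily below nominal for groups with CV > 1 —
a left-truncated normal cannot match both moments there.

Geometry is arbitrary (no absolute litre calibration): only fractions and
the Jacobian are group-calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.ndimage import gaussian_filter

from .deformation import deformation_gradient, jacobian
from .io import CTVolume, DisplacementField, LungMask
from .prm import PairedScan

COPD = "COPD"
NON_COPD = "non-COPD"
GROUPS = (COPD, NON_COPD)


@dataclass
class GroupCalibration:
    """Mean/SD of the planted burden distributions for one group."""

    emph_mean: float
    emph_sd: float
    fsad_mean: float
    fsad_sd: float
    j_mean: float
    j_sd: float


#: cohort statistics the generator reproduces (percent, percent, ratio)
DEFAULT_CALIBRATION: dict[str, GroupCalibration] = {
    COPD: GroupCalibration(8.5, 7.5, 23.7, 13.6, 1.5, 0.3),
    NON_COPD: GroupCalibration(1.7, 2.5, 11.2, 13.4, 1.7, 0.4),
}


@dataclass
class PhantomParams:
    """Everything that shapes a phantom subject.

    HU levels place each tissue class safely on its side of the −950/−856
    cuts while leaving a small misclassification tail; see the methods note
    for the tail arithmetic.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    #: ellipsoid semi-axes as fractions of the grid extent per axis
    lung_semiaxes: tuple[float, float, float] = (0.30, 0.35, 0.42)
    calibration: dict[str, GroupCalibration] = dc_field(
        default_factory=lambda: dict(DEFAULT_CALIBRATION)
    )
    burden_range: tuple[float, float] = (0.0, 60.0)
    burden_sum_max: float = 80.0
    j_range: tuple[float, float] = (1.0, 3.0)
    # (mean, sd) HU at inspiration / expiration per tissue class
    normal_in: tuple[float, float] = (-870.0, 30.0)
    normal_ex: tuple[float, float] = (-780.0, 28.0)
    emph_in: tuple[float, float] = (-975.0, 10.0)
    emph_ex: tuple[float, float] = (-920.0, 15.0)
    fsad_in: tuple[float, float] = (-900.0, 15.0)
    fsad_ex: tuple[float, float] = (-900.0, 15.0)
    background_hu: float = 40.0
    background_noise_sd: float = 10.0
    #: extra white HU noise added on top of the class distributions
    hu_noise_sd: float = 0.0
    blob_radius: tuple[float, float] = (2.0, 4.5)
    #: sampling weight of upper-third lesion centres relative to the rest
    #: (applied to COPD subjects)
    upper_lobe_bias: float = 2.0
    #: displacement-field anisotropy pattern (normalised to det 1)
    anisotropy: tuple[float, float, float] = (1.15, 1.0, 0.87)
    perturb_amp_mm: float = 1.0
    perturb_sigma_vox: float = 4.0
    #: displacement scaling inside disease blobs (air trapping, < 1)
    trap_shrink: float = 0.7

    def __post_init__(self) -> None:
        lo, hi = self.burden_range
        if not (0 <= lo < hi <= 60):
            raise ValueError("planted fractions must lie in [0, 60]")
        if self.burden_sum_max > 80:
            raise ValueError("Emph% + fSAD% cap must be ≤ 80")
        if self.j_range[0] < 1:
            raise ValueError("mean Jacobian must be ≥ 1")
        for g, cal in self.calibration.items():
            if min(cal.emph_sd, cal.fsad_sd, cal.j_sd) < 0:
                raise ValueError(f"negative SD in calibration for {g}")


@dataclass
class SubjectTruth:
    """Ground truth planted in one phantom subject."""

    group: str
    emph_pct: float
    fsad_pct: float
    mean_j: float
    lesion_centroids: list[tuple[int, int, int]] = dc_field(default_factory=list)


@dataclass
class Subject:
    subject_id: str
    truth: SubjectTruth
    pair: PairedScan
    mask: LungMask
    field: DisplacementField


@dataclass
class Cohort:
    """A labelled phantom cohort with per-subject ground truth."""

    subjects: list[Subject]
    seed: int

    @property
    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": s.subject_id,
                "group": s.truth.group,
                "planted_emph_pct": s.truth.emph_pct,
                "planted_fsad_pct": s.truth.fsad_pct,
                "planted_mean_j": s.truth.mean_j,
                "n_lesions": len(s.truth.lesion_centroids),
            }
            for s in self.subjects
        ]
        return pd.DataFrame(rows)


_trunc_loc_cache: dict[tuple[float, float, float, float], float] = {}


def truncated_mean_calibrated(mean: float, sd: float, lo: float, hi: float):
    """A truncated normal whose *truncated* mean equals ``mean``.

    Solves for the pre-truncation location μ̃ of N(μ̃, sd) truncated to
    [lo, hi] such that its mean is the nominal ``mean``; the nominal SD is
    kept as the underlying scale.  Degenerate sd = 0 returns a point mass.
    """
    if sd == 0:
        return stats.norm(loc=mean, scale=0.0)
    key = (mean, sd, lo, hi)
    if key not in _trunc_loc_cache:
        def gap(mu: float) -> float:
            a, b = (lo - mu) / sd, (hi - mu) / sd
            return stats.truncnorm.mean(a, b, loc=mu, scale=sd) - mean

        lo_b, hi_b = mean - 6 * sd, min(mean + 2 * sd, hi)
        _trunc_loc_cache[key] = float(optimize.brentq(gap, lo_b, hi_b, xtol=1e-10))
    mu = _trunc_loc_cache[key]
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return stats.truncnorm(a, b, loc=mu, scale=sd)


def sample_subject(group: str, params: PhantomParams,
                   rng: np.random.Generator) -> SubjectTruth:
    """Draw one subject's planted burdens and target Jacobian for its group."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    cal = params.calibration[group]
    lo, hi = params.burden_range
    d_emph = truncated_mean_calibrated(cal.emph_mean, cal.emph_sd, lo, hi)
    d_fsad = truncated_mean_calibrated(cal.fsad_mean, cal.fsad_sd, lo, hi)
    d_j = truncated_mean_calibrated(cal.j_mean, cal.j_sd, *params.j_range)
    for _ in range(1000):
        emph = float(d_emph.rvs(random_state=rng))
        fsad = float(d_fsad.rvs(random_state=rng))
        if emph + fsad <= params.burden_sum_max:
            break
    else:  # pragma: no cover - astronomically unlikely with defaults
        raise RuntimeError("could not draw burdens under the sum cap")
    mean_j = float(d_j.rvs(random_state=rng))
    return SubjectTruth(group=group, emph_pct=emph, fsad_pct=fsad, mean_j=mean_j)


_mask_cache: dict[tuple, dict] = {}


def _lung_geometry(params: PhantomParams) -> dict:
    """Ellipsoid mask plus precomputed lesion-centre sampling tables (cached)."""
    key = (params.shape, params.lung_semiaxes)
    if key in _mask_cache:
        return _mask_cache[key]
    nx, ny, nz = params.shape
    ax = np.array(params.lung_semiaxes) * np.array(params.shape)
    c = (np.array(params.shape) - 1) / 2.0
    X, Y, Z = np.meshgrid(*(np.arange(n) for n in params.shape), indexing="ij")
    mask = ((X - c[0]) / ax[0]) ** 2 + ((Y - c[1]) / ax[1]) ** 2 + (
        (Z - c[2]) / ax[2]
    ) ** 2 <= 1.0
    coords = np.argwhere(mask)
    zmin, zmax = coords[:, 2].min(), coords[:, 2].max()
    upper = coords[:, 2] >= zmin + 2.0 * (zmax - zmin) / 3.0
    index_of = np.full(mask.shape, -1, dtype=np.int32)
    index_of[coords[:, 0], coords[:, 1], coords[:, 2]] = np.arange(len(coords))
    geo = {"mask": mask, "coords": coords, "upper": upper,
           "index_of": index_of, "rel": {}}
    _mask_cache[key] = geo
    return geo


def _rel_coords(geo: dict, spacing: tuple) -> list[np.ndarray]:
    """Physical coordinates relative to the lung centroid (cached per spacing)."""
    key = tuple(spacing)
    if key not in geo["rel"]:
        mask = geo["mask"]
        axes = [np.arange(n) * s for n, s in zip(mask.shape, spacing)]
        X, Y, Z = np.meshgrid(*axes, indexing="ij")
        geo["rel"][key] = [
            (c - c[mask].mean()).astype(np.float32) for c in (X, Y, Z)
        ]
    return geo["rel"][key]


def _plant_blobs(labels: np.ndarray, code: int, target: int, geo: dict,
                 weights: np.ndarray, params: PhantomParams,
                 rng: np.random.Generator,
                 centroids: list[tuple[int, int, int]]) -> None:
    """Accrete random spherical blobs until exactly ``target`` voxels carry ``code``.

    Centres are drawn from unassigned lung voxels (with the upper-lobe
    weighting); the last blob is trimmed, nearest-to-centre first, so the
    planted count is exact.
    """
    coords = geo["coords"]
    shape = labels.shape
    planted = 0
    assigned = labels[coords[:, 0], coords[:, 1], coords[:, 2]] != 0
    while planted < target:
        w = weights * ~assigned
        total = w.sum()
        if total <= 0:
            raise ValueError("planted burden exceeds lung capacity")
        center = coords[rng.choice(len(coords), p=w / total)]
        r = rng.uniform(*params.blob_radius)
        ri = int(np.ceil(r))
        sl = tuple(
            slice(max(0, center[a] - ri), min(shape[a], center[a] + ri + 1))
            for a in range(3)
        )
        gx, gy, gz = np.meshgrid(
            *(np.arange(s.start, s.stop) for s in sl), indexing="ij"
        )
        d2 = (gx - center[0]) ** 2 + (gy - center[1]) ** 2 + (gz - center[2]) ** 2
        inside = (d2 <= r * r) & geo["mask"][sl] & (labels[sl] == 0)
        cand = np.argwhere(inside)
        if len(cand) == 0:
            continue
        need = target - planted
        if len(cand) > need:
            order = np.argsort(d2[inside], kind="stable")[:need]
            cand = cand[order]
        abs_idx = cand + np.array([s.start for s in sl])
        labels[abs_idx[:, 0], abs_idx[:, 1], abs_idx[:, 2]] = code
        assigned[geo["index_of"][abs_idx[:, 0], abs_idx[:, 1], abs_idx[:, 2]]] = True
        planted += len(abs_idx)
        centroids.append(tuple(int(v) for v in center))


def _displacement(labels: np.ndarray, geo: dict, truth: SubjectTruth,
                  params: PhantomParams, rng: np.random.Generator
                  ) -> DisplacementField:
    """Smooth field whose voxel-median Jacobian over the lung hits truth.mean_j.

    u = w(x)·[(A − I)(x − c) + p(x)] with A a global anisotropic scaling,
    p a band-limited Gaussian perturbation, and w < 1 inside disease blobs
    (air trapping).  Because F(s) = I + s·∇u is linear in a global scale s,
    the median Jacobian is calibrated exactly by a 1-D root solve.
    """
    shape = params.shape
    spacing = np.asarray(params.spacing, dtype=np.float64)
    mask = geo["mask"]
    rel = _rel_coords(geo, params.spacing)

    a_iso = truth.mean_j ** (1.0 / 3.0)
    aniso = np.asarray(params.anisotropy, dtype=np.float64)
    aniso = aniso / np.prod(aniso) ** (1.0 / 3.0)
    diag = a_iso * aniso - 1.0  # A − I

    u = np.empty(shape + (3,), dtype=np.float32)
    for a in range(3):
        u[..., a] = np.float32(diag[a]) * rel[a]

    if params.perturb_amp_mm > 0:
        pert = rng.standard_normal(shape + (3,)).astype(np.float32)
        for a in range(3):
            pert[..., a] = gaussian_filter(pert[..., a], params.perturb_sigma_vox)
        rms = np.sqrt(np.mean(pert**2))
        u += pert * np.float32(params.perturb_amp_mm / rms)

    if params.trap_shrink < 1.0:
        w = 1.0 - np.float32(1.0 - params.trap_shrink) * gaussian_filter(
            (labels > 0).astype(np.float32), 1.5
        )
        u *= w[..., None]

    # calibrate a global scale so the masked median of det(I + s·∇u) = mean_j
    G = np.empty(shape + (3, 3), dtype=np.float32)
    for i in range(3):
        gx, gy, gz = np.gradient(u[..., i], *spacing)
        G[..., i, 0], G[..., i, 1], G[..., i, 2] = gx, gy, gz
    Gm = G[mask].astype(np.float64)

    def med_j(s: float) -> float:
        return float(np.median(jacobian(np.eye(3) + s * Gm)))

    # The affine part alone gives med_j(1) = target, so the correction for
    # perturbation and air trapping is always near s = 1.  med_j need not be
    # monotone (the compressive anisotropy axis caps it for targets near 1),
    # so minimise the gap on a bounded interval instead of bracketing a root.
    target = truth.mean_j
    if abs(med_j(1.0) - target) > 1e-4:
        d_min = diag.min()
        s_hi = min(1.6, 0.95 / -d_min) if d_min < 0 else 1.6
        res = optimize.minimize_scalar(
            lambda s: (med_j(s) - target) ** 2, bounds=(0.0, s_hi),
            method="bounded", options={"xatol": 1e-4},
        )
        s = float(res.x)
        if abs(med_j(s) - target) > 0.02:  # pragma: no cover - geometry limit
            logger_gap = abs(med_j(s) - target)
            import logging

            logging.getLogger("prm3d").warning(
                "median-J calibration off by %.3f for target %.3f",
                logger_gap, target,
            )
    else:
        s = 1.0
    return DisplacementField((s * u).astype(np.float32), tuple(spacing))


def generate_paired_scan(truth: SubjectTruth, params: PhantomParams,
                         rng: np.random.Generator, *, with_field: bool = True
                         ) -> tuple[PairedScan, LungMask, DisplacementField | None]:
    """Materialise one subject: paired HU volumes, lung mask, displacement field."""
    geo = _lung_geometry(params)
    mask = geo["mask"]
    n_mask = len(geo["coords"])
    n_e = int(round(truth.emph_pct / 100.0 * n_mask))
    n_f = int(round(truth.fsad_pct / 100.0 * n_mask))
    if n_e + n_f > 0.9 * n_mask:
        raise ValueError("planted burdens exceed lung capacity")

    bias = params.upper_lobe_bias if truth.group == COPD else 1.0
    weights = np.where(geo["upper"], bias, 1.0)

    labels = np.zeros(params.shape, dtype=np.uint8)
    centroids: list[tuple[int, int, int]] = []
    _plant_blobs(labels, 1, n_e, geo, weights, params, rng, centroids)
    _plant_blobs(labels, 2, n_f, geo, weights, params, rng, centroids)
    truth.lesion_centroids = centroids

    hu_in = np.full(params.shape, params.background_hu, dtype=np.float64)
    hu_ex = np.full(params.shape, params.background_hu, dtype=np.float64)
    if params.background_noise_sd > 0:
        hu_in += rng.normal(0, params.background_noise_sd, params.shape)
        hu_ex += rng.normal(0, params.background_noise_sd, params.shape)
    class_levels = {
        0: (params.normal_in, params.normal_ex),
        1: (params.emph_in, params.emph_ex),
        2: (params.fsad_in, params.fsad_ex),
    }
    for code, ((m_in, s_in), (m_ex, s_ex)) in class_levels.items():
        sel = mask & (labels == code)
        n = int(sel.sum())
        if n == 0:
            continue
        hu_in[sel] = rng.normal(m_in, s_in, n)
        hu_ex[sel] = rng.normal(m_ex, s_ex, n)
    if params.hu_noise_sd > 0:
        hu_in += rng.normal(0, params.hu_noise_sd, params.shape)
        hu_ex += rng.normal(0, params.hu_noise_sd, params.shape)
    hu_in = np.clip(np.rint(hu_in), -1100, 3100).astype(np.int16)
    hu_ex = np.clip(np.rint(hu_ex), -1100, 3100).astype(np.int16)

    lung = LungMask(mask, params.spacing)
    pair = PairedScan(
        insp=CTVolume(hu_in, params.spacing),
        exp_reg=CTVolume(hu_ex, params.spacing),
        mask=lung,
    )
    # the field is drawn last, so skipping it leaves the HU stream intact
    fld = _displacement(labels, geo, truth, params, rng) if with_field else None
    return pair, lung, fld


def iter_cohort(n_copd: int, n_noncopd: int, params: PhantomParams, seed: int,
                *, with_fields: bool = True):
    """Yield ``Subject``s one at a time (memory-friendly for large cohorts).

    Subject order is all COPD first, then all non-COPD; each subject gets an
    independent child seed, so any prefix of the stream is reproducible.
    """
    if n_copd < 1 or n_noncopd < 1:
        raise ValueError("need at least one subject per group")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_copd + n_noncopd)
    groups = [COPD] * n_copd + [NON_COPD] * n_noncopd
    for i, (group, child) in enumerate(zip(groups, children)):
        rng = np.random.default_rng(child)
        truth = sample_subject(group, params, rng)
        pair, lung, fld = generate_paired_scan(truth, params, rng,
                                               with_field=with_fields)
        tag = "copd" if group == COPD else "ctrl"
        yield Subject(f"{tag}{i:04d}", truth, pair, lung, fld)


def iter_group(group: str, n: int, params: PhantomParams, seed: int,
               *, with_fields: bool = True):
    """Yield ``n`` subjects of a single group (for group-calibration studies)."""
    if n < 1:
        raise ValueError("need at least one subject")
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    ss = np.random.SeedSequence(seed)
    tag = "copd" if group == COPD else "ctrl"
    for i, child in enumerate(ss.spawn(n)):
        rng = np.random.default_rng(child)
        truth = sample_subject(group, params, rng)
        pair, lung, fld = generate_paired_scan(truth, params, rng,
                                               with_field=with_fields)
        yield Subject(f"{tag}{i:04d}", truth, pair, lung, fld)


def generate_cohort(n_copd: int, n_noncopd: int, params: PhantomParams,
                    seed: int, out_dir: str | Path | None = None) -> Cohort:
    """Generate a full in-memory cohort; optionally write volumes + manifest."""
    cohort = Cohort(list(iter_cohort(n_copd, n_noncopd, params, seed)), seed)
    if out_dir is not None:
        from . import io as pio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest = cohort.manifest
        paths = {"insp": [], "exp": [], "mask": [], "field": []}
        for s in cohort.subjects:
            base = out / s.subject_id
            pio.write_volume(s.pair.insp, f"{base}_in.nii.gz")
            pio.write_volume(s.pair.exp_reg, f"{base}_ex.nii.gz")
            pio.write_mask(s.mask, f"{base}_mask.nii.gz")
            pio.write_field(s.field, f"{base}_field.nii.gz")
            for k, suffix in zip(paths, ("in", "ex", "mask", "field")):
                paths[k].append(f"{s.subject_id}_{suffix}.nii.gz")
        for k, col in paths.items():
            manifest[f"path_{k}"] = col
        manifest.to_csv(out / "manifest.csv", index=False)
    return cohort
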