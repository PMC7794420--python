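import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from prm3d.deformation import (
    adi,
    air_fraction,
    deformation_gradient,
    delta_vair_f,
    jacobian,
    principal_stretches,
    sri,
)
from prm3d.io import CTVolume, DisplacementField, LungMask
from prm3d.prm import PairedScan


def _affine_field(A, shape=(12, 12, 12), spacing=(2.0, 2.0, 2.0)):
    idx = np.indices(shape, dtype=np.float64)
    pos = np.stack([idx[a] * spacing[a] for a in range(3)], axis=-1)
    u = pos @ (A - np.eye(3)).T
    return DisplacementField(u.astype(np.float32), spacing)


def test_zero_field_gives_identity():
    F = deformation_gradient(DisplacementField(np.zeros((8, 8, 8, 3), np.float32)))
    np.testing.assert_allclose(F, np.broadcast_to(np.eye(3), (8, 8, 8, 3, 3)),
                               atol=1e-12)


def test_affine_field_recovers_matrix_everywhere():
    A = np.diag([1.2, 1.1, 1.0])
    F = deformation_gradient(_affine_field(A))
    # exact for affine motion, including the one-sided boundary stencils
    np.testing.assert_allclose(F, np.broadcast_to(A, F.shape), atol=1e-5)


def test_gradient_converges_at_second_order():
    # smooth analytic field; halving h must shrink the error ~4x
    def field_on(shape, spacing):
        idx = np.indices(shape, dtype=np.float64)
        x, y, z = (idx[a] * spacing[a] for a in range(3))
        u = np.stack([np.sin(0.05 * x) * np.cos(0.05 * y),
                      0.5 * np.sin(0.05 * z),
                      0.1 * x * 0 + np.cos(0.05 * x) * 0.3], axis=-1)
        return DisplacementField(u.astype(np.float64), spacing), (x, y, z)

    def analytic_F(x, y, z):
        F = np.zeros(x.shape + (3, 3))
        F[..., 0, 0] = 1 + 0.05 * np.cos(0.05 * x) * np.cos(0.05 * y)
        F[..., 0, 1] = -0.05 * np.sin(0.05 * x) * np.sin(0.05 * y)
        F[..., 1, 2] = 0.5 * 0.05 * np.cos(0.05 * z)
        F[..., 1, 1] = 1.0
        F[..., 2, 0] = -0.3 * 0.05 * np.sin(0.05 * x)
        F[..., 2, 2] = 1.0
        return F

    errs = []
    for n, h in [(16, 4.0), (32, 2.0)]:
        fld, (x, y, z) = field_on((n, n, n), (h, h, h))
        interior = (slice(2, -2),) * 3
        err = np.abs(deformation_gradient(fld) - analytic_F(x, y, z))[interior]
        errs.append(err.max())
    assert errs[1] < errs[0] / 3.0


def test_jacobian_identity_and_uniform_scaling():
    F_id = np.broadcast_to(np.eye(3), (4, 4, 4, 3, 3))
    np.testing.assert_allclose(jacobian(F_id), 1.0)
    F_s = np.broadcast_to(1.2 * np.eye(3), (4, 4, 4, 3, 3))
    np.testing.assert_allclose(jacobian(F_s), 1.728, rtol=1e-12)


def test_principal_stretches_of_diagonal_and_rotated(rng):
    D = np.diag([1.5, 1.2, 0.9])
    lam = principal_stretches(D[None])
    np.testing.assert_allclose(lam[0], [1.5, 1.2, 0.9], atol=1e-12)
    R = Rotation.random(random_state=7).as_matrix()
    lam_rot = principal_stretches((R @ D)[None])
    np.testing.assert_allclose(lam_rot[0], [1.5, 1.2, 0.9], atol=1e-10)


def test_principal_stretches_match_svd_oracle(rng):
    F = np.eye(3) + 0.3 * rng.standard_normal((50, 3, 3))
    keep = jacobian(F) > 0.05
    F = F[keep]
    lam = principal_stretches(F)
    sv = np.linalg.svd(F, compute_uv=False)
    np.testing.assert_allclose(lam, sv, atol=1e-8)


def test_adi_closed_forms():
    assert adi(np.array([1.3, 1.3, 1.3])) == pytest.approx(0.0)
    assert adi(np.array([1.5, 1.0, 1.0])) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        adi(np.array([1.0, 0.5, 0.0]))


def test_sri_slab_and_rod_limits():
    # oblate (slab-like) deformation: lambda1 = lambda2 > lambda3
    assert sri(np.array([1.2, 1.2, 0.8])) == pytest.approx(0.0)
    # prolate (rod-like): lambda1 > lambda2 = lambda3
    assert sri(np.array([1.5, 1.0, 1.0])) == pytest.approx(1.0)
    assert 0.0 <= sri(np.array([1.5, 1.2, 0.9])) <= 1.0


def test_metrics_rotation_invariant(rng):
    F = np.eye(3) + 0.2 * rng.standard_normal((20, 3, 3))
    F = F[jacobian(F) > 0.1]
    R = Rotation.random(random_state=3).as_matrix()
    RF = np.einsum("ij,njk->nik", R, F)
    np.testing.assert_allclose(jacobian(RF), jacobian(F), atol=1e-10)
    np.testing.assert_allclose(adi(principal_stretches(RF)),
                               adi(principal_stretches(F)), atol=1e-8)
    np.testing.assert_allclose(sri(principal_stretches(RF)),
                               sri(principal_stretches(F)), atol=1e-8)


@pytest.mark.parametrize("hu, beta", [(-1000, 1.0), (55, 0.0), (-472.5, 0.5),
                                      (-1100, 1.0), (200, 0.0)])
def test_air_fraction_linear_map(hu, beta):
    assert air_fraction(hu) == pytest.approx(beta)


def test_delta_vair_identity_field_identical_volumes():
    hu = np.full((10, 10, 10), -800.0)
    pair = PairedScan(CTVolume(hu), CTVolume(hu.copy()),
                      LungMask(np.ones_like(hu, dtype=bool)))
    fld = DisplacementField(np.zeros(hu.shape + (3,), np.float32))
    np.testing.assert_allclose(delta_vair_f(pair, fld), 0.0, atol=1e-6)


def test_delta_vair_uniform_expansion_closed_form():
    # beta_in = 0.8 -> HU = 55 - 0.8*1055 = -789; beta_ex = 0.5 -> -472.5
    shape = (12, 12, 12)
    hu_in = np.full(shape, -789.0)
    hu_ex = np.full(shape, -472.5)
    pair = PairedScan(CTVolume(hu_in, (2, 2, 2)), CTVolume(hu_ex, (2, 2, 2)),
                      LungMask(np.ones(shape, dtype=bool), (2, 2, 2)))
    s = 1.5 ** (1 / 3)
    fld = _affine_field(s * np.eye(3), shape, (2.0, 2.0, 2.0))
    dv = delta_vair_f(pair, fld)
    interior = (slice(1, -1),) * 3
    np.testing.assert_allclose(dv[interior], 1.5 * 0.8 - 0.5, atol=1e-4)


def test_delta_vair_positive_on_inflating_phantom(copd_subject):
    dv = delta_vair_f(copd_subject.pair, copd_subject.field)
    assert dv[copd_subject.mask.voxels].mean() > 0


def test_degenerate_spacing_rejected():
    fld = DisplacementField(np.zeros((8, 8, 8, 3), np.float32))
    fld.spacing = (0.0, 1.0, 1.0)
    with pytest.raises(ValueError):
        deformation_gradient(fld)
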