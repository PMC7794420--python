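import numpy as np
import pytest

from prm3d.io import CTVolume, GeometryError, LungMask
from prm3d.prm import (
    CODE_EMPH,
    CODE_FSAD,
    CODE_NORMAL,
    PairedScan,
    PRMThresholds,
    classify_volume,
    classify_voxel,
    summarize,
)


@pytest.mark.parametrize(
    "hu_in, hu_ex, expected",
    [
        (-970, -900, CODE_EMPH),     # low at both breath holds
        (-940, -900, CODE_FSAD),     # air trapping only at expiration
        (-940, -800, CODE_NORMAL),   # above both cuts
        (-950, -856, CODE_EMPH),     # inclusive boundary on both cuts
        (-970, -800, CODE_NORMAL),   # implausible quadrant folds into normal
        (-950.0001, -856.0001, CODE_EMPH),
        (-949.9999, -856, CODE_FSAD),
    ],
)
def test_voxel_rule(hu_in, hu_ex, expected):
    assert classify_voxel(hu_in, hu_ex) == expected


def test_voxel_rule_rejects_non_finite():
    with pytest.raises(ValueError):
        classify_voxel(np.nan, -900)


def test_threshold_ordering_enforced():
    with pytest.raises(ValueError):
        PRMThresholds(insp_cut=-856, exp_cut=-950)


def _pair(hu_in, hu_ex, mask=None):
    hu_in = np.asarray(hu_in)
    if mask is None:
        mask = np.ones(hu_in.shape, dtype=bool)
    return PairedScan(CTVolume(hu_in), CTVolume(np.asarray(hu_ex)),
                      LungMask(mask))


def test_all_normal_volume():
    pair = _pair(np.full((8, 8, 8), -870.0), np.full((8, 8, 8), -780.0))
    prm = classify_volume(pair)
    assert (prm.codes == CODE_NORMAL).all()


def test_empty_mask_is_geometry_error():
    pair = _pair(np.full((8, 8, 8), -870.0), np.full((8, 8, 8), -780.0),
                 mask=np.zeros((8, 8, 8), dtype=bool))
    with pytest.raises(GeometryError):
        classify_volume(pair)


def test_geometry_mismatch_rejected():
    with pytest.raises(GeometryError):
        PairedScan(CTVolume(np.zeros((8, 8, 8))), CTVolume(np.zeros((8, 8, 9))),
                   LungMask(np.ones((8, 8, 8), dtype=bool)))


def test_volume_classifier_equals_voxel_loop(rng):
    hu_in = rng.uniform(-1050, -700, (8, 8, 8))
    hu_ex = rng.uniform(-1000, -600, (8, 8, 8))
    mask = rng.random((8, 8, 8)) > 0.3
    mask[0, 0, 0] = True
    pair = _pair(hu_in, hu_ex, mask)
    codes = classify_volume(pair).codes
    for idx in np.ndindex(8, 8, 8):
        if mask[idx]:
            assert codes[idx] == classify_voxel(hu_in[idx], hu_ex[idx])
        else:
            assert codes[idx] == 0


def test_summary_exact_counts():
    # hand-built 3x3x3: 5 emphysema, 4 fSAD, 18 normal voxels
    hu_in = np.full((3, 3, 3), -900.0)
    hu_ex = np.full((3, 3, 3), -800.0)
    flat_in = hu_in.reshape(-1)
    flat_ex = hu_ex.reshape(-1)
    flat_in[:5] = -970; flat_ex[:5] = -900        # Emph
    flat_ex[5:9] = -900                            # fSAD (IN stays -900)
    pair = _pair(hu_in, hu_ex)
    s = summarize(classify_volume(pair), pair)
    assert s.emph_pct == pytest.approx(100 * 5 / 27, abs=1e-9)
    assert s.fsad_pct == pytest.approx(100 * 4 / 27, abs=1e-9)
    assert s.normal_pct == pytest.approx(100 * 18 / 27, abs=1e-9)
    assert round(s.emph_pct, 2) == 18.52
    assert round(s.fsad_pct, 2) == 14.81
    assert round(s.normal_pct, 2) == 66.67


def test_percentages_sum_to_100(rng):
    hu_in = rng.uniform(-1050, -700, (10, 10, 10))
    hu_ex = rng.uniform(-1000, -600, (10, 10, 10))
    mask = rng.random((10, 10, 10)) > 0.4
    mask[0, 0, 0] = True
    pair = _pair(hu_in, hu_ex, mask)
    s = summarize(classify_volume(pair), pair)
    assert s.emph_pct + s.fsad_pct + s.normal_pct == pytest.approx(100, abs=1e-9)
    assert s.tlc_l >= 0 and s.frc_l >= 0


def test_threshold_monotonicity(rng):
    hu_in = rng.uniform(-1050, -700, (10, 10, 10))
    hu_ex = rng.uniform(-1000, -600, (10, 10, 10))
    pair = _pair(hu_in, hu_ex)
    base = summarize(classify_volume(pair, PRMThresholds()), pair)
    # more negative inspiratory cut can only shrink the emphysema class
    stricter = summarize(
        classify_volume(pair, PRMThresholds(-980, -856)), pair)
    assert stricter.emph_pct <= base.emph_pct
    # raising the expiratory cut can only grow fSAD + Emph together
    looser = summarize(classify_volume(pair, PRMThresholds(-950, -800)), pair)
    assert looser.fsad_pct + looser.emph_pct >= base.fsad_pct + base.emph_pct


def test_summary_permutation_invariance(rng):
    hu_in = rng.uniform(-1050, -700, (6, 6, 6))
    hu_ex = rng.uniform(-1000, -600, (6, 6, 6))
    mask = rng.random((6, 6, 6)) > 0.4
    mask[0, 0, 0] = True
    perm = rng.permutation(6 * 6 * 6)

    def apply(a):
        return a.reshape(-1)[perm].reshape(6, 6, 6)

    s1 = summarize(classify_volume(_pair(hu_in, hu_ex, mask)),
                   _pair(hu_in, hu_ex, mask))
    s2 = summarize(classify_volume(_pair(apply(hu_in), apply(hu_ex), apply(mask))),
                   _pair(apply(hu_in), apply(hu_ex), apply(mask)))
    assert s1.emph_pct == s2.emph_pct
    assert s1.fsad_pct == s2.fsad_pct
    assert s1.tlc_l == pytest.approx(s2.tlc_l)
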