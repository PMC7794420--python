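import numpy as np
import pytest
from scipy import stats

from prm3d.deformation import median_jacobian
from prm3d.phantom import (
    COPD,
    NON_COPD,
    GroupCalibration,
    PhantomParams,
    SubjectTruth,
    generate_paired_scan,
    iter_cohort,
    sample_subject,
    truncated_mean_calibrated,
)
from prm3d.prm import classify_volume, summarize


def _sd_free_params():
    return PhantomParams(calibration={
        COPD: GroupCalibration(8.5, 0.0, 23.7, 0.0, 1.5, 0.0),
        NON_COPD: GroupCalibration(1.7, 0.0, 11.2, 0.0, 1.7, 0.0),
    })


def test_sd_free_draws_hit_group_means_exactly(rng):
    p = _sd_free_params()
    t_non = sample_subject(NON_COPD, p, rng)
    assert t_non.emph_pct == pytest.approx(1.7)
    assert t_non.fsad_pct == pytest.approx(11.2)
    t_copd = sample_subject(COPD, p, rng)
    assert t_copd.fsad_pct == pytest.approx(23.7)
    assert t_copd.mean_j == pytest.approx(1.5)


def test_sampling_deterministic_given_seed(params):
    a = sample_subject(COPD, params, np.random.default_rng(5))
    b = sample_subject(COPD, params, np.random.default_rng(5))
    assert (a.emph_pct, a.fsad_pct, a.mean_j) == (b.emph_pct, b.fsad_pct, b.mean_j)


def test_unknown_group_rejected(params, rng):
    with pytest.raises(ValueError):
        sample_subject("asthma", params, rng)


def test_truncated_calibration_restores_nominal_mean():
    # plain truncation of N(1.7, 2.5) at 0 would push the mean to ~2.75;
    # the calibrated distribution keeps it at 1.7
    d = truncated_mean_calibrated(1.7, 2.5, 0.0, 60.0)
    assert d.mean() == pytest.approx(1.7, abs=1e-6)
    d2 = truncated_mean_calibrated(11.2, 13.4, 0.0, 60.0)
    assert d2.mean() == pytest.approx(11.2, abs=1e-6)
    assert d2.support()[0] >= 0.0


def test_nothing_planted_measures_clean(params, rng):
    truth = SubjectTruth(NON_COPD, 0.0, 0.0, 1.7)
    pair, mask, _ = generate_paired_scan(truth, params, rng)
    s = summarize(classify_volume(pair), pair)
    assert s.emph_pct < 0.5
    assert s.fsad_pct < 0.5


def test_planted_burden_recovered_by_prm(params, rng):
    truth = SubjectTruth(COPD, 10.0, 20.0, 1.5)
    pair, mask, _ = generate_paired_scan(truth, params, rng)
    s = summarize(classify_volume(pair), pair)
    assert s.emph_pct == pytest.approx(10.0, abs=1.5)
    assert s.fsad_pct == pytest.approx(20.0, abs=1.5)


def test_target_median_jacobian_recovered(params, rng):
    truth = SubjectTruth(COPD, 5.0, 10.0, 1.5)
    _, mask, field = generate_paired_scan(truth, params, rng)
    assert median_jacobian(field, mask) == pytest.approx(1.5, abs=0.05)


def test_capacity_error(params, rng):
    truth = SubjectTruth(COPD, 60.0, 35.0, 1.5)
    with pytest.raises(ValueError):
        generate_paired_scan(truth, params, rng)


def test_hu_within_physical_range(copd_subject):
    for vol in (copd_subject.pair.insp, copd_subject.pair.exp_reg):
        assert vol.voxels.min() >= -1100 and vol.voxels.max() <= 3100
        assert vol.voxels.dtype == np.int16


def test_cohort_labels_and_reproducibility(params):
    a = list(iter_cohort(1, 1, params, seed=21))
    assert [s.truth.group for s in a] == [COPD, NON_COPD]
    b = list(iter_cohort(1, 1, params, seed=21))
    np.testing.assert_array_equal(a[0].pair.insp.voxels, b[0].pair.insp.voxels)
    np.testing.assert_array_equal(a[0].field.vectors, b[0].field.vectors)
    c = list(iter_cohort(1, 1, params, seed=22))
    assert not np.array_equal(a[0].pair.insp.voxels, c[0].pair.insp.voxels)


def test_cohort_counts_validated(params):
    with pytest.raises(ValueError):
        list(iter_cohort(0, 1, params, seed=1))


def test_upper_lobe_bias_shifts_lesions(params):
    # with 2:1 weighting, COPD lesion centroids should sit high more often
    # than the upper third's volume share (~26%)
    rng = np.random.default_rng(77)
    truth = sample_subject(COPD, params, rng)
    truth.emph_pct, truth.fsad_pct = 10.0, 20.0
    _, mask, _ = generate_paired_scan(truth, params, rng)
    cents = np.array(truth.lesion_centroids)
    zs = np.argwhere(mask.voxels)[:, 2]
    z_cut = zs.min() + 2 * (zs.max() - zs.min()) / 3
    frac_upper = (cents[:, 2] >= z_cut).mean()
    assert frac_upper > 0.30


def test_params_validation():
    with pytest.raises(ValueError):
        PhantomParams(burden_range=(0, 70))
    with pytest.raises(ValueError):
        PhantomParams(j_range=(0.8, 3.0))
    with pytest.raises(ValueError):
        PhantomParams(calibration={COPD: GroupCalibration(8.5, -1, 23.7, 13.6, 1.5, 0.3),
                                   NON_COPD: GroupCalibration(1.7, 2.5, 11.2, 13.4, 1.7, 0.4)})
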