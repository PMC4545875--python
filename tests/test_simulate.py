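import numpy as np
import pytest

from hubshift.connectivity import pli_matrix, pli_null_quantiles
from hubshift.preprocessing import band_by_name, bandpass, instantaneous_phase
from hubshift.recording import EpochedRecording
from hubshift.simulate import (
    STUDY_GROUP_SIZES,
    SimulationSpec,
    calibrate_coupling,
    generate_cohort,
    simulate_subject,
    subject_rng,
)

ALPHA1 = "lower_alpha"
REGIONS = ("anterior", "central", "posterior")


def _spec(kappa, **kw):
    defaults = dict(
        bands=(ALPHA1,),
        base_coupling={(ALPHA1, r): kappa for r in REGIONS},
    )
    defaults.update(kw)
    return SimulationSpec(**defaults)


def _posterior_pli(rec, montage):
    band = band_by_name(ALPHA1)
    ph = instantaneous_phase(bandpass(rec.data, band, 500.0), band)
    v = pli_matrix(ph).values
    idx = montage.region_indices("posterior")
    return v[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)]


def test_spec_validation():
    with pytest.raises(ValueError, match="nonzero"):
        SimulationSpec(lag_seconds=0.0)
    with pytest.raises(ValueError, match="group_sizes"):
        SimulationSpec(group_sizes=(0, 1, 1, 1))
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        SimulationSpec(
            base_coupling={(ALPHA1, "posterior"): 0.9},
            severity_slope={(ALPHA1, "posterior"): 0.1},
        )


def test_default_spec_matches_study_shape():
    spec = SimulationSpec()
    assert sum(spec.group_sizes) == 451
    assert spec.n_epochs == 4 and spec.epoch_len == 4096
    assert spec.sampling_rate == 500.0


def test_spec_json_round_trip():
    spec = _spec(0.4, severity_slope={(ALPHA1, "posterior"): -0.05}, seed=9)
    assert SimulationSpec.from_json(spec.to_json()) == spec


def test_recording_shape_and_finiteness(montage19):
    rec = simulate_subject(_spec(0.5), 1, montage19, np.random.default_rng(0))
    assert rec.data.shape == (4, 19, 4096)
    assert np.all(np.isfinite(rec.data))
    assert rec.group == 1 and 0 <= rec.mmse <= 30 and rec.sex in (0, 1)


def test_determinism_same_seed(montage19):
    spec = _spec(0.4, group_sizes=(1, 1, 1, 1))
    a = simulate_subject(spec, 2, montage19, subject_rng(5, 2, 0))
    b = simulate_subject(spec, 2, montage19, subject_rng(5, 2, 0))
    np.testing.assert_array_equal(a.data, b.data)
    assert (a.sex, a.mmse) == (b.sex, b.mmse)


def test_pure_shared_driver_gives_pli_one(montage19):
    """kappa=1, no noise: every within-region pair has a constant nonzero
    phase offset, so PLI is exactly 1."""
    spec = _spec(1.0, noise_sd=0.0)
    rec = simulate_subject(spec, 0, montage19, np.random.default_rng(3))
    band = band_by_name(ALPHA1)
    ph = instantaneous_phase(bandpass(rec.data, band, 500.0), band)
    v = pli_matrix(ph).values
    for region in REGIONS:
        idx = montage19.region_indices(region)
        sub = v[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)]
        assert np.all(sub == 1.0)


def test_zero_coupling_matches_null_distribution(montage19):
    """kappa=0 everywhere: cross-channel PLI follows the band-matched
    finite-sample null (median agreement with the Monte-Carlo table)."""
    spec = _spec(0.0)
    vals = []
    for i in range(6):
        rec = simulate_subject(spec, 0, montage19, np.random.default_rng(40 + i))
        vals.append(_posterior_pli(rec, montage19))
    sim_median = np.median(np.concatenate(vals))
    null = pli_null_quantiles(
        4096, 4, 200, np.random.default_rng(1), band=band_by_name(ALPHA1)
    )
    assert abs(sim_median - null["0.5"]) / null["0.5"] < 0.25


def test_pli_monotone_in_kappa(montage19):
    """Paired-seed mean PLI is non-decreasing over a kappa grid."""
    grid = [0.0, 0.3, 0.6, 0.8, 1.0]
    means = []
    for kappa in grid:
        spec = _spec(kappa)
        vals = [
            _posterior_pli(
                simulate_subject(spec, 0, montage19, np.random.default_rng(7 + i)),
                montage19,
            ).mean()
            for i in range(4)
        ]
        means.append(np.mean(vals))
    assert all(b >= a - 0.005 for a, b in zip(means, means[1:]))
    assert means[grid.index(0.8)] > means[grid.index(0.3)]


def test_calibrate_upper_boundary(montage19):
    spec = _spec(0.5, noise_sd=0.0)
    k = calibrate_coupling(
        1.0, ALPHA1, spec, montage19, n_reps=2, rng=np.random.default_rng(0)
    )
    assert k == 1.0


def test_calibrate_below_floor_rejected(montage19):
    spec = _spec(0.5)
    with pytest.raises(ValueError, match="null floor"):
        calibrate_coupling(
            0.01, ALPHA1, spec, montage19, n_reps=2, rng=np.random.default_rng(0)
        )


def test_calibrate_recovers_target(montage19):
    """Bisection hits the published control-group level: re-simulation at
    kappa* stays within the stated +/-0.01 calibration tolerance."""
    spec = SimulationSpec()
    k = calibrate_coupling(
        0.274, ALPHA1, spec, montage19, n_reps=16, rng=np.random.default_rng(0)
    )
    from hubshift.simulate import _regional_band_pli

    check = _spec(0.35)
    check.base_coupling[(ALPHA1, "posterior")] = k
    sim = np.mean(
        [
            _regional_band_pli(
                simulate_subject(
                    check, 0, montage19, np.random.default_rng(10_000 + i)
                ),
                band_by_name(ALPHA1),
                montage19,
                "posterior",
            )
            for i in range(50)
        ]
    )
    assert sim == pytest.approx(0.274, abs=0.01)


def test_cohort_counts_and_determinism(montage19):
    spec = _spec(0.3, group_sizes=(2, 1, 1, 1), epoch_len=512, n_epochs=1)
    recs, table = generate_cohort(spec, montage19)
    assert len(recs) == 5 and len(table) == 5
    assert list(table["group"]) == [0, 0, 1, 2, 3]
    recs2, table2 = generate_cohort(spec, montage19)
    assert table.equals(table2)
    np.testing.assert_array_equal(recs[0].data, recs2[0].data)


def test_subject_data_invariant_to_group_sizes(montage19):
    """Per-subject substreams: the first severe subject is identical no
    matter how many controls precede it."""
    small = _spec(0.3, group_sizes=(1, 1, 1, 1), epoch_len=512, n_epochs=1)
    big = _spec(0.3, group_sizes=(3, 1, 1, 1), epoch_len=512, n_epochs=1)
    a = generate_cohort(small, montage19)[0][-1]
    b = generate_cohort(big, montage19)[0][-1]
    np.testing.assert_array_equal(a.data, b.data)


def test_covariates_match_group_presets(montage19):
    spec = _spec(
        0.2, group_sizes=(40, 40, 40, 40), epoch_len=256, n_epochs=1
    )
    _, table = generate_cohort(spec, montage19)
    means = table.groupby("group")["mmse"].mean()
    for g, target in enumerate((28.5, 25.8, 21.5, 15.4)):
        assert means[g] == pytest.approx(target, abs=1.5)
    female = table.groupby("group")["sex"].mean()
    assert female[1] < female[0]  # mild group has the lowest female share


def test_zero_slope_cohorts_show_no_trend(montage19):
    """With severity_slope = 0 the group trend on posterior lower-alpha
    PLI is non-significant at alpha = 0.05 in >= 90% of 20 replicates."""
    import statsmodels.api as sm

    non_sig = 0
    for rep in range(20):
        spec = _spec(
            0.5,
            group_sizes=(10, 10, 10, 10),
            epoch_len=1024,
            n_epochs=2,
            seed=rep,
        )
        rows = []
        for group in range(4):
            for i in range(10):
                rec = simulate_subject(
                    spec, group, montage19, subject_rng(rep, group, i)
                )
                band = band_by_name(ALPHA1)
                ph = instantaneous_phase(
                    bandpass(rec.data, band, 500.0), band
                )
                v = pli_matrix(ph).values
                idx = montage19.region_indices("posterior")
                pli = v[np.ix_(idx, idx)][np.triu_indices(7, 1)].mean()
                rows.append((group, rec.sex, pli))
        arr = np.array(rows)
        X = sm.add_constant(arr[:, :2])
        p = sm.OLS(np.log(arr[:, 2] + 1e-24), X).fit().pvalues[1]
        non_sig += p >= 0.05
    assert non_sig >= 18


def test_rejects_invalid_group(montage19):
    with pytest.raises(ValueError):
        simulate_subject(_spec(0.3), 4, montage19, np.random.default_rng(0))


def test_recording_epoch_duration():
    rec = EpochedRecording(
        subject_id="s",
        group=0,
        sex=0,
        mmse=30,
        sampling_rate=500.0,
        data=np.zeros((1, 2, 4096)),
    )
    assert rec.epoch_duration == 8.192
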