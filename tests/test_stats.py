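import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hubshift.montage import standard_montage
from hubshift.recording import EpochedRecording
from hubshift.stats import (
    LOG_OFFSET,
    log_transform,
    regional_amplitude,
    results_summary,
    spearman_mmse,
    spearman_threshold,
    trend_glm,
)


def _table(groups, values, sex=None, band="lower_alpha", region="posterior"):
    n = len(groups)
    sex = sex if sex is not None else [i % 2 for i in range(n)]
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "group": groups,
            "sex": sex,
            "mmse": np.linspace(15, 30, n),
            "band": band,
            "region": region,
            "pli": values,
            "bc": values,
            "com_x": np.zeros(n),
            "com_y": np.asarray(values, dtype=float),
            "amplitude": np.ones(n),
        }
    )


# -- log transform -------------------------------------------------------


def test_log_transform_values():
    assert log_transform(1.0) == pytest.approx(np.log(1 + LOG_OFFSET))
    assert log_transform(0.0) == pytest.approx(-24 * np.log(10), abs=1e-9)
    assert log_transform(0.0) == pytest.approx(-55.262, abs=1e-3)


def test_log_transform_monotone(rng):
    xs = np.sort(rng.uniform(0, 1, 50))
    ys = log_transform(xs)
    assert np.all(np.diff(ys) > 0)


def test_log_transform_rejects_negative():
    with pytest.raises(ValueError):
        log_transform(-0.1)


# -- trend model ---------------------------------------------------------


def test_perfect_linear_trend():
    groups = [0, 1, 2, 3] * 6
    y = 0.5 - 0.07 * np.array(groups)
    table = _table(groups, np.full(len(groups), 0.3))
    table["com_y"] = y
    res = trend_glm(table, "com_y", "lower_alpha", "posterior")
    assert res.slope == pytest.approx(-0.07, abs=1e-10)
    assert res.p_raw < 1e-12


def test_ols_matches_closed_form(rng):
    """Slope, and p on a 12-row table against the normal-equations
    matrix-algebra oracle."""
    groups = [0, 0, 0, 1, 1, 1, 2, 2, 2, 3, 3, 3]
    sex = [0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1]
    y = rng.uniform(0.1, 0.9, 12)
    table = _table(groups, y, sex=sex)
    res = trend_glm(table, "pli", "lower_alpha", "posterior")

    X = np.column_stack([np.ones(12), groups, sex])
    ylog = np.log(y + LOG_OFFSET)
    beta = np.linalg.solve(X.T @ X, X.T @ ylog)
    resid = ylog - X @ beta
    sigma2 = resid @ resid / (12 - 3)
    se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
    t = beta[1] / se
    p = 2 * sps.t.sf(abs(t), df=9)
    assert res.slope == pytest.approx(beta[1], abs=1e-10)
    assert res.p_raw == pytest.approx(p, abs=1e-12)


def test_trend_correction_factor():
    groups = [0, 1, 2, 3] * 5
    y = np.linspace(0.2, 0.4, 20)
    res = trend_glm(_table(groups, y), "pli", "lower_alpha", "posterior",
                    correction_factor=4.0)
    assert res.p_corrected == pytest.approx(min(1.0, res.p_raw * 4.0))
    assert res.p_corrected >= res.p_raw


def test_trend_errors():
    with pytest.raises(ValueError, match="3 distinct"):
        trend_glm(
            _table([0, 0, 1, 1], [0.1, 0.2, 0.3, 0.4]),
            "pli",
            "lower_alpha",
            "posterior",
        )
    with pytest.raises(ValueError, match="constant outcome"):
        trend_glm(
            _table([0, 1, 2, 3], [0.2] * 4),
            "pli",
            "lower_alpha",
            "posterior",
        )


# -- Spearman / thresholds -----------------------------------------------


def test_spearman_thresholds():
    assert spearman_threshold(merged=False) == 0.00042
    assert spearman_threshold(merged=True) == 0.00125


def test_spearman_perfect_monotone():
    groups = [1, 1, 2, 2, 3, 3, 1, 2]
    table = _table(groups, np.zeros(8))
    table["mmse"] = np.arange(8, dtype=float)
    table["pli"] = np.exp(table["mmse"])  # monotone, nonlinear
    rho, p, thr = spearman_mmse(
        table, "pli", "lower_alpha", "posterior", merged=True
    )
    assert rho == pytest.approx(1.0)
    assert thr == 0.00125


def test_spearman_within_group_mode():
    groups = [1] * 6 + [2] * 6
    table = _table(groups, np.linspace(0.1, 0.9, 12))
    rho, p, thr = spearman_mmse(
        table, "pli", "lower_alpha", "posterior", merged=False, group=1
    )
    assert thr == 0.00042
    with pytest.raises(ValueError):
        spearman_mmse(
            table, "pli", "lower_alpha", "posterior", merged=False, group=0
        )


def test_spearman_zero_variance_rejected():
    groups = [1, 2, 3, 1, 2, 3]
    table = _table(groups, [0.4] * 6)
    with pytest.raises(ValueError, match="zero-variance"):
        spearman_mmse(table, "pli", "lower_alpha", "posterior", merged=True)


# -- regional amplitude --------------------------------------------------


def test_unit_sinusoid_rms(montage19):
    t = np.arange(4096) / 500.0
    x = np.sin(2 * np.pi * 10 * t)
    data = np.tile(x, (2, 19, 1))
    rec = EpochedRecording("s", 0, 0, 30, 500.0, data)
    amps = regional_amplitude(rec, montage19)
    for region in ("anterior", "central", "posterior", "global"):
        assert amps[region] == pytest.approx(1 / np.sqrt(2), abs=1e-3)


def test_amplitude_homogeneity(montage19, rng):
    data = rng.standard_normal((2, 19, 512))
    a1 = regional_amplitude(EpochedRecording("s", 0, 0, 30, 500.0, data), montage19)
    a2 = regional_amplitude(
        EpochedRecording("s", 0, 0, 30, 500.0, 2 * data), montage19
    )
    for region in a1:
        assert a2[region] == pytest.approx(2 * a1[region])


def test_zero_signal_zero_amplitude(montage19):
    rec = EpochedRecording("s", 0, 0, 30, 500.0, np.zeros((1, 19, 64)))
    assert all(v == 0.0 for v in regional_amplitude(rec, montage19).values())


# -- summary report ------------------------------------------------------


def _cohort_table(rng, n_per_group=8, slope=0.0):
    rows = []
    for band in ("delta", "theta", "lower_alpha", "upper_alpha", "beta"):
        for region in ("anterior", "central", "posterior", "global"):
            for g in range(4):
                for i in range(n_per_group):
                    val = 0.3 + slope * g + 0.02 * rng.standard_normal()
                    rows.append(
                        {
                            "subject_id": f"g{g}s{i}",
                            "group": g,
                            "sex": i % 2,
                            "mmse": 20.0 + i,
                            "band": band,
                            "region": region,
                            "pli": max(val, 1e-3),
                            "bc": max(val, 1e-3),
                            "com_x": 0.01 * rng.standard_normal(),
                            "com_y": 0.01 * rng.standard_normal(),
                            "amplitude": 10.0,
                        }
                    )
    return pd.DataFrame(rows)


def test_summary_shape(rng):
    summary = results_summary(_cohort_table(rng))
    cells = summary[summary["region"] != "mass_center"]
    assert len(cells) == 20  # 5 bands x 4 regions
    mean_cols = [c for c in cells.columns if c.startswith("bc_mean_")]
    assert len(mean_cols) == 4  # x 20 rows = 80 BC cells
    assert len(summary[summary["region"] == "mass_center"]) == 10
    assert (summary["correction_factor"] == 4.0).all()


def test_summary_raw_means_log_inference(rng):
    """Group means are reported raw while the trend runs on logs: built so
    the raw means rise with severity but the log means fall."""
    rows = []
    for band in ("lower_alpha",):
        for region in ("anterior", "central", "posterior", "global"):
            for g in range(4):
                vals = [np.exp(-3.0 * (g + 1))] * 4 + [float(g + 1)]
                for i, v in enumerate(vals):
                    rows.append(
                        {
                            "subject_id": f"g{g}s{i}",
                            "group": g,
                            "sex": i % 2,
                            "mmse": 20.0,
                            "band": band,
                            "region": region,
                            "pli": v,
                            "bc": v,
                            "com_x": 0.001 * (i - 2),
                            "com_y": 0.001 * (i - 2) + 0.001 * g,
                            "amplitude": 1.0,
                        }
                    )
    summary = results_summary(pd.DataFrame(rows))
    row = summary[
        (summary["band"] == "lower_alpha") & (summary["region"] == "posterior")
    ].iloc[0]
    raw_means = [row[f"pli_mean_{g}"] for g in ("control", "mild", "moderate", "severe")]
    assert raw_means == sorted(raw_means)  # raw scale: increasing
    assert row["pli_slope"] < 0  # log scale: decreasing
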