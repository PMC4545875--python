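"""Group-trend inference, MMSE correlations and multiplicity control.

Severity trends are tested with an ordinary least-squares model per
(measure, band, region) cell,

    outcome ~ intercept + beta * group + gamma * sex,

where ``group`` is the ordinal severity code (controls=0, mild=1,
moderate=2, severe=3) entered as a continuous predictor; the "p for
trend" is the two-sided p-value on beta.  PLI and BC values are natural-
log transformed before modelling with an offset of 1e-24 to avoid zeros
(the reported group means stay on the raw scale); center-of-mass
coordinates are modelled untransformed since they are signed.

Multiplicity control is deliberately explicit.  The trend models use a
configurable Bonferroni factor (default 4, the number of groups), which
is always carried in the result so no report is ambiguous about the
correction applied.  The MMSE Spearman correlations divide 0.05 by the
number of tests: bands x regions x AD-groups x measures
(5*4*3*2 = 120 -> 0.00042) in within-group mode, and bands x regions x
measures (5*4*2 = 40 -> 0.00125) when the AD groups are merged; the
threshold is reported rounded to five decimal places.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .montage import Montage, REGION_NAMES
from .recording import EpochedRecording

__all__ = [
    "LOG_OFFSET",
    "log_transform",
    "TrendResult",
    "trend_glm",
    "spearman_mmse",
    "spearman_threshold",
    "regional_amplitude",
    "results_summary",
]

#: Offset added before the natural log so that exact zeros stay finite.
LOG_OFFSET = 1e-24

N_BANDS = 5
N_REGIONS = 4  # anterior, central, posterior, global
N_AD_GROUPS = 3
N_MEASURES = 2  # PLI and BC


def log_transform(x):
    """Natural log with the fixed 1e-24 offset; rejects negative input."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("log transform is defined for nonnegative values only")
    out = np.log(arr + LOG_OFFSET)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


@dataclass(frozen=True)
class TrendResult:
    measure: str
    band: str
    region: str
    slope: float
    p_raw: float
    correction_factor: float

    @property
    def p_corrected(self) -> float:
        return min(1.0, self.p_raw * self.correction_factor)


#: Measures that are log-transformed before the trend model.
_LOGGED_MEASURES = ("pli", "bc")


def trend_glm(
    table: pd.DataFrame,
    measure: str,
    band: str,
    region: str,
    correction_factor: float = 4.0,
) -> TrendResult:
    """OLS trend test for one (measure, band, region) cell.

    ``table`` is the tidy cohort table with one row per subject x band x
    region; center-of-mass measures (``com_x``, ``com_y``) are region-
    independent and selected from the rows of the requested band only.
    """
    sub = table[table["band"] == band]
    if measure not in ("com_x", "com_y"):
        sub = sub[sub["region"] == region]
    else:
        sub = sub.drop_duplicates("subject_id")
    if sub["group"].nunique() < 3:
        raise ValueError("trend test needs at least 3 distinct group values")
    y = sub[measure].to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError(f"non-finite outcome values in {measure}")
    if np.allclose(y, y[0]):
        raise ValueError(f"constant outcome {measure}; trend model undefined")
    if measure in _LOGGED_MEASURES:
        y = log_transform(y)
    sex = sub["sex"].to_numpy(dtype=float)
    cols = [sub["group"].to_numpy(dtype=float)]
    if sex.std() > 0:  # a zero-variance covariate carries no information
        cols.append(sex)
    X = sm.add_constant(np.column_stack(cols), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular design matrix")
    fit = sm.OLS(y, X).fit()
    return TrendResult(
        measure=measure,
        band=band,
        region=region,
        slope=float(fit.params[1]),
        p_raw=float(fit.pvalues[1]),
        correction_factor=float(correction_factor),
    )


def spearman_threshold(merged: bool) -> float:
    """Significance threshold for the MMSE correlations, reported rounded
    to five decimals: 0.05 / 120 -> 0.00042 within groups, 0.05 / 40 ->
    0.00125 with the AD groups merged."""
    n_tests = N_BANDS * N_REGIONS * N_MEASURES * (1 if merged else N_AD_GROUPS)
    return round(0.05 / n_tests, 5)


def spearman_mmse(
    table: pd.DataFrame,
    measure: str,
    band: str,
    region: str,
    merged: bool = False,
    group: int | None = None,
) -> tuple[float, float, float]:
    """Two-tailed Spearman correlation of a measure with MMSE over AD rows.

    In merged mode all three AD groups are pooled; otherwise ``group``
    selects one AD group (1, 2 or 3).  Returns (rho, p, threshold).
    """
    sub = table[(table["band"] == band) & (table["group"] > 0)]
    if measure not in ("com_x", "com_y"):
        sub = sub[sub["region"] == region]
    else:
        sub = sub.drop_duplicates("subject_id")
    if not merged:
        if group not in (1, 2, 3):
            raise ValueError("within-group mode needs group in {1, 2, 3}")
        sub = sub[sub["group"] == group]
    if len(sub) < 4:
        raise ValueError("Spearman correlation needs at least 4 rows")
    x = sub["mmse"].to_numpy(dtype=float)
    y = sub[measure].to_numpy(dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero-variance column in Spearman correlation")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p), spearman_threshold(merged)


def regional_amplitude(
    recording: EpochedRecording, montage: Montage
) -> dict[str, float]:
    """RMS amplitude (uV) per region: root-mean-square over samples and
    epochs per channel, averaged over the region's channels."""
    rms = np.sqrt(np.mean(recording.data**2, axis=(0, 2)))
    out = {"global": float(rms.mean())}
    for region in REGION_NAMES:
        idx = montage.region_indices(region)
        out[region] = float(rms[idx].mean())
    return out


def results_summary(
    table: pd.DataFrame,
    correction_factor: float = 4.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per band x region summary: raw group means (SD) of PLI and BC plus
    the p for trend of each measure, and per-band center-of-mass rows.

    Group means are computed on the raw scale; the trend tests run on
    log-transformed values (PLI, BC) per the modelling conventions
    above.  A cell is flagged significant when the Bonferroni-corrected
    p falls below ``alpha``; the correction factor used is recorded in
    every row.
    """
    from .recording import GROUP_NAMES

    rows = []
    bands = list(dict.fromkeys(table["band"]))
    regions = list(REGION_NAMES) + ["global"]
    for band in bands:
        for region in regions:
            sub = table[(table["band"] == band) & (table["region"] == region)]
            row: dict = {"band": band, "region": region}
            for measure in ("pli", "bc"):
                for g, gname in enumerate(GROUP_NAMES):
                    vals = sub.loc[sub["group"] == g, measure]
                    row[f"{measure}_mean_{gname}"] = vals.mean()
                    row[f"{measure}_sd_{gname}"] = vals.std(ddof=1)
                res = trend_glm(table, measure, band, region, correction_factor)
                row[f"{measure}_slope"] = res.slope
                row[f"{measure}_p_raw"] = res.p_raw
                row[f"{measure}_p_corrected"] = res.p_corrected
                row[f"{measure}_significant"] = res.p_corrected < alpha
            row["correction_factor"] = correction_factor
            rows.append(row)
        for measure in ("com_x", "com_y"):
            res = trend_glm(table, measure, band, "global", correction_factor)
            rows.append(
                {
                    "band": band,
                    "region": "mass_center",
                    f"{measure}_slope": res.slope,
                    f"{measure}_p_raw": res.p_raw,
                    f"{measure}_p_corrected": res.p_corrected,
                    f"{measure}_significant": res.p_corrected < alpha,
                    "correction_factor": correction_factor,
                }
            )
    return pd.DataFrame(rows)
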