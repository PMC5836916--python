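"""Measurement-side analysis of blood diffusion-MRI signal tables.

Operates on ROI-mean magnitude signals from a multi-channel sum-of-squares
reconstruction: noise-floor correction S_c = √(S_m² − N·σ²) (N = 6 for the
six-channel, half-signal-lower-elements coil model), exclusion of
measurements whose b = 400 s/mm² signal falls below √(10·N)·σ (SNR < √10),
three-b-value log-linear ADC fits, mono-exponential T2 fits, Pearson
correlation with critical-r gating and linear calibration against blood-count
covariates, paired comparison of monopolar vs flow-compensated ADCs, and the
blood-count → D_b calibration formulas for IVIM modeling.

Expected signal-table columns: ``sample_id, profile, TE_ms, T_ms, b_s_mm2,
direction, S_m, sigma``; blood counts: ``sample_id, hct, mcv_fl, hgb_g_dl``.
ADCs are reported in µm²/ms (1 µm²/ms = 1e-3 mm²/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "DEFAULT_NOISE_FACTOR",
    "BloodCount",
    "CalibrationResult",
    "AdcFit",
    "T2Fit",
    "noise_correct",
    "snr_exclusion_threshold",
    "exclude_low_snr",
    "fit_adc",
    "fit_t2",
    "critical_r",
    "correlate_and_regress",
    "compare_profiles",
    "predict_Db",
    "analyze_measurements",
]

#: Effective number of noise contributions in the sum-of-squares magnitude.
DEFAULT_NOISE_FACTOR = 6.0

GROUP_COLS = ["sample_id", "profile", "TE_ms", "T_ms"]


@dataclass(frozen=True)
class BloodCount:
    """Blood-count covariates: hematocrit (fraction), MCV (fL), HGB (g/dL)."""

    hct: float
    mcv: float
    hgb: float

    def __post_init__(self):
        # plausibility warnings only; pathological samples exist
        import warnings

        if not 0.2 <= self.hct <= 0.6:
            warnings.warn(f"hct={self.hct} outside the typical 0.2-0.6 range")
        if not 60.0 <= self.mcv <= 120.0:
            warnings.warn(f"mcv={self.mcv} fL outside the typical 60-120 range")
        if not 8.0 <= self.hgb <= 20.0:
            warnings.warn(f"hgb={self.hgb} g/dL outside the typical 8-20 range")


@dataclass
class CalibrationResult:
    """Pearson correlation and (gated) linear regression of ADC on a covariate."""

    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n: int
    r_crit: float

    @property
    def significant(self) -> bool:
        return abs(self.pearson_r) > self.r_crit


@dataclass
class AdcFit:
    adc: float  # µm²/ms
    ci95: float  # half-width, µm²/ms
    s0: float
    n_points: int
    b_used: tuple


@dataclass
class T2Fit:
    t2: float  # ms; inf if the signal does not decay
    ci95: float
    s0: float
    n_points: int
    flagged: bool


def noise_correct(S_m, sigma, n_factor: float = DEFAULT_NOISE_FACTOR):
    """Noise-floor correction S_c = √(max(0, S_m² − n_factor·σ²)).

    Returns (S_c, floored) where ``floored`` marks entries whose corrected
    square was negative and was clipped to zero.  Identity at σ = 0 and
    monotone in S_m; commutes with a common rescaling of S_m and σ.
    """
    S_m = np.asarray(S_m, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(S_m < 0.0) or np.any(sigma < 0.0):
        raise ValueError("S_m and sigma must be non-negative")
    sq = S_m**2 - n_factor * sigma**2
    floored = sq < 0.0
    S_c = np.sqrt(np.clip(sq, 0.0, None))
    if S_c.ndim == 0:
        return float(S_c), bool(floored)
    return S_c, floored


def snr_exclusion_threshold(n_factor: float = DEFAULT_NOISE_FACTOR) -> float:
    """Exclusion threshold in SNR units: S_c/(√n_factor·σ) < √10 ≈ 3.2."""
    return math.sqrt(10.0)


def exclude_low_snr(
    df: pd.DataFrame,
    n_factor: float = DEFAULT_NOISE_FACTOR,
    b_check: float = 400.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop ADC measurements whose corrected b = 400 s/mm² signal is below
    √(10·n_factor)·σ (i.e. SNR < √10), to avoid noise-floor ADC bias.

    One "measurement" is a (sample_id, profile, TE, T) group; the criterion is
    evaluated on the direction-averaged corrected signal at ``b_check``.
    Returns (retained rows, per-group exclusion report).
    """
    thresh_factor = math.sqrt(10.0 * n_factor)
    report_rows = []
    keep_keys = []
    for key, grp in df.groupby(GROUP_COLS, sort=False):
        at_b = grp[np.isclose(grp["b_s_mm2"], b_check)]
        if at_b.empty:
            raise ValueError(f"group {key} has no b = {b_check} s/mm² rows")
        S_m = at_b["S_m"].mean()
        sigma = at_b["sigma"].mean()
        S_c, _ = noise_correct(S_m, sigma, n_factor)
        excluded = bool(S_c < thresh_factor * sigma)
        report_rows.append(
            dict(zip(GROUP_COLS, key))
            | {
                "S_c_b400": S_c,
                "sigma": sigma,
                "snr": S_c / (math.sqrt(n_factor) * sigma) if sigma > 0 else math.inf,
                "excluded": excluded,
            }
        )
        if not excluded:
            keep_keys.append(key)
    report = pd.DataFrame(report_rows)
    kept = df.set_index(GROUP_COLS).loc[keep_keys].reset_index()
    return kept, report


def _loglinear_fit(xs: np.ndarray, ys: np.ndarray) -> tuple[float, float, float]:
    """OLS of ln(y) on x; returns (slope, intercept, 95% CI half-width of slope)."""
    n = xs.size
    res = sps.linregress(xs, np.log(ys))
    if n > 2:
        tcrit = sps.t.ppf(0.975, n - 2)
        ci = tcrit * res.stderr
    else:
        ci = math.nan
    return res.slope, res.intercept, ci


def fit_adc(group: pd.DataFrame, n_factor: float = DEFAULT_NOISE_FACTOR) -> AdcFit:
    """Three-b-value ADC for one (sample, profile, TE, T) measurement.

    Signals are noise-corrected, averaged over gradient directions (and b = 0
    repeats) per b-value, and fit log-linearly against b by unweighted OLS;
    the negative slope is the ADC, converted to µm²/ms.  Non-positive
    corrected signals are dropped; fewer than two usable b-values is an error.
    """
    S_c, _ = noise_correct(group["S_m"].to_numpy(), group["sigma"].to_numpy(), n_factor)
    tbl = pd.DataFrame({"b": group["b_s_mm2"].to_numpy(), "S_c": S_c})
    mean_per_b = tbl.groupby("b")["S_c"].mean()
    mean_per_b = mean_per_b[mean_per_b > 0.0]
    if len(mean_per_b) < 2:
        raise ValueError("fewer than two usable b-values after noise correction")
    bs = mean_per_b.index.to_numpy(dtype=float)
    slope, intercept, ci = _loglinear_fit(bs, mean_per_b.to_numpy())
    # slope is in (s/mm²)⁻¹ = mm²/s; report µm²/ms
    return AdcFit(
        adc=-slope * 1.0e3,
        ci95=ci * 1.0e3,
        s0=math.exp(intercept),
        n_points=len(mean_per_b),
        b_used=tuple(bs),
    )


def fit_t2(b0_rows: pd.DataFrame) -> T2Fit:
    """Mono-exponential T2 from unweighted (b = 0) signals across echo times.

    Log-linear least squares of the direction/repeat-averaged signal against
    TE; T2 = −1/slope in ms.  A non-decaying fit (slope ≥ 0) yields T2 = inf
    and is flagged.
    """
    at_b0 = b0_rows[np.isclose(b0_rows["b_s_mm2"], 0.0)]
    mean_per_te = at_b0.groupby("TE_ms")["S_m"].mean()
    if len(mean_per_te) < 3:
        raise ValueError("need b = 0 signals at >= 3 echo times")
    tes = mean_per_te.index.to_numpy(dtype=float)
    slope, intercept, ci = _loglinear_fit(tes, mean_per_te.to_numpy())
    if slope >= 0.0:
        return T2Fit(t2=math.inf, ci95=math.nan, s0=math.exp(intercept),
                     n_points=len(mean_per_te), flagged=True)
    t2 = -1.0 / slope
    # delta method: var(T2) = var(slope)/slope^4
    ci_t2 = ci / slope**2 if math.isfinite(ci) else math.nan
    return T2Fit(t2=t2, ci95=ci_t2, s0=math.exp(intercept),
                 n_points=len(mean_per_te), flagged=False)


def critical_r(df_resid: int, alpha: float = 0.05) -> float:
    """Critical Pearson correlation |r| for two-sided significance at ``alpha``:
    r_crit = t_{α/2,df}/√(df + t²) with df = n − 2 residual degrees of freedom."""
    if df_resid < 1:
        raise ValueError("need at least one residual degree of freedom")
    t = sps.t.ppf(1.0 - alpha / 2.0, df_resid)
    return float(t / math.sqrt(df_resid + t * t))


def correlate_and_regress(x, y, alpha: float = 0.05) -> CalibrationResult:
    """Pearson correlation with the critical-r gate, then linear regression.

    The two-sided p-value uses the exact t transform with df = n − 2.  Slope
    and intercept are filled only when |r| > r_crit (NaN otherwise), matching
    the protocol of regressing only significantly correlated pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    n = x.size
    r_crit = critical_r(n - 2, alpha)
    if abs(r) > r_crit:
        reg = sps.linregress(x, y)
        slope, intercept = reg.slope, reg.intercept
    else:
        slope = intercept = math.nan
    return CalibrationResult(
        slope=slope, intercept=intercept, pearson_r=float(r), p_value=float(p),
        n=n, r_crit=r_crit,
    )


def compare_profiles(adc_mp, adc_fc) -> tuple[float, float]:
    """Paired two-sided t-test of monopolar vs flow-compensated ADCs.

    Returns (t, p); (nan, nan) for degenerate all-equal pairs.
    """
    a = np.asarray(adc_mp, dtype=float)
    b = np.asarray(adc_fc, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("need equal-length pairings with n >= 2")
    if np.std(a - b) == 0.0:
        return math.nan, math.nan
    t, p = sps.ttest_rel(a, b)
    return float(t), float(p)


#: Published calibration formulas for the blood self-diffusion constant D_b
#: (µm²/ms), per gradient profile: value = intercept + (ref − covariate)·slope.
_DB_CALIBRATIONS = {
    ("MP", "HCT"): (1.307, 0.42, 2.846),
    ("FC", "HCT"): (1.545, 0.42, 2.169),
    ("MP", "HGB"): (1.312, 14.5, 0.087),
    ("FC", "HGB"): (1.551, 14.5, 0.053),
}

#: Profile-average recommendations with sample spreads, used without a count.
_DB_DEFAULTS = {"MP": (1.30, 0.18), "FC": (1.54, 0.12)}


def predict_Db(
    profile: str,
    hct: float | None = None,
    hgb: float | None = None,
    count: BloodCount | None = None,
) -> tuple[float, float | None]:
    """Blood self-diffusion constant D_b (µm²/ms) for IVIM modeling.

    With a hematocrit (preferred) or hemoglobin covariate, evaluates the
    published linear calibration for the given gradient profile; with neither,
    returns the profile-average recommendation.  Returns (D_b, spread) where
    ``spread`` is the quoted ± sample spread for the covariate-free constants
    and None for calibrated predictions.
    """
    kind = profile.upper()
    if kind not in _DB_DEFAULTS:
        raise ValueError(f"unknown profile kind {profile!r} (expected 'MP' or 'FC')")
    if count is not None:
        hct = count.hct if hct is None else hct
        hgb = count.hgb if hgb is None else hgb
    if hct is not None:
        intercept, ref, slope = _DB_CALIBRATIONS[(kind, "HCT")]
        return intercept + (ref - hct) * slope, None
    if hgb is not None:
        intercept, ref, slope = _DB_CALIBRATIONS[(kind, "HGB")]
        return intercept + (ref - hgb) * slope, None
    value, spread = _DB_DEFAULTS[kind]
    return value, spread


def analyze_measurements(
    signals: pd.DataFrame,
    counts: pd.DataFrame | None = None,
    n_factor: float = DEFAULT_NOISE_FACTOR,
) -> dict:
    """Full measurement pipeline on a signal table (plus optional blood counts).

    Applies the low-SNR exclusion, fits one ADC per retained (sample, profile,
    TE, T) measurement and one T2 per (sample, profile) TE series, compares
    MP vs FC per-sample mean ADCs, and — when blood counts are supplied —
    correlates/regresses per-sample mean ADCs against HCT, MCV and HGB.
    Returns a dict with keys ``adc`` (DataFrame), ``t2`` (DataFrame),
    ``exclusions`` (DataFrame), ``profile_comparison`` (dict) and
    ``calibrations`` (dict of CalibrationResult, present with counts).
    """
    kept, report = exclude_low_snr(signals, n_factor)
    adc_rows = []
    for key, grp in kept.groupby(GROUP_COLS, sort=False):
        fit = fit_adc(grp, n_factor)
        adc_rows.append(
            dict(zip(GROUP_COLS, key))
            | {"adc": fit.adc, "ci95": fit.ci95, "s0": fit.s0}
        )
    adc_df = pd.DataFrame(adc_rows)

    t2_rows = []
    for (sample, profile), grp in signals.groupby(["sample_id", "profile"], sort=False):
        if np.isclose(grp["b_s_mm2"], 0.0).any() and grp["TE_ms"].nunique() >= 3:
            fit = fit_t2(grp)
            t2_rows.append(
                {"sample_id": sample, "profile": profile, "t2_ms": fit.t2,
                 "ci95": fit.ci95, "flagged": fit.flagged}
            )
    t2_df = pd.DataFrame(t2_rows)

    out: dict = {"adc": adc_df, "t2": t2_df, "exclusions": report}

    per_sample = (
        adc_df.groupby(["sample_id", "profile"])["adc"].mean().unstack("profile")
        if not adc_df.empty
        else pd.DataFrame()
    )
    if {"MP", "FC"}.issubset(per_sample.columns):
        paired = per_sample.dropna(subset=["MP", "FC"])
        if len(paired) >= 2 and np.std(paired["MP"] - paired["FC"]) > 0:
            t, p = compare_profiles(paired["MP"], paired["FC"])
            out["profile_comparison"] = {"t": t, "p": p, "n": len(paired)}

    if counts is not None and not per_sample.empty:
        merged = per_sample.join(counts.set_index("sample_id"), how="inner")
        calib = {}
        for profile in per_sample.columns:
            for cov in ("hct", "mcv_fl", "hgb_g_dl"):
                sub = merged.dropna(subset=[profile, cov])
                if len(sub) >= 3:
                    calib[(profile, cov)] = correlate_and_regress(sub[cov], sub[profile])
        out["calibrations"] = calib
    return out
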