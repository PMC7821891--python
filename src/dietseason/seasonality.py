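"""Harmonic-regression seasonality of prices and diet costs.

A single annual harmonic is fitted to a monthly series (log scale for
prices and diet costs, level scale for kcal or cost components)::

    ln(C_kt) = b0 + bs*sin(2*pi*t/12) + bc*cos(2*pi*t/12)
               + cubic trend in t + crop-year fixed effects + e_kt

for market ``k`` and month ``t``.  The sin/cos coefficients give the
seasonal amplitude ``A = sqrt(bs^2 + bc^2)`` and peak month
``P = (12/2pi) * atan2(bs, bc)`` mapped to (0, 12] (so the component
``A*cos(2pi(t-P)/12)`` peaks at calendar month ``P``).  Delta-method
variances::

    Var(A)   = (s_s^2 bs^2 + s_c^2 bc^2 + 2 s_sc bs bc) / (bs^2 + bc^2)
    Var(phi) = (s_s^2 bc^2 + s_c^2 bs^2 - 2 s_sc bs bc) / (bs^2 + bc^2)^2
    Var(P)   = (12/2pi)^2 Var(phi)

where (s_s^2, s_c^2, s_sc) is the covariance of (bs, bc).  The sign of
the cross term in Var(phi) follows the analytic gradient of
``phi = -arctan(bs/bc)``; ``published_phase_var=True`` flips it to the
published form.  Seasonal intensity is ``exp(2A) - 1`` on the log scale
(peak-to-nadir excess as a fraction of the nadir, reported in percent)
and ``2A`` on the level scale; 95% confidence intervals use the 1.96
normal constant, and seasonality is significant when the intensity CI
excludes zero.

Multi-market panels are fitted with a linear mixed model (random
intercept and independent random sin/cos coefficients by market, REML);
single-market series use ordinary least squares.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from sklearn.base import BaseEstimator

__all__ = [
    "HarmonicFit",
    "SeasonalityEstimate",
    "HarmonicSeasonality",
    "MonthlyIndicatorModel",
    "fit_harmonic",
    "amplitude_peak",
    "intensity",
    "fit_monthly_indicator",
    "seasonality_table",
]

Z95 = 1.96
OMEGA = 2.0 * np.pi / 12.0


@dataclass
class HarmonicFit:
    """Coefficients and (bs, bc) covariance of one harmonic regression."""

    beta0: float
    beta_s: float
    beta_c: float
    cov: np.ndarray              # 2x2 covariance of (beta_s, beta_c)
    scale: str                   # "log" | "level"
    n_obs: int
    estimator: str               # "ols" | "mixed" | "ols_cluster"
    trend: np.ndarray | None = None
    crop_year_effects: dict | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.cov = np.asarray(self.cov, dtype=float)
        if self.cov.shape != (2, 2):
            raise ValueError("cov must be the 2x2 covariance of (beta_s, beta_c)")
        if self.cov[0, 0] < 0 or self.cov[1, 1] < 0:
            raise ValueError("negative coefficient variances")

    def seasonal_component(self, month) -> np.ndarray:
        m = np.asarray(month, dtype=float)
        return self.beta_s * np.sin(OMEGA * m) + self.beta_c * np.cos(OMEGA * m)


@dataclass
class SeasonalityEstimate:
    """Amplitude, peak timing and intensity with delta-method uncertainty."""

    amplitude: float
    var_amplitude: float
    peak_month: float | None      # in (0, 12]; None when bs = bc = 0
    var_peak: float | None
    intensity: float              # percent (log scale) or 2A (level scale)
    intensity_ci: tuple[float, float]
    peak_ci: tuple[float, float] | None
    significant: bool
    scale: str

    @property
    def peak_defined(self) -> bool:
        return self.peak_month is not None


def _crop_year(year: np.ndarray, month: np.ndarray, start_month: int) -> np.ndarray:
    """Crop-year label: the calendar year in which the crop year begins."""
    return np.where(month >= start_month, year, year - 1)


def _prepare(
    data: pd.DataFrame, scale: str, crop_year_start_month: int
) -> pd.DataFrame:
    for col in ("year", "month", "value"):
        if col not in data.columns:
            raise ValueError(f"series needs a {col!r} column")
    d = data.copy()
    if "market" not in d.columns:
        d["market"] = "all"
    d = d.dropna(subset=["value"])
    if scale == "log":
        if (d["value"] <= 0).any():
            raise ValueError("log scale requires strictly positive values")
        d["y"] = np.log(d["value"].to_numpy(dtype=float))
    elif scale == "level":
        d["y"] = d["value"].astype(float)
    else:
        raise ValueError("scale must be 'log' or 'level'")
    # t = 1 at January of the first observed year, so phase is calendar-anchored
    t = (d["year"] - d["year"].min()) * 12 + d["month"]
    d["t"] = t.astype(float)
    d["sin_t"] = np.sin(OMEGA * d["t"])
    d["cos_t"] = np.cos(OMEGA * d["t"])
    u = (d["t"] - d["t"].mean()) / max(d["t"].std(ddof=0), 1.0)
    d["u1"], d["u2"], d["u3"] = u, u**2, u**3
    d["crop_year"] = _crop_year(
        d["year"].to_numpy(), d["month"].to_numpy(), crop_year_start_month
    )
    return d


def fit_harmonic(
    data: pd.DataFrame,
    scale: str = "log",
    crop_year_start_month: int = 5,
    estimator: str = "auto",
    min_obs: int = 24,
) -> HarmonicFit:
    """Fit the annual harmonic model to one monthly series.

    ``data`` is tidy with columns year, month, value and (optionally)
    market.  ``estimator="auto"`` uses a mixed model when more than one
    market is present and OLS otherwise; "ols" pools all observations.
    """
    d = _prepare(data, scale, crop_year_start_month)
    if len(d) < min_obs:
        raise ValueError(
            f"need at least {min_obs} monthly observations, got {len(d)}"
        )
    n_markets = d["market"].nunique()
    use_mixed = estimator == "mixed" or (estimator == "auto" and n_markets > 1)

    fixed = "y ~ sin_t + cos_t + u1 + u2 + u3"
    crop_years = np.sort(d["crop_year"].unique())
    if len(crop_years) >= 2:
        fixed += " + C(crop_year)"

    converged = True
    est_used = "mixed" if use_mixed else "ols"
    if use_mixed:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(
                    fixed,
                    data=d,
                    groups=d["market"],
                    re_formula="1",
                    vc_formula={"sin": "0 + sin_t", "cos": "0 + cos_t"},
                )
                res = model.fit(reml=True)
            if not getattr(res, "converged", True):
                raise RuntimeError("mixed model did not converge")
        except Exception:
            # documented fallback: pooled OLS with cluster-robust errors
            res = smf.ols(fixed, data=d).fit(
                cov_type="cluster", cov_kwds={"groups": d["market"]}
            )
            est_used = "ols_cluster"
            converged = False
    else:
        res = smf.ols(fixed, data=d).fit()

    params = res.params
    cov_all = res.cov_params()
    cov = cov_all.loc[["sin_t", "cos_t"], ["sin_t", "cos_t"]].to_numpy()
    trend = np.array([params.get("u1", 0.0), params.get("u2", 0.0), params.get("u3", 0.0)])
    cy = {
        name: float(val)
        for name, val in params.items()
        if name.startswith("C(crop_year)")
    }
    return HarmonicFit(
        beta0=float(params["Intercept"]),
        beta_s=float(params["sin_t"]),
        beta_c=float(params["cos_t"]),
        cov=cov,
        scale=scale,
        n_obs=len(d),
        estimator=est_used,
        trend=trend,
        crop_year_effects=cy,
        converged=converged,
    )


def amplitude_peak(
    fit: HarmonicFit, published_phase_var: bool = False
) -> tuple[float, float, float | None, float | None]:
    """Amplitude, peak month (0, 12] and their delta-method variances.

    Returns ``(A, Var(A), P, Var(P))``; ``P`` is None (undefined) when
    both seasonal coefficients are exactly zero.
    """
    bs, bc = fit.beta_s, fit.beta_c
    s2_s, s2_c = fit.cov[0, 0], fit.cov[1, 1]
    s_sc = fit.cov[0, 1]
    a2 = bs * bs + bc * bc
    if a2 == 0.0:
        return 0.0, float(s2_s), None, None
    amp = float(np.sqrt(a2))
    var_a = (s2_s * bs * bs + s2_c * bc * bc + 2.0 * s_sc * bs * bc) / a2
    cross = 2.0 * s_sc * bs * bc
    if not published_phase_var:
        cross = -cross
    var_phi = (s2_s * bc * bc + s2_c * bs * bs + cross) / (a2 * a2)
    peak = (12.0 / (2.0 * np.pi)) * np.arctan2(bs, bc) % 12.0
    if peak == 0.0:
        peak = 12.0
    var_p = (12.0 / (2.0 * np.pi)) ** 2 * var_phi
    return amp, float(var_a), float(peak), float(var_p)


def intensity(
    amplitude: float, var_amplitude: float, scale: str = "log", z: float = Z95
) -> tuple[float, tuple[float, float]]:
    """Seasonal intensity with its 95% confidence interval.

    Log scale: ``(exp(2A) - 1) * 100`` percent of the nadir, CI obtained
    by transforming the amplitude CI endpoints.  Level scale: ``2A`` in
    the variable's units.
    """
    if var_amplitude < 0:
        raise ValueError("negative amplitude variance")
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    se = float(np.sqrt(var_amplitude))
    lo, hi = amplitude - z * se, amplitude + z * se
    if scale == "log":
        val = (np.exp(2.0 * amplitude) - 1.0) * 100.0
        ci = ((np.exp(2.0 * lo) - 1.0) * 100.0, (np.exp(2.0 * hi) - 1.0) * 100.0)
    elif scale == "level":
        val = 2.0 * amplitude
        ci = (2.0 * lo, 2.0 * hi)
    else:
        raise ValueError("scale must be 'log' or 'level'")
    return float(val), (float(ci[0]), float(ci[1]))


def summarize(fit: HarmonicFit, published_phase_var: bool = False,
              z: float = Z95) -> SeasonalityEstimate:
    """Full seasonality summary (amplitude, peak, intensity, CIs) of a fit."""
    amp, var_a, peak, var_p = amplitude_peak(fit, published_phase_var)
    val, ci = intensity(amp, var_a, fit.scale, z)
    if peak is None:
        peak_ci = None
    else:
        half = z * float(np.sqrt(max(var_p, 0.0)))
        peak_ci = (peak - half, peak + half)
    return SeasonalityEstimate(
        amplitude=amp,
        var_amplitude=var_a,
        peak_month=peak,
        var_peak=var_p,
        intensity=val,
        intensity_ci=ci,
        peak_ci=peak_ci,
        significant=bool(ci[0] > 0.0),
        scale=fit.scale,
    )


class HarmonicSeasonality(BaseEstimator):
    """sklearn-style estimator for annual harmonic seasonality.

    ``fit`` accepts a tidy DataFrame (columns year, month, value and
    optionally market) and exposes the coefficients, amplitude, peak
    month, intensity and significance as fitted attributes.
    """

    def __init__(
        self,
        scale: str = "log",
        crop_year_start_month: int = 5,
        estimator: str = "auto",
        published_phase_var: bool = False,
        min_obs: int = 24,
    ):
        self.scale = scale
        self.crop_year_start_month = crop_year_start_month
        self.estimator = estimator
        self.published_phase_var = published_phase_var
        self.min_obs = min_obs

    def fit(self, X: pd.DataFrame, y=None) -> "HarmonicSeasonality":
        fit = fit_harmonic(
            X,
            scale=self.scale,
            crop_year_start_month=self.crop_year_start_month,
            estimator=self.estimator,
            min_obs=self.min_obs,
        )
        est = summarize(fit, self.published_phase_var)
        self.fit_ = fit
        self.estimate_ = est
        self.beta0_ = fit.beta0
        self.beta_s_ = fit.beta_s
        self.beta_c_ = fit.beta_c
        self.cov_ = fit.cov
        self.n_obs_ = fit.n_obs
        self.estimator_used_ = fit.estimator
        self.converged_ = fit.converged
        self.amplitude_ = est.amplitude
        self.var_amplitude_ = est.var_amplitude
        self.peak_month_ = est.peak_month
        self.var_peak_ = est.var_peak
        self.intensity_ = est.intensity
        self.intensity_ci_ = est.intensity_ci
        self.peak_ci_ = est.peak_ci
        self.significant_ = est.significant
        return self

    def predict_seasonal(self, month) -> np.ndarray:
        """Fitted seasonal component (log or level units) at given months."""
        return self.fit_.seasonal_component(month)


class MonthlyIndicatorModel(BaseEstimator):
    """Calendar-month dummy comparator to the harmonic model.

    Regresses the (log or level) series on 11 month indicators with
    November as the base month, plus a cubic trend; used to check the
    harmonic fit's peak timing against an unrestricted monthly pattern.
    """

    def __init__(self, scale: str = "log", base_month: int = 11, min_obs: int = 24):
        self.scale = scale
        self.base_month = base_month
        self.min_obs = min_obs

    def fit(self, X: pd.DataFrame, y=None) -> "MonthlyIndicatorModel":
        d = _prepare(X, self.scale, crop_year_start_month=5)
        if len(d) < self.min_obs:
            raise ValueError(
                f"need at least {self.min_obs} monthly observations, got {len(d)}"
            )
        present = set(d["month"].unique())
        missing = sorted(set(range(1, 13)) - present)
        if missing:
            raise ValueError(f"calendar months missing entirely from data: {missing}")
        d["month_c"] = pd.Categorical(d["month"], categories=list(range(1, 13)))
        formula = (
            f"y ~ C(month_c, Treatment(reference={self.base_month})) + u1 + u2 + u3"
        )
        res = smf.ols(formula, data=d).fit()
        effects = pd.Series(0.0, index=pd.RangeIndex(1, 13, name="month"))
        prefix = f"C(month_c, Treatment(reference={self.base_month}))"
        for name, val in res.params.items():
            if name.startswith(prefix):
                match = re.search(r"\[T\.([0-9.]+)\]", name)
                effects.loc[int(float(match.group(1)))] = float(val)
        self.month_effects_ = effects
        self.intercept_ = float(res.params["Intercept"])
        self.peak_month_ = int(effects.idxmax())
        self.n_obs_ = len(d)
        self.result_ = res
        return self

    def fitted_monthly_means(self) -> pd.Series:
        """Trend-free fitted value for each calendar month."""
        return self.intercept_ + self.month_effects_


def fit_monthly_indicator(
    data: pd.DataFrame, scale: str = "log", base_month: int = 11
) -> MonthlyIndicatorModel:
    return MonthlyIndicatorModel(scale=scale, base_month=base_month).fit(data)


def seasonality_table(
    data: pd.DataFrame,
    by: str | list[str] = "key",
    scale: str = "log",
    crop_year_start_month: int = 5,
    estimator: str = "auto",
    published_phase_var: bool = False,
    location: str = "national",
) -> pd.DataFrame:
    """Seasonality estimates for every series in a keyed panel.

    ``data`` is tidy with the grouping column(s) ``by`` plus year, month,
    value and optionally market.  One output row per group; rows whose
    fit fails carry a status message instead of being dropped.
    """
    by_cols = [by] if isinstance(by, str) else list(by)
    rows = []
    for key, grp in data.groupby(by_cols, sort=True):
        key_vals = key if isinstance(key, tuple) else (key,)
        row: dict = dict(zip(by_cols, key_vals))
        row["location"] = location
        try:
            model = HarmonicSeasonality(
                scale=scale,
                crop_year_start_month=crop_year_start_month,
                estimator=estimator,
                published_phase_var=published_phase_var,
            ).fit(grp)
            row.update(
                n=model.n_obs_,
                beta_s=model.beta_s_,
                beta_c=model.beta_c_,
                amplitude=model.amplitude_,
                var_amplitude=model.var_amplitude_,
                peak_month=model.peak_month_,
                var_peak=model.var_peak_,
                intensity=model.intensity_,
                ci_low=model.intensity_ci_[0],
                ci_high=model.intensity_ci_[1],
                significant=model.significant_,
                estimator=model.estimator_used_,
                status="ok",
            )
        except (ValueError, KeyError) as exc:
            row.update(n=len(grp), significant=False, status=f"failed: {exc}")
        rows.append(row)
    return pd.DataFrame(rows)
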