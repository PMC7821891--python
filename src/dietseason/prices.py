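"""Retail price panels: data model, cleaning and currency normalisation.

The central container is a long-format panel of monthly retail prices —
one row per (market, year, month, item) holding a price in local currency
units (LCU) per kg edible matter.  Cleaning replaces extreme prices by a
winsorization cutpoint on price/median ratios; purchasing-power-parity
(PPP) conversion turns nominal daily diet costs into constant
international dollars, after smoothing the annual PPP factors into a
monthly series with an additive Denton least-squares benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diets import NutrientComposition

PANEL_COLUMNS = ["market", "year", "month", "item", "price_lcu_per_kg"]
KEY_COLUMNS = ["market", "year", "month", "item"]


@dataclass
class PricePanel:
    """Long-format market x month x item nominal retail prices.

    ``data`` columns: market, year, month (1-12), item,
    price_lcu_per_kg (> 0).  Duplicate (market, year, month, item) keys
    are a hard error: the source statistics offices already reduce to one
    value per market-month.
    """

    data: pd.DataFrame
    currency: str = "LCU"
    crop_year_start_month: int = 5

    def __post_init__(self) -> None:
        missing = [c for c in PANEL_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"price panel missing columns: {missing}")
        self.data = self.data[PANEL_COLUMNS].copy()
        self.validate()

    def validate(self) -> None:
        d = self.data
        if not d["month"].between(1, 12).all():
            raise ValueError("month must be in 1..12")
        if (d["price_lcu_per_kg"] <= 0).any() or d["price_lcu_per_kg"].isna().any():
            raise ValueError("prices must be positive and non-missing")
        dup = d.duplicated(subset=KEY_COLUMNS)
        if dup.any():
            keys = d.loc[dup, KEY_COLUMNS].head(5).to_dict("records")
            raise ValueError(f"duplicate (market, year, month, item) keys, e.g. {keys}")
        if not (1 <= self.crop_year_start_month <= 12):
            raise ValueError("crop_year_start_month must be in 1..12")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def items(self) -> np.ndarray:
        return self.data["item"].unique()

    @property
    def markets(self) -> np.ndarray:
        return self.data["market"].unique()

    def market_months(self) -> pd.DataFrame:
        return self.data[["market", "year", "month"]].drop_duplicates()

    @classmethod
    def from_csv(cls, path, **meta) -> "PricePanel":
        return cls(pd.read_csv(path), **meta)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class WinsorizationReport:
    n_replaced: int
    cutpoint: float
    upper_tail: float
    per_item: bool
    lower_tail: float | None = None
    lower_cutpoint: float | None = None


class Winsorizer:
    """Cap extreme prices at a quantile of price/median-per-item ratios.

    Each record's ratio to its item's median price is computed; records
    whose ratio exceeds the (1 - upper_tail) quantile of all ratios are
    replaced by cutpoint x median(item).  By default the cutpoint is taken
    over ratios pooled across items (a per-item quantile is ill-defined for
    thin items); ``per_item=True`` switches to per-item cutpoints.

    sklearn-style: ``fit`` learns medians and cutpoint(s), ``transform``
    caps prices, so a frozen cutpoint can be re-applied (idempotently) to
    new or already-capped data.
    """

    def __init__(
        self,
        upper_tail: float = 0.01,
        per_item: bool = False,
        lower_tail: float | None = None,
    ):
        if not (0.0 <= upper_tail < 1.0):
            raise ValueError("upper_tail must be in [0, 1)")
        self.upper_tail = upper_tail
        self.per_item = per_item
        self.lower_tail = lower_tail

    def get_params(self, deep: bool = True) -> dict:
        return {
            "upper_tail": self.upper_tail,
            "per_item": self.per_item,
            "lower_tail": self.lower_tail,
        }

    def set_params(self, **params) -> "Winsorizer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, panel: PricePanel) -> "Winsorizer":
        d = panel.data
        if d.empty:
            raise ValueError("cannot winsorize an empty panel")
        self.medians_ = d.groupby("item")["price_lcu_per_kg"].median()
        ratios = d["price_lcu_per_kg"] / d["item"].map(self.medians_)
        q = 1.0 - self.upper_tail
        if self.per_item:
            self.cutpoint_ = ratios.groupby(d["item"]).quantile(q)
        else:
            self.cutpoint_ = float(ratios.quantile(q))
        if self.lower_tail is not None:
            if self.per_item:
                self.lower_cutpoint_ = ratios.groupby(d["item"]).quantile(self.lower_tail)
            else:
                self.lower_cutpoint_ = float(ratios.quantile(self.lower_tail))
        else:
            self.lower_cutpoint_ = None
        return self

    def transform(self, panel: PricePanel) -> tuple[PricePanel, WinsorizationReport]:
        d = panel.data.copy()
        med = d["item"].map(self.medians_)
        if med.isna().any():
            bad = d.loc[med.isna(), "item"].unique().tolist()
            raise KeyError(f"items without a fitted median: {bad}")
        ratios = d["price_lcu_per_kg"] / med
        if self.per_item:
            cut = d["item"].map(self.cutpoint_)
        else:
            cut = self.cutpoint_
        over = ratios > cut
        d.loc[over, "price_lcu_per_kg"] = (cut * med)[over] if self.per_item else (
            self.cutpoint_ * med[over]
        )
        n_replaced = int(over.sum())
        if self.lower_cutpoint_ is not None:
            lcut = (
                d["item"].map(self.lower_cutpoint_)
                if self.per_item
                else self.lower_cutpoint_
            )
            under = ratios < lcut
            d.loc[under, "price_lcu_per_kg"] = (
                (lcut * med)[under] if self.per_item else self.lower_cutpoint_ * med[under]
            )
            n_replaced += int(under.sum())
        report = WinsorizationReport(
            n_replaced=n_replaced,
            cutpoint=float(np.max(np.atleast_1d(self.cutpoint_))),
            upper_tail=self.upper_tail,
            per_item=self.per_item,
            lower_tail=self.lower_tail,
            lower_cutpoint=(
                None
                if self.lower_cutpoint_ is None
                else float(np.min(np.atleast_1d(self.lower_cutpoint_)))
            ),
        )
        out = PricePanel(
            d, currency=panel.currency,
            crop_year_start_month=panel.crop_year_start_month,
        )
        return out, report

    def fit_transform(self, panel: PricePanel):
        return self.fit(panel).transform(panel)


def winsorize_prices(
    panel: PricePanel, upper_tail: float = 0.01, **kwargs
) -> tuple[PricePanel, WinsorizationReport]:
    """One-shot winsorization (fit + transform on the same panel)."""
    return Winsorizer(upper_tail=upper_tail, **kwargs).fit_transform(panel)


def price_per_100kcal(panel: PricePanel, comp: NutrientComposition) -> pd.DataFrame:
    """Express prices in LCU per 100 kcal using each item's energy density."""
    d = panel.data.copy()
    missing = set(d["item"].unique()) - set(comp.items)
    if missing:
        raise KeyError(f"items without composition rows: {sorted(missing)}")
    energy = comp.energy().reindex(d["item"]).to_numpy()
    if np.any(energy <= 0) or np.any(~np.isfinite(energy)):
        bad = d["item"][~(energy > 0)].unique().tolist()
        raise ValueError(f"zero or missing energy density for items: {bad}")
    d["price_lcu_per_100kcal"] = d["price_lcu_per_kg"] / (energy / 100.0)
    return d


@dataclass
class PPPSeries:
    """Annual PPP conversion factors (LCU per international dollar) with,
    after Denton smoothing, a monthly factor series whose 12-month average
    reproduces each year's annual factor."""

    annual: pd.Series                      # indexed by year
    monthly: pd.Series | None = None       # MultiIndex (year, month)

    def __post_init__(self) -> None:
        self.annual = self.annual.astype(float).sort_index()
        if (self.annual <= 0).any():
            raise ValueError("annual PPP factors must be positive")
        years = self.annual.index.to_numpy()
        if len(years) > 1 and not np.array_equal(
            years, np.arange(years[0], years[0] + len(years))
        ):
            raise ValueError("annual PPP factors must cover consecutive years")

    @classmethod
    def from_csv(cls, path) -> "PPPSeries":
        df = pd.read_csv(path)
        return cls(pd.Series(df["factor"].values, index=df["year"].values))

    def factor(self, year: int, month: int) -> float:
        if self.monthly is None:
            raise ValueError("call denton_smooth first: no monthly factors")
        try:
            return float(self.monthly.loc[(year, month)])
        except KeyError:
            raise KeyError(f"no PPP factor for {year}-{month:02d}") from None


def denton_smooth(series: PPPSeries) -> PPPSeries:
    """Additive Denton benchmarking of annual factors to a monthly series.

    Minimises the sum of squared first differences of the monthly path
    subject to each calendar year's 12 months averaging to that year's
    annual factor (average- not sum-consistency, the benchmark type for
    index-like series).  Solved exactly via the KKT system of the
    equality-constrained quadratic program.
    """
    a = series.annual.to_numpy(dtype=float)
    years = series.annual.index.to_numpy()
    n_years = len(a)
    n = 12 * n_years
    # objective: x' (D'D) x with D the first-difference operator
    D = np.diff(np.eye(n), axis=0)
    Q = 2.0 * D.T @ D
    A = np.zeros((n_years, n))
    for y in range(n_years):
        A[y, 12 * y : 12 * (y + 1)] = 1.0 / 12.0
    kkt = np.block([[Q, A.T], [A, np.zeros((n_years, n_years))]])
    rhs = np.concatenate([np.zeros(n), a])
    sol = np.linalg.solve(kkt, rhs)
    x = sol[:n]
    idx = pd.MultiIndex.from_product(
        [years, range(1, 13)], names=["year", "month"]
    )
    monthly = pd.Series(x, index=idx, name="ppp_factor")
    # average-consistency must hold to numerical precision
    check = monthly.groupby(level="year").mean()
    if not np.allclose(check.to_numpy(), a, rtol=1e-9, atol=0):
        raise RuntimeError("Denton smoothing failed the annual-average check")
    if (monthly <= 0).any():
        raise ValueError("smoothed monthly PPP factors are not all positive")
    return PPPSeries(annual=series.annual, monthly=monthly)


class DentonSmoother:
    """Estimator-style wrapper over :func:`denton_smooth`."""

    def get_params(self, deep: bool = True) -> dict:
        return {}

    def set_params(self, **params) -> "DentonSmoother":
        if params:
            raise ValueError("DentonSmoother has no parameters")
        return self

    def fit(self, series: PPPSeries) -> "DentonSmoother":
        self.result_ = denton_smooth(series)
        return self

    def transform(self, series: PPPSeries | None = None) -> PPPSeries:
        return self.result_

    def fit_transform(self, series: PPPSeries) -> PPPSeries:
        return self.fit(series).transform()


def to_ppp_usd(cost_lcu: float, year: int, month: int, ppp: PPPSeries) -> float:
    """Convert a daily cost in nominal LCU to constant international dollars
    using the smoothed monthly PPP factor (applied after optimisation)."""
    return cost_lcu / ppp.factor(year, month)
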