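"""Synthetic multi-market price panels with known seasonal ground truth.

Government retail price panels of the kind used to measure food-system
seasonality are rarely redistributable, so this module generates panels
with the same structure and a fully known generating process: each
item's log price follows an annual harmonic with chosen amplitude
``A*`` and peak month ``P*``, plus cubic trend, crop-year effects,
market random effects on the intercept and the sin/cos terms, and
lognormal observation noise.  The harmonic coefficients are derived from
(A*, P*) by the same phase convention the estimator inverts
(``bs = A sin(2 pi P*/12)``, ``bc = A cos(2 pi P*/12)``), so downstream
amplitude/peak estimates recover the truth exactly in the noiseless
case.

A companion generator builds a nutrient-composition table and
requirement set that are feasible by construction (they include a
designed "complete" food whose nutrient density at the energy target
meets every lower bound and violates no upper bound), or deliberately
infeasible for a chosen nutrient, so the diet LPs and the pipeline's
infeasibility accounting are testable end to end.

Reproducibility: one root seed; independent child streams per market
and per (market, item) cell, so adding markets or items never perturbs
the draws of existing ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .diets import MACRO_ENERGY_DENSITY, NutrientComposition, RequirementSet
from .foods import (
    ANIMAL_FOODS,
    FOOD_GROUPS,
    FRUITS_VEGETABLES,
    OILS_FATS,
    PULSES_NUTS_SEEDS,
    STARCHY_STAPLES,
    SWEETS,
)
from .prices import PricePanel

OMEGA = 2.0 * np.pi / 12.0


@dataclass(frozen=True)
class ItemTruth:
    """Ground-truth generating parameters for one item's log price."""

    item: str
    group: str
    base_log_price: float
    amplitude: float = 0.0
    peak_month: float = 6.0
    trend: tuple[float, float, float] = (0.0, 0.0, 0.0)
    crop_year_effects: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not (0.0 < self.peak_month <= 12.0):
            raise ValueError("peak month must lie in (0, 12]")

    @property
    def beta_s(self) -> float:
        return self.amplitude * np.sin(OMEGA * self.peak_month)

    @property
    def beta_c(self) -> float:
        return self.amplitude * np.cos(OMEGA * self.peak_month)


@dataclass
class ScenarioConfig:
    """Full description of one synthetic price-panel scenario."""

    items: list[ItemTruth]
    n_markets: int = 5
    start: tuple[int, int] = (2011, 1)      # (year, month), inclusive
    end: tuple[int, int] = (2015, 12)       # (year, month), inclusive
    sd_market_intercept: float = 0.0
    sd_market_sin: float = 0.0
    sd_market_cos: float = 0.0
    sigma_eps: float = 0.0
    missing_rate: float = 0.0
    crop_year_start_month: int = 5
    currency: str = "SYN"
    seed: int = 0
    # explicit cells to delete, e.g. to engineer infeasible market-months:
    # tuples (market, item, year, month)
    drop_cells: tuple = ()

    def __post_init__(self) -> None:
        if self.n_markets < 1 or not self.items:
            raise ValueError("need at least one market and one item")
        for sd in (self.sd_market_intercept, self.sd_market_sin,
                   self.sd_market_cos, self.sigma_eps):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing rate must be in [0, 1)")
        if self._n_months() < 1:
            raise ValueError("empty month range")

    def _n_months(self) -> int:
        y0, m0 = self.start
        y1, m1 = self.end
        return (y1 - y0) * 12 + (m1 - m0) + 1

    def calendar(self) -> pd.DataFrame:
        """(year, month, t) rows with t = 1 at January of the start year."""
        y0, m0 = self.start
        periods = self._n_months()
        years, months, ts = [], [], []
        y, m = y0, m0
        for _ in range(periods):
            years.append(y)
            months.append(m)
            ts.append((y - y0) * 12 + m)
            m += 1
            if m == 13:
                y, m = y + 1, 1
        return pd.DataFrame({"year": years, "month": months, "t": ts})

    def truth_table(self) -> pd.DataFrame:
        rows = [
            {
                "item": it.item,
                "group": it.group,
                "base_log_price": it.base_log_price,
                "amplitude": it.amplitude,
                "peak_month": it.peak_month,
                "beta_s": it.beta_s,
                "beta_c": it.beta_c,
            }
            for it in self.items
        ]
        return pd.DataFrame(rows).set_index("item")


@dataclass
class SyntheticPanel:
    """A generated panel plus its ground truth ("provenance metadata")."""

    panel: PricePanel
    truth: pd.DataFrame
    config: ScenarioConfig

    def write(self, price_csv, truth_csv=None) -> None:
        self.panel.to_csv(price_csv)
        if truth_csv is not None:
            self.truth.to_csv(truth_csv, index_label="item")


def _market_effects(seed: int, market_idx: int, cfg: ScenarioConfig):
    rng = np.random.default_rng([seed, 1, market_idx])
    draws = rng.standard_normal(3)
    return (
        cfg.sd_market_intercept * draws[0],
        cfg.sd_market_sin * draws[1],
        cfg.sd_market_cos * draws[2],
    )


def generate_price_panel(config: ScenarioConfig) -> SyntheticPanel:
    """Simulate the long-format price panel described by ``config``.

    For each retained (market, month, item) cell the price is
    ``exp(b0_i + u_k0 + (bs_i + u_ks) sin(wt) + (bc_i + u_kc) cos(wt)
    + trend + crop-year effect + eps)`` with ``eps ~ N(0, sigma_eps^2)``.
    """
    cal = config.calendar()
    t = cal["t"].to_numpy(dtype=float)
    tau = t / t[-1]
    sin_t, cos_t = np.sin(OMEGA * t), np.cos(OMEGA * t)
    crop_year = np.where(
        cal["month"].to_numpy() >= config.crop_year_start_month,
        cal["year"].to_numpy(),
        cal["year"].to_numpy() - 1,
    )
    cy_index = pd.factorize(crop_year, sort=True)[0]
    dropped = set(config.drop_cells)

    frames = []
    for k in range(config.n_markets):
        market = f"M{k + 1:02d}"
        u0, us, uc = _market_effects(config.seed, k, config)
        for i, it in enumerate(config.items):
            rng = np.random.default_rng([config.seed, 2, k, i])
            eps = (
                rng.standard_normal(len(t)) * config.sigma_eps
                if config.sigma_eps > 0
                else np.zeros(len(t))
            )
            cy_eff = np.zeros(len(t))
            if it.crop_year_effects:
                eff = np.asarray(it.crop_year_effects, dtype=float)
                cy_eff = eff[np.minimum(cy_index, len(eff) - 1)]
            c1, c2, c3 = it.trend
            log_p = (
                it.base_log_price
                + u0
                + (it.beta_s + us) * sin_t
                + (it.beta_c + uc) * cos_t
                + c1 * tau + c2 * tau**2 + c3 * tau**3
                + cy_eff
                + eps
            )
            keep = np.ones(len(t), dtype=bool)
            if config.missing_rate > 0:
                keep = rng.random(len(t)) >= config.missing_rate
            df = pd.DataFrame(
                {
                    "market": market,
                    "year": cal["year"],
                    "month": cal["month"],
                    "item": it.item,
                    "price_lcu_per_kg": np.exp(log_p),
                }
            )[keep]
            if dropped:
                mask = [
                    (market, it.item, y, m) in dropped
                    for y, m in zip(df["year"], df["month"])
                ]
                df = df[~np.asarray(mask)]
            frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    panel = PricePanel(
        data,
        currency=config.currency,
        crop_year_start_month=config.crop_year_start_month,
    )
    return SyntheticPanel(panel=panel, truth=config.truth_table(), config=config)


# --------------------------------------------------------------------------
# composition / requirements fixtures
# --------------------------------------------------------------------------

#: compact synthetic nutrient list used by default fixtures (units/day)
_SYNTH_NUTRIENTS = {
    "protein": {"lower": 40.0},
    "carbohydrate": {"lower": 100.0},
    "lipid": {},
    "iron": {"lower": 8.0, "upper": 45.0},
    "calcium": {"lower": 800.0, "upper": 2500.0},
    "vitamin_c": {"lower": 60.0, "upper": 2000.0},
    "vitamin_a_rae": {"lower": 500.0},
    "retinol": {"upper": 3000.0},
    "sodium": {"upper": 2300.0},
    "vitamin_b12": {"lower": 2.0},
}
_SYNTH_AMDR = {
    "protein": (0.10, 0.35),
    "carbohydrate": (0.45, 0.65),
    "lipid": (0.20, 0.35),
}


@dataclass
class CompositionSpec:
    """What the synthetic composition/requirements fixture should contain."""

    items_per_group: dict[str, int] = field(
        default_factory=lambda: {g: 2 for g in FOOD_GROUPS}
    )
    energy_kcal: float = 2100.0
    feasible: bool = True
    missing_nutrient: str | None = None     # make this nutrient unobtainable
    complete_item: str = "complete_staple"
    # when set, only the complete item carries this nutrient, so deleting the
    # complete item from chosen market-months engineers infeasibility there
    sole_source_nutrient: str | None = None

    def __post_init__(self) -> None:
        if self.feasible and self.missing_nutrient:
            raise ValueError(
                "cannot request a feasible fixture and a missing nutrient at once"
            )
        if any(n < 1 for n in self.items_per_group.values()):
            raise ValueError("need at least one item per requested food group")
        unknown = set(self.items_per_group) - set(FOOD_GROUPS)
        if unknown:
            raise ValueError(f"unknown food groups: {sorted(unknown)}")


# typical energy densities (kcal/kg edible) by group for plausible fixtures
_GROUP_ENERGY = {
    STARCHY_STAPLES: (2600.0, 3650.0),
    PULSES_NUTS_SEEDS: (3000.0, 5800.0),
    ANIMAL_FOODS: (600.0, 3000.0),
    FRUITS_VEGETABLES: (200.0, 900.0),
    OILS_FATS: (7000.0, 9000.0),
    SWEETS: (3000.0, 4000.0),
}
# rough macronutrient energy shares by group (protein, carb, lipid)
_GROUP_MACRO = {
    STARCHY_STAPLES: (0.10, 0.80, 0.10),
    PULSES_NUTS_SEEDS: (0.22, 0.40, 0.38),
    ANIMAL_FOODS: (0.45, 0.05, 0.50),
    FRUITS_VEGETABLES: (0.12, 0.78, 0.10),
    OILS_FATS: (0.0, 0.0, 1.0),
    SWEETS: (0.01, 0.95, 0.04),
}


def generate_composition_and_requirements(
    spec: CompositionSpec, seed: int = 0
) -> tuple[NutrientComposition, RequirementSet]:
    """Build a synthetic composition table and matching requirement set.

    When ``spec.feasible`` the table contains a designed complete staple:
    at the quantity supplying the energy target it meets every lower
    bound at 1.2x and violates no upper bound, so the nutrient-adequacy
    LP is feasible with that single food.  When ``spec.missing_nutrient``
    is set, no item contains that nutrient, so the LP must report
    infeasibility and name it.
    """
    rng = np.random.default_rng([seed, 3])
    E = spec.energy_kcal
    req = RequirementSet(
        energy_kcal=E,
        lower={j: s["lower"] for j, s in _SYNTH_NUTRIENTS.items() if "lower" in s},
        upper={j: s["upper"] for j, s in _SYNTH_NUTRIENTS.items() if "upper" in s},
        amdr=dict(_SYNTH_AMDR),
        reference="synthetic reference adult",
    )
    nutrients = list(_SYNTH_NUTRIENTS)
    micro = [j for j in nutrients if j not in MACRO_ENERGY_DENSITY]
    # micronutrient density (share of the daily target supplied at the full
    # energy budget) is highest for fruits/vegetables and animal foods
    scarcity = {
        FRUITS_VEGETABLES: 1.5,
        ANIMAL_FOODS: 1.0,
        PULSES_NUTS_SEEDS: 0.7,
        STARCHY_STAPLES: 0.35,
        OILS_FATS: 0.1,
        SWEETS: 0.1,
    }

    rows = {}
    for group, count in spec.items_per_group.items():
        e_lo, e_hi = _GROUP_ENERGY[group]
        p_sh, c_sh, l_sh = _GROUP_MACRO[group]
        for n in range(count):
            name = f"{group.split(',')[0].split(' ')[0]}_{n + 1}"
            kcal = rng.uniform(e_lo, e_hi)
            row = {"group": group, "kcal_per_kg": kcal}
            # macronutrient grams per kg consistent with the energy density
            row["protein"] = p_sh * kcal / MACRO_ENERGY_DENSITY["protein"]
            row["carbohydrate"] = c_sh * kcal / MACRO_ENERGY_DENSITY["carbohydrate"]
            row["lipid"] = l_sh * kcal / MACRO_ENERGY_DENSITY["lipid"]
            for j in micro:
                if j == spec.sole_source_nutrient:
                    row[j] = 0.0
                    continue
                target = req.lower.get(j, 0.3 * req.upper.get(j, 1.0))
                # lognormal scatter around a group-specific density, so
                # adequacy takes a mixture of foods and carries a premium
                # over bare caloric subsistence
                density = scarcity.get(group, 0.5) * target * kcal / E
                row[j] = density * rng.lognormal(0.0, 0.8)
            rows[name] = row

    if spec.feasible:
        kcal = 3200.0
        row = {"group": STARCHY_STAPLES, "kcal_per_kg": kcal}
        row["protein"] = 0.15 * kcal / 4.0
        row["carbohydrate"] = 0.55 * kcal / 4.0
        row["lipid"] = 0.30 * kcal / 9.0
        for j in micro:
            lo = req.lower.get(j)
            hi = req.upper.get(j)
            daily = 1.2 * lo if lo is not None else 0.2 * hi
            if hi is not None:
                daily = min(daily, 0.9 * hi)
            row[j] = daily * kcal / E
        rows[spec.complete_item] = row

    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "item"
    if spec.missing_nutrient:
        if spec.missing_nutrient not in table.columns:
            raise ValueError(f"unknown nutrient {spec.missing_nutrient!r}")
        table[spec.missing_nutrient] = 0.0
    return NutrientComposition(table), req


def default_scenario(
    n_markets: int = 5,
    n_items_per_group: int = 4,
    seed: int = 0,
    amplitude_range: tuple[float, float] = (0.02, 0.25),
    sigma_eps: float = 0.08,
    sd_market_intercept: float = 0.10,
    sd_market_sin: float = 0.01,
    sd_market_cos: float = 0.01,
    missing_rate: float = 0.05,
    start: tuple[int, int] = (2011, 1),
    end: tuple[int, int] = (2015, 12),
    crop_year_start_month: int = 5,
) -> ScenarioConfig:
    """A realistic default scenario: five years of monthly prices with
    item amplitudes 2-25% (strongest for fruits and vegetables, weakest
    for animal foods), mild trend and crop-year effects, 8% log-price
    noise and 5% missing cells."""
    rng = np.random.default_rng([seed, 0])
    # group-specific amplitude multipliers mirror the stylised fact that
    # perishables swing most and animal foods least
    amp_scale = {
        STARCHY_STAPLES: 1.0,
        PULSES_NUTS_SEEDS: 0.7,
        ANIMAL_FOODS: 0.25,
        FRUITS_VEGETABLES: 1.8,
        OILS_FATS: 0.4,
        SWEETS: 0.4,
    }
    # group-level base log prices keep starchy staples the cheapest calories
    # and animal foods the dearest, as in observed retail panels
    base_range = {
        STARCHY_STAPLES: (5.0, 5.8),
        PULSES_NUTS_SEEDS: (5.8, 6.6),
        ANIMAL_FOODS: (7.4, 8.2),
        FRUITS_VEGETABLES: (5.3, 6.3),
        OILS_FATS: (6.8, 7.4),
        SWEETS: (6.5, 7.1),
    }
    items = []
    for group in FOOD_GROUPS:
        for n in range(n_items_per_group):
            lo, hi = amplitude_range
            amp = min(rng.uniform(lo, hi) * amp_scale[group], 0.6)
            items.append(
                ItemTruth(
                    item=f"{group.split(',')[0].split(' ')[0]}_{n + 1}",
                    group=group,
                    base_log_price=rng.uniform(*base_range[group]),
                    amplitude=amp,
                    peak_month=float(rng.uniform(0.5, 12.0)),
                    trend=(rng.normal(0.15, 0.05), 0.0, 0.0),
                    crop_year_effects=tuple(rng.normal(0.0, 0.03, size=6)),
                )
            )
    # the designed complete staple is priced too, so every market-month that
    # retains it admits a nutrient-adequate diet by construction; it is made
    # expensive so it backstops feasibility without being the routine optimum
    # (keeping the nutrient premium strictly positive, as in observed panels)
    items.append(
        ItemTruth(
            item="complete_staple",
            group=STARCHY_STAPLES,
            base_log_price=float(rng.uniform(8.2, 8.6)),
            amplitude=float(rng.uniform(0.03, 0.10)),
            peak_month=float(rng.uniform(0.5, 12.0)),
            trend=(float(rng.normal(0.15, 0.05)), 0.0, 0.0),
            crop_year_effects=tuple(rng.normal(0.0, 0.03, size=6)),
        )
    )
    return ScenarioConfig(
        items=items,
        n_markets=n_markets,
        start=start,
        end=end,
        sd_market_intercept=sd_market_intercept,
        sd_market_sin=sd_market_sin,
        sd_market_cos=sd_market_cos,
        sigma_eps=sigma_eps,
        missing_rate=missing_rate,
        crop_year_start_month=crop_year_start_month,
        seed=seed,
    )


def scenario_to_json(config: ScenarioConfig) -> str:
    return json.dumps(asdict(config), default=list, indent=2)
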