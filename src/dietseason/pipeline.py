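"""End-to-end analysis pipeline.

Stages: load or simulate a price panel -> validate -> winsorize ->
solve the two diet LPs (nutrient adequacy and caloric subsistence) for
every market-month -> estimate seasonality of item prices, diet costs
(nationally and per market) and food-group cost/energy components ->
write tables and a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diets import (
    DietSolution,
    NutrientComposition,
    RequirementSet,
    cona_premium,
    solve_coca,
    solve_cona,
)
from .foods import FOOD_GROUPS
from .prices import PPPSeries, PricePanel, denton_smooth, to_ppp_usd, winsorize_prices
from .seasonality import seasonality_table
from .synthetic import (
    CompositionSpec,
    ScenarioConfig,
    generate_composition_and_requirements,
    generate_price_panel,
)

logger = logging.getLogger("dietseason")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``scenario`` (simulation mode) or ``price_csv`` (data
    mode) must be supplied.
    """

    scenario: ScenarioConfig | None = None
    composition_spec: CompositionSpec | None = None
    price_csv: str | Path | None = None
    composition_csv: str | Path | None = None
    requirements_yaml: str | Path | None = None
    ppp_csv: str | Path | None = None
    currency: str = "LCU"
    crop_year_start_month: int = 5
    estimator: str = "auto"
    winsorize_upper_tail: float = 0.01
    published_phase_var: bool = False
    output_dir: str | Path | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.scenario is None) == (self.price_csv is None):
            raise ValueError(
                "supply exactly one of a simulation scenario or a price CSV"
            )
        if not (1 <= self.crop_year_start_month <= 12):
            raise ValueError("crop_year_start_month must be in 1..12")

    def config_hash(self) -> str:
        # hash the scientific configuration only: where outputs land and how
        # verbosely we log must not change the stamped run identity
        fields = {
            k: repr(v)
            for k, v in vars(self).items()
            if k not in ("output_dir", "log_level")
        }
        blob = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(
    prices: pd.DataFrame,
    comp: NutrientComposition,
    req: RequirementSet,
) -> ValidationReport:
    """Schema and consistency checks; all violations are enumerated."""
    rep = ValidationReport()
    required = {"market", "year", "month", "item", "price_lcu_per_kg"}
    missing_cols = required - set(prices.columns)
    if missing_cols:
        rep.errors.append(f"price panel missing columns: {sorted(missing_cols)}")
        return rep
    bad_month = ~prices["month"].between(1, 12)
    if bad_month.any():
        rep.errors.append(f"{int(bad_month.sum())} rows with month outside 1..12")
    bad_price = ~(prices["price_lcu_per_kg"] > 0)
    if bad_price.any():
        rep.errors.append(f"{int(bad_price.sum())} rows with non-positive prices")
    dup = prices.duplicated(subset=["market", "year", "month", "item"], keep=False)
    if dup.any():
        keys = (
            prices.loc[dup, ["market", "year", "month", "item"]]
            .drop_duplicates()
            .head(5)
            .to_dict("records")
        )
        rep.errors.append(f"duplicate (market, year, month, item) keys, e.g. {keys}")
    unmapped = sorted(set(prices["item"].unique()) - set(comp.items))
    if unmapped:
        rep.errors.append(f"items priced but absent from composition: {unmapped}")
    missing_nutrients = [j for j in req.nutrients if j not in comp.table.columns]
    if missing_nutrients:
        rep.errors.append(
            f"required nutrients missing from composition table: {missing_nutrients}"
        )
    n_periods = prices[["year", "month"]].drop_duplicates().shape[0]
    if n_periods < 24:
        rep.warnings.append(
            f"only {n_periods} distinct months; seasonality fits need >= 24"
        )
    return rep


def solve_diets_table(
    panel: PricePanel,
    comp: NutrientComposition,
    req: RequirementSet,
    ppp: PPPSeries | None = None,
) -> pd.DataFrame:
    """Solve CoNA and CoCA for every market-month of a panel.

    Returns one row per market-month with costs, statuses, the CoNA
    premium, per-group cost and energy decompositions, and (when a PPP
    series is supplied) costs in constant international dollars.
    """
    wide = panel.data.pivot_table(
        index=["market", "year", "month"],
        columns="item",
        values="price_lcu_per_kg",
        aggfunc="first",
    )
    rows = []
    for (market, year, month), price_row in wide.iterrows():
        cona = solve_cona(price_row, comp, req)
        coca = solve_coca(price_row, comp, req.energy_kcal)
        row: dict = {
            "market": market,
            "year": int(year),
            "month": int(month),
            "cona_lcu": cona.cost if cona.optimal else np.nan,
            "coca_lcu": coca.cost if coca.optimal else np.nan,
            "premium_lcu": cona_premium(cona, coca),
            "status_cona": cona.status,
            "status_coca": coca.status,
            "diagnostic": cona.diagnostic or coca.diagnostic or "",
        }
        if cona.optimal:
            for g in FOOD_GROUPS:
                row[f"cost_{_slug(g)}"] = cona.group_cost[g]
                row[f"kcal_{_slug(g)}"] = cona.group_energy[g]
        if ppp is not None:
            row["cona_usd"] = (
                to_ppp_usd(cona.cost, year, month, ppp) if cona.optimal else np.nan
            )
            row["coca_usd"] = (
                to_ppp_usd(coca.cost, year, month, ppp) if coca.optimal else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def _slug(group: str) -> str:
    return group.split(",")[0].split(" ")[0]


@dataclass
class RunResult:
    diet_costs: pd.DataFrame
    item_seasonality: pd.DataFrame
    diet_cost_seasonality: pd.DataFrame
    group_seasonality: pd.DataFrame
    manifest: dict

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "diet_costs": self.diet_costs,
            "item_seasonality": self.item_seasonality,
            "diet_cost_seasonality": self.diet_cost_seasonality,
            "group_seasonality": self.group_seasonality,
        }


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all pipeline stages; see the module docstring."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    t0 = time.perf_counter()
    timings: dict[str, float] = {}

    # ---- stage 1: inputs -------------------------------------------------
    if config.scenario is not None:
        synth = generate_price_panel(config.scenario)
        panel = synth.panel
        comp_spec = config.composition_spec or CompositionSpec()
        comp, req = generate_composition_and_requirements(
            comp_spec, seed=config.scenario.seed
        )
        crop_start = config.scenario.crop_year_start_month
    else:
        panel = PricePanel.from_csv(
            config.price_csv,
            currency=config.currency,
            crop_year_start_month=config.crop_year_start_month,
        )
        if config.composition_csv is None:
            raise ValueError("data mode needs a composition CSV")
        comp = NutrientComposition.from_csv(config.composition_csv)
        req = (
            RequirementSet.from_yaml(config.requirements_yaml)
            if config.requirements_yaml
            else RequirementSet.default()
        )
        crop_start = config.crop_year_start_month
    ppp = None
    if config.ppp_csv is not None:
        ppp = denton_smooth(PPPSeries.from_csv(config.ppp_csv))
    timings["inputs"] = time.perf_counter() - t0
    logger.info("inputs: %d price rows, %d items", len(panel), len(comp.items))

    # ---- stage 2: validation --------------------------------------------
    report = validate_inputs(panel.data, comp, req)
    for w in report.warnings:
        logger.warning("validate: %s", w)
    if not report.ok:
        raise ValueError("input validation failed: " + "; ".join(report.errors))

    # ---- stage 3: cleaning ----------------------------------------------
    t1 = time.perf_counter()
    n_in = len(panel)
    panel, wreport = winsorize_prices(panel, upper_tail=config.winsorize_upper_tail)
    timings["cleaning"] = time.perf_counter() - t1

    # ---- stage 4: diet LPs ----------------------------------------------
    t1 = time.perf_counter()
    diet_costs = solve_diets_table(panel, comp, req, ppp=ppp)
    n_mm = len(diet_costs)
    n_infeasible = int((diet_costs["status_cona"] != "optimal").sum())
    timings["diet_lp"] = time.perf_counter() - t1
    logger.info(
        "diet LPs: %d market-months, %d infeasible", n_mm, n_infeasible
    )

    # ---- stage 5: seasonality -------------------------------------------
    t1 = time.perf_counter()
    common = dict(
        crop_year_start_month=crop_start,
        estimator=config.estimator,
        published_phase_var=config.published_phase_var,
    )
    item_panel = panel.data.rename(columns={"price_lcu_per_kg": "value"})
    item_panel["key"] = item_panel["item"]
    item_seas = seasonality_table(item_panel, by="key", scale="log", **common)

    feasible = diet_costs[diet_costs["status_cona"] == "optimal"]
    long_costs = []
    for indicator, col in (
        ("CoNA", "cona_lcu"),
        ("CoCA", "coca_lcu"),
        ("premium", "premium_lcu"),
    ):
        d = feasible[["market", "year", "month", col]].rename(columns={col: "value"})
        d = d.dropna(subset=["value"])
        d["key"] = indicator
        long_costs.append(d)
    cost_panel = pd.concat(long_costs, ignore_index=True)
    national = seasonality_table(
        cost_panel, by="key", scale="log", location="national", **common
    )
    sub_rows = []
    for market, grp in cost_panel.groupby("market"):
        tab = seasonality_table(
            grp, by="key", scale="log", location=str(market), **common
        )
        sub_rows.append(tab)
    diet_cost_seas = pd.concat([national, *sub_rows], ignore_index=True)

    group_long = []
    for g in FOOD_GROUPS:
        for kind, col in (("cost", f"cost_{_slug(g)}"), ("energy", f"kcal_{_slug(g)}")):
            if col not in feasible.columns:
                continue
            d = feasible[["market", "year", "month", col]].rename(
                columns={col: "value"}
            )
            d["key"] = f"{_slug(g)}_{kind}"
            group_long.append(d)
    group_seas = seasonality_table(
        pd.concat(group_long, ignore_index=True), by="key", scale="level", **common
    )
    timings["seasonality"] = time.perf_counter() - t1

    manifest = {
        "package": "dietseason",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed if config.scenario is None else config.scenario.seed,
        "mode": "simulation" if config.scenario is not None else "data",
        "rows_in": n_in,
        "rows_cleaned": len(panel),
        "rows_winsorized": wreport.n_replaced,
        "winsor_cutpoint": wreport.cutpoint,
        "n_market_months": n_mm,
        "n_infeasible_cona": n_infeasible,
        "n_infeasible_coca": int((diet_costs["status_coca"] != "optimal").sum()),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "versions": _lib_versions(),
    }
    result = RunResult(
        diet_costs=diet_costs,
        item_seasonality=item_seas,
        diet_cost_seasonality=diet_cost_seas,
        group_seasonality=group_seas,
        manifest=manifest,
    )
    if config.output_dir is not None:
        _write_outputs(result, config)
    return result


def _lib_versions() -> dict[str, str]:
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _write_outputs(result: RunResult, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = (
        f"# dietseason v{__version__} run {result.manifest['config_hash']} "
        f"seed={result.manifest['seed']}\n"
    )
    for name, table in result.tables().items():
        path = out / f"{name}.csv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(stamp)
            table.to_csv(fh, index=False)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(result.manifest, fh, indent=2)
    logger.info("wrote outputs to %s", out)
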