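"""Least-cost diet linear programs.

Two diet-cost indicators are computed for every market-month:

* **CoNA** (cost of nutrient adequacy): the minimum daily cost of a food
  combination meeting the estimated average requirement (EAR) for every
  constrained nutrient, staying below tolerable upper intake levels (UL;
  the sodium CDRR), keeping macronutrient energy shares inside their
  acceptable macronutrient distribution ranges (AMDR), and supplying the
  daily energy target ``E`` exactly.
* **CoCA** (cost of caloric adequacy): the minimum daily cost of meeting
  ``E`` from starchy staples alone — bare caloric subsistence.

The LP for CoNA is::

    min  sum_i p_i q_i
    s.t. sum_i a_ij q_i >= EAR_j                     (nutrient adequacy)
         sum_i a_ij q_i <= UL_j                      (upper limits / CDRR)
         AMDR_lo_j E/e_j <= sum_i a_ij q_i <= AMDR_hi_j E/e_j   (macros)
         sum_i a_ie q_i  = E                         (energy)
         q_i >= 0

with prices ``p_i`` in local currency per kg edible matter, composition
``a_ij`` per kg edible, and ``e_j`` the energy density of macronutrients
(4 kcal/g protein and carbohydrate, 9 kcal/g lipid).  Quantities are in
kg/day and costs in nominal local currency per day; purchasing-power
conversion happens strictly after optimisation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import linprog

from .foods import FOOD_GROUPS, STARCHY_STAPLES

__all__ = [
    "MACRO_ENERGY_DENSITY",
    "NutrientComposition",
    "RequirementSet",
    "DietSolution",
    "InfeasibleDietError",
    "compute_eer",
    "solve_cona",
    "solve_coca",
    "cona_premium",
    "group_decomposition",
]

#: kcal per gram of each macronutrient
MACRO_ENERGY_DENSITY: dict[str, float] = {
    "protein": 4.0,
    "carbohydrate": 4.0,
    "lipid": 9.0,
}

# Physical-activity coefficients of the IOM adult-female EER equation.
_PA_FEMALE = {
    "sedentary": 1.00,
    "low_active": 1.12,
    "active": 1.27,
    "very_active": 1.45,
}


def compute_eer(
    sex: str,
    age_years: float,
    weight_kg: float,
    height_m: float,
    pal_category: str = "low_active",
) -> float:
    """Estimated energy requirement (kcal/day) for a healthy adult woman.

    Implements the IOM adult-female equation
    ``EER = 354 - 6.91*age + PA*(9.36*weight + 726*height)`` with the
    physical-activity coefficient ``PA`` chosen by ``pal_category``
    (sedentary 1.00, low_active 1.12, active 1.27, very_active 1.45).

    >>> round(compute_eer("female", 24.5, 57.0, 1.63, "low_active"), 1)
    2107.6
    """
    if sex.lower() not in {"female", "f", "woman"}:
        raise ValueError("only the adult-female EER equation is implemented")
    try:
        pa = _PA_FEMALE[pal_category]
    except KeyError:
        raise ValueError(
            f"unknown PAL category {pal_category!r}; "
            f"choose from {sorted(_PA_FEMALE)}"
        ) from None
    return 354.0 - 6.91 * age_years + pa * (9.36 * weight_kg + 726.0 * height_m)


class NutrientComposition:
    """Per-item nutrient composition, amounts per kg edible matter.

    ``table`` is a DataFrame indexed by item id with a ``group`` column
    (one of the six food groups), a ``kcal_per_kg`` energy-density column,
    and one column per nutrient in the units declared by the matching
    :class:`RequirementSet`.
    """

    def __init__(self, table: pd.DataFrame):
        if "kcal_per_kg" not in table.columns:
            raise ValueError("composition table needs a 'kcal_per_kg' column")
        if "group" not in table.columns:
            raise ValueError("composition table needs a 'group' column")
        nutrient_cols = [c for c in table.columns if c not in ("group", "kcal_per_kg")]
        numeric = table[nutrient_cols + ["kcal_per_kg"]]
        if (numeric.to_numpy(dtype=float) < 0).any():
            raise ValueError("nutrient amounts and energy densities must be >= 0")
        if (table["kcal_per_kg"] <= 0).any():
            bad = table.index[table["kcal_per_kg"] <= 0].tolist()
            raise ValueError(f"non-positive energy density for items: {bad}")
        self.table = table
        self.nutrients = nutrient_cols

    @property
    def items(self) -> pd.Index:
        return self.table.index

    def energy(self, items=None) -> pd.Series:
        t = self.table if items is None else self.table.loc[items]
        return t["kcal_per_kg"]

    def amounts(self, nutrient: str, items=None) -> pd.Series:
        t = self.table if items is None else self.table.loc[items]
        return t[nutrient]

    def groups(self, items=None) -> pd.Series:
        t = self.table if items is None else self.table.loc[items]
        return t["group"]

    @classmethod
    def from_csv(cls, path) -> "NutrientComposition":
        return cls(pd.read_csv(path, index_col="item"))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="item")


@dataclass
class RequirementSet:
    """Nutrient constraint set for one reference demographic.

    ``lower`` maps nutrient -> EAR (absent key = no lower bound), ``upper``
    maps nutrient -> UL (sodium: CDRR).  ``amdr`` maps macronutrient ->
    (lower, upper) fractions of daily energy, converted to gram bounds via
    ``MACRO_ENERGY_DENSITY``.  ``energy_kcal`` is the daily target ``E``.
    """

    energy_kcal: float
    lower: dict[str, float] = field(default_factory=dict)
    upper: dict[str, float] = field(default_factory=dict)
    amdr: dict[str, tuple[float, float]] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)
    reference: str = ""

    def __post_init__(self) -> None:
        if self.energy_kcal <= 0:
            raise ValueError("daily energy target must be positive")
        for j, (lo, hi) in self.amdr.items():
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"AMDR bounds for {j} must satisfy 0<=lo<=hi<=1")
            if j not in MACRO_ENERGY_DENSITY:
                raise ValueError(f"AMDR nutrient {j!r} has no energy density e_j")
        for j, lo in self.lower.items():
            if j in self.upper and lo > self.upper[j]:
                raise ValueError(f"EAR exceeds UL for nutrient {j}")

    @property
    def nutrients(self) -> list[str]:
        """Nutrients carrying at least one constraint (EAR, UL, or AMDR)."""
        names: dict[str, None] = {}
        for source in (self.lower, self.upper, self.amdr):
            for j in source:
                names.setdefault(j, None)
        return list(names)

    @classmethod
    def from_yaml(cls, path_or_stream) -> "RequirementSet":
        if hasattr(path_or_stream, "read"):
            cfg = yaml.safe_load(path_or_stream)
        else:
            with open(path_or_stream, "r", encoding="utf-8") as fh:
                cfg = yaml.safe_load(fh)
        energy_cfg = cfg["energy"]
        if "kcal" in energy_cfg:
            energy = float(energy_cfg["kcal"])
        else:
            e = energy_cfg["eer"]
            energy = compute_eer(
                e["sex"], e["age_years"], e["weight_kg"], e["height_m"], e["pal"]
            )
        lower, upper, units = {}, {}, {}
        for name, spec in cfg.get("nutrients", {}).items():
            spec = spec or {}
            if "lower" in spec:
                lower[name] = float(spec["lower"])
            if "upper" in spec:
                upper[name] = float(spec["upper"])
            if "unit" in spec:
                units[name] = str(spec["unit"])
        amdr = {
            j: (float(b["lower"]), float(b["upper"]))
            for j, b in cfg.get("amdr", {}).items()
        }
        return cls(
            energy_kcal=energy,
            lower=lower,
            upper=upper,
            amdr=amdr,
            units=units,
            reference=str(cfg.get("reference", "")),
        )

    def to_yaml(self, path) -> None:
        cfg: dict = {
            "reference": self.reference,
            "energy": {"kcal": float(self.energy_kcal)},
            "amdr": {
                j: {"lower": float(lo), "upper": float(hi)}
                for j, (lo, hi) in self.amdr.items()
            },
            "nutrients": {},
        }
        for j in self.nutrients:
            spec: dict = {}
            if j in self.lower:
                spec["lower"] = float(self.lower[j])
            if j in self.upper:
                spec["upper"] = float(self.upper[j])
            if j in self.units:
                spec["unit"] = self.units[j]
            cfg["nutrients"][j] = spec
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=False)

    @classmethod
    def default(cls) -> "RequirementSet":
        """The shipped women-19-30 DRI set (21 constrained nutrients)."""
        ref = importlib.resources.files("dietseason.data") / "dri_women_19_30.yaml"
        with ref.open("r", encoding="utf-8") as fh:
            return cls.from_yaml(fh)


@dataclass
class DietSolution:
    """Outcome of one least-cost diet LP."""

    status: str                       # "optimal" | "infeasible"
    indicator: str                    # "CoNA" | "CoCA"
    cost: float | None                # LCU/day
    quantities: pd.Series | None      # kg/day by item
    energy_kcal: float
    binding: list[str] = field(default_factory=list)
    diagnostic: str | None = None
    group_cost: pd.Series | None = None
    group_energy: pd.Series | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


class InfeasibleDietError(RuntimeError):
    pass


def _check_items(prices: pd.Series, comp: NutrientComposition) -> pd.Index:
    prices = prices.dropna()
    if prices.empty:
        raise ValueError("no priced items for this market-month")
    if (prices <= 0).any():
        bad = prices.index[prices <= 0].tolist()
        raise ValueError(f"non-positive prices for items: {bad}")
    missing = prices.index.difference(comp.items)
    if len(missing):
        raise KeyError(
            "items priced but missing from composition table: "
            + ", ".join(map(str, missing))
        )
    return prices.index


def _unreachable_nutrients(
    items: pd.Index, comp: NutrientComposition, req: RequirementSet
) -> list[str]:
    """Nutrients with a positive lower bound that no priced item contains."""
    out = []
    for j, ear in req.lower.items():
        if ear > 0 and j in comp.table.columns:
            if not (comp.amounts(j, items) > 0).any():
                out.append(j)
    return out


def _solve(
    prices: pd.Series,
    comp: NutrientComposition,
    req: RequirementSet,
    indicator: str,
    energy_only: bool,
) -> DietSolution:
    items = _check_items(prices, comp)
    p = prices.loc[items].to_numpy(dtype=float)
    a_e = comp.energy(items).to_numpy(dtype=float)
    E = req.energy_kcal
    n = len(items)

    rows_ub: list[np.ndarray] = []
    b_ub: list[float] = []
    labels: list[str] = []

    if not energy_only:
        unreachable = _unreachable_nutrients(items, comp, req)
        if unreachable:
            return DietSolution(
                status="infeasible",
                indicator=indicator,
                cost=None,
                quantities=None,
                energy_kcal=E,
                diagnostic=(
                    "no priced item supplies required nutrient(s): "
                    + ", ".join(unreachable)
                ),
            )
        for j, ear in req.lower.items():
            if j not in comp.table.columns:
                raise KeyError(f"nutrient {j!r} missing from composition table")
            a = comp.amounts(j, items).to_numpy(dtype=float)
            rows_ub.append(-a)
            b_ub.append(-ear)
            labels.append(f"EAR:{j}")
        for j, ul in req.upper.items():
            if j not in comp.table.columns:
                raise KeyError(f"nutrient {j!r} missing from composition table")
            a = comp.amounts(j, items).to_numpy(dtype=float)
            rows_ub.append(a)
            b_ub.append(ul)
            labels.append(f"UL:{j}")
        for j, (lo, hi) in req.amdr.items():
            a = comp.amounts(j, items).to_numpy(dtype=float)
            e_j = MACRO_ENERGY_DENSITY[j]
            rows_ub.append(a)
            b_ub.append(hi * E / e_j)
            labels.append(f"AMDR_upper:{j}")
            rows_ub.append(-a)
            b_ub.append(-lo * E / e_j)
            labels.append(f"AMDR_lower:{j}")

    A_ub = np.vstack(rows_ub) if rows_ub else None
    bvec = np.asarray(b_ub) if rows_ub else None
    res = linprog(
        p,
        A_ub=A_ub,
        b_ub=bvec,
        A_eq=a_e[None, :],
        b_eq=[E],
        bounds=[(0.0, None)] * n,
        method="highs",
    )
    if res.status == 2:  # solver's infeasibility certificate
        return DietSolution(
            status="infeasible",
            indicator=indicator,
            cost=None,
            quantities=None,
            energy_kcal=E,
            diagnostic="no feasible diet under the given constraints",
        )
    if not res.success:
        raise RuntimeError(f"LP solver failed ({indicator}): {res.message}")
    q = pd.Series(res.x, index=items, name="kg_per_day").clip(lower=0.0)
    cost = float(p @ res.x)
    binding: list[str] = []
    if rows_ub:
        slack = bvec - A_ub @ res.x
        scale = np.maximum(np.abs(bvec), 1.0)
        binding = [lab for lab, s, sc in zip(labels, slack, scale) if s <= 1e-7 * sc]
    binding.append("energy")
    gc, ge = group_decomposition_arrays(q, prices.loc[items], comp)
    return DietSolution(
        status="optimal",
        indicator=indicator,
        cost=cost,
        quantities=q,
        energy_kcal=E,
        binding=binding,
        group_cost=gc,
        group_energy=ge,
    )


def solve_cona(
    prices: pd.Series, comp: NutrientComposition, req: RequirementSet
) -> DietSolution:
    """Cost of nutrient adequacy for one market-month.

    ``prices`` is a Series of LCU/kg edible indexed by item id; only items
    present (non-NaN) are offered to the optimiser.
    """
    return _solve(prices, comp, req, indicator="CoNA", energy_only=False)


def solve_coca(
    prices: pd.Series, comp: NutrientComposition, energy_kcal: float
) -> DietSolution:
    """Cost of caloric adequacy: energy target from starchy staples only.

    Equals ``E * min over staples of price-per-kcal``; the LP route keeps
    the same machinery (binding report, group decomposition) as CoNA.
    """
    prices = prices.dropna()
    in_comp = prices.index.intersection(comp.items)
    staples = in_comp[comp.groups(in_comp) == STARCHY_STAPLES]
    if len(staples) == 0:
        return DietSolution(
            status="infeasible",
            indicator="CoCA",
            cost=None,
            quantities=None,
            energy_kcal=energy_kcal,
            diagnostic="no starchy staples priced this market-month",
        )
    req = RequirementSet(energy_kcal=energy_kcal)
    return _solve(prices.loc[staples], comp, req, indicator="CoCA", energy_only=True)


def cona_premium(cona: DietSolution, coca: DietSolution) -> float:
    """CoNA − CoCA, the daily premium for nutrients beyond bare energy.

    Returns NaN when either problem is infeasible so the market-month is
    excluded downstream rather than silently imputed.
    """
    if not (cona.optimal and coca.optimal):
        return float("nan")
    return cona.cost - coca.cost


def group_decomposition_arrays(
    quantities: pd.Series, prices: pd.Series, comp: NutrientComposition
) -> tuple[pd.Series, pd.Series]:
    items = quantities.index
    groups = comp.groups(items)
    if groups.isna().any():
        bad = items[groups.isna()].tolist()
        raise ValueError(f"items without a food-group label: {bad}")
    cost = (prices.loc[items] * quantities).groupby(groups).sum()
    energy = (comp.energy(items) * quantities).groupby(groups).sum()
    cost = cost.reindex(FOOD_GROUPS, fill_value=0.0)
    energy = energy.reindex(FOOD_GROUPS, fill_value=0.0)
    cost.index.name = energy.index.name = "group"
    return cost, energy


def group_decomposition(
    solution: DietSolution, prices: pd.Series, comp: NutrientComposition
) -> pd.DataFrame:
    """Per-food-group cost (LCU/day) and energy (kcal/day) of a solved diet.

    Costs sum to the diet cost and energies to the daily energy target.
    """
    if not solution.optimal:
        raise InfeasibleDietError("cannot decompose an infeasible diet")
    cost, energy = group_decomposition_arrays(solution.quantities, prices, comp)
    return pd.DataFrame({"cost": cost, "energy_kcal": energy})
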