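"""Food-group taxonomy and item classification.

Foods are classified into six mutually exclusive groups adapted from the
Minimum Dietary Diversity for Women (MDD-W) guidelines: starchy staples
(grains, white roots and tubers, plantains); pulses, nuts, and seeds;
animal foods (dairy, eggs, meat, poultry, fish); fruits and vegetables;
oils and fats; and sweets.  Items that would not appear in substantial
quantities in an adult meal plan (condiments, infant foods, beverages)
are excluded from the analysis set.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

STARCHY_STAPLES = "starchy staples"
PULSES_NUTS_SEEDS = "pulses, nuts, and seeds"
ANIMAL_FOODS = "animal foods"
FRUITS_VEGETABLES = "fruits and vegetables"
OILS_FATS = "oils and fats"
SWEETS = "sweets"

FOOD_GROUPS: tuple[str, ...] = (
    STARCHY_STAPLES,
    PULSES_NUTS_SEEDS,
    ANIMAL_FOODS,
    FRUITS_VEGETABLES,
    OILS_FATS,
    SWEETS,
)

EXCLUDED = "excluded"

# Keyword lookup used when no explicit item->group mapping is supplied.
# First match wins; exclusion keywords are checked before group keywords.
_EXCLUDE_KEYWORDS = (
    "infant", "baby", "condiment", "spice", "pepper powder", "salt",
    "stock cube", "seasoning", "tea", "coffee", "soda",
)
_GROUP_KEYWORDS: tuple[tuple[str, tuple[str, ...]], ...] = (
    (STARCHY_STAPLES, (
        "maize", "rice", "wheat", "bread", "cassava", "potato", "yam",
        "sorghum", "millet", "teff", "plantain", "banana green", "pasta",
        "flour", "barley", "oat", "enset",
    )),
    (PULSES_NUTS_SEEDS, (
        "bean", "pea", "lentil", "groundnut", "peanut", "soy", "sesame",
        "sunflower seed", "cashew", "chickpea", "nut",
    )),
    (ANIMAL_FOODS, (
        "beef", "goat", "mutton", "chicken", "pork", "fish", "sardine",
        "dagaa", "egg", "milk", "cheese", "yoghurt", "yogurt", "meat",
        "liver", "shrimp",
    )),
    (FRUITS_VEGETABLES, (
        "tomato", "onion", "cabbage", "kale", "spinach", "amaranth",
        "mchicha", "carrot", "mango", "orange", "papaya", "avocado",
        "banana", "pumpkin", "okra", "eggplant", "rape leaves", "leafy",
        "vegetable", "fruit", "lemon", "pepper green", "green pepper",
    )),
    (OILS_FATS, ("oil", "butter", "ghee", "margarine", "fat", "lard")),
    (SWEETS, ("sugar", "honey", "jam", "sweet biscuit", "candy", "soda")),
)


@dataclass(frozen=True)
class FoodItem:
    """A food item with its (single) food-group label.

    ``include`` is False for items excluded from the analysis set
    (condiments, infant foods and similar).
    """

    item: str
    group: str
    include: bool = True

    def __post_init__(self) -> None:
        if self.include and self.group not in FOOD_GROUPS:
            raise ValueError(
                f"group {self.group!r} is not one of the six food groups"
            )


class ClassificationError(KeyError):
    """Raised when an item cannot be assigned to a food group."""


def classify_food_group(
    item_name: str,
    mapping: dict[str, str] | None = None,
    *,
    policy: str = "keyword",
) -> FoodItem:
    """Assign a food item to exactly one of the six groups, or exclude it.

    Parameters
    ----------
    item_name
        Item description, e.g. ``"maize grain"``.
    mapping
        Optional explicit ``item -> group`` lookup (values are group labels
        or ``"excluded"``).  Checked before any keyword heuristics.
    policy
        ``"keyword"`` falls back to keyword matching for unmapped items;
        ``"strict"`` raises :class:`ClassificationError` instead.
    """
    name = item_name.strip()
    key = name.lower()
    if mapping is not None:
        lowered = {k.lower(): v for k, v in mapping.items()}
        if key in lowered:
            group = lowered[key]
            if group == EXCLUDED:
                return FoodItem(name, EXCLUDED, include=False)
            return FoodItem(name, group)
    if policy == "strict":
        raise ClassificationError(f"no food-group mapping for item {item_name!r}")
    for kw in _EXCLUDE_KEYWORDS:
        if kw in key:
            return FoodItem(name, EXCLUDED, include=False)
    # exclusion keywords take precedence, so "infant cereal" never reaches
    # the starchy-staples keywords below
    for group, keywords in _GROUP_KEYWORDS:
        for kw in keywords:
            if kw in key:
                return FoodItem(name, group)
    raise ClassificationError(f"cannot classify item {item_name!r}")


def load_group_mapping(path) -> dict[str, str]:
    """Read an item-mapping CSV with columns ``item, group`` (and an
    optional ``include`` flag; ``include=0`` rows map to ``excluded``)."""
    df = pd.read_csv(path)
    required = {"item", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"mapping file must have columns {sorted(required)}")
    mapping: dict[str, str] = {}
    for _, row in df.iterrows():
        group = str(row["group"])
        if "include" in df.columns and not bool(row["include"]):
            group = EXCLUDED
        mapping[str(row["item"])] = group
    return mapping
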