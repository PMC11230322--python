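"""Food-grouping configurations and index coding vectors.

A plant-based diet index is defined by (a) a partition of foods into
named food groups, each assigned to one of three super-categories
(healthy plant, unhealthy plant, animal), and (b) a coding vector giving
each group a scoring direction: *positive* (higher intake -> higher
quintile score) or *reverse* (higher intake -> lower score).

The default configuration has 18 groups: 7 healthy-plant, 5
unhealthy-plant and 6 animal.  The overall index (PDI) codes every plant
group positively and every animal group reversely; the healthful index
(hPDI) codes only healthy-plant groups positively; the unhealthful index
(uPDI) codes only unhealthy-plant groups positively.  Animal groups are
reverse-coded in all three.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import yaml

HEALTHY_PLANT = "healthy_plant"
UNHEALTHY_PLANT = "unhealthy_plant"
ANIMAL = "animal"

SUPER_CATEGORIES = (HEALTHY_PLANT, UNHEALTHY_PLANT, ANIMAL)

#: Canonical group order.  Enumeration of coding vectors and all labels
#: depend on this order, so it is fixed here and never sorted.
DEFAULT_HEALTHY_PLANT_GROUPS = (
    "whole_grains",
    "fruits",
    "vegetables",
    "nuts",
    "legumes",
    "vegetable_oils",
    "tea_coffee",
)
DEFAULT_UNHEALTHY_PLANT_GROUPS = (
    "fruit_juices",
    "refined_grains",
    "potatoes",
    "sugar_sweetened_beverages",
    "sweets_desserts",
)
DEFAULT_ANIMAL_GROUPS = (
    "animal_fat",
    "dairy",
    "eggs",
    "fish_seafood",
    "meat",
    "misc_animal",
)

#: Items making up the potatoes group (predominantly-potato items).
POTATO_ITEMS = (
    "white_potato",
    "french_fries",
    "salty_snacks",
    "low_fat_salty_snacks",
)

POSITIVE = "positive"
REVERSE = "reverse"


class ConfigError(ValueError):
    """Raised for invalid grouping configurations or coding vectors."""


@dataclass(frozen=True)
class FoodGroupingConfig:
    """Ordered food groups, their super-categories, and an item map.

    Parameters
    ----------
    groups
        Ordered group names.  Order is semantic (it fixes enumeration
        order of coding vectors) and must not be changed casually.
    super_category
        Mapping group -> super-category.
    item_map
        Optional mapping food-item name -> group name for item-level
        data.  An item absent from the map is excluded (and logged by
        the mapping step).  A group may be fed both by a direct
        group-level column and by mapped items; intakes are summed.
    label
        Human-readable configuration label.
    """

    groups: tuple[str, ...]
    super_category: dict[str, str] = field(hash=False)
    item_map: dict[str, str] = field(default_factory=dict, hash=False)
    label: str = "custom"

    def __post_init__(self) -> None:
        if len(set(self.groups)) != len(self.groups):
            raise ConfigError("groups: duplicate group names")
        missing = [g for g in self.groups if g not in self.super_category]
        if missing:
            raise ConfigError(f"super_category: missing groups {missing}")
        bad = {g: c for g, c in self.super_category.items() if c not in SUPER_CATEGORIES}
        if bad:
            raise ConfigError(f"super_category: invalid categories {bad}")
        unknown = [i for i, g in self.item_map.items() if g not in self.groups]
        if unknown:
            raise ConfigError(f"item_map: items mapped to unknown groups: {unknown}")

    # -- structure queries -------------------------------------------------
    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def groups_in(self, category: str) -> tuple[str, ...]:
        return tuple(g for g in self.groups if self.super_category[g] == category)

    @property
    def plant_groups(self) -> tuple[str, ...]:
        return tuple(
            g for g in self.groups if self.super_category[g] in (HEALTHY_PLANT, UNHEALTHY_PLANT)
        )

    @property
    def animal_groups(self) -> tuple[str, ...]:
        return self.groups_in(ANIMAL)

    def items_of(self, group: str) -> tuple[str, ...]:
        return tuple(i for i, g in self.item_map.items() if g == group)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "groups": list(self.groups),
            "super_category": dict(self.super_category),
            "item_map": dict(self.item_map),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FoodGroupingConfig":
        return cls(
            groups=tuple(d["groups"]),
            super_category=dict(d["super_category"]),
            item_map=dict(d.get("item_map", {})),
            label=d.get("label", "custom"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FoodGroupingConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        import hashlib

        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass(frozen=True)
class CodingVector:
    """Per-group scoring direction defining one index specification."""

    direction: dict[str, str] = field(hash=False)
    label: str = "custom"

    def __post_init__(self) -> None:
        bad = {g: d for g, d in self.direction.items() if d not in (POSITIVE, REVERSE)}
        if bad:
            raise ConfigError(f"direction: invalid values {bad}")

    def validate_against(self, config: FoodGroupingConfig) -> None:
        if set(self.direction) != set(config.groups):
            extra = set(self.direction) - set(config.groups)
            missing = set(config.groups) - set(self.direction)
            raise ConfigError(
                f"coding vector does not cover config groups exactly "
                f"(missing={sorted(missing)}, extra={sorted(extra)})"
            )

    def is_positive(self, group: str) -> bool:
        return self.direction[group] == POSITIVE

    def flipped(self, *groups: str, label: str | None = None) -> "CodingVector":
        """Return a copy with the given groups' directions flipped."""
        d = dict(self.direction)
        for g in groups:
            d[g] = REVERSE if d[g] == POSITIVE else POSITIVE
        return CodingVector(direction=d, label=label or f"{self.label}_flip_{'_'.join(groups)}")

    def to_dict(self) -> dict:
        return {"label": self.label, "direction": dict(self.direction)}

    @classmethod
    def from_dict(cls, d: dict) -> "CodingVector":
        return cls(direction=dict(d["direction"]), label=d.get("label", "custom"))


def default_grouping() -> FoodGroupingConfig:
    """The 18-group configuration (7 healthy-plant, 5 unhealthy-plant,
    6 animal) with the four potato items mapped into the potatoes group."""
    groups = DEFAULT_HEALTHY_PLANT_GROUPS + DEFAULT_UNHEALTHY_PLANT_GROUPS + DEFAULT_ANIMAL_GROUPS
    super_category = {}
    super_category.update({g: HEALTHY_PLANT for g in DEFAULT_HEALTHY_PLANT_GROUPS})
    super_category.update({g: UNHEALTHY_PLANT for g in DEFAULT_UNHEALTHY_PLANT_GROUPS})
    super_category.update({g: ANIMAL for g in DEFAULT_ANIMAL_GROUPS})
    item_map = {item: "potatoes" for item in POTATO_ITEMS}
    return FoodGroupingConfig(
        groups=groups, super_category=super_category, item_map=item_map, label="table1"
    )


def scaled_grouping(n_healthy: int = 3, n_unhealthy: int = 3, n_animal: int = 6) -> FoodGroupingConfig:
    """A reduced configuration keeping the first groups of each category.

    Used for scaled-down multiverse runs (e.g. 2**6 = 64 codings with
    six plant groups) where the full 4,096-model enumeration is not
    needed.  Indices are rescaled to the 18-90 range as usual.
    """
    base = default_grouping()
    healthy = base.groups_in(HEALTHY_PLANT)[:n_healthy]
    unhealthy = base.groups_in(UNHEALTHY_PLANT)[:n_unhealthy]
    animal = base.groups_in(ANIMAL)[:n_animal]
    groups = healthy + unhealthy + animal
    sc = {g: base.super_category[g] for g in groups}
    item_map = {i: g for i, g in base.item_map.items() if g in groups}
    return FoodGroupingConfig(
        groups=groups,
        super_category=sc,
        item_map=item_map,
        label=f"scaled_h{n_healthy}_u{n_unhealthy}_a{n_animal}",
    )


def _standard_coding(config: FoodGroupingConfig, positive_cats: tuple[str, ...], label: str) -> CodingVector:
    direction = {
        g: (POSITIVE if config.super_category[g] in positive_cats else REVERSE)
        for g in config.groups
    }
    return CodingVector(direction=direction, label=label)


def pdi_coding(config: FoodGroupingConfig) -> CodingVector:
    """Overall index: all plant groups positive, animal groups reverse."""
    return _standard_coding(config, (HEALTHY_PLANT, UNHEALTHY_PLANT), "pdi")


def hpdi_coding(config: FoodGroupingConfig) -> CodingVector:
    """Healthful index: healthy-plant positive, all others reverse."""
    return _standard_coding(config, (HEALTHY_PLANT,), "hpdi")


def updi_coding(config: FoodGroupingConfig) -> CodingVector:
    """Unhealthful index: unhealthy-plant positive, all others reverse."""
    return _standard_coding(config, (UNHEALTHY_PLANT,), "updi")


STANDARD_CODINGS = {"pdi": pdi_coding, "hpdi": hpdi_coding, "updi": updi_coding}


def coding_from_bits(config: FoodGroupingConfig, bits: tuple[int, ...]) -> CodingVector:
    """Coding vector from a bit-vector over the plant groups.

    ``bits[i] == 1`` codes plant group ``i`` (in config order) positive,
    0 codes it reverse; animal groups are always reverse.  The label is
    the bit string, e.g. ``"101100110010"``.
    """
    plants = config.plant_groups
    if len(bits) != len(plants):
        raise ConfigError(f"bits: expected {len(plants)} entries, got {len(bits)}")
    direction = {g: REVERSE for g in config.groups}
    for g, b in zip(plants, bits):
        direction[g] = POSITIVE if b else REVERSE
    return CodingVector(direction=direction, label="".join(str(int(b)) for b in bits))


def enumerate_plant_codings(config: FoodGroupingConfig) -> list[CodingVector]:
    """All 2**P codings over the P plant groups, animal groups fixed reverse.

    Enumeration is lexicographic over the bit-vector in config group
    order (0...0, 0...1, ..., 1...1) so runs are deterministic and
    diffable.
    """
    plants = config.plant_groups
    return [coding_from_bits(config, bits) for bits in itertools.product((0, 1), repeat=len(plants))]
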