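"""Registry of the per-slide histomorphological variables.

The slide-level database carries one row per stained section and one column
per histomorphological variable.  Each variable has a measurement scale
(nominal / ordinal / interval), a declared value range in its own units, and
a set of stainings it can be read from.  The registry below covers the 16
variables gathered in the trial work-up: visual gradings (0-4), visually
estimated percentages (0-100 %), follicle counts, and segmented or
automatically measured areas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

Scale = Literal["nominal", "ordinal", "interval"]

#: Closed set of stains a slide can carry.
STAININGS: tuple[str, ...] = ("HE", "CD23", "CD20", "IgD")

#: Default anatomical region vocabulary: the completely worked-up central
#: plane "A" plus representative sections of the right/left lobe above and
#: below it (upper/lower).
DEFAULT_REGIONS: tuple[str, ...] = ("A", "RU", "RL", "LU", "LL")


@dataclass(frozen=True)
class VariableSpec:
    """Schema entry for one histomorphological variable.

    Parameters
    ----------
    name
        Canonical snake_case column name used in slide tables.
    scale
        Measurement scale; nominal variables are stored verbatim and
        excluded from every numeric operation.
    range_min, range_max
        Declared value range (inclusive) for ordinal/interval variables.
    units
        Human-readable unit string ("grade", "%", "count", "px").
    stainings
        Stains the variable is read from.
    """

    name: str
    scale: Scale
    range_min: float | None = None
    range_max: float | None = None
    units: str = ""
    stainings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.scale not in ("nominal", "ordinal", "interval"):
            raise ValueError(f"unknown scale {self.scale!r} for {self.name}")
        if self.scale != "nominal":
            if self.range_min is None or self.range_max is None:
                raise ValueError(f"{self.name}: ordinal/interval variables need a range")
            if not self.range_min < self.range_max:
                raise ValueError(f"{self.name}: range_min must be < range_max")
        for s in self.stainings:
            if s not in STAININGS:
                raise ValueError(f"{self.name}: unknown staining {s!r}")

    @property
    def is_numeric(self) -> bool:
        return self.scale != "nominal"

    def in_range(self, value: float) -> bool:
        """True if ``value`` respects the declared range (numeric scales only)."""
        if not self.is_numeric:
            raise ValueError(f"{self.name} is nominal; has no numeric range")
        return self.range_min <= value <= self.range_max  # type: ignore[operator]


def _grade(name: str, stainings: tuple[str, ...]) -> VariableSpec:
    return VariableSpec(name, "ordinal", 0, 4, "grade", stainings)


def _percent(name: str, stainings: tuple[str, ...]) -> VariableSpec:
    return VariableSpec(name, "interval", 0, 100, "%", stainings)


def _count(name: str, stainings: tuple[str, ...]) -> VariableSpec:
    return VariableSpec(name, "interval", 0, 100, "count", stainings)


def _area(name: str, stainings: tuple[str, ...]) -> VariableSpec:
    return VariableSpec(name, "interval", 0, 10_000, "px", stainings)


#: The 16 gathered variables, in work-up order.
VARIABLES: tuple[VariableSpec, ...] = (
    VariableSpec("follicle_morphology", "nominal", stainings=("HE", "CD23")),
    _grade("grading_atrophy", ("HE",)),
    _grade("grading_follicle", ("HE", "CD23")),
    _percent("overall_fat", ("HE",)),
    _percent("intrathymic_fat", ("HE",)),
    _percent("b_cell_infiltrate", ("CD20",)),
    _count("n_follicle", ("HE", "CD23")),
    _area("cortical_area", ("HE",)),
    _area("medullary_area", ("HE",)),
    _area("follicle_area", ("HE", "CD23", "IgD")),
    _area("germinal_centre_area", ("HE", "CD23", "IgD")),
    _area("mantle_zone_area", ("HE", "CD23", "IgD")),
    _area("marginal_zone_area", ("HE", "CD23", "IgD")),
    _area("thymic_tissue_area", ("HE",)),
    _count("n_follicle_gc", ("HE",)),
    _count("n_follicle_no_gc", ("HE",)),
)

VARIABLES_BY_NAME: dict[str, VariableSpec] = {v.name: v for v in VARIABLES}
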