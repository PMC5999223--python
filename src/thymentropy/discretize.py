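"""Mapping raw slide measurements to integer levels.

Entropy is defined on *levels*, not raw values: each measurement point
(slide) gets one integer level per variable.  Level schemes follow the
coarse a-priori binning used for the trial data:

* follicle counts — 10 levels of width 5 over [0, 50): level 0 = <5
  follicles, level 1 = 5-<10, ..., level 9 = 45-50 (counts above 50, which
  the variable range formally allows, clamp into the top level with a
  warning);
* visual gradings (atrophy, follicular hyperplasia) — identity on grades
  0-4, i.e. L = 5;
* estimated percentages (fat content, B-cell infiltrate) — 10 levels of
  width 10 % over [0, 100].

Bins are left-closed/right-open with the range maximum clamped into the top
level, and levels are 0-based throughout.  The choice of 10 levels for
interval variables deliberately mirrors the intensity-level reduction common
in image processing: enough levels not to hide heterogeneity, few enough
that trivial measurement jitter (5 % vs 8 % fat) does not register.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping

import numpy as np
import yaml

from .variables import VARIABLES_BY_NAME

if TYPE_CHECKING:  # pragma: no cover
    from .data import CaseTable

log = logging.getLogger(__name__)


class EmptySequenceError(ValueError):
    """No slide contributed a value for this case/variable."""


@dataclass(frozen=True)
class LevelScheme:
    """Discretization rule for one variable.

    Either an ordinal identity scheme (``ordinal=True``: grade g maps to
    level g - ordinal_min) or an interval scheme with ``n_levels + 1``
    strictly increasing, left-closed/right-open bin ``edges`` tiling the
    declared range.  ``clamp_max`` optionally admits values above the top
    edge (clamped into the top level with a warning), for variables whose
    formal range exceeds the binned range.
    """

    variable: str
    n_levels: int
    edges: tuple[float, ...] | None = None
    ordinal: bool = False
    ordinal_min: int = 0
    clamp_max: float | None = None

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError(f"{self.variable}: n_levels must be >= 1")
        if self.ordinal:
            if self.edges is not None:
                raise ValueError(f"{self.variable}: ordinal scheme must not carry edges")
        else:
            if self.edges is None:
                raise ValueError(f"{self.variable}: interval scheme needs edges")
            e = np.asarray(self.edges, dtype=float)
            if len(e) != self.n_levels + 1:
                raise ValueError(f"{self.variable}: need n_levels+1 edges, got {len(e)}")
            if not np.all(np.diff(e) > 0):
                raise ValueError(f"{self.variable}: edges must be strictly increasing")
            if self.clamp_max is not None and self.clamp_max < e[-1]:
                raise ValueError(f"{self.variable}: clamp_max below top edge")

    @property
    def range_min(self) -> float:
        return float(self.ordinal_min if self.ordinal else self.edges[0])  # type: ignore[index]

    @property
    def range_max(self) -> float:
        if self.ordinal:
            return float(self.ordinal_min + self.n_levels - 1)
        return float(self.clamp_max if self.clamp_max is not None else self.edges[-1])  # type: ignore[index]


@dataclass(frozen=True)
class LevelSequence:
    """Ordered per-point levels for one case and variable."""

    case_id: str
    variable: str
    levels: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.levels) < 1:
            raise EmptySequenceError(f"{self.case_id}/{self.variable}: empty level sequence")

    @property
    def m(self) -> int:
        """Number of measurement points."""
        return len(self.levels)


@dataclass(frozen=True)
class FeatureDef:
    """One entropy feature: a variable read from one staining, with its scheme."""

    name: str
    variable: str
    staining: str
    scheme: LevelScheme


def follicle_count_scheme(variable: str = "n_follicle") -> LevelScheme:
    """10 levels of width 5 follicles over [0, 50); counts up to 100 clamp."""
    return LevelScheme(
        variable, 10, edges=tuple(float(x) for x in range(0, 55, 5)), clamp_max=100.0
    )


def grade_scheme(variable: str) -> LevelScheme:
    """Identity on ordinal grades 0-4 (L = 5)."""
    return LevelScheme(variable, 5, ordinal=True, ordinal_min=0)


def percent_scheme(variable: str) -> LevelScheme:
    """10 levels of width 10 % tiling [0, 100]."""
    return LevelScheme(variable, 10, edges=tuple(float(x) for x in range(0, 110, 10)))


def default_features() -> dict[str, FeatureDef]:
    """The four entropy features analyzed by default.

    Follicles are read from CD23-stained sections (follicular dendritic
    cells mark lymphoid follicles), fat and atrophy from HE-stained ones.
    """
    return {
        "n_follicle_cd23": FeatureDef(
            "n_follicle_cd23", "n_follicle", "CD23", follicle_count_scheme()
        ),
        "grading_follicle_cd23": FeatureDef(
            "grading_follicle_cd23", "grading_follicle", "CD23", grade_scheme("grading_follicle")
        ),
        "grading_intrathymic_fat": FeatureDef(
            "grading_intrathymic_fat", "intrathymic_fat", "HE", percent_scheme("intrathymic_fat")
        ),
        "grading_atrophy": FeatureDef(
            "grading_atrophy", "grading_atrophy", "HE", grade_scheme("grading_atrophy")
        ),
    }


#: Canonical order of the four default entropy features.
DEFAULT_FEATURE_NAMES = tuple(default_features())


def default_schemes() -> dict[str, LevelScheme]:
    """Level schemes of the default features, keyed by feature name."""
    return {name: fd.scheme for name, fd in default_features().items()}


def assign_level(value: float, scheme: LevelScheme) -> int:
    """Map one raw value to its 0-based integer level.

    Interval schemes bin left-closed/right-open; a value equal to the top
    edge (or between top edge and ``clamp_max``) clamps into the top level.
    Values outside the admissible range raise ``ValueError``.
    """
    if np.isnan(value):
        raise ValueError(f"{scheme.variable}: cannot level a missing value")
    if scheme.ordinal:
        if value != int(value):
            raise ValueError(f"{scheme.variable}: ordinal value {value!r} is not an integer grade")
        lvl = int(value) - scheme.ordinal_min
        if not 0 <= lvl < scheme.n_levels:
            raise ValueError(
                f"{scheme.variable}: grade {value:g} outside "
                f"[{scheme.ordinal_min}, {scheme.ordinal_min + scheme.n_levels - 1}]"
            )
        return lvl
    edges = scheme.edges  # type: ignore[assignment]
    if value < edges[0] or value > scheme.range_max:
        raise ValueError(
            f"{scheme.variable}: value {value:g} outside [{edges[0]:g}, {scheme.range_max:g}]"
        )
    if value >= edges[-1]:
        if value > edges[-1]:
            log.warning(
                "%s: value %g above top edge %g; clamped into level %d",
                scheme.variable, value, edges[-1], scheme.n_levels - 1,
            )
        return scheme.n_levels - 1
    return int(np.searchsorted(edges, value, side="right")) - 1


def discretize_case(
    case_table: "CaseTable",
    case_id: str,
    scheme: LevelScheme,
    staining: str | None = None,
    feature: str | None = None,
) -> LevelSequence:
    """Level sequence for one case: one level per contributing slide.

    Slides are ordered by ``slide_id`` for determinism; slides missing the
    variable (after the staining filter) are dropped, shrinking m.  Zero
    contributing slides raise :class:`EmptySequenceError`.
    """
    values = case_table.values(case_id, scheme.variable, staining)
    if len(values) == 0:
        raise EmptySequenceError(
            f"{case_id}/{scheme.variable}"
            + (f" ({staining})" if staining else "")
            + ": no contributing slides"
        )
    levels = tuple(assign_level(v, scheme) for v in values)
    return LevelSequence(case_id, feature or scheme.variable, levels)


def discretize_all(
    case_table: "CaseTable",
    scheme: LevelScheme,
    staining: str | None = None,
    feature: str | None = None,
) -> dict[str, LevelSequence]:
    """Level sequences for every case; cases without data are skipped with a warning."""
    out: dict[str, LevelSequence] = {}
    for cid in case_table.case_ids:
        try:
            out[cid] = discretize_case(case_table, cid, scheme, staining, feature)
        except EmptySequenceError as exc:
            log.warning("skipping case: %s", exc)
    return out


# -- (de)serialization -------------------------------------------------

def scheme_to_dict(scheme: LevelScheme) -> dict:
    d: dict = {"variable": scheme.variable, "n_levels": scheme.n_levels}
    if scheme.ordinal:
        d["ordinal"] = True
        if scheme.ordinal_min:
            d["ordinal_min"] = scheme.ordinal_min
    else:
        d["edges"] = list(scheme.edges)  # type: ignore[arg-type]
        if scheme.clamp_max is not None:
            d["clamp_max"] = scheme.clamp_max
    return d


def scheme_from_dict(d: Mapping) -> LevelScheme:
    return LevelScheme(
        variable=d["variable"],
        n_levels=int(d["n_levels"]),
        edges=tuple(d["edges"]) if "edges" in d else None,
        ordinal=bool(d.get("ordinal", False)),
        ordinal_min=int(d.get("ordinal_min", 0)),
        clamp_max=d.get("clamp_max"),
    )


def schemes_to_yaml(schemes: Mapping[str, LevelScheme]) -> str:
    return yaml.safe_dump(
        {name: scheme_to_dict(s) for name, s in schemes.items()}, sort_keys=True
    )


def schemes_from_yaml(text: str) -> dict[str, LevelScheme]:
    raw = yaml.safe_load(text)
    return {name: scheme_from_dict(d) for name, d in raw.items()}
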