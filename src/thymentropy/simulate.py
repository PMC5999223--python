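"""Synthetic cohort generator with plantable effects of entropy on endpoints.

Emulates the structure of a 55-case thymectomy cohort: each case gets a
number of tissue blocks drawn from a rounded normal 11 +/- 5 (floor 3), and
each block yields an HE-stained slide (atrophy grade, intrathymic fat
percentage) and a CD23-stained slide (follicle count, follicular
hyperplasia grade).

Heterogeneity is parameterized at the level-distribution layer: per case
and feature a level-probability vector is drawn from a symmetric
Dirichlet(alpha) over the feature's L levels (small alpha -> one dominant
level, i.e. spatially homogeneous; large alpha -> spread, heterogeneous),
slide levels are drawn i.i.d. from it, and raw values are back-transformed
uniformly within the level's bin.  The default alpha is calibrated so that
the cohort's per-case Shannon entropy of the follicle count lands around
0.5 +/- 0.6 bit, the scale reported for the trial cohort.

Clinical endpoints are planted functions of the case's realized point-sum
entropy (the default downstream predictor): linear with Gaussian noise for
continuous endpoints, logistic for the binary ones.  The default
configuration plants a single effect - intrathymic-fat entropy on the
post-operative prednisone load - sized together with the 9 g noise sd to
give roughly 90 % power for a single-predictor refit at 200 cases.

Everything is reproducible bit-identically from (config, seed); the
manifest records the realized per-case truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import CaseTable, read_slide_table
from .discretize import FeatureDef, default_features
from .entropy import entropy_pointsum, entropy_shannon, max_entropy_reference
from .variables import DEFAULT_REGIONS

#: Symmetric Dirichlet concentration per feature (see module docstring).
DEFAULT_ALPHA = 0.04

#: Planted effect of intrathymic-fat point-sum entropy (bit) on the
#: post-operative prednisone load (g): slope in g/bit, sized together with
#: the 9 g residual sd for ~90 % single-predictor power at n = 200.
DEFAULT_FAT_EFFECT = 0.8

#: (intercept, residual sd) of the continuous endpoints, in their units.
ENDPOINT_BASE: dict[str, tuple[float, float]] = {
    "qmg_baseline": (12.0, 4.0),  # QMG score at enrollment
    "mg_duration_months": (15.0, 8.0),
    "prednisone_pre_g": (25.0, 10.0),
    "prednisone_post_g": (60.0, 9.0),
}

#: Logit-scale intercepts of the binary endpoints.
BINARY_BASE: dict[str, float] = {
    "qmg_drop_m12_36": 0.4,  # ~60 % improve by >= 3 QMG points
    "mms_m12_36": 0.2,
}


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the synthetic cohort.

    ``dirichlet_alpha`` maps feature name -> concentration; ``effects``
    maps endpoint -> {feature: slope}, on the response scale for continuous
    endpoints and on the logit scale for binary ones.  ``noise_sd``
    overrides the residual sd of continuous endpoints.  The seed is part of
    the config: the same config regenerates the same cohort bit for bit.
    """

    seed: int
    n_cases: int = 55
    slides_per_case_mean: float = 11.0
    slides_per_case_sd: float = 5.0
    min_slides_per_case: int = 3
    dirichlet_alpha: Mapping[str, float] = field(default_factory=dict)
    effects: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "prednisone_post_g": {"grading_intrathymic_fat": DEFAULT_FAT_EFFECT}
        }
    )
    noise_sd: Mapping[str, float] = field(default_factory=dict)
    female_fraction: float = 0.65

    def __post_init__(self) -> None:
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")
        if self.slides_per_case_sd < 0:
            raise ValueError("slides_per_case_sd must be >= 0")
        if self.min_slides_per_case < 1:
            raise ValueError("min_slides_per_case must be >= 1")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must be a probability")
        feats = default_features()
        for name, a in self.dirichlet_alpha.items():
            if name not in feats:
                raise ValueError(f"dirichlet_alpha: unknown feature {name!r}")
            if a <= 0:
                raise ValueError(f"dirichlet_alpha[{name!r}] must be > 0")
        known_eps = set(ENDPOINT_BASE) | set(BINARY_BASE)
        for ep, fx in self.effects.items():
            if ep not in known_eps:
                raise ValueError(f"effects: unknown endpoint {ep!r}")
            for name in fx:
                if name not in feats:
                    raise ValueError(f"effects[{ep!r}]: unknown feature {name!r}")
        for ep, sd in self.noise_sd.items():
            if ep not in ENDPOINT_BASE:
                raise ValueError(f"noise_sd: unknown continuous endpoint {ep!r}")
            if sd < 0:
                raise ValueError(f"noise_sd[{ep!r}] must be >= 0")

    def alpha_for(self, feature: str) -> float:
        return float(self.dirichlet_alpha.get(feature, DEFAULT_ALPHA))

    def sd_for(self, endpoint: str) -> float:
        return float(self.noise_sd.get(endpoint, ENDPOINT_BASE[endpoint][1]))

    def with_null_effects(self) -> "CohortConfig":
        """Copy of this config with every planted effect removed."""
        return replace(self, effects={})


@dataclass(frozen=True)
class CaseTruth:
    """Realized ground truth for one simulated case."""

    case_id: str
    n_blocks: int
    level_probs: Mapping[str, tuple[float, ...]]
    levels: Mapping[str, tuple[int, ...]]
    h_pointsum: Mapping[str, float]
    h_shannon: Mapping[str, float]
    h_max: Mapping[str, float]
    endpoint_mean: Mapping[str, float]  # linear predictor (logit scale for binary)


@dataclass(frozen=True)
class CohortManifest:
    """Per-case truth of one simulated cohort; regenerable from (config, seed)."""

    seed: int
    n_cases: int
    cases: tuple[CaseTruth, ...]

    def to_frame(self) -> pd.DataFrame:
        """True per-case entropies as a wide DataFrame (case_id index)."""
        rows = {}
        for c in self.cases:
            row: dict[str, float] = {"n_blocks": c.n_blocks}
            for f in c.h_pointsum:
                row[f"m_{f}"] = len(c.levels[f])
                row[f"H_pointsum_{f}"] = c.h_pointsum[f]
                row[f"H_shannon_{f}"] = c.h_shannon[f]
                row[f"H_max_{f}"] = c.h_max[f]
            rows[c.case_id] = row
        out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
        out.index.name = "case_id"
        return out

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "n_cases": self.n_cases,
            "cases": [
                {
                    "case_id": c.case_id,
                    "n_blocks": c.n_blocks,
                    "level_probs": {k: list(v) for k, v in c.level_probs.items()},
                    "levels": {k: list(v) for k, v in c.levels.items()},
                    "h_pointsum": dict(c.h_pointsum),
                    "h_shannon": dict(c.h_shannon),
                    "h_max": dict(c.h_max),
                    "endpoint_mean": dict(c.endpoint_mean),
                }
                for c in self.cases
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


@dataclass(frozen=True)
class SimulatedCohort:
    slides: pd.DataFrame | None
    clinical: pd.DataFrame
    manifest: CohortManifest


def _raw_value(feature: FeatureDef, level: int, rng: np.random.Generator) -> float:
    """Back-transform a level to a raw value uniformly within its bin."""
    scheme = feature.scheme
    if scheme.ordinal:
        return float(scheme.ordinal_min + level)
    lo, hi = scheme.edges[level], scheme.edges[level + 1]  # type: ignore[index]
    if feature.variable.startswith("n_follicle"):
        # counts are integers; top bin includes the closed upper edge
        top = int(hi) + 1 if level == scheme.n_levels - 1 else int(hi)
        return float(rng.integers(int(lo), top))
    return float(rng.uniform(lo, hi))


def simulate_cohort(
    config: CohortConfig,
    features: Mapping[str, FeatureDef] | None = None,
    tables: bool = True,
) -> SimulatedCohort:
    """Draw one synthetic cohort.

    With ``tables=False`` only the manifest and clinical table are built
    (identical to the ``tables=True`` draw: raw slide values come from a
    separate child random stream so skipping them does not perturb the
    truth draws).
    """
    feats = dict(features or default_features())
    truth_rng, value_rng = (
        np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(2)
    )

    n_blocks = np.maximum(
        config.min_slides_per_case,
        np.rint(
            truth_rng.normal(
                config.slides_per_case_mean, config.slides_per_case_sd, config.n_cases
            )
        ).astype(int),
    )

    cases: list[CaseTruth] = []
    clin_rows: list[dict] = []
    for i in range(config.n_cases):
        cid = f"SYN{i:03d}"
        m = int(n_blocks[i])
        level_probs: dict[str, tuple[float, ...]] = {}
        levels: dict[str, tuple[int, ...]] = {}
        h_pointsum: dict[str, float] = {}
        h_shannon: dict[str, float] = {}
        h_max: dict[str, float] = {}
        for name, fd in feats.items():
            L = fd.scheme.n_levels
            p = truth_rng.dirichlet(np.full(L, config.alpha_for(name)))
            lv = truth_rng.choice(L, size=m, p=p)
            level_probs[name] = tuple(float(x) for x in p)
            levels[name] = tuple(int(x) for x in lv)
            h_pointsum[name] = entropy_pointsum(lv)
            h_shannon[name] = entropy_shannon(lv)
            h_max[name] = max_entropy_reference(m, L)

        # demographics
        age = float(np.clip(truth_rng.normal(44.0, 13.0), 18.0, 68.0))
        sex = "female" if truth_rng.random() < config.female_fraction else "male"
        bmi = float(np.clip(truth_rng.normal(27.0, 5.0), 16.0, 45.0))

        # endpoints: planted function of the realized point-sum entropies
        endpoint_mean: dict[str, float] = {}
        clin = {"case_id": cid, "age": age, "sex": sex, "bmi": bmi}
        for ep, (intercept, _) in ENDPOINT_BASE.items():
            mu = intercept + sum(
                beta * h_pointsum[f] for f, beta in config.effects.get(ep, {}).items()
            )
            endpoint_mean[ep] = mu
            clin[ep] = mu + truth_rng.normal(0.0, config.sd_for(ep))
        for ep, b0 in BINARY_BASE.items():
            eta = b0 + sum(
                beta * h_pointsum[f] for f, beta in config.effects.get(ep, {}).items()
            )
            endpoint_mean[ep] = eta
            clin[ep] = int(truth_rng.random() < expit(eta))

        cases.append(
            CaseTruth(cid, m, level_probs, levels, h_pointsum, h_shannon, h_max, endpoint_mean)
        )
        clin_rows.append(clin)

    clinical = pd.DataFrame(clin_rows)[
        [
            "case_id", "age", "sex", "bmi", "qmg_baseline", "qmg_drop_m12_36",
            "mms_m12_36", "mg_duration_months", "prednisone_pre_g", "prednisone_post_g",
        ]
    ]
    manifest = CohortManifest(config.seed, config.n_cases, tuple(cases))

    slides = _build_slide_table(cases, feats, value_rng) if tables else None
    return SimulatedCohort(slides=slides, clinical=clinical, manifest=manifest)


def _build_slide_table(
    cases: list[CaseTruth],
    feats: Mapping[str, FeatureDef],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """One HE and one CD23 slide row per tissue block, regions round-robin."""
    by_stain: dict[str, list[FeatureDef]] = {}
    for fd in feats.values():
        by_stain.setdefault(fd.staining, []).append(fd)
    variables = sorted({fd.variable for fd in feats.values()})
    rows: list[dict] = []
    for case in cases:
        for b in range(case.n_blocks):
            region = DEFAULT_REGIONS[b % len(DEFAULT_REGIONS)]
            for stain in sorted(by_stain):
                row: dict = {
                    "case_id": case.case_id,
                    "region": region,
                    "slide_id": f"{case.case_id}_B{b:02d}_{stain}",
                    "staining": stain,
                    **{v: np.nan for v in variables},
                }
                for fd in by_stain[stain]:
                    row[fd.variable] = _raw_value(fd, case.levels[fd.name][b], rng)
                rows.append(row)
    return pd.DataFrame(rows)[["case_id", "region", "slide_id", "staining", *variables]]


def make_boundary_fixture() -> pd.DataFrame:
    """Handcrafted mini slide table exercising every level boundary.

    Three six-block cases:

    * ``FIX001`` — follicle counts {3, 5, 9, 10, 49, 50} probing the bin
      edges (levels 0, 1, 1, 2, 9, 9) and grades spanning 0-4;
    * ``FIX002`` — completely homogeneous (six identical grades and
      follicle counts): every entropy is 0 downstream;
    * ``FIX003`` — six follicle counts in six distinct levels: point-sum
      entropy log2(6).
    """
    spec = {
        "FIX001": dict(follicles=[3, 5, 9, 10, 49, 50], grades=[0, 1, 2, 3, 4, 2]),
        "FIX002": dict(follicles=[7, 7, 7, 7, 7, 7], grades=[2, 2, 2, 2, 2, 2]),
        "FIX003": dict(follicles=[2, 7, 12, 17, 22, 27], grades=[0, 0, 1, 1, 2, 2]),
    }
    rows = []
    for cid, d in spec.items():
        for b, (nf, gr) in enumerate(zip(d["follicles"], d["grades"])):
            region = DEFAULT_REGIONS[b % len(DEFAULT_REGIONS)]
            rows.append(
                {
                    "case_id": cid, "region": region,
                    "slide_id": f"{cid}_B{b:02d}_HE", "staining": "HE",
                    "grading_atrophy": gr, "grading_follicle": np.nan,
                    "intrathymic_fat": 10.0 * gr + 5.0, "n_follicle": np.nan,
                }
            )
            rows.append(
                {
                    "case_id": cid, "region": region,
                    "slide_id": f"{cid}_B{b:02d}_CD23", "staining": "CD23",
                    "grading_atrophy": np.nan, "grading_follicle": gr,
                    "intrathymic_fat": np.nan, "n_follicle": nf,
                }
            )
    cols = [
        "case_id", "region", "slide_id", "staining",
        "grading_atrophy", "grading_follicle", "intrathymic_fat", "n_follicle",
    ]
    return pd.DataFrame(rows)[cols]


def fixture_case_table() -> CaseTable:
    """The mini fixture loaded through the regular reading path."""
    import io

    buf = io.StringIO()
    make_boundary_fixture().to_csv(buf, index=False)
    buf.seek(0)
    return read_slide_table(buf)
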