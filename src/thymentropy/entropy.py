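"""Per-case entropy of discretized histomorphological features.

Two estimators are computed from each level sequence (in bits, log base 2):

* ``entropy_pointsum`` — the point-sum statistic used as the heterogeneity
  marker: H = -sum over measurement points i of p_i * log2(p_i), where p_i
  is the empirical relative frequency of point i's level.  In level terms
  this is -m * sum_k p_k^2 log2(p_k), so for a fixed level distribution it
  grows linearly with the number of measurement points m.
* ``entropy_shannon`` — the standard plug-in Shannon entropy, summed over
  *levels*: -sum_k p_k log2 p_k.  Bounded by log2(min(m, L)).

Both are exactly zero iff every point carries the same level.  The
theoretical reference maximum ``max_entropy_reference(m, L) = m * (1/L) *
log2(L)`` treats every point as carrying probability 1/L; it is the large-m
limit of the point-sum statistic per point under uniform levels times m,
but not a supremum of the statistic at finite m (two equally frequent
levels at m = 6 already give 3.0 bit > Hmax(6, 10) = 1.993 bit).

Probabilities are raw empirical frequencies; no smoothing or bias
correction is applied.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .data import CaseTable
from .discretize import (
    EmptySequenceError,
    FeatureDef,
    LevelSequence,
    default_features,
    discretize_case,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LevelDistribution:
    """Empirical level distribution of one sequence."""

    counts: dict[int, int]
    m: int
    probs: dict[int, float]


def _levels(seq: "LevelSequence | Sequence[int]") -> Sequence[int]:
    if isinstance(seq, LevelSequence):
        return seq.levels
    return list(seq)


def level_distribution(seq: "LevelSequence | Sequence[int]") -> LevelDistribution:
    """Counts and empirical relative frequencies of the observed levels."""
    levels = _levels(seq)
    if len(levels) == 0:
        raise EmptySequenceError("cannot form a distribution from an empty sequence")
    counts = dict(sorted(Counter(levels).items()))
    m = len(levels)
    probs = {k: c / m for k, c in counts.items()}
    return LevelDistribution(counts, m, probs)


def entropy_pointsum(seq: "LevelSequence | Sequence[int]") -> float:
    """Point-sum entropy: -sum over points of p_i log2 p_i, in bits.

    p_i is the empirical frequency of the level observed at point i; a
    level observed c times therefore contributes c * (-(c/m) log2(c/m)).
    Constant sequences return exactly 0.0.
    """
    dist = level_distribution(seq)
    if len(dist.counts) == 1:
        return 0.0
    m = dist.m
    return float(sum(c * (-(c / m) * math.log2(c / m)) for c in dist.counts.values()))


def entropy_shannon(seq: "LevelSequence | Sequence[int]") -> float:
    """Standard plug-in Shannon entropy over levels, in bits."""
    dist = level_distribution(seq)
    if len(dist.counts) == 1:
        return 0.0
    return float(-sum(p * math.log2(p) for p in dist.probs.values()))


def max_entropy_reference(m: int, n_levels: int) -> float:
    """Reference maximum m * (1/L) * log2(L), in bits.

    Every one of the m points is treated as carrying an equiprobable level
    (p = 1/L).  L = 1 yields 0.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if n_levels < 1:
        raise ValueError("n_levels must be >= 1")
    if n_levels == 1:
        return 0.0
    return float(m * (1.0 / n_levels) * math.log2(n_levels))


@dataclass(frozen=True)
class FeatureEntropy:
    """Entropy of one feature for one case."""

    m: int
    h_pointsum: float
    h_shannon: float
    h_max: float


@dataclass(frozen=True)
class CaseEntropyProfile:
    """Per-case entropies; features without data carry ``None``."""

    case_id: str
    features: Mapping[str, FeatureEntropy | None]


def feature_entropy(seq: "LevelSequence | Sequence[int]", n_levels: int) -> FeatureEntropy:
    """Both estimators plus the reference maximum for one sequence."""
    levels = _levels(seq)
    return FeatureEntropy(
        m=len(levels),
        h_pointsum=entropy_pointsum(levels),
        h_shannon=entropy_shannon(levels),
        h_max=max_entropy_reference(len(levels), n_levels),
    )


def compute_profiles(
    case_table: CaseTable,
    features: Mapping[str, FeatureDef] | None = None,
) -> list[CaseEntropyProfile]:
    """One entropy profile per case over the configured features.

    Cases lacking a feature (no slide with that variable/staining) carry a
    missing entry for it, never a zero.
    """
    feats = dict(features or default_features())
    profiles = []
    for cid in case_table.case_ids:
        per_feature: dict[str, FeatureEntropy | None] = {}
        for name, fd in feats.items():
            try:
                seq = discretize_case(case_table, cid, fd.scheme, fd.staining, feature=name)
            except EmptySequenceError:
                log.warning("case %s: no data for feature %s; entry left missing", cid, name)
                per_feature[name] = None
                continue
            per_feature[name] = feature_entropy(seq, fd.scheme.n_levels)
        profiles.append(CaseEntropyProfile(cid, per_feature))
    return profiles


def profiles_to_frame(profiles: Iterable[CaseEntropyProfile]) -> pd.DataFrame:
    """Wide per-case table: columns ``m_<f>, H_pointsum_<f>, H_shannon_<f>, H_max_<f>``."""
    rows = {}
    for prof in profiles:
        row: dict[str, float] = {}
        for name, fe in prof.features.items():
            if fe is None:
                row[f"m_{name}"] = float("nan")
                row[f"H_pointsum_{name}"] = float("nan")
                row[f"H_shannon_{name}"] = float("nan")
                row[f"H_max_{name}"] = float("nan")
            else:
                row[f"m_{name}"] = fe.m
                row[f"H_pointsum_{name}"] = fe.h_pointsum
                row[f"H_shannon_{name}"] = fe.h_shannon
                row[f"H_max_{name}"] = fe.h_max
        rows[prof.case_id] = row
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "case_id"
    return out


def write_entropy_table(
    profiles: Iterable[CaseEntropyProfile], path: str | Path, sep: str = ","
) -> None:
    """Write the per-case entropy table as delimited text."""
    profiles_to_frame(profiles).to_csv(path, sep=sep)
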