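"""One-call orchestration: ingest or simulate -> levels -> entropy -> statistics.

``run_pipeline`` executes the full analysis and writes a deterministic
report bundle (CSV/JSON only; identical config and seed give byte-identical
files).  Stages abort with a stage-named error and partial outputs are
removed.  Clinical data is optional: without it the run stops after the
entropy table and the feature correlation matrix.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import clinical_to_frame, read_clinical_table, read_slide_table
from .discretize import DEFAULT_FEATURE_NAMES, default_features
from .entropy import compute_profiles, profiles_to_frame
from .simulate import CohortConfig, simulate_cohort
from .stats import (
    ALPHA,
    DEFAULT_ENDPOINTS,
    CVReport,
    ModelError,
    fit_model_grid,
    fit_single_predictor,
    kfold_cv,
    pearson_with_p,
)

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source: either ``slides_path`` (with optional
    ``clinical_path``) or a ``simulate`` block.  The seed is recorded in
    every output.
    """

    out_dir: str | Path
    seed: int = 0
    slides_path: str | Path | None = None
    clinical_path: str | Path | None = None
    simulate: CohortConfig | None = None
    estimator: str = "pointsum"  # entropy estimator used as model predictor
    endpoints: Sequence[str] = DEFAULT_ENDPOINTS
    cv_endpoint: str = "prednisone_post_g"
    cv_features: Sequence[str] = ("grading_intrathymic_fat",)
    cv_k: int = 3
    sep: str = ","

    def __post_init__(self) -> None:
        if (self.slides_path is None) == (self.simulate is None):
            raise ValueError("exactly one of slides_path or simulate block required")
        if self.estimator not in ("pointsum", "shannon"):
            raise ValueError("estimator must be 'pointsum' or 'shannon'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = CohortConfig(**raw["simulate"])
        raw.update(overrides)
        return cls(**raw)


@dataclass
class PipelineResult:
    """In-memory handles on everything the run wrote."""

    out_dir: Path
    entropy_frame: pd.DataFrame
    correlation: pd.DataFrame | None = None
    grid: object | None = None
    cv: CVReport | None = None
    paths: dict[str, Path] = field(default_factory=dict)


def report_entropy_matrix(
    entropy_frame: pd.DataFrame,
    estimator: str = "pointsum",
    features: Sequence[str] = DEFAULT_FEATURE_NAMES,
    bins: int = 10,
) -> tuple[pd.DataFrame, dict]:
    """Pairwise Pearson matrix and histogram bins of the entropy features.

    Constant features leave their off-diagonal cells undefined (NaN); the
    diagonal is 1 by construction.  Histograms use ``bins`` equal-width
    bins over each feature's observed range.
    """
    cols = [f"H_{estimator}_{f}" for f in features]
    sub = entropy_frame[cols]
    if len(sub.dropna()) < 3:
        raise ModelError("entropy matrix needs >= 3 cases")
    corr = pd.DataFrame(np.nan, index=list(features), columns=list(features))
    for i, fi in enumerate(features):
        corr.loc[fi, fi] = 1.0
        for fj in features[i + 1:]:
            try:
                res = pearson_with_p(sub[f"H_{estimator}_{fi}"], sub[f"H_{estimator}_{fj}"])
                corr.loc[fi, fj] = corr.loc[fj, fi] = res.r
            except ModelError:
                log.warning("correlation %s vs %s undefined (constant feature)", fi, fj)
    hists = {}
    for f in features:
        vals = sub[f"H_{estimator}_{f}"].dropna().to_numpy()
        counts, edges = np.histogram(vals, bins=bins)
        hists[f] = {"bin_edges": [float(e) for e in edges], "counts": [int(c) for c in counts]}
    return corr, hists


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full pipeline and write the report bundle to ``out_dir``."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    warnings_log: list[str] = []

    def _write(name: str, writer) -> Path:
        path = out_dir / name
        writer(path)
        written.append(path)
        return path

    def _stage(name: str):
        class _Ctx:
            def __enter__(self):
                log.info("stage %s", name)

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    for p in written:
                        p.unlink(missing_ok=True)
                    raise PipelineError(f"stage '{name}': {exc}") from exc
                return False

        return _Ctx()

    paths: dict[str, Path] = {}

    with _stage("ingest"):
        if config.simulate is not None:
            cohort = simulate_cohort(config.simulate)
            assert cohort.slides is not None
            paths["slides"] = _write(
                "slides.csv", lambda p: cohort.slides.to_csv(p, sep=config.sep, index=False)
            )
            paths["clinical"] = _write(
                "clinical.csv", lambda p: cohort.clinical.to_csv(p, sep=config.sep, index=False)
            )
            paths["manifest"] = _write("manifest.json", cohort.manifest.to_json)
            case_table = read_slide_table(paths["slides"], sep=config.sep)
            clinical = cohort.clinical
        else:
            case_table = read_slide_table(config.slides_path, sep=config.sep)
            clinical = (
                clinical_to_frame(read_clinical_table(config.clinical_path, sep=config.sep))
                if config.clinical_path is not None
                else None
            )
        for err in case_table.row_errors:
            warnings_log.append(f"ROW_REJECTED {err}")

    with _stage("entropy"):
        profiles = compute_profiles(case_table, default_features())
        entropy_frame = profiles_to_frame(profiles)
        paths["entropy"] = _write(
            "case_entropy.csv", lambda p: entropy_frame.to_csv(p, sep=config.sep)
        )

    correlation = None
    if len(entropy_frame.dropna()) >= 3:
        with _stage("entropy_matrix"):
            correlation, hists = report_entropy_matrix(entropy_frame, config.estimator)
            paths["correlation"] = _write(
                "entropy_correlation.csv", lambda p: correlation.to_csv(p, sep=config.sep)
            )
            paths["histograms"] = _write(
                "entropy_histograms.json",
                lambda p: p.write_text(json.dumps(hists, indent=1, sort_keys=True)),
            )

    grid = None
    cv = None
    if clinical is not None:
        with _stage("model_grid"):
            grid = fit_model_grid(
                entropy_frame, clinical, config.endpoints, estimator=config.estimator
            )
            paths["model_grid"] = _write(
                "model_grid.csv", lambda p: grid.to_csv(p, sep=config.sep)
            )
            paths["model_grid_detail"] = _write("model_grid.json", grid.to_json)

        with _stage("single_predictor"):
            merged = clinical.merge(entropy_frame.reset_index(), on="case_id")
            refits = []
            pv = grid.p_values.drop(columns="intercept")
            for ep in pv.index:
                for col in pv.columns:
                    p = pv.loc[ep, col]
                    if pd.notna(p) and p < ALPHA and grid.families[ep] == "linear":
                        fit = fit_single_predictor(merged[ep], merged[col])
                        refits.append(
                            {
                                "endpoint": ep,
                                "predictor": col,
                                "slope": fit.slope,
                                "se": fit.se,
                                "p_value": fit.p_value,
                                "r_squared": fit.r_squared,
                                "n": fit.n,
                            }
                        )
            paths["single_predictor"] = _write(
                "single_predictor.json",
                lambda p: p.write_text(json.dumps(refits, indent=1, sort_keys=True)),
            )

        with _stage("cross_validation"):
            cv_cols = [f"H_{config.estimator}_{f}" for f in config.cv_features]
            try:
                cv = kfold_cv(
                    merged[config.cv_endpoint].to_numpy(),
                    merged[cv_cols].to_numpy(),
                    k=config.cv_k,
                    seed=config.seed,
                )
                paths["cv_report"] = _write(
                    "cv_report.json", lambda p: p.write_text(cv.to_json())
                )
            except ModelError as exc:
                warnings_log.append(f"CV_SKIPPED {exc}")
                log.warning("cross-validation skipped: %s", exc)

    with _stage("run_log"):
        run_log = {
            "package": "thymentropy",
            "version": __version__,
            "seed": config.seed,
            "estimator": config.estimator,
            "n_cases": int(case_table.n_cases),
            "warnings": warnings_log,
            "outputs": {k: p.name for k, p in paths.items()},
        }
        paths["run_log"] = _write(
            "run_log.json", lambda p: p.write_text(json.dumps(run_log, indent=1, sort_keys=True))
        )

    result = PipelineResult(out_dir=out_dir, entropy_frame=entropy_frame)
    result.correlation = correlation
    result.grid = grid
    result.cv = cv
    result.paths = paths
    return result
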