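"""End-to-end orchestration: configuration, report bundle, traceability.

A run either *simulates* a cohort from the calibrated generator or loads
landmark/demographic files, then produces the full analysis bundle:

* ``records.csv`` — per-subject demographics, BMI and metrics;
* ``group_comparison.csv`` / ``.txt`` — per-stratum mean (SD), ANOVA p and
  Duncan letters for BMI and every metric;
* ``correlations.csv`` — pooled BMI–metric correlations with significance
  stars and Fisher-z comparisons (20s vs 60s, and vs the published external
  cohort);
* ``te_models.json`` — per stratum: single-predictor logistic fits (odds
  ratio per comparison unit, c statistic), the BMA parsimonious model with
  coefficients, c statistic and optional LOOCV rate, and the BMI×CJWR
  interaction p;
* ``printed_predictions.csv`` — published-equation TE probabilities on a
  BMI×CJWR grid (optional);
* ``manifest.json`` — seed, configuration echo and, per artifact, the
  producing operation and a SHA-256 hash of its input data, so every
  numeric cell is traceable to the operation and inputs that made it.

Numbers are written at full precision in CSV/JSON; the plain-text rendering
rounds to display precision only.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import reference as ref
from .classifier import CANDIDATE_PREDICTORS, TaeEumClassifier, predict_printed
from .correlations import correlation_table
from .group_comparison import group_table
from .landmarks import read_demographics, read_landmarks
from .metrics import METRIC_NAMES, metrics_table
from .synthesize import default_config, generate_metric_level

__all__ = ["RunConfig", "load_config", "external_correlations_frame", "run_full"]


@dataclass
class RunConfig:
    """Pipeline run configuration (see module docstring for the schema).

    YAML schema::

        mode: simulate            # or "files"
        seed: 0                   # RNG seed, recorded in every output
        strata: [M20s, F20s, M60s, F60s]
        size_multiplier: 1        # scales simulated group sizes
        within_metric_corr: 0.0   # metric–metric within-type correlation
        alpha: 0.05               # post-hoc / starring level
        loocv: false              # leave-one-out validation (slow)
        prediction_grid: false    # published-equation probability grid
        landmarks: path.csv       # files mode
        mm_per_pixel: null        #   scale if landmark coordinates are pixels
        demographics: path.csv    # files mode
        outdir: out/
    """

    mode: str = "simulate"
    seed: int = 0
    strata: list[str] = field(default_factory=lambda: list(ref.STRATA))
    size_multiplier: int = 1
    within_metric_corr: float = 0.0
    alpha: float = 0.05
    loocv: bool = False
    prediction_grid: bool = False
    landmarks: str | None = None
    mm_per_pixel: float | None = None
    demographics: str | None = None
    outdir: str = "sasangface_out"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ValueError(f"mode must be 'simulate' or 'files', got {self.mode!r}")
        unknown = set(self.strata) - set(ref.STRATA)
        if unknown:
            raise ValueError(f"unknown strata {sorted(unknown)}")
        if self.mode == "files" and not (self.landmarks and self.demographics):
            raise ValueError("files mode requires 'landmarks' and 'demographics' paths")


def load_config(path) -> RunConfig:
    """Load a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def external_correlations_frame() -> pd.DataFrame:
    """The published external (r, n) pairs in tidy form (metric, sex, r, n)."""
    rows = []
    for sex, metrics in ref.EXTERNAL_CORRELATIONS.items():
        for metric, (r, n) in metrics.items():
            rows.append({"metric": metric, "sex": sex, "r": r, "n": n})
    return pd.DataFrame(rows)


def _sha256_of_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()


def _records_from_files(config: RunConfig) -> pd.DataFrame:
    lms = read_landmarks(config.landmarks, mm_per_pixel=config.mm_per_pixel)
    mts = metrics_table(lms)
    demo = read_demographics(config.demographics)
    return demo.merge(mts, on="subject_id", validate="one_to_one")


def _group_text(table: pd.DataFrame, types: list[str]) -> str:
    lines = []
    for stratum, sub in table.groupby("stratum", sort=True):
        lines.append(f"=== {stratum} ===")
        header = f"{'variable':<10}" + "".join(f"{t:>22}" for t in types) + f"{'P':>8}"
        lines.append(header)
        for _, row in sub.iterrows():
            cells = ""
            for t in types:
                cell = f"{row[f'mean_{t}']:.4g} ({row[f'sd_{t}']:.3g}){row[f'letter_{t}']}"
                cells += f"{cell:>22}"
            lines.append(f"{row['variable']:<10}{cells}{row['p']:>8.3f}")
        lines.append("")
    return "\n".join(lines)


def _stratum_of(row) -> str:
    return f"{row.sex}{row.age_group}"


def run_full(config: RunConfig) -> dict[str, str]:
    """Run the full pipeline and write the report bundle.

    Returns a mapping from artifact name to written path.  Any stage
    failure aborts with an error naming the stage.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config": asdict(config), "artifacts": {}}
    written: dict[str, str] = {}

    def emit(name: str, path: Path, operation: str, input_hash: str) -> None:
        manifest["artifacts"][name] = {
            "path": str(path),
            "operation": operation,
            "inputs_sha256": input_hash,
        }
        written[name] = str(path)

    # stage: records -----------------------------------------------------
    try:
        if config.mode == "simulate":
            gen = default_config(
                strata=config.strata,
                seed=config.seed,
                size_multiplier=config.size_multiplier,
                within_metric_corr=config.within_metric_corr,
            )
            records = generate_metric_level(gen)
            records_src = f"synthetic generator (seed={config.seed})"
        else:
            records = _records_from_files(config)
            records_src = f"files: {config.landmarks}, {config.demographics}"
    except Exception as exc:
        raise RuntimeError(f"stage 'records' failed: {exc}") from exc
    records = records[
        records.apply(_stratum_of, axis=1).isin(config.strata)
    ].reset_index(drop=True)
    records_hash = _sha256_of_frame(records)
    rec_path = outdir / "records.csv"
    records.to_csv(rec_path, index=False)
    emit("records", rec_path, records_src, records_hash)

    # stage: group comparison ---------------------------------------------
    try:
        gtable = group_table(records, alpha=config.alpha)
    except Exception as exc:
        raise RuntimeError(f"stage 'group_comparison' failed: {exc}") from exc
    gpath = outdir / "group_comparison.csv"
    gtable.to_csv(gpath, index=False)
    emit("group_comparison", gpath, "one_way_anova + duncan_letters", records_hash)
    types = sorted(records["sasang_type"].unique())
    (outdir / "group_comparison.txt").write_text(_group_text(gtable, types))
    emit("group_comparison_txt", outdir / "group_comparison.txt",
         "one_way_anova + duncan_letters (rendered)", records_hash)

    # stage: correlations --------------------------------------------------
    try:
        ctable = correlation_table(records, external=external_correlations_frame())
    except Exception as exc:
        raise RuntimeError(f"stage 'correlations' failed: {exc}") from exc
    cpath = outdir / "correlations.csv"
    ctable.to_csv(cpath, index=False)
    emit("correlations", cpath, "pearson_r + fisher_compare", records_hash)

    # stage: TE classifier ---------------------------------------------------
    te_report: dict = {}
    for stratum in config.strata:
        sub = records[records.apply(_stratum_of, axis=1) == stratum]
        if sub["sasang_type"].eq("TE").sum() == 0 or len(sub) < 20:
            te_report[stratum] = {"error": "insufficient data"}
            continue
        try:
            model = TaeEumClassifier(sub)
            singles = {}
            for pred in CANDIDATE_PREDICTORS:
                res = model.fit(predictors=[pred])
                orow = res.odds_ratios().loc[pred]
                singles[pred] = {
                    "unit": orow.unit,
                    "odds_ratio": orow.odds_ratio,
                    "ci": [orow.ci_low, orow.ci_high],
                    "c_statistic": res.c_statistic,
                }
            bma_res = model.fit_bma()
            pars = bma_res.parsimonious
            pars_res = model.fit(predictors=list(pars.predictor_names)) \
                if pars.predictor_names else None
            entry = {
                "n": int(len(sub)),
                "n_te": int(sub["sasang_type"].eq("TE").sum()),
                "single_predictor_models": singles,
                "bma": {
                    "parsimonious": list(pars.predictor_names),
                    "parsimonious_bic": pars.bic,
                    "inclusion_probs": bma_res.inclusion_probs,
                    "n_failed_subsets": bma_res.n_failed,
                },
            }
            if pars_res is not None:
                entry["parsimonious_fit"] = {
                    "params": pars_res.params.to_dict(),
                    "bse": pars_res.bse.to_dict(),
                    "published_convention_x": pars_res.published_equation_x().to_dict(),
                    "c_statistic": pars_res.c_statistic,
                }
                if config.loocv:
                    entry["parsimonious_fit"]["loocv_correct_rate"] = pars_res.loocv()
            if {"bmi", "CJWR"} <= set(sub.columns):
                entry["bmi_cjwr_interaction_p"] = model.interaction_check()
            te_report[stratum] = entry
        except Exception as exc:
            raise RuntimeError(f"stage 'te_classifier' ({stratum}) failed: {exc}") from exc
    tpath = outdir / "te_models.json"
    tpath.write_text(json.dumps(te_report, indent=2, default=float))
    emit("te_models", tpath, "fit_logistic + bma + c_statistic (+ loocv)", records_hash)

    # stage: published-equation grid --------------------------------------
    if config.prediction_grid:
        rows = []
        for stratum in config.strata:
            for bmi in np.arange(16.0, 32.1, 1.0):
                for cjwr in np.arange(1.00, 1.251, 0.025):
                    rows.append({
                        "stratum": stratum, "bmi": bmi, "cjwr": cjwr,
                        "p_te": predict_printed(stratum, bmi, cjwr),
                    })
        ppath = outdir / "printed_predictions.csv"
        pd.DataFrame(rows).to_csv(ppath, index=False)
        emit("printed_predictions", ppath, "predict_printed",
             hashlib.sha256(str(sorted(config.strata)).encode()).hexdigest())

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    written["manifest"] = str(outdir / "manifest.json")
    return written
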