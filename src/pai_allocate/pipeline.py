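"""End-to-end orchestration: filters -> imputation -> per-arm BMA ->
leave-one-out PAI, with every intermediate artifact written to a run
directory and a deterministic final report.

Stage order: completer filter, covariate missingness screening (on the
completer set), random-forest imputation of the remaining baseline
covariates, dummy coding, per-arm Bayesian model averaging, predictor
selection, leave-one-out factual/counterfactual prediction, PAI
summaries. All stage seeds derive from one master seed, so two runs
with the same inputs and seed produce byte-identical reports.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._version import __version__
from .bma import BMAConfig, BMAResult, enumerate_models, mcmc_bas, top_model_table
from .impute import ImputeConfig, missforest_impute
from .pai import (
    PAISummary,
    SelectionRule,
    loo_predictions,
    select_predictors,
    summarize_pai,
)
from .preprocess import encode, filter_completers, screen_missingness
from .trial import ARM_BLEND, ARM_COL, ARM_TAU, ID_COL, OUTCOME_COL, TrialTable


class PipelineStageError(RuntimeError):
    """Raised when a stage fails; names the stage, partial artifacts stay
    on disk."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    """Bundle of per-stage settings for :func:`run_pipeline`."""

    screening_threshold: float = 0.50
    impute: ImputeConfig = field(default_factory=ImputeConfig)
    bma: BMAConfig = field(default_factory=BMAConfig)
    selection: SelectionRule = field(default_factory=SelectionRule)
    pai_threshold: float = 5.0
    clip_predictions: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "screening_threshold": self.screening_threshold,
            "impute": self.impute.to_dict(),
            "bma": self.bma.to_dict(),
            "selection": {"rule": self.selection.rule},
            "pai_threshold": self.pai_threshold,
            "clip_predictions": self.clip_predictions,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            screening_threshold=d.get("screening_threshold", 0.50),
            impute=ImputeConfig(**d.get("impute", {})),
            bma=BMAConfig(**d.get("bma", {})),
            selection=SelectionRule(**d.get("selection", {})),
            pai_threshold=d.get("pai_threshold", 5.0),
            clip_predictions=d.get("clip_predictions", False),
            seed=d.get("seed", 0),
        )


@dataclass
class PipelineResult:
    """In-memory handles to everything the run produced."""

    report: dict
    bma_results: dict
    predictions: pd.DataFrame
    summary: PAISummary
    outdir: Path


def _dump(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(
    table: TrialTable, config: PipelineConfig | None = None, outdir: str | Path = "run"
) -> PipelineResult:
    """Run the full analysis on ``table`` and persist artifacts in
    ``outdir``.

    Any stage failure raises :class:`PipelineStageError` naming the
    stage; artifacts written before the failure remain in ``outdir``.
    The final ``report.json`` is a deterministic function of the input
    table and the configuration (including its seed).
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)
    log_lines = [f"pai-allocate {__version__}", f"config: {json.dumps(config.to_dict(), sort_keys=True)}"]
    report: dict = {"version": __version__, "config": config.to_dict()}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except PipelineStageError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage boundary
                log_lines.append(f"STAGE FAILED: {name}: {exc}")
                (outdir / "log.txt").write_text("\n".join(log_lines) + "\n")
                raise PipelineStageError(name, exc) from exc

        return deco

    @stage("filter_completers")
    def _completers():
        return filter_completers(table)

    completers, completer_report = _completers
    report["completers"] = completer_report.to_dict()
    _dump(completer_report.to_dict(), outdir / "completers.json")
    log_lines.append(f"completers: {completer_report.to_dict()}")

    @stage("screen_missingness")
    def _screened():
        return screen_missingness(completers, config.screening_threshold)

    screened, dropped = _screened
    report["screened_covariates"] = dropped
    _dump({"dropped": dropped, "threshold": config.screening_threshold}, outdir / "screening.json")
    log_lines.append(f"screened out: {dropped}")

    @stage("missforest_impute")
    def _imputed():
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            imputed, diag = missforest_impute(
                screened, replace(config.impute, seed=int(seeds[0]))
            )
        diag["caught_warnings"] = sorted(str(w.message) for w in caught)
        return imputed, diag

    imputed, impute_diag = _imputed
    report["imputation"] = {
        "iterations": impute_diag["iterations"],
        "differences": impute_diag["differences"],
        "warnings": impute_diag["warnings"],
    }
    _dump(impute_diag, outdir / "impute_diagnostics.json")
    from .trial import write_trial

    write_trial(imputed, outdir / "imputed.csv")

    @stage("encode")
    def _coded():
        return encode(imputed)

    coded = _coded
    coded.X.to_csv(outdir / "design_matrix.csv")
    _dump({"column_meta": [m.to_dict() for m in coded.column_meta]}, outdir / "column_meta.json")

    df = imputed.data
    arm_of = df.set_index(df[ID_COL].astype(str))[ARM_COL]
    y_all = df.set_index(df[ID_COL].astype(str))[OUTCOME_COL]
    arm_X = {a: coded.X.loc[arm_of == a] for a in (ARM_TAU, ARM_BLEND)}
    arm_y = {a: y_all.loc[arm_of == a] for a in (ARM_TAU, ARM_BLEND)}

    bma_results: dict[str, BMAResult] = {}
    selections: dict[str, object] = {}
    for k, arm in enumerate((ARM_TAU, ARM_BLEND)):

        @stage(f"bma_{arm}")
        def _bma(arm=arm, k=k):
            cfg = replace(config.bma, seed=int(seeds[1 + k]))
            X, y = arm_X[arm], arm_y[arm]
            if X.shape[1] <= cfg.enumeration_limit:
                return enumerate_models(X, y, cfg, arm=arm)
            return mcmc_bas(X, y, cfg, arm=arm)

        result = _bma
        bma_results[arm] = result
        _dump(result.to_dict(), outdir / f"bma_{arm}.json")
        top_model_table(result, 5).to_csv(outdir / f"top_models_{arm}.csv", index=False)
        sel = select_predictors(result, config.selection)
        selections[arm] = sel
        log_lines.append(f"{arm}: selected {list(sel.columns)} by {sel.rule}")

    report["bma"] = {
        arm: {
            "method": r.method,
            "n_models_evaluated": r.n_models_evaluated,
            "pip": {c: float(r.pip[c]) for c in r.columns},
            "top_models": top_model_table(r, 5).drop(columns=["Variables"]).to_dict(orient="records"),
            "top_model_variables": top_model_table(r, 5)["Variables"].tolist(),
            "selected": selections[arm].to_dict(),
            "notes": r.notes,
        }
        for arm, r in bma_results.items()
    }

    @stage("loo_predictions")
    def _preds():
        out = []
        pairs = {ARM_TAU: ARM_BLEND, ARM_BLEND: ARM_TAU}
        for arm, other in pairs.items():
            out.extend(
                loo_predictions(
                    (arm_X[arm], arm_y[arm]),
                    (arm_X[other], arm_y[other]),
                    selections[arm].columns,
                    selections[other].columns,
                    received_arm=arm,
                    other_arm=other,
                    clip=config.clip_predictions,
                )
            )
        return out

    preds = _preds
    pred_df = pd.DataFrame([p.to_dict() for p in preds])
    pred_df.to_csv(outdir / "predictions.csv", index=False)

    @stage("summarize_pai")
    def _summary():
        return summarize_pai(preds, config.pai_threshold)

    summary = _summary
    report["pai_summary"] = summary.to_dict()
    counts, edges = np.histogram([p.pai for p in preds], bins=np.arange(0.0, 16.0, 1.0))
    report["pai_histogram"] = {
        "bin_edges": [float(e) for e in edges],
        "counts": [int(c) for c in counts],
    }

    _dump(report, outdir / "report.json")
    (outdir / "log.txt").write_text("\n".join(log_lines) + "\n")
    return PipelineResult(
        report=report,
        bma_results=bma_results,
        predictions=pred_df,
        summary=summary,
        outdir=outdir,
    )
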