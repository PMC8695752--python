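"""End-to-end study orchestration: simulate -> preprocess -> split -> train ->
evaluate -> compare.

Two model presets mirror the study's configurations:

* ``preliminary`` — 64 LSTM units, batch size 8, 50 epochs, 7:3
  stratified train/test split;
* ``final`` — 256 units, batch size 16, 100 epochs, 7:2:1
  train/validation/test split.

Every run draws all randomness from one top-level seed, split into named
substreams (simulate / split / model), and writes its config, seed, data
tables, training history, metrics, and report under an output directory, so
a run is fully reconstructible from that directory's contents.
"""

from __future__ import annotations

import json
import logging
import sys
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .evaluate import (
    MetricReport,
    metrics_from_contingency,
    roc_and_auc,
    write_metric_report,
)
from .model import (
    ModelConfig,
    build_model,
    classify,
    predict_proba,
    to_arrays,
    train,
)
from .preprocess import (
    PreprocessConfig,
    SplitAssignment,
    process_cohort,
    split_dataset,
    write_splits_csv,
    write_tensors_csv,
)
from .scores import (
    KPS_RULE,
    PPI_RULE,
    apply_cutoff,
    contingency_from_predictions,
    scores_from_cohort,
)
from .simulate import (
    CohortSimParams,
    PatientMeta,
    simulate_cohort,
    write_cohort_csv,
)

__all__ = [
    "RunConfig",
    "PipelineError",
    "PRESETS",
    "derive_seeds",
    "run_experiment",
    "run_classifier_experiment",
    "experiment_sim_params",
    "compare_comparators",
    "load_config",
    "configure_logging",
]

logger = logging.getLogger(__name__)

#: preset name -> (model kwargs, split ratios)
PRESETS: dict[str, tuple[dict, tuple[float, ...]]] = {
    "preliminary": (dict(units=64, batch_size=8, epochs=50), (0.7, 0.3)),
    "final": (dict(units=256, batch_size=16, epochs=100), (0.7, 0.2, 0.1)),
}


class PipelineError(RuntimeError):
    """A stage failure with enough context to locate it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class RunConfig:
    """Complete configuration of one experiment run."""

    simulator: CohortSimParams = field(default_factory=CohortSimParams)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    horizons: tuple[float, ...] = (24.0, 48.0)
    preset: str = "final"
    output_dir: Optional[str] = None
    log_level: str = "INFO"
    write_raw_signals: bool = False

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}")
        model_kwargs, self.split_ratios = PRESETS[self.preset]
        self.model = replace(self.model, **model_kwargs)
        for h in self.horizons:
            if h < 24.0:
                warnings.warn(
                    f"horizon {h:g} h is shorter than one circadian cycle (24 h); "
                    "rest-activity rhythm information will be incomplete",
                    stacklevel=2,
                )


def derive_seeds(seed: int) -> dict[str, int]:
    """Named substream seeds (all < 2**31) from one top-level seed."""
    children = np.random.SeedSequence(seed).spawn(3)
    names = ("simulate", "split", "model")
    return {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(names, children)
    }


def _evaluate_split(
    model,
    tensors_by_id: dict,
    split: SplitAssignment,
    outcomes: dict[str, int],
    threshold: float,
) -> dict:
    """Test-set diagnostics plus train/validation accuracies from history."""
    test_ids = [pid for pid in split.ids("test") if pid in tensors_by_id]
    X, y, lengths = to_arrays([tensors_by_id[pid] for pid in test_ids])
    probs = predict_proba(model, X, lengths=lengths)
    preds = classify(probs, threshold)
    table = contingency_from_predictions(
        dict(zip(test_ids, (int(p) for p in preds))),
        {pid: outcomes[pid] for pid in test_ids},
    )
    report = metrics_from_contingency(table)
    score_map = dict(zip(test_ids, probs.astype(float)))
    outcome_map = {pid: outcomes[pid] for pid in test_ids}
    if len(set(outcome_map.values())) == 2:
        _, auc = roc_and_auc(score_map, outcome_map)
    else:
        auc = None
    report.auc = auc
    report.provenance = {"classifier": "lstm", "threshold": threshold, "ids": test_ids}
    return {
        "report": report,
        "table": table,
        "probs": score_map,
        "test_acc": report.accuracy.estimate if report.accuracy else None,
    }


def run_experiment(cfg: RunConfig, seed: int) -> pd.DataFrame:
    """Run the full study for each configured horizon; return the report table.

    The report has one row per horizon with training/validation/testing
    accuracy, sensitivity, specificity, PPV, NPV and AUC on the test set.
    Artifacts are written under ``cfg.output_dir`` when set.
    """
    seeds = derive_seeds(seed)
    out_dir = Path(cfg.output_dir) if cfg.output_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "config.json").write_text(
            json.dumps(
                {
                    "seed": seed,
                    "substream_seeds": seeds,
                    "simulator": asdict(cfg.simulator),
                    "preprocess": asdict(cfg.preprocess),
                    "model": asdict(cfg.model),
                    "horizons": list(cfg.horizons),
                    "preset": cfg.preset,
                },
                indent=2,
                default=str,
            )
        )

    try:
        cohort = simulate_cohort(replace(cfg.simulator, seed=seeds["simulate"]))
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError("simulate", str(exc)) from exc
    metas = [meta for _, meta in cohort]
    if out_dir is not None:
        write_cohort_csv(metas, out_dir / "cohort.csv")
        if cfg.write_raw_signals:
            sig_dir = out_dir / "signals"
            sig_dir.mkdir(exist_ok=True)
            from .simulate import write_series_csv

            for series, meta in cohort:
                write_series_csv(series, sig_dir / f"{meta.patient_id}.csv")

    rows = []
    for horizon in cfg.horizons:
        pre_cfg = replace(cfg.preprocess, horizon_h=float(horizon))
        try:
            tensors, excluded = process_cohort(cohort, pre_cfg)
        except Exception as exc:
            raise PipelineError("preprocess", f"horizon {horizon} h: {exc}") from exc
        if excluded:
            logger.info(
                "horizon %g h: excluded %d recording(s): %s",
                horizon, len(excluded), excluded,
            )
        tensors_by_id = {t.patient_id: t for t in tensors}
        outcomes = {m.patient_id: m.outcome for m in metas}
        labels = {t.patient_id: t.label for t in tensors}
        try:
            split = split_dataset(labels, cfg.split_ratios, seeds["split"])
        except Exception as exc:
            raise PipelineError("split", str(exc)) from exc

        def _arrays(partition: str):
            ids = [pid for pid in split.ids(partition) if pid in tensors_by_id]
            if not ids:
                return None
            return to_arrays([tensors_by_id[pid] for pid in ids])

        train_set = _arrays("train")
        val_set = _arrays("validation")
        if train_set is None:
            raise PipelineError("train", f"horizon {horizon} h: empty training set")
        model_cfg = replace(cfg.model, seed=seeds["model"])
        model = build_model(model_cfg, input_length=len(tensors[0]))
        try:
            train(model, train_set, val_set)
        except Exception as exc:
            raise PipelineError("train", f"horizon {horizon} h: {exc}") from exc
        try:
            evaluation = _evaluate_split(
                model, tensors_by_id, split, outcomes, model_cfg.classification_threshold
            )
        except Exception as exc:
            raise PipelineError("evaluate", f"horizon {horizon} h: {exc}") from exc

        val_acc = model.history["val_acc"][-1] if val_set is not None else None
        report = evaluation["report"]
        rows.append(
            {
                "model": cfg.preset,
                "horizon_h": float(horizon),
                "train_acc": model.history["train_acc"][-1],
                "val_acc": val_acc,
                "test_acc": evaluation["test_acc"],
                "sensitivity": report.sensitivity.estimate if report.sensitivity else None,
                "specificity": report.specificity.estimate if report.specificity else None,
                "ppv": report.ppv.estimate if report.ppv else None,
                "npv": report.npv.estimate if report.npv else None,
                "auc": report.auc,
            }
        )
        if out_dir is not None:
            tag = f"{cfg.preset}_{horizon:g}h"
            write_tensors_csv(tensors, out_dir / f"tensors_{tag}.csv")
            write_splits_csv(split, out_dir / f"splits_{tag}.csv")
            pd.DataFrame(model.history).to_csv(
                out_dir / f"history_{tag}.csv", index=False
            )
            model.save(out_dir / f"model_{tag}")
            write_metric_report(report, out_dir / f"metrics_{tag}.json")

    df = pd.DataFrame(rows)
    if out_dir is not None:
        df.to_csv(out_dir / "report.csv", index=False, float_format="%.6f")
    return df


# ---------------------------------------------------------------------------
# Monte-Carlo study conditions
#
# The repeated-seed experiments (discriminability, null behaviour, horizon
# comparison) run the eligible-cohort size of the study (n=44, 21 deaths / 23
# stable) at 5-minute actigraphy epochs rather than 1 Hz, which keeps a pure
# numpy LSTM tractable; see docs/methods.md for the reasoning.


def experiment_sim_params(seed: int, null: bool = False) -> CohortSimParams:
    """Simulator conditions for the repeated-seed classifier experiments.

    ``null=True`` equalises every group-level parameter (mesor, amplitude,
    frailty mean), removing the outcome signal from both the actigraphy and
    the clinical scores.
    """
    params = CohortSimParams(
        n_patients=44,
        p_death=21 / 44,
        sampling_interval_s=300.0,
        stay_days_range=(3, 6),
        offwrist_rate_per_day=1.5,
        offwrist_duration_minutes=(10.0, 40.0),
        seed=seed,
    )
    if null:
        stable_mesor = params.mesor_by_group[1]
        stable_amp = params.amplitude_by_group[1]
        mid_frailty = 0.5 * sum(params.frailty_mu_by_group)
        params = replace(
            params,
            mesor_by_group=(stable_mesor, stable_mesor),
            amplitude_by_group=(stable_amp, stable_amp),
            frailty_mu_by_group=(mid_frailty, mid_frailty),
        )
    return params


def run_classifier_experiment(
    seed: int,
    horizon_h: float = 48.0,
    preset: str = "final",
    null: bool = False,
) -> dict:
    """One seeded simulate/preprocess/split/train/evaluate pass.

    Returns the report row (dict) for the requested horizon, including the
    test-set AUC, plus the trained model's history and the per-patient test
    scores.
    """
    cfg = RunConfig(
        simulator=experiment_sim_params(seed, null=null),
        horizons=(horizon_h,),
        preset=preset,
    )
    df = run_experiment(cfg, seed)
    return df.iloc[0].to_dict()


def compare_comparators(
    metas: Sequence[PatientMeta],
    lstm_scores: Optional[dict[str, float]] = None,
    threshold: float = 0.5,
    ci_level: float = 0.95,
) -> dict[str, MetricReport]:
    """MetricReport per comparator (KPS cutoff, PPI cutoff, LSTM).

    Each comparator is evaluated on the patients for whom its score exists;
    the evaluated ids and subset size are recorded in each report's
    provenance.  A score with no values at all is omitted (and logged), as
    with PPI availability in partial-enrolment cohorts.
    """
    outcomes = {m.patient_id: m.outcome for m in metas}
    if not outcomes:
        raise ValueError("empty cohort")
    reports: dict[str, MetricReport] = {}
    for rule, name in ((KPS_RULE, "KPS"), (PPI_RULE, "PPI")):
        score_map = scores_from_cohort(metas, name)
        predictions = apply_cutoff(score_map, rule)
        if not predictions:
            logger.info("%s: no scores available; comparator omitted", name)
            continue
        subset = {pid: outcomes[pid] for pid in predictions}
        table = contingency_from_predictions(predictions, subset)
        report = metrics_from_contingency(table, ci_level=ci_level)
        if len(set(subset.values())) == 2:
            present = {pid: score_map[pid] for pid in predictions}
            _, report.auc = roc_and_auc(present, subset, direction=rule.direction)
        report.provenance = {
            "score": name,
            "cutoff": rule.cutoff,
            "direction": rule.direction,
            "ids": sorted(predictions),
        }
        reports[name] = report
    if lstm_scores is not None:
        common = sorted(set(lstm_scores) & set(outcomes))
        if not common:
            raise ValueError("no common patients between LSTM scores and cohort")
        preds = {pid: int(lstm_scores[pid] >= threshold) for pid in common}
        subset = {pid: outcomes[pid] for pid in common}
        table = contingency_from_predictions(preds, subset)
        report = metrics_from_contingency(table, ci_level=ci_level)
        if len(set(subset.values())) == 2:
            _, report.auc = roc_and_auc(
                {pid: lstm_scores[pid] for pid in common}, subset
            )
        report.provenance = {"score": "LSTM", "threshold": threshold, "ids": common}
        reports["LSTM"] = report
    return reports


# ---------------------------------------------------------------------------
# config & logging


def _build(cls, payload: dict):
    fields = {f for f in cls.__dataclass_fields__}
    unknown = set(payload) - fields
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    coerced = {}
    for key, value in payload.items():
        if isinstance(value, list):
            value = tuple(value)
        coerced[key] = value
    return cls(**coerced)


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML (or JSON) mapping."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    if "simulator" in payload:
        kwargs["simulator"] = _build(CohortSimParams, payload.pop("simulator"))
    if "preprocess" in payload:
        kwargs["preprocess"] = _build(PreprocessConfig, payload.pop("preprocess"))
    if "model" in payload:
        kwargs["model"] = _build(ModelConfig, payload.pop("model"))
    if "horizons" in payload:
        kwargs["horizons"] = tuple(payload.pop("horizons"))
    for key in ("preset", "output_dir", "log_level", "write_raw_signals"):
        if key in payload:
            kwargs[key] = payload.pop(key)
    if payload:
        raise ValueError(f"unknown config keys: {sorted(payload)}")
    return RunConfig(**kwargs)


def configure_logging(level: str = "INFO", logfile: Optional[str | Path] = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
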