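"""High-level orchestration of the two study workflows.

``run_evaluation`` reproduces the classifier-evaluation protocol: split an
annotated feature table, train the six-member ensemble with 5-fold CV
hyperparameter search, vote on the held-out peaks, and tabulate a
Table-1-style report (per-classifier confusion counts plus the conventional
idotP/mass-error filter and the unanimous-selection row).

``run_quantification`` reproduces the light/heavy comparison: pair dimethyl
groups, apply the conventional filter and the unanimous vote to each side,
quantify log ratios, and summarise them per selection set.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._domain import AnnotatedExample, PrecursorPeakGroup, feature_matrix
from . import quant as quant_mod
from .ensemble import (
    CLASSIFIER_KEYS,
    TrainedEnsemble,
    evaluate_predictions,
    stratified_split,
    train_ensemble,
)
from .features import extract_features

__all__ = ["RunConfig", "EvaluationResult", "QuantificationResult",
           "run_evaluation", "run_quantification"]


@dataclass
class RunConfig:
    """Run parameters, serialized next to every output for provenance."""

    seed: int = 0
    test_fraction: Optional[float] = 319 / 737
    test_counts: Optional[dict[str, int]] = None
    variance_target: float = 0.99
    n_components: Optional[int] = None
    grids: Optional[dict] = None
    idotp_min: float = quant_mod.QUANT_PRESET[0]
    abs_mass_error_max_ppm: float = quant_mod.QUANT_PRESET[1]
    log_base: float = 2.0
    out_dir: Optional[str] = None

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, default=str)


def _write_audit(config: RunConfig, name: str, df: pd.DataFrame) -> None:
    if config.out_dir is None:
        return
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    df.to_csv(out / f"{name}.csv", index=False)


def _conventional_mask(examples: Sequence[AnnotatedExample], config: RunConfig) -> np.ndarray:
    X, _ = feature_matrix(examples)
    idotp, err = X[:, 0], X[:, 1]
    return (idotp >= config.idotp_min) & (np.abs(err) <= config.abs_mass_error_max_ppm)


@dataclass
class EvaluationResult:
    report: pd.DataFrame
    model: TrainedEnsemble
    train: list[AnnotatedExample] = field(repr=False)
    test: list[AnnotatedExample] = field(repr=False)


def run_evaluation(
    examples: Sequence[AnnotatedExample], config: RunConfig
) -> EvaluationResult:
    """Split, train, vote and evaluate; returns the report and the model.

    The report has one row per method: the conventional idotP/mass-error
    filter, each of the six classifiers, and the unanimous selection, with
    confusion counts and precision/accuracy percentages.
    """
    if not examples:
        raise ValueError("no annotated examples supplied")
    train, test = stratified_split(
        examples, config.test_fraction, config.seed, test_counts=config.test_counts
    )
    model = train_ensemble(
        train,
        seed=config.seed,
        grids=config.grids,
        variance_target=config.variance_target,
        n_components=config.n_components,
    )

    X_test, y_test = feature_matrix(test)
    votes = model.predict_votes_batch(X_test)
    rows = []

    def add_row(method: str, predictions: np.ndarray) -> None:
        cc = evaluate_predictions(predictions, y_test)
        rows.append(
            {
                "method": method, "tp": cc.tp, "fp": cc.fp, "fn": cc.fn, "tn": cc.tn,
                "precision_pct": cc.precision_pct, "accuracy_pct": cc.accuracy_pct,
            }
        )

    add_row("conventional", _conventional_mask(test, config))
    per_clf = {k: np.array([v.votes[k] for v in votes]) for k in CLASSIFIER_KEYS}
    for key in CLASSIFIER_KEYS:
        add_row(key, per_clf[key])
    unanimous = np.array([v.unanimous_peptide for v in votes])
    add_row("unanimous", unanimous)
    report = pd.DataFrame(rows)

    # unanimity can only remove positives relative to any single member
    fp_by_clf = report.set_index("method").loc[list(CLASSIFIER_KEYS), "fp"]
    assert report.loc[report["method"] == "unanimous", "fp"].iloc[0] <= fp_by_clf.min()

    _write_audit(config, "evaluation_report", report)
    return EvaluationResult(report=report, model=model, train=list(train), test=list(test))


@dataclass
class QuantificationResult:
    pairs: pd.DataFrame
    summary: pd.DataFrame
    exclusions: list = field(default_factory=list)
    drops: list = field(default_factory=list)


def run_quantification(
    groups: Sequence[PrecursorPeakGroup],
    model: TrainedEnsemble,
    config: RunConfig,
) -> QuantificationResult:
    """Pair light/heavy groups, vote and filter both sides, quantify.

    A pair is "unanimous" when both its light and heavy groups are voted
    peptide by all six classifiers, and "conventional" when both pass the
    idotP/mass-error preset. Raises when no pair can be formed.
    """
    if model is None:
        raise ValueError("a trained ensemble is required")
    candidates, exclusions = quant_mod.match_label_pairs(groups)
    if not candidates:
        raise ValueError("no light/heavy pairs could be matched")
    pairs, drops = quant_mod.quantify_pairs(candidates, log_base=config.log_base)
    if not pairs:
        raise ValueError("all matched pairs were dropped (zero areas)")

    kept = [c for c in candidates
            if not any(d[0] == (c.sequence, c.charge) for d in drops)]
    unanimous, conventional = [], []
    for cand in kept:
        flags = []
        passes = []
        for side in (cand.light, cand.heavy):
            vote = model.predict_votes(extract_features(side))
            flags.append(vote.unanimous_peptide)
            passes.append(
                quant_mod.conventional_filter(
                    side, config.idotp_min, config.abs_mass_error_max_ppm
                )
            )
        unanimous.append(all(flags))
        conventional.append(all(passes))
    unanimous = np.array(unanimous, dtype=bool)
    conventional = np.array(conventional, dtype=bool)

    breakdown = quant_mod.selection_breakdown(unanimous, conventional)
    summary = quant_mod.summarize_quant(pairs, breakdown)
    tab = quant_mod.ma_table(pairs)
    tab["light_area"] = [p.light_area for p in pairs]
    tab["heavy_area"] = [p.heavy_area for p in pairs]
    tab["passed_conventional"] = conventional
    tab["unanimous"] = unanimous

    _write_audit(config, "quant_report", tab)
    if config.out_dir is not None:
        summary.to_csv(Path(config.out_dir) / "quant_summary.csv", index=False)
    return QuantificationResult(pairs=tab, summary=summary,
                                exclusions=exclusions, drops=drops)
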