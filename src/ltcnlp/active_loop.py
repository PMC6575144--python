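"""Iterative retraining: band-sample ambiguous cases, annotate, augment, retrain.

Each round trains the forest on the current labeled set, scores the whole
sample, draws a batch of unlabeled records from the intermediate-probability
band (stratified across probability deciles so the batch spans the band),
sends them to the annotator, folds the labels in, and retrains.  The loop
stops when the band empties, when the positive set stabilizes (changes by
less than 1% between rounds), or at ``max_rounds``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Set

import numpy as np

from .nlp_classifier import (
    DEFAULT_N_TREES,
    DEFAULT_THRESHOLD,
    CVResult,
    FeatureMatrix,
    ForestModel,
    classify,
    cross_validate,
    predict_proba,
    train_forest,
)
from .seed_annotate import SOURCE_BAND_SAMPLE, LabeledSet, record_annotations
from .types import ConfigError

__all__ = ["LoopConfig", "RoundLog", "LoopResult", "select_band_sample", "run_loop"]

STABILITY_TOLERANCE = 0.01


@dataclass
class LoopConfig:
    band_low: float = 0.10
    band_high: float = 0.90
    batch_size: int = 41
    max_rounds: int = 5
    stop_rule: str = "stable_positives"  # or "fixed_rounds"
    seed: int = 0
    n_trees: int = DEFAULT_N_TREES
    cv_folds: int = 5

    def validate(self) -> None:
        if not 0.0 <= self.band_low < self.band_high <= 1.0:
            raise ConfigError("need 0 <= band_low < band_high <= 1")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.max_rounds < 0:
            raise ConfigError("max_rounds must be >= 0")
        if self.stop_rule not in ("fixed_rounds", "stable_positives"):
            raise ConfigError(f"unknown stop_rule {self.stop_rule!r}")


@dataclass
class RoundLog:
    round: int
    labeled_size: int
    n_positives: int
    cv_f1: float
    n_annotated: int = 0


@dataclass
class LoopResult:
    model: ForestModel
    probabilities: Dict[str, float]
    labeled: LabeledSet
    rounds: List[RoundLog] = field(default_factory=list)
    aborted: Optional[str] = None


def select_band_sample(
    probs: Mapping[str, float],
    labeled: LabeledSet,
    config: LoopConfig,
) -> List[str]:
    """Draw up to ``batch_size`` unlabeled ids with band_low <= p <= band_high.

    The draw is stratified across the 0.1-wide probability deciles
    intersecting the band: strata are visited round-robin, so every nonempty
    stratum contributes at least one item whenever the batch is large enough.
    Already-labeled ids are never selected.  Returns an empty list when the
    band is empty.
    """
    config.validate()
    eligible = sorted(
        rid
        for rid, p in probs.items()
        if rid not in labeled and config.band_low <= p <= config.band_high
    )
    if not eligible:
        return []
    rng = np.random.default_rng(config.seed)
    strata: Dict[int, List[str]] = {}
    for rid in eligible:
        decile = min(int(probs[rid] * 10), 9)
        strata.setdefault(decile, []).append(rid)
    for bucket in strata.values():
        rng.shuffle(bucket)

    take = min(config.batch_size, len(eligible))
    chosen: List[str] = []
    order = sorted(strata)
    while len(chosen) < take:
        progressed = False
        for decile in order:
            bucket = strata[decile]
            if bucket and len(chosen) < take:
                chosen.append(bucket.pop())
                progressed = True
        if not progressed:
            break
    return sorted(chosen)


def run_loop(
    matrix: FeatureMatrix,
    labeled: LabeledSet,
    annotate: Callable[[Sequence[str]], Dict[str, Dict[str, int]]],
    config: LoopConfig,
) -> LoopResult:
    """Run the retraining loop and return the final model, scores, and log.

    ``annotate`` maps a list of ids to per-rater binary label maps (the
    synthetic oracle, or a shim over human annotations).  ``max_rounds=0``
    returns the model trained on the initial labeled set, untouched.
    An annotator failure aborts the loop, returning the partial log.
    """
    config.validate()
    labeled = labeled.copy()

    def fit_round() -> tuple[ForestModel, Dict[str, float], CVResult]:
        model = train_forest(
            matrix, labeled, n_trees=config.n_trees, seed=config.seed
        )
        probs = predict_proba(model, matrix)
        cv = cross_validate(
            matrix,
            labeled,
            k_folds=config.cv_folds,
            seed=config.seed,
            n_trees=config.n_trees,
        )
        return model, probs, cv

    model, probs, cv = fit_round()
    positives: Set[str] = {r for r, v in classify(probs).items() if v == 1}
    rounds = [
        RoundLog(round=0, labeled_size=len(labeled), n_positives=len(positives),
                 cv_f1=cv.mean_f1)
    ]
    result = LoopResult(model=model, probabilities=probs, labeled=labeled,
                        rounds=rounds)

    for r in range(1, config.max_rounds + 1):
        batch = select_band_sample(probs, labeled, config)
        if not batch:
            break
        try:
            rater_labels = annotate(batch)
        except Exception as exc:  # annotator failure: return partial log
            result.aborted = f"annotator failed in round {r}: {exc}"
            return result
        outcome = record_annotations(
            labeled, rater_labels, round=r, source=SOURCE_BAND_SAMPLE
        )
        labeled = outcome.labeled
        model, probs, cv = fit_round()
        new_positives = {rid for rid, v in classify(probs).items() if v == 1}
        rounds.append(
            RoundLog(round=r, labeled_size=len(labeled),
                     n_positives=len(new_positives), cv_f1=cv.mean_f1,
                     n_annotated=len(batch))
        )
        result.model, result.probabilities, result.labeled = model, probs, labeled
        if config.stop_rule == "stable_positives":
            delta = len(positives.symmetric_difference(new_positives))
            if delta / max(1, len(positives)) < STABILITY_TOLERANCE:
                positives = new_positives
                break
        positives = new_positives
    return result
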