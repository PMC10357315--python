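"""End-to-end pipeline stages and the method-comparison benchmark.

``run_pipeline_on_labels`` chains the second stage (semantics -> GPM ->
parameters) for any label stream; ``run_benchmark`` reproduces the method
comparison on synthetic data: a simulated cohort is labeled by three
methods — the ankle-speed heuristic, an SVM and a Bi-LSTM (both under
sequence-level 10-fold cross-validation) — and each method's event
localization and final parameter errors are scored against the
generator's ground truth.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .evaluation import parameter_error, segmentation_accuracy
from .features import extract_features
from .frame_classifiers import (
    BiLSTMHyperparams,
    SVMHyperparams,
    WindowConfig,
    kfold_plan,
    run_cv,
)
from .gait_parameters import CycleMeasurements, GaitParameters, compute_parameters
from .heuristic_baseline import HeuristicConfig, heuristic_events
from .semantics_gpm import (
    EventType,
    FOOT_EVENTS,
    GaitSemanticEvent,
    build_cycle_dictionary,
    extract_semantics,
    turn_intervals,
)
from .skeleton_io import FrameLabel, GaitSequence
from .synthetic_gait import GaitSimConfig, simulate_cohort

__all__ = [
    "BenchmarkConfig",
    "MethodResult",
    "BenchmarkReport",
    "run_pipeline_on_labels",
    "run_pipeline_on_events",
    "run_benchmark",
]

log = logging.getLogger(__name__)


def robust_turn_intervals(events, sequence_length: int):
    """Turn intervals tolerant of streams that open mid-turn.

    Predicted label streams can start inside a turnaround, yielding a
    Turn_end with no opening Turn_start; that turn is closed from frame 1
    (events cannot occur at frame 0).
    """
    evs = sorted(events)
    first_start = next((e.frame for e in evs if e.type is EventType.TURN_START), None)
    first_end = next((e.frame for e in evs if e.type is EventType.TURN_END), None)
    if first_end is not None and (first_start is None or first_end < first_start):
        if first_end > 1:
            evs = [GaitSemanticEvent(1, EventType.TURN_START)] + evs
        else:
            evs = [e for e in evs if not (e.type is EventType.TURN_END and e.frame == first_end)]
    return turn_intervals(evs, sequence_length=sequence_length)


def run_pipeline_on_labels(
    seq: GaitSequence, labels: list[FrameLabel]
) -> tuple[GaitParameters, CycleMeasurements, list[GaitSemanticEvent]]:
    """Semantics -> turn filtering -> GPM -> 18 parameters, from labels."""
    events = extract_semantics(labels)
    turns = robust_turn_intervals(events, sequence_length=len(seq))
    dictionary = build_cycle_dictionary(events, turns)
    params, meas = compute_parameters(seq, dictionary, events, turns, labels=labels)
    return params, meas, events


def run_pipeline_on_events(
    seq: GaitSequence,
    events: list[GaitSemanticEvent],
    turns,
) -> tuple[GaitParameters, CycleMeasurements]:
    """GPM -> parameters for an externally produced event stream."""
    dictionary = build_cycle_dictionary(events, turns)
    return compute_parameters(seq, dictionary, events, turns)


@dataclass(frozen=True)
class BenchmarkConfig:
    n_walks: int = 30
    noise_sd: float = 0.005
    k_folds: int = 10
    tolerance: int = 2
    seed: int = 0
    sim: GaitSimConfig = GaitSimConfig()
    heuristic: HeuristicConfig = HeuristicConfig()
    svm: SVMHyperparams = SVMHyperparams()
    bilstm: BiLSTMHyperparams = BiLSTMHyperparams()
    window: WindowConfig = WindowConfig()


@dataclass
class MethodResult:
    method: str
    mean_param_error: float
    sd_param_error: float
    segmentation_accuracy: float
    weighted_precision: float | None = None
    weighted_recall: float | None = None
    weighted_f1: float | None = None
    n_walks_scored: int = 0
    n_walks_failed: int = 0


@dataclass
class BenchmarkReport:
    config: BenchmarkConfig
    results: dict[str, MethodResult]
    runtime_s: dict[str, float] = field(default_factory=dict)

    def as_table(self) -> str:
        header = (
            f"{'method':<10} {'mean err %':>10} {'sd err %':>9} "
            f"{'seg acc':>8} {'w-prec':>7} {'w-rec':>7} {'w-F1':>7}"
        )
        rows = [header]
        for name in ("heuristic", "svm", "bilstm"):
            r = self.results[name]
            fmt = lambda v: "   --" if v is None else f"{v:7.3f}"
            rows.append(
                f"{r.method:<10} {r.mean_param_error:>10.2f} {r.sd_param_error:>9.2f} "
                f"{r.segmentation_accuracy:>8.3f} {fmt(r.weighted_precision):>7} "
                f"{fmt(r.weighted_recall):>7} {fmt(r.weighted_f1):>7}"
            )
        return "\n".join(rows)


def _score_events_and_params(
    walks,
    truth_events_per_walk,
    events_per_walk,
    turns_per_walk,
    labels_per_walk,
    tolerance: int,
) -> tuple[float, float, float, int, int]:
    """Pool segmentation and parameter errors over a cohort.

    Segmentation accuracy counts only foot events (the heuristic emits no
    turn or gait-start events, and cycles are built from foot events).
    Returns (mean err, sd err, seg accuracy, scored, failed).
    """
    errors: list[float] = []
    matched_total = 0
    k_total = 0
    failed = 0
    scored = 0
    for i, (seq, truth) in enumerate(walks):
        true_foot = [e for e in truth_events_per_walk[i] if e.type in FOOT_EVENTS]
        pred_foot = [e for e in events_per_walk[i] if e.type in FOOT_EVENTS]
        if true_foot:
            score = segmentation_accuracy(true_foot, pred_foot, t=tolerance)
            matched_total += score.matched
            k_total += score.K
        try:
            dictionary = build_cycle_dictionary(events_per_walk[i], turns_per_walk[i])
            params, _ = compute_parameters(
                seq,
                dictionary,
                events_per_walk[i],
                turns_per_walk[i],
                labels=labels_per_walk[i],
            )
            report = parameter_error(params, truth.parameters)
            errors.extend(report.errors.values())
            scored += 1
        except (ValueError, IndexError) as exc:
            log.warning("walk %d failed parameter computation: %s", i, exc)
            failed += 1
    if not errors:
        raise ValueError("no walk produced parameters")
    arr = np.array(errors)
    seg = matched_total / k_total if k_total else float("nan")
    return float(arr.mean()), float(arr.std()), seg, scored, failed


def run_benchmark(cfg: BenchmarkConfig) -> BenchmarkReport:
    """Simulate a cohort and compare heuristic, SVM and Bi-LSTM end to end."""
    t0 = time.perf_counter()
    runtime: dict[str, float] = {}

    sim_cfg = GaitSimConfig(
        **{**cfg.sim.__dict__, "noise_sd": cfg.noise_sd}
    )
    walks = simulate_cohort(sim_cfg, cfg.n_walks, seed=cfg.seed)
    features = [extract_features(seq) for seq, _ in walks]
    truth_events_per_walk = [truth.events for _, truth in walks]
    truth_turns = [
        turn_intervals(ev, sequence_length=len(seq))
        for (seq, _), ev in zip(walks, truth_events_per_walk)
    ]
    runtime["simulate"] = time.perf_counter() - t0

    # --- heuristic: events from ankle speed, turns supplied from truth ---
    t1 = time.perf_counter()
    heur_events = [
        heuristic_events(seq, cfg.heuristic, turns=truth_turns[i])
        for i, (seq, _) in enumerate(walks)
    ]
    heur = _score_events_and_params(
        walks, truth_events_per_walk, heur_events, truth_turns,
        [None] * len(walks), cfg.tolerance,
    )
    results = {
        "heuristic": MethodResult(
            "heuristic", heur[0], heur[1], heur[2],
            n_walks_scored=heur[3], n_walks_failed=heur[4],
        )
    }
    runtime["heuristic"] = time.perf_counter() - t1

    # --- classifier methods under sequence-level k-fold CV ---
    dataset = {
        i: (features[i].values, walks[i][1].labels) for i in range(len(walks))
    }
    plan = kfold_plan(list(dataset), k=cfg.k_folds, seed=cfg.seed)
    for kind, name in (("svm_rbf", "svm"), ("bilstm", "bilstm")):
        t1 = time.perf_counter()
        bilstm_hp = BiLSTMHyperparams(
            **{**cfg.bilstm.__dict__, "seed": cfg.seed}
        )
        reports, predictions = run_cv(
            dataset, kind, plan,
            svm_hp=cfg.svm, bilstm_hp=bilstm_hp, window_config=cfg.window,
        )
        pred_labels = [predictions[i] for i in range(len(walks))]
        pred_events = [extract_semantics(labs) for labs in pred_labels]
        pred_turns = [
            robust_turn_intervals(ev, sequence_length=len(walks[i][0]))
            for i, ev in enumerate(pred_events)
        ]
        scored = _score_events_and_params(
            walks, truth_events_per_walk, pred_events, pred_turns,
            pred_labels, cfg.tolerance,
        )
        results[name] = MethodResult(
            name, scored[0], scored[1], scored[2],
            weighted_precision=float(np.mean([r.weighted_precision for r in reports])),
            weighted_recall=float(np.mean([r.weighted_recall for r in reports])),
            weighted_f1=float(np.mean([r.weighted_f1 for r in reports])),
            n_walks_scored=scored[3], n_walks_failed=scored[4],
        )
        runtime[name] = time.perf_counter() - t1

    runtime["total"] = time.perf_counter() - t0
    return BenchmarkReport(config=cfg, results=results, runtime_s=runtime)
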