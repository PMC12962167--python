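"""Desk-scale end-to-end experiment: train on synthetic video, recover HR.

The full-scale recipe (160-frame clips of 128x128 video, 30 epochs on a
GPU) does not fit a laptop CPU, so the package ships one canonical
scaled-down experiment: a reduced network (stage widths 4/8/16/32) trained
on simulated 32x32 recordings at known heart rates, then evaluated on
held-out recordings by running the confidence-gated detector on the
concatenated clip predictions.  It is the package's integration test and
the reproducible headline result of ``scripts/acceptance.py``.

Protocol (all sizes chosen so the run takes a few CPU minutes):

* 4 training recordings of 12 s at 30 fps, constant HRs {50, 62, 86, 110}
  bpm, static motion, weak-light drift, low sensor noise — 40 training
  clips of 64 frames (50% overlap);
* 2 held-out recordings at 74 and 98 bpm (rates the model never saw);
* 24 epochs of AdamW at learning rate 2e-3 with a 4-epoch warm-up (a short
  run on a small model needs a larger step than the full-scale 1e-4; the
  schedule shape — linear warm-up into cosine decay — is unchanged);
* inference: non-overlapping clips, predictions concatenated per recording,
  median aggregation with MAD outlier removal, confidence grid-searched on
  the training recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hr import (DetectionConfig, NoEstimateError, grid_search_confidence,
                 peak_refine_hr)
from .nn.model import HbpNet, NetConfig, build_model
from .pulse import HbpMap
from .synthetic import SyntheticSpec, make_dataset
from .training import TrainConfig, TrainLog, train

__all__ = ["RecoveryResult", "scaled_down_recovery", "predict_recording"]

#: error charged to a recording for which no estimate could be formed (the
#: width of the plausible physiological band, 30-200 bpm)
NO_ESTIMATE_PENALTY_BPM = 170.0

TRAIN_HRS = (50.0, 62.0, 86.0, 110.0)
TEST_HRS = (74.0, 98.0)
CLIP_T = 64
FPS = 30.0
DURATION_S = 12.0


@dataclass
class RecoveryResult:
    """Outcome of the scaled-down parameter-recovery experiment."""

    mae_trained: float
    mae_untrained: float
    predictions: list[float]
    truths: list[float]
    untrained_predictions: list[float]
    confidence: float
    final_train_loss: float
    final_val_loss: float
    motion: str
    log: TrainLog


def predict_recording(model: HbpNet, clip_set, fps: float = FPS) -> HbpMap:
    """Concatenated clip-wise predictions for one recording (test mode)."""
    parts = [model.forward(c.data[None])[0][0] for c in clip_set.clips]
    return HbpMap(np.concatenate(parts), fps)


def _specs(hrs, base_seed: int, motion: str, noise_sd: float) -> list[SyntheticSpec]:
    return [SyntheticSpec(duration_s=DURATION_S, fps=FPS,
                          hr_trajectory=("constant", float(b)), motion=motion,
                          noise_sd=noise_sd, seed=base_seed + i)
            for i, b in enumerate(hrs)]


def _estimate_all(model: HbpNet, clip_sets, recordings, det: DetectionConfig):
    preds, errors = [], []
    for cs, rec in zip(clip_sets, recordings):
        hbp = predict_recording(model, cs, det.fps)
        try:
            est = peak_refine_hr(hbp, det)
            preds.append(est.bpm)
            errors.append(abs(est.bpm - rec.mean_hr_bpm))
        except NoEstimateError:
            preds.append(float("nan"))
            errors.append(NO_ESTIMATE_PENALTY_BPM)
    return preds, errors


def scaled_down_recovery(seed: int = 0, motion: str = "static",
                         noise_sd: float = 0.005, epochs: int = 24,
                         learning_rate: float = 2e-3,
                         max_restarts: int = 2) -> RecoveryResult:
    """Train the reduced network on synthetic video and score held-out HR.

    Returns per-recording predictions for the trained model and for the
    untrained (freshly initialized) baseline, with mean absolute errors in
    bpm.  A recording yielding no estimate is charged
    ``NO_ESTIMATE_PENALTY_BPM``.  Fully deterministic given ``seed``.
    """
    base = (seed % (1 << 20)) * 64
    train_sets, train_recs, _ = make_dataset(
        _specs(TRAIN_HRS, base, motion, noise_sd), CLIP_T, "train")
    test_sets, test_recs, _ = make_dataset(
        _specs(TEST_HRS, base + len(TRAIN_HRS), motion, noise_sd),
        CLIP_T, "test")
    clips = [c for cs in train_sets for c in cs.clips]
    labels = [lab for cs in train_sets for lab in cs.labels]
    val_clips = [cs.clips[0] for cs in train_sets]
    val_labels = [cs.labels[0] for cs in train_sets]

    config = NetConfig.reduced(T=CLIP_T)
    model = build_model(config, seed=seed)

    det0 = DetectionConfig(confidence=0.6, fps=FPS, aggregation="median")
    untrained_preds, untrained_errs = _estimate_all(model, test_sets,
                                                    test_recs, det0)

    # Short runs occasionally start in a slow-converging basin (training
    # loss stuck near the no-phase-lock plateau ~0.3).  Use up to two random
    # restarts and keep the run with the lower *training* loss; the held-out
    # recordings play no part in the selection.
    best_run = None
    for attempt in range(max_restarts):
        model_seed = (seed + 1_000_003 * attempt) % (2 ** 31)
        model = build_model(config, seed=model_seed)
        tcfg = TrainConfig(learning_rate=learning_rate, warmup_epochs=4,
                           epochs=epochs, seed=model_seed)
        _, _, log = train(model, clips, labels, val_clips, val_labels, tcfg)
        if best_run is None or log.train_loss[-1] < best_run[1].train_loss[-1]:
            best_run = (model, log)
        if best_run[1].train_loss[-1] < 0.1:    # converged; no restart needed
            break
    model, log = best_run

    # pick the confidence threshold on the *training* recordings
    train_test_sets, _, _ = make_dataset(
        _specs(TRAIN_HRS, base, motion, noise_sd), CLIP_T, "test")
    val_maps = [predict_recording(model, cs) for cs in train_test_sets]
    try:
        confidence = grid_search_confidence(
            val_maps, [r.mean_hr_bpm for r in train_recs], det0)
    except NoEstimateError:
        confidence = det0.confidence
    det = DetectionConfig(confidence=confidence, fps=FPS, aggregation="median")

    preds, errs = _estimate_all(model, test_sets, test_recs, det)
    return RecoveryResult(
        mae_trained=float(np.mean(errs)),
        mae_untrained=float(np.mean(untrained_errs)),
        predictions=preds,
        truths=[r.mean_hr_bpm for r in test_recs],
        untrained_predictions=untrained_preds,
        confidence=confidence,
        final_train_loss=log.train_loss[-1],
        final_val_loss=log.val_loss[-1],
        motion=motion,
        log=log,
    )
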