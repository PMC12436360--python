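"""Training drivers for the single-, multi-, and cross-sequence models.

Three modes share one loop:

* ``single``     — original image only, one encoder.
* ``multi``      — original + own ROI crop (identity pairing) at train time.
* ``multi_csl``  — original + the same-label crop of (usually) another
  sample, chosen by lowest raw-pixel cosine similarity without
  replacement.  Pairing applies to training batches only; the tuning and
  test sets always use identity pairing.

Optimization is AdamW with cosine learning-rate decay on the mean binary
cross-entropy; the checkpoint kept is the epoch with the best tuning-set
AUROC.  Everything is reproducible from the seeds in the configs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .matching import (
    MatchingPlan,
    SimilarityVector,
    build_cross_sequence_plan,
    flatten_for_similarity,
    identity_plan,
    resize_bilinear,
)
from .model import EncoderConfig, FusionClassifier, DESK_ENCODER
from .phantom import DatasetManifest, RadiographSample, crop_roi
from .stats import auroc

__all__ = [
    "TrainConfig",
    "TrainingLog",
    "FoldResult",
    "prepare_inputs",
    "train_model",
    "predict_scores",
    "run_cross_validation",
    "DESK_TRAIN",
    "PAPER_TRAIN",
]

MODES = ("single", "multi", "multi_csl")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 40
    batch_size: int = 16
    learning_rate: float = 5e-4
    weight_decay: float = 1e-4
    mode: str = "multi_csl"
    replan_each_epoch: bool = False
    similarity_resolution: int = 64
    grad_clip: float = 1.0
    #: small from-scratch runs occasionally fail to converge; when the best
    #: tuning AUROC stays below this, retrain with a derived seed (tune-set
    #: information only — the test split is never consulted)
    restart_tune_auroc: float = 0.9
    max_restarts: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")


#: Laptop-scale profile: small encoder, 40 epochs at lr 5e-4.
DESK_TRAIN = TrainConfig()
#: Profile mirroring the emulated study's schedule: 400 epochs, standard ViT lr.
PAPER_TRAIN = TrainConfig(epochs=400, learning_rate=1e-4)


@dataclass
class TrainingLog:
    epoch_loss: list[float] = field(default_factory=list)
    tune_auroc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    n_attempts: int = 1
    plan_modes_seen: dict = field(default_factory=lambda: {"train": set(), "eval": set()})


@dataclass
class FoldResult:
    fold_index: int
    scores: list[tuple[str, float, int]]
    auroc: float


def prepare_inputs(
    samples: list[RadiographSample], image_size: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Resize originals and ROI crops to the model resolution.

    Returns (originals (N,S,S), crops (N,S,S), labels (N,), sample_ids).
    """
    if not samples:
        raise ValueError("no samples supplied")
    originals = np.stack([resize_bilinear(s.pixels, image_size, image_size) for s in samples])
    crops = np.stack([resize_bilinear(crop_roi(s), image_size, image_size) for s in samples])
    labels = np.array([s.label for s in samples], dtype=int)
    ids = [s.sample_id for s in samples]
    return originals, crops, labels, ids


def _build_plan(samples: list[RadiographSample], resolution: int) -> MatchingPlan:
    originals = [
        SimilarityVector(s.sample_id, s.label, flatten_for_similarity(s.pixels, resolution))
        for s in samples
    ]
    crops = [
        SimilarityVector(s.sample_id, s.label, flatten_for_similarity(crop_roi(s), resolution))
        for s in samples
    ]
    return build_cross_sequence_plan(originals, crops)


def manifest_samples(
    manifest: DatasetManifest, samples: dict[str, RadiographSample], split: str | None = None
) -> list[RadiographSample]:
    """Materialize the sample objects referenced by a manifest (optionally one split)."""
    records = manifest.records if split is None else manifest.subset(split).records
    return [samples[r.sample_id] for r in records]


def train_model(
    train_samples: list[RadiographSample],
    tune_samples: list[RadiographSample],
    config: TrainConfig = DESK_TRAIN,
    encoder: EncoderConfig = DESK_ENCODER,
) -> tuple[FusionClassifier, TrainingLog]:
    """Fit one model; returns it restored to its best-tune-AUROC state.

    In ``multi_csl`` mode each training input is (original_i, crop_j) from
    the cross-sequence plan, carrying their shared label; tune evaluation
    always uses identity pairing.  If a run's best tuning AUROC stays below
    ``config.restart_tune_auroc`` the training is restarted from a seed
    derived from ``config.seed`` (at most ``max_restarts`` times) and the
    attempt with the best tuning AUROC wins.
    """
    if not train_samples:
        raise ValueError("empty training split")
    train_labels = np.array([s.label for s in train_samples])
    if train_labels.min() == train_labels.max():
        raise ValueError("training split must contain both classes")

    best = None
    for attempt in range(1 + max(0, config.max_restarts)):
        seed = (config.seed + 9973 * attempt) & 0x7FFFFFFF
        model, log, tune_auc = _train_once(
            train_samples, tune_samples, config, encoder, seed
        )
        log.n_attempts = attempt + 1
        if best is None or tune_auc > best[2]:
            best = (model, log, tune_auc)
        if best[2] >= config.restart_tune_auroc:
            break
    return best[0], best[1]


def _train_once(
    train_samples: list[RadiographSample],
    tune_samples: list[RadiographSample],
    config: TrainConfig,
    encoder: EncoderConfig,
    seed: int,
) -> tuple[FusionClassifier, TrainingLog, float]:
    y_tr_labels = np.array([s.label for s in train_samples])
    model_mode = "single" if config.mode == "single" else "multi"
    enc = EncoderConfig(**{**asdict(encoder), "seed": seed})
    model = FusionClassifier(enc, mode=model_mode)
    orig_tr, crop_tr, y_tr, _ = prepare_inputs(train_samples, enc.image_size)
    orig_tu, crop_tu, y_tu, _ = prepare_inputs(tune_samples, enc.image_size)
    assert np.array_equal(y_tr, y_tr_labels)

    log = TrainingLog()
    n = len(train_samples)
    plan: MatchingPlan
    if config.mode == "multi_csl":
        plan = _build_plan(train_samples, config.similarity_resolution)
    else:
        plan = identity_plan(n, y_tr.tolist())
    log.plan_modes_seen["train"].add(plan.mode)
    crop_index = np.array([plan.crop_for(i) for i in range(n)], dtype=int)

    opt = nn.AdamW(model.params, lr=config.learning_rate,
                   weight_decay=config.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 0x71)))
    steps_per_epoch = max(1, (n + config.batch_size - 1) // config.batch_size)
    total_steps = steps_per_epoch * config.epochs
    step = 0
    best_auc, best_state = -1.0, model.state_dict()
    # checkpoints from the LR-warmup phase are undertrained; exclude them
    # from model selection (unless the run is too short to have any other)
    min_select_epoch = min(max(1, int(round(0.1 * config.epochs))), config.epochs - 1)
    for epoch in range(config.epochs):
        if config.mode == "multi_csl" and config.replan_each_epoch and epoch > 0:
            plan = _build_plan(train_samples, config.similarity_resolution)
            crop_index = np.array([plan.crop_for(i) for i in range(n)], dtype=int)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            batch_o = orig_tr[idx]
            batch_c = crop_tr[crop_index[idx]] if model_mode == "multi" else None
            opt.zero_grad()
            logits = model.forward_logits(batch_o, batch_c, training=True, rng=rng)
            loss = nn.bce_with_logits(logits, y_tr[idx].astype(float))
            loss.backward()
            if config.grad_clip > 0:
                nn.clip_grad_norm(model.params, config.grad_clip)
            opt.step(lr=nn.cosine_lr(step, total_steps, config.learning_rate))
            step += 1
            losses.append(float(loss.data))
        log.epoch_loss.append(float(np.mean(losses)))
        tune_plan = identity_plan(len(tune_samples), y_tu.tolist())
        log.plan_modes_seen["eval"].add(tune_plan.mode)
        probs = model.predict_proba(orig_tu, crop_tu if model_mode == "multi" else None)
        auc = auroc(probs, y_tu) if y_tu.min() != y_tu.max() else float("nan")
        log.tune_auroc.append(auc)
        # >= so ties go to the later, more-converged epoch
        if epoch >= min_select_epoch and np.isfinite(auc) and auc >= best_auc:
            best_auc = auc
            best_state = model.state_dict()
            log.best_epoch = epoch
    model.load_state_dict(best_state)
    return model, log, best_auc


def predict_scores(
    model: FusionClassifier,
    samples: list[RadiographSample],
    plan: MatchingPlan | None = None,
    batch_size: int = 32,
) -> list[tuple[str, float, int]]:
    """Score samples with identity pairing; one (id, probability, label) each."""
    originals, crops, labels, ids = prepare_inputs(samples, model.config.image_size)
    if plan is None:
        plan = identity_plan(len(samples), labels.tolist())
    if plan.mode != "identity":
        raise ValueError("evaluation requires an identity pairing plan")
    if len(plan) != len(samples):
        raise ValueError("plan and sample list lengths differ")
    out = []
    for start in range(0, len(samples), batch_size):
        sl = slice(start, start + batch_size)
        probs = model.predict_proba(
            originals[sl], crops[sl] if model.mode == "multi" else None
        )
        for i, p in zip(range(sl.start, min(sl.stop, len(samples))), probs):
            out.append((ids[i], float(p), int(labels[i])))
    return out


def run_cross_validation(
    samples: list[RadiographSample],
    k: int = 10,
    config: TrainConfig = DESK_TRAIN,
    encoder: EncoderConfig = DESK_ENCODER,
    tune_fraction: float = 0.125,
) -> tuple[list[FoldResult], dict]:
    """Stratified k-fold cross-validation.

    Each fold's training portion donates a stratified ``tune_fraction`` for
    model selection.  The summary reports both per-fold metrics
    (mean +/- sd) and the AUROC of the pooled out-of-fold scores.
    """
    from sklearn.model_selection import StratifiedKFold, train_test_split

    labels = np.array([s.label for s in samples])
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = np.bincount(labels, minlength=2)
    if counts.min() < k:
        raise ValueError(f"each class needs >= {k} members for {k}-fold CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed & 0x7FFFFFFF)
    results: list[FoldResult] = []
    pooled_scores, pooled_labels = [], []
    for fold, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(samples)), labels)):
        tr_idx, tu_idx = train_test_split(
            train_idx, test_size=tune_fraction, stratify=labels[train_idx],
            random_state=(config.seed + fold) & 0x7FFFFFFF,
        )
        model, _ = train_model(
            [samples[i] for i in tr_idx], [samples[i] for i in tu_idx], config, encoder
        )
        scores = predict_scores(model, [samples[i] for i in test_idx])
        fold_auc = auroc([s[1] for s in scores], [s[2] for s in scores])
        results.append(FoldResult(fold, scores, fold_auc))
        pooled_scores.extend(s[1] for s in scores)
        pooled_labels.extend(s[2] for s in scores)
    per_fold = np.array([r.auroc for r in results])
    summary = {
        "auroc_mean": float(per_fold.mean()),
        "auroc_sd": float(per_fold.std(ddof=1)) if k > 1 else 0.0,
        "auroc_pooled": auroc(pooled_scores, pooled_labels),
        "k": k,
    }
    return results, summary
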