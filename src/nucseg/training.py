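"""Training: combined BCE+Dice loss, dynamic mixup-probability curriculum,
and sliding-window whole-slide inference.

The loss of one sample is the mean of its binary cross-entropy and its
smoothed Dice loss; the batch loss is the mean over samples:

    l_n  = (BCEloss_n + Diceloss_n) / 2
    Loss = mean(l_1 ... l_N)

The dynamic curriculum adjusts the Full-Mixup probability ``p`` each epoch
from validation feedback: when the model predicts *unmixed* patches better
than mixed ones (scores are the mean of Jaccard similarity JS and Dice
coefficient DC on the two validation subsets), ``p`` is raised by a step, and
vice versa.  Training stops once ``p`` has saturated at its ceiling for a
configured number of consecutive epochs — the epoch count is flexible rather
than fixed.  With ``dynamic=False`` the loop runs the full epoch cap at a
constant probability instead.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .metrics import instances_from_mask
from .mixup import MixupConfig, maybe_mix, normalize_patch
from .network import FGDCNet, NetworkConfig
from .nn import Adam
from .pseudolabels import SamplePatch

__all__ = [
    "TrainingConfig",
    "EpochRecord",
    "TrainingHistory",
    "bce_loss",
    "dice_loss",
    "combined_loss",
    "combined_loss_grad",
    "update_mixup_probability",
    "dynamic_train",
    "sliding_window_segment",
    "PROB_THRESHOLD",
]

#: Probability threshold that turns a soft prediction into a binary mask.
PROB_THRESHOLD = 0.5

_EPS_BCE = 1e-7
_EPS_DICE = 1.0


@dataclasses.dataclass
class TrainingConfig:
    batch_size: int = 64
    learning_rate: float = 1e-3
    epoch_cap: int = 400
    p_init: float = 0.5
    p_min: float = 0.1
    p_max: float = 0.9
    delta_p: float = 0.05
    patience: int = 3
    seed: int = 0
    dynamic: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_min <= self.p_init <= self.p_max <= 1.0:
            raise ValueError(
                f"need 0 <= p_min <= p_init <= p_max <= 1, got "
                f"({self.p_min}, {self.p_init}, {self.p_max})"
            )
        if self.delta_p <= 0:
            raise ValueError(f"delta_p must be > 0, got {self.delta_p}")
        if self.epoch_cap < 1:
            raise ValueError(f"epoch_cap must be >= 1, got {self.epoch_cap}")
        if self.patience < 1:
            raise ValueError(f"patience must be >= 1, got {self.patience}")


@dataclasses.dataclass
class EpochRecord:
    epoch: int
    mean_loss: float
    js_unmixed: float
    dc_unmixed: float
    js_mixed: float
    dc_mixed: float
    p: float        # mixup probability used during this epoch
    p_next: float   # probability carried into the next epoch


@dataclasses.dataclass
class TrainingHistory:
    records: List[EpochRecord]
    stop_reason: str  # "probability-threshold" | "epoch-cap"

    @property
    def final_p(self) -> float:
        return self.records[-1].p_next if self.records else float("nan")

    def to_rows(self) -> List[dict]:
        return [dataclasses.asdict(r) for r in self.records]


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def _check_xy(x: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"prediction/label shape mismatch: {x.shape} vs {y.shape}")
    return x, y


def bce_loss(x: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy; predictions clamped to [eps, 1-eps]."""
    x, y = _check_xy(x, y)
    xc = np.clip(x, _EPS_BCE, 1.0 - _EPS_BCE)
    return float(-np.mean(y * np.log(xc) + (1.0 - y) * np.log(1.0 - xc)))


def dice_loss(x: np.ndarray, y: np.ndarray) -> float:
    """1 - smoothed Dice overlap: 1 - (2*sum(xy)+eps)/(sum(x)+sum(y)+eps)."""
    x, y = _check_xy(x, y)
    num = 2.0 * np.sum(x * y) + _EPS_DICE
    den = np.sum(x) + np.sum(y) + _EPS_DICE
    return float(1.0 - num / den)


def combined_loss(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Batch loss: mean over samples of (BCE_n + Dice_n)/2.

    ``predictions``/``labels`` are (B, ...) with one sample per leading index.
    """
    predictions, labels = _check_xy(predictions, labels)
    if predictions.shape[0] == 0:
        raise ValueError("combined_loss requires a nonempty batch")
    per_sample = [
        (bce_loss(p, t) + dice_loss(p, t)) / 2.0
        for p, t in zip(predictions, labels)
    ]
    return float(np.mean(per_sample))


def combined_loss_grad(
    predictions: np.ndarray, labels: np.ndarray
) -> Tuple[float, np.ndarray]:
    """Combined loss and its analytic gradient w.r.t. the predictions."""
    x, y = _check_xy(predictions, labels)
    if x.shape[0] == 0:
        raise ValueError("combined_loss_grad requires a nonempty batch")
    bsz = x.shape[0]
    npix = x[0].size
    xc = np.clip(x, _EPS_BCE, 1.0 - _EPS_BCE)
    grad = np.zeros_like(x)
    total = 0.0
    axes = tuple(range(1, x.ndim))
    sx = x.sum(axis=axes)
    sy = y.sum(axis=axes)
    sxy = (x * y).sum(axis=axes)
    for n in range(bsz):
        bce = -np.mean(y[n] * np.log(xc[n]) + (1.0 - y[n]) * np.log(1.0 - xc[n]))
        dbce = (-y[n] / xc[n] + (1.0 - y[n]) / (1.0 - xc[n])) / npix
        den = sx[n] + sy[n] + _EPS_DICE
        num = 2.0 * sxy[n] + _EPS_DICE
        dice = 1.0 - num / den
        ddice = -(2.0 * y[n] * den - num) / (den * den)
        total += (bce + dice) / 2.0
        grad[n] = (dbce + ddice) / 2.0
    return total / bsz, grad / bsz


# ---------------------------------------------------------------------------
# Dynamic curriculum
# ---------------------------------------------------------------------------

def update_mixup_probability(
    score_unmixed: float, score_mixed: float, p: float, cfg: TrainingConfig
) -> float:
    """Step the mixup probability from the validation feedback.

    Raise ``p`` by ``delta_p`` when the unmixed subset scores higher (the
    model needs more mixed exposure), lower it when the mixed subset scores
    higher, leave it on an exact tie; always clip to [p_min, p_max].
    """
    if score_unmixed > score_mixed:
        p = p + cfg.delta_p
    elif score_unmixed < score_mixed:
        p = p - cfg.delta_p
    return float(np.clip(p, cfg.p_min, cfg.p_max))


def _patch_to_arrays(patch: SamplePatch) -> Tuple[np.ndarray, np.ndarray]:
    img = patch.image
    if img.dtype == np.uint8:
        img = normalize_patch(img)
    return np.asarray(img, dtype=np.float64), patch.label.astype(np.float64)


def _js_dc(pred_bin: np.ndarray, label: np.ndarray) -> Tuple[float, float]:
    inter = float(np.count_nonzero(pred_bin & label))
    union = float(np.count_nonzero(pred_bin | label))
    a = float(np.count_nonzero(pred_bin))
    b = float(np.count_nonzero(label))
    js = 1.0 if union == 0 else inter / union
    dc = 1.0 if a + b == 0 else 2.0 * inter / (a + b)
    return js, dc


def _evaluate_subset(model: FGDCNet, patches: Sequence[SamplePatch]) -> Tuple[float, float]:
    """Per-patch mean JS and DC of thresholded predictions on a subset."""
    xs = np.stack([_patch_to_arrays(p)[0] for p in patches])
    preds = model.predict(xs)
    js_all, dc_all = [], []
    for pred, patch in zip(preds, patches):
        js, dc = _js_dc(pred >= PROB_THRESHOLD, patch.label.astype(bool))
        js_all.append(js)
        dc_all.append(dc)
    return float(np.mean(js_all)), float(np.mean(dc_all))


def dynamic_train(
    train_patches: Sequence[SamplePatch],
    val_patches: Sequence[SamplePatch],
    net_config: NetworkConfig,
    cfg: TrainingConfig,
    mixup_cfg: Optional[MixupConfig] = None,
    model: Optional[FGDCNet] = None,
    evaluator: Optional[Callable[[FGDCNet, int], Tuple[float, float]]] = None,
) -> Tuple[FGDCNet, TrainingHistory]:
    """Run the (optionally dynamic) training loop.

    Parameters
    ----------
    train_patches, val_patches:
        Unmixed sample patches; mixing happens on the fly.  The mixed
        validation subset is rebuilt every epoch from ``val_patches`` with a
        per-epoch seed, so it is stochastic but reproducible.
    evaluator:
        Optional override returning ``(score_unmixed, score_mixed)`` given
        ``(model, epoch)``; the default thresholds predictions at 0.5 and
        averages JS and DC per patch.
    """
    if len(train_patches) == 0:
        raise ValueError("training split is empty")
    if len(val_patches) == 0:
        raise ValueError("validation split is empty")
    if mixup_cfg is None:
        mixup_cfg = MixupConfig(
            probability=cfg.p_init, p_min=cfg.p_min, p_max=cfg.p_max, seed=cfg.seed
        )
    if model is None:
        model = FGDCNet(net_config)
    optimizer = Adam(model.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)

    p = cfg.p_init
    streak = 0
    records: List[EpochRecord] = []
    stop_reason = "epoch-cap"

    for epoch in range(1, cfg.epoch_cap + 1):
        order = rng.permutation(len(train_patches))
        epoch_cfg = dataclasses.replace(mixup_cfg, probability=p)
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            batch = [train_patches[i] for i in idx]
            batch = maybe_mix(batch, epoch_cfg, rng, pool=train_patches)
            xs = np.stack([_patch_to_arrays(s)[0] for s in batch])
            ys = np.stack([s.label.astype(np.float64) for s in batch])
            preds = model.forward(xs)
            loss, dpred = combined_loss_grad(preds, ys)
            optimizer.zero_grad()
            model.backward(dpred)
            optimizer.step()
            losses.append(loss)

        if evaluator is not None:
            score_unmixed, score_mixed = evaluator(model, epoch)
            js_u = dc_u = score_unmixed
            js_m = dc_m = score_mixed
        else:
            js_u, dc_u = _evaluate_subset(model, val_patches)
            epoch_rng = np.random.default_rng((cfg.seed, epoch))
            mix_all = dataclasses.replace(epoch_cfg, probability=epoch_cfg.p_max)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mixed_val = maybe_mix(list(val_patches), mix_all, epoch_rng)
            mixed_val = [s for s in mixed_val if s.mixed] or list(val_patches)
            js_m, dc_m = _evaluate_subset(model, mixed_val)
            score_unmixed = (js_u + dc_u) / 2.0
            score_mixed = (js_m + dc_m) / 2.0

        p_next = p
        if cfg.dynamic:
            p_next = update_mixup_probability(score_unmixed, score_mixed, p, cfg)
            if p_next >= cfg.p_max:
                streak += 1
            else:
                streak = 0
        records.append(
            EpochRecord(
                epoch=epoch,
                mean_loss=float(np.mean(losses)),
                js_unmixed=js_u,
                dc_unmixed=dc_u,
                js_mixed=js_m,
                dc_mixed=dc_m,
                p=p,
                p_next=p_next,
            )
        )
        p = p_next
        if cfg.dynamic and streak >= cfg.patience:
            stop_reason = "probability-threshold"
            break

    return model, TrainingHistory(records=records, stop_reason=stop_reason)


# ---------------------------------------------------------------------------
# Whole-slide inference
# ---------------------------------------------------------------------------

def sliding_window_segment(
    model: FGDCNet, image: np.ndarray, batch_size: int = 16
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Segment a whole slide by exact central tiling.

    The slide is reflect-padded by N/2 on every side (plus a bottom/right
    remainder so the tiling closes), 2N x 2N windows are taken at stride N,
    and each window's central N x N prediction is placed at its location —
    every output pixel is written exactly once, no blending.  Returns the
    probability map, the thresholded binary mask, and the 8-connected
    instance label map.
    """
    n = model.config.label_size
    image = np.asarray(image)
    h, w = image.shape[:2]
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 image, got {image.shape}")
    norm = normalize_patch(image) if image.dtype == np.uint8 else np.asarray(
        image, dtype=np.float64
    )
    half = n // 2
    extra_h = (-h) % n
    extra_w = (-w) % n
    padded = np.pad(
        norm,
        ((half, half + extra_h), (half, half + extra_w), (0, 0)),
        mode="reflect",
    )
    ph, pw = padded.shape[:2]
    rows = range(0, ph - 2 * n + 1, n)
    cols = range(0, pw - 2 * n + 1, n)
    windows = [(r, c) for r in rows for c in cols]
    prob = np.zeros((h + extra_h, w + extra_w), dtype=np.float64)
    coverage = np.zeros_like(prob, dtype=np.int32)
    for start in range(0, len(windows), batch_size):
        chunk = windows[start : start + batch_size]
        xs = np.stack([padded[r : r + 2 * n, c : c + 2 * n] for r, c in chunk])
        preds = model.predict(xs)
        for (r, c), pred in zip(chunk, preds):
            prob[r : r + n, c : c + n] = pred
            coverage[r : r + n, c : c + n] += 1
    assert coverage.min() == 1 and coverage.max() == 1, "tiling must be exact"
    prob = prob[:h, :w]
    mask = prob >= PROB_THRESHOLD
    instances = instances_from_mask(mask)
    return prob, mask, instances
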