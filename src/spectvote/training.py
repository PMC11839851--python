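"""Patient-level splitting, the three training loops, and prediction.

Splitting is done on scan level: all 12 augmentation instances of a scan
travel together into train (60%), validation (20%) or test (20%), so no
scan leaks across subsets.  The same K splits are reused for every
training method.

Training follows a fixed recipe: Adam, initial learning rate 1e-4, batch
size 64, 20 epochs, binary cross-entropy for majority- and random-vote
targets, mean squared error on the sigmoid for average-vote targets.  The
final-epoch weights are used as-is; validation data play no role during
training (they are reserved for the inconclusive-interval construction).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .cohort import ScanRecord, background_roi_mask
from .labels import Method, average_vote, majority_vote
from .network import ArchitectureSpec, ResNetSlab, build_architecture, resize_bicubic


class Subset(str, enum.Enum):
    TRAIN = "TRAIN"
    VAL = "VAL"
    TEST = "TEST"


@dataclass
class SplitAssignment:
    realization: int
    assignment: dict[str, Subset]

    def scan_ids(self, subset: Subset) -> list[str]:
        return [sid for sid, s in self.assignment.items() if s is subset]


def make_splits(
    scan_ids: list[str],
    k: int = 10,
    proportions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> list[SplitAssignment]:
    """K independent scan-level random splits with deterministic rounding.

    Subset sizes are floor(p * n) with the remainder assigned in order
    train, validation, test (largest fractional part first).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    n = len(scan_ids)
    if n < len(proportions):
        raise ValueError("fewer scans than subsets")
    raw = [p * n for p in proportions]
    counts = [int(np.floor(r)) for r in raw]
    order = sorted(range(3), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[: n - sum(counts)]:
        counts[i] += 1
    rng = np.random.default_rng(seed)
    subsets = (Subset.TRAIN, Subset.VAL, Subset.TEST)
    splits = []
    for real in range(1, k + 1):
        perm = rng.permutation(n)
        assignment: dict[str, Subset] = {}
        start = 0
        for subset, c in zip(subsets, counts):
            for j in perm[start : start + c]:
                assignment[scan_ids[j]] = subset
            start += c
        splits.append(SplitAssignment(real, assignment))
    return splits


@dataclass(frozen=True)
class TrainingConfig:
    method: Method = Method.MVT
    epochs: int = 20
    batch_size: int = 64
    learning_rate: float = 1e-4
    init_seed: int = 0
    shuffle_seed: int = 1
    rvt_seed: int = 2  # seeds the single run-level random-vote stream

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")

    @property
    def loss(self) -> str:
        return "mse" if self.method is Method.AVT else "bce"


# ---------------------------------------------------------------------
# image stack assembly


def preprocess_image(pixels: np.ndarray, input_size: int) -> np.ndarray:
    """DVR-style intensity normalization and optional bicubic resize.

    Each image is divided by its background-ROI mean (reference-region
    normalization) and shifted so background sits near zero.
    """
    g = pixels.shape[0]
    ref = pixels[background_roi_mask(g)].mean()
    img = pixels / max(ref, 1e-9) - 1.0
    if input_size != g:
        img = resize_bicubic(img, input_size)
    return img.astype(np.float32)


@dataclass
class ImageStack:
    """Flat per-instance view of a cohort subset."""

    x: np.ndarray  # (N, 1, H, W) float32
    case_ids: list[str]
    scan_index: np.ndarray  # (N,) index into records
    records: list[ScanRecord] = field(repr=False, default_factory=list)


def stack_images(
    records: list[ScanRecord],
    input_size: int,
    scan_ids: set[str] | None = None,
) -> ImageStack:
    xs, case_ids, scan_idx, kept = [], [], [], []
    for rec in records:
        if scan_ids is not None and rec.scan_id not in scan_ids:
            continue
        kept.append(rec)
        for k, inst in enumerate(rec.instances):
            xs.append(preprocess_image(inst.pixels, input_size))
            case_ids.append(f"{rec.scan_id}/{inst.variant.value}/{int(inst.smoothing_fwhm_mm)}mm")
            scan_idx.append(len(kept) - 1)
    x = np.stack(xs)[:, None, :, :]
    return ImageStack(x, case_ids, np.asarray(scan_idx), kept)


# ---------------------------------------------------------------------
# training


@dataclass
class TrainedModel:
    model: ResNetSlab
    config: TrainingConfig
    arch: ArchitectureSpec
    epoch_losses: list[float]


def train(
    records: list[ScanRecord],
    split: SplitAssignment,
    config: TrainingConfig,
    arch: ArchitectureSpec,
) -> TrainedModel:
    """Train one network on the TRAIN scans of one split realization."""
    n_readers = len(records[0].votes)
    if config.method in (Method.RVT, Method.AVT) and n_readers < 2:
        raise ValueError(f"{config.method.value} requires votes from >= 2 readers")
    train_ids = set(split.scan_ids(Subset.TRAIN))
    stack = stack_images(records, arch.input_size, train_ids)
    n = stack.x.shape[0]

    # fixed per-scan targets; RVT re-draws per presentation below
    mvt = np.array([majority_vote(r.votes).value for r in stack.records], np.float32)
    avt = np.array([average_vote(r.votes).value for r in stack.records], np.float32)
    vote_matrix = np.array([r.votes.votes for r in stack.records], np.int8)

    model = build_architecture(arch, seed=config.init_seed)
    model.set_training(True)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(config.shuffle_seed)
    rvt_rng = np.random.default_rng(config.rvt_seed)  # seeded once for the run

    losses = []
    for _epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb = stack.x[idx]
            scan_of = stack.scan_index[idx]
            if config.method is Method.MVT:
                tb = mvt[scan_of]
            elif config.method is Method.AVT:
                tb = avt[scan_of]
            else:  # RVT: one vote per presentation from the run-level stream
                reader = rvt_rng.integers(n_readers, size=len(idx))
                tb = vote_matrix[scan_of, reader].astype(np.float32)
            logits = model.forward(xb)
            if config.loss == "bce":
                loss, dz = nn.bce_with_logits(logits, tb)
            else:
                loss, dz = nn.mse_on_sigmoid(logits, tb)
            model.zero_grad()
            model.backward(dz)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        losses.append(epoch_loss / n_batches)
    model.set_training(False)
    return TrainedModel(model, config, arch, losses)


# ---------------------------------------------------------------------
# prediction


def predict(
    trained: TrainedModel | ResNetSlab,
    records: list[ScanRecord],
    scan_ids: set[str] | None = None,
    batch_size: int = 256,
) -> pd.DataFrame:
    """Sigmoid outputs and 0.5-threshold predictions, one row per image.

    ``prediction`` is 0 ("normal") iff sigmoid <= 0.5, else 1 ("reduced").
    """
    model = trained.model if isinstance(trained, TrainedModel) else trained
    stack = stack_images(records, model.spec.input_size, scan_ids)
    sig = np.empty(stack.x.shape[0])
    for start in range(0, stack.x.shape[0], batch_size):
        sig[start : start + batch_size] = model.predict_proba(
            stack.x[start : start + batch_size]
        )
    rows = pd.DataFrame(
        {
            "case_id": stack.case_ids,
            "scan_id": [stack.records[i].scan_id for i in stack.scan_index],
            "sigmoid": sig,
            "prediction": (sig > 0.5).astype(int),
            "majority_label": [
                int(majority_vote(stack.records[i].votes).value) for i in stack.scan_index
            ],
            "unanimous": [stack.records[i].votes.unanimous for i in stack.scan_index],
            "true_class": [stack.records[i].true_class for i in stack.scan_index],
        }
    )
    return rows
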