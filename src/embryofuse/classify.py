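"""Stage-classification training, evaluation and the fused-vs-single-plane
comparison.

Inputs to a classifier are 224x224 crops (resized to the architecture's
input resolution) of either the fused image or the raw central focal plane
F0; the embryo boundary is always localized on the *fused* image — its edges
are sharpest — and the same crop geometry is applied to both modalities so
the comparison isolates the effect of fusion alone.  Class imbalance is
handled by oversampling minority classes with seeded rotation/flip
augmentation until every class matches the majority count each epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score

from embryofuse import nn, roi
from embryofuse.backbones import ArchSpec, build_classifier
from embryofuse.phantom import CLASSES, LabeledDataset
from embryofuse.pyramid import fuse_lp

__all__ = [
    "EvalReport", "evaluate", "cross_entropy", "prepare_inputs",
    "train_classifier", "predict", "predict_proba", "compare_modalities",
]

INPUT_MODES = ("fused", "single_plane_F0")


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalReport:
    accuracy: float
    per_class_f1: dict[str, float]
    macro_f1: float
    confusion: np.ndarray  # row-normalized, rows = truth
    classes: tuple[str, ...]
    undefined_classes: tuple[str, ...] = ()


def evaluate(predictions, truth, classes: tuple[str, ...] = CLASSES) -> EvalReport:
    """Accuracy, per-class F1, macro F1 and a row-normalized confusion matrix.

    Per-class F1 is the harmonic mean of precision and recall, reported as 0
    (and flagged in ``undefined_classes``) for classes absent from both truth
    and predictions; macro F1 is the unweighted mean over the classes that
    occur in either.  Confusion rows are normalized to sum to 1 wherever the
    true class occurs.
    """
    predictions = list(predictions)
    truth = list(truth)
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth must have equal length")
    bad = (set(predictions) | set(truth)) - set(classes)
    if bad:
        raise ValueError(f"labels outside the class set: {sorted(bad)}")

    present = [c for c in classes if c in set(predictions) | set(truth)]
    f1_present = f1_score(truth, predictions, labels=present, average=None,
                          zero_division=0)
    per_class = {c: 0.0 for c in classes}
    per_class.update({c: float(v) for c, v in zip(present, f1_present)})
    undefined = tuple(c for c in classes if c not in present)

    raw = confusion_matrix(truth, predictions, labels=list(classes)).astype(np.float64)
    row_sums = raw.sum(axis=1, keepdims=True)
    confusion = np.divide(raw, row_sums, out=np.zeros_like(raw), where=row_sums > 0)

    return EvalReport(
        accuracy=float(accuracy_score(truth, predictions)),
        per_class_f1=per_class,
        macro_f1=float(np.mean(f1_present)) if present else 0.0,
        confusion=confusion,
        classes=tuple(classes),
        undefined_classes=undefined,
    )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def cross_entropy(logits: nn.Tensor, labels: np.ndarray) -> nn.Tensor:
    """Mean cross-entropy of integer labels under softmax logits."""
    shift = logits - logits.data.max(axis=-1, keepdims=True)
    log_z = shift.exp().sum(axis=-1, keepdims=True).log()
    log_probs = shift - log_z
    picked = log_probs[np.arange(len(labels)), np.asarray(labels)]
    return -picked.mean()


def _dihedral(image: np.ndarray, code: int) -> np.ndarray:
    out = np.rot90(image, code % 4)
    if code >= 4:
        out = out[:, ::-1]
    return np.ascontiguousarray(out)


def _full_image_boundary(image: np.ndarray, margin: float) -> roi.BoundaryEstimate:
    h, w = image.shape
    radius = min(h, w) / (2.0 * (1.0 + margin))
    return roi.BoundaryEstimate(center=(w / 2.0, h / 2.0), radius=radius)


def prepare_inputs(dataset: LabeledDataset, mode: str, input_size: int,
                   n_levels: int = 4, margin: float = 0.1,
                   _cache: dict | None = None):
    """Crops and integer labels for every dataset item, in dataset order.

    The boundary is localized on the Laplacian-fused image (falling back to a
    full-image crop on the no-detection path) and the identical crop geometry
    is applied to the selected source: the fused image (``"fused"``) or the
    raw central plane (``"single_plane_F0"``).
    """
    if mode not in INPUT_MODES:
        raise ValueError(f"unknown input mode {mode!r}; expected one of {INPUT_MODES}")
    images = np.empty((len(dataset.items), 1, input_size, input_size), dtype=np.float32)
    labels = np.array([CLASSES.index(item.class_label) for item in dataset.items])
    for i, item in enumerate(dataset.items):
        key = ("geom", i)
        if _cache is not None and key in _cache:
            fused, boundary = _cache[key]
        else:
            fused = fuse_lp(item.stack, n_levels)
            try:
                boundary = roi.locate_embryo(fused)
            except (roi.NoDetectionError, roi.WeakEdgeError):
                boundary = _full_image_boundary(fused, margin)
            if _cache is not None:
                _cache[key] = (fused, boundary)
        source = fused if mode == "fused" else np.asarray(item.stack.planes[3])
        images[i, 0] = roi.crop_resize(source, boundary, out_size=input_size,
                                       margin=margin)
    return images, labels


def _balanced_order(labels: np.ndarray, rng: np.random.Generator):
    """(index, dihedral-code) pairs oversampling minorities to the majority count."""
    counts = np.bincount(labels, minlength=len(CLASSES))
    top = counts.max()
    entries = []
    for cls in np.flatnonzero(counts):
        idx = np.flatnonzero(labels == cls)
        extra = rng.choice(idx, size=top - len(idx), replace=True) if top > len(idx) else []
        for i in idx:
            entries.append((i, 0))
        for i in extra:
            entries.append((int(i), int(rng.integers(1, 8))))
    order = rng.permutation(len(entries))
    return [entries[i] for i in order]


def train_classifier(model: nn.Module, images: np.ndarray, labels: np.ndarray,
                     epochs: int, lr: float = 1e-3, seed: int = 0,
                     batch_size: int = 16, balance: bool = True) -> list[float]:
    """Cross-entropy training on prepared crops; returns per-epoch mean loss.

    With ``balance`` every epoch oversamples minority classes (seeded
    rotation/flip copies) so per-class counts match the majority.  All
    shuffling, augmentation and optimizer state derive from ``seed``.
    """
    if len(images) == 0:
        raise ValueError("empty training split")
    opt = nn.Adam(model.parameters(), lr=lr)
    model.train()
    history = []
    for epoch in range(epochs):
        rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 151, epoch]))
        if balance:
            schedule = _balanced_order(labels, rng)
        else:
            schedule = [(int(i), 0) for i in rng.permutation(len(labels))]
        total, count = 0.0, 0
        for start in range(0, len(schedule), batch_size):
            chunk = schedule[start:start + batch_size]
            xb = np.stack([
                _dihedral(images[i, 0], code)[None] if code else images[i]
                for i, code in chunk
            ])
            yb = np.array([labels[i] for i, _ in chunk])
            loss = cross_entropy(model(nn.Tensor(xb)), yb)
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data) * len(chunk)
            count += len(chunk)
        history.append(total / count)
    return history


def predict_proba(model: nn.Module, images: np.ndarray,
                  batch_size: int = 32) -> np.ndarray:
    model.eval()
    probs = []
    with nn.no_grad():
        for start in range(0, len(images), batch_size):
            logits = model(nn.Tensor(images[start:start + batch_size]))
            probs.append(logits.softmax(-1).data)
    model.train()
    return np.concatenate(probs) if probs else np.empty((0, len(CLASSES)))


def predict(model: nn.Module, images: np.ndarray) -> list[str]:
    return [CLASSES[i] for i in predict_proba(model, images).argmax(axis=1)]


# ---------------------------------------------------------------------------
# fused vs single-plane comparison
# ---------------------------------------------------------------------------

@dataclass
class ModalityRow:
    seed: int
    fused_accuracy: float
    single_plane_accuracy: float

    @property
    def difference(self) -> float:
        return self.fused_accuracy - self.single_plane_accuracy


def compare_modalities(dataset: LabeledDataset, arch: str = "small_cnn",
                       seeds=(0, 1, 2, 3, 4), epochs: int = 5, lr: float = 1e-3,
                       input_size: int | None = None,
                       modes: tuple[str, str] = ("fused", "single_plane_F0"),
                       ) -> list[ModalityRow]:
    """Paired fused-vs-F0 accuracies: one training per (seed, modality).

    Both arms of a pair share the seed, crop geometry, architecture and
    schedule; only the image source differs, so the accuracy difference
    measures the value of multi-focus fusion.  Requires at least 3 seeds.
    """
    seeds = list(seeds)
    if len(seeds) < 3:
        raise ValueError("need at least 3 seeds for a paired comparison")
    spec = ArchSpec(name=arch, input_size=input_size)
    size = spec.resolved_input_size
    cache: dict = {}
    arm_a, labels = prepare_inputs(dataset, modes[0], size, _cache=cache)
    arm_b, _ = prepare_inputs(dataset, modes[1], size, _cache=cache)
    train_idx = dataset.indices("train")
    test_idx = dataset.indices("test")
    truth = [dataset.items[i].class_label for i in test_idx]

    rows = []
    for seed in seeds:
        accs = []
        for images in (arm_a, arm_b):
            model = build_classifier(spec, seed=seed)
            train_classifier(model, images[train_idx], labels[train_idx],
                             epochs=epochs, lr=lr, seed=seed)
            accs.append(evaluate(predict(model, images[test_idx]), truth).accuracy)
        rows.append(ModalityRow(seed=seed, fused_accuracy=accs[0],
                                single_plane_accuracy=accs[1]))
    return rows
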