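"""Command-identity classification from landmark displacement sequences.

If detected movements really are responses to the spoken command, the
command presented (open your eyes / stick out your tongue / show me a
smile) should be recoverable from the facial movement pattern alone.
This module turns per-trial displacement fields into fixed-size feature
sequences (per-frame landmark step magnitudes pooled on a fixed spatial
grid, so videos with different landmark counts share a dimensionality),
balances classes by label-preserving augmentation, and trains the
bidirectional LSTM in :mod:`seeme._bilstm`.

Augmentation is applied to the training partition only, and augmented
samples are structurally barred from test sets; splits are grouped by
source trial so no trial leaks across the partition boundary.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._bilstm import BiLSTMClassifier, BiLSTMConfig
from .detection import COMMAND_TYPES, CommandEvent, TrialWindowSpec
from .tracking import DisplacementField

CLASS_INDEX = {c: i for i, c in enumerate(COMMAND_TYPES)}


@dataclass
class LabeledSequence:
    """One trial's feature sequence: (frames x channels) with its label."""

    features: np.ndarray  # (T, C)
    label: str  # EYES | TONGUE | SMILE
    trial_id: str
    augmented: bool = False

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2:
            raise ValueError("features must be (frames, channels)")
        if not np.isfinite(self.features).all():
            raise ValueError("features contain missing/non-finite frames")
        if self.label not in COMMAND_TYPES:
            raise ValueError(f"invalid label {self.label!r}")


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class EvalReport:
    """Confusion-matrix summary of a test-set evaluation."""

    classes: list[str]
    confusion: np.ndarray  # (k, k), rows = true class
    per_class_accuracy: dict[str, float]  # NaN when class absent from test
    overall_accuracy: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "classes": self.classes,
                "confusion": self.confusion.astype(int).tolist(),
                "per_class_accuracy": {
                    k: (None if np.isnan(v) else v)
                    for k, v in self.per_class_accuracy.items()
                },
                "overall_accuracy": self.overall_accuracy,
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# feature extraction


def sequences_from_field(
    field_: DisplacementField,
    events: Sequence[CommandEvent],
    window: TrialWindowSpec = TrialWindowSpec(),
    grid: tuple[int, int] = (4, 4),
    frame_shape: tuple[int, int] | None = None,
    video_id: str = "video",
) -> list[LabeledSequence]:
    """One feature sequence per command presentation.

    Landmarks are pooled into a ``grid`` of spatial cells by their
    reference position; each channel is the mean frame-to-frame
    displacement magnitude of the valid landmarks in one cell.  Sequences
    cover the response window (length ``response_window_s * fps``),
    zero-padded when the video ends early.
    """
    gx, gy = grid
    if frame_shape is None:
        h = field_.ref_positions[:, 1].max() + 1
        w = field_.ref_positions[:, 0].max() + 1
    else:
        h, w = frame_shape
    cell = (
        np.clip((field_.ref_positions[:, 0] / w * gx).astype(int), 0, gx - 1)
        + gx * np.clip((field_.ref_positions[:, 1] / h * gy).astype(int), 0, gy - 1)
    )
    sx, sy = field_.step()
    step_mag = np.hypot(sx, sy)
    both = field_.valid.copy()
    both[1:] &= field_.valid[:-1]

    n_cells = gx * gy
    t_total = field_.n_frames
    w_resp = int(round(window.response_window_s * field_.fps))
    out = []
    for ev in events:
        f0 = int(round(ev.onset_s * field_.fps))
        feats = np.zeros((w_resp, n_cells))
        for k in range(w_resp):
            t = f0 + 1 + k
            if t >= t_total:
                break
            for c in range(n_cells):
                sel = (cell == c) & both[t]
                if sel.any():
                    feats[k, c] = step_mag[t, sel].mean()
        out.append(
            LabeledSequence(
                features=feats,
                label=ev.command_type,
                trial_id=f"{video_id}:trial{ev.trial_index}",
            )
        )
    return out


def make_separable_dataset(
    n_per_class: int = 25,
    t_len: int = 50,
    n_channels: int = 12,
    noise_sd: float = 0.05,
    signal: float = 1.0,
    seed: int = 0,
    shuffle_labels: bool = False,
) -> list[LabeledSequence]:
    """Synthetic command-specific sequences, separable by construction.

    Each command activates a disjoint block of ``n_channels // 3``
    channels with a smooth bump at a random time, over Gaussian noise —
    a desk-scale stand-in for command-specific facial movement patterns.
    With ``shuffle_labels=True`` labels are permuted (chance-level
    control).
    """
    rng = np.random.default_rng(seed)
    block = n_channels // 3
    t_ax = np.arange(t_len)
    samples = []
    for ci, cls in enumerate(COMMAND_TYPES):
        for k in range(n_per_class):
            x = rng.normal(0.0, noise_sd, size=(t_len, n_channels))
            center = rng.uniform(0.25, 0.75) * t_len
            width = t_len / 8.0
            bump = signal * np.exp(-0.5 * ((t_ax - center) / width) ** 2)
            amp = rng.uniform(0.8, 1.2)
            x[:, ci * block : (ci + 1) * block] += amp * bump[:, None]
            samples.append(
                LabeledSequence(
                    features=x, label=cls, trial_id=f"synth:{cls}:{k}"
                )
            )
    if shuffle_labels:
        labels = [s.label for s in samples]
        perm = rng.permutation(len(labels))
        for s, j in zip(samples, perm):
            s.label = labels[j]
    return samples


# ---------------------------------------------------------------------------
# balancing and splitting


def balance_with_augmentation(
    dataset: Sequence[LabeledSequence], seed: int = 0, max_shift: int | None = None
) -> list[LabeledSequence]:
    """Equalize class counts with label-preserving transforms.

    Minority-class samples are resampled with a random temporal shift
    (up to ~1 s worth of frames), additive Gaussian feature noise, and
    amplitude scaling in [0.9, 1.1]; augmented copies carry a provenance
    flag.  Call this on the *training* partition only — test sets must
    stay untouched.
    """
    counts = Counter(s.label for s in dataset)
    for cls in COMMAND_TYPES:
        if cls in counts and counts[cls] == 0:
            raise ValueError(f"empty class {cls}")
    if not counts:
        raise ValueError("empty dataset")
    target = max(counts.values())
    rng = np.random.default_rng(seed)
    out = list(dataset)
    for cls, n in counts.items():
        pool = [s for s in dataset if s.label == cls]
        t_len = pool[0].features.shape[0]
        shift_max = max_shift if max_shift is not None else max(1, t_len // 20)
        for j in range(target - n):
            src = pool[rng.integers(len(pool))]
            x = src.features.copy()
            shift = int(rng.integers(-shift_max, shift_max + 1))
            x = np.roll(x, shift, axis=0)
            scale = rng.uniform(0.9, 1.1)
            sd = 0.05 * (x.std() + 1e-12)
            x = scale * x + rng.normal(0.0, sd, size=x.shape)
            out.append(
                LabeledSequence(
                    features=x,
                    label=cls,
                    trial_id=f"{src.trial_id}#aug{j}",
                    augmented=True,
                )
            )
    return out


def split_train_test(
    dataset: Sequence[LabeledSequence], spec: SplitSpec = SplitSpec()
) -> tuple[list[LabeledSequence], list[LabeledSequence]]:
    """Random train/test split, stratified by label, grouped by trial.

    All sequences sharing a source trial id land in the same partition,
    and augmented sequences are assigned to the training side regardless
    of draw.  The same seed reproduces the same split.
    """
    rng = np.random.default_rng(spec.seed)
    base = lambda tid: tid.split("#aug")[0]
    groups: dict[str, list[LabeledSequence]] = {}
    for s in dataset:
        groups.setdefault(base(s.trial_id), []).append(s)

    group_label = {g: members[0].label for g, members in groups.items()}
    if spec.stratified:
        per_label_counts = Counter(group_label.values())
        if any(v < 5 for v in per_label_counts.values()):
            raise ValueError("stratified split needs >=5 trials per class")
        strata = {}
        for g, lab in group_label.items():
            strata.setdefault(lab, []).append(g)
    else:
        strata = {"all": list(groups)}

    train: list[LabeledSequence] = []
    test: list[LabeledSequence] = []
    for gs in strata.values():
        gs = sorted(gs)
        rng.shuffle(gs)
        n_train = int(round(spec.train_fraction * len(gs)))
        for idx, g in enumerate(gs):
            members = groups[g]
            to_train = idx < n_train
            for s in members:
                if to_train:
                    train.append(s)
                elif not s.augmented:
                    test.append(s)
                # augmented copies of a test-side trial are dropped:
                # keeping them in train would leak the held-out trial
    assert not any(s.augmented for s in test)
    return train, test


# ---------------------------------------------------------------------------
# training and evaluation


def _to_arrays(samples: Sequence[LabeledSequence]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.features for s in samples])
    y = np.array([CLASS_INDEX[s.label] for s in samples])
    return x, y


def train_sequence_classifier(
    train: Sequence[LabeledSequence],
    hidden: int = 24,
    epochs: int = 80,
    learning_rate: float = 0.02,
    seed: int = 0,
) -> BiLSTMClassifier:
    """Fit the BiLSTM on a training partition (deterministic per seed)."""
    if len(train) == 0:
        raise ValueError("empty training set")
    x, y = _to_arrays(train)
    cfg = BiLSTMConfig(
        n_channels=x.shape[2],
        n_classes=len(COMMAND_TYPES),
        hidden=hidden,
        epochs=epochs,
        learning_rate=learning_rate,
        seed=seed,
    )
    return BiLSTMClassifier(cfg).fit(x, y)


def evaluate_classifier(
    model: BiLSTMClassifier, test: Sequence[LabeledSequence]
) -> EvalReport:
    """Confusion matrix, per-class and overall accuracy on a test set."""
    if len(test) == 0:
        raise ValueError("empty test set")
    x, y = _to_arrays(test)
    pred = model.predict(x)
    k = len(COMMAND_TYPES)
    conf = np.zeros((k, k), dtype=int)
    for yt, yp in zip(y, pred):
        conf[yt, yp] += 1
    per_class = {}
    for i, cls in enumerate(COMMAND_TYPES):
        row = conf[i].sum()
        per_class[cls] = conf[i, i] / row if row else float("nan")
    return EvalReport(
        classes=list(COMMAND_TYPES),
        confusion=conf,
        per_class_accuracy=per_class,
        overall_accuracy=float(np.trace(conf) / conf.sum()),
    )
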