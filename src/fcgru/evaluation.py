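"""Training loop, metrics and cross-validation protocols.

Two evaluation protocols are supported:

* **subject-dependent** — each subject's samples are split into k folds
  (10 by default); one model is trained per fold, the subject's result
  is the mean over folds, and the grand mean averages over subjects;
* **subject-independent (LOSO)** — leave-one-subject-out: each fold
  trains on all other subjects and tests on the held-out one, with no
  subject overlap between train and test.

An ablation runner re-segments the recordings with 2 s windows sliding
by 0.125 s and evaluates a grid of model variants under 5-fold and LOSO
protocols.

Metrics are accuracy ``(TP+TN)/(TP+FP+TN+FN)`` and the F1 score
``2TP/(2TP+FP+FN)`` with "high" as the positive class.  Training uses
Adam on softmax cross-entropy (defaults: learning rate 0.001, 100
epochs, batch size 200).

Band-power columns of the fused tensors are z-scored per fold using
statistics of the training split only, so the bounded connectivity
columns and unbounded power columns enter the convolutions on a common
scale without information leaking from test data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .datasets import Recording, segment_recording
from .features import sample_to_tensor
from .network import (
    CGRUModel,
    HyperParams,
    ModelVariant,
    build_model,
    cross_entropy_loss,
)

__all__ = [
    "TrainConfig",
    "ConfusionCounts",
    "Metrics",
    "EvalReport",
    "metrics",
    "confusion",
    "train",
    "prepare_features",
    "standardize_bands",
    "run_subject_dependent",
    "run_loso",
    "run_ablation",
]


@dataclass
class TrainConfig:
    """Optimizer settings; defaults follow the reference protocol."""

    learning_rate: float = 0.001
    epochs: int = 100
    batch_size: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be positive")


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class Metrics:
    accuracy: float
    f1: float
    f1_degenerate: bool = False


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Confusion counts with label 1 ("high") as the positive class."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label/prediction length mismatch")
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def metrics(counts: ConfusionCounts) -> Metrics:
    """Accuracy and F1 from confusion counts.

    When no positive labels or predictions exist (2TP+FP+FN = 0) the F1
    is undefined; it is reported as 0 with ``f1_degenerate`` set.
    """
    if counts.total == 0:
        raise ValueError("no evaluated samples")
    acc = (counts.TP + counts.TN) / counts.total
    denom = 2 * counts.TP + counts.FP + counts.FN
    if denom == 0:
        return Metrics(accuracy=acc, f1=0.0, f1_degenerate=True)
    return Metrics(accuracy=acc, f1=2 * counts.TP / denom)


class Adam:
    """Adam optimizer over a model's (params, grads) arrays."""

    def __init__(self, model: CGRUModel, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in model.params]
        self.v = [np.zeros_like(p) for p in model.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.model.params, self.model.grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train(
    model: CGRUModel,
    X: np.ndarray,
    y: np.ndarray,
    cfg: TrainConfig,
) -> list[float]:
    """Train in place; returns the per-epoch mean-loss history.

    One epoch is a full shuffled pass; a batch size exceeding the
    dataset yields a single full-batch step per epoch.  A non-finite
    loss aborts with diagnostics.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int)
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model, cfg.learning_rate)
    history: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo : lo + cfg.batch_size]
            logits = model.forward(X[idx], training=True)
            loss, dlogits = cross_entropy_loss(logits, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss {loss} at epoch {epoch}, batch offset {lo}"
                )
            model.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history


# --------------------------------------------------------------------------
# feature preparation


def prepare_features(
    recordings: list[Recording],
    dimension: str,
    threshold: float,
    window_seconds: float = 1.0,
    step_seconds: float = 1.0,
    subwindow_len: int = 64,
    subwindow_step: int = 16,
    use_plv: bool = True,
    return_trials: bool = False,
) -> dict[str, tuple[np.ndarray, ...]]:
    """Segment, label and featurize recordings.

    Returns ``{subject_id: (X, y)}`` with X of shape
    (n_samples, steps, NC, NC+5) — NC x 5 band-only when ``use_plv`` is
    off — and y the binary labels of ``dimension``.  With
    ``return_trials`` each value is ``(X, y, trials)`` where ``trials``
    holds per-sample source-trial indices (needed for trial-level fold
    splitting).
    """
    out: dict[str, tuple[np.ndarray, ...]] = {}
    for rec in recordings:
        if dimension not in rec.dimension_names:
            raise ValueError(
                f"dimension {dimension!r} not in {rec.dimension_names}"
            )
        samples = segment_recording(rec, window_seconds, step_seconds, threshold)
        X = np.stack(
            [
                sample_to_tensor(
                    s, rec.fs, subwindow_len, subwindow_step, use_plv=use_plv
                ).values
                for s in samples
            ]
        )
        y = np.array([s.labels[dimension] for s in samples], dtype=int)
        if return_trials:
            trials = np.array([s.trial_index for s in samples], dtype=int)
            out[rec.subject_id] = (X, y, trials)
        else:
            out[rec.subject_id] = (X, y)
    return out


def standardize_bands(
    X_train: np.ndarray, *X_other: np.ndarray, n_band_cols: int = 5
) -> tuple[np.ndarray, ...]:
    """Z-score the trailing band columns using training statistics only.

    Statistics are per channel and band, pooled over samples and steps.
    The leading (PLV) columns are left untouched — they are already
    bounded in [0, 1].
    """
    mu = X_train[..., -n_band_cols:].mean(axis=(0, 1), keepdims=True)
    sd = X_train[..., -n_band_cols:].std(axis=(0, 1), keepdims=True)
    sd = np.where(sd < 1e-12, 1.0, sd)

    def apply(X: np.ndarray) -> np.ndarray:
        X = X.copy()
        X[..., -n_band_cols:] = (X[..., -n_band_cols:] - mu) / sd
        return X

    return tuple(apply(X) for X in (X_train, *X_other))


# --------------------------------------------------------------------------
# protocols


@dataclass
class EvalReport:
    """Per-fold and aggregate results of one protocol run."""

    protocol: str
    dimension: str
    folds: list[dict] = field(default_factory=list)
    per_subject: dict[str, dict] = field(default_factory=dict)
    grand_accuracy: float = float("nan")
    grand_f1: float = float("nan")
    accuracy_sd: float = float("nan")
    config: dict = field(default_factory=dict)

    def finalize(self) -> "EvalReport":
        """Aggregate: grand mean = mean of per-subject means."""
        per_subj_acc = {}
        per_subj_f1 = {}
        for f in self.folds:
            per_subj_acc.setdefault(f["subject"], []).append(f["accuracy"])
            per_subj_f1.setdefault(f["subject"], []).append(f["f1"])
        self.per_subject = {
            s: {"accuracy": float(np.mean(a)), "f1": float(np.mean(per_subj_f1[s]))}
            for s, a in sorted(per_subj_acc.items())
        }
        accs = [v["accuracy"] for v in self.per_subject.values()]
        f1s = [v["f1"] for v in self.per_subject.values()]
        self.grand_accuracy = float(np.mean(accs))
        self.grand_f1 = float(np.mean(f1s))
        self.accuracy_sd = float(np.std(accs))
        return self

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(vars(self), indent=2, default=str))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.folds)


def _subseed(root: int, *branch: int) -> np.random.SeedSequence:
    """Documented seed splitter: one stream per (root, branch...) path."""
    return np.random.SeedSequence((root, *branch))


def _fit_eval_fold(
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_te: np.ndarray,
    y_te: np.ndarray,
    variant: ModelVariant,
    hyper: HyperParams,
    train_cfg: TrainConfig,
    fold_seed: np.random.SeedSequence,
) -> Metrics:
    """Standardize, build a fresh model from the fold seed, train, score."""
    X_tr, X_te = standardize_bands(X_tr, X_te)
    init_seed, shuffle_seed = (int(s.generate_state(1)[0] % 2**31)
                               for s in fold_seed.spawn(2))
    model = build_model(X_tr.shape[1:], variant, hyper, seed=init_seed)
    cfg = TrainConfig(
        learning_rate=train_cfg.learning_rate,
        epochs=train_cfg.epochs,
        batch_size=train_cfg.batch_size,
        seed=shuffle_seed,
    )
    train(model, X_tr, y_tr, cfg)
    return metrics(confusion(y_te, model.predict(X_te)))


def run_subject_dependent(
    features_by_subject: dict[str, tuple[np.ndarray, np.ndarray]],
    dimension: str,
    k: int = 10,
    variant: ModelVariant | str = ModelVariant(),
    hyper: HyperParams | None = None,
    train_cfg: TrainConfig | None = None,
    seed: int = 0,
    split_by: str = "sample",
) -> EvalReport:
    """k-fold cross-validation within each subject.

    Folds are stratified by class and shuffled with a subject-derived
    seed; each fold trains a freshly initialized model.  The grand mean
    averages the per-subject means.

    ``split_by="sample"`` follows the reference protocol (folds cut at
    the windowed-sample level).  ``split_by="trial"`` keeps all windows
    of a trial in the same fold — the hygienic choice when windows
    overlap heavily — and requires feature tuples carrying trial
    indices (``prepare_features(..., return_trials=True)``).
    """
    if split_by not in ("sample", "trial"):
        raise ValueError(f"split_by must be 'sample' or 'trial', got {split_by!r}")
    if isinstance(variant, str):
        variant = ModelVariant.named(variant)
    hyper = hyper if hyper is not None else HyperParams()
    train_cfg = train_cfg if train_cfg is not None else TrainConfig()
    if k < 2:
        raise ValueError("need k >= 2 folds")
    report = EvalReport(
        protocol=f"subject-dependent-{k}fold",
        dimension=dimension,
        config={"k": k, "variant": vars(variant), "seed": seed,
                "train": vars(train_cfg)},
    )
    for si, (subject, feats) in enumerate(sorted(features_by_subject.items())):
        X, y = feats[0], feats[1]
        if split_by == "trial" and len(feats) < 3:
            raise ValueError(
                "split_by='trial' needs trial indices; use "
                "prepare_features(..., return_trials=True)"
            )
        counts = np.bincount(y, minlength=2)
        if counts.min() < k:
            warnings.warn(
                f"subject {subject}: class counts {counts.tolist()} < k={k}; "
                "stratification degraded",
                stacklevel=2,
            )
        skf_seed = int(_subseed(seed, si).generate_state(1)[0] % 2**31)
        if split_by == "trial":
            splitter = StratifiedGroupKFold(n_splits=k, shuffle=True,
                                            random_state=skf_seed)
            split_iter = splitter.split(X, y, groups=feats[2])
        else:
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=skf_seed)
            split_iter = skf.split(X, y)
        for fold, (tr, te) in enumerate(split_iter):
            m = _fit_eval_fold(
                X[tr], y[tr], X[te], y[te], variant, hyper, train_cfg,
                _subseed(seed, si, fold),
            )
            report.folds.append(
                {"subject": subject, "fold": fold, "n_test": len(te),
                 "accuracy": m.accuracy, "f1": m.f1,
                 "test_indices_head": te[:5].tolist()}
            )
    return report.finalize()


def run_loso(
    features_by_subject: dict[str, tuple[np.ndarray, np.ndarray]],
    dimension: str,
    variant: ModelVariant | str = ModelVariant(),
    hyper: HyperParams | None = None,
    train_cfg: TrainConfig | None = None,
    seed: int = 0,
) -> EvalReport:
    """Leave-one-subject-out: train on all other subjects, test on one.

    Train and test subject sets are disjoint in every fold; the report
    mean is taken over held-out subjects.
    """
    if isinstance(variant, str):
        variant = ModelVariant.named(variant)
    hyper = hyper if hyper is not None else HyperParams()
    train_cfg = train_cfg if train_cfg is not None else TrainConfig()
    subjects = sorted(features_by_subject)
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    report = EvalReport(
        protocol="loso",
        dimension=dimension,
        config={"variant": vars(variant), "seed": seed, "train": vars(train_cfg)},
    )
    for si, held_out in enumerate(subjects):
        X_te, y_te = features_by_subject[held_out][:2]
        X_tr = np.concatenate(
            [features_by_subject[s][0] for s in subjects if s != held_out]
        )
        y_tr = np.concatenate(
            [features_by_subject[s][1] for s in subjects if s != held_out]
        )
        m = _fit_eval_fold(
            X_tr, y_tr, X_te, y_te, variant, hyper, train_cfg, _subseed(seed, si)
        )
        report.folds.append(
            {"subject": held_out, "fold": si, "n_test": len(y_te),
             "accuracy": m.accuracy, "f1": m.f1,
             "train_subjects": [s for s in subjects if s != held_out]}
        )
    return report.finalize()


def run_ablation(
    recordings: list[Recording],
    dimension: str,
    threshold: float,
    variants: dict[str, ModelVariant] | None = None,
    window_seconds: float = 2.0,
    step_seconds: float = 0.125,
    k: int = 5,
    subwindow_len: int = 64,
    subwindow_step: int = 16,
    hyper: HyperParams | None = None,
    train_cfg: TrainConfig | None = None,
    seed: int = 0,
    protocols: tuple[str, ...] = ("dependent", "loso"),
) -> dict[str, dict[str, EvalReport]]:
    """Evaluate a variant grid after re-segmenting with sliding windows.

    Defaults follow the ablation protocol: 2 s windows moving by 0.125 s,
    5-fold subject-dependent CV plus LOSO.  Returns
    ``{variant_name: {protocol: EvalReport}}``.
    """
    if variants is None:
        variants = {name: ModelVariant.named(name) for name in ModelVariant.NAMED}
    results: dict[str, dict[str, EvalReport]] = {}
    feats_cache: dict[bool, dict] = {}
    for name, variant in variants.items():
        if variant.use_plv not in feats_cache:
            feats_cache[variant.use_plv] = prepare_features(
                recordings, dimension, threshold, window_seconds, step_seconds,
                subwindow_len, subwindow_step, use_plv=variant.use_plv,
            )
        feats = feats_cache[variant.use_plv]
        results[name] = {}
        if "dependent" in protocols:
            results[name]["dependent"] = run_subject_dependent(
                feats, dimension, k, variant, hyper, train_cfg, seed
            )
        if "loso" in protocols:
            results[name]["loso"] = run_loso(
                feats, dimension, variant, hyper, train_cfg, seed
            )
    return results
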