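"""Per-subject scoring, cross-subject aggregation, and ablation runs.

Accuracy is the fraction of test windows whose fused-score argmax equals
the true movement label (no majority voting across windows).  Dataset
accuracy is the arithmetic mean of per-subject accuracies, reported with
the population standard deviation across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .training import TrainConfig, finetune_subject, pretrain
from .estimators import PFNetClassifier
from .windowing import FoldSplit, WindowSet, split_windows


@dataclass
class EvalResult:
    """Accuracies of one model variant under one windowing configuration."""

    per_subject_accuracy: dict
    mean_accuracy: float
    std_accuracy: float
    variant: str
    window_ms: float = None


def evaluate_subject(model: PFNetClassifier, X_test, y_test) -> float:
    """Window-classification accuracy on one subject's test windows.

    Argmax ties (exactly equal top scores) resolve to the lowest class
    index.
    """
    if len(X_test) == 0:
        raise ValueError("empty test set")
    pred = model.predict(np.asarray(X_test, dtype=float))
    return float(np.mean(pred == np.asarray(y_test)))


def aggregate(per_subject: dict, variant: str = None, window_ms=None,
              ddof: int = 0) -> EvalResult:
    """Mean and standard deviation across the per-subject accuracies.

    ``ddof=0`` (population std) by default; pass ``ddof=1`` for the
    sample convention.
    """
    if not per_subject:
        raise ValueError("need at least one subject")
    # fixed (sorted) order so the result is exactly order-invariant
    vals = np.array([per_subject[s] for s in sorted(per_subject)], dtype=float)
    return EvalResult(
        per_subject_accuracy=dict(per_subject),
        mean_accuracy=float(vals.mean()),
        std_accuracy=float(vals.std(ddof=ddof) if len(vals) > 1 else 0.0),
        variant=variant,
        window_ms=window_ms,
    )


def audit_no_leakage(windows_by_subject: dict, split: FoldSplit) -> None:
    """Assert that no window's repetition index sits in both sides of the
    split (and that every window's repetition is assigned a side)."""
    overlap = split.train_repetitions & split.test_repetitions
    if overlap:
        raise AssertionError(f"split is leaky: repetitions {sorted(overlap)}")
    for sid, ws in windows_by_subject.items():
        reps = set(int(r) for r in ws.repetitions())
        unassigned = reps - split.train_repetitions - split.test_repetitions
        if unassigned:
            raise AssertionError(
                f"subject {sid}: repetitions {sorted(unassigned)} belong to "
                "neither the train nor the test side"
            )


def run_intra_subject(
    windows_by_subject: dict,
    split: FoldSplit,
    cfg: TrainConfig,
    variant: str = "full",
    clf_params: dict = None,
    window_ms=None,
) -> EvalResult:
    """Full two-phase protocol for one variant.

    Pre-trains on the pooled training-repetition windows of every
    subject, then fine-tunes and scores one fold per subject.
    """
    audit_no_leakage(windows_by_subject, split)
    train_parts, test_parts = {}, {}
    for sid, ws in windows_by_subject.items():
        train_parts[sid], test_parts[sid] = split_windows(ws, split)
        if len(test_parts[sid]) == 0:
            raise ValueError(f"subject {sid}: split leaves no test windows")
        if len(train_parts[sid]) == 0:
            raise ValueError(f"subject {sid}: split leaves no training windows")

    X_pool = np.concatenate([train_parts[s].stack() for s in train_parts])
    y_pool = np.concatenate([train_parts[s].labels() for s in train_parts])
    params = dict(clf_params or {})
    params["variant"] = variant
    model = PFNetClassifier(**params)
    state = pretrain(model, X_pool, y_pool, cfg)

    per_subject = {}
    for sid in sorted(windows_by_subject):
        fold = finetune_subject(
            state, train_parts[sid].stack(), train_parts[sid].labels(),
            subject_id=sid, cfg=cfg,
        )
        per_subject[sid] = evaluate_subject(
            fold.classifier, test_parts[sid].stack(), test_parts[sid].labels()
        )
    return aggregate(per_subject, variant=variant, window_ms=window_ms)


def run_ablation_suite(
    windows_by_subject: dict,
    split: FoldSplit,
    cfg: TrainConfig,
    variants=("full", "FLonly", "DKonly"),
    clf_params: dict = None,
    window_ms=None,
) -> list:
    """One :class:`EvalResult` per variant under identical splits, seeds
    and training configuration."""
    return [
        run_intra_subject(
            windows_by_subject, split, cfg,
            variant=v, clf_params=clf_params, window_ms=window_ms,
        )
        for v in variants
    ]


def write_results_table(results, path) -> None:
    """Delimited-text table: variant, window_ms, per-subject accuracies,
    mean, std."""
    lines = ["variant,window_ms,subject,accuracy,mean,std"]
    for res in results:
        for sid, acc in sorted(res.per_subject_accuracy.items()):
            lines.append(
                f"{res.variant},{res.window_ms},{sid},{acc:.6f},"
                f"{res.mean_accuracy:.6f},{res.std_accuracy:.6f}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
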