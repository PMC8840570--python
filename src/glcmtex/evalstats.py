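"""Evaluation protocol and statistics.

The reference protocol is repeated stratified two-fold cross-validation: the
samples are randomly split in half (preserving per-class counts), a classifier
is trained on one half and scored on the other, and the split is redrawn many
times (100 by default).  The mean test AUC over repeats is the headline
metric and its standard deviation the variation measure.  Leave-one-out is
available as the optimistic bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

__all__ = [
    "SplitScheme",
    "EvalReport",
    "make_scheme",
    "roc_auc",
    "confusion_metrics",
    "run_protocol",
    "wilcoxon_compare",
]


@dataclass
class SplitScheme:
    """A reproducible evaluation plan: per-repeat train/test index lists."""

    kind: str  # "two-fold" | "leave-one-out"
    splits: list[tuple[np.ndarray, np.ndarray]]
    seed: int | None = None

    @property
    def n_repeats(self) -> int:
        return len(self.splits)


def make_scheme(
    labels: np.ndarray,
    kind: str = "two-fold",
    n_repeats: int = 100,
    seed: int | None = None,
) -> SplitScheme:
    """Build the split plan for a labelled sample set.

    Two-fold: each repeat is an independent stratified random half-split
    (train gets the floor of each class count's half, test the rest, matching
    a 31-train / 32-test split at n=63 with classes 31/32).  Leave-one-out:
    n singleton test sets.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    if kind == "leave-one-out":
        n = labels.size
        splits = [
            (np.delete(np.arange(n), i), np.array([i])) for i in range(n)
        ]
        return SplitScheme(kind=kind, splits=splits, seed=seed)
    if kind != "two-fold":
        raise ValueError(f"unknown scheme kind {kind!r}")
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c} has fewer than 2 samples")
    rng = np.random.default_rng(seed)
    splits = []
    for _ in range(n_repeats):
        train, test = [], []
        for c in classes:
            idx = np.flatnonzero(labels == c)
            perm = rng.permutation(idx)
            half = idx.size // 2
            train.append(perm[:half])
            test.append(perm[half:])
        splits.append((np.sort(np.concatenate(train)), np.sort(np.concatenate(test))))
    return SplitScheme(kind=kind, splits=splits, seed=seed)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: probability a positive outranks a negative, ties at 1/2."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("AUC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def confusion_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) at a probability threshold.

    The positive (malignant) class is label 1; sensitivity is the true
    positive rate and specificity the true negative rate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = (scores >= threshold).astype(int)
    pos = labels == 1
    neg = ~pos
    acc = float((pred == labels).mean())
    sens = float((pred[pos] == 1).mean()) if pos.any() else float("nan")
    spec = float((pred[neg] == 0).mean()) if neg.any() else float("nan")
    return acc, sens, spec


@dataclass
class EvalReport:
    """Per-repeat metrics, their mean/STD, and pooled per-sample probabilities."""

    auc: np.ndarray
    accuracy: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    probabilities: list[np.ndarray] = field(default_factory=list)
    test_indices: list[np.ndarray] = field(default_factory=list)
    skipped: list[int] = field(default_factory=list)

    @property
    def auc_mean(self) -> float:
        return float(np.mean(self.auc))

    @property
    def auc_std(self) -> float:
        return float(np.std(self.auc))

    def summary(self) -> dict:
        return {
            "n_repeats": int(len(self.auc)),
            "auc_mean": self.auc_mean,
            "auc_std": self.auc_std,
            "accuracy_mean": float(np.mean(self.accuracy)),
            "sensitivity_mean": float(np.mean(self.sensitivity)),
            "specificity_mean": float(np.mean(self.specificity)),
        }

    def pooled_probabilities(self, n_samples: int) -> np.ndarray:
        """Mean test-time probability per sample across every repeat it was held out."""
        tot = np.zeros(n_samples)
        cnt = np.zeros(n_samples)
        for probs, idx in zip(self.probabilities, self.test_indices):
            tot[idx] += probs
            cnt[idx] += 1
        with np.errstate(invalid="ignore"):
            return np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)


def run_protocol(
    fit_score,
    labels: np.ndarray,
    scheme: SplitScheme,
    threshold: float = 0.5,
) -> EvalReport:
    """Run the full protocol: fit on each train split, score each test split.

    ``fit_score(train_idx, test_idx) -> probabilities`` returns the positive
    class probability for every test sample.  Folds whose training half
    contains a single class are skipped with a record.
    """
    labels = np.asarray(labels)
    aucs, accs, sens, specs = [], [], [], []
    probs_all, idx_all, skipped = [], [], []
    for r, (train, test) in enumerate(scheme.splits):
        if np.unique(labels[train]).size < 2:
            skipped.append(r)
            continue
        probs = np.asarray(fit_score(train, test), dtype=float)
        idx_all.append(test)
        probs_all.append(probs)
        if np.unique(labels[test]).size < 2:
            skipped.append(r)
            continue
        aucs.append(roc_auc(probs, labels[test]))
        a, se, sp = confusion_metrics(probs, labels[test], threshold)
        accs.append(a)
        sens.append(se)
        specs.append(sp)
    return EvalReport(
        auc=np.asarray(aucs),
        accuracy=np.asarray(accs),
        sensitivity=np.asarray(sens),
        specificity=np.asarray(specs),
        probabilities=probs_all,
        test_indices=idx_all,
        skipped=skipped,
    )


def wilcoxon_compare(probs_a: np.ndarray, probs_b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value between paired probabilities.

    Zero differences are dropped (standard convention); the exact null
    distribution is used for 25 or fewer nonzero pairs, the normal
    approximation with continuity correction above that.
    """
    a = np.asarray(probs_a, dtype=float)
    b = np.asarray(probs_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    diff = a - b
    nz = diff[diff != 0]
    if nz.size == 0:
        raise ValueError("all paired differences are zero; test undefined")
    method = "exact" if nz.size <= 25 else "approx"
    res = sps.wilcoxon(nz, alternative="two-sided", method=method, correction=True)
    return float(res.pvalue)
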