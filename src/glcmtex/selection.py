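"""Adaptive multi-group feature integration (the hybrid model, "MGHM").

The descriptor's features are partitioned into scale groups.  Each group is
ranked by random-forest Gini importance and reduced by forward-stepwise
feature selection (FSFS) with a polynomial-kernel SVM and cross-validated AUC
as the wrapper criterion, yielding a per-group baseline subset and its
left-over complement.  The group whose baseline scores highest seeds a
hierarchical integration: the remaining whole groups, in descending order of
their whole-group AUC, and finally the seed group's complement are each passed
through FSFS against the current baseline.  Because a candidate is kept only
when it strictly improves the mean AUC, the per-level AUC trace is
monotonically non-decreasing and the final set is small.

Two evaluation modes exist (see :mod:`glcmtex.workflow`): ``nested`` re-fits
the whole selection inside each outer training fold (unbiased test AUC);
``paper`` runs selection once on the same repeated splits used for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .evalstats import SplitScheme, roc_auc

__all__ = [
    "FeatureTable",
    "ClassifierConfig",
    "FSFSResult",
    "GroupSplit",
    "DescriptorPool",
    "HierarchicalResult",
    "rank_by_rf_importance",
    "evaluate_feature_set",
    "fsfs",
    "split_group",
    "build_pool",
    "hierarchical_integrate",
    "mghm_select",
]


@dataclass
class FeatureTable:
    """Samples-by-features matrix with binary labels and a feature->group map."""

    matrix: np.ndarray
    labels: np.ndarray
    feature_labels: list[str]
    group_assignment: np.ndarray  # group id per feature column

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        self.group_assignment = np.asarray(self.group_assignment)
        n, p = self.matrix.shape
        if self.labels.size != n:
            raise ValueError("labels length != number of rows")
        if len(self.feature_labels) != p or self.group_assignment.size != p:
            raise ValueError("feature metadata length != number of columns")
        if np.isnan(self.matrix).any():
            raise ValueError("feature matrix contains missing values")
        if np.unique(self.labels).size < 2:
            raise ValueError("both classes must be present")
        if len(set(self.feature_labels)) != p:
            raise ValueError("feature labels must be unique")

    @property
    def groups(self) -> list[int]:
        return sorted(set(int(g) for g in self.group_assignment))

    def group_indices(self, g: int) -> np.ndarray:
        return np.flatnonzero(self.group_assignment == g)


@dataclass
class ClassifierConfig:
    """SVM wrapper configuration.

    The reference classifier is a cubic-polynomial-kernel SVM with
    gamma = 1/(number of variables), coef0 = 0 and tolerance 1e-3.
    Because texture measures live on wildly different scales (probabilities
    versus fourth-order cluster moments), each training fold is z-scored
    before the kernel is applied; the scaler is fit on the training data
    only.  ``epsilon`` is accepted for config compatibility but is an
    SVR-only parameter and has no effect on classification.
    """

    kernel: str = "poly"
    degree: int = 3
    coef0: float = 0.0
    tol: float = 1e-3
    C: float = 1.0
    epsilon: float = 0.1  # inert for classification
    standardize: bool = True
    max_iter: int = 1_000_000  # hard stop against pathological kernels
    seed: int = 0

    def make(self, n_features: int):
        svc = SVC(
            kernel=self.kernel,
            degree=self.degree,
            gamma=1.0 / max(n_features, 1),
            coef0=self.coef0,
            tol=self.tol,
            C=self.C,
            max_iter=self.max_iter,
            random_state=self.seed,
        )
        if not self.standardize:
            return svc
        return make_pipeline(StandardScaler(), svc)


def rank_by_rf_importance(
    table: FeatureTable,
    subset: np.ndarray,
    n_trees: int = 5000,
    seed: int | None = 0,
) -> np.ndarray:
    """Order a feature subset by decreasing random-forest Gini importance.

    Importance is the mean impurity decrease over all splits using the
    feature.  Ties break by original column order; the ordering is
    deterministic at a fixed seed.
    """
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("subset must be nonempty")
    if np.unique(table.labels).size < 2:
        raise ValueError("both classes required for importance ranking")
    rf = RandomForestClassifier(
        n_estimators=n_trees, criterion="gini", random_state=seed, n_jobs=1
    )
    rf.fit(table.matrix[:, subset], table.labels)
    imp = rf.feature_importances_
    order = np.argsort(-imp, kind="stable")  # stable => ties keep column order
    return subset[order]


def evaluate_feature_set(
    table: FeatureTable,
    subset: np.ndarray,
    classifier_cfg: ClassifierConfig,
    scheme: SplitScheme,
) -> tuple[float, float]:
    """Mean and STD of cross-validated test AUC for one feature subset.

    Trains the configured SVM on each training split and scores the matching
    test split with the decision function.  Splits whose training half holds
    one class are skipped.
    """
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        raise ValueError("cannot evaluate an empty feature set")
    X = table.matrix[:, subset]
    y = table.labels
    aucs = []
    for train, test in scheme.splits:
        if np.unique(y[train]).size < 2 or np.unique(y[test]).size < 2:
            continue
        clf = classifier_cfg.make(subset.size)
        clf.fit(X[train], y[train])
        aucs.append(roc_auc(clf.decision_function(X[test]), y[test]))
    if not aucs:
        raise ValueError("no usable splits in scheme")
    return float(np.mean(aucs)), float(np.std(aucs))


@dataclass
class FSFSResult:
    """Outcome of one forward-stepwise pass."""

    selected: np.ndarray  # baseline plus accepted candidates, in order
    accepted: np.ndarray  # the accepted candidates only
    auc_trace: list[float]  # best AUC after each accepted addition
    final_auc: float
    final_std: float


def fsfs(
    table: FeatureTable,
    baseline_idx: np.ndarray,
    candidate_ranked_idx: np.ndarray,
    classifier_cfg: ClassifierConfig,
    scheme: SplitScheme,
    min_improve: float = 0.0,
) -> FSFSResult:
    """Forward-stepwise feature selection over a ranked candidate list.

    A single pass visits candidates from most to least important; a candidate
    is permanently kept iff adding it raises the mean cross-validated AUC of
    the current set by strictly more than ``min_improve``.
    """
    baseline_idx = np.asarray(baseline_idx, dtype=int)
    candidates = [c for c in np.asarray(candidate_ranked_idx, dtype=int)
                  if c not in set(baseline_idx)]
    current = list(baseline_idx)
    if current:
        best_auc, best_std = evaluate_feature_set(
            table, np.asarray(current), classifier_cfg, scheme
        )
    else:
        best_auc, best_std = -np.inf, 0.0
    trace: list[float] = []
    accepted: list[int] = []
    for c in candidates:
        trial = np.asarray(current + [c])
        auc, std = evaluate_feature_set(table, trial, classifier_cfg, scheme)
        if auc > best_auc + min_improve:
            current.append(c)
            accepted.append(c)
            best_auc, best_std = auc, std
            trace.append(auc)
    if not np.isfinite(best_auc):
        # empty baseline and no candidate accepted (empty candidate list)
        best_auc, best_std = float("nan"), float("nan")
    return FSFSResult(
        selected=np.asarray(current, dtype=int),
        accepted=np.asarray(accepted, dtype=int),
        auc_trace=trace,
        final_auc=float(best_auc),
        final_std=float(best_std),
    )


@dataclass
class GroupSplit:
    """A group's FSFS baseline, its complement, and both AUC summaries."""

    group_id: int
    baseline_idx: np.ndarray
    complement_idx: np.ndarray
    group_auc: float
    group_auc_std: float
    baseline_auc: float
    baseline_auc_std: float


def split_group(
    table: FeatureTable,
    group_id: int,
    classifier_cfg: ClassifierConfig,
    scheme: SplitScheme,
    n_trees: int = 5000,
    seed: int | None = 0,
    min_improve: float = 0.0,
) -> GroupSplit:
    """Split one group into its FSFS-optimal baseline and left-over complement."""
    group_idx = table.group_indices(group_id)
    if group_idx.size == 0:
        raise ValueError(f"group {group_id} is empty")
    ranked = rank_by_rf_importance(table, group_idx, n_trees=n_trees, seed=seed)
    res = fsfs(table, np.array([], dtype=int), ranked, classifier_cfg, scheme,
               min_improve=min_improve)
    baseline = res.selected
    complement = np.setdiff1d(group_idx, baseline)
    g_auc, g_std = evaluate_feature_set(table, group_idx, classifier_cfg, scheme)
    return GroupSplit(
        group_id=group_id,
        baseline_idx=baseline,
        complement_idx=complement,
        group_auc=g_auc,
        group_auc_std=g_std,
        baseline_auc=res.final_auc,
        baseline_auc_std=res.final_std,
    )


@dataclass
class PoolEntry:
    indices: np.ndarray
    source: str  # e.g. "D3b", "D2", "D3c"
    role: str  # "initial-baseline" | "whole-group" | "initial-complement"


@dataclass
class DescriptorPool:
    """Ordered queue of candidate feature sets for hierarchical integration."""

    entries: list[PoolEntry]

    def __len__(self) -> int:
        return len(self.entries)


def build_pool(splits: dict[int, GroupSplit]) -> DescriptorPool:
    """Order the candidate sets for integration.

    The group with the highest baseline AUC contributes its baseline first;
    the remaining whole groups follow in descending whole-group AUC; the best
    group's complement closes the pool.  AUC ties break toward the larger
    group, then the smaller group id.
    """
    def tie_key(gs: GroupSplit, auc: float):
        return (-auc, -(gs.baseline_idx.size + gs.complement_idx.size), gs.group_id)

    best = min(splits.values(), key=lambda gs: tie_key(gs, gs.baseline_auc))
    rest = [gs for gs in splits.values() if gs.group_id != best.group_id]
    rest.sort(key=lambda gs: tie_key(gs, gs.group_auc))
    entries = [PoolEntry(best.baseline_idx, f"D{best.group_id}b", "initial-baseline")]
    for gs in rest:
        whole = np.sort(np.concatenate([gs.baseline_idx, gs.complement_idx]))
        entries.append(PoolEntry(whole, f"D{gs.group_id}", "whole-group"))
    entries.append(
        PoolEntry(best.complement_idx, f"D{best.group_id}c", "initial-complement")
    )
    return DescriptorPool(entries=entries)


@dataclass
class LevelRecord:
    level: int
    baseline_size: int
    candidate_source: str
    accepted: int
    auc_mean: float
    auc_std: float


@dataclass
class HierarchicalResult:
    """Per-level trace of the hierarchical integration and the final set."""

    levels: list[LevelRecord]
    selected: np.ndarray
    final_auc: float
    final_std: float
    pool_order: list[str] = field(default_factory=list)


def hierarchical_integrate(
    table: FeatureTable,
    pool: DescriptorPool,
    classifier_cfg: ClassifierConfig,
    scheme: SplitScheme,
    n_trees: int = 5000,
    seed: int | None = 0,
    min_improve: float = 0.0,
) -> HierarchicalResult:
    """Bottom-up hierarchical integration over the descriptor pool.

    Level 1 evaluates the pool's initial baseline; each later level ranks the
    next candidate set by random-forest importance and runs FSFS against the
    current baseline.  A level that keeps nothing advances with an unchanged
    baseline, so the per-level mean AUC never decreases.  With three groups
    there are four levels (two whole groups plus the seed group's complement).
    """
    if len(pool) == 0:
        raise ValueError("empty descriptor pool")
    first = pool.entries[0]
    baseline = np.asarray(first.indices, dtype=int)
    auc, std = evaluate_feature_set(table, baseline, classifier_cfg, scheme)
    levels = [LevelRecord(1, baseline.size, first.source, baseline.size, auc, std)]
    for lvl, entry in enumerate(pool.entries[1:], start=2):
        cand = np.asarray(entry.indices, dtype=int)
        if cand.size:
            ranked = rank_by_rf_importance(table, cand, n_trees=n_trees, seed=seed)
            res = fsfs(table, baseline, ranked, classifier_cfg, scheme,
                       min_improve=min_improve)
            if res.accepted.size:
                baseline = res.selected
                auc, std = res.final_auc, res.final_std
            accepted = int(res.accepted.size)
        else:
            accepted = 0
        levels.append(
            LevelRecord(lvl, baseline.size, entry.source, accepted, auc, std)
        )
    return HierarchicalResult(
        levels=levels,
        selected=baseline,
        final_auc=auc,
        final_std=std,
        pool_order=[e.source for e in pool.entries],
    )


def mghm_select(
    table: FeatureTable,
    classifier_cfg: ClassifierConfig,
    scheme: SplitScheme,
    n_trees: int = 5000,
    seed: int | None = 0,
    min_improve: float = 0.0,
) -> tuple[HierarchicalResult, dict[int, GroupSplit]]:
    """The full two-stage selection: per-group split, pool ordering, hierarchy."""
    splits = {
        g: split_group(table, g, classifier_cfg, scheme, n_trees=n_trees, seed=seed,
                       min_improve=min_improve)
        for g in table.groups
    }
    pool = build_pool(splits)
    result = hierarchical_integrate(
        table, pool, classifier_cfg, scheme, n_trees=n_trees, seed=seed,
        min_improve=min_improve
    )
    return result, splits
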