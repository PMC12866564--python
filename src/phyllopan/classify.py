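"""Leaf vs non-leaf classification harness.

Evaluation design for predicting isolation origin from orthogroup
gene-count features: repeated stratified k-fold cross-validation gives
the within-panel reference accuracy, and leave-one-genus-out (LOGO)
cross-validation tests whether a signature generalizes across taxonomy
— the comparison that exposes genus-confounded signals. Learners are
pluggable behind a small fit/score contract (random forest and linear
max-margin references from scikit-learn); folds, metrics and
permutation feature importance are implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.svm import SVC

from . import stats
from .io_formats import MetadataTable, OrthogroupMatrix


@dataclass(frozen=True)
class CVConfig:
    n_splits: int = 5
    n_repeats: int = 10
    seed: int = 0
    classifier: str = "rf"
    top_k_features: int = 100
    #: feature transform: raw counts, binary presence, or log1p
    transform: str = "counts"

    def __post_init__(self) -> None:
        if self.n_splits < 2:
            raise ValueError("need at least 2 splits")
        if self.transform not in ("counts", "presence", "log1p"):
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class LogoResult:
    held_out_group: str
    accuracy: float
    auc: float | None
    roc_points: np.ndarray | None
    n_test: int


CLASSIFIER_REGISTRY = {}


def register_classifier(name: str):
    def deco(factory):
        CLASSIFIER_REGISTRY[name] = factory
        return factory
    return deco


@register_classifier("rf")
def _make_rf(seed: int):
    return RandomForestClassifier(n_estimators=100, random_state=seed)


@register_classifier("svm")
def _make_svm(seed: int):
    # linear kernel; decision_function supplies ranking scores for ROC
    return SVC(kernel="linear", random_state=seed)


def make_classifier(name: str, seed: int):
    if name not in CLASSIFIER_REGISTRY:
        raise ValueError(
            f"unknown classifier {name!r}; registered: {sorted(CLASSIFIER_REGISTRY)}"
        )
    return CLASSIFIER_REGISTRY[name](seed)


def make_labels(metadata: MetadataTable, target_source: str = "leaf",
                isolates: list[str] | None = None) -> np.ndarray:
    """Binary labels: 1 iff the isolate's source equals the target."""
    sources = metadata.table["source"]
    if isolates is not None:
        sources = sources.reindex(isolates)
        if sources.isna().any():
            raise ValueError("isolate(s) missing from metadata")
    return (sources == target_source).to_numpy().astype(int)


def feature_matrix(matrix: OrthogroupMatrix, cfg: CVConfig) -> np.ndarray:
    X = matrix.counts.to_numpy(dtype=float)
    if cfg.transform == "presence":
        return (X > 0).astype(float)
    if cfg.transform == "log1p":
        return np.log1p(X)
    return X


def _scores(model, X: np.ndarray) -> np.ndarray:
    """Real-valued ranking scores for ROC (probability of class 1 when
    available, decision function otherwise). A model fitted on a single
    class has no ranking and yields constant scores."""
    classes = getattr(model, "classes_", None)
    if classes is not None and len(classes) < 2:
        return np.full(X.shape[0], 0.5)
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def repeated_stratified_cv(X: np.ndarray, y: np.ndarray, cfg: CVConfig
                           ) -> tuple[float, float, pd.DataFrame]:
    """Mean accuracy, SD over all folds, and the per-fold table.

    Folds preserve class proportions to within one item; results are
    fully determined by the config seed.
    """
    y = np.asarray(y)
    counts = np.bincount(y, minlength=2)
    if counts.min() < cfg.n_splits:
        raise ValueError(
            f"smallest class has {counts.min()} members < n_splits="
            f"{cfg.n_splits}; use a smaller k"
        )
    splitter = RepeatedStratifiedKFold(
        n_splits=cfg.n_splits, n_repeats=cfg.n_repeats, random_state=cfg.seed
    )
    rows = []
    for fold, (train, test) in enumerate(splitter.split(X, y)):
        model = make_classifier(cfg.classifier, cfg.seed)
        model.fit(X[train], y[train])
        acc = float((model.predict(X[test]) == y[test]).mean())
        rows.append({"fold": fold, "n_test": len(test), "accuracy": acc})
    table = pd.DataFrame(rows)
    return float(table["accuracy"].mean()), float(table["accuracy"].std(ddof=1)), table


def logo_cv(X: np.ndarray, y: np.ndarray, groups, cfg: CVConfig
            ) -> tuple[list[LogoResult], float, float]:
    """Leave-one-group-out cross-validation over taxonomic groups.

    Each group (genus) is held out once as the test set; the remaining
    groups train the model. AUC is reported as missing when the held-out
    test set contains a single class.
    """
    y = np.asarray(y)
    groups = np.asarray(groups)
    unique_groups = list(dict.fromkeys(groups))
    if len(unique_groups) < 2:
        raise ValueError("LOGO needs at least two groups")
    results: list[LogoResult] = []
    for group in unique_groups:
        test_mask = groups == group
        train_mask = ~test_mask
        assert not (set(np.where(test_mask)[0]) & set(np.where(train_mask)[0]))
        model = make_classifier(cfg.classifier, cfg.seed)
        model.fit(X[train_mask], y[train_mask])
        pred = model.predict(X[test_mask])
        acc = float((pred == y[test_mask]).mean())
        if len(np.unique(y[test_mask])) == 2:
            auc, roc_points = stats.roc_auc(_scores(model, X[test_mask]),
                                            y[test_mask])
        else:
            auc, roc_points = None, None
        results.append(LogoResult(
            held_out_group=str(group), accuracy=acc, auc=auc,
            roc_points=roc_points, n_test=int(test_mask.sum()),
        ))
    accs = np.array([r.accuracy for r in results])
    sd = float(accs.std(ddof=1)) if len(accs) > 1 else 0.0
    return results, float(accs.mean()), sd


def permutation_importance(model, X_test: np.ndarray, y_test: np.ndarray,
                           feature_ids: list[str] | None = None,
                           n_perm: int = 20, seed: int = 0,
                           top_k: int | None = None) -> pd.DataFrame:
    """Model-agnostic permutation feature importance.

    Importance of a feature is the mean drop in test accuracy over
    ``n_perm`` independent within-column shuffles. Deterministic given
    the seed; ties in the ranking are broken by feature id.
    """
    rng = np.random.default_rng(seed)
    y_test = np.asarray(y_test)
    base = float((model.predict(X_test) == y_test).mean())
    n_features = X_test.shape[1]
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(n_features)]
    importances = np.zeros(n_features)
    work = X_test.copy()
    for j in range(n_features):
        original = work[:, j].copy()
        if np.all(original == original[0]):
            continue  # constant feature: permuting changes nothing
        drops = np.empty(n_perm)
        for r in range(n_perm):
            work[:, j] = rng.permutation(original)
            drops[r] = base - float((model.predict(work) == y_test).mean())
        work[:, j] = original
        importances[j] = drops.mean()
    table = pd.DataFrame({"feature": feature_ids, "importance": importances})
    table = table.sort_values(["importance", "feature"],
                              ascending=[False, True], kind="stable",
                              ignore_index=True)
    if top_k is not None:
        table = table.head(top_k).reset_index(drop=True)
    return table
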