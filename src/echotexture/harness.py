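"""Evaluation protocol: stratified 80/20 split, LOOCV on the training
partition, four classifiers with fixed hyperparameters, and an incremental
best-k feature sweep.

Patients are the positive class throughout: sensitivity = TP/(TP+FN) over
patients, specificity = TN/(TN+FP) over controls, all reported as
percentages; AUC is the area under the empirical ROC curve (equivalently
the Mann-Whitney statistic, ties counted 1/2).

The four classifier configurations:

* decision tree — binary CART, ``min_samples_split`` 5, ``max_depth`` 20;
* SVM — RBF kernel, C = 1, numerical tolerance 0.10, z-score
  standardization fit inside each training fold;
* random forest — phase-specific settings: 29 trees / 5 attributes per
  split / depth 8 for the T phase, 28 / 3 / 5 for the R phase;
* AdaBoost — tree (stump) base estimator, 50 estimators, learning rate 0.1.

Splits operate on subjects, never images, so the two cardiac-phase frames
of one subject always land on the same side of the split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "CLASSIFIER_KINDS",
    "ClassifierSpec",
    "default_classifier_specs",
    "SplitPlan",
    "make_split",
    "compute_metrics",
    "loocv_train_eval",
    "feature_sweep",
    "run_full_protocol",
    "ProtocolResult",
]

CLASSIFIER_KINDS = ("decision_tree", "svm_rbf", "random_forest", "adaboost")


@dataclass(frozen=True)
class ClassifierSpec:
    """A classifier kind plus its (phase-resolved) hyperparameters."""

    kind: str
    params: dict = dc_field(default_factory=dict)

    def build(self, seed: int | None = None):
        p = self.params
        if self.kind == "decision_tree":
            return DecisionTreeClassifier(
                min_samples_split=p.get("min_samples_split", 5),
                max_depth=p.get("max_depth", 20),
                random_state=seed,
            )
        if self.kind == "svm_rbf":
            return make_pipeline(
                StandardScaler(),
                SVC(
                    C=p.get("C", 1.0),
                    kernel="rbf",
                    tol=p.get("tol", 0.10),
                ),
            )
        if self.kind == "random_forest":
            return RandomForestClassifier(
                n_estimators=p.get("n_estimators", 28),
                max_features=p.get("max_features", 3),
                max_depth=p.get("max_depth", 5),
                random_state=seed,
            )
        if self.kind == "adaboost":
            return AdaBoostClassifier(
                estimator=DecisionTreeClassifier(max_depth=1),
                n_estimators=p.get("n_estimators", 50),
                learning_rate=p.get("learning_rate", 0.1),
                random_state=seed,
            )
        raise ValueError(f"unknown classifier kind {self.kind!r}")


def default_classifier_specs(phase: str) -> dict[str, ClassifierSpec]:
    """The four classifier configurations for a given cardiac phase
    (random-forest settings differ between the T and R phases)."""
    if phase not in ("R", "T"):
        raise ValueError("phase must be 'R' or 'T'")
    rf = (
        {"n_estimators": 29, "max_features": 5, "max_depth": 8}
        if phase == "T"
        else {"n_estimators": 28, "max_features": 3, "max_depth": 5}
    )
    return {
        "decision_tree": ClassifierSpec("decision_tree"),
        "svm_rbf": ClassifierSpec("svm_rbf"),
        "random_forest": ClassifierSpec("random_forest", rf),
        "adaboost": ClassifierSpec("adaboost"),
    }


# --------------------------------------------------------------------------
# splitting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    """Disjoint train/test subject-id partition with per-class counts."""

    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    train_counts: dict[str, int]
    test_counts: dict[str, int]

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ValueError("train and test subject sets overlap")


def make_split(
    subject_labels: pd.Series,
    train_counts: tuple[int, int],
    seed: int,
) -> SplitPlan:
    """Random per-class draw of ``train_counts = (n_patients, n_controls)``
    training subjects; the remainder is the test partition.  Deterministic
    under ``seed``.  ``subject_labels`` maps subject id -> class (1/0)."""
    rng = np.random.default_rng(seed)
    ids = np.asarray(subject_labels.index)
    labels = subject_labels.to_numpy().astype(int)
    n_pat, n_ctl = train_counts
    pools = {1: ids[labels == 1], 0: ids[labels == 0]}
    wanted = {1: n_pat, 0: n_ctl}
    train: list[str] = []
    for cls in (1, 0):
        pool = np.sort(pools[cls])
        if wanted[cls] > pool.size:
            raise ValueError(
                f"requested {wanted[cls]} training subjects of class {cls} "
                f"but only {pool.size} exist"
            )
        train.extend(rng.choice(pool, size=wanted[cls], replace=False))
    train_set = set(train)
    test = [s for s in ids if s not in train_set]
    if not test:
        warnings.warn("empty test partition", RuntimeWarning, stacklevel=2)
    lab = dict(zip(ids, labels))
    return SplitPlan(
        train_ids=tuple(train),
        test_ids=tuple(test),
        train_counts={
            "patients": int(sum(lab[s] for s in train)),
            "controls": int(sum(1 - lab[s] for s in train)),
        },
        test_counts={
            "patients": int(sum(lab[s] for s in test)),
            "controls": int(sum(1 - lab[s] for s in test)),
        },
    )


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def compute_metrics(y_true, y_pred, scores=None) -> dict[str, float]:
    """Sensitivity / specificity / accuracy (percent, 2 decimals) and AUC.

    ``scores`` are continuous positive-class tendencies; AUC is omitted
    (NaN) when absent.  With a single-class truth vector the undefined rate
    is flagged as NaN rather than 0.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    sens = round(100.0 * tp / (tp + fn), 2) if tp + fn else float("nan")
    spec = round(100.0 * tn / (tn + fp), 2) if tn + fp else float("nan")
    acc = round(100.0 * (tp + tn) / y_true.size, 2)
    if scores is not None and len(np.unique(y_true)) == 2:
        auc = float(roc_auc_score(y_true, np.asarray(scores, dtype=np.float64)))
    else:
        auc = float("nan")
    return {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "auc": auc,
        "tp": tp,
        "fn": fn,
        "tn": tn,
        "fp": fp,
    }


def _positive_scores(model, x: np.ndarray) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(x), dtype=np.float64)
    proba = model.predict_proba(x)
    return np.asarray(proba[:, list(model.classes_).index(1)], dtype=np.float64)


# --------------------------------------------------------------------------
# LOOCV
# --------------------------------------------------------------------------

def loocv_train_eval(
    x: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec,
    seed: int | None = None,
) -> dict[str, float]:
    """Leave-one-out CV on the training partition: n fits, each scoring the
    held-out sample; the n pooled held-out predictions are scored once.

    A degenerate single-class fold falls back to predicting the fold's
    majority (only) class.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y).astype(int)
    n = y.size
    if min(np.sum(y == 1), np.sum(y == 0)) < 2:
        raise ValueError("LOOCV needs at least 2 samples per class")
    preds = np.empty(n, dtype=int)
    scrs = np.empty(n, dtype=np.float64)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        yt = y[mask]
        if len(np.unique(yt)) < 2:
            maj = int(np.bincount(yt).argmax())
            preds[i], scrs[i] = maj, float(maj)
        else:
            model = spec.build(seed)
            model.fit(x[mask], yt)
            preds[i] = int(model.predict(x[i : i + 1])[0])
            scrs[i] = float(_positive_scores(model, x[i : i + 1])[0])
        mask[i] = True
    return compute_metrics(y, preds, scrs)


# --------------------------------------------------------------------------
# feature sweep and full protocol
# --------------------------------------------------------------------------

def feature_sweep(
    x_train: pd.DataFrame,
    y_train: np.ndarray,
    x_test: pd.DataFrame,
    y_test: np.ndarray,
    ranked_features: list[str],
    specs: dict[str, ClassifierSpec],
    k_max: int = 10,
    seed: int | None = None,
    include_loocv: bool = True,
) -> pd.DataFrame:
    """Incremental top-k sweep, k = 1..min(k_max, available features):
    each classifier is evaluated with the k best-ranked features, both by
    LOOCV on the training partition (optional) and by fit-on-train /
    score-on-test.  Returns tidy rows
    (classifier, k, stage, sensitivity, specificity, accuracy, auc).
    """
    if not ranked_features:
        raise ValueError("ranked feature list is empty")
    rows = []
    for k in range(1, min(k_max, len(ranked_features)) + 1):
        feats = ranked_features[:k]
        xtr = x_train[feats].to_numpy(dtype=np.float64)
        xte = x_test[feats].to_numpy(dtype=np.float64)
        for name, spec in specs.items():
            if include_loocv:
                m = loocv_train_eval(xtr, y_train, spec, seed=seed)
                rows.append({"classifier": name, "k": k, "stage": "training", **m})
            model = spec.build(seed)
            model.fit(xtr, y_train)
            m = compute_metrics(
                y_test, model.predict(xte), _positive_scores(model, xte)
            )
            rows.append({"classifier": name, "k": k, "stage": "test", **m})
    return pd.DataFrame(rows)


@dataclass
class ProtocolResult:
    """Everything one phase-pair protocol run produces."""

    split: SplitPlan
    ranked: dict[str, pd.DataFrame]       # phase -> Table-1-style ranking
    screening: dict[str, pd.DataFrame]    # phase -> per-feature screen table
    sweep: dict[str, pd.DataFrame]        # phase -> sweep curve rows
    report: pd.DataFrame                  # Table-3/4-style per-classifier rows
    best: dict[str, dict[str, dict]]      # phase -> classifier -> best-k info


def run_full_protocol(
    tables: dict[str, pd.DataFrame],
    train_counts: tuple[int, int] = (50, 38),
    alpha: float = 0.05,
    relieff_k: int = 5,
    top_n: int = 10,
    k_max: int = 10,
    split_seed: int = 0,
    clf_seed: int = 0,
    include_loocv: bool = True,
) -> ProtocolResult:
    """Run the whole evaluation on per-phase feature tables (keys "R", "T"):
    screen -> Relief-F rank (top ``top_n``) -> subject-level split (shared
    by both phases) -> incremental sweep -> per-classifier report at the
    best k (selected by test accuracy, ties to the smaller k).
    """
    from .screening import rank_best, relieff_scores, screen

    if set(tables) != {"R", "T"}:
        raise ValueError("expected feature tables for phases 'R' and 'T'")
    # one subject-level split shared by both phases
    subj = tables["R"][["subject_id", "class"]].drop_duplicates()
    labels = pd.Series(
        subj["class"].to_numpy(), index=subj["subject_id"].to_numpy()
    )
    split = make_split(labels, train_counts, seed=split_seed)
    for phase in ("R", "T"):
        t_ids = set(tables[phase]["subject_id"])
        if t_ids != set(labels.index):
            raise ValueError("phase tables cover different subject sets")

    ranked, screening_tables, sweeps, best = {}, {}, {}, {}
    report_rows = []
    for phase in ("R", "T"):
        table = tables[phase]
        tr = table[table["subject_id"].isin(split.train_ids)]
        te = table[table["subject_id"].isin(split.test_ids)]
        scr = screen(tr, alpha=alpha)
        scores = relieff_scores(tr, k_neighbors=relieff_k,
                                feature_names=scr.significant)
        rk = rank_best(scores, top_n=top_n)
        ranked[phase] = rk
        screening_tables[phase] = scr.table
        specs = default_classifier_specs(phase)
        sweep = feature_sweep(
            tr, tr["class"].to_numpy(), te, te["class"].to_numpy(),
            rk["Feature"].tolist(), specs, k_max=k_max, seed=clf_seed,
            include_loocv=include_loocv,
        )
        sweeps[phase] = sweep
        best[phase] = {}
        for name in specs:
            sub = sweep[(sweep["classifier"] == name) & (sweep["stage"] == "test")]
            krow = sub.sort_values(["accuracy", "k"], ascending=[False, True]).iloc[0]
            k_best = int(krow["k"])
            best[phase][name] = {"k": k_best, "test_accuracy": float(krow["accuracy"])}
            for stage in ("training", "test") if include_loocv else ("test",):
                srow = sweep[
                    (sweep["classifier"] == name)
                    & (sweep["stage"] == stage)
                    & (sweep["k"] == k_best)
                ].iloc[0]
                report_rows.append(
                    {
                        "phase": phase,
                        "classifier": name,
                        "stage": stage,
                        "k": k_best,
                        "sensitivity": srow["sensitivity"],
                        "specificity": srow["specificity"],
                        "accuracy": srow["accuracy"],
                        "auc": round(float(srow["auc"]), 3),
                    }
                )
    return ProtocolResult(
        split=split,
        ranked=ranked,
        screening=screening_tables,
        sweep=sweeps,
        report=pd.DataFrame(report_rows),
        best=best,
    )
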