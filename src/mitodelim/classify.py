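"""Cross-validated classification of encoded alignments and site importance.

Three supervised models — random forest, RBF-kernel support vector machine,
and a single-hidden-layer multilayer perceptron trained by stochastic
gradient descent on the log-loss — are fitted to the ordinal-encoded
alignment (samples × columns, entries 0–4) and evaluated by stratified
5-fold cross-validation with precision, recall, F1, ROC/AUC and a summed
confusion matrix.

Per-site importance comes from a random forest fitted on *all* samples:
the normalised mean impurity decrease attributable to each alignment
column.  Key sites are the columns whose importance exceeds a threshold
(strict inequality), reported 1-based and sorted by importance.  The
ordinal encoding is kept as-is (no one-hot) — a deliberate, documented
simplification: it imposes an artificial ordering A<T<C<G that the tree
model tolerates well but linear views of the SVM/MLP inherit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .seqio import Alignment, EncodedMatrix

__all__ = [
    "Metrics",
    "CVReport",
    "ImportanceProfile",
    "metrics_from_confusion",
    "roc_auc",
    "train_models",
    "cross_validate",
    "feature_importance",
    "key_sites",
    "logo_data",
]

MODEL_NAMES = ("rf", "svm", "mlp")


@dataclass
class Metrics:
    """Binary confusion counts and the derived scalar metrics."""

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float
    auc: float | None = None


@dataclass
class CVReport:
    """Per-fold metrics, AUC summaries and summed confusion per model."""

    folds: int
    per_fold: dict[str, list[Metrics]]
    mean_auc: dict[str, float]
    sd_auc: dict[str, float]
    confusion: dict[str, np.ndarray]  # [[tn, fp], [fn, tp]]
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for model, metrics in self.per_fold.items():
            for fold, m in enumerate(metrics):
                rows.append(
                    {
                        "model": model,
                        "fold": fold,
                        "tp": m.tp,
                        "fp": m.fp,
                        "fn": m.fn,
                        "tn": m.tn,
                        "precision": m.precision,
                        "recall": m.recall,
                        "f1": m.f1,
                        "auc": m.auc,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class ImportanceProfile:
    """Per-alignment-column importance weights from the fitted forest."""

    importance: np.ndarray
    column_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.importance = np.asarray(self.importance, dtype=float)
        if self.column_index is None:
            self.column_index = np.arange(1, self.importance.size + 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"column": self.column_index, "importance": self.importance}
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _safe_div(num: float, den: float) -> float:
    return num / den if den else 0.0


def metrics_from_confusion(tp: int, fp: int, fn: int, tn: int) -> Metrics:
    """Precision, recall and F1 from binary confusion counts.

    Zero-denominator cases (no predicted positives, no actual positives,
    precision + recall == 0) return 0 by convention.
    """
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp == fp == fn == tn == 0:
        warnings.warn("all confusion counts are zero", stacklevel=2)
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    return Metrics(tp=tp, fp=fp, fn=fn, tn=tn,
                   precision=precision, recall=recall, f1=f1)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve for binary labels and class-1 scores.

    Equivalent to the normalised Mann–Whitney U statistic; tied scores
    contribute 1/2 per positive–negative pair.
    """
    y = np.asarray(labels)
    if np.unique(y).size != 2:
        raise ValueError("roc_auc requires both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def _make_models(seed: int, n_trees: int = 500, mlp_hidden: int = 100):
    return {
        "rf": RandomForestClassifier(
            n_estimators=n_trees, max_features="sqrt", random_state=seed
        ),
        "svm": SVC(
            kernel="rbf", probability=True, random_state=seed
        ),
        "mlp": MLPClassifier(
            hidden_layer_sizes=(mlp_hidden,),
            solver="sgd",
            learning_rate="adaptive",
            max_iter=3000,
            random_state=seed,
        ),
    }


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, EncodedMatrix):
        return np.asarray(x.values, dtype=float)
    return np.asarray(x, dtype=float)


def _as_binary(y) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(
            f"binary labels required, got {classes.size} classes"
        )
    return (y == classes[1]).astype(int)


def train_models(x, y, seed: int = 0) -> dict:
    """Fit RF, SVM and MLP on the full data; all randomness seeded."""
    xm, yb = _as_matrix(x), _as_binary(y)
    for c in (0, 1):
        if (yb == c).sum() < 2:
            raise ValueError("need at least 2 samples per class")
    models = _make_models(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter
        for model in models.values():
            model.fit(xm, yb)
    return models


def cross_validate(x, y, folds: int = 5, seed: int = 0) -> CVReport:
    """Stratified k-fold cross-validation of the three models.

    Folds are stratified by class so that imbalanced datasets (e.g. 65/30)
    cannot produce single-class test splits; every sample is tested exactly
    once.  The report is a pure function of (x, y, folds, seed).
    """
    xm, yb = _as_matrix(x), _as_binary(y)
    if xm.shape[0] < folds:
        raise ValueError("fewer samples than folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    per_fold: dict[str, list[Metrics]] = {m: [] for m in MODEL_NAMES}
    aucs: dict[str, list[float]] = {m: [] for m in MODEL_NAMES}
    confusion = {m: np.zeros((2, 2), dtype=int) for m in MODEL_NAMES}
    for train_idx, test_idx in skf.split(xm, yb):
        if np.unique(yb[train_idx]).size < 2:
            raise ValueError(
                "single-class training split; adjust folds or seed"
            )
        models = _make_models(seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for name, model in models.items():
                model.fit(xm[train_idx], yb[train_idx])
                prob = model.predict_proba(xm[test_idx])[:, 1]
                pred = (prob >= 0.5).astype(int)
                truth = yb[test_idx]
                tp = int(((pred == 1) & (truth == 1)).sum())
                fp = int(((pred == 1) & (truth == 0)).sum())
                fn = int(((pred == 0) & (truth == 1)).sum())
                tn = int(((pred == 0) & (truth == 0)).sum())
                m = metrics_from_confusion(tp, fp, fn, tn)
                m.auc = (
                    roc_auc(prob, truth)
                    if np.unique(truth).size == 2
                    else None
                )
                per_fold[name].append(m)
                if m.auc is not None:
                    aucs[name].append(m.auc)
                confusion[name] += np.array([[tn, fp], [fn, tp]])
    mean_auc = {m: float(np.mean(v)) for m, v in aucs.items()}
    sd_auc = {m: float(np.std(v)) for m, v in aucs.items()}
    return CVReport(
        folds=folds,
        per_fold=per_fold,
        mean_auc=mean_auc,
        sd_auc=sd_auc,
        confusion=confusion,
        seed=seed,
    )


def feature_importance(x, y, seed: int = 0, n_trees: int = 500) -> ImportanceProfile:
    """Impurity-decrease importance per column from an all-sample forest.

    The forest is fitted on every sample (no held-out split) — importance
    extraction is descriptive, not predictive.  Weights are non-negative
    and normalised to sum 1; a constant matrix yields all zeros with a
    warning.
    """
    xm, yb = _as_matrix(x), _as_binary(y)
    rf = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", random_state=seed
    ).fit(xm, yb)
    imp = rf.feature_importances_.copy()
    if imp.sum() == 0:
        warnings.warn("no informative columns: all importances zero",
                      stacklevel=2)
    return ImportanceProfile(importance=imp)


def key_sites(
    profile: ImportanceProfile, thresholds=(0.0, 0.1)
) -> dict[float, tuple[int, list[int]]]:
    """Columns with importance strictly above each threshold.

    Returns {threshold: (count, 1-based columns sorted by importance
    descending)}.
    """
    order = np.argsort(-profile.importance, kind="stable")
    out: dict[float, tuple[int, list[int]]] = {}
    for t in thresholds:
        cols = [
            int(profile.column_index[i])
            for i in order
            if profile.importance[i] > t
        ]
        out[float(t)] = (len(cols), cols)
    return out


def logo_data(aln: Alignment, profile: ImportanceProfile) -> pd.DataFrame:
    """Per-column A/C/G/T/gap frequencies plus the importance track.

    One row per alignment column (1-based); base frequencies sum to 1
    (ambiguity codes pooled into the gap/other bin).  The frame is directly
    consumable by sequence-logo renderers.
    """
    if profile.importance.size != aln.length:
        raise ValueError("importance profile length != alignment columns")
    counts = {b: np.zeros(aln.length) for b in "ACGT"}
    other = np.zeros(aln.length)
    for seq in aln.seqs:
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        claimed = np.zeros(aln.length, dtype=bool)
        for b in "ACGT":
            hit = arr == ord(b)
            counts[b] += hit
            claimed |= hit
        other += ~claimed
    n = float(aln.n)
    frame = pd.DataFrame(
        {
            "column": np.arange(1, aln.length + 1),
            **{b: counts[b] / n for b in "ACGT"},
            "gap": other / n,
            "importance": profile.importance,
        }
    )
    return frame
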