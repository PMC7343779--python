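"""PCA feature filtering, classifier selection and diagnostic evaluation.

The protocol uses three disjoint cohorts: a *selection* cohort on which
features are filtered by PCA and the best of seven supervised models is
chosen by majority vote over many repeated stratified ten-fold
cross-validation runs; a *training* cohort on which the winning model is
fitted; and a *test* cohort providing the unbiased confusion matrix and
derived accuracy metrics.

Model zoo (fixed precedence order, used to break accuracy ties):
KNN, SVM, elastic-net logistic regression (EN), logistic regression (LR),
random forest (RF), Gaussian naive Bayes (GNB), linear discriminant
analysis (LDA).  All models operate on z-scored features with the scaling
statistics learned on the training folds only.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from cortexdti.errors import (
    ParameterError,
    StratificationError,
    UnknownModelError,
    UnseenClassError,
)

#: fixed diagnostic class order for confusion matrices
CLASS_ORDER = ("HS", "svPPA", "bvFTD", "nfvPPA")

#: fixed model listing/precedence order
MODEL_ORDER = ("KNN", "SVM", "EN", "LR", "RF", "GNB", "LDA")

FTD_SUBTYPES = ("bvFTD", "svPPA", "nfvPPA")


@dataclasses.dataclass
class SelectionResult:
    """Outcome of repeated-CV classifier selection."""

    winner: str
    win_counts: dict[str, int]
    n_runs: int
    k_folds: int
    master_seed: int


@dataclasses.dataclass
class MetricReport:
    """Accuracy metrics derived from a confusion matrix.

    All values are percentages in [0, 100]; ``None`` marks a metric whose
    denominator (a row or column sum) was zero.  ``per_class`` maps each
    class to sensitivity (column-normalised recall), specificity,
    ppv (row-normalised precision), npv, and the false-discovery rate in
    both conventions: ``fdr_row = 100 - ppv`` and
    ``fdr_col = 100 - sensitivity``.
    """

    accuracy: float
    per_class: dict[str, dict[str, float | None]]
    positive_class: str | None = None
    binary: dict[str, float | None] | None = None


def make_model(name: str, random_state: int = 0) -> Pipeline:
    """Instantiate a zoo model as a z-scoring pipeline."""
    estimators = {
        "KNN": lambda: KNeighborsClassifier(n_neighbors=5),
        "SVM": lambda: SVC(kernel="rbf", gamma="scale"),
        "EN": lambda: LogisticRegression(
            solver="saga", l1_ratio=0.5,
            max_iter=5_000, random_state=random_state,
        ),
        "LR": lambda: LogisticRegression(max_iter=10_000, random_state=random_state),
        "RF": lambda: RandomForestClassifier(
            n_estimators=100, random_state=random_state
        ),
        "GNB": lambda: GaussianNB(),
        "LDA": lambda: LinearDiscriminantAnalysis(),
    }
    if name not in estimators:
        raise UnknownModelError(
            f"unknown model {name!r}; choose from {list(estimators)}"
        )
    return Pipeline([("scale", StandardScaler()), ("clf", estimators[name]())])


def binarize_diagnosis(diagnosis: pd.Series) -> pd.Series:
    """Collapse FTD subtypes into a single 'FTD' label (HS unchanged)."""
    return diagnosis.where(~diagnosis.isin(FTD_SUBTYPES), "FTD")


def pca_filter(
    features: pd.DataFrame,
    retention: str = "kaiser",
    n_components: int | None = None,
    loading_threshold: float = 0.5,
) -> list[str]:
    """Select features by PCA loadings, as a filter method.

    Features are z-scored; principal components of the correlation matrix
    are retained by the Kaiser rule (eigenvalue > 1, default) or as a
    fixed ``n_components``.  A feature is selected when the absolute value
    of its loading (eigenvector scaled by the component's singular
    standard deviation) on any retained component reaches
    ``loading_threshold``.  Constant features are dropped with a warning
    before the PCA.  The returned names preserve the input column order;
    if no loading reaches the threshold, the single feature with the
    largest absolute loading on the retained components is returned so the
    filter never yields an empty set.
    """
    if retention not in ("kaiser", "n_components"):
        raise ParameterError(f"unknown retention rule {retention!r}")
    if retention == "n_components" and not n_components:
        raise ParameterError("n_components retention requires n_components")
    X = features.to_numpy(dtype=float)
    if X.shape[1] < 2 or X.shape[0] <= 2:
        raise ParameterError("PCA filter needs >= 2 features and > 2 samples")
    sd = X.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        dropped = [c for c, bad in zip(features.columns, constant) if bad]
        warnings.warn(f"dropping constant features before PCA: {dropped}", stacklevel=2)
    cols = [c for c, bad in zip(features.columns, constant) if not bad]
    Z = (X[:, ~constant] - X[:, ~constant].mean(axis=0)) / sd[~constant]
    corr = np.corrcoef(Z, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if retention == "kaiser":
        keep = evals > 1.0
        if not keep.any():
            keep[0] = True
    else:
        keep = np.zeros(len(evals), dtype=bool)
        keep[: min(n_components, len(evals))] = True
    loadings = evecs[:, keep] * np.sqrt(np.maximum(evals[keep], 0.0))
    max_abs = np.abs(loadings).max(axis=1)
    selected = [c for c, m in zip(cols, max_abs) if m >= loading_threshold]
    if not selected:
        selected = [cols[int(np.argmax(max_abs))]]
    return selected


def _check_cohort(cohort: pd.DataFrame, features: list[str], label_col: str) -> None:
    missing = [f for f in features if f not in cohort.columns]
    if missing:
        raise ParameterError(f"cohort lacks feature columns: {missing}")
    if cohort[features].isna().any().any():
        raise ParameterError("cohort contains missing feature values; impute explicitly first")
    if label_col not in cohort.columns:
        raise ParameterError(f"cohort lacks label column {label_col!r}")


def select_classifier(
    cohort: pd.DataFrame,
    features: list[str],
    label_col: str = "diagnosis",
    n_runs: int = 1000,
    k_folds: int = 10,
    master_seed: int = 0,
    models: tuple[str, ...] = MODEL_ORDER,
) -> SelectionResult:
    """Choose the best model by majority vote over repeated CV runs.

    Each run re-shuffles a stratified ``k_folds``-fold split (seeded by
    ``master_seed`` + run index), scores every zoo model by mean held-out
    fold accuracy, and awards the run to the top scorer; accuracy ties go
    to the model listed earlier in ``models``.  The overall winner is the
    model with the most run wins; win counts always sum to ``n_runs``.
    """
    if n_runs < 1:
        raise ParameterError("n_runs must be >= 1")
    if k_folds < 2:
        raise ParameterError("k_folds must be >= 2")
    _check_cohort(cohort, features, label_col)
    y = cohort[label_col].to_numpy()
    class_counts = pd.Series(y).value_counts()
    if (class_counts < k_folds).any():
        small = class_counts[class_counts < k_folds].index.tolist()
        raise StratificationError(
            f"classes {small} have fewer members than k_folds={k_folds}"
        )
    X = cohort[features].to_numpy(dtype=float)
    templates = {m: make_model(m) for m in models}

    wins = {m: 0 for m in models}
    for run in range(n_runs):
        rs = int((master_seed + run) % (2**31 - 1))
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=rs)
        folds = list(skf.split(X, y))
        best_model, best_acc = None, -1.0
        for m in models:
            accs = []
            for tr, te in folds:
                est = clone(templates[m])
                if "random_state" in est.named_steps["clf"].get_params():
                    est.named_steps["clf"].set_params(random_state=rs)
                est.fit(X[tr], y[tr])
                accs.append(float((est.predict(X[te]) == y[te]).mean()))
            acc = float(np.mean(accs))
            if acc > best_acc + 1e-12:
                best_model, best_acc = m, acc
        wins[best_model] += 1
    winner = max(models, key=lambda m: wins[m])
    return SelectionResult(
        winner=winner, win_counts=wins, n_runs=n_runs,
        k_folds=k_folds, master_seed=master_seed,
    )


def _class_order(labels: np.ndarray) -> list[str]:
    present = set(labels)
    ordered = [c for c in CLASS_ORDER if c in present]
    ordered += sorted(present - set(ordered))
    return ordered


def train_and_evaluate(
    train: pd.DataFrame,
    test: pd.DataFrame,
    model_name: str,
    features: list[str],
    label_col: str = "diagnosis",
    seed: int = 0,
    positive_class: str | None = None,
) -> tuple[pd.DataFrame, MetricReport]:
    """Fit on the training cohort, evaluate on the test cohort.

    Feature standardisation statistics come from the training cohort only
    (the pipeline's scaler is fitted inside ``fit``).  Returns the
    confusion counts (rows = predicted class, columns = true class, fixed
    class order) and the derived :class:`MetricReport`.
    """
    _check_cohort(train, features, label_col)
    _check_cohort(test, features, label_col)
    train_classes = set(train[label_col])
    unseen = set(test[label_col]) - train_classes
    if unseen:
        raise UnseenClassError(f"test classes absent from training data: {sorted(unseen)}")
    model = make_model(model_name, random_state=seed)
    model.fit(train[features].to_numpy(dtype=float), train[label_col].to_numpy())
    pred = model.predict(test[features].to_numpy(dtype=float))
    truth = test[label_col].to_numpy()
    order = _class_order(np.concatenate([truth, np.asarray(list(train_classes))]))
    counts = pd.DataFrame(0, index=order, columns=order, dtype=int)
    for p, t in zip(pred, truth):
        counts.loc[p, t] += 1
    report = confusion_metrics(counts, positive_class=positive_class)
    return counts, report


def confusion_metrics(
    counts: pd.DataFrame | np.ndarray,
    class_names: list[str] | None = None,
    positive_class: str | None = None,
) -> MetricReport:
    """Derive accuracy metrics from confusion counts.

    ``counts`` has rows = predicted class, columns = true class.  Overall
    accuracy is ``100 * trace / total``.  Per class: sensitivity (recall)
    normalises the diagonal by the column (true-class) sum, ppv
    (precision) by the row (predicted-class) sum; the false-discovery
    rate is emitted in both conventions (``fdr_row = 100 - ppv``,
    ``fdr_col = 100 - sensitivity``) because published tables are not
    always explicit about which one they print.  A zero row or column sum
    marks the affected metrics ``None`` (undefined) rather than NaN.

    With ``positive_class`` set on a 2x2 table, a binary summary
    ACC/SENS/SPEC/PPV/NPV (percent) is attached.
    """
    if isinstance(counts, pd.DataFrame):
        mat = counts.to_numpy(dtype=float)
        names = list(counts.index)
    else:
        mat = np.asarray(counts, dtype=float)
        if class_names is None:
            class_names = [f"class_{i}" for i in range(mat.shape[0])]
        names = list(class_names)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1] or mat.size == 0:
        raise ParameterError("confusion counts must be a non-empty square matrix")
    if np.any(mat < 0):
        raise ParameterError("confusion counts must be non-negative")

    total = mat.sum()
    accuracy = 100.0 * np.trace(mat) / total

    def ratio(num: float, den: float) -> float | None:
        return None if den == 0 else 100.0 * num / den

    per_class: dict[str, dict[str, float | None]] = {}
    for i, cname in enumerate(names):
        tp = mat[i, i]
        col = mat[:, i].sum()
        row = mat[i, :].sum()
        fp = row - tp
        fn = col - tp
        tn = total - row - col + tp
        sens = ratio(tp, col)
        ppv = ratio(tp, row)
        per_class[cname] = {
            "sensitivity": sens,
            "specificity": ratio(tn, tn + fp),
            "ppv": ppv,
            "npv": ratio(tn, tn + fn),
            "fdr_row": None if ppv is None else 100.0 - ppv,
            "fdr_col": None if sens is None else 100.0 - sens,
        }

    binary = None
    if positive_class is not None:
        if positive_class not in names or len(names) != 2:
            raise ParameterError("positive_class requires a 2x2 table containing that class")
        neg = [c for c in names if c != positive_class][0]
        binary = {
            "ACC": accuracy,
            "SENS": per_class[positive_class]["sensitivity"],
            "SPEC": per_class[neg]["sensitivity"],
            "PPV": per_class[positive_class]["ppv"],
            "NPV": per_class[neg]["ppv"],
        }
    return MetricReport(
        accuracy=float(accuracy),
        per_class=per_class,
        positive_class=positive_class,
        binary=binary,
    )
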