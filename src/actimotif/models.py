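"""Association and classification models on FPC-score biomarkers.

Association: logistic regression of the outcome on all FPC scores plus
covariates, with an L1 (lasso) penalty whose strength is chosen by
subject-grouped cross-validation under the one-standard-error rule;
the selected support is refit unpenalized to report odds ratios, Wald
confidence intervals and p-values.  Day rows are treated as independent
observations.

Classification: leave-one-subject-out cross-validation.  All of a
subject's days are held out together; the trained classifier predicts
each held-out day and the subject-level call is the majority vote of
those daily predictions (ties resolve by the mean predicted case
probability).  Five classifiers are compared: naive Bayes, SVM,
lasso-penalized logistic regression, decision tree and random forest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .biomarkers import BiomarkerTable

__all__ = [
    "AssociationFit",
    "ClassificationReport",
    "fit_association",
    "loso_classify",
    "baseline_classify",
    "loso_splits",
    "majority_vote",
    "default_classifiers",
    "CLASSIFIER_CONFIG",
]

logger = logging.getLogger(__name__)

#: frozen classifier hyperparameters (library defaults unless noted)
CLASSIFIER_CONFIG: dict[str, dict] = {
    "naive_bayes": {},
    "svm": {"kernel": "rbf", "C": 1.0, "probability": True},
    "logistic_lasso": {"l1_ratio": 1.0, "solver": "liblinear", "C": 1.0, "max_iter": 1000},
    "decision_tree": {},
    "random_forest": {"n_estimators": 500},
}


def default_classifiers(seed: int = 0) -> dict[str, object]:
    """The five competing classifiers with frozen hyperparameters.

    The SVM runs on standardized features (margin methods are not
    scale-invariant); the other classifiers see the raw scores.
    """
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler

    return {
        "naive_bayes": GaussianNB(**CLASSIFIER_CONFIG["naive_bayes"]),
        "svm": make_pipeline(StandardScaler(), SVC(random_state=seed, **CLASSIFIER_CONFIG["svm"])),
        "logistic_lasso": LogisticRegression(
            random_state=seed, **CLASSIFIER_CONFIG["logistic_lasso"]
        ),
        "decision_tree": DecisionTreeClassifier(random_state=seed, **CLASSIFIER_CONFIG["decision_tree"]),
        "random_forest": RandomForestClassifier(
            random_state=seed, **CLASSIFIER_CONFIG["random_forest"]
        ),
    }


@dataclass
class AssociationFit:
    """Lasso-selected, unpenalized-refit logistic association model."""

    selected_scores: list[str]
    covariates: list[str]
    dropped_covariates: list[str]
    coefficients: pd.Series
    odds_ratios: pd.Series
    conf_int: pd.DataFrame  # columns ["lower", "upper"], 95% Wald
    p_values: pd.Series
    chosen_penalty: float  # inverse-regularization C at the 1-SE rule
    link: str = "logit"


def _grouped_folds(groups: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Fold id per row; folds never split a subject. Seeded subject shuffle."""
    rng = np.random.default_rng(seed)
    uniq = np.unique(groups)
    perm = rng.permutation(uniq)
    fold_of = {g: i % n_folds for i, g in enumerate(perm)}
    return np.array([fold_of[g] for g in groups])


def _lasso_path_1se(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    penalty_path: np.ndarray,
    seed: int,
    n_folds: int = 5,
) -> float:
    """C at the one-standard-error rule under subject-grouped CV.

    Both validation deviance and misclassification rate are tracked;
    each yields its own 1-SE choice (the strongest penalty within one
    standard error of that loss's best mean), and the stronger of the
    two is returned.  The deviance curve rises sharply on null data
    while the error curve is the sharper guide when real effects exist,
    so taking the more conservative of the two keeps chance columns out
    without losing planted signal.
    """
    from sklearn.metrics import log_loss

    folds = _grouped_folds(groups, n_folds, seed)
    err = np.full((penalty_path.size, n_folds), np.nan)
    dev = np.full((penalty_path.size, n_folds), np.nan)
    for ci, C in enumerate(penalty_path):
        for f in range(n_folds):
            tr = folds != f
            va = ~tr
            if len(np.unique(y[tr])) < 2:
                continue
            clf = LogisticRegression(
                l1_ratio=1.0, solver="liblinear", C=C, max_iter=2000, random_state=seed
            )
            clf.fit(X[tr], y[tr])
            err[ci, f] = float(np.mean(clf.predict(X[va]) != y[va]))
            dev[ci, f] = log_loss(y[va], clf.predict_proba(X[va])[:, 1], labels=[0, 1])
    choices = []
    for losses in (err, dev):
        mean = np.nanmean(losses, axis=1)
        se = np.nanstd(losses, axis=1, ddof=1) / np.sqrt(n_folds)
        best = int(np.nanargmin(mean))
        eligible = np.where(mean <= mean[best] + se[best])[0]
        # penalty_path is ascending in C; the smallest eligible C is the 1-SE choice
        choices.append(float(penalty_path[eligible.min()]))
    return min(choices)


def _drop_separating_covariates(
    frame: pd.DataFrame, cols: list[str], outcome: str
) -> tuple[list[str], list[str]]:
    """Identify binary covariates that perfectly separate the outcome."""
    kept, dropped = [], []
    y = frame[outcome].to_numpy()
    for c in cols:
        x = frame[c].to_numpy()
        levels = np.unique(x)
        if levels.size == 2 and all(np.unique(y[x == lv]).size == 1 for lv in levels) and (
            y[x == levels[0]][0] != y[x == levels[1]][0]
        ):
            dropped.append(c)
            logger.warning("covariate %r perfectly separates the outcome; dropped", c)
        else:
            kept.append(c)
    return kept, dropped


def fit_association(
    table: BiomarkerTable,
    link: str = "logit",
    penalty_path: np.ndarray | None = None,
    seed: int = 0,
    n_folds: int = 5,
) -> AssociationFit:
    """Lasso selection over FPC scores + covariates, then unpenalized refit.

    The lasso penalty is chosen by ``n_folds``-fold cross-validation
    grouped by subject under the one-standard-error rule.  The selected
    score columns, together with all covariates, are refit by plain
    logistic regression to report odds ratios with 95% Wald confidence
    intervals and p-values.  Covariates causing perfect separation in
    the refit are dropped with a warning.
    """
    if link != "logit":
        raise ValueError("only the logit link is supported")
    if table.outcome_col is None:
        raise ValueError("table has no outcome column")
    frame = table.frame
    y = frame[table.outcome_col].to_numpy()
    feature_cols = table.score_cols + table.covariate_cols
    X = frame[feature_cols].to_numpy(dtype=float)
    groups = frame["subject"].to_numpy()
    if penalty_path is None:
        penalty_path = np.logspace(-3, 1.5, 30)
    C = _lasso_path_1se(X, y, groups, np.sort(penalty_path), seed, n_folds)
    lasso = LogisticRegression(
        l1_ratio=1.0, solver="liblinear", C=C, max_iter=2000, random_state=seed
    )
    lasso.fit(X, y)
    support = np.abs(lasso.coef_[0]) > 1e-8
    selected_scores = [c for c, s in zip(feature_cols, support) if s and c in table.score_cols]

    covs, dropped = _drop_separating_covariates(frame, table.covariate_cols, table.outcome_col)

    def _refit(cols: list[str]):
        exog = sm.add_constant(frame[cols].to_numpy(dtype=float), has_constant="add")
        try:
            return sm.Logit(y, exog).fit(disp=0, maxiter=200)
        except Exception:
            try:  # IRLS with capped iterations survives quasi-separation
                return sm.GLM(y, exog, family=sm.families.Binomial()).fit(maxiter=100)
            except Exception:
                return None

    refit_cols = selected_scores + covs
    fit = _refit(refit_cols)
    while covs and (fit is None or np.any(np.abs(fit.params[1:]) >= 30)):
        # quasi-separation: drop the covariate with the wildest coefficient
        if fit is not None:
            cov_pos = [refit_cols.index(c) + 1 for c in covs]
            worst_col = covs[int(np.argmax(np.abs(fit.params[cov_pos])))]
        else:
            worst_col = covs[-1]
        covs.remove(worst_col)
        dropped.append(worst_col)
        logger.warning("covariate %r unstable in refit (separation); dropped", worst_col)
        refit_cols = selected_scores + covs
        fit = _refit(refit_cols)
    if fit is None:
        raise RuntimeError("association refit failed to converge")

    names = ["(intercept)"] + refit_cols
    params = pd.Series(fit.params, index=names)
    ci = pd.DataFrame(fit.conf_int(), index=names, columns=["lower", "upper"])
    return AssociationFit(
        selected_scores=selected_scores,
        covariates=covs,
        dropped_covariates=dropped,
        coefficients=params,
        odds_ratios=np.exp(params),
        conf_int=np.exp(ci),
        p_values=pd.Series(fit.pvalues, index=names),
        chosen_penalty=C,
        link=link,
    )


@dataclass
class ClassificationReport:
    """Subject-level LOSO metrics per classifier."""

    metrics: pd.DataFrame  # rows: classifier; columns accuracy/sensitivity/specificity
    confusion: dict[str, dict[str, int]]  # per classifier: TP/TN/FP/FN
    votes: pd.DataFrame  # per (classifier, subject): case votes, total days, prediction
    feature_cols: list[str] = field(default_factory=list)


def loso_splits(frame: pd.DataFrame) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """(held-out subject, train row indexer, test row indexer) triples."""
    subjects = frame["subject"].unique()
    out = []
    for s in subjects:
        test = (frame["subject"] == s).to_numpy()
        out.append((s, ~test, test))
    return out


def majority_vote(day_predictions: np.ndarray, case_probs: np.ndarray) -> int:
    """Subject call from daily calls: case iff case votes exceed half.

    Even-day ties resolve by the mean predicted case probability >= 0.5.
    """
    votes = int(np.sum(day_predictions == 1))
    n = day_predictions.size
    if 2 * votes > n:
        return 1
    if 2 * votes < n:
        return 0
    return int(np.mean(case_probs) >= 0.5)


def _classify(
    table: BiomarkerTable,
    feature_cols: list[str],
    classifiers: dict[str, object] | None,
    seed: int,
) -> ClassificationReport:
    if table.outcome_col is None:
        raise ValueError("table has no outcome column")
    frame = table.frame
    per_subject_y = frame.groupby("subject")[table.outcome_col].first()
    if per_subject_y[per_subject_y == 1].size < 2 or per_subject_y[per_subject_y == 0].size < 2:
        raise ValueError("need at least 2 subjects per class")
    if classifiers is None:
        classifiers = default_classifiers(seed)
    X = frame[feature_cols].to_numpy(dtype=float)
    y = frame[table.outcome_col].to_numpy()

    vote_rows = []
    confusion = {}
    metric_rows = []
    for name, proto in classifiers.items():
        from sklearn.base import clone

        preds = {}
        for subject, train, test in loso_splits(frame):
            clf = clone(proto)
            clf.fit(X[train], y[train])
            day_pred = clf.predict(X[test])
            if hasattr(clf, "predict_proba"):
                prob = clf.predict_proba(X[test])
                case_prob = prob[:, list(clf.classes_).index(1)] if 1 in clf.classes_ else np.zeros(len(prob))
            else:
                case_prob = day_pred.astype(float)
            preds[subject] = majority_vote(day_pred, case_prob)
            vote_rows.append(
                {
                    "classifier": name,
                    "subject": subject,
                    "case_votes": int(np.sum(day_pred == 1)),
                    "n_days": int(test.sum()),
                    "prediction": preds[subject],
                    "truth": int(per_subject_y[subject]),
                }
            )
        truth = per_subject_y.to_numpy()
        pred = np.array([preds[s] for s in per_subject_y.index])
        tp = int(np.sum((pred == 1) & (truth == 1)))
        tn = int(np.sum((pred == 0) & (truth == 0)))
        fp = int(np.sum((pred == 1) & (truth == 0)))
        fn = int(np.sum((pred == 0) & (truth == 1)))
        confusion[name] = {"TP": tp, "TN": tn, "FP": fp, "FN": fn}
        metric_rows.append(
            {
                "classifier": name,
                "accuracy": (tp + tn) / max(tp + tn + fp + fn, 1),
                "sensitivity": tp / max(tp + fn, 1),
                "specificity": tn / max(tn + fp, 1),
            }
        )
    return ClassificationReport(
        metrics=pd.DataFrame(metric_rows).set_index("classifier"),
        confusion=confusion,
        votes=pd.DataFrame(vote_rows),
        feature_cols=feature_cols,
    )


def loso_classify(
    table: BiomarkerTable,
    classifiers: dict[str, object] | None = None,
    seed: int = 0,
    include_covariates: bool = True,
) -> ClassificationReport:
    """LOSO + majority-vote classification on FPC scores (+ covariates)."""
    cols = table.score_cols + (table.covariate_cols if include_covariates else [])
    return _classify(table, cols, classifiers, seed)


def baseline_classify(
    table: BiomarkerTable,
    classifiers: dict[str, object] | None = None,
    seed: int = 0,
) -> ClassificationReport:
    """Covariates-only baseline with the same LOSO + voting protocol."""
    if not table.covariate_cols:
        raise ValueError("table has no covariates for a baseline model")
    return _classify(table, list(table.covariate_cols), classifiers, seed)
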