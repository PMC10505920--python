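"""Fast Gentle Boosting with decision stumps and text rules files.

Gentle boosting fits one regression stump per round by weighted least
squares.  With symmetric multi-class coding (y_{i,c} = +1 if example i
belongs to class c, else -1) every round selects a single (feature,
threshold) pair shared by all classes and one fitted value per class and
branch — the weighted mean of y_{i,c} within the branch, which is always
in [-1, 1].  Example weights are updated multiplicatively,
w_{i,c} <- w_{i,c} * exp(-y_{i,c} f_c(x_i)), and renormalized per class,
so misclassified examples gain influence.  The final classifier is the
argmax over classes of the summed branch scores.

A trained model serializes to a plain-text rules file, one threshold
rule per line; the rules alone fully determine predictions, so new
datasets can be classified prospectively without retraining.  The file
format is::

    classes: InFocus, OutOfFocus
    IF (Haralick_Contrast > 12.345, [s_gt...], [s_le...])

where the first score vector applies when the feature exceeds the
threshold (strict ``>``) and the second otherwise.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

logger = logging.getLogger(__name__)

DEFAULT_N_ROUNDS = 50

_RULE_RE = re.compile(
    r"^IF\s*\(\s*(?P<feat>[^\s,>]+)\s*>\s*(?P<thr>[-+0-9.eE]+)\s*,"
    r"\s*\[(?P<gt>[^\]]*)\]\s*,\s*\[(?P<le>[^\]]*)\]\s*\)\s*$")


@dataclass
class Rule:
    """One threshold rule: per-class scores for each branch."""

    feature: str
    threshold: float
    scores_gt: np.ndarray  # applied where feature > threshold
    scores_le: np.ndarray  # applied otherwise

    def format(self) -> str:
        gt = ", ".join(f"{v:.12g}" for v in self.scores_gt)
        le = ", ".join(f"{v:.12g}" for v in self.scores_le)
        return f"IF ({self.feature} > {self.threshold:.12g}, [{gt}], [{le}])"


@dataclass
class BoostModel:
    """Ordered rules plus class names; prediction needs nothing else."""

    classes: list[str]
    rules: list[Rule] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)
    n_rounds: int = 0
    seed: int | None = None

    @property
    def used_features(self) -> list[str]:
        seen: list[str] = []
        for r in self.rules:
            if r.feature not in seen:
                seen.append(r.feature)
        return seen


def _as_matrix(data, feature_names: list[str]) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        missing = [f for f in feature_names if f not in data.columns]
        if missing:
            raise KeyError(f"missing feature column(s): {', '.join(missing)}")
        return data[feature_names].to_numpy(dtype=float)
    x = np.asarray(data, dtype=float)
    if x.shape[1] != len(feature_names):
        raise ValueError("feature matrix width does not match feature names")
    return x


def train(features, labels, n_rounds: int = DEFAULT_N_ROUNDS,
          seed: int | None = None,
          feature_names: list[str] | None = None) -> BoostModel:
    """Train a Fast Gentle Boosting stump ensemble.

    Parameters
    ----------
    features
        DataFrame (columns are feature names) or (n, p) array.
    labels
        Class label per example; >= 2 classes with >= 2 examples each.
    n_rounds
        Maximum number of stump rules; training stops early once the
        training error reaches zero.

    Stump search is exhaustive: every feature, every unique observed
    value as a strict-``>`` threshold; the stump minimizing the weighted
    squared error is chosen, ties broken by (error, feature index,
    threshold).
    """
    if isinstance(features, pd.DataFrame):
        feature_names = list(features.columns)
        x = features.to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        if feature_names is None:
            feature_names = [f"f{j}" for j in range(x.shape[1])]
    if np.isnan(x).any():
        raise ValueError("feature matrix contains NaN")
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) < 2:
        raise ValueError("need >= 2 classes")
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 examples")
    if all(np.ptp(x[:, j]) == 0 for j in range(x.shape[1])):
        raise ValueError("no informative split: all features constant")

    n, p = x.shape
    k = len(classes)
    y = np.where(labels[:, None] == np.array(classes)[None, :], 1.0, -1.0)
    w = np.full((n, k), 1.0 / n)
    f_sum = np.zeros((n, k))

    order = np.argsort(x, axis=0, kind="stable")
    xs = np.take_along_axis(x, order, axis=0)

    model = BoostModel(classes=classes, feature_names=feature_names,
                       n_rounds=n_rounds, seed=seed)
    for _ in range(n_rounds):
        best = None  # (error, j, threshold, a, b)
        for j in range(p):
            idx = order[:, j]
            v = xs[:, j]
            # boundary after the last occurrence of each unique value
            bnd = np.nonzero(np.r_[v[:-1] != v[1:], True])[0]
            cw = np.cumsum(w[idx], axis=0)[bnd]          # (m, k) left sums
            cwy = np.cumsum((w * y)[idx], axis=0)[bnd]
            w_tot = cw[-1]
            s_tot = cwy[-1]
            w_gt = w_tot[None, :] - cw
            s_gt = s_tot[None, :] - cwy
            with np.errstate(divide="ignore", invalid="ignore"):
                gain_le = np.where(cw > 0, cwy ** 2 / cw, 0.0)
                gain_gt = np.where(w_gt > 0, s_gt ** 2 / w_gt, 0.0)
            err = w_tot.sum() - (gain_le + gain_gt).sum(axis=1)
            i = int(np.argmin(err))  # first minimum -> smallest threshold
            if best is None or err[i] < best[0] - 1e-15:
                with np.errstate(divide="ignore", invalid="ignore"):
                    a = np.where(w_gt[i] > 0, s_gt[i] / w_gt[i], 0.0)
                    b = np.where(cw[i] > 0, cwy[i] / cw[i], 0.0)
                # weighted means of +-1 labels; clip float cancellation
                best = (float(err[i]), j, float(v[bnd[i]]),
                        np.clip(a, -1.0, 1.0), np.clip(b, -1.0, 1.0))
        err_val, j, thr, a, b = best
        if np.allclose(a, 0) and np.allclose(b, 0):
            logger.info("no residual signal after %d rules; stopping",
                        len(model.rules))
            break
        rule = Rule(feature=feature_names[j], threshold=thr,
                    scores_gt=a.copy(), scores_le=b.copy())
        model.rules.append(rule)
        fx = np.where(x[:, j][:, None] > thr, a[None, :], b[None, :])
        f_sum += fx
        w = w * np.exp(-y * fx)
        w /= w.sum(axis=0, keepdims=True)
        if (np.asarray(classes)[np.argmax(f_sum, axis=1)] == labels).all():
            logger.info("training error reached 0 after %d rules",
                        len(model.rules))
            break
    return model


def decision_scores(model: BoostModel, features) -> np.ndarray:
    """Summed per-class rule scores, shape (n, n_classes)."""
    uniq = model.used_features
    if not uniq:
        return np.zeros((len(features), len(model.classes)))
    if isinstance(features, pd.DataFrame):
        x = _as_matrix(features, uniq)
        col = {f: i for i, f in enumerate(uniq)}
    else:
        x = np.asarray(features, dtype=float)
        if (model.feature_names
                and x.shape[1] == len(model.feature_names)):
            col = {f: i for i, f in enumerate(model.feature_names)}
        elif all(re.fullmatch(r"f\d+", f) for f in uniq):
            col = {f: int(f[1:]) for f in uniq}  # default training names
        else:
            raise ValueError(
                "array width does not match the model's feature list; "
                "pass a DataFrame with named columns")
        missing = [f for f in uniq if col.get(f, x.shape[1]) >= x.shape[1]]
        if missing:
            raise KeyError(f"missing feature column(s): {', '.join(missing)}")
    scores = np.zeros((x.shape[0], len(model.classes)))
    for r in model.rules:
        m = x[:, col[r.feature]] > r.threshold
        scores += np.where(m[:, None], r.scores_gt[None, :],
                           r.scores_le[None, :])
    return scores


def predict(model: BoostModel, features):
    """Class label per example (argmax score; ties -> earlier class)."""
    scores = decision_scores(model, features)
    labels = np.asarray(model.classes)[np.argmax(scores, axis=1)]
    return labels


# ---------------------------------------------------------------------------
# rules file serialization
# ---------------------------------------------------------------------------

def export_rules(model: BoostModel) -> str:
    """Serialize a model to rules text (header + one IF line per rule)."""
    lines = ["classes: " + ", ".join(model.classes)]
    lines += [r.format() for r in model.rules]
    return "\n".join(lines) + "\n"


def import_rules(text: str) -> BoostModel:
    """Parse rules text back into a model; inverse of :func:`export_rules`
    up to float formatting (12 significant digits)."""
    lines = [ln.strip() for ln in text.splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines or not lines[0].lower().startswith("classes:"):
        raise ValueError("rules text must start with a 'classes:' header")
    classes = [c.strip() for c in lines[0].split(":", 1)[1].split(",")]
    classes = [c for c in classes if c]
    if len(classes) < 2:
        raise ValueError("rules header must name >= 2 classes")
    rules = []
    for i, ln in enumerate(lines[1:], start=2):
        m = _RULE_RE.match(ln)
        if not m:
            raise ValueError(f"malformed rule at line {i}: {ln!r}")
        gt = np.array([float(v) for v in m.group("gt").split(",")])
        le = np.array([float(v) for v in m.group("le").split(",")])
        if len(gt) != len(classes) or len(le) != len(classes):
            raise ValueError(
                f"line {i}: score vector length != number of classes")
        rules.append(Rule(m.group("feat"), float(m.group("thr")), gt, le))
    if not rules:
        raise ValueError("rules file contains no rules")
    model = BoostModel(classes=classes, rules=rules)
    model.feature_names = model.used_features
    return model


def save_rules(model: BoostModel, path: str | Path) -> None:
    Path(path).write_text(export_rules(model))


def load_rules(path: str | Path) -> BoostModel:
    return import_rules(Path(path).read_text())


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvalResult:
    """Confusion matrix (rows = true, cols = predicted) and accuracy."""

    confusion: pd.DataFrame
    accuracy: float


def evaluate(model: BoostModel, features, labels) -> EvalResult:
    """Confusion matrix and accuracy of a fixed model on labelled data."""
    pred = predict(model, features)
    labels = np.asarray(labels)
    cm = pd.DataFrame(0, index=model.classes, columns=model.classes)
    for t, p in zip(labels, pred):
        cm.loc[t, p] += 1
    acc = float(np.trace(cm.to_numpy())) / len(labels)
    return EvalResult(confusion=cm, accuracy=acc)


def holdout_evaluate(features, labels, n_rounds: int = DEFAULT_N_ROUNDS,
                     seed: int = 0, test_frac: float = 0.3
                     ) -> tuple[BoostModel, EvalResult]:
    """Train on a stratified split, evaluate on the held-out fraction."""
    labels = np.asarray(labels)
    idx = np.arange(len(labels))
    tr, te = train_test_split(idx, test_size=test_frac, stratify=labels,
                              random_state=seed)
    if isinstance(features, pd.DataFrame):
        x_tr, x_te = features.iloc[tr], features.iloc[te]
    else:
        x_tr, x_te = features[tr], features[te]
    model = train(x_tr, labels[tr], n_rounds=n_rounds, seed=seed)
    return model, evaluate(model, x_te, labels[te])


def cross_validate(features, labels, n_rounds: int = DEFAULT_N_ROUNDS,
                   k_folds: int = 5, seed: int = 0) -> EvalResult:
    """Stratified k-fold cross-validation; pooled confusion matrix."""
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    cm = pd.DataFrame(0, index=classes, columns=classes)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        logger.debug("fold %d: %d train / %d test", fold, len(tr), len(te))
        if isinstance(features, pd.DataFrame):
            x_tr, x_te = features.iloc[tr], features.iloc[te]
        else:
            x_tr, x_te = features[tr], features[te]
        model = train(x_tr, labels[tr], n_rounds=n_rounds, seed=seed)
        for t, p in zip(labels[te], predict(model, x_te)):
            cm.loc[t, p] += 1
    acc = float(np.trace(cm.to_numpy())) / len(labels)
    return EvalResult(confusion=cm, accuracy=acc)


# ---------------------------------------------------------------------------
# two-stage application: focus QC, then phenotype
# ---------------------------------------------------------------------------

def two_stage_classify(table: pd.DataFrame,
                       focus_model: BoostModel,
                       phenotype_model: BoostModel,
                       outoffocus_label: str = "OutOfFocus") -> pd.DataFrame:
    """Focus QC then phenotype classification.

    Every row receives a ``focus_label``; rows classified as out of focus
    are retained in the output but flagged and excluded from phenotype
    scoring (``phenotype_label`` is NA for them).  Exclusion counts are
    logged, never silent.
    """
    if outoffocus_label not in focus_model.classes:
        raise ValueError(
            f"focus model has no class {outoffocus_label!r}")
    out = table.copy()
    out["focus_label"] = predict(focus_model, table)
    keep = out["focus_label"] != outoffocus_label
    n_excl = int((~keep).sum())
    logger.info("focus QC: %d/%d object-frames excluded as %s",
                n_excl, len(out), outoffocus_label)
    out["phenotype_label"] = pd.NA
    for c in phenotype_model.classes:
        out[f"score_{c}"] = np.nan
    if keep.any():
        sub = table.loc[keep]
        scores = decision_scores(phenotype_model, sub)
        out.loc[keep, "phenotype_label"] = np.asarray(
            phenotype_model.classes)[np.argmax(scores, axis=1)]
        for i, c in enumerate(phenotype_model.classes):
            out.loc[keep, f"score_{c}"] = scores[:, i]
    return out
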