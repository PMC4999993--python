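"""Per-GO-term binary SVM training, selection, calibration and prediction.

One RBF-kernel SVM is trained per GO term.  The labelled proteins are split
70/30 into training and validation sets; on the training set a backward
elimination over feature *groups* is run, where each candidate group set is
scored by the best mean k-fold cross-validated Matthews correlation
coefficient (MCC) over a small hyperparameter grid.  A removal is committed
only when it strictly improves the cross-validated MCC, so redundant but
informative groups are kept.  The winning configuration is refit on the full
training split and scored on the held-out validation set; classifiers with
validation MCC >= 0.05 are retained, refit on all labelled data, and
calibrated with a Platt sigmoid fitted to cross-validated decision values.

Class imbalance is handled by error weights inversely proportional to class
frequency.  All randomness (splits, folds, tie resampling) flows from a
single integer seed, making training reproducible bit for bit.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

from .errors import CandidateRejected, LookupError_, ValidationError
from .features import FeatureRegistry, FeatureVector, default_registry
from .ontology import AnnotationTable, Ontology
from .predictions import PredictionSet, round3

logger = logging.getLogger(__name__)

RETENTION_MCC = 0.05
DEFAULT_MIN_POS = 50
DEFAULT_MIN_FOLD = 10


# ---------------------------------------------------------------------------
# Confusion counts and MCC


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be nonnegative")

    @classmethod
    def from_labels(cls, y_true: np.ndarray, y_pred: np.ndarray
                    ) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(bool)
        y_pred = np.asarray(y_pred).astype(bool)
        return cls(
            tp=int((y_true & y_pred).sum()),
            tn=int((~y_true & ~y_pred).sum()),
            fp=int((~y_true & y_pred).sum()),
            fn=int((y_true & ~y_pred).sum()),
        )


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 by convention when any factor of
    the denominator is zero."""
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    if denom == 0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)


# ---------------------------------------------------------------------------
# Dataset assembly


@dataclass
class TermDataset:
    """Labelled proteins for one GO term with a stratified 70/30 split."""

    term: str
    positives: tuple[str, ...]
    negatives: tuple[str, ...]
    train_ids: tuple[str, ...]
    valid_ids: tuple[str, ...]
    labels: dict[str, int]

    @property
    def n_train_pos(self) -> int:
        return sum(self.labels[p] for p in self.train_ids)


def assemble_term_dataset(
    term: str,
    table: AnnotationTable,
    onto: Ontology,
    min_pos: int = DEFAULT_MIN_POS,
    seed: int = 0,
) -> TermDataset:
    """Collect positives and negatives for *term* from a propagated table.

    Positives are proteins annotated (post-propagation) with the term;
    negatives are proteins annotated in the same GO domain but with neither
    the term nor any of its descendants.  Terms with fewer than *min_pos*
    positives are rejected with :class:`CandidateRejected`.
    """
    if not table.propagated:
        raise ValidationError("annotation table must be propagated first")
    term = onto.canonical(term)
    domain = onto.domain(term)
    excluded = {term} | set(onto.descendants(term))
    positives, negatives = [], []
    for prot, terms in table.by_protein.items():
        if term in terms:
            positives.append(prot)
        elif not (terms & excluded) and any(
            onto.namespace.get(t) == domain for t in terms
        ):
            negatives.append(prot)
    if len(positives) < min_pos:
        raise CandidateRejected(
            f"{term}: {len(positives)} positives < min_pos={min_pos}"
        )
    if not negatives:
        raise CandidateRejected(f"{term}: no negative instances")
    positives.sort()
    negatives.sort()
    ids = positives + negatives
    y = [1] * len(positives) + [0] * len(negatives)
    train_ids, valid_ids = train_test_split(
        ids, test_size=0.3, stratify=y, random_state=seed % (2**32)
    )
    labels = dict(zip(ids, y))
    return TermDataset(
        term=term,
        positives=tuple(positives),
        negatives=tuple(negatives),
        train_ids=tuple(train_ids),
        valid_ids=tuple(valid_ids),
        labels=labels,
    )


def choose_k(n_positives: int, min_fold_size: int = DEFAULT_MIN_FOLD) -> int:
    """Largest k in {5, 4, 3} giving every stratified fold at least
    *min_fold_size* positives; rejects the candidate when none qualifies."""
    for k in (5, 4, 3):
        if n_positives // k >= min_fold_size:
            return k
    raise CandidateRejected(
        f"no feasible fold count for {n_positives} positives "
        f"(min_fold_size={min_fold_size})"
    )


# ---------------------------------------------------------------------------
# Scaling


@dataclass
class RangeScaler:
    """Map each training column into [-1, 1]; constant columns map to 0."""

    col_min: np.ndarray
    col_max: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "RangeScaler":
        return cls(col_min=X.min(axis=0), col_max=X.max(axis=0))

    def transform(self, X: np.ndarray) -> np.ndarray:
        span = self.col_max - self.col_min
        safe = np.where(span == 0, 1.0, span)
        Z = 2.0 * (X - self.col_min) / safe - 1.0
        Z[:, span == 0] = 0.0
        return np.clip(Z, -3.0, 3.0)


# ---------------------------------------------------------------------------
# Hyperparameter grid and the stored RBF model


def default_grid() -> list[dict]:
    """Log-spaced cost values with the data-dependent 'scale' kernel width."""
    return [{"C": c, "gamma": "scale"} for c in (1.0, 10.0, 100.0)]


@dataclass
class RBFModel:
    """A fitted RBF-kernel SVM in explicit form (support vectors, dual
    coefficients, intercept, kernel width), independent of the fitting
    library, so models serialise to plain JSON."""

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float

    @classmethod
    def from_svc(cls, svc: SVC) -> "RBFModel":
        return cls(
            support_vectors=svc.support_vectors_.copy(),
            dual_coef=svc.dual_coef_[0].copy(),
            intercept=float(svc.intercept_[0]),
            gamma=float(svc._gamma),
        )

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        d2 = (
            (X**2).sum(axis=1)[:, None]
            - 2.0 * X @ self.support_vectors.T
            + (self.support_vectors**2).sum(axis=1)[None, :]
        )
        K = np.exp(-self.gamma * np.maximum(d2, 0.0))
        return K @ self.dual_coef + self.intercept


def _fit_svc(X: np.ndarray, y: np.ndarray, params: dict) -> SVC:
    svc = SVC(
        kernel="rbf",
        C=params["C"],
        gamma=params["gamma"],
        class_weight="balanced",
        cache_size=200,
    )
    svc.fit(X, y)
    return svc


# ---------------------------------------------------------------------------
# Cross-validated model selection


def _cv_mcc(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    grid: Sequence[dict],
    seed: int,
) -> tuple[float, dict]:
    """Best (mean CV MCC, params) over the grid; ties keep grid order."""
    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=seed % (2**32))
    folds = list(skf.split(X, y))
    best_score, best_params = -np.inf, None
    for params in grid:
        scores = []
        for tr, te in folds:
            if len(np.unique(y[tr])) < 2:
                raise _DegenerateFold()
            scaler = RangeScaler.fit(X[tr])
            svc = _fit_svc(scaler.transform(X[tr]), y[tr], params)
            pred = svc.predict(scaler.transform(X[te]))
            scores.append(mcc(ConfusionCounts.from_labels(y[te], pred)))
        m = float(np.mean(scores))
        if m > best_score:
            best_score, best_params = m, params
    return best_score, best_params


class _DegenerateFold(Exception):
    pass


# ---------------------------------------------------------------------------
# The trained classifier


@dataclass
class TermClassifier:
    """One GO term's trained model with its selection and calibration state."""

    term: str
    selected_groups: tuple[str, ...]
    params: dict
    scaler: RangeScaler
    model: RBFModel
    platt_a: float
    platt_b: float
    validation_mcc: float
    retained: bool
    cv_mcc: float = 0.0
    cv_mcc_full: float = 0.0

    def decision_value(self, vec: FeatureVector) -> float:
        x = vec.to_array(self.selected_groups)[None, :]
        return float(self.model.decision(self.scaler.transform(x))[0])

    def posterior(self, raw: float) -> float:
        return 1.0 / (1.0 + math.exp(self.platt_a * raw + self.platt_b))


def predict(clf: TermClassifier, vec: FeatureVector) -> float:
    """Platt-calibrated posterior that the protein performs the term's
    function, rounded to three decimals."""
    return round3(clf.posterior(clf.decision_value(vec)))


def _fit_platt(decisions: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Platt sigmoid P(y=1|f) = 1 / (1 + exp(a f + b)) by regularised
    maximum likelihood on (cross-validated) decision values."""
    from sklearn.linear_model import LogisticRegression

    lr = LogisticRegression(C=1e4, solver="lbfgs", max_iter=1000)
    lr.fit(decisions.reshape(-1, 1), y)
    return -float(lr.coef_[0][0]), -float(lr.intercept_[0])


def _cross_val_decisions(
    X: np.ndarray, y: np.ndarray, params: dict, seed: int, k: int = 3
) -> np.ndarray:
    """Out-of-fold decision values, so the sigmoid never sees training
    scores of the model that produced them."""
    k = min(k, int(np.bincount(y).min()))
    if k < 2:
        raise _DegenerateFold()
    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=seed % (2**32))
    out = np.zeros(len(y))
    for tr, te in skf.split(X, y):
        scaler = RangeScaler.fit(X[tr])
        svc = _fit_svc(scaler.transform(X[tr]), y[tr], params)
        out[te] = RBFModel.from_svc(svc).decision(scaler.transform(X[te]))
    return out


def train_term_classifier(
    ds: TermDataset,
    vectors: Mapping[str, FeatureVector],
    registry: FeatureRegistry | None = None,
    grid: Sequence[dict] | None = None,
    seed: int = 0,
    min_fold_size: int = DEFAULT_MIN_FOLD,
) -> TermClassifier:
    """Run the full selection/validation/calibration protocol for one term.

    See the module docstring for the procedure.  Raises
    :class:`CandidateRejected` when no feasible fold count exists or a fold
    is irrecoverably single-class.
    """
    registry = registry or default_registry()
    grid = list(grid) if grid is not None else default_grid()
    if not grid:
        raise ValidationError("hyperparameter grid is empty")

    all_groups = [g for g in registry.group_names
                  if g in vectors[ds.train_ids[0]].values]
    if not all_groups:
        raise ValidationError("no feature groups available for training")

    # column slices per group in the stacked matrix
    slices: dict[str, slice] = {}
    off = 0
    for g in all_groups:
        size = len(vectors[ds.train_ids[0]].values[g])
        slices[g] = slice(off, off + size)
        off += size

    def matrix(ids: Sequence[str], groups: Sequence[str]) -> np.ndarray:
        full = np.vstack([vectors[i].to_array(all_groups) for i in ids])
        cols = np.concatenate(
            [np.arange(slices[g].start, slices[g].stop) for g in groups]
        )
        return full[:, cols]

    y_train = np.array([ds.labels[p] for p in ds.train_ids])
    k = choose_k(int(y_train.sum()), min_fold_size=min_fold_size)

    def evaluate(groups: Sequence[str], cv_seed: int) -> tuple[float, dict]:
        X = matrix(ds.train_ids, groups)
        try:
            return _cv_mcc(X, y_train, k, grid, cv_seed)
        except _DegenerateFold:
            # one retry with a reshuffled fold assignment
            try:
                return _cv_mcc(X, y_train, k, grid, cv_seed + 1)
            except _DegenerateFold:
                raise CandidateRejected(
                    f"{ds.term}: degenerate single-class fold"
                ) from None

    # step 2: full group set
    current = list(all_groups)
    best_score, best_params = evaluate(current, seed)
    full_set_score = best_score

    # step 3: greedy backward elimination; a removal is committed only when
    # it strictly improves the mean cross-validated MCC
    while len(current) > 1:
        candidates = []
        for g in current:
            trial = [x for x in current if x != g]
            score, params = evaluate(trial, seed)
            candidates.append((score, g, params))
        cand_score, cand_group, cand_params = max(
            candidates, key=lambda c: c[0]
        )
        if cand_score > best_score:
            current = [x for x in current if x != cand_group]
            best_score, best_params = cand_score, cand_params
            logger.debug("%s: removed group %s (CV MCC %.4f)",
                         ds.term, cand_group, cand_score)
        else:
            break

    selected = tuple(current)

    # step 4-5: refit on the 70% split, score on the held-out 30%
    X_train = matrix(ds.train_ids, selected)
    X_valid = matrix(ds.valid_ids, selected)
    y_valid = np.array([ds.labels[p] for p in ds.valid_ids])
    scaler = RangeScaler.fit(X_train)
    svc = _fit_svc(scaler.transform(X_train), y_train, best_params)
    val_pred = svc.predict(scaler.transform(X_valid))
    validation_mcc = mcc(ConfusionCounts.from_labels(y_valid, val_pred))
    retained = validation_mcc >= RETENTION_MCC

    # step 7: the deployed model uses every labelled protein when retained
    if retained:
        final_ids = list(ds.train_ids) + list(ds.valid_ids)
    else:
        final_ids = list(ds.train_ids)
    X_final = matrix(final_ids, selected)
    y_final = np.array([ds.labels[p] for p in final_ids])
    scaler = RangeScaler.fit(X_final)
    Z_final = scaler.transform(X_final)
    svc = _fit_svc(Z_final, y_final, best_params)
    model = RBFModel.from_svc(svc)
    try:
        dec = _cross_val_decisions(Z_final, y_final, best_params, seed)
    except _DegenerateFold:
        dec = model.decision(Z_final)
    platt_a, platt_b = _fit_platt(dec, y_final)

    params_out = dict(best_params)
    params_out["gamma_value"] = model.gamma
    return TermClassifier(
        term=ds.term,
        selected_groups=selected,
        params=params_out,
        scaler=scaler,
        model=model,
        platt_a=platt_a,
        platt_b=platt_b,
        validation_mcc=validation_mcc,
        retained=retained,
        cv_mcc=best_score,
        cv_mcc_full=full_set_score,
    )


# ---------------------------------------------------------------------------
# Library persistence and proteome-wide prediction


def classifier_to_dict(clf: TermClassifier) -> dict:
    return {
        "term": clf.term,
        "selected_groups": list(clf.selected_groups),
        "params": {k: v for k, v in clf.params.items()},
        "scaler": {
            "col_min": clf.scaler.col_min.tolist(),
            "col_max": clf.scaler.col_max.tolist(),
        },
        "model": {
            "support_vectors": clf.model.support_vectors.tolist(),
            "dual_coef": clf.model.dual_coef.tolist(),
            "intercept": clf.model.intercept,
            "gamma": clf.model.gamma,
        },
        "platt": {"a": clf.platt_a, "b": clf.platt_b},
        "validation_mcc": clf.validation_mcc,
        "retained": clf.retained,
        "cv_mcc": clf.cv_mcc,
    }


def classifier_from_dict(d: dict) -> TermClassifier:
    return TermClassifier(
        term=d["term"],
        selected_groups=tuple(d["selected_groups"]),
        params=dict(d["params"]),
        scaler=RangeScaler(
            col_min=np.array(d["scaler"]["col_min"]),
            col_max=np.array(d["scaler"]["col_max"]),
        ),
        model=RBFModel(
            support_vectors=np.array(d["model"]["support_vectors"]),
            dual_coef=np.array(d["model"]["dual_coef"]),
            intercept=float(d["model"]["intercept"]),
            gamma=float(d["model"]["gamma"]),
        ),
        platt_a=float(d["platt"]["a"]),
        platt_b=float(d["platt"]["b"]),
        validation_mcc=float(d["validation_mcc"]),
        retained=bool(d["retained"]),
        cv_mcc=float(d.get("cv_mcc", 0.0)),
    )


def save_library(classifiers: Sequence[TermClassifier], directory: str) -> None:
    """One self-describing JSON per term plus a manifest."""
    os.makedirs(directory, exist_ok=True)
    manifest = []
    for clf in classifiers:
        fname = clf.term.replace(":", "_") + ".json"
        with open(os.path.join(directory, fname), "w") as fh:
            json.dump(classifier_to_dict(clf), fh)
        manifest.append({
            "term": clf.term,
            "file": fname,
            "validation_mcc": clf.validation_mcc,
            "retained": clf.retained,
            "selected_groups": list(clf.selected_groups),
        })
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_library(directory: str) -> list[TermClassifier]:
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    out = []
    for entry in manifest:
        with open(os.path.join(directory, entry["file"])) as fh:
            out.append(classifier_from_dict(json.load(fh)))
    return out


def predict_proteome(
    classifiers: Sequence[TermClassifier],
    vectors: Mapping[str, FeatureVector],
    retained_only: bool = True,
) -> PredictionSet:
    """Score every protein against every (retained) term classifier."""
    ps = PredictionSet()
    for clf in classifiers:
        if retained_only and not clf.retained:
            continue
        for prot, vec in vectors.items():
            ps.add(prot, clf.term, predict(clf, vec))
    return ps
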