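"""Precomputed-kernel SVM with class-balanced penalties and Platt scaling.

The classifier is a standard L1 soft-margin SVM trained on a precomputed
Gram matrix (the combined site kernel).  With ``balanced=True`` the
misclassification penalty for class c is scaled inversely to class
frequency, C_c = C * N / (2 * N_c), so the minority class is not
swamped.  Decision values are

    f(t) = sum_j a_j y_j K(t, x_j) + b

over the support sites.  Class-membership probabilities are obtained by
Platt scaling: a sigmoid ``1 / (1 + exp(-(a f + b)))`` fitted to
out-of-fold decision values from a seeded internal cross-validation, so
probabilities are a strictly monotone function of decision values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .kernels import KernelMatrix

MODEL_FORMAT_VERSION = 1


@dataclass
class ModelParams:
    """SVM hyperparameters.

    C : regularization strength (solver default 1.0).
    balanced : scale per-class penalties inversely to class frequency.
    probability : fit a Platt sigmoid for probability estimates.
    seed : seed for the internal calibration cross-validation.
    """

    C: float = 1.0
    balanced: bool = True
    probability: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError(f"C must be > 0, got {self.C}")


@dataclass
class LabeledDataset:
    """Binary task labels over an ordered set of sites."""

    site_ids: list[str]
    labels: np.ndarray
    target_ptm: str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.site_ids),):
            raise ValueError("labels and site_ids length mismatch")
        if not np.isin(self.labels, (-1, 1)).all():
            raise ValueError("labels must be +1/-1")

    @property
    def n(self) -> int:
        return len(self.site_ids)


@dataclass
class TrainedModel:
    """A fitted SVM in dual form.

    ``dual_coefs[j]`` is the signed coefficient a_j * y_j of support
    site j; ``class_penalties`` maps each label to its effective box
    bound C_c, against which dual feasibility can be checked.
    """

    dual_coefs: np.ndarray
    bias: float
    support_ids: list[str]
    support_idx: np.ndarray  # indices into the training ordering
    class_penalties: dict[int, float]
    params: ModelParams
    norm_constants: tuple[float, float] | None = None
    platt: tuple[float, float] | None = None  # (slope a, intercept b)

    def __post_init__(self) -> None:
        self.dual_coefs = np.asarray(self.dual_coefs, dtype=float)
        self.support_idx = np.asarray(self.support_idx, dtype=int)


def _class_weight(params: ModelParams):
    return "balanced" if params.balanced else None


def _fit_svc(K: np.ndarray, y: np.ndarray, params: ModelParams) -> SVC:
    clf = SVC(kernel="precomputed", C=params.C, class_weight=_class_weight(params))
    clf.fit(K, y)
    return clf


def class_penalties(labels: np.ndarray, params: ModelParams) -> dict[int, float]:
    """Effective per-class box bounds C_c = C * N / (2 * N_c) (or C if uniform)."""
    labels = np.asarray(labels)
    if not params.balanced:
        return {-1: params.C, 1: params.C}
    n = len(labels)
    return {
        c: params.C * n / (2.0 * int((labels == c).sum())) for c in (-1, 1)
    }


def train(
    K_train: KernelMatrix, data: LabeledDataset, params: ModelParams
) -> TrainedModel:
    """Fit the soft-margin SVM on a precomputed kernel.

    Raises on single-class data or kernel/label misalignment.  The
    returned model satisfies the dual constraints sum_j a_j y_j = 0 and
    0 <= a_j <= C_{y_j}.
    """
    if K_train.site_ids != data.site_ids:
        raise ValueError("kernel and dataset site-id orderings differ")
    y = data.labels
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    clf = _fit_svc(K_train.values, y, params)

    platt = None
    if params.probability:
        oof = _out_of_fold_scores(K_train.values, y, params)
        platt = fit_platt(oof, y)

    return TrainedModel(
        dual_coefs=clf.dual_coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        support_ids=[data.site_ids[i] for i in clf.support_],
        support_idx=clf.support_.copy(),
        class_penalties=class_penalties(y, params),
        params=params,
        platt=platt,
    )


def _out_of_fold_scores(
    K: np.ndarray, y: np.ndarray, params: ModelParams, n_splits: int = 5
) -> np.ndarray:
    """Decision values for each sample from a model not trained on it."""
    n_splits = min(n_splits, int(min((y == -1).sum(), (y == 1).sum())))
    if n_splits < 2:
        raise ValueError("too few samples per class for probability calibration")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=params.seed)
    scores = np.empty(len(y), dtype=float)
    for tr, te in skf.split(np.zeros(len(y)), y):
        clf = _fit_svc(K[np.ix_(tr, tr)], y[tr], params)
        scores[te] = clf.decision_function(K[np.ix_(te, tr)])
    return scores


def fit_platt(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Fit the Platt sigmoid P(y=+1 | f) = 1 / (1 + exp(-(a f + b))).

    Maximum-likelihood fit with the usual regularized targets
    t+ = (N+ + 1)/(N+ + 2), t- = 1/(N- + 2) to avoid saturation.  The
    slope a is positive whenever scores and labels correlate, making the
    probability map strictly increasing in the decision value.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == -1).sum())
    t = np.where(labels == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))

    def nll_grad(ab: np.ndarray) -> tuple[float, np.ndarray]:
        z = ab[0] * scores + ab[1]
        # -[t*log(p) + (1-t)*log(1-p)] with p = expit(z), stably:
        value = float(np.sum((1.0 - t) * z + np.logaddexp(0.0, -z)))
        resid = expit(z) - t
        return value, np.array([np.dot(resid, scores), resid.sum()])

    x0 = np.array([1.0, np.log((n_pos + 1.0) / (n_neg + 1.0))])
    res = minimize(nll_grad, x0, jac=True, method="L-BFGS-B",
                   options={"gtol": 1e-12, "ftol": 1e-15})
    return float(res.x[0]), float(res.x[1])


def decision_values(model: TrainedModel, K_cross: np.ndarray) -> np.ndarray:
    """Decision values for rows of a (test x support) kernel block."""
    K_cross = np.asarray(K_cross, dtype=float)
    if K_cross.ndim != 2 or K_cross.shape[1] != len(model.support_ids):
        raise ValueError(
            f"cross-kernel block has {K_cross.shape} but model has "
            f"{len(model.support_ids)} support sites"
        )
    return K_cross @ model.dual_coefs + model.bias


def predict_proba(model: TrainedModel, scores: np.ndarray) -> np.ndarray:
    """Map decision values to P(positive) through the fitted Platt sigmoid."""
    if model.platt is None:
        raise ValueError("model was trained without probability=True")
    a, b = model.platt
    return expit(a * np.asarray(scores, dtype=float) + b)


def predict_labels(scores: np.ndarray, threshold: float = 0.0) -> np.ndarray:
    """+1 where score >= threshold (ties at the threshold are positive)."""
    return np.where(np.asarray(scores) >= threshold, 1, -1)


def check_dual_feasibility(
    model: TrainedModel, labels: np.ndarray, tol: float = 1e-6
) -> None:
    """Assert the KKT box and equality constraints of the dual solution."""
    y_sv = np.sign(model.dual_coefs)
    alphas = np.abs(model.dual_coefs)
    labels = np.asarray(labels)
    if not np.array_equal(y_sv, labels[model.support_idx]):
        raise AssertionError("signs of dual coefficients disagree with labels")
    balance = float(model.dual_coefs.sum())
    if abs(balance) > tol:
        raise AssertionError(f"sum a_i y_i = {balance:g} exceeds tolerance")
    bounds = np.array([model.class_penalties[int(c)] for c in y_sv])
    if (alphas < -tol).any() or (alphas > bounds + tol).any():
        raise AssertionError("dual coefficients violate box constraints")


# ---------------------------------------------------------------------------
# serialization

def save_model(model: TrainedModel, path: str | Path) -> None:
    """Write a self-describing, versioned JSON model file."""
    doc = {
        "format": "ptmsvm-model",
        "version": MODEL_FORMAT_VERSION,
        "dual_coefs": model.dual_coefs.tolist(),
        "bias": model.bias,
        "support_ids": model.support_ids,
        "support_idx": model.support_idx.tolist(),
        "class_penalties": {str(k): v for k, v in model.class_penalties.items()},
        "params": {
            "C": model.params.C,
            "balanced": model.params.balanced,
            "probability": model.params.probability,
            "seed": model.params.seed,
        },
        "norm_constants": list(model.norm_constants) if model.norm_constants else None,
        "platt": list(model.platt) if model.platt else None,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_model(path: str | Path) -> TrainedModel:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "ptmsvm-model":
        raise ValueError(f"{path}: not a ptmsvm model file")
    if doc.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported model format version {doc.get('version')!r}"
        )
    return TrainedModel(
        dual_coefs=np.array(doc["dual_coefs"], dtype=float),
        bias=float(doc["bias"]),
        support_ids=list(doc["support_ids"]),
        support_idx=np.array(doc["support_idx"], dtype=int),
        class_penalties={int(k): float(v) for k, v in doc["class_penalties"].items()},
        params=ModelParams(**doc["params"]),
        norm_constants=tuple(doc["norm_constants"]) if doc["norm_constants"] else None,
        platt=tuple(doc["platt"]) if doc["platt"] else None,
    )
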