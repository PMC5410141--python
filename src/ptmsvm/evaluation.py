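"""Cross-validation protocol, metrics, thresholds and candidate ranking.

Evaluation follows the repeated stratified ten-fold protocol: within a
repeat every site is scored exactly once by a model that never saw it,
scores are pooled, and the metric suite (Sn, Sp, Pre, Acc, MCC, ROC
AUC) is computed per repeat and then averaged over repeats.

Two leakage guards are built into each fold:

* the min/max constants of the sequence kernel are taken on the
  training block only and applied to the train-test cross block;
* the target-PTM column of held-out sites is zeroed in the adjacency
  matrix before the GIP kernel is recomputed, so the kernel cannot
  encode the labels being predicted.

Decision thresholds are anchored on specificity (e.g. Sp >= 95% medium
stringency, >= 99% high stringency), the convention used when false
positive control matters more than raw accuracy.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from . import model as model_mod
from .kernels import (
    InteractionProfileMatrix,
    KernelConfig,
    KernelMatrix,
    apply_normalization,
    combine_blocks,
    combine_kernels,
    gip_cross,
    gip_kernel,
    mask_profiles,
    minmax_normalize,
    nearest_psd,
    seq_similarity_cross,
    seq_similarity_matrix,
)
from .model import (
    LabeledDataset,
    ModelParams,
    TrainedModel,
    check_dual_feasibility,
    decision_values,
    predict_labels,
    predict_proba,
    train,
)
from .windows import PeptideWindow, blosum62

METRIC_NAMES = ("sn", "sp", "pre", "acc", "mcc", "auc")


@dataclass(frozen=True)
class ConfusionCounts:
    """Counts of a 2x2 confusion table."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(
        cls, predicted: np.ndarray, labels: np.ndarray
    ) -> "ConfusionCounts":
        predicted = np.asarray(predicted)
        labels = np.asarray(labels)
        return cls(
            tp=int(((predicted == 1) & (labels == 1)).sum()),
            tn=int(((predicted == -1) & (labels == -1)).sum()),
            fp=int(((predicted == 1) & (labels == -1)).sum()),
            fn=int(((predicted == -1) & (labels == 1)).sum()),
        )


@dataclass
class MetricsReport:
    """The metric suite; metrics with a zero denominator are None and flagged.

    sn = TP/(TP+FN), sp = TN/(TN+FP), pre = TP/(TP+FP),
    acc = (TP+TN)/total, mcc = (TP*TN - FP*FN)/sqrt(prod of marginals).
    """

    sn: float | None = None
    sp: float | None = None
    pre: float | None = None
    acc: float | None = None
    mcc: float | None = None
    auc: float | None = None
    roc_points: list[tuple[float, float]] | None = None
    threshold: float | None = None
    undefined: frozenset[str] = frozenset()

    def as_dict(self) -> dict:
        return {
            **{name: getattr(self, name) for name in METRIC_NAMES},
            "threshold": self.threshold,
            "undefined": sorted(self.undefined),
        }


def confusion_metrics(
    counts: ConfusionCounts, threshold: float | None = None
) -> MetricsReport:
    """Sn/Sp/Pre/Acc/MCC from a confusion table; undefined stays undefined."""
    undefined = set()
    values: dict[str, float | None] = {}

    def ratio(name: str, num: int, den: int) -> None:
        if den == 0:
            undefined.add(name)
            values[name] = None
        else:
            values[name] = num / den

    ratio("sn", counts.tp, counts.tp + counts.fn)
    ratio("sp", counts.tn, counts.tn + counts.fp)
    ratio("pre", counts.tp, counts.tp + counts.fp)
    ratio("acc", counts.tp + counts.tn, counts.total)
    mcc_den = (
        (counts.tp + counts.fn)
        * (counts.tp + counts.fp)
        * (counts.tn + counts.fn)
        * (counts.tn + counts.fp)
    )
    if mcc_den == 0:
        undefined.add("mcc")
        values["mcc"] = None
    else:
        values["mcc"] = (
            counts.tp * counts.tn - counts.fp * counts.fn
        ) / math.sqrt(mcc_den)
    return MetricsReport(threshold=threshold, undefined=frozenset(undefined), **values)


def roc_auc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[list[tuple[float, float]], float]:
    """ROC points (one vertex per distinct score, ties grouped) and AUC.

    Trapezoidal AUC over the tie-grouped ROC equals the Mann-Whitney
    concordance probability with ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes")
    fpr, tpr, _ = roc_curve(labels, scores, pos_label=1, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


class ThresholdResult(NamedTuple):
    threshold: float
    specificity: float
    reachable: bool


def threshold_at_specificity(
    scores: np.ndarray, labels: np.ndarray, sp_target: float
) -> ThresholdResult:
    """Smallest observed-score threshold with empirical Sp >= sp_target.

    A sample is called positive when its score >= threshold.  If even
    the largest observed score cannot reach the target (all negatives
    share the maximum score), the threshold is +inf and flagged
    unreachable.
    """
    if not 0.0 <= sp_target < 1.0 + 1e-12:
        raise ValueError(f"sp_target must be in [0, 1], got {sp_target}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    neg = np.sort(scores[labels == -1])
    if neg.size == 0:
        raise ValueError("no negative samples; specificity undefined")
    for t in np.unique(scores):
        sp = float(np.searchsorted(neg, t, side="left")) / neg.size
        if sp >= sp_target:
            return ThresholdResult(float(t), sp, True)
    return ThresholdResult(math.inf, 1.0, False)


def top_fraction(scores: np.ndarray, labels: np.ndarray, p: float) -> float:
    """Fraction of all positives found in the top p% of score-ranked samples."""
    if not 0.0 < p <= 100.0:
        raise ValueError(f"p must be in (0, 100], got {p}")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise ValueError("no positive samples")
    k = int(math.floor(p / 100.0 * len(scores)))
    order = np.argsort(-scores, kind="stable")
    return int((labels[order[:k]] == 1).sum()) / n_pos


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class FoldResult:
    """Everything one CV fold produced (kept for leakage auditing)."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    model: TrainedModel
    scores: np.ndarray  # decision values of the test sites
    K_train: KernelMatrix
    K_cross: np.ndarray  # test x train combined kernel block
    norm_constants: tuple[float, float]


def evaluate_fold(
    S_seq: KernelMatrix,
    profiles: InteractionProfileMatrix,
    data: LabeledDataset,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    config: KernelConfig,
    params: ModelParams,
) -> FoldResult:
    """Train on one fold split and score the held-out sites.

    The sequence similarity matrix is label-free and precomputed once
    globally; per fold only its normalization constants depend on the
    split.  The GIP kernel is recomputed from the masked adjacency.
    """
    if S_seq.site_ids != data.site_ids or profiles.site_ids != data.site_ids:
        raise ValueError("inputs are not aligned on site_ids")
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    ids = data.site_ids

    S_tr = KernelMatrix(
        [ids[i] for i in train_idx],
        S_seq.values[np.ix_(train_idx, train_idx)],
        "raw_similarity",
    )
    K_seq_tr, mn, mx = minmax_normalize(S_tr)
    K_seq_cross = apply_normalization(
        S_seq.values[np.ix_(test_idx, train_idx)], mn, mx
    )

    masked = mask_profiles(profiles, [ids[i] for i in test_idx], data.target_ptm)
    K_gip = gip_kernel(masked, config.gamma)
    K_gip_tr = KernelMatrix(
        K_seq_tr.site_ids, K_gip.values[np.ix_(train_idx, train_idx)], "gip_kernel"
    )
    K_gip_cross = K_gip.values[np.ix_(test_idx, train_idx)]

    K_train = combine_kernels([K_seq_tr, K_gip_tr], config.betas)
    if config.psd_repair:
        K_train = nearest_psd(K_train)
    K_cross = combine_blocks([K_seq_cross, K_gip_cross], config.betas)

    fold_data = LabeledDataset(
        list(K_train.site_ids), data.labels[train_idx], data.target_ptm
    )
    fitted = train(K_train, fold_data, params)
    fitted.norm_constants = (mn, mx)
    scores = decision_values(fitted, K_cross[:, fitted.support_idx])
    return FoldResult(
        train_idx, test_idx, fitted, scores, K_train, K_cross, (mn, mx)
    )


@dataclass
class CVResult:
    """Scores, fold assignments and metrics of a repeated k-fold run."""

    site_ids: list[str]
    labels: np.ndarray
    fold_assignments: np.ndarray  # (repeats, n) fold index of each site
    scores: np.ndarray  # (repeats, n) pooled out-of-fold decision values
    probabilities: np.ndarray | None  # same shape, if probability=True
    per_repeat: list[MetricsReport]
    averaged: MetricsReport
    per_fold: list[list[MetricsReport]] | None = None
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "config": self.config,
            "n_sites": len(self.site_ids),
            "per_repeat": [r.as_dict() for r in self.per_repeat],
            "averaged": self.averaged.as_dict(),
        }
        text = json.dumps(doc, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def scores_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("site_id\trepeat\tfold\tscore\tprobability\tlabel\n")
            for r in range(self.scores.shape[0]):
                for i, sid in enumerate(self.site_ids):
                    prob = (
                        f"{self.probabilities[r, i]:.17g}"
                        if self.probabilities is not None
                        else "NA"
                    )
                    fh.write(
                        f"{sid}\t{r}\t{int(self.fold_assignments[r, i])}\t"
                        f"{self.scores[r, i]:.17g}\t{prob}\t"
                        f"{int(self.labels[i]):+d}\n"
                    )

    def roc_tsv(self, path: str | Path, repeat: int = 0) -> None:
        points, _ = roc_auc(self.scores[repeat], self.labels)
        with open(path, "w") as fh:
            fh.write("fpr\ttpr\n")
            for fpr, tpr in points:
                fh.write(f"{fpr:.17g}\t{tpr:.17g}\n")


def _average_reports(reports: Sequence[MetricsReport]) -> MetricsReport:
    """Mean of each metric over repeats; undefined anywhere -> undefined."""
    values: dict[str, float | None] = {}
    undefined = set()
    for name in METRIC_NAMES:
        vals = [getattr(r, name) for r in reports]
        if any(v is None for v in vals):
            undefined.add(name)
            values[name] = None
        else:
            values[name] = float(np.mean(vals))
    thresholds = [r.threshold for r in reports if r.threshold is not None]
    return MetricsReport(
        threshold=float(np.mean(thresholds)) if thresholds else None,
        undefined=frozenset(undefined),
        **values,
    )


def _pooled_report(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> MetricsReport:
    counts = ConfusionCounts.from_predictions(
        predict_labels(scores, threshold), labels
    )
    report = confusion_metrics(counts, threshold=threshold)
    report.roc_points, report.auc = roc_auc(scores, labels)
    return report


def run_cv(
    windows: Sequence[PeptideWindow],
    profiles: InteractionProfileMatrix,
    data: LabeledDataset,
    config: KernelConfig,
    params: ModelParams,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    threshold: float = 0.0,
    per_fold_metrics: bool = False,
    check_feasibility: bool = True,
) -> CVResult:
    """Repeated stratified k-fold cross-validation of the full pipeline.

    Per repeat, sites are partitioned into ``folds`` stratified folds
    from a seed derived deterministically from the master ``seed``.
    Metrics are computed on the scores pooled within each repeat and
    averaged across repeats; per-fold metrics are optional.
    """
    if data.n < folds:
        raise ValueError(f"{data.n} samples cannot fill {folds} folds")
    window_ids = [w.site_id for w in windows]
    if window_ids != data.site_ids:
        raise ValueError("windows are not aligned with the dataset site_ids")

    S_seq = seq_similarity_matrix(windows, blosum62())
    repeat_seeds = np.random.SeedSequence(seed).generate_state(repeats) % (2**31)

    n = data.n
    all_scores = np.empty((repeats, n))
    all_probs = np.empty((repeats, n)) if params.probability else None
    assignments = np.empty((repeats, n), dtype=int)
    per_repeat: list[MetricsReport] = []
    per_fold: list[list[MetricsReport]] | None = [] if per_fold_metrics else None

    for r in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(repeat_seeds[r])
        )
        fold_reports: list[MetricsReport] = []
        for fold_no, (tr, te) in enumerate(
            skf.split(np.zeros(n), data.labels)
        ):
            if len(np.unique(data.labels[tr])) < 2:
                raise ValueError(
                    f"repeat {r}, fold {fold_no}: training data is single-class"
                )
            result = evaluate_fold(S_seq, profiles, data, tr, te, config, params)
            if check_feasibility:
                check_dual_feasibility(result.model, data.labels[tr])
            all_scores[r, te] = result.scores
            if all_probs is not None:
                all_probs[r, te] = predict_proba(result.model, result.scores)
            assignments[r, te] = fold_no
            if per_fold is not None:
                fold_reports.append(
                    _pooled_report(result.scores, data.labels[te], threshold)
                )
        per_repeat.append(_pooled_report(all_scores[r], data.labels, threshold))
        if per_fold is not None:
            per_fold.append(fold_reports)

    return CVResult(
        site_ids=list(data.site_ids),
        labels=data.labels.copy(),
        fold_assignments=assignments,
        scores=all_scores,
        probabilities=all_probs,
        per_repeat=per_repeat,
        averaged=_average_reports(per_repeat),
        per_fold=per_fold,
        config={
            "gamma": config.gamma,
            "betas": list(config.betas),
            "psd_repair": config.psd_repair,
            "C": params.C,
            "balanced": params.balanced,
            "folds": folds,
            "repeats": repeats,
            "seed": seed,
            "threshold": threshold,
            "target_ptm": data.target_ptm,
        },
    )


# ---------------------------------------------------------------------------
# final model + candidate ranking

@dataclass
class PTMPredictor:
    """A model fitted on all labeled data, with the context to score new sites.

    Keeps the support windows and (unmasked) support profiles so that a
    candidate can be scored through the combined kernel against support
    sites only.
    """

    model: TrainedModel
    support_windows: list[PeptideWindow]
    support_profiles: np.ndarray  # support x PTM adjacency rows
    ptm_names: list[str]
    target_ptm: str
    config: KernelConfig


def fit_predictor(
    windows: Sequence[PeptideWindow],
    profiles: InteractionProfileMatrix,
    data: LabeledDataset,
    config: KernelConfig,
    params: ModelParams,
) -> PTMPredictor:
    """Train a final model on every labeled site (no masking)."""
    window_ids = [w.site_id for w in windows]
    if window_ids != data.site_ids or profiles.site_ids != data.site_ids:
        raise ValueError("inputs are not aligned on site_ids")
    S_seq = seq_similarity_matrix(windows, blosum62())
    K_seq, mn, mx = minmax_normalize(S_seq)
    K_gip = gip_kernel(profiles, config.gamma)
    K = combine_kernels([K_seq, K_gip], config.betas)
    if config.psd_repair:
        K = nearest_psd(K)
    fitted = train(K, data, params)
    fitted.norm_constants = (mn, mx)
    return PTMPredictor(
        model=fitted,
        support_windows=[windows[i] for i in fitted.support_idx],
        support_profiles=profiles.A[fitted.support_idx].copy(),
        ptm_names=list(profiles.ptm_names),
        target_ptm=data.target_ptm,
        config=config,
    )


def score_candidates(
    predictor: PTMPredictor,
    candidate_windows: Sequence[PeptideWindow],
    candidate_profiles: InteractionProfileMatrix,
) -> np.ndarray:
    """Decision values for candidate sites against the support sites.

    The target-PTM column of the candidates is treated as zero: by
    definition a candidate has no experimental evidence for the PTM
    being predicted.
    """
    cand_ids = [w.site_id for w in candidate_windows]
    if candidate_profiles.site_ids != cand_ids:
        raise ValueError("candidate windows/profiles are not aligned")
    if candidate_profiles.ptm_names != predictor.ptm_names:
        raise ValueError("candidate profiles use a different PTM column ordering")
    mn, mx = predictor.model.norm_constants
    S_cross = seq_similarity_cross(
        candidate_windows, predictor.support_windows, blosum62()
    )
    K_seq_cross = apply_normalization(S_cross, mn, mx)
    masked = mask_profiles(candidate_profiles, cand_ids, predictor.target_ptm)
    K_gip_cross = gip_cross(
        masked.A, predictor.support_profiles, predictor.config.gamma
    )
    K_cross = combine_blocks(
        [K_seq_cross, K_gip_cross], predictor.config.betas
    )
    return decision_values(predictor.model, K_cross)


PREDICTOR_FORMAT_VERSION = 1


def save_predictor(predictor: PTMPredictor, path: str | Path) -> None:
    """Write a predictor (model + support context) as one versioned JSON file."""
    m = predictor.model
    doc = {
        "format": "ptmsvm-predictor",
        "version": PREDICTOR_FORMAT_VERSION,
        "dual_coefs": m.dual_coefs.tolist(),
        "bias": m.bias,
        "support_ids": m.support_ids,
        "support_idx": m.support_idx.tolist(),
        "class_penalties": {str(k): v for k, v in m.class_penalties.items()},
        "params": {
            "C": m.params.C,
            "balanced": m.params.balanced,
            "probability": m.params.probability,
            "seed": m.params.seed,
        },
        "norm_constants": list(m.norm_constants) if m.norm_constants else None,
        "platt": list(m.platt) if m.platt else None,
        "support_windows": [w.residues for w in predictor.support_windows],
        "support_profiles": predictor.support_profiles.tolist(),
        "ptm_names": predictor.ptm_names,
        "target_ptm": predictor.target_ptm,
        "gamma": predictor.config.gamma,
        "betas": list(predictor.config.betas),
        "psd_repair": predictor.config.psd_repair,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_predictor(path: str | Path) -> PTMPredictor:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "ptmsvm-predictor":
        raise ValueError(f"{path}: not a ptmsvm predictor file")
    if doc.get("version") != PREDICTOR_FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported predictor format version {doc.get('version')!r}"
        )
    fitted = TrainedModel(
        dual_coefs=np.array(doc["dual_coefs"], dtype=float),
        bias=float(doc["bias"]),
        support_ids=list(doc["support_ids"]),
        support_idx=np.array(doc["support_idx"], dtype=int),
        class_penalties={int(k): float(v) for k, v in doc["class_penalties"].items()},
        params=ModelParams(**doc["params"]),
        norm_constants=tuple(doc["norm_constants"]) if doc["norm_constants"] else None,
        platt=tuple(doc["platt"]) if doc["platt"] else None,
    )
    support_windows = [
        PeptideWindow(sid, residues)
        for sid, residues in zip(doc["support_ids"], doc["support_windows"])
    ]
    return PTMPredictor(
        model=fitted,
        support_windows=support_windows,
        support_profiles=np.array(doc["support_profiles"], dtype=np.int8),
        ptm_names=list(doc["ptm_names"]),
        target_ptm=doc["target_ptm"],
        config=KernelConfig(
            gamma=doc["gamma"], betas=tuple(doc["betas"]), psd_repair=doc["psd_repair"]
        ),
    )


def rank_candidates(
    predictor: PTMPredictor,
    candidate_windows: Sequence[PeptideWindow],
    candidate_profiles: InteractionProfileMatrix,
) -> list[tuple[str, float]]:
    """Candidates sorted by predicted probability, descending.

    Ties are broken by site id, lexicographically.  Requires a model
    fitted with ``probability=True``.
    """
    if not candidate_windows:
        return []
    scores = score_candidates(predictor, candidate_windows, candidate_profiles)
    probs = predict_proba(predictor.model, scores)
    pairs = [(w.site_id, float(p)) for w, p in zip(candidate_windows, probs)]
    return sorted(pairs, key=lambda item: (-item[1], item[0]))
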