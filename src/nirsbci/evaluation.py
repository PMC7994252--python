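"""Evaluation harnesses: LOSO cross-validation, calibration curves, statistics.

*Leave-one-subject-out* (LOSO) cross-validation operationalizes
"subject-independent": for each subject, a classifier is trained on every
other subject's trials and tested on the held-out subject, so no
test-subject sample influences training, validation splitting, or
normalization.  A trial-fingerprint audit enforces this.

The *pseudo-online* simulation measures the subject-dependent alternative:
for each subject, the chronologically first N trials per class train a
shrinkage LDA and the remaining 30 − N are tested, tracing accuracy as a
function of calibration length.

Classifier comparisons use the exact Wilcoxon signed-rank test on paired
per-subject accuracies (full sign-pattern enumeration up to n = 25, normal
approximation with continuity and tie correction beyond).
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np

from . import linear_models, neural_models
from .preprocess import (EpochSet, extract_mean_features, zscore_time)

__all__ = ["LosoFold", "EvaluationReport", "LearningCurvePoint",
           "make_loso_folds", "run_loso", "run_pseudo_online",
           "wilcoxon_signed_rank", "MODEL_BUILDERS"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LosoFold:
    test_subject: str
    train_subjects: tuple[str, ...]
    n_train_samples: int
    n_test_samples: int


@dataclass
class EvaluationReport:
    per_subject_accuracy: dict[str, float]
    model_tag: str
    folds: list[LosoFold]
    rng_seed: int
    confusion: np.ndarray | None = None  # pooled 2x2, rows true, cols predicted

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.per_subject_accuracy.values())))

    @property
    def sd(self) -> float:
        return float(np.std(list(self.per_subject_accuracy.values()), ddof=1))

    @property
    def sem(self) -> float:
        return self.sd / np.sqrt(len(self.per_subject_accuracy))

    def to_dict(self) -> dict:
        return {"model": self.model_tag, "rng_seed": self.rng_seed,
                "per_subject_accuracy": self.per_subject_accuracy,
                "mean": self.mean, "sd": self.sd, "sem": self.sem}


@dataclass
class LearningCurvePoint:
    n_train_per_class: int
    n_test_per_class: int
    per_subject_accuracy: dict[str, float]

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.per_subject_accuracy.values())))


def make_loso_folds(subject_trial_counts: dict[str, int] | list[str],
                    trials_per_subject: int | None = None) -> list[LosoFold]:
    """One fold per subject: train on everyone else, test on the holdout.

    Accepts either a ``{subject: n_trials}`` map or a subject list plus a
    common per-subject trial count.
    """
    if isinstance(subject_trial_counts, dict):
        counts = dict(subject_trial_counts)
    else:
        subjects = list(subject_trial_counts)
        if len(set(subjects)) != len(subjects):
            raise ValueError("duplicate subject ids")
        if trials_per_subject is None:
            raise ValueError("trials_per_subject required with a subject list")
        counts = {s: trials_per_subject for s in subjects}
    if len(counts) < 2:
        raise ValueError("LOSO requires at least two subjects")
    total = sum(counts.values())
    folds = []
    for s in counts:
        folds.append(LosoFold(test_subject=s,
                              train_subjects=tuple(x for x in counts if x != s),
                              n_train_samples=total - counts[s],
                              n_test_samples=counts[s]))
    return folds


def _fingerprints(data: np.ndarray) -> set[bytes]:
    return {hashlib.sha1(np.ascontiguousarray(trial).tobytes()).digest()
            for trial in data}


def _fit_predict(model_name, train_ep: EpochSet, test_ep: EpochSet, seed,
                 train_spec=None):
    """Fit one classifier on training epochs and predict test labels."""
    if model_name == "slda":
        m = linear_models.fit_slda(extract_mean_features(train_ep))
        return linear_models.predict_lda(m, extract_mean_features(test_ep))
    if model_name == "bagging":
        m = linear_models.fit_bagged_rlda(extract_mean_features(train_ep), seed=seed)
        return linear_models.predict_vote(m, extract_mean_features(test_ep))
    if model_name in ("cnn", "cnn_bnrelu", "eegnet"):
        spec = train_spec or neural_models.TrainSpec(rng_seed=seed)
        n_time, n_wide = train_ep.n_time, train_ep.data.shape[2]
        if model_name == "eegnet":
            model = neural_models.build_eegnet(
                neural_models.EegnetConfig(input_shape=(n_wide, n_time, 1)), seed=seed)
        else:
            norm = "evonorm" if model_name == "cnn" else "batchnorm_relu"
            model = neural_models.build_proposed_cnn(
                neural_models.ProposedCnnConfig(input_shape=(n_time, n_wide),
                                                normalization=norm), seed=seed)
        model, _ = neural_models.train(model, zscore_time(train_ep), spec)
        return neural_models.predict_labels(model, zscore_time(test_ep))
    raise ValueError(f"unknown model {model_name!r}; expected slda|bagging|cnn|eegnet")


MODEL_BUILDERS = ("slda", "bagging", "cnn", "cnn_bnrelu", "eegnet")


def run_loso(ep: EpochSet, model: str = "slda", seed: int = 0,
             train_spec: "neural_models.TrainSpec | None" = None,
             audit_leakage: bool = True) -> EvaluationReport:
    """LOSO evaluation of one classifier over a pooled epoch set.

    ``ep`` holds every subject's preprocessed (un-normalized) epochs.
    Normalization (per-trial z-scoring) and validation splits are computed
    inside each fold from training subjects only; a fingerprint audit
    asserts that no test trial enters training.
    """
    if ep.normalized:
        raise ValueError("pass un-normalized epochs; per-fold pipelines normalize")
    subjects = list(dict.fromkeys(ep.subject_ids.tolist()))
    counts = {s: int((ep.subject_ids == s).sum()) for s in subjects}
    folds = make_loso_folds(counts)
    per_subject = {}
    confusion = np.zeros((2, 2), dtype=int)
    for fold in folds:
        test_mask = ep.subject_ids == fold.test_subject
        train_ep = ep.select(~test_mask)
        test_ep = ep.select(test_mask)
        if np.unique(train_ep.labels).size < 2:
            raise ValueError(f"fold {fold.test_subject}: training data single-class")
        if audit_leakage and _fingerprints(train_ep.data) & _fingerprints(test_ep.data):
            raise AssertionError(
                f"fold {fold.test_subject}: test trial found in training data")
        pred = _fit_predict(model, train_ep, test_ep, seed, train_spec)
        acc = float(np.mean(pred == test_ep.labels))
        per_subject[fold.test_subject] = acc
        for t, p in zip(test_ep.labels, pred):
            confusion[t, p] += 1
        logger.info("LOSO %s fold %s: accuracy %.3f", model, fold.test_subject, acc)
    return EvaluationReport(per_subject, model, folds, seed, confusion)


def run_pseudo_online(ep: EpochSet, n_grid, seed: int = 0) -> list[LearningCurvePoint]:
    """Subject-dependent learning curve with shrinkage LDA.

    For each subject and each N in ``n_grid``, the chronologically first N
    trials of each class train the classifier and the remaining trials per
    class are tested.  Only that subject's data is used.
    """
    if ep.normalized:
        raise ValueError("pass un-normalized epochs")
    subjects = list(dict.fromkeys(ep.subject_ids.tolist()))
    per_subject_counts = {
        s: min(int((ep.labels[ep.subject_ids == s] == c).sum()) for c in (0, 1))
        for s in subjects}
    trials_per_class = min(per_subject_counts.values())
    points = []
    for n_train in n_grid:
        n_train = int(n_train)
        if not 1 <= n_train <= trials_per_class - 1:
            raise ValueError(f"N={n_train} outside [1, {trials_per_class - 1}]")
        accs = {}
        for s in subjects:
            mask = ep.subject_ids == s
            sub = ep.select(mask)
            # chronological order is the stored trial order per subject
            train_idx, test_idx = [], []
            seen = {0: 0, 1: 0}
            for i, lab in enumerate(sub.labels):
                (train_idx if seen[int(lab)] < n_train else test_idx).append(i)
                seen[int(lab)] += 1
            m = linear_models.fit_slda(
                extract_mean_features(sub.select(np.asarray(train_idx))))
            test = sub.select(np.asarray(test_idx))
            pred = linear_models.predict_lda(m, extract_mean_features(test))
            accs[s] = float(np.mean(pred == test.labels))
        points.append(LearningCurvePoint(n_train, trials_per_class - n_train, accs))
    return points


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p by enumerating the 2^n sign-assignment distribution.

    Works on doubled ranks so mid-ranks (multiples of 0.5) become integers;
    the null distribution is built by dynamic programming over achievable
    doubled-rank sums.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.rint(2.0 * w_plus))
    p_le = counts[: w2 + 1].sum()
    p_ge = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(acc_a, acc_b, exact_max_n: int = 25) -> tuple[float, float]:
    """Paired two-sided Wilcoxon signed-rank test; returns (W+, p).

    Zero differences are dropped (Wilcoxon's rule) and tied magnitudes
    mid-ranked.  Exact enumeration for n ≤ ``exact_max_n``, otherwise the
    normal approximation with continuity and tie corrections.
    """
    from scipy.stats import rankdata, norm

    a = np.asarray(acc_a, dtype=float)
    b = np.asarray(acc_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors of equal length required")
    d = a - b
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero; test undefined")
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        return w_plus, _exact_signed_rank_p(ranks, w_plus)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_corr = (tie_counts ** 3 - tie_counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    return w_plus, float(min(1.0, 2.0 * norm.sf(abs(z))))
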