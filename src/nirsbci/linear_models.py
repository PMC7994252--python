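"""Linear baselines: shrinkage LDA and a bagged ensemble of regularized LDA.

Both classifiers operate on windowed temporal-mean features
(:class:`nirsbci.preprocess.FeatureMatrix`).  The binary decision rule is
``sign(w·x + b)`` with class encoding IS=0, MA=1; exact-zero scores resolve
to IS and are counted in the model diagnostics.

Shrinkage regularizes the pooled within-class covariance toward a scaled
identity,

    Sigma_tilde = (1 - gamma) * Sigma_hat + gamma * nu * I,

with ``nu`` the mean of Sigma_hat's diagonal (average eigenvalue).  With
``gamma = "analytic"`` the intensity is the Ledoit–Wolf estimate, clipped to
[0, 1] — the standard remedy when features outnumber training trials, as in
96-dimensional fNIRS feature vectors from a few hundred trials.

The bagging ensemble follows the common BCI configuration: 50 weak
regularized-LDA learners (fixed gamma = 0.1), each trained on a
with-replacement bootstrap resample of the full training-set size, combined
by majority vote with a mean-decision-score tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import ledoit_wolf

from .preprocess import FeatureMatrix

__all__ = ["LdaModel", "BaggedEnsemble", "fit_slda", "predict_lda",
           "decision_scores", "fit_bagged_rlda", "predict_vote"]

IS, MA = 0, 1


@dataclass
class LdaModel:
    weights: np.ndarray
    bias: float
    shrinkage_intensity: float
    class_order: tuple[int, int] = (IS, MA)
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.weights.shape[0]


def _class_stats(X: np.ndarray, y: np.ndarray):
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes; got {classes.tolist()}")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"need >= 2 samples per class; class {c} has {(y == c).sum()}")
    mu0 = X[y == IS].mean(axis=0)
    mu1 = X[y == MA].mean(axis=0)
    centered = X - np.where((y == MA)[:, None], mu1, mu0)
    # pooled covariance, divisor n (population convention, fixed for exact tests)
    sigma = centered.T @ centered / X.shape[0]
    return mu0, mu1, centered, sigma


def fit_slda(features: FeatureMatrix, shrinkage="analytic") -> LdaModel:
    """Fit shrinkage LDA; ``shrinkage`` is ``"analytic"`` or a fixed gamma in [0, 1]."""
    X, y = features.values, features.labels
    mu0, mu1, centered, sigma = _class_stats(X, y)
    p = X.shape[1]
    nu = np.trace(sigma) / p
    if shrinkage == "analytic":
        _, gamma = ledoit_wolf(centered, assume_centered=True)
        gamma = float(np.clip(gamma, 0.0, 1.0))
    else:
        gamma = float(shrinkage)
        if not 0.0 <= gamma <= 1.0:
            raise ValueError("shrinkage gamma must lie in [0, 1]")
    sigma_t = (1.0 - gamma) * sigma + gamma * nu * np.eye(p)
    try:
        w = np.linalg.solve(sigma_t, mu1 - mu0)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "regularized covariance is singular; use gamma > 0") from e
    b = -float(w @ (mu0 + mu1)) / 2.0
    return LdaModel(w, b, gamma, diagnostics={"nu": float(nu)})


def decision_scores(model: LdaModel, features) -> np.ndarray:
    X = features.values if isinstance(features, FeatureMatrix) else np.asarray(features)
    if X.shape[1] != model.n_features:
        raise ValueError(f"feature dimension {X.shape[1]} != model dimension "
                         f"{model.n_features}")
    return X @ model.weights + model.bias


def predict_lda(model: LdaModel, features) -> np.ndarray:
    """Predict labels: MA where w·x + b > 0, IS otherwise (zeros count as ties)."""
    s = decision_scores(model, features)
    model.diagnostics["n_ties"] = model.diagnostics.get("n_ties", 0) + int((s == 0).sum())
    return np.where(s > 0, MA, IS)


@dataclass
class BaggedEnsemble:
    learners: list[LdaModel]
    resample_fraction: float
    gamma: float
    rng_seed: int
    n_redraws: int = 0

    @property
    def n_learners(self) -> int:
        return len(self.learners)


def fit_bagged_rlda(features: FeatureMatrix, n_learners: int = 50,
                    resample_fraction: float = 1.0, gamma: float = 0.1,
                    seed: int = 0, _identity_resample: bool = False) -> BaggedEnsemble:
    """Bagging of regularized LDA: 50 learners on full-size bootstrap resamples.

    A resample missing a class is redrawn (count recorded).  With the test
    hook ``_identity_resample`` every learner sees the full training set
    without replacement, reproducing a single ``fit_slda(gamma)`` learner.
    """
    X, y = features.values, features.labels
    _class_stats(X, y)  # validates two classes with >= 2 samples each
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    m = int(round(resample_fraction * n))
    learners, n_redraws = [], 0
    for _ in range(n_learners):
        if _identity_resample:
            idx = np.arange(n)
        else:
            idx = rng.integers(0, n, size=m)
            while np.unique(y[idx]).size < 2 or min((y[idx] == c).sum() for c in (IS, MA)) < 2:
                n_redraws += 1
                idx = rng.integers(0, n, size=m)
        sub = FeatureMatrix(X[idx], y[idx], features.feature_names)
        learners.append(fit_slda(sub, shrinkage=gamma))
    return BaggedEnsemble(learners, resample_fraction, gamma, seed, n_redraws)


def predict_vote(ens: BaggedEnsemble, features) -> np.ndarray:
    """Majority vote across learners; exact ties break by mean decision score."""
    scores = np.stack([decision_scores(m, features) for m in ens.learners])  # (L, n)
    votes_ma = (scores > 0).sum(axis=0)
    half = ens.n_learners / 2.0
    out = np.where(votes_ma > half, MA, IS)
    tied = votes_ma == half
    if np.any(tied):
        out[tied] = np.where(scores[:, tied].mean(axis=0) > 0, MA, IS)
    return out
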