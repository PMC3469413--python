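"""Single-trial leave-one-out decoding of response ensembles.

Each trial of each stimulus is decoded against a codebook of per-stimulus
mean responses computed without that trial (leave-one-out cross-validation).
Six classifiers are available:

``nearest_mean``
    template matching: decode to the stimulus whose mean response has the
    smallest Euclidean distance to the test vector.  This is the Bayes
    optimal decoder when the stimulus-conditional ensembles are independent
    multivariate normal with equal variances.
``linear`` / ``quadratic``
    Gaussian discriminants with a covariance pooled across stimuli
    (linear) or estimated per stimulus (quadratic).  To avoid
    ill-conditioned matrices on discrete counts, i.i.d. Gaussian jitter of
    standard deviation ``regularization_sd`` is added to all counts, redrawn
    on every leave-one-out fold.
``poisson_nb`` / ``multinomial_nb``
    naive Bayes with independent per-bin Poisson counts, or per-bin
    discrete count distributions with add-one smoothing over the observed
    count range.
``knn``
    majority vote among the k Euclidean-nearest training trials.

All ties (equal distances, likelihoods, or votes) break deterministically to
the lowest stimulus index.  A separate test ensemble may be supplied so that
the codebook can be built from temporally jittered windows while each test
trial is read out at its true position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ClassifierSpec",
    "ResponseEnsemble",
    "DecodingResult",
    "DecodingError",
    "loo_decode",
    "nb_loglik",
    "CLASSIFIER_NAMES",
]

CLASSIFIER_NAMES = (
    "nearest_mean",
    "linear",
    "quadratic",
    "poisson_nb",
    "multinomial_nb",
    "knn",
)


class DecodingError(ValueError):
    """Raised for invalid ensembles or singular covariance estimates."""


@dataclass(frozen=True)
class ClassifierSpec:
    name: str = "nearest_mean"
    k: int = 5  # knn only
    regularization_sd: float = 0.001  # linear/quadratic only

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(f"unknown classifier {self.name!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.regularization_sd < 0:
            raise ValueError("regularization_sd must be non-negative")


@dataclass
class ResponseEnsemble:
    """Responses organised as stimulus -> (n_trials, dimension) count array."""

    responses: list[np.ndarray]

    def __post_init__(self) -> None:
        self.responses = [np.atleast_2d(np.asarray(a, dtype=float)) for a in self.responses]
        if not self.responses:
            raise DecodingError("empty ensemble")
        d = self.responses[0].shape[1]
        for i, a in enumerate(self.responses):
            if a.shape[1] != d:
                raise DecodingError("all response vectors must share one dimension")
            if a.shape[0] < 2:
                raise DecodingError(f"stimulus {i} has fewer than 2 trials")

    @property
    def K(self) -> int:
        return len(self.responses)

    @property
    def dimension(self) -> int:
        return self.responses[0].shape[1]

    @property
    def n_total(self) -> int:
        return sum(a.shape[0] for a in self.responses)


@dataclass
class DecodingResult:
    """Percent correct plus confusion matrix for one decoding run.

    Confusion rows are true stimuli, columns decoded stimuli.  For runs that
    average over repeated shuffles the fields hold the per-shuffle mean (the
    confusion matrix then carries fractional entries).
    """

    percent_correct: float
    confusion: np.ndarray
    per_stimulus_accuracy: np.ndarray

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray, K: int) -> "DecodingResult":
        confusion = np.zeros((K, K), dtype=int)
        np.add.at(confusion, (y_true, y_pred), 1)
        row = confusion.sum(axis=1)
        diag = np.diag(confusion)
        return cls(
            percent_correct=100.0 * diag.sum() / row.sum(),
            confusion=confusion,
            per_stimulus_accuracy=diag / row,
        )

    def to_json(self) -> dict:
        return {
            "percent_correct": float(self.percent_correct),
            "confusion": np.asarray(self.confusion).tolist(),
            "per_stimulus_accuracy": np.asarray(self.per_stimulus_accuracy).tolist(),
        }


def _check_pair(train: ResponseEnsemble, test: ResponseEnsemble) -> None:
    if train.K != test.K or train.dimension != test.dimension:
        raise DecodingError("train and test ensembles must have identical layout")
    for a, b in zip(train.responses, test.responses):
        if a.shape != b.shape:
            raise DecodingError("train and test ensembles must have identical layout")


def _flatten(ensemble: ResponseEnsemble) -> tuple[np.ndarray, np.ndarray]:
    X = np.vstack(ensemble.responses)
    y = np.concatenate(
        [np.full(a.shape[0], c, dtype=int) for c, a in enumerate(ensemble.responses)]
    )
    return X, y


def _class_counts(y: np.ndarray, K: int) -> np.ndarray:
    return np.bincount(y, minlength=K)


def _predict_nearest_mean(train: ResponseEnsemble, test: ResponseEnsemble) -> np.ndarray:
    Xtr, y = _flatten(train)
    Xte, _ = _flatten(test)
    K = train.K
    ns = _class_counts(y, K).astype(float)
    sums = np.zeros((K, train.dimension))
    np.add.at(sums, y, Xtr)
    means = sums / ns[:, None]
    # distances to full-data means; own-stimulus mean corrected per fold
    D = ((Xte[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
    own_means = (sums[y] - Xtr) / (ns[y] - 1.0)[:, None]
    D[np.arange(len(y)), y] = ((Xte - own_means) ** 2).sum(axis=1)
    return np.argmin(D, axis=1)


def _poisson_ll(X: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Log-likelihood of count rows X under per-stimulus Poisson means lam
    (K, d); returns (n, K)."""
    const = gammaln(X + 1.0).sum(axis=1)
    return X @ np.log(lam).T - lam.sum(axis=1)[None, :] - const[:, None]


def _predict_poisson_nb(train: ResponseEnsemble, test: ResponseEnsemble) -> np.ndarray:
    Xtr, y = _flatten(train)
    Xte, _ = _flatten(test)
    K, d = train.K, train.dimension
    ns = _class_counts(y, K).astype(float)
    sums = np.zeros((K, d))
    np.add.at(sums, y, Xtr)
    # zero-mean bins are floored at 1/(2 * n_training_trials)
    lam_full = np.maximum(sums / ns[:, None], 1.0 / (2.0 * ns[:, None]))
    L = _poisson_ll(Xte, lam_full)
    lam_own = (sums[y] - Xtr) / (ns[y] - 1.0)[:, None]
    lam_own = np.maximum(lam_own, 1.0 / (2.0 * (ns[y] - 1.0))[:, None])
    L_own = (
        (Xte * np.log(lam_own)).sum(axis=1)
        - lam_own.sum(axis=1)
        - gammaln(Xte + 1.0).sum(axis=1)
    )
    L[np.arange(len(y)), y] = L_own
    return np.argmax(L, axis=1)


def _predict_multinomial_nb(train: ResponseEnsemble, test: ResponseEnsemble) -> np.ndarray:
    Xtr, y = _flatten(train)
    Xte, _ = _flatten(test)
    K, d = train.K, train.dimension
    ns = _class_counts(y, K)
    Xtri = np.rint(Xtr).astype(int)
    Xtei = np.rint(Xte).astype(int)
    vmax = int(max(Xtri.max(initial=0), Xtei.max(initial=0)))
    tables = np.zeros((K, d, vmax + 1))
    cols = np.broadcast_to(np.arange(d), Xtri.shape)
    np.add.at(tables, (y[:, None], cols, Xtri), 1.0)
    # add-one smoothing over the observed count range 0..vmax
    logp = np.log(tables + 1.0) - np.log(ns + vmax + 1.0)[:, None, None]
    n = len(y)
    L = np.empty((n, K))
    idx = np.arange(d)
    for c in range(K):
        L[:, c] = logp[c][idx, Xtei].sum(axis=1)
    # own-stimulus tables exclude the test trial's training vector
    match = (Xtri == Xtei).astype(float)
    own_counts = tables[y[:, None], idx[None, :], Xtei] - match
    L_own = np.log(own_counts + 1.0).sum(axis=1) - d * np.log(ns[y] - 1 + vmax + 1)
    L[np.arange(n), y] = L_own
    return np.argmax(L, axis=1)


def _predict_knn(train: ResponseEnsemble, test: ResponseEnsemble, k: int) -> np.ndarray:
    Xtr, y = _flatten(train)
    Xte, _ = _flatten(test)
    n = len(y)
    if k >= n:
        raise DecodingError("k must be smaller than the total number of trials")
    D = ((Xte[:, None, :] - Xtr[None, :, :]) ** 2).sum(axis=2)
    D[np.arange(n), np.arange(n)] = np.inf  # the test trial never votes for itself
    pred = np.empty(n, dtype=int)
    for t in range(n):
        order = np.lexsort((y, D[t]))  # distance first, stimulus index breaks ties
        votes = np.bincount(y[order[:k]], minlength=train.K)
        pred[t] = int(np.argmax(votes))  # vote ties -> lowest stimulus index
    return pred


def _predict_gaussian(
    train: ResponseEnsemble,
    test: ResponseEnsemble,
    pooled: bool,
    jitter_sd: float,
    rng: np.random.Generator,
    cov_override: np.ndarray | None = None,
) -> np.ndarray:
    """Linear (pooled covariance) or quadratic (per-stimulus) discriminant.

    ``cov_override`` substitutes a fixed pooled covariance (used to verify
    the nearest-mean equivalence with an identity covariance).
    """
    Xtr, y = _flatten(train)
    Xte, _ = _flatten(test)
    K, d = train.K, train.dimension
    n = len(y)
    pred = np.empty(n, dtype=int)
    for t in range(n):
        jitter = rng.normal(0.0, jitter_sd, size=(n, d)) if jitter_sd > 0 else 0.0
        Xj = Xtr + jitter
        xt = Xte[t] + (rng.normal(0.0, jitter_sd, size=d) if jitter_sd > 0 else 0.0)
        mask = np.ones(n, dtype=bool)
        mask[t] = False
        Xf, yf = Xj[mask], y[mask]
        ns = _class_counts(yf, K).astype(float)
        sums = np.zeros((K, d))
        np.add.at(sums, yf, Xf)
        means = sums / ns[:, None]
        resid = Xf - means[yf]
        scores = np.empty(K)
        if pooled:
            if cov_override is not None:
                cov = np.asarray(cov_override, dtype=float)
            else:
                cov = resid.T @ resid / (len(yf) - K)
            try:
                inv = np.linalg.inv(np.atleast_2d(cov))
            except np.linalg.LinAlgError:
                raise DecodingError("pooled covariance is singular after regularization")
            diff = means - xt[None, :]
            scores = -0.5 * np.einsum("ki,ij,kj->k", diff, inv, diff)
        else:
            for c in range(K):
                Z = Xf[yf == c]
                mu = means[c]
                R = Z - mu
                cov = np.atleast_2d(R.T @ R / (len(Z) - 1))
                sign, logdet = np.linalg.slogdet(cov)
                if sign <= 0:
                    raise DecodingError(
                        f"covariance for stimulus {c} is singular after regularization"
                    )
                diff = xt - mu
                scores[c] = -0.5 * (logdet + diff @ np.linalg.solve(cov, diff))
        pred[t] = int(np.argmax(scores))
    return pred


def loo_decode(
    ensemble: ResponseEnsemble,
    spec: ClassifierSpec = ClassifierSpec(),
    rng: np.random.Generator | None = None,
    test_ensemble: ResponseEnsemble | None = None,
) -> DecodingResult:
    """Leave-one-out decode an ensemble with the requested classifier.

    When ``test_ensemble`` is given, the codebook (training side) is built
    from ``ensemble`` while each left-out trial is read out from the
    corresponding entry of ``test_ensemble``; both must have identical
    layout.  This implements codebook-only temporal jitter.
    """
    if not isinstance(ensemble, ResponseEnsemble):
        ensemble = ResponseEnsemble(ensemble)
    test = ensemble if test_ensemble is None else test_ensemble
    if not isinstance(test, ResponseEnsemble):
        test = ResponseEnsemble(test)
    _check_pair(ensemble, test)
    if rng is None:
        rng = np.random.default_rng(0)

    if spec.name == "nearest_mean":
        pred = _predict_nearest_mean(ensemble, test)
    elif spec.name == "poisson_nb":
        pred = _predict_poisson_nb(ensemble, test)
    elif spec.name == "multinomial_nb":
        pred = _predict_multinomial_nb(ensemble, test)
    elif spec.name == "knn":
        pred = _predict_knn(ensemble, test, spec.k)
    elif spec.name == "linear":
        pred = _predict_gaussian(ensemble, test, True, spec.regularization_sd, rng)
    else:  # quadratic
        pred = _predict_gaussian(ensemble, test, False, spec.regularization_sd, rng)

    _, y_true = _flatten(test)
    return DecodingResult.from_predictions(y_true, pred, ensemble.K)


def nb_loglik(counts: np.ndarray, model: np.ndarray) -> float:
    """Naive-Bayes log-likelihood of one count vector under one stimulus model.

    ``model`` is either a 1-D array of per-bin Poisson means, or a 2-D
    ``(n_bins, vmax + 1)`` array of per-bin log-probabilities (multinomial
    path, already smoothed).  Decoding picks the argmax over stimuli under a
    uniform prior.
    """
    counts = np.asarray(counts, dtype=float)
    model = np.asarray(model)
    if model.ndim == 1:
        lam = np.maximum(model.astype(float), np.finfo(float).tiny)
        return float((counts * np.log(lam) - lam - gammaln(counts + 1.0)).sum())
    if model.ndim == 2:
        idx = np.rint(counts).astype(int)
        if np.any(idx < 0) or np.any(idx >= model.shape[1]):
            raise ValueError("observed count outside the model's count range")
        return float(model[np.arange(model.shape[0]), idx].sum())
    raise ValueError("model must be 1-D Poisson means or a 2-D log-probability table")
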