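"""The three extrusive OOD confidence scores: MSP, Mahalanobis, energy.

All three wrap an already-trained classifier without touching its weights,
and all are exposed under one convention: **higher score = more ID-like**.

MSP (maximum softmax probability)
    ``max_i softmax(logits)_i`` — the classifier's own top-class confidence.

MAH (class-conditional Mahalanobis confidence)
    Fit one Gaussian per class on penultimate-layer features of held-out ID
    data (per-class means ``mu_c``, one covariance ``Sigma`` tied across
    classes); score a sample by the *negated* squared Mahalanobis distance to
    the nearest class mean:

        M(x) = max_c -(f(x) - mu_c)^T Sigma^{-1} (f(x) - mu_c)  <=  0.

EBM (energy score)
    The Helmholtz free energy of the logit vector,
    ``E(x) = -T log sum_i exp(f_i(x) / T)`` with temperature T (default 1);
    low energy indicates ID, so the confidence is ``-E(x)``.

Each score is available as a plain function and as a scikit-learn style
detector estimator (``fit`` / ``score_samples`` / ``get_params``); only the
Mahalanobis detector has fitting state, which is the mechanism behind its
sensitivity — and MSP/EBM's exact insensitivity — to the composition of the
detector-fitting set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .classifier_adapter import ClassifierAdapter
from .records import FeatureTable

METHOD_MSP = "MSP"
METHOD_MAH = "MAH"
METHOD_EBM = "EBM"
METHODS = (METHOD_MSP, METHOD_MAH, METHOD_EBM)


def _as_logit_batch(logits: np.ndarray) -> tuple[np.ndarray, bool]:
    arr = np.asarray(logits, dtype=float)
    scalar = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] < 2:
        raise ValueError("logit vectors must have length >= 2")
    if not np.isfinite(arr).all():
        raise ValueError("logits must be finite")
    return arr, scalar


def msp_confidence(logits: np.ndarray) -> np.ndarray | float:
    """Maximum softmax probability, in (0, 1]; overflow-safe.

    Accepts one logit vector of length C or a batch of shape (n, C).
    """
    arr, scalar = _as_logit_batch(logits)
    z = arr - arr.max(axis=1, keepdims=True)
    e = np.exp(z)
    out = e.max(axis=1) / e.sum(axis=1)
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class EnergyConfig:
    """Temperature T of the Gibbs distribution; T = 1 in the study setting."""

    temperature: float = 1.0

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")


def energy(logits: np.ndarray, config: EnergyConfig | float = EnergyConfig()) -> np.ndarray | float:
    """Free energy E(x) = -T log sum_i exp(f_i(x)/T); lower = more ID-like."""
    T = config.temperature if isinstance(config, EnergyConfig) else float(config)
    if not T > 0:
        raise ValueError("temperature must be positive")
    arr, scalar = _as_logit_batch(logits)
    out = -T * logsumexp(arr / T, axis=1)
    return float(out[0]) if scalar else out


def energy_confidence(
    logits: np.ndarray, config: EnergyConfig | float = EnergyConfig()
) -> np.ndarray | float:
    """Negated energy, so that higher means more ID-like."""
    e = energy(logits, config)
    return -e if not np.isscalar(e) else -float(e)


# ----------------------------------------------------------- Gaussian model


@dataclass
class GaussianClassModel:
    """Per-class means and (tied or per-class) covariance with its inverse.

    ``covariance`` has shape (d, d) when tied, (C, d, d) otherwise;
    ``precision`` is the inverse of the diagonally regularized covariance
    (``covariance + reg_eps * I``).
    """

    means: np.ndarray
    covariance: np.ndarray
    precision: np.ndarray
    reg_eps: float
    tied: bool = True
    classes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariance = np.asarray(self.covariance, dtype=float)
        self.precision = np.asarray(self.precision, dtype=float)
        covs = self.covariance if self.covariance.ndim == 3 else self.covariance[None]
        for S in covs:
            if not np.allclose(S, S.T, atol=1e-8):
                raise ValueError("covariance must be symmetric")

    @property
    def n_classes(self) -> int:
        return self.means.shape[0]

    @property
    def feature_dim(self) -> int:
        return self.means.shape[1]


def _default_reg_eps(cov: np.ndarray) -> float:
    # scale-aware ridge: 1e-6 of the mean variance per dimension
    d = cov.shape[-1]
    tr = np.trace(cov) if cov.ndim == 2 else float(np.mean([np.trace(S) for S in cov]))
    return 1e-6 * float(tr) / d


def _invert(cov: np.ndarray, reg_eps: float) -> np.ndarray:
    d = cov.shape[-1]
    ridge = cov + reg_eps * np.eye(d)
    try:
        return np.linalg.inv(ridge)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "covariance is singular; increase reg_eps to regularize the inverse"
        ) from err


def fit_gaussian_model(
    features: np.ndarray,
    labels: Sequence[int] | np.ndarray,
    reg_eps: float | None = None,
    tied: bool = True,
) -> GaussianClassModel:
    """Fit per-class Gaussian parameters on detector-fitting (ID2) features.

    Means are per-class empirical means.  With ``tied=True`` (default) the
    covariance is pooled within-class scatter divided by the total sample
    count, shared by all classes; ``tied=False`` fits one covariance per
    class (each an MLE with its own class count).  ``reg_eps`` (default
    ``1e-6 * trace(Sigma)/d``) is added to the diagonal before inversion.

    Every class must contribute at least 2 samples.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels have different lengths")
    classes = np.unique(y)
    if len(classes) < 1:
        raise ValueError("no classes present")
    d = X.shape[1]
    means = np.empty((len(classes), d))
    scatters = np.zeros((len(classes), d, d))
    counts = np.empty(len(classes), dtype=int)
    for k, c in enumerate(classes):
        Xc = X[y == c]
        if len(Xc) < 2:
            raise ValueError(
                f"class {c!r} has {len(Xc)} sample(s); at least 2 are required"
            )
        counts[k] = len(Xc)
        means[k] = Xc.mean(axis=0)
        R = Xc - means[k]
        scatters[k] = R.T @ R

    if tied:
        cov = scatters.sum(axis=0) / counts.sum()
        eps = _default_reg_eps(cov) if reg_eps is None else float(reg_eps)
        prec = _invert(cov, eps)
    else:
        cov = scatters / counts[:, None, None]
        eps = (
            float(np.mean([_default_reg_eps(S) for S in cov]))
            if reg_eps is None
            else float(reg_eps)
        )
        prec = np.stack([_invert(S, eps) for S in cov])
    return GaussianClassModel(
        means=means, covariance=cov, precision=prec, reg_eps=eps, tied=tied,
        classes=classes,
    )


def mahalanobis_confidence(
    features: np.ndarray, model: GaussianClassModel
) -> np.ndarray | float:
    """Negated squared Mahalanobis distance to the nearest class mean (<= 0)."""
    X = np.asarray(features, dtype=float)
    scalar = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != model.feature_dim:
        raise ValueError(
            f"feature dim {X.shape[1]} does not match model dim {model.feature_dim}"
        )
    diffs = X[:, None, :] - model.means[None, :, :]  # (n, C, d)
    if model.tied:
        dists = np.einsum("ncd,de,nce->nc", diffs, model.precision, diffs)
    else:
        dists = np.einsum("ncd,cde,nce->nc", diffs, model.precision, diffs)
    out = -dists.min(axis=1)
    out = np.minimum(out, 0.0)  # guard tiny positive round-off
    return float(out[0]) if scalar else out


# ------------------------------------------------------- sklearn estimators


class MSPDetector(BaseEstimator):
    """Maximum-softmax-probability detector over logit vectors.

    Stateless: ``fit`` only records the logit width.  ``score_samples``
    returns scores in (0, 1]; higher = more ID-like.
    """

    def fit(self, X: np.ndarray, y=None) -> "MSPDetector":
        X, _ = _as_logit_batch(X)
        self.n_classes_ = X.shape[1]
        return self

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_1d(msp_confidence(X))


class EnergyDetector(BaseEstimator):
    """Energy-score detector over logit vectors; returns -E(x), higher = ID."""

    def __init__(self, temperature: float = 1.0):
        self.temperature = temperature

    def fit(self, X: np.ndarray, y=None) -> "EnergyDetector":
        X, _ = _as_logit_batch(X)
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")
        self.n_classes_ = X.shape[1]
        return self

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_1d(energy_confidence(X, self.temperature))


class MahalanobisDetector(BaseEstimator):
    """Class-conditional Gaussian detector over penultimate features.

    ``fit(X, y)`` estimates per-class means and a tied (or per-class)
    covariance on labeled ID features; ``score_samples`` returns the negated
    squared Mahalanobis distance to the nearest class mean.
    """

    def __init__(self, reg_eps: float | None = None, tied_covariance: bool = True):
        self.reg_eps = reg_eps
        self.tied_covariance = tied_covariance

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MahalanobisDetector":
        self.model_ = fit_gaussian_model(
            X, y, reg_eps=self.reg_eps, tied=self.tied_covariance
        )
        self.means_ = self.model_.means
        self.covariance_ = self.model_.covariance
        self.precision_ = self.model_.precision
        return self

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("MahalanobisDetector must be fitted before scoring")
        return np.atleast_1d(mahalanobis_confidence(X, self.model_))


# ------------------------------------------------------------ dataset-level


@dataclass
class ConfidenceSet:
    """Per-sample confidence scores for one method; higher = more ID-like."""

    method: str
    ids: np.ndarray
    domain: np.ndarray
    scores: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.domain = np.asarray(self.domain, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if not (len(self.ids) == len(self.domain) == len(self.scores)):
            raise ValueError("ConfidenceSet columns have inconsistent lengths")
        if len(self.scores) and not np.isfinite(self.scores).all():
            raise ValueError("confidence scores must be finite")

    def __len__(self) -> int:
        return len(self.scores)

    def take(self, indices) -> "ConfidenceSet":
        idx = np.asarray(indices, dtype=int)
        return ConfidenceSet(self.method, self.ids[idx], self.domain[idx], self.scores[idx])

    def id_scores(self) -> np.ndarray:
        return self.scores[[d == "ID" for d in self.domain]]

    def ood_scores(self) -> np.ndarray:
        return self.scores[[d == "OOD" for d in self.domain]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids.astype(str),
                "domain": self.domain.astype(str),
                "method": self.method,
                "score": self.scores,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "ConfidenceSet":
        frame = pd.read_csv(path)
        methods = frame["method"].unique()
        if len(methods) != 1:
            raise ValueError("score table must contain exactly one method")
        return cls(
            method=str(methods[0]),
            ids=frame["id"].astype(str).to_numpy(dtype=object),
            domain=frame["domain"].astype(str).to_numpy(dtype=object),
            scores=frame["score"].to_numpy(dtype=float),
        )


def score_dataset(
    records: FeatureTable,
    adapter: ClassifierAdapter,
    method: str,
    model: GaussianClassModel | None = None,
    config: EnergyConfig | None = None,
) -> ConfidenceSet:
    """Score every record with one method through the adapter.

    MAH consumes ``adapter.features`` and requires a fitted Gaussian model;
    MSP and EBM consume ``adapter.logits`` and need no fitting data — which
    is exactly why their scores cannot depend on how the detector-fitting
    set was composed.
    """
    method = method.upper()
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if len(records) == 0:
        empty = np.asarray([], dtype=object)
        return ConfidenceSet(method, empty, empty, np.asarray([], dtype=float))
    if method == METHOD_MAH:
        if model is None:
            raise ValueError("MAH scoring requires a fitted GaussianClassModel")
        scores = np.atleast_1d(
            mahalanobis_confidence(adapter.features(records.features), model)
        )
    elif method == METHOD_MSP:
        scores = np.atleast_1d(msp_confidence(adapter.logits(records.features)))
    else:
        scores = np.atleast_1d(
            energy_confidence(adapter.logits(records.features), config or EnergyConfig())
        )
    return ConfidenceSet(method, records.ids, records.domain, scores)
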