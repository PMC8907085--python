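"""Trisomy-21 risk scoring: age prior x Gaussian likelihood ratio.

The screening model combines two sources of information:

1. **Maternal-age prior** -- the background risk of a trisomy-21
   pregnancy as a function of maternal age,

   ``risk(age) = k0 + exp(alpha + beta * (age - offset))``

   with published constants k0 = 0.0000697, alpha = -18.4367,
   beta = 0.286 and offset = 0.5 years.

2. **Marker likelihood ratio** -- each outcome class (trisomy-21,
   control) is modelled as a multivariate Gaussian over the log10
   adjusted-MoM vector of a marker subset; the likelihood ratio is the
   ratio of the two class densities at a subject's marker vector.

The combined risk is reported two ways: ``ultimate``, the "1 in N"
denominator ``1 / (LR * age_risk)`` used for clinical cutoffs, and
``risk_probability = LR * age_risk`` (clipped to (0, 1)), an ascending
risk score suitable for ROC analysis.  The two orderings are
reciprocal, so they induce identical ROC curves.

With k markers there are ``2**k - 1`` non-empty marker subsets; for the
four-marker panel that is the fifteen candidate models this package
enumerates and scores.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .markers import AFFECTED_LABEL, PANEL, adjusted_column, mom_column

logger = logging.getLogger(__name__)

_PROB_CEIL = 1.0 - 1e-12


@dataclass(frozen=True)
class AgeRiskParams:
    """Parameters of the maternal-age prior risk curve."""

    k0: float = 0.0000697
    alpha: float = -18.4367
    beta: float = 0.286
    offset: float = 0.5


def maternal_age_risk(age_years, params: AgeRiskParams | None = None) -> np.ndarray:
    """Background trisomy-21 risk from maternal age.

    ``k0 + exp(alpha + beta * (age - offset))``; the result is clipped
    into (0, 1) with a logged warning if clipping occurs.  Ages outside
    15-50 years trigger a warning but are computed.
    """
    p = params or AgeRiskParams()
    age = np.asarray(age_years, dtype=float)
    if np.any((age < 15.0) | (age > 50.0)):
        warnings.warn(
            "maternal age outside the supported 15-50 y range; "
            "age-risk curve extrapolated",
            stacklevel=2,
        )
    risk = p.k0 + np.exp(p.alpha + p.beta * (age - p.offset))
    if not np.all(np.isfinite(risk)):
        raise ValueError(f"age risk not finite at age={age_years!r}")
    if np.any(risk >= 1.0) or np.any(risk <= 0.0):
        logger.warning("maternal age risk outside (0,1); clipping")
        risk = np.clip(risk, 1e-300, _PROB_CEIL)
    return risk


@dataclass(frozen=True)
class ClassDensityModel:
    """Gaussian density of one outcome class over a marker subset."""

    markers: tuple[str, ...]
    mean: np.ndarray
    covariance: np.ndarray
    class_label: str

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != len(self.markers):
            raise ValueError(
                f"expected {len(self.markers)} marker columns, got {x.shape[1]}"
            )
        return multivariate_normal.logpdf(x, mean=self.mean, cov=self.covariance)


def fit_class_density(
    log_mom_matrix,
    class_label: str,
    markers: tuple[str, ...] | None = None,
    ridge_factor: float = 1e-8,
) -> ClassDensityModel:
    """Fit one class-conditional Gaussian by moments.

    Mean is the column mean, covariance the unbiased sample covariance.
    If the smallest eigenvalue is <= 1e-12 a diagonal ridge of
    ``ridge_factor * trace / k`` (escalated tenfold until positive
    definite; floor 1e-12 for an all-zero covariance) is added with a
    logged warning -- degenerate fits are never silently accepted.
    """
    x = np.atleast_2d(np.asarray(log_mom_matrix, dtype=float))
    if x.ndim != 2:
        raise ValueError("log_mom_matrix must be 2-D (subjects x markers)")
    n, k = x.shape
    if np.isnan(x).any():
        raise ValueError("log_mom_matrix contains NaN")
    if n < k + 2:
        raise ValueError(
            f"need at least k+2={k + 2} subjects to fit a {k}-marker density, got {n}"
        )
    mean = x.mean(axis=0)
    cov = np.atleast_2d(np.cov(x, rowvar=False, ddof=1))
    if np.linalg.eigvalsh(cov).min() <= 1e-12:
        ridge = max(ridge_factor * np.trace(cov) / k, 1e-12)
        while np.linalg.eigvalsh(cov + ridge * np.eye(k)).min() <= 1e-12:
            ridge *= 10.0
        logger.warning(
            "class %r covariance near-singular; adding ridge %.3g", class_label, ridge
        )
        cov = cov + ridge * np.eye(k)
    if markers is None:
        markers = tuple(f"m{i}" for i in range(k))
    return ClassDensityModel(tuple(markers), mean, cov, class_label)


def likelihood_ratio(
    x, affected: ClassDensityModel, control: ClassDensityModel
) -> np.ndarray:
    """Density ratio affected/control at marker vector(s) ``x``.

    Computed via log-densities and exponentiated last, so intermediate
    overflow cannot occur for |log LR| up to ~700.
    """
    if len(affected.markers) != len(control.markers):
        raise ValueError("affected and control densities have different dimension")
    return np.exp(affected.logpdf(x) - control.logpdf(x))


def ultimate_risk(lr, age_risk) -> tuple[np.ndarray, np.ndarray]:
    """Combine likelihood ratio and age prior.

    Returns ``(ultimate, risk_probability)`` where ``ultimate`` is the
    "1 in N" denominator ``1 / (lr * age_risk)`` and
    ``risk_probability`` is ``lr * age_risk`` clipped to (0, 1).
    """
    lr = np.asarray(lr, dtype=float)
    age_risk = np.asarray(age_risk, dtype=float)
    if np.any(lr <= 0):
        raise ValueError("likelihood ratio must be strictly positive")
    if np.any((age_risk <= 0) | (age_risk >= 1)):
        raise ValueError("age risk must lie strictly inside (0, 1)")
    product = lr * age_risk
    return 1.0 / product, np.minimum(product, _PROB_CEIL)


def enumerate_models(panel: list[str] | tuple[str, ...] = PANEL) -> list[tuple[str, ...]]:
    """All non-empty marker subsets, ordered by size then panel order."""
    panel = tuple(panel)
    if len(panel) == 0:
        raise ValueError("panel must contain at least one marker")
    if len(set(panel)) != len(panel):
        raise ValueError("panel contains duplicate marker names")
    return [
        subset
        for size in range(1, len(panel) + 1)
        for subset in itertools.combinations(panel, size)
    ]


def model_id(markers: tuple[str, ...]) -> str:
    """Canonical '+'-joined identifier of a marker subset."""
    return "+".join(markers)


class LikelihoodRatioClassifier(BaseEstimator, ClassifierMixin):
    """Class-conditional Gaussian likelihood-ratio model over a marker subset.

    A generative two-class model: each class is a multivariate Gaussian
    fitted by moments on (by default) log10-transformed MoM values, and
    the decision score is the log likelihood ratio affected/control.
    This is QDA re-expressed as an explicit density ratio, which is the
    form screening programmes use because the ratio multiplies an
    external prior (the maternal-age risk) rather than a sample
    prevalence.

    Parameters
    ----------
    log_transform:
        Model on log10(MoM) (default) or on the natural MoM scale.
    ridge_factor:
        Relative diagonal ridge applied only when a class covariance is
        numerically singular.
    positive_label:
        Label of the affected class in ``y``.

    Attributes
    ----------
    affected_density_, control_density_ : ClassDensityModel
    classes_ : ndarray of the two labels, control first.
    """

    def __init__(
        self,
        log_transform: bool = True,
        ridge_factor: float = 1e-8,
        positive_label: str = AFFECTED_LABEL,
    ):
        self.log_transform = log_transform
        self.ridge_factor = ridge_factor
        self.positive_label = positive_label

    def _prepare(self, X) -> np.ndarray:
        X = check_array(X, ensure_2d=True, dtype=float)
        if self.log_transform:
            if np.any(X <= 0):
                raise ValueError("MoM values must be > 0 for log-scale modelling")
            X = np.log10(X)
        return X

    def fit(self, X, y, markers: tuple[str, ...] | None = None):
        X = self._prepare(X)
        y = np.asarray(y)
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have inconsistent lengths")
        labels = np.unique(y)
        if len(labels) != 2 or self.positive_label not in labels:
            raise ValueError(
                f"y must contain exactly two classes including "
                f"{self.positive_label!r}, got {labels.tolist()}"
            )
        negative = labels[labels != self.positive_label][0]
        self.classes_ = np.array([negative, self.positive_label])
        self.n_features_in_ = X.shape[1]
        self.affected_density_ = fit_class_density(
            X[y == self.positive_label],
            self.positive_label,
            markers=markers,
            ridge_factor=self.ridge_factor,
        )
        self.control_density_ = fit_class_density(
            X[y == negative], str(negative), markers=markers,
            ridge_factor=self.ridge_factor,
        )
        return self

    def likelihood_ratio(self, X) -> np.ndarray:
        check_is_fitted(self, "affected_density_")
        X = self._prepare(X)
        return likelihood_ratio(X, self.affected_density_, self.control_density_)

    def decision_function(self, X) -> np.ndarray:
        """Log likelihood ratio (affected over control)."""
        check_is_fitted(self, "affected_density_")
        X = self._prepare(X)
        return self.affected_density_.logpdf(X) - self.control_density_.logpdf(X)

    def predict(self, X) -> np.ndarray:
        return np.where(
            self.decision_function(X) >= 0.0, self.classes_[1], self.classes_[0]
        )


def score_cohort(
    cohort: pd.DataFrame,
    models: list[tuple[str, ...]] | None = None,
    age_params: AgeRiskParams | None = None,
    log_transform: bool = True,
    use_adjusted: bool = False,
    ridge_factor: float = 1e-8,
    cv: int | None = None,
    random_state: int = 0,
) -> pd.DataFrame:
    """Score every subject under every marker-subset model.

    By default the class densities are fitted on the whole cohort and
    the same subjects are scored (resubstitution, the reference study
    design; optimistic by construction).  ``cv=k`` switches to
    stratified k-fold scoring.

    Returns a long DataFrame with one row per (subject, model):
    ``subject_id, model_id, lr, age_risk, ultimate, risk_probability``.
    """
    col_of = adjusted_column if use_adjusted else mom_column
    present = [m for m in PANEL if col_of(m) in cohort.columns]
    if models is None:
        if not present:
            raise ValueError("cohort contains no marker MoM columns")
        models = enumerate_models(present)
    needed = sorted({m for subset in models for m in subset})
    missing = [m for m in needed if col_of(m) not in cohort.columns]
    if missing:
        raise ValueError(
            "cohort is missing MoM columns for markers: "
            + ", ".join(missing)
        )

    y = cohort["group"].to_numpy()
    age_risk = maternal_age_risk(
        cohort["maternal_age_years"].to_numpy(), age_params
    )
    subject_id = cohort["subject_id"].to_numpy()

    frames = []
    for subset in models:
        X = cohort[[col_of(m) for m in subset]].to_numpy(dtype=float)
        clf = LikelihoodRatioClassifier(
            log_transform=log_transform, ridge_factor=ridge_factor
        )
        if cv is None:
            clf.fit(X, y, markers=subset)
            lr = clf.likelihood_ratio(X)
        else:
            from sklearn.model_selection import StratifiedKFold

            lr = np.empty(len(y))
            splitter = StratifiedKFold(
                n_splits=cv, shuffle=True, random_state=random_state
            )
            for train, test in splitter.split(X, y):
                fold = LikelihoodRatioClassifier(
                    log_transform=log_transform, ridge_factor=ridge_factor
                ).fit(X[train], y[train], markers=subset)
                lr[test] = fold.likelihood_ratio(X[test])
        ult, prob = ultimate_risk(lr, age_risk)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": subject_id,
                    "model_id": model_id(subset),
                    "lr": lr,
                    "age_risk": age_risk,
                    "ultimate": ult,
                    "risk_probability": prob,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
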