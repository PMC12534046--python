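"""Annotation-support bias correction (ASR*).

Cross-species splicing-ratio estimates inherit a bias from annotation
confidence: genomes whose CDSs are mostly supported by experimental
evidence show systematically higher isoform counts than genomes annotated
mainly from computational models.  The correction fits a polynomial trend
of ASR on the annotation-support covariate(s) across species and removes
it additively, re-centering at a reference covariate value:

    ASR* = ASR - f_hat(c) + f_hat(c_ref)

so a species at the reference support level is left untouched, ordering
within equal-support strata is preserved, and a degree-0 model is a no-op.
The dominant covariate is the fraction of fully supported CDSs; an
optional multivariate mode adds the known- and model-derived-CDS fractions
as additive polynomial terms.

Normalized values are standardized estimates for comparability, not
absolute measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .errors import SpliceRatioError

DEFAULT_COVARIATE = "frac_fully_supported"
SUPPORT_COLUMNS = ("frac_fully_supported", "frac_known", "frac_model")


@dataclass
class SupportProfile:
    """Per-species annotation-support fractions, each in [0, 1]."""

    species_id: str
    frac_fully_supported: float
    frac_known: float = float("nan")
    frac_model: float = float("nan")

    def __post_init__(self) -> None:
        for name in SUPPORT_COLUMNS:
            v = getattr(self, name)
            if not np.isnan(v) and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


class SupportNormalizer(BaseEstimator):
    """Polynomial trend model of ASR on annotation-support covariates.

    Parameters
    ----------
    degree:
        Polynomial degree (>= 0), or ``"aic"`` to select the degree in
        1..4 minimizing the Akaike information criterion.
    covariates:
        Support columns used as predictors; additive polynomial terms are
        built per covariate.
    reference:
        Covariate value(s) at which no correction is applied.  Defaults to
        the cross-species mean of each covariate at fit time.

    Attributes
    ----------
    degree_ : int
        Degree actually used (after AIC selection if requested).
    coefficients_ : ndarray
        OLS coefficients, intercept first.
    reference_value_ : ndarray
        Covariate value(s) where the correction vanishes.
    n_species_ : int
        Number of species the trend was fitted on.
    """

    def __init__(
        self,
        degree: int | str = 2,
        covariates: tuple[str, ...] = (DEFAULT_COVARIATE,),
        reference: float | np.ndarray | None = None,
    ):
        self.degree = degree
        self.covariates = covariates
        self.reference = reference

    # -- internals ---------------------------------------------------------
    def _as_matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            X = X[list(self.covariates)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[1] != len(self.covariates):
            raise ValueError(
                f"expected {len(self.covariates)} covariate column(s), "
                f"got {X.shape[1]}"
            )
        if np.any((X < 0) | (X > 1)):
            raise ValueError("support covariates must lie in [0, 1]")
        return X

    def _design(self, X: np.ndarray, degree: int) -> np.ndarray:
        cols = [np.ones(len(X))]
        for j in range(X.shape[1]):
            for d in range(1, degree + 1):
                cols.append(X[:, j] ** d)
        return np.column_stack(cols)

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y) -> "SupportNormalizer":
        """Fit the ASR-on-support trend.

        ``X``: covariate matrix (n_species, n_covariates) or DataFrame
        with the configured support columns; ``y``: ASR values.
        """
        Xm = self._as_matrix(X)
        y = np.asarray(y, dtype=float)
        if len(y) != len(Xm):
            raise ValueError("X and y have different lengths")
        ok = np.isfinite(y) & np.all(np.isfinite(Xm), axis=1)
        Xm, y = Xm[ok], y[ok]

        if self.degree == "aic":
            candidates = range(1, 5)
        else:
            candidates = [int(self.degree)]
            if candidates[0] < 0:
                raise ValueError("degree must be >= 0")

        best = None
        for deg in candidates:
            n_params = 1 + deg * Xm.shape[1]
            if len(y) < n_params:  # saturated (interpolating) fits allowed
                continue
            D = self._design(Xm, deg)
            if deg >= 1 and np.linalg.matrix_rank(D) < D.shape[1]:
                if self.degree != "aic":
                    raise SpliceRatioError(
                        f"design matrix is rank deficient at degree {deg} "
                        "(constant covariate?); try degree 0"
                    )
                continue
            res = sm.OLS(y, D).fit()
            if best is None or res.aic < best[1].aic:
                best = (deg, res)
        if best is None:
            raise SpliceRatioError(
                f"too few species ({len(y)}) to fit the requested degree(s)"
            )
        self.degree_, self._result_ = best
        self.coefficients_ = np.asarray(self._result_.params, dtype=float)
        self.n_species_ = int(len(y))
        if self.reference is None:
            self.reference_value_ = Xm.mean(axis=0)
        else:
            self.reference_value_ = np.atleast_1d(
                np.asarray(self.reference, dtype=float)
            )
        return self

    def predict(self, X) -> np.ndarray:
        """Fitted trend value f_hat at the given covariates."""
        self._check_fitted()
        Xm = self._as_matrix(X)
        return self._design(Xm, self.degree_) @ self.coefficients_

    def normalize(self, asr, X) -> np.ndarray:
        """ASR* = ASR - f_hat(c) + f_hat(c_ref)."""
        self._check_fitted()
        asr = np.asarray(asr, dtype=float)
        at_ref = self._design(
            self.reference_value_[None, :], self.degree_
        ) @ self.coefficients_
        return asr - self.predict(X) + at_ref[0]

    def _check_fitted(self) -> None:
        if not hasattr(self, "coefficients_"):
            raise SpliceRatioError("SupportNormalizer is not fitted")

    # -- serialization -----------------------------------------------------
    def to_json(self) -> str:
        self._check_fitted()
        return json.dumps(
            {
                "degree": self.degree_,
                "covariates": list(self.covariates),
                "coefficients": self.coefficients_.tolist(),
                "reference_value": self.reference_value_.tolist(),
                "n_species": self.n_species_,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SupportNormalizer":
        d = json.loads(text)
        obj = cls(degree=d["degree"], covariates=tuple(d["covariates"]))
        obj.degree_ = int(d["degree"])
        obj.coefficients_ = np.asarray(d["coefficients"], dtype=float)
        obj.reference_value_ = np.asarray(d["reference_value"], dtype=float)
        obj.n_species_ = int(d["n_species"])
        return obj


# -- thin functional wrappers ----------------------------------------------

def fit_support_model(
    profiles: list[tuple[SupportProfile, float]],
    degree: int | str = 2,
    covariates: tuple[str, ...] = (DEFAULT_COVARIATE,),
) -> SupportNormalizer:
    """Fit the support trend from (profile, ASR) pairs."""
    X = np.array(
        [[getattr(p, c) for c in covariates] for p, _ in profiles], dtype=float
    )
    y = np.array([a for _, a in profiles], dtype=float)
    return SupportNormalizer(degree=degree, covariates=covariates).fit(X, y)


def normalize_asr(
    asr: float, profile: SupportProfile, model: SupportNormalizer
) -> float:
    """ASR* for one species."""
    x = np.array([[getattr(profile, c) for c in model.covariates]], dtype=float)
    return float(model.normalize(np.array([asr]), x)[0])


def read_support_table(path) -> pd.DataFrame:
    """Read the per-species support-fraction TSV (species_id + fractions)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "species_id" not in df.columns:
        raise ValueError("support table must have a species_id column")
    return df.set_index("species_id")
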