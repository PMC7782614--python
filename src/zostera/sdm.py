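"""Balanced-prevalence smooth-term occurrence model.

The occurrence model is a binomial GAM with logit link: one cubic-spline
smooth (4 degrees of freedom) per environmental predictor, fitted by
penalized iteratively reweighted least squares on a class-balanced sample.
Balancing the training prevalence at one half lets the predicted probability
be read directly as expected coverage.  The module also provides partial
response curves with 95% bands, drop-one predictor contributions,
rank-based ROC/AUC and stratified k-fold cross-validation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .domain import DepthGrid


class ConvergenceError(RuntimeError):
    """Raised when the penalized IRLS loop does not converge."""


# ---------------------------------------------------------------------------
# balanced sample

@dataclass(frozen=True)
class BalancedSample:
    """Training table with equal numbers of presences and absences."""

    data: pd.DataFrame
    predictor_names: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def presence(self) -> np.ndarray:
        return self.data["presence"].to_numpy()

    @property
    def prevalence(self) -> float:
        return float(self.data["presence"].mean())

    def predictors(self) -> pd.DataFrame:
        return self.data[list(self.predictor_names)]


def balance_prevalence(table: pd.DataFrame, seed: int = 0) -> BalancedSample:
    """Subsample the majority class (without replacement) to the minority size.

    ``table`` must hold a binary ``presence`` column; every other column is
    treated as a predictor.
    """
    if "presence" not in table:
        raise ValueError("table must contain a 'presence' column")
    y = table["presence"].to_numpy()
    n_pres = int((y == 1).sum())
    n_abs = int((y == 0).sum())
    if n_pres == 0 or n_abs == 0:
        raise ValueError("both presence and absence records are required")
    rng = np.random.default_rng([int(seed), 53])
    keep = np.flatnonzero(y == (1 if n_pres <= n_abs else 0))
    major = np.flatnonzero(y == (0 if n_pres <= n_abs else 1))
    sampled = rng.choice(major, size=min(n_pres, n_abs), replace=False)
    idx = np.sort(np.concatenate([keep, sampled]))
    predictors = tuple(c for c in table.columns if c != "presence")
    return BalancedSample(
        data=table.iloc[idx].reset_index(drop=True), predictor_names=predictors
    )


# ---------------------------------------------------------------------------
# spline basis

@dataclass(frozen=True)
class SplineBasis:
    """Centred cubic B-spline basis for one predictor (df columns).

    Interior knots sit at quantiles of the training values.  Outside the
    training range the basis is extended linearly from the boundary (first
    order Taylor expansion), so extrapolated partial effects are linear.
    """

    name: str
    knots: np.ndarray
    degree: int
    lower: float
    upper: float
    centers: np.ndarray
    d_lower: np.ndarray  # column derivatives at the boundaries
    d_upper: np.ndarray

    @classmethod
    def from_data(cls, x: np.ndarray, name: str, df: int = 4, degree: int = 3) -> "SplineBasis":
        x = np.asarray(x, dtype=float)
        if df <= degree:
            raise ValueError("df must exceed the spline degree")
        lo, hi = float(x.min()), float(x.max())
        if hi <= lo:
            raise ValueError(f"predictor {name!r} is constant (rank deficient)")
        n_interior = df - degree
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
        interior = np.clip(interior, lo + 1e-9 * (hi - lo), hi - 1e-9 * (hi - lo))
        knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
        basis = cls(
            name=name,
            knots=knots,
            degree=degree,
            lower=lo,
            upper=hi,
            centers=np.zeros(df),
            d_lower=cls._boundary_derivatives(knots, degree, lo),
            d_upper=cls._boundary_derivatives(knots, degree, hi),
        )
        centers = basis.design(x).mean(axis=0)
        object.__setattr__(basis, "centers", centers)
        return basis

    @staticmethod
    def _boundary_derivatives(knots, degree, at) -> np.ndarray:
        n_basis = len(knots) - degree - 1
        derivs = np.empty(n_basis - 1)
        for j in range(1, n_basis):  # first basis column is dropped
            coef = np.zeros(n_basis)
            coef[j] = 1.0
            derivs[j - 1] = BSpline(knots, coef, degree)(at, nu=1)
        return derivs

    @property
    def df(self) -> int:
        return len(self.knots) - self.degree - 2  # raw columns minus dropped first

    def design(self, x: np.ndarray) -> np.ndarray:
        """Raw (uncentred) design matrix, first column dropped."""
        x = np.asarray(x, dtype=float)
        xc = np.clip(x, self.lower, self.upper)
        dm = BSpline.design_matrix(xc, self.knots, self.degree).toarray()[:, 1:]
        below = np.minimum(x - self.lower, 0.0)
        above = np.maximum(x - self.upper, 0.0)
        dm = dm + np.outer(below, self.d_lower) + np.outer(above, self.d_upper)
        return dm

    def centered_design(self, x: np.ndarray) -> np.ndarray:
        return self.design(x) - self.centers

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "knots": self.knots.tolist(),
            "degree": self.degree,
            "lower": self.lower,
            "upper": self.upper,
            "centers": self.centers.tolist(),
            "d_lower": self.d_lower.tolist(),
            "d_upper": self.d_upper.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SplineBasis":
        return cls(
            name=d["name"],
            knots=np.asarray(d["knots"], dtype=float),
            degree=int(d["degree"]),
            lower=float(d["lower"]),
            upper=float(d["upper"]),
            centers=np.asarray(d["centers"], dtype=float),
            d_lower=np.asarray(d["d_lower"], dtype=float),
            d_upper=np.asarray(d["d_upper"], dtype=float),
        )


# ---------------------------------------------------------------------------
# fitted model

@dataclass(frozen=True)
class FittedSDM:
    """Fitted balanced-prevalence occurrence model.

    ``coef`` stacks the intercept followed by each smooth term's spline
    coefficients in ``bases`` order; ``cov`` is the penalized-IRLS
    coefficient covariance used for the confidence bands.
    """

    bases: tuple[SplineBasis, ...]
    coef: np.ndarray
    cov: np.ndarray
    deviance: float
    null_deviance: float
    training_prevalence: float
    n_obs: int
    n_iter: int
    ridge: float

    @property
    def predictor_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.bases)

    @property
    def intercept(self) -> float:
        return float(self.coef[0])

    @property
    def explained_deviance(self) -> float:
        return 1.0 - self.deviance / self.null_deviance

    def _slices(self) -> dict[str, slice]:
        out, start = {}, 1
        for b in self.bases:
            out[b.name] = slice(start, start + b.df)
            start += b.df
        return out

    def design_matrix(self, predictors: Mapping[str, np.ndarray]) -> np.ndarray:
        cols = [np.ones(len(np.asarray(predictors[self.bases[0].name])))]
        for b in self.bases:
            cols.append(b.centered_design(np.asarray(predictors[b.name], dtype=float)))
        return np.hstack([c[:, None] if c.ndim == 1 else c for c in cols])

    def linear_predictor(self, predictors: Mapping[str, np.ndarray]) -> np.ndarray:
        return self.design_matrix(predictors) @ self.coef

    def predict(self, predictors: Mapping[str, np.ndarray]) -> np.ndarray:
        """Occurrence probability for tabular predictor values."""
        for b in self.bases:
            x = np.asarray(predictors[b.name], dtype=float)
            if np.any(x < b.lower) or np.any(x > b.upper):
                warnings.warn(
                    f"predictor {b.name!r} outside the training range "
                    f"[{b.lower:.3g}, {b.upper:.3g}]; smooth extended linearly",
                    stacklevel=2,
                )
        return expit(self.linear_predictor(predictors))

    def to_dict(self) -> dict:
        return {
            "model": "balanced-prevalence binomial GAM (logit link)",
            "bases": [b.to_dict() for b in self.bases],
            "coef": self.coef.tolist(),
            "cov": self.cov.tolist(),
            "deviance": self.deviance,
            "null_deviance": self.null_deviance,
            "training_prevalence": self.training_prevalence,
            "n_obs": self.n_obs,
            "n_iter": self.n_iter,
            "ridge": self.ridge,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "FittedSDM":
        return cls(
            bases=tuple(SplineBasis.from_dict(b) for b in d["bases"]),
            coef=np.asarray(d["coef"], dtype=float),
            cov=np.asarray(d["cov"], dtype=float),
            deviance=float(d["deviance"]),
            null_deviance=float(d["null_deviance"]),
            training_prevalence=float(d["training_prevalence"]),
            n_obs=int(d["n_obs"]),
            n_iter=int(d["n_iter"]),
            ridge=float(d["ridge"]),
        )

    @classmethod
    def from_json(cls, path) -> "FittedSDM":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_gam(
    sample: BalancedSample,
    df: int = 4,
    degree: int = 3,
    ridge: float = 1e-6,
    tol: float = 1e-6,
    max_iter: int = 100,
    min_class_size: int = 50,
) -> FittedSDM:
    """Fit the binomial smooth-term model by penalized IRLS.

    One centred cubic B-spline basis (``df`` columns) per predictor plus an
    intercept; a small ridge on the spline coefficients keeps the solve
    well-posed even under complete separation.  Convergence is declared when
    the relative deviance change falls below ``tol``.
    """
    y = sample.presence.astype(float)
    n1 = int(y.sum())
    if min(n1, len(y) - n1) < min_class_size:
        raise ValueError(f"need at least {min_class_size} records per class")
    X_cols = [np.ones((len(y), 1))]
    bases = []
    for name in sample.predictor_names:
        x = sample.data[name].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError(f"predictor {name!r} has non-finite values")
        basis = SplineBasis.from_data(x, name, df=df, degree=degree)
        bases.append(basis)
        X_cols.append(basis.centered_design(x))
    X = np.hstack(X_cols)
    penalty = np.full(X.shape[1], ridge)
    penalty[0] = 0.0  # intercept unpenalized

    beta = np.zeros(X.shape[1])
    eta = X @ beta
    deviance = _binomial_deviance(y, expit(eta))
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        p = expit(eta)
        w = np.clip(p * (1 - p), 1e-10, None)
        z = eta + (y - p) / w
        Xw = X * w[:, None]
        H = X.T @ Xw + np.diag(penalty)
        beta = np.linalg.solve(H, Xw.T @ z)
        eta = X @ beta
        new_dev = _binomial_deviance(y, expit(eta))
        if abs(new_dev - deviance) < tol * (abs(deviance) + 1e-10):
            deviance = new_dev
            converged = True
            break
        deviance = new_dev
    if not converged:
        raise ConvergenceError(f"penalized IRLS did not converge in {max_iter} iterations")

    p = expit(eta)
    w = np.clip(p * (1 - p), 1e-10, None)
    cov = np.linalg.inv(X.T @ (X * w[:, None]) + np.diag(penalty))
    prevalence = float(y.mean())
    null_dev = _binomial_deviance(y, np.full_like(y, prevalence))
    return FittedSDM(
        bases=tuple(bases),
        coef=beta,
        cov=cov,
        deviance=deviance,
        null_deviance=null_dev,
        training_prevalence=prevalence,
        n_obs=len(y),
        n_iter=n_iter,
        ridge=ridge,
    )


# ---------------------------------------------------------------------------
# prediction on grids

def predict_probability(
    model: FittedSDM, grid: DepthGrid, predictor_fields: Mapping[str, np.ndarray]
) -> np.ndarray:
    """Occurrence-probability map from gridded predictor fields.

    Out-of-scope cells (and cells where any predictor is NaN) emit NaN.
    """
    scope = grid.in_scope_mask.copy()
    values = {}
    for name in model.predictor_names:
        fld = np.asarray(predictor_fields[name], dtype=float)
        if fld.shape != grid.shape:
            raise ValueError(f"predictor field {name!r} does not match the grid")
        scope &= np.isfinite(fld)
        values[name] = fld
    table = {name: fld[scope] for name, fld in values.items()}
    out = np.full(grid.shape, np.nan)
    if scope.any():
        out[scope] = model.predict(table)
    return out


# ---------------------------------------------------------------------------
# response curves

@dataclass(frozen=True)
class ResponseCurve:
    """Partial response of one predictor on the logit scale with 95% bands."""

    predictor: str
    values: np.ndarray
    effect: np.ndarray  # centred partial effect (logit scale)
    lower: np.ndarray
    upper: np.ndarray
    intercept: float

    def probability(self) -> np.ndarray:
        """Occurrence probability along the curve, other predictors at their
        training means (whose centred effects are zero)."""
        return expit(self.intercept + self.effect)

    def half_occurrence_point(self) -> float:
        """Predictor value where the curve crosses p = 0.5 (linear interp.);
        NaN when it does not cross."""
        eta = self.intercept + self.effect
        sign = np.sign(eta)
        idx = np.flatnonzero(sign[:-1] * sign[1:] <= 0)
        if idx.size == 0:
            return float("nan")
        i = idx[0]
        x0, x1 = self.values[i], self.values[i + 1]
        e0, e1 = eta[i], eta[i + 1]
        if e1 == e0:
            return float(0.5 * (x0 + x1))
        return float(x0 - e0 * (x1 - x0) / (e1 - e0))


def response_curve(
    model: FittedSDM, predictor: str, values: Sequence[float]
) -> ResponseCurve:
    """Partial effect of one predictor with pointwise 95% confidence bands.

    The effect is the centred smooth term on the logit scale; bands are
    +-1.96 standard errors from the coefficient covariance.
    """
    if predictor not in model.predictor_names:
        raise KeyError(f"unknown predictor {predictor!r}")
    values = np.asarray(values, dtype=float)
    basis = next(b for b in model.bases if b.name == predictor)
    sl = model._slices()[predictor]
    B = basis.centered_design(values)
    effect = B @ model.coef[sl]
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", B, model.cov[sl, sl], B), 0.0))
    return ResponseCurve(
        predictor=predictor,
        values=values,
        effect=effect,
        lower=effect - 1.96 * se,
        upper=effect + 1.96 * se,
        intercept=model.intercept,
    )


# ---------------------------------------------------------------------------
# predictor contributions

def predictor_contributions(
    sample: BalancedSample, model: FittedSDM | None = None, **fit_kwargs
) -> pd.Series:
    """Drop-one predictor contributions, normalized to sum to 100%.

    The contribution of a predictor is the explained deviance lost when the
    model is refitted without it, rescaled across predictors.
    """
    names = sample.predictor_names
    if len(names) < 2:
        raise ValueError("contributions need at least two predictors")
    if model is None:
        model = fit_gam(sample, **fit_kwargs)
    full = model.explained_deviance
    losses = {}
    for name in names:
        reduced_table = sample.data.drop(columns=[name])
        reduced = BalancedSample(
            data=reduced_table,
            predictor_names=tuple(n for n in names if n != name),
        )
        losses[name] = max(full - fit_gam(reduced, **fit_kwargs).explained_deviance, 0.0)
    total = sum(losses.values())
    if total == 0:
        raise ValueError("no predictor explains any deviance; contributions undefined")
    return pd.Series({k: 100.0 * v / total for k, v in losses.items()}, name="contribution_pct")


# ---------------------------------------------------------------------------
# ROC / AUC

def roc_auc(scores, labels) -> float:
    """Rank-based AUC: probability that a random positive outscores a random
    negative, ties counted half (Mann-Whitney convention)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def auc_interpretation(auc: float) -> str:
    """Discrimination label for an AUC value (0.5 none ... >=0.8 excellent)."""
    if not 0.0 <= auc <= 1.0:
        raise ValueError("AUC must lie in [0, 1]")
    if auc <= 0.5:
        return "none"
    if auc < 0.7:
        return "low"
    if auc < 0.8:
        return "acceptable"
    if auc < 0.9:
        return "excellent"
    return "outstanding"


@dataclass(frozen=True)
class CVResult:
    """Per-fold cross-validated AUC values."""

    aucs: tuple[float, ...]

    @property
    def mean(self) -> float:
        return float(np.mean(self.aucs))

    @property
    def sd(self) -> float:
        return float(np.std(self.aucs, ddof=1))


def crossvalidate_auc(
    sample: BalancedSample, k: int = 5, seed: int = 0, **fit_kwargs
) -> CVResult:
    """Stratified k-fold cross-validation of the model's held-out AUC."""
    y = sample.presence
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % 2**31)
    aucs = []
    for train_idx, test_idx in splitter.split(np.zeros(len(y)), y):
        if len(np.unique(y[test_idx])) < 2:
            raise ValueError("a fold lost one of the classes")
        train = BalancedSample(
            data=sample.data.iloc[train_idx].reset_index(drop=True),
            predictor_names=sample.predictor_names,
        )
        fitted = fit_gam(train, **fit_kwargs)
        test = sample.data.iloc[test_idx]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # held-out values may sit just outside
            scores = fitted.predict(
                {n: test[n].to_numpy() for n in sample.predictor_names}
            )
        aucs.append(roc_auc(scores, y[test_idx]))
    return CVResult(aucs=tuple(aucs))
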