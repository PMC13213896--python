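"""Logistic-model log-likelihood and per-site maximum-likelihood fitting.

This is the building block every other stage of the federated protocol
calls: the Bernoulli log-likelihood

    l(beta) = sum_i [ y_i * eta_i - log(1 + exp(eta_i)) ],   eta_i = x_i' beta,

a deterministic IRLS (Newton scoring) fitter producing coefficient
estimates, standard errors from the observed information, and Wald
confidence intervals.  The local fit is the only round-1 artifact a site
shares: aggregate-level coefficients, never records.

The model structure is fixed to the logit link; an intercept is always
implicit at position 0 of the coefficient vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import expit

from .errors import (
    DimensionMismatchError,
    NonConvergenceError,
    SeparationError,
    SingleClassOutcomeError,
)

__all__ = [
    "ModelSpec",
    "SiteDataset",
    "LocalFit",
    "log_likelihood",
    "fit_local",
    "wald_ci",
    "read_site_csv",
]

#: Linear predictors beyond this magnitude signal a diverging (separated) fit:
#: expit(+-30) is already within 1e-13 of {0, 1}, so no finite-data MLE walks
#: this far unless the likelihood is maximised at infinity.
_ETA_DIVERGENCE = 300.0

#: At a purported optimum, linear predictors beyond this magnitude put fitted
#: probabilities within ~1e-11 of 0 or 1 — a quasi-separated configuration
#: whose deviance merely flattened out, not a finite MLE.
_ETA_SATURATION = 25.0


@dataclass(frozen=True)
class ModelSpec:
    """Model structure shared by every site.

    Parameters
    ----------
    outcome
        Name of the binary (0/1) outcome column.
    covariates
        Covariate column names in design order.  The intercept is implicit
        and always occupies position 0 of the coefficient vector.
    """

    outcome: str
    covariates: tuple[str, ...]

    def __post_init__(self):
        covs = tuple(self.covariates)
        object.__setattr__(self, "covariates", covs)
        if not covs:
            raise ValueError("a model needs at least one covariate")
        if len(set(covs)) != len(covs):
            raise ValueError(f"duplicate covariate names in {covs}")
        if self.outcome in covs:
            raise ValueError("outcome cannot also be a covariate")

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return ("intercept",) + self.covariates

    @property
    def n_parameters(self) -> int:
        return 1 + len(self.covariates)


@dataclass
class SiteDataset:
    """Patient-level records held by one jurisdiction (never exported)."""

    site_id: str
    data: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.data)

    def validate(self, spec: ModelSpec) -> None:
        """Check the complete-record, binary-outcome preconditions."""
        if self.n < 1:
            raise ValueError(f"site {self.site_id!r}: dataset is empty")
        needed = [spec.outcome, *spec.covariates]
        missing = [c for c in needed if c not in self.data.columns]
        if missing:
            raise ValueError(f"site {self.site_id!r}: missing columns {missing}")
        sub = self.data[needed]
        if sub.isna().any().any():
            raise ValueError(
                f"site {self.site_id!r}: missing values present; the method "
                "assumes complete records"
            )
        y = sub[spec.outcome].to_numpy()
        if not np.isin(y, (0, 1)).all():
            raise ValueError(
                f"site {self.site_id!r}: outcome {spec.outcome!r} must be 0/1"
            )

    def design(self, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(y, X)`` with an explicit leading intercept column."""
        self.validate(spec)
        y = self.data[spec.outcome].to_numpy(dtype=float)
        X = np.column_stack(
            [np.ones(self.n)]
            + [self.data[c].to_numpy(dtype=float) for c in spec.covariates]
        )
        return y, X

    def concat(self, other: "SiteDataset", site_id: str = "pooled") -> "SiteDataset":
        return SiteDataset(
            site_id, pd.concat([self.data, other.data], ignore_index=True)
        )


def pool_datasets(datasets: list[SiteDataset], site_id: str = "pooled") -> SiteDataset:
    """Concatenate site records in the declared site order (the global model's
    input)."""
    return SiteDataset(
        site_id, pd.concat([d.data for d in datasets], ignore_index=True)
    )


@dataclass
class LocalFit:
    """One site's logistic-regression summary: the round-1 message."""

    site_id: str
    parameter_names: tuple[str, ...]
    estimates: np.ndarray
    standard_errors: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    max_loglik: float
    converged: bool
    n_iterations: int
    n: int
    ci_level: float = 0.95

    def __post_init__(self):
        p = len(self.parameter_names)
        for name in ("estimates", "standard_errors", "ci_lower", "ci_upper"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if v.shape != (p,):
                raise ValueError(f"{name} must have length {p}, got {v.shape}")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "schema": "fedlik.local_fit/1",
            "site_id": self.site_id,
            "parameter_names": list(self.parameter_names),
            "estimates": self.estimates.tolist(),
            "standard_errors": self.standard_errors.tolist(),
            "ci_lower": self.ci_lower.tolist(),
            "ci_upper": self.ci_upper.tolist(),
            "ci_level": self.ci_level,
            "max_loglik": self.max_loglik,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "n": self.n,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LocalFit":
        text = Path(source).read_text() if isinstance(source, Path) else source
        if isinstance(source, str) and not source.lstrip().startswith("{"):
            text = Path(source).read_text()
        d = json.loads(text)
        return cls(
            site_id=d["site_id"],
            parameter_names=tuple(d["parameter_names"]),
            estimates=np.array(d["estimates"]),
            standard_errors=np.array(d["standard_errors"]),
            ci_lower=np.array(d["ci_lower"]),
            ci_upper=np.array(d["ci_upper"]),
            max_loglik=d["max_loglik"],
            converged=d["converged"],
            n_iterations=d["n_iterations"],
            n=d["n"],
            ci_level=d.get("ci_level", 0.95),
        )


def _check_beta(spec: ModelSpec, beta) -> np.ndarray:
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (spec.n_parameters,):
        raise DimensionMismatchError(spec.n_parameters, beta.size)
    return beta


def log_likelihood(dataset: SiteDataset, spec: ModelSpec, beta) -> float:
    """Bernoulli log-likelihood of ``dataset`` at coefficients ``beta``.

    Computed as ``sum(y * eta - softplus(eta))`` with the softplus evaluated
    through :func:`numpy.logaddexp`, which is overflow-free for any
    representable linear predictor.  Records are summed in dataset order.
    """
    beta = _check_beta(spec, beta)
    y, X = dataset.design(spec)
    eta = X @ beta
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_local(
    dataset: SiteDataset,
    spec: ModelSpec,
    tol: float = 1e-8,
    max_iter: int = 50,
    ci_level: float = 0.95,
) -> LocalFit:
    """Fit the site's logistic regression by IRLS (Newton scoring).

    Convergence is declared when the relative change in deviance falls
    below ``tol``.  Standard errors come from the inverse observed
    information at the optimum (equal to the expected information for the
    logit link).  Raises :class:`SingleClassOutcomeError` if the outcome
    has one class, :class:`SeparationError` on complete or quasi-complete
    separation, and :class:`NonConvergenceError` if ``max_iter`` is
    exhausted.
    """
    y, X = dataset.design(spec)
    n, p = X.shape
    if y.min() == y.max():
        raise SingleClassOutcomeError(
            f"site {dataset.site_id!r}: outcome {spec.outcome!r} has a single "
            f"class (all {int(y[0])}); the model is not estimable — mirrors a "
            "jurisdiction with no recorded patients with the outcome of interest"
        )
    if n <= p:
        raise ValueError(
            f"site {dataset.site_id!r}: n={n} must exceed the parameter count {p}"
        )

    beta = np.zeros(p)
    eta = X @ beta
    deviance = -2.0 * float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    converged = False
    n_iter = 0
    hess = None
    for n_iter in range(1, max_iter + 1):
        mu = expit(eta)
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        try:
            c, low = linalg.cho_factor(hess)
            step = linalg.cho_solve((c, low), score)
        except linalg.LinAlgError as exc:  # singular information
            raise SeparationError(
                f"site {dataset.site_id!r}: observed information is singular "
                "(complete or quasi-complete separation)"
            ) from exc
        beta = beta + step
        eta = X @ beta
        if np.max(np.abs(eta)) > _ETA_DIVERGENCE:
            raise SeparationError(
                f"site {dataset.site_id!r}: estimates diverging "
                f"(|linear predictor| > {_ETA_DIVERGENCE:g}); the data are "
                "separated and the MLE is not finite"
            )
        new_deviance = -2.0 * float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        if abs(deviance - new_deviance) / (abs(new_deviance) + 0.1) < tol:
            deviance = new_deviance
            converged = True
            break
        deviance = new_deviance
    if not converged:
        raise NonConvergenceError(
            f"site {dataset.site_id!r}: IRLS did not converge in {max_iter} "
            "iterations"
        )

    if np.max(np.abs(eta)) > _ETA_SATURATION:
        raise SeparationError(
            f"site {dataset.site_id!r}: fitted probabilities saturated "
            f"(|linear predictor| > {_ETA_SATURATION:g} at the optimum); the "
            "data are separated and the MLE is not finite"
        )
    # refresh information at the solution
    mu = expit(eta)
    w = mu * (1.0 - mu)
    hess = (X * w[:, None]).T @ X
    try:
        cov = linalg.inv(hess)
    except linalg.LinAlgError as exc:
        raise SeparationError(
            f"site {dataset.site_id!r}: information matrix not invertible at "
            "the optimum"
        ) from exc
    se = np.sqrt(np.diag(cov))
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    fit = LocalFit(
        site_id=dataset.site_id,
        parameter_names=spec.parameter_names,
        estimates=beta,
        standard_errors=se,
        ci_lower=beta - z * se,
        ci_upper=beta + z * se,
        max_loglik=-deviance / 2.0,
        converged=True,
        n_iterations=n_iter,
        n=n,
        ci_level=ci_level,
    )
    return fit


def wald_ci(fit: LocalFit, level: float = 0.95) -> np.ndarray:
    """Per-parameter Wald interval ``estimate +- z(level) * SE``.

    Uses the exact standard-normal quantile (1.959964 at level 0.95), not
    the 1.96 shorthand.  Returns an array of shape ``(p, 2)``.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must be in (0, 1), got {level}")
    if not fit.converged:
        raise ValueError(f"site {fit.site_id!r}: fit did not converge")
    z = stats.norm.ppf(0.5 + level / 2.0)
    return np.column_stack(
        (fit.estimates - z * fit.standard_errors,
         fit.estimates + z * fit.standard_errors)
    )


def read_site_csv(
    path: str | Path, spec: ModelSpec | None = None, site_id: str | None = None
) -> SiteDataset:
    """Load one site's patient-level table from CSV (header row required)."""
    path = Path(path)
    ds = SiteDataset(site_id or path.stem, pd.read_csv(path))
    if spec is not None:
        ds.validate(spec)
    return ds
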