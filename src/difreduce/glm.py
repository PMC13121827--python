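"""Measurement models for a single item.

The response of respondent *i* to an item is modelled by a generalized linear
model whose linear predictor combines the target latent trait ``theta``, an
optional nuisance-trait surrogate ``eta``, and optional group covariates ``z``
(with optional trait-by-group interactions for non-uniform DIF)::

    g(E[y_i]) = beta0 + beta_theta * theta_i + beta_eta * eta_i
                + z_i @ beta_z + (theta_i * z_i) @ beta_theta_z

Supported links are ``identity`` (Gaussian responses, residual variance
``sigma2`` profiled at its MLE ``RSS/N``), ``logit`` and ``probit``
(Bernoulli responses).  The trait estimate always enters as a fixed, known
covariate: fitting is conditional maximum likelihood with ``theta`` held
fixed, which is how the two-step DIF-correction procedure uses these models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import qr
from scipy.special import expit, log_ndtr, ndtr

__all__ = [
    "MeasurementModel",
    "FitError",
    "SeparationError",
    "RankDeficiencyError",
    "loglik",
    "fit_item",
    "fisher_information_target",
]

LINKS = ("identity", "logit", "probit")

#: Newton/IRLS stopping rule: max-norm of the score vector.
GRADIENT_TOL = 1e-8
MAX_ITER = 100
#: any coefficient exceeding this magnitude during a Bernoulli fit is treated
#: as (quasi-)separation rather than allowed to diverge silently.
SEPARATION_BOUND = 30.0


class FitError(RuntimeError):
    """Base class for model-fitting failures."""


class SeparationError(FitError):
    """Perfect or quasi-perfect separation in a Bernoulli-response fit."""


class RankDeficiencyError(FitError):
    """The design matrix does not have full column rank."""


@dataclass
class MeasurementModel:
    """Fitted (or externally specified) measurement model for one item.

    ``beta_z`` has one entry per grouping variable and length zero for the
    reduced model; ``beta_theta_z`` is ``None`` unless trait-by-group
    interactions (non-uniform DIF) are included.  ``sigma2`` is the profiled
    residual variance for the identity link and ``None`` otherwise.
    """

    link: str
    beta0: float
    beta_theta: float
    beta_eta: float = 0.0
    beta_z: np.ndarray = field(default_factory=lambda: np.zeros(0))
    beta_theta_z: np.ndarray | None = None
    sigma2: float | None = None
    loglik_at_fit: float | None = None

    def __post_init__(self) -> None:
        if self.link not in LINKS:
            raise ValueError(f"unknown link {self.link!r}; expected one of {LINKS}")
        self.beta_z = np.atleast_1d(np.asarray(self.beta_z, dtype=float))
        if self.beta_theta_z is not None:
            self.beta_theta_z = np.atleast_1d(np.asarray(self.beta_theta_z, dtype=float))
        if self.link == "identity":
            if self.sigma2 is not None and self.sigma2 <= 0:
                raise ValueError("sigma2 must be positive for the identity link")
        elif self.sigma2 is not None:
            raise ValueError("sigma2 is only defined for the identity link")

    @property
    def n_groups(self) -> int:
        return len(self.beta_z)

    def linear_predictor(
        self,
        theta: np.ndarray,
        eta: np.ndarray | None = None,
        z: np.ndarray | None = None,
    ) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        lp = self.beta0 + self.beta_theta * theta
        if self.beta_eta != 0.0:
            if eta is None:
                raise ValueError("model has a surrogate coefficient but eta is absent")
            lp = lp + self.beta_eta * np.asarray(eta, dtype=float)
        elif eta is not None:
            lp = lp + self.beta_eta * np.asarray(eta, dtype=float)
        if self.n_groups:
            if z is None:
                raise ValueError("model has group coefficients but z is absent")
            zmat = _as_matrix(z)
            lp = lp + zmat @ self.beta_z
            if self.beta_theta_z is not None:
                lp = lp + (zmat * theta[:, None]) @ self.beta_theta_z
        return lp

    def predict_mean(
        self,
        theta: np.ndarray,
        eta: np.ndarray | None = None,
        z: np.ndarray | None = None,
    ) -> np.ndarray:
        lp = self.linear_predictor(theta, eta, z)
        if self.link == "identity":
            return lp
        if self.link == "logit":
            return expit(lp)
        return ndtr(lp)


def _as_matrix(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    return z


def _check_binary(y: np.ndarray) -> None:
    bad = np.flatnonzero((y != 0.0) & (y != 1.0))
    if bad.size:
        raise ValueError(
            f"binary-link response must lie in {{0, 1}}; offending index {bad[0]} "
            f"has value {y[bad[0]]!r}"
        )


def _bernoulli_loglik(link: str, y: np.ndarray, lp: np.ndarray) -> float:
    if link == "logit":
        # sum y*lp - log(1 + exp(lp)), numerically stable
        return float(np.sum(y * lp - np.logaddexp(0.0, lp)))
    # probit
    return float(np.sum(np.where(y == 1.0, log_ndtr(lp), log_ndtr(-lp))))


def loglik(
    model: MeasurementModel,
    y: np.ndarray,
    theta: np.ndarray,
    eta: np.ndarray | None = None,
    z: np.ndarray | None = None,
) -> float:
    """Exact log-likelihood of ``y`` under ``model``; additive over respondents.

    Gaussian with the stored ``sigma2`` for the identity link, Bernoulli for
    logit/probit.  Responses outside the link's domain are rejected with the
    offending index named.
    """
    y = np.asarray(y, dtype=float)
    lp = model.linear_predictor(theta, eta, z)
    if y.shape != lp.shape:
        raise ValueError("response vector not conformable with covariates")
    if model.link == "identity":
        if model.sigma2 is None:
            raise ValueError("identity-link loglik requires sigma2")
        n = len(y)
        rss = float(np.sum((y - lp) ** 2))
        return -0.5 * n * np.log(2.0 * np.pi * model.sigma2) - rss / (2.0 * model.sigma2)
    _check_binary(y)
    return _bernoulli_loglik(model.link, y, lp)


def _build_design(
    theta: np.ndarray,
    eta: np.ndarray | None,
    z: np.ndarray | None,
    interactions: bool,
) -> tuple[np.ndarray, list[str]]:
    n = len(theta)
    cols = [np.ones(n), np.asarray(theta, dtype=float)]
    names = ["const", "theta"]
    if eta is not None:
        cols.append(np.asarray(eta, dtype=float))
        names.append("eta")
    if z is not None:
        zmat = _as_matrix(z)
        for m in range(zmat.shape[1]):
            cols.append(zmat[:, m])
            names.append(f"z{m}")
        if interactions:
            for m in range(zmat.shape[1]):
                cols.append(zmat[:, m] * theta)
                names.append(f"theta:z{m}")
    elif interactions:
        raise ValueError("interactions requested without grouping variables")
    X = np.column_stack(cols)
    return X, names


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    # column-pivoted QR: tiny trailing diagonal entries identify the
    # (near-)collinear columns by pivot order.
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    deficient = np.flatnonzero(diag <= tol)
    if deficient.size:
        offending = [names[piv[k]] for k in deficient]
        raise RankDeficiencyError(
            "design matrix is rank deficient; collinear column(s): "
            + ", ".join(offending)
        )


def _fit_gaussian(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, float]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n = len(y)
    rss = float(resid @ resid)
    sigma2 = max(rss / n, 1e-300)  # MLE denominator N; guard exact interpolation
    ll = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + rss / (n * sigma2))
    return beta, sigma2, ll


def _bernoulli_irls(
    link: str,
    X: np.ndarray,
    y: np.ndarray,
    beta0: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Newton (logit) / Fisher-scoring (probit) fit with step halving."""
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    lp = X @ beta
    ll = _bernoulli_loglik(link, y, lp)
    for _ in range(MAX_ITER):
        if link == "logit":
            mu = expit(lp)
            score_lp = y - mu
            w = mu * (1.0 - mu)
        else:
            mu = ndtr(lp)
            pdf = np.exp(-0.5 * lp**2) / np.sqrt(2.0 * np.pi)
            denom = np.clip(mu * (1.0 - mu), 1e-12, None)
            score_lp = (y - mu) * pdf / denom
            w = pdf**2 / denom
        grad = X.T @ score_lp
        if np.max(np.abs(grad)) <= GRADIENT_TOL:
            return beta, ll
        H = X.T @ (X * w[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate weights
            raise FitError(f"singular information matrix during IRLS: {exc}") from exc
        # step halving to guarantee ascent
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = _bernoulli_loglik(link, y, X @ cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        if np.max(np.abs(beta)) > SEPARATION_BOUND:
            raise SeparationError(
                "coefficient magnitude exceeded "
                f"{SEPARATION_BOUND:g} during fitting; data are (quasi-)separated"
            )
        lp = X @ beta
        ll = ll_new
    # converged within tolerance? accept if gradient is nearly flat.
    if np.max(np.abs(X.T @ (y - (expit(lp) if link == "logit" else ndtr(lp))))) <= 1e-5:
        return beta, ll
    raise FitError(f"IRLS did not converge in {MAX_ITER} iterations")


def fit_item(
    link: str,
    y: np.ndarray,
    theta: np.ndarray,
    eta: np.ndarray | None = None,
    z: np.ndarray | None = None,
    interactions: bool = False,
    _warm_start: np.ndarray | None = None,
) -> MeasurementModel:
    """Maximum-likelihood fit of the measurement model with ``theta`` fixed.

    Identity link is ordinary least squares with ``sigma2 = RSS/N``; logit and
    probit use Newton/IRLS to score max-norm <= 1e-8 with a separation guard.
    """
    if link not in LINKS:
        raise ValueError(f"unknown link {link!r}")
    y = np.asarray(y, dtype=float)
    theta = np.asarray(theta, dtype=float)
    X, names = _build_design(theta, eta, z, interactions)
    if X.shape[0] != len(y):
        raise ValueError("response vector not conformable with covariates")
    _check_rank(X, names)
    if link == "identity":
        beta, sigma2, ll = _fit_gaussian(X, y)
    else:
        _check_binary(y)
        beta, ll = _bernoulli_irls(link, X, y, beta0=_warm_start)
        sigma2 = None

    idx = 2
    beta_eta = 0.0
    if eta is not None:
        beta_eta = float(beta[idx])
        idx += 1
    m = 0 if z is None else _as_matrix(z).shape[1]
    beta_z = beta[idx : idx + m].copy()
    idx += m
    beta_theta_z = beta[idx : idx + m].copy() if (interactions and m) else None
    model = MeasurementModel(
        link=link,
        beta0=float(beta[0]),
        beta_theta=float(beta[1]),
        beta_eta=beta_eta,
        beta_z=beta_z,
        beta_theta_z=beta_theta_z,
        sigma2=sigma2,
        loglik_at_fit=float(ll),
    )
    model._coef = beta  # raw coefficient vector, for warm starts
    return model


def fisher_information_target(
    model: MeasurementModel,
    theta: np.ndarray | None = None,
    eta: np.ndarray | None = None,
    z: np.ndarray | None = None,
) -> float:
    """Fisher information of the target trait contributed by this item.

    Identity link: ``beta_theta**2 / sigma2`` (constant over respondents).
    Logit: sample mean of ``beta_theta**2 * p*(1-p)`` at the fitted
    probabilities; probit uses the normal-density weight
    ``phi(x)**2 / (p*(1-p))`` analogously.
    """
    if model.loglik_at_fit is None:
        raise ValueError("Fisher information requires a fitted model")
    if model.link == "identity":
        if model.sigma2 is None:
            raise ValueError("identity-link information requires sigma2")
        return model.beta_theta**2 / model.sigma2
    if theta is None:
        raise ValueError("binary-link information requires the fitting covariates")
    lp = model.linear_predictor(theta, eta, z)
    if model.link == "logit":
        p = expit(lp)
        w = p * (1.0 - p)
    else:
        p = ndtr(lp)
        pdf = np.exp(-0.5 * lp**2) / np.sqrt(2.0 * np.pi)
        w = pdf**2 / np.clip(p * (1.0 - p), 1e-12, None)
    return float(model.beta_theta**2 * np.mean(w))
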