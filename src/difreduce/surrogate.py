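"""Nuisance-trait surrogate construction.

A secondary ("nuisance") latent dimension with group-heterogeneous
distribution induces DIF in a unidimensional measurement model.  This module
builds a surrogate for that dimension as a unit-norm linear combination of
process-data features, ``eta = F @ w``, by minimizing a likelihood-ratio-type
objective

    Q(w) = 2 * (loglik_full - loglik_reduced)

where the full model adds the grouping variable to the reduced model
``(1, theta, eta)``.  Q measures how much fit the grouping variable adds once
the surrogate is in the model, i.e. the residual DIF effect on the chi-square
scale.

For the identity link with one grouping variable the zero of Q has a closed
form.  Work in the orthogonal complement of span{1, theta_hat} with an
orthonormalized feature block ``F~`` and define

    a = F~' y~,   b = F~' z~,   c = z~' y~ .

By Frisch-Waugh, Q(w) = 0 iff the group coefficient in the full model
vanishes, i.e. iff  (w'a)(w'b) = c  for a unit vector ``w``.  The bilinear
form ``w'(ab' + ba')w / 2`` has extreme values ``(a'b ± ||a|| ||b||)/2`` over
the unit sphere, so an exact zero exists iff

    |2c - a'b| <= ||a|| ||b||            (the solvability condition)

and the two root directions in span{a, b} are the angle solutions of
``cos(2*phi - psi) = kappa`` with ``psi`` the angle of ``b`` (relative to
``a``) and ``kappa = (2c/||a|| - b'a/||a||) / ||b||``.  The root closer to the
``a`` direction (``eta1``) aligns with the projection of ``y~`` onto the
feature span and is preferred; the other (``eta2``) aligns with the
projection of ``z~``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, ndtr

from .glm import FitError, _as_matrix, _bernoulli_irls, _bernoulli_loglik, fit_item

__all__ = [
    "ResidualizedDesign",
    "SurrogateSolution",
    "residualize",
    "objective_q",
    "objective_multi",
    "check_condition10",
    "solve_linear_closed_form",
    "solve_numeric",
]

#: relative singular-value cutoff for dropping feature directions with no
#: residual variation after projecting out span{1, theta_hat}.
PCA_TOL = 1e-10


@dataclass
class ResidualizedDesign:
    """Responses, features and group variables projected off span{1, theta}.

    ``f_tilde`` has orthonormal columns (``f_tilde' f_tilde = I``); ``basis``
    maps raw feature weights so that ``M F basis = f_tilde`` with ``M`` the
    residual-maker of ``(1, theta)``.  Raw inputs are retained so that
    solutions can report weights on the original feature scale.
    """

    y_tilde: np.ndarray
    f_tilde: np.ndarray
    z_tilde: np.ndarray
    basis: np.ndarray
    dropped_dims: list[int]
    # raw inputs (kept for mapping solutions back to the original scale)
    y: np.ndarray = field(repr=False, default=None)
    theta_hat: np.ndarray = field(repr=False, default=None)
    features: np.ndarray = field(repr=False, default=None)
    z: np.ndarray = field(repr=False, default=None)


@dataclass
class SurrogateSolution:
    """Result of a surrogate search.

    ``w`` is the unit-norm weight vector on the raw feature scale;
    ``eta_hat`` is the component of ``features @ w`` orthogonal to
    span{1, theta_hat} (recomputable from ``w``; the measurement model's
    intercept and trait coefficient absorb the projected-out part, and
    orthogonality keeps the surrogate from cannibalizing the target-trait
    slope at calibration).  ``q_value`` is the achieved objective on the
    chi-square (LR statistic) scale; ``q_initial`` the objective at the
    initialization point the search actually started from.
    ``condition10_margin`` is how far the cross-moment ``z~'y~`` lies inside
    the attainable range of ``(w'a)(w'b)`` (negative when no exact zero
    exists).
    """

    w: np.ndarray
    eta_hat: np.ndarray
    q_value: float
    q_initial: float
    root_label: str
    condition10_ok: bool
    condition10_margin: float
    n_restarts_used: int = 0


def _project_off(x: np.ndarray, X: np.ndarray) -> np.ndarray:
    coef, _, _, _ = np.linalg.lstsq(X, x, rcond=None)
    return x - X @ coef


def residualize(
    y: np.ndarray,
    theta_hat: np.ndarray,
    features: np.ndarray,
    z: np.ndarray,
) -> ResidualizedDesign:
    """Project y, features and group variables off span{1, theta_hat} and
    orthonormalize the feature block by principal component analysis.

    Feature directions whose residual singular value falls below
    ``1e-10`` times the largest are dropped and reported; raw feature columns
    annihilated by the projection (e.g. a copy of ``theta_hat``) are listed in
    ``dropped_dims`` by their column index.
    """
    y = np.asarray(y, dtype=float)
    theta_hat = np.asarray(theta_hat, dtype=float)
    F = np.asarray(features, dtype=float)
    zmat = _as_matrix(z)
    n, k = F.shape
    if np.ptp(theta_hat) == 0.0:
        raise ValueError("theta_hat is constant; cannot residualize")
    if n < k + 3:
        raise ValueError(f"need N >= K + 3 respondents (got N={n}, K={k})")

    X = np.column_stack([np.ones(n), theta_hat])
    y_t = _project_off(y, X)
    z_t = np.column_stack([_project_off(zmat[:, m], X) for m in range(zmat.shape[1])])
    f0 = F - X @ np.linalg.lstsq(X, F, rcond=None)[0]

    col_norms = np.linalg.norm(f0, axis=0)
    raw_norms = np.linalg.norm(F, axis=0)
    annihilated = [
        int(j) for j in range(k) if col_norms[j] <= PCA_TOL * max(raw_norms[j], 1.0)
    ]

    U, s, Vt = np.linalg.svd(f0, full_matrices=False)
    raw_scale = np.linalg.norm(F)
    if s.size == 0 or s[0] <= PCA_TOL * max(raw_scale, 1.0):
        raise ValueError("no residual feature variation: all features lie in span{1, theta_hat}")
    keep = s > PCA_TOL * s[0]
    if not np.any(keep):
        raise ValueError("no residual feature variation: all features lie in span{1, theta_hat}")
    U_r = U[:, keep]
    basis = Vt[keep].T / s[keep]
    return ResidualizedDesign(
        y_tilde=y_t,
        f_tilde=U_r,
        z_tilde=z_t,
        basis=basis,
        dropped_dims=annihilated,
        y=y,
        theta_hat=theta_hat,
        features=F,
        z=zmat,
    )


def objective_q(
    w: np.ndarray,
    link: str,
    y: np.ndarray,
    theta_hat: np.ndarray,
    features: np.ndarray,
    z: np.ndarray,
) -> float:
    """LR-scale objective for a single grouping variable.

    Computes ``eta = features @ (w / ||w||)``, fits the full model
    ``(1, theta, eta, z)`` and the reduced model ``(1, theta, eta)``, and
    returns ``2 * (loglik_full - loglik_reduced) >= 0``.  Invariant to the
    sign and scale of ``w``.
    """
    w = np.asarray(w, dtype=float)
    norm = np.linalg.norm(w)
    if norm == 0.0:
        raise ValueError("weight vector w must be nonzero")
    eta = np.asarray(features, dtype=float) @ (w / norm)
    return _q_with_eta(link, np.asarray(y, float), np.asarray(theta_hat, float),
                       eta, np.asarray(z, float))


def _gaussian_q(y, theta_hat, eta, z) -> float:
    """Identity-link objective N*log(RSS_red/RSS_full) with degenerate guards.

    A reduced model that already interpolates the response (RSS ~ 0) leaves
    the grouping variable nothing to explain: Q = 0 by convention.
    """
    n = len(y)
    X_red = np.column_stack([np.ones(n), theta_hat, eta])
    X_full = np.column_stack([X_red, z])
    rss_red = float(np.sum((y - X_red @ np.linalg.lstsq(X_red, y, rcond=None)[0]) ** 2))
    rss_full = float(np.sum((y - X_full @ np.linalg.lstsq(X_full, y, rcond=None)[0]) ** 2))
    scale = max(float(y @ y), 1e-30)
    if rss_red <= 1e-12 * scale:
        return 0.0
    rss_full = max(rss_full, 1e-15 * rss_red)
    return max(n * np.log(rss_red / rss_full), 0.0)


def _q_with_eta(link, y, theta_hat, eta, z) -> float:
    """LR objective for a given surrogate vector (no weight handling)."""
    if link == "identity":
        return _gaussian_q(np.asarray(y, float), np.asarray(theta_hat, float),
                           np.asarray(eta, float), np.asarray(z, float))
    reduced = fit_item(link, y, theta_hat, eta=eta)
    full = fit_item(link, y, theta_hat, eta=eta, z=z)
    return max(2.0 * (full.loglik_at_fit - reduced.loglik_at_fit), 0.0)


def objective_multi(
    w: np.ndarray,
    link: str,
    y: np.ndarray,
    theta_hat: np.ndarray,
    features: np.ndarray,
    z_list: list[np.ndarray],
) -> float:
    """Summed single-variable objectives for M grouping variables.

    Reduces exactly to :func:`objective_q` when ``M == 1``.  Non-uniform DIF
    is handled by passing ``z_list = [z, theta_hat * z]``.  Duplicate
    grouping columns are double counted and trigger a warning.
    """
    import warnings

    if len(z_list) == 0:
        raise ValueError("z_list must contain at least one grouping variable")
    cols = [np.asarray(zz, dtype=float).ravel() for zz in z_list]
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if cols[i].shape == cols[j].shape and np.array_equal(cols[i], cols[j]):
                warnings.warn(
                    f"grouping variables {i} and {j} are identical; "
                    "their DIF contribution is double counted",
                    stacklevel=2,
                )
    return sum(objective_q(w, link, y, theta_hat, features, zz) for zz in z_list)


def _cross_moments(rd: ResidualizedDesign) -> tuple[np.ndarray, np.ndarray, float]:
    if rd.z_tilde.shape[1] != 1:
        raise ValueError("closed-form analysis requires a single grouping variable")
    zt = rd.z_tilde[:, 0]
    a = rd.f_tilde.T @ rd.y_tilde
    b = rd.f_tilde.T @ zt
    c = float(zt @ rd.y_tilde)
    return a, b, c


def check_condition10(rd: ResidualizedDesign) -> tuple[bool, float]:
    """Solvability condition for an exact zero of the linear objective.

    Returns ``(flag, margin)`` with ``margin = ||a|| ||b|| - |2c - a'b|``:
    the cross-moment ``c = z~'y~`` admits a unit-norm ``w`` with
    ``(w'a)(w'b) = c`` iff ``margin >= 0``.  Degenerate ``a = b = 0`` yields
    ``(False, -inf)``.
    """
    a, b, c = _cross_moments(rd)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    tol_a = 1e-10 * max(np.linalg.norm(rd.y_tilde), 1e-30)
    tol_b = 1e-10 * max(np.linalg.norm(rd.z_tilde[:, 0]), 1e-30)
    if na <= tol_a and nb <= tol_b:
        scale = np.linalg.norm(rd.y_tilde) * np.linalg.norm(rd.z_tilde[:, 0])
        if abs(c) <= 1e-10 * max(scale, 1.0):
            return True, 0.0
        return False, -np.inf
    margin = na * nb - abs(2.0 * c - float(a @ b))
    return bool(margin >= -1e-12 * max(na * nb, abs(c), 1.0)), float(margin)


def _closed_form_roots(
    a: np.ndarray, b: np.ndarray, c: float
) -> tuple[np.ndarray, np.ndarray] | None:
    """Both unit-norm roots of (w'a)(w'b) = c in span{a, b} coordinates.

    Returns ``None`` when no exact root exists (condition violated or a
    degenerate configuration with no solvable geometry).
    """
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    k = len(a)
    if na == 0.0 and nb == 0.0:
        return None
    if na == 0.0:
        # f(w) == 0 for every w; any direction works iff c == 0
        if c != 0.0:
            return None
        w = b / nb
        return w, w
    e1 = a / na
    b1 = float(b @ e1)
    b_perp = b - b1 * e1
    nb2 = np.linalg.norm(b_perp)

    if nb2 <= 1e-12 * max(nb, 1e-30):
        # b (possibly zero) collinear with a: f(w) = d * cos^2(phi) with
        # d = a'b, using any direction u orthogonal to a.
        d = float(a @ b)
        if d == 0.0:
            if c != 0.0:
                return None
            if k < 2:
                return None
            w1 = e1  # f == 0 everywhere along span additions
            return w1, w1
        t = c / d
        if t < -1e-12 or t > 1.0 + 1e-12 or (k < 2 and not np.isclose(t, 1.0)):
            return None
        t = min(max(t, 0.0), 1.0)
        if k < 2:
            return e1, e1
        # build any unit vector orthogonal to e1
        u = np.zeros(k)
        u[np.argmin(np.abs(e1))] = 1.0
        u = u - (u @ e1) * e1
        u /= np.linalg.norm(u)
        phi = np.arccos(np.sqrt(t))
        w1 = np.cos(phi) * e1 + np.sin(phi) * u
        return w1, np.cos(phi) * e1 - np.sin(phi) * u

    e2 = b_perp / nb2
    psi = np.arctan2(nb2, b1)  # angle of b in the (e1, e2) plane, in (0, pi)
    kappa = (2.0 * c / na - b1) / nb
    if abs(kappa) > 1.0 + 1e-12:
        return None
    kappa = min(max(kappa, -1.0), 1.0)
    delta = np.arccos(kappa)
    phi1 = 0.5 * (psi - delta)  # root nearer the a (y~-projection) direction
    phi2 = 0.5 * (psi + delta)  # root nearer the b (z~-projection) direction
    w1 = np.cos(phi1) * e1 + np.sin(phi1) * e2
    w2 = np.cos(phi2) * e1 + np.sin(phi2) * e2
    return w1, w2


def _finalize_solution(
    rd: ResidualizedDesign,
    w_tilde: np.ndarray,
    root_label: str,
    q_initial: float,
    cond_ok: bool,
    margin: float,
) -> SurrogateSolution:
    # orient so the surrogate correlates non-negatively with y~
    a = rd.f_tilde.T @ rd.y_tilde
    if float(w_tilde @ a) < 0.0:
        w_tilde = -w_tilde
    w_raw = rd.basis @ w_tilde
    nrm = np.linalg.norm(w_raw)
    if nrm == 0.0:
        raise FitError("degenerate surrogate weights")
    w_raw = w_raw / nrm
    n = len(rd.y)
    eta = _project_off(rd.features @ w_raw,
                       np.column_stack([np.ones(n), rd.theta_hat]))
    q = _q_with_eta("identity", rd.y, rd.theta_hat, eta, rd.z[:, 0])
    return SurrogateSolution(
        w=w_raw,
        eta_hat=eta,
        q_value=q,
        q_initial=max(q_initial, q),
        root_label=root_label,
        condition10_ok=cond_ok,
        condition10_margin=margin,
    )


def solve_linear_closed_form(
    rd: ResidualizedDesign,
    root: str = "eta1",
) -> SurrogateSolution:
    """Closed-form zero of the identity-link objective (single grouping var).

    Returns the ``eta1`` root by default — the zero whose surrogate aligns
    with the projection of ``y~`` onto the feature span (pass
    ``root="eta2"`` for the other root, which aligns with the projection of
    ``z~``, for diagnostics).  When the solvability condition fails, falls
    back to the numeric minimizer and flags ``condition10_ok=False``.
    """
    if root not in ("eta1", "eta2"):
        raise ValueError("root must be 'eta1' or 'eta2'")
    a, b, c = _cross_moments(rd)
    cond_ok, margin = check_condition10(rd)
    roots = _closed_form_roots(a, b, c) if cond_ok else None
    if roots is None:
        sol = solve_numeric(
            "identity", rd.y, rd.theta_hat, rd.features, [rd.z[:, 0]], n_restarts=10
        )
        sol.condition10_ok = False
        sol.condition10_margin = margin if np.isfinite(margin) else -np.inf
        return sol
    w_tilde = roots[0] if root == "eta1" else roots[1]
    # reference objective at the pure y~-projection direction
    na = np.linalg.norm(a)
    if na > 0:
        q_init = objective_q(rd.basis @ (a / na), "identity", rd.y, rd.theta_hat,
                             rd.features, rd.z[:, 0])
    else:
        q_init = np.inf
    return _finalize_solution(rd, w_tilde, root, q_init, cond_ok, margin)


class _QObjective:
    """Objective Q and its analytic gradient for the numeric minimizer.

    The gradient uses the envelope theorem: at the inner-fit optimum the
    derivative of the maximized log-likelihood with respect to the surrogate
    values is ``beta_eta * score(linear predictor)``, so

        dQ/d(eta) = 2 * sum_m beta_eta_full_m * s_full_m
                    - 2 * M * beta_eta_red * s_red

    and ``dQ/dw`` follows by the chain rule through ``eta = F w/||w||``.
    Inner fits are warm started from the previous evaluation.
    """

    def __init__(self, link, y, theta_hat, features, z_list):
        self.link = link
        self.y = np.asarray(y, dtype=float)
        self.theta = np.asarray(theta_hat, dtype=float)
        self.F = np.asarray(features, dtype=float)
        self.z_list = [np.asarray(zz, dtype=float).ravel() for zz in z_list]
        n = len(self.y)
        self.X_red = np.column_stack([np.ones(n), self.theta, np.zeros(n)])
        self.X_full = [
            np.column_stack([np.ones(n), self.theta, np.zeros(n), zz])
            for zz in self.z_list
        ]
        self._warm_red = None
        self._warm_full = [None] * len(self.z_list)

    def _fit(self, X, warm):
        if self.link == "identity":
            beta, _, _, _ = np.linalg.lstsq(X, self.y, rcond=None)
            resid = self.y - X @ beta
            n = len(self.y)
            rss = max(float(resid @ resid), 1e-12 * max(float(self.y @ self.y), 1e-30))
            sigma2 = rss / n
            ll = -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)
            score_lp = resid / sigma2
            return beta, ll, score_lp
        beta, ll = _bernoulli_irls(self.link, X, self.y, beta0=warm)
        lp = X @ beta
        if self.link == "logit":
            score_lp = self.y - expit(lp)
        else:
            p = ndtr(lp)
            pdf = np.exp(-0.5 * lp**2) / np.sqrt(2.0 * np.pi)
            score_lp = (self.y - p) * pdf / np.clip(p * (1.0 - p), 1e-12, None)
        return beta, ll, score_lp

    def value_and_grad(self, w: np.ndarray) -> tuple[float, np.ndarray]:
        norm = np.linalg.norm(w)
        if norm == 0.0:
            raise ValueError("weight vector w must be nonzero")
        w_unit = w / norm
        eta = self.F @ w_unit
        self.X_red[:, 2] = eta
        beta_r, ll_r, s_r = self._fit(self.X_red, self._warm_red)
        self._warm_red = beta_r
        q = 0.0
        d_eta = -2.0 * len(self.z_list) * beta_r[2] * s_r
        for m, X in enumerate(self.X_full):
            X[:, 2] = eta
            beta_f, ll_f, s_f = self._fit(X, self._warm_full[m])
            self._warm_full[m] = beta_f
            q += 2.0 * (ll_f - ll_r)
            d_eta += 2.0 * beta_f[2] * s_f
        g_unit = self.F.T @ d_eta
        grad = (g_unit - float(w_unit @ g_unit) * w_unit) / norm
        return q, grad


def solve_numeric(
    link: str,
    y: np.ndarray,
    theta_hat: np.ndarray,
    features: np.ndarray,
    z_list: list[np.ndarray],
    init: np.ndarray | None = None,
    n_restarts: int = 10,
    seed: int = 0,
) -> SurrogateSolution:
    """Quasi-Newton minimization of the (summed) objective over unit ``w``.

    Optimizes the unconstrained K-vector with normalization applied inside
    the objective; runs ``n_restarts`` random unit-vector starts plus a warm
    start from the identity-link closed form on the same data (and ``init``
    when given) and returns the best solution found.
    """
    F = np.asarray(features, dtype=float)
    k = F.shape[1]
    if k < 1:
        raise ValueError("need at least one feature")
    z_cols = [np.asarray(zz, dtype=float).ravel() for zz in z_list]
    if not z_cols:
        raise ValueError("need at least one grouping variable")
    obj = _QObjective(link, y, theta_hat, F, z_cols)

    rd = residualize(y, theta_hat, F, np.column_stack(z_cols))
    cond_ok, margin = (False, -np.inf)
    if len(z_cols) == 1:
        cond_ok, margin = check_condition10(rd)

    def _postprocess(w_best, q_best, q_init, n_starts):
        w_unit = w_best / np.linalg.norm(w_best)
        eta = _project_off(F @ w_unit,
                           np.column_stack([np.ones(F.shape[0]), theta_hat]))
        if float(eta @ rd.y_tilde) < 0.0:
            w_unit = -w_unit
            eta = -eta
        return SurrogateSolution(
            w=w_unit,
            eta_hat=eta,
            q_value=max(q_best, 0.0),
            q_initial=max(q_init, q_best, 0.0),
            root_label="numeric",
            condition10_ok=cond_ok,
            condition10_margin=float(margin),
            n_restarts_used=n_starts,
        )

    if k == 1:
        w = np.ones(1)
        q, _ = obj.value_and_grad(w)
        return _postprocess(w, q, q, 0)

    starts: list[np.ndarray] = []
    if init is not None:
        init = np.asarray(init, dtype=float)
        if np.linalg.norm(init) == 0.0:
            raise ValueError("init weight vector must be nonzero")
        starts.append(init / np.linalg.norm(init))
    # warm start: closed-form linear root on the same (possibly binary) data
    try:
        a, b, c = _cross_moments(
            rd if rd.z_tilde.shape[1] == 1
            else residualize(y, theta_hat, F, z_cols[0])
        )
        roots = _closed_form_roots(a, b, c)
        if roots is not None:
            w_warm = rd.basis @ roots[0]
            if np.linalg.norm(w_warm) > 0:
                starts.append(w_warm / np.linalg.norm(w_warm))
    except (ValueError, FitError):
        pass
    if not starts:
        na = np.linalg.norm(rd.f_tilde.T @ rd.y_tilde)
        if na > 0:
            w0 = rd.basis @ (rd.f_tilde.T @ rd.y_tilde / na)
            starts.append(w0 / np.linalg.norm(w0))
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        v = rng.standard_normal(k)
        starts.append(v / np.linalg.norm(v))

    q_initial = obj.value_and_grad(starts[0])[0]
    best_q, best_w = np.inf, None
    failures = []
    for w0 in starts:
        try:
            res = minimize(
                obj.value_and_grad,
                w0,
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": 200},
            )
        except FitError as exc:
            failures.append(str(exc))
            continue
        # strict-improvement rule: keep the earlier (warm) solution unless a
        # restart is genuinely better, so ties on a flat zero set are stable
        if best_w is None or res.fun < best_q - 1e-9 * max(1.0, abs(best_q)):
            best_q, best_w = float(res.fun), res.x
    if best_w is None:
        raise FitError(
            "all optimizer starts failed; last diagnostics: "
            + (failures[-1] if failures else "none")
        )
    return _postprocess(best_w, best_q, q_initial, len(starts))
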