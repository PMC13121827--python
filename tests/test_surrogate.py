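import numpy as np
import pytest

from difreduce.surrogate import (
    check_condition10,
    objective_multi,
    objective_q,
    residualize,
    solve_linear_closed_form,
    solve_numeric,
)

from conftest import angle_dist, angle_of, grid_q_identity, make_linear_dif_data


# ---------------------------------------------------------------- residualize

def test_residualize_orthogonality_and_orthonormality(linear_rd):
    rd = linear_rd
    n = len(rd.y_tilde)
    ones, theta = np.ones(n), rd.theta_hat
    for v in [rd.y_tilde, rd.z_tilde[:, 0], *rd.f_tilde.T]:
        assert abs(v @ ones) <= 1e-8 * np.linalg.norm(v) * np.sqrt(n)
        assert abs(v @ theta) <= 1e-8 * np.linalg.norm(v) * np.linalg.norm(theta)
    np.testing.assert_allclose(rd.f_tilde.T @ rd.f_tilde,
                               np.eye(rd.f_tilde.shape[1]), atol=1e-8)


def test_residualize_annihilates_feature_equal_to_theta(rng):
    n = 60
    theta = rng.standard_normal(n)
    F = np.column_stack([theta, rng.standard_normal(n)])
    y = theta + rng.standard_normal(n)
    z = (rng.random(n) < 0.5).astype(float)
    rd = residualize(y, theta, F, z)
    assert 0 in rd.dropped_dims
    assert rd.f_tilde.shape[1] == 1


def test_residualize_y_matches_normal_equations_oracle(rng):
    n = 12
    theta = rng.standard_normal(n)
    y = rng.standard_normal(n)
    F = rng.standard_normal((n, 3))
    z = (rng.random(n) < 0.5).astype(float)
    rd = residualize(y, theta, F, z)
    X = np.column_stack([np.ones(n), theta])
    beta = np.linalg.solve(X.T @ X, X.T @ y)   # explicit normal equations
    np.testing.assert_allclose(rd.y_tilde, y - X @ beta, atol=1e-10)


def test_residualize_rejects_constant_theta(rng):
    with pytest.raises(ValueError, match="constant"):
        residualize(rng.standard_normal(20), np.ones(20),
                    rng.standard_normal((20, 2)), np.r_[np.zeros(10), np.ones(10)])


def test_residualize_rejects_features_inside_trait_span(rng):
    n = 30
    theta = rng.standard_normal(n)
    F = np.column_stack([theta, np.ones(n), 2.0 * theta - 1.0])
    with pytest.raises(ValueError, match="no residual feature variation"):
        residualize(rng.standard_normal(n), theta, F,
                    (rng.random(n) < 0.5).astype(float))


# ---------------------------------------------------------------- objective

def test_objective_zero_when_group_orthogonal_to_everything(rng):
    n = 200
    theta = rng.standard_normal(n)
    F = rng.standard_normal((n, 3))
    y = theta + F @ [0.3, 0.2, 0.1] + 0.1 * rng.standard_normal(n)
    # build z orthogonal to y~, every feature column, 1 and theta
    M = np.column_stack([np.ones(n), theta, F, y])
    zr = rng.standard_normal(n)
    z = zr - M @ np.linalg.lstsq(M, zr, rcond=None)[0]
    for w in (np.array([1.0, 0, 0]), np.array([0.5, -0.5, 1.0])):
        assert objective_q(w, "identity", y, theta, F, z) <= 1e-8


def test_objective_sign_and_scale_invariance(rng):
    y, theta, F, z, _, _ = make_linear_dif_data(seed=3)
    w = rng.standard_normal(F.shape[1])
    q = objective_q(w, "identity", y, theta, F, z)
    assert objective_q(-w, "identity", y, theta, F, z) == pytest.approx(q, rel=1e-10)
    assert objective_q(3.7 * w, "identity", y, theta, F, z) == pytest.approx(q, rel=1e-10)


def test_objective_rejects_zero_weights():
    y, theta, F, z, _, _ = make_linear_dif_data(seed=4)
    with pytest.raises(ValueError, match="nonzero"):
        objective_q(np.zeros(F.shape[1]), "identity", y, theta, F, z)


def test_objective_matches_dual_ols_oracle():
    # tiny printed vectors; oracle = two explicit least-squares fits
    y = np.array([1.2, 0.4, -0.3, 2.0, 1.1, -0.7, 0.2, 0.9, 1.5, -1.0])
    theta = np.array([0.5, -0.2, -1.0, 1.4, 0.3, -0.8, 0.0, 0.7, 1.1, -1.2])
    F = np.column_stack([
        np.array([0.3, -0.5, 0.1, 0.8, -0.2, 0.4, -0.6, 0.2, 0.5, -0.3]),
        np.array([-0.1, 0.6, -0.4, 0.2, 0.7, -0.3, 0.1, -0.8, 0.3, 0.4]),
    ])
    z = np.array([1.0, 0, 1, 0, 1, 0, 0, 1, 1, 0])
    w = np.array([0.6, -0.8])
    eta = F @ (w / np.linalg.norm(w))
    n = len(y)

    def rss(X):
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss_red = rss(np.column_stack([np.ones(n), theta, eta]))
    rss_full = rss(np.column_stack([np.ones(n), theta, eta, z]))
    expected = n * np.log(rss_red / rss_full)
    assert objective_q(w, "identity", y, theta, F, z) == pytest.approx(
        expected, rel=1e-10
    )


def test_objective_multi_reduces_to_single_and_sums(rng):
    y, theta, F, z, _, _ = make_linear_dif_data(seed=5)
    w = rng.standard_normal(F.shape[1])
    q1 = objective_q(w, "identity", y, theta, F, z)
    assert objective_multi(w, "identity", y, theta, F, [z]) == q1
    z2 = rng.standard_normal(len(y))
    q2 = objective_q(w, "identity", y, theta, F, z2)
    total = objective_multi(w, "identity", y, theta, F, [z, z2])
    assert total == pytest.approx(q1 + q2, rel=1e-12)


def test_objective_multi_warns_on_duplicate_groups():
    y, theta, F, z, _, _ = make_linear_dif_data(seed=6)
    with pytest.warns(UserWarning, match="double counted"):
        objective_multi(np.ones(F.shape[1]), "identity", y, theta, F, [z, z.copy()])


# ---------------------------------------------------------------- condition 10

def test_condition_holds_when_group_response_cross_moment_vanishes(rng):
    n = 120
    theta = rng.standard_normal(n)
    F = rng.standard_normal((n, 3))
    y = theta + 0.5 * rng.standard_normal(n)
    M = np.column_stack([np.ones(n), theta, y])
    zr = rng.standard_normal(n)
    z = zr - M @ np.linalg.lstsq(M, zr, rcond=None)[0]  # z~'y~ = 0
    ok, margin = check_condition10(residualize(y, theta, F, z))
    assert ok and margin >= 0


def test_condition_holds_when_features_reproduce_response():
    y, theta, F, z, _, _ = make_linear_dif_data(seed=8, noise_sd=0.0)
    ok, margin = check_condition10(residualize(y, theta, F, z))
    assert ok and margin > 0


def test_condition_flag_agrees_with_angle_grid_scan(rng):
    # K=2: exhaustive scan of (w'a)(w'b) over the unit circle
    for seed in range(6):
        r = np.random.default_rng(seed)
        n = 80
        theta = r.standard_normal(n)
        F = r.standard_normal((n, 2))
        y = theta + F @ r.standard_normal(2) + r.standard_normal(n)
        z = (r.random(n) < 0.5).astype(float) + 0.1 * r.standard_normal(n)
        rd = residualize(y, theta, F, z)
        ok, _ = check_condition10(rd)
        a = rd.f_tilde.T @ rd.y_tilde
        b = rd.f_tilde.T @ rd.z_tilde[:, 0]
        c = float(rd.z_tilde[:, 0] @ rd.y_tilde)
        phi = np.linspace(0, np.pi, 100000, endpoint=False)
        f = (np.cos(phi) * a[0] + np.sin(phi) * a[1]) * (
            np.cos(phi) * b[0] + np.sin(phi) * b[1])
        attainable = f.min() - 1e-9 <= c <= f.max() + 1e-9
        assert ok == attainable


def test_degenerate_cross_moments_report_sentinel(rng):
    n = 40
    theta = rng.standard_normal(n)
    X = np.column_stack([np.ones(n), theta])
    # y and z exactly inside span{1, theta}: a = b = 0 but c != 0 impossible,
    # so push y into the span and z partly outside with zero feature overlap
    F = np.zeros((n, 2))
    F[:, 0] = rng.standard_normal(n)
    F[:, 1] = rng.standard_normal(n)
    Fo = F - X @ np.linalg.lstsq(X, F, rcond=None)[0]
    y = rng.standard_normal(n)
    z = rng.standard_normal(n)
    Mfo = np.column_stack([X, Fo])
    y = y - Mfo @ np.linalg.lstsq(Mfo, y, rcond=None)[0]
    z = z - Mfo @ np.linalg.lstsq(Mfo, z, rcond=None)[0]
    z = z + 0.5 * y  # nonzero cross moment, zero feature moments
    rd = residualize(y, theta, F, z)
    ok, margin = check_condition10(rd)
    assert not ok and margin == -np.inf


# ---------------------------------------------------------------- closed form

def test_closed_form_zeroes_objective(linear_rd):
    sol = solve_linear_closed_form(linear_rd)
    assert sol.condition10_ok
    assert sol.q_value <= 1e-8
    assert np.linalg.norm(sol.w) == pytest.approx(1.0, abs=1e-12)
    assert sol.q_value <= sol.q_initial
    assert sol.root_label == "eta1"


def test_closed_form_no_dif_degenerates_to_projection(rng):
    # z~ orthogonal to y~ and to every feature column -> w prop. to F~'y~
    n = 150
    theta = rng.standard_normal(n)
    Fr = rng.standard_normal((n, 3))
    y = theta + Fr @ [0.5, 0.3, 0.2] + 0.2 * rng.standard_normal(n)
    M = np.column_stack([np.ones(n), theta, Fr, y])
    zr = rng.standard_normal(n)
    z = zr - M @ np.linalg.lstsq(M, zr, rcond=None)[0]
    rd = residualize(y, theta, Fr, z)
    sol = solve_linear_closed_form(rd)
    proj = rd.f_tilde @ (rd.f_tilde.T @ rd.y_tilde)
    corr = np.corrcoef(sol.eta_hat, proj)[0, 1]
    assert abs(corr) >= 0.999999
    assert sol.q_value <= 1e-8


def test_closed_form_roots_match_angle_grid_minimizers():
    for seed in (1, 2, 3):
        y, theta, F, z, _, _ = make_linear_dif_data(
            seed=seed, k=2, noise_sd=0.05, append_predictor=False
        )
        rd = residualize(y, theta, F, z)
        assert rd.f_tilde.shape[1] == 2
        sol1 = solve_linear_closed_form(rd, root="eta1")
        sol2 = solve_linear_closed_form(rd, root="eta2")
        phi, q = grid_q_identity(rd, 200000)
        # circular local minima of the grid objective: the two zeros
        is_min = (q < np.roll(q, 1)) & (q <= np.roll(q, -1)) & (q <= 1e-3)
        zero_phis = phi[is_min]
        assert len(zero_phis) >= 1
        for sol in (sol1, sol2):
            ang = angle_of(rd, sol.eta_hat)
            assert min(angle_dist(ang, p) for p in zero_phis) <= 1e-4
        assert sol1.q_value <= 1e-8 and sol2.q_value <= 1e-8


def test_root_discrimination_response_copy_prefers_response():
    # features carry an exact copy of the (residualized) response
    rng = np.random.default_rng(17)
    n = 400
    theta = rng.standard_normal(n)
    z = (rng.random(n) < 0.5).astype(float)
    y = 0.2 + theta + 0.3 * z + 0.5 * rng.standard_normal(n)
    F = np.column_stack([y, z + 0.2 * rng.standard_normal(n)])
    rd = residualize(y, theta, F, z)
    sol1 = solve_linear_closed_form(rd, root="eta1")
    sol2 = solve_linear_closed_form(rd, root="eta2")
    zt = rd.z_tilde[:, 0]
    c1y = abs(np.corrcoef(sol1.eta_hat, rd.y_tilde)[0, 1])
    c1z = abs(np.corrcoef(sol1.eta_hat, zt)[0, 1])
    c2y = abs(np.corrcoef(sol2.eta_hat, rd.y_tilde)[0, 1])
    c2z = abs(np.corrcoef(sol2.eta_hat, zt)[0, 1])
    assert sol1.q_value <= 1e-8
    assert c1y > c1z          # eta1 tracks the response
    assert c2z > c2y          # eta2 tracks the grouping variable
    assert c1y > c2y


def test_closed_form_falls_back_to_numeric_when_condition_fails(rng):
    # features orthogonal to z~ but z~'y~ != 0: no exact zero exists
    n = 100
    theta = rng.standard_normal(n)
    X = np.column_stack([np.ones(n), theta])
    F = rng.standard_normal((n, 2))
    Fo = F - X @ np.linalg.lstsq(X, F, rcond=None)[0]
    z = rng.standard_normal(n)
    z = z - np.column_stack([X, Fo]) @ np.linalg.lstsq(
        np.column_stack([X, Fo]), z, rcond=None)[0]
    y = theta + 0.8 * z + 0.1 * rng.standard_normal(n)
    rd = residualize(y, theta, F, z)
    ok, _ = check_condition10(rd)
    assert not ok
    sol = solve_linear_closed_form(rd)
    assert not sol.condition10_ok
    assert sol.root_label == "numeric"
    assert sol.q_value >= 0


# ---------------------------------------------------------------- numeric

def test_numeric_agrees_with_closed_form_on_identity_link():
    for seed in (21, 22):
        y, theta, F, z, _, _ = make_linear_dif_data(seed=seed, n=400, k=3)
        rd = residualize(y, theta, F, z)
        cf = solve_linear_closed_form(rd)
        num = solve_numeric("identity", y, theta, F, [z], seed=seed)
        assert num.q_value <= cf.q_value + 1e-6
        corr = np.corrcoef(num.eta_hat, cf.eta_hat)[0, 1]
        assert abs(corr) >= 0.999


def test_numeric_single_feature_sign_convention():
    y, theta, F, z, _, _ = make_linear_dif_data(seed=30, k=1)
    F1 = F[:, :1]
    sol = solve_numeric("identity", y, theta, F1, [z])
    assert sol.w[0] == pytest.approx(1.0)
    assert sol.q_value == pytest.approx(
        objective_q(np.ones(1), "identity", y, theta, F1, z), rel=1e-10
    )


def test_numeric_logit_reduces_objective(rng):
    n = 800
    z = (rng.random(n) < 0.5).astype(float)
    theta = rng.standard_normal(n) - 0.3 * z
    F = rng.standard_normal((n, 4))
    F[:, 0] += 1.0 * z
    w_true = np.array([0.8, 0.3, 0.2, 0.1])
    w_true /= np.linalg.norm(w_true)
    eta = F @ w_true
    lp = 0.2 + theta + 0.9 * eta
    y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(float)
    sol = solve_numeric("logit", y, theta, F, [z], seed=0)
    assert sol.q_value <= sol.q_initial
    assert sol.q_value <= 0.5 * max(
        objective_q(rng.standard_normal(4), "logit", y, theta, F, z), 1e-6
    ) or sol.q_value < 1.0
    # surrogate direction recovers the generating weights
    assert abs(np.corrcoef(sol.eta_hat, F @ w_true)[0, 1]) > 0.5


def test_solution_eta_recomputable_and_unit_norm(linear_rd):
    rd = linear_rd
    sol = solve_linear_closed_form(rd)
    assert np.linalg.norm(sol.w) == pytest.approx(1.0, abs=1e-12)
    n = len(rd.y)
    X = np.column_stack([np.ones(n), rd.theta_hat])
    raw = rd.features @ sol.w
    expected = raw - X @ np.linalg.lstsq(X, raw, rcond=None)[0]
    np.testing.assert_allclose(sol.eta_hat, expected, atol=1e-10)
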