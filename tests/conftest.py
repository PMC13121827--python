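import numpy as np
import pytest

from difreduce.surrogate import residualize


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_linear_dif_data(seed, n=300, k=2, beta_eta=0.8, noise_sd=0.1,
                         append_predictor=True):
    """Small identity-link dataset with nuisance-mediated DIF.

    The last feature column is the noise-free systematic part of the
    response, so the features predict the trait-residualized response
    (almost) exactly and the closed-form solvability condition holds; the
    unequal group shifts across feature columns keep the feature/group
    cross-moment vector well away from the response one.
    """
    rng = np.random.default_rng(seed)
    z = (rng.random(n) < 0.5).astype(float)
    theta = rng.standard_normal(n) - 0.4 * z
    F = rng.standard_normal((n, k))
    F[:, 0] += 0.8 * z
    if k >= 2:
        F[:, 1] += 1.5 * z
    w_true = rng.exponential(1.0, size=k)
    w_true /= np.linalg.norm(w_true)
    eta = F @ w_true
    lp = 0.3 + 1.2 * theta + beta_eta * eta
    y = lp + noise_sd * rng.standard_normal(n)
    if append_predictor:
        F = np.column_stack([F, lp])
    return y, theta, F, z, eta, w_true


def grid_q_identity(rd, n_angles):
    """Identity-link objective on an angle grid over the orthonormalized
    2-D feature plane: an exhaustive oracle for K=2 surrogate problems.

    Uses only the tilde-space scalars (Frisch-Waugh reduction of the full
    design); independent of the closed-form root construction.
    """
    assert rd.f_tilde.shape[1] == 2, "grid oracle needs a rank-2 feature block"
    yt, zt = rd.y_tilde, rd.z_tilde[:, 0]
    a = rd.f_tilde.T @ yt
    b = rd.f_tilde.T @ zt
    c = float(zt @ yt)
    y2 = float(yt @ yt)
    z2 = float(zt @ zt)
    n = len(yt)
    phi = np.linspace(0.0, np.pi, n_angles, endpoint=False)
    u = np.cos(phi) * a[0] + np.sin(phi) * a[1]
    v = np.cos(phi) * b[0] + np.sin(phi) * b[1]
    rss_red = y2 - u**2
    det = z2 - v**2
    rss_full = y2 - (z2 * u**2 - 2.0 * u * v * c + c**2) / det
    return phi, n * np.log(np.maximum(rss_red, 1e-300) / np.maximum(rss_full, 1e-300))


def angle_of(rd, eta_hat):
    """Angle (mod pi) of a surrogate direction in the orthonormal plane."""
    w = rd.f_tilde.T @ eta_hat
    return float(np.arctan2(w[1], w[0]) % np.pi)


def angle_dist(p, q):
    d = abs(p - q) % np.pi
    return min(d, np.pi - d)


@pytest.fixture
def linear_rd():
    y, theta, F, z, _, _ = make_linear_dif_data(seed=7)
    return residualize(y, theta, F, z)
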