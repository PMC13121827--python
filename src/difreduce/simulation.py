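"""Synthetic data generation for the DIF-reduction simulation design.

Every replication builds one test form:

* respondents are split into a reference and a focal group; the target trait
  is normal within group with group-specific means;
* per-item process features are multivariate normal with a group-dependent
  mean shift, then whitened so the pooled sample covariance is exactly the
  identity;
* the true nuisance trait of each item is ``eta* = F @ w*`` with exponential
  weights scaled to unit norm (so ``eta*`` has unit pooled sample variance);
* responses follow the measurement GLM with the DIF effect entering *only*
  through the nuisance slope on DIF items (the group coefficient is zero in
  generation — DIF is purely distributional);
* for the identity link, the noise-free linear predictor of each item is
  appended as one extra feature column so that features can (almost)
  perfectly predict the response, mirroring the perfect response
  predictability of real process data.

Non-uniform DIF additionally gives the focal group a non-identity feature
covariance (diagonal with Exp(1) eigenvalues) and adds a trait-by-group
interaction coefficient on DIF items.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datasets import ItemDataset

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_dataset",
    "make_piaac_like_fixture",
    "DIF_EFFECT_PRESETS",
]

DIF_EFFECT_PRESETS = {"small": (0.2, 0.4), "large": (0.5, 1.0)}


@dataclass
class SimulationConfig:
    """All constants of the simulation design; every one is overridable."""

    n_respondents: int = 2000
    n_items: int = 20
    n_dif_items: int = 5
    dif_effect_range: tuple[float, float] = DIF_EFFECT_PRESETS["large"]
    focal_fraction: float = 0.5
    theta_means: tuple[float, float] = (0.0, -0.5)   # (reference, focal)
    difficulty_range: tuple[float, float] = (-1.0, 1.0)
    discrimination_range: tuple[float, float] = (0.8, 2.0)
    n_features: int = 10
    feature_group_shift: np.ndarray = field(
        default_factory=lambda: np.array([0.75, 0.75, 0.75] + [0.0] * 7)
    )
    weight_rate: float = 1.0
    link: str = "logit"
    noise_variance: float = 0.25
    nonuniform: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.focal_fraction < 1.0:
            raise ValueError("focal_fraction must lie in (0, 1)")
        for name in ("dif_effect_range", "difficulty_range", "discrimination_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered (lo <= hi)")
        if self.n_dif_items > self.n_items:
            raise ValueError("n_dif_items cannot exceed n_items")
        self.feature_group_shift = np.asarray(self.feature_group_shift, dtype=float)
        if len(self.feature_group_shift) != self.n_features:
            raise ValueError("feature_group_shift must have length n_features")

    def preset(self, name: str) -> "SimulationConfig":
        return replace(self, dif_effect_range=DIF_EFFECT_PRESETS[name])


@dataclass
class SimulatedDataset:
    """An :class:`ItemDataset` plus every generation ground truth."""

    dataset: ItemDataset
    theta_true: np.ndarray
    eta_true: dict[str, np.ndarray]       # DIF item -> true nuisance trait
    w_true: dict[str, np.ndarray]         # DIF item -> unit-norm true weights
    item_params_true: dict[str, dict]     # item -> {beta0, beta_theta, beta_eta, ...}
    dif_flags: dict[str, bool]
    group_assignment: np.ndarray
    config: SimulationConfig | None = None

    @property
    def dif_items(self) -> list[str]:
        return [i for i in self.dataset.item_ids if self.dif_flags[i]]

    @property
    def anchor_items(self) -> list[str]:
        return [i for i in self.dataset.item_ids if not self.dif_flags[i]]


def _whiten(F: np.ndarray) -> np.ndarray:
    """Center and right-multiply by the inverse symmetric square root of the
    pooled sample covariance, so the sample covariance is exactly identity."""
    Fc = F - F.mean(axis=0)
    cov = Fc.T @ Fc / (len(F) - 1)
    vals, vecs = np.linalg.eigh(cov)
    if np.min(vals) <= 1e-12 * np.max(vals):
        raise ValueError("degenerate feature covariance; cannot whiten")
    inv_sqrt = vecs @ np.diag(vals**-0.5) @ vecs.T
    return Fc @ inv_sqrt


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate one replication of the simulation design (deterministic in
    ``config.seed``)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, j, k = cfg.n_respondents, cfg.n_items, cfg.n_features
    if k >= n:
        raise ValueError("need more respondents than features")

    n_focal = int(round(n * cfg.focal_fraction))
    groups = np.zeros(n)
    groups[rng.choice(n, size=n_focal, replace=False)] = 1.0

    mu_ref, mu_focal = cfg.theta_means
    theta = np.where(groups == 1.0, mu_focal, mu_ref) + rng.standard_normal(n)

    item_ids = [f"item{jj + 1:02d}" for jj in range(j)]
    dif_idx = rng.choice(j, size=cfg.n_dif_items, replace=False)
    dif_flags = {item: (jj in dif_idx) for jj, item in enumerate(item_ids)}

    lo_b, hi_b = cfg.difficulty_range
    lo_a, hi_a = cfg.discrimination_range
    lo_d, hi_d = cfg.dif_effect_range

    responses = np.empty((n, j))
    features: dict[str, np.ndarray] = {}
    eta_true: dict[str, np.ndarray] = {}
    w_true: dict[str, np.ndarray] = {}
    params: dict[str, dict] = {}

    for jj, item in enumerate(item_ids):
        beta0 = rng.uniform(lo_b, hi_b)
        beta_theta = rng.uniform(lo_a, hi_a)
        F = rng.standard_normal((n, k))
        if cfg.nonuniform:
            focal_scale = np.sqrt(rng.exponential(1.0, size=k))
            F[groups == 1.0] *= focal_scale
        F = F + groups[:, None] * cfg.feature_group_shift[None, :]
        F = _whiten(F)
        w = rng.exponential(1.0 / cfg.weight_rate, size=k)
        w = w / np.linalg.norm(w)
        eta = F @ w

        beta_eta = rng.uniform(lo_d, hi_d) if dif_flags[item] else 0.0
        beta_tz = (
            rng.uniform(lo_d, hi_d) if (cfg.nonuniform and dif_flags[item]) else 0.0
        )
        lp = beta0 + beta_theta * theta + beta_eta * eta + beta_tz * theta * groups
        if cfg.link == "identity":
            y = lp + rng.normal(0.0, np.sqrt(cfg.noise_variance), size=n)
            # response-predicting column: the noise-free conditional mean
            F = np.column_stack([F, lp])
        elif cfg.link == "logit":
            y = (rng.random(n) < 1.0 / (1.0 + np.exp(-lp))).astype(float)
        elif cfg.link == "probit":
            from scipy.special import ndtr
            y = (rng.random(n) < ndtr(lp)).astype(float)
        else:
            raise ValueError(f"unknown link {cfg.link!r}")
        responses[:, jj] = y
        features[item] = F
        params[item] = {
            "beta0": beta0, "beta_theta": beta_theta,
            "beta_eta": beta_eta, "beta_theta_z": beta_tz,
        }
        if dif_flags[item]:
            eta_true[item] = eta
            w_true[item] = w

    dataset = ItemDataset(
        responses=responses,
        z=groups,
        features=features,
        item_ids=item_ids,
        link=cfg.link,
    )
    return SimulatedDataset(
        dataset=dataset,
        theta_true=theta,
        eta_true=eta_true,
        w_true=w_true,
        item_params_true=params,
        dif_flags=dif_flags,
        group_assignment=groups,
        config=cfg,
    )


def subsample(sim: SimulatedDataset, n: int) -> SimulatedDataset:
    """First-``n``-respondents view of a replication, keeping all item truths.

    Used for paired sample-size comparisons: the small-N dataset shares item
    parameters, weights and DIF effects with the large-N one, so paired
    differences isolate the effect of the sample size.
    """
    ds = sim.dataset
    if n > ds.n_respondents:
        raise ValueError("cannot subsample beyond the available respondents")
    sub = ItemDataset(
        responses=ds.responses[:n],
        z=ds.z[:n],
        features={item: F[:n] for item, F in ds.features.items()},
        item_ids=list(ds.item_ids),
        theta_hat=None if ds.theta_hat is None else ds.theta_hat[:n],
        respondent_ids=ds.respondent_ids[:n],
        link=ds.link,
    )
    return SimulatedDataset(
        dataset=sub,
        theta_true=sim.theta_true[:n],
        eta_true={k: v[:n] for k, v in sim.eta_true.items()},
        w_true=dict(sim.w_true),
        item_params_true=dict(sim.item_params_true),
        dif_flags=dict(sim.dif_flags),
        group_assignment=sim.group_assignment[:n],
        config=sim.config,
    )


def make_piaac_like_fixture(seed: int = 0, n_respondents: int = 2000) -> SimulatedDataset:
    """A 13-item binary fixture echoing a problem-solving assessment form.

    Three grouping variables — two binary (e.g. age split, income split) and
    one continuous (e.g. age in years, standardized) — with roughly half the
    items carrying nuisance-mediated DIF against all three.
    """
    rng = np.random.default_rng(seed)
    n, j, k = n_respondents, 13, 10
    z_age = (rng.random(n) < 0.5).astype(float)
    z_inc = (rng.random(n) < 0.4).astype(float)
    z_cont = 0.8 * z_age + rng.standard_normal(n)      # continuous, age-linked
    z_cont = (z_cont - z_cont.mean()) / z_cont.std()
    theta = -0.4 * z_age - 0.2 * z_inc + rng.standard_normal(n)

    item_ids = [f"U{jj + 1:02d}" for jj in range(j)]
    dif_items = set(item_ids[::2][:6])                 # 6 of 13 items
    responses = np.empty((n, j))
    features: dict[str, np.ndarray] = {}
    eta_true: dict[str, np.ndarray] = {}
    w_true: dict[str, np.ndarray] = {}
    params: dict[str, dict] = {}
    shift = np.array([0.5, 0.4, 0.3] + [0.0] * (k - 3))
    for jj, item in enumerate(item_ids):
        F = rng.standard_normal((n, k))
        F += (z_age[:, None] * shift + z_inc[:, None] * 0.6 * shift
              + z_cont[:, None] * 0.4 * shift)
        F = _whiten(F)
        w = rng.exponential(1.0, size=k)
        w /= np.linalg.norm(w)
        eta = F @ w
        beta0 = rng.uniform(-1.0, 1.0)
        beta_theta = rng.uniform(0.8, 2.0)
        beta_eta = rng.uniform(0.5, 1.0) if item in dif_items else 0.0
        lp = beta0 + beta_theta * theta + beta_eta * eta
        responses[:, jj] = (rng.random(n) < 1.0 / (1.0 + np.exp(-lp))).astype(float)
        features[item] = F
        params[item] = {"beta0": beta0, "beta_theta": beta_theta,
                        "beta_eta": beta_eta, "beta_theta_z": 0.0}
        if item in dif_items:
            eta_true[item] = eta
            w_true[item] = w

    dataset = ItemDataset(
        responses=responses,
        z=np.column_stack([z_age, z_inc, z_cont]),
        features=features,
        item_ids=item_ids,
        link="logit",
    )
    return SimulatedDataset(
        dataset=dataset,
        theta_true=theta,
        eta_true=eta_true,
        w_true=w_true,
        item_params_true=params,
        dif_flags={i: i in dif_items for i in item_ids},
        group_assignment=z_age,
        config=None,
    )
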