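"""Likelihood-ratio DIF screening per item.

An item is tested by comparing nested measurement models with and without
the grouping variables: the statistic is ``2 * (loglik_full - loglik_reduced)``
referred to a chi-square distribution with one degree of freedom per added
group term (``M`` for uniform mode, ``2M`` for non-uniform mode, which also
adds trait-by-group interactions).  Screening can run before correction
(``eta_hat=None``) or after (surrogate included in both nested models).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .glm import FitError, _as_matrix, fit_item

__all__ = ["DIFTestResult", "lrt_dif", "screen_items"]


@dataclass
class DIFTestResult:
    item_id: str
    lr_statistic: float
    df: int
    p_value: float
    flagged: bool
    mode: str
    corrected: bool
    error: str | None = None

    @property
    def untestable(self) -> bool:
        return self.error is not None


def lrt_dif(
    link: str,
    y: np.ndarray,
    theta_hat: np.ndarray,
    z: np.ndarray,
    eta_hat: np.ndarray | None = None,
    mode: str = "uniform",
    alpha: float = 0.05,
    item_id: str = "item",
) -> DIFTestResult:
    """Per-item likelihood-ratio DIF test.

    ``mode="uniform"`` adds the grouping variable(s) to the full model;
    ``mode="nonuniform"`` additionally adds trait-by-group interactions.
    A fit failure (e.g. separation) yields an "untestable" result instead of
    raising.
    """
    if mode not in ("uniform", "nonuniform"):
        raise ValueError("mode must be 'uniform' or 'nonuniform'")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    zmat = _as_matrix(z)
    m = zmat.shape[1]
    df = m if mode == "uniform" else 2 * m
    try:
        reduced = fit_item(link, y, theta_hat, eta=eta_hat)
        full = fit_item(
            link, y, theta_hat, eta=eta_hat, z=zmat,
            interactions=(mode == "nonuniform"),
        )
    except FitError as exc:
        return DIFTestResult(item_id, np.nan, df, np.nan, False, mode,
                             eta_hat is not None, error=str(exc))
    stat = max(2.0 * (full.loglik_at_fit - reduced.loglik_at_fit), 0.0)
    p = float(chi2.sf(stat, df))
    return DIFTestResult(
        item_id=item_id,
        lr_statistic=stat,
        df=df,
        p_value=p,
        flagged=bool(p < alpha),
        mode=mode,
        corrected=eta_hat is not None,
    )


def screen_items(
    dataset,
    theta_hat: np.ndarray,
    mode: str = "uniform",
    alpha: float = 0.05,
    adjust: str = "none",
    eta_hats: dict | None = None,
) -> list[DIFTestResult]:
    """Run :func:`lrt_dif` over every item of an :class:`ItemDataset`.

    ``adjust="benjamini_hochberg"`` re-flags items using BH-adjusted
    p-values at level ``alpha``; item ordering is preserved either way.
    """
    if adjust not in ("none", "benjamini_hochberg"):
        raise ValueError("adjust must be 'none' or 'benjamini_hochberg'")
    eta_hats = eta_hats or {}
    results = [
        lrt_dif(
            dataset.link,
            dataset.responses[:, j],
            theta_hat,
            dataset.z,
            eta_hat=eta_hats.get(item),
            mode=mode,
            alpha=alpha,
            item_id=item,
        )
        for j, item in enumerate(dataset.item_ids)
    ]
    if adjust == "benjamini_hochberg" and results:
        testable = [r for r in results if not r.untestable]
        if testable:
            reject, p_adj, _, _ = multipletests(
                [r.p_value for r in testable], alpha=alpha, method="fdr_bh"
            )
            for r, rej in zip(testable, reject):
                r.flagged = bool(rej)
    return results
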