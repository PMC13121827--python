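"""In-memory container for one test form.

An :class:`ItemDataset` aligns, per respondent: item responses (binary 0/1 or
continuous), one or more grouping variables (binary 0/1 coded
reference/focal, or continuous), a per-item process-feature matrix, and an
optional target-trait estimate.  All arrays share the respondent count and
ordering; missing values are rejected at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ItemDataset"]


@dataclass
class ItemDataset:
    responses: np.ndarray                 # N x J
    z: np.ndarray                         # N x M
    features: dict[str, np.ndarray]       # item -> N x K_j
    item_ids: list[str]
    theta_hat: np.ndarray | None = None   # length N
    respondent_ids: np.ndarray | None = None
    link: str = "logit"                   # default measurement link for the form

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim == 1:
            self.responses = self.responses[:, None]
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim == 1:
            self.z = self.z[:, None]
        self.item_ids = list(self.item_ids)
        n, j = self.responses.shape
        if j != len(self.item_ids):
            raise ValueError(
                f"{j} response columns but {len(self.item_ids)} item ids"
            )
        if self.z.shape[0] != n:
            raise ValueError("grouping variables and responses disagree on N")
        if self.respondent_ids is None:
            self.respondent_ids = np.arange(n)
        else:
            self.respondent_ids = np.asarray(self.respondent_ids)
            if len(self.respondent_ids) != n:
                raise ValueError("respondent_ids and responses disagree on N")
        if self.theta_hat is not None:
            self.theta_hat = np.asarray(self.theta_hat, dtype=float)
            if len(self.theta_hat) != n:
                raise ValueError("theta_hat and responses disagree on N")
            _reject_missing(self.theta_hat, "theta_hat")
        _reject_missing(self.responses, "responses")
        _reject_missing(self.z, "groups")
        for item in self.item_ids:
            if item not in self.features:
                raise ValueError(f"missing feature matrix for item {item!r}")
            F = np.asarray(self.features[item], dtype=float)
            if F.ndim != 2 or F.shape[0] != n:
                raise ValueError(f"features for item {item!r} are not N x K")
            _reject_missing(F, f"features_{item}")
            self.features[item] = F
        if self.link == "logit" or self.link == "probit":
            bad = np.flatnonzero(~np.isin(self.responses, (0.0, 1.0)).all(axis=0))
            if bad.size:
                raise ValueError(
                    f"binary responses must lie in {{0,1}}; item "
                    f"{self.item_ids[bad[0]]!r} violates this"
                )
        for m in range(self.z.shape[1]):
            col = self.z[:, m]
            if np.isin(col, (0.0, 1.0)).all():
                if not (np.any(col == 0.0) and np.any(col == 1.0)):
                    raise ValueError(
                        f"binary group column {m} must contain both 0 and 1"
                    )

    @property
    def n_respondents(self) -> int:
        return self.responses.shape[0]

    @property
    def n_items(self) -> int:
        return self.responses.shape[1]

    @property
    def n_groups(self) -> int:
        return self.z.shape[1]

    def response(self, item: str) -> np.ndarray:
        return self.responses[:, self.item_ids.index(item)]


def _reject_missing(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        idx = np.argwhere(~np.isfinite(np.atleast_2d(arr)))
        r, c = idx[0]
        raise ValueError(f"missing/non-finite value in {name} at row {r}, column {c}")
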