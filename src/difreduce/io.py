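"""Delimited-text dataset layout and run configuration.

Files (comma-separated, header row, ``respondent_id`` column first):

* ``responses.csv`` — one column per item;
* ``groups.csv`` — one column per grouping variable;
* ``theta.csv`` — optional single ``theta_hat`` column;
* ``features_<item>.csv`` — one file per item, one column per feature.

Values round-trip losslessly at 17 significant digits.  Respondent order is
canonicalized by sorting on the ID column; ID mismatches across files and
missing values are rejected with the offending location reported.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ItemDataset

__all__ = ["RunConfig", "load_dataset", "write_dataset"]

FLOAT_FMT = "%.17g"


@dataclass
class RunConfig:
    """Validated configuration for a pipeline run."""

    link: str = "logit"
    mode: str = "uniform"
    alpha: float = 0.05
    adjust: str = "none"
    max_iter: int = 10
    tol_corr: float = 0.99
    n_restarts: int = 10
    seed: int = 0
    data_dir: str = "."
    anchors: list[str] | None = None
    output_dir: str = "out"
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not -1.0 <= self.tol_corr <= 1.0:
            raise ValueError("tol_corr must lie in [-1, 1]")

    def config_hash(self) -> str:
        payload = {k: v for k, v in self.__dict__.items() if k != "extra"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _read_indexed(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns[0] != "respondent_id":
        raise ValueError(f"{path.name}: first column must be 'respondent_id'")
    df = df.set_index("respondent_id").sort_index()
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path.name}: duplicate respondent id {dup!r}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index
            raise ValueError(
                f"{path.name}: non-numeric cell in column {col!r}, "
                f"respondent {bad[0]!r}"
            )
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = df.index[df[col].isna()][0]
        raise ValueError(
            f"{path.name}: missing value at respondent {row!r}, column {col!r}"
        )
    return df


def load_dataset(data_dir: str | Path, link: str = "logit") -> ItemDataset:
    """Load and align the delimited-text dataset layout from ``data_dir``."""
    data_dir = Path(data_dir)
    resp = _read_indexed(data_dir / "responses.csv")
    groups = _read_indexed(data_dir / "groups.csv")
    ids = resp.index
    for name, df in (("groups.csv", groups),):
        if not df.index.equals(ids):
            missing = ids.difference(df.index).tolist()
            extra = df.index.difference(ids).tolist()
            raise ValueError(
                f"{name}: respondent IDs disagree with responses.csv "
                f"(missing {missing[:5]}, unexpected {extra[:5]})"
            )
    theta = None
    theta_path = data_dir / "theta.csv"
    if theta_path.exists():
        tdf = _read_indexed(theta_path)
        if not tdf.index.equals(ids):
            raise ValueError("theta.csv: respondent IDs disagree with responses.csv")
        theta = tdf.iloc[:, 0].to_numpy()
    features = {}
    for item in resp.columns:
        fpath = data_dir / f"features_{item}.csv"
        if not fpath.exists():
            raise ValueError(f"missing feature file {fpath.name}")
        fdf = _read_indexed(fpath)
        if not fdf.index.equals(ids):
            missing = ids.difference(fdf.index).tolist()
            raise ValueError(
                f"{fpath.name}: respondent IDs disagree with responses.csv "
                f"(missing {missing[:5]})"
            )
        features[item] = fdf.to_numpy()
    return ItemDataset(
        responses=resp.to_numpy(),
        z=groups.to_numpy(),
        features=features,
        item_ids=list(resp.columns),
        theta_hat=theta,
        respondent_ids=ids.to_numpy(),
        link=link,
    )


def write_dataset(
    dataset: ItemDataset,
    data_dir: str | Path,
    metadata: dict | None = None,
) -> None:
    """Write the delimited-text layout consumed by :func:`load_dataset`."""
    data_dir = Path(data_dir)
    data_dir.mkdir(parents=True, exist_ok=True)
    ids = pd.Index(dataset.respondent_ids, name="respondent_id")

    def _write(df: pd.DataFrame, name: str) -> None:
        df.to_csv(data_dir / name, float_format=FLOAT_FMT)

    _write(pd.DataFrame(dataset.responses, index=ids, columns=dataset.item_ids),
           "responses.csv")
    _write(
        pd.DataFrame(
            dataset.z, index=ids,
            columns=[f"z{m}" for m in range(dataset.n_groups)],
        ),
        "groups.csv",
    )
    if dataset.theta_hat is not None:
        _write(pd.DataFrame({"theta_hat": dataset.theta_hat}, index=ids), "theta.csv")
    for item, F in dataset.features.items():
        _write(
            pd.DataFrame(F, index=ids,
                         columns=[f"f{kk}" for kk in range(F.shape[1])]),
            f"features_{item}.csv",
        )
    if metadata is not None:
        (data_dir / "metadata.json").write_text(
            json.dumps(metadata, indent=2, default=str) + "\n"
        )
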