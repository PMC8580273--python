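"""Delimited-text and JSON interchange.

Datasets are CSV with an outcome column ``y`` and exposure columns
``x1..xT`` (optional covariates ``c1..cK``); draw matrices are CSV with
header ``w1..wT``.  Results serialize to JSON through their ``to_dict``
methods.  Occasion indices are 1-based everywhere to match the ranking
notation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError
from .model import LifecourseDataset, PosteriorDraws
from .rankings import DrawMatrix

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_draws",
    "write_draws",
    "write_posterior",
    "write_json",
    "read_json",
]


def write_dataset(data: LifecourseDataset, path) -> None:
    cols = {"y": data.outcome}
    for j in range(data.T):
        cols[f"x{j + 1}"] = data.exposures[:, j]
    for k in range(data.K):
        cols[f"c{k + 1}"] = data.covariates[:, k]
    pd.DataFrame(cols).to_csv(path, index=False)


def read_dataset(
    path,
    outcome: str = "y",
    exposures: list[str] | None = None,
    covariates: list[str] | None = None,
) -> LifecourseDataset:
    """Load a cohort CSV.  Without explicit column lists, exposure columns
    are those named ``x<j>`` and covariates those named ``c<k>``."""
    df = pd.read_csv(path)
    if outcome not in df.columns:
        raise InvalidInputError(f"outcome column {outcome!r} not found")
    if exposures is None:
        exposures = sorted(
            (c for c in df.columns if c.startswith("x") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
    if not exposures:
        raise InvalidInputError("no exposure columns found")
    if covariates is None:
        covariates = sorted(
            (c for c in df.columns if c.startswith("c") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
    missing = [c for c in [outcome, *exposures, *covariates] if c not in df.columns]
    if missing:
        raise InvalidInputError(f"missing columns: {missing}")
    return LifecourseDataset(
        outcome=df[outcome].to_numpy(float),
        exposures=df[exposures].to_numpy(float),
        covariates=df[covariates].to_numpy(float) if covariates else None,
        occasion_names=tuple(exposures),
    )


def write_draws(draws, path) -> None:
    values = draws.values if isinstance(draws, DrawMatrix) else np.asarray(draws, float)
    header = [f"w{j + 1}" for j in range(values.shape[1])]
    pd.DataFrame(values, columns=header).to_csv(path, index=False)


def read_draws(path) -> DrawMatrix:
    return DrawMatrix(pd.read_csv(path).to_numpy(float))


def write_posterior(draws: PosteriorDraws, prefix) -> None:
    """Write weight draws as CSV plus a JSON diagnostics sidecar."""
    prefix = Path(prefix)
    write_draws(draws.weight_draws, prefix.with_suffix(".csv"))
    scalars = {"delta": draws.delta_draws, "sigma": draws.sigma_draws}
    if draws.intercept_draws is not None:
        scalars["intercept"] = draws.intercept_draws
    pd.DataFrame(scalars).to_csv(prefix.parent / (prefix.name + "_scalars.csv"), index=False)
    write_json(
        {"diagnostics": draws.diagnostics, "accept_rate": draws.accept_rate},
        prefix.parent / (prefix.name + "_diagnostics.json"),
    )


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def _default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
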