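"""Reading and writing response matrices, configs and result tables.

Canonical on-disk form is a wide CSV: one row per person, one column per
item, header row of item ids, an optional leading ``person`` id column, and
a configurable missing code (default "NA").  A long form (person, item,
response) is also supported and round-trips to the wide form exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gpcm import ResponseMatrix

__all__ = ["RunConfig", "read_responses", "write_responses", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Round-trippable run configuration."""

    responses_path: str = "responses.csv"
    output_dir: str = "."
    missing_code: str = "NA"
    n_categories: int = 4
    format: str = "wide"
    seed: int = 0
    n_chains: int = 2
    n_burnin: int = 1000
    n_sampling: int = 2000
    er_lower: float = 0.05
    er_upper: float = 0.95
    d_cutoff: float = 0.1
    group_cutoff: float = 0.1
    dim_of_item: list | None = None


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=False)


def read_responses(
    path: str | Path,
    format: str = "wide",
    missing_code: str = "NA",
    c: int = 4,
) -> ResponseMatrix:
    """Read a response matrix from delimited text.

    Wide format: header of item ids, optional first column named
    ``person``.  Long format: columns person, item, response.  Categories
    are validated against ``c``; an out-of-range cell is reported by
    position.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty input file: {path}")
    if format == "wide":
        df = pd.read_csv(path, na_values=[missing_code], keep_default_na=False)
        if df.empty:
            raise ValueError(f"no data rows in {path}")
        if df.columns[0].lower() in ("person", "person_id", "id"):
            person_ids = df.iloc[:, 0].astype(str).tolist()
            df = df.iloc[:, 1:]
        else:
            person_ids = [f"p{i + 1}" for i in range(len(df))]
        item_ids = list(df.columns)
        values = df.to_numpy(dtype=float)
    elif format == "long":
        df = pd.read_csv(path, na_values=[missing_code], keep_default_na=False)
        required = {"person", "item", "response"}
        if not required.issubset(df.columns):
            raise ValueError("long format needs columns person, item, response")
        wide = df.pivot(index="person", columns="item", values="response")
        # preserve first-appearance order of persons and items
        wide = wide.reindex(
            index=pd.unique(df["person"]), columns=pd.unique(df["item"])
        )
        person_ids = [str(p) for p in wide.index]
        item_ids = [str(i) for i in wide.columns]
        values = wide.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown format {format!r}")

    mask = ~np.isfinite(values)
    ints = np.where(mask, 0, np.nan_to_num(values)).astype(np.int64)
    bad = ~mask & (np.where(mask, 1, values) != ints)
    if bad.any():
        r, col = np.argwhere(bad)[0]
        raise ValueError(
            f"non-integer response at person {person_ids[r]}, item {item_ids[col]}"
        )
    return ResponseMatrix(
        responses=ints, c=c, missing_mask=mask, person_ids=person_ids, item_ids=item_ids
    )


def write_responses(
    data: ResponseMatrix, path: str | Path, missing_code: str = "NA"
) -> None:
    """Write a response matrix as wide CSV with a leading person column."""
    out = pd.DataFrame(
        np.where(data.missing_mask, missing_code, data.responses.astype(object)),
        columns=data.item_ids,
    )
    out.insert(0, "person", data.person_ids)
    out.to_csv(path, index=False)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
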