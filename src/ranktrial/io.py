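"""CSV readers/writers and JSON output helpers.

Interchange formats
-------------------
* Tricot CSV: columns ``id, item_A, item_B, item_C, best, worst`` (best and
  worst hold the position letters "A"/"B"/"C"); any additional columns are
  carried through as block covariates.
* Long numeric CSV: columns ``block, item, value``.
* Rankings CSV: wide block x item matrix of ranks, 0 = not evaluated.

JSON artifacts written by the CLI embed the tool version, a hash of the run
configuration and the seed, so identical configuration and inputs give
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from importlib import metadata

import numpy as np
import pandas as pd

from .rankings import ItemSet, RankingMatrix, TricotRecord

__all__ = ["read_tricot_csv", "write_tricot_csv", "read_numeric_csv",
           "read_rankings_csv", "write_rankings_csv", "load_json",
           "write_json", "run_meta"]

_TRICOT_COLS = ["id", "item_A", "item_B", "item_C", "best", "worst"]
_BAD_ROW_THRESHOLD = 0.2


def _version() -> str:
    try:
        return metadata.version("ranktrial")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def run_meta(config: dict) -> dict:
    """Version + config-hash stamp embedded in every JSON artifact."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {
        "tool": "ranktrial",
        "version": _version(),
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "config": config,
    }


def read_tricot_csv(path) -> tuple[list[TricotRecord], pd.DataFrame]:
    """Parse a tricot CSV into records and the carried-through covariates.

    Rows with malformed best/worst answers are collected and reported with
    their line numbers; the run aborts if they exceed 20% of the file.
    Missing answers are represented as ``None`` (dropped later by
    :func:`ranktrial.rankings.rank_tricot`, with a warning).
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _TRICOT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"tricot file {path} is missing required column(s): {missing}")
    records: list[TricotRecord] = []
    bad: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            best = row["best"] if pd.notna(row["best"]) else None
            worst = row["worst"] if pd.notna(row["worst"]) else None
            records.append(
                TricotRecord(
                    row["id"],
                    (row["item_A"], row["item_B"], row["item_C"]),
                    best,
                    worst,
                )
            )
        except (ValueError, TypeError) as exc:
            bad.append((line, str(exc)))
    if bad:
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in bad[:5])
        if len(bad) > len(df) * _BAD_ROW_THRESHOLD:
            raise ValueError(
                f"{len(bad)} unparseable row(s) in {path} (> "
                f"{_BAD_ROW_THRESHOLD:.0%} of file): {detail}"
            )
        import warnings

        warnings.warn(
            f"skipped {len(bad)} unparseable row(s) in {path}: {detail}",
            UserWarning, stacklevel=2,
        )
    covariates = df.drop(columns=_TRICOT_COLS)
    # numeric covariate columns come back as strings; convert where possible
    for col in covariates.columns:
        try:
            covariates[col] = pd.to_numeric(covariates[col])
        except (ValueError, TypeError):
            pass
    return records, covariates


def write_tricot_csv(records, path, covariates: pd.DataFrame | None = None) -> None:
    rows = []
    for rec in records:
        rows.append(
            {
                "id": rec.block_id,
                "item_A": rec.items[0],
                "item_B": rec.items[1],
                "item_C": rec.items[2],
                "best": rec.best,
                "worst": rec.worst,
            }
        )
    df = pd.DataFrame(rows, columns=_TRICOT_COLS)
    if covariates is not None:
        df = pd.concat([df, covariates.reset_index(drop=True)], axis=1)
    df.to_csv(path, index=False)


def read_numeric_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("block", "item", "value") if c not in df.columns]
    if missing:
        raise ValueError(f"numeric file {path} is missing required column(s): {missing}")
    return df[["block", "item", "value"]]


def write_rankings_csv(R: RankingMatrix, path) -> None:
    R.to_frame().to_csv(path)


def read_rankings_csv(path) -> RankingMatrix:
    df = pd.read_csv(path, index_col=0)
    return RankingMatrix(df.to_numpy(dtype=np.int64), ItemSet(df.columns), list(df.index))


def write_json(obj: dict, path, config: dict | None = None) -> None:
    out = dict(obj)
    if config is not None:
        out["_meta"] = run_meta(config)
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2)


def load_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
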