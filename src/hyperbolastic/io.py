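"""Reading and writing growth series and parameter sets.

Series are two-column CSV/TSV files with header ``time,weight`` (days,
grams). The combined IAA+DMSO solid-Ehrlich-carcinoma arm (18 mean tumor
weights over days 9-82) ships as a packaged fixture.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import pandas as pd

from .exceptions import InputError
from .models import AnchoredParams, GrowthSeries, ModelFamily

__all__ = [
    "read_series",
    "write_series",
    "load_combined_treatment_series",
    "params_to_json",
    "params_from_json",
]

_FIXTURE = "ehrlich_combined_iaa_dmso.csv"


def read_series(path: str | Path, label: str | None = None) -> GrowthSeries:
    """Read a ``time,weight`` CSV/TSV into a :class:`GrowthSeries`.

    Times must already be sorted: unsorted input is an error, not silently
    reordered, because row order is part of the experimental record.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except Exception as exc:  # pandas raises several parser error types
        raise InputError(f"could not parse {path}: {exc}") from exc
    cols = [c.strip().lower() for c in df.columns]
    if "time" not in cols or "weight" not in cols:
        raise InputError(f"{path}: expected columns 'time' and 'weight', got {list(df.columns)}")
    df.columns = cols
    for col in ("time", "weight"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is line 1
            raise InputError(f"{path}: non-numeric value in column '{col}' at line {row}")
        if df[col].isna().any():
            row = int(df[col].isna().idxmax()) + 2
            raise InputError(f"{path}: missing value in column '{col}' at line {row}")
    t = pd.to_numeric(df["time"]).to_numpy(float)
    w = pd.to_numeric(df["weight"]).to_numpy(float)
    if len(t) and (t[1:] <= t[:-1]).any():
        row = int((t[1:] <= t[:-1]).argmax()) + 3
        raise InputError(f"{path}: times not strictly increasing at line {row}")
    try:
        return GrowthSeries(t, w, label=label if label is not None else path.stem)
    except Exception as exc:
        raise InputError(f"{path}: {exc}") from exc


def write_series(series: GrowthSeries, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    pd.DataFrame({"time": series.times, "weight": series.weights}).to_csv(
        path, index=False, sep=sep
    )


def load_combined_treatment_series() -> GrowthSeries:
    """The packaged combined IAA+DMSO treatment arm (18 observations)."""
    ref = resources.files("hyperbolastic.data").joinpath(_FIXTURE)
    with resources.as_file(ref) as p:
        return read_series(p, label="IAA+DMSO")


def params_to_json(params: AnchoredParams) -> str:
    """Serialize an anchored parameter set as a JSON object."""
    return json.dumps(
        {
            "family": params.family.value,
            "params": dict(params.values),
            "t0": params.t0,
            "P0": params.P0,
            "alpha": params.alpha,
        },
        indent=2,
    )


def params_from_json(text: str) -> AnchoredParams:
    obj = json.loads(text)
    try:
        return AnchoredParams(
            ModelFamily(obj["family"]), obj["params"], obj["t0"], obj["P0"]
        )
    except KeyError as exc:
        raise InputError(f"parameter JSON missing key {exc}") from exc
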