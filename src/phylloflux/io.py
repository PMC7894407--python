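"""CSV/JSON/YAML round-tripping for the pipeline's data products."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .kinetics import AssayTrace

_REQUIRED_SERIES_COLS = {"time_s", "phase", "light", "flow_lpm", "leaf_area_m2",
                         "temperature_K", "pressure_Pa"}


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, frozenset):
        return sorted(obj)
    return obj


def write_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n")


def write_enclosure_series(series: pd.DataFrame, path: str | Path,
                           truth: Any | None = None) -> None:
    """Write an enclosure series CSV, plus a ``<name>.truth.json``
    sidecar recording the generating scenario when given."""
    path = Path(path)
    series.to_csv(path, index=False)
    if truth is not None:
        write_json(truth, path.with_suffix(".truth.json"))


def read_enclosure_series(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = _REQUIRED_SERIES_COLS - set(df.columns)
    if missing:
        raise ValueError(f"{path}: not an enclosure series (missing {sorted(missing)})")
    return df


def write_assay_traces(traces: list[AssayTrace], path: str | Path) -> None:
    """Long-format CSV: one row per (trace, timepoint)."""
    rows = []
    for k, tr in enumerate(traces):
        for t, a in zip(tr.time, tr.absorbance):
            rows.append({"trace": k, "time_min": t, "absorbance": a,
                         "mvk_mM": tr.mvk_conc, "nadph_mM": tr.nadph_conc,
                         "temperature_C": tr.temperature,
                         "path_cm": tr.path_length, "epsilon": tr.epsilon_nadph})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_assay_traces(path: str | Path) -> list[AssayTrace]:
    df = pd.read_csv(path)
    traces = []
    for _, grp in df.groupby("trace", sort=True):
        traces.append(AssayTrace(
            time=grp["time_min"].to_numpy(), absorbance=grp["absorbance"].to_numpy(),
            mvk_conc=float(grp["mvk_mM"].iloc[0]), nadph_conc=float(grp["nadph_mM"].iloc[0]),
            temperature=float(grp["temperature_C"].iloc[0]),
            path_length=float(grp["path_cm"].iloc[0]),
            epsilon_nadph=float(grp["epsilon"].iloc[0])))
    return traces


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
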