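"""Readers and writers for the pipeline's delimited-text interchange.

Tabular data use tidy long format
(``subject_id, t_min, variable, value, units``); subject scalars are a
one-row-per-subject table; parameters, fits and statistics travel as
JSON.  No binary formats.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ClampTimeSeries, SubjectRecord
from .synthetic import Cohort

__all__ = [
    "write_series_long", "read_series_long", "write_subject_table",
    "read_subject_table", "write_cohort", "read_cohort_dir",
    "write_json", "read_json", "config_hash",
]

_UNITS = {"Gc": "mmol/L", "I": "pmol/L", "Gg": "ng/L", "CP": "nmol/L",
          "f1": "mg/kg/min", "f2": "mU/kg/min"}

_OGTT_COLS = ("ogtt_t", "ogtt_glucose", "ogtt_insulin")


def write_series_long(path, series_map: dict) -> None:
    """Write clamp series (samples + infusion grids) in tidy long format."""
    rows = []
    for sid, ts in series_map.items():
        for var, (t, v) in ts.samples.items():
            rows.append(pd.DataFrame({
                "subject_id": sid, "t_min": t, "variable": var,
                "value": v, "units": _UNITS[var]}))
        for var, arr in (("f1", ts.f1), ("f2", ts.f2)):
            if arr is not None:
                rows.append(pd.DataFrame({
                    "subject_id": sid, "t_min": np.arange(len(arr), dtype=float),
                    "variable": var, "value": arr, "units": _UNITS[var]}))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_series_long(path) -> dict:
    """Read a long-format series file back into ClampTimeSeries objects."""
    df = pd.read_csv(path)
    out = {}
    for sid, grp in df.groupby("subject_id", sort=True):
        samples, f1, f2 = {}, None, None
        for var, sub in grp.groupby("variable", sort=True):
            sub = sub.sort_values("t_min")
            if var in ("f1", "f2"):
                arr = sub["value"].to_numpy()
                if var == "f1":
                    f1 = arr
                else:
                    f2 = arr
            else:
                samples[var] = (sub["t_min"].to_numpy(),
                                sub["value"].to_numpy())
        out[str(sid)] = ClampTimeSeries(subject_id=str(sid), samples=samples,
                                        f1=f1, f2=f2)
    return out


def write_subject_table(path, records: list) -> None:
    """One-row-per-subject scalar table (OGTT series JSON-encoded inline)."""
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        for col in _OGTT_COLS:
            v = d.pop(col)
            d[col] = json.dumps(np.asarray(v).tolist()) if v is not None \
                else ""
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_subject_table(path) -> list:
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        d = row.to_dict()
        for col in _OGTT_COLS:
            v = d.get(col)
            d[col] = np.asarray(json.loads(v)) if isinstance(v, str) and v \
                else None
        d["subject_id"] = str(d["subject_id"])
        records.append(SubjectRecord(**d))
    return records


def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Emit a cohort in the preprocess input formats + ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "series": out / "clamp_series.csv",
        "subjects": out / "subjects.csv",
        "ground_truth": out / "ground_truth.json",
        "config": out / "cohort_config.json",
    }
    write_series_long(paths["series"], cohort.series)
    write_subject_table(paths["subjects"], cohort.records)
    cohort.ground_truth.to_json(paths["ground_truth"], orient="records",
                                indent=1)
    cfg = dataclasses.asdict(cohort.config)
    cfg["config_hash"] = config_hash(cohort.config)
    write_json(paths["config"], cfg)
    return {k: str(v) for k, v in paths.items()}


def read_cohort_dir(in_dir) -> tuple:
    """Load (records, series_map, ground_truth_frame) from a cohort dir."""
    p = Path(in_dir)
    records = read_subject_table(p / "subjects.csv")
    series = read_series_long(p / "clamp_series.csv")
    gt = pd.read_json(p / "ground_truth.json", orient="records") \
        if (p / "ground_truth.json").exists() else None
    return records, series, gt


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        return super().default(o)


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, cls=_NumpyEncoder, sort_keys=True)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def config_hash(config) -> str:
    """Stable short hash of a (dataclass) configuration."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        config = dataclasses.asdict(config)
    blob = json.dumps(config, sort_keys=True, cls=_NumpyEncoder)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
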