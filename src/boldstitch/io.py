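"""File formats: amplitude tables (CSV), time series (TSV), schedules and
results (JSON).

The amplitude-table schema is one row per (roi, duration, contrast, side):

    roi, duration_s, contrast, side, amplitude_pct, se_pct, n_runs

with ``side`` one of ``single_A``, ``single_B``, ``double``.  Every
(roi, duration, contrast) cell must have a ``double`` row and at least one
single-sided row; the two single sides are averaged on read.  Result
writers embed the seed and a configuration hash for provenance and use a
deterministic field order, so identical inputs give byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .deconvolution import EventSchedule, TimeSeriesDataset
from .synthetic import SummationDataset

__all__ = [
    "read_amplitude_table",
    "write_amplitude_table",
    "write_timeseries",
    "read_timeseries",
    "write_schedule",
    "read_schedule",
    "config_hash",
    "write_results",
]

AMPLITUDE_COLUMNS = ["roi", "duration_s", "contrast", "side",
                     "amplitude_pct", "se_pct", "n_runs"]
SIDES = {"single_A", "single_B", "double"}


def read_amplitude_table(path) -> list[SummationDataset]:
    """Read an amplitude-table CSV into one dataset per (roi, duration).

    Single-sided A/B rows are averaged into ``b_single`` (SE of the mean,
    assuming independent sides).  Missing columns, non-numeric cells and
    contrasts lacking a ``double`` row are errors naming the offending
    rows; a cell with only one single side is accepted with a warning.
    """
    df = pd.read_csv(path)
    missing = [c for c in AMPLITUDE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"amplitude table {path}: missing columns {missing}")
    bad_side = df.index[~df["side"].isin(SIDES)].tolist()
    if bad_side:
        raise ValueError(f"amplitude table {path}: invalid side values in "
                         f"rows {[i + 2 for i in bad_side]}")
    for col in ("duration_s", "contrast", "amplitude_pct", "se_pct", "n_runs"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna()].tolist()
        if bad:
            raise ValueError(f"amplitude table {path}: non-numeric '{col}' "
                             f"in rows {[i + 2 for i in bad]}")
        df[col] = coerced
    if not np.all(np.isfinite(df[["contrast", "amplitude_pct", "se_pct"]])):
        raise ValueError(f"amplitude table {path}: non-finite numeric fields")

    datasets = []
    for (roi, dur), grp in df.groupby(["roi", "duration_s"], sort=True):
        rows = {"contrast": [], "b_single": [], "se_single": [], "b_double": [],
                "se_double": [], "n_runs": [], "b_a": [], "b_b": []}
        for contrast, cell in grp.groupby("contrast", sort=True):
            by_side = {s: cell[cell["side"] == s] for s in SIDES}
            if len(by_side["double"]) != 1:
                raise ValueError(
                    f"amplitude table {path}: roi={roi} duration={dur} "
                    f"contrast={contrast:g} needs exactly one 'double' row, "
                    f"found {len(by_side['double'])}")
            singles = [by_side[s] for s in ("single_A", "single_B")
                       if len(by_side[s]) == 1]
            if not singles:
                raise ValueError(
                    f"amplitude table {path}: roi={roi} duration={dur} "
                    f"contrast={contrast:g} has no single-sided row")
            if len(singles) == 1:
                warnings.warn(
                    f"roi={roi} duration={dur} contrast={contrast:g}: only "
                    "one single side present; using it as b_single",
                    stacklevel=2)
            amps = [float(s["amplitude_pct"].iloc[0]) for s in singles]
            ses = [float(s["se_pct"].iloc[0]) for s in singles]
            dbl = by_side["double"]
            rows["contrast"].append(float(contrast))
            rows["b_single"].append(float(np.mean(amps)))
            rows["se_single"].append(
                float(np.sqrt(np.sum(np.square(ses))) / len(ses)))
            rows["b_double"].append(float(dbl["amplitude_pct"].iloc[0]))
            rows["se_double"].append(float(dbl["se_pct"].iloc[0]))
            rows["n_runs"].append(float(dbl["n_runs"].iloc[0]))
            rows["b_a"].append(amps[0])
            rows["b_b"].append(amps[-1])
        datasets.append(SummationDataset(
            roi_label=str(roi),
            duration_s=float(dur),
            contrasts=np.array(rows["contrast"]),
            b_single=np.array(rows["b_single"]),
            se_single=np.array(rows["se_single"]),
            b_double=np.array(rows["b_double"]),
            se_double=np.array(rows["se_double"]),
            n_runs=np.array(rows["n_runs"]),
            b_single_A=np.array(rows["b_a"]),
            b_single_B=np.array(rows["b_b"]),
        ))
    return datasets


def write_amplitude_table(datasets, path) -> None:
    """Write datasets in the amplitude-table CSV schema."""
    if isinstance(datasets, SummationDataset):
        datasets = [datasets]
    rows = []
    for ds in datasets:
        b_a = ds.b_single_A if ds.b_single_A is not None else ds.b_single
        b_b = ds.b_single_B if ds.b_single_B is not None else ds.b_single
        se_side = ds.se_single * np.sqrt(2.0)
        for i, c in enumerate(ds.contrasts):
            for side, amp, se in (("single_A", b_a[i], se_side[i]),
                                  ("single_B", b_b[i], se_side[i]),
                                  ("double", ds.b_double[i], ds.se_double[i])):
                rows.append({"roi": ds.roi_label, "duration_s": ds.duration_s,
                             "contrast": c, "side": side,
                             "amplitude_pct": amp, "se_pct": se,
                             "n_runs": ds.n_runs[i]})
    pd.DataFrame(rows, columns=AMPLITUDE_COLUMNS).to_csv(path, index=False)


def write_timeseries(ts: TimeSeriesDataset, path) -> None:
    """Plain-matrix TSV: one column per unit, plus a header comment with
    tr_s, scan boundaries and unit labels."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# tr_s={ts.tr_s}\n")
        fh.write("# scan_boundaries=" + ",".join(map(str, ts.scan_boundaries)) + "\n")
        fh.write("# units=" + ",".join(ts.unit_labels) + "\n")
        np.savetxt(fh, ts.signal.T, delimiter="\t", fmt="%.10g")


def read_timeseries(path) -> TimeSeriesDataset:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            meta[key.strip()] = val
    signal = np.loadtxt(path, delimiter="\t", comments="#").T
    return TimeSeriesDataset(
        tr_s=float(meta["tr_s"]),
        signal=np.atleast_2d(signal),
        scan_boundaries=np.array([int(x) for x in meta["scan_boundaries"].split(",")]),
        unit_labels=meta["units"].split(","),
    )


def write_schedule(schedule: EventSchedule, path) -> None:
    payload = [{"condition": c, "onset_s": o, "duration_s": d}
               for c, o, d in schedule.events]
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_schedule(path) -> EventSchedule:
    payload = json.loads(Path(path).read_text())
    return EventSchedule(events=[(e["condition"], float(e["onset_s"]),
                                  float(e["duration_s"])) for e in payload])


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def config_hash(config) -> str:
    """Stable short hash of any (nested, dataclass-friendly) configuration."""
    canon = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_results(results, path, seed: int | None = None,
                  config=None) -> None:
    """Write a results object to JSON with provenance.

    Output is deterministic (sorted keys, fixed float repr): writing the
    same results twice yields byte-identical files.
    """
    payload = {"results": _jsonable(results)}
    payload["provenance"] = {
        "seed": seed,
        "config_hash": config_hash(config) if config is not None else None,
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")
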