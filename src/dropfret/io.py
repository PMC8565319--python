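"""Plain-text I/O: decay-curve TSV, trajectory/trace CSV, results JSON.

Decay curves are stored as two- or three-column TSV (time_ns, counts,
optional sigma_ns) preceded by ``# key: value`` metadata lines.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .decay import DecayCurve
from .errors import DataError
from .kinetics import InitialConditions, IntensityTrace, ObservedTrajectory

__all__ = [
    "write_decay_tsv", "read_decay_tsv",
    "write_trajectories_csv", "read_trajectories_csv",
    "write_traces_csv", "read_traces_csv",
    "write_json", "read_json",
]


def _meta_value(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


def write_decay_tsv(curve: DecayCurve, path) -> None:
    path = Path(path)
    lines = []
    meta = {
        "window_ns": curve.window,
        "propagation_time_s": curve.propagation_time,
        "tag": curve.tag,
        "experiment_id": curve.experiment_id,
    }
    for k, v in meta.items():
        if v is not None:
            lines.append(f"# {k}: {_meta_value(v)}")
    has_sigma = curve.sigma_bins is not None
    header = "time_ns\tcounts" + ("\tsigma_ns" if has_sigma else "")
    lines.append(header)
    for i in range(curve.n_bins):
        row = f"{curve.times[i]:.9g}\t{curve.counts[i]:.9g}"
        if has_sigma:
            row += f"\t{curve.sigma_bins[i]:.9g}"
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")


def read_decay_tsv(path) -> DecayCurve:
    path = Path(path)
    meta: dict = {}
    rows = []
    header = None
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition(":")
            meta[key.strip()] = value.strip()
            continue
        if header is None:
            header = line.split("\t")
            continue
        rows.append([float(x) for x in line.split("\t")])
    if header is None or not rows:
        raise DataError(f"no decay data found in {path}")
    arr = np.asarray(rows, dtype=float)
    cols = dict(zip(header, arr.T))
    if "time_ns" not in cols or "counts" not in cols:
        raise DataError(f"{path} must have time_ns and counts columns")
    prop = meta.get("propagation_time_s")
    return DecayCurve(
        times=cols["time_ns"], counts=cols["counts"],
        window=float(meta.get("window_ns", cols["time_ns"][-1])),
        propagation_time=None if prop in (None, "") else float(prop),
        tag=meta.get("tag") or None,
        sigma_bins=cols.get("sigma_ns"),
        experiment_id=meta.get("experiment_id") or None)


def write_trajectories_csv(observed: list[ObservedTrajectory], path) -> None:
    rows = []
    for obs in observed:
        for i in range(obs.times.size):
            rows.append({
                "experiment_id": obs.experiment_id, "T_s": obs.times[i],
                "conc_sl_um": obs.sl[i], "conc_ic_um": obs.ic[i],
                "conc_ed_um": obs.ed[i],
                "sl0_um": obs.init.sl0, "p0_um": obs.init.p0,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trajectories_csv(path) -> list[ObservedTrajectory]:
    df = pd.read_csv(path)
    out = []
    for exp_id, g in df.groupby("experiment_id", dropna=False):
        g = g.sort_values("T_s")
        out.append(ObservedTrajectory(
            times=g["T_s"].to_numpy(), sl=g["conc_sl_um"].to_numpy(),
            ic=g["conc_ic_um"].to_numpy(), ed=g["conc_ed_um"].to_numpy(),
            init=InitialConditions(sl0=float(g["sl0_um"].iloc[0]),
                                   p0=float(g["p0_um"].iloc[0])),
            experiment_id=str(exp_id)))
    if not out:
        raise DataError(f"no trajectories found in {path}")
    return out


def write_traces_csv(traces: list[IntensityTrace], path) -> None:
    rows = []
    for tr in traces:
        for i in range(tr.times.size):
            rows.append({
                "experiment_id": tr.experiment_id, "time_s": tr.times[i],
                "intensity": tr.intensity[i],
                "sl0_um": tr.design.sl0, "p0_um": tr.design.p0,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_traces_csv(path) -> list[IntensityTrace]:
    df = pd.read_csv(path)
    out = []
    for exp_id, g in df.groupby("experiment_id", dropna=False):
        g = g.sort_values("time_s")
        out.append(IntensityTrace(
            times=g["time_s"].to_numpy(), intensity=g["intensity"].to_numpy(),
            design=InitialConditions(sl0=float(g["sl0_um"].iloc[0]),
                                     p0=float(g["p0_um"].iloc[0])),
            experiment_id=str(exp_id)))
    if not out:
        raise DataError(f"no traces found in {path}")
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def read_json(path) -> dict:
    return json.loads(Path(path).read_text())
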