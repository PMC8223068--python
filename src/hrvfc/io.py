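"""Plain-text readers/writers for every artifact the pipeline exchanges.

Everything is TSV with a header (or JSON for configuration/manifests):
RR series, motion parameters (tx ty tz in mm, rx ry rz in radians), parcel
time series (volumes x parcels), cardiac metric series, partition tables,
FC matrices, state masks, subject tables.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .cardiac import CardiacMetricSeries, RRSeries
from .preproc import MotionParams, ParcelTimeSeries
from .state_fc import NetworkPartition, StateMask

__all__ = [
    "write_rr", "read_rr", "write_motion", "read_motion",
    "write_parcel_ts", "read_parcel_ts", "write_metrics", "read_metrics",
    "write_partition", "read_partition", "write_fc_matrix", "read_fc_matrix",
    "write_state_mask", "read_state_mask", "write_json", "read_json",
    "file_sha256",
]


def write_rr(path, rr: RRSeries) -> None:
    # one row per beat; rr is blank for the first beat (no completed interval)
    df = pd.DataFrame({"beat_time_s": rr.beat_times,
                       "rr_ms": np.concatenate([[np.nan], rr.rr])})
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_rr(path) -> RRSeries:
    df = pd.read_csv(path, sep="\t")
    return RRSeries.from_beat_times(df["beat_time_s"].to_numpy(float))


def write_motion(path, motion: MotionParams) -> None:
    cols = ["tx_mm", "ty_mm", "tz_mm", "rx_rad", "ry_rad", "rz_rad"]
    pd.DataFrame(motion.params, columns=cols).to_csv(
        path, sep="\t", index=False, float_format="%.8f")


def read_motion(path) -> MotionParams:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 6:
        raise ValueError("motion table must have exactly six columns")
    return MotionParams(df.to_numpy(float))


def write_parcel_ts(path, ts: ParcelTimeSeries) -> None:
    df = pd.DataFrame(ts.data, columns=[str(p) for p in ts.parcel_ids])
    df.insert(0, "retained", ts.censor.astype(int))
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    meta = {"tr": ts.tr, "filtered": ts.filtered, "denoised": ts.denoised}
    Path(str(path) + ".json").write_text(json.dumps(meta))


def read_parcel_ts(path) -> ParcelTimeSeries:
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(Path(str(path) + ".json").read_text())
    censor = df.pop("retained").to_numpy(bool)
    ids = np.array([int(c) for c in df.columns])
    return ParcelTimeSeries(df.to_numpy(float), meta["tr"], ids, censor,
                            meta.get("filtered", False),
                            meta.get("denoised", False))


def write_metrics(path, m: CardiacMetricSeries) -> None:
    pd.DataFrame({
        "time_s": m.timestamps, "mean_rr_ms": m.mean_rr, "rmssd_ms": m.rmssd,
        "lf_hrv_pct": m.lf_hrv, "hf_hrv_pct": m.hf_hrv, "hr_bpm": m.hr,
    }).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_metrics(path, window_length: float = 100.0) -> CardiacMetricSeries:
    df = pd.read_csv(path, sep="\t")
    return CardiacMetricSeries(
        df["time_s"].to_numpy(float), df["mean_rr_ms"].to_numpy(float),
        df["rmssd_ms"].to_numpy(float), df["lf_hrv_pct"].to_numpy(float),
        df["hf_hrv_pct"].to_numpy(float), df["hr_bpm"].to_numpy(float),
        window_length)


def write_partition(path, partition: NetworkPartition) -> None:
    partition.table.to_csv(path, sep="\t", index=False)


def read_partition(path, validate_counts: bool = True) -> NetworkPartition:
    return NetworkPartition(pd.read_csv(path, sep="\t"),
                            validate_counts=validate_counts)


def write_fc_matrix(path, fc: np.ndarray, labels=None) -> None:
    labels = labels if labels is not None else range(1, fc.shape[0] + 1)
    pd.DataFrame(fc, columns=[str(x) for x in labels]).to_csv(
        path, sep="\t", index=False, float_format="%.6f")


def read_fc_matrix(path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(float)


def write_state_mask(path, mask: StateMask) -> None:
    pd.DataFrame({"low": mask.low.astype(int),
                  "high": mask.high.astype(int)}).to_csv(
        path, sep="\t", index=False)


def read_state_mask(path, metric: str = "") -> StateMask:
    df = pd.read_csv(path, sep="\t")
    return StateMask(metric, df["low"].to_numpy(bool), df["high"].to_numpy(bool))


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True,
                                     default=_jsonable))


def read_json(path):
    return json.loads(Path(path).read_text())


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer, np.floating, np.bool_)):
        return x.item()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
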