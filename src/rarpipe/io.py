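"""File formats: raw-signal tables, bed logs, CSV conventions.

All CSV output is UTF-8, comma-separated, "." decimal, ISO-8601
timestamps, with the explicit missing-value token ``NA``.
"""

from __future__ import annotations

import datetime as dt
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import BedTimeLog, DaySignal, RawAccelRecording

__all__ = [
    "write_csv",
    "read_csv",
    "write_raw_signal",
    "read_raw_signal",
    "write_bedlog",
    "read_bedlog",
    "sha256_of",
]

NA_TOKEN = "NA"


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, na_rep=NA_TOKEN)
    return path


def read_csv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, na_values=[NA_TOKEN], keep_default_na=True, **kwargs)


def write_raw_signal(recording: RawAccelRecording, path: str | Path) -> Path:
    """Delimited raw-signal file: timestamp, ax, ay, az, wear_flag."""
    return write_csv(recording.to_frame(), path)


def read_raw_signal(
    path: str | Path, participant_id: str = "", visit: str = ""
) -> RawAccelRecording:
    """Read a raw-signal table back into a day-chunked recording."""
    df = read_csv(path, parse_dates=["timestamp"])
    if len(df) < 2:
        raise ValueError("raw signal file needs at least two samples")
    step = (df["timestamp"].iloc[1] - df["timestamp"].iloc[0]).total_seconds()
    fs = 1.0 / step
    rec = RawAccelRecording(participant_id=participant_id, visit=visit, sample_rate=fs)
    for date, day in df.groupby(df["timestamp"].dt.date, sort=True):
        acc = day[["ax", "ay", "az"]].to_numpy(dtype=np.float32)
        wear = day["wear_flag"].to_numpy().astype(bool)
        rec.days.append(DaySignal(date=date, sample_rate=fs, acc=acc, wear=wear))
    return rec


def write_bedlog(bedlog: BedTimeLog, path: str | Path) -> Path:
    return write_csv(bedlog.frame, path)


def read_bedlog(path: str | Path) -> BedTimeLog:
    df = read_csv(path)
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return BedTimeLog(df)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
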