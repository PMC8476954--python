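"""Reading, calibrating and reducing four-channel chair load-cell recordings.

A "smart chair" carries four load cells under the seat corners: A1
(front-left), A2 (back-left), A3 (front-right) and A4 (back-right), each
reporting kilograms.  The centre of pressure (COP) of the sitter is the
corner-weighted combination

    x = (-A1 - A2 + A3 + A4) / 4        (left-right axis)
    y = ( A1 - A2 + A3 - A4) / 4        (front-back axis)

i.e. each corner load is multiplied by its corner coordinate (+-1, +-1) and
the sum is divided by four.  The coordinate is deliberately *not* divided by
the total load: downstream segmentation works on correlation structure, which
is insensitive to the overall scale, and the raw form keeps an exact linear
relationship with the sensors.  A load-normalised variant (divide by the
summed load instead of 4) is available behind ``normalize=True``.

Recordings arrive at up to 100 Hz and are reduced to 1 Hz by keeping the
first sample of each one-second bin anchored at the first timestamp of the
series.  Seconds with no data become explicit "absent" samples, as do seconds
where the total load falls below a presence threshold (default 5 kg, i.e.
nobody is on the chair).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import FormatError

logger = logging.getLogger(__name__)

LOAD_COLUMNS = ["a1_kg", "a2_kg", "a3_kg", "a4_kg"]

#: Default total-load threshold (kg) below which the chair counts as empty.
PRESENCE_THRESHOLD_KG = 5.0


@dataclass
class COPSeries:
    """A 1 Hz centre-of-pressure series for one participant-day.

    ``samples`` has columns ``t`` (seconds, strictly increasing, 1 s apart),
    ``x``, ``y`` (NaN when absent) and ``present`` (bool).
    """

    samples: pd.DataFrame
    participant_id: str = ""
    date: str = ""

    def __post_init__(self) -> None:
        missing = {"t", "x", "y", "present"} - set(self.samples.columns)
        if missing:
            raise FormatError(f"COPSeries missing columns: {sorted(missing)}")

    @property
    def present(self) -> np.ndarray:
        return self.samples["present"].to_numpy(dtype=bool)

    @property
    def xy(self) -> np.ndarray:
        return self.samples[["x", "y"]].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.samples)


def read_loadcell_csv(path) -> pd.DataFrame:
    """Read a raw load-cell CSV with columns timestamp, a1_kg..a4_kg.

    Rows are returned sorted by time with ``t`` in epoch seconds.  Duplicate
    timestamps, missing columns, unparsable timestamps and non-numeric loads
    raise :class:`FormatError` naming the offending row.
    """
    raw = pd.read_csv(path)
    missing = [c for c in ["timestamp", *LOAD_COLUMNS] if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    try:
        ts = pd.to_datetime(raw["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: unparsable timestamp ({exc})") from exc
    for col in LOAD_COLUMNS:
        vals = pd.to_numeric(raw[col], errors="coerce")
        bad = vals.isna() & raw[col].notna()
        if bad.any() or raw[col].isna().any():
            row = int(np.flatnonzero(vals.isna())[0])
            raise FormatError(f"{path}: non-numeric load in column {col}, row {row}")
        raw[col] = vals.astype(float)
    out = raw.assign(t=ts.astype("int64") / 1e9).sort_values("t", kind="stable")
    if out["t"].duplicated().any():
        row = int(np.flatnonzero(out["t"].duplicated())[0])
        raise FormatError(f"{path}: duplicate timestamp at sorted row {row}")
    return out[["t", *LOAD_COLUMNS]].reset_index(drop=True)


def calibrate(
    frames: pd.DataFrame,
    zero_offsets=(0.0, 0.0, 0.0, 0.0),
    gains=(1.0, 1.0, 1.0, 1.0),
) -> tuple[pd.DataFrame, int]:
    """Apply per-channel linear calibration ``A <- gain * (raw - zero)``.

    Negative calibrated loads are clipped to zero; the number of clipped
    values is returned alongside the calibrated frame.
    """
    gains = np.asarray(gains, dtype=float)
    zero_offsets = np.asarray(zero_offsets, dtype=float)
    if gains.shape != (4,) or zero_offsets.shape != (4,):
        raise FormatError("zero_offsets and gains must be length-4 vectors")
    if np.any(gains <= 0):
        raise FormatError("gains must all be > 0")
    out = frames.copy()
    vals = gains * (out[LOAD_COLUMNS].to_numpy(dtype=float) - zero_offsets)
    n_clipped = int(np.sum(vals < 0))
    out[LOAD_COLUMNS] = np.clip(vals, 0.0, None)
    if n_clipped:
        logger.info("calibrate: clipped %d negative loads to 0", n_clipped)
    return out, n_clipped


def compute_cop(a1, a2, a3, a4, normalize: bool = False):
    """Corner-weighted COP of one (or an array of) calibrated frame(s).

    Returns ``(x, y)``.  With ``normalize=True`` the corner sum is divided by
    the total load instead of 4 (undefined where the total is 0).
    """
    a1, a2, a3, a4 = (np.asarray(a, dtype=float) for a in (a1, a2, a3, a4))
    num_x = -a1 - a2 + a3 + a4
    num_y = a1 - a2 + a3 - a4
    if normalize:
        total = a1 + a2 + a3 + a4
        with np.errstate(divide="ignore", invalid="ignore"):
            return num_x / total, num_y / total
    return num_x / 4.0, num_y / 4.0


def detect_presence(frames: pd.DataFrame, threshold_kg: float = PRESENCE_THRESHOLD_KG):
    """True where the summed load is at (or above) the presence threshold."""
    if threshold_kg <= 0:
        raise FormatError("threshold_kg must be > 0")
    total = frames[LOAD_COLUMNS].to_numpy(dtype=float).sum(axis=1)
    return total >= threshold_kg


def downsample_1hz(frames: pd.DataFrame) -> pd.DataFrame:
    """Reduce a load-cell frame series to 1 Hz.

    Keeps the first sample within each one-second bin, bins anchored at the
    first timestamp.  Seconds with no sample ("dropouts") are inserted with
    NaN loads so that the output spacing is exactly 1 s.  Idempotent.
    """
    if len(frames) == 0:
        return frames.copy()
    t = frames["t"].to_numpy(dtype=float)
    bins = np.floor(t - t[0]).astype(np.int64)
    first = np.ones(len(bins), dtype=bool)
    first[1:] = bins[1:] != bins[:-1]
    kept = frames.loc[first].copy()
    kept_bins = bins[first]
    n_seconds = int(kept_bins[-1]) + 1
    out = pd.DataFrame(
        {"t": t[0] + np.arange(n_seconds, dtype=float)},
        columns=["t", *LOAD_COLUMNS],
    )
    out.loc[kept_bins, LOAD_COLUMNS] = kept[LOAD_COLUMNS].to_numpy(dtype=float)
    n_dropout = int(n_seconds - len(kept))
    if n_dropout:
        logger.info("downsample_1hz: inserted %d absent seconds", n_dropout)
    return out


def cop_series_from_frames(
    frames: pd.DataFrame,
    participant_id: str = "",
    date: str = "",
    threshold_kg: float = PRESENCE_THRESHOLD_KG,
    normalize: bool = False,
) -> COPSeries:
    """Downsample calibrated frames to 1 Hz and convert to a COP series.

    Dropout seconds and seconds below the presence threshold become absent
    samples (x, y = NaN).
    """
    ds = downsample_1hz(frames)
    loads = ds[LOAD_COLUMNS].to_numpy(dtype=float)
    has_data = ~np.isnan(loads).any(axis=1)
    present = np.zeros(len(ds), dtype=bool)
    if has_data.any():
        sub = ds.loc[has_data]
        present[has_data] = detect_presence(sub, threshold_kg)
    x = np.full(len(ds), np.nan)
    y = np.full(len(ds), np.nan)
    if present.any():
        a = loads[present]
        x[present], y[present] = compute_cop(a[:, 0], a[:, 1], a[:, 2], a[:, 3], normalize)
    samples = pd.DataFrame({"t": ds["t"].to_numpy(), "x": x, "y": y, "present": present})
    return COPSeries(samples=samples, participant_id=participant_id, date=date)


def sitting_time(series: COPSeries) -> float:
    """Hours of chair presence: present 1 Hz samples / 3600."""
    return float(np.count_nonzero(series.present)) / 3600.0
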