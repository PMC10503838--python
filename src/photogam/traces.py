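"""Per-fish locomotor traces and the rolling-sum response.

The raw measurement is the distance (mm) a fish moved during each 1-s bin
of the recording.  The model's response is the trailing 60-s rolling sum
(mm/min) of that series, averaged across the fish of each experimental
group within each assay: that assay-level group mean, sampled at the
regimen's stride, is the primary analysis unit.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .regimen import Regimen

logger = logging.getLogger(__name__)

#: Declared factor domains; metadata levels outside these are rejected.
FACTOR_DOMAINS: dict[str, tuple[str, ...]] = {
    "geno": ("WT", "HT", "HM"),
    "illu": ("dark", "light"),
    "dev": ("4", "5", "6", "7"),
}


class TraceError(ValueError):
    """Invalid trace data (gaps, negative distances, unknown factor levels)."""


@dataclass
class WellTrace:
    """One fish's complete per-second distance series.

    Attributes
    ----------
    assay_id : str
        Recording session (plate pair) the well belongs to.
    well_id : str
        Well within the assay.
    group_labels : dict
        Factor name -> level, e.g. ``{"geno": "HM"}``.
    distance_per_s : ndarray
        mm moved in each 1-s bin; index i covers second [i, i+1).
    """

    assay_id: str
    well_id: str
    group_labels: dict[str, str]
    distance_per_s: np.ndarray

    def __post_init__(self) -> None:
        self.distance_per_s = np.asarray(self.distance_per_s, dtype=float)
        if self.distance_per_s.ndim != 1:
            raise TraceError(f"well {self.well_id}: trace must be 1-D")
        if np.any(~np.isfinite(self.distance_per_s)):
            raise TraceError(f"well {self.well_id}: non-finite distance")
        if np.any(self.distance_per_s < 0):
            raise TraceError(f"well {self.well_id}: negative distance")
        for name, level in self.group_labels.items():
            domain = FACTOR_DOMAINS.get(name)
            if domain is not None and str(level) not in domain:
                raise TraceError(
                    f"well {self.well_id}: level {level!r} not in domain of "
                    f"factor {name!r} {domain}"
                )

    @property
    def n_seconds(self) -> int:
        return self.distance_per_s.size


@dataclass
class GroupSeries:
    """Assay-level mean rolling-sum trajectory for one experimental group."""

    assay_id: str
    group: dict[str, str]
    time_s: np.ndarray
    rsums: np.ndarray
    n_fish: int = 0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=int)
        self.rsums = np.asarray(self.rsums, dtype=float)
        if self.time_s.shape != self.rsums.shape:
            raise TraceError("time_s and rsums must have equal length")
        if np.any(self.rsums < 0):
            raise TraceError("rolling sums cannot be negative")


def rolling_sum(distance_per_s: np.ndarray, window_s: int = 60) -> np.ndarray:
    """Trailing-window rolling sum of a per-second distance series.

    ``r[t] = sum(d[t-window_s+1 .. t])`` for ``t >= window_s - 1``; the
    first ``window_s - 1`` seconds have no complete trailing window and are
    returned as NaN.  With the default 60-s window the result is in mm/min.
    """
    d = np.asarray(distance_per_s, dtype=float)
    if window_s < 1:
        raise TraceError(f"window_s must be >= 1, got {window_s}")
    if d.size < window_s:
        raise TraceError(
            f"series of length {d.size} shorter than window {window_s}"
        )
    csum = np.concatenate(([0.0], np.cumsum(d)))
    out = np.full(d.size, np.nan)
    out[window_s - 1:] = csum[window_s:] - csum[:-window_s]
    # cumulative-sum differencing can leave tiny negative round-off
    np.clip(out, 0.0, None, out=out)
    return out


def aggregate_group_mean(
    traces: Sequence[WellTrace],
    factors: Sequence[str],
    stride_s: int = 1,
    window_s: int = 60,
    start_s: int | None = None,
    end_s: int | None = None,
) -> list[GroupSeries]:
    """Collapse well traces to assay-level group-mean rolling sums.

    One :class:`GroupSeries` is produced per (assay_id, factor-level
    combination) cell, holding the across-fish mean of the rolling sum at
    every ``stride_s``-th second from ``start_s`` (default: the first
    second with a complete window) to ``end_s`` (exclusive).  Cells with no
    fish simply do not appear; a warning is emitted for declared factor
    combinations present in no trace only at the caller's level.
    """
    if not traces:
        raise TraceError("no traces to aggregate")
    for f in factors:
        missing = [t.well_id for t in traces if f not in t.group_labels]
        if missing:
            raise TraceError(f"factor {f!r} missing for wells {missing[:5]}")

    n = min(t.n_seconds for t in traces)
    if any(t.n_seconds != n for t in traces):
        raise TraceError("traces have unequal lengths")
    lo = window_s - 1 if start_s is None else max(start_s, window_s - 1)
    hi = n if end_s is None else min(end_s, n)
    if lo >= hi:
        raise TraceError("empty analysis window")
    times = np.arange(lo, hi, stride_s)

    cells: dict[tuple, list[tuple[str, np.ndarray]]] = {}
    for tr in traces:
        key = (tr.assay_id,) + tuple(str(tr.group_labels[f]) for f in factors)
        cells.setdefault(key, []).append(
            (tr.well_id, rolling_sum(tr.distance_per_s, window_s)[times])
        )

    out = []
    for key in sorted(cells):
        # sort members by well id so the mean is independent of input order
        stack = np.vstack([v for _, v in sorted(cells[key], key=lambda kv: kv[0])])
        out.append(
            GroupSeries(
                assay_id=key[0],
                group=dict(zip(factors, key[1:])),
                time_s=times,
                rsums=stack.mean(axis=0),
                n_fish=stack.shape[0],
            )
        )
    return out


def group_series_frame(series: Sequence[GroupSeries]) -> pd.DataFrame:
    """Tidy long-format view of GroupSeries (one row per analyzed second)."""
    frames = []
    for gs in series:
        df = pd.DataFrame({"assay_id": gs.assay_id, "time_s": gs.time_s,
                           "rsums": gs.rsums, "n_fish": gs.n_fish})
        for name, level in gs.group.items():
            df[name] = level
        frames.append(df)
    df = pd.concat(frames, ignore_index=True)
    factor_cols = [c for c in df.columns
                   if c not in ("assay_id", "time_s", "rsums", "n_fish")]
    return df[["assay_id", *factor_cols, "time_s", "rsums", "n_fish"]]


def frame_to_group_series(df: pd.DataFrame) -> list[GroupSeries]:
    """Inverse of :func:`group_series_frame`."""
    factor_cols = [c for c in df.columns
                   if c not in ("assay_id", "time_s", "rsums", "n_fish")]
    out = []
    for keys, sub in df.groupby(["assay_id", *factor_cols], sort=True):
        keys = (keys,) if not isinstance(keys, tuple) else keys
        sub = sub.sort_values("time_s")
        out.append(
            GroupSeries(
                assay_id=str(keys[0]),
                group={f: str(k) for f, k in zip(factor_cols, keys[1:])},
                time_s=sub["time_s"].to_numpy(),
                rsums=sub["rsums"].to_numpy(),
                n_fish=int(sub["n_fish"].iloc[0]) if "n_fish" in sub else 0,
            )
        )
    return out


def read_well_traces(
    path: str | Path, metadata_path: str | Path
) -> list[WellTrace]:
    """Read per-fish traces from the long CSV dialect plus plate metadata.

    ``path``: columns (assay_id, well_id, time_s, distance_mm), one row per
    fish per second, seconds complete from 0 to the common end.
    ``metadata_path``: one row per (assay_id, well_id) with one column per
    factor; levels are validated against :data:`FACTOR_DOMAINS`.
    """
    df = pd.read_csv(path, dtype={"assay_id": str, "well_id": str})
    meta = pd.read_csv(metadata_path, dtype=str)
    required = {"assay_id", "well_id", "time_s", "distance_mm"}
    if not required.issubset(df.columns):
        raise TraceError(f"trace CSV must have columns {sorted(required)}")
    if not {"assay_id", "well_id"}.issubset(meta.columns):
        raise TraceError("metadata CSV must have assay_id and well_id columns")

    meta_idx = meta.set_index(["assay_id", "well_id"])
    factor_cols = [c for c in meta.columns if c not in ("assay_id", "well_id")]

    traces = []
    for (assay_id, well_id), sub in df.groupby(["assay_id", "well_id"], sort=True):
        sub = sub.sort_values("time_s")
        t = sub["time_s"].to_numpy()
        expected = np.arange(t.min(), t.max() + 1)
        if t.min() != 0 or t.size != expected.size or np.any(t != expected):
            raise TraceError(
                f"well {assay_id}/{well_id}: trace has missing or duplicated "
                "seconds"
            )
        try:
            row = meta_idx.loc[(assay_id, well_id)]
        except KeyError:
            raise TraceError(f"well {assay_id}/{well_id}: no metadata row")
        labels = {c: str(row[c]) for c in factor_cols}
        traces.append(
            WellTrace(
                assay_id=str(assay_id),
                well_id=str(well_id),
                group_labels=labels,
                distance_per_s=sub["distance_mm"].to_numpy(),
            )
        )
    return traces


def write_well_traces(
    traces: Sequence[WellTrace],
    path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write traces and metadata in the CSV dialect `read_well_traces` reads."""
    rows = []
    meta_rows = []
    for tr in traces:
        rows.append(
            pd.DataFrame(
                {
                    "assay_id": tr.assay_id,
                    "well_id": tr.well_id,
                    "time_s": np.arange(tr.n_seconds),
                    "distance_mm": tr.distance_per_s,
                }
            )
        )
        meta_rows.append({"assay_id": tr.assay_id, "well_id": tr.well_id,
                          **tr.group_labels})
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.6f")
    pd.DataFrame(meta_rows).to_csv(metadata_path, index=False)
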