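"""Timestamp event tables, validation, and the EOD-blanking rule.

All analyses in this package operate on point processes: a train of electric
organ discharges (EODs) and, per recorded unit, a train of spike times. Times
are stored in seconds on disk and inside :class:`EventSeries`; analysis-side
latencies are in milliseconds, converted through :data:`MS_PER_S` only.

The blanking rule removes every spike whose latency to *any* EOD falls inside
a closed window (default [-2.5, +2.5] ms) around the discharge, where the EOD
artifact makes spike detection unreliable. Downstream histogram and ordinal
analyses assume blanking has been applied.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MS_PER_S = 1000.0

EVENT_COLUMNS = ("time_s", "kind", "unit_id", "trial_id")

__all__ = [
    "MS_PER_S",
    "ValidationError",
    "BlankingWindow",
    "EventSeries",
    "read_events",
    "write_events",
    "apply_blanking",
    "minimum_data_filter",
    "spikes_per_eod",
    "mean_isi_ms",
]


class ValidationError(ValueError):
    """Raised when an event table violates the point-process invariants."""


@dataclass(frozen=True)
class BlankingWindow:
    """Closed latency window around each EOD excluded from analysis (ms)."""

    lo_ms: float = -2.5
    hi_ms: float = 2.5

    def __post_init__(self) -> None:
        if not self.lo_ms < self.hi_ms:
            raise ValidationError(
                f"blanking window requires lo < hi, got [{self.lo_ms}, {self.hi_ms}]"
            )


@dataclass
class EventSeries:
    """A strictly increasing train of event times.

    Parameters
    ----------
    times_s:
        Event times in seconds, strictly increasing, non-negative.
    kind:
        Either ``"eod"`` or ``"spike"``.
    unit_id, trial_id:
        Optional labels carried through I/O.
    """

    times_s: np.ndarray
    kind: str = "spike"
    unit_id: str | None = None
    trial_id: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        if t.ndim != 1:
            raise ValidationError("timestamps must be a 1-D array")
        if t.size and not np.all(np.isfinite(t)):
            raise ValidationError("timestamps must be finite")
        if t.size and t[0] < 0:
            raise ValidationError("timestamps must be non-negative")
        if self.kind not in ("eod", "spike"):
            raise ValidationError(f"kind must be 'eod' or 'spike', got {self.kind!r}")
        d = np.diff(t)
        bad = np.where(d <= 0)[0]
        if bad.size:
            dup = bad[d[bad] == 0]
            if dup.size:
                raise ValidationError(
                    f"duplicate timestamps at indices {list(dup + 1)[:10]}"
                )
            raise ValidationError(
                f"timestamps not strictly increasing at indices {list(bad + 1)[:10]}"
            )
        object.__setattr__(self, "times_s", t)

    @property
    def times_ms(self) -> np.ndarray:
        return self.times_s * MS_PER_S

    def __len__(self) -> int:
        return int(self.times_s.size)

    def replace(self, **kwargs) -> "EventSeries":
        return dataclasses.replace(self, **kwargs)


def read_events(path, delimiter: str | None = None) -> list[EventSeries]:
    """Read an event table (TSV/CSV) into a list of validated series.

    The file must have a header with at least ``time_s`` and ``kind``;
    ``unit_id`` and ``trial_id`` are optional. Rows are grouped by
    (kind, unit_id, trial_id) in order of first appearance. Malformed rows
    (non-numeric times) and non-monotone series raise :class:`ValidationError`
    with the offending line numbers.
    """
    sep = delimiter
    if sep is None:
        with open(path) as fh:
            header = fh.readline()
        sep = "," if ("," in header and "\t" not in header) else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in ("time_s", "kind") if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    times = pd.to_numeric(df["time_s"], errors="coerce")
    bad = np.where(times.isna().to_numpy())[0]
    if bad.size:
        # +2: header line plus 1-based indexing
        raise ValidationError(
            f"malformed time_s values on lines {[int(i) + 2 for i in bad[:10]]}"
        )
    df = df.assign(_t=times.to_numpy(dtype=float), _line=np.arange(len(df)) + 2)
    for col in ("unit_id", "trial_id"):
        if col not in df.columns:
            df[col] = ""
    out: list[EventSeries] = []
    for (kind, unit, trial), g in df.groupby(
        ["kind", "unit_id", "trial_id"], sort=False
    ):
        t = g["_t"].to_numpy()
        d = np.diff(t)
        bad = np.where(d <= 0)[0]
        if bad.size:
            lines = [int(x) for x in g["_line"].to_numpy()[bad + 1][:10]]
            raise ValidationError(
                f"non-monotone timestamps for series ({kind!r}, {unit!r}, {trial!r}) "
                f"on lines {lines}"
            )
        out.append(
            EventSeries(t, kind=kind, unit_id=unit or None, trial_id=trial or None)
        )
    return out


def write_events(series: Iterable[EventSeries], path, delimiter: str = "\t") -> None:
    """Write one or more event series to a delimited text table."""
    frames = []
    for s in series:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": s.times_s,
                    "kind": s.kind,
                    "unit_id": s.unit_id or "",
                    "trial_id": s.trial_id or "",
                }
            )
        )
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=list(EVENT_COLUMNS))
    df.to_csv(path, sep=delimiter, index=False, float_format="%.9f")


def apply_blanking(
    spikes: EventSeries,
    eods: EventSeries,
    window: BlankingWindow = BlankingWindow(),
) -> EventSeries:
    """Remove spikes whose latency to any EOD lies inside the closed window.

    Idempotent; with an empty EOD series it is the identity. Order of the
    surviving spikes is preserved.
    """
    if len(spikes) == 0 or len(eods) == 0:
        return spikes.replace(times_s=spikes.times_s.copy())
    t = spikes.times_ms
    e = eods.times_ms
    idx = np.searchsorted(e, t)
    remove = np.zeros(t.size, dtype=bool)
    has_prev = idx > 0
    lat_prev = t[has_prev] - e[idx[has_prev] - 1]
    remove[has_prev] |= (lat_prev >= window.lo_ms) & (lat_prev <= window.hi_ms)
    has_next = idx < e.size
    lat_next = t[has_next] - e[idx[has_next]]
    keep_mask = np.zeros(t.size, dtype=bool)
    keep_mask[has_next] = (lat_next >= window.lo_ms) & (lat_next <= window.hi_ms)
    remove |= keep_mask
    return spikes.replace(times_s=spikes.times_s[~remove])


def minimum_data_filter(
    units: Mapping[str, tuple[EventSeries, EventSeries]],
    min_eods: int = 500,
    min_spikes: int = 100,
) -> list[str]:
    """Return unit ids whose recordings hold enough data for classification.

    ``units`` maps unit_id -> (spikes, eods) with blanking already applied.
    Both thresholds are inclusive: a unit is retained iff it has at least
    ``min_eods`` EODs and at least ``min_spikes`` spikes.
    """
    retained = []
    for uid, (spk, eod) in units.items():
        if len(eod) >= min_eods and len(spk) >= min_spikes:
            retained.append(uid)
    return retained


def spikes_per_eod(spikes: EventSeries, eods: EventSeries) -> float:
    """Mean number of spikes per EOD over the whole recording."""
    if len(eods) == 0:
        raise ValidationError("spikes_per_eod requires a non-empty EOD series")
    return len(spikes) / len(eods)


def mean_isi_ms(spikes: EventSeries, max_gap_ms: float = 300.0) -> float:
    """Mean inter-spike interval in ms, from the bounded ISI distribution.

    Sparse EOD-locked units are silent for stretches spanning several EOD
    cycles; successive-spike differences longer than ``max_gap_ms`` (default:
    the 300 ms forward span of the cross-correlogram window) are treated as
    silent gaps and excluded, so the statistic summarizes the ISI
    distribution over the span the analyses resolve rather than the
    recording's duty cycle. Returns NaN when fewer than two spikes, or no
    ISI, survive.
    """
    if len(spikes) < 2:
        return float("nan")
    isi = np.diff(spikes.times_ms)
    isi = isi[isi <= max_gap_ms]
    if isi.size == 0:
        return float("nan")
    return float(isi.mean())
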