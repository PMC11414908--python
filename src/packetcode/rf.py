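"""Position-resolved rate profiles for moving-object sweeps.

The object position is the primary axis: each EOD is assigned to the 1 mm
position bin the object occupied at its emission time, and the per-bin rate
is the number of spikes following those EODs (preceding-EOD convention,
matching the ordinal analysis) divided by the number of EODs in the bin. No
smoothing is applied — per-mm raw values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import EventSeries, ValidationError

__all__ = ["RateProfile", "position_rate_profile", "direction_contrast"]


@dataclass
class RateProfile:
    """Spikes-per-EOD along the sweep trajectory."""

    bin_left_mm: np.ndarray  # half-open bins [left, left + bin_mm)
    spikes_per_eod: np.ndarray
    n_eods: np.ndarray
    n_spikes: np.ndarray
    direction: str
    bin_mm: float = 1.0
    n_excluded_eods: int = 0

    def total_spikes(self) -> int:
        return int(self.n_spikes.sum())


def position_rate_profile(
    spikes: EventSeries,
    eods: EventSeries,
    trace_times_s,
    trace_pos_mm,
    bin_mm: float = 1.0,
    direction: str | None = None,
) -> RateProfile:
    """Bin EODs by object position and count the spikes each EOD evokes.

    ``trace_times_s``/``trace_pos_mm`` sample the (monotone) sweep; positions
    at EOD times are linearly interpolated. EODs outside the trace's time
    span are excluded and counted. Spikes are assigned to the preceding EOD;
    spikes after the last in-trace EOD are credited to it up to the trace
    end. Bins are half-open, ties going to the bin whose left edge they hit.
    """
    tt = np.asarray(trace_times_s, dtype=float)
    tx = np.asarray(trace_pos_mm, dtype=float)
    if tt.size < 2:
        raise ValidationError("position trace needs >= 2 samples")
    if len(eods) == 0:
        raise ValidationError("position_rate_profile requires EODs")
    et = eods.times_s
    inside = (et >= tt[0]) & (et <= tt[-1])
    n_excl = int((~inside).sum())
    et = et[inside]
    if et.size == 0:
        raise ValidationError("no EODs fall inside the position trace")
    pos = np.interp(et, tt, tx)
    if direction is None:
        direction = (
            "rostral_to_caudal" if tx[-1] >= tx[0] else "caudal_to_rostral"
        )

    lo = np.floor(tx.min() / bin_mm) * bin_mm
    hi = np.floor(tx.max() / bin_mm) * bin_mm
    lefts = np.arange(lo, hi + bin_mm * 0.5, bin_mm)
    eod_bin = np.floor((pos - lo) / bin_mm).astype(int)
    eod_bin = np.clip(eod_bin, 0, lefts.size - 1)

    # spikes to preceding in-trace EOD; last EOD collects up to the trace end
    st = spikes.times_s
    st = st[(st >= et[0]) & (st <= tt[-1])]
    spike_eod = np.searchsorted(et, st, side="right") - 1
    spike_eod = spike_eod[spike_eod >= 0]

    n_eods = np.bincount(eod_bin, minlength=lefts.size)
    n_spikes = np.bincount(eod_bin[spike_eod], minlength=lefts.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(n_eods > 0, n_spikes / np.maximum(n_eods, 1), 0.0)
    return RateProfile(
        bin_left_mm=lefts,
        spikes_per_eod=rate,
        n_eods=n_eods,
        n_spikes=n_spikes,
        direction=direction,
        bin_mm=bin_mm,
        n_excluded_eods=n_excl,
    )


def direction_contrast(profile_a: RateProfile, profile_b: RateProfile) -> dict:
    """Per-bin rate difference and a normalized L1 asymmetry index.

    The index is sum|r_a - r_b| / sum(r_a + r_b) over the common position
    bins: 0 for identical profiles, 1 when one direction is fully silenced.
    Disjoint position ranges raise.
    """
    common = np.intersect1d(profile_a.bin_left_mm, profile_b.bin_left_mm)
    if common.size == 0:
        raise ValidationError("profiles cover disjoint position ranges")
    ia = np.searchsorted(profile_a.bin_left_mm, common)
    ib = np.searchsorted(profile_b.bin_left_mm, common)
    ra = profile_a.spikes_per_eod[ia]
    rb = profile_b.spikes_per_eod[ib]
    diff = ra - rb
    denom = float((ra + rb).sum())
    index = float(np.abs(diff).sum() / denom) if denom > 0 else 0.0
    return {"bin_left_mm": common, "difference": diff, "asymmetry_index": index}
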