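"""Peri-EOD histogram families.

Three related constructions, all with 1 ms bins *centered* on integer
latencies (bin k covers [k - 0.5, k + 0.5) ms, bin zero centered at each
reference EOD):

* cross-correlation histograms over a long (-200, +300) ms window, in
  percent-per-EOD units — each spike contributes to the window of every EOD
  it falls near (sliding-reference construction), so the EOD-rate rhythm and
  the blanking notches appear at multiples of the inter-EOD interval;
* post-EOD histograms over the 2.5-40 ms window (bins centered 3..40, 38
  bins), normalized to unit sum — the rate-independent spike-timing
  probability vectors that classification and the JSD battery operate on;
* peri-EOD percentile profiles across units (20/50/80 by default) used as
  per-cluster firing-pattern images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .events import MS_PER_S, EventSeries, ValidationError

__all__ = [
    "PeriEODHistogram",
    "EmptyHistogramError",
    "POST_EOD_WINDOW_MS",
    "post_eod_bin_centers",
    "crosscorr_histogram",
    "post_eod_histogram",
    "peri_eod_profile",
]

POST_EOD_WINDOW_MS = (2.5, 40.0)
BLANKING_MS = (-2.5, 2.5)


class EmptyHistogramError(ValidationError):
    """No spikes in the analysis window; unit must be excluded upstream."""


def post_eod_bin_centers() -> np.ndarray:
    """Bin centers of the standard 2.5-40 ms post-EOD window: 3..40 ms."""
    return np.arange(3, 41, dtype=float)


@dataclass
class PeriEODHistogram:
    """Binned latency distribution relative to the EOD.

    ``values`` are per-bin relative frequencies: in ``percent_per_eod`` mode,
    100 x (spikes in bin summed over all reference EODs) / n_eods; in
    ``unit_sum`` mode a probability vector over the window. ``blanked_bins``
    indexes bins lying inside the blanking window around the reference EOD.
    """

    bin_centers_ms: np.ndarray
    values: np.ndarray
    normalization: str
    window_ms: tuple[float, float]
    n_eods: int
    n_spikes: int
    blanked_bins: np.ndarray

    def __post_init__(self) -> None:
        self.bin_centers_ms = np.asarray(self.bin_centers_ms, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.bin_centers_ms.shape != self.values.shape:
            raise ValidationError("bin centers and values must align")
        if np.any(self.values < 0):
            raise ValidationError("histogram values must be non-negative")
        if self.normalization == "unit_sum" and self.n_spikes > 0:
            s = self.values.sum()
            if abs(s - 1.0) > 1e-9:
                raise ValidationError(f"unit_sum histogram sums to {s}, not 1")

    @property
    def bin_edges_ms(self) -> np.ndarray:
        return np.concatenate(
            [self.bin_centers_ms - 0.5, [self.bin_centers_ms[-1] + 0.5]]
        )


def _latency_counts(
    spikes: EventSeries, eods: EventSeries, lo_ms: float, hi_ms: float
) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate spike latencies to every EOD within [lo, hi] into 1 ms bins.

    Returns (bin_centers, counts). Uses the sliding-reference construction:
    a spike near several EODs contributes once per reference.
    """
    centers = np.arange(np.round(lo_ms), np.round(hi_ms) + 1, dtype=float)
    counts = np.zeros(centers.size)
    if len(spikes) == 0:
        return centers, counts
    t = spikes.times_ms
    e = eods.times_ms
    lo_edge = centers[0] - 0.5
    hi_edge = centers[-1] + 0.5
    i0 = np.searchsorted(t, e + lo_edge, side="left")
    i1 = np.searchsorted(t, e + hi_edge, side="left")
    for j in range(e.size):
        if i1[j] > i0[j]:
            lat = t[i0[j]:i1[j]] - e[j]
            # bin k covers [k-0.5, k+0.5)
            k = np.floor(lat + 0.5).astype(int) - int(centers[0])
            np.add.at(counts, k, 1)
    return centers, counts


def crosscorr_histogram(
    spikes: EventSeries,
    eods: EventSeries,
    window_ms: tuple[float, float] = (-200.0, 300.0),
    blanking_ms: tuple[float, float] = BLANKING_MS,
) -> PeriEODHistogram:
    """Long cross-correlation histogram in percent-per-EOD units.

    Blanking is assumed already applied to the spike train; bins whose
    centers lie inside the blanking window around the reference EOD are
    flagged in ``blanked_bins`` (they stay zero and show as the notch
    artifact familiar from EOD-locked recordings).
    """
    if len(eods) == 0:
        raise ValidationError("cross-correlogram requires at least one EOD")
    centers, counts = _latency_counts(spikes, eods, *window_ms)
    values = 100.0 * counts / len(eods)
    blanked = np.where(
        (centers >= blanking_ms[0]) & (centers <= blanking_ms[1])
    )[0]
    return PeriEODHistogram(
        bin_centers_ms=centers,
        values=values,
        normalization="percent_per_eod",
        window_ms=window_ms,
        n_eods=len(eods),
        n_spikes=len(spikes),
        blanked_bins=blanked,
    )


def post_eod_histogram(
    spikes: EventSeries,
    eods: EventSeries,
    window_ms: tuple[float, float] = POST_EOD_WINDOW_MS,
) -> PeriEODHistogram:
    """Unit-sum post-EOD spike-timing histogram over the 2.5-40 ms window.

    Independent of EOD count and firing rate: uniformly duplicating the
    spike train leaves it unchanged. Raises :class:`EmptyHistogramError`
    when no spikes fall in the window.
    """
    if len(eods) == 0:
        raise ValidationError("post-EOD histogram requires at least one EOD")
    lo, hi = window_ms
    centers, counts = _latency_counts(spikes, eods, np.ceil(lo + 0.5), np.floor(hi))
    total = counts.sum()
    if total == 0:
        raise EmptyHistogramError(
            f"no spikes in the {lo}-{hi} ms post-EOD window"
        )
    return PeriEODHistogram(
        bin_centers_ms=centers,
        values=counts / total,
        normalization="unit_sum",
        window_ms=window_ms,
        n_eods=len(eods),
        n_spikes=int(total),
        blanked_bins=np.empty(0, dtype=int),
    )


def peri_eod_profile(
    histograms,
    percentiles: tuple[float, ...] = (20.0, 50.0, 80.0),
    window_ms: tuple[float, float] = (-15.0, 40.0),
) -> dict:
    """Per-bin percentile curves across a collection of histograms.

    All histograms must share binning; each is restricted to ``window_ms``
    (by bin center) before stacking. Returns a dict with ``bin_centers_ms``
    and one curve per requested percentile.
    """
    hists = list(histograms)
    if not hists:
        raise ValidationError("peri_eod_profile requires at least one histogram")
    ref = hists[0].bin_centers_ms
    for h in hists[1:]:
        if h.bin_centers_ms.shape != ref.shape or np.any(h.bin_centers_ms != ref):
            raise ValidationError("histograms have mismatched binning")
    sel = (ref >= window_ms[0]) & (ref <= window_ms[1])
    stack = np.vstack([h.values[sel] for h in hists])
    out = {"bin_centers_ms": ref[sel], "n_units": len(hists)}
    for q in percentiles:
        out[f"p{q:g}"] = np.percentile(stack, q, axis=0)
    return out
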