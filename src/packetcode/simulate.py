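"""Synthetic EOD trains and EOD-locked spike trains with known ground truth.

The generator is phenomenological: a gamma-renewal EOD train drives, for each
inter-EOD interval, a conditional spike intensity built from a mixture of
Gaussian latency modes plus a uniform baseline, gated by inhibition windows
and expanded by stereotyped doublet/triplet bursts. Stimulus steps modulate
the per-interval expected count (phasic gain with exponential adaptation on
top of a sustained level gain) and, optionally, shift the mode latencies —
the two "channels" (spike count and spike timing) the analysis pipeline is
designed to separate.

Six default archetypes emulate the firing-pattern types of phase-preferring
electrosensory-lobe units in *Gymnotus omarorum*: sharp monomodal (~11 ms),
broad monomodal (mode ~23 ms), bimodal (10–12 plus 15–25 ms), trimodal (an
extra sharp 5 ms spike), mildly inhibited and deeply inhibited. Their default
parameters are calibrated so that a population of such units reproduces the
observed grand means: ~0.35 spikes/EOD and ~84 ms mean inter-spike interval
(bounded-ISI definition, see :func:`packetcode.events.mean_isi_ms`), at the
resting discharge rate of 22.5 EOD/s (mean interval 44.5 ms).

No generated spike falls within ±2.5 ms of any EOD, so generation and
analysis share the blanking convention.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .events import MS_PER_S, EventSeries, ValidationError

__all__ = [
    "ParameterError",
    "ProtocolError",
    "EODTrainParams",
    "Mode",
    "InhibitionWindow",
    "Burst",
    "RFProfile",
    "UnitArchetype",
    "StepProtocol",
    "GroundTruth",
    "StepExperiment",
    "MovingObjectExperiment",
    "SimulatedUnit",
    "generate_eod_train",
    "generate_unit_spikes",
    "generate_step_experiment",
    "generate_moving_object_experiment",
    "default_archetypes",
    "ARCHETYPE_NAMES",
    "jitter_archetype",
    "simulate_population",
]

# Spikes are kept strictly outside the +/-2.5 ms blanking region.
BLANK_MS = 2.5
# At most this many primary spikes are placed in one inter-EOD interval.
MAX_SPIKES_PER_INTERVAL = 4


class ParameterError(ValidationError):
    """Invalid generator parameter."""


class ProtocolError(ValidationError):
    """Invalid experimental protocol."""


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class EODTrainParams:
    """Gamma-renewal EOD train parameters.

    ``mean_interval_ms`` is the mean inter-discharge interval; ``shape`` is
    the gamma shape (large values give the low interval jitter seen in
    rasters); ``duration_s`` the length of the generated record.
    """

    mean_interval_ms: float = 44.5
    shape: float = 50.0
    duration_s: float = 10.0

    def __post_init__(self) -> None:
        if self.mean_interval_ms <= 0:
            raise ParameterError("mean_interval_ms must be > 0")
        if self.shape <= 0:
            raise ParameterError("shape must be > 0")
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be > 0")


@dataclass(frozen=True)
class Mode:
    """One Gaussian latency mode of the post-EOD intensity (ms)."""

    latency_ms: float
    sd_ms: float
    weight: float  # expected spikes per EOD contributed by this mode


@dataclass(frozen=True)
class InhibitionWindow:
    """Post-EOD latency window in which spikes are thinned with prob. depth."""

    start_ms: float
    end_ms: float
    depth: float  # in [0, 1]

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth <= 1.0:
            raise ParameterError("inhibition depth must lie in [0, 1]")
        if not self.start_ms < self.end_ms:
            raise ParameterError("inhibition window requires start < end")


@dataclass(frozen=True)
class Burst:
    """Stereotyped burst expansion applied after primary spike placement."""

    probability: float = 0.0
    intra_isi_ms: float = 4.0
    size: int = 2  # total spikes in a burst (1 primary + size-1 extras)

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ParameterError("burst probability must lie in [0, 1]")
        if self.size < 2:
            raise ParameterError("burst size must be >= 2")


@dataclass(frozen=True)
class RFProfile:
    """Mexican-hat receptive-field gain along the rostro-caudal axis.

    gain(x) = 1 + exc_amp * G(x; center, exc_width)
                - inh_amp * G(x; center, inh_width),   clipped at 0,
    with G a unit-height Gaussian. Negative ``exc_amp`` yields a center-off
    field. When the object moves in ``suppressed_direction`` (+1 = increasing
    position), positions past the center are additionally multiplied by
    (1 - suppression), emulating the post-center depression seen only for one
    movement direction.
    """

    center_mm: float = 10.0
    exc_amp: float = 1.5
    exc_width_mm: float = 3.0
    inh_amp: float = 0.6
    inh_width_mm: float = 8.0
    suppression: float = 0.0
    suppressed_direction: int = -1

    def gain(self, positions_mm: np.ndarray, direction: int = 1) -> np.ndarray:
        x = np.asarray(positions_mm, dtype=float)
        d2 = (x - self.center_mm) ** 2
        g = (
            1.0
            + self.exc_amp * np.exp(-d2 / (2.0 * self.exc_width_mm**2))
            - self.inh_amp * np.exp(-d2 / (2.0 * self.inh_width_mm**2))
        )
        if self.suppression > 0 and direction == self.suppressed_direction:
            past = (x - self.center_mm) * direction > 0
            g = np.where(past, g * (1.0 - self.suppression), g)
        return np.clip(g, 0.0, None)


@dataclass(frozen=True)
class UnitArchetype:
    """Generative post-EOD intensity and stimulus-response model of one unit type.

    ``modes`` carry the EOD-locked excitation; ``baseline_rate_hz`` an
    EOD-independent Poisson floor; ``inhibition`` thins spikes inside its
    windows with the given depth. ``count_gain_up/down`` are the phasic
    multiplicative count factors applied at an upward/downward stimulus step,
    decaying toward 1 with e-fold constant ``adaptation_tau_eods``;
    ``level_gain`` is the sustained rate factor while the stimulus sits at the
    high level. ``latency_shift_up/down_ms`` shift all mode latencies at a
    step, with the same adaptation.
    """

    name: str
    modes: tuple[Mode, ...] = ()
    inhibition: tuple[InhibitionWindow, ...] = ()
    baseline_rate_hz: float = 0.0
    burst: Burst = Burst()
    count_gain_up: float = 1.0
    count_gain_down: float = 1.0
    level_gain: float = 1.0
    latency_shift_up_ms: float = 0.0
    latency_shift_down_ms: float = 0.0
    adaptation_tau_eods: float = 8.0
    rf: RFProfile = RFProfile()

    def __post_init__(self) -> None:
        for m in self.modes:
            if not (BLANK_MS < m.latency_ms < 40.0):
                raise ParameterError(
                    f"mode latency {m.latency_ms} ms outside (2.5, 40) ms"
                )
            if m.weight < 0 or m.sd_ms <= 0:
                raise ParameterError("mode weights must be >= 0 and sd > 0")
        if self.baseline_rate_hz < 0:
            raise ParameterError("baseline_rate_hz must be >= 0")
        if self.count_gain_up < 0 or self.count_gain_down < 0:
            raise ParameterError("count gains must be >= 0")

    @property
    def mode_weight(self) -> float:
        return float(sum(m.weight for m in self.modes))


@dataclass(frozen=True)
class StepProtocol:
    """Repeated two-level stimulus schedule (levels in arbitrary units)."""

    level_low: float = 1.0
    level_high: float = 3.0
    duty_s: tuple[float, float] = (28.0, 2.0)  # (time at low, time at high)
    n_trials: int = 16
    start_level: str = "low"

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ProtocolError("n_trials must be >= 1")
        if self.level_low <= 0 or self.level_high <= self.level_low:
            raise ProtocolError("levels must satisfy 0 < low < high")
        if min(self.duty_s) <= 0:
            raise ProtocolError("duty cycle durations must be > 0")


@dataclass
class GroundTruth:
    """Generator-side bookkeeping for downstream oracle checks."""

    archetype_name: str
    levels: np.ndarray | None = None  # per-EOD stimulus level
    positions_mm: np.ndarray | None = None  # per-EOD object position
    counts_per_interval: np.ndarray | None = None  # realized spikes per interval


@dataclass
class StepExperiment:
    spikes: EventSeries
    eods: EventSeries
    levels: np.ndarray  # per-EOD stimulus level
    schedule: list[tuple[float, float]]  # (t_on_s, level)
    step_times_up_s: np.ndarray
    step_times_down_s: np.ndarray
    ground_truth: GroundTruth = None


@dataclass
class MovingObjectExperiment:
    spikes: EventSeries
    eods: EventSeries
    positions_mm: np.ndarray  # object position at each EOD
    trace: tuple[np.ndarray, np.ndarray]  # (time_s, position_mm) samples
    direction: int
    ground_truth: GroundTruth = None


@dataclass
class SimulatedUnit:
    unit_id: str
    archetype_name: str
    archetype: UnitArchetype
    spikes: EventSeries
    eods: EventSeries


def generate_eod_train(params: EODTrainParams, seed) -> EventSeries:
    """Draw a gamma-renewal EOD train covering ``params.duration_s`` seconds."""
    rng = _as_rng(seed)
    mean = params.mean_interval_ms
    scale = mean / params.shape
    dur_ms = params.duration_s * MS_PER_S
    times = []
    t = 0.0
    # draw in chunks; renewal intervals are iid gamma
    n_chunk = max(16, int(dur_ms / mean * 1.2) + 8)
    while t < dur_ms:
        draws = rng.gamma(params.shape, scale, size=n_chunk)
        cs = t + np.cumsum(draws)
        take = cs[cs < dur_ms]
        times.append(take)
        if take.size < cs.size:
            break
        t = cs[-1]
    ts = np.concatenate(times) if times else np.empty(0)
    return EventSeries(ts / MS_PER_S, kind="eod")


def _modulation_from_levels(
    levels: np.ndarray, arch: UnitArchetype
) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval count multiplier and latency shift from a level sequence.

    Interval i (between EOD i and EOD i+1) is driven by the level seen by
    EOD i. A level change at EOD j starts a phasic transient
    1 + (G - 1)*exp(-k/tau) and a latency shift d*exp(-k/tau), k = i - j,
    on top of the sustained ``level_gain`` applied while the level is high.
    """
    levels = np.asarray(levels, dtype=float)
    n_int = levels.size - 1
    mult = np.ones(n_int)
    shift = np.zeros(n_int)
    if n_int <= 0:
        return mult, shift
    low = levels.min()
    mult[levels[:n_int] > low] = arch.level_gain
    change = np.where(np.diff(levels) != 0)[0] + 1  # EOD index seeing new level
    tau = max(arch.adaptation_tau_eods, 1e-9)
    for ci, j in enumerate(change):
        j_next = change[ci + 1] if ci + 1 < change.size else n_int
        if j >= n_int:
            break
        k = np.arange(j, min(j_next, n_int)) - j
        phase = np.exp(-k / tau)
        if levels[j] > levels[j - 1]:
            G, d = arch.count_gain_up, arch.latency_shift_up_ms
        else:
            G, d = arch.count_gain_down, arch.latency_shift_down_ms
        mult[j : j + k.size] *= 1.0 + (G - 1.0) * phase
        shift[j : j + k.size] = d * phase
    return mult, shift


def generate_unit_spikes(
    eods: EventSeries,
    archetype: UnitArchetype,
    seed,
    levels: np.ndarray | None = None,
    count_multiplier: np.ndarray | None = None,
    latency_shift_ms: np.ndarray | None = None,
    return_ledger: bool = False,
):
    """Sample one unit's spike train conditional on an EOD train.

    For each complete inter-EOD interval, a truncated-Poisson number of
    primary spikes (mean = intensity weight x gain, at most
    :data:`MAX_SPIKES_PER_INTERVAL`) is placed by sampling latencies from the
    weighted mode mixture plus uniform baseline, thinned by the inhibition
    windows (rejection, not resampling), and clipped to the blanking-safe
    range (2.5, interval - 2.5) ms. Burst expansion then appends
    ``burst.size - 1`` extra spikes at fixed intra-burst ISIs after a random
    subset of primaries.

    ``levels`` (per EOD) drives step modulation; ``count_multiplier`` /
    ``latency_shift_ms`` (per interval) allow external drive such as a moving
    object. With ``return_ledger=True`` also returns the realized per-interval
    spike counts (generator-side ground truth).
    """
    rng = _as_rng(seed)
    n_eods = len(eods)
    if n_eods == 0:
        raise ValidationError("generate_unit_spikes requires a non-empty EOD train")
    eod_ms = eods.times_ms
    intervals = np.diff(eod_ms)
    n_int = intervals.size

    mult = np.ones(n_int)
    shift = np.zeros(n_int)
    if levels is not None:
        levels = np.asarray(levels, dtype=float)
        if levels.size != n_eods:
            raise ValidationError(
                f"stimulus length {levels.size} != number of EODs {n_eods}"
            )
        m, s = _modulation_from_levels(levels, archetype)
        mult *= m
        shift += s
    if count_multiplier is not None:
        cm = np.asarray(count_multiplier, dtype=float)
        if cm.size not in (n_int, n_eods):
            raise ValidationError("count_multiplier length must match EODs/intervals")
        mult *= cm[:n_int]
    if latency_shift_ms is not None:
        ls = np.asarray(latency_shift_ms, dtype=float)
        if ls.size not in (n_int, n_eods):
            raise ValidationError("latency_shift_ms length must match EODs/intervals")
        shift += ls[:n_int]

    W = archetype.mode_weight
    base_w = archetype.baseline_rate_hz * intervals / MS_PER_S
    lam = (W + base_w) * mult
    counts = np.minimum(rng.poisson(lam), MAX_SPIKES_PER_INTERVAL)
    total = int(counts.sum())

    if total == 0:
        series = EventSeries(
            np.empty(0), kind="spike", unit_id=eods.unit_id, trial_id=eods.trial_id
        )
        return (series, np.zeros(n_int, dtype=int)) if return_ledger else series

    iidx = np.repeat(np.arange(n_int), counts)
    # component choice: baseline vs modes, proportional to per-interval weights
    tot_w = W + base_w[iidx]
    u = rng.random(total)
    is_base = u < np.where(tot_w > 0, base_w[iidx] / np.where(tot_w > 0, tot_w, 1), 0)
    lat = np.empty(total)
    lat[is_base] = rng.uniform(
        BLANK_MS, np.maximum(intervals[iidx[is_base]] - BLANK_MS, BLANK_MS + 1e-6)
    )
    n_mode = int((~is_base).sum())
    if n_mode:
        mus = np.array([m.latency_ms for m in archetype.modes])
        sds = np.array([m.sd_ms for m in archetype.modes])
        ws = np.array([m.weight for m in archetype.modes])
        comp = rng.choice(mus.size, size=n_mode, p=ws / ws.sum())
        lat[~is_base] = rng.normal(
            mus[comp] + shift[iidx[~is_base]], sds[comp]
        )

    keep = np.ones(total, dtype=bool)
    for win in archetype.inhibition:
        inside = (lat >= win.start_ms) & (lat < win.end_ms)
        keep &= ~(inside & (rng.random(total) < win.depth))
    keep &= (lat > BLANK_MS) & (lat < intervals[iidx] - BLANK_MS)

    lat = lat[keep]
    iidx = iidx[keep]

    b = archetype.burst
    if b.probability > 0 and lat.size:
        fire = rng.random(lat.size) < b.probability
        extra_lat = []
        extra_idx = []
        for k in range(1, b.size):
            el = lat[fire] + k * b.intra_isi_ms
            ei = iidx[fire]
            ok = el < intervals[ei] - BLANK_MS
            extra_lat.append(el[ok])
            extra_idx.append(ei[ok])
        if extra_lat:
            lat = np.concatenate([lat] + extra_lat)
            iidx = np.concatenate([iidx] + extra_idx)

    times_ms = eod_ms[iidx] + lat
    order = np.argsort(times_ms, kind="stable")
    times_ms = times_ms[order]
    # collapse pathological exact duplicates (possible only through bursts)
    if times_ms.size > 1:
        dedup = np.concatenate([[True], np.diff(times_ms) > 0])
        times_ms = times_ms[dedup]
        order = order[dedup]
    series = EventSeries(
        times_ms / MS_PER_S, kind="spike", unit_id=eods.unit_id, trial_id=eods.trial_id
    )
    if return_ledger:
        ledger = np.bincount(iidx, minlength=n_int)
        return series, ledger
    return series


def generate_step_experiment(
    archetype: UnitArchetype,
    protocol: StepProtocol = StepProtocol(),
    eod_params: EODTrainParams | None = None,
    seed=0,
    n_flank: int = 25,
) -> StepExperiment:
    """Simulate a repeated two-level stimulus-step experiment for one unit.

    The stimulus alternates between ``level_low`` and ``level_high`` per the
    protocol's duty cycle for ``n_trials`` repetitions; each duty phase must
    be long enough to hold at least ``n_flank`` EODs (plus one for the closing
    interval), otherwise a :class:`ProtocolError` is raised.
    """
    if eod_params is None:
        eod_params = EODTrainParams()
    need_ms = (n_flank + 1) * eod_params.mean_interval_ms
    for d in protocol.duty_s:
        if d * MS_PER_S < need_ms:
            raise ProtocolError(
                f"duty phase {d} s holds fewer than {n_flank + 1} expected EOD "
                f"intervals ({need_ms / MS_PER_S:.2f} s needed)"
            )
    rng = _as_rng(seed)
    d_first, d_second = protocol.duty_s
    if protocol.start_level == "low":
        seq = [(d_first, protocol.level_low), (d_second, protocol.level_high)]
    else:
        seq = [(d_first, protocol.level_high), (d_second, protocol.level_low)]
    schedule: list[tuple[float, float]] = []
    t = 0.0
    for _ in range(protocol.n_trials):
        for dur, lev in seq:
            schedule.append((t, lev))
            t += dur
    duration = t
    eods = generate_eod_train(
        dataclasses.replace(eod_params, duration_s=duration), rng
    )
    t_on = np.array([s[0] for s in schedule])
    levs = np.array([s[1] for s in schedule])
    levels = levs[np.searchsorted(t_on, eods.times_s, side="right") - 1]
    spikes, ledger = generate_unit_spikes(
        eods, archetype, rng, levels=levels, return_ledger=True
    )
    d_lev = np.diff(levs)
    step_t = t_on[1:]
    ups = step_t[d_lev > 0]
    downs = step_t[d_lev < 0]
    gt = GroundTruth(
        archetype_name=archetype.name, levels=levels, counts_per_interval=ledger
    )
    return StepExperiment(
        spikes=spikes,
        eods=eods,
        levels=levels,
        schedule=schedule,
        step_times_up_s=ups,
        step_times_down_s=downs,
        ground_truth=gt,
    )


def generate_moving_object_experiment(
    archetype: UnitArchetype,
    sweep: tuple[float, float, float] = (0.0, 100.0, 1.0),
    eod_params: EODTrainParams | None = None,
    seed=0,
) -> MovingObjectExperiment:
    """Simulate a constant-speed object sweep along the skin for one unit.

    ``sweep`` is (start_mm, end_mm, speed_mm_per_s); the unit's receptive
    field profile modulates the per-interval count multiplicatively.
    """
    start, end, speed = sweep
    if speed <= 0:
        raise ProtocolError("sweep speed must be > 0")
    if end == start:
        raise ProtocolError("zero-length sweep")
    if eod_params is None:
        eod_params = EODTrainParams()
    rng = _as_rng(seed)
    duration = abs(end - start) / speed
    direction = 1 if end > start else -1
    eods = generate_eod_train(
        dataclasses.replace(eod_params, duration_s=duration), rng
    )
    pos = start + direction * speed * eods.times_s
    gain = archetype.rf.gain(pos, direction=direction)
    spikes, ledger = generate_unit_spikes(
        eods, archetype, rng, count_multiplier=gain, return_ledger=True
    )
    tr_t = np.arange(0.0, duration, 0.02)
    tr_x = start + direction * speed * tr_t
    gt = GroundTruth(
        archetype_name=archetype.name, positions_mm=pos, counts_per_interval=ledger
    )
    return MovingObjectExperiment(
        spikes=spikes,
        eods=eods,
        positions_mm=pos,
        trace=(tr_t, tr_x),
        direction=direction,
        ground_truth=gt,
    )


ARCHETYPE_NAMES = (
    "sharp_monomodal",
    "broad_monomodal",
    "bimodal",
    "trimodal",
    "mildly_inhibited",
    "deeply_inhibited",
)


def default_archetypes() -> dict[str, UnitArchetype]:
    """The six calibrated default unit archetypes.

    Mode latencies and inhibition windows follow the described firing-pattern
    types; mode weights, baseline rates and burst probabilities are jointly
    calibrated so the default population reproduces the grand means of
    ~0.35 spikes/EOD and ~84 ms bounded mean ISI. Count gains implement the
    center-on (broad monomodal, bimodal, trimodal) vs center-off (sharp
    monomodal, inhibited) step responses.
    """
    return {
        "sharp_monomodal": UnitArchetype(
            name="sharp_monomodal",
            modes=(Mode(11.0, 1.0, 0.238),),
            inhibition=(InhibitionWindow(2.5, 9.0, 0.85),),
            baseline_rate_hz=1.62,
            burst=Burst(probability=0.18, intra_isi_ms=3.0, size=2),
            count_gain_up=0.4,
            count_gain_down=2.6,
            level_gain=0.7,
            rf=RFProfile(center_mm=10.0, exc_amp=-0.95, exc_width_mm=3.0,
                         inh_amp=-0.25, inh_width_mm=8.0,
                         suppression=0.5, suppressed_direction=-1),
        ),
        "broad_monomodal": UnitArchetype(
            name="broad_monomodal",
            modes=(Mode(5.0, 0.6, 0.0171), Mode(23.0, 4.0, 0.2611)),
            inhibition=(InhibitionWindow(2.5, 10.0, 0.7),),
            baseline_rate_hz=0.854,
            burst=Burst(probability=0.20, intra_isi_ms=4.5, size=2),
            count_gain_up=2.6,
            count_gain_down=0.35,
            level_gain=1.5,
            rf=RFProfile(center_mm=10.0, exc_amp=1.5, exc_width_mm=3.0,
                         inh_amp=0.6, inh_width_mm=8.0,
                         suppression=0.5, suppressed_direction=-1),
        ),
        "bimodal": UnitArchetype(
            name="bimodal",
            modes=(Mode(11.0, 0.8, 0.1014), Mode(18.0, 2.0, 0.1419)),
            inhibition=(InhibitionWindow(2.5, 8.0, 0.8),),
            baseline_rate_hz=0.4561,
            burst=Burst(probability=0.34, intra_isi_ms=4.0, size=2),
            count_gain_up=3.0,
            count_gain_down=0.3,
            level_gain=1.5,
            rf=RFProfile(center_mm=10.0, exc_amp=1.5, exc_width_mm=3.0,
                         inh_amp=0.6, inh_width_mm=8.0,
                         suppression=0.7, suppressed_direction=-1),
        ),
        "trimodal": UnitArchetype(
            name="trimodal",
            modes=(Mode(5.0, 0.5, 0.0710), Mode(11.0, 0.8, 0.0757), Mode(28.0, 6.0, 0.1089)),
            inhibition=(),
            baseline_rate_hz=0.3314,
            burst=Burst(probability=0.34, intra_isi_ms=4.0, size=2),
            count_gain_up=2.6,
            count_gain_down=0.35,
            level_gain=1.3,
            rf=RFProfile(center_mm=10.0, exc_amp=1.3, exc_width_mm=3.5,
                         inh_amp=0.5, inh_width_mm=8.0,
                         suppression=0.4, suppressed_direction=-1),
        ),
        "mildly_inhibited": UnitArchetype(
            name="mildly_inhibited",
            modes=(Mode(4.0, 1.0, 0.1223), Mode(35.0, 5.0, 0.0940)),
            inhibition=(
                InhibitionWindow(5.0, 8.0, 0.85),
                InhibitionWindow(10.0, 14.0, 0.75),
            ),
            baseline_rate_hz=3.386,
            burst=Burst(probability=0.20, intra_isi_ms=4.0, size=2),
            count_gain_up=0.35,
            count_gain_down=2.8,
            level_gain=0.7,
            rf=RFProfile(center_mm=10.0, exc_amp=-0.9, exc_width_mm=3.5,
                         inh_amp=-0.3, inh_width_mm=9.0,
                         suppression=0.4, suppressed_direction=-1),
        ),
        "deeply_inhibited": UnitArchetype(
            name="deeply_inhibited",
            modes=(Mode(37.0, 3.0, 0.2954),),
            inhibition=(InhibitionWindow(4.0, 28.0, 0.95),),
            baseline_rate_hz=6.859,
            burst=Burst(probability=0.0),
            count_gain_up=0.3,
            count_gain_down=2.5,
            level_gain=0.7,
            rf=RFProfile(center_mm=10.0, exc_amp=-0.95, exc_width_mm=4.0,
                         inh_amp=-0.3, inh_width_mm=9.0,
                         suppression=0.3, suppressed_direction=-1),
        ),
    }


def jitter_archetype(arch: UnitArchetype, rng: np.random.Generator) -> UnitArchetype:
    """Draw a unit-level variant of an archetype (mild parameter jitter).

    Mode latencies jitter by N(0, 0.15 ms) (clipped to the valid range), sds
    and weights by ~10%, baseline by ~10% — enough within-type variability to
    populate the per-cluster percentile bands without eroding separability.
    """
    modes = tuple(
        Mode(
            float(np.clip(m.latency_ms + rng.normal(0.0, 0.15), BLANK_MS + 0.6, 39.4)),
            float(m.sd_ms * rng.uniform(0.9, 1.1)),
            float(m.weight * rng.uniform(0.9, 1.1)),
        )
        for m in arch.modes
    )
    inh = tuple(
        InhibitionWindow(
            w.start_ms, w.end_ms, float(np.clip(w.depth * rng.uniform(0.9, 1.1), 0, 1))
        )
        for w in arch.inhibition
    )
    return dataclasses.replace(
        arch,
        modes=modes,
        inhibition=inh,
        baseline_rate_hz=float(arch.baseline_rate_hz * rng.uniform(0.9, 1.1)),
    )


def simulate_population(
    n_per_type: int = 17,
    n_eods: int = 500,
    seed=0,
    jitter: bool = True,
    eod_params: EODTrainParams | None = None,
    archetypes: dict[str, UnitArchetype] | None = None,
) -> list[SimulatedUnit]:
    """Simulate a baseline (no object, no steps) cohort of units.

    Each unit gets its own EOD train truncated to exactly ``n_eods``
    discharges and, with ``jitter=True``, its own mild parameter variant of
    the archetype. Determinism: all randomness derives from ``seed`` via
    spawned substreams, one per unit.
    """
    if eod_params is None:
        eod_params = EODTrainParams()
    if archetypes is None:
        archetypes = default_archetypes()
    ss = np.random.SeedSequence(seed if not isinstance(seed, np.random.SeedSequence) else None)
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    children = ss.spawn(len(archetypes) * n_per_type)
    units: list[SimulatedUnit] = []
    ci = 0
    for name in archetypes:
        base = archetypes[name]
        for j in range(n_per_type):
            rng = np.random.default_rng(children[ci])
            ci += 1
            arch = jitter_archetype(base, rng) if jitter else base
            dur = (n_eods + 30) * eod_params.mean_interval_ms / MS_PER_S
            eods = generate_eod_train(
                dataclasses.replace(eod_params, duration_s=dur), rng
            )
            while len(eods) < n_eods:  # pragma: no cover - very unlikely
                dur *= 1.2
                eods = generate_eod_train(
                    dataclasses.replace(eod_params, duration_s=dur), rng
                )
            uid = f"{name}_{j:02d}"
            eods = EventSeries(eods.times_s[:n_eods], kind="eod", unit_id=uid)
            spikes = generate_unit_spikes(eods, arch, rng)
            units.append(
                SimulatedUnit(
                    unit_id=uid,
                    archetype_name=name,
                    archetype=arch,
                    spikes=spikes,
                    eods=eods,
                )
            )
    return units
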