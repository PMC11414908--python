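"""Ordinal-EOD analysis of stimulus-step experiments.

Each trial is aligned on its stimulus step: EOD_0 is the first discharge
emitted at or after the step, and responses are indexed by ordinal EOD from
EOD_-25 to EOD_+25 (51 slots). Spike latencies are assigned to the preceding
EOD. From the alignment the module derives:

* per-ordinal spike counts (per trial, summed, and per-type median bands) —
  the spike-*count* channel of the information packet;
* triad-pooled spike-timing distributions over named ordinal ranges
  (long control -25..-4, a size-matched 3-EOD control -6..-4, pre -3..-1,
  post 0..2, late 23..25), unit-sum normalized over the 2.5-40 ms window —
  the spike-*timing* channel;
* Friedman tests "with repetitions" contrasting counts (25-repetition
  steady-state variant, 3-repetition step and adaptation variants);
* the Jensen-Shannon divergence battery (comparisons a-g) with one-sided
  sign-rank inference and Holm-Bonferroni control, plus the JSD-vs-count
  correlation that probes whether the two channels are redundant.

The sign-rank contrast tests H1: JSD(pre, post) > JSD(control, pre). The
plug-in JSD estimator carries a small-sample bias that grows as spike counts
shrink, so the reference control divergence is computed against the
size-matched 3-EOD control triad rather than the pooled long control — this
keeps the paired difference centered at zero for a stationary process (the
long-control divergences are still reported).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.stats import rankdata

from .events import MS_PER_S, EventSeries, ValidationError
from .histograms import post_eod_bin_centers
from .stats import TestResult, holm_bonferroni, pearson_with_r2, signrank_one_sided

__all__ = [
    "TRIADS",
    "OrdinalAlignment",
    "TriadDistribution",
    "JSDReport",
    "align_ordinal",
    "counts_per_ordinal",
    "type_count_profile",
    "triad_distributions",
    "friedman_replicated",
    "friedman_steady",
    "friedman_step",
    "jsd",
    "jsd_battery",
    "jsd_count_correlation",
]

# Named ordinal ranges (inclusive) pooled into triad distributions.
TRIADS: dict[str, tuple[int, int]] = {
    "long_control": (-25, -4),
    "control3": (-6, -4),  # size-matched 3-EOD control used by the sign-rank contrast
    "pre": (-3, -1),
    "post": (0, 2),
    "late": (23, 25),
}

MIN_LATENCY_MS = 2.5


@dataclass
class OrdinalAlignment:
    """Per-trial spike latencies indexed by ordinal EOD (EOD_-25..EOD_+25)."""

    ordinals: np.ndarray  # (-n_pre .. +n_post)
    latencies: list[list[np.ndarray]]  # [trial][ordinal slot] -> latencies (ms)
    counts: np.ndarray  # (n_trials, n_slots) spike counts
    step_times_s: np.ndarray  # steps actually aligned (dropped ones excluded)
    dropped: int = 0

    @property
    def n_trials(self) -> int:
        return len(self.latencies)


@dataclass
class TriadDistribution:
    """Pooled unit-sum latency histogram for one named ordinal range."""

    name: str
    probs: np.ndarray  # probability vector over the 2.5-40 ms bins
    n_spikes: int
    n_eods: int  # pooled ordinal EOD count (slots x trials)

    @property
    def spikes_per_eod(self) -> float:
        return self.n_spikes / self.n_eods if self.n_eods else float("nan")


@dataclass
class JSDReport:
    """Per-unit divergence battery with paired sign-rank inference.

    ``divergences`` maps unit -> {comparison letter -> bits}; ``tests`` maps
    (unit_type, direction) -> TestResult for H1: JSD(pre, post) >
    JSD(control, pre); ``holm_reject`` the Holm-adjusted decisions across all
    tests.
    """

    divergences: dict[str, dict[str, float]]
    tests: dict[tuple[str, str], TestResult] = field(default_factory=dict)
    holm_reject: dict[tuple[str, str], bool] = field(default_factory=dict)
    excluded_units: list[str] = field(default_factory=list)


def align_ordinal(
    spikes: EventSeries,
    eods: EventSeries,
    step_times_s,
    n_pre: int = 25,
    n_post: int = 25,
) -> OrdinalAlignment:
    """Align trials on stimulus steps by ordinal EOD.

    EOD_0 is the first EOD at or after each step time. Latencies are
    computed to the preceding EOD and restricted to [2.5 ms, following
    interval); steps without ``n_pre`` EODs before and ``n_post`` complete
    intervals after are dropped with a warning.
    """
    step_times_s = np.atleast_1d(np.asarray(step_times_s, dtype=float))
    e = eods.times_ms
    t = spikes.times_ms
    ordinals = np.arange(-n_pre, n_post + 1)
    lat_all: list[list[np.ndarray]] = []
    kept = []
    dropped = 0
    for s in step_times_s:
        i0 = int(np.searchsorted(e, s * MS_PER_S, side="left"))
        # need EODs i0-n_pre .. i0+n_post plus one more for the closing interval
        if i0 - n_pre < 0 or i0 + n_post + 1 > e.size - 1:
            dropped += 1
            continue
        slots = []
        for n in ordinals:
            a, b = e[i0 + n], e[i0 + n + 1]
            lo = np.searchsorted(t, a, side="right")
            hi = np.searchsorted(t, b, side="left")
            lat = t[lo:hi] - a
            slots.append(lat[lat >= MIN_LATENCY_MS])
        lat_all.append(slots)
        kept.append(s)
    if dropped:
        warnings.warn(
            f"{dropped} step(s) dropped: fewer than {n_pre}/{n_post} flanking EODs",
            stacklevel=2,
        )
    counts = np.array(
        [[len(sl) for sl in trial] for trial in lat_all], dtype=int
    ).reshape(len(lat_all), ordinals.size)
    return OrdinalAlignment(
        ordinals=ordinals,
        latencies=lat_all,
        counts=counts,
        step_times_s=np.asarray(kept),
        dropped=dropped,
    )


def counts_per_ordinal(alignment: OrdinalAlignment) -> dict:
    """Per-ordinal spike counts: summed over trials, with mean and SD."""
    c = alignment.counts
    return {
        "ordinals": alignment.ordinals,
        "summed": c.sum(axis=0),
        "mean": c.mean(axis=0) if len(c) else np.zeros(alignment.ordinals.size),
        "sd": c.std(axis=0, ddof=0) if len(c) else np.zeros(alignment.ordinals.size),
        "n_trials": alignment.n_trials,
    }


def type_count_profile(per_unit_means: list[np.ndarray]) -> dict:
    """Median and 20-80 percentile band of per-unit mean count profiles."""
    stack = np.vstack(per_unit_means)
    return {
        "median": np.median(stack, axis=0),
        "p20": np.percentile(stack, 20, axis=0),
        "p80": np.percentile(stack, 80, axis=0),
        "n_units": stack.shape[0],
    }


def triad_distributions(
    alignment: OrdinalAlignment,
    triads: dict[str, tuple[int, int]] | None = None,
) -> dict[str, TriadDistribution]:
    """Pool latencies over each named ordinal range into unit-sum histograms.

    Triads with zero pooled spikes get ``probs=None`` (callers exclude such
    units and log them).
    """
    if triads is None:
        triads = TRIADS
    centers = post_eod_bin_centers()
    edges = np.concatenate([centers - 0.5, [centers[-1] + 0.5]])
    out = {}
    ordinals = alignment.ordinals
    for name, (lo, hi) in triads.items():
        sel = np.where((ordinals >= lo) & (ordinals <= hi))[0]
        pooled = [
            trial[i] for trial in alignment.latencies for i in sel
        ]
        lat = np.concatenate(pooled) if pooled else np.empty(0)
        counts, _ = np.histogram(lat, bins=edges)
        total = counts.sum()
        n_eods = sel.size * alignment.n_trials
        probs = counts / total if total else None
        out[name] = TriadDistribution(
            name=name, probs=probs, n_spikes=int(total), n_eods=int(n_eods)
        )
    return out


def friedman_replicated(
    table: np.ndarray, permutation: bool = False, max_exact: int = 1_000_000
) -> TestResult:
    """Friedman test with replicated observations per block x treatment cell.

    ``table`` has shape (n_blocks, n_treatments, n_replicates). Within each
    block all t*r values are ranked jointly (average ranks for ties) and
    averaged per treatment; the per-treatment mean ranks are then re-ranked
    1..t within the block and the tie-corrected Friedman chi-square
    (df = t - 1) is computed. Missing cells (NaN) raise — no imputation.

    With ``permutation=True`` (small tables) the p-value is instead the
    exhaustive within-block permutation tail probability of the statistic.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 3:
        raise ValidationError("table must be (blocks, treatments, replicates)")
    if np.any(~np.isfinite(table)):
        raise ValidationError("missing cells in Friedman table (no imputation)")
    n, t, r = table.shape
    if n < 1 or t < 2 or r < 1:
        raise ValidationError("need >= 1 block, >= 2 treatments, >= 1 replicate")

    def statistic(tab: np.ndarray) -> float:
        # joint within-block ranking -> per-treatment mean ranks -> re-rank 1..t
        flat = tab.reshape(n, t * r)
        jr = np.apply_along_axis(rankdata, 1, flat).reshape(n, t, r)
        mean_ranks = jr.mean(axis=2)
        rr = np.apply_along_axis(rankdata, 1, mean_ranks)  # (n, t), avg ties
        rbar = (t + 1) / 2.0
        num = n * (t - 1) * np.sum((rr.mean(axis=0) - rbar) ** 2)
        den = np.sum((rr - rbar) ** 2) / n
        if den == 0:
            return float("nan")
        return float(num / den)

    chi2 = statistic(table)
    df = t - 1
    if not np.isfinite(chi2):
        return TestResult(float("nan"), 1.0, df=df, n=n,
                          note="degenerate: all within-block ranks tied")
    if permutation:
        # distinct assignments of the t*r values to ordered treatment groups
        def partitions(idx, sizes):
            if not sizes:
                yield ()
                return
            for head in itertools.combinations(idx, sizes[0]):
                rest = tuple(i for i in idx if i not in head)
                for tail in partitions(rest, sizes[1:]):
                    yield (head,) + tail

        per_block = [np.array(p) for p in partitions(tuple(range(t * r)), (r,) * t)]
        if len(per_block) ** n > max_exact:
            raise ValidationError("exhaustive permutation too large for this table")
        base = table.reshape(n, t * r)
        ge = tot = 0
        for combo in itertools.product(range(len(per_block)), repeat=n):
            tab = np.stack(
                [base[i][per_block[ci]] for i, ci in enumerate(combo)]
            )
            s = statistic(tab)
            tot += 1
            if np.isnan(s) or s >= chi2 - 1e-12:
                ge += 1
        return TestResult(chi2, ge / tot, df=df, n=n, note="exhaustive permutation")
    p = float(sps.chi2.sf(chi2, df))
    return TestResult(chi2, p, df=df, n=n)


def friedman_steady(
    weak_counts: np.ndarray, strong_counts: np.ndarray
) -> TestResult:
    """Steady-state contrast: weak vs strong stimulus spike counts.

    ``weak_counts`` and ``strong_counts`` are (n_units, n_reps) arrays of
    per-ordinal-EOD counts (the 25 EODs before a step at each level). Blocks
    are units, treatments are the two levels, replicates the ordinal EODs.
    """
    w = np.asarray(weak_counts, dtype=float)
    s = np.asarray(strong_counts, dtype=float)
    if w.shape != s.shape:
        raise ValidationError("weak/strong count tables must share shape")
    table = np.stack([w, s], axis=1)  # (units, 2, reps)
    return friedman_replicated(table)


def friedman_step(
    alignments: dict[str, OrdinalAlignment],
    pre: tuple[int, int] = (-3, -1),
    post: tuple[int, int] = (0, 2),
) -> TestResult:
    """Step contrast with 3 repetitions: counts just before vs just after.

    For each unit (block), the replicate values are the spike counts summed
    over trials at each ordinal EOD of the two triads. Also serves the
    adaptation contrast by passing post=(0, 2) vs pre=(23, 25) etc.
    """
    rows = []
    for uid, al in alignments.items():
        summed = al.counts.sum(axis=0)
        o = al.ordinals
        pre_v = summed[(o >= pre[0]) & (o <= pre[1])]
        post_v = summed[(o >= post[0]) & (o <= post[1])]
        if pre_v.size != post_v.size:
            raise ValidationError("pre/post triads must have equal length")
        rows.append(np.stack([pre_v, post_v]))
    table = np.stack(rows)  # (units, 2, reps)
    return friedman_replicated(table)


def jsd(p, q, base: float = 2.0) -> float:
    """Jensen-Shannon divergence between two probability vectors, in bits.

    JSD(p, q) = H((p+q)/2) - (H(p) + H(q))/2 with base-2 entropies and the
    0*log0 = 0 convention. Symmetric, in [0, 1]; equals the mutual
    information between a fair binary source label and a draw from the
    corresponding distribution.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValidationError("probability vectors must have equal length")
    for name, v in (("p", p), ("q", q)):
        if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-8:
            raise ValidationError(f"{name} is not a probability vector")

    def h(v):
        nz = v[v > 0]
        return -np.sum(nz * np.log(nz)) / np.log(base)

    m = 0.5 * (p + q)
    val = h(m) - 0.5 * (h(p) + h(q))
    # clamp tiny negative rounding
    return float(max(val, 0.0))


# the seven reported divergence comparisons: (label, direction, triad_a, triad_b)
_BATTERY = (
    ("a", None, ("long_control", "up"), ("long_control", "down")),
    ("b", "up", ("pre", "up"), ("long_control", "up")),
    ("c", "down", ("pre", "down"), ("long_control", "down")),
    ("d", "up", ("pre", "up"), ("post", "up")),
    ("e", "down", ("pre", "down"), ("post", "down")),
    ("f", "up", ("post", "up"), ("late", "up")),
    ("g", "down", ("post", "down"), ("late", "down")),
)


def jsd_battery(
    unit_triads: dict[str, dict[str, dict[str, TriadDistribution]]],
    unit_types: dict[str, str],
    alpha: float = 0.05,
) -> JSDReport:
    """Divergence battery (a-g) with one-sided sign-rank tests per type.

    ``unit_triads`` maps unit -> direction ("up"/"down") -> triad name ->
    TriadDistribution. Per unit the seven divergences are computed; per
    (type, direction) a one-sided sign-rank tests H1: JSD(pre, post) >
    JSD(control3, pre) across that type's units, Holm-adjusted over all
    (type, direction) tests. Units with any empty required triad are
    excluded and listed.
    """
    needed = {"long_control", "control3", "pre", "post", "late"}
    div: dict[str, dict[str, float]] = {}
    matched: dict[str, dict[str, tuple[float, float]]] = {}
    excluded = []
    for uid, dirs in unit_triads.items():
        ok = all(
            d in dirs and all(n in dirs[d] and dirs[d][n].probs is not None
                              for n in needed)
            for d in ("up", "down")
        )
        if not ok:
            excluded.append(uid)
            continue
        row = {}
        for label, _, (ta, da), (tb, db) in _BATTERY:
            row[label] = jsd(dirs[da][ta].probs, dirs[db][tb].probs)
        div[uid] = row
        matched[uid] = {
            d: (
                jsd(dirs[d]["control3"].probs, dirs[d]["pre"].probs),
                jsd(dirs[d]["pre"].probs, dirs[d]["post"].probs),
            )
            for d in ("up", "down")
        }
    tests: dict[tuple[str, str], TestResult] = {}
    types = sorted({unit_types[u] for u in div if u in unit_types})
    for ty in types:
        members = [u for u in div if unit_types.get(u) == ty]
        if len(members) < 2:
            continue
        for d in ("up", "down"):
            ref = np.array([matched[u][d][0] for u in members])
            step = np.array([matched[u][d][1] for u in members])
            tests[(ty, d)] = signrank_one_sided(step, ref, alternative="greater")
    holm: dict[tuple[str, str], bool] = {}
    if tests:
        keys = list(tests)
        reject, _ = holm_bonferroni([tests[k].p_value for k in keys], alpha=alpha)
        holm = dict(zip(keys, (bool(r) for r in reject)))
    return JSDReport(divergences=div, tests=tests, holm_reject=holm,
                     excluded_units=excluded)


def jsd_count_correlation(
    unit_triads: dict[str, dict[str, dict[str, TriadDistribution]]],
    triad_names: tuple[str, ...] = ("pre", "post", "late"),
) -> dict[str, dict]:
    """Per-unit correlation of JSD with spike-count change across triad pairs.

    For each unit, the 15 unordered pairs among its six direction-specific
    triads (pre/post/late x up/down) give paired (JSD, |delta count|,
    count ratio) samples; Pearson r, R^2 and p are reported for both count
    measures. A zero-variance regressor yields a flagged undefined result.
    """
    out: dict[str, dict] = {}
    for uid, dirs in unit_triads.items():
        triads = [
            dirs[d][n]
            for d in ("up", "down")
            if d in dirs
            for n in triad_names
            if n in dirs[d] and dirs[d][n].probs is not None
        ]
        if len(triads) < 3:
            out[uid] = {"note": "insufficient triads"}
            continue
        js, dcount, ratio = [], [], []
        for a, b in itertools.combinations(triads, 2):
            js.append(jsd(a.probs, b.probs))
            ca, cb = a.spikes_per_eod, b.spikes_per_eod
            dcount.append(abs(ca - cb))
            hi, lo = max(ca, cb), min(ca, cb)
            ratio.append(hi / lo if lo > 0 else np.nan)
        js = np.asarray(js)
        res_d = pearson_with_r2(js, np.asarray(dcount))
        rat = np.asarray(ratio)
        if np.any(~np.isfinite(rat)):
            res_r = TestResult(float("nan"), float("nan"), n=rat.size,
                               note="count ratio undefined (zero counts)")
        else:
            res_r = pearson_with_r2(js, rat)
        out[uid] = {
            "n_pairs": js.size,
            "jsd": js,
            "abs_count_diff": res_d,
            "count_ratio": res_r,
            "r2_abs_diff": float(res_d.statistic**2) if np.isfinite(res_d.statistic) else float("nan"),
            "r2_ratio": float(res_r.statistic**2) if np.isfinite(res_r.statistic) else float("nan"),
        }
    return out
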