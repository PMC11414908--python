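"""Ordinal alignment, Friedman tests, JSD battery and count correlation."""

import dataclasses
import itertools

import numpy as np
import pytest
from scipy.spatial.distance import jensenshannon
from scipy.stats import friedmanchisquare

from packetcode.events import EventSeries, ValidationError, apply_blanking
from packetcode.simulate import StepProtocol, default_archetypes, generate_step_experiment
from packetcode.steps import (
    TRIADS,
    align_ordinal,
    counts_per_ordinal,
    friedman_replicated,
    friedman_steady,
    friedman_step,
    jsd,
    jsd_battery,
    jsd_count_correlation,
    triad_distributions,
    type_count_profile,
)


def _series(ms, kind="spike"):
    return EventSeries(np.asarray(ms, dtype=float) / 1000.0, kind=kind)


def _regular_eods(n, interval=44.5, t0=0.0):
    return _series(t0 + interval * np.arange(n), "eod")


class TestAlignOrdinal:
    def test_step_at_eod_time_is_eod_zero(self):
        eods = _regular_eods(60)
        step_s = eods.times_s[30]
        al = align_ordinal(_series([]), eods, [step_s])
        assert al.n_trials == 1
        assert al.ordinals[0] == -25 and al.ordinals[-1] == 25
        assert all(len(sl) == 0 for sl in al.latencies[0])

    def test_spike_latency_assigned_to_preceding_eod(self):
        eods = _regular_eods(60)
        t0_ms = eods.times_ms[30]
        spk = _series([t0_ms + 10.0, t0_ms + 44.5 + 12.0])
        al = align_ordinal(spk, eods, [eods.times_s[30]])
        slot0 = al.latencies[0][list(al.ordinals).index(0)]
        slot1 = al.latencies[0][list(al.ordinals).index(1)]
        assert slot0 == pytest.approx([10.0])
        assert slot1 == pytest.approx([12.0])

    def test_edge_steps_dropped_with_warning(self):
        eods = _regular_eods(40)
        with pytest.warns(UserWarning, match="dropped"):
            al = align_ordinal(_series([]), eods, [eods.times_s[5]])
        assert al.n_trials == 0 and al.dropped == 1

    def test_counts_match_generator_ledger(self):
        """Ground-truth bookkeeping oracle: ordinal counts equal the
        generator's per-interval spike ledger."""
        arch = default_archetypes()["bimodal"]
        exp = generate_step_experiment(
            arch, StepProtocol(duty_s=(2.0, 2.0), n_trials=6), seed=13
        )
        al = align_ordinal(exp.spikes, exp.eods, exp.step_times_up_s)
        e = exp.eods.times_ms
        ledger = exp.ground_truth.counts_per_interval
        for trial, s in enumerate(al.step_times_s):
            i0 = np.searchsorted(e, s * 1000.0)
            expected = ledger[i0 - 25 : i0 + 26]
            np.testing.assert_array_equal(al.counts[trial], expected)


class TestCounts:
    def test_single_trial_indicator_profile(self):
        eods = _regular_eods(60)
        t0_ms = eods.times_ms[30]
        al = align_ordinal(_series([t0_ms + 8.0]), eods, [eods.times_s[30]])
        c = counts_per_ordinal(al)
        assert c["summed"][list(al.ordinals).index(0)] == 1
        assert c["summed"].sum() == 1

    def test_type_profile_band(self):
        profs = [np.ones(51), 2 * np.ones(51), 3 * np.ones(51)]
        band = type_count_profile(profs)
        assert np.all(band["median"] == 2)
        assert np.all(band["p20"] <= band["median"])


class TestTriads:
    def test_pooling_ranges_and_normalization(self):
        eods = _regular_eods(60)
        i0 = 30
        spikes = []
        for n in range(-25, 26):
            spikes.append(eods.times_ms[i0 + n] + 10.0)
        al = align_ordinal(_series(sorted(spikes)), eods, [eods.times_s[i0]])
        tri = triad_distributions(al)
        assert tri["pre"].n_spikes == 3
        assert tri["post"].n_spikes == 3
        assert tri["long_control"].n_spikes == 22
        assert tri["control3"].n_spikes == 3
        assert tri["late"].n_spikes == 3
        for t in tri.values():
            assert t.probs.sum() == pytest.approx(1.0)

    def test_empty_triad_flagged(self):
        eods = _regular_eods(60)
        al = align_ordinal(_series([]), eods, [eods.times_s[30]])
        tri = triad_distributions(al)
        assert all(t.probs is None for t in tri.values())


def permutation_friedman_p(table):
    """Independent oracle: enumerate *all* within-block orderings of the t*r
    values (redundant permutations included) and take the upper tail."""
    table = np.asarray(table, dtype=float)
    n, t, r = table.shape
    obs = friedman_replicated(table).statistic
    per_block = list(itertools.permutations(range(t * r)))
    count = tot = 0
    for combo in itertools.product(range(len(per_block)), repeat=n):
        tab = np.stack(
            [table[i].ravel()[list(per_block[ci])].reshape(t, r)
             for i, ci in enumerate(combo)]
        )
        s = friedman_replicated(tab).statistic
        tot += 1
        if np.isnan(s) or s >= obs - 1e-12:
            count += 1
    return count / tot


class TestFriedman:
    def test_matches_scipy_without_replicates(self, rng):
        """With one replicate per cell and >= 3 treatments the statistic
        reduces to the ordinary Friedman chi-square."""
        X = rng.normal(size=(10, 4))
        mine = friedman_replicated(X[:, :, None])
        ref = friedmanchisquare(*[X[:, j] for j in range(4)])
        assert mine.statistic == pytest.approx(ref.statistic)
        assert mine.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_missing_cells_raise(self):
        table = np.ones((2, 2, 3))
        table[0, 0, 0] = np.nan
        with pytest.raises(ValidationError, match="missing"):
            friedman_replicated(table)

    def test_exhaustive_permutation_oracle_two_blocks(self):
        table = np.array(
            [[[1.0, 2.0], [4.0, 5.0]],
             [[2.0, 1.0], [5.0, 6.0]]]
        )
        res = friedman_replicated(table, permutation=True)
        assert res.p_value == pytest.approx(permutation_friedman_p(table))

    def test_strong_steady_effect_significant(self):
        """Strong stimulus = 3x weak counts, 8 units: significant at 0.005
        in nearly all simulations."""
        rng = np.random.default_rng(3)
        hits = 0
        n_sim = 20
        for _ in range(n_sim):
            weak = rng.poisson(0.35, size=(8, 25))
            strong = rng.poisson(1.05, size=(8, 25))
            hits += friedman_steady(weak, strong).p_value < 0.005
        assert hits >= 18

    def test_step_contrast_direction_under_strong_effect(self):
        arch = dataclasses.replace(
            default_archetypes()["bimodal"],
            count_gain_up=3.0, level_gain=1.0,
        )
        aligns = {}
        for j in range(8):
            exp = generate_step_experiment(
                arch, StepProtocol(duty_s=(2.0, 2.0), n_trials=16), seed=50 + j
            )
            spk = apply_blanking(exp.spikes, exp.eods)
            aligns[f"u{j}"] = align_ordinal(spk, exp.eods, exp.step_times_up_s)
        res = friedman_step(aligns)
        assert res.p_value < 0.01
        for al in aligns.values():
            s = al.counts.sum(axis=0)
            o = al.ordinals
            assert s[(o >= 0) & (o <= 2)].sum() > s[(o >= -3) & (o <= -1)].sum()


class TestJSD:
    def test_identity_and_disjoint(self):
        p = np.array([0.2, 0.8, 0.0])
        q = np.array([0.0, 0.0, 1.0])
        assert jsd(p, p) == 0.0
        assert jsd(p, q) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        # H(0.75, 0.25) - 0.5 = 0.31128 bits
        assert jsd([0.5, 0.5], [1.0, 0.0]) == pytest.approx(0.311278, abs=1e-5)

    def test_symmetry_bounds_and_metric_root(self, rng):
        for _ in range(50):
            p = rng.dirichlet(np.ones(10))
            q = rng.dirichlet(np.ones(10))
            m = rng.dirichlet(np.ones(10))
            assert jsd(p, q) == pytest.approx(jsd(q, p), abs=1e-12)
            assert 0.0 <= jsd(p, q) <= 1.0
            # square root of JSD obeys the triangle inequality
            assert np.sqrt(jsd(p, q)) <= np.sqrt(jsd(p, m)) + np.sqrt(jsd(m, q)) + 1e-12

    def test_matches_scipy_cross_check(self, rng):
        p = rng.dirichlet(np.ones(38))
        q = rng.dirichlet(np.ones(38))
        assert jsd(p, q) == pytest.approx(jensenshannon(p, q, base=2) ** 2, abs=1e-10)

    def test_rejects_non_normalized(self):
        with pytest.raises(ValidationError):
            jsd([0.5, 0.6], [0.5, 0.5])


def _battery_inputs(arch, n_units, seed0, trials=16):
    unit_triads, unit_types, aligns = {}, {}, {}
    proto = StepProtocol(duty_s=(2.0, 2.0), n_trials=trials)
    for j in range(n_units):
        exp = generate_step_experiment(arch, proto, seed=seed0 + j)
        spk = apply_blanking(exp.spikes, exp.eods)
        uid = f"u{j}"
        unit_triads[uid] = {
            "up": triad_distributions(align_ordinal(spk, exp.eods, exp.step_times_up_s)),
            "down": triad_distributions(align_ordinal(spk, exp.eods, exp.step_times_down_s)),
        }
        unit_types[uid] = arch.name
    return unit_triads, unit_types


class TestJSDBattery:
    def test_reports_seven_divergences_in_range(self):
        arch = default_archetypes()["bimodal"]
        unit_triads, unit_types = _battery_inputs(arch, 3, 400)
        rep = jsd_battery(unit_triads, unit_types)
        for row in rep.divergences.values():
            assert set(row) == set("abcdefg")
            assert all(0.0 <= v <= 1.0 for v in row.values())

    def test_single_unit_no_test_but_divergences(self):
        arch = default_archetypes()["bimodal"]
        unit_triads, unit_types = _battery_inputs(arch, 1, 500)
        rep = jsd_battery(unit_triads, unit_types)
        assert len(rep.divergences) == 1
        assert rep.tests == {}

    def test_count_only_modulation_is_null_on_timing(self):
        """A step that scales counts but leaves timing untouched should not
        trigger the timing (JSD) contrast."""
        arch = dataclasses.replace(
            default_archetypes()["bimodal"],
            count_gain_up=3.0, count_gain_down=1.0, level_gain=1.0,
            latency_shift_up_ms=0.0, latency_shift_down_ms=0.0,
        )
        unit_triads, unit_types = _battery_inputs(arch, 8, 600)
        rep = jsd_battery(unit_triads, unit_types)
        assert all(t.p_value > 0.05 for t in rep.tests.values())

    def test_latency_shift_detected(self):
        """Modes moved 5 ms at the step: the JSD contrast fires."""
        arch = dataclasses.replace(
            default_archetypes()["bimodal"],
            count_gain_up=1.0, count_gain_down=1.0, level_gain=1.0,
            latency_shift_up_ms=5.0, latency_shift_down_ms=5.0,
        )
        unit_triads, unit_types = _battery_inputs(arch, 8, 700, trials=24)
        rep = jsd_battery(unit_triads, unit_types)
        assert rep.tests[("bimodal", "up")].p_value < 0.05
        assert rep.tests[("bimodal", "down")].p_value < 0.05
        assert rep.holm_reject[("bimodal", "up")]

    def test_control_pre_exchangeable_under_stationarity(self):
        """Permutation check: under a stationary generator the observed
        JSD(long_control, pre) is typical of random 22/3 re-splits of the
        pooled control+pre ordinals."""
        arch = dataclasses.replace(
            default_archetypes()["bimodal"],
            count_gain_up=1.0, count_gain_down=1.0, level_gain=1.0,
        )
        exp = generate_step_experiment(
            arch, StepProtocol(duty_s=(2.0, 2.0), n_trials=16), seed=900
        )
        spk = apply_blanking(exp.spikes, exp.eods)
        al = align_ordinal(spk, exp.eods, exp.step_times_up_s)
        tri = triad_distributions(al)
        obs = jsd(tri["long_control"].probs, tri["pre"].probs)
        rng = np.random.default_rng(1)
        ords = list(range(-25, 0))
        slot = {o: i for i, o in enumerate(al.ordinals)}
        edges = np.arange(2.5, 41.0, 1.0)

        def pooled(sel):
            lats = [trial[slot[o]] for trial in al.latencies for o in sel]
            c, _ = np.histogram(np.concatenate(lats), bins=edges)
            return c / c.sum()

        null = []
        for _ in range(200):
            perm = rng.permutation(ords)
            null.append(jsd(pooled(perm[:22]), pooled(perm[22:])))
        null = np.sort(null)
        lo, hi = null[int(0.005 * 200)], null[int(0.995 * 200) - 1]
        assert lo <= obs <= hi


class TestJSDCountCorrelation:
    def test_fifteen_pairs_reported(self):
        arch = default_archetypes()["bimodal"]
        unit_triads, _ = _battery_inputs(arch, 2, 800)
        out = jsd_count_correlation(unit_triads)
        for res in out.values():
            assert res["n_pairs"] == 15

    def test_identical_jsds_flagged_undefined(self):
        from packetcode.steps import TriadDistribution
        probs = np.zeros(38)
        probs[5] = 1.0
        tri = {name: TriadDistribution(name, probs.copy(), 10, 48)
               for name in ("pre", "post", "late")}
        out = jsd_count_correlation({"u": {"up": tri, "down": tri}})
        assert np.isnan(out["u"]["abs_count_diff"].statistic)

    def test_coupled_channels_yield_high_r2(self):
        """Positive control: coupling the timing shift to the count gain
        makes JSD track the count change."""
        arch = dataclasses.replace(
            default_archetypes()["bimodal"],
            count_gain_up=3.0, count_gain_down=0.33, level_gain=1.0,
            latency_shift_up_ms=6.0, latency_shift_down_ms=0.0,
        )
        unit_triads, _ = _battery_inputs(arch, 6, 850, trials=24)
        out = jsd_count_correlation(unit_triads)
        r2 = [r["r2_abs_diff"] for r in out.values()]
        arch0 = dataclasses.replace(arch, latency_shift_up_ms=0.0,
                                    count_gain_up=1.0, count_gain_down=1.0)
        base_triads, _ = _battery_inputs(arch0, 6, 850, trials=24)
        base = [r["r2_abs_diff"] for r in jsd_count_correlation(base_triads).values()]
        assert np.median(r2) > np.median(base)
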