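"""End-to-end pipeline: simulate -> blank -> histogram -> classify -> steps -> rf.

Every stage writes plain-text artifacts (TSV/JSON) into the output directory
with provenance (config hash, root seed, package version) in the report. All
randomness flows from the single root seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .events import (
    BlankingWindow,
    apply_blanking,
    mean_isi_ms,
    minimum_data_filter,
    spikes_per_eod,
    write_events,
)
from .classify import classify_units, linkage_to_newick, pairwise_ks_tests
from .histograms import EmptyHistogramError, crosscorr_histogram, post_eod_histogram
from .rf import direction_contrast, position_rate_profile
from .simulate import (
    EODTrainParams,
    StepProtocol,
    default_archetypes,
    generate_moving_object_experiment,
    generate_step_experiment,
    simulate_population,
)
from .steps import (
    align_ordinal,
    counts_per_ordinal,
    friedman_steady,
    friedman_step,
    jsd_battery,
    jsd_count_correlation,
    triad_distributions,
)

log = logging.getLogger("packetcode")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Defaults reproduce the standard analysis parameters.

    Blanking ±2.5 ms; 1 ms bins; cross-correlogram window −200..+300 ms;
    profile window −15..+40 ms; post-EOD window 2.5–40 ms; ordinal flanks of
    25 EODs; triads −25..−4 / −3..−1 / 0..2 / 23..25. Simulation sizes are
    chosen so the full default run completes in minutes on one CPU.
    """

    seed: int = 0
    n_per_type: int = 17
    n_eods: int = 500
    blanking_ms: tuple[float, float] = (-2.5, 2.5)
    k: int | None = None  # None -> elbow selection
    db_variant: str = "textbook"
    min_eods: int = 500
    min_spikes: int = 100
    # step stage
    step_types: tuple[str, ...] = (
        "sharp_monomodal",
        "broad_monomodal",
        "mildly_inhibited",
        "bimodal",
    )
    step_units_per_type: int = 6
    step_trials: int = 16
    step_duty_s: tuple[float, float] = (2.0, 2.0)
    # rf stage
    rf_sweep: tuple[float, float, float] = (0.0, 30.0, 1.0)
    alpha: float = 0.05
    run_ks: bool = False  # all-pairs KS stage (quadratic; off by default)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    """Load a PipelineConfig from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    fields = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("blanking_ms", "step_types", "step_duty_s", "rf_sweep"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return PipelineConfig(**raw)


def _stage(report: dict, name: str, **info) -> None:
    log.info("stage %s: %s", name, info)
    report["stages"][name] = info


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute the full pipeline on the default synthetic cohort.

    Returns the report dict (also written to ``report.json``); artifacts are
    TSVs next to it. Any stage failure raises with the stage name attached;
    artifacts written so far are preserved.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_digest": config.digest(),
        "stages": {},
    }
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: s for name, s in zip(("population", "steps", "rf"), ss.spawn(3))}
    try:
        _run_stages(config, out, report, seeds)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc
    finally:
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=_jsonable)
    return report


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    return str(obj)


def _run_stages(config, out, report, seeds):
    blank = BlankingWindow(*config.blanking_ms)

    # -- simulate + blank ---------------------------------------------------
    units = simulate_population(
        n_per_type=config.n_per_type, n_eods=config.n_eods, seed=seeds["population"]
    )
    for u in units:
        u.spikes = apply_blanking(u.spikes, u.eods, blank)
    write_events(
        [s for u in units for s in (u.eods, u.spikes)], out / "events.tsv"
    )
    _stage(report, "simulate", n_units=len(units), n_eods=config.n_eods)

    # -- filter -------------------------------------------------------------
    table = {u.unit_id: (u.spikes, u.eods) for u in units}
    retained = minimum_data_filter(
        table, min_eods=config.min_eods, min_spikes=config.min_spikes
    )
    units_in = [u for u in units if u.unit_id in set(retained)]
    _stage(report, "filter", n_in=len(units), n_retained=len(retained))

    # -- histograms ---------------------------------------------------------
    post, cross = {}, {}
    skipped = []
    for u in units_in:
        try:
            post[u.unit_id] = post_eod_histogram(u.spikes, u.eods)
        except EmptyHistogramError:
            skipped.append(u.unit_id)
            continue
        cross[u.unit_id] = crosscorr_histogram(u.spikes, u.eods)
    _stage(report, "histograms", n_units=len(post), skipped=skipped)

    # -- classify -----------------------------------------------------------
    result = classify_units(
        post, k=config.k, variant=config.db_variant, crosscorr=cross
    )
    pd.DataFrame(
        {"unit_id": list(result.labels), "cluster": list(result.labels.values())}
    ).to_csv(out / "cluster_labels.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"k": list(result.db_curve), "davies_bouldin": list(result.db_curve.values())}
    ).to_csv(out / "db_curve.tsv", sep="\t", index=False)
    (out / "dendrogram.nwk").write_text(
        linkage_to_newick(result.linkage, result.unit_ids)
    )
    for cl, prof in result.profiles.items():
        pd.DataFrame(
            {k: v for k, v in prof.items() if isinstance(v, np.ndarray)}
        ).to_csv(out / f"cluster_profile_{cl}.tsv", sep="\t", index=False)
    truth = {u.unit_id: u.archetype_name for u in units_in}
    _stage(
        report,
        "classify",
        chosen_k=result.chosen_k,
        db_curve={int(k): v for k, v in result.db_curve.items()},
        cluster_sizes=pd.Series(list(result.labels.values())).value_counts().to_dict(),
    )
    report["classification"] = {
        "labels": result.labels,
        "true_archetype": truth,
    }
    if config.run_ks:
        lat = {
            u.unit_id: _window_latencies(u) for u in units_in if u.unit_id in post
        }
        ks = pairwise_ks_tests(lat)
        _stage(report, "ks", n_pairs=ks["n_pairs"],
               fraction_significant=ks["fraction_significant"])

    # -- steps --------------------------------------------------------------
    archs = default_archetypes()
    protocol = StepProtocol(
        duty_s=config.step_duty_s, n_trials=config.step_trials
    )
    step_rng = np.random.SeedSequence(seeds["steps"].entropy).spawn(
        len(config.step_types) * config.step_units_per_type
    )
    unit_triads, unit_types, aligns_up = {}, {}, {}
    steady = {}
    si = 0
    for ty in config.step_types:
        for j in range(config.step_units_per_type):
            uid = f"{ty}_step{j}"
            exp = generate_step_experiment(
                archs[ty], protocol, seed=np.random.default_rng(step_rng[si])
            )
            si += 1
            spk = apply_blanking(exp.spikes, exp.eods, blank)
            al_up = align_ordinal(spk, exp.eods, exp.step_times_up_s)
            al_dn = align_ordinal(spk, exp.eods, exp.step_times_down_s)
            unit_triads[uid] = {
                "up": triad_distributions(al_up),
                "down": triad_distributions(al_dn),
            }
            unit_types[uid] = ty
            aligns_up.setdefault(ty, {})[uid] = al_up
            # pre-up-step ordinals sit at the low level, pre-down at the high
            pre = al_up.ordinals < 0
            steady.setdefault(ty, []).append(
                (al_up.counts.sum(axis=0)[pre], al_dn.counts.sum(axis=0)[pre])
            )
    battery = jsd_battery(unit_triads, unit_types, alpha=config.alpha)
    corr = jsd_count_correlation(unit_triads)
    step_tests = {
        ty: friedman_step(aligns_up[ty]) for ty in aligns_up
    }
    steady_tests = {
        ty: friedman_steady(
            np.stack([w for w, _ in rows]), np.stack([s for _, s in rows])
        )
        for ty, rows in steady.items()
    }
    rows = []
    for ty, al_map in aligns_up.items():
        for uid, al in al_map.items():
            c = counts_per_ordinal(al)
            for o, s in zip(c["ordinals"], c["summed"]):
                rows.append((uid, ty, int(o), int(s)))
    pd.DataFrame(
        rows, columns=["unit_id", "unit_type", "ordinal", "summed_count"]
    ).to_csv(out / "ordinal_counts.tsv", sep="\t", index=False)
    with open(out / "jsd_report.json", "w") as fh:
        json.dump(
            {
                "divergences_bits": battery.divergences,
                "tests": {f"{ty}/{d}": vars(t) for (ty, d), t in battery.tests.items()},
                "holm_reject": {f"{ty}/{d}": r for (ty, d), r in battery.holm_reject.items()},
                "excluded_units": battery.excluded_units,
            },
            fh,
            indent=1,
            default=_jsonable,
        )
    _stage(
        report,
        "steps",
        n_units=len(unit_triads),
        friedman_step_p={ty: t.p_value for ty, t in step_tests.items()},
        friedman_steady_p={ty: t.p_value for ty, t in steady_tests.items()},
        jsd_tests={f"{ty}/{d}": t.p_value for (ty, d), t in battery.tests.items()},
        median_r2_abs_diff=float(
            np.nanmedian([c.get("r2_abs_diff", np.nan) for c in corr.values()])
        ),
    )

    # -- receptive fields ---------------------------------------------------
    rf_rows = []
    asym = {}
    rf_seeds = np.random.SeedSequence(seeds["rf"].entropy).spawn(
        2 * len(config.step_types)
    )
    x0, x1, speed = config.rf_sweep
    for i, ty in enumerate(config.step_types):
        exp_rc = generate_moving_object_experiment(
            archs[ty], (x0, x1, speed), seed=np.random.default_rng(rf_seeds[2 * i])
        )
        exp_cr = generate_moving_object_experiment(
            archs[ty], (x1, x0, speed), seed=np.random.default_rng(rf_seeds[2 * i + 1])
        )
        profs = {}
        for tag, exp in (("rc", exp_rc), ("cr", exp_cr)):
            spk = apply_blanking(exp.spikes, exp.eods, blank)
            profs[tag] = position_rate_profile(
                spk, exp.eods, exp.trace[0], exp.trace[1]
            )
            for left, r in zip(profs[tag].bin_left_mm, profs[tag].spikes_per_eod):
                rf_rows.append((ty, tag, float(left), float(r)))
        asym[ty] = direction_contrast(profs["rc"], profs["cr"])["asymmetry_index"]
    pd.DataFrame(
        rf_rows, columns=["unit_type", "direction", "bin_left_mm", "spikes_per_eod"]
    ).to_csv(out / "rf_profiles.tsv", sep="\t", index=False)
    _stage(report, "rf", asymmetry_index=asym)

    # -- summary ------------------------------------------------------------
    rates = [spikes_per_eod(u.spikes, u.eods) for u in units_in]
    isis = [mean_isi_ms(u.spikes) for u in units_in]
    report["summary"] = {
        "grand_mean_spikes_per_eod": float(np.mean(rates)),
        "grand_mean_isi_ms": float(np.nanmean(isis)),
        "chosen_k": result.chosen_k,
    }


def _window_latencies(unit, lo=2.5, hi=40.5):
    """Raw spike latencies to the preceding EOD within the post-EOD window."""
    t = unit.spikes.times_ms
    e = unit.eods.times_ms
    idx = np.searchsorted(e, t) - 1
    ok = idx >= 0
    lat = t[ok] - e[idx[ok]]
    return lat[(lat >= lo) & (lat < hi)]
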