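"""End-to-end validation experiments: seeded simulation studies that
measure how well the analysis pipeline recovers each injected mechanism
(detector size and power, preferred-direction recovery, RF recovery,
desensitization strength, inherent-DS dissociation, speed invariance, the
centripetal population bias) and the calibration of the circular tests.

Each function simulates its own recording with the study's standard
conditions, runs the corresponding analysis, and returns a dict of summary
metrics.  Problem sizes default to a few hundred cells so a full pass
completes in minutes on one CPU.
"""
from __future__ import annotations

import numpy as np

from .asymmetry import classify_window
from .circstats import (circular_difference, circular_medians_multisample_test,
                        kuiper_two_sample, mean_angle_one_sample_test,
                        mean_resultant, rao_spacing_test)
from .config import RunConfig
from .geometry import RetinaGeometry
from .population import (align_to_optic_disc, desensitization_split,
                         masking_comparison, run_screen,
                         speed_tuning_analysis)
from .simulate import (MovingBarProtocol, SimCellParams, StaticBarProtocol,
                       WhiteNoiseProtocol, make_population, simulate_protocol,
                       simulate_session)

#: tissue used by the simulation studies: a 1.6 mm recorded square, which
#: puts per-cell annuli at ~650-800 um for centrally scattered cells
STANDARD_TISSUE = (1600.0, 1600.0)


def _sub(seed: int, tag: int) -> int:
    """Derived child seed (stable, < 2^31)."""
    return int(np.random.SeedSequence([int(seed), int(tag)])
               .generate_state(1)[0] % (2 ** 31))


def _tissue(width=None, height=None, **kwargs) -> RetinaGeometry:
    w, h = STANDARD_TISSUE
    return RetinaGeometry.rectangle(width or w, height or h, **kwargs)


# ---------------------------------------------------------------------------
# Detector calibration and power
# ---------------------------------------------------------------------------

def null_screen_experiment(n_cells: int = 500, seed: int = 0,
                           wn_duration: float = 150.0) -> dict:
    """Full screen (white-noise RF estimation included) on symmetric cells:
    the flagged fraction estimates the detector's false-positive rate, and
    the permutation p-values should be sub-uniform."""
    geom = _tissue()
    cells = make_population(n_cells, seed=_sub(seed, 1), geometry=geom,
                            frac_az=0.0)
    rec = simulate_session(
        cells, [WhiteNoiseProtocol(duration=wn_duration,
                                   noise_seed=_sub(seed, 2)),
                MovingBarProtocol()], geom, seed=_sub(seed, 3))
    res = run_screen(rec, RunConfig(), seed=_sub(seed, 4))
    # PRE and POST windows are disjoint, so both p-values are independent
    # draws from the screen's null; pool them for the validity check at the
    # screen's operating significance levels
    p = np.concatenate([res.reports["pre_p"].to_numpy(),
                        res.reports["post_p"].to_numpy()])
    alphas = np.array([0.01, 0.05])
    excess = float(np.max([np.mean(p <= a) - a for a in alphas]))
    return {
        "n_included": int(len(res.reports)),
        "n_excluded": int(len(res.exclusions)),
        "pre_fraction": float(res.pre_fraction),
        "p_subuniform_excess": excess,
    }


def power_screen_experiment(n_cells: int = 200, seed: int = 0,
                            gain_ratio: float = 3.0,
                            wn_duration: float = 150.0) -> dict:
    """Screen on cells that all carry an activation zone with peak drive
    ``gain_ratio`` times the baseline rate, at uniformly random angles:
    measures detector recall and preferred-direction recovery."""
    geom = _tissue()
    base = SimCellParams("x").baseline_rate
    cells = make_population(n_cells, seed=_sub(seed, 1), geometry=geom,
                            frac_az=1.0, az_angle="random",
                            az_gain=gain_ratio * base)
    rec = simulate_session(
        cells, [WhiteNoiseProtocol(duration=wn_duration,
                                   noise_seed=_sub(seed, 2)),
                MovingBarProtocol()], geom, seed=_sub(seed, 3))
    res = run_screen(rec, RunConfig(), seed=_sub(seed, 4))
    truth = {c.cell_id: c.az_angle for c in cells}
    detected = res.reports[res.reports["pre_asymmetric"]]
    recall = len(detected) / n_cells
    errs = np.array([abs(circular_difference(r["pre_pd"],
                                             truth[r["cell_id"]]))
                     for _, r in detected.iterrows()])
    return {
        "n_cells": n_cells,
        "n_detected": int(len(detected)),
        "recall": float(recall),
        "pd_within_22p5": float(np.mean(errs <= 22.5)) if len(errs) else 0.0,
        "median_pd_error_deg": float(np.median(errs)) if len(errs) else
        float("nan"),
    }


# ---------------------------------------------------------------------------
# RF recovery
# ---------------------------------------------------------------------------

def rf_recovery_experiment(n_cells: int = 40, seed: int = 0,
                           wn_duration: float = 240.0,
                           min_spikes: int = 1000) -> dict:
    """STA + Gaussian-fit recovery of injected RF centers under white
    noise; scored on cells with at least ``min_spikes`` spikes."""
    from .rf import estimate_rf
    geom = _tissue()
    proto = WhiteNoiseProtocol(duration=wn_duration,
                               noise_seed=_sub(seed, 2))
    cells = make_population(n_cells, seed=_sub(seed, 1), geometry=geom,
                            scatter=300.0)
    rec = simulate_protocol(cells, proto, geom, seed=_sub(seed, 3))
    frames = proto.frames()
    flat = frames.reshape(frames.shape[0], -1).astype(np.float32) - 0.5
    xs, ys = proto.grid()
    onset = float(rec.trials["onset"].iloc[0])
    errs = []
    for c in cells:
        spk = rec.spikes_of(c.cell_id, 0)["t_s"].to_numpy()
        if spk.size < min_spikes:
            continue
        rf = estimate_rf(spk, frames, proto.frame_rate, xs, ys, onset=onset,
                         frames_flat=flat)
        if not rf.reliable:
            errs.append(np.inf)
            continue
        errs.append(np.hypot(rf.center[0] - c.rf_center[0],
                             rf.center[1] - c.rf_center[1]))
    errs = np.array(errs)
    return {
        "n_eligible": int(errs.size),
        "center_within_checker": float(np.mean(errs < proto.checker))
        if errs.size else float("nan"),
        "median_center_error_um": float(np.median(errs[np.isfinite(errs)]))
        if np.isfinite(errs).any() else float("nan"),
    }


# ---------------------------------------------------------------------------
# Desensitization trial split
# ---------------------------------------------------------------------------

def desens_history_protocol(n_blocks: int = 24, gap: int = 100,
                            pd_deg: float = 0.0) -> StaticBarProtocol:
    """Designed static-bar sequence for the trial-history split: long runs
    of far bars (several recovery time constants) let slow desensitization
    recover before each zone probe; half the probes are immediately
    preceded by a Central flash."""
    bars = ((pd_deg, 0.0), (pd_deg, -600.0), (pd_deg, 900.0))
    seq = []
    for b in range(n_blocks):
        seq.extend([2] * gap)
        seq.append(0 if b % 2 == 0 else 2)
        seq.append(1)
    return StaticBarProtocol(bars=bars, sequence=tuple(seq))


def desens_experiment(n_cells: int = 20, seed: int = 0,
                      strength: float = 0.5, desens_tau: float = 40.0,
                      n_blocks: int = 24) -> dict:
    """Recover the injected desensitization strength from the previous-
    trial split, with a strength-0 cohort and a shuffled-history control."""
    geom = _tissue()
    out = {}
    for label, s in (("injected", strength), ("zero", 0.0)):
        cells = [SimCellParams(f"c{i}", rf_center=(0.0, 0.0),
                               has_activation_zone=True, desens_strength=s,
                               desens_tau=desens_tau)
                 for i in range(n_cells)]
        rec = simulate_protocol(cells, desens_history_protocol(n_blocks),
                                geom, seed=_sub(seed, 10 + int(10 * s)))
        ratios, shuffled = [], []
        for i, c in enumerate(cells):
            kw = dict(rf_center=c.rf_center, pd_deg=0.0,
                      central_radius=350.0, annulus_radius=800.0,
                      baseline_rate=c.baseline_rate)
            r = desensitization_split(rec.spikes_of(c.cell_id, 0),
                                      rec.trials, **kw)
            ratios.append(r["ratio"])
            if label == "injected":
                rs = desensitization_split(
                    rec.spikes_of(c.cell_id, 0), rec.trials,
                    shuffle_history_seed=_sub(seed, 100 + i), **kw)
                shuffled.append(rs["ratio"])
        out[f"ratio_{label}"] = float(np.mean(ratios))
        if shuffled:
            out["ratio_shuffled"] = float(np.mean(shuffled))
    out["injected_strength"] = strength
    return out


# ---------------------------------------------------------------------------
# Masking dissociation
# ---------------------------------------------------------------------------

def masking_experiment(n_cells: int = 100, seed: int = 0,
                       n_repeats: int = 20) -> dict:
    """Dissociate desensitization from the inherent DS component by
    masking the Central area: pure-desensitization cells should show
    balanced leading-edge responses over the zone in the two directions,
    inherent-DS cells should not."""
    geom = _tissue()
    rng = np.random.default_rng(_sub(seed, 1))
    cells = []
    truth = {}
    for i in range(n_cells):
        ds = i % 2 == 1
        cid = f"c{i:03d}"
        truth[cid] = ds
        cells.append(SimCellParams(
            cid, rf_center=tuple(rng.uniform(-150, 150, 2)),
            has_activation_zone=True,
            az_angle=float(rng.uniform(0, 360)),
            az_ds_gain=2.0 if ds else 1.0,
            desens_strength=0.0 if ds else 0.8))
    unmasked = simulate_protocol(cells, MovingBarProtocol(
        n_repeats=n_repeats), geom, seed=_sub(seed, 2))
    masked = simulate_protocol(cells, MovingBarProtocol(
        n_repeats=n_repeats, masked=True), geom, seed=_sub(seed, 3))
    out = masking_comparison(unmasked, masked, RunConfig(),
                             seed=_sub(seed, 4), rf_source="ground_truth")
    ok = out[out["dropped"].isna()] if "dropped" in out else out
    ratios = ok.set_index("cell_id")["pd_nd_ratio_masked"]
    flags = ok.set_index("cell_id")["inherent_ds"]
    ds1 = [c for c in ratios.index if not truth[c]]
    ds2 = [c for c in ratios.index if truth[c]]
    correct = sum(flags[c] == truth[c] for c in flags.index)
    return {
        "n_cells": int(len(ok)),
        "ratio_pure_desens_mean": float(np.mean(ratios[ds1])),
        "ratio_inherent_ds_mean": float(np.mean(ratios[ds2])),
        "classification_accuracy": float(correct / len(flags)),
    }


# ---------------------------------------------------------------------------
# Speed invariance
# ---------------------------------------------------------------------------

def speed_experiment(n_cells: int = 30, seed: int = 0,
                     speeds=(400.0, 600.0, 800.0, 1000.0),
                     ref_speed: float = 600.0) -> dict:
    """Speed-invariant zones: preferred directions recovered at 400-1000
    um/s should not shift relative to the reference speed, and the
    multisample circular median test on the shifts should not reject."""
    geom = _tissue()
    cells = make_population(n_cells, seed=_sub(seed, 1), geometry=geom,
                            frac_az=1.0, az_angle="random")
    per_speed = {}
    for k, v in enumerate(speeds):
        rec = simulate_protocol(cells, MovingBarProtocol(speed=v), geom,
                                seed=_sub(seed, 10 + k))
        scr = run_screen(rec, RunConfig(), seed=_sub(seed, 20 + k),
                         rf_source="ground_truth")
        per_speed[v] = {
            cid: (scr.responses[cid]["pre"],
                  classify_window(scr.responses[cid]["pre"],
                                  seed=[_sub(seed, 30 + k), j]))
            for j, cid in enumerate(scr.responses)}
    out = speed_tuning_analysis(per_speed, ref_speed=ref_speed)
    mean_dpd = {}
    for v in speeds:
        if v == ref_speed:
            continue
        m = mean_resultant(np.mod(out["delta_pd"][v], 360.0))
        mean_dpd[v] = abs(circular_difference(m.mean_deg, 0.0))
    non_ref = [v for v in speeds if v != ref_speed]
    stat, p = circular_medians_multisample_test(
        [np.mod(out["delta_pd"][v], 360.0) for v in non_ref],
        seed=_sub(seed, 40))
    return {
        "n_cells": len(out["cells"]),
        "max_abs_mean_delta_pd_deg": float(max(mean_dpd.values())),
        "median_test_p": float(p),
        "friedman_p": float(out["friedman_p"]),
    }


# ---------------------------------------------------------------------------
# Centripetal population organization
# ---------------------------------------------------------------------------

def centripetal_experiment(n_side: int = 100, seed: int = 0) -> dict:
    """Zones pointing at the optic disc: the preferred directions of
    temporal-dorsal vs nasal-dorsal cells should form distinct circular
    distributions (Kuiper two-sample)."""
    geom = RetinaGeometry.rectangle(3400.0, 2400.0, center=(0.0, 200.0),
                                    optic_disc=(0.0, 0.0))
    cells = []
    cells += make_population(n_side, seed=_sub(seed, 1), geometry=geom,
                             az_angle="centripetal", frac_az=1.0,
                             center=(700.0, 500.0), scatter=120.0)
    nasal = make_population(n_side, seed=_sub(seed, 2), geometry=geom,
                            az_angle="centripetal", frac_az=1.0,
                            center=(-700.0, 500.0), scatter=120.0)
    for i, c in enumerate(nasal):
        cells.append(SimCellParams(**{**c.__dict__,
                                      "cell_id": f"n{i:04d}"}))
    rec = simulate_protocol(cells, MovingBarProtocol(), geom,
                            seed=_sub(seed, 3))
    res = run_screen(rec, RunConfig(), seed=_sub(seed, 4),
                     rf_source="ground_truth")
    det = res.reports[res.reports["pre_asymmetric"]]
    aligned = align_to_optic_disc(det[["x", "y"]].to_numpy(), geom)
    td = det["pre_pd"].to_numpy()[
        (aligned["region"] == "temporal-dorsal").to_numpy()]
    nd = det["pre_pd"].to_numpy()[
        (aligned["region"] == "nasal-dorsal").to_numpy()]
    v, p = kuiper_two_sample(td, nd, seed=_sub(seed, 5))
    return {
        "n_temporal": int(td.size), "n_nasal": int(nd.size),
        "kuiper_v": float(v), "kuiper_p": float(p),
        "mean_pd_temporal": mean_resultant(td).mean_deg,
        "mean_pd_nasal": mean_resultant(nd).mean_deg,
    }


# ---------------------------------------------------------------------------
# Circular-test calibration
# ---------------------------------------------------------------------------

def circular_calibration(seed: int = 0, n_reps: int = 1200, n: int = 100,
                         alpha: float = 0.05) -> dict:
    """Empirical size under the null and power on separated alternatives
    for each circular test (Monte-Carlo / permutation nulls throughout)."""
    rng = np.random.default_rng(_sub(seed, 1))
    n_power = max(1, n_reps // 3)

    def rate(fn, reps):
        hits = 0
        for k in range(reps):
            hits += fn(k)
        return hits / reps

    def rao_null(k):
        a = rng.uniform(0, 360, n)
        return rao_spacing_test(a, n_mc=999, seed=_sub(seed, 1000 + k))[1] \
            <= alpha

    def rao_alt(k):
        a = np.rad2deg(rng.vonmises(0.0, 2.0, n)) % 360
        return rao_spacing_test(a, n_mc=999, seed=_sub(seed, 2000 + k))[1] \
            <= alpha

    def kuiper_null(k):
        a, b = rng.uniform(0, 360, n), rng.uniform(0, 360, n)
        return kuiper_two_sample(a, b, n_perm=499,
                                 seed=_sub(seed, 3000 + k))[1] <= alpha

    def kuiper_alt(k):
        a = np.rad2deg(rng.vonmises(0.0, 2.0, n)) % 360
        b = np.rad2deg(rng.vonmises(np.deg2rad(150.0), 2.0, n)) % 360
        return kuiper_two_sample(a, b, n_perm=499,
                                 seed=_sub(seed, 4000 + k))[1] <= alpha

    def mean_angle_null(k):
        a = np.rad2deg(rng.vonmises(np.deg2rad(40.0), 2.0, n)) % 360
        return mean_angle_one_sample_test(
            a, 40.0, n_boot=2000, alpha=alpha,
            seed=_sub(seed, 5000 + k)).reject

    def mean_angle_alt(k):
        a = (rng.normal(0.0, 5.0, n)) % 360
        return mean_angle_one_sample_test(
            a, 90.0, n_boot=2000, alpha=alpha,
            seed=_sub(seed, 6000 + k)).reject

    def medians_null(k):
        samples = [np.rad2deg(rng.vonmises(0.0, 1.0, n)) % 360
                   for _ in range(3)]
        return circular_medians_multisample_test(
            samples, n_perm=499, seed=_sub(seed, 7000 + k))[1] <= alpha

    def medians_alt(k):
        a = np.rad2deg(rng.vonmises(0.0, 2.0, n)) % 360
        b = np.rad2deg(rng.vonmises(np.pi / 2, 2.0, n)) % 360
        return circular_medians_multisample_test(
            [a, b], n_perm=499, seed=_sub(seed, 8000 + k))[1] <= alpha

    return {
        "rao_size": rate(rao_null, n_reps),
        "rao_power": rate(rao_alt, n_power),
        "kuiper_size": rate(kuiper_null, n_reps),
        "kuiper_power": rate(kuiper_alt, n_power),
        "mean_angle_size": rate(mean_angle_null, n_reps),
        "mean_angle_power": rate(mean_angle_alt, n_power),
        "medians_size": rate(medians_null, n_reps),
        "medians_power": rate(medians_alt, n_power),
        "n_reps": n_reps,
    }
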