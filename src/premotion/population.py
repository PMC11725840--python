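"""Population-level analyses: the full per-cell screen, optic-disc
alignment and regional pooling, the desensitization trial-split, the
central-masking comparison, multi-speed tuning, full-field response
clustering, and generic paired condition comparisons.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import friedmanchisquare, studentized_range, wilcoxon
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from . import rf as rfmod
from .asymmetry import (DirectionalResponse, baseline_comparison,
                        classify_window, compare_pd, count_in_window,
                        direction_spike_counts, estimate_baseline_rate,
                        static_asymmetry_index)
from .circstats import circular_difference
from .config import RunConfig
from .geometry import (CellExcluded, RetinaGeometry, build_windows,
                       distance_min, unit_vector)
from .simulate import SimRecording


class MissingProtocolError(RuntimeError):
    """A required stimulus protocol is absent from the recording."""


# ---------------------------------------------------------------------------
# Optic-disc alignment
# ---------------------------------------------------------------------------

def align_to_optic_disc(centers, geometry: RetinaGeometry,
                        eye_side: str = "right") -> pd.DataFrame:
    """Translate RF centers so the optic disc is the origin and mirror
    left-eye x so nasal/temporal pool across eyes; label dorsal quadrants.

    Region: temporal-dorsal for x > 0 and y > 0, nasal-dorsal for x < 0 and
    y > 0, otherwise "other" (ventral halves are not pooled).  A missing
    optic disc labels every cell "other".
    """
    c = np.atleast_2d(np.asarray(centers, float))
    if geometry.optic_disc is None or np.any(~np.isfinite(geometry.optic_disc)):
        return pd.DataFrame({"x": c[:, 0], "y": c[:, 1],
                             "region": "other"})
    od = np.asarray(geometry.optic_disc, float)
    x = c[:, 0] - od[0]
    y = c[:, 1] - od[1]
    if eye_side == "left":
        x = -x
    elif eye_side != "right":
        raise ValueError("eye_side must be 'left' or 'right'")
    region = np.where((x > 0) & (y > 0), "temporal-dorsal",
                      np.where((x < 0) & (y > 0), "nasal-dorsal", "other"))
    return pd.DataFrame({"x": x, "y": y, "region": region})


# ---------------------------------------------------------------------------
# The per-cell screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    reports: pd.DataFrame
    exclusions: pd.DataFrame
    responses: dict  # cell_id -> {"pre": DirectionalResponse, "post": ...}

    @property
    def pre_fraction(self) -> float:
        if not len(self.reports):
            return float("nan")
        return float(self.reports["pre_asymmetric"].mean())


def _bar_protocol_id(rec: SimRecording, speed=None, masked=False) -> int:
    for pid, proto in rec.protocols.items():
        if proto.kind == "moving_bar" and proto.masked == masked and \
                (speed is None or proto.speed == speed):
            return pid
    raise MissingProtocolError(
        f"no {'masked' if masked else 'unmasked'} moving_bar protocol"
        + (f" at speed {speed}" if speed is not None else ""))


def run_screen(rec: SimRecording, cfg: RunConfig | None = None,
               seed: int = 0, rf_source: str = "estimate",
               speed: float | None = None,
               eye_side: str = "right") -> ScreenResult:
    """The full extraclassical screen: RF estimation, inclusion gates,
    window construction, PRE/POST classification and regional labels.

    ``rf_source`` is "estimate" (white-noise STA, the default; the
    white-noise protocol must then be present) or "ground_truth" (use the
    simulator's injected parameters, for analyses that do not probe RF
    estimation).  Every excluded cell is recorded with a reason.
    Deterministic for a fixed ``seed``.
    """
    cfg = (cfg or RunConfig()).validate()
    geometry = replace(rec.geometry, central_radius=cfg.central_radius,
                       distance_min_required=cfg.distance_min_required)
    bar_pid = _bar_protocol_id(rec, speed=speed, masked=False)
    bar_proto = rec.protocols[bar_pid]
    bar_trials = rec.trials_of(bar_pid)

    wn = ff = gr = None
    for pid, proto in rec.protocols.items():
        if proto.kind == "white_noise":
            wn = (pid, proto)
        elif proto.kind == "full_field":
            ff = (pid, proto)
        elif proto.kind == "grating":
            gr = (pid, proto)
    if rf_source == "estimate":
        if wn is None:
            raise MissingProtocolError("white_noise protocol required for "
                                       "RF estimation")
        frames = wn[1].frames()
        frames_flat = frames.reshape(frames.shape[0], -1
                                     ).astype(np.float32) - 0.5
        xs, ys = wn[1].grid()
        wn_onset = float(rec.trials_of(wn[0])["onset"].iloc[0])
    elif rf_source != "ground_truth":
        raise ValueError("rf_source must be 'estimate' or 'ground_truth'")
    if rf_source == "ground_truth" and rec.ground_truth is None:
        raise ValueError("recording carries no ground truth")

    truth = {c.cell_id: c for c in (rec.ground_truth or ())}
    rows, excl_rows, responses = [], [], {}
    for ci, cell_id in enumerate(rec.cell_ids):
        # ---- receptive field -------------------------------------------
        if rf_source == "estimate":
            cell_rf = rfmod.estimate_rf(
                rec.spikes_of(cell_id, wn[0])["t_s"].to_numpy(), frames,
                wn[1].frame_rate, xs, ys, onset=wn_onset,
                n_lags=cfg.sta_n_lags, min_spikes=cfg.sta_min_spikes,
                frames_flat=frames_flat)
        else:
            gt = truth[cell_id]
            cell_rf = rfmod.ReceptiveField(
                center=tuple(gt.rf_center), sigma=gt.rf_sigma,
                polarity=gt.polarity, fit_quality=1.0, reliable=True)
        if not cell_rf.reliable:
            excl_rows.append({"cell_id": cell_id,
                              "reason": f"unreliable RF: {cell_rf.note}"})
            continue
        # ---- typing -----------------------------------------------------
        if ff is not None:
            ff_trials = rec.trials_of(ff[0])
            spk = rec.spikes_of(cell_id, ff[0])["t_s"].to_numpy()
            per_trial = [spk[(spk >= tr.onset)
                             & (spk < tr.onset + tr.duration)] - tr.onset
                         for tr in ff_trials.itertuples(index=False)]
            try:
                pol, ti, _, _ = rfmod.classify_polarity_transience(
                    per_trial, ff[1].on_duration, ff[1].off_duration,
                    polarity_ratio=cfg.polarity_ratio)
                cell_rf = rfmod.with_typing(cell_rf, polarity=pol,
                                            transience_index=ti)
            except ValueError:
                pass
        if gr is not None:
            gr_trials = rec.trials_of(gr[0])
            spk = rec.spikes_of(cell_id, gr[0])["t_s"].to_numpy()
            gcounts = _grating_counts(spk, gr_trials)
            _, gpd, _, is_ds = rfmod.grating_dsi(
                gcounts, ds_threshold=cfg.ds_threshold, alpha=cfg.alpha,
                n_perm=cfg.n_perm, seed=[seed, ci, 7])
            cell_rf = rfmod.with_typing(cell_rf, classical_ds=is_ds,
                                        classical_pd=gpd)
            if is_ds and cfg.exclude_classical_ds:
                excl_rows.append({"cell_id": cell_id,
                                  "reason": "classical DSGC"})
                continue
        # ---- geometry gate ----------------------------------------------
        try:
            windows = build_windows(
                cell_rf.center, geometry, bar_proto.width, bar_proto.speed,
                cell_id=cell_id,
                exclude_post_leading_edge=cfg.exclude_post_leading_edge)
        except CellExcluded as e:
            excl_rows.append({"cell_id": cell_id, "reason": e.reason})
            continue
        except ValueError as e:
            excl_rows.append({"cell_id": cell_id, "reason": str(e)})
            continue
        # ---- tuning ------------------------------------------------------
        spikes = rec.spikes_of(cell_id, bar_pid)
        baseline = estimate_baseline_rate(spikes, bar_trials,
                                          window=cfg.baseline_window)
        try:
            pre = direction_spike_counts(spikes, bar_trials, windows, "PRE",
                                         cell_rf.center)
            post = direction_spike_counts(spikes, bar_trials, windows,
                                          "POST", cell_rf.center)
        except ValueError as e:
            excl_rows.append({"cell_id": cell_id, "reason": str(e)})
            continue
        kw = dict(theta_mai=cfg.theta_mai, theta_nvs=cfg.theta_nvs,
                  theta_count=cfg.theta_count, alpha=cfg.alpha,
                  n_perm=cfg.n_perm)
        pre_sum = classify_window(pre, seed=[seed, ci, 1],
                                  baseline_rate=baseline, **kw)
        post_sum = classify_window(post, seed=[seed, ci, 2],
                                   baseline_rate=baseline, **kw)
        enh = baseline_comparison(pre, pre_sum, baseline, alpha=cfg.alpha)
        aligned = align_to_optic_disc([cell_rf.center], geometry,
                                      eye_side=eye_side)
        responses[cell_id] = {"pre": pre, "post": post, "windows": windows,
                              "rf": cell_rf}
        rows.append({
            "cell_id": cell_id,
            "x": cell_rf.center[0], "y": cell_rf.center[1],
            "sigma": cell_rf.sigma, "polarity": cell_rf.polarity,
            "transience_index": cell_rf.transience_index,
            "classical_ds": cell_rf.classical_ds,
            "distance_min": windows.annulus_radius,
            "region": aligned["region"].iloc[0],
            "baseline_rate": baseline,
            "pre_pd": pre_sum.pd_deg, "pre_mai": pre_sum.mai,
            "pre_nvs": pre_sum.nvs, "pre_mean_count_pd": pre_sum.mean_count_pd,
            "pre_p": pre_sum.p_perm, "pre_asymmetric": pre_sum.is_asymmetric,
            "enhancement": enh,
            "post_pd": post_sum.pd_deg, "post_mai": post_sum.mai,
            "post_nvs": post_sum.nvs, "post_p": post_sum.p_perm,
            "post_asymmetric": post_sum.is_asymmetric,
            "pre_and_post": bool(pre_sum.is_asymmetric
                                 and post_sum.is_asymmetric),
            "exclusion_reason": None,
        })
    reports = pd.DataFrame(rows)
    exclusions = pd.DataFrame(excl_rows, columns=["cell_id", "reason"])
    return ScreenResult(reports=reports, exclusions=exclusions,
                        responses=responses)


def _grating_counts(spike_times, trials: pd.DataFrame) -> np.ndarray:
    dirs = np.sort(trials["direction"].unique())
    n_rep = int(trials.groupby("direction").size().min())
    counts = np.zeros((dirs.size, n_rep), int)
    for di, d in enumerate(dirs):
        g = trials[trials["direction"] == d].sort_values("onset")
        for ri, tr in enumerate(g.iloc[:n_rep].itertuples(index=False)):
            counts[di, ri] = count_in_window(spike_times, tr.onset,
                                             tr.onset + tr.duration)
    return counts


def sensitivity_sweep_central_radius(rec: SimRecording, radii,
                                     cfg: RunConfig | None = None,
                                     seed: int = 0,
                                     rf_source: str = "ground_truth"
                                     ) -> pd.DataFrame:
    """Re-run the PRE classification for several Central-area radii and
    report the asymmetric fraction per radius (spatial-confinement probe).
    """
    cfg = cfg or RunConfig()
    rows = []
    for r in radii:
        c = replace(cfg, central_radius=float(r),
                    distance_min_required=max(cfg.distance_min_required,
                                              float(r) + 1e-9))
        res = run_screen(rec, c, seed=seed, rf_source=rf_source)
        rows.append({"central_radius": float(r),
                     "n_included": len(res.reports),
                     "pre_fraction": res.pre_fraction})
    out = pd.DataFrame(rows)
    if len(out) and (out["n_included"] == 0).all():
        warnings.warn("no cells included at any tested radius")
    return out


# ---------------------------------------------------------------------------
# Desensitization trial split
# ---------------------------------------------------------------------------

def desensitization_split(spikes: pd.DataFrame, trials: pd.DataFrame,
                          rf_center, pd_deg: float, central_radius: float,
                          annulus_radius: float, min_trials: int = 3,
                          baseline_rate: float = 0.0,
                          shuffle_history_seed=None):
    """Split activation-zone static-bar responses by previous-trial location.

    Bars are classed, per this cell, by the signed position s of the bar
    center along the preferred/null axis (negative s = the activation-zone
    side): Central (|s| <= central_radius), activation zone
    (-annulus <= s < -central_radius on the nearest-to-PD axis), or far.
    Each zone presentation contributes its onset-evoked rate (measured rate
    minus ``baseline_rate``, so the ratio estimates the desensitization
    gain directly) to the group named by the *previous* trial:
    "after_central" when the previous bar sat in the Central area,
    "no_previous" when it sat in neither the Central area nor the zone.
    Returns group means, their ratio and trial counts; raises ValueError
    when a group has fewer than ``min_trials``.  ``shuffle_history_seed``
    permutes the previous-trial labels across zone presentations — the
    negative control that breaks the history covariate (the ratio should
    then return to ~1 whatever the desensitization strength).
    """
    t = spikes["t_s"].to_numpy()
    ordered = trials.sort_values("onset").reset_index(drop=True)
    axes = np.unique(ordered["axis_deg"].to_numpy(float))
    d = np.abs(circular_difference(2 * axes, 2 * pd_deg)) / 2.0
    axis = float(axes[np.argmin(d)])
    flip = np.cos(np.deg2rad(axis - pd_deg)) < 0

    def location(trial):
        u = unit_vector(trial.axis_deg)
        rel = float(trial.offset) - float(np.dot(rf_center, u))
        on_pd_axis = np.isclose(trial.axis_deg, axis) or np.isclose(
            abs(circular_difference(trial.axis_deg, axis)), 180.0)
        s = -rel if flip else rel
        if abs(rel) <= central_radius:
            return "central"
        if on_pd_axis and -annulus_radius <= s < -central_radius:
            return "zone"
        return "far"

    pairs = []  # (previous location, evoked rate) per zone presentation
    prev_loc = None
    for trial in ordered.itertuples(index=False):
        loc = location(trial)
        if loc == "zone" and prev_loc is not None:
            rate = count_in_window(t, trial.onset,
                                   trial.onset + trial.duration) \
                / trial.duration - baseline_rate
            if prev_loc in ("central", "far"):
                pairs.append((prev_loc, rate))
        prev_loc = loc
    if shuffle_history_seed is not None and pairs:
        rng = np.random.default_rng(shuffle_history_seed)
        labels = rng.permutation([p[0] for p in pairs])
        pairs = list(zip(labels, (p[1] for p in pairs)))
    groups = {"after_central": [r for lab, r in pairs if lab == "central"],
              "no_previous": [r for lab, r in pairs if lab == "far"]}
    n_ac, n_np = len(groups["after_central"]), len(groups["no_previous"])
    if n_ac < min_trials or n_np < min_trials:
        raise ValueError(f"too few trials per condition "
                         f"(after_central={n_ac}, no_previous={n_np})")
    m_ac = float(np.mean(groups["after_central"]))
    m_np = float(np.mean(groups["no_previous"]))
    ratio = m_ac / m_np if m_np > 0 else float("nan")
    return {"after_central": m_ac, "no_previous": m_np, "ratio": ratio,
            "n_after_central": n_ac, "n_no_previous": n_np}


# ---------------------------------------------------------------------------
# Central-mask comparison
# ---------------------------------------------------------------------------

def masking_comparison(rec_unmasked: SimRecording, rec_masked: SimRecording,
                       cfg: RunConfig | None = None, seed: int = 0,
                       rf_source: str = "ground_truth") -> pd.DataFrame:
    """Compare moving-bar responses with and without the central mask.

    Per cell present in both recordings: the Central-area suppression
    fraction, the masked PRE-PD and POST-ND rates (both are responses to
    the bar's leading edge crossing the activation zone, in opposite
    directions), their ratio, an inherent-DS flag (one-sided Wilcoxon
    PRE-PD > POST-ND across repetitions), and the preferred-direction
    shift mask vs no-mask.  The POST leading-edge exclusion is *not*
    applied in the masked condition (masking removes the classical-RF
    overlap it guards against).
    """
    cfg = (cfg or RunConfig()).validate()
    scr = run_screen(rec_unmasked, cfg, seed=seed, rf_source=rf_source)
    masked_pid = _bar_protocol_id(rec_masked, masked=True)
    masked_trials = rec_masked.trials_of(masked_pid)
    rows = []
    for _, rep in scr.reports.iterrows():
        cid = rep["cell_id"]
        resp = scr.responses[cid]
        windows = resp["windows"]
        rf_center = resp["rf"].center
        spk_m = rec_masked.spikes_of(cid, masked_pid)
        if not len(masked_trials):
            continue
        try:
            pre_m = direction_spike_counts(spk_m, masked_trials, windows,
                                           "PRE", rf_center)
            post_m = direction_spike_counts(spk_m, masked_trials, windows,
                                            "POST", rf_center,
                                            apply_post_exclusion=False)
            cen_m = direction_spike_counts(spk_m, masked_trials, windows,
                                           "CENTRAL", rf_center)
        except ValueError as e:
            rows.append({"cell_id": cid, "dropped": str(e)})
            continue
        cen_u = resp.get("central")
        if cen_u is None:
            spk_u = rec_unmasked.spikes_of(
                cid, _bar_protocol_id(rec_unmasked, masked=False))
            cen_u = direction_spike_counts(
                spk_u, rec_unmasked.trials_of(
                    _bar_protocol_id(rec_unmasked, masked=False)),
                windows, "CENTRAL", rf_center)
        # suppression of the *evoked* Central response (maintained
        # discharge subtracted): the mask cannot remove baseline firing
        base0 = rep["baseline_rate"] if np.isfinite(rep["baseline_rate"]) \
            else 0.0
        u_rate = max(cen_u.rates.mean() - base0, 0.0)
        m_rate = max(cen_m.rates.mean() - base0, 0.0)
        suppression = 1.0 - m_rate / u_rate if u_rate > 0 else float("nan")
        pd_deg = rep["pre_pd"]
        if np.isfinite(pd_deg):
            dirs = np.asarray(pre_m.directions, float)
            i_pd = int(np.argmin(np.abs(circular_difference(dirs, pd_deg))))
            i_nd = int(np.argmin(np.abs(
                circular_difference(dirs, pd_deg + 180.0))))
            pd_rates = pre_m.rates[i_pd]
            nd_rates = post_m.rates[i_nd]
            # evoked (baseline-subtracted) rates: the ratio then estimates
            # the inherent DS gain of the activation zone
            base = rep["baseline_rate"] if np.isfinite(rep["baseline_rate"]) \
                else 0.0
            m_pd = max(pd_rates.mean() - base, 0.0)
            m_nd = max(nd_rates.mean() - base, 0.0)
            ratio = m_pd / m_nd if m_nd > 0 else float("inf")
            diff = pd_rates - nd_rates
            if np.allclose(diff, 0.0):
                p = 1.0
            else:
                p = float(wilcoxon(diff, alternative="greater",
                                   zero_method="wilcox").pvalue)
            inherent_ds = bool(p < cfg.alpha)
            pre_m_sum = classify_window(
                pre_m, theta_mai=cfg.theta_mai, theta_nvs=cfg.theta_nvs,
                theta_count=cfg.theta_count, alpha=cfg.alpha,
                n_perm=cfg.n_perm, seed=[seed, hash(cid) % (2 ** 31), 3])
            dpd = compare_pd(pre_m_sum.pd_deg, pd_deg)
        else:
            ratio, p, inherent_ds, dpd = (float("nan"), float("nan"),
                                          False, float("nan"))
            pd_rates = nd_rates = np.array([np.nan])
        rows.append({
            "cell_id": cid,
            "pre_asymmetric": rep["pre_asymmetric"],
            "central_suppression": float(suppression),
            "pre_pd_masked_rate": float(np.mean(pd_rates)),
            "post_nd_masked_rate": float(np.mean(nd_rates)),
            "pd_nd_ratio_masked": float(ratio),
            "inherent_ds": inherent_ds,
            "inherent_ds_p": p,
            "delta_pd_mask": dpd,
            "dropped": None,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Speed tuning
# ---------------------------------------------------------------------------

def speed_tuning_analysis(per_speed: dict, ref_speed: float = 600.0):
    """Multi-speed PRE-tuning comparison for cells classified asymmetric at
    the reference speed.

    ``per_speed`` maps speed -> {cell_id -> (DirectionalResponse,
    TuningSummary)}.  Cells missing any speed are dropped.  Returns a dict
    with per-speed preferred-direction shifts relative to the reference
    speed, tuning curves aligned to the reference PD and peak-normalized,
    per-speed mAI/NVS tables, and a Friedman test (with Tukey-Kramer
    corrected pairwise p-values) on per-cell mAI across speeds.
    """
    speeds = sorted(per_speed)
    if ref_speed not in per_speed:
        raise ValueError(f"reference speed {ref_speed} missing")
    ref = per_speed[ref_speed]
    cells = [cid for cid, (_, s) in ref.items() if s.is_asymmetric]
    cells = [cid for cid in cells
             if all(cid in per_speed[v] for v in speeds)]
    if not cells:
        raise ValueError("no cells classified asymmetric at the reference "
                         "speed are present at every speed")
    n_dir = len(ref[cells[0]][0].directions)
    dpd = {v: [] for v in speeds}
    mai = {v: [] for v in speeds}
    nvs = {v: [] for v in speeds}
    aligned = {v: [] for v in speeds}
    for cid in cells:
        pd_ref = ref[cid][1].pd_deg
        i_ref = int(round(pd_ref / (360.0 / n_dir))) % n_dir
        for v in speeds:
            resp, summ = per_speed[v][cid]
            dpd[v].append(compare_pd(summ.pd_deg, pd_ref))
            mai[v].append(summ.mai)
            nvs[v].append(summ.nvs)
            curve = np.roll(resp.mean_counts, -i_ref)
            peak = curve.max()
            aligned[v].append(curve / peak if peak > 0 else curve)
    mai_mat = np.array([mai[v] for v in speeds])  # (n_speed, n_cell)
    if len(speeds) >= 3 and np.ptp(mai_mat) > 0:
        fr = friedmanchisquare(*mai_mat)
        fr_p = float(fr.pvalue)
        posthoc = _tukey_kramer_ranks(mai_mat, speeds)
    else:
        fr_p, posthoc = 1.0, {}
    return {
        "cells": cells,
        "speeds": speeds,
        "delta_pd": {v: np.array(dpd[v]) for v in speeds},
        "mai": {v: np.array(mai[v]) for v in speeds},
        "nvs": {v: np.array(nvs[v]) for v in speeds},
        "aligned_curves": {v: np.array(aligned[v]) for v in speeds},
        "friedman_p": fr_p,
        "tukey_kramer_p": posthoc,
    }


def _tukey_kramer_ranks(mat: np.ndarray, labels) -> dict:
    """Tukey-Kramer pairwise comparisons on Friedman mean ranks."""
    k, n = mat.shape
    ranks = np.apply_along_axis(lambda col: pd.Series(col).rank().to_numpy(),
                                0, mat)
    mean_ranks = ranks.mean(axis=1)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            q = np.sqrt(2.0) * abs(mean_ranks[i] - mean_ranks[j]) / se
            p = float(studentized_range.sf(q, k, 1e6))
            out[(labels[i], labels[j])] = p
    return out


# ---------------------------------------------------------------------------
# Full-field clustering
# ---------------------------------------------------------------------------

def cluster_full_field(psths: np.ndarray, k_range=range(2, 8),
                       variance: float = 0.9, seed: int = 0):
    """Cluster full-field PSTHs: z-score, project onto the leading
    principal components (those with above-average explained variance, a
    Kaiser-style cut within the ``variance`` envelope), agglomerate with
    Ward linkage, and pick k by silhouette over ``k_range``.

    Returns (labels, k, info dict).  Fewer cells than min(k_range) + 1 is
    an error; a degenerate silhouette (single effective cluster) is
    flagged in info.
    """
    x = np.asarray(psths, float)
    if x.ndim != 2:
        raise ValueError("psths must be (n_cells, n_bins)")
    k_range = [int(k) for k in k_range]
    if x.shape[0] <= min(k_range):
        raise ValueError(f"need more than {min(k_range)} cells")
    sd = x.std(axis=1, keepdims=True)
    z = (x - x.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)
    if float(z.std(axis=0).max()) < 1e-9:  # identical PSTHs across cells
        return (np.zeros(x.shape[0], int), min(k_range),
                {"silhouette": float("nan"), "degenerate": True,
                 "n_components": 0})
    n_comp = min(z.shape[0] - 1, z.shape[1])
    p = PCA(n_components=n_comp, random_state=seed).fit(z)
    evr = p.explained_variance_ratio_
    # components well above the average ratio carry structure; the flat
    # noise tail dilutes the silhouette criterion
    keep = int(np.clip(np.count_nonzero(evr > 2.0 * evr.mean()), 2,
                       np.searchsorted(np.cumsum(evr), variance) + 1))
    feats = p.transform(z)[:, :keep]
    best = None
    degenerate = False
    for k in k_range:
        if k >= x.shape[0]:
            continue
        labels = AgglomerativeClustering(n_clusters=k,
                                         linkage="ward").fit_predict(feats)
        if len(np.unique(labels)) < 2:
            degenerate = True
            continue
        try:
            s = silhouette_score(feats, labels)
        except ValueError:
            degenerate = True
            continue
        if best is None or s > best[0]:
            best = (s, k, labels)
    if best is None:
        k0 = min(k_range)
        return (np.zeros(x.shape[0], int), k0,
                {"silhouette": float("nan"), "degenerate": True,
                 "n_components": keep})
    s, k, labels = best
    return labels, k, {"silhouette": float(s), "degenerate": degenerate,
                       "n_components": keep}


# ---------------------------------------------------------------------------
# Paired condition comparison
# ---------------------------------------------------------------------------

def condition_comparison(before, after):
    """Paired per-cell spike counts before/after a condition change
    (e.g., bath pharmacology), with a two-sided Wilcoxon signed-rank p.

    Identical conditions give p = 1 (all-zero differences).  Fewer than 5
    pairs sets ``small_n`` in the result.
    """
    b = np.asarray(before, float)
    a = np.asarray(after, float)
    if b.shape != a.shape:
        raise ValueError("before/after must be paired (same length)")
    diff = a - b
    if np.allclose(diff, 0.0):
        p = 1.0
    else:
        p = float(wilcoxon(diff, zero_method="wilcox").pvalue)
    return {"mean_before": float(b.mean()), "mean_after": float(a.mean()),
            "p": p, "n": int(b.size), "small_n": bool(b.size < 5)}
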