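"""Core screen statistics for extraclassical motion responses.

Given per-cell PRE / Central / POST windows (from :mod:`premotion.geometry`)
and a spike table, this module computes the 8-direction tuning of each
window, the motion asymmetry index (mAI), the normalized vector sum (NVS),
a direction-label permutation test, the PRE / POST asymmetry classification,
the baseline comparison, the static-bar asymmetry index (sAI), and circular
preferred-direction differences.

Definitions (direction responses are mean spike counts r_d over the eight
motion directions theta_d):

    mAI  = (r_PD - r_ND) / (r_PD + r_ND),  PD = argmax_d r_d, ND = PD + 180
    NVS  = | sum_d r_d e^{i theta_d} | / sum_d r_d

A window's response is *asymmetric* when mAI > theta_mAI, NVS > theta_NVS,
the mean PD count per repetition reaches theta_count, and the permutation
test rejects at alpha.  Spike windows are half-open [start, end).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from .circstats import circular_difference
from .geometry import (DIRECTIONS_DEG, AnalysisWindows, bar_alignment_time,
                       unit_vector)

__all__ = [
    "DirectionalResponse", "TuningSummary", "direction_spike_counts",
    "motion_asymmetry_index", "normalized_vector_sum", "permutation_test",
    "classify_window", "classify_pre", "classify_post",
    "baseline_comparison", "estimate_baseline_rate",
    "static_asymmetry_index", "compare_pd",
]


@dataclass(frozen=True)
class DirectionalResponse:
    """Spike counts per (direction x repetition) in one analysis window."""
    window_kind: str                 # PRE | CENTRAL | POST
    counts: np.ndarray               # (8, R) int
    duration: float                  # effective window length, s (per trial)
    directions: np.ndarray = field(
        default_factory=lambda: DIRECTIONS_DEG.copy())

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != len(self.directions):
            raise ValueError("counts must be (n_directions, n_repetitions)")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")

    @property
    def rates(self) -> np.ndarray:
        return self.counts / self.duration

    @property
    def mean_counts(self) -> np.ndarray:
        return self.counts.mean(axis=1)


@dataclass(frozen=True)
class TuningSummary:
    window_kind: str
    pd_deg: float                 # preferred direction: resultant angle
    pd_argmax_deg: float          # direction of the largest mean count
    mai: float
    nvs: float
    nvs_angle_deg: float
    mean_count_pd: float          # spikes per repetition in the PD
    p_perm: float
    is_asymmetric: bool
    baseline_rate: float = np.nan
    enhancement: str = "none"     # enhanced | suppressed | both | none
    defined: bool = True
    note: str = ""

    @property
    def nd_deg(self) -> float:
        return float(np.mod(self.pd_deg + 180.0, 360.0))


# ---------------------------------------------------------------------------
# Window spike counting
# ---------------------------------------------------------------------------

def count_in_window(spike_times, start, end, exclusion=None) -> int:
    """Spikes in the half-open interval [start, end), minus an optional
    excluded sub-interval [e0, e1)."""
    t = np.asarray(spike_times, float)
    n = int(np.count_nonzero((t >= start) & (t < end)))
    if exclusion is not None:
        e0, e1 = max(exclusion[0], start), min(exclusion[1], end)
        if e1 > e0:
            n -= int(np.count_nonzero((t >= e0) & (t < e1)))
    return n


def effective_duration(window, exclusion=None) -> float:
    d = window[1] - window[0]
    if exclusion is not None:
        e0, e1 = max(exclusion[0], window[0]), min(exclusion[1], window[1])
        d -= max(0.0, e1 - e0)
    return d


def direction_spike_counts(spikes: pd.DataFrame, trials: pd.DataFrame,
                           windows: AnalysisWindows, window_kind: str,
                           rf_center,
                           apply_post_exclusion: bool = True
                           ) -> DirectionalResponse:
    """Per-direction, per-repetition spike counts of one cell in one window.

    ``spikes`` holds the cell's spike times (column ``t_s``); ``trials`` the
    moving-bar trial log (one protocol, one speed).  Counts are taken in
    the window shifted to each trial's bar/RF alignment time.  A direction
    missing any repetition raises ValueError (the caller records the cell
    as incomplete).
    """
    window_kind = window_kind.upper()
    w0, w1 = windows.window(window_kind)
    excl = windows.post_exclusion \
        if (window_kind == "POST" and apply_post_exclusion) else None
    t = spikes["t_s"].to_numpy()
    dirs = np.asarray(windows.directions, float)
    if not len(trials):
        raise ValueError("no moving-bar trials")
    sizes = trials.groupby("direction").size()
    n_rep = int(sizes.max())
    per_dir = trials.groupby("direction")
    counts = np.zeros((len(dirs), n_rep), dtype=int)
    for di, d in enumerate(dirs):
        try:
            g = per_dir.get_group(d)
        except KeyError:
            raise ValueError(f"no trials for direction {d:g} deg")
        g = g.sort_values("onset")
        if len(g) < n_rep:
            raise ValueError(f"direction {d:g} deg has {len(g)} < {n_rep} "
                             "repetitions (incomplete cell)")
        for ri, trial in enumerate(g.itertuples(index=False)):
            t0 = bar_alignment_time(trial.onset, trial.p0, trial.speed,
                                    trial.direction, rf_center)
            e = None if excl is None else (t0 + excl[0], t0 + excl[1])
            counts[di, ri] = count_in_window(t, t0 + w0, t0 + w1, e)
    dur = effective_duration((w0, w1), excl)
    return DirectionalResponse(window_kind=window_kind, counts=counts,
                               duration=dur, directions=dirs)


# ---------------------------------------------------------------------------
# Indices
# ---------------------------------------------------------------------------

def motion_asymmetry_index(mean_counts, directions=None):
    """mAI = (r_PD - r_ND)/(r_PD + r_ND) with PD the argmax direction and
    ND its opposite.  Returns (mAI, pd_deg); all-zero input gives (0, nan)
    (flagged undefined by the caller)."""
    r = np.asarray(mean_counts, float)
    dirs = np.asarray(DIRECTIONS_DEG if directions is None else directions,
                      float)
    if np.any(r < 0):
        raise ValueError("counts must be non-negative")
    if r.sum() <= 0:
        return 0.0, float("nan")
    i_pd = int(np.argmax(r))
    pd_deg = float(dirs[i_pd])
    i_nd = int(np.argmin(np.abs(circular_difference(dirs, pd_deg + 180.0))))
    r_pd, r_nd = r[i_pd], r[i_nd]
    return float((r_pd - r_nd) / (r_pd + r_nd)), pd_deg


def normalized_vector_sum(mean_counts, directions=None):
    """NVS = |sum r_d e^{i theta_d}| / sum r_d and the resultant angle.
    All-zero input gives (0, nan)."""
    r = np.asarray(mean_counts, float)
    dirs = np.asarray(DIRECTIONS_DEG if directions is None else directions,
                      float)
    if np.any(r < 0):
        raise ValueError("counts must be non-negative")
    total = r.sum()
    if total <= 0:
        return 0.0, float("nan")
    z = np.sum(r * np.exp(1j * np.deg2rad(dirs)))
    nvs = float(np.abs(z) / total)
    if nvs <= 1e-12:
        return nvs, float("nan")
    ang = float(np.mod(np.rad2deg(np.angle(z)), 360.0))
    if ang >= 360.0 - 1e-9:
        ang = 0.0
    return nvs, ang


def permutation_test(counts, n_perm: int = 1000, seed=0,
                     directions=None) -> float:
    """Direction-label permutation test of tuning.

    The statistic is the resultant length |sum_d mean(r_d) e^{i theta_d}|;
    the null shuffles direction labels across all (direction x repetition)
    trials.  p = (1 + #{perm >= observed}) / (1 + n_perm); identical counts
    in every trial give p = 1.
    """
    counts = np.asarray(counts, float)
    if counts.ndim != 2:
        raise ValueError("counts must be (n_directions, n_repetitions)")
    n_dir, n_rep = counts.shape
    if n_rep < 3:
        raise ValueError("need >= 3 repetitions")
    dirs = np.asarray(DIRECTIONS_DEG if directions is None else directions,
                      float)
    phase = np.exp(1j * np.deg2rad(dirs))

    def resultant(c):
        return np.abs(c.mean(axis=-1) @ phase)

    obs = resultant(counts)
    if np.ptp(counts) == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    flat = counts.ravel()
    perms = rng.permuted(np.tile(flat, (n_perm, 1)), axis=1)
    stat = resultant(perms.reshape(n_perm, n_dir, n_rep))
    return float((1.0 + np.count_nonzero(stat >= obs - 1e-12))
                 / (1.0 + n_perm))


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_window(resp: DirectionalResponse, theta_mai: float = 0.3,
                    theta_nvs: float = 0.15, theta_count: float = 2.0,
                    alpha: float = 0.05, n_perm: int = 1000, seed=0,
                    baseline_rate: float = np.nan) -> TuningSummary:
    """Full asymmetry classification of one window's direction tuning."""
    mean = resp.mean_counts
    if mean.sum() <= 0:
        return TuningSummary(resp.window_kind, float("nan"), float("nan"),
                             0.0, 0.0, float("nan"), 0.0, 1.0, False,
                             baseline_rate=baseline_rate, defined=False,
                             note="no spikes in window")
    mai, pd_argmax = motion_asymmetry_index(mean, resp.directions)
    nvs, ang = normalized_vector_sum(mean, resp.directions)
    p = permutation_test(resp.counts, n_perm=n_perm, seed=seed,
                         directions=resp.directions)
    mean_pd = float(mean[int(np.argmax(mean))])
    flag = bool(mai > theta_mai and nvs > theta_nvs
                and mean_pd >= theta_count and p < alpha)
    # the reported PD is the resultant angle (continuous, as drawn on polar
    # plots); fall back to the argmax direction for untuned responses
    pd_deg = ang if np.isfinite(ang) else pd_argmax
    return TuningSummary(resp.window_kind, pd_deg, pd_argmax, mai, nvs, ang,
                         mean_pd, p, flag, baseline_rate=baseline_rate)


def classify_pre(resp: DirectionalResponse, **kwargs) -> TuningSummary:
    if resp.window_kind != "PRE":
        raise ValueError("expected a PRE-window response")
    return classify_window(resp, **kwargs)


def classify_post(resp: DirectionalResponse, **kwargs) -> TuningSummary:
    if resp.window_kind != "POST":
        raise ValueError("expected a POST-window response")
    return classify_window(resp, **kwargs)


# ---------------------------------------------------------------------------
# Baseline
# ---------------------------------------------------------------------------

def estimate_baseline_rate(spikes: pd.DataFrame, trials: pd.DataFrame,
                           window: float = 1.0) -> float:
    """Baseline firing rate from the final ``window`` seconds of each
    inter-trial blank."""
    t = spikes["t_s"].to_numpy()
    total, dur = 0, 0.0
    for trial in trials.itertuples(index=False):
        end = trial.onset + trial.duration + trial.blank
        start = max(end - window, trial.onset + trial.duration)
        total += np.count_nonzero((t >= start) & (t < end))
        dur += end - start
    return total / dur if dur > 0 else float("nan")


def baseline_comparison(resp: DirectionalResponse, summary: TuningSummary,
                        baseline_rate: float, alpha: float = 0.05) -> str:
    """Compare PD and ND PRE-window rates against the baseline rate.

    'enhanced' when the PD rate exceeds baseline (one-sided Wilcoxon
    signed-rank across repetitions), 'suppressed' when the ND rate falls
    below it, 'both' / 'none' accordingly.  Fewer than 3 repetitions give
    'none'.
    """
    if not np.isfinite(summary.pd_deg):
        return "none"
    rates = resp.rates
    dirs = np.asarray(resp.directions, float)
    i_pd = int(np.argmin(np.abs(circular_difference(dirs, summary.pd_deg))))
    i_nd = int(np.argmin(np.abs(circular_difference(dirs, summary.nd_deg))))
    if rates.shape[1] < 3 or not np.isfinite(baseline_rate):
        return "none"

    def one_sided(diff, alternative):
        if np.allclose(diff, 0.0):
            return 1.0
        return float(wilcoxon(diff, alternative=alternative,
                              zero_method="wilcox").pvalue)

    enh = one_sided(rates[i_pd] - baseline_rate, "greater") < alpha
    sup = one_sided(rates[i_nd] - baseline_rate, "less") < alpha
    if enh and sup:
        return "both"
    if enh:
        return "enhanced"
    if sup:
        return "suppressed"
    return "none"


# ---------------------------------------------------------------------------
# Static-bar asymmetry
# ---------------------------------------------------------------------------

def static_asymmetry_index(spikes: pd.DataFrame, trials: pd.DataFrame,
                           rf_center, pd_deg: float, central_radius: float,
                           annulus_radius: float | None = None):
    """Static-bar asymmetry index around a cell's PRE preferred direction.

    Uses flashed bars whose offset axis is the tested orientation closest
    to the PD/ND axis (i.e., bars oriented orthogonally to it).  Bars whose
    center lies beyond the Central area on the side the preferred motion
    comes from (the activation-zone side, opposite the PD vector) count as
    preferred-side; the far side as null-side.  Side responses are mean
    onset-evoked rates; sAI = (R_pref - R_null)/(R_pref + R_null).

    Returns a dict with sai, side rates, the Central-area static rate and
    the number of bars per side; sai is nan (flagged) when either side has
    no bars or no evoked spikes on both sides.
    """
    axes = np.unique(trials["axis_deg"].to_numpy(float))
    if axes.size == 0:
        raise ValueError("no static-bar trials")
    # nearest tested axis to the PD/ND axis, modulo 180
    d = np.abs(circular_difference(2 * axes, 2 * pd_deg)) / 2.0
    axis = float(axes[np.argmin(d)])
    sel = trials[np.isclose(trials["axis_deg"].astype(float), axis)]
    flip = np.cos(np.deg2rad(axis - pd_deg)) < 0  # axis anti-parallel to PD
    t = spikes["t_s"].to_numpy()
    proj = float(np.dot(np.asarray(rf_center, float), unit_vector(axis)))
    outer = annulus_radius if annulus_radius is not None else np.inf
    rates = {"pref": [], "null": [], "central": []}
    for trial in sel.itertuples(index=False):
        rel = float(trial.offset) - proj
        s = -rel if flip else rel
        n = count_in_window(t, trial.onset, trial.onset + trial.duration)
        rate = n / trial.duration
        if abs(s) <= central_radius:
            rates["central"].append(rate)
        elif abs(s) <= outer:
            # preferred side: where the PD motion comes from (-PD direction)
            rates["pref" if s < 0 else "null"].append(rate)
    out = {k: (float(np.mean(v)) if v else float("nan"))
           for k, v in rates.items()}
    n_pref, n_null = len(rates["pref"]), len(rates["null"])
    if n_pref == 0 or n_null == 0:
        sai = float("nan")
    else:
        tot = out["pref"] + out["null"]
        sai = (out["pref"] - out["null"]) / tot if tot > 0 else float("nan")
    return {"sai": sai, "rate_pref_side": out["pref"],
            "rate_null_side": out["null"], "rate_central": out["central"],
            "axis_deg": axis, "n_pref": n_pref, "n_null": n_null}


def polar_plot_frame(resp: DirectionalResponse) -> pd.DataFrame:
    """Tidy per-direction summary for polar plots: mean count, SEM and the
    individual repetition values (one row per direction x repetition)."""
    rows = []
    counts = np.asarray(resp.counts)
    for di, d in enumerate(resp.directions):
        sem = counts[di].std(ddof=1) / np.sqrt(counts.shape[1]) \
            if counts.shape[1] > 1 else np.nan
        for ri in range(counts.shape[1]):
            rows.append({"direction_deg": float(d),
                         "mean_count": float(counts[di].mean()),
                         "sem": float(sem),
                         "repetition": ri,
                         "count": int(counts[di, ri])})
    return pd.DataFrame(rows)


def compare_pd(pd_a: float, pd_b: float) -> float:
    """Circular preferred-direction difference pd_a - pd_b in (-180, 180];
    nan inputs propagate."""
    if not (np.isfinite(pd_a) and np.isfinite(pd_b)):
        return float("nan")
    return float(circular_difference(pd_a, pd_b))
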