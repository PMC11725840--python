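"""Classical receptive-field estimation and cell typing.

The RF center and size come from the spike-triggered average (STA) under
white-noise checkerboard stimulation, fitted with a 2-D Gaussian; polarity
(ON / OFF / ON-OFF) and the transience index come from full-field spot
responses; conventional direction-selective cells are flagged from
square-wave grating responses using the resultant-length index with a
permutation test.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.optimize import curve_fit

from .asymmetry import normalized_vector_sum, permutation_test


@dataclass(frozen=True)
class ReceptiveField:
    center: tuple = (np.nan, np.nan)
    sigma: float = np.nan            # geometric-mean SD of the Gaussian fit
    polarity: str = "none"           # ON | OFF | ON_OFF | none
    sta_peak_lag: float = np.nan     # s before the spike
    fit_quality: float = 0.0         # R^2 of the Gaussian fit
    transience_index: float = np.nan  # 1 = fully transient
    classical_ds: bool = False
    classical_pd: float = np.nan
    reliable: bool = False
    note: str = ""

    @property
    def size(self) -> float:
        """RF radius convention: 2 sigma of the Gaussian fit."""
        return 2.0 * self.sigma


# ---------------------------------------------------------------------------
# Spike-triggered average
# ---------------------------------------------------------------------------

def compute_sta(spike_times, frames: np.ndarray, frame_rate: float,
                onset: float = 0.0, n_lags: int = 12,
                min_spikes: int = 300, frames_flat: np.ndarray | None = None):
    """Spike-triggered average of white-noise frames.

    Returns (sta, peak_lag_index, n_spikes) where ``sta`` has shape
    (n_lags, ny, nx); lag 0 is the frame on screen at the spike.  The peak
    lag is located by the maximum |deviation from the frame mean| after a
    3x3 spatial average (the RF blob spans several checkers, single-pixel
    noise does not).  Raises ValueError if fewer than ``min_spikes`` spikes
    are available (callers flag the RF unreliable).

    ``frames_flat`` may carry the zero-mean flattened frames
    (``frames.reshape(T, -1).astype(float32) - 0.5``), precomputed once
    when many cells share the same stimulus.
    """
    spike_times = np.asarray(spike_times, float)
    n_frames = frames.shape[0]
    idx = np.floor((spike_times - onset) * frame_rate).astype(int)
    idx = idx[(idx >= n_lags - 1) & (idx < n_frames)]
    if idx.size < min_spikes:
        raise ValueError(f"too few spikes for STA ({idx.size} < {min_spikes})")
    counts = np.bincount(idx, minlength=n_frames).astype(np.float32)
    if frames_flat is None:
        frames_flat = frames.reshape(n_frames, -1).astype(np.float32) - 0.5
    total = float(counts.sum())
    # all lags in one float32 matmul: row L holds counts shifted by L frames
    lagged = np.zeros((n_lags, n_frames), dtype=np.float32)
    for lag in range(n_lags):
        lagged[lag, :n_frames - lag] = counts[lag:]
    sta = (lagged @ frames_flat).astype(float).reshape(
        (n_lags,) + frames.shape[1:]) / total
    smooth = np.abs(uniform_filter(sta, size=(1, 3, 3), mode="nearest"))
    return sta, int(np.unravel_index(np.argmax(smooth),
                                     sta.shape)[0]), int(total)


def _gauss2d(xy, amp, x0, y0, sx, sy, off):
    x, y = xy
    return (amp * np.exp(-((x - x0) ** 2 / (2 * sx ** 2)
                           + (y - y0) ** 2 / (2 * sy ** 2))) + off).ravel()


def fit_rf_gaussian(peak_frame: np.ndarray, xs, ys):
    """Least-squares 2-D Gaussian fit of the STA's peak spatial frame.

    ``xs`` / ``ys`` are the checker-center coordinates.  Returns
    (center, sigma, fit_quality, sign) with sigma the geometric mean of the
    two axis SDs; raises ValueError when no dominant blob exists (flat
    frame or divergent fit).
    """
    img = np.asarray(peak_frame, float)
    gx, gy = np.meshgrid(xs, ys)
    dev = img - np.median(img)
    if np.allclose(dev, 0.0, atol=1e-12):
        raise ValueError("flat STA frame: no dominant blob")
    # initialize on the smoothed deviation so single-pixel noise cannot
    # seed the fit away from the blob
    sm = uniform_filter(dev, size=3, mode="nearest")
    iy, ix = np.unravel_index(np.argmax(np.abs(sm)), img.shape)
    amp0 = dev[iy, ix] if abs(dev[iy, ix]) > 1e-12 else sm[iy, ix]
    checker = float(xs[1] - xs[0]) if len(xs) > 1 else 1.0
    p0 = [amp0, gx[iy, ix], gy[iy, ix], 2 * checker, 2 * checker,
          float(np.median(img))]
    try:
        popt, _ = curve_fit(_gauss2d, (gx, gy), img.ravel(), p0=p0,
                            maxfev=5000)
    except RuntimeError as e:
        raise ValueError(f"Gaussian fit diverged: {e}") from e
    amp, x0, y0, sx, sy, off = popt
    resid = img.ravel() - _gauss2d((gx, gy), *popt)
    ss_tot = float(np.sum((img - img.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
    sigma = float(np.sqrt(abs(sx) * abs(sy)))
    if not np.isfinite(sigma) or sigma <= 0:
        raise ValueError("degenerate Gaussian fit")
    return (float(x0), float(y0)), sigma, float(r2), float(np.sign(amp))


# ---------------------------------------------------------------------------
# Polarity and transience from full-field steps
# ---------------------------------------------------------------------------

def classify_polarity_transience(spike_times_per_trial, on_duration: float,
                                 off_duration: float,
                                 response_window: float = 0.5,
                                 polarity_ratio: float = 2.0,
                                 bin_s: float = 0.025):
    """Polarity and transience from full-field ON/OFF step responses.

    ``spike_times_per_trial`` holds spike times relative to each trial's ON
    onset.  Polarity compares onset- vs offset-evoked counts within
    ``response_window`` (ON if the ON count exceeds ``polarity_ratio`` times
    the OFF count, OFF for the reverse, otherwise ON_OFF).  The transience
    index is 1 - (mean rate in the late half of the dominant step) / peak.
    Returns (polarity, transience_index, psth, bin_edges); polarity "none"
    when neither step evokes spikes beyond the pre-onset rate.
    """
    trials = [np.asarray(t, float) for t in spike_times_per_trial]
    if len(trials) < 3:
        raise ValueError("need >= 3 repetitions")
    n = len(trials)
    allspk = np.concatenate(trials) if trials else np.empty(0)
    on_cnt = sum(np.count_nonzero((t >= 0) & (t < response_window))
                 for t in trials)
    off_cnt = sum(np.count_nonzero((t >= on_duration)
                                   & (t < on_duration + response_window))
                  for t in trials)
    edges = np.arange(0.0, on_duration + off_duration + bin_s, bin_s)
    psth = np.histogram(allspk, bins=edges)[0] / (n * bin_s)
    if on_cnt + off_cnt == 0:
        return "none", float("nan"), psth, edges
    if on_cnt > polarity_ratio * off_cnt:
        polarity = "ON"
        step = (0.0, on_duration)
    elif off_cnt > polarity_ratio * on_cnt:
        polarity = "OFF"
        step = (on_duration, on_duration + off_duration)
    else:
        polarity = "ON_OFF"
        step = (0.0, on_duration) if on_cnt >= off_cnt else \
            (on_duration, on_duration + off_duration)
    sel = (edges[:-1] >= step[0]) & (edges[:-1] < step[1])
    step_psth = psth[sel]
    # peak from a lightly smoothed PSTH so binning ripple does not inflate
    # the transience of sustained responses
    smooth = np.convolve(step_psth, np.full(5, 0.2), mode="same")
    peak = smooth.max(initial=0.0)
    if peak <= 0:
        return polarity, float("nan"), psth, edges
    late = step_psth[len(step_psth) // 2:]
    ti = float(np.clip(1.0 - late.mean() / peak, 0.0, 1.0))
    return polarity, ti, psth, edges


# ---------------------------------------------------------------------------
# Grating direction selectivity
# ---------------------------------------------------------------------------

def grating_dsi(counts: np.ndarray, directions=None, ds_threshold: float = 0.3,
                alpha: float = 0.05, n_perm: int = 1000, seed=0):
    """Conventional-DSGC flag from 8-direction grating spike counts.

    ``counts`` is (8, R).  The index is the resultant length of the mean
    counts (same convention as the motion screen's NVS); a cell is flagged
    DS when the index exceeds ``ds_threshold`` AND a direction-label
    permutation test rejects at ``alpha``.  Zero total spikes yield a
    non-DS flag by convention.
    Returns (index, preferred_direction_deg, p, is_ds).
    """
    counts = np.asarray(counts, float)
    mean = counts.mean(axis=1)
    if mean.sum() <= 0:
        return 0.0, float("nan"), 1.0, False
    nvs, angle = normalized_vector_sum(mean, directions)
    p = permutation_test(counts, n_perm=n_perm, seed=seed,
                        directions=directions)
    return float(nvs), float(angle), float(p), bool(
        nvs > ds_threshold and p < alpha)


# ---------------------------------------------------------------------------
# Full per-cell RF estimation
# ---------------------------------------------------------------------------

def estimate_rf(spike_times, frames, frame_rate, xs, ys, onset=0.0,
                n_lags: int = 12, min_spikes: int = 300,
                frames_flat=None) -> ReceptiveField:
    """STA + Gaussian fit wrapped into a ReceptiveField (spatial part only;
    polarity / transience / DS flags are filled by the callers that have the
    full-field and grating responses)."""
    try:
        sta, peak_lag, nspk = compute_sta(spike_times, frames, frame_rate,
                                          onset=onset, n_lags=n_lags,
                                          min_spikes=min_spikes,
                                          frames_flat=frames_flat)
        center, sigma, r2, sign = fit_rf_gaussian(sta[peak_lag], xs, ys)
    except ValueError as e:
        return ReceptiveField(reliable=False, note=str(e))
    return ReceptiveField(center=center, sigma=sigma,
                          sta_peak_lag=peak_lag / frame_rate,
                          fit_quality=r2,
                          polarity="ON" if sign > 0 else "OFF",
                          reliable=True)


def with_typing(rf: ReceptiveField, polarity=None, transience_index=None,
                classical_ds=None, classical_pd=None) -> ReceptiveField:
    kw = {}
    if polarity is not None:
        kw["polarity"] = polarity
    if transience_index is not None:
        kw["transience_index"] = transience_index
    if classical_ds is not None:
        kw["classical_ds"] = classical_ds
    if classical_pd is not None:
        kw["classical_pd"] = classical_pd
    return replace(rf, **kw)
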