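"""Synthetic retina: a generative model of RGC spike trains under the full
stimulus battery (white-noise checkerboard, full-field spots, drifting
gratings, moving / masked / static bars), with ground-truth labels for every
mechanism the analysis pipeline must recover.

Model
-----
Each cell is an inhomogeneous-Poisson unit whose rate is

    rate(t) = max(0, baseline + center_drive(t) + g_desens(t) * az_drive(t)
                     - surround_drive(t))

* ``center_drive`` — the classical receptive field: Gaussian-weighted
  stimulus contrast at the RF center, passed through a first-order
  high-pass ("transience") filter with time constant ``transience_tau``
  (large tau = sustained), polarity-signed and rectified.
* ``az_drive`` — the asymmetric activation zone: Gaussian-weighted ON
  luminance at a point ``az_offset`` away from the RF center, in the
  direction opposite ``az_angle`` (so a bar moving along ``az_angle``
  crosses the zone *before* the RF; ``az_angle`` is the ground-truth PRE
  preferred direction).  For moving stimuli the drive is multiplied by
  ``az_ds_gain`` when the motion direction lies within +-90 deg of
  ``az_angle`` — the "inherent DS component".  The zone is driven only by
  wide coherent ON stimuli (bars, full-field); fine-grained checkerboards
  and gratings do not recruit it, mirroring the large-field requirement of
  the periphery effect.
* ``g_desens`` — gain suppression after strong classical-RF stimulation:
  g(t) = 1 - desens_strength * exp(-(t - t_last_strong)/desens_tau), where
  ``t_last_strong`` is the last time the center drive exceeded half its
  nominal peak (``center_gain / 2``).  The state persists across trials.

Bars are infinite strips perpendicular to their motion vector.  All spike
times are sampled by thinning and are reproducible per (seed, protocol,
trial, cell).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import ndtr

from .geometry import DIRECTIONS_DEG, RetinaGeometry, unit_vector

RATE_DT = 0.005          # rate-grid resolution for time-continuous stimuli, s
DEFAULT_BLANK = 2.0      # inter-trial blank, s (baseline is estimated here)
SWEEP_PAD = 50.0         # extra travel beyond the tissue edge, um


# ---------------------------------------------------------------------------
# Cell and protocol parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimCellParams:
    cell_id: str
    rf_center: tuple = (0.0, 0.0)
    rf_sigma: float = 70.0
    polarity: str = "ON"              # ON | OFF | ON_OFF
    transience_tau: float = 1.5       # s; large = sustained step response
    baseline_rate: float = 8.0        # spikes/s (sustained ON cells keep
                                      # a maintained discharge)
    center_gain: float = 60.0         # spikes/s at full RF occupancy
    surround_gain: float = 0.0        # antagonistic surround, off by default
    surround_sigma_factor: float = 2.0
    has_activation_zone: bool = False
    az_offset: float = 600.0          # um from rf_center to the zone center
    az_angle: float = 0.0             # deg; ground-truth PRE preferred dir
    az_sigma: float = 150.0
    az_gain: float = 24.0             # spikes/s at full zone occupancy
                                      # (3x the baseline by default)
    az_ds_gain: float = 1.0           # >=1; inherent DS multiplier
    desens_strength: float = 0.0      # in [0, 1]
    desens_tau: float = 1.0           # s
    classical_ds: bool = False
    classical_pd: float = 0.0
    classical_ds_gain: float = 8.0    # PD:ND evoked-gain ratio of a DSGC

    def __post_init__(self):
        if self.rf_sigma <= 0:
            raise ValueError("rf_sigma must be positive")
        if self.polarity not in ("ON", "OFF", "ON_OFF"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.has_activation_zone and self.az_offset <= self.rf_sigma:
            raise ValueError("activation zone must lie outside the classical "
                             "RF (az_offset > rf_sigma)")
        if self.az_ds_gain < 1:
            raise ValueError("az_ds_gain must be >= 1")
        if not (0.0 <= self.desens_strength <= 1.0):
            raise ValueError("desens_strength must lie in [0, 1]")
        for name in ("baseline_rate", "center_gain", "az_gain",
                     "surround_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.transience_tau <= 0 or self.desens_tau <= 0:
            raise ValueError("time constants must be positive")

    @property
    def az_center(self) -> np.ndarray:
        """Activation-zone center: az_offset away from the RF center, on the
        side the preferred-direction motion comes from."""
        return (np.asarray(self.rf_center, float)
                - self.az_offset * unit_vector(self.az_angle))

    @property
    def max_rate(self) -> float:
        return (self.baseline_rate + self.center_gain
                + self.az_gain * self.az_ds_gain)


@dataclass(frozen=True)
class MovingBarProtocol:
    kind: str = field(default="moving_bar", init=False)
    width: float = 900.0
    speed: float = 600.0
    directions: tuple = tuple(DIRECTIONS_DEG)
    n_repeats: int = 5
    blank: float = DEFAULT_BLANK
    masked: bool = False
    mask_width: float = 700.0

    def __post_init__(self):
        if self.speed <= 0 or self.width <= 0:
            raise ValueError("speed and width must be positive")
        if np.any(np.mod(self.directions, 45.0) != 0):
            raise ValueError("directions must be multiples of 45 deg")


@dataclass(frozen=True)
class StaticBarProtocol:
    """Flashed stationary bars.  Each bar is the strip
    |proj(x, axis_deg) - offset| <= width/2; the full (bar x repeat) list is
    presented in a seeded pseudorandom order."""
    kind: str = field(default="static_bar", init=False)
    bars: tuple = ()          # of (axis_deg, offset)
    width: float = 300.0
    duration: float = 0.5
    n_repeats: int = 4
    blank: float = DEFAULT_BLANK
    order_seed: int = 0
    #: explicit presentation order (indices into ``bars``); overrides the
    #: shuffled (bars x repeats) order when given — used for designed
    #: trial-history sequences
    sequence: tuple | None = None


@dataclass(frozen=True)
class FullFieldProtocol:
    kind: str = field(default="full_field", init=False)
    on_duration: float = 2.0
    off_duration: float = 2.0
    n_repeats: int = 5
    blank: float = DEFAULT_BLANK


@dataclass(frozen=True)
class GratingProtocol:
    kind: str = field(default="grating", init=False)
    spatial_period: float = 600.0
    temporal_freq: float = 2.0
    directions: tuple = tuple(DIRECTIONS_DEG)
    duration: float = 4.0
    n_repeats: int = 4
    blank: float = DEFAULT_BLANK


@dataclass(frozen=True)
class WhiteNoiseProtocol:
    kind: str = field(default="white_noise", init=False)
    checker: float = 50.0
    frame_rate: float = 60.0
    duration: float = 240.0
    extent: tuple = (-1000.0, 1000.0, -1000.0, 1000.0)  # x0, x1, y0, y1
    noise_seed: int = 1234
    blank: float = DEFAULT_BLANK

    def grid(self):
        x0, x1, y0, y1 = self.extent
        xs = np.arange(x0 + self.checker / 2, x1, self.checker)
        ys = np.arange(y0 + self.checker / 2, y1, self.checker)
        return xs, ys

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    def frames(self) -> np.ndarray:
        """Binary checker frames, shape (n_frames, ny, nx), regenerated
        deterministically from ``noise_seed``."""
        xs, ys = self.grid()
        rng = np.random.default_rng(self.noise_seed)
        return rng.integers(0, 2, size=(self.n_frames, ys.size, xs.size)
                            ).astype(np.uint8)


# ---------------------------------------------------------------------------
# Recording container
# ---------------------------------------------------------------------------

TRIAL_COLUMNS = ["trial_id", "protocol_id", "kind", "onset", "duration",
                 "blank", "direction", "speed", "width", "p0", "axis_deg",
                 "offset", "repeat", "masked"]


@dataclass
class SimRecording:
    """Spike-event table + stimulus log + geometry; the pipeline's input."""
    spikes: pd.DataFrame        # cell_id, protocol_id, trial_id, t_s
    trials: pd.DataFrame        # one row per trial, TRIAL_COLUMNS
    protocols: dict             # protocol_id -> protocol dataclass
    geometry: RetinaGeometry
    ground_truth: tuple | None = None

    def validate(self) -> "SimRecording":
        t = self.trials.set_index("trial_id")
        sp = self.spikes
        if len(sp):
            onset = t.loc[sp["trial_id"], "onset"].to_numpy()
            span = (t.loc[sp["trial_id"], "duration"].to_numpy()
                    + t.loc[sp["trial_id"], "blank"].to_numpy())
            ok = (sp["t_s"].to_numpy() >= onset) & \
                 (sp["t_s"].to_numpy() < onset + span)
            if not ok.all():
                bad = sp.index[~ok][:5].tolist()
                raise ValueError(f"spikes outside their trial span, rows {bad}")
        missing = set(sp["trial_id"].unique()) - set(t.index)
        if missing:
            raise ValueError(f"spike trials missing from log: {sorted(missing)[:5]}")
        return self

    def trials_of(self, protocol_id: int) -> pd.DataFrame:
        return self.trials[self.trials["protocol_id"] == protocol_id]

    def spikes_of(self, cell_id, protocol_id=None) -> pd.DataFrame:
        s = self.spikes[self.spikes["cell_id"] == cell_id]
        if protocol_id is not None:
            s = s[s["protocol_id"] == protocol_id]
        return s

    def protocol_id_of(self, kind: str, **attrs) -> int:
        """First protocol id of the given kind whose fields match attrs."""
        for pid, proto in self.protocols.items():
            if proto.kind == kind and all(
                    getattr(proto, k) == v for k, v in attrs.items()):
                return pid
        raise KeyError(f"no {kind} protocol matching {attrs}")

    @property
    def cell_ids(self):
        if self.ground_truth is not None:
            return [c.cell_id for c in self.ground_truth]
        return sorted(self.spikes["cell_id"].unique())


# ---------------------------------------------------------------------------
# Drive primitives
# ---------------------------------------------------------------------------

def _strip_weight(lo, hi, center: float, sigma: float):
    """Gaussian(center, sigma) mass inside the interval [lo, hi] along one
    axis — the RF occupancy of an infinite strip."""
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    return np.clip(ndtr((hi - center) / sigma) - ndtr((lo - center) / sigma),
                   0.0, None)


def _masked_strip_weight(trail, lead, center, sigma, mask):
    """Occupancy of the bar [trail, lead] with luminance forced to
    background inside the mask interval."""
    occ = _strip_weight(trail, lead, center, sigma)
    if mask is not None:
        m0, m1 = mask
        lo = np.maximum(trail, m0)
        hi = np.minimum(lead, m1)
        occ = occ - np.where(hi > lo, _strip_weight(lo, hi, center, sigma), 0.0)
    return np.clip(occ, 0.0, None)


def _highpass(x: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """First-order high-pass: unit gain at stimulus onset, exponential decay
    with time constant tau (a step input returns exp(-t/tau))."""
    a = np.exp(-dt / tau)
    low = lfilter([1.0 - a], [1.0, -a], x)
    return x - low


def _center_pathway(occ: np.ndarray, cell: SimCellParams, dt: float,
                    filtered: bool = True) -> np.ndarray:
    h = _highpass(occ, cell.transience_tau, dt) if filtered else occ
    if cell.polarity == "ON":
        path = np.clip(h, 0.0, None)
    elif cell.polarity == "OFF":
        path = np.clip(-h, 0.0, None)
    else:  # ON_OFF: both onset and offset responses
        path = np.abs(h)
    return cell.center_gain * path


def _ds_multiplier(cell: SimCellParams, direction_deg: float) -> float:
    """Inherent-DS gain of the activation zone: applied when the motion
    direction is within +-90 deg of az_angle (boundary inclusive)."""
    if np.cos(np.deg2rad(direction_deg - cell.az_angle)) >= -1e-12:
        return cell.az_ds_gain
    return 1.0


def _classical_ds_multiplier(cell: SimCellParams,
                             direction_deg: float) -> float:
    """Sharply tuned classical-DSGC gain: a cubed raised cosine reaching
    ``classical_ds_gain`` at the preferred direction and 1 at the null."""
    if not cell.classical_ds:
        return 1.0
    c = np.cos(np.deg2rad(direction_deg - cell.classical_pd))
    return 1.0 + (cell.classical_ds_gain - 1.0) * ((1.0 + c) / 2.0) ** 3


def _desens_gain(t: np.ndarray, strong: np.ndarray, cell: SimCellParams,
                 t_last_strong: float):
    """Desensitization gain on a time grid, given a boolean 'center drive
    above half-max' trace; returns (gain array, updated t_last_strong)."""
    if cell.desens_strength == 0.0:
        t_new = float(t[strong][-1]) if strong.any() else t_last_strong
        return np.ones_like(t), t_new
    marks = np.where(strong, t, -np.inf)
    last = np.maximum.accumulate(np.concatenate([[t_last_strong], marks]))[1:]
    g = 1.0 - cell.desens_strength * np.exp(
        -np.clip(t - last, 0.0, None) / cell.desens_tau)
    g[np.isinf(last)] = 1.0
    return g, float(last[-1])


def rate_model(cell: SimCellParams, t: np.ndarray, center_occ: np.ndarray,
               az_on_occ: np.ndarray, dt: float,
               motion_direction: float | None = None,
               surround_occ: np.ndarray | None = None,
               t_last_strong: float = -np.inf,
               filter_center: bool = True):
    """Instantaneous firing rate on a time grid.

    Parameters follow the model described in the module docstring;
    ``center_occ`` / ``az_on_occ`` are the Gaussian-weighted stimulus
    occupancies of the classical RF and the activation zone (ON luminance),
    ``motion_direction`` is the global motion direction in degrees or None
    for static stimuli.  Returns (rate array, updated desens state).
    """
    center = _center_pathway(center_occ, cell, dt, filtered=filter_center)
    if motion_direction is not None:
        center = center * _classical_ds_multiplier(cell, motion_direction)
    strong = center > 0.5 * cell.center_gain
    g, t_last = _desens_gain(t, strong, cell, t_last_strong)
    az = 0.0
    if cell.has_activation_zone and cell.az_gain > 0:
        mult = (_ds_multiplier(cell, motion_direction)
                if motion_direction is not None else 1.0)
        az = g * cell.az_gain * mult * az_on_occ
    rate = cell.baseline_rate + center + az
    if surround_occ is not None and cell.surround_gain > 0:
        rate = rate - cell.surround_gain * surround_occ
    return np.clip(rate, 0.0, None), t_last


# ---------------------------------------------------------------------------
# Spike sampling
# ---------------------------------------------------------------------------

def sample_spikes(rate, span: tuple[float, float], seed,
                  rate_max: float | None = None) -> np.ndarray:
    """Inhomogeneous-Poisson spike times on ``span`` by thinning.

    ``rate`` is either a callable t -> spikes/s (then ``rate_max`` is a
    required finite bound) or a pair (t_grid, rate_grid) interpreted as the
    linear interpolant.  Reproducible for a fixed seed.
    """
    t0, t1 = span
    if t1 <= t0:
        return np.empty(0)
    if callable(rate):
        if rate_max is None or not np.isfinite(rate_max):
            raise ValueError("a finite rate_max bound is required for a "
                             "callable rate")
        fn = rate
        rmax = float(rate_max)
    else:
        tg, rg = rate
        rg = np.asarray(rg, float)
        if not np.all(np.isfinite(rg)):
            raise ValueError("rate grid must be finite")
        rmax = float(rg.max(initial=0.0))
        fn = lambda ts: np.interp(ts, tg, rg)
    if rmax <= 0:
        return np.empty(0)
    rng = np.random.default_rng(seed)
    n = rng.poisson(rmax * (t1 - t0))
    if n == 0:
        return np.empty(0)
    ts = np.sort(rng.uniform(t0, t1, size=n))
    keep = rng.uniform(0.0, rmax, size=n) < fn(ts)
    return ts[keep]


# ---------------------------------------------------------------------------
# Per-trial occupancy + rate evaluation
# ---------------------------------------------------------------------------

def _bar_trial_rate(cell: SimCellParams, trial, proto, t_last_strong):
    """Rate grid for one moving-bar sweep (optionally masked)."""
    u = unit_vector(trial.direction)
    d_c = float(np.dot(cell.rf_center, u))
    d_az = float(np.dot(cell.az_center, u))
    t = np.arange(0.0, trial.duration + RATE_DT, RATE_DT)
    p = trial.p0 + trial.speed * t
    lead, trailv = p + trial.width / 2.0, p - trial.width / 2.0
    mask = None
    if trial.masked:
        mask = (d_c - proto.mask_width / 2.0, d_c + proto.mask_width / 2.0)
    occ_c = _masked_strip_weight(trailv, lead, d_c, cell.rf_sigma, mask)
    occ_az = _masked_strip_weight(trailv, lead, d_az, cell.az_sigma, mask)
    occ_s = None
    if cell.surround_gain > 0:
        occ_s = _masked_strip_weight(
            trailv, lead, d_c,
            cell.rf_sigma * cell.surround_sigma_factor, mask)
    rate, t_last = rate_model(
        cell, t + trial.onset, occ_c, occ_az, RATE_DT,
        motion_direction=trial.direction, surround_occ=occ_s,
        t_last_strong=t_last_strong)
    return t + trial.onset, rate, t_last


def _static_trial_rate(cell: SimCellParams, trial, proto, t_last_strong):
    u = unit_vector(trial.axis_deg)
    d_c = float(np.dot(cell.rf_center, u))
    d_az = float(np.dot(cell.az_center, u))
    lo, hi = trial.offset - trial.width / 2.0, trial.offset + trial.width / 2.0
    t = np.arange(0.0, trial.duration + RATE_DT, RATE_DT)
    on = (t <= trial.duration).astype(float)
    occ_c = float(_strip_weight(lo, hi, d_c, cell.rf_sigma)) * on
    occ_az = float(_strip_weight(lo, hi, d_az, cell.az_sigma)) * on
    rate, t_last = rate_model(cell, t + trial.onset, occ_c, occ_az, RATE_DT,
                              motion_direction=None,
                              t_last_strong=t_last_strong)
    return t + trial.onset, rate, t_last


def _full_field_trial_rate(cell: SimCellParams, trial, proto, t_last_strong):
    t = np.arange(0.0, trial.duration + RATE_DT, RATE_DT)
    on = (t < proto.on_duration).astype(float)
    rate, t_last = rate_model(cell, t + trial.onset, on, on, RATE_DT,
                              motion_direction=None,
                              t_last_strong=t_last_strong)
    return t + trial.onset, rate, t_last


def _grating_trial_rate(cell: SimCellParams, trial, proto, t_last_strong):
    u = unit_vector(trial.direction)
    d_c = float(np.dot(cell.rf_center, u))
    t = np.arange(0.0, trial.duration + RATE_DT, RATE_DT)
    lam = proto.spatial_period
    phase = 2.0 * np.pi * (proto.temporal_freq * t - d_c / lam)
    # spatial low-pass of the grating by the RF Gaussian (fundamental)
    att = np.exp(-2.0 * (np.pi * cell.rf_sigma / lam) ** 2)
    contrast = 0.5 * att * np.sign(np.sin(phase))
    # the activation zone is not recruited by fine periodic patterns
    rate, t_last = rate_model(cell, t + trial.onset, contrast + 0.5,
                              np.zeros_like(t), RATE_DT,
                              motion_direction=trial.direction,
                              t_last_strong=t_last_strong)
    return t + trial.onset, rate, t_last


_TRIAL_RATE = {
    "moving_bar": _bar_trial_rate,
    "static_bar": _static_trial_rate,
    "full_field": _full_field_trial_rate,
    "grating": _grating_trial_rate,
}


def _white_noise_rates(cells, proto: WhiteNoiseProtocol, onset: float):
    """Piecewise-constant rate per frame for all cells at once."""
    xs, ys = proto.grid()
    frames = proto.frames().astype(np.float32)
    contrast = frames.reshape(frames.shape[0], -1) - 0.5  # (T, npix)
    gx, gy = np.meshgrid(xs, ys)  # (ny, nx)
    rates = []
    dt = 1.0 / proto.frame_rate
    for cell in cells:
        cx, cy = cell.rf_center
        w = np.exp(-((gx - cx) ** 2 + (gy - cy) ** 2)
                   / (2.0 * cell.rf_sigma ** 2)).ravel()
        s = (w / w.sum()).astype(np.float32)
        # normalized contrast signal in [-1, 1]
        drive = (contrast @ s).astype(float) * 2.0
        rate, _ = rate_model(cell, onset + np.arange(len(drive)) * dt,
                             drive + 0.0, np.zeros_like(drive), dt,
                             motion_direction=None, filter_center=True)
        rates.append(rate)
    return np.array(rates), dt


# ---------------------------------------------------------------------------
# Protocol simulation
# ---------------------------------------------------------------------------

def _build_trials(proto, geometry: RetinaGeometry, start: float,
                  protocol_id: int, trial_id0: int, rng) -> pd.DataFrame:
    rows = []
    t = start
    tid = trial_id0

    def row(**kw):
        base = dict(trial_id=kw.pop("trial_id"), protocol_id=protocol_id,
                    kind=proto.kind, onset=kw.pop("onset"),
                    duration=kw.pop("duration"), blank=proto.blank,
                    direction=np.nan, speed=np.nan, width=np.nan, p0=np.nan,
                    axis_deg=np.nan, offset=np.nan, repeat=kw.pop("repeat"),
                    masked=False)
        base.update(kw)
        return base

    if proto.kind == "moving_bar":
        half_span = geometry.bounding_radius() + SWEEP_PAD
        p0 = -(half_span + proto.width / 2.0)
        duration = (2.0 * half_span + proto.width) / proto.speed
        for rep in range(proto.n_repeats):
            dirs = rng.permutation(proto.directions)
            for d in dirs:
                rows.append(row(trial_id=tid, onset=t, duration=duration,
                                direction=float(d), speed=proto.speed,
                                width=proto.width, p0=p0, repeat=rep,
                                masked=proto.masked))
                t += duration + proto.blank
                tid += 1
    elif proto.kind == "static_bar":
        if proto.sequence is not None:
            combos = [proto.bars[i] + (k,) for k, i in
                      enumerate(proto.sequence)]
            order = range(len(combos))
        else:
            combos = [(axis, off, rep) for rep in range(proto.n_repeats)
                      for axis, off in proto.bars]
            order = np.random.default_rng(proto.order_seed).permutation(
                len(combos))
        for k in order:
            axis, off, rep = combos[k]
            rows.append(row(trial_id=tid, onset=t, duration=proto.duration,
                            axis_deg=float(axis), offset=float(off),
                            width=proto.width, repeat=rep))
            t += proto.duration + proto.blank
            tid += 1
    elif proto.kind == "full_field":
        duration = proto.on_duration + proto.off_duration
        for rep in range(proto.n_repeats):
            rows.append(row(trial_id=tid, onset=t, duration=duration,
                            repeat=rep))
            t += duration + proto.blank
            tid += 1
    elif proto.kind == "grating":
        for rep in range(proto.n_repeats):
            dirs = rng.permutation(proto.directions)
            for d in dirs:
                rows.append(row(trial_id=tid, onset=t,
                                duration=proto.duration, direction=float(d),
                                repeat=rep))
                t += proto.duration + proto.blank
                tid += 1
    elif proto.kind == "white_noise":
        rows.append(row(trial_id=tid, onset=t, duration=proto.duration,
                        repeat=0))
        t += proto.duration + proto.blank
        tid += 1
    else:
        raise ValueError(f"unknown protocol kind {proto.kind!r}")
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def simulate_protocol(population, proto, geometry: RetinaGeometry, seed: int,
                      protocol_id: int = 0, trial_id0: int = 0,
                      start_time: float = 0.0,
                      history: dict | None = None) -> SimRecording:
    """Simulate one stimulus protocol for a cell population.

    Returns a :class:`SimRecording` whose trials are separated by the
    protocol's inter-trial blank (spikes during blanks are emitted at the
    baseline rate and used downstream for baseline estimation).
    Desensitization state is carried across trials in chronological order
    (and across protocols when a shared ``history`` dict is passed).
    """
    population = list(population)
    if not population:
        raise ValueError("population must be non-empty")
    rng = np.random.default_rng([seed, protocol_id])
    trials = _build_trials(proto, geometry, start_time, protocol_id,
                           trial_id0, rng)
    history = history if history is not None else {}
    all_cells, all_tids, all_times = [], [], []

    if proto.kind == "white_noise":
        trial = trials.iloc[0]
        rates, dt = _white_noise_rates(population, proto, trial.onset)
        tg = trial.onset + np.arange(rates.shape[1]) * dt
        for ci, cell in enumerate(population):
            s_rng = [seed, protocol_id, int(trial.trial_id), ci]
            st = sample_spikes((tg, rates[ci]),
                               (trial.onset, trial.onset + trial.duration),
                               s_rng)
            bl = _blank_spikes(cell, trial, [seed, protocol_id,
                                             int(trial.trial_id), ci, 1])
            times = np.concatenate([st, bl])
            all_cells += [cell.cell_id] * len(times)
            all_tids += [int(trial.trial_id)] * len(times)
            all_times.append(times)
    else:
        rate_fn = _TRIAL_RATE[proto.kind]
        for ci, cell in enumerate(population):
            t_last = history.get(cell.cell_id, -np.inf)
            for trial in trials.itertuples(index=False):
                tg, rate, t_last = rate_fn(cell, trial, proto, t_last)
                st = sample_spikes(
                    (tg, rate), (trial.onset, trial.onset + trial.duration),
                    [seed, protocol_id, int(trial.trial_id), ci])
                bl = _blank_spikes(cell, trial,
                                   [seed, protocol_id, int(trial.trial_id),
                                    ci, 1])
                times = np.concatenate([st, bl])
                all_cells += [cell.cell_id] * len(times)
                all_tids += [int(trial.trial_id)] * len(times)
                all_times.append(times)
            history[cell.cell_id] = t_last

    times = (np.concatenate(all_times) if all_times else np.empty(0))
    spikes = pd.DataFrame({
        "cell_id": pd.Series(all_cells, dtype=object),
        "protocol_id": protocol_id,
        "trial_id": pd.Series(all_tids, dtype=np.int64),
        "t_s": times,
    }).sort_values(["cell_id", "t_s"], kind="stable").reset_index(drop=True)
    return SimRecording(spikes=spikes, trials=trials,
                        protocols={protocol_id: proto}, geometry=geometry,
                        ground_truth=tuple(population)).validate()


def _blank_spikes(cell: SimCellParams, trial, seed_key) -> np.ndarray:
    """Baseline-rate Poisson spikes in the trial's trailing blank."""
    t0 = trial.onset + trial.duration
    return sample_spikes(lambda ts: np.full(np.shape(ts), cell.baseline_rate),
                         (t0, t0 + trial.blank), seed_key,
                         rate_max=max(cell.baseline_rate, 1e-9))


def simulate_session(population, protocols, geometry: RetinaGeometry,
                     seed: int) -> SimRecording:
    """Run several protocols back to back into one recording; protocol ids
    follow list order and time advances across them."""
    recs = []
    t, tid0 = 0.0, 0
    history: dict = {}
    for pid, proto in enumerate(protocols):
        rec = simulate_protocol(population, proto, geometry, seed,
                                protocol_id=pid, trial_id0=tid0,
                                start_time=t, history=history)
        recs.append(rec)
        t = float(rec.trials["onset"].iloc[-1] + rec.trials["duration"].iloc[-1]
                  + rec.trials["blank"].iloc[-1])
        tid0 = int(rec.trials["trial_id"].max()) + 1
    spikes = pd.concat([r.spikes for r in recs], ignore_index=True)
    trials = pd.concat([r.trials for r in recs], ignore_index=True)
    protos = {}
    for r in recs:
        protos.update(r.protocols)
    return SimRecording(spikes=spikes, trials=trials, protocols=protos,
                        geometry=geometry,
                        ground_truth=tuple(population)).validate()


# ---------------------------------------------------------------------------
# Population factories
# ---------------------------------------------------------------------------

def make_population(n: int, seed: int, geometry: RetinaGeometry | None = None,
                    frac_az: float = 0.0, az_angle: str | float = "random",
                    scatter: float = 150.0, center=(0.0, 0.0),
                    **overrides) -> list[SimCellParams]:
    """Build ``n`` model cells with RF centers scattered around ``center``.

    ``az_angle`` may be a fixed angle in degrees, "random" (uniform), or
    "centripetal" (each zone points from the cell toward the optic disc,
    i.e., the preferred direction aims at the disc).  The first
    ``round(frac_az * n)`` cells carry an activation zone.
    """
    rng = np.random.default_rng(seed)
    cells = []
    n_az = int(round(frac_az * n))
    disc = np.asarray(geometry.optic_disc, float) if geometry is not None \
        else np.zeros(2)
    for i in range(n):
        pos = np.asarray(center, float) + rng.uniform(-scatter, scatter, 2)
        has_az = i < n_az
        if isinstance(az_angle, str) and az_angle == "random":
            ang = float(rng.uniform(0.0, 360.0))
        elif isinstance(az_angle, str) and az_angle == "centripetal":
            v = disc - pos
            ang = float(np.mod(np.rad2deg(np.arctan2(v[1], v[0])), 360.0))
        else:
            ang = float(az_angle)
        cells.append(SimCellParams(
            cell_id=f"c{i:04d}", rf_center=tuple(pos),
            has_activation_zone=has_az, az_angle=ang, **overrides))
    return cells
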