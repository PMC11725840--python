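"""Circular statistics for direction data.

Angles are degrees in [0, 360) at the API surface and radians internally.
All null distributions are Monte-Carlo or permutation based (seeded), so
p-values carry no table-interpolation error and remain valid at the small
sample sizes typical of per-retina cell populations.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "circular_difference",
    "mean_resultant",
    "rao_spacing_test",
    "kuiper_two_sample",
    "mean_angle_one_sample_test",
    "circular_medians_multisample_test",
    "circular_median",
]


def _wrap360(a):
    return np.mod(a, 360.0)


def circular_difference(a_deg, b_deg):
    """Signed circular difference a - b in (-180, 180] degrees."""
    d = np.mod(np.asarray(a_deg, float) - np.asarray(b_deg, float), 360.0)
    d = np.where(d > 180.0, d - 360.0, d)
    return d if np.ndim(d) else float(d)


@dataclass(frozen=True)
class ResultantSummary:
    mean_deg: float          # nan when the resultant vanishes
    resultant_length: float  # R in [0, 1]
    angular_deviation_deg: float  # sqrt(2 (1 - R)), reported in degrees
    defined: bool


def mean_resultant(angles_deg, weights=None) -> ResultantSummary:
    """First trigonometric moment: mean angle, resultant length R, and the
    standard angular deviation sqrt(2(1-R))."""
    a = np.deg2rad(np.asarray(angles_deg, float))
    if a.size < 1:
        raise ValueError("need at least one angle")
    if weights is None:
        w = np.ones_like(a)
    else:
        w = np.asarray(weights, float)
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
    z = np.sum(w * np.exp(1j * a)) / np.sum(w)
    r = float(np.abs(z))
    dev = float(np.rad2deg(np.sqrt(max(0.0, 2.0 * (1.0 - r)))))
    if r < 1e-12:
        return ResultantSummary(float("nan"), 0.0, dev, False)
    return ResultantSummary(float(_wrap360(np.rad2deg(np.angle(z)))), r, dev,
                            True)


# ---------------------------------------------------------------------------
# Rao spacing test of circular uniformity
# ---------------------------------------------------------------------------

def _rao_u(angles_deg: np.ndarray) -> float:
    """U = 1/2 sum |T_i - 360/n| over the n sorted circular gaps T_i."""
    a = np.sort(_wrap360(angles_deg))
    n = a.size
    gaps = np.diff(a, append=a[0] + 360.0)
    return float(0.5 * np.sum(np.abs(gaps - 360.0 / n)))


def rao_spacing_test(angles_deg, n_mc: int = 2000, seed=0):
    """Rao spacing test of uniformity with a Monte-Carlo null.

    Returns (U in degrees, p).  U = 0 for perfectly equispaced angles and
    grows as the sample clusters; p is estimated from ``n_mc`` uniform
    samples of the same size.
    """
    a = np.asarray(angles_deg, float)
    if a.size < 4:
        raise ValueError("Rao spacing test needs n >= 4")
    u_obs = _rao_u(a)
    rng = np.random.default_rng(seed)
    sims = rng.uniform(0.0, 360.0, size=(n_mc, a.size))
    sims.sort(axis=1)
    gaps = np.diff(sims, axis=1)
    last = 360.0 - sims[:, -1] + sims[:, 0]
    u_mc = 0.5 * (np.sum(np.abs(gaps - 360.0 / a.size), axis=1)
                  + np.abs(last - 360.0 / a.size))
    p = (1.0 + np.count_nonzero(u_mc >= u_obs - 1e-12)) / (1.0 + n_mc)
    return u_obs, float(p)


# ---------------------------------------------------------------------------
# Kuiper two-sample test
# ---------------------------------------------------------------------------

def _kuiper_v(steps: np.ndarray) -> np.ndarray:
    """V = max D - min D of the cumulative ECDF difference.

    ``steps`` holds, per row, the ECDF jump of (F_a - F_b) at each pooled
    point in sorted order; taking max minus min of the running sum makes the
    statistic invariant to the choice of circular origin."""
    d = np.cumsum(steps, axis=-1)
    return d.max(axis=-1) - np.minimum(d.min(axis=-1), 0.0)


def kuiper_two_sample(a_deg, b_deg, n_perm: int = 999, seed=0):
    """Kuiper two-sample test for circular samples, permutation p-value.

    V sums the largest positive and negative deviations between the two
    circular ECDFs, which makes it sensitive at every part of the circle
    and invariant to rotation of the origin.  Ties are handled by
    aggregating ECDF jumps at identical values (right-continuous ECDF).
    """
    a = _wrap360(np.asarray(a_deg, float))
    b = _wrap360(np.asarray(b_deg, float))
    na, nb = a.size, b.size
    if na < 5 or nb < 5:
        raise ValueError("both samples need n >= 5")
    pooled = np.concatenate([a, b])
    labels = np.concatenate([np.ones(na), np.zeros(nb)])  # 1 = sample a
    order = np.argsort(pooled, kind="stable")
    pooled_sorted = pooled[order]
    # aggregate jumps at tied values so the ECDFs are right-continuous
    uniq, inv = np.unique(pooled_sorted, return_inverse=True)

    def v_of(lab_sorted):
        step = np.where(lab_sorted, 1.0 / na, -1.0 / nb)
        if lab_sorted.ndim == 1:
            agg = np.bincount(inv, weights=step, minlength=uniq.size)
            return float(_kuiper_v(agg[None, :])[0])
        agg = np.zeros((lab_sorted.shape[0], uniq.size))
        np.add.at(agg, (np.arange(lab_sorted.shape[0])[:, None],
                        inv[None, :]), step)
        return _kuiper_v(agg)

    v_obs = v_of(labels[order].astype(bool))
    rng = np.random.default_rng(seed)
    perm_labels = rng.permuted(
        np.tile(labels[order].astype(bool), (n_perm, 1)), axis=1)
    v_perm = v_of(perm_labels)
    p = (1.0 + np.count_nonzero(v_perm >= v_obs - 1e-12)) / (1.0 + n_perm)
    return v_obs, float(p)


# ---------------------------------------------------------------------------
# One-sample test for the mean angle (bootstrap CI)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeanAngleTest:
    mean_deg: float
    ci_low_deg: float    # absolute angles bounding the 1-alpha CI
    ci_high_deg: float
    hypothesized_deg: float
    distance_deg: float  # signed circular distance mean - hypothesis
    reject: bool
    p: float
    defined: bool


def mean_angle_one_sample_test(angles_deg, hypothesized_deg,
                               n_boot: int = 10_000, alpha: float = 0.05,
                               seed=0) -> MeanAngleTest:
    """Bootstrap test of whether the population mean angle equals a given
    value: resample the sample, form the percentile CI of the mean angle,
    and reject when the hypothesized angle falls outside it."""
    a = np.asarray(angles_deg, float)
    if a.size < 5:
        raise ValueError("need n >= 5")
    obs = mean_resultant(a)
    if not obs.defined or obs.resultant_length < 1e-6:
        return MeanAngleTest(float("nan"), float("nan"), float("nan"),
                             float(hypothesized_deg), float("nan"), False,
                             float("nan"), False)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, a.size, size=(n_boot, a.size))
    z = np.exp(1j * np.deg2rad(a[idx])).mean(axis=1)
    boot_means = np.rad2deg(np.angle(z))
    deltas = circular_difference(boot_means, obs.mean_deg)
    lo, hi = np.percentile(deltas, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    d_hyp = circular_difference(hypothesized_deg, obs.mean_deg)
    reject = not (lo <= d_hyp <= hi)
    # two-sided percentile p: how deep the hypothesized angle sits in the
    # bootstrap distribution of the mean
    frac_ge = np.mean(deltas >= d_hyp)
    frac_le = np.mean(deltas <= d_hyp)
    p = float(min(1.0, 2.0 * min(frac_ge, frac_le)))
    return MeanAngleTest(obs.mean_deg, _wrap360(obs.mean_deg + lo),
                         _wrap360(obs.mean_deg + hi),
                         float(hypothesized_deg),
                         float(circular_difference(obs.mean_deg,
                                                   hypothesized_deg)),
                         bool(reject), p, True)


# ---------------------------------------------------------------------------
# Common-median multisample test
# ---------------------------------------------------------------------------

def circular_median(angles_deg) -> float:
    """Angle minimizing the mean circular arc distance to the sample;
    candidates are the data points themselves and their antipodes."""
    a = _wrap360(np.asarray(angles_deg, float))
    cand = _wrap360(np.concatenate([a, a + 180.0]))
    d = np.abs(circular_difference(a[None, :], cand[:, None]))
    cost = d.sum(axis=1)
    return float(cand[np.argmin(cost)])


def circular_medians_multisample_test(samples, n_perm: int = 999, seed=0):
    """Fisher's common-median test for >= 2 circular samples with a
    permutation p-value.

    Counts, per sample, the angles lying in the half-circle (m, m + 180]
    around the pooled circular median m and forms the chi-square-type
    statistic; the permutation null shuffles sample labels (the pooled
    median is label-invariant, so only the counts change).
    """
    samples = [np.asarray(s, float) for s in samples]
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    if any(s.size < 5 for s in samples):
        raise ValueError("each sample needs n >= 5")
    sizes = np.array([s.size for s in samples])
    pooled = np.concatenate(samples)
    n_total = pooled.size
    m = circular_median(pooled)
    # indicator: angle in the half-circle clockwise of the pooled median
    z = (circular_difference(pooled, m) > 0).astype(float)
    m_total = z.sum()
    if m_total == 0 or m_total == n_total:
        return 0.0, 1.0  # degenerate: all points on one side of the median
    labels = np.repeat(np.arange(len(samples)), sizes)

    def stat(zv, lab):
        mi = np.bincount(lab, weights=zv, minlength=len(samples))
        term = np.sum(mi ** 2 / sizes)
        return (n_total ** 2 / (m_total * (n_total - m_total))) * term \
            - n_total * m_total / (n_total - m_total)

    obs = stat(z, labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        count += stat(z, rng.permutation(labels)) >= obs - 1e-12
    p = (1.0 + count) / (1.0 + n_perm)
    return float(obs), float(p)
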