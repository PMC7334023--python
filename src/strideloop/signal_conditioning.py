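"""Raw-channel conditioning: calibration, artifact repair, smoothing,
fractional length, velocity and EMG band-pass.

The fascicle-length trace from sonomicrometry occasionally drops out or
jumps by a level shift; both are repaired before a cubic smoothing spline
is fitted.  Length is then normalized by the bird's mean level-terrain
length L_o (dimensionless fractional length L), and differentiated to
fascicle velocity V in lengths per second, with shortening negative.
Tendon-buckle voltages are converted to Newtons by an ordinary
least-squares calibration against known applied loads.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, signal, stats

from .recordings_io import TrialMeta, ValidationError


class CalibrationWarning(UserWarning):
    pass


@dataclass
class BuckleCalibration:
    """Linear force calibration of an 'E'-type tendon buckle."""

    slope: float        # N per volt
    intercept: float    # N
    r_squared: float

    def apply(self, volts: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(volts, float) + self.intercept

    def acceptable(self, r2_threshold: float = 0.97) -> bool:
        return self.r_squared > r2_threshold


def calibrate_force(raw_volts, applied_loads, r2_threshold: float = 0.97,
                    strict: bool = False) -> BuckleCalibration:
    """OLS fit of applied load (N) against buckle output (V).

    Flags the calibration (warning, or error when ``strict``) if the
    coefficient of determination does not exceed ``r2_threshold``.
    """
    v = np.asarray(raw_volts, float)
    n = np.asarray(applied_loads, float)
    if v.size < 3 or v.size != n.size:
        raise ValidationError("need >= 3 paired calibration points")
    if np.ptp(v) == 0 or np.ptp(n) == 0:
        raise ValidationError("degenerate calibration: constant input")
    res = stats.linregress(v, n)
    r2 = res.rvalue ** 2
    cal = BuckleCalibration(float(res.slope), float(res.intercept), float(r2))
    if not cal.acceptable(r2_threshold):
        msg = f"calibration R^2={r2:.4f} <= {r2_threshold}"
        if strict:
            raise ValidationError(msg)
        warnings.warn(msg, CalibrationWarning)
    return cal


# ---------------------------------------------------------------------------
# dropout / level-shift repair

def repair_dropouts(raw_length, gap_limit: int = 100,
                    jump_mad_factor: float = 6.0, min_jump_frac: float = 0.02):
    """Repair NaN dropouts and level-shift artifacts in a length trace.

    NaN runs no longer than ``gap_limit`` samples are filled with a local
    cubic spline through neighbouring valid samples.  Longer gaps are left
    as NaN and reported in the returned boolean mask so that strides
    overlapping them can be excluded rather than silently filled.

    Level shifts are single-sample discontinuities: a first difference
    that departs from the local running-median slope by more than
    ``jump_mad_factor`` robust SDs *and* by more than ``min_jump_frac`` of
    the signal range (so steep but smooth physiological segments never
    trigger).  Each shift is removed by offsetting the shorter side of the
    jump.

    Returns ``(repaired, bad_mask)``.
    """
    x = np.asarray(raw_length, float).copy()
    if x.size == 0 or np.all(np.isnan(x)):
        raise ValidationError("all-NaN input")
    bad = np.zeros(x.size, dtype=bool)

    isnan = np.isnan(x)
    if isnan.any():
        edges = np.flatnonzero(np.diff(np.concatenate(([False], isnan, [False])).astype(int)))
        for start, stop in zip(edges[::2], edges[1::2]):
            if stop - start <= gap_limit:
                x[start:stop] = _local_spline_fill(x, start, stop)
            else:
                bad[start:stop] = True

    valid = ~np.isnan(x)
    if valid.sum() >= 5:
        xv = x[valid]
        d = np.diff(xv)
        local = signal.medfilt(d, kernel_size=9)
        resid = d - local
        sigma = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        floor = min_jump_frac * np.ptp(xv)
        thr = max(jump_mad_factor * sigma, floor)
        jumps = np.flatnonzero(np.abs(resid) > thr)
        idx_valid = np.flatnonzero(valid)
        for j in jumps:
            step = resid[j]
            pos = idx_valid[j]  # jump between pos and next valid sample
            if pos + 1 <= x.size - (pos + 1):  # left side shorter
                x[: pos + 1] += step
            else:
                x[pos + 1:] -= step
    return x, bad


def _local_spline_fill(x, start, stop, context: int = 8):
    valid = np.flatnonzero(~np.isnan(x))
    left = valid[valid < start][-context:]
    right = valid[valid >= stop][:context]
    support = np.concatenate([left, right])
    if support.size < 2:
        return np.full(stop - start, np.nan)
    k = min(3, support.size - 1)
    spl = interpolate.InterpolatedUnivariateSpline(support, x[support], k=k)
    return spl(np.arange(start, stop))


# ---------------------------------------------------------------------------
# smoothing spline

def smooth_length(raw_length, tolerance: float = 0.1, t=None) -> np.ndarray:
    """Cubic smoothing spline with a residual-sum-of-squares bound.

    Returns the smoothest natural cubic smoothing spline whose summed
    squared residuals do not exceed ``tolerance`` (mm^2 for a trace in
    mm); 0 yields the interpolant.  The roughness penalty is bisected (the
    RSS is monotone in the penalty) until the bound is met, so a larger
    tolerance never yields a rougher curve.
    """
    y = np.asarray(raw_length, float)
    if y.size < 4:
        raise ValidationError("need >= 4 samples to fit a cubic smoothing spline")
    if np.isnan(y).any():
        raise ValidationError("smooth_length requires finite samples; repair gaps first")
    if tolerance < 0:
        raise ValidationError("tolerance must be >= 0")
    if tolerance == 0:
        return y.copy()
    x = np.arange(y.size, dtype=float) if t is None else np.asarray(t, float)

    def rss(lam):
        spl = interpolate.make_smoothing_spline(x, y, lam=lam)
        out = spl(x)
        return float(np.sum((y - out) ** 2)), out

    lo, hi = 1e-12, 1.0
    r_hi, out_hi = rss(hi)
    while r_hi < tolerance and hi < 1e15:
        hi *= 100.0
        r_hi, out_hi = rss(hi)
    if r_hi <= tolerance:
        return out_hi  # even maximal smoothing meets the bound
    r_lo, out_lo = rss(lo)
    if r_lo > tolerance:
        return y.copy()  # bound tighter than achievable: interpolate
    for _ in range(30):
        mid = np.sqrt(lo * hi)
        r_mid, out_mid = rss(mid)
        if r_mid <= tolerance:
            lo, r_lo, out_lo = mid, r_mid, out_mid
        else:
            hi = mid
        # the bound, not an exact RSS, is the contract: stop once close
        if hi / lo < 1.05 or r_lo > 0.95 * tolerance:
            break
    return out_lo


def auto_spline_tolerance(y: np.ndarray) -> float:
    """RSS bound ``n * sigma^2`` with a robust noise estimate.

    Sigma comes from the median absolute second difference (scaled by
    sqrt(6) for white noise), which is insensitive to the smooth waveform
    itself; a noise-free trace therefore yields a near-interpolating
    spline.
    """
    y = np.asarray(y, float)
    d2 = np.diff(y[~np.isnan(y)], 2)
    sigma = 1.4826 * np.median(np.abs(d2)) / np.sqrt(6.0)
    return float(y.size * sigma ** 2)


def roughness(y: np.ndarray, dt: float) -> float:
    """Integrated squared second derivative (smoothness measure)."""
    d2 = np.diff(y, 2) / dt ** 2
    return float(np.sum(d2 ** 2) * dt)


# ---------------------------------------------------------------------------
# fractional length / velocity / EMG

def fractional_length(smoothed_mm, reference_mask=None, L_o: float | None = None):
    """Normalize a length trace by the mean level-terrain length L_o.

    ``reference_mask`` selects the samples belonging to the bird's level
    reference strides.  Alternatively a known ``L_o`` can be supplied (for
    obstacle-terrain trials of a bird whose reference was computed from its
    level trials).  Returns ``(L, L_o)``.
    """
    y = np.asarray(smoothed_mm, float)
    if L_o is None:
        if reference_mask is None:
            raise ValidationError(
                "no level reference strides available: provide L_o explicitly "
                "(e.g. from the bird's level trial or trial metadata)")
        ref = y[np.asarray(reference_mask, bool)]
        if ref.size == 0:
            raise ValidationError("reference_mask selects no samples")
        L_o = float(np.mean(ref))
    if L_o <= 0:
        raise ValidationError("L_o must be > 0")
    return y / L_o, float(L_o)


def differentiate(L, dt: float) -> np.ndarray:
    """Fascicle velocity dL/dt (lengths/s); shortening is negative.

    Central differences in the interior, second-order one-sided at the ends.
    """
    L = np.asarray(L, float)
    if L.size < 3:
        raise ValidationError("need >= 3 samples to differentiate")
    return np.gradient(L, dt)


def condition_emg(raw_emg, fs: float, band=(10.0, 1000.0), rectify: bool = True):
    """Zero-phase band-pass then (optionally) full-wave rectify raw EMG.

    The hardware chain has already applied a 10 Hz – 3 kHz analogue filter;
    the digital band defaults to 10–1000 Hz and must sit below Nyquist.
    """
    lo, hi = band
    if lo >= hi:
        raise ValidationError(f"band edges inverted: {band}")
    if fs <= 2 * hi:
        raise ValidationError(f"sample rate {fs} Hz must exceed 2x the upper band edge {hi} Hz")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, np.asarray(raw_emg, float))
    return np.abs(y) if rectify else y


# ---------------------------------------------------------------------------
# conditioned-trial container

@dataclass
class ConditionedTrial:
    """Calibrated, smoothed, physiologically scaled traces for one trial."""

    L: np.ndarray               # fractional fascicle length (L / L_o)
    V: np.ndarray               # fascicle velocity, lengths/s (shortening < 0)
    F: np.ndarray               # tendon force, N
    emg_band: np.ndarray        # band-passed EMG (signed), mV
    emg_rect: np.ndarray        # full-wave rectified EMG, mV
    L_o_mm: float
    sample_rate_hz: float
    foot_contact: np.ndarray
    obstacle_contact: np.ndarray
    meta: TrialMeta
    toe_off: np.ndarray | None = None
    bad_mask: np.ndarray | None = None
    extras: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate_hz

    def time(self) -> np.ndarray:
        return np.arange(self.L.size) / self.sample_rate_hz


def condition_trial(trial, config: dict | None = None, L_o: float | None = None,
                    calibration: BuckleCalibration | None = None) -> ConditionedTrial:
    """Run the conditioning chain on one trial.

    For a level-terrain trial with no ``L_o`` given, the reference length is
    the mean smoothed length between the first and last foot contact (an
    integer number of strides).  Obstacle trials require ``L_o`` from the
    same bird's level recordings.
    """
    from .recordings_io import DEFAULTS, _deep_merge
    cfg = _deep_merge(DEFAULTS, config or {})
    cc = cfg["conditioning"]

    fs = trial.sample_rate_hz
    raw_len = trial.channels["fascicle_length"]
    repaired, bad = repair_dropouts(raw_len, gap_limit=cc["gap_limit"],
                                    jump_mad_factor=cc["jump_mad_factor"],
                                    min_jump_frac=cc["min_jump_frac"])
    fill = np.where(np.isnan(repaired), np.nanmean(repaired), repaired)
    tol = cc["spline_tolerance"]
    tol = auto_spline_tolerance(fill) if tol == "auto" else float(tol)
    smoothed = smooth_length(fill, tolerance=tol)

    if L_o is None:
        if trial.meta.terrain != "level":
            if trial.meta.reference_length_mm is not None:
                L_o = trial.meta.reference_length_mm
            else:
                raise ValidationError(
                    "obstacle trial needs L_o from the bird's level trials")
        else:
            i0 = int(round(trial.foot_contact[0] * fs))
            i1 = int(round(trial.foot_contact[-1] * fs))
            mask = np.zeros(smoothed.size, bool)
            mask[i0:i1] = True
            _, L_o = fractional_length(smoothed, reference_mask=mask)
    L, L_o = fractional_length(smoothed, L_o=L_o)
    V = differentiate(L, 1.0 / fs)

    force = trial.channels["tendon_force"]
    if calibration is not None:
        force = calibration.apply(force)

    lo, hi = cc["emg_band_hz"]
    hi = min(hi, 0.45 * fs)  # keep the digital edge below Nyquist
    emg_band = condition_emg(trial.channels["emg"], fs, band=(lo, hi), rectify=False)

    return ConditionedTrial(
        L=L, V=V, F=np.asarray(force, float), emg_band=emg_band,
        emg_rect=np.abs(emg_band), L_o_mm=L_o, sample_rate_hz=fs,
        foot_contact=trial.foot_contact, obstacle_contact=trial.obstacle_contact,
        meta=trial.meta, toe_off=trial.toe_off, bad_mask=bad,
    )
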