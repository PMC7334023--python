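"""Synthetic stride-cycle cohorts with known ground truth.

The generator emulates the statistical structure of in vivo treadmill
recordings of an ankle extensor during level and obstacle running: a cyclic
fascicle-length trajectory with a swing-phase stretch to a single peak
followed by rapid shortening, a unimodal stance force pulse rising quickly
to a peak before midstance, and an EMG burst placed at a configurable phase
relative to the swing peak length.  Obstacle-contact strides have earlier
foot contact (default 10% of the cycle), a higher force amplitude and a
prescribed extra mass-specific work; obstacles recur every
``obstacle_every`` strides.  Each individual receives random offsets of its
work level and force amplitude, and every channel carries additive Gaussian
sensor noise.

The stance shortening depth of each stride is solved (the work integral is
affine in the depth) so that the noise-free trapezoidal work of the stride
equals its prescribed target exactly; the ground-truth table therefore
doubles as an independent oracle for the downstream pipeline.

All randomness flows from a single seed: the same spec and seed reproduce
the output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd
from scipy import signal

from .recordings_io import TrialMeta, TrialRecording, ValidationError

# template phase landmarks (fractions of the stride cycle, which runs from
# mid-swing to mid-swing)
PHI_PEAK_LENGTH = 0.20      # swing-phase length peak
PHI_CONTACT_LEVEL = 0.35    # foot contact, level terrain
S_PEAK = 1.10               # peak fractional length of the template
S_CONTACT = 1.03            # fractional length at foot contact
FORCE_LEAD = 0.06           # force onset precedes contact by this fraction
FORCE_PEAK_POS = 0.4        # force peak position within stance (before midstance)
BURST_RAMP = 0.02           # cosine ramp width of the EMG burst envelope


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    Defaults reflect the study conditions being emulated: six individuals
    per cohort, obstacles roughly every five strides, running stride period
    0.4 s, an obstacle work increment of 3.6 J/kg and an EMG burst spanning
    29% of the cycle starting at the swing-phase length peak.
    """

    n_individuals: int = 6
    strides_per_trial: int = 16
    obstacle_every: int = 5
    stride_period_s: float = 0.4
    sample_rate_hz: float = 10000.0
    cohort_label: str = "intact"
    emg_onset_phase: float = 0.0        # burst onset relative to peak length (= true E_phase)
    emg_duration_frac: float = 0.29
    work_level_Jkg: float = 2.0
    work_obstacle_delta_Jkg: float = 3.6
    force_peak_N: float = 25.0
    noise_sd: float = 0.002             # per-channel relative noise
    individual_sd: float = 0.3          # between-individual SD of work level, J/kg
    seed: int = 0
    # secondary knobs (defaults are part of the emulated conditions)
    reference_length_mm: float = 17.0
    muscle_mass_g: float = 10.7
    speed_ms: float = 1.7
    contact_shift: float = 0.10         # obstacle contact earlier by this cycle fraction
    force_obstacle_factor: float = 1.2
    force_individual_rel_sd: float = 0.05
    emg_amp_mV: float = 0.5
    emg_obstacle_factor: float = 1.3
    emg_carrier_band_hz: tuple = (80.0, 250.0)
    emg_onset_sd: float = 0.002         # between-individual SD of burst onset phase

    def validate(self) -> None:
        positive = ["n_individuals", "strides_per_trial", "obstacle_every",
                    "stride_period_s", "sample_rate_hz", "force_peak_N",
                    "reference_length_mm", "muscle_mass_g"]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if not 0 <= self.emg_onset_phase < 1:
            raise ValidationError("emg_onset_phase must satisfy 0 <= phase < 1")
        if not 0 < self.emg_duration_frac < 1:
            raise ValidationError("emg_duration_frac must lie in (0, 1)")
        if self.emg_duration_frac < BURST_RAMP:
            raise ValidationError("emg_duration_frac shorter than the burst ramp")
        if self.noise_sd < 0 or self.individual_sd < 0:
            raise ValidationError("noise_sd and individual_sd must be >= 0")
        if self.cohort_label not in ("intact", "reinnervated"):
            raise ValidationError("cohort_label must be 'intact' or 'reinnervated'")
        if not 0 <= self.contact_shift < PHI_CONTACT_LEVEL:
            raise ValidationError("contact_shift must be in [0, contact phase)")
        lo, hi = self.emg_carrier_band_hz
        if not 0 < lo < hi < 0.5 * self.sample_rate_hz:
            raise ValidationError("emg_carrier_band_hz must fit below Nyquist")


@dataclass
class GroundTruth:
    """Per-stride true values for every generated (non-padding) stride."""

    table: pd.DataFrame
    L_o_mm: dict = field(default_factory=dict)   # bird_id -> reference length
    spec: CohortSpec | None = None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# trajectory templates

def _length_shape(phi, phi_c, phi_to, depth):
    """Fractional-length template: unit value and zero slope at the cycle
    boundaries, single swing maximum S_PEAK at PHI_PEAK_LENGTH, near-
    isometric early stance, stance shortening of the given depth."""
    phi = np.asarray(phi, float)
    s = np.empty_like(phi)
    s_min = S_CONTACT - depth
    m = phi < PHI_PEAK_LENGTH
    s[m] = 1.0 + (S_PEAK - 1.0) * 0.5 * (1 - np.cos(np.pi * phi[m] / PHI_PEAK_LENGTH))
    m = (phi >= PHI_PEAK_LENGTH) & (phi < phi_c)
    u = (phi[m] - PHI_PEAK_LENGTH) / (phi_c - PHI_PEAK_LENGTH)
    s[m] = S_PEAK - (S_PEAK - S_CONTACT) * 0.5 * (1 - np.cos(np.pi * u))
    m = (phi >= phi_c) & (phi < phi_to)
    u = (phi[m] - phi_c) / (phi_to - phi_c)
    s[m] = S_CONTACT - depth * 0.5 * (1 - np.cos(np.pi * u))
    m = phi >= phi_to
    u = (phi[m] - phi_to) / (1.0 - phi_to)
    s[m] = s_min + (1.0 - s_min) * 0.5 * (1 - np.cos(np.pi * u))
    return s


def _force_shape(phi, phi_c, phi_to):
    """Unit-amplitude force template: zero in mid-swing, rapid rise from
    just before contact to a peak before midstance, slower decline to
    toe-off."""
    phi = np.asarray(phi, float)
    f0 = max(phi_c - FORCE_LEAD, PHI_PEAK_LENGTH)
    fpk = phi_c + FORCE_PEAK_POS * (phi_to - phi_c)
    F = np.zeros_like(phi)
    m = (phi >= f0) & (phi < fpk)
    F[m] = 0.5 * (1 - np.cos(np.pi * (phi[m] - f0) / (fpk - f0)))
    m = (phi >= fpk) & (phi < phi_to)
    F[m] = 0.5 * (1 + np.cos(np.pi * (phi[m] - fpk) / (phi_to - fpk)))
    return F


def _burst_envelope(phi, onset, duration, ramp=BURST_RAMP):
    """Plateau envelope with cosine ramps centered on onset and offset, so
    the envelope crosses one half exactly at the nominal burst edges."""
    phi = np.asarray(phi, float)
    rel = (phi - (onset - ramp / 2.0)) % 1.0
    env = np.zeros_like(phi)
    m = rel < ramp
    env[m] = 0.5 * (1 - np.cos(np.pi * rel[m] / ramp))
    m = (rel >= ramp) & (rel < duration)
    env[m] = 1.0
    m = (rel >= duration) & (rel < duration + ramp)
    env[m] = 0.5 * (1 + np.cos(np.pi * (rel[m] - duration) / ramp))
    return env


def _work_of(depth, phi, phi_c, phi_to, F_amp, L0_mm, dt, mass_g):
    s = _length_shape(phi, phi_c, phi_to, depth)
    F = F_amp * _force_shape(phi, phi_c, phi_to)
    v = np.gradient(s * L0_mm, dt) / 1000.0
    return float(np.trapezoid(-F * v, dx=dt) / (mass_g / 1000.0))


def _solve_depth(target_Jkg, phi, phi_c, phi_to, F_amp, L0_mm, dt, mass_g):
    """Stance depth such that the stride's trapezoidal work equals the
    target; the work integral is affine in depth."""
    d0, d1 = 0.05, 0.15
    w0 = _work_of(d0, phi, phi_c, phi_to, F_amp, L0_mm, dt, mass_g)
    w1 = _work_of(d1, phi, phi_c, phi_to, F_amp, L0_mm, dt, mass_g)
    slope = (w1 - w0) / (d1 - d0)
    depth = d0 + (target_Jkg - w0) / slope
    if not 0.0 < depth < S_CONTACT - 0.5:
        raise ValidationError(
            f"work target {target_Jkg:.3g} J/kg needs stance depth {depth:.3g} "
            "outside the physiological template range; adjust work/force levels")
    return float(depth)


def stride_template(phase_grid, spec: CohortSpec):
    """Level-stride template on an arbitrary monotone phase grid in [0, 1).

    Returns ``(length, force, envelope)``: fractional fascicle length
    (L/L0), tendon force in N (peak ``force_peak_N``, stance depth solved
    for ``work_level_Jkg``) and the unit EMG burst envelope.
    """
    phi = np.asarray(phase_grid, float)
    if phi.size < 2 or np.any(np.diff(phi) <= 0):
        raise ValidationError("phase_grid must be strictly increasing")
    if phi[0] < 0 or phi[-1] >= 1:
        raise ValidationError("phase_grid must lie in [0, 1)")
    spec.validate()
    phi_c = PHI_CONTACT_LEVEL
    phi_to = 1.0 - PHI_CONTACT_LEVEL
    dt = spec.stride_period_s * (phi[1] - phi[0]) if phi.size > 1 else spec.stride_period_s
    depth = _solve_depth(spec.work_level_Jkg, phi, phi_c, phi_to,
                         spec.force_peak_N, spec.reference_length_mm, dt,
                         spec.muscle_mass_g)
    length = _length_shape(phi, phi_c, phi_to, depth)
    force = spec.force_peak_N * _force_shape(phi, phi_c, phi_to)
    onset = (PHI_PEAK_LENGTH + spec.emg_onset_phase) % 1.0
    env = _burst_envelope(phi, onset, spec.emg_duration_frac)
    return length, force, env


# ---------------------------------------------------------------------------
# cohort generation

def generate_cohort(spec: CohortSpec):
    """Generate one cohort of trials (one level + one obstacle trial per
    individual) with ground truth.

    Each trial carries one padding stride at either end so that downstream
    mid-swing segmentation recovers exactly ``strides_per_trial`` cycles
    matching the ground-truth rows one for one.  Returns
    ``(trials, ground_truth)``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    trials: list[TrialRecording] = []
    rows: list[dict] = []
    L_o_map: dict[str, float] = {}

    for i in range(spec.n_individuals):
        bird = f"{spec.cohort_label[:1]}{i + 1:02d}"
        work_offset = rng.normal(0.0, spec.individual_sd)
        force_factor = 1.0 + rng.normal(0.0, spec.force_individual_rel_sd)
        onset_jitter = rng.normal(0.0, spec.emg_onset_sd)
        for terrain in ("level", "obstacle"):
            trial, trial_rows = _generate_trial(
                spec, rng, bird, terrain, work_offset, force_factor, onset_jitter)
            trials.append(trial)
            rows.extend(trial_rows)

    gt = pd.DataFrame(rows)
    # reference length per bird: mean noise-free level-terrain length between
    # the first and last contact (an integer number of strides); obstacle
    # rows inherit the bird's level-terrain L_o
    for bird, sub in gt.groupby("bird_id"):
        L_o_map[bird] = float(sub["L_o_mm"].dropna().iloc[0])
    gt["L_o_mm"] = gt["bird_id"].map(L_o_map)
    gt["L_pkF"] = gt["L_pkF_mm"] / gt["L_o_mm"]
    gt["V_pkF"] = gt["V_pkF_mm_s"] / gt["L_o_mm"]
    return trials, GroundTruth(table=gt, L_o_mm=L_o_map, spec=spec)


def _generate_trial(spec: CohortSpec, rng, bird: str, terrain: str,
                    work_offset: float, force_factor: float, onset_jitter: float):
    T = spec.stride_period_s
    fs = spec.sample_rate_hz
    S = spec.strides_per_trial
    n_strides = S + 2                      # one padding stride at each end
    core = range(1, S + 1)

    flags = np.zeros(n_strides, dtype=bool)
    if terrain == "obstacle":
        for k in range(S):
            if (k + 1) % spec.obstacle_every == 0:
                flags[k + 1] = True

    phi_c = np.full(n_strides, PHI_CONTACT_LEVEL)
    phi_c[flags] = PHI_CONTACT_LEVEL - spec.contact_shift
    # toe-off placed so the toe-off/next-contact midpoint is exactly the
    # nominal stride boundary
    phi_to = np.empty(n_strides)
    phi_to[:-1] = 1.0 - phi_c[1:]
    phi_to[-1] = 1.0 - PHI_CONTACT_LEVEL

    n_total = int(round(n_strides * T * fs))
    length_mm = np.empty(n_total)
    force_N = np.zeros(n_total)
    env = np.zeros(n_total)
    onset_phase = (PHI_PEAK_LENGTH + spec.emg_onset_phase + onset_jitter) % 1.0

    depth_cache: dict[tuple, float] = {}
    stride_info = []
    for k in range(n_strides):
        i0 = int(round(k * T * fs))
        i1 = int(round((k + 1) * T * fs))
        t_local = np.arange(i0, i1) / fs - k * T
        phi = t_local / T
        F_amp = spec.force_peak_N * force_factor
        w_target = spec.work_level_Jkg + work_offset
        if flags[k]:
            F_amp *= spec.force_obstacle_factor
            w_target += spec.work_obstacle_delta_Jkg
        key = (round(phi_c[k], 9), round(phi_to[k], 9), round(F_amp, 9),
               round(w_target, 9), i1 - i0)
        if key not in depth_cache:
            depth_cache[key] = _solve_depth(w_target, phi, phi_c[k], phi_to[k],
                                            F_amp, spec.reference_length_mm,
                                            1.0 / fs, spec.muscle_mass_g)
        depth = depth_cache[key]
        length_mm[i0:i1] = spec.reference_length_mm * _length_shape(
            phi, phi_c[k], phi_to[k], depth)
        force_N[i0:i1] = F_amp * _force_shape(phi, phi_c[k], phi_to[k])
        amp = spec.emg_amp_mV * (spec.emg_obstacle_factor if flags[k] else 1.0)
        env[i0:i1] = amp * _burst_envelope(phi, onset_phase, spec.emg_duration_frac)
        stride_info.append((k, i0, i1, phi_c[k], phi_to[k], depth, F_amp, w_target))

    carrier = _bandlimited_noise(rng, n_total, fs, spec.emg_carrier_band_hz)
    emg_clean = env * carrier

    contacts = (np.arange(n_strides) + phi_c) * T
    toe_offs = (np.arange(n_strides) + phi_to) * T

    # ground truth comes from the noise-free traces
    gt_L_o = float(np.mean(length_mm[int(round(contacts[0] * fs)):
                                     int(round(contacts[-1] * fs))])) \
        if terrain == "level" else np.nan

    trial_id = f"{bird}_{'lev' if terrain == 'level' else 'obs'}"
    rows = []
    for (k, i0, i1, pc, pto, depth, F_amp, w_target) in stride_info:
        if k == 0 or k == n_strides - 1:
            continue  # padding strides carry no ground truth
        rows.append(_ground_truth_row(
            spec, bird, trial_id, terrain, k, i0, i1, pc, fs, T,
            length_mm, force_N, emg_clean, onset_phase, bool(flags[k]),
            flags, w_target))

    # additive sensor noise, scaled per channel
    noisy_len = length_mm + rng.normal(0.0, spec.noise_sd * spec.reference_length_mm, n_total)
    noisy_force = force_N + rng.normal(0.0, spec.noise_sd * spec.force_peak_N, n_total)
    noisy_emg = emg_clean + rng.normal(0.0, spec.noise_sd * spec.emg_amp_mV, n_total)

    meta = TrialMeta(bird_id=bird, cohort=spec.cohort_label, terrain=terrain,
                     speed_ms=spec.speed_ms, muscle_mass_g=spec.muscle_mass_g,
                     trial_id=trial_id)
    trial = TrialRecording(
        channels={"fascicle_length": noisy_len, "tendon_force": noisy_force,
                  "emg": noisy_emg},
        sample_rate_hz=fs, foot_contact=contacts, obstacle_contact=flags,
        meta=meta, toe_off=toe_offs)
    return trial, [dict(r, L_o_mm=gt_L_o) for r in rows]


def _ground_truth_row(spec, bird, trial_id, terrain, k, i0, i1, phi_c, fs, T,
                      length_mm, force_N, emg_clean, onset_phase, flagged,
                      flags, w_target):
    dt = 1.0 / fs
    Lmm = length_mm[i0:i1]
    F = force_N[i0:i1]
    v = np.gradient(Lmm, dt) / 1000.0
    W = float(np.trapezoid(-F * v, dx=dt) / (spec.muscle_mass_g / 1000.0))
    ipk = int(np.argmax(F))
    f_pk = float(F[ipk])
    t_force = float(np.count_nonzero(F > 0.05 * f_pk) / F.size) if f_pk > 0 else 0.0
    e_tot = float(np.trapezoid(emg_clean[i0:i1] ** 2, dx=dt))
    category = _true_category(flags, k, terrain)
    return {
        "bird_id": bird, "trial_id": trial_id, "stride_index": k - 1,
        "terrain": terrain, "category": category, "obstacle": flagged,
        "t_start": i0 / fs, "t_end": i1 / fs,
        "t_contact": (k + phi_c) * T, "contact_phase": phi_c,
        "T_stride": (i1 - i0) / fs,
        "W_net": W, "F_pk": f_pk,
        "L_pkF_mm": float(Lmm[ipk]),
        "V_pkF_mm_s": float(np.gradient(Lmm, dt)[ipk]),
        "T_force": t_force, "E_tot": e_tot,
        "E_phase": float((onset_phase - PHI_PEAK_LENGTH + 0.5) % 1.0 - 0.5),
        "E_dur": spec.emg_duration_frac,
        "emg_onset_time": i0 / fs + onset_phase * T,
        "emg_offset_time": i0 / fs + ((onset_phase + spec.emg_duration_frac) % 1.0) * T,
        "W_target": w_target,
    }


def _true_category(flags, k, terrain) -> str:
    """Category by construction (independent of the pipeline's coder)."""
    if terrain == "level":
        return "L"
    if flags[k]:
        return "S0"
    if k + 1 < flags.size and flags[k + 1]:
        return "S-1"
    if k - 1 >= 0 and flags[k - 1]:
        return "S+1"
    return "S+2"


def _bandlimited_noise(rng, n, fs, band):
    """Unit-RMS band-limited noise carrier with an equalized envelope.

    Gaussian noise is band-pass filtered and then divided by its own
    smoothed Hilbert envelope, yielding a constant-modulus carrier with the
    prescribed spectral band.  The equalization makes the per-stride
    intensity follow the burst envelope deterministically, so ground-truth
    burst timing is identifiable from a single stride; the spectral
    content that E_freq measures is unchanged.
    """
    from scipy.ndimage import gaussian_filter1d

    lo, hi = band
    white = rng.standard_normal(n)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, white)
    env = np.abs(signal.hilbert(x))
    env = gaussian_filter1d(env, max(1.0, 0.002 * fs))
    rms = x.std()
    if rms == 0:
        return x
    x = x / np.maximum(env, 0.05 * rms)
    return x / x.std()


# ---------------------------------------------------------------------------
# metric-level simulator for the statistics layer

def simulate_metric_table(n_per_cohort: int = 6, strides_level: int = 20,
                          strides_obstacle: int = 5, treatment_effect: float = 0.0,
                          category_effects: dict | None = None,
                          interaction_effects: dict | None = None,
                          resid_sd: float = 1.0, ind_sd: float = 0.5,
                          seed: int = 0, response: str = "y") -> pd.DataFrame:
    """Simulate a balanced per-stride metric table from the additive model
    underlying the mixed-effects analysis (random individual intercepts,
    treatment and stride-category fixed effects, Gaussian residuals).

    ``category_effects`` maps category -> shift applied in both cohorts;
    ``interaction_effects`` maps (cohort, category) -> extra shift.  Used
    for null and power simulations of the statistics layer at stride-table
    level, without the signal pipeline.
    """
    rng = np.random.default_rng(seed)
    category_effects = category_effects or {}
    interaction_effects = interaction_effects or {}
    rows = []
    for cohort_idx, cohort in enumerate(("intact", "reinnervated")):
        for i in range(n_per_cohort):
            ind = f"{cohort[:1]}{i + 1:02d}"
            u = rng.normal(0.0, ind_sd)
            for cat in ("L", "S-1", "S0", "S+1", "S+2"):
                n = strides_level if cat == "L" else strides_obstacle
                mu = (u + treatment_effect * (cohort_idx == 1)
                      + category_effects.get(cat, 0.0)
                      + interaction_effects.get((cohort, cat), 0.0))
                y = mu + rng.normal(0.0, resid_sd, n)
                for val in y:
                    rows.append({"ind": ind, "treatment": cohort,
                                 "stride_id": cat, response: val})
    return pd.DataFrame(rows)
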