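"""End-to-end orchestration: raw trials -> conditioned traces -> stride
cycles -> per-stride metric table -> statistics.

The reference length L_o of each bird is computed from its level-terrain
trials and shared with its obstacle trials, matching the definition of
fractional length.  Wavelet intensity is computed once per trial at full
rate; the per-stride totals (E_tot, E_freq) integrate it over the stride's
time window, while burst timing works on the phase-resampled total
intensity of each cycle.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import emg_wavelet, mixed_model_stats, signal_conditioning, stride_metrics, \
    stride_segmentation
from .recordings_io import DEFAULTS, METRIC_COLUMNS, _deep_merge
from .signal_conditioning import ConditionedTrial

logger = logging.getLogger("strideloop")


def bird_reference_length(trials, config: dict | None = None) -> dict:
    """L_o per bird from the level-terrain trials (mean smoothed length
    between first and last contact, pooled over level trials)."""
    cfg = _deep_merge(DEFAULTS, config or {})
    sums: dict[str, tuple[float, int]] = {}
    for trial in trials:
        if trial.meta.terrain != "level":
            continue
        ct = signal_conditioning.condition_trial(trial, config=cfg)
        # recover the mean in mm from the conditioned fractional trace
        fs = ct.sample_rate_hz
        i0 = int(round(ct.foot_contact[0] * fs))
        i1 = int(round(ct.foot_contact[-1] * fs))
        seg = ct.L[i0:i1] * ct.L_o_mm
        s, n = sums.get(trial.meta.bird_id, (0.0, 0))
        sums[trial.meta.bird_id] = (s + float(seg.sum()), n + seg.size)
    return {bird: s / n for bird, (s, n) in sums.items()}


def process_trial(trial, L_o: float | None = None, config: dict | None = None):
    """Condition one trial and cut it into categorized stride cycles.

    Returns ``(cycles, conditioned, spectrum)``; each cycle carries an
    ``intensity`` channel with the resampled total myoelectric intensity.
    """
    cfg = _deep_merge(DEFAULTS, config or {})
    ct = signal_conditioning.condition_trial(trial, config=cfg, L_o=L_o)
    bank = emg_wavelet.FilterBank.default(cfg["emg"]["n_bands"])
    spectrum = emg_wavelet.wavelet_intensity(ct.emg_band, ct.sample_rate_hz, bank=bank)
    ct.extras["intensity"] = spectrum.total_intensity
    cycles = stride_segmentation.cut_strides(ct, n_points=cfg["segmentation"]["n_points"])
    stride_segmentation.assign_categories(cycles, trial.obstacle_contact,
                                          terrain=trial.meta.terrain)
    return cycles, ct, spectrum


def metrics_row(cycle, spectrum, config: dict | None = None) -> dict:
    """Assemble every per-stride metric for one cycle."""
    cfg = _deep_merge(DEFAULTS, config or {})
    row = {
        "bird_id": cycle.bird_id, "trial_id": cycle.trial_id,
        "stride_index": cycle.stride_index, "cohort": cycle.cohort,
        "terrain": cycle.terrain, "category": cycle.category,
        "contact_phase": cycle.contact_phase,
    }
    row.update(stride_metrics.mechanical_metrics(
        cycle, threshold_frac=cfg["metrics"]["force_threshold_frac"]))

    fs = spectrum.sample_rate_hz
    i0 = int(round(cycle.t_start * fs))
    i1 = int(round(cycle.t_end * fs))
    e_tot, e_freq = emg_wavelet.emg_totals(spectrum, (i0, i1))
    row["E_tot"] = e_tot
    row["E_freq"] = np.nan if e_freq is None else e_freq

    ec = cfg["emg"]
    onset, offset, e_dur = emg_wavelet.detect_burst(
        cycle.channels["intensity"], cycle.phase,
        baseline_window=tuple(ec["baseline_window"]),
        k=ec["burst_k"], rel_floor=ec["burst_rel_floor"],
        smooth_frac=ec["burst_smooth_frac"])
    row["E_dur"] = e_dur
    row["emg_onset_phase"] = np.nan if onset is None else onset
    peak_phase = emg_wavelet.swing_peak_phase(cycle.channels["L"], cycle.phase,
                                              contact_phase=cycle.contact_phase)
    row["peak_length_phase"] = peak_phase
    e_phase = emg_wavelet.compute_phase(onset, peak_phase)
    row["E_phase"] = np.nan if e_phase is None else e_phase
    row["ankle_contact_angle"] = np.nan  # optional pre-computed passthrough
    return row


def build_stride_table(trials, config: dict | None = None,
                       ankle_angles: pd.DataFrame | None = None):
    """Process a list of trials into a stride table plus the cut cycles.

    ``ankle_angles`` may supply a pre-computed per-stride ankle angle at
    contact (columns bird_id, trial_id, stride_index, ankle_contact_angle)
    that flows through to the statistics layer.
    """
    cfg = _deep_merge(DEFAULTS, config or {})
    L_o_map = bird_reference_length(trials, config=cfg)
    rows, all_cycles = [], []
    for trial in trials:
        L_o = L_o_map.get(trial.meta.bird_id)
        cycles, _, spectrum = process_trial(trial, L_o=L_o, config=cfg)
        for c in cycles:
            rows.append(metrics_row(c, spectrum, config=cfg))
        all_cycles.extend(cycles)
    table = pd.DataFrame(rows)
    table = stride_segmentation.exclude_outliers(
        table, z_threshold=cfg["segmentation"]["z_threshold"])
    if ankle_angles is not None:
        keys = ["bird_id", "trial_id", "stride_index"]
        table = table.drop(columns=["ankle_contact_angle"]).merge(
            ankle_angles[keys + ["ankle_contact_angle"]], on=keys, how="left")
    logger.info("stride table: %d strides, %d flagged as outliers",
                len(table), int(table["outlier"].sum()))
    return table, all_cycles


def analyze(table: pd.DataFrame, responses=None, q: float = 0.05):
    """Statistics layer over a stride table (see mixed_model_stats)."""
    responses = responses or [c for c in METRIC_COLUMNS if c in table.columns
                              and table[c].notna().sum() > 0]
    return mixed_model_stats.analyze_metrics(table, responses, q=q)
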