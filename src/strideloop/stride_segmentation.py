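"""Stride-cycle segmentation, obstacle-relative category coding and the
outlier-exclusion rule.

Trials are cut into cycles running from mid-swing to mid-swing.  Mid-swing
is the temporal midpoint between a toe-off and the next foot contact; when
toe-off events are absent, the swing-phase peak-length instant preceding
each contact serves as the boundary (documented fallback).  Each cycle is
resampled onto a fixed phase grid.

Strides in obstacle terrain are coded relative to obstacle encounters of
the instrumented leg: S0 for the contact stride, S-1/S+1 for the strides
immediately before/after, S+2 for all other obstacle-terrain strides; all
level-terrain strides are L.  A stride adjacent to two obstacles (both
S+1 of one and S-1 of the next) takes the anticipatory S-1 label.

Outlier exclusion flags non-obstacle-encounter strides whose metrics have
|Z| above a threshold (default 4) within (cohort x category) groups;
obstacle-encounter strides (S0) are never flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recordings_io import METRIC_COLUMNS, ValidationError
from .signal_conditioning import ConditionedTrial

import logging

logger = logging.getLogger("strideloop")


@dataclass
class StrideCycle:
    """One stride's phase-resampled trajectories with category code."""

    bird_id: str
    trial_id: str
    stride_index: int
    contact_index: int
    t_start: float
    t_end: float
    t_contact: float
    phase: np.ndarray
    channels: dict[str, np.ndarray]
    category: str | None = None
    cohort: str = "intact"
    terrain: str = "level"
    L_o_mm: float = np.nan
    muscle_mass_g: float = np.nan

    @property
    def T_stride(self) -> float:
        return self.t_end - self.t_start

    @property
    def contact_phase(self) -> float:
        return (self.t_contact - self.t_start) / self.T_stride

    def validate(self) -> None:
        if not (self.t_start < self.t_contact < self.t_end):
            raise ValidationError("contact must fall strictly inside the cycle")


def cut_strides(ct: ConditionedTrial, n_points: int = 200,
                extra_channels: dict | None = None) -> list[StrideCycle]:
    """Cut a conditioned trial into mid-swing-to-mid-swing stride cycles.

    Boundaries use toe-off/contact midpoints when toe-off events exist,
    otherwise the swing peak-length instant between consecutive contacts.
    Each cycle is resampled to ``n_points`` phase-uniform samples.  Cycles
    overlapping flagged bad-gap regions are excluded (with a logged
    reason).
    """
    contacts = np.asarray(ct.foot_contact, float)
    if contacts.size < 3:
        raise ValidationError("need >= 3 foot-contact events to cut strides")
    if np.any(np.diff(contacts) <= 0):
        raise ValidationError("unordered foot-contact events")

    t = ct.time()
    channels = {"L": ct.L, "F": ct.F, "emg": ct.emg_rect}
    channels.update(ct.extras)
    if extra_channels:
        channels.update(extra_channels)

    boundaries = _cycle_boundaries(ct, contacts)

    cycles: list[StrideCycle] = []
    phase = np.arange(n_points) / n_points
    for j in range(1, contacts.size - 1):
        t0, t1 = boundaries[j - 1], boundaries[j]
        if not (t0 < contacts[j] < t1):
            logger.warning("%s: contact %d not inside its cycle, skipped", ct.meta.trial_id, j)
            continue
        if ct.bad_mask is not None and ct.bad_mask.any():
            i0, i1 = int(t0 * ct.sample_rate_hz), int(np.ceil(t1 * ct.sample_rate_hz))
            if ct.bad_mask[i0:i1].any():
                logger.info("%s: stride at contact %d overlaps an unrepaired gap, excluded",
                            ct.meta.trial_id, j)
                continue
        ts = t0 + phase * (t1 - t0)
        resampled = {name: np.interp(ts, t, x) for name, x in channels.items()}
        cyc = StrideCycle(
            bird_id=ct.meta.bird_id, trial_id=ct.meta.trial_id,
            stride_index=len(cycles), contact_index=j,
            t_start=float(t0), t_end=float(t1), t_contact=float(contacts[j]),
            phase=phase.copy(), channels=resampled,
            cohort=ct.meta.cohort, terrain=ct.meta.terrain,
            L_o_mm=ct.L_o_mm, muscle_mass_g=ct.meta.muscle_mass_g,
        )
        cyc.validate()
        cycles.append(cyc)
    return cycles


def _cycle_boundaries(ct: ConditionedTrial, contacts: np.ndarray) -> np.ndarray:
    """One boundary per consecutive contact pair (mid-swing instants)."""
    n = contacts.size
    bounds = np.empty(n - 1)
    toe = ct.toe_off
    t = ct.time()
    for j in range(n - 1):
        lo, hi = contacts[j], contacts[j + 1]
        b = None
        if toe is not None:
            in_swing = toe[(toe > lo) & (toe < hi)]
            if in_swing.size:
                b = 0.5 * (in_swing[-1] + hi)
        if b is None:
            # fallback: swing-phase peak-length instant preceding the contact
            m = (t > lo) & (t < hi)
            seg = np.flatnonzero(m)
            b = t[seg[np.argmax(ct.L[seg])]]
        bounds[j] = b
    return bounds


# ---------------------------------------------------------------------------
# category coding

def categorize_flags(obstacle_flags, terrain: str = "obstacle",
                     tie_break: str = "S-1") -> list[str]:
    """Obstacle-relative category code for each stride in a flag sequence.

    Level-terrain trials are all L.  In obstacle terrain the flagged
    strides are S0, their immediate neighbours S-1/S+1, everything else
    S+2.  A stride qualifying as both S+1 and S-1 takes the ``tie_break``
    label (default the anticipatory S-1).
    """
    flags = np.asarray(obstacle_flags, bool)
    if terrain == "level":
        if flags.any():
            raise ValidationError("level-terrain trial has obstacle flags set")
        return ["L"] * flags.size
    cats = np.array(["S+2"] * flags.size, dtype=object)
    s0 = np.flatnonzero(flags)
    for i in s0:
        if i + 1 < flags.size and not flags[i + 1]:
            cats[i + 1] = "S+1"
    for i in s0:
        if i - 1 >= 0 and not flags[i - 1]:
            # a stride that is both after one obstacle and before the next
            cats[i - 1] = tie_break if cats[i - 1] == "S+1" else "S-1"
    cats[s0] = "S0"
    return list(cats)


def assign_categories(cycles: list[StrideCycle], obstacle_flags,
                      terrain: str | None = None, tie_break: str = "S-1") -> list[StrideCycle]:
    """Assign stride categories to cut cycles.

    ``obstacle_flags`` has one flag per foot contact of the trial (the same
    vector the recording carries); each cycle looks up the category of its
    own contact.
    """
    flags = np.asarray(obstacle_flags, bool)
    if cycles and max(c.contact_index for c in cycles) >= flags.size:
        raise ValidationError(
            f"flag count {flags.size} does not cover contact indices of the cycles")
    terrain = terrain if terrain is not None else (cycles[0].terrain if cycles else "level")
    cats = categorize_flags(flags, terrain=terrain, tie_break=tie_break)
    for c in cycles:
        c.category = cats[c.contact_index]
    return cycles


# ---------------------------------------------------------------------------
# outlier rule

def exclude_outliers(table: pd.DataFrame, z_threshold: float = 4.0,
                     metrics: list[str] | None = None,
                     group_cols=("cohort", "category")) -> pd.DataFrame:
    """Flag non-obstacle-encounter strides with any metric |Z| > threshold.

    Z-scores are computed within (cohort x category) groups over all
    available stride-metric columns (any-exceeds rule).  Obstacle-encounter
    strides (S0) are never flagged.  Groups with fewer than 3 strides are
    skipped.  Returns a copy of the table with a boolean ``outlier``
    column.
    """
    out = table.copy()
    metrics = metrics or [c for c in METRIC_COLUMNS if c in out.columns]
    flagged = np.zeros(len(out), dtype=bool)
    non_s0 = out["category"] != "S0"
    for _, idx in out[non_s0].groupby(list(group_cols)).groups.items():
        if len(idx) < 3:
            logger.info("outlier rule: group of %d strides skipped", len(idx))
            continue
        sub = out.loc[idx, metrics]
        sd = sub.std(ddof=0)
        sd = sd.replace(0.0, np.nan)  # zero-variance metrics flag nothing
        z = (sub - sub.mean()) / sd
        flagged[out.index.get_indexer(idx)] |= (z.abs() > z_threshold).any(axis=1).to_numpy()
    out["outlier"] = flagged
    n = int(flagged.sum())
    if n:
        logger.info("outlier rule: flagged %d of %d strides (|Z| > %g)", n, len(out), z_threshold)
    return out
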