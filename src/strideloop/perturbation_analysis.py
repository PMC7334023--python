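"""Category-average trajectories, obstacle deviation trajectories and their
cross-correlation.

For each individual the pointwise mean trajectory (with a t-based 95%
confidence band) is built per stride category and channel.  The
perturbation response is summarized as the deviation trajectory
d_i(phi) = mean_S0,i(phi) - mean_Level,i(phi) per individual, whose grand
mean and cross-individual 95% CI localize when the obstacle response
departs from steady state: the first significant phase is the earliest
point where the CI excludes zero for a sustained run (default 2% of the
cycle, suppressing single-point crossings).  Coupling between channels
(e.g. length vs EMG deviations) is quantified by the zero-lag Pearson
correlation of the grand-mean deviation trajectories, with the full
normalized lag profile also available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .recordings_io import ValidationError


@dataclass
class CategoryAverage:
    """Pointwise mean +/- 95% CI of one individual's strides in a category."""

    phase: np.ndarray
    mean: np.ndarray
    ci_halfwidth: np.ndarray | None
    n_strides: int
    individual: str = ""
    category: str = ""
    channel: str = ""


@dataclass
class DeviationTrajectory:
    """Grand-mean (S0 - Level) deviation across individuals, per channel."""

    phase: np.ndarray
    mean: np.ndarray
    ci_halfwidth: np.ndarray
    n_individuals: int
    first_significant_phase: float | None
    per_individual: np.ndarray  # shape (n_individuals, n_points)
    channel: str = ""

    @property
    def significant(self) -> np.ndarray:
        lo = self.mean - self.ci_halfwidth
        hi = self.mean + self.ci_halfwidth
        return (lo > 0) | (hi < 0)


def _t_halfwidth(arr: np.ndarray, axis=0, level: float = 0.95):
    n = arr.shape[axis]
    sd = arr.std(axis=axis, ddof=1)
    return stats.t.ppf(0.5 + level / 2.0, n - 1) * sd / np.sqrt(n)


def average_category(cycles, individual: str, category: str, channel: str) -> CategoryAverage:
    """Pointwise mean and t-based 95% CI across one individual's strides.

    With a single stride the mean is returned and the CI is missing.
    """
    sel = [c for c in cycles if c.bird_id == individual and c.category == category]
    if not sel:
        raise ValidationError(f"no strides for {individual!r} / {category!r}")
    arr = np.vstack([c.channels[channel] for c in sel])
    phase = sel[0].phase
    mean = arr.mean(axis=0)
    hw = _t_halfwidth(arr) if arr.shape[0] >= 2 else None
    return CategoryAverage(phase=phase, mean=mean, ci_halfwidth=hw,
                           n_strides=arr.shape[0], individual=individual,
                           category=category, channel=channel)


def deviation_trajectory(averages_per_individual: dict, phase=None,
                         min_run_frac: float = 0.02, channel: str = "") -> DeviationTrajectory:
    """Grand-mean deviation trajectory across individuals.

    ``averages_per_individual`` maps individual -> (perturbed mean
    trajectory, reference mean trajectory); both arrays (or
    CategoryAverage objects) must share the phase grid.  The first
    significant phase is the start of the earliest run of at least
    ``min_run_frac`` of the cycle where the 95% CI excludes zero.
    """
    if len(averages_per_individual) < 2:
        raise ValidationError("need >= 2 individuals with both category averages")
    devs = []
    for ind, (pert, ref) in averages_per_individual.items():
        a = pert.mean if isinstance(pert, CategoryAverage) else np.asarray(pert, float)
        b = ref.mean if isinstance(ref, CategoryAverage) else np.asarray(ref, float)
        if a.shape != b.shape:
            raise ValidationError(f"phase grids differ for individual {ind!r}")
        devs.append(a - b)
        if phase is None and isinstance(pert, CategoryAverage):
            phase = pert.phase
    per_ind = np.vstack(devs)
    n_points = per_ind.shape[1]
    if phase is None:
        phase = np.arange(n_points) / n_points
    mean = per_ind.mean(axis=0)
    hw = _t_halfwidth(per_ind)
    dev = DeviationTrajectory(phase=np.asarray(phase, float), mean=mean,
                              ci_halfwidth=hw, n_individuals=per_ind.shape[0],
                              first_significant_phase=None, per_individual=per_ind,
                              channel=channel)
    dev.first_significant_phase = _first_significant(dev.significant, dev.phase,
                                                     min_run_frac)
    return dev


def deviation_from_cycles(cycles, channel: str, category: str = "S0",
                          reference: str = "L", min_run_frac: float = 0.02) -> DeviationTrajectory:
    """Build the (S0 - Level) deviation trajectory directly from cut cycles."""
    individuals = sorted({c.bird_id for c in cycles})
    pairs = {}
    for ind in individuals:
        has_pert = any(c.bird_id == ind and c.category == category for c in cycles)
        has_ref = any(c.bird_id == ind and c.category == reference for c in cycles)
        if has_pert and has_ref:
            pairs[ind] = (average_category(cycles, ind, category, channel),
                          average_category(cycles, ind, reference, channel))
    return deviation_trajectory(pairs, min_run_frac=min_run_frac, channel=channel)


def _first_significant(sig: np.ndarray, phase: np.ndarray, min_run_frac: float):
    min_run = max(1, int(np.ceil(min_run_frac * sig.size)))
    edges = np.flatnonzero(np.diff(np.concatenate(([False], sig, [False])).astype(int)))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start >= min_run:
            return float(phase[start])
    return None


def deviation_crosscorr(dev_a, dev_b):
    """Coupling between two deviation trajectories.

    Returns ``(r, lags, profile)``: the zero-lag Pearson correlation of the
    grand-mean trajectories (the headline scalar), the lag axis in phase
    fractions, and the full normalized cross-correlation profile.  A
    zero-variance trajectory yields ``r = None``.
    """
    a = dev_a.mean if isinstance(dev_a, DeviationTrajectory) else np.asarray(dev_a, float)
    b = dev_b.mean if isinstance(dev_b, DeviationTrajectory) else np.asarray(dev_b, float)
    if a.shape != b.shape:
        raise ValidationError("deviation trajectories must share the phase grid")
    n = a.size
    if a.std() == 0 or b.std() == 0:
        return None, None, None
    r = float(stats.pearsonr(a, b).statistic)
    ac = (a - a.mean()) / a.std()
    bc = (b - b.mean()) / b.std()
    profile = np.correlate(ac, bc, mode="full") / n
    lags = np.arange(-(n - 1), n) / n
    return r, lags, profile


def plot_deviation(devs: dict, out_path=None):
    """Mean-line + CI-band panel per channel (marker at the first
    significant phase), mirroring the standard deviation-trajectory layout."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(devs), 1, figsize=(6, 2.2 * len(devs)), sharex=True)
    if len(devs) == 1:
        axes = [axes]
    for ax, (name, dev) in zip(axes, devs.items()):
        ax.axhline(0.0, color="0.6", lw=0.8)
        ax.fill_between(dev.phase, dev.mean - dev.ci_halfwidth,
                        dev.mean + dev.ci_halfwidth, alpha=0.3)
        ax.plot(dev.phase, dev.mean)
        if dev.first_significant_phase is not None:
            ax.axvline(dev.first_significant_phase, ls="--", color="k", lw=0.8)
            ax.plot([dev.first_significant_phase], [0], "k*")
        ax.set_ylabel(name)
    axes[-1].set_xlabel("stride cycle (fraction)")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        plt.close(fig)
    return fig
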