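"""Trial-recording containers and file I/O.

A trial is one continuous treadmill recording of synchronized fascicle
length (sonomicrometry, mm), muscle-tendon force (tendon buckle, N) and raw
EMG (mV), together with foot-contact event times and per-contact obstacle
flags.  Two on-disk formats are supported:

* an HDF5 container (groups ``/channels``, ``/events``, root attributes for
  metadata) — the canonical format for long 10 kHz multichannel records;
* a plain-text CSV bundle (a directory with ``channels.csv``,
  ``events.csv`` and ``meta.json``) — convenient for small fixtures and
  text-only archives.

Event times are stored in seconds from trial start rather than sample
indices, so the containers are independent of sample rate.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("strideloop")

COHORTS = ("intact", "reinnervated")
TERRAINS = ("level", "obstacle")

#: stride-category codes: level terrain (L), stride before an obstacle
#: contact (S-1), the obstacle-contact stride itself (S0), the stride after
#: (S+1) and all remaining obstacle-terrain strides (S+2).
CATEGORIES = ("L", "S-1", "S0", "S+1", "S+2")


class SchemaError(ValueError):
    """A recording or table is missing required keys or is inconsistent."""


class ValidationError(ValueError):
    """A parameter set violates its documented invariants."""


@dataclass
class TrialMeta:
    bird_id: str
    cohort: str = "intact"
    terrain: str = "level"
    speed_ms: float = 1.7
    muscle_mass_g: float = 10.7
    reference_length_mm: float | None = None
    trial_id: str = "t0"

    def validate(self) -> None:
        if self.cohort not in COHORTS:
            raise ValidationError(f"cohort must be one of {COHORTS}, got {self.cohort!r}")
        if self.terrain not in TERRAINS:
            raise ValidationError(f"terrain must be one of {TERRAINS}, got {self.terrain!r}")
        if self.muscle_mass_g <= 0:
            raise ValidationError("muscle_mass_g must be > 0")


@dataclass
class TrialRecording:
    """Synchronized multichannel time series plus event annotations.

    ``channels`` maps channel names (``fascicle_length`` [mm],
    ``tendon_force`` [N], ``emg`` [mV]) to equally long 1-D arrays sampled
    at ``sample_rate_hz``.  ``foot_contact`` holds foot-contact times in
    seconds; ``obstacle_contact`` has one boolean per contact.
    """

    channels: dict[str, np.ndarray]
    sample_rate_hz: float
    foot_contact: np.ndarray
    obstacle_contact: np.ndarray
    meta: TrialMeta
    toe_off: np.ndarray | None = None

    REQUIRED_CHANNELS = ("fascicle_length", "tendon_force", "emg")

    def __post_init__(self):
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        self.foot_contact = np.asarray(self.foot_contact, dtype=float)
        self.obstacle_contact = np.asarray(self.obstacle_contact, dtype=bool)
        if self.toe_off is not None:
            self.toe_off = np.asarray(self.toe_off, dtype=float)

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz

    def validate(self, max_nan_run: int | None = None) -> None:
        missing = [c for c in self.REQUIRED_CHANNELS if c not in self.channels]
        if missing:
            raise SchemaError(f"missing channels: {missing}")
        lengths = {k: len(v) for k, v in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise SchemaError(f"channels have unequal lengths: {lengths}")
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be > 0")
        if self.foot_contact.size == 0:
            raise SchemaError("missing foot_contact events")
        if np.any(np.diff(self.foot_contact) <= 0):
            raise ValidationError("foot_contact times must be strictly increasing")
        if self.foot_contact[0] < 0 or self.foot_contact[-1] > self.duration_s:
            raise ValidationError("foot_contact times fall outside the recording span")
        if len(self.obstacle_contact) != len(self.foot_contact):
            raise SchemaError(
                f"obstacle_contact has {len(self.obstacle_contact)} flags for "
                f"{len(self.foot_contact)} contacts"
            )
        if self.toe_off is not None and np.any(np.diff(self.toe_off) <= 0):
            raise ValidationError("toe_off times must be strictly increasing")
        self.meta.validate()
        if max_nan_run is not None:
            for name, x in self.channels.items():
                run = _longest_nan_run(x)
                if run > max_nan_run:
                    raise SchemaError(
                        f"channel {name!r} has a NaN run of {run} samples "
                        f"(> max_nan_run={max_nan_run})"
                    )


def _longest_nan_run(x: np.ndarray) -> int:
    isnan = np.isnan(x)
    if not isnan.any():
        return 0
    # run-length encode the boolean mask
    edges = np.flatnonzero(np.diff(np.concatenate(([False], isnan, [False])).astype(int)))
    starts, stops = edges[::2], edges[1::2]
    return int((stops - starts).max())


# ---------------------------------------------------------------------------
# trial read/write

def _infer_format(path: Path) -> str:
    if path.suffix in (".h5", ".hdf5"):
        return "hdf5"
    return "csv"


def write_trial(trial: TrialRecording, path, format: str | None = None) -> None:
    path = Path(path)
    fmt = format or _infer_format(path)
    trial.validate()
    if fmt == "hdf5":
        _write_trial_hdf5(trial, path)
    elif fmt == "csv":
        _write_trial_csv(trial, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_trial(path, format: str | None = None, max_nan_run: int | None = None) -> TrialRecording:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "hdf5":
        trial = _read_trial_hdf5(path)
    elif fmt == "csv":
        trial = _read_trial_csv(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    trial.validate(max_nan_run=max_nan_run)
    return trial


def _write_trial_hdf5(trial: TrialRecording, path: Path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("channels")
        for name, x in trial.channels.items():
            g.create_dataset(name, data=x)
        e = f.create_group("events")
        e.create_dataset("foot_contact", data=trial.foot_contact)
        e.create_dataset("obstacle_contact", data=trial.obstacle_contact.astype(np.uint8))
        if trial.toe_off is not None:
            e.create_dataset("toe_off", data=trial.toe_off)
        f.attrs["sample_rate_hz"] = trial.sample_rate_hz
        for k, v in dataclasses.asdict(trial.meta).items():
            if v is not None:
                f.attrs[k] = v


def _read_trial_hdf5(path: Path) -> TrialRecording:
    with h5py.File(path, "r") as f:
        if "channels" not in f or "events" not in f:
            raise SchemaError(f"{path}: missing /channels or /events group")
        channels = {name: f["channels"][name][()] for name in f["channels"]}
        ev = f["events"]
        if "foot_contact" not in ev:
            raise SchemaError(f"{path}: missing /events/foot_contact")
        foot_contact = ev["foot_contact"][()]
        obstacle = ev["obstacle_contact"][()].astype(bool) if "obstacle_contact" in ev \
            else np.zeros(len(foot_contact), bool)
        toe_off = ev["toe_off"][()] if "toe_off" in ev else None
        attrs = dict(f.attrs)
    fs = float(attrs.pop("sample_rate_hz"))
    meta_fields = {f_.name for f_ in dataclasses.fields(TrialMeta)}
    meta = TrialMeta(**{k: v for k, v in attrs.items() if k in meta_fields})
    return TrialRecording(channels, fs, foot_contact, obstacle, meta, toe_off)


def _write_trial_csv(trial: TrialRecording, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    # %.17g guarantees bit-exact float round trips through text
    pd.DataFrame(trial.channels).to_csv(path / "channels.csv", index=False,
                                        float_format="%.17g")
    n = len(trial.foot_contact)
    ev = pd.DataFrame({
        "foot_contact_s": trial.foot_contact,
        "obstacle_contact": trial.obstacle_contact.astype(int),
    })
    if trial.toe_off is not None:
        toe = np.full(n, np.nan)
        toe[: len(trial.toe_off)] = trial.toe_off[:n]
        ev["toe_off_s"] = toe
    ev.to_csv(path / "events.csv", index=False, float_format="%.17g")
    meta = dataclasses.asdict(trial.meta)
    meta["sample_rate_hz"] = trial.sample_rate_hz
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def _read_trial_csv(path: Path) -> TrialRecording:
    missing = [n for n in ("channels.csv", "events.csv", "meta.json") if not (path / n).exists()]
    if missing:
        raise SchemaError(f"{path}: CSV bundle missing {missing}")
    ch = pd.read_csv(path / "channels.csv", float_precision="round_trip")
    ev = pd.read_csv(path / "events.csv", float_precision="round_trip")
    meta = json.loads((path / "meta.json").read_text())
    fs = float(meta.pop("sample_rate_hz"))
    if "foot_contact_s" not in ev.columns:
        raise SchemaError(f"{path}: events.csv lacks foot_contact_s")
    toe = None
    if "toe_off_s" in ev.columns:
        toe = ev["toe_off_s"].dropna().to_numpy()
    meta_fields = {f_.name for f_ in dataclasses.fields(TrialMeta)}
    meta_obj = TrialMeta(**{k: v for k, v in meta.items() if k in meta_fields and v is not None})
    return TrialRecording(
        {c: ch[c].to_numpy() for c in ch.columns},
        fs,
        ev["foot_contact_s"].to_numpy(),
        ev["obstacle_contact"].to_numpy().astype(bool),
        meta_obj,
        toe,
    )


# ---------------------------------------------------------------------------
# stride tables

#: column order of the per-stride outcome table; units in STRIDE_TABLE_UNITS
STRIDE_TABLE_COLUMNS = [
    "bird_id", "trial_id", "stride_index", "cohort", "terrain", "category",
    "T_stride", "W_net", "F_pk", "L_pkF", "V_pkF", "T_force",
    "E_tot", "E_freq", "E_phase", "E_dur", "ankle_contact_angle", "outlier",
]

STRIDE_TABLE_UNITS = {
    "T_stride": "s", "W_net": "J/kg", "F_pk": "N", "L_pkF": "L/Lo",
    "V_pkF": "L/s", "T_force": "fraction of stride", "E_tot": "a.u.",
    "E_freq": "Hz", "E_phase": "fraction of stride", "E_dur": "fraction of stride",
    "ankle_contact_angle": "deg", "outlier": "bool",
}

METRIC_COLUMNS = ["W_net", "F_pk", "L_pkF", "V_pkF", "T_force", "T_stride",
                  "E_tot", "E_freq", "E_phase", "E_dur"]


def write_stride_table(table: pd.DataFrame, path) -> None:
    """Write a stride table as CSV with a commented units header."""
    path = Path(path)
    cols = [c for c in STRIDE_TABLE_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    bad = table["category"].dropna()[~table["category"].dropna().isin(CATEGORIES)] \
        if "category" in table.columns else pd.Series(dtype=object)
    if len(bad):
        raise ValidationError(f"unknown stride categories: {sorted(set(bad))}")
    with open(path, "w") as fh:
        units = "; ".join(f"{k}[{v}]" for k, v in STRIDE_TABLE_UNITS.items() if k in cols)
        fh.write(f"# strideloop stride table; units: {units}\n")
        table[cols].to_csv(fh, index=False, float_format="%.17g")


def read_stride_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


# ---------------------------------------------------------------------------
# configuration

DEFAULTS: dict = {
    "io": {"max_nan_run": 2000},
    "conditioning": {
        # "auto" scales the smoothing-spline residual bound with the series
        # length and a robust noise estimate; a number is an absolute
        # residual-sum-of-squares bound in mm^2.
        "spline_tolerance": "auto",
        "gap_limit": 100,
        "jump_mad_factor": 6.0,
        "min_jump_frac": 0.02,
        "emg_band_hz": [10.0, 1000.0],
        "r2_threshold": 0.97,
    },
    "segmentation": {"n_points": 200, "z_threshold": 4.0},
    "metrics": {"force_threshold_frac": 0.05},
    "emg": {
        "n_bands": 11,
        "burst_k": 3.0,
        # crossing level as a fraction of the burst plateau amplitude; the
        # analytic filterbank's step response passes the true edge at ~0.6
        # of the plateau (quadrature component), not 0.5
        "burst_rel_floor": 0.6,
        "burst_smooth_frac": 0.01,
        "baseline_window": [0.875, 0.125],
    },
    "perturbation": {"min_run_frac": 0.02},
    "stats": {"q": 0.05},
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None) -> dict:
    """Load a YAML config, merged over the package defaults."""
    cfg = {k: dict(v) for k, v in DEFAULTS.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _deep_merge(cfg, user)
    logger.info("configuration: %s", cfg)
    return cfg
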