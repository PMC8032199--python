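"""Reading and writing trial tables, count tables and model configs."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .dynamics import TRIAL_COLUMNS
from .params import ModelParams

__all__ = [
    "write_trials_csv",
    "read_trials_csv",
    "load_config",
    "params_from_config",
]


def write_trials_csv(trials: pd.DataFrame, path) -> None:
    """Write a trial table using the canonical column order.

    Missing optional columns (condition, rating) are filled with empty /
    NA values so every trials.csv has the same header.
    """
    out = trials.copy()
    if "condition" not in out:
        out["condition"] = ""
    if "rating" not in out:
        out["rating"] = pd.NA
    out[TRIAL_COLUMNS].to_csv(path, index=False)


def read_trials_csv(path) -> pd.DataFrame:
    trials = pd.read_csv(path)
    missing = {"stimulus", "response", "rt_steps"} - set(trials.columns)
    if missing:
        raise ValueError(f"trial table {path} lacks required columns: {sorted(missing)}")
    return trials


def load_config(path) -> dict:
    """Load a YAML/JSON condition configuration file.

    The file maps condition names to flat parameter sections, e.g.::

        low_med:
          s_drives: [0.012, 0.0012]
          sigma_acc: 0.1
          threshold: 1.0
          tau: 60
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or not cfg:
        raise ValueError(f"config {path} must map condition names to parameter sections")
    return cfg


def params_from_config(section: Mapping) -> ModelParams:
    """Build :class:`ModelParams` from one config section."""
    known = {
        "s_drives",
        "sigma_acc",
        "sigma_diff",
        "threshold",
        "tau",
        "rating_thresholds",
        "n_ratings",
        "max_steps",
    }
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    kwargs = dict(section)
    if "s_drives" in kwargs:
        kwargs["s_drives"] = tuple(float(s) for s in kwargs["s_drives"])
    if kwargs.get("rating_thresholds") is not None:
        kwargs["rating_thresholds"] = tuple(float(u) for u in kwargs["rating_thresholds"])
    return ModelParams(**kwargs)
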