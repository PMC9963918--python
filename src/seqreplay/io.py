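"""File formats: choice-table CSV, epoch/reactivation HDF5, result export.

Trial tables travel as CSV with a fixed required column set; arrays travel
as HDF5 groups with datasets ``data``, ``labels`` (epochs only) and
``time_ms``; results as TSV/JSON.  An optional column-name mapping (YAML)
adapts externally deposited trial tables to the internal schema.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .neural import EpochSet, ReactivationMatrix

__all__ = [
    "CHOICE_COLUMNS", "read_choice_csv", "write_choice_csv",
    "write_epochs_h5", "read_epochs_h5",
    "write_reactivations_h5", "read_reactivations_h5",
    "write_json", "write_tsv",
]

logger = logging.getLogger(__name__)

CHOICE_COLUMNS = ("participant", "trial", "block", "world", "start_state",
                  "choice", "path", "reward", "stakes", "rt")


def read_choice_csv(path, column_map: dict | str | Path | None = None
                    ) -> pd.DataFrame:
    """Read a trial table; validates schema, sorts by (participant, trial).

    ``column_map`` (dict or YAML file of ``external: internal`` names) adapts
    externally deposited tables.  Unknown columns are preserved.
    """
    df = pd.read_csv(path)
    if column_map is not None:
        if not isinstance(column_map, dict):
            with open(column_map) as fh:
                column_map = yaml.safe_load(fh)
        df = df.rename(columns=column_map)
    missing = [c for c in CHOICE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"choice CSV missing columns {missing}; expected header "
            f"{list(CHOICE_COLUMNS)}")
    ordered = df.sort_values(["participant", "trial"], kind="stable")
    if not ordered.index.equals(df.index):
        logger.warning("choice CSV rows were out of order; sorted by "
                       "(participant, trial)")
    return ordered.reset_index(drop=True)


def write_choice_csv(data: pd.DataFrame, path) -> None:
    missing = [c for c in CHOICE_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"choice table missing columns {missing}")
    data.to_csv(path, index=False)


def write_epochs_h5(epochs: EpochSet, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=epochs.data)
        fh.create_dataset("labels", data=epochs.labels)
        fh.create_dataset("time_ms", data=epochs.times_ms)


def read_epochs_h5(path) -> EpochSet:
    with h5py.File(path, "r") as fh:
        return EpochSet(fh["data"][...], fh["labels"][...], fh["time_ms"][...])


def write_reactivations_h5(reacts, path) -> None:
    """Write a list of ReactivationMatrix as numbered HDF5 groups."""
    with h5py.File(path, "w") as fh:
        for i, r in enumerate(reacts):
            g = fh.create_group(f"trial{i:04d}")
            g.create_dataset("data", data=r.values)
            g.create_dataset("time_ms", data=r.times_ms)
            g.attrs["window"] = r.window
            g.attrs["trial_id"] = -1 if r.trial_id is None else r.trial_id


def read_reactivations_h5(path) -> list:
    out = []
    with h5py.File(path, "r") as fh:
        for key in sorted(fh.keys()):
            g = fh[key]
            tid = int(g.attrs["trial_id"])
            out.append(ReactivationMatrix(
                g["data"][...], g["time_ms"][...], str(g.attrs["window"]),
                None if tid < 0 else tid))
    return out


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.integer):
            return int(obj)
        if isinstance(obj, np.floating):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
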