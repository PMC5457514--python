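"""CSV/TSV/JSON readers and writers for the pipeline's table schemas.

All writers use a fixed float format so that reruns with identical seeds
produce byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

FLOAT_FMT = "%.10g"

SPIKES_COLS = ["unit_id", "trial_id", "t_rel_s"]
TRIALS_COLS = ["trial_id", "eye", "orientation_deg", "sf_cpd", "is_blank", "duration_s"]
WAVEFORM_COLS = ["unit_id", "sample_idx", "amplitude"]
TRAJECTORY_COLS = ["t_s", "x_cm", "y_cm"]
VEP_COLS = ["eye", "sf_cpd", "p1_uv"]


def _write_csv(df: pd.DataFrame, path, cols=None, sep=","):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df[cols] if cols else df
    out.to_csv(path, index=False, float_format=FLOAT_FMT, sep=sep)
    return path


def write_spikes(df, path):
    return _write_csv(df, path, SPIKES_COLS)


def read_spikes(path):
    return pd.read_csv(path)


def write_trials(df, path):
    return _write_csv(df, path, TRIALS_COLS)


def read_trials(path):
    return pd.read_csv(path)


def write_waveforms(df, path, meta: dict | None = None, meta_path=None):
    p = _write_csv(df, path, WAVEFORM_COLS)
    if meta is not None:
        meta_path = Path(meta_path or Path(path).with_name("meta.json"))
        meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return p


def read_waveforms(path, meta_path=None):
    df = pd.read_csv(path)
    meta = None
    meta_path = Path(meta_path or Path(path).with_name("meta.json"))
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    return df, meta


def write_expression(matrix: pd.DataFrame, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(path, sep="\t", float_format=FLOAT_FMT)
    return path


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_trajectory(df, path):
    return _write_csv(df, path, TRAJECTORY_COLS)


def read_trajectory(path):
    return pd.read_csv(path)


def write_vep_amplitudes(df, path):
    return _write_csv(df, path, VEP_COLS)


def read_vep_amplitudes(path):
    return pd.read_csv(path)


def write_table(df, path):
    """Generic fixed-format CSV writer for result tables."""
    return _write_csv(df, path)


def write_json(obj, path):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")
    return path
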