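"""End-to-end orchestration: run pipeline stages from a config mapping.

A run is deterministic given its config (every stochastic stage takes an
explicit seed) and leaves a manifest recording package/library versions,
seeds and SHA-256 hashes of the input files it consumed.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import binomatch
from binomatch import classify as _classify
from binomatch import io as bio
from binomatch import tuning as _tuning
from binomatch.protocol import make_stimulus_protocol
from binomatch.simulate import simulate_unit_population

__all__ = ["load_config", "run_pipeline"]

DEFAULT_CONFIG = {
    "seed": 0,
    "stages": ["simulate", "tuning", "classify"],
    "protocol": {},
    "simulate": {"n_units": 20, "mismatch_model": "matched", "kappa": 20.0},
    "tuning": {"resp_mode": "raw", "cbi_mode": "classes"},
    "classify": {"f1f0_threshold": 1.0},
    "inputs": {},
}

_VALID_STAGES = ("simulate", "tuning", "classify")


def load_config(path) -> dict:
    """Load and validate a YAML run config (missing keys get defaults)."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge_config(user)


def _merge_config(user: dict) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for k, v in (user or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    unknown = [s for s in cfg["stages"] if s not in _VALID_STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    if not isinstance(cfg["seed"], int):
        raise ValueError("seed must be an integer")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict | str | Path, out_dir) -> dict:
    """Run the configured stages, writing result tables and a manifest.

    ``config`` is a mapping (or path to a YAML file) following
    ``DEFAULT_CONFIG``. When the ``simulate`` stage is absent, the
    ``inputs`` section must point at existing spike/trial/waveform files;
    missing files raise an error listing them.

    Returns a dict with the in-memory tables and the manifest.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    else:
        config = _merge_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proto = make_stimulus_protocol(config.get("protocol") or None)
    manifest = {
        "package_version": binomatch.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "python_version": platform.python_version(),
        "config": config,
        "inputs": {},
        "outputs": [],
    }
    results = {"manifest": manifest}

    spikes = trials = waveforms = meta = truth = None
    if "simulate" in config["stages"]:
        sim_cfg = dict(config["simulate"])
        pop = simulate_unit_population(
            sim_cfg.pop("n_units"),
            sim_cfg.pop("mismatch_model", "matched"),
            protocol=proto,
            seed=config["seed"],
            **sim_cfg,
        )
        spikes, trials, waveforms = pop.spikes, pop.trials, pop.waveforms
        meta, truth = pop.meta, pop.truth
        manifest["outputs"] += [
            str(bio.write_spikes(spikes, out / "spike_events.csv")),
            str(bio.write_trials(trials, out / "trials.csv")),
            str(bio.write_waveforms(waveforms, out / "waveforms.csv", meta)),
            str(bio.write_table(truth, out / "truth_units.csv")),
        ]
        results["truth"] = truth
    else:
        paths = {k: Path(v) for k, v in config["inputs"].items()}
        required = {"spikes", "trials", "waveforms"}
        missing = sorted(
            [str(paths[k]) for k in required & set(paths) if not paths[k].exists()]
            + [k for k in required - set(paths)]
        )
        if missing:
            raise FileNotFoundError(f"missing inputs: {missing}")
        spikes = bio.read_spikes(paths["spikes"])
        trials = bio.read_trials(paths["trials"])
        waveforms, meta = bio.read_waveforms(paths["waveforms"])
        manifest["inputs"] = {k: _sha256(v) for k, v in paths.items()}

    if "tuning" in config["stages"]:
        metrics = _tuning.analyze_units(
            spikes, trials, proto, resp_mode=config["tuning"]["resp_mode"]
        )
        results["unit_metrics"] = metrics
        manifest["outputs"].append(str(bio.write_table(metrics, out / "unit_metrics.csv")))
        animals = config.get("animal_ids")
        per_animal, pooled = _tuning.population_summary(
            metrics, animals, cbi_mode=config["tuning"]["cbi_mode"]
        )
        results["animal_summary"] = per_animal
        results["pooled_summary"] = pooled
        manifest["outputs"].append(
            str(bio.write_table(per_animal, out / "animal_summary.csv"))
        )

    if "classify" in config["stages"]:
        if "unit_metrics" not in results:
            raise ValueError("classify stage requires the tuning stage")
        sampling = (meta or {}).get("sampling_rate_hz", 30000.0)
        classes = _classify.classify_units(
            spikes,
            trials,
            proto,
            results["unit_metrics"],
            waveforms,
            sampling,
            f1f0_threshold=config["classify"]["f1f0_threshold"],
            seed=config["seed"],
        )
        results["unit_classes"] = classes
        manifest["outputs"].append(str(bio.write_table(classes, out / "unit_classes.csv")))

    bio.write_json(manifest, out / "manifest.json")
    return results
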