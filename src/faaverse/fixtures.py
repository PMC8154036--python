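"""Fixture and configuration I/O.

Studies round-trip through portable ``.npz`` array containers (one file per
study) plus a single delimited metadata table (one row per subject).  Study
configurations are read from YAML with every StudyConfig field addressable;
run manifests are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import RawStudy, SpectralDataset
from .layouts import ChannelLayout, make_standard_layout
from .synth import ConfoundModel, StudyConfig, default_study_configs, scaled_configs

__all__ = [
    "save_raw_study", "load_raw_study",
    "save_spectral", "load_spectral",
    "save_metadata", "load_metadata",
    "study_config_from_dict", "load_run_config",
    "write_manifest",
]

_META_DTYPES = {"subject_id": str, "study_id": str, "group": str,
                "score": "Int64", "age": float, "gender": str,
                "education": float}


def save_metadata(metas: list[pd.DataFrame], path: str | Path) -> None:
    pd.concat(metas, ignore_index=True).to_csv(path, index=False)


def load_metadata(path: str | Path, study_id: str | None = None) -> pd.DataFrame:
    meta = pd.read_csv(path, dtype=_META_DTYPES)
    if study_id is not None:
        meta = meta[meta["study_id"] == study_id].reset_index(drop=True)
    return meta


def _layout_arrays(layout: ChannelLayout) -> dict:
    return {"channel_names": np.array(layout.names),
            "channel_positions": layout.positions}


def _layout_from_arrays(d) -> ChannelLayout:
    return ChannelLayout(tuple(str(n) for n in d["channel_names"]),
                         np.asarray(d["channel_positions"], float))


def save_raw_study(raw: RawStudy, path: str | Path) -> None:
    np.savez_compressed(path, data=raw.data, sfreq=raw.sfreq,
                        bad_mask=raw.bad_mask, study_id=raw.study_id,
                        **_layout_arrays(raw.layout))


def load_raw_study(path: str | Path, meta: pd.DataFrame) -> RawStudy:
    with np.load(path, allow_pickle=False) as d:
        return RawStudy(data=d["data"], sfreq=float(d["sfreq"]),
                        layout=_layout_from_arrays(d), bad_mask=d["bad_mask"],
                        meta=meta, study_id=str(d["study_id"]))


def save_spectral(spec: SpectralDataset, path: str | Path) -> None:
    np.savez_compressed(path, power=spec.power, freqs=spec.freqs,
                        space=spec.space, study_id=spec.study_id,
                        **_layout_arrays(spec.layout))


def load_spectral(path: str | Path, meta: pd.DataFrame) -> SpectralDataset:
    with np.load(path, allow_pickle=False) as d:
        return SpectralDataset(power=d["power"], freqs=d["freqs"],
                               layout=_layout_from_arrays(d), meta=meta,
                               space=str(d["space"]),
                               study_id=str(d["study_id"]))


def study_config_from_dict(entry: dict) -> StudyConfig:
    """Build a StudyConfig from a plain mapping (YAML-friendly).

    ``channel_layout`` may be a list of built-in montage labels;
    ``confound_model`` a nested mapping of ConfoundModel fields.
    """
    entry = dict(entry)
    if "channel_layout" in entry and entry["channel_layout"] is not None:
        entry["channel_layout"] = make_standard_layout(list(entry["channel_layout"]))
    if "confound_model" in entry and entry["confound_model"] is not None:
        cm = entry["confound_model"]
        if isinstance(cm, dict):
            base = ConfoundModel()
            merged = {}
            for f in dataclasses.fields(ConfoundModel):
                v = cm.get(f.name, getattr(base, f.name))
                if isinstance(v, dict) and isinstance(getattr(base, f.name), dict):
                    v = {**getattr(base, f.name), **v}
                merged[f.name] = v
            entry["confound_model"] = ConfoundModel(**merged)
    return StudyConfig(**entry)


def load_run_config(path: str | Path) -> dict:
    """Read a run configuration: study recipes plus pipeline parameters.

    YAML keys: ``studies`` ('default' or a list of StudyConfig mappings),
    optional ``scale`` ({subject_scale, duration, sfreq}) applied to the
    default studies, and ``seed, n_perm, n_boot, alpha, two_sided_p``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    seed = int(cfg.get("seed", 0))
    studies = cfg.get("studies", "default")
    if studies == "default" or studies is None:
        configs = default_study_configs(seed=seed)
    else:
        configs = [study_config_from_dict({"seed": seed, **s}) for s in studies]
    if "scale" in cfg:
        sc = cfg["scale"] or {}
        configs = scaled_configs(configs,
                                 subject_scale=float(sc.get("subject_scale", 1.0)),
                                 duration=sc.get("duration"),
                                 sfreq=sc.get("sfreq"))
    alpha = float(cfg.get("alpha", 0.05))
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    return {
        "configs": configs,
        "seed": seed,
        "n_perm": int(cfg.get("n_perm", 1000)),
        "n_boot": int(cfg.get("n_boot", 1000)),
        "alpha": alpha,
        "two_sided_p": bool(cfg.get("two_sided_p", False)),
        "grid": str(cfg.get("grid", "full")),
    }


def write_manifest(path: str | Path, **payload) -> None:
    """JSON run manifest: seeds, parameters and package version."""
    from . import __version__

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            d = dataclasses.asdict(o)
            d.pop("channel_layout", None)
            return d
        if isinstance(o, ChannelLayout):
            return list(o.names)
        return str(o)

    with open(path, "w") as fh:
        json.dump({"faaverse_version": __version__, **payload}, fh,
                  indent=2, default=default)
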