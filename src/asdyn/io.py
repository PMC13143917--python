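"""File I/O shared by the CLI and library: long-format trajectory CSVs with
JSON metadata sidecars, profile and scenario documents (YAML or JSON), EMA
observation tables, and provenance records."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .engine import Scenario, TrajectoryBundle
from .params import IndividualProfile, WEIGHT_SUM_TOL
from .synthetic import EMADataset

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "load_profile",
    "save_profile",
    "scenario_to_dict",
    "scenario_from_dict",
    "load_scenario",
    "write_ema",
    "read_ema",
    "provenance_record",
]

log = logging.getLogger(__name__)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_trajectory(path, bundle: TrajectoryBundle) -> None:
    """Write a bundle as tidy CSV (time, variable, value) plus a JSON
    sidecar carrying metadata, the event log and any bout sequence."""
    path = Path(path)
    frames = [pd.DataFrame({"time": bundle.t, "variable": name, "value": vals})
              for name, vals in bundle.series.items()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.12g")
    meta = {"metadata": bundle.metadata, "events": bundle.events}
    if bundle.bouts is not None:
        meta["bouts"] = {"onsets": bundle.bouts.onsets.tolist(),
                         "durations": bundle.bouts.durations.tolist()}
    _sidecar(path).write_text(json.dumps(meta, indent=2, default=str))


def read_trajectory(path) -> TrajectoryBundle:
    """Read a trajectory CSV written by :func:`write_trajectory`.

    Malformed or non-numeric rows raise with their line numbers; a missing
    sidecar degrades to empty metadata with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"time": str, "variable": str, "value": str})
    required = {"time", "variable", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory CSV must have columns {sorted(required)}")
    bad_lines = []
    for col in ("time", "value"):
        num = pd.to_numeric(df[col], errors="coerce")
        bad_lines.extend((df.index[num.isna()] + 2).tolist())  # +2: header, 1-based
        df[col] = num
    if bad_lines:
        raise ValueError(f"non-numeric cells at line(s) {sorted(set(bad_lines))}")
    series = {}
    t = None
    for name, grp in df.groupby("variable", sort=False):
        grp = grp.sort_values("time", kind="stable")
        series[name] = grp["value"].to_numpy(float)
        if t is None or grp.shape[0] > t.size:
            t = grp["time"].to_numpy(float)
    meta, events, bouts = {}, [], None
    sc = _sidecar(path)
    if sc.exists():
        payload = json.loads(sc.read_text())
        meta = payload.get("metadata", {})
        events = payload.get("events", [])
        if "bouts" in payload:
            from .domain_b import BoutSequence
            bouts = BoutSequence(onsets=np.asarray(payload["bouts"]["onsets"]),
                                 durations=np.asarray(payload["bouts"]["durations"]))
    else:
        log.warning("metadata sidecar %s missing; loading with empty metadata", sc)
    return TrajectoryBundle(t=t, series=series, events=events, metadata=meta,
                            bouts=bouts)


def _load_doc(path: Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    return json.loads(text)


def _dump_doc(obj: dict, path: Path) -> None:
    path = Path(path)
    if str(path).endswith((".yaml", ".yml")):
        path.write_text(yaml.safe_dump(obj, sort_keys=False))
    else:
        path.write_text(json.dumps(obj, indent=2))


def load_profile(path) -> IndividualProfile:
    """Load a profile document (one section per submodel), renormalising
    composite weights when they do not already sum to one."""
    prof = IndividualProfile.from_dict(_load_doc(Path(path)))
    total = sum(prof.composite.w.values())
    if abs(total - 1.0) > WEIGHT_SUM_TOL:
        log.info("composite weights summed to %.6g; renormalised on load", total)
        prof.composite = prof.composite.renormalised()
    return prof


def save_profile(profile: IndividualProfile, path) -> None:
    _dump_doc(profile.to_dict(), Path(path))


_SCENARIO_FIELDS = [f.name for f in dataclasses.fields(Scenario) if f.name != "profile"]


def scenario_to_dict(s: Scenario) -> dict:
    d = {"profile": s.profile.to_dict()}
    for name in _SCENARIO_FIELDS:
        v = getattr(s, name)
        if isinstance(v, tuple):
            v = list(v)
        if name == "alignment_switches":
            v = [list(x) for x in v]
        d[name] = v
    return d


def scenario_from_dict(d: dict) -> Scenario:
    kw = {}
    if "profile" in d:
        kw["profile"] = IndividualProfile.from_dict(d["profile"])
    for name in _SCENARIO_FIELDS:
        if name in d:
            v = d[name]
            if name in ("entropy_t", "entropy_H"):
                v = tuple(v)
            if name == "alignment_switches":
                v = [tuple(x) for x in v]
            kw[name] = v
    return Scenario(**kw)


def load_scenario(path) -> Scenario:
    return scenario_from_dict(_load_doc(Path(path)))


def write_ema(dataset: EMADataset, path) -> None:
    """EMA observations as CSV plus a truth-provenance sidecar."""
    path = Path(path)
    dataset.observations.to_csv(path, index=False, float_format="%.12g")
    _sidecar(path).write_text(json.dumps(
        {"design": {k: list(v) if isinstance(v, tuple) else v
                    for k, v in dataset.design.items()},
         "noise": dataset.noise, "truth": dataset.truth}, indent=2, default=str))


def read_ema(path) -> EMADataset:
    path = Path(path)
    obs = pd.read_csv(path)
    sc = _sidecar(path)
    payload = json.loads(sc.read_text()) if sc.exists() else {}
    if not sc.exists():
        log.warning("EMA sidecar %s missing; loading with empty provenance", sc)
    return EMADataset(observations=obs, design=payload.get("design", {}),
                      noise=payload.get("noise", {}), truth=payload.get("truth", {}))


def provenance_record(config: dict, seed, out_dir) -> Path:
    """Write the run's provenance (config hash, seed, package version)."""
    from . import __version__
    blob = json.dumps(config, sort_keys=True, default=str)
    record = {"config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
              "seed": seed, "package_version": __version__, "config": config}
    out = Path(out_dir) / "provenance.json"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(record, indent=2, default=str))
    return out
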