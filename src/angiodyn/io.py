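"""Configuration loading, preset resolution and run serialization.

A run is described by a nested mapping with blocks ``params``, ``grid``,
``initial``, ``schedule`` (and ``schedule_multi`` for treatment presets),
``run`` and, for non-PDE presets, ``map`` or ODE-style ``initial``/``run``.
Resolution precedence is preset < config file < explicit overrides, and
unknown keys are rejected with an itemised error.  Every figure-level
experiment ships as a named preset whose numbers are caption values
verbatim (deviations are flagged as decision defaults in the provenance
string).
"""

from __future__ import annotations

import dataclasses
import json
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .params import DoseSchedule, Params
from .pde import Grid1D, TissueState

__all__ = ["ConfigError", "RunSpec", "list_presets", "load_preset",
           "load_config", "write_run"]

_PARAM_KEYS = {f.name for f in dataclasses.fields(Params)}
_SCHEDULE_KEYS = {f.name for f in dataclasses.fields(DoseSchedule)}
_SCHEMA = {
    "name": None,
    "kind": None,
    "provenance": None,
    "params": _PARAM_KEYS,
    "grid": {"L", "n", "dx"},
    "initial": {"p_seed", "seed_width", "p0", "v0"},
    "schedule": _SCHEDULE_KEYS,
    "schedule_multi": _SCHEDULE_KEYS,
    "run": {"variant", "t_end", "dt_out", "n_out", "rtol", "atol"},
    "map": {"delta_range", "dp_range", "n"},
}


class ConfigError(ValueError):
    """Schema violation; ``problems`` itemises every offending key."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n  - " +
                         "\n  - ".join(problems))


def _validate(doc: Mapping[str, Any]) -> None:
    problems = []
    for key, val in doc.items():
        if key not in _SCHEMA:
            problems.append(f"unknown top-level key {key!r}")
            continue
        allowed = _SCHEMA[key]
        if allowed is not None and isinstance(val, Mapping):
            for sub in val:
                if sub not in allowed:
                    problems.append(f"unknown key {key}.{sub}")
    if problems:
        raise ConfigError(problems)


def _merge(base: dict, extra: Mapping) -> dict:
    out = {k: dict(v) if isinstance(v, Mapping) else v
           for k, v in base.items()}
    for key, val in extra.items():
        if isinstance(val, Mapping) and isinstance(out.get(key), dict):
            out[key].update(val)
        else:
            out[key] = val
    return out


@dataclasses.dataclass
class RunSpec:
    """A fully resolved run description."""

    raw: dict

    @property
    def name(self) -> str:
        return self.raw.get("name", "unnamed")

    @property
    def kind(self) -> str:
        return self.raw.get("kind", "pde")

    @property
    def provenance(self) -> str:
        return self.raw.get("provenance", "")

    @property
    def params(self) -> Params:
        return Params(**self.raw["params"])

    @property
    def grid(self) -> Grid1D:
        g = self.raw["grid"]
        if "dx" in g and "n" not in g:
            return Grid1D.from_dx(g["L"], g["dx"])
        return Grid1D(L=g["L"], n=g["n"])

    @property
    def schedule(self) -> DoseSchedule:
        return DoseSchedule(**self.raw.get("schedule", {"mode": "none"}))

    @property
    def schedule_multi(self) -> Optional[DoseSchedule]:
        block = self.raw.get("schedule_multi")
        return DoseSchedule(**block) if block else None

    @property
    def initial(self) -> dict:
        return dict(self.raw.get("initial", {}))

    @property
    def run(self) -> dict:
        return dict(self.raw.get("run", {}))

    def to_dict(self) -> dict:
        return json.loads(json.dumps(self.raw))


def _preset_dir():
    return resources.files("angiodyn") / "data" / "presets"


def list_presets() -> list[str]:
    """Names of the shipped figure-level presets."""
    return sorted(p.name[:-5] for p in _preset_dir().iterdir()
                  if p.name.endswith(".yaml"))


def load_preset(name: str) -> RunSpec:
    path = _preset_dir() / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise ConfigError(
            [f"unknown preset {name!r}; available: {', '.join(list_presets())}"]
        ) from None
    doc = yaml.safe_load(text)
    _validate(doc)
    return RunSpec(raw=doc)


def load_config(path: str | Path | None = None,
                preset: str | None = None,
                overrides: Mapping[str, Any] | None = None) -> RunSpec:
    """Resolve a run spec with precedence preset < file < overrides.

    ``path`` may be a YAML or JSON file (a manifest written by
    :func:`write_run` round-trips).  ``overrides`` is a nested mapping,
    e.g. ``{"params": {"delta": 1.0}}``.
    """
    doc: dict = {}
    if preset is not None:
        doc = load_preset(preset).raw
    if path is not None:
        path = Path(path)
        loaded = (json.loads(path.read_text()) if path.suffix == ".json"
                  else yaml.safe_load(path.read_text()))
        if "spec" in loaded and isinstance(loaded["spec"], dict):
            loaded = loaded["spec"]      # manifest file
        _validate(loaded)
        doc = _merge(doc, loaded) if doc else loaded
    if overrides:
        _validate(overrides)
        doc = _merge(doc, overrides)
    if not doc:
        raise ConfigError(["no preset, file or overrides given"])
    _validate(doc)
    return RunSpec(raw=doc)


def write_run(states: list[TissueState], metrics: Mapping[str, Any],
              outdir: str | Path, spec: RunSpec | None = None,
              solver: Mapping[str, Any] | None = None) -> dict[str, Path]:
    """Serialize profile snapshots (CSV), metrics (JSON) and a manifest.

    The manifest contains the fully resolved spec and solver tolerances so
    that re-running from the manifest alone reproduces the metrics.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n_nodes = len(states[0].p)
    x = np.linspace(0.0, 1.0, n_nodes)
    if spec is not None and len(spec.grid.x) == n_nodes:
        x = spec.grid.x
    frames = []
    for st in states:
        cols = {"t": np.full(n_nodes, st.t), "x": x}
        frames.append(pd.DataFrame({**cols, **st.fields()}))
    profiles = pd.concat(frames, ignore_index=True)
    paths = {}
    paths["profiles"] = outdir / "profiles.csv"
    profiles.to_csv(paths["profiles"], index=False)
    paths["metrics"] = outdir / "metrics.json"
    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return float(obj)

    paths["metrics"].write_text(json.dumps(metrics, indent=2,
                                           default=_default))
    manifest = {"spec": spec.to_dict() if spec else {},
                "solver": dict(solver or {})}
    paths["manifest"] = outdir / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths
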