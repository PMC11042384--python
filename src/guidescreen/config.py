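"""YAML configuration for pipeline runs.

A single YAML file can declare the simulation, architecture, training,
hyperparameter-search and analysis settings. Unknown keys are rejected
so typos fail loudly. Example:

```yaml
simulation:
  n_dhs: 500
  guides_per_dhs: 10
  seed: 1
cnn:
  ablation: full
training:
  task: fitness
  max_epochs: 100
xgb_search:
  n_configs: 57
analysis:
  min_sig: 3           # significant guides required per DHS for top-k
  yates: false         # chi-square continuity correction
  winsorize_scope: train   # or "global"
  log1p_counts: true   # transform of the wild-type abundance target
  continuous_columns: [H3K27ac, H3K4me3, ATAC, dG_H, dG_B]
```
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .boost import XgbSearchSpec
from .cnn import CnnSpec, TrainSpec
from .simulate import SimConfig

_ANALYSIS_DEFAULTS = {
    "min_sig": 3,
    "yates": False,
    "winsorize_scope": "train",
    "log1p_counts": True,
    "continuous_columns": None,
}


def _build(cls, section: dict, name: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {name!r}: {sorted(unknown)}")
    if "head_fc_nodes" in section:
        section = {**section, "head_fc_nodes": tuple(section["head_fc_nodes"])}
    for tuple_key in ("effect_positions", "informative_annotations", "kernel_groups"):
        if tuple_key in section:
            section = {**section, tuple_key: tuple(section[tuple_key])}
    return cls(**section)


def load_config(path) -> dict:
    """Parse a YAML config into spec objects.

    Returns a dict with ``simulation`` (SimConfig), ``cnn`` (CnnSpec),
    ``training`` (TrainSpec), ``xgb_search`` (XgbSearchSpec) and
    ``analysis`` (plain dict with defaults filled in). Sections are
    optional; omitted ones get defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {"simulation", "cnn", "training", "xgb_search", "analysis"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")

    training = dict(raw.get("training", {}))
    task = training.pop("task", None)
    train_spec = (TrainSpec.for_task(task, **training) if task
                  else _build(TrainSpec, training, "training"))

    analysis = dict(_ANALYSIS_DEFAULTS)
    extra = set(raw.get("analysis", {})) - set(_ANALYSIS_DEFAULTS)
    if extra:
        raise ValueError(f"unknown keys in 'analysis': {sorted(extra)}")
    analysis.update(raw.get("analysis", {}))
    if analysis["winsorize_scope"] not in ("train", "global"):
        raise ValueError("winsorize_scope must be 'train' or 'global'")

    return {
        "simulation": _build(SimConfig, raw.get("simulation", {}), "simulation"),
        "cnn": _build(CnnSpec, raw.get("cnn", {}), "cnn"),
        "training": train_spec,
        "xgb_search": _build(XgbSearchSpec, raw.get("xgb_search", {}), "xgb_search"),
        "analysis": analysis,
    }
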