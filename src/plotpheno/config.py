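"""Task and extraction-strategy configuration files (YAML or JSON).

A strategy file lists features in execution order::

    features:
      - {kind: formula, name: NDVI, preset: NDVI, source: ms}
      - {kind: formula, name: myvi, expression: "(g-r)/(g+r)", source: rgb,
         statistic: mean, aggregate: pixel}
      - {kind: height, name: height, ground: 20.0}
      - {kind: biomass, name: biomass, expression: "0.5*height"}
      - {kind: external, name: lrs, interpreter: /usr/bin/python3,
         script: predict.py, source: rgb, timeout: 60}

A task file adds dates/images/ROIs/output (see ``load_task``). Custom
formulas declared here are also recorded to a local strategy file next to
the task outputs, so a run's exact recipe is reproducible.
"""

from __future__ import annotations

import datetime as _dt
import json
from pathlib import Path

import yaml

from .batch_store import BatchTask, DateInputs
from .extraction import (
    BiomassSpec,
    ExternalFeatureSpec,
    ExternalSpec,
    ExtractionStrategy,
    FormulaSpec,
    HeightSpec,
)
from .formula_engine import parse_formula, registry
from .geodata_io import BandMap

__all__ = ["load_strategy", "load_task", "strategy_from_dict", "save_strategy"]


def _load_mapping(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def strategy_from_dict(spec: dict) -> ExtractionStrategy:
    features = []
    for entry in spec.get("features", []):
        kind = entry.get("kind", "formula")
        name = entry["name"]
        if kind == "formula":
            if "preset" in entry:
                sensor = "MS" if entry.get("source", "ms") == "ms" else "RGB"
                formula = registry.expand(entry["preset"])
                registry.get(entry["preset"], sensor)  # sensor gate
            else:
                formula = parse_formula(name, entry["expression"])
            features.append(FormulaSpec(
                name=name,
                formula=formula,
                source=entry.get("source", "ms"),
                statistic=entry.get("statistic", "mean"),
                aggregate=entry.get("aggregate", "pixel"),
            ))
        elif kind == "height":
            features.append(HeightSpec(name=name,
                                       source=entry.get("source", "dsm"),
                                       ground=entry.get("ground")))
        elif kind == "biomass":
            features.append(BiomassSpec(
                name=name, formula=parse_formula(name, entry["expression"])))
        elif kind == "external":
            features.append(ExternalSpec(
                name=name,
                spec=ExternalFeatureSpec(
                    interpreter=entry["interpreter"],
                    script=entry["script"],
                    extra_args=tuple(entry.get("extra_args", [])),
                    timeout=float(entry.get("timeout", 60.0)),
                ),
                source=entry.get("source", "rgb"),
            ))
        else:
            raise ValueError(f"unknown feature kind {kind!r}")
    return ExtractionStrategy(features)


def load_strategy(path) -> ExtractionStrategy:
    return strategy_from_dict(_load_mapping(path))


def save_strategy(strategy: ExtractionStrategy, path) -> None:
    """Record a strategy back to a local YAML file."""
    entries = []
    for feature in strategy.features:
        if isinstance(feature, FormulaSpec):
            entries.append({"kind": "formula", "name": feature.name,
                            "expression": feature.formula.expression,
                            "source": feature.source,
                            "statistic": feature.statistic,
                            "aggregate": feature.aggregate})
        elif isinstance(feature, HeightSpec):
            entries.append({"kind": "height", "name": feature.name,
                            "source": feature.source,
                            "ground": feature.ground})
        elif isinstance(feature, BiomassSpec):
            entries.append({"kind": "biomass", "name": feature.name,
                            "expression": feature.formula.expression})
        elif isinstance(feature, ExternalSpec):
            entries.append({"kind": "external", "name": feature.name,
                            "interpreter": feature.spec.interpreter,
                            "script": feature.spec.script,
                            "extra_args": list(feature.spec.extra_args),
                            "timeout": feature.spec.timeout,
                            "source": feature.source})
    Path(path).write_text(yaml.safe_dump({"features": entries},
                                         sort_keys=False))


def _band_map_from(entry) -> BandMap:
    if isinstance(entry, str):
        return BandMap.rgb() if entry.upper() == "RGB" else BandMap.ms()
    return BandMap(entry["sensor"], {k: int(v) for k, v
                                     in entry["bindings"].items()})


def load_task(path) -> BatchTask:
    """Read a batch-task file; relative paths resolve against the file."""
    path = Path(path)
    spec = _load_mapping(path)
    root = path.parent

    def resolve(p):
        return p if p is None else str((root / p).resolve())

    dates = []
    for entry in spec["dates"]:
        panels = None
        if entry.get("panels_shp") and entry.get("panels_csv"):
            from .synthetic_fixtures import load_panels
            panels = load_panels(resolve(entry["panels_shp"]),
                                 resolve(entry["panels_csv"]))
        dates.append(DateInputs(
            date=_dt.date.fromisoformat(str(entry["date"])),
            rgb=resolve(entry.get("rgb")),
            ms=resolve(entry.get("ms")),
            dsm=resolve(entry.get("dsm")),
            panels=panels,
        ))
    strategy_spec = spec.get("strategy")
    if isinstance(strategy_spec, str):
        strategy = load_strategy(resolve(strategy_spec))
    else:
        strategy = strategy_from_dict(strategy_spec)
    band_maps = {role: _band_map_from(entry)
                 for role, entry in spec.get("band_maps", {}).items()}
    return BatchTask(
        task_name=spec.get("task_name", path.stem),
        dates=dates,
        roi_path=resolve(spec["roi_path"]),
        strategy=strategy,
        output_root=resolve(spec.get("output_root", "output")),
        band_maps=band_maps,
        database=resolve(spec.get("database")),
        write_xlsx=bool(spec.get("write_xlsx", False)),
    )
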