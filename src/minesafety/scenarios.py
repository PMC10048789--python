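"""Scenario batteries: new-mine / production-mine runs and influence rankings.

A scenario fixes the initial safety level (HV), a baseline construction
standard (AV) applied to every element, and optional AV overrides for single
elements, element categories, or whole layers.  Influence experiments raise
one factor's construction standard at a time and rank factors by the
time-averaged difference they induce in a response stock — the package's
quantitative reading of "degree of influence", since only orderings are
reported for the original experiments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cause_weights import SchemaError
from .model24 import ModelParameters, simulate
from .sd_engine import SimulationConfig, Trajectory

__all__ = [
    "Scenario",
    "SummaryMetrics",
    "InfluenceRanking",
    "LAYER_LABELS",
    "category_labels",
    "run_scenario",
    "summarize_trajectory",
    "layer_influence_experiment",
    "element_influence_experiment",
    "grid_run",
]

#: layer label -> the element-AV codes that the layer's construction raises
LAYER_LABELS = ("safety culture", "safety management system", "safety ability")

#: response stock per layer and per element group
_LAYER_RESPONSE = {"safety culture": "SC",
                   "safety management system": "SM",
                   "safety ability": "SA"}
_GROUP_RESPONSE = {"a": "SC", "b": "SM2", "c": "SM3", "d": "SM",
                   "e": "SA1", "f": "SA2", "g": "SA4", "h": "SA"}

#: display names of the composite categories of groups d and h
_D_CATEGORY_LABELS = {
    "SM1": "safety policy",
    "SM2": "safety management organizational structure",
    "SM3": "safety management procedures",
}
_H_CATEGORY_LABELS = {
    "SA1": "safety knowledge",
    "SA2": "safety awareness",
    "SA3": "safety habits",
    "SA4": "safety psychology",
}


def _layer_codes(params: ModelParameters) -> dict[str, tuple[str, ...]]:
    g = params.taxonomy.groups
    return {
        "safety culture": tuple(g["a"]),
        "safety management system": ("SM1",) + tuple(g["b"]) + tuple(g["c"]),
        "safety ability": tuple(g["e"]) + tuple(g["f"]) + tuple(g["g"]) + ("SA31",),
    }


def _category_codes(params: ModelParameters,
                    group_id: str) -> dict[str, tuple[str, ...]]:
    """AV element codes raised when one category of a group is raised."""
    g = params.taxonomy.groups
    if group_id in ("a", "b", "c", "e", "f", "g"):
        return {code: (code,) for code in g[group_id]}
    if group_id == "d":
        return {"SM1": ("SM1",), "SM2": tuple(g["b"]), "SM3": tuple(g["c"])}
    if group_id == "h":
        return {"SA1": tuple(g["e"]), "SA2": tuple(g["f"]),
                "SA3": ("SA31",), "SA4": tuple(g["g"])}
    raise SchemaError(f"unknown group {group_id!r}")


def category_labels(params: ModelParameters, group_id: str) -> dict[str, str]:
    """Display label per category of a weight group."""
    if group_id == "a":
        return dict(params.a_category_map)
    if group_id == "d":
        return dict(_D_CATEGORY_LABELS)
    if group_id == "h":
        return dict(_H_CATEGORY_LABELS)
    return {code: code for code in _category_codes(params, group_id)}


@dataclass(frozen=True)
class Scenario:
    """One simulation setting: safety level, baseline AV, and AV overrides.

    ``overrides`` maps an element code, a group id (``a`` .. ``h``), a group-d
    or -h category code (e.g. ``SM2``, ``SA1``), or a layer label to the AV
    applied to the corresponding elements.
    """

    label: str
    hv: float = 0.0
    av: float = 60.0
    overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.av <= 100:
            raise ValueError(f"baseline AV {self.av} outside [0, 100]")
        for key, v in self.overrides.items():
            if not 0 <= v <= 100:
                raise ValueError(f"override {key!r}={v} outside [0, 100]")

    def resolve_av(self, params: ModelParameters) -> dict[str, float]:
        from .model24 import uniform_av

        av = uniform_av(self.av, params.taxonomy)
        layers = _layer_codes(params)
        for key, value in self.overrides.items():
            if key in av:
                codes: Sequence[str] = (key,)
            elif key in params.taxonomy.groups:
                codes = sum((_category_codes(params, key)[c]
                             for c in _category_codes(params, key)), ())
            elif key in _D_CATEGORY_LABELS:
                codes = _category_codes(params, "d")[key]
            elif key in _H_CATEGORY_LABELS:
                codes = _category_codes(params, "h")[key]
            elif key in layers:
                codes = layers[key]
            else:
                raise SchemaError(f"unknown override target {key!r}")
            for c in codes:
                av[c] = float(value)
        return av


@dataclass(frozen=True)
class SummaryMetrics:
    """Peak / trough / final summary of one stock's trajectory.

    The peak is the earliest grid argmax; the trough is the earliest argmin
    over times strictly after the peak, reported only when such times exist
    (a series peaking at the end of the horizon has no trough).
    """

    peak_value: float
    peak_time: float
    trough_time: float | None
    final_value: float


@dataclass(frozen=True)
class InfluenceRanking:
    """Factors ordered by descending effect size on a response stock."""

    response_stock: str
    entries: tuple[tuple[str, float], ...]  # (factor label, effect)

    def labels(self) -> tuple[str, ...]:
        return tuple(lbl for lbl, _ in self.entries)

    def effects(self) -> dict[str, float]:
        return dict(self.entries)

    def to_records(self) -> list[dict]:
        return [{"factor": lbl, "effect": eff, "rank": i + 1}
                for i, (lbl, eff) in enumerate(self.entries)]

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_records(), fh, indent=2)


def run_scenario(scenario: Scenario, params: ModelParameters,
                 config: SimulationConfig = SimulationConfig()) -> Trajectory:
    """Simulate one scenario: stocks start at HV, AV overrides applied."""
    p = replace(params, av=scenario.resolve_av(params), hv=scenario.hv)
    return simulate(p, config)


def summarize_trajectory(traj: Trajectory) -> dict[str, SummaryMetrics]:
    """Per-stock peak/trough/final summary (earliest-time tie-breaking)."""
    out = {}
    for stock in traj.stock_order:
        v = traj[stock]
        i_peak = int(np.argmax(v))
        trough_time = None
        tail = v[i_peak + 1:]
        if tail.size:
            trough_time = float(traj.times[i_peak + 1 + int(np.argmin(tail))])
        out[stock] = SummaryMetrics(
            peak_value=float(v[i_peak]),
            peak_time=float(traj.times[i_peak]),
            trough_time=trough_time,
            final_value=float(v[-1]),
        )
    return out


def _mean_difference(expt: Trajectory, base: Trajectory, stock: str,
                     window: tuple[float, float] | None) -> float:
    mask = np.ones_like(base.times, dtype=bool)
    if window is not None:
        lo, hi = window
        mask = (base.times >= lo) & (base.times <= hi)
    return float(np.mean(expt[stock][mask] - base[stock][mask]))


def _ranked(response: str, effects: Mapping[str, float]) -> InfluenceRanking:
    entries = sorted(effects.items(), key=lambda kv: -kv[1])
    return InfluenceRanking(response_stock=response, entries=tuple(entries))


def layer_influence_experiment(
    hv: float,
    baseline_av: float,
    raised_av: float,
    params: ModelParameters,
    config: SimulationConfig = SimulationConfig(),
    window: tuple[float, float] | None = None,
) -> InfluenceRanking:
    """Rank the three layers by their effect on safety acts.

    One run per layer with only that layer's element AVs raised from
    ``baseline_av`` to ``raised_av``; effect = time-averaged difference in
    the UA trajectory against the all-baseline run.
    """
    if raised_av < baseline_av:
        raise ValueError("raised_av must be >= baseline_av")
    base = run_scenario(Scenario("baseline", hv, baseline_av), params, config)
    effects = {}
    for layer in LAYER_LABELS:
        sc = Scenario(layer, hv, baseline_av, overrides={layer: raised_av})
        effects[layer] = _mean_difference(
            run_scenario(sc, params, config), base, "UA", window)
    return _ranked("UA", effects)


def element_influence_experiment(
    group_id: str,
    hv: float,
    baseline_av: float,
    raised_av: float,
    params: ModelParameters,
    config: SimulationConfig = SimulationConfig(),
    response_stock: str | None = None,
    window: tuple[float, float] | None = None,
) -> InfluenceRanking:
    """Rank one group's element categories by effect on their parent stock.

    One run per category with only its AV raised; effect = time-averaged
    difference of the response stock against the all-baseline run.
    """
    if raised_av < baseline_av:
        raise ValueError("raised_av must be >= baseline_av")
    if group_id not in _GROUP_RESPONSE:
        raise SchemaError(f"unknown group {group_id!r}")
    response = response_stock or _GROUP_RESPONSE[group_id]
    labels = category_labels(params, group_id)
    categories = _category_codes(params, group_id)
    base = run_scenario(Scenario("baseline", hv, baseline_av), params, config)
    effects = {}
    for cat, codes in categories.items():
        sc = Scenario(cat, hv, baseline_av,
                      overrides={c: raised_av for c in codes})
        effects[labels[cat]] = _mean_difference(
            run_scenario(sc, params, config), base, response, window)
    return _ranked(response, effects)


def grid_run(
    hv_set: Sequence[float],
    av_set: Sequence[float],
    params: ModelParameters,
    config: SimulationConfig = SimulationConfig(),
) -> pd.DataFrame:
    """Cartesian HV x AV battery, one tidy summary row per (scenario, stock)."""
    if not len(hv_set) or not len(av_set):
        raise ValueError("hv_set and av_set must be nonempty")
    rows = []
    for hv in hv_set:
        for av in av_set:
            label = f"hv{hv:g}_av{av:g}"
            traj = run_scenario(Scenario(label, hv, av), params, config)
            for stock, sm in summarize_trajectory(traj).items():
                rows.append({
                    "scenario": label, "hv": hv, "av": av, "stock": stock,
                    "peak_value": sm.peak_value, "peak_time": sm.peak_time,
                    "trough_time": sm.trough_time,
                    "final_value": sm.final_value,
                })
    return pd.DataFrame(rows)
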