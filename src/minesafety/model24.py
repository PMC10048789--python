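"""Rate equations of the safety-culture / management-system / ability model.

The system tracks eleven stocks on a 0-1 scale over a 24-month horizon:

* ``SC`` — safety culture, fed by four weighted culture element categories;
* ``SM`` — safety management system, with sub-system stocks ``SM1`` (safety
  policy), ``SM2`` (organizational structure, three weighted sub-elements)
  and ``SM3`` (procedures, seven weighted sub-elements);
* ``SA`` — individual safety ability, with component stocks ``SA1``
  (knowledge, seven sub-elements), ``SA2`` (awareness, three), ``SA3``
  (habits, one) and ``SA4`` (psychology, four);
* ``UA`` — safety acts (higher = more consistently safe behaviour).

Element construction standards (AV, 0-100) drive saturating uptake rates of
the form ``(1 - 2**(-S/80)) * 2**(-t/6)``: half-saturation at a weighted AV
sum of 80, and a construction-effort half-life of six months.  Layer-to-layer
transmission (culture -> management system -> ability) and the negative
feedback of safety acts on the three upper layers pass through first-order
material delays.  Safety acts themselves rise with the ability level, damped
by the level already attained; no outflow is modelled by default.

All exponentials use base 2 (the original equations carry ln2 factors), so
each constant is readable as a half-saturation point or half-life.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple

import yaml

from .cause_weights import (
    DEFAULT_TAXONOMY,
    CauseTaxonomy,
    WeightTable,
    default_weight_table,
)
from .sd_engine import Delay1State, SimulationConfig, Trajectory, delay1_init, integrate

__all__ = [
    "STOCK_ORDER",
    "DELAY_NAMES",
    "AV_ELEMENT_CODES",
    "ModelOptions",
    "ModelParameters",
    "ModelState",
    "uniform_av",
    "element_uptake",
    "layer_uptake_core",
    "feedback_decay_core",
    "acts_uptake",
    "compute_rates",
    "default_parameters",
    "simulate",
    "DomainError",
]

STOCK_ORDER: tuple[str, ...] = (
    "SC", "SM", "SM1", "SM2", "SM3", "SA", "SA1", "SA2", "SA3", "SA4", "UA",
)

#: the five first-order delays and their default delay times (months)
DEFAULT_DELAY_TIMES: dict[str, float] = {
    "SC_down": 1.0,
    "SM_up": 0.25,
    "SM_down": 0.5,
    "SA_up": 0.25,
    "SA_down": 0.25,
}
DELAY_NAMES: tuple[str, ...] = tuple(DEFAULT_DELAY_TIMES)

#: weight groups whose elements carry construction-standard AVs, plus the two
#: single-element stocks (safety policy SM1 and the habits element SA31)
_AV_GROUPS = ("a", "b", "c", "e", "f", "g")
_AV_SINGLETONS = ("SM1", "SA31")


def _av_codes(taxonomy: CauseTaxonomy = DEFAULT_TAXONOMY) -> tuple[str, ...]:
    codes: list[str] = []
    for g in _AV_GROUPS:
        codes.extend(taxonomy.groups[g])
    codes.extend(_AV_SINGLETONS)
    return tuple(codes)


AV_ELEMENT_CODES: tuple[str, ...] = _av_codes()


class DomainError(ValueError):
    """Raised when a rate-core argument leaves its stated range."""


def uniform_av(value: float,
               taxonomy: CauseTaxonomy = DEFAULT_TAXONOMY) -> dict[str, float]:
    """Construction standard ``value`` applied to every element."""
    if not 0 <= value <= 100:
        raise DomainError(f"AV must lie in [0, 100], got {value}")
    return {code: float(value) for code in _av_codes(taxonomy)}


@dataclass(frozen=True)
class ModelOptions:
    """Switches for the structurally ambiguous parts of the model.

    sm1
        ``"exogenous"`` (default): safety policy is a constant at AV_SM1/100
        — policy is promulgated, not built up over time; ``"stock"``: SM1
        accumulates like the single-element habits stock.
    sa_damping
        Self-damping term of the ability-layer uptake: ``"sm"`` (default, as
        the equation list has it) or the symmetric ``"sa"`` reading.
    ua_outflow
        ``"none"`` (default: no printed outflow of safety acts) or
        ``"feedback"`` for an exploratory decay of the same form as the
        upper-layer feedback.
    delay_init
        DELAY1 initialization, ``"steady"`` or ``"empty"``.
    """

    sm1: str = "exogenous"
    sa_damping: str = "sm"
    ua_outflow: str = "none"
    delay_init: str = "steady"

    def __post_init__(self) -> None:
        checks = {
            "sm1": ("exogenous", "stock"),
            "sa_damping": ("sm", "sa"),
            "ua_outflow": ("none", "feedback"),
            "delay_init": ("steady", "empty"),
        }
        for name, allowed in checks.items():
            if getattr(self, name) not in allowed:
                raise ValueError(
                    f"option {name}={getattr(self, name)!r}; allowed {allowed}"
                )


#: default display mapping of the four culture element categories; the
#: weight-index-to-category assignment is configurable, not fixed.
DEFAULT_A_CATEGORY_MAP: dict[str, str] = {
    "SC1": "safety concept elements",
    "SC2": "safety discipline elements",
    "SC3": "safety responsibility elements",
    "SC4": "safety measures elements",
}


@dataclass(frozen=True)
class ModelParameters:
    """Weights, construction standards, and rate constants of the model."""

    weights: WeightTable = field(default_factory=default_weight_table)
    av: Mapping[str, float] = field(default_factory=lambda: uniform_av(60.0))
    hv: float = 0.0
    gain: float = 1.5                      # layer-uptake gain
    sat_denominator: float = 80.0          # AV half-saturation sum
    time_halflife: float = 6.0             # months; construction-effort decay
    act_feedback_divisor: float = 4.0      # UA half-saturation of feedback
    upstream_divisor: float = 2.0          # upstream-level half-saturation
    delay_times: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DELAY_TIMES))
    options: ModelOptions = field(default_factory=ModelOptions)
    a_category_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_A_CATEGORY_MAP))
    taxonomy: CauseTaxonomy = DEFAULT_TAXONOMY

    def __post_init__(self) -> None:
        for code in _av_codes(self.taxonomy):
            v = self.av.get(code)
            if v is None:
                raise ValueError(f"missing AV for element {code!r}")
            if not 0 <= v <= 100:
                raise DomainError(f"AV[{code!r}]={v} outside [0, 100]")
        if not 0 <= self.hv <= 1:
            raise DomainError(f"hv={self.hv} outside [0, 1]")
        for name, val in (("gain", self.gain),
                          ("sat_denominator", self.sat_denominator),
                          ("time_halflife", self.time_halflife),
                          ("act_feedback_divisor", self.act_feedback_divisor),
                          ("upstream_divisor", self.upstream_divisor)):
            if val <= 0:
                raise ValueError(f"{name} must be > 0, got {val}")
        if set(self.delay_times) != set(DEFAULT_DELAY_TIMES):
            raise ValueError(
                f"delay_times must name exactly {sorted(DEFAULT_DELAY_TIMES)}"
            )
        if any(t <= 0 for t in self.delay_times.values()):
            raise ValueError("all delay times must be > 0")

    # -- weighted AV sums -------------------------------------------------
    def weighted_av(self, group_id: str) -> float:
        codes = self.taxonomy.groups[group_id]
        w = self.weights[group_id]
        return float(sum(wi * self.av[c] for wi, c in zip(w, codes)))

    def with_av(self, av: Mapping[str, float]) -> "ModelParameters":
        return replace(self, av=dict(av))

    def with_hv(self, hv: float) -> "ModelParameters":
        return replace(self, hv=hv)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "weights": self.weights.to_dict(),
            "av": dict(self.av),
            "hv": self.hv,
            "constants": {
                "gain": self.gain,
                "sat_denominator": self.sat_denominator,
                "time_halflife": self.time_halflife,
                "act_feedback_divisor": self.act_feedback_divisor,
                "upstream_divisor": self.upstream_divisor,
            },
            "delays": dict(self.delay_times),
            "options": {
                "sm1": self.options.sm1,
                "sa_damping": self.options.sa_damping,
                "ua_outflow": self.options.ua_outflow,
                "delay_init": self.options.delay_init,
            },
            "a_category_map": dict(self.a_category_map),
        }

    @classmethod
    def from_dict(cls, data: Mapping,
                  taxonomy: CauseTaxonomy = DEFAULT_TAXONOMY) -> "ModelParameters":
        kwargs: dict = {"taxonomy": taxonomy}
        if "weights" in data:
            kwargs["weights"] = WeightTable(data["weights"], taxonomy)
        av = data.get("av", data.get("av_all"))
        if av is not None:
            kwargs["av"] = uniform_av(av, taxonomy) if isinstance(
                av, (int, float)) else dict(av)
        if "hv" in data:
            kwargs["hv"] = float(data["hv"])
        for key in data.get("constants", {}):
            kwargs[key] = float(data["constants"][key])
        if "delays" in data:
            kwargs["delay_times"] = {k: float(v)
                                     for k, v in data["delays"].items()}
        if "options" in data:
            kwargs["options"] = ModelOptions(**data["options"])
        if "a_category_map" in data:
            kwargs["a_category_map"] = dict(data["a_category_map"])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path,
                  taxonomy: CauseTaxonomy = DEFAULT_TAXONOMY) -> "ModelParameters":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh), taxonomy)


def default_parameters(av: float = 60.0, hv: float = 0.0,
                       **overrides) -> ModelParameters:
    """Model parameterisation with the published weights and constants."""
    return ModelParameters(av=uniform_av(av), hv=hv, **overrides)


@dataclass(frozen=True)
class ModelState:
    """Stock values plus the five DELAY1 side states at one instant."""

    stocks: Mapping[str, float]
    delays: Mapping[str, Delay1State]

    def __post_init__(self) -> None:
        missing = set(STOCK_ORDER) - set(self.stocks)
        if missing:
            raise ValueError(f"missing stocks {sorted(missing)}")
        for s in STOCK_ORDER:
            v = self.stocks[s]
            if not 0 <= v <= 1:
                raise DomainError(f"stock {s}={v} outside [0, 1]")
        if set(self.delays) != set(DELAY_NAMES):
            raise ValueError(f"delays must name exactly {sorted(DELAY_NAMES)}")


# ---------------------------------------------------------------------------
# rate cores
# ---------------------------------------------------------------------------

def element_uptake(weighted_av_sum: float, time: float,
                   sat_denominator: float = 80.0,
                   time_halflife: float = 6.0) -> float:
    """Uptake of an element-driven stock: ``(1 - 2**(-S/80)) * 2**(-t/6)``.

    Saturating in the weighted AV sum ``S`` (half-saturation at
    ``sat_denominator``) and decaying in time with the construction-effort
    half-life.
    """
    if weighted_av_sum < 0:
        raise DomainError(f"weighted AV sum must be >= 0, got {weighted_av_sum}")
    return (1.0 - 2.0 ** (-weighted_av_sum / sat_denominator)) \
        * 2.0 ** (-time / time_halflife)


def layer_uptake_core(upstream: float, weighted_substock_sum: float, n: int,
                      self_level: float, gain: float = 1.5,
                      upstream_divisor: float = 2.0) -> float:
    """Pre-delay uptake of a layer stock fed by its upstream layer.

    ``gain * (1 - 2**(-up/2)) * (1 - 2**(-W/n)) * 2**(-self)`` — zero when
    either the upstream level or the weighted sub-stock sum W is zero, and
    damped by the level already attained.
    """
    if n <= 0:
        raise DomainError(f"group size n must be > 0, got {n}")
    if not 0 <= upstream <= 1:
        raise DomainError(f"upstream level {upstream} outside [0, 1]")
    if weighted_substock_sum < 0:
        raise DomainError("weighted sub-stock sum must be >= 0")
    return gain * (1.0 - 2.0 ** (-upstream / upstream_divisor)) \
        * (1.0 - 2.0 ** (-weighted_substock_sum / n)) \
        * 2.0 ** (-self_level)


def feedback_decay_core(ua_level: float,
                        act_feedback_divisor: float = 4.0) -> float:
    """Pre-delay negative feedback of safety acts: ``1 - 2**(-UA/4)``."""
    if not 0 <= ua_level <= 1:
        raise DomainError(f"UA level {ua_level} outside [0, 1]")
    return 1.0 - 2.0 ** (-ua_level / act_feedback_divisor)


def acts_uptake(sa_level: float, ua_level: float,
                upstream_divisor: float = 2.0) -> float:
    """Safety-acts inflow ``(1 - 2**(-SA/2)) * 2**(-UA)``."""
    if not 0 <= sa_level <= 1:
        raise DomainError(f"SA level {sa_level} outside [0, 1]")
    if not 0 <= ua_level <= 1:
        raise DomainError(f"UA level {ua_level} outside [0, 1]")
    return (1.0 - 2.0 ** (-sa_level / upstream_divisor)) * 2.0 ** (-ua_level)


# ---------------------------------------------------------------------------
# full rate assembly
# ---------------------------------------------------------------------------

class RatesResult(NamedTuple):
    rates: dict[str, float]
    delay_inputs: dict[str, float]
    delay_outputs: dict[str, float]


def _delay_inputs(stocks: Mapping[str, float], params: ModelParameters,
                  time: float) -> dict[str, float]:
    """Instantaneous pre-delay inputs of the five DELAY1s."""
    w = params.weights
    feedback = feedback_decay_core(stocks["UA"], params.act_feedback_divisor)
    sm_substock = float(sum(
        wi * stocks[c] for wi, c in zip(w["d"], params.taxonomy.groups["d"])))
    sa_substock = float(sum(
        wi * stocks[c] for wi, c in zip(w["h"], params.taxonomy.groups["h"])))
    sa_damp = stocks["SM"] if params.options.sa_damping == "sm" else stocks["SA"]
    return {
        "SC_down": feedback,
        "SM_down": feedback,
        "SA_down": feedback,
        "SM_up": layer_uptake_core(stocks["SC"], sm_substock, 3, stocks["SM"],
                                   params.gain, params.upstream_divisor),
        "SA_up": layer_uptake_core(stocks["SM"], sa_substock, 4, sa_damp,
                                   params.gain, params.upstream_divisor),
    }


def _net_rates(stocks: Mapping[str, float],
               delay_outputs: Mapping[str, float],
               params: ModelParameters, time: float) -> dict[str, float]:
    """Net rate of every stock given the current delay outputs."""
    p = params
    uptake = lambda gid: element_uptake(  # noqa: E731 - local shorthand
        p.weighted_av(gid), time, p.sat_denominator, p.time_halflife)

    rates: dict[str, float] = {}
    rates["SC"] = uptake("a") - delay_outputs["SC_down"]
    rates["SM"] = delay_outputs["SM_up"] - delay_outputs["SM_down"]
    if p.options.sm1 == "exogenous":
        rates["SM1"] = 0.0  # policy pinned at AV_SM1 / 100
    else:
        rates["SM1"] = element_uptake(p.av["SM1"], time,
                                      p.sat_denominator, p.time_halflife)
    rates["SM2"] = uptake("b")
    rates["SM3"] = uptake("c")
    rates["SA"] = delay_outputs["SA_up"] - delay_outputs["SA_down"]
    # knowledge uptake is damped by its own level rather than by time
    rates["SA1"] = (1.0 - 2.0 ** (-p.weighted_av("e") / p.sat_denominator)) \
        * 2.0 ** (-stocks["SA1"])
    rates["SA2"] = uptake("f")
    rates["SA3"] = element_uptake(p.av["SA31"], time,
                                  p.sat_denominator, p.time_halflife)
    rates["SA4"] = uptake("g")
    rates["UA"] = acts_uptake(stocks["SA"], stocks["UA"], p.upstream_divisor)
    if p.options.ua_outflow == "feedback":
        rates["UA"] -= feedback_decay_core(stocks["UA"], p.act_feedback_divisor)
    return rates


def compute_rates(state: ModelState, params: ModelParameters,
                  time: float) -> RatesResult:
    """Assemble every net stock rate and the pre-delay inputs at ``time``.

    Returns the net rates (using the current delay outputs), the
    instantaneous delay inputs with which the five delay states advance, and
    the delay outputs used.
    """
    delay_inputs = _delay_inputs(state.stocks, params, time)
    delay_outputs = {n: d.output for n, d in state.delays.items()}
    rates = _net_rates(state.stocks, delay_outputs, params, time)
    return RatesResult(rates, delay_inputs, delay_outputs)


def initial_stocks(params: ModelParameters) -> dict[str, float]:
    """Every stock starts at the safety level HV; exogenous policy is pinned."""
    stocks = {s: params.hv for s in STOCK_ORDER}
    if params.options.sm1 == "exogenous":
        stocks["SM1"] = params.av["SM1"] / 100.0
    return stocks


def simulate(params: ModelParameters,
             config: SimulationConfig = SimulationConfig()) -> Trajectory:
    """Integrate the full model on the configured time grid."""

    def rate_fn(stocks, delay_outputs, t):
        return _net_rates(stocks, delay_outputs, params, t)

    def delay_input_fn(stocks, t):
        return _delay_inputs(stocks, params, t)

    return integrate(
        initial_stocks(params),
        rate_fn,
        delay_input_fn,
        dict(params.delay_times),
        config,
        delay_init=params.options.delay_init,
    )
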