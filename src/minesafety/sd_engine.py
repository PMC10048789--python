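"""Minimal deterministic stock-and-flow integrator.

Fixed-step explicit Euler updates of stocks clamped to [0, 1], plus
first-order material delays (the classic DELAY1 of system-dynamics practice:
the delay output is an exponentially smoothed version of its input, with
``d(level)/dt = input - level/delay_time`` and ``output = level/delay_time``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "Delay1State",
    "Trajectory",
    "delay1_init",
    "delay1_step",
    "integrate",
    "InvalidDelayError",
    "NumericalFailureError",
]


class InvalidDelayError(ValueError):
    """Raised for a nonpositive delay time."""


class NumericalFailureError(ArithmeticError):
    """Raised when a rate becomes non-finite during integration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Time grid of the simulation, in months.

    The grid must close exactly: ``(t_end - t0) / dt`` is a positive integer.
    """

    t0: float = 0.0
    t_end: float = 24.0
    dt: float = 0.25

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        span = self.t_end - self.t0
        if span <= 0:
            raise ValueError("t_end must exceed t0")
        n = span / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"grid does not close: ({self.t_end} - {self.t0}) / {self.dt} "
                "is not an integer"
            )

    @property
    def n_steps(self) -> int:
        return int(round((self.t_end - self.t0) / self.dt))

    def time_grid(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_steps + 1)


@dataclass(frozen=True)
class Delay1State:
    """In-transit level of a first-order material delay."""

    level: float
    delay_time: float

    def __post_init__(self) -> None:
        if self.delay_time <= 0:
            raise InvalidDelayError(
                f"delay_time must be > 0, got {self.delay_time}"
            )

    @property
    def output(self) -> float:
        return self.level / self.delay_time


def delay1_init(input0: float, delay_time: float) -> Delay1State:
    """Initialize a DELAY1 at steady state: output(t0) equals input(t0)."""
    if delay_time <= 0:
        raise InvalidDelayError(f"delay_time must be > 0, got {delay_time}")
    return Delay1State(level=input0 * delay_time, delay_time=delay_time)


def delay1_step(state: Delay1State, input_rate: float, dt: float) -> Delay1State:
    """Advance a DELAY1 one Euler step: level += dt * (input - level/T)."""
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    new_level = state.level + dt * (input_rate - state.level / state.delay_time)
    return replace(state, level=new_level)


@dataclass(frozen=True)
class Trajectory:
    """Stock values sampled on the simulation time grid."""

    times: np.ndarray
    stocks: Mapping[str, np.ndarray]
    stock_order: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        order = self.stock_order or tuple(self.stocks)
        object.__setattr__(self, "stock_order", order)

    def __getitem__(self, stock: str) -> np.ndarray:
        return self.stocks[stock]

    def final(self, stock: str) -> float:
        return float(self.stocks[stock][-1])

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.times}
        data.update({s: self.stocks[s] for s in self.stock_order})
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        # fixed 6-decimal formatting keeps repeated runs byte-identical
        self.to_frame().to_csv(path, index=False, float_format="%.6f")


RateFunction = Callable[[Mapping[str, float], Mapping[str, float], float],
                        Mapping[str, float]]
DelayInputFunction = Callable[[Mapping[str, float], float], Mapping[str, float]]


def integrate(
    initial_stocks: Mapping[str, float],
    rate_fn: RateFunction,
    delay_input_fn: DelayInputFunction | None = None,
    delay_times: Mapping[str, float] | None = None,
    config: SimulationConfig = SimulationConfig(),
    delay_init: str = "steady",
    clamp: tuple[float, float] | None = (0.0, 1.0),
) -> Trajectory:
    """Integrate a clamped stock-and-flow system with DELAY1 side states.

    Parameters
    ----------
    initial_stocks
        Stock name -> value at ``config.t0``.
    rate_fn
        ``rate_fn(stocks, delay_outputs, t)`` returns one net rate per stock.
    delay_input_fn
        ``delay_input_fn(stocks, t)`` returns the instantaneous pre-delay
        input of every DELAY1 named in ``delay_times``.
    delay_times
        Delay name -> delay time in months.
    delay_init
        ``"steady"`` (level = input(t0) * T, so output(t0) = input(t0)) or
        ``"empty"`` (level = 0).
    clamp
        Bounds applied to every stock after each step; the default unit
        interval matches stocks defined as 0-100% ratios.  ``None`` leaves
        stocks unbounded (Vensim-like behaviour) for exploration.

    Each step applies explicit Euler with clamping,
    ``stock <- clip(stock + dt * rate, *clamp)``, and advances every delay
    with the pre-delay input evaluated at the current state.  The trajectory
    records every grid point including t0.
    """
    delay_times = dict(delay_times or {})
    if delay_times and delay_input_fn is None:
        raise ValueError("delay_times given without a delay_input_fn")
    if delay_init not in ("steady", "empty"):
        raise ValueError(f"unknown delay_init {delay_init!r}")

    def _clip(v: float) -> float:
        return float(np.clip(v, *clamp)) if clamp is not None else float(v)

    names = tuple(initial_stocks)
    state = {s: _clip(v) for s, v in initial_stocks.items()}

    delays: dict[str, Delay1State] = {}
    if delay_times:
        inputs0 = delay_input_fn(state, config.t0)
        for name, T in delay_times.items():
            if delay_init == "steady":
                delays[name] = delay1_init(inputs0[name], T)
            else:
                delays[name] = Delay1State(level=0.0, delay_time=T)

    times = config.time_grid()
    out = {s: np.empty(len(times)) for s in names}
    for s in names:
        out[s][0] = state[s]

    t = config.t0
    for k in range(config.n_steps):
        delay_inputs = delay_input_fn(state, t) if delay_times else {}
        delay_outputs = {n: d.output for n, d in delays.items()}
        rates = rate_fn(state, delay_outputs, t)
        for s in names:
            r = rates[s]
            if not np.isfinite(r):
                raise NumericalFailureError(
                    f"non-finite rate for stock {s!r} at t={t:g}"
                )
            state[s] = _clip(state[s] + config.dt * r)
        for n in delays:
            delays[n] = delay1_step(delays[n], delay_inputs[n], config.dt)
        t = times[k + 1]
        for s in names:
            out[s][k + 1] = state[s]

    return Trajectory(times=times, stocks=out, stock_order=names)
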