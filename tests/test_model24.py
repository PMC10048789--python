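"""Rate cores, full rate assembly (vs. an independent transcription), runs."""

import math
from dataclasses import replace

import numpy as np
import pytest

from minesafety.model24 import (
    DEFAULT_DELAY_TIMES,
    STOCK_ORDER,
    DomainError,
    ModelOptions,
    ModelParameters,
    ModelState,
    acts_uptake,
    compute_rates,
    default_parameters,
    element_uptake,
    feedback_decay_core,
    initial_stocks,
    layer_uptake_core,
    simulate,
    uniform_av,
)
from minesafety.sd_engine import Delay1State, SimulationConfig


class TestRateCores:
    @pytest.mark.parametrize("S,t,expected", [
        (80.0, 0.0, 0.5),    # half-saturation at the denominator
        (0.0, 0.0, 0.0),
        (0.0, 13.0, 0.0),
        (80.0, 6.0, 0.25),   # one construction half-life
    ])
    def test_element_uptake_closed_form(self, S, t, expected):
        assert element_uptake(S, t) == pytest.approx(expected, abs=1e-12)

    def test_element_uptake_monotone_in_standard(self):
        vals = [element_uptake(S, 3.0) for S in np.linspace(0, 100, 11)]
        assert np.all(np.diff(vals) > 0)

    def test_element_uptake_negative_sum_rejected(self):
        with pytest.raises(DomainError):
            element_uptake(-1.0, 0.0)

    @pytest.mark.parametrize("up,W,n,self_lvl,expected", [
        (0.0, 1.0, 3, 0.5, 0.0),
        (1.0, 0.0, 3, 0.5, 0.0),
        (1.0, 4.0, 4, 0.0, 1.5 * (1 - 2 ** -0.5) * 0.5),  # ~0.219670
    ])
    def test_layer_uptake_closed_form(self, up, W, n, self_lvl, expected):
        assert layer_uptake_core(up, W, n, self_lvl) == pytest.approx(
            expected, abs=1e-9)

    def test_layer_uptake_decreasing_in_self_level(self):
        vals = [layer_uptake_core(0.8, 1.5, 3, s)
                for s in np.linspace(0, 1, 5)]
        assert np.all(np.diff(vals) < 0)

    def test_layer_uptake_bad_group_size_rejected(self):
        with pytest.raises(DomainError):
            layer_uptake_core(0.5, 1.0, 0, 0.5)

    @pytest.mark.parametrize("ua,expected", [
        (0.0, 0.0),
        (1.0, 1 - 2 ** -0.25),   # ~0.159104
        (0.5, 1 - 2 ** -0.125),  # ~0.083000
    ])
    def test_feedback_decay_closed_form(self, ua, expected):
        assert feedback_decay_core(ua) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("sa,ua,expected", [
        (0.0, 0.3, 0.0),
        (1.0, 0.0, 1 - 2 ** -0.5),          # ~0.292893
        (1.0, 1.0, (1 - 2 ** -0.5) / 2),    # exactly half the previous
    ])
    def test_acts_uptake_closed_form(self, sa, ua, expected):
        assert acts_uptake(sa, ua) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("fn,args", [
        (feedback_decay_core, (1.5,)),
        (acts_uptake, (1.5, 0.0)),
        (acts_uptake, (0.5, -0.1)),
    ])
    def test_out_of_range_levels_rejected(self, fn, args):
        with pytest.raises(DomainError):
            fn(*args)

    def test_cores_bounded(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            up, w, s, ua = rng.uniform(0, 1, 4)
            assert 0 <= layer_uptake_core(up, w * 3, 3, s) <= 1.5
            assert 0 <= feedback_decay_core(ua) < 1
            assert 0 <= acts_uptake(s, ua) < 1


class TestDefaultParameters:
    def test_published_weight_vectors(self, params):
        np.testing.assert_allclose(params.weights["h"], [0.5, 0.1, 0.2, 0.2])
        np.testing.assert_allclose(params.weights["d"], [0.2, 0.5, 0.3])
        np.testing.assert_allclose(params.weights["g"],
                                   [0.4085, 0.2022, 0.2336, 0.1557])

    def test_constants_and_delays(self, params):
        assert (params.gain, params.sat_denominator, params.time_halflife,
                params.act_feedback_divisor, params.upstream_divisor) \
            == (1.5, 80.0, 6.0, 4.0, 2.0)
        assert dict(params.delay_times) == {
            "SC_down": 1.0, "SM_up": 0.25, "SM_down": 0.5,
            "SA_up": 0.25, "SA_down": 0.25}
        assert all(v == 60.0 for v in params.av.values())
        assert params.hv == 0.0

    @pytest.mark.parametrize("bad", [
        dict(hv=1.5),
        dict(gain=-1.0),
        dict(av={"SC1": 120.0}),
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises((DomainError, ValueError)):
            if "av" in bad:
                av = uniform_av(60.0)
                av.update(bad["av"])
                ModelParameters(av=av)
            else:
                default_parameters(**bad)

    def test_invalid_option_values_rejected(self):
        with pytest.raises(ValueError):
            ModelOptions(sm1="nope")

    def test_yaml_round_trip(self, tmp_path, params):
        p = replace(params, hv=0.25,
                    options=ModelOptions(sm1="stock", ua_outflow="feedback"))
        p.to_yaml(tmp_path / "p.yaml")
        q = ModelParameters.from_yaml(tmp_path / "p.yaml")
        assert q.to_dict() == p.to_dict()

    def test_scalar_av_expansion(self):
        p = ModelParameters.from_dict({"av_all": 80})
        assert all(v == 80.0 for v in p.av.values())


def transcribed_rates(stocks, params, t, delay_outputs):
    """Independent straight-line transcription of the thirteen rate equations.

    Written directly from the reconstructed equation list with explicit
    ``exp``/``log`` arithmetic; shares no code with the implementation.
    """
    w = params.weights
    av = params.av
    ln2 = math.log(2.0)

    def sat(x, denom):
        return 1.0 - math.exp(-ln2 * x / denom)

    s_a = sum(w["a"][i] * av[c] for i, c in enumerate(
        ["SC1", "SC2", "SC3", "SC4"]))
    s_b = sum(w["b"][i] * av[c] for i, c in enumerate(
        ["SM21", "SM22", "SM23"]))
    s_c = sum(w["c"][i] * av[c] for i, c in enumerate(
        ["SM31", "SM32", "SM33", "SM34", "SM35", "SM36", "SM37"]))
    s_e = sum(w["e"][i] * av[c] for i, c in enumerate(
        ["SA11", "SA12", "SA13", "SA14", "SA15", "SA16", "SA17"]))
    s_f = sum(w["f"][i] * av[c] for i, c in enumerate(
        ["SA21", "SA22", "SA23"]))
    s_g = sum(w["g"][i] * av[c] for i, c in enumerate(
        ["SA41", "SA42", "SA43", "SA44"]))

    time_decay = math.exp(-t * ln2 / 6.0)
    rates = {}
    rates["SC"] = sat(s_a, 80.0) * time_decay - delay_outputs["SC_down"]
    rates["SM"] = delay_outputs["SM_up"] - delay_outputs["SM_down"]
    rates["SM1"] = (0.0 if params.options.sm1 == "exogenous"
                    else sat(av["SM1"], 80.0) * time_decay)
    rates["SM2"] = sat(s_b, 80.0) * time_decay
    rates["SM3"] = sat(s_c, 80.0) * time_decay
    rates["SA"] = delay_outputs["SA_up"] - delay_outputs["SA_down"]
    rates["SA1"] = sat(s_e, 80.0) * math.exp(-stocks["SA1"] * ln2)
    rates["SA2"] = sat(s_f, 80.0) * time_decay
    rates["SA3"] = sat(av["SA31"], 80.0) * time_decay
    rates["SA4"] = sat(s_g, 80.0) * time_decay
    rates["UA"] = sat(stocks["SA"], 2.0) * math.exp(-stocks["UA"] * ln2)
    if params.options.ua_outflow == "feedback":
        rates["UA"] -= sat(stocks["UA"], 4.0)

    # pre-delay inputs of the five DELAY1s
    feedback = sat(stocks["UA"], 4.0)
    w_sm = (w["d"][0] * stocks["SM1"] + w["d"][1] * stocks["SM2"]
            + w["d"][2] * stocks["SM3"])
    w_sa = (w["h"][0] * stocks["SA1"] + w["h"][1] * stocks["SA2"]
            + w["h"][2] * stocks["SA3"] + w["h"][3] * stocks["SA4"])
    sa_damp = (stocks["SM"] if params.options.sa_damping == "sm"
               else stocks["SA"])
    inputs = {
        "SC_down": feedback,
        "SM_down": feedback,
        "SA_down": feedback,
        "SM_up": 1.5 * sat(stocks["SC"], 2.0) * sat(w_sm, 3.0)
        * math.exp(-stocks["SM"] * ln2),
        "SA_up": 1.5 * sat(stocks["SM"], 2.0) * sat(w_sa, 4.0)
        * math.exp(-sa_damp * ln2),
    }
    return rates, inputs


class TestComputeRates:
    def _random_state(self, rng):
        stocks = {s: float(rng.uniform(0, 1)) for s in STOCK_ORDER}
        delays = {n: Delay1State(level=float(rng.uniform(0, 0.5)),
                                 delay_time=T)
                  for n, T in DEFAULT_DELAY_TIMES.items()}
        return ModelState(stocks=stocks, delays=delays)

    @pytest.mark.parametrize("options", [
        ModelOptions(),
        ModelOptions(sm1="stock", sa_damping="sa", ua_outflow="feedback"),
    ])
    def test_matches_independent_transcription(self, options):
        rng = np.random.default_rng(1234)
        params = default_parameters(
            av=float(rng.uniform(0, 100)), options=options)
        for _ in range(1000):
            state = self._random_state(rng)
            t = float(rng.uniform(0, 24))
            result = compute_rates(state, params, t)
            exp_rates, exp_inputs = transcribed_rates(
                state.stocks, params, t, result.delay_outputs)
            for s in STOCK_ORDER:
                assert result.rates[s] == pytest.approx(
                    exp_rates[s], abs=1e-12), s
            for n in DEFAULT_DELAY_TIMES:
                assert result.delay_inputs[n] == pytest.approx(
                    exp_inputs[n], abs=1e-12), n

    def test_origin_is_fixed_point(self):
        params = default_parameters(av=0.0, hv=0.0,
                                    options=ModelOptions(sm1="stock"))
        state = ModelState(
            stocks={s: 0.0 for s in STOCK_ORDER},
            delays={n: Delay1State(0.0, T)
                    for n, T in DEFAULT_DELAY_TIMES.items()})
        result = compute_rates(state, params, 0.0)
        assert all(r == 0.0 for r in result.rates.values())

    def test_culture_rate_half_at_saturating_standard(self):
        params = default_parameters(av=80.0)
        state = ModelState(
            stocks={s: 0.0 for s in STOCK_ORDER},
            delays={n: Delay1State(0.0, T)
                    for n, T in DEFAULT_DELAY_TIMES.items()})
        assert compute_rates(state, params, 0.0).rates["SC"] == pytest.approx(
            0.5, abs=1e-12)


class TestSimulate:
    def test_all_zero_inputs_stay_identically_zero(self):
        params = default_parameters(av=0.0, hv=0.0,
                                    options=ModelOptions(sm1="stock"))
        traj = simulate(params)
        for s in STOCK_ORDER:
            assert np.all(traj[s] == 0.0), s

    def test_stocks_stay_in_unit_interval(self):
        traj = simulate(default_parameters(av=90.0, hv=0.5))
        for s in STOCK_ORDER:
            assert np.all((traj[s] >= 0.0) & (traj[s] <= 1.0)), s

    def test_exogenous_policy_pinned(self):
        traj = simulate(default_parameters(av=70.0))
        assert np.all(traj["SM1"] == 0.7)

    def test_inflow_only_substocks_nondecreasing_in_time(self):
        traj = simulate(default_parameters(av=75.0, hv=0.1))
        for s in ("SM2", "SM3", "SA2", "SA3", "SA4"):
            assert np.all(np.diff(traj[s]) >= -1e-12), s

    def test_substocks_nondecreasing_in_their_standards(self):
        lo = simulate(default_parameters(av=60.0))
        hi = simulate(default_parameters(av=80.0))
        for s in ("SM2", "SM3", "SA2", "SA3", "SA4"):
            assert np.all(hi[s] - lo[s] >= -1e-12), s

    def test_new_mine_trends(self):
        """Safety acts rise monotonically; the three layers rise then fall."""
        traj = simulate(default_parameters(av=80.0, hv=0.0))
        assert np.all(np.diff(traj["UA"]) >= -1e-15)
        for s in ("SC", "SM", "SA"):
            v = traj[s]
            i_first = int(np.argmax(v))
            i_last = len(v) - 1 - int(np.argmax(v[::-1]))
            assert 0 < i_first and i_last < len(v) - 1, s  # interior peak
            assert np.all(np.diff(v[:i_first + 1]) >= -1e-12), s  # rise
            assert np.all(np.diff(v[i_last:]) <= 1e-12), s        # fall
            assert v[-1] < v[i_first], s

    def test_step_halving_convergence(self):
        """Halving dt moves the horizon-end stocks by less than 0.01."""
        params = default_parameters(av=80.0)
        coarse = simulate(params, SimulationConfig(dt=0.25))
        fine = simulate(params, SimulationConfig(dt=0.125))
        for s in STOCK_ORDER:
            assert abs(coarse.final(s) - fine.final(s)) < 0.01, s

    def test_initial_stocks_at_safety_level(self):
        stocks = initial_stocks(default_parameters(av=60.0, hv=0.4))
        assert stocks["SM1"] == 0.6  # exogenous policy at AV/100
        assert all(stocks[s] == 0.4 for s in STOCK_ORDER if s != "SM1")
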