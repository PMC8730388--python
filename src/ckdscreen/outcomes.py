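"""QALY and cost accrual, discounting, and the cost-effectiveness comparison.

Each surviving, non-censored individual-year contributes an EQ-5D
utility keyed to the CKD stage (GFR band, with a separate RRT value),
renal-replacement costs while on RRT, annualized ACEI costs after a
positive test, and the testing-occasion costs of the cycle.  Costs and
QALYs are accumulated both raw and discounted at a fixed annual rate on
a shared clock (years since simulation start; year 0 undiscounted).

Scenario arms are summarized into the standard cost-effectiveness
outputs — lifetime RRT prevalence, mean ages at RRT start and death,
share censored at the age cap, QALYs and cost components per individual,
false-positive share — with normal-approximation 95% confidence
intervals, and compared against the base case as cost per QALY gained,
with and without the averted RRT costs.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtri

from .params import ParameterSet

__all__ = [
    "discount_factor",
    "accrue",
    "confidence_interval",
    "summarize_scenario",
    "compare_scenarios",
]

#: EUR per year of ACEI: the 100-day pharmacy price annualized.
DAYS_PER_YEAR = 365.25


def discount_factor(t, rate: float):
    """Discount factor (1+rate)^(-t) for year index ``t`` (0 = undiscounted)."""
    t_arr = np.asarray(t)
    if np.any(t_arr < 0):
        raise ValueError("year index must be >= 0")
    out = (1.0 + rate) ** (-t_arr.astype(float))
    return out if out.shape else float(out)


def accrue(state, p: ParameterSet, test_cost: np.ndarray) -> None:
    """Accumulate one cycle's QALYs and costs onto the state.

    Called after screening and mortality: only individuals alive at the
    end of the cycle accrue the year's utility, medication and RRT
    costs.  Testing costs were incurred during the cycle and are charged
    to everyone tested, alive or not.
    """
    from .progression import utility_stage  # deferred import (module cycle)

    c = p.compiled()
    df = discount_factor(state.t, p.discount_rate)
    act = state.active

    qaly = np.where(act, c.utility[utility_stage(state)], 0.0)
    state.qaly_undisc += qaly
    state.qaly_disc += qaly * df

    med = np.where(act & state.acei_from_test, p.c_med_100d * DAYS_PER_YEAR / 100.0, 0.0)
    state.cost_med_undisc += med
    state.cost_med_disc += med * df

    rrt = np.where(act & state.on_rrt, p.c_rrt_year, 0.0)
    state.cost_rrt_undisc += rrt
    state.cost_rrt_disc += rrt * df

    state.cost_test_undisc += test_cost
    state.cost_test_disc += test_cost * df

    state.years_stage3a5 += np.where(act & ((state.gfr < 60) | state.on_rrt), 1.0, 0.0)


def confidence_interval(values, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation CI: mean +/- z * sd / sqrt(n) (Wald for indicators)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values for a confidence interval")
    z = float(ndtri(0.5 + level / 2.0))
    mean = values.mean()
    half = z * values.std(ddof=0) / np.sqrt(values.size)
    return float(mean - half), float(mean + half)


def _mean_ci(values) -> dict:
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return {"mean": float("nan"), "ci": (float("nan"), float("nan")), "n": 0}
    if values.size == 1:
        return {"mean": float(values[0]), "ci": (float(values[0]), float(values[0])), "n": 1}
    return {"mean": float(values.mean()), "ci": confidence_interval(values), "n": int(values.size)}


def summarize_scenario(state, p: ParameterSet, name: str = "") -> dict:
    """Scenario summary over all simulated individuals, with 95% CIs."""
    pct = lambda ind: _mean_ci(np.asarray(ind, float) * 100.0)
    died = ~state.alive
    out = {
        "name": name,
        "n": state.n,
        "rrt_prevalence_pct": pct(state.on_rrt),
        "mean_age_at_rrt": _mean_ci(state.age_at_rrt[~np.isnan(state.age_at_rrt)]),
        "mean_age_at_death": _mean_ci(state.age_at_death[died]),
        "censored_pct": pct(state.censored & state.alive),
        "false_positive_pct": pct(state.false_positive),
        "mean_years_ckd3a5": _mean_ci(state.years_stage3a5),
        "capped_prob_events": int(state.capped_prob_events),
    }
    for disc in ("undisc", "disc"):
        out[f"qaly_{disc}"] = _mean_ci(getattr(state, f"qaly_{disc}"))
        for comp in ("test", "med", "rrt"):
            out[f"cost_{comp}_{disc}"] = _mean_ci(getattr(state, f"cost_{comp}_{disc}"))
    return out


def compare_scenarios(base: dict, alt: dict) -> dict:
    """Incremental results of a testing scenario against the base case.

    cost per QALY gained = (testing + medication costs) / QALY gained;
    the net variant subtracts the RRT costs averted relative to base.
    A non-positive QALY gain leaves the ratios undefined (None) with a
    diagnostic note.
    """
    if base["n"] != alt["n"]:
        raise ValueError("scenario summaries come from different population sizes")
    out = {"base": base["name"], "scenario": alt["name"]}
    for disc in ("undisc", "disc"):
        dq = alt[f"qaly_{disc}"]["mean"] - base[f"qaly_{disc}"]["mean"]
        extra = alt[f"cost_test_{disc}"]["mean"] + alt[f"cost_med_{disc}"]["mean"]
        saved_rrt = base[f"cost_rrt_{disc}"]["mean"] - alt[f"cost_rrt_{disc}"]["mean"]
        block = {"delta_qaly": dq, "extra_cost": extra, "saved_rrt_cost": saved_rrt}
        if dq > 0:
            block["cost_per_qaly"] = extra / dq
            block["net_cost_per_qaly"] = (extra - saved_rrt) / dq
        else:
            block["cost_per_qaly"] = None
            block["net_cost_per_qaly"] = None
            block["note"] = "QALY gain is not positive; ratio undefined"
        out[disc] = block
    return out
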