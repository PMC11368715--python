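"""One-compartment concentration-time solutions.

Closed forms for first-order oral absorption and constant-rate IV infusion,
multiple-dose superposition, and analytic steady-state troughs; plus
numerical-ODE references (linear and Michaelis-Menten elimination) used as
independent oracles and for the nonlinear-elimination comparison model.

Units are mg, L, h throughout, so concentrations come out in mg/L, which is
numerically identical to ug/mL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .records import DoseEvent, ROUTE_IV, ROUTE_ORAL

#: Relative |ka - k| / ka below which the oral solution switches to its
#: analytic ka == k limiting form.
_KA_K_SWITCH = 1e-6


@dataclass(frozen=True)
class PKParameters:
    """Structural parameters: clearance CL (L/h), volume V (L), absorption
    rate constant ka (1/h), oral bioavailability F."""

    CL: float
    V: float
    ka: float = 1.1
    F: float = 1.0

    def __post_init__(self) -> None:
        if self.CL <= 0 or self.V <= 0 or self.ka <= 0 or self.F <= 0:
            raise ValueError("all PK parameters must be > 0")

    @property
    def k(self) -> float:
        """First-order elimination rate constant CL/V (1/h)."""
        return self.CL / self.V


def conc_oral(dose: float, t, p: PKParameters):
    """Concentration after a single oral dose at t = 0.

    Bateman solution F*D*ka/(V*(ka-k)) * (e^(-k t) - e^(-ka t)); when
    ka ~= k the limiting form F*D*ka*t*e^(-k t)/V is used.
    """
    t = np.asarray(t, dtype=float)
    k = p.k
    c = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    if abs(p.ka - k) <= _KA_K_SWITCH * p.ka:
        c[pos] = p.F * dose * p.ka * tp * np.exp(-k * tp) / p.V
    else:
        a = p.F * dose * p.ka / (p.V * (p.ka - k))
        c[pos] = a * (np.exp(-k * tp) - np.exp(-p.ka * tp))
    return c if c.ndim else float(c)


def conc_infusion(dose: float, duration: float, t, p: PKParameters):
    """Concentration during/after a constant-rate IV infusion started at
    t = 0 with total ``dose`` over ``duration`` hours.

    C = (R/CL)(1 - e^(-k t))                 for t <= duration
    C = (R/CL)(1 - e^(-k Tinf)) e^(-k (t-Tinf))  afterwards,
    continuous at t = duration.
    """
    if duration <= 0:
        raise ValueError("infusion duration must be > 0")
    t = np.asarray(t, dtype=float)
    k = p.k
    rate = dose / duration
    te = np.clip(t, 0.0, duration)            # time infused so far
    td = np.clip(t - duration, 0.0, None)     # time since end of infusion
    c = (rate / p.CL) * (1.0 - np.exp(-k * te)) * np.exp(-k * td)
    c = np.where(t > 0, c, 0.0)
    return c if c.ndim else float(c)


def superpose(doses: Iterable[DoseEvent], times, p: PKParameters,
              structural: str = "one_compartment_linear"):
    """Concentration series for a multi-dose history by linear superposition.

    Valid only for the linear structural model; the Michaelis-Menten
    alternative must go through :func:`conc_mm_ode`.
    """
    if structural != "one_compartment_linear":
        raise ValueError(
            "superposition is invalid for nonlinear elimination; "
            "use conc_mm_ode for the Michaelis-Menten model")
    times = np.asarray(times, dtype=float)
    c = np.zeros_like(times)
    for dose in _expand(doses):
        rel = times - dose.time
        if dose.route == ROUTE_ORAL:
            c += conc_oral(dose.amount, rel, p)
        else:
            c += conc_infusion(dose.amount, dose.infusion_duration, rel, p)
    return c if c.ndim else float(c)


def steady_state_trough(dose: float, interval: float, route: str,
                        duration: float, p: PKParameters) -> float:
    """Trough immediately before the next dose at steady state under
    q-``interval`` dosing (geometric-series accumulation closed form)."""
    k = p.k
    acc = 1.0 / (1.0 - np.exp(-k * interval))
    if route == ROUTE_IV:
        if interval <= duration:
            raise ValueError("dosing interval must exceed infusion duration")
        rate = dose / duration
        single = (rate / p.CL) * (1.0 - np.exp(-k * duration)) \
            * np.exp(-k * (interval - duration))
        return float(single * acc)
    if abs(p.ka - k) <= _KA_K_SWITCH * p.ka:
        # ka -> k limit: -d/dk [e^(-k tau) / (1 - e^(-k tau))]
        e = np.exp(-k * interval)
        return float(p.F * dose * p.ka / p.V * interval * e / (1 - e) ** 2)
    a = p.F * dose * p.ka / (p.V * (p.ka - k))
    ek, eka = np.exp(-k * interval), np.exp(-p.ka * interval)
    return float(a * (ek / (1.0 - ek) - eka / (1.0 - eka)))


# ---------------------------------------------------------------------------
# Numerical oracles

def _expand(doses: Iterable[DoseEvent]) -> list[DoseEvent]:
    out: list[DoseEvent] = []
    for d in doses:
        out.extend(d.expand())
    return sorted(out, key=lambda d: d.time)


def _integrate_events(doses: Sequence[DoseEvent], times, rhs_elim, V: float,
                      ka: float, F: float, rtol: float, atol: float):
    """Piecewise integration of depot/central amounts over a dose history.

    ``rhs_elim(central_amount)`` returns the elimination rate in mg/h.
    Oral doses add F*amount to the depot at their event time; infusions
    contribute a constant central input rate while running.
    """
    doses = _expand(doses)
    times = np.asarray(times, dtype=float)
    breaks = {0.0}
    for d in doses:
        breaks.add(d.time)
        if d.route == ROUTE_IV:
            breaks.add(d.time + d.infusion_duration)
    breaks |= set(times.tolist())
    grid = sorted(b for b in breaks if b >= 0)

    def inrate(t: float) -> float:
        r = 0.0
        for d in doses:
            if d.route == ROUTE_IV and d.time <= t < d.time + d.infusion_duration:
                r += d.amount / d.infusion_duration
        return r

    def rhs(t, y):
        depot, central = y
        return [-ka * depot, ka * depot + inrate(t) - rhs_elim(central)]

    y = np.array([0.0, 0.0])
    conc = {}
    for t0, t1 in zip(grid, grid[1:]):
        for d in doses:
            if d.route == ROUTE_ORAL and np.isclose(d.time, t0):
                y[0] += F * d.amount
        if t0 in set(times.tolist()):
            conc[t0] = y[1] / V
        mid = 0.5 * (t0 + t1)
        sol = solve_ivp(rhs, (t0, t1), y, method="DOP853", rtol=rtol,
                        atol=atol, args=(), dense_output=False,
                        first_step=min(t1 - t0, 0.1))
        if not sol.success:
            raise RuntimeError(f"ODE integration failed on [{t0}, {t1}]: "
                               f"{sol.message}")
        del mid
        y = sol.y[:, -1]
    for d in doses:
        if d.route == ROUTE_ORAL and np.isclose(d.time, grid[-1]):
            y[0] += F * d.amount
    conc[grid[-1]] = y[1] / V
    return np.array([conc[t] for t in times])


def conc_ode(doses: Iterable[DoseEvent], times, p: PKParameters,
             rtol: float = 1e-10, atol: float = 1e-12):
    """Linear-elimination ODE reference solution (oracle for the closed
    forms; not used in estimation)."""
    k = p.k
    return _integrate_events(list(doses), times, lambda a: k * a, p.V, p.ka,
                             p.F, rtol, atol)


def conc_mm_ode(doses: Iterable[DoseEvent], times, Vmax: float, Km: float,
                V: float, ka: float = 1.1, F: float = 1.0,
                rtol: float = 1e-8, atol: float = 1e-10):
    """Michaelis-Menten elimination alternative: dA/dt includes
    -Vmax*C/(Km + C) with C = A/V.  Used only for base-model comparison
    experiments; superposition does not apply."""
    if Vmax <= 0 or Km <= 0:
        raise ValueError("Vmax and Km must be > 0")
    return _integrate_events(list(doses), times,
                             lambda a: Vmax * (a / V) / (Km + a / V),
                             V, ka, F, rtol, atol)
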