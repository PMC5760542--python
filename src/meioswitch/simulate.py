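"""Trajectory integration with input steps and division events.

The integrator (stiff LSODA/BDF via ``scipy.integrate.solve_ivp``) is
restarted at every schedule breakpoint so that piecewise-constant input
steps are sharp, and -- for the integrated model -- at every division
event, where the cell mass is halved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = ["Trajectory", "simulate"]

RTOL = 1e-8
ATOL = 1e-10


@dataclass
class Trajectory:
    """Dense model output: times, state matrix, observables, events."""

    t: np.ndarray
    y: np.ndarray                      # shape (n_vars, n_times)
    variables: tuple[str, ...]
    observables: dict[str, np.ndarray] = field(default_factory=dict)
    events: list[tuple[float, str]] = field(default_factory=list)

    def __getitem__(self, name: str) -> np.ndarray:
        if name == "t":
            return self.t
        if name in self.variables:
            return self.y[self.variables.index(name)]
        if name in self.observables:
            return self.observables[name]
        raise KeyError(f"unknown variable or observable {name!r}")

    @property
    def names(self) -> tuple[str, ...]:
        return self.variables + tuple(self.observables)

    def final(self, name: str) -> float:
        return float(self[name][-1])

    def peak(self, name: str) -> float:
        return float(np.max(self[name]))

    def division_times(self) -> list[float]:
        return [t for t, kind in self.events if kind == "division"]

    def first_crossing(self, name: str, threshold: float) -> float:
        """First time the signal rises through ``threshold`` (inf if never)."""
        x = self[name]
        above = x >= threshold
        if not above.any():
            return float("inf")
        i = int(np.argmax(above))
        if i == 0:
            return float(self.t[0])
        # linear interpolation inside the bracketing step
        t0, t1 = self.t[i - 1], self.t[i]
        x0, x1 = x[i - 1], x[i]
        if x1 == x0:
            return float(t1)
        return float(t0 + (threshold - x0) * (t1 - t0) / (x1 - x0))

    def to_frame(self, wide: bool = True) -> pd.DataFrame:
        cols = {"t": self.t}
        cols.update({v: self.y[i] for i, v in enumerate(self.variables)})
        cols.update(self.observables)
        df = pd.DataFrame(cols)
        if wide:
            return df
        return df.melt(id_vars="t", var_name="variable", value_name="value")


def _integrate_segment(rhs, y0, t0, t1, t_eval=None, events=None,
                       rtol=RTOL, atol=ATOL):
    # a modest max_step when events are active keeps the dense-output
    # interpolant sign-consistent with the step endpoints, which the
    # event root-finder requires
    kw = {"max_step": 2.0} if events else {}
    sol = solve_ivp(rhs, (t0, t1), y0, method="LSODA", rtol=rtol, atol=atol,
                    t_eval=t_eval, events=events,
                    dense_output=t_eval is None, **kw)
    if not sol.success:
        raise RuntimeError(f"integration failed on [{t0}, {t1}]: {sol.message}")
    if t_eval is None:
        return sol.y[:, -1]
    return sol


def simulate(model, t_end: float, y0: np.ndarray | None = None,
             dt: float = 0.5, rtol: float = RTOL, atol: float = ATOL,
             record_events: bool = True) -> Trajectory:
    """Integrate ``model`` from its default initial condition to ``t_end``.

    The model supplies ``rhs(t, y)`` (already closed over parameters and
    schedule), ``variables``, ``observe`` and optionally
    ``division_event``/``halve_mass`` hooks for the integrated model.
    """
    if y0 is None:
        y0 = model.steady_state(0.0)
    y0 = np.asarray(y0, dtype=float)

    breakpoints = [t for t in model.schedule.times if 0.0 < t < t_end]
    seg_edges = [0.0] + breakpoints + [t_end]
    events_log: list[tuple[float, str]] = []
    for t in breakpoints:
        events_log.append((t, "input_step"))

    has_division = hasattr(model, "division_event")
    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    y = y0.copy()
    for t0, t1 in zip(seg_edges, seg_edges[1:]):
        seg_start = t0
        while True:
            n_pts = max(int(np.ceil((t1 - seg_start) / dt)), 2)
            t_eval = np.linspace(seg_start, t1, n_pts + 1)
            ev = [model.division_event] if has_division else None
            sol = _integrate_segment(lambda tt, yy: model.rhs(tt, yy),
                                     y, seg_start, t1, t_eval=t_eval,
                                     events=ev, rtol=rtol, atol=atol)
            ts.append(sol.t)
            ys.append(sol.y)
            if has_division and sol.t_events[0].size:
                t_div = float(sol.t_events[0][0])
                y = model.halve_mass(sol.y_events[0][0])
                if record_events:
                    events_log.append((t_div, "division"))
                # keep the post-division state on the grid; restart just
                # past the event so it cannot re-trigger at the boundary
                ts.append(np.array([t_div]))
                ys.append(y[:, None])
                seg_start = t_div + 1e-6
                if t1 - seg_start < 1e-6:
                    break
                continue
            y = sol.y[:, -1]
            break

    t = np.concatenate(ts)
    Y = np.concatenate(ys, axis=1)
    # drop duplicated segment edges for a clean monotone grid, but keep
    # post-division duplicates (state is discontinuous there)
    keep = np.ones(t.size, dtype=bool)
    keep[1:] = np.diff(t) >= 0
    t, Y = t[keep], Y[:, keep]
    obs = model.observe(t, Y)
    events_log.sort()
    return Trajectory(t=t, y=Y, variables=tuple(model.variables),
                      observables=obs, events=events_log)
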