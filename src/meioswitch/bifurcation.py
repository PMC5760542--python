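"""One-parameter steady-state analysis: multi-start equilibrium finding,
pseudo-arclength continuation, linear stability, and fold/Hopf detection.

The continuation is a standard predictor-corrector on the extended
system F(y, p) = 0: secant (or tangent) predictor along arclength,
damped-Newton corrector orthogonal to the predictor direction, adaptive
step.  Folds (saddle-nodes) are flagged where the parameter component of
the branch tangent changes sign, and refined by bisection on that sign;
Hopf points where a complex-conjugate eigenvalue pair of the Jacobian
crosses the imaginary axis along the branch.  A multi-start root finder
serves as an independent oracle for validating branches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "SteadyStateBranch", "BifurcationPoint", "find_steady_states",
    "numerical_jacobian", "jacobian_stability", "continue_branch",
    "subsystem_branch", "cellmass_diagram",
]

RES_TOL = 1e-9          # ||rhs||_inf at accepted equilibria
DEDUP_TOL = 1e-6
STAB_TOL = -1e-8        # max Re(eig) below this counts as stable


@dataclass
class BifurcationPoint:
    kind: str                   # "SN" or "HB"
    param: float
    state: np.ndarray


@dataclass
class SteadyStateBranch:
    """An equilibrium branch: ordered points with stability annotation."""

    param_name: str
    params: np.ndarray                 # shape (n_pts,)
    states: np.ndarray                 # shape (n_pts, n_vars)
    stable: np.ndarray                 # bool, shape (n_pts,)
    leading_real: np.ndarray           # max Re(eigenvalue) per point
    points: list[BifurcationPoint] = field(default_factory=list)
    truncated: bool = False            # corrector gave up before the end

    def __len__(self):
        return self.params.size

    def folds(self):
        return [bp for bp in self.points if bp.kind == "SN"]

    def hopf_points(self):
        return [bp for bp in self.points if bp.kind == "HB"]

    def states_at(self, param_value: float, tol: float = None) -> np.ndarray:
        """All branch intersections with a vertical line (interpolated)."""
        out = []
        pv = self.params
        for i in range(len(pv) - 1):
            lo, hi = sorted((pv[i], pv[i + 1]))
            if lo <= param_value <= hi and hi > lo:
                f = (param_value - pv[i]) / (pv[i + 1] - pv[i])
                out.append(self.states[i] + f * (self.states[i + 1] - self.states[i]))
            elif pv[i] == param_value:
                out.append(self.states[i])
        return np.array(out)

    def to_frame(self, variables=None) -> pd.DataFrame:
        cols = {self.param_name: self.params}
        nv = self.states.shape[1]
        names = list(variables) if variables is not None else [
            f"y{i}" for i in range(nv)]
        for i, nm in enumerate(names):
            cols[nm] = self.states[:, i]
        cols["stable"] = self.stable
        cols["leading_real"] = self.leading_real
        return pd.DataFrame(cols)


def find_steady_states(rhs, box, n_starts: int = 50, seed: int = 0,
                       res_tol: float = RES_TOL,
                       dedup_tol: float = DEDUP_TOL) -> list[np.ndarray]:
    """Multi-start equilibrium search inside a box (the oracle).

    ``rhs(y)`` maps state to derivative; ``box`` is a sequence of
    (lo, hi) per variable.  Returns a deduplicated list of states with
    ``||rhs||_inf < res_tol``; deterministic for a given seed.  An empty
    list (no equilibrium found) is a valid result.
    """
    box = np.asarray(box, dtype=float)
    if not np.all(np.isfinite(box)):
        raise ValueError("box must be finite")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = box[:, 0], box[:, 1]
    found: list[np.ndarray] = []

    def polish(y0):
        sol = optimize.root(lambda y: np.asarray(rhs(y)), y0,
                            method="hybr", tol=1e-12)
        return sol.x

    for k in range(n_starts):
        y0 = lo + (hi - lo) * rng.random(lo.size)
        y = polish(y0)
        if np.max(np.abs(np.asarray(rhs(y)))) >= res_tol:
            # steep switching terms defeat Newton from afar: relax along
            # the flow toward an attractor first, then polish
            try:
                from scipy.integrate import solve_ivp
                sol_ivp = solve_ivp(lambda t, yy: np.asarray(rhs(yy)),
                                    (0.0, 3000.0), y0, method="LSODA",
                                    rtol=1e-8, atol=1e-10)
                if not sol_ivp.success or not np.all(
                        np.isfinite(sol_ivp.y[:, -1])):
                    continue
                y = polish(sol_ivp.y[:, -1])
            except Exception:
                continue
        if np.max(np.abs(np.asarray(rhs(y)))) >= res_tol:
            continue
        if np.any(y < lo - 0.5 * (hi - lo)) or np.any(y > hi + 0.5 * (hi - lo)):
            continue
        if not any(np.max(np.abs(y - f)) < dedup_tol for f in found):
            found.append(y)
    found.sort(key=lambda y: tuple(np.round(y, 9)))
    return found


def numerical_jacobian(rhs, y, rel_step: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian with adaptive (scaled) steps."""
    y = np.asarray(y, dtype=float)
    n = y.size
    J = np.empty((n, n))
    for j in range(n):
        h = rel_step * max(abs(y[j]), 1e-3)
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        J[:, j] = (np.asarray(rhs(yp)) - np.asarray(rhs(ym))) / (2.0 * h)
    return J


def jacobian_stability(rhs, state, res_tol: float = 1e-8):
    """(stable flag, eigenvalues) of an equilibrium of ``rhs``."""
    state = np.asarray(state, dtype=float)
    if np.max(np.abs(np.asarray(rhs(state)))) > res_tol:
        raise ValueError("state is not an equilibrium at the required tolerance")
    eig = np.linalg.eigvals(numerical_jacobian(rhs, state))
    return bool(np.max(eig.real) < STAB_TOL), eig


def _newton_correct(F, z0, direction, z_pred, tol=1e-10, max_iter=25):
    """Damped Newton for F(z)=0 with the arclength constraint
    ``direction . (z - z_pred) = 0``; z = (y, p)."""
    z = z0.copy()
    n = z.size - 1
    for _ in range(max_iter):
        f = np.asarray(F(z))
        g = float(direction @ (z - z_pred))
        res = np.concatenate([f, [g]])
        if np.max(np.abs(res)) < tol:
            return z, True
        # Jacobian of the extended system
        J = np.empty((n + 1, n + 1))
        for j in range(n + 1):
            h = 1e-7 * max(abs(z[j]), 1e-3)
            zp = z.copy()
            zp[j] += h
            J[:n, j] = (np.asarray(F(zp)) - f) / h
        J[n, :] = direction
        try:
            dz = np.linalg.solve(J, -res)
        except np.linalg.LinAlgError:
            return z, False
        lam = 1.0
        base = np.max(np.abs(res))
        for _damp in range(8):
            z_try = z + lam * dz
            f_try = np.asarray(F(z_try))
            g_try = float(direction @ (z_try - z_pred))
            if np.max(np.abs(np.concatenate([f_try, [g_try]]))) < base:
                break
            lam *= 0.5
        z = z + lam * dz
    f = np.asarray(F(z))
    g = float(direction @ (z - z_pred))
    return z, np.max(np.abs(np.concatenate([f, [g]]))) < 1e-8


def _hopf_crossed(eig_a, eig_b):
    """True if a complex pair crossed the imaginary axis between the
    two spectra (and the crossing is not a real fold eigenvalue)."""
    def max_complex_real(eig):
        cplx = eig[np.abs(eig.imag) > 1e-7]
        return np.max(cplx.real) if cplx.size else -np.inf
    a, b = max_complex_real(eig_a), max_complex_real(eig_b)
    return np.isfinite(a) and np.isfinite(b) and (a < 0.0 <= b or b < 0.0 <= a)


def continue_branch(rhs, param_name, param_range, start_state, params=None,
                    set_param=None, initial_step=None, min_step=None,
                    max_step=None, max_points: int = 2000,
                    fold_tol_rel: float = 1e-6) -> SteadyStateBranch:
    """Pseudo-arclength continuation of an equilibrium branch.

    ``rhs(y, p)`` is the right-hand side as a function of state and the
    scalar parameter value.  ``start_state`` must be an equilibrium at
    ``param_range[0]``.  The branch is followed until the parameter
    leaves ``param_range`` or the corrector gives up (-> ``truncated``).
    """
    p_lo, p_hi = float(param_range[0]), float(param_range[1])
    span = abs(p_hi - p_lo)
    h0 = initial_step if initial_step is not None else 1e-3 * span
    h_min = min_step if min_step is not None else 1e-5 * span
    h_max = max_step if max_step is not None else 1e-2 * span

    y0 = np.asarray(start_state, dtype=float)
    if np.max(np.abs(np.asarray(rhs(y0, p_lo)))) > 1e-8:
        raise ValueError("start_state is not an equilibrium at the range start")
    n = y0.size

    # scaling: parameter measured in units of the range span
    def F(z):
        return np.asarray(rhs(z[:n], z[n] * span + p_lo))

    zs = [np.concatenate([y0, [(p_lo - p_lo) / span]])]
    sgn = 1.0 if p_hi > p_lo else -1.0
    direction = np.zeros(n + 1)
    direction[n] = sgn

    states, pars, stabs, leads, eigs = [], [], [], [], []

    def record(z):
        y, ps = z[:n], z[n] * span + p_lo
        eig = np.linalg.eigvals(numerical_jacobian(lambda yy: rhs(yy, ps), y))
        states.append(y.copy())
        pars.append(ps)
        stabs.append(bool(np.max(eig.real) < STAB_TOL))
        leads.append(float(np.max(eig.real)))
        eigs.append(eig)

    record(zs[0])
    bif: list[BifurcationPoint] = []
    truncated = False
    h = h0 / span
    z = zs[0]
    while len(pars) < max_points:
        z_pred = z + h * direction
        z_new, ok = _newton_correct(F, z_pred, direction, z_pred)
        if not ok:
            h *= 0.5
            if h < h_min / span:
                truncated = True
                break
            continue
        tan = z_new - z
        norm = np.linalg.norm(tan)
        if norm == 0.0:
            truncated = True
            break
        tan /= norm
        # fold: sign change of the parameter tangent component
        if len(pars) >= 1 and np.sign(tan[n]) != 0 and \
                np.sign(tan[n]) != np.sign(direction[n]) and abs(direction[n]) > 1e-12:
            p_fold = _refine_fold(F, z, z_new, direction, n)
            bif.append(BifurcationPoint("SN", p_fold * span + p_lo,
                                        z_new[:n].copy()))
        record(z_new)
        if _hopf_crossed(eigs[-2], eigs[-1]):
            bif.append(BifurcationPoint(
                "HB", 0.5 * (pars[-2] + pars[-1]),
                0.5 * (states[-2] + states[-1])))
        direction = tan
        z = z_new
        if h < h_max / span:
            h = min(h * 1.3, h_max / span)
        pcur = z[n] * span + p_lo
        lo_edge, hi_edge = min(p_lo, p_hi), max(p_lo, p_hi)
        if pcur > hi_edge + 0.02 * span or pcur < lo_edge - 0.02 * span:
            break

    branch = SteadyStateBranch(
        param_name=param_name, params=np.array(pars),
        states=np.array(states), stable=np.array(stabs, dtype=bool),
        leading_real=np.array(leads), points=bif, truncated=truncated)
    return branch


def _refine_fold(F, z_a, z_b, direction, n, iters: int = 40):
    """Bisection on the parameter-tangent sign between two branch points."""
    za, zb = z_a.copy(), z_b.copy()
    for _ in range(iters):
        zm_pred = 0.5 * (za + zb)
        zm, ok = _newton_correct(F, zm_pred, direction, zm_pred)
        if not ok:
            break
        # which side of the fold: compare parameter against endpoints
        if abs(zm[n] - za[n]) < 1e-12:
            break
        if (zm[n] - za[n]) * (zb[n] - zm[n]) > 0:
            za = zm
        else:
            zb = zm
        if abs(zb[n] - za[n]) < 1e-8:
            break
    return 0.5 * (za[n] + zb[n])


def subsystem_branch(params, param_name: str, param_range, schedule=None,
                     start_state=None, **kwargs) -> SteadyStateBranch:
    """Continuation of the meiosis subsystem in one parameter.

    Starts from the resting state at ``param_range[0]`` under rich
    inputs (or the given schedule) unless ``start_state`` is supplied.
    Parameter values proposed outside [0, inf) by the predictor are
    clamped before building the model.
    """
    from .meiosis import MeiosisModel
    from .schedule import NutrientSchedule

    sched = schedule if schedule is not None else NutrientSchedule.rich()

    def rhs(y, value):
        m = MeiosisModel(params.replace(**{param_name: max(value, 0.0)}),
                         sched)
        return m.rhs(0.0, y)

    if start_state is None:
        m0 = MeiosisModel(params.replace(
            **{param_name: max(param_range[0], 0.0)}), sched)
        start_state = m0.steady_state(0.0)
    return continue_branch(rhs, param_name, param_range, start_state,
                           **kwargs)


# ---------------------------------------------------------------------------
# cell-size bifurcation diagram (Cdk1:Cdc13 activity vs cell mass)

def cellmass_diagram(params, condition: str = "rich", phes: float = 0.0,
                     ste11n: float = 0.0,
                     mass_range=(0.3, 3.5), n_grid: int = 100,
                     seeds=None, seed: int = 0):
    """Equilibria of the cell-cycle submodel with mass as the parameter.

    Growth and division are frozen; the nitrogen pool is held at its
    starvation-onset value (``condition='starved'``) or the external
    supply is used (``'rich'``).  ``phes`` is the clamped pheromone
    signalling level feeding the Rum1 brake.  Each mass point is probed
    from phase-informed seeds (G1-like, S/G2-like and M-like initial
    conditions) that are relaxed along the flow and polished by Newton,
    which resolves all coexisting stable branches; unstable segments
    between them are accessible through :func:`continue_branch`.
    Returns a tidy DataFrame (mass, mpf, cdc13t, rum1, stable,
    leading_real).
    """
    from scipy.integrate import solve_ivp

    from .cellcycle import CellCycleModel, mpf_activity
    from .schedule import NutrientSchedule

    if condition == "rich":
        tor2, pka = 1.0, 1.0
    elif condition == "starved":
        tor2, pka = 0.0, 0.75
    else:
        raise ValueError(f"unknown condition {condition!r}")
    model = CellCycleModel(params, NutrientSchedule.constant(tor2, pka))

    # 9 free variables: everything except mass (parameter) and npool
    idx = [0, 1, 2, 3, 4, 5, 6, 7, 9]
    igo0 = 0.0 if condition == "rich" else 0.9

    if seeds is None:
        g1 = [0.02, 0.0, 0.95, 0.05, 0.0, 0.0, 2.0, 0.0, igo0]
        sg2 = [1.0, 0.9, 0.0, 0.05, 0.0, 0.05, 0.05, 1.0, igo0]
        m_hi = [1.5, 0.05, 0.0, 0.5, 0.05, 0.8, 0.02, 1.0, igo0]
        seeds = [np.array(s) for s in (g1, sg2, m_hi)]

    def rhs_at(mass):
        def f(yfree):
            y = np.empty(11)
            y[idx] = yfree
            y[8] = mass
            y[10] = 1.0           # pool at its onset value
            return model.cc_rhs(0.0, y, tor2, pka, phes=phes,
                                ste11n=ste11n)[idx]
        return f

    rows = []
    masses = np.linspace(mass_range[0], mass_range[1], n_grid)
    for mass in masses:
        f = rhs_at(mass)
        eqs = []
        for s in seeds:
            y0 = s.copy()
            sol = solve_ivp(lambda t, yy: f(yy), (0.0, 800.0), y0,
                            method="LSODA", rtol=1e-6, atol=1e-9)
            cand = sol.y[:, -1] if sol.success else y0
            root = optimize.root(lambda y: f(y), cand, method="hybr",
                                 tol=1e-12)
            y = root.x
            if np.max(np.abs(f(y))) >= RES_TOL or np.any(~np.isfinite(y)):
                continue
            if any(np.max(np.abs(y - e)) < 1e-5 for e in eqs):
                continue
            eqs.append(y)
        for y in eqs:
            stable, eig = jacobian_stability(f, y)
            mpf = float(mpf_activity(max(y[0], 1e-12), y[1], y[6], params))
            rows.append(dict(mass=float(mass), mpf=mpf, cdc13t=float(y[0]),
                             prempf=float(y[1]), rum1=float(y[6]),
                             stable=stable,
                             leading_real=float(np.max(eig.real))))
    return pd.DataFrame(rows)
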