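"""Fission-yeast mitotic cell-cycle model and its meiosis coupling.

The cell-cycle submodel is an M-phase-control model in the Novak-Tyson
tradition: total Cdk1:Cdc13 with synthesis proportional to cell mass,
degradation by Ste9/APC and Slp1/APC; Tyr15 inhibitory phosphorylation
(Wee1/Cdc25 as zero-order ultrasensitive switches); the CKI Rum1 binding
Cdk1:Cdc13 in a rapid-equilibrium trimer; a starter kinase SK driven by
a mass-dependent transcription factor; and an intermediary-enzyme delay
for Slp1 activation.  On top of that sits the nutrient layer: Tor2
inactivation activates Ppk18 (greatwall), which phosphorylates Igo1;
Igo1-P inhibits PP2A:B55, the phosphatase that keeps Wee1 active and
Cdc25 inactive, so starvation advances mitotic onset at a smaller size.
An intracellular nitrogen pool sustains cyclin and SK synthesis for a
while after starvation and then depletes, which (with the PheS brake on
Rum1 degradation) produces the accelerated divisions followed by G1
arrest with high Rum1.

Couplings to the meiosis subsystem: Cdk1:Cdc13 gates Ste11-driven
transcription (Ste11 pulses in G1); PheS slows Rum1 degradation.
Division is an event: when Cdk1:Cdc13 activity falls through the exit
threshold after mitosis the mass is halved exactly.
"""

from __future__ import annotations

import numpy as np

from .kinetics import goldbeter_koshland, hill_activation
from .meiosis import MeiosisModel, MEIOSIS_VARIABLES
from .params import ParameterSet, default_parameters
from .schedule import NutrientSchedule

__all__ = [
    "CELLCYCLE_VARIABLES", "CellCycleModel", "IntegratedModel",
    "detect_division_events", "g1_arrest",
]

CELLCYCLE_VARIABLES = (
    "cdc13t",    # total Cdk1:Cdc13 (all phosphoforms and complexes)
    "prempf",    # Tyr15-phosphorylated (inhibited) Cdk1:Cdc13
    "ste9",      # APC/C-Ste9 activity
    "slp1t",     # total Slp1
    "slp1",      # active Slp1 (APC/C-Slp1)
    "iep",       # intermediary enzyme linking MPF to Slp1 activation
    "rum1",      # total Rum1 (CKI)
    "sk",        # starter kinase (G1/S cyclin-Cdk activity)
    "mass",      # cell mass, arbitrary units
    "igo1p",     # phosphorylated Igo1 (PP2A:B55 inhibitor)
    "npool",     # intracellular nitrogen store (fraction remaining)
)

CC_OBSERVABLES = ("mpf", "b55", "trimer")


def _trimer(cdc13t, rum1, kdiss):
    """Rapid-equilibrium Cdk1:Cdc13 / Rum1 complex concentration."""
    s = cdc13t + rum1 + kdiss
    disc = s * s - 4.0 * cdc13t * rum1
    return 2.0 * cdc13t * rum1 / (s + np.sqrt(np.maximum(disc, 0.0)))


def mpf_activity(cdc13t, prempf, rum1, params):
    """Active MPF given totals: unphosphorylated and Rum1-free fraction."""
    cdc13t = np.maximum(cdc13t, 1e-12)
    tri = _trimer(cdc13t, rum1, params["kdiss"])
    return (cdc13t - prempf) * (cdc13t - tri) / cdc13t


def b55_activity(igo1p, params):
    """PP2A:B55 activity under Igo1-P inhibition."""
    return params["b55_t"] * params["k_ib55"] / (params["k_ib55"] + igo1p)


class CellCycleModel:
    """Standalone mitotic cycle (no meiosis variables).

    ``nu`` multiplies cyclin/SK synthesis (1 in rich medium; under
    starvation the depleting nitrogen pool takes over); ``phes`` feeds
    the Rum1-degradation brake and is 0 for the standalone model.
    """

    variables = CELLCYCLE_VARIABLES
    observables = CC_OBSERVABLES

    def __init__(self, params: ParameterSet | None = None,
                 schedule: NutrientSchedule | None = None):
        self.params = params if params is not None else default_parameters("cellcycle")
        self.schedule = schedule if schedule is not None else NutrientSchedule.rich()
        self.n = len(self.variables)
        self._armed = False

        def div(t, y):
            # latched event: arms when MPF exceeds the mitotic threshold,
            # fires on the downward crossing of the exit threshold, and
            # is disarmed by the mass-halving transform, so it cannot
            # re-trigger at a restart boundary
            mpf = self.mpf_of(np.maximum(np.asarray(y, dtype=float), 0.0))
            if mpf >= self.params["mpf_mitotic"]:
                self._armed = True
            return mpf - self.params["mpf_exit"] if self._armed else 1.0

        div.terminal = True
        div.direction = -1
        self.division_event = div

    # offsets into the state vector (subclass shifts them)
    _off = 0

    def inputs_at(self, t):
        return self.schedule.at(t)

    def mpf_of(self, y):
        o = self._off
        return mpf_activity(y[o + 0], y[o + 1], y[o + 6], self.params)

    def _growing(self, tor2, pka):
        # growth requires active nutrient signalling (both branches)
        return tor2 * pka > 0.25

    def cc_rhs(self, t, y, tor2, pka, phes=0.0, ste11n=0.0):
        """Cell-cycle part of the derivative (11 components)."""
        p = self.params
        o = self._off
        (cdc13t, prempf, ste9, slp1t, slp1, iep, rum1, sk, mass, igo1p,
         npool) = np.maximum(y[o:o + 11], 0.0)
        mass = max(mass, 1e-9)

        rich = self._growing(tor2, pka)
        nu = 1.0 if rich else p["n_pool0"] * npool
        # clamp: root-finder trial points can put prempf above cdc13t
        mpf = max(mpf_activity(cdc13t, prempf, rum1, p), 0.0)
        b55 = b55_activity(igo1p, p)
        fb55 = (p["eps_b55"] + b55) / (p["eps_b55"] + p["b55_t"])

        kd13 = (p["kd_cdc13_b"] + p["kd_cdc13_ste9"] * ste9
                + p["kd_cdc13_slp1"] * slp1)
        d_cdc13t = p["ks_cdc13"] * mass * nu - kd13 * cdc13t

        kwee = p["kwee_lo"] + (p["kwee_hi"] - p["kwee_lo"]) * goldbeter_koshland(
            p["v_awee"] * fb55, p["v_iwee"] * mpf, p["j_awee"], p["j_iwee"])
        k25 = p["k25_lo"] + (p["k25_hi"] - p["k25_lo"]) * goldbeter_koshland(
            p["v_a25"] * mpf, p["v_i25"] * fb55, p["j_a25"], p["j_i25"])
        d_prempf = (kwee * (cdc13t - prempf) - k25 * prempf - kd13 * prempf)

        d_ste9 = (p["ka_ste9"] * (1.0 + p["ka_ste9_slp1"] * slp1)
                  * (1.0 - ste9) / (p["j_ste9a"] + 1.0 - ste9)
                  - (p["ki_ste9_sk"] * sk + p["ki_ste9_mpf"] * mpf)
                  * ste9 / (p["j_ste9i"] + ste9))

        # PP2A:B55 also restrains APC/Slp1 activation: the MPF threshold
        # for Slp1 synthesis drops as B55 is inhibited (starvation), so
        # starved cells cannot park in a stable mitotic state
        j_slp1 = p["j_slp1"] * (1.0 - p["w_slp1_b55"] * (1.0 - fb55))
        d_slp1t = (p["ks_slp1_b"]
                   + p["ks_slp1_mpf"] * hill_activation(
                       mpf, j_slp1, p["h_slp1"])
                   - p["kd_slp1"] * slp1t)
        d_slp1 = (p["ka_slp1"] * iep * (slp1t - slp1)
                  / (p["j_a_slp1"] + slp1t - slp1)
                  - p["ki_slp1"] * slp1 / (p["j_i_slp1"] + slp1)
                  - p["kd_slp1"] * slp1)
        d_iep = p["ka_iep"] * mpf * (1.0 - iep) - p["ki_iep"] * iep

        kd_rum1 = (p["kd_rum1_b"] + p["kd_rum1_sk"] * sk
                   + p["kd_rum1_mpf"] * mpf) / (1.0 + p["k_rum1_phes"] * phes)
        d_rum1 = p["ks_rum1"] - kd_rum1 * rum1

        tf = goldbeter_koshland(
            p["ka_tf_m"] * mass * nu,
            p["ki_tf_b"] + p["ki_tf_mpf"] * mpf,
            p["j_a_tf"], p["j_i_tf"])
        arrest = p["a_sk_arrest"] * hill_activation(
            ste11n, p["k_sk_arrest"], p["h_sk_arrest"])
        d_sk = (p["ks_sk"] * tf * nu
                / (1.0 + p["k_sk_phes"] * phes)
                / (1.0 + arrest)
                - p["kd_sk"] * sk)

        d_mass = p["mu"] * mass if rich else 0.0

        ppk18 = min(max(1.0 - tor2, 0.0), 1.0)
        d_igo1p = (p["k_igo"] * ppk18 * (1.0 - igo1p)
                   - p["kdp_igo"] * (b55 / p["b55_t"]) * igo1p)

        d_npool = 0.0 if rich else -p["kd_pool"] * npool

        out = np.array([d_cdc13t, d_prempf, d_ste9, d_slp1t, d_slp1, d_iep,
                        d_rum1, d_sk, d_mass, d_igo1p, d_npool])
        # restore toward zero outside the physical domain
        return out - np.minimum(y[o:o + 11], 0.0)

    def rhs(self, t, y):
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n,):
            raise ValueError(
                f"state shape {y.shape} does not match {self.n} variables")
        tor2, pka, _ = self.inputs_at(t)
        return self.cc_rhs(t, y, tor2, pka, phes=0.0)

    def halve_mass(self, y):
        """State transform applied at a division event."""
        self._armed = False
        y = np.array(y, dtype=float)
        y[self._off + 8] *= 0.5
        return y

    def observe(self, t, y):
        y = np.asarray(y, dtype=float)
        single = y.ndim == 1
        Y = np.maximum(y[:, None] if single else y, 0.0)
        o = self._off
        p = self.params
        out = {
            "mpf": mpf_activity(Y[o + 0], Y[o + 1], Y[o + 6], p),
            "b55": b55_activity(Y[o + 9], p),
            "trimer": _trimer(np.maximum(Y[o + 0], 1e-12), Y[o + 6],
                              p["kdiss"]),
        }
        if single:
            out = {k: float(np.asarray(v).ravel()[0]) for k, v in out.items()}
        return out

    def cycling_state(self, t_relax: float = 2000.0) -> np.ndarray:
        """A point on the nutrient-rich limit cycle, just after division."""
        from .simulate import simulate
        y0 = np.zeros(self.n)
        y0[6] = 1.0          # start with Rum1 high (G1-like)
        y0[8] = 1.0          # unit mass
        y0[10] = 1.0         # full nitrogen pool
        tr = simulate(self, t_relax, y0=y0, dt=1.0, record_events=True)
        divs = tr.division_times()
        if not divs:
            raise RuntimeError("no division events; the cycle did not start")
        i = int(np.searchsorted(tr.t, divs[-1], side="right"))
        i = min(i, tr.t.size - 1)
        return tr.y[:, i]


class IntegratedModel(CellCycleModel):
    """Meiosis subsystem + cell cycle, coupled.

    State = 8 meiosis variables followed by the 11 cell-cycle variables.
    Couplings: Cdk1:Cdc13 gates Ste11-driven transcription; PheS slows
    Rum1 degradation.  Both are parameters (``k_cdk_ste11``/
    ``h_cdk_ste11`` and ``k_rum1_phes``); setting ``k_rum1_phes = 0``
    and the gate threshold very high recovers the uncoupled limit.
    """

    variables = MEIOSIS_VARIABLES + CELLCYCLE_VARIABLES
    observables = MeiosisModel.observables + CC_OBSERVABLES
    _off = len(MEIOSIS_VARIABLES)

    def __init__(self, params: ParameterSet | None = None,
                 schedule: NutrientSchedule | None = None):
        params = params if params is not None else default_parameters("integrated")
        super().__init__(params, schedule)
        self.n = len(self.variables)
        self._meiosis = MeiosisModel.__new__(MeiosisModel)
        self._meiosis.params = params
        self._meiosis.schedule = self.schedule
        self._meiosis.n = len(MEIOSIS_VARIABLES)

    def cdk_gate(self, mpf: float) -> float:
        """Multiplicative inhibition of Ste11-driven transcription by Cdk1."""
        p = self.params
        return 1.0 - hill_activation(mpf, p["k_cdk_ste11"], p["h_cdk_ste11"])

    def rhs(self, t, y):
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n,):
            raise ValueError(
                f"state shape {y.shape} does not match {self.n} variables")
        tor2, pka, _ = self.inputs_at(t)
        mpf = self.mpf_of(np.maximum(y, 0.0))
        d_mei = self._meiosis.rhs(t, y[:self._off], cdk_gate=self.cdk_gate(mpf))
        phes = max(y[4], 0.0)
        d_cc = self.cc_rhs(t, y, tor2, pka, phes=phes,
                           ste11n=max(y[1], 0.0))
        return np.concatenate([d_mei, d_cc])

    def observe(self, t, y):
        y = np.asarray(y, dtype=float)
        single = y.ndim == 1
        Y = np.maximum(y[:, None] if single else y, 0.0)
        out = self._meiosis.observe(t, Y[:self._off])
        out.update(CellCycleModel.observe(self, t, Y))
        if single:
            out = {k: (float(np.asarray(v).ravel()[0])
                       if not np.isscalar(v) else v) for k, v in out.items()}
        return out

    def cycling_state(self, t_relax: float = 2000.0) -> np.ndarray:
        from .simulate import simulate
        y0 = np.zeros(self.n)
        y0[:self._off] = 0.01
        y0[self._off + 6] = 1.0
        y0[self._off + 8] = 1.0
        y0[self._off + 10] = 1.0
        tr = simulate(self, t_relax, y0=y0, dt=1.0)
        divs = tr.division_times()
        if not divs:
            raise RuntimeError("no division events; the cycle did not start")
        i = int(np.searchsorted(tr.t, divs[-1], side="right"))
        return tr.y[:, min(i, tr.t.size - 1)]

    # the default initial condition for simulate()
    def steady_state(self, t: float = 0.0):
        return self.cycling_state()


def detect_division_events(trajectory, mitotic: float | None = None,
                           exit_threshold: float | None = None,
                           params: ParameterSet | None = None) -> list[float]:
    """Division times from a trajectory: downward crossings of the exit
    threshold by Cdk1:Cdc13 activity after having exceeded the mitotic
    threshold.  Works on recorded trajectories (post hoc), independent of
    the event handling used during integration."""
    p = params if params is not None else default_parameters("cellcycle")
    mitotic = p["mpf_mitotic"] if mitotic is None else mitotic
    exit_threshold = p["mpf_exit"] if exit_threshold is None else exit_threshold
    t = trajectory.t
    if np.any(np.diff(t) < 0):
        raise ValueError("time grid must be non-decreasing")
    mpf = trajectory["mpf"]
    armed = False
    out = []
    for i in range(1, t.size):
        if mpf[i] >= mitotic:
            armed = True
        if armed and mpf[i - 1] > exit_threshold >= mpf[i]:
            # linear interpolation of the crossing
            f = (mpf[i - 1] - exit_threshold) / (mpf[i - 1] - mpf[i])
            out.append(float(t[i - 1] + f * (t[i] - t[i - 1])))
            armed = False
    return out


def g1_arrest(trajectory, window: float, params: ParameterSet | None = None,
              rum1_ref: float | None = None):
    """G1-arrest verdict over the final ``window`` minutes.

    True iff Cdk1:Cdc13 stays below the exit threshold and Rum1 stays
    above ``rum1_ref`` (default: the mid-cycle mean Rum1 of the
    nutrient-rich first half of the trajectory).  Returns
    ``(arrested, mean_rum1, mean_mpf)``.
    """
    p = params if params is not None else default_parameters("cellcycle")
    t = trajectory.t
    if window >= t[-1] - t[0]:
        raise ValueError("window longer than the trajectory span")
    tail = t >= t[-1] - window
    mpf = trajectory["mpf"]
    rum1 = trajectory["rum1"]
    if rum1_ref is None:
        head = t <= t[0] + 0.5 * (t[-1] - t[0])
        rum1_ref = float(np.mean(rum1[head]))
    arrested = bool(np.all(mpf[tail] < p["mpf_exit"])
                    and np.all(rum1[tail] > rum1_ref))
    return arrested, float(np.mean(rum1[tail])), float(np.mean(mpf[tail]))
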