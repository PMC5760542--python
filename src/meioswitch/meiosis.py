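"""The Ste11-Mei2-Pat1 meiotic-entry subsystem.

The network (nutrient inputs Tor2/PKA; transcription activator Ste11
with nuclear-cytoplasmic shuttling and autoregulation; RNA-binding
protein Mei2 with destabilizing multi-site phosphorylation by Pat1 and
Tor2; pheromone signalling lumped as PheS; mating-type product Mat1-Pm;
Pat1 inhibitor Mei3) is expressed as 8 ODEs.  Ste11-driven syntheses use
Hill kinetics, Mei2 (de)phosphorylation uses Michaelis-Menten kinetics,
and everything else is mass action.  Pat1 is conserved: free Pat1 plus
the Pat1:Mei3 complex equals ``pat1_t`` at all times, and PheS lowers
the *activity* of the free pool by rapid-equilibrium inhibition.

Two transcriptional activities are algebraic functions of the state:
Rst2 (repressed by PKA) and Rpol (Pol II CTD phosphorylation, promoted
by total Mei2 via the stress-MAPK/CTDK-I route).
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from .kinetics import hill_activation, mm_flux
from .params import ParameterSet, default_parameters
from .schedule import NutrientSchedule

__all__ = [
    "MEIOSIS_VARIABLES", "MeiosisModel", "pat1_partition",
    "rst2_activity", "rpol_activity",
]

MEIOSIS_VARIABLES = (
    "ste11",      # cytoplasmic Ste11
    "ste11n",     # nuclear (transcriptionally active) Ste11
    "mei2",       # dephosphorylated, active Mei2
    "mei2p",      # phosphorylated (Pat1/Tor2-site) Mei2, unstable
    "phes",       # lumped pheromone-signalling activity
    "mat1pm",     # Mat1-Pm
    "mei3",       # free Mei3
    "pat1mei3",   # stoichiometric Pat1:Mei3 inhibitory complex
)

# observables derived from the state vector
MEIOSIS_OBSERVABLES = (
    "ste11_t", "mei2_t", "mei3_t", "pat1_free", "pat1_active",
    "rst2", "rpol",
)


def rst2_activity(pka: float, params) -> float:
    """Rst2 transcriptional activity, repressed by PKA."""
    return 1.0 - hill_activation(pka, params["k_mpka"], params["h_pka"])


def rpol_activity(mei2_total, params):
    """Pol II CTD phosphorylation activity, promoted by total Mei2.

    The Mei2 -> Sty1 -> CTDK-I coupling carries weight ``w_rpol``
    (zeroed by the lsk1 deletion); ``rpol_b`` is the Mei2-independent
    basal activity.
    """
    b = params["rpol_b"]
    return b + params["w_rpol"] * (1.0 - b) * hill_activation(
        mei2_total, params["k_mrpol"], params["h_rpol"])


def pat1_partition(pat1_total, mei3_complexed, phes, params):
    """Partition total Pat1 into (active, inhibited).

    Mei3 inhibits stoichiometrically (the dynamically tracked
    Pat1:Mei3 complex); PheS inhibits the remaining free pool by
    rapid-equilibrium binding, so the PheS-inhibited form is
    ``free * k_iphe * PheS / (1 + k_iphe * PheS)``.  Active plus
    inhibited always sums to ``pat1_total``.
    """
    if min(pat1_total, mei3_complexed, phes) < 0:
        raise ValueError("pat1_partition arguments must be >= 0")
    free = max(pat1_total - mei3_complexed, 0.0)
    active = free / (1.0 + params["k_iphe"] * phes)
    return active, pat1_total - active


class MeiosisModel:
    """ODE right-hand side and observables for the meiosis subsystem.

    Parameters
    ----------
    params : ParameterSet, optional
        Defaults to the bundled calibrated set.
    schedule : NutrientSchedule, optional
        Defaults to constant nitrogen-rich inputs.
    """

    variables = MEIOSIS_VARIABLES
    observables = MEIOSIS_OBSERVABLES

    def __init__(self, params: ParameterSet | None = None,
                 schedule: NutrientSchedule | None = None):
        self.params = params if params is not None else default_parameters("meiosis")
        self.schedule = schedule if schedule is not None else NutrientSchedule.rich()
        self.n = len(self.variables)

    # -- inputs ------------------------------------------------------------
    def inputs_at(self, t: float) -> tuple[float, float, bool]:
        return self.schedule.at(t)

    # -- right-hand side ---------------------------------------------------
    def rhs(self, t: float, y: np.ndarray, cdk_gate: float = 1.0) -> np.ndarray:
        """d(state)/dt at time ``t``.

        ``cdk_gate`` multiplies the Ste11 autoregulatory synthesis term;
        the integrated model passes the Cdk1-dependent gate here, the
        isolated subsystem leaves it at 1 (constitutive *ste11*
        transcription, the ste11-T82A limit).
        """
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n,):
            raise ValueError(
                f"state shape {y.shape} does not match {self.n} variables")
        p = self.params
        tor2, pka, phes_enabled = self.inputs_at(t)
        ste11, ste11n, mei2, mei2p, phes, mat1pm, mei3, cplx = np.maximum(y, 0.0)

        rst2 = rst2_activity(pka, p)
        rpol = rpol_activity(mei2 + mei2p, p)
        pat1_act, _ = pat1_partition(p["pat1_t"], cplx, phes, p)
        pat1_free = max(p["pat1_t"] - cplx, 0.0)

        # Pat1 phosphorylation of Ste11 (Rad24-dependent) inhibits both
        # its transcriptional activity and its nuclear residence, and
        # Cdk1-site phosphorylation abolishes DNA binding (w_ste11); the
        # transcriptionally effective nuclear Ste11:
        ste11n_eff = (p["w_ste11"] * ste11n
                      / (1.0 + p["k_tapat"] * pat1_act))

        # Ste11 synthesis and shuttling.  Cdk1-site phosphorylation of
        # Ste11 blocks DNA binding, so the gate (1 in the isolated
        # subsystem) multiplies all regulated ste11 transcription.
        syn = p["ks11b"] + cdk_gate * (
            p["ks11r"] * rst2
            + p["ks11a"]
            * hill_activation(ste11n_eff, p["k_mste11"], p["hs"])
        ) * rpol
        imp = p["k_imste11"] * (1.0 + p["k_imphe"] * phes)
        exp = p["k_exste11"] * (
            1.0 + p["k_expat"] * pat1_act + p["k_exnut"] * tor2 * pka)

        d_ste11 = syn - p["kd_ste11"] * ste11 - imp * ste11 + exp * ste11n
        d_ste11n = imp * ste11 - exp * ste11n - p["kd_ste11"] * ste11n

        # Mei2: Pat1-site phosphorylation is an inactivating
        # Michaelis-Menten cycle (near zero-order, so Pat1 activity acts
        # as a sharp threshold); Tor2-site phosphorylation destabilizes
        # both forms (first-order phospho-degron, strongly synergistic
        # with the Pat1-phosphorylated form).
        v_pat = mm_flux(mei2, pat1_act, p["kp_pat"], p["km_p"])
        v_dp = mm_flux(mei2p, 1.0, p["kdp_mei2"], p["km_dp"])
        syn_mei2 = p["ks_mei2"] * (
            p["eps_mei2"]
            + hill_activation(ste11n_eff, p["k_mmei2"], p["h_mei2"])
        ) + p["ks_mei2h"] * hill_activation(
            ste11n_eff, p["k_mmei2h"], p["h_mei2h"])
        kd_a = p["kd_mei2"] * (1.0 + p["kp_tor"] * tor2)
        kd_p_ = p["kd_mei2p"] * (1.0 + p["kp_torp"] * tor2 * pat1_act)
        d_mei2 = syn_mei2 - kd_a * mei2 - v_pat + v_dp
        d_mei2p = v_pat - v_dp - kd_p_ * mei2p

        # pheromone signalling
        syn_phe = (p["k_sphe"] * hill_activation(ste11n_eff, p["k_mphe"],
                                                 p["h_phe"])
                   + p["k_sphe_b"]) if phes_enabled else 0.0
        d_phes = syn_phe - p["kd_phe"] * phes

        # Mat1-Pm (high Ste11 threshold) and Mei3
        d_mat1pm = (p["k_smat"] * hill_activation(ste11n_eff, p["k_mmat"],
                                                  p["h_mat"])
                    - p["kd_mat"] * mat1pm)
        assoc = p["k_as"] * pat1_free * mei3
        d_mei3 = (p["k_smei3"] * hill_activation(mat1pm, p["k_mmei3"], p["h_mei3"])
                  - p["kd_mei3"] * mei3 - assoc + p["k_di"] * cplx)
        d_cplx = assoc - p["k_di"] * cplx - p["kd_cplx"] * cplx

        out = np.array([d_ste11, d_ste11n, d_mei2, d_mei2p,
                        d_phes, d_mat1pm, d_mei3, d_cplx])
        # outside the physical domain (negative components, reachable by
        # root-finder trial points) the dynamics restore toward zero, so
        # the clamped region is never flat
        return out - np.minimum(y, 0.0)

    # -- derived observables ----------------------------------------------
    def observe(self, t, y) -> dict[str, np.ndarray]:
        """Derived observables for a state or a trajectory (vars x time)."""
        y = np.asarray(y, dtype=float)
        single = y.ndim == 1
        Y = np.maximum(y[:, None] if single else y, 0.0)
        p = self.params
        tarr = np.atleast_1d(np.asarray(t, dtype=float))
        pka = np.array([self.inputs_at(tt)[1] for tt in tarr])
        cplx = Y[7]
        phes = Y[4]
        free = np.maximum(p["pat1_t"] - cplx, 0.0)
        active = free / (1.0 + p["k_iphe"] * phes)
        mei2_t = Y[2] + Y[3]
        out = {
            "ste11_t": Y[0] + Y[1],
            "mei2_t": mei2_t,
            "mei3_t": Y[6] + Y[7],
            "pat1_free": free,
            "pat1_active": active,
            "rst2": np.array([rst2_activity(pk, p) for pk in pka]),
            "rpol": rpol_activity(mei2_t, p),
        }
        if single:
            out = {k: float(np.asarray(v).ravel()[0]) for k, v in out.items()}
        return out

    # -- steady states -----------------------------------------------------
    def steady_state(self, t: float = 0.0,
                     guess: np.ndarray | None = None,
                     relax_time: float = 5000.0) -> np.ndarray:
        """Steady state reached from low activity under the inputs at ``t``.

        Inputs are frozen at their ``t`` values, the system is relaxed by
        integration from a low-activity initial condition (so that for a
        bistable parameter set the resting, pre-differentiation state is
        selected when it exists), and the result is polished by root
        finding.  This is the default initial condition of every
        simulation, matching growth under the starting inputs.
        """
        if guess is None:
            guess = np.full(self.n, 0.01)

        def f(y):
            return self.rhs(t, y)  # t fixed: inputs frozen

        from .simulate import _integrate_segment
        y = _integrate_segment(lambda _tt, yy: f(yy), guess, 0.0, relax_time)
        sol = optimize.root(f, y, method="hybr", tol=1e-12)
        if np.max(np.abs(f(np.maximum(sol.x, 0.0)))) <= 1e-8:
            y = np.maximum(sol.x, 0.0)
        else:
            y = _integrate_segment(lambda _tt, yy: f(yy), y, 0.0, 10 * relax_time)
            sol = optimize.root(f, y, method="hybr", tol=1e-12)
            y = np.maximum(sol.x, 0.0)
        if np.max(np.abs(f(y))) > 1e-8:
            raise RuntimeError("steady-state search did not converge")
        return y
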