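"""Named in-silico experiments: nutrient shifts, return-to-growth,
commitment-window bisection, and the sequential-order check.

Each protocol fixes a genotype, a nutrient schedule, a model variant and
a horizon.  The shipped protocol set covers the canonical nutrient-shift
experiments: subsystem starvation and mutant time courses, the
return-to-growth (commitment) experiments, wild-type and ste11-T82A
cell cycling, and starvation applied at two points of the cell cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cellcycle import IntegratedModel
from .genotypes import apply_genotype, strain_registry
from .meiosis import MeiosisModel
from .params import ParameterSet, default_parameters
from .schedule import NutrientSchedule, STARVED_PKA
from .simulate import Trajectory, simulate

__all__ = [
    "Protocol", "PROTOCOLS", "run_protocol", "ReversalOutcome",
    "run_return_to_growth", "commitment_window", "sequential_order_check",
    "reference_plateaus",
]

# verdict thresholds for commitment (fractions, logged in every report)
PAT1_OFF_FRACTION = 0.10      # free/active Pat1 below 10% of Pat1_T
MEI2_ON_FRACTION = 0.50       # active Mei2 above 50% of committed plateau


@dataclass(frozen=True)
class Protocol:
    """A reusable in-silico experiment."""

    name: str
    genotype: str                         # registered strain name
    schedule: NutrientSchedule
    model: str = "meiosis"                # "meiosis" or "integrated"
    observables: tuple[str, ...] = ("ste11_t", "phes", "mat1pm", "mei3_t",
                                    "mei2", "pat1_active")
    horizon: float = 700.0

    def __post_init__(self):
        if self.model not in ("meiosis", "integrated"):
            raise ValueError(f"unknown model selector {self.model!r}")
        if self.genotype not in strain_registry():
            raise ValueError(f"protocol references unregistered genotype "
                             f"{self.genotype!r}")


def _starve_then_regrow(t_readd: float) -> NutrientSchedule:
    """Starvation at t=0; Tor2/PKA restored and PheS disabled at t_readd."""
    return NutrientSchedule((
        (0.0, 0.0, STARVED_PKA, True),
        (t_readd, 1.0, 1.0, False),
    ))


_CC_OBS = ("mpf", "rum1", "mass", "ste11_t", "phes", "mei2", "pat1_active")

PROTOCOLS: dict[str, Protocol] = {p.name: p for p in [
    Protocol("fig2a", "wild type", NutrientSchedule.starvation_at(50.0)),
    Protocol("fig2b", "mei3D", NutrientSchedule.starvation_at(50.0)),
    Protocol("fig2c", "pat1-114 (34C)", NutrientSchedule.rich()),
    Protocol("fig2d", "pat1-114 (30C)", NutrientSchedule.rich()),
    Protocol("fig4a", "wild type", _starve_then_regrow(135.0), horizon=800.0),
    Protocol("fig4b", "wild type", _starve_then_regrow(150.0), horizon=800.0),
    Protocol("fig5a", "wild type", NutrientSchedule.rich(),
             model="integrated", observables=_CC_OBS, horizon=400.0),
    Protocol("fig5b", "ste11-T82A", NutrientSchedule.rich(),
             model="integrated", observables=_CC_OBS, horizon=400.0),
    Protocol("fig6a", "wild type", NutrientSchedule.starvation_at(150.0),
             model="integrated", observables=_CC_OBS, horizon=900.0),
    Protocol("fig6b", "wild type", NutrientSchedule.starvation_at(135.0),
             model="integrated", observables=_CC_OBS, horizon=900.0),
]}


def build_model(protocol: Protocol, params: ParameterSet | None = None):
    """Instantiate the model a protocol runs, with its genotype applied."""
    registry = strain_registry()
    genotype = registry[protocol.genotype]
    if params is None:
        params = default_parameters(
            "integrated" if protocol.model == "integrated" else "meiosis")
    p, sched = apply_genotype(params, genotype, protocol.schedule)
    if protocol.model == "integrated":
        return IntegratedModel(p, sched)
    return MeiosisModel(p, sched)


def run_protocol(name: str, params: ParameterSet | None = None,
                 dt: float = 1.0) -> Trajectory:
    """Run a registered protocol from its resting initial condition."""
    proto = PROTOCOLS[name]
    model = build_model(proto, params)
    if proto.model == "integrated":
        y0 = model.cycling_state()
    else:
        # start from the wild-type nutrient-rich resting state
        wt = MeiosisModel(default_parameters("meiosis"),
                          NutrientSchedule.rich())
        y0 = wt.steady_state(0.0)
    return simulate(model, proto.horizon, y0=y0, dt=dt)


# ---------------------------------------------------------------------------
# return-to-growth / commitment

@dataclass(frozen=True)
class ReversalOutcome:
    """Verdict of a return-to-growth experiment."""

    t_readd: float
    verdict: str                  # "reversible" or "irreversible"
    final_pat1_active: float
    final_mei2: float
    thresholds: dict = field(default_factory=dict)

    @property
    def irreversible(self) -> bool:
        return self.verdict == "irreversible"


_REFERENCE_CACHE: dict = {}


def committed_plateau(params: ParameterSet | None = None) -> float:
    """Active-Mei2 plateau of the committed wild-type starved state."""
    params = params if params is not None else default_parameters("meiosis")
    key = ("plateau", tuple(sorted(params.to_dict().items())))
    if key not in _REFERENCE_CACHE:
        m = MeiosisModel(params, NutrientSchedule.constant(0.0, STARVED_PKA))
        y0 = MeiosisModel(params, NutrientSchedule.rich()).steady_state(0.0)
        tr = simulate(m, 700.0, y0=y0, dt=2.0)
        _REFERENCE_CACHE[key] = tr.final("mei2")
    return _REFERENCE_CACHE[key]


def run_return_to_growth(t_readd: float,
                         params: ParameterSet | None = None,
                         horizon: float = 600.0) -> ReversalOutcome:
    """Starve at t=0, restore nutrients (and disable PheS) at ``t_readd``.

    The verdict is irreversible iff, at ``t_readd + horizon``, active
    Pat1 is below 10% of total Pat1 and active Mei2 above 50% of the
    wild-type committed plateau.
    """
    params = params if params is not None else default_parameters("meiosis")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    m = MeiosisModel(params, _starve_then_regrow(t_readd))
    y0 = MeiosisModel(params, NutrientSchedule.rich()).steady_state(0.0)
    tr = simulate(m, t_readd + horizon, y0=y0, dt=2.0)
    pat1 = tr.final("pat1_active")
    mei2 = tr.final("mei2")
    ref = committed_plateau()
    thr = {"pat1_off": PAT1_OFF_FRACTION * params["pat1_t"],
           "mei2_on": MEI2_ON_FRACTION * ref}
    irr = pat1 < thr["pat1_off"] and mei2 > thr["mei2_on"]
    return ReversalOutcome(t_readd, "irreversible" if irr else "reversible",
                           pat1, mei2, thr)


def commitment_window(params: ParameterSet | None = None,
                      resolution: float = 1.0,
                      bracket=(120.0, 165.0)):
    """Bisect the reversible->irreversible flip of return-to-growth.

    Returns ``(t_reversible_max, t_irreversible_min)`` at the requested
    resolution.  If no flip exists inside the bracket, the degenerate
    outcome ``(bracket_end, inf)`` (never committed) or
    ``(-inf, bracket_start)`` (already committed) is returned instead of
    raising.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    lo, hi = float(bracket[0]), float(bracket[1])
    lo_irr = run_return_to_growth(lo, params).irreversible
    hi_irr = run_return_to_growth(hi, params).irreversible
    if lo_irr:
        return (-np.inf, lo)
    if not hi_irr:
        return (hi, np.inf)
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if run_return_to_growth(mid, params).irreversible:
            hi = mid
        else:
            lo = mid
    return (lo, hi)


# ---------------------------------------------------------------------------
# sequential upregulation

ORDER_SIGNALS = ("phes", "mat1pm", "mei3_t", "mei2")


def reference_plateaus(params: ParameterSet | None = None) -> dict[str, float]:
    """Wild-type starved plateaus of the ordered observables (cached)."""
    params = params if params is not None else default_parameters("meiosis")
    key = ("ref", tuple(sorted(params.to_dict().items())))
    if key not in _REFERENCE_CACHE:
        m = MeiosisModel(params, NutrientSchedule.constant(0.0, STARVED_PKA))
        y0 = MeiosisModel(params, NutrientSchedule.rich()).steady_state(0.0)
        tr = simulate(m, 700.0, y0=y0, dt=2.0)
        _REFERENCE_CACHE[key] = {s: tr.final(s) for s in ORDER_SIGNALS}
    return dict(_REFERENCE_CACHE[key])


def sequential_order_check(trajectory: Trajectory,
                           reference: dict[str, float] | None = None
                           ) -> dict[str, float]:
    """Half-maximum first-crossing times of PheS, Mat1-Pm, Mei3 and
    active Mei2, against the wild-type starved plateaus.

    A signal that never crosses its half-maximum maps to ``inf``.
    """
    ref = reference if reference is not None else reference_plateaus()
    return {s: trajectory.first_crossing(s, 0.5 * ref[s])
            for s in ORDER_SIGNALS}
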