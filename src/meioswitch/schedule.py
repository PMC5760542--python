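"""Piecewise-constant nutrient-input schedules.

Tor2 and PKA activities encode the nutritional status (1 = nitrogen
rich; starvation is modelled as Tor2 = 0 with PKA only partially
inhibited, 0.75).  Levels are held constant between breakpoints; the
integrator is restarted at every breakpoint so step discontinuities are
never smoothed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["NutrientSchedule", "RICH", "STARVED_PKA"]

RICH = (1.0, 1.0)
STARVED_PKA = 0.75  # PKA is not completely inhibited under starvation


@dataclass(frozen=True)
class NutrientSchedule:
    """Ordered breakpoints of (time_min, tor2, pka, phes_enabled)."""

    breakpoints: tuple[tuple[float, float, float, bool], ...] = field(
        default_factory=lambda: ((0.0, 1.0, 1.0, True),))

    def __post_init__(self):
        bps = tuple(
            (float(t), float(tor2), float(pka), bool(phes))
            for (t, tor2, pka, phes) in self.breakpoints)
        if not bps or bps[0][0] != 0.0:
            raise ValueError("first breakpoint must be at t = 0")
        times = [bp[0] for bp in bps]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("breakpoint times must be strictly increasing")
        for _, tor2, pka, _ in bps:
            if not (0.0 <= tor2 <= 1.5 and 0.0 <= pka <= 1.5):
                raise ValueError(
                    "input levels must lie in [0, 1.5] "
                    "(values above 1 encode overexpression)")
        object.__setattr__(self, "breakpoints", bps)

    @classmethod
    def constant(cls, tor2: float, pka: float,
                 phes_enabled: bool = True) -> "NutrientSchedule":
        return cls(((0.0, tor2, pka, phes_enabled),))

    @classmethod
    def rich(cls) -> "NutrientSchedule":
        return cls.constant(1.0, 1.0)

    @classmethod
    def starvation_at(cls, t_starve: float, tor2: float = 0.0,
                      pka: float = STARVED_PKA) -> "NutrientSchedule":
        """Rich growth, then a Tor2/PKA step down at ``t_starve``."""
        if t_starve <= 0:
            return cls.constant(tor2, pka)
        return cls(((0.0, 1.0, 1.0, True), (t_starve, tor2, pka, True)))

    def then(self, t: float, tor2: float, pka: float,
             phes_enabled: bool = True) -> "NutrientSchedule":
        """Append a breakpoint (t must exceed the last breakpoint time)."""
        return NutrientSchedule(self.breakpoints + ((t, tor2, pka, phes_enabled),))

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(bp[0] for bp in self.breakpoints)

    def at(self, t: float) -> tuple[float, float, bool]:
        """Input levels (tor2, pka, phes_enabled) in force at time t."""
        if t < 0:
            raise ValueError("schedule is defined for t >= 0")
        current = self.breakpoints[0]
        for bp in self.breakpoints:
            if bp[0] <= t:
                current = bp
            else:
                break
        return current[1], current[2], current[3]
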