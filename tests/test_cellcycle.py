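"""Cell-cycle submodel: oscillation, division events, arrest detection,
uncoupled-limit equivalence and event determinism."""

import numpy as np
import pytest

import meioswitch as ms
from meioswitch import CellCycleModel, IntegratedModel, NutrientSchedule
from meioswitch.cellcycle import detect_division_events, g1_arrest


@pytest.fixture(scope="module")
def rich_cc_run(integrated_params):
    from meioswitch.params import CELLCYCLE_DEFAULTS, ParameterSet
    p = ParameterSet({k: integrated_params[k] for k in CELLCYCLE_DEFAULTS},
                     model="cellcycle")
    m = CellCycleModel(p, NutrientSchedule.rich())
    y0 = np.zeros(m.n)
    y0[6] = 1.0   # Rum1 high (G1-like start)
    y0[8] = 1.0   # unit mass
    y0[10] = 1.0  # full nitrogen pool
    return p, m, ms.simulate(m, 900.0, y0=y0, dt=1.0)


class TestOscillation:
    def test_period_locks_to_mass_doubling(self, rich_cc_run):
        p, _, tr = rich_cc_run
        divs = tr.division_times()
        assert len(divs) >= 3
        periods = np.diff(divs)
        doubling = np.log(2.0) / p["mu"]
        assert abs(periods[-1] - doubling) / doubling < 0.01

    def test_mass_halves_at_division(self, rich_cc_run):
        _, _, tr = rich_cc_run
        t_div = tr.division_times()[-1]
        i = np.searchsorted(tr.t, t_div)
        mass = tr["mass"]
        # mass is ~2x the post-division value just before the event
        assert mass[max(i - 2, 0)] / mass[min(i + 1, mass.size - 1)] == \
            pytest.approx(2.0, rel=0.02)

    def test_post_hoc_event_detection_agrees(self, rich_cc_run):
        p, _, tr = rich_cc_run
        recorded = tr.division_times()
        detected = detect_division_events(tr, params=p)
        assert len(detected) == len(recorded)
        assert np.allclose(detected, recorded, atol=1.5)

    def test_event_determinism_under_tolerance_refinement(
            self, rich_cc_run):
        p, m, tr = rich_cc_run
        y0 = np.zeros(m.n)
        y0[6] = 1.0
        y0[8] = 1.0
        y0[10] = 1.0
        t_ref = ms.simulate(m, 400.0, y0=y0, dt=1.0,
                            rtol=1e-9, atol=1e-11).division_times()
        t_std = [d for d in tr.division_times() if d < 400.0]
        assert len(t_ref) == len(t_std)
        assert max(abs(a - b) for a, b in zip(t_ref, t_std)) < 0.5


class TestDetectDivisions:
    def test_constant_low_cdk1_has_no_events(self, rich_cc_run):
        p, _, _ = rich_cc_run

        class Flat:
            t = np.linspace(0, 100, 50)
            def __getitem__(self, k):
                return np.full(50, 0.02)
        assert detect_division_events(Flat(), params=p) == []

    def test_non_monotone_grid_rejected(self, rich_cc_run):
        p, _, _ = rich_cc_run

        class Bad:
            t = np.array([0.0, 2.0, 1.0])
            def __getitem__(self, k):
                return np.zeros(3)
        with pytest.raises(ValueError, match="grid"):
            detect_division_events(Bad(), params=p)


class TestArrestDetector:
    def test_rich_cycling_is_not_arrested(self, rich_cc_run):
        p, _, tr = rich_cc_run
        arrested, _, _ = g1_arrest(tr, 150.0, p)
        assert not arrested

    def test_window_longer_than_span_rejected(self, rich_cc_run):
        p, _, tr = rich_cc_run
        with pytest.raises(ValueError, match="window"):
            g1_arrest(tr, 1e6, p)


def test_uncoupled_limit_matches_standalone(integrated_params,
                                            cycling_state):
    """With the couplings zeroed, the integrated model's cell-cycle block
    reproduces the standalone model's trajectory (period to <1%)."""
    from meioswitch.params import CELLCYCLE_DEFAULTS, ParameterSet

    # integrated model with couplings removed: no PheS brake, no Cdk1
    # gate influence back onto the cycle (the meiosis variables read the
    # cycle but nothing flows back)
    p_unc = integrated_params.replace(k_rum1_phes=0.0, a_sk_arrest=0.0)
    mi = IntegratedModel(p_unc, NutrientSchedule.rich())
    off = mi._off
    y0 = cycling_state.copy()
    y0[:off] = 0.0  # silence the meiosis side entirely
    tr_i = ms.simulate(mi, 500.0, y0=y0, dt=1.0)

    pc = ParameterSet({k: p_unc[k] for k in CELLCYCLE_DEFAULTS},
                      model="cellcycle")
    mc = CellCycleModel(pc, NutrientSchedule.rich())
    tr_c = ms.simulate(mc, 500.0, y0=cycling_state[off:], dt=1.0)

    di, dc = tr_i.division_times(), tr_c.division_times()
    assert len(di) == len(dc) >= 2
    per_i, per_c = np.diff(di)[-1], np.diff(dc)[-1]
    assert abs(per_i - per_c) / per_c < 0.01
    # state deviation at matched times (MPF trace)
    mpf_i = np.interp(tr_c.t, tr_i.t, tr_i["mpf"])
    assert np.max(np.abs(mpf_i - tr_c["mpf"])) < 0.05


def test_ste11_pulses_in_g1(integrated_params, cycling_state):
    """Rich cycling: Ste11 is high when Cdk1 activity is low (Fig-5-type
    anti-phase), and the T82A limit shows elevated, non-pulsing Ste11
    without Mei2 activation."""
    mi = IntegratedModel(integrated_params, NutrientSchedule.rich())
    tr = ms.simulate(mi, 420.0, y0=cycling_state, dt=1.0)
    st, mpf = tr["ste11_t"], tr["mpf"]
    assert st.max() / max(st.min(), 1e-9) > 1.5          # visible pulsing
    assert np.corrcoef(st, mpf)[0, 1] < -0.2             # anti-phase

    p82 = integrated_params.replace(k_cdk_ste11=1e6)     # gate removed
    tr82 = ms.simulate(IntegratedModel(p82, NutrientSchedule.rich()),
                       420.0, y0=cycling_state, dt=1.0)
    late = tr82.t > 100.0
    st82 = tr82["ste11_t"][late]
    assert st82.min() > 0.9 * st.max()                   # elevated, sustained
    assert tr82.final("mei2") < 0.05                     # still no meiosis
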