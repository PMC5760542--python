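"""Protocol layer: sequential ordering, return-to-growth, commitment
window and its Mei3-sensitivity."""

import numpy as np
import pytest

import meioswitch as ms
from meioswitch import MeiosisModel, NutrientSchedule
from meioswitch.protocols import (PROTOCOLS, commitment_window,
                                  run_protocol, run_return_to_growth,
                                  sequential_order_check)
from meioswitch.schedule import STARVED_PKA


def test_protocol_registry_covers_figures():
    for name in ("fig2a", "fig2b", "fig2c", "fig2d", "fig4a", "fig4b",
                 "fig5a", "fig5b", "fig6a", "fig6b"):
        assert name in PROTOCOLS


class TestSequentialOrder:
    def test_wild_type_order(self, wt_starved_run):
        times = sequential_order_check(wt_starved_run)
        seq = [times[s] for s in ("phes", "mat1pm", "mei3_t", "mei2")]
        assert all(np.isfinite(seq))
        assert seq == sorted(seq)
        assert len(set(np.round(seq, 3))) == 4  # strictly increasing

    def test_mei3_deletion_never_activates_mei2(self, meiosis_params,
                                                wt_rich_state):
        p = meiosis_params.replace(k_smei3=0.0)
        m = MeiosisModel(p, NutrientSchedule.constant(0.0, STARVED_PKA))
        tr = ms.simulate(m, 700.0, y0=wt_rich_state, dt=2.0)
        times = sequential_order_check(tr)
        assert np.isfinite(times["phes"]) and np.isfinite(times["mat1pm"])
        assert np.isinf(times["mei3_t"]) and np.isinf(times["mei2"])

    def test_pat1_loss_activates_mei2_without_mei3(self):
        tr = run_protocol("fig2c", dt=2.0)
        times = sequential_order_check(tr)
        assert np.isfinite(times["mei2"])
        assert np.isinf(times["mei3_t"])


class TestReturnToGrowth:
    def test_early_readdition_reverses(self):
        out = run_return_to_growth(135.0)
        assert out.verdict == "reversible"
        assert out.final_pat1_active > out.thresholds["pat1_off"]
        assert out.final_mei2 < out.thresholds["mei2_on"]

    def test_late_readdition_is_committed(self):
        out = run_return_to_growth(150.0)
        assert out.verdict == "irreversible"
        assert out.final_pat1_active < 0.1
        assert out.final_mei2 > out.thresholds["mei2_on"]

    def test_fully_committed_cell_stays_committed(self):
        out = run_return_to_growth(400.0)
        assert out.verdict == "irreversible"

    def test_bad_horizon_rejected(self):
        with pytest.raises(ValueError):
            run_return_to_growth(100.0, horizon=-5.0)


class TestCommitmentWindow:
    def test_flip_lies_between_135_and_150(self):
        lo, hi = commitment_window(resolution=2.0)
        assert 135.0 <= lo < hi <= 150.0

    def test_mei3_deletion_cannot_commit(self, meiosis_params):
        p = meiosis_params.replace(k_smei3=0.0)
        lo, hi = commitment_window(p, resolution=8.0)
        assert np.isinf(hi)  # degenerate: never irreversible

    def test_flip_moves_earlier_with_faster_mei3(self, meiosis_params):
        """Commitment is sensitive to the Mei3 synthesis rate: doubling
        k_smei3 moves the flip strictly earlier; scanning three rates
        gives a monotone sequence."""
        flips = []
        for factor in (1.0, 2.0, 4.0):
            p = meiosis_params.scale("k_smei3", factor)
            lo, hi = commitment_window(p, resolution=4.0,
                                       bracket=(60.0, 165.0))
            flips.append(hi)
        assert all(np.isfinite(flips))
        assert flips[0] > flips[1] > flips[2]


def test_phes_needed_to_enter_not_to_maintain(meiosis_params,
                                              wt_rich_state):
    """Disabling PheS after the transition does not re-activate Pat1."""
    m = MeiosisModel(meiosis_params,
                     NutrientSchedule.constant(0.0, STARVED_PKA))
    tr = ms.simulate(m, 300.0, y0=wt_rich_state, dt=2.0)
    committed = tr.y[:, -1]
    sched = NutrientSchedule(((0.0, 0.0, STARVED_PKA, False),))  # PheS off
    m2 = MeiosisModel(meiosis_params, sched)
    tr2 = ms.simulate(m2, 500.0, y0=committed, dt=2.0)
    assert tr2.final("pat1_active") < 0.05
    assert tr2.final("mei2") > 1.0


def test_single_input_loss_suffices_and_needs_phes(meiosis_params,
                                                   wt_rich_state):
    """Either PKA or Tor2 inactivation alone activates Mei2, and with
    PheS disabled neither does; PKA loss acts faster than Tor2 loss."""
    crossings = {}
    for name, (tor2, pka) in {"pka_off": (1.0, 0.0),
                              "tor2_off": (0.0, 1.0)}.items():
        m = MeiosisModel(meiosis_params,
                         NutrientSchedule.constant(tor2, pka))
        tr = ms.simulate(m, 700.0, y0=wt_rich_state, dt=2.0)
        assert tr.final("mei2") > 1.0
        crossings[name] = tr.first_crossing("mei2", 1.0)
        p = meiosis_params.replace(k_sphe=0.0)
        m0 = MeiosisModel(p, NutrientSchedule.constant(tor2, pka))
        tr0 = ms.simulate(m0, 700.0, y0=wt_rich_state, dt=2.0)
        assert tr0.final("mei2") < 0.2
    assert crossings["pka_off"] < crossings["tor2_off"]


def test_shipped_protocol_fixture_matches_registry():
    """The YAML protocol fixture in the package data mirrors the in-code
    registry (genotype, model, horizon, schedule breakpoints)."""
    import importlib.resources as res
    import yaml
    with res.as_file(res.files("meioswitch") / "data"
                     / "protocols.yaml") as path:
        data = yaml.safe_load(path.read_text())
    for name, proto in PROTOCOLS.items():
        entry = data[name]
        assert entry["genotype"] == proto.genotype
        assert entry["model"] == proto.model
        assert entry["horizon"] == proto.horizon
        bps = [(bp["t"], bp["tor2"], bp["pka"], bp["phes_enabled"])
               for bp in entry["schedule"]]
        assert tuple(bps) == proto.schedule.breakpoints
    # the cell-size diagram configurations ride along
    assert data["fig7a"]["condition"] == "rich"
    assert data["fig7b_green"]["phes"] == 2.0
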