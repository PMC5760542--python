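"""Parameter-set validation, file loaders and nutrient schedules."""

import pytest

from meioswitch import NutrientSchedule, default_parameters
from meioswitch.params import (ParameterSet, load_parameters,
                               parameter_manifest, write_parameters)


class TestParameterSet:
    def test_defaults_validate(self):
        for model in ("meiosis", "cellcycle", "integrated"):
            p = default_parameters(model)
            assert all(v >= 0 for v in p.values())

    def test_unknown_and_missing_names_reported(self):
        good = default_parameters("meiosis").to_dict()
        bad = dict(good)
        bad["k_bogus"] = 1.0
        del bad["k_imste11"]
        with pytest.raises(ValueError, match="k_bogus"):
            ParameterSet(bad, model="meiosis")
        with pytest.raises(ValueError, match="k_imste11"):
            ParameterSet(bad, model="meiosis")

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            default_parameters("meiosis").replace(k_sphe=-1.0)

    def test_hill_coefficient_floor(self):
        with pytest.raises(ValueError, match="Hill"):
            default_parameters("meiosis").replace(hs=0.5)

    def test_replace_leaves_original(self):
        p = default_parameters("meiosis")
        q = p.replace(k_sphe=0.0)
        assert p["k_sphe"] > 0 and q["k_sphe"] == 0.0
        assert q.scale("pat1_t", 0.5)["pat1_t"] == 0.5 * p["pat1_t"]


class TestLoaders:
    def test_ode_round_trip(self, tmp_path):
        p = default_parameters("meiosis")
        path = write_parameters(p, tmp_path / "m.ode")
        assert load_parameters(path, model="meiosis") == p

    def test_json_round_trip(self, tmp_path):
        p = default_parameters("integrated")
        path = write_parameters(p, tmp_path / "m.json")
        assert load_parameters(path, model="integrated") == p

    def test_ode_parsing_details(self, tmp_path):
        # case-insensitive names, several assignments per line, comments
        p = default_parameters("meiosis")
        lines = [f"# a comment", "init ste11=0.1"]
        items = sorted(p)
        lines.append("par " + ",".join(
            f"{k.upper()}={p[k]!r}" for k in items[:5]))
        lines += [f"p {k}={p[k]!r}" for k in items[5:]]
        lines.append("ste11' = something_ignored")
        f = tmp_path / "mixed.ode"
        f.write_text("\n".join(lines))
        assert load_parameters(f, model="meiosis") == p

    def test_bundled_ode_fixture_matches_defaults(self):
        import importlib.resources as res
        with res.as_file(res.files("meioswitch") / "data"
                         / "meiosis_default.ode") as path:
            assert load_parameters(path, model="meiosis") == \
                default_parameters("meiosis")

    def test_empty_file_lists_missing_names(self, tmp_path):
        f = tmp_path / "empty.ode"
        f.write_text("")
        with pytest.raises(ValueError, match="k_imste11"):
            load_parameters(f, model="meiosis")

    def test_bad_line_reports_number(self, tmp_path):
        f = tmp_path / "bad.ode"
        f.write_text("par ok=1.0\npar broken\n")
        with pytest.raises(ValueError, match="line 2"):
            load_parameters(f, model="meiosis")

    def test_manifest_is_text_table(self):
        text = parameter_manifest("integrated")
        assert "k_imste11" in text and "mu" in text


class TestSchedule:
    def test_levels_and_breakpoints(self):
        s = NutrientSchedule.starvation_at(50.0)
        assert s.at(0.0) == (1.0, 1.0, True)
        assert s.at(49.999) == (1.0, 1.0, True)
        assert s.at(50.0) == (0.0, 0.75, True)

    def test_validation(self):
        with pytest.raises(ValueError, match="t = 0"):
            NutrientSchedule(((5.0, 1.0, 1.0, True),))
        with pytest.raises(ValueError, match="increasing"):
            NutrientSchedule(((0.0, 1, 1, True), (0.0, 0, 0.75, True)))
        with pytest.raises(ValueError, match="0, 1.5"):
            NutrientSchedule.constant(2.0, 1.0)

    def test_then_appends(self):
        s = NutrientSchedule.rich().then(100.0, 0.0, 0.75)
        assert s.at(150.0)[:2] == (0.0, 0.75)
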