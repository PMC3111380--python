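"""ICD-10 cause mapping, CSV round-trips, config and CLI determinism."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import injury_aaf as ia
from injury_aaf import io as aio
from injury_aaf.causes import default_cause_map, map_cause
from injury_aaf.cli import main as cli_main


class TestCauseMap:
    @pytest.mark.parametrize(
        "code,cause,cls",
        [
            ("W10", "Falls", "nonMVA"),
            ("X45", "Poisonings and exposure to alcohol", "wholly"),
            ("X65", "Intentional self-poisoning by and exposure to alcohol", "wholly"),
            ("X44", "Poisonings", "nonMVA"),
            ("V43", "Motor vehicle collision", "MVA"),
            ("V01", "Other unintentional injuries", "nonMVA"),
            ("W70", "Drowning", "nonMVA"),
            ("X62", "Self-inflicted injuries", "nonMVA"),
            ("Y87.0", "Self-inflicted injuries", "nonMVA"),
            ("Y87.1", "Homicide", "nonMVA"),
            ("X95", "Homicide", "nonMVA"),
            ("Y36", "Other intentional injuries", "nonMVA"),
            ("X05", "Fires", "nonMVA"),
        ],
    )
    def test_mapping(self, code, cause, cls):
        cat = map_cause(code)
        assert cat.name == cause
        assert cat.injury_class == cls

    def test_x45_overrides_poisoning_range(self):
        # inside X40-X49 but wholly attributable by definition
        assert map_cause("X45").injury_class == "wholly"

    def test_unmapped_code_reported(self):
        with pytest.raises(KeyError, match="A00"):
            map_cause("A00")

    def test_malformed_code_rejected(self):
        with pytest.raises(ValueError):
            map_cause("not-a-code")

    def test_every_category_represented(self):
        assert len(default_cause_map().categories) == 11


def write_bundle(tmp_path, seed=5, survey_n=None):
    runner = CliRunner()
    args = ["simulate", "--seed", str(seed), "--out-dir", str(tmp_path / "bundle")]
    if survey_n:
        args += ["--survey-n", str(survey_n)]
    result = runner.invoke(cli_main, args, catch_exceptions=False)
    assert result.exit_code == 0
    return tmp_path / "bundle"


class TestIO:
    def test_consumption_round_trip(self, tmp_path):
        bundle_dir = write_bundle(tmp_path)
        summaries = aio.read_consumption(bundle_dir / "consumption.csv")
        assert len(summaries) == 4
        again = aio.read_consumption(bundle_dir / "consumption.csv")
        assert summaries == again

    def test_invalid_prevalence_reported_with_row(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "age_group,sex,p_abst_former,p_current,raw_mean_gday,raw_mean_se,"
            "binge_prev,binge_occasions_yr\n"
            "15-29,M,0.3,0.7,10,1,0.1,20\n"
            "30-44,M,-0.2,1.2,10,1,0.1,20\n"
        )
        with pytest.raises(ValueError, match="row 3"):
            aio.read_consumption(path)

    def test_mortality_resolves_causes(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(
            "cause_id,icd10_range,age_group,sex,deaths\n"
            "falls,W00-W19,15-29,M,120\n"
            "alc_poisoning,X45,15-29,M,10\n"
        )
        mort = aio.read_mortality(path)
        assert list(mort["cause"]) == ["Falls", "Poisonings and exposure to alcohol"]

    def test_negative_deaths_reported(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text(
            "cause_id,icd10_range,age_group,sex,deaths\nfalls,W00-W19,15-29,M,-2\n"
        )
        with pytest.raises(ValueError, match="row 2"):
            aio.read_mortality(path)

    def test_missing_stratum_enumerated(self, tmp_path):
        bundle_dir = write_bundle(tmp_path)
        mort = tmp_path / "m.csv"
        mort.write_text(
            "cause_id,icd10_range,age_group,sex,deaths\nfalls,W00-W19,99-120,M,5\n"
        )
        with pytest.raises(ValueError, match="99-120"):
            aio.read_inputs(bundle_dir / "consumption.csv", mort)

    def test_results_round_trip(self, tmp_path):
        frame = pd.DataFrame({"cause": ["Falls"], "aaf_total": [0.25]})
        out = tmp_path / "r.csv"
        aio.write_results(frame, out, scenario="main", seed=7)
        back = aio.read_results(out)
        assert back.equals(frame)
        assert "# scenario=main seed=7" in out.read_text()

    def test_config_round_trip(self, tmp_path):
        cfg = ia.ScenarioConfig(scenario="SA_I", per_capita=24.0, intake_model="point")
        curves = ia.published_anchor_curves()
        path = tmp_path / "scenario.yaml"
        aio.write_config(path, cfg, curves=curves, metabolism=ia.MetabolismModel())
        cfg2, curves2, metab2, mc = aio.load_config(path)
        assert cfg2 == cfg
        assert curves2["MVA"].coefficient == pytest.approx(curves["MVA"].coefficient)
        assert metab2 == ia.MetabolismModel()
        assert mc is None


class TestCLI:
    def test_aaf_reruns_are_byte_identical(self, tmp_path):
        bundle_dir = write_bundle(tmp_path, survey_n=2000)
        runner = CliRunner()
        outputs = []
        for name in ("a.csv", "b.csv"):
            result = runner.invoke(
                cli_main,
                [
                    "aaf",
                    "--consumption", str(bundle_dir / "consumption.csv"),
                    "--mortality", str(bundle_dir / "mortality.csv"),
                    "--config", str(bundle_dir / "scenario.yaml"),
                    "--scenario", "main",
                    "--out", str(tmp_path / name),
                ],
                catch_exceptions=False,
            )
            assert result.exit_code == 0
            outputs.append((tmp_path / name).read_bytes())
        assert outputs[0] == outputs[1]

    def test_ci_command_fixed_seed_reproducible(self, tmp_path):
        bundle_dir = write_bundle(tmp_path, survey_n=2000)
        runner = CliRunner()
        outputs = []
        for name in ("c1.csv", "c2.csv"):
            result = runner.invoke(
                cli_main,
                [
                    "ci",
                    "--consumption", str(bundle_dir / "consumption.csv"),
                    "--mortality", str(bundle_dir / "mortality.csv"),
                    "--config", str(bundle_dir / "scenario.yaml"),
                    "--draws", "200",
                    "--seed", "42",
                    "--prevalence-ess", "2000",
                    "--out", str(tmp_path / name),
                ],
                catch_exceptions=False,
            )
            assert result.exit_code == 0
            outputs.append((tmp_path / name).read_bytes())
        assert outputs[0] == outputs[1]
        back = aio.read_results(tmp_path / "c1.csv")
        assert (back["ci_low"] <= back["aaf_total"]).all()
        assert (back["aaf_total"] <= back["ci_high"]).all()

    def test_calibrate_command(self, tmp_path):
        anchors = tmp_path / "anchors.csv"
        anchors.write_text("dose_g,rr\n54.4,5.03\n68,6.08\n81.6,7.23\n")
        runner = CliRunner()
        result = runner.invoke(
            cli_main,
            [
                "calibrate",
                "--anchors", str(anchors),
                "--dose-power", "0.5",
                "--injury-class", "nonMVA",
                "--out", str(tmp_path / "curve.yaml"),
            ],
            catch_exceptions=False,
        )
        assert result.exit_code == 0
        _, curves, _, _ = aio.load_config(tmp_path / "curve.yaml")
        assert curves["nonMVA"].coefficient == pytest.approx(0.2190, rel=5e-4)
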