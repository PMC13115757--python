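"""Synthetic-data generators, CSV schemas and the pipeline driver."""

import json
from pathlib import Path

import numpy as np
import pytest

from dclkit import io as dio
from dclkit import synth
from dclkit.errors import DomainError, ValidationError
from dclkit.pipeline import run_pipeline, validate_inputs

ALL_SCENARIOS = sorted(synth.SCENARIOS)


class TestGenerators:
    @pytest.mark.parametrize("scenario", ALL_SCENARIOS)
    def test_fixed_seed_reproduces_byte_identical_files(self, scenario,
                                                        tmp_path):
        cfg = {"scenario": scenario, "seed": 13}
        p1 = synth.generate(cfg, tmp_path / "a")
        p2 = synth.generate(cfg, tmp_path / "b")
        assert [p.name for p in p1] == [p.name for p in p2]
        for f1, f2 in zip(p1, p2):
            assert Path(f1).read_bytes() == Path(f2).read_bytes()

    @pytest.mark.parametrize("scenario", ALL_SCENARIOS)
    def test_sidecar_records_truth_and_files(self, scenario, tmp_path):
        paths = synth.generate({"scenario": scenario, "seed": 1}, tmp_path)
        sidecar = json.loads(Path(paths[-1]).read_text())
        assert sidecar["scenario"] == scenario
        assert sidecar["truth"]
        for name in sidecar["files"]:
            assert (tmp_path / name).exists()

    @pytest.mark.parametrize("scenario", ALL_SCENARIOS)
    def test_emitted_files_pass_input_validation(self, scenario, tmp_path):
        paths = synth.generate({"scenario": scenario, "seed": 2}, tmp_path)
        csvs = [p for p in paths if str(p).endswith(".csv")]
        report = validate_inputs(csvs)
        assert all(v["status"] == "ok" for v in report.values()), report

    def test_unknown_scenario_rejected(self, tmp_path):
        with pytest.raises(DomainError, match="scenario"):
            synth.generate({"scenario": "nope", "seed": 0}, tmp_path)

    def test_titration_series_derives_K_from_thermodynamics(self):
        tits, truth = synth.make_titration_series(medium="PBS_pH7.4",
                                                  sigma_r=0.0)
        from dclkit import fit_binding_isotherm, vant_hoff_fit
        Ks = {t.temperature: fit_binding_isotherm(t, "1:1").K for t in tits}
        th = vant_hoff_fit(Ks)
        assert th.dH == pytest.approx(truth["dH"], rel=1e-3)
        assert th.dS == pytest.approx(truth["dS"], rel=1e-3)


class TestCSVRoundTrips:
    def test_titration_round_trip(self, tmp_path, noiseless_titration):
        t, _ = noiseless_titration
        path = dio.save_titration(tmp_path / "t.csv", t)
        back = dio.load_titration(path)
        np.testing.assert_allclose(back.host_conc, t.host_conc)
        np.testing.assert_allclose(back.r_obs, t.r_obs)
        assert back.medium == t.medium
        assert back.temperature == t.temperature

    def test_quench_and_release_round_trips(self, tmp_path):
        q, _ = synth.make_quench(seed=3)
        qb = dio.load_quench(dio.save_quench(tmp_path / "q.csv", q))
        np.testing.assert_allclose(qb.intensity_ratio, q.intensity_ratio)
        assert qb.tau0 == q.tau0
        r, _ = synth.make_release(seed=3)
        rb = dio.load_release(dio.save_release(tmp_path / "r.csv", r))
        np.testing.assert_allclose(rb.intensity, r.intensity)

    def test_dose_response_round_trip(self, tmp_path):
        dr, _ = synth.make_dose_response(seed=3)
        back = dio.load_dose_response(
            dio.save_dose_response(tmp_path / "m.csv", dr))
        np.testing.assert_allclose(back.survival, dr.survival)
        assert back.cell_line == dr.cell_line


class TestValidateInputs:
    def test_negative_concentration_flagged(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("# temperature_K = 298.15\n# medium = PBS_pH7.4\n"
                     "# guest_total_M = 1e-6\n"
                     "host_conc_M,r_obs\n0,0.005\n-0.001,0.01\n")
        report = validate_inputs([p])
        assert report[str(p)]["status"] == "error"

    def test_non_integer_counts_flagged_with_row(self, tmp_path):
        p = tmp_path / "decay.csv"
        p.write_text("time_ns,counts\n0.0,100\n0.1,55.5\n0.2,30\n")
        report = validate_inputs([p])
        assert report[str(p)]["status"] == "error"
        assert "row" in report[str(p)]["message"]

    def test_unreadable_file_does_not_stop_others(self, tmp_path):
        good = tmp_path / "ok.csv"
        q, _ = synth.make_quench(seed=0)
        dio.save_quench(good, q)
        report = validate_inputs([tmp_path / "missing.csv", good])
        assert report[str(good)]["status"] == "ok"
        assert report[str(tmp_path / "missing.csv")]["status"] == "error"


@pytest.fixture(scope="module")
def demo_report(tmp_path_factory):
    out = tmp_path_factory.mktemp("pipe")
    cfg = {
        "seed": 7,
        "stages": {
            "isotherms": {"synthetic": {"scenario": "cmbcd_1to1",
                                        "parameters": {"sigma_r": 0.0}}},
            "solubility": {"synthetic": {
                "scenario": "solubility",
                "parameters": {"sigma_frac": 0.0}}},
            "release": {"synthetic": {"scenario": "release",
                                      "parameters": {"sigma_frac": 0.0}}},
        },
    }
    return cfg, out, run_pipeline(cfg, out, seed=7)


class TestPipeline:
    def test_stages_complete_and_recover_truth(self, demo_report):
        _, out, rep = demo_report
        assert not rep.failures
        vh = rep.stages["isotherms"]["vant_hoff"]["citrate_pH3.5"]
        assert vh["dS_J_K_mol"] == pytest.approx(38.6, rel=1e-3)
        sol = rep.stages["solubility"]["solubility.csv"]
        assert sol["type"] == "A_L"
        assert sol["K_stability"] == pytest.approx(54.0, rel=5e-3)
        rel = rep.stages["release"]["release.csv"]
        assert rel["tau_half_min"] == pytest.approx(67.3, abs=0.3)

    def test_rerun_is_byte_identical(self, demo_report, tmp_path):
        cfg, out, _ = demo_report
        run_pipeline(cfg, tmp_path, seed=7)
        assert ((out / "results.json").read_bytes()
                == (tmp_path / "results.json").read_bytes())

    def test_empty_config_rejected(self, tmp_path):
        with pytest.raises(ValidationError):
            run_pipeline({"stages": {}}, tmp_path)

    def test_missing_file_named_in_failure(self, tmp_path):
        rep = run_pipeline(
            {"stages": {"release": {"file": str(tmp_path / "absent.csv")}}},
            tmp_path)
        assert "absent.csv" in rep.failures["release"]
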