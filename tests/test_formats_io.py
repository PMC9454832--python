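import numpy as np
import pandas as pd
import pytest

from ivgp.errors import ConfigError, DataError, FormatError, ValidationError
from ivgp.formats_io import (
    BottleMeta,
    RunConfig,
    read_endpoints,
    read_pressure_log,
    read_sample_sheet,
    write_endpoints,
    write_pressure_log,
    write_results_table,
    write_sample_sheet,
)
from ivgp.gas_conversion import PressureTrace


class TestPressureLog:
    def test_two_bottle_log_parses_to_two_traces(self, tmp_path):
        path = tmp_path / "log.csv"
        path.write_text(
            "bottle_id,time_min,cum_pressure_psi\n"
            "a,0,0.0\na,10,0.5\na,20,0.9\nb,0,0.0\nb,10,0.4\n"
        )
        traces = read_pressure_log(path)
        assert [t.bottle_id for t in traces] == ["a", "b"]
        assert [t.times_min.size for t in traces] == [3, 2]

    def test_rows_sorted_by_time_within_trace(self, tmp_path):
        path = tmp_path / "log.csv"
        path.write_text(
            "bottle_id,time_min,cum_pressure_psi\na,20,0.9\na,0,0.0\na,10,0.5\n"
        )
        (trace,) = read_pressure_log(path)
        assert np.all(np.diff(trace.times_min) > 0)
        assert trace.cum_psi[0] == 0.0

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "log.csv"
        path.write_text("bottle_id,time_min\na,0\n")
        with pytest.raises(FormatError, match="cum_pressure_psi"):
            read_pressure_log(path)

    def test_duplicate_bottle_time_is_data_error(self, tmp_path):
        path = tmp_path / "log.csv"
        path.write_text(
            "bottle_id,time_min,cum_pressure_psi\na,10,0.5\na,10,0.6\n"
        )
        with pytest.raises(DataError):
            read_pressure_log(path)

    def test_empty_data_section_gives_empty_collection(self, tmp_path, caplog):
        path = tmp_path / "log.csv"
        path.write_text("bottle_id,time_min,cum_pressure_psi\n")
        with caplog.at_level("WARNING"):
            assert read_pressure_log(path) == []
        assert "empty" in caplog.text

    def test_write_then_read_round_trip_is_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        traces = [
            PressureTrace("a", np.arange(5.0), rng.random(5)),
            PressureTrace("b", np.arange(3.0) * 10, rng.random(3) * 7),
        ]
        path = tmp_path / "log.csv"
        write_pressure_log(traces, path)
        back = read_pressure_log(path)
        for orig, rt in zip(traces, back):
            assert orig.bottle_id == rt.bottle_id
            np.testing.assert_array_equal(orig.times_min, rt.times_min)
            np.testing.assert_array_equal(orig.cum_psi, rt.cum_psi)


class TestSampleSheet:
    def _write(self, tmp_path, rows):
        path = tmp_path / "sheet.csv"
        header = "bottle_id,treatment,dose_pct,incubation_id,sample_mass_mg,dm_fraction,is_blank\n"
        path.write_text(header + "".join(rows))
        return path

    def test_study_design_parses_to_80_plus_blanks(self, tmp_path):
        rows = []
        cells = [("MS", 0)] + [(t, d) for t in ("BA", "HA", "TC")
                               for d in (20, 40, 100)]
        for inc in ("I1", "I2"):
            for t, d in cells:
                for r in range(4):
                    rows.append(f"{inc}_{t}{d}_r{r},{t},{d},{inc},500,0.93,False\n")
            rows.append(f"{inc}_BL,BL,0,{inc},,,True\n")
        metas = read_sample_sheet(self._write(tmp_path, rows))
        assert len(metas) == 82
        assert sum(not m.is_blank for m in metas) == 80

    def test_zero_dm_fraction_rejected(self, tmp_path):
        path = self._write(tmp_path, ["b,MS,0,I1,500,0.0,False\n"])
        with pytest.raises(ValidationError, match="dm_fraction"):
            read_sample_sheet(path)

    def test_unknown_treatment_rejected(self, tmp_path):
        path = self._write(tmp_path, ["b,XX,0,I1,500,0.9,False\n"])
        with pytest.raises(ValidationError, match="treatment"):
            read_sample_sheet(path)

    def test_dose_outside_design_rejected(self, tmp_path):
        path = self._write(tmp_path, ["b,BA,50,I1,500,0.9,False\n"])
        with pytest.raises(ValidationError, match="dose"):
            read_sample_sheet(path)

    def test_blank_row_without_mass_accepted(self, tmp_path):
        path = self._write(tmp_path, ["b,BL,0,I1,,,True\n"])
        (meta,) = read_sample_sheet(path)
        assert meta.is_blank and meta.dm_mass_g == 0.0

    def test_round_trip_preserves_fields(self, tmp_path):
        metas = [
            BottleMeta("b1", "BA", 40.0, "I2", 500.0, 0.931),
            BottleMeta("b2", "BL", 0.0, "I2", 0.0, 1.0, is_blank=True),
        ]
        path = tmp_path / "sheet.csv"
        write_sample_sheet(metas, path)
        assert read_sample_sheet(path) == metas


class TestResultsTable:
    def test_kinetics_rows_have_expected_columns(self, tmp_path):
        rows = [
            {"treatment": "BA", "dose_pct": 20.0, "A1": 185.7, "H1": 15.8,
             "Vmax": 8.7, "Tmax": 663.8, "GP6": 9.3, "GP48": 168.1},
        ]
        path = tmp_path / "t.tsv"
        write_results_table(rows, path)
        header = path.read_text().splitlines()[0].split("\t")
        for col in ("A1", "H1", "Vmax", "Tmax", "GP6", "GP48"):
            assert col in header

    def test_empty_input_yields_header_only(self, tmp_path):
        path = tmp_path / "t.tsv"
        write_results_table(pd.DataFrame(columns=["treatment", "A1"]), path)
        assert path.read_text().strip() == "treatment\tA1"

    def test_rerun_is_byte_identical_and_order_deterministic(self, tmp_path):
        rows = [
            {"treatment": "HA", "dose_pct": 40.0, "A1": 2.0},
            {"treatment": "BA", "dose_pct": 100.0, "A1": 1.0},
            {"treatment": "BA", "dose_pct": 20.0, "A1": 3.0},
        ]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_results_table(rows, p1)
        write_results_table(list(reversed(rows)), p2)
        assert p1.read_bytes() == p2.read_bytes()
        body = p1.read_text().splitlines()[1:]
        assert [line.split("\t")[0] for line in body] == ["BA", "BA", "HA"]


class TestEndpoints:
    def test_round_trip(self, tmp_path, small_experiment):
        path = tmp_path / "endpoints.csv"
        write_endpoints(small_experiment.records, path)
        back = read_endpoints(path)
        assert len(back) == len(small_experiment.records)
        orig = small_experiment.records[0]
        rt = next(r for r in back if r.bottle_id == orig.bottle_id)
        assert rt.vfa_mmol_per_l == dict(orig.vfa_mmol_per_l)
        assert rt.residue_dm_mg == orig.residue_dm_mg


class TestRunConfig:
    def test_headspace_is_required(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("incubation_temp_c: 39.0\n")
        with pytest.raises(ConfigError, match="headspace_ml"):
            RunConfig.from_yaml(path)

    def test_yaml_round_trip(self, tmp_path, run_cfg):
        path = tmp_path / "cfg.yaml"
        run_cfg.to_yaml(path)
        assert RunConfig.from_yaml(path) == run_cfg

    def test_fixed_hours_must_lie_in_horizon(self):
        with pytest.raises(ConfigError):
            RunConfig(headspace_ml=110.0, fixed_hours=(6.0, 72.0))
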