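"""Configuration handling, fixture generation and the command-line surface."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from hiertissue import ConfigError, FixtureSpec, d_crit, generate_fixture, load_config
from hiertissue.cli import main


@pytest.fixture
def config_file(tmp_path):
    p = tmp_path / "tissue.yaml"
    p.write_text(
        "N0: 10\nN: 2000\nn: 3\ngamma: 2.0\nt_life: 1.0\n"
        "s: 0.6\nmu: 0.005\nthreshold: 0.05\nseed: 3\nreplicates: 300\n"
        "grid_m: 400\nstem_asym_fraction: 1.0\n")
    return p


class TestConfig:
    def test_round_trip(self, config_file):
        cfg = load_config(config_file)
        assert cfg.N0 == 10 and cfg.gamma == 2.0 and cfg.seed == 3

    def test_unknown_keys_rejected(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("N0: 10\nN: 100\nbogus_knob: 1\n")
        with pytest.raises(ConfigError, match="bogus_knob"):
            load_config(p)

    def test_invalid_values_rejected(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("N0: 10\nN: 1\n")
        with pytest.raises(ConfigError):
            load_config(p)

    def test_overrides_take_precedence(self, config_file):
        cfg = load_config(config_file, gamma=3.0)
        assert cfg.gamma == 3.0


class TestFixtureGenerator:
    def test_deterministic_under_seed(self):
        H1, d1 = generate_fixture(FixtureSpec(seed=5))
        H2, d2 = generate_fixture(FixtureSpec(seed=5))
        assert H1.cell_numbers == H2.cell_numbers
        assert H1.rates == H2.rates
        assert (d1.s, d1.mu) == (d2.s, d2.mu)

    def test_fixture_contract(self):
        """Every fixture is homeostatic, integer-valued, and oracle-cheap."""
        for seed in range(6):
            H, spec = generate_fixture(FixtureSpec(seed=seed))
            Nk, W, delta = H.N_k, H.W_k, H.delta_k
            assert np.allclose(delta[:-1], Nk[1:] * W[1:], rtol=1e-10)
            assert np.allclose(Nk, np.round(Nk))
            gamma = H.gamma_k[1]
            dc = d_crit(spec.s, gamma)
            assert 1 <= dc <= 3
            assert 2 <= H.n <= 4
            assert spec.mu >= 1e-3
            # constant stem pool: purely asymmetric stem divisions
            assert H.rates[0].sym_diff == 0.0
            assert H.rates[0].sym_renewal == 0.0

    def test_d_crit_arithmetic_example(self):
        # gamma = 2, s = 0.6: two drivers of strength 0.6 overcome pi = 1
        assert d_crit(0.6, 2.0) == 2


class TestCli:
    def test_dcrit(self):
        res = CliRunner().invoke(main, ["dcrit", "--s", "0.1", "--gamma", "2"])
        assert res.exit_code == 0
        assert res.output.strip() == "10"

    def test_derive_emits_per_level_table(self, config_file):
        res = CliRunner().invoke(main, ["derive", "--config", str(config_file)])
        assert res.exit_code == 0
        lines = [l for l in res.output.splitlines() if l.strip()]
        assert lines[0].startswith("k\tN_k")
        assert len(lines) == 4  # header + levels 0..2

    def test_risk_json_contract(self, config_file, tmp_path):
        out = tmp_path / "risk.json"
        res = CliRunner().invoke(
            main, ["risk", "--config", str(config_file), "--json-out", str(out)])
        assert res.exit_code == 0, res.output
        payload = json.loads(out.read_text())
        for key in ("P_cancer", "stem_lineage_term", "development_term",
                    "d_crit", "grid_M"):
            assert key in payload
        assert payload["P_cancer"] == pytest.approx(
            payload["stem_lineage_term"] + payload["development_term"])

    def test_risk_deterministic_round_trip(self, config_file, tmp_path):
        outs = []
        for name in ("a.json", "b.json"):
            out = tmp_path / name
            res = CliRunner().invoke(
                main, ["risk", "--config", str(config_file), "--json-out", str(out)])
            assert res.exit_code == 0
            outs.append(out.read_text())
        assert outs[0] == outs[1]

    def test_simulate_outputs(self, config_file, tmp_path):
        out = tmp_path / "sim.json"
        res = CliRunner().invoke(
            main, ["simulate", "--config", str(config_file),
                   "--json-out", str(out)])
        assert res.exit_code == 0, res.output
        payload = json.loads(out.read_text())
        assert payload["replicates"] == 300
        assert payload["seed"] == 3
        assert 0 <= payload["frequency"] <= 1

    def test_invalid_config_exits_2(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("nonsense: true\n")
        res = CliRunner().invoke(main, ["risk", "--config", str(p)])
        assert res.exit_code == 2

    def test_scan_emits_one_row_per_cell(self, tmp_path):
        p = tmp_path / "scan.yaml"
        p.write_text(
            "N0: 100\nN: 1.0e6\nt_life: 80.0\nthreshold: 0.05\n"
            "s_values: [0.4, 0.6]\nmu_values: [1.0e-4, 1.0e-3]\n")
        res = CliRunner().invoke(main, ["scan", "--config", str(p)])
        assert res.exit_code == 0, res.output
        lines = [l for l in res.output.splitlines() if l.strip()]
        assert len(lines) == 5  # header + 4 cells
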