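"""Batch and CLI tests: config validation, orchestration, reproducibility."""

import json
from pathlib import Path

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from hamfrac.batch import ConfigError, run_batch, validate_config
from hamfrac.cli import main as cli_main


def small_config(out_dir, n_per_class=5, seed=7):
    """A fast end-to-end config: 2 classes x 5 slices at 128 px."""
    return validate_config(
        {
            "seed": seed,
            "out_dir": str(out_dir),
            "methods": ["unfiltered", "hp25", "hp50"],
            "filter": {"crop_side": 128},
            "sandbox": {"n_centers": 100, "n_radii": 8},
            "fixture": {
                "n_per_class": n_per_class,
                "classes": {
                    "low": {"side_px": 128, "fat_fraction_target": 0.15},
                    "high": {"side_px": 128, "fat_fraction_target": 0.30},
                },
            },
        }
    )


class TestValidateConfig:
    def test_minimal_fixture_config_gets_all_defaults(self):
        cfg = validate_config(
            {"fixture": {"classes": {"a": {"fat_fraction_target": 0.2}}}}
        )
        assert cfg.filter.radius_px == 25.0
        assert cfg.filter.threshold_unfiltered == 175
        assert cfg.filter.threshold_filtered == 150
        assert cfg.filter.crop_side == 512
        assert cfg.methods == ("unfiltered", "hp25", "hp50")
        assert cfg.sandbox.n_centers == 1000

    @pytest.mark.parametrize(
        "raw,fragment",
        [
            ({"fixture": {"classes": {"a": {}}}, "bogus": 1}, "bogus"),
            ({"fixture": {"classes": {"a": {}}}, "filter": {"radius_px": 300}}, "filter"),
            ({"fixture": {"classes": {"a": {}}}, "filter": {"threshold_filtered": 400}}, "filter"),
            ({"fixture": {"classes": {"a": {"wat": 1}}}}, "wat"),
            ({"fixture": {"classes": {}}}, "classes"),
            ({"fixture": {"classes": {"a": {}}}, "methods": []}, "method"),
            ({"fixture": {"classes": {"a": {}}}, "methods": ["lowpass"]}, "lowpass"),
            ({}, "fixture"),
        ],
    )
    def test_violations_reported_with_field_path(self, raw, fragment):
        with pytest.raises(ConfigError, match=fragment):
            validate_config(raw)


@pytest.fixture(scope="module")
def completed(tmp_path_factory):
    out = tmp_path_factory.mktemp("run")
    cfg = small_config(out)
    manifest = run_batch(cfg)
    return out, cfg, manifest


class TestRunBatch:
    def test_record_cardinality(self, completed):
        out, cfg, manifest = completed
        assert manifest.ok
        n_images = 2 * cfg.fixture.n_per_class
        assert len(list((out / "mfa").glob("*.json"))) == n_images * 3
        assert len(list((out / "masks").glob("*.png"))) == n_images * 3
        assert len(list((out / "tables").glob("*.csv"))) == n_images * 3

    def test_summary_files_present(self, completed):
        out, _, manifest = completed
        for name in ("scatter.csv", "summary.csv", "boxstats.csv", "dispersion.csv"):
            assert (out / name).exists()
            assert name in manifest.summary_files

    def test_manifest_lists_every_output_once(self, completed):
        out, _, manifest = completed
        listed = [p for rec in manifest.images for o in rec["outputs"].values()
                  for p in o.values()]
        assert len(listed) == len(set(listed))
        for rel in listed:
            assert (out / rel).exists()

    def test_manifest_recreates_run(self, completed, tmp_path):
        """The manifest's config echo reproduces every artifact byte."""
        out, _, manifest = completed
        raw = dict(manifest.config)
        raw["out_dir"] = str(tmp_path / "again")
        again = run_batch(validate_config(raw))
        for rec in manifest.images:
            for outputs in rec["outputs"].values():
                for rel in outputs.values():
                    assert (Path(raw["out_dir"]) / rel).read_bytes() == (out / rel).read_bytes()


class TestCli:
    @pytest.fixture()
    def runner(self):
        return CliRunner()

    def test_generate_pipeline_mfa_chain(self, runner, tmp_path):
        spec = {
            "n_per_class": 2,
            "classes": {"a": {"side_px": 64, "fat_fraction_target": 0.25}},
        }
        spec_path = tmp_path / "fixture.yaml"
        spec_path.write_text(yaml.safe_dump(spec))
        fx_dir = tmp_path / "fx"
        res = runner.invoke(cli_main, ["generate", "--config", str(spec_path),
                                       "--seed", "3", "--out", str(fx_dir)])
        assert res.exit_code == 0, res.output
        manifest = json.loads((fx_dir / "fixture.json").read_text())
        assert len(manifest["images"]) == 2

        res = runner.invoke(cli_main, ["pipeline", "--input", str(fx_dir / "a_000.png"),
                                       "--method", "hp25", "--out-dir", str(tmp_path / "seg")])
        assert res.exit_code == 0, res.output
        assert "fat fraction" in res.output

        res = runner.invoke(cli_main, ["mfa", "--input", str(tmp_path / "seg" / "a_000_hp25.csv"),
                                       "--n-centers", "50", "--seed", "1",
                                       "--out", str(tmp_path / "mfa.json")])
        assert res.exit_code == 0, res.output
        rec = json.loads((tmp_path / "mfa.json").read_text())
        assert {e["q"] for e in rec["estimates"]} == {0.0, 1.0, 2.0}

    def test_run_command_exit_code(self, runner, tmp_path):
        cfg = {
            "seed": 1,
            "methods": ["unfiltered", "hp25", "hp50"],
            "filter": {"crop_side": 128},
            "sandbox": {"n_centers": 100, "n_radii": 8},
            "fixture": {
                "n_per_class": 2,
                "classes": {"a": {"side_px": 128, "fat_fraction_target": 0.2}},
            },
        }
        cfg_path = tmp_path / "run.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg))
        res = runner.invoke(cli_main, ["run", "--config", str(cfg_path),
                                       "--out", str(tmp_path / "out")])
        assert res.exit_code == 0, res.output
        assert (tmp_path / "out" / "manifest.json").exists()
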