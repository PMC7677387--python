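"""NIfTI round-trips, configuration, CLI and pipeline orchestration."""

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from psoasvol import io
from psoasvol.cli import main as cli_main
from psoasvol.config import PipelineConfig, PipelineError, stage_seed
from psoasvol.core import DixonVolume, LandmarkSet, MuscleMask
from psoasvol.pipeline import run_pipeline
from psoasvol.synthetic import PhantomSpec


class TestNiftiIO:
    def test_volume_roundtrip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        vol = DixonVolume(rng.random((12, 10, 8), dtype=np.float32).astype(np.float32))
        io.write_volume(vol, tmp_path / "v.nii")
        back = io.read_volume(tmp_path / "v.nii")
        assert np.array_equal(back.data, vol.data)
        assert np.allclose(back.voxel_mm, vol.voxel_mm, atol=1e-6)

    def test_mask_roundtrip_uint8(self, tmp_path):
        m = MuscleMask((np.random.default_rng(1).random((6, 6, 6)) > 0.5
                        ).astype(np.uint8))
        io.write_mask(m, tmp_path / "m.nii")
        back = io.read_mask(tmp_path / "m.nii")
        assert np.array_equal(back.data, m.data)
        assert back.data.dtype == np.uint8

    def test_anisotropic_affine_voxel_extraction(self, tmp_path):
        data = np.zeros((5, 6, 7), dtype=np.float32)
        affine = np.diag([1.5, 2.25, 3.75, 1.0])
        nib.save(nib.Nifti1Image(data, affine), str(tmp_path / "a.nii"))
        vol = io.read_volume(tmp_path / "a.nii")
        assert vol.voxel_mm == pytest.approx((1.5, 2.25, 3.75))

    def test_non_nifti_file_raises_format_error(self, tmp_path):
        bad = tmp_path / "bad.nii"
        bad.write_text("this is not a nifti")
        with pytest.raises(io.FormatError):
            io.read_volume(bad)

    def test_landmark_csv_roundtrip(self, tmp_path):
        lms = {"s1": LandmarkSet((3, 4, 5), (1, 4, 5))}
        io.write_landmarks(lms, tmp_path / "lm.csv")
        back = io.read_landmarks(tmp_path / "lm.csv")
        assert back["s1"] == lms["s1"]

    def test_malformed_landmark_csv(self, tmp_path):
        (tmp_path / "lm.csv").write_text("subject_id,lx\na,1\n")
        with pytest.raises(io.FormatError, match="missing"):
            io.read_landmarks(tmp_path / "lm.csv")


class TestConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = PipelineConfig(seed=5, n_female=2, n_male=3)
        path = tmp_path / "c.yaml"
        import yaml

        path.write_text(yaml.safe_dump(cfg.to_dict()))
        back = PipelineConfig.from_yaml(path)
        assert back.seed == 5
        assert back.config_hash() == cfg.config_hash()

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown config"):
            PipelineConfig.from_dict({"bogus": 1})

    def test_stage_seed_fanout_distinct_and_stable(self):
        seeds = {s: stage_seed(42, s) for s in ("train", "segment", "stats")}
        assert len(set(seeds.values())) == 3
        assert stage_seed(42, "train") == seeds["train"]


def _tiny_config(out_dir, seed=3):
    from psoasvol.training import TrainConfig

    cfg = PipelineConfig(out_dir=str(out_dir), seed=seed,
                         n_female=2, n_male=2)
    cfg.phantom = PhantomSpec.desk()
    cfg.train = TrainConfig(learning_rate=1e-3, batch_size=3, epochs=2, seed=seed)
    return cfg


class TestPipeline:
    def test_stats_without_cohort_names_quantify(self, tmp_path):
        cfg = _tiny_config(tmp_path / "run")
        with pytest.raises(PipelineError, match="quantify"):
            run_pipeline(cfg, ["stats"])

    def test_segment_without_model_names_train(self, tmp_path):
        cfg = _tiny_config(tmp_path / "run")
        run_pipeline(cfg, ["generate-phantoms"])
        with pytest.raises(PipelineError, match="train"):
            run_pipeline(cfg, ["segment"])

    def test_full_run_produces_all_artifacts(self, tmp_path):
        out = tmp_path / "run"
        cfg = _tiny_config(out)
        run_pipeline(cfg)
        for artifact in ("landmarks.csv", "demographics.csv",
                         "model/weights.npz", "cohort.csv",
                         "report/stats.json"):
            assert (out / artifact).exists(), artifact
        cohort = pd.read_csv(out / "cohort.csv")
        assert len(cohort) == 4
        assert {"left_ml", "right_ml", "total_ml", "imi"} <= set(cohort.columns)
        # provenance sidecars carry the seed and config hash
        side = json.loads((out / "cohort.csv.provenance.json").read_text())
        assert side["seed"] == cfg.seed
        assert side["config_hash"] == cfg.config_hash()

    def test_repeat_run_byte_identical_cohort(self, tmp_path):
        a = _tiny_config(tmp_path / "a", seed=11)
        b = _tiny_config(tmp_path / "b", seed=11)
        run_pipeline(a)
        run_pipeline(b)
        assert (tmp_path / "a" / "cohort.csv").read_bytes() == \
            (tmp_path / "b" / "cohort.csv").read_bytes()

    def test_unknown_stage_rejected(self, tmp_path):
        with pytest.raises(PipelineError, match="unknown"):
            run_pipeline(_tiny_config(tmp_path / "x"), ["explode"])


class TestCli:
    def test_help_lists_subcommands(self):
        result = CliRunner().invoke(cli_main, ["--help"])
        assert result.exit_code == 0
        for cmd in ("generate-phantoms", "preprocess", "augment", "train",
                    "cross-validate", "segment", "quantify", "stats",
                    "run-all"):
            assert cmd in result.output

    def test_generate_phantoms_command(self, tmp_path):
        import yaml

        cfg = _tiny_config(tmp_path / "out")
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg.to_dict()))
        result = CliRunner().invoke(cli_main, [
            "generate-phantoms", "--config", str(cfg_path)])
        assert result.exit_code == 0, result.output
        assert (tmp_path / "out" / "landmarks.csv").exists()

    def test_stats_missing_cohort_is_actionable(self, tmp_path):
        result = CliRunner().invoke(cli_main, [
            "stats", "--cohort", str(tmp_path / "nope.csv")])
        assert result.exit_code != 0
        assert "quantify" in result.output
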