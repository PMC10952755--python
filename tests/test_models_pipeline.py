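"""Model/Results interfaces, the end-to-end pipeline, and the CLI."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from b1dam.b0model import fit_b0_spline
from b1dam.bloch import AcquisitionParams
from b1dam.models import DoubleAngleModel, VFAT1Model
from b1dam.phantom import (PhantomConfig, generate_phantom, forward_dam,
                           sample_b0_map)
from b1dam.pipeline import RunConfig, run_pipeline

FAST = dict(phantom={"nx": 10, "ny": 10}, n_z=51, pulse_samples=256,
            roi_diameter_px=3, t1_fit_roi_only=True)


@pytest.fixture(scope="module")
def noiseless_report():
    cfg = RunConfig(dam_noise_sigma=0.0, spgr_noise_sigma=0.0,
                    b0_noise_hz=0.0, **FAST)
    return run_pipeline(cfg)


class TestDoubleAngleModel:
    def test_shape_mismatch_fails_fast(self):
        with pytest.raises(ValueError, match="shape"):
            DoubleAngleModel(np.zeros((4, 4, 3)), np.zeros((4, 5, 3)))

    def test_all_false_mask_gives_empty_map(self, lut):
        img = np.ones((4, 4, 3))
        model = DoubleAngleModel(img, img, mask=np.zeros((4, 4, 3), bool),
                                 lut=lut)
        res = model.fit("slice_profile")
        assert np.all(np.isnan(res.b1_factor))
        assert res.method == "slice_profile"

    def test_unknown_method_rejected(self, lut):
        img = np.ones((2, 2, 2))
        with pytest.raises(ValueError, match="unknown method"):
            DoubleAngleModel(img, img, lut=lut).fit("magic")

    def test_naive_fit_needs_no_lut(self):
        img1 = np.full((3, 3, 2), 1.0)
        img2 = np.full((3, 3, 2), 1.0)   # ratio 1 -> 60 deg -> b1 = 60/65
        res = DoubleAngleModel(img1, img2).fit("naive")
        assert np.allclose(res.b1_factor, 60.0 / 65.0, atol=1e-9)

    def test_summary_has_per_slice_rows(self, noiseless_report):
        df = noiseless_report["b1_maps"]["b0_corrected"].summary()
        assert set(["slice", "n_voxels", "median_b1"]).issubset(df.columns)
        assert len(df) == 15

    def test_qc_plot_smoke(self, noiseless_report):
        import matplotlib
        matplotlib.use("Agg")
        ax = noiseless_report["b1_maps"]["b0_corrected"].plot(slice_index=3)
        assert ax.get_title().startswith("B1+")
        ax2 = noiseless_report["t1_maps"]["b0_corrected"].plot(slice_index=3)
        assert "T1" in ax2.get_title()


class TestPipeline:
    def test_report_contains_three_b1_methods_and_two_t1_maps(
            self, noiseless_report):
        assert set(noiseless_report["b1_maps"]) == {
            "naive", "slice_profile", "b0_corrected"}
        assert set(noiseless_report["t1_maps"]) == {
            "slice_profile", "b0_corrected"}

    def test_median_error_ordering(self, noiseless_report):
        """Median |B1+ error|: naive > slice-profile > gradient-corrected."""
        tbl = noiseless_report["b1_error_table"].set_index("method")
        med = tbl["median_err_pct"].abs()
        assert med["naive"] > med["slice_profile"] > med["b0_corrected"]

    def test_corrected_b1_error_below_half_percent(self, noiseless_report):
        err = noiseless_report["b1_maps"]["b0_corrected"].error_vs(
            noiseless_report["phantom"].b1_true)
        assert np.nanmedian(np.abs(err)) < 0.5

    def test_error_grows_linearly_with_local_gradient(self, noiseless_report):
        """Slice-profile-only error vs local through-slice gradient follows
        the scaling law on the phantom (a few %/10 Hz/cm, negative sign)."""
        rep = noiseless_report
        ph = rep["phantom"]
        err = rep["b1_maps"]["slice_profile"].error_vs(ph.b1_true)
        zc = ph.slice_centers_cm
        ii, jj, ss = np.nonzero(np.isfinite(err) & ph.mask)
        # local gradient of the continuous field at each voxel center
        h = 0.05
        g = (ph.b0_at(ii, jj, zc[ss][:, None] + h)[:, 0]
             - ph.b0_at(ii, jj, zc[ss][:, None] - h)[:, 0]) / (2 * h)
        e = err[ii, jj, ss]
        slope = np.polyfit(g, e, 1)[0] * 10
        assert -5.0 < slope < -2.0

    def test_rerun_same_config_gives_identical_outputs(self, tmp_path):
        cfg = RunConfig(**FAST)
        digests = []
        for d in ("a", "b"):
            out = tmp_path / d
            run_pipeline(cfg, out_dir=out)
            h = hashlib.sha256()
            for f in sorted(Path(out).glob("*.csv")):
                h.update(f.read_bytes())
            digests.append(h.hexdigest())
        assert digests[0] == digests[1]
        assert (tmp_path / "a" / "config.yaml").exists()
        assert (tmp_path / "a" / "manifest.json").exists()

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = RunConfig(**FAST)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = RunConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back == cfg
        assert back.digest() == cfg.digest()


class TestVFAT1Model:
    def test_b1_map_resampled_to_spgr_grid(self):
        from b1dam.epg import SPGRAcquisition
        b1 = np.full((8, 8, 15), 1.0)
        vols = np.full((16, 16, 15, 4), 0.01)
        model = VFAT1Model(vols, SPGRAcquisition(), b1, spoiling=None)
        assert model.b1.shape == (16, 16, 15)
        assert np.allclose(model.b1, 1.0)

    def test_wrong_volume_count_rejected(self):
        from b1dam.epg import SPGRAcquisition
        with pytest.raises(ValueError):
            VFAT1Model(np.zeros((4, 4, 3, 2)), SPGRAcquisition(),
                       np.ones((4, 4, 3)), spoiling=None)


def test_cli_file_based_workflow(tmp_path):
    """make-phantom -> correct-b1 -> fit-t1 -> analyze-trend on NIfTI files."""
    from click.testing import CliRunner
    from b1dam.cli import main
    import yaml
    from dataclasses import asdict

    cfg = RunConfig(dam_noise_sigma=0.0, spgr_noise_sigma=0.0, b0_noise_hz=0.0,
                    phantom={"nx": 8, "ny": 8}, n_z=51, pulse_samples=256)
    cfg_path = tmp_path / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh)
    runner = CliRunner()
    data = tmp_path / "data"
    res = runner.invoke(main, ["make-phantom", "--config", str(cfg_path),
                               "--seed", "4", "--out", str(data)])
    assert res.exit_code == 0, res.output

    b1_path = tmp_path / "b1.nii.gz"
    res = runner.invoke(main, [
        "correct-b1", "--alpha-img", str(data / "dam_alpha.nii.gz"),
        "--double-img", str(data / "dam_2alpha.nii.gz"),
        "--b0-map", str(data / "b0_map.nii.gz"),
        "--mask", str(data / "mask.nii.gz"),
        "--config", str(cfg_path), "--method", "b0_corrected",
        "--out", str(b1_path)])
    assert res.exit_code == 0, res.output

    t1_path = tmp_path / "t1.nii.gz"
    args = ["fit-t1"]
    for k in range(4):
        args += ["--spgr-imgs", str(data / f"spgr_fa{k}.nii.gz")]
    args += ["--b1-map", str(b1_path), "--mask", str(data / "mask.nii.gz"),
             "--config", str(cfg_path), "--out", str(t1_path)]
    res = runner.invoke(main, args)
    assert res.exit_code == 0, res.output

    rois = pd.DataFrame([(s, 3.5, 3.5, 3.0) for s in range(15)],
                        columns=["slice", "center_x", "center_y", "diameter_px"])
    roi_path = tmp_path / "rois.csv"
    rois.to_csv(roi_path, index=False)
    res = runner.invoke(main, ["analyze-trend", "--t1-map", str(t1_path),
                               "--rois", str(roi_path),
                               "--out", str(tmp_path / "trend.csv")])
    assert res.exit_code == 0, res.output
    trend = pd.read_csv(tmp_path / "trend.csv")
    assert np.isfinite(trend["delta_t1_ms"][0])
    # noiseless, B0-corrected: the residual T1 trend is essentially flat
    assert abs(trend["delta_t1_ms"][0]) < 20.0


def test_cli_build_lut_and_run_all(tmp_path):
    from click.testing import CliRunner
    from b1dam.cli import main
    import yaml
    from dataclasses import asdict

    cfg = RunConfig(dam_noise_sigma=0.0, spgr_noise_sigma=0.0, b0_noise_hz=0.0,
                    **FAST)
    cfg_path = tmp_path / "config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh)

    runner = CliRunner()
    res = runner.invoke(main, ["build-lut", "--config", str(cfg_path),
                               "--out", str(tmp_path / "lut")])
    assert res.exit_code == 0, res.output
    assert "ambiguity angle" in res.output
    assert (tmp_path / "lut.csv").exists()

    res = runner.invoke(main, ["run-all", "--config", str(cfg_path),
                               "--seed", "0", "--out", str(tmp_path / "run")])
    assert res.exit_code == 0, res.output
    assert (tmp_path / "run" / "delta_t1.csv").exists()
    dt = pd.read_csv(tmp_path / "run" / "delta_t1.csv")
    assert set(dt["b1_method"]) == {"slice_profile", "b0_corrected"}
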