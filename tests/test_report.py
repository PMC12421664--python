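import numpy as np
import pytest
import yaml
from matplotlib import pyplot as plt
from openpyxl import load_workbook

from ledkit import (
    HeatmapSpec,
    assemble_fp_nbody,
    assemble_standard_nbody,
    assemble_twobody,
    export_matrices,
    generate_ground_truth,
    load_matrices,
    render_heatmap,
    run_pipeline,
    write_mock_outputs,
)
from ledkit.errors import ConfigurationError, LEDParseError
from ledkit.report import _draw_heatmap, matrixset_from_export


def _nbody_sets(S=2, f=(2, 2), seed=0, mode="uncorrected"):
    gt = generate_ground_truth(S, f, seed=seed)
    recs = gt.records("main", mode)
    std = assemble_standard_nbody(recs["super"], list(recs["subsystems"].values()), gt.subsystems)
    return gt, recs, std


class TestExport:
    def test_sheet_inventory_fp(self, tmp_path):
        _, _, std = _nbody_sets()
        fp = assemble_fp_nbody(std)
        path = export_matrices(fp, tmp_path / "fp.xlsx")
        wb = load_workbook(path)
        assert set(wb.sheetnames) == {"total", "elprep", "elstat", "exch", "no_disp", "disp", "metadata"}

    def test_round_trip_exact(self, tmp_path):
        _, _, std = _nbody_sets(seed=4)
        path = export_matrices(std, tmp_path / "std.xlsx")
        frames, meta = load_matrices(path)
        np.testing.assert_allclose(frames["total"].to_numpy(), std.components["total"], atol=1e-12)
        assert meta["layout"] == "standard"
        assert meta["units"] == "kcal/mol"
        # CSV mirrors exist and carry full precision
        csv = path.with_suffix("").as_posix() + "_total.csv"
        import pandas as pd

        np.testing.assert_allclose(
            pd.read_csv(csv, index_col=0).to_numpy(), std.components["total"], atol=1e-12
        )

    def test_absent_cells_written_empty(self, tmp_path):
        gt = generate_ground_truth(2, (2, 1), seed=2)
        recs = gt.records("main", "uncorrected")
        tb = assemble_twobody(
            list(recs["pairs"].values()), list(recs["monomers"].values()), gt.subsystems, False, layout="fp"
        )
        path = export_matrices(tb, tmp_path / "tb.xlsx")
        wb = load_workbook(path)
        # cell (1,2) is intra-subsystem -> absent -> empty, not 0
        assert tb.absent_mask[0, 1]
        assert wb["total"].cell(row=2, column=3).value is None

    def test_matrixset_from_export_reconstructs(self, tmp_path):
        _, _, std = _nbody_sets(seed=6)
        path = export_matrices(std, tmp_path / "std.xlsx")
        back = matrixset_from_export(path)
        assert back.fragment_labels == std.fragment_labels
        assert back.subsystem_of == std.subsystem_of
        np.testing.assert_allclose(back.components["elstat"], std.components["elstat"], atol=1e-12)


class TestHeatmap:
    def test_all_zero_matrix_uniform_neutral(self):
        _, _, std = _nbody_sets()
        for mat in std.components.values():
            mat[:] = 0.0
        fig, ax = _draw_heatmap(std, "total", HeatmapSpec())
        im = ax.images[0]
        rgba = im.cmap(im.norm(im.get_array()))
        # all cells identical -> single neutral colour
        assert np.allclose(rgba, rgba[0, 0], atol=1e-12)
        plt.close(fig)

    def test_attraction_red_repulsion_blue(self):
        """The most negative (attractive) cell sits at the red end of the
        diverging colormap and the most positive at the blue end."""
        _, _, std = _nbody_sets(seed=9)
        fig, ax = _draw_heatmap(std, "total", HeatmapSpec())
        im = ax.images[0]
        data = np.asarray(im.get_array())
        positions = np.asarray(im.norm(data))  # 0 = red end, 1 = blue end for coolwarm_r
        i, j = np.unravel_index(np.argmin(data), data.shape)
        assert positions[i, j] == pytest.approx(positions.min(), abs=1e-12)
        r, g, b, _ = im.cmap(positions[i, j])
        assert r > b  # attraction rendered red
        k, l = np.unravel_index(np.argmax(data), data.shape)
        r2, g2, b2, _ = im.cmap(positions[k, l])
        assert data[k, l] <= 0 or b2 > r2  # repulsion rendered blue
        # zero maps to the neutral midpoint
        rz, gz, bz, _ = im.cmap(float(im.norm(0.0)))
        assert abs(rz - bz) < 0.1
        plt.close(fig)

    def test_black_box_spans_intersubsystem_block(self):
        gt = generate_ground_truth(2, (3, 3), seed=1)
        recs = gt.records("main", "uncorrected")
        std = assemble_standard_nbody(recs["super"], list(recs["subsystems"].values()), gt.subsystems)
        fp = assemble_fp_nbody(std)
        fig, ax = _draw_heatmap(fp, "total", HeatmapSpec())
        box = next(p for p in ax.patches if p.get_gid() == "box:black:A-B")
        assert box.get_xy() == (2.5, -0.5)
        assert (box.get_width(), box.get_height()) == (3, 3)
        # green boxes around both three-fragment subsystems, no turquoise in fp
        green = [p for p in ax.patches if (p.get_gid() or "").startswith("box:green")]
        turquoise = [p for p in ax.patches if (p.get_gid() or "").startswith("box:turquoise")]
        assert len(green) == 2 and not turquoise
        plt.close(fig)

    def test_standard_layout_gets_turquoise_diagonal_boxes(self):
        _, _, std = _nbody_sets(S=2, f=(2, 2))
        fig, ax = _draw_heatmap(std, "total", HeatmapSpec())
        turquoise = [p for p in ax.patches if (p.get_gid() or "").startswith("box:turquoise")]
        assert len(turquoise) == 4
        plt.close(fig)

    def test_unknown_component_rejected(self, tmp_path):
        _, _, std = _nbody_sets()
        with pytest.raises(ConfigurationError):
            render_heatmap(std, "bogus", HeatmapSpec(output_path=tmp_path / "x"))

    def test_render_writes_file(self, tmp_path):
        _, _, std = _nbody_sets()
        out = render_heatmap(std, "total", HeatmapSpec(output_path=tmp_path / "hm", figure_format="png"))
        assert out.exists() and out.suffix == ".png"


def _write_config(tmp_path, gt, mode, twobody=True, **extra):
    tag = "cp" if mode == "corrected" else "nocp"
    d = tmp_path / "outs"
    cfg = {
        "output_dir": str(tmp_path / "bundle"),
        "bsse_corrected": mode == "corrected",
        "subsystems": {s.name: sorted(s.fragment_ids) for s in gt.subsystems},
        "nbody": {
            "supersystem": str(d / f"main_{tag}_super.out"),
            "subsystems": {
                s.name: str(d / f"main_{tag}_sub-{s.name}.out") for s in gt.subsystems
            },
        },
        **extra,
    }
    if twobody:
        cfg["twobody"] = {
            "pairs": [str(p) for p in sorted(d.glob(f"main_{tag}_pair-*.out"))],
            "monomers": [str(p) for p in sorted(d.glob(f"main_{tag}_mono-*.out"))],
        }
    path = tmp_path / "config.yaml"
    path.write_text(yaml.safe_dump(cfg))
    return path


class TestPipeline:
    def test_nbody_only_config_produces_no_cooperativity(self, tmp_path):
        gt = generate_ground_truth(2, (2, 1), seed=3)
        write_mock_outputs(gt, tmp_path / "outs", mode="uncorrected")
        bundle = run_pipeline(_write_config(tmp_path, gt, "uncorrected", twobody=False))
        assert not any("cooperativity" in name for name in bundle)
        assert "nbody_standard.xlsx" in bundle and "nbody_fp.xlsx" in bundle

    def test_full_mock_campaign_bundle_inventory(self, tmp_path):
        gt = generate_ground_truth(2, (2, 2), seed=5)
        write_mock_outputs(gt, tmp_path / "outs", mode="corrected")
        bundle = run_pipeline(
            _write_config(tmp_path, gt, "corrected", heatmaps={"components": ["total"]})
        )
        for stem in (
            "nbody_standard",
            "nbody_fp",
            "twobody_standard",
            "twobody_fp",
            "cooperativity_standard",
            "cooperativity_fp",
        ):
            assert f"{stem}.xlsx" in bundle
            assert f"{stem}_total.png" in bundle
        assert (tmp_path / "bundle" / "ledkit.log").exists()

    def test_bsse_correction_read_out_as_cooperativity(self, tmp_path):
        """Corrected outputs as N-body vs uncorrected as two-body isolates the
        counterpoise correction on a two-fragment system."""
        gt = generate_ground_truth(2, (1, 1), seed=8)
        d = tmp_path / "outs"
        write_mock_outputs(gt, d, mode="corrected")
        write_mock_outputs(gt, d, mode="uncorrected")
        cfg = {
            "output_dir": str(tmp_path / "bundle"),
            "bsse_corrected": True,
            "subsystems": {"A": [1], "B": [2]},
            "nbody": {
                "supersystem": str(d / "main_cp_super.out"),
                "subsystems": {"A": str(d / "main_cp_sub-A.out"), "B": str(d / "main_cp_sub-B.out")},
            },
            # the uncorrected N-body files, fed in as the "two-body" analysis
            "twobody": {
                "bsse_corrected": False,
                "pairs": [str(d / "main_nocp_super.out")],
                "monomers": [str(d / "main_nocp_sub-A.out"), str(d / "main_nocp_sub-B.out")],
            },
        }
        p = tmp_path / "cfg.yaml"
        p.write_text(yaml.safe_dump(cfg))
        bundle = run_pipeline(p)
        coop = matrixset_from_export(bundle["cooperativity_standard.xlsx"])
        t = gt.plants["main"]
        from ledkit import HARTREE_TO_KCAL

        for x in (1, 2):
            expected = (
                (t["sub_pert"]["uncorrected"][x]["ref"] - t["sub_pert"]["corrected"][x]["ref"])
                + (t["sub_pert"]["uncorrected"][x]["corr"] - t["sub_pert"]["corrected"][x]["corr"])
            ) * HARTREE_TO_KCAL
            assert coop.components["total"][x - 1, x - 1] == pytest.approx(expected, abs=1e-6)
            assert expected >= 0  # BSSE correction is repulsive on each part
        # the genuine pair interaction cancels between the two analyses
        assert coop.components["total"][0, 1] == pytest.approx(0.0, abs=1e-6)

    def test_stage_error_names_stage_and_file(self, tmp_path):
        gt = generate_ground_truth(2, (1, 1), seed=4)
        d = tmp_path / "outs"
        write_mock_outputs(gt, d, mode="uncorrected")
        (d / "main_nocp_sub-A.out").write_text("not an output file\n")
        with pytest.raises(LEDParseError, match="N-body parse/align"):
            run_pipeline(_write_config(tmp_path, gt, "uncorrected", twobody=False))

    def test_alternative_output_salvages_partial_main(self, tmp_path):
        from ledkit import parse_led_output, write_led_output

        gt = generate_ground_truth(2, (1, 1), seed=12)
        d = tmp_path / "outs"
        write_mock_outputs(gt, d, mode="uncorrected")
        # cripple the main supersystem file: drop all correlation lines
        main = d / "main_nocp_super.out"
        alt = d / "main_nocp_super_alt.out"
        alt.write_text(main.read_text())
        crippled = [
            l
            for l in main.read_text().splitlines()
            if "correlation" not in l and "CORR." not in l and "Total interaction" not in l
        ]
        main.write_text("\n".join(crippled) + "\n")
        cfg_path = _write_config(tmp_path, gt, "uncorrected", twobody=False)
        cfg = yaml.safe_load(cfg_path.read_text())
        cfg["nbody"]["alternatives"] = {"supersystem": str(alt)}
        cfg_path.write_text(yaml.safe_dump(cfg))
        bundle = run_pipeline(cfg_path)
        ms = matrixset_from_export(bundle["nbody_standard.xlsx"])
        truth = gt.expected_standard_components("main", "uncorrected")
        np.testing.assert_allclose(ms.components["total"], truth["total"], atol=1e-6)
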