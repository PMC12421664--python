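"""Spreadsheet export, heat maps, and end-to-end pipeline orchestration.

Heat-map conventions follow the field's habit for interaction-energy
matrices: a diverging colormap centered at zero with red for attraction
(negative energies) and blue for repulsion (positive), plus overlay boxes
derived from the subsystem definition — turquoise around the diagonal
electronic-preparation cells (standard layout), green around each
multi-fragment subsystem's differential block, and a black box around every
inter-subsystem submatrix of genuine pair interactions. Absent cells are
drawn hatched and exported as empty spreadsheet cells, never as zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml
from matplotlib import colors as mcolors
from matplotlib.patches import Rectangle

from .errors import ConfigurationError, LedkitError
from .extrap import ExtrapolationParams, default_cbs_params, extrapolate_matrixset
from .inputgen import SubsystemSpec
from .ledmat import (
    LEDMatrixSet,
    PUBLIC_COMPONENTS,
    assemble_fp_nbody,
    assemble_standard_nbody,
    assemble_twobody,
    cooperativity,
)
from .ledout import LEDRecord, align_labels, exclude_redundant_hfld, merge_alternative, parse_led_output, relabel

__all__ = [
    "HeatmapSpec",
    "export_matrices",
    "load_matrices",
    "matrixset_from_export",
    "render_heatmap",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class HeatmapSpec:
    """Rendering options for one heat map."""

    colormap: str = "coolwarm_r"  # reversed so negative (attractive) is red
    annotate_cells: bool = True
    value_format: int = 2  # decimal places
    overlay_boxes: bool = True
    triangular: bool = False
    title: str = ""
    output_path: str | Path = "heatmap.png"
    figure_format: str = "png"


def export_matrices(ms: LEDMatrixSet, path: str | Path, precision: int = 2) -> Path:
    """Write an xlsx workbook (one sheet per component + metadata) and CSV mirrors.

    Cell values are stored at full precision with a ``precision``-decimal
    display format; the CSV mirrors always carry full precision. Absent cells
    are written empty.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    labels = [str(l) for l in ms.fragment_labels]
    frames: dict[str, pd.DataFrame] = {}
    for name in PUBLIC_COMPONENTS:
        if name not in ms.components:
            continue
        frames[name] = pd.DataFrame(ms.components[name], index=labels, columns=labels)

    meta_rows = [
        ("layout", ms.layout),
        ("body_order", ms.body_order),
        ("bsse_corrected", str(ms.bsse_corrected)),
        ("units", "kcal/mol"),
        ("fragment_labels", " ".join(labels)),
        ("subsystem_of", " ".join(f"{k}:{v}" for k, v in sorted(ms.subsystem_of.items()))),
    ] + [(k, str(v)) for k, v in sorted(ms.meta.items())]
    meta = pd.DataFrame(meta_rows, columns=["key", "value"])

    with pd.ExcelWriter(path, engine="openpyxl") as writer:
        for name, frame in frames.items():
            frame.to_excel(writer, sheet_name=name)
            sheet = writer.book[name]
            fmt = "0." + "0" * precision
            for row in sheet.iter_rows(min_row=2, min_col=2):
                for cell in row:
                    cell.number_format = fmt
        meta.to_excel(writer, sheet_name="metadata", index=False)

    for name, frame in frames.items():
        frame.to_csv(path.with_suffix("") .as_posix() + f"_{name}.csv")
    return path


def load_matrices(path: str | Path) -> tuple[dict[str, pd.DataFrame], dict[str, str]]:
    """Read back an exported workbook: component frames plus metadata dict."""
    sheets = pd.read_excel(Path(path), sheet_name=None, index_col=0)
    meta_frame = sheets.pop("metadata").reset_index()
    meta = dict(zip(meta_frame["key"].astype(str), meta_frame["value"].astype(str)))
    return sheets, meta


def matrixset_from_export(path: str | Path) -> LEDMatrixSet:
    """Rebuild a (public-component) matrix set from an exported workbook."""
    frames, meta = load_matrices(path)
    labels = [int(l) for l in meta["fragment_labels"].split()]
    sub_of = dict(pair.split(":") for pair in meta["subsystem_of"].split())
    components = {name: frame.to_numpy(dtype=float) for name, frame in frames.items()}
    probe = components.get("elstat", next(iter(components.values())))
    return LEDMatrixSet(
        layout=meta["layout"],
        components=components,
        fragment_labels=labels,
        subsystem_of={int(k): v for k, v in sub_of.items()},
        bsse_corrected=meta["bsse_corrected"] == "True",
        body_order=meta["body_order"],
        absent_mask=np.isnan(probe) if meta["body_order"] != "nbody" else None,
        meta={k: v for k, v in meta.items() if k not in ("layout", "body_order", "bsse_corrected", "units", "fragment_labels", "subsystem_of")},
    )


def _subsystem_blocks(ms: LEDMatrixSet) -> dict[str, tuple[int, int]]:
    """Index range (first, last) each subsystem occupies along the matrix axis."""
    blocks: dict[str, tuple[int, int]] = {}
    for i, label in enumerate(ms.fragment_labels):
        name = ms.subsystem_of[label]
        lo, hi = blocks.get(name, (i, i))
        blocks[name] = (min(lo, i), max(hi, i))
    return blocks


def render_heatmap(ms: LEDMatrixSet, component: str, spec: HeatmapSpec | None = None) -> Path:
    """Render one component matrix as a heat map figure file."""
    spec = spec or HeatmapSpec()
    fig, _ = _draw_heatmap(ms, component, spec)
    out = Path(spec.output_path).with_suffix(f".{spec.figure_format}")
    out.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out


def _draw_heatmap(ms: LEDMatrixSet, component: str, spec: HeatmapSpec):
    """Build the heat-map figure; separated from file output for testability."""
    if component not in ms.components:
        raise ConfigurationError(f"matrix set has no component {component!r}")
    mat = ms.components[component].copy()
    f = ms.n_fragments
    if spec.triangular:
        mat[np.tril_indices(f, k=-1)] = np.nan

    finite = mat[np.isfinite(mat)]
    halfrange = max(float(np.max(np.abs(finite))) if finite.size else 0.0, 1e-12)
    norm = mcolors.CenteredNorm(vcenter=0.0, halfrange=halfrange)

    fig, ax = plt.subplots(figsize=(1.1 * f + 2.2, 1.1 * f + 1.6))
    masked = np.ma.masked_invalid(mat)
    cmap = plt.get_cmap(spec.colormap).copy()
    cmap.set_bad(color="0.85")
    im = ax.imshow(masked, cmap=cmap, norm=norm)
    fig.colorbar(im, ax=ax, label="kcal/mol")

    labels = [str(l) for l in ms.fragment_labels]
    ax.set_xticks(range(f), labels)
    ax.set_yticks(range(f), labels)
    ax.set_title(spec.title or f"{ms.body_order} {ms.layout} LED: {component}")

    if spec.annotate_cells:
        for i in range(f):
            for j in range(f):
                if np.isfinite(mat[i, j]):
                    ax.text(j, i, f"{mat[i, j]:.{spec.value_format}f}", ha="center", va="center", fontsize=8)
                elif ms.absent_mask[i, j] and (not spec.triangular or j >= i):
                    ax.text(j, i, "—", ha="center", va="center", fontsize=8, color="0.4")

    if spec.overlay_boxes:
        blocks = _subsystem_blocks(ms)
        if ms.layout == "standard":
            for i in range(f):
                ax.add_patch(
                    Rectangle((i - 0.5, i - 0.5), 1, 1, fill=False, edgecolor="turquoise", lw=2.0, gid=f"box:turquoise:{i}")
                )
        for name, (lo, hi) in blocks.items():
            if hi > lo:
                ax.add_patch(
                    Rectangle((lo - 0.5, lo - 0.5), hi - lo + 1, hi - lo + 1, fill=False, edgecolor="green", lw=2.0, gid=f"box:green:{name}")
                )
        names = sorted(blocks)
        for a in range(len(names)):
            for b in range(a + 1, len(names)):
                (rlo, rhi), (clo, chi) = blocks[names[a]], blocks[names[b]]
                ax.add_patch(
                    Rectangle(
                        (clo - 0.5, rlo - 0.5),
                        chi - clo + 1,
                        rhi - rlo + 1,
                        fill=False,
                        edgecolor="black",
                        lw=2.0,
                        gid=f"box:black:{names[a]}-{names[b]}",
                    )
                )

    return fig, ax


# ---------------------------------------------------------------- pipeline


def _parse_and_align(paths: dict, super_path: str, alternatives: dict | None, hfld: bool, tol: float):
    """Parse the supersystem and part files, align everything to supersystem labels."""
    super_rec = parse_led_output(super_path)
    alternatives = alternatives or {}
    if "supersystem" in alternatives:
        super_rec = merge_alternative(super_rec, parse_led_output(alternatives["supersystem"]), tol=tol)
    if hfld:
        super_rec = exclude_redundant_hfld(super_rec)
    parts = []
    for name, p in paths.items():
        rec = parse_led_output(p)
        if name in alternatives:
            rec = merge_alternative(rec, parse_led_output(alternatives[name]), tol=tol)
        rec = relabel(rec, align_labels(rec, super_rec, tol=tol))
        if hfld:
            rec = exclude_redundant_hfld(rec)
        parts.append(rec)
    return super_rec, parts


def _load_aligned(paths: list, super_rec: LEDRecord, hfld: bool, tol: float) -> list[LEDRecord]:
    out = []
    for p in paths:
        rec = parse_led_output(p)
        rec = relabel(rec, align_labels(rec, super_rec, tol=tol))
        if hfld:
            rec = exclude_redundant_hfld(rec)
        out.append(rec)
    return out


def run_pipeline(config_path: str | Path) -> dict[str, Path]:
    """Run parse -> align -> assemble -> (two-body, cooperativity, extrapolation)
    -> export + heat maps from a YAML config; returns the produced file bundle.

    Cooperativity runs automatically whenever both N-body and two-body inputs
    are configured. Any stage failure is re-raised with the stage name.
    """
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    out_dir = Path(cfg.get("output_dir", "ledkit_out"))
    out_dir.mkdir(parents=True, exist_ok=True)

    log_handler = logging.FileHandler(out_dir / "ledkit.log")
    log_handler.setLevel(logging.INFO)
    logging.getLogger("ledkit").addHandler(log_handler)
    logging.getLogger("ledkit").setLevel(logging.INFO)

    bundle: dict[str, Path] = {}
    stage = "configuration"
    try:
        subsystems = [SubsystemSpec(name, ids) for name, ids in cfg["subsystems"].items()]
        hfld = str(cfg.get("method", "")).upper() == "HFLD"
        bsse = bool(cfg.get("bsse_corrected", False))
        scheme = cfg.get("fp_scheme", "equal")
        tol = float(cfg.get("alignment_tolerance", 1e-4))

        def build_sets(section: dict, tag: str) -> dict[str, LEDMatrixSet]:
            nonlocal stage
            stage = f"{tag}: N-body parse/align"
            nb = section["nbody"]
            super_rec, parts = _parse_and_align(
                nb["subsystems"], nb["supersystem"], nb.get("alternatives"), hfld, tol
            )
            stage = f"{tag}: N-body assembly"
            std = assemble_standard_nbody(super_rec, parts, subsystems)
            fp = assemble_fp_nbody(std, partitioner=scheme)
            sets = {"nbody_standard": std, "nbody_fp": fp}
            tb = section.get("twobody")
            if tb:
                stage = f"{tag}: two-body parse/align"
                tb_bsse = bool(tb.get("bsse_corrected", bsse))
                pair_recs = _load_aligned(tb["pairs"], super_rec, hfld, tol)
                mono_recs = _load_aligned(tb["monomers"], super_rec, hfld, tol)
                stage = f"{tag}: two-body assembly"
                sets["twobody_standard"] = assemble_twobody(pair_recs, mono_recs, subsystems, tb_bsse, layout="standard")
                sets["twobody_fp"] = assemble_twobody(pair_recs, mono_recs, subsystems, tb_bsse, layout="fp")
                stage = f"{tag}: cooperativity"
                logger.info("both N-body and two-body inputs configured; running cooperativity")
                sets["cooperativity_standard"] = cooperativity(sets["nbody_standard"], sets["twobody_standard"])
                sets["cooperativity_fp"] = cooperativity(sets["nbody_fp"], sets["twobody_fp"])
            return sets

        sets = build_sets(cfg, "main")

        ext_cfg = cfg.get("extrapolation")
        if ext_cfg:
            stage = "extrapolation"
            kind = str(ext_cfg["kind"]).upper()
            x, y = int(ext_cfg["x"]), int(ext_cfg["y"])
            if kind == "CBS" and "alpha" not in ext_cfg:
                params = default_cbs_params(x, y, ext_cfg.get("basis_family", "cc"))
            else:
                params = ExtrapolationParams(
                    kind, x, y,
                    alpha=ext_cfg.get("alpha"), beta=ext_cfg.get("beta"), F=ext_cfg.get("f"),
                )
            second = build_sets(ext_cfg["second"], "extrapolation-Y")
            stage = "extrapolation"
            for key in list(sets):
                if key in second and not key.startswith("cooperativity"):
                    sets[f"extrapolated_{key}"] = extrapolate_matrixset(sets[key], second[key], params)

        stage = "export"
        for name, ms in sets.items():
            bundle[f"{name}.xlsx"] = export_matrices(ms, out_dir / f"{name}.xlsx")

        hm_cfg = cfg.get("heatmaps")
        if hm_cfg:
            stage = "heat maps"
            components = hm_cfg.get("components", ["total"])
            fmt = hm_cfg.get("format", "png")
            for name, ms in sets.items():
                for comp in components:
                    if comp not in ms.components:
                        continue
                    spec = HeatmapSpec(
                        output_path=out_dir / f"{name}_{comp}.{fmt}",
                        figure_format=fmt,
                        annotate_cells=bool(hm_cfg.get("annotate", True)),
                        value_format=int(hm_cfg.get("decimals", 2)),
                    )
                    bundle[f"{name}_{comp}.{fmt}"] = render_heatmap(ms, comp, spec)
    except LedkitError as exc:
        raise type(exc)(f"pipeline stage '{stage}' failed: {exc}") from exc
    finally:
        logging.getLogger("ledkit").removeHandler(log_handler)
        log_handler.close()

    return bundle
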