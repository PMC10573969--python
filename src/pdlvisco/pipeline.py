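"""End-to-end orchestration: synthesize (or load) a study, analyze every
stage, and write a report bundle.

The bundle contains the three summary tables the study design calls for —
reduced moduli per region x plane, collagen content per region x slice,
and fitted creep parameters per sample — plus averaged strain curves and a
manifest recording the seed, configuration hash, and package version.
Re-running with an identical configuration is bit-reproducible (plots,
which embed no randomness but are raster artifacts, are opt-in).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .creep import SchaperyCreepModel, fit_all
from .fiber import ROI, StainedImage, content_table, measure_vf, segment_collagen, summarize_region
from .indentation import (
    IndentationRecord,
    modulus_table,
    reduced_modulus_flat_punch,
    segment_record,
    strain_from_displacement,
    average_curves,
)
from .synthetic import generate_study

log = logging.getLogger("pdlvisco.pipeline")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name and offending sample id."""

    def __init__(self, stage: str, sample: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {sample!r}: {cause}")
        self.stage = stage
        self.sample = sample
        self.__cause__ = cause


def _load_manifest(data_dir: Path) -> dict:
    mpath = data_dir / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"no manifest.json in {data_dir}")
    return json.loads(mpath.read_text())


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run generate -> segment -> strain -> fit -> fiber-content -> report.

    Returns the report manifest (also written to ``out_dir``/report.json).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proto = config.protocol.build()
    context = config.context.build()
    seg_params = config.segmentation.build()

    # --- data stage ---------------------------------------------------------
    if config.synthesize:
        data_dir = out / "data"
        log.info("synthesizing study into %s (seed=%d)", data_dir, config.seed)
        manifest = generate_study(
            data_dir,
            seed=config.seed,
            noise_sd=config.synthesis.noise_sd,
            protocol=proto,
            thickness_um=config.synthesis.thickness_um,
            image_size=config.synthesis.image_size,
            n_points_per_region=config.synthesis.n_points_per_region,
            n_slices=config.synthesis.n_slices,
        )
    else:
        if config.input_dir is None:
            raise FileNotFoundError("synthesize=false requires input_dir")
        data_dir = Path(config.input_dir)
        if not data_dir.exists():
            raise FileNotFoundError(f"input directory does not exist: {data_dir}")
        manifest = _load_manifest(data_dir)

    # --- indentation analysis ----------------------------------------------
    curves = []
    modulus_rows = []
    strain_series: dict[tuple[str, str], list] = {}
    for entry in manifest["records"]:
        sample = entry["path"]
        try:
            rec = IndentationRecord.from_csv(data_dir / sample)
            seg = segment_record(rec, proto)
            curve = strain_from_displacement(
                rec, seg, hold_relative=config.hold_relative_strain
            )
            curves.append(curve)
            strain_series.setdefault((rec.region, rec.plane), []).append(
                (curve.t, curve.eps)
            )
            u0, u1 = seg.unload
            if u1 - u0 >= 2:
                em = reduced_modulus_flat_punch(
                    rec.P[u0:u1], rec.h[u0:u1], proto.indenter_radius_um,
                    top_fraction=config.unload_top_fraction,
                )
                modulus_rows.append((rec.region, rec.plane, em.E_star_MPa))
        except Exception as exc:  # noqa: BLE001 — re-raise with stage context
            raise PipelineStageError("indentation", sample, exc) from exc

    # --- creep fitting ------------------------------------------------------
    try:
        fit_table = fit_all(curves, context)
    except Exception as exc:
        raise PipelineStageError("creep_fitting", "<all curves>", exc) from exc
    fit_path = out / "creep_parameters.csv"
    fit_table.to_csv(fit_path, index=False, float_format="%.10g")

    # --- averaged strain curves --------------------------------------------
    avg_frames = []
    for (region, plane), series in sorted(strain_series.items(), key=str):
        xg, mean_eps, count = average_curves(series)
        avg_frames.append(
            pd.DataFrame(
                {"region": region, "plane": plane, "time_s": xg,
                 "mean_strain": mean_eps, "n": count}
            )
        )
    avg_path = out / "averaged_strain_curves.csv"
    pd.concat(avg_frames, ignore_index=True).to_csv(
        avg_path, index=False, float_format="%.10g"
    )

    # --- reduced modulus table ---------------------------------------------
    mod_path = None
    if modulus_rows:
        mod_path = out / "reduced_modulus.csv"
        modulus_table(modulus_rows).to_csv(mod_path, float_format="%.10g")

    # --- fiber content ------------------------------------------------------
    per_region_vf: dict[str, list[float]] = {}
    for entry in manifest["images"]:
        sample = entry["path"]
        try:
            img = StainedImage.read(data_dir / sample, region=entry["region"])
            roi = ROI(rect=(0, 0, *img.shape))
            mask = segment_collagen(img, roi, seg_params)
            m = measure_vf(mask, roi, slice_id=img.slice_id, region=img.region)
            per_region_vf.setdefault(entry["region"], []).append(m.vf)
        except Exception as exc:
            raise PipelineStageError("fiber_content", sample, exc) from exc
    summaries = [
        summarize_region(vals, region) for region, vals in sorted(per_region_vf.items())
    ]
    vf_path = None
    if summaries:
        vf_path = out / "collagen_content.csv"
        content_table(summaries).to_csv(vf_path, float_format="%.10g")

    # --- optional plots -----------------------------------------------------
    if config.make_plots:
        _plot_curves(curves, fit_table, context, out / "plots")

    report = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "segmentation_rule": config.segmentation.model_dump(),
        "n_curves": len(curves),
        "n_images": len(manifest["images"]),
        "outputs": {
            "creep_parameters": fit_path.name,
            "averaged_strain_curves": avg_path.name,
            "reduced_modulus": mod_path.name if mod_path else None,
            "collagen_content": vf_path.name if vf_path else None,
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    log.info("report written to %s", out / "report.json")
    return report


def _plot_curves(curves, fit_table, context, plot_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot_dir.mkdir(parents=True, exist_ok=True)
    for curve in curves:
        res = SchaperyCreepModel(curve, context).fit()
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(curve.t, curve.eps, ".", ms=3, label="data")
        ax.plot(curve.t, res.predict(), "-", label="fit")
        ax.set_xlabel("hold time (s)")
        ax.set_ylabel("strain")
        ax.set_title(curve.sample_id)
        ax.legend()
        fig.tight_layout()
        fig.savefig(plot_dir / f"{curve.sample_id}.png", dpi=100)
        plt.close(fig)
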