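"""Synthetic study generator.

Emulates the experimental design the analysis modules expect, with known
ground truth everywhere:

* nano-indentation records following the constant-load creep protocol
  (0.5 mN/s ramp to 3 mN, 200 s hold, flat cylindrical R = 100 um indenter)
  whose hold-stage depth follows the fiber-content strain law;
* Masson-style stained images whose collagen mask covers a prescribed
  area fraction, rendered in Masson-blue collagen on red background;
* a full study layout: 3 root regions x 2 sampling planes x 5 indentation
  points, and 5 stained slices x 3 regions, plus a JSON manifest.

Everything is driven by one integer seed; identical specs give identical
output.  Analyzers never read the ground truth — only tests do.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.color import hsv2rgb

from .constitutive import (
    SLSParameters,
    SchaperyParameters,
    StepLoad,
    ValidationError,
    reduced_from_full,
)
from .creep import CreepCurve
from .fiber import StainedImage
from .indentation import IndentationRecord, LoadProtocol
from . import reference

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_indentation_record",
    "generate_masson_image",
    "generate_study",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Everything needed to synthesize one indentation record.

    ``noise_sd`` is the depth-noise standard deviation in strain units
    (i.e. the depth noise is noise_sd * thickness, um).  ``unload_E_star_MPa``
    sets the elastic stiffness of the optional linear unload branch.
    """

    protocol: LoadProtocol = field(default_factory=LoadProtocol)
    sls: SLSParameters = field(default_factory=lambda: SLSParameters(1.0, 1.0, 260.0))
    schapery: SchaperyParameters = field(
        default_factory=lambda: SchaperyParameters(g0=0.005, g1=1.0, g2=-0.01)
    )
    load: StepLoad = field(default_factory=lambda: StepLoad(1.0))
    thickness_um: float = 200.0
    noise_sd: float = 0.0
    n_points_per_region: int = 5
    seed: int = 0
    include_unload: bool = True
    unload_E_star_MPa: float = 3.0
    dt_loading_s: float = 0.1
    dt_hold_s: float = 1.0
    dt_unload_s: float = 0.25

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.thickness_um <= 0:
            raise ValidationError("thickness_um must be > 0")
        if self.n_points_per_region < 1:
            raise ValidationError("n_points_per_region must be >= 1")


@dataclass
class GroundTruth:
    """Generating truth serialized alongside every synthetic artifact."""

    schapery: dict | None = None
    sls: dict | None = None
    sigma0: float | None = None
    reduced: dict | None = None
    segments: dict | None = None
    unload_E_star_MPa: float | None = None
    target_vf: float | None = None
    mask_vf: float | None = None
    seed: int | None = None

    def to_json(self) -> str:
        d = {k: v for k, v in asdict(self).items() if v is not None}
        return json.dumps(d, indent=1, sort_keys=True)


def _warn_unresolvable(sls: SLSParameters, hold_time: float) -> None:
    import warnings

    if sls.tau1 >= 5.0 * hold_time:
        warnings.warn(
            f"retardation time tau1 = {sls.tau1:.1f} s >= 5x hold time "
            f"({hold_time:.0f} s): creep parameters will be poorly resolvable",
            stacklevel=3,
        )


def generate_indentation_record(
    spec: SyntheticSpec,
    region: str | None = None,
    plane: str | None = None,
    point_id: str = "synthetic",
    rng: np.random.Generator | None = None,
) -> tuple[IndentationRecord, GroundTruth]:
    """One synthetic time/load/depth record following the creep protocol.

    Loading ramp: P(t) = rate * t to the peak; depth quasi-static from the
    instantaneous term g0*D0p*sigma(t) only (the hold stage is what the
    fits use).  Hold: depth = thickness * eps(t_hold) from the full strain
    law, so the hold-stage strain equals the constitutive response exactly
    in the noiseless case.  Optional linear elastic unload with stiffness
    S = 2 E* R.  Gaussian noise of sd noise_sd * thickness is added to
    depth when requested.
    """
    proto = spec.protocol
    _warn_unresolvable(spec.sls, proto.hold_time_s)
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    red = reduced_from_full(spec.schapery, spec.sls, spec.load)
    t_load_end = proto.loading_duration_s

    t_load = np.arange(0.0, t_load_end, spec.dt_loading_s)
    n_hold = int(round(proto.hold_time_s / spec.dt_hold_s)) + 1
    t_hold = t_load_end + np.arange(n_hold) * spec.dt_hold_s

    P_load = proto.loading_rate_mN_s * t_load
    P_hold = np.full(n_hold, proto.peak_load_mN)
    # instantaneous strain tracks the ramping stress
    eps_load = red.A * (P_load / proto.peak_load_mN)
    eps_hold = np.asarray(red.strain(t_hold - t_load_end))
    h_load = spec.thickness_um * eps_load
    h_hold = spec.thickness_um * eps_hold

    t_parts = [t_load, t_hold]
    P_parts = [P_load, P_hold]
    h_parts = [h_load, h_hold]

    if spec.include_unload:
        S_mN_um = 2.0 * spec.unload_E_star_MPa * proto.indenter_radius_um * 1e-3
        n_un = max(int(round(t_load_end / spec.dt_unload_s)), 2)
        t_un = t_hold[-1] + np.arange(1, n_un + 1) * spec.dt_unload_s
        P_un = proto.peak_load_mN - proto.loading_rate_mN_s * (t_un - t_hold[-1])
        P_un = np.clip(P_un, 0.0, None)
        h_un = h_hold[-1] - (proto.peak_load_mN - P_un) / S_mN_um
        t_parts.append(t_un)
        P_parts.append(P_un)
        h_parts.append(h_un)

    t = np.concatenate(t_parts)
    P = np.concatenate(P_parts)
    h = np.concatenate(h_parts)
    if spec.noise_sd > 0:
        h = h + rng.normal(0.0, spec.noise_sd * spec.thickness_um, size=h.shape)

    i_hold0 = len(t_load)
    i_hold1 = i_hold0 + n_hold
    rec = IndentationRecord(
        t=t, P=P, h=h, thickness_um=spec.thickness_um,
        region=region, plane=plane, point_id=point_id,
    )
    truth = GroundTruth(
        schapery=asdict(spec.schapery),
        sls=asdict(spec.sls),
        sigma0=spec.load.sigma0,
        reduced={"A": red.A, "B": red.B, "tau": red.tau},
        segments={
            "loading": [0, i_hold0],
            "hold": [i_hold0, i_hold1],
            "unload": [i_hold1, len(t)],
        },
        unload_E_star_MPa=spec.unload_E_star_MPa if spec.include_unload else None,
        seed=spec.seed,
    )
    return rec, truth


def generate_hold_curve(
    schapery: SchaperyParameters,
    sls: SLSParameters,
    load: StepLoad | None = None,
    n_points: int = 201,
    hold_time_s: float = 200.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    **meta,
) -> CreepCurve:
    """Hold-stage strain curve straight from the strain law (no record plumbing)."""
    load = load or StepLoad(1.0)
    t = np.linspace(0.0, hold_time_s, n_points)
    red = reduced_from_full(schapery, sls, load)
    eps = np.asarray(red.strain(t))
    if noise_sd > 0:
        if rng is None:
            raise ValidationError("noisy generation requires an explicit rng")
        eps = eps + rng.normal(0.0, noise_sd, size=eps.shape)
    return CreepCurve(t=t, eps=eps, **meta)


def _fiber_field(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    """Curvilinear fiber-bundle texture: anisotropically smoothed noise.

    Three independently oriented elongated smoothing kernels are blended so
    threshold sets look like wavy interwoven bundles rather than blobs.
    """
    h, w = shape
    field = np.zeros(shape)
    for sig in ((1.5, 10.0), (10.0, 1.5), (4.0, 4.0)):
        field += gaussian_filter(rng.standard_normal(shape), sigma=sig)
    # mild large-scale modulation so bundle density varies across the frame
    field += 0.5 * gaussian_filter(rng.standard_normal(shape), sigma=min(h, w) / 8.0)
    return field


def generate_masson_image(
    target_vf: float,
    size: int = 1024,
    seed: int = 0,
    rgb_noise: float = 0.02,
    **meta,
) -> tuple[StainedImage, np.ndarray, GroundTruth]:
    """Masson-style image whose true collagen mask covers ``target_vf`` %.

    The mask is a quantile threshold of a fiber-bundle texture, so its area
    fraction matches the target to sub-pixel quantization.  Collagen pixels
    are rendered in Masson-blue hues, background in red; a little RGB noise
    keeps segmentation honest.  Returns (image, ground-truth mask, truth).
    """
    if not 0.0 <= target_vf <= 100.0:
        raise ValidationError("target_vf must lie in [0, 100]")
    if size < 8:
        raise ValidationError("size must be >= 8 px")
    rng = np.random.default_rng(seed)
    shape = (size, size)
    if target_vf == 0.0:
        mask = np.zeros(shape, dtype=bool)
    elif target_vf == 100.0:
        mask = np.ones(shape, dtype=bool)
    else:
        fieldv = _fiber_field(shape, rng)
        thresh = np.quantile(fieldv, 1.0 - target_vf / 100.0)
        mask = fieldv > thresh

    hsv = np.empty(shape + (3,))
    # collagen: blue hue band; background: red (hue wraps near 0)
    hsv[..., 0] = np.where(mask, rng.uniform(0.52, 0.66, shape), rng.uniform(0.96, 1.0, shape) % 1.0)
    hsv[..., 1] = np.where(mask, rng.uniform(0.45, 0.85, shape), rng.uniform(0.35, 0.75, shape))
    hsv[..., 2] = rng.uniform(0.55, 0.95, shape)
    rgb = hsv2rgb(hsv)
    if rgb_noise > 0:
        rgb = np.clip(rgb + rng.normal(0.0, rgb_noise, rgb.shape), 0.0, 1.0)
    pixels = (rgb * 255).round().astype(np.uint8)

    img = StainedImage(pixels=pixels, **meta)
    truth = GroundTruth(
        target_vf=float(target_vf),
        mask_vf=100.0 * float(mask.sum()) / mask.size,
        seed=seed,
    )
    return img, mask, truth


# package convention: sample index 1 = transverse, 2 = longitudinal
STUDY_PLANES = {"transverse": 1, "longitudinal": 2}


def generate_study(
    out_dir: str | Path,
    seed: int = 0,
    noise_sd: float = 0.0,
    protocol: LoadProtocol | None = None,
    thickness_um: float = 200.0,
    image_size: int = 256,
    n_points_per_region: int = reference.POINTS_PER_REGION,
    n_slices: int = reference.SLICES_PER_REGION,
    write_masks: bool = True,
) -> dict:
    """Write a full synthetic study to ``out_dir`` and return its manifest.

    Layout: records/<region>_<plane>_p<k>.csv (+ JSON sidecars),
    images/<region>_s<j>.png (+ ground-truth masks), manifest.json.
    Each region x plane uses the published creep-parameter column for that
    region (column 1 = transverse, 2 = longitudinal); each region's slice
    images target the published per-slice collagen fractions.
    """
    out = Path(out_dir)
    (out / "records").mkdir(parents=True, exist_ok=True)
    (out / "images").mkdir(parents=True, exist_ok=True)
    protocol = protocol or LoadProtocol()
    root = np.random.SeedSequence(seed)
    manifest: dict = {
        "seed": seed,
        "noise_sd": noise_sd,
        "thickness_um": thickness_um,
        "records": [],
        "images": [],
    }

    regions = ("neck", "middle", "apex")
    rec_seeds = iter(root.spawn(len(regions) * len(STUDY_PLANES) * n_points_per_region))
    for region in regions:
        for plane, col in STUDY_PLANES.items():
            pars = reference.CREEP_PARAMETERS[f"{region}-{col}"]
            sch = SchaperyParameters(g0=pars["g0"], g1=1.0, g2=pars["g2"])
            sls = SLSParameters(1.0, 1.0, pars["eta"])
            for k in range(1, n_points_per_region + 1):
                ss = next(rec_seeds)
                child_seed = int(ss.generate_state(1)[0] % (2**31))
                spec = SyntheticSpec(
                    protocol=protocol,
                    sls=sls,
                    schapery=sch,
                    load=StepLoad(1.0),
                    thickness_um=thickness_um,
                    noise_sd=noise_sd,
                    seed=child_seed,
                )
                point_id = f"{region}_{plane}_p{k}"
                rec, truth = generate_indentation_record(
                    spec, region=region, plane=plane, point_id=point_id
                )
                path = out / "records" / f"{point_id}.csv"
                rec.to_csv(path)
                (out / "records" / f"{point_id}.truth.json").write_text(truth.to_json())
                manifest["records"].append(
                    {
                        "path": f"records/{point_id}.csv",
                        "region": region,
                        "plane": plane,
                        "point": k,
                        "truth": f"records/{point_id}.truth.json",
                        "generating": {"g0": sch.g0, "g2": sch.g2, "eta": sls.eta},
                    }
                )

    img_seeds = iter(root.spawn(len(regions) * n_slices))
    for region in regions:
        slice_targets = reference.COLLAGEN_VF_SLICES[region]
        for j in range(1, n_slices + 1):
            ss = next(img_seeds)
            child_seed = int(ss.generate_state(1)[0] % (2**31))
            target = slice_targets[(j - 1) % len(slice_targets)]
            slice_id = f"{region}_s{j}"
            img, mask, truth = generate_masson_image(
                target_vf=target, size=image_size, seed=child_seed,
                slice_id=slice_id, region=region,
            )
            img.write(out / "images" / f"{slice_id}.png")
            entry = {
                "path": f"images/{slice_id}.png",
                "region": region,
                "slice": j,
                "target_vf": target,
                "mask_vf": truth.mask_vf,
            }
            if write_masks:
                iio.imwrite(
                    out / "images" / f"{slice_id}.mask.png",
                    (mask.astype(np.uint8) * 255),
                )
                entry["mask"] = f"images/{slice_id}.mask.png"
            manifest["images"].append(entry)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
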