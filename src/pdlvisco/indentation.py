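"""Nano-indentation record handling.

Parses time/load/depth records from a constant-load creep protocol
(load ramp at a fixed rate to a peak, hold at peak, unload), segments them
into loading / hold / unload stages, converts hold-stage displacement to
strain by dividing by the local PDL thickness, averages replicate curves,
and extracts the reduced elastic modulus from the unloading branch.

The indenter is a rigid flat-ended cylinder of radius R, so the contact
area is constant and the unloading stiffness S = dP/dh relates to the
reduced modulus by the flat-punch result E* = S / (2R) (the constant-area
specialization of the Oliver–Pharr unloading analysis).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constitutive import DegenerateInputError, ValidationError
from .creep import CreepCurve

__all__ = [
    "LoadProtocol",
    "IndentationRecord",
    "SegmentedRecord",
    "ReducedModulus",
    "SegmentationError",
    "segment_record",
    "strain_from_displacement",
    "average_curves",
    "reduced_modulus_flat_punch",
]


class SegmentationError(ValueError):
    """The record cannot be split into the protocol's stages."""


@dataclass(frozen=True)
class LoadProtocol:
    """Constant-load creep protocol for a flat cylindrical indenter."""

    loading_rate_mN_s: float = 0.5
    peak_load_mN: float = 3.0
    hold_time_s: float = 200.0
    indenter_radius_um: float = 100.0
    indenter_shape: str = "cylindrical"

    def __post_init__(self) -> None:
        for name in ("loading_rate_mN_s", "peak_load_mN", "hold_time_s", "indenter_radius_um"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.indenter_shape != "cylindrical":
            raise ValidationError("only the cylindrical flat-punch indenter is supported")

    @property
    def loading_duration_s(self) -> float:
        return self.peak_load_mN / self.loading_rate_mN_s

    @property
    def contact_area_mm2(self) -> float:
        """Flat-punch face area pi*R^2, mm^2."""
        r_mm = self.indenter_radius_um / 1000.0
        return float(np.pi * r_mm**2)


@dataclass(frozen=True)
class IndentationRecord:
    """Raw time/load/depth triplets plus sample metadata.

    t in s, P in mN, h in um (zero-corrected depth); thickness is the local
    PDL thickness in um used for the strain conversion.
    """

    t: np.ndarray
    P: np.ndarray
    h: np.ndarray
    thickness_um: float
    region: str | None = None
    plane: str | None = None
    point_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        P = np.asarray(self.P, dtype=float)
        h = np.asarray(self.h, dtype=float)
        for name, arr in (("t", t), ("P", P), ("h", h)):
            object.__setattr__(self, name, arr)
        if not (len(t) == len(P) == len(h)) or t.ndim != 1:
            raise ValidationError("t, P, h must be 1-D arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("t must be strictly increasing")
        if np.any(P < 0):
            raise ValidationError("loads must be non-negative")
        if not (np.isfinite(self.thickness_um) and self.thickness_um > 0):
            raise ValidationError("thickness_um must be finite and > 0")

    @classmethod
    def from_csv(
        cls, path: str | Path, thickness_um: float | None = None, **meta
    ) -> "IndentationRecord":
        """Read columns time_s, load_mN, depth_um; metadata from a JSON
        sidecar (<stem>.json) when present, overridden by keyword args."""
        path = Path(path)
        df = pd.read_csv(path)
        sidecar = path.with_suffix(".json")
        info: dict = {}
        if sidecar.exists():
            info = json.loads(sidecar.read_text())
        if thickness_um is not None:
            info["thickness_um"] = thickness_um
        info.update(meta)
        if "thickness_um" not in info:
            raise ValidationError(f"no thickness for {path.name}: pass thickness_um or a sidecar JSON")
        return cls(
            t=df["time_s"].to_numpy(),
            P=df["load_mN"].to_numpy(),
            h=df["depth_um"].to_numpy(),
            thickness_um=float(info["thickness_um"]),
            region=info.get("region"),
            plane=info.get("plane"),
            point_id=str(info.get("point_id", path.stem)),
        )

    def to_csv(self, path: str | Path, sidecar: bool = True) -> None:
        path = Path(path)
        pd.DataFrame({"time_s": self.t, "load_mN": self.P, "depth_um": self.h}).to_csv(
            path, index=False
        )
        if sidecar:
            meta = {
                "thickness_um": self.thickness_um,
                "region": self.region,
                "plane": self.plane,
                "point_id": self.point_id,
            }
            path.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))


@dataclass(frozen=True)
class SegmentedRecord:
    """Contiguous half-open index ranges [start, stop) for the three stages."""

    loading: tuple[int, int]
    hold: tuple[int, int]
    unload: tuple[int, int]

    def __post_init__(self) -> None:
        lo, ho, un = self.loading, self.hold, self.unload
        if not (lo[0] <= lo[1] == ho[0] <= ho[1] == un[0] <= un[1]):
            raise ValidationError("stage ranges must be contiguous, ordered, non-overlapping")


@dataclass(frozen=True)
class ReducedModulus:
    """Flat-punch reduced modulus from the unloading branch."""

    E_star_MPa: float
    stiffness_mN_um: float
    method: str = "flat_punch_oliver_pharr"

    def __post_init__(self) -> None:
        if self.E_star_MPa < 0:
            raise ValidationError("E* must be >= 0")


def segment_record(
    rec: IndentationRecord, proto: LoadProtocol, tol: float = 0.01
) -> SegmentedRecord:
    """Split a record into loading / hold / unload index ranges.

    Loading ends at the first sample with P >= peak*(1 - tol); the hold
    spans hold_time_s from there; everything after is the unload (possibly
    empty).
    """
    thresh = proto.peak_load_mN * (1.0 - tol)
    reached = np.nonzero(rec.P >= thresh)[0]
    if len(reached) == 0:
        raise SegmentationError(
            f"peak load {proto.peak_load_mN} mN never reached "
            f"(max observed {rec.P.max():.4g} mN)"
        )
    i_peak = int(reached[0])
    t_hold_end = rec.t[i_peak] + proto.hold_time_s
    # hold = samples in (t_peak, t_peak + hold_time]; a small slack absorbs
    # floating-point grid endpoints
    slack = 1e-9 * max(proto.hold_time_s, 1.0)
    in_hold = np.nonzero(rec.t <= t_hold_end + slack)[0]
    i_hold_end = int(in_hold[-1]) + 1
    return SegmentedRecord(
        loading=(0, i_peak),
        hold=(i_peak, i_hold_end),
        unload=(i_hold_end, len(rec.t)),
    )


def strain_from_displacement(
    rec: IndentationRecord,
    seg: SegmentedRecord,
    hold_relative: bool = False,
) -> CreepCurve:
    """Hold-stage strain curve: eps = h / thickness, hold clock re-zeroed.

    By default strain keeps the loading-phase penetration (total depth over
    thickness).  ``hold_relative=True`` instead measures depth from the
    hold-onset value.
    """
    i0, i1 = seg.hold
    if i1 - i0 < 4:
        raise ValidationError("hold stage too short to form a creep curve")
    t = rec.t[i0:i1] - rec.t[i0]
    h = rec.h[i0:i1].copy()
    if hold_relative:
        h = h - h[0]
    eps = h / rec.thickness_um
    return CreepCurve(
        t=t, eps=eps, sample_id=rec.point_id, region=rec.region, plane=rec.plane
    )


def average_curves(
    series: Sequence[tuple[np.ndarray, np.ndarray]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise mean of replicate (x, y) series on the first series' grid.

    Other series are linearly interpolated onto that grid; no extrapolation
    — the grids must share a common span.  Returns (x, mean_y, count).
    """
    if len(series) == 0:
        raise ValidationError("need at least one series")
    x0 = np.asarray(series[0][0], dtype=float)
    lo = max(np.min(np.asarray(x)) for x, _ in series)
    hi = min(np.max(np.asarray(x)) for x, _ in series)
    if lo > hi:
        raise ValidationError("series abscissa ranges are disjoint; cannot average")
    keep = (x0 >= lo) & (x0 <= hi)
    if not np.any(keep):
        raise ValidationError("no common abscissa support on the reference grid")
    xg = x0[keep]
    stack = np.empty((len(series), len(xg)))
    for i, (x, y) in enumerate(series):
        stack[i] = np.interp(xg, np.asarray(x, dtype=float), np.asarray(y, dtype=float))
    count = np.full(len(xg), len(series), dtype=int)
    return xg, stack.mean(axis=0), count


def reduced_modulus_flat_punch(
    P_unload: np.ndarray,
    h_unload: np.ndarray,
    radius_um: float,
    top_fraction: float = 0.5,
) -> ReducedModulus:
    """Reduced modulus E* = S/(2R) from an unloading load-depth branch.

    The unloading stiffness S is the slope of a straight-line fit to the
    upper ``top_fraction`` of the branch by load.  Units: P in mN, h in um,
    R in um; E* comes out in MPa (mN/um / um = 1e3 MPa / 2R[um]... worked
    through: S[mN/um] / (2 R[um]) * 1e3 = MPa).
    """
    P = np.asarray(P_unload, dtype=float)
    h = np.asarray(h_unload, dtype=float)
    if len(P) != len(h) or len(P) < 2:
        raise ValidationError("need >= 2 unloading points")
    if radius_um <= 0:
        raise ValidationError("radius must be > 0")
    if not 0 < top_fraction <= 1:
        raise ValidationError("top_fraction must lie in (0, 1]")
    pmax, pmin = P.max(), P.min()
    cutoff = pmax - top_fraction * (pmax - pmin)
    sel = P >= cutoff
    if sel.sum() < 2:
        sel = np.ones_like(P, dtype=bool)
    hs, ps = h[sel], P[sel]
    if np.ptp(hs) == 0:
        raise DegenerateInputError("constant-depth unload: stiffness undefined")
    S = float(np.polyfit(hs, ps, 1)[0])  # mN/um
    # S/(2R): mN/um / um = mN/um^2 = 1e-3 N / 1e-6 mm^2 = 1e3 N/mm^2 = 1e3 MPa
    E_star = S / (2.0 * radius_um) * 1e3
    return ReducedModulus(E_star_MPa=max(E_star, 0.0), stiffness_mN_um=S)


def modulus_table(results: Sequence[tuple[str, str, float]]) -> pd.DataFrame:
    """Pivot (region, plane, E*) triples into a region x plane mean table."""
    df = pd.DataFrame(results, columns=["region", "plane", "E_star_MPa"])
    table = df.pivot_table(index="region", columns="plane", values="E_star_MPa", aggfunc="mean")
    order = [r for r in ("neck", "middle", "apex") if r in table.index]
    cols = [p for p in ("transverse", "longitudinal") if p in table.columns]
    return table.loc[order, cols]
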