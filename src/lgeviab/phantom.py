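"""Synthetic short-axis LV phantoms with exact scar ground truth.

The phantom is an annular left-ventricular myocardium drawn on a stack of
short-axis slices (7 mm slice thickness, 3 mm gap, so 10 mm slice
increments). Scar is modelled as subendocardial wedges of controlled
angular span and transmural depth; remote myocardium is "nulled" (low
signal) and scar is bright, as on an inversion-recovery LGE acquisition.

Angular convention, used everywhere in this package: angle 0 lies at the
anterior insertion of the right ventricle, and angles increase
counter-clockwise as viewed from the apex (standard mathematical CCW with
the y-axis pointing up in the image plane).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Geometry",
    "ScarWedge",
    "PhantomSpec",
    "ImageStack",
    "generate_phantom",
    "wedge_area_fraction",
    "wedge_volume_mm3",
    "write_nifti",
    "read_nifti",
]


@dataclass(frozen=True)
class Geometry:
    """Voxel geometry and angular reference of a short-axis stack."""

    pixel_spacing_mm: float = 1.0
    slice_thickness_mm: float = 7.0
    slice_gap_mm: float = 3.0
    anchor_deg: float = 0.0  # image angle of the anterior RV insertion

    @property
    def slice_increment_mm(self) -> float:
        return self.slice_thickness_mm + self.slice_gap_mm

    @property
    def voxel_volume_cm3(self) -> float:
        # voxel footprint times the imaged slab (the gap holds no signal)
        return self.pixel_spacing_mm**2 * self.slice_thickness_mm / 1000.0


@dataclass(frozen=True)
class ScarWedge:
    """A subendocardial scar wedge on one slice.

    ``depth`` is the transmural depth as a fraction of wall thickness,
    measured radially outward from the endocardium. The wedge spans
    ``[start_deg, end_deg)``; a span crossing 0 wraps around.
    """

    slice_index: int
    start_deg: float
    end_deg: float
    depth: float


@dataclass(frozen=True)
class PhantomSpec:
    grid_size: int = 129
    pixel_spacing_mm: float = 1.0
    n_slices: int = 6
    endo_radius_mm: float | tuple[float, ...] = 22.0
    epi_radius_mm: float | tuple[float, ...] = 32.0
    wedges: tuple[ScarWedge, ...] = ()
    remote_mean: float = 15.0
    scar_mean: float = 90.0
    noise_sd: float = 0.0
    noise_model: str = "gaussian"  # or "rician"
    anchor_deg: float = 0.0
    seed: int = 0
    # per-slice annotations used by slice-selection rules; defaults cover a
    # 6-slice stack with papillary muscle mid-cavity and trabeculated apex
    lvot: tuple[bool, ...] | None = None
    papillary: tuple[bool, ...] | None = None
    trabeculation: tuple[bool, ...] | None = None
    myo_coverage: tuple[float, ...] | None = None

    def radii(self) -> tuple[np.ndarray, np.ndarray]:
        endo = np.broadcast_to(np.asarray(self.endo_radius_mm, float), (self.n_slices,))
        epi = np.broadcast_to(np.asarray(self.epi_radius_mm, float), (self.n_slices,))
        return endo.copy(), epi.copy()

    def validate(self) -> None:
        endo, epi = self.radii()
        if np.any(endo <= 0) or np.any(epi <= endo):
            raise ValueError("require epicardial radius > endocardial radius > 0 on every slice")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        half_extent = (self.grid_size - 1) / 2 * self.pixel_spacing_mm
        if np.any(epi > half_extent):
            raise ValueError("epicardium exceeds the image grid")
        for w in self.wedges:
            if not 0 <= w.slice_index < self.n_slices:
                raise ValueError(f"wedge on slice {w.slice_index} outside the stack")
            if not 0.0 <= w.depth <= 1.0:
                raise ValueError("transmural depth fraction must lie in [0, 1]")
            if not (0 <= w.start_deg < 360 and 0 <= w.end_deg < 360):
                raise ValueError("wedge angles must lie in [0, 360)")
            if epi[w.slice_index] > half_extent:
                raise ValueError("scar wedge outside myocardium extent: epicardium exceeds grid")


def _default_annotations(spec: PhantomSpec) -> pd.DataFrame:
    n = spec.n_slices
    lvot = spec.lvot if spec.lvot is not None else (False,) * n
    pap = spec.papillary
    trab = spec.trabeculation
    if pap is None:
        pap = tuple(2 <= i <= 3 for i in range(n))
    if trab is None:
        trab = tuple(i >= 4 for i in range(n))
    cov = spec.myo_coverage if spec.myo_coverage is not None else (1.0,) * n
    return pd.DataFrame(
        {
            "slice": np.arange(n),
            "myo_coverage": list(cov),
            "lvot": list(lvot),
            "papillary": list(pap),
            "trabeculation": list(trab),
        }
    )


@dataclass
class ImageStack:
    """A short-axis intensity stack plus exact masks and ground truth.

    Arrays are indexed ``[slice, row, col]``. ``scar_truth`` and ``remote``
    are subsets of ``myocardium``. ``truth_sectors`` records, for the
    default 8-sector grid, the analytic transmural depth and area-fraction
    %LGE of every (slice, sector) — the generator's ground truth against
    which planimetry is checked.
    """

    intensity: np.ndarray
    myocardium: np.ndarray
    scar_truth: np.ndarray
    remote: np.ndarray
    geometry: Geometry
    endo_radius_mm: np.ndarray
    epi_radius_mm: np.ndarray
    annotations: pd.DataFrame
    truth_sectors: pd.DataFrame
    spec: PhantomSpec | None = None

    @property
    def n_slices(self) -> int:
        return self.intensity.shape[0]

    @property
    def center(self) -> tuple[float, float]:
        n = self.intensity.shape[1]
        return ((n - 1) / 2.0, (self.intensity.shape[2] - 1) / 2.0)


def _angle_grid(n_rows: int, n_cols: int, anchor_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Radius (pixels) and angle (deg, relative to the anchor) per pixel."""
    cr, cc = (n_rows - 1) / 2.0, (n_cols - 1) / 2.0
    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    dx = cols - cc
    dy = cr - rows  # y-axis up
    radius = np.hypot(dx, dy)
    theta = (np.degrees(np.arctan2(dy, dx)) - anchor_deg) % 360.0
    return radius, theta


def _wedge_angular_mask(theta: np.ndarray, start: float, end: float) -> np.ndarray:
    if start <= end:
        return (theta >= start) & (theta < end)
    return (theta >= start) | (theta < end)  # wraps through 0


def wedge_area_fraction(endo_mm: float, epi_mm: float, depth: float) -> float:
    """Closed-form area fraction of a subendocardial wedge within its span.

    A wedge of transmural depth fraction ``depth`` occupies the radial band
    [endo, endo + depth*(epi - endo)]; its cross-sectional area divided by
    the full wall cross-section over the same angular span is independent
    of the span:

        ((endo + d*t)^2 - endo^2) / (epi^2 - endo^2),  t = epi - endo.
    """
    r_out = endo_mm + depth * (epi_mm - endo_mm)
    return (r_out**2 - endo_mm**2) / (epi_mm**2 - endo_mm**2)


def wedge_volume_mm3(
    endo_mm: float, epi_mm: float, depth: float, span_deg: float, thickness_mm: float
) -> float:
    """Analytic volume of a scar wedge on one slice (imaged slab only)."""
    r_out = endo_mm + depth * (epi_mm - endo_mm)
    return np.pi * (r_out**2 - endo_mm**2) * (span_deg / 360.0) * thickness_mm


def _angular_distance(theta: np.ndarray, start: float, end: float) -> np.ndarray:
    """Smallest angular distance (deg) from each angle to the arc [start, end)."""
    inside = _wedge_angular_mask(theta, start, end)
    d_start = np.abs((theta - start + 180.0) % 360.0 - 180.0)
    d_end = np.abs((theta - end + 180.0) % 360.0 - 180.0)
    dist = np.minimum(d_start, d_end)
    dist[inside] = 0.0
    return dist


def _truth_sector_table(spec: PhantomSpec, n_sectors: int = 8) -> pd.DataFrame:
    """Analytic per-sector ground truth on an ``n_sectors`` grid.

    Depth is the maximum wedge depth touching the sector; %LGE is the exact
    area fraction of the sector's wall cross-section covered by wedges
    (angular overlap times the radial band ratio).
    """
    endo, epi = spec.radii()
    width = 360.0 / n_sectors
    rows = []
    for s in range(spec.n_slices):
        for k in range(n_sectors):
            a0, a1 = k * width, (k + 1) * width
            depth = 0.0
            area_frac = 0.0
            for w in spec.wedges:
                if w.slice_index != s:
                    continue
                # angular overlap of [a0,a1) with the (possibly wrapping) wedge
                spans = (
                    [(w.start_deg, w.end_deg)]
                    if w.start_deg <= w.end_deg
                    else [(w.start_deg, 360.0), (0.0, w.end_deg)]
                )
                overlap = sum(max(0.0, min(a1, e) - max(a0, b)) for b, e in spans)
                if overlap > 0:
                    depth = max(depth, w.depth)
                    frac = wedge_area_fraction(endo[s], epi[s], w.depth)
                    area_frac += (overlap / width) * frac
            rows.append(
                {
                    "slice": s,
                    "sector": k,
                    "gt_depth": depth,
                    "gt_pct_lge": 100.0 * min(area_frac, 1.0),
                }
            )
    return pd.DataFrame(rows)


def generate_phantom(spec: PhantomSpec) -> ImageStack:
    """Render a :class:`PhantomSpec` into an :class:`ImageStack`.

    The myocardial and scar masks are exact (defined by the same analytic
    geometry that produced the intensities), and the remote ROI is the
    myocardium at least 30 degrees away from every scar wedge on its slice
    — clean by construction.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.grid_size
    endo, epi = spec.radii()
    geom = Geometry(pixel_spacing_mm=spec.pixel_spacing_mm, anchor_deg=spec.anchor_deg)

    radius_px, theta = _angle_grid(n, n, spec.anchor_deg)
    radius_mm = radius_px * spec.pixel_spacing_mm

    intensity = np.zeros((spec.n_slices, n, n))
    myo = np.zeros_like(intensity, dtype=bool)
    scar = np.zeros_like(myo)
    remote = np.zeros_like(myo)

    for s in range(spec.n_slices):
        ring = (radius_mm >= endo[s]) & (radius_mm < epi[s])
        myo[s] = ring
        wall = epi[s] - endo[s]
        min_dist = np.full((n, n), np.inf)
        for w in spec.wedges:
            if w.slice_index != s:
                continue
            ang = _wedge_angular_mask(theta, w.start_deg, w.end_deg)
            band = (radius_mm >= endo[s]) & (radius_mm < endo[s] + w.depth * wall)
            scar[s] |= ring & ang & band
            min_dist = np.minimum(min_dist, _angular_distance(theta, w.start_deg, w.end_deg))
        remote[s] = ring & (min_dist >= 30.0)

        sl = np.zeros((n, n))
        sl[ring] = spec.remote_mean
        sl[scar[s]] = spec.scar_mean
        if spec.noise_sd > 0:
            if spec.noise_model == "rician":
                n1 = rng.normal(0.0, spec.noise_sd, (n, n))
                n2 = rng.normal(0.0, spec.noise_sd, (n, n))
                sl = np.hypot(sl + n1, n2)
            else:
                sl = sl + rng.normal(0.0, spec.noise_sd, (n, n))
        intensity[s] = np.where(ring, sl, 0.0)

    return ImageStack(
        intensity=intensity,
        myocardium=myo,
        scar_truth=scar,
        remote=remote,
        geometry=geom,
        endo_radius_mm=endo,
        epi_radius_mm=epi,
        annotations=_default_annotations(spec),
        truth_sectors=_truth_sector_table(spec),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# NIfTI round trip: intensities in one file, masks as a label map, geometry
# and annotations in a JSON sidecar.

_LABEL_MYO, _LABEL_SCAR, _LABEL_REMOTE = 1, 2, 3


def write_nifti(stack: ImageStack, prefix: str | Path) -> tuple[Path, Path, Path]:
    import nibabel as nib

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    g = stack.geometry
    affine = np.diag([g.pixel_spacing_mm, g.pixel_spacing_mm, g.slice_increment_mm, 1.0])
    # axis order (row, col, slice) for NIfTI
    img = nib.Nifti1Image(np.transpose(stack.intensity, (1, 2, 0)).astype(np.float32), affine)
    labels = np.zeros_like(stack.intensity, dtype=np.uint8)
    labels[stack.myocardium] = _LABEL_MYO
    labels[stack.remote] = _LABEL_REMOTE
    labels[stack.scar_truth] = _LABEL_SCAR
    lab = nib.Nifti1Image(np.transpose(labels, (1, 2, 0)), affine)
    img_path = prefix.with_suffix(".nii")
    lab_path = Path(str(prefix) + "_labels.nii")
    side_path = prefix.with_suffix(".json")
    nib.save(img, img_path)
    nib.save(lab, lab_path)
    sidecar = {
        "pixel_spacing_mm": g.pixel_spacing_mm,
        "slice_thickness_mm": g.slice_thickness_mm,
        "slice_gap_mm": g.slice_gap_mm,
        "anchor_deg": g.anchor_deg,
        "endo_radius_mm": stack.endo_radius_mm.tolist(),
        "epi_radius_mm": stack.epi_radius_mm.tolist(),
        "annotations": stack.annotations.to_dict(orient="list"),
        "truth_sectors": stack.truth_sectors.to_dict(orient="list"),
    }
    side_path.write_text(json.dumps(sidecar, indent=1))
    return img_path, lab_path, side_path


def read_nifti(prefix: str | Path) -> ImageStack:
    import nibabel as nib

    prefix = Path(prefix)
    img = nib.load(prefix.with_suffix(".nii"))
    lab = nib.load(Path(str(prefix) + "_labels.nii"))
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    intensity = np.transpose(np.asarray(img.dataobj, dtype=float), (2, 0, 1))
    labels = np.transpose(np.asarray(lab.dataobj), (2, 0, 1))
    geom = Geometry(
        pixel_spacing_mm=sidecar["pixel_spacing_mm"],
        slice_thickness_mm=sidecar["slice_thickness_mm"],
        slice_gap_mm=sidecar["slice_gap_mm"],
        anchor_deg=sidecar["anchor_deg"],
    )
    return ImageStack(
        intensity=intensity,
        myocardium=labels > 0,
        scar_truth=labels == _LABEL_SCAR,
        remote=labels == _LABEL_REMOTE,
        geometry=geom,
        endo_radius_mm=np.asarray(sidecar["endo_radius_mm"]),
        epi_radius_mm=np.asarray(sidecar["epi_radius_mm"]),
        annotations=pd.DataFrame(sidecar["annotations"]),
        truth_sectors=pd.DataFrame(sidecar["truth_sectors"]),
    )
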