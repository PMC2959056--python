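"""Mapping slices and angular sectors onto segmentation models.

Two segmentation schemes are supported: a 48-segment model (6 slices x 8
sectors of 45 degrees) and the AHA 16-segment model (6 basal + 6 mid + 4
apical segments, omitting the true apex, segment 17). Segment 1 sits at
the anterior insertion of the right ventricle; sectors are numbered
counter-clockwise as viewed from the apex. Apical segments are rotated 45
degrees relative to the basal anchor, per the standard AHA diagram.

Slice selection follows two distinct basal rules, both implemented:
for volumetry, the most basal slice whose circumference is at least 50%
myocardium; for segment registration, the first slice (from the base)
without left-ventricular outflow tract in any phase. Mid and apical rings
sit 20 mm (two 10-mm slice increments) below the base, conditioned on
papillary-muscle / trabeculation content with a small fallback search.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import ImageStack
from .quant import grade_transmurality

__all__ = [
    "SegmentationScheme",
    "AHA16",
    "SEG48",
    "select_basal_slice",
    "select_aha_rings",
    "register_sectors",
]

_EPS = 1e-9


@dataclass(frozen=True)
class _RingSpec:
    n_segments: int  # angular segments on this ring
    anchor_offset_deg: float  # rotation of segment boundaries vs the anchor
    first_segment: int  # segment number of the first (anchor-side) sector


@dataclass(frozen=True)
class SegmentationScheme:
    """Ring layout of a segmentation model."""

    scheme_id: str
    rings: tuple[_RingSpec, ...]

    @property
    def n_segments(self) -> int:
        return sum(r.n_segments for r in self.rings)


AHA16 = SegmentationScheme(
    "AHA16",
    (
        _RingSpec(6, 0.0, 1),  # basal 1-6
        _RingSpec(6, 0.0, 7),  # mid 7-12
        _RingSpec(4, 45.0, 13),  # apical 13-16
    ),
)

SEG48 = SegmentationScheme("SEG48", tuple(_RingSpec(8, 0.0, 1 + 8 * i) for i in range(6)))


def select_basal_slice(stack: ImageStack, context: str = "registration") -> int:
    """Basal slice index under the rule for the given context.

    ``context="volumetry"``: most basal slice with >= 50% myocardial
    circumference. ``context="registration"``: first slice without LVOT in
    any phase. Slices are ordered base (index 0) to apex.
    """
    ann = stack.annotations
    if context == "volumetry":
        ok = ann.loc[ann["myo_coverage"] >= 0.5, "slice"]
        if ok.empty:
            raise ValueError("no slice has >= 50% myocardial circumference")
    elif context == "registration":
        ok = ann.loc[~ann["lvot"].astype(bool), "slice"]
        if ok.empty:
            raise ValueError("every slice contains LVOT; no basal slice")
    else:
        raise ValueError(f"unknown context {context!r}")
    return int(ok.iloc[0])


def _ring_condition(ann: pd.DataFrame, idx: int, need_pap: bool) -> bool:
    row = ann.loc[ann["slice"] == idx]
    if row.empty:
        return False
    pap = bool(row["papillary"].iloc[0])
    trab = bool(row["trabeculation"].iloc[0])
    return (pap and not trab) if need_pap else (trab and not pap)


def _find_ring(ann: pd.DataFrame, nominal: int, n_slices: int, need_pap: bool, what: str) -> int:
    # nominal slice first, then fallback +1, -1, +2, -2 increments
    # (apex-ward preferred on ties)
    for off in (0, 1, -1, 2, -2):
        idx = nominal + off
        if 0 <= idx < n_slices and _ring_condition(ann, idx, need_pap):
            return idx
    cond = "papillary muscle but no trabeculation" if need_pap else "trabeculation but no papillary muscle"
    raise ValueError(
        f"no {what} slice with {cond} within +/-2 increments of slice {nominal}"
    )


def select_aha_rings(stack: ImageStack, base_index: int | None = None) -> tuple[int, int, int]:
    """(basal, mid, apical) slice indices for the AHA 16-segment model.

    The mid-ventricular slice is nominally 20 mm (two slice increments)
    below the base and must contain papillary muscle but no trabeculation;
    the apical slice is 20 mm below the mid slice with trabeculation but no
    papillary muscle. When the nominal slice fails its condition the
    nearest satisfying slice within +/-2 increments is used (search order
    +1, -1, +2, -2).
    """
    if base_index is None:
        base_index = select_basal_slice(stack, "registration")
    ann = stack.annotations
    n = stack.n_slices
    if not 0 <= base_index < n:
        raise ValueError("base index outside the stack")
    mid = _find_ring(ann, base_index + 2, n, need_pap=True, what="mid-ventricular")
    apical = _find_ring(ann, mid + 2, n, need_pap=False, what="apical")
    return base_index, mid, apical


def _aggregate_ring(
    sectors: pd.DataFrame, ring: _RingSpec, patient_id, scheme_id: str
) -> list[dict]:
    """Area-weighted aggregation of fine sectors into one ring's segments.

    Fine-sector boundaries must align with segment boundaries (the sector
    grid must subdivide the ring segments exactly).
    """
    width = 360.0 / ring.n_segments
    out = []
    for j in range(ring.n_segments):
        a0 = (ring.anchor_offset_deg + j * width) % 360.0
        a1 = a0 + width
        start = sectors["start_deg"].to_numpy() % 360.0
        end = start + (sectors["end_deg"].to_numpy() - sectors["start_deg"].to_numpy())
        if a1 <= 360.0 + _EPS:
            inside = (start >= a0 - _EPS) & (end <= a1 + _EPS)
        else:  # segment wraps through 0
            inside = (start >= a0 - _EPS) | (end <= (a1 - 360.0) + _EPS)
        sub = sectors.loc[inside]
        covered = float(sub["end_deg"].sub(sub["start_deg"]).sum())
        if abs(covered - width) > 1e-6:
            raise ValueError(
                f"sector grid does not align with {scheme_id} segment boundaries "
                f"(segment {ring.first_segment + j}: covered {covered:.3f} of {width:.3f} deg)"
            )
        seg_no = ring.first_segment + j
        valid = sub.loc[~sub["missing"].astype(bool)]
        if valid.empty or valid["myo_area_mm2"].sum() <= 0:
            out.append(
                {
                    "patient_id": patient_id,
                    "scheme": scheme_id,
                    "segment": seg_no,
                    "pct_lge": np.nan,
                    "grade": -1,
                    "myo_area_mm2": 0.0,
                    "missing": True,
                }
            )
            continue
        w = valid["myo_area_mm2"].to_numpy()
        pct = float(np.average(valid["pct_lge"].to_numpy(), weights=w))
        out.append(
            {
                "patient_id": patient_id,
                "scheme": scheme_id,
                "segment": seg_no,
                "pct_lge": pct,
                "grade": grade_transmurality(pct),
                "myo_area_mm2": float(w.sum()),
                "missing": False,
            }
        )
    return out


def register_sectors(
    sector_table: pd.DataFrame,
    scheme: SegmentationScheme,
    ring_slices: tuple[int, ...] | None = None,
    patient_id: str | int = 0,
) -> pd.DataFrame:
    """Aggregate a fine per-slice sector table into model segments.

    ``sector_table`` is the output of
    :func:`lgeviab.quant.sector_transmurality` (angles relative to the
    anchor). For AHA16, ``ring_slices`` gives the (basal, mid, apical)
    slice indices (from :func:`select_aha_rings`); for SEG48 it defaults to
    the six most basal slices present. A segment's %LGE is the
    myocardial-area-weighted mean of its constituent sectors, re-graded
    with the standard bins; segments without myocardium are flagged
    missing.
    """
    slices = sorted(sector_table["slice"].unique())
    if ring_slices is None:
        if scheme.scheme_id == "AHA16":
            raise ValueError("AHA16 registration requires ring_slices=(basal, mid, apical)")
        ring_slices = tuple(slices[: len(scheme.rings)])
    if len(ring_slices) != len(scheme.rings):
        raise ValueError(
            f"{scheme.scheme_id} needs {len(scheme.rings)} ring slices, got {len(ring_slices)}"
        )
    rows: list[dict] = []
    for ring, sl in zip(scheme.rings, ring_slices):
        if sl not in slices:
            raise ValueError(f"ring slice {sl} absent from the sector table")
        sectors = sector_table.loc[sector_table["slice"] == sl]
        rows.extend(_aggregate_ring(sectors, ring, patient_id, scheme.scheme_id))
    out = pd.DataFrame(rows)
    assert len(out) == scheme.n_segments  # segment count conservation
    return out
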