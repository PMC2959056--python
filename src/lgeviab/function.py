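"""Ventricular volumes, wall-motion scoring, viability classification.

Regional wall motion is scored 1 (normally contracting) to 5 (dyskinetic);
a segment has recovered when it improves by at least one grade, with the
single exception of 5 -> 4 (dyskinetic to akinetic), which does not count.
Volumes come from short-axis disc summation at 10-mm slice increments.

Viability labels per AHA segment: a segment is *normal* when its pre-op
wall-motion grade is 1 (regardless of scar); otherwise it is *viable* when
its transmural scar extent is below the cutoff (default 50 %LGE) and
*nonviable* otherwise. The per-patient predictors are the count of viable
segments and the count of viable+normal segments out of 16.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "compute_volumes",
    "segment_recovered",
    "classify_segment",
    "count_patient",
    "responder",
    "score_segments",
    "patient_counts",
]

VALID_CUTOFFS = (25, 50, 75)
N_AHA_SEGMENTS = 16


@dataclass(frozen=True)
class VolumeResult:
    edv_ml: float
    esv_ml: float
    ef_pct: float
    edvi_ml_m2: float
    esvi_ml_m2: float


def compute_volumes(
    ed_areas_cm2,
    es_areas_cm2,
    bsa_m2: float,
    slice_increment_mm: float = 10.0,
) -> VolumeResult:
    """Disc-summation volumes, EF and BSA-indexed volumes.

    Each slice contributes (cavity area) x (slice increment); with areas in
    cm^2 and a 10-mm increment a slice of 20 cm^2 adds 20 ml. Papillary
    muscle is excluded from the cavity by the input contract.
    """
    ed = np.asarray(ed_areas_cm2, dtype=float)
    es = np.asarray(es_areas_cm2, dtype=float)
    if np.any(ed < 0) or np.any(es < 0):
        raise ValueError("contour areas must be non-negative")
    if bsa_m2 <= 0:
        raise ValueError("BSA must be positive")
    h_cm = slice_increment_mm / 10.0
    edv = float(ed.sum() * h_cm)
    esv = float(es.sum() * h_cm)
    if esv > edv:
        raise ValueError(f"ESV ({esv:.1f} ml) exceeds EDV ({edv:.1f} ml)")
    ef = 100.0 * (edv - esv) / edv if edv > 0 else 0.0
    return VolumeResult(edv, esv, ef, edv / bsa_m2, esv / bsa_m2)


def _check_grade(g) -> None:
    arr = np.asarray(g)
    if not np.all((arr >= 1) & (arr <= 5) & (arr == np.floor(arr))):
        raise ValueError("wall-motion grades must be integers in 1..5")


def segment_recovered(pre, post):
    """True when contraction improved by >=1 grade, except 5 -> 4."""
    _check_grade(pre)
    _check_grade(post)
    pre_a, post_a = np.asarray(pre), np.asarray(post)
    out = (post_a <= pre_a - 1) & ~((pre_a == 5) & (post_a == 4))
    return bool(out) if np.isscalar(pre) else out


def classify_segment(rwms_pre, pct_lge, cutoff: int = 50, missing: bool = False) -> str:
    """Label one segment: ``normal`` / ``viable`` / ``nonviable`` / ``missing``."""
    if cutoff not in VALID_CUTOFFS:
        raise ValueError(f"cutoff must be one of {VALID_CUTOFFS}")
    if missing or rwms_pre is None or (isinstance(pct_lge, float) and np.isnan(pct_lge)):
        return "missing"
    _check_grade(rwms_pre)
    if rwms_pre == 1:
        return "normal"
    return "viable" if pct_lge < cutoff else "nonviable"


def count_patient(labels) -> tuple[int, int]:
    """(N_viable, N_viable+normal) from 16 segment labels.

    Missing segments count as neither and are reported with a warning;
    normal + viable + nonviable + missing always totals the input length.
    """
    labels = list(labels)
    unknown = set(labels) - {"normal", "viable", "nonviable", "missing"}
    if unknown:
        raise ValueError(f"unknown labels {sorted(unknown)}")
    n_missing = labels.count("missing")
    if n_missing:
        warnings.warn(f"{n_missing} missing segment(s) excluded from viability counts")
    n_viable = labels.count("viable")
    return n_viable, n_viable + labels.count("normal")


def responder(delta_ef: float, threshold: float = 3.0) -> bool:
    """EF improvement of at least ``threshold`` absolute EF points (inclusive)."""
    return bool(delta_ef >= threshold)


# ---------------------------------------------------------------------------
# table-level wrappers over the shared segments.csv / patients.csv schemas


def score_segments(segments: pd.DataFrame, cutoff: int = 50) -> pd.DataFrame:
    """Add label / dysfunctional / recovered columns to a segment table.

    Expects columns patient_id, segment, pct_lge, rwms_pre, rwms_post and
    an optional ``missing`` flag.
    """
    seg = segments.copy()
    missing = seg["missing"].astype(bool) if "missing" in seg else pd.Series(False, index=seg.index)
    seg["label"] = [
        classify_segment(r, p, cutoff, missing=m)
        for r, p, m in zip(seg["rwms_pre"], seg["pct_lge"], missing)
    ]
    seg["dysfunctional"] = ~missing & (seg["rwms_pre"] > 1)
    seg["viable"] = seg["label"] == "viable"
    seg["recovered"] = False
    ok = ~missing
    seg.loc[ok, "recovered"] = segment_recovered(
        seg.loc[ok, "rwms_pre"].to_numpy(), seg.loc[ok, "rwms_post"].to_numpy()
    )
    return seg


def patient_counts(scored: pd.DataFrame) -> pd.DataFrame:
    """Per-patient viability counts from a scored segment table."""
    rows = []
    for pid, grp in scored.groupby("patient_id", sort=True):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            n_v, n_vn = count_patient(grp["label"])
        rows.append({"patient_id": pid, "n_viable": n_v, "n_viable_normal": n_vn})
    return pd.DataFrame(rows)
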