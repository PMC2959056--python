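"""Synthetic patient cohorts with known ground truth.

Each synthetic patient carries 16 AHA segments with transmural scar
grades, pre/post wall-motion scores, and patient-level volumes. The
generative structure mirrors the clinical setting the package analyses:

* recovery probability of a dysfunctional segment decreases monotonically
  with its transmurality grade;
* the change in ejection fraction at follow-up is linear in the number of
  viable+normal segments (ΔEF = β0 + β1·N + ε); with the default intercept
  the expected ΔEF reaches the 3-point responder criterion just below
  N = 10 segments, so the generative change-point of the counting rule
  "responder iff N >= threshold" is 10;
* baseline EF is centred near 38% (SD 11), indexed volumes near
  EDVI 118 / ESVI 75 ml·m⁻², scar mass near 28 g, and the viable+normal
  count near 11 ± 3 — the marginals of a surgical-revascularisation
  heart-failure cohort.

Observable tables and ground-truth labels (``gt_`` columns) are kept side
by side so every downstream stage can be tested against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .function import count_patient, responder, segment_recovered

__all__ = [
    "CohortConfig",
    "PatientStudy",
    "generate_cohort",
    "cohort_frames",
    "write_cohort",
    "read_cohort",
]

LAD_TERRITORY = (1, 2, 7, 8, 13, 14)  # anterior / anteroseptal AHA segments

# uniform %LGE range of each transmurality grade
_GRADE_PCT = {0: (0.0, 0.0), 1: (1.0, 25.0), 2: (26.0, 50.0), 3: (51.0, 75.0), 4: (76.0, 100.0)}


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters of a synthetic cohort.

    ``recover_p[g]`` is the probability that a dysfunctional segment of
    transmurality grade g recovers contraction by follow-up; it must be
    monotone non-increasing in g. ``delta_ef_slope`` is in EF points per
    viable+normal segment; the default intercept places the expected ΔEF
    at the 3-point responder threshold when exactly 10 segments are
    viable+normal.
    """

    n_patients: int = 33
    seed: int = 0
    # segment-count structure: nonviable = dysfunctional with >=50% scar
    nonviable_mean: float = 5.0
    nonviable_sd: float = 3.0
    low_scar_mean: float = 3.0  # Poisson mean of grade-1/2 scarred segments
    dysfunct_unscarred_frac: float = 0.25
    recover_p: tuple[float, ...] = (0.73, 0.65, 0.50, 0.25, 0.10)
    # patient-level response model; the intercept puts the expected ΔEF at
    # the 3-point criterion for N = 9 and clearly above it from N = 10 up,
    # so that "positive iff N >= 10" is the population-optimal Youden rule
    delta_ef_slope: float = 1.298
    delta_ef_intercept: float = 3.0 - 1.298 * 9.0
    delta_ef_noise_sd: float = 2.0
    responder_thresholds: tuple[float, float] = (3.0, 5.0)
    # baseline marginals
    ef_mean: float = 38.0
    ef_sd: float = 11.0
    edvi_mean: float = 118.0
    edvi_sd: float = 33.0
    bsa_mean: float = 2.0
    bsa_sd: float = 0.2
    # remodeling response of EDVI to ΔEF, ml·m⁻² per EF point
    edvi_response_slope: float = 1.6
    edvi_noise_sd: float = 5.0
    # scar mass: grams per summed segment-%LGE point
    mass_per_pct_point: float = 0.066
    mass_noise_sd: float = 5.0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        p = np.asarray(self.recover_p, float)
        if p.size != 5 or np.any((p < 0) | (p > 1)):
            raise ValueError("recover_p must be 5 probabilities in [0, 1]")
        if np.any(np.diff(p) > 0):
            raise ValueError("recover_p must be monotone non-increasing in grade")
        for name in ("delta_ef_noise_sd", "edvi_noise_sd", "mass_noise_sd", "nonviable_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.dysfunct_unscarred_frac <= 1.0:
            raise ValueError("dysfunct_unscarred_frac must lie in [0, 1]")


@dataclass
class PatientStudy:
    """One synthetic patient: volumes, counts and the 16-segment table."""

    patient_id: int
    bsa_m2: float
    ef_pre: float
    ef_post: float
    delta_ef: float
    edv_pre: float
    esv_pre: float
    edv_post: float
    esv_post: float
    edvi_pre: float
    esvi_pre: float
    edvi_post: float
    esvi_post: float
    scar_mass_g: float
    n_viable: int
    n_viable_normal: int
    responder_3: bool
    responder_5: bool
    covariates: dict = field(default_factory=dict)
    segments: pd.DataFrame = field(default_factory=pd.DataFrame)


def _segment_table(cfg: CohortConfig, rng: np.random.Generator, pid: int) -> pd.DataFrame:
    k_nonviable = int(np.clip(np.rint(rng.normal(cfg.nonviable_mean, cfg.nonviable_sd)), 0, 16))
    n_low = int(min(16 - k_nonviable, rng.poisson(cfg.low_scar_mean)))
    order = rng.permutation(np.arange(1, 17))
    seg_rows = []
    for pos, seg in enumerate(order):
        if pos < k_nonviable:
            grade = int(rng.choice([3, 4]))
        elif pos < k_nonviable + n_low:
            grade = int(rng.choice([1, 2]))
        else:
            grade = 0
        lo, hi = _GRADE_PCT[grade]
        pct = float(rng.uniform(lo, hi)) if grade else 0.0
        if grade > 0:
            dysfunctional = True
        else:
            dysfunctional = bool(rng.random() < cfg.dysfunct_unscarred_frac)
        if dysfunctional:
            extra = int(rng.binomial(3, 0.10 + 0.15 * grade))
            rwms_pre = 2 + extra
        else:
            rwms_pre = 1
        p_rec = cfg.recover_p[grade] if dysfunctional else 0.0
        if dysfunctional and rng.random() < p_rec:
            rwms_post = 3 if rwms_pre == 5 else rwms_pre - 1
        else:
            rwms_post = rwms_pre
        seg_rows.append(
            {
                "patient_id": pid,
                "scheme": "AHA16",
                "segment": int(seg),
                "pct_lge": pct,
                "grade": grade,
                "rwms_pre": rwms_pre,
                "rwms_post": rwms_post,
                "gt_p_recover": p_rec,
            }
        )
    seg = pd.DataFrame(seg_rows).sort_values("segment").reset_index(drop=True)
    seg["dysfunctional"] = seg["rwms_pre"] > 1
    seg["recovered"] = segment_recovered(seg["rwms_pre"].to_numpy(), seg["rwms_post"].to_numpy())
    return seg


def generate_cohort(config: CohortConfig) -> list[PatientStudy]:
    """Draw a full synthetic cohort; a fixed seed reproduces it exactly."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    studies = []
    for pid in range(1, config.n_patients + 1):
        seg = _segment_table(config, rng, pid)

        labels = [
            "normal" if r == 1 else ("viable" if p < 50.0 else "nonviable")
            for r, p in zip(seg["rwms_pre"], seg["pct_lge"])
        ]
        seg["label"] = labels
        n_viable, n_vn = count_patient(labels)

        delta_ef = (
            config.delta_ef_intercept
            + config.delta_ef_slope * n_vn
            + (rng.normal(0.0, config.delta_ef_noise_sd) if config.delta_ef_noise_sd > 0 else 0.0)
        )
        ef_pre = float(np.clip(rng.normal(config.ef_mean, config.ef_sd), 12.0, 75.0))
        ef_post = float(np.clip(ef_pre + delta_ef, 1.0, 99.0))
        delta_ef = ef_post - ef_pre  # unchanged unless the clip binds

        bsa = float(np.clip(rng.normal(config.bsa_mean, config.bsa_sd), 1.4, 2.6))
        edvi_pre = float(np.clip(rng.normal(config.edvi_mean, config.edvi_sd), 50.0, 240.0))
        edvi_shift = config.edvi_response_slope * delta_ef + (
            rng.normal(0.0, config.edvi_noise_sd) if config.edvi_noise_sd > 0 else 0.0
        )
        edvi_post = float(np.clip(edvi_pre - edvi_shift, 40.0, 260.0))
        esvi_pre = edvi_pre * (1.0 - ef_pre / 100.0)
        esvi_post = edvi_post * (1.0 - ef_post / 100.0)

        total_pct = float(seg["pct_lge"].sum())
        mass = max(
            0.0,
            config.mass_per_pct_point * total_pct
            + (rng.normal(0.0, config.mass_noise_sd) if config.mass_noise_sd > 0 else 0.0),
        )

        lad = seg[seg["segment"].isin(LAD_TERRITORY)]
        pct_lad_viable = 100.0 * float((lad["pct_lge"] < 50.0).mean())

        covariates = {
            "age": float(np.clip(rng.normal(66.0, 8.0), 40.0, 90.0)),
            "sex_male": int(rng.random() < 0.85),
            "bmi": float(np.clip(rng.normal(28.0, 4.0), 18.0, 45.0)),
            "n_grafts": int(np.clip(np.rint(rng.normal(3.7, 0.8)), 2, 6)),
            "onbeat": int(rng.random() < 12.0 / 33.0),
            "scan_interval_days": float(np.clip(rng.normal(217.0, 23.0), 150.0, 300.0)),
            "pct_lad_viable": pct_lad_viable,
        }

        studies.append(
            PatientStudy(
                patient_id=pid,
                bsa_m2=bsa,
                ef_pre=ef_pre,
                ef_post=ef_post,
                delta_ef=delta_ef,
                edv_pre=edvi_pre * bsa,
                esv_pre=esvi_pre * bsa,
                edv_post=edvi_post * bsa,
                esv_post=esvi_post * bsa,
                edvi_pre=edvi_pre,
                esvi_pre=esvi_pre,
                edvi_post=edvi_post,
                esvi_post=esvi_post,
                scar_mass_g=mass,
                n_viable=n_viable,
                n_viable_normal=n_vn,
                responder_3=responder(delta_ef, config.responder_thresholds[0]),
                responder_5=responder(delta_ef, config.responder_thresholds[1]),
                covariates=covariates,
                segments=seg,
            )
        )
    return studies


def cohort_frames(studies: list[PatientStudy]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(patients, segments) DataFrames in the shared CSV schemas."""
    prows = []
    for st in studies:
        row = {
            "patient_id": st.patient_id,
            "bsa_m2": st.bsa_m2,
            "ef_pre": st.ef_pre,
            "ef_post": st.ef_post,
            "delta_ef": st.delta_ef,
            "edv_pre": st.edv_pre,
            "esv_pre": st.esv_pre,
            "edv_post": st.edv_post,
            "esv_post": st.esv_post,
            "edvi_pre": st.edvi_pre,
            "esvi_pre": st.esvi_pre,
            "edvi_post": st.edvi_post,
            "esvi_post": st.esvi_post,
            "scar_mass_g": st.scar_mass_g,
            "n_viable": st.n_viable,
            "n_viable_normal": st.n_viable_normal,
            "responder_3": int(st.responder_3),
            "responder_5": int(st.responder_5),
        }
        row.update(st.covariates)
        prows.append(row)
    patients = pd.DataFrame(prows)
    segments = pd.concat([st.segments for st in studies], ignore_index=True)
    return patients, segments


def write_cohort(studies: list[PatientStudy], outdir: str | Path) -> tuple[Path, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    patients, segments = cohort_frames(studies)
    p_path, s_path = outdir / "patients.csv", outdir / "segments.csv"
    patients.to_csv(p_path, index=False, float_format="%.10g")
    segments.to_csv(s_path, index=False, float_format="%.10g")
    return p_path, s_path


def read_cohort(indir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    indir = Path(indir)
    return pd.read_csv(indir / "patients.csv"), pd.read_csv(indir / "segments.csv")
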