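"""Synthetic overweight cohort generation.

The study population the pipeline is designed for is a cohort of
overweight adults (BMI > 25 kg·m⁻²) whose liver fat fraction (MRI PDFF, %)
varies from ~1 % to ~28 % and whose liver conductivity decreases with fat
content.  No quantitative conductivity-vs-PDFF calibration exists, so the
generator uses the weakest model consistent with that structure: a linear
decreasing map σ_liver = a − b·PDFF with additive Gaussian scatter, with
defaults spanning the observed conductivity band (~0.27–0.35 S·m⁻¹).
Demographics (sex, age, height, BMI, waist) are drawn independently of
PDFF by default, matching the null demographic correlations the analysis
stage is meant to detect; correlation knobs exist for power studies.

``subject_to_phantom`` turns a record into a physics phantom: the liver
conductivity follows the map and the outline is scaled isotropically so its
perimeter tracks the subject's waist circumference.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator
from shapely.geometry import Point, Polygon

from .errors import ParameterError, PlacementError
from .mesh import PhantomSpec, RegionSpec


class CohortSpec(BaseModel):
    """Generator configuration; defaults emulate the study population."""

    n_subjects: int = Field(default=19, ge=1)
    pdff_range: tuple[float, float] = (1.0, 28.0)
    conductivity_a: float = 0.355   # S/m at PDFF = 0
    conductivity_b: float = 0.003   # S/m per PDFF %
    conductivity_noise_sd: float = 0.012  # S/m, subject-level scatter
    bmi_mean: float = 34.0
    bmi_sd: float = 6.5
    height_mean_cm: float = 167.0
    height_sd_cm: float = 8.5
    waist_mean_cm: float = 110.0
    waist_sd_cm: float = 14.0
    age_range: tuple[int, int] = (26, 74)
    male_fraction: float = 4.0 / 19.0
    pdff_corr: dict[str, float] = Field(default_factory=dict)  # e.g. {"bmi": 0.3}
    exclusion_rate: float = Field(default=3.0 / 19.0, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _physical(self) -> "CohortSpec":
        if self.conductivity_b <= 0:
            raise ParameterError("conductivity map must be decreasing (b > 0)")
        if self.conductivity_noise_sd < 0:
            raise ParameterError("conductivity noise SD must be >= 0")
        lo, hi = self.pdff_range
        if not (0.0 <= lo < hi <= 100.0):
            raise ParameterError("pdff_range must satisfy 0 <= lo < hi <= 100")
        if self.conductivity_a - self.conductivity_b * hi <= 0:
            raise ParameterError("conductivity map reaches sigma <= 0 inside pdff_range")
        return self

    def conductivity_of(self, pdff: float) -> float:
        return self.conductivity_a - self.conductivity_b * pdff


@dataclass
class SubjectRecord:
    id: int
    sex: str
    bmi: float
    age: int
    waist: float
    height: float
    weight: float
    pdff: float
    eit_mean: float
    eit_sd: float
    injection_current: float
    excluded: bool = False
    exclusion_reason: str = ""


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Draw a reproducible synthetic cohort from ``spec`` (fixed seed contract)."""
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.pdff_range
    pdff = rng.uniform(lo, hi, spec.n_subjects)
    z_pdff = (pdff - pdff.mean()) / (pdff.std() or 1.0)

    def maybe_corr(name: str, raw_z: np.ndarray) -> np.ndarray:
        rho = float(spec.pdff_corr.get(name, 0.0))
        if rho == 0.0:
            return raw_z
        return rho * z_pdff + np.sqrt(1.0 - rho * rho) * raw_z

    height = np.clip(
        spec.height_mean_cm + spec.height_sd_cm * rng.standard_normal(spec.n_subjects),
        145.0, 200.0,
    )
    bmi = np.clip(
        spec.bmi_mean + spec.bmi_sd * maybe_corr("bmi", rng.standard_normal(spec.n_subjects)),
        25.1, 55.0,
    )
    waist = np.clip(
        spec.waist_mean_cm
        + spec.waist_sd_cm * maybe_corr("waist", rng.standard_normal(spec.n_subjects)),
        85.0, 150.0,
    )
    weight = bmi * (height / 100.0) ** 2  # keeps the BMI identity exact
    age = rng.integers(spec.age_range[0], spec.age_range[1] + 1, spec.n_subjects)
    sex = np.where(rng.random(spec.n_subjects) < spec.male_fraction, "M", "F")
    eit = spec.conductivity_a - spec.conductivity_b * pdff
    eit = eit + rng.normal(0.0, spec.conductivity_noise_sd, spec.n_subjects)
    # individual noise draws are floored at a small physical conductivity;
    # a map that is non-positive anywhere in pdff_range is rejected upfront
    eit = np.maximum(eit, 0.02)
    eit_sd = np.abs(rng.normal(0.017, 0.006, spec.n_subjects)) + 1e-4
    current = rng.integers(1, 4, spec.n_subjects).astype(float)
    excluded = rng.random(spec.n_subjects) < spec.exclusion_rate

    return [
        SubjectRecord(
            id=i + 1,
            sex=str(sex[i]),
            bmi=float(bmi[i]),
            age=int(age[i]),
            waist=float(waist[i]),
            height=float(height[i]),
            weight=float(weight[i]),
            pdff=float(pdff[i]),
            eit_mean=float(eit[i]),
            eit_sd=float(eit_sd[i]),
            injection_current=float(current[i]),
            excluded=bool(excluded[i]),
            exclusion_reason="confounding condition (synthetic)" if excluded[i] else "",
        )
        for i in range(spec.n_subjects)
    ]


def subject_to_phantom(
    record: SubjectRecord,
    base: PhantomSpec,
    spec: CohortSpec | None = None,
) -> PhantomSpec:
    """Subject-specific phantom: liver conductivity from the PDFF map and the
    whole cross-section scaled isotropically so the outline perimeter equals
    the subject's waist circumference."""
    spec = spec if spec is not None else CohortSpec()
    if not any(r.label == "liver" for r in base.regions):
        raise ParameterError("base phantom has no liver region")
    perim = Polygon(base.outline).exterior.length
    s = record.waist / perim

    def scale(poly: Sequence[tuple[float, float]]):
        return [(s * x, s * y) for x, y in poly]

    regions = []
    for r in base.regions:
        cond = spec.conductivity_of(record.pdff) if r.label == "liver" else r.conductivity
        regions.append(RegionSpec(label=r.label, polygon=scale(r.polygon), conductivity=cond))
    return PhantomSpec(
        outline=scale(base.outline),
        regions=regions,
        background_conductivity=base.background_conductivity,
        n_electrodes=base.n_electrodes,
        electrode_width=base.electrode_width,
    )


def roi_mean(
    fieldfn: Callable[[np.ndarray, np.ndarray], np.ndarray],
    roi_centres: Sequence[tuple[float, float]],
    roi_area_mm2: float = 5.0,
    liver_polygon: Sequence[tuple[float, float]] | None = None,
) -> float:
    """Mean of per-ROI means of a percentage field over small circular ROIs.

    Emulates reading a fat-fraction map with a handful of ~5 mm² circular
    regions of interest inside the liver; the result is clipped to [0, 100].
    ``fieldfn`` maps (x, y) arrays in cm to field values in %.
    """
    if len(roi_centres) < 1:
        raise ParameterError("need at least one ROI")
    r_cm = float(np.sqrt(roi_area_mm2 / np.pi)) / 10.0
    liver = Polygon(liver_polygon) if liver_polygon is not None else None
    # midpoint polar quadrature: exact for linear fields, ~1e-3 for smooth ones
    nr, nt = 8, 24
    rr = (np.arange(nr) + 0.5) / nr * r_cm
    tt = (np.arange(nt) + 0.5) / nt * 2.0 * np.pi
    R, T = np.meshgrid(rr, tt, indexing="ij")
    w = R.ravel()  # area weight ∝ r for equal dr·dθ cells
    means = []
    for cx, cy in roi_centres:
        if liver is not None and not liver.contains(Point(cx, cy).buffer(r_cm)):
            raise PlacementError(f"ROI at ({cx}, {cy}) is not inside the liver region")
        x = cx + (R * np.cos(T)).ravel()
        y = cy + (R * np.sin(T)).ravel()
        means.append(float(np.average(np.asarray(fieldfn(x, y), dtype=float), weights=w)))
    return float(np.clip(np.mean(means), 0.0, 100.0))


# ---------------------------------------------------------------------------
# CSV layout mirroring the packaged fixture tables

COHORT_COLUMNS = [
    "subject", "sex", "bmi", "age", "waist", "height", "weight",
    "pdff", "eit_mean", "eit_sd", "injection_current", "excluded", "exclusion_reason",
]


def save_cohort(records: Sequence[SubjectRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(COHORT_COLUMNS)
        for r in records:
            wr.writerow(
                [
                    r.id, r.sex, repr(r.bmi), r.age, repr(r.waist), repr(r.height),
                    repr(r.weight), repr(r.pdff), repr(r.eit_mean), repr(r.eit_sd),
                    repr(r.injection_current), int(r.excluded), r.exclusion_reason,
                ]
            )


def load_cohort(path) -> list[SubjectRecord]:
    out = []
    with open(path) as fh:
        rd = csv.DictReader(fh)
        if rd.fieldnames is None or "subject" not in rd.fieldnames:
            from .errors import SchemaError

            raise SchemaError(f"{path}: not a cohort CSV")
        for row in rd:
            out.append(
                SubjectRecord(
                    id=int(row["subject"]),
                    sex=row.get("sex", ""),
                    bmi=float(row["bmi"]),
                    age=int(float(row["age"])),
                    waist=float(row["waist"]),
                    height=float(row["height"]),
                    weight=float(row["weight"]),
                    pdff=float(row["pdff"]),
                    eit_mean=float(row["eit_mean"]),
                    eit_sd=float(row["eit_sd"]),
                    injection_current=float(row["injection_current"]),
                    excluded=bool(int(row.get("excluded", 0) or 0)),
                    exclusion_reason=row.get("exclusion_reason", "") or "",
                )
            )
    return out
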