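"""Reproducible pipeline stages: simulate → reconstruct → stats.

A single :class:`RunConfig` (JSON or YAML on disk) describes the phantom,
stimulation pattern, noise model, inversion parameters and cohort choice.
Each stage writes its artifacts plus a ``manifest.json`` recording the full
config, its hash and the seed, sufficient to re-run the stage bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from .cohort import (
    CohortSpec,
    SubjectRecord,
    generate_cohort,
    load_cohort,
    save_cohort,
    subject_to_phantom,
)
from .errors import InputError, LiverEITError
from .forward import (
    MeasurementSet,
    NoiseModel,
    add_noise,
    load_measurements,
    make_skip_pattern,
    save_measurements,
    solve_forward,
)
from .inverse import (
    GammaWeights,
    ReconstructionResult,
    Regularization,
    liver_conductivity,
    reconstruct,
)
from .mesh import (
    PhantomSpec,
    TriMesh,
    anatomical_abdomen_phantom,
    build_phantom,
    phantom_conductivity,
    reference_abdomen_phantom,
    region_mask,
    save_mesh,
)
from .stats import CohortTable, reports_frame, run_study_analysis, scatter_with_ci
from .forward import ConductivityField

log = logging.getLogger("livereit")


class PatternConfig(BaseModel):
    n_electrodes: int = 32
    skip: int = 4
    current_ma: float = 2.0
    frequency_khz: float = 50.0


class NoiseConfig(BaseModel):
    kind: Literal["none", "additive", "additive_relative", "multiplicative"] = (
        "additive_relative"
    )
    sd: float = Field(default=0.001, ge=0.0)
    seed: int = 0

    def model(self) -> NoiseModel:
        return NoiseModel(self.kind, self.sd)


class InversionConfig(BaseModel):
    sigma0: Optional[float] = None          # None → homogeneous best fit
    lam: Optional[float] = None             # None → alpha heuristic
    alpha: float = 1.0
    gamma_within: float = 1.0
    gamma_cross: float = 0.1
    tol: float = 1e-3
    max_iter: int = 25
    electrode_model: Literal["point", "complete"] = "complete"
    contact_impedance: float = 50.0

    def regularization(self) -> Regularization:
        return Regularization(
            lam=self.lam,
            alpha=self.alpha,
            gamma_weights=GammaWeights(self.gamma_within, self.gamma_cross),
        )


class RunConfig(BaseModel):
    """One config drives every stage; stages ignore the parts they don't use."""

    phantom: str = "reference"              # 'reference' | 'anatomical' | path to JSON
    liver_conductivity: float = 0.30
    background_conductivity: float = 0.45
    target_element_size: float = 1.2        # cm
    pattern: PatternConfig = Field(default_factory=PatternConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    inversion: InversionConfig = Field(default_factory=InversionConfig)
    cohort: CohortSpec = Field(default_factory=CohortSpec)
    policy: Literal["none", "study_n16", "study_n18"] = "study_n16"

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            payload = yaml.safe_load(text)
        else:
            payload = json.loads(text)
        return cls.model_validate(payload)

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()


def resolve_phantom(cfg: RunConfig) -> PhantomSpec:
    if cfg.phantom == "reference":
        return reference_abdomen_phantom(
            cfg.liver_conductivity, cfg.background_conductivity,
            n_electrodes=cfg.pattern.n_electrodes,
        )
    if cfg.phantom == "anatomical":
        return anatomical_abdomen_phantom(
            cfg.liver_conductivity, cfg.background_conductivity,
            n_electrodes=cfg.pattern.n_electrodes,
        )
    p = Path(cfg.phantom)
    if not p.exists():
        raise InputError(f"config field 'phantom': file not found: {p}")
    return PhantomSpec.from_json(p)


def write_manifest(outdir: Path, cfg: RunConfig, stage: str, extra: dict | None = None):
    payload = {
        "stage": stage,
        "package": "livereit",
        "version": __version__,
        "config": cfg.model_dump(),
        "config_sha256": cfg.sha256(),
        "seed": cfg.noise.seed,
    }
    payload.update(extra or {})
    (outdir / "manifest.json").write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# stages


def cmd_simulate(cfg: RunConfig, outdir) -> Path:
    """Phantom → mesh → forward solve → noise → measurement CSV + manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = resolve_phantom(cfg)
    mesh = build_phantom(spec, cfg.target_element_size)
    sigma = ConductivityField.from_values(mesh, phantom_conductivity(mesh, spec))
    pattern = make_skip_pattern(
        cfg.pattern.n_electrodes, cfg.pattern.skip, cfg.pattern.current_ma
    )
    log.info("simulate: %d elements, %d frames", mesh.n_elements, len(pattern.frames))
    data = solve_forward(
        mesh, sigma, pattern, cfg.inversion.electrode_model,
        cfg.inversion.contact_impedance, frequency_khz=cfg.pattern.frequency_khz,
    )
    data = add_noise(data, cfg.noise.model(), cfg.noise.seed)
    save_mesh(mesh, outdir / "mesh.txt")
    save_measurements(data, outdir / "measurements.csv", outdir / "measurements.json")
    write_manifest(outdir, cfg, "simulate", {"n_elements": mesh.n_elements})
    return outdir / "measurements.csv"


def cmd_reconstruct(cfg: RunConfig, data_path, outdir) -> ReconstructionResult:
    """Measurement CSV → absolute conductivity map + JSON report (+ PNG)."""
    outdir = Path(outdir)
    data_path = Path(data_path)
    sidecar = data_path.with_suffix(".json")
    data = load_measurements(data_path, sidecar if sidecar.exists() else None)
    spec = resolve_phantom(cfg)
    mesh = build_phantom(spec, cfg.target_element_size)
    if data.pattern.n_electrodes != mesh.n_electrodes:
        raise InputError(
            f"data is for {data.pattern.n_electrodes} electrodes, mesh has {mesh.n_electrodes}"
        )
    result = reconstruct(
        mesh, data,
        sigma0=cfg.inversion.sigma0,
        reg=cfg.inversion.regularization(),
        tol=cfg.inversion.tol,
        max_iter=cfg.inversion.max_iter,
        electrode_model=cfg.inversion.electrode_model,
        contact_impedance=cfg.inversion.contact_impedance,
    )
    log.info(
        "reconstruct: %d iterations, converged=%s, misfit %.3e",
        result.iterations, result.converged, result.objective_trace[-1],
    )
    outdir.mkdir(parents=True, exist_ok=True)
    report = {
        "converged": result.converged,
        "iterations": result.iterations,
        "lambda": result.lam_used,
        "sigma0": result.sigma0,
        "objective_trace": result.objective_trace,
    }
    try:
        lm, lsd = liver_conductivity(result, mesh)
        report["liver_mean_S_per_m"] = lm
        report["liver_sd_S_per_m"] = lsd
    except KeyError:
        pass
    np.savetxt(outdir / "conductivity.txt", result.sigma.values, fmt="%r")
    (outdir / "report.json").write_text(json.dumps(report, indent=1))
    _render_map(mesh, result.sigma.values, outdir / "conductivity.png")
    write_manifest(outdir, cfg, "reconstruct", {"data": str(data_path)})
    return result


def _render_map(mesh: TriMesh, values: np.ndarray, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    tc = ax.tripcolor(
        mesh.nodes[:, 0], mesh.nodes[:, 1], mesh.elements, facecolors=values,
        cmap="viridis",
    )
    fig.colorbar(tc, ax=ax, label="conductivity (S/m)")
    ax.set_aspect("equal")
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def cmd_stats(cfg: RunConfig, cohort: str, outdir, plots: bool = True) -> pd.DataFrame:
    """Correlation grid on the packaged fixture or a cohort CSV."""
    outdir = Path(outdir)
    if cohort == "fixture":
        table = CohortTable.fixture(cfg.policy)
    else:
        p = Path(cohort)
        if not p.exists():
            raise InputError(f"cohort file not found: {p}")
        table = CohortTable.from_records(load_cohort(p), cfg.policy)
    if len(table.filtered()) < 3:
        raise InputError("cohort has fewer than 3 usable subjects")
    reports = run_study_analysis(table)
    df = reports_frame(reports)
    outdir.mkdir(parents=True, exist_ok=True)
    df.to_csv(outdir / "correlations.csv", index=False)
    (outdir / "correlations.json").write_text(df.to_json(orient="records", indent=1))
    if plots:
        sub = table.filtered()
        for xv, yv in [("pdff", "eit_mean"), ("bmi", "pdff"), ("bmi", "eit_mean")]:
            scatter_with_ci(sub, xv, yv, outdir / f"{yv}_vs_{xv}.png")
    write_manifest(outdir, cfg, "stats", {"cohort": cohort, "policy": cfg.policy})
    return df


def reference_recovery_experiment(liver_sigma: float = 0.30, seed: int = 42) -> dict:
    """Forward-simulate the reference abdomen phantom at the study conditions
    (32 electrodes, skip 4, 0.1 % additive noise) and reconstruct it.

    Returns the mesh, data, result, and area-weighted liver/background means —
    the canonical single-subject recovery experiment.
    """
    spec = reference_abdomen_phantom(
        liver_conductivity=liver_sigma, background_conductivity=0.45
    )
    mesh = build_phantom(spec, 1.2)
    truth = ConductivityField.from_values(mesh, phantom_conductivity(mesh, spec))
    pattern = make_skip_pattern(32, 4, 2.0)
    clean = solve_forward(mesh, truth, pattern, "complete")
    noisy = add_noise(clean, NoiseModel("additive_relative", 0.001), seed=seed)
    result = reconstruct(mesh, noisy, reg=Regularization(), tol=1e-3, max_iter=25)
    liver_mean, liver_sd = liver_conductivity(result, mesh)
    bg = region_mask(mesh, "background")
    w = mesh.element_areas()[bg]
    bg_mean = float(np.average(result.sigma.values[bg], weights=w))
    return {
        "mesh": mesh,
        "data": noisy,
        "result": result,
        "liver_mean": liver_mean,
        "liver_sd": liver_sd,
        "bg_mean": bg_mean,
        "truth": liver_sigma,
    }


def run_cohort_pipeline(
    cfg: RunConfig,
    records: list[SubjectRecord] | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """End-to-end physics run: per subject, phantom → forward (noisy) →
    reconstruct → liver mean; returns a frame with true PDFF and the
    reconstructed conductivity (``eit_recon``) per subject."""
    if records is None:
        records = generate_cohort(cfg.cohort)
    base = resolve_phantom(cfg)
    pattern = make_skip_pattern(
        cfg.pattern.n_electrodes, cfg.pattern.skip, cfg.pattern.current_ma
    )
    from shapely.geometry import Polygon

    base_perimeter = Polygon(base.outline).exterior.length
    rows = []
    for i, rec in enumerate(records):
        spec = subject_to_phantom(rec, base, cfg.cohort)
        # element size scales with the subject so relative resolution is constant
        h = cfg.target_element_size * rec.waist / base_perimeter
        mesh = build_phantom(spec, h)
        sigma = ConductivityField.from_values(mesh, phantom_conductivity(mesh, spec))
        data = solve_forward(
            mesh, sigma, pattern, cfg.inversion.electrode_model,
            cfg.inversion.contact_impedance,
        )
        data = add_noise(data, cfg.noise.model(), cfg.noise.seed + rec.id)
        result = reconstruct(
            mesh, data,
            sigma0=cfg.inversion.sigma0,
            reg=cfg.inversion.regularization(),
            tol=cfg.inversion.tol,
            max_iter=cfg.inversion.max_iter,
            electrode_model=cfg.inversion.electrode_model,
            contact_impedance=cfg.inversion.contact_impedance,
        )
        lm, lsd = liver_conductivity(result, mesh)
        rows.append(
            {
                "subject": rec.id,
                "pdff": rec.pdff,
                "waist": rec.waist,
                "sigma_liver_true": cfg.cohort.conductivity_of(rec.pdff),
                "eit_recon": lm,
                "eit_recon_sd": lsd,
                "converged": result.converged,
                "iterations": result.iterations,
                "excluded": rec.excluded,
            }
        )
        if progress:
            log.info("subject %d/%d: liver %.4f S/m", i + 1, len(records), lm)
    return pd.DataFrame(rows)


def cmd_end_to_end(cfg: RunConfig, outdir) -> pd.DataFrame:
    """Synthetic cohort through the whole physics + statistics pipeline."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = generate_cohort(cfg.cohort)
    save_cohort(records, outdir / "cohort.csv")
    df = run_cohort_pipeline(cfg, records)
    df.to_csv(outdir / "pipeline_subjects.csv", index=False)
    from .stats import pearson

    sub = df[~df["excluded"]]
    r, p, n = pearson(sub["pdff"], sub["eit_recon"])
    summary = {"r_recon_vs_pdff": r, "p": p, "n": n}
    (outdir / "pipeline_summary.json").write_text(json.dumps(summary, indent=1))
    write_manifest(outdir, cfg, "end_to_end", summary)
    return df
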