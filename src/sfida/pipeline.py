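"""End-to-end orchestration: simulate → analyze → cohort.

A run is driven by a :class:`RunConfig` (YAML-serialisable). ``run_simulate``
writes a synthetic plate (TIFF stacks + layout + ground truth + cohort
table); ``run_analyze`` turns images into QC-screened well and sample
readouts, fits the calibration, computes the LoD, and calibrates sample
concentrations (applying the assay-specific fecal dilution factor);
``run_cohort`` produces the diagnostic statistics. Every stage records
provenance (config hash, seed, package version) so identical configs
reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import (
    CalibrationCurve,
    LodEstimate,
    compute_lod,
    fit_calibration,
    pixel_to_concentration,
    select_calibration_points,
)
from .cohort import compare_groups, covariate_correlations, normality_suite, roc_youden
from .errors import AssayInvalidError, DataError, ParameterError
from .images import CV_GATES, QcParams, determine_cutoff, replicate_stats, well_readout
from .io import read_layout, read_stack, write_calibration_json, write_layout, write_stack
from .simulate import (
    CohortSimParams,
    ImagingParams,
    PlateSpec,
    WellAssignment,
    gen_cohort,
    gen_plate,
)

logger = logging.getLogger("sfida")

__all__ = ["RunConfig", "ResultsBundle", "run_simulate", "run_analyze", "run_cohort", "run_all"]

#: Default nanoparticle standard series: 1:5 dilution steps from 10 pM down,
#: expressed in fM, listed most dilute first.
DEFAULT_STANDARDS = [0.64, 3.2, 16.0, 80.0, 400.0, 2000.0, 10000.0]


@dataclass
class RunConfig:
    """Configuration for an end-to-end run. All concentrations in fM."""

    output_dir: str = "sfida_run"
    seed: int = 0
    imaging: ImagingParams = field(default_factory=ImagingParams)
    cohort_sim: CohortSimParams = field(default_factory=CohortSimParams)
    standard_concentrations: list[float] = field(default_factory=lambda: list(DEFAULT_STANDARDS))
    spots_per_fM: float = 0.5
    n_blank_wells: int = 24
    n_replicates: int = 4
    include_cohort_wells: bool = True
    cutoff_target_fraction: float = 1e-5
    qc: QcParams = field(default_factory=QcParams)
    min_accepted_fraction: float = 0.6
    calibration_alpha: float = 0.05
    linear_range_max_residual: float = 0.2
    fecal_dilution_factor: float = 5.0
    cv_gates: dict = field(default_factory=lambda: dict(CV_GATES))

    def __post_init__(self) -> None:
        if not (0 < self.cutoff_target_fraction < 1):
            raise ParameterError("cutoff_target_fraction must be in (0, 1)")
        if self.fecal_dilution_factor <= 0:
            raise ParameterError("fecal_dilution_factor must be positive")

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "imaging" in d and isinstance(d["imaging"], dict):
            d["imaging"] = ImagingParams(**d["imaging"])
        if "cohort_sim" in d and isinstance(d["cohort_sim"], dict):
            d["cohort_sim"] = CohortSimParams(**d["cohort_sim"])
        if "qc" in d and isinstance(d["qc"], dict):
            d["qc"] = QcParams(**d["qc"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class ResultsBundle:
    wells: pd.DataFrame | None = None
    samples: pd.DataFrame | None = None
    calibration: CalibrationCurve | None = None
    lod: LodEstimate | None = None
    stats: dict | None = None
    status: str = "ok"
    provenance: dict = field(default_factory=dict)


def _provenance(config: RunConfig, stage: str) -> dict:
    return {
        "stage": stage,
        "software_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }


def _build_plate_spec(config: RunConfig, cohort: pd.DataFrame | None) -> PlateSpec:
    from .simulate import _well_ids  # plate-position bookkeeping

    wells: list[WellAssignment] = []
    n_fecal = 0 if cohort is None else len(cohort)
    total = (
        config.n_blank_wells
        + len(config.standard_concentrations) * config.n_replicates
        + n_fecal * config.n_replicates
    )
    ids = iter(_well_ids(total))
    for _ in range(config.n_blank_wells):
        wells.append(WellAssignment(next(ids), "BC", "blank", 0.0, "BC"))
    for conc in config.standard_concentrations:
        sid = f"STD_{conc:g}fM"
        for _ in range(config.n_replicates):
            wells.append(WellAssignment(next(ids), sid, "standard", float(conc), sid))
    if cohort is not None:
        for row in cohort.itertuples():
            # in-well concentration is the endogenous level over the assay dilution
            in_well = float(row.true_concentration_fM) / config.fecal_dilution_factor
            for _ in range(config.n_replicates):
                wells.append(
                    WellAssignment(next(ids), str(row.sample_id), "fecal", in_well, str(row.sample_id))
                )
    return PlateSpec(wells=wells, expected_replicates=config.n_replicates)


def run_simulate(config: RunConfig) -> Path:
    """Write a synthetic plate and cohort to ``config.output_dir``.

    Outputs: ``images/<well>.tif`` stacks, ``layout.csv``, ``truth.csv``,
    ``cohort.csv`` and a provenance block; all deterministic in the seed.
    """
    out = Path(config.output_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    imaging = dataclasses.replace(config.imaging, seed=config.seed)
    cohort = None
    if config.include_cohort_wells:
        cohort = gen_cohort(dataclasses.replace(config.cohort_sim, seed=config.seed))
        cohort.to_csv(out / "cohort.csv", index=False)
    spec = _build_plate_spec(config, cohort)
    plate = gen_plate(imaging, spec, config.spots_per_fM)
    for well_id, stack in plate.images.items():
        write_stack(out / "images" / f"{well_id}.tif", stack)
    write_layout(out / "layout.csv", plate.layout)
    plate.truth.to_csv(out / "truth.csv", index=False)
    config.to_yaml(out / "config.yaml")
    (out / "provenance_simulate.json").write_text(
        json.dumps(_provenance(config, "simulate"), indent=2)
    )
    logger.info("simulated %d wells into %s", len(plate.images), out)
    return out


def run_analyze(config: RunConfig, run_dir: str | Path | None = None) -> ResultsBundle:
    """Analyse a plate directory: QC → cutoff → readouts → calibration →
    calibrated concentrations with below-LoD flags."""
    out = Path(run_dir) if run_dir is not None else Path(config.output_dir)
    layout = read_layout(out / "layout.csv")
    qc_log: list[str] = []

    # --- read stacks and screen blanks -------------------------------------
    stacks = {
        str(r.well_id): read_stack(
            out / "images" / f"{r.well_id}.tif",
            well_id=str(r.well_id),
            bit_depth=config.imaging.bit_depth,
        )
        for r in layout.itertuples()
    }
    blank_wells = layout.loc[layout.sample_kind == "blank", "well_id"].astype(str)
    if blank_wells.empty:
        raise AssayInvalidError("plate has no blank-control wells; cannot set a cutoff")
    blank_images = [im for w in blank_wells for im in stacks[w]]
    cutoff = determine_cutoff(
        blank_images, target_fraction=config.cutoff_target_fraction, qc_params=config.qc
    )

    # --- well readouts -----------------------------------------------------
    well_rows = []
    for r in layout.itertuples():
        w = well_readout(
            stacks[str(r.well_id)],
            cutoff,
            qc_params=config.qc,
            min_accepted_fraction=config.min_accepted_fraction,
        )
        if not w.valid:
            qc_log.append(f"well {r.well_id}: excluded ({w.exclusion_reason})")
        if w.images_accepted < w.images_total:
            qc_log.append(
                f"well {r.well_id}: {w.images_total - w.images_accepted} image(s) excluded by QC"
            )
        well_rows.append(
            {
                "well_id": r.well_id,
                "sample_id": r.sample_id,
                "sample_kind": r.sample_kind,
                "nominal_concentration_fM": r.nominal_concentration_fM,
                "images_total": w.images_total,
                "images_accepted": w.images_accepted,
                "raw_pixel_count": w.raw_pixel_count,
                "pixel_count": w.pixel_count,
                "valid": w.valid,
            }
        )
    wells = pd.DataFrame(well_rows)

    # --- replicate aggregation ---------------------------------------------
    sample_rows = []
    for (sid, kind), grp in wells.groupby(["sample_id", "sample_kind"], sort=False):
        counts = grp.loc[grp.valid, "pixel_count"].tolist()
        gate = config.cv_gates.get(kind, 25.0)
        s = replicate_stats(counts, sample_id=str(sid), sample_kind=str(kind), acceptance_cv=gate)
        sample_rows.append(
            {
                "sample_id": sid,
                "sample_kind": kind,
                "nominal_concentration_fM": grp.nominal_concentration_fM.iloc[0],
                "n_replicates": s.n_replicates,
                "pixel_count_mean": s.mean,
                "pixel_count_sd": s.sd,
                "cv_percent": s.cv_percent,
                "cv_pass": s.cv_pass,
                "reliable": s.reliable,
            }
        )
    samples = pd.DataFrame(sample_rows)

    bundle = ResultsBundle(wells=wells, samples=samples, provenance=_provenance(config, "analyze"))
    bundle.provenance["cutoff"] = {
        "cutoff": cutoff.cutoff,
        "positive_fraction": cutoff.positive_fraction_at_cutoff,
        "target_fraction": cutoff.target_fraction,
        "blank_pixel_total": cutoff.blank_pixel_total,
    }

    # --- calibration -------------------------------------------------------
    bc_counts = wells.loc[
        (wells.sample_kind == "blank") & wells.valid, "pixel_count"
    ].to_numpy(dtype=float)
    std = samples[samples.sample_kind == "standard"].sort_values("nominal_concentration_fM")
    if std.empty:
        bundle.status = "no calibration: plate has no standard wells"
        qc_log.append(bundle.status)
    else:
        std_wells = wells[(wells.sample_kind == "standard") & wells.valid]
        standards = [
            (
                float(conc),
                std_wells.loc[std_wells.nominal_concentration_fM == conc, "pixel_count"].tolist(),
            )
            for conc in std.nominal_concentration_fM
        ]
        points = select_calibration_points(
            standards,
            bc_counts,
            alpha=config.calibration_alpha,
            max_rel_residual=config.linear_range_max_residual,
        )
        curve = fit_calibration(points, alpha=config.calibration_alpha)
        lod = compute_lod(bc_counts, curve)
        bundle.calibration, bundle.lod = curve, lod

        conc_vals, below_blank = pixel_to_concentration(
            samples.pixel_count_mean.to_numpy(dtype=float), curve
        )
        dilution = np.where(samples.sample_kind == "fecal", config.fecal_dilution_factor, 1.0)
        samples["concentration_fM"] = conc_vals * dilution
        samples["below_blank"] = below_blank
        samples["below_lod"] = samples.pixel_count_mean < lod.lod_pixel
        bundle.samples = samples

    # --- persist -----------------------------------------------------------
    wells.to_csv(out / "wells.csv", index=False)
    bundle.samples.to_csv(out / "samples.csv", index=False)
    write_calibration_json(out / "calibration.json", bundle.calibration, bundle.lod)
    (out / "qc_log.txt").write_text("\n".join(qc_log) + "\n" if qc_log else "")
    (out / "provenance_analyze.json").write_text(json.dumps(bundle.provenance, indent=2))
    return bundle


def _cohort_table(config: RunConfig, run_dir: Path) -> pd.DataFrame:
    cohort_path = run_dir / "cohort.csv"
    samples_path = run_dir / "samples.csv"
    if not cohort_path.exists():
        raise DataError(f"cohort table not found at {cohort_path}")
    cohort = pd.read_csv(cohort_path)
    if samples_path.exists():
        samples = pd.read_csv(samples_path)
        if "concentration_fM" in samples.columns:
            measured = samples[samples.sample_kind == "fecal"][
                ["sample_id", "concentration_fM", "below_lod"]
            ]
            cohort = cohort.drop(columns=["concentration_fM"], errors="ignore").merge(
                measured, on="sample_id", how="left"
            )
    if "concentration_fM" not in cohort.columns:
        raise DataError("no calibrated concentrations available for the cohort")
    return cohort


def run_cohort(config: RunConfig, run_dir: str | Path | None = None) -> ResultsBundle:
    """Cohort statistics: normality suite, AD-vs-HC comparison, covariate
    correlations, ROC/Youden. Samples lacking a concentration are excluded
    (logged)."""
    out = Path(run_dir) if run_dir is not None else Path(config.output_dir)
    cohort = _cohort_table(config, out)
    n_total = len(cohort)
    cohort = cohort.dropna(subset=["concentration_fM"])
    n_missing = n_total - len(cohort)
    if n_missing:
        logger.warning("excluded %d cohort sample(s) without a concentration", n_missing)
    groups = set(cohort["group"].unique())
    if not {"AD", "HC"} <= groups:
        raise DataError(f"cohort must contain both AD and HC groups, found {sorted(groups)}")

    normality = normality_suite(cohort["concentration_fM"])
    comparison = compare_groups(cohort)
    roc = roc_youden(cohort)
    covars = [c for c in ("bristol", "age") if c in cohort.columns]
    correlations = covariate_correlations(cohort, covars) if covars else pd.DataFrame()

    stats = {
        "n_samples": int(len(cohort)),
        "n_excluded_missing_concentration": int(n_missing),
        "normality": normality.table.to_dict(orient="records"),
        "non_normal": normality.non_normal,
        "group_comparison": dataclasses.asdict(comparison),
        "covariate_correlations": correlations.to_dict(orient="records"),
        "roc": {
            "auc": roc.auc,
            "youden_threshold_fM": roc.youden_threshold,
            "youden_j": roc.youden_j,
            "sensitivity_percent": roc.sens_at_youden,
            "specificity_percent": roc.spec_at_youden,
            "n_ad": roc.n_ad,
            "n_hc": roc.n_hc,
        },
    }
    bundle = ResultsBundle(stats=stats, provenance=_provenance(config, "cohort"))
    (out / "stats_report.json").write_text(json.dumps(stats, indent=2, default=float))
    roc.to_frame().to_csv(out / "roc.csv", index=False)
    return bundle


def run_all(config: RunConfig) -> ResultsBundle:
    """simulate → analyze → cohort under one config."""
    run_simulate(config)
    analyzed = run_analyze(config)
    if analyzed.status != "ok":
        return analyzed
    cohort = run_cohort(config)
    cohort.wells = analyzed.wells
    cohort.samples = analyzed.samples
    cohort.calibration = analyzed.calibration
    cohort.lod = analyzed.lod
    return cohort
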