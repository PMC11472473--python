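"""Synthetic TIRFM plates and cohorts with known ground truth.

Emulates the data a single-particle surface immunoassay produces: blank
camera frames (Gaussian read noise on a constant offset, 14-bit data in a
16-bit container), concentration-dependent fields of diffraction-limited
spots (symmetric 2-D Gaussian profiles, log-normal amplitudes, Poisson spot
numbers proportional to the nanoparticle standard concentration), corrupted
frames for exercising the QC operators, and two-group log-normal cohorts of
calibrated aggregate concentrations.

Everything is deterministic given ``(seed, index)``; ground truth (spot
tables, generative concentrations) is returned alongside the rendered data
so downstream tests never have to re-derive it from the rendering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError
from .images import TirfmImage

__all__ = [
    "ImagingParams",
    "CohortSimParams",
    "PlateSpec",
    "WellAssignment",
    "SimulatedPlate",
    "gen_blank_image",
    "gen_spot_image",
    "gen_corrupted_image",
    "gen_plate",
    "gen_calibration_plate",
    "gen_cohort",
]

SAMPLE_KINDS = ("blank", "standard", "iqc", "fecal", "control")


@dataclass(frozen=True)
class ImagingParams:
    """Acquisition geometry and noise/spot model of the simulated microscope.

    Defaults are the study conditions: 25 frames per well of 1000×1000
    pixels holding 14-bit grayscale data. Read noise is Gaussian on a
    constant offset; an optional Poisson shot-noise term can be enabled.
    The point-spread function is a symmetric 2-D Gaussian (sigma in pixels)
    and spot amplitudes are log-normal with the given mean/SD in ADU.
    """

    image_height: int = 1000
    image_width: int = 1000
    bit_depth: int = 14
    images_per_well: int = 25
    background_mean: float = 500.0
    background_sd: float = 20.0
    psf_sigma: float = 1.5
    spot_amplitude_mean: float = 3000.0
    spot_amplitude_sd: float = 1500.0
    poisson_noise: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ParameterError("image dimensions must be positive")
        if not (1 <= self.bit_depth <= 16):
            raise ParameterError("bit_depth must be in 1..16")
        if self.images_per_well < 1:
            raise ParameterError("images_per_well must be >= 1")
        if self.psf_sigma <= 0:
            raise ParameterError("psf_sigma must be > 0")
        if self.background_sd < 0 or self.spot_amplitude_sd < 0:
            raise ParameterError("standard deviations must be >= 0")
        if self.background_mean < 0 or self.spot_amplitude_mean <= 0:
            raise ParameterError("background_mean >= 0 and spot_amplitude_mean > 0 required")

    @property
    def max_intensity(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def n_pixels(self) -> int:
        return self.image_height * self.image_width


@dataclass(frozen=True)
class CohortSimParams:
    """Two-group log-normal concentration model for simulated cohorts.

    Defaults emulate the proof-of-concept study design: 26 AD vs 31 HC,
    a common log-SD of 1.5 (spanning roughly 1 fM to 3 pM across 57 draws),
    a group separation of 1.13 natural-log units (normal-model AUC
    Φ(Δ/(σ√2)) ≈ 0.70), and 18.7% replicate CV (the observed mean fecal
    intra-assay variability).
    """

    n_ad: int = 26
    n_hc: int = 31
    log_mean_hc: float = 3.0
    log_mean_ad: float = 4.13
    log_sd: float = 1.5
    replicate_cv: float = 0.187
    n_replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ad < 1 or self.n_hc < 1:
            raise ParameterError("group sizes must be >= 1")
        if self.log_sd < 0 or self.replicate_cv < 0:
            raise ParameterError("log_sd and replicate_cv must be >= 0")
        if self.n_replicates < 1:
            raise ParameterError("n_replicates must be >= 1")


@dataclass(frozen=True)
class WellAssignment:
    well_id: str
    sample_id: str
    sample_kind: str
    nominal_concentration_fM: float  # NaN where not applicable
    replicate_group: str


@dataclass
class PlateSpec:
    """Assignment of wells to samples in replicate groups (default 4-fold)."""

    wells: list[WellAssignment]
    expected_replicates: int = 4

    def __post_init__(self) -> None:
        groups: dict[str, set[str]] = {}
        for w in self.wells:
            if w.sample_kind not in SAMPLE_KINDS:
                raise ParameterError(f"unknown sample_kind {w.sample_kind!r}")
            groups.setdefault(w.sample_id, set()).add(w.replicate_group)
        for sid, gs in groups.items():
            if len(gs) != 1:
                raise ParameterError(
                    f"sample {sid!r} appears in multiple replicate groups: {sorted(gs)}"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(w) for w in self.wells])

    @classmethod
    def from_frame(cls, df: pd.DataFrame, expected_replicates: int = 4) -> "PlateSpec":
        wells = [
            WellAssignment(
                well_id=str(r.well_id),
                sample_id=str(r.sample_id),
                sample_kind=str(r.sample_kind),
                nominal_concentration_fM=float(r.nominal_concentration_fM),
                replicate_group=str(r.replicate_group),
            )
            for r in df.itertuples()
        ]
        return cls(wells=wells, expected_replicates=expected_replicates)


@dataclass
class SimulatedPlate:
    """Rendered plate: per-well image stacks plus layout and ground truth."""

    images: dict[str, list[TirfmImage]]
    layout: pd.DataFrame
    truth: pd.DataFrame  # per well: n_spots, expected_spots_per_image


def _rng(seed: int, *index: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *[int(i) for i in index]])


def _background(params: ImagingParams, rng: np.random.Generator) -> np.ndarray:
    shape = (params.image_height, params.image_width)
    img = rng.normal(params.background_mean, params.background_sd, size=shape)
    if params.poisson_noise:
        img += rng.poisson(np.clip(img, 0, None)) - np.clip(img, 0, None)
    return img


def _finalize(params: ImagingParams, img: np.ndarray, **meta) -> TirfmImage:
    px = np.clip(np.rint(img), 0, params.max_intensity).astype(np.uint16)
    return TirfmImage(pixels=px, bit_depth=params.bit_depth, **meta)


def _lognormal_amplitudes(params: ImagingParams, n: int, rng: np.random.Generator) -> np.ndarray:
    m, s = params.spot_amplitude_mean, params.spot_amplitude_sd
    if s == 0:
        return np.full(n, float(m))
    sigma2 = math.log1p((s / m) ** 2)
    mu = math.log(m) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)


def _render_spots(
    canvas: np.ndarray, xs: np.ndarray, ys: np.ndarray, amps: np.ndarray, sigma: float
) -> None:
    """Add symmetric 2-D Gaussian profiles in place (x = column, y = row)."""
    h, w = canvas.shape
    radius = max(1, int(math.ceil(4.0 * sigma)))
    for x, y, a in zip(xs, ys, amps):
        x_lo = max(0, int(math.floor(x)) - radius)
        x_hi = min(w, int(math.floor(x)) + radius + 1)
        y_lo = max(0, int(math.floor(y)) - radius)
        y_hi = min(h, int(math.floor(y)) + radius + 1)
        if x_lo >= x_hi or y_lo >= y_hi:
            continue
        dx2 = (np.arange(x_lo, x_hi) - x) ** 2
        dy2 = (np.arange(y_lo, y_hi) - y) ** 2
        canvas[y_lo:y_hi, x_lo:x_hi] += a * np.exp(
            -(dy2[:, None] + dx2[None, :]) / (2.0 * sigma * sigma)
        )


def gen_blank_image(params: ImagingParams, index: int) -> TirfmImage:
    """One blank-control frame: clipped, rounded draws from the background
    noise model. Bit-identical for identical ``(seed, index)``."""
    rng = _rng(params.seed, index)
    return _finalize(params, _background(params, rng), position_index=index)


def gen_spot_image(
    params: ImagingParams,
    n_spots: int,
    index: int,
    positions: np.ndarray | None = None,
    amplitudes: np.ndarray | None = None,
) -> tuple[TirfmImage, pd.DataFrame]:
    """Blank frame plus ``n_spots`` Gaussian spots at uniform sub-pixel
    positions; returns the rendered image and the ground-truth spot table
    (columns x, y, amplitude).

    ``positions`` (n×2 array of x, y) and ``amplitudes`` may be supplied to
    pin spots deterministically, e.g. for PSF tests.
    """
    if n_spots < 0:
        raise ParameterError("n_spots must be >= 0")
    if n_spots > 0.1 * params.n_pixels:
        raise ParameterError("n_spots exceeds 10% of pixels; density out of range")
    rng = _rng(params.seed, index)
    img = _background(params, rng)
    if positions is None:
        xs = rng.uniform(0, params.image_width, size=n_spots)
        ys = rng.uniform(0, params.image_height, size=n_spots)
    else:
        positions = np.asarray(positions, dtype=float).reshape(-1, 2)
        if len(positions) != n_spots:
            raise ParameterError("positions length must equal n_spots")
        xs, ys = positions[:, 0], positions[:, 1]
    if amplitudes is None:
        amps = _lognormal_amplitudes(params, n_spots, rng)
    else:
        amps = np.asarray(amplitudes, dtype=float)
        if len(amps) != n_spots:
            raise ParameterError("amplitudes length must equal n_spots")
    _render_spots(img, xs, ys, amps, params.psf_sigma)
    truth = pd.DataFrame({"x": xs, "y": ys, "amplitude": amps})
    return _finalize(params, img, position_index=index), truth


def gen_corrupted_image(
    params: ImagingParams,
    mode: str,
    index: int,
    n_spots: int = 50,
    blob_fraction: float = 0.005,
    defocus_factor: float = 4.0,
) -> TirfmImage:
    """Deliberately unusable frame for QC exercising.

    ``artifact`` injects a saturated connected disk covering at least
    ``blob_fraction`` of the pixels (default 0.5%); ``defocus`` renders the
    spot field with the PSF sigma inflated by ``defocus_factor`` (>= 4 by
    default) so the variance-of-Laplacian focus score collapses. A
    ``blob_fraction`` of 0 degenerates to a plain blank frame.
    """
    if mode not in ("artifact", "defocus"):
        raise ParameterError(f"mode must be 'artifact' or 'defocus', got {mode!r}")
    if mode == "artifact":
        rng = _rng(params.seed, index, 7)
        img = _background(params, rng)
        if n_spots:
            xs = rng.uniform(0, params.image_width, size=n_spots)
            ys = rng.uniform(0, params.image_height, size=n_spots)
            _render_spots(img, xs, ys, _lognormal_amplitudes(params, n_spots, rng), params.psf_sigma)
        if blob_fraction > 0:
            area = blob_fraction * params.n_pixels
            radius = math.sqrt(area / math.pi)
            cx = rng.uniform(radius, params.image_width - radius)
            cy = rng.uniform(radius, params.image_height - radius)
            yy, xx = np.ogrid[: params.image_height, : params.image_width]
            dist2 = (yy - cy) ** 2 + (xx - cx) ** 2
            # grow the rasterised disk until it covers the requested area
            while np.count_nonzero(dist2 <= radius**2) < area:
                radius *= 1.02
            img[dist2 <= radius**2] = params.max_intensity
        return _finalize(params, img, position_index=index)
    if defocus_factor < 1:
        raise ParameterError("defocus_factor must be >= 1")
    blurred = replace(params, psf_sigma=params.psf_sigma * defocus_factor)
    image, _ = gen_spot_image(blurred, n_spots, index)
    return image


def _well_ids(n: int) -> list[str]:
    """384-well-style identifiers A01..P24, row-major."""
    rows = "ABCDEFGHIJKLMNOP"
    ids = [f"{r}{c:02d}" for r in rows for c in range(1, 25)]
    if n > len(ids):
        raise ParameterError(f"plate capacity exceeded ({n} > {len(ids)} wells)")
    return ids[:n]


def default_calibration_spec(
    standard_concentrations: Sequence[float],
    n_replicates: int = 4,
    n_blank_wells: int = 24,
) -> PlateSpec:
    """Plate layout with blanks first, then one replicate group per standard."""
    wells: list[WellAssignment] = []
    total = n_blank_wells + len(standard_concentrations) * n_replicates
    ids = iter(_well_ids(total))
    for _ in range(n_blank_wells):
        wells.append(WellAssignment(next(ids), "BC", "blank", 0.0, "BC"))
    for conc in standard_concentrations:
        sid = f"STD_{conc:g}fM"
        for _ in range(n_replicates):
            wells.append(WellAssignment(next(ids), sid, "standard", float(conc), sid))
    return PlateSpec(wells=wells, expected_replicates=n_replicates)


def gen_plate(
    params: ImagingParams, spec: PlateSpec, spots_per_fM: float
) -> SimulatedPlate:
    """Render every well of a plate layout.

    For a well at nominal concentration c the number of spots in each frame
    is Poisson with mean ``spots_per_fM * c``; blank wells render pure
    background. Ground truth records the realised and expected spot numbers
    per well.
    """
    if spots_per_fM < 0:
        raise ParameterError("spots_per_fM must be >= 0")
    images: dict[str, list[TirfmImage]] = {}
    truth_rows = []
    for w_index, w in enumerate(spec.wells):
        rng = _rng(params.seed, 1000 + w_index)
        conc = 0.0 if w.sample_kind == "blank" else float(w.nominal_concentration_fM)
        if not np.isfinite(conc):
            conc = 0.0
        mean_spots = spots_per_fM * conc
        stack: list[TirfmImage] = []
        n_total = 0
        for i in range(params.images_per_well):
            n = int(rng.poisson(mean_spots)) if mean_spots > 0 else 0
            n_total += n
            sub_seed = int(rng.integers(0, 2**31 - 1))
            frame_params = replace(params, seed=sub_seed)
            if n > 0:
                im, _ = gen_spot_image(frame_params, n, i + 1)
            else:
                im = gen_blank_image(frame_params, i + 1)
            im.well_id = w.well_id
            stack.append(im)
        images[w.well_id] = stack
        truth_rows.append(
            {
                "well_id": w.well_id,
                "sample_id": w.sample_id,
                "sample_kind": w.sample_kind,
                "nominal_concentration_fM": w.nominal_concentration_fM,
                "n_spots": n_total,
                "expected_spots_per_image": mean_spots,
            }
        )
    return SimulatedPlate(images=images, layout=spec.to_frame(), truth=pd.DataFrame(truth_rows))


def gen_calibration_plate(
    params: ImagingParams,
    standard_concentrations: Sequence[float],
    spots_per_fM: float,
    spec: PlateSpec | None = None,
    n_replicates: int = 4,
    n_blank_wells: int = 24,
) -> SimulatedPlate:
    """Calibration plate: blank wells plus a nanoparticle standard series.

    Concentrations must be non-negative and strictly increasing (a dilution
    series listed from the most dilute point upward).
    """
    conc = [float(c) for c in standard_concentrations]
    if not conc:
        raise ParameterError("standard_concentrations must be non-empty")
    if any(c < 0 for c in conc):
        raise ParameterError("concentrations must be non-negative")
    if any(b <= a for a, b in zip(conc, conc[1:])):
        raise ParameterError("concentrations must be strictly increasing")
    if spec is None:
        spec = default_calibration_spec(conc, n_replicates, n_blank_wells)
    return gen_plate(params, spec, spots_per_fM)


def gen_cohort(params: CohortSimParams) -> pd.DataFrame:
    """Simulated two-group cohort table with ground truth.

    Per sample: a true concentration drawn log-normally by group,
    ``n_replicates`` readouts jittered with a mean-one log-normal factor of
    CV ``replicate_cv``, and demographic covariates (age, sex, Bristol
    stool score) drawn to match the study's group summaries. Columns:
    sample_id, group, true_concentration_fM, concentration_fM (replicate
    mean), cv_percent, bristol, age, sex.
    """
    rng = _rng(params.seed, 42)
    rows = []
    group_specs = [
        ("AD", params.n_ad, params.log_mean_ad, 71.1, 8.6, 0.423, 4.4, 0.9),
        ("HC", params.n_hc, params.log_mean_hc, 49.2, 16.4, 0.645, 5.1, 0.8),
    ]
    if params.replicate_cv > 0:
        s2 = math.log1p(params.replicate_cv**2)
        jitter_mu, jitter_sigma = -s2 / 2.0, math.sqrt(s2)
    for group, n, log_mean, age_m, age_s, f_frac, bristol_m, bristol_s in group_specs:
        true = np.exp(rng.normal(log_mean, params.log_sd, size=n))
        ages = rng.normal(age_m, age_s, size=n)
        female = rng.random(n) < f_frac
        bristol = np.clip(np.rint(rng.normal(bristol_m, bristol_s, size=n)), 1, 7)
        for i in range(n):
            if params.replicate_cv > 0:
                reps = true[i] * rng.lognormal(jitter_mu, jitter_sigma, size=params.n_replicates)
            else:
                reps = np.full(params.n_replicates, true[i])
            mean = float(np.mean(reps))
            sd = float(np.std(reps, ddof=1)) if params.n_replicates > 1 else 0.0
            rows.append(
                {
                    "sample_id": f"{group}{i + 1:02d}",
                    "group": group,
                    "true_concentration_fM": float(true[i]),
                    "concentration_fM": mean,
                    "cv_percent": 100.0 * sd / mean if mean > 0 else float("nan"),
                    "bristol": int(bristol[i]),
                    "age": float(np.round(ages[i], 1)),
                    "sex": "F" if female[i] else "M",
                }
            )
    return pd.DataFrame(rows)
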