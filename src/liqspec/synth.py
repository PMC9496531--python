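"""Synthetic ATR-FTIR spectra of lipid/contaminant mixtures.

Spectra are rendered as sums of Gaussian bands at the catalogued diagnostic
wavenumbers (CH stretches 2958/2922/2888, ester 1740 and carboxyl 1710,
amide I/II 1645/1550, phosphate 1245/1080, sugar C-O 1160/1034, amide A 3525,
alkene CH 3020, plus a broad OH/NH hump), with absorbance exactly linear in
each analyte amount (Beer-Lambert), sampled on an instrument-like 8 cm^-1
grid, with optional additive white Gaussian noise and an optional linear
drift to exercise the anchored baseline correction.

The per-analyte band amplitudes are free parameters of this fixture library.
They were calibrated once so that the analyte set reproduces the qualitative
structure of real contaminant spectra — a pure-lipid LiQ score in the
1.7-2.0 pure band, a metabolite score below the 0.3514 cut-off, detergents
with an elevated CH_min/CH_max proportion, proteins dominated by amide I and
sugars by the 1034 cm^-1 band — and are frozen here. The default noise level
(0.006 AU) puts the closed-form CH-region detection limit of the lipid model
at ~12 ng, the regime of a well-performing ATR instrument.

Gaussian band shape keeps every oracle (peak heights, region integrals via
erf) in closed form; the linearity and ratio properties under test do not
depend on the line shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from .errors import ConfigurationError, DomainError
from .spectra_io import Spectrum, SpectrumSet

__all__ = [
    "Band",
    "AnalyteModel",
    "DEFAULT_ANALYTES",
    "MixtureSpec",
    "DEFAULT_GRID",
    "DEFAULT_NOISE_SD",
    "render_spectrum",
    "analytic_absorbance",
    "analytic_region_integral",
    "predicted_lod",
    "generate_titration",
    "generate_contamination_series",
    "generate_cohort",
    "DEFAULT_TITRATION_MASSES",
]

#: Instrument-like acquisition grid: 4000 down to 656 cm^-1 at 8 cm^-1
#: sampling (419 points), stored ascending.
DEFAULT_GRID = np.arange(656.0, 4001.0, 8.0)

#: Default additive white-noise SD on absorbance (AU). Chosen so the
#: closed-form CH-region LOD of the default lipid model is ~12 ng.
DEFAULT_NOISE_SD = 0.006


@dataclass(frozen=True)
class Band:
    """One Gaussian absorption band: amplitude * exp(-(v-center)^2 / 2 width^2)."""

    center: float
    width: float
    relative_amplitude: float

    def __post_init__(self):
        if self.width <= 0:
            raise DomainError(f"band width must be > 0, got {self.width!r}")
        if self.relative_amplitude < 0:
            raise DomainError("band amplitude must be >= 0")


@dataclass(frozen=True)
class AnalyteModel:
    """Band set and scalar response (absorbance per ug) for one analyte."""

    name: str
    bands: tuple[Band, ...]
    response: float = 1.0

    def __post_init__(self):
        if self.response <= 0:
            raise DomainError("analyte response must be > 0")


def _bands(*triples: tuple[float, float, float]) -> tuple[Band, ...]:
    return tuple(Band(c, w, a) for c, w, a in triples)


#: Frozen fixture library (amplitudes calibrated once, see module docstring).
DEFAULT_ANALYTES: dict[str, AnalyteModel] = {
    "lipid_ester": AnalyteModel(
        "lipid_ester",
        _bands((2958, 12, 0.55), (2922, 12, 1.00), (2888, 10, 0.52),
               (1740, 10, 0.45)),
        response=1.0,
    ),
    "fatty_acid": AnalyteModel(
        "fatty_acid",
        _bands((2958, 12, 0.55), (2922, 12, 1.00), (2888, 10, 0.52),
               (1710, 10, 0.50)),
        response=1.0,
    ),
    "protein": AnalyteModel(
        "protein",
        _bands((3525, 60, 0.30), (2925, 14, 0.25), (1645, 25, 1.00),
               (1550, 20, 0.70)),
        response=1.0,
    ),
    "rna": AnalyteModel(
        "rna",
        _bands((3525, 60, 0.20), (2925, 14, 0.20), (1645, 25, 0.80),
               (1245, 18, 0.55), (1080, 18, 0.65), (1034, 18, 0.45)),
        response=1.0,
    ),
    "sugar": AnalyteModel(
        "sugar",
        _bands((3300, 120, 0.35), (2925, 14, 0.15), (1160, 18, 0.55),
               (1034, 20, 1.00)),
        response=1.0,
    ),
    "detergent": AnalyteModel(
        "detergent",
        _bands((2958, 12, 0.60), (2922, 12, 1.00), (2888, 10, 0.95),
               (1100, 25, 0.30)),
        response=1.0,
    ),
    "metabolite": AnalyteModel(
        "metabolite",
        _bands((3300, 140, 0.25), (2925, 14, 0.51), (2888, 10, 0.12),
               (1645, 25, 0.55), (1160, 18, 0.45), (1080, 18, 0.30),
               (1034, 20, 1.00)),
        response=3.0,
    ),
    "broad_OH": AnalyteModel(
        "broad_OH",
        _bands((3000, 200, 1.00),),
        response=1.0,
    ),
}


@dataclass(frozen=True)
class MixtureSpec:
    """Composition and acquisition conditions for one synthetic spectrum.

    ``amounts`` maps analyte name to amount in ug; ``drift`` is an optional
    (offset, slope) line a + b*wavenumber added before baseline correction.
    """

    amounts: Mapping[str, float]
    grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())
    noise_sd: float = 0.0
    seed: int = 0
    drift: tuple[float, float] | None = None

    def __post_init__(self):
        for name, amount in self.amounts.items():
            if amount < 0:
                raise DomainError(f"negative amount for {name!r}")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")


def analytic_absorbance(
    amounts: Mapping[str, float],
    wavenumbers,
    models: Mapping[str, AnalyteModel] | None = None,
) -> np.ndarray:
    """Noise-free band-model absorbance at arbitrary wavenumbers (closed form)."""
    models = DEFAULT_ANALYTES if models is None else models
    v = np.asarray(wavenumbers, dtype=float)
    signal = np.zeros_like(v)
    for name, amount in amounts.items():
        if name not in models:
            raise ConfigurationError(f"unknown analyte {name!r}")
        model = models[name]
        scale = amount * model.response
        for band in model.bands:
            signal = signal + scale * band.relative_amplitude * np.exp(
                -((v - band.center) ** 2) / (2.0 * band.width**2)
            )
    return signal


def analytic_region_integral(
    amounts: Mapping[str, float],
    low: float,
    high: float,
    models: Mapping[str, AnalyteModel] | None = None,
) -> float:
    """Exact integral of the noise-free band model over [low, high] via erf."""
    models = DEFAULT_ANALYTES if models is None else models
    total = 0.0
    for name, amount in amounts.items():
        if name not in models:
            raise ConfigurationError(f"unknown analyte {name!r}")
        model = models[name]
        scale = amount * model.response
        for band in model.bands:
            s = band.width
            z_hi = (high - band.center) / (s * np.sqrt(2.0))
            z_lo = (low - band.center) / (s * np.sqrt(2.0))
            total += (
                scale
                * band.relative_amplitude
                * s
                * np.sqrt(np.pi / 2.0)
                * (erf(z_hi) - erf(z_lo))
            )
    return float(total)


def render_spectrum(
    mix: MixtureSpec,
    models: Mapping[str, AnalyteModel] | None = None,
    *,
    sample_id: str = "",
    replicate_id: str = "",
) -> Spectrum:
    """Render one synthetic spectrum: bands + drift + seeded Gaussian noise.

    Deterministic for a fixed :class:`MixtureSpec`. Drift-free spectra are
    flagged ``baseline_corrected`` — the band model is zero in both anchor
    windows, so a drift-free render already sits on the blank baseline.
    """
    grid = np.asarray(mix.grid, dtype=float)
    signal = analytic_absorbance(mix.amounts, grid, models)
    if mix.drift is not None:
        offset, slope = mix.drift
        signal = signal + offset + slope * grid
    if mix.noise_sd > 0:
        rng = np.random.default_rng(mix.seed)
        signal = signal + rng.normal(0.0, mix.noise_sd, size=grid.size)
    return Spectrum(
        grid, signal,
        sample_id=sample_id,
        replicate_id=replicate_id,
        baseline_corrected=mix.drift is None,
    )


def _trapezoid_weights(ws: np.ndarray) -> np.ndarray:
    w = np.zeros_like(ws)
    d = np.diff(ws)
    w[:-1] += d / 2.0
    w[1:] += d / 2.0
    return w


def predicted_lod(
    analyte: str = "lipid_ester",
    *,
    noise_sd: float = DEFAULT_NOISE_SD,
    low: float = 2800.0,
    high: float = 3000.0,
    grid: np.ndarray | None = None,
    models: Mapping[str, AnalyteModel] | None = None,
) -> float:
    """Closed-form LOD (ng) implied by the generator's own parameters.

    The trapezoid AUC of white noise over the snapped region has SD
    noise_sd * sqrt(sum of squared trapezoid weights); the response slope per
    ng is the trapezoid AUC of a 1 ug noiseless render divided by 1000.
    LOD = 3 * SD_auc / slope, the same ICH formula the fitting code applies
    to measured blanks, evaluated on known parameters instead of data.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    mask = (grid >= low) & (grid <= high)
    ws = grid[mask]
    weights = _trapezoid_weights(ws)
    sd_auc = noise_sd * float(np.sqrt(np.sum(weights**2)))
    unit = analytic_absorbance({analyte: 1.0}, ws, models)
    slope_per_ng = float(np.sum(weights * unit)) / 1000.0
    return 3.0 * sd_auc / slope_per_ng


#: Titration design covering the quantitative range, with triplicate blanks
#: for the blank-SD estimate.
DEFAULT_TITRATION_MASSES: tuple[float, ...] = (0, 0, 0, 40, 125, 250, 500, 1000, 3000)


def _child_seed(seed: int, index: int) -> np.random.Generator:
    # sequence seeding gives independent, reproducible streams per spectrum
    return np.random.default_rng([seed, index])


def generate_titration(
    analyte: str = "lipid_ester",
    masses_ng: Sequence[float] = DEFAULT_TITRATION_MASSES,
    replicates: int = 3,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    *,
    grid: np.ndarray | None = None,
    models: Mapping[str, AnalyteModel] | None = None,
    require_blanks: bool = True,
) -> tuple[SpectrumSet, pd.DataFrame]:
    """Seeded external-standard titration plus its truth table.

    Every (mass level, replicate) pair gets an independent noise stream.
    Returns the spectra and a DataFrame (sample_id, replicate_id, mass_ng);
    each spectrum is its own calibration point.
    """
    models = DEFAULT_ANALYTES if models is None else models
    if analyte not in models:
        raise ConfigurationError(f"unknown analyte {analyte!r}")
    masses = [float(m) for m in masses_ng]
    if require_blanks and not any(m == 0 for m in masses):
        raise ConfigurationError(
            "titration must include blank (mass 0) levels for the blank SD"
        )
    if len([m for m in set(masses) if m > 0]) < 3:
        raise ConfigurationError("titration needs >=3 distinct non-zero mass levels")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)

    sset = SpectrumSet()
    rows = []
    index = 0
    for level_no, mass in enumerate(masses):
        for rep in range(1, replicates + 1):
            sample_id = f"{analyte}_L{level_no:02d}_{mass:g}ng_r{rep}"
            signal = analytic_absorbance({analyte: mass / 1000.0}, grid, models)
            if noise_sd > 0:
                signal = signal + _child_seed(seed, index).normal(
                    0.0, noise_sd, size=grid.size
                )
            sset.add(
                Spectrum(grid, signal, sample_id=sample_id,
                         replicate_id=f"r{rep}", baseline_corrected=True)
            )
            rows.append({"sample_id": sample_id, "replicate_id": f"r{rep}",
                         "mass_ng": mass})
            index += 1
    return sset, pd.DataFrame(rows)


def generate_contamination_series(
    lipid_ug: float = 1.0,
    contaminant: str = "metabolite",
    levels: Sequence[float] = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    lipid: str = "lipid_ester",
    grid: np.ndarray | None = None,
    models: Mapping[str, AnalyteModel] | None = None,
) -> tuple[SpectrumSet, pd.DataFrame]:
    """Constant-lipid spike-in series with increasing contaminant amount (ug).

    Mirrors the spike-in design of contamination assays: the lipid amount is
    held fixed while the contaminant level varies, so any change in AUC or
    score is attributable to the contaminant. Level 0 with the same seed is
    bit-identical to the pure-lipid render.
    """
    models = DEFAULT_ANALYTES if models is None else models
    for name in (contaminant, lipid):
        if name not in models:
            raise ConfigurationError(f"unknown analyte {name!r}")
    if any(level < 0 for level in levels):
        raise DomainError("contaminant levels must be >= 0")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)

    sset = SpectrumSet()
    rows = []
    for i, level in enumerate(levels):
        sample_id = f"{lipid}+{contaminant}_{level:g}ug"
        signal = analytic_absorbance(
            {lipid: lipid_ug, contaminant: float(level)}, grid, models
        )
        if noise_sd > 0:
            signal = signal + _child_seed(seed, i).normal(0.0, noise_sd, grid.size)
        sset.add(Spectrum(grid, signal, sample_id=sample_id, baseline_corrected=True))
        rows.append({"sample_id": sample_id, "lipid_ug": lipid_ug,
                     "contaminant": contaminant, "contaminant_ug": float(level)})
    return sset, pd.DataFrame(rows)


def generate_cohort(
    n_samples: int = 107,
    n_contaminated: int = 25,
    seed: int = 0,
    *,
    replicates: int = 3,
    lipid_range_ug: tuple[float, float] = (0.3, 1.5),
    clean_ratio_range: tuple[float, float] = (1.0, 4.0),
    contaminated_ratio_range: tuple[float, float] = (15.0, 30.0),
    noise_sd: float = DEFAULT_NOISE_SD,
    ms_response_per_ug: float = 1.0e6,
    ms_noise_cv: float = 0.08,
    ms_fraction: float = 0.06,
    ftir_fraction: float = 1.0 / 12.0,
    grid: np.ndarray | None = None,
    models: Mapping[str, AnalyteModel] | None = None,
) -> tuple[SpectrumSet, pd.DataFrame]:
    """A plasma-like screening cohort with planted low-quality samples.

    Every sample is a monophasic-extract-like lipid+metabolite mixture; the
    metabolite load is expressed as the ratio of metabolite band response to
    lipid band response. Clean samples draw ratios in ``clean_ratio_range``
    (LiQ roughly 0.42-0.68, the plasma-extract band), contaminated samples in
    ``contaminated_ratio_range`` (LiQ well below the 0.3514 cut-off). A
    synthetic MS total intensity tracks the true lipid amount with lognormal
    measurement noise and is scaled to the MS measured fraction, so the truth
    table can stand in for an exported MS total-intensity table.

    Returns the replicate spectra and a truth table with one row per sample
    (sample_id, lipid_ug, metabolite_ratio, contaminated, total_intensity).
    """
    if not 0 <= n_contaminated <= n_samples:
        raise ConfigurationError("n_contaminated must be between 0 and n_samples")
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    models = DEFAULT_ANALYTES if models is None else models
    rng = np.random.default_rng([seed, 987654321])

    contaminated_idx = set(
        rng.choice(n_samples, size=n_contaminated, replace=False).tolist()
    )
    metabolite_response = models["metabolite"].response

    sset = SpectrumSet()
    rows = []
    stream = 0
    for i in range(n_samples):
        sample_id = f"S{i + 1:03d}"
        contaminated = i in contaminated_idx
        lipid_ug = float(rng.uniform(*lipid_range_ug))
        lo, hi = contaminated_ratio_range if contaminated else clean_ratio_range
        ratio = float(rng.uniform(lo, hi))
        metabolite_ug = ratio * lipid_ug / metabolite_response
        amounts = {"lipid_ester": lipid_ug, "metabolite": metabolite_ug}
        for rep in range(1, replicates + 1):
            signal = analytic_absorbance(amounts, grid, models)
            if noise_sd > 0:
                signal = signal + _child_seed(seed, stream).normal(
                    0.0, noise_sd, grid.size
                )
            stream += 1
            sset.add(
                Spectrum(grid, signal, sample_id=sample_id,
                         replicate_id=f"r{rep}", baseline_corrected=True)
            )
        ti = (
            lipid_ug
            * ms_response_per_ug
            * (ms_fraction / ftir_fraction)
            * float(np.exp(rng.normal(0.0, ms_noise_cv)))
        )
        rows.append({
            "sample_id": sample_id,
            "lipid_ug": lipid_ug,
            "metabolite_ratio": ratio,
            "contaminated": contaminated,
            "total_intensity": ti,
        })
    return sset, pd.DataFrame(rows)
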