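"""Region AUC quantification, calibration curves with ICH figures of merit,
absolute quantification, and FTIR-vs-MS comparison.

Total lipid is quantified from the area under the baseline-corrected
absorbance trace over a lipid-characteristic region — by default the
CH-stretching region (3000-2800 cm^-1); the ester/carbonyl C=O region
(1760-1710 cm^-1) is the secondary choice. Absorbance is linear in analyte
amount (Beer-Lambert), so an external standard titration yields a straight
calibration line AUC = slope*mass + intercept, and ICH detection limits
follow as LOD = 3*SD_blank/slope and LOQ = 10*SD_blank/slope.

An optional *local baseline* subtracts the chord joining the region's
endpoint absorbances from the AUC. This is deliberately exposed because it is
a common default in instrument software, but it biases quantification of
impure extracts (neighbouring bands lift the endpoints and bisect the peak);
the recommended default is the plain CH-region AUC without it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DomainError,
    GridError,
    InsufficientDataError,
    InvalidCurveError,
    NotBaselinedError,
    SpectralRangeError,
)
from .spectra_io import Spectrum, SpectrumSet

__all__ = [
    "Region",
    "REGIONS",
    "region_auc",
    "CalibrationCurve",
    "fit_calibration",
    "calibrate_from_titration",
    "QuantResult",
    "quantify",
    "percent_error",
    "measured_fraction",
    "MsComparison",
    "compare_to_ms",
]


@dataclass(frozen=True)
class Region:
    """A named closed wavenumber interval [low, high] in cm^-1."""

    name: str
    low: float
    high: float

    def __post_init__(self):
        if not self.low < self.high:
            raise DomainError(f"region {self.name!r}: low must be < high")


#: Named quantification regions. The extended variants cover the alkene CH
#: band of unsaturated lipids (up to 3010 cm^-1) and the free fatty-acid
#: carboxyl band (down to 1700 cm^-1).
REGIONS: dict[str, Region] = {
    "CH": Region("CH", 2800.0, 3000.0),
    "C=O": Region("C=O", 1710.0, 1760.0),
    "CH_extended": Region("CH_extended", 2800.0, 3010.0),
    "C=O_extended": Region("C=O_extended", 1700.0, 1760.0),
}


def region_auc(
    spectrum: Spectrum,
    region: Region,
    local_baseline: bool = False,
    *,
    require_baselined: bool = True,
) -> float:
    """Composite trapezoid AUC of the spectrum over a region.

    Region bounds snap to the grid points falling inside the closed interval.
    With ``local_baseline`` the chord area
    (height_low + height_high)/2 * (high - low) computed from the snapped
    endpoints is subtracted, giving the signed area between the trace and the
    straight chord joining its endpoints (may be negative).
    """
    if require_baselined and not spectrum.baseline_corrected:
        raise NotBaselinedError(
            "region_auc requires a baseline-corrected spectrum "
            "(pass require_baselined=False to override)"
        )
    w, a = spectrum.wavenumbers, spectrum.absorbance
    if region.high < w[0] or region.low > w[-1]:
        raise SpectralRangeError(
            f"region {region.name!r} ({region.low:g}-{region.high:g}) is outside "
            f"the grid span ({w[0]:g}, {w[-1]:g})"
        )
    mask = (w >= region.low) & (w <= region.high)
    if mask.sum() < 2:
        raise GridError(
            f"region {region.name!r} contains {int(mask.sum())} grid points; "
            "need at least 2"
        )
    ws, As = w[mask], a[mask]
    auc = float(np.trapezoid(As, ws))
    if local_baseline:
        chord = (As[0] + As[-1]) / 2.0 * (ws[-1] - ws[0])
        auc -= float(chord)
    return auc


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted linear calibration with ICH figures of merit.

    ``slope``/``intercept`` are on the fitted scale (raw AUC vs ng, or
    log2-log2 when ``log_log``). ``lod``/``loq`` are always in ng on the
    linear scale and satisfy loq/lod = 10/3 exactly by construction.
    """

    region: Region
    slope: float
    intercept: float
    slope_se: float
    r_squared: float
    sd_blank: float
    snr: float
    lod: float
    loq: float
    log_log: bool = False
    local_baseline: bool = False

    def to_json(self, path=None) -> str:
        payload = asdict(self)
        payload["region"] = {"name": self.region.name,
                             "low": self.region.low, "high": self.region.high}
        payload["lod_ng"] = payload.pop("lod")
        payload["loq_ng"] = payload.pop("loq")
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "CalibrationCurve":
        if hasattr(source, "read"):
            payload = json.load(source)
        elif isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        region = Region(**payload.pop("region"))
        payload["lod"] = payload.pop("lod_ng")
        payload["loq"] = payload.pop("loq_ng")
        return cls(region=region, **payload)


def _linear_slope(masses: np.ndarray, aucs: np.ndarray) -> float:
    res = stats.linregress(masses, aucs)
    return float(res.slope)


def fit_calibration(
    masses_ng: Sequence[float],
    aucs: Sequence[float],
    region: Region = REGIONS["CH"],
    *,
    log_log: bool = False,
    sd_blank: float | None = None,
    local_baseline: bool = False,
) -> CalibrationCurve:
    """Ordinary least squares calibration fit with ICH LOD/LOQ and SNR.

    Blank points (mass 0) are used to estimate ``sd_blank`` (SD of blank
    AUCs, ddof=1, >=3 blanks required) unless it is supplied, and are excluded
    from the regression itself. LOD = 3*sd_blank/slope and
    LOQ = 10*sd_blank/slope are computed on the linear (non-log) scale; for a
    log-log curve the linear-scale slope comes from an auxiliary OLS on the
    raw points. SNR is the mean blank-corrected signal at the lowest non-zero
    standard divided by sd_blank (NaN when no blanks were measured).
    """
    masses = np.asarray(masses_ng, dtype=float)
    aucs = np.asarray(aucs, dtype=float)
    if masses.shape != aucs.shape:
        raise DomainError("masses and AUCs must have the same length")
    if (masses < 0).any():
        raise DomainError("negative calibration mass")

    blank_mask = masses == 0
    blanks = aucs[blank_mask]
    masses_nz, aucs_nz = masses[~blank_mask], aucs[~blank_mask]
    levels = np.unique(masses_nz)
    if levels.size < 3:
        raise InsufficientDataError(
            f"calibration needs >=3 distinct non-zero mass levels, got {levels.size}"
        )
    if sd_blank is None:
        if blanks.size < 3:
            raise InsufficientDataError(
                "sd_blank estimation needs >=3 blank (mass 0) replicates; "
                f"got {blanks.size} (or supply sd_blank explicitly)"
            )
        sd_blank = float(np.std(blanks, ddof=1))
    sd_blank = float(sd_blank)
    if sd_blank < 0:
        raise DomainError("sd_blank must be non-negative")

    if log_log:
        if (masses_nz <= 0).any() or (aucs_nz <= 0).any():
            raise DomainError("log-log calibration requires positive masses and AUCs")
        x, y = np.log2(masses_nz), np.log2(aucs_nz)
    else:
        x, y = masses_nz, aucs_nz
    res = stats.linregress(x, y)
    if res.slope <= 0:
        raise InvalidCurveError(
            f"calibration slope {res.slope:g} is not positive; no usable response"
        )
    linear_slope = _linear_slope(masses_nz, aucs_nz) if log_log else float(res.slope)
    if linear_slope <= 0:
        raise InvalidCurveError("linear-scale response slope is not positive")

    lod = 3.0 * sd_blank / linear_slope
    loq = 10.0 * sd_blank / linear_slope

    if blanks.size and sd_blank > 0:
        lowest = levels.min()
        signal = float(aucs_nz[masses_nz == lowest].mean() - blanks.mean())
        snr = signal / sd_blank
    else:
        snr = float("nan")

    return CalibrationCurve(
        region=region,
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=float(res.stderr),
        r_squared=float(res.rvalue) ** 2,
        sd_blank=sd_blank,
        snr=snr,
        lod=float(lod),
        loq=float(loq),
        log_log=log_log,
        local_baseline=local_baseline,
    )


def calibrate_from_titration(
    spectra: SpectrumSet,
    truth: pd.DataFrame,
    region: Region = REGIONS["CH"],
    *,
    log_log: bool = False,
    local_baseline: bool = False,
    sd_blank: float | None = None,
    id_column: str = "sample_id",
    mass_column: str = "mass_ng",
) -> CalibrationCurve:
    """Fit a calibration curve directly from titration spectra plus truth table."""
    mass_by_id = dict(zip(truth[id_column].astype(str), truth[mass_column].astype(float)))
    masses, aucs = [], []
    for s in spectra:
        key = s.sample_id
        if key not in mass_by_id:
            raise DomainError(f"spectrum {key!r} missing from the calibration table")
        masses.append(mass_by_id[key])
        aucs.append(region_auc(s, region, local_baseline))
    return fit_calibration(
        masses, aucs, region,
        log_log=log_log, sd_blank=sd_blank, local_baseline=local_baseline,
    )


@dataclass(frozen=True)
class QuantResult:
    """Absolute quantification of one sample against a calibration curve."""

    sample_id: str
    region: str
    auc: float
    mass_ng: float
    below_lod: bool
    below_loq: bool


def quantify(auc: float, curve: CalibrationCurve, *, sample_id: str = "") -> QuantResult:
    """Invert the calibration to an absolute mass in ng.

    For a linear curve mass = (auc - intercept)/slope; a value at or below
    the intercept yields a non-positive mass, reported as computed (flagged
    below LOD, never clipped). For a log-log curve
    mass = 2**((log2 auc - intercept)/slope), requiring auc > 0.
    """
    if curve.log_log:
        if auc <= 0:
            raise DomainError("log-log quantification requires a positive AUC")
        mass = float(2.0 ** ((math.log2(auc) - curve.intercept) / curve.slope))
    else:
        mass = float((auc - curve.intercept) / curve.slope)
    return QuantResult(
        sample_id=sample_id,
        region=curve.region.name,
        auc=float(auc),
        mass_ng=mass,
        below_lod=mass < curve.lod,
        below_loq=mass < curve.loq,
    )


def percent_error(estimate: float, truth: float) -> float:
    """Signed percent error of an estimate against a known value."""
    if truth == 0:
        raise DomainError("percent error undefined for a zero reference")
    return 100.0 * (estimate - truth) / truth


def measured_fraction(volume_measured: float, total_volume: float) -> float:
    """Fraction of the total sample consumed per acquisition (e.g. 1/12 = 0.0833)."""
    if volume_measured <= 0 or total_volume <= 0:
        raise DomainError("volumes must be positive")
    if volume_measured > total_volume:
        raise DomainError("measured volume exceeds total volume")
    return volume_measured / total_volume


class MsComparison(NamedTuple):
    pearson_r: float
    r_squared: float
    p_value: float
    slope: float
    n: int


def compare_to_ms(
    quantities: pd.DataFrame,
    ms_totals: pd.DataFrame,
    *,
    fraction_ftir: float = 1.0 / 12.0,
    fraction_ms: float = 0.06,
    quant_id: str = "sample_id",
    quant_value: str = "mass_ng",
    ms_id: str = "sample_id",
    ms_value: str = "total_intensity",
) -> MsComparison:
    """Compare FTIR quantities with MS total intensities on paired samples.

    MS totals are rescaled by fraction_ftir/fraction_ms to put both methods on
    the same measured-fraction basis before the comparison. Returns the
    Pearson r, the OLS R^2 and two-sided p-value for the slope, and the slope
    of FTIR quantity on rescaled MS intensity.
    """
    for frac, name in ((fraction_ftir, "fraction_ftir"), (fraction_ms, "fraction_ms")):
        if not 0 < frac <= 1:
            raise DomainError(f"{name} must be in (0, 1], got {frac!r}")
    merged = pd.merge(
        quantities[[quant_id, quant_value]],
        ms_totals[[ms_id, ms_value]],
        left_on=quant_id, right_on=ms_id, how="inner",
    )
    if len(merged) < 3:
        raise InsufficientDataError(
            f"need >=3 paired samples after id join, got {len(merged)}"
        )
    ftir = merged[quant_value].to_numpy(dtype=float)
    ms = merged[ms_value].to_numpy(dtype=float) * (fraction_ftir / fraction_ms)
    if np.ptp(ftir) == 0 or np.ptp(ms) == 0:
        raise DomainError("degenerate input: zero variance in one of the variables")
    r, _ = stats.pearsonr(ftir, ms)
    reg = stats.linregress(ms, ftir)
    return MsComparison(
        pearson_r=float(r),
        r_squared=float(reg.rvalue) ** 2,
        p_value=float(reg.pvalue),
        slope=float(reg.slope),
        n=len(merged),
    )
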