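"""External-calibration semi-quantitation with LOD/LOQ censoring.

River-water concentrations are estimated against an external calibration
curve of the parent drug (standards 1-750 ng/L, ordinary least squares on
peak area).  Samples are enriched by solid-phase extraction before injection
- 500 mL of water reconstituted into 500 uL of extract, a 1000x volumetric
enrichment - so back-calculated extract concentrations are divided by the
enrichment factor, and optionally by the per-analyte SPE recovery fraction.

Detection and quantitation limits follow the calibration-based convention
LOD = 3.3 * s_res / slope and LOQ = 10 * s_res / slope, with the option of
fixed overrides when experimentally determined limits are to be applied.
Parent-drug concentrations below the LOQ are censored and reported "n.d.";
transformation products, quantified against the parent's curve under the
assumption of similar ionization efficiency, are reported as uncensored
semi-quantitative estimates (their published values sit below the parent's
LOQ by construction) and flagged accordingly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CalibrationCurve",
    "SamplePrepFactors",
    "QuantResult",
    "fit_calibration",
    "quantify",
    "quantify_tp",
]


@dataclass
class CalibrationCurve:
    """Ordinary least-squares external calibration: area = slope*c + intercept."""

    levels: np.ndarray  # ng/L in the injected standard
    responses: np.ndarray  # peak areas
    slope: float
    intercept: float
    residual_sd: float
    r_squared: float
    lod: float  # ng/L
    loq: float  # ng/L

    def concentration(self, area: float) -> float:
        """Back-calculated concentration in the injected extract (ng/L)."""
        return (area - self.intercept) / self.slope


@dataclass(frozen=True)
class SamplePrepFactors:
    """SPE enrichment and recovery bookkeeping.

    The enrichment factor defaults to the volumetric ratio
    loaded_volume / reconstitution_volume.  Recovery correction (dividing by
    the recovery fraction) is opt-in.
    """

    loaded_volume_ml: float = 500.0
    reconstitution_volume_ul: float = 500.0
    recovery: float = 1.0
    apply_recovery: bool = False
    enrichment_override: float | None = None

    def __post_init__(self) -> None:
        if self.loaded_volume_ml <= 0 or self.reconstitution_volume_ul <= 0:
            raise ValueError("volumes must be positive")
        if not 0 < self.recovery <= 1:
            raise ValueError("recovery must be in (0, 1]")

    @property
    def enrichment(self) -> float:
        if self.enrichment_override is not None:
            return self.enrichment_override
        return self.loaded_volume_ml * 1000.0 / self.reconstitution_volume_ul


@dataclass(frozen=True)
class QuantResult:
    """A censored concentration for one analyte in one sample."""

    analyte: str
    concentration_ng_l: float
    censored: bool
    loq_ng_l: float
    site: str = ""
    month: str = ""
    semi_quantitative: bool = False

    @property
    def display(self) -> str:
        return "n.d." if self.censored else f"{self.concentration_ng_l:.2f}"


def fit_calibration(
    levels: np.ndarray,
    responses: np.ndarray,
    lod_override: float | None = None,
    loq_override: float | None = None,
) -> CalibrationCurve:
    """Fit the external calibration line and derive LOD/LOQ.

    Requires at least five distinct standard levels.  LOD and LOQ use the
    3.3/10 x residual-SD over slope convention unless overrides (e.g.
    experimentally determined limits) are supplied.
    """
    levels = np.asarray(levels, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if np.unique(levels).size < 5:
        raise ValueError("need at least 5 distinct calibration levels")
    design = np.column_stack([levels, np.ones_like(levels)])
    (slope, intercept), *_ = np.linalg.lstsq(design, responses, rcond=None)
    if slope <= 0:
        raise ValueError("calibration slope must be positive")
    resid = responses - (slope * levels + intercept)
    dof = max(levels.size - 2, 1)
    s_res = float(np.sqrt(np.sum(resid**2) / dof))
    ss_tot = float(np.sum((responses - responses.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    lod = 3.3 * s_res / slope if lod_override is None else lod_override
    loq = 10.0 * s_res / slope if loq_override is None else loq_override
    return CalibrationCurve(
        levels=levels,
        responses=responses,
        slope=float(slope),
        intercept=float(intercept),
        residual_sd=s_res,
        r_squared=r2,
        lod=lod,
        loq=loq,
    )


def _back_calculate(
    area: float, curve: CalibrationCurve, prep: SamplePrepFactors
) -> float:
    c_extract = curve.concentration(area)
    c_sample = c_extract / prep.enrichment
    if prep.apply_recovery:
        c_sample /= prep.recovery
    if c_sample < 0:
        warnings.warn("negative back-calculated concentration; reporting 0",
                      stacklevel=3)
        c_sample = 0.0
    return c_sample


def quantify(
    area: float,
    curve: CalibrationCurve,
    prep: SamplePrepFactors,
    analyte: str = "",
    site: str = "",
    month: str = "",
) -> QuantResult:
    """Quantify a parent analyte, censoring below the LOQ as "n.d."."""
    c = _back_calculate(area, curve, prep)
    return QuantResult(
        analyte=analyte,
        concentration_ng_l=c,
        censored=c < curve.loq,
        loq_ng_l=curve.loq,
        site=site,
        month=month,
    )


def quantify_tp(
    area: float,
    parent_curve: CalibrationCurve,
    prep: SamplePrepFactors,
    analyte: str = "",
    site: str = "",
    month: str = "",
    tp_loq: float = 0.005,
) -> QuantResult:
    """Semi-quantify a TP against the parent's calibration curve.

    Identical arithmetic to :func:`quantify` under the assumption that the
    TP ionizes like its parent.  The parent's LOQ is not applied (reported
    TP levels sit below it); a TP is censored only when its estimate does
    not exceed ``tp_loq``, which defaults to half the last reported digit
    (0.005 ng/L) so that genuine non-detections never surface as spurious
    sub-picogram figures.  Results are flagged ``semi_quantitative``.
    """
    c = _back_calculate(area, parent_curve, prep)
    return QuantResult(
        analyte=analyte,
        concentration_ng_l=c,
        censored=c <= tp_loq,
        loq_ng_l=tp_loq,
        site=site,
        month=month,
        semi_quantitative=True,
    )
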