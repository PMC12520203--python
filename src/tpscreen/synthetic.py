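"""Deterministic generators for every input the pipeline consumes.

Nothing in this package can see a mass spectrometer, so the study conditions
are emulated: TiO2-photocatalysis LC-MS runs over the sampling grid
{0, 5, 10, 15, 30, 60, 120} min containing the parent drug and its registry
TPs, tandem spectra transcribed from the reference fragmentation tables, an
external calibration series, and a river-sample batch with the published
site x month concentration structure.

Design contract: a scenario plus a seed is byte-reproducible.  All random
draws (per-species ppm offsets, multiplicative intensity noise, calibration
noise) flow from one seeded generator per scenario.  Every generated signal's
true provenance (m/z, retention time, kinetic parameters, concentration) is
recorded in a ground-truth ledger so tests can compare pipeline output with
the truth without ever letting the pipeline itself peek at it.

What is emulated and what is not: chromatographic peaks are Gaussian with a
fixed width, ionization physics and matrix effects are absent, "not
detected" river cells are true zeros, and isotopologues are emitted at unit
mass-shift bins (M+2, M+4) only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .formula import (
    CL37_CL35_SHIFT,
    ElementalComposition,
    IonSpecies,
    ion_mz,
    parse_formula,
    isotope_pattern,
)
from .kinetics import KINETIC_PRESETS, TIME_GRID_MIN
from .spectra import CentroidPeak, LcMsRun, MsnSpectrum
from .transformations import (
    PARENT_FORMULA,
    PROTON,
    load_registry,
    _read_tsv,
)

__all__ = [
    "PhotocatalysisScenario",
    "RiverBatchScenario",
    "SpectrumTemplate",
    "load_msn_template",
    "generate_msn_spectra",
    "generate_photocatalysis_dataset",
    "generate_river_batch",
    "TABLE3_TRUTH",
    "SITES",
    "MONTHS",
]

PARENT_RT_MIN = {"haloperidol": 21.35, "aripiprazole": 25.46}

#: Published experimental limits (ng/L), applied as censoring overrides.
LOD_NG_L = {"haloperidol": 0.40, "aripiprazole": 4.5}
LOQ_NG_L = {"haloperidol": 1.0, "aripiprazole": 10.0}

#: SPE recovery fractions per analyte.
RECOVERY = {"haloperidol": 0.77, "aripiprazole": 0.45}

SITES = (
    "Po River, Torino",
    "Sangone River, Moncalieri",
    "Sangone River, Forno di Coazze",
)
MONTHS = ("June", "July", "August")

#: River-batch ground truth (ng/L); zeros are genuine absences.
TABLE3_TRUTH: dict[str, dict[tuple[str, str], float]] = {
    "haloperidol": {
        ("June", SITES[0]): 0.0, ("June", SITES[1]): 0.0, ("June", SITES[2]): 0.0,
        ("July", SITES[0]): 0.0, ("July", SITES[1]): 3.0, ("July", SITES[2]): 27.0,
        ("August", SITES[0]): 25.0, ("August", SITES[1]): 7.0, ("August", SITES[2]): 8.0,
    },
    "aripiprazole": {
        ("June", SITES[0]): 0.0, ("June", SITES[1]): 0.0, ("June", SITES[2]): 0.0,
        ("July", SITES[0]): 0.0, ("July", SITES[1]): 67.0, ("July", SITES[2]): 29.0,
        ("August", SITES[0]): 28.0, ("August", SITES[1]): 0.0, ("August", SITES[2]): 34.0,
    },
    "TP314-F": {("August", SITES[0]): 0.16},
    "TP388-B": {("August", SITES[0]): 0.25},
    "TP392-D": {("August", SITES[0]): 0.47},
}

#: Parent drug whose calibration curve quantifies each analyte.
QUANT_PARENT = {
    "haloperidol": "haloperidol",
    "aripiprazole": "aripiprazole",
    "TP314-F": "haloperidol",
    "TP388-B": "haloperidol",
    "TP392-D": "haloperidol",
}


# ---------------------------------------------------------------------------
# MSn spectrum templates (reference fragmentation tables)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TemplateRow:
    ms_level: int
    precursor: ElementalComposition
    fragment: ElementalComposition
    observed_mz: float
    abundance_pct: float
    loss: ElementalComposition
    printed_dppm: float
    printed_loss: str
    radical: bool


@dataclass
class SpectrumTemplate:
    """Transcribed MSn reference rows for one precursor drug."""

    name: str
    precursor_formula: ElementalComposition  # [M+H]+ cation formula
    precursor_observed_mz: float
    rows: list[TemplateRow]

    def validate_loss_closure(self) -> None:
        """Every row must satisfy fragment + loss = precursor exactly."""
        for row in self.rows:
            if row.fragment + row.loss != row.precursor:
                raise ValueError(
                    f"loss closure violated for fragment {row.fragment.hill()} "
                    f"of {row.precursor.hill()}"
                )

    def ms2_rows(self) -> list[TemplateRow]:
        return [r for r in self.rows if r.ms_level == 2]

    def ms3_rows(self) -> list[TemplateRow]:
        return [r for r in self.rows if r.ms_level == 3]


def load_msn_template(drug: str) -> SpectrumTemplate:
    """Load the transcribed MSn table for a drug preset."""
    rows = []
    precursor_formula = None
    precursor_mz = None
    for raw in _read_tsv(f"msn_{drug}.tsv"):
        level = int(raw["ms_level"])
        if level == 1:
            precursor_formula = parse_formula(raw["fragment_formula"])
            precursor_mz = float(raw["observed_mz"])
            continue
        rows.append(
            TemplateRow(
                ms_level=level,
                precursor=parse_formula(raw["precursor_formula"]),
                fragment=parse_formula(raw["fragment_formula"]),
                observed_mz=float(raw["observed_mz"]),
                abundance_pct=float(raw["abundance_pct"]),
                loss=parse_formula(raw["loss_formula"]),
                printed_dppm=float(raw["printed_dppm"]),
                printed_loss=raw["printed_loss"],
                radical=raw["radical"] == "1",
            )
        )
    if precursor_formula is None:
        raise ValueError(f"no precursor row in MSn table for {drug!r}")
    template = SpectrumTemplate(
        name=drug,
        precursor_formula=precursor_formula,
        precursor_observed_mz=precursor_mz,
        rows=rows,
    )
    template.validate_loss_closure()
    return template


def generate_msn_spectra(
    template: SpectrumTemplate,
    ppm_offset: float = 0.0,
    rt_min: float = 0.0,
    scan_prefix: str = "tmpl",
) -> list[MsnSpectrum]:
    """Emit MS2 and MS3 spectra with fragments at theoretical m/z + offset.

    Fragment peaks carry the transcribed relative abundances (base peak 100).
    MS3 spectra are grouped by their MS2 precursor fragment; the precursor
    path records the (offset) m/z chain.
    """
    template.validate_loss_closure()
    shift = 1.0 + ppm_offset * 1e-6
    root_mz = ion_mz(IonSpecies(template.precursor_formula)) * shift
    spectra = []
    ms2_peaks = []
    ms2_mz_by_formula: dict[ElementalComposition, float] = {}
    for row in template.ms2_rows():
        mz = ion_mz(IonSpecies(row.fragment)) * shift
        ms2_peaks.append(CentroidPeak(mz, row.abundance_pct))
        ms2_mz_by_formula[row.fragment] = mz
    spectra.append(
        MsnSpectrum(
            scan_id=f"{scan_prefix}_ms2",
            ms_level=2,
            rt_min=rt_min,
            precursor_path=(root_mz,),
            peaks=ms2_peaks,
        )
    )
    ms3_groups: dict[ElementalComposition, list[TemplateRow]] = {}
    for row in template.ms3_rows():
        ms3_groups.setdefault(row.precursor, []).append(row)
    for i, (prec_formula, rows) in enumerate(sorted(
        ms3_groups.items(), key=lambda kv: kv[0].hill()
    )):
        prec_mz = ms2_mz_by_formula.get(
            prec_formula, ion_mz(IonSpecies(prec_formula)) * shift
        )
        spectra.append(
            MsnSpectrum(
                scan_id=f"{scan_prefix}_ms3_{i}",
                ms_level=3,
                rt_min=rt_min,
                precursor_path=(root_mz, prec_mz),
                peaks=[
                    CentroidPeak(ion_mz(IonSpecies(r.fragment)) * shift, r.abundance_pct)
                    for r in rows
                ],
            )
        )
    return spectra


# ---------------------------------------------------------------------------
# Photocatalysis LC-MS time series
# ---------------------------------------------------------------------------

@dataclass
class PhotocatalysisScenario:
    """Study conditions for one simulated photocatalysis experiment."""

    drug: str = "haloperidol"
    seed: int = 42
    noise_sigma: float = 0.0  # multiplicative intensity noise
    max_ppm_offset: float = 5.0  # per-species fixed offset drawn once
    emit_isotopes: bool = True
    time_grid: tuple[float, ...] = TIME_GRID_MIN
    rt_step_min: float = 0.05
    peak_sigma_min: float = 0.05  # chromatographic Gaussian width
    parent_intensity: float = 1.0e6
    tp_intensity: float = 1.0e5

    def __post_init__(self) -> None:
        if self.drug not in PARENT_FORMULA:
            raise ValueError(f"unknown drug preset {self.drug!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")


@dataclass(frozen=True)
class _Species:
    """Internal: one chromatographic species to emit."""

    name: str
    isomer: str
    cation: ElementalComposition
    rt: float
    base_intensity: float
    t_max: float | None  # None = parent (first-order decay)
    ppm_offset: float = 0.0

    @property
    def theoretical_mz(self) -> float:
        return ion_mz(IonSpecies(self.cation))

    @property
    def observed_mz(self) -> float:
        return self.theoretical_mz * (1.0 + self.ppm_offset * 1e-6)


def _bateman(t: np.ndarray | float, t_max: float) -> np.ndarray | float:
    """Rise-and-fall profile normalized to 1 at its maximum ``t_max``.

    Two-compartment (formation/decay) shape with a fixed 5:1 rate ratio,
    parameterized directly by the time of maximum.
    """
    kd = math.log(5.0) / (4.0 * t_max)
    kf = 5.0 * kd
    t = np.asarray(t, dtype=float)
    raw = np.exp(-kd * t) - np.exp(-kf * t)
    peak = math.exp(-kd * t_max) - math.exp(-kf * t_max)
    return raw / peak


def _slow_isomer(drug: str, name: str, letter: str) -> bool:
    """TP_ha_314 isomers A and C peak only after 60 min."""
    return drug == "haloperidol" and name == "TP_ha_314" and letter in ("A", "C")


def _build_species(
    scenario: PhotocatalysisScenario, rng: np.random.Generator
) -> list[_Species]:
    drug = scenario.drug
    registry = load_registry(drug)
    parent_cation = parse_formula(PARENT_FORMULA[drug]) + PROTON
    species = [
        _Species(
            name=drug,
            isomer="A",
            cation=parent_cation,
            rt=PARENT_RT_MIN[drug],
            base_intensity=scenario.parent_intensity,
            t_max=None,
            ppm_offset=float(rng.uniform(-scenario.max_ppm_offset,
                                         scenario.max_ppm_offset)),
        )
    ]
    ordered = sorted(registry, key=lambda e: e.theoretical_mz)
    for idx, entry in enumerate(ordered):
        base_rt = 12.5 + 0.5 * idx
        offset = float(rng.uniform(-scenario.max_ppm_offset,
                                   scenario.max_ppm_offset))
        prev_rt = None
        for i, (letter, printed_rt) in enumerate(entry.isomers):
            if printed_rt is not None:
                rt = printed_rt
            elif prev_rt is None:
                rt = base_rt
            elif entry.name == "TP_ha_392" and letter == "B":
                # resolved minor shoulder 0.2 min after isomer A
                rt = prev_rt + 0.2
            else:
                rt = prev_rt + 0.35
            prev_rt = rt
            amp = scenario.tp_intensity * (0.9**i)
            if entry.name == "TP_ha_392" and letter == "B":
                amp = 0.25 * scenario.tp_intensity
            t_max = 60.0 if _slow_isomer(drug, entry.name, letter) else 10.0
            species.append(
                _Species(
                    name=entry.name,
                    isomer=letter,
                    cation=entry.cation_formula,
                    rt=rt,
                    base_intensity=amp,
                    t_max=t_max,
                    ppm_offset=offset,
                )
            )
    return species


def _kinetic_value(sp: _Species, t: float, k_parent: float) -> float:
    if sp.t_max is None:
        return math.exp(-k_parent * t)
    return float(_bateman(t, sp.t_max))


def generate_photocatalysis_dataset(
    scenario: PhotocatalysisScenario,
) -> tuple[dict[float, LcMsRun], pd.DataFrame]:
    """Simulate one LC-MS run per photocatalysis time point plus the ledger.

    MS1 scans cover the retention window of all species on a regular grid;
    each species contributes a Gaussian elution profile scaled by its kinetic
    archetype (first-order decay for the parent, rise-and-fall with the
    configured time of maximum for TPs).  Chlorinated species also emit M+2
    and M+4 isotopologue centroids.  MS2 (and, for the parent, MS3) spectra
    are attached to the 10-minute run at each species' retention time.

    Returns ``(runs_by_time, ledger)``; the ledger records the true m/z,
    ppm offset, retention time, intensity and kinetic parameters per species.
    """
    rng = np.random.default_rng(scenario.seed)
    species = _build_species(scenario, rng)
    k_parent = KINETIC_PRESETS[scenario.drug]
    sigma = scenario.peak_sigma_min
    rts = [sp.rt for sp in species]
    grid = np.arange(min(rts) - 1.0, max(rts) + 1.0 + 1e-9, scenario.rt_step_min)

    # isotopologue emission ratios per distinct cation formula
    iso_ratios: dict[ElementalComposition, list[tuple[float, float]]] = {}
    if scenario.emit_isotopes:
        for sp in species:
            if sp.cation in iso_ratios:
                continue
            pattern = isotope_pattern(IonSpecies(sp.cation), n_isotopologues=5)
            ratios = []
            for shift, rel in pattern:
                if shift in (2, 4) and rel >= 0.005:
                    ratios.append((shift / 2 * CL37_CL35_SHIFT, rel))
            iso_ratios[sp.cation] = ratios

    template = load_msn_template(scenario.drug)
    runs: dict[float, LcMsRun] = {}
    ledger_rows = []
    for t in scenario.time_grid:
        spectra: list[MsnSpectrum] = []
        amps = {
            id(sp): sp.base_intensity * _kinetic_value(sp, t, k_parent)
            for sp in species
        }
        for scan_idx, rt in enumerate(grid):
            peaks = []
            for sp in species:
                amp = amps[id(sp)]
                if amp <= 0:
                    continue
                c = amp * math.exp(-((rt - sp.rt) ** 2) / (2 * sigma**2))
                if c < amp * 1e-4 or c <= 0:
                    continue
                if scenario.noise_sigma > 0:
                    c *= max(0.0, 1.0 + scenario.noise_sigma * rng.standard_normal())
                peaks.append(CentroidPeak(sp.observed_mz, c))
                for dmz, rel in iso_ratios.get(sp.cation, ()):
                    peaks.append(CentroidPeak(sp.observed_mz + dmz, c * rel))
            peaks.sort(key=lambda p: p.mz)
            spectra.append(
                MsnSpectrum(
                    scan_id=f"t{t:g}_ms1_{scan_idx}",
                    ms_level=1,
                    rt_min=float(rt),
                    peaks=peaks,
                )
            )
        if t == 10.0:
            spectra.extend(_msn_spectra_at_10min(scenario, species, template))
        spectra.sort(key=lambda s: (s.rt_min, s.ms_level, s.scan_id))
        runs[t] = LcMsRun(label=f"{scenario.drug}_t{t:g}min", spectra=spectra)

    removal_120 = 100.0 * (1.0 - math.exp(-k_parent * 120.0))
    for sp in species:
        ledger_rows.append(
            {
                "species": sp.name,
                "isomer": sp.isomer,
                "cation_formula": sp.cation.hill(),
                "mz_theoretical": sp.theoretical_mz,
                "ppm_offset": sp.ppm_offset,
                "mz_observed": sp.observed_mz,
                "rt_min": sp.rt,
                "base_intensity": sp.base_intensity,
                "t_max_min": np.nan if sp.t_max is None else sp.t_max,
                "k_per_min": k_parent if sp.t_max is None else np.nan,
                "removal_120_pct": removal_120 if sp.t_max is None else np.nan,
            }
        )
    return runs, pd.DataFrame(ledger_rows)


def _msn_spectra_at_10min(
    scenario: PhotocatalysisScenario,
    species: list[_Species],
    template: SpectrumTemplate,
) -> list[MsnSpectrum]:
    """Tandem spectra for the 10-minute run: templates for the parent,
    a small-neutral-loss MS2 for every TP isomer."""
    # generic diagnostic losses, tried in order: water, then HCl for
    # oxygen-free chlorinated cations
    losses = [parse_formula("H2O"), parse_formula("HCl")]
    spectra = []
    for sp in species:
        if sp.t_max is None:  # parent: full transcribed MSn set
            shift_ppm = sp.ppm_offset
            spectra.extend(
                generate_msn_spectra(
                    template,
                    ppm_offset=shift_ppm,
                    rt_min=sp.rt,
                    scan_prefix=f"{sp.name}_{sp.isomer}",
                )
            )
            continue
        loss = next((l for l in losses if sp.cation.contains(l)), None)
        if loss is None:
            continue
        frag = sp.cation - loss
        shift = 1.0 + sp.ppm_offset * 1e-6
        spectra.append(
            MsnSpectrum(
                scan_id=f"{sp.name}_{sp.isomer}_ms2",
                ms_level=2,
                rt_min=sp.rt,
                precursor_path=(sp.observed_mz,),
                peaks=[
                    CentroidPeak(ion_mz(IonSpecies(frag)) * shift, 100.0),
                    CentroidPeak(sp.observed_mz, 20.0),
                ],
            )
        )
    return spectra


# ---------------------------------------------------------------------------
# River batch + calibration
# ---------------------------------------------------------------------------

@dataclass
class RiverBatchScenario:
    """Study conditions for the river-sample semi-quantitation batch."""

    seed: int = 42
    noise_sigma_area: float = 0.0  # additive area noise, in slope units (ng/L)
    levels_ng_l: tuple[float, ...] = (1.0, 2.5, 5.0, 10.0, 25.0, 50.0, 100.0,
                                      250.0, 500.0, 750.0)
    truth: Mapping[str, Mapping[tuple[str, str], float]] = field(
        default_factory=lambda: TABLE3_TRUTH
    )
    model_recovery: bool = False
    enrichment: float = 1000.0
    #: instrument response (area per ng/L in the extract) and baseline
    slope: Mapping[str, float] = field(
        default_factory=lambda: {"haloperidol": 120.0, "aripiprazole": 85.0}
    )
    intercept: Mapping[str, float] = field(
        default_factory=lambda: {"haloperidol": 50.0, "aripiprazole": 30.0}
    )


def generate_river_batch(
    scenario: RiverBatchScenario,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Simulate the calibration series and the river-sample areas.

    Returns ``(calibrations, batch, truth)``:

    * ``calibrations`` maps each parent drug to a (level_ng_l, area) table of
      standards measured directly (no SPE).
    * ``batch`` has one row per (site, month, analyte) with the measured
      area after the SPE enrichment; TP rows are generated through the
      parent drug's response, mirroring the like-parent ionization
      assumption.
    * ``truth`` is the ground-truth concentration ledger.
    """
    rng = np.random.default_rng(scenario.seed)
    calibrations = {}
    for drug in ("haloperidol", "aripiprazole"):
        levels = np.array(scenario.levels_ng_l)
        areas = scenario.slope[drug] * levels + scenario.intercept[drug]
        if scenario.noise_sigma_area > 0:
            areas = areas + scenario.slope[drug] * scenario.noise_sigma_area * (
                rng.standard_normal(levels.size)
            )
        calibrations[drug] = pd.DataFrame(
            {"level_ng_l": levels, "area": areas}
        )
    batch_rows = []
    truth_rows = []
    for analyte, grid in scenario.truth.items():
        parent = QUANT_PARENT[analyte]
        recovery = RECOVERY[parent] if scenario.model_recovery else 1.0
        for month in MONTHS:
            for site in SITES:
                c_sample = float(grid.get((month, site), 0.0))
                c_extract = c_sample * scenario.enrichment * recovery
                area = (
                    scenario.slope[parent] * c_extract
                    + scenario.intercept[parent]
                )
                if scenario.noise_sigma_area > 0:
                    area += (
                        scenario.slope[parent]
                        * scenario.noise_sigma_area
                        * float(rng.standard_normal())
                    )
                batch_rows.append(
                    {
                        "site": site,
                        "month": month,
                        "analyte": analyte,
                        "parent": parent,
                        "area": area,
                    }
                )
                truth_rows.append(
                    {
                        "site": site,
                        "month": month,
                        "analyte": analyte,
                        "true_ng_l": c_sample,
                    }
                )
    return calibrations, pd.DataFrame(batch_rows), pd.DataFrame(truth_rows)
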