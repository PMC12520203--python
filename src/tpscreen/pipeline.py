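"""End-to-end orchestration: simulate -> screen -> annotate -> quantify.

These functions tie the stage modules together exactly the way the
command-line interface exposes them, and are what the acceptance checks and
worked examples call.  They contain no science of their own.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import pandas as pd
import yaml

from .annotation import AnnotatedTP, screen_suspects
from .formula import parse_formula
from .kinetics import TIME_GRID_MIN
from .semiquant import SamplePrepFactors, fit_calibration, quantify, quantify_tp
from .spectra import LcMsRun
from .synthetic import (
    LOD_NG_L,
    LOQ_NG_L,
    MONTHS,
    RECOVERY,
    SITES,
    PhotocatalysisScenario,
    RiverBatchScenario,
    generate_photocatalysis_dataset,
    generate_river_batch,
)
from .transformations import (
    PARENT_FORMULA,
    load_registry,
    load_rules,
    registry_reachability,
)

__all__ = [
    "PipelineConfig",
    "screen_scenario",
    "screening_report",
    "quantify_batch",
    "render_concentration_table",
]


@dataclass
class PipelineConfig:
    """Validated tolerances and defaults for the whole workflow."""

    screen_tol_ppm: float = 50.0
    fragment_tol_ppm: float = 10.0
    detection_threshold: float = 0.0
    noise_multiple: float = 3.0
    rule_depth: int = 4
    rt_cluster_min: float = 0.1
    time_grid: tuple[float, ...] = TIME_GRID_MIN
    apply_recovery: bool = False
    enrichment_override: float | None = None
    seed: int = 42

    def __post_init__(self) -> None:
        if self.screen_tol_ppm <= 0 or self.fragment_tol_ppm <= 0:
            raise ValueError("tolerances must be positive")
        if self.rule_depth < 0:
            raise ValueError("rule depth must be >= 0")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "time_grid" in data:
            data["time_grid"] = tuple(data["time_grid"])
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def screen_scenario(
    scenario: PhotocatalysisScenario,
    config: PipelineConfig | None = None,
) -> tuple[list[AnnotatedTP], pd.DataFrame, dict]:
    """Simulate a photocatalysis dataset and screen it for registry TPs.

    Returns ``(detections, ledger, coverage)`` where ``coverage`` is the
    rule-reachability report for the registry used.
    """
    config = config or PipelineConfig()
    runs, ledger = generate_photocatalysis_dataset(scenario)
    detections, coverage = screen_runs(list(runs.values()), scenario.drug, config)
    return detections, ledger, coverage


def screen_runs(
    runs: list[LcMsRun],
    drug: str,
    config: PipelineConfig | None = None,
) -> tuple[list[AnnotatedTP], dict]:
    """Enumerate candidates, check registry coverage, and screen the runs."""
    config = config or PipelineConfig()
    registry = load_registry(drug)
    rules = load_rules(drug)
    parent = parse_formula(PARENT_FORMULA[drug])
    coverage = registry_reachability(registry, parent, rules, config.rule_depth)
    detections = screen_suspects(
        runs,
        registry,
        screen_tol_ppm=config.screen_tol_ppm,
        frag_tol_ppm=config.fragment_tol_ppm,
        detection_threshold=config.detection_threshold,
        noise_multiple=config.noise_multiple,
        rt_cluster_min=config.rt_cluster_min,
    )
    return detections, coverage


def screening_report(detections: list[AnnotatedTP]) -> pd.DataFrame:
    """Flat per-isomer report mirroring the reference-table column layout."""
    rows = []
    for tp in detections:
        for iso in tp.isomers:
            rows.append(
                {
                    "name": tp.name,
                    "isomer": iso.letter,
                    "cation_formula": tp.cation_formula.hill(),
                    "mz_theoretical": round(tp.theoretical_mz, 4),
                    "rt_min": round(iso.rt, 2),
                    "apex_intensity": iso.apex_intensity,
                    "area": iso.area,
                    "category": tp.category,
                    "cl_count": tp.cl_count,
                    "confidence_level": tp.confidence_level,
                    "n_fragments_assigned": len(tp.ms2_evidence),
                }
            )
    return pd.DataFrame(rows)


def quantify_batch(
    calibrations: dict[str, pd.DataFrame],
    batch: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Fit per-parent calibration curves and quantify every batch row.

    Parent analytes are censored at their (override) LOQ; TPs are
    semi-quantified through the parent curve without the parent LOQ censor.
    """
    config = config or PipelineConfig()
    curves = {
        drug: fit_calibration(
            df["level_ng_l"].to_numpy(),
            df["area"].to_numpy(),
            lod_override=LOD_NG_L.get(drug),
            loq_override=LOQ_NG_L.get(drug),
        )
        for drug, df in calibrations.items()
    }
    rows = []
    for rec in batch.itertuples(index=False):
        parent = rec.parent
        prep = SamplePrepFactors(
            recovery=RECOVERY.get(parent, 1.0),
            apply_recovery=config.apply_recovery,
            enrichment_override=config.enrichment_override,
        )
        if rec.analyte == parent:
            result = quantify(
                rec.area, curves[parent], prep,
                analyte=rec.analyte, site=rec.site, month=rec.month,
            )
        else:
            result = quantify_tp(
                rec.area, curves[parent], prep,
                analyte=rec.analyte, site=rec.site, month=rec.month,
            )
        rows.append(
            {
                "analyte": result.analyte,
                "site": result.site,
                "month": result.month,
                "concentration_ng_l": result.concentration_ng_l,
                "censored": result.censored,
                "display": result.display,
                "semi_quantitative": result.semi_quantitative,
            }
        )
    return pd.DataFrame(rows)


def render_concentration_table(quant: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long quantitation table into the analyte x site-month grid."""
    table = quant.pivot_table(
        index="analyte",
        columns=["month", "site"],
        values="display",
        aggfunc="first",
    )
    ordered_cols = [
        (m, s) for m in MONTHS for s in SITES if (m, s) in table.columns
    ]
    return table.loc[:, ordered_cols]
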