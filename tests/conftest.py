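"""Shared fixtures: everything is generated programmatically at test time."""

from __future__ import annotations

import pytest

from tpscreen.pipeline import PipelineConfig, screen_scenario
from tpscreen.synthetic import (
    PhotocatalysisScenario,
    RiverBatchScenario,
    generate_river_batch,
    load_msn_template,
)


@pytest.fixture(scope="session")
def haloperidol_template():
    return load_msn_template("haloperidol")


@pytest.fixture(scope="session")
def aripiprazole_template():
    return load_msn_template("aripiprazole")


@pytest.fixture(scope="session")
def haloperidol_screening():
    """Full enumerate -> simulate -> screen run for the haloperidol scenario."""
    detections, ledger, coverage = screen_scenario(
        PhotocatalysisScenario(drug="haloperidol", seed=42)
    )
    return detections, ledger, coverage


@pytest.fixture(scope="session")
def aripiprazole_screening():
    detections, ledger, coverage = screen_scenario(
        PhotocatalysisScenario(drug="aripiprazole", seed=42)
    )
    return detections, ledger, coverage


@pytest.fixture(scope="session")
def river_batch():
    """Noiseless river-sample batch plus calibration standards."""
    return generate_river_batch(RiverBatchScenario(seed=42))
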