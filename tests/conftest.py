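from __future__ import annotations

import warnings

import pytest

from netpharm.models import CompoundRecord, Prescription
from netpharm.pipeline import PipelineConfig, run_all
from netpharm.synthetic import gen_bundle


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # zero-variance herb rows are routine in small prescription sets
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="zero-variance herb row")
        yield


@pytest.fixture
def toy_prescriptions() -> list[Prescription]:
    return [
        Prescription("P1", frozenset({"A", "B"})),
        Prescription("P2", frozenset({"B", "C"})),
    ]


@pytest.fixture
def toy_compounds() -> list[CompoundRecord]:
    return [
        CompoundRecord("c-eh", 11, 300.0, 45.0, 0.3, frozenset({"EH"})),
        CompoundRecord("c-cs", 12, 310.0, 50.0, 0.4, frozenset({"CS"})),
        CompoundRecord("c-shared", 13, 320.0, 40.0, 0.25, frozenset({"EH", "CS"})),
        CompoundRecord("c-fail", 14, 330.0, 10.0, 0.05, frozenset({"EH"})),
    ]


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One default synthetic input bundle plus its pipeline run report."""
    outdir = tmp_path_factory.mktemp("bundle")
    paths, truth = gen_bundle(outdir, seed=11)
    config = PipelineConfig.from_yaml(paths["config"])
    report = run_all(config)
    return {"paths": paths, "truth": truth, "config": config, "report": report}
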