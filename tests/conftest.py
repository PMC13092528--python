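"""Shared fixtures: small synthetic registries generated at test time."""

import pytest

from msprogrisk import SimConfig, generate_registry, apply_inclusion_criteria


@pytest.fixture(scope="session")
def small_registry():
    """400-patient registry with default (cohort-emulating) settings."""
    records, truth = generate_registry(SimConfig(n_patients=400, seed=42))
    return records, truth


@pytest.fixture(scope="session")
def included_records(small_registry):
    records, _ = small_registry
    report = apply_inclusion_criteria(records, mode="base")
    return [r for r in records if r.patient_id in report.included_ids]
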