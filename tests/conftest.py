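from datetime import date, timedelta

import numpy as np
import pytest

from pji_cea.records import (
    OperationEvent,
    PatientRecord,
    TreatmentMethod,
    classify_operation,
)
from pji_cea.synthetic import CohortConfig, generate_cohort

# short aliases for toy operation sequences
OP_A = "Debridement + spacer installation"
OP_B = "Endoprosthesis (EP) installation + spacer removal"
OP_C = "Debridement"


def make_record(
    op_labels,
    outcome="Success",
    method=TreatmentMethod.RA,
    pid="P1",
    costs=None,
    utilities=None,
    months_between=2,
    censor_months=24,
):
    """Build a valid record whose operation sequence is ``op_labels`` and
    whose terminal outcome label is ``outcome``."""
    manifest = date(2016, 1, 1)
    ops = []
    for i, label in enumerate(op_labels):
        d = manifest + timedelta(days=30 * months_between * i + 15)
        cost = costs[i] if costs else 50_000.0
        ops.append(OperationEvent(d, classify_operation(label), cost))
    death = None
    status = "NO_PJI"
    if outcome == "Failure":
        status = "PJI_PRESENT"
    elif outcome == "Death":
        status = "PJI_PRESENT"
        death = manifest + timedelta(days=30 * censor_months)
    return PatientRecord(
        id=pid,
        birthdate=date(1950, 6, 1),
        sex="M",
        method=method,
        manifestation_date=manifest,
        operations=tuple(ops),
        last_status=status,
        death_date=death,
        censor_date=manifest + timedelta(days=30 * censor_months),
        utility_increments=tuple(utilities) if utilities else None,
    )


@pytest.fixture
def toy_tree_records():
    """Three RA patients: sequences [A,B], [A,C], [A,B] with outcomes
    Success, Success, Failure (the hand-countable prefix example)."""
    return [
        make_record([OP_A, OP_B], "Success", pid="P1", costs=[100_000.0, 120_000.0]),
        make_record([OP_A, OP_C], "Success", pid="P2", costs=[90_000.0, 30_000.0]),
        make_record([OP_A, OP_B], "Failure", pid="P3", costs=[110_000.0, 140_000.0]),
    ]


@pytest.fixture(scope="session")
def default_cohort():
    """The default 600-patient synthetic cohort (seed 1), shared read-only."""
    return generate_cohort(CohortConfig(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
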