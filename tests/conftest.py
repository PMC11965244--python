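import numpy as np
import pandas as pd
import pytest

from flankerlab import design, simulate
from flankerlab.design import (
    CONGRUENT,
    EXP1,
    INCONGRUENT,
    LEFT,
    RIGHT,
    TrialSpec,
)
from flankerlab.simulate import CellParams, GenParams, Population


def flat_design(n_per_cong: int, soa_ms: int = 0) -> list[TrialSpec]:
    """Minimal one-block EXP1-style design with a single SOA level."""
    specs = []
    idx = 0
    for i in range(n_per_cong):
        for c in (CONGRUENT, INCONGRUENT):
            idx += 1
            d = LEFT if (i + idx) % 2 else RIGHT
            specs.append(TrialSpec(EXP1, 1, idx, c, d, soa_ms=soa_ms))
    return specs


def single_cell_params(
    delta0=0.0, delta1=0.0, e_cong=0.0, e_incong=0.0, soa_ms=0, timeout_ms=1e9, seed=0
) -> GenParams:
    return GenParams(
        EXP1,
        Population(),
        {str(soa_ms): CellParams(delta0, delta1, e_cong, e_incong)},
        timeout_ms=timeout_ms,
        rng_seed=seed,
    )


@pytest.fixture(scope="session")
def exp1_design():
    return design.build_exp1(1)


@pytest.fixture(scope="session")
def exp3_design():
    return design.build_exp3("ABBA", 3)


@pytest.fixture(scope="session")
def exp3_table():
    """Small classified + carry-over-labeled EXP3 table (4 subjects)."""
    from flankerlab import preprocess

    specs = design.build_exp3("ABBA", 11)
    params = simulate.preset_canonical("EXP3", seed=11)
    table = simulate.simulate_experiment(specs, n_subjects=4, params=params)
    table = preprocess.classify_trials(table)
    table, _ = preprocess.label_carryover(table)
    return table
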