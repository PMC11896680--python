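import json
from importlib import resources

import numpy as np
import pytest

from thyrostage import load_paper_cohort
from thyrostage.model import (
    SUBSITES,
    Involvement,
    MCategory,
    NCategory,
    ResidualCode,
    TCategory,
    TNMCategory,
)
from thyrostage.notation import ParsedClassification


@pytest.fixture(scope="session")
def paper_cohort():
    return load_paper_cohort()


@pytest.fixture(scope="session")
def cohort_by_id(paper_cohort):
    return {case.record.case_id: case for case in paper_cohort}


@pytest.fixture(scope="session")
def paper_cohort_raw():
    return json.loads(
        resources.files("thyrostage.data").joinpath("paper_cohort.json").read_text()
    )


@pytest.fixture(scope="session")
def random_classification():
    """Factory fixture: draw a random valid ParsedClassification."""
    return random_parsed_classification


def random_parsed_classification(rng: np.random.Generator) -> ParsedClassification:
    """Draw a random valid ParsedClassification (shared by round-trip tests)."""
    n = int(rng.integers(0, len(SUBSITES) + 1))
    chosen = rng.choice(len(SUBSITES), size=n, replace=False)
    involvements = set()
    for idx in chosen:
        sub = SUBSITES[int(idx)]
        degree = int(rng.integers(0, 2)) if sub.takes_degree else None
        rings = None
        if sub.takes_ring_count and rng.random() < 0.7:
            rings = int(rng.integers(1, 6))
        involvements.add(Involvement(sub.category, sub.code, degree, rings))
    rec = bool(rng.random() < 0.25)
    tnm = None
    if not rec and rng.random() < 0.9:
        tnm = TNMCategory(
            t=list(TCategory)[int(rng.integers(0, len(TCategory)))],
            n=list(NCategory)[int(rng.integers(0, len(NCategory)))],
            m=list(MCategory)[int(rng.integers(0, len(MCategory)))],
        )
    residual = list(ResidualCode)[int(rng.integers(0, 3))]
    if not rec and tnm is None and not involvements and residual is ResidualCode.R0:
        # the grammar has no empty classification; force a TNM
        tnm = TNMCategory(t=TCategory.T2)
    return ParsedClassification(
        rec_prefix=rec,
        residual=residual,
        tnm=tnm,
        involvements=frozenset(involvements),
    )
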