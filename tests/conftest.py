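"""Shared fixtures: study cohort, hand-audited filter toy, toy GFF3."""

from __future__ import annotations

import pandas as pd
import pytest

from broodmeth import benchmarks
from broodmeth.benchmarks import TOY_GFF3, study_cohort as cohort_design


@pytest.fixture(scope="session")
def design50() -> pd.DataFrame:
    """25 reduced + 25 enlarged recaptured birds, fixed seed."""
    return cohort_design(1)


@pytest.fixture()
def toy_design4() -> pd.DataFrame:
    """Minimal design: two individuals per treatment."""
    return benchmarks.toy_design4()


@pytest.fixture()
def filter_toy(toy_design4):
    """Hand-audited 10-site toy for the filter pipeline (10 -> 8 -> 5 -> 4)."""
    matrix, _, _ = benchmarks.filter_toy()
    return matrix, toy_design4


@pytest.fixture(scope="session")
def toy_gff3(tmp_path_factory):
    path = tmp_path_factory.mktemp("gff") / "toy.gff3"
    path.write_text(TOY_GFF3)
    return path
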