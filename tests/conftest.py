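import numpy as np
import pandas as pd
import pytest

from pedscan.pedigree import Pedigree, PedigreeRecord, additive_relationship
from pedscan.simulate import SimConfig, generate_cohort


def make_pedigree(rows):
    """rows: (fam, iid, father, mother, sex) tuples; None = missing parent."""
    return Pedigree([PedigreeRecord(*r) for r in rows])


@pytest.fixture
def trio_pedigree():
    return make_pedigree([
        ("F1", "P1", None, None, "male"),
        ("F1", "P2", None, None, "female"),
        ("F1", "C1", "P1", "P2", "female"),
    ])


@pytest.fixture
def sib_pedigree():
    """Two full sibs, one half sib (shared father, different mothers)."""
    return make_pedigree([
        ("F1", "PA", None, None, "male"),
        ("F1", "MA", None, None, "female"),
        ("F1", "MB", None, None, "female"),
        ("F1", "S1", "PA", "MA", "male"),
        ("F1", "S2", "PA", "MA", "female"),
        ("F1", "H1", "PA", "MB", "male"),
    ])


@pytest.fixture(scope="session")
def small_cohort():
    """Shared mid-sized cohort with one planted BMI effect and one planted
    coexpression pair; used by several scan-level tests."""
    cfg = SimConfig(
        n_families=80, n_mrna=120, n_mirna=15, seed=11,
        effect_table=[("G00000", "BMI", 0.5)],
        coexpression_table=[("miR-000", "G00010", 0.6)],
    )
    return generate_cohort(cfg)


def standardized(series: pd.Series) -> pd.Series:
    return (series - series.mean()) / series.std()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
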