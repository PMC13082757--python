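import numpy as np
import pandas as pd
import pytest

from toxconcord.records import AERecord, ae_records_to_frame
from toxconcord.simulate import (
    PlantedAEProfile,
    SimConfig,
    VocabTerm,
    default_vocab,
    generate_cohort,
)


def rec(drug, species, soc, pt, **kw):
    return AERecord.make(drug, species, soc, pt, **kw)


def frame(*records):
    return ae_records_to_frame(records)


@pytest.fixture
def gi_soc():
    return "Gastrointestinal disorders"


@pytest.fixture
def four_drug_frame(gi_soc):
    """Universe {A,B,C,D}: A has the PT on both sides, B animal-only,
    C human-only, D neither; every drug carries anchor records on both
    sides so all four stay in the stratum universe."""
    rows = []
    for d in "ABCD":
        rows.append(rec(d, "human", "Investigations", "Clinical finding present"))
        rows.append(rec(d, "dog", "Investigations", "Animal finding present"))
    rows.append(rec("A", "human", gi_soc, "Vomiting"))
    rows.append(rec("A", "dog", gi_soc, "Vomiting"))
    rows.append(rec("B", "dog", gi_soc, "Vomiting"))
    rows.append(rec("C", "human", gi_soc, "Vomiting"))
    return frame(*rows)


@pytest.fixture(scope="session")
def planted_cohort():
    """One strongly concordant AE (sens .6, spec .95, prev .3) in rats."""
    prof = PlantedAEProfile(
        pt="Vomiting",
        soc="Gastrointestinal disorders",
        prevalence_human=0.3,
        sensitivity=0.6,
        specificity=0.95,
        linked_targets={"HTR3A", "OPRM1"},
    )
    cfg = SimConfig(n_drugs=2000, species_panel=("rat",), vocab=default_vocab(), seed=11)
    return generate_cohort(cfg, [prof]), prof


def random_table(rng, max_cell=60):
    return tuple(int(v) for v in rng.integers(0, max_cell, size=4))
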