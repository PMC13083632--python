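"""Shared fixtures: small hand-built tables mirroring the worked examples."""

import pytest

from tablign import as_target_schema, load_standard, validate_table
from tablign.fixtures import FixtureSpec, generate_fixture


@pytest.fixture
def cnv_source():
    return validate_table(
        {"CNV_class": ["CNV_LOW", "CNV_HIGH", "CNV_LOW"]}, name="cnv_source"
    )


@pytest.fixture
def cnv_target():
    return validate_table(
        {"CNV_status": ["CNV_L", "CNV_H", "CNV_H"]}, name="cnv_target"
    )


@pytest.fixture
def geo_source():
    """A tiny assay-metadata table: one assay, two organisms."""
    return validate_table(
        {
            "Assay Type": ["RNA-Seq", "RNA-Seq", "RNA-Seq"],
            "Organism": ["Homo sapiens", "Homo sapiens", "Mus musculus"],
        },
        name="geo_source",
    )


@pytest.fixture
def geo_target_table():
    """Target-side assay table with the values the triage rules look at."""
    return validate_table(
        {
            "Assay": ["RNA-seq", "RNA-seq", "RNA-seq"],
            "Species": ["Homo sapiens", "Mus musculus", "Homo sapiens"],
            "LibraryPreparationMethod": ["TruSeq", "Nextera XT", "KAPA HyperPrep"],
        },
        name="geo_target",
    )


@pytest.fixture
def rcc_source():
    """Renal-carcinoma-style clinical table with ages in years."""
    return validate_table(
        {
            "Gender": ["Female", "Male", "Female"],
            "Race": ["White", "Asian", "White"],
            "BMI": ["22.5", "30.1", "27.4"],
            "Tumor_Focality": ["Unifocal", "Multifocal", "Unifocal"],
            "Age": ["65", "54", "71"],
        },
        name="rcc_source",
    )


@pytest.fixture
def toy_cdm_schema():
    return load_standard("toy_cdm").get_table_representation()


@pytest.fixture
def clean_fixture_pair():
    """A 10-column fixture table and its own schema (no perturbations)."""
    source, target, truth = generate_fixture(FixtureSpec(seed=11, n_columns=10))
    return source, target, truth


@pytest.fixture
def perturbed_fixture_pair():
    source, target, truth = generate_fixture(
        FixtureSpec(
            seed=5,
            perturbations=frozenset({"case_change", "snake_camel", "value_recode"}),
        )
    )
    return source, target, truth
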