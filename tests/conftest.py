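from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_bundle(
    patients=None, encounters=None, documents=None, diagnoses=None, prescriptions=None
):
    """Small hand-built EHR bundle for unit tests."""
    from litcomorbid.cohort import EhrBundle, TABLE_SCHEMAS

    def df(rows, name):
        cols = TABLE_SCHEMAS[name]
        return pd.DataFrame(rows or [], columns=cols)

    return EhrBundle(
        patients=df(patients, "patients"),
        encounters=df(encounters, "encounters"),
        documents=df(documents, "documents"),
        diagnoses=df(diagnoses, "diagnoses"),
        prescriptions=df(prescriptions, "prescriptions"),
    )


@pytest.fixture(scope="session")
def tables():
    from litcomorbid.fixtures import fixture_tables

    return fixture_tables()


@pytest.fixture(scope="session")
def mappings():
    from litcomorbid.fixtures import load_default_mappings

    return load_default_mappings()
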