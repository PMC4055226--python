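import pytest

from fse import datasets


@pytest.fixture
def candidates():
    """3 x 5 running-example decision table (objects x1..x3)."""
    return datasets.candidates()


@pytest.fixture
def symptoms():
    return datasets.disease_symptoms()


@pytest.fixture
def tools():
    return datasets.disease_tools()


@pytest.fixture
def patient_symptoms(symptoms):
    """Symptom table restricted to the observed symptoms of the patient."""
    return symptoms.restrict(datasets.PATIENT_SYMPTOMS)
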