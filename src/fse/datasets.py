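"""Bundled example fuzzy soft sets.

Small worked-example tables shipped as CSV fixtures: a crisp and a fuzzy
house-selection table, the three-candidate / five-parameter running example,
and the medical-diagnosis pair (four diseases described by seven symptoms and
by three diagnostic tools).  All load through the regular CSV reader, so
textual precision is recorded.
"""

from __future__ import annotations

from importlib import resources

from .core import FuzzySoftSet
from .io import parse_fss

__all__ = [
    "house_soft_set",
    "house_fuzzy_set",
    "candidates",
    "disease_symptoms",
    "disease_tools",
    "load",
]

#: the three symptoms observed on the example patient (fever, running nose,
#: orofacial pain); the diagnosis pipeline restricts the symptom table to these
PATIENT_SYMPTOMS = ("e1", "e2", "e4")


def load(name: str) -> FuzzySoftSet:
    """Load a bundled fixture by file name (e.g. ``"candidates.csv"``)."""
    text = resources.files("fse.data").joinpath(name).read_text()
    return parse_fss(text, name=name)


def house_soft_set() -> FuzzySoftSet:
    """Crisp house-selection soft set: six houses, four binary attributes."""
    return load("house_soft.csv")


def house_fuzzy_set() -> FuzzySoftSet:
    """Fuzzy house-selection table: six houses, four graded attributes."""
    return load("house_fuzzy.csv")


def candidates() -> FuzzySoftSet:
    """The 3 × 5 running-example decision table (x1..x3 over e1..e5)."""
    return load("candidates.csv")


def disease_symptoms() -> FuzzySoftSet:
    """Four diseases against seven symptoms (memberships from statistics)."""
    return load("disease_symptoms.csv")


def disease_tools() -> FuzzySoftSet:
    """Four diseases against three diagnostic tools."""
    return load("disease_tools.csv")
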