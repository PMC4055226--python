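"""Mass functions, belief, and Dempster combination."""

from itertools import chain, combinations, permutations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fse import (
    THETA,
    FrameMismatchError,
    FuzzySoftSet,
    MassFunction,
    TotalConflictError,
    belief,
    build_mass_functions,
    combine2,
    combine_all,
    grey_analysis,
    information_structure_image,
)


def brute_force_combine(m1: MassFunction, m2: MassFunction):
    """Independent oracle: enumerate every pair of subsets of the frame.

    Walks the full power set of the frame for both operands (not just the
    stored focal sets), accumulating conflict and intersection products
    directly from the defining rule.
    """
    frame = list(m1.frame)
    subsets = [
        frozenset(c)
        for c in chain.from_iterable(
            combinations(frame, k) for k in range(1, len(frame) + 1)
        )
    ]
    conflict = 0.0
    raw: dict[frozenset, float] = {}
    for a in subsets:
        for b in subsets:
            product = m1.mass(a) * m2.mass(b)
            if product == 0.0:
                continue
            inter = a & b
            if inter:
                raw[inter] = raw.get(inter, 0.0) + product
            else:
                conflict += product
    return conflict, {k: v / (1.0 - conflict) for k, v in raw.items()}


def singleton_theta_mass(frame, singles, theta):
    assignment = dict(zip(frame, singles))
    assignment[THETA] = theta
    return MassFunction(frame, assignment)


@st.composite
def random_mass(draw, frame):
    """A random mass over arbitrary non-empty subsets of the frame."""
    subsets = [
        frozenset(c)
        for c in chain.from_iterable(
            combinations(frame, k) for k in range(1, len(frame) + 1)
        )
    ]
    focal = draw(st.lists(st.sampled_from(subsets), min_size=1, max_size=4,
                          unique=True))
    weights = draw(st.lists(st.floats(0.05, 1.0), min_size=len(focal),
                            max_size=len(focal)))
    total = sum(weights)
    return MassFunction(frame, {tuple(sorted(s)): w / total
                                for s, w in zip(focal, weights)})


class TestMassFunction:
    def test_rejects_unnormalised_assignment(self):
        with pytest.raises(ValueError, match="sum"):
            MassFunction(("a", "b"), {"a": 0.5, "b": 0.4})

    def test_rejects_mass_on_empty_set(self):
        with pytest.raises(ValueError, match="empty"):
            MassFunction(("a", "b"), {(): 0.2, "a": 0.8})

    def test_rejects_focal_outside_frame(self):
        with pytest.raises(ValueError, match="frame"):
            MassFunction(("a", "b"), {"c": 1.0})

    def test_theta_key_and_tuple_key_coincide(self):
        m = MassFunction(("a", "b"), {THETA: 0.4, "a": 0.6})
        assert m.mass(("a", "b")) == pytest.approx(0.4)
        assert m.theta_mass == pytest.approx(0.4)

    def test_serialisation_uses_sorted_labels(self):
        m = MassFunction(("b", "a", "c"), {("c", "a"): 0.3, "b": 0.2, THETA: 0.5})
        assert m.to_dict() == {"b": 0.2, "a|c": 0.3, THETA: 0.5}


class TestBelief:
    def test_certain_singleton(self):
        m = MassFunction(("x",), {"x": 1.0})
        assert belief(m, "x") == pytest.approx(1.0)

    def test_whole_frame_has_full_belief(self):
        m = MassFunction(("a", "b"), {"a": 0.3, "b": 0.2, THETA: 0.5})
        assert belief(m, THETA) == pytest.approx(1.0)

    def test_subset_enumeration(self):
        m = MassFunction(("a", "b", "c"), {"a": 0.3, "b": 0.2, THETA: 0.5})
        assert belief(m, ("a", "b")) == pytest.approx(0.5)

    def test_labels_outside_frame_error(self):
        m = MassFunction(("a", "b"), {THETA: 1.0})
        with pytest.raises(ValueError, match="frame"):
            belief(m, ("a", "z"))


class TestCombine2:
    def test_two_element_frame_worked_example(self):
        m1 = MassFunction(("A1", "A2"), {"A1": 0.2, "A2": 0.5, THETA: 0.3})
        m2 = MassFunction(("A1", "A2"), {"A1": 0.4, "A2": 0.3, THETA: 0.3})
        result = combine2(m1, m2)
        assert result.conflict == pytest.approx(0.26, abs=1e-12)
        assert result.combined.mass("A1") == pytest.approx(0.3514, abs=1.5e-4)
        assert result.combined.mass("A2") == pytest.approx(0.5270, abs=1.5e-4)
        assert result.combined.theta_mass == pytest.approx(0.1216, abs=1.5e-4)

    def test_vacuous_mass_is_neutral(self):
        m = MassFunction(("a", "b", "c"), {"a": 0.6, ("b", "c"): 0.3, THETA: 0.1})
        vacuous = MassFunction(("a", "b", "c"), {THETA: 1.0})
        result = combine2(m, vacuous)
        assert result.conflict == 0.0
        for focal in m.focal_sets():
            assert result.combined.mass(focal) == pytest.approx(m.mass(focal))

    def test_total_conflict_is_an_error(self):
        m1 = MassFunction(("a", "b"), {"a": 1.0})
        m2 = MassFunction(("a", "b"), {"b": 1.0})
        with pytest.raises(TotalConflictError):
            combine2(m1, m2)

    def test_frame_mismatch_is_an_error(self):
        m1 = MassFunction(("a", "b"), {THETA: 1.0})
        m2 = MassFunction(("a", "c"), {THETA: 1.0})
        with pytest.raises(FrameMismatchError):
            combine2(m1, m2)

    @settings(deadline=None, max_examples=100)
    @given(st.data())
    def test_agrees_with_power_set_oracle(self, data):
        frame = ("a", "b", "c", "d")
        m1 = data.draw(random_mass(frame))
        m2 = data.draw(random_mass(frame))
        oracle_conflict, oracle_masses = brute_force_combine(m1, m2)
        if oracle_conflict >= 1.0 - 1e-9:
            with pytest.raises(TotalConflictError):
                combine2(m1, m2)
            return
        result = combine2(m1, m2)
        assert result.conflict == pytest.approx(oracle_conflict, abs=1e-9)
        for focal, value in oracle_masses.items():
            assert result.combined.mass(focal) == pytest.approx(value, abs=1e-9)


class TestCombineAll:
    def test_running_example_five_evidences(self, candidates):
        g = grey_analysis(candidates)
        masses = build_mass_functions(information_structure_image(candidates), g.doi)
        fused = combine_all(masses)
        assert fused.mass("x1") == pytest.approx(0.2690, abs=1.5e-4)
        assert fused.mass("x2") == pytest.approx(0.3309, abs=1.5e-4)
        assert fused.mass("x3") == pytest.approx(0.3218, abs=1.5e-4)
        assert fused.theta_mass == pytest.approx(0.0782, abs=1.5e-4)

    def test_medical_nine_evidences(self, patient_symptoms, tools):
        from fse import and_product

        table = and_product(patient_symptoms, tools)
        g = grey_analysis(table)
        masses = build_mass_functions(information_structure_image(table), g.doi)
        fused = combine_all(masses)
        assert fused.mass("d3") == pytest.approx(0.8349, abs=1.5e-4)
        assert fused.theta_mass == pytest.approx(0.0069, abs=1.5e-4)

    def test_single_mass_is_returned_unchanged(self):
        m = MassFunction(("a", "b"), {"a": 0.4, THETA: 0.6})
        fused = combine_all([m])
        assert fused.mass("a") == pytest.approx(0.4)

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_order_independence(self, seed):
        rng = np.random.default_rng(seed)
        frame = tuple(f"x{i}" for i in range(int(rng.integers(2, 6))))
        masses = []
        for _ in range(3):
            singles = rng.uniform(0.05, 1.0, size=len(frame))
            theta = rng.uniform(0.05, 1.0)
            total = singles.sum() + theta
            masses.append(
                singleton_theta_mass(frame, singles / total, theta / total))
        reference = combine_all(masses)
        for perm in permutations(masses):
            fused = combine_all(list(perm))
            for x in frame:
                assert fused.mass(x) == pytest.approx(reference.mass(x), abs=1e-9)
            assert fused.theta_mass == pytest.approx(reference.theta_mass, abs=1e-9)

    def test_combination_reduces_residual_ignorance(self, candidates):
        # fusing several evidences leaves less mass on Θ than any single one
        g = grey_analysis(candidates)
        masses = build_mass_functions(information_structure_image(candidates), g.doi)
        fused = combine_all(masses)
        assert fused.theta_mass < min(m.theta_mass for m in masses)


class TestBuildMassFunctions:
    def test_running_example_first_parameter(self, candidates):
        g = grey_analysis(candidates)
        masses = build_mass_functions(information_structure_image(candidates), g.doi)
        assert masses[0].mass("x1") == pytest.approx(0.2138, abs=1.5e-4)
        assert masses[0].theta_mass == pytest.approx(0.4341, abs=1.5e-4)

    def test_theta_mass_equals_uncertainty_degree(self, patient_symptoms, tools):
        from fse import and_product

        table = and_product(patient_symptoms, tools)
        g = grey_analysis(table)
        masses = build_mass_functions(information_structure_image(table), g.doi)
        for m, doi in zip(masses, g.doi):
            assert m.theta_mass == pytest.approx(doi, abs=1e-9)

    def test_fully_uncertain_parameter_is_vacuous(self):
        f = FuzzySoftSet(("x1", "x2"), ("e1",), np.array([[0.4], [0.6]]))
        masses = build_mass_functions(
            information_structure_image(f), np.array([1.0]))
        assert masses[0].theta_mass == pytest.approx(1.0)
        assert masses[0].mass("x1") == 0.0
        assert masses[0].mass("x2") == 0.0

    def test_doi_outside_range_is_an_error(self, candidates):
        img = information_structure_image(candidates)
        with pytest.raises(ValueError, match="\\(0, 1\\]"):
            build_mass_functions(img, np.array([0.4, 0.5, 0.5, 0.4, 1.2]))
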