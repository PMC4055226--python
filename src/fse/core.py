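"""Fuzzy soft sets and their elementary algebra.

A fuzzy soft set ``(F, A)`` over a finite universe of objects assigns to each
parameter ``e`` in ``A`` a fuzzy subset of the universe: tabularly, an
objects-by-parameters matrix of membership degrees in ``[0, 1]``.  This module
provides the container plus the operations the decision pipelines are built
from: fuzzy soft subset comparison, the AND-product (pointwise minimum on the
Cartesian product of parameter sets), level soft sets with per-object choice
values, significant-figure arithmetic on memberships as written, and the
performance measure used to compare decision methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FuzzySoftSet",
    "LevelSoftSet",
    "UniverseMismatchError",
    "UndefinedPerformanceError",
    "is_fuzzy_subset",
    "and_product",
    "level_soft_set",
    "parameter_spreads",
    "object_spreads",
    "count_sig_figs",
    "max_significant_figures",
    "round_sig",
    "performance_measure",
]

#: slack used when comparing memberships against a level threshold; thresholds
#: come from significant-figure rounding and are exact decimals, memberships
#: are parsed from text, so only representation noise needs absorbing.
LEVEL_EPS = 1e-9


class UniverseMismatchError(ValueError):
    """Two fuzzy soft sets are defined over different object universes."""


class UndefinedPerformanceError(ValueError):
    """The performance measure is undefined (zero membership spread)."""


def _check_unique(labels: Sequence[str], kind: str) -> tuple[str, ...]:
    labels = tuple(str(x) for x in labels)
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValueError(f"duplicate {kind} labels: {dupes}")
    if not labels:
        raise ValueError(f"at least one {kind} label is required")
    return labels


@dataclass(frozen=True)
class FuzzySoftSet:
    """An objects × parameters table of membership degrees in [0, 1].

    Parameters
    ----------
    objects
        Ordered, unique object (alternative) labels; length ``m >= 1``.
    parameters
        Ordered, unique parameter labels; length ``n >= 1``.
    values
        ``m × n`` membership matrix with entries in ``[0, 1]``.
    precision
        Optional ``m × n`` integer matrix recording, per entry, the number of
        significant decimal digits of the value *as written* in its source
        text.  Present when the set was parsed from a file or built by the
        synthetic generator; needed by :func:`max_significant_figures`.
    """

    objects: tuple[str, ...]
    parameters: tuple[str, ...]
    values: np.ndarray
    precision: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        objects = _check_unique(self.objects, "object")
        parameters = _check_unique(self.parameters, "parameter")
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(objects), len(parameters)):
            raise ValueError(
                f"membership matrix shape {values.shape} does not match "
                f"{len(objects)} objects x {len(parameters)} parameters"
            )
        if np.any(values < 0.0) or np.any(values > 1.0):
            i, j = np.argwhere((values < 0.0) | (values > 1.0))[0]
            raise ValueError(
                f"membership {values[i, j]} at ({objects[i]}, {parameters[j]}) "
                "is outside [0, 1]"
            )
        values = values.copy()
        values.setflags(write=False)
        object.__setattr__(self, "objects", objects)
        object.__setattr__(self, "parameters", parameters)
        object.__setattr__(self, "values", values)
        if self.precision is not None:
            prec = np.asarray(self.precision, dtype=int)
            if prec.shape != values.shape:
                raise ValueError("precision matrix shape mismatch")
            prec.setflags(write=False)
            object.__setattr__(self, "precision", prec)

    # -- convenience accessors -------------------------------------------

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    @property
    def n_parameters(self) -> int:
        return len(self.parameters)

    def membership(self, obj: str, param: str) -> float:
        return float(self.values[self._oi(obj), self._pi(param)])

    def object_row(self, obj: str) -> np.ndarray:
        return self.values[self._oi(obj)]

    def parameter_column(self, param: str) -> np.ndarray:
        return self.values[:, self._pi(param)]

    def restrict(self, parameters: Iterable[str]) -> "FuzzySoftSet":
        """Return the fuzzy soft set restricted to a subset of parameters."""
        keep = [self._pi(p) for p in parameters]
        return FuzzySoftSet(
            self.objects,
            tuple(self.parameters[j] for j in keep),
            self.values[:, keep],
            None if self.precision is None else self.precision[:, keep],
        )

    def reorder_objects(self, objects: Sequence[str]) -> "FuzzySoftSet":
        idx = [self._oi(o) for o in objects]
        return FuzzySoftSet(
            tuple(self.objects[i] for i in idx),
            self.parameters,
            self.values[idx],
            None if self.precision is None else self.precision[idx],
        )

    def _oi(self, obj: str) -> int:
        try:
            return self.objects.index(obj)
        except ValueError:
            raise KeyError(f"unknown object label {obj!r}") from None

    def _pi(self, param: str) -> int:
        try:
            return self.parameters.index(param)
        except ValueError:
            raise KeyError(f"unknown parameter label {param!r}") from None


@dataclass(frozen=True)
class LevelSoftSet:
    """Binarization of a fuzzy soft set at a threshold.

    ``indicator[i, j] = 1`` iff the membership of object ``i`` under parameter
    ``j`` is at least the threshold; ``choice_values`` are the indicator row
    sums, the classical choice values of soft-set decision making.
    """

    objects: tuple[str, ...]
    parameters: tuple[str, ...]
    indicator: np.ndarray
    threshold: float
    choice_values: np.ndarray

    def choice_value(self, obj: str) -> int:
        return int(self.choice_values[self.objects.index(obj)])


def _require_same_universe(f: FuzzySoftSet, g: FuzzySoftSet) -> FuzzySoftSet:
    """Align ``g``'s rows to ``f``'s object order; error on set mismatch."""
    if set(f.objects) != set(g.objects):
        raise UniverseMismatchError(
            f"object universes differ: {sorted(f.objects)} vs {sorted(g.objects)}"
        )
    if f.objects == g.objects:
        return g
    return g.reorder_objects(f.objects)


def is_fuzzy_subset(f: FuzzySoftSet, g: FuzzySoftSet) -> bool:
    """Whether ``f`` is a fuzzy soft subset of ``g``.

    True iff every parameter of ``f`` also belongs to ``g`` and, for each
    shared parameter, ``f``'s membership never exceeds ``g``'s at any object.
    Both sets must be defined over the same object universe.
    """
    g = _require_same_universe(f, g)
    if not set(f.parameters) <= set(g.parameters):
        return False
    for p in f.parameters:
        if np.any(f.parameter_column(p) > g.parameter_column(p)):
            return False
    return True


def and_product(f: FuzzySoftSet, g: FuzzySoftSet) -> FuzzySoftSet:
    """The AND-product: pointwise minimum over the parameter product A × B.

    The result's parameters are the ordered pairs ``(a, b)`` in row-major
    order over ``f``'s times ``g``'s parameter lists, labelled ``"(a,b)"``;
    its membership at object ``x`` and pair ``(a, b)`` is
    ``min(f(a)(x), g(b)(x))``.
    """
    g = _require_same_universe(f, g)
    pair_labels = tuple(
        f"({a},{b})" for a in f.parameters for b in g.parameters
    )
    # m x (na*nb): broadcast min over all column pairs, row-major in (a, b)
    vals = np.minimum(
        f.values[:, :, None], g.values[:, None, :]
    ).reshape(f.n_objects, -1)
    return FuzzySoftSet(f.objects, pair_labels, vals)


def level_soft_set(f: FuzzySoftSet, threshold: float) -> LevelSoftSet:
    """The crisp level soft set of ``f`` at ``threshold`` (>= convention)."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    indicator = (f.values >= threshold - LEVEL_EPS).astype(int)
    indicator.setflags(write=False)
    choice = indicator.sum(axis=1)
    choice.setflags(write=False)
    return LevelSoftSet(f.objects, f.parameters, indicator, float(threshold), choice)


def parameter_spreads(f: FuzzySoftSet) -> np.ndarray:
    """Per-parameter spread: max minus min membership down each column."""
    return f.values.max(axis=0) - f.values.min(axis=0)


def object_spreads(f: FuzzySoftSet) -> np.ndarray:
    """Per-object spread: max minus min membership along each row."""
    return f.values.max(axis=1) - f.values.min(axis=1)


def count_sig_figs(text: str) -> int:
    """Significant decimal digits of a number as written.

    Digits after leading zeros, the sign and the decimal point are counted;
    trailing zeros that were written are significant ("0.30" has two).  A bare
    zero counts as one digit.
    """
    s = text.strip().lstrip("+-")
    if not s or any(c not in "0123456789." for c in s) or s.count(".") > 1:
        raise ValueError(f"not a plain decimal literal: {text!r}")
    digits = s.replace(".", "").lstrip("0")
    return max(len(digits), 1)


def max_significant_figures(f: FuzzySoftSet, override: int | None = None) -> int:
    """Maximum significant-figure count over all memberships of ``f``.

    Requires the per-entry precision record captured when the set was parsed
    from text; pass ``override`` to supply the count explicitly when the set
    was constructed in memory.
    """
    if override is not None:
        if override < 1:
            raise ValueError("significant-figure override must be >= 1")
        return int(override)
    if f.precision is None:
        raise ValueError(
            "textual precision unavailable for this fuzzy soft set; "
            "pass an explicit significant-figure override"
        )
    return int(f.precision.max())


def round_sig(x: float, ndigits: int) -> float:
    """Round ``x`` to ``ndigits`` significant figures, half away from zero.

    The value is first normalised through a 12-significant-digit decimal
    string so that binary representation noise (0.6259999...) does not defeat
    the decimal rounding.
    """
    if ndigits < 1:
        raise ValueError("ndigits must be >= 1")
    if x == 0:
        return 0.0
    d = Decimal(f"{x:.12g}")
    quantum = Decimal(1).scaleb(d.adjusted() - (ndigits - 1))
    return float(d.quantize(quantum, rounding=ROUND_HALF_UP))


def performance_measure(f: FuzzySoftSet, optimal_object: str) -> float:
    """Performance measure Υ of a decision method at its chosen optimum.

    With memberships ``v_1 .. v_n`` of the optimal object over the choice
    parameters, ``Υ = 1 / S + Σ_i v_i`` where ``S`` is the sum of
    ``|v_i − v_j|`` over unordered pairs ``i < j``.  Larger is better: the
    optimum should hold high memberships with little spread among them.

    Raises
    ------
    UndefinedPerformanceError
        If all memberships of the optimum coincide (``S = 0``).
    ValueError
        If there are fewer than two choice parameters.
    """
    if f.n_parameters < 2:
        raise ValueError("performance measure needs at least two parameters")
    row = f.object_row(optimal_object)
    spread = float(sum(abs(a - b) for a, b in combinations(row, 2)))
    if spread == 0.0:
        raise UndefinedPerformanceError(
            f"all memberships of {optimal_object!r} coincide; Υ is undefined"
        )
    return 1.0 / spread + float(row.sum())
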