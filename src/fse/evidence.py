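"""Dempster-Shafer machinery: mass functions, belief, and combination.

A mass function (basic probability assignment) distributes one unit of
support over non-empty subsets of a finite frame of discernment Θ; the mass
on Θ itself is the evidence's residual ignorance.  Dempster's rule combines
independent mass functions by intersecting focal sets and renormalising away
the conflicting mass K.  The decision pipelines only ever build masses on
singletons plus Θ, but the machinery here handles arbitrary focal sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .grey import ImageMatrix

__all__ = [
    "MassFunction",
    "CombinationResult",
    "FrameMismatchError",
    "TotalConflictError",
    "THETA",
    "build_mass_functions",
    "combine2",
    "combine_all",
    "belief",
]

#: serialization label that denotes the whole frame in report dictionaries
THETA = "THETA"

_MASS_TOL = 1e-9


class FrameMismatchError(ValueError):
    """Mass functions to combine are defined over different frames."""


class TotalConflictError(ValueError):
    """Dempster combination failed: the evidences are in total conflict."""


class MassFunction:
    """A basic probability assignment over subsets of a finite frame.

    Parameters
    ----------
    frame
        Ordered labels of the mutually exclusive, exhaustive alternatives.
    assignment
        Mapping from focal sets (iterables of frame labels, or the string
        ``"THETA"`` for the whole frame) to non-negative masses summing to 1.
        The empty set may not carry mass and is never stored.
    """

    __slots__ = ("frame", "_masses")

    def __init__(
        self,
        frame: Sequence[str],
        assignment: Mapping[Iterable[str] | str, float],
    ) -> None:
        self.frame = tuple(str(x) for x in frame)
        if len(set(self.frame)) != len(self.frame) or not self.frame:
            raise ValueError("frame must be a non-empty sequence of unique labels")
        universe = frozenset(self.frame)
        masses: dict[frozenset, float] = {}
        for key, value in assignment.items():
            focal = universe if key == THETA else frozenset(
                [key] if isinstance(key, str) else key
            )
            if not focal:
                raise ValueError("the empty set may not carry mass")
            if not focal <= universe:
                raise ValueError(f"focal set {sorted(focal)} not within the frame")
            value = float(value)
            if value < -_MASS_TOL:
                raise ValueError(f"negative mass {value} on {sorted(focal)}")
            if value > 0.0:
                masses[focal] = masses.get(focal, 0.0) + value
        total = sum(masses.values())
        if abs(total - 1.0) > _MASS_TOL:
            raise ValueError(f"masses sum to {total}, not 1")
        self._masses = masses

    # -- queries ----------------------------------------------------------

    def mass(self, focal: Iterable[str] | str) -> float:
        """Mass of a focal set (0 for sets that carry none)."""
        key = frozenset(self.frame) if focal == THETA else frozenset(
            [focal] if isinstance(focal, str) else focal
        )
        return self._masses.get(key, 0.0)

    @property
    def theta_mass(self) -> float:
        """Residual ignorance: mass assigned to the whole frame."""
        return self._masses.get(frozenset(self.frame), 0.0)

    def focal_sets(self) -> list[frozenset]:
        return list(self._masses)

    def items(self):
        return self._masses.items()

    def belief(self, subset: Iterable[str] | str) -> float:
        """Bel(A): total mass of focal sets contained in ``A``."""
        return belief(self, subset)

    def to_dict(self) -> dict[str, float]:
        """Serialise as ``{"a|b": mass}`` with ``"THETA"`` for the frame."""
        universe = frozenset(self.frame)
        out = {}
        for focal, value in sorted(
            self._masses.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
        ):
            key = THETA if focal == universe else "|".join(sorted(focal))
            out[key] = value
        return out

    def __repr__(self) -> str:
        parts = ", ".join(f"{k}: {v:.4f}" for k, v in self.to_dict().items())
        return f"MassFunction({{{parts}}})"


@dataclass(frozen=True)
class CombinationResult:
    """Outcome of one Dempster combination: the merged mass and conflict K."""

    combined: MassFunction
    conflict: float


def build_mass_functions(image: ImageMatrix, doi: np.ndarray) -> list[MassFunction]:
    """One mass function per parameter from grey uncertainty degrees.

    For parameter ``j`` the singleton ``{x_i}`` receives
    ``image[i, j] · (1 − DOI_j)`` and the whole frame receives the remainder,
    which equals ``DOI_j`` because image columns sum to one: the less a
    parameter discriminates, the more of its unit mass stays on Θ.
    """
    doi = np.asarray(doi, dtype=float)
    if doi.shape != (len(image.parameters),):
        raise ValueError("need one uncertainty degree per parameter")
    if np.any(doi <= 0) or np.any(doi > 1):
        raise ValueError("uncertainty degrees must lie in (0, 1]")
    frame = image.objects
    out = []
    for j in range(len(image.parameters)):
        singles = image.values[:, j] * (1.0 - doi[j])
        assignment: dict = {x: s for x, s in zip(frame, singles)}
        assignment[THETA] = 1.0 - float(singles.sum())
        out.append(MassFunction(frame, assignment))
    return out


def combine2(m1: MassFunction, m2: MassFunction) -> CombinationResult:
    """Dempster's rule for two mass functions on the same frame.

    The conflict ``K`` is the total product mass of focal-set pairs with
    empty intersection; the surviving products are renormalised by
    ``1 / (1 − K)``.  ``K = 1`` (all pairs disjoint) means the evidences are
    non-combinable and raises :class:`TotalConflictError`.
    """
    if set(m1.frame) != set(m2.frame):
        raise FrameMismatchError(
            f"frames differ: {sorted(m1.frame)} vs {sorted(m2.frame)}"
        )
    products: dict[frozenset, float] = {}
    conflict = 0.0
    for a, va in m1.items():
        for b, vb in m2.items():
            inter = a & b
            if inter:
                products[inter] = products.get(inter, 0.0) + va * vb
            else:
                conflict += va * vb
    if conflict >= 1.0 - _MASS_TOL:
        raise TotalConflictError(
            f"total conflict (K = {conflict:.6f}); evidences are non-combinable"
        )
    norm = 1.0 / (1.0 - conflict)
    combined = MassFunction(
        m1.frame, {tuple(sorted(k)): v * norm for k, v in products.items()}
    )
    return CombinationResult(combined, conflict)


def combine_all(masses: Sequence[MassFunction]) -> MassFunction:
    """n-ary Dempster combination as a left fold of pairwise combinations.

    Dempster's rule is commutative and associative, so the fold equals the
    single-normalisation n-ary formula and is independent of input order.
    """
    if not masses:
        raise ValueError("need at least one mass function")
    acc = masses[0]
    for m in masses[1:]:
        acc = combine2(acc, m).combined
    return acc


def belief(m: MassFunction, subset: Iterable[str] | str) -> float:
    """Bel(A): the sum of masses of all focal sets contained in ``A``."""
    if subset == THETA:
        target = frozenset(m.frame)
    else:
        target = frozenset([subset] if isinstance(subset, str) else subset)
    stray = target - frozenset(m.frame)
    if stray:
        raise ValueError(f"labels {sorted(stray)} are not in the frame")
    return sum(v for focal, v in m.items() if focal <= target)
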