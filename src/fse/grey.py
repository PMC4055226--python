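"""Grey relational analysis of a fuzzy soft decision matrix.

Each alternative's memberships are compared against their own row mean: the
absolute deviations form the difference matrix, which is rescaled column-wise
(per parameter, min/max over alternatives) into grey mean relational degrees
in (0, 1].  The q-norm column average of those degrees is the parameter's
uncertainty degree (DOI): a parameter whose memberships all sit close to the
row means discriminates poorly between alternatives and carries a high DOI,
so its evidence is later discounted.  Column normalisation of the decision
matrix (the information structure image) turns each parameter's memberships
into a distribution over alternatives, ready for mass construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FuzzySoftSet

__all__ = [
    "GreyResult",
    "ImageMatrix",
    "row_means",
    "difference_matrix",
    "grey_relational_matrix",
    "uncertainty_degrees",
    "information_structure_image",
    "grey_analysis",
]


@dataclass(frozen=True)
class GreyResult:
    """All intermediates of the grey relational chain on one decision matrix."""

    objects: tuple[str, ...]
    parameters: tuple[str, ...]
    row_means: np.ndarray       # length m, mean membership of each alternative
    delta: np.ndarray           # m x n, |d_ij - mean_i|
    relational: np.ndarray      # m x n grey mean relational degrees in (0, 1]
    doi: np.ndarray             # length n uncertainty degrees
    rho: float
    q: float

    @property
    def mean_doi(self) -> float:
        """Average uncertainty degree over all parameters."""
        return float(self.doi.mean())


@dataclass(frozen=True)
class ImageMatrix:
    """Column-normalised decision matrix: each column sums to one."""

    objects: tuple[str, ...]
    parameters: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if np.any(vals < 0):
            raise ValueError("image matrix entries must be non-negative")
        if not np.allclose(vals.sum(axis=0), 1.0, atol=1e-12, rtol=0.0):
            raise ValueError("image matrix columns must sum to 1")
        vals = vals.copy()
        vals.setflags(write=False)
        object.__setattr__(self, "values", vals)


def row_means(f: FuzzySoftSet) -> np.ndarray:
    """Mean membership of each alternative across all parameters."""
    return f.values.mean(axis=1)


def difference_matrix(f: FuzzySoftSet, means: np.ndarray | None = None) -> np.ndarray:
    """Absolute deviation of each membership from its alternative's mean."""
    if means is None:
        means = row_means(f)
    means = np.asarray(means, dtype=float)
    if means.shape != (f.n_objects,):
        raise ValueError("means must have one entry per object")
    return np.abs(f.values - means[:, None])


def grey_relational_matrix(delta: np.ndarray, rho: float = 0.5) -> np.ndarray:
    """Grey mean relational degrees from a difference matrix.

    Per parameter column ``j`` with ``a = min_i Δ_ij`` and ``b = max_i Δ_ij``:
    ``r_ij = (a + rho·b) / (Δ_ij + rho·b)``.  The distinguishing coefficient
    ``rho`` in (0, 1) compresses or expands the spread of the degrees.  A
    degenerate column (``b = 0``: every alternative exactly at its row mean)
    is assigned the constant 1, the continuous limit as the deviations vanish.
    """
    if not 0.0 < rho < 1.0:
        raise ValueError(f"distinguishing coefficient rho={rho} outside (0, 1)")
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise ValueError("difference matrix entries must be non-negative")
    a = delta.min(axis=0)
    b = delta.max(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a + rho * b) / (delta + rho * b)
    return np.where(b > 0, r, 1.0)


def uncertainty_degrees(relational: np.ndarray, q: float = 2.0) -> np.ndarray:
    """q-order uncertainty degree of each parameter.

    ``DOI(e_j) = (1/m) · (Σ_i r_ij^q)^(1/q)``, always in ``(0, m^(-1/2)]``
    for q = 2 since every relational degree lies in (0, 1].
    """
    if q < 1:
        raise ValueError("order q must be >= 1")
    relational = np.asarray(relational, dtype=float)
    m = relational.shape[0]
    return (1.0 / m) * (np.sum(relational**q, axis=0)) ** (1.0 / q)


def information_structure_image(f: FuzzySoftSet) -> ImageMatrix:
    """Column-normalise the decision matrix into per-parameter distributions.

    Raises
    ------
    ValueError
        If some parameter has zero total membership: such a parameter carries
        no evidence about any alternative and must be dropped explicitly by
        the caller rather than silently redistributed.
    """
    sums = f.values.sum(axis=0)
    if np.any(sums <= 0):
        bad = [f.parameters[j] for j in np.flatnonzero(sums <= 0)]
        raise ValueError(
            f"parameter(s) {bad} have zero total membership and carry no "
            "evidence; drop them before normalising"
        )
    return ImageMatrix(f.objects, f.parameters, f.values / sums)


def grey_analysis(f: FuzzySoftSet, rho: float = 0.5, q: float = 2.0) -> GreyResult:
    """Run the full grey relational chain on a fuzzy soft decision matrix."""
    means = row_means(f)
    delta = difference_matrix(f, means)
    relational = grey_relational_matrix(delta, rho=rho)
    doi = uncertainty_degrees(relational, q=q)
    return GreyResult(
        f.objects, f.parameters, means, delta, relational, doi, float(rho), float(q)
    )
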