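"""End-to-end decision pipelines over fuzzy soft sets.

Two methods are provided.  ``gds_decide`` runs the grey-relational /
Dempster-Shafer chain: grey analysis yields per-parameter uncertainty
degrees, each parameter becomes a mass function discounted by its
uncertainty, and Dempster's rule fuses the parameter evidences into a single
belief assignment over the alternatives.  ``mean_potentiality_decide`` is the
level-soft-set baseline: threshold first at the grand mean of all
memberships, then at the mean column spread, and break remaining ties by the
smallest row spread.  ``compare_methods`` scores both methods' optima with
the performance measure Υ.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np

from .core import (
    FuzzySoftSet,
    level_soft_set,
    max_significant_figures,
    object_spreads,
    parameter_spreads,
    performance_measure,
    round_sig,
)
from .evidence import MassFunction, build_mass_functions, combine_all
from .grey import GreyResult, ImageMatrix, grey_analysis, information_structure_image

__all__ = [
    "DecisionReport",
    "MPReport",
    "ComparisonResult",
    "TiedOptimumError",
    "gds_decide",
    "mean_potentiality_decide",
    "normal_parameter_reduction",
    "compare_methods",
]

_TIE_TOL = 1e-12


class TiedOptimumError(ValueError):
    """A method returned several tied optima where a unique one is needed."""


def _ranking_groups(labels: Sequence[str], scores: Sequence[float]) -> list[list[str]]:
    """Labels sorted by score descending, exact ties grouped together."""
    order = sorted(range(len(labels)), key=lambda i: (-scores[i], labels[i]))
    groups: list[list[str]] = []
    last = None
    for i in order:
        if last is not None and abs(scores[i] - last) <= _TIE_TOL:
            groups[-1].append(labels[i])
        else:
            groups.append([labels[i]])
        last = scores[i]
    return groups


@dataclass(frozen=True)
class DecisionReport:
    """Result of the grey + evidence-combination pipeline."""

    method: str
    objects: tuple[str, ...]
    combined: dict[str, float]          # combined singleton mass per alternative
    theta_mass: float                   # residual ignorance after combination
    mean_doi: float                     # mean input uncertainty before combination
    ranking: list[list[str]]            # descending, exact ties grouped
    optimal: list[str]                  # every argmax of the combined mass
    grey: GreyResult | None = field(default=None, compare=False)
    image: ImageMatrix | None = field(default=None, compare=False)
    parameter_masses: list[MassFunction] | None = field(default=None, compare=False)

    def summary(self) -> str:
        rank = " ≻ ".join(
            group[0] if len(group) == 1 else "{" + ", ".join(group) + "}"
            for group in self.ranking
        )
        return (
            f"method: {self.method}\n"
            f"ranking: {rank}\n"
            f"optimal: {', '.join(self.optimal)}\n"
            f"residual uncertainty m(Θ): {self.theta_mass:.4f} "
            f"(mean input uncertainty {self.mean_doi:.4f})"
        )


@dataclass(frozen=True)
class MPReport:
    """Full trace of the mean potentiality baseline."""

    reduction: tuple[str, ...] | None   # remaining parameters if a reduction exists
    mean_potentiality: float            # grand mean m_p before rounding
    mean_potentiality_rounded: float    # m_p' at the data's significant figures
    first_choice_values: dict[str, int]
    alpha: float | None                 # mean column spread, None if stopped early
    alpha_rounded: float | None
    second_choice_values: dict[str, int] | None
    beta: dict[str, float] | None       # per-object row spreads
    stage: int                          # 4, 8 or 9: where the decision resolved
    optimal: list[str]

    def summary(self) -> str:
        lines = [
            "method: mean_potentiality",
            f"m_p = {self.mean_potentiality:.6g} -> {self.mean_potentiality_rounded}",
            f"choice values: {self.first_choice_values}",
        ]
        if self.alpha is not None:
            lines.append(f"alpha = {self.alpha:.6g} -> {self.alpha_rounded}")
            lines.append(f"second choice values: {self.second_choice_values}")
        lines.append(f"resolved at stage {self.stage}; optimal: {', '.join(self.optimal)}")
        return "\n".join(lines)


@dataclass(frozen=True)
class ComparisonResult:
    """Both methods' optima and performance measures on one decision table."""

    gds_optimal: str
    mp_optimal: str
    gds_performance: float
    mp_performance: float
    better: str                         # "grey_ds" | "mean_potentiality" | "same"


def gds_decide(
    f: FuzzySoftSet, rho: float = 0.5, q: float = 2.0, keep_intermediates: bool = True
) -> DecisionReport:
    """Rank alternatives by combining grey-discounted parameter evidences.

    Chain: row means → difference matrix → grey relational degrees (with
    distinguishing coefficient ``rho``) → q-order uncertainty degrees →
    column-normalised image → one mass function per parameter → Dempster
    combination.  Alternatives are ranked by combined singleton mass (equal
    to the belief of the singleton); every argmax is reported as optimal.
    """
    grey = grey_analysis(f, rho=rho, q=q)
    image = information_structure_image(f)
    masses = build_mass_functions(image, grey.doi)
    fused = combine_all(masses)
    singles = {x: fused.mass(x) for x in f.objects}
    scores = [singles[x] for x in f.objects]
    ranking = _ranking_groups(list(f.objects), scores)
    best = max(scores)
    optimal = [x for x in f.objects if abs(singles[x] - best) <= _TIE_TOL]
    return DecisionReport(
        method="grey_ds",
        objects=f.objects,
        combined=singles,
        theta_mass=fused.theta_mass,
        mean_doi=grey.mean_doi,
        ranking=ranking,
        optimal=optimal,
        grey=grey if keep_intermediates else None,
        image=image if keep_intermediates else None,
        parameter_masses=masses if keep_intermediates else None,
    )


def normal_parameter_reduction(
    f: FuzzySoftSet, max_subset_size: int = 3
) -> tuple[str, ...] | None:
    """Remaining parameters after removing the smallest dispensable subset.

    A parameter subset C is dispensable when every object gains the same
    total membership over C, so deleting C shifts all choice values equally
    and preserves their order.  Subsets are searched in increasing size up to
    ``max_subset_size`` (the search is combinatorial); C must be a proper
    subset.  Returns None when no dispensable subset exists.
    """
    n = f.n_parameters
    cap = min(max_subset_size, n - 1)
    for size in range(1, cap + 1):
        for combo in combinations(range(n), size):
            sums = f.values[:, combo].sum(axis=1)
            if np.ptp(sums) <= 1e-9:
                drop = set(combo)
                return tuple(p for j, p in enumerate(f.parameters) if j not in drop)
    return None


def mean_potentiality_decide(
    f: FuzzySoftSet,
    sig_figs: int | None = None,
    reduction: bool = True,
    max_reduction_size: int = 3,
) -> MPReport:
    """The level-soft-set baseline driven by the mean potentiality.

    After an optional normal parameter reduction, the grand mean of all
    memberships (the mean potentiality m_p, rounded to the data's maximum
    significant figures) thresholds the table; a unique maximal choice value
    decides immediately (stage 4).  Otherwise the mean column spread α
    (rounded likewise) thresholds a second time (stage 8), and any remaining
    tie goes to the tied object with the smallest row spread β (stage 9).

    ``sig_figs`` overrides the significant-figure count when the set was not
    parsed from text.
    """
    kept = normal_parameter_reduction(f, max_reduction_size) if reduction else None
    work = f.restrict(kept) if kept is not None else f
    rho_figs = max_significant_figures(work, override=sig_figs)

    m_p = float(work.values.mean())
    m_p_rounded = round_sig(m_p, rho_figs)
    first_level = level_soft_set(work, m_p_rounded)
    first_cv = {x: int(c) for x, c in zip(work.objects, first_level.choice_values)}
    best = max(first_cv.values())
    tied = [x for x in work.objects if first_cv[x] == best]
    if len(tied) == 1:
        return MPReport(
            kept, m_p, m_p_rounded, first_cv,
            None, None, None, None, stage=4, optimal=tied,
        )

    alpha_per_param = parameter_spreads(work)
    beta_per_object = object_spreads(work)
    beta = {x: float(b) for x, b in zip(work.objects, beta_per_object)}
    alpha = float(alpha_per_param.mean())
    alpha_rounded = round_sig(alpha, rho_figs)
    second_level = level_soft_set(work, alpha_rounded)
    second_cv = {x: int(c) for x, c in zip(work.objects, second_level.choice_values)}
    best2 = max(second_cv.values())
    tied2 = [x for x in work.objects if second_cv[x] == best2]
    if len(tied2) == 1:
        return MPReport(
            kept, m_p, m_p_rounded, first_cv,
            alpha, alpha_rounded, second_cv, beta, stage=8, optimal=tied2,
        )

    # stage 9: among the objects still tied, the smallest row spread wins
    min_beta = min(beta[x] for x in tied2)
    optimal = [x for x in tied2 if abs(beta[x] - min_beta) <= _TIE_TOL]
    return MPReport(
        kept, m_p, m_p_rounded, first_cv,
        alpha, alpha_rounded, second_cv, beta, stage=9, optimal=optimal,
    )


def compare_methods(
    f: FuzzySoftSet,
    rho: float = 0.5,
    q: float = 2.0,
    sig_figs: int | None = None,
) -> ComparisonResult:
    """Score both pipelines' optima with the performance measure Υ.

    Υ depends only on the chosen optimum's membership row, so equal optima
    give equal performance.  Either method returning a tied optimal set is an
    error: Υ needs a single chosen object.
    """
    gds = gds_decide(f, rho=rho, q=q, keep_intermediates=False)
    mp = mean_potentiality_decide(f, sig_figs=sig_figs)
    if len(gds.optimal) != 1:
        raise TiedOptimumError(f"grey_ds optimum is tied: {gds.optimal}")
    if len(mp.optimal) != 1:
        raise TiedOptimumError(f"mean_potentiality optimum is tied: {mp.optimal}")
    y_gds = performance_measure(f, gds.optimal[0])
    y_mp = performance_measure(f, mp.optimal[0])
    if abs(y_gds - y_mp) <= _TIE_TOL:
        better = "same"
    elif y_gds > y_mp:
        better = "grey_ds"
    else:
        better = "mean_potentiality"
    return ComparisonResult(gds.optimal[0], mp.optimal[0], y_gds, y_mp, better)
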