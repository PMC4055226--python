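"""Reading, writing and generating fuzzy soft sets; JSON report output.

The on-disk format is plain comma-separated text: a header row of parameter
labels, one row per object with its label in the first cell, memberships as
decimals in [0, 1].  Parsing keeps each cell's textual form so the
significant-figure logic of the mean potentiality method can recover the
precision the numbers were written with.
"""

from __future__ import annotations

import csv
import io as _io
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any

import numpy as np

from .core import FuzzySoftSet, count_sig_figs
from .decide import ComparisonResult, DecisionReport, MPReport
from .evidence import MassFunction
from .grey import GreyResult, ImageMatrix

__all__ = [
    "read_fss",
    "parse_fss",
    "write_fss",
    "fss_to_csv",
    "synth_fss",
    "report_to_dict",
    "write_report",
]


def parse_fss(text: str, name: str = "<string>") -> FuzzySoftSet:
    """Parse a fuzzy soft set from delimited text, recording cell precision."""
    rows = [r for r in csv.reader(_io.StringIO(text)) if any(c.strip() for c in r)]
    if len(rows) < 2:
        raise ValueError(f"{name}: need a header row and at least one object row")
    params = [c.strip() for c in rows[0][1:]]
    objects: list[str] = []
    values: list[list[float]] = []
    precision: list[list[int]] = []
    for i, row in enumerate(rows[1:], start=2):
        if len(row) != len(params) + 1:
            raise ValueError(
                f"{name} row {i}: expected {len(params) + 1} cells, got {len(row)}"
            )
        objects.append(row[0].strip())
        vals, precs = [], []
        for j, cell in enumerate(row[1:]):
            where = f"{name} row {i} (object {row[0].strip()!r}), column {params[j]!r}"
            try:
                v = float(cell)
                p = count_sig_figs(cell)
            except ValueError:
                raise ValueError(f"{where}: {cell.strip()!r} is not a number") from None
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{where}: membership {cell.strip()} outside [0, 1]")
            vals.append(v)
            precs.append(p)
        values.append(vals)
        precision.append(precs)
    return FuzzySoftSet(tuple(objects), tuple(params), np.array(values), np.array(precision))


def read_fss(path: str | Path) -> FuzzySoftSet:
    """Read a fuzzy soft set from a comma-separated text file."""
    path = Path(path)
    return parse_fss(path.read_text(), name=path.name)


def fss_to_csv(f: FuzzySoftSet) -> str:
    """Render a fuzzy soft set as delimited text (shortest exact decimals)."""
    buf = _io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["", *f.parameters])
    for i, obj in enumerate(f.objects):
        writer.writerow([obj, *(repr(float(v)) for v in f.values[i])])
    return buf.getvalue()


def write_fss(f: FuzzySoftSet, path: str | Path) -> None:
    Path(path).write_text(fss_to_csv(f))


def synth_fss(m: int, n: int, seed: int, decimals: int = 2) -> FuzzySoftSet:
    """A seeded random fuzzy soft set for property tests and demos.

    Memberships are independent uniforms on [0, 1] written to ``decimals``
    decimal places; the same seed always reproduces the same set.  Labels are
    ``x1..xm`` and ``e1..en``.
    """
    if m < 1 or n < 1:
        raise ValueError("need at least one object and one parameter")
    if decimals < 1:
        raise ValueError("decimals must be >= 1")
    rng = np.random.default_rng(seed)
    raw = rng.uniform(0.0, 1.0, size=(m, n))
    # go through the text form so values and recorded precision agree exactly
    cells = [[f"{v:.{decimals}f}" for v in row] for row in raw]
    values = np.array([[float(c) for c in row] for row in cells])
    precision = np.array([[count_sig_figs(c) for c in row] for row in cells])
    return FuzzySoftSet(
        tuple(f"x{i + 1}" for i in range(m)),
        tuple(f"e{j + 1}" for j in range(n)),
        values,
        precision,
    )


# -- report serialization -------------------------------------------------


def _num(x: float) -> dict[str, float]:
    """Full-precision value plus a 4-decimal display rendering."""
    x = float(x)
    return {"value": x, "display": round(x, 4)}


def _matrix(values: np.ndarray) -> list[list[float]]:
    return [[float(v) for v in row] for row in np.asarray(values)]


def _grey_dict(g: GreyResult) -> dict[str, Any]:
    return {
        "rho": g.rho,
        "q": g.q,
        "row_means": {x: _num(v) for x, v in zip(g.objects, g.row_means)},
        "delta": _matrix(g.delta),
        "relational": _matrix(g.relational),
        "doi": {e: _num(v) for e, v in zip(g.parameters, g.doi)},
        "mean_doi": _num(g.mean_doi),
    }


def report_to_dict(report: Any) -> dict[str, Any]:
    """Convert any pipeline result into a JSON-serialisable dictionary."""
    if isinstance(report, DecisionReport):
        out: dict[str, Any] = {
            "method": report.method,
            "combined_mass": {x: _num(v) for x, v in report.combined.items()},
            "theta_mass": _num(report.theta_mass),
            "mean_input_uncertainty": _num(report.mean_doi),
            "ranking": report.ranking,
            "optimal": report.optimal,
        }
        intermediates: dict[str, Any] = {}
        if report.grey is not None:
            intermediates["grey"] = _grey_dict(report.grey)
        if report.image is not None:
            intermediates["image"] = _matrix(report.image.values)
        if report.parameter_masses is not None:
            intermediates["parameter_masses"] = [
                {k: _num(v) for k, v in m.to_dict().items()}
                for m in report.parameter_masses
            ]
        if intermediates:
            out["intermediates"] = intermediates
        return out
    if isinstance(report, MPReport):
        return {
            "method": "mean_potentiality",
            "reduction": list(report.reduction) if report.reduction else None,
            "mean_potentiality": _num(report.mean_potentiality),
            "mean_potentiality_rounded": report.mean_potentiality_rounded,
            "first_choice_values": report.first_choice_values,
            "alpha": None if report.alpha is None else _num(report.alpha),
            "alpha_rounded": report.alpha_rounded,
            "second_choice_values": report.second_choice_values,
            "beta": None
            if report.beta is None
            else {x: _num(v) for x, v in report.beta.items()},
            "stage": report.stage,
            "optimal": report.optimal,
        }
    if isinstance(report, ComparisonResult):
        return {
            "method": "compare",
            "grey_ds": {
                "optimal": report.gds_optimal,
                "performance": _num(report.gds_performance),
            },
            "mean_potentiality": {
                "optimal": report.mp_optimal,
                "performance": _num(report.mp_performance),
            },
            "better": report.better,
        }
    if isinstance(report, GreyResult):
        return _grey_dict(report)
    if isinstance(report, ImageMatrix):
        return {"objects": list(report.objects), "parameters": list(report.parameters),
                "image": _matrix(report.values)}
    if isinstance(report, MassFunction):
        return {k: _num(v) for k, v in report.to_dict().items()}
    if is_dataclass(report):
        return asdict(report)
    raise TypeError(f"cannot serialise {type(report).__name__}")


def write_report(report: Any, path: str | Path) -> None:
    """Write a pipeline result as deterministic JSON (sorted keys)."""
    Path(path).write_text(
        json.dumps(report_to_dict(report), indent=2, sort_keys=True) + "\n"
    )
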