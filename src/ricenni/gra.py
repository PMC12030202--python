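"""Gray relational analysis (Deng) for vegetation-index screening.

The NNI series of the plots is the reference sequence; each vegetation
index is a comparison sequence.  After non-dimensionalisation, the
relational coefficient at position k is

    gamma_oi(k) = (Dmin + rho * Dmax) / (D_oi(k) + rho * Dmax)

with D_oi(k) = |x0(k) - xi(k)|, Dmin/Dmax the global minimum/maximum of
those differences over ALL comparison series jointly, and rho the
resolution coefficient (0.5 by convention).  The relational degree of a
series is the arithmetic mean of its coefficients; indices whose degree
clears a threshold in every growth stage are selected for the inversion
model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RelationalResult",
    "normalize_series",
    "relational_coefficients",
    "relational_degree",
    "gray_relational_analysis",
    "rank_and_select",
]


@dataclass
class RelationalResult:
    """Coefficients, degrees and ranking of one gray relational run."""

    coefficients: dict  # name -> coefficient sequence
    degrees: dict  # name -> scalar degree
    rank: list  # names, best first
    delta_min: float
    delta_max: float
    rho: float
    degree_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def normalize_series(reference, comparisons: dict, method: str = "mean") -> tuple:
    """Non-dimensionalise the reference and comparison sequences.

    ``method="mean"`` divides each sequence by its own mean (default);
    ``method="initial"`` divides by its first element.  Sequences whose
    normaliser is zero are rejected.
    """
    if method not in ("mean", "initial"):
        raise ValueError("method must be 'mean' or 'initial'")

    def _norm(x, label):
        x = np.asarray(x, dtype=float)
        if x.size < 2:
            raise ValueError(f"series {label!r} must have length >= 2")
        denom = x.mean() if method == "mean" else x[0]
        if denom == 0:
            raise ValueError(f"series {label!r} has zero {method} value; cannot normalise")
        return x / denom

    ref = _norm(reference, "reference")
    comps = {name: _norm(series, name) for name, series in comparisons.items()}
    lengths = {len(ref)} | {len(v) for v in comps.values()}
    if len(lengths) != 1:
        raise ValueError("all sequences must share the same length")
    return ref, comps


def _deltas(reference, comparisons: dict) -> dict:
    ref = np.asarray(reference, dtype=float)
    out = {}
    for name, series in comparisons.items():
        series = np.asarray(series, dtype=float)
        if series.shape != ref.shape:
            raise ValueError(f"series {name!r} length differs from the reference")
        out[name] = np.abs(ref - series)
    return out


def relational_coefficients(reference, comparison, all_comparisons: dict, rho: float = 0.5):
    """Deng relational coefficients of one comparison series.

    Dmin and Dmax are taken over ``all_comparisons`` jointly (the series
    itself included).  When Dmax is zero - every series identical to the
    reference - the coefficients are defined as 1.
    """
    if not 0 <= rho <= 1:
        raise ValueError("rho must lie in [0, 1]")
    deltas = _deltas(reference, dict(all_comparisons))
    delta = _deltas(reference, {"_": comparison})["_"]
    stacked = np.concatenate(list(deltas.values()))
    d_min, d_max = float(stacked.min()), float(stacked.max())
    if d_max == 0.0:
        return np.ones_like(delta)
    return (d_min + rho * d_max) / (delta + rho * d_max)


def relational_degree(coefficients) -> float:
    """Gray relational degree: arithmetic mean of the coefficients."""
    coefficients = np.asarray(coefficients, dtype=float)
    if coefficients.size == 0:
        raise ValueError("empty coefficient sequence")
    return float(coefficients.mean())


def gray_relational_analysis(
    reference, comparisons: dict, rho: float = 0.5, normalize: str | None = "mean"
) -> RelationalResult:
    """Full run: normalise, coefficients per series, degrees and ranking.

    ``normalize=None`` skips non-dimensionalisation (useful when the
    inputs are already commensurate).  Ranking is by descending degree
    with ties broken by the input ordering of ``comparisons``.
    """
    if normalize is not None:
        reference, comparisons = normalize_series(reference, comparisons, method=normalize)
    deltas = _deltas(reference, comparisons)
    stacked = np.concatenate(list(deltas.values()))
    d_min, d_max = float(stacked.min()), float(stacked.max())
    coeffs = {}
    for name, delta in deltas.items():
        if d_max == 0.0:
            coeffs[name] = np.ones_like(delta)
        else:
            coeffs[name] = (d_min + rho * d_max) / (delta + rho * d_max)
    degrees = {name: relational_degree(c) for name, c in coeffs.items()}
    order = list(comparisons)
    rank = sorted(order, key=lambda n: (-degrees[n], order.index(n)))
    table = pd.DataFrame({"index": list(degrees), "degree": list(degrees.values())})
    table["rank"] = table["degree"].rank(ascending=False, method="first").astype(int)
    return RelationalResult(
        coefficients=coeffs,
        degrees=degrees,
        rank=rank,
        delta_min=d_min,
        delta_max=d_max,
        rho=rho,
        degree_table=table.sort_values("rank").reset_index(drop=True),
    )


def rank_and_select(
    degrees_by_stage: dict, threshold: float = 0.7, order: tuple | None = None
) -> list:
    """Select indices whose degree clears ``threshold`` in every stage.

    ``degrees_by_stage`` maps stage -> {index name -> degree}.  The
    selection is ranked by descending mean degree across stages; ties
    break by ``order`` (defaults to first-seen order).  An empty
    selection triggers a warning.
    """
    if not degrees_by_stage:
        raise ValueError("no stages supplied")
    stages = list(degrees_by_stage)
    names = list(degrees_by_stage[stages[0]])
    for stage in stages[1:]:
        if set(degrees_by_stage[stage]) != set(names):
            raise ValueError("all stages must report the same index set")
    if order is None:
        order = tuple(names)
    selected = [
        n for n in names if all(degrees_by_stage[s][n] > threshold for s in stages)
    ]
    if not selected:
        warnings.warn(f"no index exceeds degree {threshold} in every stage", stacklevel=2)
    mean_degree = {n: float(np.mean([degrees_by_stage[s][n] for s in stages])) for n in names}
    selected.sort(key=lambda n: (-mean_degree[n], order.index(n)))
    return selected
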