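"""Cell-division bookkeeping and effective population size of MA lines.

Each transfer of an MA line founds a colony from a single cell; the
number of divisions T between transfers is estimated as log2 of the
colony-forming units (CFU) of the grown colony.  Because the colony
expands geometrically through population sizes 1, 2, 4, ..., 2^T, the
effective population size relevant to drift is the harmonic mean of
those sizes:

    Ne = (T + 1) / sum_{i=0}^{T} 2^(-i) = (T + 1) / (2 - 2^(-T)),

which the closed form extends continuously to non-integer T (an
average over colonies).  Ne of order 10 means drift overwhelms
selection for all but strongly deleterious mutations.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence, Union

import numpy as np

__all__ = [
    "divisions_per_transfer_from_cfu",
    "total_divisions",
    "effective_population_size",
]


def divisions_per_transfer_from_cfu(
    cfu_values: Union[Sequence[float], Sequence[Sequence[float]]],
    method: str = "geometric",
) -> float:
    """Divisions per transfer, T, from colony-forming-unit counts.

    A colony grown from one cell reaches 2^T cells, so T = log2(CFU).
    The default averages on the log scale (geometric mean of CFU),
    which is unbiased for T under multiplicative count noise;
    ``method="arithmetic"`` takes log2 of the arithmetic mean CFU
    instead.  A nested sequence is treated as multiple sampling
    rounds and the grand mean of the per-round estimates is returned.
    """
    cfu_values = list(cfu_values)
    if not cfu_values:
        raise ValueError("no CFU values")
    if isinstance(cfu_values[0], (Sequence, np.ndarray)) and \
            not isinstance(cfu_values[0], (str, bytes)):
        return float(np.mean([
            divisions_per_transfer_from_cfu(round_vals, method=method)
            for round_vals in cfu_values
        ]))
    arr = np.asarray(cfu_values, dtype=float)
    if np.any(arr < 1):
        raise ValueError("CFU values must be >= 1 (a colony has at least one cell)")
    if method == "geometric":
        return float(np.mean(np.log2(arr)))
    if method == "arithmetic":
        return float(np.log2(arr.mean()))
    raise ValueError(f"unknown method {method!r}")


def total_divisions(grand_mean_T: float, transfers: int) -> float:
    """Total cell divisions of a line: grand-mean T times total transfers."""
    if grand_mean_T <= 0 or transfers <= 0:
        raise ValueError("both factors must be positive")
    return grand_mean_T * transfers


def effective_population_size(T: float) -> float:
    """Harmonic-mean Ne over the T doublings of a single-cell bottleneck.

    Ne = (T + 1) / (2 - 2^(-T)); for integer T this equals the
    explicit harmonic mean of 1, 2, ..., 2^T, and the closed form is
    monotone and continuous in between.  Ne -> (T + 1)/2 as T grows.
    """
    if T < 0:
        raise ValueError(f"T must be non-negative, got {T}")
    return (T + 1) / (2.0 - 2.0 ** (-T))
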