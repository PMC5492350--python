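"""Trajectory-average binding enthalpy with block-averaged uncertainty.

The binding enthalpy of a complex is estimated as the difference of
trajectory-averaged internal energies,

    E_b = <U_complex> - <U_component1> - <U_component2>,

where each average is taken over the full series from a separate simulation
(the three series may therefore differ in length).  More negative E_b means
more favorable binding.

MD energy series are autocorrelated, so naive standard errors understate the
uncertainty; each term's standard error is instead obtained by block
averaging (split the series into contiguous blocks, take the sd of block
means over sqrt(n_blocks)) and the three are combined in quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure_io import EnergySeries

__all__ = [
    "BindingEnergyResult",
    "VariantComparison",
    "binding_enthalpy",
    "block_standard_error",
    "compare_variants",
]

DEFAULT_N_BLOCKS = 10


@dataclass(frozen=True)
class BindingEnergyResult:
    """E_b estimate with block-averaged standard error.

    ``n_frames`` holds the (complex, component1, component2) series lengths.
    """

    e_b: float
    se: float
    n_frames: tuple[int, int, int]
    block_size: int
    units: str = "kcal/mol"

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be non-negative")

    @property
    def indistinguishable_from_zero(self) -> bool:
        """True when |E_b| < 2 se — no resolvable binding signal."""
        return abs(self.e_b) < 2.0 * self.se


def block_standard_error(series: EnergySeries | np.ndarray, n_blocks: int = DEFAULT_N_BLOCKS) -> float:
    """Standard error of the series mean from ``n_blocks`` contiguous blocks.

    Blocks are as equal in size as possible (``numpy.array_split``).  The
    estimate is sd(block means, ddof=1) / sqrt(n_blocks).
    """
    values = series.values if isinstance(series, EnergySeries) else np.asarray(series, dtype=float)
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if values.size < n_blocks:
        raise ValueError(f"series length {values.size} < n_blocks {n_blocks}")
    block_means = np.array([b.mean() for b in np.array_split(values, n_blocks)])
    return float(np.std(block_means, ddof=1) / math.sqrt(n_blocks))


def _term_se(series: EnergySeries, n_blocks: int) -> float:
    n = len(series)
    if n == 1:
        return 0.0
    blocks = min(n_blocks, n)
    return block_standard_error(series, blocks)


def binding_enthalpy(
    u_cmplx: EnergySeries,
    u_m1: EnergySeries,
    u_m2: EnergySeries,
    n_blocks: int = DEFAULT_N_BLOCKS,
) -> BindingEnergyResult:
    """E_b = mean(u_cmplx) - mean(u_m1) - mean(u_m2), se in quadrature.

    Series shorter than ``n_blocks`` fall back to one block per frame
    (length-1 series contribute zero uncertainty).
    """
    e_b = u_cmplx.mean() - u_m1.mean() - u_m2.mean()
    se = math.sqrt(sum(_term_se(s, n_blocks) ** 2 for s in (u_cmplx, u_m1, u_m2)))
    return BindingEnergyResult(
        e_b=e_b,
        se=se,
        n_frames=(len(u_cmplx), len(u_m1), len(u_m2)),
        block_size=max(1, len(u_cmplx) // n_blocks),
        units=u_cmplx.units,
    )


@dataclass(frozen=True)
class VariantComparison:
    """Variants ordered most-favorable (lowest E_b) first."""

    order: tuple[str, ...]
    results: dict[str, BindingEnergyResult]
    pairwise: dict[tuple[str, str], tuple[float, float]]  # (delta e_b, propagated se)
    near_zero: tuple[str, ...]  # labels with |e_b| < 2 se

    def as_rows(self) -> list[tuple[str, float, float, str]]:
        return [
            (
                label,
                self.results[label].e_b,
                self.results[label].se,
                "indistinguishable from zero"
                if label in self.near_zero
                else "",
            )
            for label in self.order
        ]


def compare_variants(results: dict[str, BindingEnergyResult]) -> VariantComparison:
    """Rank labelled binding-enthalpy results, most favorable first.

    Labels whose estimate is within two standard errors of zero are flagged
    as indistinguishable from zero.  Pairwise differences carry standard
    errors propagated in quadrature (the underlying simulations are
    independent).
    """
    if len(results) < 2:
        raise ValueError("compare_variants requires at least two labelled results")
    order = tuple(sorted(results, key=lambda k: (results[k].e_b, k)))
    pairwise: dict[tuple[str, str], tuple[float, float]] = {}
    labels = list(order)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            delta = results[a].e_b - results[b].e_b
            se = math.sqrt(results[a].se ** 2 + results[b].se ** 2)
            pairwise[(a, b)] = (delta, se)
    near_zero = tuple(l for l in order if results[l].indistinguishable_from_zero)
    return VariantComparison(order=order, results=dict(results), pairwise=pairwise,
                             near_zero=near_zero)
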