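"""Precision tools: ratio standard errors, empirical CEs, sampling plans."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from .phantom import as_rng

__all__ = ["cochran_ratio_se", "empirical_ce", "SamplingPlan", "plan_sampling"]


def cochran_ratio_se(xs, ys) -> float:
    """Standard error of the pooled ratio R = sum(y) / sum(x) over images.

    Classical ratio-estimator form:
    SE(R) = sqrt( sum((y_i - R*x_i)^2) / (n-1) ) * sqrt(n) / sum(x).
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if len(x) != len(y):
        raise ValueError("xs and ys must have equal length")
    n = len(x)
    if n < 2:
        raise ValueError("at least two images are required for a ratio SE")
    sx = x.sum()
    if sx <= 0:
        raise ValueError("sum of denominators must be positive")
    R = y.sum() / sx
    resid = y - R * x
    return float(np.sqrt(np.sum(resid ** 2) / (n - 1)) * np.sqrt(n) / sx)


def empirical_ce(
    estimator: Callable[[np.random.Generator], float],
    n_replicates: int = 1000,
    seed=None,
) -> tuple[float, np.ndarray]:
    """Empirical coefficient of error CE = SD/mean over fresh random placements.

    ``estimator`` re-runs the full sampling + estimation pipeline with the
    generator it is handed; failures propagate with the replicate index.
    """
    if n_replicates < 100:
        raise ValueError("need at least 100 replicates for a stable CE")
    rng = as_rng(seed)
    values = np.empty(n_replicates)
    for i in range(n_replicates):
        try:
            values[i] = estimator(rng)
        except Exception as exc:  # noqa: BLE001 - annotate replicate and re-raise
            raise RuntimeError(f"estimator failed at replicate {i}") from exc
    mean = values.mean()
    ce = float(values.std(ddof=1) / mean) if mean != 0 else np.inf
    return ce, values


@dataclass
class SamplingPlan:
    total_sections: int
    sections_used: int
    spacing_k: Optional[float] = None  # um between used sections
    pair_spacing: Optional[int] = None  # sections between disector pairs
    directions: int = 2
    expected_structures: Optional[int] = None
    expected_Qminus: Optional[float] = None
    expected_points: Optional[float] = None
    warnings: list = field(default_factory=list)

    @property
    def sampling_fraction(self) -> float:
        return self.sections_used / self.total_sections

    @property
    def inverse_fraction(self) -> float:
        return self.total_sections / self.sections_used

    @property
    def count_multiplier(self) -> Optional[float]:
        if self.pair_spacing is None:
            return None
        return self.pair_spacing / self.directions


def plan_sampling(
    total_sections: int,
    sections_used: int,
    spacing_k: Optional[float] = None,
    pair_spacing: Optional[int] = None,
    directions: int = 2,
    expected_structures: Optional[int] = None,
    target_count_band: tuple = (100, 200),
) -> SamplingPlan:
    """Workload prediction for a parallel-section-stack design.

    Computes the sampling fraction, the inverse-fraction multiplier for total
    counts, and the expected disector yield E[Q-] = N * directions / spacing.
    An advisory warning is attached when expected counts per specimen fall
    outside the 100-200 band that normally suffices for comparative work.
    """
    if total_sections < 1 or sections_used < 1:
        raise ValueError("section counts must be positive")
    if sections_used > total_sections:
        raise ValueError("cannot use more sections than exist")
    if pair_spacing is not None and pair_spacing < 1:
        raise ValueError("pair spacing must be >= 1")
    plan = SamplingPlan(
        total_sections=total_sections,
        sections_used=sections_used,
        spacing_k=spacing_k,
        pair_spacing=pair_spacing,
        directions=directions,
        expected_structures=expected_structures,
    )
    if expected_structures is not None and pair_spacing is not None:
        plan.expected_Qminus = expected_structures * directions / pair_spacing
        lo, hi = target_count_band
        if not (lo <= plan.expected_Qminus <= hi):
            plan.warnings.append(
                f"expected counts {plan.expected_Qminus:.1f} outside the "
                f"{lo}-{hi} band (advisory)"
            )
    return plan
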