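"""Bias-corrected standardized mean difference (Hedges' g) per comparison.

Sign convention is treated minus control throughout, so "lower is better"
outcomes (e.g. feed conversion ratio, drip loss, abdominal fat) show
improvement as negative g. No per-outcome sign flipping is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from smdmeta.errors import DegenerateComparisonError, DomainError
from smdmeta.ingest import ComparisonRecord, normalize_arm

__all__ = ["EffectSize", "hedges_g", "effect_from_record"]


@dataclass
class EffectSize:
    """Hedges' g and its large-sample sampling variance for one comparison."""

    g: float
    var: float
    comparison: ComparisonRecord | None = None

    @property
    def se(self) -> float:
        return math.sqrt(self.var)


def hedges_g(
    mean_t: float,
    sd_t: float,
    n_t: int,
    mean_c: float,
    sd_c: float,
    n_c: int,
) -> EffectSize:
    """Compute Hedges' g = J * (mean_t - mean_c) / s_pooled.

    s_pooled uses the df-weighted pooled SD; J = 1 - 3/(4m - 1) with
    m = n_t + n_c - 2 is the small-sample bias correction; the variance is
    (n_t + n_c)/(n_t * n_c) + g^2 / (2 (n_t + n_c)).
    """
    if n_t < 2 or n_c < 2:
        raise DomainError(f"both arms need n >= 2, got n_t={n_t}, n_c={n_c}")
    if sd_t < 0 or sd_c < 0:
        raise DomainError("arm SDs must be non-negative")
    m = n_t + n_c - 2
    s_pooled = math.sqrt(((n_t - 1) * sd_t**2 + (n_c - 1) * sd_c**2) / m)
    if s_pooled == 0:
        if mean_t == mean_c:
            raise DegenerateComparisonError(
                "pooled SD is zero: comparison carries no information"
            )
        raise DegenerateComparisonError(
            "pooled SD is zero with unequal means: SMD undefined"
        )
    d = (mean_t - mean_c) / s_pooled
    j = 1.0 - 3.0 / (4.0 * m - 1.0)
    g = j * d
    n_total = n_t + n_c
    var = n_total / (n_t * n_c) + g**2 / (2.0 * n_total)
    return EffectSize(g=g, var=var)


def effect_from_record(record: ComparisonRecord) -> EffectSize:
    """Compute the effect size for one comparison record (SDs must already
    be normalized; a missing SD is filled from SE here as a convenience)."""
    c = normalize_arm(record.control)
    t = normalize_arm(record.treated)
    es = hedges_g(t.mean, t.sd, t.n, c.mean, c.sd, c.n)
    es.comparison = record
    return es
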