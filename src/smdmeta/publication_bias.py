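"""Publication-bias robustness via Rosenberg's weighted fail-safe number.

The fail-safe number is the count of mean-weight zero-effect studies that
must be added to lift the combined p-value of a significant pooled effect
to the target alpha. The decision rule: a pooled result is robust when
Nfs strictly exceeds 5n + 10, n being the number of pooled comparisons.

Reference variant uses fixed-effect weights; a random-effects variant
(weights 1/(var + tau^2)) is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from smdmeta.effect_size import EffectSize
from smdmeta.errors import DomainError
from smdmeta.pooling import dl_tau2

__all__ = [
    "BiasResult",
    "rosenberg_fsn",
    "robustness_threshold",
    "assess_robustness",
]


@dataclass
class BiasResult:
    """Fail-safe number bundled with the 5n+10 robustness decision."""

    Nfs: int
    n_comparisons: int
    threshold: int
    robust: bool
    observed_significance: float
    target_significance: float


def _weights(effects: Sequence[EffectSize], random_effects: bool) -> np.ndarray:
    v = np.array([e.var for e in effects], dtype=float)
    if np.any(v <= 0):
        raise DomainError("all sampling variances must be positive")
    if random_effects:
        return 1.0 / (v + dl_tau2(effects))
    return 1.0 / v


def _combined_p(effects: Sequence[EffectSize], w: np.ndarray) -> float:
    g = np.array([e.g for e in effects], dtype=float)
    z = np.sum(w * g) / math.sqrt(np.sum(w))
    return float(2.0 * stats.norm.sf(abs(z)))


def rosenberg_fsn(
    effects: Sequence[EffectSize],
    alpha: float = 0.05,
    random_effects: bool = False,
) -> int:
    """Rosenberg's weighted fail-safe number (ceiling-rounded integer).

    Nfs = ceil(max(0, ((sum w g)^2 / z_crit^2 - sum w) / mean(w))): the
    number of zero-effect studies at mean weight required to raise the
    weighted combined p to alpha. Returns 0 when the combined effect is
    already non-significant.
    """
    if len(effects) == 0:
        raise DomainError("need at least one effect")
    w = _weights(effects, random_effects)
    if _combined_p(effects, w) >= alpha:
        return 0
    g = np.array([e.g for e in effects], dtype=float)
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    s_wg = float(np.sum(w * g))
    s_w = float(np.sum(w))
    w_bar = s_w / len(effects)
    nfs = (s_wg**2 / z_crit**2 - s_w) / w_bar
    return int(math.ceil(max(0.0, nfs)))


def robustness_threshold(n_comparisons: int) -> int:
    """The 5n + 10 robustness cutoff for n pooled comparisons."""
    if n_comparisons < 0:
        raise DomainError(f"n_comparisons must be >= 0, got {n_comparisons}")
    return 5 * n_comparisons + 10


def assess_robustness(
    effects: Sequence[EffectSize],
    alpha: float = 0.05,
    random_effects: bool = False,
) -> BiasResult:
    """Bundle Nfs, the 5n+10 threshold, and the strict-inequality verdict."""
    nfs = rosenberg_fsn(effects, alpha, random_effects)
    n = len(effects)
    threshold = robustness_threshold(n)
    w = _weights(effects, random_effects)
    return BiasResult(
        Nfs=nfs,
        n_comparisons=n,
        threshold=threshold,
        robust=nfs > threshold,
        observed_significance=_combined_p(effects, w),
        target_significance=alpha,
    )
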