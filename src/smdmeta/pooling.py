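"""Fixed- and random-effects pooling, heterogeneity, and subgroup analysis.

The random-effects reference behaviour is DerSimonian-Laird tau-squared with
Wald z-based confidence intervals (symmetric about the estimate); REML is
available as an opt-in tau-squared method. Subgroup analyses estimate
tau-squared separately within each moderator level.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from smdmeta.effect_size import EffectSize, effect_from_record
from smdmeta.errors import DomainError
from smdmeta.ingest import ComparisonRecord, detect_shared_controls

__all__ = [
    "PooledResult",
    "Heterogeneity",
    "SubgroupLevel",
    "SubgroupTable",
    "fixed_effect_pool",
    "dl_tau2",
    "reml_tau2",
    "random_effects_pool",
    "heterogeneity",
    "i2_from_q",
    "q_partition",
    "subgroup_analysis",
]


@dataclass
class PooledResult:
    """Pooled SMD with Wald CI for a set of comparisons."""

    estimate: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    k: int
    model: str  # "fixed" or "random"


@dataclass
class Heterogeneity:
    """Cochran's Q, its p-value, I-squared (%), and tau-squared."""

    Q: float
    df: int
    p_Q: float
    I2: float
    tau2: float


@dataclass
class SubgroupLevel:
    """One moderator level of a subgroup table."""

    level: str
    k: int
    pooled: PooledResult
    het: Heterogeneity | None  # None when k == 1 (heterogeneity undefined)


@dataclass
class SubgroupTable:
    moderator: str
    outcome: str | None
    levels: list[SubgroupLevel]

    @property
    def total_k(self) -> int:
        return sum(lvl.k for lvl in self.levels)


def _arrays(effects: Sequence[EffectSize]) -> tuple[np.ndarray, np.ndarray]:
    g = np.array([e.g for e in effects], dtype=float)
    v = np.array([e.var for e in effects], dtype=float)
    if np.any(v <= 0):
        raise DomainError("all sampling variances must be positive")
    return g, v


def _wald_pool(g, v, k, alpha, model) -> PooledResult:
    w = 1.0 / v
    est = float(np.sum(w * g) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    z = est / se
    p = 2.0 * stats.norm.sf(abs(z))
    return PooledResult(
        estimate=est,
        ci_low=est - z_crit * se,
        ci_high=est + z_crit * se,
        z=z,
        p=float(p),
        k=k,
        model=model,
    )


def fixed_effect_pool(effects: Sequence[EffectSize], alpha: float = 0.05) -> PooledResult:
    """Inverse-variance weighted fixed-effect pool."""
    if len(effects) < 1:
        raise DomainError("need at least one effect to pool")
    g, v = _arrays(effects)
    return _wald_pool(g, v, len(effects), alpha, "fixed")


def _cochran_q(g: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    est = np.sum(w * g) / np.sum(w)
    return float(np.sum(w * (g - est) ** 2))


def i2_from_q(Q: float, df: int) -> float:
    """I-squared in percent: max(0, 100 (Q - df) / Q); 0 when Q == 0."""
    if Q <= 0:
        return 0.0
    return max(0.0, 100.0 * (Q - df) / Q)


def dl_tau2(effects: Sequence[EffectSize]) -> float:
    """DerSimonian-Laird method-of-moments between-study variance.

    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) with
    fixed-effect weights w = 1/var.
    """
    if len(effects) < 2:
        raise DomainError("tau^2 estimation needs k >= 2")
    g, v = _arrays(effects)
    w = 1.0 / v
    q = _cochran_q(g, v)
    c = np.sum(w) - np.sum(w**2) / np.sum(w)
    return max(0.0, float((q - (len(effects) - 1)) / c))


def reml_tau2(effects: Sequence[EffectSize]) -> float:
    """Restricted maximum-likelihood tau^2 (opt-in alternative to DL)."""
    if len(effects) < 2:
        raise DomainError("tau^2 estimation needs k >= 2")
    g, v = _arrays(effects)

    def neg_restricted_ll(tau2: float) -> float:
        wi = 1.0 / (v + tau2)
        mu = np.sum(wi * g) / np.sum(wi)
        return 0.5 * (
            np.sum(np.log(v + tau2))
            + math.log(np.sum(wi))
            + np.sum(wi * (g - mu) ** 2)
        )

    upper = max(dl_tau2(effects) * 10.0, float(np.var(g)) * 10.0, 1e-3)
    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(0.0, upper), method="bounded",
        options={"xatol": 1e-10},
    )
    return max(0.0, float(res.x))


_TAU2_METHODS = {"DL": dl_tau2, "REML": reml_tau2}


def heterogeneity(effects: Sequence[EffectSize]) -> Heterogeneity:
    """Cochran's Q with its chi-square p-value, I-squared, and DL tau^2."""
    if len(effects) < 2:
        raise DomainError("heterogeneity needs k >= 2")
    g, v = _arrays(effects)
    q = _cochran_q(g, v)
    df = len(effects) - 1
    return Heterogeneity(
        Q=q,
        df=df,
        p_Q=float(stats.chi2.sf(q, df)),
        I2=i2_from_q(q, df),
        tau2=dl_tau2(effects),
    )


def random_effects_pool(
    effects: Sequence[EffectSize],
    alpha: float = 0.05,
    tau2_method: str = "DL",
) -> tuple[PooledResult, Heterogeneity]:
    """Random-effects pool with weights 1/(var + tau^2).

    Returns the pooled result together with the heterogeneity summary
    (Q, I-squared computed from fixed-effect weights).
    """
    if len(effects) < 2:
        raise DomainError("random-effects pooling needs k >= 2")
    if tau2_method not in _TAU2_METHODS:
        raise DomainError(f"unknown tau2 method {tau2_method!r}")
    g, v = _arrays(effects)
    het = heterogeneity(effects)
    tau2 = _TAU2_METHODS[tau2_method](effects)
    het.tau2 = tau2
    pooled = _wald_pool(g, v + tau2, len(effects), alpha, "random")
    return pooled, het


def q_partition(
    effects: Sequence[EffectSize], labels: Sequence[str]
) -> tuple[float, float, float]:
    """Decompose the fixed-effect Q over a partition of the effects.

    Returns (Q_total, sum of within-group Q, between-group Q); the identity
    Q_total = Q_within + Q_between holds exactly with common fixed-effect
    weights.
    """
    if len(effects) != len(labels):
        raise DomainError("labels must align with effects")
    g, v = _arrays(effects)
    w = 1.0 / v
    q_total = _cochran_q(g, v)
    grand = np.sum(w * g) / np.sum(w)
    q_within = 0.0
    q_between = 0.0
    for lab in dict.fromkeys(labels):
        idx = [i for i, x in enumerate(labels) if x == lab]
        gw, ww = g[idx], w[idx]
        mean_g = np.sum(ww * gw) / np.sum(ww)
        q_within += float(np.sum(ww * (gw - mean_g) ** 2))
        q_between += float(np.sum(ww) * (mean_g - grand) ** 2)
    return q_total, q_within, q_between


def _single_effect_result(e: EffectSize, alpha: float) -> PooledResult:
    z_crit = stats.norm.ppf(1.0 - alpha / 2.0)
    se = e.se
    z = e.g / se
    return PooledResult(
        estimate=e.g,
        ci_low=e.g - z_crit * se,
        ci_high=e.g + z_crit * se,
        z=z,
        p=float(2.0 * stats.norm.sf(abs(z))),
        k=1,
        model="single",
    )


def subgroup_analysis(
    records: Sequence[ComparisonRecord],
    moderator: str,
    outcome: str | None = None,
    alpha: float = 0.05,
    tau2_method: str = "DL",
) -> SubgroupTable:
    """Random-effects pool within each level of a moderator.

    tau^2 is estimated separately per level. Levels with a single
    comparison report that effect with its own Wald CI and no
    heterogeneity. Comparisons sharing a control arm are flagged with a
    warning and pooled as independent.
    """
    if outcome is not None:
        records = [r for r in records if r.outcome == outcome]
    if not records:
        raise DomainError("no records to analyse")
    if detect_shared_controls(records):
        warnings.warn(
            "comparisons sharing a control arm detected; treated as independent",
            stacklevel=2,
        )
    groups: dict[str, list[ComparisonRecord]] = {}
    for r in records:
        groups.setdefault(str(r.moderator_level(moderator)), []).append(r)
    levels: list[SubgroupLevel] = []
    for label in sorted(groups):
        effects = [effect_from_record(r) for r in groups[label]]
        if len(effects) == 1:
            levels.append(
                SubgroupLevel(
                    level=label,
                    k=1,
                    pooled=_single_effect_result(effects[0], alpha),
                    het=None,
                )
            )
        else:
            pooled, het = random_effects_pool(effects, alpha, tau2_method)
            levels.append(SubgroupLevel(level=label, k=len(effects), pooled=pooled, het=het))
    return SubgroupTable(moderator=moderator, outcome=outcome, levels=levels)
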