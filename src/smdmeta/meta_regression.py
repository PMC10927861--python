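"""Mixed-effects meta-regression of effect sizes on study-level moderators.

Reference mode is univariable: one moderator per model, fitted separately
per outcome. Categorical moderators are dummy-coded against the
alphabetically-first level; dose can alternatively enter as a centered
continuous covariate. Residual tau-squared uses the method-of-moments
generalization of DerSimonian-Laird (REML opt-in), and QM is the Wald
chi-square on all non-intercept coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from smdmeta.effect_size import effect_from_record
from smdmeta.errors import DegenerateDesignError, DomainError
from smdmeta.ingest import ComparisonRecord
from smdmeta.pooling import dl_tau2, i2_from_q

__all__ = ["MetaRegResult", "fit_meta_regression"]


@dataclass
class MetaRegResult:
    """Moderator-model fit summary."""

    moderator: str
    outcome: str | None
    k: int
    coef_names: list[str]
    coefficients: np.ndarray
    coef_se: np.ndarray
    QM: float
    df_M: int
    p_QM: float
    QE: float
    p_QE: float
    tau2_resid: float
    tau2_total: float
    I2_resid: float
    R2: float
    grand_mean: float  # inverse-variance weighted grand mean of the effects
    alpha: float = 0.05

    def coefficient(self, name: str) -> float:
        return float(self.coefficients[self.coef_names.index(name)])


def _mom_tau2(y: np.ndarray, v: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    """Method-of-moments residual tau^2 for a weighted linear model.

    Uses fixed-effect weights W = diag(1/v) and the projection
    P = W - W X (X' W X)^{-1} X' W; returns (tau2, QE) where
    QE = y' P y and tau2 = max(0, (QE - (k - p)) / tr(P)).
    """
    k, p = X.shape
    w = 1.0 / v
    W = np.diag(w)
    XtWX_inv = np.linalg.inv(X.T @ (w[:, None] * X))
    P = W - (w[:, None] * X) @ XtWX_inv @ (X.T * w[None, :])
    qe = float(y @ P @ y)
    denom = float(np.trace(P))
    tau2 = max(0.0, (qe - (k - p)) / denom)
    return tau2, qe


def _reml_tau2_reg(y: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    k, p = X.shape

    def neg_restricted_ll(tau2: float) -> float:
        wi = 1.0 / (v + tau2)
        XtWX = X.T @ (wi[:, None] * X)
        beta = np.linalg.solve(XtWX, X.T @ (wi * y))
        resid = y - X @ beta
        sign, logdet = np.linalg.slogdet(XtWX)
        return 0.5 * (np.sum(np.log(v + tau2)) + logdet + np.sum(wi * resid**2))

    start, _ = _mom_tau2(y, v, X)
    upper = max(start * 10.0, float(np.var(y)) * 10.0, 1e-3)
    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(0.0, upper), method="bounded",
        options={"xatol": 1e-10},
    )
    return max(0.0, float(res.x))


def _design_matrix(
    records: Sequence[ComparisonRecord], moderator: str, continuous_dose: bool
) -> tuple[np.ndarray, list[str]]:
    if continuous_dose:
        if moderator not in ("dose_bin", "dose"):
            raise DomainError("continuous mode applies to the dose moderator only")
        doses = np.array([r.dose for r in records], dtype=float)
        if np.ptp(doses) == 0:
            raise DegenerateDesignError("dose has no spread across records")
        centered = doses - doses.mean()
        X = np.column_stack([np.ones(len(records)), centered])
        return X, ["intercept", "dose_centered"]
    labels = [str(r.moderator_level(moderator)) for r in records]
    levels = sorted(set(labels))
    if len(levels) < 2:
        raise DegenerateDesignError(
            f"moderator {moderator!r} has a single observed level: {levels[0]!r}"
        )
    reference, *others = levels
    X = np.column_stack(
        [np.ones(len(labels))]
        + [[1.0 if lab == lvl else 0.0 for lab in labels] for lvl in others]
    )
    return X, ["intercept"] + [f"{moderator}[{lvl}]" for lvl in others]


def fit_meta_regression(
    records: Sequence[ComparisonRecord],
    moderator: str,
    outcome: str | None = None,
    alpha: float = 0.05,
    continuous_dose: bool = False,
    tau2_method: str = "DL",
) -> MetaRegResult:
    """Fit a univariable mixed-effects meta-regression.

    R^2 (percent heterogeneity accounted for) compares the residual
    tau^2 against the intercept-only (total) tau^2 and is truncated to
    [0, 100].
    """
    if outcome is not None:
        records = [r for r in records if r.outcome == outcome]
    effects = [effect_from_record(r) for r in records]
    y = np.array([e.g for e in effects], dtype=float)
    v = np.array([e.var for e in effects], dtype=float)
    X, names = _design_matrix(records, moderator, continuous_dose)
    k, p = X.shape
    if k < p + 2:
        raise DomainError(f"need at least {p + 2} comparisons, got {k}")

    if tau2_method == "DL":
        tau2_resid, qe = _mom_tau2(y, v, X)
    elif tau2_method == "REML":
        tau2_resid = _reml_tau2_reg(y, v, X)
        _, qe = _mom_tau2(y, v, X)
    else:
        raise DomainError(f"unknown tau2 method {tau2_method!r}")

    # final coefficients: WLS with random-effects weights
    wi = 1.0 / (v + tau2_resid)
    XtWX_inv = np.linalg.inv(X.T @ (wi[:, None] * X))
    beta = XtWX_inv @ (X.T @ (wi * y))
    se = np.sqrt(np.diag(XtWX_inv))

    # omnibus moderator test on the non-intercept block
    b_mod = beta[1:]
    cov_mod = XtWX_inv[1:, 1:]
    qm = float(b_mod @ np.linalg.solve(cov_mod, b_mod))
    df_m = p - 1
    p_qm = float(stats.chi2.sf(qm, df_m))

    tau2_total = dl_tau2(effects)
    r2 = 0.0
    if tau2_total > 0:
        r2 = max(0.0, 100.0 * (1.0 - tau2_resid / tau2_total))
    r2 = min(100.0, r2)

    w_fixed = 1.0 / v
    grand = float(np.sum(w_fixed * y) / np.sum(w_fixed))
    return MetaRegResult(
        moderator=moderator,
        outcome=outcome,
        k=k,
        coef_names=names,
        coefficients=beta,
        coef_se=se,
        QM=qm,
        df_M=df_m,
        p_QM=p_qm,
        QE=qe,
        p_QE=float(stats.chi2.sf(qe, k - p)),
        tau2_resid=tau2_resid,
        tau2_total=tau2_total,
        I2_resid=i2_from_q(qe, k - p),
        R2=r2,
        grand_mean=grand,
        alpha=alpha,
    )
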