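"""Synthetic comparison-table generator.

Produces ensembles with exactly the statistical structure the meta-analytic
model assumes: true effects drawn from a normal random-effects distribution
(grand mean + moderator shifts + N(0, tau^2)), normal sampling error on arm
means (SD/sqrt(n)), and chi-square sampling on arm SDs
(sd^2 ~ sigma^2 chi^2_{n-1} / (n-1)). The generating parameters are
returned alongside the records so estimator-recovery tests can compare
estimate against truth.

All randomness flows from one counter-based Philox stream seeded by the
config seed, so adding draw sites does not silently shift existing tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from smdmeta.errors import DomainError
from smdmeta.ingest import (
    ArmSummary,
    ComparisonRecord,
    DoseBin,
    assign_dose_bin,
)

__all__ = ["SimulationConfig", "TrueParams", "simulate_ensemble", "make_fixture_table"]


# default moderator-level compositions (dominant strain/leaf/microbe, doses
# mostly in the low bin, mirroring a realistic trial base)
_DEFAULT_LEVELS: dict[str, dict[str, float]] = {
    "strain": {"Arbor Acres": 0.8, "Yellow feathered": 0.1, "Lohmann": 0.1},
    "leaf_type": {"G. biloba": 0.7, "M. alba": 0.1, "S. androgynus": 0.1, "C. album": 0.1},
    "microbes": {
        "A. niger": 0.35,
        "A. niger + C. utilis": 0.25,
        "T. harzianum": 0.1,
        "B. subtilis": 0.1,
        "B. licheniformis": 0.1,
        "C. utilis": 0.1,
    },
    "dose_bin": {"0-5": 0.65, "6-10": 0.17, "11-14": 0.18},
    "phase_bin": {"starter": 0.3, "finisher": 0.3, "overall": 0.4},
}

_DOSE_RANGES = {"0-5": (1.0, 5.0), "6-10": (6.0, 10.0), "11-14": (11.0, 14.0)}
_PHASE_WINDOWS = {"starter": (1, 21), "finisher": (22, 42), "overall": (1, 56)}

#: fill probabilities so defaults sum to one even when leftovers exist
_LEFTOVER = 1e-9


@dataclass
class SimulationConfig:
    """Parameters of one synthetic ensemble.

    ``moderator_effects`` maps (moderator, level) to an additive shift of
    the true effect; ``outcome_scales`` maps outcome name to the control
    arm's (mean, SD) scale. Default tau2 puts simulated I-squared in the
    60-90% band at the default arm sizes.
    """

    k: int = 84
    mu: float = 0.33
    tau2: float = 0.65
    moderator_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    level_probabilities: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    n_range: tuple[int, int] = (6, 12)
    outcome_scales: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"FI": (100.0, 8.0)}
    )
    se_fraction: float = 0.0  # fraction of rows reporting SE instead of SD
    shared_control_block: int = 0  # >1: comparisons per shared-control study
    seed: int = 0

    def validate(self) -> None:
        if self.k < 1:
            raise DomainError(f"k must be >= 1, got {self.k}")
        if self.tau2 < 0:
            raise DomainError(f"tau2 must be >= 0, got {self.tau2}")
        lo, hi = self.n_range
        if not (2 <= lo <= hi <= 1000):
            raise DomainError(f"n_range must lie in [2, 1000], got {self.n_range}")
        if not 0 <= self.se_fraction <= 1:
            raise DomainError("se_fraction must be in [0, 1]")
        for mod, probs in self.level_probabilities.items():
            if mod not in _DEFAULT_LEVELS:
                raise DomainError(f"unknown moderator {mod!r}")
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise DomainError(f"probabilities for {mod!r} sum to {total}, not 1")
        for (mod, level), _ in self.moderator_effects.items():
            if mod not in _DEFAULT_LEVELS:
                raise DomainError(f"unknown moderator {mod!r} in moderator_effects")

    def levels_for(self, moderator: str) -> tuple[list[str], np.ndarray]:
        probs = dict(self.level_probabilities.get(moderator, _DEFAULT_LEVELS[moderator]))
        labels = list(probs)
        p = np.array([probs[x] for x in labels], dtype=float)
        return labels, p / p.sum()


@dataclass
class TrueParams:
    """Generating parameters emitted next to the synthetic records."""

    mu: float
    tau2: float
    theta: np.ndarray  # per-comparison true standardized effects
    moderator_effects: dict

    def write(self, dest) -> None:
        lines = [f"mu\t{self.mu}", f"tau2\t{self.tau2}"]
        for (mod, level), shift in self.moderator_effects.items():
            lines.append(f"shift\t{mod}\t{level}\t{shift}")
        lines += [f"theta_{i}\t{t}" for i, t in enumerate(self.theta)]
        text = "\n".join(lines) + "\n"
        if hasattr(dest, "write"):
            dest.write(text)
        else:
            with open(dest, "w") as fh:
                fh.write(text)


def simulate_ensemble(
    config: SimulationConfig,
) -> tuple[list[ComparisonRecord], TrueParams]:
    """Generate k comparison records plus their generating parameters.

    Identical seed and config yield identical output.
    """
    config.validate()
    rng = np.random.Generator(np.random.Philox(config.seed))
    k = config.k

    draws: dict[str, np.ndarray] = {}
    for mod in ("strain", "leaf_type", "microbes", "dose_bin", "phase_bin"):
        labels, p = config.levels_for(mod)
        draws[mod] = rng.choice(labels, size=k, p=p)

    shift = np.zeros(k)
    for (mod, level), delta in config.moderator_effects.items():
        shift += np.where(draws[mod] == level, delta, 0.0)

    theta = config.mu + shift + rng.normal(0.0, math.sqrt(config.tau2), size=k)

    lo, hi = config.n_range
    n_t = rng.integers(lo, hi + 1, size=k)
    n_c = rng.integers(lo, hi + 1, size=k)

    outcomes = list(config.outcome_scales)
    outcome_idx = rng.integers(0, len(outcomes), size=k)

    dose_lo = np.array([_DOSE_RANGES[b][0] for b in draws["dose_bin"]])
    dose_hi = np.array([_DOSE_RANGES[b][1] for b in draws["dose_bin"]])
    dose = np.round(rng.uniform(dose_lo, dose_hi), 1)

    mean_noise_c = rng.normal(size=k)
    mean_noise_t = rng.normal(size=k)
    sd_chi_c = rng.chisquare(n_c - 1) / (n_c - 1)
    sd_chi_t = rng.chisquare(n_t - 1) / (n_t - 1)

    block = max(1, config.shared_control_block)
    records: list[ComparisonRecord] = []
    for i in range(k):
        outcome = outcomes[outcome_idx[i]]
        mu_c, sigma = config.outcome_scales[outcome]
        study = i // block if block > 1 else i
        if block > 1 and i % block != 0:
            # re-use the first comparison of the block as the control arm
            anchor = records[(i // block) * block]
            control = anchor.control
        else:
            control = ArmSummary(
                mean=mu_c + sigma / math.sqrt(n_c[i]) * mean_noise_c[i],
                sd=sigma * math.sqrt(sd_chi_c[i]),
                n=int(n_c[i]),
            )
        mu_t = mu_c + theta[i] * sigma
        treated = ArmSummary(
            mean=mu_t + sigma / math.sqrt(n_t[i]) * mean_noise_t[i],
            sd=sigma * math.sqrt(sd_chi_t[i]),
            n=int(n_t[i]),
        )
        start, end = _PHASE_WINDOWS[draws["phase_bin"][i]]
        records.append(
            ComparisonRecord(
                study_id=f"S{study:04d}",
                country="Simulated",
                strain=str(draws["strain"][i]),
                leaf_type=str(draws["leaf_type"][i]),
                microbes=str(draws["microbes"][i]),
                dose=float(dose[i]),
                phase_start=float(start),
                phase_end=float(end),
                outcome=outcome,
                control=control,
                treated=treated,
            )
        )

    if config.se_fraction > 0:
        flip = rng.random(k) < config.se_fraction
        for i in np.nonzero(flip)[0]:
            for arm in (records[i].control, records[i].treated):
                arm.se = arm.sd / math.sqrt(arm.n)
                arm.sd = None

    params = TrueParams(
        mu=config.mu,
        tau2=config.tau2,
        theta=theta,
        moderator_effects=dict(config.moderator_effects),
    )
    return records, params


def make_fixture_table() -> list[ComparisonRecord]:
    """Deterministic 12-row toy table for unit tests.

    Spans every strain, leaf type, dose bin and phase bin, and exercises
    both SD-style and SE-style arm reporting.
    """
    rows = [
        # study, strain, leaf, microbes, dose, (start, end), outcome
        ("Chen-2019", "Arbor Acres", "G. biloba", "A. niger", 3.5, (1, 21), "FI"),
        ("Chen-2019", "Arbor Acres", "G. biloba", "A. niger", 3.5, (22, 42), "FI"),
        ("Niu-2017", "Arbor Acres", "G. biloba", "A. niger + C. utilis", 2.5, (1, 42), "ADG"),
        ("Niu-2017", "Arbor Acres", "G. biloba", "A. niger + C. utilis", 5.0, (1, 42), "ADG"),
        ("Zhang-2020", "Yellow feathered", "M. alba", "B. subtilis + Lactobacillus + Saccharomycetes", 7.0, (1, 56), "FCR"),
        ("Zhang-2020", "Yellow feathered", "M. alba", "B. subtilis + Lactobacillus + Saccharomycetes", 10.0, (1, 56), "FCR"),
        ("Sari-2018", "Lohmann", "S. androgynus", "T. harzianum", 12.0, (1, 21), "FI"),
        ("Sari-2018", "Lohmann", "S. androgynus", "T. harzianum", 14.0, (22, 42), "FI"),
        ("Wang-2021", "Arbor Acres", "C. album", "B. subtilis + L. plantarum + S. cerevisiae", 4.0, (1, 21), "ADG"),
        ("Wang-2021", "Arbor Acres", "C. album", "B. subtilis + L. plantarum + S. cerevisiae", 8.0, (22, 42), "ADG"),
        ("Li-2022", "Arbor Acres", "G. biloba", "B. licheniformis", 1.5, (1, 56), "breast_drip_loss"),
        ("Li-2022", "Arbor Acres", "G. biloba", "C. utilis", 11.0, (1, 56), "breast_drip_loss"),
    ]
    base_means = {
        "FI": 95.0,
        "ADG": 55.0,
        "FCR": 1.8,
        "breast_drip_loss": 2.4,
    }
    base_sds = {"FI": 6.0, "ADG": 4.0, "FCR": 0.1, "breast_drip_loss": 0.3}
    records = []
    for i, (study, strain, leaf, microbes, dose, (start, end), outcome) in enumerate(rows):
        mean_c = base_means[outcome]
        sd = base_sds[outcome]
        # a deterministic, mildly varying effect pattern
        delta = sd * (0.2 + 0.05 * (i % 5)) * (1 if outcome in ("FI", "ADG") else -1)
        n = 8 + (i % 3)
        if i % 4 == 3:  # every fourth row reports SE instead of SD
            control = ArmSummary(mean=mean_c, se=sd / math.sqrt(n), n=n)
            treated = ArmSummary(mean=mean_c + delta, se=sd / math.sqrt(n), n=n)
        else:
            control = ArmSummary(mean=mean_c, sd=sd, n=n)
            treated = ArmSummary(mean=mean_c + delta, sd=sd * (1 + 0.02 * i), n=n)
        records.append(
            ComparisonRecord(
                study_id=study,
                country="CN" if "Sari" not in study else "ID",
                strain=strain,
                leaf_type=leaf,
                microbes=microbes,
                dose=dose,
                phase_start=float(start),
                phase_end=float(end),
                outcome=outcome,
                control=control,
                treated=treated,
            )
        )
    return records
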