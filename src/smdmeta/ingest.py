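"""Read, validate, and normalize the per-comparison extraction table.

One row of the table is one control-vs-treated contrast of a single outcome
in a single rearing phase, carrying the five study-level moderators
(broiler strain, leaf-meal species, fermentation microbes, supplementation
dose in g/kg feed, rearing-phase day window) plus the two arm summaries
(mean, SD or SE, replicate count).
"""

from __future__ import annotations

import enum
import io
import math
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from smdmeta.errors import DomainError, SchemaError, ValidationError

__all__ = [
    "ArmSummary",
    "ComparisonRecord",
    "DoseBin",
    "PhaseBin",
    "COLUMNS",
    "STRAINS",
    "LEAF_TYPES",
    "MICROBE_ORGANISMS",
    "OUTCOMES",
    "MODERATORS",
    "se_to_sd",
    "sd_to_se",
    "assign_dose_bin",
    "assign_phase_bin",
    "normalize_arm",
    "read_comparisons",
    "write_comparisons",
    "validate_records",
    "detect_shared_controls",
]

#: Column order of the CSV dialect (header row required, UTF-8, empty = missing).
COLUMNS = [
    "study_id",
    "country",
    "strain",
    "leaf_type",
    "microbes",
    "dose_g_per_kg",
    "phase_start_day",
    "phase_end_day",
    "outcome",
    "mean_c",
    "sd_c",
    "se_c",
    "n_c",
    "mean_t",
    "sd_t",
    "se_t",
    "n_t",
]

STRAINS = ("Arbor Acres", "Yellow feathered", "Lohmann")

LEAF_TYPES = ("G. biloba", "M. alba", "S. androgynus", "C. album")

#: Single organisms that may appear alone or in "+"-joined mixtures.
MICROBE_ORGANISMS = (
    "A. niger",
    "T. harzianum",
    "B. subtilis",
    "B. licheniformis",
    "C. utilis",
    "L. plantarum",
    "S. cerevisiae",
    "Lactobacillus",
    "Saccharomycetes",
)

#: Closed outcome vocabulary. Muscle-quality traits are prefixed by muscle,
#: gut-histology traits by intestinal segment.
OUTCOMES = (
    "FI",
    "ADG",
    "FCR",
    "cholesterol",
    "triglycerides",
    "HDL",
    "LDL",
    "duodenum_VH",
    "duodenum_CD",
    "duodenum_VH_CD",
    "jejunum_VH",
    "jejunum_CD",
    "jejunum_VH_CD",
    "ileum_VH",
    "ileum_CD",
    "ileum_VH_CD",
    "dressing_percentage",
    "breast",
    "thigh",
    "abdominal_fat",
    "breast_pH",
    "breast_drip_loss",
    "breast_shear_force",
    "breast_L",
    "breast_a",
    "breast_b",
    "thigh_pH",
    "thigh_drip_loss",
    "thigh_shear_force",
    "thigh_L",
    "thigh_a",
    "thigh_b",
)

#: Moderator names accepted by subgroup and meta-regression analyses.
MODERATORS = ("strain", "leaf_type", "microbes", "dose_bin", "phase_bin")


def _normkey(value: str) -> str:
    """Fold a categorical label to a canonical matching key.

    Trims, collapses internal whitespace, case-folds, and treats the
    separators ``/ : - _ *`` and periods as insignificant.
    """
    s = value.strip().casefold()
    s = re.sub(r"[/:*._-]", " ", s)
    s = re.sub(r"\s+", " ", s).strip()
    return s


_STRAIN_LOOKUP = {_normkey(v): v for v in STRAINS}
_LEAF_LOOKUP = {_normkey(v): v for v in LEAF_TYPES}
_ORGANISM_LOOKUP = {_normkey(v): v for v in MICROBE_ORGANISMS}
_OUTCOME_LOOKUP = {_normkey(v): v for v in OUTCOMES}
# tolerate the common "VH:CD"/"VH/CD ratio" spellings
for _seg in ("duodenum", "jejunum", "ileum"):
    _OUTCOME_LOOKUP[_normkey(f"{_seg} VH CD ratio")] = f"{_seg}_VH_CD"


class DoseBin(enum.Enum):
    """Supplementation-level bin in g/kg feed.

    Half-open partition of [0, 14]: LOW = [0, 5], MID = (5, 10],
    HIGH = (10, 14]. A non-integer dose such as 5.5 therefore maps to MID.
    """

    LOW = "0-5"
    MID = "6-10"
    HIGH = "11-14"


class PhaseBin(enum.Enum):
    """Rearing-phase bin derived from the trial's day window."""

    STARTER = "starter"
    FINISHER = "finisher"
    OVERALL = "overall"


def se_to_sd(se: float, n: int) -> float:
    """Convert a standard error of the mean to a standard deviation.

    SD = SE * sqrt(n), n being the per-arm replicate count.
    """
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    if se < 0:
        raise DomainError(f"se must be >= 0, got {se}")
    return se * math.sqrt(n)


def sd_to_se(sd: float, n: int) -> float:
    """Inverse of :func:`se_to_sd`: SE = SD / sqrt(n)."""
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n}")
    if sd < 0:
        raise DomainError(f"sd must be >= 0, got {sd}")
    return sd / math.sqrt(n)


def assign_dose_bin(dose: float) -> DoseBin:
    """Map a dose in g/kg feed to its bin. Total on [0, 14]."""
    if not 0 <= dose <= 14:
        raise DomainError(f"dose must be in [0, 14] g/kg, got {dose}")
    if dose <= 5:
        return DoseBin.LOW
    if dose <= 10:
        return DoseBin.MID
    return DoseBin.HIGH


def assign_phase_bin(phase_start: float, phase_end: float) -> PhaseBin:
    """Classify a (start day, end day) rearing window.

    starter iff the window ends by day 21; overall iff it starts at day 0/1
    and spans more than 21 days past brooding (covers both starter and
    finisher territory); finisher otherwise.
    """
    if not (0 <= phase_start < phase_end <= 56):
        raise DomainError(
            f"phase window must satisfy 0 <= start < end <= 56, "
            f"got ({phase_start}, {phase_end})"
        )
    if phase_end <= 21:
        return PhaseBin.STARTER
    if phase_start <= 1 and (phase_end - phase_start) > 21:
        return PhaseBin.OVERALL
    return PhaseBin.FINISHER


@dataclass
class ArmSummary:
    """Summary statistics of one trial arm.

    Exactly one of ``sd``/``se`` may be missing on input; after
    :func:`normalize_arm` the SD is always present.
    """

    mean: float
    sd: float | None = None
    se: float | None = None
    n: int = 1

    def normalized(self) -> "ArmSummary":
        return normalize_arm(self)


def normalize_arm(arm: ArmSummary) -> ArmSummary:
    """Fill a missing SD from SE via SD = SE * sqrt(n).

    A provided SD is never overwritten; SE takes precedence only when the
    SD is absent.
    """
    if arm.sd is not None:
        return arm
    if arm.se is None:
        raise ValidationError("arm has neither sd nor se")
    return replace(arm, sd=se_to_sd(arm.se, arm.n))


@dataclass
class ComparisonRecord:
    """One control-vs-treated contrast with its five moderators."""

    study_id: str
    strain: str
    leaf_type: str
    microbes: str
    dose: float
    phase_start: float
    phase_end: float
    outcome: str
    control: ArmSummary
    treated: ArmSummary
    country: str = ""

    @property
    def dose_bin(self) -> DoseBin:
        return assign_dose_bin(self.dose)

    @property
    def phase_bin(self) -> PhaseBin:
        return assign_phase_bin(self.phase_start, self.phase_end)

    def moderator_level(self, moderator: str) -> str:
        """Return the record's level of a named moderator as a string label."""
        if moderator not in MODERATORS:
            raise DomainError(
                f"unknown moderator {moderator!r}; expected one of {MODERATORS}"
            )
        if moderator == "dose_bin":
            return self.dose_bin.value
        if moderator == "phase_bin":
            return self.phase_bin.value
        return getattr(self, moderator)


def _match_categorical(value: str, lookup: dict, what: str, row: int) -> str:
    key = _normkey(value)
    if key not in lookup:
        raise ValidationError(f"row {row}: unknown {what} {value!r}")
    return lookup[key]


def _normalize_microbes(value: str, row: int) -> str:
    """Canonicalize a microbe label: mixtures are matched per organism and
    re-joined in sorted order with " + "."""
    parts = [p for p in re.split(r"\+|,|&|\band\b", value) if p.strip()]
    if not parts:
        raise ValidationError(f"row {row}: empty microbes field")
    organisms = sorted(
        _match_categorical(p, _ORGANISM_LOOKUP, "microbe organism", row)
        for p in parts
    )
    return " + ".join(organisms)


def _parse_float(raw: str, column: str, row: int) -> float | None:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        return float(raw)
    except ValueError:
        raise ValidationError(f"row {row}: {column} is not numeric: {raw!r}") from None


def _parse_int(raw: str, column: str, row: int) -> int:
    value = _parse_float(raw, column, row)
    if value is None:
        raise ValidationError(f"row {row}: {column} is required")
    if value != int(value):
        raise ValidationError(f"row {row}: {column} must be an integer, got {raw!r}")
    return int(value)


def _parse_arm(row_data: pd.Series, suffix: str, row: int) -> ArmSummary:
    mean = _parse_float(row_data[f"mean_{suffix}"], f"mean_{suffix}", row)
    if mean is None:
        raise ValidationError(f"row {row}: mean_{suffix} is required")
    sd = _parse_float(row_data[f"sd_{suffix}"], f"sd_{suffix}", row)
    se = _parse_float(row_data[f"se_{suffix}"], f"se_{suffix}", row)
    n = _parse_int(row_data[f"n_{suffix}"], f"n_{suffix}", row)
    if sd is None and se is None:
        raise ValidationError(f"row {row}: both sd_{suffix} and se_{suffix} are missing")
    return ArmSummary(mean=mean, sd=sd, se=se, n=n)


def read_comparisons(csv_source, normalize: bool = True) -> list[ComparisonRecord]:
    """Read the per-comparison CSV table into records.

    Parameters
    ----------
    csv_source
        Path, file-like object, or the CSV text itself.
    normalize
        When true (default), fill missing arm SDs from SEs.

    Row order is preserved; categorical fields are matched
    case/whitespace-insensitively against the closed vocabularies.
    """
    if isinstance(csv_source, str) and "\n" in csv_source:
        csv_source = io.StringIO(csv_source)
    frame = pd.read_csv(csv_source, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records: list[ComparisonRecord] = []
    for i, (_, row) in enumerate(frame.iterrows()):
        country = row["country"].strip()
        if not country:
            warnings.warn(f"row {i}: country metadata missing", stacklevel=2)
        dose = _parse_float(row["dose_g_per_kg"], "dose_g_per_kg", i)
        if dose is None:
            raise ValidationError(f"row {i}: dose_g_per_kg is required")
        start = _parse_float(row["phase_start_day"], "phase_start_day", i)
        end = _parse_float(row["phase_end_day"], "phase_end_day", i)
        if start is None or end is None:
            raise ValidationError(f"row {i}: phase day window is required")
        record = ComparisonRecord(
            study_id=row["study_id"].strip(),
            country=country,
            strain=_match_categorical(row["strain"], _STRAIN_LOOKUP, "strain", i),
            leaf_type=_match_categorical(
                row["leaf_type"], _LEAF_LOOKUP, "leaf_type", i
            ),
            microbes=_normalize_microbes(row["microbes"], i),
            dose=dose,
            phase_start=start,
            phase_end=end,
            outcome=_match_categorical(row["outcome"], _OUTCOME_LOOKUP, "outcome", i),
            control=_parse_arm(row, "c", i),
            treated=_parse_arm(row, "t", i),
        )
        if normalize:
            record.control = normalize_arm(record.control)
            record.treated = normalize_arm(record.treated)
        records.append(record)
    return records


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        value = float(value)  # strip numpy scalar types for a clean repr
        if value == int(value) and abs(value) < 1e15:
            return str(int(value))
        return repr(value)
    return str(value)


def write_comparisons(records: Iterable[ComparisonRecord], dest) -> None:
    """Write records back out in the ingest CSV dialect (deterministic)."""
    rows = []
    for r in records:
        rows.append(
            {
                "study_id": r.study_id,
                "country": r.country,
                "strain": r.strain,
                "leaf_type": r.leaf_type,
                "microbes": r.microbes,
                "dose_g_per_kg": _fmt(r.dose),
                "phase_start_day": _fmt(r.phase_start),
                "phase_end_day": _fmt(r.phase_end),
                "outcome": r.outcome,
                "mean_c": _fmt(r.control.mean),
                "sd_c": _fmt(r.control.sd),
                "se_c": _fmt(r.control.se),
                "n_c": _fmt(r.control.n),
                "mean_t": _fmt(r.treated.mean),
                "sd_t": _fmt(r.treated.sd),
                "se_t": _fmt(r.treated.se),
                "n_t": _fmt(r.treated.n),
            }
        )
    pd.DataFrame(rows, columns=COLUMNS).to_csv(dest, index=False)


def _check_arm(violations: list, i: int, label: str, arm: ArmSummary) -> None:
    if arm.n < 1:
        violations.append(f"record {i}: {label}.n: must be >= 1, got {arm.n}")
    if arm.sd is None and arm.se is None:
        violations.append(f"record {i}: {label}: neither sd nor se present")
    if arm.sd is not None and arm.sd < 0:
        violations.append(f"record {i}: {label}.sd: must be >= 0, got {arm.sd}")
    if arm.se is not None and arm.se < 0:
        violations.append(f"record {i}: {label}.se: must be >= 0, got {arm.se}")


def validate_records(records: Sequence[ComparisonRecord]) -> list[str]:
    """Check every record against the type invariants.

    Violations are returned as data (one description naming record index,
    field, and rule per problem), never raised.
    """
    violations: list[str] = []
    for i, r in enumerate(records):
        if not 0 <= r.dose <= 14:
            violations.append(f"record {i}: dose: must be in [0, 14], got {r.dose}")
        if not r.phase_start < r.phase_end:
            violations.append(
                f"record {i}: phase window: start must precede end, "
                f"got ({r.phase_start}, {r.phase_end})"
            )
        elif not (0 <= r.phase_start and r.phase_end <= 56):
            violations.append(
                f"record {i}: phase window: days must lie in [0, 56], "
                f"got ({r.phase_start}, {r.phase_end})"
            )
        if r.strain not in STRAINS:
            violations.append(f"record {i}: strain: unknown value {r.strain!r}")
        if r.leaf_type not in LEAF_TYPES:
            violations.append(f"record {i}: leaf_type: unknown value {r.leaf_type!r}")
        if r.outcome not in OUTCOMES:
            violations.append(f"record {i}: outcome: unknown value {r.outcome!r}")
        _check_arm(violations, i, "control", r.control)
        _check_arm(violations, i, "treated", r.treated)
    return violations


def detect_shared_controls(records: Sequence[ComparisonRecord]) -> list[tuple[int, ...]]:
    """Find groups of comparisons that appear to re-use one control arm.

    Multi-dose trials contribute one comparison per dose against a common
    control; the pipeline treats them as independent but flags them.
    Returns index tuples of each group of size > 1.
    """
    by_key: dict[tuple, list[int]] = {}
    for i, r in enumerate(records):
        key = (
            r.study_id,
            r.outcome,
            r.phase_start,
            r.phase_end,
            r.control.mean,
            r.control.sd,
            r.control.n,
        )
        by_key.setdefault(key, []).append(i)
    return [tuple(v) for v in by_key.values() if len(v) > 1]
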