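"""Per-lesion cohort table: records, I/O and the study eligibility filter.

The reference cohort shipped with the package is a 33-lesion hepatocellular
carcinoma (HCC) series with, per lesion: WHO differentiation grade (G1 well,
G2 moderately, G3 poorly differentiated), the fraction of OATP1B3-positive
tumor cells and the membranous staining intensity from immunohistochemistry,
the T1 reduction rate between the native and hepatobiliary phases, the
macroscopic growth pattern, the lesion volume, and the Ishak fibrosis stage
of the background liver.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "LesionRecord",
    "EligibilityFlags",
    "SchemaError",
    "ValidationError",
    "load_cohort",
    "reference_cohort",
    "write_cohort",
    "filter_eligible",
    "to_frame",
    "GRADES",
    "INTENSITY_LABELS",
]

GRADES = ("G1", "G2", "G3")
INTENSITY_LABELS = ("absent", "weak", "moderate", "strong")

#: symbol forms used in pathology tables; blank and "0" both mean absent
_SYMBOL_TO_LABEL = {
    "0": "absent",
    "": "absent",
    "-": "absent",
    "+": "weak",
    "++": "moderate",
    "+++": "strong",
}

_COLUMNS = (
    "lesion_id",
    "grade",
    "pct_positive",
    "intensity",
    "reduction_rate",
    "growth_pattern",
    "volume_cm3",
    "ishak",
)


class SchemaError(ValueError):
    """Input table is missing required columns or is unparseable."""


class ValidationError(ValueError):
    """A field value violates the cohort's range constraints."""


@dataclass(frozen=True)
class LesionRecord:
    """One lesion of the cohort.

    ``pct_positive`` is the fraction (0-1) of OATP1B3-immunopositive tumor
    cells; ``intensity_label`` the membranous staining intensity;
    ``reduction_rate`` the dimensionless T1 reduction rate
    (T1_plain - T1_HBP) / T1_plain; ``ishak`` the 0-6 fibrosis stage of the
    non-tumorous background liver.
    """

    lesion_id: int
    grade: str
    pct_positive: float
    intensity_label: str
    reduction_rate: float
    growth_pattern: str
    volume_cm3: float
    ishak: int

    def __post_init__(self) -> None:
        if self.lesion_id <= 0:
            raise ValidationError(f"lesion_id must be positive, got {self.lesion_id}")
        if self.grade not in GRADES:
            raise ValidationError(f"grade must be one of {GRADES}, got {self.grade!r}")
        if not 0.0 <= self.pct_positive <= 1.0:
            raise ValidationError(
                f"pct_positive must be a fraction in [0, 1], got {self.pct_positive}"
            )
        if self.intensity_label not in INTENSITY_LABELS:
            raise ValidationError(
                f"intensity_label must be one of {INTENSITY_LABELS}, "
                f"got {self.intensity_label!r}"
            )
        if self.reduction_rate > 1.0:
            raise ValidationError(
                f"reduction_rate cannot exceed 1, got {self.reduction_rate}"
            )
        if self.volume_cm3 <= 0:
            raise ValidationError(f"volume_cm3 must be > 0, got {self.volume_cm3}")
        if self.ishak not in range(7):
            raise ValidationError(f"ishak must be an integer 0-6, got {self.ishak}")


@dataclass(frozen=True)
class EligibilityFlags:
    """Exclusion flags for one screened lesion; eligible iff all are False."""

    lesion_id: int
    sub_cm: bool = False  # largest diameter < 1 cm
    infiltrative: bool = False
    mixed_tumor: bool = False
    pretreated: bool = False
    repeat_mri: bool = False
    technical_error: bool = False

    REASONS = (
        "sub_cm",
        "infiltrative",
        "mixed_tumor",
        "pretreated",
        "repeat_mri",
        "technical_error",
    )

    @property
    def eligible(self) -> bool:
        return not any(getattr(self, r) for r in self.REASONS)


def parse_intensity(value: object) -> str:
    """Map a staining-intensity symbol (``+``/``++``/``+++``/``0``) or word to
    its canonical label."""
    text = str(value).strip()
    if text in _SYMBOL_TO_LABEL:
        return _SYMBOL_TO_LABEL[text]
    word = text.lower()
    if word in INTENSITY_LABELS:
        return word
    raise ValidationError(f"unrecognized staining intensity {value!r}")


def _records_from_frame(df: pd.DataFrame) -> list[LesionRecord]:
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table is missing columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            LesionRecord(
                lesion_id=int(row.lesion_id),
                grade=str(row.grade).strip(),
                pct_positive=float(row.pct_positive),
                intensity_label=parse_intensity(row.intensity),
                reduction_rate=float(row.reduction_rate),
                growth_pattern=str(row.growth_pattern).strip().lower(),
                volume_cm3=float(row.volume_cm3),
                ishak=int(row.ishak),
            )
        )
    return records


def load_cohort(source: str | Path | None = None) -> list[LesionRecord]:
    """Load a lesion cohort from a CSV file, or the embedded reference cohort
    when ``source`` is None.

    The intensity column accepts both symbol (``+``, ``++``, ``+++``, ``0``)
    and word (absent/weak/moderate/strong) forms; percentages of positive
    cells are fractions in [0, 1].
    """
    if source is None:
        ref = importlib.resources.files("hepquant.data") / "table1_cohort.csv"
        with importlib.resources.as_file(ref) as path:
            df = pd.read_csv(path, dtype={"intensity": str})
    else:
        try:
            df = pd.read_csv(source, dtype={"intensity": str})
        except pd.errors.EmptyDataError as exc:
            raise SchemaError(f"cohort file {source} is empty") from exc
    if df.empty:
        raise SchemaError("cohort table has no rows")
    return _records_from_frame(df)


def reference_cohort() -> list[LesionRecord]:
    """The embedded 33-lesion reference cohort."""
    return load_cohort(None)


def to_frame(records: Iterable[LesionRecord]) -> pd.DataFrame:
    """Tabular view of a cohort (intensity as canonical word labels)."""
    rows = []
    for r in records:
        rows.append(
            {
                "lesion_id": r.lesion_id,
                "grade": r.grade,
                "pct_positive": r.pct_positive,
                "intensity": r.intensity_label,
                "reduction_rate": r.reduction_rate,
                "growth_pattern": r.growth_pattern,
                "volume_cm3": r.volume_cm3,
                "ishak": r.ishak,
            }
        )
    return pd.DataFrame(rows, columns=list(_COLUMNS))


def write_cohort(records: Iterable[LesionRecord], path: str | Path) -> None:
    """Write a cohort to CSV; ``load_cohort`` round-trips it exactly."""
    to_frame(records).to_csv(path, index=False)


def filter_eligible(
    records: Sequence[LesionRecord], flags: Sequence[EligibilityFlags]
) -> tuple[list[LesionRecord], dict[str, int]]:
    """Apply the study's eligibility filter.

    Returns the subset of ``records`` whose flags are all False, together
    with per-reason exclusion counts (a lesion excluded for several reasons
    counts once per reason).
    """
    by_id = {f.lesion_id: f for f in flags}
    missing = [r.lesion_id for r in records if r.lesion_id not in by_id]
    if missing:
        raise ValidationError(f"no eligibility flags for lesion ids {missing}")
    counts = {reason: 0 for reason in EligibilityFlags.REASONS}
    kept = []
    for rec in records:
        f = by_id[rec.lesion_id]
        if f.eligible:
            kept.append(rec)
        else:
            for reason in EligibilityFlags.REASONS:
                if getattr(f, reason):
                    counts[reason] += 1
    return kept, counts
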