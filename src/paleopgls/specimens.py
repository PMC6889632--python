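"""Specimen measurement tables and dataset variants.

A specimen table holds one row per fossil individual: femur length (FL)
and humerus length (HL) in mm, taxonomy, clade memberships, a stratigraphic
age range in Ma, and an ontogenetic status. FL is the body-size proxy and
HL the forelimb proxy; both are analysed on the log10 scale, so the
allometric relation log10(HL) = a + b*log10(FL) is linear.

Four dataset variants are supported:

``complete``
    every specimen;
``reduced``
    one specimen per species — the largest, by FL;
``adult``
    every specimen not proposed to be a juvenile (subadult/unknown kept);
``juvenile``
    only specimens proposed to be juveniles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import pandas as pd

logger = logging.getLogger(__name__)

ONTO_STATUSES = ("adult", "subadult", "juvenile", "unknown")
VARIANT_NAMES = ("complete", "reduced", "adult", "juvenile")

#: header of the specimen CSV format; `clades` is semicolon-separated
CSV_COLUMNS = (
    "specimen_id",
    "species",
    "genus",
    "clades",
    "fl_mm",
    "hl_mm",
    "age_min_ma",
    "age_max_ma",
    "onto_status",
)

# plausible theropod limb-bone lengths; outside -> warning only
_PLAUSIBLE_MM = (1.0, 2500.0)


class SchemaError(ValueError):
    """The CSV is missing a required column."""


class ValidationError(ValueError):
    """A row violates a hard invariant (non-positive length, bad ages...)."""


@dataclass(frozen=True)
class SpecimenRecord:
    """One fossil individual with measurements, taxonomy and age range."""

    specimen_id: str
    species: str
    genus: str
    clade_labels: frozenset[str]
    fl_mm: float
    hl_mm: float
    age_min_ma: float
    age_max_ma: float
    onto_status: str = "unknown"

    def __post_init__(self) -> None:
        if not self.fl_mm > 0 or not self.hl_mm > 0:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: FL and HL must be positive "
                f"(got FL={self.fl_mm}, HL={self.hl_mm})"
            )
        if not (self.age_max_ma >= self.age_min_ma >= 0):
            raise ValidationError(
                f"specimen {self.specimen_id!r}: need age_max >= age_min >= 0 "
                f"(got [{self.age_min_ma}, {self.age_max_ma}])"
            )
        if self.onto_status not in ONTO_STATUSES:
            raise ValidationError(
                f"specimen {self.specimen_id!r}: unknown ontogenetic status "
                f"{self.onto_status!r}"
            )
        for name, value in (("FL", self.fl_mm), ("HL", self.hl_mm)):
            if not _PLAUSIBLE_MM[0] <= value <= _PLAUSIBLE_MM[1]:
                logger.warning(
                    "specimen %s: %s=%.3g mm outside plausible range %s",
                    self.specimen_id, name, value, _PLAUSIBLE_MM,
                )

    @property
    def log_fl(self) -> float:
        return math.log10(self.fl_mm)

    @property
    def log_hl(self) -> float:
        return math.log10(self.hl_mm)


@dataclass(frozen=True)
class DatasetVariant:
    """A named subset of the specimen table (see module docstring)."""

    name: str
    records: tuple[SpecimenRecord, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def species(self) -> set[str]:
        return {r.species for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)


def _record_from_row(row: pd.Series) -> SpecimenRecord:
    clades = row.get("clades", "")
    if pd.isna(clades):
        clades = ""
    labels = frozenset(c.strip() for c in str(clades).split(";") if c.strip())
    return SpecimenRecord(
        specimen_id=str(row["specimen_id"]),
        species=str(row["species"]),
        genus=str(row["genus"]),
        clade_labels=labels,
        fl_mm=float(row["fl_mm"]),
        hl_mm=float(row["hl_mm"]),
        age_min_ma=float(row["age_min_ma"]),
        age_max_ma=float(row["age_max_ma"]),
        onto_status=str(row["onto_status"]),
    )


def load_measurements(path) -> list[SpecimenRecord]:
    """Read a specimen CSV into validated records.

    Rows with missing FL or HL are dropped with a logged reason; rows with
    non-positive measurements raise :class:`ValidationError` naming the row.
    """
    df = pd.read_csv(path, dtype={"specimen_id": str})
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {sorted(missing)}")
    records: list[SpecimenRecord] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        if pd.isna(row["fl_mm"]) or pd.isna(row["hl_mm"]):
            logger.info(
                "dropping specimen %s: missing FL or HL", row["specimen_id"]
            )
            continue
        rec = _record_from_row(row)
        if rec.specimen_id in seen:
            raise ValidationError(f"duplicate specimen_id {rec.specimen_id!r}")
        seen.add(rec.specimen_id)
        records.append(rec)
    return records


def records_to_frame(records) -> pd.DataFrame:
    """Tabulate records in the CSV column layout (plus log columns)."""
    rows = []
    for r in records:
        rows.append(
            {
                "specimen_id": r.specimen_id,
                "species": r.species,
                "genus": r.genus,
                "clades": ";".join(sorted(r.clade_labels)),
                "fl_mm": r.fl_mm,
                "hl_mm": r.hl_mm,
                "age_min_ma": r.age_min_ma,
                "age_max_ma": r.age_max_ma,
                "onto_status": r.onto_status,
                "log_fl": r.log_fl,
                "log_hl": r.log_hl,
            }
        )
    return pd.DataFrame(rows, columns=list(CSV_COLUMNS) + ["log_fl", "log_hl"])


def write_measurements(records, path) -> None:
    """Write records as a specimen CSV (round-trips with load_measurements)."""
    records_to_frame(records)[list(CSV_COLUMNS)].to_csv(path, index=False)


def make_variant(records, name: str) -> DatasetVariant:
    """Build one of the four dataset variants.

    ``reduced`` keeps, per species, the specimen with maximal FL (ties broken
    by specimen_id so the choice is deterministic).
    """
    records = list(records)
    if not records:
        raise ValidationError("cannot build a variant from an empty record list")
    if name == "complete":
        kept = records
    elif name == "reduced":
        best: dict[str, SpecimenRecord] = {}
        for r in sorted(records, key=lambda r: r.specimen_id):
            cur = best.get(r.species)
            if cur is None or r.fl_mm > cur.fl_mm:
                best[r.species] = r
        kept = [r for r in records if best[r.species] is r]
    elif name == "adult":
        # conservative: only proposed juveniles are excluded
        kept = [r for r in records if r.onto_status != "juvenile"]
    elif name == "juvenile":
        kept = [r for r in records if r.onto_status == "juvenile"]
    else:
        raise ValueError(f"unknown variant {name!r}; expected one of {VARIANT_NAMES}")
    if not kept:
        raise ValidationError(f"variant {name!r} selects no specimens")
    return DatasetVariant(name=name, records=tuple(kept))


def assign_clades(records, clade_table: dict[str, set[str]]) -> list[SpecimenRecord]:
    """Attach clade labels from a species -> clade-names map.

    Species absent from the table get an empty label set and a warning;
    a species may carry multiple nested labels.
    """
    out = []
    for r in records:
        if r.species not in clade_table:
            logger.warning("species %r absent from clade table; no labels", r.species)
            labels: frozenset[str] = frozenset()
        else:
            labels = frozenset(clade_table[r.species])
        out.append(replace(r, clade_labels=labels))
    return out


def species_age_ranges(records) -> dict[str, tuple[float, float]]:
    """Pooled stratigraphic range per species (union over its specimens)."""
    out: dict[str, tuple[float, float]] = {}
    for r in records:
        lo, hi = out.get(r.species, (r.age_min_ma, r.age_max_ma))
        out[r.species] = (min(lo, r.age_min_ma), max(hi, r.age_max_ma))
    return out


def species_to_specimens(records) -> dict[str, list[str]]:
    """Map species name -> specimen ids (tree-expansion input)."""
    out: dict[str, list[str]] = {}
    for r in records:
        out.setdefault(r.species, []).append(r.specimen_id)
    return out
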