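"""Measurement-level data model and per-species maximum-size summaries.

The unit of analysis is a *reported maximum size*: the largest linear
dimension (length, height, width, or diameter) published for a species in
some source.  A species with at least two such reports gets a summary with
the smallest, largest, and mean reported maximum (in cm), and the range
statistic

    maxsize_range = log10(maxsize_largest) - log10(maxsize_smallest),

measured in orders of magnitude.  No quality control is applied at ingest:
gross errors (unit slips, colony-vs-zooid confusion) are deliberately kept
so that downstream stages can quantify and flag them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SizeUnit",
    "Habitat",
    "Skeleton",
    "CountClass",
    "RangeMagnitude",
    "MeasurementRecord",
    "SpeciesAnnotation",
    "SpeciesSizeSummary",
    "SchemaError",
    "RowError",
    "read_measurements",
    "read_annotations",
    "to_cm",
    "assign_count_class",
    "summarize_species",
    "filter_phyla",
    "classify_range_magnitude",
    "summaries_to_frame",
    "write_summaries",
    "read_summaries",
]


class SizeUnit(str, Enum):
    """Accepted linear-size units; everything is converted to cm internally."""

    UM = "um"
    MM = "mm"
    CM = "cm"
    M = "m"


#: multiplicative factor taking a value in the given unit to centimetres
_CM_FACTOR = {SizeUnit.UM: 1e-4, SizeUnit.MM: 0.1, SizeUnit.CM: 1.0, SizeUnit.M: 100.0}


class Habitat(str, Enum):
    BENTHIC = "benthic"
    PELAGIC = "pelagic"
    UNSPECIFIED = "unspecified"


class Skeleton(str, Enum):
    NONE = "none"
    EXOSKELETON = "exoskeleton"
    ENDOSKELETON = "endoskeleton"


class CountClass(str, Enum):
    """Four-level categorisation of the number of reports per species."""

    C2 = "c2"
    C3 = "c3"
    C4_5 = "c4_5"
    C6PLUS = "c6plus"


class RangeMagnitude(str, Enum):
    """Disjoint magnitude classes of maxsize_range (orders of magnitude)."""

    ZERO = "zero"
    LT_HALF = "lt_half"
    HALF_TO_ONE = "half_to_one"
    ONE_TO_TWO = "one_to_two"
    GT_TWO = "gt_two"


class SchemaError(ValueError):
    """A required column is missing or the file cannot be interpreted."""


class RowError(ValueError):
    """A single row violates the measurement contract (carries the row number)."""

    def __init__(self, message: str, row: int):
        super().__init__(f"row {row}: {message}")
        self.row = row


@dataclass(frozen=True)
class MeasurementRecord:
    """One reported maximum size for one species from one source."""

    species_name: str
    aphia_id: int
    size_value: float
    size_unit: SizeUnit
    source_id: str

    def __post_init__(self):
        if not (self.size_value > 0):
            raise ValueError(f"size_value must be > 0, got {self.size_value}")

    @property
    def size_cm(self) -> float:
        return to_cm(self.size_value, self.size_unit)


@dataclass(frozen=True)
class SpeciesAnnotation:
    """Per-species taxonomy and ecology used as model covariates."""

    aphia_id: int
    phylum: str
    class_: str | None = None
    order_: str | None = None
    family_: str | None = None
    genus: str | None = None
    habitat: Habitat = Habitat.UNSPECIFIED
    skeleton: Skeleton = Skeleton.NONE
    invertebrate: bool | None = None

    @property
    def is_invertebrate(self) -> bool:
        # Chordata is the only phylum here with an endoskeletal vertebrate bauplan;
        # an explicit flag overrides the phylum-based default.
        if self.invertebrate is not None:
            return self.invertebrate
        return self.phylum.strip().lower() != "chordata"


@dataclass(frozen=True)
class SpeciesSizeSummary:
    """Per-species summary of reported maxima (all sizes in cm, logs base 10)."""

    aphia_id: int
    count: int
    count_class: CountClass
    maxsize_smallest: float
    maxsize_largest: float
    maxsize_mean: float
    maxsize_range: float

    def __post_init__(self):
        if not (self.maxsize_smallest <= self.maxsize_mean <= self.maxsize_largest):
            raise ValueError("summary ordering violated: smallest <= mean <= largest")
        if self.maxsize_range < 0:
            raise ValueError("maxsize_range must be >= 0")

    @property
    def log10_smallest(self) -> float:
        return math.log10(self.maxsize_smallest)

    @property
    def log10_largest(self) -> float:
        return math.log10(self.maxsize_largest)

    @property
    def log10_mean(self) -> float:
        return math.log10(self.maxsize_mean)


def to_cm(size_value: float, size_unit: SizeUnit | str) -> float:
    """Convert a positive linear size to centimetres.

    um x 1e-4, mm x 0.1, cm x 1, m x 100.
    """
    try:
        unit = SizeUnit(size_unit)
    except ValueError:
        accepted = ", ".join(u.value for u in SizeUnit)
        raise ValueError(f"unknown unit {size_unit!r}; accepted units: {accepted}") from None
    return size_value * _CM_FACTOR[unit]


def assign_count_class(count: int) -> CountClass:
    """Map a report count (>= 2) to the four-level count category."""
    if count < 2:
        raise ValueError(f"count must be >= 2, got {count}")
    if count == 2:
        return CountClass.C2
    if count == 3:
        return CountClass.C3
    if count <= 5:
        return CountClass.C4_5
    return CountClass.C6PLUS


_MEASUREMENT_COLS = ["species_name", "aphia_id", "size_value", "size_unit", "source_id"]
_ANNOTATION_COLS = ["aphia_id", "phylum"]


def read_measurements(
    path, unit_default: SizeUnit | str = SizeUnit.CM
) -> list[MeasurementRecord]:
    """Read a measurement CSV into records, retaining every row verbatim.

    Required columns: species_name, aphia_id, size_value, size_unit, source_id.
    An empty ``size_unit`` cell falls back to *unit_default*.  Sizes must be
    positive reals; no other quality control is applied.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _MEASUREMENT_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    default = SizeUnit(unit_default)
    records: list[MeasurementRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        raw_size = getattr(row, "size_value")
        try:
            size = float(raw_size)
        except ValueError:
            raise RowError(f"non-numeric size {raw_size!r}", i) from None
        if not (size > 0) or not math.isfinite(size):
            raise RowError(f"size must be a positive real, got {raw_size!r}", i)
        unit_token = getattr(row, "size_unit").strip().lower()
        if unit_token == "":
            unit = default
        else:
            try:
                unit = SizeUnit(unit_token)
            except ValueError:
                accepted = ", ".join(u.value for u in SizeUnit)
                raise RowError(
                    f"unknown unit {unit_token!r}; accepted units: {accepted}", i
                ) from None
        try:
            aphia = int(getattr(row, "aphia_id"))
        except ValueError:
            raise RowError(f"non-integer aphia_id {getattr(row, 'aphia_id')!r}", i) from None
        records.append(
            MeasurementRecord(
                species_name=getattr(row, "species_name"),
                aphia_id=aphia,
                size_value=size,
                size_unit=unit,
                source_id=getattr(row, "source_id"),
            )
        )
    return records


def read_annotations(path) -> list[SpeciesAnnotation]:
    """Read the per-species annotation CSV (taxonomy, habitat, skeleton).

    Habitat and skeleton tokens are case-insensitive; empty or unknown habitat
    maps to ``unspecified``.  An optional ``invertebrate`` column overrides the
    phylum-based default.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _ANNOTATION_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    annotations = []
    for i, row in df.iterrows():
        habitat_token = row.get("habitat", "").strip().lower()
        if habitat_token in ("", "unknown", "unspecified/unknown"):
            habitat = Habitat.UNSPECIFIED
        else:
            try:
                habitat = Habitat(habitat_token)
            except ValueError:
                habitat = Habitat.UNSPECIFIED
        skeleton_token = row.get("skeleton", "none").strip().lower()
        try:
            skeleton = Skeleton(skeleton_token)
        except ValueError:
            raise RowError(
                f"unknown skeleton {skeleton_token!r}; accepted: "
                + ", ".join(s.value for s in Skeleton),
                int(i) + 2,
            ) from None
        invert_token = row.get("invertebrate", "").strip().lower()
        invertebrate = None
        if invert_token in ("true", "1", "yes"):
            invertebrate = True
        elif invert_token in ("false", "0", "no"):
            invertebrate = False
        annotations.append(
            SpeciesAnnotation(
                aphia_id=int(row["aphia_id"]),
                phylum=row["phylum"],
                class_=row.get("class") or None,
                order_=row.get("order") or None,
                family_=row.get("family") or None,
                genus=row.get("genus") or None,
                habitat=habitat,
                skeleton=skeleton,
                invertebrate=invertebrate,
            )
        )
    return annotations


def summarize_species(
    records: Iterable[MeasurementRecord], mean_mode: str = "log_arithmetic"
) -> list[SpeciesSizeSummary]:
    """Collapse measurement records to one summary per species.

    All sizes are converted to cm first.  ``maxsize_range`` is the log10 ratio
    of the largest to the smallest reported maximum; a species whose reports
    are all identical after unit conversion gets a range of exactly 0.

    ``mean_mode`` selects the species mean: ``log_arithmetic`` (default) is the
    arithmetic mean of log10 sizes (the geometric mean on the raw scale, the
    scale every downstream analysis works on); ``raw_arithmetic`` is the plain
    arithmetic mean of cm values.

    Species with fewer than two reports are excluded with a warning: the study
    universe is species with at least two independent estimates.
    """
    if mean_mode not in ("log_arithmetic", "raw_arithmetic"):
        raise ValueError(f"unknown mean_mode {mean_mode!r}")

    by_species: dict[int, list[float]] = {}
    for rec in records:
        by_species.setdefault(rec.aphia_id, []).append(rec.size_cm)

    summaries = []
    for aphia_id in sorted(by_species):
        sizes = by_species[aphia_id]
        if len(sizes) < 2:
            logger.warning(
                "species %d has %d report(s); at least 2 required - excluded",
                aphia_id,
                len(sizes),
            )
            continue
        smallest, largest = min(sizes), max(sizes)
        if smallest == largest:
            rng = 0.0  # exact zero for all-equal reports, no log round-off
        else:
            rng = math.log10(largest) - math.log10(smallest)
        if mean_mode == "log_arithmetic":
            mean = 10 ** (sum(math.log10(s) for s in sizes) / len(sizes))
        else:
            mean = sum(sizes) / len(sizes)
        # guard against float round-off pushing the geometric mean past the bounds
        mean = min(max(mean, smallest), largest)
        summaries.append(
            SpeciesSizeSummary(
                aphia_id=aphia_id,
                count=len(sizes),
                count_class=assign_count_class(len(sizes)),
                maxsize_smallest=smallest,
                maxsize_largest=largest,
                maxsize_mean=mean,
                maxsize_range=rng,
            )
        )
    return summaries


def filter_phyla(
    summaries: Sequence[SpeciesSizeSummary],
    annotations: Mapping[int, SpeciesAnnotation] | Sequence[SpeciesAnnotation],
    min_species: int = 100,
) -> tuple[list[SpeciesSizeSummary], pd.DataFrame]:
    """Keep only species from phyla with at least ``min_species`` species.

    Returns the filtered summaries plus a per-phylum tally table (species
    totals and habitat/skeleton breakdowns) covering the *input* cohort, so
    the filter's effect is auditable.
    """
    ann = _as_annotation_map(annotations)
    for s in summaries:
        if s.aphia_id not in ann:
            raise KeyError(f"species {s.aphia_id} has no annotation")

    tally_rows: dict[str, dict[str, int]] = {}
    for s in summaries:
        a = ann[s.aphia_id]
        row = tally_rows.setdefault(
            a.phylum,
            {
                "n_species": 0,
                "benthic": 0,
                "pelagic": 0,
                "unspecified": 0,
                "skeleton_none": 0,
                "exoskeleton": 0,
                "endoskeleton": 0,
            },
        )
        row["n_species"] += 1
        row[a.habitat.value] += 1
        row[{"none": "skeleton_none", "exoskeleton": "exoskeleton", "endoskeleton": "endoskeleton"}[a.skeleton.value]] += 1

    tally = (
        pd.DataFrame.from_dict(tally_rows, orient="index")
        .rename_axis("phylum")
        .sort_index()
        .reset_index()
    )
    keep = {p for p, row in tally_rows.items() if row["n_species"] >= min_species}
    kept = [s for s in summaries if ann[s.aphia_id].phylum in keep]
    logger.info(
        "phylum filter (>=%d species): %d/%d species retained from %d/%d phyla",
        min_species,
        len(kept),
        len(summaries),
        len(keep),
        len(tally_rows),
    )
    return kept, tally


def classify_range_magnitude(maxsize_range: float) -> RangeMagnitude:
    """Bin a range (orders of magnitude) into disjoint magnitude classes.

    Zero is its own class; the interior bins are half-open [0.5, 1) and
    [1, 2]; ``gt_two`` is strictly above 2.
    """
    if maxsize_range < 0:
        raise ValueError(f"maxsize_range must be >= 0, got {maxsize_range}")
    if maxsize_range == 0:
        return RangeMagnitude.ZERO
    if maxsize_range > 2:
        return RangeMagnitude.GT_TWO
    if maxsize_range >= 1:
        return RangeMagnitude.ONE_TO_TWO
    if maxsize_range >= 0.5:
        return RangeMagnitude.HALF_TO_ONE
    return RangeMagnitude.LT_HALF


def summaries_to_frame(summaries: Sequence[SpeciesSizeSummary]) -> pd.DataFrame:
    """Summaries as a tidy DataFrame, one row per species."""
    return pd.DataFrame(
        {
            "aphia_id": [s.aphia_id for s in summaries],
            "count": [s.count for s in summaries],
            "count_class": [s.count_class.value for s in summaries],
            "maxsize_smallest": [s.maxsize_smallest for s in summaries],
            "maxsize_largest": [s.maxsize_largest for s in summaries],
            "maxsize_mean": [s.maxsize_mean for s in summaries],
            "log10_smallest": [s.log10_smallest for s in summaries],
            "log10_largest": [s.log10_largest for s in summaries],
            "log10_mean": [s.log10_mean for s in summaries],
            "maxsize_range": [s.maxsize_range for s in summaries],
        }
    )


def write_summaries(summaries: Sequence[SpeciesSizeSummary], path) -> None:
    """Write the per-species summary table as CSV with full float precision."""
    summaries_to_frame(summaries).to_csv(path, index=False)


def read_summaries(path) -> list[SpeciesSizeSummary]:
    """Re-read a summary CSV written by :func:`write_summaries`."""
    df = pd.read_csv(path, float_precision="round_trip")
    return [
        SpeciesSizeSummary(
            aphia_id=int(r.aphia_id),
            count=int(r.count),
            count_class=CountClass(r.count_class),
            maxsize_smallest=float(r.maxsize_smallest),
            maxsize_largest=float(r.maxsize_largest),
            maxsize_mean=float(r.maxsize_mean),
            maxsize_range=float(r.maxsize_range),
        )
        for r in df.itertuples(index=False)
    ]


def _as_annotation_map(
    annotations: Mapping[int, SpeciesAnnotation] | Sequence[SpeciesAnnotation],
) -> Mapping[int, SpeciesAnnotation]:
    if isinstance(annotations, Mapping):
        return annotations
    return {a.aphia_id: a for a in annotations}
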