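"""Cohort containers: labeled per-subject regional brain volumes.

The unit of analysis is one subject's set of medial-temporal-lobe (MTL)
sub-region volumes in mm^3, keyed by (region, hemisphere).  Cohorts are
exchanged as tidy CSV tables with the header
``subject_id,group,region,hemisphere,volume_mm3``.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .errors import CohortValidationError, IncompleteRecordError, SchemaError

logger = logging.getLogger(__name__)


class Region(str, enum.Enum):
    """The four MTL sub-regions whose atrophy marks Alzheimer's disease."""

    HIPPOCAMPUS = "hippocampus"
    AMYGDALA = "amygdala"
    ENTORHINAL = "entorhinal"
    PARAHIPPOCAMPAL = "parahippocampal"


class Hemisphere(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class Group(str, enum.Enum):
    AD = "AD"
    NC = "NC"
    UNKNOWN = "UNKNOWN"


#: Accepted spellings (lower-cased) for each region in input tables.
_REGION_ALIASES: dict[str, Region] = {
    "hippocampus": Region.HIPPOCAMPUS,
    "amygdala": Region.AMYGDALA,
    "entorhinal": Region.ENTORHINAL,
    "parahippocampal": Region.PARAHIPPOCAMPAL,
    "para-hippocampal": Region.PARAHIPPOCAMPAL,
    "para_hippocampal": Region.PARAHIPPOCAMPAL,
}

REQUIRED_COLUMNS = ("subject_id", "group", "region", "hemisphere", "volume_mm3")


@dataclass(frozen=True)
class MeasureSpec:
    """A volumetric measure: the sum of selected (region, hemisphere) volumes.

    The bilateral MTL measure sums all four regions over both hemispheres
    (eight terms); the bilateral hippocampus sums two.
    """

    name: str
    regions: frozenset[Region]
    hemispheres: frozenset[Hemisphere]

    def __post_init__(self) -> None:
        if not self.regions or not self.hemispheres:
            raise ValueError("MeasureSpec needs at least one region and hemisphere")

    def keys(self) -> tuple[tuple[Region, Hemisphere], ...]:
        """The (region, hemisphere) pairs this measure sums, in fixed order."""
        return tuple(
            (r, h)
            for r in sorted(self.regions, key=lambda r: r.value)
            for h in sorted(self.hemispheres, key=lambda h: h.value)
        )

    @staticmethod
    def bilateral(region: Region, name: str | None = None) -> "MeasureSpec":
        return MeasureSpec(
            name or f"{region.value}_total",
            frozenset({region}),
            frozenset({Hemisphere.LEFT, Hemisphere.RIGHT}),
        )

    @staticmethod
    def unilateral(region: Region, hemisphere: Hemisphere) -> "MeasureSpec":
        return MeasureSpec(
            f"{region.value}_{hemisphere.value}",
            frozenset({region}),
            frozenset({hemisphere}),
        )


#: Total MTL volume: all four regions, both hemispheres.
MTL = MeasureSpec(
    "mtl_total",
    frozenset(Region),
    frozenset({Hemisphere.LEFT, Hemisphere.RIGHT}),
)
#: Total (bilateral) hippocampal volume.
HIPPOCAMPUS_TOTAL = MeasureSpec.bilateral(Region.HIPPOCAMPUS, "hippocampus_total")

#: Named measures accepted by the CLI and run configs.
NAMED_MEASURES: dict[str, MeasureSpec] = {
    "mtl": MTL,
    "mtl_total": MTL,
    "hippocampus": HIPPOCAMPUS_TOTAL,
    "hippocampus_total": HIPPOCAMPUS_TOTAL,
    **{r.value: MeasureSpec.bilateral(r) for r in Region},
    **{
        f"{r.value}_{h.value}": MeasureSpec.unilateral(r, h)
        for r in Region
        for h in Hemisphere
    },
}


@dataclass
class SubjectRecord:
    """One subject's labeled volumes, at most one per (region, hemisphere)."""

    subject_id: str
    group: Group
    volumes: dict[tuple[Region, Hemisphere], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise CohortValidationError("subject_id must be non-empty")
        for (region, hemi), v in self.volumes.items():
            if not np.isfinite(v) or v <= 0:
                raise CohortValidationError(
                    f"subject {self.subject_id!r}: non-positive volume "
                    f"{v!r} for ({region.value}, {hemi.value})"
                )


def measure_value(record: SubjectRecord, spec: MeasureSpec) -> float:
    """Sum the record's volumes over the measure's (region, hemisphere) pairs.

    Raises IncompleteRecordError naming the first missing pair.
    """
    total = 0.0
    for key in spec.keys():
        try:
            total += record.volumes[key]
        except KeyError:
            region, hemi = key
            raise IncompleteRecordError(
                f"subject {record.subject_id!r} lacks volume for "
                f"({region.value}, {hemi.value}) required by measure {spec.name!r}"
            ) from None
    return total


@dataclass
class CohortTable:
    """An ordered collection of subject records with unique subject ids."""

    records: list[SubjectRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.subject_id in seen:
                raise CohortValidationError(
                    f"duplicate subject_id {rec.subject_id!r} in cohort "
                    f"{self.provenance!r}"
                )
            seen.add(rec.subject_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.records)

    def filter_group(self, group: Group) -> "CohortTable":
        return CohortTable(
            [r for r in self.records if r.group is group],
            provenance=f"{self.provenance}[{group.value}]",
        )

    def group_counts(self) -> dict[Group, int]:
        counts = {g: 0 for g in Group}
        for rec in self.records:
            counts[rec.group] += 1
        return counts

    def measure_values(self, spec: MeasureSpec, group: Group | None = None) -> np.ndarray:
        """Per-subject measure values (mm^3), optionally restricted to a group."""
        recs = self.records if group is None else [r for r in self.records if r.group is group]
        return np.array([measure_value(r, spec) for r in recs], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": rec.subject_id,
                "group": rec.group.value,
                "region": region.value,
                "hemisphere": hemi.value,
                "volume_mm3": vol,
            }
            for rec in self.records
            for (region, hemi), vol in sorted(
                rec.volumes.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)
            )
        ]
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


def _parse_group(raw: str) -> Group:
    token = str(raw).strip().upper()
    if token in ("AD", "NC"):
        return Group(token)
    return Group.UNKNOWN


def load_cohort_csv(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    provenance: str | None = None,
) -> CohortTable:
    """Read a tidy volume CSV into a validated CohortTable.

    ``schema`` optionally maps the canonical column names
    (subject_id, group, region, hemisphere, volume_mm3) to the file's actual
    column names.  Region and hemisphere strings are normalized
    case-insensitively; rows naming regions outside the four MTL sub-regions
    are skipped with a logged warning (FreeSurfer exports carry dozens of
    regions the analysis never uses).
    """
    path = Path(path)
    rename = {v: k for k, v in (schema or {}).items()}
    df = pd.read_csv(path).rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    records: dict[str, SubjectRecord] = {}
    for idx, row in df.iterrows():
        region_token = str(row["region"]).strip().lower()
        region = _REGION_ALIASES.get(region_token)
        if region is None:
            logger.warning("%s row %d: skipping unknown region %r", path, idx, region_token)
            continue
        hemi_token = str(row["hemisphere"]).strip().lower()
        try:
            hemi = Hemisphere(hemi_token)
        except ValueError:
            raise CohortValidationError(
                f"{path} row {idx}: unknown hemisphere {hemi_token!r}"
            ) from None
        try:
            volume = float(row["volume_mm3"])
        except (TypeError, ValueError):
            raise CohortValidationError(
                f"{path} row {idx}: non-numeric volume {row['volume_mm3']!r}"
            ) from None
        if not np.isfinite(volume) or volume <= 0:
            raise CohortValidationError(
                f"{path} row {idx}: non-positive volume {volume!r}"
            )
        subject_id = str(row["subject_id"]).strip()
        if not subject_id:
            raise CohortValidationError(f"{path} row {idx}: empty subject_id")
        rec = records.get(subject_id)
        if rec is None:
            rec = records[subject_id] = SubjectRecord(subject_id, _parse_group(row["group"]), {})
        if (region, hemi) in rec.volumes:
            raise CohortValidationError(
                f"{path} row {idx}: duplicate entry for subject {subject_id!r}, "
                f"({region.value}, {hemi.value})"
            )
        rec.volumes[(region, hemi)] = volume
    return CohortTable(list(records.values()), provenance=provenance or path.stem)


def write_cohort_csv(table: CohortTable, path: str | Path) -> None:
    """Write a cohort as a tidy CSV; volumes serialized at full float precision."""
    df = table.to_dataframe()
    df["volume_mm3"] = [repr(float(v)) for v in df["volume_mm3"]]
    df.to_csv(path, index=False)


def concat_cohorts(tables: Iterable[CohortTable], provenance: str = "") -> CohortTable:
    records: list[SubjectRecord] = []
    for t in tables:
        records.extend(t.records)
    return CohortTable(records, provenance=provenance)
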