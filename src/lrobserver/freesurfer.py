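"""Readers for FreeSurfer stats tables (aseg.stats / ?h.aparc.stats).

Only the volumes the MTL analysis needs are extracted: hippocampus and
amygdala from the subcortical segmentation table (``Volume_mm3`` column of
``aseg.stats``) and entorhinal / parahippocampal gray-matter volumes from the
per-hemisphere cortical parcellation tables (``GrayVol`` column of
``?h.aparc.stats``, Desikan-Killiany names).  Running FreeSurfer itself, or
reading images, is out of scope.
"""
from __future__ import annotations

from pathlib import Path

from .cohort import Group, Hemisphere, Region, SubjectRecord
from .errors import MissingStructureError, StatsParseError

# aseg StructName -> (region, hemisphere)
_ASEG_STRUCTURES = {
    "Left-Hippocampus": (Region.HIPPOCAMPUS, Hemisphere.LEFT),
    "Right-Hippocampus": (Region.HIPPOCAMPUS, Hemisphere.RIGHT),
    "Left-Amygdala": (Region.AMYGDALA, Hemisphere.LEFT),
    "Right-Amygdala": (Region.AMYGDALA, Hemisphere.RIGHT),
}
# aparc StructName -> region (hemisphere comes from the file)
_APARC_STRUCTURES = {
    "entorhinal": Region.ENTORHINAL,
    "parahippocampal": Region.PARAHIPPOCAMPAL,
}


def parse_stats_table(path: str | Path) -> list[dict[str, str]]:
    """Parse a FreeSurfer stats file into one dict per data row.

    The column names are taken from the ``# ColHeaders`` comment line; data
    rows are whitespace-delimited.
    """
    path = Path(path)
    headers: list[str] | None = None
    rows: list[dict[str, str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            if stripped.startswith("# ColHeaders"):
                headers = stripped.removeprefix("# ColHeaders").split()
            continue
        if headers is None:
            raise StatsParseError(f"{path}: data row before any '# ColHeaders' line")
        fields = stripped.split()
        if len(fields) != len(headers):
            raise StatsParseError(
                f"{path} line {lineno}: expected {len(headers)} fields, got {len(fields)}"
            )
        rows.append(dict(zip(headers, fields)))
    if headers is None:
        raise StatsParseError(f"{path}: no '# ColHeaders' line found")
    return rows


def _extract(path: Path, wanted: dict[str, tuple[Region, Hemisphere]], column: str):
    rows = parse_stats_table(path)
    by_name = {row.get("StructName"): row for row in rows}
    found: dict[tuple[Region, Hemisphere], float] = {}
    missing: list[str] = []
    for name, key in wanted.items():
        row = by_name.get(name)
        if row is None or column not in row:
            missing.append(name)
            continue
        try:
            found[key] = float(row[column])
        except ValueError:
            raise StatsParseError(
                f"{path}: non-numeric {column} for {name!r}: {row[column]!r}"
            ) from None
    if missing:
        raise MissingStructureError(f"{path}: missing structure(s) {missing}")
    return found


def load_freesurfer_stats(
    aseg_path: str | Path,
    aparc_left_path: str | Path,
    aparc_right_path: str | Path,
    subject_id: str,
    group: Group,
) -> SubjectRecord:
    """Assemble one SubjectRecord from a subject's three stats files."""
    volumes: dict[tuple[Region, Hemisphere], float] = {}
    volumes.update(_extract(Path(aseg_path), _ASEG_STRUCTURES, "Volume_mm3"))
    for aparc_path, hemi in (
        (Path(aparc_left_path), Hemisphere.LEFT),
        (Path(aparc_right_path), Hemisphere.RIGHT),
    ):
        wanted = {name: (region, hemi) for name, region in _APARC_STRUCTURES.items()}
        volumes.update(_extract(aparc_path, wanted, "GrayVol"))
    return SubjectRecord(subject_id=subject_id, group=group, volumes=volumes)
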