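"""Observation-window and site-environment data model and file I/O.

The atomic field record is one five-minute census of the bird species
present at one army-ant swarm on one day (an *observation window*).  A
swarm followed on a given day is the sampling unit for one network, so
records are grouped by the (site, swarm, date) key.

File formats are plain delimited text (CSV by default, UTF-8, header
required).  The species present in a window are stored in a single cell
separated by a configurable sub-delimiter (default ``";"``).
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import SchemaError, ValidationError

WINDOW_COLUMNS = ("site_id", "swarm_id", "date", "window_index", "species")
SITE_COLUMNS = ("site_id", "rainfall_mm", "suitability")


@dataclass(frozen=True, order=True)
class SwarmKey:
    """Identity of one network: one swarm followed on one calendar day."""

    site_id: str
    swarm_id: str
    date: _dt.date


@dataclass(frozen=True)
class ObservationWindow:
    """One 5-minute census of species present at a swarm."""

    site_id: str
    swarm_id: str
    date: _dt.date
    window_index: int
    species: frozenset[str]

    @property
    def key(self) -> SwarmKey:
        return SwarmKey(self.site_id, self.swarm_id, self.date)


@dataclass(frozen=True)
class SiteEnvironment:
    """Per-site environmental covariates.

    rainfall : mean annual rainfall, mm/yr (> 0)
    suitability : proportion of suitable habitat in [0, 1]
    """

    site_id: str
    rainfall: float
    suitability: float

    def __post_init__(self):
        if not self.rainfall > 0:
            raise ValidationError(
                f"site {self.site_id!r}: rainfall must be > 0, got {self.rainfall}"
            )
        if not 0.0 <= self.suitability <= 1.0:
            raise ValidationError(
                f"site {self.site_id!r}: suitability must be in [0, 1], "
                f"got {self.suitability}"
            )


def _parse_species_cell(cell: str, species_sep: str) -> frozenset[str]:
    names = [s.strip() for s in cell.split(species_sep)]
    names = [s for s in names if s]
    return frozenset(names)


def read_windows(
    path: str | Path,
    *,
    delimiter: str = ",",
    species_sep: str = ";",
) -> list[ObservationWindow]:
    """Read and validate observation windows from a delimited text file.

    Species strings are whitespace-trimmed and duplicates within one
    window collapse to a set.  Raises :class:`SchemaError` for a missing
    column and :class:`ValidationError` (with the line number) for an
    empty species cell, a bad date/index, or a repeated window_index
    within one swarm-day.
    """
    path = Path(path)
    records: list[ObservationWindow] = []
    seen: set[tuple[SwarmKey, int]] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for col in WINDOW_COLUMNS:
            if col not in header:
                raise SchemaError(f"{path}: missing required column {col!r}")
        for lineno, row in enumerate(reader, start=2):
            species = _parse_species_cell(row["species"] or "", species_sep)
            if not species:
                raise ValidationError(f"{path}:{lineno}: empty species cell")
            try:
                date = _dt.date.fromisoformat(row["date"].strip())
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: bad date: {exc}") from exc
            try:
                window_index = int(row["window_index"])
            except ValueError as exc:
                raise ValidationError(
                    f"{path}:{lineno}: bad window_index {row['window_index']!r}"
                ) from exc
            if window_index < 1:
                raise ValidationError(
                    f"{path}:{lineno}: window_index must be >= 1, got {window_index}"
                )
            rec = ObservationWindow(
                site_id=row["site_id"].strip(),
                swarm_id=row["swarm_id"].strip(),
                date=date,
                window_index=window_index,
                species=species,
            )
            dup_key = (rec.key, window_index)
            if dup_key in seen:
                raise ValidationError(
                    f"{path}:{lineno}: window_index {window_index} repeated "
                    f"within swarm-day {rec.key}"
                )
            seen.add(dup_key)
            records.append(rec)
    return records


def write_windows(
    records: Iterable[ObservationWindow],
    path: str | Path,
    *,
    delimiter: str = ",",
    species_sep: str = ";",
) -> None:
    """Write windows as delimited text, rows sorted by (key, window_index)."""
    rows = sorted(records, key=lambda r: (r.key, r.window_index))
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(WINDOW_COLUMNS)
        for r in rows:
            writer.writerow(
                [
                    r.site_id,
                    r.swarm_id,
                    r.date.isoformat(),
                    r.window_index,
                    species_sep.join(sorted(r.species)),
                ]
            )


def read_site_env(path: str | Path, *, delimiter: str = ",") -> dict[str, SiteEnvironment]:
    """Read the per-site environment table (site_id, rainfall_mm, suitability)."""
    path = Path(path)
    out: dict[str, SiteEnvironment] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames
        if header is None:
            raise ValidationError(f"{path}: empty site table")
        for col in SITE_COLUMNS:
            if col not in header:
                raise SchemaError(f"{path}: missing required column {col!r}")
        for lineno, row in enumerate(reader, start=2):
            site_id = row["site_id"].strip()
            if site_id in out:
                raise ValidationError(f"{path}:{lineno}: duplicate site_id {site_id!r}")
            try:
                rainfall = float(row["rainfall_mm"])
                suitability = float(row["suitability"])
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-numeric value: {exc}") from exc
            out[site_id] = SiteEnvironment(site_id, rainfall, suitability)
    if not out:
        raise ValidationError(f"{path}: site table has no data rows")
    return out


def write_site_env(
    sites: Mapping[str, SiteEnvironment] | Iterable[SiteEnvironment],
    path: str | Path,
) -> None:
    if isinstance(sites, Mapping):
        sites = sites.values()
    rows = sorted(sites, key=lambda s: s.site_id)
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SITE_COLUMNS)
        for s in rows:
            writer.writerow([s.site_id, repr(s.rainfall), repr(s.suitability)])


def group_by_swarm(
    windows: Sequence[ObservationWindow],
) -> dict[SwarmKey, list[ObservationWindow]]:
    """Partition windows by swarm-day, sorted by window_index within each key.

    Group sizes sum to the input length; keys with zero windows are never
    emitted.
    """
    groups: dict[SwarmKey, list[ObservationWindow]] = {}
    for w in windows:
        groups.setdefault(w.key, []).append(w)
    for key in groups:
        groups[key].sort(key=lambda w: w.window_index)
    return dict(sorted(groups.items()))
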